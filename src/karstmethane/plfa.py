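"""PLFA tools: FAME methylation correction and dose–response regression.

Transesterification adds one methyl carbon (from the derivatization
methanol) to each fatty acid, so the measured δ¹³C of the methyl ester
(FAME) is a (n+1)-carbon mixture.  The mass-balance correction recovers
the free fatty acid value:

    δ¹³C_PLFA = [(n+1)·δ¹³C_FAME − δ¹³C_methanol] / n

with n the number of carbon atoms in the free fatty acid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "correct_fame_delta",
    "fame_from_plfa_delta",
    "DoseResponseFit",
    "dose_response",
]


def correct_fame_delta(delta_fame, n_carbons: int, delta_methanol: float):
    """Correct a measured FAME δ¹³C for the derivatization methyl carbon."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    delta_fame = np.asarray(delta_fame, dtype=float)
    out = ((n_carbons + 1) * delta_fame - delta_methanol) / n_carbons
    return float(out) if out.ndim == 0 else out


def fame_from_plfa_delta(delta_plfa, n_carbons: int, delta_methanol: float):
    """Inverse correction: free-fatty-acid δ¹³C → expected FAME δ¹³C."""
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    delta_plfa = np.asarray(delta_plfa, dtype=float)
    out = (n_carbons * delta_plfa + delta_methanol) / (n_carbons + 1)
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseFit:
    """OLS fit of a per-compound response against total CH₄ added."""

    compound: str
    response: str  # "concentration" or "delta_plfa"
    slope: float
    intercept: float
    se_slope: float
    r_squared: float
    residuals: np.ndarray
    n: int
    nonpositive_slope: bool


def _ols(x, y):
    X = sm.add_constant(np.asarray(x, dtype=float))
    return sm.OLS(np.asarray(y, dtype=float), X).fit()


def dose_response(endpoints, total_ch4_added: dict) -> dict:
    """Per-compound linear dose–response of PLFA concentration and δ¹³C.

    Parameters
    ----------
    endpoints : sequence of SedimentEndpoint
        Replicate endpoints across dose levels; replicates of a treatment
        are averaged before the (unweighted) regression on treatment means.
    total_ch4_added : dict
        treatment_id → total CH₄ added per bottle (ng).

    Returns
    -------
    dict
        compound → {"concentration": DoseResponseFit, "delta_plfa": DoseResponseFit}.
        δ¹³C values are methylation-corrected before fitting.
    """
    per = {}
    for e in endpoints:
        if e.treatment_id not in total_ch4_added:
            continue
        dose = total_ch4_added[e.treatment_id]
        for r in e.plfa_records:
            d = correct_fame_delta(r.delta_fame, r.n_carbons, e.delta_methanol)
            per.setdefault(r.compound, {}).setdefault(
                e.treatment_id, {"dose": dose, "conc": [], "delta": []}
            )
            per[r.compound][e.treatment_id]["conc"].append(r.concentration)
            per[r.compound][e.treatment_id]["delta"].append(d)

    fits: dict = {}
    for comp, treatments in per.items():
        doses = [v["dose"] for v in treatments.values()]
        if len(set(doses)) < 3:
            raise ValueError(
                f"compound {comp}: at least 3 dose levels required, "
                f"got {len(set(doses))}"
            )
        conc = [float(np.mean(v["conc"])) for v in treatments.values()]
        delt = [float(np.mean(v["delta"])) for v in treatments.values()]
        fits[comp] = {}
        for name, y in (("concentration", conc), ("delta_plfa", delt)):
            res = _ols(doses, y)
            slope = float(res.params[1])
            fits[comp][name] = DoseResponseFit(
                compound=comp,
                response=name,
                slope=slope,
                intercept=float(res.params[0]),
                se_slope=float(res.bse[1]),
                r_squared=float(res.rsquared),
                residuals=np.asarray(res.resid),
                n=len(y),
                nonpositive_slope=slope <= 0,
            )
    return fits
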