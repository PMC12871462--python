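"""Stable carbon isotope arithmetic and the ¹³C mass balance.

Conventions
-----------
δ¹³C values are per mil (‰) relative to VPDB.  Atom percent (AT%) is the
percentage of carbon atoms that are ¹³C.  The two are related through the
isotope ratio R = ¹³C/¹²C of the standard:

    AT% = 100 · (δ/1000 + 1)·Rst / (1 + (δ/1000 + 1)·Rst)

¹³C *masses* in per-bottle inventories use the isotopic molar mass
13.003 g mol⁻¹; the published-form sediment excess (``excess_13c_soc``)
is kept exactly in its printed form, which folds the conversion constants
into a factor of 100 and therefore reports mass on the average-carbon
(≈12 g mol⁻¹) scale.  The per-bottle budget uses the atom-consistent
path throughout so that supplied, residual, respired and assimilated
¹³C close to 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "R_VPDB",
    "M_12C",
    "M_13C",
    "M_C",
    "M_CH4",
    "R_GAS_L_ATM",
    "IsotopeConstants",
    "IsotopeBudget",
    "atom_percent",
    "atom_fraction",
    "delta_from_atom_percent",
    "delta_from_atom_fraction",
    "natural_atom_percent",
    "excess_13c_soc",
    "co2_13c_inventory",
    "supplied_13c",
    "assimilation_efficiency",
]

#: ¹³C/¹²C ratio of the VPDB reference standard.
R_VPDB = 0.0111802

#: Exact-isotope and average molar masses (g mol⁻¹).
M_12C = 12.000
M_13C = 13.003
M_C = 12.011
M_CH4 = 16.04

#: Gas constant in L·atm·mol⁻¹·K⁻¹ (ideal-gas headspace arithmetic).
R_GAS_L_ATM = 0.0820573


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference-standard constants used throughout the mass balance."""

    r_standard: float = R_VPDB
    natural_at: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "natural_at", atom_percent(0.0, self.r_standard)
        )


def atom_percent(delta, r_standard: float = R_VPDB):
    """Convert δ¹³C (‰ vs. standard) to ¹³C atom percent.

    Parameters
    ----------
    delta : float or array_like
        δ¹³C in per mil; must be ≥ −1000 (−1000 ‰ means zero ¹³C).
    r_standard : float
        ¹³C/¹²C ratio of the reference standard (default VPDB).

    Returns
    -------
    float or ndarray
        Atom percent in [0, 100); strictly increasing in ``delta``.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000.0):
        raise ValueError("delta below -1000 permil is unphysical")
    r = (delta / 1000.0 + 1.0) * r_standard
    out = 100.0 * r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def atom_fraction(delta, r_standard: float = R_VPDB):
    """¹³C atom fraction (0–1) for a δ¹³C value."""
    return atom_percent(delta, r_standard) / 100.0


def delta_from_atom_percent(at, r_standard: float = R_VPDB):
    """Invert :func:`atom_percent`: atom percent → δ¹³C (‰).

    ``at`` must lie strictly inside (0, 100).
    """
    at = np.asarray(at, dtype=float)
    if np.any(at <= 0.0) or np.any(at >= 100.0):
        raise ValueError("atom percent must lie strictly in (0, 100)")
    r = (at / (100.0 - at)) / r_standard
    out = (r - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def delta_from_atom_fraction(x, r_standard: float = R_VPDB):
    """Atom fraction (0–1) → δ¹³C (‰)."""
    return delta_from_atom_percent(np.asarray(x, dtype=float) * 100.0, r_standard)


def natural_atom_percent(r_standard: float = R_VPDB) -> float:
    """Atom percent at δ = 0 (natural abundance on the standard's scale)."""
    return atom_percent(0.0, r_standard)


def excess_13c_soc(toc: float, at_labeled: float, at_unlabeled: float) -> float:
    """Excess ¹³C in sediment organic carbon, mg per kg dry sediment.

    Published mass-balance form::

        13C_SOC (mg kg⁻¹) = 10 × TOC(%) × [AT(%)_labeled − AT(%)_unlabeled] × 10

    i.e. 1% TOC with a 1-percentage-point atom excess carries 100 mg kg⁻¹.
    Negative results (possible within measurement noise) are returned as-is;
    callers flag rather than clamp them.
    """
    if toc < 0:
        raise ValueError("toc must be nonnegative")
    for at in (at_labeled, at_unlabeled):
        if not 0.0 <= at <= 100.0:
            raise ValueError("atom percent must lie in [0, 100]")
    return 10.0 * toc * (at_labeled - at_unlabeled) * 10.0


def _headspace_mol(ppmv: float, volume_l: float, temperature_c: float,
                   pressure_atm: float) -> float:
    tk = temperature_c + 273.15
    return ppmv * 1e-6 * pressure_atm * volume_l / (R_GAS_L_ATM * tk)


def co2_13c_inventory(series, config, r_standard: float = R_VPDB,
                      baseline=None) -> float:
    """¹³C inventory of the CO₂ pools of one bottle, in µg.

    Sums the final headspace CO₂ (ppm and δ¹³C of the last observation,
    converted to mol C by the ideal-gas law and to ¹³C mass through the
    atom fraction and 13.003 g mol⁻¹) and the cumulative ¹³C removed by
    headspace swaps/flushes logged in ``vented_co2_13c``.

    If ``baseline`` (the paired unlabeled/ambient control series) is given,
    the same inventory of the control is subtracted, yielding excess ¹³C
    above natural abundance and background respiration.

    Raises
    ------
    ValueError
        If the series has no observations (missing endpoint).
    """
    if len(series.time) == 0:
        raise ValueError(
            f"series {series.treatment_id}/{series.replicate}: "
            "no observations; endpoint measurement missing"
        )
    co2_ppm = float(series.co2[-1])
    delta = float(series.delta_co2[-1])
    total = float(series.vented_co2_13c[-1])  # µg, cumulative
    if co2_ppm > 0 and math.isfinite(delta):
        mol = _headspace_mol(co2_ppm, config.headspace_volume,
                             config.temperature, config.pressure)
        total += mol * atom_fraction(delta, r_standard) * M_13C * 1e6
    if baseline is not None:
        total -= co2_13c_inventory(baseline, config, r_standard, baseline=None)
    return total


def supplied_13c(config, target_ppm: float, label_atom_fraction: float | None = None,
                 r_standard: float = R_VPDB, excess: bool = True) -> float:
    """¹³C supplied to one bottle over the incubation, in µg.

    The injection log is reconstructed from the design: one injection to the
    target mixing ratio at t = 0 and at every replenishment interval before
    the end of the incubation.  Under the study conditions each cycle's CH₄
    is fully consumed before the next injection, so every injection adds the
    full target amount; all injected label is counted, including label
    consumed before the mid-incubation headspace swap.

    With ``excess=True`` (default) the natural-abundance ¹³C the same amount
    of unlabeled CH₄ would carry is subtracted, giving the excess ¹³C that
    the mass balance traces.
    """
    if label_atom_fraction is None:
        label_atom_fraction = config.label_atom_fraction
    n_inj = int(math.floor(config.duration / config.replenish_interval - 1e-9)) + 1
    mol_per_inj = _headspace_mol(target_ppm, config.headspace_volume,
                                 config.temperature, config.pressure)
    x = label_atom_fraction
    if excess:
        x = x - natural_atom_percent(r_standard) / 100.0
    return n_inj * mol_per_inj * x * M_13C * 1e6


def _mean(values) -> float:
    return float(np.mean(np.asarray(values, dtype=float)))


@dataclass
class IsotopeBudget:
    """Per-treatment ¹³C ledger (all masses µg per bottle, excess over control).

    ``efficiency`` is the share of supplied excess ¹³C recovered in sediment
    organic carbon; ``partition_*`` give the biomass/CO₂ split of the supplied
    label; ``recovery`` sums residual CH₄, CO₂ and SOC pools.
    """

    treatment_id: str
    supplied_13c: float
    supplied_13c_gross: float
    residual_ch4_13c: float
    co2_13c: float
    soc_excess_13c: float
    soc_excess_mg_per_kg: float
    assimilation_efficiency: float
    partition_biomass: float
    partition_co2: float
    recovery: float
    qc_negative_excess: bool = False


def assimilation_efficiency(endpoints_labeled, endpoints_unlabeled,
                            supplied_13c_ug: float, config, *,
                            series_labeled=None, series_unlabeled=None,
                            supplied_13c_gross: float | None = None,
                            r_standard: float = R_VPDB) -> IsotopeBudget:
    """Carbon assimilation efficiency and ¹³C partitioning for one treatment.

    Parameters
    ----------
    endpoints_labeled, endpoints_unlabeled : sequence of SedimentEndpoint
        Replicate end-of-incubation measurements for the labeled treatment
        and its paired unlabeled (or ambient) control at the same CH₄ level.
    supplied_13c_ug : float
        Excess ¹³C supplied per bottle (µg); see :func:`supplied_13c`.
    series_labeled, series_unlabeled : sequence of HeadspaceSeries, optional
        Replicate gas time series; required for the CO₂ partition and the
        residual-CH₄ term of the recovery.

    Notes
    -----
    TOC excess is converted from atom fractions to µg ¹³C through mol C and
    13.003 g mol⁻¹ so that it is commensurable with the gas-phase inventories;
    the printed-form mg kg⁻¹ quantity (average-carbon mass scale) is reported
    alongside as ``soc_excess_mg_per_kg``.
    """
    if len(endpoints_labeled) == 0 or len(endpoints_unlabeled) == 0:
        raise ValueError("paired labeled and unlabeled endpoints are required")
    if supplied_13c_ug <= 0:
        raise ValueError("supplied_13c_ug must be positive")
    tid = endpoints_labeled[0].treatment_id

    toc_lab = _mean([e.toc for e in endpoints_labeled])
    at_lab = _mean([atom_percent(e.delta_toc, r_standard) for e in endpoints_labeled])
    at_unl = _mean([atom_percent(e.delta_toc, r_standard) for e in endpoints_unlabeled])

    # Printed-form excess (mg per kg dry sediment).
    soc_mg_kg = excess_13c_soc(toc_lab, at_lab, at_unl)

    # Atom-consistent per-bottle excess: TOC mass -> mol C -> excess 13C mass.
    x_lab = at_lab / 100.0
    mass_c = toc_lab / 100.0 * config.sediment_dry_mass  # g C per bottle
    mbar = M_12C * (1.0 - x_lab) + M_13C * x_lab
    mol_c = mass_c / mbar
    soc_ug = mol_c * (at_lab - at_unl) / 100.0 * M_13C * 1e6

    efficiency = soc_ug / supplied_13c_ug * 100.0

    co2_ug = float("nan")
    residual_ug = 0.0
    if series_labeled is not None:
        pairs = zip(series_labeled, series_unlabeled or [None] * len(series_labeled))
        co2_vals = [co2_13c_inventory(s, config, r_standard, baseline=b)
                    for s, b in pairs]
        co2_ug = _mean(co2_vals)
        x_nat = natural_atom_percent(r_standard) / 100.0
        res = []
        for s in series_labeled:
            mol = _headspace_mol(float(s.ch4[-1]), config.headspace_volume,
                                 config.temperature, config.pressure)
            res.append(mol * (float(s.ch4_13f[-1]) - x_nat) * M_13C * 1e6)
        residual_ug = _mean(res)

    partition_biomass = efficiency
    partition_co2 = (co2_ug / supplied_13c_ug * 100.0
                     if math.isfinite(co2_ug) else float("nan"))
    recovery = (residual_ug + soc_ug
                + (co2_ug if math.isfinite(co2_ug) else 0.0)) / supplied_13c_ug * 100.0

    if supplied_13c_gross is None:
        supplied_13c_gross = supplied_13c_ug
    return IsotopeBudget(
        treatment_id=tid,
        supplied_13c=supplied_13c_ug,
        supplied_13c_gross=supplied_13c_gross,
        residual_ch4_13c=residual_ug,
        co2_13c=co2_ug,
        soc_excess_13c=soc_ug,
        soc_excess_mg_per_kg=soc_mg_kg,
        assimilation_efficiency=efficiency,
        partition_biomass=partition_biomass,
        partition_co2=partition_co2,
        recovery=recovery,
        qc_negative_excess=soc_ug < 0,
    )
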