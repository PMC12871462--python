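"""Oxidation-rate estimation, Michaelis–Menten fitting and gas-unit conversions.

Rates are expressed as ng CH₄ per g dry sediment per hour.  The
half-saturation constant is fitted on the measured axis (headspace ppmv)
and converted to the aqueous concentration the enzyme actually sees using
the Bunsen solubility coefficient, with the ideal-gas molar volume
evaluated at the incubation temperature (24.055 L mol⁻¹ at 20 °C) — the
convention that maps 138.8 ppm to 196 nM at β = 0.034.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .isotopes import M_CH4, R_GAS_L_ATM

__all__ = [
    "RateEstimate",
    "KineticsFit",
    "ppm_to_mass",
    "mass_to_ppm",
    "headspace_to_aqueous",
    "aqueous_to_headspace",
    "specific_affinity",
    "estimate_oxidation_rate",
    "fit_michaelis_menten",
    "michaelis_menten",
]


def _check_temperature(temperature: float) -> float:
    tk = temperature + 273.15
    if tk <= 0:
        raise ValueError("temperature must be above absolute zero")
    return tk


def molar_volume(temperature: float, pressure: float = 1.0) -> float:
    """Ideal-gas molar volume (L mol⁻¹) at the given temperature/pressure."""
    return R_GAS_L_ATM * _check_temperature(temperature) / pressure


def ppm_to_mass(mixing_ratio: float, volume: float, temperature: float,
                pressure: float = 1.0) -> float:
    """CH₄ mass (ng) in a headspace of ``volume`` liters at ``mixing_ratio`` ppmv."""
    if mixing_ratio < 0 or volume < 0 or pressure < 0:
        raise ValueError("mixing ratio, volume and pressure must be nonnegative")
    tk = _check_temperature(temperature)
    mol = mixing_ratio * 1e-6 * pressure * volume / (R_GAS_L_ATM * tk)
    return mol * M_CH4 * 1e9


def mass_to_ppm(mass_ng: float, volume: float, temperature: float,
                pressure: float = 1.0) -> float:
    """Inverse of :func:`ppm_to_mass`."""
    tk = _check_temperature(temperature)
    mol = mass_ng * 1e-9 / M_CH4
    return mol * R_GAS_L_ATM * tk / (pressure * volume) * 1e6


def headspace_to_aqueous(mixing_ratio: float, temperature: float = 20.0,
                         pressure: float = 1.0, bunsen: float = 0.034) -> float:
    """Headspace mixing ratio (ppmv) → dissolved CH₄ concentration (nM).

    C_aq = β · (x·P) / V_m(T), with V_m the ideal-gas molar volume at the
    incubation temperature.  (138.8 ppm, 20 °C, 1 atm, β = 0.034) → 196 nM.
    """
    if mixing_ratio < 0 or pressure < 0 or bunsen < 0:
        raise ValueError("inputs must be nonnegative")
    vm = molar_volume(temperature, 1.0)
    return bunsen * (mixing_ratio * 1e-6 * pressure) / vm * 1e9


def aqueous_to_headspace(conc_nm: float, temperature: float = 20.0,
                         pressure: float = 1.0, bunsen: float = 0.034) -> float:
    """Dissolved CH₄ (nM) → headspace mixing ratio (ppmv); inverse conversion."""
    if bunsen <= 0 or pressure <= 0:
        raise ValueError("bunsen and pressure must be positive")
    vm = molar_volume(temperature, 1.0)
    return conc_nm * 1e-9 * vm / (bunsen * pressure) * 1e6


def specific_affinity(vmax: float, km_aq: float, gene_copies_per_g: float,
                      genes_per_cell: float = 1.0) -> float:
    """Per-cell specific affinity a⁰ₛ = Vmax(app)/Km(app), L cell⁻¹ h⁻¹.

    ``vmax`` is ng CH₄ g⁻¹ h⁻¹; cell density is ``gene_copies_per_g`` marker
    copies per gram divided by ``genes_per_cell`` (one particulate methane
    monooxygenase gene copy per cell by default); ``km_aq`` is nM.
    """
    if km_aq <= 0 or gene_copies_per_g <= 0 or genes_per_cell <= 0:
        raise ValueError("km_aq, gene_copies_per_g and genes_per_cell must be positive")
    if vmax < 0:
        raise ValueError("vmax must be nonnegative")
    cells_per_g = gene_copies_per_g / genes_per_cell
    vmax_mol_per_cell = vmax * 1e-9 / M_CH4 / cells_per_g
    return vmax_mol_per_cell / (km_aq * 1e-9)


@dataclass
class RateEstimate:
    """Initial methane oxidation rate of one bottle."""

    treatment_id: str
    replicate: int
    initial_ppm: float
    rate: float          # ng CH4 g^-1 dry h^-1
    se_rate: float
    window: tuple[float, float]
    method: str
    n_points: int


@dataclass
class KineticsFit:
    """Michaelis–Menten fit: v = Vmax·S/(Km + S) on the headspace-ppm axis."""

    vmax: float
    km_ppm: float
    km_aq: float
    se_vmax: float
    se_km_ppm: float
    r_squared: float
    n_points: int
    converged: bool
    sse: float = float("nan")


def michaelis_menten(s, vmax, km):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def _initial_window(time, ch4, events, max_drawdown: float):
    """Observation mask for the initial-rate window of the first cycle.

    Takes consecutive points from the series start until either the next
    replenish/swap event or until CH₄ has fallen below
    (1 − max_drawdown) × the starting value, whichever comes first, and
    always keeps at least three points (bias grows with drawdown, so fine
    early sampling is expected for initial-rate assays).
    """
    n = len(time)
    # end of first cycle: first event after t0
    end = n
    for i in range(1, n):
        if events[i] != "none":
            end = i
            break
    c0 = ch4[0]
    cutoff = (1.0 - max_drawdown) * c0
    k = end
    for i in range(1, end):
        if ch4[i] < cutoff:
            k = i + 1  # include the first point past the cutoff
            break
    k = max(k, min(3, end))
    return 0, k


def estimate_oxidation_rate(series, config, method: str = "first_order",
                            window: tuple[float, float] | None = None,
                            max_drawdown: float = 0.10) -> RateEstimate:
    """Estimate the initial oxidation rate of one bottle from its time series.

    ``first_order`` fits ln(ppm) against time and reports the rate at the
    window start, k·C(t₀), converted to ng g⁻¹ h⁻¹ through the headspace
    ideal-gas CH₄ mass and the sediment dry mass.  ``linear`` reports the
    −slope of ppm vs. time, converted the same way.  The default window is
    the early drawdown of the first replenishment cycle (see
    ``max_drawdown``); an explicit ``window=(t_start, t_end)`` in hours may
    not contain replenish/swap events.
    """
    time = np.asarray(series.time, dtype=float)
    ch4 = np.asarray(series.ch4, dtype=float)
    events = list(series.event)
    if window is None:
        i0, i1 = _initial_window(time, ch4, events, max_drawdown)
        mask = np.zeros(len(time), dtype=bool)
        mask[i0:i1] = True
    else:
        t0, t1 = window
        mask = (time >= t0) & (time <= t1)
        inner = [e for e, t, m in zip(events, time, mask)
                 if m and t > t0 and e != "none"]
        if inner:
            raise ValueError(f"window {window} contains events: {inner}")
    t = time[mask]
    c = ch4[mask]
    if len(t) < 3:
        raise ValueError("at least 3 observations are required in the window")

    if method == "first_order" and np.any(c <= 0):
        warnings.warn(
            "nonpositive CH4 in first_order window; falling back to linear",
            stacklevel=2,
        )
        method = "linear"

    conv = ppm_to_mass(1.0, config.headspace_volume, config.temperature,
                       config.pressure) / config.sediment_dry_mass  # ng/g per ppm
    if method == "first_order":
        res = stats.linregress(t, np.log(c))
        k = -res.slope
        c0 = math.exp(res.intercept + res.slope * t[0])
        rate = k * c0 * conv
        se = res.stderr * c0 * conv
    elif method == "linear":
        res = stats.linregress(t, c)
        rate = -res.slope * conv
        se = res.stderr * conv
    else:
        raise ValueError(f"unknown method {method!r}")

    return RateEstimate(
        treatment_id=series.treatment_id,
        replicate=series.replicate,
        initial_ppm=float(c[0]),
        rate=float(rate),
        se_rate=float(se),
        window=(float(t[0]), float(t[-1])),
        method=method,
        n_points=int(len(t)),
    )


def fit_michaelis_menten(rates, temperature: float = 20.0, pressure: float = 1.0,
                         bunsen: float = 0.034, n_starts: int = 8) -> KineticsFit:
    """Fit v = Vmax·S/(Km+S) to (concentration ppm, rate) pairs.

    Unweighted nonlinear least squares with ``n_starts`` multi-start Km
    initial values log-spaced across (and beyond) the observed concentration
    range; standard errors come from the Jacobian at the optimum.  A fit that
    fails from every start returns ``converged=False`` rather than raising.
    """
    arr = np.asarray(list(rates), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("rates must be (concentration, rate) pairs")
    s, v = arr[:, 0], arr[:, 1]
    n = len(s)
    if len(np.unique(s)) < 4:
        raise ValueError("at least 4 distinct concentrations are required")

    failed = KineticsFit(
        vmax=float("nan"), km_ppm=float("nan"), km_aq=float("nan"),
        se_vmax=float("nan"), se_km_ppm=float("nan"),
        r_squared=float("nan"), n_points=n, converged=False,
    )
    if np.allclose(v, 0.0):
        return failed

    smin, smax = s[s > 0].min(), s.max()
    km0s = np.geomspace(smin / 10.0, smax * 10.0, n_starts)
    best = None
    for km0 in km0s:
        vmax0 = max(v.max(), 1e-12) * (1.0 + km0 / smax)
        try:
            popt, pcov = optimize.curve_fit(
                michaelis_menten, s, v, p0=[vmax0, km0],
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((v - michaelis_menten(s, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        return failed

    sse, (vmax, km), pcov = best
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    # curve_fit's pcov is already scaled by the residual variance.
    se = np.sqrt(np.abs(np.diag(pcov)))
    return KineticsFit(
        vmax=float(vmax),
        km_ppm=float(km),
        km_aq=headspace_to_aqueous(km, temperature, pressure, bunsen),
        se_vmax=float(se[0]),
        se_km_ppm=float(se[1]),
        r_squared=r2,
        n_points=n,
        converged=True,
        sse=sse,
    )
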