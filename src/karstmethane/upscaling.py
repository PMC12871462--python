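"""Regional methane-sink upscaling and habitat-stratified rate summaries.

The sink of a karst region is the product of its area, the areal mass of
the methanotrophically active sediment layer, the per-mass oxidation
rate and the active fraction of the year:

    sink (Tg yr⁻¹) = area[km²]·10⁶ · mass[kg m⁻²]·10³ · rate[ng g⁻¹ h⁻¹]
                     · active_fraction · hours · 10⁻²¹

Any of mass/rate may be a distribution; uncertainty comes from seeded
Monte-Carlo draws.  Scenario parameters are user-supplied — the shipped
example values are illustrative, not a survey product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DistSpec",
    "UpscalingScenario",
    "SinkEstimate",
    "HABITATS",
    "regional_sink",
    "offset_fraction",
    "habitat_summary",
    "compact_letters",
]

HABITATS = ("forest", "grassland", "farmland", "cave", "other")


class DistSpec(BaseModel):
    """Distribution for a scenario parameter.

    ``normal``: params mean, sd; ``lognormal``: params mu, sigma (log scale,
    central value exp(mu)); ``uniform``: params low, high.
    """

    dist: Literal["normal", "lognormal", "uniform"]
    params: dict[str, float]

    def central(self) -> float:
        p = self.params
        if self.dist == "normal":
            return p["mean"]
        if self.dist == "lognormal":
            return float(np.exp(p["mu"]))
        return 0.5 * (p["low"] + p["high"])

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.dist == "normal":
            return rng.normal(p["mean"], p["sd"], n)
        if self.dist == "lognormal":
            return rng.lognormal(p["mu"], p["sigma"], n)
        return rng.uniform(p["low"], p["high"], n)


Param = Union[float, DistSpec]


def _central(x: Param) -> float:
    return x.central() if isinstance(x, DistSpec) else float(x)


def _sample(x: Param, rng, n) -> np.ndarray:
    return x.sample(rng, n) if isinstance(x, DistSpec) else np.full(n, float(x))


class UpscalingScenario(BaseModel):
    """Parameters of one regional-sink scenario."""

    name: str = "scenario"
    area: float = Field(ge=0, description="km^2")
    reactive_mass_per_area: Param = Field(description="kg dry sediment m^-2")
    rate: Param = Field(description="ng CH4 g^-1 h^-1")
    active_fraction: float = Field(1.0, ge=0, le=1)
    hours_per_year: float = Field(8760.0, gt=0)
    draws: int = Field(1, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check_draws(self) -> "UpscalingScenario":
        if self.draws > 1 and not (
            isinstance(self.reactive_mass_per_area, DistSpec)
            or isinstance(self.rate, DistSpec)
        ):
            raise ValueError(
                "draws > 1 requires a distribution for reactive_mass_per_area "
                "or rate"
            )
        return self


@dataclass
class SinkEstimate:
    point: float            # Tg CH4 yr^-1
    interval: tuple[float, float] | None
    draws: np.ndarray | None


_NG_TO_TG = 1e-21


def _sink_tg(area_km2, mass_kg_m2, rate, active_fraction, hours):
    return (area_km2 * 1e6) * (mass_kg_m2 * 1e3) * rate * active_fraction \
        * hours * _NG_TO_TG


def regional_sink(scenario: UpscalingScenario) -> SinkEstimate:
    """Point estimate (central values) and seeded Monte-Carlo 95% interval."""
    point = _sink_tg(
        scenario.area,
        _central(scenario.reactive_mass_per_area),
        _central(scenario.rate),
        scenario.active_fraction,
        scenario.hours_per_year,
    )
    if scenario.draws <= 1:
        return SinkEstimate(point=point, interval=None, draws=None)
    rng = np.random.default_rng(scenario.seed)
    mass = _sample(scenario.reactive_mass_per_area, rng, scenario.draws)
    rate = _sample(scenario.rate, rng, scenario.draws)
    draws = _sink_tg(scenario.area, mass, rate, scenario.active_fraction,
                     scenario.hours_per_year)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return SinkEstimate(point=point, interval=(float(lo), float(hi)), draws=draws)


def offset_fraction(sink: float, emission: float) -> float:
    """Sink as a percentage of an emission term (round at reporting only)."""
    if emission <= 0:
        raise ValueError("emission must be positive")
    return 100.0 * sink / emission


def compact_letters(groups: list[str], sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Groups not significantly different share at least one letter; every
    significantly different pair shares none.
    """
    sets: list[set[str]] = [set(groups)]
    for a, b in sig_pairs:
        new: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new.append(s - {a})
                new.append(s - {b})
            else:
                new.append(s)
        # absorb: drop duplicates and subsets
        sets = []
        for s in new:
            if any(s < t for t in new) or s in sets or not s:
                continue
            sets.append(s)
    # stable letter order: by first group appearance
    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: min(order[g] for g in s))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, s in zip(letters, sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def habitat_summary(records, bins, alpha: float = 0.05) -> pd.DataFrame:
    """Mean ± sd oxidation rate per habitat within CH₄-concentration bins.

    ``records`` is a DataFrame (columns habitat, initial_ch4_ppm,
    rate_ng_g_h) or a sequence of objects with matching attributes.  Bins
    are half-open intervals (low, high].  Within each bin, habitats with at
    least two records are compared all-pairs by rank (Mann-Whitney U) with
    Benjamini-Hochberg adjustment at ``alpha``; shared letters mark
    statistically indistinguishable habitats.
    """
    if isinstance(records, pd.DataFrame):
        df = records.rename(
            columns={"initial_ch4": "initial_ch4_ppm", "rate": "rate_ng_g_h"}
        ).copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "habitat": r.habitat,
                    "initial_ch4_ppm": r.initial_ch4,
                    "rate_ng_g_h": r.rate,
                }
                for r in records
            ]
        )
    bad = set(df["habitat"]) - set(HABITATS)
    if bad:
        raise ValueError(f"unknown habitat labels: {sorted(bad)}")

    rows = []
    for low, high in bins:
        sub = df[(df["initial_ch4_ppm"] > low) & (df["initial_ch4_ppm"] <= high)]
        groups = {
            h: g["rate_ng_g_h"].to_numpy()
            for h, g in sub.groupby("habitat", sort=False)
            if len(g) >= 2
        }
        names = [h for h in HABITATS if h in groups]
        sig: set[tuple[str, str]] = set()
        if len(names) >= 2:
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
            pvals = []
            for a, b in pairs:
                if (np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0
                        and groups[a][0] == groups[b][0]):
                    pvals.append(1.0)
                    continue
                pvals.append(
                    float(stats.mannwhitneyu(groups[a], groups[b],
                                             alternative="two-sided").pvalue)
                )
            reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
            sig = {p for p, r in zip(pairs, reject) if r}
        letters = compact_letters(names, sig) if names else {}
        for h in names:
            x = groups[h]
            rows.append(
                {
                    "habitat": h,
                    "bin_low_ppm": low,
                    "bin_high_ppm": high,
                    "mean_rate_ng_g_h": float(np.mean(x)),
                    "sd_rate_ng_g_h": float(np.std(x, ddof=1)),
                    "n": int(len(x)),
                    "group": letters[h],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "habitat", "bin_low_ppm", "bin_high_ppm", "mean_rate_ng_g_h",
            "sd_rate_ng_g_h", "n", "group",
        ],
    )
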