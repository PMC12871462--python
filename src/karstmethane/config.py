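"""Validated experiment configuration and generative ground truth.

`IncubationConfig` captures the microcosm design (bottle geometry, CH₄
targets, replenishment schedule, controls, measurement noise);
`TrueState` holds the generative parameters the synthetic-data module
uses and the analysis chain tries to recover.  Both load from TOML via
:func:`load_config`.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, model_validator

__all__ = ["IncubationConfig", "TrueState", "load_config"]


class IncubationConfig(BaseModel):
    """Design of one microcosm treatment set.

    Defaults reproduce the study design: triplicate 125-ml bottles with
    20 g air-dried sediment (≈0.105 L headspace), targets 2–500 ppmv, a
    99 atom% ¹³C label against an unlabeled control, replenishment every
    3 days, a full headspace swap on day 15, 30-day duration at 20 °C,
    plus sterile and ambient-air controls.
    """

    sediment_dry_mass: float = Field(20.0, gt=0, description="g dry sediment")
    moisture_fraction: float = Field(0.2, ge=0, le=1)
    headspace_volume: float = Field(0.105, gt=0, description="L")
    temperature: float = Field(20.0, gt=-273.15, description="degC")
    pressure: float = Field(1.0, gt=0, description="atm")
    target_ch4: list[float] = Field(
        default_factory=lambda: [2.0, 10.0, 50.0, 100.0, 250.0, 500.0],
        description="ppmv targets",
    )
    label_atom_fraction: float = Field(0.99, ge=0, le=1)
    replenish_interval: float = Field(72.0, gt=0, description="h")
    headspace_swap_time: float | None = Field(
        360.0, gt=0, description="h; None disables the mid-incubation swap"
    )
    duration: float = Field(720.0, gt=0, description="h")
    sampling_interval: float = Field(12.0, gt=0, description="h")
    replicates: int = Field(3, ge=1)
    include_sterile_control: bool = True
    include_ambient_control: bool = True
    measurement_cv: float = Field(0.05, ge=0,
                                  description="lognormal CV on concentrations")
    delta_sd: float = Field(0.2, ge=0,
                            description="permil-scale sd on isotope ratios")
    ambient_ch4: float = Field(1.9, gt=0, description="ppmv, ambient-air control")
    bunsen: float = Field(0.034, gt=0, description="CH4 Bunsen coefficient")
    seed: int = 0

    @model_validator(mode="after")
    def _check_schedule(self) -> "IncubationConfig":
        if any(t <= 0 for t in self.target_ch4):
            raise ValueError("target_ch4: all targets must be positive")
        ratio = self.replenish_interval / self.sampling_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "sampling_interval: must divide evenly into replenish_interval"
            )
        if self.headspace_swap_time is not None:
            if self.duration < self.headspace_swap_time:
                raise ValueError("duration: must be >= headspace_swap_time")
            ratio = self.headspace_swap_time / self.replenish_interval
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    "headspace_swap_time: must fall on a replenishment boundary"
                )
        return self


class TrueState(BaseModel):
    """Generative ground truth of the simulated sediment.

    Defaults are calibrated so that the Michaelis–Menten rate at 500 ppm is
    90.7 ng g⁻¹ h⁻¹ with a half-saturation constant of 196 nM aqueous CH₄
    (138.8 ppm at 20 °C, β = 0.034), and a carbon assimilation efficiency
    of 60%.  Background respiration, its δ¹³C, the unlabeled-tank CH₄ δ¹³C
    and the PLFA background pools are synthetic-only plumbing that gives the
    control bottles realistic natural-abundance baselines.
    """

    vmax_true: float = Field(115.9, gt=0, description="ng CH4 g^-1 h^-1")
    km_aq_true: float = Field(196.2, gt=0, description="nM aqueous CH4")
    f_assim: float = Field(0.60, ge=0, le=1)
    epsilon_ox: float = Field(-20.0, description="permil kinetic fractionation")
    toc0: float = Field(0.6, gt=0, description="% C of dry mass")
    delta_toc0: float = Field(-24.5, ge=-1000)
    respiration_rate: float = Field(10.0, ge=0, description="ng C g^-1 h^-1")
    delta_resp: float = Field(-25.0, ge=-1000)
    plfa_yield: float = Field(0.06, ge=0, le=1)
    plfa_allocation: dict[str, float] = Field(
        default_factory=lambda: {"16:0": 0.45, "16:1w7c": 0.35, "other": 0.20}
    )
    # synthetic-only sources for control baselines and FAME derivatization
    delta_ch4_unlabeled: float = Field(-40.0, ge=-1000)
    delta_methanol: float = Field(-38.7, ge=-1000)
    delta_plfa0: float = Field(-28.0, ge=-1000)
    plfa_background: dict[str, float] = Field(
        default_factory=lambda: {"16:0": 2500.0, "16:1w7c": 1800.0, "other": 3200.0}
    )
    plfa_n_carbons: dict[str, int] = Field(
        default_factory=lambda: {"16:0": 16, "16:1w7c": 16, "other": 17}
    )

    @model_validator(mode="after")
    def _check_allocation(self) -> "TrueState":
        total = sum(self.plfa_allocation.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("plfa_allocation: fractions must sum to 1")
        if any(f < 0 for f in self.plfa_allocation.values()):
            raise ValueError("plfa_allocation: fractions must be nonnegative")
        missing = set(self.plfa_allocation) - set(self.plfa_background)
        if missing:
            raise ValueError(f"plfa_background: missing compounds {sorted(missing)}")
        return self


def rate_assay_config(sampling_interval: float = 0.25, duration: float = 12.0,
                      **overrides) -> IncubationConfig:
    """Config for a short initial-rate assay: fine early sampling, no swap.

    Initial-rate estimation needs observations before the headspace has
    drawn down appreciably, so the assay samples on a sub-hour grid and
    runs for a single (long) cycle without replenishment or swap.
    """
    defaults = dict(
        sampling_interval=sampling_interval,
        duration=duration,
        replenish_interval=max(duration, 72.0),
        headspace_swap_time=None,
        measurement_cv=0.0,
        delta_sd=0.0,
    )
    defaults.update(overrides)
    return IncubationConfig(**defaults)


def load_config(path) -> tuple[IncubationConfig, TrueState]:
    """Read a TOML file with ``[incubation]`` and ``[truth]`` tables."""
    with open(Path(path), "rb") as fh:
        raw = tomllib.load(fh)
    cfg = IncubationConfig(**raw.get("incubation", {}))
    truth = TrueState(**raw.get("truth", {}))
    return cfg, truth
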