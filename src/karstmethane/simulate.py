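"""Seeded synthetic ¹³CH₄/¹²CH₄ microcosm generator.

Simulates sealed-bottle incubations of methane-oxidizing cave sediment:
CH₄ is consumed by Michaelis–Menten kinetics acting on the aqueous
concentration (instantaneous headspace–water equilibrium through the
Bunsen coefficient), the oxidized carbon is split between sediment
organic carbon (fraction ``f_assim``, a slice of which enters PLFA
pools) and CO₂ (mixed with unlabeled background respiration), and the
replenishment/swap schedule of the incubation design is replayed
exactly.  Isotopes are tracked as separate ¹²C/¹³C mol pools, so mass
and label conservation hold by construction; measurement noise is
applied to observations only, never to the state.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IncubationConfig, TrueState
from .isotopes import (
    M_12C,
    M_13C,
    M_CH4,
    R_GAS_L_ATM,
    atom_fraction,
    delta_from_atom_fraction,
)
from .kinetics import headspace_to_aqueous

__all__ = [
    "BottleSpec",
    "HeadspaceSeries",
    "PlfaRecord",
    "SedimentEndpoint",
    "SimulationLedger",
    "generate_design",
    "simulate_microcosm",
    "simulate_design",
    "write_dataset",
    "total_ch4_added",
]

MAX_STEP_H = 0.5


@dataclass(frozen=True)
class BottleSpec:
    """One bottle of the factorial design."""

    treatment_id: str
    replicate: int
    target_ppm: float
    label_atom_fraction: float
    oxidation_enabled: bool = True
    respiration_enabled: bool = True
    full_swap_each_cycle: bool = False  # ambient-air control protocol


@dataclass
class SimulationLedger:
    """Internal truth ledger (mol C unless noted); closes exactly."""

    supplied_mol: float = 0.0
    supplied_13c_mol: float = 0.0
    oxidized_mol: float = 0.0
    oxidized_13c_mol: float = 0.0
    assimilated_13c_mol: float = 0.0
    co2_from_ch4_13c_mol: float = 0.0
    respired_13c_mol: float = 0.0
    vented_co2_13c_mol: float = 0.0
    vented_ch4_13c_mol: float = 0.0


@dataclass
class HeadspaceSeries:
    """Per-bottle gas time series (observations, noise included)."""

    treatment_id: str
    replicate: int
    time: np.ndarray
    ch4: np.ndarray
    ch4_13f: np.ndarray
    co2: np.ndarray
    delta_co2: np.ndarray
    event: list[str]
    vented_co2_13c: np.ndarray  # cumulative ug 13C removed by swaps/flushes
    ledger: SimulationLedger | None = field(default=None, repr=False, compare=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treatment_id": self.treatment_id,
                "replicate": self.replicate,
                "time_h": self.time,
                "ch4_ppmv": self.ch4,
                "ch4_13f": self.ch4_13f,
                "co2_ppmv": self.co2,
                "delta_co2_permil": self.delta_co2,
                "event": self.event,
                "vented_13c_ug": self.vented_co2_13c,
            }
        )


@dataclass
class PlfaRecord:
    compound: str
    n_carbons: int
    concentration: float  # ng g^-1 dry
    delta_fame: float     # permil, as measured on the methyl ester


@dataclass
class SedimentEndpoint:
    """End-of-incubation sediment measurements for one bottle."""

    treatment_id: str
    replicate: int
    toc: float            # % C of dry mass
    delta_toc: float      # permil VPDB
    delta_methanol: float  # permil, derivatization methanol
    plfa_records: list[PlfaRecord]


def generate_design(config: IncubationConfig) -> list[BottleSpec]:
    """Expand the factorial design into one descriptor per bottle.

    Each CH₄ target is crossed with a ¹³C-labeled and an unlabeled
    treatment; optional sterile (autoclaved, oxidation disabled) and
    ambient-air (headspace fully exchanged each cycle) controls are
    appended, each at the configured replicate count.
    """
    nat = atom_fraction(-40.0)  # tank CH4, natural abundance
    specs: list[BottleSpec] = []
    for ppm in config.target_ch4:
        for labeled in (True, False):
            label = "13C" if labeled else "12C"
            for rep in range(1, config.replicates + 1):
                specs.append(
                    BottleSpec(
                        treatment_id=f"{label}-{ppm:g}ppm",
                        replicate=rep,
                        target_ppm=ppm,
                        label_atom_fraction=(
                            config.label_atom_fraction if labeled else nat
                        ),
                    )
                )
    if config.include_sterile_control:
        for rep in range(1, config.replicates + 1):
            specs.append(
                BottleSpec(
                    treatment_id="sterile-2ppm",
                    replicate=rep,
                    target_ppm=2.0,
                    label_atom_fraction=nat,
                    oxidation_enabled=False,
                    respiration_enabled=False,
                )
            )
    if config.include_ambient_control:
        for rep in range(1, config.replicates + 1):
            specs.append(
                BottleSpec(
                    treatment_id="ambient",
                    replicate=rep,
                    target_ppm=config.ambient_ch4,
                    label_atom_fraction=nat,
                    full_swap_each_cycle=True,
                )
            )
    return specs


def _headspace_total_mol(config: IncubationConfig) -> float:
    tk = config.temperature + 273.15
    return config.pressure * config.headspace_volume / (R_GAS_L_ATM * tk)


def _carbon_fraction(n_carbons: int) -> float:
    """Carbon mass fraction of a CnH2nO2 fatty acid."""
    mw = 14.027 * n_carbons + 31.998
    return 12.011 * n_carbons / mw


class _Noise:
    """Observation noise: lognormal on concentrations, ratio-scale on isotopes."""

    def __init__(self, rng: np.random.Generator, cv: float, delta_sd: float):
        self.rng = rng
        self.cv = cv
        self.rsd = delta_sd / 1000.0  # relative sd of the isotope ratio

    def conc(self, x: float) -> float:
        if self.cv <= 0 or x == 0:
            return x
        sigma = math.sqrt(math.log(1.0 + self.cv**2))
        return x * self.rng.lognormal(-0.5 * sigma**2, sigma)

    def frac13(self, x: float) -> float:
        """Perturb an atom fraction on the 13/12 ratio scale."""
        if self.rsd <= 0 or not (0.0 < x < 1.0):
            return x
        r = x / (1.0 - x) * (1.0 + self.rng.normal(0.0, self.rsd))
        r = max(r, 0.0)
        return r / (1.0 + r)

    def delta(self, d: float) -> float:
        if self.rsd <= 0 or not math.isfinite(d):
            return d
        return (d + 1000.0) * (1.0 + self.rng.normal(0.0, self.rsd)) - 1000.0


def simulate_microcosm(
    spec: BottleSpec,
    truth: TrueState,
    config: IncubationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HeadspaceSeries, SedimentEndpoint]:
    """Simulate one bottle; deterministic given (spec, truth, config, rng state).

    Integration is a fixed-step explicit update (step ≤ 0.5 h) between
    sampling times; events (replenish to target, day-15 full headspace swap,
    ambient-control full exchange) are applied at their scheduled times and
    each observation row reports the post-event state with the event flagged.
    """
    if rng is None:
        key = zlib.crc32(f"{spec.treatment_id}/{spec.replicate}".encode())
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(key,))
        )
    noise = _Noise(rng, config.measurement_cv, config.delta_sd)

    n_sub = max(1, math.ceil(config.sampling_interval / MAX_STEP_H))
    dt = config.sampling_interval / n_sub
    if dt <= 0:
        raise ValueError("nonpositive integration step; decrease sampling_interval")

    dry = config.sediment_dry_mass

    # --- pools (mol) ---
    c12 = c13 = 0.0            # headspace CH4
    o12 = o13 = 0.0            # headspace CO2 (synthetic air: starts at 0)
    x0 = atom_fraction(truth.delta_toc0)
    mass_c0 = truth.toc0 / 100.0 * dry
    mol_c0 = mass_c0 / (M_12C * (1 - x0) + M_13C * x0)
    t13 = mol_c0 * x0
    t12 = mol_c0 - t13
    xp0 = atom_fraction(truth.delta_plfa0)
    plfa: dict[str, list[float]] = {}
    for comp, conc in truth.plfa_background.items():
        n_c = truth.plfa_n_carbons[comp]
        mol = conc * 1e-9 * dry * _carbon_fraction(n_c) / (
            M_12C * (1 - xp0) + M_13C * xp0
        )
        plfa[comp] = [mol * (1 - xp0), mol * xp0]

    led = SimulationLedger()
    n_total = _headspace_total_mol(config)
    x_label = spec.label_atom_fraction
    x_resp = atom_fraction(truth.delta_resp)
    alpha = 1.0 + truth.epsilon_ox / 1000.0
    resp_mol_h = (truth.respiration_rate * dry * 1e-9 / 12.011
                  if spec.respiration_enabled else 0.0)

    def ppm_of(n_mol: float) -> float:
        return n_mol / n_total * 1e6

    def inject_to_target() -> None:
        nonlocal c12, c13
        target_mol = spec.target_ppm * 1e-6 * n_total
        add = max(0.0, target_mol - (c12 + c13))
        c13 += add * x_label
        c12 += add * (1.0 - x_label)
        led.supplied_mol += add
        led.supplied_13c_mol += add * x_label

    def vent_all() -> None:
        nonlocal c12, c13, o12, o13
        led.vented_co2_13c_mol += o13
        led.vented_ch4_13c_mol += c13
        c12 = c13 = o12 = o13 = 0.0

    def consumption_mol_h(ch4_mol: float) -> float:
        if ch4_mol <= 0:
            return 0.0
        s_aq = headspace_to_aqueous(
            ppm_of(ch4_mol), config.temperature, config.pressure, config.bunsen
        )
        v = truth.vmax_true * s_aq / (truth.km_aq_true + s_aq)  # ng/g/h
        return v * dry * 1e-9 / M_CH4

    def step(h: float) -> None:
        nonlocal c12, c13, o12, o13, t12, t13
        ch4 = c12 + c13
        if spec.oxidation_enabled and ch4 > 0:
            # classic RK4 on total CH4; isotope split applied to the increment
            k1 = consumption_mol_h(ch4)
            k2 = consumption_mol_h(max(ch4 - 0.5 * h * k1, 0.0))
            k3 = consumption_mol_h(max(ch4 - 0.5 * h * k2, 0.0))
            k4 = consumption_mol_h(max(ch4 - h * k3, 0.0))
            d = min(h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, ch4)
            if d > 0:
                d13 = d * alpha * c13 / (c12 + alpha * c13)
                d13 = min(d13, c13)
                d12 = min(d - d13, c12)
                c12 -= d12
                c13 -= d13
                a12 = truth.f_assim * d12
                a13 = truth.f_assim * d13
                t12 += a12
                t13 += a13
                for comp, frac in truth.plfa_allocation.items():
                    plfa[comp][0] += truth.plfa_yield * a12 * frac
                    plfa[comp][1] += truth.plfa_yield * a13 * frac
                o12 += d12 - a12
                o13 += d13 - a13
                led.oxidized_mol += d12 + d13
                led.oxidized_13c_mol += d13
                led.assimilated_13c_mol += a13
                led.co2_from_ch4_13c_mol += d13 - a13
        if resp_mol_h > 0:
            r = resp_mol_h * h
            o12 += r * (1.0 - x_resp)
            o13 += r * x_resp
            led.respired_13c_mol += r * x_resp

    times = np.arange(
        0.0, config.duration + 0.5 * config.sampling_interval,
        config.sampling_interval,
    )
    rows_t, rows_ch4, rows_13f, rows_co2, rows_dco2, rows_v = [], [], [], [], [], []
    rows_ev: list[str] = []
    eps = 1e-9

    for i, t in enumerate(times):
        if i > 0:
            for _ in range(n_sub):
                step(dt)
        # events (applied at t; the row reports the post-event state)
        event = "none"
        on_cycle = abs(t / config.replenish_interval
                       - round(t / config.replenish_interval)) < eps
        if t < config.duration - eps or i == 0:
            if i == 0:
                inject_to_target()
                event = "replenish"
            elif spec.full_swap_each_cycle and on_cycle:
                vent_all()
                inject_to_target()
                event = "swap"
            elif (config.headspace_swap_time is not None
                  and abs(t - config.headspace_swap_time) < eps):
                vent_all()
                inject_to_target()
                event = "swap"
            elif on_cycle:
                inject_to_target()
                event = "replenish"
        # observation
        ch4 = c12 + c13
        x13 = c13 / ch4 if ch4 > 0 else float("nan")
        co2 = o12 + o13
        if co2 > 0:
            dco2 = delta_from_atom_fraction(o13 / co2)
        else:
            dco2 = float("nan")
        rows_t.append(t)
        rows_ch4.append(noise.conc(ppm_of(ch4)))
        rows_13f.append(noise.frac13(x13) if math.isfinite(x13) else x13)
        rows_co2.append(noise.conc(ppm_of(co2)))
        rows_dco2.append(noise.delta(dco2))
        rows_ev.append(event)
        rows_v.append(led.vented_co2_13c_mol * M_13C * 1e6)

    series = HeadspaceSeries(
        treatment_id=spec.treatment_id,
        replicate=spec.replicate,
        time=np.asarray(rows_t),
        ch4=np.asarray(rows_ch4),
        ch4_13f=np.asarray(rows_13f),
        co2=np.asarray(rows_co2),
        delta_co2=np.asarray(rows_dco2),
        event=rows_ev,
        vented_co2_13c=np.asarray(rows_v),
        ledger=led,
    )

    # --- sediment endpoint ---
    mol_c = t12 + t13
    x_toc = t13 / mol_c
    toc_mass = t12 * M_12C + t13 * M_13C
    toc_pct = toc_mass / dry * 100.0
    records: list[PlfaRecord] = []
    for comp, (p12, p13) in plfa.items():
        n_c = truth.plfa_n_carbons[comp]
        xp = p13 / (p12 + p13)
        conc = (p12 * M_12C + p13 * M_13C) / _carbon_fraction(n_c) / dry * 1e9
        delta_plfa = delta_from_atom_fraction(xp)
        delta_fame = (n_c * delta_plfa + truth.delta_methanol) / (n_c + 1)
        records.append(
            PlfaRecord(
                compound=comp,
                n_carbons=n_c,
                concentration=noise.conc(conc),
                delta_fame=noise.delta(delta_fame),
            )
        )
    endpoint = SedimentEndpoint(
        treatment_id=spec.treatment_id,
        replicate=spec.replicate,
        toc=noise.conc(toc_pct),
        delta_toc=noise.delta(delta_from_atom_fraction(x_toc)),
        delta_methanol=truth.delta_methanol,
        plfa_records=records,
    )
    return series, endpoint


def simulate_design(
    config: IncubationConfig, truth: TrueState | None = None
) -> tuple[list[HeadspaceSeries], list[SedimentEndpoint]]:
    """Simulate every bottle of the design with per-bottle seeded substreams."""
    if truth is None:
        truth = TrueState()
    specs = generate_design(config)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(specs))
    series_list, endpoints = [], []
    for spec, ss in zip(specs, children):
        s, e = simulate_microcosm(spec, truth, config, np.random.default_rng(ss))
        series_list.append(s)
        endpoints.append(e)
    return series_list, endpoints


def total_ch4_added(config: IncubationConfig, target_ppm: float) -> float:
    """Total CH₄ injected per bottle over the incubation (ng)."""
    from .kinetics import ppm_to_mass

    n_inj = int(math.floor(config.duration / config.replenish_interval - 1e-9)) + 1
    return n_inj * ppm_to_mass(
        target_ppm, config.headspace_volume, config.temperature, config.pressure
    )


def write_dataset(series_list, endpoints, path, metadata: dict | None = None):
    """Write tidy headspace.csv / endpoints.csv / plfa.csv under ``path``."""
    from .io import write_table

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not series_list:
        warnings.warn("empty series list; writing header-only files", stacklevel=2)

    head = (
        pd.concat([s.to_frame() for s in series_list], ignore_index=True)
        if series_list
        else pd.DataFrame(
            columns=[
                "treatment_id", "replicate", "time_h", "ch4_ppmv", "ch4_13f",
                "co2_ppmv", "delta_co2_permil", "event", "vented_13c_ug",
            ]
        )
    )
    ep_rows, plfa_rows = [], []
    for e in endpoints:
        ep_rows.append(
            {
                "treatment_id": e.treatment_id,
                "replicate": e.replicate,
                "toc_pct": e.toc,
                "delta_toc_permil": e.delta_toc,
                "delta_methanol_permil": e.delta_methanol,
            }
        )
        for r in e.plfa_records:
            plfa_rows.append(
                {
                    "treatment_id": e.treatment_id,
                    "replicate": e.replicate,
                    "compound": r.compound,
                    "n_carbons": r.n_carbons,
                    "conc_ng_per_g": r.concentration,
                    "delta_fame_permil": r.delta_fame,
                }
            )
    eps = pd.DataFrame(
        ep_rows,
        columns=[
            "treatment_id", "replicate", "toc_pct", "delta_toc_permil",
            "delta_methanol_permil",
        ],
    )
    plfa = pd.DataFrame(
        plfa_rows,
        columns=[
            "treatment_id", "replicate", "compound", "n_carbons",
            "conc_ng_per_g", "delta_fame_permil",
        ],
    )
    files = {
        "headspace.csv": ("headspace", head),
        "endpoints.csv": ("endpoints", eps),
        "plfa.csv": ("plfa", plfa),
    }
    out = {}
    for name, (schema, df) in files.items():
        out[schema] = write_table(df, path / name, schema, metadata=metadata)
    return out
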