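"""Synthetic microcosm generator: design expansion, dynamics, conservation."""

import numpy as np
import pytest
from pydantic import ValidationError

from karstmethane import (
    IncubationConfig,
    TrueState,
    estimate_oxidation_rate,
    fit_michaelis_menten,
)
from karstmethane.config import rate_assay_config
from karstmethane.io import read_endpoints, read_headspace
from karstmethane.simulate import (
    BottleSpec,
    generate_design,
    simulate_design,
    simulate_microcosm,
    write_dataset,
)

from conftest import NAT_CH4, run_pair


class TestDesign:
    def test_full_design_counts(self):
        cfg = IncubationConfig()
        specs = generate_design(cfg)
        # 6 concentrations x 2 labels x 3 reps + sterile x3 + ambient x3
        assert len(specs) == 42
        tids = {s.treatment_id for s in specs}
        for ppm in (2, 10, 50, 100, 250, 500):
            assert f"13C-{ppm}ppm" in tids and f"12C-{ppm}ppm" in tids
        assert "sterile-2ppm" in tids and "ambient" in tids

    def test_minimal_design(self):
        cfg = IncubationConfig(
            target_ch4=[100.0], replicates=1,
            include_sterile_control=False, include_ambient_control=False,
        )
        specs = generate_design(cfg)
        assert len(specs) == 2
        assert {s.label_atom_fraction for s in specs} == {0.99, NAT_CH4}

    def test_sterile_has_oxidation_disabled(self):
        specs = generate_design(IncubationConfig())
        sterile = [s for s in specs if s.treatment_id.startswith("sterile")]
        assert sterile and all(not s.oxidation_enabled for s in sterile)

    def test_ambient_targets_atmospheric(self):
        specs = generate_design(IncubationConfig(ambient_ch4=1.9))
        amb = [s for s in specs if s.treatment_id == "ambient"]
        assert amb and all(s.target_ppm == 1.9 for s in amb)
        assert all(s.full_swap_each_cycle for s in amb)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("sediment_dry_mass", -1.0),
            ("label_atom_fraction", 1.5),
            ("replicates", 0),
            ("sampling_interval", 7.0),  # does not divide the 72-h cycle
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ValidationError) as err:
            IncubationConfig(**{field: value})
        assert field in str(err.value)


class TestDynamics:
    def test_sterile_control_is_flat(self, truth, noiseless_cfg):
        spec = BottleSpec("sterile-2ppm", 1, 2.0, NAT_CH4,
                          oxidation_enabled=False, respiration_enabled=False)
        s, e = simulate_microcosm(spec, truth, noiseless_cfg)
        assert np.allclose(s.ch4, 2.0, rtol=1e-9)
        assert e.delta_toc == pytest.approx(truth.delta_toc0, abs=1e-6)

    def test_complete_consumption_within_cycle(self, truth, noiseless_cfg):
        # CH4 drops below 5% of target well before each 3-day replenishment
        for ppm in noiseless_cfg.target_ch4:
            spec = BottleSpec(f"12C-{ppm:g}ppm", 1, ppm, NAT_CH4)
            s, _ = simulate_microcosm(spec, truth, noiseless_cfg)
            before = s.ch4[np.isclose(s.time, 60.0)][0]
            assert before < 0.05 * ppm

    def test_labeled_unlabeled_overlay(self, truth, noiseless_cfg):
        (sl, _), (su, _) = run_pair(250.0, truth, noiseless_cfg)
        assert np.allclose(sl.ch4, su.ch4, rtol=1e-6)

    def test_label_invariance_without_fractionation(self, noiseless_cfg):
        truth0 = TrueState(epsilon_ox=0.0)
        rng = lambda: np.random.default_rng(11)  # noqa: E731
        sl, _ = simulate_microcosm(
            BottleSpec("13C-100ppm", 1, 100.0, 0.99), truth0, noiseless_cfg,
            rng())
        su, _ = simulate_microcosm(
            BottleSpec("12C-100ppm", 1, 100.0, NAT_CH4), truth0, noiseless_cfg,
            rng())
        assert np.allclose(sl.ch4, su.ch4, rtol=1e-12, atol=0)

    def test_endpoint_dose_monotonicity(self, truth, noiseless_cfg):
        deltas = []
        for ppm in noiseless_cfg.target_ch4:
            spec = BottleSpec(f"13C-{ppm:g}ppm", 1, ppm, 0.99)
            _, e = simulate_microcosm(spec, truth, noiseless_cfg)
            deltas.append(e.delta_toc)
        assert np.all(np.diff(deltas) > 0)

    def test_monotone_in_label_fraction(self, truth, noiseless_cfg):
        deltas = []
        for x in (NAT_CH4, 0.5, 0.99):
            spec = BottleSpec("13C-100ppm", 1, 100.0, x)
            s, e = simulate_microcosm(spec, truth, noiseless_cfg)
            deltas.append((e.delta_toc, s.delta_co2[-1]))
        toc, co2 = zip(*deltas)
        assert np.all(np.diff(toc) > 0) and np.all(np.diff(co2) > 0)

    def test_carbon_ledger_closes(self, truth, noiseless_cfg, pair_500):
        (sl, _), _ = pair_500
        led = sl.ledger
        residual_mol = None  # everything consumed; closure on totals
        assert led.oxidized_mol == pytest.approx(led.supplied_mol, rel=5e-3)
        assert led.oxidized_13c_mol == pytest.approx(
            led.supplied_13c_mol, rel=5e-3
        )
        # oxidized 13C is partitioned without loss
        assert led.assimilated_13c_mol + led.co2_from_ch4_13c_mol == (
            pytest.approx(led.oxidized_13c_mol, rel=1e-12)
        )

    def test_determinism_bit_identical(self, truth):
        cfg = IncubationConfig(seed=42, target_ch4=[10.0, 250.0], replicates=2)
        s1, e1 = simulate_design(cfg, truth)
        s2, e2 = simulate_design(cfg, truth)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.ch4, b.ch4)
            assert np.array_equal(a.delta_co2, b.delta_co2, equal_nan=True)
        for a, b in zip(e1, e2):
            assert a.delta_toc == b.delta_toc and a.toc == b.toc


class TestParameterRecovery:
    def test_rate_at_500ppm_matches_calibration(self, truth):
        # truth is calibrated so the initial rate at 500 ppm is 90.7 ng/g/h
        cfg = rate_assay_config(sampling_interval=0.25, duration=24.0, seed=5)
        spec = BottleSpec("12C-500ppm", 1, 500.0, NAT_CH4)
        s, _ = simulate_microcosm(spec, truth, cfg)
        est = estimate_oxidation_rate(s, cfg)
        assert est.rate == pytest.approx(90.7, rel=0.05)

    def test_noiseless_kinetics_recovery(self, truth):
        # tight windows on finely sampled noiseless assays: (Vmax, Km) to 1%
        cfg = rate_assay_config(sampling_interval=0.02, duration=6.0, seed=5)
        rates = []
        for ppm in (2.0, 10.0, 50.0, 100.0, 250.0, 500.0):
            spec = BottleSpec(f"12C-{ppm:g}ppm", 1, ppm, NAT_CH4)
            s, _ = simulate_microcosm(spec, truth, cfg)
            est = estimate_oxidation_rate(s, cfg, max_drawdown=0.01)
            rates.append((ppm, est.rate))
        fit = fit_michaelis_menten(rates)
        assert fit.converged
        assert fit.vmax == pytest.approx(truth.vmax_true, rel=0.01)
        assert fit.km_aq == pytest.approx(truth.km_aq_true, rel=0.01)


class TestDatasetIO:
    def test_round_trip(self, truth, tmp_path):
        cfg = IncubationConfig(
            target_ch4=[10.0, 500.0], replicates=2, seed=3,
            include_ambient_control=False,
        )
        series, endpoints = simulate_design(cfg, truth)
        write_dataset(series, endpoints, tmp_path, metadata={"seed": cfg.seed})
        back_s = read_headspace(tmp_path / "headspace.csv")
        back_e = read_endpoints(tmp_path / "endpoints.csv",
                                tmp_path / "plfa.csv")
        assert len(back_s) == len(series) and len(back_e) == len(endpoints)
        by_key = {(s.treatment_id, s.replicate): s for s in back_s}
        for s in series:
            b = by_key[(s.treatment_id, s.replicate)]
            assert np.allclose(b.ch4, s.ch4)
            assert np.allclose(b.delta_co2, s.delta_co2, equal_nan=True)
            assert list(b.event) == list(s.event)
        by_key = {(e.treatment_id, e.replicate): e for e in back_e}
        for e in endpoints:
            b = by_key[(e.treatment_id, e.replicate)]
            assert b.toc == pytest.approx(e.toc, rel=1e-12)
            assert len(b.plfa_records) == len(e.plfa_records)

    def test_full_design_endpoint_rows(self, truth, tmp_path):
        cfg = IncubationConfig(seed=3, sampling_interval=24.0)
        series, endpoints = simulate_design(cfg, truth)
        write_dataset(series, endpoints, tmp_path)
        assert len(read_endpoints(tmp_path / "endpoints.csv")) == 42

    def test_empty_write_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="header-only"):
            write_dataset([], [], tmp_path)
        text = (tmp_path / "headspace.csv").read_text()
        assert "ch4_ppmv" in text
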