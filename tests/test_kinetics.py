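"""Gas-unit conversions, rate estimation and Michaelis-Menten fitting."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from karstmethane.kinetics import (
    aqueous_to_headspace,
    estimate_oxidation_rate,
    fit_michaelis_menten,
    headspace_to_aqueous,
    michaelis_menten,
    ppm_to_mass,
    specific_affinity,
)
from karstmethane.config import IncubationConfig
from karstmethane.simulate import HeadspaceSeries


def make_series(time, ch4, treatment="12C-500ppm", replicate=1):
    n = len(time)
    return HeadspaceSeries(
        treatment_id=treatment,
        replicate=replicate,
        time=np.asarray(time, dtype=float),
        ch4=np.asarray(ch4, dtype=float),
        ch4_13f=np.full(n, 0.0107),
        co2=np.zeros(n),
        delta_co2=np.full(n, np.nan),
        event=["none"] * n,
        vented_co2_13c=np.zeros(n),
    )


class TestConversions:
    def test_reported_km_aqueous(self):
        # fitted half-saturation constant on the headspace axis -> aqueous nM
        assert round(headspace_to_aqueous(138.8, 20.0, 1.0, 0.034)) == 196

    def test_zero(self):
        assert headspace_to_aqueous(0.0, 5.0, 2.0, 0.1) == 0.0

    def test_500ppm(self):
        assert headspace_to_aqueous(500.0, 20.0, 1.0, 0.034) == pytest.approx(
            706.7, abs=0.5
        )

    def test_temperature_domain_error(self):
        with pytest.raises(ValueError):
            headspace_to_aqueous(10.0, -300.0, 1.0, 0.034)

    @given(
        st.floats(min_value=1e-3, max_value=1e6),
        st.floats(min_value=-20.0, max_value=60.0),
    )
    def test_round_trip(self, ppm, temp):
        back = aqueous_to_headspace(
            headspace_to_aqueous(ppm, temp, 1.0, 0.034), temp, 1.0, 0.034
        )
        assert back == pytest.approx(ppm, rel=1e-10)

    def test_pure_methane_is_one_mol(self):
        # 24.055 L of pure CH4 at 20C/1 atm is one mole = 1.604e10 ng
        assert ppm_to_mass(1e6, 24.055, 20.0, 1.0) == pytest.approx(
            1.604e10, rel=1e-3
        )

    def test_mass_zero(self):
        assert ppm_to_mass(0.0, 0.105, 20.0, 1.0) == 0.0

    def test_bottle_mass_500ppm(self):
        assert ppm_to_mass(500.0, 0.105, 20.0, 1.0) == pytest.approx(
            35.0e3, rel=0.01
        )


class TestSpecificAffinity:
    def test_reference_magnitude(self):
        # per-cell vmax 1.96e-16 mol/cell/h at 196 nM -> 1.0e-9 L/cell/h
        vmax_ng_g = 1.96e-16 * 1e7 * 16.04e9
        assert specific_affinity(vmax_ng_g, 196.0, 1e7) == pytest.approx(
            1.0e-9, rel=1e-6
        )

    def test_zero_vmax(self):
        assert specific_affinity(0.0, 196.0, 1e7) == 0.0

    def test_genes_per_cell_proportionality(self):
        one = specific_affinity(50.0, 196.0, 1e7, genes_per_cell=1)
        two = specific_affinity(50.0, 196.0, 1e7, genes_per_cell=2)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_zero_cell_density_rejected(self):
        with pytest.raises(ValueError):
            specific_affinity(50.0, 196.0, 0.0)

    def test_per_gram_per_cell_consistency(self):
        # expressing vmax per cell with density 1 equals per gram with density N
        n = 3.7e6
        a = specific_affinity(80.0, 150.0, n)
        b = specific_affinity(80.0 / n, 150.0, 1.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestRateEstimation:
    def test_exponential_closed_form(self):
        # C(t) = 500 exp(-0.05 t) ppm in a 0.105-L headspace over 20 g at 20C
        k, c0 = 0.05, 500.0
        t = np.arange(0.0, 24.1, 2.0)
        series = make_series(t, c0 * np.exp(-k * t))
        cfg = IncubationConfig(measurement_cv=0, delta_sd=0)
        est = estimate_oxidation_rate(series, cfg, window=(0.0, 24.0))
        expected = k * ppm_to_mass(c0, 0.105, 20.0, 1.0) / 20.0
        assert est.rate == pytest.approx(expected, rel=1e-6)
        assert est.method == "first_order"

    def test_flat_sterile_series(self):
        t = np.arange(0.0, 36.1, 6.0)
        series = make_series(t, np.full(len(t), 2.0), treatment="sterile-2ppm")
        cfg = IncubationConfig(measurement_cv=0, delta_sd=0)
        est = estimate_oxidation_rate(series, cfg, window=(0.0, 36.0))
        assert est.rate == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_falls_back_to_linear(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        series = make_series(t, np.array([10.0, 5.0, 1.0, 0.0]))
        cfg = IncubationConfig(measurement_cv=0, delta_sd=0)
        with pytest.warns(UserWarning, match="falling back to linear"):
            est = estimate_oxidation_rate(series, cfg, window=(0.0, 6.0))
        assert est.method == "linear"
        assert est.rate > 0

    def test_too_few_points(self):
        series = make_series([0.0, 1.0], [10.0, 9.0])
        cfg = IncubationConfig(measurement_cv=0, delta_sd=0)
        with pytest.raises(ValueError, match="3 observations"):
            estimate_oxidation_rate(series, cfg, window=(0.0, 1.0))

    def test_window_with_event_rejected(self):
        t = np.array([0.0, 2.0, 4.0, 6.0])
        series = make_series(t, np.array([10.0, 8.0, 20.0, 16.0]))
        series.event[2] = "replenish"
        cfg = IncubationConfig(measurement_cv=0, delta_sd=0)
        with pytest.raises(ValueError, match="events"):
            estimate_oxidation_rate(series, cfg, window=(0.0, 6.0))


class TestMichaelisMentenFit:
    S = np.array([2.0, 10.0, 50.0, 100.0, 250.0, 500.0])

    def test_exact_recovery(self):
        v = michaelis_menten(self.S, 100.0, 50.0)
        fit = fit_michaelis_menten(list(zip(self.S, v)))
        assert fit.converged
        assert fit.vmax == pytest.approx(100.0, rel=1e-6)
        assert fit.km_ppm == pytest.approx(50.0, rel=1e-6)
        assert fit.km_aq == pytest.approx(
            headspace_to_aqueous(fit.km_ppm), rel=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_beats_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        v = michaelis_menten(self.S, 115.9, 138.8) * rng.lognormal(
            0, 0.05, len(self.S)
        )
        fit = fit_michaelis_menten(list(zip(self.S, v)))
        vg = np.linspace(0.2 * v.max(), 3.0 * v.max(), 200)
        kg = np.geomspace(self.S.min() / 10, self.S.max() * 10, 200)
        pred = vg[:, None, None] * self.S[None, None, :] / (
            kg[None, :, None] + self.S[None, None, :]
        )
        grid_min = float(np.min(np.sum((pred - v[None, None, :]) ** 2, axis=2)))
        assert fit.sse <= grid_min * (1 + 1e-9)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        v = michaelis_menten(self.S, 80.0, 120.0) * rng.lognormal(
            0, 0.05, len(self.S)
        )
        f1 = fit_michaelis_menten(list(zip(self.S, v)))
        c = 7.3
        f2 = fit_michaelis_menten(list(zip(self.S, c * v)))
        assert f2.vmax == pytest.approx(c * f1.vmax, rel=1e-6)
        assert f2.km_ppm == pytest.approx(f1.km_ppm, rel=1e-6)

    def test_all_zero_rates_not_converged(self):
        fit = fit_michaelis_menten([(s, 0.0) for s in self.S])
        assert not fit.converged

    def test_too_few_concentrations(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_michaelis_menten([(1.0, 1.0), (2.0, 2.0), (3.0, 2.5)])
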