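"""Virtual populations and the origin of the inverse TSH-TH relationship."""

import numpy as np
import pandas as pd
import pytest

from hptaxis import (
    PopulationSample,
    PopulationSpec,
    fit_log_linear,
    gain_from_population,
    sample_population,
    steady_state,
)


def _make_sample(records: pd.DataFrame, base) -> PopulationSample:
    spec = PopulationSpec(base=base, varied=(), n_individuals=len(records))
    return PopulationSample(spec=spec, records=records)


class TestSampling:
    def test_seeded_reproducibility(self, design_a):
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.2),), n_individuals=40, seed=123)
        a = sample_population(spec).records
        b = sample_population(spec).records
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_zero_cv_collapses_to_base_steady_state(self, design_a):
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.0),), n_individuals=5, seed=1)
        sample = sample_population(spec)
        base_ss = steady_state(design_a)
        for col, value in (("TRH", base_ss.trh), ("TSH", base_ss.tsh), ("TH", base_ss.th)):
            assert sample.records[col].to_numpy() == pytest.approx(value, rel=1e-9)

    def test_single_individual(self, design_a):
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.0),), n_individuals=1, seed=1)
        sample = sample_population(spec)
        assert len(sample.records) == 1
        assert sample.n_failed == 0

    def test_draws_have_median_at_base_value(self, design_a):
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.3),), n_individuals=2000, seed=5)
        draws = sample_population(spec).records["k1"]
        assert np.median(draws) == pytest.approx(design_a.k1, rel=0.05)

    def test_unknown_parameter_rejected(self, design_a):
        with pytest.raises(KeyError):
            PopulationSpec(base=design_a, varied=(("kX", 0.1),), n_individuals=10)


class TestRelationshipDichotomy:
    """Variability on the thyroid side produces the inverse log-linear
    TSH-TH relationship; variability on the brain side produces a positive
    one — in both amplifier placements."""

    @pytest.mark.parametrize("preset_fixture", ["design_a", "design_b"])
    @pytest.mark.parametrize("param", ["k1", "k2"])
    def test_thyroid_side_variation_gives_inverse_relationship(
        self, preset_fixture, param, request
    ):
        base = request.getfixturevalue(preset_fixture)
        spec = PopulationSpec(base=base, varied=((param, 0.2),), n_individuals=500, seed=42)
        slope, _, r = fit_log_linear(sample_population(spec))
        assert slope < 0
        assert r < -0.9

    @pytest.mark.parametrize("preset_fixture", ["design_a", "design_b"])
    @pytest.mark.parametrize("param", ["k3", "Kd3", "k5"])
    def test_brain_side_variation_gives_positive_relationship(
        self, preset_fixture, param, request
    ):
        base = request.getfixturevalue(preset_fixture)
        spec = PopulationSpec(base=base, varied=((param, 0.2),), n_individuals=500, seed=42)
        slope, _, r = fit_log_linear(sample_population(spec))
        assert slope > 0
        assert r > 0.9

    def test_amplification_asymmetry(self, design_a):
        # TSH swings much more than TH when the perturbation enters at the
        # thyroid: quantile fold-range of TSH exceeds that of TH raised to
        # the direct feedback coefficient.
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.2),), n_individuals=500, seed=42)
        rec = sample_population(spec).records
        th_fold = np.quantile(rec["TH"], 0.975) / np.quantile(rec["TH"], 0.025)
        tsh_fold = np.quantile(rec["TSH"], 0.975) / np.quantile(rec["TSH"], 0.025)
        assert tsh_fold > th_fold ** 4


class TestGainEstimation:
    def test_population_gain_matches_local_loop_arithmetic(self, design_a):
        # Small thyroid-side variability probes the local TH -> TSH arm:
        # n3*0.9 + n5*0.9*n7*0.9 = 6.84 at the basal saturation of 10%.
        spec = PopulationSpec(base=design_a, varied=(("k1", 0.05),), n_individuals=400, seed=42)
        gain = gain_from_population(sample_population(spec))
        assert gain == pytest.approx(6.84, abs=0.15)

    def test_thyroid_amplified_design_has_weak_feedback_arm(self, design_b):
        spec = PopulationSpec(base=design_b, varied=(("k1", 0.05),), n_individuals=400, seed=42)
        gain = gain_from_population(sample_population(spec))
        assert gain == pytest.approx(1.71, abs=0.1)

    def test_gain_estimate_converges_as_variability_shrinks(self, design_a):
        target = 6.84
        errors = []
        for cv in (0.2, 0.1, 0.05):
            spec = PopulationSpec(base=design_a, varied=(("k1", cv),), n_individuals=300, seed=7)
            errors.append(abs(gain_from_population(sample_population(spec)) - target))
        assert errors[0] >= errors[1] >= errors[2]

    def test_noiseless_power_law_recovered_exactly(self, design_a):
        g = 5.5
        th = np.linspace(10.0, 20.0, 25)
        records = pd.DataFrame(
            {"individual": np.arange(25), "TRH": 1.0, "TSH": th ** (-g), "TH": th}
        )
        assert gain_from_population(_make_sample(records, design_a)) == pytest.approx(g)

    def test_gain_refused_for_positive_association(self, design_a):
        th = np.linspace(10.0, 20.0, 10)
        records = pd.DataFrame(
            {"individual": np.arange(10), "TRH": 1.0, "TSH": th ** 2, "TH": th}
        )
        with pytest.raises(ValueError):
            gain_from_population(_make_sample(records, design_a))


class TestLogLinearFit:
    def test_exact_log_linear_input_recovered(self, design_a):
        a, b = 2.0, 0.456
        th = np.linspace(10.0, 20.0, 30)
        records = pd.DataFrame(
            {"individual": np.arange(30), "TRH": 1.0, "TSH": np.exp(a - b * th), "TH": th}
        )
        slope, intercept, r = fit_log_linear(_make_sample(records, design_a))
        assert slope == pytest.approx(-b)
        assert intercept == pytest.approx(a)
        assert r == pytest.approx(-1.0)

    def test_degenerate_th_spread_rejected(self, design_a):
        records = pd.DataFrame(
            {"individual": range(5), "TRH": 1.0, "TSH": [1, 2, 3, 4, 5], "TH": 15.0}
        )
        with pytest.raises(ValueError):
            fit_log_linear(_make_sample(records, design_a))
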