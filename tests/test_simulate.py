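"""Synthetic-data generators: determinism, ground truth, moments."""
import numpy as np
import pytest
from scipy import stats

from protflux import (
    DegradationSimParams,
    DoseSimParams,
    OPLSimParams,
    gen_degradation,
    gen_dose_response,
    gen_opl_stack,
)
from protflux.simulate import four_pl
from protflux.degradation import courses_from_records


class TestOPLGenerator:
    def test_empty_field(self):
        stack, truth = gen_opl_stack(OPLSimParams(n_cells=0, seed=1))
        assert truth.empty
        assert stack.n_frames == 7

    def test_seed_determinism(self, small_opl_params):
        s1, t1 = gen_opl_stack(small_opl_params)
        s2, t2 = gen_opl_stack(small_opl_params)
        assert np.array_equal(s1.red, s2.red)
        assert t1.equals(t2)

    def test_mean_red_intensity_decreases(self):
        params = OPLSimParams(
            n_cells=200, halflife_median_h=20.0, halflife_sigma_log=0.4,
            field_shape=(1024, 1024), seed=2,
        )
        stack, _ = gen_opl_stack(params)
        means = stack.red.mean(axis=(1, 2))
        assert np.all(np.diff(means) < 0)

    def test_overcrowded_field_errors(self):
        with pytest.raises(ValueError, match="larger field"):
            gen_opl_stack(OPLSimParams(n_cells=500, field_shape=(128, 128), seed=3))

    def test_halflife_marginal_matches_lognormal(self):
        """Sampled half-lives agree with the target lognormal (KS)."""
        params = OPLSimParams(n_cells=0, seed=4)
        rng = np.random.default_rng(4)
        sample = rng.lognormal(np.log(params.halflife_median_h),
                               params.halflife_sigma_log, 10_000)
        res = stats.kstest(
            sample, "lognorm",
            args=(params.halflife_sigma_log, 0, params.halflife_median_h),
        )
        assert res.pvalue > 0.01


class TestDoseGenerator:
    def test_midpoint_expectation(self):
        assert four_pl(2e-6, 30, 0, 2e-6, 1.0) == pytest.approx(15.0)

    def test_vehicle_maps_to_top(self):
        assert four_pl(0.0, 30, 5, 2e-6, 1.0) == pytest.approx(30.0)

    def test_low_doses_sit_at_top(self):
        params = DoseSimParams(
            concentrations=(0, 1e-12, 2e-12, 5e-12), true_ld50=2e-6,
            n_replicates=30, seed=5,
        )
        recs = gen_dose_response(params)
        counts = [r.count_or_signal for r in recs]
        assert np.mean(counts) == pytest.approx(30.0, rel=0.1)

    def test_seed_determinism(self):
        a = gen_dose_response(DoseSimParams(seed=6))
        b = gen_dose_response(DoseSimParams(seed=6))
        assert a == b


class TestDegradationGenerator:
    def test_zero_rate_stays_at_one(self):
        recs = gen_degradation(
            DegradationSimParams(deg_rate_per_min=0.0, noise_cv=0.0, seed=7)
        )
        assert all(r.normalized == pytest.approx(1.0) for r in recs)

    def test_noiseless_closed_form(self):
        recs = gen_degradation(
            DegradationSimParams(
                deg_rate_per_min=0.1, noise_cv=0.0, seed=8,
                inhibition_factors={"1:0": 1.0},
            )
        )
        at5 = [r for r in recs if r.time_min == 5.0]
        assert all(r.normalized == pytest.approx(np.exp(-0.5)) for r in at5)

    def test_inhibition_reduces_drop(self):
        """Smaller inhibition factor -> smaller 0-to-15-minute drop."""
        recs = gen_degradation(
            DegradationSimParams(
                noise_cv=0.0, seed=9,
                inhibition_factors={"full": 1.0, "half": 0.5},
            )
        )
        courses = courses_from_records(recs)
        drop = {c.condition: c.delta_0_15 for c in courses}
        assert drop["full"] > drop["half"]
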