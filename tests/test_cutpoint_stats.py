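import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atabridge.cutpoint_stats import (
    AnimalBaseline,
    CutpointMode,
    TiterChange,
    classify_titer_change,
    classify_value,
    expected_null_rates,
    make_individual_cutpoints,
    normal_cutpoint_factor,
    null_false_positive_rates,
    pooled_sd_mean_of_sds,
    pooled_sd_rms,
)
from atabridge.titration import Censoring, TiterResult


def _baseline(animal, *values):
    return AnimalBaseline(str(animal), tuple(values))


def _pair_baselines_from_sds(sds):
    # a pair (0, s*sqrt(2)) has sample SD exactly s
    return [_baseline(i, 0.0, s * math.sqrt(2)) for i, s in enumerate(sds)]


class TestPooledEstimators:
    def test_mean_of_sds_arithmetic(self):
        assert pooled_sd_mean_of_sds(_pair_baselines_from_sds([1.0, 2.0])) == pytest.approx(1.5)

    def test_mean_of_sds_identity_when_equal(self):
        assert pooled_sd_mean_of_sds(_pair_baselines_from_sds([0.7] * 5)) == pytest.approx(0.7)

    def test_rms_arithmetic(self):
        assert pooled_sd_rms(_pair_baselines_from_sds([1.0, 2.0])) == pytest.approx(math.sqrt(2.5))

    def test_rms_identity_when_equal(self):
        assert pooled_sd_rms(_pair_baselines_from_sds([0.7] * 5)) == pytest.approx(0.7)

    @pytest.mark.parametrize("fn", [pooled_sd_mean_of_sds, pooled_sd_rms])
    def test_empty_input_raises(self, fn):
        with pytest.raises(ValueError):
            fn([])

    def test_monte_carlo_recovery_of_common_sigma(self):
        """RMS pooling is consistent for sigma; mean-of-SDs converges to
        sqrt(2/pi)*sigma (half-normal mean) for paired baselines."""
        sigma = 0.3
        rng = np.random.default_rng(11)
        pre = rng.normal(0.0, sigma, size=(2000, 2)) + rng.normal(0, 3, size=(2000, 1))
        baselines = [AnimalBaseline(str(i), tuple(row)) for i, row in enumerate(pre)]
        assert pooled_sd_rms(baselines) == pytest.approx(sigma, rel=0.05)
        assert pooled_sd_mean_of_sds(baselines) == pytest.approx(
            sigma * math.sqrt(2 / math.pi), rel=0.05
        )

    @given(
        sds=st.lists(st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=1, max_size=30)
    )
    def test_rms_dominates_mean_of_sds(self, sds):
        baselines = _pair_baselines_from_sds(sds)
        assert pooled_sd_rms(baselines) >= pooled_sd_mean_of_sds(baselines) - 1e-9

    @given(
        values=st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=2, max_size=10
        ),
        shift=st.floats(-100, 100),
        seed=st.integers(0, 2**16),
    )
    def test_invariant_to_ordering_and_per_animal_shifts(self, values, shift, seed):
        baselines = [_baseline(i, a, b) for i, (a, b) in enumerate(values)]
        rng = np.random.default_rng(seed)
        shuffled = [baselines[i] for i in rng.permutation(len(baselines))]
        shifted = [_baseline(0, values[0][0] + shift, values[0][1] + shift)] + baselines[1:]
        for fn in (pooled_sd_mean_of_sds, pooled_sd_rms):
            assert fn(shuffled) == pytest.approx(fn(baselines), abs=1e-9)
            assert fn(shifted) == pytest.approx(fn(baselines), abs=1e-6)


class TestNormalFactor:
    def test_ninety_ninth_percentile_is_2_33(self):
        assert round(normal_cutpoint_factor(0.99), 2) == 2.33

    def test_median_is_zero(self):
        assert normal_cutpoint_factor(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_sided_95_is_1_96(self):
        assert round(normal_cutpoint_factor(0.975), 2) == 1.96

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_probability_out_of_range_raises(self, p):
        with pytest.raises(ValueError):
            normal_cutpoint_factor(p)


class TestIndividualCutpoints:
    def test_two_sided_arithmetic(self):
        [cp] = make_individual_cutpoints([_baseline("A", 2.0, 2.0)], 0.3, 2.33)
        assert cp.lower == pytest.approx(2.0 - 0.699)
        assert cp.upper == pytest.approx(2.0 + 0.699)

    def test_zero_pooled_sd_degenerates_to_center(self):
        [cp] = make_individual_cutpoints([_baseline("A", 2.0, 2.0)], 0.0)
        assert cp.lower == cp.center == cp.upper == 2.0

    def test_upper_only_mode(self):
        [cp] = make_individual_cutpoints(
            [_baseline("A", 10.0, 10.0)], 4.0, 2.33, CutpointMode.UPPER_ONLY
        )
        assert cp.upper == pytest.approx(19.32)
        assert cp.lower == float("-inf")


class TestClassification:
    @pytest.fixture
    def band(self):
        [cp] = make_individual_cutpoints([_baseline("A", 2.0, 2.0)], 0.3, 2.33)
        return cp  # (1.301, 2.699)

    def test_above_band_is_increased(self, band):
        assert classify_value(3.1, band) is TiterChange.INCREASED

    def test_below_band_is_decreased(self, band):
        assert classify_value(1.0, band) is TiterChange.DECREASED

    def test_boundary_is_inclusive_unchanged(self, band):
        assert classify_value(band.upper, band) is TiterChange.UNCHANGED
        assert classify_value(band.lower, band) is TiterChange.UNCHANGED

    def test_below_range_censored_below_band_is_decreased(self, band):
        post = TiterResult(0.0, Censoring.BELOW_RANGE, 0.1)
        assert classify_titer_change(post, band) is TiterChange.DECREASED

    def test_below_range_censored_inside_band_is_indeterminate(self):
        [wide] = make_individual_cutpoints([_baseline("A", 0.5, 0.5)], 0.3, 2.33)
        post = TiterResult(0.0, Censoring.BELOW_RANGE, 0.1)
        assert classify_titer_change(post, wide) is TiterChange.INDETERMINATE

    def test_above_range_censored_above_band_is_increased(self, band):
        post = TiterResult(7.0, Censoring.ABOVE_RANGE, 0.1)
        assert classify_titer_change(post, band) is TiterChange.INCREASED

    def test_upper_only_cutpoint_rejected_for_band_classification(self):
        [cp] = make_individual_cutpoints(
            [_baseline("A", 2.0, 2.0)], 0.3, mode=CutpointMode.UPPER_ONLY
        )
        with pytest.raises(ValueError, match="titer_range"):
            classify_value(1.0, cp)


class TestNullRates:
    def test_closed_form_values(self):
        """Post minus a 2-sample baseline mean is N(0, 1.5 sigma^2), so the
        band at 2.33 sigma is exceeded with probability ~5.7% (two-sided)."""
        two, one = expected_null_rates(2.33, n_pre=2)
        assert two == pytest.approx(0.0571, abs=0.0005)
        assert one == pytest.approx(0.0286, abs=0.0003)

    def test_simulation_converges_to_closed_form(self):
        n = 20_000
        two_exp, one_exp = expected_null_rates(2.33)
        two, one = null_false_positive_rates(n, seed=0)
        for observed, expected in [(two, two_exp), (one, one_exp)]:
            envelope = 1.96 * math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < envelope
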