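"""Feature metrics against independent oracles, layout and pruning."""

import numpy as np
import pytest

from ictalsel.features import (
    FeatureConfig,
    FeatureMatrix,
    amplitude_stats,
    extract_features,
    hjorth,
    prune_correlated,
    sample_entropy,
    spectral_metrics,
)
from ictalsel.preprocess import EpochSet


def sampen_bruteforce(x, m=2, r_coeff=0.2):
    """Direct O(n^2) template-pair counting, independent of the package."""
    x = np.asarray(x, float)
    n = len(x)
    r = r_coeff * x.std()
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i:i + m] - x[j:j + m])) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return np.log(n)
    return -np.log(a / b)


class TestAmplitudeStats:
    def test_alternating_signal(self):
        out = amplitude_stats([1, -1, 1, -1])
        assert out["zc"] == 3
        assert out["range"] == 2
        assert out["mean"] == 0

    def test_constant_signal_conventions(self):
        out = amplitude_stats([5.0, 5.0, 5.0, 5.0])
        assert out["var"] == 0 and out["rms"] == 5
        assert out["mad"] == 0 and out["iqr"] == 0
        assert out["skew"] == 0 and out["kurt"] == 0    # 0/0 convention, not NaN

    def test_percentile_based_stats(self):
        out = amplitude_stats([1, 2, 3, 4, 5])
        assert out["iqr"] == 2 and out["mad"] == 1 and out["min"] == 1

    def test_zero_sample_inherits_previous_sign(self):
        # 1,0,1: the zero keeps the + state, so no crossing happens
        assert amplitude_stats([1.0, 0.0, 1.0])["zc"] == 0
        assert amplitude_stats([1.0, 0.0, -1.0])["zc"] == 1

    def test_excess_kurtosis_of_normal_near_zero(self, rng):
        x = rng.standard_normal(200_000)
        assert abs(amplitude_stats(x)["kurt"]) < 0.05


class TestSpectral:
    def test_pure_tone_peak_and_median(self):
        t = np.arange(512) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        out = spectral_metrics(x, 256.0)
        assert out["peak_frequency"] == pytest.approx(10.0, abs=0.5)
        assert out["median_frequency"] == pytest.approx(10.0, abs=0.5)

    def test_two_tone_median_between(self):
        t = np.arange(512) / 256.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        out = spectral_metrics(x, 256.0)
        assert 5.0 < out["median_frequency"] < 15.0

    def test_zero_power_convention(self):
        out = spectral_metrics(np.zeros(64), 256.0)
        assert out == {"median_frequency": 0.0, "peak_frequency": 0.0}


class TestHjorth:
    @pytest.mark.parametrize("freq", [5.0, 10.0, 20.0])
    def test_sinusoid_mobility_closed_form(self, freq):
        # discrete first difference of a sinusoid scales by 2 sin(pi f / fs)
        fs = 256.0
        t = np.arange(int(4 * fs)) / fs
        out = hjorth(np.sin(2 * np.pi * freq * t))
        assert out["mobility"] == pytest.approx(2 * np.sin(np.pi * freq / fs), rel=1e-2)

    def test_white_noise_complexity_above_one(self, rng):
        values = [hjorth(rng.standard_normal(512))["complexity"] for _ in range(10)]
        assert np.mean(values) > 1.0

    def test_constant_convention(self):
        assert hjorth(np.ones(32)) == {"mobility": 0.0, "complexity": 0.0}


class TestSampleEntropy:
    def test_constant_signal_is_zero(self):
        assert sample_entropy(np.ones(50)) == 0.0

    def test_periodic_signal_is_zero(self):
        x = np.tile([1.0, 2.0], 50)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_on_noise(self, seed):
        x = np.random.default_rng(seed).standard_normal(80)
        assert sample_entropy(x) == pytest.approx(sampen_bruteforce(x), abs=1e-12)

    def test_nonnegative_and_capped(self, rng):
        for _ in range(5):
            x = rng.standard_normal(60)
            assert 0.0 <= sample_entropy(x) <= np.log(60)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            sample_entropy(np.ones(3), m=2)


def random_epochs(n, channels, samples=256, bands=("complete", "delta"), seed=0):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n, channels, samples))
    return EpochSet(
        base, rng.integers(0, 2, n), [f"C{i}" for i in range(channels)], 256.0,
        band_epochs={b: base + rng.standard_normal(base.shape) * 0.1 for b in bands},
    )


class TestExtractLayout:
    @pytest.mark.parametrize("feature_set,channels,expected", [
        ("FS1", 3, 3 * 2 * 8),
        ("FS2", 2, 2 * 2 * 8),
    ])
    def test_column_count_identity(self, feature_set, channels, expected):
        fm = extract_features(random_epochs(6, channels),
                              FeatureConfig(feature_set=feature_set))
        assert fm.n_features == expected

    def test_column_order_band_major_then_channel_then_metric(self):
        fm = extract_features(random_epochs(4, 2))
        assert fm.feature_names[:3] == [
            "complete_C0_medfreq", "complete_C0_var", "complete_C0_skew"]
        assert fm.feature_names[8] == "complete_C1_medfreq"
        assert fm.feature_names[16] == "delta_C0_medfreq"

    def test_requires_band_decomposition(self):
        eps = EpochSet(np.zeros((2, 1, 64)), np.zeros(2), ["A"], 256.0)
        with pytest.raises(ValueError):
            extract_features(eps)

    def test_matrix_round_trips_through_csv(self, tmp_path):
        fm = extract_features(random_epochs(5, 2))
        fm.to_csv(tmp_path / "fm.csv")
        back = FeatureMatrix.from_csv(tmp_path / "fm.csv")
        assert back.feature_names == fm.feature_names
        assert np.allclose(back.values, fm.values)
        assert np.array_equal(back.labels, fm.labels)


SCALE_INVARIANT = ("skew", "kurt", "zc")
SCALE_EQUIVARIANT = ("rms", "range", "sd", "iqr", "mad")


class TestScaleBehavior:
    @pytest.mark.parametrize("metric", SCALE_EQUIVARIANT)
    def test_amplitude_metrics_scale_linearly(self, metric, rng):
        x = rng.standard_normal(256)
        c = 3.7
        assert amplitude_stats(c * x)[metric] == pytest.approx(
            c * amplitude_stats(x)[metric], rel=1e-9)

    @pytest.mark.parametrize("metric", SCALE_INVARIANT)
    def test_shape_metrics_scale_invariant(self, metric, rng):
        x = rng.standard_normal(256)
        assert amplitude_stats(3.7 * x)[metric] == pytest.approx(
            amplitude_stats(x)[metric], rel=1e-9)

    def test_variance_scales_quadratically(self, rng):
        x = rng.standard_normal(256)
        assert amplitude_stats(2.0 * x)["var"] == pytest.approx(
            4.0 * amplitude_stats(x)["var"], rel=1e-9)

    def test_hjorth_and_frequencies_scale_invariant(self, rng):
        x = rng.standard_normal(512)
        assert hjorth(3.0 * x) == pytest.approx(hjorth(x))
        a, b = spectral_metrics(x, 256.0), spectral_metrics(3.0 * x, 256.0)
        assert a == pytest.approx(b)

    def test_sampen_scale_invariant(self, rng):
        # tolerance r is proportional to sd, so scaling cancels exactly
        x = rng.standard_normal(100)
        assert sample_entropy(5.0 * x) == pytest.approx(sample_entropy(x), rel=1e-9)


def matrix_from(values, names=None):
    values = np.asarray(values, float)
    names = names or [f"f{i}" for i in range(values.shape[1])]
    return FeatureMatrix(values, names, np.zeros(values.shape[0], dtype=int))


class TestPrune:
    def test_duplicate_column_dropped(self, rng):
        x = rng.standard_normal((50, 3))
        fm = matrix_from(np.column_stack([x, x[:, 0]]), ["a", "b", "c", "a_copy"])
        pruned, audit = prune_correlated(fm)
        assert pruned.feature_names == ["a", "b", "c"]
        dropped = [r for r in audit if r.reason == "correlated"]
        assert [r.name for r in dropped] == ["a_copy"]
        assert dropped[0].partner == "a"

    def test_independent_noise_untouched(self, rng):
        fm = matrix_from(rng.standard_normal((1000, 6)))
        pruned, audit = prune_correlated(fm)
        assert pruned.n_features == 6 and audit == []

    def test_three_identical_keep_first(self, rng):
        x = rng.standard_normal(50)
        fm = matrix_from(np.column_stack([x, x, x]), ["a", "b", "c"])
        pruned, _ = prune_correlated(fm)
        assert pruned.feature_names == ["a"]

    def test_anticorrelated_duplicates_removed(self, rng):
        x = rng.standard_normal(50)
        fm = matrix_from(np.column_stack([x, -x]), ["a", "neg_a"])
        pruned, _ = prune_correlated(fm)
        assert pruned.feature_names == ["a"]

    def test_zero_variance_retained_but_flagged(self, rng):
        fm = matrix_from(np.column_stack([rng.standard_normal(50), np.full(50, 2.0)]),
                         ["a", "const"])
        pruned, audit = prune_correlated(fm)
        assert pruned.feature_names == ["a", "const"]
        assert [(r.name, r.reason) for r in audit] == [("const", "zero_variance")]

    def test_idempotent(self, planted_features):
        again, audit = prune_correlated(planted_features)
        assert again.feature_names == planted_features.feature_names
        assert all(r.reason == "zero_variance" for r in audit)

    def test_survivors_below_threshold(self, planted_features):
        corr = np.corrcoef(planted_features.values, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        assert np.nanmax(np.abs(corr)) <= 0.95
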