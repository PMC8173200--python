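import numpy as np
import pandas as pd
import pytest

from dundun.stats import corrected_threshold, group_feature_tests, vif_screen, welch_t
from dundun.synthetic import synthetic_stimulus_features


def welch_oracle(a, b):
    """Textbook Welch formula, independent of the implementation path."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df


class TestWelchT:
    def test_identical_groups(self, rng):
        a = rng.standard_normal(15)
        r = welch_t(a, a.copy())
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.d == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        for _ in range(10):
            a = rng.standard_normal(rng.integers(5, 40)) * rng.uniform(0.5, 3)
            b = rng.standard_normal(rng.integers(5, 40)) + rng.uniform(-2, 2)
            r = welch_t(a, b)
            t, df = welch_oracle(a, b)
            assert r.t == pytest.approx(t, abs=1e-10)
            assert r.df == pytest.approx(df, abs=1e-10)

    def test_unit_effect_size_recovered_in_simulation(self, rng):
        """A ~ N(0,1) vs B ~ N(1,1) at n=15: mean Cohen's d across 500
        simulations is close to the population value of 1."""
        ds = [
            welch_t(rng.standard_normal(15), rng.standard_normal(15) + 1.0).d
            for _ in range(500)
        ]
        assert abs(np.mean(ds) + 1.0) < 0.1  # A - B, so d is about -1

    def test_degenerate_inputs(self):
        with pytest.warns(UserWarning):
            r = welch_t(np.full(5, 2.0), np.full(5, 2.0))
        assert r.t == 0.0
        with pytest.raises(ValueError):
            welch_t(np.ones(1), np.ones(5))


class TestCorrectedThreshold:
    @pytest.mark.parametrize(
        "alpha,n,expected", [(0.05, 10, 0.005), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_bonferroni(self, alpha, n, expected):
        assert corrected_threshold(alpha, n) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            corrected_threshold(1.5, 10)
        with pytest.raises(ValueError):
            corrected_threshold(0.05, 0)


class TestVifScreen:
    def test_orthogonal_predictors_untouched(self, rng):
        X = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        out = vif_screen(X)
        assert out["retained"] == list("abcd")
        assert all(v < 1.2 for v in out["vif"].values())

    def test_near_duplicate_columns_flagged_and_threshold_met(self, rng):
        """A near-duplicate pair has VIF >> 5 for both members; the screen
        (one pass over the full matrix) removes the pair and leaves a
        retained set whose VIFs all meet the threshold."""
        x1 = rng.standard_normal(100)
        X = pd.DataFrame(
            {"x1": x1, "x2": x1 + rng.standard_normal(100) * 0.02, "z": rng.standard_normal(100)}
        )
        out = vif_screen(X)
        removed = dict(out["removed"])
        assert set(removed) == {"x1", "x2"}
        assert all(v > 5.0 for v in removed.values())
        assert out["retained"] == ["z"]
        assert all(v <= 5.0 for v in out["vif"].values())

    def test_exact_duplicate_handled(self, rng):
        x = rng.standard_normal(50)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(50)})
        out = vif_screen(X)
        assert "a" in out["retained"] and "b" not in out["retained"]

    def test_constructed_timing_intensity_collinearity(self):
        """Feature generator reproduces the observed collinearity block (IOI
        with intensity and intensity change): the screen removes intensity
        change first (largest VIF), then IOI, and keeps intensity."""
        feats = synthetic_stimulus_features(seed=0)
        cols = [c for c in feats.columns if c.startswith(("mean_", "ams_", "pulse_"))]
        out = vif_screen(feats[cols])
        removed = [name for name, _ in out["removed"]]
        assert removed[0] == "mean_intensity_change"
        assert set(removed) == {"mean_intensity_change", "mean_ioi_ms"}
        assert "mean_intensity" in out["retained"]

    def test_too_few_rows_errors(self, rng):
        X = pd.DataFrame(rng.standard_normal((3, 4)))
        X.columns = list("abcd")
        with pytest.raises(ValueError):
            vif_screen(X)


class TestGroupFeatureTests:
    def test_sign_and_significance_pattern(self, stimulus_features):
        """Category contrasts drawn at the observed effect directions come
        back with the right signs: speech louder (t<0 for music-speech),
        longer IOI, smaller intensity change, and null pitch effects."""
        tests = group_feature_tests(stimulus_features).set_index("feature")
        assert tests.loc["mean_intensity", "t"] < 0
        assert tests.loc["mean_ioi_ms", "t"] < 0
        assert tests.loc["mean_intensity_change", "t"] > 0
        assert tests.loc["mean_intensity", "significant_after_correction"]
        assert tests.loc["mean_ioi_ms", "significant_after_correction"]
        assert not tests.loc["mean_pitch", "significant_after_correction"]
        assert not tests.loc["mean_pitch_change", "significant_after_correction"]
        assert tests.attrs["corrected_threshold"] == pytest.approx(0.005)
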