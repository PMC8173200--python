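import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dundun.audio_io import compute_frame_features
from dundun.features import (
    aggregate_notes,
    consecutive_changes,
    interval_ratio,
    interval_ratios,
    probability_density,
    scale_within_recording,
    summarize_stimulus,
)
from dundun.segmentation import OnsetList


class TestScaleWithinRecording:
    def test_percentile_anchors(self):
        v = np.arange(1001, dtype=float)
        out = scale_within_recording(v)
        lo, hi = np.percentile(v, [0.5, 99.5])
        expected_mid = (500 - lo) / (hi - lo)
        assert np.isclose(out[500], expected_mid, atol=1e-12)
        assert out[0] == 0.0 and out[-1] == 1.0  # clipped beyond the percentiles

    def test_constant_sequence_maps_to_half(self):
        assert np.all(scale_within_recording(np.full(10, 3.0)) == 0.5)

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            scale_within_recording(np.array([np.nan, np.nan]))

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_output_in_unit_interval_nan_passthrough(self, seed):
        r = np.random.default_rng(seed)
        v = r.normal(size=50) * r.uniform(0.1, 100)
        v[r.integers(0, 50, 5)] = np.nan
        out = scale_within_recording(v)
        finite = np.isfinite(v)
        assert np.all((out[finite] >= 0) & (out[finite] <= 1))
        assert np.all(np.isnan(out[~finite]))


class TestIntervalRatio:
    @pytest.mark.parametrize(
        "i1,i2,expected",
        [(200.0, 200.0, 0.5), (100.0, 300.0, 0.25), (300.0, 100.0, 0.75)],
    )
    def test_known_ratios(self, i1, i2, expected):
        assert interval_ratio(i1, i2) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_ratio(0.0, 100.0)

    def test_overlapping_pairs(self):
        r = interval_ratios(np.array([100.0, 100.0, 300.0]))
        assert np.allclose(r, [0.5, 0.25])


class TestNoteAggregation:
    def test_two_note_pitches_recovered(self):
        from conftest import RATE, harmonic_tone

        a = harmonic_tone(150.0, 0.5).samples
        b = harmonic_tone(300.0, 0.5).samples
        from dundun.audio_io import AudioRecording

        rec = AudioRecording(np.concatenate([a, b]), RATE, "pair")
        ff = compute_frame_features(rec)
        notes = aggregate_notes(ff, OnsetList("pair", np.array([0.0, 500.0])))
        assert len(notes) == 2
        assert notes["pitch"].iloc[0] == pytest.approx(150.0, rel=0.03)
        assert notes["pitch"].iloc[1] == pytest.approx(300.0, rel=0.03)
        assert notes["ioi_ms"].iloc[0] == pytest.approx(500.0)
        assert np.isnan(notes["ioi_ms"].iloc[1])  # last note has no next onset

    def test_unvoiced_span_keeps_row_with_missing_pitch(self, rng):
        from dundun.audio_io import AudioRecording

        rec = AudioRecording(rng.standard_normal(22050) * 0.1, 22050.0, "wn")
        ff = compute_frame_features(rec)
        notes = aggregate_notes(ff, OnsetList("wn", np.array([0.0, 500.0])))
        assert len(notes) == 2
        assert notes["pitch"].isna().all()
        assert notes["intensity"].notna().all()

    def test_empty_onsets_warns_empty_table(self, sine220_frames):
        with pytest.warns(UserWarning, match="no onsets"):
            notes = aggregate_notes(sine220_frames, OnsetList("tone220", np.empty(0)))
        assert notes.empty

    def test_scaled_columns_in_unit_interval(self, small_corpus):
        recs, gts, _ = small_corpus
        ff = compute_frame_features(recs[0])
        notes = aggregate_notes(ff, gts[0])
        for col in ("scaled_pitch", "scaled_intensity", "scaled_entropy"):
            vals = notes[col].dropna()
            assert np.all((vals >= 0) & (vals <= 1))


class TestConsecutiveChanges:
    def test_absolute_differences(self):
        notes = pd.DataFrame(
            {
                "stimulus_id": "s",
                "scaled_pitch": [0.1, 0.1, 0.1],
                "scaled_intensity": [0.2, 0.7, 0.7],
                "scaled_entropy": [0.0, 1.0, 0.0],
            }
        )
        ch = consecutive_changes(notes)
        assert np.allclose(ch["intensity_change"], [0.5, 0.0])
        assert np.allclose(ch["entropy_change"], [1.0, 1.0])
        assert np.allclose(ch["pitch_change"], [0.0, 0.0])

    def test_single_note_warns_empty(self):
        notes = pd.DataFrame(
            {"stimulus_id": ["s"], "scaled_pitch": [0.5], "scaled_intensity": [0.5], "scaled_entropy": [0.5]}
        )
        with pytest.warns(UserWarning):
            assert consecutive_changes(notes).empty


class TestSummarize:
    def test_single_note_stimulus(self):
        notes = pd.DataFrame(
            {
                "stimulus_id": ["s"],
                "note_index": [0],
                "onset_ms": [0.0],
                "pitch": [150.0],
                "intensity": [0.3],
                "entropy": [-3.0],
                "ioi_ms": [np.nan],
                "scaled_pitch": [0.5],
                "scaled_intensity": [0.5],
                "scaled_entropy": [0.5],
            }
        )
        s = summarize_stimulus(notes, intended_category="music")
        assert s["mean_pitch"] == 150.0 and s["n_notes"] == 1
        assert np.isnan(s["mean_intensity_change"])

    def test_isochronous_ground_truth_iois(self, small_corpus):
        recs, gts, gt_notes = small_corpus
        ff = compute_frame_features(recs[0])
        notes = aggregate_notes(ff, gts[0])
        s = summarize_stimulus(notes)
        true_mean_ioi = np.diff(gts[0].onsets_ms).mean()
        assert s["mean_ioi_ms"] == pytest.approx(true_mean_ioi, rel=1e-6)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            summarize_stimulus(pd.DataFrame())


class TestGroupDensities:
    def test_per_group_density_rows_integrate_to_one(self, rng):
        from dundun.pipeline import group_densities

        notes = pd.DataFrame(
            {
                "stimulus_id": ["m"] * 30 + ["s"] * 30,
                "pitch": rng.normal(170, 20, 60),
                "intensity": rng.uniform(0.1, 0.9, 60),
                "entropy": rng.normal(-4, 1, 60),
                "ioi_ms": rng.uniform(120, 400, 60),
            }
        )
        stimuli = pd.DataFrame(
            {"stimulus_id": ["m", "s"], "intended_category": ["music", "speech"]}
        )
        dens = group_densities(notes, stimuli, n_grid=64)
        assert set(dens["intended_category"]) == {"music", "speech"}
        for (_, _), sub in dens.groupby(["intended_category", "measure"]):
            area = np.trapezoid(sub["density"], sub["grid"])
            assert 0.7 < area < 1.1


class TestProbabilityDensity:
    def test_standard_normal_density_at_zero(self, rng):
        v = rng.standard_normal(10_000)
        grid = np.linspace(-4, 4, 801)
        dens = probability_density(v, grid)
        assert dens[400] == pytest.approx(1 / np.sqrt(2 * np.pi), rel=0.05)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_uniform_density_on_interior(self, rng):
        v = rng.uniform(0, 1, 10_000)
        grid = np.linspace(0.2, 0.8, 61)
        assert np.all(np.abs(probability_density(v, grid) - 1.0) < 0.1)

    def test_degenerate_and_tiny_inputs_error(self):
        with pytest.raises(ValueError):
            probability_density(np.ones(10), np.linspace(0, 2, 5))
        with pytest.raises(ValueError):
            probability_density(np.arange(4.0), np.linspace(0, 2, 5))
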