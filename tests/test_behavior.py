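import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dundun.behavior import (
    ConfusionCounts,
    accuracy,
    confidence_summary,
    confusion,
    group_mcc_test,
    mcc,
    participant_metrics,
)
from dundun.synthetic import ListenerConfig, simulate_listeners


def make_responses(pairs, participant="P1", familiar=True, confidence=3):
    rows = []
    for i, (intended, perceived) in enumerate(pairs):
        rows.append(
            {
                "participant_id": participant,
                "stimulus_id": f"s{i}",
                "intended": intended,
                "perceived": perceived,
                "confidence": confidence,
                "familiar": familiar,
                "yoruba_speaker": False,
            }
        )
    return pd.DataFrame(rows)


class TestConfusion:
    def test_perfect_classification(self):
        pairs = [("music", "music")] * 15 + [("speech", "speech")] * 15
        c = confusion(make_responses(pairs))
        assert (c.TP, c.FP, c.FN, c.TN) == (15, 0, 0, 15)

    def test_all_music_responder(self):
        pairs = [("music", "music")] * 15 + [("speech", "music")] * 15
        c = confusion(make_responses(pairs))
        assert (c.TP, c.FP, c.FN, c.TN) == (15, 15, 0, 0)

    def test_empty_and_bad_labels_error(self):
        with pytest.raises(ValueError):
            confusion(pd.DataFrame())
        bad = make_responses([("music", "music")])
        bad.loc[0, "perceived"] = "noise"
        with pytest.raises(ValueError, match="perceived"):
            confusion(bad)


class TestAccuracyMcc:
    @pytest.mark.parametrize(
        "counts,expected",
        [((15, 0, 0, 15), 1.0), ((15, 15, 0, 0), 0.5), ((10, 3, 5, 12), 22 / 30)],
    )
    def test_accuracy_values(self, counts, expected):
        assert accuracy(ConfusionCounts(*counts)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((15, 0, 0, 15), 1.0),   # perfect performance
            ((0, 15, 15, 0), -1.0),  # perfect misclassification
            ((15, 15, 0, 0), 0.0),   # all-music responder: denominator rule
        ],
    )
    def test_mcc_anchor_values(self, counts, expected):
        assert mcc(ConfusionCounts(*counts)) == pytest.approx(expected)

    def test_mcc_matches_correlation_oracle_all_tables_sum8(self):
        """Brute force: every confusion table with 8 observations must match
        the Pearson correlation of the expanded binary label vectors."""
        for tp, fp, fn in itertools.product(range(9), repeat=3):
            tn = 8 - tp - fp - fn
            if tn < 0:
                continue
            intended = np.array([1] * tp + [0] * fp + [1] * fn + [0] * tn)
            perceived = np.array([1] * tp + [1] * fp + [0] * fn + [0] * tn)
            ours = mcc(ConfusionCounts(tp, fp, fn, tn))
            if intended.std() == 0 or perceived.std() == 0:
                assert ours == 0.0  # zero denominator -> set to 1 -> numerator 0
            else:
                ref = np.corrcoef(intended, perceived)[0, 1]
                assert abs(ours - ref) < 1e-12

    @given(st.tuples(*[st.integers(0, 20)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_mcc_bounded_and_swap_symmetric(self, counts):
        c = ConfusionCounts(*counts)
        v = mcc(c)
        assert -1.0 <= v <= 1.0
        # swapping both classes and predictions leaves MCC unchanged
        swapped = ConfusionCounts(TP=c.TN, FP=c.FN, FN=c.FP, TN=c.TP)
        assert mcc(swapped) == pytest.approx(v, abs=1e-12)

    def test_accuracy_one_iff_no_errors(self):
        assert accuracy(ConfusionCounts(3, 0, 0, 5)) == 1.0
        assert accuracy(ConfusionCounts(3, 1, 0, 5)) < 1.0


class TestConfidenceSummary:
    def test_uniform_ratings_density(self):
        pairs = [("music", "music")] * 8
        df = pd.concat(
            [make_responses(pairs, confidence=c) for c in (1, 2, 3, 4)],
            ignore_index=True,
        )
        df["stimulus_id"] = [f"s{i}" for i in range(len(df))]
        out = confidence_summary(df)
        tp_fam = out[(out.quadrant == "TP") & out.familiar].iloc[0]
        assert tp_fam[["p1", "p2", "p3", "p4"]].to_numpy() == pytest.approx([0.25] * 4)
        assert tp_fam["mean_confidence"] == 2.5

    def test_empty_quadrant_flagged(self):
        out = confidence_summary(make_responses([("music", "music")] * 4))
        assert out[(out.quadrant == "FP") & out.familiar]["empty"].all()

    def test_evidence_tracking_confidence_higher_when_correct(self, stimulus_features):
        """Simulated listeners rate confidence by |decision evidence|, so
        correct quadrants carry higher mean confidence than error quadrants."""
        cfg = ListenerConfig(n_familiar=40, n_unfamiliar=40, seed=9)
        out = confidence_summary(simulate_listeners(cfg, stimulus_features))
        m = out.dropna(subset=["mean_confidence"]).set_index(["quadrant", "familiar"])
        correct = m.loc[[("TP", True), ("TN", True)], "mean_confidence"].mean()
        wrong = m.loc[[("FP", True), ("FN", True)], "mean_confidence"].mean()
        assert correct > wrong


class TestGroupMccTest:
    def test_familiarity_boost_detected(self, stimulus_features):
        cfg = ListenerConfig(n_familiar=50, n_unfamiliar=50, familiarity_gain=1.8, seed=11)
        res = group_mcc_test(simulate_listeners(cfg, stimulus_features))
        assert res["delta_mcc"] > 0
        assert res["p"] < 0.05
        assert res["unfamiliar_vs_zero_p"] < 0.05  # discriminating betas: above chance

    def test_chance_listeners_calibrated_type1(self, stimulus_features):
        """Unfamiliar group at chance: the one-sample test of MCC vs 0
        rejects at ~5% across replicates."""
        rejections = 0
        n_sims = 300
        for s in range(n_sims):
            cfg = ListenerConfig(
                n_familiar=2, n_unfamiliar=30, beta0=0.0, beta={},
                sigma_participant=0.0, sigma_stimulus=0.0, seed=10_000 + s,
            )
            resp = simulate_listeners(cfg, stimulus_features)
            res = group_mcc_test(resp)
            rejections += res["unfamiliar_vs_zero_p"] < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09

    def test_small_group_errors(self):
        pairs = [("music", "music")] * 4
        df = make_responses(pairs, participant="P1", familiar=True)
        df2 = make_responses(pairs, participant="P2", familiar=False)
        with pytest.raises(ValueError, match="2 participants"):
            group_mcc_test(pd.concat([df, df2], ignore_index=True))


class TestParticipantMetrics:
    def test_per_participant_rows(self, listener_responses):
        m = participant_metrics(listener_responses)
        assert len(m) == listener_responses["participant_id"].nunique()
        assert m["mcc"].between(-1, 1).all()
        assert m["accuracy"].between(0, 1).all()
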