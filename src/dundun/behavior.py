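"""Scoring of listener judgments against performer intent.

Music is (arbitrarily) the positive class: TP = intended music perceived as
music, TN = intended speech perceived as speech.  The primary per-participant
index is the Matthews correlation coefficient with the degenerate-case rule
that a zero denominator is replaced by 1 (so an all-one-answer responder
scores exactly 0, i.e. chance).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "validate_responses",
    "confusion",
    "accuracy",
    "mcc",
    "participant_metrics",
    "confidence_summary",
    "group_mcc_test",
]

LABELS = ("music", "speech")

RESPONSE_COLUMNS = [
    "participant_id",
    "stimulus_id",
    "intended",
    "perceived",
    "confidence",
    "familiar",
    "yoruba_speaker",
]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def validate_responses(responses: pd.DataFrame) -> pd.DataFrame:
    if responses.empty:
        raise ValueError("response table is empty")
    missing = set(RESPONSE_COLUMNS) - set(responses.columns)
    if missing:
        raise ValueError(f"response table missing columns: {sorted(missing)}")
    for col in ("intended", "perceived"):
        bad = set(responses[col].unique()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    conf = responses["confidence"]
    if not conf.isin([1, 2, 3, 4]).all():
        raise ValueError("confidence ratings must be integers 1-4")
    dup = responses.duplicated(subset=["participant_id", "stimulus_id"])
    if dup.any():
        raise ValueError("duplicate participant x stimulus rows")
    return responses


def confusion(responses: pd.DataFrame, by: str = "pooled"):
    """Confusion counts, pooled or one :class:`ConfusionCounts` per participant."""
    validate_responses(responses)

    def _count(df: pd.DataFrame) -> ConfusionCounts:
        i_music = df["intended"] == "music"
        p_music = df["perceived"] == "music"
        return ConfusionCounts(
            TP=int((i_music & p_music).sum()),
            FP=int((~i_music & p_music).sum()),
            FN=int((i_music & ~p_music).sum()),
            TN=int((~i_music & ~p_music).sum()),
        )

    if by == "pooled":
        return _count(responses)
    if by == "participant":
        return {pid: _count(df) for pid, df in responses.groupby("participant_id", sort=True)}
    raise ValueError(f"by must be 'pooled' or 'participant', got {by!r}")


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN) / total."""
    if c.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion table")
    return (c.TP + c.TN) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero denominator is set to 1."""
    num = c.TP * c.TN - c.FP * c.FN
    den = math.sqrt(
        (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if den == 0:
        den = 1.0
    return num / den


def participant_metrics(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-participant accuracy and MCC with familiarity flags."""
    per = confusion(responses, by="participant")
    flags = responses.drop_duplicates("participant_id").set_index("participant_id")
    rows = []
    for pid, c in per.items():
        rows.append(
            {
                "participant_id": pid,
                "accuracy": accuracy(c),
                "mcc": mcc(c),
                "familiar": bool(flags.loc[pid, "familiar"]),
                "yoruba_speaker": bool(flags.loc[pid, "yoruba_speaker"]),
            }
        )
    return pd.DataFrame(rows)


def _quadrant(intended: pd.Series, perceived: pd.Series) -> pd.Series:
    i_music = intended == "music"
    p_music = perceived == "music"
    out = pd.Series("TN", index=intended.index)
    out[i_music & p_music] = "TP"
    out[~i_music & p_music] = "FP"
    out[i_music & ~p_music] = "FN"
    return out


def confidence_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Confidence-rating densities and means per response quadrant x familiarity.

    Returns one row per (quadrant, familiar) cell with the normalized
    histogram over ratings 1-4 (``p1``..``p4``), the mean rating and the cell
    count.  Quadrants with zero rows are flagged with ``empty=True``.
    """
    validate_responses(responses)
    df = responses.copy()
    df["quadrant"] = _quadrant(df["intended"], df["perceived"])
    rows = []
    for quad in ("TP", "FP", "FN", "TN"):
        for fam in (True, False):
            cell = df[(df["quadrant"] == quad) & (df["familiar"] == fam)]
            row = {"quadrant": quad, "familiar": fam, "n": len(cell), "empty": cell.empty}
            if cell.empty:
                row.update({f"p{r}": np.nan for r in range(1, 5)})
                row["mean_confidence"] = np.nan
            else:
                counts = cell["confidence"].value_counts(normalize=True)
                row.update({f"p{r}": float(counts.get(r, 0.0)) for r in range(1, 5)})
                row["mean_confidence"] = float(cell["confidence"].mean())
            rows.append(row)
    return pd.DataFrame(rows)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Pooled-SD Cohen's d for two independent samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0
    return (a.mean() - b.mean()) / sp


def group_mcc_test(responses: pd.DataFrame) -> dict:
    """Familiar vs unfamiliar comparison of per-participant MCCs.

    Welch two-sample t-test (familiar - unfamiliar) plus a one-sample t-test
    of the unfamiliar group's MCC against chance (0).
    """
    metrics = participant_metrics(responses)
    fam = metrics.loc[metrics["familiar"], "mcc"].to_numpy()
    unfam = metrics.loc[~metrics["familiar"], "mcc"].to_numpy()
    if fam.size < 2 or unfam.size < 2:
        raise ValueError("need at least 2 participants per familiarity group")
    if fam.var(ddof=1) == 0 and unfam.var(ddof=1) == 0 and fam.mean() == unfam.mean():
        warnings.warn("identical zero-variance groups; t set to 0 by convention")
        t, p, df = 0.0, 1.0, float(fam.size + unfam.size - 2)
    else:
        res = sps.ttest_ind(fam, unfam, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    one = sps.ttest_1samp(unfam, 0.0)
    return {
        "t": t,
        "df": df,
        "p": p,
        "d": cohens_d(fam, unfam),
        "delta_mcc": float(fam.mean() - unfam.mean()),
        "mean_mcc_familiar": float(fam.mean()),
        "mean_mcc_unfamiliar": float(unfam.mean()),
        "unfamiliar_vs_zero_t": float(one.statistic),
        "unfamiliar_vs_zero_p": float(one.pvalue),
    }
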