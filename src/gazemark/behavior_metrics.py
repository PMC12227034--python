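"""Emotion-classification performance measures.

Confusion matrices, Wagner's unbiased hit rate ``Hu = n_ee^2 / (S_e * R_e)``
(the product of hit rate n_ee/S_e and precision n_ee/R_e, robust to response
bias), the multinomial response-bias test, the 5-SD response-time outlier
rule, and grouped medians.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import EMOTIONS

logger = logging.getLogger(__name__)

__all__ = [
    "confusion_matrix",
    "unbiased_hit_rate",
    "response_bias_test",
    "response_label_summary",
    "rt_outlier_filter",
    "median_rt",
    "performance_table",
]


def confusion_matrix(
    trials: pd.DataFrame,
    participant=None,
    condition: str | None = None,
    labels: tuple[str, ...] = EMOTIONS,
) -> pd.DataFrame:
    """Counts of presentations (rows) answered with each label (columns).

    Optional scoping by participant and/or condition.  Unknown labels in
    either field raise.
    """
    scoped = trials
    if participant is not None:
        scoped = scoped[scoped["participant_id"] == participant]
    if condition is not None:
        scoped = scoped[scoped["condition"] == condition]
    unknown = (set(scoped["emotion"]) | set(scoped["response"])) - set(labels)
    if unknown:
        raise ValueError(f"unknown labels: {sorted(unknown)}")
    cm = pd.crosstab(scoped["emotion"], scoped["response"], dropna=False)
    cm = cm.reindex(index=labels, columns=labels, fill_value=0)
    cm.index.name = "emotion"
    cm.columns.name = "response"
    return cm


def unbiased_hit_rate(cm: pd.DataFrame) -> pd.Series:
    """Wagner's Hu per presented category.

    ``Hu_e = n_ee^2 / (S_e * R_e)`` with row sums S_e and column sums R_e.
    A label never used (R_e = 0) yields Hu = 0 -- absent evidence is treated
    as zero performance.  An emotion never presented (S_e = 0) raises.
    """
    s = cm.sum(axis=1)
    r = cm.sum(axis=0)
    if (s == 0).any():
        missing = list(s.index[s == 0])
        raise ValueError(f"emotion(s) never presented in scope: {missing}")
    diag = pd.Series(np.diag(cm.to_numpy()), index=cm.index, dtype=float)
    denom = s.astype(float) * r.reindex(cm.index).astype(float)
    hu = pd.Series(0.0, index=cm.index, name="hu")
    nonzero = denom > 0
    hu[nonzero] = diag[nonzero] ** 2 / denom[nonzero]
    return hu


def response_bias_test(label_counts) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of label usage against uniform expectation.

    Returns ``(chi2, df, p)`` with ``df = K - 1``.
    """
    counts = np.asarray(
        list(label_counts.values()) if isinstance(label_counts, dict) else label_counts,
        dtype=float,
    )
    if counts.size < 2:
        raise ValueError("need at least two labels")
    if counts.sum() <= 0:
        raise ValueError("zero total count")
    chi2, p = stats.chisquare(counts)
    return float(chi2), counts.size - 1, float(p)


def response_label_summary(label_counts: dict[str, float], n_participants: int) -> pd.DataFrame:
    """Share (%) and mean per-participant selections for each response label."""
    total = float(sum(label_counts.values()))
    if total <= 0 or n_participants < 1:
        raise ValueError("need positive totals")
    rows = [
        (label, count, 100.0 * count / total, count / n_participants)
        for label, count in label_counts.items()
    ]
    return pd.DataFrame(
        rows, columns=["label", "count", "share_pct", "mean_per_participant"]
    ).set_index("label")


def rt_outlier_filter(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Remove correct trials with extreme response times.

    Per participant: mean and SD of *all* correct-trial RTs (across
    conditions); correct trials with ``|rt - mean| > 5 * SD`` are dropped.
    Incorrect trials pass through untouched.  Returns the filtered table and
    the removed fraction of correct trials.  Participants with fewer than
    two correct trials are left unfiltered with a warning.
    """
    correct = trials[trials["correct"]]
    n_correct = len(correct)
    if n_correct == 0:
        return trials, 0.0
    drop_idx = []
    for pid, grp in correct.groupby("participant_id", sort=False):
        if len(grp) < 2:
            logger.warning("rt_outlier_filter: participant %s has <2 correct trials", pid)
            continue
        mean = grp["rt_s"].mean()
        sd = grp["rt_s"].std(ddof=1)
        if sd == 0:
            continue
        out = grp.index[(grp["rt_s"] - mean).abs() > 5.0 * sd]
        drop_idx.extend(out)
    removed_fraction = len(drop_idx) / n_correct
    if drop_idx:
        logger.info(
            "rt_outlier_filter: removed %d/%d = %.2f%% of correct trials",
            len(drop_idx),
            n_correct,
            100.0 * removed_fraction,
        )
    return trials.drop(index=drop_idx), removed_fraction


def median_rt(trials: pd.DataFrame, by: list[str]) -> pd.Series:
    """Per-group median RT of correct trials (even counts: mean of the
    central pair).  Empty groups are simply absent, with a warning if the
    grouping was specified over known levels."""
    correct = trials[trials["correct"]]
    if correct.empty:
        logger.warning("median_rt: no correct trials")
        return pd.Series(dtype=float, name="median_rt")
    med = correct.groupby(by)["rt_s"].median()
    med.name = "median_rt"
    return med


def performance_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, condition, emotion): Hu, hit rate and median
    correct RT.  Hu comes from each participant-condition confusion matrix,
    as the repeated-measures analyses consume it."""
    rows = []
    for (pid, cond), grp in trials.groupby(["participant_id", "condition"], sort=True):
        cm = confusion_matrix(grp)
        hu = unbiased_hit_rate(cm)
        hit = pd.Series(np.diag(cm.to_numpy()), index=cm.index) / cm.sum(axis=1).replace(0, np.nan)
        med = grp[grp["correct"]].groupby("emotion")["rt_s"].median()
        for emo in cm.index:
            rows.append(
                (pid, cond, emo, float(hu[emo]), float(hit[emo]), float(med.get(emo, np.nan)))
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "emotion", "hu", "hit_rate", "median_rt_s"],
    )
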