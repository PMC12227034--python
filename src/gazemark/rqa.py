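"""Recurrence quantification analysis (RQA) of per-trial scanpaths.

A trial's scanpath is its ordered sequence of fixation positions.  Two
fixations recur when they lie within a fixed spatial radius of each other
(default 62 px = 2.5 deg visual angle; boundary inclusive).  From the
upper triangle of the N x N recurrence matrix (main diagonal excluded) four
standard measures are derived, following the eye-movement RQA toolbox
conventions with minimum line length 2:

* REC  -- percentage of recurrent fixation pairs, ``100 * 2R / (N(N-1))``;
* DET  -- percentage of recurrent points lying on diagonal runs of length
  >= ``min_line`` (repeated fixation *sequences*), ``100 * |D_L| / R``;
* LAM  -- percentage on horizontal or vertical runs (repeatedly fixated
  *areas*), ``100 * (|H_L| + |V_L|) / (2R)``;
* CORM -- center of recurrence mass, ``100 * sum (j-i) r_ij / ((N-1) R)``;
  small values mean refixations close together in time.

Fixation duration plays no role here; RQA is position/order only.  DET, LAM
and CORM are undefined (NaN) when a trial has no recurrent pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import Geometry, to_image_frame

__all__ = [
    "RecurrenceMatrix",
    "RqaTrialResult",
    "recurrence_matrix",
    "rqa_measures",
    "rqa_trial",
    "per_trial_rqa",
    "aggregate_rqa",
]


class TooFewFixationsError(ValueError):
    """RQA needs at least two fixations in a trial."""


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Boolean N x N recurrence matrix; only the upper triangle (i < j) is
    meaningful, the diagonal is False by construction."""

    matrix: np.ndarray
    radius_px: float

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class RqaTrialResult:
    n: int
    r: int
    rec: float
    det: float  # NaN when r == 0
    lam: float  # NaN when r == 0
    corm: float  # NaN when r == 0


def recurrence_matrix(points: np.ndarray, radius_px: float = 62.0) -> RecurrenceMatrix:
    """Pairwise recurrence of an ordered (N, 2) array of fixation positions.

    Distance boundary is inclusive: exactly ``radius_px`` apart counts as a
    recurrence.  Positions may be in any frame that is a rigid translation
    of the image frame (distances are all that matter).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (N, 2)")
    n = pts.shape[0]
    if n < 2:
        raise TooFewFixationsError(f"need at least 2 fixations, got {n}")
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.hypot(diff[..., 0], diff[..., 1])
    mat = dist <= radius_px
    np.fill_diagonal(mat, False)
    return RecurrenceMatrix(matrix=mat, radius_px=float(radius_px))


def _run_lengths(line: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    runs = []
    count = 0
    for v in line:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def _points_in_long_runs(line: np.ndarray, min_line: int) -> int:
    return sum(r for r in _run_lengths(line) if r >= min_line)


def rqa_measures(m: RecurrenceMatrix, min_line: int = 2) -> RqaTrialResult:
    """REC, DET, LAM and CORM from a recurrence matrix.

    Counting is restricted to the upper triangle.  Diagonal runs for DET
    follow lines parallel to the main diagonal (r_{i,j}, r_{i+1,j+1}, ...);
    LAM counts points on horizontal plus vertical runs, normalised by 2R.
    """
    n = m.n
    upper = np.triu(m.matrix, k=1)
    r = int(upper.sum())
    rec = 100.0 * 2.0 * r / (n * (n - 1))
    if r == 0:
        return RqaTrialResult(n=n, r=0, rec=rec, det=np.nan, lam=np.nan, corm=np.nan)
    d_l = 0
    for offset in range(1, n):
        d_l += _points_in_long_runs(np.diagonal(upper, offset=offset), min_line)
    h_l = sum(_points_in_long_runs(upper[i, :], min_line) for i in range(n))
    v_l = sum(_points_in_long_runs(upper[:, j], min_line) for j in range(n))
    i_idx, j_idx = np.nonzero(upper)
    corm = 100.0 * float(np.sum(j_idx - i_idx)) / ((n - 1) * r)
    det = 100.0 * d_l / r
    lam = 100.0 * (h_l + v_l) / (2.0 * r)
    return RqaTrialResult(n=n, r=r, rec=rec, det=det, lam=lam, corm=corm)


def rqa_trial(
    points: np.ndarray, radius_px: float = 62.0, min_line: int = 2
) -> RqaTrialResult:
    """Convenience: recurrence matrix + measures for one scanpath."""
    return rqa_measures(recurrence_matrix(points, radius_px), min_line=min_line)


def per_trial_rqa(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    radius_px: float = 62.0,
    min_line: int = 2,
    geom: Geometry | None = None,
) -> pd.DataFrame:
    """One RQA result row per trial with >= 2 fixations.

    Positions are taken in the image frame (a per-trial translation of the
    screen frame, so within-trial distances are identical in either frame).
    """
    geom = geom or Geometry()
    fix = to_image_frame(fixations, trials, geom)
    fix = fix.sort_values(["participant_id", "trial_id", "index"], kind="stable")
    rows = []
    for (pid, tid), grp in fix.groupby(["participant_id", "trial_id"], sort=False):
        if len(grp) < 2:
            continue
        res = rqa_trial(
            grp[["x_img", "y_img"]].to_numpy(), radius_px=radius_px, min_line=min_line
        )
        rows.append((pid, tid, res.n, res.r, res.rec, res.det, res.lam, res.corm))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "trial_id", "n", "r", "rec", "det", "lam", "corm"],
    )


def aggregate_rqa(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    radius_px: float = 62.0,
    min_line: int = 2,
    trial_scope: str = "all",
    geom: Geometry | None = None,
) -> pd.DataFrame:
    """Participant x condition x emotion cell means of the four measures.

    ``trial_scope`` restricts to correct trials ("correct_only") or keeps
    everything ("all").  Per-trial NaNs (no recurrent pair) are excluded
    measure-wise; ``n_trials`` counts trials contributing to REC.
    """
    if trial_scope not in ("all", "correct_only"):
        raise ValueError(f"unknown trial_scope: {trial_scope!r}")
    scoped = trials if trial_scope == "all" else trials[trials["correct"]]
    table = per_trial_rqa(
        fixations, trials, radius_px=radius_px, min_line=min_line, geom=geom
    )
    merged = table.merge(
        scoped[["participant_id", "trial_id", "condition", "emotion"]],
        on=["participant_id", "trial_id"],
        how="inner",
    )
    grouped = merged.groupby(["participant_id", "condition", "emotion"], sort=True)
    out = grouped[["rec", "det", "lam", "corm"]].mean()
    out["n_trials"] = grouped["rec"].count()
    return out.reset_index()
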