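"""Shared data model for fixation and trial tables.

Fixation records are eye-tracker output already parsed into fixations: one
row per fixation with screen-pixel coordinates and a duration in
milliseconds.  Trial records carry the experimental metadata (viewed emotion,
presentation condition, where the face image was placed on the screen, the
participant's response and response time).  Both tables are plain pandas
DataFrames validated against a fixed schema; keys are
``(participant_id, trial_id)``.

Coordinate conventions
----------------------
Pixels are 0-based with origin at the top-left corner, x increasing
rightward and y downward.  Cells are half-open bins: a real-valued fixation
coordinate ``(x, y)`` falls in cell ``(floor(x), floor(y))``.  Image-frame
coordinates place the face image so that its top-left corner is at (0, 0);
because the image is centered on a per-trial fixation-cross location, the
screen-to-image transform is a pure per-trial translation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

EMOTIONS: tuple[str, ...] = ("anger", "disgust", "fear", "surprise", "sadness")
CONDITIONS: tuple[str, ...] = (
    "unrestricted",
    "blindspot",
    "neutral_blindspot",
    "spotlight",
)

FIXATION_COLUMNS = (
    "participant_id",
    "trial_id",
    "index",
    "x_screen",
    "y_screen",
    "duration_ms",
    "onset_ms",
)
TRIAL_COLUMNS = (
    "participant_id",
    "trial_id",
    "emotion",
    "condition",
    "identity_id",
    "image_center_x",
    "image_center_y",
    "response",
    "rt_s",
)


class SchemaError(ValueError):
    """A table is missing a required column or carries an unknown label."""


class ReferentialError(ValueError):
    """A fixation references a trial absent from the trial table."""


@dataclass(frozen=True)
class Geometry:
    """Display and analysis geometry, in the screen's native pixels.

    The degree-to-pixel conversions are carried as the three literal pixel
    constants used by the analyses (13 px = 0.5 deg smoothing sigma, 62 px =
    2.5 deg recurrence radius, 30 px = 1.2 deg trigger window) rather than a
    single px/deg scalar, because the three printed conversions imply
    slightly different scalars.
    """

    screen_size: tuple[int, int] = (1024, 768)  # (width, height)
    image_size: tuple[int, int] = (384, 576)  # (width, height)
    smoothing_sigma_px: float = 13.0  # 0.5 deg visual angle
    rqa_radius_px: float = 62.0  # 2.5 deg visual angle
    trigger_radius_px: float = 30.0  # 1.2 deg visual angle

    def __post_init__(self) -> None:
        if min(self.screen_size) <= 0 or min(self.image_size) <= 0:
            raise ValueError("screen_size and image_size must be positive")
        for name in ("smoothing_sigma_px", "rqa_radius_px", "trigger_radius_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing required column {col!r}")


def validate_fixations(fixations: pd.DataFrame) -> pd.DataFrame:
    _require_columns(fixations, FIXATION_COLUMNS, "fixations")
    if len(fixations) and (fixations["duration_ms"] <= 0).any():
        raise SchemaError("fixation durations must be strictly positive")
    return fixations


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    required = [c for c in TRIAL_COLUMNS]
    _require_columns(trials, required, "trials")
    bad_emotion = set(trials["emotion"]) - set(EMOTIONS)
    if bad_emotion:
        raise SchemaError(f"unknown emotion labels: {sorted(bad_emotion)}")
    bad_resp = set(trials["response"]) - set(EMOTIONS)
    if bad_resp:
        raise SchemaError(f"unknown response labels: {sorted(bad_resp)}")
    bad_cond = set(trials["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise SchemaError(f"unknown condition labels: {sorted(bad_cond)}")
    if len(trials) and (trials["rt_s"] <= 0).any():
        raise SchemaError("response times must be strictly positive")
    trials = trials.copy()
    trials["correct"] = trials["response"] == trials["emotion"]
    return trials


def load_dataset(
    fixations_path: str | Path, trials_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load and validate the fixation and trial CSV files.

    Raises :class:`SchemaError` for missing columns or unknown labels and
    :class:`ReferentialError` if a fixation references a trial that the
    trial table does not contain.  Row order is preserved.
    """
    fixations = validate_fixations(pd.read_csv(fixations_path))
    trials = validate_trials(pd.read_csv(trials_path))
    trial_keys = set(zip(trials["participant_id"], trials["trial_id"]))
    fix_keys = set(zip(fixations["participant_id"], fixations["trial_id"]))
    orphans = fix_keys - trial_keys
    if orphans:
        example = sorted(orphans)[0]
        raise ReferentialError(
            f"{len(orphans)} fixation trial key(s) absent from the trial table, "
            f"e.g. {example}"
        )
    return fixations, trials


def write_dataset(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    fixations_path: str | Path,
    trials_path: str | Path,
) -> None:
    """Write both tables as CSV (UTF-8, comma-separated, full precision)."""
    fixations.loc[:, list(FIXATION_COLUMNS)].to_csv(fixations_path, index=False)
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(trials_path, index=False)


def filter_min_duration(fixations: pd.DataFrame, min_ms: float = 100.0) -> pd.DataFrame:
    """Drop fixations shorter than ``min_ms`` (boundary inclusive: kept at 100).

    The tracker's minimum-duration rule is applied to already-parsed
    fixations; original row order is preserved and the number of removals is
    logged.
    """
    keep = fixations["duration_ms"] >= min_ms
    removed = int((~keep).sum())
    if removed:
        logger.info("filter_min_duration: removed %d of %d fixations", removed, len(fixations))
    return fixations.loc[keep]


def to_image_frame(
    fixations: pd.DataFrame, trials: pd.DataFrame, geom: Geometry | None = None
) -> pd.DataFrame:
    """Re-express fixations in image coordinates of each trial's face image.

    Adds columns ``x_img``, ``y_img`` and ``in_bounds`` (0-based, half-open:
    in bounds iff ``0 <= x_img < width`` and ``0 <= y_img < height``).  The
    transform is a per-trial translation, so pairwise distances within a
    trial are unchanged.
    """
    geom = geom or Geometry()
    w, h = geom.image_size
    merged = fixations.merge(
        trials[["participant_id", "trial_id", "image_center_x", "image_center_y"]],
        on=["participant_id", "trial_id"],
        how="left",
        validate="many_to_one",
    )
    if merged["image_center_x"].isna().any():
        n = int(merged["image_center_x"].isna().sum())
        raise ReferentialError(f"{n} fixation(s) reference trials without metadata")
    out = fixations.copy()
    out["x_img"] = merged["x_screen"].to_numpy() - (
        merged["image_center_x"].to_numpy() - w / 2
    )
    out["y_img"] = merged["y_screen"].to_numpy() - (
        merged["image_center_y"].to_numpy() - h / 2
    )
    out["in_bounds"] = (
        (out["x_img"] >= 0) & (out["x_img"] < w) & (out["y_img"] >= 0) & (out["y_img"] < h)
    )
    return out


def first_fixations(fixations: pd.DataFrame) -> pd.DataFrame:
    """Keep only each trial's first recorded fixation after image onset.

    The fixation that triggered stimulus onset (on the cross) is not part of
    the recorded sequence, so "first" is simply the lowest ``index`` within
    each ``(participant_id, trial_id)`` group.  Works on shuffled input.
    """
    if fixations.empty:
        return fixations
    order = fixations.sort_values("index", kind="stable")
    first = order.groupby(["participant_id", "trial_id"], sort=False).head(1)
    return first.sort_index()
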