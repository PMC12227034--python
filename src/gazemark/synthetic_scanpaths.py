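"""Synthetic scanpath generator with known ground truth.

Emulates the structure of a gaze-contingent emotion-classification
experiment: 35 participants x (12 identities x 5 emotions x 4 presentation
conditions) = 240 three-second trials per participant, each trial an ordered
sequence of 5-12 fixations with log-normal durations.  The generative model
is deliberately simple but carries the statistical structure the analyses
assume:

* emotion-specific spatial hotspots -- each emotion draws fixations from a
  Gaussian mixture over facial landmarks, with a dominant "diagnostic"
  landmark (central brow for anger, philtrum for disgust, left eye for fear,
  mouth for surprise, right eye for sadness);
* a common center bias and a first fixation near the face center, slightly
  up and to the left, shared by all emotions;
* condition-specific refixation dynamics -- with some per-condition
  probability a fixation revisits an earlier location (within jitter of the
  recurrence radius), less often and at shorter lags when extrafoveal
  information is absent (spotlight);
* confusion-structured categorical responses (disgust answered as anger and
  fear as surprise more than other errors; the spotlight condition markedly
  less accurate) and response times slower in the spotlight condition.

The generator is deterministic given ``seed``; each participant consumes an
independent RNG stream derived from the master seed, so per-participant data
are stable under changes to ``n_participants``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import CONDITIONS, EMOTIONS, Geometry

__all__ = [
    "LandmarkSet",
    "SimConfig",
    "GroundTruth",
    "default_config",
    "disjoint_hotspot_config",
    "category_free_config",
    "spotlight_divergent_config",
    "generate_dataset",
    "permute_labels",
    "empirical_refixation_rate",
]


class ConfigError(ValueError):
    """The simulation configuration is inconsistent."""


@dataclass(frozen=True)
class LandmarkSet:
    """Named facial landmarks in image coordinates (384 x 576 px)."""

    points: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "left_eye": (140.0, 220.0),
            "right_eye": (244.0, 220.0),
            "nasion": (192.0, 205.0),
            "brow_center": (192.0, 180.0),
            "nose_tip": (192.0, 300.0),
            "philtrum": (192.0, 330.0),
            "mouth_center": (192.0, 370.0),
        }
    )

    def __post_init__(self) -> None:
        for name, (x, y) in self.points.items():
            if not (0 <= x < 384 and 0 <= y < 576):
                raise ConfigError(f"landmark {name!r} outside image bounds: {(x, y)}")


DIAGNOSTIC_LANDMARKS: dict[str, str] = {
    "anger": "brow_center",
    "disgust": "philtrum",
    "fear": "left_eye",
    "surprise": "mouth_center",
    "sadness": "right_eye",
}

_DEFAULT_HOTSPOT_WEIGHTS: dict[str, dict[str, float]] = {
    "anger": {"brow_center": 0.55, "nasion": 0.15, "left_eye": 0.15, "right_eye": 0.10, "nose_tip": 0.05},
    "disgust": {"philtrum": 0.50, "nose_tip": 0.15, "brow_center": 0.15, "mouth_center": 0.10, "nasion": 0.10},
    "fear": {"left_eye": 0.50, "mouth_center": 0.15, "right_eye": 0.15, "nasion": 0.10, "brow_center": 0.10},
    "surprise": {"mouth_center": 0.45, "left_eye": 0.25, "nose_tip": 0.15, "right_eye": 0.10, "nasion": 0.05},
    "sadness": {"right_eye": 0.50, "nose_tip": 0.20, "left_eye": 0.15, "philtrum": 0.10, "nasion": 0.05},
}

# Response rows (true emotion -> probability over response labels).  The
# confusion structure mirrors the qualitative pattern typical of five-way
# emotion classification -- disgust->anger and fear->surprise inflated, the
# foveal-only spotlight condition much less accurate -- without asserting any
# particular study's exact rates.
_PRESENT_ROWS: dict[str, dict[str, float]] = {
    "anger": {"anger": 0.78, "disgust": 0.06, "fear": 0.04, "surprise": 0.04, "sadness": 0.08},
    "disgust": {"anger": 0.24, "disgust": 0.62, "fear": 0.05, "surprise": 0.03, "sadness": 0.06},
    "fear": {"anger": 0.06, "disgust": 0.05, "fear": 0.64, "surprise": 0.17, "sadness": 0.08},
    "surprise": {"anger": 0.08, "disgust": 0.05, "fear": 0.04, "surprise": 0.74, "sadness": 0.09},
    "sadness": {"anger": 0.06, "disgust": 0.06, "fear": 0.07, "surprise": 0.03, "sadness": 0.78},
}
_SPOTLIGHT_ROWS: dict[str, dict[str, float]] = {
    "anger": {"anger": 0.42, "disgust": 0.13, "fear": 0.10, "surprise": 0.10, "sadness": 0.25},
    "disgust": {"anger": 0.32, "disgust": 0.45, "fear": 0.08, "surprise": 0.06, "sadness": 0.09},
    "fear": {"anger": 0.08, "disgust": 0.08, "fear": 0.48, "surprise": 0.26, "sadness": 0.10},
    "surprise": {"anger": 0.12, "disgust": 0.10, "fear": 0.16, "surprise": 0.52, "sadness": 0.10},
    "sadness": {"anger": 0.22, "disgust": 0.13, "fear": 0.15, "surprise": 0.10, "sadness": 0.40},
}


def _default_response_model() -> dict[tuple[str, str], dict[str, float]]:
    model: dict[tuple[str, str], dict[str, float]] = {}
    for emotion in EMOTIONS:
        for condition in CONDITIONS:
            if condition == "spotlight":
                row = dict(_SPOTLIGHT_ROWS[emotion])
            else:
                row = dict(_PRESENT_ROWS[emotion])
                if condition == "neutral_blindspot":
                    # marginally harder: shave 2 points off the diagonal
                    top_err = max((k for k in row if k != emotion), key=row.get)
                    row[emotion] -= 0.02
                    row[top_err] += 0.02
            model[(emotion, condition)] = row
    return model


@dataclass(frozen=True)
class SimConfig:
    """Everything the generator needs; defaults emulate the study design."""

    n_participants: int = 35
    identities: int = 12
    emotions: tuple[str, ...] = EMOTIONS
    conditions: tuple[str, ...] = CONDITIONS
    fix_count_range: tuple[int, int] = (5, 12)
    duration_median_ms: float = 250.0
    duration_sigma_log: float = 0.35
    landmarks: LandmarkSet = field(default_factory=LandmarkSet)
    hotspot_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {e: dict(w) for e, w in _DEFAULT_HOTSPOT_WEIGHTS.items()}
    )
    condition_hotspot_overrides: dict[str, dict[str, dict[str, float]]] | None = None
    hotspot_sd: float = 18.0
    center_bias_weight: float = 0.15
    center_bias_sd: float = 55.0
    first_fix_offset: tuple[float, float] = (-10.0, -20.0)
    first_fix_sd: float = 8.0
    refixation_prob: dict[str, float] = field(
        default_factory=lambda: {
            "unrestricted": 0.45,
            "blindspot": 0.45,
            "neutral_blindspot": 0.43,
            "spotlight": 0.30,
        }
    )
    refixation_jitter_px: float = 31.0  # half the 62 px recurrence radius
    revisit_lag_model: dict[str, str] = field(
        default_factory=lambda: {
            "unrestricted": "uniform",
            "blindspot": "uniform",
            "neutral_blindspot": "uniform",
            "spotlight": "recent",
        }
    )
    response_model: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_response_model
    )
    rt_condition_base: dict[str, float] = field(
        default_factory=lambda: {
            "unrestricted": 4.00,
            "blindspot": 4.05,
            "neutral_blindspot": 4.09,
            "spotlight": 4.44,
        }
    )
    rt_emotion_shift: dict[str, float] = field(
        default_factory=lambda: {
            "anger": -0.10,
            "sadness": -0.08,
            "fear": 0.08,
            "surprise": 0.12,
            "disgust": 0.12,
        }
    )
    rt_participant_sd: float = 0.25
    rt_trial_sd: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.identities < 1:
            raise ConfigError("n_participants and identities must be >= 1")
        lo, hi = self.fix_count_range
        if not (1 <= lo <= hi):
            raise ConfigError("fix_count_range must satisfy 1 <= lo <= hi")
        for emotion in self.emotions:
            self._check_mixture(self.hotspot_weights.get(emotion), f"hotspot_weights[{emotion}]")
        if self.condition_hotspot_overrides:
            for condition, per_emotion in self.condition_hotspot_overrides.items():
                for emotion, row in per_emotion.items():
                    self._check_mixture(row, f"override[{condition}][{emotion}]")
        for (emotion, condition), row in self.response_model.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigError(
                    f"response row for {(emotion, condition)} sums to {total}, not 1"
                )
            if any(not (0.0 <= p <= 1.0) for p in row.values()):
                raise ConfigError(f"response row for {(emotion, condition)} has p outside [0,1]")
        for condition in self.conditions:
            p = self.refixation_prob[condition]
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"refixation_prob[{condition}] = {p} outside [0,1]")

    def _check_mixture(self, row: dict[str, float] | None, what: str) -> None:
        if row is None:
            raise ConfigError(f"{what} missing")
        total = sum(row.values())
        if abs(total - 1.0) > 1e-8:
            raise ConfigError(f"{what} sums to {total}, not 1")
        if any(w < 0 for w in row.values()):
            raise ConfigError(f"{what} has negative weight")
        unknown = set(row) - set(self.landmarks.points)
        if unknown:
            raise ConfigError(f"{what} references unknown landmarks {sorted(unknown)}")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a dataset."""

    diagnostic_landmarks: dict[str, str]
    refixation_prob: dict[str, float]
    accuracy: dict[tuple[str, str], float]
    seed: int


def default_config(seed: int = 0, **overrides) -> SimConfig:
    return dataclasses.replace(SimConfig(), seed=seed, **overrides)


def disjoint_hotspot_config(seed: int = 0, **overrides) -> SimConfig:
    """Degenerate, fully separable configuration: every non-first fixation
    lands exactly on the emotion's single diagnostic landmark (no hotspot
    noise, no center bias, no refixation process, deterministic first
    fixation)."""
    one_hot = {e: {DIAGNOSTIC_LANDMARKS[e]: 1.0} for e in EMOTIONS}
    return default_config(
        seed=seed,
        hotspot_weights=one_hot,
        hotspot_sd=0.0,
        center_bias_weight=0.0,
        refixation_prob={c: 0.0 for c in CONDITIONS},
        refixation_jitter_px=0.0,
        first_fix_sd=0.0,
        **overrides,
    )


def category_free_config(seed: int = 0, **overrides) -> SimConfig:
    """Null configuration: all emotions share one hotspot mixture, so
    fixation locations carry no information about the viewed category."""
    shared = {"nasion": 0.3, "nose_tip": 0.3, "left_eye": 0.2, "right_eye": 0.2}
    return default_config(
        seed=seed, hotspot_weights={e: dict(shared) for e in EMOTIONS}, **overrides
    )


def spotlight_divergent_config(seed: int = 0, **overrides) -> SimConfig:
    """Spotlight fixations drawn from a distinct, mouth-dominated mixture for
    every emotion, emulating foveal-only exploration diverging from the
    other conditions."""
    mouthy = {"mouth_center": 0.5, "philtrum": 0.3, "nose_tip": 0.2}
    overrides_map = {"spotlight": {e: dict(mouthy) for e in EMOTIONS}}
    return default_config(seed=seed, condition_hotspot_overrides=overrides_map, **overrides)


def _draw_truncated(rng, mean_xy, sd, w, h, max_tries=100):
    if sd == 0.0:
        return float(mean_xy[0]), float(mean_xy[1])
    for _ in range(max_tries):
        x = rng.normal(mean_xy[0], sd)
        y = rng.normal(mean_xy[1], sd)
        if 0 <= x < w and 0 <= y < h:
            return x, y
    return float(np.clip(x, 0, w - 1e-6)), float(np.clip(y, 0, h - 1e-6))


def generate_dataset(
    config: SimConfig | None = None, geom: Geometry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (fixations, trials, ground_truth) under ``config``.

    Trials follow the full factorial design: every participant sees each
    (identity, emotion) once per condition.  Fixations are returned in
    screen coordinates; the image center varies per trial over the 25
    fixation-cross locations (offsets of 0, +-25, +-50 px per axis from
    screen center).
    """
    config = config or SimConfig()
    config.validate()
    geom = geom or Geometry()
    w, h = geom.image_size
    sw, sh = geom.screen_size
    face_center = (w / 2, h / 2)
    mu_log = math.log(config.duration_median_ms)
    offsets = np.array([-50.0, -25.0, 0.0, 25.0, 50.0])
    emotions = list(config.emotions)
    label_list = list(EMOTIONS)

    fix_rows: list[tuple] = []
    trial_rows: list[tuple] = []

    for p_idx in range(config.n_participants):
        rng = np.random.default_rng([config.seed, p_idx])
        participant_id = f"P{p_idx + 1:02d}"
        subj_rt = rng.normal(0.0, config.rt_participant_sd)
        trial_counter = 0
        for condition in config.conditions:
            refix_p = config.refixation_prob[condition]
            lag_model = config.revisit_lag_model.get(condition, "uniform")
            for emotion in emotions:
                weights = config.hotspot_weights[emotion]
                if config.condition_hotspot_overrides:
                    weights = config.condition_hotspot_overrides.get(condition, {}).get(
                        emotion, weights
                    )
                names = list(weights)
                probs = np.array([weights[n] for n in names])
                probs = probs / probs.sum()
                points = np.array([config.landmarks.points[n] for n in names])
                resp_row = config.response_model[(emotion, condition)]
                resp_p = np.array([resp_row.get(lbl, 0.0) for lbl in label_list])
                resp_p = resp_p / resp_p.sum()
                for identity in range(1, config.identities + 1):
                    trial_counter += 1
                    trial_id = f"T{trial_counter:03d}"
                    cx = sw / 2 + offsets[rng.integers(0, 5)]
                    cy = sh / 2 + offsets[rng.integers(0, 5)]
                    lo, hi = config.fix_count_range
                    n_fix = int(rng.integers(lo, hi + 1))
                    durations = rng.lognormal(mu_log, config.duration_sigma_log, n_fix)
                    xs = np.empty(n_fix)
                    ys = np.empty(n_fix)
                    x0 = face_center[0] + config.first_fix_offset[0]
                    y0 = face_center[1] + config.first_fix_offset[1]
                    xs[0], ys[0] = _draw_truncated(rng, (x0, y0), config.first_fix_sd, w, h)
                    for k in range(1, n_fix):
                        if rng.random() < refix_p:
                            if lag_model == "recent":
                                g = int(rng.geometric(0.55))
                                j = max(0, k - g)
                            else:
                                j = int(rng.integers(0, k))
                            bx, by = xs[j], ys[j]
                            if config.refixation_jitter_px > 0:
                                r = config.refixation_jitter_px * math.sqrt(rng.random())
                                theta = rng.uniform(0.0, 2 * math.pi)
                                bx += r * math.cos(theta)
                                by += r * math.sin(theta)
                            xs[k] = float(np.clip(bx, 0, w - 1e-6))
                            ys[k] = float(np.clip(by, 0, h - 1e-6))
                        elif rng.random() < config.center_bias_weight:
                            xs[k], ys[k] = _draw_truncated(
                                rng, face_center, config.center_bias_sd, w, h
                            )
                        else:
                            i = int(rng.choice(len(names), p=probs))
                            xs[k], ys[k] = _draw_truncated(
                                rng, points[i], config.hotspot_sd, w, h
                            )
                    # screen frame: image top-left at (cx - w/2, cy - h/2)
                    xs_scr = xs + (cx - w / 2)
                    ys_scr = ys + (cy - h / 2)
                    onset = 0.0
                    for k in range(n_fix):
                        fix_rows.append(
                            (
                                participant_id,
                                trial_id,
                                k + 1,
                                xs_scr[k],
                                ys_scr[k],
                                durations[k],
                                onset,
                            )
                        )
                        onset += durations[k] + 30.0  # 30 ms saccade gap
                    response = label_list[int(rng.choice(len(label_list), p=resp_p))]
                    rt = (
                        config.rt_condition_base[condition]
                        + config.rt_emotion_shift.get(emotion, 0.0)
                        + subj_rt
                        + rng.normal(0.0, config.rt_trial_sd)
                    )
                    rt = max(0.8, rt)
                    trial_rows.append(
                        (
                            participant_id,
                            trial_id,
                            emotion,
                            condition,
                            identity,
                            cx,
                            cy,
                            response,
                            rt,
                        )
                    )

    fixations = pd.DataFrame(
        fix_rows,
        columns=[
            "participant_id",
            "trial_id",
            "index",
            "x_screen",
            "y_screen",
            "duration_ms",
            "onset_ms",
        ],
    )
    trials = pd.DataFrame(
        trial_rows,
        columns=[
            "participant_id",
            "trial_id",
            "emotion",
            "condition",
            "identity_id",
            "image_center_x",
            "image_center_y",
            "response",
            "rt_s",
        ],
    )
    trials["correct"] = trials["response"] == trials["emotion"]
    truth = GroundTruth(
        diagnostic_landmarks={
            e: max(config.hotspot_weights[e], key=config.hotspot_weights[e].get)
            for e in emotions
        },
        refixation_prob=dict(config.refixation_prob),
        accuracy={
            (e, c): config.response_model[(e, c)].get(e, 0.0)
            for e in emotions
            for c in config.conditions
        },
        seed=config.seed,
    )
    return fixations, trials, truth


def permute_labels(trials: pd.DataFrame, field_name: str, seed: int) -> pd.DataFrame:
    """Permute one metadata field across trials *within* each participant.

    Everything else is unchanged, so the per-participant multiset of labels
    is preserved; used to build decoding null models.
    """
    if field_name not in trials.columns:
        raise KeyError(f"no such field: {field_name}")
    out = trials.copy()
    rng = np.random.default_rng(seed)
    for _, idx in out.groupby("participant_id", sort=False).groups.items():
        values = out.loc[idx, field_name].to_numpy()
        out.loc[idx, field_name] = values[rng.permutation(len(values))]
    if {"emotion", "response"} <= set(out.columns):
        out["correct"] = out["response"] == out["emotion"]
    return out


def empirical_refixation_rate(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    radius_px: float = 62.0,
    geom: Geometry | None = None,
) -> pd.Series:
    """Mean per-trial recurrence rate (REC/100) by condition.

    Delegates the pairwise recurrence computation to :mod:`gazemark.rqa`;
    trials with fewer than two fixations are excluded.
    """
    from . import rqa  # local import to avoid a cycle

    geom = geom or Geometry()
    table = rqa.per_trial_rqa(fixations, trials, radius_px=radius_px, geom=geom)
    merged = table.merge(
        trials[["participant_id", "trial_id", "condition"]],
        on=["participant_id", "trial_id"],
    )
    return merged.groupby("condition")["rec"].mean() / 100.0
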