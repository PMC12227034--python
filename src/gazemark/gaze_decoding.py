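"""Leave-one-subject-out (LOSO) decoding of viewed category from gaze.

For each held-out participant, category-specific *marginal* FDMs are built
from the remaining participants' trials only.  Each of the held-out
participant's trials receives one goodness-of-fit score per category: the
sum of the marginal-map values at the trial's fixated cells, weighted by
fixation duration.  The category with the largest score is the prediction;
per-participant accuracy is the fraction of correctly predicted trials, and
the accuracies are tested against chance (1/K) with a one-sided t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core_data import CONDITIONS, EMOTIONS, Geometry, to_image_frame
from .density_maps import DensityMap, FdmSpec, category_fdms, marginal_maps, scope_fixations, scope_trials

logger = logging.getLogger(__name__)

__all__ = [
    "DecodingSpec",
    "DecodingResult",
    "goodness_of_fit",
    "predict_trial",
    "loso_decode",
    "test_vs_chance",
]

#: Canonical tie-breaking orders per category field.
CANONICAL_ORDER = {"emotion": EMOTIONS, "condition": CONDITIONS}


@dataclass(frozen=True)
class DecodingSpec:
    """What is decoded from which trials and fixations.

    ``category_field`` is "emotion" (chance 1/5) or "condition" (chance
    1/4).  ``condition_filter`` restricts emotion decoding to a single
    presentation condition (both training and test trials).
    """

    category_field: str = "emotion"
    condition_filter: str = "all"
    fixation_scope: str = "all"
    trial_scope: str = "all"

    def __post_init__(self) -> None:
        if self.category_field not in CANONICAL_ORDER:
            raise ValueError(f"unknown category_field {self.category_field!r}")
        if self.category_field == "condition" and self.condition_filter != "all":
            raise ValueError("condition decoding cannot filter by condition")

    @property
    def categories(self) -> tuple[str, ...]:
        return CANONICAL_ORDER[self.category_field]

    @property
    def chance(self) -> float:
        return 1.0 / len(self.categories)

    def fdm_spec(self) -> FdmSpec:
        return FdmSpec(
            fixation_scope=self.fixation_scope,
            trial_scope=self.trial_scope,
            condition_filter=self.condition_filter,
        )


@dataclass(frozen=True)
class DecodingResult:
    accuracies: pd.Series  # per participant
    mean: float
    sd: float
    chance: float
    t: float
    df: int
    p_one_sided: float
    d: float
    d_ci_lower: float  # one-sided 95% CI: (lower, inf)
    predictions: pd.DataFrame  # per-trial predicted and true labels
    tie_count: int
    dropped_participants: tuple = ()


def goodness_of_fit(
    trial_fixations: pd.DataFrame,
    marginal_map: DensityMap,
    trial: pd.Series | None = None,
    geom: Geometry | None = None,
) -> float:
    """Duration-weighted sum of marginal-map values at fixated cells.

    ``trial_fixations`` may already carry image-frame columns (``x_img``,
    ``y_img``, ``in_bounds``); otherwise ``trial`` metadata is required to
    transform.  Out-of-bounds fixations contribute 0.  The same floor
    binning as map construction keeps train/test geometry identical.
    """
    if marginal_map.stage != "marginal":
        raise ValueError(f"expected a marginal map, got stage {marginal_map.stage!r}")
    fix = trial_fixations
    if "x_img" not in fix.columns:
        if trial is None:
            raise ValueError("trial metadata required to transform fixations")
        trials = pd.DataFrame([trial])
        fix = to_image_frame(fix, trials, geom or Geometry())
    inb = fix["in_bounds"].to_numpy()
    if not inb.any():
        return 0.0
    xi = np.floor(fix.loc[inb, "x_img"].to_numpy()).astype(int)
    yi = np.floor(fix.loc[inb, "y_img"].to_numpy()).astype(int)
    dur = fix.loc[inb, "duration_ms"].to_numpy()
    return float(np.sum(dur * marginal_map.grid[yi, xi]))


def predict_trial(
    trial_fixations: pd.DataFrame,
    marginal_by_category: dict[str, DensityMap],
    order: tuple[str, ...] | None = None,
) -> tuple[str, bool]:
    """Argmax of goodness-of-fit over categories.

    Returns ``(label, tied)``; exact ties are broken by canonical category
    order and flagged.
    """
    if not marginal_by_category:
        raise ValueError("need at least one category map")
    order = order or tuple(marginal_by_category)
    scores = np.array(
        [goodness_of_fit(trial_fixations, marginal_by_category[c]) for c in order]
    )
    best = int(np.argmax(scores))
    tied = bool(np.sum(scores == scores[best]) > 1)
    return order[best], tied


def loso_decode(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    spec: DecodingSpec,
    geom: Geometry | None = None,
    sigma_px: float | None = None,
) -> DecodingResult:
    """Leave-one-subject-out decoding under ``spec``.

    Training maps for each fold are computed only from the non-held-out
    participants (no leakage); the held-out participant's scoped trials are
    scored against the fold's marginal maps.  A fold with an empty category
    raises; a participant with zero scoped trials is dropped with a warning.
    """
    geom = geom or Geometry()
    participants = sorted(trials["participant_id"].unique())
    if len(participants) < 2:
        raise ValueError("LOSO needs at least two participants")
    fdm_spec = spec.fdm_spec()
    scoped_trials = scope_trials(trials, fdm_spec)
    scoped_fix = scope_fixations(fixations, fdm_spec)
    fix_img = to_image_frame(scoped_fix, trials, geom)
    fix_by_trial = dict(tuple(fix_img.groupby(["participant_id", "trial_id"], sort=False)))

    order = spec.categories
    acc: dict[str, float] = {}
    pred_rows = []
    ties = 0
    dropped = []
    for held_out in participants:
        test_trials = scoped_trials[scoped_trials["participant_id"] == held_out]
        if test_trials.empty:
            logger.warning("loso_decode: participant %s has zero scoped trials", held_out)
            dropped.append(held_out)
            continue
        try:
            cat_maps = category_fdms(
                fixations,
                trials,
                category_field=spec.category_field,
                spec=fdm_spec,
                exclude_participant=held_out,
                geom=geom,
                sigma_px=sigma_px,
                categories=list(order),
            )
        except ValueError as err:
            raise ValueError(f"fold holding out {held_out}: {err}") from err
        marginals = marginal_maps(cat_maps)
        n_correct = 0
        for _, trial in test_trials.iterrows():
            key = (trial["participant_id"], trial["trial_id"])
            tf = fix_by_trial.get(key)
            if tf is None or tf.empty:
                continue
            label, tied = predict_trial(tf, marginals, order=order)
            ties += tied
            truth = trial[spec.category_field]
            n_correct += label == truth
            pred_rows.append((held_out, trial["trial_id"], truth, label, tied))
        acc[held_out] = n_correct / len(test_trials)
    accuracies = pd.Series(acc, name="accuracy")
    predictions = pd.DataFrame(
        pred_rows, columns=["participant_id", "trial_id", "true", "predicted", "tied"]
    )
    try:
        t, df, p, d, ci_lower = test_vs_chance(accuracies.to_numpy(), spec.chance)
    except ValueError as err:
        # zero-variance accuracies: report them exactly, leave the test undefined
        logger.warning("loso_decode: %s", err)
        t = p = d = ci_lower = float("nan")
        df = len(accuracies) - 1
    return DecodingResult(
        accuracies=accuracies,
        mean=float(accuracies.mean()),
        sd=float(accuracies.std(ddof=1)),
        chance=spec.chance,
        t=t,
        df=df,
        p_one_sided=p,
        d=d,
        d_ci_lower=ci_lower,
        predictions=predictions,
        tie_count=int(ties),
        dropped_participants=tuple(dropped),
    )


def test_vs_chance(
    accuracies: np.ndarray, chance: float
) -> tuple[float, int, float, float, float]:
    """One-sided one-sample t-test of decoding accuracies against chance.

    Returns ``(t, df, p_one_sided, d, d_ci_lower)`` where ``d`` is Cohen's d
    ``(mean - chance) / sd`` and ``d_ci_lower`` the lower bound of the
    one-sided 95% CI for d, obtained by noncentral-t inversion (the upper
    bound is +inf).  Zero variance raises: report the exact accuracies
    instead.
    """
    x = np.asarray(accuracies, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two accuracies")
    sd = x.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError(
            f"zero variance in accuracies (all equal {x[0]:.4f}); t-test undefined"
        )
    df = n - 1
    t = (x.mean() - chance) / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df))
    d = (x.mean() - chance) / sd
    ci_lower = _noncentral_d_lower(t, df, n, level=0.95)
    return float(t), df, p, float(d), float(ci_lower)


def _noncentral_d_lower(t_obs: float, df: int, n: int, level: float = 0.95) -> float:
    """Lower bound of the one-sided CI for Cohen's d via nc-t inversion.

    Solves for the noncentrality nc at which observing ``t_obs`` or more has
    probability 1 - level; then d = nc / sqrt(n).
    """

    def upper_tail(nc):
        return stats.nct.sf(t_obs, df, nc) - (1.0 - level)

    lo, hi = t_obs - 2.0, t_obs + 2.0
    while upper_tail(lo) > 0 and lo > t_obs - 200:
        lo -= 2.0
    while upper_tail(hi) < 0 and hi < t_obs + 200:
        hi += 2.0
    nc = optimize.brentq(upper_tail, lo, hi, xtol=1e-8)
    return nc / np.sqrt(n)
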