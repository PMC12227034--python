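"""Fixation density maps (FDMs) and their comparisons.

An FDM accumulates fixation durations over image-frame pixel cells: each
in-bounds fixation adds its duration (ms) to the cell ``(floor(x), floor(y))``.
Category maps average the accumulated map over trials, are smoothed with an
isotropic Gaussian (sigma = 13 px = 0.5 deg by default) and z-scored over
cells.  Marginal maps subtract the unweighted grand mean of the category
maps from each category map, removing spatial structure shared by all
categories (most prominently the center bias); what remains is each
category's signed fixation-density signature.

The processing order raw -> smoothed -> zscored -> marginal is enforced via
a ``stage`` flag on every map.  Grids are stored as ``(height, width)``
arrays indexed ``grid[y, x]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_data import Geometry, first_fixations, to_image_frame

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "FdmSpec",
    "SimilarityContrastResult",
    "accumulate_fdm",
    "smooth_map",
    "zscore_map",
    "category_fdms",
    "marginal_maps",
    "map_correlation",
    "similarity_contrast",
    "cross_condition_similarity",
    "refixation_map",
]

STAGES = ("raw", "smoothed", "zscored", "marginal")


class StageError(ValueError):
    """Map operation applied out of pipeline order."""


class DegenerateMapError(ValueError):
    """A constant map carries no usable fixation structure."""


@dataclass(frozen=True)
class DensityMap:
    """A 2-D map in image coordinates with provenance metadata."""

    grid: np.ndarray  # shape (height, width), grid[y, x]
    stage: str
    category: str = ""
    n_trials: int = 0
    n_fixations: int = 0
    total_mass: float = 0.0
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass(frozen=True)
class FdmSpec:
    """Which fixations and trials feed a map.

    ``fixation_scope``: "all" or "first" (first fixation of each trial);
    ``trial_scope``: "all", "correct_only" or "incorrect_only";
    ``condition_filter``: a condition label or "all".
    """

    fixation_scope: str = "all"
    trial_scope: str = "all"
    condition_filter: str = "all"

    def __post_init__(self) -> None:
        if self.fixation_scope not in ("all", "first"):
            raise ValueError(f"unknown fixation_scope {self.fixation_scope!r}")
        if self.trial_scope not in ("all", "correct_only", "incorrect_only"):
            raise ValueError(f"unknown trial_scope {self.trial_scope!r}")


def scope_trials(trials: pd.DataFrame, spec: FdmSpec) -> pd.DataFrame:
    out = trials
    if spec.condition_filter != "all":
        out = out[out["condition"] == spec.condition_filter]
    if spec.trial_scope == "correct_only":
        out = out[out["correct"]]
    elif spec.trial_scope == "incorrect_only":
        out = out[~out["correct"]]
    return out


def scope_fixations(fixations: pd.DataFrame, spec: FdmSpec) -> pd.DataFrame:
    return first_fixations(fixations) if spec.fixation_scope == "first" else fixations


def accumulate_fdm(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    geom: Geometry | None = None,
    category: str = "",
) -> DensityMap:
    """Duration-weighted accumulation of fixations into a raw map.

    Each in-bounds fixation adds its duration to its floor-binned cell;
    out-of-bounds fixations contribute nothing and are counted (clipping
    them to the border would fabricate edge density).  An empty selection
    yields a zero map, not an error.
    """
    geom = geom or Geometry()
    w, h = geom.image_size
    grid = np.zeros((h, w), dtype=float)
    n_trials = int(trials[["participant_id", "trial_id"]].drop_duplicates().shape[0])
    if fixations.empty:
        logger.info("accumulate_fdm: empty fixation selection for %r", category)
        return DensityMap(grid=grid, stage="raw", category=category, n_trials=n_trials)
    fix = to_image_frame(fixations, trials, geom)
    inb = fix["in_bounds"].to_numpy()
    n_oob = int((~inb).sum())
    xi = np.floor(fix.loc[inb, "x_img"].to_numpy()).astype(int)
    yi = np.floor(fix.loc[inb, "y_img"].to_numpy()).astype(int)
    dur = fix.loc[inb, "duration_ms"].to_numpy()
    np.add.at(grid, (yi, xi), dur)
    return DensityMap(
        grid=grid,
        stage="raw",
        category=category,
        n_trials=n_trials,
        n_fixations=int(inb.sum()),
        total_mass=float(dur.sum()),
        n_out_of_bounds=n_oob,
    )


def smooth_map(m: DensityMap, sigma_px: float = 13.0) -> DensityMap:
    """Gaussian smoothing with zero padding at the image border.

    The discrete kernel is normalised, so any delta farther than the kernel
    radius (4 sigma) from every edge retains its mass exactly.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be strictly positive")
    if m.stage not in ("raw", "smoothed"):
        raise StageError(f"cannot smooth a {m.stage} map")
    grid = ndimage.gaussian_filter(m.grid, sigma=sigma_px, mode="constant", truncate=4.0)
    return replace(m, grid=grid, stage="smoothed")


def zscore_map(m: DensityMap) -> DensityMap:
    """Standardise a map over all cells (population SD; mean 0, SD 1).

    Population vs. sample SD differs by a constant factor that cancels in
    correlations and argmax decoding.
    """
    if m.stage not in ("raw", "smoothed"):
        raise StageError(f"cannot z-score a {m.stage} map")
    sd = float(m.grid.std())
    if sd == 0.0:
        raise DegenerateMapError("constant map: no usable fixation structure")
    grid = (m.grid - m.grid.mean()) / sd
    return replace(m, grid=grid, stage="zscored")


def category_fdms(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    category_field: str = "emotion",
    spec: FdmSpec | None = None,
    exclude_participant=None,
    include_participants=None,
    geom: Geometry | None = None,
    sigma_px: float | None = None,
    categories=None,
) -> dict[str, DensityMap]:
    """Per-category z-scored FDMs: accumulate over scoped trials, divide by
    trial count, smooth, z-score.

    ``exclude_participant`` drops one participant (LOSO training maps);
    ``include_participants`` restricts to a set (individual-level maps).  A
    category with zero scoped trials raises a ValueError naming it, so a
    decoder cannot silently skip a class.
    """
    geom = geom or Geometry()
    spec = spec or FdmSpec()
    sigma = geom.smoothing_sigma_px if sigma_px is None else sigma_px
    scoped = scope_trials(trials, spec)
    if exclude_participant is not None:
        scoped = scoped[scoped["participant_id"] != exclude_participant]
    if include_participants is not None:
        scoped = scoped[scoped["participant_id"].isin(set(include_participants))]
    if scoped.empty:
        raise ValueError("no trials left after scoping")
    fix_scoped = scope_fixations(fixations, spec)
    if categories is None:
        categories = sorted(trials[category_field].unique())
    maps: dict[str, DensityMap] = {}
    for cat in categories:
        cat_trials = scoped[scoped[category_field] == cat]
        if cat_trials.empty:
            raise ValueError(f"category {cat!r} has zero trials after scoping")
        keys = pd.MultiIndex.from_frame(cat_trials[["participant_id", "trial_id"]])
        fkeys = pd.MultiIndex.from_frame(fix_scoped[["participant_id", "trial_id"]])
        cat_fix = fix_scoped[fkeys.isin(keys)]
        raw = accumulate_fdm(cat_fix, cat_trials, geom, category=str(cat))
        raw = replace(raw, grid=raw.grid / len(cat_trials))
        maps[cat] = zscore_map(smooth_map(raw, sigma_px=sigma))
    return maps


def marginal_maps(category_maps: dict[str, DensityMap]) -> dict[str, DensityMap]:
    """Subtract the unweighted cellwise grand mean of the category maps.

    Requires >= 2 z-scored maps of identical shape.  By construction the
    marginal maps sum to zero at every cell.
    """
    if len(category_maps) < 2:
        raise ValueError("need at least two category maps")
    shapes = {m.grid.shape for m in category_maps.values()}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among category maps: {shapes}")
    for cat, m in category_maps.items():
        if m.stage != "zscored":
            raise StageError(f"map for {cat!r} has stage {m.stage!r}, expected zscored")
    grand = np.mean([m.grid for m in category_maps.values()], axis=0)
    return {
        cat: replace(m, grid=m.grid - grand, stage="marginal")
        for cat, m in category_maps.items()
    }


def _grid_of(x) -> np.ndarray:
    return x.grid if isinstance(x, DensityMap) else np.asarray(x, dtype=float)


def map_correlation(a, b) -> float:
    """Pearson correlation between two maps over all cells."""
    ga, gb = _grid_of(a), _grid_of(b)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch: {ga.shape} vs {gb.shape}")
    if ga.std() == 0.0 or gb.std() == 0.0:
        raise DegenerateMapError("constant map has no defined correlation")
    return float(np.corrcoef(ga.ravel(), gb.ravel())[0, 1])


@dataclass(frozen=True)
class SimilarityContrastResult:
    """Within- vs between-category FDM similarity across participants."""

    per_participant: pd.DataFrame  # columns: within_r, between_r, within_z, between_z
    t: float
    df: int
    p: float
    d_z: float
    n_dropped: int = 0
    dropped_participants: tuple = field(default_factory=tuple)


def _participant_maps(fixations, trials, category_field, spec, participant, geom, sigma_px):
    try:
        return category_fdms(
            fixations,
            trials,
            category_field=category_field,
            spec=spec,
            include_participants=[participant],
            geom=geom,
            sigma_px=sigma_px,
        )
    except (ValueError, DegenerateMapError):
        return None


def similarity_contrast(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    spec_a: FdmSpec,
    spec_b: FdmSpec,
    category_field: str = "emotion",
    geom: Geometry | None = None,
    sigma_px: float | None = None,
    alternative: str = "greater",
) -> SimilarityContrastResult:
    """Are same-category maps more alike than different-category maps?

    For each participant, individual-level category maps are built under
    ``spec_a`` and ``spec_b``; the mean correlation over same-category pairs
    (within) and over all cross-category pairs (between) is Fisher
    z-transformed, and within vs. between is compared with a paired t-test
    across participants (one-sided, within > between, by default).
    Participants lacking any category under either spec are dropped with a
    warning.
    """
    from .stats_inference import paired_or_one_sample_t

    geom = geom or Geometry()
    participants = sorted(trials["participant_id"].unique())
    categories = sorted(trials[category_field].unique())
    rows, dropped = [], []
    for p in participants:
        maps_a = _participant_maps(fixations, trials, category_field, spec_a, p, geom, sigma_px)
        maps_b = _participant_maps(fixations, trials, category_field, spec_b, p, geom, sigma_px)
        if maps_a is None or maps_b is None:
            dropped.append(p)
            continue
        within = [map_correlation(maps_a[c], maps_b[c]) for c in categories]
        between = [
            map_correlation(maps_a[c1], maps_b[c2])
            for c1 in categories
            for c2 in categories
            if c1 != c2
        ]
        rows.append((p, float(np.mean(within)), float(np.mean(between))))
    if dropped:
        logger.warning("similarity_contrast: dropped participants %s", dropped)
    per = pd.DataFrame(rows, columns=["participant_id", "within_r", "between_r"])
    per = per.set_index("participant_id")
    per["within_z"] = np.arctanh(np.clip(per["within_r"], -1 + 1e-12, 1 - 1e-12))
    per["between_z"] = np.arctanh(np.clip(per["between_r"], -1 + 1e-12, 1 - 1e-12))
    res = paired_or_one_sample_t(
        per["within_z"].to_numpy(), per["between_z"].to_numpy(), alternative=alternative
    )
    return SimilarityContrastResult(
        per_participant=per,
        t=res.statistic,
        df=res.df,
        p=res.p,
        d_z=res.effect_size,
        n_dropped=len(dropped),
        dropped_participants=tuple(dropped),
    )


def cross_condition_similarity(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    fixation_scope: str = "all",
    trial_scope: str = "all",
    geom: Geometry | None = None,
    sigma_px: float | None = None,
) -> pd.DataFrame:
    """Within-emotion FDM correlations across all 6 condition pairs.

    Per participant: one z-scored FDM per (emotion, condition); for each
    condition pair, the mean over emotions of the same-emotion correlation;
    the table reports the mean and SD over participants per pair.
    """
    geom = geom or Geometry()
    conditions = sorted(trials["condition"].unique())
    emotions = sorted(trials["emotion"].unique())
    participants = sorted(trials["participant_id"].unique())
    per_pair: dict[tuple[str, str], list[float]] = {
        (a, b): []
        for i, a in enumerate(conditions)
        for b in conditions[i + 1 :]
    }
    for p in participants:
        maps: dict[tuple[str, str], DensityMap] = {}
        ok = True
        for cond in conditions:
            spec = FdmSpec(
                fixation_scope=fixation_scope,
                trial_scope=trial_scope,
                condition_filter=cond,
            )
            got = _participant_maps(fixations, trials, "emotion", spec, p, geom, sigma_px)
            if got is None:
                ok = False
                break
            for emo in emotions:
                maps[(emo, cond)] = got[emo]
        if not ok:
            logger.warning("cross_condition_similarity: dropped participant %s", p)
            continue
        for (a, b), acc in per_pair.items():
            rs = [map_correlation(maps[(e, a)], maps[(e, b)]) for e in emotions]
            acc.append(float(np.mean(rs)))
    rows = [
        (a, b, float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else np.nan, len(v))
        for (a, b), v in per_pair.items()
    ]
    return pd.DataFrame(
        rows, columns=["condition_a", "condition_b", "mean_r", "sd_r", "n_participants"]
    )


def refixation_map(
    fixations: pd.DataFrame,
    trials: pd.DataFrame,
    radius_px: float = 62.0,
    geom: Geometry | None = None,
) -> DensityMap:
    """Unweighted density of refixations.

    A fixation counts once (regardless of how many earlier fixations it
    recurs with) if any earlier fixation in its trial lies within
    ``radius_px``; it adds 1 -- not its duration -- at its cell.  Only the
    later member of a recurrent pair is counted, so the map represents
    revisits rather than pairs.
    """
    geom = geom or Geometry()
    w, h = geom.image_size
    grid = np.zeros((h, w), dtype=float)
    fix = to_image_frame(fixations, trials, geom)
    fix = fix.sort_values(["participant_id", "trial_id", "index"], kind="stable")
    n_refix = 0
    n_oob = 0
    for _, grp in fix.groupby(["participant_id", "trial_id"], sort=False):
        pts = grp[["x_img", "y_img"]].to_numpy()
        if len(pts) < 2:
            continue
        diff = pts[:, None, :] - pts[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        close = dist <= radius_px
        inb = grp["in_bounds"].to_numpy()
        for j in range(1, len(pts)):
            if close[j, :j].any():
                if not inb[j]:
                    n_oob += 1
                    continue
                grid[int(np.floor(pts[j, 1])), int(np.floor(pts[j, 0]))] += 1.0
                n_refix += 1
    n_trials = int(trials[["participant_id", "trial_id"]].drop_duplicates().shape[0])
    return DensityMap(
        grid=grid,
        stage="raw",
        category="refixation",
        n_trials=n_trials,
        n_fixations=n_refix,
        total_mass=float(grid.sum()),
        n_out_of_bounds=n_oob,
    )
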