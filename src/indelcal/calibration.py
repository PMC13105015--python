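"""Local posterior probability calibration of predictor scores.

Given labeled pathogenic/benign score samples for one tool and one variant
type, this module estimates the local posterior probability of pathogenicity
along the score axis, attaches one-sided bootstrap confidence bounds, and
extracts per-evidence-level score thresholds under the point-based framework
of :mod:`indelcal.evidence`.  Insertions and deletions are always calibrated
independently, each with its own prior.

The local estimator at an (oriented) score ``x`` expands a symmetric window
``[x - eps, x + eps]`` until it holds at least ``min_count`` calibration
variants pooled over both classes, then reweights the in-window class
fractions by the prior::

    posterior(x) = prior * cP/nP / (prior * cP/nP + (1 - prior) * cB/nB)

Windows are closed on both ends; ``eps`` is the minimal half-width achieving
the count (the continuous limit of an expansion schedule), clipped only by
the data themselves: near the extremes the window simply spans all data.
Counting uses sorted arrays and ``searchsorted`` prefix sums so that a full
10,000-replicate bootstrap over a 1,001-point grid is a matter of minutes on
one CPU.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .evidence import (
    EVIDENCE_LEVELS,
    PointScale,
    posterior_threshold_for_level,
)

__all__ = [
    "ScoreSet",
    "WindowRule",
    "PosteriorCurve",
    "LevelInterval",
    "EvidenceThresholds",
    "orient_scores",
    "local_posterior_at",
    "estimate_posterior_curve",
    "bootstrap_bounds",
    "extract_thresholds",
    "calibrate_tool",
]

VARIANT_TYPES = ("insertion", "deletion")
DIRECTIONS = ("higher_pathogenic", "lower_pathogenic")


@dataclass(frozen=True)
class ScoreSet:
    """Paired pathogenic/benign score samples for one tool and variant type.

    ``direction`` states which end of the score axis is pathogenic and is
    always declared by the caller, never inferred from the data.
    """

    tool: str
    variant_type: str
    direction: str
    pathogenic_scores: np.ndarray
    benign_scores: np.ndarray
    oriented: bool = False
    truth: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.variant_type not in VARIANT_TYPES:
            raise ConfigurationError(
                f"variant_type must be one of {VARIANT_TYPES}; got {self.variant_type!r}"
            )
        if self.direction not in DIRECTIONS:
            raise ConfigurationError(
                f"direction must be one of {DIRECTIONS}; got {self.direction!r}"
            )
        for name in ("pathogenic_scores", "benign_scores"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or arr.size == 0:
                raise InputError(f"{name} must be a non-empty 1-D array")
            if not np.all(np.isfinite(arr)):
                raise InputError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)

    @property
    def n_pathogenic(self) -> int:
        return self.pathogenic_scores.size

    @property
    def n_benign(self) -> int:
        return self.benign_scores.size


def orient_scores(score_set: ScoreSet) -> ScoreSet:
    """Return a copy in which higher scores always mean more pathogenic.

    ``lower_pathogenic`` sets are negated; the transformation is an
    involution (applying it twice recovers the original values), with the
    ``oriented`` flag toggled so reports can map back to original units.
    """
    if score_set.direction == "higher_pathogenic":
        return replace(score_set, oriented=True)
    return replace(
        score_set,
        pathogenic_scores=-score_set.pathogenic_scores,
        benign_scores=-score_set.benign_scores,
        oriented=not score_set.oriented,
    )


def _ensure_oriented(score_set: ScoreSet) -> ScoreSet:
    return score_set if score_set.oriented else orient_scores(score_set)


@dataclass(frozen=True)
class WindowRule:
    """Adaptive-window settings for the local posterior estimator."""

    min_count: int = 100
    grid_size: int = 1001

    def __post_init__(self):
        if self.min_count < 1:
            raise ConfigurationError("min_count must be >= 1")
        if self.grid_size < 2:
            raise ConfigurationError("grid_size must be >= 2")


@dataclass
class PosteriorCurve:
    """Score grid with local posterior estimates and bootstrap bounds.

    All arrays are in oriented units (higher = more pathogenic).  ``lower``
    and ``upper`` are the pointwise 5th/95th bootstrap percentiles; the
    stringent side is ``lower`` for pathogenic levels and ``upper`` for
    benign levels.  ``pooled_scores`` retains the sorted oriented
    calibration scores so that threshold support can be audited downstream.
    """

    grid: np.ndarray
    estimate: np.ndarray
    half_width: np.ndarray
    c_path: np.ndarray
    c_benign: np.ndarray
    pooled_scores: np.ndarray
    settings: dict
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.lower is not None and self.upper is not None:
            if np.any(self.lower > self.upper + 1e-12):
                raise InputError("lower bound exceeds upper bound")

    @property
    def has_bounds(self) -> bool:
        return self.lower is not None and self.upper is not None

    def to_frame(self) -> pd.DataFrame:
        data = {
            "grid": self.grid,
            "estimate": self.estimate,
            "lower": self.lower if self.has_bounds else np.nan,
            "upper": self.upper if self.has_bounds else np.nan,
            "half_width": self.half_width,
            "c_path": self.c_path,
            "c_benign": self.c_benign,
        }
        return pd.DataFrame(data)


def _min_halfwidth(grid: np.ndarray, pooled_sorted: np.ndarray, min_count: int) -> np.ndarray:
    """Minimal symmetric half-width holding >= min_count pooled points.

    For each grid value the optimal closed window covers some run of
    ``m = min(min_count, N)`` consecutive sorted scores; scan the m candidate
    runs straddling the insertion point (vectorised over the grid).
    """
    n = pooled_sorted.size
    m = min(min_count, n)
    pos = np.searchsorted(pooled_sorted, grid)
    best = np.full(grid.shape, np.inf)
    hi_idx = n - m
    for offset in range(m):
        j = np.clip(pos - offset, 0, hi_idx)
        eps = np.maximum(grid - pooled_sorted[j], pooled_sorted[j + m - 1] - grid)
        np.minimum(best, eps, out=best)
    return np.maximum(best, 0.0)


def _curve_values(
    path_sorted: np.ndarray,
    benign_sorted: np.ndarray,
    grid: np.ndarray,
    prior: float,
    min_count: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n_p, n_b = path_sorted.size, benign_sorted.size
    pooled = np.sort(np.concatenate([path_sorted, benign_sorted]))
    eps = _min_halfwidth(grid, pooled, min_count)
    # tiny relative slack so the defining boundary point survives rounding
    pad = eps * 1e-12 + 1e-15
    lo, hi = grid - eps - pad, grid + eps + pad
    c_p = np.searchsorted(path_sorted, hi, side="right") - np.searchsorted(
        path_sorted, lo, side="left"
    )
    c_b = np.searchsorted(benign_sorted, hi, side="right") - np.searchsorted(
        benign_sorted, lo, side="left"
    )
    num = prior * c_p / n_p
    den = num + (1.0 - prior) * c_b / n_b
    if np.any(den <= 0):
        raise RuntimeError("empty window despite expansion rule")  # pragma: no cover
    return num / den, eps, c_p, c_b


def local_posterior_at(
    point: float,
    score_set: ScoreSet,
    prior: float,
    rule: Optional[WindowRule] = None,
) -> Tuple[float, float, int, int]:
    """Local posterior at a single oriented score.

    Returns ``(posterior, half_width, c_path, c_benign)``.
    """
    rule = rule or WindowRule()
    s = _ensure_oriented(score_set)
    post, eps, c_p, c_b = _curve_values(
        np.sort(s.pathogenic_scores),
        np.sort(s.benign_scores),
        np.asarray([float(point)]),
        prior,
        rule.min_count,
    )
    return float(post[0]), float(eps[0]), int(c_p[0]), int(c_b[0])


def _make_grid(pooled: np.ndarray, grid_size: int) -> np.ndarray:
    lo, hi = float(pooled.min()), float(pooled.max())
    if lo == hi:
        warnings.warn("degenerate score range: all scores identical; single-point curve")
        return np.asarray([lo])
    return np.linspace(lo, hi, grid_size)


def _base_settings(s: ScoreSet, prior: float, rule: WindowRule) -> dict:
    return {
        "tool": s.tool,
        "variant_type": s.variant_type,
        "direction": s.direction,
        "prior": float(prior),
        "min_count": rule.min_count,
        "grid_size": rule.grid_size,
        "n_path": s.n_pathogenic,
        "n_benign": s.n_benign,
    }


def estimate_posterior_curve(
    score_set: ScoreSet,
    prior: float,
    rule: Optional[WindowRule] = None,
) -> PosteriorCurve:
    """Local posterior estimate on an even grid over the pooled score range."""
    rule = rule or WindowRule()
    s = _ensure_oriented(score_set)
    path = np.sort(s.pathogenic_scores)
    ben = np.sort(s.benign_scores)
    pooled = np.sort(np.concatenate([path, ben]))
    grid = _make_grid(pooled, rule.grid_size)
    post, eps, c_p, c_b = _curve_values(path, ben, grid, prior, rule.min_count)
    return PosteriorCurve(
        grid=grid,
        estimate=post,
        half_width=eps,
        c_path=c_p,
        c_benign=c_b,
        pooled_scores=pooled,
        settings=_base_settings(s, prior, rule),
    )


def bootstrap_bounds(
    score_set: ScoreSet,
    prior: float,
    rule: Optional[WindowRule] = None,
    B: int = 10_000,
    seed: Optional[int] = None,
) -> PosteriorCurve:
    """Posterior curve with pointwise one-sided 95% bootstrap bounds.

    Each of the ``B`` replicates resamples the pathogenic and benign score
    lists independently with replacement at their original sizes and
    recomputes the full curve, including window re-selection, on the grid of
    the original data.  ``lower``/``upper`` are the 5th/95th percentiles per
    grid point; the stringent side is ``lower`` for pathogenic evidence and
    ``upper`` for benign evidence.
    """
    if B < 1:
        raise ConfigurationError("bootstrap iterations B must be >= 1")
    if seed is None:
        raise ConfigurationError("a seed is mandatory for the bootstrap stage")
    rule = rule or WindowRule()
    curve = estimate_posterior_curve(score_set, prior, rule)
    s = _ensure_oriented(score_set)
    path, ben = s.pathogenic_scores, s.benign_scores
    rng = np.random.default_rng(seed)
    reps = np.empty((B, curve.grid.size), dtype=np.float32)
    for b in range(B):
        p_star = np.sort(rng.choice(path, size=path.size, replace=True))
        b_star = np.sort(rng.choice(ben, size=ben.size, replace=True))
        post, _, _, _ = _curve_values(p_star, b_star, curve.grid, prior, rule.min_count)
        reps[b] = post
    lower = np.percentile(reps, 5.0, axis=0).astype(float)
    upper = np.percentile(reps, 95.0, axis=0).astype(float)
    curve.lower = np.minimum(lower, upper)
    curve.upper = np.maximum(lower, upper)
    curve.settings.update({"B": int(B), "seed": int(seed)})
    return curve


@dataclass(frozen=True)
class LevelInterval:
    """Half-open/closed score interval for one evidence level, original units."""

    level: int
    low: float
    high: float
    low_inclusive: bool
    high_inclusive: bool
    support_n: Optional[int] = None

    def contains(self, score: float) -> bool:
        if np.isnan(score):
            return False
        if score < self.low or (score == self.low and not self.low_inclusive):
            return False
        if score > self.high or (score == self.high and not self.high_inclusive):
            return False
        return True


@dataclass
class EvidenceThresholds:
    """Per-level score intervals for one tool and variant type.

    The machine form of a published thresholds table row set: each attained
    level carries a score interval in the tool's original units, intervals of
    distinct levels are disjoint, and a score on a shared boundary belongs to
    the stronger level.  Levels dropped for lack of extreme data support are
    listed in ``excluded`` with a reason.
    """

    tool: str
    variant_type: str
    direction: str
    prior: Optional[float] = None
    intervals: Dict[int, LevelInterval] = field(default_factory=dict)
    excluded: List[Tuple[int, str]] = field(default_factory=list)
    settings: dict = field(default_factory=dict)

    @property
    def attained_levels(self) -> List[int]:
        return sorted(self.intervals)

    def assign(self, score: float) -> Optional[int]:
        """Evidence level for a score; 0 between intervals, None if unscored."""
        if score is None or (isinstance(score, float) and np.isnan(score)):
            return None
        for interval in self.intervals.values():
            if interval.contains(float(score)):
                return interval.level
        return 0

    def threshold_score(self, level: int) -> float:
        """The level's own threshold boundary in original units.

        For pathogenic levels this is the interval end nearer the benign
        side (the score at which the level is first reached); symmetrically
        for benign levels.
        """
        iv = self.intervals[level]
        if (level > 0) == (self.direction == "higher_pathogenic"):
            return iv.low
        return iv.high

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in self.attained_levels:
            iv = self.intervals[level]
            rows.append(
                {
                    "tool": self.tool,
                    "variant_type": self.variant_type,
                    "direction": self.direction,
                    "prior": self.prior,
                    "level": level,
                    "interval_low": iv.low,
                    "interval_high": iv.high,
                    "low_inclusive": iv.low_inclusive,
                    "high_inclusive": iv.high_inclusive,
                    "support_n": iv.support_n,
                    "excluded_reason": "",
                }
            )
        for level, reason in self.excluded:
            rows.append(
                {
                    "tool": self.tool,
                    "variant_type": self.variant_type,
                    "direction": self.direction,
                    "prior": self.prior,
                    "level": level,
                    "interval_low": np.nan,
                    "interval_high": np.nan,
                    "low_inclusive": False,
                    "high_inclusive": False,
                    "support_n": np.nan,
                    "excluded_reason": reason,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> List["EvidenceThresholds"]:
        out = []
        for (tool, vtype), grp in df.groupby(["tool", "variant_type"], sort=False):
            direction = grp["direction"].iloc[0]
            prior = grp["prior"].iloc[0] if "prior" in grp else None
            prior = None if pd.isna(prior) else float(prior)
            obj = cls(tool=tool, variant_type=vtype, direction=direction, prior=prior)
            for _, row in grp.iterrows():
                reason = row.get("excluded_reason", "")
                if isinstance(reason, str) and reason:
                    obj.excluded.append((int(row["level"]), reason))
                    continue
                level = int(row["level"])
                support = row.get("support_n")
                obj.intervals[level] = LevelInterval(
                    level=level,
                    low=float(row["interval_low"]),
                    high=float(row["interval_high"]),
                    low_inclusive=bool(row["low_inclusive"]),
                    high_inclusive=bool(row["high_inclusive"]),
                    support_n=None if pd.isna(support) else int(support),
                )
            out.append(obj)
        return out


def _suffix_start(ok: np.ndarray) -> Optional[int]:
    """First index of the trailing all-True run, or None if ok[-1] is False."""
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return 0
    if bad[-1] == ok.size - 1:
        return None
    return int(bad[-1]) + 1


def _prefix_end(ok: np.ndarray) -> Optional[int]:
    """Last index of the leading all-True run, or None if ok[0] is False."""
    bad = np.nonzero(~ok)[0]
    if bad.size == 0:
        return ok.size - 1
    if bad[0] == 0:
        return None
    return int(bad[0]) - 1


def _to_original(iv_low, iv_high, low_inc, high_inc, direction):
    if direction == "higher_pathogenic":
        return iv_low, iv_high, low_inc, high_inc
    return -iv_high, -iv_low, high_inc, low_inc


def extract_thresholds(
    curve: PosteriorCurve,
    scale: PointScale,
    min_support: int = 10,
    bound: str = "stringent",
) -> EvidenceThresholds:
    """Per-level score thresholds from a posterior curve.

    For pathogenic level ``+k`` the threshold is the least oriented grid
    score ``t`` such that the stringent (lower) bound meets the level's
    posterior bar at every grid point ``u >= t``; benign levels mirror this
    with the upper bound on a leading prefix.  A level is reported only when
    at least ``min_support`` pooled calibration variants lie at or beyond
    its threshold; otherwise it is excluded with a reason, mirroring the
    exclusion of poorly supported extremes.  ``bound="estimate"`` extracts
    from the point estimate instead (used for conservatism audits).

    An empty thresholds object is a valid outcome when no level is reached.
    """
    if bound not in ("stringent", "estimate"):
        raise ConfigurationError("bound must be 'stringent' or 'estimate'")
    prior = curve.settings["prior"]
    if abs(prior - scale.prior) > 1e-12:
        raise InputError(
            f"scale prior {scale.prior} does not match curve prior {prior}"
        )
    if bound == "stringent":
        if not curve.has_bounds:
            raise InputError("stringent extraction requires bootstrap bounds")
        low_arr, up_arr = curve.lower, curve.upper
    else:
        low_arr = up_arr = curve.estimate

    grid = curve.grid
    pooled = curve.pooled_scores
    n_pooled = pooled.size
    tol = 1e-12

    result = EvidenceThresholds(
        tool=curve.settings.get("tool", ""),
        variant_type=curve.settings.get("variant_type", "deletion"),
        direction=curve.settings.get("direction", "higher_pathogenic"),
        prior=prior,
        settings={**curve.settings, "min_support": int(min_support), "bound": bound},
    )
    if grid.size < 2:
        return result

    # oriented thresholds per attained level (nested: +k attained => +(k-1) attained)
    path_t: Dict[int, float] = {}
    path_support: Dict[int, int] = {}
    for k in EVIDENCE_LEVELS:
        bar = posterior_threshold_for_level(prior, k)
        start = _suffix_start(low_arr >= bar - tol)
        if start is None:
            break
        t = float(grid[start])
        path_t[k] = t
        path_support[k] = int(n_pooled - np.searchsorted(pooled, t, side="left"))
    benign_t: Dict[int, float] = {}
    benign_support: Dict[int, int] = {}
    for k in EVIDENCE_LEVELS:
        bar = posterior_threshold_for_level(prior, -k)
        end = _prefix_end(up_arr <= bar + tol)
        if end is None:
            break
        t = float(grid[end])
        benign_t[k] = t
        benign_support[k] = int(np.searchsorted(pooled, t, side="right"))

    # drop unsupported extremes, strongest level inward
    for k in sorted(path_t, reverse=True):
        if path_support[k] < min_support:
            result.excluded.append((k, "insufficient extreme support"))
            del path_t[k]
        else:
            break
    for k in sorted(benign_t, reverse=True):
        if benign_support[k] < min_support:
            result.excluded.append((-k, "insufficient extreme support"))
            del benign_t[k]
        else:
            break

    # oriented intervals; shared boundaries belong to the stronger level
    ks = sorted(path_t)
    for i, k in enumerate(ks):
        lo = path_t[k]
        hi = path_t[ks[i + 1]] if i + 1 < len(ks) else np.inf
        o_low, o_high, li, hi_inc = _to_original(lo, hi, True, False, result.direction)
        result.intervals[k] = LevelInterval(
            level=k,
            low=o_low,
            high=o_high,
            low_inclusive=li,
            high_inclusive=hi_inc,
            support_n=path_support[k],
        )
    ks = sorted(benign_t)
    for i, k in enumerate(ks):
        hi = benign_t[k]
        lo = benign_t[ks[i + 1]] if i + 1 < len(ks) else -np.inf
        o_low, o_high, li, hi_inc = _to_original(lo, hi, False, True, result.direction)
        result.intervals[-k] = LevelInterval(
            level=-k,
            low=o_low,
            high=o_high,
            low_inclusive=li,
            high_inclusive=hi_inc,
            support_n=benign_support[k],
        )
    return result


@dataclass
class ToolCalibration:
    """Full calibration output for one variant type."""

    curve: PosteriorCurve
    thresholds: EvidenceThresholds


def calibrate_tool(
    insertion_set: Optional[ScoreSet],
    deletion_set: Optional[ScoreSet],
    insertion_prior: Optional[float],
    deletion_prior: Optional[float],
    *,
    rule: Optional[WindowRule] = None,
    B: int = 10_000,
    seed: Optional[int] = None,
    min_support: int = 10,
) -> Dict[str, ToolCalibration]:
    """Run the full chain per variant type, never pooling types.

    Each variant type is calibrated with its own prior; a missing type is
    skipped with a warning and absent from the result.
    """
    out: Dict[str, ToolCalibration] = {}
    for name, score_set, prior in (
        ("insertion", insertion_set, insertion_prior),
        ("deletion", deletion_set, deletion_prior),
    ):
        if score_set is None:
            warnings.warn(f"no {name} score set supplied; skipping {name} calibration")
            continue
        if score_set.variant_type != name:
            raise ConfigurationError(
                f"score set passed as {name} is typed {score_set.variant_type!r}"
            )
        if prior is None:
            raise ConfigurationError(f"missing prior for {name} calibration")
        curve = bootstrap_bounds(score_set, prior, rule=rule, B=B, seed=seed)
        scale = PointScale.from_prior(prior)
        thresholds = extract_thresholds(curve, scale, min_support=min_support)
        out[name] = ToolCalibration(curve=curve, thresholds=thresholds)
    return out
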