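"""Applying calibrated thresholds to new score sets.

Per-variant evidence assignment, evidence-bin occupancy percentages,
bin-level likelihood ratios against the expected per-level minima, indel
length stratification, and per-proband evidence-yield summaries.

Likelihood ratios are reported the way clinical evaluations print them:
standard LRs (TPR/FPR) for pathogenic bins and inverse LRs (FPR/TPR) for
benign bins, so higher is better on both sides.  A bin with members of one
class only has an infinite (reported) LR; an empty bin is *undefined*,
which is kept distinct from infinite so sparse test sets do not silently
divide zero by zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import EvidenceThresholds
from .errors import InputError
from .evidence import PointScale, expected_lr_for_level

__all__ = [
    "EvidenceAssignment",
    "BinLR",
    "LevelSummary",
    "assign_points",
    "assign_many",
    "bin_percentages",
    "bin_likelihood_ratios",
    "compare_to_expected",
    "stratify_by_length",
    "proband_evidence_summary",
]


@dataclass(frozen=True)
class EvidenceAssignment:
    variant_id: str
    tool: str
    variant_type: str
    level: Optional[int]  # None when the tool could not score the variant


def assign_points(score, thresholds: EvidenceThresholds) -> Optional[int]:
    """Evidence level for one score: the unique containing interval's level,
    0 between intervals (indeterminate), None for a missing score."""
    return thresholds.assign(score)


def assign_many(scores, thresholds: EvidenceThresholds) -> np.ndarray:
    """Vector of levels as floats, NaN marking unscored variants."""
    arr = np.asarray(scores, dtype=float)
    out = np.empty(arr.shape, dtype=float)
    for i, s in enumerate(arr.ravel()):
        level = thresholds.assign(s)
        out.ravel()[i] = np.nan if level is None else level
    return out


def bin_percentages(
    scores, thresholds: EvidenceThresholds
) -> Tuple[Dict[int, float], float]:
    """Percentage of scored variants in each evidence bin, plus the
    unscored fraction (reported separately; percentages over scored
    variants sum to 100)."""
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise InputError("empty score list")
    levels = assign_many(arr, thresholds)
    scored = levels[~np.isnan(levels)]
    unscored_fraction = 1.0 - scored.size / arr.size
    if scored.size == 0:
        raise InputError("no scored variants")
    all_levels = sorted(set(thresholds.attained_levels) | {0})
    pct = {
        lvl: 100.0 * float(np.sum(scored == lvl)) / scored.size for lvl in all_levels
    }
    return pct, unscored_fraction


@dataclass(frozen=True)
class BinLR:
    """Likelihood ratio of one evidence bin on a labeled test set."""

    level: int
    n_path_in_bin: int
    n_benign_in_bin: int
    n_path_total: int
    n_benign_total: int
    lr: Optional[float]  # reported value; inf allowed; None when undefined (0/0)
    reported_as: str  # standard (TPR/FPR) | inverse (FPR/TPR)

    @property
    def undefined(self) -> bool:
        return self.lr is None


def _bin_lr(level, cp, cb, np_tot, nb_tot) -> BinLR:
    reported_as = "standard" if level > 0 else "inverse"
    tpr = cp / np_tot
    fpr = cb / nb_tot
    num, den = (tpr, fpr) if level > 0 else (fpr, tpr)
    if cp == 0 and cb == 0:
        lr = None
    elif den == 0:
        lr = math.inf
    else:
        lr = num / den
    return BinLR(
        level=level,
        n_path_in_bin=cp,
        n_benign_in_bin=cb,
        n_path_total=np_tot,
        n_benign_total=nb_tot,
        lr=lr,
        reported_as=reported_as,
    )


def bin_likelihood_ratios(
    pathogenic_scores, benign_scores, thresholds: EvidenceThresholds
) -> List[BinLR]:
    """Per-bin LRs for every attained evidence level of the thresholds.

    Unscored (NaN) variants are excluded from the denominators.
    """
    path = np.asarray(pathogenic_scores, dtype=float)
    ben = np.asarray(benign_scores, dtype=float)
    if path.size == 0 or np.all(np.isnan(path)):
        raise InputError("test set is missing the pathogenic class")
    if ben.size == 0 or np.all(np.isnan(ben)):
        raise InputError("test set is missing the benign class")
    lv_path = assign_many(path, thresholds)
    lv_ben = assign_many(ben, thresholds)
    np_tot = int(np.sum(~np.isnan(lv_path)))
    nb_tot = int(np.sum(~np.isnan(lv_ben)))
    out = []
    for level in thresholds.attained_levels:
        cp = int(np.sum(lv_path == level))
        cb = int(np.sum(lv_ben == level))
        out.append(_bin_lr(level, cp, cb, np_tot, nb_tot))
    return out


def compare_to_expected(
    bin_lrs: Iterable[BinLR], scale: PointScale
) -> Dict[int, str]:
    """Pass/fail of each bin against the expected per-level LR minimum.

    Pathogenic level ``+k`` passes when its standard LR reaches ``s**k``;
    benign level ``-k`` passes when its inverse LR reaches the same
    reciprocal bound ``s**k``.  Infinite LRs pass at any level; undefined
    bins are reported as ``not_evaluable``.
    """
    out: Dict[int, str] = {}
    for bin_lr in bin_lrs:
        if bin_lr.undefined:
            out[bin_lr.level] = "not_evaluable"
            continue
        bound = expected_lr_for_level(scale.prior, abs(bin_lr.level))
        out[bin_lr.level] = "pass" if bin_lr.lr >= bound else "fail"
    return out


def stratify_by_length(variants: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    """Partition scored variants into single vs multi amino acid indels.

    ``single_aa`` is a net change of exactly ±3 nt; ``multi_aa`` is a larger
    in-frame change.  Frameshift or balanced records are an input error.
    """
    if "net_nt" not in variants.columns:
        raise InputError("variant table must carry a net_nt column")
    net = variants["net_nt"].astype(int)
    bad = (net % 3 != 0) | (net == 0)
    if bad.any():
        raise InputError(
            f"non-in-frame net length {int(net[bad].iloc[0])} in length stratification"
        )
    single = net.abs() == 3
    return {
        "single_aa": variants[single],
        "multi_aa": variants[~single],
    }


@dataclass(frozen=True)
class LevelSummary:
    mean: float
    min: int
    max: int


def proband_evidence_summary(
    cohort: pd.DataFrame,
    thresholds: EvidenceThresholds,
    probands: Optional[Sequence[str]] = None,
) -> Dict[int, LevelSummary]:
    """Mean and (min–max) range of per-proband variant counts per level.

    ``cohort`` maps probands to scored variants (columns ``proband_id`` and
    ``score``).  Probands listed in ``probands`` but absent from the table
    contribute zero counts at every level; unscored variants are ignored.
    """
    if len(cohort) == 0 and not probands:
        raise InputError("empty cohort")
    ids = list(probands) if probands is not None else sorted(cohort["proband_id"].unique())
    if not ids:
        raise InputError("empty cohort")
    levels = sorted(set(thresholds.attained_levels) | {0})
    counts = pd.DataFrame(0, index=ids, columns=levels)
    for proband, grp in cohort.groupby("proband_id"):
        if proband not in counts.index:
            raise InputError(f"cohort proband {proband!r} missing from proband list")
        assigned = assign_many(grp["score"].to_numpy(), thresholds)
        for lvl in levels:
            counts.loc[proband, lvl] = int(np.sum(assigned == lvl))
    return {
        lvl: LevelSummary(
            mean=float(counts[lvl].mean()),
            min=int(counts[lvl].min()),
            max=int(counts[lvl].max()),
        )
        for lvl in levels
    }
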