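"""Synthetic inputs with known ground truth for every pipeline stage.

Real calibration inputs (clinical archives, population references, cohort
genotypes, external predictor scores) are not redistributable and not
desk-reproducible, so every downstream stage is exercised on generated data
with planted truth instead:

* two-class score samples with known class-conditional densities, so the
  analytic posterior ``alpha*fP(s) / (alpha*fP(s) + (1-alpha)*fB(s))`` is
  available at any score;
* positive/unlabeled feature matrices with a planted mixing proportion, for
  prior-estimation recovery tests;
* variant tables with planted per-filter-rule outcomes and a precomputed
  audit;
* per-proband cohorts with planted per-evidence-level variant counts.

All generators draw from one explicit seed per call; no global RNG state.
Bounded-score tools are emulated with Beta distributions on a finite
support and unbounded tools with Gaussians (optionally mixtures of either).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Mapping, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import EvidenceThresholds, ScoreSet
from .errors import ConfigurationError, InputError
from .filtering import (
    BENIGN_CLASSES,
    CLASSIFICATIONS,
    GENE_VALIDITY_TIERS,
    PATHOGENIC_CLASSES,
    FilterAudit,
    AuditStep,
)

__all__ = [
    "ScoreDistributionSpec",
    "SyntheticTruth",
    "PUData",
    "gen_two_class_scores",
    "gen_pu_features",
    "gen_filter_fixture",
    "gen_proband_cohort",
]


@dataclass(frozen=True)
class ScoreDistributionSpec:
    """A score distribution: Gaussian, Beta (rescaled) or a mixture.

    ``components`` holds ``(weight, a, b)`` tuples: ``(mu, sigma)`` for the
    Gaussian family, Beta shape parameters for the beta family.  For
    ``family="mixture"`` each component is ``(weight, spec)`` with a nested
    spec.  Weights must be positive and sum to 1.  Beta supports must be
    finite; the beta density is rescaled from [0, 1] onto ``support``.
    """

    family: str
    components: Tuple
    support: Tuple[float, float] = (-math.inf, math.inf)

    def __post_init__(self):
        if self.family not in ("gaussian", "beta", "mixture"):
            raise ConfigurationError(f"unknown distribution family {self.family!r}")
        if not self.components:
            raise ConfigurationError("distribution needs at least one component")
        weights = [c[0] for c in self.components]
        if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
            raise ConfigurationError("component weights must be positive and sum to 1")
        if self.family == "beta":
            lo, hi = self.support
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ConfigurationError("beta support must be a finite interval")
            for _, a, b in self.components:
                if a <= 0 or b <= 0:
                    raise ConfigurationError("beta shape parameters must be > 0")
        if self.family == "mixture":
            for _, spec in self.components:
                if not isinstance(spec, ScoreDistributionSpec):
                    raise ConfigurationError("mixture components must be specs")

    @classmethod
    def gaussian(cls, mu: float, sigma: float) -> "ScoreDistributionSpec":
        if sigma <= 0:
            raise ConfigurationError("gaussian sigma must be > 0")
        return cls(family="gaussian", components=((1.0, mu, sigma),))

    @classmethod
    def beta(
        cls, a: float, b: float, support: Tuple[float, float] = (0.0, 1.0)
    ) -> "ScoreDistributionSpec":
        return cls(family="beta", components=((1.0, a, b),), support=support)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        if self.family == "gaussian":
            for w, mu, sigma in self.components:
                out += w * stats.norm.pdf(x, mu, sigma)
        elif self.family == "beta":
            lo, hi = self.support
            for w, a, b in self.components:
                out += w * stats.beta.pdf(x, a, b, loc=lo, scale=hi - lo)
        else:
            for w, spec in self.components:
                out += w * spec.pdf(x)
        return out

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.components), size=n, p=[c[0] for c in self.components])
        out = np.empty(n)
        for i, comp in enumerate(self.components):
            mask = idx == i
            k = int(mask.sum())
            if k == 0:
                continue
            if self.family == "gaussian":
                _, mu, sigma = comp
                out[mask] = rng.normal(mu, sigma, size=k)
            elif self.family == "beta":
                lo, hi = self.support
                _, a, b = comp
                out[mask] = lo + (hi - lo) * rng.beta(a, b, size=k)
            else:
                out[mask] = comp[1].rvs(k, rng)
        return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a two-class score simulation.

    ``prior`` is the class prior alpha (fraction pathogenic), strictly in
    (0, 1); the analytic posterior is computable at any score of the common
    support.
    """

    pathogenic_spec: ScoreDistributionSpec
    benign_spec: ScoreDistributionSpec
    prior: float
    seed: int

    def __post_init__(self):
        if not (0.0 < self.prior < 1.0):
            raise ConfigurationError("prior must lie strictly inside (0, 1)")

    def analytic_posterior(self, s) -> np.ndarray:
        """``alpha*fP(s) / (alpha*fP(s) + (1-alpha)*fB(s))``; NaN where both vanish."""
        fp = self.pathogenic_spec.pdf(s)
        fb = self.benign_spec.pdf(s)
        num = self.prior * fp
        den = num + (1.0 - self.prior) * fb
        with np.errstate(invalid="ignore", divide="ignore"):
            post = np.where(den > 0, num / den, np.nan)
        if np.ndim(s) == 0:
            return float(post)
        return post


def gen_two_class_scores(
    truth: SyntheticTruth,
    n_path: int,
    n_benign: int,
    tool: str = "synthetic",
    variant_type: str = "deletion",
    direction: str = "higher_pathogenic",
) -> ScoreSet:
    """Draw independent pathogenic and benign score samples.

    The returned :class:`ScoreSet` retains the truth object so the analytic
    posterior oracle stays available downstream.  Pathogenic scores are
    drawn first, then benign, from a generator seeded with ``truth.seed``;
    identical inputs give byte-identical outputs.
    """
    if n_path < 1 or n_benign < 1:
        raise ConfigurationError("n_path and n_benign must be >= 1")
    rng = np.random.default_rng(truth.seed)
    path = truth.pathogenic_spec.rvs(n_path, rng)
    benign = truth.benign_spec.rvs(n_benign, rng)
    return ScoreSet(
        tool=tool,
        variant_type=variant_type,
        direction=direction,
        pathogenic_scores=path,
        benign_scores=benign,
        truth=truth,
    )


class PUData(NamedTuple):
    """Positive/unlabeled feature matrices with planted component labels."""

    positives: np.ndarray
    unlabeled: np.ndarray
    unlabeled_is_positive: np.ndarray  # planted component label per unlabeled row
    n_planted: int


def gen_pu_features(
    true_alpha: float,
    n_pos: int,
    n_unl: int,
    dim: int,
    separation: float,
    seed: int,
    exact_count: bool = True,
) -> PUData:
    """Positive and unlabeled feature matrices with a planted mixing fraction.

    The positive component is N(separation * 1, I) and the negative
    component N(0, I) in ``dim`` dimensions.  The unlabeled sample mixes the
    two: a fraction ``true_alpha`` of its rows comes from the positive
    component — exactly ``round(true_alpha * n_unl)`` rows in the default
    exact-count mode, or a Binomial(n_unl, true_alpha) draw otherwise.  Rows
    are shuffled; the planted labels are returned for oracle checks.
    """
    if not (0.0 <= true_alpha <= 1.0):
        raise ConfigurationError("true_alpha must lie in [0, 1]")
    if n_unl < 1:
        raise ConfigurationError("n_unl must be >= 1")
    if n_pos < 1 or dim < 1 or separation < 0:
        raise ConfigurationError("need n_pos >= 1, dim >= 1, separation >= 0")
    rng = np.random.default_rng(seed)
    shift = separation * np.ones(dim)
    positives = rng.standard_normal((n_pos, dim)) + shift
    if exact_count:
        k = int(round(true_alpha * n_unl))
    else:
        k = int(rng.binomial(n_unl, true_alpha))
    labels = np.zeros(n_unl, dtype=bool)
    labels[:k] = True
    unl = rng.standard_normal((n_unl, dim))
    unl[labels] += shift
    perm = rng.permutation(n_unl)
    return PUData(
        positives=positives,
        unlabeled=unl[perm],
        unlabeled_is_positive=labels[perm],
        n_planted=k,
    )


_NET_CHOICES = (-60, -51, -50, -48, -12, -9, -6, -4, -3, -2, -1, 0, 1, 2, 3, 6, 9, 45, 51, 60)
_BASES = np.array(list("ACGT"))


def _alleles_for_net(net: int, complex_pair: bool, rng: np.random.Generator) -> Tuple[str, str]:
    stub = 2 if complex_pair else 1
    ref_len = stub + max(0, -net)
    alt_len = stub + max(0, net)
    ref = "".join(rng.choice(_BASES, size=ref_len))
    alt = "".join(rng.choice(_BASES, size=alt_len))
    return ref, alt


def gen_filter_fixture(n: int, seed: int) -> Tuple[pd.DataFrame, Dict[str, FilterAudit]]:
    """Variant table exercising every filter rule, with a planted audit.

    Each record carries all fields the clinical, population and genotype
    filters consume, plus per-rule planted pass/fail columns (prefix
    ``planted_``).  The expected audits are computed here by sequentially
    applying each rule's predicate in the documented order, independently of
    the filter implementations, and must match them exactly.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    nets = rng.choice(_NET_CHOICES, size=n)
    pairs = [
        _alleles_for_net(int(net), bool(rng.random() < 0.2), rng) for net in nets
    ]
    af = rng.uniform(0.0, 0.02, size=n)
    af[rng.random(n) < 0.3] = np.nan
    gq = rng.integers(20, 80, size=n).astype(float)
    gq[rng.random(n) < 0.1] = np.nan
    depth = rng.integers(2, 40, size=n).astype(float)
    ab = np.round(rng.uniform(0.0, 0.6, size=n), 3)

    df = pd.DataFrame(
        {
            "assembly": "GRCh38",
            "chrom": rng.choice([f"chr{i}" for i in range(1, 23)], size=n),
            "pos": rng.integers(1, 10_000_000, size=n),
            "ref_allele": [p[0] for p in pairs],
            "alt_allele": [p[1] for p in pairs],
            "gene": [f"GENE{i % 97}" for i in range(n)],
            "gene_validity": rng.choice(GENE_VALIDITY_TIERS, size=n),
            "consequence": "other",
            "classification": rng.choice(CLASSIFICATIONS, size=n),
            "review_stars": rng.integers(0, 5, size=n),
            "has_conflict": rng.random(n) < 0.2,
            "allele_freq": af,
            "qc_pass": rng.random(n) < 0.8,
            "genotype_quality": gq,
            "depth": depth,
            "allele_balance": ab,
        }
    )
    net = df["alt_allele"].str.len() - df["ref_allele"].str.len()
    planted = {
        "gene": df["gene_validity"].isin(("definitive", "strong", "moderate")),
        "review": (df["review_stars"] >= 1) & ~df["has_conflict"],
        "af": df["allele_freq"].isna() | (df["allele_freq"] <= 0.01),
        "length": net.abs() <= 50,
        "classification": df["classification"].isin(PATHOGENIC_CLASSES + BENIGN_CLASSES),
        "in_frame": (net % 3 == 0) & (net != 0),
        "qc": df["qc_pass"].astype(bool),
        "gt_present": df["genotype_quality"].notna()
        & df["depth"].notna()
        & df["allele_balance"].notna(),
        "gq": df["genotype_quality"] >= 40,
        "dp": df["depth"] >= 10,
        "ab": df["allele_balance"] >= 0.2,
    }
    for name, mask in planted.items():
        df[f"planted_{name}"] = mask.to_numpy()

    def chain(rules: Sequence[Tuple[str, pd.Series]]) -> FilterAudit:
        audit = FilterAudit()
        alive = pd.Series(True, index=df.index)
        for rule_name, mask in rules:
            n_in = int(alive.sum())
            alive &= mask
            audit.steps.append(AuditStep(rule=rule_name, n_in=n_in, n_kept=int(alive.sum())))
        return audit

    expected = {
        "clinical": chain(
            [
                ("gene_validity", planted["gene"]),
                ("review_status", planted["review"]),
                ("allele_frequency", planted["af"]),
                ("net_length", planted["length"]),
                ("classification", planted["classification"]),
                ("in_frame_indel", planted["in_frame"]),
            ]
        ),
        "population": chain(
            [
                ("gene_validity", planted["gene"]),
                ("allele_frequency", planted["af"]),
                ("in_frame_indel", planted["in_frame"]),
                ("net_length", planted["length"]),
                ("qc_pass", planted["qc"]),
            ]
        ),
        "genotype": chain(
            [
                ("genotype_fields_present", planted["gt_present"]),
                ("genotype_quality", planted["gq"].fillna(False)),
                ("depth", planted["dp"].fillna(False)),
                ("allele_balance", planted["ab"].fillna(False)),
                ("net_length", planted["length"]),
            ]
        ),
    }
    return df, expected


CountSpec = Union[int, Callable[[np.random.Generator], int]]


def _sample_in_level(
    thresholds: EvidenceThresholds, level: int, rng: np.random.Generator
) -> float:
    """A score guaranteed to be assigned the requested evidence level."""
    if level != 0:
        if level not in thresholds.intervals:
            raise ConfigurationError(
                f"level {level:+d} not attained by thresholds for "
                f"{thresholds.tool}/{thresholds.variant_type}"
            )
        iv = thresholds.intervals[level]
        lo, hi = iv.low, iv.high
        if math.isinf(lo):
            x = hi - rng.exponential(1.0)
        elif math.isinf(hi):
            x = lo + rng.exponential(1.0)
        else:
            x = lo + (hi - lo) * rng.uniform(0.05, 0.95)
        if thresholds.assign(x) != level:  # measure-zero fallbacks
            x = (lo + hi) / 2 if math.isfinite(lo) and math.isfinite(hi) else x
        if thresholds.assign(x) != level:
            raise RuntimeError("failed to sample inside level interval")  # pragma: no cover
        return float(x)
    # level 0: probe midpoints between interval endpoints for the indeterminate gap
    ends = sorted(
        {b for iv in thresholds.intervals.values() for b in (iv.low, iv.high) if math.isfinite(b)}
    )
    candidates = []
    if not ends:
        candidates = [0.0]
    else:
        candidates.extend([ends[0] - 1.0, ends[-1] + 1.0])
        candidates.extend((a + b) / 2 for a, b in zip(ends, ends[1:]))
    gaps = [c for c in candidates if thresholds.assign(c) == 0]
    if not gaps:
        raise ConfigurationError(
            "thresholds leave no indeterminate region; cannot plant level-0 variants"
        )
    center = gaps[int(rng.integers(0, len(gaps)))]
    for scale in (0.25, 0.1, 0.01, 0.0):
        x = center + scale * rng.standard_normal()
        if thresholds.assign(x) == 0:
            return float(x)
    return float(center)  # pragma: no cover


def gen_proband_cohort(
    n_probands: int,
    planted_level_counts: Mapping[int, CountSpec],
    thresholds: EvidenceThresholds,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-proband score table with planted per-evidence-level counts.

    For each proband, draws the number of variants at each requested level
    (an integer for a fixed count, or a callable of the RNG) and emits
    scores guaranteed to fall inside the corresponding threshold interval.
    Returns ``(cohort, planted)``: the cohort score table (one row per
    variant; probands may have none) and the planted per-proband per-level
    count table.
    """
    if n_probands < 1:
        raise ConfigurationError("n_probands must be >= 1")
    for level in planted_level_counts:
        if level != 0 and level not in thresholds.intervals:
            raise ConfigurationError(
                f"requested level {level:+d} absent from thresholds"
            )
    rng = np.random.default_rng(seed)
    rows = []
    planted_rows = []
    vid = 0
    for p in range(n_probands):
        proband = f"proband_{p:04d}"
        for level, spec in sorted(planted_level_counts.items()):
            count = spec(rng) if callable(spec) else int(spec)
            planted_rows.append({"proband_id": proband, "level": level, "count": count})
            for _ in range(count):
                rows.append(
                    {
                        "proband_id": proband,
                        "variant_id": f"var_{vid:06d}",
                        "tool": thresholds.tool,
                        "variant_type": thresholds.variant_type,
                        "score": _sample_in_level(thresholds, level, rng),
                        "planted_level": level,
                    }
                )
                vid += 1
    cohort = pd.DataFrame(
        rows,
        columns=["proband_id", "variant_id", "tool", "variant_type", "score", "planted_level"],
    )
    planted = pd.DataFrame(planted_rows, columns=["proband_id", "level", "count"])
    return cohort, planted
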