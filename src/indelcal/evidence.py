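"""Point-based Bayesian evidence framework for ACMG/AMP variant classification.

The ACMG/AMP guidelines combine evidence for and against pathogenicity in
signed integer *points* (supporting = ±1, moderate = ±2, strong = ±4) and,
in their Bayesian adaptation, require the combined posterior probability of
pathogenicity to satisfy fixed floors: ≥ 0.99 for pathogenic, ≥ 0.90 for
likely pathogenic, ≤ 0.10 for likely benign and ≤ 0.01 for benign.

Evidence combines multiplicatively on the likelihood-ratio scale, so the
whole system is determined by a single *per-point likelihood ratio* ``s``:
``k`` points of evidence correspond to a likelihood ratio of ``s**k``.  The
scale is anchored by requiring that six points of pathogenic evidence reach
exactly the likely-pathogenic posterior floor of 0.90 at the prior
probability of pathogenicity ``alpha``::

    posterior(s**6, alpha) = 0.90
    =>  s(alpha) = (9 * (1 - alpha) / alpha) ** (1 / 6)

where ``posterior(lr, alpha) = lr * alpha / (lr * alpha + 1 - alpha)`` is the
Bayes odds update.  The framework's very-strong odds constant is ``C = s**8``
(for the historical missense prior alpha = 0.10 this gives C ≈ 350).

For a class of variants with prior ``alpha``, the minimum likelihood ratio a
predictor must achieve for level ``+k`` is ``s**k``; benign levels ``-k``
carry the reciprocal bound ``s**-k`` (an upper bound on the LR, equivalently
a lower bound of ``s**k`` on the inverse likelihood ratio).  For in-frame
indel deletions with ``alpha = 0.046`` this yields the supporting-level LR
of 2.39; the low insertion prior pushes every bound higher, which is why
insertions are harder to classify in both directions.

``s(alpha) <= 1`` whenever ``alpha >= 0.9``: the prior alone already exceeds
the likely-pathogenic floor and the point system degenerates.  Such scales
are flagged rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

from .errors import InputError

__all__ = [
    "EVIDENCE_LEVELS",
    "PointScale",
    "posterior_from_lr",
    "per_point_lr",
    "expected_lr_for_level",
    "posterior_threshold_for_level",
    "validate_point_scale",
]

#: Magnitudes of the evidence levels the framework reports (supporting,
#: moderate, +3, strong).
EVIDENCE_LEVELS = (1, 2, 3, 4)

#: Posterior floor for "likely pathogenic" used to anchor the scale.
LIKELY_PATHOGENIC_POSTERIOR = 0.90

#: Number of points that must reach the likely-pathogenic floor.
ANCHOR_POINTS = 6


def _check_prior(prior: float) -> None:
    if not (0.0 < float(prior) < 1.0):
        raise InputError(f"prior must lie strictly inside (0, 1); got {prior!r}")


def posterior_from_lr(lr, prior: float):
    """Bayes odds update: posterior probability of pathogenicity.

    Parameters
    ----------
    lr
        Non-negative likelihood ratio (scalar or array).  ``inf`` maps to a
        posterior of 1.
    prior
        Prior probability of pathogenicity, strictly inside (0, 1).

    Returns
    -------
    float or ndarray
        ``lr * prior / (lr * prior + (1 - prior))``, strictly increasing
        in ``lr``.
    """
    _check_prior(prior)
    arr = np.asarray(lr, dtype=float)
    if np.any(arr < 0):
        raise InputError("likelihood ratio must be non-negative")
    num = arr * prior
    with np.errstate(invalid="ignore"):
        post = num / (num + (1.0 - prior))
    post = np.where(np.isinf(arr), 1.0, post)
    if np.ndim(lr) == 0:
        return float(post)
    return post


def per_point_lr(prior: float) -> float:
    """Per-point likelihood ratio ``s`` solving ``posterior(s**6, prior) = 0.90``.

    Closed form: ``s = (9 * (1 - prior) / prior) ** (1 / 6)``.  For
    ``prior >= 0.9`` the solution satisfies ``s <= 1`` (degenerate scale);
    the value is returned and callers flag it via :class:`PointScale`.
    """
    _check_prior(prior)
    return float((9.0 * (1.0 - prior) / prior) ** (1.0 / ANCHOR_POINTS))


def _check_level(k: int) -> int:
    k = int(k)
    if k == 0 or abs(k) not in EVIDENCE_LEVELS:
        raise InputError(
            f"evidence level must be a signed integer in ±{EVIDENCE_LEVELS}; got {k}"
        )
    return k


def expected_lr_for_level(prior: float, k: int) -> float:
    """Likelihood-ratio bound ``s**k`` for evidence level ``k``.

    Pathogenic levels (``k > 0``) return the minimum LR the level demands.
    Benign levels (``k < 0``) return ``s**k < 1``, an *upper* bound whose
    reciprocal is the reported inverse likelihood ratio bound.
    """
    k = _check_level(k)
    return per_point_lr(prior) ** k


def posterior_threshold_for_level(prior: float, k: int) -> float:
    """Posterior bound for level ``k``: ``posterior(s**k, prior)``.

    Pathogenic levels are lower bounds on the local posterior probability;
    benign levels are upper bounds.
    """
    return posterior_from_lr(expected_lr_for_level(prior, k), prior)


@dataclass(frozen=True)
class PointScale:
    """The evidence framework instantiated at one prior.

    Attributes
    ----------
    prior
        Prior probability of pathogenicity alpha.
    per_point_lr
        The per-point likelihood ratio ``s``.
    level_lr
        Map ``k -> s**k`` for ``k`` in ±1…±4.
    level_posterior
        Map ``k -> posterior(s**k, prior)``.
    odds_constant
        The very-strong odds constant ``C = s**8``.
    degenerate
        True when ``s <= 1`` (prior ≥ 0.9): points carry no discriminative
        weight and thresholds collapse onto the prior.
    """

    prior: float
    per_point_lr: float
    level_lr: Dict[int, float] = field(repr=False)
    level_posterior: Dict[int, float] = field(repr=False)
    odds_constant: float
    degenerate: bool

    @classmethod
    def from_prior(cls, prior: float) -> "PointScale":
        _check_prior(prior)
        s = per_point_lr(prior)
        levels = [k * sign for k in EVIDENCE_LEVELS for sign in (1, -1)]
        level_lr = {k: s**k for k in sorted(levels)}
        level_posterior = {
            k: posterior_from_lr(lr, prior) for k, lr in level_lr.items()
        }
        return cls(
            prior=float(prior),
            per_point_lr=s,
            level_lr=level_lr,
            level_posterior=level_posterior,
            odds_constant=s**8,
            degenerate=s <= 1.0,
        )

    def to_dict(self) -> dict:
        return {
            "prior": self.prior,
            "per_point_lr": self.per_point_lr,
            "level_lr": {str(k): v for k, v in self.level_lr.items()},
            "level_posterior": {str(k): v for k, v in self.level_posterior.items()},
            "odds_constant": self.odds_constant,
            "degenerate": self.degenerate,
        }


def validate_point_scale(scale: PointScale, atol: float = 1e-9) -> dict:
    """Consistency report for a :class:`PointScale`.

    Checks the classification floors of the Bayesian ACMG/AMP adaptation:
    posterior at +10 points ≥ 0.99 (pathogenic), at +6 points = 0.90 exactly
    (likely pathogenic, the defining anchor), and at −6 points ≤ 0.10
    (likely benign).  Degenerate scales fail the checks but never raise.
    """
    s, a = scale.per_point_lr, scale.prior
    p10 = posterior_from_lr(s**10, a)
    p6 = posterior_from_lr(s**6, a)
    m6 = posterior_from_lr(s**-6, a)
    checks = {
        "pathogenic_10pt": {"value": p10, "bound": 0.99, "pass": bool(p10 >= 0.99 - atol)},
        "likely_pathogenic_6pt": {
            "value": p6,
            "bound": LIKELY_PATHOGENIC_POSTERIOR,
            "pass": bool(abs(p6 - LIKELY_PATHOGENIC_POSTERIOR) <= max(atol, 1e-9)),
        },
        "likely_benign_minus6pt": {"value": m6, "bound": 0.10, "pass": bool(m6 <= 0.10 + atol)},
    }
    return {
        "prior": a,
        "per_point_lr": s,
        "degenerate": scale.degenerate,
        "checks": checks,
        "pass": bool(all(c["pass"] for c in checks.values()) and not scale.degenerate),
    }
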