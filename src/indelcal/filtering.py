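"""Dataset-construction rules for in-frame indel calibration sets.

Implements the filters that shape the three kinds of input table the
pipeline consumes: a clinical-archive table (classification, review stars,
conflict flags), a population-reference table (QC status, allele
frequencies) and a per-proband genotype table (GQ/DP/allele balance).
Variant tables are plain :class:`pandas.DataFrame` objects with the column
schema of :data:`VARIANT_COLUMNS`; every filter returns the kept rows plus a
:class:`FilterAudit` recording per-rule input/kept counts in application
order.

Indels are typed by their *net* effect on sequence length, so complex
substitutions (e.g. ``AT -> GCCAT``) are classed by ``len(alt) - len(ref)``;
a net change of zero is ``balanced`` and is excluded from the
insertion/deletion calibration streams.  "In-frame indel" throughout means a
nonzero net change divisible by 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "IndelClass",
    "FilterAudit",
    "ClinicalFilterConfig",
    "classify_indel",
    "net_length_change",
    "filter_clinical",
    "filter_population",
    "filter_genotypes",
    "exclude_overlap",
    "crop_window",
    "VARIANT_COLUMNS",
    "CLASSIFICATIONS",
    "PATHOGENIC_CLASSES",
    "BENIGN_CLASSES",
]

VARIANT_COLUMNS = (
    "assembly",
    "chrom",
    "pos",
    "ref_allele",
    "alt_allele",
    "gene",
    "gene_validity",
    "consequence",
    "classification",
    "review_stars",
    "has_conflict",
    "allele_freq",
    "qc_pass",
    "genotype_quality",
    "depth",
    "allele_balance",
)

GENE_VALIDITY_TIERS = ("definitive", "strong", "moderate", "limited", "other", "none")
CLASSIFICATIONS = ("P", "P/LP", "LP", "B", "B/LB", "LB", "VUS", "conflicting", "none")
PATHOGENIC_CLASSES = ("P", "P/LP", "LP")
BENIGN_CLASSES = ("B", "B/LB", "LB")
KEY_COLUMNS = ("assembly", "chrom", "pos", "ref_allele", "alt_allele")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class IndelClass:
    """Net-length typing of one ref/alt allele pair."""

    kind: str  # insertion | deletion | balanced
    net_nt: int
    in_frame: bool


def _check_allele(allele: str, name: str) -> str:
    if not isinstance(allele, str) or len(allele) == 0:
        raise InputError(f"{name} allele must be a non-empty string")
    if not set(allele) <= _VALID_BASES:
        raise InputError(f"{name} allele {allele!r} is not an uppercase ACGT string")
    return allele


def classify_indel(ref_allele: str, alt_allele: str) -> IndelClass:
    """Type a variant by its net nucleotide length change.

    ``net_nt = len(alt) - len(ref)``: positive is an insertion, negative a
    deletion, zero is balanced.  ``in_frame`` is true when the net change is
    divisible by 3 (note a balanced change is trivially in frame but is not
    an in-frame *indel*).
    """
    ref = _check_allele(ref_allele, "ref")
    alt = _check_allele(alt_allele, "alt")
    net = len(alt) - len(ref)
    kind = "insertion" if net > 0 else "deletion" if net < 0 else "balanced"
    return IndelClass(kind=kind, net_nt=net, in_frame=net % 3 == 0)


def net_length_change(df: pd.DataFrame) -> pd.Series:
    """Vectorised ``len(alt) - len(ref)`` for a variant table."""
    return df["alt_allele"].str.len() - df["ref_allele"].str.len()


@dataclass(frozen=True)
class AuditStep:
    rule: str
    n_in: int
    n_kept: int

    @property
    def n_excluded(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class FilterAudit:
    """Per-rule input/kept counts in application order."""

    steps: List[AuditStep] = field(default_factory=list)

    @property
    def final_kept(self) -> int:
        return self.steps[-1].n_kept if self.steps else 0

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"rule": s.rule, "n_in": s.n_in, "n_kept": s.n_kept} for s in self.steps
            ],
            "final_kept": self.final_kept,
        }

    def kept_counts(self) -> List[int]:
        return [s.n_kept for s in self.steps]


@dataclass(frozen=True)
class ClinicalFilterConfig:
    """Thresholds of the clinical/population filters.

    Defaults encode the calibration-set construction rules: disease genes
    with definitive/strong/moderate validity, at least one review star with
    no conflicts, global AF absent or <= 1%, net length <= 50 bp, and an
    unambiguous pathogenic- or benign-side classification.
    """

    max_allele_freq: float = 0.01
    max_net_length: int = 50
    min_review_stars: int = 1
    allowed_validity: Tuple[str, ...] = ("definitive", "strong", "moderate")
    allowed_classifications: Tuple[str, ...] = PATHOGENIC_CLASSES + BENIGN_CLASSES


def _validate_classifications(df: pd.DataFrame) -> None:
    if "classification" not in df.columns:
        return
    bad = ~df["classification"].isin(CLASSIFICATIONS)
    if bad.any():
        idx = df.index[bad][0]
        raise InputError(
            f"unknown classification token {df.loc[idx, 'classification']!r} "
            f"in record {idx}"
        )


def _apply_rules(
    df: pd.DataFrame, rules: Sequence[Tuple[str, pd.Series]]
) -> Tuple[pd.DataFrame, FilterAudit]:
    audit = FilterAudit()
    kept = df
    for name, mask in rules:
        mask = mask.reindex(kept.index, fill_value=False)
        n_in = len(kept)
        kept = kept[mask.loc[kept.index]]
        audit.steps.append(AuditStep(rule=name, n_in=n_in, n_kept=len(kept)))
    return kept, audit


def filter_clinical(
    records: pd.DataFrame, config: Optional[ClinicalFilterConfig] = None
) -> Tuple[pd.DataFrame, FilterAudit]:
    """Clinical-archive calibration-set filter.

    Rules in order: gene validity tier, review status (stars and conflicts),
    allele frequency (missing counts as absent from the reference
    population and passes), net indel length, classification set, and
    in-frame-indel status.  Order affects per-rule audit counts only; the
    final kept set is the intersection of all predicates.
    """
    cfg = config or ClinicalFilterConfig()
    _validate_classifications(records)
    net = net_length_change(records)
    rules = [
        ("gene_validity", records["gene_validity"].isin(cfg.allowed_validity)),
        (
            "review_status",
            (records["review_stars"] >= cfg.min_review_stars)
            & ~records["has_conflict"].astype(bool),
        ),
        (
            "allele_frequency",
            records["allele_freq"].isna()
            | (records["allele_freq"] <= cfg.max_allele_freq),
        ),
        ("net_length", net.abs() <= cfg.max_net_length),
        (
            "classification",
            records["classification"].isin(cfg.allowed_classifications),
        ),
        ("in_frame_indel", (net % 3 == 0) & (net != 0)),
    ]
    return _apply_rules(records, rules)


def filter_population(
    records: pd.DataFrame, config: Optional[ClinicalFilterConfig] = None
) -> Tuple[pd.DataFrame, FilterAudit]:
    """Population-reference filter: gene tier, AF, frame, length, QC pass."""
    cfg = config or ClinicalFilterConfig()
    net = net_length_change(records)
    rules = [
        ("gene_validity", records["gene_validity"].isin(cfg.allowed_validity)),
        (
            "allele_frequency",
            records["allele_freq"].isna()
            | (records["allele_freq"] <= cfg.max_allele_freq),
        ),
        ("in_frame_indel", (net % 3 == 0) & (net != 0)),
        ("net_length", net.abs() <= cfg.max_net_length),
        ("qc_pass", records["qc_pass"].astype(bool)),
    ]
    return _apply_rules(records, rules)


def filter_genotypes(records: pd.DataFrame) -> Tuple[pd.DataFrame, FilterAudit]:
    """Per-proband genotype-quality filter: GQ >= 40, DP >= 10, AB >= 0.2.

    Records with missing genotype fields are excluded by a dedicated audit
    step rather than raising.  All bounds are inclusive.
    """
    net = net_length_change(records)
    present = (
        records["genotype_quality"].notna()
        & records["depth"].notna()
        & records["allele_balance"].notna()
    )
    rules = [
        ("genotype_fields_present", present),
        ("genotype_quality", records["genotype_quality"] >= 40),
        ("depth", records["depth"] >= 10),
        ("allele_balance", records["allele_balance"] >= 0.2),
        ("net_length", net.abs() <= 50),
    ]
    return _apply_rules(records, rules)


def exclude_overlap(
    records: pd.DataFrame,
    exclusion_keys: Iterable[Tuple],
    allow_mixed_assembly: bool = False,
) -> Tuple[pd.DataFrame, int]:
    """Remove records whose (assembly, chrom, pos, ref, alt) key is excluded.

    Keys are compared exactly as given; inputs must be pre-normalized.
    Comparing across assemblies without ``allow_mixed_assembly`` raises, as
    identical coordinates on different builds are distinct variants.
    """
    keys: Set[Tuple] = {tuple(k) for k in exclusion_keys}
    if not allow_mixed_assembly and keys:
        assemblies = {k[0] for k in keys} | set(records["assembly"].unique())
        if len(assemblies) > 1:
            raise InputError(
                f"mixed assemblies {sorted(assemblies)} in overlap comparison; "
                "pass allow_mixed_assembly=True if intended"
            )
    record_keys = list(
        zip(*(records[c] for c in KEY_COLUMNS))
    )
    mask = np.fromiter((k not in keys for k in record_keys), dtype=bool, count=len(records))
    remaining = records[mask]
    removed = int(len(records) - len(remaining))
    return remaining, removed


def crop_window(
    wt_seq: str,
    var_seq: str,
    var_start: int,
    var_end: int,
    max_len: int = 2046,
) -> Tuple[str, str]:
    """Crop long protein sequences to a window centred on the variant.

    Sequences of at most ``max_len`` residues are returned unchanged.
    Longer ones are cropped to exactly ``max_len`` residues centred at
    ``floor((var_start + var_end) / 2)`` (1-based), with a left-biased split
    of the even window (1023 residues before the centre, 1022 after) and a
    minimal shift to stay within sequence boundaries.  The procedure is
    applied independently to the wild-type and variant sequences, so a
    length-changing variant yields windows computed against each sequence's
    own length.
    """
    if var_start < 1 or var_end < var_start:
        raise InputError(
            f"invalid variant coordinates ({var_start}, {var_end}); need 1 <= start <= end"
        )

    def crop(seq: str, name: str) -> str:
        length = len(seq)
        if var_start > length:
            raise InputError(
                f"variant start {var_start} outside {name} sequence of length {length}"
            )
        if length <= max_len:
            return seq
        center = (var_start + min(var_end, length)) // 2
        start = center - max_len // 2  # 1-based, 1023 residues left of centre
        end = start + max_len - 1
        if start < 1:
            start, end = 1, max_len
        elif end > length:
            start, end = length - max_len + 1, length
        return seq[start - 1 : end]

    return crop(wt_seq, "wild-type"), crop(var_seq, "variant")
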