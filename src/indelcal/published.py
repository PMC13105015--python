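"""Machine-readable fixture of published per-tool evidence thresholds.

These interval tables encode *printed* results for eight in-frame indel
predictors (insertions and deletions separately), transcribed from the
published threshold tables; they are not recomputed by this package and are
used only as interval-convention fixtures in tests (boundary membership,
disjointness, ordering).  Two entries are normalized to the tables' own
boundary-to-stronger-level convention: the ProGen2 insertion +2 bound is
encoded as inclusive at -0.076 and the bare VEST-Indel insertion +3 value
1.0 as ">= 1.0".
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Tuple

import pandas as pd

from .calibration import EvidenceThresholds

__all__ = ["load_published_thresholds"]


def load_published_thresholds() -> Dict[Tuple[str, str], EvidenceThresholds]:
    """Published threshold sets keyed by ``(tool, variant_type)``."""
    with resources.files("indelcal.data").joinpath("published_thresholds.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["low_inclusive"] = df["low_inclusive"].astype(bool)
    df["high_inclusive"] = df["high_inclusive"].astype(bool)
    df["prior"] = float("nan")
    out = {}
    for thresholds in EvidenceThresholds.from_frame(df):
        thresholds.settings["source"] = "published"
        out[(thresholds.tool, thresholds.variant_type)] = thresholds
    return out
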