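"""Delimited-text readers/writers for the pipeline's file formats.

All formats are TSV with a named header; JSON sidecars carry provenance.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .calibration import EvidenceThresholds, PosteriorCurve, ScoreSet
from .errors import ConfigurationError, InputError

SCORE_COLUMNS = ("variant_id", "tool", "variant_type", "label", "score")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path, obj) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder, allow_nan=True) + "\n"
    )


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_score_sets(path, score_sets: List[ScoreSet]) -> None:
    frames = []
    for s in score_sets:
        for label, scores in (
            ("pathogenic", s.pathogenic_scores),
            ("benign", s.benign_scores),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "variant_id": [
                            f"{s.tool}_{s.variant_type}_{label}_{i}"
                            for i in range(scores.size)
                        ],
                        "tool": s.tool,
                        "variant_type": s.variant_type,
                        "label": label,
                        "score": scores,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_score_sets(path, directions: Dict[str, str]) -> List[ScoreSet]:
    """Read labeled scores; per-tool directions are declared, never inferred."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"score table {path} lacks columns {sorted(missing)}")
    out = []
    for (tool, vtype), grp in df.groupby(["tool", "variant_type"], sort=False):
        if tool not in directions:
            raise ConfigurationError(
                f"no score direction declared for tool {tool!r}; directions are never inferred"
            )
        path_scores = grp.loc[grp["label"] == "pathogenic", "score"].to_numpy()
        ben_scores = grp.loc[grp["label"] == "benign", "score"].to_numpy()
        out.append(
            ScoreSet(
                tool=tool,
                variant_type=vtype,
                direction=directions[tool],
                pathogenic_scores=path_scores,
                benign_scores=ben_scores,
            )
        )
    return out


def write_thresholds(path, thresholds: List[EvidenceThresholds]) -> None:
    pd.concat([t.to_frame() for t in thresholds], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )


def read_thresholds(path) -> List[EvidenceThresholds]:
    df = pd.read_csv(path, sep="\t")
    df["excluded_reason"] = df.get("excluded_reason", "").fillna("")
    return EvidenceThresholds.from_frame(df)


def write_curve(path, curve: PosteriorCurve) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False)


def write_variant_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_features(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_features(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
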