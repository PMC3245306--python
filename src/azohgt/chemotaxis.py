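"""Chemotaxis-class assignment from CheA model score tables.

Each CheA sequence is scored against class-specific models (F5, F7, F8,
F9, ACF, ...) and one model built from the entire CheA set.  A sequence is
assigned the class of its top-scoring class model; when the full-set model
strictly outscores every class model the sequence is unclassified
("Unc").  Ties between class models break lexicographically with a
warning.  Scores must share one comparable scale (higher is better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = ["CheAScoreRow", "classify_chea", "read_chea_scores", "classify_chea_table"]

UNCLASSIFIED = "Unc"


@dataclass(frozen=True)
class CheAScoreRow:
    sequence_id: str
    class_scores: Mapping[str, float]
    full_set_score: float

    def __post_init__(self) -> None:
        if not self.class_scores:
            raise ValueError(f"{self.sequence_id}: no class scores")


def classify_chea(row: CheAScoreRow) -> str:
    """Assign a chemotaxis class, or ``"Unc"`` if the generic model wins."""
    best = max(row.class_scores.values())
    if row.full_set_score > best:
        return UNCLASSIFIED
    winners = sorted(k for k, v in row.class_scores.items() if v == best)
    if len(winners) > 1:
        warnings.warn(
            f"{row.sequence_id}: tie between class models {winners}; "
            f"taking {winners[0]} (lexicographic)"
        )
    return winners[0]


def read_chea_scores(path) -> list[CheAScoreRow]:
    """Read a score TSV: sequence_id, full_set, then one column per class model."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("sequence_id", "full_set"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    class_cols = [c for c in df.columns if c not in ("sequence_id", "full_set")]
    if not class_cols:
        raise ValueError(f"{path}: no class-model score columns")
    return [
        CheAScoreRow(
            sequence_id=str(row["sequence_id"]),
            class_scores={c: float(row[c]) for c in class_cols},
            full_set_score=float(row["full_set"]),
        )
        for _, row in df.iterrows()
    ]


def classify_chea_table(rows: list[CheAScoreRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sequence_id": [r.sequence_id for r in rows],
            "assigned_class": [classify_chea(r) for r in rows],
        }
    )
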