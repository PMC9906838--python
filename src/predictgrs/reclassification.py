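"""Chemotherapy-benefit categories and reclassification tables.

Patients are stratified by predicted absolute 10-year survival benefit of
adjuvant chemotherapy: low (< 3 percentage points, chemotherapy usually not
offered), intermediate (3-5 inclusive, discussion of pros and cons) and
high (> 5, chemotherapy recommended). A reclassification table
cross-tabulates the categories under two models and summarises movements,
with special attention to the intermediate band, where treatment decisions
are least clear-cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

LABELS = ("low", "intermediate", "high")
_LOW_BOUND = 3.0
_HIGH_BOUND = 5.0


def categorize_benefit(benefit: float) -> str:
    """Benefit category: low iff < 3, intermediate iff 3 <= b <= 5, high iff > 5.

    Both boundary values belong to the intermediate band (the only reading
    that partitions the line given strict inequalities on the outer bands).
    """
    if not np.isfinite(benefit):
        raise ValueError(f"benefit must be finite, got {benefit}")
    if benefit < _LOW_BOUND:
        return "low"
    if benefit <= _HIGH_BOUND:
        return "intermediate"
    return "high"


def categorize_benefits(benefits) -> pd.Series:
    """Vectorised :func:`categorize_benefit` preserving the input index."""
    b = pd.Series(benefits, dtype=float)
    if not np.isfinite(b.to_numpy()).all():
        raise ValueError("benefits must be finite")
    out = pd.Series(
        np.where(b < _LOW_BOUND, "low",
                 np.where(b <= _HIGH_BOUND, "intermediate", "high")),
        index=b.index)
    return out


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ReclassificationTable:
    """3x3 cross-tabulation of benefit categories under two models.

    Rows are categories under model A (the standalone model), columns under
    model B (the modified model).
    """

    matrix: np.ndarray
    model_a: str = "A"
    model_b: str = "B"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=int)
        if self.matrix.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if np.any(self.matrix < 0):
            raise ValueError("matrix entries must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.matrix.sum())

    @property
    def n_reclassified(self) -> int:
        return int(self.matrix.sum() - np.trace(self.matrix))

    @property
    def pct_reclassified(self) -> float:
        return 100.0 * self.n_reclassified / self.n_total

    @property
    def into_intermediate(self) -> int:
        return int(self.matrix[:, 1].sum() - self.matrix[1, 1])

    @property
    def out_of_intermediate(self) -> int:
        return int(self.matrix[1, :].sum() - self.matrix[1, 1])

    @property
    def low_to_high(self) -> int:
        return int(self.matrix[0, 2])

    @property
    def high_to_low(self) -> int:
        return int(self.matrix[2, 0])

    def transpose(self) -> "ReclassificationTable":
        return ReclassificationTable(self.matrix.T, self.model_b, self.model_a)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix,
                            index=pd.Index(LABELS, name=self.model_a),
                            columns=pd.Index(LABELS, name=self.model_b))

    def summary(self) -> dict:
        return {
            "model_a": self.model_a, "model_b": self.model_b,
            "n_total": self.n_total,
            "n_reclassified": self.n_reclassified,
            "pct_reclassified": self.pct_reclassified,
            "pct_reclassified_rounded": _round_half_away(self.pct_reclassified),
            "into_intermediate": self.into_intermediate,
            "out_of_intermediate": self.out_of_intermediate,
            "low_to_high": self.low_to_high,
            "high_to_low": self.high_to_low,
        }


def build_table(categories_a: pd.Series, categories_b: pd.Series,
                model_a: str = "A", model_b: str = "B") -> ReclassificationTable:
    """Cross-tabulate per-patient labels under two models.

    Both series must be indexed by the same patient set with no missing
    labels; a mismatch raises with the differing ids listed.
    """
    a = pd.Series(categories_a)
    b = pd.Series(categories_b)
    only_a = a.index.difference(b.index)
    only_b = b.index.difference(a.index)
    if len(only_a) or len(only_b):
        raise ValueError(
            f"mismatched patient sets: only in A {list(only_a[:5])}, "
            f"only in B {list(only_b[:5])}")
    b = b.reindex(a.index)
    for name, s in (("A", a), ("B", b)):
        bad = set(s) - set(LABELS)
        if bad:
            raise ValueError(f"illegal label(s) under model {name}: {sorted(bad)}")
    idx = {lab: i for i, lab in enumerate(LABELS)}
    matrix = np.zeros((3, 3), dtype=int)
    for la, lb in zip(a, b):
        matrix[idx[la], idx[lb]] += 1
    return ReclassificationTable(matrix, model_a, model_b)


def from_matrix(matrix, model_a: str = "A", model_b: str = "B") -> ReclassificationTable:
    """Build a table directly from a printed 3x3 count matrix."""
    return ReclassificationTable(np.asarray(matrix), model_a, model_b)


def summarize_all(tables: Mapping[str, ReclassificationTable]) -> pd.DataFrame:
    """One summary row per signature (movement counts and rounded percents)."""
    if not tables:
        raise ValueError("need at least one table")
    rows = []
    for name, table in tables.items():
        row = {"signature": name}
        row.update(table.summary())
        rows.append(row)
    return pd.DataFrame(rows)
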