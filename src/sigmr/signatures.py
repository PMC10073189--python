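"""Signature-level operations: query construction, correlation, concordance filtering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SignatureMatrix


@dataclass
class ExpressionSignature:
    """One perturbation's per-gene z-scores with landmark flags and metadata."""

    gene_ids: list[str]
    z: np.ndarray
    is_landmark: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.is_landmark = np.asarray(self.is_landmark, dtype=bool)
        if len(self.gene_ids) != len(self.z) or len(self.z) != len(self.is_landmark):
            raise ValueError("gene_ids, z and is_landmark must have equal length")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("signature z-scores must be finite")

    @classmethod
    def from_matrix(cls, matrix: SignatureMatrix, column_id: str) -> "ExpressionSignature":
        meta = matrix.column_meta.loc[column_id].to_dict()
        meta["column_id"] = column_id
        return cls(
            gene_ids=list(matrix.gene_ids),
            z=matrix.column_values(column_id),
            is_landmark=matrix.gene_is_landmark,
            meta=meta,
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.z, index=self.gene_ids)


@dataclass
class QuerySignature:
    """Top-k up and bottom-k down landmark genes of a perturbation."""

    up: list[str]
    down: list[str]
    query_id: str = ""

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("query up and down sets overlap")
        if len(self.up) != len(self.down):
            raise ValueError("query up and down sets must have equal size")

    @property
    def k(self) -> int:
        return len(self.up)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.up) + list(self.down),
                "direction": ["up"] * len(self.up) + ["down"] * len(self.down),
            }
        )


def build_query(sig: ExpressionSignature, k: int, query_id: str = "") -> QuerySignature:
    """Select the k most up- and k most down-regulated landmark genes.

    Ties in z are broken by lexicographic gene id so the selection is
    deterministic regardless of input gene order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lm_idx = np.flatnonzero(sig.is_landmark)
    if len(lm_idx) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} landmark genes for k={k}, found {len(lm_idx)}"
        )
    genes = [sig.gene_ids[i] for i in lm_idx]
    z = sig.z[lm_idx]
    # sort by (-z, gene_id): descending z, ascending id on ties
    order_desc = sorted(range(len(genes)), key=lambda i: (-z[i], genes[i]))
    up = [genes[i] for i in order_desc[:k]]
    # sort by (z, gene_id): ascending z, ascending id on ties
    order_asc = sorted(range(len(genes)), key=lambda i: (z[i], genes[i]))
    down = [genes[i] for i in order_asc[:k]]
    return QuerySignature(up=up, down=down, query_id=query_id or str(sig.meta.get("column_id", "")))


def signature_correlation(
    a: ExpressionSignature,
    b: ExpressionSignature,
    gene_scope: Literal["all", "landmark"] = "all",
) -> float:
    """Pearson r of two signatures over the intersection of in-scope genes."""
    if gene_scope not in ("all", "landmark"):
        raise ValueError(f"unknown gene_scope {gene_scope!r}")
    sa = a.as_series()
    sb = b.as_series()
    if gene_scope == "landmark":
        sa = sa[np.asarray(a.is_landmark)]
        sb = sb[np.asarray(b.is_landmark)]
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, found {len(shared)}")
    x = sa.loc[shared].to_numpy()
    y = sb.loc[shared].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant signature")
    # direct formula: bitwise symmetric in (a, b), unlike np.corrcoef
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def concordance_filter(
    collection: Mapping[str, ExpressionSignature] | Sequence[tuple[str, ExpressionSignature]],
    min_mean_r: float = 0.2,
    gene_scope: Literal["all", "landmark"] = "all",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Drop compounds whose mean pairwise correlation with the rest is low.

    Returns (kept ids, dropped ids, report) where the report lists every
    compound's mean pairwise r. Mirrors discarding an outlier compound whose
    signature disagrees with the rest of its class.
    """
    items = list(collection.items()) if isinstance(collection, Mapping) else list(collection)
    if len(items) < 3:
        raise ValueError("concordance filter needs >= 3 compounds")
    ids = [i for i, _ in items]
    n = len(ids)
    rmat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            rmat[i, j] = rmat[j, i] = signature_correlation(items[i][1], items[j][1], gene_scope)
    mean_r = (rmat.sum(axis=1) - 1.0) / (n - 1)
    report = pd.DataFrame({"compound": ids, "mean_pairwise_r": mean_r})
    report["kept"] = report["mean_pairwise_r"] >= min_mean_r
    kept = report.loc[report["kept"], "compound"].tolist()
    dropped = report.loc[~report["kept"], "compound"].tolist()
    return kept, dropped, report
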