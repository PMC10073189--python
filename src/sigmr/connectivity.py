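"""Weighted-KS connectivity scoring: WTCS, group normalization, Tau percentiles.

The scoring chain is:

1. rank each reference signature's genes by descending z;
2. score a query's up and down gene sets by a weighted Kolmogorov-Smirnov
   running-sum enrichment statistic (ES);
3. combine the two sides into the weighted two-sided connectivity score
   WTCS = (ES_up - ES_down)/2 when the sides disagree in sign, else 0;
4. normalize WTCS within (cell line, perturbation type) groups by the mean
   magnitude of same-sign scores (NCS);
5. convert NCS to a signed percentile (Tau in [-100, 100]) against the
   touchstone reference distribution of the same group;
6. summarize Tau across cell lines by the maximal-magnitude 33rd/67th
   nearest-rank quantile, and average Tau across query compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SignatureMatrix
from .signatures import ExpressionSignature, QuerySignature

logger = logging.getLogger(__name__)

DEFAULT_PERTURBATION_TYPE = "trt_cp"


@dataclass
class RankedReference:
    """A reference signature's genes ordered by descending z.

    Ties are broken by ascending gene id so the ranking is strict and
    deterministic.
    """

    gene_ids: list[str]
    z: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if len(self.gene_ids) != len(self.z):
            raise ValueError("gene_ids and z must have equal length")
        order = sorted(range(len(self.gene_ids)), key=lambda i: (-self.z[i], self.gene_ids[i]))
        self.gene_ids = [self.gene_ids[i] for i in order]
        self.z = self.z[order]
        self._rank = {g: i for i, g in enumerate(self.gene_ids)}

    @classmethod
    def from_signature(
        cls, sig: ExpressionSignature, gene_scope: str = "landmark"
    ) -> "RankedReference":
        if gene_scope == "landmark":
            keep = np.asarray(sig.is_landmark)
        elif gene_scope == "all":
            keep = np.ones(len(sig.gene_ids), dtype=bool)
        else:
            raise ValueError(f"unknown gene_scope {gene_scope!r}")
        genes = [g for g, k in zip(sig.gene_ids, keep) if k]
        return cls(gene_ids=genes, z=sig.z[keep], meta=dict(sig.meta))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene in self._rank

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array(sorted(self._rank[g] for g in genes), dtype=int)


@dataclass
class ConnectivityRecord:
    query_id: str
    reference_id: str
    wtcs: float
    ncs: float = np.nan
    tau: float = np.nan

    def __post_init__(self) -> None:
        if abs(self.wtcs) > 1 + 1e-12:
            raise ValueError(f"|wtcs| > 1: {self.wtcs}")
        if np.isfinite(self.tau) and abs(self.tau) > 100:
            raise ValueError(f"|tau| > 100: {self.tau}")


def weighted_ks_enrichment(
    reference: RankedReference,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` in the ranked reference.

    Walking down the ranked list, hits increment the running sum by
    ``|z|^w / sum_set(|z|^w)`` and misses decrement it by ``1/(N - n)``;
    the ES is the running deviation of maximal absolute value (signed),
    so ES lies in [-1, 1].
    """
    genes = set(gene_set)
    n_total = len(reference)
    if not genes:
        raise ValueError("empty gene set")
    missing = genes - set(reference.gene_ids)
    if missing:
        raise ValueError(f"gene set members absent from reference: {sorted(missing)[:5]}")
    n_set = len(genes)
    if n_set >= n_total:
        raise ValueError("gene set must be a proper subset of reference genes")

    hit_ranks = reference.ranks_of(genes)
    w = np.abs(reference.z[hit_ranks]) ** weight_exponent
    w_sum = w.sum()
    if w_sum == 0:
        # all-zero weights degenerate to the unweighted statistic
        w = np.ones_like(w)
        w_sum = float(n_set)

    miss_step = 1.0 / (n_total - n_set)
    # running sum evaluated at each hit position: value just after the hit
    # and value just before it (after the preceding misses) both matter.
    cum_hits = np.cumsum(w) / w_sum
    n_misses_before = hit_ranks - np.arange(n_set)  # misses preceding each hit
    at_hit = cum_hits - n_misses_before * miss_step
    before_hit = np.concatenate(([0.0], cum_hits[:-1])) - n_misses_before * miss_step
    max_pos = max(float(at_hit.max()), 0.0)
    min_neg = min(float(before_hit.min()), 0.0)
    # tie convention: when the extreme deviations match in magnitude (within
    # tolerance, since exact ties are common), the positive one wins
    if max_pos >= -min_neg - 1e-9:
        return max_pos
    return min_neg


def wtcs(
    query: QuerySignature,
    reference: RankedReference,
    weight_exponent: float = 1.0,
    min_side_fraction: float = 0.5,
) -> float:
    """Weighted two-sided connectivity score in [-1, 1].

    Query genes absent from the reference are dropped with a warning; if
    fewer than ``min_side_fraction`` of either side survives, the query is
    considered degenerate and an error is raised. The two one-sided ES
    values combine as (ES_up - ES_down)/2 when of opposite sign, else 0.
    """
    up = [g for g in query.up if g in reference]
    down = [g for g in query.down if g in reference]
    n_dropped = (len(query.up) - len(up)) + (len(query.down) - len(down))
    if n_dropped:
        logger.warning(
            "query %s: dropped %d genes absent from reference %s",
            query.query_id,
            n_dropped,
            reference.meta.get("column_id", "?"),
        )
    if not up and not down:
        raise ValueError("both query sides empty after intersecting with reference")
    if len(up) < min_side_fraction * len(query.up) or len(down) < min_side_fraction * len(query.down):
        raise ValueError(
            f"query {query.query_id}: fewer than {min_side_fraction:.0%} of a query side "
            "overlaps the reference"
        )
    es_up = weighted_ks_enrichment(reference, up, weight_exponent)
    es_down = weighted_ks_enrichment(reference, down, weight_exponent)
    if es_up == 0.0 or es_down == 0.0 or np.sign(es_up) != np.sign(es_down):
        return float((es_up - es_down) / 2.0)
    return 0.0


def normalize_scores(
    raw: pd.DataFrame,
    grouping: Mapping[str, tuple],
) -> pd.DataFrame:
    """Normalize a query x reference WTCS matrix to NCS within groups.

    ``grouping`` maps each reference id to its (cell line, perturbation
    type) group. Within each query row and group, positive scores are
    divided by the mean positive magnitude and negative scores by the mean
    negative magnitude; zeros stay zero.
    """
    missing = set(raw.columns) - set(grouping)
    if missing:
        raise ValueError(f"references without a group assignment: {sorted(missing)[:5]}")
    ncs = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    groups: dict[tuple, list[str]] = {}
    for ref in raw.columns:
        groups.setdefault(tuple(grouping[ref]), []).append(ref)
    for refs in groups.values():
        block = raw[refs].to_numpy(dtype=float)
        out = np.zeros_like(block)
        for sign in (1.0, -1.0):
            mask = np.sign(block) == sign
            for i in range(block.shape[0]):
                row_mask = mask[i]
                if not row_mask.any():
                    continue
                denom = np.abs(block[i, row_mask]).mean()
                if denom == 0:
                    raise ValueError("same-sign group mean is zero with nonzero member")
                out[i, row_mask] = block[i, row_mask] / denom
        ncs.loc[:, refs] = out
    return ncs


def tau(ncs_value: float, touchstone_group_ncs: Sequence[float] | np.ndarray) -> float:
    """Signed percentile of |NCS| against the touchstone distribution.

    ``tau = sign(ncs) * 100 * fraction of touchstone |NCS| strictly below
    |ncs|``; lies in [-100, 100].
    """
    ts = np.abs(np.asarray(touchstone_group_ncs, dtype=float))
    if ts.size == 0:
        raise ValueError("empty touchstone group")
    if ncs_value == 0:
        return 0.0
    frac = float(np.mean(ts < abs(ncs_value)))
    return float(np.sign(ncs_value) * 100.0 * frac)


def _nearest_rank_percentile(values: np.ndarray, pct: float) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    rank = int(np.ceil(pct / 100.0 * n))
    rank = min(max(rank, 1), n)
    return float(v[rank - 1])


def summarize_across_cells(per_cell_taus: Sequence[float] | np.ndarray) -> float:
    """Maximal-magnitude quantile summary of per-cell-line Tau values.

    Takes the 33rd and 67th nearest-rank percentiles and returns whichever
    has larger magnitude (ties favour the upper quantile).
    """
    vals = np.asarray(per_cell_taus, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one cell-line value")
    q_lo = _nearest_rank_percentile(vals, 33.0)
    q_hi = _nearest_rank_percentile(vals, 67.0)
    return q_hi if abs(q_hi) >= abs(q_lo) else q_lo


def average_connectivity(taus_over_queries: pd.DataFrame) -> pd.Series:
    """Arithmetic mean Tau per reference across query compounds.

    ``taus_over_queries`` is queries x references; every query must cover
    the full reference set (no missing values).
    """
    if taus_over_queries.isna().any().any():
        bad = taus_over_queries.columns[taus_over_queries.isna().any()].tolist()
        raise ValueError(f"missing tau for reference(s) {bad[:5]} in some query profile")
    return taus_over_queries.mean(axis=0)


# ---------------------------------------------------------------------------
# Collection-level driver
# ---------------------------------------------------------------------------


def dedupe_by_touchstone(matrix: SignatureMatrix, compounds: pd.DataFrame) -> SignatureMatrix:
    """When one compound has several profiles in a cell line, keep the
    touchstone-flagged column (falling back to the lexicographically first)."""
    meta = matrix.column_meta.loc[matrix.column_ids].copy()
    meta["_col"] = matrix.column_ids
    in_ts = {
        cid: bool(compounds.loc[cid, "in_touchstone"]) if cid in compounds.index else False
        for cid in meta["compound_id"]
    }
    meta["_ts"] = [in_ts[c] for c in meta["compound_id"]]
    keep: list[str] = []
    for _, grp in meta.groupby(["compound_id", "cell_line"], sort=False):
        grp = grp.sort_values(["_ts", "_col"], ascending=[False, True])
        keep.append(grp["_col"].iloc[0])
    keep = [c for c in matrix.column_ids if c in set(keep)]
    if len(keep) == matrix.n_columns:
        return matrix
    return matrix.subset_columns(keep)


def connectivity_table(
    matrix: SignatureMatrix,
    queries: Sequence[QuerySignature],
    compounds: pd.DataFrame | None = None,
    gene_scope: str = "landmark",
    weight_exponent: float = 1.0,
    perturbation_type: str = DEFAULT_PERTURBATION_TYPE,
) -> pd.DataFrame:
    """Score every query against every reference column of ``matrix``.

    Returns a long-format frame (query_id, reference_id, cell_line, wtcs,
    ncs, tau). NCS normalization groups references by (cell line,
    perturbation type); Tau is computed against the touchstone members of
    the same group (all members if the compound table is absent or the
    touchstone subset is empty).
    """
    refs = {
        cid: RankedReference.from_signature(
            ExpressionSignature.from_matrix(matrix, cid), gene_scope
        )
        for cid in matrix.column_ids
    }
    raw = pd.DataFrame(
        {
            cid: [wtcs(q, ref, weight_exponent) for q in queries]
            for cid, ref in refs.items()
        },
        index=[q.query_id for q in queries],
    )
    cell_of = {cid: str(matrix.column_meta.loc[cid, "cell_line"]) for cid in matrix.column_ids}
    grouping = {cid: (cell_of[cid], perturbation_type) for cid in matrix.column_ids}
    ncs = normalize_scores(raw, grouping)

    if compounds is not None:
        comp_of = {cid: str(matrix.column_meta.loc[cid, "compound_id"]) for cid in matrix.column_ids}
        is_ts = {
            cid: bool(compounds.loc[comp_of[cid], "in_touchstone"])
            if comp_of[cid] in compounds.index
            else False
            for cid in matrix.column_ids
        }
    else:
        is_ts = {cid: True for cid in matrix.column_ids}

    group_members: dict[tuple, list[str]] = {}
    for cid in matrix.column_ids:
        group_members.setdefault(grouping[cid], []).append(cid)

    rows = []
    for q in queries:
        for cid in matrix.column_ids:
            members = group_members[grouping[cid]]
            ts_members = [m for m in members if is_ts[m]] or members
            ts_ncs = ncs.loc[q.query_id, ts_members].to_numpy(dtype=float)
            t = tau(float(ncs.loc[q.query_id, cid]), ts_ncs)
            rows.append(
                {
                    "query_id": q.query_id,
                    "reference_id": cid,
                    "compound_id": str(matrix.column_meta.loc[cid, "compound_id"]),
                    "cell_line": cell_of[cid],
                    "wtcs": float(raw.loc[q.query_id, cid]),
                    "ncs": float(ncs.loc[q.query_id, cid]),
                    "tau": t,
                }
            )
    return pd.DataFrame(rows)


def average_tau_profile(conn: pd.DataFrame, by: str = "compound_id") -> pd.Series:
    """Collapse a long connectivity table to mean Tau per reference compound.

    Multi-cell-line tables are first summarized per (query, compound)
    across cell lines, then averaged over queries.
    """
    key = by if by in conn.columns else "reference_id"
    per_qr = (
        conn.groupby(["query_id", key])["tau"]
        .apply(lambda v: summarize_across_cells(v.to_numpy()))
        .unstack(key)
    )
    return average_connectivity(per_qr)
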