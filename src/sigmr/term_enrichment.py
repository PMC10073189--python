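"""Hypergeometric over-representation analysis over a term DAG.

Annotations are materialized up the DAG (a gene annotated to a term counts
for every ancestor), p-values are one-sided upper-tail hypergeometric, and
significant terms can be rolled up to ancestors at a chosen depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import TermGraph


@dataclass(frozen=True)
class TermEnrichmentResult:
    term_id: str
    k: int
    n_set: int
    K_term: int
    N: int
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False

    def __post_init__(self) -> None:
        if self.k > min(self.n_set, self.K_term):
            raise ValueError("overlap exceeds set or annotation size")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError(f"p_raw out of (0, 1]: {self.p_raw}")


def hypergeom_pvalue(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrichment(
    gene_set: Iterable[str],
    background: Iterable[str],
    term_graph: TermGraph,
) -> list[TermEnrichmentResult]:
    """One-sided over-representation of ``gene_set`` terms vs ``background``.

    Annotations are restricted to the background and materialized through
    the DAG; terms with no annotated background genes are skipped.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    gs = set(gene_set)
    if not gs <= bg:
        raise ValueError("gene set must be a subset of the background")
    term_genes = term_graph.term_to_genes(background=bg)
    N = len(bg)
    n = len(gs)
    results = []
    for term in sorted(term_genes):
        annotated = term_genes[term]
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & gs)
        p = hypergeom_pvalue(k, N, K, n)
        results.append(TermEnrichmentResult(term_id=term, k=k, n_set=n, K_term=K, N=N, p_raw=p))
    return results


def correct_pvalues(
    p_list: Sequence[float],
    method: Literal["bonferroni", "bh"] = "bonferroni",
) -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "bh":
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / (np.arange(m) + 1)
        adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(adj_sorted, 1.0)
        return adj
    raise ValueError(f"unknown correction method {method!r}")


def annotate_results(
    results: list[TermEnrichmentResult],
    method: Literal["bonferroni", "bh"] = "bonferroni",
    alpha: float = 0.05,
) -> list[TermEnrichmentResult]:
    """Attach adjusted p-values and significance flags."""
    if not results:
        return []
    adj = correct_pvalues([r.p_raw for r in results], method)
    return [
        TermEnrichmentResult(
            term_id=r.term_id,
            k=r.k,
            n_set=r.n_set,
            K_term=r.K_term,
            N=r.N,
            p_raw=r.p_raw,
            p_adj=float(a),
            significant=bool(a < alpha),
        )
        for r, a in zip(results, adj)
    ]


def results_frame(results: list[TermEnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "k", "n_set", "K_term", "N", "p_raw", "p_adj", "significant"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)


def _ancestors_at_level(term: str, tg: TermGraph, level: int) -> set[str]:
    """Ancestors of ``term`` (or itself) sitting exactly at ``level`` from roots."""
    if tg.depth(term) <= level:
        return {term}
    out = set()
    for anc in tg.ancestors(term):
        if tg.depth(anc) == level:
            # only keep ancestors on a path from term upward (any ancestor is)
            out.add(anc)
    return out or {term}


def rollup_ancestors(
    significant_terms: Iterable[str],
    term_graph: TermGraph,
    ancestor_level: int = 1,
) -> pd.DataFrame:
    """Group significant terms under their ancestor(s) at a depth level.

    Terms shallower than the level map to themselves; a term reachable from
    several ancestors at the level appears once per ancestor. Returns one
    row per (ancestor, term).
    """
    rows = []
    for term in significant_terms:
        if term not in term_graph.graph:
            raise KeyError(f"term absent from graph: {term}")
        for anc in sorted(_ancestors_at_level(term, term_graph, ancestor_level)):
            rows.append(
                {
                    "ancestor": anc,
                    "ancestor_name": term_graph.term_names.get(anc, ""),
                    "term": term,
                    "term_name": term_graph.term_names.get(term, ""),
                }
            )
    return pd.DataFrame(rows, columns=["ancestor", "ancestor_name", "term", "term_name"])
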