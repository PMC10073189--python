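"""Readers/writers for the on-disk formats the pipeline touches.

Formats handled (all plain text):

* GCT 1.3 signature matrices (z-scores, with a per-row landmark flag column);
* COJO ``.ma``-style whitespace-delimited summary statistics
  (``SNP A1 A2 freq b se p N``);
* TSV compound tables, LD matrices, dosage matrices;
* TSV term-graph edge lists and gene->term annotations.

Binary formats (GCTX/HDF5, BESD, PLINK bed) are out of scope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GCT_VERSION = "#1.3"
DEFAULT_LANDMARK_COLUMN = "pr_is_lm"

#: required columns of the .ma summary-statistics dialect, in order
MA_COLUMNS = ("SNP", "A1", "A2", "freq", "b", "se", "p", "n")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Signature matrices
# ---------------------------------------------------------------------------


@dataclass
class SignatureMatrix:
    """Per-gene z-scores for a collection of perturbations (genes x columns).

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    gene_is_landmark
        Boolean flag per gene; landmark genes are directly measured.
    column_ids
        Ordered, unique perturbation identifiers (columns).
    column_meta
        Per-column metadata frame indexed by ``column_ids`` with at least
        the columns ``compound_id``, ``compound_name``, ``cell_line``,
        ``dose``, ``time``.
    values
        Numeric matrix of shape ``(n_genes, n_columns)``; finite.
    """

    gene_ids: list[str]
    gene_is_landmark: np.ndarray
    column_ids: list[str]
    column_meta: pd.DataFrame
    values: np.ndarray

    META_FIELDS = ("compound_id", "compound_name", "cell_line", "dose", "time")

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        self.gene_is_landmark = np.asarray(self.gene_is_landmark, dtype=bool)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in signature matrix")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValueError("duplicate column_ids in signature matrix")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature matrix contains non-finite values")
        if self.gene_is_landmark.shape != (len(self.gene_ids),):
            raise ValueError("gene_is_landmark length does not match gene_ids")
        if not self.gene_is_landmark.any():
            raise ValueError("signature matrix has no landmark genes")
        missing = set(self.column_ids) - set(map(str, self.column_meta.index))
        if missing:
            raise ValueError(f"column_meta missing entries for columns: {sorted(missing)}")
        for fld in self.META_FIELDS:
            if fld not in self.column_meta.columns:
                raise ValueError(f"column_meta lacks required field {fld!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    @property
    def landmark_gene_ids(self) -> list[str]:
        return [g for g, lm in zip(self.gene_ids, self.gene_is_landmark) if lm]

    def column_values(self, column_id: str) -> np.ndarray:
        return self.values[:, self.column_ids.index(column_id)]

    def subset_columns(self, column_ids: Sequence[str]) -> "SignatureMatrix":
        idx = [self.column_ids.index(c) for c in column_ids]
        return SignatureMatrix(
            gene_ids=list(self.gene_ids),
            gene_is_landmark=self.gene_is_landmark.copy(),
            column_ids=list(column_ids),
            column_meta=self.column_meta.loc[list(column_ids)].copy(),
            values=self.values[:, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignatureMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.column_ids == other.column_ids
            and np.array_equal(self.gene_is_landmark, other.gene_is_landmark)
            and np.array_equal(self.values, other.values)
            and self.column_meta.loc[self.column_ids, list(self.META_FIELDS)]
            .astype(str)
            .equals(other.column_meta.loc[other.column_ids, list(self.META_FIELDS)].astype(str))
        )


def read_gct(path, landmark_column: str = DEFAULT_LANDMARK_COLUMN) -> SignatureMatrix:
    """Parse a GCT 1.3 text file into a :class:`SignatureMatrix`.

    The landmark flag is read from the row-metadata column named
    ``landmark_column``; if that column is absent every gene is flagged
    landmark and a warning is emitted.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != GCT_VERSION:
        raise ParseError(f"{path}: line 1: expected GCT version tag {GCT_VERSION!r}")
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated file (no dimension line or header)")
    dims = lines[1].split("\t")
    if len(dims) != 4:
        raise ParseError(f"{path}: line 2: dimension line must have 4 fields, got {len(dims)}")
    try:
        n_rows, n_cols, n_rmeta, n_cmeta = (int(d) for d in dims)
    except ValueError as exc:
        raise ParseError(f"{path}: line 2: non-integer dimension: {exc}") from exc

    header = lines[2].split("\t")
    expected_header_len = 1 + n_rmeta + n_cols
    if len(header) != expected_header_len:
        raise ParseError(
            f"{path}: line 3: header has {len(header)} fields, expected {expected_header_len}"
        )
    rmeta_names = header[1 : 1 + n_rmeta]
    column_ids = header[1 + n_rmeta :]
    if len(set(column_ids)) != n_cols:
        raise ParseError(f"{path}: line 3: duplicate column ids")

    # column-metadata rows follow the header, one per metadata field
    cmeta: dict[str, list[str]] = {}
    for i in range(n_cmeta):
        lineno = 4 + i
        if lineno - 1 >= len(lines):
            raise ParseError(f"{path}: line {lineno}: missing column-metadata row")
        parts = lines[lineno - 1].split("\t")
        if len(parts) != expected_header_len:
            raise ParseError(
                f"{path}: line {lineno}: column-metadata row has {len(parts)} fields, "
                f"expected {expected_header_len}"
            )
        cmeta[parts[0]] = parts[1 + n_rmeta :]

    body = lines[3 + n_cmeta :]
    body = [ln for ln in body if ln.strip()]
    if len(body) != n_rows:
        raise ParseError(
            f"{path}: body has {len(body)} data rows but dimension line promises {n_rows}"
        )

    gene_ids: list[str] = []
    rmeta_values: dict[str, list[str]] = {name: [] for name in rmeta_names}
    values = np.empty((n_rows, n_cols), dtype=float)
    for r, line in enumerate(body):
        lineno = 4 + n_cmeta + r
        parts = line.split("\t")
        if len(parts) != expected_header_len:
            raise ParseError(
                f"{path}: line {lineno}: row has {len(parts)} fields, "
                f"expected {expected_header_len}"
            )
        gene_ids.append(parts[0])
        for j, name in enumerate(rmeta_names):
            rmeta_values[name].append(parts[1 + j])
        try:
            values[r] = [float(v) for v in parts[1 + n_rmeta :]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric value: {exc}") from exc

    if len(set(gene_ids)) != n_rows:
        raise ParseError(f"{path}: duplicate gene ids in body")

    if landmark_column in rmeta_values:
        is_lm = np.array([v.strip() in ("1", "1.0", "true", "True") for v in rmeta_values[landmark_column]])
    else:
        warnings.warn(
            f"{path}: landmark column {landmark_column!r} absent; treating all genes as landmark",
            stacklevel=2,
        )
        is_lm = np.ones(n_rows, dtype=bool)

    meta_df = pd.DataFrame(index=pd.Index(column_ids, name="column_id"))
    for fld in SignatureMatrix.META_FIELDS:
        meta_df[fld] = cmeta.get(fld, [""] * n_cols)

    return SignatureMatrix(
        gene_ids=gene_ids,
        gene_is_landmark=is_lm,
        column_ids=column_ids,
        column_meta=meta_df,
        values=values,
    )


def write_gct(
    matrix: SignatureMatrix,
    path,
    landmark_column: str = DEFAULT_LANDMARK_COLUMN,
    float_format: str = "%.17g",
) -> None:
    """Write a :class:`SignatureMatrix` as GCT 1.3 text.

    ``%.17g`` guarantees float64 round-trips bit-exactly through decimal.
    """
    matrix.validate()
    meta_fields = [f for f in SignatureMatrix.META_FIELDS if f in matrix.column_meta.columns]
    with open(path, "w") as fh:
        fh.write(GCT_VERSION + "\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_columns}\t1\t{len(meta_fields)}\n")
        fh.write("\t".join(["id", landmark_column] + matrix.column_ids) + "\n")
        for fld in meta_fields:
            vals = [str(matrix.column_meta.loc[c, fld]) for c in matrix.column_ids]
            fh.write("\t".join([fld, "-"] + vals) + "\n")
        for r, gene in enumerate(matrix.gene_ids):
            row = [gene, "1" if matrix.gene_is_landmark[r] else "0"]
            row += [float_format % v for v in matrix.values[r]]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Compound tables
# ---------------------------------------------------------------------------

COMPOUND_CLASS_VOCABULARY = frozenset(
    {"statin", "antidepressant", "control", "other"}
)


def read_compound_table(path, class_vocabulary: Iterable[str] = COMPOUND_CLASS_VOCABULARY) -> pd.DataFrame:
    """Read a TSV compound table (compound_id, name, atc_code, class_label, in_touchstone)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"compound_id", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: compound table missing columns {sorted(missing)}")
    if df["compound_id"].duplicated().any():
        dupes = df.loc[df["compound_id"].duplicated(), "compound_id"].tolist()
        raise ParseError(f"{path}: duplicate compound_id values: {dupes}")
    if "atc_code" not in df.columns:
        df["atc_code"] = ""
    if "class_label" not in df.columns:
        df["class_label"] = ""
    vocab = set(class_vocabulary) | {""}
    bad = sorted(set(df["class_label"]) - vocab)
    if bad:
        raise ParseError(f"{path}: class labels outside declared vocabulary: {bad}")
    if "in_touchstone" in df.columns:
        df["in_touchstone"] = df["in_touchstone"].map(
            lambda v: str(v).strip().lower() in ("1", "true", "yes")
        )
    else:
        df["in_touchstone"] = True
    return df.set_index("compound_id", drop=False)


def write_compound_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["in_touchstone"] = out["in_touchstone"].map(lambda b: "1" if b else "0")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------


@dataclass
class SumStatsTable:
    """Typed per-variant association records for one study (.ma dialect).

    ``records`` is a DataFrame with columns ``variant_id, effect_allele,
    other_allele, eaf, beta, se, p, n`` indexed by ``variant_id``.
    """

    records: pd.DataFrame
    n_rejected: int = 0

    def __post_init__(self) -> None:
        req = {"variant_id", "effect_allele", "other_allele", "eaf", "beta", "se", "p", "n"}
        missing = req - set(self.records.columns)
        if missing:
            raise ValueError(f"SumStatsTable missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, variant_id: str) -> pd.Series:
        return self.records.loc[variant_id]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records.index


def _validate_sumstat_rows(df: pd.DataFrame, origin: str, z_p_rtol: float = 0.05) -> tuple[pd.DataFrame, int]:
    """Drop rows violating record invariants; return (valid rows, n dropped)."""
    from scipy import stats

    a1 = df["effect_allele"].astype(str).str.upper()
    a2 = df["other_allele"].astype(str).str.upper()
    ok = (
        (a1 != a2)
        & a1.str.fullmatch(r"[ACGT]+")
        & a2.str.fullmatch(r"[ACGT]+")
        & (df["se"] > 0)
        & (df["p"] > 0)
        & (df["p"] <= 1)
        & df["eaf"].between(0.0, 1.0)
        & np.isfinite(df["beta"])
        & (df["n"] > 0)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d rows violating summary-stat invariants", origin, n_bad)
    valid = df.loc[ok].copy()
    valid["effect_allele"] = a1.loc[ok]
    valid["other_allele"] = a2.loc[ok]
    # soft consistency check: p vs two-sided normal tail of beta/se
    with np.errstate(divide="ignore"):
        p_implied = 2.0 * stats.norm.sf(np.abs(valid["beta"] / valid["se"]))
    inconsistent = ~np.isclose(
        np.log(np.maximum(valid["p"], 1e-300)),
        np.log(np.maximum(p_implied, 1e-300)),
        rtol=z_p_rtol,
        atol=0.5,
    )
    valid["p_consistent"] = ~inconsistent
    if inconsistent.any():
        logger.warning(
            "%s: %d rows have p inconsistent with beta/se (flagged, kept)",
            origin,
            int(inconsistent.sum()),
        )
    return valid, n_bad


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> SumStatsTable:
    """Read COJO ``.ma``-style summary statistics.

    Default columns are ``SNP A1 A2 freq b se p N`` (case-insensitive for N/n);
    ``column_map`` maps internal names (``variant_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``p``, ``n``) to file column
    names for other dialects.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    default_map = {
        "variant_id": "SNP",
        "effect_allele": "A1",
        "other_allele": "A2",
        "eaf": "freq",
        "beta": "b",
        "se": "se",
        "p": "p",
        "n": "N",
    }
    cmap = dict(default_map)
    if column_map:
        cmap.update(column_map)
    # tolerate lowercase n
    if cmap["n"] not in df.columns and cmap["n"].lower() in df.columns:
        cmap["n"] = cmap["n"].lower()
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out = pd.DataFrame({k: df[v] for k, v in cmap.items()})
    for col in ("eaf", "beta", "se", "p"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    out["n"] = pd.to_numeric(out["n"], errors="coerce")
    out = out.dropna(subset=["eaf", "beta", "se", "p", "n"])
    valid, n_bad = _validate_sumstat_rows(out, str(path))
    if valid.empty:
        raise ParseError(f"{path}: no valid summary-statistic rows")
    if valid["variant_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate variant ids")
    return SumStatsTable(records=valid.set_index("variant_id", drop=False), n_rejected=n_bad)


def write_sumstats(table: SumStatsTable, path) -> None:
    df = table.records
    out = pd.DataFrame(
        {
            "SNP": df["variant_id"],
            "A1": df["effect_allele"],
            "A2": df["other_allele"],
            "freq": df["eaf"],
            "b": df["beta"],
            "se": df["se"],
            "p": df["p"],
            "N": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def sumstats_from_arrays(
    variant_ids: Sequence[str],
    effect_alleles: Sequence[str],
    other_alleles: Sequence[str],
    eaf: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    p: np.ndarray,
    n: np.ndarray | int,
) -> SumStatsTable:
    """Assemble a validated table directly from arrays (simulation output)."""
    n_arr = np.full(len(variant_ids), n) if np.isscalar(n) else np.asarray(n)
    df = pd.DataFrame(
        {
            "variant_id": [str(v) for v in variant_ids],
            "effect_allele": [str(a) for a in effect_alleles],
            "other_allele": [str(a) for a in other_alleles],
            "eaf": np.asarray(eaf, dtype=float),
            "beta": np.asarray(beta, dtype=float),
            "se": np.asarray(se, dtype=float),
            "p": np.asarray(p, dtype=float),
            "n": n_arr,
        }
    )
    valid, n_bad = _validate_sumstat_rows(df, "<arrays>")
    if valid.empty:
        raise ValueError("no valid summary-statistic rows")
    return SumStatsTable(records=valid.set_index("variant_id", drop=False), n_rejected=n_bad)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


@dataclass
class LdSource:
    """Signed LD correlation matrix aligned to ``variant_ids``."""

    variant_ids: list[str]
    ld_matrix: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.ld_matrix = np.asarray(self.ld_matrix, dtype=float)
        m = self.ld_matrix
        k = len(self.variant_ids)
        if m.shape != (k, k):
            raise ValueError(f"LD matrix shape {m.shape} does not match {k} variants")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("LD matrix not symmetric within 1e-8")
        if not np.allclose(np.diag(m), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal must be 1")
        if np.any(np.abs(m) > 1 + 1e-8):
            raise ValueError("LD entries must lie in [-1, 1]")

    def r(self, a: str, b: str) -> float:
        i, j = self.variant_ids.index(a), self.variant_ids.index(b)
        return float(self.ld_matrix[i, j])

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.variant_ids.index(v) for v in ids]
        return self.ld_matrix[np.ix_(idx, idx)]


def ld_from_dosages(dosages: np.ndarray, variant_ids: Sequence[str] | None = None) -> LdSource:
    """Pearson correlation of dosage rows (variants x samples) -> signed LD.

    Raises on monomorphic variants (zero variance), naming them.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] < 2:
        raise ValueError("dosage matrix must be variants x samples with >= 2 samples")
    ids = [str(v) for v in (variant_ids if variant_ids is not None else range(d.shape[0]))]
    var = d.var(axis=1)
    mono = [ids[i] for i in np.flatnonzero(var <= 0)]
    if mono:
        raise ValueError(f"monomorphic variant(s): {mono}")
    r = np.atleast_2d(np.corrcoef(d))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LdSource(variant_ids=ids, ld_matrix=r)


def read_ld_matrix(path) -> LdSource:
    """Read a TSV square LD matrix with variant ids as header and first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ParseError(f"{path}: LD matrix row and column ids differ")
    return LdSource(variant_ids=list(df.columns.astype(str)), ld_matrix=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdSource, path) -> None:
    pd.DataFrame(ld.ld_matrix, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def read_dosages(path) -> tuple[list[str], np.ndarray]:
    """Read a TSV dosage matrix (variants x samples, first column = variant id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    d = df.to_numpy(dtype=float)
    if np.any((d < 0) | (d > 2)):
        raise ParseError(f"{path}: dosages must lie in [0, 2]")
    return list(df.index.astype(str)), d


# ---------------------------------------------------------------------------
# Term graphs
# ---------------------------------------------------------------------------


@dataclass
class TermGraph:
    """Term DAG (child -> parent edges) with gene annotations.

    ``graph`` stores one directed edge child -> parent per relation; roots
    have out-degree 0. ``annotations`` maps gene -> set of directly annotated
    terms (ancestor closure is computed on demand).
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("term graph contains a cycle")
        for gene, terms in self.annotations.items():
            for t in terms:
                if t not in self.graph:
                    self.graph.add_node(t)

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All ancestors (transitive parents), excluding the term itself."""
        return set(nx.descendants(self.graph, term))

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def depth(self, term: str) -> int:
        """Shortest distance (in parent hops) from the term up to any root."""
        if term not in self.graph:
            raise KeyError(term)
        if self.graph.out_degree(term) == 0:
            return 0
        return 1 + min(self.depth(p) for p in self.parents(term))

    def materialized_annotations(self) -> dict[str, set[str]]:
        """Gene -> direct terms plus all their ancestors."""
        out: dict[str, set[str]] = {}
        anc_cache: dict[str, set[str]] = {}
        for gene, terms in self.annotations.items():
            full = set(terms)
            for t in terms:
                if t not in anc_cache:
                    anc_cache[t] = self.ancestors(t)
                full |= anc_cache[t]
            out[gene] = full
        return out

    def term_to_genes(self, background: Iterable[str] | None = None) -> dict[str, set[str]]:
        """Term -> set of genes annotated to it or any descendant."""
        bg = set(background) if background is not None else None
        out: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        for gene, terms in self.materialized_annotations().items():
            if bg is not None and gene not in bg:
                continue
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


def read_term_graph(edges_path, annotations_path, names_path=None) -> TermGraph:
    """Read a term graph from TSV edge list (child, parent) and annotation TSV (gene, term)."""
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    if not {"child", "parent"} <= set(edges.columns):
        raise ParseError(f"{edges_path}: edge list must have columns child, parent")
    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_edge(row["child"], row["parent"])
    ann_df = pd.read_csv(annotations_path, sep="\t", dtype=str)
    if not {"gene", "term"} <= set(ann_df.columns):
        raise ParseError(f"{annotations_path}: annotations must have columns gene, term")
    annotations: dict[str, set[str]] = {}
    for _, row in ann_df.iterrows():
        annotations.setdefault(row["gene"], set()).add(row["term"])
    names: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", dtype=str)
        names = dict(zip(nd["term"], nd["name"]))
    return TermGraph(graph=g, annotations=annotations, term_names=names)


def write_term_graph(tg: TermGraph, edges_path, annotations_path) -> None:
    rows = [{"child": c, "parent": p} for c, p in sorted(tg.graph.edges)]
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(edges_path, sep="\t", index=False)
    arows = [
        {"gene": g, "term": t}
        for g in sorted(tg.annotations)
        for t in sorted(tg.annotations[g])
    ]
    pd.DataFrame(arows, columns=["gene", "term"]).to_csv(annotations_path, sep="\t", index=False)
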