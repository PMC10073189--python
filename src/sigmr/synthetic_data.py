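"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_signatures` — z-score signature collections with planted
  compound classes that share latent perturbation directions plus noise;
* :func:`simulate_term_graph` — random term DAGs with gene annotations;
* :func:`simulate_cohort` — two non-overlapping cohorts' worth of marginal
  association statistics (eQTL and GWAS) generated from simulated genotypes
  under causal, null, or linkage scenarios, plus an LD reference.

Genotypes follow a latent-Gaussian AR(1) model thresholded to
Hardy-Weinberg dosages, which gives tunable LD without haplotype machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import LdSource, SignatureMatrix, SumStatsTable, ld_from_dosages, sumstats_from_arrays
from .io import TermGraph

ATC_BY_CLASS = {"statin": "C10AA", "antidepressant": "N06A"}


# ---------------------------------------------------------------------------
# Signature collections
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassSpec:
    """One planted compound class."""

    label: str
    n_compounds: int
    latent_strength: float
    share_latent_with: str | None = None  # reuse another class's latent direction

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError(f"class {self.label!r} must have >= 1 compound")
        if self.latent_strength < 0:
            raise ValueError("latent_strength must be >= 0")


@dataclass
class SignatureSimParams:
    n_genes: int
    n_landmark: int
    classes: Sequence[ClassSpec]
    noise_sd: float = 1.0
    cell_lines: Sequence[str] = ("HA1E",)
    cell_line_corr: float = 1.0  # correlation of class latents across cell lines
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_landmark > self.n_genes:
            raise ValueError("n_landmark must be <= n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0.0 <= self.cell_line_corr <= 1.0:
            raise ValueError("cell_line_corr must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth emitted alongside every simulated dataset."""

    kind: str
    seed: int
    true_b_xy: float | None = None
    causal_variant_ids: list[str] = field(default_factory=list)
    scenario: str | None = None
    class_latents: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "kind": self.kind,
            "seed": self.seed,
            "true_b_xy": self.true_b_xy,
            "causal_variant_ids": self.causal_variant_ids,
            "scenario": self.scenario,
            "class_latents": {
                k: np.asarray(v).tolist() for k, v in self.class_latents.items()
            },
            "extra": self.extra,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def simulate_signatures(
    params: SignatureSimParams,
) -> tuple[SignatureMatrix, pd.DataFrame, TruthRecord]:
    """Planted-class signature collection.

    Each compound's signature is ``latent_strength x class latent + noise``
    per gene, standardized per column to a z-like scale. Class latents are
    redrawn per cell line with correlation ``cell_line_corr`` to a base
    latent; classes may share a latent direction via ``share_latent_with``.
    """
    rng = np.random.default_rng(params.seed)
    n_g = params.n_genes
    labels = [c.label for c in params.classes]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate class labels")
    by_label = {c.label: c for c in params.classes}
    for c in params.classes:
        if c.share_latent_with is not None and c.share_latent_with not in by_label:
            raise ValueError(f"unknown share_latent_with target {c.share_latent_with!r}")

    # base latents; shared classes point at their donor's latent
    base_latents: dict[str, np.ndarray] = {}
    for c in params.classes:
        if c.share_latent_with is None:
            base_latents[c.label] = rng.standard_normal(n_g)
    for c in params.classes:
        if c.share_latent_with is not None:
            base_latents[c.label] = base_latents[c.share_latent_with]

    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    is_lm = np.zeros(n_g, dtype=bool)
    is_lm[: params.n_landmark] = True

    col_ids: list[str] = []
    meta_rows: list[dict] = []
    cols: list[np.ndarray] = []
    cell_latents: dict[str, np.ndarray] = {}
    rho = params.cell_line_corr
    for cell in params.cell_lines:
        for c in params.classes:
            base = base_latents[c.label]
            latent = rho * base + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n_g)
            cell_latents[f"{c.label}:{cell}"] = latent
            for i in range(c.n_compounds):
                comp_id = f"{c.label}_{i:03d}"
                sig = c.latent_strength * latent + params.noise_sd * rng.standard_normal(n_g)
                sd = sig.std()
                if sd > 0:
                    sig = (sig - sig.mean()) / sd
                col_ids.append(f"{comp_id}:{cell}")
                meta_rows.append(
                    {
                        "compound_id": comp_id,
                        "compound_name": comp_id,
                        "cell_line": cell,
                        "dose": "10 uM",
                        "time": "24 h",
                    }
                )
                cols.append(sig)

    matrix = SignatureMatrix(
        gene_ids=gene_ids,
        gene_is_landmark=is_lm,
        column_ids=col_ids,
        column_meta=pd.DataFrame(meta_rows, index=pd.Index(col_ids, name="column_id")),
        values=np.column_stack(cols),
    )
    comp_rows = []
    for c in params.classes:
        for i in range(c.n_compounds):
            comp_id = f"{c.label}_{i:03d}"
            comp_rows.append(
                {
                    "compound_id": comp_id,
                    "name": comp_id,
                    "atc_code": ATC_BY_CLASS.get(c.label, ""),
                    "class_label": c.label,
                    "in_touchstone": True,
                }
            )
    compounds = pd.DataFrame(comp_rows).set_index("compound_id", drop=False)
    truth = TruthRecord(
        kind="signatures",
        seed=params.seed,
        class_latents=cell_latents,
        extra={
            "classes": {
                c.label: {
                    "n_compounds": c.n_compounds,
                    "latent_strength": c.latent_strength,
                    "share_latent_with": c.share_latent_with,
                }
                for c in params.classes
            },
            "noise_sd": params.noise_sd,
        },
    )
    return matrix, compounds, truth


# ---------------------------------------------------------------------------
# Term graphs
# ---------------------------------------------------------------------------


def simulate_term_graph(
    n_terms: int,
    n_genes: int,
    depth: int,
    seed: int = 0,
    max_direct_terms_per_gene: int = 3,
) -> TermGraph:
    """Random layered DAG: every non-root term gets 1-2 parents from
    shallower levels; genes are annotated to random terms (ancestors are
    materialized on demand by :class:`~sigmr.io.TermGraph`)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if n_terms < depth + 1:
        raise ValueError("need at least depth+1 terms")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    # geometric-ish growth of level sizes
    weights = np.array([2.0**lvl for lvl in range(depth + 1)])
    sizes = np.maximum(1, np.floor(n_terms * weights / weights.sum()).astype(int))
    while sizes.sum() > n_terms:
        sizes[np.argmax(sizes)] -= 1
    sizes[-1] += n_terms - sizes.sum()
    levels: list[list[str]] = []
    pos = 0
    for s in sizes:
        levels.append(terms[pos : pos + s])
        pos += s

    g = nx.DiGraph()
    g.add_nodes_from(terms)
    shallower: list[str] = list(levels[0])
    for lvl in range(1, depth + 1):
        for term in levels[lvl]:
            n_par = int(rng.integers(1, 3))
            parents = rng.choice(shallower, size=min(n_par, len(shallower)), replace=False)
            for p in parents:
                g.add_edge(term, p)  # child -> parent
        shallower.extend(levels[lvl])

    genes = [f"G{i:05d}" for i in range(n_genes)]
    annotations: dict[str, set[str]] = {}
    for gene in genes:
        k = int(rng.integers(1, max_direct_terms_per_gene + 1))
        annotations[gene] = set(rng.choice(terms, size=k, replace=False))
    names = {t: f"term {t}" for t in terms}
    return TermGraph(graph=g, annotations=annotations, term_names=names)


# ---------------------------------------------------------------------------
# Cohort summary statistics
# ---------------------------------------------------------------------------

SCENARIOS = ("causal", "null", "linkage")


@dataclass
class CohortSimParams:
    n_individuals: int = 10_000
    n_variants: int = 20
    maf: float = 0.3
    ld_decay_rho: float = 0.8
    b_zx: float = 0.3
    b_xy: float = 0.2
    scenario: str = "causal"
    linkage_r2: float = 0.6
    seed: int = 0
    causal_index: int = 0
    b_zy_linkage: float | None = None  # per-allele effect of the 2nd variant on y
    ld_ref_n: int = 4_000

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0.0 <= self.ld_decay_rho < 1.0:
            raise ValueError("ld_decay_rho must lie in [0, 1)")
        if self.scenario == "linkage" and self.n_variants < 2:
            raise ValueError("linkage scenario needs >= 2 variants")
        if not 0.0 <= self.linkage_r2 < 1.0:
            raise ValueError("linkage_r2 must lie in [0, 1)")


def _hwe_thresholds(maf: float) -> tuple[float, float]:
    q = 1.0 - maf
    return stats.norm.ppf(q * q), stats.norm.ppf(1.0 - maf * maf)


@lru_cache(maxsize=256)
def _dosage_corr_from_latent(latent_r: float, maf: float) -> float:
    """Exact dosage correlation of two HWE-thresholded latent normals."""
    t1, t2 = _hwe_thresholds(maf)
    cuts = [-np.inf, t1, t2, np.inf]
    cov = np.array([[1.0, latent_r], [latent_r, 1.0]])
    mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True)

    def rect(a1, b1, a2, b2):
        def cdf(x, y):
            if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
                return 0.0
            xx = 10.0 if np.isinf(x) else x
            yy = 10.0 if np.isinf(y) else y
            return float(mvn.cdf([xx, yy]))

        return cdf(b1, b2) - cdf(a1, b2) - cdf(b1, a2) + cdf(a1, a2)

    e_g = 2.0 * maf
    var_g = 2.0 * maf * (1.0 - maf)
    e_g1g2 = 0.0
    for i in range(3):
        for j in range(3):
            if i == 0 or j == 0:
                continue
            p = rect(cuts[i], cuts[i + 1], cuts[j], cuts[j + 1])
            e_g1g2 += i * j * p
    return (e_g1g2 - e_g**2) / var_g


def latent_corr_for_dosage_r(target_r: float, maf: float) -> float:
    """Invert the latent->dosage correlation map (monotone in latent r)."""
    if target_r == 0.0:
        return 0.0
    f = lambda a: _dosage_corr_from_latent(a, maf) - target_r
    return float(optimize.brentq(f, -0.999, 0.999, xtol=1e-4))


def _simulate_dosages(
    rng: np.random.Generator,
    n: int,
    params: CohortSimParams,
    pair_latent_r: float | None,
) -> np.ndarray:
    """n x m dosage matrix under sequential latent AR(1) + HWE thresholding.

    ``pair_latent_r`` overrides the latent correlation between the causal
    variant and the next one (linkage scenario).
    """
    m = params.n_variants
    rho = params.ld_decay_rho
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    for k in range(1, m):
        r = rho
        if pair_latent_r is not None and k == params.causal_index + 1:
            r = pair_latent_r
        z[:, k] = r * z[:, k - 1] + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    t1, t2 = _hwe_thresholds(params.maf)
    return (z > t1).astype(float) + (z > t2)


def _marginal_regression(g: np.ndarray, pheno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant OLS slope, se and two-sided normal p (vectorized)."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    pc = pheno - pheno.mean()
    var_g = (gc**2).sum(axis=0)
    if np.any(var_g == 0):
        raise ValueError("monomorphic variant in cohort")
    beta = gc.T @ pc / var_g
    resid_var = ((pc**2).sum() - beta**2 * var_g) / (n - 2)
    se = np.sqrt(resid_var / var_g)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, 1e-300, 1.0)


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[SumStatsTable, SumStatsTable, LdSource, TruthRecord]:
    """Two-sample summary statistics with known causal structure.

    The eQTL cohort measures expression ``x = b_zx * g_causal + e`` (unit
    variance); the independent GWAS cohort measures a trait that is
    ``b_xy * x + e`` (causal), pure noise (null), or driven by a second
    variant in LD with the causal one (linkage). A third independent sample
    provides the LD reference.
    """
    rng = np.random.default_rng(params.seed)
    var_g = 2.0 * params.maf * (1.0 - params.maf)
    if params.b_zx**2 * var_g >= 1.0:
        raise ValueError("b_zx too large for unit-variance expression")

    pair_latent_r = None
    second_idx = None
    if params.scenario == "linkage":
        second_idx = params.causal_index + 1
        if second_idx >= params.n_variants:
            raise ValueError("causal_index+1 out of range for linkage scenario")
        target_r = float(np.sqrt(params.linkage_r2))
        pair_latent_r = latent_corr_for_dosage_r(target_r, params.maf)

    variant_ids = [f"rs{i + 1:05d}" for i in range(params.n_variants)]
    ci = params.causal_index

    # eQTL cohort
    g_e = _simulate_dosages(rng, params.n_individuals, params, pair_latent_r)
    e_sd = np.sqrt(1.0 - params.b_zx**2 * var_g)
    x = params.b_zx * g_e[:, ci] + e_sd * rng.standard_normal(params.n_individuals)
    b_e, se_e, p_e = _marginal_regression(g_e, x)

    # GWAS cohort (independent sample)
    g_y = _simulate_dosages(rng, params.n_individuals, params, pair_latent_r)
    if params.scenario == "causal":
        x_y = params.b_zx * g_y[:, ci] + e_sd * rng.standard_normal(params.n_individuals)
        y = params.b_xy * x_y + np.sqrt(1.0 - params.b_xy**2) * rng.standard_normal(
            params.n_individuals
        )
        true_b_xy = params.b_xy
        causal_ids = [variant_ids[ci]]
    elif params.scenario == "null":
        y = rng.standard_normal(params.n_individuals)
        true_b_xy = 0.0
        causal_ids = [variant_ids[ci]]
    else:  # linkage
        b_lin = (
            params.b_zy_linkage
            if params.b_zy_linkage is not None
            else params.b_zx * params.b_xy
        )
        if b_lin**2 * var_g >= 1.0:
            raise ValueError("linkage effect too large for unit-variance trait")
        y = b_lin * g_y[:, second_idx] + np.sqrt(1.0 - b_lin**2 * var_g) * rng.standard_normal(
            params.n_individuals
        )
        true_b_xy = 0.0
        causal_ids = [variant_ids[ci], variant_ids[second_idx]]
    b_g, se_g, p_g = _marginal_regression(g_y, y)

    # LD reference cohort (independent); redraw on monomorphism
    ld = None
    for _ in range(10):
        g_ld = _simulate_dosages(rng, params.ld_ref_n, params, pair_latent_r)
        if np.all(g_ld.var(axis=0) > 0):
            ld = ld_from_dosages(g_ld.T, variant_ids)
            break
    if ld is None:
        raise RuntimeError("could not draw a polymorphic LD reference sample")

    alleles_eff = ["A"] * params.n_variants
    alleles_oth = ["G"] * params.n_variants
    eqtl = sumstats_from_arrays(
        variant_ids, alleles_eff, alleles_oth,
        eaf=g_e.mean(axis=0) / 2.0, beta=b_e, se=se_e, p=p_e, n=params.n_individuals,
    )
    gwas = sumstats_from_arrays(
        variant_ids, alleles_eff, alleles_oth,
        eaf=g_y.mean(axis=0) / 2.0, beta=b_g, se=se_g, p=p_g, n=params.n_individuals,
    )
    truth = TruthRecord(
        kind="cohort",
        seed=params.seed,
        true_b_xy=true_b_xy,
        causal_variant_ids=causal_ids,
        scenario=params.scenario,
        extra={
            "b_zx": params.b_zx,
            "maf": params.maf,
            "ld_decay_rho": params.ld_decay_rho,
            "linkage_r2": params.linkage_r2 if params.scenario == "linkage" else None,
        },
    )
    return eqtl, gwas, ld, truth
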