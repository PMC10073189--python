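"""End-to-end orchestration of the two analysis arms.

The transcriptomic arm runs: concordance filter over the query-class
signatures -> query construction -> connectivity scoring -> average Tau ->
high-connectivity classification -> drug-class enrichment -> per-pair
directional concordance -> term enrichment with ancestor roll-up.

The genetic arm runs, per (gene, trait): instrument selection ->
harmonization -> SMR -> HEIDI -> multiple-testing flagging.

Every stage writes a TSV; each arm writes a JSON summary with a config echo
so runs are fully reproducible. Outputs are never overwritten unless
``force`` is set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import class_enrichment as ce
from . import concordance as cc
from . import connectivity as conn_mod
from . import io as sio
from . import mr as mr_mod
from . import term_enrichment as te
from .signatures import ExpressionSignature, build_query, concordance_filter

logger = logging.getLogger(__name__)


@dataclass
class MrEntry:
    name: str
    sumstats: str


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults match the primary analysis.

    Sensitivity alternates (k_query 100/150, z_threshold 1.5/2) are plain
    config changes.
    """

    # transcriptomic arm inputs
    signatures: str = ""
    compounds: str = ""
    term_edges: str = ""
    term_annotations: str = ""
    # transcriptomic arm parameters
    query_class: str = "statin"
    target_class: str = "antidepressant"
    k_query: int = 50
    z_threshold: float = 1.0
    tau_cutoff: float = 90.0
    min_mean_r: float = 0.2
    gene_scope: str = "landmark"
    weight_exponent: float = 1.0
    enrichment_alpha: float = 0.05
    correction_method: str = "bonferroni"
    chi2_correction: str = "none"
    ancestor_level: int = 1
    # genetic arm inputs
    genes: list[MrEntry] = field(default_factory=list)
    traits: list[MrEntry] = field(default_factory=list)
    ld: str = ""
    frame_inhibition: bool = True
    f_min: float = 10.0
    mr_alpha: float = 0.05
    heidi_min_snps: int = 3
    heidi_max_snps: int = 20
    heidi_r2_window: tuple[float, float] = (0.05, 0.9)
    # shared
    seed: int = 0
    outdir: str = "results"
    force: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("genes", "traits"):
            if key in data:
                data[key] = [MrEntry(**e) if isinstance(e, dict) else e for e in data[key]]
        if "heidi_r2_window" in data:
            data["heidi_r2_window"] = tuple(data["heidi_r2_window"])
        return cls(**data)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["heidi_r2_window"] = list(self.heidi_r2_window)
        return d


def _prepare_outdir(cfg: RunConfig, names: list[str]) -> Path:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not cfg.force:
        clashes = [n for n in names if (out / n).exists()]
        if clashes:
            raise FileExistsError(
                f"output file(s) exist (use force to overwrite): {clashes}"
            )
    return out


def run_transcriptomic_arm(cfg: RunConfig) -> dict:
    """Execute the signature-matching arm; returns the JSON-able summary."""
    out = _prepare_outdir(
        cfg,
        [
            "filter_report.tsv",
            "queries.tsv",
            "connectivity.tsv",
            "average_tau.tsv",
            "class_enrichment.tsv",
            "concordance_pairs.tsv",
            "term_enrichment.tsv",
            "term_rollup.tsv",
            "transcriptomic_summary.json",
        ],
    )
    matrix = sio.read_gct(cfg.signatures)
    compounds = sio.read_compound_table(cfg.compounds)
    matrix = conn_mod.dedupe_by_touchstone(matrix, compounds)

    comp_of = {c: str(matrix.column_meta.loc[c, "compound_id"]) for c in matrix.column_ids}
    query_compounds = set(
        compounds.loc[compounds["class_label"] == cfg.query_class, "compound_id"]
    )
    query_cols = [c for c in matrix.column_ids if comp_of[c] in query_compounds]
    if len(query_cols) < 3:
        raise ValueError(
            f"stage filter: need >= 3 {cfg.query_class!r} signatures, found {len(query_cols)}"
        )

    # 1. concordance filter over the query-class signatures
    sigs = {c: ExpressionSignature.from_matrix(matrix, c) for c in query_cols}
    kept, dropped, filt_report = concordance_filter(sigs, cfg.min_mean_r)
    filt_report.to_csv(out / "filter_report.tsv", sep="\t", index=False)

    # 2. query construction
    queries = [build_query(sigs[c], cfg.k_query, query_id=c) for c in kept]
    pd.concat(
        [q.to_frame().assign(query_id=q.query_id) for q in queries], ignore_index=True
    ).to_csv(out / "queries.tsv", sep="\t", index=False)

    # 3/4. connectivity scoring and average Tau
    conn = conn_mod.connectivity_table(
        matrix,
        queries,
        compounds,
        gene_scope=cfg.gene_scope,
        weight_exponent=cfg.weight_exponent,
    )
    conn.to_csv(out / "connectivity.tsv", sep="\t", index=False, float_format="%.10g")
    avg_tau = conn_mod.average_tau_profile(conn)
    avg_tau.rename("average_tau").to_csv(out / "average_tau.tsv", sep="\t", float_format="%.10g")

    # 5/6. classification + class enrichment (query compounds excluded)
    high, low = ce.threshold_classify(avg_tau, cfg.tau_cutoff, exclude=query_compounds)
    target_members = set(
        compounds.loc[compounds["class_label"] == cfg.target_class, "compound_id"]
    )
    table = ce.build_enrichment_table(high, low, target_members)
    chi2, p_enrich, odds = ce.class_enrichment_test(table, cfg.chi2_correction)
    pd.DataFrame(
        [
            {
                "class": cfg.target_class,
                "a_class_high": table.a,
                "b_class_low": table.b,
                "c_other_high": table.c,
                "d_other_low": table.d,
                "chi2": chi2,
                "p": p_enrich,
                "odds_ratio": odds,
            }
        ]
    ).to_csv(out / "class_enrichment.tsv", sep="\t", index=False, float_format="%.10g")

    # 7. directional concordance for query x high-connectivity target pairs
    high_target_cols = [
        c for c in matrix.column_ids if comp_of[c] in (target_members & high)
    ]
    pair_frames = []
    same_union: set[str] = set()
    opp_union: set[str] = set()
    for qc in kept:
        for tc in high_target_cols:
            sp = cc.shared_perturbation_frame(
                sigs[qc], ExpressionSignature.from_matrix(matrix, tc), cfg.z_threshold
            )
            sp.insert(0, "compound_b", comp_of[tc])
            sp.insert(0, "compound_a", comp_of[qc])
            pair_frames.append(sp)
            same_union |= set(sp.loc[sp["direction_class"] != "opposite", "gene"])
            opp_union |= set(sp.loc[sp["direction_class"] == "opposite", "gene"])
    pairs_df = (
        pd.concat(pair_frames, ignore_index=True)
        if pair_frames
        else pd.DataFrame(columns=["compound_a", "compound_b", "gene", "z_a", "z_b", "direction_class"])
    )
    pairs_df.to_csv(out / "concordance_pairs.tsv", sep="\t", index=False, float_format="%.10g")

    # 8. term enrichment over the union-of-evidence gene sets
    n_sig_terms = 0
    term_frames = []
    rollup_frames = []
    if cfg.term_edges and cfg.term_annotations:
        tg = sio.read_term_graph(cfg.term_edges, cfg.term_annotations)
        background = set(matrix.gene_ids)
        for label, gene_set in (("same", same_union), ("opposite", opp_union)):
            if not gene_set:
                continue
            results = te.annotate_results(
                te.hypergeom_enrichment(gene_set & background, background, tg),
                method=cfg.correction_method,
                alpha=cfg.enrichment_alpha,
            )
            frame = te.results_frame(results)
            frame.insert(0, "direction", label)
            term_frames.append(frame)
            sig_terms = [r.term_id for r in results if r.significant]
            n_sig_terms += len(sig_terms)
            if sig_terms:
                roll = te.rollup_ancestors(sig_terms, tg, cfg.ancestor_level)
                roll.insert(0, "direction", label)
                rollup_frames.append(roll)
    term_df = (
        pd.concat(term_frames, ignore_index=True)
        if term_frames
        else pd.DataFrame(
            columns=["direction", "term_id", "k", "n_set", "K_term", "N", "p_raw", "p_adj", "significant"]
        )
    )
    term_df.to_csv(out / "term_enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    rollup_df = (
        pd.concat(rollup_frames, ignore_index=True)
        if rollup_frames
        else pd.DataFrame(columns=["direction", "ancestor", "ancestor_name", "term", "term_name"])
    )
    rollup_df.to_csv(out / "term_rollup.tsv", sep="\t", index=False)

    summary = {
        "filter": {"kept": sorted(kept), "dropped": sorted(dropped)},
        "query": {"k": cfg.k_query, "n_queries": len(queries)},
        "connectivity": {
            "n_references": int(conn["reference_id"].nunique()),
            "n_high": len(high),
            "tau_cutoff": cfg.tau_cutoff,
        },
        "class_enrichment": {
            "class": cfg.target_class,
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "chi2": chi2,
            "p": p_enrich,
            "odds_ratio": odds,
        },
        "concordance": {
            "n_pairs": len(kept) * len(high_target_cols),
            "n_same_union": len(same_union),
            "n_opposite_union": len(opp_union),
            "z_threshold": cfg.z_threshold,
        },
        "term_enrichment": {"n_significant": n_sig_terms, "method": cfg.correction_method},
        "config": cfg.echo(),
        "seed": cfg.seed,
    }
    (out / "transcriptomic_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def run_mr_arm(cfg: RunConfig) -> dict:
    """Execute the MR arm over every (gene, trait) pair; returns the summary."""
    out = _prepare_outdir(cfg, ["mr_results.tsv", "mr_summary.json"])
    if not cfg.genes or not cfg.traits or not cfg.ld:
        raise ValueError("MR arm needs genes, traits and an LD matrix")
    ld = sio.read_ld_matrix(cfg.ld)
    threshold = mr_mod.multiple_testing_threshold(len(cfg.genes), len(cfg.traits), cfg.mr_alpha)
    rows = []
    for gene in cfg.genes:
        eqtl = sio.read_sumstats(gene.sumstats)
        instrument = mr_mod.select_instrument(eqtl, cfg.f_min)
        for trait in cfg.traits:
            gwas = sio.read_sumstats(trait.sumstats)
            if instrument.variant_id not in gwas:
                logger.warning(
                    "stage smr: instrument %s absent from %s; skipping",
                    instrument.variant_id,
                    trait.name,
                )
                continue
            pair = mr_mod.harmonize(
                eqtl.get(instrument.variant_id),
                gwas.get(instrument.variant_id),
                frame_inhibition=cfg.frame_inhibition,
            )
            res = mr_mod.smr_test(pair)
            heidi = mr_mod.heidi_test(
                eqtl,
                gwas,
                ld,
                instrument,
                r2_window=cfg.heidi_r2_window,
                max_snps=cfg.heidi_max_snps,
                min_snps=cfg.heidi_min_snps,
            )
            rows.append(
                {
                    "gene": gene.name,
                    "trait": trait.name,
                    "instrument": instrument.variant_id,
                    "f_stat": instrument.f_stat,
                    "b_xy": res.b_xy,
                    "se_xy": res.se_xy,
                    "ci_lo": res.ci95[0],
                    "ci_hi": res.ci95[1],
                    "p_smr": res.p_smr,
                    "p_heidi": heidi.p_heidi if heidi.computed else float("nan"),
                    "n_snps_heidi": heidi.n_snps_used,
                    "heidi_computed": heidi.computed,
                    "significant_at_corrected": bool(res.p_smr < threshold),
                }
            )
    results = pd.DataFrame(rows)
    results.to_csv(out / "mr_results.tsv", sep="\t", index=False, float_format="%.10g")
    summary = {
        "n_tests": len(rows),
        "threshold": threshold,
        "n_significant": int(results["significant_at_corrected"].sum()) if len(rows) else 0,
        "frame_inhibition": cfg.frame_inhibition,
        "config": cfg.echo(),
        "seed": cfg.seed,
    }
    (out / "mr_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
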