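import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sigmr.connectivity import (
    RankedReference,
    average_connectivity,
    average_tau_profile,
    connectivity_table,
    normalize_scores,
    summarize_across_cells,
    tau,
    weighted_ks_enrichment,
    wtcs,
)
from sigmr.signatures import ExpressionSignature, QuerySignature, build_query
from sigmr.synthetic_data import ClassSpec, SignatureSimParams, simulate_signatures
from tests.conftest import make_signature


def brute_force_es(ref: RankedReference, gene_set, w: float = 1.0) -> float:
    """Independent running-sum oracle with the shared positive-wins tie rule."""
    hits = set(gene_set)
    n_total = len(ref)
    w_sum = sum(abs(ref.z[i]) ** w for i in range(n_total) if ref.gene_ids[i] in hits)
    miss_step = 1.0 / (n_total - len(hits))
    run, max_pos, min_neg = 0.0, 0.0, 0.0
    for i in range(n_total):
        if ref.gene_ids[i] in hits:
            run += abs(ref.z[i]) ** w / w_sum
        else:
            run -= miss_step
        max_pos = max(max_pos, run)
        min_neg = min(min_neg, run)
    return max_pos if max_pos >= -min_neg - 1e-9 else min_neg


class TestWeightedKs:
    def test_top_ranks_give_one(self):
        ref = RankedReference(gene_ids=list("abcde"), z=[5, 4, 3, 2, 1])
        assert weighted_ks_enrichment(ref, ["a", "b"]) == pytest.approx(1.0)

    def test_bottom_ranks_give_minus_one(self):
        ref = RankedReference(gene_ids=list("abcde"), z=[5, 4, 3, 2, 1])
        assert weighted_ks_enrichment(ref, ["d", "e"]) == pytest.approx(-1.0)

    def test_hand_enumeration(self):
        ref = RankedReference(gene_ids=list("abcd"), z=[3, 2, 1, 0.5])
        assert weighted_ks_enrichment(ref, ["a", "c"]) == pytest.approx(0.75)

    def test_empty_set_error(self):
        ref = RankedReference(gene_ids=list("ab"), z=[1, 0])
        with pytest.raises(ValueError, match="empty"):
            weighted_ks_enrichment(ref, [])

    def test_full_set_error(self):
        ref = RankedReference(gene_ids=list("ab"), z=[1, 0])
        with pytest.raises(ValueError, match="proper subset"):
            weighted_ks_enrichment(ref, ["a", "b"])

    def test_against_brute_force(self, rng):
        for _ in range(300):
            n = int(rng.integers(3, 13))
            ref = RankedReference(
                gene_ids=[f"g{i}" for i in range(n)], z=rng.standard_normal(n)
            )
            k = int(rng.integers(1, n))
            gene_set = list(rng.choice(ref.gene_ids, size=k, replace=False))
            assert weighted_ks_enrichment(ref, gene_set) == pytest.approx(
                brute_force_es(ref, gene_set), abs=1e-12
            )

    def test_bounded(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 40))
            ref = RankedReference(
                gene_ids=[f"g{i}" for i in range(n)], z=rng.standard_normal(n) * 3
            )
            k = int(rng.integers(1, n))
            gene_set = list(rng.choice(ref.gene_ids, size=k, replace=False))
            assert abs(weighted_ks_enrichment(ref, gene_set)) <= 1.0 + 1e-12


class TestWtcs:
    def test_opposite_signs_formula(self):
        # up genes at top, down genes near bottom -> ES_up > 0, ES_down < 0
        ref = RankedReference(gene_ids=list("abcdefgh"), z=[8, 7, 6, 5, 4, 3, 2, 1])
        q = QuerySignature(up=["a", "b"], down=["g", "h"], query_id="q")
        es_up = weighted_ks_enrichment(ref, ["a", "b"])
        es_down = weighted_ks_enrichment(ref, ["g", "h"])
        assert es_up > 0 > es_down
        assert wtcs(q, ref) == pytest.approx((es_up - es_down) / 2)

    def test_same_sign_gives_zero(self):
        ref = RankedReference(gene_ids=list("abcdefgh"), z=[8, 7, 6, 5, 4, 3, 2, 1])
        q = QuerySignature(up=["a", "b"], down=["c", "d"], query_id="q")
        assert weighted_ks_enrichment(ref, ["c", "d"]) > 0
        assert wtcs(q, ref) == 0.0

    def test_self_connectivity_is_one(self, rng):
        sig = make_signature(rng.standard_normal(100))
        ref = RankedReference.from_signature(sig, gene_scope="landmark")
        q = build_query(sig, k=10)
        assert wtcs(q, ref) == pytest.approx(1.0)

    def test_missing_genes_dropped_with_floor(self):
        ref = RankedReference(gene_ids=list("abcdef"), z=[6, 5, 4, 3, 2, 1])
        q = QuerySignature(up=["a", "x"], down=["f", "y"], query_id="q")
        # half of each side survives -> allowed
        assert np.isfinite(wtcs(q, ref))
        q2 = QuerySignature(up=["x", "y"], down=["f", "e"], query_id="q2")
        with pytest.raises(ValueError):
            wtcs(q2, ref)

    def test_bounds_random(self, rng):
        for _ in range(100):
            n = 30
            sig = make_signature(rng.standard_normal(n))
            ref = RankedReference.from_signature(sig)
            q = build_query(make_signature(rng.standard_normal(n)), k=5)
            assert abs(wtcs(q, ref)) <= 1.0 + 1e-12


class TestNormalizeScores:
    def test_arithmetic_oracle(self):
        raw = pd.DataFrame({"r1": [0.2], "r2": [0.4]}, index=["q"])
        grouping = {"r1": ("HA1E", "trt_cp"), "r2": ("HA1E", "trt_cp")}
        ncs = normalize_scores(raw, grouping)
        assert ncs.loc["q", "r1"] == pytest.approx(0.2 / 0.3)
        assert ncs.loc["q", "r2"] == pytest.approx(0.4 / 0.3)

    def test_all_equal_positive_gives_one(self):
        raw = pd.DataFrame({"r1": [0.3], "r2": [0.3], "r3": [0.3]}, index=["q"])
        grouping = {r: ("c", "t") for r in raw.columns}
        assert np.allclose(normalize_scores(raw, grouping), 1.0)

    def test_zero_stays_zero(self):
        raw = pd.DataFrame({"r1": [0.0], "r2": [0.5]}, index=["q"])
        grouping = {r: ("c", "t") for r in raw.columns}
        ncs = normalize_scores(raw, grouping)
        assert ncs.loc["q", "r1"] == 0.0

    def test_sign_stratified(self):
        raw = pd.DataFrame({"r1": [0.2], "r2": [-0.8]}, index=["q"])
        grouping = {r: ("c", "t") for r in raw.columns}
        ncs = normalize_scores(raw, grouping)
        assert ncs.loc["q", "r1"] == pytest.approx(1.0)
        assert ncs.loc["q", "r2"] == pytest.approx(-1.0)

    def test_ungrouped_reference_error(self):
        raw = pd.DataFrame({"r1": [0.2]}, index=["q"])
        with pytest.raises(ValueError, match="group"):
            normalize_scores(raw, {})


class TestTau:
    def test_above_all_touchstone(self):
        assert tau(2.0, [0.1, 0.5, 1.0]) == 100.0

    def test_zero_is_zero(self):
        assert tau(0.0, [0.1, 0.5]) == 0.0

    def test_counting_oracle(self):
        ts = np.arange(1, 11) / 10.0  # 0.1 .. 1.0
        assert tau(0.55, ts) == pytest.approx(50.0)
        assert tau(-0.55, ts) == pytest.approx(-50.0)

    def test_antisymmetry(self, rng):
        ts = rng.uniform(0, 2, 50)
        for v in rng.uniform(-2, 2, 20):
            assert tau(-v, ts) == pytest.approx(-tau(v, ts))

    def test_strict_inequality(self):
        assert tau(0.5, [0.5, 0.5, 0.5]) == 0.0

    def test_empty_touchstone_error(self):
        with pytest.raises(ValueError, match="touchstone"):
            tau(0.5, [])


class TestSummarizeAcrossCells:
    def test_all_equal(self):
        assert summarize_across_cells([42.0] * 9) == 42.0

    def test_nearest_rank_example(self):
        assert summarize_across_cells([-95.0, 0.0, 20.0]) == -95.0

    def test_single_cell(self):
        assert summarize_across_cells([-7.0]) == -7.0

    def test_tie_prefers_upper(self):
        assert summarize_across_cells([-50.0, 50.0]) == 50.0


class TestAverageConnectivity:
    def test_identical_profiles(self):
        prof = pd.DataFrame([[10.0, -5.0]] * 6, columns=["r1", "r2"])
        avg = average_connectivity(prof)
        assert avg["r1"] == 10.0 and avg["r2"] == -5.0

    def test_arithmetic(self):
        prof = pd.DataFrame({"r": [99.0, 81.0]})
        assert average_connectivity(prof)["r"] == pytest.approx(90.0)

    def test_column_mean_oracle(self, rng):
        prof = pd.DataFrame(rng.uniform(-100, 100, size=(6, 100)))
        assert np.allclose(average_connectivity(prof), prof.to_numpy().mean(axis=0))

    def test_missing_reference_error(self):
        prof = pd.DataFrame({"r1": [1.0, np.nan], "r2": [2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            average_connectivity(prof)


@pytest.fixture(scope="module")
def planted():
    params = SignatureSimParams(
        n_genes=400,
        n_landmark=300,
        classes=[
            ClassSpec("statin", 6, 2.0),
            ClassSpec("antidepressant", 12, 1.6, share_latent_with="statin"),
            ClassSpec("control", 40, 0.0),
        ],
        noise_sd=1.0,
        seed=99,
    )
    return simulate_signatures(params)


class TestStatisticalProperties:
    def test_self_connectivity_dominance(self, planted, rng):
        matrix, _, _ = planted
        ref_col = matrix.column_ids[0]
        sig = ExpressionSignature.from_matrix(matrix, ref_col)
        ref = RankedReference.from_signature(sig)
        q_self = build_query(sig, k=25)
        self_score = wtcs(q_self, ref)
        assert self_score == pytest.approx(1.0)
        others = rng.choice(matrix.column_ids[1:], size=15, replace=False)
        for other in others:
            q_other = build_query(ExpressionSignature.from_matrix(matrix, other), k=25)
            assert wtcs(q_other, ref) <= self_score + 1e-12

    def test_planted_class_recovers_high_tau(self, planted):
        matrix, compounds, _ = planted
        statin_cols = [c for c in matrix.column_ids if c.startswith("statin")]
        queries = [
            build_query(ExpressionSignature.from_matrix(matrix, c), 25, query_id=c)
            for c in statin_cols
        ]
        conn = connectivity_table(matrix, queries, compounds)
        avg = average_tau_profile(conn)
        ad = avg[avg.index.str.startswith("antidepressant")]
        ctl = avg[avg.index.str.startswith("control")]
        stat, p = sps.ranksums(ad, ctl)
        assert stat > 0 and p < 0.01
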