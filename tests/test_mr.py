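import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sigmr.io import LdSource, sumstats_from_arrays
from sigmr.mr import (
    HarmonizedPair,
    harmonize,
    heidi_test,
    instrument_f_stat,
    multiple_testing_threshold,
    quadform_tail,
    select_instrument,
    smr_test,
)
from sigmr.synthetic_data import CohortSimParams, simulate_cohort


def make_sumstats(rows):
    """rows: list of (id, a1, a2, eaf, beta, se, p, n)."""
    cols = list(zip(*rows))
    return sumstats_from_arrays(
        cols[0], cols[1], cols[2],
        np.array(cols[3]), np.array(cols[4]), np.array(cols[5]), np.array(cols[6]),
        np.array(cols[7]),
    )


class TestSelectInstrument:
    def test_f_from_p_example(self):
        # z for a two-sided p of 4.1e-7 is ~5.06, so F = z^2 ~ 25.6 > 10
        z = sps.norm.isf(4.1e-7 / 2)
        t = make_sumstats([("rs9", "A", "G", 0.3, z * 0.05, 0.05, 4.1e-7, 30000)])
        inst = select_instrument(t, f_min=10)
        assert inst.f_stat == pytest.approx(25.6, abs=0.1)
        assert instrument_f_stat(z * 0.05, 0.05) == pytest.approx(25.6, abs=0.1)

    def test_weak_instruments_rejected(self):
        # |z| < 3.16 for every record -> F <= 10 -> no valid instrument
        t = make_sumstats(
            [(f"rs{i}", "A", "G", 0.3, 0.03 * i, 0.05, 0.4, 1000) for i in range(1, 4)]
        )
        with pytest.raises(ValueError, match="no valid instrument"):
            select_instrument(t, f_min=10)

    def test_smallest_p_wins(self):
        t = make_sumstats(
            [
                ("rs_b", "A", "G", 0.3, 0.30, 0.05, 1e-8, 1000),
                ("rs_a", "A", "G", 0.3, 0.33, 0.05, 1e-10, 1000),
            ]
        )
        assert select_instrument(t).variant_id == "rs_a"

    def test_tie_broken_by_id(self):
        t = make_sumstats(
            [
                ("rs_b", "A", "G", 0.3, 0.30, 0.05, 1e-9, 1000),
                ("rs_a", "A", "G", 0.3, 0.30, 0.05, 1e-9, 1000),
            ]
        )
        assert select_instrument(t).variant_id == "rs_a"


class TestHarmonize:
    def _recs(self, g_a1="A", g_a2="G", g_beta=0.1):
        eqtl = pd.Series(
            {"variant_id": "rs1", "effect_allele": "A", "other_allele": "G",
             "eaf": 0.3, "beta": 0.5, "se": 0.05, "p": 1e-20, "n": 30000}
        )
        gwas = pd.Series(
            {"variant_id": "rs1", "effect_allele": g_a1, "other_allele": g_a2,
             "eaf": 0.3, "beta": g_beta, "se": 0.02, "p": 1e-6, "n": 50000}
        )
        return eqtl, gwas

    def test_aligned_unchanged(self):
        pair = harmonize(*self._recs())
        assert pair.b_zy == 0.1 and pair.b_zx == 0.5

    def test_other_allele_coding_flips_sign(self):
        pair = harmonize(*self._recs(g_a1="G", g_a2="A"))
        assert pair.b_zy == -0.1

    def test_double_flip_identity(self):
        once = harmonize(*self._recs(g_a1="G", g_a2="A"))
        eqtl, gwas = self._recs(g_a1="G", g_a2="A")
        gwas2 = gwas.copy()
        gwas2["effect_allele"], gwas2["other_allele"] = "A", "G"
        gwas2["beta"] = -gwas2["beta"]
        twice = harmonize(eqtl, gwas2)
        assert twice.b_zy == once.b_zy

    def test_allele_mismatch_error(self):
        eqtl, gwas = self._recs(g_a1="A", g_a2="C")
        with pytest.raises(ValueError, match="mismatch"):
            harmonize(eqtl, gwas)

    def test_palindromic_warned_and_dropped(self):
        eqtl, gwas = self._recs()
        for rec in (eqtl, gwas):
            rec["effect_allele"], rec["other_allele"] = "A", "T"
            rec["eaf"] = 0.49
        with pytest.warns(UserWarning, match="palindromic"):
            pair = harmonize(eqtl, gwas)
        assert pair is not None
        with pytest.warns(UserWarning, match="palindromic"):
            dropped = harmonize(eqtl, gwas, drop_palindromic=True)
        assert dropped is None

    def test_inhibition_frame_flips_reported_effect(self):
        eqtl, gwas = self._recs()
        plain = smr_test(harmonize(eqtl, gwas))
        framed = smr_test(harmonize(eqtl, gwas, frame_inhibition=True))
        assert framed.b_xy == pytest.approx(-plain.b_xy)
        assert framed.p_smr == plain.p_smr


class TestSmrTest:
    def _pair(self, b_zx=0.5, se_zx=0.05, b_zy=0.1, se_zy=0.02, framed=False):
        return HarmonizedPair(
            variant_id="rs1", effect_allele="A", other_allele="G",
            b_zx=b_zx, se_zx=se_zx, b_zy=b_zy, se_zy=se_zy, inhibition_framed=framed,
        )

    def test_worked_example(self):
        res = smr_test(self._pair())
        assert res.b_xy == pytest.approx(0.2)
        assert res.t_smr == pytest.approx(20.0)
        assert res.se_xy == pytest.approx(0.2 / np.sqrt(20), rel=1e-12)
        assert res.p_smr == pytest.approx(7.744e-6, rel=1e-3)

    def test_null_outcome(self):
        res = smr_test(self._pair(b_zy=0.0))
        assert res.b_xy == 0.0 and res.t_smr == 0.0 and res.p_smr == 1.0

    def test_zero_exposure_error(self):
        with pytest.raises(ValueError, match="b_zx"):
            smr_test(self._pair(b_zx=0.0))

    def test_ci_definition(self):
        res = smr_test(self._pair())
        assert res.ci95[0] == pytest.approx(res.b_xy - 1.96 * res.se_xy)
        assert res.ci95[1] == pytest.approx(res.b_xy + 1.96 * res.se_xy)

    def test_scale_equivariance(self):
        base = smr_test(self._pair())
        scaled = smr_test(self._pair(b_zy=0.1 * 3, se_zy=0.02 * 3))
        assert scaled.b_xy == pytest.approx(3 * base.b_xy)
        assert scaled.se_xy == pytest.approx(3 * base.se_xy)
        assert scaled.p_smr == pytest.approx(base.p_smr, rel=1e-12)

    def test_p_matches_normal_square(self, rng):
        for _ in range(50):
            pair = self._pair(
                b_zx=rng.uniform(0.1, 1), se_zx=rng.uniform(0.01, 0.1),
                b_zy=rng.uniform(-0.5, 0.5), se_zy=rng.uniform(0.01, 0.1),
            )
            res = smr_test(pair)
            z_equiv = np.sqrt(res.t_smr)
            assert res.p_smr == pytest.approx(2 * sps.norm.sf(z_equiv), abs=1e-10)

    def test_null_type_one_error(self):
        # under b_xy = 0, SMR p at alpha=.05 rejects ~5% of the time
        rej = 0
        n_rep = 300
        for s in range(n_rep):
            eqtl, gwas, _, _ = simulate_cohort(
                CohortSimParams(n_individuals=2000, n_variants=1, scenario="null",
                                seed=20_000 + s, ld_ref_n=200)
            )
            inst = select_instrument(eqtl)
            res = smr_test(harmonize(eqtl.get(inst.variant_id), gwas.get(inst.variant_id)))
            rej += res.p_smr < 0.05
        rate = rej / n_rep
        ci = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < ci + 0.01


class TestMultipleTestingThreshold:
    def test_gene_trait_grid(self):
        thr = multiple_testing_threshold(3, 29, 0.05)
        assert thr == pytest.approx(0.0005747, abs=1e-7)
        assert float(f"{thr:.2g}") == 0.00057

    def test_trivial(self):
        assert multiple_testing_threshold(1, 1, 0.05) == 0.05
        assert multiple_testing_threshold(2, 10, 0.05) == pytest.approx(0.0025)

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            multiple_testing_threshold(0, 5)


class TestQuadformTail:
    def test_single_lambda_is_chi2(self):
        for t in (0.5, 2.0, 6.0):
            assert quadform_tail(t, np.array([1.0])) == pytest.approx(
                sps.chi2.sf(t, 1), abs=1e-6
            )

    def test_imhof_vs_mc(self, rng):
        for _ in range(5):
            lam = rng.uniform(0.1, 2.0, size=int(rng.integers(2, 8)))
            t = float(rng.uniform(0.5, 2.0) * lam.sum())
            p_imhof = quadform_tail(t, lam, method="imhof")
            p_mc = quadform_tail(t, lam, method="mc", rng=rng, n_mc=400_000)
            assert p_imhof == pytest.approx(p_mc, abs=4 * np.sqrt(0.25 / 400_000) + 5e-3)

    def test_satterthwaite_close(self, rng):
        lam = np.array([1.0, 0.8, 0.6])
        t = 4.0
        assert quadform_tail(t, lam, "satterthwaite") == pytest.approx(
            quadform_tail(t, lam, "imhof"), abs=0.03
        )

    def test_nonpositive_t(self):
        assert quadform_tail(0.0, np.array([1.0, 2.0])) == 1.0


class TestHeidi:
    def _consistent_region(self, m=6, b_xy=0.2):
        """All SNPs exactly consistent with a single causal signal."""
        rng = np.random.default_rng(0)
        b_zx = rng.uniform(0.2, 0.5, m)
        se = np.full(m, 0.01)
        b_zy = b_xy * b_zx
        ids = [f"rs{i}" for i in range(m)]
        eqtl = make_sumstats(
            [(ids[i], "A", "G", 0.3, b_zx[i], se[i],
              float(2 * sps.norm.sf(abs(b_zx[i] / se[i]))) or 1e-300, 30000)
             for i in range(m)]
        )
        gwas = make_sumstats(
            [(ids[i], "A", "G", 0.3, b_zy[i], se[i],
              min(1.0, float(2 * sps.norm.sf(abs(b_zy[i] / se[i])))), 50000)
             for i in range(m)]
        )
        R = 0.5 * np.ones((m, m)) + 0.5 * np.eye(m)
        ld = LdSource(variant_ids=ids, ld_matrix=R)
        return eqtl, gwas, ld

    def test_consistent_region_accepts(self):
        eqtl, gwas, ld = self._consistent_region()
        top = select_instrument(eqtl)
        res = heidi_test(eqtl, gwas, ld, top)
        assert res.computed
        assert res.p_heidi > 0.9
        assert res.passed

    def test_too_few_snps_flagged(self):
        eqtl, gwas, ld = self._consistent_region(m=3)
        top = select_instrument(eqtl)
        res = heidi_test(eqtl, gwas, ld, top, min_snps=5)
        assert not res.computed
        assert np.isnan(res.p_heidi)

    def test_top_absent_error(self):
        eqtl, gwas, ld = self._consistent_region()
        from sigmr.mr import Instrument

        ghost = Instrument("rs_nope", 0.3, 0.01, 1e-10, 900.0)
        with pytest.raises(ValueError, match="absent"):
            heidi_test(eqtl, gwas, ld, ghost)

    def test_linkage_rejected_more_than_causal(self):
        # power check at modest replicate count; the heavier calibration
        # lives in the acceptance suite
        def rejection_rate(scenario, n_rep, base_seed):
            rej = comp = 0
            for s in range(n_rep):
                eqtl, gwas, ld, _ = simulate_cohort(
                    CohortSimParams(
                        n_individuals=6000, n_variants=12, scenario=scenario,
                        b_zx=0.35, b_xy=0.25, linkage_r2=0.6,
                        seed=base_seed + s, ld_ref_n=3000,
                    )
                )
                try:
                    top = select_instrument(eqtl)
                except ValueError:
                    continue
                res = heidi_test(eqtl, gwas, ld, top)
                if res.computed:
                    comp += 1
                    rej += res.p_heidi < 0.01
            return rej, comp

        rej_c, comp_c = rejection_rate("causal", 40, 1_000)
        rej_l, comp_l = rejection_rate("linkage", 40, 2_000)
        assert comp_c > 20 and comp_l > 20
        assert rej_l / comp_l > rej_c / comp_c
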