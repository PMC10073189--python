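"""Summary-data Mendelian randomization of gene expression on outcome traits.

Implements single-instrument ratio MR from two independent summary-statistic
studies (eQTL exposure, GWAS outcome): instrument selection by strength,
allele harmonization, the SMR chi-square test on the Wald ratio, and the
HEIDI heterogeneity test that distinguishes a single shared causal variant
from distinct variants in LD by comparing ratio estimates across linked SNPs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .io import LdSource, SumStatsTable

logger = logging.getLogger(__name__)

PALINDROMIC_PAIRS = frozenset({frozenset({"A", "T"}), frozenset({"C", "G"})})


@dataclass(frozen=True)
class Instrument:
    """A selected eQTL instrument with its strength statistic."""

    variant_id: str
    b_zx: float
    se_zx: float
    p_zx: float
    f_stat: float


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects aligned to the same effect allele."""

    variant_id: str
    effect_allele: str
    other_allele: str
    b_zx: float
    se_zx: float
    b_zy: float
    se_zy: float
    inhibition_framed: bool = False


@dataclass(frozen=True)
class SMRResult:
    b_xy: float
    se_xy: float
    ci95: tuple[float, float]
    p_smr: float
    t_smr: float


@dataclass(frozen=True)
class HEIDIResult:
    p_heidi: float
    n_snps_used: int
    passed: bool
    computed: bool = True

    def __post_init__(self) -> None:
        if self.computed and not np.isfinite(self.p_heidi):
            raise ValueError("computed HEIDI result must carry a finite p")


def instrument_f_stat(beta: float, se: float) -> float:
    """Single-SNP instrument strength approximated as z^2 = (beta/se)^2."""
    return float((beta / se) ** 2)


def select_instrument(eqtl: SumStatsTable, f_min: float = 10.0) -> Instrument:
    """Pick the strongest eligible eQTL: F > f_min, then smallest p, ties by id.

    Raises ``ValueError("no valid instrument")`` when nothing passes.
    """
    df = eqtl.records
    if df.empty:
        raise ValueError("no valid instrument")
    f = (df["beta"] / df["se"]) ** 2
    eligible = df.loc[f > f_min].copy()
    if eligible.empty:
        raise ValueError("no valid instrument")
    eligible["_f"] = f.loc[eligible.index]
    eligible = eligible.reset_index(drop=True).sort_values(["p", "variant_id"], kind="stable")
    row = eligible.iloc[0]
    return Instrument(
        variant_id=str(row["variant_id"]),
        b_zx=float(row["beta"]),
        se_zx=float(row["se"]),
        p_zx=float(row["p"]),
        f_stat=float(row["_f"]),
    )


def harmonize(
    eqtl_rec,
    gwas_rec,
    frame_inhibition: bool = False,
    drop_palindromic: bool = False,
    ambiguous_eaf_band: float = 0.08,
) -> HarmonizedPair | None:
    """Align the GWAS record to the eQTL record's effect allele.

    If the GWAS effect allele is the eQTL's other allele, the GWAS beta sign
    is flipped. Strand-ambiguous palindromic variants (A/T or C/G) with
    allele frequency near 0.5 trigger a warning and, when
    ``drop_palindromic`` is set, are dropped (returns ``None``).

    ``frame_inhibition`` marks the pair so downstream causal estimates are
    reported per one SD *decrease* in expression.
    """
    if str(eqtl_rec["variant_id"]) != str(gwas_rec["variant_id"]):
        raise ValueError("harmonize requires records for the same variant")
    e_a1, e_a2 = str(eqtl_rec["effect_allele"]), str(eqtl_rec["other_allele"])
    g_a1, g_a2 = str(gwas_rec["effect_allele"]), str(gwas_rec["other_allele"])
    if {e_a1, e_a2} != {g_a1, g_a2}:
        raise ValueError(
            f"allele mismatch for {eqtl_rec['variant_id']}: "
            f"{{{e_a1},{e_a2}}} vs {{{g_a1},{g_a2}}}"
        )
    if frozenset({e_a1, e_a2}) in PALINDROMIC_PAIRS:
        eaf = float(eqtl_rec["eaf"])
        if abs(eaf - 0.5) < ambiguous_eaf_band:
            warnings.warn(
                f"{eqtl_rec['variant_id']}: strand-ambiguous palindromic variant "
                f"with eaf {eaf:.3f}",
                stacklevel=2,
            )
            if drop_palindromic:
                return None
    b_zy = float(gwas_rec["beta"])
    if g_a1 != e_a1:
        b_zy = -b_zy
    return HarmonizedPair(
        variant_id=str(eqtl_rec["variant_id"]),
        effect_allele=e_a1,
        other_allele=e_a2,
        b_zx=float(eqtl_rec["beta"]),
        se_zx=float(eqtl_rec["se"]),
        b_zy=b_zy,
        se_zy=float(gwas_rec["se"]),
        inhibition_framed=frame_inhibition,
    )


def smr_test(pair: HarmonizedPair) -> SMRResult:
    """SMR chi-square test of the Wald ratio b_zy / b_zx.

    ``t_smr = z_zy^2 z_zx^2 / (z_zy^2 + z_zx^2)`` (1 df chi-square);
    ``se_xy = |b_xy| / sqrt(t_smr)`` (delta-method fallback at b_zy = 0).
    Inhibition framing negates the reported effect and interval only.
    """
    if pair.se_zx <= 0 or pair.se_zy <= 0:
        raise ValueError("standard errors must be positive")
    if pair.b_zx == 0:
        raise ValueError("b_zx = 0: Wald ratio undefined")
    b_xy = pair.b_zy / pair.b_zx
    z_zx2 = (pair.b_zx / pair.se_zx) ** 2
    z_zy2 = (pair.b_zy / pair.se_zy) ** 2
    if z_zy2 == 0.0:
        t_smr = 0.0
        # delta-method se at the null of the ratio
        se_xy = float(
            np.sqrt(
                pair.se_zy**2 / pair.b_zx**2
                + pair.b_zy**2 * pair.se_zx**2 / pair.b_zx**4
            )
        )
    else:
        t_smr = (z_zy2 * z_zx2) / (z_zy2 + z_zx2)
        se_xy = abs(b_xy) / np.sqrt(t_smr)
    p_smr = float(stats.chi2.sf(t_smr, df=1)) if t_smr > 0 else 1.0
    if pair.inhibition_framed:
        b_xy = -b_xy
    ci = (b_xy - 1.96 * se_xy, b_xy + 1.96 * se_xy)
    return SMRResult(b_xy=float(b_xy), se_xy=float(se_xy), ci95=ci, p_smr=p_smr, t_smr=float(t_smr))


def multiple_testing_threshold(n_genes: int, n_traits: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold over the gene x trait test grid."""
    if n_genes < 1 or n_traits < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_genes * n_traits)


# ---------------------------------------------------------------------------
# Quadratic forms in correlated normals
# ---------------------------------------------------------------------------


def quadform_tail(
    t: float,
    lambdas: np.ndarray,
    method: str = "imhof",
    rng: np.random.Generator | None = None,
    n_mc: int = 200_000,
) -> float:
    """Tail probability P(sum_k lambda_k chi2_1 > t).

    ``imhof`` integrates Imhof's inversion formula numerically (accurate);
    ``satterthwaite`` matches the first two moments to a scaled chi-square;
    ``mc`` simulates. Falls back from imhof to satterthwaite on integration
    failure.
    """
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[np.abs(lam) > 1e-12]
    if lam.size == 0 or t <= 0:
        return 1.0
    if lam.size == 1 and method != "mc":
        return float(stats.chi2.sf(t / lam[0], df=1))
    if method == "mc":
        rng = rng or np.random.default_rng(0)
        draws = rng.chisquare(1.0, size=(n_mc, lam.size)) @ lam
        return float(np.mean(draws > t))
    if method == "satterthwaite":
        s1, s2 = lam.sum(), (lam**2).sum()
        scale = s2 / s1
        df = s1**2 / s2
        return float(stats.chi2.sf(t / scale, df=df))
    if method != "imhof":
        raise ValueError(f"unknown method {method!r}")

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        rho = np.prod((1.0 + (lam * u) ** 2) ** 0.25)
        return float(np.sin(theta) / (u * rho))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", integrate.IntegrationWarning)
            val, _ = integrate.quad(integrand, 0.0, np.inf, limit=400)
        p = 0.5 + val / np.pi
    except Exception:  # pragma: no cover - defensive fallback
        logger.warning("Imhof integration failed; falling back to Satterthwaite")
        return quadform_tail(t, lam, method="satterthwaite")
    if not np.isfinite(p):
        return quadform_tail(t, lam, method="satterthwaite")
    return float(min(max(p, 0.0), 1.0))


# ---------------------------------------------------------------------------
# HEIDI
# ---------------------------------------------------------------------------


def _align_gwas_to_eqtl(eqtl_rec, gwas_rec) -> float:
    """GWAS beta recoded onto the eQTL's effect allele (sign flip if needed)."""
    if {str(eqtl_rec["effect_allele"]), str(eqtl_rec["other_allele"])} != {
        str(gwas_rec["effect_allele"]),
        str(gwas_rec["other_allele"]),
    }:
        raise ValueError(f"allele mismatch at {eqtl_rec['variant_id']}")
    b = float(gwas_rec["beta"])
    return b if str(gwas_rec["effect_allele"]) == str(eqtl_rec["effect_allele"]) else -b


def heidi_test(
    region_eqtl: SumStatsTable,
    region_gwas: SumStatsTable,
    ld: LdSource,
    top: Instrument,
    r2_window: tuple[float, float] = (0.05, 0.9),
    max_snps: int = 20,
    min_snps: int = 3,
    eqtl_chi2_min: float = 10.0,
    tail_method: str = "imhof",
) -> HEIDIResult:
    """Heterogeneity-in-dependent-instruments test around the top instrument.

    Candidate SNPs are region variants with eQTL chi-square above
    ``eqtl_chi2_min`` and LD r^2 with the top SNP inside ``r2_window``
    (strongest ``max_snps`` kept by eQTL p). Each candidate's Wald ratio is
    contrasted with the top SNP's; the differences are standardized with a
    delta-method covariance that carries the signed LD r between variants,
    and their squared sum is referred to a weighted-chi-square null via
    eigen-decomposition. Fewer than ``min_snps`` candidates flags the result
    not-computed.
    """
    edf = region_eqtl.records
    if top.variant_id not in edf.index:
        raise ValueError(f"top instrument {top.variant_id} absent from eQTL region")
    shared = [
        v
        for v in edf.index
        if v in region_gwas and v in ld.variant_ids and v != top.variant_id
    ]
    lo, hi = r2_window
    candidates = []
    for v in shared:
        rec = edf.loc[v]
        chi2_zx = (rec["beta"] / rec["se"]) ** 2
        r = ld.r(v, top.variant_id)
        if chi2_zx > eqtl_chi2_min and lo <= r**2 <= hi:
            candidates.append((float(rec["p"]), str(v)))
    candidates.sort()
    snps = [v for _, v in candidates[:max_snps]]
    if len(snps) < min_snps:
        return HEIDIResult(p_heidi=float("nan"), n_snps_used=len(snps), passed=False, computed=False)

    ids = [top.variant_id] + snps
    b_zx = np.array([float(edf.loc[v, "beta"]) for v in ids])
    se_zx = np.array([float(edf.loc[v, "se"]) for v in ids])
    b_zy = np.array([_align_gwas_to_eqtl(edf.loc[v], region_gwas.get(v)) for v in ids])
    se_zy = np.array([float(region_gwas.get(v)["se"]) for v in ids])
    R = ld.submatrix(ids)

    b_xy = b_zy / b_zx
    # delta-method covariance of the Wald ratios; eQTL and GWAS cohorts are
    # independent, so the two terms add.
    cov_zy = R * np.outer(se_zy, se_zy)
    cov_zx = R * np.outer(se_zx, se_zx)
    grad_y = 1.0 / b_zx
    grad_x = -b_zy / b_zx**2
    cov_xy = cov_zy * np.outer(grad_y, grad_y) + cov_zx * np.outer(grad_x, grad_x)

    m = len(snps)
    d = b_xy[1:] - b_xy[0]
    # cov(d_i, d_j) = cov_ij - cov_i0 - cov_j0 + var_0
    Vd = (
        cov_xy[1:, 1:]
        - cov_xy[1:, [0]]
        - cov_xy[[0], 1:]
        + cov_xy[0, 0]
    )
    sd = np.sqrt(np.diag(Vd))
    if np.any(sd <= 0):
        return HEIDIResult(p_heidi=float("nan"), n_snps_used=m, passed=False, computed=False)
    z_d = d / sd
    C = Vd / np.outer(sd, sd)
    T = float(np.sum(z_d**2))
    lam = np.linalg.eigvalsh((C + C.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    p = quadform_tail(T, lam, method=tail_method)
    return HEIDIResult(p_heidi=p, n_snps_used=m, passed=bool(p > 0.01), computed=True)
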