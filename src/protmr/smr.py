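"""Summary-data-based MR (SMR) and the HEIDI heterogeneity test.

SMR tests the protein-to-disease effect at the single top cis-pQTL
variant.  A significant SMR signal is consistent with causality or
pleiotropy at one shared variant, but also with linkage between two
distinct causal variants.  HEIDI (heterogeneity in dependent
instruments) separates the two: under a single shared causal variant,
the SMR ratio estimated at every variant in LD with the top variant
targets the same quantity, so deviations from the top-variant ratio
beyond sampling noise indicate linkage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedPair

# Eligibility conventions for the HEIDI variant set.
HEIDI_R2_MIN = 0.05
HEIDI_R2_MAX = 0.9
HEIDI_MAX_SNPS = 20
# z^2 > 10 instrument convention, i.e. pQTL p below this.
HEIDI_INSTRUMENT_P = float(2 * stats.norm.sf(np.sqrt(10.0)))  # 1.565e-3


@dataclass(frozen=True)
class SMRResult:
    """SMR estimate at the top cis variant plus the HEIDI p-value."""

    top_variant_id: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: Optional[float]
    n_heidi_snps: int


def smr_test(
    z_qtl: float, z_gwas: float, b_qtl: float, b_gwas: float
) -> tuple[float, float, float]:
    """SMR effect and test at one variant.

    b_SMR = b_GWAS / b_QTL; the test statistic
    T = z_GWAS²·z_QTL² / (z_GWAS² + z_QTL²) is referred to chi-square(1),
    and se_SMR = |b_SMR| / sqrt(T).
    """
    if b_qtl == 0:
        raise ValueError("b_qtl is zero; SMR effect undefined")
    b_smr = b_gwas / b_qtl
    zq2, zg2 = z_qtl ** 2, z_gwas ** 2
    if zq2 + zg2 == 0:
        return b_smr, float("inf"), 1.0
    t = zg2 * zq2 / (zg2 + zq2)
    p = float(stats.chi2.sf(t, 1))
    se = abs(b_smr) / np.sqrt(t) if t > 0 else float("inf")
    return b_smr, float(se), p


def top_variant(pairs: Sequence[HarmonizedPair]) -> HarmonizedPair:
    """The variant with the strongest pQTL association (largest |z_exp|)."""
    usable = [p for p in pairs if not p.dropped]
    if not usable:
        raise ValueError("no usable pairs at locus")
    return max(usable, key=lambda p: abs(p.beta_exp / p.se_exp))


def heidi_select(
    pairs: Sequence[HarmonizedPair],
    ld: pd.DataFrame,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    max_snps: int = HEIDI_MAX_SNPS,
    instrument_p: float = HEIDI_INSTRUMENT_P,
) -> list[str]:
    """Choose the HEIDI test set around the top variant.

    Eligible variants have r² with the top variant in [r2_min, r2_max]
    and a pQTL association with z² > 10 (p below ``instrument_p``);
    the list is truncated to the ``max_snps`` highest-r² variants.  The
    top variant itself is excluded.  Fewer than 3 eligible variants
    means HEIDI is not applicable (the caller records that).
    """
    usable = [p for p in pairs if not p.dropped]
    top = top_variant(usable)
    eligible: list[tuple[float, str]] = []
    for p in usable:
        if p.variant_id == top.variant_id:
            continue
        r2 = float(ld.loc[top.variant_id, p.variant_id]) ** 2
        if not (r2_min <= r2 <= r2_max):
            continue
        z2 = (p.beta_exp / p.se_exp) ** 2
        if z2 <= stats.chi2.isf(instrument_p, 1):
            continue
        eligible.append((r2, p.variant_id))
    eligible.sort(key=lambda t: (-t[0], t[1]))
    return [vid for _, vid in eligible[:max_snps]]


def heidi_test(
    selected: Sequence[HarmonizedPair],
    top: HarmonizedPair,
    ld: pd.DataFrame,
    ridge: float = 1e-8,
) -> float:
    """HEIDI p-value for heterogeneity of SMR ratios in an LD block.

    For each selected variant i, d_i = b_SMR(i) − b_SMR(top).  The
    covariance of d is propagated from the GWAS and pQTL sampling errors
    with the LD correlations (first-order delta method; the two traits
    come from non-overlapping samples and are independent).  The
    statistic Σ z_d_i² is a weighted sum of chi-squares whose weights
    are the eigenvalues of the correlation matrix of z_d; its tail
    probability is evaluated by Imhof characteristic-function inversion
    (see ``correlated_chisq_tail``).
    """
    m = len(selected)
    if m < 3:
        raise ValueError("HEIDI requires >= 3 selected variants")
    ids = [p.variant_id for p in selected]
    bq = np.array([p.beta_exp for p in selected])
    sq = np.array([p.se_exp for p in selected])
    bg = np.array([p.beta_out for p in selected])
    sg = np.array([p.se_out for p in selected])
    all_ids = ids + [top.variant_id]
    r = ld.loc[all_ids, all_ids].to_numpy(dtype=float)

    bq_t, sq_t = top.beta_exp, top.se_exp
    bg_t, sg_t = top.beta_out, top.se_out
    b_top = bg_t / bq_t
    d = bg / bq - b_top

    # delta-method covariance of the SMR ratios, including the top variant
    bq_all = np.append(bq, bq_t)
    sq_all = np.append(sq, sq_t)
    bg_all = np.append(bg, bg_t)
    sg_all = np.append(sg, sg_t)
    cov_g = r * np.outer(sg_all, sg_all)
    cov_q = r * np.outer(sq_all, sq_all)
    ratio_cov = (cov_g / np.outer(bq_all, bq_all)
                 + cov_q * np.outer(bg_all / bq_all ** 2, bg_all / bq_all ** 2))

    # cov(d_i, d_j) = cov(s_i,s_j) − cov(s_i,s_top) − cov(s_j,s_top) + var(s_top)
    s_cov = ratio_cov[:m, :m]
    s_top_cov = ratio_cov[:m, m]
    var_top = ratio_cov[m, m]
    cov_d = s_cov - s_top_cov[:, None] - s_top_cov[None, :] + var_top
    cov_d = cov_d + ridge * np.eye(m)

    sd = np.sqrt(np.diag(cov_d))
    z_d = d / sd
    corr = cov_d / np.outer(sd, sd)
    stat = float(np.sum(z_d ** 2))
    return correlated_chisq_tail(stat, corr)


def correlated_chisq_tail(stat: float, corr: np.ndarray) -> float:
    """P(Σ z_i² > stat) for z ~ N(0, corr).

    The quadratic form is a weighted sum of independent chi-square(1)
    variables with weights the eigenvalues of ``corr``.  The tail is
    evaluated by Imhof's numerical inversion of the characteristic
    function, falling back to a Satterthwaite-Welch two-moment
    chi-square approximation if the integration fails to converge."""
    eig = np.clip(np.linalg.eigvalsh(np.asarray(corr, dtype=float)), 0.0, None)
    eig = eig[eig > 1e-12]
    if eig.size == 0 or stat <= 0:
        return 1.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(eig * u)) - 0.5 * stat * u
        rho = np.exp(0.25 * np.sum(np.log1p((eig * u) ** 2)))
        return np.sin(theta) / (u * rho)

    try:
        import warnings
        from scipy.integrate import IntegrationWarning, quad
        with warnings.catch_warnings():
            # the oscillatory integrand can exhaust subdivisions; accuracy
            # is still guarded by the error estimate below
            warnings.simplefilter("ignore", IntegrationWarning)
            val, err = quad(integrand, 0.0, np.inf, limit=200)
        if np.isfinite(val) and err < 1e-4:
            return float(min(1.0, max(0.0, 0.5 + val / np.pi)))
    except Exception:
        pass
    mean = float(eig.sum())
    var = float(2.0 * np.sum(eig ** 2))
    g = var / (2.0 * mean)
    df = 2.0 * mean ** 2 / var
    return float(stats.chi2.sf(stat / g, df))


def classify_smr(p_smr: float, m_tests: int, p_heidi: Optional[float]) -> bool:
    """Pass iff SMR p < 0.05/m_tests (strict) and HEIDI p > 0.05.

    An undefined HEIDI p (too few eligible variants) fails the call."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    if p_heidi is None:
        return False
    return p_smr < 0.05 / m_tests and p_heidi > 0.05


def smr_heidi(
    pairs: Sequence[HarmonizedPair],
    ld: pd.DataFrame,
    r2_min: float = HEIDI_R2_MIN,
    r2_max: float = HEIDI_R2_MAX,
    max_snps: int = HEIDI_MAX_SNPS,
) -> SMRResult:
    """Run SMR at the top cis variant and HEIDI over its LD block."""
    top = top_variant(pairs)
    z_q = top.beta_exp / top.se_exp
    z_g = top.beta_out / top.se_out
    b, se, p = smr_test(z_q, z_g, top.beta_exp, top.beta_out)
    sel_ids = heidi_select(pairs, ld, r2_min, r2_max, max_snps)
    by_id = {pr.variant_id: pr for pr in pairs}
    selected = [by_id[v] for v in sel_ids]
    if len(selected) >= 3:
        p_heidi = heidi_test(selected, top, ld)
    else:
        p_heidi = None
    return SMRResult(top.variant_id, b, se, p, p_heidi, len(selected))
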