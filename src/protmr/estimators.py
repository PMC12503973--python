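"""Summary-data MR causal estimators and instrument-level diagnostics.

All estimators operate on harmonized exposure/outcome pairs and return
causal effects on the log scale (log-odds of disease per SD of protein
for a case-control outcome).  Exponentiation to odds ratios happens only
at report time.

Implemented methods: Wald ratio (single instrument), fixed-effect and
multiplicative-random-effects IVW, MR-Egger regression, weighted median,
simple and weighted mode, and MR-PRESSO.  Diagnostics: Cochran's Q and
the Egger intercept test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .sumstats import HarmonizedPair

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate on the log scale with a 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    extras: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass(frozen=True)
class Diagnostics:
    """Heterogeneity and pleiotropy diagnostics for one instrument set.

    Components that require more instruments than available are None.
    """

    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    egger_intercept: Optional[float] = None
    egger_intercept_se: Optional[float] = None
    egger_intercept_pval: Optional[float] = None
    presso_global_pval: Optional[float] = None
    presso_outliers: tuple[str, ...] = ()


class NotApplicable(Exception):
    """A method cannot be computed at this instrument count."""


def _usable(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if not p.dropped]


def _arrays(pairs: Sequence[HarmonizedPair]):
    pairs = _usable(pairs)
    be = np.array([p.beta_exp for p in pairs])
    se_e = np.array([p.se_exp for p in pairs])
    bo = np.array([p.beta_out for p in pairs])
    se_o = np.array([p.se_out for p in pairs])
    ids = [p.variant_id for p in pairs]
    return be, se_e, bo, se_o, ids


def _two_sided_normal_p(z: float) -> float:
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def _estimate(method: str, beta: float, se: float, pval: float,
              n_snp: int, **extras) -> MREstimate:
    return MREstimate(method, beta, se, beta - Z95 * se, beta + Z95 * se,
                      pval, n_snp, dict(extras))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate: beta_out / beta_exp.

    SE uses the first-order delta rule se_out/|beta_exp| (uncertainty in
    the exposure effect ignored, standard for a strong instrument).
    """
    if pair.beta_exp == 0:
        raise ValueError("beta_exp is zero; Wald ratio undefined")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    p = _two_sided_normal_p(beta / se)
    return _estimate("wald_ratio", beta, se, p, 1)


def _ratio_weights(pairs: Sequence[HarmonizedPair]):
    be, _, bo, se_o, _ = _arrays(pairs)
    if np.any(be == 0):
        raise ValueError("beta_exp of zero among instruments")
    ratios = bo / be
    weights = (be / se_o) ** 2  # 1 / (se_out/beta_exp)^2
    return ratios, weights


def ivw(pairs: Sequence[HarmonizedPair], mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted combination of per-variant ratio estimates.

    ``fixed``: SE = (Σ w_j)^(−1/2).
    ``multiplicative_random``: fixed SE inflated by
    max(1, sqrt(Q/(J−1))), absorbing residual overdispersion.
    """
    usable = _usable(pairs)
    if len(usable) < 2:
        raise ValueError("IVW requires >= 2 instruments; use wald_ratio")
    ratios, w = _ratio_weights(usable)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    method = "ivw_fe"
    if mode == "multiplicative_random":
        q = float(np.sum(w * (ratios - beta) ** 2))
        scale = max(1.0, math.sqrt(q / (len(usable) - 1)))
        se *= scale
        method = "ivw_mre"
    elif mode != "fixed":
        raise ValueError(f"unknown IVW mode {mode!r}")
    p = _two_sided_normal_p(beta / se)
    return _estimate(method, beta, se, p, len(usable))


def cochran_q(pairs: Sequence[HarmonizedPair]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic across ratio estimates.

    Q = Σ w_j (β_j − β_IVW)², chi-square with J−1 df under homogeneity.
    """
    usable = _usable(pairs)
    if len(usable) < 2:
        raise ValueError("Cochran's Q requires >= 2 instruments")
    ratios, w = _ratio_weights(usable)
    beta = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta) ** 2))
    df = len(usable) - 1
    p = float(stats.chi2.sf(q, df))
    return q, df, p


def egger(pairs: Sequence[HarmonizedPair]) -> tuple[MREstimate, float, float, float]:
    """MR-Egger regression: slope = pleiotropy-adjusted causal effect,
    intercept = average directional pleiotropy.

    Pairs are oriented so beta_exp >= 0 (both betas negated where
    needed), then beta_out is regressed on beta_exp with an intercept,
    weighted by 1/se_out².  SEs use multiplicative residual scaling
    floored at 1 and a t reference with J−2 df.

    Raises NotApplicable for fewer than 3 usable pairs.
    """
    usable = _usable(pairs)
    if len(usable) < 3:
        raise NotApplicable("MR-Egger requires >= 3 instruments")
    be, _, bo, se_o, _ = _arrays(usable)
    sign = np.where(be < 0, -1.0, 1.0)
    be, bo = be * sign, bo * sign
    if np.ptp(be) == 0:
        raise ValueError("degenerate design: all beta_exp equal after orientation")
    w = 1.0 / se_o ** 2
    X = np.column_stack([np.ones_like(be), be])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ bo)
    resid = bo - X @ coef
    df = len(usable) - 2
    sigma2 = float(np.sum(w * resid ** 2) / df)
    scale = max(1.0, sigma2)
    cov = np.linalg.inv(xtwx) * scale
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    intercept, slope = float(coef[0]), float(coef[1])
    p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df))
    p_int = float(2 * stats.t.sf(abs(intercept / se_int), df))
    tcrit = stats.t.ppf(0.975, df)
    est = MREstimate("egger", slope, se_slope,
                     slope - tcrit * se_slope, slope + tcrit * se_slope,
                     p_slope, len(usable),
                     {"intercept": intercept, "intercept_se": se_int,
                      "intercept_pval": p_int})
    return est, intercept, se_int, p_int


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(s, 0.5))
    # interpolate between the bracketing ratios
    frac = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
    return float(r[k - 1] + frac * (r[k] - r[k - 1]))


def weighted_median(
    pairs: Sequence[HarmonizedPair],
    n_boot: int = 5000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate (valid if instruments holding
    >= 50% of the weight are valid), SE by seeded parametric bootstrap."""
    usable = _usable(pairs)
    if len(usable) < 3:
        raise NotApplicable("weighted median requires >= 3 instruments")
    be, se_e, bo, se_o, _ = _arrays(usable)
    ratios, w = _ratio_weights(usable)
    point = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, se_o)
        be_b = np.where(be_b == 0, 1e-12, be_b)
        r_b = bo_b / be_b
        w_b = (be_b / se_o) ** 2
        boots[b] = _weighted_median_point(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    p = _two_sided_normal_p(point / se) if se > 0 else 1.0
    return _estimate("weighted_median", point, se, p, len(usable))


def _kde_mode(values: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Mode of a weighted normal-kernel density with Silverman bandwidth."""
    w = weights / weights.sum()
    n = len(values)
    s = float(np.std(values, ddof=1)) if n > 1 else 0.0
    if s == 0:
        return float(values[0])
    iqr = float(np.percentile(values, 75) - np.percentile(values, 25))
    spread = min(s, iqr / 1.34) if iqr > 0 else s
    h = phi * 0.9 * spread * n ** (-0.2)
    grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - values[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    pairs: Sequence[HarmonizedPair],
    kind: str = "simple",
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based causal estimate: the mode of the kernel-smoothed ratio
    density.  ``simple`` uses equal weights, ``weighted`` inverse-variance
    weights.  SE by seeded parametric bootstrap."""
    usable = _usable(pairs)
    if len(usable) < 3:
        raise NotApplicable("mode estimators require >= 3 instruments")
    if kind not in ("simple", "weighted"):
        raise ValueError(f"unknown mode kind {kind!r}")
    be, se_e, bo, se_o, _ = _arrays(usable)
    ratios, ivw_w = _ratio_weights(usable)
    w = ivw_w if kind == "weighted" else np.ones_like(ratios)
    point = _kde_mode(ratios, w, phi)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        be_b = rng.normal(be, se_e)
        bo_b = rng.normal(bo, se_o)
        be_b = np.where(be_b == 0, 1e-12, be_b)
        r_b = bo_b / be_b
        w_b = (be_b / se_o) ** 2 if kind == "weighted" else np.ones_like(r_b)
        boots[b] = _kde_mode(r_b, w_b, phi)
    se = float(np.std(boots, ddof=1))
    p = _two_sided_normal_p(point / se) if se > 0 else 1.0
    return _estimate(f"{kind}_mode", point, se, p, len(usable))


def _loo_ivw_betas(be, bo, se_o) -> np.ndarray:
    """Leave-one-out ratio-IVW slope for each instrument."""
    w = (be / se_o) ** 2
    ratios = bo / be
    num, den = np.sum(w * ratios), np.sum(w)
    out = np.empty(len(be))
    for j in range(len(be)):
        out[j] = (num - w[j] * ratios[j]) / (den - w[j])
    return out


def mr_presso(
    pairs: Sequence[HarmonizedPair],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> tuple[float, list[str], Optional[MREstimate]]:
    """MR-PRESSO: residual-sum-of-squares global pleiotropy test with
    outlier detection and an outlier-corrected IVW estimate.

    The observed RSS sums each instrument's inverse-variance-weighted
    squared deviation of beta_out from its leave-one-out IVW prediction.
    The null distribution is simulated by redrawing exposure effects
    around their observed values and outcome effects around the
    leave-one-out predictions, then recomputing the leave-one-out RSS on
    each simulated dataset — so the simulated statistic carries the same
    estimation noise as the observed one.  The empirical global p uses
    (1 + #{sim >= obs})/(n_sim + 1) so it is never zero.  Per-instrument
    outlier p-values compare each observed contribution with its own
    simulated contributions and are Bonferroni-adjusted by J.

    Returns (global p, outlier ids, corrected estimate or None if all
    instruments were flagged).
    """
    usable = _usable(pairs)
    j = len(usable)
    if j < 4:
        raise NotApplicable("MR-PRESSO requires >= 4 instruments")
    be, se_e, bo, se_o, ids = _arrays(usable)
    w = 1.0 / se_o ** 2
    loo = _loo_ivw_betas(be, bo, se_o)
    pred = loo * be
    obs_contrib = w * (bo - pred) ** 2
    obs_rss = float(obs_contrib.sum())

    rng = np.random.default_rng(seed)
    sim_be = rng.normal(be[None, :], se_e[None, :], size=(n_sim, j))
    sim_bo = rng.normal(loo[None, :] * sim_be, se_o[None, :], size=(n_sim, j))
    # vectorized leave-one-out IVW slope per simulated dataset
    sim_ratio = sim_bo / np.where(sim_be == 0, 1e-12, sim_be)
    sim_w = (sim_be / se_o[None, :]) ** 2
    num = np.sum(sim_w * sim_ratio, axis=1, keepdims=True)
    den = np.sum(sim_w, axis=1, keepdims=True)
    sim_loo = (num - sim_w * sim_ratio) / (den - sim_w)
    sim_contrib = w[None, :] * (sim_bo - sim_loo * sim_be) ** 2
    sim_rss = sim_contrib.sum(axis=1)
    global_p = float((1 + np.sum(sim_rss >= obs_rss)) / (n_sim + 1))

    per_snp_p = (1 + np.sum(sim_contrib >= obs_contrib[None, :], axis=0)) / (n_sim + 1)
    adj = np.minimum(1.0, per_snp_p * j)
    outliers = [ids[k] for k in range(j) if adj[k] < outlier_alpha]

    keep = [p for p in usable if p.variant_id not in set(outliers)]
    corrected: Optional[MREstimate] = None
    if len(keep) >= 2:
        base = ivw(keep, mode="fixed")
        corrected = MREstimate("presso_corrected", base.beta, base.se,
                               base.ci_low, base.ci_high, base.pval,
                               base.n_snp, {"n_outliers_removed": len(outliers)})
    elif len(keep) == 1:
        base = wald_ratio(keep[0])
        corrected = MREstimate("presso_corrected", base.beta, base.se,
                               base.ci_low, base.ci_high, base.pval,
                               1, {"n_outliers_removed": len(outliers)})
    return global_p, outliers, corrected


def compute_diagnostics(
    pairs: Sequence[HarmonizedPair],
    presso_n_sim: int = 1000,
    seed: int = 0,
) -> Diagnostics:
    """All diagnostics available at the current instrument count."""
    usable = _usable(pairs)
    kw: dict = {}
    if len(usable) >= 2:
        q, df, qp = cochran_q(usable)
        kw.update(q_stat=q, q_df=df, q_pval=qp)
    if len(usable) >= 3:
        try:
            _, b0, se0, p0 = egger(usable)
            kw.update(egger_intercept=b0, egger_intercept_se=se0,
                      egger_intercept_pval=p0)
        except ValueError:
            pass
    if len(usable) >= 4:
        gp, outliers, _ = mr_presso(usable, n_sim=presso_n_sim, seed=seed)
        kw.update(presso_global_pval=gp, presso_outliers=tuple(outliers))
    return Diagnostics(**kw)
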