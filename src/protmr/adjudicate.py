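"""Diagnostics-driven method selection, Bonferroni logic and meta-analysis.

The adjudication rule maps diagnostics to a primary method per protein:

* one instrument                    -> Wald ratio;
* no heterogeneity, no pleiotropy   -> IVW;
* heterogeneity only                -> the larger-p of {weighted median,
  multiplicative-random-effects IVW};
* pleiotropy only                   -> the larger-p of {MR-Egger,
  MR-PRESSO outlier-corrected};
* both                              -> the largest-p of all four.

Choosing the largest p-value among robust methods is deliberately
conservative: the reported estimate is the one its own robust method is
least confident about.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import math

import numpy as np
from scipy import stats

from .estimators import Diagnostics, MREstimate

# Candidate order doubles as the tie-break order.
_HET_ONLY = ("weighted_median", "ivw_mre")
_PLEIO_ONLY = ("egger", "presso_corrected")
_BOTH = ("weighted_median", "ivw_mre", "egger", "presso_corrected")


@dataclass
class AdjudicatedResult:
    """Primary estimate for one protein plus the audit trail behind it."""

    protein_id: str
    primary_method: Optional[str]
    primary_estimate: Optional[MREstimate]
    heterogeneity_detected: bool
    pleiotropy_detected: bool
    candidate_methods_considered: list[str]
    discovery_significant: bool = False
    replication_significant: dict[str, bool] = field(default_factory=dict)
    prioritized: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def inconclusive(self) -> bool:
        return self.primary_estimate is None


def detect_flags(
    diag: Diagnostics, alpha: float = 0.05
) -> tuple[bool, bool]:
    """Heterogeneity iff Q p < alpha; pleiotropy iff Egger-intercept p
    OR MR-PRESSO global p < alpha (strict).  A missing diagnostic counts
    as not-detected."""
    het = diag.q_pval is not None and diag.q_pval < alpha
    pleio = (
        (diag.egger_intercept_pval is not None and diag.egger_intercept_pval < alpha)
        or (diag.presso_global_pval is not None and diag.presso_global_pval < alpha)
    )
    return het, pleio


def choose_primary(
    protein_id: str,
    estimates: Mapping[str, MREstimate],
    flags: tuple[bool, bool],
    n_snp: int,
    alpha: float = 0.05,
) -> AdjudicatedResult:
    """Select the primary causal estimate per the adjudication rule.

    ``estimates`` maps method tags (wald_ratio, ivw_fe, ivw_mre, egger,
    weighted_median, presso_corrected, ...) to estimates; methods
    unavailable at this instrument count are simply absent and are
    excluded from the candidate set (recorded in ``notes``).
    Ties on p-value go to the method listed first.
    """
    het, pleio = flags
    notes: list[str] = []

    if n_snp == 1:
        candidates = ["wald_ratio"]
    elif not het and not pleio:
        candidates = ["ivw_fe"]
    elif het and not pleio:
        candidates = list(_HET_ONLY)
    elif pleio and not het:
        candidates = list(_PLEIO_ONLY)
    else:
        candidates = list(_BOTH)

    available = [m for m in candidates if m in estimates and estimates[m] is not None]
    for m in candidates:
        if m not in available:
            notes.append(f"method {m} unavailable (insufficient instruments)")

    if not available:
        notes.append("inconclusive: empty candidate set after exclusions")
        return AdjudicatedResult(protein_id, None, None, het, pleio,
                                 candidates, notes=notes)

    if len(available) == 1:
        chosen = available[0]
    else:
        # argmax p; ties resolved by candidate (listed) order
        best_p = max(estimates[m].pval for m in available)
        chosen = next(m for m in available if estimates[m].pval == best_p)

    return AdjudicatedResult(protein_id, chosen, estimates[chosen], het, pleio,
                             candidates, notes=notes)


def bonferroni_flag(
    pvals: Mapping[str, float], m: int, alpha: float = 0.05
) -> dict[str, bool]:
    """Significance at the family-wise level: p < alpha/m, strict."""
    if m < 1:
        raise ValueError("m must be >= 1")
    cut = alpha / m
    return {k: (p < cut) for k, p in pvals.items()}


def replication_consistency(
    discovery: AdjudicatedResult,
    replications: Sequence[AdjudicatedResult],
    require_direction: bool = True,
) -> bool:
    """Prioritize a protein iff its discovery association is significant,
    at least one replication passes its own Bonferroni, and (optionally)
    every significant replication estimate shares the discovery sign."""
    if not discovery.discovery_significant:
        return False
    sig_reps = [r for r in replications
                if r.discovery_significant and r.primary_estimate is not None]
    if not sig_reps:
        return False
    if require_direction and discovery.primary_estimate is not None:
        d_sign = math.copysign(1.0, discovery.primary_estimate.beta)
        for r in sig_reps:
            if math.copysign(1.0, r.primary_estimate.beta) != d_sign:
                return False
    return True


def meta_fixed(estimates: Sequence[MREstimate]) -> MREstimate:
    """Fixed-effect inverse-variance meta-analysis on the log-OR scale.

    A single estimate passes through unchanged (identity with a note in
    the extras)."""
    if len(estimates) == 0:
        raise ValueError("no estimates to pool")
    if len(estimates) == 1:
        e = estimates[0]
        return MREstimate("meta_fixed", e.beta, e.se, e.ci_low, e.ci_high,
                          e.pval, e.n_snp, {"k_studies": 1, "passthrough": True})
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    z95 = stats.norm.ppf(0.975)
    return MREstimate("meta_fixed", beta, se, beta - z95 * se, beta + z95 * se,
                      p, sum(e.n_snp for e in estimates),
                      {"k_studies": len(estimates)})
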