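"""Bayesian colocalization of two traits at a locus via approximate Bayes factors.

Under a single-causal-variant-per-trait assumption, five hypotheses are
enumerated over the M intersecting variants:

* H0 — no association with either trait;
* H1 / H2 — association with trait 1 / trait 2 only;
* H3 — both traits associated, distinct causal variants (linkage);
* H4 — both traits associated, one shared causal variant.

Per-variant evidence is the Wakefield approximate Bayes factor computed
from beta and SE, and posteriors combine per-hypothesis prior weights
p1, p2, p12 in log space with log-sum-exp for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

PRIOR_SD_QUANT = 0.15
PRIOR_SD_CC = 0.2
P1_DEFAULT = 1e-4
P2_DEFAULT = 1e-4
P12_DEFAULT = 1e-5


@dataclass
class LocusDataset:
    """Per-variant summary statistics for one trait at one locus."""

    variant_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    trait_type: str = "quantitative"
    n: Optional[float] = None
    case_fraction: Optional[float] = None

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.variant_ids) == len(self.beta) == len(self.se)):
            raise ValueError("variant_ids, beta, se must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("all SEs must be positive")

    @property
    def prior_sd(self) -> float:
        return PRIOR_SD_CC if self.trait_type == "case_control" else PRIOR_SD_QUANT


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    priors: tuple[float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])

    @property
    def modal_hypothesis(self) -> int:
        return int(np.argmax(self.as_array()))


def log_abf(beta, se, prior_sd_w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant.

    With z = beta/se, V = se², W = prior_sd_w² and r = W/(W+V):
    log ABF = 0.5·log(1−r) + 0.5·r·z².
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("SE must be positive")
    w = prior_sd_w ** 2
    v = se ** 2
    r = w / (w + v)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * r * z ** 2


def _intersect(d1: LocusDataset, d2: LocusDataset) -> tuple[LocusDataset, LocusDataset]:
    common = [v for v in d1.variant_ids if v in set(d2.variant_ids)]
    if not common:
        raise ValueError("no intersecting variants between datasets")
    idx1 = [d1.variant_ids.index(v) for v in common]
    idx2 = [d2.variant_ids.index(v) for v in common]
    sub1 = LocusDataset(common, d1.beta[idx1], d1.se[idx1], d1.trait_type,
                        d1.n, d1.case_fraction)
    sub2 = LocusDataset(common, d2.beta[idx2], d2.se[idx2], d2.trait_type,
                        d2.n, d2.case_fraction)
    return sub1, sub2


def coloc_abf(
    d1: LocusDataset,
    d2: LocusDataset,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    p12: float = P12_DEFAULT,
    prior_sd_1: Optional[float] = None,
    prior_sd_2: Optional[float] = None,
) -> ColocResult:
    """Enumerate the five hypotheses and return normalized posteriors.

    All sums are taken in log space.  With per-variant log ABFs l1, l2:

    * H1: log Σ_i exp(l1_i), weight p1 per configuration;
    * H2: symmetric;
    * H4: log Σ_i exp(l1_i + l2_i), weight p12;
    * H3: log [ (Σ e^{l1}) (Σ e^{l2}) − Σ e^{l1+l2} ], weight p1·p2
      (ordered pairs i ≠ j).  With a single variant H3 has zero mass.
    """
    d1, d2 = _intersect(d1, d2)
    m = len(d1.variant_ids)
    l1 = log_abf(d1.beta, d1.se, prior_sd_1 or d1.prior_sd)
    l2 = log_abf(d2.beta, d2.se, prior_sd_2 or d2.prior_sd)

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(p1) + lsum1
    lh2 = np.log(p2) + lsum2
    lh4 = np.log(p12) + lsum12

    if m >= 2:
        # Σ_{i≠j} e^{l1_i + l2_j} = (Σ e^{l1})(Σ e^{l2}) − Σ e^{l1_i+l2_i}
        both = lsum1 + lsum2
        delta = lsum12 - both
        if delta >= 0 or np.exp(delta) >= 1.0:
            lh3 = -np.inf  # degenerate: all cross-pair mass is on the diagonal
        else:
            lh3 = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(delta))
    else:
        lh3 = -np.inf

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(logs - logsumexp(logs))
    post = post / post.sum()
    return ColocResult(*post.tolist(), n_snps=m, priors=(p1, p2, p12))


def classify_coloc(result: ColocResult, pp4_threshold: float = 0.80) -> bool:
    """Shared-causal-variant call: PP4 strictly above the threshold."""
    return result.pp4 > pp4_threshold
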