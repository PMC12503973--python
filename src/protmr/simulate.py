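"""Synthetic paired pQTL / disease-GWAS summary statistics with known truth.

The generator works at the summary level: for a locus of m variants with
LD correlation matrix R and standardized joint causal effects b, the
expected marginal standardized effects are R·b and the sampled marginal
estimates are multivariate normal with covariance R/n_eff.  Per-allele
effects and SEs are recovered by dividing by the genotype SD
sqrt(2·f·(1−f)).  Case-control outcomes are simulated directly on the
log-odds scale with the effective sample size n·cf·(1−cf).

Five locus architectures cover every colocalization hypothesis:
H0 (no association), H1 (protein only), H2 (disease only), H3 (distinct
causal variants in LD — linkage), H4 (one shared causal variant, with
the disease effect gamma × the protein effect plus any direct effect).

``simulate_mr_protein`` generates independent post-clumping instruments
for the MR estimator suite, with controllable causal effect, directional
or balanced pleiotropy, planted outliers and instrument-strength band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair, VariantRecord
from .coloc import LocusDataset

# Default study scale, chosen to emulate a large proteogenomic cohort
# (tens of thousands of measured proteomes) and a biobank-scale
# case-control GWAS with a few percent cases.
N_EXPOSURE = 35_000
N_OUTCOME = 350_000
CASE_FRACTION = 0.03

ARCHITECTURES = ("H0_null", "H1_protein_only", "H2_disease_only",
                 "H3_linkage", "H4_shared")


@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth for one simulated locus."""

    architecture: str
    causal_exposure: tuple[int, ...]   # variant indices
    causal_outcome: tuple[int, ...]
    gamma: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    outlier_ids: tuple[str, ...] = ()
    seed: int = 0
    exposure_effect: float = 0.15      # standardized pQTL effect at causal variant
    outcome_effect: float = 0.15       # standardized log-odds effect for H2/H3

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "H4_shared":
            if set(self.causal_exposure) != set(self.causal_outcome) or not self.causal_exposure:
                raise ValueError("H4 requires an identical shared causal variant")
        if self.architecture == "H3_linkage":
            if set(self.causal_exposure) & set(self.causal_outcome):
                raise ValueError("H3 requires distinct causal variants")


@dataclass
class SimulatedStudy:
    """Paired exposure/outcome sumstats sharing an LD matrix, plus truth."""

    ld: pd.DataFrame
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    truth: ScenarioTruth

    def exposure_records(self) -> list[VariantRecord]:
        return _frame_to_records(self.exposure, "quantitative")

    def outcome_records(self) -> list[VariantRecord]:
        return _frame_to_records(self.outcome, "case_control")

    def exposure_locus(self) -> LocusDataset:
        return LocusDataset(list(self.exposure.variant_id),
                            self.exposure.beta.to_numpy(),
                            self.exposure.se.to_numpy(),
                            "quantitative")

    def outcome_locus(self) -> LocusDataset:
        return LocusDataset(list(self.outcome.variant_id),
                            self.outcome.beta.to_numpy(),
                            self.outcome.se.to_numpy(),
                            "case_control")

    def write(self, out_dir: str | Path) -> None:
        """Emit exposure.tsv / outcome.tsv / ld.tsv / truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.exposure.to_csv(out / "exposure.tsv", sep="\t", index=False)
        self.outcome.to_csv(out / "outcome.tsv", sep="\t", index=False)
        self.ld.to_csv(out / "ld.tsv", sep="\t")
        with open(out / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=2)


IDENTITY_DIALECT = {k: k for k in (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n", "n_case", "n_control")}


def _frame_to_records(df: pd.DataFrame, trait_type: str) -> list[VariantRecord]:
    recs = []
    for r in df.itertuples(index=False):
        recs.append(VariantRecord(
            variant_id=r.variant_id, chrom=str(r.chrom), pos=int(r.pos),
            effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=float(r.eaf), beta=float(r.beta), se=float(r.se),
            pval=float(r.pval), n=float(r.n),
            n_case=int(r.n_case) if "n_case" in df.columns and pd.notna(r.n_case) else None,
            n_control=int(r.n_control) if "n_control" in df.columns and pd.notna(r.n_control) else None,
            trait_type=trait_type))
    return recs


def make_ld(m: int, rho: float) -> pd.DataFrame:
    """AR(1) LD correlation matrix: entry (i,j) = rho^|i−j|.

    Symmetric positive definite for |rho| < 1; indexed by snp ids."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(m)
    mat = rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)
    ids = [f"snp{i:04d}" for i in range(m)]
    return pd.DataFrame(mat, index=ids, columns=ids)


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats
    return np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))


def _sample_trait(
    rng: np.random.Generator,
    r_chol: np.ndarray,
    b_std: np.ndarray,
    n_eff: float,
    geno_sd: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marginal per-allele beta-hat, SE and p for one trait."""
    r = r_chol @ r_chol.T
    mu_std = r @ b_std
    noise = r_chol @ rng.standard_normal(len(b_std)) / np.sqrt(n_eff)
    est_std = mu_std + noise
    beta = est_std / geno_sd
    se = 1.0 / (geno_sd * np.sqrt(n_eff))
    pvals = _two_sided_p(est_std * np.sqrt(n_eff))
    return beta, se, pvals


def simulate_locus(
    truth: ScenarioTruth,
    m: int = 50,
    rho: float = 0.7,
    n_exp: float = N_EXPOSURE,
    n_out: float = N_OUTCOME,
    case_fraction: float = CASE_FRACTION,
    seed: Optional[int] = None,
) -> SimulatedStudy:
    """Simulate one locus under the truth's architecture.

    Bit-for-bit reproducible from (arguments, seed); ``seed`` defaults
    to ``truth.seed``."""
    if not 0.0 < case_fraction < 1.0:
        raise ValueError("case_fraction must lie in (0,1)")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    ld = make_ld(m, rho)
    r = ld.to_numpy()
    r_chol = np.linalg.cholesky(r)
    ids = list(ld.index)

    eaf = rng.uniform(0.05, 0.95, size=m)
    geno_sd = np.sqrt(2.0 * eaf * (1.0 - eaf))

    b_exp = np.zeros(m)
    for i in truth.causal_exposure:
        b_exp[i] = truth.exposure_effect

    b_out = np.zeros(m)
    if truth.architecture == "H4_shared":
        direct = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd) \
            if truth.pleiotropy_sd > 0 or truth.pleiotropy_mean != 0 else 0.0
        for i in truth.causal_outcome:
            b_out[i] = truth.gamma * b_exp[i] + direct
    elif truth.architecture in ("H2_disease_only", "H3_linkage"):
        for i in truth.causal_outcome:
            b_out[i] = truth.outcome_effect

    n_eff_out = n_out * case_fraction * (1.0 - case_fraction)
    beta_e, se_e, p_e = _sample_trait(rng, r_chol, b_exp, n_exp, geno_sd)
    beta_o, se_o, p_o = _sample_trait(rng, r_chol, b_out, n_eff_out, geno_sd)

    pos = 1_000_000 + 1_000 * np.arange(m)
    base = dict(variant_id=ids, chrom="1", pos=pos,
                effect_allele="A", other_allele="G", eaf=eaf)
    exposure = pd.DataFrame({**base, "beta": beta_e, "se": se_e,
                             "pval": p_e, "n": float(n_exp)})
    n_case = int(round(n_out * case_fraction))
    outcome = pd.DataFrame({**base, "beta": beta_o, "se": se_o,
                            "pval": p_o, "n": float(n_out),
                            "n_case": n_case, "n_control": int(n_out) - n_case})
    return SimulatedStudy(ld, exposure, outcome, truth)


def standard_truth(
    architecture: str,
    m: int = 50,
    seed: int = 0,
    gamma: float = 0.3,
    exposure_effect: float = 0.15,
    outcome_effect: float = 0.15,
    linkage_separation: int = 2,
) -> ScenarioTruth:
    """Preset truth for an architecture: causal variant(s) mid-locus.

    H3 places the two causal variants ``linkage_separation`` positions
    apart (AR(1) r = rho^separation between them)."""
    mid = m // 2
    if architecture == "H0_null":
        ce, co = (), ()
    elif architecture == "H1_protein_only":
        ce, co = (mid,), ()
    elif architecture == "H2_disease_only":
        ce, co = (), (mid,)
    elif architecture == "H3_linkage":
        ce, co = (mid,), (mid + linkage_separation,)
    elif architecture == "H4_shared":
        ce, co = (mid,), (mid,)
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    return ScenarioTruth(architecture, ce, co, gamma=gamma, seed=seed,
                         exposure_effect=exposure_effect,
                         outcome_effect=outcome_effect)


def simulate_mr_protein(
    j_instruments: int = 20,
    gamma: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    outlier_fraction: float = 0.0,
    n_exp: float = N_EXPOSURE,
    n_out: float = N_OUTCOME,
    case_fraction: float = CASE_FRACTION,
    f_band: tuple[float, float] = (50.0, 500.0),
    outlier_scale: float = 10.0,
    seed: int = 0,
) -> tuple[list[HarmonizedPair], ScenarioTruth]:
    """Independent post-clumping instruments for the estimator suite.

    Exposure effect sizes target per-variant F uniformly in ``f_band``
    (R² = F/(N−2+F)).  Each instrument's outcome effect is
    gamma·beta_exp plus a direct (pleiotropic) effect drawn from
    Normal(pleiotropy_mean, pleiotropy_sd); a fraction of instruments
    additionally receive a large direct effect of ``outlier_scale``
    outcome SEs (random sign), with their ids recorded in the truth.
    """
    if j_instruments < 1:
        raise ValueError("j_instruments must be >= 1")
    rng = np.random.default_rng(seed)
    j = j_instruments
    eaf = rng.uniform(0.05, 0.95, size=j)
    geno_sd = np.sqrt(2.0 * eaf * (1.0 - eaf))

    f_target = rng.uniform(*f_band, size=j)
    r2 = f_target / (n_exp - 2.0 + f_target)
    beta_exp_true = np.sqrt(r2) / geno_sd * rng.choice([-1.0, 1.0], size=j)
    se_exp = 1.0 / (geno_sd * np.sqrt(n_exp))

    n_eff_out = n_out * case_fraction * (1.0 - case_fraction)
    se_out = 1.0 / (geno_sd * np.sqrt(n_eff_out))

    # Directional pleiotropy is defined on the exposure-increasing allele
    # (the Egger orientation): on the raw allele frame the direct effect
    # carries the sign of the exposure effect.
    direct = rng.normal(pleiotropy_mean, pleiotropy_sd, size=j) \
        if (pleiotropy_sd > 0 or pleiotropy_mean != 0) else np.zeros(j)
    direct = direct * np.sign(beta_exp_true)
    n_outlier = int(round(outlier_fraction * j))
    outlier_idx = rng.choice(j, size=n_outlier, replace=False) if n_outlier else np.array([], dtype=int)
    for i in outlier_idx:
        direct[i] += outlier_scale * se_out[i] * rng.choice([-1.0, 1.0])

    beta_out_true = gamma * beta_exp_true + direct
    beta_exp = rng.normal(beta_exp_true, se_exp)
    beta_out = rng.normal(beta_out_true, se_out)

    pairs = []
    for i in range(j):
        pairs.append(HarmonizedPair(
            variant_id=f"iv{i:03d}", effect_allele="A",
            beta_exp=float(beta_exp[i]), se_exp=float(se_exp[i]), eaf_exp=float(eaf[i]),
            beta_out=float(beta_out[i]), se_out=float(se_out[i]), eaf_out=float(eaf[i]),
            flag="aligned"))
    truth = ScenarioTruth(
        "H4_shared" if gamma != 0 else "H0_null",
        causal_exposure=tuple(range(j)) if gamma != 0 else (),
        causal_outcome=tuple(range(j)) if gamma != 0 else (),
        gamma=gamma, pleiotropy_mean=pleiotropy_mean,
        pleiotropy_sd=pleiotropy_sd,
        outlier_ids=tuple(f"iv{i:03d}" for i in sorted(outlier_idx)),
        seed=seed)
    return pairs, truth


def simulate_proteome(
    n_proteins: int = 50,
    fraction_causal: float = 0.1,
    gamma_causal: float = 0.3,
    j_instruments: int = 10,
    seed: int = 0,
    **protein_kwargs,
) -> tuple[dict[str, list[HarmonizedPair]], pd.DataFrame]:
    """Independent multi-protein study for pipeline-level power/FWER checks.

    A ``fraction_causal`` share of proteins get gamma = ``gamma_causal``,
    the rest gamma = 0.  Returns per-protein harmonized instrument sets
    and a truth table (protein_id, gamma, causal)."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    n_causal = int(round(fraction_causal * n_proteins))
    causal_set = set(rng.choice(n_proteins, size=n_causal, replace=False).tolist())
    studies: dict[str, list[HarmonizedPair]] = {}
    rows = []
    for i in range(n_proteins):
        pid = f"PROT{i:04d}"
        gamma = gamma_causal if i in causal_set else 0.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pairs, _ = simulate_mr_protein(
            j_instruments=j_instruments, gamma=gamma, seed=sub_seed,
            **protein_kwargs)
        studies[pid] = pairs
        rows.append({"protein_id": pid, "gamma": gamma, "causal": gamma != 0})
    return studies, pd.DataFrame(rows)
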