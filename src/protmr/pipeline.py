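"""Orchestration: discovery → replication → colocalization → SMR/HEIDI.

Per protein the full estimator suite is run on the harmonized
instrument set, diagnostics drive the adjudication rule, and Bonferroni
uses the count of proteins with a valid estimate as denominator.  The
final report mirrors the triangulation table: one row per
discovery-significant protein with the discovery OR and CI, replication
p, colocalization PP4, SMR effect and p, HEIDI p and the prioritized
flag.  Not-applicable stages propagate as "NA", never silent blanks.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .adjudicate import (AdjudicatedResult, bonferroni_flag, choose_primary,
                         detect_flags, meta_fixed, replication_consistency)
from .coloc import ColocResult, classify_coloc, coloc_abf
from .estimators import (Diagnostics, MREstimate, NotApplicable,
                         compute_diagnostics, egger, ivw, mode_estimate,
                         mr_presso, wald_ratio, weighted_median)
from .smr import SMRResult, classify_smr, smr_heidi
from .sumstats import HarmonizedPair


@dataclass
class ProteinAnalysis:
    """All estimates, diagnostics and the adjudicated primary result."""

    protein_id: str
    estimates: dict[str, MREstimate]
    diagnostics: Diagnostics
    result: AdjudicatedResult


def analyze_protein(
    protein_id: str,
    pairs: Sequence[HarmonizedPair],
    seed: int = 0,
    n_boot: int = 1000,
    presso_n_sim: int = 1000,
    alpha: float = 0.05,
) -> ProteinAnalysis:
    """Run every applicable estimator and adjudicate the primary method."""
    usable = [p for p in pairs if not p.dropped]
    estimates: dict[str, MREstimate] = {}
    j = len(usable)
    if j == 0:
        res = AdjudicatedResult(protein_id, None, None, False, False, [],
                                notes=["no qualified instrument"])
        return ProteinAnalysis(protein_id, {}, Diagnostics(), res)

    if j == 1:
        estimates["wald_ratio"] = wald_ratio(usable[0])
        diag = Diagnostics()
    else:
        estimates["ivw_fe"] = ivw(usable, "fixed")
        estimates["ivw_mre"] = ivw(usable, "multiplicative_random")
        if j >= 3:
            try:
                est, *_ = egger(usable)
                estimates["egger"] = est
            except (NotApplicable, ValueError):
                pass
            try:
                estimates["weighted_median"] = weighted_median(
                    usable, n_boot=n_boot, seed=seed)
            except NotApplicable:
                pass
            for kind in ("simple", "weighted"):
                try:
                    estimates[f"{kind}_mode"] = mode_estimate(
                        usable, kind, n_boot=max(200, n_boot // 5), seed=seed)
                except NotApplicable:
                    pass
        diag = compute_diagnostics(usable, presso_n_sim=presso_n_sim, seed=seed)
        if j >= 4:
            _, _, corrected = mr_presso(usable, n_sim=presso_n_sim, seed=seed)
            if corrected is not None:
                estimates["presso_corrected"] = corrected

    flags = detect_flags(diag, alpha)
    result = choose_primary(protein_id, estimates, flags, j, alpha)
    return ProteinAnalysis(protein_id, estimates, diag, result)


def run_discovery(
    studies: Mapping[str, Sequence[HarmonizedPair]],
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 500,
    presso_n_sim: int = 500,
) -> dict[str, ProteinAnalysis]:
    """Analyze every protein and apply Bonferroni with m = count of
    proteins holding a valid primary estimate."""
    analyses: dict[str, ProteinAnalysis] = {}
    for i, (pid, pairs) in enumerate(studies.items()):
        analyses[pid] = analyze_protein(
            pid, pairs, seed=seed + i, n_boot=n_boot,
            presso_n_sim=presso_n_sim, alpha=alpha)
    valid = {pid: a for pid, a in analyses.items() if a.result.primary_estimate}
    if not valid:
        reasons = {pid: "; ".join(a.result.notes) for pid, a in analyses.items()}
        raise RuntimeError(f"no protein with a qualified instrument: {reasons}")
    m = len(valid)
    flags = bonferroni_flag(
        {pid: a.result.primary_estimate.pval for pid, a in valid.items()},
        m, alpha)
    for pid, a in valid.items():
        a.result.discovery_significant = flags[pid]
        a.result.notes.append(f"bonferroni_m={m}")
    return analyses


def discovery_table(analyses: Mapping[str, ProteinAnalysis]) -> pd.DataFrame:
    """Per-protein discovery results (all proteins, valid or not)."""
    rows = []
    for pid, a in analyses.items():
        est = a.result.primary_estimate
        rows.append({
            "protein_id": pid,
            "method": a.result.primary_method or "NA",
            "n_snp": est.n_snp if est else 0,
            "beta": est.beta if est else float("nan"),
            "se": est.se if est else float("nan"),
            "or": math.exp(est.beta) if est else float("nan"),
            "or_ci_low": math.exp(est.ci_low) if est else float("nan"),
            "or_ci_high": math.exp(est.ci_high) if est else float("nan"),
            "pval": est.pval if est else float("nan"),
            "heterogeneity": a.result.heterogeneity_detected,
            "pleiotropy": a.result.pleiotropy_detected,
            "significant": a.result.discovery_significant,
            "notes": "; ".join(a.result.notes),
        })
    return pd.DataFrame(rows)


def _fmt(x, digits=6) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "NA"
    return f"{x:.{digits}g}"


def full_report(
    discovery: Mapping[str, ProteinAnalysis],
    replications: Mapping[str, Mapping[str, ProteinAnalysis]],
    coloc_results: Mapping[str, ColocResult],
    smr_results: Mapping[str, SMRResult],
    require_direction: bool = True,
    pp4_threshold: float = 0.80,
    smr_m_tests: Optional[int] = None,
) -> pd.DataFrame:
    """Triangulation table: one row per discovery-significant protein."""
    sig = {pid: a for pid, a in discovery.items()
           if a.result.discovery_significant}
    smr_m = smr_m_tests or max(1, len(sig))
    rows = []
    for pid, a in sig.items():
        est = a.result.primary_estimate
        reps = [r[pid].result for r in replications.values() if pid in r]
        rep_sig = [r for r in reps if r.discovery_significant and r.primary_estimate]
        prioritized = replication_consistency(
            a.result, reps, require_direction=require_direction)
        a.result.prioritized = prioritized
        best_rep_p = min((r.primary_estimate.pval for r in rep_sig), default=None)
        cres = coloc_results.get(pid)
        sres = smr_results.get(pid)
        rows.append({
            "protein_id": pid,
            "or_discovery": f"{math.exp(est.beta):.2f} "
                            f"({math.exp(est.ci_low):.2f}-{math.exp(est.ci_high):.2f})",
            "p_discovery": _fmt(est.pval),
            "p_replication": _fmt(best_rep_p),
            "pp_h4": _fmt(cres.pp4 if cres else None),
            "colocalized": classify_coloc(cres, pp4_threshold) if cres else "NA",
            "smr_beta": _fmt(sres.b_smr if sres else None),
            "smr_p": _fmt(sres.p_smr if sres else None),
            "heidi_p": _fmt(sres.p_heidi if sres else None),
            "smr_pass": classify_smr(sres.p_smr, smr_m, sres.p_heidi) if sres else "NA",
            "prioritized": prioritized,
        })
    df = pd.DataFrame(rows)
    assert df.protein_id.is_unique if len(df) else True
    return df


def make_manifest(config: dict, seed: int, version: str) -> dict:
    """Run manifest: config hash + seeds + software version."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config_hash": hashlib.sha256(blob).hexdigest(),
        "config": config,
        "seed": seed,
        "version": version,
    }
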