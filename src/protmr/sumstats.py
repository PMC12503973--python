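"""Reading, validation and allele harmonization of GWAS/pQTL summary statistics.

Exposure (protein level, SD units) and outcome (disease, log-odds) effects
must be expressed on the same effect allele before any two-sample MR step.
Harmonization flips outcome effects where the allele labels are swapped and
drops strand-ambiguous (palindromic) variants whose frequency cannot
disambiguate the strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd
import yaml

VALID_ALLELES = frozenset("ACGT")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

TraitType = Literal["quantitative", "case_control"]


class SumstatsConfigError(ValueError):
    """Raised when a column mapping does not cover the mandatory fields."""


class AlleleError(ValueError):
    """Raised for non-ACGT or otherwise invalid allele input."""


@dataclass(frozen=True)
class VariantRecord:
    """One variant's summary association for one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele``:
    log-odds for case-control traits, SD units for quantitative traits.
    Positions are 1-based.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: float
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    trait_type: TraitType = "quantitative"

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise AlleleError(f"invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise AlleleError(f"invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele identical")
        if not self.se > 0:
            raise ValueError("nonpositive SE")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError("EAF out of (0,1)")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError("p-value out of (0,1]")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one variant on a common effect allele.

    ``flag`` records what harmonization did: ``aligned`` (no change),
    ``flipped`` (outcome beta negated, EAF complemented),
    ``dropped_palindromic`` or ``dropped_mismatch`` (excluded with a reason).
    """

    variant_id: str
    effect_allele: str
    beta_exp: float
    se_exp: float
    eaf_exp: float
    beta_out: float
    se_out: float
    eaf_out: float
    flag: Literal["aligned", "flipped", "dropped_palindromic", "dropped_mismatch"]
    reason: str = ""

    @property
    def dropped(self) -> bool:
        return self.flag.startswith("dropped")


# Mandatory fields every dialect must map.  n_case / n_control are optional
# and only required for binary-trait colocalization priors.
_MANDATORY = (
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
)

_NUMERIC = ("pos", "eaf", "beta", "se", "pval", "n")


def load_dialect(path: str | Path) -> dict:
    """Load a YAML column-mapping config: field name -> column name."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_sumstats(
    path: str | Path,
    dialect: dict,
    trait_type: TraitType = "quantitative",
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Read delimited summary statistics into validated records.

    Parameters
    ----------
    path
        Tab- or comma-delimited text file with a header row.
    dialect
        Mapping of record field names to the file's column names.  Must
        cover variant_id, chrom, pos, effect_allele, other_allele, eaf,
        beta, se, pval, n.  May additionally map n_case and n_control.
    trait_type
        Applied to every record read from this file.

    Returns
    -------
    (records, rejections)
        Valid records in file order, and a DataFrame of rejected rows
        with columns ``row`` (0-based data row) and ``reason``.

    Raises
    ------
    SumstatsConfigError
        When a mandatory column named in the dialect is absent from the
        file, or the dialect omits a mandatory field.
    """
    missing_fields = [f for f in _MANDATORY if f not in dialect]
    if missing_fields:
        raise SumstatsConfigError(f"dialect missing fields: {missing_fields}")

    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing_cols = [dialect[f] for f in _MANDATORY if dialect[f] not in df.columns]
    if missing_cols:
        raise SumstatsConfigError(f"missing mandatory columns: {missing_cols}")

    records: list[VariantRecord] = []
    rejects: list[tuple[int, str]] = []
    for i in range(len(df)):
        raw = {f: df.iloc[i][dialect[f]] for f in _MANDATORY}
        try:
            parsed = {f: raw[f] for f in ("variant_id", "chrom")}
            ea = str(raw["effect_allele"]).upper()
            oa = str(raw["other_allele"]).upper()
            if len(ea) != 1 or len(oa) != 1:
                raise ValueError("multi-base allele (indels out of scope)")
            nums = {}
            for f in _NUMERIC:
                try:
                    nums[f] = float(raw[f])
                except (TypeError, ValueError):
                    raise ValueError(f"unparseable numeric in column {dialect[f]!r}")
            kwargs = dict(
                variant_id=str(raw["variant_id"]),
                chrom=str(raw["chrom"]),
                pos=int(nums["pos"]),
                effect_allele=ea,
                other_allele=oa,
                eaf=nums["eaf"],
                beta=nums["beta"],
                se=nums["se"],
                pval=nums["pval"],
                n=nums["n"],
                trait_type=trait_type,
            )
            for opt in ("n_case", "n_control"):
                if opt in dialect and dialect[opt] in df.columns:
                    val = df.iloc[i][dialect[opt]]
                    if pd.notna(val):
                        kwargs[opt] = int(float(val))
            rec = VariantRecord(**kwargs)
            rec.validate()
            records.append(rec)
        except (ValueError, AlleleError) as exc:
            rejects.append((i, str(exc)))

    rejections = pd.DataFrame(rejects, columns=["row", "reason"])
    return records, rejections


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous (A/T or C/G)."""
    ea, oa = effect_allele.upper(), other_allele.upper()
    if ea not in VALID_ALLELES or oa not in VALID_ALLELES:
        raise AlleleError(f"non-ACGT allele in ({effect_allele}, {other_allele})")
    return _COMPLEMENT[ea] == oa


def _check_unique(records: Iterable[VariantRecord], label: str) -> dict[str, VariantRecord]:
    out: dict[str, VariantRecord] = {}
    for rec in records:
        if rec.variant_id in out:
            raise ValueError(f"duplicate variant_id {rec.variant_id!r} in {label}")
        out[rec.variant_id] = rec
    return out


def harmonize(
    exposure: list[VariantRecord],
    outcome: list[VariantRecord],
    palindromic_eaf_limit: float = 0.42,
) -> list[HarmonizedPair]:
    """Place outcome effects on the exposure's effect allele.

    For each exposure variant:

    * outcome alleles identical -> ``aligned``;
    * outcome alleles swapped -> negate outcome beta, complement its EAF,
      ``flipped``;
    * palindromic pair with either trait's EAF inside
      ``[palindromic_eaf_limit, 1 - palindromic_eaf_limit]`` ->
      ``dropped_palindromic`` (strand unresolvable by frequency); outside
      that band, alignment by frequency: if the outcome EAF sits on the
      opposite side of 0.5 from the exposure EAF the outcome is flipped;
    * variant absent from the outcome, or alleles incompatible ->
      ``dropped_mismatch``.

    Every exposure variant appears exactly once in the output.
    """
    out_by_id = _check_unique(outcome, "outcome")
    _check_unique(exposure, "exposure")
    pairs: list[HarmonizedPair] = []
    for exp in exposure:
        out = out_by_id.get(exp.variant_id)
        if out is None:
            pairs.append(HarmonizedPair(
                exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                float("nan"), float("nan"), float("nan"),
                "dropped_mismatch", "absent from outcome"))
            continue

        palindrome = is_palindromic(exp.effect_allele, exp.other_allele)
        same = (out.effect_allele == exp.effect_allele
                and out.other_allele == exp.other_allele)
        swapped = (out.effect_allele == exp.other_allele
                   and out.other_allele == exp.effect_allele)

        if palindrome:
            # same/swapped are indistinguishable from strand flips; use EAF
            lo, hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
            if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                pairs.append(HarmonizedPair(
                    exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                    float("nan"), float("nan"), float("nan"),
                    "dropped_palindromic", "ambiguous frequency"))
                continue
            if not (same or swapped):
                pairs.append(HarmonizedPair(
                    exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                    float("nan"), float("nan"), float("nan"),
                    "dropped_mismatch", "incompatible alleles"))
                continue
            flip = (exp.eaf < 0.5) != (out.eaf < 0.5)
            if flip:
                pairs.append(HarmonizedPair(
                    exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                    -out.beta, out.se, 1.0 - out.eaf, "flipped"))
            else:
                pairs.append(HarmonizedPair(
                    exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                    out.beta, out.se, out.eaf, "aligned"))
            continue

        if same:
            pairs.append(HarmonizedPair(
                exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                out.beta, out.se, out.eaf, "aligned"))
        elif swapped:
            pairs.append(HarmonizedPair(
                exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                -out.beta, out.se, 1.0 - out.eaf, "flipped"))
        else:
            pairs.append(HarmonizedPair(
                exp.variant_id, exp.effect_allele, exp.beta, exp.se, exp.eaf,
                float("nan"), float("nan"), float("nan"),
                "dropped_mismatch", "incompatible alleles"))
    return pairs


def pairs_to_frame(pairs: list[HarmonizedPair]) -> pd.DataFrame:
    """Harmonized pairs as a DataFrame (TSV-ready, flag column included)."""
    return pd.DataFrame([{
        "variant_id": p.variant_id,
        "effect_allele": p.effect_allele,
        "beta_exp": p.beta_exp, "se_exp": p.se_exp, "eaf_exp": p.eaf_exp,
        "beta_out": p.beta_out, "se_out": p.se_out, "eaf_out": p.eaf_out,
        "flag": p.flag, "reason": p.reason,
    } for p in pairs])
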