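"""High-functional-impact (HFI) variant triage.

A variant is eligible if its consequence is exonic non-synonymous (missense,
frameshift, nonsense), UTR, or splice-site. An eligible variant is HFI if it
meets the first matching criterion of an ordered cascade:

  A. ClinVar Pathogenic or Likely pathogenic;
  B. rare: population MAF (ExAC non-Finnish European) < 0.005, absent
     frequency counting as 0;
  C. mid-frequency: MAF in [0.005, 0.05] and CADD > 20.

Benign/likely-benign ClinVar labels do not veto criteria B/C: "VUS" is read
operationally as "not ClinVar P/LP", so a common-but-deleterious allele
(high CADD, mid MAF) still triages in via C.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .callset import VariantAnnotation, VariantCall

CONSEQUENCE_CLASSES = ("exonic_nonsynonymous", "utr", "splice_site", "other")

# synonym table across common annotation vocabularies (VEP, ANNOVAR, free text)
DEFAULT_CONSEQUENCE_SYNONYMS: dict[str, str] = {
    # exonic non-synonymous: missense / frameshift / nonsense
    "missense_variant": "exonic_nonsynonymous",
    "missense": "exonic_nonsynonymous",
    "nonsynonymous snv": "exonic_nonsynonymous",
    "nonsynonymous_snv": "exonic_nonsynonymous",
    "exonic non-synonymous": "exonic_nonsynonymous",
    "exonic nonsynonymous": "exonic_nonsynonymous",
    "stopgain": "exonic_nonsynonymous",
    "stop_gained": "exonic_nonsynonymous",
    "stoploss": "exonic_nonsynonymous",
    "stop_lost": "exonic_nonsynonymous",
    "nonsense": "exonic_nonsynonymous",
    "frameshift": "exonic_nonsynonymous",
    "frameshift_variant": "exonic_nonsynonymous",
    "frameshift insertion": "exonic_nonsynonymous",
    "frameshift deletion": "exonic_nonsynonymous",
    "frameshift_insertion": "exonic_nonsynonymous",
    "frameshift_deletion": "exonic_nonsynonymous",
    # UTR
    "utr": "utr",
    "utr5": "utr",
    "utr3": "utr",
    "5_prime_utr_variant": "utr",
    "3_prime_utr_variant": "utr",
    "5' utr": "utr",
    "3' utr": "utr",
    # splice site
    "splicing": "splice_site",
    "splice-site": "splice_site",
    "splice_site": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    # explicit exclusions
    "synonymous snv": "other",
    "synonymous_snv": "other",
    "synonymous": "other",
    "synonymous_variant": "other",
    "intronic": "other",
    "intron_variant": "other",
    "intergenic": "other",
}

HFI_CRITERIA = ("A_clinvar_plp", "B_rare_vus", "C_midfreq_cadd", "none")


@dataclass(frozen=True)
class HfiThresholds:
    """Tunable cascade cut-offs (defaults follow the published triage rules)."""

    maf_rare: float = 0.005   # strict upper bound for criterion B
    maf_max: float = 0.05     # closed upper bound for criterion C
    cadd_min: float = 20.0    # strict lower bound for criterion C


@dataclass(frozen=True)
class HfiVerdict:
    is_hfi: bool
    criterion: str  # one of HFI_CRITERIA
    consequence_class: str
    inputs_used: tuple[str, Optional[float], Optional[float]]  # clinvar, maf, cadd

    def __post_init__(self) -> None:
        assert self.is_hfi == (self.criterion != "none")


def classify_consequence(
    annotation: VariantAnnotation,
    synonyms: Optional[dict[str, str]] = None,
) -> str:
    """Map a raw consequence string onto the four-class vocabulary.

    Matching is case-insensitive; comma-separated multi-consequence strings
    take the most severe class present (exonic > splice > UTR > other).
    Empty strings map to "other" with a warning.
    """
    table = DEFAULT_CONSEQUENCE_SYNONYMS if synonyms is None else synonyms
    raw = (annotation.consequence or "").strip()
    if not raw:
        warnings.warn("empty consequence string; classifying as 'other'")
        return "other"
    severity = {"exonic_nonsynonymous": 0, "splice_site": 1, "utr": 2, "other": 3}
    best = "other"
    for token in raw.split(","):
        cls = table.get(token.strip().lower(), "other")
        if severity[cls] < severity[best]:
            best = cls
    return best


def is_hfi(
    v: VariantCall | VariantAnnotation,
    thresholds: HfiThresholds = HfiThresholds(),
    synonyms: Optional[dict[str, str]] = None,
) -> HfiVerdict:
    """Apply the triage cascade to one variant; first matching criterion wins.

    An absent MAF is treated as frequency 0 (never observed in the reference
    population), so unannotated variants qualify as rare under criterion B.
    An absent CADD simply fails criterion C.
    """
    ann = v.annotation if isinstance(v, VariantCall) else v
    cls = classify_consequence(ann, synonyms)
    inputs = (ann.clinvar_sig, ann.maf_exac_nfe, ann.cadd)
    if cls == "other":
        return HfiVerdict(False, "none", cls, inputs)
    if ann.clinvar_sig in ("Pathogenic", "Likely_pathogenic"):
        return HfiVerdict(True, "A_clinvar_plp", cls, inputs)
    maf = ann.maf_exac_nfe if ann.maf_exac_nfe is not None else 0.0
    if maf < thresholds.maf_rare:
        return HfiVerdict(True, "B_rare_vus", cls, inputs)
    if maf <= thresholds.maf_max and ann.cadd is not None and ann.cadd > thresholds.cadd_min:
        return HfiVerdict(True, "C_midfreq_cadd", cls, inputs)
    return HfiVerdict(False, "none", cls, inputs)


def classify_callset(
    calls: Sequence[VariantCall],
    thresholds: HfiThresholds = HfiThresholds(),
    synonyms: Optional[dict[str, str]] = None,
) -> tuple[list[VariantCall], pd.DataFrame]:
    """Partition a callset into HFI calls plus a per-call verdict table.

    The verdict table has one row per input call with the variant key, the
    consequence class, the winning criterion, and the boolean verdict;
    criterion counts are recoverable by value_counts on the criterion column.
    """
    verdicts = [is_hfi(c, thresholds, synonyms) for c in calls]
    hfi_calls = [c for c, vd in zip(calls, verdicts) if vd.is_hfi]
    table = pd.DataFrame(
        {
            "chrom": [c.chrom for c in calls],
            "pos": [c.pos_1based for c in calls],
            "ref": [c.ref for c in calls],
            "alt": [c.alt for c in calls],
            "sample_id": [c.sample_id for c in calls],
            "platform": [c.platform for c in calls],
            "consequence_class": [vd.consequence_class for vd in verdicts],
            "criterion": [vd.criterion for vd in verdicts],
            "is_hfi": [vd.is_hfi for vd in verdicts],
        }
    )
    return hfi_calls, table


def verdicts_for(annotations: Iterable[VariantAnnotation],
                 thresholds: HfiThresholds = HfiThresholds()) -> list[HfiVerdict]:
    """Convenience wrapper for annotation-only triage (e.g. published rows)."""
    return [is_hfi(a, thresholds) for a in annotations]
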