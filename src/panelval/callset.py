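"""Annotated variant callsets: parsing, normalization, matching and filtering.

A callset is a flat list of :class:`VariantCall` records, one per sample x
platform x alternate allele. Variants are matched across platforms by the
normalized key (chrom, pos, ref, alt); indels are left-normalized to the
unique left-most minimal representation before matching.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Protocol, Sequence

import pandas as pd

from .intervals import PanelDesign

CLINVAR_LEVELS = (
    "Pathogenic",
    "Likely_pathogenic",
    "Uncertain",
    "Conflicting",
    "Likely_benign",
    "Benign",
    "Not_found",
)

# case-insensitive synonyms across ClinVar / annotation-server dialects
_CLINVAR_SYNONYMS = {
    "pathogenic": "Pathogenic",
    "likely pathogenic": "Likely_pathogenic",
    "likely_pathogenic": "Likely_pathogenic",
    "uncertain": "Uncertain",
    "uncertain significance": "Uncertain",
    "uncertain_significance": "Uncertain",
    "vus": "Uncertain",
    "conflicting": "Conflicting",
    "conflicting interpretations of pathogenicity": "Conflicting",
    "conflicting_interpretations_of_pathogenicity": "Conflicting",
    "conflicting interpretations": "Conflicting",
    "likely benign": "Likely_benign",
    "likely_benign": "Likely_benign",
    "benign": "Benign",
    "not_found": "Not_found",
    "not found": "Not_found",
    ".": "Not_found",
    "": "Not_found",
}

_BASES = frozenset("ACGT")


class CallsetError(ValueError):
    """Raised for malformed callset records or files."""


def normalize_clinvar_sig(raw: Optional[str]) -> str:
    """Map a free-text clinical-significance string onto the closed enum."""
    if raw is None:
        return "Not_found"
    key = str(raw).strip().lower()
    if key in _CLINVAR_SYNONYMS:
        return _CLINVAR_SYNONYMS[key]
    if key.title().replace(" ", "_") in CLINVAR_LEVELS:
        return key.title().replace(" ", "_")
    warnings.warn(f"unrecognized ClinVar significance {raw!r}; mapping to Not_found")
    return "Not_found"


@dataclass
class VariantAnnotation:
    """Functional annotations attached to a call (all inputs, never computed here
    except optional GC content from a reference window)."""

    consequence: str = ""
    clinvar_sig: str = "Not_found"
    maf_exac_nfe: Optional[float] = None
    cadd: Optional[float] = None
    gene: str = ""
    rsid: Optional[str] = None
    gc_content_pct: Optional[float] = None
    repeat_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.clinvar_sig not in CLINVAR_LEVELS:
            self.clinvar_sig = normalize_clinvar_sig(self.clinvar_sig)
        if self.maf_exac_nfe is not None and not (0.0 <= self.maf_exac_nfe <= 1.0):
            raise CallsetError(f"MAF must lie in [0,1], got {self.maf_exac_nfe}")


@dataclass
class VariantCall:
    chrom: str
    pos_1based: int
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    filter_pass: bool
    platform: str
    sample_id: str
    annotation: VariantAnnotation = field(default_factory=VariantAnnotation)

    def __post_init__(self) -> None:
        if self.pos_1based < 1:
            raise CallsetError(f"position must be >= 1, got {self.pos_1based}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= _BASES:
                raise CallsetError(f"{label} allele must be a non-empty A/C/G/T string, got {allele!r}")
        if self.ref == self.alt:
            raise CallsetError(f"ref and alt are identical at {self.chrom}:{self.pos_1based}")
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise CallsetError(f"alt_fraction must lie in [0,1], got {self.alt_fraction}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self)


def variant_key(v: VariantCall) -> tuple[str, int, str, str]:
    """Matching key: (chrom, pos, ref, alt). Calls match iff keys are equal."""
    return (v.chrom, v.pos_1based, v.ref, v.alt)


class SequenceAccessor(Protocol):
    """Anything providing reference bases as fetch(chrom, start0, end0) -> str."""

    def fetch(self, chrom: str, start0: int, end0: int) -> str: ...


class DictReference:
    """In-memory reference: mapping chrom -> sequence string (position 0 = base 1)."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = {c: s.upper() for c, s in seqs.items()}

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self.seqs[chrom][start0:end0]


def left_normalize(v: VariantCall, reference: SequenceAccessor) -> VariantCall:
    """Return the unique left-most minimal representation of a variant.

    Shared trailing bases are trimmed (extending left through the reference
    when an allele would empty), then shared leading bases are trimmed. SNVs
    are fixed points. Raises on REF/reference disagreement.
    """
    pos0 = v.pos_1based - 1
    ref, alt = v.ref, v.alt
    observed = reference.fetch(v.chrom, pos0, pos0 + len(ref))
    if observed != ref:
        raise CallsetError(
            f"REF mismatch at {v.chrom}:{v.pos_1based}: call says {ref!r}, reference has {observed!r}"
        )
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos0 == 0:
                    raise CallsetError(f"cannot left-extend past chromosome start at {v.chrom}:1")
                pos0 -= 1
                base = reference.fetch(v.chrom, pos0, pos0 + 1)
                ref, alt = base + ref, base + alt
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    if (v.pos_1based, v.ref, v.alt) == (pos0 + 1, ref, alt):
        return v
    return replace(v, pos_1based=pos0 + 1, ref=ref, alt=alt)


# ---------------------------------------------------------------------------
# Filters (each returns a new list; all are order-independent set filters)
# ---------------------------------------------------------------------------

def restrict_to_targets(calls: Iterable[VariantCall], design: PanelDesign) -> list[VariantCall]:
    """Keep calls whose anchor (left-most, 1-based) base lies in a target."""
    return [c for c in calls if design.contains(c.chrom, c.pos_1based)]


def apply_depth_filter(calls: Iterable[VariantCall], min_depth: int = 10) -> list[VariantCall]:
    """Keep calls with read depth >= min_depth (the 10x cutoff convention)."""
    return [c for c in calls if c.depth >= min_depth]


def apply_af_filter(
    calls: Iterable[VariantCall],
    min_fraction: float = 0.20,
    platforms: frozenset[str] = frozenset({"WES"}),
) -> list[VariantCall]:
    """Drop calls of the listed platforms with alt-read fraction below the cutoff.

    The fraction filter is part of the exome pipeline only by default; calls
    from other platforms pass through untouched.
    """
    return [
        c for c in calls
        if c.platform not in platforms or c.alt_fraction >= min_fraction
    ]


def apply_pass_filter(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Keep only calls that passed their platform pipeline filter (e.g. VQSR)."""
    return [c for c in calls if c.filter_pass]


def compute_gc_content(reference: SequenceAccessor, chrom: str, pos_1based: int,
                       window: int = 50) -> float:
    """Percent G+C in a (2*window+1) bp reference window centered on the variant."""
    start = max(0, pos_1based - 1 - window)
    seq = reference.fetch(chrom, start, pos_1based + window)
    if not seq:
        raise CallsetError(f"no reference sequence at {chrom}:{pos_1based}")
    gc = sum(1 for b in seq if b in "GC")
    return 100.0 * gc / len(seq)


# ---------------------------------------------------------------------------
# Flat-TSV and VCF I/O
# ---------------------------------------------------------------------------

TSV_COLUMNS = [
    "sample_id", "platform", "chrom", "pos", "ref", "alt", "depth",
    "alt_fraction", "filter_pass", "rsid", "consequence", "clinvar_sig",
    "maf_exac_nfe", "cadd", "gene", "gc_pct", "repeat_flag",
]


def _opt_float(val) -> Optional[float]:
    if val is None or (isinstance(val, float) and pd.isna(val)) or val in (".", ""):
        return None
    return float(val)


def read_callset_tsv(path, platform: Optional[str] = None) -> list[VariantCall]:
    """Read the flat callset TSV dialect (see TSV_COLUMNS)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str, "gene": str})
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise CallsetError(f"{path}: missing columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        if platform is not None and row.platform != platform:
            continue
        try:
            ann = VariantAnnotation(
                consequence="" if pd.isna(row.consequence) else str(row.consequence),
                clinvar_sig="Not_found" if pd.isna(row.clinvar_sig) else str(row.clinvar_sig),
                maf_exac_nfe=_opt_float(row.maf_exac_nfe),
                cadd=_opt_float(row.cadd),
                gene="" if pd.isna(row.gene) else str(row.gene),
                rsid=None if pd.isna(row.rsid) else str(row.rsid),
                gc_content_pct=_opt_float(row.gc_pct),
                repeat_flag=None if pd.isna(row.repeat_flag) else bool(row.repeat_flag),
            )
            calls.append(VariantCall(
                chrom=str(row.chrom), pos_1based=int(row.pos), ref=str(row.ref),
                alt=str(row.alt), depth=int(row.depth),
                alt_fraction=float(row.alt_fraction),
                filter_pass=bool(row.filter_pass), platform=str(row.platform),
                sample_id=str(row.sample_id), annotation=ann,
            ))
        except (CallsetError, ValueError) as exc:
            raise CallsetError(f"{path}: line {i}: {exc}") from exc
    return calls


def write_callset_tsv(calls: Sequence[VariantCall], path) -> None:
    rows = []
    for c in calls:
        a = c.annotation
        rows.append({
            "sample_id": c.sample_id, "platform": c.platform, "chrom": c.chrom,
            "pos": c.pos_1based, "ref": c.ref, "alt": c.alt, "depth": c.depth,
            "alt_fraction": c.alt_fraction, "filter_pass": c.filter_pass,
            "rsid": a.rsid, "consequence": a.consequence,
            "clinvar_sig": a.clinvar_sig, "maf_exac_nfe": a.maf_exac_nfe,
            "cadd": a.cadd, "gene": a.gene, "gc_pct": a.gc_content_pct,
            "repeat_flag": a.repeat_flag,
        })
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


DEFAULT_VCF_INFO_KEYS = {
    "clinvar_sig": "CLNSIG",
    "cadd": "CADD",
    "maf_exac_nfe": "MAF",
    "consequence": "CSQ",
    "gene": "GENE",
    "gc_pct": "GC_PCT",
    "repeat_flag": "REPEAT",
}


def read_callset_vcf(path, platform: str, sample_id: Optional[str] = None,
                     info_keys: Optional[dict[str, str]] = None) -> list[VariantCall]:
    """Read an annotated VCF into a callset.

    Multi-allelic records are split into one call per alternate allele. Depth
    comes from INFO/DP, alt fraction from INFO/AF (one value per alt), and the
    annotation fields from the configurable INFO key map.
    """
    import pysam

    keys = dict(DEFAULT_VCF_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    def info_get(info, key, default=None):
        # pysam raises on INFO keys absent from the header, not just the record
        try:
            return info.get(key, default)
        except (KeyError, ValueError):
            return default

    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        sid = sample_id or (list(vcf.header.samples)[0] if list(vcf.header.samples) else "sample")
        for rec in vcf:
            info = rec.info
            afs = info_get(info, "AF")
            for j, alt in enumerate(rec.alts or ()):
                if set(alt.upper()) - _BASES:
                    continue  # symbolic / spanning-deletion alleles are out of scope
                af = afs[j] if isinstance(afs, tuple) else (afs if afs is not None else 0.5)
                raw_csq = info_get(info, keys["consequence"], "")
                csq = ",".join(raw_csq) if isinstance(raw_csq, tuple) else str(raw_csq)
                raw_sig = info_get(info, keys["clinvar_sig"], "Not_found")
                sig = raw_sig[0] if isinstance(raw_sig, tuple) else str(raw_sig)
                ann = VariantAnnotation(
                    consequence=csq,
                    clinvar_sig=normalize_clinvar_sig(sig),
                    maf_exac_nfe=_opt_float(_scalar(info_get(info, keys["maf_exac_nfe"]))),
                    cadd=_opt_float(_scalar(info_get(info, keys["cadd"]))),
                    gene=str(_scalar(info_get(info, keys["gene"], "")) or ""),
                    rsid=rec.id,
                    gc_content_pct=_opt_float(_scalar(info_get(info, keys["gc_pct"]))),
                    repeat_flag=bool(info_get(info, keys["repeat_flag"], False)) or None,
                )
                calls.append(VariantCall(
                    chrom=rec.chrom, pos_1based=rec.pos, ref=rec.ref, alt=alt,
                    depth=int(_scalar(info_get(info, "DP", 0)) or 0),
                    alt_fraction=float(af),
                    filter_pass=("PASS" in rec.filter or len(rec.filter) == 0),
                    platform=platform, sample_id=sid, annotation=ann,
                ))
    return calls


def _scalar(val):
    if isinstance(val, tuple):
        return val[0] if val else None
    return val


def read_callset(path, platform: str, **kwargs) -> list[VariantCall]:
    """Dispatch on extension: .vcf via pysam, otherwise the flat TSV dialect."""
    if platform not in ("TS", "WES"):
        raise CallsetError(f"unknown platform {platform!r}")
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_callset_vcf(path, platform, **kwargs)
    return read_callset_tsv(path, platform=platform, **kwargs)
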