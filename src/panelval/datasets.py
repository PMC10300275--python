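"""Reference data from the published validation cohort.

Nineteen adult patients with undiagnosed chronic liver disease were sequenced
with both a custom 82-gene targeted panel (TS) and exome capture (WES), and
the two callsets were compared within the panel's target regions. This module
bundles the study's printed summary numbers so the analysis arithmetic can be
re-run without access to the deposited reads: the per-sample coverage table,
the nine platform-discrepant high-impact variants with their full annotation
rows, and the callset set-decomposition counts.
"""
from __future__ import annotations

import pandas as pd

from .callset import VariantAnnotation
from .intervals import PANEL_CATEGORIES, GeneModel, GenomicInterval

# Per-sample coverage across the panel targets: TS mean depth, percent of
# target bases at >=10x in TS, WES mean depth within TS regions, percent at
# >=10x in WES. One row per patient.
_COVERAGE_ROWS = [
    # sample, ts_depth, ts_pct10, wes_depth, wes_pct10
    (1, 206, 97, 95, 85),
    (2, 601, 99, 102, 85),
    (3, 738, 99, 96, 85),
    (4, 475, 99, 96, 86),
    (5, 455, 97, 94, 85),
    (6, 189, 99, 103, 85),
    (7, 269, 97, 102, 87),
    (8, 212, 98, 96, 87),
    (9, 253, 98, 96, 87),
    (10, 197, 98, 102, 90),
    (11, 193, 97, 100, 90),
    (12, 179, 97, 106, 91),
    (13, 178, 94, 94, 89),
    (14, 122, 93, 103, 91),
    (15, 135, 91, 97, 86),
    (16, 658, 99, 119, 92),
    (17, 229, 98, 112, 87),
    (18, 200, 98, 115, 88),
    (19, 221, 98, 105, 87),
]


def load_coverage_table() -> pd.DataFrame:
    """The 19-patient per-sample coverage summary (both platforms)."""
    return pd.DataFrame(
        _COVERAGE_ROWS,
        columns=["sample", "ts_mean_depth", "ts_pct_ge10x",
                 "wes_mean_depth", "wes_pct_ge10x"],
    )


# The nine high-functional-impact variants detected by exactly one platform,
# with the annotation columns of the study's discrepancy tables. depth_own is
# the sequencing depth on the calling platform, depth_other on the other
# platform at the corresponding locus. reason is the study's proposed
# explanation, normalized to this package's reason vocabulary.
_DISCREPANT_ROWS = [
    # platform, gene, rsid, hgvs_c, consequence, clinvar_sig, cadd, maf,
    # confirmed, gc_pct, depth_own, depth_other, reason
    ("TS", "PCSK7", "rs781628227", "c.2347C>G", "Exonic non-synonymous",
     "Not_Found", 24.5, 0.0, True, 55.9, 569, 0,
     "insufficient_coverage_other_platform"),
    ("TS", "CIDEC", "rs757906759", "c.209C>T", "Exonic non-synonymous",
     "Not_Found", 32.0, 0.00004496, True, 51.3, 436, 298,
     "pipeline_filter_fail"),
    ("TS", "SMPD1", "rs78250081", "c.113C>T", "Exonic non-synonymous",
     "Not_Found", 17.7, 0.00005943, False, 73.5, 610, 54,
     "false_positive_misalignment"),
    ("TS", "CP", "rs61733458", "c.1652C>T", "Exonic non-synonymous",
     "Benign", 29.7, 0.0301, True, 44.8, 199, 94,
     "pipeline_filter_fail"),
    ("TS", "RTEL1", "rs201365106", "c.232G>A", "Exonic non-synonymous",
     "Uncertain significance", 2.8, 0.0, False, 75.0, 498, 275,
     "false_positive_misalignment"),
    ("TS", "PCSK7", None, "c.1737C>A", "Exonic non-synonymous",
     "Not_Found", 41.0, 0.0, True, 60.0, 754, 0,
     "insufficient_coverage_other_platform"),
    ("WES", "CAV1", "rs150368249", "c.463G>A", "Exonic non-synonymous",
     "Likely benign", 16.3, 0.0002472, True, 46.8, 165, 15,
     "insufficient_coverage_other_platform"),
    ("WES", "PHKA2", "rs145406549", "c.785T>G", "Exonic non-synonymous",
     "Not_Found", 27.9, 0.0003297, True, 40.2, 219, 14,
     "insufficient_coverage_other_platform"),
    ("WES", "PHKB", "rs151155518", "c.500A>G", "Exonic non-synonymous",
     "Conflicting interpretations of pathogenicity", 27.2, 0.006614, True,
     44.4, 74, 10, "insufficient_coverage_other_platform"),
]

DISCREPANT_COLUMNS = ["platform", "gene", "rsid", "hgvs_c", "consequence",
                      "clinvar_sig", "cadd", "maf_exac_nfe", "confirmed",
                      "gc_pct", "depth_own", "depth_other", "reason"]


def load_discrepant_variants() -> pd.DataFrame:
    """The nine platform-unique HFI variants with their printed annotations."""
    return pd.DataFrame(_DISCREPANT_ROWS, columns=DISCREPANT_COLUMNS)


def discrepant_annotations() -> list[VariantAnnotation]:
    """The nine rows as :class:`VariantAnnotation` objects, entered verbatim."""
    return [
        VariantAnnotation(
            consequence=row.consequence,
            clinvar_sig=row.clinvar_sig,
            maf_exac_nfe=row.maf_exac_nfe,
            cadd=row.cadd,
            gene=row.gene,
            rsid=row.rsid,
            gc_content_pct=row.gc_pct,
        )
        for row in load_discrepant_variants().itertuples()
    ]


# Callset set decomposition over all samples, within TS target regions.
ALL_VARIANT_COUNTS = {"both": 288, "ts_only": 66, "wes_only": 20, "total": 374}

# High-functional-impact subset before truth adjudication: 89 shared plus the
# 9 discrepant rows above (6 TS-only of which 2 unconfirmed, 3 WES-only).
HFI_SHARED = 89
HFI_TOTAL = 98

# The realized discrepancy decomposition used as the simulator's default
# scenario: shared true, TS-only true, WES-only true, TS false positives,
# WES false positives.
DEFAULT_PLANTED_COUNTS = (89, 4, 3, 2, 0)

# Cohort size and platform depth distribution summaries (mean, sd, range).
N_SAMPLES = 19
TS_DEPTH_MEAN, TS_DEPTH_SD = 300.0, 190.0
WES_DEPTH_MEAN, WES_DEPTH_SD = 102.0, 7.0


def study_comparison():
    """Rebuild the study's HFI comparison from the bundled counts and rows.

    The 89 dual-platform HFI variants are represented by placeholder keys
    (their identities are not printed); the nine platform-unique variants come
    from the discrepancy rows, with their Sanger labels. Returns the
    truth-assigned :class:`~panelval.concordance.ComparisonResult`.
    """
    from .concordance import ComparisonResult, assign_truth

    shared = {(f"shared{i:03d}", 1, "A", "C") for i in range(HFI_SHARED)}
    ts_only, wes_only, sanger = set(), set(), {}
    for i, row in enumerate(load_discrepant_variants().itertuples()):
        key = (row.gene, 100 + i, "A", "G")
        (ts_only if row.platform == "TS" else wes_only).add(key)
        sanger[key] = bool(row.confirmed)
    cmp = ComparisonResult(shared=shared, ts_only=ts_only, wes_only=wes_only)
    return assign_truth(cmp, sanger)


def toy_panel(flank_ready: bool = False) -> list[GeneModel]:
    """A six-gene toy panel, one gene per disease category.

    A stand-in for the real 82-gene design (whose full region list is not
    bundled); coordinates are synthetic but realistically sized.
    """
    genes = []
    base = 10_000
    for i, category in enumerate(PANEL_CATEGORIES):
        chrom = f"chr{i % 3 + 1}"
        start = base + i * 5_000
        exons = [GenomicInterval(chrom, start + j * 400, start + j * 400 + 150)
                 for j in range(4)]
        extra = [GenomicInterval(chrom, start - 600, start - 400)]  # promoter/UTR
        genes.append(GeneModel(name=f"GENE{i + 1}", category=category,
                               exons=exons, extra_regions=extra))
    return genes
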