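"""Targeted-panel design model: genes, exons, and flanked/merged target intervals.

Coordinates are BED-style 0-based half-open everywhere inside the package;
conversion to/from VCF-style 1-based happens only at variant I/O boundaries
and in :func:`PanelDesign.contains`.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

PANEL_CATEGORIES = (
    "iron overload",
    "lipid metabolism",
    "cholestatic diseases",
    "storage diseases",
    "specific hereditary CLD",
    "susceptibility to liver diseases",
)

REGION_TYPES = ("exon", "utr", "promoter")


class PanelInputError(ValueError):
    """Raised for malformed panel definitions or files."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on `chrom` (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise PanelInputError("interval chromosome must be non-empty")
        if self.start < 0:
            raise PanelInputError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise PanelInputError(
                f"interval end must exceed start, got [{self.start},{self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def flanked(self, flank: int) -> "GenomicInterval":
        """Expand by `flank` bp on both sides, floored at position 0."""
        return GenomicInterval(self.chrom, max(0, self.start - flank), self.end + flank)


@dataclass
class GeneModel:
    """A panel gene: symbol, disease category, exons and optional extra regions.

    `extra_regions` carries UTR/promoter additions, which are included in the
    target set unflanked (flanks apply to coding exons only).
    """

    name: str
    category: str
    exons: list[GenomicInterval]
    extra_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in PANEL_CATEGORIES:
            raise PanelInputError(
                f"gene {self.name}: unknown category {self.category!r}; "
                f"must be one of {PANEL_CATEGORIES}"
            )
        if not self.exons and not self.extra_regions:
            raise PanelInputError(f"gene {self.name}: no exons or extra regions")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge into a sorted, pairwise-disjoint set covering the same bases.

    Overlapping and book-ended ([a,b)+[b,c)) intervals are merged, so the
    total length of the output equals the size of the base-set union.
    """
    ivs = sorted(intervals)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


@dataclass
class PanelDesign:
    """Merged target intervals of a panel, with gene provenance retained.

    `gene_targets` maps each gene symbol to the merged flanked intervals derived
    from that gene alone (before the panel-wide merge), so per-gene coverage
    statistics remain computable after merging.
    """

    genes: list[GeneModel]
    targets: list[GenomicInterval]
    flank: int = 25
    gene_targets: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    # per-chrom sorted (starts, ends) arrays for O(log n) membership queries
    _index: dict[str, tuple[list[int], list[int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.targets:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            self._index[chrom] = ([iv.start for iv in ivs], [iv.end for iv in ivs])

    @property
    def total_target_length(self) -> int:
        return sum(len(iv) for iv in self.targets)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True iff the 1-based position lies in a target interval.

        Unknown chromosomes return False rather than raising.
        """
        if pos_1based < 1:
            raise ValueError(f"1-based position must be >= 1, got {pos_1based}")
        idx = self._index.get(chrom)
        if idx is None:
            return False
        starts, ends = idx
        pos0 = pos_1based - 1
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]

    def intervals_for_gene(self, gene: str) -> list[GenomicInterval]:
        return self.gene_targets.get(gene, [])


def build_targets(genes: Sequence[GeneModel], flank: int = 25) -> PanelDesign:
    """Build a :class:`PanelDesign` by flanking exons and merging all regions.

    Each coding exon is expanded by `flank` bp on both sides (floored at 0),
    unioned with the gene's extra regions, and merged per chromosome into
    sorted disjoint targets.
    """
    if flank < 0:
        raise PanelInputError(f"flank must be non-negative, got {flank}")
    all_ivs: list[GenomicInterval] = []
    gene_targets: dict[str, list[GenomicInterval]] = {}
    for gene in genes:
        ivs = [ex.flanked(flank) for ex in gene.exons] + list(gene.extra_regions)
        gene_targets[gene.name] = merge_intervals(ivs)
        all_ivs.extend(ivs)
    return PanelDesign(
        genes=list(genes),
        targets=merge_intervals(all_ivs),
        flank=flank,
        gene_targets=gene_targets,
    )


# ---------------------------------------------------------------------------
# File I/O: BED3 targets and the flat gene-model TSV
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open) into a list of intervals."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelInputError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except (ValueError, PanelInputError) as exc:
                raise PanelInputError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(design_or_intervals, path) -> None:
    """Write target intervals as BED3."""
    ivs = (
        design_or_intervals.targets
        if isinstance(design_or_intervals, PanelDesign)
        else design_or_intervals
    )
    with open(path, "w") as fh:
        for iv in sorted(ivs):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_gene_models(path) -> list[GeneModel]:
    """Read the flat gene-model TSV.

    Columns: gene, category, chrom, region_start, region_end, region_type
    (region_type in {exon, utr, promoter}; coordinates 0-based half-open).
    """
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["gene", "category", "chrom", "region_start", "region_end", "region_type"]
        if header != expected:
            raise PanelInputError(f"{path}: expected header {expected}, got {header}")
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise PanelInputError(f"{path}:{lineno}: expected 6 columns")
            name, category, chrom, start, end, rtype = fields
            if rtype not in REGION_TYPES:
                raise PanelInputError(f"{path}:{lineno}: unknown region_type {rtype!r}")
            try:
                iv = GenomicInterval(chrom, int(start), int(end))
            except (ValueError, PanelInputError) as exc:
                raise PanelInputError(f"{path}:{lineno}: gene {name}: {exc}") from exc
            if name not in genes:
                genes[name] = GeneModel(name=name, category=category, exons=[iv]
                                        if rtype == "exon" else [],
                                        extra_regions=[] if rtype == "exon" else [iv])
            else:
                (genes[name].exons if rtype == "exon" else genes[name].extra_regions).append(iv)
    return list(genes.values())


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcategory\tchrom\tregion_start\tregion_end\tregion_type\n")
        for g in genes:
            for iv in g.exons:
                fh.write(f"{g.name}\t{g.category}\t{iv.chrom}\t{iv.start}\t{iv.end}\texon\n")
            for iv in g.extra_regions:
                fh.write(f"{g.name}\t{g.category}\t{iv.chrom}\t{iv.start}\t{iv.end}\tutr\n")
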