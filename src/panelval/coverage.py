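"""Per-base coverage benchmarking over panel targets.

Summaries mirror the standard validation readouts for a targeted panel run
alongside exome capture: per-sample mean depth and fraction of target bases at
a depth threshold, per-gene pooled depth, the fraction of (exon, sample) units
with low mean depth, plus the paired signed-rank and 2x2 chi-squared tests used
to compare platforms.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, PanelDesign

PLATFORMS = ("TS", "WES")


@dataclass
class DepthTrack:
    """Per-base depth for one sample on one platform.

    Positions are stored per chromosome as parallel sorted arrays
    (0-based positions, integer depths). Bases absent from the track are
    treated as depth 0.
    """

    sample_id: str
    platform: str
    data: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")

    def depths_over(self, interval: GenomicInterval) -> np.ndarray:
        """Depth for every base of `interval`, zeros where unrecorded."""
        out = np.zeros(len(interval), dtype=np.int64)
        entry = self.data.get(interval.chrom)
        if entry is None:
            return out
        pos, dep = entry
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        out[pos[lo:hi] - interval.start] = dep[lo:hi]
        return out

    def depth_at(self, chrom: str, pos_1based: int) -> int:
        """Depth at a 1-based position; 0 if unrecorded."""
        entry = self.data.get(chrom)
        if entry is None:
            return 0
        pos, dep = entry
        i = np.searchsorted(pos, pos_1based - 1)
        if i < len(pos) and pos[i] == pos_1based - 1:
            return int(dep[i])
        return 0

    def set_depth(self, chrom: str, pos0: int, depth: int) -> None:
        """Overwrite depth at a recorded 0-based position (inserts if absent)."""
        entry = self.data.get(chrom)
        if entry is None:
            self.data[chrom] = (np.array([pos0]), np.array([depth]))
            return
        pos, dep = entry
        i = int(np.searchsorted(pos, pos0))
        if i < len(pos) and pos[i] == pos0:
            dep[i] = depth
        else:
            self.data[chrom] = (np.insert(pos, i, pos0), np.insert(dep, i, depth))


def read_depth_tsv(path, sample_id: str, platform: str) -> DepthTrack:
    """Read a per-base depth TSV (chrom, 1-based pos, depth) into a track."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                     comment="#", dtype={"chrom": str})
    data = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64) - 1
        order = np.argsort(pos)
        data[str(chrom)] = (pos[order], grp["depth"].to_numpy(dtype=np.int64)[order])
    return DepthTrack(sample_id=sample_id, platform=platform, data=data)


def write_depth_tsv(track: DepthTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            pos, dep = track.data[chrom]
            for p, d in zip(pos.tolist(), dep.tolist()):
                fh.write(f"{chrom}\t{p + 1}\t{d}\n")


def _require_targets(design: PanelDesign) -> None:
    if design.total_target_length == 0:
        raise ValueError("no target bases: panel design is empty")


def sample_mean_depth(track: DepthTrack, design: PanelDesign) -> float:
    """Mean depth over all target bases (absent bases count as depth 0)."""
    _require_targets(design)
    total = sum(int(track.depths_over(iv).sum()) for iv in design.targets)
    return total / design.total_target_length


def pct_bases_at_threshold(track: DepthTrack, design: PanelDesign, threshold: int = 10) -> float:
    """Percent of target bases with depth >= threshold."""
    _require_targets(design)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n_at = sum(int((track.depths_over(iv) >= threshold).sum()) for iv in design.targets)
    return 100.0 * n_at / design.total_target_length


def gene_pooled_depth(
    tracks: Sequence[DepthTrack], design: PanelDesign, platform: str
) -> dict[str, float]:
    """Per-gene mean depth pooled across all samples of one platform.

    For each gene the sum of depths over the gene's target bases in every
    sample is divided by (gene target length x number of samples). Genes with
    zero target bases are excluded with a warning.
    """
    sel = [t for t in tracks if t.platform == platform]
    if not sel:
        raise ValueError(f"no depth tracks for platform {platform}")
    out: dict[str, float] = {}
    for gene in design.genes:
        ivs = design.intervals_for_gene(gene.name)
        n_bases = sum(len(iv) for iv in ivs)
        if n_bases == 0:
            warnings.warn(f"gene {gene.name} has zero target bases; excluded")
            continue
        total = sum(int(t.depths_over(iv).sum()) for t in sel for iv in ivs)
        out[gene.name] = total / (n_bases * len(sel))
    return out


def exon_low_coverage_fraction(
    tracks: Sequence[DepthTrack], design: PanelDesign, platform: str, threshold: int = 10
) -> float:
    """Fraction of (exon, sample) units with mean depth below threshold.

    The unit is a flanked exon in one sample; the fraction pools all samples of
    the platform, matching the "fraction of exons covered below tenfold" view.
    """
    sel = [t for t in tracks if t.platform == platform]
    if not sel:
        raise ValueError(f"no depth tracks for platform {platform}")
    exons = [ex.flanked(design.flank) for g in design.genes for ex in g.exons]
    if not exons:
        return 0.0
    n_low = sum(
        1 for t in sel for ex in exons if t.depths_over(ex).mean() < threshold
    )
    return n_low / (len(exons) * len(sel))


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def paired_signed_rank(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped before ranking (the classical convention).
    For n <= 25 retained pairs the exact null distribution of the signed-rank
    sum is computed by dynamic programming over sign assignments (midranks for
    tied |differences|); above that a normal approximation with continuity
    correction is used. Returns 1.0 with a warning when all differences are
    zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p-value = 1.0")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        return _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    # tie correction for the variance of W+
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    z = (abs(w_plus - mean) - 0.5) / np.sqrt(var)
    return float(2 * stats.norm.sf(z))


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolving the +/- rank assignment distribution.

    Ranks are midranks, so doubling makes them integers; the DP counts, over
    all 2^n equiprobable sign vectors, how many yield each doubled rank sum.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def two_by_two_chi_squared(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared p-value (1 df, no continuity correction) for a 2x2 table."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: a marginal total is zero")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Summary assembly
# ---------------------------------------------------------------------------

@dataclass
class CoverageSummary:
    """Bundle of coverage readouts for a paired-platform run."""

    per_sample: pd.DataFrame  # sample_id, platform, mean_depth, pct_bases_at_threshold
    per_gene: pd.DataFrame    # gene, platform, pooled_mean_depth
    exon_low_fraction: dict[str, float]
    threshold: int = 10


def summarize_coverage(
    tracks: Iterable[DepthTrack], design: PanelDesign, threshold: int = 10
) -> CoverageSummary:
    tracks = list(tracks)
    rows = [
        {
            "sample_id": t.sample_id,
            "platform": t.platform,
            "mean_depth": sample_mean_depth(t, design),
            "pct_bases_at_threshold": pct_bases_at_threshold(t, design, threshold),
        }
        for t in tracks
    ]
    gene_rows = []
    low = {}
    for platform in PLATFORMS:
        if any(t.platform == platform for t in tracks):
            for gene, depth in gene_pooled_depth(tracks, design, platform).items():
                gene_rows.append({"gene": gene, "platform": platform,
                                  "pooled_mean_depth": depth})
            low[platform] = exon_low_coverage_fraction(tracks, design, platform, threshold)
    return CoverageSummary(
        per_sample=pd.DataFrame(rows),
        per_gene=pd.DataFrame(gene_rows),
        exon_low_fraction=low,
        threshold=threshold,
    )
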