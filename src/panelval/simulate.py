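"""Synthetic panels, depth tracks and paired callsets with planted truth.

The generator emulates the statistical structure of a paired targeted-panel /
exome validation run: deep but highly variable amplicon coverage (per-sample
mean ~300x, sd ~190x) versus shallower, tightly clustered exome coverage
(~102x, sd ~7x) with capture dropouts concentrated in GC-rich exons; paired
callsets whose shared/unique decomposition, miss mechanisms (coverage gap or
pipeline-filter failure) and misalignment false positives are planted, so the
whole pipeline can be checked against exact ground truth.

A single numpy Generator seeded once drives every stage; identical config and
seed reproduce identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import datasets
from .callset import VariantAnnotation, VariantCall
from .coverage import DepthTrack
from .intervals import PANEL_CATEGORIES, GeneModel, GenomicInterval, PanelDesign, build_targets

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition defaults for the paired-platform simulation."""

    seed: int = 0
    n_genes: int = 82
    exons_per_gene: tuple[int, int] = (3, 20)
    exon_length: tuple[int, int] = (80, 250)
    flank: int = 25
    n_samples: int = datasets.N_SAMPLES          # 19 patients
    ts_depth_mean: float = datasets.TS_DEPTH_MEAN   # 300x
    ts_depth_sd: float = datasets.TS_DEPTH_SD       # 190x across samples
    wes_depth_mean: float = datasets.WES_DEPTH_MEAN  # 102x
    wes_depth_sd: float = datasets.WES_DEPTH_SD      # 7x across samples
    ts_base_dispersion: float = 8.0   # neg-binomial size; smaller = noisier
    wes_base_dispersion: float = 30.0
    ts_dropout_rate: float = 0.03     # fraction of target bases below 10x
    wes_dropout_rate: float = 0.13
    gc_rich_fraction: float = 0.10    # exons flagged GC-rich (dropout-prone in WES)
    # HFI variant decomposition: shared true, TS-only true, WES-only true,
    # TS false positives, WES false positives
    planted_counts: tuple[int, int, int, int, int] = datasets.DEFAULT_PLANTED_COUNTS
    # additional non-HFI (synonymous, common) background variants
    background_counts: tuple[int, int, int] = (199, 60, 17)  # shared/TS-only/WES-only
    filter_fail_fraction: float = 0.5  # TS-only true misses caused by WES filter fail
    min_depth: int = 10

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.planted_counts + self.background_counts):
            raise ValueError("planted counts must be non-negative")
        for rate in (self.ts_dropout_rate, self.wes_dropout_rate, self.gc_rich_fraction,
                     self.filter_fail_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0,1]")

    @property
    def n_true_variants(self) -> int:
        return sum(self.planted_counts[:3])


@dataclass
class PlantedVariant:
    key: tuple[str, int, str, str]
    sample_id: str
    platforms: tuple[str, ...]        # platforms that emit a passing call
    truth: bool
    criterion: str                    # intended HFI criterion, or "none"
    intended_reason: Optional[str]    # for platform-unique variants
    hfi: bool


@dataclass
class PlantedTruth:
    variants: list[PlantedVariant] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        hfi = [v for v in self.variants if v.hfi]
        return {
            "shared_true": sum(1 for v in hfi if v.truth and len(v.platforms) == 2),
            "ts_only_true": sum(1 for v in hfi if v.truth and v.platforms == ("TS",)),
            "wes_only_true": sum(1 for v in hfi if v.truth and v.platforms == ("WES",)),
            "ts_false_positives": sum(1 for v in hfi if not v.truth and v.platforms == ("TS",)),
            "wes_false_positives": sum(1 for v in hfi if not v.truth and v.platforms == ("WES",)),
        }


def simulate_panel(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> PanelDesign:
    """Generate a toy panel: genes cycle through the six disease categories,
    spread over several chromosomes, exons spaced so genes never overlap."""
    if cfg.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n_chroms = max(2, min(6, cfg.n_genes))
    cursors = {f"chr{i + 1}": 100_000 for i in range(n_chroms)}
    genes = []
    for g in range(cfg.n_genes):
        chrom = f"chr{g % n_chroms + 1}"
        pos = cursors[chrom]
        n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
            exons.append(GenomicInterval(chrom, pos, pos + length))
            pos += length + int(rng.integers(200, 2_000))  # intron gap >> 2*flank
        genes.append(GeneModel(
            name=f"GENE{g + 1:03d}",
            category=PANEL_CATEGORIES[g % len(PANEL_CATEGORIES)],
            exons=exons,
        ))
        cursors[chrom] = pos + 10_000
    return build_targets(genes, flank=cfg.flank)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def simulate_depth(
    cfg: SimulationConfig, design: PanelDesign, rng: Optional[np.random.Generator] = None
) -> list[DepthTrack]:
    """Per-base depth tracks for every sample on both platforms.

    Per-sample platform means are lognormal (matching the reported platform
    mean/sd); per-base depth is negative-binomial around the sample mean.
    Dropout exons (whole flanked exons forced below the 10x cutoff) are chosen
    once per platform — capture/amplicon dropouts are design properties shared
    by all samples — preferentially among GC-rich-flagged exons for WES.
    """
    if design.total_target_length == 0:
        raise ValueError("empty panel design")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    exons = [ex.flanked(cfg.flank) for g in design.genes for ex in g.exons]
    gc_rich = rng.random(len(exons)) < cfg.gc_rich_fraction

    chrom_pos = {}
    for chrom in sorted({iv.chrom for iv in design.targets}):
        ivs = [iv for iv in design.targets if iv.chrom == chrom]
        chrom_pos[chrom] = np.concatenate([np.arange(iv.start, iv.end) for iv in ivs])

    # dropout exons chosen once per platform (design-level, shared by samples)
    dropout_masks: dict[str, dict[str, np.ndarray]] = {}
    for platform, rate in (("TS", cfg.ts_dropout_rate), ("WES", cfg.wes_dropout_rate)):
        target = rate * design.total_target_length
        weights = np.ones(len(exons))
        if platform == "WES":
            weights[gc_rich] = 10.0  # GC-rich exons drop out preferentially
        order = sorted(range(len(exons)), key=lambda i: -weights[i] * rng.random())
        masks = {c: np.zeros(len(p), dtype=bool) for c, p in chrom_pos.items()}
        n_chosen = 0
        for i in order:
            if n_chosen >= target:
                break
            ex = exons[i]
            pos = chrom_pos[ex.chrom]
            sel = (pos >= ex.start) & (pos < ex.end)
            n_chosen += int(sel.sum())
            masks[ex.chrom] |= sel
        dropout_masks[platform] = masks

    tracks = []
    params = {"TS": (cfg.ts_depth_mean, cfg.ts_depth_sd, cfg.ts_base_dispersion,
                     cfg.ts_dropout_rate),
              "WES": (cfg.wes_depth_mean, cfg.wes_depth_sd, cfg.wes_base_dispersion,
                      cfg.wes_dropout_rate)}
    drop_mean = (cfg.min_depth - 1) / 2.0  # mean of the planted dropout depths
    for s in range(cfg.n_samples):
        sid = f"S{s + 1:02d}"
        for platform in ("TS", "WES"):
            mean, sd, size, rate = params[platform]
            mu, sigma = _lognormal_params(mean, sd)
            # compensate for dropout bases so the realized track mean matches
            # the configured per-sample platform mean
            sample_mean = float(rng.lognormal(mu, sigma))
            sample_mean = max(1.0, (sample_mean - rate * drop_mean) / (1.0 - rate))
            data = {}
            for chrom, pos in chrom_pos.items():
                p = size / (size + sample_mean)
                dep = rng.negative_binomial(size, p, len(pos)).astype(np.int64)
                mask = dropout_masks[platform][chrom]
                if mask.any():
                    dep[mask] = rng.integers(0, cfg.min_depth, int(mask.sum()))
                data[chrom] = (pos.copy(), dep)
            tracks.append(DepthTrack(sample_id=sid, platform=platform, data=data))
    return tracks


def _criterion_annotation(criterion: str, rng: np.random.Generator,
                          false_positive: bool = False) -> VariantAnnotation:
    """Annotations drawn from criterion-conditional ranges so the verdict is
    decidable by construction."""
    consequence = str(rng.choice(
        ["missense_variant", "missense_variant", "stop_gained",
         "5_prime_utr_variant", "splice_donor_variant"]))
    if criterion == "A_clinvar_plp":
        sig = str(rng.choice(["Pathogenic", "Likely_pathogenic"]))
        maf = float(rng.uniform(0, 0.01))
        cadd = float(rng.uniform(0, 40))
    elif criterion == "B_rare_vus":
        sig = str(rng.choice(["Uncertain", "Not_found"]))
        maf = float(rng.uniform(0, 0.004))
        cadd = float(rng.uniform(0, 40))
    elif criterion == "C_midfreq_cadd":
        sig = str(rng.choice(["Uncertain", "Benign", "Conflicting"]))
        maf = float(rng.uniform(0.005, 0.045))
        cadd = float(rng.uniform(20.5, 40))
    else:  # non-HFI background: synonymous and common
        return VariantAnnotation(
            consequence="synonymous SNV",
            clinvar_sig=str(rng.choice(["Not_found", "Benign"])),
            maf_exac_nfe=float(rng.uniform(0.06, 0.5)),
            cadd=float(rng.uniform(0, 10)),
        )
    if false_positive:
        # misalignment-compatible context: GC-rich window or repeat flag
        if rng.random() < 0.5:
            gc, repeat = float(rng.uniform(70, 85)), None
        else:
            gc, repeat = float(rng.uniform(40, 60)), True
    else:
        gc, repeat = float(rng.uniform(30, 65)), None
    return VariantAnnotation(consequence=consequence, clinvar_sig=sig,
                             maf_exac_nfe=maf, cadd=cadd,
                             gc_content_pct=gc, repeat_flag=repeat)


def simulate_callsets(
    cfg: SimulationConfig,
    design: PanelDesign,
    tracks: Sequence[DepthTrack],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantCall], list[VariantCall], dict, PlantedTruth]:
    """Plant variants into the depth landscape and emit both platform callsets.

    Returns (ts_calls, wes_calls, sanger_labels, planted_truth). Platform-
    unique true variants are hidden from the other platform by the intended
    mechanism: depth forced below the calling cutoff at the locus, or (for
    WES misses of TS-only variants) an emitted record with a failing pipeline
    filter flag. False positives get a misalignment-compatible annotation and
    a "not confirmed" label; every other platform-unique variant is labeled
    confirmed.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if cfg.n_true_variants == 0:
        raise ValueError("no truth universe: zero true variants requested")
    shared_n, ts_only_n, wes_only_n, ts_fp_n, wes_fp_n = cfg.planted_counts
    bg_shared, bg_ts, bg_wes = cfg.background_counts
    n_total = sum(cfg.planted_counts) + sum(cfg.background_counts)

    # candidate positions: all target bases, globally unique per variant
    all_pos = [(iv.chrom, p) for iv in design.targets for p in range(iv.start, iv.end)]
    if n_total > len(all_pos):
        raise ValueError(
            f"insufficient covered positions: need {n_total}, have {len(all_pos)}")
    pool = [all_pos[i] for i in rng.permutation(len(all_pos))]
    pool_iter = iter(pool)

    ts_tracks = {t.sample_id: t for t in tracks if t.platform == "TS"}
    wes_tracks = {t.sample_id: t for t in tracks if t.platform == "WES"}
    sample_ids = sorted(ts_tracks)

    def draw_position(sid: str, need_ts: bool, need_wes: bool) -> tuple[str, int]:
        """Next pooled position whose depths satisfy the platform requirements;
        if the pool runs dry of qualifying spots, depths are forced instead."""
        tried = []
        for chrom, pos0 in pool_iter:
            ok = ((not need_ts or ts_tracks[sid].depth_at(chrom, pos0 + 1) >= cfg.min_depth)
                  and (not need_wes or wes_tracks[sid].depth_at(chrom, pos0 + 1) >= cfg.min_depth))
            if ok:
                return chrom, pos0
            tried.append((chrom, pos0))
            if len(tried) > 500:
                break
        chrom, pos0 = tried.pop() if tried else next(pool_iter)
        if need_ts:
            ts_tracks[sid].set_depth(chrom, pos0, int(rng.integers(80, 400)))
        if need_wes:
            wes_tracks[sid].set_depth(chrom, pos0, int(rng.integers(60, 150)))
        return chrom, pos0

    def snv_alleles() -> tuple[str, str]:
        ref, alt = rng.choice(4, size=2, replace=False)
        return str(_BASES[ref]), str(_BASES[alt])

    criteria_cycle = ["A_clinvar_plp", "B_rare_vus", "C_midfreq_cadd"]
    ts_calls: list[VariantCall] = []
    wes_calls: list[VariantCall] = []
    sanger: dict[tuple[str, int, str, str], bool] = {}
    truth = PlantedTruth()

    def make_call(platform: str, sid: str, chrom: str, pos0: int, ref: str, alt: str,
                  ann: VariantAnnotation, filter_pass: bool = True,
                  af_lo: float = 0.35, af_hi: float = 0.65) -> VariantCall:
        track = (ts_tracks if platform == "TS" else wes_tracks)[sid]
        return VariantCall(
            chrom=chrom, pos_1based=pos0 + 1, ref=ref, alt=alt,
            depth=track.depth_at(chrom, pos0 + 1),
            alt_fraction=float(rng.uniform(af_lo, af_hi)),
            filter_pass=filter_pass, platform=platform, sample_id=sid,
            annotation=ann,
        )

    spec_rows: list[tuple[str, bool, bool]] = []   # (kind, hfi, truth)
    spec_rows += [("shared", True, True)] * shared_n
    spec_rows += [("ts_only", True, True)] * ts_only_n
    spec_rows += [("wes_only", True, True)] * wes_only_n
    spec_rows += [("ts_fp", True, False)] * ts_fp_n
    spec_rows += [("wes_fp", True, False)] * wes_fp_n
    spec_rows += [("shared", False, True)] * bg_shared
    spec_rows += [("ts_only", False, True)] * bg_ts
    spec_rows += [("wes_only", False, True)] * bg_wes

    n_filter_fail = int(round(cfg.filter_fail_fraction * ts_only_n))
    ts_only_seen = 0
    hfi_i = 0
    for kind, hfi, is_true in spec_rows:
        sid = sample_ids[int(rng.integers(len(sample_ids)))]
        criterion = criteria_cycle[hfi_i % 3] if hfi else "none"
        if hfi:
            hfi_i += 1
        ann = _criterion_annotation(criterion, rng, false_positive=not is_true)
        ref, alt = snv_alleles()

        if kind == "shared":
            chrom, pos0 = draw_position(sid, need_ts=True, need_wes=True)
            ts_calls.append(make_call("TS", sid, chrom, pos0, ref, alt, ann))
            wes_calls.append(make_call("WES", sid, chrom, pos0, ref, alt, ann))
            platforms: tuple[str, ...] = ("TS", "WES")
            reason = None
        elif kind == "ts_only":
            use_filter_fail = hfi and ts_only_seen < n_filter_fail
            if hfi:
                ts_only_seen += 1
            if use_filter_fail:
                chrom, pos0 = draw_position(sid, need_ts=True, need_wes=True)
                ts_calls.append(make_call("TS", sid, chrom, pos0, ref, alt, ann))
                wes_calls.append(make_call("WES", sid, chrom, pos0, ref, alt, ann,
                                           filter_pass=False))
                reason = "pipeline_filter_fail"
            else:
                chrom, pos0 = draw_position(sid, need_ts=True, need_wes=False)
                ts_calls.append(make_call("TS", sid, chrom, pos0, ref, alt, ann))
                wes_tracks[sid].set_depth(chrom, pos0, int(rng.integers(0, cfg.min_depth)))
                reason = "insufficient_coverage_other_platform"
            platforms = ("TS",)
        elif kind == "wes_only":
            chrom, pos0 = draw_position(sid, need_ts=False, need_wes=True)
            wes_calls.append(make_call("WES", sid, chrom, pos0, ref, alt, ann))
            ts_tracks[sid].set_depth(chrom, pos0, int(rng.integers(0, cfg.min_depth)))
            platforms = ("WES",)
            reason = "insufficient_coverage_other_platform"
        elif kind == "ts_fp":
            chrom, pos0 = draw_position(sid, need_ts=True, need_wes=True)
            ts_calls.append(make_call("TS", sid, chrom, pos0, ref, alt, ann,
                                      af_lo=0.22, af_hi=0.45))
            platforms = ("TS",)
            reason = "false_positive_misalignment"
        else:  # wes_fp
            chrom, pos0 = draw_position(sid, need_ts=True, need_wes=True)
            wes_calls.append(make_call("WES", sid, chrom, pos0, ref, alt, ann,
                                       af_lo=0.22, af_hi=0.45))
            platforms = ("WES",)
            reason = "false_positive_misalignment"

        key = (chrom, pos0 + 1, ref, alt)
        if len(platforms) == 1:
            sanger[key] = is_true
        truth.variants.append(PlantedVariant(
            key=key, sample_id=sid, platforms=platforms, truth=is_true,
            criterion=criterion, intended_reason=reason, hfi=hfi,
        ))
    return ts_calls, wes_calls, sanger, truth


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    design: PanelDesign
    tracks: list[DepthTrack]
    ts_calls: list[VariantCall]
    wes_calls: list[VariantCall]
    sanger: dict
    truth: PlantedTruth


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run every stage off one seeded generator stream."""
    rng = np.random.default_rng(cfg.seed)
    design = simulate_panel(cfg, rng)
    tracks = simulate_depth(cfg, design, rng)
    ts_calls, wes_calls, sanger, truth = simulate_callsets(cfg, design, tracks, rng)
    return SimulatedStudy(cfg, design, tracks, ts_calls, wes_calls, sanger, truth)


def run_recovery(cfg: SimulationConfig) -> dict:
    """Simulate, run the full pipeline, and compare recovered counts/metrics
    to the planted truth. Returns a report dict with an overall "ok" flag."""
    from .pipeline import run_pipeline_from_objects

    study = simulate_study(cfg)
    report = run_pipeline_from_objects(
        design=study.design, tracks=study.tracks,
        ts_calls=study.ts_calls, wes_calls=study.wes_calls, sanger=study.sanger,
    )
    planted = study.truth.counts()
    rec = report["hfi_concordance"]["counts"]
    recovered = {
        "shared_true": rec["n_true"] - rec["n_true_unique_ts"] - rec["n_true_unique_wes"],
        "ts_only_true": rec["n_true_unique_ts"],
        "wes_only_true": rec["n_true_unique_wes"],
        "ts_false_positives": rec["n_false_ts"],
        "wes_false_positives": rec["n_false_wes"],
    }
    ok = recovered == planted
    return {
        "planted": planted,
        "recovered": recovered,
        "metrics": report["hfi_concordance"]["metrics"],
        "report": report,
        "ok": ok,
    }
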