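"""End-to-end orchestration: filters -> coverage -> triage -> concordance -> report.

The report is a plain JSON-serializable dict in which every printed percentage
is recomputable from integer counts also present in the report.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .callset import (VariantCall, apply_af_filter, apply_depth_filter,
                      apply_pass_filter, read_callset, restrict_to_targets,
                      variant_key)
from .concordance import (ComparisonResult, VariantKey, assign_all_reasons,
                          assign_truth, compare_callsets, round_half_up,
                          true_keys, venn_summary)
from .coverage import DepthTrack, read_depth_tsv, summarize_coverage
from .hfi import HfiThresholds, classify_callset
from .intervals import PanelDesign, build_targets, read_gene_models


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full validation run."""

    panel_path: Optional[str] = None
    depth_dir: Optional[str] = None        # {sample}.{platform}.depth.tsv files
    ts_callset_path: Optional[str] = None
    wes_callset_path: Optional[str] = None
    sanger_path: Optional[str] = None
    out_dir: str = "panelval_out"
    min_depth: int = 10
    min_af: float = 0.20
    maf_rare: float = 0.005
    maf_max: float = 0.05
    cadd_min: float = 20.0
    reason_depth_threshold: int = 10
    gc_misalign: float = 70.0
    coverage_threshold: int = 10
    flank: int = 25
    metrics_over_all_variants: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def key_str(key: VariantKey) -> str:
    return f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"


def read_sanger_tsv(path) -> dict[VariantKey, bool]:
    """Confirmation labels: TSV with columns chrom, pos, ref, alt, confirmed."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    labels = {}
    for row in df.itertuples(index=False):
        confirmed = str(row.confirmed).strip().lower() in ("yes", "true", "confirmed", "1")
        labels[(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))] = confirmed
    return labels


def write_sanger_tsv(labels: Mapping[VariantKey, bool], path) -> None:
    rows = [{"chrom": k[0], "pos": k[1], "ref": k[2], "alt": k[3],
             "confirmed": "yes" if v else "no"} for k, v in sorted(labels.items())]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "confirmed"]).to_csv(
        path, sep="\t", index=False)


def _concordance_block(cmp: ComparisonResult) -> dict:
    """Counts + metrics for an adjudicated comparison (truth assigned)."""
    from .concordance import detection_rate, specificity

    truths = true_keys(cmp)
    falses = {k for k, t in cmp.truth.items() if t == "false_unconfirmed"}
    counts = {
        "n_true": len(truths),
        "n_true_unique_ts": len(cmp.ts_only & truths),
        "n_true_unique_wes": len(cmp.wes_only & truths),
        "n_false_ts": len(cmp.ts_only & falses),
        "n_false_wes": len(cmp.wes_only & falses),
        "n_calls_ts": len({k for k in cmp.platform_keys("TS")
                           if cmp.truth.get(k) != "untested"}),
        "n_calls_wes": len({k for k in cmp.platform_keys("WES")
                            if cmp.truth.get(k) != "untested"}),
        "n_untested": sum(1 for t in cmp.truth.values() if t == "untested"),
    }
    metrics = {
        "detection_rate_ts": detection_rate(cmp, "TS"),
        "detection_rate_wes": detection_rate(cmp, "WES"),
        "specificity_ts": specificity(cmp, "TS"),
        "specificity_wes": specificity(cmp, "WES"),
    }
    return {"counts": counts, "metrics": metrics,
            "venn_true": venn_summary(cmp, true_only=True)}


def run_pipeline_from_objects(
    design: PanelDesign,
    tracks: Sequence[DepthTrack],
    ts_calls: Sequence[VariantCall],
    wes_calls: Sequence[VariantCall],
    sanger: Mapping[VariantKey, bool],
    config: Optional[PipelineConfig] = None,
) -> dict:
    """Run restrict -> filters -> coverage -> triage -> compare -> truth ->
    reasons -> metrics on in-memory objects and return the report dict."""
    cfg = config or PipelineConfig()
    thresholds = HfiThresholds(maf_rare=cfg.maf_rare, maf_max=cfg.maf_max,
                               cadd_min=cfg.cadd_min)
    raw_calls = list(ts_calls) + list(wes_calls)

    def filtered(calls):
        out = restrict_to_targets(calls, design)
        out = apply_depth_filter(out, cfg.min_depth)
        out = apply_af_filter(out, cfg.min_af)
        return apply_pass_filter(out)

    ts_f, wes_f = filtered(ts_calls), filtered(wes_calls)

    hfi_calls, verdicts = classify_callset(ts_f + wes_f, thresholds)
    hfi_keys = {variant_key(c) for c in hfi_calls}
    criterion_counts = (
        verdicts.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
        ["criterion"].value_counts().to_dict()
    )

    cmp = compare_callsets(ts_f, wes_f)
    cmp = assign_truth(cmp, sanger)
    ts_tracks = {t.sample_id: t for t in tracks if t.platform == "TS"}
    wes_tracks = {t.sample_id: t for t in tracks if t.platform == "WES"}

    cmp_hfi = cmp.subset(hfi_keys)
    assign_all_reasons(cmp_hfi, ts_tracks, wes_tracks, raw_calls,
                       reason_depth_threshold=cfg.reason_depth_threshold,
                       gc_misalign=cfg.gc_misalign)

    coverage = summarize_coverage(tracks, design, cfg.coverage_threshold) if tracks else None

    report: dict = {
        "n_calls": {"TS_raw": len(ts_calls), "WES_raw": len(wes_calls),
                    "TS_filtered": len(ts_f), "WES_filtered": len(wes_f)},
        "no_variants": not (ts_f or wes_f),
        "all_variants_venn": venn_summary(cmp),
        "hfi": {
            "n_hfi_keys": len(hfi_keys),
            "criterion_counts": {k: int(v) for k, v in sorted(criterion_counts.items())},
        },
        "hfi_venn": venn_summary(cmp, hfi_keys=hfi_keys),
        "hfi_concordance": _concordance_block(cmp_hfi) if cmp_hfi.all_keys else None,
        "discrepancy_reasons": {key_str(k): v for k, v in sorted(cmp_hfi.reasons.items())},
    }
    if cfg.metrics_over_all_variants and cmp.all_keys:
        report["all_concordance"] = _concordance_block(cmp)
    if coverage is not None:
        per_sample = coverage.per_sample.sort_values(["platform", "sample_id"])
        report["coverage"] = {
            "per_sample": per_sample.to_dict(orient="records"),
            "exon_low_fraction": coverage.exon_low_fraction,
            "threshold": coverage.threshold,
            "platform_means": {
                p: round_half_up(float(g["mean_depth"].mean()))
                for p, g in per_sample.groupby("platform")
            },
        }
    report["_objects"] = {"cmp": cmp, "cmp_hfi": cmp_hfi, "hfi_keys": hfi_keys,
                         "verdicts": verdicts, "coverage": coverage,
                         "raw_calls": raw_calls}
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """File-driven run: read inputs per config, execute, write the report bundle."""
    if not all([cfg.panel_path, cfg.ts_callset_path, cfg.wes_callset_path]):
        raise ValueError("panel_path, ts_callset_path and wes_callset_path are required")
    genes = read_gene_models(cfg.panel_path)
    design = build_targets(genes, flank=cfg.flank)
    tracks = []
    if cfg.depth_dir:
        for path in sorted(Path(cfg.depth_dir).glob("*.depth.tsv")):
            sample_id, platform = path.name.split(".")[0:2]
            tracks.append(read_depth_tsv(path, sample_id, platform))
    ts_calls = read_callset(cfg.ts_callset_path, "TS")
    wes_calls = read_callset(cfg.wes_callset_path, "WES")
    sanger = read_sanger_tsv(cfg.sanger_path) if cfg.sanger_path else {}
    report = run_pipeline_from_objects(design, tracks, ts_calls, wes_calls, sanger, cfg)
    write_report(report, cfg.out_dir)
    return report


def write_report(report: dict, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in report.items() if not k.startswith("_")}
    with open(out / "report.json", "w") as fh:
        json.dump(serializable, fh, indent=2, sort_keys=True, default=str)
    tables = render_tables(report)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


DISCREPANCY_COLUMNS = ["platform", "gene", "rsid", "consequence", "clinvar_sig",
                       "cadd", "maf_exac_nfe", "confirmation", "gc_pct",
                       "depth_TS", "depth_WES", "reason"]


def render_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Render the publication-style output tables from a report.

    coverage_summary: one row per sample with both platforms side by side,
    plus "mean" and "sd" rows (sample sd, n-1). discrepancies: one row per
    platform-unique HFI variant with the 12-column discrepancy-table layout.
    venn: set-decomposition counts and integer percentages.
    """
    tables: dict[str, pd.DataFrame] = {}

    cov = report.get("coverage")
    if cov and cov["per_sample"]:
        df = pd.DataFrame(cov["per_sample"])
        wide = df.pivot_table(index="sample_id", columns="platform",
                              values=["mean_depth", "pct_bases_at_threshold"])
        wide.columns = [f"{p}_{m}" for m, p in wide.columns]
        wide = wide.reset_index()
        data_cols = [c for c in wide.columns if c != "sample_id"]
        mean_row = {"sample_id": "mean", **{c: round_half_up(wide[c].mean(), 1)
                                            for c in data_cols}}
        sd_row = {"sample_id": "sd", **{c: round_half_up(wide[c].std(ddof=1), 1)
                                        for c in data_cols}}
        tables["coverage_summary"] = pd.concat(
            [wide, pd.DataFrame([mean_row, sd_row])], ignore_index=True)
    else:
        tables["coverage_summary"] = pd.DataFrame(
            columns=["sample_id", "TS_mean_depth", "TS_pct_bases_at_threshold",
                     "WES_mean_depth", "WES_pct_bases_at_threshold"])

    rows = []
    objs = report.get("_objects")
    if objs is not None:
        cmp_hfi = objs["cmp_hfi"]
        by_key: dict = {}
        for c in objs["raw_calls"]:
            by_key.setdefault(variant_key(c), c)
        for key in sorted(cmp_hfi.ts_only | cmp_hfi.wes_only):
            call = by_key.get(key)
            ann = call.annotation if call else None
            platform = "TS" if key in cmp_hfi.ts_only else "WES"
            truth = cmp_hfi.truth.get(key, "untested")
            rows.append({
                "platform": platform,
                "gene": ann.gene if ann else "",
                "rsid": (ann.rsid or "") if ann else "",
                "consequence": ann.consequence if ann else "",
                "clinvar_sig": ann.clinvar_sig if ann else "",
                "cadd": ann.cadd if ann else None,
                "maf_exac_nfe": ann.maf_exac_nfe if ann else None,
                "confirmation": {"true_confirmed": "Confirmed",
                                 "false_unconfirmed": "Not Confirmed",
                                 "true_shared": "Not tested",
                                 "untested": "Not tested"}[truth],
                "gc_pct": ann.gc_content_pct if ann else None,
                "depth_TS": call.depth if call and platform == "TS" else None,
                "depth_WES": call.depth if call and platform == "WES" else None,
                "reason": cmp_hfi.reasons.get(key, ""),
            })
    tables["discrepancies"] = pd.DataFrame(rows, columns=DISCREPANCY_COLUMNS)

    venn_rows = []
    for name in ("all_variants_venn", "hfi_venn"):
        block = report.get(name)
        if block:
            for part in ("both", "ts_only", "wes_only"):
                venn_rows.append({"universe": name, "part": part,
                                  "count": block["counts"][part],
                                  "percent": block["percentages"][part]})
    conc = report.get("hfi_concordance")
    if conc:
        for part in ("both", "ts_only", "wes_only"):
            venn_rows.append({"universe": "hfi_true_venn", "part": part,
                              "count": conc["venn_true"]["counts"][part],
                              "percent": conc["venn_true"]["percentages"][part]})
    tables["venn"] = pd.DataFrame(venn_rows,
                                  columns=["universe", "part", "count", "percent"])
    return tables
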