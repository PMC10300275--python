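"""Cross-platform callset comparison, truth assignment, and validation metrics.

The truth model follows the validation-study convention for paired platforms:
a variant detected by both platforms is accepted as true without orthogonal
testing; a platform-unique variant is adjudicated by its Sanger confirmation
label (confirmed -> true, not confirmed -> false positive; unlabeled ->
untested and excluded from metrics with a warning).

  detection rate of platform P = 100 x (true variants called by P) / (all true)
  specificity of platform P    = 100 x (true calls by P) / (all calls by P)
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .callset import VariantCall, variant_key
from .coverage import DepthTrack

VariantKey = tuple[str, int, str, str]

TRUTH_STATES = ("true_shared", "true_confirmed", "false_unconfirmed", "untested")
DISCREPANCY_REASONS = (
    "insufficient_coverage_other_platform",
    "pipeline_filter_fail",
    "false_positive_misalignment",
    "unexplained",
)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (printed-report convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ComparisonResult:
    """Three-way key partition of two platform callsets, with per-key records."""

    shared: set[VariantKey]
    ts_only: set[VariantKey]
    wes_only: set[VariantKey]
    # key -> set of sample_ids per platform
    samples: dict[VariantKey, dict[str, set[str]]] = field(default_factory=dict)
    truth: dict[VariantKey, str] = field(default_factory=dict)
    reasons: dict[VariantKey, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.shared & self.ts_only)
        assert not (self.shared & self.wes_only)
        assert not (self.ts_only & self.wes_only)

    @property
    def all_keys(self) -> set[VariantKey]:
        return self.shared | self.ts_only | self.wes_only

    def platform_keys(self, platform: str) -> set[VariantKey]:
        unique = self.ts_only if platform == "TS" else self.wes_only
        return self.shared | unique

    def subset(self, keys: set[VariantKey]) -> "ComparisonResult":
        """Restrict the comparison to a key subset (e.g. the HFI universe)."""
        return ComparisonResult(
            shared=self.shared & keys,
            ts_only=self.ts_only & keys,
            wes_only=self.wes_only & keys,
            samples={k: v for k, v in self.samples.items() if k in keys},
            truth={k: v for k, v in self.truth.items() if k in keys},
            reasons={k: v for k, v in self.reasons.items() if k in keys},
        )


def compare_callsets(
    ts_calls: Sequence[VariantCall], wes_calls: Sequence[VariantCall]
) -> ComparisonResult:
    """Partition the union of variant keys into shared / TS-only / WES-only.

    Callsets must already be normalized, target-restricted and filtered. The
    universe is deduplicated at the key level across samples: a key counts as
    shared when both platforms called it (in any sample).
    """
    samples: dict[VariantKey, dict[str, set[str]]] = {}
    for calls, platform in ((ts_calls, "TS"), (wes_calls, "WES")):
        for c in calls:
            rec = samples.setdefault(variant_key(c), {"TS": set(), "WES": set()})
            rec[platform].add(c.sample_id)
    shared, ts_only, wes_only = set(), set(), set()
    for key, rec in samples.items():
        if rec["TS"] and rec["WES"]:
            shared.add(key)
        elif rec["TS"]:
            ts_only.add(key)
        else:
            wes_only.add(key)
    return ComparisonResult(shared=shared, ts_only=ts_only, wes_only=wes_only,
                            samples=samples)


def assign_truth(
    cmp: ComparisonResult, sanger: Mapping[VariantKey, bool]
) -> ComparisonResult:
    """Attach a truth status to every key.

    Shared keys are true without testing; platform-unique keys need a Sanger
    label (confirmed/not confirmed); unlabeled unique keys become "untested"
    and are excluded from metrics.
    """
    truth: dict[VariantKey, str] = {}
    n_untested = 0
    for key in cmp.shared:
        truth[key] = "true_shared"
    for key in cmp.ts_only | cmp.wes_only:
        if key in sanger:
            truth[key] = "true_confirmed" if sanger[key] else "false_unconfirmed"
        else:
            truth[key] = "untested"
            n_untested += 1
    if n_untested:
        warnings.warn(
            f"{n_untested} platform-unique variants lack a confirmation label; "
            "excluded from detection-rate/specificity metrics"
        )
    cmp.truth = truth
    return cmp


def _require_truth(cmp: ComparisonResult) -> None:
    if not cmp.truth and cmp.all_keys:
        raise ValueError("truth not assigned: call assign_truth first")


def true_keys(cmp: ComparisonResult) -> set[VariantKey]:
    return {k for k, t in cmp.truth.items() if t in ("true_shared", "true_confirmed")}


def detection_rate(cmp: ComparisonResult, platform: str) -> float:
    """Percent of all true variants called by the platform, half-up to 1 dp."""
    _require_truth(cmp)
    truths = true_keys(cmp)
    if not truths:
        raise ValueError("zero true variants: detection rate undefined")
    called = cmp.platform_keys(platform) & truths
    return round_half_up(100.0 * len(called) / len(truths), 1)


def specificity(cmp: ComparisonResult, platform: str) -> float:
    """Percent of the platform's (adjudicated) calls that are true, 1 dp."""
    _require_truth(cmp)
    calls = {k for k in cmp.platform_keys(platform) if cmp.truth.get(k) != "untested"}
    if not calls:
        raise ValueError(f"zero adjudicated calls for platform {platform}")
    n_true = len(calls & true_keys(cmp))
    return round_half_up(100.0 * n_true / len(calls), 1)


@dataclass(frozen=True)
class ConcordanceMetrics:
    detection_rate_ts: float
    detection_rate_wes: float
    specificity_ts: float
    specificity_wes: float
    n_true: int
    n_true_ts: int
    n_true_wes: int
    n_calls_ts: int
    n_calls_wes: int
    n_false_ts: int
    n_false_wes: int


def concordance_metrics(cmp: ComparisonResult) -> ConcordanceMetrics:
    """All four headline metrics plus the integer counts behind them."""
    _require_truth(cmp)
    truths = true_keys(cmp)
    falses = {k for k, t in cmp.truth.items() if t == "false_unconfirmed"}
    ts_calls = {k for k in cmp.platform_keys("TS") if cmp.truth.get(k) != "untested"}
    wes_calls = {k for k in cmp.platform_keys("WES") if cmp.truth.get(k) != "untested"}
    return ConcordanceMetrics(
        detection_rate_ts=detection_rate(cmp, "TS"),
        detection_rate_wes=detection_rate(cmp, "WES"),
        specificity_ts=specificity(cmp, "TS"),
        specificity_wes=specificity(cmp, "WES"),
        n_true=len(truths),
        n_true_ts=len(ts_calls & truths),
        n_true_wes=len(wes_calls & truths),
        n_calls_ts=len(ts_calls),
        n_calls_wes=len(wes_calls),
        n_false_ts=len(ts_calls & falses),
        n_false_wes=len(wes_calls & falses),
    )


def assign_discrepancy_reason(
    key: VariantKey,
    cmp: ComparisonResult,
    ts_tracks: Mapping[str, DepthTrack],
    wes_tracks: Mapping[str, DepthTrack],
    raw_calls: Sequence[VariantCall] = (),
    reason_depth_threshold: int = 10,
    gc_misalign: float = 70.0,
) -> str:
    """Explain why a platform-unique variant was missed by the other platform.

    Cascade, first hit wins:
      1. the non-calling platform's depth at the locus (in the sample(s) where
         the variant was called) is below `reason_depth_threshold` ->
         insufficient coverage; a missing track counts as depth 0;
      2. the non-calling platform produced a record at the key that failed its
         pipeline filter -> pipeline filter fail;
      3. the variant is an unconfirmed false positive with GC-rich
         (>= `gc_misalign` %) or repeat-flagged context -> misalignment FP;
      4. otherwise unexplained.

    `reason_depth_threshold` defaults to the 10x calling cutoff but is
    configurable: published discrepancy tables label loci at 14-15x as
    insufficiently covered, i.e. use an operational threshold above the cutoff.
    """
    if key in cmp.shared:
        raise ValueError("discrepancy reasons apply to platform-unique variants only")
    chrom, pos, _, _ = key
    calling = "TS" if key in cmp.ts_only else "WES"
    other = "WES" if calling == "TS" else "TS"
    other_tracks = wes_tracks if other == "WES" else ts_tracks
    call_samples = cmp.samples.get(key, {}).get(calling, set()) or {None}

    depths = []
    for sid in call_samples:
        track = other_tracks.get(sid) if sid is not None else None
        depths.append(track.depth_at(chrom, pos) if track is not None else 0)
    if max(depths, default=0) < reason_depth_threshold:
        return "insufficient_coverage_other_platform"

    for c in raw_calls:
        if c.platform == other and variant_key(c) == key and not c.filter_pass:
            return "pipeline_filter_fail"

    if cmp.truth.get(key) == "false_unconfirmed":
        anns = [c.annotation for c in raw_calls
                if variant_key(c) == key and c.platform == calling]
        for ann in anns:
            gc_rich = ann.gc_content_pct is not None and ann.gc_content_pct >= gc_misalign
            if gc_rich or ann.repeat_flag:
                return "false_positive_misalignment"
    return "unexplained"


def assign_all_reasons(
    cmp: ComparisonResult,
    ts_tracks: Mapping[str, DepthTrack],
    wes_tracks: Mapping[str, DepthTrack],
    raw_calls: Sequence[VariantCall] = (),
    **kwargs,
) -> ComparisonResult:
    cmp.reasons = {
        key: assign_discrepancy_reason(key, cmp, ts_tracks, wes_tracks, raw_calls, **kwargs)
        for key in cmp.ts_only | cmp.wes_only
    }
    return cmp


def venn_summary(cmp: ComparisonResult, hfi_keys: Optional[set[VariantKey]] = None,
                 true_only: bool = False) -> dict:
    """Set-decomposition counts with integer percentages of the total.

    With `true_only`, untested and false keys are dropped first (requires
    truth); with `hfi_keys`, the universe is first restricted to those keys.
    """
    sub = cmp.subset(hfi_keys) if hfi_keys is not None else cmp
    if true_only:
        _require_truth(sub)
        sub = sub.subset(true_keys(sub))
    counts = {"both": len(sub.shared), "ts_only": len(sub.ts_only),
              "wes_only": len(sub.wes_only)}
    total = sum(counts.values())
    pcts = {k: (int(round_half_up(100.0 * v / total)) if total else 0)
            for k, v in counts.items()}
    return {"counts": {**counts, "total": total}, "percentages": pcts}
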