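"""Calling histone-degradation regions from pulse-chase peak comparisons.

A region is called degraded in a genotype when the labeled-histone signal
present at chase time 0 h is gone or significantly reduced at 4 h:

* a 0-h peak with no overlapping 4-h peak at all ("unique at 0 h"), or
* a common peak whose 0-h density exceeds the depth-normalized 4-h density
  by at least ``min_m`` log2 units with an Audic-Claverie p-value below
  ``alpha``.

PA200-dependent regions are then the wild-type degraded regions that do
not overlap any knockout degraded region: degradation that the knockout
fails to perform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, overlap_length
from .peaks import NormalizationModel, Peak, classify_common_unique, differential_pvalue, pair_common_peaks

__all__ = ["RegionCall", "DegradationRegionSet", "call_degraded_regions", "pa200_dependent_regions"]

UNIQUE_0H = "unique_0h"
DIFFERENTIAL_COMMON = "differential_common"


@dataclass(frozen=True)
class RegionCall:
    """One degraded region with its provenance and, for common-peak calls,
    the degradation statistics (M = log2 0h/4h, AC p-value)."""

    interval: GenomicInterval
    provenance: str
    m: float | None = None
    pvalue: float | None = None


@dataclass
class DegradationRegionSet:
    regions: list[RegionCall]
    genotype: str

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [r.interval for r in self.regions]

    def counts_by_provenance(self) -> dict[str, int]:
        out = {UNIQUE_0H: 0, DIFFERENTIAL_COMMON: 0}
        for r in self.regions:
            out[r.provenance] += 1
        return out


def _merge_calls(calls: list[RegionCall]) -> list[RegionCall]:
    """Merge overlapping calls; mixed provenance becomes differential_common."""
    merged: list[RegionCall] = []
    for call in sorted(calls, key=lambda r: (r.interval.chrom, r.interval.start)):
        if merged and overlap_length(merged[-1].interval, call.interval) > 0:
            prev = merged[-1]
            iv = GenomicInterval(
                prev.interval.chrom,
                prev.interval.start,
                max(prev.interval.end, call.interval.end),
            )
            prov = (
                UNIQUE_0H
                if prev.provenance == call.provenance == UNIQUE_0H
                else DIFFERENTIAL_COMMON
            )
            ms = [x for x in (prev.m, call.m) if x is not None]
            ps = [x for x in (prev.pvalue, call.pvalue) if x is not None]
            merged[-1] = RegionCall(
                iv,
                prov,
                m=max(ms) if ms else None,
                pvalue=min(ps) if ps else None,
            )
        else:
            merged.append(call)
    return merged


def call_degraded_regions(
    peaks_0h: list[Peak],
    peaks_4h: list[Peak],
    model: NormalizationModel,
    alpha: float = 0.01,
    min_m: float = 1.0,
    min_bp: int = 1,
    genotype: str = "",
) -> DegradationRegionSet:
    """Degraded regions = unique-at-0h peaks plus significantly dropped common peaks.

    ``model`` must have been fitted with the 0-h sample as sample 1 and the
    4-h sample as sample 2 (so its M is log2 4h/0h); the per-region M
    reported here is the degradation direction, log2(0h / normalized 4h).
    """
    common0, _, unique0, _ = classify_common_unique(peaks_0h, peaks_4h, min_bp=min_bp)
    calls = [RegionCall(p.interval, UNIQUE_0H) for p in unique0]

    for p0, p4 in pair_common_peaks(common0, peaks_4h):
        d0 = p0.raw_density
        d4n = model.normalized_density2(d0, p4.raw_density)
        c = model.pseudocount
        m_deg = float(np.log2((d0 + c) / (d4n + c)))
        length_kb = p0.interval.length / 1000.0
        p = differential_pvalue(d0 * length_kb, d4n * length_kb)
        if m_deg >= min_m and p < alpha:
            calls.append(RegionCall(p0.interval, DIFFERENTIAL_COMMON, m=m_deg, pvalue=p))

    return DegradationRegionSet(_merge_calls(calls), genotype=genotype)


def pa200_dependent_regions(
    wt: DegradationRegionSet,
    ko: DegradationRegionSet,
    min_bp: int = 1,
) -> DegradationRegionSet:
    """Wild-type degraded regions with no >= min_bp overlap with any KO region."""
    ko_by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in ko.regions:
        ko_by_chrom.setdefault(r.interval.chrom, []).append(r.interval)
    kept = [
        r
        for r in wt.regions
        if not any(
            overlap_length(r.interval, q) >= min_bp
            for q in ko_by_chrom.get(r.interval.chrom, [])
        )
    ]
    return DegradationRegionSet(kept, genotype="PA200-dependent")
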