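"""WGBS-style methylation: region classification, genome areas, and DMRs.

The classification rule follows the hyper/hypo convention used for
CpG methylation summaries: a region or genome area is *hyper*-methylated
iff its unweighted mean CpG (CG) level is strictly greater than 0.5, and
*hypo*-methylated otherwise, provided it contains at least ``min_sites``
CpGs (fewer gives ``no_data``). Hyper-methylation proxies transcriptionally
inactive chromatin; hypo-methylation proxies active chromatin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .intervals import GenomicInterval

__all__ = [
    "MethylationTable",
    "AreaClassification",
    "HYPER",
    "HYPO",
    "NO_DATA",
    "region_mean_methylation",
    "classify_regions",
    "segment_genome_areas",
    "call_dmrs",
]

HYPER = "hyper"
HYPO = "hypo"
NO_DATA = "no_data"


class MethylationTable:
    """Per-CpG methylation levels, sorted by position within each chromosome."""

    def __init__(
        self,
        positions: Mapping[str, np.ndarray],
        levels: Mapping[str, np.ndarray],
        coverage: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.positions: dict[str, np.ndarray] = {}
        self.levels: dict[str, np.ndarray] = {}
        self.coverage: dict[str, np.ndarray] | None = (
            {} if coverage is not None else None
        )
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            lev = np.asarray(levels[chrom], dtype=float)
            if pos.shape != lev.shape:
                raise ValueError(f"position/level length mismatch on {chrom}")
            if np.any((lev < 0) | (lev > 1)):
                raise ValueError(f"levels outside [0, 1] on {chrom}")
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = pos[order]
            self.levels[chrom] = lev[order]
            if coverage is not None:
                self.coverage[chrom] = np.asarray(coverage[chrom])[order]  # type: ignore[index]

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def sites_in(self, region: GenomicInterval) -> np.ndarray:
        """Indices of CpGs falling inside ``region`` (half-open)."""
        pos = self.positions.get(region.chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        return np.arange(lo, hi)

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "MethylationTable":
        """Read per-CpG bedGraph: level in column 4, optional coverage column 5."""
        pos: dict[str, list[int]] = {}
        lev: dict[str, list[float]] = {}
        cov: dict[str, list[float]] = {}
        have_cov = None
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("track"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >= 4 columns")
                chrom = fields[0]
                pos.setdefault(chrom, []).append(int(fields[1]))
                lev.setdefault(chrom, []).append(float(fields[3]))
                if have_cov is None:
                    have_cov = len(fields) > 4
                if have_cov:
                    cov.setdefault(chrom, []).append(float(fields[4]))
        positions = {c: np.array(v) for c, v in pos.items()}
        levels = {c: np.array(v) for c, v in lev.items()}
        coverage = {c: np.array(v) for c, v in cov.items()} if have_cov else None
        return cls(positions, levels, coverage)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.positions):
                pos = self.positions[chrom]
                lev = self.levels[chrom]
                cov = self.coverage[chrom] if self.coverage is not None else None
                for i in range(len(pos)):
                    p = int(pos[i])
                    line = f"{chrom}\t{p}\t{p + 1}\t{lev[i]:.6g}"
                    if cov is not None:
                        line += f"\t{cov[i]:g}"
                    fh.write(line + "\n")


@dataclass(frozen=True)
class AreaClassification:
    interval: GenomicInterval
    mean_cg: float  # nan for no_data
    label: str
    n_sites: int = 0


def region_mean_methylation(
    region: GenomicInterval,
    records: MethylationTable,
    min_sites: int = 3,
) -> float | None:
    """Unweighted mean CpG level inside ``region``; None if < min_sites CpGs."""
    idx = records.sites_in(region)
    if len(idx) < min_sites:
        return None
    return float(records.levels[region.chrom][idx].mean())


def _classify_mean(mean: float | None) -> str:
    if mean is None:
        return NO_DATA
    return HYPER if mean > 0.5 else HYPO


def classify_regions(
    regions: Sequence[GenomicInterval],
    records: MethylationTable,
    min_sites: int = 3,
) -> tuple[dict[str, int], list[AreaClassification]]:
    """Label each region hyper (mean CG > 0.5), hypo, or no_data.

    Returns (counts, per-region classifications); counts sum to len(regions).
    """
    labeled: list[AreaClassification] = []
    counts = {HYPER: 0, HYPO: 0, NO_DATA: 0}
    for region in regions:
        idx = records.sites_in(region)
        mean = (
            float(records.levels[region.chrom][idx].mean())
            if len(idx) >= min_sites
            else None
        )
        label = _classify_mean(mean)
        counts[label] += 1
        labeled.append(
            AreaClassification(
                region,
                mean if mean is not None else float("nan"),
                label,
                n_sites=len(idx),
            )
        )
    return counts, labeled


def segment_genome_areas(
    records: MethylationTable,
    chrom_sizes: Mapping[str, int],
    window: int = 10_000,
    min_sites: int = 3,
) -> list[AreaClassification]:
    """Tile the genome in fixed windows and merge same-label runs into areas.

    Each window is classified by the hyper/hypo rule; adjacent windows with
    the same label merge into one area, and no_data windows (kept in the
    output) break merging. Area mean is the unweighted mean over the CpGs
    of the merged span.
    """
    if window < 1000:
        raise ValueError("window must be >= 1000 bp")
    areas: list[AreaClassification] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        run: tuple[int, int, str] | None = None  # start, end, label
        for start in range(0, size, window):
            end = min(start + window, size)
            w = GenomicInterval(chrom, start, end)
            idx = records.sites_in(w)
            mean = (
                float(records.levels[chrom][idx].mean())
                if len(idx) >= min_sites
                else None
            )
            label = _classify_mean(mean)
            if run is not None and run[2] == label:
                run = (run[0], end, label)
            else:
                if run is not None:
                    areas.append(_finish_area(run, chrom, records, min_sites))
                run = (start, end, label)
        if run is not None:
            areas.append(_finish_area(run, chrom, records, min_sites))
    return areas


def _finish_area(
    run: tuple[int, int, str],
    chrom: str,
    records: MethylationTable,
    min_sites: int,
) -> AreaClassification:
    start, end, label = run
    iv = GenomicInterval(chrom, start, end)
    idx = records.sites_in(iv)
    mean = float(records.levels[chrom][idx].mean()) if len(idx) >= min_sites else float("nan")
    return AreaClassification(iv, mean, label, n_sites=len(idx))


@dataclass(frozen=True)
class DMR:
    interval: GenomicInterval
    direction: str  # hyper / hypo in sample b relative to sample a
    mean_a: float
    mean_b: float
    pvalue: float


def call_dmrs(
    records_a: MethylationTable,
    records_b: MethylationTable,
    chrom_sizes: Mapping[str, int],
    window: int = 1000,
    min_diff: float = 0.2,
    alpha: float = 0.05,
    min_sites: int = 3,
) -> list[DMR]:
    """Windowed differential-methylation caller.

    Windows with ``|mean_b - mean_a| >= min_diff`` in which a two-sample
    test passes BH-adjusted ``alpha`` are DMRs; adjacent same-direction
    windows merge. With per-CpG coverage on both sides the test is a
    coverage-weighted two-proportion z-test, otherwise Welch's t-test on
    site levels. Direction is hyper/hypo in b relative to a.
    """
    cand: list[tuple[GenomicInterval, float, float, float]] = []
    for chrom in sorted(chrom_sizes):
        for start in range(0, chrom_sizes[chrom], window):
            end = min(start + window, chrom_sizes[chrom])
            w = GenomicInterval(chrom, start, end)
            ia = records_a.sites_in(w)
            ib = records_b.sites_in(w)
            if len(ia) < min_sites or len(ib) < min_sites:
                continue
            la = records_a.levels[chrom][ia]
            lb = records_b.levels[chrom][ib]
            diff = float(lb.mean() - la.mean())
            if abs(diff) < min_diff - 1e-9:  # tolerance keeps exact-threshold shifts in
                continue
            p = _window_test(records_a, records_b, chrom, ia, ib, la, lb)
            cand.append((w, float(la.mean()), float(lb.mean()), p))
    if not cand:
        return []
    reject, *_ = multipletests([c[3] for c in cand], alpha=alpha, method="fdr_bh")
    windows = [
        DMR(w, HYPER if mb > ma else HYPO, ma, mb, p)
        for (w, ma, mb, p), keep in zip(cand, reject)
        if keep
    ]
    return _merge_dmrs(windows, window)


def _window_test(
    records_a: MethylationTable,
    records_b: MethylationTable,
    chrom: str,
    ia: np.ndarray,
    ib: np.ndarray,
    la: np.ndarray,
    lb: np.ndarray,
) -> float:
    if records_a.coverage is not None and records_b.coverage is not None:
        ca = records_a.coverage[chrom][ia]
        cb = records_b.coverage[chrom][ib]
        meth = np.array([np.sum(la * ca), np.sum(lb * cb)])
        tot = np.array([ca.sum(), cb.sum()])
        if tot.min() <= 0:
            return 1.0
        with np.errstate(invalid="ignore"):
            _, p = proportions_ztest(np.round(meth), tot)
        return float(p) if np.isfinite(p) else 1.0
    if np.var(la) == 0 and np.var(lb) == 0:
        return 0.0 if la.mean() != lb.mean() else 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(la, lb, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def _merge_dmrs(windows: list[DMR], window: int) -> list[DMR]:
    merged: list[DMR] = []
    for d in sorted(windows, key=lambda d: (d.interval.chrom, d.interval.start)):
        if (
            merged
            and merged[-1].direction == d.direction
            and merged[-1].interval.chrom == d.interval.chrom
            and merged[-1].interval.end == d.interval.start
        ):
            prev = merged[-1]
            merged[-1] = DMR(
                GenomicInterval(prev.interval.chrom, prev.interval.start, d.interval.end),
                prev.direction,
                (prev.mean_a + d.mean_a) / 2,
                (prev.mean_b + d.mean_b) / 2,
                min(prev.pvalue, d.pvalue),
            )
        else:
            merged.append(d)
    return merged
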