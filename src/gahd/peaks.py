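"""Simplified peak calling and MAnorm-style M-A normalization.

The caller scores each bin against a Poisson background whose rate is the
larger of the genome-wide mean and a local (10 kb) mean, controls the
bin-level FDR by Benjamini-Hochberg, and merges nearby significant bins.
It stands in for a full-featured caller where only peak locations and read
densities are needed downstream.

Two samples are then compared MAnorm-style: peaks overlapping between the
samples ("common" peaks) are assumed unchanged on average, an ordinary
least-squares line of M = log2 density ratio on A = mean log2 density is
fitted over them, and sample 2 is rescaled so the common-peak M values
centre on zero. Per-peak significance of a difference uses the
Audic-Claverie test on the rescaled counts rather than MAnorm's Bayesian
formulation: it is closed-form and plays the same decision role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .intervals import GenomicInterval, SignalTrack, overlap_length

__all__ = [
    "Peak",
    "NormalizationModel",
    "call_peaks",
    "classify_common_unique",
    "pair_common_peaks",
    "fit_manorm",
    "differential_pvalue",
]


@dataclass(frozen=True)
class Peak:
    """A called enrichment region with its read density (reads/kb)."""

    interval: GenomicInterval
    raw_density: float
    summit: int
    pvalue_enrichment: float
    normalized_density: float | None = None

    def __post_init__(self) -> None:
        if self.raw_density < 0:
            raise ValueError("density must be >= 0")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak")

    @property
    def count(self) -> float:
        """Approximate read count: density x length / 1000."""
        return self.raw_density * self.interval.length / 1000.0


def _bh_reject(pvalues: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up; returns boolean rejection mask."""
    m = pvalues.size
    order = np.argsort(pvalues, kind="stable")
    ranked = pvalues[order]
    thresh = alpha * np.arange(1, m + 1) / m
    below = ranked <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


def call_peaks(
    track: SignalTrack,
    fdr: float = 0.05,
    min_len: int = 200,
    merge_gap: int = 100,
    local_window: int = 10_000,
) -> list[Peak]:
    """Call enriched regions on a binned track.

    Per-bin Poisson upper-tail p-values against lambda = max(genome mean,
    centred ``local_window`` mean), BH-controlled at ``fdr``; significant
    bins closer than ``merge_gap`` bp are merged and peaks shorter than
    ``min_len`` bp are dropped. The summit is the centre of the highest bin.
    """
    b = track.bin_size
    total_bins = track.n_bins
    if total_bins == 0:
        raise ValueError("empty track")
    genome_mean = track.library_size / total_bins
    if genome_mean == 0:
        return []

    chroms = sorted(track.values)
    pvals: list[np.ndarray] = []
    for chrom in chroms:
        v = track.values[chrom]
        w = max(1, local_window // b)
        local = uniform_filter1d(v, size=w, mode="nearest")
        lam = np.maximum(genome_mean, local)
        # upper tail P(X >= v) for integer-ish counts
        pvals.append(stats.poisson.sf(np.ceil(v) - 1, lam))
    flat = np.concatenate(pvals)
    sig = _bh_reject(flat, fdr)

    peaks: list[Peak] = []
    gap_bins = merge_gap // b
    offset = 0
    for chrom, p in zip(chroms, pvals):
        v = track.values[chrom]
        n = len(v)
        mask = sig[offset : offset + n]
        offset += n
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            continue
        # merge runs of significant bins separated by <= gap_bins bins
        breaks = np.nonzero(np.diff(idx) > gap_bins + 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        for s_i, e_i in zip(starts, ends):
            k0, k1 = idx[s_i], idx[e_i]
            start_bp = int(k0 * b)
            end_bp = int(min((k1 + 1) * b, track.chrom_sizes[chrom]))
            if end_bp - start_bp < min_len:
                continue
            counts = float(v[k0 : k1 + 1].sum())
            kmax = k0 + int(np.argmax(v[k0 : k1 + 1]))
            summit = min(int(kmax * b + b // 2), end_bp - 1)
            density = counts / ((end_bp - start_bp) / 1000.0)
            peaks.append(
                Peak(
                    GenomicInterval(chrom, start_bp, end_bp),
                    raw_density=density,
                    summit=summit,
                    pvalue_enrichment=float(p[k0 : k1 + 1].min()),
                )
            )
    return peaks


def classify_common_unique(
    peaks1: list[Peak],
    peaks2: list[Peak],
    min_bp: int = 1,
) -> tuple[list[Peak], list[Peak], list[Peak], list[Peak]]:
    """Partition two peak lists into (common1, common2, unique1, unique2).

    A peak is common iff it overlaps any peak of the other sample by at
    least ``min_bp`` bases; the four lists are exhaustive and disjoint.
    """

    def split(query: list[Peak], subject: list[Peak]) -> tuple[list[Peak], list[Peak]]:
        by_chrom: dict[str, list[Peak]] = {}
        for p in subject:
            by_chrom.setdefault(p.interval.chrom, []).append(p)
        for lst in by_chrom.values():
            lst.sort(key=lambda p: p.interval.start)
        common: list[Peak] = []
        unique: list[Peak] = []
        for p in query:
            cands = by_chrom.get(p.interval.chrom, [])
            hit = any(
                overlap_length(p.interval, q.interval) >= min_bp
                for q in cands
                if q.interval.start < p.interval.end
                and q.interval.end > p.interval.start
            )
            (common if hit else unique).append(p)
        return common, unique

    common1, unique1 = split(peaks1, peaks2)
    common2, unique2 = split(peaks2, peaks1)
    return common1, common2, unique1, unique2


def pair_common_peaks(
    common1: list[Peak], peaks2: list[Peak]
) -> list[tuple[Peak, Peak]]:
    """Pair each common peak of sample 1 with its maximum-overlap sample-2 peak."""
    pairs: list[tuple[Peak, Peak]] = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks2:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for p in common1:
        best, best_ov = None, 0
        for q in by_chrom.get(p.interval.chrom, []):
            ov = overlap_length(p.interval, q.interval)
            if ov > best_ov:
                best, best_ov = q, ov
        if best is not None:
            pairs.append((p, best))
    return pairs


@dataclass(frozen=True)
class NormalizationModel:
    """M-A rescaling fitted on common peaks.

    M = log2((d2+c)/(d1+c)) and A = 0.5*log2((d1+c)(d2+c)) over paired
    common-peak densities; the fitted line ``M = slope*A + intercept``
    captures depth and intensity-dependent distortion of sample 2 relative
    to sample 1, which :meth:`normalized_m` removes.
    """

    slope: float
    intercept: float
    pseudocount: float
    n_common: int

    def ma(self, d1: float, d2: float) -> tuple[float, float]:
        c = self.pseudocount
        m = np.log2((d2 + c) / (d1 + c))
        a = 0.5 * np.log2((d1 + c) * (d2 + c))
        return float(m), float(a)

    def predicted_m(self, a: float) -> float:
        return self.slope * a + self.intercept

    def normalized_m(self, d1: float, d2: float) -> float:
        m, a = self.ma(d1, d2)
        return m - self.predicted_m(a)

    def normalized_density2(self, d1: float, d2: float) -> float:
        """Sample-2 density rescaled onto sample 1's scale."""
        c = self.pseudocount
        _, a = self.ma(d1, d2)
        d2n = (d2 + c) * 2.0 ** (-self.predicted_m(a)) - c
        return max(0.0, float(d2n))


def fit_manorm(
    common1: list[Peak],
    common2: list[Peak],
    pseudocount: float = 1.0,
) -> NormalizationModel:
    """Fit the M-A rescaling over common peaks.

    ``common2`` may be the full sample-2 peak list; pairing picks the
    maximum-overlap partner for each sample-1 common peak. Requires at
    least 10 common peaks for a stable fit.
    """
    pairs = pair_common_peaks(common1, common2)
    if len(pairs) < 10:
        raise ValueError(f"need >= 10 common peaks to fit, got {len(pairs)}")
    c = pseudocount
    d1 = np.array([p.raw_density for p, _ in pairs])
    d2 = np.array([q.raw_density for _, q in pairs])
    m = np.log2((d2 + c) / (d1 + c))
    a = 0.5 * np.log2((d1 + c) * (d2 + c))
    if np.ptp(a) == 0:  # all densities equal: depth shift only
        slope, intercept = 0.0, float(m.mean())
    else:
        slope, intercept = np.polyfit(a, m, 1)
    return NormalizationModel(
        slope=float(slope),
        intercept=float(intercept),
        pseudocount=pseudocount,
        n_common=len(pairs),
    )


def differential_pvalue(x1: float, x2: float) -> float:
    """One-sided p-value that sample 1's count exceeds sample 2's.

    Under the Audic-Claverie equal-library model the second count given
    ``x1`` follows a negative binomial with n = x1 + 1 and p = 1/2; the
    p-value is P(Y <= x2). With this convention swapping the samples maps
    p to exactly 1 - p.
    """
    if x1 < 0 or x2 < 0:
        raise ValueError("counts must be >= 0")
    x1, x2 = int(round(x1)), int(round(x2))
    return float(stats.nbinom.cdf(x2, x1 + 1, 0.5))
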