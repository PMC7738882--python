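"""Genomic intervals, binned signal tracks, and the standard text formats.

Everything downstream (peak calling, degradation regions, metagene profiles)
is built on three containers defined here:

* :class:`GenomicInterval` — a 0-based half-open span (BED convention).
* :class:`SignalTrack` — per-chromosome read counts in fixed-width bins.
* :class:`GeneAnnotation` — a gene span with strand-aware TSS/TTS.

Strand affects only TSS/TTS orientation and profile flipping, never the
interval algebra itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "GeneAnnotation",
    "SignalTrack",
    "overlaps",
    "overlap_length",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_annotation",
    "write_gene_annotation",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Overlap in bp under half-open semantics: ``max(0, min(end) - max(start))``."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def overlaps(a: GenomicInterval, b: GenomicInterval, min_bp: int = 1) -> bool:
    """True iff ``a`` and ``b`` share at least ``min_bp`` bases."""
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    return overlap_length(a, b) >= min_bp


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene span; TSS/TTS follow strand (swapped for minus-strand genes)."""

    interval: GenomicInterval
    gene_id: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand != "-" else self.interval.start


class SignalTrack:
    """Per-chromosome binned read coverage.

    ``values[chrom][k]`` is the signal attributed to bases
    ``[k * bin_size, (k+1) * bin_size)``; every base within a bin carries the
    bin's value, which is what :meth:`range_sum` integrates over.
    """

    def __init__(
        self,
        values: Mapping[str, np.ndarray],
        bin_size: int,
        chrom_sizes: Mapping[str, int] | None = None,
    ) -> None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        self.bin_size = int(bin_size)
        self.values: dict[str, np.ndarray] = {
            c: np.asarray(v, dtype=float) for c, v in values.items()
        }
        for c, v in self.values.items():
            if v.ndim != 1:
                raise ValueError(f"values for {c} must be 1-D")
            if np.any(v < 0):
                raise ValueError(f"negative signal on {c}")
        if chrom_sizes is None:
            chrom_sizes = {c: len(v) * self.bin_size for c, v in self.values.items()}
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self._cum: dict[str, np.ndarray] = {}

    @property
    def library_size(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    @property
    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.values.values()))

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def _cumsum(self, chrom: str) -> np.ndarray:
        cum = self._cum.get(chrom)
        if cum is None:
            cum = np.concatenate([[0.0], np.cumsum(self.values[chrom])])
            self._cum[chrom] = cum
        return cum

    def range_sum(self, chrom: str, start: int, end: int) -> float:
        """Per-base integral of the track over ``[start, end)``.

        Equals the brute-force sum of the bin value at every base; partial
        bins contribute proportionally to the covered length.
        """
        if start >= end:
            raise ValueError("start must be < end")
        v = self.values[chrom]
        b = self.bin_size
        if start < 0 or end > len(v) * b:
            raise ValueError(f"[{start}, {end}) outside {chrom} track bounds")
        k0, k1 = start // b, (end - 1) // b
        if k0 == k1:
            return float(v[k0] * (end - start))
        total = v[k0] * ((k0 + 1) * b - start) + v[k1] * (end - k1 * b)
        if k1 > k0 + 1:
            cum = self._cumsum(chrom)
            total += (cum[k1] - cum[k0 + 1]) * b
        return float(total)

    def range_mean(self, chrom: str, start: int, end: int) -> float:
        return self.range_sum(chrom, start, end) / (end - start)

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: v * factor for c, v in self.values.items()},
            self.bin_size,
            self.chrom_sizes,
        )

    def rpm(self) -> "SignalTrack":
        """Depth-normalized copy (reads-per-million)."""
        lib = self.library_size
        if lib == 0:
            return self.scaled(1.0)
        return self.scaled(1e6 / lib)


# ---------------------------------------------------------------------------
# text-format I/O (tab-separated, '#' comments skipped)
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (file order, 0-based half-open)."""
    out: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
        name = fields[3] if len(fields) > 3 else None
        score = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed score") from exc
        strand = fields[5] if len(fields) > 5 else "."
        try:
            out.append(GenomicInterval(chrom, start, end, strand, name, score))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(repr(iv.score) if iv.score is not None else ".")
                fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(
    path: str | Path,
    bin_size: int,
    chrom_sizes: Mapping[str, int] | None = None,
) -> SignalTrack:
    """Rebin a 4-column bedGraph into a :class:`SignalTrack`.

    Each bin's value is the length-weighted average of overlapping records,
    with uncovered bases counting as zero. Overlapping records are rejected
    (the signal would be ambiguous).
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        records.setdefault(chrom, []).append((start, end, value))

    values: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for chrom, recs in records.items():
        recs.sort()
        for (s0, e0, _), (s1, _, _) in zip(recs, recs[1:]):
            if s1 < e0:
                raise ValueError(
                    f"overlapping bedGraph records on {chrom} at {s1} < {e0}"
                )
        if chrom_sizes is not None:
            length = chrom_sizes[chrom]
        else:
            length = -(-recs[-1][1] // bin_size) * bin_size
        n = -(-length // bin_size)
        acc = np.zeros(n)
        for start, end, value in recs:
            if end > length:
                raise ValueError(f"record past chromosome end on {chrom}")
            k0, k1 = start // bin_size, (end - 1) // bin_size
            if k0 == k1:
                acc[k0] += value * (end - start)
            else:
                acc[k0] += value * ((k0 + 1) * bin_size - start)
                acc[k1] += value * (end - k1 * bin_size)
                acc[k0 + 1 : k1] += value * bin_size
        values[chrom] = acc / bin_size
        sizes[chrom] = length
    if chrom_sizes is not None:
        for chrom, length in chrom_sizes.items():
            sizes[chrom] = length
            if chrom not in values:
                values[chrom] = np.zeros(-(-length // bin_size))
    return SignalTrack(values, bin_size, sizes)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write a track as bedGraph, merging runs of equal-valued bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            v = track.values[chrom]
            b = track.bin_size
            length = track.chrom_sizes[chrom]
            if len(v) == 0:
                continue
            run_start = 0
            for k in range(1, len(v) + 1):
                if k == len(v) or v[k] != v[run_start]:
                    if v[run_start] != 0.0:
                        end = min(k * b, length)
                        fh.write(
                            f"{chrom}\t{run_start * b}\t{end}\t{v[run_start]:g}\n"
                        )
                    run_start = k


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the 5-column annotation TSV (chrom, start, end, gene_id, strand)."""
    genes: list[GeneAnnotation] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 5:
            raise ValueError(f"{path}:{lineno}: expected 5 annotation columns")
        try:
            iv = GenomicInterval(
                fields[0], int(fields[1]), int(fields[2]), strand=fields[4]
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        genes.append(GeneAnnotation(iv, fields[3]))
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tstrand\n")
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t{iv.strand}\n")
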