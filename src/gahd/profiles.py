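"""Metagene and TSS-anchored signal profiles.

A metagene matrix has one row per gene and columns laid out as
``flank/flank_bin`` fixed-width upstream bins, ``n_body_bins`` equal
segments of the (variable-length) gene body, and ``flank/flank_bin``
downstream bins. Minus-strand genes are column-reversed so that column 0
is always biologically upstream of the TSS. Cells whose span falls even
partly outside the chromosome are NaN and are ignored by column averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .intervals import GeneAnnotation, SignalTrack

__all__ = [
    "ProfileMatrix",
    "metagene_matrix",
    "column_summary",
    "ratio_profile",
    "tss_signal",
]


@dataclass
class ProfileMatrix:
    values: np.ndarray  # genes x columns, NaN = no data
    gene_ids: list[str]
    flank: int
    flank_bin: int
    n_body_bins: int
    n_skipped: int = 0

    @property
    def n_flank_bins(self) -> int:
        return self.flank // self.flank_bin

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    def same_geometry(self, other: "ProfileMatrix") -> bool:
        return (
            self.flank == other.flank
            and self.flank_bin == other.flank_bin
            and self.n_body_bins == other.n_body_bins
            and self.gene_ids == other.gene_ids
        )


def _gene_segments(
    gene: GeneAnnotation,
    flank: int,
    n_body_bins: int,
    flank_bin: int,
) -> list[tuple[int, int]]:
    """Segment spans in genomic order: left flank bins, body bins, right flank."""
    iv = gene.interval
    segs: list[tuple[int, int]] = []
    for k in range(flank // flank_bin):
        s = iv.start - flank + k * flank_bin
        segs.append((s, s + flank_bin))
    bounds = [iv.start + round(i * iv.length / n_body_bins) for i in range(n_body_bins + 1)]
    for i in range(n_body_bins):
        segs.append((bounds[i], bounds[i + 1]))
    for k in range(flank // flank_bin):
        s = iv.end + k * flank_bin
        segs.append((s, s + flank_bin))
    return segs


def metagene_matrix(
    track: SignalTrack,
    genes: Sequence[GeneAnnotation],
    flank: int,
    n_body_bins: int = 100,
    flank_bin: int = 300,
) -> ProfileMatrix:
    """Scaled-gene-body profile matrix for ``genes`` over ``track``.

    Flank bins are fixed-width per-base means; the body is split into
    ``n_body_bins`` near-equal integer segments, each the per-base mean of
    the track over its span. Genes shorter than ``n_body_bins`` bp are
    skipped (counted in ``n_skipped``).
    """
    if flank % flank_bin != 0:
        raise ValueError("flank must be a multiple of flank_bin")
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped = 0
    for gene in genes:
        if gene.interval.length < n_body_bins:
            skipped += 1
            continue
        chrom = gene.interval.chrom
        size = track.chrom_sizes[chrom]
        row = np.empty(2 * (flank // flank_bin) + n_body_bins)
        for j, (s, e) in enumerate(_gene_segments(gene, flank, n_body_bins, flank_bin)):
            if s < 0 or e > size:
                row[j] = np.nan
            else:
                row[j] = track.range_mean(chrom, s, e)
        if gene.strand == "-":
            row = row[::-1]
        rows.append(row)
        ids.append(gene.gene_id)
    values = (
        np.vstack(rows)
        if rows
        else np.empty((0, 2 * (flank // flank_bin) + n_body_bins))
    )
    return ProfileMatrix(values, ids, flank, flank_bin, n_body_bins, n_skipped=skipped)


def column_summary(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise mean profile, ignoring NaN cells."""
    if matrix.values.shape[0] < 1:
        raise ValueError("need at least one gene row")
    with np.errstate(invalid="ignore"):
        return np.nanmean(matrix.values, axis=0)


def ratio_profile(
    numerator: ProfileMatrix,
    denominator: ProfileMatrix,
    pseudocount: float = 0.1,
    numerator_reference: ProfileMatrix | None = None,
    denominator_reference: ProfileMatrix | None = None,
) -> np.ndarray:
    """Per-column log2 ratio of column summaries.

    Single mode: ``log2((num + c) / (den + c))``. Double mode (both
    reference matrices given, e.g. H3): each side is first divided by its
    reference summary, matching mark-change-normalized-to-H3 profiles.
    """
    if not numerator.same_geometry(denominator):
        raise ValueError("matrix geometries differ")
    num = column_summary(numerator)
    den = column_summary(denominator)
    if (numerator_reference is None) != (denominator_reference is None):
        raise ValueError("provide both reference matrices or neither")
    if numerator_reference is not None:
        if not numerator_reference.same_geometry(numerator):
            raise ValueError("reference geometry differs")
        num = num / column_summary(numerator_reference)
        den = den / column_summary(denominator_reference)
    return np.log2((num + pseudocount) / (den + pseudocount))


def tss_signal(
    track: SignalTrack,
    genes: Sequence[GeneAnnotation],
    half_width: int = 2500,
    bin: int = 50,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Strand-oriented TSS +/- half_width signal per gene.

    Returns (matrix genes x bins, promoter means, gene ids); the promoter
    mean is the per-base mean over the in-bounds part of the window.
    Column 0 is the most upstream bin for every gene.
    """
    if half_width % bin != 0:
        raise ValueError("half_width must be a multiple of bin")
    n_bins = 2 * half_width // bin
    rows = np.empty((len(genes), n_bins))
    ids: list[str] = []
    for i, gene in enumerate(genes):
        chrom = gene.interval.chrom
        size = track.chrom_sizes[chrom]
        tss = gene.tss
        for k in range(n_bins):
            s = tss - half_width + k * bin
            e = s + bin
            rows[i, k] = (
                track.range_mean(chrom, s, e) if (s >= 0 and e <= size) else np.nan
            )
        if gene.strand == "-":
            rows[i] = rows[i, ::-1]
        ids.append(gene.gene_id)
    with np.errstate(invalid="ignore"):
        promoter_means = np.nanmean(rows, axis=1)
    return rows, promoter_means, ids
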