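"""Cross-dataset joins: marks vs expression classes, Pol II, DMRs, methylation.

All joins are by gene id; the per-gene report keeps one row per annotated
gene and records missing values instead of dropping rows. The headline
methylation percentage uses only classified regions (hyper + hypo) in its
denominator, matching the 550-of-6522 style of arithmetic, and rounds
half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .degradation import DegradationRegionSet
from .intervals import GeneAnnotation, GenomicInterval, overlap_length
from .methylation import HYPER, HYPO, MethylationTable, classify_regions

__all__ = [
    "mark_change_by_deg_class",
    "polii_concordance",
    "dmr_mark_inversion",
    "degradation_methylation_summary",
    "methylation_percentages",
]


def _round_half_up(x: float, digits: int) -> float:
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassSummary:
    means: dict[str, float | None]  # per DEG class, None where class empty
    n: dict[str, int]
    p_up_vs_down: float | None


def mark_change_by_deg_class(
    deg_records,
    tss_means_wt: Mapping[str, float],
    tss_means_ko: Mapping[str, float],
    pseudocount: float = 1.0,
) -> ClassSummary:
    """Mean promoter log2(KO/WT) mark change per expression class.

    Classes are the DEG calls (up/down/unchanged); significance of the
    up-vs-down separation is a two-sided Mann-Whitney test. A class with
    no genes gets a None mean.
    """
    groups: dict[str, list[float]] = {"up": [], "down": [], "unchanged": []}
    for rec in deg_records:
        wt = tss_means_wt.get(rec.gene_id)
        ko = tss_means_ko.get(rec.gene_id)
        if wt is None or ko is None or not (np.isfinite(wt) and np.isfinite(ko)):
            continue
        groups[rec.call].append(
            float(np.log2((ko + pseudocount) / (wt + pseudocount)))
        )
    means = {
        k: (float(np.mean(v)) if v else None) for k, v in groups.items()
    }
    p = None
    if groups["up"] and groups["down"]:
        p = float(
            stats.mannwhitneyu(
                groups["up"], groups["down"], alternative="two-sided"
            ).pvalue
        )
    return ClassSummary(
        means=means, n={k: len(v) for k, v in groups.items()}, p_up_vs_down=p
    )


def polii_concordance(
    mark_ratio_per_gene: Mapping[str, float],
    polii_ratio_per_gene: Mapping[str, float],
) -> tuple[float, float]:
    """Spearman correlation and sign-agreement between mark and Pol II changes."""
    shared = sorted(set(mark_ratio_per_gene) & set(polii_ratio_per_gene))
    shared = [
        g
        for g in shared
        if np.isfinite(mark_ratio_per_gene[g]) and np.isfinite(polii_ratio_per_gene[g])
    ]
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared genes, got {len(shared)}")
    x = np.array([mark_ratio_per_gene[g] for g in shared])
    y = np.array([polii_ratio_per_gene[g] for g in shared])
    rho = float(stats.spearmanr(x, y).statistic)
    agree = float(np.mean(np.sign(x) == np.sign(y)))
    return rho, agree


@dataclass(frozen=True)
class InversionSummary:
    mean_hypo_dmr: float | None
    mean_hyper_dmr: float | None
    n_hypo_genes: int
    n_hyper_genes: int

    @property
    def inversion_statistic(self) -> float | None:
        """mean(mark change over hypo-DMR genes) - mean(over hyper-DMR genes).

        Positive when marks move opposite to methylation (the inverse
        correlation direction).
        """
        if self.mean_hypo_dmr is None or self.mean_hyper_dmr is None:
            return None
        return self.mean_hypo_dmr - self.mean_hyper_dmr


def dmr_mark_inversion(
    dmrs,
    mark_ratio_per_gene: Mapping[str, float],
    genes: Sequence[GeneAnnotation],
) -> InversionSummary:
    """Mean mark change for genes overlapping hyper- vs hypo-DMRs."""
    hyper_genes: set[str] = set()
    hypo_genes: set[str] = set()
    for d in dmrs:
        for g in genes:
            if overlap_length(d.interval, g.interval) > 0:
                (hyper_genes if d.direction == HYPER else hypo_genes).add(g.gene_id)

    def group_mean(ids: set[str]) -> tuple[float | None, int]:
        vals = [
            mark_ratio_per_gene[g]
            for g in ids
            if g in mark_ratio_per_gene and np.isfinite(mark_ratio_per_gene[g])
        ]
        return (float(np.mean(vals)) if vals else None), len(vals)

    mean_hyper, n_hyper = group_mean(hyper_genes)
    mean_hypo, n_hypo = group_mean(hypo_genes)
    return InversionSummary(mean_hypo, mean_hyper, n_hypo, n_hyper)


def methylation_percentages(n_hyper: int, n_hypo: int) -> dict[str, float]:
    """Hyper fraction of classified regions, as headline integer and 2-dp value."""
    classified = n_hyper + n_hypo
    if classified == 0:
        raise ValueError("no classified regions")
    pct = 100.0 * n_hyper / classified
    return {
        "n_hyper": n_hyper,
        "n_hypo": n_hypo,
        "percent_hyper": _round_half_up(pct, 2),
        "percent_hyper_headline": _round_half_up(pct, 0),
    }


def degradation_methylation_summary(
    pa200_regions: DegradationRegionSet | Sequence[GenomicInterval],
    records: MethylationTable,
    min_sites: int = 3,
) -> dict[str, float]:
    """Classify degradation regions by methylation and report the hyper share.

    The percentage denominator is the classified regions only
    (hyper + hypo); no_data regions are reported but excluded, matching
    count-based fraction arithmetic such as 550/6522.
    """
    intervals = (
        pa200_regions.intervals
        if isinstance(pa200_regions, DegradationRegionSet)
        else list(pa200_regions)
    )
    counts, _ = classify_regions(intervals, records, min_sites=min_sites)
    if counts[HYPER] + counts[HYPO] == 0:
        raise ValueError("no classified regions")
    out = methylation_percentages(counts[HYPER], counts[HYPO])
    out["n_no_data"] = counts["no_data"]
    return out
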