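"""Synthetic genomes, tracks, methylomes and count tables with planted truth.

The generator emulates the signal structure of a pulse-chase histone-
degradation study in two genotypes (wild type and a degradation-deficient
knockout), so that every downstream stage of the pipeline has a
recoverable ground truth:

* labeled-histone coverage at chase times 0 h and 4 h, with planted
  degraded regions (strong 0-h enrichment that largely disappears at 4 h
  in the wild type but is retained in the knockout at the PA200-dependent
  subset), a baseline TSS-shaped enrichment in all tracks, and a TSS
  accumulation effect in the knockout 4-h track;
* histone-mark and Pol II tracks whose knockout/wild-type ratio over gene
  bodies is coupled to planted up-/down-regulated gene classes;
* a per-CpG methylome with Beta-distributed levels forming hyper- and
  hypo-methylated domains, arranged so a configurable small fraction of
  the planted degradation regions falls in hyper domains;
* negative-binomial count tables with planted fold changes.

All counts are Poisson (tracks) or negative binomial (genes); every track
draws from its own seeded integer RNG stream, so a fixed seed reproduces
every byte of output on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import CountTable
from .intervals import GeneAnnotation, GenomicInterval, SignalTrack, overlap_length
from .methylation import MethylationTable

__all__ = [
    "SimulationConfig",
    "Genome",
    "TruthSet",
    "simulate_genome",
    "simulate_gahd_tracks",
    "simulate_mark_tracks",
    "simulate_methylation",
    "simulate_counts",
    "simulate_dmr_pair",
    "simulate_area_methylome",
]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults describe the reference simulation: a 2 x 10 Mb genome with
    200 genes and 60 planted wild-type degraded regions, 40 of which are
    PA200-dependent (retained in the knockout).
    """

    n_chroms: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 200
    gene_length: tuple[int, int] = (5_000, 30_000)

    n_degraded_regions: int = 60
    n_pa200_dependent: int = 40
    region_length: tuple[int, int] = (1_500, 3_000)
    degraded_fraction_retained_4h_wt: float = 0.2
    degraded_fraction_retained_4h_ko: float = 0.85
    tss_accumulation_factor_ko_4h: float = 1.5
    ko_0h_scale: float = 0.7

    bin_size: int = 50
    background_rate: float = 5.0  # reads per bin
    peak_enrichment: float = 8.0  # fold over background in planted regions
    tss_enrichment: float = 6.0  # baseline fold at the TSS apex (all tracks)
    tss_halfwidth: int = 1_000

    methyl_spacing: int = 100
    methyl_hyper_level: float = 0.8
    methyl_hypo_level: float = 0.15
    methyl_concentration: float = 20.0
    hyper_exception_fraction: float = 0.08
    n_hyper_domains: int = 30
    hyper_domain_length: tuple[int, int] = (30_000, 60_000)

    n_deg_up: int = 30
    n_deg_down: int = 30
    deg_log2fc: float = 2.0
    dispersion: float = 0.02
    base_mean: float = 200.0

    mark_background_rate: float = 2.0
    h3_gene_enrichment: float = 3.0
    mark_gene_enrichment: float = 6.0
    mark_log2fc: float = 1.0

    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "degraded_fraction_retained_4h_wt",
            "degraded_fraction_retained_4h_ko",
            "hyper_exception_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("tss_accumulation_factor_ko_4h", "peak_enrichment", "ko_0h_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_pa200_dependent > self.n_degraded_regions:
            raise ValueError("n_pa200_dependent cannot exceed n_degraded_regions")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for a named stage stream."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: list[GeneAnnotation]


@dataclass
class TruthSet:
    """Planted ground truth, emitted in the same shapes the pipeline consumes."""

    degraded_regions_wt: list[GenomicInterval] = field(default_factory=list)
    degraded_regions_ko: list[GenomicInterval] = field(default_factory=list)
    pa200_dependent_regions: list[GenomicInterval] = field(default_factory=list)
    hyper_domains: list[GenomicInterval] = field(default_factory=list)
    hypo_domains: list[GenomicInterval] = field(default_factory=list)
    deg_up_ids: list[str] = field(default_factory=list)
    deg_down_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(config: SimulationConfig) -> Genome:
    """Random non-overlapping genes on equal-sized chromosomes."""
    rng = config.rng(0)
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    chroms = list(chrom_sizes)
    per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    genes: list[GeneAnnotation] = []
    gid = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        lengths = rng.integers(
            config.gene_length[0], config.gene_length[1] + 1, size=n
        )
        free = config.chrom_length - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"cannot pack {n} genes of total {lengths.sum()} bp into "
                f"{chrom} ({config.chrom_length} bp)"
            )
        gaps = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
        pos = 0
        for i in range(n):
            pos += int(gaps[i])
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneAnnotation(
                    GenomicInterval(chrom, start, end, strand), f"gene_{gid:04d}"
                )
            )
            gid += 1
            pos = end
    return Genome(chrom_sizes, genes)


def _place_regions(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    avoid: list[GenomicInterval],
    min_gap: int = 1_000,
) -> list[GenomicInterval]:
    """Rejection-sample bin-aligned regions avoiding ``avoid`` and each other."""
    b = config.bin_size
    chroms = sorted(genome.chrom_sizes)
    placed: list[GenomicInterval] = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ValueError("could not place regions; genome too crowded")
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = genome.chrom_sizes[chrom]
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        length = max(b, (length // b) * b)
        start = int(rng.integers(0, (size - length) // b)) * b
        cand = GenomicInterval(chrom, start, start + length)
        pad = GenomicInterval(
            chrom, max(0, start - min_gap), min(size, start + length + min_gap)
        )
        if any(overlap_length(pad, a) > 0 for a in avoid if a.chrom == chrom):
            continue
        if any(overlap_length(pad, p) > 0 for p in placed if p.chrom == chrom):
            continue
        placed.append(cand)
    placed.sort(key=lambda r: (r.chrom, r.start))
    return placed


# ---------------------------------------------------------------------------
# GAHD tracks
# ---------------------------------------------------------------------------


def _tss_weight_profile(
    genome: Genome, config: SimulationConfig, halfwidth: int
) -> dict[str, np.ndarray]:
    """Per-bin triangular TSS kernel weight in [0, 1], apex 1 at the TSS bin."""
    b = config.bin_size
    out: dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        out[chrom] = np.zeros(-(-size // b))
    for gene in genome.genes:
        w = out[gene.interval.chrom]
        tss = gene.tss
        k0 = max(0, (tss - halfwidth) // b)
        k1 = min(len(w) - 1, (tss + halfwidth) // b)
        for k in range(k0, k1 + 1):
            center = k * b + b / 2
            weight = max(0.0, 1.0 - abs(center - tss) / halfwidth)
            w[k] = max(w[k], weight)
    return out


def _region_mask(
    genome: Genome, config: SimulationConfig, regions: list[GenomicInterval]
) -> dict[str, np.ndarray]:
    b = config.bin_size
    out = {
        chrom: np.zeros(-(-size // b), dtype=bool)
        for chrom, size in genome.chrom_sizes.items()
    }
    for r in regions:
        out[r.chrom][r.start // b : -(-r.end // b)] = True
    return out


def _poisson_track(
    rates: dict[str, np.ndarray],
    config: SimulationConfig,
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
) -> SignalTrack:
    values = {c: rng.poisson(r).astype(float) for c, r in sorted(rates.items())}
    return SignalTrack(values, config.bin_size, chrom_sizes)


def simulate_gahd_tracks(
    config: SimulationConfig, genome: Genome
) -> tuple[dict[str, SignalTrack], TruthSet]:
    """Four labeled-histone tracks (WT0h, WT4h, KO0h, KO4h) plus truth.

    Planted regions are enriched ``peak_enrichment``-fold at 0 h in both
    genotypes; at 4 h each region retains the configured fraction of its
    0-h mean (wild-type fraction everywhere in WT; in KO the PA200-
    dependent subset retains the higher knockout fraction, the remainder
    the wild-type fraction). The KO track is globally scaled down and its
    4-h signal inside TSS windows multiplied by the accumulation factor.
    """
    rng = config.rng(1)
    avoid = [
        GenomicInterval(
            g.interval.chrom,
            max(0, g.tss - 2_000),
            min(genome.chrom_sizes[g.interval.chrom], g.tss + 2_000),
        )
        for g in genome.genes
    ]
    regions = _place_regions(
        config, genome, rng, config.n_degraded_regions, config.region_length, avoid
    )
    idx = rng.permutation(len(regions))
    pa200_idx = set(idx[: config.n_pa200_dependent].tolist())
    pa200 = [regions[i] for i in sorted(pa200_idx)]
    shared = [regions[i] for i in range(len(regions)) if i not in pa200_idx]

    truth = TruthSet(
        degraded_regions_wt=list(regions),
        degraded_regions_ko=list(shared),
        pa200_dependent_regions=pa200,
    )
    # planted expression classes, used by the mark and count generators
    gene_ids = [g.gene_id for g in genome.genes]
    perm = rng.permutation(len(gene_ids))
    truth.deg_up_ids = sorted(gene_ids[i] for i in perm[: config.n_deg_up])
    truth.deg_down_ids = sorted(
        gene_ids[i] for i in perm[config.n_deg_up : config.n_deg_up + config.n_deg_down]
    )

    tssw = _tss_weight_profile(genome, config, config.tss_halfwidth)
    mask_pa200 = _region_mask(genome, config, pa200)
    mask_shared = _region_mask(genome, config, shared)

    rates: dict[str, dict[str, np.ndarray]] = {}
    for name in ("WT0h", "WT4h", "KO0h", "KO4h"):
        genotype_scale = 1.0 if name.startswith("WT") else config.ko_0h_scale
        per_chrom: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_sizes:
            base = 1.0 + (config.tss_enrichment - 1.0) * tssw[chrom]
            region_factor = np.ones_like(base)
            if name.endswith("0h"):
                region_factor[mask_pa200[chrom]] = config.peak_enrichment
                region_factor[mask_shared[chrom]] = config.peak_enrichment
            else:
                wt_ret = config.degraded_fraction_retained_4h_wt
                ko_ret = config.degraded_fraction_retained_4h_ko
                if name == "WT4h":
                    region_factor[mask_pa200[chrom]] = config.peak_enrichment * wt_ret
                    region_factor[mask_shared[chrom]] = config.peak_enrichment * wt_ret
                else:  # KO4h: PA200-dependent regions are retained high
                    region_factor[mask_pa200[chrom]] = config.peak_enrichment * ko_ret
                    region_factor[mask_shared[chrom]] = config.peak_enrichment * wt_ret
            rate = config.background_rate * genotype_scale * base * region_factor
            if name == "KO4h":
                accum = 1.0 + (config.tss_accumulation_factor_ko_4h - 1.0) * (
                    tssw[chrom] > 0
                )
                rate = rate * accum
            per_chrom[chrom] = rate
        rates[name] = per_chrom

    tracks = {
        name: _poisson_track(rates[name], config, config.rng(10 + i), genome.chrom_sizes)
        for i, name in enumerate(("WT0h", "WT4h", "KO0h", "KO4h"))
    }
    return tracks, truth


# ---------------------------------------------------------------------------
# mark / Pol II tracks
# ---------------------------------------------------------------------------

MARKS = ("H3", "H3K4me3", "H3K56ac", "PolII")


def simulate_mark_tracks(
    config: SimulationConfig, genome: Genome, truth: TruthSet
) -> dict[str, dict[str, SignalTrack]]:
    """H3, H3K4me3, H3K56ac and Pol II tracks for WT and KO.

    H3 is uniform over gene bodies and identical between genotypes. The
    marks and Pol II carry gene-body (H3K56ac, Pol II) or TSS-shaped
    (H3K4me3) enrichment whose knockout component is multiplied by
    ``2**mark_log2fc`` for planted up genes and ``2**-mark_log2fc`` for
    planted down genes, so mark changes and Pol II recruitment co-vary
    with the planted expression classes.
    """
    b = config.bin_size
    up = set(truth.deg_up_ids)
    down = set(truth.deg_down_ids)
    factors = {
        g.gene_id: (
            2.0**config.mark_log2fc
            if g.gene_id in up
            else 2.0**-config.mark_log2fc
            if g.gene_id in down
            else 1.0
        )
        for g in genome.genes
    }
    tssw = _tss_weight_profile(genome, config, 1_000)

    def gene_component(mark: str) -> dict[str, dict[str, np.ndarray]]:
        """Per-genotype additive enrichment component (reads/bin)."""
        comp = {
            gt: {
                chrom: np.zeros(-(-size // b))
                for chrom, size in genome.chrom_sizes.items()
            }
            for gt in ("WT", "KO")
        }
        for gene in genome.genes:
            chrom = gene.interval.chrom
            k0 = gene.interval.start // b
            k1 = -(-gene.interval.end // b)
            if mark == "H3":
                add = np.full(
                    k1 - k0,
                    config.mark_background_rate * (config.h3_gene_enrichment - 1.0),
                )
            elif mark == "H3K4me3":
                add = (
                    config.mark_background_rate
                    * (config.mark_gene_enrichment - 1.0)
                    * np.maximum(tssw[chrom][k0:k1], 0.25)
                )
            else:  # H3K56ac, PolII: uniform body enrichment
                add = np.full(
                    k1 - k0,
                    config.mark_background_rate * (config.mark_gene_enrichment - 1.0),
                )
            comp["WT"][chrom][k0:k1] += add
            f = factors[gene.gene_id] if mark != "H3" else 1.0
            comp["KO"][chrom][k0:k1] += add * f
        return comp

    out: dict[str, dict[str, SignalTrack]] = {}
    for m_i, mark in enumerate(MARKS):
        comp = gene_component(mark)
        out[mark] = {}
        for g_i, gt in enumerate(("WT", "KO")):
            rates = {
                chrom: config.mark_background_rate + comp[gt][chrom]
                for chrom in genome.chrom_sizes
            }
            rng = config.rng(20 + 2 * m_i + g_i)
            out[mark][gt] = _poisson_track(rates, config, rng, genome.chrom_sizes)
    return out


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


def simulate_methylation(
    config: SimulationConfig, genome: Genome, truth: TruthSet
) -> MethylationTable:
    """Per-CpG methylome with planted hyper domains.

    CpGs sit every ``methyl_spacing`` bp; levels are Beta-distributed with
    mean ``methyl_hyper_level`` inside hyper domains and
    ``methyl_hypo_level`` elsewhere. A fraction
    ``hyper_exception_fraction`` of the PA200-dependent regions is covered
    by a hyper domain (the regions that degrade despite sitting in
    inactive chromatin); all other planted regions stay hypo-methylated.
    Updates ``truth.hyper_domains`` / ``truth.hypo_domains`` in place.
    """
    rng = config.rng(30)
    planted = list(truth.degraded_regions_wt)
    n_exc = int(round(config.hyper_exception_fraction * len(truth.pa200_dependent_regions)))
    exc_idx = rng.choice(
        len(truth.pa200_dependent_regions), size=n_exc, replace=False
    ) if n_exc else np.array([], dtype=int)
    hyper: list[GenomicInterval] = []
    for i in sorted(exc_idx.tolist()):
        r = truth.pa200_dependent_regions[i]
        size = genome.chrom_sizes[r.chrom]
        hyper.append(
            GenomicInterval(r.chrom, max(0, r.start - 5_000), min(size, r.end + 5_000))
        )
    covered = {(h.chrom, h.start, h.end) for h in hyper}
    avoid = [r for r in planted] + hyper
    hyper += _place_regions(
        config,
        genome,
        rng,
        config.n_hyper_domains,
        config.hyper_domain_length,
        avoid,
        min_gap=10_000,
    )
    hyper.sort(key=lambda r: (r.chrom, r.start))
    truth.hyper_domains = hyper
    truth.hypo_domains = _complement(hyper, genome.chrom_sizes)

    kappa = config.methyl_concentration
    a_hyper = config.methyl_hyper_level * kappa
    b_hyper = (1 - config.methyl_hyper_level) * kappa
    a_hypo = config.methyl_hypo_level * kappa
    b_hypo = (1 - config.methyl_hypo_level) * kappa

    positions: dict[str, np.ndarray] = {}
    levels: dict[str, np.ndarray] = {}
    for chrom, size in genome.chrom_sizes.items():
        pos = np.arange(config.methyl_spacing // 2, size, config.methyl_spacing)
        in_hyper = np.zeros(len(pos), dtype=bool)
        for h in hyper:
            if h.chrom == chrom:
                in_hyper |= (pos >= h.start) & (pos < h.end)
        lev = np.where(
            in_hyper,
            rng.beta(a_hyper, b_hyper, size=len(pos)),
            rng.beta(a_hypo, b_hypo, size=len(pos)),
        )
        positions[chrom] = pos
        levels[chrom] = lev
    return MethylationTable(positions, levels)


def _complement(
    regions: list[GenomicInterval], chrom_sizes: dict[str, int]
) -> list[GenomicInterval]:
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        pos = 0
        for r in sorted(
            (r for r in regions if r.chrom == chrom), key=lambda r: r.start
        ):
            if r.start > pos:
                out.append(GenomicInterval(chrom, pos, r.start))
            pos = max(pos, r.end)
        if pos < chrom_sizes[chrom]:
            out.append(GenomicInterval(chrom, pos, chrom_sizes[chrom]))
    return out


def simulate_dmr_pair(
    base: MethylationTable,
    dmr_regions: list[GenomicInterval],
    delta: float = 0.4,
    seed: int = 0,
) -> MethylationTable:
    """Second-condition methylome: ``base`` shifted by ``delta`` inside DMRs.

    Positive ``delta`` plants hyper-DMRs (sample b more methylated);
    regions may carry their own sign via a negative delta by passing
    ``delta`` per call. Levels are clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    positions = {c: p.copy() for c, p in base.positions.items()}
    levels = {c: v.copy() for c, v in base.levels.items()}
    for r in dmr_regions:
        pos = positions.get(r.chrom)
        if pos is None:
            continue
        mask = (pos >= r.start) & (pos < r.end)
        jitter = rng.normal(0.0, 0.02, size=int(mask.sum()))
        levels[r.chrom][mask] = np.clip(levels[r.chrom][mask] + delta + jitter, 0.0, 1.0)
    return MethylationTable(positions, levels)


def simulate_area_methylome(
    n_hyper: int = 684,
    n_hypo: int = 123,
    domain_length: int = 20_000,
    gap: int = 25_000,
    spacing: int = 100,
    hyper_level: float = 0.8,
    hypo_level: float = 0.15,
    concentration: float = 20.0,
    seed: int = 3,
) -> tuple[MethylationTable, dict[str, int], list[str]]:
    """A one-chromosome methylome of separated hyper/hypo domains.

    Domains are laid out in shuffled order along a synthetic chromosome,
    separated by CpG-free gaps wide enough that window segmentation sees a
    no-data break between consecutive domains — so each planted domain
    should be recovered as exactly one genome area. Returns the table, the
    chromosome sizes, and the planted label sequence.
    """
    rng = np.random.default_rng(seed)
    labels = ["hyper"] * n_hyper + ["hypo"] * n_hypo
    rng.shuffle(labels)
    pos_list: list[np.ndarray] = []
    lev_list: list[np.ndarray] = []
    cursor = gap
    for lab in labels:
        pos = np.arange(cursor + spacing // 2, cursor + domain_length, spacing)
        mu = hyper_level if lab == "hyper" else hypo_level
        lev = rng.beta(mu * concentration, (1 - mu) * concentration, size=len(pos))
        pos_list.append(pos)
        lev_list.append(lev)
        cursor += domain_length + gap
    chrom_sizes = {"chrS": cursor}
    table = MethylationTable(
        {"chrS": np.concatenate(pos_list)}, {"chrS": np.concatenate(lev_list)}
    )
    return table, chrom_sizes, labels


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    config: SimulationConfig, genome: Genome, truth: TruthSet
) -> CountTable:
    """Negative-binomial two-condition counts with planted fold changes.

    Condition-a means are log-normal around ``base_mean``; planted up and
    down genes get their condition-b mean multiplied by ``2**±deg_log2fc``.
    Condition b carries an overall depth factor within 2x of condition a.
    """
    rng = config.rng(40)
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)
    base = rng.lognormal(mean=np.log(config.base_mean), sigma=1.0, size=n)
    fc = np.ones(n)
    up, down = set(truth.deg_up_ids), set(truth.deg_down_ids)
    for i, gid in enumerate(gene_ids):
        if gid in up:
            fc[i] = 2.0**config.deg_log2fc
        elif gid in down:
            fc[i] = 2.0**-config.deg_log2fc
    depth_b = rng.uniform(0.75, 1.5)

    def nb(mean: np.ndarray) -> np.ndarray:
        if config.dispersion <= 0:
            return rng.poisson(mean)
        r = 1.0 / config.dispersion
        p = r / (r + mean)
        return rng.negative_binomial(r, p)

    counts_a = nb(base)
    counts_b = nb(base * fc * depth_b)
    # library sizes are the true simulated depths, not column sums: planted
    # fold changes would otherwise leak into the normalization (composition
    # bias) and shrink every observed ratio.
    lib_a = float(base.sum())
    return CountTable(
        gene_ids,
        counts_a.astype(np.int64),
        counts_b.astype(np.int64),
        library_size_a=lib_a,
        library_size_b=lib_a * depth_b,
    )
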