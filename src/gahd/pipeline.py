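"""End-to-end synthetic-study pipeline and its configuration.

``run_pipeline`` drives the full chain — simulate, peak calling, M-A
normalization, degradation-region calling, PA200-dependence, methylation
classification, DMRs, DEG calling, metagene profiles, integration — and
writes text outputs plus a manifest with a content hash per file, so a
fixed seed reproduces every byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import profiles as prof
from .degradation import call_degraded_regions, pa200_dependent_regions
from .expression import call_degs, write_deg_table
from .integration import (
    degradation_methylation_summary,
    dmr_mark_inversion,
    mark_change_by_deg_class,
    methylation_percentages,
    polii_concordance,
)
from .intervals import GenomicInterval, write_bed, write_gene_annotation
from .methylation import HYPER, HYPO, call_dmrs, segment_genome_areas
from .peaks import call_peaks, classify_common_unique, fit_manorm
from .simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_dmr_pair,
    simulate_gahd_tracks,
    simulate_genome,
    simulate_mark_tracks,
    simulate_methylation,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline plus the simulation conditions."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    peak_fdr: float = 0.05
    peak_min_len: int = 200
    peak_merge_gap: int = 100
    manorm_pseudocount: float = 1.0
    degrade_alpha: float = 0.01
    degrade_min_m: float = 1.0
    overlap_min_bp: int = 1

    methyl_min_sites: int = 3
    area_window: int = 10_000
    dmr_window: int = 1_000
    dmr_min_diff: float = 0.2
    dmr_alpha: float = 0.05

    deg_min_log2_ratio: float = 1.0
    deg_min_diverge_probability: float = 0.8

    profile_flank: int = 21_000
    profile_flank_bin: int = 300
    profile_body_bins: int = 100
    promoter_half_width: int = 2_500

    def __post_init__(self) -> None:
        for name in ("peak_fdr", "degrade_alpha", "dmr_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.deg_min_diverge_probability < 0 or self.deg_min_diverge_probability > 1:
            raise ValueError("deg_min_diverge_probability must be in [0, 1]")
        if self.overlap_min_bp < 1:
            raise ValueError("overlap_min_bp must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        sim_data = data.pop("simulation", {})
        known = {f.name for f in fields(cls)} - {"simulation"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_known = {f.name for f in fields(SimulationConfig)}
        sim_unknown = set(sim_data) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
        sim = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in sim_data.items()
        })
        return cls(simulation=sim, **data)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _region_bed(region_set, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tprovenance\tM\tp\n")
        for r in region_set.regions:
            m = f"{r.m:.4f}" if r.m is not None else "."
            p = f"{r.pvalue:.3e}" if r.pvalue is not None else "."
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}"
                f"\t{r.provenance}\t{m}\t{p}\n"
            )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a fresh simulation; returns the output manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(path: Path) -> None:
        written.append(path)

    cfg_path = out / "config.json"
    _dump_json(config.to_dict(), cfg_path)
    save(cfg_path)

    sim = config.simulation

    # --- simulate ---------------------------------------------------------
    genome = simulate_genome(sim)
    write_gene_annotation(genome.genes, out / "genes.tsv")
    save(out / "genes.tsv")
    tracks, truth = simulate_gahd_tracks(sim, genome)
    for name, regs in (
        ("truth_degraded_wt.bed", truth.degraded_regions_wt),
        ("truth_degraded_ko.bed", truth.degraded_regions_ko),
        ("truth_pa200_dependent.bed", truth.pa200_dependent_regions),
    ):
        write_bed(regs, out / name)
        save(out / name)

    # --- peaks / normalization / degradation ------------------------------
    peaks = {
        name: call_peaks(
            tracks[name],
            fdr=config.peak_fdr,
            min_len=config.peak_min_len,
            merge_gap=config.peak_merge_gap,
        )
        for name in ("WT0h", "WT4h", "KO0h", "KO4h")
    }
    for name, plist in peaks.items():
        write_bed(
            [
                GenomicInterval(
                    p.interval.chrom,
                    p.interval.start,
                    p.interval.end,
                    name=f"peak_{i}",
                    score=round(p.raw_density, 4),
                )
                for i, p in enumerate(plist)
            ],
            out / f"peaks_{name}.bed",
        )
        save(out / f"peaks_{name}.bed")

    degraded = {}
    for genotype in ("WT", "KO"):
        p0, p4 = peaks[f"{genotype}0h"], peaks[f"{genotype}4h"]
        common0, *_ = classify_common_unique(p0, p4, min_bp=config.overlap_min_bp)
        model = fit_manorm(common0, p4, pseudocount=config.manorm_pseudocount)
        degraded[genotype] = call_degraded_regions(
            p0,
            p4,
            model,
            alpha=config.degrade_alpha,
            min_m=config.degrade_min_m,
            min_bp=config.overlap_min_bp,
            genotype=genotype,
        )
        _region_bed(degraded[genotype], out / f"degraded_{genotype}.bed")
        save(out / f"degraded_{genotype}.bed")
    pa200 = pa200_dependent_regions(
        degraded["WT"], degraded["KO"], min_bp=config.overlap_min_bp
    )
    _region_bed(pa200, out / "pa200_dependent.bed")
    save(out / "pa200_dependent.bed")
    # secondary, non-headline direction: degradation gained in the knockout
    ko_only = pa200_dependent_regions(
        degraded["KO"], degraded["WT"], min_bp=config.overlap_min_bp
    )
    degrade_summary = {
        "WT": degraded["WT"].counts_by_provenance() | {"total": len(degraded["WT"])},
        "KO": degraded["KO"].counts_by_provenance() | {"total": len(degraded["KO"])},
        "pa200_dependent": len(pa200),
        "ko_minus_wt_secondary": len(ko_only),
    }
    _dump_json(degrade_summary, out / "degrade_summary.json")
    save(out / "degrade_summary.json")

    # --- methylation -------------------------------------------------------
    methylome = simulate_methylation(sim, genome, truth)
    methylome.to_bedgraph(out / "methylation.bedgraph")
    save(out / "methylation.bedgraph")
    meth_summary = degradation_methylation_summary(
        pa200, methylome, min_sites=config.methyl_min_sites
    )
    areas = segment_genome_areas(
        methylome,
        genome.chrom_sizes,
        window=config.area_window,
        min_sites=config.methyl_min_sites,
    )
    n_hyper = sum(a.label == HYPER for a in areas)
    n_hypo = sum(a.label == HYPO for a in areas)
    area_summary = methylation_percentages(n_hyper, n_hypo)
    _dump_json(
        {"pa200_regions": meth_summary, "genome_areas": area_summary},
        out / "methylation_summary.json",
    )
    save(out / "methylation_summary.json")

    # --- expression --------------------------------------------------------
    table = simulate_counts(sim, genome, truth)
    table.to_tsv(out / "counts.tsv")
    save(out / "counts.tsv")
    deg_records, deg_summary = call_degs(
        table,
        min_log2_ratio=config.deg_min_log2_ratio,
        min_diverge_probability=config.deg_min_diverge_probability,
    )
    write_deg_table(deg_records, out / "degs.tsv")
    save(out / "degs.tsv")

    # --- marks, profiles ---------------------------------------------------
    marks = simulate_mark_tracks(sim, genome, truth)
    wt0_rpm = tracks["WT0h"].rpm()
    mat = prof.metagene_matrix(
        wt0_rpm,
        genome.genes,
        flank=config.profile_flank,
        n_body_bins=config.profile_body_bins,
        flank_bin=config.profile_flank_bin,
    )
    summary_profile = prof.column_summary(mat)
    np.savetxt(out / "metagene_WT0h.tsv", summary_profile[None, :], delimiter="\t", fmt="%.6g")
    save(out / "metagene_WT0h.tsv")

    def promoter_means(track) -> dict[str, float]:
        _, means, ids = prof.tss_signal(
            track.rpm(), genome.genes, half_width=config.promoter_half_width
        )
        return dict(zip(ids, means))

    def body_ratio(mark: str) -> dict[str, float]:
        wt, ko = marks[mark]["WT"].rpm(), marks[mark]["KO"].rpm()
        out_map: dict[str, float] = {}
        for g in genome.genes:
            iv = g.interval
            w = wt.range_mean(iv.chrom, iv.start, iv.end)
            k = ko.range_mean(iv.chrom, iv.start, iv.end)
            out_map[g.gene_id] = float(np.log2((k + 0.1) / (w + 0.1)))
        return out_map

    k4_wt = promoter_means(marks["H3K4me3"]["WT"])
    k4_ko = promoter_means(marks["H3K4me3"]["KO"])
    class_summary = mark_change_by_deg_class(deg_records, k4_wt, k4_ko)
    k56_ratio = body_ratio("H3K56ac")
    polii_ratio = body_ratio("PolII")
    rho, sign_agree = polii_concordance(k56_ratio, polii_ratio)

    # --- DMRs, anti-correlated with planted expression classes -------------
    # Plant DMRs anti-correlated with the expression classes: down genes
    # gain methylation in condition b (hyper-DMR), up genes gain it in
    # condition a instead, which reads as a hypo-DMR of b relative to a.
    id_to_gene = {g.gene_id: g for g in genome.genes}
    hypo_dmr_regions = [id_to_gene[g].interval for g in truth.deg_up_ids]
    hyper_dmr_regions = [id_to_gene[g].interval for g in truth.deg_down_ids]
    methylome_a = simulate_dmr_pair(
        methylome, hypo_dmr_regions, delta=0.4, seed=sim.seed % (2**31)
    )
    methylome_b = simulate_dmr_pair(
        methylome, hyper_dmr_regions, delta=0.4, seed=(sim.seed + 1) % (2**31)
    )
    dmrs = call_dmrs(
        methylome_a,
        methylome_b,
        genome.chrom_sizes,
        window=config.dmr_window,
        min_diff=config.dmr_min_diff,
        alpha=config.dmr_alpha,
        min_sites=config.methyl_min_sites,
    )
    inversion = dmr_mark_inversion(dmrs, k56_ratio, genome.genes)

    integration_summary = {
        "deg_summary": deg_summary,
        "mark_change_by_class": {
            "means": class_summary.means,
            "n": class_summary.n,
            "p_up_vs_down": class_summary.p_up_vs_down,
        },
        "polii_spearman": rho,
        "polii_sign_agreement": sign_agree,
        "n_dmrs": len(dmrs),
        "n_dmr_hyper": sum(d.direction == HYPER for d in dmrs),
        "n_dmr_hypo": sum(d.direction == HYPO for d in dmrs),
        "dmr_inversion_statistic": inversion.inversion_statistic,
    }
    _dump_json(integration_summary, out / "integration_summary.json")
    save(out / "integration_summary.json")

    manifest = {
        "seed": sim.seed,
        "files": {p.name: _sha256(p) for p in sorted(written)},
    }
    _dump_json(manifest, out / "manifest.json")
    return manifest
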