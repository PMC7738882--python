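import numpy as np
import pytest

from gahd.intervals import GenomicInterval, SignalTrack
from gahd.simulate import SimulationConfig, simulate_gahd_tracks, simulate_genome


def per_base_values(track: SignalTrack, chrom: str) -> np.ndarray:
    """Expand a binned track to one value per base (brute-force reference)."""
    v = track.values[chrom]
    size = track.chrom_sizes[chrom]
    return np.repeat(v, track.bin_size)[:size]


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    if ov == 0:
        return 0.0
    return ov / (len(a) + len(b) - ov)


def random_track(rng: np.random.Generator, size: int = 100_000, bin_size: int = 50,
                 rate: float = 5.0, chrom: str = "chr1") -> SignalTrack:
    n = -(-size // bin_size)
    return SignalTrack(
        {chrom: rng.poisson(rate, size=n).astype(float)}, bin_size, {chrom: size}
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced simulation for fast unit tests."""
    return SimulationConfig(
        n_chroms=1,
        chrom_length=2_000_000,
        n_genes=40,
        n_degraded_regions=12,
        n_pa200_dependent=8,
        n_deg_up=8,
        n_deg_down=8,
        n_hyper_domains=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    genome = simulate_genome(small_config)
    tracks, truth = simulate_gahd_tracks(small_config, genome)
    return small_config, genome, tracks, truth
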