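import numpy as np
import pytest

from tfrewire.intervals import GenomeLayout, GenomicInterval, IntervalSet
from tfrewire.simulate import SimulationConfig, simulate_all


def random_interval_set(rng, n, layout, max_len=2000, with_signal=False):
    """Fuzz helper: n random intervals on the layout (may overlap)."""
    ivs = []
    for _ in range(n):
        chrom = layout.chrom_names[int(rng.integers(len(layout.chrom_names)))]
        L = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout.length_of(chrom) - L))
        signal = float(rng.uniform(0, 10)) if with_signal else None
        ivs.append(GenomicInterval(chrom, start, start + L, signal=signal))
    return IntervalSet(ivs)


@pytest.fixture(scope="session")
def small_layout():
    return GenomeLayout.from_lengths({"chr1": 100_000, "chr2": 80_000})


@pytest.fixture(scope="session")
def default_dataset():
    """The default noise-free synthetic study (seed 7), shared read-only."""
    return simulate_all(SimulationConfig(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-size synthetic study at the standard noise level."""
    return simulate_all(SimulationConfig(seed=7, noise_sd=0.1))
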