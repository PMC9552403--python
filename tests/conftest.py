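import numpy as np
import pytest

from pigatlas.quantify import build_atlas
from pigatlas.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default desk-scale study: 4 tissues x 2 replicates, 2000 peaks."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_atlas(default_study):
    atlas = build_atlas(
        default_study.atlas.per_sample_peaks,
        default_study.atlas.sheet,
        mode="reproducible",
    )
    atlas.attach_counts(default_study.atlas.counts)
    return atlas


def link_config(**overrides):
    """60-sample configuration used for link-recovery checks."""
    base = dict(
        seed=1,
        n_tissues=30,
        n_replicates=2,
        n_peaks=300,
        n_genes=200,
        n_true_links=40,
        n_tes=100,
        te_accessible_frac=0.1,
        n_variants_in_peaks=5,
        n_variants_outside=20,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def link_study():
    return simulate_study(link_config())


def random_intervals(rng: np.random.Generator, n: int, chroms=("chrA", "chrB"), span=10_000, max_len=400):
    """Random small intervals for oracle comparisons (<=10 kb coordinate space)."""
    from pigatlas.intervals import GenomicInterval

    out = []
    for _ in range(n):
        chrom = str(rng.choice(list(chroms)))
        start = int(rng.integers(0, span - 1))
        length = int(rng.integers(1, min(max_len, span - start) + 1))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


def coverage_mask(intervals, chroms=("chrA", "chrB"), span=10_000):
    """Per-base boolean-coverage oracle."""
    masks = {c: np.zeros(span, dtype=bool) for c in chroms}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks
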