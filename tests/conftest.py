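import numpy as np
import pytest

from hapblock.genotype_io import GenotypeMatrix, MarkerMap, HOMOZYGOUS, PHASED_DIPLOID
from hapblock.synthetic import SimConfig, simulate_population, simulate_phenotypes


def make_homozygous(dosage_rows, positions=None, chrom="1"):
    """GenotypeMatrix + MarkerMap from literal homozygous dosage rows."""
    d = np.asarray(dosage_rows, dtype=np.int16)
    n, m = d.shape
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], d, HOMOZYGOUS)
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    mmap = MarkerMap(
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.array([chrom] * m, dtype=object),
        np.asarray(positions),
    )
    return gm, mmap


def make_phased(phase_pairs, positions=None, chrom="1"):
    """GenotypeMatrix from per-sample (hap1, hap2) allele tuples."""
    phases = np.asarray(phase_pairs, dtype=np.int8)  # (n, 2, m)
    d = phases.sum(axis=1).astype(np.int16)
    n, m = d.shape
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], d, PHASED_DIPLOID, phases)
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    mmap = MarkerMap(
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.array([chrom] * m, dtype=object),
        np.asarray(positions),
    )
    return gm, mmap


# Frozen hand-checkable panel: 6 homozygous lines x 4 markers.
# Columns 0 and 1 are identical (r2 = 1); column 2 is the complement of 0
# (r = -1, r2 = 1); column 3 splits the lines orthogonally to column 0.
FROZEN_PANEL = [
    [0, 0, 2, 0],
    [0, 0, 2, 2],
    [0, 0, 2, 0],
    [2, 2, 0, 2],
    [2, 2, 0, 0],
    [2, 2, 0, 2],
]


@pytest.fixture(scope="session")
def frozen_panel():
    return make_homozygous(FROZEN_PANEL)


def random_panel(seed, n=20, m=12, n_chrom=1, block_structure=True):
    """Small random homozygous panel with optional LD-block structure."""
    rng = np.random.default_rng(seed)
    cols = []
    j = 0
    while j < m:
        if block_structure and rng.random() < 0.6 and j + 2 <= m:
            base = rng.integers(0, 2, n)
            run = int(rng.integers(2, 5))
            for _ in range(min(run, m - j)):
                col = base.copy()
                flip = rng.random(n) < 0.1
                col[flip] = 1 - col[flip]
                cols.append(col)
                j += 1
        else:
            cols.append(rng.integers(0, 2, n))
            j += 1
    d = (np.column_stack(cols[:m]) * 2).astype(np.int16)
    per = m // n_chrom
    chroms = np.array(
        [f"c{(k // per) + 1}" if k // per < n_chrom else f"c{n_chrom}" for k in range(m)],
        dtype=object,
    )
    positions = np.concatenate(
        [np.arange(1, np.sum(chroms == c) + 1) * 50 for c in dict.fromkeys(chroms)]
    )
    gm = GenotypeMatrix([f"s{i}" for i in range(n)], d, HOMOZYGOUS)
    mmap = MarkerMap(np.array([f"m{k}" for k in range(m)], dtype=object), chroms, positions)
    return gm, mmap


@pytest.fixture(scope="session")
def sim_inbred():
    """Medium simulated inbred panel shared by model tests."""
    cfg = SimConfig(
        n_samples=150, n_chromosomes=3, markers_per_chromosome=40,
        n_founders=10, n_generations=3, n_qtl=30, h2_target=0.5, seed=11,
    )
    gm, mmap, _ = simulate_population(cfg)
    pt, truth = simulate_phenotypes(gm, mmap, cfg)
    return cfg, gm, mmap, pt, truth


@pytest.fixture(scope="session")
def sim_nam():
    cfg = SimConfig(
        n_samples=150, n_chromosomes=3, markers_per_chromosome=30,
        n_founders=8, n_families=5, material="dh_nam", crossover_rate=1.0,
        n_qtl=25, h2_target=0.6, seed=21,
    )
    gm, mmap, fams = simulate_population(cfg)
    pt, truth = simulate_phenotypes(gm, mmap, cfg)
    return cfg, gm, mmap, pt, truth, fams
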