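"""Forward-in-time population simulator for fixtures and benchmarks.

Founder haplotypes are drawn at per-marker allele frequencies ~ U(0.1, 0.9);
descendants arise through meioses with Poisson-distributed crossovers placed
uniformly along each chromosome.  Three material types are supported:

* ``inbred``   — random mating for ``n_generations``, then every sample is a
  doubled gamete (fully homozygous panel);
* ``dh_nam``   — half-sib DH families from a common parent crossed to one
  donor founder per family (doubled F1 gametes);
* ``hybrid``   — DH pollinators crossed in silico to a common DH tester
  (phased diploid hybrids).

Phenotypes combine additive QTL effects with pairwise products of
physically close markers (local epistasis); the residual is rescaled so the
realized sample heritability equals the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .genotype_io import (
    HOMOZYGOUS,
    PHASED_DIPLOID,
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
    in_silico_cross,
)


@dataclass
class SimConfig:
    n_founders: int = 8
    n_samples: int = 200
    n_chromosomes: int = 3
    markers_per_chromosome: int = 40
    chromosome_length_bp: int = 1_000_000
    crossover_rate: float = 1.5
    n_generations: int = 3
    material: str = "inbred"
    n_families: int = 5
    n_qtl: int = 20
    epistatic_pairs: int = 0
    epistasis_window_bp: int = 100_000
    h2_target: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_samples", "n_chromosomes", "markers_per_chromosome",
                     "chromosome_length_bp", "n_qtl"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ParameterError("h2_target must be in [0, 1]")
        if self.epistasis_window_bp > self.chromosome_length_bp:
            raise ParameterError("epistasis_window_bp exceeds chromosome length")
        if self.material not in ("inbred", "dh_nam", "hybrid"):
            raise ParameterError(f"unknown material {self.material!r}")
        if self.material == "dh_nam" and self.n_families > self.n_founders - 1:
            raise ParameterError("n_families must be <= n_founders - 1")


@dataclass
class SimTruth:
    qtl_indices: np.ndarray
    additive_effects: np.ndarray
    epistatic_pairs: list  # [(i, j, effect), ...]
    true_genetic_values: np.ndarray
    realized_h2: float


def _make_map(cfg: SimConfig, rng) -> MarkerMap:
    ids, chroms, poss = [], [], []
    for c in range(cfg.n_chromosomes):
        pos = np.sort(
            rng.choice(cfg.chromosome_length_bp, size=cfg.markers_per_chromosome, replace=False)
        ) + 1
        for k, p in enumerate(pos):
            ids.append(f"chr{c + 1}_m{k + 1}")
            chroms.append(f"chr{c + 1}")
            poss.append(int(p))
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(poss))


def _meiosis(g1: np.ndarray, g2: np.ndarray, mmap: MarkerMap, rate: float, rng) -> np.ndarray:
    """One recombinant gamete from a pair of parental gametes."""
    child = np.empty_like(g1)
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        pos = mmap.position_bp[lo:hi]
        length = pos[-1] if len(pos) else 1
        k = rng.poisson(rate)
        current = rng.integers(0, 2)
        if k == 0:
            src = np.full(hi - lo, current)
        else:
            xovers = np.sort(rng.uniform(0, length, size=k))
            src = np.full(hi - lo, current)
            flips = np.searchsorted(xovers, pos)  # crossovers left of each marker
            src = (current + flips) % 2
        seg = np.where(src == 0, g1[lo:hi], g2[lo:hi])
        child[lo:hi] = seg
    return child


def simulate_population(config: SimConfig):
    """Simulate a genotype panel; returns (GenotypeMatrix, MarkerMap,
    family_labels or None)."""
    rng = np.random.default_rng(config.seed)
    mmap = _make_map(config, rng)
    m = len(mmap)
    freqs = rng.uniform(0.1, 0.9, size=m)
    founder_gametes = (rng.random((config.n_founders, m)) < freqs).astype(np.int8)

    def dh_matrix(gametes: np.ndarray, ids: list) -> GenotypeMatrix:
        return GenotypeMatrix(ids, (gametes.astype(np.int16)) * 2, HOMOZYGOUS)

    if config.material == "inbred":
        gams = _random_mating_gametes(founder_gametes, config, mmap, rng, config.n_samples)
        gm = dh_matrix(gams, [f"line{i + 1}" for i in range(config.n_samples)])
        return gm, mmap, None

    if config.material == "dh_nam":
        common = founder_gametes[0]
        sizes = _family_sizes(config.n_samples, config.n_families)
        gams, labels, ids = [], [], []
        count = 0
        for f in range(config.n_families):
            donor = founder_gametes[f + 1]
            for _ in range(sizes[f]):
                g = _meiosis(common, donor, mmap, config.crossover_rate, rng)
                gams.append(g)
                labels.append(f"fam{f + 1}")
                count += 1
                ids.append(f"dh{count}")
        gm = dh_matrix(np.array(gams), ids)
        return gm, mmap, np.array(labels, dtype=object)

    # hybrid: DH pollinators x one common DH tester
    pol_gams = _random_mating_gametes(founder_gametes, config, mmap, rng, config.n_samples)
    tester_gam = _meiosis(founder_gametes[0], founder_gametes[-1], mmap, config.crossover_rate, rng)
    mothers = dh_matrix(pol_gams, [f"pol{i + 1}" for i in range(config.n_samples)])
    father = dh_matrix(tester_gam[None, :], ["tester"])
    hybrids = in_silico_cross(mothers, father, [(mid, "tester") for mid in mothers.sample_ids])
    return hybrids, mmap, None


def _family_sizes(n: int, k: int) -> list:
    base = n // k
    sizes = [base] * k
    for i in range(n - base * k):
        sizes[i] += 1
    return sizes


def _random_mating_gametes(founder_gametes, cfg: SimConfig, mmap, rng, n_out: int) -> np.ndarray:
    """Random mating from homozygous founders; returns one final gamete per
    output sample (to be doubled into a DH line)."""
    nf = founder_gametes.shape[0]
    # individuals as pairs of gametes; generation 0 = founders (homozygous)
    pop = [(founder_gametes[i], founder_gametes[i]) for i in range(nf)]
    size = max(n_out, nf)
    for _gen in range(cfg.n_generations):
        nxt = []
        for _ in range(size):
            pa, ma = rng.integers(0, len(pop)), rng.integers(0, len(pop))
            g1 = _meiosis(*pop[pa], mmap, cfg.crossover_rate, rng)
            g2 = _meiosis(*pop[ma], mmap, cfg.crossover_rate, rng)
            nxt.append((g1, g2))
        pop = nxt
    out = np.empty((n_out, founder_gametes.shape[1]), dtype=np.int8)
    for i in range(n_out):
        out[i] = _meiosis(*pop[i % len(pop)], mmap, cfg.crossover_rate, rng)
    return out


def simulate_phenotypes(gm: GenotypeMatrix, mmap: MarkerMap, config: SimConfig):
    """Additive + local-epistatic phenotypes at the target heritability.

    Returns (PhenotypeTable, SimTruth); the residual is rescaled so that
    var(g) / var(y) equals ``h2_target`` on the emitted sample.
    """
    if gm.has_missing:
        raise ValidationError("complete genotypes required")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    d = gm.dosages.astype(float)
    poly = np.flatnonzero(d.std(axis=0) > 0)
    if len(poly) < config.n_qtl:
        raise ParameterError(
            f"only {len(poly)} polymorphic markers but n_qtl={config.n_qtl}"
        )
    qtl = np.sort(rng.choice(poly, size=config.n_qtl, replace=False))
    add_eff = rng.standard_normal(config.n_qtl)
    dc = d - d.mean(axis=0)
    g = dc[:, qtl] @ add_eff

    epi = []
    if config.epistatic_pairs > 0:
        is_poly = np.zeros(len(mmap), dtype=bool)
        is_poly[poly] = True
        candidates = []
        for chrom, (lo, hi) in mmap.chrom_ranges().items():
            for a in range(lo, hi):
                if not is_poly[a]:
                    continue
                for b in range(a + 1, hi):
                    if is_poly[b] and mmap.position_bp[b] - mmap.position_bp[a] <= config.epistasis_window_bp:
                        candidates.append((a, b))
        if not candidates:
            raise ParameterError("no polymorphic marker pairs inside the epistasis window")
        take = rng.choice(len(candidates), size=min(config.epistatic_pairs, len(candidates)), replace=False)
        for t in take:
            a, b = candidates[int(t)]
            eff = rng.standard_normal()
            epi.append((a, b, float(eff)))
            g = g + eff * dc[:, a] * dc[:, b]

    var_g = float(np.var(g))
    if config.h2_target >= 1.0:
        y = g.copy()
    elif config.h2_target <= 0.0:
        e = rng.standard_normal(gm.n_samples)
        y = e / e.std()
    else:
        if var_g <= 0:
            raise ParameterError("genetic values are constant; cannot hit target h2")
        e = rng.standard_normal(gm.n_samples)
        gc = g - g.mean()
        e = e - e.mean()
        e -= gc * (e @ gc) / (gc @ gc)  # orthogonalize so realized h2 is exact
        e *= np.sqrt(var_g * (1.0 - config.h2_target) / config.h2_target) / e.std()
        y = g + e
    var_y = float(np.var(y))
    realized = var_g / var_y if var_y > 0 and config.h2_target > 0 else (1.0 if config.h2_target >= 1 else 0.0)
    pt = PhenotypeTable(gm.sample_ids, y)
    truth = SimTruth(qtl, add_eff, epi, g, float(realized))
    return pt, truth
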