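"""Pairwise linkage-disequilibrium statistics on phase-resolved panels.

All statistics operate on gametes: a homozygous line contributes one gamete,
a phased diploid two. r-squared is computed on dosage vectors (composite LD),
which coincides with gametic r-squared for fully homozygous material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import MonomorphicError, ParameterError
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GameteCounts:
    """Two-locus gamete counts; allele 1 at each locus is written uppercase."""

    n_AB: int
    n_Ab: int
    n_aB: int
    n_ab: int

    @property
    def n_total(self) -> int:
        return self.n_AB + self.n_Ab + self.n_aB + self.n_ab

    @classmethod
    def from_gametes(cls, ga: np.ndarray, gb: np.ndarray) -> "GameteCounts":
        ga = np.asarray(ga, dtype=bool)
        gb = np.asarray(gb, dtype=bool)
        return cls(
            n_AB=int(np.sum(ga & gb)),
            n_Ab=int(np.sum(ga & ~gb)),
            n_aB=int(np.sum(~ga & gb)),
            n_ab=int(np.sum(~ga & ~gb)),
        )


@dataclass(frozen=True)
class PairLD:
    r2: float
    dprime: float
    dprime_ci: tuple


def gamete_counts(gm: GenotypeMatrix, marker_a: int, marker_b: int) -> GameteCounts:
    """Tally the four two-locus gamete classes over all phase-resolved gametes."""
    g = gm.gametes()
    return GameteCounts.from_gametes(g[:, marker_a], g[:, marker_b])


def compute_r2(gm: GenotypeMatrix, marker_a: int, marker_b: int) -> float:
    """Squared Pearson correlation of the two dosage columns."""
    a = gm.dosages[:, marker_a].astype(float)
    b = gm.dosages[:, marker_b].astype(float)
    if a.std() == 0 or b.std() == 0:
        raise MonomorphicError("r2 undefined for a monomorphic marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def compute_dprime(counts: GameteCounts) -> float:
    """Lewontin-normalized |D| / D_max from gamete counts."""
    n = counts.n_total
    if n == 0:
        raise ParameterError("empty gamete counts")
    pA = (counts.n_AB + counts.n_Ab) / n
    pB = (counts.n_AB + counts.n_aB) / n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicError("D' undefined for a monomorphic locus")
    D = counts.n_AB / n - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return 0.0
    dp = abs(D) / dmax
    if dp >= 1.0 - 1e-12:  # snap float noise at complete LD
        return 1.0
    return float(dp)


def pair_dprime(gm: GenotypeMatrix, marker_a: int, marker_b: int) -> float:
    return compute_dprime(gamete_counts(gm, marker_a, marker_b))


def dprime_ci(
    gm: GenotypeMatrix,
    marker_a: int,
    marker_b: int,
    conf: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple:
    """Percentile bootstrap confidence interval for D'.

    Individuals (not gametes) are resampled with replacement; replicates that
    collapse a locus to monomorphic are redrawn up to 10 times, then skipped.
    """
    if n_boot < 50:
        raise ParameterError("n_boot must be >= 50")
    if not (0.0 < conf < 1.0):
        raise ParameterError("conf must be in (0, 1)")
    # point estimate also validates that the pair is polymorphic
    compute_dprime(gamete_counts(gm, marker_a, marker_b))
    gams = gm.gametes()
    k = gm.gametes_per_sample()
    n = gm.n_samples
    ga_all = gams[:, marker_a].reshape(n, k)
    gb_all = gams[:, marker_b].reshape(n, k)
    rng = np.random.default_rng(seed)
    reps = []
    n_skipped = 0
    for _ in range(n_boot):
        value = None
        for _attempt in range(10):
            idx = rng.integers(0, n, n)
            try:
                value = compute_dprime(
                    GameteCounts.from_gametes(ga_all[idx].ravel(), gb_all[idx].ravel())
                )
                break
            except MonomorphicError:
                continue
        if value is None:
            n_skipped += 1
        else:
            reps.append(value)
    if n_skipped:
        logger.warning("dprime_ci: %d bootstrap replicates skipped (monomorphic)", n_skipped)
    if not reps:
        raise MonomorphicError("all bootstrap replicates collapsed to monomorphic")
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def four_gamete_evidence(counts: GameteCounts, freq_min: float = 0.01) -> bool:
    """True iff all four gamete classes occur at frequency >= ``freq_min``
    (evidence for a historical recombination between the two loci)."""
    if counts.n_total == 0:
        raise ParameterError("empty gamete counts")
    least = min(counts.n_AB, counts.n_Ab, counts.n_aB, counts.n_ab)
    return least / counts.n_total >= freq_min


def pair_ld(
    gm: GenotypeMatrix,
    marker_a: int,
    marker_b: int,
    conf: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> PairLD:
    """Bundle r2, D' and its bootstrap CI for one marker pair."""
    return PairLD(
        r2=compute_r2(gm, marker_a, marker_b),
        dprime=pair_dprime(gm, marker_a, marker_b),
        dprime_ci=dprime_ci(gm, marker_a, marker_b, conf=conf, n_boot=n_boot, seed=seed),
    )


def export_pairwise_ld(gm, mmap, path: str, conf: float = 0.95, n_boot: int = 200, seed: int = 0):
    """Long-format intrachromosomal pairwise LD table (tab-delimited)."""
    import pandas as pd

    rows = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        for a in range(lo, hi):
            for b in range(a + 1, hi):
                try:
                    ld = pair_ld(gm, a, b, conf=conf, n_boot=n_boot, seed=seed)
                except MonomorphicError:
                    continue
                rows.append(
                    (chrom, mmap.marker_ids[a], mmap.marker_ids[b], ld.r2, ld.dprime, *ld.dprime_ci)
                )
    df = pd.DataFrame(
        rows, columns=["chrom", "marker_a", "marker_b", "r2", "dprime", "ci_lo", "ci_hi"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
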