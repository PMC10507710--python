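"""Haplotype enumeration within blocks and the centered multi-allelic design.

A block's haplotypes are the distinct allele strings observed among the
panel's gametes over the block's markers, treated as alleles of one
multi-allelic locus.  Blocks with exactly two haplotypes are coded like a
standard biallelic marker (one column for the minor haplotype); blocks with
k > 2 haplotypes contribute one column per haplotype.  Columns are centered
by twice the haplotype frequency and the VanRaden denominator
2 * sum p_i (1 - p_i) runs over all emitted columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block_builders import BlockPartition
from .errors import ValidationError
from .genotype_io import GenotypeMatrix


@dataclass
class BlockHaplotypes:
    """Distinct haplotypes of one block, ordered by descending frequency then
    lexicographically, with per-sample copy numbers (rows sum to 2)."""

    haplotypes: list
    frequencies: np.ndarray
    dosages: np.ndarray  # n_samples x k

    @property
    def k(self) -> int:
        return len(self.haplotypes)


@dataclass
class HaplotypeCatalog:
    blocks: list  # list[BlockHaplotypes], parallel to the partition's blocks
    n_samples: int
    total_gametes: int


@dataclass
class HaploDesign:
    Z: np.ndarray  # centered n_samples x n_columns
    column_freqs: np.ndarray
    column_map: list  # (block_index, haplotype_index) per column
    denominator: float

    @property
    def n_columns(self) -> int:
        return self.Z.shape[1]

    @property
    def raw_counts(self) -> np.ndarray:
        """Uncentered 0/1/2 copy numbers (the Bayesian-regression M coding)."""
        return self.Z + 2.0 * self.column_freqs


def enumerate_haplotypes(gm: GenotypeMatrix, partition: BlockPartition) -> HaplotypeCatalog:
    """List each block's haplotypes with gamete-count frequencies and
    per-sample copy numbers."""
    if gm.has_missing:
        raise ValidationError("complete (imputed) genotypes required")
    gams = gm.gametes()
    gps = gm.gametes_per_sample()
    n = gm.n_samples
    total_gametes = gams.shape[0]
    out = []
    for b in partition.blocks:
        sub = np.ascontiguousarray(gams[:, b.start_idx : b.end_idx])
        uniq, inverse, counts = np.unique(sub, axis=0, return_inverse=True, return_counts=True)
        strings = ["".join(str(int(a)) for a in row) for row in uniq]
        freqs = counts / total_gametes
        # order: descending frequency, then lexicographic
        order = sorted(range(len(strings)), key=lambda i: (-freqs[i], strings[i]))
        rank = np.empty(len(order), dtype=int)
        for newpos, old in enumerate(order):
            rank[old] = newpos
        strings = [strings[i] for i in order]
        freqs = freqs[np.array(order)]
        hap_of_gamete = rank[inverse]
        dos = np.zeros((n, len(strings)), dtype=np.int16)
        if gps == 1:
            dos[np.arange(n), hap_of_gamete] = 2
        else:
            per = hap_of_gamete.reshape(n, 2)
            np.add.at(dos, (np.arange(n), per[:, 0]), 1)
            np.add.at(dos, (np.arange(n), per[:, 1]), 1)
        out.append(BlockHaplotypes(strings, freqs, dos))
    return HaplotypeCatalog(out, n_samples=n, total_gametes=total_gametes)


@dataclass
class CountSummary:
    n_blocks: int
    n_unblocked: int
    n_haplotypes: int  # excluding single-SNP blocks
    n_rare: dict  # cut -> count (inclusive <=), same haplotype set


def count_summary(
    catalog: HaplotypeCatalog,
    partition: BlockPartition,
    rare_cuts: tuple = (0.05, 0.01),
) -> CountSummary:
    """Block/haplotype bookkeeping: block count, unblocked (single-SNP)
    blocks, haplotypes available from multi-SNP blocks, and how many of those
    haplotypes are rare at each (inclusive) frequency cut."""
    if len(catalog.blocks) != len(partition.blocks):
        raise ValidationError("catalog and partition disagree in block count")
    n_blocks = partition.n_blocks
    n_unblocked = partition.n_unblocked
    n_haplotypes = 0
    n_rare = {cut: 0 for cut in rare_cuts}
    for b, bh in zip(partition.blocks, catalog.blocks):
        if b.n_markers < 2:
            continue
        n_haplotypes += bh.k
        for cut in rare_cuts:
            n_rare[cut] += int(np.sum(bh.frequencies <= cut))
    return CountSummary(n_blocks, n_unblocked, n_haplotypes, n_rare)


def build_design(catalog: HaplotypeCatalog, min_hap_freq: float = 0.0) -> HaploDesign:
    """Centered multi-allelic design matrix.

    Two-haplotype blocks contribute a single minor-haplotype column; blocks
    with k > 2 haplotypes contribute all k columns (their raw counts sum to 2
    per sample); monomorphic blocks contribute nothing.  ``min_hap_freq``
    optionally drops haplotype columns below that frequency (off by default).
    """
    cols, freqs, cmap = [], [], []
    for bi, bh in enumerate(catalog.blocks):
        if bh.k < 2:
            continue
        if bh.k == 2:
            take = [1]  # minor haplotype: lowest frequency, ties broken by order
        else:
            take = list(range(bh.k))
        for hi in take:
            p = float(bh.frequencies[hi])
            if min_hap_freq > 0.0 and p < min_hap_freq:
                continue
            cols.append(bh.dosages[:, hi].astype(float) - 2.0 * p)
            freqs.append(p)
            cmap.append((bi, hi))
    if cols:
        Z = np.column_stack(cols)
        p = np.array(freqs)
    else:
        Z = np.zeros((catalog.n_samples, 0))
        p = np.zeros(0)
    denominator = float(2.0 * np.sum(p * (1.0 - p)))
    return HaploDesign(Z, p, cmap, denominator)


def export_catalog(catalog: HaplotypeCatalog, path: str) -> None:
    rows = []
    for bi, bh in enumerate(catalog.blocks):
        for h, f in zip(bh.haplotypes, bh.frequencies):
            rows.append((f"block{bi}", h, f))
    pd.DataFrame(rows, columns=["block_id", "haplotype", "frequency"]).to_csv(
        path, sep="\t", index=False
    )
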