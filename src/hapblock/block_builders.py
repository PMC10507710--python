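"""Haplotype-block partition builders.

Six construction rules are provided: an LD-threshold extension rule with a
misplaced-marker tolerance, fixed windows of adjacent markers, fixed windows
of adjacent base pairs, a D'-confidence-interval rule, the four-gamete
recombination rule, and the solid-spine-of-LD rule, plus an import hook for
partitions produced by external tools.

Every builder returns a :class:`BlockPartition` whose blocks are
non-overlapping, within-chromosome, and jointly cover every marker; markers
not absorbed by a rule become singleton blocks ("unblocked SNPs").
Block index ranges are half-open over the global marker order of the map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MonomorphicError, ParameterError, ValidationError
from .genotype_io import GenotypeMatrix, MarkerMap
from .ld_stats import compute_dprime, dprime_ci, gamete_counts, four_gamete_evidence


@dataclass(frozen=True)
class Block:
    chromosome: object
    start_idx: int
    end_idx: int  # half-open

    def __post_init__(self):
        if self.end_idx <= self.start_idx:
            raise ValidationError("block end_idx must exceed start_idx")

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx

    def span_bp(self, mmap: MarkerMap) -> int:
        return int(mmap.position_bp[self.end_idx - 1] - mmap.position_bp[self.start_idx] + 1)


@dataclass
class BlockPartition:
    blocks: list
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.blocks = sorted(self.blocks, key=lambda b: b.start_idx)
        prev_end = 0
        for b in self.blocks:
            if b.start_idx < prev_end:
                raise ValidationError("blocks overlap")
            prev_end = b.end_idx

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_unblocked(self) -> int:
        return sum(1 for b in self.blocks if b.n_markers == 1)

    def block_sizes(self) -> np.ndarray:
        return np.array([b.n_markers for b in self.blocks])

    def validate(self, mmap: MarkerMap) -> None:
        """Assert the partition is exhaustive and within-chromosome."""
        covered = np.zeros(len(mmap), dtype=bool)
        ranges = mmap.chrom_ranges()
        for b in self.blocks:
            lo, hi = ranges[b.chromosome]
            if b.start_idx < lo or b.end_idx > hi:
                raise ValidationError(f"block crosses chromosome bounds: {b}")
            if covered[b.start_idx : b.end_idx].any():
                raise ValidationError(f"overlapping block: {b}")
            covered[b.start_idx : b.end_idx] = True
        if not covered.all():
            raise ValidationError("partition does not cover all markers")


def _fill_singletons(blocks: list, chrom, lo: int, hi: int, assigned: np.ndarray) -> None:
    for i in range(lo, hi):
        if not assigned[i - lo]:
            blocks.append(Block(chrom, i, i + 1))


def _r2_adjacent_safe(dosages: np.ndarray, a: int, b: int) -> float:
    """r2 of two dosage columns; NaN (fails any threshold) if monomorphic."""
    x = dosages[:, a].astype(float)
    y = dosages[:, b].astype(float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def blocks_ld_threshold(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    threshold: float,
    tolerance: int = 1,
) -> BlockPartition:
    """LD-threshold blocks with a misplaced-marker tolerance.

    Per chromosome, a block is seeded at the unassigned adjacent marker pair
    with the highest r2 at or above ``threshold`` (ties to the lowest index)
    and grown at both borders: a candidate adjacent marker joins if its r2
    with the current border marker reaches the threshold; up to ``tolerance``
    consecutive failing markers are absorbed when the marker just past them
    passes against the same border marker.  Unassignable markers end up as
    singleton blocks.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError("threshold must be in (0, 1]")
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    if gm.has_missing:
        raise ValidationError("complete (imputed) genotypes required")
    d = gm.dosages
    blocks: list = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        nc = hi - lo
        assigned = np.zeros(nc, dtype=bool)
        adj = np.array([_r2_adjacent_safe(d, lo + k, lo + k + 1) for k in range(nc - 1)])
        while True:
            best, best_r2 = -1, -np.inf
            for k in range(nc - 1):
                if assigned[k] or assigned[k + 1]:
                    continue
                r2 = adj[k]
                if not np.isnan(r2) and r2 >= threshold and r2 > best_r2:
                    best, best_r2 = k, r2
            if best < 0:
                break
            left, right = best, best + 1

            def _extend(border: int, step: int) -> int:
                # walk outward from `border`; return the new border offset
                failures = 0
                cand = border + step
                while 0 <= cand < nc and not assigned[cand]:
                    r2 = _r2_adjacent_safe(d, lo + border, lo + cand)
                    if not np.isnan(r2) and r2 >= threshold:
                        border = cand
                        failures = 0
                    else:
                        failures += 1
                        if failures > tolerance:
                            break
                    cand += step
                return border

            right = _extend(right, +1)
            left = _extend(left, -1)
            assigned[left : right + 1] = True
            blocks.append(Block(chrom, lo + left, lo + right + 1))
        _fill_singletons(blocks, chrom, lo, hi, assigned)
    return BlockPartition(blocks, "ld_threshold", {"threshold": threshold, "tolerance": tolerance})


def blocks_fixed_markers(mmap: MarkerMap, m: int) -> BlockPartition:
    """Consecutive windows of ``m`` markers per chromosome (last may be short)."""
    if m < 1:
        raise ParameterError("m must be >= 1")
    blocks = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        for start in range(lo, hi, m):
            blocks.append(Block(chrom, start, min(start + m, hi)))
    return BlockPartition(blocks, "fixed_markers", {"m": m})


def blocks_fixed_bp(mmap: MarkerMap, window_bp: int) -> BlockPartition:
    """Bins of ``window_bp`` base pairs anchored at position 1 per chromosome."""
    if window_bp < 1:
        raise ParameterError("window_bp must be >= 1")
    blocks = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        pos = mmap.position_bp[lo:hi]
        bins = (pos - 1) // window_bp
        start = lo
        for k in range(1, hi - lo + 1):
            if k == hi - lo or bins[k] != bins[k - 1]:
                blocks.append(Block(chrom, start, lo + k))
                start = lo + k
    return BlockPartition(blocks, "fixed_bp", {"window_bp": window_bp})


def blocks_gabriel(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    ci_upper_min: float = 0.98,
    ci_lower_min: float = 0.70,
    conf: float = 0.95,
    seed: int = 0,
    n_boot: int = 100,
) -> BlockPartition:
    """D'-confidence-interval blocks.

    A pair is in "strong LD" if the bootstrap CI of D' has upper bound
    > ``ci_upper_min`` and lower bound > ``ci_lower_min``.  Blocks grow left
    to right while the pair (first block marker, candidate) stays in strong
    LD; the CI bootstrap seed is derived per pair so results do not depend on
    evaluation order.
    """
    for name, v in (("ci_upper_min", ci_upper_min), ("ci_lower_min", ci_lower_min), ("conf", conf)):
        if not (0.0 < v < 1.0 or (name != "conf" and v == 1.0)):
            raise ParameterError(f"{name} out of bounds")
    if gm.has_missing:
        raise ValidationError("complete (imputed) genotypes required")

    def strong(a: int, b: int) -> bool:
        pair_seed = int(np.random.SeedSequence([seed, a, b]).generate_state(1)[0])
        try:
            lo_, hi_ = dprime_ci(gm, a, b, conf=conf, n_boot=n_boot, seed=pair_seed)
        except MonomorphicError:
            return False
        return hi_ > ci_upper_min and lo_ > ci_lower_min

    blocks = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        i = lo
        while i < hi:
            j = i + 1
            while j < hi and strong(i, j):
                j += 1
            blocks.append(Block(chrom, i, j))
            i = j
    return BlockPartition(
        blocks,
        "gabriel",
        {"ci_upper_min": ci_upper_min, "ci_lower_min": ci_lower_min, "conf": conf,
         "n_boot": n_boot, "seed": seed},
    )


def blocks_four_gamete(gm: GenotypeMatrix, mmap: MarkerMap, freq_min: float = 0.01) -> BlockPartition:
    """Four-gamete-rule blocks.

    Scanning left to right, a candidate marker joins the current block only
    if no pair (block member, candidate) shows all four gametes at frequency
    >= ``freq_min``; otherwise a border is drawn and a new block starts.
    """
    if not (0.0 < freq_min < 1.0):
        raise ParameterError("freq_min must be in (0, 1)")
    if gm.has_missing:
        raise ValidationError("complete (imputed) genotypes required")
    blocks = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        start = lo
        for cand in range(lo + 1, hi):
            recomb = any(
                four_gamete_evidence(gamete_counts(gm, m, cand), freq_min)
                for m in range(start, cand)
            )
            if recomb:
                blocks.append(Block(chrom, start, cand))
                start = cand
        blocks.append(Block(chrom, start, hi))
    return BlockPartition(blocks, "four_gamete", {"freq_min": freq_min})


def blocks_solid_spine(gm: GenotypeMatrix, mmap: MarkerMap, dprime_min: float = 0.8) -> BlockPartition:
    """Solid-spine-of-LD blocks.

    From each anchor the farthest downstream marker with pairwise D' above
    ``dprime_min`` closes a block spanning everything in between (interior
    markers need not be in LD); scanning resumes past the block.
    """
    if not (0.0 <= dprime_min < 1.0):
        raise ParameterError("dprime_min must be in [0, 1)")
    if gm.has_missing:
        raise ValidationError("complete (imputed) genotypes required")

    def dp(a: int, b: int) -> float:
        try:
            return compute_dprime(gamete_counts(gm, a, b))
        except MonomorphicError:
            return float("nan")

    blocks = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        i = lo
        while i < hi:
            found = -1
            for j in range(hi - 1, i, -1):
                v = dp(i, j)
                if not math.isnan(v) and v > dprime_min:
                    found = j
                    break
            if found < 0:
                blocks.append(Block(chrom, i, i + 1))
                i += 1
            else:
                blocks.append(Block(chrom, i, found + 1))
                i = found + 1
    return BlockPartition(blocks, "solid_spine", {"dprime_min": dprime_min})


def ld_threshold_grid() -> list:
    """The default LD-threshold sweep: 0.01, 0.02, ..., 1.00 (100 values)."""
    return [round(k / 100.0, 2) for k in range(1, 101)]


def window_size_grid(kind: str, max_extent: int) -> list:
    """Window sizes ceil(2**x) with x = 1, 1.5, 2, ... (markers) or
    x = 10, 10.5, 11, ... (bp), truncated after the first value at or above
    ``max_extent`` so the whole-chromosome case stays representable."""
    if kind == "markers":
        x = 1.0
    elif kind == "bp":
        x = 10.0
    else:
        raise ParameterError("kind must be 'markers' or 'bp'")
    first = math.ceil(2.0**x)
    if max_extent < first:
        raise ParameterError(f"max_extent must be >= {first}")
    sizes: list = []
    while True:
        v = math.ceil(2.0**x)
        if not sizes or v != sizes[-1]:
            sizes.append(v)
        if v >= max_extent:
            break
        x += 0.5
    return sizes


def import_partition(path: str, mmap: MarkerMap) -> BlockPartition:
    """Import an externally produced partition from a tab-delimited interval
    file with columns (chromosome, start_bp, end_bp), 1-based inclusive.

    Markers inside an interval form a block; uncovered markers become
    singletons; overlapping intervals or unknown chromosomes are rejected.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chromosome", "start_bp", "end_bp"],
        dtype={"chromosome": str}, comment="#",
    )
    ranges = {str(c): r for c, r in mmap.chrom_ranges().items()}
    covered = np.zeros(len(mmap), dtype=bool)
    blocks = []
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        chrom = str(row.chromosome)
        if chrom not in ranges:
            raise ValidationError(f"{path}: unknown chromosome {chrom!r} (line {line_no})")
        lo, hi = ranges[chrom]
        pos = mmap.position_bp[lo:hi]
        inside = np.flatnonzero((pos >= row.start_bp) & (pos <= row.end_bp))
        if inside.size == 0:
            continue
        s, e = lo + int(inside[0]), lo + int(inside[-1]) + 1
        if covered[s:e].any():
            raise ValidationError(f"{path}: overlapping interval (line {line_no})")
        covered[s:e] = True
        blocks.append(Block(_orig_chrom(mmap, lo), s, e))
    for i in range(len(mmap)):
        if not covered[i]:
            blocks.append(Block(mmap.chromosome[i], i, i + 1))
    return BlockPartition(blocks, "imported", {"path": str(path)})


def _orig_chrom(mmap: MarkerMap, idx: int):
    return mmap.chromosome[idx]


def export_partition_bed(partition: BlockPartition, mmap: MarkerMap, path: str) -> None:
    """Write blocks as BED-like half-open 0-based intervals."""
    rows = []
    for k, b in enumerate(partition.blocks):
        rows.append(
            (
                b.chromosome,
                int(mmap.position_bp[b.start_idx]) - 1,
                int(mmap.position_bp[b.end_idx - 1]),
                f"block{k}",
                b.n_markers,
                partition.method,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


BUILDERS = {
    "ld_threshold": blocks_ld_threshold,
    "fixed_markers": blocks_fixed_markers,
    "fixed_bp": blocks_fixed_bp,
    "gabriel": blocks_gabriel,
    "four_gamete": blocks_four_gamete,
    "solid_spine": blocks_solid_spine,
}


def singleton_partition(mmap: MarkerMap) -> BlockPartition:
    """All-singleton partition (plain SNP coding)."""
    blocks = [Block(mmap.chromosome[i], i, i + 1) for i in range(len(mmap))]
    return BlockPartition(blocks, "fixed_markers", {"m": 1})
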