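import math

import numpy as np
import pytest

from hapblock.block_builders import (
    Block,
    BlockPartition,
    blocks_fixed_bp,
    blocks_fixed_markers,
    blocks_four_gamete,
    blocks_gabriel,
    blocks_ld_threshold,
    blocks_solid_spine,
    import_partition,
    ld_threshold_grid,
    singleton_partition,
    window_size_grid,
)
from hapblock.errors import ParameterError, ValidationError
from hapblock.ld_stats import dprime_ci

from conftest import make_homozygous, random_panel


# ---------------------------------------------------------------------------
# independent oracles: literal re-implementations of each acceptance rule


def _r2(d, a, b):
    x, y = d[:, a].astype(float), d[:, b].astype(float)
    if x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _gamete_freqs(gametes, a, b):
    n = len(gametes)
    f = {}
    for row in gametes:
        key = (int(row[a]), int(row[b]))
        f[key] = f.get(key, 0) + 1
    return {k: v / n for k, v in f.items()}


def _dprime(gametes, a, b):
    f = _gamete_freqs(gametes, a, b)
    pA = f.get((1, 1), 0) + f.get((1, 0), 0)
    pB = f.get((1, 1), 0) + f.get((0, 1), 0)
    if pA in (0, 1) or pB in (0, 1):
        return None
    D = f.get((1, 1), 0) - pA * pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D > 0 else min(pA * pB, (1 - pA) * (1 - pB))
    return min(abs(D) / dmax, 1.0) if dmax > 0 else 0.0


def oracle_ld_threshold(gm, mmap, threshold, tolerance):
    """Step-by-step re-implementation of the seed-and-extend rule."""
    d = gm.dosages
    result = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        members = set()
        chrom_blocks = []
        while True:
            # best unassigned adjacent seed pair at/above the threshold
            seeds = []
            for k in range(lo, hi - 1):
                if k in members or (k + 1) in members:
                    continue
                r2 = _r2(d, k, k + 1)
                if r2 is not None and r2 >= threshold:
                    seeds.append((r2, -k))
            if not seeds:
                break
            r2max, negk = max(seeds)
            left = right = -negk
            right += 1
            # grow rightward with tolerance
            fails = 0
            cand = right + 1
            while cand < hi and cand not in members:
                r2 = _r2(d, right, cand)
                if r2 is not None and r2 >= threshold:
                    right = cand
                    fails = 0
                else:
                    fails += 1
                    if fails > tolerance:
                        break
                cand += 1
            # grow leftward with tolerance
            fails = 0
            cand = left - 1
            while cand >= lo and cand not in members:
                r2 = _r2(d, left, cand)
                if r2 is not None and r2 >= threshold:
                    left = cand
                    fails = 0
                else:
                    fails += 1
                    if fails > tolerance:
                        break
                cand -= 1
            chrom_blocks.append((left, right + 1))
            members.update(range(left, right + 1))
        for k in range(lo, hi):
            if k not in members:
                chrom_blocks.append((k, k + 1))
        result.extend(sorted(chrom_blocks))
    return sorted(result)


def oracle_gabriel(gm, mmap, seed, n_boot=60):
    def strong(a, b):
        pair_seed = int(np.random.SeedSequence([seed, a, b]).generate_state(1)[0])
        try:
            lo_, hi_ = dprime_ci(gm, a, b, n_boot=n_boot, seed=pair_seed)
        except Exception:
            return False
        return hi_ > 0.98 and lo_ > 0.70

    result = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        i = lo
        while i < hi:
            j = i + 1
            while j < hi and strong(i, j):
                j += 1
            result.append((i, j))
            i = j
    return result


def oracle_four_gamete(gm, mmap, freq_min=0.01):
    gametes = gm.gametes()

    def recombined(a, b):
        f = _gamete_freqs(gametes, a, b)
        return len(f) == 4 and min(f.values()) >= freq_min

    result = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        start = lo
        for cand in range(lo + 1, hi):
            if any(recombined(m, cand) for m in range(start, cand)):
                result.append((start, cand))
                start = cand
        result.append((start, hi))
    return result


def oracle_solid_spine(gm, mmap, dprime_min=0.8):
    gametes = gm.gametes()
    result = []
    for chrom, (lo, hi) in mmap.chrom_ranges().items():
        i = lo
        while i < hi:
            best = None
            for j in range(i + 1, hi):  # exhaustive search, keep the farthest
                v = _dprime(gametes, i, j)
                if v is not None and v > dprime_min:
                    best = j
            if best is None:
                result.append((i, i + 1))
                i += 1
            else:
                result.append((i, best + 1))
                i = best + 1
    return result


def ranges(partition):
    return sorted((b.start_idx, b.end_idx) for b in partition.blocks)


# ---------------------------------------------------------------------------


class TestLdThreshold:
    def test_duplicated_columns_one_block(self):
        gm, mmap = make_homozygous([[0, 0, 0], [2, 2, 2], [0, 0, 0], [2, 2, 2]])
        part = blocks_ld_threshold(gm, mmap, threshold=1.0)
        assert ranges(part) == [(0, 3)]

    def test_uncorrelated_all_singletons(self):
        gm, mmap = make_homozygous(
            [[0, 0, 0], [0, 0, 2], [0, 2, 0], [0, 2, 2], [2, 0, 0], [2, 0, 2], [2, 2, 0], [2, 2, 2]]
        )
        part = blocks_ld_threshold(gm, mmap, threshold=0.5)
        assert part.n_blocks == 3 and part.n_unblocked == 3

    def test_tolerance_bridges_outlier(self):
        # markers 0-5 and 7-11 share one haplotype pattern; marker 6 is noise
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, 20)
        cols = [base] * 6 + [rng.integers(0, 2, 20)] + [base] * 5
        gm, mmap = make_homozygous(np.column_stack(cols) * 2)
        bridged = blocks_ld_threshold(gm, mmap, threshold=0.9, tolerance=1)
        assert ranges(bridged) == [(0, 12)]
        split = blocks_ld_threshold(gm, mmap, threshold=0.9, tolerance=0)
        assert ranges(split) == [(0, 6), (6, 7), (7, 12)]

    @pytest.mark.parametrize("tolerance", [0, 1])
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle(self, seed, tolerance):
        gm, mmap = random_panel(seed, n=20, m=12)
        for threshold in (0.3, 0.7, 1.0):
            part = blocks_ld_threshold(gm, mmap, threshold, tolerance=tolerance)
            part.validate(mmap)
            assert ranges(part) == oracle_ld_threshold(gm, mmap, threshold, tolerance)

    def test_threshold_bounds(self):
        gm, mmap = random_panel(1)
        with pytest.raises(ParameterError):
            blocks_ld_threshold(gm, mmap, 0.0)
        with pytest.raises(ParameterError):
            blocks_ld_threshold(gm, mmap, 1.5)

    def test_two_marker_monotonicity(self):
        # on a 2-marker chromosome, a higher threshold can only split, never merge
        for seed in range(20):
            gm, mmap = random_panel(100 + seed, n=12, m=2, block_structure=False)
            merged_low = ranges(blocks_ld_threshold(gm, mmap, 0.2, tolerance=0)) == [(0, 2)]
            merged_high = ranges(blocks_ld_threshold(gm, mmap, 0.9, tolerance=0)) == [(0, 2)]
            assert merged_low or not merged_high


class TestFixedWindows:
    def test_marker_window_sizes(self):
        gm, mmap = random_panel(2, n=5, m=10)
        part = blocks_fixed_markers(mmap, 4)
        assert [b.n_markers for b in part.blocks] == [4, 4, 2]

    def test_m1_singletons(self):
        gm, mmap = random_panel(2, n=5, m=10)
        assert blocks_fixed_markers(mmap, 1).n_unblocked == 10

    def test_whole_chromosome(self):
        gm, mmap = random_panel(2, n=5, m=10, n_chrom=2)
        part = blocks_fixed_markers(mmap, 99)
        assert part.n_blocks == 2
        assert all(b.n_markers == 5 for b in part.blocks)

    def test_block_count_formula(self):
        for seed in range(5):
            gm, mmap = random_panel(seed, n=5, m=11, n_chrom=2)
            for m in (1, 2, 3, 5, 8):
                part = blocks_fixed_markers(mmap, m)
                expect = sum(
                    math.ceil((hi - lo) / m) for _, (lo, hi) in mmap.chrom_ranges().items()
                )
                assert part.n_blocks == expect

    def test_bp_binning(self):
        gm, mmap = make_homozygous([[0, 0, 0], [2, 2, 2]], positions=[100, 900, 1100])
        part = blocks_fixed_bp(mmap, 1024)
        assert ranges(part) == [(0, 2), (2, 3)]

    def test_bp_window_larger_than_chromosome(self):
        gm, mmap = random_panel(3, n=5, m=8, n_chrom=2)
        part = blocks_fixed_bp(mmap, 10**9)
        assert part.n_blocks == 2

    def test_bp_window_one(self):
        gm, mmap = random_panel(3, n=5, m=8)
        assert blocks_fixed_bp(mmap, 1).n_unblocked == 8


class TestGabriel:
    def test_cosegregating_run(self):
        col = np.array([0, 0, 2, 2, 0, 2, 0, 2, 2, 0])
        gm, mmap = make_homozygous(np.column_stack([col] * 5))
        part = blocks_gabriel(gm, mmap, seed=1, n_boot=60)
        assert ranges(part) == [(0, 5)]

    def test_independent_markers_singletons(self):
        gm, mmap = random_panel(40, n=20, m=6, block_structure=False)
        part = blocks_gabriel(gm, mmap, seed=2, n_boot=60)
        part.validate(mmap)
        assert part.n_unblocked >= 4

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_oracle(self, seed):
        gm, mmap = random_panel(200 + seed, n=20, m=10)
        part = blocks_gabriel(gm, mmap, seed=seed, n_boot=60)
        part.validate(mmap)
        assert ranges(part) == sorted(oracle_gabriel(gm, mmap, seed=seed, n_boot=60))


class TestFourGamete:
    def test_two_gamete_panel_single_block(self):
        # complementary haplotypes only -> never four gametes
        gm, mmap = make_homozygous([[0, 0, 0], [2, 2, 2]] * 3)
        part = blocks_four_gamete(gm, mmap)
        assert ranges(part) == [(0, 3)]

    def test_all_four_gametes_singletons(self):
        gm, mmap = make_homozygous(
            [[0, 0, 0], [0, 2, 2], [2, 0, 2], [2, 2, 0], [0, 0, 2], [2, 2, 2], [0, 2, 0], [2, 0, 0]]
        )
        part = blocks_four_gamete(gm, mmap)
        assert part.n_unblocked == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle(self, seed):
        gm, mmap = random_panel(300 + seed, n=20, m=15 if seed % 2 else 12)
        part = blocks_four_gamete(gm, mmap)
        part.validate(mmap)
        assert ranges(part) == sorted(oracle_four_gamete(gm, mmap))


class TestSolidSpine:
    def test_spine_over_uncorrelated_interior(self):
        rng = np.random.default_rng(5)
        anchor = np.array([0, 0, 0, 1, 1, 1, 0, 1, 0, 1])
        cols = [anchor]
        for _ in range(3):
            cols.append(rng.integers(0, 2, 10))
        cols.append(anchor)  # D'(0, 4) = 1
        gm, mmap = make_homozygous(np.column_stack(cols) * 2)
        part = blocks_solid_spine(gm, mmap)
        assert ranges(part)[0] == (0, 5)

    def test_no_pair_above_threshold(self):
        gm, mmap = make_homozygous(
            [[0, 0, 0], [0, 2, 2], [2, 0, 2], [2, 2, 0], [0, 0, 2], [2, 2, 2], [0, 2, 0], [2, 0, 0]]
        )
        part = blocks_solid_spine(gm, mmap, dprime_min=0.8)
        assert part.n_unblocked == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_oracle(self, seed):
        gm, mmap = random_panel(400 + seed, n=20, m=12)
        part = blocks_solid_spine(gm, mmap)
        part.validate(mmap)
        assert ranges(part) == sorted(oracle_solid_spine(gm, mmap))


class TestGrids:
    def test_ld_grid(self):
        grid = ld_threshold_grid()
        assert grid[0] == 0.01
        assert grid[-1] == 1.00
        assert len(grid) == 100
        assert all(b > a for a, b in zip(grid, grid[1:]))

    def test_marker_window_grid(self):
        assert window_size_grid("markers", 20)[:7] == [2, 3, 4, 6, 8, 12, 16]

    def test_bp_window_grid(self):
        assert window_size_grid("bp", 3000)[:3] == [1024, 1449, 2048]

    def test_truncation_keeps_whole_chromosome_value(self):
        grid = window_size_grid("markers", 10)
        assert grid[-1] >= 10
        assert grid == [2, 3, 4, 6, 8, 12]

    def test_minimal_extent(self):
        assert window_size_grid("markers", 2) == [2]

    def test_extent_below_first_value(self):
        with pytest.raises(ParameterError):
            window_size_grid("bp", 100)


class TestImportPartition:
    def test_full_coverage(self, tmp_path):
        gm, mmap = random_panel(6, n=5, m=8)
        pos = mmap.position_bp
        p = tmp_path / "blocks.tsv"
        p.write_text(f"c1\t{pos[0]}\t{pos[3]}\nc1\t{pos[4]}\t{pos[7]}\n")
        part = import_partition(str(p), mmap)
        assert ranges(part) == [(0, 4), (4, 8)]

    def test_partial_coverage(self, tmp_path):
        gm, mmap = random_panel(6, n=5, m=8)
        pos = mmap.position_bp
        p = tmp_path / "blocks.tsv"
        p.write_text(f"c1\t{pos[0]}\t{pos[3]}\n")
        part = import_partition(str(p), mmap)
        part.validate(mmap)
        assert part.n_blocks == 5  # one 4-marker block + 4 singletons

    def test_overlap_rejected(self, tmp_path):
        gm, mmap = random_panel(6, n=5, m=8)
        pos = mmap.position_bp
        p = tmp_path / "blocks.tsv"
        p.write_text(f"c1\t{pos[0]}\t{pos[4]}\nc1\t{pos[3]}\t{pos[7]}\n")
        with pytest.raises(ValidationError, match="overlap"):
            import_partition(str(p), mmap)

    def test_unknown_chromosome_rejected(self, tmp_path):
        gm, mmap = random_panel(6, n=5, m=8)
        p = tmp_path / "blocks.tsv"
        p.write_text("chr9\t1\t100\n")
        with pytest.raises(ValidationError, match="unknown chromosome"):
            import_partition(str(p), mmap)


class TestPartitionProperty:
    """Every builder must yield a disjoint, exhaustive, within-chromosome
    partition on randomized small panels."""

    @pytest.mark.parametrize("seed", range(25))
    def test_cheap_builders(self, seed):
        gm, mmap = random_panel(1000 + seed, n=15, m=10, n_chrom=2)
        blocks_ld_threshold(gm, mmap, 0.5).validate(mmap)
        blocks_ld_threshold(gm, mmap, 0.9, tolerance=0).validate(mmap)
        blocks_fixed_markers(mmap, 3).validate(mmap)
        blocks_fixed_bp(mmap, 120).validate(mmap)
        blocks_four_gamete(gm, mmap).validate(mmap)
        blocks_solid_spine(gm, mmap).validate(mmap)

    @pytest.mark.parametrize("seed", range(4))
    def test_gabriel_partition_property(self, seed):
        gm, mmap = random_panel(2000 + seed, n=12, m=8, n_chrom=2)
        blocks_gabriel(gm, mmap, seed=seed, n_boot=60).validate(mmap)

    def test_singleton_partition(self):
        gm, mmap = random_panel(7, n=5, m=9, n_chrom=3)
        part = singleton_partition(mmap)
        part.validate(mmap)
        assert part.n_unblocked == 9


class TestBlockTypes:
    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError):
            Block("1", 3, 3)

    def test_overlapping_partition_rejected(self):
        with pytest.raises(ValidationError):
            BlockPartition([Block("1", 0, 2), Block("1", 1, 3)], "fixed_markers")

    def test_span_bp(self):
        gm, mmap = make_homozygous([[0, 0, 0], [2, 2, 2]], positions=[100, 900, 1100])
        assert Block("1", 0, 3).span_bp(mmap) == 1001
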