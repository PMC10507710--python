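"""Genotype/phenotype containers, file I/O, marker filtering and in-silico crossing.

Dosages count copies of the minor allele (orientation fixed at read time from
the full sample) and live in {0, 1, 2}; ``MISSING`` (-1) marks absent calls.
Two ploidy modes are supported: fully homozygous material (DH/inbred lines,
no dosage of 1 allowed) and phased diploids (in-silico hybrids) whose two
haplotype phases are carried explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EmptyResultError, ParameterError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MISSING = -1

HOMOZYGOUS = "homozygous"
PHASED_DIPLOID = "phased_diploid"


@dataclass
class MarkerMap:
    """Physical map: one (chromosome, 1-based bp position) per marker.

    Markers must be sorted by chromosome then ascending position, and every
    (chromosome, position) pair must be unique.
    """

    marker_ids: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        n = len(self.marker_ids)
        if len(self.chromosome) != n or len(self.position_bp) != n:
            raise ValidationError("marker map field lengths differ")
        if n != len(set(self.marker_ids)):
            raise ValidationError("marker ids are not unique")
        if n and self.position_bp.min() < 1:
            raise ValidationError("positions must be positive 1-based bp")
        pairs = list(zip(self.chromosome, self.position_bp))
        if len(pairs) != len(set(pairs)):
            raise ValidationError("duplicate (chromosome, position) pairs")
        # sorted by chromosome (order of first appearance), then position
        for lo, hi in self.chrom_ranges().values():
            pos = self.position_bp[lo:hi]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("markers not sorted by position within chromosome")

    def __len__(self) -> int:
        return len(self.marker_ids)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        seen: dict = {}
        for c in self.chromosome:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_ranges(self) -> dict:
        """Map chromosome -> (lo, hi) half-open global marker-index range."""
        out: dict = {}
        for i, c in enumerate(self.chromosome):
            if c in out:
                lo, hi = out[c]
                if i != hi:
                    raise ValidationError(f"chromosome {c} is not contiguous in the map")
                out[c] = (lo, i + 1)
            else:
                out[c] = (i, i + 1)
        return out

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        idx = np.asarray(idx)
        return MarkerMap(self.marker_ids[idx], self.chromosome[idx], self.position_bp[idx])


@dataclass
class GenotypeMatrix:
    """Sample-by-marker minor-allele dosage matrix.

    ``phases`` is required for phased diploids: an (n_samples, 2, n_markers)
    array of per-gamete minor-allele indicators whose sum recovers the dosage.
    """

    sample_ids: list
    dosages: np.ndarray
    ploidy_mode: str = HOMOZYGOUS
    phases: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.sample_ids = list(self.sample_ids)
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise ValidationError("sample ids are not unique")
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.sample_ids):
            raise ValidationError("dosage matrix shape does not match sample ids")
        ok = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not ok.all():
            raise ValidationError("dosages must be in {0,1,2} or missing (-1)")
        if self.ploidy_mode == HOMOZYGOUS:
            if (self.dosages == 1).any():
                raise ValidationError("homozygous material cannot carry dosage 1")
        elif self.ploidy_mode == PHASED_DIPLOID:
            if self.phases is None:
                raise ValidationError("phased_diploid requires explicit phases")
            self.phases = np.asarray(self.phases, dtype=np.int8)
            if self.phases.shape != (self.n_samples, 2, self.n_markers):
                raise ValidationError("phases shape must be (n_samples, 2, n_markers)")
            obs = self.dosages != MISSING
            if not np.array_equal(self.phases.sum(axis=1)[obs], self.dosages[obs]):
                raise ValidationError("phases do not sum to dosages")
        else:
            raise ValidationError(f"unknown ploidy_mode {self.ploidy_mode!r}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def gametes(self) -> np.ndarray:
        """Phase-resolved gamete matrix (n_gametes x n_markers) of 0/1 alleles.

        A homozygous line contributes one gamete; a phased diploid two.
        Requires complete data.
        """
        if self.has_missing:
            raise ValidationError("gametes undefined with missing dosages; impute first")
        if self.ploidy_mode == HOMOZYGOUS:
            return (self.dosages // 2).astype(np.int8)
        return self.phases.reshape(self.n_samples * 2, self.n_markers)

    def gametes_per_sample(self) -> int:
        return 1 if self.ploidy_mode == HOMOZYGOUS else 2

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        phases = self.phases[:, :, idx] if self.phases is not None else None
        return GenotypeMatrix(self.sample_ids, self.dosages[:, idx], self.ploidy_mode, phases)

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx]
        phases = self.phases[idx] if self.phases is not None else None
        return GenotypeMatrix(ids, self.dosages[idx], self.ploidy_mode, phases)


@dataclass
class PhenotypeTable:
    """Adjusted trait means with optional fixed covariates and family labels."""

    sample_ids: list
    trait_values: np.ndarray
    fixed_covariates: np.ndarray | None = None
    family_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.trait_values = np.asarray(self.trait_values, dtype=float)
        if len(self.trait_values) != len(self.sample_ids):
            raise ValidationError("trait vector length does not match sample ids")
        if np.isnan(self.trait_values).any():
            raise ValidationError("missing trait values are not allowed")
        if self.fixed_covariates is not None:
            self.fixed_covariates = np.atleast_2d(np.asarray(self.fixed_covariates, dtype=float))
            if self.fixed_covariates.shape[0] != len(self.sample_ids):
                raise ValidationError("covariate rows do not match sample ids")
        if self.family_labels is not None:
            self.family_labels = np.asarray(self.family_labels, dtype=object)
            if len(self.family_labels) != len(self.sample_ids):
                raise ValidationError("family labels do not match sample ids")

    def design_matrix(self) -> np.ndarray:
        """Fixed-effect design with an intercept column always included."""
        n = len(self.sample_ids)
        cols = [np.ones((n, 1))]
        if self.fixed_covariates is not None:
            cols.append(self.fixed_covariates)
        return np.hstack(cols)


# ---------------------------------------------------------------------------
# readers / writers


def _orient_minor(dosages: np.ndarray) -> np.ndarray:
    """Flip columns so dosages count the minor allele (ties untouched)."""
    d = dosages.copy()
    for j in range(d.shape[1]):
        col = d[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.mean() / 2.0 > 0.5:
            flip = col != MISSING
            col[flip] = 2 - col[flip]
    return d


def _read_vcf(path: str):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    dos_cols, phase_cols, ids, chroms, poss = [], [], [], [], []
    any_het = False
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            warnings.warn(
                f"skipping non-biallelic site {var.CHROM}:{var.POS} (record {k + 1})"
            )
            continue
        col = np.full(len(samples), MISSING, dtype=np.int16)
        ph = np.zeros((len(samples), 2), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                continue
            col[i] = a0 + a1
            if a0 != a1:
                any_het = True
                if not phased:
                    raise ParseError(
                        f"unphased heterozygote at {var.CHROM}:{var.POS} sample "
                        f"{samples[i]}; phase-resolved input required"
                    )
            ph[i] = (a0, a1)
        dos_cols.append(col)
        phase_cols.append(ph)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    if not ids:
        raise ParseError(f"no usable biallelic sites in {path}")
    dosages = np.column_stack(dos_cols)
    # (n_markers, n_samples, 2) -> (n_samples, 2, n_markers)
    phases = np.transpose(np.stack(phase_cols, axis=0), (1, 2, 0))
    mmap = MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object), np.array(poss))
    order = _sort_order(mmap)
    mmap = mmap.subset(order)
    dosages = dosages[:, order]
    phases = phases[:, :, order]
    dosages = _orient_minor(dosages)
    if any_het:
        # re-derive phases for flipped columns
        flip = [
            j
            for j in range(dosages.shape[1])
            if not np.array_equal(
                phases[:, :, j].sum(axis=1)[dosages[:, j] != MISSING],
                dosages[:, j][dosages[:, j] != MISSING],
            )
        ]
        for j in flip:
            phases[:, :, j] = 1 - phases[:, :, j]
        gm = GenotypeMatrix(samples, dosages, PHASED_DIPLOID, phases)
    else:
        gm = GenotypeMatrix(samples, dosages, HOMOZYGOUS)
    return gm, mmap


def _sort_order(mmap: MarkerMap) -> np.ndarray:
    chrom_rank = {c: i for i, c in enumerate(mmap.chromosomes)}
    keys = [(chrom_rank[c], p) for c, p in zip(mmap.chromosome, mmap.position_bp)]
    return np.array(sorted(range(len(mmap)), key=lambda i: keys[i]))


def _matrix_paths(prefix: str) -> tuple[str, str, str]:
    return f"{prefix}.geno.tsv", f"{prefix}.map.tsv", f"{prefix}.phase.tsv"


def _read_matrix(prefix: str):
    import os

    geno_path, map_path, phase_path = _matrix_paths(str(prefix))
    for p in (geno_path, map_path):
        if not os.path.exists(p):
            raise ParseError(f"missing file {p}")
    geno = pd.read_csv(geno_path, sep="\t", index_col=0)
    mdf = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
    for col in ("marker", "chromosome", "position_bp"):
        if col not in mdf.columns:
            raise ParseError(f"{map_path}: missing column {col!r} (line 1)")
    if list(geno.columns) != list(mdf["marker"]):
        raise ParseError(f"{geno_path}: marker columns disagree with {map_path}")
    dosages = geno.to_numpy()
    bad = ~np.isin(dosages, (MISSING, 0, 1, 2))
    if bad.any():
        r = int(np.argwhere(bad)[0][0])
        raise ParseError(f"{geno_path}: invalid dosage on data line {r + 2}")
    mmap = MarkerMap(
        mdf["marker"].to_numpy(dtype=object),
        mdf["chromosome"].to_numpy(dtype=object),
        mdf["position_bp"].to_numpy(),
    )
    dosages = dosages.astype(np.int16)
    if os.path.exists(phase_path):
        pdf = pd.read_csv(phase_path, sep="\t", index_col=0)
        n, m = dosages.shape
        phases = np.zeros((n, 2, m), dtype=np.int8)
        for j, colname in enumerate(pdf.columns):
            parts = pdf[colname].str.split("|", expand=True).to_numpy().astype(np.int8)
            phases[:, :, j] = parts
        gm = GenotypeMatrix(list(geno.index), dosages, PHASED_DIPLOID, phases)
    else:
        gm = GenotypeMatrix(list(geno.index), dosages, HOMOZYGOUS)
    return gm, mmap


def read_genotypes(path: str, format: str = "vcf"):
    """Read genotypes and the physical map.

    ``format='vcf'`` expects a VCF file path; ``format='matrix'`` expects the
    prefix used by :func:`write_genotypes` (``<prefix>.geno.tsv`` etc.).
    Returns ``(GenotypeMatrix, MarkerMap)`` with dosages oriented on the minor
    allele and the map sorted.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path)
    raise ParameterError(f"unknown format {format!r}")


def write_genotypes(gm: GenotypeMatrix, mmap: MarkerMap, prefix: str, format: str = "matrix") -> None:
    """Write genotypes; inverse of :func:`read_genotypes` for both formats."""
    if gm.n_markers != len(mmap):
        raise ValidationError("genotypes and map disagree in marker count")
    if format == "matrix":
        geno_path, map_path, phase_path = _matrix_paths(str(prefix))
        pd.DataFrame(gm.dosages, index=gm.sample_ids, columns=mmap.marker_ids).to_csv(
            geno_path, sep="\t", index_label="sample"
        )
        pd.DataFrame(
            {"marker": mmap.marker_ids, "chromosome": mmap.chromosome, "position_bp": mmap.position_bp}
        ).to_csv(map_path, sep="\t", index=False)
        if gm.ploidy_mode == PHASED_DIPLOID:
            strings = np.char.add(
                np.char.add(gm.phases[:, 0, :].astype(str), "|"), gm.phases[:, 1, :].astype(str)
            )
            pd.DataFrame(strings, index=gm.sample_ids, columns=mmap.marker_ids).to_csv(
                phase_path, sep="\t", index_label="sample"
            )
    elif format == "vcf":
        _write_vcf(gm, mmap, str(prefix))
    else:
        raise ParameterError(f"unknown format {format!r}")


def _write_vcf(gm: GenotypeMatrix, mmap: MarkerMap, path: str) -> None:
    # REF=A carries the major allele, ALT=B the minor, so that re-reading
    # does not flip the orientation.
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in mmap.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in gm.sample_ids) + "\n")
        sep = "|" if gm.ploidy_mode == PHASED_DIPLOID else "/"
        for j in range(gm.n_markers):
            gts = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                if d == MISSING:
                    gts.append(f".{sep}.")
                elif gm.ploidy_mode == PHASED_DIPLOID:
                    a, b = gm.phases[i, :, j]
                    gts.append(f"{a}|{b}")
                else:
                    gts.append(f"{d // 2}/{d // 2}")
            fh.write(
                f"{mmap.chromosome[j]}\t{mmap.position_bp[j]}\t{mmap.marker_ids[j]}"
                f"\tA\tB\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_phenotypes(path: str, covariate_cols: list | None = None) -> PhenotypeTable:
    """Read a phenotype CSV with columns ``sample``, ``trait`` and optionally
    covariate columns and a ``family`` column."""
    df = pd.read_csv(path)
    for col in ("sample", "trait"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    covs = None
    if covariate_cols:
        missing = [c for c in covariate_cols if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing covariate columns {missing}")
        covs = df[covariate_cols].to_numpy(dtype=float)
    fam = df["family"].to_numpy(dtype=object) if "family" in df.columns else None
    return PhenotypeTable(list(df["sample"]), df["trait"].to_numpy(dtype=float), covs, fam)


def write_phenotypes(pt: PhenotypeTable, path: str) -> None:
    data = {"sample": pt.sample_ids, "trait": pt.trait_values}
    if pt.fixed_covariates is not None:
        for k in range(pt.fixed_covariates.shape[1]):
            data[f"cov{k + 1}"] = pt.fixed_covariates[:, k]
    if pt.family_labels is not None:
        data["family"] = pt.family_labels
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# filtering / imputation / crossing


def filter_markers(
    gm: GenotypeMatrix,
    mmap: MarkerMap,
    maf_min: float = 0.05,
    max_missing: float = 0.10,
):
    """Retain markers with MAF >= ``maf_min`` (boundary inclusive) and a
    missing fraction <= ``max_missing``.

    Returns ``(GenotypeMatrix, MarkerMap, report)`` where the report is a
    DataFrame listing each dropped marker and the reason.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ParameterError("maf_min must be in [0, 0.5]")
    if not (0.0 <= max_missing <= 1.0):
        raise ParameterError("max_missing must be in [0, 1]")
    if gm.n_markers != len(mmap):
        raise ValidationError("genotypes and map disagree in marker count")
    d = gm.dosages
    miss = d == MISSING
    miss_frac = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        obs = np.where(miss, 0, d).sum(axis=0).astype(float)
        n_obs = (~miss).sum(axis=0)
        p = np.where(n_obs > 0, obs / np.maximum(2 * n_obs, 1), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = np.ones(gm.n_markers, dtype=bool)
    reasons = {}
    for j in range(gm.n_markers):
        if n_obs[j] == 0:
            keep[j] = False
            reasons[j] = "all_missing"
        elif miss_frac[j] > max_missing:
            keep[j] = False
            reasons[j] = f"missing_frac={miss_frac[j]:.4f}>{max_missing}"
        elif maf[j] < maf_min:
            keep[j] = False
            reasons[j] = f"maf={maf[j]:.4f}<{maf_min}"
    if not keep.any():
        raise EmptyResultError("all markers removed by filtering")
    report = pd.DataFrame(
        {
            "marker": [mmap.marker_ids[j] for j in sorted(reasons)],
            "reason": [reasons[j] for j in sorted(reasons)],
        }
    )
    idx = np.flatnonzero(keep)
    return gm.subset_markers(idx), mmap.subset(idx), report


def impute_naive(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace missing entries by draws from each marker's observed dosage
    distribution (gamete-level for phased material). Deterministic per seed."""
    if not gm.has_missing:
        return gm
    rng = np.random.default_rng(seed)
    d = gm.dosages.copy()
    phases = gm.phases.copy() if gm.phases is not None else None
    for j in range(gm.n_markers):
        col = d[:, j]
        miss = np.flatnonzero(col == MISSING)
        if miss.size == 0:
            continue
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValidationError(f"marker column {j} is fully missing; cannot impute")
        if gm.ploidy_mode == HOMOZYGOUS:
            col[miss] = rng.choice(obs, size=miss.size)
        else:
            q = obs.mean() / 2.0  # observed minor-allele frequency
            draw = (rng.random((miss.size, 2)) < q).astype(np.int8)
            phases[miss, :, j] = draw
            col[miss] = draw.sum(axis=1)
    return GenotypeMatrix(gm.sample_ids, d, gm.ploidy_mode, phases)


def in_silico_cross(
    mothers: GenotypeMatrix,
    fathers: GenotypeMatrix,
    pairings: list,
) -> GenotypeMatrix:
    """Cross homozygous parents to phased hybrid genotypes.

    ``pairings`` holds (mother_id, father_id) tuples; the hybrid dosage is the
    mean of the parental dosages and the two parental gametes become the
    hybrid's phases.
    """
    for gm in (mothers, fathers):
        if gm.ploidy_mode != HOMOZYGOUS:
            raise ValidationError("parents must be homozygous (phase undefined otherwise)")
        if gm.has_missing:
            raise ValidationError("parents must be complete; impute first")
    if mothers.n_markers != fathers.n_markers:
        raise ValidationError("parental panels differ in marker count")
    midx = {s: i for i, s in enumerate(mothers.sample_ids)}
    fidx = {s: i for i, s in enumerate(fathers.sample_ids)}
    n, m = len(pairings), mothers.n_markers
    dosages = np.zeros((n, m), dtype=np.int16)
    phases = np.zeros((n, 2, m), dtype=np.int8)
    ids = []
    for k, (mo, fa) in enumerate(pairings):
        if mo not in midx:
            raise ValidationError(f"unknown mother {mo!r}")
        if fa not in fidx:
            raise ValidationError(f"unknown father {fa!r}")
        gm_row = mothers.dosages[midx[mo]] // 2
        gf_row = fathers.dosages[fidx[fa]] // 2
        phases[k, 0] = gm_row
        phases[k, 1] = gf_row
        dosages[k] = gm_row + gf_row
        ids.append(f"{mo}x{fa}")
    return GenotypeMatrix(ids, dosages, PHASED_DIPLOID, phases)
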