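"""Genomic relationship kernels: additive (VanRaden), epistatic (Hadamard
square) and Gaussian, plus relationship-structure comparison."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ModelFitError, ParameterError, ValidationError
from .haplotype_coding import HaploDesign

JITTER = 1e-8  # times mean(diag), added before any factorization


@dataclass
class KernelMatrix:
    values: np.ndarray
    sample_ids: list | None = None
    kind: str = "additive"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kernel must be symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self) -> None:
        """Reject kernels with eigenvalues below -1e-8 * trace / n."""
        w = np.linalg.eigvalsh(self.values)
        tol = 1e-8 * np.trace(self.values) / self.n
        if w[0] < -max(tol, 1e-12):
            raise ModelFitError(f"kernel not PSD (min eigenvalue {w[0]:.3e})")

    def jittered(self) -> np.ndarray:
        """Values with a small diagonal jitter for stable factorization."""
        eps = JITTER * max(float(np.mean(np.diag(self.values))), 1.0)
        return self.values + eps * np.eye(self.n)

    def subset(self, idx) -> "KernelMatrix":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx] if self.sample_ids else None
        return KernelMatrix(self.values[np.ix_(idx, idx)], ids, self.kind, dict(self.provenance))

    def cross(self, rows, cols) -> np.ndarray:
        return self.values[np.ix_(np.asarray(rows), np.asarray(cols))]


def grm_vanraden(design: HaploDesign, sample_ids: list | None = None) -> KernelMatrix:
    """Additive genomic relationship matrix G = Z Z' / (2 sum p_i (1-p_i))."""
    if design.denominator <= 0:
        raise ParameterError("zero VanRaden denominator: no polymorphic columns")
    G = design.Z @ design.Z.T / design.denominator
    return KernelMatrix(G, sample_ids, "additive", {"n_columns": design.n_columns})


def epistatic_grm(G: KernelMatrix) -> KernelMatrix:
    """Additive-by-additive kernel: elementwise square of G."""
    if G.kind != "additive":
        raise ParameterError("epistatic kernel is derived from an additive G")
    return KernelMatrix(G.values * G.values, G.sample_ids, "epistatic", dict(G.provenance))


def gaussian_kernels(
    design: HaploDesign,
    bandwidths: tuple = (0.1, 0.5, 2.5),
    sample_ids: list | None = None,
) -> list:
    """Gaussian kernels K_l = exp(-h_l * d2 / mean(d2)) from pairwise squared
    Euclidean distances between genotype profiles; the mean off-diagonal
    squared distance makes the printed bandwidths scale-free."""
    if any(h <= 0 for h in bandwidths):
        raise ParameterError("bandwidths must be positive")
    Z = design.Z
    sq = np.sum(Z * Z, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * Z @ Z.T
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    n = Z.shape[0]
    off = d2[~np.eye(n, dtype=bool)]
    mean_d2 = float(off.mean()) if off.size else 0.0
    if mean_d2 <= 0:
        raise ParameterError("all samples identical: Gaussian kernel undefined")
    out = []
    for h in bandwidths:
        K = np.exp(-h * d2 / mean_d2)
        np.fill_diagonal(K, 1.0)
        out.append(KernelMatrix(K, sample_ids, "gaussian", {"bandwidth": h}))
    return out


def relationship_correlation(G_a: KernelMatrix, G_b: KernelMatrix) -> float:
    """Pearson correlation of the strict upper-triangle relationship
    coefficients of two kernels over the same samples."""
    if G_a.n != G_b.n:
        raise ValidationError("kernels must cover the same samples")
    if G_a.sample_ids and G_b.sample_ids and G_a.sample_ids != G_b.sample_ids:
        raise ValidationError("kernel sample orders differ")
    iu = np.triu_indices(G_a.n, k=1)
    a, b = G_a.values[iu], G_b.values[iu]
    if a.std() == 0 or b.std() == 0:
        raise ParameterError("constant off-diagonal relationship coefficients")
    return float(np.corrcoef(a, b)[0, 1])


def write_kernel(K: KernelMatrix, path: str) -> None:
    ids = K.sample_ids or [f"s{i}" for i in range(K.n)]
    pd.DataFrame(K.values, index=ids, columns=ids).to_csv(path, sep="\t", index_label="sample")


def read_kernel(path: str, kind: str = "additive") -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KernelMatrix(df.to_numpy(), list(df.columns), kind, {"path": str(path)})
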