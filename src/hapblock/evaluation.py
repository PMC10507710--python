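"""Cross-validation schemes, the accuracy metric, and sweep orchestration.

Random CV is repeated random subsampling (independent 80/20 splits, not
k-fold); family CV is leave-one-family-out.  Accuracy is the Pearson
correlation between observed and predicted phenotypes in the validation set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .block_builders import (
    BUILDERS,
    blocks_fixed_bp,
    blocks_fixed_markers,
    singleton_partition,
)
from .errors import HapblockError, ParameterError, ValidationError
from .haplotype_coding import build_design, enumerate_haplotypes
from .kinship import KernelMatrix, gaussian_kernels, grm_vanraden
from . import predictors

logger = logging.getLogger(__name__)

MODELS = ("gblup", "egblup", "bayesian_lasso", "rkhs")


@dataclass
class ModelSpec:
    name: str
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODELS:
            raise ParameterError(f"unknown model {self.name!r}; choose from {MODELS}")


@dataclass
class CVResult:
    scheme: str
    per_run_accuracy: list
    n_runs: int
    seed: int
    n_failed: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_run_accuracy)) if self.per_run_accuracy else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.per_run_accuracy, ddof=1)) if len(self.per_run_accuracy) > 1 else float("nan")


def accuracy(observed, predicted) -> float:
    """Pearson correlation between observed and predicted values."""
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.shape != predicted.shape or len(observed) < 3:
        raise ParameterError("vectors must have equal length >= 3")
    if observed.std() == 0 or predicted.std() == 0:
        raise ParameterError("accuracy undefined for a constant vector")
    return float(np.corrcoef(observed, predicted)[0, 1])


def fit_and_predict(spec: ModelSpec, y, X, data: dict, train, test, seed: int = 0) -> np.ndarray:
    """Fit ``spec`` on the training subset and predict the test subset.

    ``data`` carries the full-population objects the model needs:
    ``kernels`` (list of KernelMatrix) for gblup/egblup/rkhs, ``M`` (raw
    0/1/2 profile matrix) for the Bayesian LASSO.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    train = np.asarray(train)
    test = np.asarray(test)
    ytr, Xtr, Xte = y[train], X[train], X[test]
    opts = dict(spec.options)
    if spec.name == "gblup":
        G = data["kernels"][0]
        fit = predictors.fit_gblup(ytr, Xtr, [G.subset(train)])
        return predictors.predict(fit, [G.cross(test, train)], Xte)
    if spec.name == "egblup":
        G = data["kernels"][0]
        fit = predictors.fit_egblup(ytr, Xtr, G.subset(train))
        Gc = G.cross(test, train)
        return predictors.predict(fit, [Gc, Gc * Gc], Xte)
    if spec.name == "bayesian_lasso":
        M = np.asarray(data["M"], dtype=float)
        fit = predictors.fit_bayesian_lasso(ytr, Xtr, M[train], seed=seed, **opts)
        return predictors.predict_lasso(fit, M[test], Xte)
    if spec.name == "rkhs":
        ks = data["kernels"]
        fit = predictors.fit_rkhs(ytr, Xtr, [K.subset(train) for K in ks], seed=seed, **opts)
        return predictors.predict_rkhs(fit, [K.cross(test, train) for K in ks], Xte)
    raise ParameterError(f"unknown model {spec.name!r}")


def _split_sizes(n: int, test_frac: float) -> int:
    # ties round toward the larger validation set
    return int(np.floor(test_frac * n + 0.5))


def random_splits(n: int, n_runs: int, test_frac: float, seed: int):
    """Yield (train, test) index pairs for repeated random subsampling.

    Each run is an independent simple random split derived deterministically
    from ``seed`` and the run index; train and test are disjoint and exhaust
    the population."""
    n_test = _split_sizes(n, test_frac)
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence([seed, run]))
        perm = rng.permutation(n)
        yield perm[n_test:], perm[:n_test]


def random_cv(
    y,
    X,
    data: dict,
    spec: ModelSpec,
    n_runs: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
) -> CVResult:
    """Repeated random-split cross-validation.

    Each run draws a fresh simple random 80/20 split (derived deterministically
    from ``seed`` and the run index), refits the model on the training part
    and scores Pearson accuracy on the validation part.  Failed runs are
    excluded from the mean and counted.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    n_test = _split_sizes(n, test_frac)
    if n_test < 3:
        raise ParameterError("validation set must have >= 3 samples")
    accs, n_failed = [], 0
    for run, (train, test) in enumerate(random_splits(n, n_runs, test_frac, seed)):
        run_seed = int(np.random.SeedSequence([seed, run, 1]).generate_state(1)[0])
        try:
            pred = fit_and_predict(spec, y, X, data, train, test, seed=run_seed)
            accs.append(accuracy(y[test], pred))
        except HapblockError as exc:
            n_failed += 1
            logger.warning("random_cv run %d failed: %s", run, exc)
    return CVResult(
        "random", accs, n_runs=n_runs, seed=seed, n_failed=n_failed,
        metadata={"model": spec.name, "test_frac": test_frac},
    )


def family_cv(
    y,
    X,
    data: dict,
    spec: ModelSpec,
    family_labels,
    seed: int = 0,
    min_family_size: int = 3,
) -> CVResult:
    """Leave-one-family-out cross-validation; families smaller than
    ``min_family_size`` are skipped with a warning."""
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(family_labels, dtype=object)
    if len(labels) != len(y):
        raise ValidationError("family labels do not match y")
    fams = list(dict.fromkeys(labels))
    retained = []
    for fam in fams:
        size = int(np.sum(labels == fam))
        if size < min_family_size:
            logger.warning("family %r skipped (size %d < %d)", fam, size, min_family_size)
        else:
            retained.append(fam)
    if len(retained) < 2:
        raise ParameterError("need >= 2 families of sufficient size")
    accs, n_failed = [], 0
    for k, fam in enumerate(retained):
        test = np.flatnonzero(labels == fam)
        train = np.flatnonzero(labels != fam)
        run_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0])
        try:
            pred = fit_and_predict(spec, y, X, data, train, test, seed=run_seed)
            accs.append(accuracy(y[test], pred))
        except HapblockError as exc:
            n_failed += 1
            logger.warning("family_cv family %r failed: %s", fam, exc)
    return CVResult(
        "family", accs, n_runs=len(retained), seed=seed, n_failed=n_failed,
        metadata={"model": spec.name, "families": retained},
    )


def build_model_data(gm, mmap, partition, models) -> dict:
    """Derive the per-model inputs (kernels, M) for one block partition."""
    catalog = enumerate_haplotypes(gm, partition)
    design = build_design(catalog)
    data: dict = {"design": design, "n_columns": design.n_columns}
    names = {m.name if isinstance(m, ModelSpec) else m for m in models}
    if names & {"gblup", "egblup"}:
        data["kernels"] = [grm_vanraden(design, gm.sample_ids)]
    if "rkhs" in names:
        data["rkhs_kernels"] = gaussian_kernels(design, sample_ids=gm.sample_ids)
    if "bayesian_lasso" in names:
        data["M"] = design.raw_counts
    return data


def _partition_for_spec(block_spec: dict, gm, mmap):
    method = block_spec["method"]
    param = block_spec.get("param")
    if method == "snp":
        return singleton_partition(mmap)
    if method not in BUILDERS:
        raise ParameterError(f"unknown block method {method!r}")
    if method == "fixed_markers":
        return blocks_fixed_markers(mmap, int(param))
    if method == "fixed_bp":
        return blocks_fixed_bp(mmap, int(param))
    if method == "ld_threshold":
        return BUILDERS[method](gm, mmap, float(param), **block_spec.get("kwargs", {}))
    kwargs = block_spec.get("kwargs", {})
    if param is not None:
        return BUILDERS[method](gm, mmap, param, **kwargs)
    return BUILDERS[method](gm, mmap, **kwargs)


def sweep(
    y,
    X,
    gm,
    mmap,
    block_specs: list,
    models: list,
    cv_spec: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the block-method x parameter x model grid.

    ``block_specs`` is a list of dicts like ``{"method": "fixed_markers",
    "param": 4}`` (``{"method": "snp"}`` for the single-marker baseline);
    ``cv_spec`` selects the scheme and its settings.  Returns a long-format
    table; cell failures are recorded and the sweep continues.
    """
    cv_spec = dict(cv_spec or {})
    scheme = cv_spec.pop("scheme", "random")
    rows = []
    for bi, bspec in enumerate(block_specs):
        try:
            partition = _partition_for_spec(bspec, gm, mmap)
            data = build_model_data(gm, mmap, partition, models)
        except HapblockError as exc:
            for mi, model in enumerate(models):
                rows.append(_sweep_row(bspec, model, None, 0, error=str(exc)))
            continue
        for mi, model in enumerate(models):
            spec = model if isinstance(model, ModelSpec) else ModelSpec(model)
            cell_seed = int(np.random.SeedSequence([seed, bi, mi]).generate_state(1)[0])
            cell = dict(data)
            if spec.name == "rkhs":
                cell["kernels"] = data.get("rkhs_kernels")
            try:
                if scheme == "random":
                    res = random_cv(y, X, cell, spec, seed=cell_seed, **cv_spec)
                elif scheme == "family":
                    res = family_cv(y, X, cell, spec, seed=cell_seed, **cv_spec)
                else:
                    raise ParameterError(f"unknown CV scheme {scheme!r}")
                rows.append(_sweep_row(bspec, spec, res, data["n_columns"]))
            except HapblockError as exc:
                rows.append(_sweep_row(bspec, spec, None, data["n_columns"], error=str(exc)))
    return pd.DataFrame(rows)


def _sweep_row(bspec, model, res, n_predictors: int, error: str | None = None) -> dict:
    name = model.name if isinstance(model, ModelSpec) else str(model)
    return {
        "block_method": bspec.get("method"),
        "param": bspec.get("param"),
        "model": name,
        "mean_r": res.mean if res else float("nan"),
        "sd_r": res.sd if res else float("nan"),
        "n_runs": res.n_runs if res else 0,
        "n_failed": res.n_failed if res else 0,
        "n_effective_predictors": n_predictors,
        "error": error or "",
    }
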