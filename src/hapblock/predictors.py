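"""Genomic prediction models.

Frequentist: GBLUP and EGBLUP fitted by REML — a spectral shortcut (one
eigendecomposition, 1-D profile likelihood) for a single kernel, and bounded
derivative-free optimization over log-variances with Cholesky likelihoods for
multiple kernels.

Bayesian: a Gibbs sampler for the Bayesian LASSO (exponential-mixture
representation of the double-exponential prior on marker/haplotype effects)
and an RKHS kernel-averaging sampler with one random effect per kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .errors import ModelFitError, ParameterError, ValidationError
from .kinship import KernelMatrix, epistatic_grm

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-10


@dataclass
class MixedModelFit:
    beta: np.ndarray
    variance_components: dict  # {"k0": sa2, ..., "residual": se2}
    blups: list  # per-kernel BLUP vectors on the training samples
    reml_loglik: float
    alpha: list  # per-kernel weights: sigma_k^2 * Vinv @ (y - X beta)
    fitted: np.ndarray
    kernels: list = field(default_factory=list)

    @property
    def h2(self) -> float:
        """Genomic heritability: per-kernel variances are weighted by the
        mean kernel diagonal (about 2 for fully inbred panels under the
        VanRaden scaling), so the ratio matches var(g)/var(y) in simulation."""
        names = [k for k in self.variance_components if k != "residual"]
        scales = [
            float(np.mean(np.diag(K.values))) if K is not None else 1.0
            for K in (self.kernels or [None] * len(names))
        ]
        gvar = sum(self.variance_components[nm] * s for nm, s in zip(names, scales))
        return float(gvar / (gvar + self.variance_components["residual"]))


@dataclass
class McmcFit:
    model: str
    posterior_means: dict
    chain: dict
    predictor_state: dict = field(default_factory=dict)


def _validate_xy(y: np.ndarray, X: np.ndarray) -> tuple:
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValidationError("X rows do not match y")
    if not np.isfinite(y).all():
        raise ValidationError("y must be complete and finite")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelFitError("fixed-effect design X is rank deficient")
    return y, X


def reml_loglik(y: np.ndarray, X: np.ndarray, kernel_values: list, variances: np.ndarray):
    """Restricted log-likelihood of y ~ N(Xb, sum_k s2_k G_k + s2_e I).

    ``variances`` holds the kernel variances followed by the residual
    variance. Returns ``(loglik, beta, Vinv_resid)``.
    """
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    V = variances[-1] * np.eye(n)
    for s2, G in zip(variances[:-1], kernel_values):
        V += s2 * G
    try:
        c, low = cho_factor(V)
    except np.linalg.LinAlgError as exc:
        raise ModelFitError(f"V not positive definite: {exc}") from exc
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    VinvX = cho_solve((c, low), X)
    Vinvy = cho_solve((c, low), y)
    XtVinvX = X.T @ VinvX
    sign, logdetXtVinvX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        raise ModelFitError("X' V^-1 X not positive definite")
    beta = np.linalg.solve(XtVinvX, X.T @ Vinvy)
    resid = y - X @ beta
    Vinv_resid = Vinvy - VinvX @ beta
    quad = float(resid @ Vinv_resid)
    _, logdetXtX = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        (n - p) * np.log(2.0 * np.pi) + logdetV + logdetXtVinvX - logdetXtX + quad
    )
    return float(ll), beta, Vinv_resid


def _fit_single_kernel_spectral(y, X, G):
    """Profile REML over the variance ratio via one eigendecomposition."""
    n, p = X.shape
    w, U = np.linalg.eigh(G)
    if w[0] < -1e-6 * max(w[-1], 1.0):
        raise ModelFitError(f"kernel not PSD (min eigenvalue {w[0]:.3e})")
    w = np.maximum(w, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log_lam):
        lam = np.exp(log_lam)
        d = lam * w + 1.0
        XtWX = (Xt / d[:, None]).T @ Xt
        try:
            beta = np.linalg.solve(XtWX, (Xt / d[:, None]).T @ yt)
        except np.linalg.LinAlgError:
            return 1e30
        r = yt - Xt @ beta
        quad = float(np.sum(r * r / d))
        se2 = quad / (n - p)
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0 or se2 <= 0:
            return 1e30
        ll = -0.5 * ((n - p) * (np.log(2 * np.pi * se2) + 1.0) + np.sum(np.log(d)) + logdetXtWX)
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-14.0, 14.0), method="bounded")
    lam = float(np.exp(res.x))
    d = lam * w + 1.0
    XtWX = (Xt / d[:, None]).T @ Xt
    beta = np.linalg.solve(XtWX, (Xt / d[:, None]).T @ yt)
    r = yt - Xt @ beta
    se2 = float(np.sum(r * r / d) / (n - p))
    sg2 = lam * se2
    return np.array([max(sg2, _VAR_FLOOR), max(se2, _VAR_FLOOR)])


def fit_gblup(
    y,
    X,
    kernels: list,
    fixed_variances: dict | None = None,
) -> MixedModelFit:
    """REML fit of y = Xb + sum_k u_k + e with u_k ~ N(0, G_k s2_k).

    ``fixed_variances`` optionally pins kernel variances (index -> value),
    e.g. to drop an epistatic term from an EGBLUP fit.
    """
    y, X = _validate_xy(y, X)
    if not kernels:
        raise ParameterError("at least one kernel required")
    kv = []
    for K in kernels:
        K.check_psd()
        if K.n != len(y):
            raise ValidationError("kernel size does not match y")
        kv.append(K.jittered())
    nk = len(kv)
    fixed_variances = fixed_variances or {}

    if nk == 1 and not fixed_variances:
        variances = _fit_single_kernel_spectral(y, X, kv[0])
    else:
        variances = _fit_multi_kernel(y, X, kv, fixed_variances)

    ll, beta, Vinv_resid = reml_loglik(y, X, kv, variances)
    alpha = [variances[k] * Vinv_resid for k in range(nk)]
    blups = [kv[k] @ alpha[k] for k in range(nk)]
    fitted = X @ beta + np.sum(blups, axis=0)
    vc = {f"k{k}": float(variances[k]) for k in range(nk)}
    vc["residual"] = float(variances[-1])
    return MixedModelFit(beta, vc, blups, ll, alpha, fitted, kernels=kernels)


def _fit_multi_kernel(y, X, kv, fixed_variances):
    n = len(y)
    nk = len(kv)
    vy = float(np.var(y)) or 1.0
    free = [k for k in range(nk) if k not in fixed_variances]

    def unpack(theta):
        variances = np.empty(nk + 1)
        for k, v in fixed_variances.items():
            variances[k] = max(v, _VAR_FLOOR)
        for t, k in zip(theta[:-1], free):
            variances[k] = np.exp(t)
        variances[-1] = np.exp(theta[-1])
        return variances

    def objective(theta):
        variances = unpack(theta)
        try:
            ll, _, _ = reml_loglik(y, X, kv, variances)
        except ModelFitError:
            return 1e30
        return -ll

    start = np.log(np.full(len(free) + 1, vy / (len(free) + 1)))
    best = None
    for scale in (1.0, 0.2):
        res = optimize.minimize(
            objective,
            start * scale if scale != 1.0 else start,
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = np.clip(best.x, np.log(_VAR_FLOOR), 20.0)
    return unpack(theta)


def fit_egblup(y, X, G: KernelMatrix, fixed_aa: float | None = None) -> MixedModelFit:
    """GBLUP extended with the additive-by-additive kernel G # G."""
    kernels = [G, epistatic_grm(G)]
    fixed = {1: fixed_aa} if fixed_aa is not None else None
    return fit_gblup(y, X, kernels, fixed_variances=fixed)


def predict(fit: MixedModelFit, kernel_cross: list, X_new) -> np.ndarray:
    """BLUP prediction for new samples.

    ``kernel_cross[k]`` holds G_k(new, train); the prediction is
    X_new beta + sum_k G_k(new, train) alpha_k with the training-time
    alpha_k = s2_k V^-1 (y - X beta).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != len(fit.beta):
        raise ValidationError("X_new column count does not match the fit")
    if len(kernel_cross) != len(fit.alpha):
        raise ValidationError("one cross-kernel block per fitted kernel required")
    yhat = X_new @ fit.beta
    for Kc, a in zip(kernel_cross, fit.alpha):
        Kc = np.asarray(Kc, dtype=float)
        if Kc.shape != (X_new.shape[0], len(a)):
            raise ValidationError("cross-kernel block has wrong shape")
        yhat = yhat + Kc @ a
    return yhat


# ---------------------------------------------------------------------------
# MCMC

MCMC_DEFAULTS = {"n_iter": 6000, "burn_in": 1000, "thin": 5}
# weakly informative hyperpriors, recorded in every fit's chain metadata
LASSO_LAMBDA2_SHAPE = 1.0
LASSO_LAMBDA2_RATE = 0.1
DF0 = 5.0


def _check_chain(n_iter, burn_in, thin):
    if n_iter <= burn_in:
        raise ParameterError("n_iter must exceed burn_in")
    if thin < 1:
        raise ParameterError("thin must be >= 1")


def _sample_beta(rng, XtX_chol, XtX, X, target, sigma2):
    """beta | rest under a flat prior: N((X'X)^-1 X' target, s2 (X'X)^-1)."""
    mean = cho_solve(XtX_chol, X.T @ target)
    z = rng.standard_normal(X.shape[1])
    L = np.linalg.cholesky(np.linalg.inv(XtX) * sigma2)
    return mean + L @ z


def fit_bayesian_lasso(
    y,
    X,
    M,
    n_iter: int = MCMC_DEFAULTS["n_iter"],
    burn_in: int = MCMC_DEFAULTS["burn_in"],
    thin: int = MCMC_DEFAULTS["thin"],
    seed: int = 0,
) -> McmcFit:
    """Gibbs sampler for the Bayesian LASSO (Park & Casella parameterization).

    Effects f_j ~ N(0, s2 tau_j^2) with tau_j^2 ~ Exp(lambda^2 / 2) marginally
    giving the double-exponential prior; flat priors on the fixed effects.
    ``M`` carries marker/haplotype profiles coded 0, 1, 2.
    """
    _check_chain(n_iter, burn_in, thin)
    y, X = _validate_xy(y, X)
    M = np.asarray(M, dtype=float)
    if M.shape[0] != len(y):
        raise ValidationError("M rows do not match y")
    n, m = M.shape
    rng = np.random.default_rng(seed)

    XtX = X.T @ X
    XtX_chol = cho_factor(XtX)
    col_ss = np.sum(M * M, axis=0)
    vy = float(np.var(y)) or 1.0
    S0 = vy * 0.5 * (DF0 + 2.0)  # scaled-inv-chi2 prior mode near vy/2

    beta = np.linalg.solve(XtX, X.T @ y)
    f = np.zeros(m)
    tau2 = np.ones(m)
    sigma2 = vy / 2.0
    lambda2 = max(m / 2.0, 1.0)
    e = y - X @ beta

    keep_beta = np.zeros_like(beta)
    keep_f = np.zeros(m)
    keep_s2 = 0.0
    keep_l2 = 0.0
    keep_g = np.zeros(n)
    n_kept = 0

    for it in range(n_iter):
        # marker effects, coordinate-wise with residual updates
        for j in range(m):
            if col_ss[j] == 0.0:
                f[j] = 0.0
                continue
            e += M[:, j] * f[j]
            prec = col_ss[j] + 1.0 / tau2[j]
            mean = (M[:, j] @ e) / prec
            f[j] = mean + rng.standard_normal() * np.sqrt(sigma2 / prec)
            e -= M[:, j] * f[j]
        # tau_j^2 via inverse-Gaussian draw of 1/tau_j^2
        fj2 = np.maximum(f * f, 1e-12)
        mu = np.sqrt(lambda2 * sigma2 / fj2)
        inv_tau2 = rng.wald(np.minimum(mu, 1e8), lambda2)
        tau2 = 1.0 / np.maximum(inv_tau2, 1e-12)
        # fixed effects
        target = e + X @ beta
        new_beta = _sample_beta(rng, XtX_chol, XtX, X, target, sigma2)
        e = target - X @ new_beta
        beta = new_beta
        # residual variance (scaled-inv-chi2)
        active = col_ss > 0
        ss = float(e @ e) + float(np.sum(f[active] ** 2 / tau2[active])) + DF0 * S0
        dfree = n + int(active.sum()) + DF0
        sigma2 = ss / rng.chisquare(dfree)
        # shrinkage hyperparameter
        lambda2 = rng.gamma(
            m + LASSO_LAMBDA2_SHAPE, 1.0 / (np.sum(tau2) / 2.0 + LASSO_LAMBDA2_RATE)
        )
        if not (np.isfinite(sigma2) and np.isfinite(f).all()):
            raise ModelFitError(f"Bayesian LASSO chain diverged at iteration {it}")
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_beta += beta
            keep_f += f
            keep_s2 += sigma2
            keep_l2 += lambda2
            keep_g += M @ f
            n_kept += 1

    post = {
        "beta": keep_beta / n_kept,
        "effects": keep_f / n_kept,
        "sigma2_e": keep_s2 / n_kept,
        "lambda2": keep_l2 / n_kept,
        "genetic_values": keep_g / n_kept,
    }
    chain = {
        "n_iter": n_iter,
        "burn_in": burn_in,
        "thin": thin,
        "seed": seed,
        "n_kept": n_kept,
        "lambda2_hyperprior": (LASSO_LAMBDA2_SHAPE, LASSO_LAMBDA2_RATE),
    }
    return McmcFit("bayesian_lasso", post, chain)


def predict_lasso(fit: McmcFit, M_new, X_new) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    return X_new @ fit.posterior_means["beta"] + np.asarray(M_new, float) @ fit.posterior_means["effects"]


def fit_rkhs(
    y,
    X,
    kernels: list,
    n_iter: int = MCMC_DEFAULTS["n_iter"],
    burn_in: int = MCMC_DEFAULTS["burn_in"],
    thin: int = MCMC_DEFAULTS["thin"],
    seed: int = 0,
) -> McmcFit:
    """Gibbs sampler for RKHS regression with kernel averaging.

    One random effect u_l ~ N(0, K_l s2_l) per kernel; each kernel is
    eigendecomposed once and the u_l update reduces to a diagonal Gaussian in
    the eigenbasis.  Kernel weights emerge through the sampled variances.
    """
    _check_chain(n_iter, burn_in, thin)
    y, X = _validate_xy(y, X)
    if not kernels:
        raise ParameterError("at least one kernel required")
    n = len(y)
    rng = np.random.default_rng(seed)
    eig = []
    for K in kernels:
        K.check_psd()
        if K.n != n:
            raise ValidationError("kernel size does not match y")
        w, U = np.linalg.eigh(K.jittered())
        keep = w > max(1e-10, 1e-8 * w[-1])
        eig.append((w[keep], U[:, keep]))

    XtX = X.T @ X
    XtX_chol = cho_factor(XtX)
    vy = float(np.var(y)) or 1.0
    L = len(kernels)
    S0_u = vy * 0.5 / L * (DF0 + 2.0)
    S0_e = vy * 0.5 * (DF0 + 2.0)

    beta = np.linalg.solve(XtX, X.T @ y)
    b = [np.zeros(len(w)) for w, _ in eig]
    u = [np.zeros(n) for _ in range(L)]
    s2u = [vy / (2.0 * L)] * L
    sigma2 = vy / 2.0
    e = y - X @ beta

    keep_beta = np.zeros_like(beta)
    keep_g = np.zeros(n)
    keep_alpha = [np.zeros(n) for _ in range(L)]
    keep_s2u = [0.0] * L
    keep_s2e = 0.0
    n_kept = 0

    for it in range(n_iter):
        for l in range(L):
            w, U = eig[l]
            r = e + u[l]
            var = 1.0 / (1.0 / sigma2 + 1.0 / (w * s2u[l]))
            mean = var * (U.T @ r) / sigma2
            b[l] = mean + rng.standard_normal(len(w)) * np.sqrt(var)
            u[l] = U @ b[l]
            e = r - u[l]
            ss = float(np.sum(b[l] * b[l] / w)) + DF0 * S0_u
            s2u[l] = ss / rng.chisquare(len(w) + DF0)
        target = e + X @ beta
        new_beta = _sample_beta(rng, XtX_chol, XtX, X, target, sigma2)
        e = target - X @ new_beta
        beta = new_beta
        sigma2 = (float(e @ e) + DF0 * S0_e) / rng.chisquare(n + DF0)
        if not np.isfinite(sigma2):
            raise ModelFitError(f"RKHS chain diverged at iteration {it}")
        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_beta += beta
            keep_g += np.sum(u, axis=0)
            for l in range(L):
                w, U = eig[l]
                keep_alpha[l] += U @ (b[l] / w)
                keep_s2u[l] += s2u[l]
            keep_s2e += sigma2
            n_kept += 1

    post = {
        "beta": keep_beta / n_kept,
        "genetic_values": keep_g / n_kept,
        "kernel_variances": [s / n_kept for s in keep_s2u],
        "sigma2_e": keep_s2e / n_kept,
    }
    state = {"alpha": [a / n_kept for a in keep_alpha]}
    chain = {"n_iter": n_iter, "burn_in": burn_in, "thin": thin, "seed": seed, "n_kept": n_kept}
    return McmcFit("rkhs", post, chain, predictor_state=state)


def predict_rkhs(fit: McmcFit, kernel_cross: list, X_new) -> np.ndarray:
    """Extend posterior-mean kernel effects to new samples:
    yhat = X_new beta + sum_l K_l(new, train) alpha_l with alpha_l the
    posterior mean of K_l^- u_l."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    yhat = X_new @ fit.posterior_means["beta"]
    for Kc, a in zip(kernel_cross, fit.predictor_state["alpha"]):
        yhat = yhat + np.asarray(Kc, float) @ a
    return yhat
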