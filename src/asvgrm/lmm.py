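"""Single-kernel linear mixed model: REML variance components and GBLUP.

Model: ``y = 1 mu + g + e`` with ``g ~ N(0, K sigma_g^2)`` and
``e ~ N(0, I sigma_e^2)``, where ``y`` holds entry means (LSMs) and ``K`` is
any genomic relationship matrix.  REML works on an orthonormal basis of the
contrast space orthogonal to the intercept (Helmert contrasts ``A`` with
``A A' = I`` and ``A 1 = 0``); there the restricted likelihood is the exact
Gaussian likelihood of ``A y ~ N(0, A V A')`` with ``V = K sigma_g^2 +
I sigma_e^2``.

:func:`fit_reml` profiles the restricted likelihood over the variance ratio
``lambda = sigma_g^2 / sigma_e^2`` after a single eigendecomposition of the
contrast-projected kernel, scanning ``log10 lambda`` on [-10, 10] and
polishing with bounded scalar minimization; ``sigma_e^2`` is then closed
form.  :func:`restricted_loglik` evaluates the same criterion at arbitrary
``(sigma_g^2, sigma_e^2)`` through a Cholesky factorization and serves as
the oracle surface for brute-force checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, helmert
from scipy.optimize import minimize_scalar

from .grm import RelationshipMatrix

__all__ = [
    "PhenotypeVector",
    "VarianceComponents",
    "BLUPResult",
    "restricted_loglik",
    "fit_reml",
    "gblup",
    "predict_heldout",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_LOG10_LAMBDA_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class PhenotypeVector:
    """Entry-mean phenotypes (LSMs) with entry labels."""

    values: np.ndarray
    entry_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("phenotypes must be a 1-D vector")
        if len(self.entry_ids) != v.size:
            raise ValueError("entry_ids length does not match phenotype length")
        if len(set(self.entry_ids)) != v.size:
            raise ValueError("entry_ids are not unique")
        if not np.all(np.isfinite(v)):
            raise ValueError("phenotypes contain non-finite values")

    def reindex(self, ids: Sequence[str]) -> "PhenotypeVector":
        """Reorder to the given entry ids; error listing any missing ids."""
        pos = {e: i for i, e in enumerate(self.entry_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"phenotypes missing for entries: {missing}")
        idx = [pos[i] for i in ids]
        return PhenotypeVector(self.values[idx], tuple(ids))


@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates of (sigma_g^2, sigma_e^2) and fit metadata.

    ``lambda_`` is the variance ratio sigma_g^2 / sigma_e^2; ``boundary``
    flags an optimum at the edge of the log10-lambda search interval.
    ``grm_method`` records which GRM the fit used, so downstream trace
    adjustments can check provenance.
    """

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    lambda_: float
    converged: bool
    n_iter: int
    grm_method: str | None = None
    boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "sigma_g2": self.sigma_g2,
            "sigma_e2": self.sigma_e2,
            "lambda": self.lambda_,
            "reml_loglik": self.reml_loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "method_tag": self.grm_method,
        }


@dataclass(frozen=True)
class BLUPResult:
    """Intercept estimate, predicted genetic values, and their PEV.

    ``reliability`` is the selection reliability ``1 - PEV / sigma_g^2``
    (zero when sigma_g^2 = 0).
    """

    mu_hat: float
    g_hat: np.ndarray
    pev: np.ndarray
    entry_ids: tuple[str, ...]
    reliability: np.ndarray


def _check_alignment(y: PhenotypeVector, K: RelationshipMatrix) -> None:
    if y.entry_ids != K.entry_ids:
        raise ValueError("phenotype and relationship-matrix entry ids do not align")


def _contrasts(n: int) -> np.ndarray:
    # (n-1) x n orthonormal rows, each orthogonal to the ones vector
    return helmert(n, full=False)


def restricted_loglik(
    y: PhenotypeVector,
    K: RelationshipMatrix,
    sigma_g2: float,
    sigma_e2: float,
) -> float:
    """Restricted log-likelihood of y under the intercept-only LMM.

    Contrast-space evaluation: with orthonormal contrasts A (A 1 = 0),
    ``l_R = -1/2 [(n-1) log 2 pi + log|A V A'| + (Ay)' (A V A')^-1 (Ay)]``.
    Deterministic; raises a numerical error with a condition report when
    the projected V is not positive definite.
    """
    if sigma_e2 <= 0.0 or sigma_g2 < 0.0:
        raise ValueError("need sigma_e2 > 0 and sigma_g2 >= 0")
    _check_alignment(y, K)
    n = K.n
    A = _contrasts(n)
    S = sigma_g2 * (A @ K.values @ A.T) + sigma_e2 * np.eye(n - 1)
    try:
        cf = cho_factor((S + S.T) / 2.0, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond((S + S.T) / 2.0)
        raise np.linalg.LinAlgError(
            f"projected V is not positive definite (condition number {cond:.3g})"
        ) from exc
    z = A @ y.values
    quad = float(z @ cho_solve(cf, z))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * ((n - 1) * _LOG2PI + logdet + quad)


def fit_reml(
    y: PhenotypeVector,
    K: RelationshipMatrix,
    n_grid: int = 201,
    tol: float = 1e-10,
) -> VarianceComponents:
    """Profile-REML fit of (sigma_g^2, sigma_e^2) for one GRM kernel.

    Spectral route: eigendecompose the contrast-projected kernel once, then
    maximize the profile restricted likelihood in log10 lambda on [-10, 10]
    (coarse scan of ``n_grid`` points, then bounded polish to ``tol`` in
    log-lambda); sigma_e^2 follows in closed form.  Kernels that are
    indefinite beyond round-off receive a diagonal jitter of
    1e-8 x mean diagonal, with a warning.
    """
    _check_alignment(y, K)
    n = K.n
    if n < 3:
        raise ValueError("need n >= 3 entries for REML")
    var_y = float(np.var(y.values, ddof=1))
    floor = 1e-10 * var_y if var_y > 0 else 1e-10

    if var_y == 0.0:
        warnings.warn("zero phenotypic variance; variance components at floor", stacklevel=2)
        return VarianceComponents(floor, floor, np.nan, 1.0, True, 0, K.method)

    off = K.values - np.diag(np.diag(K.values))
    diag_scale = max(np.abs(np.diag(K.values)).max(), np.finfo(float).tiny)
    if np.abs(off).max() < 1e-10 * diag_scale:
        warnings.warn(
            "K is (numerically) a multiple of the identity; sigma_g2 and sigma_e2 "
            "are not separately identifiable",
            stacklevel=2,
        )

    A = _contrasts(n)
    Ks = A @ K.values @ A.T
    d, U = np.linalg.eigh((Ks + Ks.T) / 2.0)
    dmax = max(d.max(), 0.0)
    if d.min() < -1e-8 * max(dmax, np.finfo(float).tiny):
        jitter = 1e-8 * float(np.mean(np.diag(K.values)))
        warnings.warn(
            f"K is not PSD (min contrast eigenvalue {d.min():.3g}); "
            f"adding diagonal jitter {jitter:.3g}",
            stacklevel=2,
        )
        d = d + jitter
    d = np.maximum(d, 0.0)
    yt = U.T @ (A @ y.values)
    yt2 = yt**2
    n1 = n - 1

    def profile_negloglik(x: float) -> float:
        lam = 10.0**x
        w = lam * d + 1.0
        s2e = max(float(np.mean(yt2 / w)), floor)
        ll = -0.5 * (n1 * _LOG2PI + float(np.log(w).sum()) + n1 * np.log(s2e) + n1)
        return -ll

    lo, hi = _LOG10_LAMBDA_BOUNDS
    xs = np.linspace(lo, hi, n_grid)
    vals = np.array([profile_negloglik(x) for x in xs])
    i = int(np.argmin(vals))
    span = xs[1] - xs[0]
    a, b = max(lo, xs[i] - span), min(hi, xs[i] + span)
    res = minimize_scalar(
        profile_negloglik, bounds=(a, b), method="bounded", options={"xatol": tol}
    )
    x_hat = float(res.x)
    # also consider the scan endpoints (sigma_g2 effectively 0 or huge)
    cands = [(profile_negloglik(lo), lo), (profile_negloglik(hi), hi), (res.fun, x_hat)]
    fbest, x_hat = min(cands, key=lambda t: t[0])

    lam = 10.0**x_hat
    w = lam * d + 1.0
    sigma_e2 = max(float(np.mean(yt2 / w)), floor)
    sigma_g2 = lam * sigma_e2
    boundary = x_hat <= lo + 10 * tol or x_hat >= hi - 10 * tol
    return VarianceComponents(
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        reml_loglik=float(-fbest),
        lambda_=float(lam),
        converged=bool(res.success),
        n_iter=int(res.nfev) + n_grid,
        grm_method=K.method,
        boundary=bool(boundary),
    )


def _v_factor(K: np.ndarray, vc: VarianceComponents):
    n = K.shape[0]
    V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(n)
    try:
        return cho_factor((V + V.T) / 2.0, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"V is not positive definite (condition number {cond:.3g})"
        ) from exc


def gblup(
    y: PhenotypeVector, K: RelationshipMatrix, vc: VarianceComponents
) -> BLUPResult:
    """BLUPs of genetic values for the observed entries.

    GLS intercept ``mu = (1'V^-1 1)^-1 1'V^-1 y``, predictions
    ``g_hat = sigma_g^2 K V^-1 (y - 1 mu)``, and PEV from the mixed-model
    conditional variance ``diag(G - G P G)`` with
    ``P = V^-1 - V^-1 1 (1'V^-1 1)^-1 1'V^-1`` and ``G = K sigma_g^2``.
    """
    _check_alignment(y, K)
    n = K.n
    cf = _v_factor(K.values, vc)
    ones = np.ones(n)
    Vi1 = cho_solve(cf, ones)
    denom = float(ones @ Vi1)
    mu = float(Vi1 @ y.values) / denom
    r = y.values - mu
    G = vc.sigma_g2 * K.values
    g_hat = G @ cho_solve(cf, r)
    ViG = cho_solve(cf, G)
    PG = ViG - np.outer(Vi1, (Vi1 @ G)) / denom
    pev = np.diag(G) - np.einsum("ij,ji->i", G, PG)
    pev = np.maximum(pev, 0.0)
    if vc.sigma_g2 > 0:
        reliability = 1.0 - pev / vc.sigma_g2
    else:
        reliability = np.zeros(n)
    return BLUPResult(mu, g_hat, pev, K.entry_ids, reliability)


def predict_heldout(
    y_train: PhenotypeVector,
    K_full: RelationshipMatrix,
    train_ids: Sequence[str],
    vc: VarianceComponents,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Predict genetic values of entries not in ``train_ids``.

    ``g_test = sigma_g^2 K[test, train] V_train^-1 (y_train - 1 mu)`` with
    the GLS intercept from the training block.  Returns (predictions,
    test entry ids in K_full order).
    """
    train_ids = list(train_ids)
    pos = {e: i for i, e in enumerate(K_full.entry_ids)}
    missing = [t for t in train_ids if t not in pos]
    if missing:
        raise KeyError(f"train ids not present in K: {missing}")
    tr_idx = [pos[t] for t in train_ids]
    te_ids = tuple(e for e in K_full.entry_ids if e not in set(train_ids))
    if not te_ids:
        raise ValueError("test set is empty")
    te_idx = [pos[t] for t in te_ids]

    yv = y_train.reindex(train_ids).values
    Ktr = K_full.values[np.ix_(tr_idx, tr_idx)]
    cf = _v_factor(Ktr, vc)
    ones = np.ones(len(tr_idx))
    Vi1 = cho_solve(cf, ones)
    mu = float(Vi1 @ yv) / float(ones @ Vi1)
    alpha = cho_solve(cf, yv - mu)
    g_test = vc.sigma_g2 * (K_full.values[np.ix_(te_idx, tr_idx)] @ alpha)
    return g_test, te_ids
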