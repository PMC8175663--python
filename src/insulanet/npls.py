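"""Partial least squares (PLS) and N-way PLS fitters.

PLS finds unit-norm weight vectors ``w_x`` (brain) and ``w_y`` (behavior)
whose latent scores ``c_x = w_x' x_s`` and ``c_y = w_y' y_s`` have maximal
sample covariance.  N-way PLS generalizes this to matrix-valued brain data
(one V1 x V2 matrix per subject, e.g. a seed-by-target connectivity
submatrix): it finds a weight vector per matrix mode, ``w_x1`` (V1, the seed
salience) and ``w_x2`` (V2, the whole-brain salience), maximizing
``cov(w_x1' X_s w_x2, y_s' w_y)`` subject to all weights having unit norm.
Successive components are constrained orthogonal to earlier weight vectors.

The trilinear problem is solved by alternating least squares (ALS); for a
single behavioral column the global optimum is the leading singular pair of
the contracted cross-covariance ``M = sum_s y~_s X~_s / (S - 1)``, which
serves as an independent oracle in the test suite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "NPLSModel",
    "PLSComponent",
    "NPLSComponent",
    "fit_pls",
    "fit_npls",
    "project_scores",
]


class DegenerateModelWarning(UserWarning):
    """Raised when the cross-covariance is numerically zero."""


@dataclass
class PLSComponent:
    w_x: np.ndarray          # unit V-vector of voxel/feature saliences
    w_y: np.ndarray          # unit B-vector
    c_x: np.ndarray          # S latent brain scores ("diffusivity scores" for DTI use)
    c_y: np.ndarray          # S latent behavior scores
    cov_value: float
    degenerate: bool = False


@dataclass
class PLSModel:
    components: list[PLSComponent]
    x_mean: np.ndarray
    y_mean: np.ndarray
    center: bool = True

    # convenience accessors for the (most common) first component
    @property
    def w_x(self) -> np.ndarray:
        return self.components[0].w_x

    @property
    def w_y(self) -> np.ndarray:
        return self.components[0].w_y

    @property
    def c_x(self) -> np.ndarray:
        return self.components[0].c_x

    @property
    def cov_value(self) -> float:
        return self.components[0].cov_value

    def to_json(self) -> str:
        return json.dumps(_model_dict(self), indent=2)


@dataclass
class NPLSComponent:
    w_x1: np.ndarray         # unit V1-vector (seed-mode salience)
    w_x2: np.ndarray         # unit V2-vector (whole-brain salience)
    w_y: np.ndarray          # unit B-vector
    c_x: np.ndarray          # S network expression scores  w_x1' X~_s w_x2
    c_y: np.ndarray
    cov_value: float
    n_iter: int = 0
    converged: bool = True
    degenerate: bool = False


@dataclass
class NPLSModel:
    components: list[NPLSComponent]
    x_mean: np.ndarray       # V1 x V2 per-entry mean over subjects
    y_mean: np.ndarray
    center: bool = True
    tol: float = 1e-10
    max_iter: int = 500
    cov_trace: list[np.ndarray] = field(default_factory=list)

    @property
    def w_x1(self) -> np.ndarray:
        return self.components[0].w_x1

    @property
    def w_x2(self) -> np.ndarray:
        return self.components[0].w_x2

    @property
    def c_x(self) -> np.ndarray:
        return self.components[0].c_x

    @property
    def cov_value(self) -> float:
        return self.components[0].cov_value

    def to_json(self) -> str:
        return json.dumps(_model_dict(self), indent=2)


def _model_dict(model) -> dict:
    out = {"center": model.center, "x_mean": model.x_mean.tolist(),
           "y_mean": model.y_mean.tolist(), "components": []}
    for c in model.components:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in vars(c).items()}
        out["components"].append(d)
    return out


def _as_2d_y(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.ndim != 2:
        raise ValueError("Y must be an S-vector or an S x B matrix")
    return Y


def _validate_finite(name: str, a: np.ndarray) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")


def _sample_cov(a: np.ndarray, b: np.ndarray) -> float:
    n = len(a)
    return float(np.dot(a - a.mean(), b - b.mean()) / (n - 1))


def fit_pls(X: np.ndarray, Y: np.ndarray, K: int = 1, *, center: bool = True) -> PLSModel:
    """Fit a two-block PLS model by SVD of the cross-covariance.

    Parameters
    ----------
    X : (S, V) array of brain features (e.g. masked voxel values).
    Y : (S,) or (S, B) behavior block; a single +/-1 column yields the
        discriminant-PLS group contrast.
    K : number of latent components.

    Columns of X and Y are mean-centered (unless ``center=False``); for each
    component the weights are the leading singular pair of
    ``X~' Y~ / (S - 1)``, after which X is deflated by regression on the
    brain scores.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d_y(Y)
    _validate_finite("X", X)
    _validate_finite("Y", Y)
    S, V = X.shape
    if S < 3:
        raise ValueError("need at least 3 subjects")
    if Y.shape[0] != S:
        raise ValueError("X and Y subject counts differ")

    x_mean = X.mean(axis=0) if center else np.zeros(V)
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - x_mean
    Yc = Y - y_mean

    comps: list[PLSComponent] = []
    Xd = Xc.copy()
    for _ in range(K):
        C = Xd.T @ Yc / (S - 1)
        norm = np.linalg.norm(C)
        if norm < 1e-300 or not np.isfinite(norm):
            w_x = np.zeros(V)
            w_x[0] = 1.0
            w_y = np.zeros(Y.shape[1])
            w_y[0] = 1.0
            warnings.warn("zero cross-covariance; degenerate PLS component",
                          DegenerateModelWarning, stacklevel=2)
            comps.append(PLSComponent(w_x, w_y, Xd @ w_x, Yc @ w_y, 0.0, True))
            continue
        if Y.shape[1] == 1:
            w_y = np.ones(1)
            w_x = C[:, 0] / np.linalg.norm(C[:, 0])
        else:
            U, s, Vt = np.linalg.svd(C, full_matrices=False)
            w_x, w_y = U[:, 0], Vt[0]
        c_x = Xd @ w_x
        c_y = Yc @ w_y
        cov = _sample_cov(c_x, c_y)
        if cov < 0:
            w_x, c_x, cov = -w_x, -c_x, -cov
        comps.append(PLSComponent(w_x, w_y, c_x, c_y, cov))
        # deflate X by the rank-1 score regression
        denom = float(c_x @ c_x)
        if denom > 0:
            p = Xd.T @ c_x / denom
            Xd = Xd - np.outer(c_x, p)
    return PLSModel(comps, x_mean, y_mean, center)


def _init_wx2(Xc: np.ndarray, cy: np.ndarray,
              prev_w1: list[np.ndarray], prev_w2: list[np.ndarray]) -> np.ndarray:
    """Deterministic ALS start: top right-singular vector of the
    behavior-weighted contraction ``M0 = sum_s c_y(s) X~_s``, projected
    orthogonal to earlier components' weight vectors.  No RNG is involved,
    so repeated fits are bit-identical."""
    M0 = np.einsum("s,sij->ij", cy, Xc)
    for b in prev_w1:
        M0 -= np.outer(b, b @ M0)
    for b in prev_w2:
        M0 -= np.outer(M0 @ b, b)
    if not np.any(M0):
        return np.zeros(Xc.shape[2])
    _, _, Vt = np.linalg.svd(M0, full_matrices=False)
    return Vt[0]


def _orthogonalize(w: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        w = w - np.dot(w, b) * b
    return w


def fit_npls(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 1,
    *,
    tol: float = 1e-10,
    max_iter: int = 500,
    center: bool = True,
) -> NPLSModel:
    """Fit the trilinear N-way PLS model by alternating least squares.

    Parameters
    ----------
    X : (S, V1, V2) tensor; one brain matrix per subject (for insular
        connectivity, V1=12 seed parcels by V2=246 target parcels).
    Y : (S,) or (S, B) behavior block.
    K : number of latent components; later components' weight vectors are
        kept orthogonal (Gram-Schmidt within the ALS updates) to earlier
        ones.
    tol : relative change in cov(c_x, c_y) declaring convergence.

    Each ALS sweep updates ``w_x1 ~ sum_s c_y(s) X~_s w_x2`` (normalized),
    then symmetrically ``w_x2``, then ``w_y`` from the brain scores; the
    covariance is non-decreasing over sweeps.
    """
    X = np.asarray(X, dtype=float)
    Y = _as_2d_y(Y)
    _validate_finite("X", X)
    _validate_finite("Y", Y)
    if X.ndim != 3:
        raise ValueError("X must be an S x V1 x V2 tensor")
    S, V1, V2 = X.shape
    if S < 3:
        raise ValueError("need at least 3 subjects")
    if Y.shape[0] != S:
        raise ValueError("X and Y subject counts differ")

    x_mean = X.mean(axis=0) if center else np.zeros((V1, V2))
    y_mean = Y.mean(axis=0) if center else np.zeros(Y.shape[1])
    Xc = X - x_mean
    Yc = Y - y_mean
    B = Y.shape[1]

    comps: list[NPLSComponent] = []
    traces: list[np.ndarray] = []
    prev_w1: list[np.ndarray] = []
    prev_w2: list[np.ndarray] = []

    for _ in range(K):
        if np.max(np.abs(Xc)) < 1e-300 or np.max(np.abs(Yc)) < 1e-300:
            w1 = np.zeros(V1); w1[0] = 1.0
            w2 = np.zeros(V2); w2[0] = 1.0
            wy = np.zeros(B); wy[0] = 1.0
            warnings.warn("zero data block; degenerate NPLS component",
                          DegenerateModelWarning, stacklevel=2)
            comps.append(NPLSComponent(w1, w2, wy, np.zeros(S), Yc @ wy,
                                       0.0, 0, True, True))
            traces.append(np.zeros(1))
            prev_w1.append(w1)
            prev_w2.append(w2)
            continue

        wy = np.ones(B) / np.sqrt(B)
        cy = Yc @ wy
        w2 = _init_wx2(Xc, cy, prev_w1, prev_w2)
        w2 = _orthogonalize(w2, prev_w2)
        n2 = np.linalg.norm(w2)
        if n2 < 1e-8:   # start exhausted by orthogonality constraint
            w2 = _fresh_direction(V2, prev_w2)
        else:
            w2 = w2 / n2
        cov_prev = -np.inf
        trace = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # mode-1 update: w_x1 proportional to sum_s c_y(s) X~_s w_x2
            w1 = np.einsum("s,sij,j->i", cy, Xc, w2)
            w1 = _orthogonalize(w1, prev_w1)
            n1 = np.linalg.norm(w1)
            if n1 < 1e-300:
                break
            w1 = w1 / n1
            # mode-2 update
            w2 = np.einsum("s,sij,i->j", cy, Xc, w1)
            w2 = _orthogonalize(w2, prev_w2)
            n2 = np.linalg.norm(w2)
            if n2 < 1e-300:
                break
            w2 = w2 / n2
            cx = np.einsum("i,sij,j->s", w1, Xc, w2)
            if B > 1:
                wy = Yc.T @ (cx - cx.mean())
                ny = np.linalg.norm(wy)
                if ny < 1e-300:
                    break
                wy = wy / ny
                cy = Yc @ wy
            cov = _sample_cov(cx, cy)
            trace.append(abs(cov))
            if abs(cov) < 1e-300:
                break
            if abs(cov - cov_prev) <= tol * max(abs(cov), 1e-300):
                converged = True
                break
            cov_prev = cov
        else:  # pragma: no cover - loop exits via break or exhaustion
            pass

        if not trace or trace[-1] < 1e-300:
            w1 = np.zeros(V1); w1[0] = 1.0
            w2 = np.zeros(V2); w2[0] = 1.0
            wy = np.zeros(B); wy[0] = 1.0
            comps.append(NPLSComponent(w1, w2, wy, np.zeros(S), Yc @ wy,
                                       0.0, n_iter, True, True))
            traces.append(np.asarray(trace if trace else [0.0]))
            prev_w1.append(w1)
            prev_w2.append(w2)
            continue

        if not converged:
            warnings.warn(f"NPLS ALS did not converge in {max_iter} iterations",
                          UserWarning, stacklevel=2)
        cx = np.einsum("i,sij,j->s", w1, Xc, w2)
        cy = Yc @ wy
        cov = _sample_cov(cx, cy)
        # sign convention: cov >= 0, then largest-|.| entry of w_x2 positive
        if cov < 0:
            w1, cx, cov = -w1, -cx, -cov
        peak = np.argmax(np.abs(w2))
        if w2[peak] < 0:
            w1, w2 = -w1, -w2          # joint flip preserves c_x and cov
        cx = np.einsum("i,sij,j->s", w1, Xc, w2)
        comps.append(NPLSComponent(w1, w2, wy, cx, cy, cov, n_iter, converged))
        traces.append(np.asarray(trace))
        prev_w1.append(w1)
        prev_w2.append(w2)

    return NPLSModel(comps, x_mean, y_mean, center, tol, max_iter, traces)


def _fresh_direction(dim: int, basis: list[np.ndarray]) -> np.ndarray:
    for i in range(dim):
        e = np.zeros(dim)
        e[i] = 1.0
        e = _orthogonalize(e, basis)
        n = np.linalg.norm(e)
        if n > 1e-8:
            return e / n
    raise RuntimeError("weight space exhausted")


def project_scores(model, X_new: np.ndarray, component: int = 0) -> np.ndarray:
    """Project new subjects onto a fitted component.

    Applies the model's stored centering, then ``c = w_x1' X~ w_x2`` for
    NPLS models or ``c = w_x' x~`` for PLS models.  Projecting the training
    data reproduces the training scores.
    """
    X_new = np.asarray(X_new, dtype=float)
    comp = model.components[component]
    if isinstance(model, NPLSModel):
        single = X_new.ndim == 2
        if single:
            X_new = X_new[None]
        if X_new.shape[1:] != model.x_mean.shape:
            raise ValueError("X_new dimensions do not match the fitted model")
        Xc = X_new - model.x_mean
        out = np.einsum("i,sij,j->s", comp.w_x1, Xc, comp.w_x2)
        return out[0] if single else out
    single = X_new.ndim == 1
    if single:
        X_new = X_new[None]
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError("X_new dimensions do not match the fitted model")
    out = (X_new - model.x_mean) @ comp.w_x
    return out[0] if single else out
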