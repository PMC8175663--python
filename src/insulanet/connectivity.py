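"""Parcel connectivity: correlation matrices from parcel time series,
extraction of the insula-to-whole-brain submatrix stack, and multivariate
outlier screening.

The parcellation is a 246-parcel whole-brain atlas whose 12 insular
subregions (hypergranular G, dorsal granular dIg, dorsal dysgranular dId,
dorsal agranular dIa, ventral dysgranular/granular vId/vIg, ventral
agranular vIa; left and right) act as seeds.  Each subject contributes a
symmetric 246 x 246 Pearson correlation matrix; the analysis operates on
the 12 x 246 insula-row submatrix X_s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParcelTimeSeries",
    "ConnectivityTensor",
    "OutlierReport",
    "correlation_matrix",
    "extract_insula_submatrices",
    "detect_outliers",
    "validate_correlation_matrix",
]


@dataclass
class ParcelTimeSeries:
    subject_id: str
    data: np.ndarray                     # P x T parcel-mean BOLD
    parcel_labels: list[str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 3:
            raise ValueError("time series must be P x T with T >= 3")


@dataclass
class ConnectivityTensor:
    subjects: list[str]
    matrices: np.ndarray                 # S x P x P
    insula_indices: np.ndarray           # 12 seed-row indices

    def __post_init__(self):
        self.matrices = np.asarray(self.matrices, dtype=float)
        self.insula_indices = np.asarray(self.insula_indices, dtype=int)
        S = self.matrices.shape[0]
        if len(self.subjects) != S:
            raise ValueError("subject list does not match matrix count")

    @property
    def submatrices(self) -> np.ndarray:
        return extract_insula_submatrices(self)


@dataclass
class OutlierReport:
    subjects: list[str]
    distance: np.ndarray
    p: np.ndarray
    flagged: list[str]
    method: dict = field(default_factory=dict)


def validate_correlation_matrix(M: np.ndarray, atol: float = 1e-8) -> None:
    """Raise unless M is symmetric with unit diagonal and entries in [-1, 1]."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("not square")
    if not np.allclose(M, M.T, atol=atol):
        raise ValueError("not symmetric")
    if not np.allclose(np.diag(M), 1.0, atol=atol):
        raise ValueError("diagonal is not 1")
    if np.any(np.abs(M) > 1 + atol):
        raise ValueError("entries outside [-1, 1]")


def correlation_matrix(ts: ParcelTimeSeries | np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of parcel time series (P x T -> P x P).

    Constant-in-time parcels yield a zeroed row/column (diagonal kept at 1)
    with a warning rather than NaNs.
    """
    data = ts.data if isinstance(ts, ParcelTimeSeries) else np.asarray(ts, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("time series must be P x T with T >= 3")
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant parcel time series; "
                      "their correlations are set to 0", UserWarning,
                      stacklevel=2)
    safe = data.copy()
    # give constant rows unit variance noiseless stand-ins, then zero them out
    safe[constant] = np.arange(data.shape[1])
    M = np.corrcoef(safe)
    M[constant, :] = 0.0
    M[:, constant] = 0.0
    np.fill_diagonal(M, 1.0)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    return M


def extract_insula_submatrices(tensor: ConnectivityTensor) -> np.ndarray:
    """Insular seed rows of every subject's matrix: an S x 12 x P stack.

    Row i of a submatrix equals row ``insula_indices[i]`` of the full
    matrix, so insula-insula entries (including the unit self-entries) are
    retained, matching the 12 x 246 dimensionality of the model.
    """
    idx = tensor.insula_indices
    P = tensor.matrices.shape[1]
    if len(idx) != len(set(idx.tolist())):
        raise ValueError("duplicate insula indices")
    if np.any((idx < 0) | (idx >= P)):
        raise ValueError("insula index out of range")
    return tensor.matrices[:, idx, :]


def detect_outliers(
    features: np.ndarray,
    alpha: float = 0.05,
    n_pc: int = 5,
    seed: int = 0,
    subjects: list[str] | None = None,
) -> OutlierReport:
    """Screen subjects for multivariate outliers before covariance modeling.

    Features (e.g. flattened connectivity submatrices) are projected onto
    their top ``n_pc`` principal components; a robust Mahalanobis distance
    is formed with per-component median/MAD scaling, and each subject gets
    a leave-one-out empirical p (its rank among the other subjects'
    distances).  Subjects with p < alpha are flagged.  The procedure is
    deterministic; ``seed`` is recorded for provenance only.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be S x D")
    S = X.shape[0]
    if not (S > n_pc >= 1):
        raise ValueError("need S > n_pc >= 1")
    Xc = X - X.mean(axis=0)
    # PCA scores via thin SVD
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pc] * s[:n_pc]
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    mad = np.where(mad > 0, mad, 1.0)
    d = np.sqrt(np.sum(((scores - med) / mad) ** 2, axis=1))
    p = np.empty(S)
    for i in range(S):
        others = np.delete(d, i)
        p[i] = (1 + np.sum(others >= d[i])) / S
    flagged_idx = np.where(p < alpha)[0]
    ids = subjects if subjects is not None else [str(i) for i in range(S)]
    return OutlierReport(
        list(ids), d, p, [ids[i] for i in flagged_idx],
        method={
            "name": "pca-robust-mahalanobis-loo",
            "description": ("synthetic stand-in screen: top-PC robust "
                            "(median/MAD) Mahalanobis distance with "
                            "leave-one-out empirical p"),
            "n_pc": n_pc, "alpha": alpha, "seed": seed,
        },
    )
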