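"""Bootstrap inference over subjects: salience bootstrap ratios, FDR
thresholding, and score-on-score regressions.

The standardized effect size used throughout is the bootstrap ratio (BSR):
the mean of a quantity over bootstrap resamples divided by its bootstrap
standard error, treated as z-distributed when converting to p-values.
Salience maps are thresholded with Benjamini-Hochberg FDR at q = 0.05 by
default, applied jointly over the concatenated weight elements of a
component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .npls import NPLSModel, PLSModel, fit_npls, fit_pls

__all__ = [
    "SalienceInference",
    "RegressionResult",
    "bootstrap_saliences",
    "fdr_bh",
    "regress_scores",
    "adjust_covariates_sensitivity",
]

#: Sentinel BSR for elements with zero bootstrap spread.
BSR_INF = np.inf


@dataclass
class SalienceInference:
    """Element-wise bootstrap summary of a component's weight vectors.

    ``blocks`` records how the concatenated element axis splits back into
    the original weight vectors (e.g. ``{"w_x1": 12, "w_x2": 246}``).
    """

    mean: np.ndarray
    se: np.ndarray
    bsr: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    blocks: dict[str, int]
    q: float
    n_boot: int
    n_failed: int
    seed: int
    flip_record: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def block(self, name: str, arr: np.ndarray | None = None) -> np.ndarray:
        """Slice of the concatenated axis belonging to one weight vector."""
        arr = self.bsr if arr is None else arr
        start = 0
        for key, size in self.blocks.items():
            if key == name:
                return arr[start:start + size]
            start += size
        raise KeyError(name)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    ci_low: float
    ci_high: float
    bsr: float
    p_empirical: float
    intercept_ci: tuple[float, float]
    n_boot: int
    seed: int
    outcome_label: str = "outcome"
    predictor_label: str = "predictor"
    # raw inputs retained so sensitivity analyses can re-bootstrap pairwise
    outcome: np.ndarray | None = None
    predictor: np.ndarray | None = None
    covariates: np.ndarray | None = None


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject


def _component_weights(model, component: int = 0) -> tuple[np.ndarray, dict[str, int]]:
    comp = model.components[component]
    if isinstance(model, NPLSModel):
        return (np.concatenate([comp.w_x1, comp.w_x2]),
                {"w_x1": len(comp.w_x1), "w_x2": len(comp.w_x2)})
    return comp.w_x.copy(), {"w_x": len(comp.w_x)}


def _align_sign(w_rep: np.ndarray, w_full: np.ndarray, blocks: dict[str, int]) -> tuple[np.ndarray, int]:
    """Jointly flip a replicate's weight vectors to match the full-sample
    solution (sign of the inner product on the last block, the whole-brain
    or voxel salience); a joint flip of both tensor modes preserves c_x."""
    start = sum(list(blocks.values())[:-1])
    s = 1 if np.dot(w_rep[start:], w_full[start:]) >= 0 else -1
    return s * w_rep, s


def bootstrap_saliences(
    fit_fn,
    X: np.ndarray,
    Y: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    fdr_family: str = "joint",
    component: int = 0,
) -> SalienceInference:
    """Bootstrap the weight vectors of a PLS/NPLS component over subjects.

    ``fit_fn(X, Y)`` must be deterministic and return a fitted model; by
    default pass :func:`insulanet.npls.fit_npls` or ``fit_pls``.  Subjects
    are resampled with replacement (keeping X/Y rows paired), the model is
    refitted, and each replicate's weights are sign-aligned to the
    full-sample solution before accumulating the element-wise bootstrap
    mean, SE, BSR and normal-theory p-value.  ``fdr_family`` selects whether
    BH runs jointly over all elements of the component ("joint") or within
    each weight vector ("per-block").
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    S = X.shape[0]
    full = fit_fn(X, Y)
    w_full, blocks = _component_weights(full, component)

    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, w_full.size))
    flips = np.zeros(n_boot, dtype=int)
    n_failed = 0
    kept = 0
    for b in range(n_boot):
        idx = rng.integers(0, S, size=S)
        try:
            m = fit_fn(X[idx], Y[idx])
            w, _ = _component_weights(m, component)
            if not np.all(np.isfinite(w)):
                raise FloatingPointError("non-finite replicate weights")
        except Exception:
            n_failed += 1
            continue
        w, s = _align_sign(w, w_full, blocks)
        reps[kept] = w
        flips[kept] = s
        kept += 1
    if n_failed > 0.10 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    reps = reps[:kept]
    flips = flips[:kept]

    mean = reps.mean(axis=0)
    se = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(se > 0, mean / np.where(se > 0, se, 1.0),
                       np.sign(mean) * BSR_INF)
    bsr = np.where((se == 0) & (mean == 0), 0.0, bsr)
    p = 2.0 * stats.norm.sf(np.abs(bsr))

    if fdr_family == "joint":
        mask = fdr_bh(p, q)
    elif fdr_family == "per-block":
        mask = np.zeros_like(p, dtype=bool)
        start = 0
        for size in blocks.values():
            mask[start:start + size] = fdr_bh(p[start:start + size], q)
            start += size
    else:
        raise ValueError("fdr_family must be 'joint' or 'per-block'")

    return SalienceInference(mean, se, bsr, p, mask, blocks, q,
                             n_boot, n_failed, seed, flips)


def _ols(outcome: np.ndarray, predictor: np.ndarray,
         covariates: np.ndarray | None) -> tuple[float, float, float]:
    """Slope/intercept/R^2 of outcome on predictor, with optional covariate
    columns partialled out of both sides (Frisch-Waugh)."""
    y = outcome
    x = predictor
    if covariates is not None and covariates.size:
        Z = np.column_stack([np.ones(len(y)), covariates])
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    sx = x.std(ddof=1)
    if sx == 0:
        raise ValueError("constant predictor")
    xm, ym = x.mean(), y.mean()
    slope = float(np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm))
    intercept = float(ym - slope * xm)
    sy = y.std(ddof=1)
    if sy == 0:
        r2 = 0.0
    else:
        r = float(np.dot(x - xm, y - ym) / ((len(x) - 1) * sx * sy))
        r2 = r * r
    return slope, intercept, r2


def _empirical_p(boot: np.ndarray, n_boot: int) -> float:
    lo = np.mean(boot <= 0)
    hi = np.mean(boot >= 0)
    return float(np.clip(2.0 * min(lo, hi), 1.0 / n_boot, 1.0))


def regress_scores(
    outcome: np.ndarray,
    predictor: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    outcome_label: str = "outcome",
    predictor_label: str = "predictor",
) -> RegressionResult:
    """OLS of one per-subject score on another, with subject-bootstrap CI,
    BSR and empirical p for the slope.

    In the connectivity analyses the outcome is the network expression
    score ``c_x`` and the predictor the clinical composite (or the
    diffusivity score ``d_s`` in the DTI follow-up); optional covariate
    columns (age, sex, history of concussion) are partialled from both
    sides before the fit.
    """
    outcome = np.asarray(outcome, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if outcome.shape != predictor.shape:
        raise ValueError("outcome and predictor lengths differ")
    if len(outcome) < 3:
        raise ValueError("need at least 3 subjects")
    if not (np.all(np.isfinite(outcome)) and np.all(np.isfinite(predictor))):
        raise ValueError("non-finite values in regression inputs")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov is not None and cov.shape[0] != len(outcome):
        cov = cov.T
    slope, intercept, r2 = _ols(outcome, predictor, cov)

    rng = np.random.default_rng(seed)
    S = len(outcome)
    bs = np.empty(n_boot)
    bi = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, S, size=S)
        try:
            b, a, _ = _ols(outcome[idx], predictor[idx],
                           None if cov is None else cov[idx])
        except (ValueError, np.linalg.LinAlgError):
            continue
        bs[kept], bi[kept] = b, a
        kept += 1
    bs, bi = bs[:kept], bi[:kept]
    ci = np.percentile(bs, [2.5, 97.5])
    se = bs.std(ddof=1)
    bsr = float(bs.mean() / se) if se > 0 else float(np.sign(bs.mean()) * BSR_INF)
    p = _empirical_p(bs, n_boot)
    ici = np.percentile(bi, [2.5, 97.5])
    return RegressionResult(slope, intercept, r2, float(ci[0]), float(ci[1]),
                            bsr, p, (float(ici[0]), float(ici[1])), n_boot,
                            seed, outcome_label, predictor_label,
                            outcome, predictor, cov)


@dataclass
class SensitivityResult:
    delta_b: float
    ci_low: float
    ci_high: float
    bsr: float
    p_empirical: float
    n_boot: int
    seed: int


def adjust_covariates_sensitivity(
    result_unadjusted: RegressionResult,
    result_adjusted: RegressionResult,
    n_boot: int = 1000,
    seed: int = 0,
) -> SensitivityResult:
    """Paired bootstrap of the change in slope when covariates are added.

    Both results must have been fitted on the same subjects (in the same
    order); each bootstrap resample refits both models and takes the
    difference of slopes, yielding a BSR and empirical p for the impact of
    covariate adjustment.
    """
    ru, ra = result_unadjusted, result_adjusted
    if ru.outcome is None or ra.outcome is None:
        raise ValueError("results must retain their raw inputs")
    if len(ru.outcome) != len(ra.outcome) or not np.allclose(ru.outcome, ra.outcome):
        raise ValueError("results were not fitted on identical subjects")
    rng = np.random.default_rng(seed)
    S = len(ru.outcome)
    deltas = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, S, size=S)
        try:
            b0, _, _ = _ols(ru.outcome[idx], ru.predictor[idx],
                            None if ru.covariates is None else ru.covariates[idx])
            b1, _, _ = _ols(ra.outcome[idx], ra.predictor[idx],
                            None if ra.covariates is None else ra.covariates[idx])
        except (ValueError, np.linalg.LinAlgError):
            continue
        deltas[kept] = b1 - b0
        kept += 1
    deltas = deltas[:kept]
    ci = np.percentile(deltas, [2.5, 97.5])
    se = deltas.std(ddof=1)
    bsr = float(deltas.mean() / se) if se > 0 else 0.0
    return SensitivityResult(ra.slope - ru.slope, float(ci[0]), float(ci[1]),
                             bsr, _empirical_p(deltas, n_boot), n_boot, seed)
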