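"""Clinical scoring: symptom sums, the PCA cognitive composite, rank-based
normal-scores transforms, and bootstrap group comparisons / correlations.

The pipeline summarizes each athlete by two clinical quantities: SYM, the
sum of the six cognition-related items of the 22-item SCAT5 symptom scale
(each rated 0-6), and COG, the first principal component of the four timed
neurocognitive subtests (SRT, CRT, TMT-A, TMT-B; larger = slower).  Both
are mapped to standard-normal quantile scores z(SYM) and z(COG) relative to
the concussed cohort, from which the orthogonal composites
severity = z(SYM) + z(COG) and mismatch = z(SYM) - z(COG) are formed.
Positive mismatch denotes symptom over-reporting relative to measured
performance; negative, under-reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "COGNITIVE_ITEM_POSITIONS",
    "SUBTEST_COLUMNS",
    "PCAResult",
    "BootstrapComparison",
    "cognitive_symptom_score",
    "normal_scores_transform",
    "reference_normal_scores",
    "cog_composite",
    "composite_scores",
    "bootstrap_mean_difference",
    "spearman_bootstrap",
    "score_table",
]

# 0-based positions of the six cognition-probing items within the standard
# 22-item SCAT5 symptom ordering: feeling slowed down, feeling "in a fog",
# "don't feel right", difficulty concentrating, difficulty remembering,
# confusion.
COGNITIVE_ITEM_POSITIONS: tuple[int, ...] = (9, 10, 11, 12, 13, 15)

SUBTEST_COLUMNS = ("srt_ms", "crt_ms", "tmta_s", "tmtb_s")


@dataclass
class PCAResult:
    loadings: np.ndarray             # unit 4-vector (SRT, CRT, TMT-A, TMT-B)
    variance_explained: float
    loading_ci: np.ndarray           # 4 x 2 bootstrap 95% intervals
    variance_ci: tuple[float, float]
    scores: np.ndarray               # per-subject COG
    n_boot: int
    seed: int


@dataclass
class BootstrapComparison:
    estimate: float
    ci_low: float
    ci_high: float
    bsr: float
    p_empirical: float
    n_boot: int
    seed: int


def cognitive_symptom_score(
    item_ratings: np.ndarray,
    positions: tuple[int, ...] = COGNITIVE_ITEM_POSITIONS,
) -> int:
    """Sum the six cognitive-item Likert ratings of a 22-item checklist."""
    r = np.asarray(item_ratings)
    if r.shape != (22,):
        raise ValueError("expected exactly 22 item ratings")
    if np.any((r < 0) | (r > 6)):
        raise ValueError("item ratings must lie in [0, 6]")
    return int(np.sum(r[list(positions)]))


def normal_scores_transform(values: np.ndarray, convention: str = "midrank") -> np.ndarray:
    """Rank-based inverse-normal (normal scores) transform.

    Maps each value to the standard-normal quantile of its mid-rank:
    ``z_i = ppf((r_i - 0.5) / n)`` for the default ``"midrank"`` convention,
    or ``ppf(r_i / (n + 1))`` for ``"rank-over-n1"``.  Invariant to any
    strictly monotone rescaling of the input; ties share a mid-rank.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-d vector of at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; normal scores degenerate to 0",
                      UserWarning, stacklevel=2)
        return np.zeros_like(v)
    r = stats.rankdata(v, method="average")
    n = v.size
    if convention == "midrank":
        u = (r - 0.5) / n
    elif convention == "rank-over-n1":
        u = r / (n + 1)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return stats.norm.ppf(u)


def reference_normal_scores(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Normal scores of ``values`` through the empirical quantile map of a
    reference sample (used to place controls on the concussed cohort's
    z-scale).  Quantiles are mid-rank positions of each value within the
    reference, clipped away from 0 and 1."""
    v = np.asarray(values, dtype=float)
    ref = np.sort(np.asarray(reference, dtype=float))
    n = ref.size
    below = np.searchsorted(ref, v, side="left")
    above = np.searchsorted(ref, v, side="right")
    u = (below + 0.5 * (above - below) + 0.5) / (n + 1)
    u = np.clip(u, 0.5 / (n + 1), 1 - 0.5 / (n + 1))
    return stats.norm.ppf(u)


def _pca_first(Xc: np.ndarray) -> tuple[np.ndarray, float]:
    cov = np.cov(Xc, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    lead = vecs[:, -1]
    if lead.sum() < 0:
        lead = -lead
    return lead, float(vals[-1] / vals.sum())


def cog_composite(
    subtests: pd.DataFrame | np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    convention: str = "midrank",
) -> PCAResult:
    """COG summary score: first principal component of the four subtests.

    Columns are individually normal-scores transformed, mean centered, and
    decomposed; the first component's unit loading vector (sign fixed so the
    loading sum is positive: larger COG = slower) and per-subject scores are
    returned with subject-bootstrap 95% CIs on loadings and variance
    explained (replicates sign-aligned to the full-sample loadings).
    """
    X = np.asarray(subtests, dtype=float)
    if X.ndim != 2:
        raise ValueError("subtests must be a 2-d table")
    S, J = X.shape
    if S < 5:
        raise ValueError("need at least 5 subjects")
    for j in range(J):
        if np.ptp(X[:, j]) == 0:
            name = (subtests.columns[j] if isinstance(subtests, pd.DataFrame)
                    else f"column {j}")
            raise ValueError(f"constant subtest column: {name}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        Z = np.column_stack([normal_scores_transform(X[:, j], convention)
                             for j in range(J)])
    Z = Z - Z.mean(axis=0)
    loadings, varexp = _pca_first(Z)
    scores = Z @ loadings

    rng = np.random.default_rng(seed)
    boot_load = np.empty((n_boot, J))
    boot_var = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, S, size=S)
        Zb = Z[idx] - Z[idx].mean(axis=0)
        lb, vb = _pca_first(Zb)
        if np.dot(lb, loadings) < 0:
            lb = -lb
        boot_load[b] = lb
        boot_var[b] = vb
    lci = np.percentile(boot_load, [2.5, 97.5], axis=0).T
    vci = np.percentile(boot_var, [2.5, 97.5])
    return PCAResult(loadings, varexp, lci, (float(vci[0]), float(vci[1])),
                     scores, n_boot, seed)


def composite_scores(z_sym: np.ndarray, z_cog: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Severity (sum) and appraisal-mismatch (difference) composites."""
    z_sym = np.asarray(z_sym, dtype=float)
    z_cog = np.asarray(z_cog, dtype=float)
    if z_sym.shape != z_cog.shape:
        raise ValueError("z_sym and z_cog lengths differ")
    return z_sym + z_cog, z_sym - z_cog


def _boot_comparison(boot: np.ndarray, estimate: float, n_boot: int,
                     seed: int) -> BootstrapComparison:
    ci = np.percentile(boot, [2.5, 97.5])
    se = boot.std(ddof=1)
    if se == 0:
        bsr = float(np.sign(boot.mean()) * np.inf) if boot.mean() != 0 else 0.0
        p = 1.0 / n_boot if boot.mean() != 0 else 1.0
    else:
        bsr = float(boot.mean() / se)
        lo = np.mean(boot <= 0)
        hi = np.mean(boot >= 0)
        p = float(np.clip(2.0 * min(lo, hi), 1.0 / n_boot, 1.0))
    return BootstrapComparison(estimate, float(ci[0]), float(ci[1]), bsr, p,
                               n_boot, seed)


def bootstrap_mean_difference(a: np.ndarray, b: np.ndarray,
                              n_boot: int = 1000, seed: int = 0) -> BootstrapComparison:
    """Bootstrap test of mean(b) - mean(a) with percentile 95% CI, BSR and
    two-sided empirical p (floored at 1/n_boot)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    est = float(b.mean() - a.mean())
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        boot[i] = (b[rng.integers(0, b.size, b.size)].mean()
                   - a[rng.integers(0, a.size, a.size)].mean())
    return _boot_comparison(boot, est, n_boot, seed)


def spearman_bootstrap(x: np.ndarray, y: np.ndarray,
                       n_boot: int = 1000, seed: int = 0) -> BootstrapComparison:
    """Spearman rank correlation (mid-rank ties) with bootstrap CI/BSR/p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    est = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            continue
        boot[kept] = stats.spearmanr(x[idx], y[idx]).statistic
        kept += 1
    return _boot_comparison(boot[:kept], est, n_boot, seed)


def score_table(
    clinical: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    positions: tuple[int, ...] = COGNITIVE_ITEM_POSITIONS,
) -> tuple[pd.DataFrame, PCAResult]:
    """Score a raw clinical table in place of the individual operations.

    Adds ``sym`` (six-item sum), ``cog`` (pooled-cohort PCA composite),
    ``z_sym``/``z_cog`` (normal scores referenced to the concussed cohort;
    controls are mapped through the concussed empirical quantile map),
    ``severity`` and ``mismatch`` columns.  Returns the augmented copy and
    the PCA fit.
    """
    df = clinical.copy()
    items = df[[f"sym_item_{i}" for i in range(1, 23)]].to_numpy()
    df["sym"] = [cognitive_symptom_score(row, positions) for row in items]

    pca = cog_composite(df[list(SUBTEST_COLUMNS)], n_boot=n_boot, seed=seed)
    df["cog"] = pca.scores

    conc = df["group"] == "concussed"
    sym_c = df.loc[conc, "sym"].to_numpy(float)
    cog_c = df.loc[conc, "cog"].to_numpy(float)
    z_sym = np.full(len(df), np.nan)
    z_cog = np.full(len(df), np.nan)
    z_sym[conc.to_numpy()] = normal_scores_transform(sym_c)
    z_cog[conc.to_numpy()] = normal_scores_transform(cog_c)
    ctrl = ~conc.to_numpy()
    if ctrl.any():
        z_sym[ctrl] = reference_normal_scores(df.loc[~conc, "sym"].to_numpy(float), sym_c)
        z_cog[ctrl] = reference_normal_scores(df.loc[~conc, "cog"].to_numpy(float), cog_c)
    df["z_sym"] = z_sym
    df["z_cog"] = z_cog
    df["severity"], df["mismatch"] = composite_scores(z_sym, z_cog)
    return df, pca
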