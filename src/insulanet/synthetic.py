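"""Synthetic cohort generator with planted, parameterized effects.

Generates complete study cohorts — a clinical table, per-subject parcel
time series / connectivity matrices, and FA/MD volumes — so that every
downstream stage (composite scoring, NPLS, bootstrap inference, voxelwise
DTI PLS) can be exercised and validated against known ground truth.

The default parameters emulate the study conditions the pipeline was built
for: 136 control / 59 concussed athletes; concussed slower on all four
timed subtests; zero-inflated symptom scores (control median 0, concussed
median near 6 with quartiles near 2 and 16); a weak symptom-cognition
correlation; a subject-varying rank-1 insula-by-brain connectivity
component coupled both to group membership and to a latent appraisal
mismatch; and white-matter clusters where FA decreases and MD increases
with the planted network score.

Connectivity is generated through latent time series rather than by
perturbing matrices directly, so every output is a valid (positive
semidefinite, unit-diagonal) correlation matrix by construction.  The
planted mismatch is a latent subject variable feeding both symptom
inflation and connectivity coupling, so the observable z(SYM) - z(COG)
correlates with, but does not equal, the planted score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityTensor, correlation_matrix
from .dti import VoxelMapSet

__all__ = [
    "CohortSpec",
    "DTIEffect",
    "PlantedTruth",
    "GenerationError",
    "simulate_clinical",
    "simulate_connectivity",
    "simulate_dti",
    "simulate_cohort",
    "Cohort",
]

LATENT_COLUMNS = ("latent_speed", "latent_mismatch")

# 0-based positions of the 12 insular subregions in the 246-parcel atlas
DEFAULT_INSULA_INDICES = tuple(range(162, 174))


class GenerationError(RuntimeError):
    pass


@dataclass
class DTIEffect:
    """Planted diffusion effects: per-cluster slope of voxel value against
    the planted network score (FA negative, MD positive), with per-metric
    voxel noise and cluster counts."""

    fa_slope: float = -0.05      # FA units per unit planted score
    md_slope: float = 1.5e-4     # mm^2/s per unit planted score
    fa_noise: float = 0.015
    md_noise: float = 5.0e-5
    n_fa_clusters: int = 2
    n_md_clusters: int = 4


@dataclass
class CohortSpec:
    """All generator knobs for one synthetic cohort.

    Identical specs (including ``seed``) produce bit-identical cohorts.
    """

    n_control: int = 136
    n_concussed: int = 59
    n_parcels: int = 246
    insula_indices: tuple[int, ...] = DEFAULT_INSULA_INDICES
    n_timepoints: int = 191

    # additive concussion slowing per subtest (SRT ms, CRT ms, TMT-A s, TMT-B s)
    group_slow_ms: tuple[float, float, float, float] = (11.3, 22.9, 1.65, 3.65)

    # log-scale subtest marginals (SRT, CRT in ms; TMT-A/B in s)
    subtest_log_mu: tuple[float, ...] = (5.570, 5.894, 2.786, 3.460)
    subtest_log_sd: tuple[float, ...] = (0.093, 0.134, 0.289, 0.270)
    speed_loading: float = 0.62      # shared slowness latent -> each subtest

    # zero-inflated symptom model: {group: params}
    sym_distribution: dict = field(default_factory=lambda: {
        "control": {"zero_prob": 0.60, "tail_rate": 0.8},
        "concussed": {"zero_prob": 0.10, "log_mu": 1.9, "log_sd": 1.4,
                      "speed_weight": 0.35, "mismatch_weight": 0.80},
    })

    # rank-1 connectivity coupling: s_i = group_coupling * group(+-1)
    #   + mismatch_coupling * latent mismatch + coupling_noise * eps
    group_coupling: float = -0.5
    mismatch_coupling: float = 0.15
    coupling_noise: float = 0.03
    source_strength: float = 1.0     # insula expression of the coupling signal
    community_weight: float = 0.3    # shared community variance fraction
    community_jitter: float = 0.5    # subject-level spread of community strength
    n_communities: int = 6
    noise_sd: float = 0.5            # measurement noise on time series

    dti_effect: DTIEffect = field(default_factory=DTIEffect)
    volume_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.dti_effect, dict):
            self.dti_effect = DTIEffect(**self.dti_effect)
        self.validate()

    def validate(self) -> None:
        for name in ("n_control", "n_concussed", "n_parcels", "n_timepoints"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"invalid CohortSpec field: {name} must be > 0")
        if self.noise_sd <= 0:
            raise ValueError("invalid CohortSpec field: noise_sd must be > 0")
        idx = np.asarray(self.insula_indices)
        if len(idx) != len(set(idx.tolist())):
            raise ValueError("invalid CohortSpec field: duplicate insula_indices")
        if np.any((idx < 0) | (idx >= self.n_parcels)):
            raise ValueError("invalid CohortSpec field: insula_indices out of range")
        if not (0 < self.community_weight < 1):
            raise ValueError("invalid CohortSpec field: community_weight in (0,1)")

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_concussed

    @property
    def subject_ids(self) -> list[str]:
        return [f"sub-{i:04d}" for i in range(self.n_subjects)]


@dataclass
class PlantedTruth:
    """Ground truth planted in a cohort, for recovery tests."""

    u_true: np.ndarray               # unit 12-vector, insula mode
    v_true: np.ndarray               # unit 246-vector, whole-brain mode
    subject_scores: np.ndarray       # planted coupling s_i per subject
    mismatch_latent: np.ndarray      # latent mismatch per subject
    cluster_masks: list[dict] = field(default_factory=list)

    def __post_init__(self):
        for name in ("u_true", "v_true"):
            v = getattr(self, name)
            if abs(np.linalg.norm(v) - 1.0) > 1e-8:
                raise ValueError(f"{name} must have unit norm")
        if not np.all(np.isfinite(self.subject_scores)):
            raise ValueError("subject_scores must be finite")


def _rng(spec: CohortSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, spec.seed])


def _allocate_items(rng: np.random.Generator, total: int, n_items: int,
                    cap: int = 6) -> np.ndarray:
    """Distribute ``total`` Likert units over ``n_items`` items with a per
    item cap, one unit at a time."""
    out = np.zeros(n_items, dtype=int)
    for _ in range(int(total)):
        open_items = np.where(out < cap)[0]
        out[open_items[rng.integers(0, len(open_items))]] += 1
    return out


def simulate_clinical(spec: CohortSpec) -> pd.DataFrame:
    """Draw the clinical table: demographics, four timed subtests, and the
    22 symptom items.

    Concussed subtest times are the control-like draw plus the additive
    ``group_slow_ms`` shift.  The returned frame carries two extra latent
    columns (``latent_speed``, ``latent_mismatch``) used by the
    connectivity generator; they belong in the truth sidecar, not the
    observable table.
    """
    spec.validate()
    rng = _rng(spec, 1)
    n = spec.n_subjects
    groups = ["control"] * spec.n_control + ["concussed"] * spec.n_concussed

    age_params = {"control": (20.3, 2.0), "concussed": (20.6, 2.1)}
    female_prob = {"control": 0.49, "concussed": 0.50}
    hoc_prob = {"control": 0.40, "concussed": 0.47}

    g_lat = rng.standard_normal(n)      # shared slowness latent
    m_lat = rng.standard_normal(n)      # appraisal-mismatch latent

    rows = []
    lam = spec.speed_loading
    resid = np.sqrt(1.0 - lam ** 2)
    for i, grp in enumerate(groups):
        mu_a, sd_a = age_params[grp]
        age = float(np.clip(rng.normal(mu_a, sd_a), 17, 35))
        sex = "F" if rng.random() < female_prob[grp] else "M"
        hoc = bool(rng.random() < hoc_prob[grp])
        times = []
        for j in range(4):
            z = lam * g_lat[i] + resid * rng.standard_normal()
            t = float(np.exp(spec.subtest_log_mu[j] + spec.subtest_log_sd[j] * z))
            if grp == "concussed":
                t += spec.group_slow_ms[j]
            times.append(t)

        pars = spec.sym_distribution[grp]
        if grp == "concussed":
            if rng.random() < pars["zero_prob"]:
                sym = 0
            else:
                w_g, w_m = pars["speed_weight"], pars["mismatch_weight"]
                w_e = np.sqrt(max(1.0 - w_g ** 2 - w_m ** 2, 0.0))
                z = w_g * g_lat[i] + w_m * m_lat[i] + w_e * rng.standard_normal()
                sym = int(np.clip(round(np.exp(pars["log_mu"] + pars["log_sd"] * z)), 1, 36))
            other_rate = 1.2
        else:
            sym = 0 if rng.random() < pars["zero_prob"] else \
                int(min(1 + rng.poisson(pars["tail_rate"]), 36))
            other_rate = 0.05

        items = np.zeros(22, dtype=int)
        from .clinical import COGNITIVE_ITEM_POSITIONS
        cog_pos = list(COGNITIVE_ITEM_POSITIONS)
        items[cog_pos] = _allocate_items(rng, sym, 6)
        other_pos = [k for k in range(22) if k not in cog_pos]
        items[other_pos] = np.minimum(rng.poisson(other_rate, size=len(other_pos)), 6)

        row = {"subject_id": spec.subject_ids[i], "group": grp, "age": age,
               "sex": sex, "hoc": hoc,
               "srt_ms": times[0], "crt_ms": times[1],
               "tmta_s": times[2], "tmtb_s": times[3]}
        row.update({f"sym_item_{k + 1}": int(items[k]) for k in range(22)})
        row["latent_speed"] = g_lat[i]
        row["latent_mismatch"] = m_lat[i]
        rows.append(row)
    return pd.DataFrame(rows)


def planted_vectors(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (per seed) planted unit vectors: a smooth positive
    insula profile and a sparse signed whole-brain target pattern supported
    off the insula."""
    rng = _rng(spec, 7)
    k = len(spec.insula_indices)
    u = np.linspace(0.5, 1.5, k)
    u = u / np.linalg.norm(u)
    v = np.zeros(spec.n_parcels)
    candidates = np.setdiff1d(np.arange(spec.n_parcels),
                              np.asarray(spec.insula_indices))
    n_support = min(40, len(candidates))
    support = rng.choice(candidates, size=n_support, replace=False)
    vals = rng.standard_normal(n_support)
    v[support] = vals
    v = v / np.linalg.norm(v)
    return u, v


def planted_subject_scores(spec: CohortSpec, clinical: pd.DataFrame) -> np.ndarray:
    rng = _rng(spec, 8)
    group_pm = np.where(clinical["group"].to_numpy() == "concussed", 1.0, -1.0)
    m = clinical["latent_mismatch"].to_numpy(float)
    return (spec.group_coupling * group_pm
            + spec.mismatch_coupling * m
            + spec.coupling_noise * rng.standard_normal(len(clinical)))


def simulate_connectivity(
    spec: CohortSpec, clinical: pd.DataFrame
) -> tuple[ConnectivityTensor, PlantedTruth]:
    """Generate per-subject parcel time series and correlation matrices
    with a planted rank-1 insula-to-brain coupling.

    Each parcel's series mixes a shared community signal with parcel noise;
    insula parcels additionally express a coupling signal h(t) with fixed
    amplitude ``source_strength * u_true``, and every parcel receives
    ``s_i * v_true`` of the same signal, where the subject coupling
    ``s_i`` combines group membership and the latent mismatch.  The
    correlation between insula row j and parcel p therefore gains an
    approximately linear rank-1 term proportional to ``s_i u_j v_p``.
    """
    if len(clinical) != spec.n_subjects:
        raise ValueError("clinical rows do not match spec subject count")
    for col in LATENT_COLUMNS:
        if col not in clinical.columns:
            raise ValueError(f"clinical table lacks generator column {col!r}")

    u, v = planted_vectors(spec)
    s = planted_subject_scores(spec, clinical)
    amp = abs(spec.source_strength) * np.max(np.abs(u))
    coup = np.max(np.abs(s)) * np.max(np.abs(v))
    if amp > 5 or coup > 5:
        raise GenerationError("coupling so large that series variance is "
                              "dominated by the planted signal")

    rng = _rng(spec, 2)
    P, T = spec.n_parcels, spec.n_timepoints
    comm = np.arange(P) % spec.n_communities
    w = spec.community_weight
    ins = np.asarray(spec.insula_indices)

    mats = np.empty((spec.n_subjects, P, P))
    for i in range(spec.n_subjects):
        C = rng.standard_normal((T, spec.n_communities))
        # subject-level variation in community coupling strength: a few
        # low-rank between-subject factors, as in real cohorts, so that
        # between-subject connectivity spread is not just sampling noise
        amp = np.sqrt(w) * np.clip(
            1.0 + spec.community_jitter * rng.standard_normal(spec.n_communities),
            0.2, None)
        series = C[:, comm] * amp[comm] + np.sqrt(1 - w) * rng.standard_normal((T, P))
        h = rng.standard_normal(T)
        series[:, ins] += spec.source_strength * np.outer(h, u)
        series += s[i] * np.outer(h, v)
        series += spec.noise_sd * rng.standard_normal((T, P))
        mats[i] = correlation_matrix(series.T)

    tensor = ConnectivityTensor(list(clinical["subject_id"]), mats, ins)
    truth = PlantedTruth(u, v, s, clinical["latent_mismatch"].to_numpy(float))
    return tensor, truth


def _wm_ellipsoid(shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) * 0.33
    r2 = sum(((grid[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    return r2 <= 1.0


def _place_clusters(rng: np.random.Generator, wm: np.ndarray,
                    sizes: list[int], taken: np.ndarray) -> list[np.ndarray]:
    """Grow face-connected clusters of given voxel counts inside the mask."""
    from scipy import ndimage

    clusters = []
    for size in sizes:
        for _ in range(200):
            seed_idx = np.argwhere(wm & ~taken)
            start = tuple(seed_idx[rng.integers(0, len(seed_idx))])
            grown = np.zeros_like(wm)
            grown[start] = True
            while grown.sum() < size:
                frontier = ndimage.binary_dilation(grown) & wm & ~taken & ~grown
                cand = np.argwhere(frontier)
                if len(cand) == 0:
                    break
                grown[tuple(cand[rng.integers(0, len(cand))])] = True
            if grown.sum() == size:
                clusters.append(grown)
                taken |= ndimage.binary_dilation(grown)
                break
        else:
            raise GenerationError("could not place a planted cluster")
    return clusters


def simulate_dti(
    spec: CohortSpec, truth: PlantedTruth
) -> tuple[VoxelMapSet, VoxelMapSet, np.ndarray]:
    """Generate FA and MD volumes with planted clusters coupled to the
    subject scores (FA decreasing, MD increasing), plus the WM mask.

    Inside each planted cluster, voxel value = baseline + slope * s_i +
    noise; outside, baseline + noise.  Baseline FA inside the WM mask
    exceeds the 0.30 masking threshold by construction.  Cluster masks and
    slopes are appended to ``truth.cluster_masks``.
    """
    shape = tuple(spec.volume_shape)
    wm = _wm_ellipsoid(shape)
    eff = spec.dti_effect
    rng = _rng(spec, 3)

    sizes_fa = [8, 6][: eff.n_fa_clusters] + [8] * max(0, eff.n_fa_clusters - 2)
    sizes_md = ([30, 20, 10, 8][: eff.n_md_clusters]
                + [10] * max(0, eff.n_md_clusters - 4))
    taken = np.zeros(shape, dtype=bool)
    fa_clusters = _place_clusters(rng, wm, sizes_fa, taken)
    md_clusters = _place_clusters(rng, wm, sizes_md, taken)
    for c in fa_clusters:
        if not np.all(wm[c]):
            raise GenerationError("planted cluster outside the volume mask")

    n = len(truth.subject_scores)
    V = int(wm.sum())
    fa_base = 0.45 + 0.05 * rng.random(V)
    md_base = 7.5e-4 + 5.0e-5 * rng.random(V)

    fa = np.empty((n, V))
    md = np.empty((n, V))
    fa_sl = np.zeros(V)
    md_sl = np.zeros(V)
    for c in fa_clusters:
        fa_sl[c[wm]] = eff.fa_slope
    for c in md_clusters:
        md_sl[c[wm]] = eff.md_slope
    s = truth.subject_scores
    for i in range(n):
        fa[i] = np.clip(fa_base + fa_sl * s[i] + eff.fa_noise * rng.standard_normal(V),
                        0.0, 1.0)
        md[i] = np.maximum(md_base + md_sl * s[i] + eff.md_noise * rng.standard_normal(V),
                           1e-6)

    half = spec.voxel_size_mm * (np.asarray(shape) - 1) / 2.0
    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -half

    truth.cluster_masks = (
        [{"metric": "FA", "slope": eff.fa_slope,
          "voxels": np.argwhere(c).tolist()} for c in fa_clusters]
        + [{"metric": "MD", "slope": eff.md_slope,
            "voxels": np.argwhere(c).tolist()} for c in md_clusters])

    ids = [f"sub-{i:04d}" for i in range(n)]
    return (VoxelMapSet(ids, fa, wm, affine, "FA"),
            VoxelMapSet(ids, md, wm, affine, "MD"),
            wm)


@dataclass
class Cohort:
    spec: CohortSpec
    clinical: pd.DataFrame
    tensor: ConnectivityTensor
    truth: PlantedTruth
    fa: VoxelMapSet
    md: VoxelMapSet
    wm_mask: np.ndarray


def simulate_cohort(spec: CohortSpec, dti: bool = True) -> Cohort:
    """Generate a full cohort (clinical + connectivity + optionally DTI)."""
    clinical = simulate_clinical(spec)
    tensor, truth = simulate_connectivity(spec, clinical)
    if dti:
        fa, md, wm = simulate_dti(spec, truth)
        fa.subjects = list(clinical["subject_id"])
        md.subjects = list(clinical["subject_id"])
    else:
        fa = md = None
        wm = None
    return Cohort(spec, clinical, tensor, truth, fa, md, wm)
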