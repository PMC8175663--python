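"""Readers, writers, run configuration and the end-to-end pipeline.

On-disk layout of a cohort directory (all plain text except NIfTI):

    clinical.tsv            tab-delimited clinical table
    parcels.tsv             parcel lookup (index, name, is_insula, MNI x/y/z)
    matrices/sub-XXXX.txt   one 246-line delimited correlation matrix each
    matrices/manifest.tsv   subject_id -> matrix file
    volumes/sub-XXXX_fa.nii.gz / _md.nii.gz
    wm_mask.nii.gz
    truth.json              planted ground truth (synthetic cohorts only)
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import score_table
from .connectivity import ConnectivityTensor, detect_outliers, extract_insula_submatrices
from .dti import VoxelMapSet, dti_pls
from .inference import bootstrap_saliences, regress_scores
from .npls import fit_npls
from .synthetic import LATENT_COLUMNS, Cohort, CohortSpec, simulate_cohort

log = logging.getLogger("insulanet")

ANALYSES = ("main_effect", "severity", "mismatch", "dti_fa", "dti_md")


# ---------------------------------------------------------------- writers

def write_clinical(df: pd.DataFrame, path: Path) -> None:
    obs = df.drop(columns=[c for c in LATENT_COLUMNS if c in df.columns])
    obs.to_csv(path, sep="\t", index=False)


def read_clinical(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"subject_id", "group", "srt_ms", "crt_ms", "tmta_s", "tmtb_s"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def write_parcel_lut(path: Path, n_parcels: int, insula_indices) -> None:
    ins = set(int(i) for i in insula_indices)
    insula_names = ["G", "dIg", "dId", "dIa", "vId/vIg", "vIa"]
    rows = []
    rank = 0
    for i in range(n_parcels):
        if i in ins:
            side = "L" if rank % 2 == 0 else "R"
            name = f"insula_{insula_names[(rank // 2) % 6]}_{side}"
            rank += 1
        else:
            name = f"parcel_{i:03d}"
        rows.append({"index": i, "name": name, "is_insula": int(i in ins),
                     "mni_x": 0.0, "mni_y": 0.0, "mni_z": 0.0})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_parcel_lut(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_matrices(tensor: ConnectivityTensor, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, M in zip(tensor.subjects, tensor.matrices):
        fname = f"{sid}.txt"
        np.savetxt(outdir / fname, M, fmt="%.6f", delimiter="\t")
        rows.append({"subject_id": sid, "file": fname})
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)


def read_matrices(matrix_dir: Path, insula_indices) -> ConnectivityTensor:
    manifest = pd.read_csv(Path(matrix_dir) / "manifest.tsv", sep="\t")
    mats = [np.loadtxt(Path(matrix_dir) / f, delimiter="\t")
            for f in manifest["file"]]
    return ConnectivityTensor(list(manifest["subject_id"]), np.stack(mats),
                              np.asarray(insula_indices, dtype=int))


def write_volumes(maps: VoxelMapSet, outdir: Path, suffix: str) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, row in zip(maps.subjects, maps.data):
        img = nib.Nifti1Image(maps.unmask(row).astype(np.float32), maps.affine)
        nib.save(img, outdir / f"{sid}_{suffix}.nii.gz")


def read_volumes(vol_dir: Path, subjects: list[str], suffix: str,
                 mask: np.ndarray, affine: np.ndarray,
                 metric: str) -> tuple[VoxelMapSet, list[str]]:
    """Load per-subject volumes; subjects with a missing file are excluded
    (returned separately) rather than failing the analysis."""
    data, kept, missing = [], [], []
    for sid in subjects:
        p = Path(vol_dir) / f"{sid}_{suffix}.nii.gz"
        if not p.exists():
            missing.append(sid)
            continue
        vol = np.asarray(nib.load(p).dataobj, dtype=float)
        data.append(vol[mask])
        kept.append(sid)
    if not kept:
        raise FileNotFoundError(f"no {suffix} volumes found under {vol_dir}")
    return VoxelMapSet(kept, np.stack(data), mask, affine, metric), missing


def write_cohort(cohort: Cohort, outdir: Path) -> None:
    """Write the full input layout the pipeline expects, plus the planted
    truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_clinical(cohort.clinical, outdir / "clinical.tsv")
    write_parcel_lut(outdir / "parcels.tsv", cohort.spec.n_parcels,
                     cohort.spec.insula_indices)
    write_matrices(cohort.tensor, outdir / "matrices")
    if cohort.fa is not None:
        write_volumes(cohort.fa, outdir / "volumes", "fa")
        write_volumes(cohort.md, outdir / "volumes", "md")
        img = nib.Nifti1Image(cohort.wm_mask.astype(np.uint8), cohort.fa.affine)
        nib.save(img, outdir / "wm_mask.nii.gz")
    truth = {
        "u_true": cohort.truth.u_true.tolist(),
        "v_true": cohort.truth.v_true.tolist(),
        "subject_scores": cohort.truth.subject_scores.tolist(),
        "mismatch_latent": cohort.truth.mismatch_latent.tolist(),
        "cluster_masks": cohort.truth.cluster_masks,
        "spec": _spec_dict(cohort.spec),
    }
    (outdir / "truth.json").write_text(json.dumps(truth))


def _spec_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    return json.loads(json.dumps(d, default=lambda o: list(o) if isinstance(o, tuple) else o))


def load_cohort_spec(path: Path) -> CohortSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown CohortSpec keys: {sorted(unknown)}")
    for key in ("insula_indices", "group_slow_ms", "subtest_log_mu",
                "subtest_log_sd", "volume_shape"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortSpec(**raw)


# ---------------------------------------------------------------- pipeline

@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    analysis: str = "mismatch"
    n_boot: int = 1000
    q_fdr: float = 0.05
    min_cluster: int = 3
    seed: int = 0
    n_components: int = 1
    center: bool = True
    outlier_alpha: float = 0.01
    outlier_n_pc: int = 5
    covariates: bool = False

    def __post_init__(self):
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


def load_config(path: Path, **overrides) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _regression_dict(reg) -> dict:
    if reg is None:
        return {"skipped": True, "reason": "no voxels survived thresholding"}
    return {"slope": reg.slope, "intercept": reg.intercept,
            "r_squared": reg.r_squared, "ci": [reg.ci_low, reg.ci_high],
            "bsr": reg.bsr, "p_empirical": reg.p_empirical,
            "intercept_ci": list(reg.intercept_ci), "n_boot": reg.n_boot,
            "outcome": reg.outcome_label, "predictor": reg.predictor_label}


def _salience_dict(inf) -> dict:
    return {"bsr": inf.bsr.tolist(), "p": inf.p.tolist(),
            "fdr_mask": inf.fdr_mask.astype(int).tolist(),
            "mean": inf.mean.tolist(), "se": inf.se.tolist(),
            "blocks": inf.blocks, "q": inf.q, "n_boot": inf.n_boot,
            "n_failed": inf.n_failed, "seed": inf.seed}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one analysis end-to-end and write its result bundle.

    Stages: clinical scoring -> connectivity loading -> outlier screen ->
    NPLS fit -> bootstrap salience inference -> score regressions ->
    (for dti_* analyses) voxelwise PLS with cluster reporting.  Every
    output is JSON/TSV/NIfTI; a MANIFEST records completed stages and a
    run log records seeds and versions.
    """
    cohort = Path(config.cohort_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"analysis": config.analysis, "stages": []}
    run_log = {"version": __version__, "seed": config.seed,
               "n_boot": config.n_boot, "config": dataclasses.asdict(config)}

    def _stage(name: str):
        manifest["stages"].append(name)
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))
        log.info("stage complete: %s", name)

    try:
        clinical = read_clinical(cohort / "clinical.tsv")
        scored, pca = score_table(clinical, n_boot=config.n_boot, seed=config.seed)
        scored.to_csv(out / "scored_clinical.tsv", sep="\t", index=False)
        (out / "cog_pca.json").write_text(json.dumps({
            "loadings": pca.loadings.tolist(),
            "variance_explained": pca.variance_explained,
            "loading_ci": pca.loading_ci.tolist(),
            "variance_ci": list(pca.variance_ci)}, indent=2))
        _stage("clinical_scores")

        lut = read_parcel_lut(cohort / "parcels.tsv")
        insula = lut.loc[lut["is_insula"] == 1, "index"].to_numpy()
        tensor = read_matrices(cohort / "matrices", insula)
        X_all = extract_insula_submatrices(tensor)
        _stage("connectivity")

        rep = detect_outliers(X_all.reshape(len(X_all), -1),
                              alpha=config.outlier_alpha,
                              n_pc=config.outlier_n_pc, seed=config.seed,
                              subjects=tensor.subjects)
        keep = [s not in set(rep.flagged) for s in tensor.subjects]
        (out / "outliers.json").write_text(json.dumps({
            "flagged": rep.flagged, "p": rep.p.tolist(),
            "method": rep.method}, indent=2))
        scored = scored.set_index("subject_id").loc[
            [s for s, k in zip(tensor.subjects, keep) if k]].reset_index()
        X_all = X_all[np.asarray(keep)]
        _stage("outlier_screen")

        if config.analysis == "main_effect":
            y = np.where(scored["group"] == "concussed", 1.0, -1.0)
            if len(np.unique(y)) < 2:
                raise ValueError("degenerate contrast: only one group present")
            X, sub = X_all, scored
        else:
            conc = (scored["group"] == "concussed").to_numpy()
            sub = scored.loc[conc].reset_index(drop=True)
            X = X_all[conc]
            col = "mismatch" if config.analysis.startswith(("mismatch", "dti")) else "severity"
            y = sub[col].to_numpy(float)

        fit_fn = lambda A, b: fit_npls(A, b, K=config.n_components,
                                       center=config.center)
        model = fit_fn(X, y)
        (out / "npls_model.json").write_text(model.to_json())
        _stage("npls_fit")

        inferences = []
        for k in range(config.n_components):
            inf = bootstrap_saliences(fit_fn, X, y, n_boot=config.n_boot,
                                      seed=config.seed + k, q=config.q_fdr,
                                      component=k)
            inferences.append(inf)
        (out / "salience_inference.json").write_text(
            json.dumps([_salience_dict(i) for i in inferences], indent=2))
        _salience_table(inferences[0], lut, out / "significant_parcels.tsv")
        _stage("salience_bootstrap")

        results: dict = {}
        if config.analysis == "main_effect":
            from .clinical import bootstrap_mean_difference
            conc = (scored["group"] == "concussed").to_numpy()
            cmp = bootstrap_mean_difference(model.c_x[conc], model.c_x[~conc],
                                           n_boot=config.n_boot, seed=config.seed)
            results["score_difference_control_minus_concussed"] = dataclasses.asdict(cmp)
        else:
            cov = None
            if config.covariates:
                cov = np.column_stack([
                    sub["age"].to_numpy(float),
                    (sub["sex"] == "F").to_numpy(float),
                    sub["hoc"].astype(float).to_numpy()])
            reg = regress_scores(model.c_x, y, n_boot=config.n_boot,
                                 seed=config.seed, covariates=cov,
                                 outcome_label="network_expression",
                                 predictor_label=config.analysis)
            results["score_regression"] = _regression_dict(reg)
        (out / "regressions.json").write_text(json.dumps(results, indent=2))
        _stage("score_regression")

        if config.analysis in ("dti_fa", "dti_md"):
            metric = "FA" if config.analysis == "dti_fa" else "MD"
            mask_img = nib.load(cohort / "wm_mask.nii.gz")
            mask = np.asarray(mask_img.dataobj) > 0
            maps, missing = read_volumes(cohort / "volumes",
                                         list(sub["subject_id"]),
                                         metric.lower(), mask,
                                         mask_img.affine, metric)
            if missing:
                log.info("excluded %d subjects with missing DTI data", len(missing))
            present = [s in set(maps.subjects) for s in sub["subject_id"]]
            scores = model.c_x[np.asarray(present)]
            dmodel, dinf, clusters, dreg = dti_pls(
                scores, maps, n_boot=config.n_boot, seed=config.seed,
                q=config.q_fdr, min_cluster=config.min_cluster)
            clusters.to_csv(out / f"clusters_{metric.lower()}.tsv",
                            sep="\t", index=False)
            bsr_img = nib.Nifti1Image(maps.unmask(dinf.bsr).astype(np.float32),
                                      maps.affine)
            nib.save(bsr_img, out / f"bsr_{metric.lower()}.nii.gz")
            (out / f"dti_{metric.lower()}.json").write_text(json.dumps({
                "regression": _regression_dict(dreg),
                "n_significant_voxels": int(dinf.fdr_mask.sum()),
                "n_clusters": int(len(clusters)),
                "excluded_missing": missing}, indent=2))
            _stage(f"dti_{metric.lower()}")

        run_log["status"] = "ok"
        return {"manifest": manifest, "out_dir": str(out)}
    except Exception as exc:
        stage = manifest["stages"][-1] if manifest["stages"] else "start"
        run_log["status"] = f"failed after {stage}: {exc}"
        raise
    finally:
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))


def _salience_table(inf, lut: pd.DataFrame, path: Path) -> None:
    """Export FDR-significant whole-brain salience elements with parcel
    names and MNI centers (region / center of mass / BSR columns)."""
    bsr = inf.block("w_x2")
    mask = inf.block("w_x2", inf.fdr_mask)
    rows = []
    for idx in np.where(mask)[0]:
        row = lut.iloc[idx]
        rows.append({"region": row["name"],
                     "mni_x": row["mni_x"], "mni_y": row["mni_y"],
                     "mni_z": row["mni_z"], "bsr": bsr[idx]})
    pd.DataFrame(rows, columns=["region", "mni_x", "mni_y", "mni_z", "bsr"]) \
        .to_csv(path, sep="\t", index=False)
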