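"""Voxelwise diffusion analysis: PLS of FA/MD maps against network
expression scores, with bootstrap-ratio/FDR thresholding, minimum-cluster
filtering, and MNI-space cluster reporting.

FA (fractional anisotropy, unitless in [0, 1]) and MD (mean diffusivity,
mm^2/s) maps are analyzed separately inside a white-matter mask defined by
mean FA > 0.30.  For each metric, a one-response PLS yields a voxel
salience map w_x and per-subject "diffusivity scores" d_s = w_x' x~_s;
voxels surviving FDR thresholding of the salience BSRs are grouped into
face-connected clusters, singletons (below a minimum size of 3) removed,
and the network expression scores regressed on d_s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .inference import RegressionResult, SalienceInference, bootstrap_saliences, regress_scores
from .npls import PLSModel, fit_pls

__all__ = [
    "VoxelMapSet",
    "build_wm_mask",
    "cluster_components",
    "cluster_report",
    "dti_pls",
]

_CONNECTIVITY_STRUCTS = {6: 1, 18: 2, 26: 3}


@dataclass
class VoxelMapSet:
    """Masked voxel data for one diffusion metric.

    ``data`` holds one row per subject of the ``mask.sum()`` in-mask voxel
    values; ``affine`` maps 0-based voxel indices to MNI mm (RAS+).
    """

    subjects: list[str]
    data: np.ndarray          # S x V
    mask: np.ndarray          # 3-d boolean
    affine: np.ndarray        # 4 x 4 voxel -> mm
    metric: str = "FA"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.shape[1] != int(self.mask.sum()):
            raise ValueError("data columns do not match mask voxel count")

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.mask.shape, fill, dtype=float)
        vol[self.mask] = values
        return vol


def build_wm_mask(mean_fa: np.ndarray, threshold: float = 0.30,
                  exclusion_mask: np.ndarray | None = None) -> np.ndarray:
    """White-matter analysis mask: voxels with mean FA strictly above the
    threshold, minus an optional exclusion region."""
    fa = np.asarray(mean_fa, dtype=float)
    if not np.all(np.isfinite(fa)):
        raise ValueError("mean FA volume contains non-finite values")
    mask = fa > threshold
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    if not mask.any():
        raise ValueError("white-matter mask is empty")
    return mask


def cluster_components(mask3d: np.ndarray, min_size: int = 3,
                       connectivity: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component labeling with a minimum-extent filter.

    Returns the labeled volume (labels 1..n in descending size order;
    0 = background) and the sorted cluster sizes.  ``connectivity``
    chooses face (6), face+edge (18) or face+edge+corner (26) adjacency.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask3d = np.asarray(mask3d, dtype=bool)
    struct = ndimage.generate_binary_structure(3, _CONNECTIVITY_STRUCTS[connectivity])
    labeled, n = ndimage.label(mask3d, structure=struct)
    if n == 0:
        return np.zeros(mask3d.shape, dtype=int), np.zeros(0, dtype=int)
    sizes = ndimage.sum_labels(mask3d, labeled, index=np.arange(1, n + 1)).astype(int)
    keep = np.where(sizes >= min_size)[0]
    order = keep[np.argsort(sizes[keep])[::-1]]
    out = np.zeros(mask3d.shape, dtype=int)
    for new, old in enumerate(order, start=1):
        out[labeled == old + 1] = new
    return out, sizes[order]


def cluster_report(labeled: np.ndarray, bsr_map: np.ndarray,
                   affine: np.ndarray, atlas_lut=None):
    """Tabulate clusters: region label, center of mass in MNI mm, volume in
    mm^3 (count x voxel volume), and signed peak BSR (value of maximum
    magnitude).  ``atlas_lut``, if given, is a callable mapping an MNI mm
    coordinate to a region name; otherwise clusters are "unlabeled"."""
    import pandas as pd

    affine = np.asarray(affine, dtype=float)
    lin = affine[:3, :3]
    det = np.linalg.det(lin)
    if det == 0:
        raise ValueError("affine is non-invertible")
    voxel_volume = abs(det)
    rows = []
    for lab in range(1, int(labeled.max()) + 1):
        idx = np.argwhere(labeled == lab)
        com_vox = idx.mean(axis=0)
        com_mm = lin @ com_vox + affine[:3, 3]
        vals = bsr_map[labeled == lab]
        peak = vals[np.argmax(np.abs(vals))]
        region = atlas_lut(com_mm) if atlas_lut is not None else "unlabeled"
        rows.append({
            "cluster": lab,
            "region": region,
            "com_x_mm": com_mm[0], "com_y_mm": com_mm[1], "com_z_mm": com_mm[2],
            "n_voxels": len(idx),
            "volume_mm3": len(idx) * voxel_volume,
            "peak_bsr": float(peak),
        })
    return pd.DataFrame(rows, columns=["cluster", "region", "com_x_mm",
                                       "com_y_mm", "com_z_mm", "n_voxels",
                                       "volume_mm3", "peak_bsr"])


def dti_pls(
    scores: np.ndarray,
    maps: VoxelMapSet,
    n_boot: int = 1000,
    seed: int = 0,
    q: float = 0.05,
    min_cluster: int = 3,
    connectivity: int = 6,
    atlas_lut=None,
) -> tuple[PLSModel, SalienceInference, "pd.DataFrame", RegressionResult | None]:
    """Voxelwise PLS of a diffusion metric against network expression scores.

    Fits a one-response PLS with Y = scores, bootstraps the voxel saliences
    (BSR, normal-theory p, joint BH-FDR at ``q``), keeps surviving voxels in
    face-connected clusters of at least ``min_cluster`` voxels, and, when
    any survive, regresses the network scores on the diffusivity scores
    d_s.  Returns (model, salience inference, cluster table, regression or
    None).
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(maps.subjects):
        raise ValueError("score vector does not match subject count")

    model = fit_pls(maps.data, scores, K=1)
    inf = bootstrap_saliences(lambda X, Y: fit_pls(X, Y, K=1), maps.data,
                              scores, n_boot=n_boot, seed=seed, q=q)
    sig_vol = maps.unmask(inf.fdr_mask.astype(float)) > 0.5
    labeled, _ = cluster_components(sig_vol, min_size=min_cluster,
                                    connectivity=connectivity)
    bsr_vol = maps.unmask(inf.bsr)
    table = cluster_report(labeled, bsr_vol, maps.affine, atlas_lut)

    if labeled.max() == 0:
        return model, inf, table, None
    d = model.c_x  # diffusivity scores of the training subjects
    reg = regress_scores(scores, d, n_boot=n_boot, seed=seed,
                         outcome_label="network_expression",
                         predictor_label=f"diffusivity_{maps.metric.lower()}")
    return model, inf, table, reg
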