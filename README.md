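# insulanet

Brain–behavior analysis of insular functional connectivity and the
self-appraisal of cognitive function after sport-related concussion.

After a concussion, the severity of self-reported cognitive symptoms often
correlates only weakly with measured performance on timed neurocognitive
tests. This *appraisal mismatch* — over- or under-reporting of cognitive
issues relative to objective performance — is clinically important, and the
insula, a hub for interoception and self-monitoring, is a natural candidate
substrate. `insulanet` implements, as a tested and reusable pipeline, a
multivariate analysis linking insula-to-whole-brain functional connectivity
to clinical variables, together with a synthetic cohort generator that
plants known effects so every stage can be validated without access to
clinical data.

## The model

Each subject *s* contributes a 12 × 246 submatrix **X**ₛ of Pearson
correlations between the 12 insular subregions of a 246-parcel whole-brain
atlas and all parcels, plus a clinical value *y*ₛ — either group coding
(−1 = control, +1 = concussed; a discriminant model) or a composite score.
N-way partial least squares (NPLS) finds unit-norm weight vectors: an
insular salience **w**ˣ¹ (12), a whole-brain salience **w**ˣ² (246) and a
behavioral weight **w**ʸ maximizing

cov(*c*ₛˣ, *c*ₛʸ),  *c*ₛˣ = **w**ˣ¹ᵀ **X**ₛ **w**ˣ²,  *c*ₛʸ = **y**ₛᵀ **w**ʸ,  ‖**w**ˣ¹‖ = ‖**w**ˣ²‖ = ‖**w**ʸ‖ = 1,

by alternating least squares, with later components kept orthogonal to
earlier weight vectors. *c*ₛˣ is the subject's *network expression score*.
Inference is by bootstrap resampling of subjects: each weight element gets a
bootstrap ratio (BSR = bootstrap mean / bootstrap SE, treated as
z-distributed) and the resulting p-values are thresholded by
Benjamini–Hochberg FDR at q = 0.05.

Clinical composites: SYM is the sum of the six cognition-related items of a
22-item symptom checklist (0–6 Likert each); COG is the first principal
component of four timed subtests (SRT, CRT, TMT-A, TMT-B) after a
rank-based inverse-normal transform (larger = slower). Both are mapped to
normal scores z(SYM), z(COG) over the concussed cohort, giving the
orthogonal composites *severity* = z(SYM) + z(COG) and *mismatch* =
z(SYM) − z(COG); positive mismatch means symptom over-reporting.

A voxelwise PLS follow-up relates network expression scores to diffusion
FA/MD maps inside a white-matter mask (mean FA > 0.30), with BSR/FDR
thresholding, removal of clusters below 3 face-connected voxels, and
cluster reporting (center of mass in MNI mm, volume, signed peak BSR).

## Worked example

```python
import numpy as np
from insulanet import CohortSpec, simulate_clinical, simulate_connectivity, fit_npls
from insulanet.clinical import score_table
from insulanet.inference import bootstrap_saliences, regress_scores

spec = CohortSpec(seed=42)                     # 136 controls + 59 concussed
clinical = simulate_clinical(spec)
tensor, truth = simulate_connectivity(spec, clinical)
scored, pca = score_table(clinical, n_boot=1000, seed=42)
print(np.round(pca.loadings, 3), f"{100*pca.variance_explained:.1f}%")

conc = (scored.group == "concussed").to_numpy()
mismatch = scored.loc[conc, "mismatch"].to_numpy()
model = fit_npls(tensor.submatrices[conc], mismatch)
reg = regress_scores(model.c_x, mismatch, n_boot=1000, seed=42)
print(f"b={reg.slope:.3f} CI=({reg.ci_low:.3f},{reg.ci_high:.3f}) "
      f"BSR={reg.bsr:.2f} p={reg.p_empirical:.3f} R2={reg.r_squared:.3f}")
```

prints

```
[0.528 0.502 0.465 0.503] 57.4%
b=0.351 CI=(0.136,0.604) BSR=3.05 p=0.006 R2=0.103
```

The COG composite loads positively on all four subtests and carries ~57% of
their covariance. Within the concussed group, the fitted network expression
score rises with the appraisal-mismatch composite (b = 0.351, bootstrap
p = 0.006): over-reporters express more of the identified insular
subnetwork, under-reporters less. On this cohort the in-sample R² is 0.103
— a modest association, by design of the generator's default conditions.

The same analyses run from the shell:

```bash
insulanet simulate --out cohort/ --seed 42
insulanet fit --analysis mismatch --cohort-dir cohort/ --out results/ --n-boot 1000
insulanet dti --metric fa --cohort-dir cohort/ --out results_fa/
insulanet report results/
```

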