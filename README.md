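# gblica

Linked independent component analysis (linked ICA) of large-scale brain
network connectivity and gut microbiome composition.

Studies of the gut–brain axis usually correlate one microbiome summary with
one brain measure at a time. `gblica` implements the multivariate
alternative: subject-specific resting-state network maps (obtained by dual
regression of canonical network templates against each subject's fMRI) and
a genus-level relative-abundance table are **jointly** factorized into
components that share a single subject-loading matrix, so each component
expresses a coupled pattern of inter-individual variation across brain
networks and gut genera. The package is aimed at researchers who want to
run, or stress-test on synthetic cohorts with known ground truth, this kind
of multimodal decomposition end to end.

## The model

Each standardized modality `X_k` (features × subjects; voxel z-maps for
each network, proportions for the genus table) is modeled as

```
X_k = S_k diag(λ_k) H + E_k ,     E_k ~ N(0, 1/β_k)
```

with one **shared** subject-loading matrix `H` (components × subjects,
unit-norm rows), per-modality source maps `S_k` (unit-norm columns),
non-negative component weights `λ_k` and modality noise precisions `β_k`.
Source entries carry a sparsity-inducing mixture-of-Gaussians prior (narrow
spike + wide slab, parameters estimated per modality and component); this
non-Gaussianity is what turns the otherwise rotation-ambiguous
factorization into an ICA, and it shrinks `λ_k,c → 0` in modalities a
component does not explain (automatic relevance determination). Fitting is
variational EM with a monotone objective; see `docs/methods.md`.

For each component, the modality contribution fraction is
`P[k,c] = λ_k,c² / Σ_k' λ_k',c²`. Components are carried forward when both
the microbiome fraction and the summed brain fraction exceed 0.2, then
screened for two artifacts: loading rows dominated by a single subject, and
spatially constant source maps. Surviving loadings are standardized within
column and displayed above |z| > 3 (brain) and |z| > 2.3 (genera).

## Worked example

```python
import numpy as np
import gblica
from gblica.evaluate import match_components

cohort = gblica.make_joint_dataset(seed=0)   # 40 subjects, 2 networks of
                                             # 6x6x6 voxels, 30 genera,
                                             # 3 planted components
inp = gblica.standardize_modalities(cohort.modalities,
                                    cohort.modality_names,
                                    cohort.subject_ids)
model = gblica.fit_lica(inp, n_components=3, seed=0)
perm, r = match_components(model.H, cohort.truth.H)
print("matched |r|:", np.round(r, 3))
print("contributions:\n", np.round(gblica.contribution_fractions(model).P, 3))
```

prints

```
matched |r|: [1. 1. 1.]
contributions:
 [[0.457 0.456 0.458]
 [0.478 0.479 0.477]
 [0.065 0.065 0.065]]
```

Every planted loading row is recovered (absolute correlation 1.0 after
matching), and each component's explained variance splits across the two
network modalities and the genus modality close to the planted shares
(the genus modality carries 30 of 462 standardized features, hence ~6.5%).

The same flow runs from the shell:

```bash
gblica simulate --out cohort --seed 0          # writes NIfTI + TSV + config
gblica run --config cohort/config.yaml         # prep -> dualreg -> fit -> report
cat cohort/run/report/digest.txt
```

The run directory contains the shared loadings (`H.tsv`), weights
(`lambda.tsv`), contribution fractions (`P.tsv`), genus loadings, brain
source maps as NIfTI, and a per-component digest with QC flags.

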