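# connparc

Connectivity-based parcellation of an anatomical mask from resting-state
fMRI, with single-subject back-projection, probabilistic atlases, and
permutation-based group inference.

## The problem

Seed-based resting-state analyses live or die by seed placement: a 4 mm
sphere dropped on a literature coordinate can sit on the edge of the
functional region it is meant to sample, diluting the network signal and
hiding group differences. `connparc` implements a data-driven
alternative: partition the anatomical region of interest into subregions
with distinct *connectivity fingerprints*, check how well the group-level
partition replicates in each individual, and use the resulting
probabilistic maps — rather than spheres — as seeds for group inference.

The pipeline:

1. **Preprocess** each subject's 4D series: scrub volumes with framewise
   displacement FD > 0.5 mm or DVARS > 0.5 % of the mean signal, regress
   the Friston 24-parameter motion expansion plus the first 3 principal
   components of white matter and CSF, band-pass 0.009–0.2 Hz.
2. **Fingerprints.** For every voxel *i* in the seed mask and every
   grey-matter voxel *j*, compute z(i,j) = atanh r(i,j), the Fisher-z
   Pearson correlation of their time courses. A fixed-effects group
   matrix is the voxelwise mean of the z matrices, mapped back to r.
3. **Parcellate.** Average-linkage hierarchical clustering of seed
   voxels under correlation distance (1 − Pearson r between fingerprint
   rows). The dendrogram is cut at many uniform height levels; each
   level's labeling is scored on every subject's own fingerprints with
   the mean silhouette s(i) = (b−a)/max(a,b), and a one-sample t across
   subjects rates each level. Local maxima of the t profile are the
   candidate cluster numbers K.
4. **Back-project and match.** Each subject is re-clustered at the group
   K; group and subject clusters are matched by average-linkage
   clustering of the Dice-overlap matrix (scanning all cut heights for
   the one maximising one-group-one-subject pairs — no minimum-overlap
   cutoff). Matched subject clusters are binarised and summed into
   per-cluster probability maps; thresholding (25 %) plus
   winner-take-all assignment gives the final atlas.
5. **Group statistics.** Seed-to-voxel Fisher-z maps enter a GLM with
   scanning centre, mean FD, IQ, log(age), group, Group × log(age) and
   (optionally voxel-dependent) grey-matter density with Group × GM.
   Inference is by Freedman–Lane subject permutation restricted within
   scanning centre, with max-statistic voxelwise FWE and
   max-cluster-extent FWE (forming threshold |Z| > 3.1).

A synthetic-phantom module generates multi-subject cohorts with known
parcels, known network targets, motion spikes and a planted
Group × Age connectivity slope difference, so every stage can be
validated against ground truth.

## Worked example

```python
import numpy as np
from connparc import (CohortSpec, default_phantom_spec, make_cohort,
                      mask_to_gm_matrix, group_fixed_effects,
                      FingerprintParcellation)
from sklearn.metrics import adjusted_rand_score

spec = CohortSpec(n_per_group=10, phantom=default_phantom_spec(seed=7))
subjects, covariates, truth = make_cohort(spec)
mats = [mask_to_gm_matrix(bold.data, masks.seed, masks.gm, subject_id=sid)
        for (bold, masks, _, _), sid in zip(subjects,
                                            covariates["subject_id"])]
model = FingerprintParcellation(n_levels=100)
model.fit(group_fixed_effects(mats), subject_matrices=mats)
print("chosen K:", model.n_clusters_)
print("silhouette-t maxima at K:",
      [int(model.profile_.k_per_level[i])
       for i in model.profile_.local_maxima])
print("adjusted Rand vs ground truth:",
      adjusted_rand_score(truth.parcel_labels, model.labels_))
```

prints

```
chosen K: 6
silhouette-t maxima at K: [6]
adjusted Rand vs ground truth: 1.0
```

i.e. on a 20-subject phantom with 6 planted parcels (latent coupling
0.7, unit voxel noise, 200 volumes), the silhouette-t profile has a
single local maximum at K = 6 and the selected labeling matches the
planted partition exactly.

The same workflow is available from the shell:

```
connparc init-config cfg.json
connparc run-all --config cfg.json --output-dir work --seed 7
```

which writes the atlas (`atlas_wta.nii`, per-cluster probability
volumes), the match report (replication % and Dice per cluster) and the
GLM statistic maps into `work/`.

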