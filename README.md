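# voxsal

Explainable 3D-CNN saliency analysis of volumetric brain images.

Deep 3D classifiers can separate patient from control structural MRI, but a
bare accuracy number says nothing about *where* in the brain the decision
comes from. `voxsal` implements the full analysis chain that turns a 3D
convolutional classifier into regional, network-level and clinical
statements:

1. **Classifier** — a truncated 3D residual network (12 learnable layers,
   4.7M parameters vs 33.2M for the full 18-layer plan) whose 3D kernels
   can be built by replicating 2D kernels along the depth axis ("weight
   inflation"), trained with k-fold cross-validation, harmonization
   augmentation (random blur, 2% intensity drop, uniform noise) and the
   published hyperparameter set.
2. **Saliency** — GradCAM on held-out subjects: channel weights
   `W_c = (1/N) Σ_xyz ∂y^h/∂A^c`, map `M = ReLU(Σ_c W_c A^c)` upsampled to
   the input grid, computed for each subject by the fold that never saw
   them, on the class channel the model predicts.
3. **Parcellation** — probability-weighted regional scores
   `score_a = Σ_v p_a(v) M(v) / Σ_v p_a(v)` over a probabilistic atlas,
   aggregated to lobe and class profiles with 95% intervals.
4. **Statistics** — misclassification exclusion, inter-fold regression,
   pairwise Kendall tau-b with significance filtering, per-area node
   scores `NS(a) = Σ_{b≠a} τ_{a,b}·[p < 0.05]`, intra-network versus
   brain-wide correlation contrast, and saliency–clinical-score
   association (motor score, cognition, medication dose, disease
   duration).
5. **Synthetic cohorts** — because the target data class is
   access-restricted, a seeded generator produces phantom atlases and
   volumes with planted regional deficits scaled by a latent severity,
   network-correlated effect factors, heterogeneous blur/noise, and
   clinical scores linearly coupled to severity, so the entire pipeline is
   testable offline.

Inputs and outputs use standard formats throughout: NIfTI volumes, a 4D
NIfTI + TSV probabilistic atlas, CSV subject/score tables.

## Worked example

```python
import numpy as np
from voxsal import (
    ArchitectureSpec, build_model, count_parameters, resnet18_3d_spec,
    make_atlas, recovery_spec, make_cohort, TrainingConfig, cross_validate,
    evaluate, reduced_spec,
)
from voxsal.saliency import holdout_maps
from voxsal.parcellation import regional_matrix, class_profiles
from voxsal.stats import exclude_misclassified

print(f"truncated: {count_parameters(build_model(ArchitectureSpec())) / 1e6:.1f}M parameters")
print(f"full 18-layer: {count_parameters(build_model(resnet18_3d_spec())) / 1e6:.1f}M parameters")

atlas = make_atlas(n_areas=12, grid_shape=(16, 16, 16), n_networks=4, seed=0)
spec = recovery_spec(atlas, seed=0, n_per_class=10)   # effect planted in network "net0"
subjects, volumes = make_cohort(spec, atlas)
models, folds, fold_stats = cross_validate(
    subjects, volumes, TrainingConfig(seed=0), reduced_spec(), k=4
)
pooled = evaluate([s.true_class for s in subjects], [s.predicted_class for s in subjects])
print(f"held-out accuracy over {len(subjects)} subjects: {pooled.accuracy:.2f}")

maps = holdout_maps(models, folds, subjects, volumes)
retained, report = exclude_misclassified(subjects)
print(f"excluded {report['PD']} PD and {report['CT']} CT misclassified subjects")
matrix = regional_matrix(maps, atlas).loc[[s.id for s in retained]]
profiles = class_profiles(matrix, retained)
print(profiles.loc["PD"]["mean"].sort_values(ascending=False).head(3))
```

prints

```
truncated: 4.7M parameters
full 18-layer: 33.2M parameters
held-out accuracy over 20 subjects: 0.70
excluded 4 PD and 2 CT misclassified subjects
area000_fron_R    1.743
area004_limb_R    1.177
area007_temp_L    1.006
```

Two of the three areas the generator planted the deficit in (`area000`,
`area004`; members of `net0`) top the patient-class saliency profile even
at this miniature scale — the mean-1 map normalization makes 1.0 the
"average importance" baseline. At the reference desk scale (60 subjects,
32³ volumes) accuracy reaches 0.77–0.88 and planted-area recovery is
substantially sharper; `voxsal.pipeline.run_recovery(seed)` runs that
configuration end to end and reports ranks, associations and network
contrasts.

The same pipeline is scriptable from a shell via the `voxsal` CLI
(`simulate`, `train`, `saliency`, `score`, `stats` subcommands); pass
`--help` to any of them for the file-level interface.

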