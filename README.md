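# seg2fe

Statistical-shape-model adjustment of automatic bone segmentations and
hexahedral cartilage meshing for knee finite-element (FE) models.

Automatic knee-MRI segmentation networks produce voxel masks of the femur
and tibia whose surfaces carry staircase roughness, speckles and holes —
usable for overlap scores, but not for FE meshing. This toolkit implements
the post-processing side of a semi-automated segmentation-to-FE workflow:

1. **Statistical shape model (SSM).** Dense correspondence is established
   between a template bone surface and a population of training surfaces
   (coarse moment alignment, coherent-point-drift rigid registration, and a
   multiscale coherent closest-point transport), rigid differences are
   removed by generalized Procrustes analysis, and PCA yields the linear
   point-distribution model `Shape = M + PC · b` with mean `M`, orthonormal
   modes `PC`, and mode weights `b`.
2. **Segmentation adjustment.** The SSM is fitted to the marching-cubes
   surface of a binary mask by alternating pose and regularized mode-weight
   updates with a ±3σ plausibility clamp, producing a smooth, hole-free,
   anatomically plausible surface with the template's tessellation.
3. **Evaluation metrics.** Dice similarity coefficient, symmetric Hausdorff
   distance, average surface distance, and the percentage of surface area
   displaced by more than 1 mm.
4. **Cartilage extrusion.** The bone–cartilage contact patch is meshed with
   quadrilaterals and swept to the articular surface as 5 layers of 8-node
   hexahedra (Abaqus C3D8P) with conforming interface nodes, plus scaled-
   Jacobian quality checks and INP export.
5. **1-D statistical parametric mapping (SPM).** Two-sample t-tests over
   stance-phase trajectories of mechanical outputs, with the family-wise
   error controlled by a random-field-theory threshold at α = 0.05.

A synthetic-data module generates everything needed to exercise the
pipeline without clinical data: a distal-femur-like shape population with
known latent modes, degraded masks emulating network output (noise, holes,
boundary misclassification; 0.36 × 0.36 × 0.7 mm MRI-like grids available
as a preset), articular surfaces, and smooth trajectory ensembles.

## Worked example

Build a model from a synthetic population, degrade one held-out shape into
a mask the way an automatic segmentation would see it, and adjust it:

```python
import numpy as np
from seg2fe import mesh_core, metrics, ssm, synthetic_data as sd

template = sd.synth_bone(11.0, 24.0, 9.0)
meshes, _ = sd.synth_population(sd.PopulationSpec(n_shapes=30, seed=7))
cfg = ssm.CorrespondenceConfig(n_points=600)
model, aligned = ssm.build_from_meshes(template, meshes, cfg, variance_fraction=0.95)
print(f"{model.n_modes} modes retain 95% of variance over {model.n_training} shapes")

rng = np.random.default_rng(0)
b_true = rng.uniform(-2, 2, model.n_modes) * model.sigmas
truth = ssm.instance_mesh(model, ssm.ssm_instance(model, b_true))
mask = sd.synth_degrade(truth, sd.DegradationSpec(seed=1))   # noisy, holed mask
raw = mesh_core.mask_to_surface(mask)                        # marching cubes
fit = ssm.ssm_fit(model, raw)                                # SSM adjustment

for name, mesh in (("raw", raw), ("adjusted", fit.fitted_mesh)):
    d = metrics.surface_distances(mesh, truth)
    print(f"{name:9s} average {d.average:.3f} mm, Hausdorff {d.hausdorff:.2f} mm")
```

which prints

```
2 modes retain 95% of variance over 30 shapes
raw       average 0.197 mm, Hausdorff 2.10 mm
adjusted  average 0.028 mm, Hausdorff 0.11 mm
```

The raw marching-cubes surface sits ~0.2 mm from the truth with a 2.1 mm
worst-case error at the carved holes; the model adjustment removes the
holes and staircase noise, cutting both numbers by an order of magnitude.

The same workflow is available from the shell:

```bash
seg2fe synth --n-shapes 10 --out synthetic/       # population + masks
seg2fe build-ssm template.ply sample_*.ply --out model.h5
seg2fe adjust degraded.nii.gz model.h5 --out adjusted.ply
seg2fe metrics adjusted.ply ground_truth.ply
seg2fe extrude bone.ply cartilage.ply --out cartilage.inp
seg2fe spm trajectories.csv --parameter fluid_pressure --zone deep
seg2fe run config.yaml                            # full pipeline
```

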