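# voxelgeom

How do the **size** and **shape** of an MRI voxel limit the accuracy with
which small brain nuclei can be labeled?  Structures such as the subthalamic
nucleus (STN, ~130 mm³) and the internal globus pallidus (GPi, ~380 mm³) are
routinely delineated on scans whose voxels — often anisotropic, with slices
several times thicker than the in-plane resolution — are a substantial
fraction of the structure itself.  The partial volume effect (PVE) then blurs
every border, and both the measured volume and the recovered shape drift away
from the truth.

`voxelgeom` quantifies that drift by simulation, for researchers planning
acquisition protocols for subcortical volumetry and for methodologists
studying segmentation accuracy.  It provides:

* **Analytic phantoms** (`voxelgeom.phantom`) — triaxial ellipsoids whose
  continuous Fourier transform is known in closed form.  For a unit-intensity
  ellipsoid with semi-axes *(a, b, c)*, volume *V*, rotation *R* and centre
  *t*, the k-space signal at frequency **k** is

  $$F(\mathbf{k}) = V\,\frac{3\,(\sin u - u\cos u)}{u^{3}}\;
  e^{-2\pi i\,\mathbf{k}\cdot \mathbf{t}},\qquad
  u = 2\pi\,\lVert(a k'_x,\; b k'_y,\; c k'_z)\rVert,\;
  \mathbf{k}' = R^{\mathsf T}\mathbf{k},$$

  evaluated exactly on the discrete k-grid of any anisotropic Cartesian
  acquisition and reconstructed by inverse DFT — producing noise-free images
  with the same PVE and Gibbs ringing as a real scan at that voxel geometry.
  A brute-force rasterization oracle provides an independent cross-check.
* **Simulated raters** (`voxelgeom.raters`) — the labeling decision is a
  logistic psychometric curve in voxel intensity,
  $P(\text{label}\mid i) = 1/(1+e^{-(\beta_0+\beta_1 i)})$, fitted from
  (intensity, label) tables by maximum likelihood, applied stochastically or
  deterministically; a conservative *joint* rater intersects two masks; and
  an *optimal* rater thresholds at the intensity whose suprathreshold
  proportion matches the object's known proportional volume.
* **Metrics** (`voxelgeom.metrics`) — mask volumes, signed percentage
  deviation from truth, nearest-neighbor upsampling to a common 0.1 mm grid
  (volume-preserving, including the odd-matrix slice counts), and the Dice
  coefficient $\mathrm{DCS} = 2|A\cap B|/(|A|+|B|)$ against the variant's
  high-resolution optimal-rater reference.
* **The experiment** (`voxelgeom.experiment`) — the full factorial design
  (rigid-body variants x 3 orientations x 5 in-plane sizes x 6 thickness
  factors), per-cell accuracy summaries, the equal-voxel-volume
  isotropic-vs-anisotropic comparison, an exponential Dice-vs-deviation
  curve, and a guideline table flagging which voxel geometries stay in the
  ideal (DCS > 0.90) and acceptable (DCS > 0.75) ranges.

## Worked example

```python
import voxelgeom as vg

# a 164.9 mm^3 ellipsoid (the size of a DBS target), tilted 45 degrees to
# the slice axis, acquired at 1.0 x 1.0 mm in-plane with 3.0 mm slices
ell = vg.default_ellipsoid()
pose = vg.base_orientation("diagonal")
grid = vg.GridSpec(fov=(36.0, 36.0, 36.0), in_plane=1.0, thickness_factor=3.0)
img = vg.reconstruct(vg.analytic_kspace(ell, pose, grid))

# optimal labeling at acquisition resolution vs. the 0.1 mm reference
ref_grid = vg.GridSpec((36.0, 36.0, 36.0), 0.1, 1.0)
ref = vg.optimal_label(vg.reconstruct(vg.analytic_kspace(ell, pose, ref_grid)), ell)
labeled = vg.optimal_label(img, ell)
rec = vg.evaluate_mask(labeled.mask, ell.volume, ref.mask)
print(f"truth {ell.volume:.1f} mm^3, labeled {rec.labeled_volume:.1f} mm^3, "
      f"deviation {rec.pct_deviation:+.1f}%, Dice {rec.dcs:.3f}")
```

prints

```
truth 164.9 mm^3, labeled 162.0 mm^3, deviation -1.8%, Dice 0.794
```

Even a rater that recovers the *volume* almost perfectly (−1.8%) recovers the
*shape* poorly at this geometry (Dice 0.79): with 3 mm slices across a 10.8 mm
long diagonal structure, the labeled mask is nearly the right size but the
wrong shape.  The same comparison at 0.2 mm isotropic voxels gives a
deviation of +0.00% and Dice 0.979.

A small factorial run from the shell:

```bash
voxelgeom run --variants 3 --in-plane 0.5 --in-plane 2.0 --rater optimal \
    --rater joint --seed 7 --out trials.csv
voxelgeom summarize --results trials.csv
voxelgeom guidelines --results trials.csv
voxelgeom literature          # packaged STN/GPi volume table
```

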