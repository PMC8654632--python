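# Methods

## The model

`spacems` treats a binary white-matter lesion mask as a 3-D point cloud:
the world-millimetre positions **r**ᵢ of its foreground voxels, obtained by
applying the NIfTI affine to the 0-based integer voxel indices (indices
address voxel centres; no half-voxel shift). Two families of metrics
summarise that cloud.

### Covariance-tensor shape metrics

The centred population covariance of the positions,

    C = (1/N) Σᵢ (rᵢ − r̄)(rᵢ − r̄)ᵀ      [mm²],

is decomposed into eigenvalues u₁ ≥ u₂ ≥ u₃ ≥ 0. Four rotation- and
translation-invariant scalars follow:

| metric | formula | range | meaning |
|---|---|---|---|
| MCI | (u₁+u₂+u₃)/3 | [0, ∞) mm² | total spatial spread |
| CAI | √(3/2)·‖u−ū‖/‖u‖ | [0, 1] | one dominant direction (prolate) |
| CPI | 2(u₂−u₃)/(u₁+u₂+u₃) | [0, 1] | spread confined to a plane (oblate) |
| CSI | 3u₃/(u₁+u₂+u₃) | [0, 1] | spread equal in all directions |

CAI is the fractional-anisotropy formula of diffusion-tensor MRI applied to
the covariance eigenvalues. Under uniform scaling by s, MCI scales by s²
and the three shape indices are unchanged; all four are invariant to rigid
motion. These invariances are asserted numerically at 1e-9 in the tests.

**Centred vs uncentred.** A raw second moment E[r rᵀ] would mix spread with
head position in the scanner and destroy translation invariance, so the
centred covariance is the default; the uncentred moment and the sample
(1/(N−1)) normalisation remain available through
`covariance_tensor(centred=..., ddof=...)` for audit. At realistic voxel
counts the 1/N-vs-1/(N−1) difference is far below the metric tolerances.

### Neuraxis caudality

The neuraxis is the segment from the centre of mass of the unified
bilateral supplementary motor areas (r_SMA) to the centre of mass of the
brainstem (r_BS). For any voxel set with centre of mass r_mask,

    NCI = (r_mask − r_SMA)·(r_BS − r_SMA) / ‖r_BS − r_SMA‖²,

i.e. 0 at the SMA level and 1 at the brainstem level; division by the
squared axis length normalises out head size, so NCI is invariant to rigid
motion and uniform scaling of the whole geometry. NCI is mathematically
unbounded; values outside the anatomically plausible band [0, 1.5] are
logged as warnings, never errors. The *maximum lesion NCI* is the NCI of
the lowermost individual lesion, defined as the lesion whose centre of mass
projects farthest along the axis — a definition that, unlike a raw minimum
world-z, does not depend on how the head was oriented in the scanner. Ties
are broken towards the smallest lesion ID.

## Lesion identity

Individual lesions are connected components of the binary mask. Adjacency
is parameterised by the maximum number of orthogonal hops between
neighbours (1 = 6-neighbourhood, 2 = 18, 3 = 26); the default is the full
26-neighbourhood. Components are labelled with `scipy.ndimage.label` and
then renumbered by the raster position of each component's first voxel, so
identical input yields byte-identical labels. Connectivity is defined on
the voxel grid, not in millimetres — on strongly anisotropic grids a
"neighbour" in index space can be 3 mm away along one axis and 1 mm along
another; inputs resampled to near-isotropic resolution avoid the issue.

Longitudinal identity uses the *all-timepoints merged image*: the voxelwise
union of a subject's masks across timepoints is labelled once, and each
timepoint mask inherits the union label at every foreground voxel. Two
lesions that are separate at baseline but bridged by later lesional tissue
therefore share a single ID at **all** timepoints, including baseline, and
the per-timepoint lesion count is stable under merging. Timepoint masks
are required to share the grid and affine (within 1e-3 mm elementwise);
no registration is attempted — inputs must arrive rigidly aligned.

## Degenerate inputs and numerical choices

- A single-voxel lesion has zero covariance: MCI = 0 and CAI/CPI/CSI are
  0/0. They are reported as NaN with `degenerate_flag=True`, never silently
  as 0.
- Symmetric eigensolvers can emit tiny negative eigenvalues; values down to
  −1e-9·u₁ are clamped to zero, anything lower raises, as it indicates
  corrupt input rather than round-off.
- CAI is clipped at 1.0 to absorb last-ulp overshoot at the (a, 0, 0)
  extreme.
- An empty lesion mask at some timepoint is legitimate: the pipeline emits
  a whole-brain row with `n_voxels=0`, all metrics NaN and the degenerate
  flag set, and continues. Empty SMA or brainstem masks are errors, and
  coincident SMA/brainstem centres (< 1e-6 mm apart) raise a
  degenerate-neuraxis error.
- When both sform and qform are present in a NIfTI header the sform wins;
  probabilistic masks are binarized at value > 0.5 by default.

## The phantom generator

Phantoms provide ground truth without imaging data. Lesions are solid
ellipsoids — chosen because a uniformly filled ellipsoid with semi-axes
a ≥ b ≥ c has position covariance R·diag(a², b², c²)/5·Rᵀ, a closed form
that makes every shape metric analytically checkable. Each lesion is
placed at a programmed fraction along a synthetic neuraxis (0 = SMA blob,
1 = brainstem blob), which is the ground truth for its NCI. SMA and
brainstem are 4 mm-radius spheres. A `present_from_timepoint` per lesion
produces growth/appearance/merging series for the longitudinal machinery.
Rasterization keeps the voxels whose *centres* fall inside the ellipsoid,
so recovered eigenvalues converge to the closed form as resolution grows;
at semi-axes ≥ 5 voxels they agree within 5 % relative error (tested).

The random cohort (`random_cohort`) draws, per subject, 1–5 lesions with
semi-axes 2–10 mm, uniform random orientations, and axial fractions
0.05–1.1 on a 96³ 1 mm grid — sizes chosen so the whole validation suite
runs on a laptop in seconds while spanning the metric space from needle to
sphere and from rostral to caudal. Everything is driven by one
`numpy.random.default_rng` seed and is byte-reproducible.

What the phantoms deliberately omit: realistic (non-ellipsoidal) lesion
shapes, partial-volume / probabilistic masks, scanner noise, segmentation
and registration error, and real neuroanatomy. Passing phantom tests
demonstrates that the geometry and metric algebra are correct, not that
upstream segmentation is robust.

## Scope and limitations

- All MRI pre-processing (segmentation, co-registration, resampling, lesion
  filling, parcellation) is out of scope; masks must arrive binarized and
  aligned in one shared space. `spacems validate` checks only that
  contract.
- Voxels are weighted uniformly; no intensity or probability weighting.
- Metrics are computed in whatever space the inputs share; the
  `--space-tag` label is carried into the output so native-space and
  common-space runs can be compared by invoking the tool twice.
- Per-lesion metrics are off by default (`--per-lesion` enables them);
  whole-brain metrics are the primary output.
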