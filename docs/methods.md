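# Methods

This note documents the models implemented in `chromadist`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer should know about.
All empirical statements below refer to quantities the test suite or
`scripts/acceptance.py` compute.

## Coordinate convention

All positions exchanged between modules are physical coordinates in
nanometers, ordered (x, y, z); intensity arrays are indexed (z, y, x).
The origin is the *center* of voxel (0, 0, 0) with 0-based indices, so
voxel (iz, iy, ix) has its center at (ix·vx, iy·vy, iz·vz). Confocal
voxels are strongly anisotropic (default 103.8 × 103.8 × 250 nm), so any
geometry done in voxel units would be wrong; voxel indices exist only at
the IO boundary. The configured voxel size always overrides TIFF metadata,
because resolution tags are written inconsistently across acquisition
software.

## Detection

The default detector is a scale-matched Laplacian of Gaussian: the stack
is filtered with `-gaussian_laplace` at per-axis sigmas equal to the
expected spot sigma divided by the voxel size on that axis (so the filter
is matched despite anisotropy), and local maxima of the response are
thresholded. Defaults: expected sigma (130, 300) nm lateral/axial, roughly
a confocal PSF for red/far-red dyes at NA 1.4 (see below).

The automatic threshold is `median(response) + k·MAD` with k = 8. This is
deliberately conservative: in noisy FISH images false positives are the
dominant detection failure mode, and false negatives only reduce yield
(pair counts per image), whereas false positives corrupt the pairing and
the correction fits. Maxima closer than `min_separation_nm` (default
500 nm) keep only the strongest, with exact response ties broken toward
the lexicographically smallest voxel index for determinism.

Detection is done directly in 3D rather than per-plane with subsequent
volume assembly; at the candidate-contract level (stack in, voxel
candidates out) the two are equivalent, and 3D is simpler. The detector
sits behind a minimal interface (`detect(stack) -> candidates`) so a
learned detector can be substituted: `ExternalCandidateAdapter` serves
coordinates produced by any external model through the same contract,
and external nuclei label volumes are accepted as TIFF.

Nuclei segmentation (for the optional in-nucleus gate) is Gaussian
smoothing (default 1 µm), Otsu threshold, per-plane hole filling, removal
of components below `min_volume_nm3` (default 1 µm³), and 26-connected
labeling. It is a classical stand-in adequate for bright nuclear
counterstains; it is not expected to match a trained segmenter on dim or
crowded nuclei.

## Sub-pixel localization

Each candidate is refined by least squares of

    I(x, y, z) = B + A · exp(−(dx² + dy²)/(2 σ_xy²) − dz²/(2 σ_z²))

over a crop around the candidate, evaluated at voxel centers in physical
units (`scipy.optimize.least_squares`, trf, bounded). The lateral sigma is
shared between x and y — confocal PSFs are laterally isotropic to a good
approximation — with a separate axial sigma; 7 parameters total keeps the
fit stable on the 5–7-voxel crops the detector's minimum separation
allows.

Initial sigmas come from the standard paraxial Gaussian-PSF approximation
σ_xy = 0.225·λ/NA, σ_z = 0.78·λ·n/NA², or from configuration. Crop
half-size defaults to 4× the initial sigma per axis (≥ 3 voxels): > 99.9%
of the spot mass while excluding neighbors at the detector's minimum
separation. Bounds: center inside the crop; sigmas within [0.5×, 3×] the
initial estimate (fits wandering onto neighbors are rejected by bounds
rather than silently accepted); amplitude positive; background
non-negative. Initialization: candidate voxel center, A = crop peak −
crop min, B = crop min.

Per-candidate failures (crop outside the stack, flat crop, non-converged
fit) are handled by policy: `drop` (default — failed fits simply reduce
yield) or `centroid` (intensity-weighted centroid of the clipped crop,
flagged `source='fallback'`, quality 0). Fit quality is
amplitude / residual RMS.

On noiseless rendered spots the fit recovers the true center to well under
0.01 voxel per axis (the model is exactly realizable, so the optimizer
converges to the exact parameters); under Poisson noise the RMS error
decreases monotonically with amplitude, as photon statistics require.

## Pairing

Mutual nearest neighbors: a pair is kept only when each centroid is the
other's closest cross-channel partner, making the match one-to-one. A
one-sided rule would let one bright spot absorb several partners at
realistic spot densities. Pairs farther than `max_pair_distance_nm`
(default 1000 nm) are discarded — uncorrected chromatic offsets reach a
few hundred nanometers, so 1 µm keeps genuine pairs while capping
mispairing across neighboring loci. Distance ties break toward the
smallest centroid index. The implementation uses an exact all-pairs
distance matrix up to 10⁷ evaluations and KD-trees beyond.

Before affine fitting, pair distances pass an outlier fence
`distance ≤ median + k·IQR` with k = 1.5 (the conventional Tukey-style
multiplier), inclusive so a degenerate IQR of 0 keeps everything at the
common value. A retention floor never lets the fence remove more than 25%
of pairs (if it would, the smallest-distance 75% are kept) — protection
against collapsing IQR on tightly clustered data.

## Linear chromatic correction (LCC)

For paired differences d = b − a (moving minus reference):

1. subtract the mean difference (global translation),
2. per axis, OLS of the centered difference on the *reference* coordinate
   a_k, giving intercept α_k and slope β_k (the scaling bias),
3. total correction b_k ← b_k − (mean_k + α_k + β_k·a_k).

Because OLS residuals are mean-free, the corrected differences have
exactly zero per-axis mean on the training pairs — the residual
translation removal is built into the update rule. The regressor choice
(a_k rather than b_k or the pair midpoint) matters only at second order in
the aberration; it is fixed to the reference frame and documented for
reproducibility, since the reference channel is never modified.

LCC is self-calibrating: it needs no colocalization standard, because
isotropically oriented pairs — colocalized or separated — have zero
expected difference. The test suite verifies this premise directly:
fitted on pairs at a true separation of 120 nm under an injected
translation + scaling aberration, LCC removes the aberration without
biasing the median separation beyond Monte-Carlo uncertainty.

Applying a fitted LCC twice is not a no-op (a translation is subtracted
twice); refitting on corrected output yields the identity. Guards: ≥ 10
pairs, nonzero variance of the reference coordinate on every axis.

## Affine chromatic correction (ACC)

The full 12-degree-of-freedom affine T minimizing Σ‖T(bᵢ) − aᵢ‖² over
translation, rotation, anisotropic scale and shear, fitted on aggregated,
IQR-filtered *colocalized* pairs. The problem is linear in the parameters
and is solved in one SVD-based least-squares solve (numpy `lstsq`); a
single linear solve is the minimal model covering all four component
types, in preference to a similarity-plus-shear decomposition. Both point
sets are centered before the solve — the raw design matrix (coordinates
~10⁴ nm against a unit intercept column) is badly conditioned, and
centering removes that without changing the minimizer (the optimal
intercept always equals mean(a) − M·mean(b)).

Guards: ≥ 20 pairs after filtering, and the smallest singular value of the
centered moving-coordinate matrix must exceed 10⁻⁶ of the largest
(coplanar geometry leaves the axial column of a 12-dof affine
unconstrained). The correction direction is fixed and recorded: the
transform maps moving-channel coordinates into the reference frame, and
the channel labels ride along in the transform metadata so a stored
transform cannot silently be applied with channels swapped.

Transforms persist as versioned JSON (`chromadist-transform/1`): the 4×4
row-major matrix in nm (floats serialized at full repr precision, so the
round trip is bit-exact), channel labels, pair count and creation
timestamp. Reuse across datasets is the intended workflow: calibrate on
colocalization stacks, store, apply to measurement stacks acquired under
the same optical conditions.

## The two-method agreement diagnostic

LCC (translation + axis-aligned scaling) is a strict subset of ACC's
model class. When the real aberration is within both classes the two
corrections coincide (verified to 10⁻⁶ on noiseless translation+scaling);
when it contains rotation or shear, ACC fits strictly better. On real
optics both should land within a few nanometers of each other —
`correction_agreement` reports the per-pair deltas and medians and flags
divergence above a configurable threshold (default 10 nm on the median),
which would indicate optical instability or a field-varying aberration
that a global model cannot express.

## Synthetic scenes: what they emulate, and what they do not

`chromadist.simulate` generates the two validation geometries:

* **Colocalization control** (true separation L = 0): both channels
  observe the same positions; any measured distance is technical error.
* **Nanoruler emulation** (L = 120 or 160 nm, matching commercial
  DNA-origami standards): B sits at A + L·u with u an exactly isotropic
  unit vector (normalized Gaussian draws).

Channel-A positions are uniform in the scene bounds with rejection
sampling at a minimum separation (capped at 100 attempts per spot, then
the spec is declared infeasible). The aberration — an arbitrary affine —
is applied to channel B only; channel A is the reference frame, matching
the pipeline's correction direction. Noise enters in one of two
deliberately separate modes:

* **point-space** per-axis Gaussian noise on both channels, which tests
  the corrections and statistics in isolation (the paired difference is
  then Gaussian with per-axis s.d. σ√2, so the colocalized 3D distance is
  σ√2·χ₃ — median ≈ 43.5 nm at σ = 20 nm, the closed form the acceptance
  checks use);
* **image-space** Poisson shot noise on stacks rendered with 3D Gaussian
  spots, which tests detection and localization.

Default study conditions: σ = 20 nm per axis per channel in point-space
scenes; rendered spots with σ_xy = 130 nm, σ_z = 300 nm, amplitude 1000
counts on background 100 (peak SNR ~ 100); injected aberrations of
translation (30, 27, 160) nm — lateral ~30 nm and axial ~160 nm being the
magnitudes confocal systems actually show — with per-axis scales within
±0.5% and sub-degree rotations where a full affine is wanted.

Not emulated: realistic PSF models (Gibson–Lanni), spectral bleed-through,
depth- or field-dependent aberration, probe-accessibility or chromatin
heterogeneity, detector read noise. Passing tests therefore demonstrate
the correctness of the measurement chain and corrections under a uniform
affine aberration with well-separated spots — not performance on dim,
dense, or optically unstable real data. In particular a field-varying
aberration violates both correction models by construction; the agreement
diagnostic is the tool that would expose it.

## Problem sizes and numerics

Statistical checks use 20 000 pairs for the noise-floor comparison (1%
band on the median), 6 000 pairs per nanoruler condition (spacing checked
against a 400 000-draw Monte-Carlo oracle via bootstrap CI), and the
image-domain end-to-end run uses six rendered stacks of 100 spots each
(16×256×256 voxels), giving ~270 measured pairs — enough that the
corrected median sits within the 10% band of the identity-aberration
control run with comfortable margin. Quartiles everywhere use linear
interpolation between order statistics (numpy default, "type 7"), fixed
so IQR values reproduce bit-for-bit. Per-axis displacement medians are
reported both signed (the quantity LCC drives to zero mean) and absolute
(a magnitude readout); the two answer different questions.

Determinism: every stochastic step takes a seed (`numpy.random.default_rng`);
identical scene specs produce bit-identical scenes and stacks, and the CLI
writes the resolved configuration next to every run's outputs.

## Known limitations

* The LoG detector and Otsu nuclei segmenter are classical stand-ins; on
  low-SNR or densely packed real images a trained detector behind the
  adapter interface will do better.
* Single-emitter fits only: overlapping spots within a crop bias the fit
  (mitigated, not eliminated, by sigma bounds and the detector's minimum
  separation).
* Global correction models only; no field-varying correction.
* No multi-scale detection, no drift correction, no time series.
* Proprietary microscope formats (CZI/LIF/ND2) are out of scope; inputs
  are plain multi-page TIFF (CZYX or ZCYX) or centroid CSVs.
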