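# chromadist

Chromatic-aberration-corrected 3D distance measurement for multi-color
DNA-FISH confocal stacks.

## The problem

Multi-color FISH (e.g. Oligopaint probes on two dyes) measures the physical
distance between two genomic loci as the 3D distance between spot centroids
in two fluorescence channels. On a standard confocal microscope, chromatic
aberration displaces the channels against each other by an amount —
~30 nm laterally and well over 100 nm axially — that is comparable to or
larger than the short-range (kilobase-scale) distances of interest. Without
correction, colocalized control spots appear hundreds of nanometers apart.

`chromadist` implements the full measurement chain:

1. **Spot detection** — scale-matched 3D Laplacian-of-Gaussian candidates
   (anisotropy handled in voxel units), behind a pluggable detector
   interface that also accepts externally produced coordinates or masks;
   optional nuclei segmentation restricts spots to nuclear signal.
2. **Sub-pixel localization** — nonlinear least-squares fit of a 3D
   Gaussian `B + A·exp(−(dx²+dy²)/2σ_xy² − dz²/2σ_z²)` per spot, in
   physical nanometers.
3. **Pairing** — mutual nearest neighbors across channels (one-to-one by
   construction), with optional same-nucleus and maximum-distance gates.
4. **Chromatic correction**, two independent estimators:
   - **LCC** (linear chromatic correction): per axis k, center the paired
     differences `d_k = b_k − a_k`, regress the centered difference on the
     reference coordinate (OLS), and correct
     `b_k ← b_k − (mean_k + α_k + β_k a_k)`. Self-calibrating: valid on
     colocalized *or* separated pairs, because isotropically oriented pairs
     have zero expected difference.
   - **ACC** (affine chromatic correction): the 12-parameter affine `T`
     minimizing `Σᵢ‖T(bᵢ) − aᵢ‖²` (translation, rotation, anisotropic
     scale, shear), solved by SVD least squares on IQR-filtered,
     aggregated colocalization pairs; persisted as JSON and reapplied to
     measurement data acquired under the same optics.
5. **Statistics** — per-pair displacements and robust median/IQR summaries,
   histograms and violin plots.

Agreement between the two corrections is itself a diagnostic: they
parameterize the same optics differently, so medians differing by more
than a few nanometers flag optical instability or a non-global aberration
field.

Validation is entirely on synthetic scenes with known ground truth
(`chromadist.simulate`): colocalization controls (true separation 0, all
measured distance is technical error) and nanoruler emulations (pairs at
fixed separations such as 120/160 nm with random 3D orientation, the
geometry of DNA-origami distance standards).

## Worked example

Simulate a colocalization control with a realistic injected aberration
(translation 30/27/160 nm), render it as a two-channel Poisson-noise stack,
and measure it:

```bash
chromadist simulate --n-spots 30 --separation 0 --noise-sigma 0 0 0 \
    --translate 30 27 160 --seed 31 --out sim/
chromadist measure sim/synthetic.tif --method both --out results/
```

which prints (stage counts on stderr):

```
 uncorrected: n=26  median=165.7 nm  IQR=[162.5, 168.0] nm
         lcc: n=26  median=3.6 nm  IQR=[3.0, 4.7] nm
         acc: n=26  median=3.7 nm  IQR=[2.9, 4.4] nm
```

The uncorrected median (~166 nm) is almost entirely the injected chromatic
offset (‖(30, 27, 160)‖ ≈ 165 nm plus localization noise); both corrections
collapse it to the few-nanometer localization floor of the rendered spots,
and agree with each other — the pipeline's internal consistency check.
`results/` contains the pair tables (uncorrected and per method), the
summary CSV, distribution figures, the fitted transform JSON and the
resolved configuration.

For real data the affine is calibrated once on colocalization stacks and
reused on measurement stacks:

```bash
chromadist calibrate coloc1.tif coloc2.tif --transform-out acc.json
chromadist measure sample.tif --method both --transform acc.json --out out/
```

The same functionality is available as a library (`PipelineConfig`,
`run_calibrate`, `run_measure`); the correction estimators
(`LinearChromaticCorrection`, `AffineChromaticCorrection`) follow the
scikit-learn `fit`/`transform` convention and compose with sklearn
tooling.

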