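# Methods

## The model

Single-particle cryo-EM produces many noisy 2D projection images
("particles") of one macromolecular complex in unknown orientations.
`cryolite` recovers the underlying 3D density (or a set of 2D class
averages) by regularised-likelihood expectation-maximisation:

* **Observation model.** A particle image `X` is a central Fourier slice
  of the reference transform at orientation `A`, translated by `(dx, dy)`,
  plus Gaussian noise that is independent across Fourier pixels with a
  per-resolution-shell variance `sigma2[s]` learnt from the data.  Writing
  `P_{k,i}` for the projection of class `k` at orientation `i`, the
  negative log-likelihood of one hypothesis is

      diff(k, i, t) = sum_pixels |shift(X, t) - P_{k,i}|^2 / (2 sigma2)
                      + sum_pixels log(2 pi sigma2).

* **E-step.** `diff` is evaluated over all classes, a quasi-uniform
  orientation grid, and a square grid of translations; hypotheses become
  posterior weights through a max-subtracted softmax with class priors.
  The smallest hypothesis set holding 99.9% of the posterior mass is
  "significant".  When that set has localised (at most 16 distinct
  orientations), the search is repeated on a locally refined grid at half
  the step; a flat posterior is not refined, because denser sampling of an
  uninformative landscape only costs time.  The weighted, translated
  particle transforms are then back-projected into per-class accumulators.
  The significant set used for back-projection is truncated at the 64
  strongest hypotheses (renormalised); the discarded tail carries
  negligible mass once the posterior has any structure.
* **M-step.** Each class accumulator is converted to a real-space
  reference by the gridding reconstruction described below; class priors
  become occupancies, and `sigma2` becomes the weighted per-shell mean of
  the squared residuals (floored at `1e-5` of the strongest shell so that
  noise-free data cannot produce quasi-infinite weights).

The per-iteration diagnostic `loglik` is the full-grid log-sum-exp of the
coarse pass including the Gaussian normalisation term.  On a **fixed**
sampling grid (refinement factor 1) it is non-decreasing, as expectation-
conditional-maximisation guarantees; with adaptive two-pass search the
references optimise the fine grid, and the coarse-grid diagnostic can
wobble by a few parts in 1e6 near convergence.  The convergence
experiment therefore runs with fixed sampling; adaptive search remains
the default for alignment accuracy.

## Fourier geometry

Orientations are intrinsic ZYZ Euler angles `(rot, tilt, psi)` in degrees
with `A = Rz(psi) Ry(tilt) Rz(rot)`, the convention used by STAR particle
tables, so metadata interoperates.  References are zero-padded two-fold
before transforming; a particle of size `D` samples the padded transform
at integer multiples of the padding factor, where trilinear interpolation
is accurate.  Slice extraction and insertion share the same trilinear
weights (gather vs scatter) and are exact adjoints — the property the
back-projection step relies on and the tests verify to 1e-6.

Two practical points discovered while validating the operators:

* **In-plane oversampled insertion.**  Inserting the raw `D x D` slice
  leaves its samples two grid units apart on the padded grid, so a large
  fraction of voxels falls outside every trilinear footprint at *all*
  radii.  Reconstruction-bound insertions therefore first upsample the
  slice two-fold in-plane (exact trigonometric interpolation via
  real-space zero-padding), giving unit sample spacing on the slice
  plane.  The plain, strictly adjoint variant remains the default for the
  operator algebra.
* **Gap filling.**  Even with dense in-plane samples, voxels far from
  every slice plane (angular sampling gaps at high radius) receive no
  data.  The reconstruction estimates sampled voxels by Wiener-damped
  division (`data / (weight + lambda)`, with `lambda` either a small
  constant or `1/tau2[s]`), then fills unsampled voxels with an
  onion-shell neighbourhood average and relaxes them toward the harmonic
  interpolant of their sampled surroundings (Jacobi sweeps).  The inverse
  transform is cropped from `2D` to `D` and divided by the real-space
  window of the trilinear kernel (`sinc^2`).  Reconstruction always runs
  in double precision; the E-step runs in single precision (complex64
  BLAS), a hybrid that the precision experiment validates: float32 vs
  float64 E-steps disagree on angular assignments by no more than two
  double-precision runs with different seeds do.

With 1000 uniformly distributed views of a 64^3 phantom, this pipeline
reproduces every shell up to 0.8 Nyquist with correlation > 0.99; the
number of views matters because plane coverage at radius `r` scales as
`n_views / r`.

## Auto-refinement

Gold-standard refinement splits particles into two random halves refined
strictly independently.  The angular step starts at 15 degrees (global
search) and halves whenever the half-map FSC resolution stalls, switching
to local searches in a neighbourhood of 2.5 steps around each particle's
previous orientation with psi sampled at +/-2 steps.  Each half map is
low-pass filtered to two shells beyond its current FSC(0.143) resolution
before the next iteration — the regularisation that keeps the halves
independent of each other's noise.  The schedule stops at a quarter of
the initial step (after three settling iterations): at desk scale,
alignment accuracy saturates near the interpolation fidelity of the
reconstructed references, and annealing below that step adds cost without
accuracy.  Resolution is reported at the FSC = 0.143 threshold (field
convention).

Post-processing follows standard practice: a solvent mask is built by
binarising a 15 Å low-pass filtered map and adding a five-pixel
cosine-shaped soft edge; the masked FSC is corrected for mask-induced
correlation by randomising phases beyond the shell where the masked FSC
first drops below 0.8 (plus two safety shells) and computing
`(FSC_masked - FSC_rand) / (1 - FSC_rand)`.

## Template picking

Micrographs are optionally low-pass filtered and downscaled by
`floor(lowpass / (2 px))` (exact integer ratio, Fourier-crop) before
cross-correlation — discarding frequencies the templates do not contain
shrinks the FFTs that dominate the cost.  The per-pixel score is a
locally normalised cross-correlation: templates are zero-mean unit-norm
under a circular mask; micrograph local moments come from FFT box
filters; FFT sizes are padded to 7-smooth integers.  The score map is the
maximum over all templates and in-plane rotations (default step 5
degrees, i.e. 72 rotations).  Peaks are accepted greedily in descending
score order with non-maximum suppression at the particle diameter, and
centers within half a template of the border are excluded (no full
template support).  Pick sets are compared by one-to-one greedy matching
within a 35-pixel center cutoff; recall is matched/|reference| and FDR is
(|picked|-matched)/|picked|.

## Synthetic data

The generator emulates exactly the structures the algorithms consume: 3D
phantoms as sums of Gaussian blobs (analytic integrals and projections
available for oracles), particle stacks rendered through the same Fourier
slice operator with known orientations/translations plus white Gaussian
noise, and micrographs with templates embedded at known coordinates.
Three stock phantoms serve different roles: `default_phantom` (two
flavors, visibly different — the two-class problem), `smooth_phantom`
(compact, wide blobs — the projection oracle, where interpolation should
be the only error), and `sharp_phantom` (narrow blobs with signal past
0.8 Nyquist — shell-resolved reconstruction fidelity).

SNR is defined as signal variance inside the particle support over the
noise variance.  White noise is deliberate: the likelihood learns a
per-shell variance, which flat spectra exercise cleanly.  What the
generator does **not** emulate — contrast transfer functions, coloured
noise, radiation damage, particle heterogeneity beyond discrete classes —
bounds what passing tests show: they validate the estimation machinery,
not robustness to microscope physics.  CTF handling is delegated to
upstream tools in real pipelines and is out of scope here.

## Study conditions and problem sizes

The validation experiments run at desk scale, chosen so the whole suite
completes on one CPU core in minutes: projection oracle on a 64^3
phantom, 20 views; adjoint identity on 32^3, 100 rotations; phantom
recovery from 1000 slices at 64^3; E-M convergence on 500 particles of
64^2 at SNR 0.5, 10 iterations; two-class recovery on 400 particles at
SNR 0.5; auto-refinement of 500 noise-free 32^2 particles; precision
comparison on 200 particles of 48^2; picking equivalence on a 768^2
micrograph with 24 embedded particles at SNR 0.1, filtered to 8 Å.

## Numerical choices

* Softmax weights are max-subtracted; weight normalisation is enforced to
  1e-6.
* Significance mass 0.999 (configurable).
* Ties in significance selection and peak search break toward the lower
  flat index, making runs bitwise reproducible for a fixed seed.
* `sigma2` floors: absolute 1e-10 and relative 1e-5 of the strongest
  shell.
* Gridding: damping `lambda = 1e-8 * max(weight)` (or `1/tau2`), 6
  onion-fill passes, 10 relaxation sweeps by default.
* Degenerate inputs fail fast: all-zero particles, empty masks, empty
  accumulators (warn + zero map), non-finite data.

## Known limitations

* No CTF or coloured-noise model in the likelihood.
* No point-group symmetry in orientation grids.
* Orientation priors are uniform; auto-refine local searches use a hard
  window rather than a smooth prior.
* Reconstruction fidelity beyond ~0.8 Nyquist depends on view count; the
  trilinear kernel is the documented compromise between speed and
  accuracy.
* The picking score is a locally normalised cross-correlation; it is a
  deliberate, documented concretisation of template-matching "R-value"
  scores.
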