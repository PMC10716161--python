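# Methods

This note records the model, the algorithms and the numerical choices the
package is built on, including the choices that were genuinely open and
how they were settled.

## Acquisition model

Golden-angle radial sampling: spoke i has azimuth i · 180/φ degrees
(90·(√5−1) ≈ 111.2461°, displayed as 111.25°), reduced modulo 360° by
default (each spoke is an oriented diameter; 180° is available for
scanners that fold angles).  The exact increment is accumulated in double
precision — rounding the increment to 111.25° before accumulating would
drift by ~1.5° over 400 spokes — and rounding is applied only for
display.  A group is p = SPF × FPG spokes; spoke i belongs to frame
⌊i/SPF⌋, and the trajectory repeats with a period of one group, so every
group of an acquisition shares one set of NUFFT plans.  Readout samples
sit at radii (j − P/2)/P cycles/pixel, j = 0…P−1, so every spoke passes
through the k-space origin and |k| ≤ 0.5; P defaults to the matrix size.

Nyquist needs round(N·π/2) spokes at matrix N (201 at 128, 402 at 256);
the per-frame acceleration factor is R = round(N·π/2)/SPF, reported
rounded to the nearest integer.  Timing arithmetic is exact and
unrounded internally (one spoke costs one TR per z-partition): 20
spokes/frame at TR 4 ms is 80 ms/frame and 0.4 s per 5-frame group; the
8-partition stack-of-stars variant at TR 4.58 ms gives 732.8 ms/volume
and 3.664 s/group.

## Encoding operator and NUFFT

E = Ω F C encodes each frame independently: multiply by each coil map,
evaluate the non-uniform Fourier transform on that frame's spokes.  The
forward convention is d(k) = (1/N) Σ_r x(r) exp(−2πi k·(r−c)), DC at the
centre pixel c = N//2, k in cycles/pixel.

No NUFFT library ships with the package's environment, so the transform
is implemented directly as Kaiser–Bessel gridding: deapodisation, zero
padding to a 2× oversampled grid, centred FFT, then interpolation of each
off-grid sample from its 6-tap-per-axis Kaiser–Bessel neighbourhood
(Beatty's β for oversampling 2).  The interpolation is materialised as a
sparse matrix, so the adjoint is the exact conjugate transpose of the
forward composition — dot-product tests pass at machine precision by
construction, independent of gridding accuracy.  The deapodisation
profile is obtained by numerical quadrature of the kernel's Fourier
integral rather than a closed form, which removes one class of
convention bugs.  Against a brute-force non-uniform DFT the forward
transform agrees to ~4·10⁻⁵ maximum absolute error on 32×32 problems
(the width-6 kernel's aliasing floor; width 8 reaches 5·10⁻⁷ if ever
needed).

Density compensation (radial ramp |k|, centre sample weighted by a
quarter ring, global gain calibrated so a centred point source
round-trips to unit amplitude) exists **only** as an initialisation and
display aid.  The objective and its gradient always use the plain,
unweighted operator.

Coil maps are synthetic: complex Gaussian lobes on a ring of radius
0.55 N around the FOV with a gentle linear phase, normalised pixelwise to
unit sum of squares.  They stand in for measured maps — no calibration
(ESPIRiT etc.) is modelled, and reconstruction assumes the maps known.
Stack-of-stars data are decoupled into slices by a centred orthonormal
inverse FFT along the partition axis (energy-preserving), after which
everything is 2D.

## The LSFP model and the PDFP solver

With z = (L, S), B z = (ψL, ψS, ∇_t S), h the nuclear term on L and g
the weighted ℓ1 over the three transform blocks, one iteration is

1. z̄ = z_k − γ (E^H r, E^H r), r = E(L_k+S_k) − d
2. y = prox_{γh}(z̄ − λ B^H v_k)
3. v_{k+1} = (I − prox_{(γ/λ)g})(B y + v_k)
4. z_{k+1} = prox_{γh}(z̄ − λ B^H v_{k+1})

prox_{γh} is singular-value thresholding of the pixels × frames Casorati
matrix of L (economy SVD — FPG ≤ 10 keeps it trivial) and the identity on
S; prox of g is complex-magnitude soft-thresholding blockwise.  The dual
blocks for ψL, ψS and ∇_t S are separate (the shared-versus-separate
question is open in the problem statement; separate blocks are the
natural PDFP splitting).

Steps are auto-set from power iterations when not given: γ = 0.99/‖E‖²
(the coupled gradient (E^H E s, E^H E s), s = L+S, is 2‖E‖²-Lipschitz on
(L,S), so convergence needs γ < 1/‖E‖²) and λ = 1/‖B‖², where ‖B‖² ≤ 1 +
‖∇_t‖² because the framelet is Parseval.  The solver starts from the
density-compensated adjoint with S = 0: the plain adjoint of undersampled
radial data is off by a large, frequency-dependent gain that 60 gradient
steps cannot undo, while the gridding image is correctly scaled and is
then only refined.  Stopping: relative iterate change below `tol` (1e−5
default) or `max_iter` (60); the objective is recorded every iteration
and an increase beyond 10× the initial value aborts with diagnostics.

Default weights are data-scaled so behaviour is resolution-independent:
λ_L = 0.01·‖E^H d‖_∞ and λ_s = λ_L^ψ = λ_S^ψ = 0.005·‖E^H d‖_∞.  The
temporal TV uses forward differences with zero boundary (interventions
are not periodic in time); the framelet is a single-level undecimated
Haar frame with ±1/4 taps and periodic boundaries, which makes it exactly
Parseval (tight, redundancy 4) so synthesis is both adjoint and inverse.

The classical L + S baseline shares the same objective with the framelet
weights at zero: a joint gradient step, SVT on M − S, then the exact prox
of the temporal-TV term on M − L.  That prox has no closed form; it is
computed by an accelerated dual (FISTA) iteration on the short temporal
chains, effectively to machine precision.  Keeping the baseline on the
*same* objective (temporal differences, not a temporal FFT) is what makes
the two-solver cross-check meaningful: on a small fully sampled instance
both reach the same objective value to < 1 % when run to convergence.

## The unrolled network

Each of N_b blocks is one PDFP iteration with the framelet pairs
{ψ_L, ψ_Lᵀ} and {ψ_S, ψ_Sᵀ} replaced by four independent stacks of N_c
3D convolutions (3×3×3 over frame–y–x, circular padding, ReLU between
layers, none after the last).  Complex images enter the stacks as two
real channels; hidden layers carry n_features channels **read as
n_features/2 (real, imaginary) pairs**, and the learned soft-threshold
shrinks pair magnitudes — the same complex ℓ1 prox as the solver.  This
pairing plus circular padding is what lets a 2-block net with weights
frozen to the Haar filters reproduce two classical iterations to machine
precision, which is the network's structural correctness test.  The SVT
and the temporal-difference dual block stay exact, with learnable
thresholds; γ, λ and the four thresholds are per-block scalars
initialised from the solver defaults (training inputs are normalised so
the gridding adjoint has unit peak, making those initial values
data-independent).

Because no deep-learning framework is available in the package's
dependency set, the network runs on a small in-repo reverse-mode autodiff
engine (`imri.autodiff`): real tensors, explicit vector–Jacobian products
for convolution, ReLU, magnitude soft-thresholding, the encoding normal
operator (self-adjoint, so its VJP is one more application) and SVT.  The
SVT backward pass uses SVT(M) = M·V h(Λ)V^H with A = M^H M = VΛV^H,
h(λ) = max(1 − τ/√λ, 0), differentiated through the FPG × FPG
eigendecomposition by the Daleckii–Krein divided-difference formula — the
backward cost is independent of the pixel count.  Every custom VJP is
checked against central finite differences in the test suite.

Training is plain Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, lr 1e−4, batch
1 by default) on the mean squared error between the complex
reconstruction and the ground truth, sample by sample; scalar parameters
are projected to ≥ 0 after each step.  The loss function of the original
method is not public knowledge here; complex MSE is the standard choice
for unrolled reconstruction and a magnitude-moment–augmented variant is
exposed as an option.  The learned transforms are unconstrained (no tight
frame penalty); the synthesis stacks train freely.

## The simulator

The generator emulates the study conditions, not patient data: a
deterministic nested-ellipse head phantom (bright skull rim, two
hemispheres, hypointense ventricles) with smooth seeded Gaussian texture
replaces the volunteer backgrounds; a needle of width 1.5 mm (the
ceramic needle's diameter) advances from entry toward target at a
constant per-frame speed, multiplying the underlying signal by contrast
0.1 (a signal void; ceramic appears dark).  Bilateral setups insert a
second, mirrored needle; the DBS variant uses a hyperintense tip ahead of
a void shaft and emits 5 frames per slice.  One simulated frame is one
reconstruction frame; physical time attaches through the TR-based timing
arithmetic.  The headline scenario advances 1.525 mm/frame for 40
frames (61 mm), the speed and travel of the reference uniform-velocity
insertion.  Multi-coil k-space comes from the package's own encoding
operator, optionally with circular complex Gaussian noise (default
noiseless); paired HDF5/NIfTI files and a parameter manifest can be
emitted for every group.

What the simulator does **not** model — and what passing tests therefore
do not show about real data: MR contrast physics (relaxation, flip
angles), phase (truths are real; a phase map can be added), tissue
deformation, susceptibility artifacts near the needle, coil-map error,
gradient delays and trajectory infidelity.

## Tip tracking

Depth is measured per frame from the magnitude difference to a
pre-insertion baseline, binarised at half its maximum (threshold fraction
exposed), restricted to a corridor of ±5 mm around the planned
entry→target segment with projections clipped to the segment, and
reported as the farthest projection from the entry point.  The corridor
is essential: without it, skull-rim reconstruction error far from the
trajectory projects onto the planned line and dominates the farthest
projection.  A subpixel half-max interpolating variant was evaluated and
rejected — on reconstructed (noisy) profiles it overshoots and is
strictly worse than the plain farthest-pixel rule.  The estimator
quantises to pixel centres, so ±0.5 px is its intrinsic accuracy; on
noiseless truth sequences it recovers programmed depths within one pixel.

On the headline experiment (128 matrix at 1 mm, 20 spokes/frame, 5
frames/group, 8 coils, 40 frames, solver reconstruction) the measured
depth stays within 0.55 mm of the programmed depth on 39 of 40 frames;
the worst frame lags 1.1 mm.  That frame is the last of its group: its
newest 1.5 mm tip extension is seen by only 20 spokes and the temporal TV
pulls it toward the previous frame — an honest limitation of group-wise
solver-only reconstruction at R = 10.

## Evaluation conventions

Magnitudes are normalised to the reference peak before scoring ("pixel
values normalised without dimension").  PSNR = 20 log₁₀(1/RMSE), capped
at 99 dB for identical images; SSIM is the Gaussian-window (σ 1.5, 11×11)
mean structural similarity with K₁ = 0.01, K₂ = 0.03 and data range 1,
computed by scikit-image and cross-checked in the tests against an
independently coded implementation of the defining formula.  Aggregates
are reported mean ± sample standard deviation (n − 1).

## Problem sizes

Everything runs on one CPU core.  The test suite works at 8–32 matrix
sizes for operator/solver properties, trains toy networks at 32 × 32
(FPG 3, 8 features, 2 conv layers, 8 training samples, 25–50 epochs,
lr 3·10⁻⁴ — the paper-scale lr 1e−4 remains the package default), and
checks tracking on 3 groups of the 128-matrix intervention; the
acceptance script runs the full 40-frame tracking experiment.  These
sizes are the package's desk-scale study conditions; the network
architecture default (N_b = 3, N_c = 3, 32 features, 3×3×3 kernels)
matches the full-scale configuration.

## Known limitations

* The gridding NUFFT's width-6 accuracy floor (~1e−5 relative) bounds
  how exactly forward models can be inverted; tests account for it.
* PDFP and the baseline converge slowly on strongly undersampled radial
  data (the normal operator is ill-conditioned); 60 iterations with the
  density-compensated warm start are a pragmatic operating point, not
  convergence.
* Thresholds in the network are clamped at zero with a zero subgradient
  below; a threshold driven to zero during training stays there.
* The simulator's disjoint train/validation/test splits rely on
  non-overlapping seed blocks chosen by the caller (the CLI uses
  seed, seed+1000); nothing enforces disjointness across arbitrary
  seeds.
* Groups are disjoint; the optional sharing of overlapped spokes between
  neighbouring groups is not implemented (sliding-window reconstruction
  would reuse the same operators).
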