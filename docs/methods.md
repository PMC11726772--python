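# Methods

This note records the models implemented in `radrelax`, the conventions
and defaults that matter, and the reasoning behind choices the design
left open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Signal models

**Saturation-recovery look-locker (T1 mode).** Under continuous
small-flip-angle readout the longitudinal magnetization recovers toward
a driven steady state with an apparent time constant `T1eff`,

    S(t) = offset + S_ss · (1 − η · exp(−t / T1eff)),

with saturation efficiency η ∈ [0, 1] (default 0.95 in simulation,
modeling imperfect adiabatic saturation) and steady-state amplitude
`S_ss = M0 · T1eff / T1`. The apparent rate obeys
`1/T1eff = 1/T1 − ln(cos α)/τ` for flip angle α and spoke duration τ;
the mapping inverts this exactly. When `1/T1eff + ln(cos α)/τ ≤ 0` the
correction is unstable (high α, long T1) and the voxel is censored with
a dedicated error type — this is the known failure regime of flip-angle
based corrections, and the reason small flip angles are used for long-T1
samples.

*Parameter count and identifiability.* The fit reports five parameters
(steady state, saturation efficiency, T1eff, constant offset, global
phase), but `offset + S_ss(1 − η e^{−t/T})` has only three identifiable
real degrees of freedom plus the phase: the offset and the plateau are
confounded, as are S_ss and η through the decay depth. The fit therefore
pins the offset to 0 by default (`fit_offset=True` frees it); the phase
is estimated only for complex input and reported as 0 for magnitude
input. With this convention noiseless recovery is exact and the
parameters keep their physical meaning.

**Spin-lock decay and T1 normalization (T1ρ mode).** Frame intensity at
spin-lock duration `t_sl` is modeled as the readout-average of the
post-preparation recovery:

    S(t_sl) = M0 · (1 − (1 − exp(−t_sl/T1ρ)) · f),
    f = (T1 / T_read) · (1 − exp(−T_read / T1)),   T_read = prep_period · τ.

`f ∈ (0, 1]` is the readout-recovery weight; as T1 → ∞, f → 1 and the
model reduces to a pure mono-exponential. The mapping-side
normalization divides by the TSL = 0 signal and inverts this relation
using the voxel's T1, so the normalized series is exactly
`exp(−t_sl/T1ρ)` for model-matched data, equals 1 at TSL = 0 by
construction, and reduces to plain division when no T1 reference is
available. With T_read = 48 ms and myocardial T1 ≈ 1.4 s, f ≈ 0.983 —
a small but systematic correction.

**Multi-component surrogates.** Besides the two-parameter
mono-exponential fit, the asymptotic-average T1ρ is the negative
inverse log-slope over the first two TSL points and the slow-component
T1ρ the same over the remaining points (computed only where all
normalized values are positive). For bi-exponential voxels the
single-component estimate lies between the two surrogates; all three
coincide for mono-exponential decay.

**Fit numerics.** Mono-exponential fits are initialized by log-linear
regression and solved by bounded trust-region least squares; the
look-locker fit starts from (max, η=0.98, median time). Time-constant
bounds scale with the sampled window ([10⁻³, 10²] × span); a fit that
lands on the upper bound is censored as NaN — a decay 100× slower than
the sampled window is not resolvable from it, and such voxels (flat or
artifact-dominated curves) would otherwise dominate ROI means. All
voxelwise failures produce NaN, never exceptions, and are counted.

## Trajectory and binning

Spoke directions follow a two-parameter golden-means sequence on the
sphere, so *any* contiguous subset is quasi-uniform — the property that
makes retrospective under-sampling meaningful. An Archimedean-spiral
scheme (uniform only as a complete set) is available for comparison.
k-space radius is normalized to [0, 0.5) cycles/voxel; each center-out
spoke has `samples_per_spoke = matrix` samples (radial spacing
0.5/S, i.e. 2× radial oversampling), images use 0-based centered voxel
indexing.

Look-locker binning groups spokes by position within the
saturation-recovery curve, pooled across curves; the frame time is the
mean mid-spoke time of its members (an unbiased effective recovery time
for fitting, rather than the first or last spoke). Under-sampling
retains `keep` spokes per frame: `prefix` (the first acquired — how a
shortened acquisition would look) for the spin-lock mode, and
`uniform-stride` across the curve sequence for the T1 mode, because a
per-frame prefix concentrates on the first few curves and measurably
degrades angular coverage at 10× acceleration.

## Phantoms

The MnCl₂ phantom is four cylinders whose rates are exactly linear in
concentration, `R = R0 + r·c`; defaults (`r_T1ρ = 0.0025`,
`R0 = 1/0.462 s⁻¹`; `r_T1 = 0.00024`, `R0 = 1/2.45 s⁻¹`) place the tube
time constants in the range of published dilution-series measurements
at 9.4 T. Concentrations are numeric values with an explicit unit
string: published dilution series for this kind of phantom are quoted
inconsistently (mM in methods, 10⁻¹ mM in results), and the printed
relaxivities are unit-consistent only with a µM-scale axis, so the
package refuses to guess.

The heart-like phantom is a stylized left-ventricle: an annular wall of
remote tissue, a septal bar of inflamed tissue, a fibrotic lesion in
the anterior wall, and a separate control cylinder. The geometry is
deliberately thin-structured so that block-wise low-rank blurring is
visible in map space. Tissue values are literature-typical means for
subacute-infarct mouse myocardium (3D: T1 0.68/1.4/1.65/1.9 s, T1ρ
30/31/50/84 ms for control/remote/inflammation/fibrosis); the
inflammation T1 and fibrosis T2 are synthetic placements (between their
neighbors) because those entries are not separately characterized in
the reference measurements. Optional per-voxel Gaussian jitter with the
tabulated spreads emulates biological heterogeneity. Ground-truth maps
are exactly piecewise constant before jitter.

*What the generator does not emulate:* coil sensitivity profiles, B0/B1
inhomogeneity, T2* decay along the readout, swept-excitation
deconvolution, motion, and partial-volume mixtures at tissue borders
(labels are binary). Passing tests therefore demonstrate correctness of
the algorithm chain, not robustness to every scanner non-ideality.

## Forward model and NUFFT

Each frame is a static contrast-weighted image (intra-frame relaxation
is below the binning granularity); sampling evaluates
`E(k) = Σ_x ρ(x) e^{−2πi k·x}` along the frame's spokes, with a single
receive channel (volume transceiver) and i.i.d. circular complex
Gaussian noise. SNR is reported as `M0 / (σ √samples_per_spoke)`.

The sampling operator is a Kaiser–Bessel gridding NUFFT (default
kernel width 4, grid oversampling 1.25, β per the standard
minimum-aliasing formula, analytic deapodization). The adjoint is the
exact algebraic transpose of the forward — adjoint identities hold to
machine precision regardless of interpolation accuracy. Defaults give
~10⁻² relative accuracy against direct summation on white-spectrum
images (typical object spectra fare better); width 8 at 2× oversampling
reaches ~10⁻⁷ and is used in verification against the exact DFT engine.
Inner loops are JIT-compiled (numba) with a pure-numpy fallback.

Density compensation uses radial shell volumes per frame. Two
normalizations serve two purposes: `density_compensation` returns
weights summing to 1 per frame, making a delta's adjoint round trip
unit-amplitude; the adjoint baseline reconstructor uses raw cell-volume
quadrature weights, which preserve smooth-image amplitudes. (The two
differ by the sampled-ball volume ≈ π/6: a discrete delta's flat
spectrum extends into cube corners radial sampling never sees.) The
adjoint+DCF round trip is validated on a band-limited Gaussian at 2×
radial oversampling (~2% error); piecewise-constant objects are
Gibbs-limited (~15–20% whole-image error for any linear reconstruction
from ball-limited samples) — this is an information limit, not an
operator defect.

## Reconstruction

Objective: `½‖A(x) − y‖² + λ Σ_b ‖R_b(x)‖_*` with non-overlapping 8³
blocks, zero-padded at edges, no inter-iteration block shifts
(determinism over the marginal quality of random cycling). In T1 mode
`x` holds K coefficient volumes of a temporal subspace built from an
SVD of unit-normalized recovery curves over a log grid of T1eff (and a
small saturation-efficiency grid); K = 5 by default — the brute-force
residual spectrum puts the worst-case dictionary projection error at
1.3×10⁻³ for K = 5 and 2.9×10⁻⁴ for K = 6 under this frame-time
convention. The T1ρ series is reconstructed frame-wise with LLR only.

The solver is a preconditioned primal-dual (Chambolle–Pock type)
iteration, 70 iterations by default: diagonal *dual* preconditioner
proportional to the density-compensation weights (max-normalized) and a
scalar primal step, with the step product bounded by 20 power
iterations (seeded). Density-based dual scaling is the meaningful
diagonal choice for Fourier sampling operators, whose rows all have
equal norm; it whitens the center-dense radial spectrum and converges
fast on these problems. The objective (data term + λ × block nuclear
norm) is traced at checkpoints; an objective exceeding 10× its initial
value raises a divergence error suggesting smaller steps.

λ is tuned manually, as is standard for this reconstruction family: the
CLI exposes a λ-ladder (`--lambda 0,1000,3000`) that emits one series
per value for visual comparison. The shipped operating points, chosen
once on phantom data via that ladder, are λ = 0 for fully-sampled
noiseless runs, λ = 1000 for 10× under-sampled T1ρ and λ = 3000 for 10×
under-sampled T1 (the λ scale is tied to the unnormalized data term; at
100× the tuned value the per-block rank collapses to 1 and maps blur —
the documented over-regularization regime).

*Solver verification.* Against a conjugate-gradient least-squares
oracle (λ = 0, fully sampled, noiseless, 16³), solutions are compared
on the determined spectral interior |k| ≤ 0.4 cycles/voxel: ball-edge
and corner modes have near-zero eigenvalues, where a first-order method
and a Krylov method differ for any practical iteration count while
carrying no data-determined information. Interior agreement is <1% at
70 iterations with a data-domain residual <0.1%.

## Mapping and analysis conventions

Masks default to thresholding the maximum frame magnitude at 5% of its
99th percentile (deterministic stand-in for manual ROI drawing).
Multi-component surrogates are computed only where all normalized
points are positive. Maps are NIfTI with a units tag and a JSON sidecar
recording failure counts.

RRTD is `(mean_damage − mean_remote)/mean_remote`, scale-invariant,
reported at full precision in CSV and to two significant figures in
tables. Relaxivity is the OLS slope of 1/T against concentration.
Group comparison is an unpaired equal-variance t-test with Bonferroni
correction by default (`equal_var=False` switches to Welch); the
equal-variance unpaired form is the smallest-assumption reading of a
generic "t-test with correction" protocol. Parameter-recovery checks
use per-compartment *medians*: at high acceleration, boundary voxels
(partial volume plus residual aliasing) produce heavy-tailed fit
errors that distort means but not medians.

## Desk-scale study conditions

Simulated studies run at matrix 32³ (16³ for solver-level checks) with
the protocol structure preserved: T1 — 65 536 spokes, 1024 per curve,
64 curves, 32 frames of 2048 spokes, α = 4° (2° for the MnCl₂ phantom
in T1 mode), τ = 3 ms; T1ρ — 8 TSL frames (0…28 ms), preparation every
16 spokes, 4096 spokes/frame fully sampled (~1.3× the radial Nyquist
count π·N² at N = 32), 410/frame at 10× acceleration, mirroring the
published 6553-of-65 536 retention ratio at full scale. Noise is set by
SNR 30 where noise is used. These sizes were chosen once as the
smallest grids on which the thin heart structures remain resolvable.

## Known limitations

* Magnetization preparation is modeled at the signal-equation level;
  adiabatic pulse trains are not Bloch-simulated, so preparation
  imperfections (B1-dependent lock efficiency, off-resonance) are
  outside the model.
* The swept-excitation acquisition's dead-time gap and correlation
  reconstruction are not modeled; sampling is ideal center-out radial.
* Single receive channel; no parallel-imaging dimension.
* The heart phantom's geometry is stylized, not anatomical; absolute
  ROI sizes and partial-volume statistics do not transfer to real
  anatomy.
* Gradient-delay/eddy-current trajectory errors and motion are out of
  scope (the target application is ex vivo, static).
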