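# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `epidyn`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

A `TrackTable` is a per-(track, frame) table of nucleus centroids (μm) on
a uniform frame grid (Δt = 5 min by default, configurable), with optional
nucleus long-axis orientation θ and axis lengths. Coordinates follow the
image convention (origin top-left, y downward); every statistic uses
position *differences*, so the convention never enters results.
Orientations are nematic: stored in [0, π), differenced modulo π into
(−π/2, π/2]. The rotational MSD unwraps these per-frame nematic steps
cumulatively, which assumes single-frame rotations stay below π/2 — the
convention is noted here because tracking exports do not state theirs.

Gapped tracks are never interpolated; `filter_complete_tracks` keeps only
trajectories present at every frame, mirroring standard practice for
long-time single-cell statistics. Boundary handling is by exclusion
everywhere (reference cells within the probe range of the field edge are
dropped), never by periodic wrapping — the field of view is a bounded
window on a larger tissue.

## The synthetic tissue

The generator is a statistical test harness, not a mechanistic tissue
model: it produces trajectories with the correlation structure the
analyses probe, with known ground truth, so every estimator can be
validated end to end. It does not model forces, cell shapes, contact
inhibition, or neighbour exchange, so passing tests demonstrate estimator
correctness — not biological fidelity of any particular tissue.

**Trap/creep model** (default). Each trajectory is
r(t) = c(t) + s(t): a Brownian cage centre (diffusivity D_c) plus an
independent 2D Ornstein-Uhlenbeck fluctuation (relaxation time τ_r,
stationary RMS σ_s per axis), simulated with the exact OU discretization
and a stationary start. Its TMSD has the closed form

    ⟨δr²(δt)⟩ = 4·D_c·δt + 4·σ_s²·(1 − exp(−δt/τ_r)),

which gives plateau-free subdiffusion with anticorrelated steps crossing
over to diffusion near τ_r — the minimal generator of creep. Defaults
mirror the reference experimental conditions: 828 × 621 μm field,
Δt = 5 min, 325 frames (~27 h), τ_r = 200 min, and σ_s = 1.5 μm with
D_c = 0.0125 μm²/min, chosen so the long-time TMSD reaches ≈ 20 μm² per
27 h record and the intracage and cage-centre contributions are comparable
at the crossover. Initial positions are a jittered hexagonal packing at
the target density (jitter 1.5 μm), which reproduces liquid-like
short-range order in g(r).

Other models: `brownian` (one D), `heterogeneous` (per-cell D from an
exponential or gamma distribution; the exponential mixture yields Laplace
displacement distributions with α₂ = 1), `anisotropic` (diffusion tensor
with eigenvalues along/across each cell's fixed θ, mean D preserved), and
`clustered` (trap model with σ_s modulated log-normally by a smooth
Gaussian random field of stated correlation length — producing spatially
clustered fast cells and a nonzero, δt-dependent α₂).

**Events.** Divisions and extrusions are Poisson processes in time
(defaults: one per ~10 min and one per ~40 min, the reference rates) at
uniform positions. Each event adds, per frame after the event, an outward
displacement increment of magnitude A·Δt·e^{−d/λ}·e^{−(t−t_e)/τ_b}, with
the distance d and outward direction frozen at the event time
(λ = 20 μm, τ_b = 30 min, A = 0.2 μm/min by default). The cumulative
outward offset therefore saturates at A·τ_b·e^{−d/λ}; the step series
decays with τ_b and the step profile with λ, which is what the recovery
analysis measures. Division boosts can be modulated by
(1 + bias·cos 2φ) about the division axis so axis-aligned averaging shows
the oriented outflow. The generator enlarges the declared field to the
trajectory bounding box rather than reflecting at the boundary, consistent
with analysis-by-exclusion.

All outputs are bit-reproducible functions of `rng_seed`.

## Estimator choices

**Time origins.** All time-averaged statistics use sliding origins at
frame spacing (maximal overlap) and report sample counts. Standard errors
quoted in tests are computed across cells (independent by construction in
the generator), not across overlapping origins.

**Cage-relative MSD** subtracts the mean displacement of each cell's
initial neighbours (cells within the first-peak distance of g(r),
default 13 μm) before squaring; cells without neighbours keep their raw
displacement and are counted. This removes rigid local drift but not
rotation.

**Fs(q, δt)** averages the vector form ⟨cos(q·Δr)⟩ over 12 equally spaced
q directions (isotropic averaging is implied by reporting a scalar q); the
literal modulus form ⟨cos(q|Δr|)⟩ sits behind `use_modulus=True`. The
default grid is q = 0.04–0.2 μm⁻¹ in steps of 0.013. Stretched-exponential
fits run per q on unweighted Fs with bounds τ > 0, β ∈ (0.2, 3),
initialised from the 1/e crossing and β = 1; q values whose Fs does not
decay below 0.2 in the sampled window are excluded and reported. The τ(q)
exponent comes from a log-log line with its standard error (reported only
when ≥ 3 q values converge).

**Van Hove / Gumbel.** PDFs are rescaled by the RMS displacement per lag;
α₂ is computed from raw (unbinned) moments. The displacement-form Gumbel
density is normalized analytically, A(ζ) = 1/(2ζ(1−e⁻¹)); the fit is least
squares on ln f over |δx|/σ ≤ 3, and the reported diagnostics are the rms
log-residual (large for Gaussian input) and the mean data/fit ratio beyond
the fit range (the excess tail).

**Step memory.** FWHM of the conditional step distributions uses the
moment definition w = 2√(2 ln 2)·√m₂ (the Gaussian-equivalent width), not
a literal half-maximum crossing. In the lowest d₀₁ bins the conditional
mean sits off the bin centre because the d₀₁ density grows ∝ r within the
bin; tests account for this.

**Self-overlap** Qᵢ(a, δt) defaults to a = 1.2 μm, δt = 200 min, averaged
over t ∈ [105, 1625] min (origins whose endpoint leaves the record are
dropped, and the pipeline clips the window to the record length for short
inputs).

**Structure.** g(r) is border-corrected by excluding reference points
within r_max of the edge and normalized so Poisson patterns give 1. The
aligned 2D map rotates neighbour separations by the reference nucleus's
−θ only (neighbour orientation ignored). The structure factor is computed
from density fluctuations — the uniform-box characteristic function is
subtracted from the Fourier amplitude — because otherwise the finite
rectangular field of view injects O(1) spurious peaks at q directions
nearly aligned with the box axes. Voronoi neighbours are pairs sharing a
positive-length ridge (zero-length ridges at degenerate 4-fold vertices do
not count, so a square lattice gives 4 neighbours); unbounded or
field-crossing cells are flagged as boundary and excluded from density and
entropy. The hexatic order takes the modulus |⟨e^{i6γ}⟩| so O⁶ ∈ [0, 1].

**Structural entropy.** gᵢ(r) is a Gaussian-kernel estimate (width
1.0 μm, r_max 50 μm, both configurable and reported) of each cell's
neighbour-distance density, and Sᵢ is the trapezoid integral of
−(ρ/2)·2πr(g ln g − g + 1), which is ≤ 0 by construction. A single-frame
kernel estimate carries a finite-sampling noise floor (the integrand is
non-negative, so noise biases Sᵢ negative, by several units at one frame);
`pool_frames` averages gᵢ over evenly spaced frames, shrinking the floor
∝ 1/pool. Per-cell maps intended for correlation analyses should be pooled
over the averaging window, as the reference protocol does. The kernel
width and cutoff are this package's choices; the magnitude of Sᵢ depends
on both, so only comparisons at fixed settings are meaningful.

**Clusters.** Fast cells are the top ⌈fraction·N⌉ by displacement over δt
(ties broken by track id), clustered by transitive closure below
r* = 15 μm — the first valley of g(r) for the reference tissue. The
anisotropy is evaluated in the gyration tensor's principal frame,
ξ_c = (λ₁−λ₂)/(λ₁+λ₂), which is rotation-invariant, lies in [0, 1] and
reproduces the stated endpoints (1 for a line, 0 for a disk); the
axis-frame form (Mxx−Myy)/(Mxx+Myy) is frame-dependent and can be
negative, so it is not used. Size distributions are fitted by discrete
maximum likelihood with the normalization over N_c = 1..∞ (singletons
included; the sum is truncated adaptively with error < 1e−6). Shape and
fractal statistics use clusters with N_c > 5.

**Events.** Neighbourhood membership is frozen at the event time (the
region is 100 × 100 μm by default); the dividing cell itself is not a
tracked member in synthetic data. Random controls are seeded uniform
(position, time) draws keeping one region-width from true event centres
(spatial exclusion only). Scale recovery uses the excess of the mean
*squared* step over the pre-event baseline, because
⟨|b+v|²⟩ = v² + ⟨|b|²⟩ exactly for an isotropic background — the mean
|step| excess is nonlinear in the boost near the noise floor and biases
exponential fits. Divergence is computed by central differences on the
event-averaged binned field.

**Soft modes.** The covariance D_kl = ⟨u_k u_l⟩ (biased 1/T estimator)
over T₁ = [0, 100] min is diagonalized via the economy SVD of the T × 2N
fluctuation matrix — identical spectrum, no 2N × 2N matrix in memory; with
21 frames the rank is ≤ 21, so only the top modes (default 10, the lowest
frequencies ω = 1/√λ) are interpreted. ⟨M⟩ᵢ is the unweighted mean of the
per-cell mode magnitudes (an eigenvalue-weighted variant is available);
mode signs are arbitrary and never used. The correlation with Qᵢ enforces
T₁ ∩ T₂ = ∅ as a hard error — otherwise the "prediction" would be
circular.

## Pipeline

`PipelineConfig` defaults are the reference analysis conditions
(a = 1.2 μm, r* = 15 μm, 10% fast fraction, 100 μm event regions,
40/20 μm coarse-grain windows, T₁ = [0, 100] min, T₂ = [105, 1625] min,
Einstein fit window 200–400 min, q = 0.04–0.2 μm⁻¹ step 0.013). The
config serializes losslessly to JSON next to the outputs; identical
config + seed gives identical outputs (timings aside). The CLI
(`epidyn synth`, `epidyn analyze`) is a thin wrapper; stage selection is
via `--stages`, and the summary JSON is the run's report.

## Problem sizes

Tests and the acceptance script run at desk scale as the package's own
choice of statistical adequacy: 1000–4000 cells and 120–1600 frames for
closed-form checks (cells are independent, so standard errors scale as
1/√N), 5000 draws for the size-law recovery, ≥ 50 events for boost
recovery, 500 cells for the soft-mode fixture. The trap-crossover check
simulates 8000 min so that lags δt ≫ τ_r = 200 min are reachable with
dense origin averaging; within a 27-h record the late-time log-log slope
of this model is still depressed by the saturated intracage term.

## Known limitations

- The generator has no excluded volume or neighbour exchange; cage-relative
  statistics and velocity correlations are validated on constructed or
  statistical fixtures, not interacting ones.
- Single-frame structural entropy is comparable only at fixed kernel
  settings and pooling; its absolute scale is estimator-dependent.
- `fit_stretched_exponential` needs the record to cover the decay of Fs
  below its threshold for the q values of interest; short records leave
  low-q rows unfitted (reported, not extrapolated).
- TrackMate XML reading covers spots+edges models (the common export); gap
  closing is deliberately not reimplemented — gapped tracks are dropped.
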