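# Methods

`dxduo` implements the two complementary X-ray single-molecule motion assays
that use diffracting nanocrystals as orientation probes on a protein, with
*two* chemically distinct probes (Au and ZnO) recorded simultaneously so that
two protein domains can be followed in one experiment:

* **DXB (diffracted X-ray blinking)** — monochromatic beam. A probe crystal
  diffracts only while its lattice planes satisfy the Bragg condition, so
  rotational motion makes the photon count in a Debye–Scherrer-ring pixel
  *blink*. The decay constant of the pixel-intensity autocorrelation function
  measures how fast the probe reorients.
* **DXT (diffracted X-ray tracking)** — pink (broad-band) beam. Each crystal
  produces a Laue spot whose on-detector trajectory maps the probe's angular
  motion: azimuthal displacement about the beam axis is twisting (χ), radial
  displacement is bending (θ) of the diffracting plane.

Because Au is cubic (a = 4.08 Å) and ZnO hexagonal (a = 3.25 Å, c = 5.2 Å),
their rings — Au (111), (200); ZnO (100), (002), (101), (102) — fall at
distinct radii (minimum gap ≈ 8 px at 17.7 keV, 95 mm, 172 µm pixels) and the
two probes can be analysed independently.

## Ring geometry

Plane spacings use the standard closed forms (cubic: d = a/√(h²+k²+l²);
hexagonal: 1/d² = (4/3)(h²+hk+k²)/a² + l²/c²), the Bragg angle
θ_B = arcsin(λ/2d) with λ[Å] = 12.3984/E[keV], and a flat-detector
projection r = L·tan 2θ_B / pitch with no polarization or solid-angle
correction. Pixels are 0-based (row, col) with centers at integer
coordinates; ring ROIs are annuli |r − r_ring| ≤ half-width (default 2 px,
an analysis choice — the width is not physically constrained) minus any
rectangular masks (e.g. intermodule gaps, supplied in the config because gap
placement is instrument-specific). For a pink beam of fractional bandwidth
b, a ring becomes a radius band spanning the energies E(1 ± b/2); spot
routing accepts a radius within the band plus tolerance, and an observed
radius matching two rings is an error, never silently attributed.

## DXB analysis

Per ROI pixel the non-centered autocorrelation

    ACF(τ = mΔ) = ⟨I(t) I(t+m)⟩ / ⟨I(t)²⟩

uses the (n − m) available pairs in the numerator and the full-trace mean
square in the denominator (the denominator is deliberately lag-independent,
so ACF(0) = 1 exactly). For white noise the τ>0 plateau is μ²/(μ²+σ²) —
25/30 for Poisson(5) — which the tests use as a closed-form oracle. The
default maximum lag is n/4 (longer lags are pair-starved); the benchmark
analyses fit a window of roughly one to two correlation times (see
"Operating range" below).

Each pixel ACF (τ > 0) is fitted with k + A·exp(−T·τ) by unbounded
least squares. Initialisation: k₀ = min(ACF), A₀ = ACF(Δ) − k₀, T₀ from the
lag where the curve falls to A₀/e above k₀; if the curve rises overall a
growing-exponential start is also tried so the solver can reach T < 0
solutions, and up to five jittered restarts (seeded) run before a fit is
declared non-converged. Fits are *accepted* only when k > 0, A > 0, T > 0;
non-convergence is encoded in the flag, never raised. Accepted curves can
also be pixel-averaged and refitted with weights 1/SE², where SE is the
per-lag standard error across pixels (zero SEs get the largest finite
weight present).

Accepted decay constants per probe/condition are summarised as the
five-number box statistic (type-7 linear-interpolation quantiles, the common
default). The mobility decomposition fits the decay histogram
(Freedman–Diaconis binning unless overridden) with a sum of two Gaussians by
least squares on bin counts, orders components μ₁ ≤ μ₂ (group-I = low
mobility) and reports area percentages from the analytic component areas,
which makes pct₁ + pct₂ = 100 an identity. Conditions are compared with the
two-sided Wilcoxon rank-sum test: exact enumeration of all C(n, n_a) midrank
assignments when n_a + n_b ≤ 12 (two-sided p = min(1, 2·min(P≤, P≥))),
otherwise the normal approximation with midrank-tie and continuity
corrections. Stars: *** p<0.001, ** p<0.01, * p<0.05 (only the *** threshold
is standard in this workflow; the lower tiers are the usual conventions).

The radiation-damage check splits a movie at the midpoint, runs the full
per-pixel chain on each half independently, and flags damage when the two
accepted-T distributions differ at p < 0.001.

## DXT analysis

Movies are first calibrated by the per-frame incident intensity
(frame × mean(I₀)/I₀), which preserves the stack mean. Spots are local
maxima above a median-background-subtracted threshold with non-maximum
suppression (integer count ties can otherwise duplicate a peak), refined to
sub-pixel position by intensity-weighted centroid in a 7×7 window. Linking
is greedy nearest-neighbour with per-frame displacement limit (default 5 px)
and gap memory (default 2 frames); crossing-track disambiguation is out of
scope and the simulations used for validation are constructed non-crossing.
Each trajectory is routed to a ring by its mean radius.

The angular decomposition sets χ = unwrapped azimuth about the beam center
and θ = ½·Δ(2θ_scatter) with 2θ_scatter = arctan(r·pitch/L), both cumulative
from 0. The ½ factor encodes that tilting a crystal plane by δ deflects the
Bragg-reflected ray by 2δ; this convention is recorded in output metadata
because the axis definitions are not standardised.

Per trajectory the temporal MSD δ²(mΔ) = ⟨[x(t+mΔ) − x(t)]²⟩_t is computed
for m = 1…n/4 and fitted with the anomalous-diffusion model
δ²(t) = D_α·t^α + 2β², with D_α, β² ≥ 0 and α ∈ (0, 3]. Weights follow the
relative-variance growth of a single-trajectory temporal MSD,
σ_m ∝ δ²(m)·√(m/(n−m)), so pair-starved long lags do not dominate. α
classifies the regime (subdiffusion < 1 < superdiffusion, "normal" within
1e-6 of 1 — with noise a fitted α is almost never exactly 1, so the label
"normal" effectively marks noiseless/idealised inputs). Lifetime filtering
(keep min ≤ lifetime ≤ max) separates fast-moving populations (short-lived
spots under a pink beam, which tolerates only ≈ ±0.4° of tilt at 10%
bandwidth) from slow ones.

Motion maps place one point per trajectory at (S_χ, S_θ); the default
statistic S is log₁₀ of the temporal MSD at lag 1 frame, per axis. What
quantity such published maps bin is the single largest inferential gap in
this workflow, so the statistic, lag and units are embedded in every
histogram's metadata, and net displacement or D_α can be selected instead.
Densities are normalized to unit sum; subtraction maps are density
differences (total exactly 0) on *shared* bin edges (no resampling — a
mismatch is an error); hotspots are bins above a density quantile (default
0.90 of occupied bins) with density-weighted centroids, and hotspot
movement between conditions is the centroid displacement. Peak positions
use 3-point parabolic refinement; FWHM interpolates the half-maximum
crossings linearly (clamped at the histogram edge if a side never crosses;
single occupied bin ⇒ FWHM = bin width).

## Synthetic data

No public beamline recordings exist for this assay, so the package ships a
generator whose *generating parameters are the oracles* for every test.

Orientation dynamics use a small-angle planar approximation: independent
tilt and azimuth axes with Gaussian increments of variance 2·d_rot·Δt
(d_rot in rad²/s). This keeps χ and θ independent by construction and is
adequate for the sub-degree to few-degree motions of interest; it does not
model full SO(3) diffusion.

**DXB movies.** A free tilt walk would leave the Bragg acceptance
permanently and the blinking would be nonstationary, so the rendered
blinking uses a *confined* tilt: a stationary Ornstein–Uhlenbeck process
with relaxation rate λ = d_rot/σ² (Einstein relation; short-time increments
still 2·d_rot·Δt) and stationary spread σ equal to the rocking half-width w
— a tethered probe revisits the acceptance, which is what sustains
blinking. The diffracted rate is M·exp(−tilt²/2w²) (Gaussian acceptance
standing in for mosaic spread; σ = w gives usable blinking contrast
A/k ≈ 0.15 while keeping the ACF near-exponential). The default rocking
half-width of 30° is an *effective* angular acceptance of the probe+tether
system, not a crystallographic rocking curve; it places the decay constants
produced by d_rot values of order 10⁻²–1 rad²/s inside the window the
100 ms cadence can resolve. Each of n_crystals distinct ROI pixels hosts
`crystals_per_pixel` independent crystals (default 1; a ring pixel
physically integrates every probe whose azimuth maps onto it, but stacking
crystals divides the ACF contrast by their number). Counts are Poisson; the
flat background default is 0.1 counts/pixel/frame (photon-counting
detector, no read noise). The default d_rot (0.0117 rad²/s) sets the
nominal decay 2·d_rot/w² to 0.085 s⁻¹, the scale reported for
membrane-protein domains at this cadence.

For this model the intensity ACF has a closed form (a bivariate-normal
integral): ⟨L(t)L(t+τ)⟩ = M²/√((1+a)² − a²e^(−2λτ)) with a = σ²/w², plus
shot-noise and background terms (`dxb_expected_acf`). It is *near*- but not
exactly single-exponential; `dxb_expected_decay_constant` fits the
exponential to this noiseless curve to define the effective decay constant
(≈ 1.1–1.3 × the nominal 2·d_rot/w², window-dependent), and
`dxb_config_for_decay` root-finds d_rot so the effective decay equals a
requested value. These closed forms, not the simulation, are the
correlation-time oracle.

**Operating range (measured, and why the benchmark sits where it does).**
With 2000 × 100 ms frames, the median of per-pixel fitted T is a consistent
estimator only when the record holds roughly ≥ 40 intensity correlation
times. In 12-seed scans the median lay within a few % of the effective
decay (worst seed −9%…+9%) at a 5 s correlation time with a 100-frame fit
window, but was skewed +15…+30% (worst +64%) at a 10 s correlation time —
a record-length limitation, not a fitting bug, and one that applies equally
to real recordings. The parameter-recovery benchmark therefore runs at an
effective decay of 0.2 s⁻¹ (5 s correlation time) with a 100-frame window;
slower motions are still *ordered* correctly (the monotonicity check spans
d_rot = 0.01–1 rad²/s) and are quantifiable via the pixel-averaged weighted
fit, which stays within ~10% down to 10 s correlation times. For the same
reason the radiation-damage benchmark compares half-records with a 50-frame
window (≈ one correlation time per window); at those settings 20/20
stationary runs stay below the damage threshold while frozen-second-half
movies are flagged at p ≤ 10⁻⁹.

**DXT trajectories.** Spots are born at staggered frames (first at 0),
live geometric(lifetime_mean) frames (default mean 200), and walk on their
ring: azimuth moves the spot along the ring, tilt moves it radially through
r = L·tan(2θ_B + 2·tilt)/pitch. The default d_rot = 5·10⁻⁶ rad²/s keeps
tilt drift inside the 10%-bandwidth acceptance over a typical lifetime. For
tracker validation each ring offers fixed azimuth slots on the detector's
long-axis arcs (non-crossing regime by construction); for ensemble
statistics azimuths are drawn uniformly. Rendering stamps a Gaussian PSF
(σ = 1.2 px, 400 expected photons/spot) on a flat background and
Poisson-samples each frame.

The generator does **not** emulate: crossing trajectories, energy-resolved
Laue intensities, detector distortion or gain structure, structured cell
background, intensity blinking of Laue spots, or probe-size effects.
Passing tests therefore demonstrate correctness of the estimators under the
stated stochastic model, not robustness to every artefact of beamline data.

## Problem sizes used in tests and the acceptance script

Blinking benchmarks render 200-pixel ROI movies at the full 2000-frame
protocol on a compact 120×120 detector (the ring geometry is exact; the
smaller sensor only trims empty background). Tracking benchmarks render the
full 195×487 PILATUS-100K frame for 5000 frames with ~20 concurrent spots,
and use 100 full-length ground-truth trajectories for anomalous-diffusion
recovery. The damage check uses 20 independent stationary movies plus
frozen-second-half movies. Mixture decomposition uses n = 5000 draws.

## Known limitations

* Per-pixel decay medians are biased high for correlation times ≳ 1/20 of
  the record (see Operating range); prefer the averaged-ACF fit there.
* The greedy linker will mis-assign crossing spots; dense recordings need a
  global tracker, which is out of scope.
* The two-Gaussian decomposition is a histogram fit, not a mixture
  likelihood; with heavily overlapping groups the split depends on binning
  (binning is therefore configurable and recorded).
* θ–χ map axes are convention-dependent; compare maps only with identical
  axis statistic, lag and edges (the code enforces shared edges).
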