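# Methods

`tightdock` quantifies the structural signature of tightly docked
membrane–membrane interfaces: local bilayer thickening, protein
depletion from the contact zone, and the relaxation kinetics that order
the underlying molecular events (headgroup tilt → lateral area
shrinkage → membrane thickening). Because raw micrographs and long
atomistic trajectories are not redistributable, every analysis ships
with a seeded synthetic generator that emulates the statistical
structure the analysis assumes, carrying full ground truth so each
estimator can be scored end to end.

## Image model and thickness estimation

A membrane in projection is modelled as two Gaussian ridges of unit
amplitude and width σ_ridge (default 0.8 nm), one per headgroup layer,
at signed distance ±t/2 from the membrane mid-surface; the
peak-to-peak distance across the membrane therefore equals the
thickness t by construction. Free vesicles are circles; docked pairs
share a flat contact face — a chord of each sphere at the common
tangent, with half-width h (default 12 nm). At a *tight* interface the
local thickness is t + Δ (default Δ = 0.6 nm) inside the contact zone,
and the protein channel (a single Gaussian ridge on the mid-surface)
is scaled there by the interface/free signal ratio (default 0.2 tight,
1.6 loose). Pixel size defaults to 0.5 nm/px — a free parameter of the
generator, chosen as a typical cryoEM scale, not a measured value.
i.i.d. Gaussian noise (σ 0.05 of ridge amplitude) is added last;
all randomness derives from one spec seed.

Thickness is read out exactly as in the imaging analysis it
reproduces: intensity profiles are taken either radially about a
vesicle centre (azimuthal mean per radial bin, free membranes) or
along a line perpendicular to the docking interface (bilinear
interpolation, averaged over an odd number of parallel pixel rows).
Profiles are smoothed (Gaussian, σ = 1 px), local maxima above a
prominence threshold (10 % of the dynamic range) are refined to
sub-sample precision by a three-point quadratic fit, and thickness is
the separation of the two peaks assigned to one membrane. At an
interface, the four sorted peaks split into outer/inner pairs per
membrane; if the proximal ridges of the apposed membranes have merged
(separation ≲ 2 σ_ridge), the affected measurements are returned with
`resolved=False` rather than a number.

Known bias: overlapping ridge tails pull neighbouring peaks together.
At the default interface geometry (proximal ridge separation 2.5 nm)
this inflates each membrane's measured interface thickness by roughly
+0.1 nm, so the recovered tight-vs-free thickening is ≈0.75 nm for a
true 0.6 nm. The effect shrinks with ridge separation and vanishes for
isolated membranes (free-vesicle bias < 0.01 nm). We keep the
peak-based estimator because it is the field's standard readout; a
multi-Gaussian fit would remove the bias at the cost of a different
estimator than the one being emulated.

The default tight-interface geometry keeps the facing headgroup ridges
2.5 nm apart so that all four peaks are resolvable and per-membrane
thickness can be scored; real tight interfaces often blend the
proximal ridges into a single line, which the pipeline reports as
`resolved=False` (exercised separately in the tests).

## Docking classification

A pair is called *tight* when the background-subtracted peak protein
signal on a line profile across the interface, divided by the same
quantity on the free membrane, falls below a threshold. The source
rule is qualitative (signal "decreased or absent"); the default
threshold of 0.6 is our quantification, conservative toward the loose
call (ties → loose) and exposed in configuration. Background defaults
to the median of a 5-px border frame. Being a ratio of
background-subtracted signals, the call is invariant to global
intensity rescaling.

## Group comparisons

Thickness distributions are compared with a one-tailed unpaired
Student t-test (equal variances), matched within-membrane comparisons
with the Wilcoxon matched-pairs signed-ranks test (exact null
distribution where available; all-zero differences return p = 1,
flagged). For combined sample sizes ≤ 16 the t-test p-value is taken
from the exact permutation distribution of the t statistic (full
enumeration of group relabelings, ties counted half), which reproduces
p = 0.5 exactly under the symmetric null and agrees with conventional
enumeration to 1/(2·n_splits) on tie-free data; larger samples use the
t distribution.

## Trajectory observables

Frames hold particle positions (nm) with role labels (P, N, chain
bead, water oxygen), per-particle lipid indices and an orthorhombic
box. The membrane normal is fixed to the z-axis; no local-normal
estimation. Leaflets are found by 1D clustering of the P
z-coordinates: the 2·n_membranes clusters are cut at the largest
sorted-z gaps, and the assignment is accepted only when every boundary
gap exceeds three times the largest within-cluster gap — otherwise the
frame is rejected with the ambiguous lipids named, rather than
silently mis-assigned.

- **Thickness**: |mean z(P, top leaflet) − mean z(P, bottom leaflet)|
  per membrane; **inter-membrane distance**: same quantity between the
  two gap-facing P layers.
- **Lateral area**: box_x·box_y; **area per lipid**: divided by the
  leaflet lipid count; **volume**: lateral area × P-to-P thickness.
  The volume observable is not given a microscopic definition in the
  source analysis; the area×thickness definition makes the
  incompressibility argument (area ↓5 % at fixed volume ⇒ thickness
  ×1/0.95) an algebraic identity, which the tests exercise.
- **Headgroup tilt**: cos φ = (P→N)·n̂/|P→N| with n̂ the leaflet
  outward normal (+z for the top leaflet of each membrane). Headgroups
  are assumed not to wrap across the periodic z boundary. The source
  wording leaves the vector direction ambiguous; we fix P→N and expose
  a flip flag in the restraint module.
- **Chain order**: S = (3⟨cos²θ⟩ − 1)/2 per successive chain-bead
  bond, θ against the z-axis — the standard second-Legendre order
  parameter, used here as the interpretation of an otherwise
  unspecified "chain order" observable.
- **Hydration**: water oxygens strictly between the facing mean P
  layers, per nm² of lateral area.
- **Leaflet electrostatics**: E = Σ_{i<j} k_C q_i q_j / r_ij over all
  particle pairs within one leaflet with r ≤ 1.2 nm, minimum-image in
  x,y only, k_C = 138.935458 kJ·mol⁻¹·nm·e⁻². This is a direct cutoff
  sum, not Ewald/PME: a reciprocal-space term cannot be decomposed per
  leaflet, so the per-leaflet observable is defined by the real-space
  pair sum. All intra-leaflet pairs are included (no intramolecular
  exclusions — the source analysis does not state any). Default role
  charges are the zwitterionic ±1e on P and N with neutral chains.

The frame generator places lipids on a jittered lattice, realises the
requested per-leaflet mean cos φ exactly (polar angle arccos(c),
uniform azimuth), and separates P layers by exactly the requested
thickness/distance before optional Gaussian positional noise — so
every metric must recover its spec value exactly at zero noise, which
is the closure property the tests enforce.

## Relaxation kinetics

Each observable's equilibration to the double-membrane state is
modelled as f(t) = x∞ + (x0 − x∞)·e^(−t/τ) and fitted per replica by
trust-region least squares with an analytic Jacobian and τ bounded
positive. Initialisation is derivative-free: x0 from the first sample,
x∞ from the last-decile mean, τ from the 63 % crossing time. Constant
series, optimiser failures, and τ beyond 100× the data window return
`converged=False` (never an exception); diverged fits are excluded
from medians but counted.

Normalisation to the [0, 1] range maps the single-bilayer equilibrium
to 0 and the double-bilayer equilibrium to 1 via
y = (x − x_single)/(x_double − x_single); it is exactly affine-invariant
and exactly invertible.

The temporal ordering is declared from median τ per observable. The
source analysis reports the ordering without an uncertainty procedure;
our addition is a bootstrap over replicas (default 1000 resamples,
fixed seed): for each pair, the support is the fraction of resamples
in which the medians reproduce the order, and the full ordering is
declared only when every adjacent pair reaches 0.95 support. Under an
equal-τ null this declares an ordering in ≤5 % of repeats (checked by
simulation with 100 repeats of 100-replica ensembles at 0.5 ns
sampling-interval-doubled grids to keep the check fast).

Study conditions for the ordering experiment: 500 replicas, 1 ns
duration at 1 ps sampling, additive Gaussian noise σ = 0.05 on
normalised observables, true τ = 0.05 / 0.15 / 0.40 ns for tilt /
area / thickness. Each replica draws from an independent child of the
ensemble seed, so the ensemble is bit-reproducible.

## Angle restraint

The tilt bias E(φ) = k(1 − cos(φ − φ0)) (k in kJ/mol, φ0 the minimum)
is implemented with analytic forces on both headgroup particles,
written via cos φ = v_z/|v| and sin φ = |v_xy|/|v| so the gradient is
smooth off the polar axis; on the axis the azimuth is degenerate and
the in-plane force is taken as zero. Pair forces sum to zero exactly.
The demo relaxation is explicitly *not* molecular dynamics: it is an
overdamped orientation-only update on the unit sphere (bond length
fixed) with thermal noise (kT default 2.494 kJ/mol ≈ 300 K) and a
reflecting boundary at the equator, matching the outward-hemisphere
convention of the synthetic frames; it exists to produce bias-driven
cos φ series that exercise the kinetics module end to end. With k = 0
its long-time mean cos φ is the hemisphere average 1/2.

## What the synthetic data does and does not show

The generators emulate the *statistical* structure the estimators
assume: Gaussian ridges with known separation, lattice bilayers with
exact layer spacing, closed-form relaxations with i.i.d. noise. They
do not model CTF, defocus, 3D projection, realistic lipid chemistry,
thermal membrane undulations, or correlated noise. Passing tests
therefore demonstrate that the estimators are correct and unbiased
under their own model assumptions (and quantify the one known bias,
ridge-tail overlap); they do not certify accuracy on real micrographs
or trajectories, where model mismatch dominates.

## Problem sizes and numerical choices

Default problem sizes — 50 images per condition, 100 lipids per
leaflet, 500 relaxation replicas, 1000 bootstrap resamples, 100 null
repeats at 100 replicas — are the package's study conditions and keep
a full validation run in the order of half a minute on one core.
Tolerances used by the tests: machine-precision closure (≤1e-9 nm) on
noise-free frames, 1e-6 relative force agreement against central
differences (h = 1e-6 nm), sub-0.1 px peak localisation against
dense-grid oracles. Ties in peak assignment are broken by position
order; ratio ties in classification go to loose; leaflet clustering
ambiguity is a hard error.
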