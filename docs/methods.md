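# Methods

## Scope and model

The package analyses *Emiliania huxleyi* coccolith populations the way a
calcification-ecology study does: per-coccolith mass and length from
cross-polarized light microscopy (PLM), shape descriptors from SEM-style
measurement tables, a per-sample calcification index, classification of
Type A coccoliths into four calcification varieties, and correlation/
ordination of the resulting per-sample aggregates against environmental
gradients. Because per-coccolith field data of this kind are essentially
never deposited, the package's evidence base is a synthetic generator
with exact ground truth; this note records the models, the defaults and
what the synthetic results do and do not demonstrate.

## Coccolith geometry and mass

A coccolith is modelled in plan view as three concentric similar
ellipses on the distal shield: a central area (semi-major radius r_c,
covered by calcite of thickness t_central over a fraction `closure` of
its area, with the thin base plate elsewhere), the calcite tube of
radial width TW and thickness t_tube (the optically dominant ring), and
the outer shield of radial extent SL and thickness t_shield. With
semi-major radius a = DSL/2, the radial budget r_c + TW + SL = a gives
the constraint SL + TW ≤ DSL/2. True mass is the closed-form sum of
thickness × region area × ρ_c (ρ_c = 2.7 pg µm⁻³); the rasterizer
reproduces it to well below 1% at the default 0.05 µm/px, which is what
the mass-conservation tests check.

This is a deliberately flat model: no proximal-shield 3-D structure, no
element sutures, no interference colours. Its purpose is to make the
measurement chain falsifiable, not to render photorealistic coccoliths.

## Optics

Grey level is linear in total calcite thickness with a plateau at
1.55 µm (the first-order birefringence limit for calcite), additive
Gaussian read noise, and 16-bit quantization:
`grey = clip(bg + gain·t, bg, bg + gain·1.55)`. Defaults: 0.05 µm/px
(≈ ×1000 with a typical microscope camera), gain 30 000 grey/µm,
background 800 grey, noise σ = 40 grey. The gain is a free calibration
parameter in real use; the default puts the thickest tubes (~1.1 µm)
around half of the 16-bit range, comfortably below saturation.

## Generator defaults

Per-variety size/thickness distributions are free parameters — the
field literature gives qualitative definitions (A1 low-, A2 medium-,
A3a/A3b high-calcified) but no quantitative distributions. Defaults
were chosen once to produce DSL ≈ 2.5–4.5 µm and single-coccolith
masses of a few pg, with A3b drawn larger and thicker-tubed than A1 so
that the positive size–calcification covariance seen in natural
populations emerges in aggregates. Tube width is drawn as a fraction of
DSL (7–18.5% depending on variety) and SL as a ratio of TW, so
populations are geometrically similar in plan view; a consequence is
that the apparent-length shortening (see below) is roughly proportional
to size and the apparent-vs-true-length regression slope stays below 1,
as it must for a length-correction calibration to be meaningful.

The SL/TW ratios are drawn with a separation margin of 0.15: A1 at
ratio ≥ 1.15, A3b at ≤ 0.85, A2 within ±0.05 of 1. A classifier with
tolerance ε between 0.05 and 0.15 therefore recovers the generated
labels exactly when measurement noise is off — the round-trip tests
quantify this.

## Rendering and measurement

The open central area carries the thin base-plate thickness rather than
zero, so each coccolith is one connected above-background region — on
real micrographs the proximal plate keeps the central area from being
optically empty. Segmentation thresholds the raster (default: Otsu on
log(grey − background) restricted to pixels above a 5σ MAD noise floor,
which places the split between the dim shield and the bright tube; a
fixed threshold is available for strict reproducibility), fills holes
so a tube annulus plus closed center is a single intact component, and
flags components that touch the frame border, fall below a minimum area
(30 px), or whose convex hulls overlap another component's ("intact and
isolated" filters). Flagged particles are excluded from all statistics.

Mass integrates background-subtracted grey over the above-background
region connected to the detection mask (hysteresis growth), so the dim
shield's calcite is counted. Apparent length is the maximum Feret
diameter of the *bright* mask only — chosen over the ellipse major axis
for robustness to slit-induced concavity — which is why it
systematically underestimates DSL: the thin shield renders below the
detection threshold by design, mirroring the bias that motivates the
length correction. Over a 500-coccolith rendered batch the median
absolute mass error is under 2% and >99% of apparent lengths fall short
of the true DSL.

## Length correction

`LengthCalibration` is an OLS regression of SEM total length on
apparent length (scipy linregress underneath), exposed as a sklearn
estimator with standard errors for both coefficients. The published
Type A coefficients (slope 0.585, intercept 0.4537 µm) ship as a
constructed fallback model; `inverse()` exposes the opposite
orientation rather than guessing which scale a user's lengths are on.
Corrected lengths that come out non-positive are flagged as NaN with a
warning instead of propagating silently.

## Calcification index

`C_i = M_s / (k_s · L_c³ · ρ_c)` with k_s = 0.02 (Type A only; no
per-morphotype shape constants are provided). The default averaging
order computes C_i from the sample-mean mass and the cube of the
sample-mean corrected length; `calcification_index_per_coccolith`
averages individual ratios instead. The two differ by a Jensen gap on
heterogeneous samples, which a test demonstrates; neither order is
canonical, so both are exposed.

C_i is scale-invariant under geometric similarity (mass ∝ length³),
strictly increasing in M_s and strictly decreasing in L_c — these are
property-tested, and they are what makes C_i a size-normalized
calcification measure rather than a restatement of mass.

## Variety classification

Rules, in order of precedence: closure ≥ closure_cut → A3a (the SL/TW
ratio of closed-center coccoliths is too variable to use); else
SL > TW·(1+ε) → A1; SL < TW·(1−ε) → A3b; otherwise A2, with boundary
equality resolving to A2. Defaults ε = 0.10 and closure_cut = 0.75 are
operationalizations of the qualitative field definitions ("SL ≈ TW",
"nearly or completely closed") and are surfaced in the API and CLI.
The rules partition the measurement space — every valid measurement
receives exactly one label — and percentages are reported relative to
the Type A total, so the four always sum to 100. Type B/C enters only
as a labelled fraction; no B/C geometry is modelled.

## Transect and niches

The virtual transect spans −5.5°E to 33°E with per-variable smooth
profiles (linear or logistic in longitude, linear in depth, small
Gaussian jitter): salinity, alkalinity, temperature and carbonate ion
rising eastward; pCO₂ and nutrients falling; PAR% decaying with depth
(e-folding 35 m). Variety abundances follow Gaussian niche responses on
standardized environmental variables — the standard community-ecology
response model — with defaults encoding the qualitative field pattern:
A1 in fresh, well-lit western surface water; A3b in salty eastern
mid-photic water; A3a in cold western water; B/C with the Atlantic
inflow. Per-sample counts are multinomial over the niche scores. All
randomness flows from the config seed; identical configs give
byte-identical outputs.

The end-to-end tests run 20 stations × 2 depths × 150 coccoliths with
up to 3 rendered frames of 16 coccoliths per sample — sizes chosen to
keep a full pipeline run around a minute while leaving the rank
correlations decisively signed. What passing shows: the measurement
chain does not destroy the generator's ordering structure (signs and
significance of the configured responses, eigen-structure of the CCA).
What it does not show: anything about magnitudes of real-world
correlations, which depend on field noise sources (coccosphere
fragments, overlapping debris, reworked nannofossils, optical
miscalibration) that the generator deliberately omits.

## Spearman and CCA

Spearman's ρ is the Pearson correlation of mid-ranks (average ranks on
ties). Two-sided p-values: exact enumeration of all n! permutations for
n ≤ 9, t approximation with n−2 degrees of freedom above. Significance
is flagged at p ≤ 0.05 with the usual one/two-star table convention; no
multiple-testing correction is applied to the battery by default
(a Benjamini–Hochberg helper is provided).

CCA follows the weighted-regression formulation: chi-square
standardized residuals Q̄ = (P − rcᵀ)/√(rcᵀ) of the relative-abundance
table, environmental columns standardized with row weights r, Q̄
projected onto the √r-weighted predictor span, and the projection
SVD-decomposed. Eigenvalues are reported as percent of constrained
inertia (percent of total inertia is also emitted, since ordination
software differs on this convention). Species scores use scaling
type 2; site scores are weighted averages by default with
linear-combination scores behind a flag; environment–axis association
is the intraset correlation (weighted Pearson with the LC axes, bounded
by 1 by Cauchy–Schwarz). Constant or collinear environmental columns
are dropped greedily with a warning (relative tolerance 1e-8);
all-zero abundance rows/columns are removed with a warning. Eigenvalues
are verified against an explicit projector-matrix eigendecomposition to
1e-10 and against an independent ordination implementation.

## Numerical and degenerate-input choices

- Pixel coordinates are 0-based, row-major, pixel-center.
- A flat (single-grey) foreground falls back to the midpoint threshold;
  an all-saturated raster raises, since its greys are uncalibratable.
- `measure_sem` derives central-area + tube length as DSL − 2·SL and
  raises if geometry makes it negative; optional Gaussian measurement
  noise clips lengths at zero.
- OLS calibration requires ≥ 2 pairs with distinct x; constant vectors
  give an undefined Spearman ρ (flagged NaN, not significant) rather
  than an exception, matching how correlation batteries over many
  variable pairs need to behave.
- Seeds: every stochastic routine takes a `numpy.random.Generator` or a
  config seed; nothing draws from global state.

## Known limitations

- The optics model is first-order linear; thick (>1.55 µm) calcite
  saturates rather than cycling through interference orders, so the
  package must not be used to quantify heavily over-calcified taxa.
- SEM measurement is table-driven; no SEM image processing is included.
- The calibration's orientation (which instrument is x) is the user's
  responsibility; the shipped coefficients are applied exactly as
  published.
- CCA significance testing (permutation tests on axes) is not
  implemented; the package reports the ordination itself.
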