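# Methods

This note documents the models implemented in `microlift`, the choices made
where the design was genuinely open, and what the synthetic-data generators
do and do not capture.

## Lift physics (`lift_physics`)

**Model.** The capillary opening is treated as a point sink of strength
proportional to the suction flow *Q*, near a rigid no-penetration wall (the
dish bottom). The method of images enforces zero normal flow at the wall by
adding a mirrored sink, giving the two-term axial velocity field in the
module docstring. The lift criterion is a Bernoulli force balance over the
tissue: the suction-induced dynamic-pressure drop across the tissue's top
face must exceed its submerged weight, `½ρv²A ≥ (ρc−ρ)Vc·g`. Only the axial
velocity component enters the criterion by default (the capillary is
nominally centered over the tissue, so lateral components are second
order); `full_magnitude=True` uses |u| instead.

**Normalization of the sink strength.** The raw two-term image sum with
per-term coefficient *Q* limits to `4Qh/d³` on axis for `h ≪ d`, whereas
the closed-form lift condition (and the headline d_max values it produces)
is built on the limit `v = 2Qh/d³`. We therefore carry the factor ½ on the
velocity field, i.e. `u_x = (Q/2)[(x−d)/R₁³ + (x+d)/R₂³]`. This is the
unique normalization under which the velocity-threshold criterion, its
small-height limit, and the closed-form maximum distance
`d_max = [2Q²h²ρA/((ρc−ρ)Vc·g)]^(1/6)` are mutually consistent; tests
verify the agreement of the two criteria on random far-field scenarios. The
placement of the face area *A* in the numerator of d_max was likewise fixed
by requiring that the closed form reproduce both the expected operating
values (1.2 mm for a 400-μm cuboid, 1.1 mm for 250 μm at 56 μl/s and
ρc = 1.079 g/cm³) and the scaling `d_max ∼ Q^(1/3)h^(1/6)` when `A ≈ h²`,
`Vc ≈ h³`. No other placement satisfies both.

**Assumptions and limits.** Ideal (inviscid, irrotational) flow; no tissue
deformation, adhesion or shear damage; *Q* is the pulse's peak value
treated as a step (a shaped pulse that dwells above the minimum lift flow
would make the effective d_max somewhat larger — not modeled). Off-axis
lift in `success_map(mode="model")` is an extrapolation of the on-axis
model; the measured lateral behavior is a "mushroom" profile (narrow
~0.4-mm lift radius within ~0.6 mm of the tissue, abruptly widening to
~1.2 mm above) that the point-sink model does not reproduce, which is why
`mode="empirical"` interpolates a packaged success table instead. That
table is a **synthetic surrogate**: the measurements exist only as a plot,
so the table encodes their qualitative geometry (stem radius 0.4 mm, cap
radius 1.2 mm from 0.6 mm height, decay to zero beyond 1.5 mm at the
0.8-mm operating height, loss of lift above ~1 mm) on a 0.1-mm grid with a
0.3-mm-wide linear decay band.

**Units.** SI internally (m, kg, s); constructors and CLI accept μm, mm,
μl/s and g/cm³. A test evaluates the closed form independently in a
mm–μl–s unit system to confirm dimensional consistency at 1e-9 relative.

## Pump model (`pump_model`)

Peak flow vs. speed setting is interpolated with a shape-preserving
monotone cubic (PCHIP): the calibration is smooth but has only four knots
(10/25/50/100% of maximum angular speed → 10.4/24.6/33.5/56 μl/s), and a
monotone interpolant is exact at the knots and cannot overshoot between
them. Settings outside the calibrated range are clamped with a warning —
this is also how sub-range settings (e.g. the ~3% setting near the minimum
lift flow of 5.1 μl/s) get flagged. Pulse volume is the trapezoid integral
of a sampled Q(t) trace. The packaged pulse trace is a constructed
surrogate: an asymmetric triangle with a 56 μl/s peak shaped so its
integral is 6.4 μl, the two properties that matter downstream; the true
waveform shape is not reproduced. The 30° operating arc (180°–210°) is
stored as metadata only.

## Vision (`vision`)

The generator renders dark anti-aliased disks (edge coverage encoded as a
linear intensity ramp one pixel wide) on a bright background (levels
60/200) with additive Gaussian noise, deterministic per seed. Detection
thresholds the image (Otsu by default, with a guard that refuses to split a
blob-free noise image; a fixed threshold is available for full
reproducibility), labels 8-connected components, and measures each blob.

The equivalent diameter uses a **subpixel area**: the summed
darkness fraction `(background − I)/(background − foreground)` over the
component's dilated support, with the foreground level estimated from the
blob's eroded core. For an anti-aliased disk this recovers the covered area
to well under a pixel, giving mean diameter errors ≈1–2 μm at 10 μm/px —
inside the ±3.5 μm accuracy the test suite asserts. That figure is a
property of the synthetic fixture at the stated pixel pitch, not a claim
about arbitrary cameras. Centroids are darkness-weighted (typical error
≪ 0.1 px). Adhered pairs are rendered as overlapping disks and deliberately
surface as a single larger detection — the platform's real failure mode —
rather than being resolved. The bubble heuristic flags blobs whose center
is nearly background-bright (rings); it is intentionally minimal.

Isolation filtering keeps tissues whose nearest neighbor (KD-tree over
centroids) is at least 2.0 mm away — the default matches the operating rule
derived from the wide lift radius at the 0.8-mm hover height — and whose
diameter falls in the user's size window. Camera→stage mapping is an
ordinary least-squares affine fit (exact on noise-free correspondences;
collinear or <3 points rejected), with residual RMS reported in mm. Pick
verification re-detects within 0.5 mm (default) of the target in the
after image: a tissue that merely shifted less than that still counts as
"still present", forcing a retry.

Coordinates: image origin top-left, x right / y down, 0-based pixels, with
pixel *i* centered at *i* + 0.5 grid units; physical dish mm coordinates
include that half-pixel offset. The stage plane is mm with y up; the affine
calibration absorbs the flip.

## Transfer simulator (`transfer_sim`)

Wells are visited row-major (A1…A24, B1…). Each attempt draws one of:
adhered pair (double delivered), stick (tissue lodges in the capillary —
its well stays empty and the error is invisible to the before/after image
check because the tissue did leave the dish), unpickable (tissue stays put
— visible to the image check, so the well is retried, once by default,
after a rescan that returns the tissue to the candidate pool), float
(tissue drifts — the after image no longer shows it at the target, so the
error goes uncorrected), or a clean single. A stuck tissue (queue depth
≤ 1) is dislodged by the next ejection, producing the empty→double
adjacency signature. Conservation of picked objects (an adhered pair is one
object) across dish, capillary and plate is asserted at every log step, and
logs are byte-identical per seed.

The "mouse" and "human" presets are **calibrated reproductions, not
predictions**: per-attempt probabilities were set analytically so the
expected per-well outcome rates match the measured plate statistics
(mouse ≈ 98.4/0.5/1.0% single/empty/double with no stick pathway, i.e. no
carryover doubles; human ≈ 92.8/4.1/3.2% with the stick pathway sized so
~56% of doubles follow an empty well). With the mouse preset an occasional
double can still *coincidentally* sit after an unrelated empty well; the
mechanistic claim — zero carryover doubles — is what the tests assert.

The timing model has two parameters, per-trip overhead and per-pick cost
(`t(n) = t_trip + n·t_pick`, capillary capacity 6). Their ratio is fitted
by least squares to the measured multi-pick speedups (1.35/1.66/1.8× for
2/4/6 tissues per trip) and the absolute scale anchored to ~65 min for one
384-well plate (~10.2 s per single transfer). Placement noise is a
per-calibration 2-D Gaussian bias (per-axis sd 103 μm, chosen so the mean
bias magnitude equals the measured ~129 μm accuracy via the Rayleigh mean
`sd·√(π/2)`) plus per-attempt isotropic jitter (sd 26 μm, the measured
repeatability); offsets can be composed with the empirical success table
to fail attempts that land outside the lift radius.

Open parameters the hardware does not pin down — retry count (default 1,
keeping runs finite) and rescan cost (default 3 s) — are configurable.

## Plate analysis (`plate_analysis`)

Well signal is the mean intensity inside a circular ROI minus a background
estimate (global blank-well median, or per-well annulus); subtraction is
floored at zero and shift-equivariant. Drug response is the per-well ratio
of corrected signal at day *N* to day 1; wells flagged at either timepoint
are excluded and their flags propagate, and an unflagged zero baseline is
flagged `ratio_undefined`. Outlier filters take their thresholds as
explicit inputs (in practice they are read off control wells, which only
the analyst can judge): the low cut applies at every timepoint, the high
cut only on the listed late days (default 7 and 12, when overgrown or
double-seeded wells reveal themselves). Filters flag rows, never drop them.

The sample-size helper uses the standard two-sample normal-approximation
formula `n = 2(z₁₋α/2 + z₁₋β)²(sd/Δ)²`, ceiling-rounded (16 at sd = Δ,
power 0.8, α 0.05); `method="t"` iterates with t quantiles for small-n
correction. It is a planning aid, not a test procedure; significance
testing itself is left to standard statistics packages.

The readout generator draws a lognormal per-well baseline (CV 0.30,
emulating tissue-to-tissue heterogeneity of patient material), scales later
days by the programmed condition effect, and adds a flat background plus
5% multiplicative read noise. It does not model spatial gradients, optical
crosstalk between wells, reagent decay, or growth dynamics between
timepoints — passing recovery tests shows the analysis arithmetic is
unbiased under heterogeneity and noise, not that real plates are this
clean.

## Problem sizes used in the test suite

Stochastic checks run at sizes chosen to keep Monte-Carlo error well below
the asserted tolerances: 500 seeded 384-well fills for rate recovery, 200
for the carryover correlation, 50 synthetic dishes (10 tissues each at
10 μm/px) for detection recall and centroid accuracy, and 20 synthetic
plates for drug-effect recovery. The whole suite runs in well under a
minute on one CPU.
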