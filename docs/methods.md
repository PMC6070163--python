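# Methods

This note records the models implemented in `cvdcmap`, the parameter
choices that matter, and the limits of what the test suite shows.

## Color appearance model

All perceptual computation happens in CAM02-UCS (J′a′b′), the uniform
space derived from the CIECAM02 appearance model with the Luo et al.
"large and small differences" constants (K_L = 1, c₁ = 0.007,
c₂ = 0.0228). The forward path is

encoded sRGB → linear RGB (piecewise IEC 61966-2-1 transfer curve) →
CIE XYZ (full-precision sRGB primaries matrix, D65 white) → CIECAM02
(J, M, h) → (J′, a′, b′),

and the inverse runs the appearance model backwards. The
implementation reproduces the two published CIECAM02 worked examples to
the printed precision (J = 41.73, C = 0.1047, h = 219.05°, etc.) and
round-trips random in-gamut colors at ≈ 1e-13 per channel.

**Viewing conditions.** Fixed to the standard-dynamic-range sRGB
convention: D65 adapting white, average surround (F = 1, c = 0.69,
N_c = 1), background luminance factor Y_b = 20, adapting luminance
L_A = 64/(5π) ≈ 4.07 cd/m². All pipeline numbers depend on this
preset; it is exposed as `ViewingConditions` for other targets. One
consequence worth knowing: at this low adapting luminance chromatic
adaptation is incomplete (D ≈ 0.83), so the display's neutral axis
carries a little UCS chroma — white sits at (100, −1.92, −1.14), not
(100, 0, 0) — and the displayable lightness range at a′ = b′ = 0 tops
out near J′ ≈ 99, not 100.

**Gamut handling.** `ucs_to_srgb` never clamps: out-of-gamut requests
return raw channel values outside [0, 1] so callers can measure the
violation. Clamping to [0, 1]³ (absolute colorimetric intent) is the
explicit `clamp_gamut` step. A request whose inverse model is
undefined (e.g. negative-lightness intermediates) yields NaN, treated
as out-of-gamut by every consumer.

## CVD simulation

The physiologically-based two-stage matrix model: a 3×3 matrix applied
in **linear** RGB (decode → multiply → re-encode → clamp). Applying it
in encoded space would change every downstream number. Severity is a
0–100 dial; the shipped anchor table holds the identity (severity 0)
and the published full-dichromacy matrices for deuteranopia,
protanopia and tritanopia (severity 100), with element-wise linear
interpolation between bracketing anchors. Both endpoints — the only
severities any reported number uses — are exact; intermediate
severities are a linear approximation of the published 10-step series
(the series itself is close to linear in severity, and the monotone
properties tested here are preserved). Matrix rows sum to ≈ 1, so
grays are preserved to < 0.01 per channel. The default deficiency is
deuteranomaly at severity 100: the most common CVD class at its
complete form, so one map serves mild through dichromatic viewers.

## Optimization pipeline

Stage order: simulate → lift to UCS → equalize a′b′ → linearize J′ →
convert back, clamp, re-convert.

**Equalization** interpolates a′ and b′ piecewise-linearly against the
original parameterization at `n_interp = 10,000` points, accumulates
polyline arc length, and selects `n_out = 256` points spaced
(total length)/255 apart, interpolating inside the crossing segment
rather than snapping to samples. J′ is carried along at the same
positions so the trajectory remains one coherent path; endpoints are
preserved exactly, as is the total arc length (within 0.5%), so the
map keeps its original hues and path. `n_out` generalizes to 512/1024.
A path whose total a′b′ arc length is below 1.0 UCS units (under one
just-noticeable difference across the whole map) is treated as
achromatic: equalization is skipped and the path is resampled linearly
in index instead.

**Displayable-lightness corridor.** For each equalized (a′, b′), the
J′ values displayable in sRGB are found by scanning J′ ∈ [0, 100] at
`jp_step = 0.1` with an in-gamut test at 1e-6 channel tolerance; the
scan agrees with a 0.01-step scan to within the step size. Entries
with no displayable J′ yield an explicitly empty interval.

**Linearization** replaces J′ with a straight line in entry index,
three ways:

* `fit` — ordinary least squares against the original J′ trend.
  Stays closest to the input but ignores displayability.
* `maxrange` (default) — the line from the *lowest* displayable J′ at
  the first entry to the *highest* displayable J′ at the last
  (mirrored for decreasing maps). This puts the ends of the map as far
  apart in lightness as the gamut allows, maximizing perceptual range;
  the line may dip outside the corridor at interior entries, and those
  entries clamp at finalization. That trade — a strictly larger
  lightness range in exchange for a small, fully reported clamp error
  at a handful of entries — is deliberate, and is what produces the
  characteristic clamped dark-blue start of the optimized viridis.
* `steepest` — the steepest line satisfying the corridor at *every*
  index, solved exactly as a linear program (slope-sign branch
  matching the input's J′ direction; ties broken by maximizing the
  uniform margin to the corridor walls). Never clamps, at the cost of
  a smaller range. Verified against a brute-force grid search over
  (slope, intercept) at 0.01 resolution.

If a gamut-bounded method is infeasible (e.g. the corridor crosses
against the map's direction), `optimize` falls back to `fit` and
records that in the report.

**Clamp-error accounting.** The finalizer reports, per entry, both the
absolute UCS distance between the intended (pre-conversion) J′a′b′
point and the point recovered after clamping and re-conversion
(`clamp_delta_e`, a percentage of the 0–100 lightness scale for
near-unit errors), and the same distance relative to the intended
vector norm (`clamp_error_pct`), plus map-mean and affected-entry-mean
summaries of each. On the default viridis run the 22 clamp-affected
entries average 0.61 UCS units of departure (map mean 0.17% relative);
the worst single entry reaches 3.5% relative. All analysis downstream
(adjacent-delta profiles, CDPS) uses the *re-converted* final colors,
never the intended trajectory, so clamping cannot hide.

## CDPS

For a transect of data values in [0, 1] rendered through an N-entry
map (value v → entry round(v·(N−1))): data deltas |v_i − v_j| and UCS
perceptual deltas are computed over **all** C(n, 2) unordered pairs in
a fixed lexicographic order (adjacent pairs alone cannot span the full
data-delta range). Perceptual deltas are divided by the
ordinary-least-squares slope (with intercept) of the grayscale
reference on the same transect, then m and r² come from OLS of
normalized perceptual delta on data delta. The grayscale therefore
scores m = 1 identically, by construction.

The grayscale reference is the **perceptually uniform** gray ramp:
equal-RGB colors whose J′ runs linearly 0 → 100 across the entries
(obtained by inverting a dense lightness-versus-gray-level table). An
RGB-linear ramp is not perceptually uniform — its J′ is visibly curved
against the encoded value, and it measures r² ≈ 0.990 versus ≈ 0.99996
for the uniform ramp — so the uniform ramp is also what `fixture("gray")`
returns.

The adjacent-delta profile (consecutive-entry UCS distances, optionally
after CVD simulation) is summarized by the "imperfection"
max|δ − mean δ|: 0.19 for the optimized viridis, 1.26 for jet.

## Test image

value(x, y) = clip₀₁(x/(W−1) + A(y)·sin(2πx/λ)) with A growing
linearly from 0 at the bottom row to `max_amplitude` at the top.
Defaults W×H = 512×128, λ = 8 px, amplitude 5% of range, following the
established convention for this diagnostic; all exposed as flags.
Overshoot at the left/right edges is clipped to keep the image in
[0, 1]; edge columns are excluded from quantitative checks.

## Synthetic data

`synth_trajectory(seed, n, chroma_radius, jp_range)` draws a circular
arc (random center angle and sweep of 90–270°) of the given radius in
the a′b′ plane with J′ linear over `jp_range`, converted to sRGB.
Defaults (radius 15, J′ 25–75) generate valid in-gamut maps across
seeds; geometry that leaves the gamut raises rather than silently
clamping. These maps are smooth and moderately chromatic — they
exercise equalization, linearization and invariants on paths with
benign curvature. What they do not emulate: the near-gamut-boundary
hues, sharp curvature and clamping behavior of real designed maps, so
pipeline behavior at the gamut edge is tested on the bundled standard
tables (viridis, jet), not on synthetic arcs.

## Numerical choices and degenerate inputs

* a′b′ interpolation is piecewise linear (splines would change arc
  length); the equal-spacing walk interpolates within the crossing
  segment.
* Equal-chord spacing holds to < 0.5% on smooth paths. Where the path
  has a hairpin (the simulated-viridis yellow end), chords of equal
  *arcs* are intrinsically shorter near the turn — up to ≈ 20%
  locally, insensitive to `n_interp` — which contributes part of the
  final 0.19 imperfection. This is a property of chord-based spacing
  on curved paths, not a resolution artifact.
* LP solved with HiGHS; deterministic for fixed inputs.
* Constant transects (zero data variance) and achromatic colormaps
  raise typed degenerate-input errors rather than returning NaN.
* The ImageJ LUT format is the raw 768-byte binary (256 R, 256 G,
  256 B bytes), channels quantized by round(v·255); text tables use an
  explicit float01/int255 dialect flag because values like "1" are
  ambiguous between the two scales.

## Known limitations

* Intermediate CVD severities (1–99) interpolate between identity and
  dichromacy rather than the published 10-step anchor series.
* The gamut corridor is resolved at 0.1 J′; bounds inherit that
  granularity.
* CDPS is 1-D (transect-based); no spatially aware difference metric.
* Diverging/cyclic maps are out of scope: the linearizers assume a
  monotone lightness target (a custom J′ profile can be substituted by
  calling the stage functions directly).
* Wide-gamut (non-sRGB) displays are supported only insofar as the
  viewing conditions and gamut test are configurable; no wide-gamut
  primaries ship with the package.
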