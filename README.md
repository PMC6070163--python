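# cvdcmap

Colormap optimization and evaluation for color vision deficiency (CVD),
working in the CIECAM02-UCS color appearance space.

More than 4% of viewers perceive color differently because of a CVD
(deuteranomaly and protanomaly — red–green deficiencies — being the most
common). Colormaps that look informative to a normal trichromat can
collapse into ambiguous bands for these viewers, and even for normal
vision many popular maps (jet above all) step through color at wildly
uneven perceptual rates. `cvdcmap` takes any ordered table of sRGB
colors and rebuilds it so that, *as seen by a viewer with a chosen CVD
type and severity*, it is

* **perceptually uniform** — consecutive entries are equidistant in
  CIECAM02-UCS (J′a′b′), the uniform space in which Euclidean distance
  approximates perceived color difference, and
* **brightness-linearized** — lightness J′ increases as a straight line
  across the map, over as large a range as the display gamut allows.

Applying the default settings (deuteranomaly, severity 100 = complete
red–green dichromacy, maximal-range linearization) to viridis yields a
blue-to-yellow map of the cividis family.

## Method

A colormap `C = (c_0 … c_{N-1})` is processed as:

1. **CVD simulation.** Each color is transformed by the
   physiologically-based matrix model: a severity-dependent 3×3 matrix
   applied in linear RGB (severity 0 = identity, 100 = dichromacy).
2. **Lift to CIECAM02-UCS.** Encoded sRGB → linear RGB → CIE XYZ →
   CIECAM02 under standard sRGB viewing conditions (D65 white, average
   surround, Y_b = 20, L_A = 64/(5π) cd/m²) → the Luo et al. uniform
   space (J′, a′, b′).
3. **Perceptual equalization.** a′ and b′ are interpolated at 10,000
   points; the a′b′ polyline arc length L is divided by N−1 and points
   are re-selected L/(N−1) apart, so consecutive colors are equidistant
   in hue/chroma while the path (the hues) is unchanged.
4. **Lightness linearization.** J′ is replaced by a straight line in
   entry index: either the least-squares fit to the original J′ trend
   (`fit`), or the line spanning the maximal displayable lightness
   range — from the lowest J′ displayable with the first entry's
   (a′, b′) to the highest displayable with the last (`maxrange`); a
   strictly gamut-feasible steepest line (`steepest`, an exact linear
   program) is also available.
5. **Return to sRGB.** The trajectory is converted back to sRGB and
   clamped to [0,1] (absolute colorimetric rendering intent); the
   clamped colors are re-converted to UCS so every departure from the
   intended trajectory is measured and reported, not hidden.

Colormaps are scored with the **colormap–data perceptual sensitivity**
(CDPS) statistic: over all pairs of points of a data transect, the
perceptual difference of the rendered colors is regressed on the
underlying data difference (normalized so a perceptually uniform
grayscale scores slope m = 1). The slope m measures sensitivity, r²
measures uniformity. A sine-wave test image (ramp plus oscillation with
amplitude growing toward the top edge) is provided for visual checks.

## Worked example

```python
import cvdcmap as cm

viridis = cm.fixture("viridis")
spec = cm.CVDSpec("deuteranomaly", 100.0)
report = cm.optimize(viridis, spec, method="maxrange")

value, entry = report.min_pre_clamp_channel
print(f"min pre-clamp channel {value:.4f} at entry {entry}")
print(f"clamp-affected entries: {report.clamp_affected.sum()}")
print(f"mean UCS error at affected entries: {report.affected_mean_delta_e:.3f}")
deltas, imperfection = cm.adjacent_delta_profile(report.final)
print(f"adjacent-delta imperfection: {imperfection:.3f}")

jet = cm.fixture("jet")
print(f"jet imperfection: {cm.adjacent_delta_profile(jet)[1]:.3f}")
res = cm.cdps(cm.uniform_transect(64), cm.fixture("gray"))
print(f"gray CDPS: m={res.m:.1f}, r2={res.r2:.5f}")
```

prints

```
min pre-clamp channel -0.0469 at entry 19
clamp-affected entries: 22
mean UCS error at affected entries: 0.611
adjacent-delta imperfection: 0.191
jet imperfection: 1.262
gray CDPS: m=1.0, r2=0.99996
```

The negative channel near entry 20 is the well-known dark-blue corner
of the optimized map that falls slightly outside the sRGB gamut: the
maximal-range lightness line dips below what that entry's chroma can
display, so the red channel goes to ≈ −0.05 and is clamped to 0. The
resulting departure from the intended J′a′b′ line averages ≈ 0.6 UCS
units over the affected entries — visible as a small bump in the
otherwise flat perceptual-delta profile (maximum deviation 0.19 from
the mean, versus 1.26 for jet). The grayscale reference scores exactly
m = 1 by construction and r² ≈ 1 because it is perceptually uniform.

The same workflow is available from a shell:

```sh
cvdcmap optimize --input fixtures:viridis --method maxrange \
    --cvd-type deuteranomaly --severity 100 --out cividis_like.csv
cvdcmap cdps --input fixtures:gray --transect uniform:64
cvdcmap testimage --cmap fixtures:viridis --out preview.png
```

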