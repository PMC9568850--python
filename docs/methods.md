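# Methods

## The measurement model

Intra-colony channels are cell-free conduits radiating from the centre of a
colony biofilm. In a fluorescence image of a GFP-expressing colony they are
darker curves inside a bright colony. The package measures the *width* of a
channel where it crosses a circle of radius r about the colony centre, for
a grid of radii, and characterises how that width changes with r.

The central trick is the polar unwrap: resampling the image about the
colony centre so that the circle of radius r becomes row r of a
(radius × angle) raster. A channel crossing then appears as a dip (after
inversion: a peak) on a 1-D angular profile, and its width is a 1-D peak
problem. The measured quantity is the full width at half maximum, with the
half-maximum level referenced to the peak's topographic prominence (apex
minus half the prominence), which makes the width insensitive to sloping
baselines such as the colony's radial intensity fall-off or its
ellipticity. An angular width Δk converts to micrometres by arc length,
Δk / n_angular · 2πr.

Profiles are treated as circular throughout: local maxima, prominences,
minimum peak separation and FWHM crossings all wrap across the 0°/360°
seam. A circumference has no endpoints, and linear treatment would split
any channel crossing the seam into two half-peaks.

## Pipeline stages and parameters

| stage | parameter | default | why |
|---|---|---|---|
| prefilter | disk median radius | 2 px | standard widefield denoise step before analysis |
| segmentation | threshold | mean gray level | deterministic, parameter-free; ties (= mean) go to foreground |
| polar unwrap | angular samples / turn | 7200 | 20 per degree; at r = 200 μm one sample ≈ 0.17 μm of arc |
| CLAHE | tile, slope, bins | 60 px, 3, 256 | contextual-tile equalisation with slope-capped histograms |
| despeckle | kernel | 3×3 median | removes residual impulse noise |
| peak detection | prominence | 20 % of profile range | rejects texture and noise bumps |
| peak detection | min separation | 9 angular px | merges double detections of one channel; kept constant at every radius even though its μm equivalent grows with r (a μm-based alternative is available via the config but off by default) |
| radial grid | start, step | 200 μm, 50 μm | below 200 μm the unwrap is too distorted to measure reliably |
| outlier filter | modified z-score cutoff | 3 (strict >) | M = 0.6745(x − median)/MAD; if MAD = 0, M = (x − median)/(1.253314·meanAD); if that is 0 too, keep all |
| trend fits | exponential form | y = a·e^{bx} | fitted log-linearly; R² in log space (the spreadsheet-trendline convention); an original-space R² is available behind a flag |
| comparison | test, α | Mann–Whitney U, 0.05 | rank test for non-normal, unequal-size samples; exact null for tie-free n_a·n_b ≤ 400, otherwise normal approximation with tie and continuity correction. No multiple-testing correction is applied — a deliberate caveat when many positions are compared |
| boxplot summary | quartiles, whiskers | linear-interpolation quartiles; Q1 − 1.5·IQR and Q3 + 1.5·IQR clamped to the data range | the convention common plotting libraries draw |

The lateral pixel size is a mandatory input everywhere. Image metadata is
never trusted for calibration because sensor-level and resampled pixel
sizes of large-field instruments frequently disagree.

Only radii whose entire circumference lies inside both the image frame and
the colony mask are measured (the full-circumference exclusion). The rule
is enforced twice: geometrically, by capping the radial grid at the largest
fully enclosed circle about the centroid; and at measurement time, because
out-of-frame polar samples carry an invalid flag that makes profile
extraction refuse the row.

## The synthetic generator

The generator is the package's ground-truth instrument, not a test
fixture. It renders, analytically:

- an elliptical colony (default semi-major axis 1150 μm, axis ratio 0.95)
  with a dome intensity profile `pedestal + (1 − pedestal)(1 − ρ^p)`
  (pedestal 0.75, p = 2) on a dark background — real colonies fluoresce
  strongly out to the rim, hence the pedestal;
- `n_channels` (default 30) channels radiating from the centre at jittered
  regular angles, each carved as a raised-cosine dip
  (depth 0.25 of the local dome) whose programmed local full width follows
  a constant, linear or exponential law in radius. The raised-cosine
  cross-section makes programmed width equal FWHM *exactly* by
  construction, so ground truth is unambiguous. An optional smoothed
  random angular wander reproduces meandering channel trajectories;
  amplitude 0 gives the straight radial channels typical of
  nutrient-limited growth;
- degradation: Gaussian blur of σ = 0.3 px (the σ-equivalent of a 700 nm
  FWHM lateral resolution at the default 1 μm/px sampling), then additive
  Gaussian noise (σ = 3 on the 8-bit scale; optionally Poisson), then
  8-bit quantisation. Identical seeds give bit-identical images.

Defaults were chosen once for realism: ~30 channels per circumference is
comparable to per-circumference detection counts on real colonies; the
channel depth reflects that a widefield image integrates the cell-filled
dome above the basal channels, so channels appear as partial dips rather
than black voids; 1 μm/px keeps a 12 μm channel 12 px wide while a
full colony still fits a ~2800 px frame.

What the generator deliberately does **not** emulate: single-cell texture,
channel branching and folding (the channel count per circumference is
fixed, where real networks branch), sectoring, uneven illumination, and
deconvolution artefacts. Passing tests therefore demonstrate that the
measurement chain recovers known geometry under realistic optics, noise
and colony shape — not that it is robust to every pathology of real data.

## Measurement accuracy and known biases

Characterised on constant-width phantoms (programmed 12 μm, defaults):

- **CLAHE shape distortion.** Histogram equalisation is a monotone but
  nonlinear intensity remap, which moves half-maximum crossings. With
  60 px tiles it narrows wide peaks (channels at small radii span more
  angular pixels than a tile: ≈ −6 % at r = 200 μm) and widens narrow
  ones (≈ +7 % at r = 1000 μm, where a 12 μm channel is ~14 angular px).
  This is intrinsic to measuring FWHM after local equalisation, not an
  implementation artefact; a per-pixel sliding-window variant showed
  distortion of the same magnitude.
- **Noise-prominence bias.** The prominence base is a minimum over the
  baseline, which noise biases low, lowering the half-maximum level and
  widening the measured FWHM. The disk-median prefilter keeps this to a
  few percent at the default noise level.
- **Blur.** Gaussian blur adds in near-quadrature;
  at σ = 1 px the inflation of a 12 px wide channel is ≈ 2 %, and the
  bias at σ = 1 px stays below 15 % for widths ≥ 8 px.

Net effect: per-radius mean widths stay within ±10 % of the programmed
truth over radii 200–1000 μm (asserted in the acceptance tests; worst
case ≈ 9 % at the rim). Because the CLAHE distortion grows with radius, a
*gentle* programmed radial trend is measured slightly steeper than
programmed — visible as a positive bias when recovering small exponential
rates at the image level, while series-level rate recovery (trend fitting
on given means) is accurate to a few percent.

## Numerical choices and edge cases

- Polar sampling is bilinear; angle 0 lies along +x, increasing towards
  +y. Any consistent convention is valid — every downstream statistic is
  rotation-invariant, and the tests assert the cyclic-shift property
  rather than an absolute orientation.
- Plateau peaks take their midpoint (left-of-centre for even runs) as the
  representative index. Ties in the peak distance rule break towards the
  higher, then the more prominent, then the lower-index peak.
- A peak whose half-maximum level is never crossed on one side (possible
  only at the edge of valid data) is discarded with a logged warning.
- CLAHE histograms exclude invalid (out-of-frame) samples; a tile with no
  valid pixels maps through the identity.
- Linear fits define R² := 0 when the data have zero variance. The
  exponential fit requires strictly positive means and at least 3 radii.
- The thickness profile is smoothed with a 3-point moving average before
  locating minima (switchable); endpoint slices count as minima when lower
  than their single neighbour.
- The outlier filter is applied once per biofilm across all its widths, as
  a single pass; dropped rows stay in the output table flagged
  `retained = False`.
- Normalised radial positions pick the nearest sampled grid radius (ties
  towards the smaller radius); no interpolation between radii.

## Validation design

Every low-level operator (disk median, 3×3 median, circular peak
detection, modified z-score filter, Mann–Whitney p-values) is checked
against an independently written brute-force implementation on randomised
inputs, and the whole pipeline is validated end to end against the
generator's ground truth: width recovery per radius, base area across
ellipticities, trend-model discrimination (on mean-width series with
1.8 % multiplicative noise — the standard error of a mean over ~30
detections with ~10 % individual scatter), monotonicity of increasing
width laws, the exclusion rule on frame-clipped colonies, and the power
(25 % width difference, lognormal CV 0.3, n = 500/group) and nominal size
of the group comparison. `scripts/acceptance.py` recomputes all of these
from scratch at a chosen seed.
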