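# Methods

This note records the models, defaults and design choices behind
`stainscan`, and what the synthetic phantoms do and do not establish about
real acquisitions.

## Acquisition model

An acquisition is an ordered grid of channels, one per (excitation light,
bandpass filter) pair, with exactly one LED active per channel. The
standard protocol is three LEDs — red 625 nm, green 525 nm, blue 460 nm —
against filter positions 420, 440, …, 720 nm: 3 × 16 = 48 frames per
scene. Frames are stored as 8-bit grayscale PNGs next to a TSV manifest;
in memory, intensity is the fixed mapping `v/255` onto [0, 1] (16-bit PNGs:
`v/65535`). Normalisation is deliberately *not* per-image min–max: the
detection threshold (0.35) is an absolute intensity, and it must mean the
same thing in every frame of every acquisition.

LED drive (`I_rel`, 0–255) defaults to 255 for red and blue and 50 for
green. The low green drive mirrors operational practice: when an LED's
wavelength sits near the filter sweep's informative passbands, full drive
saturates the background (see the leak term below), and green is the light
whose line sits closest to the emission bands that matter here.

Hardware quantities the model needs but that no datasheet was available
for are configurable defaults, chosen as typical for this class of
hardware: LED bandwidth 25 nm FWHM, filter passband 10 nm FWHM (Gaussian
transmission), blue LED center 460 nm, pixel scale 0.05 mm/px (which makes
the reference 3 × 1.5 mm stain exactly 60 × 30 px and a 0.5 mm crop
exactly 10 px).

## Forward model

Per channel (light L, filter F) and pixel:

```
I = b  +  I_rel/255 · leak(L, F)  +  Σ_stains c_s · R(fluor_s, L, F)  +  ε,
```

clipped to [0, 1], with:

- `b` — illumination-independent background floor (default 0.2).
- `leak(L, F)` — reflected excitation light passing the filter: a unit-peak
  Gaussian in the light–filter wavelength offset whose width is the LED and
  filter FWHM added in quadrature. This term is what makes a full-drive
  channel with the filter on the LED line saturate, and what vanishes when
  `I_rel` drops to 50 — the overexposure behaviour the protocol is designed
  around. (A strictly illumination-independent background could not show
  that behaviour, which is why the background here is floor + leak rather
  than a single per-channel constant.)
- `R(fluor, L, F)` — fluorescence response of a unit-concentration stain:
  quantum scale × unit-peak Gaussian excitation spectrum evaluated at the
  LED center × `I_rel/255` × the unit-area Gaussian emission density
  integrated against the filter transmission. The integral has the closed
  form `s_f/√(s_e²+s_f²) · exp(−(μ_e−μ_f)²/(2(s_e²+s_f²)))`. Spectra are
  hard-zeroed beyond five FWHM of their peak, so far-off-band responses
  are exactly 0 rather than 1e-17. The response is linear in both
  concentration and `I_rel`.
- `ε` — i.i.d. Gaussian sensor noise, σ = 0.02 by default (a few grey
  levels of an 8-bit camera). Dirty and clean stacks get independent noise
  fields (two acquisitions) drawn in a fixed order from one seeded
  generator, so a scene spec plus seed renders bit-identically.

The default stain fluorophore is riboflavin-like: excitation peak 460 nm
with a broad 120 nm FWHM band, emission 500 ± 60 nm FWHM, quantum scale 25.
The broad excitation band is a deliberate choice: the stains of interest
fluoresce at ~500 nm under both blue *and* green illumination, and a
Stokes-consistent spectrum (emission peak ≥ excitation peak) can only show
green-excited 500 nm emission through a wide excitation tail reaching past
525 nm. With these defaults the green/500 nm channel carries a stain
signal of ≈ 0.36 over a background of ≈ 0.22 — a gap of ~18 σ at the
default noise, and comfortably bracketing the 0.35 threshold.

Stain geometry is exact, not anti-aliased: a rectangle covers the pixels
whose centers fall in its half-open box, an ellipse the centers at
normalized radius ≤ 1. This makes the planted truth mask a crisp oracle
(`dirty − clean` is nonzero exactly on it at zero noise) at the cost of
ignoring partial-pixel coverage at stain borders — a real camera would
show soft edges, which is one reason noisy-recovery Jaccard on real data
would be below the phantom values.

## Detectors

**Thresholding.** `threshold_map` marks intensity strictly above the
threshold as candidate stain; a pixel exactly at the threshold is
background (the defining inequalities are strict, and equality had to be
assigned somewhere). `differential_mask` is
`above(dirty) AND NOT above(clean)` for the same channel of a registered
pair, which removes fixed bright features. No morphological cleanup is
applied by default — the mask is the raw pixelwise decision. Automatic
threshold selection (Otsu and friends) is intentionally out of scope; the
operating threshold is a hand-picked parameter of the method.

**Two-channel clustering.** The manual detector extracts per-pixel
(condition A, condition B) intensity pairs from named crops — by default
0.5 × 0.5 mm (10 × 10 px) stain and background patches — under e.g. green
and red excitation with the same 500 nm filter. `separation_score` is the
between-centroid distance divided by the pooled within-group RMS spread
(0 for identical groups, capped at 1e6 for degenerate zero-spread
groups). `cleaned_overlay` merges the after-cleaning crops with
`cleaned-` labels; on phantoms the cleaned-stain centroid coincides with
background at zero noise.

**Full-cube k-means.** Per-pixel vectors over all channels of a region,
each channel standardized to zero mean / unit variance within the region
before clustering; without this, high-drive and saturated channels
dominate the Euclidean metric, and constant (e.g. saturated) channels are
dropped to zero. Clustering is Lloyd's algorithm with k-means++ seeding
(scikit-learn), k = 2, 10 restarts, 300-iteration cap, tolerance 1e-4,
fixed seed. k = 2 encodes the stain-vs-background question; the true
number of materials is unknown and configurable. The stain cluster is the
one with the higher mean *raw* intensity in the channel nearest the
expected emission (green/500 nm default); a minority-size fallback rule
exists for stains without a known emission band. Correctness is checked
against exhaustive enumeration of all 2-partitions on ≤ 12 points, where
the seeded multi-restart run attains the global optimum.

**Tile classification.** The region of interest is tiled row-major by
squares (default 10 px = 0.5 mm; right/bottom remainders narrower than a
tile are discarded with a warning). Each tile's features are per-channel
mean and per-channel SD (2 × 48 = 96 features for the full protocol) —
a transparent stand-in for whatever proprietary features a production rig
uses, isolated behind one function so it can be swapped. The classifier
is a soft-margin linear SVM (hinge loss + L2, scikit-learn LinearSVC,
deterministic for fixed seed and data order) with class-balanced hinge
weights: stains cover few tiles by nature, and an unweighted margin on a
97 : 3 tile split happily sacrifices the whole minority class. Training
labels on phantoms come from planted-truth coverage (≥ 50 % of a tile ⇒
dirty). The surface call is dirty as soon as ≥ 1 tile (configurable) is
dirty, matching the operational reading that any dirty square on a
surface is signal.

## Hygiene benchmarks

ATP ≥ 1 RLU/cm² is dirty (inclusive); TPC ≥ 2.5 CFU/cm² exceeds the
hospital benchmark and ≥ 40 CFU/cm² is heavy growth, with no more-severe
category above it (191 CFU/cm² is still "heavy growth"). TPC below the
detection limit is stored as half the limit (0.5 CFU/cm²). Aggregation
reports per-location N/mean/SD (n−1 denominator)/min/max and
indicator-bacteria positive percentages; a single-sample location reports
SD 0 with `sd_defined = False` rather than NaN. Pooling per-location
percentages reconstructs integer counts as `round(pct · n / 100)` and
warns when a percentage does not correspond to a whole count.

The bundled reference survey has a documented internal inconsistency: its
per-location TPC sample counts sum to 102 while its overall row reports
N(TPC) = 112 (and 44 ATP + 112 TPC matches the study's stated 156
samples), so ten TPC samples are unattributed to any listed location.
`survey_totals` therefore pools reconstructed positives over the
*reported* total N — the overall rate's own definition (positives per
total number of samples) — and exposes both counts (`n_tpc_rows` = 102,
`n_tpc` = 112) so the discrepancy stays visible. The overall-row
convention is assumed to be sample-pooled, not location-averaged.
Significance testing (ANOVA, post-hoc comparisons) is out of scope; the
module stops at threshold classification and descriptive aggregation.

## Pipeline and determinism

`run_all` executes simulate → differential detection → k-means → tiles
(→ hygiene, if a samples CSV is given) on the same rendered pair, writing
every artifact plus a `report.json` with each detector's Jaccard against
truth. All randomness fans out from one run seed by fixed offsets
(scene = seed, k-means = seed+1, SVM = seed+2). Reports round floats to
9 decimals and sort keys, so identical config + seed reproduces identical
bytes; this is asserted in the acceptance suite. A scene with no stains
degrades gracefully: the differential mask is empty, the featureless
noise-free cube is reported as having no stain cluster rather than
failing, and with fewer than two dirty training tiles the tile stage
calls everything clean instead of fitting a one-class SVM.

## Problem sizes

Tests and the acceptance script render phantoms at 96 × 128 px (full
48-channel protocol), 110 × 110 px for single-light tile scenarios, with
the native 1393 × 1040 px frame geometry exercised through metadata and a
constant-frame I/O round trip. These sizes keep every quantity the
package reports — channel counts, stain pixel geometry, Jaccard indices,
tile fractions — independent of frame size while keeping the full suite
fast; nothing in the method depends on the frame being desk-scale.

## Known limitations

- No point-spread function, lens distortion, dark current, shot noise or
  radiometric calibration; noise is additive Gaussian only. Phantom
  recovery scores are therefore upper bounds on real-data performance.
- Perfect dirty/clean registration is assumed (the rig images both states
  from a fixed mount); there is no registration step, and misaligned real
  pairs would corrupt the differential detector first.
- The tile features (mean + SD per channel) are a documented choice, not
  a claim about what any production system computes.
- No spectral unmixing or fluorophore identification: the pipeline says
  *where* a stain is, not *what* it is.
- Correlating the tile classifier's output with real ATP readings
  requires paired field data that is not available; the false-positive
  property (clean phantoms produce zero dirty tiles) stands in for it.
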