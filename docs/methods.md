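# Methods

## Model and coordinate conventions

An Archimedes spiral of scale `b > 0` px/rad rotated by `θr` about its
center satisfies `r = b(θ + θr)` with `θ > −θr`. All internal
mathematics uses the y-up mathematical orientation; image rows are
flipped once on read and once on write, so equations hold verbatim
inside the package. Ink is stored as a density in `[0, 1]` with
1 = fully dark, the inversion of 8-bit greyscale (`density = 1 −
grey/255`); RGB collapses to Rec. 601 luminance.

The two-point fit is exact algebra, not least squares: two on-curve
points with zone-unwrapped angles one or more turns apart give `b` and
`θr` in closed form. Zone `k` contributes `θ = θ′ + 2π(k−1)` with
`θ′ ∈ [0, 2π)` — the first turn keeps its plain polar angle, which is
what makes "first point in zone one, second in zone two" consistent
with points one turn apart differing by exactly `2π`. The offset is
configurable (`zone_offset`) because the opposite convention
(first turn = `2π`) appears in the field.

## Flattening

Each ink pixel above a density floor (default 0.1 — background haze
sits well below it and would only cost time) maps to a *family* of
flattened points, one per candidate turn index in `n_list` (default
`[1, 2, 3, 4]`, covering a four-turn template). Family members are
spaced exactly `(2πα, −2πbβ)`; the correctly unwrapped member of every
pixel lands on the stitched band of its curve. With `α = β = 1`
(the defaults; they only rescale axes), flattened x is in radians and
flattened y in source pixels.

The target raster is an engineering choice the method itself does not
constrain. Deposition is nearest-cell with max-aggregation, so the
darkest contribution wins — consistent with the darkest-pixel
semantics of extraction. Default pitches: `y_pitch` = 1 source pixel;
`x_pitch` = 1/mean ink radius, i.e. one column per source pixel on the
average ring. Inner turns are therefore undersampled (their pixels are
angularly sparser than the grid); those columns come out empty or weak
and are handled by the missing-column interpolation and the near-origin
noise crop. The alternative — pitching the grid to the innermost
turn — would inflate the raster by the outer/inner radius ratio for no
benefit, since the analysis lives on the outer turns.

A sliver of the drawing with `−θr < θ < 0` (before the first
positive-angle crossing) has no valid candidate in the default
`n_list`; it maps only to out-of-band junk and is removed by the
near-origin crop. This is why the noise-crop bound should be at least
`s(θr)` when the page is rotated.

## Extraction and the two published rules

The sources describe column extraction two ways: take the darkest
pixel, and take the first sufficiently dark pixel scanning upward.
These differ exactly when a column is multivalued (loops, crossings).
First-hit above a threshold (default 0.5) is primary here, with
darkest-pixel as the sub-threshold fallback, because only first-hit
produces the documented lower-branch behaviour on loops. The printed
reference template is rendered (and in practice scanned) lighter than
the pen stroke, so the threshold also separates the hand band from the
reference line that shares `y ≈ 0` with it; with a fallback hit on the
reference the column reads `y ≈ 0`, a conservative error.

Arc length follows `s = ½bφ²` (`φ = θ + θr`), the integral of
`ds = r dθ`. Uniform-`φ` columns become quadratically stretched in
`s`; linear interpolation onto `N` uniform `s`-samples (default 1000,
even by construction so `Ncoeff = N/2 + 1` exactly) restores uniform
sampling. Interior missing columns are bridged linearly (a gap wider
than 5 % of the extent warns); leading/trailing missing columns are
trimmed.

`cropping_ratio` is reconstructed as the retained fraction of the
originally extracted arc-length extent, multiplying over every
shrinking step (noise crop, edge trimming). Its purpose is the Hz
axis: drawing at constant arc-length speed for `T` seconds, the
retained record lasts `T · cropping_ratio`, so bin `k` maps to
`f_k = k/(T · cropping_ratio)` Hz — the standard DFT bin width for
that effective duration. Neither the ratio's formula nor the Hz
formula is published; both are the reconstructions that make the
bookkeeping self-consistent, and tests confirm the peak lands within
one bin of the generator's truth.

Normalization maps the mean-removed profile to peak magnitude exactly
1000 px ("bounded by 1000" read as scaled-to-bound); the
pre-normalization RMS is kept as the amplitude measure in pixels, and
a profile flat to below 1e-9 px is rejected as degenerate rather than
amplified.

## Spectral reduction

`numpy.fft.rfft` supplies the real DFT; magnitude and phase are stored
separately because both are needed to invert. The low-pass is a
brick-wall zeroing above `floor(0.4 · Ncoeff)` (the published cutoff
names no filter shape; brick-wall is the simplest faithful reading),
applied before truncation to the leading 150 pairs, matching the
published step order. Phases of zeroed coefficients are set to 0 for
determinism. The truncation error is `100 · RMS(a − b)/RMS(a)` with
`a` the untruncated signal; the denominator is not published, and the
fixed-bound alternative (`/1000`) is available behind a keyword. The
Savitzky–Golay smoother (window 51, order 3) exists purely for
plotting and never feeds back into analysis — a test asserts the
stored spectrum is untouched.

## Synthetic generator

The generator emulates the documented input conditions: a reference
spiral at arbitrary rotation `θr ∈ [0, 2π)` whose outer turn fills
~42–45 % of a 1024-px canvas (`b ≈ 17–18` px/rad over four turns),
strokes of 1–5 px width with slowly varying grey level, a light-grey
background, and a hand curve `r(θ) = b(θ+θr) + d(s)` with

    d(s) = A sin(2π f (s/s_total) T + φ₀),

i.e. a radial sinusoid drawn at constant arc-length speed — the
simplest model consistent with labelling the spectrum in Hz from the
drawing time. Cohort ranges (chosen once as mild-to-moderate
conditions): `A ∈ [3, 20]` px, `f ∈ [3, 8]` Hz, `T ∈ [8, 15]` s.
Artifacts are injected per flag: pen-lift gaps (blank arcs of 1.5–3 %
of the stroke), a small closed loop, a crossing excursion of `1.3πb`
(past the half ring spacing, so the stroke invades the neighbouring
turn), and dark specks near the origin. The reference renders at
density ~0.40, the pen at ~0.85, mirroring the printed-template versus
pen contrast that the threshold rule exploits.

What the generator does **not** emulate: tremor harmonics and
amplitude drift, speed variation along the stroke, paper texture,
JPEG artifacts, and genuinely non-Archimedean (distorted) templates.
Passing tests therefore demonstrate the pipeline's correctness under
the stated model, not clinical performance on patient data; in
particular the cohort truncation-error level depends on stroke
rasterization noise and artifact mix, and is checked only as an
order-of-magnitude band (mean in 2–20 % at 150 coefficients), not as
a point value.

## Numerical and design choices

* Extraction threshold 0.5 (configurable): between the template's
  ~0.4 and the pen's ~0.7+ under jitter.
* Peak search band 1–12 Hz: the upper edge is the clinical tremor
  ceiling; the lower edge excludes the drawing's slow drift. Exact
  magnitude ties resolve to the lower frequency.
* Frequency-recovery and equivariance tests use problem sizes of a
  1024-px canvas and 18–20 pipeline runs, keeping the full suite in
  seconds while leaving each DFT bin (~0.1 Hz) far below the 1 Hz
  grid of tested frequencies.
* Rotation/translation equivariance holds to about one flattened grid
  cell (1 px RMS): re-rasterization at a new angle shifts stroke edges
  by sub-pixel amounts that first-hit extraction quantizes.
* The near-origin crop default in synthetic configs is
  `s(θr + 0.5)`, past both the unmappable sliver and origin specks.

## Known limitations

Multivalued columns are resolved to the lower branch, which
underestimates the raw RMS amplitude when loops are dense. Crossing
strokes leak wrong-turn copies into the cropped band and inflate the
truncation error for those samples. Distorted (non-Archimedean)
templates are supported only via an externally cleaned flattened image
or mask; the tool performs no in-image erasing. The Hz axis assumes
constant drawing speed; real hands accelerate, smearing the peak.
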