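# tonguefan

Polar normalization and penalized-spline additive mixed modeling of
midsagittal ultrasound tongue contours.

The package implements a complete analysis chain for traced tongue
surfaces compared across speakers, languages, and produced tokens
(vowels, or sustained musical notes at several intensities):

1. **geometry** — estimate the ultrasound *virtual origin* (the fan
   apex) and pixel scale from per-subject fan annotations, convert
   contours between Cartesian image coordinates and polar
   `(theta, rho)` coordinates, and rotate/scale every subject onto a
   common reference space using the mean high-front-vowel contour as
   the anchor.
2. **contours** — data model and CSV I/O for long-format contour
   tables, cubic-spline resampling to a standard 100 points per
   contour, MAD-based outlier screening, and penalized-spline mean
   contours.
3. **smoothing** — the model engine: cardinal cubic regression spline
   basis with second-derivative penalty, ordered-factor difference
   smooths, per-level random factor smooths with shrinkage,
   restricted-likelihood smoothing-parameter selection, and two-stage
   AR(1) residual whitening along each contour.
4. **inference** — difference curves between condition smooths with
   pointwise (or simultaneous) intervals, extraction of significant
   theta regions, sweep-based interval-coverage agreement across many
   comparisons, group-average splines over model predictions, and
   note-comparison enumeration.
5. **variance** — per-speaker, per-category variance curves over 100
   theta bins and the variance-response model comparing languages.
6. **synth** — synthetic datasets with the full study structure
   (10 subjects per language, 13 + 5 vowel categories, 5 notes x 4
   intensities with one missing cell, per-subject rotation/scale
   offsets, localized group-difference bumps, AR(1) noise, variable
   trace lengths) and exact ground truth for recovery testing.
7. **pipeline / cli** — an end-to-end `normalize -> fit -> diff ->
   variance -> plot` workflow with a reproducibility manifest, plus
   polar visualization with shaded significance sectors.

## Conventions

Pixel coordinates are image coordinates (y increases downward).  The
polar angle is `atan2(dy, dx)` about the virtual origin, so the tongue
surface lives at negative angles, roughly `(-2.8, -0.5)` rad, with more
negative theta more posterior.  Plots show the anterior direction at
the right and label angles as fractions of pi.

## CLI

```sh
tonguefan simulate --scale 0.25 --seed 1 --out contours.csv
tonguefan normalize contours.csv --reference NZE01 --out normalized.csv
tonguefan fit normalized.csv --kind note --out summary.json
tonguefan variance normalized.csv --out variance.csv
tonguefan run --config pipeline.yaml          # full workflow
tonguefan plot normalized.csv --out mean.png
```

`tonguefan run` reads a YAML file whose keys mirror
`tonguefan.pipeline.PipelineConfig` (output directory, simulation scale
or an input contour CSV, reference subject, model options, alpha, seed,
...) and writes every artifact plus a `manifest.json` with SHA-256
hashes; reruns with the same config are byte-identical.

## Contour CSV schema

Header (UTF-8, required): `subject, language, token_kind, category,
intensity, preceding, following, rep_index, point_index, theta, rho`.
`intensity` is set for notes only; `preceding`/`following` (phonetic
context) for vowels only.  One row per traced point; `theta` strictly
increasing within a contour, `rho` in pixels from the virtual origin.

## Model specification

`tonguefan.smoothing.ModelSpec` describes one model: a response column
(`rho` or `var_rho`), an ordered parametric factor (e.g. the
language x note x intensity interaction), a reference smooth in theta,
one difference smooth per non-reference level, random factor-smooth
terms such as `("subject", None)` or `("subject", "note_intensity")`,
and the AR(1) treatment (`"estimate"`, a fixed value, or 0).  Specs are
constructible from plain dicts (`ModelSpec.from_config`), so they can
live in the pipeline YAML.

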