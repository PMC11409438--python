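# Methods

This note documents the models and conventions behind `wormscreen`: what the
simulator renders and why, how detection and gating work, the statistics,
the decision rules, and the limits of what synthetic-data tests can show.

## Synthetic well model

A well is four non-overlapping image fields (2×2 tiles, default 512×512 px
at a nominal 2.5 µm/px) in two channels. The GFP channel is the analysis
channel; brightfield carries body silhouettes only and is unused by the
default pipeline (retained for format fidelity).

**Worm load.** Unless fixed, the worm count per well is
`round(Normal(25.5, 7.4))` clipped to [5, 66] — the per-well animal
statistics typical of the liquid-culture assay this package emulates. Each
worm is an adult with probability `adult_fraction` (default 0.8 at analysis
time); low values emulate toxic growth retardation.

**Optics.** Worms are constant-intensity plateau shapes softened by a 1 px
Gaussian blur, with strict ordering

    vulval focus (40000) > adult pharynx (20000) > larval pharynx (12000)
    > body autofluorescence (2000) > background (400)

in arbitrary 16-bit units (no calibration is claimed). The body is a
capsule (adults 120–160 × 9–13 px, larvae 40–65 × 4–6 px; straight, as
sedated worms are). The pharynx is a convex ellipse at one body end whose
rasterised footprint is drawn uniformly inside the corresponding detection
gate with a safety margin (adults 300–700 px², larvae 60–180 px²). An early
design used a two-lobed pharynx; it was replaced by the single convex
ellipse because a two-lobed plateau has a saddle that can split into two
components as the segmentation threshold rises, breaking the detector's
guarantee that object counts are non-increasing in threshold. Convex
plateaus have connected superlevel sets, so the guarantee holds by
construction.

**Vulval foci** are circular plateaus (45–85 px² target footprint) offset
to one side of the body axis. Foci are placed on an axial interval that
stays 12 px clear of the pharynx edge and 2 px clear of the tail tip;
multiple foci are evenly spaced on that interval so neighbouring foci never
fuse under the detection blur. Per-adult focus counts follow the
`vulva_rate_adult` parameter: rates ≤1 draw Bernoulli(rate) (a wild-type
adult has at most one vulva; suppression removes it), rates >1 enter the
multivulva regime `2 + Poisson(rate − 2)` truncated at 4. A `muv_fraction`
mixture (each adult Muv with probability *m*, otherwise one focus) supports
counter-screen genotypes, and `vulva_dist="fixed"` gives exact counts for
oracle tests. Larvae never carry foci.

**Confounder speckles** emulate fluorescence from progeny, bacteria and
drug precipitates — the dominant failure mode of automated focus counting.
Defaults: Poisson(rate) per field, radius 1.8–3.4 px, peak 15000–45000, so
a fraction of speckles falls inside the vulva gate and produces genuine
vulva-class false positives while staying below the larval-pharynx size
gate. "Speckle storm" overrides (rate 40/field, radius 3.2–5.5 px, peak
≥32000) emulate precipitate-laden artifact wells. Speckles are placed off
worms (outside the dilated worm footprints); real debris can overlap
animals, which this simplification deliberately avoids so planted artifact
semantics stay exact.

**Placement** is rejection sampling with non-overlap enforced on 5
px-dilated footprints; worms are wholly contained in their field (oriented
bounding extents, so edge-adjacent placements are still sampled). Requested
densities that cannot be placed raise an explicit `PlacementError` — never
silent truncation. Determinism: all draws flow from a per-well
`numpy` `SeedSequence`; plate rendering derives each well's seed from the
top-level seed plus CRC32 of the plate and well ids, so adding wells never
perturbs existing wells.

## Detection and gating

Segmentation is smooth (Gaussian, σ = 2 px) → threshold → 8-connected
components → feature extraction, with features measured on the original
intensities. The default threshold is background-relative: background
median plus `max(6 × MAD, 4000)` of the smoothed field. The MAD term adapts
to pixel noise; the 4000-unit floor keeps dim body autofluorescence out of
the object mask even in noise-free images. Components smaller than 15 px
are dropped.

The object **area** feature is the full-width-at-half-maximum support: the
pixels of a component at or above background + half the
background-subtracted smoothed peak. For plateau objects this measures the
geometric footprint independently of where the global threshold sits, so
the size gates do not drift with noise level. Gates (area_min, area_max,
peak_min) default to

| class | area (px²) | min peak |
| --- | --- | --- |
| vulva | 30–120 | 30000 |
| adult_pharynx | 250–900 | 8000 |
| larval_pharynx | 40–220 | 6000 |

applied in precedence order vulva → adult_pharynx → larval_pharynx →
rejected; the vulva-first rule mirrors the "large, intense" character of
vulval foci and resolves the area overlap with larval pharynges by
intensity. Every object receives exactly one label. These defaults are
calibrated to the simulator's optics, not to any particular instrument; on
real images every gate is configuration (`DetectionConfig` YAML).

Edge behaviour: an object is counted in the field containing its centroid.
Fields are processed independently and summed per well — acquisition is
non-overlapping, so nothing is double-counted and no stitching is done.

**Body assignment (counter-screen only).** Bodies are segmented at a low
threshold (background + 1000) so each worm silhouette forms one component
(≥300 px); a vulva-class focus belongs to the body containing its centroid,
else the nearest body within 20 px, else it stays unassigned. A body is
adult if it contains an adult-pharynx centroid; an adult with ≥2 assigned
foci is Muv. This is an automated, testable proxy for manual Muv scoring;
it needs moderate noise (σ ≲ 1000) because body autofluorescence is only
2000 units above background — at the default screen noise the dim bodies
are not reliably segmentable, which matches the biological practice of
scoring Muv in dedicated low-throughput runs.

## Scores and statistics

`vulvae_per_adult` is undefined (NaN, never 0) in zero-adult wells and the
undefined marker propagates through every aggregation with dropped-count
reporting; `pct_larvae` uses worm-classified objects only (rejected objects
and vulvae are not animals). Wells above 1.5 vulvae/adult are flagged as
outliers — the signature of confounder fluorescence — but are only removed
by the explicit `--drop-outliers` option, keeping the human-inspection
step visible rather than silently automated.

The Z-factor uses sample SDs (n−1) — material for 6-well control groups —
and is computed on vulvae/adult scores. It is ≤1 by construction, exactly
1 only for zero-spread separated controls, affine-invariant, and undefined
(explicit error) for equal control means. Buckets: ≥0.5 excellent, [0, 0.5)
marginal, <0 unusable. Controls are pooled across experiments by default;
`--per-experiment` adds a per-experiment breakdown, since per-plate versus
pooled computation is a genuine design freedom.

Dose–response aggregation is experiment-first: replicate wells average
within an experiment, cells report mean ± SD of experiment means (SD
undefined for a single experiment). The pipeline-comparison regression is
ordinary least squares of pipeline A on pipeline B paired by condition,
reporting slope, intercept and R² = 1 − SS_res/SS_tot.

## Decision layer

Criteria are strict inequalities applied in fixed order (artifact →
toxicity → threshold), so boundary values (exactly 2× the control adults,
exactly 30%, exactly 0.4 vulvae/adult) never trigger. "The number of
adults in the positive control" is the mean adult count over the
positive-control wells of the same plate: the mean is stable, and controls
are laid out per plate. Validation keeps a compound iff some concentration
has mean-over-experiments vulvae/adult ≤ 0.4 (the complement of "above 0.4
at all concentrations"). The counter-screen classifies, in order: adult
count below 30% of the untreated lin-1 control → `indeterminate_growth`
(analysis precluded); Muv fraction below 0.5× control → `downstream_or_
parallel`; otherwise `on_pathway_hit`. The 0.5 suppression factor is a
package convention — configurable and echoed into every output — not an
inference about any published analysis.

## Benchmark layouts and problem sizes

`wormscreen.benchmarks` defines two programmatic layouts used by the test
suite and `scripts/acceptance.py`:

* a 96-well *calibration plate* whose test columns span vulva rates 0–2
  (suppressed → wild type → mild Muv) with default noise (σ = 4000, i.e.
  10% of the vulval plateau) and 2 speckles/field — wide dynamic range for
  count-error and regression benchmarks;
* a *planted validation screen*: 433 test compounds over five plates with
  7 strong suppressors (vulva rate 0.05), 20 speckle-storm artifact wells
  and 15 toxic wells (adult fraction 0.05) interleaved among inactive
  fillers. Planted wells use a fixed nominal load of 25 worms and positive
  controls 30 all-adult worms, so the planted classes are separated from
  the decision thresholds by construction (a toxic well cannot luck into
  enough adults to escape criterion ii) rather than by the density draw.

Benchmarks render 384×384 px fields, a size chosen so a full screen builds,
images, scores and hit-calls in a few minutes on one CPU while leaving
placement density and class separability unchanged.

## Known limitations

* Worms are straight plateau capsules: no curvature, touching/crossing
  animals, z-structure or photorealistic texture. Exact-recovery results
  certify the gating logic, not performance on entangled real worms.
* Intensities are arbitrary units with a fixed class ordering; real
  reporter variability (expression mosaicism, bleaching, focus drift) is
  not modelled, so the default gates must be re-calibrated on real data.
* Speckles never overlap worms and speckle/vulva discrimination rests
  solely on the size/intensity gates, as in the emulated pipelines.
* Body segmentation (Muv proxy) requires low-noise images; the default
  screen noise level defeats it by design.
* The screen is single-datapoint and threshold-based; no significance
  testing, IC50 fitting, or compound annotation is attempted.
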