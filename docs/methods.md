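# Methods

This note documents the models, parameters, numerical choices, and
limitations behind the three quantification pipelines and the synthetic
data generator. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Viability pipeline

### Projection and thresholding

Z-stacks are collapsed per channel by maximum intensity projection
(MIP); the analysis is 2-D throughout. Otsu's threshold is computed on
an intensity histogram and the foreground is `image > threshold`.

*Histogram convention.* For integer images whose value span fits in 256
levels (all 8-bit data), the histogram has **one bin per integer level**
and every possible split is evaluated, so the result coincides exactly
with an exhaustive integer-candidate scan. Float images use a 256-bin
histogram over the observed min–max range, and the returned threshold is
the bin edge of the best split. A fixed 256-bin min–max histogram for
integer data was rejected because its fractional bin width can merge two
adjacent 8-bit levels, making the result depend on the image range in a
way an exact scan never would. Ties take the lowest threshold. A
constant image raises an error: there are no separable classes.

### Segmentation

The watershed is seeded at local maxima of the Euclidean distance
transform of the foreground, with a minimum seed separation of
`min_separation_um` (default 5 μm ≈ one expected cell radius); this
splits touching cells at their waist. Regions smaller than
`min_cell_area` (default 20 μm², debris exclusion) are removed and
labels relabeled contiguously. An empty foreground returns an empty
segmentation, not an error. Areas are always reported in μm² via
`pixel_size²`; coordinates are 0-based (row, col).

### Live/dead classification

Each cell's mean intensity in the live and dead MIPs is scaled by that
channel's own Otsu threshold, making the two dyes comparable despite
different gains; the larger scaled score wins. Exact ties go to *dead*
(conservative for an injury assay; configurable). A constant channel —
e.g. a dead channel with no dead cells and no noise — carries no signal
and scores 0.

### Registration and the death area

Pre/post alignment is integer-translation only: specimens are re-imaged
in a fixed holder, so translation dominates and rotation/scale are out
of scope. The search is exhaustive over ±`max_shift` (default 50 px)
and exact: the cross term for every shift comes from one FFT
cross-correlation, and per-shift overlap means/variances from
summed-area tables, which is algebraically identical to the naive
per-shift Pearson correlation (the test suite checks this against a
loop oracle). Ties prefer the smallest offset; a best score below
`score_floor` (default 0.2) flags the alignment as low-confidence but
still returns it.

The impact-induced death area has no unique definition, so this one is
stated prominently: **death_area = post dead area − pre dead area,
pixel-accounted inside the registered overlap ROI, clamped at zero**,
with the raw signed value retained and a companion fraction normalized
by the pre-impact live area in the same ROI. Counts use cell centroids;
areas are pixel-exact within the ROI. No cell tracking across frames is
attempted — the accounting is area-based. An optional exclusion mask
supports restricting analysis to the curved cap region of a humeral
head when the surrounding tissue should not be counted; no automatic
cap detection is attempted.

## 2. Calcium pipeline

The baseline window is **all samples strictly before the treatment
time** (nominally 1 min into a 6-min recording, treatment at 60 s);
baseline statistics are the mean and sample SD (ddof = 1), requiring at
least 3 pre-treatment samples. The response window runs from the
treatment time to the end of the recording; no photobleach or artifact
correction is applied.

The responder criterion is interpreted as

    (peak − baseline mean) ≥ k × SD(baseline),  k = 3 by default,

with an **inclusive** boundary; `k` is a parameter. Because test
fixtures construct peaks as `mean + k·sd` in floating point, inclusivity
is honored to within float rounding (relative 1e-9). The set-level
resting [Ca²⁺]₀ averages baselines over **all** cells (the alternative —
responsive cells only — is not distinguishable from the assay
description; all-cells is the less biased choice). Δ[Ca²⁺] averages
(peak − baseline) over responsive cells only and is reported as missing
when no cell responds, never as 0.

Ratio traces (340/380 nm) are supported via an elementwise ratio with a
positive floor on the denominator; samples that hit the floor are
counted and surfaced as a QC signal. Ratio-to-concentration calibration
is deliberately out of scope: the pipeline operates in whatever units
the input provides.

## 3. Immunofluorescence pipeline

Integrated density is the raw sum of pixel intensities over the cell
mask; constant-offset background subtraction exists but is **off by
default** (quantitative IF protocols differ on this, and silently
subtracting changes the statistic's meaning).

*Circularity.* 4πA/P² clipped to [0, 1]. The perimeter P is the length
of the half-level marching-squares boundary polygon after a 5-vertex
moving-average smoothing of its vertices. The smoothing suppresses the
staircase overestimate of rasterized smooth boundaries: rasterized discs
and ellipses measure within ~1% of their analytic circularity, an
axis-aligned square converges to π/4 from above (corner rounding costs
~window/side), and thin lines score near 0. This estimator was chosen
over chain-code and Crofton perimeters, which fail thin shapes and
polygons respectively.

*ROI selection.* Cells with circularity ≥ `circularity_min` (default
0.8) qualify; up to `n_target` (default 20) per anatomical compartment
are kept, ranked most-circular-first with ties broken by descending
area, then label — all criteria independent of the intensity being
measured, so selection cannot bias the expression score directionally.
**The selection rule is this module's largest documented divergence
risk**: the original protocol does not state how its per-compartment
cells were chosen (random? most circular? manual?), and results can be
sensitive to it. Under-target compartments are flagged, not errored;
compartments with zero qualifying cells report a missing mean.

Compartment assignment requires user-supplied polygons (humeral /
glenoid): the compartments are anatomical, not derivable from the
image. The joint score sums the defined compartment means;
normalization divides by a control joint score (> 0 enforced). Both
"contralateral limb" and "group mean" control modes are expressible —
the control score is simply a number the caller provides — and neither
is asserted as the original.

## 4. Synthetic data generator

The generator defines the study conditions the pipelines are validated
under; its defaults are fixed, not tuned per test.

*Viability fields.* 512×512 px at 0.5 μm/px (a typical confocal
magnification; the source protocol states no acquisition metadata, so
this default is explicitly uncalibrated), 60 cells of radius 4–7 μm
(superficial-zone chondrocyte scale), rendered as uniform discs at
intensity 200 over background 10, additive Gaussian noise SD 8 clipped
at zero. Cells are placed by rejection sampling with a strict
non-overlap rule (center distance > sum of radii); failure to place
within a bounded attempt budget raises a named error rather than
degrading silently. Z-stacks are 5 planes with Gaussian defocus growing
1.2 px·plane away from the central sharp plane, so the MIP is exercised
nontrivially while remaining exactly recoverable. The impact flips each
cell to the dead state with probability `death_probability_inside`
(default 0.8) within a 60-μm-radius focal region, else
`death_probability_outside` (default 0.02); a dead cell is bright in
the dead channel and dark in the live channel — partial transitions are
not modeled. An integer `post_shift` exercises registration. Every
random decision draws from a documented seeded stream
(`default_rng([seed, stream])`), so truth can be replayed
independently, and re-rendering the truth record reproduces the
noise-free frames exactly.

*Traces.* 6-min recordings at 1 Hz, treatment at 60 s, baseline
100 ± 5 nM. Baseline fluctuation is **bounded (uniform) white noise**
on ±√3·SD. This is a deliberate modeling decision: under Gaussian
fluctuation of any correlation structure, the maximum of a 5-minute
response window exceeds 3×SD of a 1-minute baseline in roughly a
quarter to half of resting cells, so a raw-peak criterion would be
useless — the published criterion presupposes resting traces whose
excursions are bounded within a few SD, which is what
resolution-limited ratiometric readouts look like. Responder transients
are (1 − e^(−τ/rise)) e^(−τ/decay) (rise 5 s, decay 30 s — slow-agonist
scale), normalized on the sampled grid so the noise-free sampled peak
equals the nominal amplitude (default 8×SD) exactly; in the zero-noise
limit the amplitude falls back to a floor SD (0.5 nM) so it stays
defined.

*IF fields.* Elliptical cells (area-preserving axis ratio inverted from
a target circularity drawn in [0.85, 1.0] via Ramanujan's perimeter
approximation) in two half-field compartments, 25 cells each,
intensities N(100, 15) by default, zero background so each cell's true
integrated density is exactly intensity × pixel count, noise SD 2, plus
a nuclei channel. Per-cell truth records the exact noise-free signal
sum.

What the generator does **not** emulate: Poisson shot noise (no SNR
data to calibrate it), optical vignetting and depth attenuation,
partial live/dead transitions, cell shape irregularity beyond ellipses,
drift within a recording, and spatial intensity gradients in IF fields.
Passing tests therefore demonstrate correctness of the quantification
logic under controlled conditions, not robustness to every real-world
artifact.

## 5. Statistics and orchestration

The statistics layer is deliberately thin: two-sided paired/unpaired
Student's t and one-way ANOVA at α = 0.05, no multiple-testing
correction, no post-hoc tests. A paired difference vector with zero
variance is flagged as degenerate instead of producing an infinite
statistic (p = 1 for identically zero differences, p = 0 for a constant
nonzero difference). Null calibration (type-I error within
[0.04, 0.06] at 10⁴ replicates) is part of the acceptance script.

Experiments are TOML configs (kind, groups with generator overrides or
file inputs, pairing flag, seed, parameter overrides). Per-sample seeds
derive from the experiment seed via `SeedSequence([seed, group,
sample])`; a group may pin an explicit generator seed (which is how a
deliberately degenerate identical-groups design is expressed). Reports
embed the config hash (SHA-256 of the canonicalized config), seed and
package version, contain no timestamps, and are byte-identical across
reruns of the same config + seed.

## 6. Problem sizes

The test suite and acceptance script run everything at reduced but
statistically meaningful sizes chosen to keep a full run under a minute
of compute on one CPU: 50 images for the Otsu-vs-exhaustive-scan check,
4–5 default-noise fields (240–300 cells) for segmentation
recall/precision, 60–100 registration trials at 256 px, 10–20 lethal
impact fields for death-area recovery, 200 cells for responder
accuracy, 20–40 replicates of the 4-vs-4 specimen Δ[Ca²⁺] experiment,
5 sample pairs for the IF ratio, 10 replicates of the 8-pair paired-t
power simulation, and 10⁴ null replicates for t-test calibration. The geometric disc-recovery check uses single-plane
noise-free fields because comparison against analytic disc areas is
only meaningful without out-of-focus halo, and lattice quantization
alone already costs ~3% at 8–14 px radii.

## 7. Known limitations

- 2-D only: the Z-stack is projected, never segmented in 3-D.
- Registration is rigid integer translation; nonrigid deformation of
  cartilage under impact is not modeled or corrected.
- The death-area statistic identifies *net* area conversion, not which
  individual cells died.
- The IF 20-cell selection rule is a convention, not a reconstruction
  of the original manual choice (see §3).
- Generator realism limits are listed in §4; conclusions about real
  micrographs require validation on real micrographs.
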