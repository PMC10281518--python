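# Methods

`hcscreen` reimplements, end to end and on synthetic ground truth, the
analysis chain of an imaging-based arrayed RNAi screen whose readout is the
mean nuclear fluorescence of a tagged reporter protein (here modelled on a
YFP-tagged centromeric histone variant whose nuclear over-accumulation marks
its mislocalization), together with the spot-level immunofluorescence
quantification used to validate hits on chromosome spreads.

## Screen design and layout

The library arrays one siRNA per well, three independent siRNAs per gene,
for 521 genes by default, on 384-well (16x24) plates with two biological
replicates. Controls occupy the two right-most columns: a scrambled
negative-control siRNA in the odd rows of column 23 (even rows left empty)
and two positive-control siRNAs — targeting a gene whose depletion raises
the readout — alternating by row parity down column 24. Library siRNAs fill
columns 1–22 in row-major order, a gene's three siRNAs consecutively,
spilling over plates as needed (521 x 3 = 1563 siRNAs -> 5 plates, the
fifth partially empty). Fill order is not statistically meaningful; it is
pinned for reproducibility.

## Generative well-value model

The readout is modelled strictly additively, matching the scale on which
the normalization operates:

    raw = baseline + gene_effect * sirna_potency + off_target
        + pos_control_effect + row[r] + col[c] + N(0, noise_sd)

Defaults: baseline 1000 intensity units; per-siRNA potency Uniform(0.5, 1)
unless pinned; row/column artifact vectors drawn per (replicate, plate)
from configurable uniform ranges; positive-control shift +300 (large and
positive, the direction of the assay); 1500 cells seeded per well with a
0.35 imaging-attrition factor feeding a Poisson imaged-nuclei count.
Off-target effects attach an additive shift to a single siRNA regardless of
its gene, which is what the gene-level median is designed to suppress.

A caution learned the hard way: spiked effects placed on *consecutive*
genes concentrate in one plate row and are absorbed by the median polish as
a row artifact. Benchmarks spike scattered genes, as a real library would
intersperse hits.

## Image rendering

Wells are rendered single-plane, two-channel (DAPI + reporter), 16-bit by
default. Nuclei are ellipses (axis asymmetry up to 15%) optionally
perturbed by low-frequency cosine modes of the boundary radius
(`irregularity` in [0, 1]); placement is rejection-sampled with a
worst-case effective radius so non-overlapping nuclei always keep a >= 2 px
background corridor (otherwise hole-filling during segmentation can annex
enclosed background pixels). Inside each nucleus the reporter channel is
set so the ROI mean equals the requested target exactly before blur and
noise; centromere-like foci, when enabled, are mean-compensated. The
ground-truth label mask and per-nucleus table (area, centroid, roundness,
border contact, true mean) are emitted with every render, and the truth
table is computed from the emitted mask, so the two can never disagree.

Metaphase-spread fixtures are Gaussian spots on a flat background — one
bright centromeric spot per chromosome plus optional dimmer arm spots —
with integer-pixel centers so the noiseless center pixel is exactly
background + amplitude, plus a cytoplasm mask far from every spot for
background boxes.

## Nuclear quantification

Segmentation: Gaussian smoothing (sigma 1 px by default; 0 for blur-free
synthetic images), global Otsu threshold, hole filling, minimum-area filter
(default 30–50 px at 256x256 scale), distance-transform-seeded watershed to
split touching nuclei. Deterministic throughout.

Roundness is 4*pi*A/P^2 clipped to [0, 1], with the perimeter P estimated
by the 4-direction Crofton formula (a fixed length increment per 2x2 pixel
configuration). Under this estimator a digitized disk scores ~1 and a
1x50 px line ~0.07, so the conventional cutoff of 0.775 cleanly separates
round nuclei from elongated or ragged segmentation artifacts. The cutoff
keeps values exactly equal to 0.775 ("below" excludes strictly). We note
that commercial high-content software does not disclose its roundness
formula, so numeric equivalence with any particular vendor pipeline is not
claimed; the threshold is exposed as a parameter. Nuclei touching the image
border are excluded.

The well value is the unweighted mean of per-nucleus mean reporter
intensities (each cell counts once; not pixel-pooled, not area-weighted). A
companion ratio readout divides summed per-nucleus mean signal by the total
nucleus count. Wells with zero surviving nuclei are flagged missing and
propagate as missing through scoring.

Known measurement property: with defocus blur, reporter signal smears
beyond the segmented boundary and the ROI mean under-measures the pre-blur
nuclear mean by O(sigma/R) — about 10% at sigma = 0.8 px for 6–10 px
nuclei. This is optics, not a pipeline defect; recovery benchmarks
therefore use sensor noise (sd 30 on a 2000-unit signal) without defocus,
which isolates segmentation and averaging accuracy (errors < 1%).

## Screen statistics

**B-score (per plate).** A two-way median polish (alternating row-then-
column median sweeps from zero effects, NaN-aware, rows first, default 20
iterations, tolerance 1e-6 relative) is fitted on *library wells only*;
control and empty wells are treated as missing during fitting. Residuals
against the fitted surface are computed for every well, re-centered on the
median of the plate's library residuals (library-median centrality), and
divided by 1.4826 x MAD of the library residuals (per-plate variance
adjustment; 1.4826 makes the MAD consistent for a Gaussian SD). By
construction the plate's library B-scores then have median 0 and scaled
MAD exactly 1. If the library MAD vanishes (an exactly additive plate, to
float round-off) all B-scores are set to 0 and a degeneracy flag raised.
Because controls enter neither the fit nor the scale, arbitrarily extreme
control wells cannot move any library B-score.

Median polish is iterative and, with missing cells, converges geometrically
(observed rate ~0.93 per sweep); results quoted to better than 1e-9 are run
for a fixed large sweep count rather than an early-stopping tolerance.
Sweep order is pinned rows-first since it can matter on pathological grids.

**Z-score (per replicate).** All B-scores of a biological replicate are
scored against that replicate's library wells: robust by default
(median / 1.4826 x MAD), classical mean/SD as an option. Controls are
scored against the same library reference.

**Aggregation.** siRNA-level score = arithmetic mean of the available
replicate Z-scores (count recorded; a missing replicate falls back to the
remaining one). Gene-level score = median of the gene's siRNA-level scores;
with three siRNAs this is the second strongest oligo, so a single
strong off-target siRNA cannot carry a gene. Genes are ranked by descending
median Z with lexicographic tie-breaks; hit calling is a simple threshold
on the gene median Z (no p-value/FDR machinery — ranking is the product).

A quantitative limit of the median-of-three rule, visible in our spike-in
benchmarks: a decoy gene with one very strong off-target siRNA still scores
the *maximum* of its two clean siRNAs — a positively biased order statistic
— so with ~500 genes roughly two of ten such decoys are expected inside the
top 20 ranks purely by that bias, at any noise scale. The rule reduces
off-target false positives; it does not eliminate them.

## Spot-level quantification

Spot intensity is the maximum pixel value in an 8x8 px box at an annotated
spot center (box spans rows/cols [round(x)-3, round(x)+4]). Background is
the average of the per-box maxima of four seeded-random, mutually disjoint
8x8 boxes placed fully inside the cytoplasm mask of the same cell;
corrected intensity = spot max - background, kept (and flagged) when
negative. Per-condition summaries report mean ± s.e.m. (sample SD / sqrt n;
per-spot replication by default, per-cell optional) and fold change against
a reference condition. Significance: unpaired two-tailed t-test
(equal-variance Student's by default, Welch optional) and one-way ANOVA
with Tukey's HSD via the studentized-range distribution.

Because the background estimate is a mean of *maxima*, it is biased upward
by ~2.45 sigma under iid Gaussian noise (expected maximum of 64 draws),
which biases corrected intensities down by the same amount and inflates
amplitude ratios when amplitudes are comparable to that bias. This is
inherent to the max-box protocol. Recovery benchmarks use noise sd 8 for
absolute-amplitude recovery (bias ~3% of a 400-unit spot) and sd 2 for
fold-change recovery.

## Pipeline and reproducibility

One global seed governs every stochastic stage through documented
sub-seeding (children of `numpy.random.SeedSequence(seed)` spawned in the
fixed order truth, simulate, render, spots; each truncated to 31 bits).
Identical config + seed produce bit-identical CSV outputs; timings go only
to the run log. CSV dialect is pinned (comma, UTF-8, `.` decimal, empty
missing fields, headers validated on read). The image path of the pipeline
renders and quantifies non-empty wells only; empty wells never enter
fitting or scaling, so the direct and image paths rank genes identically in
the noiseless limit (verified bit-for-bit with integer effects, where
16-bit quantization is exact).

## What the synthetic data does and does not establish

The generator reproduces the *structure* of the screen (layout, controls,
additive plate artifacts, per-siRNA potency variation, off-target oligos,
nucleus-level image statistics) with known truth, so passing tests
establish correctness of the layout, normalization, scoring, segmentation
and measurement code, and realistic sensitivity/specificity behavior of
the median-of-three rule. They do not establish equivalence with any
vendor image-analysis pipeline (undisclosed algorithms), nor do they
reproduce the original screen's numerical results, whose raw images and
well tables are not public. Cell-to-cell biological variability,
transfection efficiency, cell-cycle structure, 3D optics and illumination
artifacts are deliberately out of scope of the renderer.

## Problem sizes used by the benchmarks

Acceptance-style runs use: 100 random 8x12 grids (10% missing) for polish
oracle equivalence; one full 16x24 plate (117 genes) for artifact removal
and control immunity; the full 521-gene, 2-replicate design across 5 seeds
for hit recovery; 20 wells of 30–80 nuclei at 256x256 for the image stage;
a 40-gene screen for two-path consistency; 100 spots at 1024x1024 for spot
recovery. These sizes exercise every code path at full plate geometry while
keeping a complete run in tens of seconds.
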