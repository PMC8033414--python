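# Methods

This note documents the models, algorithms, defaults and numerical
choices behind `cytofpipe`, and what the synthetic-data tests do and do
not establish about real data.

## The analysis problem

Suspension mass cytometry of dissociated tissue produces, per acquired
event, ion counts on ~50 metal channels: antibody markers, a DNA
intercalator (iridium), a viability stain (cisplatin), an apoptosis
marker (cleaved caspase-3), normalization-bead channels, palladium
barcode channels and instrument diagnostics. Large studies are acquired
in several batches on different days; staining intensity and machine
state drift between batches. When no shared anchor sample was run in
every batch, batch effects must be corrected *unanchored*, i.e. by
aligning the marker distributions themselves.

## Synthetic cohort generator

The generator is the package's test bed: it emulates the statistical
structure the pipeline assumes, with known per-event truth.

**Population model.** 21 immune populations (six macrophage, four
dendritic-cell, six T-cell subsets, B cells, NK cells, eosinophils and
two MDSC subsets) are specified as Gaussians per marker on the
*transformed* (arcsinh) scale — the space the pipeline analyses — with a
background level of 0.4 and hot-marker levels of ~3.5–6 (s.d. 0.35).
Signatures follow standard murine immunophenotyping (e.g. G-MDSC:
CD11b+ Ly6-G+ Ly6-C-low; M-MDSC: CD11b+ Ly6-C+ Ly6-G−; PD-L1+ DC:
CD11c+ PD-L1+ MHC-II-high). Templates are mutually separable by
construction (minimum pairwise distance of the mean vectors > 4× the
background s.d.), which is what makes exact recovery measurable; real
populations form continua and will cluster less cleanly.

**Event composition.** Default fractions of acquired events: 3% beads
(hot bead channel, low DNA), 5% debris (low DNA, low everything), 15% of
cellular events dead or apoptotic (hot cisplatin / hot c-Cas3), and a
live CD45+ *target* fraction of 5% of all events, mirroring an
unenriched tumor dissociate; the remaining live cells are CD45− tumor
cells (high DNA, low markers). The 1–12% target range seen across real
batches is reachable through `frac_cd45`.

**Abundance model.** Per sample, population probabilities are baseline
abundance × exp(group log-fold effect, HFD arm only) × a per-population
lognormal biological factor (s.d. 0.25 on the log scale), renormalized;
events are then drawn multinomially. The planted default effect is
G-MDSC +0.7, PD-L1+ DC +0.7, and both CD8 T subsets −0.5 (log scale).
The baseline is a generic mixed infiltrate with every population ≥ 1%,
chosen so that all 21 metaclusters are populated at desk-scale event
counts; it does not reproduce any specific tumor model's composition.
The 0.25 biological s.d. is a deliberately moderate choice — with 8
samples per arm it puts the +0.7 log-fold effect near 95–100% t-test
power, i.e. an effect a well-powered cohort should detect.

**Physics layer.** Transformed-scale draws are pushed through the
inverse transform (`5·sinh(x)`) to ion counts; per-batch per-marker
scale factors (lognormal, s.d. 0.15 on the log scale) and small positive
shifts emulate unanchored batch effects on the raw scale; counts are
rounded and uniform(−1, 0) noise is added, emulating vendor
"uniform negative distribution" randomization; samples within a batch
share interleaved acquisition order and a time channel at 500 events/s.
Barcodes are the 20-plex 3-hot-of-6 palladium scheme; hot channels sit
at 4.5 ± 0.35, cold at 0.15 ± 0.1 (transformed scale). Not simulated:
spillover between mass channels, detector saturation, acquisition drift
beyond the linear shift, and doublets — so passing tests say nothing
about robustness to those artifacts.

**Determinism.** One global seed feeds a hierarchical `SeedSequence`
spawned per batch and per sample, so any sub-cohort regenerates
identically on its own.

## Debarcoding

Barcode channels are arcsinh transformed, rescaled to [0, 1] by their
within-file 0.1/99.9 percentile range (config-exposed), and sorted per
event. *Separation* is the gap between the k-th and (k+1)-th largest
normalized intensities (k = 3). An event is assigned to the key whose
hot set equals its top-k channels; ties give separation 0 and are never
assigned. Events with separation < 0.12 are unassigned. A single-pass
Mahalanobis filter then removes events further than 30 from their
preliminary barcode population's mean/covariance in normalized barcode
space (singular covariances fall back to the diagonal with a warning).
Iterative re-estimation is intentionally omitted: one pass keeps the
contract testable and matches the common tool default.

## Gating

The original strategy is manual; the package automates it with
data-derived thresholds so runs are reproducible. Directional gates
(bead-low, DNA-high, cisplatin-low, c-Cas3-low, CD45-high) use the
kernel-density valley between the two most prominent modes, with a
minimum bandwidth of 0.15 (transformed scale) so ion-count discreteness
near zero cannot fabricate modes, and peaks required to be ≥ 0.8 apart.
When a channel is effectively unimodal the minority population is taken
to be absent and the gate stays permissive (median ± 5 robust s.d.) —
the right behavior when, e.g., a debarcoded sample no longer contains
beads. Gaussian acquisition parameters are gated to median ± 5 robust
s.d. Every threshold is overridable. Samples with fewer than 5,000 live
CD45+ events are excluded (boundary inclusive: exactly 5,000 is kept).

## Batch correction

All corrections are per-marker, per-batch monotone 1-D maps fitted on
live-CD45+ gated, arcsinh-transformed events, consistent with the
pipeline's order of operations; the apoptosis stain is not corrected
since it is only used during pre-gating. Corrected channels are emitted
alongside the originals with a `c_` prefix.

* **range** (default): each batch's [q_lo, q_hi] quantile interval
  (default 0.001/0.999, config-exposed) is mapped affinely onto the
  across-batch mean interval. Equalizes the chosen quantile pair
  exactly (to 1e-9) and removes scale/shift effects without forcing
  distributions to be identical.
* **quantile**: empirical quantile function composed with the
  across-batch average inverse quantile function on a 1,001-point
  probability grid; equalizes all interior quantiles. On mixtures whose
  component weights genuinely differ between batches this erases real
  biology — the package's evaluation (earth-mover distance to planted
  truth) quantifies exactly this failure mode, and the test suite
  asserts quantile is worse than range there.
* **warp**: Silverman-bandwidth KDE per batch; landmarks are density
  peaks above 5% of the maximum (config-exposed); landmarks are matched
  across batches by rank and aligned to their cross-batch means with a
  monotone piecewise-linear map (linear extrapolation beyond the
  outermost landmarks). Markers with fewer than two usable landmarks in
  any batch fall back to range with a warning.

`evaluate_correction` reports per marker and method: mean pairwise
cross-batch earth-mover distance, maximum pairwise distance between
per-batch density modes, a near-zero gap score (fraction deficit of
events in (0, 0.5] relative to uncorrected — the warp failure mode),
and the minimum within-batch Spearman correlation pre/post (exactly 1
for all three methods, which are monotone by construction).

## Multistep clustering

Equal-event subsampling (default 5,206 per kept file, sampling without
replacement) removes sample-size bias from the pooled embedding.
Barnes-Hut t-SNE (scikit-learn; perplexity 30, angle 0.5, 4,000
iterations, PCA initialization, fixed seed) embeds the pooled events on
the embedding marker set — lineage/phenotype markers only; activation
and exhaustion markers and CD5 are excluded to avoid over-representing
activated T cells. k-means (k-means++ with 10 restarts, fixed seed) is
run on the two embedding coordinates alone so the clustering inherits
the dimensionality reduction; k = 40 deliberately over-clusters.
Curation is an explicit, logged merge map (identity by default; an
automatic suggestion merges mutually-nearest centroid pairs within a
small fraction of the map span). MEM scores each curated cluster
against the pooled events *outside* it — medians (MAG) and
interquartile ranges (IQR) per marker:

    raw = |MAG_pop − MAG_ref| + IQR_ref / IQR_pop − 1, clamped at ≥ 0,
    signed by (MAG_pop − MAG_ref)

with a zero population IQR replaced by 0.5 (transformed scale, warned),
and the matrix rescaled so the largest |score| is 10. Metaclusters come
from a Ward/Euclidean cut of the MEM row dendrogram (default 21 groups;
a column dendrogram over markers is produced as well). Every embedded
event carries exactly one cluster, curated and metacluster id — no
exclusions, no double counting — which the tests assert end to end.

## Differential abundance

Abundance is percent of each sample's live CD45+ events per
metacluster. Group comparison is the unpaired two-tailed t-test with
pooled variance (equal s.d. assumed between the two diet groups, not
between metaclusters), deliberately unadjusted by default;
Benjamini–Hochberg is available. Groups with fewer than two samples
yield no statistic, with the reason recorded. CD4/CD8 summaries
(CD4/CD8 ratio, CD8 and CD4 as % of T cells, T cells as % of CD45+)
come from embedding-space CD3 gating plus biaxial CD4/CD8 thresholds
(DN = CD4− CD8−, with a CD4+CD8+ remainder class); samples with zero
CD8 counts are excluded from the ratio with a warning.

The CITRUS-style confirmation Ward-clusters pooled events in marker
space. Because agglomeration is O(n²), events are subsampled per sample
first (default 500/sample, config-exposed); features are per-sample
fractions among that sample's sampled events. Every tree node holding
≥ 1% of pooled events is a candidate. The SAM statistic per node is
d = (mean_HFD − mean_chow)/(s + s0) with s the pooled standard error
and s0 the median of s over candidate nodes (the classic exchangeability
fudge; config-exposed). The null comes from distinct balanced
group-label permutations (exhaustive when fewer than `n_perm` exist);
FDR per node follows the original SAM definition — median permuted
count of |d_perm| ≥ |d| divided by the observed count — with
significance at FDR ≤ 0.05. Nested candidate nodes are correlated by
construction; the null simulations measure the *node-level*
false-positive fraction, which is strongly conservative here (≈ 0.6%
at nominal 5%).

## Problem sizes used by the tests and the acceptance run

The suite and `scripts/acceptance.py` exercise the full chain at
reduced sizes chosen to keep a complete run in minutes on one CPU while
preserving every structural property: the default verification cohort
uses 2 batches × 8 samples × 20,000 events (the ~5% target fraction
giving ~1,000 live CD45+ cells per sample), analysed at 800 events per
file with 750 t-SNE iterations and 500-permutation SAM; the
pooled-event arithmetic is checked at the full 67 × 5,206 scale; power
is measured at the abundance level (the same multinomial + lognormal
model the event generator realizes) over 100 seeds. On this cohort the
pipeline recovers the 21 planted populations with ARI ≈ 0.89 and flags
all four planted effects by both statistical routes.

## Known limitations

* FCS support covers single-dataset list-mode files with float or
  unsigned-integer data — sufficient for normalized CyTOF exports, not
  a general FCS implementation.
* t-SNE coordinates are platform-reproducible only (fixed seed, same
  BLAS); all CSV outputs downstream of a fixed embedding are
  bit-reproducible.
* Automated gate thresholds assume roughly bimodal gating channels;
  pathological distributions should be gated with explicit thresholds
  via the config.
* The synthetic generator's separable Gaussian populations make
  recovery metrics optimistic relative to real continua of cell states;
  treat the ARI and power numbers as verification of the machinery, not
  as expected field performance.
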