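# Methods

This note documents the models implemented in `mitoniche`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical choices that affect results.

## Mitogenome annotation model

An annotated mitogenome is a circular sequence with ordered features in
1-based inclusive coordinates, all expressed on the majority (J) strand;
minority-strand (N) features are stored in the same coordinate frame and
reverse-complemented on extraction. This matches how insect mitogenome
feature tables are published and keeps a single coordinate system.

* The intergenic spacer between consecutive features is
  `IGS = start_downstream − stop_upstream − 1`; negative values are gene
  overlaps. The terminal spacer closes the circle:
  `genome_length = last_stop + terminal_IGS` under the convention that the
  first feature starts at position 1. The bundled published annotations of
  the two *Phthorimaea* mitogenomes reconstruct their deposited lengths
  (15,295 and 15,269 bp) exactly this way, with no sequence needed.
* At most one feature may wrap the origin; a wrapping feature must be the
  last in genome order, otherwise `stop < start` is a coordinate error.
  Wrapping never occurs in the bundled annotations but is exercised by the
  rotation-invariance tests.
* Protein-coding genes may end in incomplete stop codons (T or TA); these
  are completed to TAA by polyadenylation of the mature transcript and are
  accepted by the codon verifier. A coding length not congruent to 0 mod 3
  after stop completion is flagged but not fatal — published tables contain
  such rows.
* The total length of the 13 protein-coding genes is reported both as the
  raw sum of per-gene sizes and as an overlap-deduplicated count of covered
  positions. Published totals differ between these conventions by a few bp;
  the package asserts neither, it reports both.

## Pairwise comparison

Homologous protein-coding genes are extracted on their coding strand and
aligned per gene (global Needleman–Wunsch with affine gaps; a gap of length
L scores `open + (L−1)·extend`, defaults match=1, mismatch=−1,
open=extend=−2). Per-gene alignment is robust to orthologue length
differences (e.g. ATP8 171 vs 165 bp); whole-genome alignment is available
for identity statistics. The aligner is a C dynamic program that handles
two ~15 kb genomes in desk memory and a few seconds; tests verify its
optima against an independent quadratic-space scorer.

SNP columns are mismatching, gap-free, N-free columns. The identity
percentage uses all alignment columns as denominator (viewer convention),
while SNP counting excludes gap/N columns.

Synonymous/non-synonymous classification pairs codons column-wise along the
first row's reading frame. Codons containing a gap or N in either row are
excluded, which also resynchronises the frame at the next clean codon
boundary after an indel. A codon pair is one unit: if the translations
(invertebrate mitochondrial code, table 5) differ, every variant position
in that codon counts as non-synonymous, otherwise all count as synonymous.
This yields a single syn/nonsyn partition of the SNPs. Because the
percentage of non-synonymous changes is reported under two circulating
conventions, the per-gene summary carries both: percent of SNPs and percent
of aligned gene length.

## Distances and ordination

p-distance is the proportion of differing sites among comparable columns;
K2P applies the transition/transversion correction
`d = −½·ln((1−2P−Q)√(1−2Q))` and raises a saturation error when a log
argument is non-positive. Gaps and IUPAC ambiguity codes are removed
pairwise, matching common distance-software defaults. Group means average
all cross-group pairs (within-group means on the diagonal; NA for
singletons). Percentages are `100·d`, rounded only at presentation.

PCoA is classical metric scaling: double-centre `−½·J·D²·J`, symmetric
eigendecomposition, coordinates = eigenvectors scaled by the square root of
positive eigenvalues. Negative eigenvalues (non-Euclidean input) are
reported and never used; requesting more axes than positive eigenvalues
truncates with a warning. Tests verify Euclidean self-consistency at 1e−8
and agreement with an independent implementation.

## BIOCLIM

The envelope stores the presence sample per variable (sorted values, mean,
sd, min, max, percentiles). The percentile score is two-tailed:

    s_v(x) = min(1, 2·min(P(X ≤ x), P(X ≥ x)))

with X the empirical presence distribution — 1 at the presence median, 0 at
or beyond the presence extremes — and the cell score is the minimum over
variables. This tail-probability form was chosen because it makes the
presence median score exactly 1 and reduces to the familiar
`2·min(F, 1−F)` away from ties. The alternative rectangular envelope
(mean ± k·sd, default k=2, binary score) is available as `mode="meansd"`.
Both scores are invariant under affine rescaling of any input variable.

Known behaviour: the empirical envelope is exactly 0 outside the presence
min–max of any variable, so a large share of map cells can tie at 0. This
caps whole-map rank agreement with a smooth truth surface and is intrinsic
to envelope models, not an implementation artifact.

## MaxEnt

Features are standardised linear and quadratic terms of each variable
(standardisation constants and clamp bounds from the training background).
The model maximises the L1-penalised presence log-likelihood of the Gibbs
distribution over background cells; splitting λ into positive and negative
parts turns the problem into a smooth bound-constrained convex program
solved with L-BFGS-B. Defaults:

* `beta_scale = 0.05` — β_j is 0.05 × the presence sd of feature j
  (floored at 1e−6), a small scale-aware budget in the spirit of the
  reference software's feature-class defaults;
* `max_iter = 5000` — the optimiser iteration cap from the study protocol
  (convergence is typically reached within ~50 iterations at this scale);
* `tol = 1e−5` — controls the projected-gradient stopping rule. The
  relative-objective criterion is effectively disabled (1e−13): stopping on
  small objective change can leave the moment conditions
  `|E_p[f_j] − f̄_presence,j| ≤ β_j` violated even though the fit looks
  converged, while the projected-gradient norm bounds that slack directly.

Predictions: `raw` is the Gibbs density normalised over the model's
background reference (sums to 1 there); `cloglog = 1 − exp(−e^H·raw)` with
H the entropy of the raw distribution, giving a [0, 1] score. Projection
clamps features to their training range (logged). Scale invariance holds
exactly for multiplicative rescaling of a variable; a shift additionally
rotates the quadratic feature basis, so the L1 optimum can move very
slightly — only multiplicative invariance is asserted.

Only linear + quadratic features are implemented (no hinge, product or
threshold features). This keeps the fit a small convex program and is
adequate for the Gaussian-type responses studied here; it is a documented
divergence from the full reference implementation.

## Evaluation, consensus, overlap

* AUC is the Mann–Whitney pair statistic (ties ½), invariant under
  monotone transforms; correlation is point-biserial (Pearson against 0/1
  labels).
* Permutation importance shuffles one variable's values across valid cells
  and measures the mean AUC drop over repeats (default 3); contributions
  are also normalised to percentages (negative drops clipped at 0).
* Consensus is the AUC-weighted cell-wise average with weights
  `AUC_i / Σ AUC_i` of the [0, 1]-scaled member predictions. Raw AUC is
  used (not AUC − 0.5), matching the stated weighting; members should be
  rescaled first where their native scales differ.
* The ecoclimatic-index classes partition [0, 1] as: exactly 0 →
  unsuitable; (0, 0.2) → marginal; [0.2, 0.5) → high; [0.5, 1] → optimal.
  The published scale prints "≤ 0.19" and "0.2–0.49"; extending marginal to
  the open interval (0, 0.2) removes the gap for continuous values while
  preserving the class order.
* Niche overlap: `min` returns the cell-wise minimum (continuous shared
  suitability); `subtract` implements the description "combined consensus
  minus each species' exclusive surplus", which is algebraically identical
  to `min` (with C = (a+b)/2: C − (a−C)₊ − (b−C)₊ = min(a, b)); `binary`
  reports only threshold masks. Because cloglog/consensus surfaces are
  weakly positive almost everywhere, the bundled two-species workflow masks
  at the "high" threshold (0.2) rather than >0, otherwise the marginal
  masks are degenerate.
* Niche expansion/unfilling/stability are computed on bin occupancy over
  the first two principal axes of the (standardised) available environment:
  expansion = invaded-only / invaded-occupied bins, unfilling =
  native-only / native-occupied bins, stability = shared / invaded-occupied
  bins, restricted to bins containing available environment; expansion +
  stability = 1 by construction. Default 100×100 bins; the bundled
  workflow uses 50×50 because with a few hundred presence points per
  species finer grids make occupancy so sparse that expansion/unfilling
  approach 1 through sampling alone — a known binning artifact to keep in
  mind when reading these fractions.

## Synthetic data

* **Mitogenome pairs.** The template genome copies the gene order,
  categories and strands of the published *P. absoluta* annotation, laid
  end-to-end without overlaps; PCGs get ATG…TAA frames of random sense
  codons. Mutations are planted one per interior codon, codon-aware
  (synonymous changes preserve the table-5 amino acid), with no indels, so
  the comparison stage must recover the per-gene ledger exactly — and the
  tests require exactly that. Not emulated: indels, gene overlaps in the
  template, among-site rate variation, composition bias. Passing recovery
  therefore validates the counting/classification machinery, not alignment
  robustness to structural variation.
* **Climate stacks.** Each layer is Gaussian-smoothed noise (sigma
  `smoothness` cells, default 3) plus a small deterministic planar gradient
  (amplitude 0.2 sd, direction varying per layer), affinely mapped onto
  distinct plausible scales (temperature-like, precipitation-like, …).
  The smoothed fields are empirically whitened and then mixed to the
  requested cross-correlation matrix, so realised correlations match the
  request to within a few hundredths. Not emulated: anisotropy, coastline
  masks (a random-nodata option exists), realistic covariance among 19
  bioclim variables.
* **Species.** True suitability is Gaussian,
  `S*(x) = exp(−Σ_v (x_v − μ_v)²/(2σ_v²))`; presence cells are drawn
  without replacement with probability ∝ S*. Default fixture scale:
  100×100 grid, 6 variables, 200 presences per species, 2,000 background
  points. The model-recovery fixture uses 600 presences with a strong
  2-variable response (σ = 1.6 and 1.3 on layers whose marginal sds are
  ~6 and ~4): envelope models need a few hundred points before their
  empirical min–max stops truncating the graded score over much of the
  map, and compendium-scale datasets for these cosmopolitan pests are of
  that order. Sampling is presence-only and spatially unbiased; real
  occurrence data's observation bias is not emulated, so passing recovery
  bounds say nothing about bias robustness.

All generators take one explicit integer seed; there is no global random
state, and equal seeds reproduce outputs byte-for-byte.

## Problem sizes

The test suite and `scripts/acceptance.py` run the full pipeline at the
fixture scale above (single-species recovery, a three-seed recovery sweep,
and the two-species ensemble each complete in seconds on one CPU). The
whole-genome alignment of a ~15 kb pair takes ~3 s.

## Known limitations

* Real-data headline numbers that require the deposited sequences or the
  global occurrence compendia (whole-genome identity of the two species,
  their 866 PCG SNPs, barcode group means, world maps) are out of reach of
  the offline synthetic system; the pipeline computes the same quantities
  on synthetic inputs with known truth instead.
* GeoTIFF input is not supported; rasters are ESRI ASCII grids. Grids are
  treated on their native (lat-long) cell geometry; no great-circle or
  equal-area corrections.
* MaxEnt omits hinge/product/threshold features and the default
  feature-class schedule of the reference software; absolute suitability
  values are therefore not comparable to it, though rankings on smooth
  responses are.
* The syn/nonsyn partition treats each codon pair as a single event;
  multi-hit codons are not decomposed along mutational paths, which is the
  right convention for the planted-truth fixtures but differs from
  path-counting estimators used for dN/dS.
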