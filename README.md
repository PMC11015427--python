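# mitoniche

Comparative mitogenomics and ensemble habitat-suitability modelling for two
invasive *Phthorimaea* pest moths — the potato tuber moth (*Phthorimaea
operculella*) and the tomato leaf miner (*Phthorimaea absoluta*). Both
species attack solanaceous crops, can complete their life cycles on each
other's principal host, and are spreading worldwide; quantifying how similar
their mitochondrial genomes are and how much their climatic niches overlap
is the basis for early-warning surveillance and phytosanitary policy.

The package implements two analysis tracks as a tested, reusable library
(`src/mitoniche`), with narrative drivers under `analysis/` and synthetic
data generators so every stage runs and is verifiable offline.

## Track 1 — mitogenome comparison

* **Annotation arithmetic** on circular mitogenomes in 1-based inclusive
  J-strand coordinates: feature sizes, intergenic spacers
  (IGS = start₂ − stop₁ − 1, negative values are gene overlaps), genome
  length reconstruction, start/stop codon verification with incomplete
  stops (T/TA completed by polyadenylation). The published annotations of
  both *Phthorimaea* mitogenomes (BioProject PRJNA902348) are bundled as
  plain TSV tables.
* **Pairwise comparison**: global (Needleman–Wunsch, affine gaps)
  alignment, identity statistics, per-PCG SNP counts, and codon-wise
  synonymous/non-synonymous classification under the invertebrate
  mitochondrial code (translation table 5: ATA=Met, TGA=Trp, AGA/AGG=Ser).
* **Distances and ordination**: uncorrected p-distance and the Kimura
  2-parameter distance
  `d = −½·ln((1−2P−Q)·√(1−2Q))`
  with P/Q the transition/transversion proportions (pairwise deletion of
  gaps and ambiguity codes), species-group mean distances, and classical
  PCoA (cmdscale: double-centre −½·J·D²·J, eigendecompose).

## Track 2 — habitat suitability and niche overlap

* **BIOCLIM** climate envelope: each cell scores
  `s_v = min(1, 2·min(P(X≤x), P(X≥x)))` per variable against the presence
  sample's empirical distribution (1 at the presence median, 0 outside the
  presence min–max) and takes the minimum over variables. A rectangular
  mean ± k·sd mode is available.
* **MaxEnt**: the Gibbs distribution `p(x) ∝ exp(Σ_j λ_j f_j(x))` over
  background cells, with standardised linear + quadratic features and
  L1 regularisation β_j, fit by maximising the penalised presence
  log-likelihood (convex; at the optimum `|E_p[f_j] − f̄_presence,j| ≤ β_j`).
  Output on the raw (sums to 1 over background) or cloglog scale.
* **Evaluation and ensemble**: AUC (Mann–Whitney pair statistic),
  point-biserial correlation, permutation variable importance; AUC-weighted
  consensus `Σ w_i·r_i` with `w_i = AUC_i / Σ AUC_i`; ecoclimatic-index
  classification (0 unsuitable, (0, 0.2) marginal, [0.2, 0.5) high,
  [0.5, 1] optimal); continuous niche overlap (cell-wise minimum /
  subtraction), binary overlap masks, and niche expansion / unfilling /
  stability in binned environmental space.

Calibration follows the study protocol: 75/25 presence split, ≥10,000
background points by default, 5,000-iteration optimiser cap. Rasters are
read and written as ESRI ASCII grids; occurrences as
`species,longitude,latitude` CSV.

## Worked example

```sh
python analysis/01_mitogenome_features.py
```

```
P_absoluta: 15295 bp, 38 features, ND5 1735 bp, ATP8 171 bp, 4 overlaps, largest spacer 69 bp before tRNA-Ala
P_operculella: 15269 bp, 38 features, ND5 1732 bp, ATP8 165 bp, 4 overlaps, largest spacer 57 bp before ND2
```

Both genomes close exactly at their published lengths when reconstructed
from the printed coordinates plus the terminal spacer; ND5 is the longest
protein-coding gene and ATP8 the shortest, and each annotation carries four
short gene overlaps (the largest, 8 bp, between tRNA-Trp and tRNA-Cys).

```sh
python analysis/04_habitat_suitability.py --seed 1
```

```
species_a: BIOCLIM AUC 0.724, MaxEnt AUC 0.816; optimal 5.9% of cells, high 51.0%
species_b: BIOCLIM AUC 0.774, MaxEnt AUC 0.752; optimal 4.0% of cells, high 61.3%
shared-suitability cells: 47.2% (a-only 9.7%, b-only 18.1%)
niche dynamics (B vs A): expansion 0.76, stability 0.24, unfilling 0.75
```

Two simulated species with partially overlapping Gaussian niches are each
modelled with both SDMs; the AUC-weighted consensus puts ~5% of the map in
the optimal EI class for each species, and about half of the cells that are
at least highly suitable for one species are suitable for both — the
niche-overlap signal the ensemble is designed to expose. (The `analysis/02`
and `analysis/03` drivers run the comparison and distance/PCoA tracks the
same way.)

The other numbered drivers follow the same pattern; a `mitoniche` console
script exposes each stage as a subcommand (`mitoniche simulate`,
`sdm-fit`, `consensus`, `classify`, `overlap`, …) with a JSON run manifest
per invocation.

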