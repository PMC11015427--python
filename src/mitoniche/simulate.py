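"""Synthetic fixtures with known truth for every pipeline stage.

Three generators stand in for the study's raw inputs:

- :func:`make_template_genome` + :func:`simulate_mitogenome_pair` build a
  Phthorimaea-like annotated circular mitogenome and a diverged partner
  with a per-gene ledger of planted SNPs and non-synonymous substitutions,
  so the comparison stage can be checked for exact recovery;
- :func:`simulate_climate_stack` builds spatially autocorrelated, optionally
  cross-correlated environmental layers;
- :func:`simulate_species` samples presence points from a known Gaussian-
  response suitability surface, returning the true surface for recovery
  tests.

All randomness flows through one explicit integer seed per call; there is
no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy.ndimage import gaussian_filter

from .annotation import AnnotatedMitogenome, GeneFeature, load_reference_annotation
from .raster import ClimateStack, GridTransform, SuitabilityRaster
from .sdm import OccurrenceSet

logger = logging.getLogger(__name__)

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
_SENSE_CODONS = sorted(_TABLE5.forward_table)
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Mitogenome pair with planted substitution truth
# ---------------------------------------------------------------------------

@dataclass
class PlantedSNP:
    gene: str
    genome_position: int  # 1-based J-strand coordinate
    base_a: str
    base_b: str
    synonymous: Optional[bool]  # None for non-coding SNPs


@dataclass
class SubstitutionTruth:
    """Ledger of planted differences between a simulated genome pair."""

    snps: dict[str, int] = field(default_factory=dict)
    nonsyn: dict[str, int] = field(default_factory=dict)
    records: list[PlantedSNP] = field(default_factory=list)

    def __post_init__(self) -> None:
        for g, n in self.snps.items():
            if self.nonsyn.get(g, 0) > n:
                raise ValueError(f"{g}: planted nonsyn exceeds planted SNPs")


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + TAA under the invertebrate mito code."""
    interior = rng.choice(_SENSE_CODONS, size=max(n_codons - 2, 0))
    return "ATG" + "".join(interior) + "TAA"


def make_template_genome(
    seed: int = 0,
    organism: str = "synthetic-template",
    scale: float = 1.0,
) -> AnnotatedMitogenome:
    """A synthetic annotated mitogenome laid out like the Phthorimaea ones.

    Gene order, names, categories and strands follow the published
    P. absoluta annotation; features are laid end-to-end with small random
    spacers (no overlaps, so per-gene extraction is unambiguous for the
    planted-truth simulations).  PCG lengths are the published lengths
    rounded down to whole codons; ``scale`` shrinks every feature for
    fast tests (lengths are re-rounded to codons, minimum 6).
    """
    rng = np.random.default_rng(seed)
    ref, _ = load_reference_annotation("P_absoluta")
    pieces: list[tuple[GeneFeature, str]] = []
    for f in ref.features:
        length = f.stop - f.start + 1
        length = max(int(length * scale), 12)
        if f.category == "PCG":
            n_codons = max(length // 3, 4)
            coding = _random_coding_sequence(n_codons, rng)
            seq = coding if f.strand == "J" else str(Seq(coding).reverse_complement())
        else:
            seq = "".join(rng.choice(list(_BASES), size=length))
        pieces.append((f, seq))
    features: list[GeneFeature] = []
    sequence_parts: list[str] = []
    pos = 1
    for f, seq in pieces:
        gap = int(rng.integers(0, 6))
        sequence_parts.append("".join(rng.choice(list(_BASES), size=gap)))
        start = pos + gap
        stop = start + len(seq) - 1
        features.append(
            GeneFeature(
                name=f.name, category=f.category, strand=f.strand,
                start=start, stop=stop,
            )
        )
        sequence_parts.append(seq)
        pos = stop + 1
    # terminal spacer back to the origin
    sequence_parts.append("".join(rng.choice(list(_BASES), size=int(rng.integers(0, 6)))))
    return AnnotatedMitogenome(
        organism=organism, features=features, sequence="".join(sequence_parts)
    )


def _synonymous_change(codon: str, rng: np.random.Generator) -> Optional[tuple[int, str]]:
    """A (position, new_base) single-base synonymous change, if one exists."""
    aa = _TABLE5.forward_table[codon]
    options = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _TABLE5.forward_table.get(alt) == aa:
                options.append((pos, b))
    if not options:
        return None
    return options[rng.integers(len(options))]


def _nonsynonymous_change(codon: str, rng: np.random.Generator) -> tuple[int, str]:
    aa = _TABLE5.forward_table[codon]
    options = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = _TABLE5.forward_table.get(alt)
            if alt_aa is not None and alt_aa != aa:
                options.append((pos, b))
    if not options:  # every sense codon has a non-synonymous neighbour
        raise RuntimeError(f"no non-synonymous change for codon {codon}")
    return options[rng.integers(len(options))]


def simulate_mitogenome_pair(
    template: AnnotatedMitogenome,
    truth_spec: dict[str, tuple[int, int]],
    seed: int = 0,
) -> tuple[AnnotatedMitogenome, AnnotatedMitogenome, SubstitutionTruth]:
    """Mutate a copy of ``template`` codon-aware per a (snps, nonsyn) ledger.

    ``truth_spec`` maps gene name to (total SNPs, non-synonymous SNPs) for
    that gene.  Mutations hit distinct interior codons (one SNP per codon,
    start/stop codons untouched, no indels), so the comparison stage must
    recover the ledger exactly.  Raises if a gene is too short for the
    request or lacks enough synonymous sites.
    """
    rng = np.random.default_rng(seed)
    if template.sequence is None:
        raise ValueError("template needs a sequence")
    seq_b = list(template.sequence)
    truth = SubstitutionTruth()
    for gene, (n_snps, n_nonsyn) in truth_spec.items():
        f = template.feature(gene)
        if f.category != "PCG":
            raise ValueError(f"{gene}: truth ledger only supports PCGs")
        if n_nonsyn > n_snps:
            raise ValueError(f"{gene}: nonsyn > snps in request")
        coding = template.extract(f)
        n_codons = len(coding) // 3
        interior = list(range(1, n_codons - 1))
        if n_snps > len(interior):
            raise ValueError(
                f"{gene}: requested {n_snps} SNPs but only {len(interior)} "
                "interior codons available"
            )
        rng.shuffle(interior)
        n_syn = n_snps - n_nonsyn
        placed_syn = placed_nonsyn = 0
        for ci in interior:
            if placed_syn == n_syn and placed_nonsyn == n_nonsyn:
                break
            codon = coding[3 * ci : 3 * ci + 3]
            if placed_nonsyn < n_nonsyn:
                pos, b = _nonsynonymous_change(codon, rng)
                syn_flag = False
                placed_nonsyn += 1
            else:
                change = _synonymous_change(codon, rng)
                if change is None:
                    continue  # e.g. TGG: no synonymous neighbour; try next codon
                pos, b = change
                syn_flag = True
                placed_syn += 1
            offset = 3 * ci + pos  # position within the coding strand
            if f.strand == "J":
                gpos = f.start + offset
                new_base = b
            else:
                gpos = f.stop - offset
                new_base = str(Seq(b).complement())
            old = seq_b[gpos - 1]
            seq_b[gpos - 1] = new_base
            truth.records.append(
                PlantedSNP(gene, gpos, old, new_base, syn_flag)
            )
        if placed_syn < n_syn:
            raise ValueError(
                f"{gene}: could not place {n_syn} synonymous SNPs "
                f"(only {placed_syn} synonymous sites found)"
            )
        truth.snps[gene] = n_snps
        truth.nonsyn[gene] = n_nonsyn
    genome_a = AnnotatedMitogenome(
        organism=template.organism + "-A",
        features=list(template.features),
        sequence=template.sequence,
    )
    genome_b = AnnotatedMitogenome(
        organism=template.organism + "-B",
        features=list(template.features),
        sequence="".join(seq_b),
    )
    return genome_a, genome_b, truth


# ---------------------------------------------------------------------------
# Climate stacks
# ---------------------------------------------------------------------------

#: plausible offsets/amplitudes cycled over variables so layers live on
#: different scales (temperature-like, precipitation-like, ...)
_VAR_OFFSETS = (15.0, 800.0, 25.0, 120.0, 5.0, 60.0)
_VAR_AMPLITUDES = (6.0, 300.0, 4.0, 45.0, 8.0, 20.0)


def simulate_climate_stack(
    n_vars: int = 6,
    nrows: int = 100,
    ncols: int = 100,
    smoothness: float = 3.0,
    correlation: Optional[np.ndarray] = None,
    seed: int = 0,
    gradient_scale: float = 0.2,
    nodata_fraction: float = 0.0,
    transform: GridTransform = GridTransform(30.0, -10.0, 0.05),
) -> ClimateStack:
    """Spatially autocorrelated, optionally cross-correlated layers.

    Each variable is a deterministic planar gradient (direction varying per
    variable, amplitude ``gradient_scale`` relative to the noise sd) plus
    Gaussian-smoothed noise (``smoothness`` = filter sigma in cells; 0 gives
    white noise).  ``correlation`` (n_vars x n_vars, positive semidefinite)
    sets the cross-variable correlation of the noise component; the smoothed
    fields are empirically whitened before mixing, so the realised noise
    correlations match the request up to the small gradient contribution.
    Layers are affinely mapped onto distinct plausible scales; models must
    be invariant to that choice.
    """
    if nrows < 10 or ncols < 10:
        raise ValueError("grid must be at least 10 x 10")
    rng = np.random.default_rng(seed)
    if correlation is None:
        target_chol = np.eye(n_vars)
    else:
        corr = np.asarray(correlation, dtype=float)
        if corr.shape != (n_vars, n_vars):
            raise ValueError("correlation matrix shape must be (n_vars, n_vars)")
        w, v = np.linalg.eigh((corr + corr.T) / 2)
        if w.min() < -1e-10:
            raise ValueError("correlation matrix is not positive semidefinite")
        # eigen square root tolerates semidefinite inputs
        target_chol = v @ np.diag(np.sqrt(np.clip(w, 0, None)))
    noise = rng.standard_normal((n_vars, nrows, ncols))
    if smoothness > 0:
        for v_i in range(n_vars):
            noise[v_i] = gaussian_filter(noise[v_i], sigma=smoothness, mode="reflect")
    # empirically whiten the smoothed fields, then mix to the target
    flat = noise.reshape(n_vars, -1)
    flat = flat - flat.mean(axis=1, keepdims=True)
    cov = flat @ flat.T / flat.shape[1]
    flat = np.linalg.solve(np.linalg.cholesky(cov), flat)
    flat = target_chol @ flat
    noise = flat.reshape(n_vars, nrows, ncols)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, nrows), np.linspace(-1, 1, ncols), indexing="ij"
    )
    grids = np.empty_like(noise)
    for v_i in range(n_vars):
        theta = 2 * np.pi * v_i / max(n_vars, 1)
        grad = np.cos(theta) * xx + np.sin(theta) * yy
        z = noise[v_i] + gradient_scale * grad
        off = _VAR_OFFSETS[v_i % len(_VAR_OFFSETS)]
        amp = _VAR_AMPLITUDES[v_i % len(_VAR_AMPLITUDES)]
        grids[v_i] = off + amp * z
    mask = np.ones((nrows, ncols), dtype=bool)
    if nodata_fraction > 0:
        n_bad = int(round(nodata_fraction * nrows * ncols))
        flat = rng.choice(nrows * ncols, size=n_bad, replace=False)
        mask.flat[flat] = False
        grids[:, ~mask] = np.nan
    names = [f"bio{i + 1}" for i in range(n_vars)]
    return ClimateStack(names, grids, transform, mask)


# ---------------------------------------------------------------------------
# Species from a known suitability surface
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTruth:
    """Gaussian response spec: S*(x) = exp(-sum_v (x_v - mu_v)^2 / (2 s_v^2))."""

    species: str
    response: dict[str, tuple[float, float]]  # var -> (optimum, breadth)
    n_presence: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for v, (_, s) in self.response.items():
            if s <= 0:
                raise ValueError(f"{v}: breadth must be positive")


def true_suitability(stack: ClimateStack, truth: SpeciesTruth) -> SuitabilityRaster:
    missing = [v for v in truth.response if v not in stack.names]
    if missing:
        raise ValueError(f"stack lacks response variables: {missing}")
    log_s = np.zeros(stack.shape)
    for var, (mu, sigma) in truth.response.items():
        g = stack.grid(var)
        log_s = log_s - (g - mu) ** 2 / (2 * sigma ** 2)
    s = np.where(stack.mask, np.exp(log_s), np.nan)
    return SuitabilityRaster(s, "rescaled01", stack.mask, stack.transform)


def simulate_species(
    stack: ClimateStack, truth: SpeciesTruth
) -> tuple[OccurrenceSet, SuitabilityRaster]:
    """Sample presence cells without replacement with probability ∝ S*.

    Returns cell-centre occurrence points and the true suitability surface
    (for recovery tests).  Raises if fewer cells than ``n_presence`` have
    positive suitability.
    """
    surface = true_suitability(stack, truth)
    rng = np.random.default_rng(truth.seed)
    cells = stack.valid_cells()
    s = surface.values[cells[:, 0], cells[:, 1]]
    positive = s > 0
    if positive.sum() < truth.n_presence:
        raise ValueError(
            f"only {int(positive.sum())} cells with positive suitability; "
            f"cannot place {truth.n_presence} presences"
        )
    p = np.where(positive, s, 0.0)
    p = p / p.sum()
    pick = rng.choice(len(cells), size=truth.n_presence, replace=False, p=p)
    chosen = cells[pick]
    lon = stack.transform.xllcorner + (chosen[:, 1] + 0.5) * stack.transform.cellsize
    lat = (
        stack.transform.yllcorner
        + (stack.nrows - 1 - chosen[:, 0] + 0.5) * stack.transform.cellsize
    )
    occ = OccurrenceSet(species=truth.species, points=np.stack([lon, lat], axis=1))
    return occ, surface
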