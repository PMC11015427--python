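"""Canonical end-to-end runs over the synthetic study system.

These functions wire the pipeline stages together under fixed study
conditions so the analysis drivers, the test suite and the reproduction
script all execute the same computations:

- :func:`mitogenome_feature_summary` — feature arithmetic on the bundled
  published Phthorimaea annotations;
- :func:`comparison_recovery` — planted-truth mitogenome pair comparison;
- :func:`sdm_recovery` — single-species model fit/evaluation against a
  known Gaussian response;
- :func:`two_species_consensus` — the full two-species ensemble, EI
  classification, overlap and niche-dynamics run.

Problem sizes: 100 x 100 grids with 6 variables and 2,000 background
points keep every run under a few seconds; the model-recovery fixture uses
600 presences (a realistic compendium-scale occurrence set for these
cosmopolitan pests) with a strong 2-variable Gaussian response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .annotation import (
    feature_length,
    load_reference_annotation,
    pcg_length_summary,
)
from .compare import snps_by_gene
from .evaluate import (
    classify_ei,
    consensus,
    evaluate_model,
    niche_dynamics,
    niche_overlap,
    permutation_importance,
)
from .raster import ClimateStack
from .sdm import (
    dedup_occurrences,
    fit_bioclim,
    fit_maxent,
    sample_background,
    train_test_split,
)
from .simulate import (
    SpeciesTruth,
    make_template_genome,
    simulate_climate_stack,
    simulate_mitogenome_pair,
    simulate_species,
)

#: planted per-gene (SNPs, non-synonymous) ledger used by the comparison runs
DEFAULT_TRUTH_SPEC = {"COI": (10, 2), "ND5": (5, 1), "ATP8": (4, 3), "COII": (0, 0)}

#: strong Gaussian response for the model-recovery fixture: optima near the
#: centre of the bio1/bio3 layers, breadths well inside the layer sd
RECOVERY_RESPONSE = {"bio1": (13.0, 1.6), "bio3": (24.0, 1.3)}
RECOVERY_N_PRESENCE = 600

#: partially overlapping two-species responses for the consensus/overlap run
SPECIES_A_RESPONSE = {"bio1": (13.0, 2.5), "bio3": (24.0, 2.0)}
SPECIES_B_RESPONSE = {"bio1": (16.0, 2.5), "bio3": (26.0, 2.0)}


def mitogenome_feature_summary() -> dict:
    """Feature arithmetic on the two published Phthorimaea annotations."""
    out = {}
    for species in ("P_absoluta", "P_operculella"):
        genome, report = load_reference_annotation(species)
        out[species] = {
            "genome_length_bp": genome.genome_length,
            "n_features": len(genome.features),
            "n_overlaps": report.n_overlaps,
            "overlaps": report.overlaps,
            "largest_spacer": report.largest_spacer(),
            "nd5_length_bp": feature_length(genome.feature("ND5")),
            "atp8_length_bp": feature_length(genome.feature("ATP8")),
            "pcg_lengths": pcg_length_summary(genome),
        }
    return out


def comparison_recovery(seed: int, truth_spec: dict | None = None) -> dict:
    """Simulate a mitogenome pair with planted truth and compare it back."""
    truth_spec = truth_spec or DEFAULT_TRUTH_SPEC
    template = make_template_genome(seed=seed)
    ga, gb, truth = simulate_mitogenome_pair(template, truth_spec, seed=seed)
    summaries = snps_by_gene(ga, gb)
    recovered = {s.gene: (s.snps, s.nonsyn) for s in summaries if s.gene in truth_spec}
    return {
        "planted": dict(truth_spec),
        "recovered": recovered,
        "exact": all(recovered.get(g) == v for g, v in truth_spec.items()),
        "summaries": summaries,
        "genomes": (ga, gb),
    }


@dataclass
class SdmRun:
    """One species' fitted models plus evaluation artefacts."""

    bioclim: object
    maxent: object
    bioclim_eval: object
    maxent_eval: object
    bioclim_rank_corr: float
    maxent_rank_corr: float
    occurrences: object
    train_points: np.ndarray
    test_points: np.ndarray
    background: np.ndarray
    true_surface: object
    stack: ClimateStack


def sdm_recovery(
    seed: int,
    stack: ClimateStack | None = None,
    response: dict | None = None,
    n_presence: int = RECOVERY_N_PRESENCE,
    n_background: int = 2000,
) -> SdmRun:
    """Fit and evaluate both models on a known Gaussian-response species.

    The 75/25 presence split, background sampling, model fits, held-out
    evaluation and whole-map Spearman correlation against the true
    suitability surface are all driven by ``seed``.
    """
    if stack is None:
        stack = simulate_climate_stack(seed=seed)
    response = response or RECOVERY_RESPONSE
    truth = SpeciesTruth("synthetic-species", response, n_presence=n_presence,
                         seed=seed)
    occ_raw, surface = simulate_species(stack, truth)
    occ = dedup_occurrences(occ_raw.points, stack, species=truth.species)
    train, test = train_test_split(occ, 0.75, seed=seed)
    bg = sample_background(stack, n=n_background, exclude=occ, seed=seed + 100)
    train_env = stack.extract(train.points)
    bg_env = stack.extract(bg)
    env = fit_bioclim(train_env, variables=stack.names)
    mx = fit_maxent(train_env, bg_env, variables=stack.names)
    ev_b = evaluate_model(env, stack, test.points, bg)
    ev_m = evaluate_model(mx, stack, test.points, bg)
    valid = stack.mask
    rc_b = float(spearmanr(env.predict(stack).values[valid],
                           surface.values[valid]).statistic)
    rc_m = float(spearmanr(mx.predict(stack).values[valid],
                           surface.values[valid]).statistic)
    return SdmRun(
        bioclim=env, maxent=mx, bioclim_eval=ev_b, maxent_eval=ev_m,
        bioclim_rank_corr=rc_b, maxent_rank_corr=rc_m,
        occurrences=occ, train_points=train.points, test_points=test.points,
        background=bg,
        true_surface=surface, stack=stack,
    )


def variable_importance(run: SdmRun, seed: int, repeats: int = 3) -> dict:
    """Permutation importance of the MaxEnt model from an :class:`SdmRun`."""
    return permutation_importance(
        run.maxent, run.stack, run.test_points, run.background,
        seed=seed, repeats=repeats,
    )


def two_species_consensus(
    seed: int,
    n_presence: int = 200,
    n_background: int = 2000,
    overlap_method: str = "min",
) -> dict:
    """Full ensemble run for two species with partially overlapping niches.

    For each species: fit BIOCLIM + MaxEnt, evaluate, and combine the
    (already [0,1]-scaled) predictions into an AUC-weighted consensus; then
    classify both consensus surfaces on the EI scale, compute the niche
    overlap, and the niche dynamics of species B's occupied environment
    relative to species A's.
    """
    stack = simulate_climate_stack(seed=seed)
    results: dict = {"stack": stack, "species": {}}
    responses = {"species_a": SPECIES_A_RESPONSE, "species_b": SPECIES_B_RESPONSE}
    env_samples = {}
    for i, (name, response) in enumerate(responses.items()):
        truth = SpeciesTruth(name, response, n_presence=n_presence,
                             seed=seed + 10 * i + 1)
        occ_raw, surface = simulate_species(stack, truth)
        occ = dedup_occurrences(occ_raw.points, stack, species=name)
        train, test = train_test_split(occ, 0.75, seed=seed + 10 * i + 2)
        bg = sample_background(stack, n=n_background, exclude=occ,
                               seed=seed + 10 * i + 3)
        train_env = stack.extract(train.points)
        env = fit_bioclim(train_env, variables=stack.names)
        mx = fit_maxent(train_env, stack.extract(bg), variables=stack.names)
        ev_b = evaluate_model(env, stack, test.points, bg)
        ev_m = evaluate_model(mx, stack, test.points, bg)
        cons = consensus(
            [env.predict(stack), mx.predict(stack)], [ev_b.auc, ev_m.auc]
        )
        results["species"][name] = {
            "occurrences": occ,
            "bioclim_auc": ev_b.auc,
            "maxent_auc": ev_m.auc,
            "consensus": cons,
            "ei": classify_ei(cons),
            "true_surface": surface,
        }
        env_samples[name] = stack.extract(occ.points)
    a = results["species"]["species_a"]["consensus"]
    b = results["species"]["species_b"]["consensus"]
    # mask at EI "high or better": continuous consensus surfaces are weakly
    # positive almost everywhere, so the marginal (>0) masks are degenerate
    results["overlap"] = niche_overlap(a, b, method=overlap_method, threshold=0.2)
    results["dynamics"] = niche_dynamics(
        env_samples["species_a"], env_samples["species_b"],
        stack.env_table(), bins=50,
    )
    return results
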