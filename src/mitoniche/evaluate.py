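"""Model evaluation, ensemble consensus and niche-overlap metrics.

Presence-only models are evaluated against background samples with the area
under the ROC curve (Mann-Whitney formulation: the probability a presence
site outscores a background site, ties counted half) and the point-biserial
correlation between scores and presence/background labels.  Variable
importance is measured by permutation: the mean AUC drop when one
variable's cell values are shuffled across valid cells.

The two-model ensemble is the AUC-weighted cell-wise average of the
rescaled member predictions.  The consensus surface is classified on the
ecoclimatic-index (EI) scale — unsuitable (0), marginal (0 < EI < 0.2),
high (0.2 <= EI < 0.5), optimal (EI >= 0.5) — and two species' consensus
surfaces are combined into overlap masks and niche
expansion/unfilling/stability fractions in binned environmental space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .raster import ClimateStack, SuitabilityRaster

logger = logging.getLogger(__name__)

EI_CLASSES = ("unsuitable", "marginal", "high", "optimal")


@dataclass
class ModelEvaluation:
    auc: float
    cor: float
    n_presence_test: int
    n_background: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must be in [0, 1]")
        if not -1.0 <= self.cor <= 1.0:
            raise ValueError("cor must be in [-1, 1]")


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """AUC as the Mann-Whitney pair statistic, ties counted 1/2."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score groups must be non-empty")
    ranks = rankdata(np.concatenate([sp, sb]))
    u = ranks[: sp.size].sum() - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


def point_biserial(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pearson correlation between scores and 0/1 presence labels."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both label classes must be present")
    if s.std() == 0:
        raise ValueError("undefined correlation: zero score variance")
    return float(np.corrcoef(s, y)[0, 1])


def evaluate_model(
    model,
    stack: ClimateStack,
    test_presence_points: np.ndarray,
    background_points: np.ndarray,
    **predict_kw,
) -> ModelEvaluation:
    """AUC + point-biserial correlation of a fitted model on held-out data."""
    pred = model.predict(stack, **predict_kw)
    sp = pred.at_points(np.atleast_2d(test_presence_points), stack)
    sb = pred.at_points(np.atleast_2d(background_points), stack)
    sp, sb = sp[~np.isnan(sp)], sb[~np.isnan(sb)]
    scores = np.concatenate([sp, sb])
    labels = np.concatenate([np.ones(sp.size), np.zeros(sb.size)])
    return ModelEvaluation(
        auc=auc(sp, sb),
        cor=point_biserial(scores, labels),
        n_presence_test=int(sp.size),
        n_background=int(sb.size),
    )


def permutation_importance(
    model,
    stack: ClimateStack,
    test_presence_points: np.ndarray,
    background_points: np.ndarray,
    seed: int = 0,
    repeats: int = 3,
    **predict_kw,
) -> dict:
    """Per-variable mean AUC drop under cell-value permutation.

    For each variable, its values across valid cells are shuffled (the rest
    of the stack untouched), the model re-projected, and the AUC recomputed;
    the drop from the baseline AUC, averaged over ``repeats`` shuffles, is
    the variable's importance.  Also returns contributions normalised to
    percentages (negative drops clipped to zero).
    """
    rng = np.random.default_rng(seed)
    base = evaluate_model(model, stack, test_presence_points, background_points,
                          **predict_kw).auc
    cells = stack.valid_cells()
    drops = {}
    for vi, name in enumerate(stack.names):
        ds = []
        for _ in range(repeats):
            grids = stack.grids.copy()
            vals = grids[vi, cells[:, 0], cells[:, 1]]
            grids[vi, cells[:, 0], cells[:, 1]] = rng.permutation(vals)
            shuffled = ClimateStack(stack.names, grids, stack.transform, stack.mask)
            a = evaluate_model(model, shuffled, test_presence_points,
                               background_points, **predict_kw).auc
            ds.append(base - a)
        drops[name] = float(np.mean(ds))
    clipped = np.array([max(d, 0.0) for d in drops.values()])
    total = clipped.sum()
    pct = clipped / total * 100.0 if total > 0 else np.zeros_like(clipped)
    return {
        "baseline_auc": base,
        "auc_drop": drops,
        "percent_contribution": dict(zip(drops, pct)),
    }


# ---------------------------------------------------------------------------
# Consensus and classification
# ---------------------------------------------------------------------------

def rescale01(r: SuitabilityRaster) -> SuitabilityRaster:
    """Min-max rescale valid cells to [0, 1]."""
    v = r.valid_values()
    lo, hi = np.nanmin(v), np.nanmax(v)
    if not np.isfinite(lo) or hi == lo:
        raise ValueError("undefined rescale: raster has < 2 distinct values")
    vals = (r.values - lo) / (hi - lo)
    return SuitabilityRaster(vals, "rescaled01", r.mask, r.transform)


@dataclass
class ConsensusSpec:
    """AUC-proportional weights for an ensemble of member models."""

    aucs: list[float]

    def __post_init__(self) -> None:
        a = np.asarray(self.aucs, dtype=float)
        if ((a <= 0) | (a > 1)).any():
            raise ValueError("member AUCs must lie in (0, 1]")

    @property
    def weights(self) -> np.ndarray:
        a = np.asarray(self.aucs, dtype=float)
        return a / a.sum()


def consensus(
    rasters: Sequence[SuitabilityRaster], aucs: Sequence[float]
) -> SuitabilityRaster:
    """AUC-weighted cell-wise average of member suitability rasters."""
    if len(rasters) != len(aucs) or not rasters:
        raise ValueError("need one AUC per member raster")
    shapes = {r.values.shape for r in rasters}
    if len(shapes) != 1:
        raise ValueError(f"member rasters disagree in shape: {shapes}")
    w = ConsensusSpec(list(aucs)).weights
    vals = sum(wi * r.values for wi, r in zip(w, rasters))
    return SuitabilityRaster(vals, "rescaled01", rasters[0].mask, rasters[0].transform)


@dataclass
class EIClassifiedRaster:
    """4-class ecoclimatic-index classification of a suitability surface."""

    classes: np.ndarray  # int grid, -1 invalid, 0..3 = EI_CLASSES
    thresholds: tuple[float, float]
    mask: np.ndarray
    labels: tuple[str, ...] = EI_CLASSES

    def fraction(self, label: str) -> float:
        code = self.labels.index(label)
        valid = self.classes[self.mask]
        return float((valid == code).mean())


def classify_ei(
    r: SuitabilityRaster, thresholds: tuple[float, float] = (0.2, 0.5)
) -> EIClassifiedRaster:
    """Classify EI values: 0 unsuitable, (0, t1) marginal, [t1, t2) high,
    [t2, 1] optimal.

    The published scale prints "<= 0.19" for marginal and "0.2-0.49" for
    high; for continuous values marginal is extended to the open interval
    (0, 0.2) so the classes partition [0, 1] with no gap.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2 <= 1:
        raise ValueError("thresholds must satisfy 0 < t1 < t2 <= 1")
    v = r.values
    valid = r.mask & ~np.isnan(v)
    vv = v[valid]
    if ((vv < 0) | (vv > 1)).any():
        raise ValueError("EI input values must lie in [0, 1]")
    cls = np.full(v.shape, -1, dtype=int)
    cls[valid] = 1  # marginal
    cls[valid & (v == 0)] = 0
    cls[valid & (v >= t1)] = 2
    cls[valid & (v >= t2)] = 3
    return EIClassifiedRaster(classes=cls, thresholds=(t1, t2), mask=valid)


# ---------------------------------------------------------------------------
# Niche overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    overlap_raster: SuitabilityRaster
    both_suitable: np.ndarray
    a_only: np.ndarray
    b_only: np.ndarray
    fractions: dict = field(default_factory=dict)


def niche_overlap(
    consensus_a: SuitabilityRaster,
    consensus_b: SuitabilityRaster,
    method: str = "min",
    threshold: float = 0.0,
) -> OverlapResult:
    """Shared-suitability surface and exclusive-area masks for two species.

    ``min``: cell-wise minimum of the two surfaces (continuous shared
    suitability).  ``subtract``: the combined equal-weight consensus minus
    each species' exclusive surplus — algebraically identical to ``min``
    since (a+b)/2 - (a-b)+/2 - (b-a)+/2 = min(a, b); kept as a named method
    because ensemble studies describe the operation this way.  ``binary``:
    only the threshold masks.  Suitability above ``threshold`` (default 0,
    i.e. EI class marginal or better) defines "suitable" for the masks; mask
    areal fractions are reported over valid cells.
    """
    a, b = consensus_a.values, consensus_b.values
    if a.shape != b.shape:
        raise ValueError("rasters disagree in shape")
    valid = consensus_a.mask & consensus_b.mask & ~np.isnan(a) & ~np.isnan(b)
    sa = valid & (a > threshold)
    sb = valid & (b > threshold)
    both = sa & sb
    a_only = sa & ~sb
    b_only = sb & ~sa
    if method in ("min", "binary"):
        shared = np.where(valid, np.minimum(a, b), np.nan)
    elif method == "subtract":
        comb = (a + b) / 2.0
        shared = comb - np.clip(a - comb, 0, None) - np.clip(b - comb, 0, None)
        shared = np.where(valid, shared, np.nan)
    else:
        raise ValueError(f"unknown overlap method {method!r}")
    if method == "binary":
        shared = np.where(valid, both.astype(float), np.nan)
    n_valid = int(valid.sum())
    fractions = {
        "both_suitable": float(both.sum()) / n_valid,
        "a_only": float(a_only.sum()) / n_valid,
        "b_only": float(b_only.sum()) / n_valid,
        "n_valid_cells": n_valid,
    }
    return OverlapResult(
        overlap_raster=SuitabilityRaster(
            shared, "rescaled01", valid, consensus_a.transform
        ),
        both_suitable=both,
        a_only=a_only,
        b_only=b_only,
        fractions=fractions,
    )


def niche_dynamics(
    env_native: np.ndarray,
    env_invaded: np.ndarray,
    env_available: np.ndarray,
    bins: int = 100,
) -> dict:
    """Niche expansion / unfilling / stability in environmental space.

    The available environment is reduced to its first two principal axes
    (standardised PCA) and binned ``bins x bins`` over the available range.
    Within analogous bins (those containing available environment), a bin is
    "occupied" by a range if it holds at least one of that range's samples:

    - expansion  = occupied-invaded-only bins / invaded-occupied bins;
    - stability  = bins occupied in both / invaded-occupied bins;
    - unfilling  = occupied-native-only bins / native-occupied bins.

    By construction ``expansion + stability == 1`` over the invaded-occupied
    analogous bins.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins per axis")
    avail = np.atleast_2d(np.asarray(env_available, dtype=float))
    nat = np.atleast_2d(np.asarray(env_native, dtype=float))
    inv = np.atleast_2d(np.asarray(env_invaded, dtype=float))
    mu, sd = avail.mean(axis=0), avail.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (avail - mu) / sd
    # principal axes of the available environment
    _, _, vt = np.linalg.svd(z - z.mean(axis=0), full_matrices=False)
    axes = vt[: min(2, vt.shape[0])].T

    def project(x: np.ndarray) -> np.ndarray:
        return ((x - mu) / sd) @ axes

    pa, pn, pi = project(avail), project(nat), project(inv)
    lo = pa.min(axis=0)
    hi = pa.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def bin_ids(p: np.ndarray) -> np.ndarray:
        ij = np.floor((p - lo) / span * bins).astype(int)
        ij = np.clip(ij, 0, bins - 1)
        return ij[:, 0] * bins + (ij[:, 1] if ij.shape[1] > 1 else 0)

    analogous = set(bin_ids(pa))
    occ_nat = set(bin_ids(pn)) & analogous
    occ_inv = set(bin_ids(pi)) & analogous
    if not analogous:
        raise ValueError("no analogous bins")
    if not occ_inv or not occ_nat:
        raise ValueError("a range has no occupied analogous bins")
    stability_bins = occ_nat & occ_inv
    expansion = len(occ_inv - occ_nat) / len(occ_inv)
    stability = len(stability_bins) / len(occ_inv)
    unfilling = len(occ_nat - occ_inv) / len(occ_nat)
    return {
        "expansion": expansion,
        "unfilling": unfilling,
        "stability": stability,
        "n_analogous_bins": len(analogous),
    }


def write_overlap_csv(result: OverlapResult, path) -> None:
    """Overlap summary: class areas in cells and as fractions."""
    n = result.fractions["n_valid_cells"]
    with open(path, "w") as fh:
        fh.write("mask,cells,fraction\n")
        for key, m in (
            ("both_suitable", result.both_suitable),
            ("a_only", result.a_only),
            ("b_only", result.b_only),
        ):
            fh.write(f"{key},{int(m.sum())},{result.fractions[key]:.6f}\n")
        fh.write(f"valid,{n},1.0\n")
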