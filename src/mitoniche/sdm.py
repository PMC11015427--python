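"""Presence-only species distribution models: BIOCLIM and MaxEnt.

Both models score every raster cell for climatic suitability from presence
records alone, contrasted against randomly sampled background
(pseudo-absence) cells.

BIOCLIM is a climate envelope: each cell is scored by how central its value
is within the presence sample's distribution of each variable, and the cell
takes the worst (minimum) variable score.  The percentile score used here is
two-tailed, ``s_v = min(1, 2 * min(P(X <= x), P(X >= x)))`` with X the
presence empirical distribution — 1 at the presence median, 0 outside the
presence min-max.  A rectangular mean +/- k*sd envelope mode is available.

MaxEnt estimates the Gibbs distribution p(x) ∝ exp(Σ_j λ_j f_j(x)) over
background cells whose feature expectations match the presence means up to
an L1 regularisation budget β_j per feature:

    max_λ  (1/n_p) Σ_presence λ·f(x)  -  log Z_bg(λ)  -  Σ_j β_j |λ_j|

Features are standardised linear and quadratic terms of each variable.  The
problem is convex; it is solved as a bound-constrained smooth program by
splitting λ into positive and negative parts, and at the optimum the KKT
conditions give the audit |E_p[f_j] - mean_presence[f_j]| <= β_j.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .raster import ClimateStack, SuitabilityRaster

logger = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """De-duplicated presence records for one species."""

    species: str
    points: np.ndarray  # (n, 2) of (longitude, latitude)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2:
            raise ValueError("points must be (n, 2) of (lon, lat)")

    def __len__(self) -> int:
        return len(self.points)


def dedup_occurrences(
    raw_points: np.ndarray,
    stack: ClimateStack,
    species: str = "species",
    one_per_cell: bool = False,
) -> OccurrenceSet:
    """Clean raw occurrence coordinates against a climate stack.

    Exact duplicate coordinates are removed; points falling off-grid or on
    nodata cells are dropped (counts logged); optionally the set is thinned
    to one record per raster cell.
    """
    pts = np.atleast_2d(np.asarray(raw_points, dtype=float))
    if not np.isfinite(pts).all():
        raise ValueError("occurrence coordinates must be finite")
    _, idx = np.unique(pts, axis=0, return_index=True)
    pts = pts[np.sort(idx)]
    n_dupes = len(raw_points) - len(pts)
    cells = stack.cell_of_points(pts)
    ok = stack.in_bounds(cells)
    ok[ok] &= stack.mask[cells[ok, 0], cells[ok, 1]]
    n_nodata = int((~ok).sum())
    pts, cells = pts[ok], cells[ok]
    if one_per_cell:
        _, idx = np.unique(cells, axis=0, return_index=True)
        keep = np.sort(idx)
        pts = pts[keep]
    if n_dupes or n_nodata:
        logger.info(
            "dedup_occurrences(%s): removed %d duplicates, %d nodata/off-grid",
            species, n_dupes, n_nodata,
        )
    if len(pts) == 0:
        raise ValueError("no usable occurrences after cleaning")
    return OccurrenceSet(species=species, points=pts)


def train_test_split(
    occ: OccurrenceSet, train_fraction: float = 0.75, seed: int = 0
) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Reproducible presence split; test size = floor(n * (1 - fraction))."""
    n = len(occ)
    if n < 4:
        raise ValueError("need at least 4 presence points to split")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(np.floor(n * (1 - train_fraction)))
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    return (
        OccurrenceSet(occ.species, occ.points[np.sort(train_idx)]),
        OccurrenceSet(occ.species, occ.points[np.sort(test_idx)]),
    )


def sample_background(
    stack: ClimateStack,
    n: int = 10000,
    exclude: Optional[OccurrenceSet] = None,
    seed: int = 0,
) -> np.ndarray:
    """Uniform sample of valid background cells, presence cells excluded.

    Returns (n, 2) cell-centre coordinates (lon, lat), sampled without
    replacement with a reproducible generator.
    """
    mask = stack.mask.copy()
    if exclude is not None and len(exclude):
        cells = stack.cell_of_points(exclude.points)
        ok = stack.in_bounds(cells)
        mask[cells[ok, 0], cells[ok, 1]] = False
    candidates = np.argwhere(mask)
    if len(candidates) < n:
        raise ValueError(
            f"insufficient background cells: requested {n}, only "
            f"{len(candidates)} valid after exclusion"
        )
    rng = np.random.default_rng(seed)
    pick = candidates[rng.choice(len(candidates), size=n, replace=False)]
    lon = stack.transform.xllcorner + (pick[:, 1] + 0.5) * stack.transform.cellsize
    lat = stack.transform.yllcorner + (stack.nrows - 1 - pick[:, 0] + 0.5) * stack.transform.cellsize
    return np.stack([lon, lat], axis=1)


# ---------------------------------------------------------------------------
# Occurrence CSV I/O (header: species,longitude,latitude)
# ---------------------------------------------------------------------------

def read_occurrences_csv(path) -> dict[str, OccurrenceSet]:
    """Read occurrences grouped by species from a CSV."""
    import csv

    by_species: dict[str, list[list[float]]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            by_species.setdefault(row["species"], []).append(
                [float(row["longitude"]), float(row["latitude"])]
            )
    return {
        sp: OccurrenceSet(species=sp, points=np.asarray(pts))
        for sp, pts in by_species.items()
    }


def write_occurrences_csv(sets: Sequence[OccurrenceSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("species,longitude,latitude\n")
        for occ in sets:
            for lon, lat in occ.points:
                fh.write(f"{occ.species},{lon:.6f},{lat:.6f}\n")


# ---------------------------------------------------------------------------
# BIOCLIM
# ---------------------------------------------------------------------------

@dataclass
class Envelope:
    """Per-variable presence summaries defining a climate envelope."""

    variables: list[str]
    samples: np.ndarray  # (n_presence, n_vars) sorted per column
    mean: np.ndarray
    sd: np.ndarray
    min: np.ndarray
    max: np.ndarray
    percentiles: dict[int, np.ndarray] = field(default_factory=dict)

    def to_json(self, path) -> None:
        obj = {
            "variables": self.variables,
            "samples": self.samples.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "min": self.min.tolist(),
            "max": self.max.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "Envelope":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            variables=obj["variables"],
            samples=np.asarray(obj["samples"]),
            mean=np.asarray(obj["mean"]),
            sd=np.asarray(obj["sd"]),
            min=np.asarray(obj["min"]),
            max=np.asarray(obj["max"]),
        )

    def predict(self, stack: ClimateStack, **kw) -> SuitabilityRaster:
        return predict_bioclim(self, stack, **kw)


def fit_bioclim(
    presence_env: np.ndarray, variables: Optional[Sequence[str]] = None
) -> Envelope:
    """Fit the envelope: store the presence sample's per-variable summaries."""
    x = np.atleast_2d(np.asarray(presence_env, dtype=float))
    if len(x) < 5:
        raise ValueError("need at least 5 presence points")
    if np.isnan(x).any():
        raise ValueError("presence environment contains missing values")
    if variables is None:
        variables = [f"var{i}" for i in range(x.shape[1])]
    sorted_samples = np.sort(x, axis=0)
    qs = {q: np.percentile(x, q, axis=0) for q in (5, 25, 50, 75, 95)}
    return Envelope(
        variables=list(variables),
        samples=sorted_samples,
        mean=x.mean(axis=0),
        sd=x.std(axis=0, ddof=1),
        min=x.min(axis=0),
        max=x.max(axis=0),
        percentiles=qs,
    )


def _tail_score(values: np.ndarray, sample: np.ndarray) -> np.ndarray:
    """Two-tailed envelope score of ``values`` against a sorted presence sample."""
    n = len(sample)
    le = np.searchsorted(sample, values, side="right") / n  # P(X <= x)
    lt = np.searchsorted(sample, values, side="left") / n   # P(X < x)
    ge = 1.0 - lt                                           # P(X >= x)
    s = 2.0 * np.minimum(le, ge)
    return np.clip(s, 0.0, 1.0)


def predict_bioclim(
    env: Envelope,
    stack: ClimateStack,
    mode: str = "percentile",
    k: float = 2.0,
) -> SuitabilityRaster:
    """Score every valid cell against the envelope (min over variables).

    ``mode="percentile"`` gives the graded two-tailed score; cells outside
    the presence min-max of any variable score 0.  ``mode="meansd"`` is the
    binary rectangular envelope mean +/- k*sd.
    """
    missing = [v for v in env.variables if v not in stack.names]
    if missing:
        raise ValueError(f"stack lacks envelope variables: {missing}")
    cells = stack.valid_cells()
    x = stack.subset(env.variables).values_at_cells(cells)  # (n_cells, n_vars)
    n_vars = len(env.variables)
    if mode == "percentile":
        score = np.ones(len(x))
        for j in range(n_vars):
            sj = _tail_score(x[:, j], env.samples[:, j])
            sj[(x[:, j] < env.min[j]) | (x[:, j] > env.max[j])] = 0.0
            score = np.minimum(score, sj)
    elif mode == "meansd":
        lo = env.mean - k * env.sd
        hi = env.mean + k * env.sd
        inside = (x >= lo) & (x <= hi)
        score = inside.all(axis=1).astype(float)
    else:
        raise ValueError(f"unknown bioclim mode {mode!r}")
    grid = np.full(stack.shape, np.nan)
    grid[cells[:, 0], cells[:, 1]] = score
    return SuitabilityRaster(grid, "rescaled01", stack.mask, stack.transform)


# ---------------------------------------------------------------------------
# MaxEnt
# ---------------------------------------------------------------------------

@dataclass
class FeatureMap:
    """Standardised linear + quadratic features of each variable."""

    variables: list[str]
    center: np.ndarray  # (n_features,)
    scale: np.ndarray
    clamp_lo: np.ndarray  # raw-feature clamp bounds from training background
    clamp_hi: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return [f"{v}" for v in self.variables] + [f"{v}^2" for v in self.variables]

    @property
    def n_features(self) -> int:
        return 2 * len(self.variables)

    def raw(self, env: np.ndarray) -> np.ndarray:
        env = np.atleast_2d(env)
        return np.concatenate([env, env ** 2], axis=1)

    def __call__(self, env: np.ndarray, clamp: bool = False) -> np.ndarray:
        f = self.raw(env)
        if clamp:
            n_out = int((f < self.clamp_lo).sum() + (f > self.clamp_hi).sum())
            if n_out:
                logger.info("maxent: clamped %d feature values to training range", n_out)
            f = np.clip(f, self.clamp_lo, self.clamp_hi)
        return (f - self.center) / self.scale


@dataclass
class MaxentModel:
    """Fitted maximum-entropy model (weights, regularisation, background)."""

    feature_map: FeatureMap
    weights: np.ndarray  # λ per feature
    beta: np.ndarray  # β per feature
    background_env: np.ndarray  # reference sample used for normalisation
    converged: bool = True
    final_grad_norm: float = 0.0
    n_iter: int = 0

    def linear_predictor(self, env: np.ndarray, clamp: bool = True) -> np.ndarray:
        return self.feature_map(env, clamp=clamp) @ self.weights

    def raw_at(self, env: np.ndarray) -> np.ndarray:
        """Background-normalised Gibbs density at arbitrary environments."""
        eta_bg = self.linear_predictor(self.background_env, clamp=False)
        log_z = logsumexp(eta_bg)
        return np.exp(self.linear_predictor(env) - log_z)

    def entropy(self) -> float:
        eta_bg = self.linear_predictor(self.background_env, clamp=False)
        log_p = eta_bg - logsumexp(eta_bg)
        return float(-np.sum(np.exp(log_p) * log_p))

    def predict(self, stack: ClimateStack, scale: str = "cloglog") -> SuitabilityRaster:
        return predict_maxent(self, stack, scale=scale)

    def to_json(self, path) -> None:
        obj = {
            "variables": self.feature_map.variables,
            "center": self.feature_map.center.tolist(),
            "scale": self.feature_map.scale.tolist(),
            "clamp_lo": self.feature_map.clamp_lo.tolist(),
            "clamp_hi": self.feature_map.clamp_hi.tolist(),
            "weights": self.weights.tolist(),
            "beta": self.beta.tolist(),
            "background_env": self.background_env.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "MaxentModel":
        with open(path) as fh:
            o = json.load(fh)
        fm = FeatureMap(
            o["variables"],
            np.asarray(o["center"]),
            np.asarray(o["scale"]),
            np.asarray(o["clamp_lo"]),
            np.asarray(o["clamp_hi"]),
        )
        return cls(fm, np.asarray(o["weights"]), np.asarray(o["beta"]),
                   np.asarray(o["background_env"]))


def build_feature_map(
    background_env: np.ndarray, variables: Sequence[str]
) -> FeatureMap:
    bg = np.atleast_2d(np.asarray(background_env, dtype=float))
    raw = np.concatenate([bg, bg ** 2], axis=1)
    center = raw.mean(axis=0)
    scale = raw.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FeatureMap(
        variables=list(variables),
        center=center,
        scale=scale,
        clamp_lo=raw.min(axis=0),
        clamp_hi=raw.max(axis=0),
    )


def fit_maxent(
    presence_env: np.ndarray,
    background_env: np.ndarray,
    variables: Optional[Sequence[str]] = None,
    beta_scale: float = 0.05,
    max_iter: int = 5000,
    tol: float = 1e-5,
) -> MaxentModel:
    """Fit the L1-regularised maximum-entropy model.

    ``beta_scale`` sets β_j = beta_scale * sd of feature j over presence
    points (floored to a small positive value for constant features), a
    scale-aware regularisation in the spirit of the reference software's
    defaults.  ``max_iter`` caps optimiser iterations and ``tol`` controls
    the stopping rule (projected-gradient norm, which bounds how far the
    fitted moments may drift beyond β).
    """
    pres = np.atleast_2d(np.asarray(presence_env, dtype=float))
    bg = np.atleast_2d(np.asarray(background_env, dtype=float))
    if len(pres) == 0 or len(bg) == 0:
        raise ValueError("presence and background must be non-empty")
    if np.isnan(pres).any() or np.isnan(bg).any():
        raise ValueError("missing values in environment matrices")
    if variables is None:
        variables = [f"var{i}" for i in range(pres.shape[1])]
    fmap = build_feature_map(bg, variables)
    if fmap.n_features < 2:
        raise ValueError("need at least 2 features")
    f_pres = fmap(pres)  # (n_p, k) standardised
    f_bg = fmap(bg)
    pres_mean = f_pres.mean(axis=0)
    beta = np.maximum(beta_scale * f_pres.std(axis=0, ddof=0), 1e-6)
    k = fmap.n_features

    def objective(uv: np.ndarray):
        lam = uv[:k] - uv[k:]
        eta = f_bg @ lam
        log_z = logsumexp(eta)
        p = np.exp(eta - log_z)
        e_bg = p @ f_bg
        # negative penalised log-likelihood (per presence point)
        val = log_z - lam @ pres_mean + beta @ (uv[:k] + uv[k:])
        g_lam = e_bg - pres_mean
        grad = np.concatenate([g_lam + beta, -g_lam + beta])
        return val, grad

    x0 = np.zeros(2 * k)
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * k),
        # ftol is effectively off; convergence is judged on the projected
        # gradient, whose sup-norm bounds the moment-condition slack
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": tol * 1e-2},
    )
    lam = res.x[:k] - res.x[k:]
    grad_norm = float(np.linalg.norm(res.jac)) if res.jac is not None else np.nan
    if not res.success:
        logger.warning(
            "maxent did not converge in %d iterations (grad norm %.3g)",
            max_iter, grad_norm,
        )
    return MaxentModel(
        feature_map=fmap,
        weights=lam,
        beta=beta,
        background_env=bg,
        converged=bool(res.success),
        final_grad_norm=grad_norm,
        n_iter=int(res.nit),
    )


def moment_condition_gaps(model: MaxentModel, presence_env: np.ndarray) -> np.ndarray:
    """|E_p[f_j] - presence mean f_j| per feature (audit: should be <= β_j)."""
    f_bg = model.feature_map(model.background_env, clamp=False)
    eta = f_bg @ model.weights
    p = np.exp(eta - logsumexp(eta))
    e_bg = p @ f_bg
    pres_mean = model.feature_map(np.atleast_2d(presence_env)).mean(axis=0)
    return np.abs(e_bg - pres_mean)


def predict_maxent(
    model: MaxentModel, stack: ClimateStack, scale: str = "cloglog"
) -> SuitabilityRaster:
    """Project the fitted model over a stack.

    ``raw`` values are the Gibbs density normalised over the model's
    background reference (they sum to 1 over those cells); ``cloglog``
    applies 1 - exp(-e^H * raw) with H the model entropy, mapping to [0, 1].
    Features outside the training range are clamped (logged).
    """
    cells = stack.valid_cells()
    env = stack.subset(model.feature_map.variables).values_at_cells(cells)
    raw = model.raw_at(env)
    if scale == "raw":
        vals = raw
    elif scale == "cloglog":
        vals = 1.0 - np.exp(-np.exp(model.entropy()) * raw)
        vals = np.clip(vals, 0.0, 1.0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    grid = np.full(stack.shape, np.nan)
    grid[cells[:, 0], cells[:, 1]] = vals
    return SuitabilityRaster(grid, scale, stack.mask, stack.transform)
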