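"""Genetic distances and principal coordinate ordination.

Distances between aligned nucleotide sequences are computed either
uncorrected (p-distance: proportion of differing sites) or corrected under
the Kimura 2-parameter model,

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q)),

with P and Q the proportions of transition- and transversion-differing
sites among comparable (non-gap, unambiguous) columns.  Group (species)
mean distances summarise a labelled matrix, and classical PCoA (cmdscale)
embeds it for ordination plots.

Ambiguity codes and gaps are removed pairwise (pairwise deletion), matching
common distance-software defaults.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """K2P distance undefined: log argument non-positive."""


@dataclass(frozen=True)
class SubstitutionCounts:
    """Transition/transversion proportions over comparable sites."""

    P: float
    Q: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError("require P >= 0, Q >= 0, P + Q <= 1")


def count_substitutions(a: str, b: str) -> SubstitutionCounts:
    """Classify differing sites into transitions and transversions.

    Columns where either sequence has a gap or an ambiguity code are
    excluded from the denominator (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in VALID or y not in VALID:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return SubstitutionCounts(P=ts / n, Q=tv / n, n_sites=n)


def p_distance(a: str, b: str) -> float:
    """Uncorrected proportion of differing sites (pairwise deletion)."""
    c = count_substitutions(a, b)
    return c.P + c.Q


def k2p_from_counts(P: float, Q: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("distance undefined (saturated)")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str, b: str) -> float:
    """Kimura 2-parameter corrected distance between aligned sequences."""
    c = count_substitutions(a, b)
    return k2p_from_counts(c.P, c.Q)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-sequence group labels."""

    labels: list[str]
    values: np.ndarray
    groups: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if self.groups is not None and len(self.groups) != n:
            raise ValueError("one group label per sequence required")

    def __len__(self) -> int:
        return len(self.labels)


def pairwise_distance_matrix(
    sequences: dict[str, str],
    groups: Optional[dict[str, str]] = None,
    metric: str = "k2p",
) -> DistanceMatrix:
    """All-pairs distance matrix over an aligned sequence set.

    ``metric`` is ``"k2p"`` (default: the methods name the Kimura
    2-parameter model) or ``"p"`` for the uncorrected distance.
    """
    fn = {"k2p": k2p_distance, "p": p_distance}[metric]
    labels = list(sequences)
    n = len(labels)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = fn(sequences[labels[i]], sequences[labels[j]])
    glist = [groups[l] for l in labels] if groups is not None else None
    return DistanceMatrix(labels=labels, values=m, groups=glist)


def group_mean_distances(m: DistanceMatrix) -> pd.DataFrame:
    """Species-by-species mean distances.

    Off-diagonal entries average all cross-group pairs; diagonal entries
    average within-group pairs (NaN for singleton groups).
    """
    if m.groups is None:
        raise ValueError("distance matrix carries no group labels")
    species = list(dict.fromkeys(m.groups))
    garr = np.asarray(m.groups)
    out = pd.DataFrame(index=species, columns=species, dtype=float)
    for i, gi in enumerate(species):
        ii = np.where(garr == gi)[0]
        for gj in species[i:]:
            jj = np.where(garr == gj)[0]
            if gi == gj:
                if len(ii) < 2:
                    val = np.nan
                    logger.warning("singleton group %r: within-group mean is NA", gi)
                else:
                    iu = np.triu_indices(len(ii), k=1)
                    val = m.values[np.ix_(ii, ii)][iu].mean()
            else:
                val = m.values[np.ix_(ii, jj)].mean()
            out.loc[gi, gj] = out.loc[gj, gi] = val
    return out


@dataclass
class OrdinationResult:
    """Classical-MDS embedding: points, eigenvalues, explained fractions."""

    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    explained: np.ndarray  # fraction of positive-eigenvalue sum per kept axis
    labels: Optional[list[str]] = None


def pcoa(m: DistanceMatrix, k: int = 2, eps: float = 1e-9) -> OrdinationResult:
    """Principal coordinate analysis (classical MDS / cmdscale).

    Double-centres ``-1/2 * J D^2 J``, eigendecomposes, and scales the
    eigenvectors of positive eigenvalues by sqrt(eigenvalue).  Negative
    eigenvalues (non-Euclidean input) are reported but never used; if ``k``
    exceeds the number of positive eigenvalues the embedding is truncated
    with a warning.
    """
    d = m.values
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > eps * max(abs(evals).max(), 1.0)).sum())
    if k > n_pos:
        logger.warning("pcoa: requested %d axes, only %d positive; truncated", k, n_pos)
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k]) if k else np.zeros((n, 0))
    pos_sum = evals[:n_pos].sum() if n_pos else 1.0
    explained = evals[:k] / pos_sum if k else np.zeros(0)
    return OrdinationResult(
        coordinates=coords, eigenvalues=evals, explained=explained, labels=m.labels
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_group_csv(path) -> dict[str, str]:
    """Sidecar CSV with columns ``id,species`` mapping sequences to groups."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = row["species"]
    return out


def write_distance_matrix(m: DistanceMatrix, path, fmt: str = "tsv") -> None:
    """Write a square TSV or PHYLIP-style distance matrix."""
    with open(path, "w") as fh:
        if fmt == "tsv":
            fh.write("\t" + "\t".join(m.labels) + "\n")
            for lab, row in zip(m.labels, m.values):
                fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
        elif fmt == "phylip":
            fh.write(f"{len(m)}\n")
            for lab, row in zip(m.labels, m.values):
                fh.write(f"{lab[:10]:<10}" + " ".join(f"{v:.6f}" for v in row) + "\n")
        else:
            raise ValueError(f"unknown format {fmt!r}")


def write_ordination(res: OrdinationResult, path) -> None:
    """CSV of coordinates plus an eigenvalue footer."""
    n, k = res.coordinates.shape
    labels = res.labels or [f"s{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("id," + ",".join(f"axis{i+1}" for i in range(k)) + "\n")
        for lab, row in zip(labels, res.coordinates):
            fh.write(lab + "," + ",".join(f"{v:.8f}" for v in row) + "\n")
        fh.write("# eigenvalues," + ",".join(f"{v:.8f}" for v in res.eigenvalues) + "\n")
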