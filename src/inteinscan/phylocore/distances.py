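"""Pairwise maximum-likelihood distances and patristic (tree-path) distances.

The ML distance between two aligned sequences maximises the likelihood of
the two-taxon tree, Sum_sites log(pi_a [P(t)]_ab) (summed over the model's
rate mixture), over the branch length t by bounded scalar optimisation with
a coarse bracketing grid.  Gapped columns are handled by pairwise deletion;
distances are capped at ``d_max`` (divergent pairs hit the cap and are
reported with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .models import N_STATES, SubstModel, encode_sequence

D_MAX = 15.0


class UndefinedDistanceError(ValueError):
    """No shared non-gap column between the two sequences."""


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon distances in substitutions/site."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(v, v.T, atol=1e-9) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        self.values = v
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, keep) -> "DistanceMatrix":
        keep = [t for t in self.taxa if t in set(keep)]
        idx = [self._index[t] for t in keep]
        return DistanceMatrix(keep, self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.taxa, columns=self.taxa).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(t) for t in df.index], df.values.astype(float))


def _pair_counts(s1: str, s2: str) -> np.ndarray:
    e1, e2 = encode_sequence(s1), encode_sequence(s2)
    if e1.shape != e2.shape:
        raise ValueError("sequences must have equal aligned length")
    keep = (e1 >= 0) & (e2 >= 0)
    if not keep.any():
        raise UndefinedDistanceError("no shared non-gap columns")
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (e1[keep], e2[keep]), 1.0)
    return counts


def _pair_lnl(counts: np.ndarray, model: SubstModel, t: float) -> float:
    P = model.transition_matrices(t)  # (ncat, 20, 20)
    w = model.category_weights
    mix = np.einsum("c,cab->ab", w, P)
    lik = model.frequencies[:, None] * np.maximum(mix, 1e-300)
    return float((counts * np.log(lik)).sum())


def ml_pairwise_distance(s1: str, s2: str, model: SubstModel, d_max: float = D_MAX) -> float:
    """ML branch length between two aligned sequences (pairwise deletion)."""
    counts = _pair_counts(s1, s2)
    if counts.sum() == np.trace(counts):  # identical over shared columns
        return 0.0
    neg = lambda t: -_pair_lnl(counts, model, t)
    # coarse log-grid bracket, then bounded Brent inside the bracketing cell
    grid = np.concatenate([[1e-8], np.geomspace(1e-4, d_max, 80)])
    vals = [neg(t) for t in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-6})
    t = float(res.x)
    return min(t, d_max)


def distance_matrix(data, model: SubstModel, d_max: float = D_MAX) -> DistanceMatrix:
    """All-pairs ML distances for a Partition or Alignment.

    Pairs with no shared columns are imputed at ``d_max`` with a warning, as
    are pairs whose estimate hits the cap.
    """
    if hasattr(data, "alignment"):
        data = data.alignment
    if hasattr(data, "ids"):
        taxa, rows = list(data.ids), data.rows
    else:
        taxa, rows = list(data), data
    n = len(taxa)
    out = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            d = ml_pairwise_distance(rows[taxa[i]], rows[taxa[j]], model, d_max)
        except UndefinedDistanceError:
            warnings.warn(
                f"no shared columns for ({taxa[i]}, {taxa[j]}); imputing d_max={d_max}"
            )
            d = d_max
        if d >= d_max:
            warnings.warn(f"distance for ({taxa[i]}, {taxa[j]}) capped at d_max={d_max}")
            d = d_max
        out[i, j] = out[j, i] = d
    return DistanceMatrix(taxa, out)


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Path-length (sum of branch lengths) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label)
    n = len(taxa)
    vals = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[i], taxa[j])
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix([t.label for t in taxa], vals)
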