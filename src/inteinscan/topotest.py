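"""Site-likelihood topology tests: KH, SH, and AU.

All three tests operate on a table of per-site log-likelihoods for a set of
candidate trees, resampling site contributions instead of re-optimising
trees (RELL).  The Kishino-Hasegawa test compares a pair of trees against
the centred bootstrap distribution of their likelihood difference; the
Shimodaira-Hasegawa test compares every tree against the best over a shared
centred replicate set; the approximately unbiased test fits the multiscale
bootstrap proportions BP(s) of a tree being best at several resampling
scales to the signed-distance/curvature form
``Phi^-1(1 - BP(s)) = d*sqrt(s) + c/sqrt(s)`` and reports
``p_AU = 1 - Phi(d - c)``.

A tree whose p-value falls below 0.05 is flagged as rejected from the 95%
confidence set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .phylocore.likelihood import EncodedData, PruningEngine
from .phylocore.models import SubstModel

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))
REJECTION_ALPHA = 0.05


@dataclass
class SiteLikTable:
    """Per-site log-likelihoods, one row per candidate tree."""

    tree_ids: list[str]
    values: np.ndarray            # (n_trees, n_sites)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != len(self.tree_ids):
            raise ValueError("values must be (n_trees, n_sites)")
        if not np.isfinite(v).all():
            raise ValueError("site log-likelihoods must be finite")
        self.values = v

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    def row(self, tree_id: str) -> np.ndarray:
        return self.values[self.tree_ids.index(tree_id)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.tree_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SiteLikTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.values.astype(float))


def rell_replicates(table: SiteLikTable, n_reps: int, scale: float = 1.0,
                    seed: int = 0) -> np.ndarray:
    """Per-tree sums of resampled site log-likelihoods; shape (n_trees, n_reps).

    Each replicate draws ``round(n_sites * scale)`` site indices with
    replacement; the same index draw is applied to every tree.
    """
    if table.values.size == 0:
        raise ValueError("empty site-likelihood table")
    if n_reps < 1 or scale <= 0:
        raise ValueError("n_reps >= 1 and scale > 0 required")
    n = table.n_sites
    m = max(int(round(n * scale)), 1)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_reps, m))
    out = np.empty((len(table.tree_ids), n_reps))
    for t in range(len(table.tree_ids)):
        out[t] = table.values[t][idx].sum(axis=1)
    return out


def kh_test(table: SiteLikTable, tree_a: str, tree_b: str,
            n_reps: int = 10_000, seed: int = 0) -> float:
    """One-sided KH p-value for the lower-likelihood tree of the pair."""
    la, lb = table.row(tree_a), table.row(tree_b)
    if np.array_equal(la, lb):
        return 1.0
    if la.sum() < lb.sum():        # orient so that a is the better tree
        la, lb = lb, la
    diff = la - lb
    d_obs = diff.sum()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(diff), size=(n_reps, len(diff)))
    reps = diff[idx].sum(axis=1)
    centered = reps - reps.mean()
    return float((centered >= d_obs).mean())


def sh_test(table: SiteLikTable, n_reps: int = 10_000, seed: int = 0) -> dict[str, float]:
    """Shimodaira-Hasegawa p-values for every tree in the table."""
    if len(table.tree_ids) < 2:
        raise ValueError("SH test needs at least 2 trees")
    totals = table.values.sum(axis=1)
    best = totals.max()
    reps = rell_replicates(table, n_reps, 1.0, seed)
    centered = reps - reps.mean(axis=1, keepdims=True)
    rep_max = centered.max(axis=0)
    out = {}
    for t, tid in enumerate(table.tree_ids):
        d_obs = best - totals[t]
        out[tid] = float(((rep_max - centered[t]) >= d_obs).mean())
    return out


def _bp_best(reps: np.ndarray) -> np.ndarray:
    """Per-tree fraction of replicates where it is best; exact ties split."""
    n_trees, n_reps = reps.shape
    mx = reps.max(axis=0)
    is_best = reps >= mx[None, :] - 1e-12
    share = is_best / is_best.sum(axis=0, keepdims=True)
    return share.sum(axis=1) / n_reps


@dataclass
class AUResult:
    p: float
    degenerate: bool
    d: float = np.nan
    c: float = np.nan


def au_test(table: SiteLikTable, scales=DEFAULT_SCALES,
            n_reps_per_scale: int = 10_000, seed: int = 0,
            full: bool = False) -> dict[str, float] | dict[str, AUResult]:
    """Approximately unbiased p-values from the multiscale bootstrap."""
    scales = tuple(scales)
    if len(table.tree_ids) < 2:
        raise ValueError("AU test needs at least 2 trees")
    if len(scales) < 5 or min(scales) >= 1.0 or max(scales) <= 1.0:
        raise ValueError("need >= 5 scales spanning values below and above 1")
    B = n_reps_per_scale
    bp = np.empty((len(scales), len(table.tree_ids)))
    for si, s in enumerate(scales):
        reps = rell_replicates(table, B, s, seed + si)
        bp[si] = _bp_best(reps)
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    bp_cl = np.clip(bp, lo, hi)
    sqrt_s = np.sqrt(np.asarray(scales))
    out: dict[str, AUResult] = {}
    for t, tid in enumerate(table.tree_ids):
        y = norm.ppf(1.0 - bp_cl[:, t])
        informative = (bp[:, t] > lo) & (bp[:, t] < hi)
        if informative.sum() < 3:
            # BP pinned at the clamp on (nearly) every scale: the tree is
            # always or never best, and the signed-distance fit is undefined
            p = hi if bp[:, t].mean() > 0.5 else lo
            out[tid] = AUResult(p=float(p), degenerate=True)
            continue
        # weighted LS with binomial variance of the probit-transformed BP,
        # using only scales with informative bootstrap proportions
        yk = y[informative]
        sk = sqrt_s[informative]
        bk = bp_cl[informative, t]
        var = bk * (1 - bk) / (B * norm.pdf(yk) ** 2)
        w = 1.0 / np.maximum(var, 1e-12)
        X = np.column_stack([sk, 1.0 / sk])
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ yk)
        d_hat, c_hat = beta
        out[tid] = AUResult(p=float(1.0 - norm.cdf(d_hat - c_hat)),
                            degenerate=False, d=float(d_hat), c=float(c_hat))
    if full:
        return out
    return {k: v.p for k, v in out.items()}


@dataclass
class TreeTestRow:
    tree_id: str
    lnl: float
    delta_lnl: float
    p_kh: float
    p_sh: float
    p_au: float
    au_degenerate: bool
    rejected: bool


@dataclass
class TopoTestResult:
    rows: list[TreeTestRow]
    n_reps: int
    scales: tuple
    seed: int
    best_tree: str = ""
    trees: dict = field(default_factory=dict)

    def row(self, tree_id: str) -> TreeTestRow:
        return next(r for r in self.rows if r.tree_id == tree_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def site_likelihood_table(data, model: SubstModel, trees: dict,
                          optimize: bool = True, bl_tol: float = 0.01
                          ) -> tuple[SiteLikTable, dict[str, float]]:
    """Optimise branch lengths per tree and collect per-site log-likelihoods."""
    enc = EncodedData(data)
    ids, rows, totals = [], [], {}
    for tid, tree in trees.items():
        eng = PruningEngine(tree, enc, model)
        if optimize:
            totals[tid] = eng.optimize_branch_lengths(tol=bl_tol)
        total, per_site = eng.lnl()
        totals[tid] = total
        ids.append(tid)
        rows.append(per_site)
    return SiteLikTable(ids, np.vstack(rows)), totals


def test_suite(data, model: SubstModel, hypothesis_trees: dict,
               n_reps: int = 10_000, scales=DEFAULT_SCALES,
               seed: int = 0, optimize: bool = True) -> TopoTestResult:
    """Run KH, SH and AU on a set of candidate trees for one partition.

    ``hypothesis_trees`` maps a hypothesis name to a tree sharing the
    partition's taxa.  Trees with ``p_AU < 0.05`` are flagged as rejected
    from the 95% confidence set.
    """
    table, totals = site_likelihood_table(data, model, hypothesis_trees,
                                          optimize=optimize)
    best_id = max(totals, key=totals.get)
    if len(table.tree_ids) == 1:
        p_sh = {best_id: 1.0}
        p_au = {best_id: AUResult(p=1.0, degenerate=True)}
    else:
        p_sh = sh_test(table, n_reps, seed)
        p_au = au_test(table, scales, n_reps, seed, full=True)
    rows = []
    for tid in table.tree_ids:
        p_kh = 1.0 if tid == best_id else kh_test(table, best_id, tid, n_reps, seed)
        au = p_au[tid]
        rows.append(TreeTestRow(
            tree_id=tid,
            lnl=totals[tid],
            delta_lnl=totals[best_id] - totals[tid],
            p_kh=p_kh,
            p_sh=p_sh[tid],
            p_au=au.p,
            au_degenerate=au.degenerate,
            rejected=au.p < REJECTION_ALPHA,
        ))
    return TopoTestResult(rows=rows, n_reps=n_reps, scales=tuple(scales),
                          seed=seed, best_tree=best_id, trees=dict(hypothesis_trees))
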