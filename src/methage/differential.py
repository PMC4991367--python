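"""Two-class differential methylation: rank product and lineage t-test.

The rank-product statistic works on per-pair beta *differences* rather than
ratios: beta values are bounded in [0, 1] and may be exactly zero, so
fold-changes are ill-defined on this scale. For every one of the n1 x n2
between-class sample pairs, probes are ranked by the difference (rank 1 = most
extreme in the tested direction, average ranks on ties) and the statistic is
the geometric mean of a probe's ranks across pairs, computed separately for
the hyper (class1 > class2) and hypo directions.

Significance comes from permutations that shuffle probe labels within each
*array* (sample) and recompute the pair differences and ranks. Shuffling per
sample, rather than per pair, keeps a probe's ranks correlated across the
pairs that share a sample — the correlation real data has under the null —
so the permutation distribution is calibrated even for unbalanced designs.
With the pooled null of ``n_permutations x n_probes`` rank products, ``p_g``
is the fraction of null values at or below the observed one, and the
percentage of false prediction pfp_g = p_g * n_probes / rank_g is the
rank-product analogue of the FDR. Tiny instances can enumerate all shuffle
combinations exhaustively instead of sampling.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import ReferencePanel

__all__ = ["rank_product_test", "call_ml_cpgs"]


def _pair_differences(beta: np.ndarray, idx1: np.ndarray, idx2: np.ndarray) -> np.ndarray:
    """probes x (n1*n2) matrix of class1-minus-class2 differences."""
    return (beta[:, idx1, None] - beta[:, None, idx2]).reshape(beta.shape[0], -1)


def _log_rank_products(
    values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(up, down) mean log ranks per probe over all between-class pairs.

    Rank 1 = most extreme in the tested direction, ties averaged. The down
    ranks follow from the up ranks: average ranks of mirrored orderings sum
    to m + 1 per entry.
    """
    diffs = _pair_differences(values, idx1, idx2)
    m = diffs.shape[0]
    r_up = stats.rankdata(-diffs, axis=0)
    return np.log(r_up).mean(axis=1), np.log(m + 1 - r_up).mean(axis=1)


def _null_log_rps_sampled(
    values: np.ndarray,
    idx1: np.ndarray,
    idx2: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled null: shuffle probe labels within each sample, re-rank pairs."""
    m, n = values.shape
    up = np.empty((n_permutations, m))
    down = np.empty((n_permutations, m))
    for b in range(n_permutations):
        # argsort of iid uniforms = a uniform random permutation per column
        perm = np.argsort(rng.random((m, n)), axis=0)
        shuffled = np.take_along_axis(values, perm, axis=0)
        up[b], down[b] = _log_rank_products(shuffled, idx1, idx2)
    return up.ravel(), down.ravel()


def _null_log_rps_exhaustive(
    values: np.ndarray, idx1: np.ndarray, idx2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """All (m!)^n_samples within-sample shuffles; feasible only for toy instances."""
    m, n = values.shape
    total = math.factorial(m) ** n
    if total > 200_000:
        raise ValueError(f"exhaustive enumeration infeasible: {total} shuffle combinations")
    perms = list(itertools.permutations(range(m)))
    up_pool, down_pool = [], []
    for combo in itertools.product(perms, repeat=n):
        shuffled = np.column_stack([values[list(p), j] for j, p in enumerate(combo)])
        up, down = _log_rank_products(shuffled, idx1, idx2)
        up_pool.append(up)
        down_pool.append(down)
    return np.concatenate(up_pool), np.concatenate(down_pool)


def _pooled_pvalues(observed: np.ndarray, null_pool: np.ndarray) -> np.ndarray:
    """P(null RP <= observed RP) against the pooled null distribution."""
    null_sorted = np.sort(null_pool)
    counts = np.searchsorted(null_sorted, observed + 1e-12, side="right")
    return counts / null_pool.size


def _pfp(pvals: np.ndarray, log_rp: np.ndarray) -> np.ndarray:
    """Percentage of false prediction: expected false positives / positives."""
    m = pvals.size
    order = np.argsort(log_rp, kind="stable")
    ranks = np.empty(m)
    ranks[order] = np.arange(1, m + 1)
    return np.minimum(pvals * m / ranks, 1.0)


def rank_product_test(
    beta: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 100,
    seed: int | None = None,
    class1: str | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Rank-product test of ``class1`` vs the other class, both directions.

    ``groups`` maps sample id to one of exactly two labels; ``class1``
    defaults to the lexicographically first label. Returns a table with
    rp_up/rp_down (geometric-mean ranks), permutation p-values, pfp estimates,
    mean beta difference and the called direction for the smaller pfp side.
    """
    groups = groups.loc[beta.columns]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two classes, got {labels}")
    c1 = class1 if class1 is not None else labels[0]
    c2 = [l for l in labels if l != c1][0]
    idx1 = np.where(groups.to_numpy() == c1)[0]
    idx2 = np.where(groups.to_numpy() == c2)[0]
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("each class needs at least 2 samples")
    if n_permutations < 1 and not exhaustive:
        raise ValueError("n_permutations must be >= 1")
    if seed is None and not exhaustive:
        raise ValueError("seed is mandatory for sampled permutations")

    values = beta.to_numpy(dtype=float)
    obs_up, obs_down = _log_rank_products(values, idx1, idx2)
    if exhaustive:
        null_up, null_down = _null_log_rps_exhaustive(values, idx1, idx2)
    else:
        rng = np.random.default_rng(seed)
        null_up, null_down = _null_log_rps_sampled(values, idx1, idx2, n_permutations, rng)
    out: dict[str, np.ndarray] = {}
    for direction, log_rp, pool in (("up", obs_up, null_up), ("down", obs_down, null_down)):
        p = _pooled_pvalues(log_rp, pool)
        out[f"rp_{direction}"] = np.exp(log_rp)
        out[f"p_{direction}"] = p
        out[f"pfp_{direction}"] = _pfp(p, log_rp)

    mean_diff = values[:, idx1].mean(axis=1) - values[:, idx2].mean(axis=1)
    up_wins = out["pfp_up"] <= out["pfp_down"]
    table = pd.DataFrame(
        {
            "direction": np.where(up_wins, 1, -1),
            "rp_up": out["rp_up"],
            "rp_down": out["rp_down"],
            "p": np.where(up_wins, out["p_up"], out["p_down"]),
            "p_up": out["p_up"],
            "p_down": out["p_down"],
            "fdr": np.where(up_wins, out["pfp_up"], out["pfp_down"]),
            "mean_diff": mean_diff,
        },
        index=beta.index,
    )
    table.attrs["class1"], table.attrs["class2"] = c1, c2
    return table


def call_ml_cpgs(panel: ReferencePanel, fdr: float = 0.05) -> pd.DataFrame:
    """Myeloid-vs-lymphoid differentially methylated probes by Welch t-test.

    Tests every probe across the panel's replicate profiles, adjusts with
    Benjamini-Hochberg, and returns the called probes with the signed
    myeloid-minus-lymphoid mean difference (direction +1 = hyper in myeloid).
    """
    lineage = panel.subtype_of.map(panel.lineage_of)
    mye = panel.profiles.loc[:, (lineage == "myeloid").to_numpy()]
    lym = panel.profiles.loc[:, (lineage == "lymphoid").to_numpy()]
    if mye.shape[1] < 2 or lym.shape[1] < 2:
        raise ValueError("need >=2 myeloid and >=2 lymphoid replicate profiles")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(mye, lym, axis=1, equal_var=False)
    mean_diff = mye.mean(axis=1) - lym.mean(axis=1)
    # zero variance in both groups: p is NaN; equal means carry no signal
    p = np.where(np.isnan(p), np.where(mean_diff.abs() > 0, 0.0, 1.0), p)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "direction": np.sign(mean_diff).astype(int),
            "p": p,
            "fdr": q,
            "mean_diff": mean_diff,
        },
        index=panel.profiles.index,
    )
    return table[table["fdr"] < fdr]
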