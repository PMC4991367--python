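"""Concordance and overlap statistics for signed CpG lists.

The central question: does a CpG list called in bulk whole blood (age- or
AD-associated) merely track the shifting myeloid:lymphoid ratio, or does it
reflect intrinsic methylation change? Each list carries a direction per probe
(+1/-1: sign of the age correlation, hyper/hypo in AD, or hyper/hypo in
myeloid vs lymphoid). Under every comparison mode a shared probe is
*concordant* when the two directions agree, so composition-driven signal shows
up as high concordance with the myeloid-lymphoid (ML) difference list —
especially at probes with large between-lineage differences.

Chance concordance is a fair coin per shared probe (p_e = 0.5), assessed with
the upper cumulative binomial tail; list overlap against a probe universe is
assessed with the hypergeometric upper tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceResult",
    "OverlapResult",
    "MODES",
    "binomial_tail",
    "hypergeometric_overlap",
    "classify_concordance",
    "concordance_by_difference_threshold",
    "filter_composition_concordant",
    "plot_threshold_curve",
]

#: comparison modes; all reduce to sign agreement under the direction semantics
MODES = ("age-age", "age-ml", "ad-ml", "ad-age")

_EXACT_K_LIMIT = 1000


@dataclass(frozen=True)
class ConcordanceResult:
    k: int  # shared probes
    s: int  # concordant among them
    rate: float  # s / k (nan when k == 0)
    p_value: float  # P(X >= s), X ~ Binomial(k, p_e)
    p_e: float
    mode: str


@dataclass(frozen=True)
class OverlapResult:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float  # hypergeometric upper tail P(X >= overlap)


def binomial_tail(s: int, k: int, p_e: float = 0.5) -> float:
    """Upper cumulative binomial tail P(X >= s) for X ~ Binomial(k, p_e).

    Exact rational arithmetic up to k = 1000; the scipy survival function
    (log-space internally) beyond that.
    """
    if not 0 <= s <= k:
        raise ValueError(f"require 0 <= s <= k, got s={s}, k={k}")
    if not 0.0 <= p_e <= 1.0:
        raise ValueError("p_e must be a probability")
    if s == 0:
        return 1.0
    if k <= _EXACT_K_LIMIT:
        pe = Fraction(p_e)
        tail = sum(
            Fraction(math.comb(k, i)) * pe**i * (1 - pe) ** (k - i) for i in range(s, k + 1)
        )
        return float(tail)
    return float(stats.binom.sf(s - 1, k, p_e))


def hypergeometric_overlap(N: int, K: int, n: int, k: int) -> OverlapResult:
    """Upper-tail hypergeometric test of an overlap of ``k`` between lists of
    sizes ``K`` and ``n`` drawn from a universe of ``N`` probes."""
    if K > N or n > N:
        raise ValueError("list sizes exceed the universe")
    if k > min(K, n) or k < 0:
        raise ValueError("overlap inconsistent with list sizes")
    if k == 0:
        p = 1.0
    elif N <= 30:
        # exact enumeration-free rational tail for small universes
        total = Fraction(math.comb(N, n))
        p = float(
            sum(
                Fraction(math.comb(K, i) * math.comb(N - K, n - i)) / total
                for i in range(k, min(K, n) + 1)
            )
        )
    else:
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return OverlapResult(universe=N, size_a=K, size_b=n, overlap=k, p_value=p)


def _as_direction_series(signed_list: pd.Series | dict) -> pd.Series:
    s = pd.Series(signed_list)
    if s.index.has_duplicates:
        raise ValueError("signed CpG list contains duplicate probes")
    if not s.isin([1, -1]).all():
        raise ValueError("directions must be +1 or -1")
    return s.astype(int)


def classify_concordance(
    list_a: pd.Series | dict,
    list_b: pd.Series | dict,
    mode: str = "age-ml",
    p_e: float = 0.5,
) -> ConcordanceResult:
    """Concordance rate s/k of two signed CpG lists and its binomial p-value.

    Under every mode a shared probe counts as concordant when the two signed
    directions agree; the mode label records which comparison is being made
    (two age lists, age vs myeloid-lymphoid, AD vs myeloid-lymphoid, AD vs
    age).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    a = _as_direction_series(list_a)
    b = _as_direction_series(list_b)
    shared = a.index.intersection(b.index)
    k = len(shared)
    if k == 0:
        logger.warning("lists share no probes; concordance rate undefined")
        return ConcordanceResult(k=0, s=0, rate=float("nan"), p_value=1.0, p_e=p_e, mode=mode)
    s = int((a[shared] == b[shared]).sum())
    return ConcordanceResult(
        k=k, s=s, rate=s / k, p_value=binomial_tail(s, k, p_e), p_e=p_e, mode=mode
    )


def concordance_by_difference_threshold(
    signed_list: pd.Series | dict,
    ml_table: pd.DataFrame,
    thresholds: list[float],
    mode: str = "age-ml",
) -> pd.DataFrame:
    """Concordance with the ML list restricted to ever-larger lineage differences.

    For each threshold t, the overlap is cut down to probes whose absolute
    myeloid-minus-lymphoid mean difference exceeds t (strict), and the
    surviving count and concordance rate are reported — the threshold-curve
    view of how composition-driven concordance grows with the between-lineage
    difference. ``ml_table`` needs ``direction`` and ``mean_diff`` columns.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        logger.warning("thresholds not ascending; sorting")
        thresholds = sorted(thresholds)
    a = _as_direction_series(signed_list)
    ml_dir = ml_table["direction"].astype(int)
    abs_diff = ml_table["mean_diff"].abs()
    rows = []
    for t in thresholds:
        surviving = ml_dir.index[abs_diff > t]
        res = classify_concordance(a, ml_dir[surviving], mode=mode)
        rows.append(
            {
                "threshold": t,
                "count": res.k,
                "concordant": res.s,
                "rate": res.rate,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def filter_composition_concordant(
    signed_list: pd.Series | dict, ml_list: pd.Series | dict
) -> pd.Series:
    """Drop probes whose direction agrees with the myeloid-lymphoid difference.

    A bulk age/AD probe that is also lineage-differential *in the same
    direction* is the signature of a composition-driven call; removing these
    leaves the candidates for intrinsic methylation change.
    """
    a = _as_direction_series(signed_list)
    ml = _as_direction_series(ml_list)
    shared = a.index.intersection(ml.index)
    concordant = shared[(a[shared] == ml[shared])]
    return a.drop(concordant)


def plot_threshold_curve(curve: pd.DataFrame, ax=None, title: str | None = None):
    """Bar/line view of a threshold curve: surviving counts and concordance rate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(curve["threshold"], curve["count"], width=0.8 * np.min(np.diff(curve["threshold"]))
           if len(curve) > 1 else 0.05, color="0.7", label="surviving CpGs")
    ax.set_xlabel("|myeloid − lymphoid| mean beta difference >")
    ax.set_ylabel("CpG count")
    ax2 = ax.twinx()
    ax2.plot(curve["threshold"], curve["rate"], "k--o", label="concordance rate")
    ax2.set_ylabel("concordance rate")
    ax2.set_ylim(0, 1.05)
    if title:
        ax.set_title(title)
    return ax
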