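"""Reference-based leukocyte deconvolution by nonnegative least squares.

Solves AX ~ B per bulk sample: A holds the subtype-mean beta profiles at the
marker loci, B the sample's betas, and X >= 0 the subtype proportions.
Markers are the loci most variable across subtype means. Raw weights are kept
as a quality metric (their sum should be near 1 for a genuine mixture) and
normalized to a probability vector for lineage aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "ProportionEstimate",
    "select_marker_loci",
    "estimate_proportions",
    "estimate_proportions_cohort",
    "aggregate_lineages",
    "correlate_proportions_age",
]


@dataclass
class ProportionEstimate:
    """Subtype weights for one bulk sample."""

    weights: pd.Series  # raw NNLS solution, >= 0
    normalized: pd.Series  # weights rescaled to sum to 1
    residual: float  # ||A x - b|| at the markers
    n_markers_used: int


def select_marker_loci(panel: ReferencePanel, n_markers: int = 500) -> list[str]:
    """Top ``n_markers`` probes by variance of the subtype-mean betas.

    Ties are broken by probe id (lexicographic) so the selection is
    deterministic regardless of input order.
    """
    means = panel.subtype_means()
    if n_markers > means.shape[0]:
        raise ValueError(f"n_markers={n_markers} exceeds {means.shape[0]} panel probes")
    variances = means.var(axis=1, ddof=1)
    if (variances == 0).all():
        logger.warning("all probes constant across subtypes; markers carry no signal")
    order = pd.DataFrame({"v": -variances, "id": variances.index.astype(str)})
    ranked = order.sort_values(["v", "id"], kind="stable")
    return ranked.index[:n_markers].tolist()


def estimate_proportions(
    sample_beta: pd.Series,
    panel: ReferencePanel,
    markers: list[str],
    max_missing: float = 0.10,
) -> ProportionEstimate:
    """Nonnegative least squares fit of one sample onto the reference panel.

    Markers missing in the sample are dropped with a warning when fewer than
    ``max_missing`` of them are missing, otherwise an error is raised.
    """
    means = panel.subtype_means()
    b = sample_beta.reindex(markers)
    missing = b.isna()
    if missing.any():
        rate = missing.mean()
        if rate >= max_missing:
            raise ValueError(f"{rate:.0%} of marker loci missing in sample (limit {max_missing:.0%})")
        logger.warning("dropping %d missing marker loci", int(missing.sum()))
        b = b[~missing]
    a = means.loc[b.index].to_numpy()
    x, residual = optimize.nnls(a, b.to_numpy())
    weights = pd.Series(x, index=means.columns, name="weight")
    total = weights.sum()
    normalized = weights / total if total > 0 else weights * np.nan
    return ProportionEstimate(
        weights=weights,
        normalized=normalized,
        residual=float(residual),
        n_markers_used=len(b),
    )


def aggregate_lineages(
    est: ProportionEstimate, panel: ReferencePanel
) -> tuple[float, float]:
    """(myeloid fraction, lymphoid fraction) of the normalized weights."""
    lineage = pd.Series({s: panel.lineage_of[s] for s in est.normalized.index})
    myeloid = float(est.normalized[lineage == "myeloid"].sum())
    lymphoid = float(est.normalized[lineage == "lymphoid"].sum())
    return myeloid, lymphoid


def estimate_proportions_cohort(
    beta: pd.DataFrame,
    panel: ReferencePanel,
    markers: list[str] | None = None,
    n_markers: int = 500,
) -> pd.DataFrame:
    """Per-sample proportion table: subtype weights, lineage fractions, residual."""
    if markers is None:
        markers = select_marker_loci(panel, n_markers)
    coverage = pd.Index(markers).isin(beta.index).mean()
    if coverage < 0.8:
        logger.warning("only %.0f%% of marker loci present in the bulk matrix", 100 * coverage)
    markers = [m for m in markers if m in beta.index]
    rows = []
    for sample in beta.columns:
        est = estimate_proportions(beta[sample], panel, markers)
        mye, lym = aggregate_lineages(est, panel)
        row = est.normalized.to_dict()
        row.update(
            myeloid=mye,
            lymphoid=lym,
            residual=est.residual,
            raw_sum=float(est.weights.sum()),
        )
        rows.append(row)
    return pd.DataFrame(rows, index=beta.columns)


def correlate_proportions_age(
    fractions: pd.DataFrame, ann: pd.DataFrame, lineages: tuple[str, ...] = ("myeloid", "lymphoid")
) -> pd.DataFrame:
    """Spearman rank correlation of each lineage fraction with age (two-sided)."""
    common = fractions.index.intersection(ann.index)
    if len(common) < 5:
        raise ValueError("need at least 5 samples for a rank correlation")
    age = ann.loc[common, "age"]
    rows = {}
    for lin in lineages:
        f = fractions.loc[common, lin]
        if f.nunique() <= 1:
            logger.warning("constant %s fractions: correlation undefined", lin)
            rows[lin] = {"r": np.nan, "p": np.nan, "n": len(common)}
            continue
        r, p = stats.spearmanr(f, age)
        rows[lin] = {"r": float(r), "p": float(p), "n": len(common)}
    return pd.DataFrame(rows).T
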