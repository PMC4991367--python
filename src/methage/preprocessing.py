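"""Quality control of Infinium-style beta matrices.

Fixed pipeline order: beta computation from intensities, sample-missingness
filter (strict >10%), k-nearest-neighbour imputation across probe rows (k=1),
iterative inter-array-correlation outlier removal (2 SD, 3 iterations), then
probe filtering (platform-shared set, X/Y drop). No normalization, detection
p-values or dye-bias correction are applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "EmptyResultError",
    "UnimputableProbeError",
    "compute_beta",
    "filter_samples_by_missingness",
    "impute_knn",
    "remove_outlier_samples",
    "filter_probes",
    "preprocess",
]


class EmptyResultError(RuntimeError):
    """A filter removed every sample (or probe)."""


class UnimputableProbeError(RuntimeError):
    """A probe row has no observed value to impute from."""


@dataclass
class QCReport:
    """Per-stage accounting of removed samples/probes and imputed cells."""

    removed_samples_missingness: list[str] = field(default_factory=list)
    removed_samples_outlier: list[list[str]] = field(default_factory=list)
    removed_probes: list[str] = field(default_factory=list)
    n_imputed: int = 0
    n_beta_undefined: int = 0

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            self.removed_samples_missingness + other.removed_samples_missingness,
            self.removed_samples_outlier + other.removed_samples_outlier,
            self.removed_probes + other.removed_probes,
            self.n_imputed + other.n_imputed,
            self.n_beta_undefined + other.n_beta_undefined,
        )

    def to_dict(self) -> dict:
        return {
            "removed_samples_missingness": self.removed_samples_missingness,
            "removed_samples_outlier": self.removed_samples_outlier,
            "removed_probes": self.removed_probes,
            "n_imputed": self.n_imputed,
            "n_beta_undefined": self.n_beta_undefined,
        }


def compute_beta(
    methylated: pd.DataFrame | np.ndarray | float,
    unmethylated: pd.DataFrame | np.ndarray | float,
) -> pd.DataFrame | np.ndarray | float:
    """Beta value max(M, 0) / (M + U + 100), elementwise.

    Negative intensities are allowed on input: the numerator is clamped at
    zero and entries whose denominator is non-positive (possible for very
    negative M) are marked missing.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if m.shape != u.shape:
        raise ValueError("methylated and unmethylated intensities are misaligned")
    denom = m + u + 100.0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, np.maximum(m, 0.0) / denom, np.nan)
    n_bad = int(np.sum(denom <= 0))
    if n_bad:
        logger.warning("beta undefined (denominator <= 0) for %d entries; set missing", n_bad)
    if isinstance(methylated, pd.DataFrame):
        return pd.DataFrame(beta, index=methylated.index, columns=methylated.columns)
    if np.isscalar(methylated) or beta.ndim == 0:
        return float(beta)
    return beta


def filter_samples_by_missingness(
    beta: pd.DataFrame, max_rate: float = 0.10
) -> tuple[pd.DataFrame, QCReport]:
    """Drop samples whose missing fraction is strictly greater than ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    rates = beta.isna().mean(axis=0)
    removed = rates.index[rates > max_rate].tolist()
    kept = beta.drop(columns=removed)
    if kept.shape[1] == 0:
        raise EmptyResultError("missingness filter removed every sample")
    return kept, QCReport(removed_samples_missingness=removed)


def _nearest_rows(values: np.ndarray, target: int, valid: np.ndarray) -> np.ndarray:
    """Indices of candidate rows ordered by Euclidean distance to ``target``.

    Distances use mutually observed columns only; rows with no shared observed
    column rank last. Ties keep row order (stable sort).
    """
    t = values[target]
    diff = values[valid] - t
    shared = ~np.isnan(diff)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d2 = np.nansum(diff**2, axis=1)
    d2[~shared.any(axis=1)] = np.inf
    dist = np.sqrt(d2)
    return valid[np.argsort(dist, kind="stable")]


def impute_knn(beta: pd.DataFrame, k: int = 1) -> tuple[pd.DataFrame, QCReport]:
    """Fill missing cells from the k nearest probe rows (default k=1).

    Nearness is Euclidean distance over mutually non-missing samples; for each
    missing cell the nearest rows that are observed at that sample supply the
    value (mean over the k nearest when k > 1).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = beta.to_numpy(dtype=float, copy=True)
    missing_rows = np.where(np.isnan(values).any(axis=1))[0]
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = beta.index[all_missing].tolist()
        raise UnimputableProbeError(f"probes with no observed value: {bad}")
    n_imputed = 0
    original = beta.to_numpy(dtype=float)  # donors are pre-imputation rows
    for i in missing_rows:
        candidates = np.where(~np.isnan(original).all(axis=1))[0]
        candidates = candidates[candidates != i]
        order = _nearest_rows(original, i, candidates)
        for j in np.where(np.isnan(original[i]))[0]:
            donors = order[~np.isnan(original[order, j])][:k]
            if donors.size == 0:
                raise UnimputableProbeError(
                    f"no donor row observed at sample {beta.columns[j]!r} "
                    f"for probe {beta.index[i]!r}"
                )
            values[i, j] = float(np.mean(original[donors, j]))
            n_imputed += 1
    return (
        pd.DataFrame(values, index=beta.index, columns=beta.columns),
        QCReport(n_imputed=n_imputed),
    )


def _mean_interarray_correlation(values: np.ndarray) -> np.ndarray:
    """Per-sample mean Pearson correlation with all other samples."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    if np.isnan(corr).any():
        logger.warning("constant sample column(s): undefined correlations treated as 0")
        corr = np.nan_to_num(corr, nan=0.0)
    n = corr.shape[0]
    return (corr.sum(axis=1) - np.diag(corr)) / (n - 1)


def remove_outlier_samples(
    beta: pd.DataFrame, sd_threshold: float = 2.0, n_iterations: int = 3
) -> tuple[pd.DataFrame, QCReport]:
    """Iteratively drop samples with anomalously low inter-array correlation.

    Each iteration computes every sample's mean Pearson correlation with the
    other samples (across all probes) and removes samples lying more than
    ``sd_threshold`` standard deviations *below* the mean of those means; only
    the low side is an outlier, since an above-mean sample is maximally
    typical. Stops early when an iteration removes nothing or fewer than three
    samples would remain.
    """
    if beta.shape[1] < 3:
        raise ValueError("outlier removal needs at least 3 samples")
    if beta.isna().any().any():
        raise ValueError("impute missing values before outlier removal")
    kept = beta
    report = QCReport()
    for _ in range(n_iterations):
        mean_corr = _mean_interarray_correlation(kept.to_numpy(dtype=float))
        mu, sd = mean_corr.mean(), mean_corr.std(ddof=0)
        removed = kept.columns[mean_corr < mu - sd_threshold * sd].tolist()
        if not removed:
            break
        if kept.shape[1] - len(removed) < 3:
            logger.warning("outlier removal stopped: fewer than 3 samples would remain")
            break
        report.removed_samples_outlier.append(removed)
        kept = kept.drop(columns=removed)
    return kept, report


def filter_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    shared_only: bool = True,
    drop_xy: bool = True,
    missing_annotation: str = "drop",
) -> tuple[pd.DataFrame, QCReport]:
    """Restrict to platform-shared autosomal probes.

    ``annotation`` must carry columns ``chromosome`` and ``shared_27k``
    indexed by probe id. Probes absent from the annotation are dropped with a
    warning by default (``missing_annotation='error'`` raises instead).
    """
    known = beta.index.isin(annotation.index)
    if not known.all():
        absent = beta.index[~known].tolist()
        if missing_annotation == "error":
            raise KeyError(f"probes absent from annotation: {absent[:5]}...")
        logger.warning("dropping %d probes absent from annotation", len(absent))
    ann = annotation.reindex(beta.index[known])
    keep = pd.Series(True, index=ann.index)
    if shared_only:
        keep &= ann["shared_27k"].astype(bool)
    if drop_xy:
        keep &= ~ann["chromosome"].astype(str).str.upper().isin(["X", "Y"])
    kept_ids = keep.index[keep]
    removed = beta.index.difference(kept_ids).tolist()
    kept = beta.loc[kept_ids]
    if kept.shape[0] == 0:
        raise EmptyResultError("probe filter removed every probe")
    return kept, QCReport(removed_probes=removed)


def preprocess(
    beta: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    max_missing_rate: float = 0.10,
    knn_k: int = 1,
    outlier_sd: float = 2.0,
    outlier_iterations: int = 3,
    shared_only: bool = True,
    drop_xy: bool = True,
) -> tuple[pd.DataFrame, QCReport]:
    """Full QC pipeline in the fixed order; returns matrix plus merged report."""
    beta, report = filter_samples_by_missingness(beta, max_missing_rate)
    beta, r = impute_knn(beta, knn_k)
    report = report.merge(r)
    beta, r = remove_outlier_samples(beta, outlier_sd, outlier_iterations)
    report = report.merge(r)
    if annotation is not None:
        beta, r = filter_probes(beta, annotation, shared_only=shared_only, drop_xy=drop_xy)
        report = report.merge(r)
    return beta, report
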