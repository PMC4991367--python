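"""Per-CpG age association by linear regression and cross-dataset integration.

Each probe's beta value is regressed on age plus optional covariates
(ordinary least squares, shared design matrix across probes, two-sided t-test
on the age coefficient). Benjamini-Hochberg adjustment is applied within each
dataset; an integration rule then combines per-dataset calls: significant
(q < 0.05) in at least one dataset, nominally significant (p < 0.05) in at
least one other, and never nominally significant with opposite directions in
two datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SingularDesignError",
    "build_design",
    "fit_age_model",
    "fit_age_models",
    "call_age_cpgs",
    "integrate_age_cpgs",
]


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


def build_design(ann: pd.DataFrame, covariate_names: list[str] | None = None) -> pd.DataFrame:
    """Design matrix [intercept, age, one-hot covariates], checked for full rank."""
    if "age" not in ann.columns:
        raise ValueError("sample annotation must contain an 'age' column")
    cols = {"intercept": np.ones(len(ann)), "age": ann["age"].to_numpy(dtype=float)}
    for name in covariate_names or []:
        col = ann[name]
        if pd.api.types.is_numeric_dtype(col):
            cols[name] = col.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
    design = pd.DataFrame(cols, index=ann.index)
    if np.var(design["age"]) == 0:
        raise ValueError("age has zero variance")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # near-zero diagonal of R in QR exposes columns dependent on earlier ones
        r = np.linalg.qr(design.to_numpy(), mode="r")
        dependent = design.columns[np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(r[0, 0]))]
        raise SingularDesignError(f"collinear design columns: {list(dependent)}")
    return design


@dataclass(frozen=True)
class AgeFit:
    slope: float
    direction: int
    p_value: float
    degenerate: bool = False


def _ols_age_stats(
    y: np.ndarray, design: np.ndarray, age_col: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each row of ``y`` on the shared design matrix.

    Returns (age slopes, two-sided p-values for the age coefficient).
    """
    n, p = design.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} samples for {p} design columns")
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = y @ design @ xtx_inv.T  # probes x p
    resid = y - coef @ design.T
    dof = n - p
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[age_col, age_col], 0.0))
    slope = coef[:, age_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, slope / se, 0.0)
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    # constant rows: no information about age
    const = np.ptp(y, axis=1) == 0
    slope[const], pval[const] = 0.0, 1.0
    return slope, pval


def fit_age_model(
    beta_row: pd.Series | np.ndarray,
    ann: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> AgeFit:
    """OLS fit of one probe's betas on age (+ covariates); two-sided age p-value."""
    design = build_design(ann, covariate_names)
    y = np.asarray(beta_row, dtype=float)[None, :]
    if y.shape[1] != design.shape[0]:
        raise ValueError("beta row and annotation have different sample counts")
    degenerate = bool(np.ptp(y) == 0)
    slope, pval = _ols_age_stats(y, design.to_numpy(), age_col=1)
    s = float(slope[0])
    return AgeFit(
        slope=s,
        direction=int(np.sign(s)) if s != 0 else 0,
        p_value=float(pval[0]),
        degenerate=degenerate,
    )


def fit_age_models(
    beta: pd.DataFrame,
    ann: pd.DataFrame,
    covariate_names: list[str] | None = None,
    dataset_id: str | None = None,
) -> pd.DataFrame:
    """Association table for every probe: slope, direction, p, BH q, n, dataset."""
    ann = ann.loc[beta.columns]
    design = build_design(ann, covariate_names)
    slope, pval = _ols_age_stats(beta.to_numpy(dtype=float), design.to_numpy(), age_col=1)
    q = multipletests(pval, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "slope": slope,
            "direction": np.sign(slope).astype(int),
            "p": pval,
            "q": q,
            "n": beta.shape[1],
            "dataset": dataset_id or "",
        },
        index=beta.index,
    )


def call_age_cpgs(table: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Probes significant after BH adjustment over all tested probes.

    The adjustment is recomputed from the raw p-values so the call is
    self-contained; values of the returned series are directions (+1/-1).
    """
    if table.empty:
        raise ValueError("association table is empty")
    q = multipletests(table["p"], method="fdr_bh")[1]
    called = table[q < fdr]
    return called["direction"].astype(int)


def integrate_age_cpgs(
    tables: list[pd.DataFrame], fdr: float = 0.05, nominal_p: float = 0.05
) -> pd.Series:
    """Combine per-dataset association tables into one reliable Age-CpG set.

    A probe is included iff it is FDR-significant (q < ``fdr``) in at least one
    dataset, nominally significant (p < ``nominal_p``) in at least one *other*
    dataset, and no two datasets call it nominally significant with opposite
    directions. Returns probe -> shared direction.
    """
    if len(tables) < 2:
        raise ValueError("integration requires at least two association tables")
    probes: pd.Index = tables[0].index
    for t in tables[1:]:
        probes = probes.union(t.index)

    q = pd.DataFrame({i: t["q"] for i, t in enumerate(tables)}).reindex(probes)
    p = pd.DataFrame({i: t["p"] for i, t in enumerate(tables)}).reindex(probes)
    d = pd.DataFrame({i: t["direction"] for i, t in enumerate(tables)}).reindex(probes)

    fdr_hit = (q < fdr).fillna(False)
    nominal = (p < nominal_p).fillna(False)
    # (a) FDR in >=1 and (b) nominal in >=1 *other* dataset
    support = fdr_hit.any(axis=1) & ((nominal & ~fdr_hit).any(axis=1) | (fdr_hit.sum(axis=1) >= 2))
    # (c) no direction conflict among nominally significant datasets
    dir_nominal = d.where(nominal)
    has_pos = (dir_nominal > 0).any(axis=1)
    has_neg = (dir_nominal < 0).any(axis=1)
    conflict = has_pos & has_neg
    n_conflict = int((support & conflict).sum())
    if n_conflict:
        logger.info("excluding %d probes with inconsistent directions across datasets", n_conflict)
    final = support & ~conflict
    direction = dir_nominal.where(dir_nominal.notna()).mean(axis=1)
    return np.sign(direction[final]).astype(int)
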