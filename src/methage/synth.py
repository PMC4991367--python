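"""Synthetic whole-blood methylation cohorts with known ground truth.

The generator emulates the structure of an Infinium-style beta-value study of
peripheral whole blood (PWB): a reference panel of purified leukocyte subtypes
(myeloid: monocytes, granulocytes, neutrophils; lymphoid: B, NK, T cells),
bulk mixtures whose myeloid:lymphoid ratio drifts linearly with age, probes
with intrinsic linear-in-age methylation changes, probes shifted in Alzheimer
(AD) samples, missing values and low-quality outlier arrays.

Composition-driven age (and AD) signal is *emergent*: at probes that differ
between the lineages, the bulk beta value tracks the drifting myeloid fraction
and therefore correlates with age without any intrinsic effect being planted.
This is exactly the confound the downstream concordance framework is built to
detect, so the planted age/AD/ML probe sets are kept disjoint.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ReferencePanel",
    "generate_reference_panel",
    "generate_mixture_cohort",
    "generate_probe_annotation",
    "generate_term_map",
    "write_beta_tsv",
    "read_beta_tsv",
]

#: Subtype composition of the purified-leukocyte reference set, with lineage tags.
DEFAULT_SUBTYPES: tuple[tuple[str, str], ...] = (
    ("monocytes", "myeloid"),
    ("granulocytes", "myeloid"),
    ("neutrophils", "myeloid"),
    ("B_cells", "lymphoid"),
    ("NK_cells", "lymphoid"),
    ("T_cells", "lymphoid"),
)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is degenerate or inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults are a desk-scale stand-in for a multi-cohort whole-blood aging
    study: 2000 probes, 120 bulk samples split over two datasets, an AD case/
    control cohort of 48 vs 9, and a six-subtype reference panel.
    """

    n_probes: int = 2000
    n_samples: int = 120
    subtype_names: tuple[tuple[str, str], ...] = DEFAULT_SUBTYPES
    n_replicates: int = 5
    age_range: tuple[float, float] = (20.0, 80.0)
    n_age_cpgs: int = 100
    age_slope_range: tuple[float, float] = (0.002, 0.004)
    n_ad_cpgs: int = 60
    ad_effect_range: tuple[float, float] = (0.05, 0.15)
    n_ml_cpgs: int = 200
    ml_diff_range: tuple[float, float] = (0.2, 0.6)
    #: subtype-specific signature loci (per subtype) that make the reference
    #: profiles identifiable below the lineage level
    n_subtype_cpgs: int = 30
    subtype_shift_range: tuple[float, float] = (0.3, 0.5)
    #: per-year increase of the expected myeloid fraction
    proportion_drift: float = 0.004
    #: expected myeloid fraction at the youngest age
    myeloid_base: float = 0.5
    #: Dirichlet concentration for realized subtype weights
    dirichlet_concentration: float = 200.0
    #: additional myeloid-fraction shift in AD samples
    ad_proportion_shift: float = 0.05
    #: fraction of AD-effect probes planted on age-effect probes, sign-matched
    ad_overlap_fraction: float = 0.4
    ad_fraction: float = 0.0
    n_datasets: int = 2
    noise_sd: float = 0.02
    missing_rate: float = 0.01
    n_outliers: int = 2
    seed: int = 0
    #: seed for the planted biology (which probes carry effects, their signs and
    #: sizes); cohorts sharing it share the same underlying effects while
    #: drawing independent samples. Defaults to ``seed``.
    effects_seed: int | None = None

    def validate(self) -> None:
        if self.n_probes <= 0 or self.n_samples <= 0:
            raise InvalidConfigError("n_probes and n_samples must be positive")
        if len(self.subtype_names) < 2:
            raise InvalidConfigError("need at least two leukocyte subtypes")
        lineages = {lin for _, lin in self.subtype_names}
        if not {"myeloid", "lymphoid"} <= lineages:
            raise InvalidConfigError("need at least one myeloid and one lymphoid subtype")
        if lineages - {"myeloid", "lymphoid"}:
            raise InvalidConfigError(f"unknown lineage tags: {lineages - {'myeloid', 'lymphoid'}}")
        n_planted = (
            self.n_age_cpgs
            + self.n_ad_cpgs
            + self.n_ml_cpgs
            + self.n_subtype_cpgs * len(self.subtype_names)
        )
        if n_planted > self.n_probes:
            raise InvalidConfigError("planted probe counts exceed n_probes")
        lo, hi = self.age_range
        if hi <= lo:
            raise InvalidConfigError("age_range must be increasing")
        for age in (lo, hi):
            m = self.expected_myeloid_fraction(age)
            if not 0.0 <= m <= 1.0:
                raise InvalidConfigError(
                    f"proportion_drift drives expected myeloid fraction to {m:.3f} "
                    f"at age {age:g}, outside [0, 1]"
                )
        if not 0.0 <= self.missing_rate < 1.0:
            raise InvalidConfigError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.ad_fraction <= 1.0:
            raise InvalidConfigError("ad_fraction must be in [0, 1]")

    def expected_myeloid_fraction(self, age: float) -> float:
        return self.myeloid_base + self.proportion_drift * (age - self.age_range[0])

    def probe_ids(self) -> pd.Index:
        width = len(str(self.n_probes))
        return pd.Index([f"cg{i:0{width}d}" for i in range(self.n_probes)], name="probe_id")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class ReferencePanel:
    """Purified leukocyte subtype beta profiles.

    ``profiles`` holds one column per replicate array; ``subtype_of`` maps the
    replicate column to its subtype and ``lineage_of`` maps subtype to lineage.
    """

    profiles: pd.DataFrame
    subtype_of: pd.Series
    lineage_of: dict[str, str]
    #: signed myeloid-minus-lymphoid mean difference of the planted ML probes
    ml_truth: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def subtype_means(self) -> pd.DataFrame:
        """Probes x subtypes matrix of replicate-mean betas (the A of AX~B)."""
        return self.profiles.T.groupby(self.subtype_of).mean().T

    def subtypes(self) -> list[str]:
        return list(dict.fromkeys(self.subtype_of))

    def lineage_members(self, lineage: str) -> list[str]:
        return [s for s in self.subtypes() if self.lineage_of[s] == lineage]


@dataclass
class GroundTruth:
    """What was planted, for parameter-recovery checks."""

    true_proportions: pd.DataFrame
    true_age_cpgs: pd.Series  # probe -> signed slope (beta/yr)
    true_ad_cpgs: pd.Series  # probe -> signed AD-vs-control beta shift
    true_ml_cpgs: pd.Series  # probe -> signed myeloid-minus-lymphoid difference
    outlier_samples: list[str]

    def myeloid_fraction(self, lineage_of: dict[str, str]) -> pd.Series:
        cols = [s for s in self.true_proportions.columns if lineage_of[s] == "myeloid"]
        return self.true_proportions[cols].sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_proportions": {
                s: self.true_proportions.loc[s].round(6).to_dict()
                for s in self.true_proportions.index
            },
            "true_age_cpgs": self.true_age_cpgs.to_dict(),
            "true_ad_cpgs": self.true_ad_cpgs.to_dict(),
            "true_ml_cpgs": self.true_ml_cpgs.to_dict(),
            "outlier_samples": list(self.outlier_samples),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _baseline_betas(rng: np.random.Generator, n: int) -> np.ndarray:
    # bimodal baseline typical of CpG methylation: most probes near 0 or 1
    return rng.beta(0.4, 0.4, size=n)


def generate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Simulate purified-subtype replicate profiles with planted lineage differences.

    The last ``n_ml_cpgs`` probes of the probe index get a signed
    myeloid-minus-lymphoid mean difference drawn from ``ml_diff_range``; all
    other probes share a common baseline across subtypes. Replicates add
    truncated Gaussian noise (sd ``noise_sd``) on the beta scale.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probes = config.probe_ids()
    subtypes = [name for name, _ in config.subtype_names]
    lineage_of = dict(config.subtype_names)

    base = _baseline_betas(rng, config.n_probes)
    mean_by_subtype = pd.DataFrame(
        np.tile(base[:, None], (1, len(subtypes))), index=probes, columns=subtypes
    )

    # planted probe blocks: [age | ad | ml | background], fixed layout
    ml_probes = probes[config.n_age_cpgs + config.n_ad_cpgs :][: config.n_ml_cpgs]
    lo, hi = config.ml_diff_range
    diffs = rng.uniform(lo, hi, size=len(ml_probes)) * rng.choice([-1.0, 1.0], len(ml_probes))
    centers = np.array([rng.uniform(abs(d) / 2, 1 - abs(d) / 2) for d in diffs])
    for subtype in subtypes:
        sign = 1.0 if lineage_of[subtype] == "myeloid" else -1.0
        mean_by_subtype.loc[ml_probes, subtype] = centers + sign * diffs / 2

    # subtype-specific signature loci: one subtype shifted against the rest
    tail = probes[config.n_age_cpgs + config.n_ad_cpgs + config.n_ml_cpgs :]
    lo, hi = config.subtype_shift_range
    for j, subtype in enumerate(subtypes):
        marks = tail[j * config.n_subtype_cpgs :][: config.n_subtype_cpgs]
        shifts = rng.uniform(lo, hi, size=len(marks))
        c = np.array([rng.uniform(0.05, 1 - 0.05 - s) for s in shifts])
        mean_by_subtype.loc[marks, :] = np.tile(c[:, None], (1, len(subtypes)))
        mean_by_subtype.loc[marks, subtype] = c + shifts

    columns, col_subtype = [], []
    blocks = []
    for subtype in subtypes:
        for r in range(config.n_replicates):
            columns.append(f"{subtype}_r{r + 1}")
            col_subtype.append(subtype)
            noise = rng.normal(0.0, config.noise_sd, size=config.n_probes)
            blocks.append(np.clip(mean_by_subtype[subtype].to_numpy() + noise, 0.0, 1.0))
    profiles = pd.DataFrame(np.column_stack(blocks), index=probes, columns=columns)
    return ReferencePanel(
        profiles=profiles,
        subtype_of=pd.Series(col_subtype, index=columns, name="subtype"),
        lineage_of=lineage_of,
        ml_truth=pd.Series(diffs, index=ml_probes, name="ml_diff"),
    )


def generate_mixture_cohort(
    panel: ReferencePanel, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate bulk whole-blood samples as subtype mixtures plus planted effects.

    Each sample's beta vector is ``profiles @ weights`` with Dirichlet-realized
    subtype weights centered on an age-linear expected myeloid fraction, plus
    intrinsic age slopes on the planted Age-CpGs, AD shifts on the planted
    AD-CpGs of AD-labelled samples, Gaussian noise, clipping to [0, 1],
    missingness, and ``n_outliers`` samples replaced by uniform-random betas.

    Returns (beta matrix probes x samples, sample annotation, ground truth).
    """
    config.validate()
    probes = config.probe_ids()
    if not probes.isin(panel.profiles.index).all():
        raise InvalidConfigError("panel does not cover the configured probe set")
    rng = np.random.default_rng(config.seed + 1)

    n = config.n_samples
    sample_ids = [f"s{i:04d}" for i in range(n)]
    ages = rng.uniform(*config.age_range, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    n_ad = int(round(config.ad_fraction * n))
    groups = np.array(["normal"] * n, dtype=object)
    if n_ad > 0:
        # age-matched case/control design: controls at centered, evenly spaced
        # positions of the age ordering so group labels are not confounded
        # with age (centering keeps the group age means aligned)
        n_ctrl = n - n_ad
        order = np.argsort(ages)
        pos = np.round((np.arange(n_ctrl) + 0.5) * n / n_ctrl - 0.5).astype(int) if n_ctrl else []
        pos = np.unique(np.clip(pos, 0, n - 1))
        free = [i for i in range(n) if i not in set(pos)]
        pos = np.sort(np.concatenate([pos, free[: n_ctrl - len(pos)]]).astype(int))
        is_ctrl = np.zeros(n, dtype=bool)
        is_ctrl[pos] = True
        groups[order] = np.where(is_ctrl, "control", "AD")
    datasets = np.array([f"ds{(i % config.n_datasets) + 1}" for i in range(n)])

    subtypes = panel.subtypes()
    myeloid = [s for s in subtypes if panel.lineage_of[s] == "myeloid"]
    lymphoid = [s for s in subtypes if panel.lineage_of[s] == "lymphoid"]

    weights = np.empty((n, len(subtypes)))
    for i in range(n):
        m = config.expected_myeloid_fraction(ages[i])
        if groups[i] == "AD":
            m = min(m + config.ad_proportion_shift, 1.0)
        expected = np.empty(len(subtypes))
        for j, s in enumerate(subtypes):
            expected[j] = m / len(myeloid) if s in myeloid else (1 - m) / len(lymphoid)
        alpha = np.maximum(expected * config.dirichlet_concentration, 1e-6)
        weights[i] = rng.dirichlet(alpha)

    mean_profiles = panel.subtype_means()[subtypes].loc[probes].to_numpy()
    beta = mean_profiles @ weights.T  # probes x samples

    # planted biology comes from the effects seed so that cohorts sharing it
    # carry the same slopes and AD effects at the same probes
    effects_seed = config.effects_seed if config.effects_seed is not None else config.seed
    fx = np.random.default_rng(effects_seed + 4)

    age_probes = probes[: config.n_age_cpgs]
    lo, hi = config.age_slope_range
    slopes = fx.uniform(lo, hi, config.n_age_cpgs) * fx.choice([-1.0, 1.0], config.n_age_cpgs)
    age_mid = np.mean(config.age_range)
    age_idx = probes.get_indexer(age_probes)
    beta[age_idx, :] += np.outer(slopes, ages - age_mid)

    ad_probes = probes[config.n_age_cpgs :][: config.n_ad_cpgs]
    lo, hi = config.ad_effect_range
    effects = fx.uniform(lo, hi, config.n_ad_cpgs) * fx.choice([-1.0, 1.0], config.n_ad_cpgs)
    # a configured fraction of AD effects sits on Age-CpG probes, sign-matched
    n_shared = int(round(config.ad_overlap_fraction * config.n_ad_cpgs))
    n_shared = min(n_shared, config.n_age_cpgs)
    if n_shared:
        shared = fx.choice(config.n_age_cpgs, size=n_shared, replace=False)
        ad_probe_list = list(age_probes[shared]) + list(ad_probes[: config.n_ad_cpgs - n_shared])
        effects[:n_shared] = np.abs(effects[:n_shared]) * np.sign(slopes[shared])
    else:
        ad_probe_list = list(ad_probes)
    ad_probes = pd.Index(ad_probe_list, name="probe_id")
    is_ad = groups == "AD"
    if is_ad.any():
        beta[probes.get_indexer(ad_probes)[:, None], np.where(is_ad)[0][None, :]] += effects[
            :, None
        ]

    beta += rng.normal(0.0, config.noise_sd, size=beta.shape)
    beta = np.clip(beta, 0.0, 1.0)

    outliers = list(rng.choice(sample_ids, size=min(config.n_outliers, n), replace=False))
    for sid in outliers:
        beta[:, sample_ids.index(sid)] = rng.uniform(0.0, 1.0, size=config.n_probes)

    if config.missing_rate > 0:
        mask = rng.random(beta.shape) < config.missing_rate
        beta = np.where(mask, np.nan, beta)

    beta_df = pd.DataFrame(beta, index=probes, columns=sample_ids)
    ann = pd.DataFrame(
        {"age": ages, "sex": sexes, "group": groups, "dataset": datasets},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        true_proportions=pd.DataFrame(weights, index=ann.index, columns=subtypes),
        true_age_cpgs=pd.Series(slopes, index=age_probes, name="slope"),
        true_ad_cpgs=pd.Series(effects, index=ad_probes, name="effect"),
        true_ml_cpgs=panel.ml_truth.copy(),
        outlier_samples=outliers,
    )
    return beta_df, ann, truth


def generate_probe_annotation(
    config: SimulationConfig,
    probes_per_gene: int = 2,
    xy_fraction: float = 0.05,
    unshared_fraction: float = 0.03,
) -> pd.DataFrame:
    """Probe -> gene / chromosome / platform annotation for the synthetic probes.

    Planted (leading) probes are kept autosomal and platform-shared so that the
    probe filter does not silently discard the ground truth; the X/Y and
    unshared flags are assigned to trailing background probes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    probes = config.probe_ids()
    n = config.n_probes
    genes = [f"GENE{i // probes_per_gene:04d}" for i in range(n)]
    chroms = [str(rng.integers(1, 23)) for _ in range(n)]
    shared = np.ones(n, dtype=int)

    n_planted = (
        config.n_age_cpgs
        + config.n_ad_cpgs
        + config.n_ml_cpgs
        + config.n_subtype_cpgs * len(config.subtype_names)
    )
    n_xy = int(xy_fraction * n)
    n_unshared = int(unshared_fraction * n)
    tail = rng.permutation(np.arange(n_planted, n))
    for i in tail[:n_xy]:
        chroms[i] = rng.choice(["X", "Y"])
    shared[tail[n_xy : n_xy + n_unshared]] = 0
    return pd.DataFrame(
        {"gene_ids": genes, "chromosome": chroms, "shared_27k": shared}, index=probes
    )


def generate_term_map(
    annotation: pd.DataFrame,
    truth: GroundTruth,
    n_terms: int = 20,
    term_size: int = 30,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Toy gene-set map: random terms plus one term enriched in planted genes."""
    rng = np.random.default_rng(seed + 3)
    genes = sorted(set(annotation["gene_ids"]))
    terms: dict[str, set[str]] = {}
    for t in range(n_terms):
        terms[f"T{t:03d}"] = set(rng.choice(genes, size=min(term_size, len(genes)), replace=False))
    planted_probes = truth.true_age_cpgs.index.union(truth.true_ad_cpgs.index)
    planted_genes = sorted(set(annotation.loc[annotation.index.isin(planted_probes), "gene_ids"]))
    picked = rng.choice(planted_genes, size=min(term_size, len(planted_genes)), replace=False)
    terms["T_planted"] = set(picked)
    return terms


def write_beta_tsv(beta: pd.DataFrame, path: str | Path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
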