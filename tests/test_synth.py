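"""The generator must honour its construction contracts and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methage import synth
from methage.synth import InvalidConfigError, SimulationConfig


class TestReferencePanel:
    def test_planted_ml_differences_exact_without_noise(self):
        cfg = SimulationConfig(n_probes=50, n_ml_cpgs=10, noise_sd=0.0, seed=3,
                               n_age_cpgs=0, n_ad_cpgs=0, n_subtype_cpgs=0)
        panel = synth.generate_reference_panel(cfg)
        means = panel.subtype_means()
        lineage = pd.Series({s: panel.lineage_of[s] for s in means.columns})
        mye = means.loc[:, (lineage == "myeloid").to_numpy()].mean(axis=1)
        lym = means.loc[:, (lineage == "lymphoid").to_numpy()].mean(axis=1)
        observed = (mye - lym).reindex(panel.ml_truth.index)
        np.testing.assert_allclose(observed, panel.ml_truth, atol=1e-12)
        # non-ML probes share a common baseline across lineages
        background = means.index.difference(panel.ml_truth.index)
        np.testing.assert_allclose(mye[background], lym[background], atol=1e-12)

    def test_replicates_identical_without_noise(self):
        cfg = SimulationConfig(n_probes=30, n_ml_cpgs=5, noise_sd=0.0, n_replicates=3, seed=1,
                               n_age_cpgs=0, n_ad_cpgs=0, n_subtype_cpgs=0)
        panel = synth.generate_reference_panel(cfg)
        for subtype in panel.subtypes():
            reps = panel.profiles.loc[:, (panel.subtype_of == subtype).to_numpy()]
            assert (reps.nunique(axis=1) == 1).all()

    def test_same_seed_identical_panel(self):
        cfg = SimulationConfig(n_probes=40, seed=11, n_age_cpgs=5, n_ad_cpgs=5,
                               n_ml_cpgs=5, n_subtype_cpgs=2)
        pd.testing.assert_frame_equal(
            synth.generate_reference_panel(cfg).profiles,
            synth.generate_reference_panel(cfg).profiles,
        )

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_probes": 0},
            {"subtype_names": (("monocytes", "myeloid"),)},
            {"subtype_names": (("a", "myeloid"), ("b", "myeloid"))},
            {"n_age_cpgs": 500, "n_probes": 100, "n_ad_cpgs": 0, "n_ml_cpgs": 0},
            {"proportion_drift": 0.02},  # 0.5 + 0.02*60 > 1
        ],
    )
    def test_degenerate_config_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            synth.generate_reference_panel(SimulationConfig(**bad))


class TestMixtureCohort:
    def test_single_subtype_noiseless_equals_profile(self):
        cfg = SimulationConfig(
            n_probes=20, n_samples=5,
            subtype_names=(("mono", "myeloid"), ("tcell", "lymphoid")),
            n_age_cpgs=0, n_ad_cpgs=0, n_ml_cpgs=0, n_subtype_cpgs=0,
            proportion_drift=0.0, myeloid_base=1.0, dirichlet_concentration=1e9,
            noise_sd=0.0, missing_rate=0.0, n_outliers=0, seed=5,
        )
        panel = synth.generate_reference_panel(cfg)
        beta, _, truth = synth.generate_mixture_cohort(panel, cfg)
        mono = panel.subtype_means()["mono"]
        for s in beta.columns:
            np.testing.assert_allclose(beta[s], mono, atol=1e-3)
        np.testing.assert_allclose(truth.true_proportions["mono"], 1.0, atol=1e-3)

    def test_planted_slope_shows_in_pairwise_beta_differences(self):
        # at a planted age probe (non-ML, so the mixture term is constant),
        # beta_i - beta_j = slope * (age_i - age_j) exactly when noise is off
        cfg = SimulationConfig(
            n_probes=30, n_samples=10, n_age_cpgs=3, n_ad_cpgs=0, n_ml_cpgs=0,
            n_subtype_cpgs=0,
            noise_sd=0.0, missing_rate=0.0, n_outliers=0, proportion_drift=0.0,
            dirichlet_concentration=1e9, seed=2,
        )
        panel = synth.generate_reference_panel(cfg)
        beta, ann, truth = synth.generate_mixture_cohort(panel, cfg)
        probe = truth.true_age_cpgs.index[0]
        slope = truth.true_age_cpgs.iloc[0]
        row = beta.loc[probe]
        interior = (row > 0) & (row < 1)  # clipping would break linearity
        samples = row.index[interior][:5]
        for i in samples:
            for j in samples:
                expected = slope * (ann.loc[i, "age"] - ann.loc[j, "age"])
                assert row[i] - row[j] == pytest.approx(expected, abs=1e-9)

    def test_myeloid_drift_correlates_with_age(self, small_cohort, small_panel):
        _, ann, truth = small_cohort
        mf = truth.myeloid_fraction(small_panel.lineage_of)
        r, p = stats.spearmanr(mf, ann["age"])
        assert r > 0 and p < 1e-6

    def test_values_in_unit_interval_and_missing_rate(self):
        cfg = SimulationConfig(n_probes=1000, n_samples=100, missing_rate=0.05, seed=9)
        panel = synth.generate_reference_panel(cfg)
        beta, _, _ = synth.generate_mixture_cohort(panel, cfg)
        values = beta.to_numpy()
        observed = values[~np.isnan(values)]
        assert observed.min() >= 0.0 and observed.max() <= 1.0
        assert np.isnan(values).mean() == pytest.approx(0.05, abs=0.02)

    def test_truth_ids_exist_and_planted_sets_disjoint(self, small_cohort):
        beta, ann, truth = small_cohort
        for ids in (truth.true_age_cpgs.index, truth.true_ad_cpgs.index,
                    truth.true_ml_cpgs.index):
            assert ids.isin(beta.index).all()
        assert set(truth.outlier_samples) <= set(beta.columns)
        # ML probes never overlap the intrinsic-effect probes
        assert not truth.true_ml_cpgs.index.intersection(truth.true_age_cpgs.index).size
        assert not truth.true_ml_cpgs.index.intersection(truth.true_ad_cpgs.index).size

    def test_weights_are_probability_vectors(self, small_cohort):
        _, _, truth = small_cohort
        w = truth.true_proportions.to_numpy()
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_same_seed_identical_cohort(self, small_config, small_panel):
        b1, a1, _ = synth.generate_mixture_cohort(small_panel, small_config)
        b2, a2, _ = synth.generate_mixture_cohort(small_panel, small_config)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(a1, a2)

    def test_shared_effects_seed_gives_same_planted_biology(self, small_config, small_panel):
        other = small_config.replace(seed=123, effects_seed=small_config.seed,
                                     n_samples=40, ad_fraction=0.5)
        _, _, t1 = synth.generate_mixture_cohort(small_panel, small_config)
        _, _, t2 = synth.generate_mixture_cohort(small_panel, other)
        pd.testing.assert_series_equal(t1.true_age_cpgs, t2.true_age_cpgs)
        pd.testing.assert_series_equal(t1.true_ad_cpgs, t2.true_ad_cpgs)

    def test_ad_labels_are_age_matched(self):
        cfg = SimulationConfig(n_probes=10, n_samples=57, ad_fraction=48 / 57,
                               n_age_cpgs=0, n_ad_cpgs=5, n_ml_cpgs=0,
                               n_subtype_cpgs=0, seed=4)
        panel = synth.generate_reference_panel(cfg)
        _, ann, _ = synth.generate_mixture_cohort(panel, cfg)
        assert (ann["group"] == "AD").sum() == 48
        mean_gap = ann[ann.group == "AD"]["age"].mean() - ann[ann.group == "control"]["age"].mean()
        assert abs(mean_gap) < 3.0  # years; matched design keeps means close


def test_probe_annotation_protects_planted_probes(small_config, small_cohort):
    ann = synth.generate_probe_annotation(small_config)
    _, _, truth = small_cohort
    planted = truth.true_age_cpgs.index.union(truth.true_ml_cpgs.index)
    assert (ann.loc[planted, "shared_27k"] == 1).all()
    assert (~ann.loc[planted, "chromosome"].isin(["X", "Y"])).all()
    assert ann["chromosome"].isin([str(c) for c in range(1, 23)] + ["X", "Y"]).all()


def test_beta_tsv_round_trip(tmp_path, toy_beta):
    toy_beta.iloc[0, 0] = np.nan
    toy_beta.index.name = "probe_id"
    path = tmp_path / "beta.tsv"
    synth.write_beta_tsv(toy_beta, path)
    back = synth.read_beta_tsv(path)
    pd.testing.assert_frame_equal(back, toy_beta)
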