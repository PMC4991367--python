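"""QC stages: beta arithmetic, filters, imputation, outlier removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methage import preprocessing as pp


class TestComputeBeta:
    @pytest.mark.parametrize(
        "m,u,expected",
        [(0, 0, 0.0), (900, 0, 0.9), (-50, 100, 0.0), (100, 100, 100 / 300)],
    )
    def test_known_values(self, m, u, expected):
        assert pp.compute_beta(m, u) == pytest.approx(expected)

    def test_nonpositive_denominator_marked_missing(self):
        m = pd.DataFrame([[-200.0, 50.0]], index=["cg1"], columns=["s1", "s2"])
        u = pd.DataFrame([[50.0, 50.0]], index=["cg1"], columns=["s1", "s2"])
        beta = pp.compute_beta(m, u)
        assert np.isnan(beta.iloc[0, 0])
        assert beta.iloc[0, 1] == pytest.approx(50 / 200)

    @given(
        m=st.floats(min_value=-1e6, max_value=1e6),
        u=st.floats(min_value=0, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_for_nonnegative_u(self, m, u):
        b = pp.compute_beta(m, u)
        if m + u + 100 > 0:
            assert 0.0 <= b <= 1.0
        else:  # undefined denominator is reported as missing
            assert np.isnan(b)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            pp.compute_beta(np.zeros((2, 2)), np.zeros((2, 3)))


class TestMissingnessFilter:
    def _matrix(self, missing_per_sample):
        n_probes = 100
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(
            rng.uniform(size=(n_probes, len(missing_per_sample))),
            columns=[f"s{i}" for i in range(len(missing_per_sample))],
        )
        for j, n_miss in enumerate(missing_per_sample):
            beta.iloc[:n_miss, j] = np.nan
        return beta

    def test_strictly_above_threshold_removed_at_exactly_retained(self):
        beta = self._matrix([11, 10, 0])
        kept, report = pp.filter_samples_by_missingness(beta, max_rate=0.10)
        assert report.removed_samples_missingness == ["s0"]
        assert list(kept.columns) == ["s1", "s2"]

    def test_no_missing_is_identity(self, toy_beta):
        kept, report = pp.filter_samples_by_missingness(toy_beta)
        pd.testing.assert_frame_equal(kept, toy_beta)
        assert report.removed_samples_missingness == []

    def test_all_samples_removed_raises(self):
        beta = self._matrix([50, 60])
        with pytest.raises(pp.EmptyResultError):
            pp.filter_samples_by_missingness(beta, max_rate=0.10)


class TestKnnImputation:
    def test_fill_from_identical_row(self):
        beta = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.1, 0.2, np.nan]],
            index=["a", "b"], columns=["s1", "s2", "s3"],
        )
        out, report = pp.impute_knn(beta, k=1)
        assert out.loc["b", "s3"] == pytest.approx(0.3)
        assert report.n_imputed == 1

    def test_no_missing_is_identity(self, toy_beta):
        out, report = pp.impute_knn(toy_beta)
        pd.testing.assert_frame_equal(out, toy_beta)
        assert report.n_imputed == 0

    def test_matches_brute_force_nearest_row(self):
        rng = np.random.default_rng(42)
        beta = pd.DataFrame(
            rng.uniform(size=(12, 6)),
            index=[f"cg{i}" for i in range(12)],
            columns=[f"s{i}" for i in range(6)],
        )
        holes = [(0, 2), (3, 5), (7, 0), (7, 1)]
        for i, j in holes:
            beta.iloc[i, j] = np.nan
        out, _ = pp.impute_knn(beta, k=1)
        raw = beta.to_numpy()
        for i, j in holes:
            # oracle: scan every donor row observed at column j, Euclidean
            # distance over mutually observed columns
            best, best_d = None, np.inf
            for r in range(raw.shape[0]):
                if r == i or np.isnan(raw[r, j]):
                    continue
                shared = ~np.isnan(raw[i]) & ~np.isnan(raw[r])
                if not shared.any():
                    continue
                d = np.sqrt(np.sum((raw[i, shared] - raw[r, shared]) ** 2))
                if d < best_d:
                    best, best_d = r, d
            assert out.iloc[i, j] == pytest.approx(raw[best, j])

    def test_fully_missing_probe_raises(self):
        beta = pd.DataFrame([[np.nan, np.nan], [0.1, 0.2]], columns=["s1", "s2"])
        with pytest.raises(pp.UnimputableProbeError):
            pp.impute_knn(beta)


class TestOutlierRemoval:
    def test_uniform_random_sample_removed_first_iteration(self):
        # ten tight replicates + one uniform-random array; with so few samples
        # the outlier itself inflates the SD of the mean correlations, so a
        # handful of clean arrays are needed before the 2-SD rule can bite
        rng = np.random.default_rng(1)
        base = rng.uniform(0.1, 0.9, size=200)
        cols = {f"s{i}": np.clip(base + rng.normal(0, 0.01, 200), 0, 1) for i in range(10)}
        cols["weird"] = rng.uniform(size=200)
        beta = pd.DataFrame(cols)
        kept, report = pp.remove_outlier_samples(beta)
        assert report.removed_samples_outlier[0] == ["weird"]
        assert "weird" not in kept.columns

    def test_identical_nonconstant_samples_never_removed(self):
        col = np.linspace(0.1, 0.9, 50)
        beta = pd.DataFrame({f"s{i}": col for i in range(5)})
        kept, report = pp.remove_outlier_samples(beta)
        assert kept.shape[1] == 5
        assert report.removed_samples_outlier == []

    def test_idempotent_on_clean_matrix(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(0.2, 0.8, 300)
        beta = pd.DataFrame(
            {f"s{i}": base + rng.normal(0, 0.005, 300) for i in range(10)}
        )
        _, report = pp.remove_outlier_samples(beta, n_iterations=3)
        # whatever iteration 1 does, later iterations on tight replicates stop
        assert len(report.removed_samples_outlier) <= 1

    def test_requires_three_samples_and_no_missing(self, toy_beta):
        with pytest.raises(ValueError):
            pp.remove_outlier_samples(toy_beta.iloc[:, :2])
        holed = toy_beta.copy()
        holed.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            pp.remove_outlier_samples(holed)


class TestProbeFilter:
    @pytest.fixture()
    def annotation(self):
        return pd.DataFrame(
            {
                "gene_ids": [f"G{i}" for i in range(10)],
                "chromosome": ["1", "2", "X", "Y", "3", "4", "5", "6", "7", "8"],
                "shared_27k": [1, 1, 1, 1, 0, 1, 1, 1, 1, 1],
            },
            index=[f"cg{i}" for i in range(10)],
        )

    def test_hand_counted_toy(self, annotation):
        rng = np.random.default_rng(0)
        beta = pd.DataFrame(rng.uniform(size=(10, 3)), index=annotation.index)
        kept, report = pp.filter_probes(beta, annotation, shared_only=True, drop_xy=True)
        assert kept.shape[0] == 7  # 10 - 2 on X/Y - 1 unshared
        assert set(report.removed_probes) == {"cg2", "cg3", "cg4"}

    def test_flags_independent(self, annotation):
        beta = pd.DataFrame(np.full((10, 2), 0.5), index=annotation.index)
        kept_xy, _ = pp.filter_probes(beta, annotation, shared_only=False, drop_xy=True)
        assert "cg2" not in kept_xy.index and "cg4" in kept_xy.index
        kept_sh, _ = pp.filter_probes(beta, annotation, shared_only=True, drop_xy=False)
        assert "cg2" in kept_sh.index and "cg4" not in kept_sh.index

    def test_unannotated_probe_dropped_or_error(self, annotation):
        beta = pd.DataFrame(np.full((2, 2), 0.5), index=["cg0", "novel"])
        kept, _ = pp.filter_probes(beta, annotation)
        assert list(kept.index) == ["cg0"]
        with pytest.raises(KeyError):
            pp.filter_probes(beta, annotation, missing_annotation="error")


def test_preprocess_accounts_for_every_removal(small_cohort, small_config):
    from methage import synth

    beta, _, truth = small_cohort
    annotation = synth.generate_probe_annotation(small_config)
    clean, report = pp.preprocess(beta, annotation)
    assert not clean.isna().any().any()
    removed_samples = set(report.removed_samples_missingness) | {
        s for it in report.removed_samples_outlier for s in it
    }
    assert removed_samples.isdisjoint(clean.columns)
    assert set(report.removed_probes).isdisjoint(clean.index)
    assert len(clean.columns) + len(removed_samples) == beta.shape[1]
    assert len(clean.index) + len(report.removed_probes) == beta.shape[0]
    # the uniform-random outlier samples are caught by the correlation screen
    assert set(truth.outlier_samples) <= removed_samples
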