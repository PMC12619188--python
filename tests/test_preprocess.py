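"""QC filtering, imputation, transforms, PCA and merging behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gdmetab.preprocess import (
    PreprocessConfig,
    apply_rsd_filter,
    compute_rsd,
    filter_missingness,
    impute_half_min,
    log1p_transform,
    merge_datasets,
    preprocess_dataset,
    run_pca,
    standardize,
)
from tests.conftest import make_matrix


def qc_matrix(qc_cols, bio_rows=3):
    """Matrix with given per-metabolite QC triples plus constant bio rows."""
    qc = np.asarray(qc_cols, dtype=float).T  # rows = QC injections
    bio = np.full((bio_rows, qc.shape[1]), 5.0)
    vals = np.vstack([bio, qc])
    n = vals.shape[0]
    return make_matrix(
        vals,
        is_qc=[False] * bio_rows + [True] * qc.shape[0],
        labels=[0.0, 1.0] * (bio_rows // 2) + [0.0] * (bio_rows % 2) + [np.nan] * qc.shape[0],
    )


class TestRSD:
    def test_zero_variance_gives_zero(self):
        rep = compute_rsd(qc_matrix([[10, 10, 10]]))
        assert rep.rsd.iloc[0] == 0.0

    def test_analytic_value(self):
        # sd(8,10,12)=2, mean=10 -> exactly 20%
        rep = compute_rsd(qc_matrix([[8, 10, 12]]))
        assert rep.rsd.iloc[0] == pytest.approx(20.0, abs=1e-12)

    def test_zero_mean_gives_inf(self):
        rep = compute_rsd(qc_matrix([[0, 0, 0]]))
        assert np.isinf(rep.rsd.iloc[0])

    def test_requires_two_qc_samples(self):
        m = make_matrix(np.ones((3, 2)), is_qc=[False, False, True])
        with pytest.raises(ValueError, match="QC"):
            compute_rsd(m)


class TestRSDFilter:
    def test_above_threshold_nulled_at_and_below_kept(self):
        # RSDs: 25% (nulled), exactly 20% (kept), 0% (kept)
        m = qc_matrix([[7.5, 10, 12.5], [8, 10, 12], [10, 10, 10]])
        rep = compute_rsd(m)
        out = apply_rsd_filter(m, rep, threshold=20.0)
        assert out.values.iloc[:, 0].isna().all()
        assert not out.values.iloc[:, 1].isna().any()
        assert not out.is_qc.any()  # QC rows dropped
        assert (out.values.iloc[:, 1] == 5.0).all()

    def test_all_pass_is_identity_on_biologicals(self):
        m = qc_matrix([[10, 10, 10], [9, 10, 11]])
        out = apply_rsd_filter(m, compute_rsd(m))
        pd.testing.assert_frame_equal(out.values, m.biological_values())

    def test_threshold_validation(self):
        m = qc_matrix([[10, 10, 10]])
        with pytest.raises(ValueError):
            apply_rsd_filter(m, compute_rsd(m), threshold=0.0)


class TestMissingness:
    def make(self, n_missing, n=100):
        vals = np.ones((n, 2))
        vals[:n_missing, 0] = np.nan
        return make_matrix(vals)

    def test_41_percent_dropped(self):
        out = filter_missingness(self.make(41), 0.40)
        assert out.n_metabolites == 1

    def test_40_percent_retained(self):
        out = filter_missingness(self.make(40), 0.40)
        assert out.n_metabolites == 2

    def test_fully_observed_retained(self):
        out = filter_missingness(self.make(0), 0.40)
        assert out.n_metabolites == 2


class TestImputeAndLog:
    def test_half_minimum(self):
        m = make_matrix([[4.0, 1.0], [np.nan, 2.0], [8.0, np.nan]])
        out = impute_half_min(m)
        assert out.values.iloc[1, 0] == 2.0     # half of min 4.0
        assert out.values.iloc[2, 1] == 0.5     # half of min 1.0
        assert out.values.iloc[0, 0] == 4.0     # observed untouched

    def test_no_missing_is_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(impute_half_min(m).values, m.values)

    def test_zero_minimum_imputes_zero(self):
        m = make_matrix([[0.0], [np.nan]])
        assert impute_half_min(m).values.iloc[1, 0] == 0.0

    def test_all_missing_metabolite_raises(self):
        m = make_matrix([[np.nan], [np.nan]])
        with pytest.raises(ValueError):
            impute_half_min(m)

    def test_log1p_values(self):
        m = make_matrix([[0.0, np.e - 1.0]])
        out = log1p_transform(m)
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == pytest.approx(1.0)

    def test_log1p_rejects_negative(self):
        m = make_matrix([[1.0]])
        m.values.iloc[0, 0] = -1.0
        with pytest.raises(ValueError):
            log1p_transform(m)


class TestStandardize:
    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.lognormal(size=(30, 4)))
        out = standardize(m)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-10
        assert np.allclose(out.values.std(axis=0, ddof=1), 1.0)

    def test_constant_column_dropped(self):
        m = make_matrix([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        out = standardize(m)
        assert out.n_metabolites == 1

    def test_two_sample_column(self):
        # (a, b) standardized with ddof=1 -> (-1/sqrt(2), +1/sqrt(2))
        m = make_matrix([[3.0], [7.0]])
        out = standardize(m)
        assert np.allclose(out.values.iloc[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=40)
        vals = np.outer(t, [1.0, 2.0, -1.0])
        res = run_pca(make_matrix(vals).flag_transformed(), n_components=2)
        assert res.explained_variance_ratio[0] > 0.999

    def test_isotropic_noise_spreads_variance(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(4000, 5)) + 10).flag_transformed()
        res = run_pca(standardize(m), n_components=5)
        assert np.allclose(res.explained_variance_ratio, 0.2, atol=0.02)

    def test_ranking_is_sign_invariant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(30, 4))
        m1 = make_matrix(vals).flag_transformed()
        m2 = make_matrix(-vals).flag_transformed()
        r1 = run_pca(m1, 2).rank_metabolites()
        r2 = run_pca(m2, 2).rank_metabolites()
        assert list(r1.index) == list(r2.index)

    def test_too_many_components(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 3))).flag_transformed()
        with pytest.raises(ValueError):
            run_pca(m, n_components=5)


class TestMerge:
    def _mk(self, n, cols, dataset):
        m = make_matrix(np.random.default_rng(1).lognormal(size=(n, len(cols))), columns=cols)
        m.metabolite_meta["dataset"] = dataset
        return m

    def test_identical_sample_sets_concatenate(self):
        a = self._mk(10, ["m1", "m2"], "polar")
        b = self._mk(10, ["m3"], "nonpolar_pos")
        out = merge_datasets(a, b)
        assert out.values.shape == (10, 3)

    def test_absent_sample_excluded(self):
        a = self._mk(10, ["m1"], "polar")
        b = self._mk(10, ["m2"], "nonpolar_pos")
        b.values = b.values.iloc[:9]
        b.sample_meta = b.sample_meta.iloc[:9]
        out = merge_datasets(a, b)
        assert out.values.shape[0] == 9

    def test_name_collision_suffixed(self):
        a = self._mk(5, ["m1"], "polar")
        b = self._mk(5, ["m1"], "nonpolar_pos")
        out = merge_datasets(a, b)
        assert sorted(out.values.columns) == ["m1__nonpolar_pos", "m1__polar"]

    def test_empty_intersection_raises(self):
        a = self._mk(5, ["m1"], "polar")
        b = self._mk(5, ["m2"], "nonpolar_pos")
        b.values.index = [f"T{i}" for i in range(5)]
        b.sample_meta.index = b.values.index
        with pytest.raises(ValueError):
            merge_datasets(a, b)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    thr_lo=st.floats(5.0, 50.0),
    thr_hi=st.floats(5.0, 50.0),
)
def test_filter_monotonicity(seed, thr_lo, thr_hi):
    """Lowering the RSD threshold never increases the retained count."""
    lo, hi = sorted((thr_lo, thr_hi))
    rng = np.random.default_rng(seed)
    qc = rng.lognormal(sigma=rng.uniform(0.05, 0.5, size=8), size=(6, 8))
    m = qc_matrix(qc.T, bio_rows=4)

    def retained(threshold):
        rep = compute_rsd(m, threshold)
        out = filter_missingness(apply_rsd_filter(m, rep), 0.40)
        return out.n_metabolites

    assert retained(lo) <= retained(hi)


def test_filters_idempotent_on_clean_data():
    m = qc_matrix([[10, 10.5, 9.8], [5, 5.2, 4.9]], bio_rows=4)
    rep = compute_rsd(m)
    once = filter_missingness(apply_rsd_filter(m, rep), 0.40)
    twice = filter_missingness(once, 0.40)
    pd.testing.assert_frame_equal(once.values, twice.values)


def test_stage_ledger_is_conserved(small_cohort):
    matrices, _, _ = small_cohort
    for m in matrices.values():
        _, report = preprocess_dataset(m, PreprocessConfig())
        assert report.ledger_consistent()


def test_preprocess_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(rsd_threshold=0)
    with pytest.raises(ValueError):
        PreprocessConfig(max_missing_fraction=1.5)
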