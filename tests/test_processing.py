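import numpy as np
import pandas as pd
import pytest

from metamwas.processing import (AlignmentConfig, FilterConfig, align_runs,
                                 collapse_replicates, combat_adjust,
                                 detect_technical_clusters, filter_features,
                                 quantile_normalize, replace_zeros)
from tests.conftest import make_feature_table


def _two_run_tables(mz_a, rt_a, mz_b, rt_b, column="c18neg"):
    n_a, n_b = len(mz_a), len(mz_b)
    a = make_feature_table(np.ones((n_a, 2)), mz=mz_a, rt=rt_a, column=column,
                           subject_of=["A1", "A2"], run_of=[1, 1])
    b = make_feature_table(2 * np.ones((n_b, 2)), mz=mz_b, rt=rt_b, column=column,
                           subject_of=["B1", "B2"], run_of=[2, 2])
    b.injections.index = pd.Index([f"J{j}" for j in range(n_b and 2)], name="injection_id")
    b.intensity.columns = b.injections.index
    return a, b


class TestAlignRuns:
    def test_identity_alignment(self):
        a, b = _two_run_tables([100.0, 200.0, 300.0], [50.0, 60.0, 70.0],
                               [100.0, 200.0, 300.0], [50.0, 60.0, 70.0])
        merged = align_runs(a, b)
        assert merged.n_features == 3
        assert merged.n_injections == 4
        assert (merged.intensity.to_numpy() > 0).all()

    def test_mz_boundary_inclusive(self):
        # relative difference exactly 1e-05 must match
        a, b = _two_run_tables([200.0], [100.0], [200.002], [100.0])
        merged = align_runs(a, b)
        assert merged.n_features == 1
        assert merged.features["mz"].iloc[0] == pytest.approx(200.001)

    def test_rt_beyond_tolerance_unmatched(self):
        # 40 s apart on C18 exceeds the 37.016 s tolerance
        a, b = _two_run_tables([200.0], [100.0], [200.0], [140.0])
        merged = align_runs(a, b)
        assert merged.n_features == 2
        # unmatched features carry zeros for the other run
        assert (merged.intensity.iloc[0, 2:] == 0).all()
        assert (merged.intensity.iloc[1, :2] == 0).all()

    def test_mixed_columns_rejected(self):
        a, _ = _two_run_tables([200.0], [100.0], [200.0], [100.0], column="c18neg")
        _, b = _two_run_tables([200.0], [100.0], [200.0], [100.0], column="hilicpos")
        with pytest.raises(ValueError, match="column"):
            align_runs(a, b)

    def test_greedy_prefers_closest(self):
        a, b = _two_run_tables([200.0], [100.0], [200.0004, 200.001], [100.0, 100.0])
        merged = align_runs(a, b)
        matched_mz = sorted(merged.features["mz"])
        assert matched_mz[0] == pytest.approx(200.0002)  # paired with the nearer one


class TestFilterFeatures:
    def _triplicate_table(self, per_subject_values, n_subjects=6):
        """per_subject_values: list over features of a 3-replicate pattern."""
        n_feat = len(per_subject_values)
        cols = []
        subj, reps = [], []
        for s in range(n_subjects):
            for r in range(3):
                subj.append(f"S{s}")
                reps.append(r)
        intensity = np.zeros((n_feat, n_subjects * 3))
        for g, pattern in enumerate(per_subject_values):
            for s in range(n_subjects):
                intensity[g, s * 3:(s + 1) * 3] = np.asarray(pattern)
        return make_feature_table(intensity, subject_of=subj, replicate_of=reps)

    def test_constant_triplicate_kept(self):
        t = self._triplicate_table([[100.0, 100.0, 100.0]])
        kept, report = filter_features(t)
        assert kept.n_features == 1
        assert report.kept == ["F000"]

    def test_subject_cv_value(self):
        t = self._triplicate_table([[90.0, 100.0, 110.0]])
        _, report = filter_features(t)
        # sd(90,100,110) = 10, mean = 100 -> CV 10%
        assert report.median_cv["F000"] == pytest.approx(0.10, abs=1e-4)

    def test_high_cv_dropped(self):
        t = self._triplicate_table([[10.0, 100.0, 400.0]])
        kept, report = filter_features(t)
        assert kept.n_features == 0
        assert report.dropped_cv == ["F000"]

    def test_low_detection_dropped(self):
        # nonzero in only 40% of subjects (2 of 5)
        subj = [f"S{s}" for s in range(5) for _ in range(3)]
        reps = [0, 1, 2] * 5
        intensity = np.zeros((1, 15))
        intensity[0, :6] = 100.0
        t = make_feature_table(intensity, subject_of=subj, replicate_of=reps)
        kept, report = filter_features(t)
        assert kept.n_features == 0
        assert report.dropped_detection == ["F000"]

    def test_no_replicates_skips_replicate_rules(self):
        intensity = np.full((2, 4), 50.0)
        t = make_feature_table(intensity)
        kept, report = filter_features(t)
        assert report.replicate_rules_skipped
        assert kept.n_features == 2

    def test_report_partitions_dropped(self, tiny_cohort):
        table, _, _ = tiny_cohort
        sub = table.subset_column("c18neg")
        kept, report = filter_features(sub)
        dropped = set(report.dropped_cv) | set(report.dropped_correlation) | set(report.dropped_detection)
        assert len(dropped) == (len(report.dropped_cv) + len(report.dropped_correlation)
                                + len(report.dropped_detection))
        assert set(report.kept) | dropped == set(sub.features.index)
        assert not (set(report.kept) & dropped)

    def test_junk_features_filtered(self, tiny_cohort):
        table, _, truth = tiny_cohort
        kept, _ = filter_features(table)
        junk = truth.per_feature.index[truth.per_feature["is_junk"]]
        assert len(set(kept.features.index) & set(junk)) == 0


class TestCollapseReplicates:
    def _table(self, values):
        subj = ["S0"] * len(values)
        reps = list(range(len(values)))
        return make_feature_table(np.asarray([values]), subject_of=subj,
                                  replicate_of=reps)

    def test_median_of_three(self):
        out = collapse_replicates(self._table([1.0, 2.0, 3.0]))
        assert out.intensity.iloc[0, 0] == 2.0

    def test_single_replicate_identity(self):
        out = collapse_replicates(self._table([7.0]))
        assert out.intensity.iloc[0, 0] == 7.0

    def test_zero_majority_stays_zero(self):
        out = collapse_replicates(self._table([0.0, 0.0, 5.0]))
        assert out.intensity.iloc[0, 0] == 0.0

    def test_one_column_per_subject(self, tiny_cohort):
        table, subjects, _ = tiny_cohort
        out = collapse_replicates(table)
        study = out.injections[out.injections["role"] == "study"]
        assert len(study) == len(subjects)
        assert sorted(study["subject_id"]) == sorted(subjects.index)


class TestReplaceZeros:
    def test_stated_rule(self):
        m = pd.DataFrame([[0.0, 12.5, 40.0]])
        out = replace_zeros(m)
        assert out.iloc[0, 0] == 12.5

    def test_no_change_when_all_detected(self):
        m = pd.DataFrame([[1.0, 2.0]])
        pd.testing.assert_frame_equal(replace_zeros(m), m)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = pd.DataFrame({"a": [5.0, 1.0, 3.0], "b": [5.0, 1.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_two_column_example(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 4.0]})
        out = quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [1.5, 3.5])
        np.testing.assert_allclose(out["b"], [1.5, 3.5])

    def test_columns_share_multiset(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(40, 5)))
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(rng.normal(size=(30, 4)))
        out = quantile_normalize(m)
        for j in range(4):
            assert (np.argsort(out.iloc[:, j].to_numpy(), kind="stable")
                    == np.argsort(m.iloc[:, j].to_numpy(), kind="stable")).all()

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(50, 6)))
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-12

    def test_ties_get_mean_of_would_be_quantiles(self):
        # tied pair in column a occupies ranks 1-2: value = mean(ref[0], ref[1])
        m = pd.DataFrame({"a": [1.0, 1.0, 2.0, 5.0], "b": [3.0, 4.0, 6.0, 9.0]})
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        out = quantile_normalize(m)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[1] == pytest.approx((ref[0] + ref[1]) / 2)


def reference_combat(Y, batch_idx, C=None, conv=1e-10):
    """Straightforward loop-based reference of the parametric empirical-Bayes
    location/scale batch adjustment, following the published algorithm step
    by step.  Deliberately unvectorized and independent of the package code."""
    Y = np.asarray(Y, dtype=float)
    G, N = Y.shape
    batches = sorted(set(batch_idx))
    n_batches = len(batches)
    design_cols = []
    for b in batches:
        design_cols.append([1.0 if batch_idx[j] == b else 0.0 for j in range(N)])
    if C is not None:
        C = np.asarray(C, dtype=float)
        for k in range(C.shape[1]):
            design_cols.append(list(C[:, k]))
    X = np.array(design_cols).T
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)
    n_per = [sum(1 for j in range(N) if batch_idx[j] == b) for b in batches]
    grand_mean = np.zeros(G)
    for i, b in enumerate(batches):
        grand_mean += (n_per[i] / N) * B_hat[i]
    stand_mean = np.tile(grand_mean, (N, 1))
    if C is not None:
        stand_mean += C @ B_hat[n_batches:]
    var_pooled = np.zeros(G)
    resid = Y.T - X @ B_hat
    for g in range(G):
        var_pooled[g] = np.mean(resid[:, g] ** 2)
    Z = (Y - stand_mean.T) / np.sqrt(var_pooled)[:, None]

    def aprior(d):
        m, s2 = np.mean(d), np.var(d, ddof=1)
        return (2 * s2 + m ** 2) / s2

    def bprior(d):
        m, s2 = np.mean(d), np.var(d, ddof=1)
        return (m * s2 + m ** 3) / s2

    adj = Z.copy()
    for i, b in enumerate(batches):
        sel = [j for j in range(N) if batch_idx[j] == b]
        Zi = Z[:, sel]
        g_hat = Zi.mean(axis=1)
        d_hat = Zi.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, bp = aprior(d_hat), bprior(d_hat)
        n = len(sel)
        g_old, d_old = g_hat.copy(), d_hat.copy()
        while True:
            g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
            sum2 = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + bp) / (n / 2.0 + a - 1.0)
            change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                         np.max(np.abs(d_new - d_old) / np.abs(d_old)))
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        for k, j in enumerate(sel):
            adj[:, j] = adj[:, j] if j not in sel else adj[:, j]
        adj[:, sel] = (Zi - g_old[:, None]) / np.sqrt(d_old)[:, None]
    return adj * np.sqrt(var_pooled)[:, None] + stand_mean.T


class TestCombat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(10, 1, size=(20, 10)))
        out = combat_adjust(m, [0] * 10)
        assert np.abs(out.to_numpy() - m.to_numpy()).max() < 1e-8

    def test_singleton_batch_error_names_batch(self):
        m = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="solo"):
            combat_adjust(m, ["a", "a", "a", "solo"])

    def test_non_full_rank_protected_rejected(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        bad = np.ones((8, 2))  # duplicated constant columns
        with pytest.raises(ValueError, match="rank"):
            combat_adjust(m, [0, 0, 0, 0, 1, 1, 1, 1], protected=bad)

    def test_removes_planted_shift_and_preserves_effect(self):
        """+2 additive shift on half the columns: residual batch-mean
        difference < 0.05 per feature; planted case effect moves < 0.02."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            G, N = 150, 200
            batch = np.repeat([0, 1], N // 2)
            case = np.tile([0.0, 1.0], N // 2)
            beta = rng.normal(0, 0.5, G)
            Y = rng.normal(12, 0.2, (G, N)) + np.outer(beta, case) + 2.0 * batch[None, :]
            adj = combat_adjust(pd.DataFrame(Y), batch, protected=case[:, None])
            diff = adj.to_numpy()[:, batch == 1].mean(axis=1) - \
                adj.to_numpy()[:, batch == 0].mean(axis=1)
            assert np.abs(diff).max() < 0.05
            X = np.column_stack([np.ones(N), case, batch])
            fit = lambda M: np.linalg.lstsq(X, M.T, rcond=None)[0][1]
            assert np.abs(fit(adj.to_numpy()) - fit(Y)).max() < 0.02

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        G, N = 10, 20
        batch = [0] * 8 + [1] * 12
        C = rng.normal(size=(N, 2))
        Y = rng.normal(8, 1, (G, N)) + np.outer(rng.normal(0, 1, G),
                                                np.array(batch, dtype=float))
        ours = combat_adjust(pd.DataFrame(Y), batch, protected=C)
        ref = reference_combat(Y, batch, C=C)
        assert np.abs(ours.to_numpy() - ref).max() < 1e-6

    def test_matches_reference_no_covariates(self):
        rng = np.random.default_rng(43)
        Y = rng.normal(0, 2, (10, 20)) + 1.5 * np.array([0] * 10 + [1] * 10)[None, :]
        batch = [0] * 10 + [1] * 10
        ours = combat_adjust(pd.DataFrame(Y), batch)
        ref = reference_combat(Y, batch)
        assert np.abs(ours.to_numpy() - ref).max() < 1e-6


class TestDetectTechnicalClusters:
    def test_planted_offset_recovered_exactly(self):
        rng = np.random.default_rng(9)
        n = 100
        plant = np.zeros(n, dtype=int)
        plant[:30] = 1
        base = rng.normal(0, 1, (50, n))
        base[:, plant == 1] += 3.0
        ind = detect_technical_clusters(pd.DataFrame(base))
        assert (ind == plant).all()

    def test_homogeneous_data_not_flagged(self):
        rng = np.random.default_rng(10)
        m = pd.DataFrame(rng.normal(0, 1, (50, 80)))
        assert not detect_technical_clusters(m).any()

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        m = pd.DataFrame(rng.normal(0, 1, (30, 60)))
        m.iloc[:, :20] += 2.5
        first = detect_technical_clusters(m)
        for _ in range(3):
            assert (detect_technical_clusters(m) == first).all()


class TestPreprocess:
    def test_provenance_order(self, tiny_processed):
        matrix, _, _ = tiny_processed
        steps = [p["step"] for p in matrix.provenance]
        assert steps[:6] == ["filter_features", "collapse_replicates",
                             "zero_replacement", "log2", "quantile_normalize",
                             "combat_adjust"]

    def test_values_finite_and_subject_indexed(self, tiny_processed, tiny_cohort):
        matrix, _, _ = tiny_processed
        _, subjects, _ = tiny_cohort
        assert np.isfinite(matrix.values.to_numpy()).all()
        assert sorted(matrix.values.columns) == sorted(subjects.index)

    def test_qc_cv_reduced_by_processing(self, tiny_processed):
        matrix, cv_report, _ = tiny_processed
        summary = cv_report.summary()
        assert summary["after"]["mean"] < summary["before"]["mean"]

    def test_qc_cv_reduced_other_column(self, tiny_cohort):
        from metamwas.processing import preprocess

        table, subjects, _ = tiny_cohort
        _, cv_report, _ = preprocess(table.subset_column("hilicpos"), subjects)
        summary = cv_report.summary()
        assert summary["after"]["mean"] < summary["before"]["mean"]

    def test_case_signal_survives_preprocessing(self, tiny_cohort, tiny_processed):
        """Planted case effects should be estimable after the full chain."""
        from metamwas.mwas import fit_moderated_linear, mwas_design

        table, subjects, truth = tiny_cohort
        matrix, _, _ = tiny_processed
        res, _ = fit_moderated_linear(matrix.values, mwas_design(subjects))
        tf = truth.per_feature.loc[res.index]
        planted = tf["true_log2fc"].abs() > 0.5
        if planted.sum():
            assert np.corrcoef(res.loc[planted.to_numpy(), "log2fc"],
                               tf.loc[planted, "true_log2fc"])[0, 1] > 0.8
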