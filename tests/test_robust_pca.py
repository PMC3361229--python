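import numpy as np
import pytest
from scipy import stats

from nirclass.preprocessing import restrict_range
from nirclass.robust_pca import (RPCASettings, RobustPCAModel,
                                 classify_samples, diagnose_class,
                                 distance_cutoffs, fit_robpca,
                                 orthogonal_distance, outlyingness,
                                 score_distance, select_k_by_press)


def subspace_angle_deg(A, B):
    """Largest principal angle between the column spaces of A and B."""
    qa, _ = np.linalg.qr(A)
    qb, _ = np.linalg.qr(B)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(s.min(), -1, 1)))


class TestOutlyingness:
    def test_gross_outlier_has_largest_value(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [25, 30]])
        out = outlyingness(X, n_directions=100, seed=0)  # all 10 pairs used
        assert np.argmax(out) == 4

    def test_symmetric_points_equal(self, rng):
        half = rng.normal(size=(6, 3))
        X = np.vstack([half, -half])
        out = outlyingness(X, n_directions=1000, seed=0)
        assert np.allclose(out[:6], out[6:], rtol=1e-10)

    def test_duplicated_rows_duplicate_values(self, rng):
        X = rng.normal(size=(8, 4))
        X2 = np.vstack([X, X])
        out = outlyingness(X2, n_directions=10000, seed=0)
        assert np.allclose(out[:8], out[8:])

    def test_identical_points_degenerate(self):
        with pytest.raises(ValueError):
            outlyingness(np.ones((5, 3)))


class TestFitRobpca:
    def test_matches_classical_pca_on_clean_data(self, rng):
        X = rng.normal(size=(200, 10)) * np.sqrt(
            np.array([9, 4, 1, .1, .1, .1, .1, .1, .1, .1]))
        model = fit_robpca(X, 3, seed=0)
        C = np.cov(X.T)
        evals, evecs = np.linalg.eigh(C)
        Vc = evecs[:, np.argsort(evals)[::-1][:3]]
        assert subspace_angle_deg(model.loadings, Vc) < 10
        # eigenvalues consistent within 15%
        lam_c = np.sort(evals)[::-1][:3]
        assert np.all(np.abs(model.eigenvalues - lam_c) / lam_c < 0.15)

    def test_resists_gross_contamination(self, rng):
        clean = rng.normal(size=(180, 10)) * np.sqrt(
            np.array([9, 4, 1, .01, .01, .01, .01, .01, .01, .01]))
        C = np.cov(clean.T)
        evals, evecs = np.linalg.eigh(C)
        Vc = evecs[:, np.argsort(evals)[::-1][:3]]
        junk = np.zeros((20, 10))
        junk[:, -1] = 40.0 + rng.normal(0, 0.5, 20)   # orthogonal cluster
        X = np.vstack([clean, junk])
        robust = fit_robpca(X, 3, seed=0)
        assert subspace_angle_deg(robust.loadings, Vc) < 10
        evals2, evecs2 = np.linalg.eigh(np.cov(X.T))
        Vbad = evecs2[:, np.argsort(evals2)[::-1][:3]]
        assert subspace_angle_deg(Vbad, Vc) > 45   # classical PCA broken

    def test_degenerate_and_parameter_errors(self):
        with pytest.raises(ValueError):
            fit_robpca(np.ones((3, 4)), 1)
        with pytest.raises(ValueError):
            fit_robpca(np.random.default_rng(0).normal(size=(10, 4)), 9)

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(60, 12))
        m = fit_robpca(X, 4, seed=1)
        assert np.allclose(m.loadings.T @ m.loadings, np.eye(4), atol=1e-8)
        assert np.all(np.diff(m.eigenvalues) <= 1e-12)


class TestDistances:
    @pytest.fixture
    def model(self, rng):
        X = rng.normal(size=(80, 6)) * np.sqrt(np.array([9, 4, 1, .1, .1, .1]))
        return fit_robpca(X, 2, seed=0), X

    def test_center_has_zero_sd(self, model):
        m, _ = model
        assert score_distance(m, m.center[None, :])[0] == pytest.approx(0)

    def test_unit_sd_along_first_loading(self, model):
        m, _ = model
        x = m.center + np.sqrt(m.eigenvalues[0]) * m.loadings[:, 0]
        assert score_distance(m, x[None, :])[0] == pytest.approx(1.0)

    def test_sd_matches_naive_loop(self, model):
        m, X = model
        sd = score_distance(m, X)
        for i in range(0, 80, 7):
            t = (X[i] - m.center) @ m.loadings
            ref = np.sqrt(sum(t[j] ** 2 / m.eigenvalues[j]
                              for j in range(m.k)))
            assert sd[i] == pytest.approx(ref)

    def test_od_zero_in_plane(self, model):
        m, _ = model
        x = m.center + 3.1 * m.loadings[:, 0] - 1.7 * m.loadings[:, 1]
        assert orthogonal_distance(m, x[None, :])[0] == pytest.approx(0, abs=1e-9)

    def test_od_of_orthogonal_offset(self, model):
        m, _ = model
        u = np.linalg.svd(m.loadings.T)[2][-1]   # in the null space
        x = m.center + 2.5 * u
        assert orthogonal_distance(m, x[None, :])[0] == pytest.approx(2.5)

    def test_od_matches_projection_oracle(self, model):
        m, X = model
        od = orthogonal_distance(m, X)
        P = m.loadings @ m.loadings.T
        for i in range(0, 80, 11):
            d = X[i] - m.center
            assert od[i] == pytest.approx(np.linalg.norm(d - P @ d))

    def test_shape_errors(self, model):
        m, _ = model
        with pytest.raises(ValueError):
            score_distance(m, np.zeros((3, 5)))
        with pytest.raises(ValueError):
            orthogonal_distance(m, np.zeros((3, 7)))

    def test_rotation_invariance(self, model, rng):
        """SD and OD are unchanged under a global orthogonal rotation."""
        m, X = model
        Q = np.linalg.qr(rng.normal(size=(6, 6)))[0]
        m_rot = RobustPCAModel(center=m.center @ Q, loadings=Q.T @ m.loadings,
                               eigenvalues=m.eigenvalues, k=m.k,
                               alpha_coverage=m.alpha_coverage,
                               significance=m.significance)
        assert np.allclose(score_distance(m, X),
                           score_distance(m_rot, X @ Q), atol=1e-8)
        assert np.allclose(orthogonal_distance(m, X),
                           orthogonal_distance(m_rot, X @ Q), atol=1e-8)


class TestCutoffsAndGroups:
    def test_sd_cutoff_chi_square_value(self):
        m = RobustPCAModel(center=np.zeros(3),
                           loadings=np.eye(3)[:, :2],
                           eigenvalues=np.array([2.0, 1.0]), k=2,
                           alpha_coverage=0.75, significance=0.05)
        sd_cut, _ = distance_cutoffs(m, np.array([1.0, 1.0]))
        assert sd_cut == pytest.approx(np.sqrt(5.9915), abs=1e-3)

    def test_constant_od_degenerates_with_warning(self):
        m = RobustPCAModel(center=np.zeros(3), loadings=np.eye(3)[:, :2],
                           eigenvalues=np.array([2.0, 1.0]), k=2,
                           alpha_coverage=0.75, significance=0.05)
        with pytest.warns(UserWarning):
            _, od_cut = distance_cutoffs(m, np.full(10, 0.7))
        assert od_cut == pytest.approx(0.7)

    def test_od_cutoff_calibrated_on_normal_residuals(self):
        """Fraction above the cutoff ~ significance +- 3 SE over 50 seeds."""
        sig, n, dof = 0.05, 200, 40
        m = RobustPCAModel(center=np.zeros(3), loadings=np.eye(3)[:, :2],
                           eigenvalues=np.array([2.0, 1.0]), k=2,
                           alpha_coverage=0.75, significance=sig)
        rates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            od = np.sqrt(stats.chi2.rvs(dof, size=n, random_state=rng))
            _, cut = distance_cutoffs(m, od)
            rates.append(np.mean(od > cut))
        se = np.sqrt(sig * (1 - sig) / (n * 50))
        assert abs(np.mean(rates) - sig) < 3 * se + 0.01

    def test_four_group_rule(self):
        sd = np.array([1.0, 3.0, 1.0, 3.0, 2.0])
        od = np.array([1.0, 1.0, 3.0, 3.0, 2.0])
        groups = classify_samples(sd, od, 2.0, 2.0)
        assert list(groups) == ["regular", "good_leverage",
                                "orthogonal_outlier", "bad_leverage",
                                "regular"]   # boundary is "not large"

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            classify_samples(np.ones(3), np.ones(4), 1, 1)


class TestSelectK:
    def test_rank_two_fixture(self, rng):
        scores = rng.normal(size=(60, 2)) * [3.0, 1.5]
        load = np.linalg.qr(rng.normal(size=(20, 2)))[0]
        X = scores @ load.T + rng.normal(0, 0.01, (60, 20))
        assert select_k_by_press(X, 6, seed=1) == 2

    def test_pure_noise_gives_one(self, rng):
        assert select_k_by_press(rng.normal(size=(50, 15)), 6, seed=1) == 1

    def test_k_max_one(self, rng):
        assert select_k_by_press(rng.normal(size=(30, 5)), 1, seed=0) == 1


class TestDiagnoseClass:
    def test_injected_orthogonal_outliers_excluded(self, default_set):
        data, truth = default_set
        restricted = restrict_range(data, 4000, 10000)
        diag = diagnose_class(restricted, "transgenic", RPCASettings(seed=3))
        excluded = set(diag.excluded_ids.tolist())
        injected = {s for s, kind in truth.outlier_of.items()
                    if truth.class_of[s] == "transgenic"}
        assert injected <= excluded

    def test_leverage_sample_flagged_with_largest_sd(self, default_set):
        data, truth = default_set
        restricted = restrict_range(data, 4000, 10000)
        diag = diagnose_class(restricted, "parent", RPCASettings(seed=3))
        i = int(np.flatnonzero(diag.sample_ids == 1)[0])  # injected leverage
        assert diag.group[i] in ("bad_leverage", "good_leverage")
        assert diag.sd[i] == np.max(diag.sd)

    def test_partition_and_exclusion_policy(self, default_set):
        data, _ = default_set
        restricted = restrict_range(data, 4000, 10000)
        diag = diagnose_class(restricted, "hybrid", RPCASettings(seed=3))
        assert set(diag.group) <= {"regular", "good_leverage",
                                   "orthogonal_outlier", "bad_leverage"}
        assert np.array_equal(
            diag.excluded,
            np.isin(diag.group, ("orthogonal_outlier", "bad_leverage")))

    def test_errors(self, default_set):
        data, _ = default_set
        with pytest.raises(KeyError):
            diagnose_class(data, "nosuch")
        small = data.select_samples(data.sample_ids[:5])
        with pytest.raises(ValueError):
            diagnose_class(small, "parent")
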