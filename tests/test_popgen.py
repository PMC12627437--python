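import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karyoscan import popgen
from karyoscan.popgen import (
    GroupAssignment,
    classical_mds,
    compare_tajima_in_out,
    ibs_distance,
    pairwise_r2,
    rosner_outliers,
    wc_fst_site,
    windowed_fst,
    windowed_pi,
    windowed_tajimas_d,
)

import oracles
from conftest import make_matrix


def _two_group(n1=4, n2=4):
    samples = [f"S{i:03d}" for i in range(n1 + n2)]
    groups = GroupAssignment({s: ("g1" if i < n1 else "g2")
                              for i, s in enumerate(samples)})
    return samples, groups


class TestWcFst:
    def test_fixed_difference_is_one(self):
        samples, groups = _two_group()
        gm = make_matrix([[0]] * 4 + [[2]] * 4, samples=samples)
        a, b, c = wc_fst_site(gm, groups, 0)
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        samples, groups = _two_group()
        col = [0, 1, 1, 2]
        gm = make_matrix([[g] for g in col + col], samples=samples)
        a, b, c = wc_fst_site(gm, groups, 0)
        assert a / (a + b + c) <= 0

    def test_monomorphic_components_zero(self):
        samples, groups = _two_group()
        gm = make_matrix([[0]] * 8, samples=samples)
        assert wc_fst_site(gm, groups, 0) == (0.0, 0.0, 0.0)

    def test_matches_bruteforce_on_random_sites(self):
        rng = np.random.default_rng(42)
        samples, groups = _two_group(5, 7)
        for _ in range(60):
            col = rng.integers(0, 3, size=12)
            if rng.random() < 0.3:
                col[rng.integers(0, 12)] = -1
            g1, g2 = col[:5], col[5:]
            if (g1 >= 0).sum() == 0 or (g2 >= 0).sum() == 0:
                continue
            gm = make_matrix(col[:, None], samples=samples)
            got = wc_fst_site(gm, groups, 0)
            want = oracles.wc_fst_components(g1, g2)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_windowed_weighting(self):
        # one fixed difference + one identical-group site in one window:
        # weighted value is sum(a)/sum(a+b+c), not the mean of ratios
        samples, groups = _two_group()
        G = np.array([[0, 1], [0, 0], [0, 1], [0, 2],
                      [2, 1], [2, 0], [2, 1], [2, 2]])
        gm = make_matrix(G, pos=[100, 200], samples=samples)
        track = windowed_fst(gm, groups, window_bp=10_000, step_bp=10_000)
        comps = [oracles.wc_fst_components(G[:4, s], G[4:, s]) for s in range(2)]
        want = sum(c[0] for c in comps) / sum(sum(c) for c in comps)
        assert track["value"].iloc[0] == pytest.approx(want, rel=1e-12)

    def test_single_site_window_equals_site_ratio(self):
        samples, groups = _two_group()
        gm = make_matrix([[0], [1], [0], [1], [2], [2], [1], [2]], samples=samples)
        a, b, c = wc_fst_site(gm, groups, 0)
        track = windowed_fst(gm, groups, window_bp=1_000, step_bp=1_000)
        assert track["value"].iloc[0] == pytest.approx(a / (a + b + c))

    def test_windowed_never_exceeds_one(self, inversion_scenario):
        _, gm, truth = inversion_scenario
        kappa = truth.karyotypes[:, 0]
        homo = {gm.samples[i]: str(kappa[i]) for i in range(len(kappa)) if kappa[i] != 1}
        track = windowed_fst(gm.subset_sites(np.flatnonzero(
            np.asarray(gm.sites["chrom"] == "chr2"))[:5000]), GroupAssignment(homo))
        assert np.nanmax(track["value"].to_numpy()) <= 1.0 + 1e-12


class TestR2:
    def test_identical_columns(self):
        gm = make_matrix(np.array([[0, 0], [1, 1], [2, 2], [1, 1]]))
        pairs = pairwise_r2(gm, "chr1", thin_frac=1.0, r2_min=0.0)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        gm = make_matrix(np.array([[0, 2], [1, 1], [2, 0], [1, 1]]))
        pairs = pairwise_r2(gm, "chr1", thin_frac=1.0, r2_min=0.0)
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            G = rng.integers(0, 3, size=(8, 2))
            gm = make_matrix(G)
            want = oracles.pearson_r2(G[:, 0], G[:, 1])
            pairs = pairwise_r2(gm, "chr1", thin_frac=1.0, r2_min=-1.0)
            if np.isnan(want):
                assert pairs.empty
            else:
                np.testing.assert_allclose(pairs["r2"].iloc[0], want, rtol=1e-10)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, size=(10, 4))
        gm = make_matrix(G)
        p1 = pairwise_r2(gm, "chr1", thin_frac=1.0, r2_min=0.0)
        p2 = pairwise_r2(gm.relabelled(), "chr1", thin_frac=1.0, r2_min=0.0)
        pd.testing.assert_frame_equal(p1, p2)

    def test_thinning_is_seeded(self, inversion_scenario):
        _, gm, _ = inversion_scenario
        a = pairwise_r2(gm, "chr2", seed=3)
        b = pairwise_r2(gm, "chr2", seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestPi:
    def test_monomorphic_window_zero(self):
        gm = make_matrix(np.zeros((4, 10), dtype=int))
        track = windowed_pi(gm, window_bp=10_000, step_bp=10_000)
        assert track["value"].iloc[0] == 0.0

    def test_closed_form_single_site(self):
        # j = 4 of m = 8 alleles in a 10 kb window
        gm = make_matrix([[2], [2], [0], [0]])
        track = windowed_pi(gm, window_bp=10_000, step_bp=10_000)
        assert track["value"].iloc[0] == pytest.approx((2 * 4 * 4 / (8 * 7)) / 10_000)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            col = rng.integers(0, 3, size=6)
            if not 0 < col.sum() < 12:
                continue
            gm = make_matrix(col[:, None])
            track = windowed_pi(gm, window_bp=1_000, step_bp=1_000)
            want = oracles.site_pi(col) / 1_000
            np.testing.assert_allclose(track["value"].iloc[0], want, rtol=1e-10)

    def test_sample_permutation_invariant(self):
        rng = np.random.default_rng(10)
        G = rng.integers(0, 3, size=(6, 30))
        t1 = windowed_pi(make_matrix(G))
        t2 = windowed_pi(make_matrix(G[rng.permutation(6)]))
        pd.testing.assert_frame_equal(t1, t2)


class TestTajima:
    def test_no_segregating_sites_is_nan(self):
        gm = make_matrix(np.full((4, 5), 2))
        track = windowed_tajimas_d(gm)
        assert np.isnan(track["value"].iloc[0])

    def test_singletons_give_negative_d(self):
        # m = 8 chromosomes, 3 sites each with one alt copy
        G = np.zeros((4, 3), dtype=int)
        G[0, 0] = G[1, 1] = G[2, 2] = 1
        gm = make_matrix(G)
        track = windowed_tajimas_d(gm, window_bp=10_000)
        want = oracles.tajimas_d(G)
        assert want < 0
        np.testing.assert_allclose(track["value"].iloc[0], want, rtol=1e-10)

    def test_matches_bruteforce_random_windows(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            G = rng.integers(0, 3, size=(rng.integers(3, 9), rng.integers(1, 12)))
            gm = make_matrix(G, pos=np.arange(1, G.shape[1] + 1) * 10)
            track = windowed_tajimas_d(gm, window_bp=10_000)
            want = oracles.tajimas_d(G)
            got = track["value"].iloc[0]
            if np.isnan(want):
                assert np.isnan(got)
            else:
                np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_sign_matches_pi_minus_watterson(self):
        rng = np.random.default_rng(12)
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(8, 40))
        gm = make_matrix(G, pos=np.arange(1, 41) * 10)
        track = windowed_tajimas_d(gm, window_bp=10_000)
        m = 16
        a1 = np.sum(1.0 / np.arange(1, m))
        seg = [s for s in range(40) if 0 < G[:, s].sum() < m]
        pi_hat = sum(oracles.site_pi(G[:, s]) for s in seg)
        assert np.sign(track["value"].iloc[0]) == np.sign(pi_hat - len(seg) / a1)


class TestWilcoxon:
    def test_identical_distributions_p_near_one(self):
        track = pd.DataFrame({
            "chrom": "c", "start_bp": np.arange(8) * 100 + 1,
            "end_bp": np.arange(8) * 100 + 100,
            # inside = even windows, outside = odd: identical value multisets
            "value": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 4.0, 4.0],
        })
        res = compare_tajima_in_out(
            track, [("c", 1, 100), ("c", 201, 300), ("c", 401, 500), ("c", 601, 700)])
        assert res.p > 0.5

    def test_complete_separation_matches_enumeration(self):
        track = pd.DataFrame({
            "chrom": "c", "start_bp": np.arange(6) * 100 + 1,
            "end_bp": np.arange(6) * 100 + 100,
            "value": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        })
        res = compare_tajima_in_out(track, [("c", 1, 300)])
        u, p = oracles.wilcoxon_exact_p([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.u == u == 0
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.method == "exact"

    def test_matches_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            nx, ny = rng.integers(2, 7), rng.integers(2, 7)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            n = nx + ny
            track = pd.DataFrame({
                "chrom": "c", "start_bp": np.arange(n) * 100 + 1,
                "end_bp": np.arange(n) * 100 + 100,
                "value": np.concatenate([x, y]),
            })
            res = compare_tajima_in_out(track, [("c", 1, nx * 100)])
            _, p = oracles.wilcoxon_exact_p(x, y)
            np.testing.assert_allclose(res.p, p, rtol=1e-10)

    def test_empty_side_errors(self):
        track = pd.DataFrame({"chrom": ["c"], "start_bp": [1], "end_bp": [100],
                              "value": [1.0]})
        with pytest.raises(ValueError):
            compare_tajima_in_out(track, [])


class TestIbsMds:
    def test_ibs_extremes_and_hand_value(self):
        gm = make_matrix(np.array([[0, 1, 2], [0, 1, 2], [2, 1, 0]]))
        D = ibs_distance(gm)
        assert D.iloc[0, 1] == 0.0
        assert D.iloc[0, 2] == pytest.approx(2 / 3)
        gm2 = make_matrix(np.array([[0, 0], [2, 2]]))
        assert ibs_distance(gm2).iloc[0, 1] == 1.0

    def test_ibs_matches_bruteforce(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            G = rng.integers(0, 3, size=(4, 10))
            G[rng.integers(0, 4), rng.integers(0, 10)] = -1
            D = ibs_distance(make_matrix(G))
            j, k = rng.integers(0, 4, size=2)
            want = oracles.ibs_distance(G[j], G[k])
            np.testing.assert_allclose(D.iloc[j, k], want, rtol=1e-10)

    def test_mds_collinear_points(self):
        # distances of points at 0, 1, 3 on a line
        D = np.abs(np.subtract.outer([0.0, 1.0, 3.0], [0.0, 1.0, 3.0]))
        coords, evals = classical_mds(pd.DataFrame(D, index=list("abc"),
                                                   columns=list("abc")), n_axes=2)
        x = coords["axis1"].to_numpy()
        np.testing.assert_allclose(np.abs(np.diff(np.sort(x))), [1.0, 2.0], atol=1e-8)
        np.testing.assert_allclose(coords["axis2"], 0.0, atol=1e-8)

    def test_mds_reconstructs_euclidean_distances(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(7, 3))
        D = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        coords, evals = classical_mds(pd.DataFrame(D), n_axes=3)
        D2 = np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None, :],
                            axis=2)
        np.testing.assert_allclose(D2, D, atol=1e-8)
        assert np.all(np.diff(evals) <= 1e-9)
        np.testing.assert_allclose(coords.sum(axis=0), 0.0, atol=1e-8)

    def test_asymmetric_errors(self):
        with pytest.raises(ValueError):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestRosner:
    def test_no_iqr_outliers_no_test(self):
        rng = np.random.default_rng(16)
        x = rng.uniform(size=40)  # uniform: nothing beyond 1.5 IQR
        res = rosner_outliers(x)
        assert res.k_suspected == 0 and res.n_outliers == 0

    def test_injected_gross_outlier_found(self):
        rng = np.random.default_rng(17)
        x = np.append(rng.normal(size=1000), 10.0)
        res = rosner_outliers(x, alpha=0.01)
        assert 1000 in set(res.outlier_indices)

    def test_lambdas_match_bruteforce(self):
        rng = np.random.default_rng(18)
        x = np.append(rng.normal(size=47), [8.0, 9.0, 12.0])  # n = 50
        res = rosner_outliers(x, alpha=0.01, k=3)
        want = oracles.rosner_lambdas(50, 0.01, 3)
        np.testing.assert_allclose(res.stats["lam"].to_numpy(), want, rtol=1e-10)

    def test_outlier_count_monotone_in_alpha(self):
        # larger alpha = less strict critical values = at least as many outliers
        rng = np.random.default_rng(19)
        x = np.append(rng.normal(size=200), [4.0, 4.5, 5.0, 8.0])
        counts = [rosner_outliers(x, alpha=a).n_outliers
                  for a in (0.001, 0.01, 0.05, 0.1)]
        assert counts == sorted(counts)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            rosner_outliers(np.array([1.0] * 30), k=2)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_r2_symmetric_and_bounded(seed):
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 3, size=(6, 5))
    pairs = pairwise_r2(make_matrix(G), "chr1", thin_frac=1.0, r2_min=0.0)
    assert ((pairs["r2"] >= 0) & (pairs["r2"] <= 1 + 1e-12)).all()
    assert (pairs["pos_a"] < pairs["pos_b"]).all()
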