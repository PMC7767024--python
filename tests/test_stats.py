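import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riverchem.errors import ValidationError
from riverchem.io import PeakTable
from riverchem.stats import (
    beta_dispersion,
    euclidean_distance,
    mannwhitney_fdr,
    pca,
    permanova,
    presence_absence,
)

from conftest import make_table


class TestPresenceAbsence:
    def test_binarizes_and_is_scale_invariant(self, tiny_table):
        mat = presence_absence(tiny_table)
        assert set(np.unique(mat.to_numpy())) <= {0.0, 1.0}
        doubled = PeakTable(tiny_table.peaks, tiny_table.detections * 2)
        pd.testing.assert_frame_equal(mat, presence_absence(doubled))

    def test_all_zero_sample_retained(self):
        table = make_table([(200.0, 10, 16, 0, 5, 0, 0, False, 1.0, 0.0)])
        mat = presence_absence(table)
        assert mat.loc["s2"].sum() == 0

    def test_euclidean_is_sqrt_hamming(self, default_study):
        mat = presence_absence(default_study.table).iloc[:6]
        dist = euclidean_distance(mat)
        values = mat.to_numpy()
        for i in range(6):
            for j in range(6):
                hamming = np.sum(values[i] != values[j])
                assert dist.iloc[i, j] == pytest.approx(np.sqrt(hamming), abs=1e-9)


class TestPCA:
    def test_two_samples_single_component(self):
        mat = pd.DataFrame([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]], index=["a", "b"])
        res = pca(mat)
        assert res.proportion_variance[0] == pytest.approx(1.0)

    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 2, (4, 30)).astype(float)
        mat = pd.DataFrame(np.vstack([base, base[:1]]))
        res = pca(mat)
        assert np.allclose(res.scores.iloc[0], res.scores.iloc[4], atol=1e-9)

    def test_variance_conservation(self):
        rng = np.random.default_rng(2)
        mat = pd.DataFrame(rng.integers(0, 2, (10, 50)).astype(float))
        res = pca(mat)
        total = np.var(mat.to_numpy(), axis=0, ddof=1).sum()
        component_var = np.var(res.scores.to_numpy(), axis=0, ddof=1).sum()
        assert component_var == pytest.approx(total, abs=1e-9)
        assert res.proportion_variance.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.proportion_variance) <= 1e-12)

    def test_scores_preserve_pairwise_distances(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.integers(0, 2, (8, 40)).astype(float))
        res = pca(mat)
        centred = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        orig = euclidean_distance(pd.DataFrame(centred)).to_numpy()
        proj = euclidean_distance(res.scores).to_numpy()
        assert np.allclose(orig, proj, atol=1e-8)

    def test_constant_matrix_warns_and_returns_zero_variance(self):
        mat = pd.DataFrame(np.ones((4, 5)))
        res = pca(mat)
        assert np.all(res.proportion_variance == 0)


def _toy_distance(points, index=None):
    mat = pd.DataFrame(np.asarray(points, float))
    if index is not None:
        mat.index = index
    return euclidean_distance(mat)


class TestPermanova:
    def test_pseudo_f_matches_hand_computation(self):
        points = [[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]]
        groups = ["a", "a", "a", "b", "b", "b"]
        dist = _toy_distance(points)
        d2 = dist.to_numpy() ** 2
        sst = d2.sum() / (2 * 6)
        ssw = d2[:3, :3].sum() / (2 * 3) + d2[3:, 3:].sum() / (2 * 3)
        expected_f = (sst - ssw) / 1 / (ssw / 4)
        res = permanova(dist, groups, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(expected_f, rel=1e-12)
        assert res.r_squared == pytest.approx((sst - ssw) / sst, rel=1e-12)

    def test_pseudo_f_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        points = rng.normal(size=(12, 5))
        groups = ["a"] * 6 + ["b"] * 6
        dist = _toy_distance(points)
        res = permanova(dist, groups, n_permutations=99, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dist.to_numpy()), grouping=list(groups), permutations=99)
        assert res.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_perfect_separation_gives_minimal_p(self):
        # 12 per group: the chance of a random permutation recreating the
        # observed partition (which would tie the F statistic) is ~1e-4
        points = [[0.0, 0.0]] * 12 + [[100.0, 100.0]] * 12
        res = permanova(_toy_distance(points), ["a"] * 12 + ["b"] * 12,
                        n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_seeded_reproducibility_and_order_invariance(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(14, 6))
        groups = np.array(["a"] * 7 + ["b"] * 7)
        dist = _toy_distance(points)
        r1 = permanova(dist, groups, n_permutations=199, seed=42)
        r2 = permanova(dist, groups, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value and r1.pseudo_f == r2.pseudo_f
        perm = rng.permutation(14)
        shuffled = dist.to_numpy()[np.ix_(perm, perm)]
        r3 = permanova(pd.DataFrame(shuffled), groups[perm], n_permutations=199, seed=42)
        assert r3.p_value == r1.p_value
        assert r3.pseudo_f == pytest.approx(r1.pseudo_f, rel=1e-12)

    def test_singleton_group_rejected(self):
        points = [[0.0], [1.0], [2.0]]
        with pytest.raises(ValidationError):
            permanova(_toy_distance(points), ["a", "a", "b"], n_permutations=99)

    def test_null_rejection_rate_on_gaussian_data(self):
        rng = np.random.default_rng(6)
        rejections = 0
        n_runs = 300
        for _ in range(n_runs):
            points = rng.normal(size=(12, 8))
            res = permanova(_toy_distance(points), ["a"] * 6 + ["b"] * 6,
                            n_permutations=99, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.02 <= rejections / n_runs <= 0.09


class TestBetaDispersion:
    def test_identical_points_have_zero_dispersion(self):
        points = [[1.0, 1.0]] * 4 + [[3.0, 0.0], [4.0, 1.0], [5.0, 2.0]]
        res = beta_dispersion(_toy_distance(points), ["a"] * 4 + ["b"] * 3)
        assert np.allclose(res.distances.iloc[:4], 0.0, atol=1e-9)

    def test_one_dimensional_hand_geometry(self):
        points = [[0.0], [2.0], [0.0], [6.0]]
        res = beta_dispersion(_toy_distance(points), ["a", "a", "b", "b"])
        assert np.allclose(res.distances.to_numpy(), [1.0, 1.0, 3.0, 3.0], atol=1e-9)

    def test_matches_direct_centroid_computation(self):
        rng = np.random.default_rng(7)
        points = rng.normal(size=(10, 4))
        groups = np.array(["a"] * 5 + ["b"] * 5)
        res = beta_dispersion(_toy_distance(points), groups)
        for label in ("a", "b"):
            members = points[groups == label]
            centroid = members.mean(axis=0)
            direct = np.linalg.norm(members - centroid, axis=1)
            assert np.allclose(res.distances.to_numpy()[groups == label], direct, atol=1e-9)

    def test_recovers_planted_dispersion_difference(self):
        rng = np.random.default_rng(8)
        tight = rng.normal(scale=0.2, size=(10, 3))
        loose = rng.normal(scale=3.0, size=(10, 3))
        res = beta_dispersion(_toy_distance(np.vstack([tight, loose])),
                              ["tight"] * 10 + ["loose"] * 10)
        assert res.group_means["loose"] > res.group_means["tight"]
        assert res.p_value < 0.01


class TestMannWhitneyFDR:
    def _frame(self, a, b):
        data = pd.DataFrame({"m": np.concatenate([a, b])})
        groups = pd.Series(["a"] * len(a) + ["b"] * len(b), index=data.index)
        return data, groups

    def test_identical_groups_p_one(self):
        data, groups = self._frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = mannwhitney_fdr(data, groups)
        assert out["p_value"].iloc[0] == 1.0
        assert out["p_adjusted"].iloc[0] == 1.0
        assert out["direction"].iloc[0] == "none"

    def test_constant_tied_data_p_one(self):
        data, groups = self._frame([5.0] * 4, [5.0] * 4)
        assert mannwhitney_fdr(data, groups)["p_value"].iloc[0] == 1.0

    def test_bh_adjustment_hand_example(self):
        # BH on {0.01, 0.02, 0.03} gives {0.03, 0.03, 0.03}
        from statsmodels.stats.multitest import multipletests
        adjusted = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert np.allclose(adjusted, [0.03, 0.03, 0.03])

    def test_power_and_direction_on_shifted_groups(self):
        rng = np.random.default_rng(9)
        data, groups = self._frame(rng.normal(0, 1, 20), rng.normal(3, 1, 20))
        out = mannwhitney_fdr(data, groups)
        assert out["p_adjusted"].iloc[0] < 0.05
        assert out["direction"].iloc[0] == "b>a"

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=12))
    def test_bh_is_monotone_and_dominates_raw(self, pvals):
        from statsmodels.stats.multitest import multipletests
        raw = np.array(pvals)
        adjusted = multipletests(raw, method="fdr_bh")[1]
        assert np.all(adjusted >= raw - 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(adjusted[order]) >= -1e-12)

    def test_requires_two_groups(self):
        data = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        groups = pd.Series(["a", "a", "a"], index=data.index)
        with pytest.raises(ValidationError):
            mannwhitney_fdr(data, groups)
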