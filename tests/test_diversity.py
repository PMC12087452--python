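import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from ruminate.cohort import CohortError, FeatureTable
from ruminate.diversity import (
    bray_curtis,
    chao1,
    individual_variability,
    pcoa,
    permanova,
    shannon,
)


class TestAlpha:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 3, 3], 3.0),  # no rare taxa -> observed richness
            ([1, 1, 2, 5, 9], 5 + 2 * 1 / (2 * 2)),  # S=5, F1=2, F2=1 -> 5.5
            ([2, 2, 3], 3.0),  # no singletons -> S_obs
        ],
    )
    def test_chao1_bias_corrected_formula(self, counts, expected):
        assert chao1(np.array(counts)) == pytest.approx(expected)

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.integers(0, 6, size=20)
            if v.sum() == 0:
                continue
            assert chao1(v) >= (v > 0).sum() - 1e-12

    def test_chao1_all_zero_is_error(self):
        with pytest.raises(CohortError):
            chao1(np.zeros(4, dtype=int))

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([5, 5, 5, 5], math.log(4)),
            ([9, 0, 0], 0.0),
            ([1, 1, 2], -(0.25 * math.log(0.25) * 2 + 0.5 * math.log(0.5))),
        ],
    )
    def test_shannon_natural_log(self, counts, expected):
        assert shannon(np.array(counts)) == pytest.approx(expected, abs=1e-9)

    def test_shannon_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.integers(0, 50, size=12)
            if v.sum() == 0:
                continue
            h = shannon(v)
            assert -1e-12 <= h <= math.log((v > 0).sum()) + 1e-12


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[3, 4], [3, 4]]))
        assert bray_curtis(t).data[0, 1] == 0

    def test_disjoint_support_distance_one(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[5, 0], [0, 9]]))
        assert bray_curtis(t).data[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[2, 2], [2, 0]]))
        assert bray_curtis(t).data[0, 1] == pytest.approx(2 / 6)


class TestPcoa:
    def test_points_on_a_line_recovered_on_one_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert (res.eigenvalues > 1e-8).sum() == 1
        rec = np.abs(res.coordinates[:, 0][:, None] - res.coordinates[:, 0][None, :])
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_euclidean_input_is_isometry(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(10)]))
        rec = squareform(pdist(res.coordinates[:, :2]))
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_all_zero_distances_degenerate(self):
        res = pcoa(DistanceMatrix(np.zeros((4, 4)), ids=list("abcd")))
        assert np.all(res.eigenvalues <= 1e-12)


class TestPermanova:
    @staticmethod
    def _brute_force_p(d2, labels, f_obs):
        """Independent enumeration oracle over distinct label arrangements."""
        n = len(labels)
        seen = set()
        ge = 0
        for perm in itertools.permutations(range(n)):
            lab = tuple(labels[list(perm)])
            if lab in seen:
                continue
            seen.add(lab)
            ss_total = d2[np.triu_indices(n, 1)].sum() / n
            ss_within = 0.0
            for g in set(lab):
                idx = [i for i, l in enumerate(lab) if l == g]
                sub = d2[np.ix_(idx, idx)]
                ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
            a = len(set(lab))
            f = ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))
            if f >= f_obs - 1e-12:
                ge += 1
        return ge / len(seen)

    def test_exhaustive_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.5
        d = squareform(pdist(pts))
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = permanova(DistanceMatrix(d, ids=list("abcdef")), labels, exhaustive=True)
        oracle = self._brute_force_p(d**2, labels, res.f_statistic)
        assert res.p_value == pytest.approx(oracle)

    def test_all_identical_labels_error(self):
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=list("abcd"))
        with pytest.raises(CohortError):
            permanova(d, ["g"] * 4)

    def test_separated_clusters_r2_near_one(self):
        rng = np.random.default_rng(4)
        pts = np.vstack([rng.normal(0, 0.01, (5, 2)), rng.normal(50, 0.01, (5, 2))])
        d = squareform(pdist(pts))
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(DistanceMatrix(d, ids=[str(i) for i in range(10)]), labels,
                        n_perm=99, seed=0)
        assert res.r_squared > 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        d = squareform(pdist(rng.normal(size=(12, 3))))
        dm = DistanceMatrix(d, ids=[str(i) for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        r1 = permanova(dm, labels, n_perm=199, seed=11)
        r2 = permanova(dm, labels, n_perm=199, seed=11)
        assert r1.p_value == r2.p_value


class TestIndividualVariability:
    def test_identical_within_disjoint_between(self):
        import pandas as pd
        from ruminate.cohort import CohortDesign

        counts = np.array([[5, 0], [5, 0], [0, 5], [0, 5]])
        t = FeatureTable(["a1", "a2", "b1", "b2"], ["x", "y"], counts)
        frame = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "b1", "b2"],
                "subject_id": ["A", "A", "B", "B"],
                "day": [-21, 1, -21, 1],
                "habitat": ["rumen"] * 4,
            }
        )
        out = individual_variability(bray_curtis(t), CohortDesign(frame))
        assert out.loc["A", "intra"] == 0
        assert out.loc["A", "inter"] == 1

    def test_matches_pair_enumeration_oracle(self):
        import pandas as pd
        from ruminate.cohort import CohortDesign

        rng = np.random.default_rng(6)
        counts = rng.integers(1, 30, size=(9, 5))
        ids = [f"s{i}" for i in range(9)]
        subj = [f"c{i // 3}" for i in range(9)]
        t = FeatureTable(ids, list("abcde"), counts)
        frame = pd.DataFrame(
            {"sample_id": ids, "subject_id": subj,
             "day": [-21, 1, 3] * 3, "habitat": ["rumen"] * 9}
        )
        dm = bray_curtis(t)
        out = individual_variability(dm, CohortDesign(frame))
        # oracle: direct enumeration of within- and between-subject pairs
        d = dm.data
        for s in ("c0", "c1", "c2"):
            own = [i for i in range(9) if subj[i] == s]
            other = [i for i in range(9) if subj[i] != s]
            intra = np.median([d[i, j] for i, j in itertools.combinations(own, 2)])
            inter = np.median([d[i, j] for i in own for j in other])
            assert out.loc[s, "intra"] == pytest.approx(intra)
            assert out.loc[s, "inter"] == pytest.approx(inter)
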