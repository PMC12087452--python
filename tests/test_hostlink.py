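import numpy as np
import pandas as pd
import pytest

from ruminate.cohort import CohortDesign, CohortError, FeatureTable
from ruminate.diversity import OrdinationResult
from ruminate.hostlink import (
    compare_residuals,
    envfit,
    procrustes,
    rbhb,
    source_track,
    succession_type_effects,
    track_fecal_sources,
)


def _ordination(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(coords))]
    k = coords.shape[1]
    return OrdinationResult(ids, coords, np.ones(k), np.full(k, 1.0 / k))


class TestProcrustes:
    def test_rotated_scaled_copy_gives_zero_m2(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(12, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b = 3.0 * a @ R + 5.0
        res = procrustes(_ordination(a), _ordination(b), n_perm=49, seed=0)
        assert res.m_squared <= 1e-10

    def test_m2_invariant_to_joint_rigid_motion(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(10, 2)), rng.normal(size=(10, 2))
        base = procrustes(_ordination(a), _ordination(b), n_perm=9, seed=0)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = procrustes(
            _ordination(2.0 * a @ R + 1.0), _ordination(2.0 * b @ R + 1.0),
            n_perm=9, seed=0,
        )
        assert moved.m_squared == pytest.approx(base.m_squared, abs=1e-10)

    def test_independent_configurations_near_one(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(100, 2)), rng.normal(size=(100, 2))
        res = procrustes(_ordination(a), _ordination(b), n_perm=99, seed=0)
        assert res.m_squared > 0.8

    def test_too_few_shared_samples_rejected(self):
        a = _ordination(np.eye(2), ids=["x", "y"])
        with pytest.raises(CohortError):
            procrustes(a, a, n_perm=9)


class TestCompareResiduals:
    def test_identical_residuals_p_one(self):
        r = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        out = compare_residuals(r, r.copy())
        assert out["p_value"] == 1.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(3)
        idx = [f"s{i}" for i in range(50)]
        a = pd.Series(rng.normal(1.0, 0.1, 50), index=idx)
        out = compare_residuals(a, a + 0.2)
        assert out["p_value"] < 0.01
        assert out["median_difference"] == pytest.approx(-0.2, abs=1e-9)

    def test_unmatched_sets_rejected(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(CohortError):
            compare_residuals(a, b)


class TestSourceTracking:
    def test_single_source_sink_recovered(self):
        rng = np.random.default_rng(4)
        # two clearly distinct source communities (sparse Dirichlet shapes)
        src1 = rng.multinomial(5000, rng.dirichlet(np.full(40, 0.3)))
        src2 = rng.multinomial(5000, rng.dirichlet(np.full(40, 0.3)))
        sink = rng.multinomial(1500, src1 / src1.sum())
        table = FeatureTable(["sink"], [f"t{i}" for i in range(40)], sink[None, :])
        prof = source_track(
            table, [("one", src1), ("two", src2)],
            burn_in=100, draws=15, restarts=2, seed=0,
        )
        assert prof.proportions.loc["sink", "one"] >= 0.9
        np.testing.assert_allclose(prof.proportions.sum(axis=1), 1.0, atol=1e-8)

    def test_disjoint_sink_goes_to_unknown(self):
        src = np.zeros(30, dtype=int)
        src[:15] = 100
        sink = np.zeros(30, dtype=int)
        sink[15:] = 50  # taxa never seen in the source
        table = FeatureTable(["sink"], [f"t{i}" for i in range(30)], sink[None, :])
        prof = source_track(
            table, [("src", src)], burn_in=30, draws=10, restarts=3, seed=0
        )
        assert prof.proportions.loc["sink", "unknown"] >= 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        src = rng.integers(0, 50, size=20)
        sink = rng.multinomial(300, np.ones(20) / 20)
        table = FeatureTable(["sink"], [f"t{i}" for i in range(20)], sink[None, :])
        kw = dict(burn_in=20, draws=5, restarts=2, seed=3)
        p1 = source_track(table, [("s", src)], **kw).proportions
        p2 = source_track(table, [("s", src)], **kw).proportions
        pd.testing.assert_frame_equal(p1, p2)

    def test_fecal_design_uses_prior_feces_and_same_day_rumen(self):
        # two subjects, two days, both habitats; feces at day 1 resampled
        # from feces at day -21 -> prior-feces proportion should dominate
        rng = np.random.default_rng(6)
        taxa = [f"t{i}" for i in range(30)]
        rows, ids, counts = [], [], []
        for subj in ("c1", "c2"):
            fecal_prev = rng.integers(1, 100, size=30)
            rumen_same = np.zeros(30, dtype=int)
            rumen_same[:5] = 200  # rumen profile disjoint from feces
            sink = rng.multinomial(800, fecal_prev / fecal_prev.sum())
            for day, habitat, vec in (
                (-21, "feces", fecal_prev),
                (1, "feces", sink),
                (1, "rumen", rumen_same),
            ):
                sid = f"{subj}.d{day}.{habitat}"
                ids.append(sid)
                counts.append(vec)
                rows.append({"sample_id": sid, "subject_id": subj,
                             "day": day, "habitat": habitat})
        table = FeatureTable(ids, taxa, np.asarray(counts))
        design = CohortDesign(pd.DataFrame(rows))
        out = track_fecal_sources(
            table, design, burn_in=30, draws=10, restarts=2, seed=0
        )
        assert len(out) == 2
        assert (out["prior_feces"] > 0.7).all()
        assert (out["same_day_rumen"] < 0.2).all()


class TestEnvfit:
    def test_covariate_equal_to_axis_fits_perfectly(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(30, 2))
        cov = pd.DataFrame({"v": coords[:, 0]}, index=[f"s{i}" for i in range(30)])
        out = envfit(_ordination(coords), cov, n_perm=99, seed=0)
        assert out.loc["v", "r2"] == pytest.approx(1.0)
        assert out.loc["v", "p"] == pytest.approx(1 / 100)

    def test_separable_factor_r2_near_one(self):
        coords = np.vstack([np.random.default_rng(8).normal(0, 0.05, (10, 2)),
                            np.random.default_rng(9).normal(4, 0.05, (10, 2))])
        ids = [f"s{i}" for i in range(20)]
        cov = pd.DataFrame({"grp": ["a"] * 10 + ["b"] * 10}, index=ids)
        out = envfit(_ordination(coords, ids), cov, n_perm=99, seed=0)
        assert out.loc["grp", "r2"] > 0.99

    def test_constant_covariate_flagged(self):
        coords = np.random.default_rng(10).normal(size=(12, 2))
        cov = pd.DataFrame({"c": np.ones(12)}, index=[f"s{i}" for i in range(12)])
        out = envfit(_ordination(coords), cov, n_perm=9, seed=0)
        assert out.loc["c", "r2"] == 0.0
        assert bool(out.loc["c", "constant"])

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(25, 2))
        v = coords[:, 0] + rng.normal(0, 0.5, 25)
        ids = [f"s{i}" for i in range(25)]
        o = _ordination(coords, ids)
        r_raw = envfit(o, pd.DataFrame({"v": v}, index=ids), n_perm=9, seed=1)
        r_scaled = envfit(o, pd.DataFrame({"v": 100 * v - 7}, index=ids), n_perm=9, seed=1)
        assert r_raw.loc["v", "r2"] == pytest.approx(r_scaled.loc["v", "r2"])


class TestRbhb:
    def test_printed_formula_values(self):
        assert rbhb(100, 10, 1, 10) == pytest.approx(0.25)
        assert rbhb(100, 10, 1, 1) == pytest.approx(1 / 3)

    def test_nonpositive_component_undefined(self):
        assert np.isnan(rbhb(100, 10, 0.0, 10))

    def test_vectorised(self):
        out = rbhb([100, 100], [10, 10], [1, 1], [10, 1])
        np.testing.assert_allclose(out, [0.25, 1 / 3])


class TestSuccessionTypeEffects:
    @staticmethod
    def _cohort(effect=0.0, n_subjects=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        days = [0, 1, 2]
        labels = {}
        for i in range(n_subjects):
            subj = f"c{i}"
            stages = ["S1", "S1", "S2"] if i % 2 else ["S1", "S2", "S2"]
            base = rng.normal(10, 1)
            for d, st in zip(days, stages):
                sid = f"{subj}.d{d}"
                labels[sid] = st
                val = base + rng.normal(0, 0.5)
                if st == "S2" and i % 2 == 0:
                    val += effect  # planted shift on the S1->S2 group
                rows.append({"sample_id": sid, "subject_id": subj, "day": d,
                             "habitat": "rumen", "GLU": val})
        design = CohortDesign(pd.DataFrame(rows), phenotype_cols=["GLU"])
        return design, labels

    def test_null_data_not_flagged(self):
        design, labels = self._cohort(effect=0.0, seed=1)
        out = succession_type_effects(design, labels, min_group=5)
        assert (out["kw_p_adj"] > 0.05).all()

    def test_planted_shift_flagged(self):
        design, labels = self._cohort(effect=3.0, seed=2)
        out = succession_type_effects(design, labels, min_group=5)
        assert out.loc[out.phenotype == "GLU", "kw_p_adj"].iloc[0] < 0.01

    def test_small_groups_excluded(self):
        design, labels = self._cohort(effect=0.0, seed=3, n_subjects=40)
        # a singleton transition type must be dropped, not tested
        labels[f"c0.d0"] = "S9"
        out = succession_type_effects(design, labels, min_group=5)
        assert not out.empty
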