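import numpy as np
import pandas as pd
import pytest

from ruminate.cohort import CohortError
from ruminate.mediate import (
    differential_filter,
    mediate,
    mediation_screen,
    species_zscores,
)
from ruminate.simulate import (
    SyntheticCohortConfig,
    simulate_cohort,
    simulate_mediation_triple,
)


class TestDifferentialFilter:
    def test_hand_enumerated_survivors(self):
        # 6 samples x 5 taxa: only taxa A and B pass >50% prevalence AND
        # >0.1% mean relative abundance
        data = pd.DataFrame(
            {
                "A": [500, 500, 500, 500, 500, 500],
                "B": [100, 120, 90, 100, 0, 110],
                "C": [0, 0, 0, 4, 5, 6],        # prevalence 50% (not >50%)
                "D": [0, 0, 0, 0, 0, 3],        # rare and sparse
                "E": [1, 0, 1, 0, 1, 0],        # prevalence 50%
            },
            index=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=data.index)
        out = differential_filter(data, groups)
        assert out.surviving == ["A", "B"]

    def test_prevalence_one_keeps_only_ubiquitous(self):
        data = pd.DataFrame(
            {"A": [10, 10, 10, 10], "B": [10, 10, 10, 0]},
            index=[f"s{i}" for i in range(4)],
        )
        groups = pd.Series(["x", "x", "y", "y"], index=data.index)
        out = differential_filter(data, groups, prevalence_min=0.999)
        assert out.surviving == ["A"]

    def test_null_groups_rarely_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(20):
            data = pd.DataFrame(
                rng.integers(50, 150, size=(20, 8)),
                index=[f"s{i}" for i in range(20)],
                columns=[f"f{j}" for j in range(8)],
            )
            groups = pd.Series(["x"] * 10 + ["y"] * 10, index=data.index)
            out = differential_filter(data, groups)
            hits += int((out.stats["p_adj"] < 0.05).any())
        assert hits <= 2

    def test_single_group_rejected(self):
        data = pd.DataFrame({"A": [1, 2]}, index=["s0", "s1"])
        with pytest.raises(CohortError):
            differential_filter(data, pd.Series(["x", "x"], index=data.index))

    def test_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            rng.integers(0, 100, size=(12, 6)),
            index=[f"s{i}" for i in range(12)],
            columns=list("ABCDEF"),
        )
        groups = pd.Series(["x"] * 6 + ["y"] * 6, index=data.index)
        first = differential_filter(data, groups)
        again = differential_filter(data[first.surviving], groups,
                                    prevalence_min=0.0, abundance_min=0.0)
        assert set(again.surviving) == set(first.surviving)
        shuffled = differential_filter(data[list("FEDCBA")], groups)
        assert set(shuffled.surviving) == set(first.surviving)


class TestMediate:
    def test_recovers_planted_effects(self):
        s, m, y = simulate_mediation_triple(0.5, 0.4, 0.2, noise_sd=0.1, n=500, seed=0)
        res = mediate(s, m, y, n_boot=500, seed=0)
        assert res.acme == pytest.approx(0.20, abs=0.05)
        assert res.ade == pytest.approx(0.20, abs=0.05)
        assert res.total == pytest.approx(0.40, abs=0.05)
        assert res.acme_ci[0] <= 0.20 <= res.acme_ci[1]

    def test_acme_plus_ade_equals_total_exactly(self):
        s, m, y = simulate_mediation_triple(0.7, 0.1, -0.3, n=200, seed=1)
        res = mediate(s, m, y, n_boot=200, seed=1)
        assert res.acme + res.ade == pytest.approx(res.total, abs=1e-12)
        # and the total equals the simple-regression slope of y on s
        slope = np.cov(s, y)[0, 1] / np.var(s, ddof=1)
        assert res.total == pytest.approx(slope, rel=1e-9)

    def test_broken_mediation_ci_covers_zero(self):
        s, m, y = simulate_mediation_triple(0.5, 0.0, 0.3, n=400, seed=2)
        res = mediate(s, m, y, n_boot=500, seed=2)
        assert res.acme_ci[0] <= 0.0 <= res.acme_ci[1]

    def test_collinear_mediator_flagged(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=50)
        y = 0.5 * s + rng.normal(0, 0.1, 50)
        res = mediate(s, s * 2.0 + 1.0, y, n_boot=100, seed=0)
        assert res.collinear

    def test_zero_variance_rejected(self):
        s = np.zeros(20)
        with pytest.raises(CohortError):
            mediate(s, np.arange(20), np.arange(20), n_boot=10)

    def test_deterministic_given_seed(self):
        s, m, y = simulate_mediation_triple(n=100, seed=4)
        r1 = mediate(s, m, y, n_boot=200, seed=9)
        r2 = mediate(s, m, y, n_boot=200, seed=9)
        assert r1.acme_ci == r2.acme_ci and r1.acme_p == r2.acme_p


class TestSpeciesZscores:
    def test_zero_replacement_and_standardisation(self):
        z = species_zscores(np.array([0.0, 0.01, 0.1, 0.4]))
        assert np.isfinite(z).all()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)


class TestMediationScreen:
    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = SyntheticCohortConfig(n_subjects=60, habitats=("rumen",), seed=7)
        table, design, _, pathways, truth = simulate_cohort(cfg)
        phen = design.frame.set_index("sample_id")[["NEFA", "INS", "TG"]]
        return table, pathways, phen, truth

    def test_planted_triples_rank_as_full_mediations(self, cohort):
        table, pathways, phen, truth = cohort
        out = mediation_screen(
            table, pathways, phen, n_boot=300, seed=0,
            species_abundance_min=0.0001,
        )
        full = out[out.full]
        planted = {(t["species"], t["pathway"], t["phenotype"])
                   for t in truth.mediation_triples}
        found = set(map(tuple, full[["species", "pathway", "phenotype"]].to_numpy()))
        assert planted <= found
        # every extra discovery must be signal-linked: same mediator pathway
        # and phenotype as a planted triple, through a species whose
        # abundance tracks the planted species (state block-mates)
        from ruminate.mediate import species_zscores

        rel = table.relative_abundance()
        t_idx = {t: j for j, t in enumerate(table.taxon_ids)}
        planted_by_pw = {(t["pathway"], t["phenotype"]): t["species"]
                         for t in truth.mediation_triples}
        for sp, pw, ph in found - planted:
            # the causal route itself must be a planted one: the pathway and
            # phenotype carry real signal, the species is merely a proxy
            assert (pw, ph) in planted_by_pw
            anchor = planted_by_pw[(pw, ph)]
            r = np.corrcoef(
                species_zscores(rel[:, t_idx[sp]]),
                species_zscores(rel[:, t_idx[anchor]]),
            )[0, 1]
            assert abs(r) > 0.1

    def test_permuted_phenotypes_yield_no_full_set(self, cohort):
        table, pathways, phen, _ = cohort
        rng = np.random.default_rng(1)
        shuffled = phen.copy()
        shuffled[:] = phen.to_numpy()[rng.permutation(len(phen))]
        out = mediation_screen(
            table, pathways, shuffled, n_boot=200, seed=1,
            species_abundance_min=0.0001,
        )
        assert out[out.full].empty

    def test_empty_survivor_set_returns_empty(self, cohort):
        table, pathways, phen, _ = cohort
        out = mediation_screen(
            table, pathways, phen, prevalence_min=1.1, n_boot=50, seed=0
        )
        assert out.empty
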