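"""The six causal-strength measures against enumeration oracles."""

import numpy as np
import pandas as pd
import pytest

from causalworlds import (
    ElectoralMap,
    WorldEnsemble,
    cesm,
    cesm_exhaustive,
    delta_p_interventional,
    delta_p_observational,
    necessity,
    nsm_score,
    pivotality,
    power_pc,
    score_all,
    sufficiency_strength,
)
from causalworlds.causal_measures import (
    MEASURES,
    cesm_mc_se,
    pivotality_brute_force,
    twin_pair,
)

from conftest import enumerate_product_ensemble, weighted_pearson

# Frozen from the enumeration oracle on the conjunctive toy (A p=.9/2 votes,
# B p=.5/1 vote, threshold 3): CESM equals the weighted Pearson r of S with P.
CESM_A_CONJUNCTIVE = 0.30151134457776363
CESM_B_CONJUNCTIVE = 0.9045340337332909


def toy_map(votes=(2, 1), threshold=3) -> ElectoralMap:
    return ElectoralMap(tuple("AB"), votes, threshold)


class TestTwinPair:
    def test_win_win_versus_lose_lose_contributes_ratio_one(self):
        # focal unit won and presidency won; twin loses both
        emap = toy_map(votes=(2, 1), threshold=2)
        pair = twin_pair(np.array([1, 1]), "A", emap, twin_value=0)
        assert pair.delta_s == -1 and pair.delta_p == -1
        assert pair.ratio == 1.0

    def test_unchanged_twin_has_no_ratio(self):
        pair = twin_pair(np.array([1, 1]), "A", toy_map(), twin_value=1)
        assert pair.delta_s == 0
        with pytest.raises(ValueError):
            pair.ratio


class TestCESM:
    def test_conjunctive_toy_matches_enumeration_oracle(self, conjunctive_toy):
        assert cesm_exhaustive(conjunctive_toy, "A") == pytest.approx(
            CESM_A_CONJUNCTIVE, abs=1e-12
        )
        assert cesm_exhaustive(conjunctive_toy, "B") == pytest.approx(
            CESM_B_CONJUNCTIVE, abs=1e-12
        )

    def test_constant_unit_scores_zero(self):
        emap = toy_map(threshold=2)
        ens = WorldEnsemble(emap, np.array([[1, 0], [1, 1], [1, 0]]))
        assert cesm_exhaustive(ens, "A") == 0.0
        assert cesm(ens, "A", rng=0) == 0.0

    def test_sampled_version_is_reproducible_and_near_exhaustive(
        self, conjunctive_toy
    ):
        big = WorldEnsemble(
            conjunctive_toy.map,
            np.repeat(conjunctive_toy.outcomes, 500, axis=0),
            np.repeat(conjunctive_toy.weights, 500),
        )
        a = cesm(big, "B", rng=42)
        assert a == cesm(big, "B", rng=42)
        se = cesm_mc_se(big, "B")
        assert abs(a - cesm_exhaustive(big, "B")) < 3 * se

    def test_equals_weighted_pearson_on_independent_ensembles(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(2, 9)
            votes = rng.integers(1, 10, size=n)
            emap = ElectoralMap(
                tuple(f"u{i}" for i in range(n)),
                tuple(int(v) for v in votes),
                int(rng.integers(1, votes.sum() + 1)),
            )
            probs = rng.uniform(0.1, 0.9, size=n)
            ens = enumerate_product_ensemble(emap, probs)
            if ens.sd_presidency == 0:
                continue
            p_vec = ens.presidency.astype(float)
            for j in rng.choice(n, size=min(3, n), replace=False):
                unit = emap.units[j]
                oracle = weighted_pearson(
                    ens.outcomes[:, j].astype(float), p_vec, ens.weights
                )
                assert cesm_exhaustive(ens, unit) == pytest.approx(oracle, abs=1e-12)

    def test_conjunctive_prefers_improbable_disjunctive_prefers_probable(
        self, conjunctive_toy, disjunctive_toy
    ):
        # both-needed rule: the less likely win (B) is the stronger cause;
        # either-suffices rule: the ordering reverses.
        assert cesm_exhaustive(conjunctive_toy, "B") > cesm_exhaustive(
            conjunctive_toy, "A"
        )
        assert cesm_exhaustive(disjunctive_toy, "A") > cesm_exhaustive(
            disjunctive_toy, "B"
        )

    def test_errors(self, conjunctive_toy):
        with pytest.raises(KeyError):
            cesm_exhaustive(conjunctive_toy, "Z")
        one = WorldEnsemble(toy_map(), np.array([[1, 1]]))
        with pytest.raises(ValueError):
            cesm(one, "A", rng=0)


class TestNecessity:
    def test_threshold_examples(self):
        emap = toy_map(threshold=2)
        world = np.array([1, 1])
        assert necessity(world, "A", emap) is True  # 1 < 2 after flip
        assert necessity(world, "B", emap) is False  # 2 >= 2 remains

    def test_exact_k_of_n_makes_every_yes_voter_necessary(self):
        emap = ElectoralMap(tuple(f"v{i}" for i in range(7)), (1,) * 7, 4)
        world = np.array([1, 1, 1, 1, 0, 0, 0])
        for u in ("v0", "v1", "v2", "v3"):
            assert necessity(world, u, emap) is True

    def test_requires_occurred_outcome(self):
        with pytest.raises(ValueError, match="occurred"):
            necessity(np.array([0, 0]), "A", toy_map())


class TestSufficiency:
    def test_conjunctive_toy_equals_partner_probability(self, conjunctive_toy):
        # qualifying worlds lost A and the presidency; forcing A wins iff B won
        assert sufficiency_strength(conjunctive_toy, "A", min_sims=1) == pytest.approx(
            0.5
        )

    def test_unit_meeting_threshold_alone_is_fully_sufficient(self):
        emap = ElectoralMap(("big", "small"), (5, 1), 5)
        ens = enumerate_product_ensemble(emap, np.array([0.5, 0.5]))
        assert sufficiency_strength(ens, "big", min_sims=1) == pytest.approx(1.0)

    def test_min_sims_filter_boundary(self):
        emap = toy_map(threshold=3)
        # 9 qualifying simulations (A lost, presidency lost)
        rows = np.array([[0, 1]] * 9 + [[1, 1]] * 11)
        ens = WorldEnsemble(emap, rows)
        assert np.isnan(sufficiency_strength(ens, "A", min_sims=10))
        assert not np.isnan(sufficiency_strength(ens, "A", min_sims=9))


class TestNSM:
    def test_combination_rule(self, conjunctive_toy):
        actual = np.array([1, 1])
        # A and B are both necessary under the conjunctive threshold
        p_a = conjunctive_toy.p_win("A")
        suff_a = sufficiency_strength(conjunctive_toy, "A", min_sims=1)
        got = nsm_score(conjunctive_toy, "A", actual, min_sims=1)
        assert got == pytest.approx(1.0 + p_a * suff_a)

    def test_non_necessary_unit_keeps_only_sufficiency_term(self):
        emap = ElectoralMap(("A", "B", "C"), (2, 2, 1), 3)
        probs = np.array([0.6, 0.6, 0.5])
        ens = enumerate_product_ensemble(emap, probs)
        actual = np.array([1, 1, 1])  # 5 votes: C not necessary
        assert not necessity(actual, "C", emap)
        expected = ens.p_win("C") * sufficiency_strength(ens, "C", min_sims=1)
        assert nsm_score(ens, "C", actual, min_sims=1) == pytest.approx(expected)

    def test_na_propagates(self, conjunctive_toy):
        assert np.isnan(
            nsm_score(conjunctive_toy, "A", np.array([1, 1]), min_sims=10**6)
        )


class TestPivotality:
    @pytest.mark.parametrize("n_yes,k,strength", [(6, 0, 1.0), (7, 1, 0.5)])
    def test_committee_worked_examples(self, n_yes, k, strength):
        emap = ElectoralMap.majority([f"v{i}" for i in range(11)], [1] * 11)
        world = np.array([1] * n_yes + [0] * (11 - n_yes))
        assert pivotality(world, "v0", emap) == (k, strength)

    def test_weighted_toy_matches_brute_force(self):
        emap = ElectoralMap(("a", "b", "c", "d"), (5, 3, 2, 4), 6)
        world = np.array([1, 1, 1, 0])
        assert pivotality(world, "c", emap) == pivotality_brute_force(world, "c", emap)

    def test_dp_equals_brute_force_on_random_maps(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            votes = tuple(int(v) for v in rng.integers(1, 12, size=n))
            emap = ElectoralMap(tuple(f"u{i}" for i in range(n)), votes, 1)
            world = rng.integers(0, 2, size=n)
            won = np.nonzero(world)[0]
            if won.size == 0:
                continue
            threshold = int(rng.integers(1, world @ np.array(votes) + 1))
            emap = ElectoralMap(emap.units, votes, threshold)
            focal = emap.units[int(rng.choice(won))]
            got = pivotality(world, focal, emap)
            want = pivotality_brute_force(world, focal, emap)
            assert got == want or (np.isnan(got[0]) and np.isnan(want[0]))

    def test_strength_one_iff_necessary(self):
        emap = ElectoralMap(("A", "B", "C"), (3, 2, 2), 4)
        world = np.array([1, 1, 0])
        for u in ("A", "B"):
            k, s = pivotality(world, u, emap)
            assert (s == 1.0) == necessity(world, u, emap)

    def test_unreachable_pivotal_configuration_is_na(self):
        # a 1-vote focal unit can never be pivotal for threshold 2 when the
        # only other unit carries 10 votes
        emap = ElectoralMap(("A", "B"), (1, 10), 2)
        k, s = pivotality(np.array([1, 1]), "A", emap)
        assert np.isnan(k) and np.isnan(s)

    def test_preconditions(self):
        emap = toy_map(threshold=2)
        with pytest.raises(ValueError, match="occurred"):
            pivotality(np.array([0, 0]), "A", emap)
        with pytest.raises(ValueError, match="not won"):
            pivotality(np.array([1, 0]), "B", emap)


class TestProbabilisticContrasts:
    def test_conjunctive_toy_values(self, conjunctive_toy):
        assert delta_p_observational(conjunctive_toy, "A") == pytest.approx(0.5)
        assert delta_p_interventional(conjunctive_toy, "A") == pytest.approx(0.5)
        assert power_pc(conjunctive_toy, "A") == pytest.approx(0.5)

    def test_degenerate_strata_are_na(self):
        emap = toy_map(threshold=2)
        ens = WorldEnsemble(emap, np.array([[1, 0], [1, 1]]))
        assert np.isnan(delta_p_observational(ens, "A"))  # no S=0 stratum
        assert np.isnan(power_pc(ens, "A"))

    def test_power_pc_guard_when_baseline_certain(self):
        # B irrelevant: A alone wins; P(P | not B) = p(A) = 1 in this ensemble
        emap = ElectoralMap(("A", "B"), (2, 1), 2)
        ens = WorldEnsemble(emap, np.array([[1, 0], [1, 1]]))
        assert np.isnan(power_pc(ens, "B"))

    def test_interventional_equals_observational_under_independence(self):
        rng = np.random.default_rng(5)
        emap = ElectoralMap(("A", "B", "C"), (3, 2, 2), 4)
        ens = enumerate_product_ensemble(emap, rng.uniform(0.2, 0.8, 3))
        for u in emap.units:
            assert delta_p_interventional(ens, u) == pytest.approx(
                delta_p_observational(ens, u), abs=1e-12
            )

    def test_they_differ_under_a_shared_national_shock(self, preset_ensemble):
        # observational contrast absorbs the national swing; interventional not
        diff = abs(
            delta_p_observational(preset_ensemble, "VT")
            - delta_p_interventional(preset_ensemble, "VT")
        )
        assert diff > 0.1

    def test_irrelevant_unit_has_zero_interventional_contrast(self):
        emap = ElectoralMap(("A", "B"), (5, 1), 5)
        ens = WorldEnsemble(emap, np.array([[1, 0], [1, 1]]))
        assert delta_p_interventional(ens, "B") == 0.0


class TestScoreAll:
    def test_table_covers_won_units_with_all_measures(self, conjunctive_toy):
        table = score_all(conjunctive_toy, np.array([1, 1]), min_sims=1)
        assert list(table.columns) == list(MEASURES)
        assert list(table.index) == ["A", "B"]

    def test_measure_subset(self, conjunctive_toy):
        table = score_all(
            conjunctive_toy, np.array([1, 1]), measures=("cesm", "pivotality")
        )
        assert list(table.columns) == ["cesm", "pivotality"]

    def test_same_seed_reproduces_sampled_table(self, conjunctive_toy):
        kw = dict(cesm_mode="sampled", seed=3, min_sims=1)
        t1 = score_all(conjunctive_toy, np.array([1, 1]), **kw)
        t2 = score_all(conjunctive_toy, np.array([1, 1]), **kw)
        pd.testing.assert_frame_equal(t1, t2)

    def test_rejects_losing_actual_world(self, conjunctive_toy):
        with pytest.raises(ValueError, match="won"):
            score_all(conjunctive_toy, np.array([0, 1]))

    def test_scores_invariant_to_row_order_and_duplication(self, conjunctive_toy):
        base = score_all(conjunctive_toy, np.array([1, 1]), min_sims=1)
        rng = np.random.default_rng(0)
        perm = rng.permutation(conjunctive_toy.n_sims)
        shuffled = WorldEnsemble(
            conjunctive_toy.map,
            conjunctive_toy.outcomes[perm],
            conjunctive_toy.weights[perm],
        )
        doubled = WorldEnsemble(
            conjunctive_toy.map,
            np.vstack([conjunctive_toy.outcomes] * 2),
            np.hstack([conjunctive_toy.weights] * 2),
        )
        for variant in (shuffled, doubled):
            other = score_all(variant, np.array([1, 1]), min_sims=1)
            pd.testing.assert_frame_equal(base, other, check_exact=False, atol=1e-12)

    def test_preset_nsm_bounds_and_na_pattern(self, preset_scores):
        table = preset_scores
        assert table["cesm"].between(-1, 1).all()
        assert table["pivotality"].dropna().between(0, 1).all()
        for col in ("delta_p_obs", "delta_p_int"):
            assert table[col].dropna().between(-1, 1).all()
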