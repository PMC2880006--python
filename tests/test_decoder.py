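"""Viterbi decoding: initialization, induction, backtracking, full decode."""
import numpy as np
import pytest

import pepdesign as pkg
from pepdesign import (
    DecodeConfig,
    DegenerateModelError,
    EnergyTables,
    InputError,
    ObservationSet,
    PairTable,
    PlantSpec,
    SingletTable,
    Thermo,
)
from pepdesign.decoder import backtrack, induct, initialize, score_sequence
from conftest import brute_force_decode, model_log_terms, random_energy_tables


def uniform_obs(tables, regions=None):
    return pkg.synth_observations(tables, "uniform", regions=regions)


class TestInitialize:
    def test_uniform_inputs_give_equal_deltas(self):
        delta = initialize(
            np.full(20, 1 / 20), np.full(20, 3), SingletTable.uniform()
        )
        np.testing.assert_allclose(delta, np.log(1 / 20) + np.log(1 / 11))

    def test_concentrated_binding_probability_dominates(self):
        eps = 1e-9
        p1 = np.full(20, eps)
        w = pkg.AA_ORDER.index("W")
        p1[w] = 1 - 19 * eps
        delta = initialize(p1, np.full(20, 3), SingletTable.uniform())
        assert int(np.argmax(delta)) == w

    def test_matches_per_residue_product(self):
        rng = np.random.default_rng(0)
        p1 = rng.dirichlet(np.ones(20))
        obs = rng.integers(1, 12, size=20)
        s = SingletTable.uniform()
        s.values = rng.dirichlet(np.ones(11), size=20)
        delta = initialize(p1, obs, s)
        for i in range(20):
            assert delta[i] == pytest.approx(
                np.log(p1[i]) + np.log(s.values[i, obs[i] - 1]), rel=1e-12
            )

    def test_missing_observation_shape_is_rejected(self):
        with pytest.raises(InputError, match="first-grid"):
            initialize(np.full(20, 1 / 20), np.full(19, 3), SingletTable.uniform())


class TestInduct:
    def test_uniform_step_adds_a_constant(self):
        rng = np.random.default_rng(1)
        delta = rng.normal(size=20)
        log_a = np.full((20, 20), np.log(1 / 20))
        log_b = np.full((20, 20), np.log(1 / 121))
        nxt, bp = induct(delta, log_a, log_b)
        np.testing.assert_allclose(
            nxt, delta.max() + np.log(1 / 20) + np.log(1 / 121)
        )
        assert (bp == int(np.argmax(delta))).all()

    def test_identity_dominant_transitions_point_back_to_self(self):
        delta = np.zeros(20)
        log_a = np.full((20, 20), -50.0)
        np.fill_diagonal(log_a, -1.0)
        nxt, bp = induct(delta, log_a, np.zeros((20, 20)))
        np.testing.assert_array_equal(bp, np.arange(20))

    def test_matches_explicit_loop_maximum(self):
        rng = np.random.default_rng(2)
        delta = rng.normal(size=20)
        log_a = rng.normal(size=(20, 20))
        log_b = rng.normal(size=(20, 20))
        nxt, bp = induct(delta, log_a, log_b)
        for j in range(20):
            col = [delta[i] + log_a[i, j] + log_b[i, j] for i in range(20)]
            assert nxt[j] == pytest.approx(max(col), rel=1e-12)
            assert bp[j] == int(np.argmax(col))

    def test_fully_impossible_step_raises_naming_the_grid(self):
        delta = np.full(20, -np.inf)
        with pytest.raises(DegenerateModelError, match="grid 2"):
            induct(delta, np.zeros((20, 20)), np.zeros((20, 20)), grid=2)


class TestBacktrack:
    def test_length_one_returns_argmax_of_delta1(self):
        delta1 = np.array([0.1, 0.9, 0.3])
        seq, score = backtrack([delta1], [], "ACD")
        assert seq == "C" and score == pytest.approx(0.9)

    def test_planted_strictly_dominant_path_is_recovered(self, thermo):
        spec = PlantSpec(planted_sequence="WYVAL", margin=1.0, noise_sd=0.2, seed=4)
        tab = pkg.synth_energy_tables(spec)
        res = pkg.decode(tab, thermo, uniform_obs(tab),
                         SingletTable.uniform(), PairTable.uniform())
        assert res.sequence == "WYVAL"

    def test_matches_enumeration_on_small_random_instance(self, thermo):
        rng = np.random.default_rng(3)
        tab = random_energy_tables(rng, "AC", 3)
        obs = pkg.synth_observations(tab, "random", seed=3,
                                     regions=pkg.RegionSet.default())
        s, p = SingletTable.uniform(), PairTable.uniform()
        s.values = rng.dirichlet(np.ones(11), size=20)
        p.values = rng.dirichlet(np.ones(11), size=(20, 20))
        res = pkg.decode(tab, thermo, obs, s, p)
        ref_seq, ref_score, _ = brute_force_decode(tab, thermo, obs, s, p)
        assert res.sequence == ref_seq
        assert res.log_score == pytest.approx(ref_score, abs=1e-10)


class TestDecode:
    def test_fully_uniform_model_closed_form(self, thermo):
        n = 3
        tab = EnergyTables(np.zeros(20), [np.zeros((20, 20))] * (n - 1))
        res = pkg.decode(tab, thermo, uniform_obs(tab),
                         SingletTable.uniform(), PairTable.uniform())
        expected = (
            np.log(1 / 20) + (n - 1) * np.log(1 / 121)
            + np.log(1 / 11) + (n - 1) * np.log(1 / 20)
        )
        assert res.sequence == "AAA"  # tie-break: lowest canonical index
        assert res.log_score == pytest.approx(expected, abs=1e-10)

    def test_matches_brute_force_over_all_tripeptides(self, thermo, regions):
        rng = np.random.default_rng(21)
        tab = random_energy_tables(rng, pkg.AA_ORDER, 3, scale=1.5)
        obs = pkg.synth_observations(tab, "random", seed=21, regions=regions)
        s, p = SingletTable.uniform(), PairTable.uniform()
        s.values = rng.dirichlet(np.ones(11), size=20)
        p.values = rng.dirichlet(np.ones(11), size=(20, 20))
        res = pkg.decode(tab, thermo, obs, s, p)
        ref_seq, ref_score, total = brute_force_decode(tab, thermo, obs, s, p)
        assert res.sequence == ref_seq
        assert res.log_score == pytest.approx(ref_score, abs=1e-10)
        assert not (total > res.log_score + 1e-12).any()

    def test_rescoring_the_decoded_sequence_reproduces_log_score(self, thermo, regions):
        rng = np.random.default_rng(22)
        tab = random_energy_tables(rng, pkg.AA_ORDER, 5)
        obs = pkg.synth_observations(tab, "random", seed=22, regions=regions)
        res = pkg.decode(tab, thermo, obs, SingletTable.uniform(), PairTable.uniform())
        log_p1, log_e1, log_trans, log_B = model_log_terms(
            tab, thermo, obs, SingletTable.uniform(), PairTable.uniform()
        )
        total, breakdown = score_sequence(
            res.sequence, log_p1, log_e1, log_trans, log_B, tab.alphabet
        )
        assert total == pytest.approx(res.log_score, abs=1e-10)
        flat = sum((v for v in res.breakdown.values()), [])
        assert sum(flat) == pytest.approx(res.log_score, abs=1e-10)

    def test_scaling_emissions_shifts_score_but_not_sequence(self, thermo, regions):
        rng = np.random.default_rng(23)
        tab = random_energy_tables(rng, pkg.AA_ORDER, 4)
        obs = pkg.synth_observations(tab, "random", seed=23, regions=regions)
        s = SingletTable.uniform()
        base = pkg.decode(tab, thermo, obs, s, PairTable.uniform())
        for c in (0.5, 3.0):
            scaled = PairTable.uniform()
            scaled.values = scaled.values * c
            got = pkg.decode(tab, thermo, obs, s, scaled)
            assert got.sequence == base.sequence
            assert got.log_score == pytest.approx(
                base.log_score + (tab.n - 1) * np.log(c), abs=1e-10
            )

    def test_adversarial_observations_with_zero_floor_veto_the_planted_path(self, thermo):
        spec = PlantSpec(planted_sequence="WYV", margin=1.0, seed=5)
        tab = pkg.synth_energy_tables(spec)
        obs = pkg.synth_observations(tab, "adversarial", planted_sequence="WYV")
        res = pkg.decode(tab, thermo, obs, SingletTable.uniform(),
                         PairTable.uniform(), DecodeConfig(floor=0.0))
        assert res.sequence != "WYV"
        assert np.isfinite(res.log_score)

    def test_planted_recovery_across_seeds(self, thermo):
        hits = 0
        for seed in range(20):
            spec = PlantSpec(planted_sequence="MAS", margin=1.0, noise_sd=0.2, seed=seed)
            tab = pkg.synth_energy_tables(spec)
            res = pkg.decode(tab, thermo, uniform_obs(tab),
                             SingletTable.uniform(), PairTable.uniform())
            hits += res.sequence == "MAS"
        assert hits == 20

    def test_operation_count_is_quadratic_in_states_linear_in_length(self, thermo):
        for n in (2, 4, 7):
            tab = EnergyTables(np.zeros(20), [np.zeros((20, 20))] * (n - 1))
            res = pkg.decode(tab, thermo, uniform_obs(tab),
                             SingletTable.uniform(), PairTable.uniform())
            assert res.op_count == (n - 1) * 20 * 20

    def test_joint_transition_mode_matches_its_own_enumeration(self, thermo, regions):
        rng = np.random.default_rng(24)
        tab = random_energy_tables(rng, "ACD", 3)
        obs = pkg.synth_observations(tab, "random", seed=24, regions=regions)
        cfg = DecodeConfig(transition_mode="joint")
        res = pkg.decode(tab, thermo, obs, SingletTable.uniform(),
                         PairTable.uniform(), cfg)
        ref_seq, ref_score, _ = brute_force_decode(
            tab, thermo, obs, SingletTable.uniform(), PairTable.uniform(), cfg
        )
        assert res.sequence == ref_seq
        assert res.log_score == pytest.approx(ref_score, abs=1e-10)

    def test_mismatched_alphabets_are_rejected(self, thermo):
        tab = EnergyTables(np.zeros(2), [np.zeros((2, 2))], alphabet="AC")
        obs = ObservationSet(
            alphabet="AD", first_states=np.full(2, 3),
            pair_states=[np.full((2, 2, 2), 3)],
        )
        with pytest.raises(InputError, match="alphabet"):
            pkg.decode(tab, thermo, obs, SingletTable.uniform(), PairTable.uniform())

    def test_fully_unclassified_observations_with_zero_floor_are_degenerate(self, thermo):
        tab = EnergyTables(np.zeros(20), [np.zeros((20, 20))])
        obs = ObservationSet(
            alphabet=pkg.AA_ORDER,
            first_states=np.zeros(20, dtype=int),
            pair_states=[np.zeros((20, 20, 2), dtype=int)],
        )
        with pytest.raises(DegenerateModelError):
            pkg.decode(tab, thermo, obs, SingletTable.uniform(),
                       PairTable.uniform(), DecodeConfig(floor=0.0))


def test_observation_shape_validation():
    with pytest.raises(InputError, match="grid pair 1"):
        ObservationSet(
            alphabet="AC", first_states=np.full(2, 3),
            pair_states=[np.full((2, 2), 3)],
        )
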