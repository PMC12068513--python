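"""Generation grammars: staging, action legality, transitions, clustering."""

import numpy as np
import pytest
from scipy.stats import chisquare

from symfrag.chem_core import heavy_atom_count, to_smiles
from symfrag.fragment_decomposition import MarkedFragment
from symfrag.mdp_environments import (
    CHOOSE_CLUSTER,
    CHOOSE_FRAGMENT,
    IllegalActionError,
    SKIP_PI_BRIDGE,
    STAGE_BRIDGE_CLUSTER,
    ActionSpec,
    GenerationState,
    Y6Environment,
    cluster_fragments,
    enumerate_terminals,
    random_rollout,
)


class TestY6Environment:
    def test_initial_state_has_four_pending_positions(self, toy_env):
        state = toy_env.initial_state()
        assert state.stage == "core-mod"
        assert len(state.stage_data[0]) == 4

    def test_initial_state_heavy_atoms_match_core(self, toy_env):
        state = toy_env.initial_state()
        assert state.heavy_atoms == heavy_atom_count(state.mol)
        assert state.heavy_atoms == 20  # four 5-rings in a row

    def test_initial_state_deterministic(self, toy_env):
        assert toy_env.initial_state() == toy_env.initial_state()

    def test_open_marks_are_end_and_alkyl_sites(self, toy_env):
        state = toy_env.initial_state()
        assert state.open_marks == frozenset({10, 11})

    def test_alkyl_stage_offers_exactly_methyl(self, toy_env, rng):
        env = toy_env
        state = env.initial_state()
        while state.stage != "alkyl":
            state = env.step(state, env.legal_actions(state)[0], rng).next_state
        actions = env.legal_actions(state)
        assert len(actions) == 1
        nxt = env.step(state, actions[0], rng).next_state
        assert env.is_terminal(nxt)
        assert env.legal_actions(nxt) == []

    def test_pi_bridge_stage_includes_skip(self, toy_env, rng):
        env = toy_env
        state = env.initial_state()
        while state.stage != "pi-bridge":
            state = env.step(state, env.legal_actions(state)[0], rng).next_state
        kinds = {a.kind for a in env.legal_actions(state)}
        assert SKIP_PI_BRIDGE in kinds

    def test_all_transitions_deterministic(self, toy_env, rng):
        env = toy_env
        state = env.initial_state()
        while not env.is_terminal(state):
            result = env.step(state, env.legal_actions(state)[-1], rng)
            assert result.probability == 1.0
            assert result.sampled_mark is None
            state = result.next_state

    def test_illegal_action_raises(self, toy_env, rng):
        state = toy_env.initial_state()
        with pytest.raises(IllegalActionError):
            toy_env.step(state, ActionSpec("choose-alkyl", (0,)), rng)

    def test_trajectory_molecule_requires_terminal(self, toy_env):
        with pytest.raises(ValueError):
            toy_env.trajectory_molecule(toy_env.initial_state())

    def test_malformed_template_rejected(self):
        with pytest.raises(ValueError, match="core template"):
            Y6Environment({"core_template": "not-a-smiles-{x0}{x1}{x2}{x3}"})

    def test_enumeration_matches_direct_assembly(self, toy_env):
        """The grammar's terminal set equals molecules assembled directly
        from the libraries with the shared attachment primitive."""
        import itertools

        from symfrag.chem_core import (
            attach_at_mark,
            attachment_points,
            mol_from_smiles,
        )

        env = toy_env
        direct = set()
        combos = itertools.product(
            *(env.core_choices[p] for p in env.positions))
        for combo in combos:
            core_smi = env._instantiate(dict(zip(env.positions, combo)))
            for bridge in [None] + env.pi_bridges:
                for end in env.end_groups:
                    mol = mol_from_smiles(core_smi)
                    mark = 10
                    if bridge is not None:
                        mol = attach_at_mark(mol, 10, mol_from_smiles(bridge))
                        (mark,) = {a.mark for a in attachment_points(mol)
                                   if a.mark != 11}
                    mol = attach_at_mark(mol, mark, mol_from_smiles(end))
                    mol = attach_at_mark(mol, 11,
                                         mol_from_smiles(env.alkyls[0]))
                    direct.add(to_smiles(mol))
        assert sorted(direct) == enumerate_terminals(env)


class TestPatentEnvironment:
    def test_initial_state_is_empty(self, patent_env):
        state = patent_env.initial_state()
        assert state.smiles is None
        assert state.stage == "core-cluster"

    def test_cluster_choice_is_deterministic(self, patent_env, rng):
        state = patent_env.initial_state()
        action = patent_env.legal_actions(state)[0]
        assert action.kind == CHOOSE_CLUSTER
        result = patent_env.step(state, action, rng)
        assert result.probability == 1.0
        assert result.sampled_mark is None

    def test_no_bridge_actions_after_two_rounds(self, patent_env):
        state = GenerationState(
            smiles="[*:1]c1ccc([*:2])cc1", stage=STAGE_BRIDGE_CLUSTER,
            bridge_rounds=2,
        )
        kinds = {a.kind for a in patent_env.legal_actions(state)}
        assert kinds == {SKIP_PI_BRIDGE}

    def test_used_identity_masked_from_fragment_choices(self, patent_env):
        pool = patent_env.pool
        # pick a cluster holding at least two distinct fragment identities
        cluster, cidx = None, None
        for i, c in enumerate(patent_env.clusters["end"]):
            strips = {pool.fragments[m].stripped for m in c.members}
            if len(strips) > 1:
                cluster, cidx = c, i
                break
        assert cluster is not None, "fixture pool has no mixed cluster"
        used = pool.fragments[cluster.members[0]].stripped
        state = GenerationState(
            smiles="[*:1]c1ccc([*:2])cc1", stage="end-frag",
            stage_data=(cidx,), used_identities=frozenset({used}),
        )
        chosen = [a.payload[1] for a in patent_env.legal_actions(state)]
        assert chosen  # masking never empties the action set
        assert all(pool.fragments[i].stripped != used for i in chosen)

    def test_masking_relaxes_rather_than_deadlocks(self, patent_env):
        pool = patent_env.pool
        cluster = patent_env.clusters["end"][0]
        all_strips = {pool.fragments[m].stripped for m in cluster.members}
        state = GenerationState(
            smiles="[*:1]c1ccc([*:2])cc1", stage="end-frag",
            stage_data=(0,), used_identities=frozenset(all_strips),
        )
        chosen = [a.payload[1] for a in patent_env.legal_actions(state)]
        assert sorted(chosen) == sorted(cluster.members)

    def test_mark_sampling_uniform_over_k4(self, patent_env):
        state = GenerationState(
            smiles="[*:1]c1cc([*:2])c([*:3])cc1[*:4]", stage="end-frag",
            stage_data=(0,),
        )
        assert state.k_t == 4
        rng = np.random.default_rng(0)
        counts = {m: 0 for m in (1, 2, 3, 4)}
        for _ in range(10000):
            mark, prob = patent_env.sample_mark(state, rng)
            assert prob == 0.25
            counts[mark] += 1
        stat, p = chisquare(list(counts.values()))
        assert p > 0.01

    def test_single_mark_is_deterministic(self, patent_env):
        state = GenerationState(
            smiles="[*:1]c1ccc([*:1])cc1", stage="end-frag", stage_data=(0,),
        )
        assert state.k_t == 1
        rng = np.random.default_rng(0)
        mark, prob = patent_env.sample_mark(state, rng)
        assert (mark, prob) == (1, 1.0)

    def test_rollouts_respect_constraints(self, patent_env):
        """Cap, mark-uniqueness, and bridge-round constraints over random
        trajectories; attachments provably cover all equally marked sites."""
        env = patent_env
        rng = np.random.default_rng(42)
        for _ in range(200):
            state = env.initial_state()
            sampled_marks = []
            bridge_attachments = 0
            while not env.is_terminal(state):
                actions = env.legal_actions(state)
                action = actions[rng.integers(len(actions))]
                before = state
                result = env.step(state, action, rng)
                state = result.next_state
                if action.kind == CHOOSE_FRAGMENT and \
                        action.payload[0] == "bridge":
                    bridge_attachments += 1
                if result.sampled_mark is not None:
                    # each mark is consumed when filled, so it can never be
                    # sampled twice along one trajectory
                    assert result.sampled_mark not in sampled_marks
                    sampled_marks.append(result.sampled_mark)
                    frag = env.pool.fragments[action.payload[1]]
                    n_sites = sum(
                        1 for ap in
                        _aps(before) if ap.mark == result.sampled_mark)
                    delta = state.heavy_atoms - before.heavy_atoms
                    # either every marked site got a copy, or the cap fired
                    assert delta in (n_sites * frag.heavy_atoms, 0)
            assert bridge_attachments <= 2
            mol = env.trajectory_molecule(state)
            assert heavy_atom_count(mol) <= env.max_heavy_atoms

    def test_fixed_seed_reproducible_trajectories(self, patent_env):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            runs.append([
                to_smiles(patent_env.trajectory_molecule(
                    random_rollout(patent_env, rng)))
                for _ in range(10)
            ])
        assert runs[0] == runs[1]


def _aps(state):
    from symfrag.chem_core import attachment_points

    return attachment_points(state.mol)


class TestClusterFragments:
    def test_three_fragments_three_singletons(self):
        frags = [MarkedFragment(s) for s in
                 ["C[*:1]", "[*:1]c1ccccc1", "N#C[*:1]"]]
        clusters = cluster_fragments(frags, 3, seed=0)
        assert sorted(len(c.members) for c in clusters) == [1, 1, 1]

    def test_duplicate_fingerprints_share_cluster(self):
        # identical stripped structure under different marks -> same bits
        frags = [MarkedFragment("C[*:1]"), MarkedFragment("C[*:5]"),
                 MarkedFragment("[*:1]c1ccccc1")]
        clusters = cluster_fragments(frags, 2, seed=0)
        for c in clusters:
            if 0 in c.members:
                assert 1 in c.members

    def test_k_clamps_to_pool(self):
        frags = [MarkedFragment("C[*:1]"), MarkedFragment("N#C[*:1]")]
        clusters = cluster_fragments(frags, 100, seed=0)
        assert len(clusters) == 2

    def test_empty_pool_raises(self):
        with pytest.raises(ValueError):
            cluster_fragments([], 5, seed=0)

    def test_deterministic_given_seed(self, patent_pool):
        a = cluster_fragments(patent_pool.fragments, 6, seed=3)
        b = cluster_fragments(patent_pool.fragments, 6, seed=3)
        assert [c.members for c in a] == [c.members for c in b]
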