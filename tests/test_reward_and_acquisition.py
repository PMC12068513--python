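"""Penalized rewards, expected improvement, acquisition, and the AL loop."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from symfrag.chem_core import mol_from_smiles, morgan_fingerprint, tanimoto
from symfrag.mcts_engine import SearchConfig, best_in_window, run_search
from symfrag.reward_and_acquisition import (
    ConjugationBandgapOracle,
    FingerprintRidgeEnsemble,
    PerturbedOracleEnsemble,
    RewardSpec,
    acquire_batch,
    al_loop,
    expected_improvement,
    iterative_diverse_search,
    penalized_reward,
)
from symfrag.mdp_environments import random_rollout


class FixedPredictor:
    def __init__(self, value):
        self.value = value

    def predict(self, mol):
        return self.value


class TestPenalizedReward:
    def test_empty_inventory_is_pure_property(self):
        spec = RewardSpec(predictor=FixedPredictor(1.5))
        assert penalized_reward("c1ccccc1", spec) == pytest.approx(-1.5)

    def test_self_in_inventory_penalty_one(self):
        spec = RewardSpec(predictor=FixedPredictor(1.0),
                          inventory=["c1ccccc1"])
        assert penalized_reward("c1ccccc1", spec) == pytest.approx(-1.0 - 1.0)

    def test_weighted_max_aggregation_arithmetic(self):
        x, y1, y2 = "c1ccc(-c2ccccc2)cc1", "c1ccccc1", "Cc1ccccc1"
        fp = morgan_fingerprint(x)
        s1 = tanimoto(fp, morgan_fingerprint(y1))
        s2 = tanimoto(fp, morgan_fingerprint(y2))
        spec = RewardSpec(predictor=FixedPredictor(1.0),
                          similarity_weight=2.0, inventory=[y1, y2])
        assert penalized_reward(x, spec) == \
            pytest.approx(-1.0 - 2.0 * max(s1, s2))

    def test_mean_aggregation(self):
        x, y1, y2 = "c1ccc(-c2ccccc2)cc1", "c1ccccc1", "Cc1ccccc1"
        fp = morgan_fingerprint(x)
        sims = [tanimoto(fp, morgan_fingerprint(y)) for y in (y1, y2)]
        spec = RewardSpec(predictor=FixedPredictor(1.0), aggregation="mean",
                          inventory=[y1, y2])
        assert penalized_reward(x, spec) == \
            pytest.approx(-1.0 - float(np.mean(sims)))

    def test_zero_similarity_weight_ignores_inventory(self):
        bare = RewardSpec(predictor=FixedPredictor(2.0), similarity_weight=0.0)
        loaded = RewardSpec(predictor=FixedPredictor(2.0),
                            similarity_weight=0.0,
                            inventory=["c1ccccc1", "Cc1ccccc1"])
        for smiles in ("c1ccccc1", "c1ccncc1"):
            assert penalized_reward(smiles, bare) == \
                penalized_reward(smiles, loaded)

    def test_predictor_failure_carries_molecule_context(self):
        class Broken:
            def predict(self, mol):
                raise RuntimeError("boom")

        spec = RewardSpec(predictor=Broken())
        with pytest.raises(RuntimeError, match="c1ccccc1"):
            penalized_reward("c1ccccc1", spec)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RewardSpec(predictor=FixedPredictor(1.0), property_weight=0.0)
        with pytest.raises(ValueError):
            RewardSpec(predictor=FixedPredictor(1.0), similarity_weight=-1.0)


class TestExpectedImprovement:
    def test_at_the_incumbent_equals_phi_zero(self):
        assert expected_improvement(0.0, 1.0, 0.0) == \
            pytest.approx(1.0 / math.sqrt(2.0 * math.pi), abs=1e-12)

    def test_zero_sigma_limit(self):
        assert expected_improvement(-1.0, 0.0, 0.0) == 0.0
        assert expected_improvement(2.0, 0.0, 0.5) == pytest.approx(1.5)
        # near-zero sigma agrees with the exact limit
        assert expected_improvement(2.0, 1e-12, 0.5) == \
            pytest.approx(1.5, abs=1e-9)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            expected_improvement(0.0, -0.1, 0.0)

    def test_monte_carlo_oracle(self, rng):
        mu, sigma, f_star = 1.0, 0.5, 0.0
        draws = rng.normal(mu, sigma, size=10**6)
        mc = np.maximum(draws - f_star, 0.0).mean()
        assert expected_improvement(mu, sigma, f_star) == \
            pytest.approx(mc, abs=1e-3)

    def test_nonnegative_and_monotone_in_sigma(self):
        for mu in np.linspace(-2, 2, 9):
            previous = -1.0
            for sigma in np.linspace(0.01, 3, 12):
                ei = expected_improvement(float(mu), float(sigma), 0.5)
                assert ei >= 0.0
                if mu < 0.5:
                    assert ei >= previous
                previous = ei

    def test_ranking_matches_quadrature_oracle(self, rng):
        """Sorting 50 synthetic (mu, sigma) pairs by closed-form EI equals
        sorting by numerically integrated E[max(R - f*, 0)]."""
        f_star = 0.0
        pairs = [(float(rng.normal()), float(rng.uniform(0.05, 2.0)))
                 for _ in range(50)]
        closed = [expected_improvement(m, s, f_star) for m, s in pairs]

        def quad_ei(mu, sigma):
            val, _ = integrate.quad(
                lambda r: (r - f_star) * norm.pdf(r, mu, sigma),
                f_star, mu + 12 * sigma,
            )
            return val

        oracle = [quad_ei(m, s) for m, s in pairs]
        assert np.argsort(closed).tolist() == np.argsort(oracle).tolist()


class TestIterativeDiverseSearch:
    def test_single_iteration_reduces_to_plain_search(self, toy_env, oracle):
        cfg = SearchConfig(n_steps=300, window=100, seed=4)
        spec = RewardSpec(predictor=oracle)
        records = iterative_diverse_search(toy_env, spec, 1, cfg)
        plain = run_search(toy_env, lambda m: -oracle.predict(m), cfg)
        assert records[0].smiles == best_in_window(plain.ledger, 100).smiles
        assert records[0].penalty_term == 0.0

    def test_five_iterations_distinct_inventory(self, toy_env, oracle):
        spec = RewardSpec(predictor=oracle)
        records = iterative_diverse_search(
            toy_env, spec, 5, SearchConfig(n_steps=400, window=100, seed=0))
        smiles = [r.smiles for r in records]
        assert len(set(smiles)) == 5
        fps = [morgan_fingerprint(s) for s in smiles]
        for i in range(5):
            for j in range(i + 1, 5):
                assert tanimoto(fps[i], fps[j]) < 1.0
        assert records[0].penalty_term == 0.0
        assert all(r.penalty_term > 0.0 for r in records[1:])

    def test_zero_iterations_rejected(self, toy_env, oracle):
        with pytest.raises(ValueError):
            iterative_diverse_search(toy_env, RewardSpec(predictor=oracle), 0)


class TestAcquireBatch:
    def test_defaults(self):
        from symfrag.reward_and_acquisition import (
            DEFAULT_N_SAMPLES,
            DEFAULT_N_TOP,
        )

        assert (DEFAULT_N_SAMPLES, DEFAULT_N_TOP) == (10000, 100)

    def test_deduplicates_and_ranks_by_ei(self, toy_env):
        ensemble = PerturbedOracleEnsemble(ConjugationBandgapOracle(), seed=0)
        batch = acquire_batch(toy_env, ensemble, n_samples=300, n_top=20,
                              seed=1)
        assert len(batch) == 20
        assert len({b.smiles for b in batch}) == 20
        eis = [b.ei for b in batch]
        assert eis == sorted(eis, reverse=True)
        f_star = max(b.mu for b in batch)
        for b in batch:
            assert b.ei == pytest.approx(
                expected_improvement(b.mu, b.sigma, f_star), abs=1e-9)

    def test_zero_samples_rejected(self, toy_env):
        ensemble = PerturbedOracleEnsemble(ConjugationBandgapOracle())
        with pytest.raises(ValueError):
            acquire_batch(toy_env, ensemble, n_samples=0, n_top=0)

    def test_single_model_ensemble_degenerates_to_zero_sigma(self):
        ens = PerturbedOracleEnsemble(ConjugationBandgapOracle(), n_members=1,
                                      sigma=0.5)
        _, std = ens.predict_with_std(mol_from_smiles("c1ccccc1"))
        assert std == 0.0


class TestActiveLearning:
    def test_perfect_predictor_stops_first_round(self, toy_env, oracle):
        spec = RewardSpec(predictor=oracle)
        ensemble = PerturbedOracleEnsemble(oracle, seed=0)
        summaries = al_loop(
            toy_env, spec, ensemble,
            trainer_callback=lambda acquired, i: 0.0,
            stopping_rmse=0.3, max_rounds=5, n_iterations=1,
            search_config=SearchConfig(n_steps=60, window=30, seed=0),
            n_samples=50, n_top=10,
        )
        assert len(summaries) == 1
        assert summaries[0].rmse == 0.0

    def test_zero_rounds_rejected(self, toy_env, oracle):
        with pytest.raises(ValueError):
            al_loop(toy_env, RewardSpec(predictor=oracle),
                    PerturbedOracleEnsemble(oracle),
                    trainer_callback=lambda a, i: 0.0, max_rounds=0)

    def test_ridge_ensemble_rmse_shrinks_with_data(self, toy_env, oracle,
                                                   rng):
        """A trainable surrogate labelled by the oracle improves (held-out
        RMSE) as AL rounds accumulate data."""
        from symfrag.chem_core import to_smiles

        holdout = sorted({
            to_smiles(toy_env.trajectory_molecule(
                random_rollout(toy_env, rng)))
            for _ in range(60)
        })
        holdout_labels = np.array(
            [oracle.predict(mol_from_smiles(s)) for s in holdout])

        model = FingerprintRidgeEnsemble(n_members=3, seed=0)
        labelled: dict[str, float] = {}

        def trainer(acquired, round_index):
            for s in acquired:
                labelled[s] = oracle.predict(mol_from_smiles(s))
            model.fit(list(labelled), list(labelled.values()))
            preds = np.array(
                [model.predict(mol_from_smiles(s)) for s in holdout])
            return float(np.sqrt(np.mean((preds - holdout_labels) ** 2)))

        spec = RewardSpec(predictor=oracle)
        ensemble = PerturbedOracleEnsemble(oracle, seed=0)
        summaries = al_loop(
            toy_env, spec, ensemble, trainer_callback=trainer,
            stopping_rmse=0.0, max_rounds=3, n_iterations=2,
            search_config=SearchConfig(n_steps=80, window=40, seed=0),
            n_samples=60, n_top=15,
        )
        rmses = [s.rmse for s in summaries]
        assert len(rmses) == 3
        assert rmses[-1] <= rmses[0] + 0.02
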