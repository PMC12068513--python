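"""Diversity-penalized rewards, the iterative re-search loop, expected
improvement, and the active-learning round machinery.

The property reward is ``C(x) = -bandgap(x)`` (bandgaps in eV; lower
bandgap = higher reward).  At search iteration i the reward is penalized by
similarity to the inventory of previous iteration winners::

    R_i(x) = w_p * C(x) - w_s * agg_{y in Y_<i} S(x, y)

with S the Tanimoto similarity of Morgan fingerprints, ``agg`` either the
maximum (default, strongest diversity pressure) or the mean, and an empty
inventory contributing nothing.  Re-running the search with R_i and
appending each run's windowed best to the inventory yields a set of
chemically distinct, high-reward candidates.

The property predictor is a pluggable contract (``predict(mol) -> eV``;
ensembles additionally expose a prediction std).  Two reference
implementations ship here: a deterministic toy oracle mapping conjugation
extent to a bandgap, and a fingerprint ridge-regression ensemble that can
be trained on labelled SMILES.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import norm

from .chem_core import (
    Fingerprint,
    fingerprint_array,
    mol_from_smiles,
    morgan_fingerprint,
    tanimoto,
    to_smiles,
)
from .mcts_engine import SearchConfig, best_in_window, run_search
from .mdp_environments import Environment, random_rollout

logger = logging.getLogger(__name__)

AGG_MAX = "max"
AGG_MEAN = "mean"

DEFAULT_N_SAMPLES = 10000
DEFAULT_N_TOP = 100
DEFAULT_STOPPING_RMSE = 0.3  # eV


# ---------------------------------------------------------------------------
# Predictor contract and reference implementations
# ---------------------------------------------------------------------------

class PropertyPredictor(Protocol):
    """Scores a molecule with a scalar property (bandgap, eV)."""

    def predict(self, mol: Chem.Mol) -> float: ...


class EnsemblePredictor(PropertyPredictor, Protocol):
    """Predictor exposing ensemble mean and spread."""

    def predict_with_std(self, mol: Chem.Mol) -> tuple[float, float]: ...


class ConjugationBandgapOracle:
    """Deterministic toy bandgap oracle used for offline testing.

    Bandgap decreases monotonically with the extent of conjugation
    (aromatic atoms plus non-aromatic multiple-bond atoms), with a small
    deterministic heteroatom contribution so that chemically distinct
    molecules rarely tie.  Values stay in a physically plausible window
    (roughly 0.3-4 eV) but carry no quantum-chemical meaning.
    """

    def __init__(self, base: float = 4.0, floor: float = 0.3,
                 scale: float = 18.0, noise: float = 0.0,
                 noise_seed: int = 0):
        self.base = base
        self.floor = floor
        self.scale = scale
        self.noise = noise
        self._noise_rng = np.random.default_rng(noise_seed)

    @staticmethod
    def conjugated_atoms(mol: Chem.Mol) -> int:
        conj = set()
        for bond in mol.GetBonds():
            if bond.GetIsAromatic() or bond.GetIsConjugated():
                conj.add(bond.GetBeginAtomIdx())
                conj.add(bond.GetEndAtomIdx())
        return len(conj)

    def predict(self, mol: Chem.Mol) -> float:
        n_conj = self.conjugated_atoms(mol)
        hetero = sum(
            {7: 2, 8: 1, 16: 3, 34: 5, 9: 1, 17: 2}.get(a.GetAtomicNum(), 0)
            for a in mol.GetAtoms()
        )
        gap = self.floor + (self.base - self.floor) * math.exp(-n_conj / self.scale)
        gap += 0.003 * hetero
        if self.noise > 0:
            gap += float(self._noise_rng.normal(0.0, self.noise))
        return float(gap)


class FingerprintRidgeEnsemble:
    """Bagged ridge regressions on Morgan fingerprints.

    A lightweight, trainable reference implementation of the ensemble
    predictor contract: each member is fit on a bootstrap resample of the
    labelled molecules, the prediction is the member mean and the
    uncertainty the member std (0 for a single member).
    """

    def __init__(self, n_members: int = 5, alpha: float = 1.0, seed: int = 0,
                 radius: int = 2, n_bits: int = 2048):
        self.n_members = n_members
        self.alpha = alpha
        self.seed = seed
        self.radius = radius
        self.n_bits = n_bits
        self._models: list = []

    def _features(self, mols: Sequence[Chem.Mol]) -> np.ndarray:
        return np.array([
            fingerprint_array(morgan_fingerprint(m, self.radius, self.n_bits))
            for m in mols
        ])

    def fit(self, smiles: Sequence[str], labels: Sequence[float]) -> None:
        from sklearn.linear_model import Ridge

        mols = [mol_from_smiles(s) for s in smiles]
        X = self._features(mols)
        y = np.asarray(labels, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._models = []
        for _ in range(self.n_members):
            idx = rng.integers(0, len(y), size=len(y))
            model = Ridge(alpha=self.alpha)
            model.fit(X[idx], y[idx])
            self._models.append(model)

    def _member_predictions(self, mol: Chem.Mol) -> np.ndarray:
        if not self._models:
            raise RuntimeError("ensemble has not been fit")
        X = self._features([mol])
        return np.array([m.predict(X)[0] for m in self._models])

    def predict(self, mol: Chem.Mol) -> float:
        return float(self._member_predictions(mol).mean())

    def predict_with_std(self, mol: Chem.Mol) -> tuple[float, float]:
        preds = self._member_predictions(mol)
        std = float(preds.std()) if len(preds) > 1 else 0.0
        return float(preds.mean()), std


class PerturbedOracleEnsemble:
    """Synthetic ensemble built by deterministically jittering a base
    predictor; stands in for a trained model ensemble in offline demos."""

    def __init__(self, base: PropertyPredictor, n_members: int = 5,
                 sigma: float = 0.1, seed: int = 0):
        self.base = base
        self.n_members = n_members
        self.sigma = sigma
        self.seed = seed

    def _member_predictions(self, mol: Chem.Mol) -> np.ndarray:
        mu = self.base.predict(mol)
        # per-molecule deterministic jitter keyed on the canonical form
        # (crc32, not hash(): stable across processes)
        import zlib

        key = zlib.crc32(to_smiles(mol).encode()) % (2**31)
        rng = np.random.default_rng((self.seed, key))
        return mu + rng.normal(0.0, self.sigma, size=self.n_members)

    def predict(self, mol: Chem.Mol) -> float:
        return float(self._member_predictions(mol).mean())

    def predict_with_std(self, mol: Chem.Mol) -> tuple[float, float]:
        preds = self._member_predictions(mol)
        return float(preds.mean()), float(preds.std())


# ---------------------------------------------------------------------------
# Diversity-penalized reward
# ---------------------------------------------------------------------------

@dataclass
class RewardSpec:
    """Configuration of the iteration reward R_i."""

    predictor: PropertyPredictor
    property_weight: float = 1.0
    similarity_weight: float = 1.0
    aggregation: str = AGG_MAX
    inventory: list[str] = field(default_factory=list)
    fp_radius: int = 2
    fp_bits: int = 2048
    _inventory_fps: list[Fingerprint] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.property_weight <= 0:
            raise ValueError("property_weight must be > 0")
        if self.similarity_weight < 0:
            raise ValueError("similarity_weight must be >= 0")
        if self.aggregation not in (AGG_MAX, AGG_MEAN):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        self._inventory_fps = [
            morgan_fingerprint(s, self.fp_radius, self.fp_bits)
            for s in self.inventory
        ]

    def add_to_inventory(self, smiles: str) -> None:
        self.inventory.append(smiles)
        self._inventory_fps.append(
            morgan_fingerprint(smiles, self.fp_radius, self.fp_bits)
        )

    def similarity_penalty(self, mol: Chem.Mol) -> float:
        """Aggregated Tanimoto similarity of ``mol`` to the inventory
        (0 when the inventory is empty)."""
        if not self._inventory_fps:
            return 0.0
        fp = morgan_fingerprint(mol, self.fp_radius, self.fp_bits)
        sims = [tanimoto(fp, y) for y in self._inventory_fps]
        return max(sims) if self.aggregation == AGG_MAX else float(np.mean(sims))


def penalized_reward(mol: Chem.Mol | str, spec: RewardSpec) -> float:
    """R_i(x) = w_p * C(x) - w_s * agg_y S(x, y), with C = -bandgap."""
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    try:
        prop = -float(spec.predictor.predict(mol))
    except Exception as exc:
        raise RuntimeError(
            f"property predictor failed on {to_smiles(mol)}: {exc}"
        ) from exc
    return spec.property_weight * prop \
        - spec.similarity_weight * spec.similarity_penalty(mol)


# ---------------------------------------------------------------------------
# Iterative diverse search
# ---------------------------------------------------------------------------

@dataclass
class IterationRecord:
    iteration: int
    smiles: str
    reward: float
    property_term: float
    penalty_term: float


def iterative_diverse_search(
    env: Environment,
    spec: RewardSpec,
    n_iterations: int,
    search_config: Optional[SearchConfig] = None,
) -> list[IterationRecord]:
    """Run MCTS ``n_iterations`` times with a fresh tree each time, adding
    each run's windowed best molecule to the inventory so later iterations
    are pushed away from earlier winners.

    With ``n_iterations == 1`` and an empty inventory this is exactly one
    plain search.  Each iteration's search is seeded from the base seed so
    the whole loop is reproducible.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    base = search_config or SearchConfig()
    records: list[IterationRecord] = []
    for i in range(1, n_iterations + 1):
        cfg = SearchConfig(
            c=base.c, n_steps=base.n_steps, window=base.window,
            seed=base.seed + i - 1, reward_floor=base.reward_floor,
            merge_transpositions=base.merge_transpositions,
            cache_rewards=base.cache_rewards,
        )
        result = run_search(env, lambda m: penalized_reward(m, spec), cfg)
        best = best_in_window(result.ledger, cfg.window)
        mol = mol_from_smiles(best.smiles)
        penalty = spec.similarity_weight * spec.similarity_penalty(mol)
        prop = -float(spec.predictor.predict(mol)) * spec.property_weight
        records.append(IterationRecord(
            iteration=i, smiles=best.smiles, reward=best.reward,
            property_term=prop, penalty_term=penalty,
        ))
        logger.info(
            "iteration %d: best %s reward %.4f (property %.4f, penalty %.4f)",
            i, best.smiles, best.reward, prop, penalty,
        )
        spec.add_to_inventory(best.smiles)
    return records


# ---------------------------------------------------------------------------
# Expected improvement and batch acquisition
# ---------------------------------------------------------------------------

def expected_improvement(mu: float, sigma: float, f_star: float) -> float:
    """Closed-form EI = E[max(R - f_star, 0)] for R ~ Normal(mu, sigma^2).

    EI = (mu - f_star) * Phi(z) + sigma * phi(z), z = (mu - f_star) / sigma;
    the sigma -> 0 limit is max(mu - f_star, 0).  Always >= 0.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    improvement = mu - f_star
    if sigma == 0.0:
        return max(improvement, 0.0)
    z = improvement / sigma
    return float(max(improvement * norm.cdf(z) + sigma * norm.pdf(z), 0.0))


@dataclass
class AcquisitionScore:
    smiles: str
    mu: float
    sigma: float
    ei: float


def acquire_batch(
    env: Environment,
    ensemble: EnsemblePredictor,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_top: int = DEFAULT_N_TOP,
    seed: int = 0,
) -> list[AcquisitionScore]:
    """EI acquisition: sample ``n_samples`` random rollouts, score each with
    the ensemble (mu = negative predicted bandgap, sigma = ensemble std),
    set f_star to the best predicted reward in the batch, and return the
    ``n_top`` candidates by EI (deduplicated by canonical form first)."""
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if n_top > n_samples:
        raise ValueError("n_top must not exceed n_samples")
    rng = np.random.default_rng(seed)
    seen: dict[str, tuple[float, float]] = {}
    for _ in range(n_samples):
        terminal = random_rollout(env, rng)
        mol = env.trajectory_molecule(terminal)
        smiles = to_smiles(mol)
        if smiles in seen:
            continue
        gap_mu, gap_sigma = ensemble.predict_with_std(mol)
        seen[smiles] = (-gap_mu, gap_sigma)
    f_star = max(mu for mu, _ in seen.values())
    scored = [
        AcquisitionScore(
            smiles=s, mu=mu, sigma=sigma,
            ei=expected_improvement(mu, sigma, f_star),
        )
        for s, (mu, sigma) in seen.items()
    ]
    scored.sort(key=lambda a: (-a.ei, a.smiles))
    return scored[:n_top]


def acquisition_frame(batch: Sequence[AcquisitionScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.smiles, a.mu, a.sigma, a.ei) for a in batch],
        columns=["smiles", "mu", "sigma", "ei"],
    )


# ---------------------------------------------------------------------------
# Active-learning loop
# ---------------------------------------------------------------------------

@dataclass
class ALRoundSummary:
    round_index: int
    n_acquired: int
    rmse: float
    acquired: list[str]


def al_loop(
    env: Environment,
    spec: RewardSpec,
    ensemble: EnsemblePredictor,
    trainer_callback: Callable[[list[str], int], float],
    stopping_rmse: float = DEFAULT_STOPPING_RMSE,
    max_rounds: int = 3,
    n_iterations: int = 3,
    search_config: Optional[SearchConfig] = None,
    n_samples: int = DEFAULT_N_SAMPLES,
    n_top: int = DEFAULT_N_TOP,
) -> list[ALRoundSummary]:
    """Active-learning rounds combining the two acquisition strategies.

    Each round acquires (1) the per-iteration best molecules of a
    diversity-penalized iterative search and (2) the top-EI molecules among
    random rollouts, then hands the union to ``trainer_callback`` (which
    labels them, retrains the predictor, and reports a held-out RMSE in eV).
    Stops when RMSE <= ``stopping_rmse`` or after ``max_rounds`` rounds.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    summaries: list[ALRoundSummary] = []
    base = search_config or SearchConfig()
    for round_index in range(1, max_rounds + 1):
        round_spec = RewardSpec(
            predictor=spec.predictor,
            property_weight=spec.property_weight,
            similarity_weight=spec.similarity_weight,
            aggregation=spec.aggregation,
            inventory=list(spec.inventory),
            fp_radius=spec.fp_radius, fp_bits=spec.fp_bits,
        )
        cfg = SearchConfig(
            c=base.c, n_steps=base.n_steps, window=base.window,
            seed=base.seed + 1000 * round_index,
            reward_floor=base.reward_floor,
            merge_transpositions=base.merge_transpositions,
            cache_rewards=base.cache_rewards,
        )
        records = iterative_diverse_search(env, round_spec, n_iterations, cfg)
        batch = acquire_batch(env, ensemble, n_samples, n_top,
                              seed=cfg.seed + 1)
        acquired = sorted(
            {r.smiles for r in records} | {a.smiles for a in batch}
        )
        try:
            rmse = float(trainer_callback(acquired, round_index))
        except Exception as exc:
            raise RuntimeError(
                f"trainer callback failed in round {round_index}: {exc}"
            ) from exc
        summaries.append(ALRoundSummary(
            round_index=round_index, n_acquired=len(acquired),
            rmse=rmse, acquired=acquired,
        ))
        logger.info("AL round %d: %d acquired, held-out RMSE %.4f eV",
                    round_index, len(acquired), rmse)
        if rmse <= stopping_rmse:
            break
    return summaries
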