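"""UCT Monte Carlo Tree Search over any environment satisfying the MDP
contract, including stochastic ones.

Each search iteration performs the four standard steps:

selection
    Descend from the root with the UCT policy: argmax over legal actions of
    ``Q(a) + c * sqrt(ln N_parent / N(a))``.  Unvisited actions have infinite
    priority and are taken before any visited one; ties break uniformly at
    random.  Taking an unvisited action *is* the expansion step (one new
    child, chosen uniformly among the unexpanded, per the random-expansion
    convention).
expansion / rollout
    From the newly created child (or a newly sampled stochastic outcome), a
    uniform random policy runs the trajectory to termination.
backpropagation
    The terminal molecule's scalar reward increments N and W on every edge
    of the selection path; Q is the running mean W/N.

Stochastic environments are handled by keying each edge's children on the
outcome state, so edge statistics marginalize over the environment's
position sampling.  By default nodes are keyed on the canonical state, so
transpositions (identical states reached along different paths) share
statistics; ``merge_transpositions=False`` keys nodes on the full path for
strict-tree semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_core import to_smiles
from .mdp_environments import ActionSpec, Environment, GenerationState

logger = logging.getLogger(__name__)

DEFAULT_EXPLORATION_C = 1.0 / math.sqrt(2.0)
DEFAULT_N_STEPS = 2000
DEFAULT_WINDOW = 100
DEFAULT_REWARD_FLOOR = -100.0


@dataclass
class SearchConfig:
    """MCTS hyperparameters.

    ``c`` is scale-sensitive because rewards are used unnormalized;
    ``window`` is the trailing slice of the ledger from which the best
    candidate of a run is extracted.
    """

    c: float = DEFAULT_EXPLORATION_C
    n_steps: int = DEFAULT_N_STEPS
    window: int = DEFAULT_WINDOW
    seed: int = 0
    reward_floor: float = DEFAULT_REWARD_FLOOR
    merge_transpositions: bool = True
    cache_rewards: bool = True

    def __post_init__(self):
        if self.c < 0:
            raise ValueError("exploration coefficient c must be >= 0")
        if self.window > self.n_steps:
            raise ValueError("window must not exceed n_steps")


@dataclass
class EdgeStats:
    """Visit bookkeeping for one (node, action) edge."""

    action: ActionSpec
    N: int = 0
    W: float = 0.0
    children: dict = field(default_factory=dict)  # outcome key -> TreeNode

    @property
    def Q(self) -> float:
        return self.W / self.N if self.N > 0 else 0.0


@dataclass
class TreeNode:
    state: GenerationState
    visits: int = 0
    edges: dict = field(default_factory=dict)  # ActionSpec -> EdgeStats
    actions: Optional[list[ActionSpec]] = None  # legal actions, lazily filled


@dataclass
class LedgerEntry:
    step: int
    smiles: str
    reward: float


@dataclass
class SearchResult:
    ledger: list[LedgerEntry]
    root: TreeNode
    config: SearchConfig

    def ledger_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.step, e.smiles, e.reward) for e in self.ledger],
            columns=["step", "smiles", "reward"],
        )


# ---------------------------------------------------------------------------
# UCT selection
# ---------------------------------------------------------------------------

def uct_argmax(
    q: Sequence[float],
    n: Sequence[int],
    n_parent: int,
    c: float,
    rng: np.random.Generator,
) -> int:
    """Index of the UCT-optimal action among parallel (Q, N) arrays.

    Actions with ``N == 0`` have infinite priority and are chosen (uniformly
    at random among themselves) before any visited action; among visited
    actions the score is ``Q + c * sqrt(ln(N_parent) / N)`` with uniform
    random tie-breaking.
    """
    if len(q) != len(n) or not q:
        raise ValueError("q and n must be equal-length, non-empty sequences")
    unvisited = [i for i, ni in enumerate(n) if ni == 0]
    if unvisited:
        return int(unvisited[rng.integers(len(unvisited))])
    log_np = math.log(n_parent) if n_parent > 0 else 0.0
    scores = [qi + c * math.sqrt(log_np / ni) for qi, ni in zip(q, n)]
    best = max(scores)
    ties = [i for i, s in enumerate(scores) if s == best]
    return int(ties[rng.integers(len(ties))])


def uct_select(node: TreeNode, c: float, rng: np.random.Generator) -> ActionSpec:
    """UCT-optimal action at a tree node (see :func:`uct_argmax`)."""
    if not node.actions:
        raise ValueError("uct_select called on a node with no legal actions")
    q, n = [], []
    for action in node.actions:
        edge = node.edges.get(action)
        q.append(edge.Q if edge else 0.0)
        n.append(edge.N if edge else 0)
    idx = uct_argmax(q, n, node.visits, c, rng)
    return node.actions[idx]


# ---------------------------------------------------------------------------
# The search loop
# ---------------------------------------------------------------------------

class _RewardCache:
    def __init__(self, fn: Callable[[Chem.Mol], float], floor: float,
                 enabled: bool):
        self.fn = fn
        self.floor = floor
        self.enabled = enabled
        self.cache: dict[str, float] = {}

    def __call__(self, mol: Chem.Mol) -> float:
        key = to_smiles(mol)
        if self.enabled and key in self.cache:
            return self.cache[key]
        try:
            value = float(self.fn(mol))
        except Exception as exc:
            logger.warning("reward failed for %s (%s); using floor %.3g",
                           key, exc, self.floor)
            value = self.floor
        if self.enabled:
            self.cache[key] = value
        return value


def run_search(
    env: Environment,
    reward_fn: Callable[[Chem.Mol], float],
    config: Optional[SearchConfig] = None,
) -> SearchResult:
    """Run ``config.n_steps`` MCTS iterations, returning the ledger of all
    terminal molecules evaluated (one per iteration) and the search tree.

    Fully reproducible: every random draw (tie-breaks, expansion choice,
    rollout policy, environment position sampling) comes from one generator
    seeded with ``config.seed``.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(config.seed)
    reward = _RewardCache(reward_fn, config.reward_floor, config.cache_rewards)

    nodes: dict = {}

    def node_key(state: GenerationState, path_len: int) -> tuple:
        if config.merge_transpositions:
            return state.key()
        return (state.key(), path_len)

    def get_node(state: GenerationState, path_len: int) -> TreeNode:
        key = node_key(state, path_len)
        node = nodes.get(key)
        if node is None:
            node = TreeNode(state=state)
            if not env.is_terminal(state):
                node.actions = env.legal_actions(state)
            nodes[key] = node
        return node

    root = get_node(env.initial_state(), 0)
    ledger: list[LedgerEntry] = []

    for step in range(1, config.n_steps + 1):
        node = root
        state = root.state
        path: list[tuple[EdgeStats, TreeNode]] = []  # (edge taken, child reached)

        # selection (the first unvisited action taken is the expansion)
        while not env.is_terminal(state):
            action = uct_select(node, config.c, rng)
            edge = node.edges.get(action)
            if edge is None:
                edge = EdgeStats(action=action)
                node.edges[action] = edge
            fresh = edge.N == 0
            result = env.step(state, action, rng)
            state = result.next_state
            okey = state.key()
            child = edge.children.get(okey)
            new_outcome = child is None
            if new_outcome:
                child = get_node(state, len(path) + 1)
                edge.children[okey] = child
            path.append((edge, child))
            node = child
            if fresh or new_outcome:
                break  # expansion done; roll out from here

        # rollout with a uniform random policy
        while not env.is_terminal(state):
            actions = env.legal_actions(state)
            action = actions[rng.integers(len(actions))]
            state = env.step(state, action, rng).next_state

        mol = env.trajectory_molecule(state)
        value = reward(mol)
        ledger.append(LedgerEntry(step=step, smiles=to_smiles(mol), reward=value))

        # backpropagation along the selection path
        root.visits += 1
        for edge, child in path:
            edge.N += 1
            edge.W += value
            child.visits += 1

    return SearchResult(ledger=ledger, root=root, config=config)


def best_in_window(
    ledger: Sequence[LedgerEntry], window: int = DEFAULT_WINDOW
) -> LedgerEntry:
    """Highest-reward entry among the final ``window`` ledger entries (the
    whole ledger when it is shorter)."""
    if not ledger:
        raise ValueError("ledger is empty")
    tail = ledger[-window:] if window > 0 else ledger
    return max(tail, key=lambda e: e.reward)
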