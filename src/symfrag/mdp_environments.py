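"""Generation grammars (MDPs) for fragment-constrained molecule building.

Two environments share one contract (``initial_state``, ``legal_actions``,
``step``, ``is_terminal``, ``trajectory_molecule``):

* :class:`Y6Environment` — a small, focused grammar around an editable
  fused/oligo-ring acceptor core: four heteroatom modifications at marked
  core positions, an optional pi-bridge, an end-group, and an alkyl chain
  (restricted to methyl).  All transitions are deterministic.

* :class:`PatentEnvironment` — an open grammar over a fragment pool obtained
  from corpus decomposition.  Fragment choices are factorized into a
  deterministic cluster choice (k-means over Morgan fingerprints) followed
  by a fragment choice; for pi-bridge and end-group attachments the reactive
  position is *not* an action: a mark is sampled uniformly from the k_t
  distinct open marks (probability 1/k_t) and the fragment is attached at
  every position bearing it.  Pi-bridge insertion is optional and allowed at
  most twice; end-group attachment iterates until no open positions remain
  or the heavy-atom cap (default 100) would be exceeded, in which case the
  remaining positions are hydrogen-capped and the state is terminal.

Because a fragment is always attached at *all* positions sharing the
sampled mark, identically marked positions always receive identical
fragments; differently marked positions receive different fragment
identities, enforced by masking already-used identities out of the action
set (relaxed with a warning if masking would empty it).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Protocol, Sequence

import numpy as np
from rdkit import Chem

from .chem_core import (
    attach_at_mark,
    attachment_points,
    cap_open_positions,
    fingerprint_array,
    heavy_atom_count,
    mol_from_smiles,
    morgan_fingerprint,
    open_marks,
    to_smiles,
)
from .fragment_decomposition import FragmentPool, MarkedFragment

logger = logging.getLogger(__name__)

DEFAULT_MAX_HEAVY_ATOMS = 100
DEFAULT_K_CLUSTERS = 100
DEFAULT_MAX_BRIDGE_ROUNDS = 2

# stage names
STAGE_CORE_MOD = "core-mod"
STAGE_PI_BRIDGE = "pi-bridge"
STAGE_END_GROUP = "end-group"
STAGE_ALKYL = "alkyl"
STAGE_CORE_CLUSTER = "core-cluster"
STAGE_CORE_FRAG = "core-frag"
STAGE_BRIDGE_CLUSTER = "bridge-cluster"
STAGE_BRIDGE_FRAG = "bridge-frag"
STAGE_END_CLUSTER = "end-cluster"
STAGE_END_FRAG = "end-frag"
STAGE_TERMINAL = "terminal"

# action kinds
MODIFY_CORE_POSITION = "modify-core-position"
CHOOSE_CLUSTER = "choose-cluster"
CHOOSE_FRAGMENT = "choose-fragment"
SKIP_PI_BRIDGE = "skip-pi-bridge"
CHOOSE_END_GROUP = "choose-end-group"
CHOOSE_ALKYL = "choose-alkyl"


class IllegalActionError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class ActionSpec:
    """One action in a generation grammar: a kind plus a hashable payload."""

    kind: str
    payload: tuple = ()


@dataclass(frozen=True)
class GenerationState:
    """Immutable state of a partial generation trajectory.

    ``smiles`` is the canonical marked form of the partial molecule (``None``
    before a core exists); ``stage_data`` holds stage-local bookkeeping such
    as pending core positions or the chosen cluster index.
    """

    smiles: Optional[str]
    stage: str
    stage_data: tuple = ()
    bridge_rounds: int = 0
    used_identities: frozenset = frozenset()

    @property
    def mol(self) -> Optional[Chem.Mol]:
        return mol_from_smiles(self.smiles) if self.smiles else None

    @property
    def open_marks(self) -> frozenset:
        if not self.smiles:
            return frozenset()
        return frozenset(open_marks(self.mol))

    @property
    def k_t(self) -> int:
        """Number of distinct open reactive positions."""
        return len(self.open_marks)

    @property
    def heavy_atoms(self) -> int:
        return heavy_atom_count(self.mol) if self.smiles else 0

    def key(self) -> tuple:
        return (self.smiles, self.stage, self.stage_data,
                self.bridge_rounds, self.used_identities)


@dataclass(frozen=True)
class TransitionResult:
    next_state: GenerationState
    sampled_mark: Optional[int]
    probability: float


class Environment(Protocol):
    """Contract every generation MDP satisfies."""

    def initial_state(self) -> GenerationState: ...

    def legal_actions(self, state: GenerationState) -> list[ActionSpec]: ...

    def step(self, state: GenerationState, action: ActionSpec,
             rng: np.random.Generator) -> TransitionResult: ...

    def is_terminal(self, state: GenerationState) -> bool: ...

    def trajectory_molecule(self, state: GenerationState) -> Chem.Mol: ...


def _require_legal(env, state: GenerationState, action: ActionSpec) -> None:
    if action not in env.legal_actions(state):
        raise IllegalActionError(
            f"action {action} is not legal in stage {state.stage!r}"
        )


# ---------------------------------------------------------------------------
# Fragment clustering (breadth-for-depth trade)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentCluster:
    """One k-means cluster of pool fragments (indices into the pool)."""

    index: int
    members: tuple[int, ...]
    centroid: tuple[float, ...] = ()


def cluster_fragments(
    pool: Sequence[MarkedFragment],
    k_clusters: int = DEFAULT_K_CLUSTERS,
    seed: int = 0,
) -> list[FragmentCluster]:
    """Partition fragments into k-means clusters of their Morgan fingerprints.

    ``k_clusters`` is clamped to the pool size (logged); the result is
    deterministic for a fixed seed and every cluster is non-empty.
    """
    if not pool:
        raise ValueError("cannot cluster an empty fragment pool")
    X = np.array([fingerprint_array(morgan_fingerprint(f.mol)) for f in pool])
    # duplicate fingerprints must share a cluster, so k is bounded by the
    # number of distinct fingerprint vectors, not the pool size
    n_unique = len(np.unique(X, axis=0))
    k = min(k_clusters, n_unique)
    if k < k_clusters:
        logger.info(
            "k_clusters clamped from %d to %d distinct fingerprints",
            k_clusters, k,
        )
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    clusters = []
    for new_index, i in enumerate(sorted(set(int(l) for l in labels))):
        members = tuple(int(j) for j in np.flatnonzero(labels == i))
        clusters.append(FragmentCluster(
            index=new_index, members=members,
            centroid=tuple(float(v) for v in km.cluster_centers_[i]),
        ))
    assert all(c.members for c in clusters)
    return clusters


# ---------------------------------------------------------------------------
# Focused Y6-style environment
# ---------------------------------------------------------------------------

#: End-group attachment sites carry mark 10, alkyl sites mark 11 in the core
#: template (marks 0/1 of the grammar, offset to keep atom-map 0 reserved).
Y6_END_MARK = 10
Y6_ALKYL_MARK = 11

#: Illustrative default core template: four conjugated rings in a row with a
#: variable divalent heteroatom slot in each ({x0}..{x3}), end-group sites on
#: the outer rings and alkyl sites on the inner rings.  This stands in for
#: the acceptor-core grammar; real studies supply their own template and
#: libraries via config.
DEFAULT_Y6_CORE_TEMPLATE = (
    "[*:10]c1ccc(-c2c([*:11])cc(-c3cc([*:11])c(-c4ccc([*:10]){x3}4){x2}3)"
    "{x1}2){x0}1"
)

DEFAULT_Y6_CONFIG: dict = {
    "core_template": DEFAULT_Y6_CORE_TEMPLATE,
    "core_choices": {
        "pos0": ["s", "o", "[se]"],
        "pos1": ["s", "o", "[se]"],
        "pos2": ["s", "o", "[se]"],
        "pos3": ["s", "o", "[se]"],
    },
    # pi-bridges have two attachment points; end-groups exactly one
    "pi_bridges": ["[*:1]c1ccc([*:2])s1", "[*:1]/C=C/[*:2]", "[*:1]C#C[*:2]"],
    "end_groups": ["[*:1]C=C(C#N)C#N", "[*:1]C=O", "[*:1][N+](=O)[O-]",
                   "[*:1]c1ccc(C#N)cc1"],
    "alkyls": ["[*:1]C"],
}


class Y6Environment:
    """Staged, deterministic grammar over an editable acceptor core.

    Stages run in order: heteroatom choice at each of pos0..pos3 (applied by
    substituting ring-heteroatom tokens into the core template), an optional
    pi-bridge attached at every end-group site, an end-group attached at
    every remaining end site, and a methyl at every alkyl site.  Attachment
    at *all* sites sharing a mark keeps the two molecule arms identical, the
    acceptor–donor–acceptor symmetry of this molecule family.
    """

    def __init__(self, config: Optional[dict] = None):
        cfg = dict(DEFAULT_Y6_CONFIG)
        if config:
            cfg.update(config)
        self.core_template: str = cfg["core_template"]
        self.core_choices: dict[str, list[str]] = {
            k: list(v) for k, v in cfg["core_choices"].items()
        }
        self.positions: list[str] = sorted(self.core_choices)
        self.pi_bridges: list[str] = list(cfg["pi_bridges"])
        self.end_groups: list[str] = list(cfg["end_groups"])
        self.alkyls: list[str] = list(cfg["alkyls"])
        # validate the template with the first choice at every position
        try:
            self._instantiate({p: c[0] for p, c in self.core_choices.items()})
        except Exception as exc:
            raise ValueError(f"malformed core template: {exc}") from exc
        # transitions are deterministic, so they are memoized
        self._step_cache: dict = {}

    def _instantiate(self, choices: dict[str, str]) -> str:
        tokens = {f"x{i}": choices[p] for i, p in enumerate(self.positions)}
        return to_smiles(mol_from_smiles(self.core_template.format(**tokens)))

    # -- contract ----------------------------------------------------------

    def initial_state(self) -> GenerationState:
        choices = {p: c[0] for p, c in self.core_choices.items()}
        return GenerationState(
            smiles=self._instantiate(choices),
            stage=STAGE_CORE_MOD,
            stage_data=(tuple(self.positions), tuple(sorted(choices.items()))),
        )

    def legal_actions(self, state: GenerationState) -> list[ActionSpec]:
        if state.stage == STAGE_TERMINAL:
            return []
        if state.stage == STAGE_CORE_MOD:
            pending = state.stage_data[0]
            pos = pending[0]
            return [ActionSpec(MODIFY_CORE_POSITION, (pos, tok))
                    for tok in self.core_choices[pos]]
        if state.stage == STAGE_PI_BRIDGE:
            acts = [ActionSpec(SKIP_PI_BRIDGE)]
            acts += [ActionSpec(CHOOSE_FRAGMENT, ("bridge", i))
                     for i in range(len(self.pi_bridges))]
            return acts
        if state.stage == STAGE_END_GROUP:
            return [ActionSpec(CHOOSE_END_GROUP, (i,))
                    for i in range(len(self.end_groups))]
        if state.stage == STAGE_ALKYL:
            return [ActionSpec(CHOOSE_ALKYL, (i,))
                    for i in range(len(self.alkyls))]
        raise RuntimeError(f"unknown stage {state.stage!r}")  # pragma: no cover

    def step(self, state: GenerationState, action: ActionSpec,
             rng: np.random.Generator) -> TransitionResult:
        cache_key = (state.key(), action)
        cached = self._step_cache.get(cache_key)
        if cached is not None:
            return cached
        result = self._step(state, action)
        if len(self._step_cache) < 200_000:
            self._step_cache[cache_key] = result
        return result

    def _step(self, state: GenerationState,
              action: ActionSpec) -> TransitionResult:
        _require_legal(self, state, action)
        if state.stage == STAGE_CORE_MOD:
            pending, chosen = state.stage_data
            pos, tok = action.payload
            choices = dict(chosen)
            choices[pos] = tok
            remaining = tuple(p for p in pending if p != pos)
            smiles = self._instantiate(choices)
            if remaining:
                nxt = GenerationState(
                    smiles=smiles, stage=STAGE_CORE_MOD,
                    stage_data=(remaining, tuple(sorted(choices.items()))),
                )
            else:
                nxt = GenerationState(smiles=smiles, stage=STAGE_PI_BRIDGE)
            return TransitionResult(nxt, None, 1.0)

        mol = state.mol
        if state.stage == STAGE_PI_BRIDGE:
            if action.kind == SKIP_PI_BRIDGE:
                nxt = GenerationState(
                    smiles=state.smiles, stage=STAGE_END_GROUP,
                    stage_data=(Y6_END_MARK,),
                )
                return TransitionResult(nxt, None, 1.0)
            frag = mol_from_smiles(self.pi_bridges[action.payload[1]])
            out = attach_at_mark(mol, Y6_END_MARK, frag)
            new_marks = open_marks(out) - {Y6_ALKYL_MARK}
            (end_mark,) = new_marks
            nxt = GenerationState(
                smiles=to_smiles(out), stage=STAGE_END_GROUP,
                stage_data=(end_mark,),
            )
            return TransitionResult(nxt, None, 1.0)
        if state.stage == STAGE_END_GROUP:
            (end_mark,) = state.stage_data
            frag = mol_from_smiles(self.end_groups[action.payload[0]])
            out = attach_at_mark(mol, end_mark, frag)
            nxt = GenerationState(smiles=to_smiles(out), stage=STAGE_ALKYL)
            return TransitionResult(nxt, None, 1.0)
        if state.stage == STAGE_ALKYL:
            frag = mol_from_smiles(self.alkyls[action.payload[0]])
            out = attach_at_mark(mol, Y6_ALKYL_MARK, frag)
            nxt = GenerationState(smiles=to_smiles(out), stage=STAGE_TERMINAL)
            return TransitionResult(nxt, None, 1.0)
        raise RuntimeError(f"unknown stage {state.stage!r}")  # pragma: no cover

    def is_terminal(self, state: GenerationState) -> bool:
        return state.stage == STAGE_TERMINAL

    def trajectory_molecule(self, state: GenerationState) -> Chem.Mol:
        if not self.is_terminal(state):
            raise ValueError("trajectory_molecule called on non-terminal state")
        mol = state.mol
        assert not attachment_points(mol)
        return mol


# ---------------------------------------------------------------------------
# Open patent-fragment environment
# ---------------------------------------------------------------------------

class PatentEnvironment:
    """Open grammar over a decomposition-derived fragment pool.

    Action hierarchy per trajectory: core cluster → core fragment (both
    deterministic), at most ``max_bridge_rounds`` optional pi-bridge rounds
    (cluster → fragment, reactive position sampled), then alternating
    end-group cluster/fragment choices until every reactive position is
    filled or the heavy-atom cap forces hydrogen capping.  With k distinct
    open marks the end phase needs at most 2k steps.
    """

    def __init__(
        self,
        pool: FragmentPool,
        k_clusters: int = DEFAULT_K_CLUSTERS,
        seed: int = 0,
        max_heavy_atoms: int = DEFAULT_MAX_HEAVY_ATOMS,
        max_bridge_rounds: int = DEFAULT_MAX_BRIDGE_ROUNDS,
    ):
        if len(pool) == 0:
            raise ValueError("fragment pool is empty")
        self.pool = pool
        self._relax_warned: set[tuple[str, int]] = set()
        self.max_heavy_atoms = max_heavy_atoms
        self.max_bridge_rounds = max_bridge_rounds
        roles = pool.by_role()
        self.role_fragments: dict[str, list[int]] = roles
        self.clusters: dict[str, list[FragmentCluster]] = {}
        for role in ("core", "bridge", "end"):
            members = roles[role]
            if members:
                frags = [pool.fragments[i] for i in members]
                clusters = cluster_fragments(frags, k_clusters, seed)
                # remap member indices back into pool indices
                self.clusters[role] = [
                    FragmentCluster(
                        index=c.index,
                        members=tuple(members[m] for m in c.members),
                        centroid=c.centroid,
                    )
                    for c in clusters
                ]
            else:
                self.clusters[role] = []
        if not self.clusters["core"]:
            raise ValueError("no core fragments in pool")
        if not self.clusters["end"]:
            raise ValueError("no single-position (end-group) fragments in pool")

    # -- identity masking --------------------------------------------------

    def _allowed(self, role: str, cluster: FragmentCluster,
                 state: GenerationState) -> list[int]:
        """Pool indices in a cluster not excluded by the distinct-identity
        rule; relaxed (with a warning) if masking would empty the cluster."""
        allowed = [
            i for i in cluster.members
            if self.pool.fragments[i].stripped not in state.used_identities
        ]
        if not allowed:
            key = (role, cluster.index)
            if key not in self._relax_warned:
                self._relax_warned.add(key)
                logger.warning(
                    "identity masking emptied cluster %d (%s); relaxing the "
                    "distinct-fragment constraint for this step",
                    cluster.index, role,
                )
            return list(cluster.members)
        return allowed

    def _cluster_has_allowed(self, role: str, cluster: FragmentCluster,
                             state: GenerationState) -> bool:
        return True  # relaxation guarantees every cluster stays actionable

    # -- contract ----------------------------------------------------------

    def initial_state(self) -> GenerationState:
        return GenerationState(smiles=None, stage=STAGE_CORE_CLUSTER)

    def legal_actions(self, state: GenerationState) -> list[ActionSpec]:
        if state.stage == STAGE_TERMINAL:
            return []
        if state.stage == STAGE_CORE_CLUSTER:
            return [ActionSpec(CHOOSE_CLUSTER, ("core", c.index))
                    for c in self.clusters["core"]]
        if state.stage == STAGE_CORE_FRAG:
            (cidx,) = state.stage_data
            cluster = self.clusters["core"][cidx]
            return [ActionSpec(CHOOSE_FRAGMENT, ("core", i))
                    for i in self._allowed("core", cluster, state)]
        if state.stage == STAGE_BRIDGE_CLUSTER:
            acts = [ActionSpec(SKIP_PI_BRIDGE)]
            if state.bridge_rounds < self.max_bridge_rounds:
                acts += [ActionSpec(CHOOSE_CLUSTER, ("bridge", c.index))
                         for c in self.clusters["bridge"]]
            return acts
        if state.stage == STAGE_BRIDGE_FRAG:
            (cidx,) = state.stage_data
            cluster = self.clusters["bridge"][cidx]
            return [ActionSpec(CHOOSE_FRAGMENT, ("bridge", i))
                    for i in self._allowed("bridge", cluster, state)]
        if state.stage == STAGE_END_CLUSTER:
            return [ActionSpec(CHOOSE_CLUSTER, ("end", c.index))
                    for c in self.clusters["end"]]
        if state.stage == STAGE_END_FRAG:
            (cidx,) = state.stage_data
            cluster = self.clusters["end"][cidx]
            return [ActionSpec(CHOOSE_FRAGMENT, ("end", i))
                    for i in self._allowed("end", cluster, state)]
        raise RuntimeError(f"unknown stage {state.stage!r}")  # pragma: no cover

    def sample_mark(self, state: GenerationState,
                    rng: np.random.Generator) -> tuple[int, float]:
        """Uniform draw of a reactive position: each of the k_t distinct open
        marks has probability 1/k_t."""
        marks = sorted(state.open_marks)
        if not marks:
            raise ValueError("state has no open reactive positions")
        mark = int(marks[rng.integers(len(marks))])
        return mark, 1.0 / len(marks)

    def _attach_sampled(self, state: GenerationState, frag: MarkedFragment,
                        rng: np.random.Generator,
                        next_stage_open: str) -> TransitionResult:
        """Shared pi-bridge/end-group attachment with position sampling and
        heavy-atom-cap enforcement."""
        mark, prob = self.sample_mark(state, rng)
        mol = state.mol
        n_sites = sum(1 for ap in attachment_points(mol) if ap.mark == mark)
        projected = state.heavy_atoms + n_sites * frag.heavy_atoms
        used = state.used_identities | {frag.stripped}
        if projected > self.max_heavy_atoms:
            capped = cap_open_positions(mol, "hydrogen")
            nxt = GenerationState(
                smiles=to_smiles(capped), stage=STAGE_TERMINAL,
                bridge_rounds=state.bridge_rounds,
                used_identities=state.used_identities,
            )
            return TransitionResult(nxt, mark, prob)
        out = attach_at_mark(mol, mark, frag.mol)
        if open_marks(out):
            stage = next_stage_open
        else:
            stage = STAGE_TERMINAL
        nxt = GenerationState(
            smiles=to_smiles(out), stage=stage,
            bridge_rounds=state.bridge_rounds
            + (1 if next_stage_open == STAGE_BRIDGE_CLUSTER else 0),
            used_identities=used,
        )
        return TransitionResult(nxt, mark, prob)

    def step(self, state: GenerationState, action: ActionSpec,
             rng: np.random.Generator) -> TransitionResult:
        _require_legal(self, state, action)
        kind = action.kind
        if kind == CHOOSE_CLUSTER:
            role, cidx = action.payload
            stage = {"core": STAGE_CORE_FRAG, "bridge": STAGE_BRIDGE_FRAG,
                     "end": STAGE_END_FRAG}[role]
            nxt = replace(state, stage=stage, stage_data=(cidx,))
            return TransitionResult(nxt, None, 1.0)
        if kind == SKIP_PI_BRIDGE:
            nxt = replace(state, stage=STAGE_END_CLUSTER, stage_data=())
            return TransitionResult(nxt, None, 1.0)
        role, fidx = action.payload
        frag = self.pool.fragments[fidx]
        if role == "core":
            mol = frag.mol
            used = frozenset({frag.stripped})
            if attachment_points(mol):
                stage = STAGE_BRIDGE_CLUSTER
            else:
                stage = STAGE_TERMINAL
            nxt = GenerationState(
                smiles=to_smiles(mol), stage=stage, used_identities=used,
            )
            return TransitionResult(nxt, None, 1.0)
        if role == "bridge":
            return self._attach_sampled(state, frag, rng, STAGE_BRIDGE_CLUSTER)
        if role == "end":
            return self._attach_sampled(state, frag, rng, STAGE_END_CLUSTER)
        raise RuntimeError(f"unknown role {role!r}")  # pragma: no cover

    def is_terminal(self, state: GenerationState) -> bool:
        return state.stage == STAGE_TERMINAL

    def trajectory_molecule(self, state: GenerationState) -> Chem.Mol:
        if not self.is_terminal(state):
            raise ValueError("trajectory_molecule called on non-terminal state")
        mol = state.mol
        if attachment_points(mol):  # defensive; terminal states are capped
            mol = cap_open_positions(mol, "hydrogen")
        return mol


# ---------------------------------------------------------------------------
# Shared helpers
# ---------------------------------------------------------------------------

def random_rollout(
    env: Environment,
    rng: np.random.Generator,
    state: Optional[GenerationState] = None,
) -> GenerationState:
    """Follow a uniform random policy from ``state`` (default: initial) to a
    terminal state."""
    if state is None:
        state = env.initial_state()
    while not env.is_terminal(state):
        actions = env.legal_actions(state)
        action = actions[rng.integers(len(actions))]
        state = env.step(state, action, rng).next_state
    return state


def enumerate_terminals(env: Environment, max_terminals: int = 100000) -> list[str]:
    """Exhaustively enumerate the canonical SMILES of all terminal molecules
    of a *deterministic* environment (brute-force oracle for small grammars)."""
    rng = np.random.default_rng(0)  # never consulted on deterministic paths
    out: set[str] = set()

    def walk(state: GenerationState) -> None:
        if len(out) > max_terminals:
            raise RuntimeError("terminal space larger than max_terminals")
        if env.is_terminal(state):
            out.add(to_smiles(env.trajectory_molecule(state)))
            return
        for action in env.legal_actions(state):
            walk(env.step(state, action, rng).next_state)

    walk(env.initial_state())
    return sorted(out)
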