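"""Symmetry-aware fragment decomposition.

A molecule is recursively cut at *cleavable* bonds — single, acyclic bonds
that connect an aromatic atom to an aliphatic atom or to another aromatic
ring — forming a binary decomposition tree.  Each cut leaves a wildcard
attachment point on both sides, and the new point is labelled (marked)
with the integer vocabulary ID of the fragment that sat on the other side
of that bond *in the original molecule*.  Two attachment points therefore
carry the same mark exactly when the substructures historically attached
there were identical: the mark encodes the molecule's attachment symmetry,
which the generator later preserves.

The vocabulary is built from all single-cut fragments of the molecule
(marks stripped, cut wildcards retained), deduplicated and sorted so IDs
are reproducible across runs; every mark assigned during recursion
resolves in it.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .chem_core import (
    attachment_points,
    heavy_atom_count,
    join_at_atoms,
    mol_from_smiles,
    strip_marks,
    to_smiles,
)

logger = logging.getLogger(__name__)

#: Cleavable-bond pattern: a single, non-ring bond with an aromatic atom on
#: one end and any non-wildcard atom on the other.  This matches exactly the
#: aromatic–aliphatic and aromatic–aromatic (inter-ring) single bonds; ring
#: bonds are never matched, so fragments are never cut inside rings.
CLEAVABLE_BOND_SMARTS = "[a]-!@[!#0]"
_CLEAVABLE_PATTERN = Chem.MolFromSmarts(CLEAVABLE_BOND_SMARTS)

# isotope tag used transiently to find the freshly created cut wildcards
_FRESH_CUT_ISOTOPE = 1

#: Serialization dialect: a wildcard labelled with vocabulary ID k carries
#: atom-map number k + 1, because atom-map 0 means "no label" in SMILES and
#: is reserved for free (unmarked) attachment points.
MARK_OFFSET = 1


def mark_for_id(fid: int) -> int:
    """Attachment-point mark (atom-map number) encoding vocabulary ID ``fid``."""
    return fid + MARK_OFFSET


def id_for_mark(mark: int) -> int:
    """Vocabulary ID encoded by attachment-point ``mark``."""
    return mark - MARK_OFFSET


class DecompositionError(ValueError):
    """Raised when reassembly inputs are inconsistent (orphan marks)."""


# ---------------------------------------------------------------------------
# Fragment and vocabulary containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MarkedFragment:
    """A fragment with integer-labelled attachment points.

    ``smiles`` is the canonical SMILES in the package's wildcard dialect
    (marks carried as atom maps on ``*`` atoms).
    """

    smiles: str

    @property
    def mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)

    @property
    def marks(self) -> list[int]:
        return [ap.mark for ap in attachment_points(self.mol)]

    @property
    def stripped(self) -> str:
        """Canonical form with mark labels removed, wildcards kept."""
        return strip_marks(self.mol)

    @property
    def n_reactive(self) -> int:
        """r(f): number of reactive positions (attachment points)."""
        return len(attachment_points(self.mol))

    @property
    def heavy_atoms(self) -> int:
        """n(f): number of heavy (non-H, non-wildcard) atoms."""
        return heavy_atom_count(self.mol)


class FragmentVocabulary:
    """Bijection between stripped canonical fragment forms and IDs [0, N)."""

    def __init__(self, forms: Sequence[str] = ()):  # forms assumed unique
        self._forms: list[str] = list(forms)
        self._ids: dict[str, int] = {f: i for i, f in enumerate(self._forms)}
        if len(self._ids) != len(self._forms):
            raise ValueError("vocabulary forms must be unique")

    def __len__(self) -> int:
        return len(self._forms)

    def __contains__(self, form: str) -> bool:
        return form in self._ids

    def __eq__(self, other) -> bool:
        return isinstance(other, FragmentVocabulary) and self._forms == other._forms

    def form(self, fid: int) -> str:
        return self._forms[fid]

    def lookup(self, form: str) -> int:
        return self._ids[form]

    def get(self, form: str) -> Optional[int]:
        return self._ids.get(form)

    def lookup_or_add(self, form: str) -> int:
        """ID of ``form``, appending it with the next free ID if absent."""
        fid = self._ids.get(form)
        if fid is None:
            fid = len(self._forms)
            self._forms.append(form)
            self._ids[form] = fid
            logger.debug("vocabulary extended: id %d <- %s", fid, form)
        return fid

    @property
    def forms(self) -> list[str]:
        return list(self._forms)

    def to_json(self, counts: Optional[dict[str, int]] = None) -> str:
        entries = [
            {"id": i, "smiles": f, "count": (counts or {}).get(f, 1)}
            for i, f in enumerate(self._forms)
        ]
        return json.dumps({"entries": entries}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FragmentVocabulary":
        data = json.loads(text)
        entries = sorted(data["entries"], key=lambda e: e["id"])
        return cls([e["smiles"] for e in entries])


# ---------------------------------------------------------------------------
# Cleavable bonds and single cuts
# ---------------------------------------------------------------------------

def find_cleavable_bonds(mol: Chem.Mol) -> list[tuple[int, int]]:
    """Bonds matching the cleavable pattern, as sorted (i, j) atom pairs in
    canonical atom-index order.  Ring bonds are never included."""
    seen = set()
    for a, b in mol.GetSubstructMatches(_CLEAVABLE_PATTERN):
        seen.add((min(a, b), max(a, b)))
    return sorted(seen)


def cleave_bond(mol: Chem.Mol, bond: tuple[int, int]) -> tuple[Chem.Mol, Chem.Mol]:
    """Cut one bond, returning (side containing atom i, side containing atom j).

    Each side gains one fresh, unlabelled wildcard at the cut position;
    wildcards inherited from earlier cuts keep their marks.
    """
    i, j = bond
    b = mol.GetBondBetweenAtoms(i, j)
    if b is None:
        raise ValueError(f"no bond between atoms {i} and {j}")
    fragmented = Chem.FragmentOnBonds(
        mol, [b.GetIdx()], addDummies=True,
        dummyLabels=[(_FRESH_CUT_ISOTOPE, _FRESH_CUT_ISOTOPE)],
    )
    frag_indices = Chem.GetMolFrags(fragmented)
    frag_mols = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    side_i = side_j = None
    for indices, fmol in zip(frag_indices, frag_mols):
        if i in indices:
            side_i = fmol
        if j in indices:
            side_j = fmol
    if side_i is None or side_j is None:  # pragma: no cover
        raise RuntimeError("cleaved bond did not split the molecule in two")
    for side in (side_i, side_j):
        for atom in side.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetIsotope() == _FRESH_CUT_ISOTOPE:
                atom.SetIsotope(0)
    return side_i, side_j


def _fresh_cut_atom(side: Chem.Mol) -> int:
    """Index of the wildcard created by the most recent cut (map number 0)."""
    for atom in side.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 0:
            return atom.GetIdx()
    raise RuntimeError("no fresh cut wildcard found")  # pragma: no cover


# ---------------------------------------------------------------------------
# Vocabulary construction
# ---------------------------------------------------------------------------

def single_cut_forms(mol: Chem.Mol) -> list[str]:
    """Stripped canonical forms of both sides of every single-bond cut."""
    forms = []
    for bond in find_cleavable_bonds(mol):
        for side in cleave_bond(mol, bond):
            forms.append(strip_marks(side))
    return forms


def build_vocabulary(mol: Chem.Mol | str) -> FragmentVocabulary:
    """Vocabulary of unique single-cut fragments of one molecule.

    Forms are deduplicated and sorted so IDs are reproducible.  A molecule
    with no cleavable bonds yields a vocabulary containing only itself.
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    forms = sorted(set(single_cut_forms(mol)))
    if not forms:
        forms = [strip_marks(mol)]
    return FragmentVocabulary(forms)


# ---------------------------------------------------------------------------
# Recursive decomposition
# ---------------------------------------------------------------------------

@dataclass
class DecompositionNode:
    """Node of the binary decomposition tree."""

    fragment: MarkedFragment
    cleaved_bond: Optional[tuple[int, int]] = None
    children: tuple["DecompositionNode", "DecompositionNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class DecompositionTree:
    root: DecompositionNode
    memo_hits: int = 0

    def leaves(self) -> list[MarkedFragment]:
        out: list[MarkedFragment] = []

        def walk(node: DecompositionNode) -> None:
            if node.is_leaf:
                out.append(node.fragment)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out


_ORIG_IDX_PROP = "_symfragOrigIdx"


def decompose(
    mol: Chem.Mol | str,
    vocab: Optional[FragmentVocabulary] = None,
    use_memo: bool = True,
) -> tuple[list[MarkedFragment], DecompositionTree]:
    """Recursively decompose a molecule into marked leaf fragments.

    Marks carry the identity of the substructure attached at each position
    *in the original molecule*: cutting a bond labels the new attachment
    point on each side with the vocabulary ID of the single-cut fragment on
    the other side of that same bond in the input molecule.  Two attachment
    points therefore share a mark exactly when the branches attached there
    were identical, which is the symmetry information the generator later
    preserves — and every mark resolves in the single-cut vocabulary, so no
    new IDs are minted during recursion.  The leaf multiset and all marks
    are consequently independent of the cut order; bonds are cut
    first-in-canonical-atom-index-order.

    Memoization caches the subtree for repeated sub-fragments (keyed on the
    marked form plus the original side identities of its remaining
    cleavable bonds); it is purely an optimization and never changes the
    leaf multiset (``use_memo=False`` disables it).
    """
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    original = Chem.Mol(mol)
    for atom in original.GetAtoms():
        atom.SetIntProp(_ORIG_IDX_PROP, atom.GetIdx())

    # single-cut side forms of every cleavable bond of the input molecule
    side_forms: dict[tuple[int, int], dict[int, str]] = {}
    for bond in find_cleavable_bonds(original):
        i, j = bond
        side_i, side_j = cleave_bond(original, bond)
        side_forms[bond] = {i: strip_marks(side_i), j: strip_marks(side_j)}
    if vocab is None:
        forms = sorted({f for pair in side_forms.values()
                        for f in pair.values()})
        vocab = FragmentVocabulary(forms or [strip_marks(original)])

    def orig_bond(m: Chem.Mol, x: int, y: int) -> tuple[int, int]:
        ox = m.GetAtomWithIdx(x).GetIntProp(_ORIG_IDX_PROP)
        oy = m.GetAtomWithIdx(y).GetIntProp(_ORIG_IDX_PROP)
        return (min(ox, oy), max(ox, oy)), ox, oy

    def memo_key(m: Chem.Mol) -> tuple:
        # marks plus the original-side identities of the remaining cuts
        # fully determine the leaf multiset of a sub-fragment
        bond_ids = []
        for x, y in find_cleavable_bonds(m):
            okey, ox, oy = orig_bond(m, x, y)
            pair = side_forms[okey]
            bond_ids.append(tuple(sorted((pair[ox], pair[oy]))))
        return (to_smiles(m), tuple(sorted(bond_ids)))

    memo: dict[tuple, DecompositionNode] = {}
    tree = DecompositionTree(root=None)  # type: ignore[arg-type]

    def recurse(m: Chem.Mol) -> DecompositionNode:
        key = memo_key(m) if use_memo else None
        if use_memo and key in memo:
            tree.memo_hits += 1
            return memo[key]
        bonds = find_cleavable_bonds(m)
        smiles = to_smiles(m)
        if not bonds:
            node = DecompositionNode(fragment=MarkedFragment(smiles))
        else:
            x, y = bonds[0]
            okey, ox, oy = orig_bond(m, x, y)
            pair = side_forms[okey]
            side_x, side_y = cleave_bond(m, (x, y))
            mark_x = mark_for_id(vocab.lookup_or_add(pair[oy]))
            mark_y = mark_for_id(vocab.lookup_or_add(pair[ox]))
            side_x.GetAtomWithIdx(_fresh_cut_atom(side_x)).SetAtomMapNum(mark_x)
            side_y.GetAtomWithIdx(_fresh_cut_atom(side_y)).SetAtomMapNum(mark_y)
            node = DecompositionNode(
                fragment=MarkedFragment(smiles),
                cleaved_bond=(x, y),
                children=(recurse(side_x), recurse(side_y)),
            )
        if use_memo:
            memo[key] = node
        return node

    tree.root = recurse(original)
    return tree.leaves(), tree


# ---------------------------------------------------------------------------
# Reassembly (inverse operation; round-trip oracle)
# ---------------------------------------------------------------------------

def reassemble(
    leaves: Iterable[MarkedFragment], vocab: FragmentVocabulary
) -> Chem.Mol:
    """Rebuild the original molecule from decomposition leaves.

    A mark names the complete branch that was attached at a position in the
    original molecule, so a piece may absorb a partner exactly when that
    partner is a *finished* branch: a piece with a single open attachment
    point whose stripped form equals the vocabulary form the mark names.
    Joining proceeds leaves-inward; because several pieces can share a
    stripped form while belonging to different positions, the join order is
    found by backtracking search with failed sub-states memoized.  Raises
    :class:`DecompositionError` listing orphan marks when no join order
    completes the assembly.
    """
    start = tuple(sorted(to_smiles(leaf.mol) for leaf in leaves))
    if not start:
        raise DecompositionError("no leaves to reassemble")

    dead_ends: set[tuple[str, ...]] = set()

    def candidate_joins(pieces: tuple[str, ...]) -> list[tuple[str, ...]]:
        mols = [mol_from_smiles(s) for s in pieces]
        aps = [attachment_points(m) for m in mols]
        strips = [strip_marks(m) for m in mols]
        ids = [vocab.get(s) for s in strips]
        successors: set[tuple[str, ...]] = set()
        for ib in range(len(pieces)):
            # the absorbed partner must be a finished branch: exactly one
            # open point, and a stripped form known to the vocabulary
            if len(aps[ib]) != 1 or ids[ib] is None:
                continue
            wanted = mark_for_id(ids[ib])
            for ia in range(len(pieces)):
                if ia == ib:
                    continue
                for ap_a in aps[ia]:
                    if ap_a.mark != wanted:
                        continue
                    merged = join_at_atoms(
                        mols[ia], ap_a.atom_index,
                        mols[ib], aps[ib][0].atom_index,
                    )
                    rest = [s for k, s in enumerate(pieces)
                            if k not in (ia, ib)]
                    successors.add(tuple(sorted(rest + [to_smiles(merged)])))
        return sorted(successors)

    def search(pieces: tuple[str, ...]) -> Optional[str]:
        if len(pieces) == 1 and not attachment_points(mol_from_smiles(pieces[0])):
            return pieces[0]
        if pieces in dead_ends:
            return None
        for nxt in candidate_joins(pieces):
            result = search(nxt)
            if result is not None:
                return result
        dead_ends.add(pieces)
        return None

    assembled = search(start)
    if assembled is None:
        orphans = sorted(
            {ap.mark for s in start
             for ap in attachment_points(mol_from_smiles(s))}
        )
        raise DecompositionError(
            f"cannot resolve attachment marks {orphans}: no join order "
            "reassembles the leaves into a single closed molecule"
        )
    return mol_from_smiles(assembled)


# ---------------------------------------------------------------------------
# Corpus-level decomposition and the filtered fragment pool
# ---------------------------------------------------------------------------

ROLE_CORE = "core"
ROLE_BRIDGE = "bridge"
ROLE_END = "end"


@dataclass
class FragmentPool:
    """Union of leaf fragments over a corpus, with duplicate counts.

    Roles partition generation duty by reactive-position count r(f):
    end-groups cap exactly one position (r = 1), pi-bridges extend through
    two (r = 2), and any fragment may serve as a core.
    """

    fragments: list[MarkedFragment]
    counts: list[int]
    vocab: FragmentVocabulary

    def __len__(self) -> int:
        return len(self.fragments)

    def by_role(self) -> dict[str, list[int]]:
        roles: dict[str, list[int]] = {ROLE_CORE: [], ROLE_BRIDGE: [], ROLE_END: []}
        for i, frag in enumerate(self.fragments):
            roles[ROLE_CORE].append(i)
            if frag.n_reactive == 1:
                roles[ROLE_END].append(i)
            elif frag.n_reactive == 2:
                roles[ROLE_BRIDGE].append(i)
        return roles

    def to_json(self) -> str:
        entries = [
            {
                "smiles": f.smiles,
                "stripped": f.stripped,
                "count": c,
                "n_reactive": f.n_reactive,
                "heavy_atoms": f.heavy_atoms,
            }
            for f, c in zip(self.fragments, self.counts)
        ]
        return json.dumps(
            {"entries": entries, "vocabulary": json.loads(self.vocab.to_json())},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FragmentPool":
        data = json.loads(text)
        vocab = FragmentVocabulary.from_json(json.dumps(data["vocabulary"]))
        frags = [MarkedFragment(e["smiles"]) for e in data["entries"]]
        counts = [e["count"] for e in data["entries"]]
        return cls(frags, counts, vocab)


def decompose_corpus(
    mols: Sequence[Chem.Mol | str],
    size_cap: int = 40,
    reactive_cap: int = 6,
    use_memo: bool = True,
) -> FragmentPool:
    """Decompose a corpus under one global vocabulary and pool the leaves.

    The vocabulary is the sorted union of single-cut forms over the whole
    corpus, so IDs do not depend on per-molecule order.  Leaves are merged by canonical marked form with counts retained, and the
    pool is filtered to fragments with r(f) ≤ ``reactive_cap`` reactive
    positions and n(f) ≤ ``size_cap`` heavy atoms.
    """
    parsed = [mol_from_smiles(m) if isinstance(m, str) else m for m in mols]
    forms: set[str] = set()
    for m in parsed:
        forms.update(single_cut_forms(m))
    vocab = FragmentVocabulary(sorted(forms))

    counter: Counter[str] = Counter()
    for m in parsed:
        leaves, _ = decompose(m, vocab, use_memo=use_memo)
        counter.update(leaf.smiles for leaf in leaves)

    fragments: list[MarkedFragment] = []
    counts: list[int] = []
    for smiles in sorted(counter):
        frag = MarkedFragment(smiles)
        if frag.n_reactive > reactive_cap or frag.heavy_atoms > size_cap:
            continue
        fragments.append(frag)
        counts.append(counter[smiles])
    return FragmentPool(fragments=fragments, counts=counts, vocab=vocab)
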