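"""Synthetic fixture corpora with known fragment composition.

Stands in for a mined molecule corpus: molecules are assembled from small
libraries of aromatic cores, two-point bridges, and one-point end-groups,
with a controlled attachment symmetry (``symmetry_degree`` sites per core
share one substituent).  Every attachment is an aromatic–aromatic or
aromatic–aliphatic single bond, so the decomposition algorithm can cut the
molecule exactly back into its constituent parts; the ground truth is
retained alongside each molecule for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from .chem_core import (
    attach_at_mark,
    attachment_points,
    mol_from_smiles,
    strip_marks,
    to_smiles,
)

#: Core scaffolds; wildcard maps number the substituent sites.  None contains
#: an internal cleavable bond, so each survives decomposition as one leaf.
CORE_LIBRARY: list[str] = [
    "[*:1]c1ccc([*:2])cc1",             # benzene-1,4
    "[*:1]c1cc([*:2])cc([*:3])c1",      # benzene-1,3,5
    "[*:1]c1ccc([*:2])s1",              # thiophene-2,5
    "[*:1]c1ccc([*:2])o1",              # furan-2,5
    "[*:1]c1cccc([*:2])n1",             # pyridine-2,6
    "[*:1]c1ccc2cc([*:2])ccc2c1",       # naphthalene-2,6
    "[*:1]c1cc([*:2])c([*:3])cc1[*:4]", # benzene-1,2,4,5
]

#: Conjugated two-point bridges (aromatic, so both junctions are cleavable).
BRIDGE_LIBRARY: list[str] = [
    "[*:1]c1ccc([*:2])s1",
    "[*:1]c1ccc([*:2])o1",
    "[*:1]c1ccc([*:2])cc1",
]

#: One-point end-groups; none contains an internal cleavable bond.
ENDGROUP_LIBRARY: list[str] = [
    "[*:1]C",
    "[*:1]CC",
    "[*:1]C(C)C",
    "[*:1]C#N",
    "[*:1]C=O",
    "[*:1]OC",
    "[*:1]C(F)(F)F",
    "[*:1]N(C)C",
    "[*:1]c1ccccc1",
    "[*:1]c1ccco1",
]


#: A reduced, fully enumerable focused grammar (120 distinct terminal
#: molecules): two heteroatom choices per core position, two pi-bridges
#: plus skip, four end-groups, methyl alkyl.  Small enough for exhaustive
#: enumeration, used as the brute-force optimality oracle for the search.
TOY_Y6_CONFIG: dict = {
    "core_choices": {
        "pos0": ["s", "o"],
        "pos1": ["s", "o"],
        "pos2": ["s", "o"],
        "pos3": ["s", "o"],
    },
    "pi_bridges": ["[*:1]c1ccc([*:2])s1", "[*:1]/C=C/[*:2]"],
    "end_groups": ["[*:1]C=C(C#N)C#N", "[*:1]C=O", "[*:1][N+](=O)[O-]",
                   "[*:1]c1ccc(C#N)cc1"],
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic corpus.

    ``n_cores``/``n_bridges``/``n_endgroups`` select the first entries of
    the built-in libraries; ``symmetry_degree`` is the number of core sites
    that share one substituent (clamped to the number of sites on a core).
    """

    n_cores: int = len(CORE_LIBRARY)
    n_bridges: int = len(BRIDGE_LIBRARY)
    n_endgroups: int = len(ENDGROUP_LIBRARY)
    n_molecules: int = 50
    symmetry_degree: int = 2
    bridge_probability: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if min(self.n_cores, self.n_bridges, self.n_endgroups,
               self.n_molecules) < 1:
            raise ValueError("all fixture counts must be positive")
        if self.symmetry_degree < 1:
            raise ValueError("symmetry_degree must be >= 1")


@dataclass(frozen=True)
class FixtureMolecule:
    """An assembled molecule with its ground-truth parts (stripped forms)."""

    smiles: str
    core: str
    substituents: tuple[tuple[tuple[int, ...], Optional[str], str], ...]
    # each: (site marks sharing the substituent, bridge or None, end-group)

    def part_multiset(self) -> list[str]:
        """Stripped canonical forms of every constituent fragment, with one
        bridge and one end-group copy per attachment site."""
        parts = [strip_marks(mol_from_smiles(self.core))]
        for sites, bridge, end in self.substituents:
            for _ in sites:
                if bridge is not None:
                    parts.append(strip_marks(mol_from_smiles(bridge)))
                parts.append(strip_marks(mol_from_smiles(end)))
        return sorted(parts)


def generate_fixtures(spec: FixtureSpec) -> list[FixtureMolecule]:
    """Deterministically generate a corpus of distinct fixture molecules."""
    rng = np.random.default_rng(spec.seed)
    cores = CORE_LIBRARY[: spec.n_cores]
    bridges = BRIDGE_LIBRARY[: spec.n_bridges]
    ends = ENDGROUP_LIBRARY[: spec.n_endgroups]

    seen: set[str] = set()
    out: list[FixtureMolecule] = []
    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(out) < spec.n_molecules and attempts < max_attempts:
        attempts += 1
        core_smiles = cores[rng.integers(len(cores))]
        mol = mol_from_smiles(core_smiles)
        site_marks = sorted(ap.mark for ap in attachment_points(mol))
        # partition sites into groups of symmetry_degree that share a
        # substituent (a shorter trailing group absorbs the remainder)
        order = [site_marks[i] for i in rng.permutation(len(site_marks))]
        groups: list[tuple[int, ...]] = []
        step = max(1, min(spec.symmetry_degree, len(order)))
        for i in range(0, len(order), step):
            groups.append(tuple(sorted(order[i:i + step])))

        substituents = []
        try:
            for group in groups:
                # merge the group's sites onto one shared mark
                shared = group[0]
                for atom in mol.GetAtoms():
                    if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() in group:
                        atom.SetAtomMapNum(shared)
                bridge = None
                if rng.random() < spec.bridge_probability:
                    bridge = bridges[rng.integers(len(bridges))]
                end = ends[rng.integers(len(ends))]
                if bridge is not None:
                    mol = attach_at_mark(mol, shared, mol_from_smiles(bridge))
                    (new_mark,) = {ap.mark for ap in attachment_points(mol)
                                   if ap.mark not in site_marks}
                    mol = attach_at_mark(mol, new_mark, mol_from_smiles(end))
                else:
                    mol = attach_at_mark(mol, shared, mol_from_smiles(end))
                site_marks = [m for m in site_marks if m not in group]
                substituents.append((group, bridge, end))
        except Exception:  # infeasible combination; resample
            continue
        assert not attachment_points(mol)
        smiles = to_smiles(mol)
        if smiles in seen:
            continue
        seen.add(smiles)
        out.append(FixtureMolecule(
            smiles=smiles, core=core_smiles,
            substituents=tuple(substituents),
        ))
    if len(out) < spec.n_molecules:
        raise RuntimeError(
            f"could only generate {len(out)} distinct fixtures "
            f"(requested {spec.n_molecules}); enlarge the libraries"
        )
    return out


def fixtures_to_json(fixtures: Sequence[FixtureMolecule]) -> str:
    return json.dumps(
        [
            {
                "smiles": f.smiles,
                "core": f.core,
                "substituents": [
                    {"sites": list(sites), "bridge": bridge, "end": end}
                    for sites, bridge, end in f.substituents
                ],
            }
            for f in fixtures
        ],
        indent=2,
    )
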