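"""Shared molecule handling: canonicalization, fingerprints, attachment chemistry.

Molecules are RDKit ``Mol`` objects throughout the package.  Open attachment
points ("reactive positions") are represented as wildcard (dummy) atoms whose
integer *mark* is stored in the atom-map number, so a phenyl fragment with one
open position labelled 3 serializes as ``[*:3]c1ccccc1``.  This single
serialization dialect is used everywhere: files round-trip bit-exactly through
canonical SMILES.

Aromaticity follows RDKit's default perception (the RDKit aromaticity model),
applied on every parse, so equivalent Kekulé and aromatic inputs canonicalize
identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

#: Community-default Morgan fingerprint parameters, overridable per call.
DEFAULT_FP_RADIUS = 2
DEFAULT_FP_NBITS = 2048

HYDROGEN_CAP = "hydrogen"
METHYL_CAP = "methyl"


class InvalidMoleculeError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class AttachmentError(ValueError):
    """Raised when an attachment or capping operation is chemically impossible."""


@dataclass(frozen=True)
class AttachmentPoint:
    """An open reactive position: a wildcard atom and its integer mark."""

    atom_index: int
    mark: int


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary Morgan fingerprint."""

    bits: DataStructs.ExplicitBitVect
    radius: int
    n_bits: int

    def popcount(self) -> int:
        return int(self.bits.GetNumOnBits())


# ---------------------------------------------------------------------------
# Parsing / canonical forms
# ---------------------------------------------------------------------------

def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES into an RDKit molecule with aromaticity perceived.

    Raises :class:`InvalidMoleculeError` naming the offending string on
    failure.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise InvalidMoleculeError(f"invalid SMILES input: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidMoleculeError(f"could not parse SMILES: {smiles!r}")
    return mol


def to_smiles(mol: Chem.Mol) -> str:
    """Canonical SMILES of a molecule (marks serialized as atom maps)."""
    return Chem.MolToSmiles(mol)


def canonicalize(smiles: str) -> str:
    """Deterministic canonical SMILES form; idempotent."""
    return to_smiles(mol_from_smiles(smiles))


def copy_mol(mol: Chem.Mol) -> Chem.Mol:
    return Chem.Mol(mol)


def heavy_atom_count(mol: Chem.Mol) -> int:
    """Number of non-hydrogen, non-wildcard atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


# ---------------------------------------------------------------------------
# Fingerprints and similarity
# ---------------------------------------------------------------------------

_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    gen = _FP_GENERATORS.get(key)
    if gen is None:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        _FP_GENERATORS[key] = gen
    return gen


def morgan_fingerprint(
    mol: Chem.Mol | str,
    radius: int = DEFAULT_FP_RADIUS,
    n_bits: int = DEFAULT_FP_NBITS,
) -> Fingerprint:
    """Morgan (ECFP-style) bit fingerprint of a molecule."""
    if isinstance(mol, str):
        mol = mol_from_smiles(mol)
    bits = _generator(radius, n_bits).GetFingerprint(mol)
    return Fingerprint(bits=bits, radius=radius, n_bits=n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto similarity |A∩B| / |A∪B| on fingerprint bit sets, in [0, 1].

    Identical non-empty vectors give 1.0; by the RDKit convention two
    all-zero vectors give 0.0.
    """
    if a.n_bits != b.n_bits:
        raise ValueError(
            f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}"
        )
    return float(DataStructs.TanimotoSimilarity(a.bits, b.bits))


def fingerprint_array(fp: Fingerprint):
    """Fingerprint as a dense numpy float array (for k-means / PCA)."""
    import numpy as np

    arr = np.zeros(fp.n_bits, dtype=np.float64)
    for bit in fp.bits.GetOnBits():
        arr[bit] = 1.0
    return arr


# ---------------------------------------------------------------------------
# Attachment points
# ---------------------------------------------------------------------------

def attachment_points(mol: Chem.Mol) -> list[AttachmentPoint]:
    """All open attachment points (wildcard atoms), in atom-index order."""
    return [
        AttachmentPoint(atom_index=a.GetIdx(), mark=a.GetAtomMapNum())
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0
    ]


def open_marks(mol: Chem.Mol) -> set[int]:
    """Set of distinct marks currently open on the molecule."""
    return {ap.mark for ap in attachment_points(mol)}


def strip_marks(mol: Chem.Mol) -> str:
    """Canonical form with mark labels removed but wildcard atoms retained.

    This is the vocabulary lookup key: fragments that differ only in their
    mark labels collapse to the same form, while fragments differing in
    attachment position stay distinct.
    """
    stripped = Chem.Mol(mol)
    for atom in stripped.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(stripped)


def set_all_marks(mol: Chem.Mol, mark: int) -> Chem.Mol:
    """Copy of ``mol`` with every wildcard atom relabelled to ``mark``."""
    out = Chem.Mol(mol)
    for atom in out.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomMapNum(mark)
    return out


def _sanitized(rw: Chem.RWMol) -> Chem.Mol:
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - valence errors are rare
        raise AttachmentError(f"valence violation after attachment: {exc}") from exc
    return mol


def attach_at_mark(state_mol: Chem.Mol, mark: int, frag: Chem.Mol) -> Chem.Mol:
    """Bond one copy of ``frag`` at *every* position of ``state_mol`` carrying
    ``mark``, via new single bonds.

    The fragment's first attachment point (lowest atom index) is consumed by
    the bond; its remaining attachment points become new open positions with
    fresh marks.  The fresh marks are shared across copies, so positions that
    were symmetric before the attachment remain symmetric after it — the
    mechanism by which identically marked sites always end up with identical
    substituents.
    """
    targets = [ap.atom_index for ap in attachment_points(state_mol) if ap.mark == mark]
    if not targets:
        raise AttachmentError(f"no attachment point with mark {mark} on molecule")
    frag_aps = attachment_points(frag)
    if not frag_aps:
        raise AttachmentError("fragment has no free attachment point")
    bond_ap = frag_aps[0].atom_index

    # Fresh marks for the fragment's leftover points, distinct from anything
    # open on the state or on the fragment itself.
    existing = open_marks(state_mol) | {ap.mark for ap in frag_aps}
    next_mark = max(existing, default=-1) + 1
    relabel = {}
    for ap in frag_aps[1:]:
        relabel[ap.atom_index] = next_mark
        next_mark += 1

    frag = Chem.Mol(frag)
    for idx, new_mark in relabel.items():
        frag.GetAtomWithIdx(idx).SetAtomMapNum(new_mark)

    rw = Chem.RWMol(state_mol)
    doomed: list[int] = []
    for t in targets:
        offset = rw.GetNumAtoms()
        rw.InsertMol(frag)
        state_nbrs = rw.GetAtomWithIdx(t).GetNeighbors()
        if not state_nbrs:
            raise AttachmentError(f"attachment point atom {t} has no neighbor")
        frag_dummy = offset + bond_ap
        frag_nbrs = rw.GetAtomWithIdx(frag_dummy).GetNeighbors()
        if not frag_nbrs:
            raise AttachmentError("fragment attachment point has no neighbor")
        rw.AddBond(state_nbrs[0].GetIdx(), frag_nbrs[0].GetIdx(), Chem.BondType.SINGLE)
        doomed.extend([t, frag_dummy])
    for idx in sorted(doomed, reverse=True):
        rw.RemoveAtom(idx)
    return _sanitized(rw)


def join_at_atoms(mol_a: Chem.Mol, ap_a: int, mol_b: Chem.Mol, ap_b: int) -> Chem.Mol:
    """Join two molecules with a single bond, consuming one attachment point
    (given by wildcard atom index) on each side."""
    rw = Chem.RWMol(mol_a)
    offset = rw.GetNumAtoms()
    rw.InsertMol(mol_b)
    nbr_a = rw.GetAtomWithIdx(ap_a).GetNeighbors()[0].GetIdx()
    nbr_b = rw.GetAtomWithIdx(offset + ap_b).GetNeighbors()[0].GetIdx()
    rw.AddBond(nbr_a, nbr_b, Chem.BondType.SINGLE)
    for idx in sorted([ap_a, offset + ap_b], reverse=True):
        rw.RemoveAtom(idx)
    return _sanitized(rw)


def cap_open_positions(mol: Chem.Mol, cap: str = HYDROGEN_CAP) -> Chem.Mol:
    """Replace every open attachment point with a terminal cap.

    ``hydrogen`` removes the wildcard (the neighbour regains an implicit H),
    leaving the heavy-atom count unchanged; ``methyl`` converts the wildcard
    into a carbon, adding one heavy atom per capped position.
    """
    if cap not in (HYDROGEN_CAP, METHYL_CAP):
        raise ValueError(f"unknown cap {cap!r}; expected 'hydrogen' or 'methyl'")
    aps = attachment_points(mol)
    if not aps:
        return Chem.Mol(mol)
    rw = Chem.RWMol(mol)
    if cap == METHYL_CAP:
        for ap in aps:
            atom = rw.GetAtomWithIdx(ap.atom_index)
            atom.SetAtomicNum(6)
            atom.SetAtomMapNum(0)
    else:
        for ap in sorted(aps, key=lambda p: p.atom_index, reverse=True):
            rw.RemoveAtom(ap.atom_index)
    return _sanitized(rw)


# ---------------------------------------------------------------------------
# File I/O: .smi and SDF readers
# ---------------------------------------------------------------------------

def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read a one-record-per-line .smi file.

    Each line is ``SMILES`` optionally followed by a tab/space-separated name.
    Returns ``(canonical_smiles, name)`` pairs; blank lines and ``#`` comments
    are skipped.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            records.append((canonicalize(smiles), name))
    return records


def read_sdf_file(path) -> list[tuple[str, str]]:
    """Read molecules from an SDF file as ``(canonical_smiles, name)`` pairs."""
    records = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
        records.append((to_smiles(mol), name or f"mol{i + 1}"))
    return records


def write_smiles_file(path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for smiles, name in records:
            fh.write(f"{smiles}\t{name}\n")
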