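"""Systematic two-step matched-molecular-pair (MMP) fragmentation.

Step one cuts every eligible acyclic single bond of a compound once,
producing (key, value) pairs: the larger piece is the key (core), the
smaller the value (substituent). Step two applies the same cut rule to the
cores themselves; cores whose second-step cuts share a common scaffold form
"core MMPs", the relation that later groups analog series into one SAR
matrix.

Cut eligibility follows the standard single-cut MMP convention: single,
non-ring bonds between two heavy atoms. Cuts producing a bare-hydrogen value
cannot arise (both bond atoms are heavy). Size caps keep analog semantics:
a value may span at most ``max_value_fraction`` of the parent's heavy atoms
(default 0.5) and a core's distinguishing fragment at most
``max_distinguishing_fraction`` of the core's heavy atoms (default 1/3);
both are configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

from rdkit import Chem

from .chem_io import (
    Compound,
    Fragment,
    _n_heavy,
    fragment_from_mol,
    mol_from_fragment_smiles,
)

DEFAULT_MAX_VALUE_FRACTION = 0.5
DEFAULT_MAX_DISTINGUISHING_FRACTION = 1.0 / 3.0


@dataclass(frozen=True, order=True)
class Fragmentation:
    """One single-cut decomposition of a compound into (key, value)."""

    compound_id: str
    key: Fragment
    value: Fragment


@dataclass(frozen=True, order=True)
class CoreRelation:
    """Two cores forming an MMP under second-step fragmentation.

    Stored with ``core_a < core_b`` (canonical notation order) so the
    relation set is symmetric-free and irreflexive by construction.
    """

    core_a: Fragment
    core_b: Fragment
    shared_scaffold: str


def _eligible_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of cuttable bonds: acyclic single bonds between heavy atoms."""
    out = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 0 or b.GetAtomicNum() == 0:
            continue  # never cut the bond to an attachment point
        out.append(bond.GetIdx())
    return out


def _cut(mol: Chem.Mol, bond_idx: int, label: int) -> tuple[Chem.Mol, Chem.Mol]:
    """Break one bond, capping both ends with wildcard atoms mapped ``label``."""
    fragmented = Chem.FragmentOnBonds(
        mol, [bond_idx], addDummies=True, dummyLabels=[(label, label)]
    )
    # FragmentOnBonds writes the label as an isotope; move it to an atom map
    for atom in fragmented.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetIsotope():
            atom.SetAtomMapNum(atom.GetIsotope())
            atom.SetIsotope(0)
    pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    if len(pieces) != 2:  # pragma: no cover - acyclic cut always splits in two
        raise RuntimeError("single acyclic cut did not yield two pieces")
    return pieces[0], pieces[1]


def _prepare_mol(smiles: str, keep_stereo: bool) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid structure: {smiles!r}")
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    return mol


def fragment_compound(
    c: Compound,
    max_value_fraction: float = DEFAULT_MAX_VALUE_FRACTION,
    *,
    keep_stereo: bool = True,
) -> set[Fragmentation]:
    """Enumerate all single-cut (key, value) fragmentations of a compound.

    One :class:`Fragmentation` per eligible bond; the smaller piece becomes
    the value (ties broken toward the lexicographically smaller canonical
    notation). Cuts whose value exceeds ``max_value_fraction`` of the
    parent's heavy atoms are discarded. Returns the empty set when no bond
    is cuttable (single-atom or all-ring molecules).
    """
    if not 0 < max_value_fraction <= 0.5:
        raise ValueError("max_value_fraction must be in (0, 0.5]")
    if c.structure is None:
        raise ValueError(f"compound {c.id} has no structure")
    mol = _prepare_mol(c.structure, keep_stereo)
    total = _n_heavy(mol)
    out: set[Fragmentation] = set()
    for bond_idx in _eligible_bonds(mol):
        p, q = (fragment_from_mol(m) for m in _cut(mol, bond_idx, label=1))
        value, key = sorted((p, q), key=lambda f: (f.n_heavy, f.notation))
        if value.n_heavy / total > max_value_fraction:
            continue
        out.add(Fragmentation(compound_id=c.id, key=key, value=value))
    return out


def reassemble(key: Fragment, value: Fragment) -> str:
    """Join a key and a value at their matching attachment points.

    Returns the canonical SMILES of the reassembled molecule.
    """
    combined = Chem.CombineMols(
        mol_from_fragment_smiles(key.notation),
        mol_from_fragment_smiles(value.notation),
    )
    merged = Chem.molzip(combined)
    return Chem.MolToSmiles(merged)


def fragment_core(
    k: Fragment,
    max_distinguishing_fraction: float = DEFAULT_MAX_DISTINGUISHING_FRACTION,
) -> set[tuple[Fragment, Fragment]]:
    """Second-step fragmentation of a core into (scaffold, distinguishing) pairs.

    The core's existing attachment point stays inside whichever piece
    contains it; that piece is the second-step key (the scaffold candidate,
    carrying attachment labels 1 and 2). The other piece is the
    distinguishing fragment — the localized difference between related
    cores. Pairs whose distinguishing fragment exceeds
    ``max_distinguishing_fraction`` of the core's heavy atoms are discarded.
    """
    mol = mol_from_fragment_smiles(k.notation)
    n_attach = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)
    if n_attach != 1:
        raise ValueError(f"core must carry exactly one attachment point: {k.notation}")
    total = _n_heavy(mol)
    out: set[tuple[Fragment, Fragment]] = set()
    for bond_idx in _eligible_bonds(mol):
        p, q = _cut(mol, bond_idx, label=2)
        p_has_origin = any(
            a.GetAtomicNum() == 0 and a.GetAtomMapNum() == 1 for a in p.GetAtoms()
        )
        scaffold_mol, dist_mol = (p, q) if p_has_origin else (q, p)
        scaffold = fragment_from_mol(scaffold_mol)
        distinguishing = fragment_from_mol(dist_mol)
        if distinguishing.n_heavy / total > max_distinguishing_fraction:
            continue
        out.add((scaffold, distinguishing))
    return out


def core_scaffold_groups(
    cores: Iterable[Fragment],
    max_distinguishing_fraction: float = DEFAULT_MAX_DISTINGUISHING_FRACTION,
) -> dict[str, list[Fragment]]:
    """Index cores by shared second-step scaffold.

    Returns scaffold notation → sorted cores producing it; only scaffolds
    shared by at least two distinct cores are kept. This hash-grouping is
    the main path for core-MMP discovery (no all-pairs comparison).
    """
    index: dict[str, set[Fragment]] = {}
    for core in set(cores):
        for scaffold, _dist in fragment_core(core, max_distinguishing_fraction):
            index.setdefault(scaffold.notation, set()).add(core)
    return {
        s: sorted(members)
        for s, members in index.items()
        if len(members) >= 2
    }


def core_mmp_pairs(
    cores: Iterable[Fragment],
    max_distinguishing_fraction: float = DEFAULT_MAX_DISTINGUISHING_FRACTION,
) -> set[CoreRelation]:
    """All unordered pairs of distinct cores sharing a second-step scaffold."""
    relations: set[CoreRelation] = set()
    for scaffold, members in core_scaffold_groups(
        cores, max_distinguishing_fraction
    ).items():
        for a, b in itertools.combinations(members, 2):
            relations.add(CoreRelation(core_a=a, core_b=b, shared_scaffold=scaffold))
    return relations


def fragment_library(
    compounds: Iterable[Compound],
    max_value_fraction: float = DEFAULT_MAX_VALUE_FRACTION,
    *,
    keep_stereo: bool = True,
) -> set[Fragmentation]:
    """First-step fragmentation of a whole library."""
    out: set[Fragmentation] = set()
    for c in compounds:
        out |= fragment_compound(c, max_value_fraction, keep_stereo=keep_stereo)
    return out
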