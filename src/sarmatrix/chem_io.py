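"""Compound/fragment I/O and canonical identity.

Compound tables are plain delimited text (CSV/TSV) holding SMILES plus a
potency (negative log molar, e.g. pIC50) and/or a binary activity label.
Fragment tables are the structure-free alternative: rows of
(compound_id, core_id, value_id, class[, potency]) as used by public SARM
depositions in which compound structures are withheld.

Fragments carry exactly one labelled attachment point, written as a mapped
wildcard atom (``[*:1]``); canonicalization is delegated to RDKit so that two
fragments differing only by input atom order share one canonical string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ACTIVE = "active"
INACTIVE = "inactive"
CLASSES = (ACTIVE, INACTIVE)

#: column names of a structure-free fragment table
FRAGMENT_TABLE_COLUMNS = ("compound_id", "core_id", "value_id")


class LibraryError(ValueError):
    """Fatal problem with an input compound table."""


@dataclass(frozen=True)
class Compound:
    """One library member.

    Parameters
    ----------
    id:
        Opaque unique identifier.
    structure:
        SMILES, or ``None`` for structure-free records.
    potency:
        Negative log molar potency (pIC50-like), if measured.
    activity_class:
        ``"active"`` / ``"inactive"``, if classified.
    """

    id: str
    structure: str | None = None
    potency: float | None = None
    activity_class: str | None = None

    @property
    def is_measured(self) -> bool:
        return self.potency is not None or self.activity_class is not None

    def with_class(self, label: str) -> "Compound":
        return replace(self, activity_class=label)


@dataclass(frozen=True, order=True)
class Fragment:
    """A canonical fragment: SMILES with labelled attachment point(s).

    ``notation`` is the RDKit canonical SMILES including the mapped wildcard
    atoms, so value-equality of two :class:`Fragment` objects is graph
    identity of the underlying fragments.
    """

    notation: str
    n_heavy: int

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.notation


# fragments playing the row role (cores / keys) vs column role (values)
FragmentKey = Fragment
FragmentValue = Fragment


def _n_heavy(mol: Chem.Mol) -> int:
    """Heavy-atom count excluding wildcard attachment atoms."""
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def _n_attachments(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 0)


def mol_from_fragment_smiles(notation: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(notation)
    if mol is None:
        raise ValueError(f"unparseable fragment notation: {notation!r}")
    return mol


def fragment_from_mol(mol: Chem.Mol) -> Fragment:
    """Canonicalize an RDKit fragment molecule (wildcards already mapped)."""
    return Fragment(notation=Chem.MolToSmiles(mol), n_heavy=_n_heavy(mol))


def canonical_fragment(notation: str, n_attachments: int = 1) -> Fragment:
    """Return the canonical form of a fragment notation.

    The notation must contain exactly ``n_attachments`` wildcard atoms
    (``*`` / ``[*:n]``). Canonicalization is idempotent and invariant under
    atom reordering of the input.
    """
    mol = mol_from_fragment_smiles(notation)
    found = _n_attachments(mol)
    if found != n_attachments:
        raise ValueError(
            f"fragment must have exactly {n_attachments} attachment point(s), "
            f"found {found}: {notation!r}"
        )
    # normalize unmapped wildcards to label 1 (single-cut convention)
    if n_attachments == 1:
        for atom in mol.GetAtoms():
            if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum() == 0:
                atom.SetAtomMapNum(1)
    return fragment_from_mol(mol)


def _normalize_class(raw: object) -> str:
    label = str(raw).strip().lower()
    if label in {"active", "act", "1", "true", "a"}:
        return ACTIVE
    if label in {"inactive", "inact", "0", "false", "i"}:
        return INACTIVE
    raise LibraryError(f"unrecognized activity class label: {raw!r}")


def read_library(
    path: str | Path,
    format: str = "smiles-csv",
    *,
    columns: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[Compound] | pd.DataFrame:
    """Read a compound library table.

    Parameters
    ----------
    path:
        Delimited text file.
    format:
        ``"smiles-csv"`` — SMILES table, returns a list of :class:`Compound`
        (unparseable structures are logged and skipped);
        ``"fragment-table"`` — structure-free (compound_id, core_id, value_id,
        class[, potency][, matrix_id]) records, returned as a DataFrame.
    columns:
        Optional mapping from logical names (``id``, ``smiles``, ``potency``,
        ``class``) to the actual column headers.
    delimiter:
        Field delimiter; sniffed by pandas when ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"input file not found: {path}")
    df = pd.read_csv(path, sep=delimiter, engine="python")

    if format == "fragment-table":
        colmap = dict(columns or {})
        df = df.rename(columns={v: k for k, v in colmap.items()})
        missing = [c for c in FRAGMENT_TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise LibraryError(f"fragment table missing columns: {missing}")
        if df.empty:
            raise LibraryError(f"no records in fragment table: {path}")
        dup = df["compound_id"][df["compound_id"].duplicated()].unique()
        if len(dup):
            raise LibraryError(f"duplicated compound ids: {sorted(map(str, dup))}")
        if "class" in df.columns:
            df = df.assign(**{"class": df["class"].map(_normalize_class)})
        return df

    if format != "smiles-csv":
        raise ValueError(f"unknown library format: {format!r}")

    names = {"id": "id", "smiles": "smiles", "potency": "potency", "class": "class"}
    names.update(columns or {})
    for logical in ("id", "smiles"):
        if names[logical] not in df.columns:
            raise LibraryError(
                f"required column {names[logical]!r} ({logical}) absent from {path}"
            )
    has_potency = names["potency"] in df.columns
    has_class = names["class"] in df.columns
    if not has_potency and not has_class:
        raise LibraryError(
            "library must carry a potency or an activity-class column "
            f"({names['potency']!r} / {names['class']!r})"
        )

    compounds: list[Compound] = []
    n_skipped = 0
    for _, row in df.iterrows():
        smiles = str(row[names["smiles"]])
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            n_skipped += 1
            logger.warning("skipping unparseable SMILES for id=%s: %s",
                           row[names["id"]], smiles)
            continue
        potency = None
        if has_potency and pd.notna(row[names["potency"]]):
            potency = float(row[names["potency"]])
        label = None
        if has_class and pd.notna(row[names["class"]]):
            label = _normalize_class(row[names["class"]])
        compounds.append(
            Compound(id=str(row[names["id"]]), structure=Chem.MolToSmiles(mol),
                     potency=potency, activity_class=label)
        )
    if n_skipped:
        logger.warning("skipped %d unparseable structure(s) in %s", n_skipped, path)
    if not compounds:
        raise LibraryError(f"no parseable compounds in {path}")
    ids = [c.id for c in compounds]
    dup = sorted({i for i in ids if ids.count(i) > 1})
    if dup:
        raise LibraryError(f"duplicated compound ids: {dup}")
    return compounds


def write_library(compounds: Iterable[Compound], path: str | Path) -> None:
    """Write compounds as CSV (round-trips ids, potencies and classes)."""
    rows = [
        {"id": c.id, "smiles": c.structure, "potency": c.potency,
         "class": c.activity_class}
        for c in compounds
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def compounds_by_id(compounds: Sequence[Compound]) -> dict[str, Compound]:
    return {c.id: c for c in compounds}
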