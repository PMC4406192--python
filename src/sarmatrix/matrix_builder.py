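"""SAR matrix (SARM) construction, virtual-compound enumeration and filtering.

A SARM is a cores × substituents grid gathering all analog series whose
cores share one second-step scaffold. Filled cells are library compounds;
empty cells are virtual compounds (VCs) — unexplored core–substituent
combinations implied by the matrix. Matrices are built deterministically:
rows and columns are sorted by canonical notation and matrix ids follow the
sorted scaffold order.

Row overlap — the mean, over rows, of the fraction of a row's filled
columns that are also filled in at least one other row — measures how much
substitution patterns are shared between the series of a matrix; matrices
with more than 50% row overlap are considered informative for probability
calculations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .chem_io import Compound, Fragment
from .fragmentation import CoreRelation, Fragmentation, reassemble

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERLAP = 0.5
DEFAULT_MIN_COMPOUNDS = 5

#: cell marker used in long-form exports for empty cells
VIRTUAL = "VIRTUAL"


class CellConflictError(ValueError):
    """Two distinct compounds claim the same (core, value) cell."""


@dataclass
class SARMatrix:
    """One SAR matrix: rows are cores, columns are substituents."""

    matrix_id: str
    rows: list[str]
    columns: list[str]
    cells: dict[tuple[str, str], Compound]
    scaffold: str | None = None
    fragments: dict[str, Fragment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (core, value) in self.cells:
            if core not in self.rows or value not in self.columns:
                raise ValueError(f"cell ({core}, {value}) outside matrix axes")

    @property
    def n_filled(self) -> int:
        return len(self.cells)

    @property
    def n_virtual(self) -> int:
        return len(self.rows) * len(self.columns) - self.n_filled

    def compound_at(self, core: str, value: str) -> Compound | None:
        return self.cells.get((core, value))

    def is_filled(self, core: str, value: str) -> bool:
        return (core, value) in self.cells

    def row_cells(self, core: str) -> list[tuple[str, Compound]]:
        return [(v, c) for (r, v), c in self.cells.items() if r == core]

    def column_cells(self, value: str) -> list[tuple[str, Compound]]:
        return [(r, c) for (r, v), c in self.cells.items() if v == value]


@dataclass(frozen=True)
class VirtualCompound:
    """An empty matrix cell: an unexplored core–substituent combination."""

    matrix_id: str
    core: str
    value: str
    assembled_structure: str | None = None

    @property
    def id(self) -> str:
        return f"{self.matrix_id}:{self.core}|{self.value}"


def build_matrices(
    fragmentations: Iterable[Fragmentation],
    relations: Iterable[CoreRelation],
    compounds: Mapping[str, Compound],
) -> list[SARMatrix]:
    """Group fragmentations into SAR matrices keyed by shared scaffold.

    One matrix per second-step scaffold appearing in ``relations``: its rows
    are all cores related through that scaffold, its columns the union of
    substituents observed with those cores. A core participating in several
    scaffolds appears in several matrices. Matrices with fewer than two rows
    or two columns are discarded.

    Raises
    ------
    CellConflictError
        If two distinct compounds fragment into the same (core, value).
    """
    frags = list(fragmentations)
    by_core: dict[str, list[Fragmentation]] = {}
    fragment_lookup: dict[str, Fragment] = {}
    for f in frags:
        by_core.setdefault(f.key.notation, []).append(f)
        fragment_lookup[f.key.notation] = f.key
        fragment_lookup[f.value.notation] = f.value

    groups: dict[str, set[str]] = {}
    for rel in relations:
        groups.setdefault(rel.shared_scaffold, set()).update(
            (rel.core_a.notation, rel.core_b.notation)
        )
        fragment_lookup.setdefault(rel.core_a.notation, rel.core_a)
        fragment_lookup.setdefault(rel.core_b.notation, rel.core_b)

    matrices: list[SARMatrix] = []
    for i, scaffold in enumerate(sorted(groups)):
        cores = sorted(c for c in groups[scaffold] if c in by_core)
        cells: dict[tuple[str, str], Compound] = {}
        for core in cores:
            for f in by_core[core]:
                cell = (core, f.value.notation)
                previous = cells.get(cell)
                if previous is not None and previous.id != f.compound_id:
                    raise CellConflictError(
                        f"cell {cell} claimed by compounds "
                        f"{previous.id!r} and {f.compound_id!r}"
                    )
                cells[cell] = compounds[f.compound_id]
        columns = sorted({v for (_, v) in cells})
        if len(cores) < 2 or len(columns) < 2:
            continue
        matrices.append(
            SARMatrix(
                matrix_id=f"M{i:05d}",
                rows=cores,
                columns=columns,
                cells=cells,
                scaffold=scaffold,
                fragments={k: fragment_lookup[k] for k in (*cores, *columns)},
            )
        )
    return matrices


def build_matrices_from_records(
    records: pd.DataFrame,
    *,
    require_min_shape: bool = True,
) -> list[SARMatrix]:
    """Build matrices from a structure-free fragment table.

    ``records`` needs columns compound_id, core_id, value_id and class
    and/or potency; an optional ``matrix_id`` (or ``scaffold_id``) column
    partitions the records, otherwise all records form a single matrix.
    This is the input path for deposited SARMs whose structures are
    withheld.
    """
    df = records.copy()
    group_col = next(
        (c for c in ("matrix_id", "scaffold_id") if c in df.columns), None
    )
    if group_col is None:
        group_col = "matrix_id"
        df[group_col] = "all"

    matrices: list[SARMatrix] = []
    for i, (gid, sub) in enumerate(sorted(df.groupby(group_col, sort=True))):
        cells: dict[tuple[str, str], Compound] = {}
        for _, row in sub.iterrows():
            compound = Compound(
                id=str(row["compound_id"]),
                potency=float(row["potency"]) if "potency" in sub.columns
                and pd.notna(row["potency"]) else None,
                activity_class=row["class"] if "class" in sub.columns
                and pd.notna(row["class"]) else None,
            )
            cell = (str(row["core_id"]), str(row["value_id"]))
            previous = cells.get(cell)
            if previous is not None and previous.id != compound.id:
                raise CellConflictError(
                    f"cell {cell} claimed by compounds "
                    f"{previous.id!r} and {compound.id!r}"
                )
            cells[cell] = compound
        rows = sorted({r for (r, _) in cells})
        columns = sorted({v for (_, v) in cells})
        if require_min_shape and (len(rows) < 2 or len(columns) < 2):
            continue
        matrices.append(
            SARMatrix(matrix_id=f"M{i:05d}", rows=rows, columns=columns,
                      cells=cells, scaffold=str(gid))
        )
    return matrices


def enumerate_virtuals(m: SARMatrix) -> list[VirtualCompound]:
    """All empty cells of a matrix, as virtual compounds.

    When the matrix carries structural fragments, each VC's structure is
    assembled by joining its core and substituent at the attachment point.
    """
    out: list[VirtualCompound] = []
    for core in m.rows:
        for value in m.columns:
            if m.is_filled(core, value):
                continue
            structure = None
            if core in m.fragments and value in m.fragments:
                structure = reassemble(m.fragments[core], m.fragments[value])
            out.append(
                VirtualCompound(matrix_id=m.matrix_id, core=core, value=value,
                                assembled_structure=structure)
            )
    return out


def row_overlap(m: SARMatrix) -> float:
    """Mean fraction of each row's filled columns shared with other rows."""
    if len(m.rows) < 2:
        raise ValueError(f"matrix {m.matrix_id} has fewer than two rows")
    filled_by_row = {r: {v for (rr, v) in m.cells if rr == r} for r in m.rows}
    fractions = []
    for r, cols in filled_by_row.items():
        if not cols:
            fractions.append(0.0)
            continue
        others = set().union(
            *(filled_by_row[o] for o in m.rows if o != r)
        )
        fractions.append(len(cols & others) / len(cols))
    return sum(fractions) / len(fractions)


def filter_informative(
    matrices: Sequence[SARMatrix],
    min_overlap: float = DEFAULT_MIN_OVERLAP,
    min_compounds: int = DEFAULT_MIN_COMPOUNDS,
) -> list[SARMatrix]:
    """Keep matrices with row overlap above ``min_overlap`` and at least
    ``min_compounds`` filled cells."""
    kept = [
        m
        for m in matrices
        if row_overlap(m) > min_overlap and m.n_filled >= min_compounds
    ]
    logger.info("kept %d / %d informative matrices", len(kept), len(matrices))
    return kept


def matrices_to_long(matrices: Sequence[SARMatrix]) -> pd.DataFrame:
    """Long-form export: one row per cell, empty cells marked VIRTUAL."""
    rows = []
    for m in matrices:
        for core in m.rows:
            for value in m.columns:
                c = m.compound_at(core, value)
                rows.append(
                    {
                        "matrix_id": m.matrix_id,
                        "core": core,
                        "value": value,
                        "compound_id": c.id if c else VIRTUAL,
                        "class": c.activity_class if c else None,
                        "potency": c.potency if c else None,
                    }
                )
    return pd.DataFrame(rows)


def summarize_matrices(matrices: Sequence[SARMatrix]) -> pd.DataFrame:
    """Per-matrix statistics (shape, fill, row overlap)."""
    return pd.DataFrame(
        [
            {
                "matrix_id": m.matrix_id,
                "n_rows": len(m.rows),
                "n_cols": len(m.columns),
                "n_filled": m.n_filled,
                "n_virtual": m.n_virtual,
                "row_overlap": row_overlap(m),
            }
            for m in matrices
        ]
    )
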