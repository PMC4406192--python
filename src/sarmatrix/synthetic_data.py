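"""Synthetic libraries with known ground truth.

Two generators make every stage of the pipeline testable without external
data:

* :func:`demo_screen` — the canonical nine-compound, three-core,
  four-value binary screen used throughout the documentation to trace the
  conditional-probability calculation by hand.
* :func:`generate_library` — combinatorial scaffold × core × value
  libraries with a planted additive potency model (potency = mu + a_core +
  b_value + noise), optional activity cliffs, controlled sparsity, and a
  label cutoff; the planted truth is emitted alongside so tests can check
  exact recovery, ranking quality and matrix shapes against the plan.

Structure-free mode emits opaque core/value identifiers (mirroring public
SARM depositions without structures); structural mode assembles real
molecules from ring scaffolds and substituent fragments so that the
fragmentation machinery can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import ACTIVE, INACTIVE, Compound, canonical_fragment
from .fragmentation import reassemble

# ---------------------------------------------------------------------------
# nine-compound demo screen
# ---------------------------------------------------------------------------

#: (compound_id, core_id, value_id, class). The class assignment is the
#: unique one consistent with the method's reference description of this
#: matrix: value v1 occurs in one active and one inactive compound; core c3
#: is twice as likely inactive as active (2/3 vs 1/3); both compounds with
#: value v2 are active; the two v3 compounds split one per class; two of
#: the three v4 compounds are inactive, with the inactive v4 compound on
#: core c3 being I; and compound A (core c1) belongs to c1's majority
#: (active) class while D (core c2) is c2's minority (inactive) compound.
DEMO_SCREEN_RECORDS: tuple[tuple[str, str, str, str], ...] = (
    ("A", "c1", "v1", ACTIVE),
    ("B", "c1", "v2", ACTIVE),
    ("C", "c1", "v4", INACTIVE),
    ("D", "c2", "v1", INACTIVE),
    ("E", "c2", "v3", ACTIVE),
    ("F", "c2", "v4", ACTIVE),
    ("G", "c3", "v2", ACTIVE),
    ("H", "c3", "v3", INACTIVE),
    ("I", "c3", "v4", INACTIVE),
)


def demo_screen() -> pd.DataFrame:
    """The nine-compound demo fragment table (structure-free records)."""
    return pd.DataFrame(
        DEMO_SCREEN_RECORDS, columns=["compound_id", "core_id", "value_id", "class"]
    )


# ---------------------------------------------------------------------------
# planned combinatorial libraries
# ---------------------------------------------------------------------------


@dataclass
class LibraryPlan:
    """Recipe for a combinatorial library with planted truth.

    Default condition emulates a small screening campaign over closely
    related analog series: six scaffold families of four cores sharing ten
    substituents, 70% of cells measured, potencies on a pIC50-like scale
    (mu = 5) with core effects of SD 0.5 log units, substituent effects of
    SD 1 log unit and assay noise of 0.3 log units, and an activity call
    at pPot >= 6 (roughly the top fifth of the library).
    """

    n_scaffolds: int = 6
    cores_per_scaffold: int = 4
    n_values: int = 10
    fill_fraction: float = 0.7
    mu: float = 5.0
    core_effect_sd: float = 0.5
    value_effect_sd: float = 1.0
    noise_sd: float = 0.3
    active_threshold: float | None = 6.0
    #: optional planted activity cliff: (scaffold_idx, core_idx, value_idx, delta)
    cliff: tuple[int, int, int, float] | None = None
    #: when set, classes come from planted fragment roles instead of the
    #: potency cutoff: these fractions of values / cores are designated
    #: active-driving and a cell is active iff both its fragments are
    active_value_fraction: float | None = None
    active_core_fraction: float | None = None
    seed: int = 0

    @classmethod
    def binary_screen(cls, seed: int = 0, **overrides) -> "LibraryPlan":
        """Default binary-screen condition with planted active fragments.

        30% of values and 50% of cores are active-driving and a compound is
        active iff both its fragments are, giving roughly 15% active cells.
        Matrices are kept dense (eight cores sharing twelve substituents at
        80% fill, ~460 compounds) because the conditional-probability
        method is a per-fragment counting statistic: with only a handful of
        compounds per column, a planted role can be entirely unexpressed in
        the measured cells (an active core observed only with inactive
        substituents is indistinguishable from an inactive one), so sparse
        conditions probe identifiability rather than the classifier.
        """
        fields = dict(active_value_fraction=0.3, active_core_fraction=0.5,
                      cores_per_scaffold=8, n_values=12, fill_fraction=0.8,
                      seed=seed)
        fields.update(overrides)
        return cls(**fields)

    def __post_init__(self) -> None:
        if not 0 < self.fill_fraction <= 1:
            raise ValueError("fill_fraction must be in (0, 1]")
        if self.n_scaffolds < 1 or self.cores_per_scaffold < 2 or self.n_values < 2:
            raise ValueError(
                "need at least 2 cores per scaffold and 2 values to form matrices"
            )


def _fill_mask(
    rng: np.random.Generator, n_rows: int, n_cols: int, fill: float
) -> np.ndarray:
    """Random boolean mask with every row and column hit at least once."""
    mask = rng.random((n_rows, n_cols)) < fill
    for i in range(n_rows):
        if not mask[i].any():
            mask[i, rng.integers(n_cols)] = True
    for j in range(n_cols):
        if not mask[:, j].any():
            mask[rng.integers(n_rows), j] = True
    return mask


def generate_library(plan: LibraryPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structure-free combinatorial library with planted additive potency.

    Returns ``(library, truth)``:

    * ``library`` — measured cells only: compound_id, scaffold_id, core_id,
      value_id, potency (planted + noise) and, when the plan sets an
      ``active_threshold``, a binary class. Labels derive from the planted
      (noise-free) potency: the binary call emulates a screening cutoff on
      the underlying activity, while ``noise_sd`` models assay scatter on
      the numeric potency channel.
    * ``truth`` — every cell (measured and virtual): planted noise-free
      potency, planted class, core/value effects, and whether the cell was
      measured. Same seed, same output.
    """
    rng = np.random.default_rng(plan.seed)
    fragment_roles = plan.active_value_fraction is not None

    def _pick_roles(n: int, fraction: float) -> np.ndarray:
        # the plan states a fraction, so realize it exactly (which
        # fragments get the role stays seeded-random)
        roles = np.zeros(n, dtype=bool)
        k = max(1, round(fraction * n))
        roles[rng.choice(n, size=k, replace=False)] = True
        return roles

    value_ids = [f"v{j:02d}" for j in range(plan.n_values)]
    b = rng.normal(0.0, plan.value_effect_sd, plan.n_values)
    value_active = (
        _pick_roles(plan.n_values, plan.active_value_fraction)
        if fragment_roles else np.zeros(plan.n_values, dtype=bool)
    )

    lib_rows, truth_rows = [], []
    for s in range(plan.n_scaffolds):
        scaffold_id = f"s{s:02d}"
        core_ids = [f"{scaffold_id}_c{i:02d}" for i in range(plan.cores_per_scaffold)]
        a = rng.normal(0.0, plan.core_effect_sd, plan.cores_per_scaffold)
        core_active = (
            _pick_roles(
                plan.cores_per_scaffold,
                plan.active_core_fraction
                if plan.active_core_fraction is not None else 0.5,
            )
            if fragment_roles
            else np.zeros(plan.cores_per_scaffold, dtype=bool)
        )
        mask = _fill_mask(rng, plan.cores_per_scaffold, plan.n_values,
                          plan.fill_fraction)
        if plan.cliff is not None and plan.cliff[0] == s:
            mask[plan.cliff[1], plan.cliff[2]] = True  # a cliff must be observed
        noise = rng.normal(0.0, plan.noise_sd, mask.shape) if plan.noise_sd else (
            np.zeros(mask.shape))
        for i, core_id in enumerate(core_ids):
            for j, value_id in enumerate(value_ids):
                planted = plan.mu + a[i] + b[j]
                if plan.cliff is not None and (s, i, j) == plan.cliff[:3]:
                    planted += plan.cliff[3]
                measured = bool(mask[i, j])
                observed = planted + noise[i, j] if measured else np.nan
                if fragment_roles:
                    planted_class = (
                        ACTIVE if core_active[i] and value_active[j] else INACTIVE
                    )
                else:
                    planted_class = (
                        ACTIVE if plan.active_threshold is not None
                        and planted >= plan.active_threshold else INACTIVE
                    )
                truth_rows.append(
                    {
                        "scaffold_id": scaffold_id,
                        "core_id": core_id,
                        "value_id": value_id,
                        "core_effect": a[i],
                        "value_effect": b[j],
                        "core_active": bool(core_active[i]),
                        "value_active": bool(value_active[j]),
                        "planted_potency": planted,
                        "planted_class": planted_class,
                        "measured": measured,
                        "compound_id": f"{core_id}_{value_id}" if measured else None,
                    }
                )
                if measured:
                    row = {
                        "compound_id": f"{core_id}_{value_id}",
                        "scaffold_id": scaffold_id,
                        "core_id": core_id,
                        "value_id": value_id,
                        "potency": observed,
                    }
                    if fragment_roles or plan.active_threshold is not None:
                        row["class"] = planted_class
                    lib_rows.append(row)
    return pd.DataFrame(lib_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# structural mode
# ---------------------------------------------------------------------------

#: two-site ring scaffolds: site 1 takes the value, site 2 the
#: core-distinguishing substituent
RING_SCAFFOLDS: tuple[str, ...] = (
    "[*:1]c1ccc([*:2])cc1",       # benzene, para
    "[*:1]c1ccc([*:2])nc1",       # pyridine
    "[*:1]c1ccc([*:2])s1",        # thiophene
    "[*:1]c1ccc([*:2])o1",        # furan
    "[*:1]c1ccc2ccc([*:2])cc2c1", # naphthalene
    "[*:1]c1cnc([*:2])cn1",       # pyrazine
)

# core and value alphabets are disjoint so that no two planned
# (core, value) combinations assemble into the same molecule (which would
# be a legitimate duplicate-cell error downstream)
CORE_SUBSTITUENTS: tuple[str, ...] = (
    "[*:2]F", "[*:2]Cl", "[*:2]Br", "[*:2]I", "[*:2]C#N", "[*:2]SC",
)

VALUE_SUBSTITUENTS: tuple[str, ...] = (
    "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]CCO", "[*:1]OC", "[*:1]OCC",
    "[*:1]N", "[*:1]NC", "[*:1]CO", "[*:1]C(C)C",
)


@dataclass
class StructuralLibrary:
    compounds: list[Compound]
    #: compound_id -> (planned core notation, planned value notation)
    planned: dict[str, tuple[str, str]] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def generate_structural_library(plan: LibraryPlan) -> StructuralLibrary:
    """Assemble real molecules realizing a :class:`LibraryPlan`.

    Each scaffold family uses one ring system; cores are ring + one
    distinguishing substituent (with the value attachment open) and values
    are small substituent fragments shared across families. Potencies and
    labels follow the same planted additive model as the structure-free
    mode, drawn with the same seed.
    """
    if plan.n_scaffolds > len(RING_SCAFFOLDS):
        raise ValueError(f"at most {len(RING_SCAFFOLDS)} structural scaffolds")
    if plan.cores_per_scaffold > len(CORE_SUBSTITUENTS):
        raise ValueError(f"at most {len(CORE_SUBSTITUENTS)} cores per scaffold")
    if plan.n_values > len(VALUE_SUBSTITUENTS):
        raise ValueError(f"at most {len(VALUE_SUBSTITUENTS)} structural values")

    library, truth = generate_library(plan)
    values = {
        f"v{j:02d}": canonical_fragment(VALUE_SUBSTITUENTS[j])
        for j in range(plan.n_values)
    }
    cores: dict[str, str] = {}
    for s in range(plan.n_scaffolds):
        ring = Chem.MolFromSmiles(RING_SCAFFOLDS[s])
        for i in range(plan.cores_per_scaffold):
            sub = Chem.MolFromSmiles(CORE_SUBSTITUENTS[i])
            merged = Chem.molzip(Chem.CombineMols(ring, sub))
            cores[f"s{s:02d}_c{i:02d}"] = Chem.MolToSmiles(merged)

    compounds, planned = [], {}
    for _, row in library.iterrows():
        core_frag = canonical_fragment(cores[row["core_id"]])
        value_frag = values[row["value_id"]]
        smiles = reassemble(core_frag, value_frag)
        compounds.append(
            Compound(
                id=row["compound_id"],
                structure=smiles,
                potency=float(row["potency"]),
                activity_class=row.get("class"),
            )
        )
        planned[row["compound_id"]] = (core_frag.notation, value_frag.notation)
    return StructuralLibrary(compounds=compounds, planned=planned, truth=truth)


def random_molecules(
    rng: np.random.Generator, n: int, id_prefix: str = "R"
) -> list[Compound]:
    """Small random molecules assembled from the structural building blocks.

    Used by oracle-equivalence tests that need varied but valid chemistry.
    """
    out = []
    for k in range(n):
        ring = Chem.MolFromSmiles(RING_SCAFFOLDS[rng.integers(len(RING_SCAFFOLDS))])
        sub = Chem.MolFromSmiles(
            CORE_SUBSTITUENTS[rng.integers(len(CORE_SUBSTITUENTS))]
        )
        core = Chem.MolToSmiles(Chem.molzip(Chem.CombineMols(ring, sub)))
        value = VALUE_SUBSTITUENTS[rng.integers(len(VALUE_SUBSTITUENTS))]
        smiles = reassemble(canonical_fragment(core), canonical_fragment(value))
        out.append(Compound(id=f"{id_prefix}{k:03d}", structure=smiles,
                            potency=float(rng.normal(6.0, 1.0))))
    return out


def shuffle_smiles(smiles: str, rng: np.random.Generator) -> str:
    """Re-serialize a (fragment) SMILES with a random atom order."""
    mol = Chem.MolFromSmiles(smiles)
    order = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
    return Chem.MolToSmiles(Chem.RenumberAtoms(mol, order), canonical=False)
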