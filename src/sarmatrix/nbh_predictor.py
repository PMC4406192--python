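"""Neighborhood (NBH) potency prediction for virtual compounds.

A qualifying neighborhood of a virtual compound X is a triple of measured
compounds in one matrix: D shares X's substituent, G shares X's core, and E
sits at D's core and G's substituent. Under the Free-Wilson additivity
assumption (potency decomposes, on a log scale, into independent core and
substituent contributions) each triple yields a local mini-QSAR estimate

    pot(X) = pot(D) + pot(G) - pot(E)

and the final prediction averages over all qualifying neighborhoods found
across all matrices containing X's core and substituent. The standard
deviation across neighborhoods is reported as a reliability indicator: low
SD signals SAR continuity (trustworthy additivity), high SD signals
discontinuity / activity cliffs, where additivity breaks down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .chem_io import Compound
from .matrix_builder import SARMatrix, VirtualCompound, enumerate_virtuals


@dataclass(frozen=True)
class NeighborhoodTriple:
    """One (D, E, G) neighborhood supporting a prediction for X."""

    matrix_id: str
    D: Compound  # shares X's value, different core
    E: Compound  # D's core combined with G's value
    G: Compound  # shares X's core, different value

    @property
    def ids(self) -> tuple[str, str, str]:
        return (self.D.id, self.E.id, self.G.id)


@dataclass(frozen=True)
class PotencyPrediction:
    virtual_compound: VirtualCompound
    mean_potency: float
    sd: float
    n_neighborhoods: int
    per_nbh_values: tuple[float, ...]


def find_neighborhoods(
    x: VirtualCompound, matrices: Sequence[SARMatrix]
) -> list[NeighborhoodTriple]:
    """Enumerate all qualifying (D, E, G) triples for a virtual compound.

    Searches every matrix whose axes contain X's core and substituent and
    whose (core, value) cell is empty; triples recurring in several
    matrices are de-duplicated by their compound-id triple.
    """
    seen: set[tuple[str, str, str]] = set()
    triples: list[NeighborhoodTriple] = []
    for m in matrices:
        if x.core not in m.rows or x.value not in m.columns:
            continue
        if m.is_filled(x.core, x.value):
            continue
        for d_core in m.rows:
            if d_core == x.core:
                continue
            D = m.compound_at(d_core, x.value)
            if D is None or D.potency is None:
                continue
            for g_value in m.columns:
                if g_value == x.value:
                    continue
                G = m.compound_at(x.core, g_value)
                E = m.compound_at(d_core, g_value)
                if G is None or G.potency is None or E is None or E.potency is None:
                    continue
                t = NeighborhoodTriple(matrix_id=m.matrix_id, D=D, E=E, G=G)
                if t.ids not in seen:
                    seen.add(t.ids)
                    triples.append(t)
    return triples


def predict_from_triple(t: NeighborhoodTriple) -> float:
    """Free-Wilson estimate from one neighborhood: D + G - E."""
    if t.D.potency is None or t.E.potency is None or t.G.potency is None:
        raise ValueError(f"neighborhood {t.ids} has a missing potency")
    return t.D.potency + t.G.potency - t.E.potency


def predict_potency(
    x: VirtualCompound, matrices: Sequence[SARMatrix]
) -> PotencyPrediction | None:
    """Aggregate all neighborhoods of X into a mean/SD prediction.

    Returns ``None`` when no qualifying neighborhood exists. All triples
    are pooled into a single mean and (population) standard deviation, so
    a single-neighborhood prediction has SD exactly 0.
    """
    values = tuple(predict_from_triple(t) for t in find_neighborhoods(x, matrices))
    if not values:
        return None
    mean = sum(values) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
    return PotencyPrediction(
        virtual_compound=x,
        mean_potency=mean,
        sd=sd,
        n_neighborhoods=len(values),
        per_nbh_values=values,
    )


def predict_all(matrices: Sequence[SARMatrix]) -> pd.DataFrame:
    """Potency predictions for every virtual compound of every matrix.

    Virtual compounds sharing one (core, value) combination across matrices
    are predicted once, pooling neighborhoods from all matrices.
    """
    seen: set[tuple[str, str]] = set()
    rows = []
    for m in matrices:
        for vc in enumerate_virtuals(m):
            key = (vc.core, vc.value)
            if key in seen:
                continue
            seen.add(key)
            p = predict_potency(vc, matrices)
            if p is None:
                continue
            rows.append(
                {
                    "vc_id": vc.id,
                    "core": vc.core,
                    "value": vc.value,
                    "mean_potency": p.mean_potency,
                    "sd": p.sd,
                    "n_nbh": p.n_neighborhoods,
                }
            )
    return pd.DataFrame(rows)
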