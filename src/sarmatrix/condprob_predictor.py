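"""Conditional-probability activity prediction from binary screening data.

Given a SAR matrix whose filled cells carry binary labels (active /
inactive), the method scores every virtual compound X = (core c, value v)
in five steps:

1. Initial class probabilities per fragment: P(y|v) and P(y|c) are the
   fraction of compounds containing the value v (resp. core c) that belong
   to class y.
2. Weighted matrices: each measured compound x receives weight
   1 / P(y(x)|v(x)) in the value-weighted matrix and 1 / P(y(x)|c(x)) in
   the core-weighted matrix. A compound of the minority class for its
   fragment gets a high weight: its class is unlikely to be explained by
   that fragment, so the blame shifts to the partner fragment.
3. Class contributions with additive smoothing alpha (default 0.1, which
   keeps contributions positive for fragment/class combinations without
   observations): for a core c in the value-weighted matrix

       C_c(y) = (alpha + sum of weights of class-y compounds with core c)
                / (2*alpha + N_c)

   where N_c counts measured compounds containing c; analogously C_v(y)
   from the core-weighted matrix.
4. Normalization: P(y) = C(y) / (C(active) + C(inactive)), a proper
   two-class probability per fragment.
5. Combination: the activity probability of X is the normalized product

       p_x = P_c(act) P_v(act) / (P_c(act) P_v(act) + P_c(inact) P_v(inact))

A virtual compound occurring in several informative matrices is scored in
each and the per-matrix probabilities are aggregated (arithmetic mean by
default). Classification applies a caller-chosen threshold (default 0.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import pandas as pd

from .chem_io import ACTIVE, CLASSES, INACTIVE
from .matrix_builder import SARMatrix, VirtualCompound

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.1
DEFAULT_THRESHOLD = 0.5

Flavor = Literal["value-weighted", "core-weighted"]


@dataclass
class ClassProbabilityTable:
    """Initial conditional class probabilities per core and value."""

    core_probs: dict[str, dict[str, float]]
    value_probs: dict[str, dict[str, float]]
    core_counts: dict[str, dict[str, int]]
    value_counts: dict[str, dict[str, int]]

    def prob(self, role: str, fragment: str, y: str) -> float:
        table = self.core_probs if role == "core" else self.value_probs
        return table[fragment][y]


@dataclass
class WeightedMatrix:
    """Per-compound weights derived from inverse class probabilities."""

    matrix: SARMatrix
    flavor: Flavor
    weights: dict[str, float]  # compound_id -> weight > 0


@dataclass(frozen=True)
class ClassContribution:
    fragment: str
    contributions: dict[str, float]  # class -> C(y) >= alpha/(2 alpha + N)
    alpha: float

    def __getitem__(self, y: str) -> float:
        return self.contributions[y]


@dataclass
class ActivityProbability:
    """Final score of one virtual (core, value) combination."""

    core: str
    value: str
    p_x: float
    per_matrix: dict[str, float]
    classification: str
    threshold: float

    @property
    def n_matrices(self) -> int:
        return len(self.per_matrix)

    @property
    def vc_id(self) -> str:
        return f"{self.core}|{self.value}"


def _measured_cells(m: SARMatrix) -> list[tuple[str, str, str, str]]:
    """(core, value, compound_id, class) for every filled cell; labels required."""
    out = []
    for (core, value), c in m.cells.items():
        if c.activity_class not in CLASSES:
            raise ValueError(
                f"compound {c.id} in matrix {m.matrix_id} has no binary "
                f"activity class (got {c.activity_class!r})"
            )
        out.append((core, value, c.id, c.activity_class))
    return out


def initial_class_probabilities(m: SARMatrix) -> ClassProbabilityTable:
    """Observed class frequencies per core and per value (step 1)."""
    core_counts: dict[str, dict[str, int]] = {}
    value_counts: dict[str, dict[str, int]] = {}
    for core, value, _cid, y in _measured_cells(m):
        core_counts.setdefault(core, {c: 0 for c in CLASSES})[y] += 1
        value_counts.setdefault(value, {c: 0 for c in CLASSES})[y] += 1

    def to_probs(counts: dict[str, dict[str, int]]) -> dict[str, dict[str, float]]:
        return {
            frag: {y: n[y] / (n[ACTIVE] + n[INACTIVE]) for y in CLASSES}
            for frag, n in counts.items()
        }

    return ClassProbabilityTable(
        core_probs=to_probs(core_counts),
        value_probs=to_probs(value_counts),
        core_counts=core_counts,
        value_counts=value_counts,
    )


def weight_matrix(
    m: SARMatrix, table: ClassProbabilityTable, flavor: Flavor
) -> WeightedMatrix:
    """Assign each measured compound the inverse of its own-class
    probability given its value (value-weighted) or core (core-weighted)
    fragment (step 2)."""
    role = "value" if flavor == "value-weighted" else "core"
    weights: dict[str, float] = {}
    for core, value, cid, y in _measured_cells(m):
        fragment = value if role == "value" else core
        p = table.prob(role, fragment, y)
        if p == 0:  # cannot occur: the compound itself witnesses its class
            raise ZeroDivisionError(
                f"zero class probability for {role} {fragment!r}, class {y}"
            )
        weights[cid] = 1.0 / p
    return WeightedMatrix(matrix=m, flavor=flavor, weights=weights)


def class_contribution(
    fragment: str, wm: WeightedMatrix, alpha: float = DEFAULT_ALPHA
) -> ClassContribution:
    """Smoothed, weight-summed class contribution of one fragment (step 3).

    Core contributions come from the value-weighted matrix and value
    contributions from the core-weighted matrix.
    """
    if alpha <= 0:
        raise ValueError("smoothing alpha must be > 0")
    role = "core" if wm.flavor == "value-weighted" else "value"
    sums = {c: 0.0 for c in CLASSES}
    n = 0
    for core, value, cid, y in _measured_cells(wm.matrix):
        if (core if role == "core" else value) != fragment:
            continue
        sums[y] += wm.weights[cid]
        n += 1
    if n == 0:
        raise ValueError(
            f"{role} {fragment!r} has no measured compound in matrix "
            f"{wm.matrix.matrix_id}"
        )
    return ClassContribution(
        fragment=fragment,
        contributions={y: (alpha + sums[y]) / (2 * alpha + n) for y in CLASSES},
        alpha=alpha,
    )


def normalize_contribution(c: ClassContribution) -> tuple[float, float]:
    """Normalize contributions into a two-class probability (step 4)."""
    total = c[ACTIVE] + c[INACTIVE]
    if total <= 0:  # unreachable for alpha > 0
        raise ZeroDivisionError("class contributions sum to zero")
    return c[ACTIVE] / total, c[INACTIVE] / total


def combine_probability(
    core_probs: tuple[float, float], value_probs: tuple[float, float]
) -> float:
    """Normalized product of core and value activity probabilities (step 5)."""
    ca, ci = core_probs
    va, vi = value_probs
    denominator = ca * va + ci * vi
    if denominator == 0:
        raise ZeroDivisionError("degenerate core/value probabilities")
    return ca * va / denominator


@dataclass
class MatrixExplanation:
    """All intermediates of a single-matrix probability calculation."""

    matrix_id: str
    core: str
    value: str
    alpha: float
    initial: ClassProbabilityTable
    value_weighted: WeightedMatrix
    core_weighted: WeightedMatrix
    core_contribution: ClassContribution
    value_contribution: ClassContribution
    core_probs: tuple[float, float] = field(default=(0.0, 0.0))
    value_probs: tuple[float, float] = field(default=(0.0, 0.0))
    p_x: float = 0.0


def explain_probability(
    m: SARMatrix, core: str, value: str, alpha: float = DEFAULT_ALPHA
) -> MatrixExplanation:
    """Score one (core, value) cell in one matrix, keeping every intermediate.

    The cell's own compound, if filled, is part of the statistics only
    through its row/column partners — scoring is meant for empty cells.
    """
    table = initial_class_probabilities(m)
    vw = weight_matrix(m, table, "value-weighted")
    cw = weight_matrix(m, table, "core-weighted")
    core_c = class_contribution(core, vw, alpha)
    value_c = class_contribution(value, cw, alpha)
    ex = MatrixExplanation(
        matrix_id=m.matrix_id, core=core, value=value, alpha=alpha,
        initial=table, value_weighted=vw, core_weighted=cw,
        core_contribution=core_c, value_contribution=value_c,
    )
    ex.core_probs = normalize_contribution(core_c)
    ex.value_probs = normalize_contribution(value_c)
    ex.p_x = combine_probability(ex.core_probs, ex.value_probs)
    return ex


def matrix_probability(
    m: SARMatrix, core: str, value: str, alpha: float = DEFAULT_ALPHA
) -> float:
    """Single-matrix activity probability for a (core, value) combination."""
    return explain_probability(m, core, value, alpha).p_x


def predict_activity(
    vcs: Sequence[VirtualCompound],
    matrices: Sequence[SARMatrix],
    alpha: float = DEFAULT_ALPHA,
    threshold: float = DEFAULT_THRESHOLD,
    strategy: Literal["mean", "max"] = "mean",
) -> list[ActivityProbability]:
    """Score virtual compounds across all (pre-filtered) matrices.

    ``matrices`` should already be restricted to informative ones (see
    :func:`sarmatrix.matrix_builder.filter_informative`); the restriction
    is left to the caller. Virtual compounds whose (core, value) occurs as
    an empty cell in none of the matrices are omitted, with a logged count.
    Results are sorted by decreasing probability.
    """
    by_matrix = {m.matrix_id: m for m in matrices}
    keys: list[tuple[str, str]] = []
    for vc in vcs:
        if (vc.core, vc.value) not in keys:
            keys.append((vc.core, vc.value))

    results: list[ActivityProbability] = []
    n_omitted = 0
    for core, value in keys:
        per_matrix: dict[str, float] = {}
        for mid, m in by_matrix.items():
            if core in m.rows and value in m.columns and not m.is_filled(core, value):
                per_matrix[mid] = matrix_probability(m, core, value, alpha)
        if not per_matrix:
            n_omitted += 1
            continue
        p = (
            sum(per_matrix.values()) / len(per_matrix)
            if strategy == "mean"
            else max(per_matrix.values())
        )
        results.append(
            ActivityProbability(
                core=core, value=value, p_x=p, per_matrix=per_matrix,
                classification=ACTIVE if p >= threshold else INACTIVE,
                threshold=threshold,
            )
        )
    if n_omitted:
        logger.info(
            "%d virtual compound(s) occur in no informative matrix and were "
            "omitted", n_omitted,
        )
    results.sort(key=lambda r: (-r.p_x, r.core, r.value))
    return results


def predictions_to_frame(results: Sequence[ActivityProbability]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vc_id": r.vc_id,
                "core": r.core,
                "value": r.value,
                "p_x": r.p_x,
                "n_matrices": r.n_matrices,
                "classification": r.classification,
            }
            for r in results
        ]
    )


def display_value(x: float, decimals: int = 2) -> float:
    """Two-decimal display convention used in worked-example reports.

    Values are floored at the last kept digit (1.125 -> 1.12,
    0.7659 -> 0.76); internal math is never rounded.
    """
    scale = 10**decimals
    return int(x * scale) / scale
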