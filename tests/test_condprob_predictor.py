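"""Conditional-probability activity prediction.

The nine-compound demo matrix is the hand-checkable reference: all of its
intermediates have closed-form fractions (weights are inverses of small
class fractions, contributions are ratios of small sums), asserted here
exactly.
"""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sarmatrix.chem_io import ACTIVE, INACTIVE, Compound
from sarmatrix.condprob_predictor import (
    class_contribution,
    combine_probability,
    display_value,
    explain_probability,
    initial_class_probabilities,
    matrix_probability,
    normalize_contribution,
    predict_activity,
    weight_matrix,
)
from sarmatrix.matrix_builder import (
    SARMatrix,
    build_matrices_from_records,
    enumerate_virtuals,
    filter_informative,
)
from sarmatrix.synthetic_data import LibraryPlan, generate_library


def classed_matrix(cells, mid="M00000"):
    rows = sorted({r for r, _ in cells})
    cols = sorted({v for _, v in cells})
    return SARMatrix(
        matrix_id=mid, rows=rows, columns=cols,
        cells={
            (r, v): Compound(id=f"{r}{v}", activity_class=y)
            for (r, v), y in cells.items()
        },
    )


class TestInitialProbabilities:
    def test_demo_value_v1_is_even_split(self, demo_matrix):
        table = initial_class_probabilities(demo_matrix)
        assert table.value_probs["v1"] == {ACTIVE: 0.5, INACTIVE: 0.5}

    def test_demo_core_c3_twice_as_inactive(self, demo_matrix):
        table = initial_class_probabilities(demo_matrix)
        assert table.core_probs["c3"][INACTIVE] == pytest.approx(2 / 3)
        assert table.core_probs["c3"][ACTIVE] == pytest.approx(1 / 3)

    def test_all_active_matrix(self):
        m = classed_matrix({(r, v): ACTIVE for r in "ab" for v in "xy"})
        table = initial_class_probabilities(m)
        assert all(p[ACTIVE] == 1.0 for p in table.core_probs.values())
        assert all(p[ACTIVE] == 1.0 for p in table.value_probs.values())

    def test_unlabeled_cell_rejected(self):
        m = SARMatrix(
            matrix_id="M", rows=["a", "b"], columns=["x", "y"],
            cells={("a", "x"): Compound("1", potency=5.0),
                   ("b", "y"): Compound("2", activity_class=ACTIVE)},
        )
        with pytest.raises(ValueError, match="no binary activity class"):
            initial_class_probabilities(m)


class TestWeights:
    def test_demo_value_weights(self, demo_matrix):
        """Weights are inverse own-class value probabilities: G -> 1.0
        (v2 all active), H -> 2.0 (v3 split), I -> 1.5 (v4 two-thirds
        inactive)."""
        table = initial_class_probabilities(demo_matrix)
        wm = weight_matrix(demo_matrix, table, "value-weighted")
        assert wm.weights["G"] == pytest.approx(1.0)
        assert wm.weights["H"] == pytest.approx(2.0)
        assert wm.weights["I"] == pytest.approx(1.5)

    def test_demo_core_weights(self, demo_matrix):
        """A (majority class of c1) gets 1.5; D (minority of c2) gets 3.0."""
        table = initial_class_probabilities(demo_matrix)
        wm = weight_matrix(demo_matrix, table, "core-weighted")
        assert wm.weights["A"] == pytest.approx(1.5)
        assert wm.weights["D"] == pytest.approx(3.0)


class TestContributions:
    def test_demo_core_c3(self, demo_matrix):
        table = initial_class_probabilities(demo_matrix)
        wm = weight_matrix(demo_matrix, table, "value-weighted")
        c = class_contribution("c3", wm, alpha=0.1)
        assert c[ACTIVE] == pytest.approx((0.1 + 1.0) / 3.2)   # 0.34
        assert c[INACTIVE] == pytest.approx((0.1 + 2.0 + 1.5) / 3.2)  # 1.12

    def test_demo_value_v1(self, demo_matrix):
        table = initial_class_probabilities(demo_matrix)
        wm = weight_matrix(demo_matrix, table, "core-weighted")
        c = class_contribution("v1", wm, alpha=0.1)
        assert c[ACTIVE] == pytest.approx((0.1 + 1.5) / 2.2)   # 0.72
        assert c[INACTIVE] == pytest.approx((0.1 + 3.0) / 2.2)  # 1.40

    def test_unseen_class_gets_smoothing_floor(self):
        m = classed_matrix({("a", "x"): ACTIVE, ("a", "y"): ACTIVE,
                            ("b", "x"): ACTIVE, ("b", "y"): ACTIVE})
        table = initial_class_probabilities(m)
        wm = weight_matrix(m, table, "value-weighted")
        c = class_contribution("a", wm, alpha=0.1)
        assert c[INACTIVE] == pytest.approx(0.1 / 2.2)
        assert c[INACTIVE] > 0

    def test_absent_fragment_rejected(self, demo_matrix):
        table = initial_class_probabilities(demo_matrix)
        wm = weight_matrix(demo_matrix, table, "value-weighted")
        with pytest.raises(ValueError, match="no measured compound"):
            class_contribution("c99", wm)


class TestNormalizeAndCombine:
    def test_demo_normalized_probabilities(self, demo_matrix):
        ex = explain_probability(demo_matrix, "c3", "v1")
        assert ex.core_probs == pytest.approx((1.1 / 4.7, 3.6 / 4.7))
        assert ex.value_probs == pytest.approx((1.6 / 4.7, 3.1 / 4.7))

    def test_normalization_sums_to_one(self, demo_matrix):
        ex = explain_probability(demo_matrix, "c3", "v1")
        assert sum(ex.core_probs) == pytest.approx(1.0, abs=1e-12)
        assert sum(ex.value_probs) == pytest.approx(1.0, abs=1e-12)

    def test_equal_contributions_give_half(self):
        from sarmatrix.condprob_predictor import ClassContribution

        c = ClassContribution("f", {ACTIVE: 0.7, INACTIVE: 0.7}, alpha=0.1)
        assert normalize_contribution(c) == pytest.approx((0.5, 0.5))

    def test_uninformative_fragments_combine_to_half(self):
        assert combine_probability((0.5, 0.5), (0.5, 0.5)) == pytest.approx(0.5)

    def test_fully_active_limit(self):
        eps = 1e-9
        p = combine_probability((1 - eps, eps), (1 - eps, eps))
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_demo_combined_probability(self, demo_matrix):
        """p_x for the (c3, v1) cell is 0.1362 (displays as 0.13) and the
        0.5-threshold call is inactive."""
        (res,) = [
            r
            for r in predict_activity(
                enumerate_virtuals(demo_matrix), [demo_matrix]
            )
            if (r.core, r.value) == ("c3", "v1")
        ]
        expected = (1.1 * 1.6) / (1.1 * 1.6 + 3.6 * 3.1)
        assert res.p_x == pytest.approx(expected, abs=1e-12)
        assert display_value(res.p_x) == 0.13
        assert res.classification == INACTIVE


class TestPredictActivity:
    def test_duplicate_matrix_mean_is_single_value(self, demo_records):
        (m1,) = build_matrices_from_records(demo_records)
        (m2,) = build_matrices_from_records(demo_records)
        m2.matrix_id = "M99999"
        single = matrix_probability(m1, "c3", "v1")
        (res,) = [
            r
            for r in predict_activity(enumerate_virtuals(m1), [m1, m2])
            if (r.core, r.value) == ("c3", "v1")
        ]
        assert res.n_matrices == 2
        assert res.p_x == pytest.approx(single)

    def test_vc_outside_informative_matrices_omitted(self, demo_matrix, caplog):
        from sarmatrix.matrix_builder import VirtualCompound

        stranger = VirtualCompound(matrix_id="MX", core="c9", value="v9")
        with caplog.at_level("INFO"):
            res = predict_activity([stranger], [demo_matrix])
        assert res == []

    def test_ranking_separates_planted_roles(self):
        """Planted-active VCs rank above planted-inactive VCs on the
        default binary screen (independent rank statistic from sklearn)."""
        from sklearn.metrics import roc_auc_score

        lib, truth = generate_library(LibraryPlan.binary_screen(seed=1))
        mats = filter_informative(build_matrices_from_records(lib))
        vcs = [v for m in mats for v in enumerate_virtuals(m)]
        res = predict_activity(vcs, mats)
        t = truth.set_index(["core_id", "value_id"])
        y = [int(t.loc[(r.core, r.value), "planted_class"] == ACTIVE) for r in res]
        assert roc_auc_score(y, [r.p_x for r in res]) > 0.9


unit_open = st.floats(min_value=1e-6, max_value=1 - 1e-6)


class TestCombinationAlgebra:
    @given(pc=unit_open, pv=unit_open)
    @settings(derandomize=True, max_examples=200)
    def test_combined_probability_is_a_probability(self, pc, pv):
        p = combine_probability((pc, 1 - pc), (pv, 1 - pv))
        assert 0.0 <= p <= 1.0

    @given(pc=unit_open, pv=unit_open)
    @settings(derandomize=True, max_examples=200)
    def test_class_swap_complements(self, pc, pv):
        p = combine_probability((pc, 1 - pc), (pv, 1 - pv))
        q = combine_probability((1 - pc, pc), (1 - pv, pv))
        assert q == pytest.approx(1.0 - p, abs=1e-9)

    @given(pc=unit_open, pv=unit_open)
    @settings(derandomize=True, max_examples=200)
    def test_uninformative_partner_is_identity(self, pc, pv):
        assert combine_probability((0.5, 0.5), (pv, 1 - pv)) == pytest.approx(pv)
        assert combine_probability((pc, 1 - pc), (0.5, 0.5)) == pytest.approx(pc)

    @given(
        contributions=st.tuples(
            st.floats(min_value=1e-3, max_value=1e3),
            st.floats(min_value=1e-3, max_value=1e3),
        )
    )
    @settings(derandomize=True, max_examples=200)
    def test_normalization_is_scale_free(self, contributions):
        from sarmatrix.condprob_predictor import ClassContribution

        ca, ci = contributions
        base = normalize_contribution(
            ClassContribution("f", {ACTIVE: ca, INACTIVE: ci}, alpha=0.1)
        )
        scaled = normalize_contribution(
            ClassContribution("f", {ACTIVE: 7 * ca, INACTIVE: 7 * ci}, alpha=0.1)
        )
        assert sum(base) == pytest.approx(1.0, abs=1e-12)
        assert scaled == pytest.approx(base)


class TestInvariants:
    def _relabelled(self, records):
        flip = {ACTIVE: INACTIVE, INACTIVE: ACTIVE}
        out = records.copy()
        out["class"] = out["class"].map(flip)
        return out

    def test_class_relabelling_maps_p_to_one_minus_p(self, demo_records):
        (m,) = build_matrices_from_records(demo_records)
        (mf,) = build_matrices_from_records(self._relabelled(demo_records))
        for core, value in (("c3", "v1"), ("c1", "v3"), ("c2", "v2")):
            p = matrix_probability(m, core, value)
            pf = matrix_probability(mf, core, value)
            assert pf == pytest.approx(1.0 - p, abs=1e-12)

    def test_alpha_continuity_and_limit(self, demo_matrix):
        """p_x varies smoothly in alpha and flattens to 1/2 as alpha grows."""
        alphas = [0.01, 0.1, 1.0, 10.0, 1e4]
        ps = [matrix_probability(demo_matrix, "c3", "v1", alpha=a)
              for a in alphas]
        gaps = [abs(p - 0.5) for p in ps]
        assert all(b < a for a, b in zip(gaps, gaps[1:]))
        assert ps[-1] == pytest.approx(0.5, abs=1e-3)
        for a, b in zip(alphas, alphas[1:]):
            # no jumps: probe midpoints
            mid = matrix_probability(demo_matrix, "c3", "v1",
                                     alpha=(a + b) / 2)
            assert min(
                matrix_probability(demo_matrix, "c3", "v1", alpha=a),
                matrix_probability(demo_matrix, "c3", "v1", alpha=b),
            ) <= mid <= 0.5 + max(gaps)

    def test_every_fragment_normalizes_everywhere(self):
        lib, _ = generate_library(LibraryPlan.binary_screen(seed=2))
        for m in build_matrices_from_records(lib):
            table = initial_class_probabilities(m)
            vw = weight_matrix(m, table, "value-weighted")
            cw = weight_matrix(m, table, "core-weighted")
            for core in m.rows:
                pa, pi = normalize_contribution(class_contribution(core, vw))
                assert pa + pi == pytest.approx(1.0, abs=1e-12)
            for value in m.columns:
                pa, pi = normalize_contribution(class_contribution(value, cw))
                assert pa + pi == pytest.approx(1.0, abs=1e-12)
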