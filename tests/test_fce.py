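"""Fuzzy composition, aggregation, classification, end-to-end grading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldstress import fce
from coldstress.exceptions import (
    DegenerateInputError,
    DomainError,
    ValidationError,
)

W1, W2, W3 = [0.39, 0.11, 0.05], [0.14, 0.05, 0.03, 0.13], [0.06, 0.03, 0.02, 0.01]
E1 = fce.MembershipMatrix(
    [[0, 1, 0, 0, 0], [0, 0.9, 0.1, 0, 0], [1, 0, 0, 0, 0]],
    ("b11", "b12", "b13"),
    "B1",
)
E2 = fce.MembershipMatrix(
    [[1, 0, 0, 0, 0], [0.8, 0.2, 0, 0, 0], [0.7, 0.3, 0, 0, 0], [1, 0, 0, 0, 0]],
    ("b21", "b22", "b23", "b24"),
    "B2",
)
E3 = fce.MembershipMatrix(
    [[0.8, 0.2, 0, 0, 0], [0.9, 0.1, 0, 0, 0], [0.6, 0.4, 0, 0, 0], [1, 0, 0, 0, 0]],
    ("b31", "b32", "b33", "b34"),
    "B3",
)


class TestCompose:
    def test_environmental_group_vector(self):
        b1 = fce.compose(W1, E1)
        np.testing.assert_allclose(b1, [0.05, 0.489, 0.011, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.round(b1, 2), [0.05, 0.49, 0.01, 0, 0])

    def test_physiological_group_vector(self):
        b2 = fce.compose(W2, E2)
        np.testing.assert_allclose(b2, [0.331, 0.019, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.round(b2, 2), [0.33, 0.02, 0, 0, 0])

    def test_behavioral_group_vector_hand_product(self):
        np.testing.assert_allclose(
            fce.compose(W3, E3), [0.097, 0.023, 0, 0, 0], atol=1e-12
        )

    @pytest.mark.parametrize("operator", ["weighted_average", "max_min"])
    def test_one_hot_weights_select_a_row(self, operator):
        w = [1.0, 0.0, 0.0]
        np.testing.assert_allclose(
            fce.compose(w, E1, operator=operator), E1.values[0]
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fce.compose([0.5, 0.5], E1)

    def test_row_stochastic_plus_sum1_weights_give_sum1(self):
        w = np.array([0.2, 0.5, 0.3])
        assert fce.compose(w, E1).sum() == pytest.approx(1.0, abs=1e-12)


class TestAggregateNormalizeClassify:
    def test_comprehensive_vector_matches_published_example(self):
        b = [fce.compose(W1, E1), fce.compose(W2, E2), fce.compose(W3, E3)]
        v = fce.aggregate([0.54, 0.35, 0.11], b)
        np.testing.assert_allclose(np.round(v, 2), [0.15, 0.27, 0.01, 0, 0])
        v_norm = fce.normalize(v)
        assert round(float(v_norm[0]), 2) == 0.35
        idx, label = fce.classify(v_norm)
        assert (idx, label) == (2, "mild")

    def test_degenerate_first_level_weight_selects_group(self):
        b = [fce.compose(W1, E1), fce.compose(W2, E2), fce.compose(W3, E3)]
        np.testing.assert_allclose(fce.aggregate([1, 0, 0], b), b[0])

    def test_equal_group_vectors_are_a_fixed_point(self):
        vec = np.array([0.1, 0.6, 0.2, 0.1, 0.0])
        out = fce.aggregate([0.3, 0.45, 0.25], [vec, vec, vec])
        np.testing.assert_allclose(out, vec, atol=1e-12)

    def test_normalize_uniform_unchanged(self):
        np.testing.assert_allclose(fce.normalize([0.2] * 5), [0.2] * 5)

    def test_normalize_rejects_all_zero(self):
        with pytest.raises(DegenerateInputError):
            fce.normalize([0, 0, 0, 0, 0])

    def test_classify_one_hot_extreme(self):
        assert fce.classify([0, 0, 0, 0, 1]) == (5, "extreme")

    def test_classify_tie_breaks_toward_severe(self):
        assert fce.classify([0.4, 0.4, 0.2, 0, 0])[0] == 2

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_classification_invariant_to_positive_scaling(self, scale):
        v = np.array([0.12, 0.31, 0.27, 0.2, 0.1])
        assert fce.classify(fce.normalize(v)) == fce.classify(
            fce.normalize(v * scale)
        )


class TestMembershipFunctions:
    def _two_level_spec(self):
        # explicit trapezoids: level-2 plateau on [4, 6], symmetric
        # level-1/level-2 overlap on [2, 4]
        traps = (
            fce.Trapezoid(0, 0, 2, 4),
            fce.Trapezoid(2, 4, 6, 8),
            fce.Trapezoid(6, 8, 10, 12),
            fce.Trapezoid(10, 12, 14, 16),
            fce.Trapezoid(14, 16, 20, 20),
        )
        return fce.MembershipFunctionSpec(
            functions={"temperature_c": traps},
            domains={"temperature_c": (0.0, 20.0)},
        )

    def test_plateau_center_is_crisp(self):
        spec = self._two_level_spec()
        np.testing.assert_allclose(
            spec.memberships("temperature_c", 5.0), [0, 1, 0, 0, 0]
        )

    def test_symmetric_overlap_splits_evenly(self):
        spec = self._two_level_spec()
        np.testing.assert_allclose(
            spec.memberships("temperature_c", 3.0), [0.5, 0.5, 0, 0, 0]
        )

    def test_out_of_domain_names_indicator_and_bounds(self):
        spec = self._two_level_spec()
        with pytest.raises(DomainError, match=r"temperature_c.*\[0.0, 20.0\]"):
            spec.memberships("temperature_c", 25.0)

    def test_row_sums_to_one_across_domain(self, default_spec):
        for value in np.linspace(-59.9, 44.9, 200):
            row = default_spec.memberships("temperature_c", float(value))
            assert row.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(row >= 0)
        assert row.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(row >= 0)

    def test_from_centers_decreasing_marks_lower_as_severe(self, default_spec):
        assert default_spec.directions["temperature_c"] == "lower"
        assert default_spec.directions["humidity_pct"] == "higher"
        # far below the coldest center -> fully extreme
        np.testing.assert_allclose(
            default_spec.memberships("temperature_c", -50.0), [0, 0, 0, 0, 1]
        )


def _model(weights, e_matrices, operator="weighted_average"):
    return fce.EvaluationModel(
        weights=weights,
        group_indicators={
            "B1": ("b11", "b12", "b13"),
            "B2": ("b21", "b22", "b23", "b24"),
            "B3": ("b31", "b32", "b33", "b34"),
        },
        e_matrices=e_matrices,
        operator=operator,
    )


def _published_weights():
    return fce.FceWeights(
        group_weights={"B1": np.array(W1), "B2": np.array(W2), "B3": np.array(W3)},
        first_level=np.array([0.54, 0.35, 0.11]),
        group_order=("B1", "B2", "B3"),
        mode="global",
    )


class TestEvaluate:
    def test_worked_example_classifies_mild(self, worked_example_config):
        res = fce.evaluate(None, worked_example_config.evaluation_model())
        assert (res.level_index, res.label) == (2, "mild")
        np.testing.assert_allclose(
            np.round(res.combined, 2), [0.15, 0.27, 0.01, 0, 0]
        )
        assert round(float(res.normalized[0]), 2) == 0.35

    @pytest.mark.parametrize("level", [1, 2, 3, 4, 5])
    def test_all_one_hot_memberships_classify_that_level(self, level):
        onehot = np.zeros(5)
        onehot[level - 1] = 1.0
        e_matrices = {
            g: fce.MembershipMatrix(
                np.tile(onehot, (k, 1)), tuple(f"{g}_{i}" for i in range(k)), g
            )
            for g, k in (("B1", 3), ("B2", 4), ("B3", 4))
        }
        model = fce.EvaluationModel(
            weights=_published_weights(),
            group_indicators={g: e.indicator_labels for g, e in e_matrices.items()},
            e_matrices=e_matrices,
        )
        assert fce.evaluate(None, model).level_index == level

    def test_global_and_local_weight_modes_agree_on_worked_example(self, expert_hierarchy):
        e_matrices = {"B1": E1, "B2": E2, "B3": E3}
        levels = []
        for mode in ("global", "local"):
            weights = fce.FceWeights.from_hierarchy(expert_hierarchy, mode=mode)
            res = fce.evaluate(None, _model(weights, e_matrices))
            levels.append(res.level_index)
        assert levels[0] == levels[1]

    def test_local_mode_combined_vector_sums_to_one(self, expert_hierarchy):
        weights = fce.FceWeights.from_hierarchy(expert_hierarchy, mode="local")
        res = fce.evaluate(None, _model(weights, {"B1": E1, "B2": E2, "B3": E3}))
        assert res.combined.sum() == pytest.approx(1.0, abs=1e-9)

    def test_shifting_mass_toward_severe_never_decreases_level(self):
        rng = np.random.default_rng(42)
        weights = _published_weights()
        for _ in range(30):
            rows = rng.dirichlet(np.ones(5), size=11)
            base = {
                "B1": fce.MembershipMatrix(rows[:3], ("b11", "b12", "b13"), "B1"),
                "B2": fce.MembershipMatrix(
                    rows[3:7], ("b21", "b22", "b23", "b24"), "B2"
                ),
                "B3": fce.MembershipMatrix(
                    rows[7:], ("b31", "b32", "b33", "b34"), "B3"
                ),
            }
            before = fce.evaluate(None, _model(weights, base)).level_index
            # push one row's entire mass to the most severe level
            shifted = {g: m.values.copy() for g, m in base.items()}
            shifted["B1"][0] = [0, 0, 0, 0, 1]
            base2 = dict(base)
            base2["B1"] = fce.MembershipMatrix(
                shifted["B1"], ("b11", "b12", "b13"), "B1"
            )
            after = fce.evaluate(None, _model(weights, base2)).level_index
            assert after >= before

    def test_evaluation_is_deterministic(self, worked_example_config):
        model = worked_example_config.evaluation_model()
        a = fce.evaluate(None, model)
        b = fce.evaluate(None, model)
        assert a.normalized.tobytes() == b.normalized.tobytes()
        assert (a.level_index, a.label) == (b.level_index, b.label)

    def test_record_driven_evaluation_with_default_spec(
        self, expert_config, default_spec, nov9_record
    ):
        model = expert_config.evaluation_model(membership_spec=default_spec)
        res = fce.evaluate(nov9_record, model)
        assert 1 <= res.level_index <= 5
        assert res.normalized.sum() == pytest.approx(1.0, abs=1e-9)
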