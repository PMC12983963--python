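"""Fuzzy comprehensive evaluation of calf cold stress.

Indicator values (or expert-supplied membership rows) are composed with
AHP weights into per-group fuzzy vectors over the five-level evaluation
set *none < mild < moderate < severe < extreme*, aggregated across
groups, normalized, and classified by the maximum-membership principle
(ties broken toward the more severe level — welfare-conservative).

Two weighting modes are supported:

``global``
    Group composition uses *global* second-level weights (which sum to
    the group's share, not to 1) and the first-level weights are applied
    again at aggregation; the final normalization absorbs the double
    weighting.  This is the arithmetic the worked field example uses,
    so it is the default.
``local``
    Local (within-group, sum-1) weights at the group stage and
    first-level local weights at aggregation; the combined vector is
    already a convex combination of membership rows and needs no
    renormalization.

Both modes classify the same record identically whenever group global
weights are proportional to local ones within each group, which holds
for any hierarchy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import ahp
from .exceptions import (
    DegenerateInputError,
    DomainError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "COLD_STRESS_LEVELS",
    "EvaluationSet",
    "CalfDailyRecord",
    "MembershipMatrix",
    "Trapezoid",
    "MembershipFunctionSpec",
    "FceWeights",
    "EvaluationModel",
    "FceResult",
    "membership_from_record",
    "compose",
    "aggregate",
    "normalize",
    "classify",
    "evaluate",
]

COLD_STRESS_LEVELS = ("none", "mild", "moderate", "severe", "extreme")

N_LEVELS = 5


@dataclass(frozen=True)
class EvaluationSet:
    """Ordered five-level cold-stress grading scale."""

    levels: tuple[str, ...] = COLD_STRESS_LEVELS

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) != N_LEVELS:
            raise ValidationError(
                f"evaluation set must have exactly {N_LEVELS} levels, "
                f"got {len(self.levels)}"
            )
        if len(set(self.levels)) != N_LEVELS:
            raise ValidationError("evaluation levels must be distinct")


@dataclass(frozen=True)
class CalfDailyRecord:
    """One calf-day of environmental, physiological and behavioral data."""

    calf_id: str
    date: str
    temperature_c: float
    humidity_pct: float
    wind: float
    weight_kg: float
    height_cm: float
    diagonal_cm: float
    chest_cm: float
    lying_min: float
    standing_min: float
    rr_per_min: float
    urination_n: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.humidity_pct <= 100.0:
            raise DomainError(
                f"relative humidity must be in [0, 100] %, got {self.humidity_pct}"
            )
        if self.wind < 0:
            raise DomainError(f"wind speed must be non-negative, got {self.wind}")
        for f in ("lying_min", "standing_min"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1440.0:
                raise DomainError(f"{f} must be within [0, 1440] min/day, got {v}")

    def indicator(self, name: str) -> float:
        try:
            return float(getattr(self, name))
        except AttributeError:
            raise SchemaError(f"record has no indicator {name!r}") from None


@dataclass(frozen=True)
class MembershipMatrix:
    """Row-stochastic indicator x 5-level fuzzy evaluation matrix."""

    values: np.ndarray
    indicator_labels: tuple[str, ...]
    group: str

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        object.__setattr__(self, "indicator_labels", tuple(self.indicator_labels))
        if a.ndim != 2 or a.shape[1] != N_LEVELS:
            raise ValidationError(
                f"membership matrix must have {N_LEVELS} columns, got shape {a.shape}"
            )
        if a.shape[0] != len(self.indicator_labels):
            raise ValidationError("one label per membership row required")
        if np.any(a < 0) or np.any(a > 1):
            raise ValidationError("memberships must lie in [0, 1]")
        rowsums = a.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9, rtol=0):
            bad = int(np.argmax(np.abs(rowsums - 1.0)))
            raise ValidationError(
                f"membership row {self.indicator_labels[bad]!r} sums to "
                f"{rowsums[bad]!r}, expected 1"
            )


@dataclass(frozen=True)
class Trapezoid:
    """Trapezoidal membership function (left_foot, left_shoulder,
    right_shoulder, right_foot); degenerate edges (foot == shoulder)
    give crisp boundaries."""

    left_foot: float
    left_shoulder: float
    right_shoulder: float
    right_foot: float

    def __post_init__(self) -> None:
        a, b, c, d = (
            self.left_foot,
            self.left_shoulder,
            self.right_shoulder,
            self.right_foot,
        )
        if not (a <= b <= c <= d):
            raise ValidationError(f"trapezoid corners must be ordered, got {(a, b, c, d)}")

    def __call__(self, x: float) -> float:
        a, b, c, d = (
            self.left_foot,
            self.left_shoulder,
            self.right_shoulder,
            self.right_foot,
        )
        if b <= x <= c:
            return 1.0
        if x <= a or x >= d:
            return 0.0
        if x < b:  # rising edge, a < x < b
            return (x - a) / (b - a)
        return (d - x) / (d - c)  # falling edge, c < x < d


@dataclass(frozen=True)
class MembershipFunctionSpec:
    """Per-indicator trapezoidal membership functions over the 5 levels.

    ``functions`` maps an indicator name to its 5 trapezoids in severity
    order (none .. extreme), expressed directly in indicator units.
    ``directions`` records, per indicator, whether severity grows with
    the value (``"higher"``) or against it (``"lower"``); it documents
    intent and is checked against the trapezoid layout.  ``domains``
    gives the admissible (min, max) per indicator; memberships at any
    in-domain value must have positive total mass and are renormalized
    to sum 1.
    """

    functions: Mapping[str, tuple[Trapezoid, ...]]
    domains: Mapping[str, tuple[float, float]]
    directions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, traps in self.functions.items():
            if len(traps) != N_LEVELS:
                raise ValidationError(
                    f"indicator {name!r} needs {N_LEVELS} trapezoids, got {len(traps)}"
                )
            if name not in self.domains:
                raise ValidationError(f"indicator {name!r} has no declared domain")
            direction = self.directions.get(name)
            if direction not in (None, "higher", "lower"):
                raise ValidationError(
                    f"direction for {name!r} must be 'higher' or 'lower'"
                )

    def memberships(self, name: str, value: float) -> np.ndarray:
        """Renormalized 5-vector of level memberships for one indicator."""
        if name not in self.functions:
            raise SchemaError(f"no membership functions declared for {name!r}")
        lo, hi = self.domains[name]
        if not lo <= value <= hi:
            raise DomainError(
                f"{name} = {value} outside declared domain [{lo}, {hi}]"
            )
        mu = np.array([t(value) for t in self.functions[name]], dtype=float)
        total = mu.sum()
        if total <= 0:
            raise DomainError(
                f"{name} = {value} receives zero membership in every level; "
                "trapezoids do not cover the domain"
            )
        return mu / total

    @classmethod
    def from_centers(
        cls,
        centers: Mapping[str, Sequence[float]],
        domains: Mapping[str, tuple[float, float]],
    ) -> "MembershipFunctionSpec":
        """Build a fuzzy partition from 5 level centers per indicator.

        Adjacent levels overlap linearly between their centers (hat
        functions), so raw memberships already sum to 1 everywhere on
        the domain.  Centers may be given in decreasing indicator order
        for lower-is-more-severe indicators.
        """
        functions: dict[str, tuple[Trapezoid, ...]] = {}
        directions: dict[str, str] = {}
        for name, cs in centers.items():
            if len(cs) != N_LEVELS:
                raise ValidationError(
                    f"indicator {name!r} needs {N_LEVELS} centers, got {len(cs)}"
                )
            lo, hi = domains[name]
            increasing = all(cs[i] < cs[i + 1] for i in range(N_LEVELS - 1))
            decreasing = all(cs[i] > cs[i + 1] for i in range(N_LEVELS - 1))
            if not (increasing or decreasing):
                raise ValidationError(
                    f"centers for {name!r} must be strictly monotone"
                )
            directions[name] = "higher" if increasing else "lower"
            axis = list(cs) if increasing else [-c for c in cs]
            dlo, dhi = (lo, hi) if increasing else (-hi, -lo)
            traps = []
            for k in range(N_LEVELS):
                left = dlo if k == 0 else axis[k - 1]
                right = dhi if k == N_LEVELS - 1 else axis[k + 1]
                traps.append(
                    Trapezoid(
                        left_foot=left,
                        left_shoulder=dlo if k == 0 else axis[k],
                        right_shoulder=dhi if k == N_LEVELS - 1 else axis[k],
                        right_foot=right,
                    )
                )
            if decreasing:  # mirror back to indicator units
                traps = [
                    Trapezoid(-t.right_foot, -t.right_shoulder, -t.left_shoulder, -t.left_foot)
                    for t in traps
                ]
            functions[name] = tuple(traps)
        return cls(functions=functions, domains=dict(domains), directions=directions)


def membership_from_record(
    record: CalfDailyRecord,
    spec: MembershipFunctionSpec,
    group: str,
    indicators: Sequence[str],
) -> MembershipMatrix:
    """Evaluate the spec's trapezoids at the record's indicator values."""
    rows = [spec.memberships(name, record.indicator(name)) for name in indicators]
    return MembershipMatrix(np.vstack(rows), tuple(indicators), group)


def compose(
    weights: Sequence[float] | np.ndarray,
    e: MembershipMatrix,
    operator: str = "weighted_average",
) -> np.ndarray:
    """Compose indicator weights with a membership matrix into a 5-vector.

    ``weighted_average`` is the ordinary vector-matrix product
    (the M(., +) operator); ``max_min`` is max_i min(w_i, e_ik).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size != e.values.shape[0]:
        raise ValidationError(
            f"weight length {w.size} does not match {e.values.shape[0]} "
            "membership rows"
        )
    if operator == "weighted_average":
        return w @ e.values
    if operator == "max_min":
        return np.minimum(w[:, None], e.values).max(axis=0)
    raise ValidationError(f"unknown composition operator {operator!r}")


def aggregate(
    first_level_weights: Sequence[float] | np.ndarray,
    group_vectors: Sequence[np.ndarray] | np.ndarray,
    operator: str = "weighted_average",
) -> np.ndarray:
    """Aggregate the stacked group vectors with the first-level weights."""
    b = np.vstack(group_vectors)
    w = np.asarray(first_level_weights, dtype=float)
    if w.size != b.shape[0] or b.shape[1] != N_LEVELS:
        raise ValidationError(
            f"cannot aggregate {b.shape} group matrix with {w.size} weights"
        )
    if operator == "weighted_average":
        return w @ b
    if operator == "max_min":
        return np.minimum(w[:, None], b).max(axis=0)
    raise ValidationError(f"unknown composition operator {operator!r}")


def normalize(v: Sequence[float] | np.ndarray) -> np.ndarray:
    """Scale a non-negative vector to sum 1."""
    a = np.asarray(v, dtype=float)
    if np.any(a < 0):
        raise ValidationError("membership vector must be non-negative")
    s = a.sum()
    if s <= 0:
        raise DegenerateInputError("cannot normalize an all-zero membership vector")
    return a / s


def classify(
    v_norm: Sequence[float] | np.ndarray,
    levels: EvaluationSet | None = None,
) -> tuple[int, str]:
    """Maximum-membership classification; ties go to the severer level.

    Returns the 1-based level index and its label.
    """
    levels = levels or EvaluationSet()
    a = np.asarray(v_norm, dtype=float)
    if a.size != N_LEVELS:
        raise ValidationError(f"expected a {N_LEVELS}-vector, got size {a.size}")
    # argmax on the reversed vector finds the *last* maximum.
    idx = a.size - 1 - int(np.argmax(a[::-1]))
    return idx + 1, levels.levels[idx]


@dataclass(frozen=True)
class FceWeights:
    """Weight bundle used by :func:`evaluate`.

    ``group_weights`` maps group label -> per-indicator weight vector
    (global scale in ``paper`` mode, local sum-1 scale in ``standard``
    mode); ``first_level`` holds the group weights used at aggregation,
    in ``group_order``.
    """

    group_weights: Mapping[str, np.ndarray]
    first_level: np.ndarray
    group_order: tuple[str, ...]
    mode: str = "global"

    def __post_init__(self) -> None:
        if self.mode not in ("global", "local"):
            raise ValidationError(f"unknown weight mode {self.mode!r}")
        if len(self.group_order) != np.asarray(self.first_level).size:
            raise ValidationError("one first-level weight per group required")

    @classmethod
    def from_hierarchy(cls, h: ahp.HierarchyModel, mode: str = "global",
                       force: bool = False) -> "FceWeights":
        fw = ahp.local_weights(h.first_level)
        if mode == "global":
            gg = ahp.group_global_weights(h, force=force)
            group_weights = {g: wv.weights for g, wv in gg.items()}
        else:
            ahp.global_weights(h, force=force)  # consistency gate
            group_weights = {
                g: ahp.local_weights(m).weights for g, m in h.groups.items()
            }
        return cls(
            group_weights=group_weights,
            first_level=fw.weights,
            group_order=fw.labels,
            mode=mode,
        )


@dataclass(frozen=True)
class EvaluationModel:
    """Everything needed to grade one record: weights, levels, and a
    membership source (explicit E matrices take precedence over a
    trapezoid spec)."""

    weights: FceWeights
    group_indicators: Mapping[str, tuple[str, ...]]
    levels: EvaluationSet = field(default_factory=EvaluationSet)
    e_matrices: Mapping[str, MembershipMatrix] | None = None
    membership_spec: MembershipFunctionSpec | None = None
    operator: str = "weighted_average"

    def __post_init__(self) -> None:
        if self.e_matrices is None and self.membership_spec is None:
            raise ValidationError(
                "an EvaluationModel needs explicit E matrices or a "
                "membership-function spec"
            )


@dataclass(frozen=True)
class FceResult:
    """All intermediates of one evaluation, for auditability."""

    group_vectors: dict[str, np.ndarray]
    combined: np.ndarray
    normalized: np.ndarray
    level_index: int
    label: str


def evaluate(record: CalfDailyRecord | None, model: EvaluationModel) -> FceResult:
    """End-to-end fuzzy comprehensive evaluation of one calf-day.

    ``record`` may be None when the model carries explicit membership
    matrices for every group (expert-scored mode).
    """
    group_vectors: dict[str, np.ndarray] = {}
    for g in model.weights.group_order:
        indicators = model.group_indicators[g]
        if model.e_matrices is not None and g in model.e_matrices:
            e = model.e_matrices[g]
        elif model.membership_spec is not None:
            if record is None:
                raise ValidationError(
                    f"group {g!r} has no explicit memberships and no record "
                    "was supplied"
                )
            e = membership_from_record(record, model.membership_spec, g, indicators)
        else:
            raise ValidationError(f"no membership source for group {g!r}")
        group_vectors[g] = compose(
            model.weights.group_weights[g], e, operator=model.operator
        )
    combined = aggregate(
        model.weights.first_level,
        [group_vectors[g] for g in model.weights.group_order],
        operator=model.operator,
    )
    v_norm = normalize(combined)
    idx, label = classify(v_norm, model.levels)
    return FceResult(
        group_vectors=group_vectors,
        combined=combined,
        normalized=v_norm,
        level_index=idx,
        label=label,
    )
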