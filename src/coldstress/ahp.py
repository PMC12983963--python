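"""Analytic hierarchy process: judgment matrices, weights, consistency.

The hierarchy has one first-level judgment matrix over the three factor
groups (environmental, physiological, behavioral) and one second-level
matrix per group over its indicators.  Pairwise importances use Saaty's
1-9 scale; weights come from column normalization followed by row
averaging, and consistency is checked through the classical
CI = (lambda_max - n)/(n - 1), CR = CI/RI scheme.

Two conventions matter for reproducibility and are enforced here:

* lower-triangle entries are always *exact* reciprocals of the upper
  triangle (a_ji = 1/a_ij), never rounded displays such as 0.33 for 1/3;
* lambda_max is estimated as the mean of the component-wise ratios
  (A w)_i / w_i under the column-normalization weights.  A principal
  eigenvalue solver is available as :func:`principal_eigen` for
  cross-checking but is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, ConsistencyError, ValidationError

__all__ = [
    "RANDOM_INDEX",
    "CR_THRESHOLD",
    "JudgmentMatrix",
    "WeightVector",
    "ConsistencyReport",
    "HierarchyModel",
    "complete_reciprocal",
    "local_weights",
    "lambda_max",
    "consistency",
    "global_weights",
    "principal_eigen",
]

#: Average random consistency index for matrix orders 1..10.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
    10: 1.49,
}

#: A matrix is acceptably consistent iff CR is strictly below this.
CR_THRESHOLD: float = 0.10

_SAATY_VALUES = np.array(
    [k for k in range(1, 10)] + [1.0 / k for k in range(2, 10)], dtype=float
)

_RECIPROCITY_TOL = 1e-12


def _on_saaty_scale(value: float, tol: float = 1e-9) -> bool:
    return bool(np.any(np.abs(_SAATY_VALUES - value) <= tol))


@dataclass(frozen=True)
class JudgmentMatrix:
    """Positive reciprocal pairwise-comparison matrix on the 1-9 scale.

    Parameters
    ----------
    values
        ``n x n`` array with unit diagonal and exact reciprocal symmetry.
    labels
        Indicator identifiers, one per row/column.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", a)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = a.shape[0]
        if a.ndim != 2 or a.shape[1] != n:
            raise ValidationError(f"judgment matrix must be square, got {a.shape}")
        if not 2 <= n <= 10:
            raise ValidationError(f"matrix order must be in [2, 10], got {n}")
        if len(self.labels) != n:
            raise ValidationError("one label required per indicator")
        if np.any(a <= 0):
            raise ValidationError("all pairwise importances must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCITY_TOL, rtol=0):
            raise ValidationError("diagonal entries must all equal 1")
        prod = a * a.T
        if not np.allclose(prod, 1.0, atol=1e-9, rtol=0):
            i, j = np.unravel_index(np.argmax(np.abs(prod - 1.0)), prod.shape)
            raise ValidationError(
                f"reciprocity violated at ({self.labels[i]}, {self.labels[j]}): "
                f"a_ij * a_ji = {prod[i, j]!r}"
            )
        # Discrete 1-9 scale membership is enforced on the configuration
        # path (complete_reciprocal), not here: exactly consistent
        # matrices a_ij = w_i/w_j used for cross-checks are off-scale.

    @property
    def order(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Named weights, either local (sum 1) or global (sum = parent weight)."""

    weights: np.ndarray
    labels: tuple[str, ...]
    scope: str = "local"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.scope not in ("local", "global"):
            raise ValidationError(f"unknown weight scope {self.scope!r}")
        if w.ndim != 1 or len(self.labels) != w.size:
            raise ValidationError("weights and labels must align")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if self.scope == "local" and abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"local weights must sum to 1, got {w.sum()!r}")

    def as_dict(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.weights)}


@dataclass(frozen=True)
class ConsistencyReport:
    """Outcome of the consistency check for one judgment matrix."""

    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool


def complete_reciprocal(
    upper_entries: Mapping[tuple[int, int], float],
    order: int,
    labels: Sequence[str] | None = None,
) -> JudgmentMatrix:
    """Build a full judgment matrix from its strict upper triangle.

    Keys of ``upper_entries`` are 0-based ``(i, j)`` pairs with ``i < j``.
    The lower triangle is filled with exact reciprocals and the diagonal
    with ones.  Printed rounded reciprocals (0.33 for 1/3, 0.25 for 1/4)
    must never be supplied; reciprocals are always recomputed here.
    """
    if labels is None:
        labels = tuple(f"x{i + 1}" for i in range(order))
    a = np.eye(order, dtype=float)
    for i in range(order):
        for j in range(i + 1, order):
            if (i, j) not in upper_entries:
                raise ConfigurationError(
                    f"missing pairwise comparison ({labels[i]}, {labels[j]})"
                )
            v = float(upper_entries[(i, j)])
            if not _on_saaty_scale(v):
                raise ValidationError(
                    f"comparison ({labels[i]}, {labels[j]}) = {v!r} is off the "
                    "1-9 scale"
                )
            a[i, j] = v
            a[j, i] = 1.0 / v
    extra = set(upper_entries) - {
        (i, j) for i in range(order) for j in range(i + 1, order)
    }
    if extra:
        raise ConfigurationError(f"entries outside the upper triangle: {sorted(extra)}")
    return JudgmentMatrix(a, tuple(labels))


def local_weights(m: JudgmentMatrix) -> WeightVector:
    """Weights by column normalization and row averaging.

    Each column is scaled to sum 1, rows are averaged, and the resulting
    vector renormalized to sum 1.
    """
    a = m.values
    col_normalized = a / a.sum(axis=0, keepdims=True)
    w = col_normalized.mean(axis=1)
    w = w / w.sum()
    return WeightVector(w, m.labels, scope="local")


def lambda_max(m: JudgmentMatrix, w: WeightVector | None = None) -> float:
    """Maximum-eigenvalue estimate: mean of (A w)_i / w_i.

    ``w`` defaults to :func:`local_weights` of ``m``; positivity of the
    matrix guarantees strictly positive weights.
    """
    if w is None:
        w = local_weights(m)
    wv = w.weights
    return float(np.mean((m.values @ wv) / wv))


def consistency(m: JudgmentMatrix) -> ConsistencyReport:
    """Consistency check: CI = (lambda_max - n)/(n - 1), CR = CI/RI.

    For n <= 2 the random index is 0 and CR is defined as 0 (always
    acceptable).  Acceptability is the strict inequality CR < 0.10.
    """
    n = m.order
    if n not in RANDOM_INDEX:
        raise ValidationError(f"no random index tabulated for order {n}")
    lam = lambda_max(m)
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    cr = ci / ri if ri > 0 else 0.0
    return ConsistencyReport(
        lambda_max=lam, ci=ci, ri=ri, cr=cr, acceptable=cr < CR_THRESHOLD
    )


def principal_eigen(m: JudgmentMatrix) -> tuple[float, np.ndarray]:
    """True principal eigenvalue and (sum-1) right eigenvector.

    Cross-check utility only; the pipeline's default estimator is
    :func:`lambda_max` with column-normalization weights.
    """
    vals, vecs = np.linalg.eig(m.values)
    k = int(np.argmax(vals.real))
    v = np.abs(vecs[:, k].real)
    return float(vals[k].real), v / v.sum()


@dataclass
class HierarchyModel:
    """Three-group, eleven-indicator evaluation hierarchy.

    ``groups`` maps each first-level label (in the order of
    ``first_level.labels``) to its second-level judgment matrix.
    """

    first_level: JudgmentMatrix
    groups: dict[str, JudgmentMatrix]
    _reports: dict[str, ConsistencyReport] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.first_level.labels) - set(self.groups)
        if missing:
            raise ConfigurationError(
                f"no second-level matrix for group(s) {sorted(missing)}"
            )

    def consistency_reports(self) -> dict[str, ConsistencyReport]:
        """Per-matrix consistency reports, keyed ``first_level`` / group label."""
        if not self._reports:
            self._reports = {"first_level": consistency(self.first_level)}
            for g, m in self.groups.items():
                self._reports[g] = consistency(m)
        return self._reports

    def first_level_weights(self) -> WeightVector:
        return local_weights(self.first_level)

    def group_local_weights(self) -> dict[str, WeightVector]:
        return {g: local_weights(m) for g, m in self.groups.items()}


def global_weights(h: HierarchyModel, force: bool = False) -> dict[str, float]:
    """Total-sorting weights, synthesized top-down.

    A second-level node's global weight is its local weight times its
    group's first-level local weight; first-level globals equal locals.
    Raises :class:`ConsistencyError` if any matrix fails CR < 0.10,
    unless ``force`` is set (the failure is then only reported by
    :meth:`HierarchyModel.consistency_reports`).
    """
    reports = h.consistency_reports()
    bad = {k: r.cr for k, r in reports.items() if not r.acceptable}
    if bad and not force:
        worst = max(bad, key=bad.get)  # type: ignore[arg-type]
        raise ConsistencyError(
            f"judgment matrix {worst!r} fails the consistency check "
            f"(CR = {bad[worst]:.3f} >= {CR_THRESHOLD}); failing matrices: "
            f"{ {k: round(v, 3) for k, v in bad.items()} }"
        )
    out: dict[str, float] = {}
    fw = h.first_level_weights()
    for g_label, g_weight in zip(fw.labels, fw.weights):
        out[g_label] = float(g_weight)
        lw = local_weights(h.groups[g_label])
        for lab, w in zip(lw.labels, lw.weights):
            out[lab] = float(w * g_weight)
    return out


def group_global_weights(h: HierarchyModel, force: bool = False) -> dict[str, WeightVector]:
    """Global second-level weights bundled per group as WeightVectors."""
    flat = global_weights(h, force=force)
    out: dict[str, WeightVector] = {}
    for g, m in h.groups.items():
        out[g] = WeightVector(
            np.array([flat[lab] for lab in m.labels]), m.labels, scope="global"
        )
    return out
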