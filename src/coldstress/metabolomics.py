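"""Two-group differential-metabolite screening.

The screening rule declares a feature differential when all three
criteria hold simultaneously (inclusive comparisons):

1. VIP >= 1 from a PLS-DA model of the two-group contrast;
2. fold-change ratio (treatment mean / control mean) >= 1.5 or <= 1/1.5;
3. p <= 0.05 from a per-feature two-group test (Welch's t on log2
   abundances by default; raw scale available).

PLS-DA itself is fitted with the NIPALS-based PLS regression of
scikit-learn on autoscaled features against a centered 0/1 group
response; R2Y is the in-sample explained response variance and Q2 its
cross-validated counterpart (stratified K-fold, 7 folds by default).
VIP scores are computed here from the fitted weights and scores:

    vip_j = sqrt(p * sum_a(ssy_a * w_aj^2) / sum_a(ssy_a))

with unit-norm weight vectors w_a, so mean(vip^2) = 1 identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .exceptions import SchemaError, ValidationError

__all__ = [
    "MetaboliteTable",
    "PlsdaModel",
    "ScreenResult",
    "plsda_fit",
    "vip_scores",
    "apply_criteria",
    "screen",
]


@dataclass(frozen=True)
class MetaboliteTable:
    """Samples x features abundance table with two-group labels."""

    abundances: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        ab = self.abundances
        gr = pd.Series(self.groups)
        object.__setattr__(self, "groups", gr)
        if ab.shape[0] != gr.size:
            raise SchemaError(
                f"{ab.shape[0]} samples but {gr.size} group labels"
            )
        labels = pd.unique(gr)
        if len(labels) != 2:
            raise ValidationError(
                f"exactly two group labels required, found {list(labels)}"
            )
        if (ab.to_numpy(float) < 0).any():
            raise ValidationError("abundances must be non-negative")

    @property
    def group_labels(self) -> tuple[str, str]:
        """(control, treatment) in sorted label order.

        Sorted order keeps the assignment invariant under sample
        reordering; pass ``treatment`` explicitly to :func:`screen`
        when the convention does not fit.
        """
        labels = sorted(str(g) for g in pd.unique(self.groups))
        return labels[0], labels[1]

    @classmethod
    def from_wide_csv(cls, path, group_col: str = "group") -> "MetaboliteTable":
        df = pd.read_csv(path, index_col=0)
        if group_col not in df.columns:
            raise SchemaError(f"wide table must carry a {group_col!r} column")
        groups = df[group_col].astype(str)
        return cls(df.drop(columns=[group_col]).astype(float), groups)


@dataclass
class PlsdaModel:
    """Fitted PLS-DA model with in-sample and cross-validated fit indices."""

    pls: PLSRegression
    feature_names: tuple[str, ...]
    group_labels: tuple[str, str]
    r2y: float
    q2: float
    n_components: int
    scores: np.ndarray = field(repr=False)

    @property
    def loadings(self) -> np.ndarray:
        return self.pls.x_loadings_


def _encode_response(groups: pd.Series) -> np.ndarray:
    treatment = sorted(str(g) for g in pd.unique(groups))[1]
    return (groups.astype(str).to_numpy() == treatment).astype(float)


def plsda_fit(
    t: MetaboliteTable,
    n_components: int = 2,
    n_splits: int = 7,
    log2_transform: bool = True,
    random_state: int | None = 0,
) -> PlsdaModel:
    """Fit PLS-DA and compute R2Y and cross-validated Q2.

    Features are log2-transformed (with a half-minimum offset for
    zeros) and autoscaled inside the PLS fit.  Q2 = 1 - PRESS/SSY over
    stratified K-fold held-out predictions; the fold count is capped at
    the smaller group size.
    """
    x = t.abundances.to_numpy(float)
    if log2_transform:
        x = _log2_safe(x)
    y = _encode_response(t.groups)
    n, p = x.shape
    n_min = int(min(np.sum(y == 0), np.sum(y == 1)))
    if n_min < 3:
        raise ValidationError("need at least 3 samples per group for PLS-DA")
    if n_components >= n:
        raise ValidationError(
            f"{n_components} components cannot be extracted from {n} samples"
        )
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(x, y)
    y_hat = pls.predict(x).ravel()
    ssy = float(np.sum((y - y.mean()) ** 2))
    r2y = 1.0 - float(np.sum((y - y_hat) ** 2)) / ssy

    n_splits = min(n_splits, n_min)
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=random_state)
    press = 0.0
    for train, test in cv.split(x, y):
        m = PLSRegression(n_components=min(n_components, len(train) - 1), scale=True)
        m.fit(x[train], y[train])
        pred = m.predict(x[test]).ravel()
        press += float(np.sum((y[test] - pred) ** 2))
    q2 = 1.0 - press / ssy
    return PlsdaModel(
        pls=pls,
        feature_names=tuple(map(str, t.abundances.columns)),
        group_labels=t.group_labels,
        r2y=r2y,
        q2=q2,
        n_components=n_components,
        scores=pls.x_scores_,
    )


def _log2_safe(x: np.ndarray) -> np.ndarray:
    """log2 with zeros replaced by half the smallest positive value."""
    x = np.asarray(x, dtype=float)
    positive = x[x > 0]
    if positive.size == 0:
        raise ValidationError("abundance table is identically zero")
    floor = positive.min() / 2.0
    return np.log2(np.where(x > 0, x, floor))


def vip_scores(model: PlsdaModel) -> np.ndarray:
    """Variable importance in projection for every feature.

    Uses the response variance captured by each component,
    ssy_a = (t_a' t_a) q_a^2, and the unit-norm x-weights; the identity
    sum(vip^2) = n_features holds to numerical precision.
    """
    pls = model.pls
    w = pls.x_weights_  # (p, A), columns unit norm
    t_scores = pls.x_scores_  # (n, A)
    q = pls.y_loadings_.ravel()  # (A,)
    p = w.shape[0]
    ssy = np.sum(t_scores**2, axis=0) * q**2
    w2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    return np.sqrt(p * (w2 @ ssy) / ssy.sum())


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature screening table plus pass/regulation tallies."""

    table: pd.DataFrame
    model: PlsdaModel
    thresholds: dict

    @property
    def n_pass(self) -> int:
        return int(self.table["passes"].sum())

    @property
    def n_up(self) -> int:
        return int((self.table["regulation"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["regulation"] == "down").sum())

    def differential(self) -> pd.DataFrame:
        return self.table[self.table["passes"]].reset_index(drop=True)


def apply_criteria(
    ratio: float,
    p: float,
    vip: float,
    vip_min: float = 1.0,
    fc_min: float = 1.5,
    p_max: float = 0.05,
) -> tuple[bool, str]:
    """The three-way differential call on one feature's summary numbers.

    All comparisons are inclusive: VIP >= vip_min, ratio >= fc_min or
    <= 1/fc_min, p <= p_max.  Returns (passes, regulation) with
    regulation 'up'/'down' for passing features and 'none' otherwise.
    """
    passes = (vip >= vip_min) and (ratio >= fc_min or ratio <= 1.0 / fc_min) and (
        p <= p_max
    )
    if not passes:
        return False, "none"
    return True, ("up" if ratio > 1.0 else "down")


def screen(
    t: MetaboliteTable,
    vip_min: float = 1.0,
    fc_min: float = 1.5,
    p_max: float = 0.05,
    n_components: int = 2,
    log2_tests: bool = True,
    random_state: int | None = 0,
    treatment: str | None = None,
) -> ScreenResult:
    """Screen every feature against the three differential criteria.

    Ratios are treatment/control means on the raw abundance scale
    (treatment defaults to the second group label in sorted order);
    p-values come from Welch's t-test on log2 abundances unless
    ``log2_tests`` is disabled.
    """
    model = plsda_fit(t, n_components=n_components, random_state=random_state)
    vips = vip_scores(model)
    if treatment is None:
        _, treatment = t.group_labels
    elif treatment not in set(map(str, pd.unique(t.groups))):
        raise ValidationError(f"treatment label {treatment!r} not present")
    x = t.abundances.to_numpy(float)
    mask_t = (t.groups.to_numpy() == treatment)
    xt, xc = x[mask_t], x[~mask_t]
    ratios = xt.mean(axis=0) / xc.mean(axis=0)
    test_t, test_c = (
        (_log2_safe(x)[mask_t], _log2_safe(x)[~mask_t]) if log2_tests else (xt, xc)
    )
    pvals = sps.ttest_ind(test_t, test_c, axis=0, equal_var=False).pvalue
    rows = []
    for name, r, p, v in zip(model.feature_names, ratios, pvals, vips):
        ok, reg = apply_criteria(
            float(r), float(p), float(v), vip_min=vip_min, fc_min=fc_min, p_max=p_max
        )
        rows.append(
            {
                "feature": name,
                "ratio": float(r),
                "p": float(p),
                "vip": float(v),
                "passes": ok,
                "regulation": reg,
            }
        )
    table = pd.DataFrame(rows)
    return ScreenResult(
        table=table,
        model=model,
        thresholds={"vip_min": vip_min, "fc_min": fc_min, "p_max": p_max},
    )
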