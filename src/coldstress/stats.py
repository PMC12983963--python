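"""Association and group-comparison statistics.

Kendall's tau-b is implemented here directly (concordant/discordant
pair counts with the standard tie corrections and the tie-adjusted
normal approximation for the p-value), so it can be verified against a
brute-force pair-counting oracle and against an independent library
implementation.  Two-group comparison tables follow the animal-science
convention of one pooled-SEM column per variable with a/b significance
letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InsufficientDataError, ValidationError

__all__ = ["PairedSeries", "kendall_tau_b", "two_group_table"]


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length numeric sequences with no missing values."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
            raise ValidationError("x and y must be 1-D and of equal length")
        if x.size < 2:
            raise InsufficientDataError("need at least two pairs")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValidationError("x and y must be finite (filter missing first)")


def kendall_tau_b(s: PairedSeries) -> tuple[float, float]:
    """Kendall's tau-b with tie correction, and a two-sided p-value.

    tau_b = (C - D) / sqrt((n0 - n1)(n0 - n2)) where n0 = n(n-1)/2 and
    n1, n2 are the within-tie pair counts of x and y.  The p-value uses
    the tie-adjusted normal approximation for the null variance of
    C - D; for the tiny n used in exact tests an enumeration oracle is
    the reference, not this approximation.
    """
    x, y = s.x, s.y
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise InsufficientDataError(
            "tau-b is undefined when either series is constant"
        )
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    prod = dx[iu] * dy[iu]
    c_minus_d = float(prod.sum())

    n0 = n * (n - 1) / 2.0
    tx = np.unique(x, return_counts=True)[1]
    ty = np.unique(y, return_counts=True)[1]
    n1 = float((tx * (tx - 1) / 2.0).sum())
    n2 = float((ty * (ty - 1) / 2.0).sum())
    tau = c_minus_d / np.sqrt((n0 - n1) * (n0 - n2))

    # Tie-adjusted null variance of C - D (Kendall, Rank Correlation
    # Methods, ch. 4); matches the asymptotic method of standard
    # libraries.
    def _v(t: np.ndarray, k: int) -> float:
        return float((t * (t - 1.0) * (2.0 * t + 5.0)).sum()) if k == 0 else (
            float((t * (t - 1.0) * (t - 2.0)).sum())
            if k == 1
            else float((t * (t - 1.0)).sum())
        )

    v0 = n * (n - 1.0) * (2.0 * n + 5.0)
    var = (v0 - _v(tx, 0) - _v(ty, 0)) / 18.0
    if n > 2:
        var += (_v(tx, 1) * _v(ty, 1)) / (9.0 * n * (n - 1.0) * (n - 2.0))
    var += (_v(tx, 2) * _v(ty, 2)) / (2.0 * n * (n - 1.0))
    if var <= 0:
        return float(tau), 1.0
    z = c_minus_d / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(tau), min(p, 1.0)


def _pooled_sem(g1: np.ndarray, g2: np.ndarray) -> float:
    """Single-column SEM: sqrt(MSE / harmonic mean of group sizes).

    MSE is the pooled within-group variance; for balanced groups this
    is the familiar sqrt(MSE/n) printed in livestock summary tables.
    """
    n1, n2 = g1.size, g2.size
    mse = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    return float(np.sqrt(mse * (1.0 / n1 + 1.0 / n2) / 2.0))


def two_group_table(
    data: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
    groups: tuple[str, str] | None = None,
    welch: bool = False,
    per_group_sem: bool = False,
) -> pd.DataFrame:
    """Two-group summary table: means, pooled SEM, p, significance letters.

    One row per variable.  Letters 'a'/'b' are assigned (higher mean
    gets 'a') only when p < 0.05; otherwise both groups share 'a'.
    Student's pooled-variance t-test is the default; set ``welch`` for
    Welch's unequal-variance test.
    """
    if groups is None:
        found = list(pd.unique(data[group_col]))
        if len(found) != 2:
            raise ValidationError(
                f"expected exactly two groups in {group_col!r}, found {found}"
            )
        groups = (str(found[0]), str(found[1]))
    g1_label, g2_label = groups
    rows = []
    for var in variables:
        g1 = data.loc[data[group_col] == g1_label, var].dropna().to_numpy(float)
        g2 = data.loc[data[group_col] == g2_label, var].dropna().to_numpy(float)
        if g1.size < 2 or g2.size < 2:
            raise InsufficientDataError(
                f"variable {var!r}: both groups need n >= 2 "
                f"(got {g1.size}, {g2.size})"
            )
        res = sps.ttest_ind(g1, g2, equal_var=not welch)
        p = float(res.pvalue)
        m1, m2 = float(g1.mean()), float(g2.mean())
        if p < 0.05:
            letters = ("a", "b") if m1 > m2 else ("b", "a")
        else:
            letters = ("a", "a")
        row = {
            "variable": var,
            f"mean_{g1_label}": m1,
            f"mean_{g2_label}": m2,
            "sem": _pooled_sem(g1, g2),
            "p": p,
            f"letter_{g1_label}": letters[0],
            f"letter_{g2_label}": letters[1],
        }
        if per_group_sem:
            row[f"sem_{g1_label}"] = float(g1.std(ddof=1) / np.sqrt(g1.size))
            row[f"sem_{g2_label}"] = float(g2.std(ddof=1) / np.sqrt(g2.size))
        rows.append(row)
    return pd.DataFrame(rows)
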