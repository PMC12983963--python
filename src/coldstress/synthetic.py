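"""Synthetic winter calf cohort and two-group metabolome generators.

The cohort generator emulates the statistical structure of a 60-day
indoor-vs-outdoor winter rearing trial with 10 Holstein suckling calves
per group: an outdoor daily temperature path bounded in [-26, 1.21] deg C
(half-cosine seasonal descent plus AR(1) noise, so the trial mean sits
near -12.4 deg C), relative humidity near 71-75 %, wind near
8.4-9.4 km/h, a constant 5 deg C / 75 % indoor barn, phase-wise growth
trajectories, and per-group behavioral means (lying 1027.12 vs 918.68
min/day, respiratory rate 34.51 vs 44.86 /min, urination 1.91 vs 1.42
/day, defecation 1.83 vs 1.47 /day).  Gaussian daily noise is scaled as
SEM * sqrt(10) from the group summary tables (raw SDs are not
published); counts are Poisson.  Lying + standing minutes always sum to
1440.

The metabolome generator spikes a configurable number of features with
fold changes drawn from the observed differential-metabolite envelope
(|log2 FC| between log2 1.5 and log2 4.86, random direction) on top of
log-normal baseline abundances, and returns the ground-truth spike list
for recovery testing.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .metabolomics import MetaboliteTable

__all__ = [
    "CohortConfig",
    "MetabolomeConfig",
    "generate_cohort",
    "generate_metabolome",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "calf_id",
    "date",
    "group",
    "temperature_c",
    "humidity_pct",
    "wind",
    "weight_kg",
    "height_cm",
    "diagonal_cm",
    "chest_cm",
    "lying_min",
    "standing_min",
    "rr_per_min",
    "urination_n",
    "defecation_n",
]

# Per-group behavioral targets (indoor, outdoor): daily mean and the SD
# implied by the printed SEM with n = 10 calves (SD = SEM * sqrt(10)).
_BEHAVIOR = {
    "lying_min": ((918.68, 1027.12), 10.28 * np.sqrt(10.0)),
    "rr_per_min": ((44.86, 34.51), 0.618 * np.sqrt(10.0)),
}
_COUNTS = {
    "urination_n": (1.42, 1.91),
    "defecation_n": (1.47, 1.83),
}
# Phase-wise average daily gain, kg/d, for days 1-30 and 31-60.
_ADG = {"indoor": (0.76, 0.71), "outdoor": (0.66, 1.22)}
# Body-size anchor points (day 1, 30, 60) per group, cm.
_BODY_SIZE = {
    "height_cm": {"indoor": (76.2, 81.60, 87.1), "outdoor": (75.7, 83.45, 90.4)},
    "diagonal_cm": {"indoor": (61.1, 70.61, 79.4), "outdoor": (58.7, 65.2, 81.9)},
    "chest_cm": {"indoor": (81.5, 96.30, 105.9), "outdoor": (82.8, 105.2, 111.5)},
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic winter cohort."""

    n_per_group: int = 10
    n_days: int = 60
    seed: int = 0
    start_date: str = "2022-11-09"
    outdoor_temp_range: tuple[float, float] = (-26.0, 1.21)
    outdoor_rh_range: tuple[float, float] = (71.0, 75.0)
    outdoor_wind_range: tuple[float, float] = (8.4, 9.4)
    indoor_temp: float = 5.0
    indoor_rh: float = 75.0
    indoor_wind: float = 0.0
    ar1_rho: float = 0.7
    temp_noise_sd: float = 2.0
    initial_weight_mean: float = 35.39
    initial_weight_sd: float = 1.57
    frailty_sd: float = 0.05
    body_size_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0 or self.n_days <= 0:
            raise ConfigurationError("n_per_group and n_days must be positive")
        if self.outdoor_temp_range[0] >= self.outdoor_temp_range[1]:
            raise ConfigurationError("outdoor temperature range must be ordered")


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def _outdoor_weather(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo, hi = cfg.outdoor_temp_range
    d = np.arange(cfg.n_days)
    # Half-cosine descent from the warm start to the coldest day; its
    # time average equals the midpoint, matching the reported trial mean.
    trend = lo + (hi - lo) * (1.0 + np.cos(np.pi * d / max(cfg.n_days - 1, 1))) / 2.0
    temp = np.clip(trend + _ar1(rng, cfg.n_days, cfg.ar1_rho, cfg.temp_noise_sd), lo, hi)
    rh_lo, rh_hi = cfg.outdoor_rh_range
    rh = np.clip(
        (rh_lo + rh_hi) / 2.0 + _ar1(rng, cfg.n_days, cfg.ar1_rho, 1.0), rh_lo, rh_hi
    )
    w_lo, w_hi = cfg.outdoor_wind_range
    wind = np.clip(
        (w_lo + w_hi) / 2.0 + _ar1(rng, cfg.n_days, cfg.ar1_rho, 0.3), w_lo, w_hi
    )
    return pd.DataFrame({"temperature_c": temp, "humidity_pct": rh, "wind": wind})


def _weight_path(cfg: CohortConfig, group: str, days: np.ndarray) -> np.ndarray:
    adg1, adg2 = _ADG[group]
    return np.where(
        days <= 30,
        adg1 * days,
        adg1 * 30.0 + adg2 * (days - 30.0),
    )


def _body_size_path(anchors: tuple[float, float, float], days: np.ndarray) -> np.ndarray:
    return np.interp(days, [0.0, 29.0, 59.0], anchors)


def generate_cohort(cfg: CohortConfig | None = None) -> pd.DataFrame:
    """Generate the full two-group daily-record table.

    Returns one row per calf-day in the standard record schema plus a
    ``group`` column and defecation counts; byte-identical for a given
    config (determinism contract).
    """
    cfg = cfg or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    weather = _outdoor_weather(cfg, rng)
    dates = pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")
    days = np.arange(cfg.n_days, dtype=float)

    rows: list[pd.DataFrame] = []
    for group in ("indoor", "outdoor"):
        g_idx = 0 if group == "indoor" else 1
        if group == "indoor":
            temp = np.full(cfg.n_days, cfg.indoor_temp)
            rh = np.full(cfg.n_days, cfg.indoor_rh)
            wind = np.full(cfg.n_days, cfg.indoor_wind)
        else:
            temp = weather["temperature_c"].to_numpy()
            rh = weather["humidity_pct"].to_numpy()
            wind = weather["wind"].to_numpy()
        for k in range(cfg.n_per_group):
            calf_id = f"{group}_{k + 1:02d}"
            initial = rng.normal(cfg.initial_weight_mean, cfg.initial_weight_sd)
            frailty = rng.normal(1.0, cfg.frailty_sd)
            weight = initial + frailty * _weight_path(cfg, group, days)
            lying_mean, lying_sd = _BEHAVIOR["lying_min"][0][g_idx], _BEHAVIOR["lying_min"][1]
            lying = np.clip(rng.normal(lying_mean, lying_sd, cfg.n_days), 0.0, 1440.0)
            rr_mean, rr_sd = _BEHAVIOR["rr_per_min"][0][g_idx], _BEHAVIOR["rr_per_min"][1]
            rr = np.clip(rng.normal(rr_mean, rr_sd, cfg.n_days), 1.0, None)
            frame = pd.DataFrame(
                {
                    "calf_id": calf_id,
                    "date": dates.strftime("%Y-%m-%d"),
                    "group": group,
                    "temperature_c": temp,
                    "humidity_pct": rh,
                    "wind": wind,
                    "weight_kg": weight,
                    "height_cm": _body_size_path(_BODY_SIZE["height_cm"][group], days)
                    + rng.normal(0.0, cfg.body_size_noise_sd, cfg.n_days),
                    "diagonal_cm": _body_size_path(_BODY_SIZE["diagonal_cm"][group], days)
                    + rng.normal(0.0, cfg.body_size_noise_sd, cfg.n_days),
                    "chest_cm": _body_size_path(_BODY_SIZE["chest_cm"][group], days)
                    + rng.normal(0.0, cfg.body_size_noise_sd, cfg.n_days),
                    "lying_min": lying,
                    "standing_min": 1440.0 - lying,
                    "rr_per_min": rr,
                    "urination_n": rng.poisson(_COUNTS["urination_n"][g_idx], cfg.n_days),
                    "defecation_n": rng.poisson(_COUNTS["defecation_n"][g_idx], cfg.n_days),
                }
            )
            rows.append(frame)
    return pd.concat(rows, ignore_index=True)[COHORT_COLUMNS]


@dataclass(frozen=True)
class MetabolomeConfig:
    """Parameters of the spiked two-group synthetic metabolome."""

    n_per_group: int = 10
    n_features: int = 200
    n_differential: int = 20
    fold_changes: tuple[float, ...] | float | None = None
    noise_sd: float = 0.5
    base_log2_mean: float = 10.0
    base_log2_sd: float = 2.0
    fc_envelope: tuple[float, float] = (1.5, 4.86)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_features:
            raise ConfigurationError(
                f"cannot spike {self.n_differential} of {self.n_features} features"
            )
        if self.n_per_group < 3:
            raise ConfigurationError("need at least 3 samples per group")
        fcs = self.fold_changes
        if fcs is not None:
            if np.isscalar(fcs):
                fcs = (float(fcs),)
                object.__setattr__(self, "fold_changes", fcs)
            if any(fc == 1.0 for fc in fcs):  # type: ignore[union-attr]
                raise ConfigurationError("spiked fold changes must differ from 1")


def generate_metabolome(
    cfg: MetabolomeConfig | None = None,
) -> tuple[MetaboliteTable, pd.DataFrame]:
    """Generate a spiked two-group metabolome plus its ground truth.

    Baseline log2 abundances are Gaussian per feature; the first
    ``n_differential`` randomly chosen features are shifted by log2 of a
    fold change in the treatment (outdoor) group.  Fold changes come
    from ``fold_changes`` (cycled) or, when None, are drawn with
    magnitude uniform in log2 over the configured envelope and random
    direction.  Returns the table and a ground-truth frame with columns
    ``feature``, ``fold_change``, ``regulation``.
    """
    cfg = cfg or MetabolomeConfig()
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_group
    features = [f"met_{i + 1:04d}" for i in range(cfg.n_features)]
    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, cfg.n_features)
    log2_x = base[None, :] + rng.normal(0.0, cfg.noise_sd, (n, cfg.n_features))

    spiked = np.sort(rng.choice(cfg.n_features, size=cfg.n_differential, replace=False))
    if cfg.fold_changes is not None:
        fcs = np.array(
            [cfg.fold_changes[i % len(cfg.fold_changes)] for i in range(cfg.n_differential)]
        )
    else:
        lo, hi = cfg.fc_envelope
        mags = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), cfg.n_differential)
        signs = rng.choice([-1.0, 1.0], cfg.n_differential)
        fcs = mags**signs
    treat = slice(cfg.n_per_group, n)  # second block of samples is outdoor
    log2_x[treat, spiked] += np.log2(fcs)[None, :]

    samples = [f"indoor_{i + 1:02d}" for i in range(cfg.n_per_group)] + [
        f"outdoor_{i + 1:02d}" for i in range(cfg.n_per_group)
    ]
    abundances = pd.DataFrame(2.0**log2_x, index=samples, columns=features)
    groups = pd.Series(
        ["indoor"] * cfg.n_per_group + ["outdoor"] * cfg.n_per_group,
        index=samples,
        name="group",
    )
    truth = pd.DataFrame(
        {
            "feature": [features[i] for i in spiked],
            "fold_change": fcs,
            "regulation": np.where(fcs > 1.0, "up", "down"),
        }
    )
    return MetaboliteTable(abundances, groups), truth
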