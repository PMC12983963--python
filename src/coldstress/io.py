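"""Configuration documents, record CSV I/O, and shipped fixtures.

A model configuration is a single YAML (or JSON) document carrying the
evaluation levels, one or more rating panels (each a first-level
judgment matrix plus per-group matrices as upper triangles), the
mapping of groups to record fields, and optionally explicit membership
matrices, explicit weight vectors, or trapezoid membership-function
centers.  Judgment values may be integers, floats, or fraction strings
like ``"1/3"`` (exact reciprocals are always recomputed; rounded
decimal reciprocals must not be entered).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import ahp, fce
from .exceptions import ConfigurationError, DomainError, SchemaError

logger = logging.getLogger("coldstress")

__all__ = [
    "ModelConfig",
    "load_model",
    "save_model",
    "fixture_path",
    "default_membership_spec",
    "read_records",
    "read_records_frame",
    "write_results",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "calf_id",
    "date",
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
]


def fixture_path(name: str) -> Path:
    """Path to a shipped configuration fixture (e.g. ``expert.yaml``)."""
    p = resources.files("coldstress").joinpath("data", name)
    return Path(str(p))


def _parse_judgment(value, where: str) -> float:
    if isinstance(value, str):
        try:
            return float(Fraction(value))
        except (ValueError, ZeroDivisionError):
            raise ConfigurationError(
                f"{where}: cannot parse judgment value {value!r}"
            ) from None
    if isinstance(value, (int, float)):
        return float(value)
    raise ConfigurationError(f"{where}: judgment value {value!r} has bad type")


def _matrix_from_doc(doc: Mapping, where: str) -> ahp.JudgmentMatrix:
    try:
        labels = list(doc["labels"])
        upper = doc["upper"]
    except (KeyError, TypeError) as err:
        raise ConfigurationError(f"{where}: needs 'labels' and 'upper'") from err
    index = {lab: i for i, lab in enumerate(labels)}
    entries: dict[tuple[int, int], float] = {}
    for key, value in upper.items():
        try:
            a, b = (part.strip() for part in str(key).split("/"))
            i, j = index[a], index[b]
        except (ValueError, KeyError) as err:
            raise ConfigurationError(
                f"{where}: bad upper-triangle key {key!r} (use 'label/label' "
                f"with labels from {labels})"
            ) from err
        if i >= j:
            raise ConfigurationError(
                f"{where}: {key!r} is not above the diagonal; supply only "
                "upper-triangle comparisons"
            )
        entries[(i, j)] = _parse_judgment(value, f"{where}/{key}")
    return ahp.complete_reciprocal(entries, len(labels), labels)


@dataclass
class ModelConfig:
    """Parsed and validated model configuration document."""

    levels: fce.EvaluationSet
    panels: dict[str, ahp.HierarchyModel]
    group_indicators: dict[str, tuple[str, ...]]
    explicit_weights: fce.FceWeights | None = None
    e_matrices: dict[str, fce.MembershipMatrix] | None = None
    membership_spec: fce.MembershipFunctionSpec | None = None
    operator: str = "weighted_average"
    weight_mode: str = "global"

    def evaluation_model(
        self,
        panel: str = "expert",
        membership_spec: fce.MembershipFunctionSpec | None = None,
        force: bool = False,
    ) -> fce.EvaluationModel:
        """Assemble an :class:`~coldstress.fce.EvaluationModel`.

        Explicit weight vectors in the document override panel-derived
        weights; explicit E matrices override any membership-function
        spec (document spec first, then the ``membership_spec``
        argument as fallback).
        """
        if self.explicit_weights is not None:
            weights = self.explicit_weights
        else:
            if panel not in self.panels:
                raise ConfigurationError(
                    f"no panel {panel!r} in config; available: {sorted(self.panels)}"
                )
            weights = fce.FceWeights.from_hierarchy(
                self.panels[panel], mode=self.weight_mode, force=force
            )
        spec = self.membership_spec or membership_spec
        return fce.EvaluationModel(
            weights=weights,
            group_indicators=self.group_indicators,
            levels=self.levels,
            e_matrices=self.e_matrices,
            membership_spec=spec,
            operator=self.operator,
        )


def load_model(path, strict_consistency: bool = False) -> ModelConfig:
    """Load and validate a model configuration document.

    Judgment matrices failing CR < 0.10 are logged as warnings; with
    ``strict_consistency`` they abort loading instead (weight synthesis
    will in any case refuse inconsistent panels unless forced).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: document root must be a mapping")

    levels = fce.EvaluationSet(tuple(doc.get("evaluation_levels", fce.COLD_STRESS_LEVELS)))

    panels: dict[str, ahp.HierarchyModel] = {}
    for panel_name, panel_doc in (doc.get("panels") or {}).items():
        where = f"{path}#/panels/{panel_name}"
        first = _matrix_from_doc(panel_doc["first_level"], f"{where}/first_level")
        groups = {
            g: _matrix_from_doc(gdoc, f"{where}/groups/{g}")
            for g, gdoc in panel_doc["groups"].items()
        }
        model = ahp.HierarchyModel(first_level=first, groups=groups)
        for name, report in model.consistency_reports().items():
            if not report.acceptable:
                msg = (
                    f"{where}/{name}: CR = {report.cr:.3f} >= "
                    f"{ahp.CR_THRESHOLD} (inconsistent judgments)"
                )
                if strict_consistency:
                    raise ConfigurationError(msg)
                logger.warning(msg)
        panels[panel_name] = model

    indicators_doc = doc.get("indicators") or {}
    group_indicators = {g: tuple(v) for g, v in indicators_doc.items()}
    if not group_indicators and panels:
        any_panel = next(iter(panels.values()))
        group_indicators = {g: m.labels for g, m in any_panel.groups.items()}

    e_matrices = None
    if "e_matrices" in doc:
        e_matrices = {}
        for g, rows in doc["e_matrices"].items():
            labels = group_indicators.get(g) or tuple(
                f"{g}_{i + 1}" for i in range(len(rows))
            )
            e_matrices[g] = fce.MembershipMatrix(np.asarray(rows, float), labels, g)

    explicit_weights = None
    if "explicit_weights" in doc:
        ew = doc["explicit_weights"]
        try:
            group_order = tuple(ew.get("group_order") or ew["groups"].keys())
            explicit_weights = fce.FceWeights(
                group_weights={
                    g: np.asarray(v, float) for g, v in ew["groups"].items()
                },
                first_level=np.asarray(ew["first_level"], float),
                group_order=group_order,
                mode=str(ew.get("mode", "global")),
            )
        except KeyError as err:
            raise ConfigurationError(
                f"{path}#/explicit_weights: needs 'groups' and 'first_level'"
            ) from err

    membership_spec = None
    if "membership_centers" in doc:
        mc = doc["membership_centers"]
        membership_spec = fce.MembershipFunctionSpec.from_centers(
            centers={k: list(v) for k, v in mc["centers"].items()},
            domains={k: tuple(v) for k, v in mc["domains"].items()},
        )

    return ModelConfig(
        levels=levels,
        panels=panels,
        group_indicators=group_indicators,
        explicit_weights=explicit_weights,
        e_matrices=e_matrices,
        membership_spec=membership_spec,
        operator=str(doc.get("operator", "weighted_average")),
        weight_mode=str(doc.get("weight_mode", "global")),
    )


def _matrix_to_doc(m: ahp.JudgmentMatrix) -> dict:
    upper = {
        f"{m.labels[i]}/{m.labels[j]}": float(m.values[i, j])
        for i in range(m.order)
        for j in range(i + 1, m.order)
    }
    return {"labels": list(m.labels), "upper": upper}


def save_model(cfg: ModelConfig, path) -> None:
    """Serialize a model configuration back to YAML at full precision."""
    doc: dict = {
        "evaluation_levels": list(cfg.levels.levels),
        "weight_mode": cfg.weight_mode,
        "operator": cfg.operator,
    }
    if cfg.panels:
        doc["panels"] = {
            name: {
                "first_level": _matrix_to_doc(model.first_level),
                "groups": {g: _matrix_to_doc(m) for g, m in model.groups.items()},
            }
            for name, model in cfg.panels.items()
        }
    if cfg.group_indicators:
        doc["indicators"] = {g: list(v) for g, v in cfg.group_indicators.items()}
    if cfg.e_matrices is not None:
        doc["e_matrices"] = {
            g: [[float(x) for x in row] for row in e.values]
            for g, e in cfg.e_matrices.items()
        }
    if cfg.explicit_weights is not None:
        ew = cfg.explicit_weights
        doc["explicit_weights"] = {
            "mode": ew.mode,
            "group_order": list(ew.group_order),
            "first_level": [float(x) for x in np.asarray(ew.first_level)],
            "groups": {
                g: [float(x) for x in np.asarray(v)]
                for g, v in ew.group_weights.items()
            },
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_membership_spec() -> fce.MembershipFunctionSpec:
    """The shipped illustrative trapezoid spec (not from any survey)."""
    with open(fixture_path("membership_default.yaml")) as fh:
        doc = yaml.safe_load(fh)
    mc = doc["membership_centers"]
    return fce.MembershipFunctionSpec.from_centers(
        centers={k: list(v) for k, v in mc["centers"].items()},
        domains={k: tuple(v) for k, v in mc["domains"].items()},
    )


def read_records_frame(path) -> pd.DataFrame:
    """Read a record CSV into a frame, checking schema and units."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing record column(s) {missing}")
    for line_offset, (_, row) in enumerate(df.iterrows(), start=2):
        if not 0.0 <= row["humidity_pct"] <= 100.0:
            raise DomainError(
                f"{path}:{line_offset}: humidity_pct = {row['humidity_pct']} "
                "outside [0, 100]"
            )
        for col in ("lying_min", "standing_min"):
            if not 0.0 <= row[col] <= 1440.0:
                raise DomainError(
                    f"{path}:{line_offset}: {col} = {row[col]} outside [0, 1440]"
                )
    return df


def read_records(path) -> list[fce.CalfDailyRecord]:
    """Read a record CSV as typed :class:`CalfDailyRecord` objects."""
    df = read_records_frame(path)
    records = []
    for line_offset, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            records.append(
                fce.CalfDailyRecord(
                    calf_id=str(row["calf_id"]),
                    date=str(row["date"]),
                    **{c: float(row[c]) for c in RECORD_COLUMNS[2:]},
                )
            )
        except (TypeError, ValueError) as err:
            raise SchemaError(f"{path}:{line_offset}: malformed row ({err})") from err
    return records


def write_results(
    path,
    results: Sequence[tuple[fce.CalfDailyRecord | None, fce.FceResult]],
) -> pd.DataFrame:
    """Serialize evaluation results (all intermediates) to CSV.

    Floats are written at full precision; returns the frame written.
    """
    rows = []
    for record, res in results:
        row: dict = {
            "calf_id": record.calf_id if record else "",
            "date": record.date if record else "",
        }
        for g, vec in res.group_vectors.items():
            for k, v in enumerate(vec, start=1):
                row[f"{g}_v{k}"] = v
        for k, v in enumerate(res.combined, start=1):
            row[f"combined_v{k}"] = v
        for k, v in enumerate(res.normalized, start=1):
            row[f"norm_v{k}"] = v
        row["level_index"] = res.level_index
        row["label"] = res.label
        rows.append(row)
    frame = pd.DataFrame(rows)
    # %.17g guarantees float round-trip through text
    frame.to_csv(path, index=False, float_format="%.17g")
    return frame
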