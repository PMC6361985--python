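"""Cohort file formats: schema-validated JSON (canonical) and flat CSV export.

Groups are ragged (member counts vary), so the canonical interchange format
is a nested JSON document validated on read: unknown fields are rejected
with a named error, numbers round-trip at full precision, and observed
finals may be absent (prediction-only workflows).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError

from .dynamics import OpinionArray
from .synthetic import GroupRecord

__all__ = ["CohortFile", "SchemaError", "cohort_to_dataframe",
           "read_cohort", "write_cohort"]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A cohort file violates the schema; the message names field and group."""


class _GroupModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    group_id: str
    supply: float
    simplex_constrained: bool = True
    x0: List[List[float]]
    chips: List[List[int]]
    observed_final: Optional[List[List[float]]] = None
    experiment_kind: str = "unconstrained"


class _CohortModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: int
    experiment_kind: str = "unconstrained"
    groups: List[_GroupModel]


@dataclass
class CohortFile:
    """A validated cohort: schema version, experiment tag and group records."""

    groups: List[GroupRecord]
    experiment_kind: str = "unconstrained"
    schema_version: int = SCHEMA_VERSION


def _group_to_dict(g: GroupRecord) -> dict:
    d = {
        "group_id": g.group_id,
        "supply": g.supply,
        "simplex_constrained": g.X0.simplex_constrained,
        "x0": g.X0.X.tolist(),
        "chips": g.chips.tolist(),
        "observed_final": None if g.observed_final is None
        else g.observed_final.X.tolist(),
        "experiment_kind": g.experiment_kind,
    }
    return d


def _group_from_model(gm: _GroupModel) -> GroupRecord:
    try:
        X0 = OpinionArray(np.array(gm.x0, dtype=float), supply=gm.supply,
                          simplex_constrained=gm.simplex_constrained)
        observed = None
        if gm.observed_final is not None:
            observed = OpinionArray(np.array(gm.observed_final, dtype=float),
                                    supply=gm.supply,
                                    simplex_constrained=gm.simplex_constrained)
        return GroupRecord(group_id=gm.group_id, X0=X0,
                           chips=np.array(gm.chips),
                           observed_final=observed,
                           experiment_kind=gm.experiment_kind)
    except ValueError as exc:
        raise SchemaError(f"group {gm.group_id!r}: {exc}") from exc


def write_cohort(cohort: CohortFile, path) -> None:
    """Serialize a cohort as a single JSON document at full precision."""
    doc = {
        "schema_version": cohort.schema_version,
        "experiment_kind": cohort.experiment_kind,
        "groups": [_group_to_dict(g) for g in cohort.groups],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_cohort(path) -> CohortFile:
    """Read and schema-validate a cohort JSON file.

    Raises :class:`SchemaError` naming the offending field (and group, for
    record-level violations such as off-simplex opinions or malformed chip
    matrices).
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"not valid JSON: {exc}") from exc
    try:
        model = _CohortModel.model_validate(raw)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(f"schema violation at {loc}: {first['msg']}") from exc
    if model.schema_version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema_version {model.schema_version}")
    groups = [_group_from_model(gm) for gm in model.groups]
    return CohortFile(groups=groups, experiment_kind=model.experiment_kind,
                      schema_version=model.schema_version)


def cohort_to_dataframe(cohort: CohortFile) -> pd.DataFrame:
    """Flat per-member table (wide CSV export; JSON remains canonical)."""
    rows = []
    for g in cohort.groups:
        for i in range(g.n):
            rec = {"group_id": g.group_id, "member": i, "n": g.n, "m": g.m,
                   "supply": g.supply, "experiment_kind": g.experiment_kind}
            for j in range(g.m):
                rec[f"x0_{j}"] = g.X0.X[i, j]
            for k in range(g.n):
                rec[f"chips_{k}"] = g.chips[i, k]
            if g.observed_final is not None:
                for j in range(g.m):
                    rec[f"observed_{j}"] = g.observed_final.X[i, j]
            rows.append(rec)
    return pd.DataFrame(rows)
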