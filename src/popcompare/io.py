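"""Reading and writing population data.

Two input dialects, shared by the CLI and the library:

* **matrix JSON** — one population per file::

      {"stages": ["seedling", "adult"],
       "F": [[0.0, 2.0], [0.0, 0.0]],
       "U": [[0.0, 0.0], [0.5, 0.8]],
       "n_per_stage": [40, 25],
       "census": "prebreeding",
       "sampling": "random"}

  ``n_per_stage`` is mandatory: it is not possible to compare populations
  from their projection matrices if the numbers of individuals used to
  construct them are not available — any nonidentical matrices become
  "significantly different" given enough assumed individuals.

* **raw CSV + sidecar** — one record per individual with columns
  ``individual_id,population_id,initial_stage,final_stage,recruits``
  (recruits as ``stage:count`` pairs joined by ``;``) and a YAML/JSON
  sidecar declaring ``stages``, ``reproduction_type``, ``census``,
  ``sampling`` and, for anonymous reproduction (anon1),
  ``reproductive_stages`` and per-population ``recruit_totals``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .demography import ProjectionModel
from .histories import HistoryTable, RawDataset, histories_from_matrix, histories_from_raw

__all__ = [
    "read_matrix_json",
    "write_matrix_json",
    "read_raw_csv",
    "write_raw_csv",
    "read_inputs",
    "InputError",
]


class InputError(ValueError):
    """Invalid or inconsistent input data (CLI exit code 2)."""


def read_matrix_json(path: "str | Path") -> ProjectionModel:
    """Load one population's projection model from matrix JSON."""
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("stages", "F", "U"):
        if key not in doc:
            raise InputError(f"{path}: missing required key {key!r}")
    if "n_per_stage" not in doc:
        raise InputError(
            f"{path}: 'n_per_stage' is missing — it is not possible to compare "
            "populations using their projection matrices if the numbers of "
            "individuals used for their construction are not available"
        )
    try:
        return ProjectionModel(
            stage_names=tuple(str(s) for s in doc["stages"]),
            F=np.asarray(doc["F"], dtype=float),
            U=np.asarray(doc["U"], dtype=float),
            census=doc.get("census", "prebreeding"),
            n_per_stage=np.asarray(doc["n_per_stage"], dtype=int),
            sampling=doc.get("sampling", "random"),
        )
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_matrix_json(model: ProjectionModel, path: "str | Path") -> None:
    doc = {
        "stages": list(model.stage_names),
        "F": model.F.tolist(),
        "U": model.U.tolist(),
        "n_per_stage": None if model.n_per_stage is None else model.n_per_stage.tolist(),
        "census": model.census,
        "sampling": model.sampling,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _load_sidecar(path: "str | Path") -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_raw_csv(csv_path: "str | Path", sidecar_path: "str | Path") -> RawDataset:
    """Load raw demographic data plus its metadata sidecar."""
    meta = _load_sidecar(sidecar_path)
    if "stages" not in meta:
        raise InputError(f"{sidecar_path}: sidecar must declare 'stages'")
    data = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    required = {"individual_id", "population_id", "initial_stage", "final_stage"}
    missing = required - set(data.columns)
    if missing:
        raise InputError(f"{csv_path}: missing column(s) {sorted(missing)}")
    if "recruits" not in data.columns:
        data["recruits"] = ""
    return RawDataset(
        data=data,
        stage_names=tuple(str(s) for s in meta["stages"]),
        reproduction_type=meta.get("reproduction_type", "identified"),
        census=meta.get("census", "prebreeding"),
        sampling=meta.get("sampling", "random"),
        reproductive_stages=tuple(str(s) for s in meta.get("reproductive_stages", ())),
        recruit_totals={
            str(pop): {str(k): int(v) for k, v in totals.items()}
            for pop, totals in meta.get("recruit_totals", {}).items()
        },
    )


def write_raw_csv(raw: RawDataset, csv_path: "str | Path", sidecar_path: "str | Path") -> None:
    raw.data.to_csv(csv_path, index=False)
    meta = {
        "stages": list(raw.stage_names),
        "reproduction_type": raw.reproduction_type,
        "census": raw.census,
        "sampling": raw.sampling,
    }
    if raw.reproduction_type == "anon1":
        meta["reproductive_stages"] = list(raw.reproductive_stages)
        meta["recruit_totals"] = raw.recruit_totals
    Path(sidecar_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_inputs(
    paths: Sequence["str | Path"],
    sidecar: Optional["str | Path"] = None,
) -> list[HistoryTable]:
    """Load any mix the CLI accepts and return validated HistoryTables.

    ``.json`` paths are matrix files (one population each, reconstructed into
    integer histories from the matrix and its individual counts); ``.csv``
    paths are raw data (one or many populations) and need the metadata
    ``sidecar``.  All populations must share the data type, the sampling
    design and the number of stages.
    """
    tables: list[HistoryTable] = []
    for path in paths:
        p = str(path)
        if p.endswith(".json"):
            model = read_matrix_json(p)
            table = histories_from_matrix(model)
            table.population_id = Path(p).stem
            tables.append(table)
        elif p.endswith(".csv"):
            if sidecar is None:
                raise InputError(f"{p}: raw CSV input requires a metadata sidecar")
            tables.extend(histories_from_raw(read_raw_csv(p, sidecar)))
        else:
            raise InputError(f"{p}: unknown input format (expected .json or .csv)")
    if not tables:
        raise InputError("no populations found in the given inputs")
    first = tables[0]
    for t in tables[1:]:
        if len(t.stage_names) != len(first.stage_names):
            raise InputError(
                f"populations {first.population_id!r} and {t.population_id!r} have "
                f"{len(first.stage_names)} vs {len(t.stage_names)} stages; all "
                "populations must have the same number of stages"
            )
        if t.sampling != first.sampling or t.reproduction_type != first.reproduction_type:
            raise InputError(
                "all populations must share the data type and sampling design"
            )
    return tables
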