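"""Tabular text I/O for parameter tables, feature tables and schema manifests.

Feature tables are comma-separated text whose header must match the schema
manifest exactly (same names, same order); a foreign column order is
rejected rather than silently reordered.  Numeric values round-trip at full
precision (17 significant digits).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ReferenceTable
from .sumstats import FeatureSchema

__all__ = [
    "write_schema_manifest",
    "read_schema_manifest",
    "write_feature_table",
    "read_feature_table",
    "write_reference_table",
    "read_reference_table",
]

_FLOAT_FMT = "%.17g"


def write_schema_manifest(schema: FeatureSchema, path) -> None:
    Path(path).write_text(json.dumps(schema.to_manifest(), indent=1))


def read_schema_manifest(path) -> FeatureSchema:
    data = json.loads(Path(path).read_text())
    names = tuple(f["name"] for f in data["features"])
    classes = tuple(f["class"] for f in data["features"])
    scopes = tuple(f["scope"] for f in data["features"])
    base_names = tuple(n.rsplit("-", 1)[0] for n in names)
    return FeatureSchema(names=names, base_names=base_names, classes=classes, scopes=scopes)


def write_feature_table(values: np.ndarray, names, path) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=list(names))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_feature_table(path, expected_names=None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed feature table {path}: {exc}") from exc
    if expected_names is not None:
        got, want = list(df.columns), list(expected_names)
        if got != want:
            missing = [c for c in want if c not in got]
            extra = [c for c in got if c not in want]
            reordered = not missing and not extra
            raise ValueError(
                f"feature table {path} does not match the schema manifest: "
                + (
                    "columns are present but in a foreign order"
                    if reordered
                    else f"missing={missing[:5]} extra={extra[:5]}"
                )
            )
    return df


def write_reference_table(table: ReferenceTable, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = pd.DataFrame(table.params, columns=table.param_names)
    params["split"] = table.split
    params.to_csv(out / "params.csv", index=False, float_format=_FLOAT_FMT)
    write_feature_table(table.features, table.feature_names, out / "features.csv")


def read_reference_table(out_dir, schema: FeatureSchema | None = None) -> ReferenceTable:
    out = Path(out_dir)
    params = pd.read_csv(out / "params.csv")
    split = params.pop("split").to_numpy(dtype=object)
    features = read_feature_table(
        out / "features.csv", schema.names if schema is not None else None
    )
    return ReferenceTable(
        param_names=list(params.columns),
        params=params.to_numpy(dtype=float),
        feature_names=list(features.columns),
        features=features.to_numpy(dtype=float),
        split=split,
    )
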