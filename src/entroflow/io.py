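"""Readers and writers for the pipeline's tabular and JSON artifacts.

Input matrices are CSV/TSV with a header row of feature names and a first
column of subject ids, accompanied by a sidecar YAML declaring each
feature's data type and role (and optional categorical code overrides):

    features:
      age:  {type: continuous, role: covariate}
      sex:  {type: binary, role: covariate}
    overrides:
      sex: {"0": 0, "1": 5}

Floating-point outputs are written with 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .renormalize import (
    CodedMatrix,
    FeatureSpec,
    PossiblyGappedHistogram,
    RawDataMatrix,
    RenormalizeConfig,
)

FLOAT_DIGITS = 12


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.{FLOAT_DIGITS}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True))


def read_feature_yaml(path) -> tuple[dict[str, dict], dict[str, dict]]:
    """Parse a sidecar YAML into (feature declarations, override maps)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "features" not in doc:
        raise ValueError("feature spec required: YAML must contain a 'features' map")
    return doc["features"], doc.get("overrides", {}) or {}


def read_raw_matrix(csv_path, spec_path, sep: str | None = None) -> tuple[
    RawDataMatrix, dict[str, dict]
]:
    """Read a CSV/TSV matrix plus its YAML feature declarations.

    Returns the RawDataMatrix (columns ordered as in the file) and the
    override maps.  The separator is sniffed from the extension unless
    given.
    """
    csv_path = Path(csv_path)
    if sep is None:
        sep = "\t" if csv_path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(csv_path, sep=sep, index_col=0)
    decls, overrides = read_feature_yaml(spec_path)
    missing = [c for c in frame.columns if c not in decls]
    if missing:
        raise ValueError(f"features without declaration: {missing}")
    specs = [
        FeatureSpec(c, decls[c]["type"], decls[c]["role"]) for c in frame.columns
    ]
    return RawDataMatrix(frame, specs), overrides


def write_coded_csv(coded: CodedMatrix, path) -> None:
    coded.codes.to_csv(path, index_label="subject_id")


def write_histograms_json(hists: dict[str, PossiblyGappedHistogram], path) -> None:
    write_json({name: h.to_dict() for name, h in hists.items()}, path)


def write_entropy_csv(xi, path) -> None:
    xi.to_dataframe().to_csv(path, index_label="feature",
                             float_format=f"%.{FLOAT_DIGITS}g")


def write_tree_json(tree, path) -> None:
    write_json(tree.to_dict(), path)


def write_tree_newick(tree, path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


def write_geometry_json(geometry, path) -> None:
    write_json(geometry.to_dict(), path)


def write_flow_json(result, path) -> None:
    write_json(result.to_dict(), path)


def overrides_to_config(overrides: dict[str, dict], **kwargs) -> RenormalizeConfig:
    """Build a RenormalizeConfig carrying the YAML override maps."""
    return RenormalizeConfig(overrides=dict(overrides), **kwargs)
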