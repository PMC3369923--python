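"""Matrix, panel, model and config I/O.

Matrices travel as TSV/CSV with a header row of feature ids and the line id
in the first column; missing cells are written as ``NA``.  Model stacks are
serialized to a single schema-versioned JSON file (edge lists, intercepts,
ranges, baseline expression) so that ``load(save(x))`` reproduces
predictions bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import LayerModel, ModelStack
from .panel import OmicsPanel

MODEL_SCHEMA_VERSION = 1


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path) -> pd.DataFrame:
    """Read a lines x features matrix (TSV by default, CSV by extension)."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate feature id {name!r} in {path}")
        seen.add(name)
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0,
            na_values=["NA"], keep_default_na=False,
        )
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate line id {dup!r} in {path}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate feature id {dup!r} in {path}")
    return df.astype(float)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep=_sep_for(path), na_rep="NA")


def write_panel(panel: OmicsPanel, directory) -> None:
    """Write a panel as expression/metabolites/traits TSVs (+ latent block)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if panel.expression is not None:
        write_matrix(panel.expression, directory / "expression.tsv")
    write_matrix(panel.metabolites, directory / "metabolites.tsv")
    write_matrix(panel.traits, directory / "traits.tsv")
    if panel.latent:
        for name, mat in panel.latent.items():
            write_matrix(mat, directory / f"latent_{name}.tsv")
    if panel.report:
        with open(directory / "report.json", "w") as fh:
            json.dump(panel.report, fh, indent=2, default=str)


def read_panel(directory) -> OmicsPanel:
    directory = Path(directory)
    expr_path = directory / "expression.tsv"
    expression = read_matrix(expr_path) if expr_path.exists() else None
    latent = {}
    for name in ("expression", "metabolites", "traits"):
        p = directory / f"latent_{name}.tsv"
        if p.exists():
            latent[name] = read_matrix(p)
    report = {}
    rp = directory / "report.json"
    if rp.exists():
        with open(rp) as fh:
            report = json.load(fh)
    return OmicsPanel(
        expression=expression,
        metabolites=read_matrix(directory / "metabolites.tsv"),
        traits=read_matrix(directory / "traits.tsv"),
        latent=latent or None,
        report=report,
    )


# ---------------------------------------------------------------------------
# model stack JSON


def _layer_to_dict(layer: LayerModel) -> dict:
    tt, pp = np.nonzero(layer.coef.to_numpy())
    edges = [
        [str(layer.coef.index[t]), str(layer.coef.columns[p]),
         float(layer.coef.iat[t, p])]
        for t, p in zip(tt, pp)
    ]
    d = {
        "layer": layer.layer,
        "targets": list(map(str, layer.coef.index)),
        "predictors": list(map(str, layer.coef.columns)),
        "edges": edges,
        "intercept": {str(k): float(v) for k, v in layer.intercept.items()},
        "calibration": float(layer.calibration),
        "delta": float(layer.delta),
        "meta": _jsonable(layer.meta),
    }
    if layer.gene_ranges is not None:
        d["gene_ranges"] = {
            str(g): [float(r["min"]), float(r["max"])]
            for g, r in layer.gene_ranges.iterrows()
        }
    return d


def _layer_from_dict(d: dict) -> LayerModel:
    coef = pd.DataFrame(0.0, index=d["targets"], columns=d["predictors"])
    for t, p, c in d["edges"]:
        coef.loc[t, p] = c
    ranges = None
    if "gene_ranges" in d:
        ranges = pd.DataFrame(
            {g: {"min": lo, "max": hi} for g, (lo, hi) in d["gene_ranges"].items()}
        ).T.reindex(d["targets"])
    return LayerModel(
        layer=d["layer"], coef=coef,
        intercept=pd.Series(d["intercept"]).reindex(d["targets"]),
        calibration=float(d["calibration"]),
        gene_ranges=ranges, delta=float(d["delta"]),
        meta=d.get("meta", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def save_model(stack: ModelStack, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "tool_version": __version__,
        "layers": {
            "genes": _layer_to_dict(stack.genes),
            "metabolites": _layer_to_dict(stack.metabolites),
        },
        "meta": _jsonable(stack.meta),
    }
    if stack.traits is not None:
        doc["layers"]["traits"] = _layer_to_dict(stack.traits)
    if stack.expression is not None:
        doc["expression"] = {
            "index": list(map(str, stack.expression.index)),
            "columns": list(map(str, stack.expression.columns)),
            "data": [[float(v) for v in row] for row in stack.expression.to_numpy()],
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> ModelStack:
    path = Path(path)
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} unsupported "
            f"(this build reads version {MODEL_SCHEMA_VERSION})"
        )
    layers = doc["layers"]
    expression = None
    if "expression" in doc:
        e = doc["expression"]
        expression = pd.DataFrame(e["data"], index=e["index"], columns=e["columns"])
    return ModelStack(
        genes=_layer_from_dict(layers["genes"]),
        metabolites=_layer_from_dict(layers["metabolites"]),
        traits=_layer_from_dict(layers["traits"]) if "traits" in layers else None,
        expression=expression,
        meta=doc.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# run configuration


DEFAULT_CONFIG = {
    "preprocess": {"span": 0.3, "presence_fraction": 0.8, "cv_max": None,
                   "log_transform": False, "lowess": False},
    "infer": {"z_star": 2.0, "t_lasso": None, "bins": None, "folds": 5,
              "n_boot": 10000, "delta": 0.0},
    "seed": 0,
}


def load_run_config(path: Optional[str]) -> dict:
    """YAML/JSON run config merged over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if isinstance(values, dict) and isinstance(cfg.get(section), dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]
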