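"""Delimited-text I/O, configuration loading, and the end-to-end pipeline.

The interchange format is plain CSV: one header row, feature columns named
``f0..f{d-1}``, an optional ``split`` column, and a final ``label`` column.
Feature roles (for synthetic data) live in an optional sidecar CSV. The
pipeline chains filter scoring, GA selection, and KNN classification with a
shared seed and records everything needed to re-run it in a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .datasets import FeatureDataset, SyntheticSpec, generate_dataset, split_dataset
from .errors import GafsError, ParseError
from .filtering import get_filter
from .ga import GAConfig, run_ga
from .metrics import evaluate, knn_predict

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"
SPLIT_COLUMN = "split"


def write_feature_table(
    ds: FeatureDataset, path: Union[str, Path], roles_path: Optional[Union[str, Path]] = None
) -> None:
    """Write a dataset as CSV (features f0.., optional split, label last);
    optionally write the feature-role sidecar."""
    d = ds.n_features
    # repr() is the shortest exact round-trip form; pandas' default float
    # formatting can be off by one ulp
    cols = {
        f"f{j}": [repr(float(v)) for v in ds.matrix[:, j]] for j in range(d)
    }
    if ds.split_assignment is not None:
        cols[SPLIT_COLUMN] = np.asarray(ds.split_assignment)
    cols[LABEL_COLUMN] = ds.labels
    pd.DataFrame(cols).to_csv(path, index=False)
    if roles_path is not None and ds.feature_roles is not None:
        pd.DataFrame(
            {
                "feature": [f"f{j}" for j in range(d)],
                "role": ds.feature_roles,
                "source": ds.redundant_source
                if ds.redundant_source is not None
                else np.full(d, -1),
            }
        ).to_csv(roles_path, index=False)


def read_feature_table(path: Union[str, Path]) -> FeatureDataset:
    """Read a dataset from CSV, validating shape and types.

    Errors name the offending row/column: ragged rows, non-numeric feature
    cells and missing values are all rejected, as is an absent ``label``
    column."""
    path = Path(path)
    try:
        # default parser can be one ulp off; round_trip is exact
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed delimited text ({exc})") from exc
    if LABEL_COLUMN not in df.columns:
        raise ParseError(f"{path}: no '{LABEL_COLUMN}' column in header")
    feature_cols = [c for c in df.columns if c not in (LABEL_COLUMN, SPLIT_COLUMN)]
    if not feature_cols:
        raise ParseError(f"{path}: no feature columns")

    for col in feature_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, "
                f"column {col!r}"
            )
        df[col] = numeric
    na = df[feature_cols + [LABEL_COLUMN]].isna()
    if na.any().any():
        col = na.any(axis=0).idxmax()
        row = int(na[col].idxmax())
        raise ParseError(f"{path}: missing value at row {row}, column {col!r}")

    split = (
        df[SPLIT_COLUMN].to_numpy() if SPLIT_COLUMN in df.columns else None
    )
    labels = df[LABEL_COLUMN].to_numpy()
    return FeatureDataset(
        matrix=df[feature_cols].to_numpy(dtype=float),
        labels=labels,
        split_assignment=split,
        feature_names=feature_cols,
    )


def load_ga_config(source: Union[str, Path, dict]) -> GAConfig:
    """GAConfig from a flat YAML mapping (or an already-parsed dict);
    unknown keys are rejected."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise GafsError("GA config must be a flat key/value mapping")
    allowed = set(GAConfig.__dataclass_fields__)
    unknown = set(data) - allowed
    if unknown:
        raise GafsError(f"unknown config keys: {sorted(unknown)}")
    return GAConfig(**data)


def sha256_of(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a pipeline identically: the echoed
    configuration, the seeds, input digests, and per-stage outputs."""

    config: dict
    seed: int
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "inputs": self.inputs,
                "stages": self.stages,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


PIPELINE_KEYS = {"data", "split_fractions", "ga", "knn_k", "knn_scale", "out_dir"}


def run_pipeline(
    config: Union[str, Path, dict], out_dir: Optional[Union[str, Path]] = None
) -> RunManifest:
    """Execute score -> select -> classify with a shared seed.

    ``config`` is a YAML file (or dict) with keys:

    - ``data``: either ``{"path": csv}`` or a mapping of SyntheticSpec
      fields for generated input;
    - ``split_fractions``: train/val/test proportions (default 0.7/0.2/0.1),
      applied when the input has no split column;
    - ``ga``: flat GAConfig mapping (validated before any stage runs);
    - ``knn_k`` (default: the GA config's k) and ``knn_scale`` (default on);
    - ``out_dir``: run directory for all outputs.

    Outputs (scores.csv, result.json, report.json, manifest.json) go to the
    run directory; input files are never modified.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(config)
    if not isinstance(cfg, dict):
        raise GafsError("pipeline config must be a mapping")
    unknown = set(cfg) - PIPELINE_KEYS
    if unknown:
        raise GafsError(f"unknown pipeline config keys: {sorted(unknown)}")

    ga_config = load_ga_config(cfg.get("ga", {}))  # validates before stages
    out_dir = Path(out_dir or cfg.get("out_dir") or "gafs_run")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=_jsonable(cfg), seed=ga_config.seed)

    # ---- stage: input
    try:
        data_cfg = dict(cfg.get("data") or {})
        if "path" in data_cfg:
            path = data_cfg["path"]
            ds = read_feature_table(path)
            manifest.inputs["dataset"] = {
                "path": str(path),
                "sha256": sha256_of(path),
            }
        else:
            spec = SyntheticSpec(**{**data_cfg, "seed": data_cfg.get("seed", ga_config.seed)})
            ds = generate_dataset(spec)
            manifest.inputs["dataset"] = {"synthetic_spec": _jsonable(spec.__dict__)}
        if ds.split_assignment is None:
            fractions = cfg.get("split_fractions", (0.7, 0.2, 0.1))
            ds = split_dataset(ds, fractions, seed=ga_config.seed)
            manifest.stages["split"] = {"fractions": list(map(float, fractions))}
        dataset_path = out_dir / "dataset.csv"
        write_feature_table(ds, dataset_path)
        manifest.outputs["dataset"] = dataset_path.name
    except Exception as exc:
        raise GafsError(f"pipeline stage 'input' failed: {exc}") from exc

    # ---- stage: score
    try:
        scores = get_filter(ga_config.filter_name)(ds, split="train")
        scores_path = out_dir / "scores.csv"
        write_scores(scores, scores_path)
        manifest.stages["score"] = {"filter": ga_config.filter_name}
        manifest.outputs["scores"] = scores_path.name
    except Exception as exc:
        raise GafsError(f"pipeline stage 'score' failed: {exc}") from exc

    # ---- stage: select
    try:
        result = run_ga(ds, ga_config, scores=scores)
        result_path = out_dir / "result.json"
        result_payload = {
            "config": ga_config.to_dict(),
            "seed": ga_config.seed,
            "selected_indices": result.selected_indices.tolist(),
            "best_fitness": result.best_fitness,
            "trajectory": result.trajectory,
            "evaluations": result.evaluations,
        }
        result_path.write_text(json.dumps(result_payload, indent=2, sort_keys=True))
        manifest.stages["select"] = {
            "n_selected": int(result.selected_indices.size),
            "best_fitness": result.best_fitness,
        }
        manifest.outputs["result"] = result_path.name
    except Exception as exc:
        raise GafsError(f"pipeline stage 'select' failed: {exc}") from exc

    # ---- stage: classify
    try:
        k = int(cfg.get("knn_k", ga_config.knn_k))
        scale = bool(cfg.get("knn_scale", True))
        train = ds.rows("train")
        test = ds.rows("test")
        if not test.any():  # no held-out rows: fall back to val
            test = ds.rows("val")
        sel = result.selected_indices
        pred = knn_predict(
            ds.matrix[np.ix_(train, np.isin(np.arange(ds.n_features), sel))],
            ds.labels[train],
            ds.matrix[np.ix_(test, np.isin(np.arange(ds.n_features), sel))],
            k=k,
            scale=scale,
        )
        report = evaluate(ds.labels[test], pred)
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
        manifest.stages["classify"] = {"k": k, "accuracy": report.accuracy}
        manifest.outputs["report"] = report_path.name
    except Exception as exc:
        raise GafsError(f"pipeline stage 'classify' failed: {exc}") from exc

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    logger.info("pipeline complete: %s", manifest_path)
    return manifest


def write_scores(scores, path: Union[str, Path]) -> None:
    """Score table CSV: feature index, relevance, mRMR score, selection rank."""
    ranks = scores.rank_of()
    pd.DataFrame(
        {
            "feature": np.arange(scores.n_features),
            "relevance": scores.relevance,
            "mrmr_score": scores.scores,
            "selection_rank": ranks,
        }
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
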