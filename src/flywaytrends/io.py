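"""Readers and writers for the pipeline's plain-text formats.

Counts: long CSV ``site_id,node_id,year,month,count`` (blank count = missing
replicate). Trees: Newick, one per line. Comparative tables: CSV with
``taxon,trend,trend_lo,trend_hi`` plus covariate columns. Ground-truth
sidecars and run configuration: YAML.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .datasets import (
    COUNT_COLUMNS,
    ComparativeDataset,
    CountDataset,
    DataValidationError,
    TreeSet,
)


def read_counts(path) -> CountDataset:
    """Read and validate a counts CSV; schema errors name the offending rows."""
    df = pd.read_csv(path)
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing columns {missing}; expected {COUNT_COLUMNS}"
        )
    try:
        return CountDataset(df)
    except DataValidationError as e:
        raise DataValidationError(f"{path}: {e}") from None


def write_counts(dataset: CountDataset, path) -> None:
    dataset.df.to_csv(path, index=False)


def read_trees(path, ultrametric: str = "warn") -> TreeSet:
    """Read a multi-tree Newick file (one tree per line).

    ``ultrametric`` controls the root-to-tip height check: "warn" (default,
    credible tree sets are often only near-ultrametric), "error", or
    "ignore".
    """
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", rooting="default-rooted"
    )
    if len(trees) == 0:
        raise DataValidationError(f"{path}: no trees parsed")
    ts = TreeSet(trees=trees)
    if ultrametric != "ignore":
        import warnings

        for q in range(ts.n_trees):
            if not ts.is_ultrametric(q, tol=1e-6):
                msg = f"{path}: tree {q} is not ultrametric within tolerance"
                if ultrametric == "error":
                    raise DataValidationError(msg)
                warnings.warn(msg)
                break
    return ts


def write_trees(tree_set: TreeSet, path) -> None:
    Path(path).write_text(tree_set.as_newick() + "\n")


def read_comparative(path, covariates=None) -> ComparativeDataset:
    df = pd.read_csv(path)
    kw = {} if covariates is None else {"covariates": list(covariates)}
    try:
        return ComparativeDataset(df=df, **kw)
    except DataValidationError as e:
        raise DataValidationError(f"{path}: {e}") from None


def write_comparative(data: ComparativeDataset, path) -> None:
    data.df.to_csv(path, index=False)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_ground_truth(truth: dict, path) -> None:
    """YAML sidecar of a simulation's latent draws (config stored by name)."""
    plain = {}
    for k, v in truth.items():
        if k == "config":
            plain[k] = _to_plain(vars(v).copy())
        else:
            plain[k] = _to_plain(v)
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=False))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def write_yaml(obj: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(obj), sort_keys=False))
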