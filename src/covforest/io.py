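"""Table reading, model archives and run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._tree import Tree
from .forest import ForestModel
from .params import ForestParams
from .sample import SupervisedSample

ARCHIVE_VERSION = 1


def read_table(path, role: str = "covariates", sep: str = ",") -> pd.DataFrame:
    """Read a delimited text table with a header row.

    Responses must be fully numeric; covariate columns that fail numeric
    parsing become categoricals downstream.  Missing values are a hard error
    naming the offending cell.
    """
    if role not in ("covariates", "responses"):
        raise ValueError("role must be 'covariates' or 'responses'")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ValueError(f"duplicate column names in {path}: {dups}")
    df = pd.read_csv(path, sep=sep)
    na = df.isna()
    if na.any().any():
        col = na.any()[na.any()].index[0]
        row = int(na[col].idxmax())
        raise ValueError(
            f"missing value in {path} at row {row}, column {col!r}"
        )
    if role == "responses":
        for c in df.columns:
            if not pd.api.types.is_numeric_dtype(df[c]):
                raise ValueError(
                    f"response column {c!r} in {path} is not numeric"
                )
    return df


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: dict) -> Path:
    """Record config, seed, package version and input digests beside outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "covforest",
        "version": __version__,
        "config": config,
        "inputs": {k: file_digest(v) for k, v in inputs.items()},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def save_model(results, path) -> None:
    """Serialize a fitted model: JSON manifest + one .npz of arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    forest: ForestModel = results.forest
    d = forest.sample
    arrays = {
        "X": d.X,
        "Y": d.Y,
        "is_categorical": d.is_categorical,
        "inbag": np.array(forest.inbag),
    }
    for b, tree in enumerate(forest.trees):
        arrays[f"t{b}_feature"] = tree.feature
        arrays[f"t{b}_threshold"] = tree.threshold
        arrays[f"t{b}_left_mask"] = tree.left_mask
        arrays[f"t{b}_left_child"] = tree.left_child
        arrays[f"t{b}_right_child"] = tree.right_child
        arrays[f"t{b}_members"] = np.concatenate(tree.members)
        arrays[f"t{b}_offsets"] = np.cumsum([len(m) for m in tree.members])
    np.savez_compressed(path / "arrays.npz", **arrays)
    from . import __version__

    meta = {
        "archive_version": ARCHIVE_VERSION,
        "package_version": __version__,
        "params": {
            k: getattr(results.params, k)
            for k in (
                "n_trees",
                "mtry",
                "nsplit",
                "nodesize",
                "sampsize",
                "min_child",
                "seed",
            )
        },
        "x_names": d.x_names,
        "y_names": d.y_names,
        "levels": {str(k): list(map(str, v)) for k, v in d.levels.items()},
        "n_trees": forest.n_trees,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    from .model import CovarianceForest, CovarianceForestResults

    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta["archive_version"] != ARCHIVE_VERSION:
        raise ValueError(
            f"unsupported archive version {meta['archive_version']}"
        )
    with np.load(path / "arrays.npz") as z:
        data = SupervisedSample(
            X=z["X"],
            Y=z["Y"],
            is_categorical=z["is_categorical"],
            levels={int(k): v for k, v in meta["levels"].items()},
            x_names=meta["x_names"],
            y_names=meta["y_names"],
        )
        trees = []
        for b in range(meta["n_trees"]):
            offsets = z[f"t{b}_offsets"]
            flat = z[f"t{b}_members"]
            starts = np.r_[0, offsets[:-1]]
            members = [flat[s:e] for s, e in zip(starts, offsets)]
            trees.append(
                Tree(
                    feature=z[f"t{b}_feature"],
                    threshold=z[f"t{b}_threshold"],
                    left_mask=z[f"t{b}_left_mask"],
                    left_child=z[f"t{b}_left_child"],
                    right_child=z[f"t{b}_right_child"],
                    members=members,
                )
            )
        inbag = [np.asarray(r) for r in z["inbag"]]
    params = ForestParams(**meta["params"])
    all_rows = np.arange(data.n)
    oob = [np.setdiff1d(all_rows, ib, assume_unique=True) for ib in inbag]
    forest = ForestModel(
        sample=data, params=params, trees=trees, inbag=inbag, oob=oob
    )
    model = CovarianceForest(data.Y, data.X)
    model.data = data  # keep categorical metadata
    return CovarianceForestResults(model, forest, params, None)
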