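"""Readers, writers and model serialization shared by all commands.

TSV is the canonical interchange format (inspectable and language
neutral); PNG images round-trip through 16-bit grayscale; model and prior
metadata live in JSON sidecars, with HDF5 for the prior covariance stack.
All files use 0-based indices and row-major image flattening, and every
sidecar states those conventions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .containers import ImageSet, ResponseSet
from .encoding import EncodingModel
from .gating import GatingModel
from .prior import ImageNormalization, MixturePrior

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_images",
    "write_images",
    "read_labels",
    "write_labels",
    "read_responses",
    "write_responses",
    "write_report",
    "read_report",
    "save_encoding_model",
    "load_encoding_model",
    "save_prior",
    "load_prior",
    "save_gating_model",
    "load_gating_model",
    "write_png_montage",
]

logger = logging.getLogger(__name__)

_CONVENTIONS = {"flattening": "row-major", "indexing": "0-based"}


def write_matrix(path, matrix: np.ndarray, columns=None) -> None:
    """Write a numeric matrix as TSV, optionally with a header row."""
    df = pd.DataFrame(np.asarray(matrix), columns=columns)
    df.to_csv(path, sep="\t", index=False, header=columns is not None,
              float_format="%.17g")


def read_matrix(path, header: bool = False) -> tuple[np.ndarray, list | None]:
    """Read a TSV matrix; returns ``(values, column_names_or_None)``."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path} is empty")
    try:
        df = pd.read_csv(path, sep="\t", header=0 if header else None)
    except Exception as err:
        raise ValueError(f"malformed matrix file {path}: {err}") from err
    cols = list(df.columns) if header else None
    return df.to_numpy(dtype=float), cols


def write_labels(path, labels) -> None:
    Path(path).write_text("\n".join(str(l) for l in labels) + "\n")


def read_labels(path) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"label file {path} is empty")
    return np.array([l.strip() for l in lines if l.strip()])


def write_images(path_prefix, images: ImageSet, png_dir=None) -> None:
    """Write an image set: TSV matrix + JSON sidecar (+ optional PNG dir).

    ``<prefix>.tsv`` holds the trial-by-pixel matrix, ``<prefix>.json``
    the grid shape and conventions, ``<prefix>.labels.tsv`` the labels if
    present.  With ``png_dir`` each trial is additionally saved as a
    16-bit grayscale PNG scaled to the set's intensity range.
    """
    prefix = Path(path_prefix)
    write_matrix(prefix.with_suffix(".tsv"), images.data)
    sidecar = {
        "grid_shape": list(images.grid_shape),
        "n_trials": images.n_trials,
        **_CONVENTIONS,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if images.labels is not None:
        write_labels(prefix.parent / (prefix.name + ".labels.tsv"), images.labels)
    if png_dir is not None:
        png_dir = Path(png_dir)
        png_dir.mkdir(parents=True, exist_ok=True)
        lo, hi = images.data.min(), images.data.max()
        span = hi - lo if hi > lo else 1.0
        for i in range(images.n_trials):
            arr = ((images.image(i) - lo) / span * 65535).astype(np.uint16)
            Image.fromarray(arr).save(png_dir / f"trial{i:04d}.png")


def read_images(path_prefix) -> ImageSet:
    prefix = Path(path_prefix)
    data, _ = read_matrix(prefix.with_suffix(".tsv"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    labels_path = prefix.parent / (prefix.name + ".labels.tsv")
    labels = read_labels(labels_path) if labels_path.exists() else None
    return ImageSet(data, tuple(sidecar["grid_shape"]), labels)


def write_responses(path, responses: ResponseSet) -> None:
    """TSV with a header row of voxel identifiers."""
    write_matrix(path, responses.data, columns=list(responses.voxel_ids))


def read_responses(path) -> ResponseSet:
    data, cols = read_matrix(path, header=True)
    return ResponseSet(data, np.array(cols))


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


# ---------------------------------------------------------------------------
# model serialization


def save_encoding_model(out_dir, model: EncodingModel) -> None:
    """JSON metadata plus a TSV payload for the weight matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_pixels": model.n_pixels,
        "n_voxels": model.n_voxels,
        "sigma2": model.sigma2.tolist(),
        "lambdas": model.lambdas.tolist(),
        "selected": model.selected.astype(int).tolist(),
        "response_mean": model.response_mean.tolist(),
        "response_std": model.response_std.tolist(),
        "threshold": model.threshold,
        "seed": model.seed,
        "lambda_grid": None if model.lambda_grid is None
        else model.lambda_grid.tolist(),
        **_CONVENTIONS,
    }
    (out / "model.json").write_text(json.dumps(meta, indent=2))
    write_matrix(out / "B.tsv", model.B)


def load_encoding_model(out_dir) -> EncodingModel:
    out = Path(out_dir)
    meta = json.loads((out / "model.json").read_text())
    B, _ = read_matrix(out / "B.tsv")
    return EncodingModel(
        B=B,
        sigma2=np.array(meta["sigma2"]),
        lambdas=np.array(meta["lambdas"]),
        selected=np.array(meta["selected"], dtype=bool),
        response_mean=np.array(meta["response_mean"]),
        response_std=np.array(meta["response_std"]),
        threshold=meta["threshold"],
        seed=meta["seed"],
        lambda_grid=None if meta["lambda_grid"] is None
        else np.array(meta["lambda_grid"]),
    )


def save_prior(out_dir, prior: MixturePrior) -> None:
    """JSON metadata, HDF5 for means/covariances, TSV for the label table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_components": prior.n_components,
        "n_pixels": prior.n_pixels,
        "weights": prior.weights.tolist(),
        "label_names": None if prior.label_names is None
        else [str(l) for l in prior.label_names],
        "grid_shape": None if prior.grid_shape is None
        else list(prior.grid_shape),
        "normalization": None if prior.normalization is None
        else {"vmin": prior.normalization.vmin, "vmax": prior.normalization.vmax},
        **_CONVENTIONS,
    }
    (out / "prior.json").write_text(json.dumps(meta, indent=2))
    with h5py.File(out / "prior.h5", "w") as f:
        f.create_dataset("means", data=prior.means)
        f.create_dataset("covariances", data=prior.covariances)
    if prior.label_table is not None:
        write_matrix(out / "label_table.tsv", prior.label_table)


def load_prior(out_dir) -> MixturePrior:
    out = Path(out_dir)
    meta = json.loads((out / "prior.json").read_text())
    with h5py.File(out / "prior.h5", "r") as f:
        means = f["means"][...]
        covs = f["covariances"][...]
    table = None
    if (out / "label_table.tsv").exists():
        table, _ = read_matrix(out / "label_table.tsv")
    norm = None
    if meta["normalization"] is not None:
        norm = ImageNormalization(**meta["normalization"])
    return MixturePrior(
        means=means,
        covariances=covs,
        weights=np.array(meta["weights"]),
        label_table=table,
        label_names=None if meta["label_names"] is None
        else np.array(meta["label_names"]),
        normalization=norm,
        grid_shape=None if meta["grid_shape"] is None
        else tuple(meta["grid_shape"]),
    )


def save_gating_model(path, model: GatingModel) -> None:
    """Single JSON file with sparse weights as index/value lists."""
    idx = np.nonzero(model.weights)
    payload = {
        "intercepts": model.intercepts.tolist(),
        "n_features": model.n_features,
        "penalty": model.penalty,
        "class_order": [str(c) for c in model.class_order],
        "weight_rows": idx[0].tolist(),
        "weight_cols": idx[1].tolist(),
        "weight_values": model.weights[idx].tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_gating_model(path) -> GatingModel:
    payload = json.loads(Path(path).read_text())
    K = len(payload["intercepts"])
    W = np.zeros((K, payload["n_features"]))
    W[payload["weight_rows"], payload["weight_cols"]] = payload["weight_values"]
    return GatingModel(
        intercepts=np.array(payload["intercepts"]),
        weights=W,
        penalty=payload["penalty"],
        class_order=np.array(payload["class_order"]),
    )


def write_png_montage(path, images: ImageSet, n_cols: int = 10) -> None:
    """Tile all trials into one 16-bit grayscale PNG."""
    H, W = images.grid_shape
    n = images.n_trials
    n_cols = min(n_cols, n)
    n_rows = int(np.ceil(n / n_cols))
    canvas = np.zeros((n_rows * H, n_cols * W))
    for i in range(n):
        r, c = divmod(i, n_cols)
        canvas[r * H : (r + 1) * H, c * W : (c + 1) * W] = images.image(i)
    lo, hi = canvas.min(), canvas.max()
    span = hi - lo if hi > lo else 1.0
    arr = ((canvas - lo) / span * 65535).astype(np.uint16)
    Image.fromarray(arr).save(path)
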