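"""Reading images, dataset manifests, and delimited feature matrices.

A dataset manifest is a CSV with header
``path,label,subject,eye_lx,eye_ly,eye_rx,eye_ry``; the four eye columns
are optional, and when absent images are assumed pre-cropped to 110x150.
Feature matrices are written as whitespace-delimited text (rows =
samples) with a JSON sidecar recording the operator, grid and bin count.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .lbp import EyePair, LbpParams, extract_lbp_features, normalize_face

__all__ = [
    "read_gray_image",
    "read_manifest",
    "extract_dataset_features",
    "save_features",
    "load_features",
]

MANIFEST_COLUMNS = ["path", "label", "subject"]
EYE_COLUMNS = ["eye_lx", "eye_ly", "eye_rx", "eye_ry"]


def read_gray_image(path) -> np.ndarray:
    """Read a PNG/PGM/TIFF image as a 2-D float array.

    Color images are converted by averaging the channels, with a warning.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        warnings.warn(f"{path}: color image converted to gray by channel average",
                      stacklevel=2)
        arr = arr[..., :3].mean(axis=-1)
    return arr.astype(np.float64)


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a dataset manifest CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns {missing}")
    has_eyes = all(c in df.columns for c in EYE_COLUMNS)
    if not has_eyes:
        present = [c for c in EYE_COLUMNS if c in df.columns]
        if present:
            raise ValueError(
                f"manifest has only some eye columns ({present}); provide all "
                f"of {EYE_COLUMNS} or none"
            )
    return df


def extract_dataset_features(
    manifest: pd.DataFrame,
    root=None,
    params: LbpParams = LbpParams(),
    grid=(7, 6),
    normalize: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LBP features for every manifest row: (X, labels, subjects).

    When eye columns are present each image is geometrically normalized
    to the 110x150 face crop first.
    """
    root = Path(root) if root is not None else None
    has_eyes = all(c in manifest.columns for c in EYE_COLUMNS)
    rows = []
    for rec in manifest.itertuples(index=False):
        p = Path(rec.path)
        if root is not None and not p.is_absolute():
            p = root / p
        img = read_gray_image(p)
        if has_eyes:
            eyes = EyePair((rec.eye_lx, rec.eye_ly), (rec.eye_rx, rec.eye_ry))
            img = normalize_face(img, eyes)
        rows.append(extract_lbp_features(img, params, grid, normalize=normalize))
    X = np.vstack(rows)
    return X, manifest["label"].to_numpy(), manifest["subject"].to_numpy()


def save_features(path, X, labels=None, subjects=None, params: LbpParams = LbpParams(),
                  grid=(7, 6), normalized: bool = False) -> None:
    """Write a feature matrix as delimited text plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(X), fmt="%.10g")
    meta = {
        "operator": {"P": params.P, "R": params.R, "uniform": params.uniform},
        "grid": list(grid) if not hasattr(grid, "n_rows") else [grid.n_rows, grid.n_cols],
        "n_bins": params.n_labels,
        "normalized": normalized,
        "n_samples": int(np.asarray(X).shape[0]),
        "n_features": int(np.asarray(X).shape[1]),
    }
    if labels is not None:
        meta["labels"] = [l.item() if hasattr(l, "item") else l for l in labels]
    if subjects is not None:
        meta["subjects"] = [s.item() if hasattr(s, "item") else s for s in subjects]
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_features(path):
    """Load a feature matrix and its sidecar; returns (X, meta dict)."""
    path = Path(path)
    X = np.loadtxt(path, ndmin=2)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return X, meta


def write_expression_dataset(dataset, out_dir) -> Path:
    """Write a synthetic image set as PNGs plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, lab, sub) in enumerate(
        zip(dataset.images, dataset.labels, dataset.subjects)
    ):
        name = f"img_{i:04d}_s{sub:02d}_c{lab}.png"
        iio.imwrite(out_dir / name, img)
        rows.append({"path": name, "label": int(lab), "subject": int(sub)})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
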