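"""Image ingestion, resizing, and Box-Cox intensity normalization.

Raw 8-bit lesion images (grayscale or RGB) are standardized to a common
square size by corner-aligned bilinear interpolation and then intensity
normalized with a Box-Cox power transform

    y = (x**lam - 1) / lam        (lam != 0)
    y = log(x)                    (lam == 0)

applied per pixel.  Box-Cox requires strictly positive inputs while 8-bit
pixels include 0, so each intensity v in [0, 255] is first mapped to
x = (v + 1) / 256 in (0, 1]; after the transform each image is min-max
rescaled to [0, 1].  Both steps are strictly monotone, so pixel rank order
is preserved, and the whole pipeline is a pure function of the input bytes
and parameters: re-running it produces bit-identical outputs.

Processed images are stored as float32 ``.npy`` arrays (shape H x W x C);
manifests are CSV files with header ``path,modality,label,split,fold``.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._nn import bilinear_resize
from .errors import DataError, InvalidInputError, NumericError

__all__ = [
    "BoxCoxParams",
    "DatasetManifest",
    "read_manifest",
    "write_manifest",
    "load_image",
    "resize_image",
    "box_cox_raw",
    "box_cox_transform",
    "preprocess_dataset",
]

MANIFEST_COLUMNS = ["path", "modality", "label", "split", "fold"]
MODALITIES = ("MGI", "USI")
LABELS = ("benign", "malignant")


@dataclasses.dataclass
class BoxCoxParams:
    """Box-Cox transform parameters.

    lam
        Power-transform exponent; 0.5 by default (square-root-like transform).
    epsilon_shift
        Positive offset added to the 8-bit intensity before scaling by 1/256,
        guaranteeing a strictly positive transform domain.
    """

    lam: float = 0.5
    epsilon_shift: float = 1.0

    def __post_init__(self):
        if self.epsilon_shift <= 0:
            raise InvalidInputError("epsilon_shift must be > 0")


@dataclasses.dataclass
class DatasetManifest:
    """A table of image records plus the generation seed and image size."""

    frame: pd.DataFrame
    seed: int | None = None
    image_size: int | None = None

    def __post_init__(self):
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidInputError(f"manifest missing columns: {missing}")
        if self.frame["path"].duplicated().any():
            raise InvalidInputError("manifest paths must be unique")

    def __len__(self):
        return len(self.frame)


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    frame = pd.read_csv(path, dtype={"path": str, "modality": str, "label": str,
                                     "split": str, "fold": str})
    return DatasetManifest(frame=frame)


def write_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    manifest.frame.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG as a uint8 array of shape (H, W) or (H, W, 3)."""
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read image {path}: {exc}") from exc
    return arr


def resize_image(img: np.ndarray, out_w: int, out_h: int) -> np.ndarray:
    """Bilinear resize to (out_h, out_w), preserving the channel count.

    Uses the corner-aligned convention: output sample i reads input
    coordinate ``i * (n_in - 1) / (n_out - 1)``.  Constant images map to
    constant images of the same value.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise InvalidInputError("empty image")
    if out_w < 1 or out_h < 1:
        raise InvalidInputError("output dimensions must be >= 1")
    if img.ndim not in (2, 3):
        raise InvalidInputError(f"expected 2-D or 3-D image, got ndim={img.ndim}")
    return bilinear_resize(img.astype(np.float64), out_h, out_w)


def box_cox_raw(x: np.ndarray | float, lam: float) -> np.ndarray | float:
    """The Box-Cox power transform on a strictly positive domain."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise InvalidInputError("Box-Cox requires strictly positive inputs")
    if lam == 0:
        return np.log(x)
    # expm1 keeps the transform accurate (and strictly monotone) for tiny lam,
    # where x**lam - 1 would round to zero
    return np.expm1(lam * np.log(x)) / lam


def box_cox_transform(img: np.ndarray, params: BoxCoxParams) -> np.ndarray:
    """Normalize pixel intensities with a shifted Box-Cox transform.

    Intensities v (expected within [0, 255]) are mapped to the positive
    domain x = (v + epsilon_shift) / 256, power-transformed, then min-max
    rescaled to [0, 1] per image.  A constant image maps to all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise InvalidInputError("empty image")
    if img.min() < 0 or img.max() > 255:
        raise InvalidInputError("pixel intensities must lie within [0, 255]")
    x = (img + params.epsilon_shift) / 256.0
    y = box_cox_raw(x, params.lam)
    if not np.all(np.isfinite(y)):
        raise NumericError("Box-Cox transform produced non-finite values")
    lo, hi = y.min(), y.max()
    if hi > lo:
        y = (y - lo) / (hi - lo)
    else:
        y = np.zeros_like(y)
    return y


def preprocess_dataset(manifest: DatasetManifest, params: BoxCoxParams,
                       size: int, out_dir: str | os.PathLike) -> DatasetManifest:
    """Resize + Box-Cox normalize every record; write float32 .npy outputs.

    The output manifest mirrors the input record-for-record with paths
    pointing at the processed arrays.  Any unreadable input aborts the run
    with a summary listing every failing path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    failures: list[str] = []
    new_paths: list[str] = []
    for rec in manifest.frame.itertuples(index=False):
        try:
            img = load_image(rec.path)
            img = resize_image(img, size, size)
            img = box_cox_transform(np.clip(img, 0.0, 255.0), params)
        except (DataError, InvalidInputError, NumericError) as exc:
            failures.append(f"{rec.path}: {exc}")
            continue
        if img.ndim == 2:
            img = img[:, :, None]
        out_path = out_dir / (Path(rec.path).stem + ".npy")
        np.save(out_path, img.astype(np.float32))
        new_paths.append(str(out_path))
    if failures:
        raise DataError(
            f"preprocessing failed for {len(failures)} of {len(manifest)} records:\n"
            + "\n".join(failures))
    frame = manifest.frame.copy()
    frame["path"] = new_paths
    return DatasetManifest(frame=frame, seed=manifest.seed, image_size=size)


def load_processed(path: str | os.PathLike) -> np.ndarray:
    """Load a preprocessed float32 array written by :func:`preprocess_dataset`."""
    arr = np.load(path)
    if arr.ndim != 3:
        raise DataError(f"processed image {path} has unexpected shape {arr.shape}")
    return arr
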