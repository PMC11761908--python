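"""Seeded synthetic multimodal lesion-image generator.

Emulates the *shape* of a two-modality breast-lesion dataset so the whole
pipeline is testable without any external image collection:

* mammogram-like images (``MGI``): a bright lesion on a smooth
  low-frequency background with additive Gaussian noise;
* ultrasound-like images (``USI``): a bright lesion on a dark background
  with multiplicative unit-mean speckle noise.

The class contrast is morphological — the canonical visual contrast in
breast imaging: benign lesions are smooth ellipses, malignant lesions are
spiculated star-shaped masses (radial lobes superimposed on an elliptical
core).  Lesion geometry is randomized per image within class-specific
ranges; everything is driven by a single integer seed, and the same seed
reproduces identical image bytes and manifests.

Images are written as 8-bit RGB PNGs (grayscale replicated to 3 planes);
the manifest is the CSV defined in :mod:`dsunet.io_preprocess`, and the
generation config is echoed to a JSON sidecar next to it.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import InvalidInputError
from .io_preprocess import DatasetManifest, LABELS, MODALITIES, write_manifest

__all__ = [
    "LesionSpec",
    "make_lesion_mask",
    "render_modality",
    "sample_lesion_spec",
    "generate_dataset",
    "boundary_irregularity",
]

# rendering constants: background / lesion intensity levels per modality
_MGI_BG_LO, _MGI_BG_HI = 90.0, 150.0
_MGI_LESION = 80.0          # added on top of the background
_MGI_NOISE_SIGMA = 8.0      # additive Gaussian noise std (8-bit scale)
_USI_BG = 45.0
_USI_LESION = 120.0
# gamma shape k (scale 1/k gives unit mean): k = 9 emulates multi-look
# smoothed speckle and keeps the mass clipped at 255 negligible, so the
# unit-mean contract holds for rendered lesion intensities
_SPECKLE_SHAPE = 9.0
_EDGE_SIGMA = 1.0           # Gaussian blur softening the lesion boundary
_FIT_MARGIN = 2             # pixels of clearance required inside the frame


@dataclasses.dataclass
class LesionSpec:
    """Geometry of a single lesion.

    Benign lesions are plain ellipses (``spicule_amplitude == 0``);
    malignant lesions carry ``spicule_count >= 5`` radial lobes of amplitude
    ``spicule_amplitude`` pixels on top of the elliptical core.
    """

    label: str
    modality: str
    center: tuple[float, float]
    radii: tuple[float, float]
    spicule_count: int = 0
    spicule_amplitude: float = 0.0
    rotation: float = 0.0
    phase: float = 0.0

    def __post_init__(self):
        if self.label not in LABELS:
            raise InvalidInputError(f"unknown label {self.label!r}")
        if self.modality not in MODALITIES:
            raise InvalidInputError(f"unknown modality {self.modality!r}")
        if min(self.radii) <= 0:
            raise InvalidInputError("radii must be positive")
        if self.label == "benign" and self.spicule_amplitude != 0:
            raise InvalidInputError("benign lesions have spicule_amplitude == 0")
        if self.label == "malignant" and (self.spicule_count < 5
                                          or self.spicule_amplitude <= 0):
            raise InvalidInputError(
                "malignant lesions need >= 5 spicules with positive amplitude")


def make_lesion_mask(spec: LesionSpec, size: int) -> np.ndarray:
    """Render the lesion boundary as a binary mask of shape (size, size).

    The boundary is defined in polar coordinates around the lesion center:
    an ellipse radius r_e(theta) plus, for malignant lesions,
    ``amplitude * cos(count * theta + phase)``.  Identical specs produce
    identical masks.
    """
    a, b = spec.radii
    reach = max(a, b) + spec.spicule_amplitude
    r0, c0 = spec.center
    if (r0 - reach < _FIT_MARGIN or c0 - reach < _FIT_MARGIN
            or r0 + reach > size - 1 - _FIT_MARGIN
            or c0 + reach > size - 1 - _FIT_MARGIN):
        raise InvalidInputError("lesion does not fit within the image with margin")
    rr, cc = np.mgrid[0:size, 0:size]
    dy = rr - r0
    dx = cc - c0
    cos_t, sin_t = np.cos(spec.rotation), np.sin(spec.rotation)
    u = cos_t * dx + sin_t * dy
    v = -sin_t * dx + cos_t * dy
    dist = np.hypot(u, v)
    theta = np.arctan2(v, u)
    # ellipse boundary radius at angle theta (in the rotated frame)
    r_ell = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r_bound = r_ell + spec.spicule_amplitude * np.cos(
        spec.spicule_count * theta + spec.phase)
    return dist <= r_bound


def render_modality(mask: np.ndarray, modality: str,
                    rng: np.random.Generator, noise_scale: float = 1.0) -> np.ndarray:
    """Render a binary lesion mask as an 8-bit image in the given modality.

    MGI: deterministic smooth background + lesion, plus additive Gaussian
    noise scaled by ``noise_scale`` (0 gives a deterministic function of the
    mask).  USI: dark background + bright lesion, multiplied by unit-mean
    gamma speckle (shape 4); ``noise_scale`` interpolates the speckle toward
    1.  Output is clipped to [0, 255] and returned as uint8 (H, W).
    """
    mask = np.asarray(mask, dtype=bool)
    size = mask.shape[0]
    lesion = ndimage.gaussian_filter(mask.astype(np.float64), _EDGE_SIGMA)
    if modality == "MGI":
        # fixed low-frequency background: diagonal ramp plus a gentle sinusoid
        rr, cc = np.mgrid[0:size, 0:size]
        t = (rr + cc) / (2.0 * max(size - 1, 1))
        bg = _MGI_BG_LO + (_MGI_BG_HI - _MGI_BG_LO) * (
            0.5 * t + 0.25 * (1 + np.sin(2 * np.pi * (rr / size))) / 2
            + 0.25 * (1 + np.cos(2 * np.pi * (cc / size))) / 2)
        img = bg + _MGI_LESION * lesion
        img = img + noise_scale * _MGI_NOISE_SIGMA * rng.standard_normal(mask.shape)
    elif modality == "USI":
        base = _USI_BG + _USI_LESION * lesion
        speckle = rng.gamma(_SPECKLE_SHAPE, 1.0 / _SPECKLE_SHAPE, size=mask.shape)
        img = base * (1.0 + noise_scale * (speckle - 1.0))
    else:
        raise InvalidInputError(f"unknown modality {modality!r}")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def sample_lesion_spec(label: str, modality: str, size: int,
                       rng: np.random.Generator) -> LesionSpec:
    """Draw a random lesion geometry for the given class within the frame."""
    a = rng.uniform(0.13, 0.20) * size
    b = rng.uniform(0.08, 0.14) * size
    if label == "malignant":
        count = int(rng.integers(6, 12))
        amplitude = rng.uniform(0.30, 0.45) * min(a, b)
    else:
        count, amplitude = 0, 0.0
    reach = max(a, b) + amplitude + _FIT_MARGIN + 1
    center = (rng.uniform(reach, size - 1 - reach),
              rng.uniform(reach, size - 1 - reach))
    return LesionSpec(label=label, modality=modality, center=center,
                      radii=(a, b), spicule_count=count,
                      spicule_amplitude=amplitude,
                      rotation=rng.uniform(0, 2 * np.pi),
                      phase=rng.uniform(0, 2 * np.pi))


def generate_dataset(n_per_class_per_modality: int, size: int, seed: int,
                     out_dir: str | os.PathLike,
                     train_fraction: float = 0.8) -> DatasetManifest:
    """Generate a balanced, stratified, fully seeded synthetic dataset.

    Writes ``4 * n`` PNGs (2 classes x 2 modalities), a CSV manifest, and a
    JSON sidecar echoing the generation config.  The train/test split is
    stratified by class x modality.
    """
    if n_per_class_per_modality < 1:
        raise InvalidInputError("n_per_class_per_modality must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise InvalidInputError("train_fraction must lie in (0, 1)")
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    records = []
    root = np.random.SeedSequence(seed)
    n = n_per_class_per_modality
    n_train = int(round(n * train_fraction))
    cell = 0
    for modality in MODALITIES:
        for label in LABELS:
            for i in range(n):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed,
                                           spawn_key=(cell, i)))
                spec = sample_lesion_spec(label, modality, size, rng)
                mask = make_lesion_mask(spec, size)
                img = render_modality(mask, modality, rng)
                rgb = np.repeat(img[:, :, None], 3, axis=2)
                name = f"{modality}_{label}_{i:05d}.png"
                path = img_dir / name
                Image.fromarray(rgb, mode="RGB").save(path)
                records.append({
                    "path": str(path),
                    "modality": modality,
                    "label": label,
                    "split": "train" if i < n_train else "test",
                    "fold": "none",
                })
            cell += 1

    frame = pd.DataFrame.from_records(records)
    manifest = DatasetManifest(frame=frame, seed=seed, image_size=size)
    write_manifest(manifest, out_dir / "manifest.csv")
    sidecar = {
        "n_per_class_per_modality": n_per_class_per_modality,
        "size": size,
        "seed": seed,
        "train_fraction": train_fraction,
    }
    (out_dir / "manifest.json").write_text(json.dumps(sidecar, indent=2))
    return manifest


def boundary_irregularity(mask: np.ndarray) -> float:
    """Isoperimetric ratio perimeter**2 / (4 * pi * area) of a binary mask.

    1.0 for a perfect disk; strictly larger for irregular boundaries.  The
    perimeter is estimated from axis-aligned boundary transitions.
    """
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        raise InvalidInputError("empty mask")
    horiz = np.count_nonzero(mask[:, 1:] != mask[:, :-1])
    vert = np.count_nonzero(mask[1:, :] != mask[:-1, :])
    horiz += np.count_nonzero(mask[:, 0]) + np.count_nonzero(mask[:, -1])
    vert += np.count_nonzero(mask[0, :]) + np.count_nonzero(mask[-1, :])
    perimeter = horiz + vert
    # axis-aligned transition counts overestimate smooth perimeters by up to
    # 4/pi; normalize by that factor so a disk scores close to 1
    perimeter *= np.pi / 4.0
    return float(perimeter ** 2 / (4.0 * np.pi * area))
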