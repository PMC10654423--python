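"""Synthetic CT phantoms: an elliptical "liver" field carrying 0–k
hypodense "tumor" blobs with fuzzy boundaries and additive noise.

Each slice emulates the structure the segmentation task assumes — a
bright organ against a darker background with lower-intensity lesions —
without any anatomical realism: background ≈ −100 HU, liver ellipse
≈ 60 HU, tumors at liver-minus-contrast HU, Gaussian-blurred edges and
Gaussian noise.  The ground-truth mask marks the pre-blur tumor
supports, so boundary fuzziness is part of the learning problem, as it
is in real contrast CT.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi

from .errors import ConfigurationError, GenerationError

BACKGROUND_HU = -100.0
LIVER_HU = 60.0


@dataclass
class PhantomSpec:
    """Parameters of the phantom slice generator."""

    extent: int = 96
    liver_axes: Tuple[float, float] = (0.38, 0.30)   # half-axes as fractions of the extent
    tumor_count: Tuple[int, int] = (1, 3)
    tumor_radius: Tuple[float, float] = (3.0, 12.0)  # pixels
    contrast: float = 45.0                           # HU below liver
    blur_sigma: float = 1.5                          # pixels
    noise_sigma: float = 10.0                        # HU
    slices_per_volume: int = 20
    spacing: Tuple[float, float] = (0.7, 0.7)        # mm, stored in NIfTI headers
    seed: int = 0
    max_retries: int = 200

    def __post_init__(self):
        if self.extent < 32:
            raise ConfigurationError(f"extent must be >= 32, got {self.extent}")
        if self.tumor_radius[0] <= 0 or self.tumor_radius[1] < self.tumor_radius[0]:
            raise ConfigurationError(f"invalid tumor radius range {self.tumor_radius}")
        if self.tumor_count[0] < 0 or self.tumor_count[1] < self.tumor_count[0]:
            raise ConfigurationError(f"invalid tumor count range {self.tumor_count}")


def _liver_support(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.extent
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    cy = n / 2 + rng.uniform(-0.03, 0.03) * n
    cx = n / 2 + rng.uniform(-0.03, 0.03) * n
    ay = spec.liver_axes[0] * n * rng.uniform(0.9, 1.1)
    ax = spec.liver_axes[1] * n * rng.uniform(0.9, 1.1)
    theta = rng.uniform(0, np.pi)
    yr = (yy - cy) * np.cos(theta) + (xx - cx) * np.sin(theta)
    xr = -(yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)
    return (yr / ay) ** 2 + (xr / ax) ** 2 <= 1.0


def sample_tumors(spec: PhantomSpec,
                  liver: np.ndarray,
                  rng: np.random.Generator) -> List[Tuple[float, float, float]]:
    """Draw tumor placements (cy, cx, radius) fully inside the liver support.

    The tumor count is uniform over the spec's count range and each radius
    uniform over the radius range; positions are rejection-sampled.
    """
    n = spec.extent
    n_tumors = int(rng.integers(spec.tumor_count[0], spec.tumor_count[1] + 1))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    tumors = []
    for _ in range(n_tumors):
        for _ in range(spec.max_retries):
            r = rng.uniform(*spec.tumor_radius)
            cy = rng.uniform(r, n - r)
            cx = rng.uniform(r, n - r)
            blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            if blob.any() and not (blob & ~liver).any():  # fully inside the liver
                tumors.append((cy, cx, r))
                break
        else:
            raise GenerationError(
                f"could not place tumor (radius range {spec.tumor_radius}) inside the "
                f"liver ellipse after {spec.max_retries} retries; spec: {spec}"
            )
    return tumors


def generate_slice(spec: PhantomSpec,
                   rng: Optional[np.random.Generator] = None) -> Tuple[np.ndarray, np.ndarray]:
    """One phantom slice: (image in HU, binary tumor mask)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.extent
    liver = _liver_support(spec, rng)
    mask = np.zeros((n, n), dtype=np.uint8)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    for cy, cx, r in sample_tumors(spec, liver, rng):
        mask[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = 1
    image = np.full((n, n), BACKGROUND_HU, dtype=np.float32)
    image[liver] = LIVER_HU
    image[mask.astype(bool)] = LIVER_HU - spec.contrast
    if spec.blur_sigma > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape).astype(np.float32)
    return image.astype(np.float32), mask


def generate_stack(spec: PhantomSpec,
                   n_slices: int,
                   rng: Optional[np.random.Generator] = None) -> Tuple[np.ndarray, np.ndarray]:
    """A stack of independent phantom slices: (images [n,h,w], masks [n,h,w])."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    imgs, masks = zip(*(generate_slice(spec, rng) for _ in range(n_slices)))
    return np.stack(imgs), np.stack(masks)


def generate_dataset(spec: PhantomSpec,
                     n_volumes: int,
                     slices_per_volume: Optional[int] = None,
                     out_dir=None) -> "pd.DataFrame":
    """Write phantom volumes as NIfTI image/mask pairs plus a CSV manifest.

    Tumor-free slices are possible (when the count range includes 0) and
    are retained, so downstream slice selection has real work to do.
    Returns the manifest as a DataFrame; files are named
    ``vol###_img.nii.gz`` / ``vol###_mask.nii.gz``.
    """
    import nibabel as nib
    import pandas as pd

    if out_dir is None:
        raise ValueError("out_dir is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = slices_per_volume or spec.slices_per_volume
    rng = np.random.default_rng(spec.seed)
    rows = []
    affine = np.diag([spec.spacing[0], spec.spacing[1], 1.0, 1.0])
    for v in range(n_volumes):
        imgs, masks = generate_stack(spec, k, rng)
        # store as (H, W, slices) which is the axis order NIfTI viewers expect
        img_path = out / f"vol{v:03d}_img.nii.gz"
        mask_path = out / f"vol{v:03d}_mask.nii.gz"
        nib.save(nib.Nifti1Image(np.moveaxis(imgs, 0, -1), affine), str(img_path))
        nib.save(nib.Nifti1Image(np.moveaxis(masks, 0, -1).astype(np.uint8), affine), str(mask_path))
        rows.append({
            "volume_id": f"vol{v:03d}",
            "image": img_path.name,
            "mask": mask_path.name,
            "n_slices": k,
            "tumor_slices": int((masks.reshape(k, -1).sum(axis=1) > 0).sum()),
            "tumor_pixels": int(masks.sum()),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
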