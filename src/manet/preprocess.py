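"""CT intensity conditioning, augmentation and dataset splitting.

The intensity pipeline follows standard soft-tissue CT practice: clip raw
Hounsfield units to a liver window ([-150, 250] HU by default), apply
global histogram equalization (256 bins) and min–max normalize to [0, 1].
Augmentation applies one random geometric transform (vertical flip,
shift/scale/rotate) identically to image and mask, with nearest-neighbour
resampling for the mask so labels stay binary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure

from .errors import ConfigurationError

HU_WINDOW = (-150.0, 250.0)


def hu_window(image: np.ndarray, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> np.ndarray:
    """Clip Hounsfield units to the soft-tissue window [lo, hi] (idempotent)."""
    if lo >= hi:
        raise ConfigurationError(f"window bounds must satisfy lo < hi, got [{lo}, {hi}]")
    image = np.asarray(image, dtype=np.float32)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite Hounsfield values in input slice")
    return np.clip(image, lo, hi)


def equalize_and_normalize(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Global histogram equalization followed by min–max normalization to [0, 1].

    A constant slice has no contrast to redistribute and maps to all zeros.
    """
    image = np.asarray(image, dtype=np.float32)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image, dtype=np.float32)
    eq = exposure.equalize_hist(image, nbins=nbins).astype(np.float32)
    mn, mx = float(eq.min()), float(eq.max())
    if mx == mn:  # pathological single-level output
        return np.zeros_like(eq)
    return (eq - mn) / (mx - mn)


def preprocess_slice(image: np.ndarray, lo: float = HU_WINDOW[0], hi: float = HU_WINDOW[1]) -> np.ndarray:
    """Full intensity pipeline: window, equalize, normalize."""
    return equalize_and_normalize(hu_window(image, lo, hi))


@dataclass
class AugmentSpec:
    """Random geometric augmentation parameters (probabilities and limits)."""

    vflip_prob: float = 0.5
    shift_limit: float = 0.10     # fraction of the extent
    scale_limit: float = 0.10     # fractional zoom range
    rotate_limit: float = 15.0    # degrees
    ssr_prob: float = 0.5         # probability of the shift/scale/rotate transform
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("vflip_prob", "ssr_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("shift_limit", "scale_limit", "rotate_limit"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def augment(image: np.ndarray,
            mask: np.ndarray,
            spec: AugmentSpec,
            rng: Optional[np.random.Generator] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Apply one random transform identically to image and mask.

    The image is resampled bilinearly, the mask with nearest neighbour so
    its value set stays {0, 1}.  Pass an explicit ``rng`` to draw several
    augmentations from one reproducible stream.
    """
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} extents differ")
    if rng is None:
        rng = spec.rng()

    if rng.random() < spec.vflip_prob:
        image = image[::-1].copy()
        mask = mask[::-1].copy()
    if rng.random() < spec.ssr_prob:
        h, w = image.shape
        angle = rng.uniform(-spec.rotate_limit, spec.rotate_limit)
        scale = 1.0 + rng.uniform(-spec.scale_limit, spec.scale_limit)
        ty = rng.uniform(-spec.shift_limit, spec.shift_limit) * h
        tx = rng.uniform(-spec.shift_limit, spec.shift_limit) * w
        theta = np.deg2rad(angle)
        # inverse map: output -> input, rotation+zoom about the center plus shift
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        m = rot / scale
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        offset = center - m @ (center + np.array([ty, tx]))
        image = ndi.affine_transform(image, m, offset=offset, order=1, mode="constant", cval=0.0)
        mask = ndi.affine_transform(mask, m, offset=offset, order=0, mode="constant", cval=0)
    return image, mask


def select_tumor_slices(masks: Sequence[np.ndarray], min_pixels: int = 1) -> List[int]:
    """Indices of slices whose mask carries at least ``min_pixels`` tumor pixels."""
    return [i for i, m in enumerate(masks) if int(np.count_nonzero(m)) >= min_pixels]


def split_dataset(items: Sequence,
                  ratio: float = 0.8,
                  mode: str = "slice",
                  seed: int = 0,
                  volume_ids: Optional[Sequence] = None) -> Tuple[list, list]:
    """Random disjoint, exhaustive train/test split (default 4:1).

    In ``volume`` mode every item of a volume lands on one side of the
    split, so there is no leakage between training and test scans;
    ``volume_ids`` must then give one id per item.
    """
    items = list(items)
    if len(items) < 5:
        raise ValueError(f"need at least 5 items to split 4:1, got {len(items)}")
    rng = np.random.default_rng(seed)
    if mode == "slice":
        order = rng.permutation(len(items))
        n_train = int(round(ratio * len(items)))
        train_idx = set(order[:n_train].tolist())
        train = [it for i, it in enumerate(items) if i in train_idx]
        test = [it for i, it in enumerate(items) if i not in train_idx]
        return train, test
    if mode == "volume":
        if volume_ids is None or len(volume_ids) != len(items):
            raise ValueError("volume mode requires one volume id per item")
        vols = sorted(set(volume_ids), key=str)
        order = rng.permutation(len(vols))
        n_train = int(round(ratio * len(vols)))
        train_vols = {vols[i] for i in order[:n_train]}
        train = [it for it, v in zip(items, volume_ids) if v in train_vols]
        test = [it for it, v in zip(items, volume_ids) if v not in train_vols]
        return train, test
    raise ConfigurationError(f"unknown split mode {mode!r}; expected 'slice' or 'volume'")


def load_nifti_volume(path) -> Tuple[np.ndarray, Tuple[float, float]]:
    """Read a NIfTI volume as (slices, H, W) plus in-plane spacing in mm."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    # store volumes as (H, W, slices) on disk; present slices-first
    data = np.moveaxis(data, -1, 0)
    spacing = (float(zooms[0]), float(zooms[1]))
    return np.ascontiguousarray(data), spacing
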