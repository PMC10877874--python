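"""Slice preprocessing: min-max intensity normalization, tumor-covering
ROI cropping, and five-fold geometric augmentation.

Coordinate convention everywhere: row-major, 0-based indices, half-open
crop windows ``[r0, r0+size) × [c0, c0+size)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .synthetic import PhantomDataset, SlicePair

__all__ = [
    "NormalizedSlice",
    "ROISpec",
    "normalize_intensity",
    "normalize_pair",
    "crop_roi",
    "augment_five_fold",
    "AUGMENT_VARIANTS",
]

#: The five variants per training pair: identity plus 90°/180° rotations
#: and the two axis flips, applied congruently to image and mask.
AUGMENT_VARIANTS = ("orig", "rot90", "rot180", "flipud", "fliplr")

_VARIANT_FN = {
    "orig": lambda a: a,
    "rot90": lambda a: np.rot90(a, 1),
    "rot180": lambda a: np.rot90(a, 2),
    "flipud": np.flipud,
    "fliplr": np.fliplr,
}


@dataclass(frozen=True)
class NormalizedSlice:
    """An intensity image rescaled to [0, 1], with its source id."""

    image: np.ndarray
    provenance: str = ""


@dataclass(frozen=True)
class ROISpec:
    """A square crop window; ``center`` defaults to the tumor centroid."""

    size: int
    center: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be positive")


def normalize_intensity(image: np.ndarray, provenance: str = "") -> NormalizedSlice:
    """Min-max normalize: I_norm = (I - I_min) / (I_max - I_min).

    A constant image has no intensity span, so it maps to all zeros with
    a warning.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = image.min(), image.max()
    if hi == lo:
        warnings.warn(
            "constant image: normalization is undefined, returning zeros"
        )
        return NormalizedSlice(image=np.zeros_like(image), provenance=provenance)
    return NormalizedSlice(image=(image - lo) / (hi - lo), provenance=provenance)


def normalize_pair(pair: SlicePair) -> SlicePair:
    """Apply intensity normalization to a pair's image, keeping its mask."""
    norm = normalize_intensity(pair.image, provenance=pair.id)
    return replace(pair, image=norm.image)


def crop_roi(pair: SlicePair, roi: ROISpec) -> SlicePair:
    """Crop a square ROI covering the tumor, congruently on image and mask.

    With no explicit center the window is centered on the tumor centroid;
    windows are clamped to lie fully inside the image (shifted inward, not
    padded) so cropped intensities are always true pixel values.
    """
    if not pair.mask.any():
        raise ValueError("ROI must cover tumor: mask is empty")
    h, w = pair.image.shape
    size = roi.size
    if size > h or size > w:
        raise ValueError(f"ROI size {size} exceeds image shape {(h, w)}")
    if roi.center is None:
        cr, cc = ndimage.center_of_mass(pair.mask)
    else:
        cr, cc = roi.center
    r0 = int(round(cr - size / 2))
    c0 = int(round(cc - size / 2))
    r0 = min(max(r0, 0), h - size)
    c0 = min(max(c0, 0), w - size)
    return replace(
        pair,
        image=pair.image[r0 : r0 + size, c0 : c0 + size].copy(),
        mask=pair.mask[r0 : r0 + size, c0 : c0 + size].copy(),
        id=f"{pair.id}-roi{size}",
    )


def augment_five_fold(dataset: PhantomDataset) -> PhantomDataset:
    """Expand a dataset to five times its size by geometric variants.

    Each pair yields {original, rot90, rot180, vertical flip, horizontal
    flip}; intensities are untouched, only geometry changes, and image
    and mask are transformed congruently.
    """
    if len(dataset) == 0:
        raise ValueError("cannot augment an empty dataset")
    pairs = []
    for pair in dataset:
        for variant in AUGMENT_VARIANTS:
            fn = _VARIANT_FN[variant]
            pairs.append(
                replace(
                    pair,
                    image=np.ascontiguousarray(fn(pair.image)),
                    mask=np.ascontiguousarray(fn(pair.mask)),
                    id=f"{pair.id}:{variant}",
                )
            )
    return PhantomDataset(pairs=tuple(pairs))
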