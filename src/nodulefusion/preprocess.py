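"""Slice selection and two-scale preprocessing.

For each case the slices in which the nodule is visible are selected.  Two
parallel representations are then built:

* small scale — per-slice nodule patches: the tight in-slice bounding box of
  the mask plus an 8-pixel margin is cropped from the raw HU slice,
  normalised to the lung window, and zero-padded symmetrically to 224x224
  with the content centred (an extra pixel goes to the high side when the
  padding is odd);
* large scale — per-slice lung-parenchyma images: a lung mask is applied
  (non-lung pixels are floored to air before normalisation, so they map to
  exactly 0), then the slice is normalised and resized to 256x256 with
  bilinear interpolation (masks are resized nearest-neighbour so non-lung
  output pixels stay exactly 0).

Lung segmentation is a pluggable interface; the default is a morphological
fallback (threshold at -320 HU, drop border-connected air, keep the two
largest components, fill holes).  A trained segmenter can be registered
under a name and selected per run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
import warnings

import numpy as np
from scipy import ndimage
from skimage.segmentation import clear_border
from skimage.transform import resize

from .dataio import CTVolume, NoduleMask

__all__ = [
    "SliceSelection", "NodulePatchStack", "LungSliceStack",
    "select_slices", "hu_normalize", "crop_patch", "lung_slices",
    "fallback_lung_segment", "register_segmenter", "get_segmenter",
    "PATCH_SIZE", "LUNG_SIZE", "CROP_MARGIN",
]

PATCH_SIZE = 224
LUNG_SIZE = 256
CROP_MARGIN = 8
HU_WINDOW = (-1000.0, 400.0)


@dataclass
class SliceSelection:
    case_id: str
    indices: list[int]

    def __post_init__(self):
        if not self.indices:
            raise ValueError(f"no nodule-bearing slices for {self.case_id!r}")
        if any(b <= a for a, b in zip(self.indices, self.indices[1:])):
            raise ValueError("slice indices must be strictly increasing")

    def __len__(self):
        return len(self.indices)


@dataclass
class NodulePatchStack:
    case_id: str
    patches: np.ndarray           # (n, 224, 224) normalised
    crop_boxes: list[tuple[int, int, int, int, int]]  # (slice, r0, c0, h, w)


@dataclass
class LungSliceStack:
    case_id: str
    images: np.ndarray            # (n, 256, 256) normalised, non-lung == 0
    lung_masks: np.ndarray        # (n, 256, 256) binary, at output resolution


def select_slices(mask: NoduleMask) -> SliceSelection:
    """Indices of slices containing at least one mask voxel, ascending."""
    hits = np.flatnonzero(mask.mask.reshape(mask.mask.shape[0], -1).any(axis=1))
    return SliceSelection(case_id=mask.case_id, indices=[int(i) for i in hits])


def hu_normalize(image: np.ndarray) -> np.ndarray:
    """Clip to the lung window [-1000, 400] HU and map linearly to [0, 1]."""
    lo, hi = HU_WINDOW
    x = np.clip(np.asarray(image, dtype=np.float64), lo, hi)
    return (x - lo) / (hi - lo)


def crop_patch(volume: CTVolume, mask: NoduleMask, slice_index: int,
               allow_center_crop: bool = False
               ) -> tuple[np.ndarray, tuple[int, int, int, int, int]]:
    """Crop the in-slice mask bounding box (+margin), normalise, centre in a
    zero-padded 224x224 patch.

    Returns the patch and the crop box ``(slice, row0, col0, height, width)``
    of the raw sub-image taken from the slice.
    """
    sl = volume.voxels[slice_index]
    msk = mask.mask[slice_index]
    if msk.sum() == 0:
        raise ValueError(f"slice {slice_index} contains no mask voxels")
    rows = np.flatnonzero(msk.any(axis=1))
    cols = np.flatnonzero(msk.any(axis=0))
    r0 = max(int(rows[0]) - CROP_MARGIN, 0)
    r1 = min(int(rows[-1]) + 1 + CROP_MARGIN, sl.shape[0])
    c0 = max(int(cols[0]) - CROP_MARGIN, 0)
    c1 = min(int(cols[-1]) + 1 + CROP_MARGIN, sl.shape[1])
    h, w = r1 - r0, c1 - c0
    if h > PATCH_SIZE or w > PATCH_SIZE:
        if not allow_center_crop:
            raise ValueError(
                f"crop box {h}x{w} exceeds {PATCH_SIZE}; pass "
                "allow_center_crop=True to centre-crop oversized nodules"
            )
        # centre-crop the bounding box down to the patch size
        if h > PATCH_SIZE:
            extra = h - PATCH_SIZE
            r0 += extra // 2
            r1 = r0 + PATCH_SIZE
            h = PATCH_SIZE
        if w > PATCH_SIZE:
            extra = w - PATCH_SIZE
            c0 += extra // 2
            c1 = c0 + PATCH_SIZE
            w = PATCH_SIZE
    sub = hu_normalize(sl[r0:r1, c0:c1])
    patch = np.zeros((PATCH_SIZE, PATCH_SIZE))
    top = (PATCH_SIZE - h) // 2
    left = (PATCH_SIZE - w) // 2
    patch[top:top + h, left:left + w] = sub
    return patch, (int(slice_index), r0, c0, h, w)


def build_patch_stack(volume: CTVolume, mask: NoduleMask,
                      selection: SliceSelection | None = None,
                      allow_center_crop: bool = False) -> NodulePatchStack:
    if selection is None:
        selection = select_slices(mask)
    patches, boxes = [], []
    for idx in selection.indices:
        p, box = crop_patch(volume, mask, idx, allow_center_crop)
        patches.append(p)
        boxes.append(box)
    return NodulePatchStack(case_id=volume.case_id,
                            patches=np.stack(patches), crop_boxes=boxes)


# ---------------------------------------------------------------------------
# lung segmentation plugin registry
# ---------------------------------------------------------------------------

LungSegmenter = Callable[[np.ndarray], np.ndarray]
_SEGMENTERS: dict[str, LungSegmenter] = {}


def register_segmenter(name: str, fn: LungSegmenter) -> None:
    _SEGMENTERS[name] = fn


def get_segmenter(name: str = "fallback") -> LungSegmenter:
    try:
        return _SEGMENTERS[name]
    except KeyError:
        raise KeyError(
            f"unknown segmenter {name!r}; registered: {sorted(_SEGMENTERS)}"
        ) from None


def fallback_lung_segment(slice_hu: np.ndarray) -> np.ndarray:
    """Morphological lung segmentation of a single HU slice.

    Threshold at -320 HU, remove air connected to the border, keep the two
    largest interior components, fill holes.  Idempotent on its own output
    (a masked slice re-segments to the same mask).
    """
    air = np.asarray(slice_hu) < -320.0
    interior = clear_border(air)
    labels, n = ndimage.label(interior)
    if n == 0:
        return np.zeros_like(air, dtype=np.uint8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:2] + 1
    lung = np.isin(labels, keep)
    lung = ndimage.binary_fill_holes(lung)
    return lung.astype(np.uint8)


register_segmenter("fallback", fallback_lung_segment)


def lung_slices(volume: CTVolume, selection: SliceSelection,
                segmenter: LungSegmenter | str = "fallback") -> LungSliceStack:
    """Lung-masked, normalised, 256x256 images for the selected slices."""
    if isinstance(segmenter, str):
        segmenter = get_segmenter(segmenter)
    images, masks = [], []
    floor = HU_WINDOW[0]
    for idx in selection.indices:
        sl = volume.voxels[idx]
        lung = segmenter(sl).astype(bool)
        if lung.sum() == 0:
            warnings.warn(
                f"case {volume.case_id}: empty lung mask on slice {idx}; "
                "passing the whole slice through",
                stacklevel=2,
            )
            lung = np.ones_like(lung, dtype=bool)
        masked = np.where(lung, sl, floor)
        norm = hu_normalize(masked)
        img = resize(norm, (LUNG_SIZE, LUNG_SIZE), order=1, mode="edge",
                     anti_aliasing=False)
        out_mask = resize(lung.astype(float), (LUNG_SIZE, LUNG_SIZE), order=0,
                          mode="edge", anti_aliasing=False) > 0.5
        images.append(img * out_mask)
        masks.append(out_mask.astype(np.uint8))
    return LungSliceStack(case_id=volume.case_id,
                          images=np.stack(images), lung_masks=np.stack(masks))
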