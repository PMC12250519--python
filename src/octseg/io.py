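"""Reading/writing B-scan image stacks and label masks, plus the geometric
preprocessing (resize to 460x460, zero-pad to 512x512) applied before the
segmentation network.

On disk images are 8/16-bit grayscale PNG or TIFF (multi-page TIFF is one
stack); masks use the {0,255} dialect and are held in memory as {0,1}.
Intensities are normalized to [0,1] on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize as _sk_resize

__all__ = [
    "BScanImage", "ImageStack", "SegmentationMask", "MaskStack",
    "read_image_stack", "read_mask_stack", "write_image_stack",
    "write_mask_stack", "preprocess_geometry", "restore_geometry",
]

_IMG_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass
class BScanImage:
    """One grayscale OCT cross-section with intensities in [0,1]."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("B-scan must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("B-scan contains non-finite intensities")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ImageStack:
    """Ordered, co-registered B-scans forming one 3-D scan."""

    slices: list[BScanImage]

    def __post_init__(self):
        shapes = {s.pixels.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices have mixed dimensions: {sorted(shapes)}")

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def as_array(self) -> np.ndarray:
        return np.stack([s.pixels for s in self.slices])


@dataclass
class SegmentationMask:
    """Integer class labels aligned with a B-scan (0 = background)."""

    labels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("mask labels must be integers")
            self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.labels.min() < 0:
            raise ValueError("negative labels are not allowed")


@dataclass
class MaskStack:
    slices: list[SegmentationMask]

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self):
        return iter(self.slices)

    def as_array(self) -> np.ndarray:
        return np.stack([s.labels for s in self.slices])


def _numeric_key(path: Path):
    """Sort key: last integer in the stem, then the full name."""
    nums = re.findall(r"\d+", path.stem)
    return (int(nums[-1]) if nums else -1, path.name)


def _normalize(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float32) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float32) / 65535.0
    return np.clip(arr.astype(np.float32), 0.0, 1.0)


def _read_gray(path: Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # collapse accidental RGB
        arr = arr[..., 0]
    return arr


def _stack_files(path: Path) -> list[Path]:
    files = [p for p in path.iterdir()
             if p.suffix.lower() in _IMG_SUFFIXES and p.is_file()]
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF files under {path}")
    return sorted(files, key=_numeric_key)


def read_image_stack(path, pattern: str = "numeric") -> ImageStack:
    """Read a directory of PNG/TIFF slices (numeric-suffix order) or one
    multi-page TIFF into an ImageStack with intensities in [0,1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_file():
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        slices = [BScanImage(_normalize(p), {"slice_index": i})
                  for i, p in enumerate(pages)]
    else:
        files = (_stack_files(path) if pattern == "numeric"
                 else sorted(path.iterdir()))
        slices = []
        for i, f in enumerate(files):
            arr = _read_gray(f)
            if slices and arr.shape != slices[0].pixels.shape:
                raise ValueError(
                    f"dimension mismatch in {f.name}: {arr.shape} vs "
                    f"{slices[0].pixels.shape}"
                )
            slices.append(BScanImage(_normalize(arr),
                                     {"file": f.name, "slice_index": i}))
    return ImageStack(slices)


def read_mask_stack(path) -> MaskStack:
    """Read label images ({0,255} on disk) back to {0,1} masks."""
    stack = read_image_stack(path)
    out = []
    for s in stack:
        labels = (s.pixels > 0.5).astype(np.int64)
        out.append(SegmentationMask(labels, dict(s.meta)))
    return MaskStack(out)


def write_image_stack(stack: ImageStack, path, fmt: str = "png") -> None:
    path = Path(path)
    if fmt == "tiff":
        arr = (np.clip(stack.as_array(), 0, 1) * 255).round().astype(np.uint8)
        tifffile.imwrite(path, arr)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(stack):
        arr = (np.clip(s.pixels, 0, 1) * 255).round().astype(np.uint8)
        iio.imwrite(path / f"slice_{i:04d}.png", arr)


def write_mask_stack(masks: MaskStack, path, fmt: str = "png") -> None:
    """Write binary masks as 8-bit images (0 -> 0, 1 -> 255); the write/read
    round trip reproduces labels exactly."""
    if len(masks) == 0:
        raise ValueError("mask stack is empty")
    path = Path(path)
    if fmt == "tiff":
        arr = (masks.as_array() * 255).astype(np.uint8)
        tifffile.imwrite(path, arr)
        return
    path.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(masks):
        iio.imwrite(path / f"mask_{i:04d}.png",
                    (m.labels * 255).astype(np.uint8))


def preprocess_geometry(image: BScanImage, resize_to=(460, 460),
                        pad_to=(512, 512)) -> BScanImage:
    """Resize (bilinear for images, nearest for masks via ``is_mask``) and
    center in a zero-padded frame; original geometry kept in metadata."""
    return _geometry(image.pixels, image.meta, resize_to, pad_to,
                     is_mask=False)


def preprocess_mask_geometry(mask: SegmentationMask, resize_to=(460, 460),
                             pad_to=(512, 512)) -> SegmentationMask:
    out = _geometry(mask.labels.astype(np.float32), mask.meta, resize_to,
                    pad_to, is_mask=True)
    return SegmentationMask(out.pixels.astype(np.int64), out.meta)


def _geometry(pixels, meta, resize_to, pad_to, is_mask):
    rh, rw = resize_to
    ph, pw = pad_to
    if rh > ph or rw > pw:
        raise ValueError(f"pad_to {pad_to} smaller than resize_to {resize_to}")
    oh, ow = pixels.shape
    if (oh, ow) != (rh, rw):
        order = 0 if is_mask else 1
        content = _sk_resize(pixels, (rh, rw), order=order,
                             preserve_range=True, anti_aliasing=False)
    else:
        content = pixels
    top = (ph - rh) // 2
    left = (pw - rw) // 2
    out = np.zeros((ph, pw), dtype=np.float32)
    out[top:top + rh, left:left + rw] = content
    new_meta = dict(meta)
    new_meta["original_shape"] = (oh, ow)
    new_meta["resize_to"] = (rh, rw)
    new_meta["pad_offset"] = (top, left)
    return BScanImage(out, new_meta)


def restore_geometry(mask: SegmentationMask) -> SegmentationMask:
    """Invert preprocess_geometry on a predicted mask: crop the padded frame
    and nearest-neighbour resize back to the original scan dimensions."""
    meta = mask.meta
    if "original_shape" not in meta:
        return mask
    oh, ow = meta["original_shape"]
    rh, rw = meta["resize_to"]
    top, left = meta["pad_offset"]
    content = mask.labels[top:top + rh, left:left + rw]
    if (oh, ow) != (rh, rw):
        content = _sk_resize(content.astype(np.float32), (oh, ow), order=0,
                             preserve_range=True,
                             anti_aliasing=False).astype(np.int64)
    new_meta = {k: v for k, v in meta.items()
                if k not in ("original_shape", "resize_to", "pad_offset")}
    return SegmentationMask(content, new_meta)
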