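"""Image reading, segmentation rendering, and region-of-interest crops.

Conventions (fixed throughout the package): pixels are indexed 0-based,
row-major, from a top-left origin; crop rectangles are half-open.  Cluster
reporting order is stabilised by renumbering clusters 1..k by ascending
centroid luminance (0.299 R + 0.587 G + 0.114 B) — raw k-means label order
depends on the seed, so renumbering makes "cluster 1" mean the same thing
across runs and images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .kmeans import KMeansResult
from .pixels import PixelMatrix

__all__ = [
    "SegmentationMap",
    "load_image",
    "save_image",
    "render_segmentation",
    "crop_roi",
    "luminance_order",
    "CATEGORICAL_PALETTE",
]

#: High-contrast display palette for categorical label rendering (10 colors,
#: cycled if k > 10).  Chosen for mutual distinguishability, not meaning.
CATEGORICAL_PALETTE = np.array(
    [
        [230, 25, 75],
        [60, 180, 75],
        [255, 225, 25],
        [0, 130, 200],
        [245, 130, 48],
        [145, 30, 180],
        [70, 240, 240],
        [240, 50, 230],
        [128, 128, 0],
        [0, 0, 128],
    ],
    dtype=np.uint8,
)

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path, color_space: str = "rgb") -> PixelMatrix:
    """Read a raster image (PNG/TIFF/JPEG/BMP) into a PixelMatrix.

    Channels are scaled to [0, 1] by the source bit depth (8- or 16-bit
    integer, or float assumed already in [0, 1]).  Grayscale sources are
    replicated to three channels; an alpha channel is dropped.  With
    ``color_space="lab"`` pixels are converted to CIELAB and rescaled to
    [0, 1] per channel (L/100, (a+128)/255, (b+128)/255), where Euclidean
    distances are perceptually more uniform than in RGB.
    """
    path = Path(path)
    if color_space not in ("rgb", "lab"):
        raise ValueError(f"unknown color_space {color_space!r}; choose 'rgb' or 'lab'")
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"cannot read image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        img = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        img = np.clip(arr.astype(np.float64), 0.0, 1.0)
    else:
        raise ValueError(f"unsupported image bit depth/dtype {arr.dtype} in {path}")

    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    elif img.ndim == 3 and img.shape[2] == 2:  # gray + alpha
        img = np.repeat(img[:, :, :1], 3, axis=2)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")

    order = "RGB"
    if color_space == "lab":
        from skimage.color import rgb2lab

        lab = rgb2lab(img)
        img = np.empty_like(lab)
        img[..., 0] = lab[..., 0] / 100.0
        img[..., 1] = (lab[..., 1] + 128.0) / 255.0
        img[..., 2] = (lab[..., 2] + 128.0) / 255.0
        order = "LAB"
    return PixelMatrix.from_image_array(img, channel_order=order, source_path=str(path))


def save_image(image, path) -> None:
    """Write an image (float [0,1] or uint8 array, or PixelMatrix) as 8-bit."""
    if isinstance(image, PixelMatrix):
        image = image.to_image_array()
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def luminance_order(centroids: np.ndarray) -> np.ndarray:
    """Permutation of raw cluster indices by ascending centroid luminance.

    ``order[new] = old``; ties broken by raw index (stable sort).  For
    non-RGB feature spaces the same weights are applied — only stability of
    the ordering matters there, not its perceptual meaning.
    """
    c = np.asarray(centroids, dtype=np.float64)
    luma = c[:, : len(_LUMA)] @ _LUMA[: c.shape[1]]
    return np.argsort(luma, kind="stable")


@dataclass
class SegmentationMap:
    """Label image plus display palette, in reporting (luminance) order."""

    labels_2d: np.ndarray       # (H, W) ints in [0, k)
    palette: np.ndarray         # (k, 3) uint8 display colors
    mode: str                   # "centroid_color" | "categorical"
    k: int

    def __post_init__(self) -> None:
        self.labels_2d = np.asarray(self.labels_2d)
        self.palette = np.asarray(self.palette, dtype=np.uint8)
        if self.labels_2d.ndim != 2:
            raise ValueError("labels_2d must be 2-D")
        if self.labels_2d.min() < 0 or self.labels_2d.max() >= self.k:
            raise ValueError(f"labels must lie in [0, {self.k})")
        if self.palette.shape != (self.k, 3):
            raise ValueError(f"palette must have exactly {self.k} RGB entries")

    def to_rgb(self) -> np.ndarray:
        """Render as an (H, W, 3) uint8 image — a pure function of
        (labels_2d, palette)."""
        return self.palette[self.labels_2d]

    def labels_flat(self) -> np.ndarray:
        return self.labels_2d.reshape(-1)

    def write(self, stem: Path | str) -> dict[str, Path]:
        """Write ``<stem>.png`` (rendered), ``<stem>_labels.png``
        (single-channel label image) and ``<stem>_palette.json``."""
        stem = Path(stem)
        out = {
            "rendered": stem.with_suffix(".png"),
            "labels": stem.parent / f"{stem.name}_labels.png",
            "palette": stem.parent / f"{stem.name}_palette.json",
        }
        iio.imwrite(out["rendered"], self.to_rgb())
        iio.imwrite(out["labels"], self.labels_2d.astype(np.uint8))
        out["palette"].write_text(
            json.dumps(
                {
                    "mode": self.mode,
                    "k": self.k,
                    "palette": self.palette.tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        return out


def render_segmentation(
    result: KMeansResult, height: int, width: int, mode: str = "centroid_color"
) -> SegmentationMap:
    """Turn a clustering into a display image.

    ``centroid_color`` paints every pixel with its cluster's mean color
    (the classic posterised segmentation look); ``categorical`` uses a
    fixed high-contrast palette so adjacent regions are maximally distinct.
    Clusters are renumbered by ascending centroid luminance first.
    """
    if mode not in ("centroid_color", "categorical"):
        raise ValueError(
            f"unknown render mode {mode!r}; choose 'centroid_color' or 'categorical'"
        )
    n = result.labels.shape[0]
    if height * width != n:
        raise ValueError(
            f"height * width = {height * width} does not match {n} labeled pixels"
        )
    order = luminance_order(result.centroids)        # order[new] = old
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))           # inverse[old] = new
    labels_2d = inverse[result.labels].reshape(height, width)
    k = result.centroids.shape[0]
    if mode == "centroid_color":
        pal = np.clip(np.rint(result.centroids[order][:, :3] * 255.0), 0, 255).astype(
            np.uint8
        )
    else:
        pal = CATEGORICAL_PALETTE[np.arange(k) % len(CATEGORICAL_PALETTE)]
    return SegmentationMap(labels_2d=labels_2d, palette=pal, mode=mode, k=k)


def annotate_regions(seg: SegmentationMap):
    """Categorical rendering with 'Cluster i' text placed at each cluster's
    pixel centroid (1-based labels, matching the stats tables). Returns a
    PIL image."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(seg.to_rgb())
    draw = ImageDraw.Draw(img)
    h, w = seg.labels_2d.shape
    for i in range(seg.k):
        ys, xs = np.nonzero(seg.labels_2d == i)
        if len(ys) == 0:
            continue
        cy, cx = float(ys.mean()), float(xs.mean())
        text = f"Cluster {i + 1}"
        draw.text((min(cx, w - 1), min(cy, h - 1)), text, fill=(0, 0, 0), anchor="mm")
    return img


def crop_roi(data: PixelMatrix, top: int, left: int, height: int, width: int) -> PixelMatrix:
    """Half-open rectangular crop ``[top, top+height) x [left, left+width)``."""
    if not data.is_image:
        raise ValueError("crop_roi requires an image-derived PixelMatrix")
    if top < 0:
        raise ValueError(f"crop top edge {top} is above the image (must be >= 0)")
    if left < 0:
        raise ValueError(f"crop left edge {left} is outside the image (must be >= 0)")
    if height < 1 or width < 1:
        raise ValueError(f"crop extent must be positive, got {height} x {width}")
    if top + height > data.height:
        raise ValueError(
            f"crop bottom edge {top + height} exceeds image height {data.height}"
        )
    if left + width > data.width:
        raise ValueError(
            f"crop right edge {left + width} exceeds image width {data.width}"
        )
    img = data.to_image_array()
    sub = img[top : top + height, left : left + width]
    return PixelMatrix.from_image_array(
        sub, channel_order=data.channel_order, source_path=data.source_path
    )
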