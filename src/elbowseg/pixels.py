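"""Flattened per-pixel feature matrices tied to source-image geometry.

A color image of shape ``(height, width, 3)`` is clustered as a table of
``N = height * width`` feature rows, one per pixel, in row-major order:
row ``r`` holds pixel ``(r // width, r % width)``.  The same container also
carries plain point clouds (no image geometry) so the clustering core can be
exercised on synthetic blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PixelMatrix"]


@dataclass
class PixelMatrix:
    """N x D table of real-valued features, optionally image-shaped.

    Parameters
    ----------
    features : ndarray of shape (n_points, n_features)
        Finite real features.  For images these are color channels scaled
        to [0, 1] (D = 3).
    height, width : int, optional
        Source image dimensions.  When given, ``height * width`` must equal
        the number of rows and row ``r`` maps to pixel ``(r // width,
        r % width)`` (0-based, row-major, top-left origin).
    channel_order : str
        Declared channel semantics, e.g. ``"RGB"`` or ``"LAB"``.
    source_path : str, optional
        Provenance of the data, if file-derived.
    """

    features: np.ndarray
    height: int | None = None
    width: int | None = None
    channel_order: str = "RGB"
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2:
            raise ValueError(
                f"features must be 2-D (n_points, n_features), got shape "
                f"{self.features.shape}"
            )
        n, d = self.features.shape
        if n < 1 or d < 1:
            raise ValueError(f"need at least one point and one feature, got {n} x {d}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if (self.height is None) != (self.width is None):
            raise ValueError("height and width must be given together")
        if self.height is not None:
            if self.height < 1 or self.width < 1:
                raise ValueError(
                    f"image dimensions must be positive, got {self.height} x {self.width}"
                )
            if self.height * self.width != n:
                raise ValueError(
                    f"height * width = {self.height * self.width} does not match "
                    f"{n} feature rows"
                )

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def is_image(self) -> bool:
        return self.height is not None

    @classmethod
    def from_image_array(
        cls,
        image: np.ndarray,
        channel_order: str = "RGB",
        source_path: str | None = None,
    ) -> "PixelMatrix":
        """Flatten an (H, W, D) array row-major into an (H*W, D) matrix."""
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 3:
            raise ValueError(f"expected (H, W, D) array, got shape {image.shape}")
        h, w, d = image.shape
        return cls(
            features=image.reshape(h * w, d),
            height=h,
            width=w,
            channel_order=channel_order,
            source_path=source_path,
        )

    def to_image_array(self) -> np.ndarray:
        """Reshape back to (height, width, n_features); inverse of flattening."""
        if not self.is_image:
            raise ValueError("PixelMatrix has no image geometry")
        return self.features.reshape(self.height, self.width, self.n_features)
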