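"""Core data containers shared across the decoding pipeline.

An :class:`ImageSet` holds a stack of grayscale images flattened row-major
into a trial-by-pixel matrix, together with the image grid shape and
optional per-trial category labels.  A :class:`ResponseSet` holds the
paired trial-by-voxel response matrix.  Both validate their invariants at
construction so downstream numerical code can assume finite, consistent
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageSet", "ResponseSet"]


def _as_float_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class ImageSet:
    """Trial-by-pixel stimulus matrix with grid shape and optional labels.

    Parameters
    ----------
    data : (N, p) array
        One flattened image per row, row-major flattening of an ``H x W``
        grid, so ``p == H * W``.
    grid_shape : (int, int)
        Image height and width.
    labels : sequence of length N, optional
        Per-trial category identifiers (e.g. character labels).
    """

    data: np.ndarray
    grid_shape: tuple[int, int]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = _as_float_matrix(self.data, "ImageSet.data")
        h, w = (int(self.grid_shape[0]), int(self.grid_shape[1]))
        if h <= 0 or w <= 0:
            raise ValueError("grid_shape entries must be positive")
        self.grid_shape = (h, w)
        if self.data.shape[1] != h * w:
            raise ValueError(
                f"pixel count {self.data.shape[1]} does not match grid "
                f"{h}x{w} = {h * w}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.data.shape[0],):
                raise ValueError("labels must have one entry per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    def image(self, i: int) -> np.ndarray:
        """Return trial ``i`` reshaped to the H x W grid."""
        return self.data[i].reshape(self.grid_shape)

    def subset(self, idx) -> "ImageSet":
        labels = None if self.labels is None else self.labels[idx]
        return ImageSet(self.data[idx], self.grid_shape, labels)


@dataclass
class ResponseSet:
    """Trial-by-voxel response matrix with voxel identifiers."""

    data: np.ndarray
    voxel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _as_float_matrix(self.data, "ResponseSet.data")
        if self.voxel_ids is None:
            self.voxel_ids = np.array(
                [f"v{i}" for i in range(self.data.shape[1])]
            )
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if self.voxel_ids.shape != (self.data.shape[1],):
                raise ValueError("voxel_ids must have one entry per voxel")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def subset(self, idx) -> "ResponseSet":
        return ResponseSet(self.data[idx], self.voxel_ids)
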