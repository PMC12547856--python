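"""EM image preprocessing: histogram matching and offset tile grids.

Large EM frames are cut into fixed-size tiles several times, each pass with
the grid origin shifted, so that a structure truncated at one pass's tile
boundary is seen whole in another pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.exposure import match_histograms

DEFAULT_FRAME = 640


class DegenerateReferenceError(ValueError):
    """Raised when the histogram-matching reference is constant."""


def match_histogram(image: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Remap ``image`` gray levels so its histogram matches ``reference``.

    Thin wrapper around :func:`skimage.exposure.match_histograms` that
    rejects a constant (zero-contrast) reference and preserves the input
    dtype for integer images.
    """
    image = np.asarray(image)
    reference = np.asarray(reference)
    if image.size == 0 or reference.size == 0:
        raise ValueError("image and reference must be nonempty")
    if reference.min() == reference.max():
        raise DegenerateReferenceError(
            "reference image is constant; histogram matching is degenerate")
    out = match_histograms(image, reference)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out


def pass_offsets(frame: int, n_passes: int) -> list[int]:
    """Grid-origin offsets for multi-pass tiling.

    A frame of 640 px with 5 passes gives offsets [0, 128, 256, 384, 512]:
    the frame length divided by the number of passes, accumulated.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    if frame % n_passes != 0:
        valid = [k for k in range(1, frame + 1) if frame % k == 0]
        raise ValueError(
            f"frame {frame} is not divisible by n_passes {n_passes}; "
            f"valid pass counts include {valid[:12]}")
    stride = frame // n_passes
    return [k * stride for k in range(n_passes)]


@dataclass(frozen=True)
class TileGrid:
    """One pass's disjoint tiling of a padded image.

    ``pad_offsets`` pixels are prepended on the top/left; the padded image
    is then grown on the bottom/right to the next multiple of ``frame`` and
    cut into ``frame`` x ``frame`` tiles whose origins are listed row-major
    in padded coordinates.
    """

    image_shape: tuple[int, int]
    frame: int
    offset: int
    pass_index: int = 0
    padded_shape: tuple[int, int] = field(init=False)
    pad_offsets: tuple[int, int] = field(init=False)
    tile_origins: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self):
        if self.frame <= 0:
            raise ValueError("frame must be positive")
        if not 0 <= self.offset < self.frame:
            raise ValueError("offset must satisfy 0 <= offset < frame")
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be positive")
        ph = -(-(h + self.offset) // self.frame) * self.frame
        pw = -(-(w + self.offset) // self.frame) * self.frame
        origins = tuple((r, c)
                        for r in range(0, ph, self.frame)
                        for c in range(0, pw, self.frame))
        object.__setattr__(self, "padded_shape", (ph, pw))
        object.__setattr__(self, "pad_offsets", (self.offset, self.offset))
        object.__setattr__(self, "tile_origins", origins)

    @property
    def n_tiles(self) -> int:
        return len(self.tile_origins)

    def to_json(self) -> str:
        return json.dumps({
            "image_shape": list(self.image_shape), "frame": self.frame,
            "offset": self.offset, "pass_index": self.pass_index,
            "padded_shape": list(self.padded_shape),
            "pad_offsets": list(self.pad_offsets),
            "tile_origins": [list(o) for o in self.tile_origins]})

    @classmethod
    def from_json(cls, text: str) -> "TileGrid":
        d = json.loads(text)
        return cls(tuple(d["image_shape"]), d["frame"], d["offset"],
                   d.get("pass_index", 0))


def build_tile_grid(image_shape: tuple[int, int], frame: int = DEFAULT_FRAME,
                    offset: int = 0, pass_index: int = 0) -> TileGrid:
    return TileGrid(tuple(image_shape), frame, offset, pass_index)


def build_pass_grids(image_shape: tuple[int, int], frame: int = DEFAULT_FRAME,
                     n_passes: int = 5) -> list[TileGrid]:
    """One grid per pass, offsets spaced by frame / n_passes."""
    return [build_tile_grid(image_shape, frame, off, k)
            for k, off in enumerate(pass_offsets(frame, n_passes))]


def pad_image(image: np.ndarray, grid: TileGrid) -> np.ndarray:
    """Reflect-pad ``image`` to the grid's padded shape.

    Reflection (falling back to edge replication for very small images)
    avoids the hard black borders that constant padding would introduce at
    tile edges.
    """
    h, w = image.shape
    top, left = grid.pad_offsets
    bottom = grid.padded_shape[0] - h - top
    right = grid.padded_shape[1] - w - left
    pads = ((top, bottom), (left, right))
    mode = "reflect"
    if max(top, bottom) >= h or max(left, right) >= w:
        mode = "edge"  # reflect requires pad < dim
    return np.pad(image, pads, mode=mode)


def extract_tiles(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut the padded image into the grid's tiles (row-major)."""
    if tuple(image.shape) != tuple(grid.image_shape):
        raise ValueError("image shape does not match grid")
    padded = pad_image(image, grid)
    f = grid.frame
    return [padded[r:r + f, c:c + f] for r, c in grid.tile_origins]


def to_original_coords(grid: TileGrid, tile_index: int,
                       point: tuple[int, int]) -> tuple[int, int, bool]:
    """Map a point in tile coordinates back to original-image coordinates.

    Returns ``(row, col, in_image)`` where ``in_image`` is False when the
    point lands in the padding margin (coordinates may then be negative or
    beyond the image).
    """
    if not 0 <= tile_index < grid.n_tiles:
        raise IndexError(f"tile_index {tile_index} out of range "
                         f"[0, {grid.n_tiles})")
    orr, orc = grid.tile_origins[tile_index]
    r = orr + int(point[0]) - grid.pad_offsets[0]
    c = orc + int(point[1]) - grid.pad_offsets[1]
    h, w = grid.image_shape
    return r, c, (0 <= r < h and 0 <= c < w)
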