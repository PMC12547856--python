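"""Per-tile instance segmentation: backend contract, toy backend, datasets.

The detection backend is pluggable.  The deterministic classical backend
included here thresholds the phantom's fixed class intensity bands, so the
whole pipeline is testable without trained network weights.  A neural
adapter implementing the same :class:`SegmentationBackend` protocol can be
dropped in for real EM data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import imageio.v3 as iio
import numpy as np
import yaml
from scipy import ndimage as ndi
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter

from .phantom import BAND_HALFWIDTH, INTENSITY_BANDS
from .preprocess import TileGrid, extract_tiles
from .rois import CLASS_NAMES, ROISet

log = logging.getLogger(__name__)


@dataclass
class Detection:
    """One detected instance in tile coordinates."""

    class_id: int
    mask: np.ndarray            # boolean, tile-sized (or image-sized after mapping)
    confidence: float
    tile_index: int = 0
    pass_index: int = 0

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")
        if not self.mask.any():
            raise ValueError("detection mask must be nonempty")


@runtime_checkable
class SegmentationBackend(Protocol):
    """Contract every detector must satisfy."""

    name: str
    class_names: tuple[str, ...]

    def predict(self, tile: np.ndarray) -> list[Detection]:
        ...


class ToyBandBackend:
    """Deterministic classical detector for phantom images.

    Segments each class by its fixed intensity band on a median-smoothed
    tile, splits into connected components, and scores each component by
    band purity (the fraction of its raw pixels inside the band).
    """

    name = "toy"
    class_names = CLASS_NAMES

    def __init__(self, bands: dict[str, int] | None = None,
                 halfwidth: float = BAND_HALFWIDTH, min_area: int = 12):
        self.bands = dict(bands or INTENSITY_BANDS)
        self.halfwidth = float(halfwidth)
        self.min_area = int(min_area)

    def predict(self, tile: np.ndarray) -> list[Detection]:
        tile = np.asarray(tile, dtype=float)
        smoothed = ndi.median_filter(tile, size=3)
        detections: list[Detection] = []
        for class_id, name in enumerate(self.class_names):
            center = self.bands[name]
            in_band = np.abs(smoothed - center) <= self.halfwidth
            if not in_band.any():
                continue
            labels, n = ndi.label(in_band)
            for lab in range(1, n + 1):
                mask = labels == lab
                if mask.sum() < self.min_area:
                    continue
                purity = float(np.mean(np.abs(tile[mask] - center)
                                       <= self.halfwidth))
                detections.append(Detection(class_id, mask,
                                            min(1.0, purity)))
        return detections


def run_pass(image: np.ndarray, grid: TileGrid,
             backend: SegmentationBackend) -> list[Detection]:
    """Run the backend over every tile of one pass.

    Returned detections carry masks in original-image coordinates, clipped
    to the image bounds; detections falling wholly inside the padding are
    dropped.  A backend failure on a tile is logged and the tile skipped.
    """
    h, w = grid.image_shape
    tiles = extract_tiles(image, grid)
    out: list[Detection] = []
    failures = 0
    for tile_index, tile in enumerate(tiles):
        try:
            dets = backend.predict(tile)
        except Exception:  # noqa: BLE001 - backend is third-party code
            failures += 1
            log.exception("backend %s failed on tile %d of pass %d; skipped",
                          getattr(backend, "name", "?"), tile_index,
                          grid.pass_index)
            continue
        orr, orc = grid.tile_origins[tile_index]
        r0 = orr - grid.pad_offsets[0]
        c0 = orc - grid.pad_offsets[1]
        for det in dets:
            full = np.zeros((h, w), dtype=bool)
            tr0, tr1 = max(0, -r0), min(grid.frame, h - r0)
            tc0, tc1 = max(0, -c0), min(grid.frame, w - c0)
            if tr0 >= tr1 or tc0 >= tc1:
                continue
            full[r0 + tr0:r0 + tr1, c0 + tc0:c0 + tc1] = \
                det.mask[tr0:tr1, tc0:tc1]
            if not full.any():
                continue  # wholly inside padding
            out.append(Detection(det.class_id, full, det.confidence,
                                 tile_index, grid.pass_index))
    if failures:
        log.warning("pass %d: %d/%d tiles failed", grid.pass_index, failures,
                    len(tiles))
    return out


def run_passes(image: np.ndarray, grids: Sequence[TileGrid],
               backend: SegmentationBackend) -> list[Detection]:
    """All passes, concatenated (input to the multi-pass merge)."""
    detections: list[Detection] = []
    for grid in grids:
        detections.extend(run_pass(image, grid, backend))
    return detections


# ---------------------------------------------------------------------------
# polygon label export (training-data format)
# ---------------------------------------------------------------------------

def _boundary_vertices(mask: np.ndarray) -> np.ndarray:
    """External-contour pixel coordinates (row, col), corner-reduced.

    Traces the half-level iso-contour around the mask, snaps each vertex to
    the nearest mask pixel, and reduces collinear runs to polygon corners.
    Holes are discarded (single external contour per instance).
    """
    h, w = mask.shape
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2), dtype=int)
    contour = max(contours, key=len) - 1.0  # undo padding
    snapped: list[tuple[int, int]] = []
    for r, c in contour[:-1]:  # last point repeats the first
        best = None
        for rr in (int(np.floor(r)), int(np.ceil(r))):
            for cc in (int(np.floor(c)), int(np.ceil(c))):
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                    d = (r - rr) ** 2 + (c - cc) ** 2
                    if best is None or d < best[0]:
                        best = (d, (rr, cc))
        if best is not None and (not snapped or snapped[-1] != best[1]):
            snapped.append(best[1])
    if len(snapped) > 1 and snapped[0] == snapped[-1]:
        snapped.pop()
    if len(snapped) < 3:
        return np.asarray(snapped, dtype=int).reshape(-1, 2)
    poly = measure.approximate_polygon(np.asarray(snapped, dtype=float),
                                       tolerance=0.4)
    if len(poly) > 1 and np.array_equal(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly.astype(int)


def masks_to_labels(truth: ROISet, image_shape: tuple[int, int] | None = None
                    ) -> list[str]:
    """One polygon label line per instance.

    Format: ``class_id x1 y1 x2 y2 ...`` with coordinates normalized to
    [0, 1] by image width/height.  Instances whose boundary yields fewer
    than 3 vertices are skipped with a warning.
    """
    shape = tuple(image_shape or truth.image_shape)
    h, w = shape
    lines: list[str] = []
    for inst in truth:
        verts = _boundary_vertices(inst.mask)
        if len(verts) < 3:
            warnings.warn(f"instance {inst.instance_id}: fewer than 3 "
                          "boundary vertices, skipped", stacklevel=2)
            continue
        coords = []
        for r, c in verts:
            coords.append(f"{c / w:.6f}")
            coords.append(f"{r / h:.6f}")
        lines.append(" ".join([str(inst.class_id)] + coords))
    return lines


def labels_to_masks(lines: Sequence[str], image_shape: tuple[int, int]
                    ) -> ROISet:
    """Rasterize polygon label lines back into an instance set."""
    h, w = image_shape
    rois = ROISet(image_shape=tuple(image_shape))
    for line in lines:
        parts = line.split()
        if len(parts) < 7:  # class + 3 vertices minimum
            continue
        class_id = int(parts[0])
        vals = np.asarray(parts[1:], dtype=float).reshape(-1, 2)
        cols = vals[:, 0] * w
        rows = vals[:, 1] * h
        rr, cc = draw_polygon(rows, cols, shape=(h, w))
        mask = np.zeros((h, w), dtype=bool)
        mask[rr, cc] = True
        # the fill excludes edge pixels whose centers fall outside; the
        # boundary vertices themselves are mask pixels, so paint the outline
        er, ec = polygon_perimeter(rows, cols, shape=(h, w))
        mask[er, ec] = True
        if mask.any():
            rois.add(class_id, mask)
    return rois


# ---------------------------------------------------------------------------
# dataset builder
# ---------------------------------------------------------------------------

SPLIT_NAMES = ("train", "val", "test")


def build_dataset(samples: Sequence[tuple[str, np.ndarray, ROISet]],
                  out_dir: str | Path,
                  splits: tuple[float, float, float] = (0.8, 0.2, 0.0),
                  seed: int = 0) -> Path:
    """Write a train/val/test directory tree plus a dataset config file.

    ``samples`` are (name, image, truth) triples.  Images land under
    ``<split>/images``, polygon labels under ``<split>/labels``; the YAML
    config lists the split paths, the 6 class names and the class count.
    The split assignment is a seeded deterministic shuffle.
    """
    splits = tuple(float(f) for f in splits)
    if len(splits) != 3 or any(f < 0 for f in splits):
        raise ValueError("splits must be 3 nonnegative fractions")
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if splits[0] <= 0:
        raise ValueError("train fraction must be positive")
    n = len(samples)
    n_nonzero = sum(1 for f in splits if f > 0)
    if n < n_nonzero:
        raise ValueError(f"{n} samples cannot fill {n_nonzero} nonempty splits")

    counts = [int(np.floor(f * n)) for f in splits]
    i = 0
    while sum(counts) < n:  # hand leftovers to nonzero splits in order
        if splits[i % 3] > 0:
            counts[i % 3] += 1
        i += 1
    order = np.random.default_rng(seed).permutation(n)

    out = Path(out_dir)
    config: dict = {"path": str(out.resolve()), "nc": len(CLASS_NAMES),
                    "names": list(CLASS_NAMES)}
    start = 0
    for split, count in zip(SPLIT_NAMES, counts):
        if count == 0:
            continue
        img_dir = out / split / "images"
        lab_dir = out / split / "labels"
        img_dir.mkdir(parents=True, exist_ok=True)
        lab_dir.mkdir(parents=True, exist_ok=True)
        config[split] = f"{split}/images"
        for idx in order[start:start + count]:
            name, image, truth = samples[int(idx)]
            iio.imwrite(img_dir / f"{name}.png", np.asarray(image))
            (lab_dir / f"{name}.txt").write_text(
                "\n".join(masks_to_labels(truth)) + "\n")
        start += count
    config_path = out / "dataset.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return config_path
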