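"""Multi-plane ion-count stacks: dead-time correction, drift, accumulation.

A NanoSIMS measurement rasters the sample several times ("planes"); each
plane is an image of ion counts per pixel.  Before summation the planes must
be corrected for detector dead time (a nonlinear count-rate loss) and for
stage/beam drift between planes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

DEFAULT_DWELL_TIME_S = 5e-3   # 5 ms per pixel
DEFAULT_DEAD_TIME_S = 44e-9   # typical electron-multiplier dead time


class SaturationError(ValueError):
    """Observed count rate at or beyond the dead-time saturation limit."""


@dataclass
class IonStack:
    """Planes of per-pixel ion counts for one secondary-ion species."""

    species: str
    planes: np.ndarray  # (n_planes, H, W), counts >= 0
    dwell_time: float = DEFAULT_DWELL_TIME_S
    dead_time: float = DEFAULT_DEAD_TIME_S
    pixel_size_nm: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        planes = np.asarray(self.planes, dtype=float)
        if planes.ndim == 2:
            planes = planes[None]
        if planes.ndim != 3:
            raise ValueError("planes must be a (n_planes, H, W) array")
        if (planes < 0).any():
            raise ValueError("ion counts must be nonnegative")
        if not self.dwell_time > 0:
            raise ValueError("dwell_time must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be nonnegative")
        self.planes = planes

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    # -- I/O: multi-page TIFF + JSON sidecar --------------------------------

    def save(self, tiff_path: str | Path, sidecar_path: str | Path | None = None
             ) -> None:
        tifffile.imwrite(Path(tiff_path), self.planes.astype(np.float32),
                         photometric="minisblack")
        if sidecar_path is not None:
            Path(sidecar_path).write_text(json.dumps({
                "species": self.species, "dwell_time": self.dwell_time,
                "dead_time": self.dead_time,
                "pixel_size_nm": self.pixel_size_nm, "meta": self.meta,
            }, indent=2))

    @classmethod
    def load(cls, tiff_path: str | Path, sidecar_path: str | Path | None = None
             ) -> "IonStack":
        planes = tifffile.imread(Path(tiff_path)).astype(float)
        kw = {}
        if sidecar_path is not None:
            d = json.loads(Path(sidecar_path).read_text())
            kw = dict(species=d.get("species", "unknown"),
                      dwell_time=d.get("dwell_time", DEFAULT_DWELL_TIME_S),
                      dead_time=d.get("dead_time", DEFAULT_DEAD_TIME_S),
                      pixel_size_nm=d.get("pixel_size_nm"),
                      meta=d.get("meta", {}))
        else:
            kw = dict(species="unknown")
        return cls(planes=planes, **kw)


def dead_time_correct(stack: IonStack) -> IonStack:
    """Invert dead-time count losses: N_true = N_obs / (1 - N_obs * tau/T).

    ``tau`` is the detector dead time and ``T`` the per-pixel dwell time.
    Counts at or beyond saturation (denominator <= 0) raise
    :class:`SaturationError`.  With zero dead time the stack is returned
    unchanged.
    """
    if stack.dead_time == 0:
        return stack
    ratio = stack.dead_time / stack.dwell_time
    denom = 1.0 - stack.planes * ratio
    if (denom <= 0).any():
        idx = tuple(int(i) for i in np.unravel_index(
            int(np.argmax(stack.planes)), stack.planes.shape))
        raise SaturationError(
            f"count {stack.planes[idx]:g} at plane/row/col {idx} saturates "
            f"the detector (dead_time={stack.dead_time:g}s, "
            f"dwell_time={stack.dwell_time:g}s)")
    corrected = stack.planes / denom
    return replace(stack, planes=corrected,
                   meta={**stack.meta, "dead_time_corrected": True})


def estimate_plane_drift(stack: IonStack, reference_plane: int = 0
                         ) -> list[tuple[int, int]]:
    """Integer (drow, dcol) drift of each plane relative to the reference.

    The returned drift ``d`` satisfies ``plane ~ shift(reference, d)``;
    phase correlation locates the peak, rounded to whole pixels.  Flat
    planes get drift (0, 0) with a warning.
    """
    if stack.n_planes < 2:
        return [(0, 0)] * stack.n_planes
    if not 0 <= reference_plane < stack.n_planes:
        raise IndexError("reference_plane out of range")
    ref = stack.planes[reference_plane]
    drifts: list[tuple[int, int]] = []
    for i in range(stack.n_planes):
        if i == reference_plane:
            drifts.append((0, 0))
            continue
        plane = stack.planes[i]
        if plane.std() == 0 or ref.std() == 0:
            warnings.warn(f"plane {i}: zero variance, assuming no drift",
                          stacklevel=2)
            drifts.append((0, 0))
            continue
        shift, _, _ = phase_cross_correlation(ref, plane, normalization=None)
        drifts.append((-int(round(shift[0])), -int(round(shift[1]))))
    return drifts


def accumulate(stack: IonStack, drifts: list[tuple[int, int]] | None = None
               ) -> np.ma.MaskedArray:
    """Drift-align the planes and sum them into one count image.

    Each plane is shifted back by its drift vector before summation.  The
    shift wraps at the frame edge, so pixels whose content wrapped in (and
    therefore lack genuine full-plane coverage) are masked out.
    """
    if drifts is None:
        drifts = estimate_plane_drift(stack)
    if len(drifts) != stack.n_planes:
        raise ValueError("need one drift vector per plane")
    h, w = stack.frame_shape
    accum = np.zeros((h, w), dtype=float)
    valid = np.ones((h, w), dtype=bool)
    for plane, (dr, dc) in zip(stack.planes, drifts):
        if abs(dr) >= h or abs(dc) >= w:
            raise ValueError(f"drift ({dr}, {dc}) exceeds frame {h}x{w}")
        accum += np.roll(plane, (-dr, -dc), axis=(0, 1))
        if dr > 0:
            valid[h - dr:, :] = False
        elif dr < 0:
            valid[:-dr, :] = False
        if dc > 0:
            valid[:, w - dc:] = False
        elif dc < 0:
            valid[:, :-dc] = False
    return np.ma.MaskedArray(accum, mask=~valid)


def correct_stack(stack: IonStack, reference_plane: int = 0
                  ) -> tuple[np.ma.MaskedArray, list[tuple[int, int]]]:
    """Dead-time correct, estimate drift, accumulate.  Returns (image, drifts)."""
    corrected = dead_time_correct(stack)
    drifts = estimate_plane_drift(corrected, reference_plane)
    return accumulate(corrected, drifts), drifts
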