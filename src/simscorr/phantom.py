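"""Synthetic EM / ion-image phantoms with known ground truth.

Generates EM-like textured organelle images with instance masks, plus
matched Poisson ion-count stacks whose per-class isotope enrichment decays
exponentially with a known half-life, under a known EM->SIMS similarity
transform, known inter-plane drift and optional dead-time distortion.
Every downstream stage of the pipeline is testable against these phantoms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import ellipse as draw_ellipse
from skimage.morphology import dilation, disk as disk_footprint

from .register import SimilarityTransform, warp_image
from .rois import CLASS_NAMES, ROISet
from .sims import DEFAULT_DEAD_TIME_S, DEFAULT_DWELL_TIME_S, IonStack

#: Mean gray level of each organelle class in the EM phantom.  The bands are
#: separated widely enough that the toy segmentation backend can classify by
#: intensity alone; this mapping is fixed so the backend is parameter-free.
INTENSITY_BANDS: dict[str, int] = {
    "nucleolus": 30,
    "mitochondria": 62,
    "ER": 94,
    "Golgi": 170,
    "vacuoles": 205,
    "vesicles": 240,
}
BAND_HALFWIDTH = 14
BACKGROUND_LEVEL = 132

#: Relative CN- yield per class (protein-dense structures emit more CN).
#: Nucleoli are boosted strongly so they serve as auto-registration anchors.
CN14_CLASS_GAIN: dict[str, float] = {
    "nucleolus": 2.5,
    "mitochondria": 1.3,
    "ER": 1.2,
    "Golgi": 1.3,
    "vacuoles": 1.1,
    "vesicles": 1.2,
}

#: Natural 15N/14N abundance ratio, used as the unlabeled baseline.
NATURAL_ABUNDANCE = 0.0037


class PlacementError(RuntimeError):
    """Image too small / too crowded to place the requested instances."""


@dataclass(frozen=True)
class ClassShape:
    """Ellipse geometry for one class: semi-axis range and elongation."""

    radius: tuple[float, float]       # minor semi-axis range, px
    aspect: tuple[float, float] = (1.0, 1.0)
    texture_amplitude: float = 3.0

    def __post_init__(self):
        if min(*self.radius, *self.aspect) <= 0:
            raise ValueError("shape parameters must be positive")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be nonnegative")


DEFAULT_SHAPES: dict[str, ClassShape] = {
    "nucleolus": ClassShape((24.0, 38.0), (1.0, 1.3)),
    "mitochondria": ClassShape((6.0, 10.0), (2.0, 3.0)),
    "ER": ClassShape((3.5, 5.0), (3.5, 5.0)),
    "Golgi": ClassShape((5.0, 8.0), (2.2, 3.2)),
    "vacuoles": ClassShape((10.0, 16.0)),
    "vesicles": ClassShape((5.0, 8.0)),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one EM phantom frame."""

    image_shape: tuple[int, int] = (512, 512)
    counts: dict = field(default_factory=dict)  # class -> int or (lo, hi)
    shapes: dict = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    classes: tuple[str, ...] = CLASS_NAMES
    background: int = BACKGROUND_LEVEL
    noise_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if len(self.classes) != 6:
            raise ValueError("exactly six organelle classes are required")
        if set(self.classes) != set(CLASS_NAMES):
            raise ValueError(f"classes must match {CLASS_NAMES}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name, shape in self.shapes.items():
            if name not in self.classes:
                raise ValueError(f"unknown class in shapes: {name!r}")
            if not isinstance(shape, ClassShape):
                raise TypeError("shapes values must be ClassShape")

    def count_range(self, name: str) -> tuple[int, int]:
        val = self.counts.get(name, 0)
        if np.isscalar(val):
            return int(val), int(val)
        lo, hi = val
        return int(lo), int(hi)


def make_em_phantom(spec: PhantomSpec) -> tuple[np.ndarray, ROISet]:
    """Render the EM phantom and its ground-truth instance set.

    Instances are mutually disjoint ellipses (with a 2 px separation margin)
    filled with their class intensity band plus Gaussian texture.  Identical
    spec and seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    truth = ROISet(image_shape=(h, w), class_names=spec.classes)
    occupied = np.zeros((h, w), dtype=bool)
    margin_fp = disk_footprint(2)

    image = np.full((h, w), float(spec.background))
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=(h, w))

    for class_id, name in enumerate(spec.classes):
        lo, hi = spec.count_range(name)
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        shape = spec.shapes.get(name, DEFAULT_SHAPES[name])
        for _ in range(n):
            mask = _place_instance(rng, (h, w), shape, occupied, name)
            occupied |= dilation(mask, margin_fp)
            level = float(INTENSITY_BANDS[name])
            tex = rng.normal(0.0, shape.texture_amplitude, size=int(mask.sum()))
            image[mask] = level + tex
            truth.add(class_id, mask)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8), truth


def _place_instance(rng: np.random.Generator, frame: tuple[int, int],
                    shape: ClassShape, occupied: np.ndarray, name: str,
                    max_tries: int = 1000) -> np.ndarray:
    h, w = frame
    for _ in range(max_tries):
        r_minor = rng.uniform(*shape.radius)
        r_major = r_minor * rng.uniform(*shape.aspect)
        theta = rng.uniform(0, np.pi)
        pad = int(np.ceil(r_major)) + 3
        if 2 * pad >= h or 2 * pad >= w:
            continue
        cr = rng.uniform(pad, h - pad)
        cc = rng.uniform(pad, w - pad)
        rr, cc_idx = draw_ellipse(cr, cc, r_minor, r_major, shape=frame,
                                  rotation=theta)
        if rr.size < 4:
            continue
        mask = np.zeros(frame, dtype=bool)
        mask[rr, cc_idx] = True
        if not (mask & occupied).any():
            return mask
    raise PlacementError(
        f"could not place a {name!r} instance after {max_tries} tries: "
        f"image {h}x{w} too small or too crowded")


# ---------------------------------------------------------------------------
# matched ion-count stacks
# ---------------------------------------------------------------------------

def decay_ratio(t: float, t_half: float, e0: float,
                e_nat: float = NATURAL_ABUNDANCE) -> float:
    """Expected 15N/14N ratio after chase time ``t``: first-order decay of
    the labeled fraction toward the natural-abundance baseline."""
    return e_nat + (e0 - e_nat) * 2.0 ** (-t / t_half)


@dataclass(frozen=True)
class IonPhantomSpec:
    """Recipe for ion stacks matched to an EM phantom truth."""

    sims_shape: tuple[int, int] = (256, 256)
    chase_times: tuple[float, ...] = (0.0, 12.0, 24.0, 48.0, 96.0)
    half_lives: dict = field(default_factory=dict)  # class name -> hours
    e0: float = 0.05
    e_nat: float = NATURAL_ABUNDANCE
    mean_cn14: float = 50.0        # expected counts / pixel / plane (background)
    cn14_gain: dict = field(default_factory=lambda: dict(CN14_CLASS_GAIN))
    n_planes: int = 4
    drift: tuple[tuple[int, int], ...] | None = None  # per-plane (drow, dcol)
    em_to_sims: SimilarityTransform = field(
        default_factory=SimilarityTransform.identity)
    dwell_time: float = DEFAULT_DWELL_TIME_S
    dead_time: float = 0.0
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        for name, th in self.half_lives.items():
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown class in half_lives: {name!r}")
            if not th > 0:
                raise ValueError("half-lives must be positive")
        if not 0 <= self.e_nat < 1 or not self.e_nat <= self.e0 < 1:
            raise ValueError("require 0 <= e_nat <= e0 < 1")
        ct = np.asarray(self.chase_times, dtype=float)
        if (ct < 0).any() or (np.diff(ct) <= 0).any():
            raise ValueError("chase_times must be nonnegative and strictly "
                             "increasing")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if self.mean_cn14 <= 0:
            raise ValueError("mean_cn14 must be positive")
        if self.drift is not None:
            if len(self.drift) != self.n_planes:
                raise ValueError("need one drift vector per plane")
            h, w = self.sims_shape
            for dr, dc in self.drift:
                if abs(int(dr)) >= h or abs(int(dc)) >= w:
                    raise ValueError(f"drift ({dr}, {dc}) larger than the "
                                     f"{h}x{w} SIMS frame")

    def plane_drift(self) -> list[tuple[int, int]]:
        if self.drift is None:
            return [(0, 0)] * self.n_planes
        return [(int(dr), int(dc)) for dr, dc in self.drift]


def expected_sims_maps(spec: IonPhantomSpec, truth: ROISet,
                       chase_time: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free per-plane expectation images (cn14, cn15) in the SIMS frame."""
    ratio_em = np.full(truth.image_shape, spec.e_nat)
    gain_em = np.ones(truth.image_shape)
    for inst in truth:
        name = truth.class_name(inst.class_id)
        t_half = spec.half_lives.get(name)
        if t_half is not None:
            ratio_em[inst.mask] = decay_ratio(chase_time, t_half, spec.e0,
                                              spec.e_nat)
        gain_em[inst.mask] = spec.cn14_gain.get(name, 1.0)
    # nearest-neighbour warp keeps the piecewise-constant maps exact
    ratio = warp_image(ratio_em, spec.em_to_sims, spec.sims_shape, order=0)
    gain = warp_image(gain_em, spec.em_to_sims, spec.sims_shape, order=0)
    # outside the warped EM footprint, fall back to plain background
    outside = gain == 0.0
    gain[outside] = 1.0
    ratio[outside] = spec.e_nat
    cn14 = spec.mean_cn14 * gain
    cn15 = ratio * cn14
    return cn14, cn15


def make_ion_stack(spec: IonPhantomSpec, truth: ROISet, chase_time: float
                   ) -> tuple[IonStack, IonStack]:
    """Simulate the (cn14, cn15) ion stacks for one chase time point.

    Each plane is the expectation image shifted by that plane's drift
    vector (wrapping at the frame edge), Poisson-sampled unless noiseless
    mode is requested, then deflated by the inverse dead-time correction so
    that :func:`simscorr.sims.dead_time_correct` recovers the counts
    exactly.
    """
    cn14_exp, cn15_exp = expected_sims_maps(spec, truth, chase_time)
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, int(round(chase_time * 1000))]))
    drifts = spec.plane_drift()

    stacks = []
    for species, exp in (("12C14N", cn14_exp), ("12C15N", cn15_exp)):
        planes = np.empty((spec.n_planes, *spec.sims_shape), dtype=float)
        for p, (dr, dc) in enumerate(drifts):
            shifted = np.roll(exp, (dr, dc), axis=(0, 1))
            planes[p] = rng.poisson(shifted) if spec.poisson else shifted
        if spec.dead_time > 0:
            r = spec.dead_time / spec.dwell_time
            planes = planes / (1.0 + planes * r)  # exact inverse of correction
        stacks.append(IonStack(
            species=species, planes=planes, dwell_time=spec.dwell_time,
            dead_time=spec.dead_time,
            meta={"chase_time_h": float(chase_time), "seed": spec.seed,
                  "drift": [list(d) for d in drifts],
                  "em_to_sims": json.loads(spec.em_to_sims.to_json()),
                  "poisson": spec.poisson}))
    return stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# on-disk study layout
# ---------------------------------------------------------------------------

def make_study(out_dir: str | Path,
               em_spec: PhantomSpec,
               ion_spec: IonPhantomSpec,
               frame: int = 320,
               n_passes: int = 5,
               group: str = "phantom",
               anchor_points: np.ndarray | None = None) -> Path:
    """Write a complete multi-timepoint study ready for the pipeline.

    One EM phantom is generated per chase time (layout seeds derived from
    ``em_spec.seed``), each with matched ion stacks, an anchor CSV derived
    from the known EM->SIMS transform, and a pipeline config.  Returns the
    path of the study YAML.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h, w = em_spec.image_shape
    if anchor_points is None:
        m_r, m_c = h // 8, w // 8
        anchor_points = np.array([
            [m_c, m_r], [w - m_c, m_r], [w - m_c, h - m_r], [m_c, h - m_r]],
            dtype=float)
    anchors = np.column_stack([anchor_points,
                               ion_spec.em_to_sims.apply(anchor_points)])

    samples = []
    for i, t in enumerate(ion_spec.chase_times):
        stem = f"t{i:02d}"
        spec_i = PhantomSpec(
            image_shape=em_spec.image_shape, counts=em_spec.counts,
            shapes=em_spec.shapes, classes=em_spec.classes,
            background=em_spec.background, noise_sd=em_spec.noise_sd,
            seed=em_spec.seed + 1000 * i)
        image, truth = make_em_phantom(spec_i)
        save_phantom(out, image, truth, stem=stem)
        cn14, cn15 = make_ion_stack(ion_spec, truth, t)
        save_ion_pair(out, cn14, cn15, stem=stem)
        anchor_csv = out / f"{stem}_anchors.csv"
        pd.DataFrame(anchors, columns=["em_x", "em_y", "sims_x", "sims_y"]
                     ).to_csv(anchor_csv, index=False)
        samples.append({
            "image_id": stem, "em_image": f"{stem}_em.tif",
            "cn14": f"{stem}_cn14.tif", "cn15": f"{stem}_cn15.tif",
            "sidecar": f"{stem}_meta.json",
            "anchors": anchor_csv.name, "chase_time_h": float(t),
            "group": group})

    config = {
        "frame": frame, "n_passes": n_passes, "backend": "toy",
        "registration_mode": "anchors", "baseline": ion_spec.e_nat,
        "seed": em_spec.seed, "samples": samples}
    study_yaml = out / "study.yaml"
    study_yaml.write_text(yaml.safe_dump(config, sort_keys=False))
    return study_yaml


def save_phantom(out_dir: str | Path, image: np.ndarray, truth: ROISet,
                 stem: str = "phantom") -> dict[str, Path]:
    """Write EM TIFF + indexed-PNG truth + CSV instance table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "em": out / f"{stem}_em.tif",
        "labels": out / f"{stem}_truth.png",
        "table": out / f"{stem}_truth.csv",
    }
    tifffile.imwrite(paths["em"], image)
    truth.save(paths["labels"], paths["table"])
    return paths


def save_ion_pair(out_dir: str | Path, cn14: IonStack, cn15: IonStack,
                  stem: str = "sims") -> dict[str, Path]:
    """Write both species stacks as multi-page TIFFs plus one JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cn14": out / f"{stem}_cn14.tif",
        "cn15": out / f"{stem}_cn15.tif",
        "sidecar": out / f"{stem}_meta.json",
    }
    cn14.save(paths["cn14"])
    cn15.save(paths["cn15"])
    paths["sidecar"].write_text(json.dumps({
        "species": [cn14.species, cn15.species],
        "dwell_time": cn14.dwell_time, "dead_time": cn14.dead_time,
        "meta": cn14.meta}, indent=2))
    return paths
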