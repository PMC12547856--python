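"""End-to-end study orchestration from a single YAML config.

Stages per sample: histogram match -> multi-pass segmentation -> merge ->
morphological filter -> EM/SIMS registration -> ion-stack corrections ->
ROI warp -> enrichment extraction.  Across samples: per-class decay fits by
group and pairwise group comparisons.  A manifest records the config hash,
package versions, seeds and per-stage timings for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .assemble import DEFAULT_FILTER_RULES, merge_passes, morphological_filter
from .metrics import MAP_THRESHOLDS  # noqa: F401  (re-export convenience)
from .preprocess import build_pass_grids, match_histogram, pass_offsets
from .register import AnchorSet, SimilarityTransform, auto_anchor_nuclei, \
    fit_similarity, warp_mask
from .rois import CLASS_NAMES, ROISet
from .segment import ToyBandBackend, run_passes
from .sims import IonStack, correct_stack
from .turnover import DEFAULT_BASELINE, compare_groups, fit_decay, \
    measurements_to_frame, roi_enrichment

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, sample: str | None, cause: Exception):
        self.stage = stage
        self.sample = sample
        super().__init__(f"stage {stage!r}"
                         + (f" (sample {sample})" if sample else "")
                         + f" failed: {cause}")


@dataclass
class SampleConfig:
    image_id: str
    em_image: str
    cn14: str
    cn15: str
    chase_time_h: float
    group: str = "default"
    sidecar: str | None = None
    anchors: str | None = None      # CSV of anchor pairs
    transform: str | None = None    # precomputed transform JSON

    @classmethod
    def from_dict(cls, d: dict) -> "SampleConfig":
        return cls(**{k: d[k] for k in d if k in cls.__dataclass_fields__})


@dataclass
class PipelineConfig:
    samples: list[SampleConfig]
    reference: str | None = None
    frame: int = 640
    n_passes: int = 5
    backend: str = "toy"
    iou_link: float = 0.5
    min_support: int = 2
    filter_rules: dict = field(default_factory=lambda: dict(DEFAULT_FILTER_RULES))
    registration_mode: str = "anchors"  # anchors | auto | transform
    baseline: float = DEFAULT_BASELINE
    fix_baseline: bool = True
    seed: int = 0

    def validate(self, base: Path | None = None) -> None:
        pass_offsets(self.frame, self.n_passes)  # raises on bad combination
        if self.backend != "toy":
            raise ValueError(f"unknown backend {self.backend!r}; only the "
                             "'toy' backend ships with this package")
        if self.registration_mode not in ("anchors", "auto", "transform"):
            raise ValueError("registration_mode must be anchors, auto or "
                             "transform")
        if not self.samples:
            raise ValueError("config lists no samples")
        root = base or Path(".")
        for s in self.samples:
            for attr in ("em_image", "cn14", "cn15", "anchors", "transform",
                         "sidecar"):
                p = getattr(s, attr)
                if p is not None and not (root / p).exists():
                    raise FileNotFoundError(
                        f"sample {s.image_id}: {attr} file not found: {p}")
        if self.reference is not None and not (root / self.reference).exists():
            raise FileNotFoundError(f"reference image not found: "
                                    f"{self.reference}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        samples = [SampleConfig.from_dict(s) for s in d.pop("samples", [])]
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(samples=samples, **known)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps({
        "samples": [vars(s) for s in config.samples],
        **{k: v for k, v in vars(config).items() if k != "samples"}},
        sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _resolve_transform(config: PipelineConfig, sample: SampleConfig,
                       base: Path, em: np.ndarray, cn14_img: np.ndarray
                       ) -> tuple[SimilarityTransform, float]:
    if config.registration_mode == "transform" or sample.transform:
        tf = SimilarityTransform.from_json(
            (base / sample.transform).read_text())
        return tf, 0.0
    if config.registration_mode == "auto":
        anchors = auto_anchor_nuclei(em, cn14_img)
    else:
        if not sample.anchors:
            raise ValueError(f"sample {sample.image_id}: registration_mode "
                             "'anchors' requires an anchors CSV")
        anchors = AnchorSet.from_csv(base / sample.anchors)
    return fit_similarity(anchors)


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 base_dir: str | Path | None = None) -> Path:
    """Execute every stage and write all artifacts under ``out_dir``."""
    base = Path(base_dir) if base_dir else Path(".")
    config.validate(base)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config_hash": _config_hash(config),
        "simscorr_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "offsets": pass_offsets(config.frame, config.n_passes),
        "samples": [],
    }
    backend = ToyBandBackend()
    reference = (tifffile.imread(base / config.reference)
                 if config.reference else None)

    all_measurements: list[pd.DataFrame] = []
    for sample in config.samples:
        t0 = time.perf_counter()
        stage = "load"
        try:
            em = tifffile.imread(base / sample.em_image)
            cn14 = IonStack.load(base / sample.cn14, sample.sidecar and
                                 base / sample.sidecar)
            cn15 = IonStack.load(base / sample.cn15, sample.sidecar and
                                 base / sample.sidecar)

            stage = "preprocess"
            matched = (match_histogram(em, reference)
                       if reference is not None else em)

            stage = "segment"
            grids = build_pass_grids(matched.shape, config.frame,
                                     config.n_passes)
            detections = run_passes(matched, grids, backend)

            stage = "assemble"
            rois = merge_passes(detections, matched.shape, config.n_passes,
                                config.iou_link, config.min_support)
            rois, removed = morphological_filter(rois, config.filter_rules)

            stage = "sims_correct"
            cn14_img, drifts14 = correct_stack(cn14)
            cn15_img, _ = correct_stack(cn15)

            stage = "register"
            tform, rms = _resolve_transform(config, sample, base, matched,
                                            np.ma.filled(cn14_img, 0.0))

            stage = "warp"
            sims_rois = ROISet(image_shape=cn14_img.shape,
                               class_names=rois.class_names)
            for inst in rois:
                with warnings.catch_warnings():
                    # instances outside the SIMS field of view are expected
                    # and silently dropped here
                    warnings.filterwarnings(
                        "ignore", message="warped mask is empty")
                    warped = warp_mask(inst.mask, tform, cn14_img.shape)
                if warped.any():
                    sims_rois.add(inst.class_id, warped,
                                  support=inst.support,
                                  confidence=inst.confidence)

            stage = "quantify"
            measurements = roi_enrichment(sims_rois, cn14_img, cn15_img,
                                          chase_time=sample.chase_time_h)
            frame = measurements_to_frame(measurements, CLASS_NAMES)
            frame.insert(0, "image_id", sample.image_id)
            frame.insert(1, "group", sample.group)
            all_measurements.append(frame)

            stage = "write"
            sdir = out / sample.image_id
            sdir.mkdir(exist_ok=True)
            rois.save(sdir / "rois_em.png", sdir / "rois_em.csv")
            sims_rois.save(sdir / "rois_sims.png", sdir / "rois_sims.csv")
            tifffile.imwrite(sdir / "cn14_accumulated.tif",
                             np.ma.filled(cn14_img, 0.0).astype(np.float32))
            tifffile.imwrite(sdir / "cn15_accumulated.tif",
                             np.ma.filled(cn15_img, 0.0).astype(np.float32))
            (sdir / "transform.json").write_text(tform.to_json())
            frame.to_csv(sdir / "measurements.csv", index=False)
            manifest["samples"].append({
                "image_id": sample.image_id, "group": sample.group,
                "chase_time_h": sample.chase_time_h,
                "n_detections": len(detections), "n_rois": len(rois),
                "n_removed": len(removed), "drift": drifts14,
                "registration_rms_px": rms,
                "transform": json.loads(tform.to_json())})
        except Exception as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, sample.image_id, exc) from exc
        timings[sample.image_id] = time.perf_counter() - t0

    stage = "fit"
    try:
        table = (pd.concat(all_measurements, ignore_index=True)
                 if all_measurements else measurements_to_frame([]))
        table.to_csv(out / "measurements.csv", index=False)
        fits = []
        for (group, class_id), sub in table.groupby(["group", "class_id"]):
            if sub["chase_time_h"].nunique() < 3:
                continue
            fit = fit_decay((sub["chase_time_h"].to_numpy(),
                             sub["ratio"].to_numpy()),
                            fix_baseline=config.fix_baseline,
                            baseline=config.baseline, class_id=int(class_id))
            fits.append({"group": group,
                         "class_name": CLASS_NAMES[int(class_id)],
                         **fit.as_dict()})
        pd.DataFrame(fits).to_csv(out / "fits.csv", index=False)

        stage = "compare"
        comparisons = []
        groups = sorted(table["group"].unique()) if len(table) else []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                for class_id in sorted(table["class_id"].unique()):
                    a = table.query("group == @ga and class_id == @class_id")
                    b = table.query("group == @gb and class_id == @class_id")
                    for t in sorted(set(a["chase_time_h"]) &
                                    set(b["chase_time_h"])):
                        va = a.loc[a.chase_time_h == t, "ratio"]
                        vb = b.loc[b.chase_time_h == t, "ratio"]
                        if len(va) < 2 or len(vb) < 2:
                            continue
                        cmp = compare_groups(va, vb)
                        comparisons.append({
                            "group_a": ga, "group_b": gb,
                            "class_name": CLASS_NAMES[int(class_id)],
                            "chase_time_h": t, "t": cmp.t_statistic,
                            "p": cmp.p_value, "stars": cmp.stars})
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, None, exc) from exc

    manifest["timings_s"] = timings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out
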