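"""Labeled organelle instances for one image frame.

An :class:`ROISet` holds instance masks in image coordinates together with
their class assignment, merge support and confidence.  It is the common
currency between the phantom generator (ground truth), the multi-pass mask
assembly and the evaluation metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Canonical organelle classes, in class-id order.
CLASS_NAMES = ("nucleolus", "mitochondria", "ER", "Golgi", "vacuoles", "vesicles")


@dataclass
class ROIInstance:
    """One organelle instance: full-frame boolean mask plus bookkeeping."""

    instance_id: int
    class_id: int
    mask: np.ndarray
    support: int = 1
    confidence: float = 1.0

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class ROISet:
    """A set of labeled instances sharing one image frame."""

    image_shape: tuple[int, int]
    instances: list[ROIInstance] = field(default_factory=list)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def add(self, class_id: int, mask: np.ndarray, support: int = 1,
            confidence: float = 1.0) -> ROIInstance:
        if mask.shape != tuple(self.image_shape):
            raise ValueError(
                f"mask shape {mask.shape} != image shape {self.image_shape}")
        inst = ROIInstance(len(self.instances) + 1, int(class_id),
                           mask.astype(bool), support, float(confidence))
        self.instances.append(inst)
        return inst

    def by_class(self, class_id: int) -> list[ROIInstance]:
        return [i for i in self.instances if i.class_id == class_id]

    def class_name(self, class_id: int) -> str:
        return self.class_names[class_id]

    # ------------------------------------------------------------------
    # serialization: indexed PNG (pixel value = instance id) + CSV table
    # ------------------------------------------------------------------

    def to_label_image(self) -> np.ndarray:
        """Instance-id image (uint16).  Overlapping instances: later id wins."""
        lab = np.zeros(self.image_shape, dtype=np.uint16)
        for inst in self.instances:
            lab[inst.mask] = inst.instance_id
        return lab

    def to_table(self) -> pd.DataFrame:
        rows = []
        for inst in self.instances:
            r, c = inst.centroid if inst.area else (np.nan, np.nan)
            rows.append({
                "instance_id": inst.instance_id,
                "class_id": inst.class_id,
                "class_name": self.class_name(inst.class_id),
                "area_px": inst.area,
                "centroid_row": r,
                "centroid_col": c,
                "support": inst.support,
                "confidence": inst.confidence,
            })
        return pd.DataFrame(rows, columns=[
            "instance_id", "class_id", "class_name", "area_px",
            "centroid_row", "centroid_col", "support", "confidence"])

    def save(self, label_png: str | Path, table_csv: str | Path) -> None:
        iio.imwrite(Path(label_png), self.to_label_image())
        self.to_table().to_csv(table_csv, index=False)

    @classmethod
    def load(cls, label_png: str | Path, table_csv: str | Path,
             class_names: tuple[str, ...] = CLASS_NAMES) -> "ROISet":
        lab = np.asarray(iio.imread(Path(label_png)))
        table = pd.read_csv(table_csv)
        rois = cls(image_shape=lab.shape, class_names=class_names)
        for _, row in table.iterrows():
            mask = lab == int(row["instance_id"])
            if not mask.any():
                continue
            rois.instances.append(ROIInstance(
                int(row["instance_id"]), int(row["class_id"]), mask,
                int(row.get("support", 1)), float(row.get("confidence", 1.0))))
        return rois
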