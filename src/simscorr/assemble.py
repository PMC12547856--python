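"""Compile multi-pass detections into one instance mask and filter it.

Detections of the same class from different passes are linked by mask
overlap; groups seen in too few passes are dropped (they are typically
fragments truncated at a tile boundary), the survivors' masks are unioned,
and implausible shapes are removed by per-class morphological rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .rois import ROISet
from .segment import Detection

#: Default per-class filter rules.  Disk-like classes additionally require a
#: round shape so boundary-truncated fragments are rejected.
DEFAULT_FILTER_RULES: dict[str, dict] = {
    "nucleolus": {"min_area": 20},
    "mitochondria": {"min_area": 20},
    "ER": {"min_area": 20},
    "Golgi": {"min_area": 20},
    "vacuoles": {"min_area": 20, "min_circularity": 0.8},
    "vesicles": {"min_area": 20, "min_circularity": 0.8},
}


@dataclass(frozen=True)
class ShapeDescriptors:
    area: float
    perimeter: float
    circularity: float   # 4*pi*A / P^2
    solidity: float      # A / convex hull area


def _contour_perimeter(mask: np.ndarray) -> float:
    """Boundary length as the arc length of the half-level iso-contours.

    The raw marching-squares contour staircases along diagonals and
    overestimates curved boundaries, so it is simplified with a 1 px
    tolerance first (a rasterized disk then measures close to 2*pi*r while
    square corners stay exact).
    """
    padded = np.pad(mask, 1).astype(float)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        poly = measure.approximate_polygon(contour, tolerance=1.0)
        total += float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
    return total


def shape_descriptors(mask: np.ndarray) -> ShapeDescriptors:
    """Area, perimeter, circularity and solidity of one instance mask."""
    mask = np.asarray(mask, dtype=bool)
    area = float(mask.sum())
    if area == 0:
        raise ValueError("cannot describe an empty mask")
    perimeter = _contour_perimeter(mask)
    props = measure.regionprops(mask.astype(np.uint8))[0]
    circularity = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else 0.0
    return ShapeDescriptors(area=area, perimeter=perimeter,
                            circularity=circularity,
                            solidity=float(props.solidity))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rr, cc = np.nonzero(mask)
    return rr.min(), rr.max(), cc.min(), cc.max()


def link_detections(detections: list[Detection], iou_link: float = 0.5,
                    containment_link: float = 0.8) -> list[list[int]]:
    """Transitive closure of same-class pairwise mask overlap links.

    Two detections are linked when their mask IoU reaches ``iou_link`` or
    when the smaller mask is mostly contained in the larger one
    (intersection / smaller area >= ``containment_link``).  The containment
    branch absorbs boundary-truncated fragments, whose IoU with the
    complete detection from an offset pass hovers ambiguously around 0.5.
    Returns groups of detection indices; exposed separately from
    :func:`merge_passes` so it can be checked against a brute-force
    closure oracle.
    """
    if not 0 < iou_link < 1:
        raise ValueError("iou_link must lie in (0, 1)")
    if not 0 < containment_link <= 1:
        raise ValueError("containment_link must lie in (0, 1]")
    by_class: dict[int, list[int]] = {}
    for i, det in enumerate(detections):
        by_class.setdefault(det.class_id, []).append(i)

    uf = _UnionFind(len(detections))
    bboxes = [_bbox(d.mask) for d in detections]
    for indices in by_class.values():
        for ai in range(len(indices)):
            a = indices[ai]
            ra0, ra1, ca0, ca1 = bboxes[a]
            for bi in range(ai + 1, len(indices)):
                b = indices[bi]
                rb0, rb1, cb0, cb1 = bboxes[b]
                if ra0 > rb1 or rb0 > ra1 or ca0 > cb1 or cb0 > ca1:
                    continue  # bounding boxes disjoint
                inter = np.logical_and(detections[a].mask,
                                       detections[b].mask).sum()
                if inter == 0:
                    continue
                area_a = detections[a].mask.sum()
                area_b = detections[b].mask.sum()
                iou = inter / (area_a + area_b - inter)
                containment = inter / min(area_a, area_b)
                if iou >= iou_link or containment >= containment_link:
                    uf.union(a, b)

    groups: dict[int, list[int]] = {}
    for i in range(len(detections)):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def merge_passes(detections: list[Detection], image_shape: tuple[int, int],
                 n_passes: int, iou_link: float = 0.5,
                 min_support: int = 2,
                 containment_link: float = 0.8) -> ROISet:
    """Link same-class detections across passes and keep the consensus.

    Detections are linked into groups by pairwise mask IoU >= ``iou_link``
    (transitive closure).  Groups contributed by fewer than ``min_support``
    distinct passes are dropped; each surviving instance is the union of its
    members' masks with confidence = max member confidence.  Where two
    surviving same-class instances still overlap, the higher-confidence one
    claims the contested pixels (an instance losing all its pixels is
    dropped).
    """
    if not 0 < iou_link < 1:
        raise ValueError("iou_link must lie in (0, 1)")
    if not 1 <= min_support <= n_passes:
        raise ValueError("min_support must lie in [1, n_passes]")

    rois = ROISet(image_shape=tuple(image_shape))
    if not detections:
        return rois

    merged: list[tuple[int, np.ndarray, int, float]] = []
    for members in link_detections(detections, iou_link, containment_link):
        support = len({detections[i].pass_index for i in members})
        if support < min_support:
            continue
        mask = np.zeros(image_shape, dtype=bool)
        for i in members:
            mask |= detections[i].mask
        conf = max(detections[i].confidence for i in members)
        merged.append((detections[members[0]].class_id, mask, support, conf))

    # same-class overlap: higher confidence claims contested pixels
    merged.sort(key=lambda m: -m[3])
    claimed: dict[int, np.ndarray] = {}
    for class_id, mask, support, conf in merged:
        taken = claimed.setdefault(class_id, np.zeros(image_shape, dtype=bool))
        mask = mask & ~taken
        if not mask.any():
            continue
        taken |= mask
        rois.add(class_id, mask, support=support, confidence=conf)
    return rois


def morphological_filter(rois: ROISet, rules: dict[str, dict] | None = None
                         ) -> tuple[ROISet, list[dict]]:
    """Drop instances violating their class's shape rules.

    ``rules`` maps class name to ``{"min_area": px2, "min_circularity": x}``
    (circularity optional).  Returns the filtered set and a removal log of
    ``{"instance_id", "class_name", "rule", "value"}`` records.
    """
    rules = dict(DEFAULT_FILTER_RULES if rules is None else rules)
    unknown = set(rules) - set(rois.class_names)
    if unknown:
        raise ValueError(f"filter rules reference unknown classes: "
                         f"{sorted(unknown)}")
    kept = ROISet(image_shape=rois.image_shape, class_names=rois.class_names)
    removed: list[dict] = []
    for inst in rois:
        name = rois.class_name(inst.class_id)
        rule = rules.get(name, {})
        desc = shape_descriptors(inst.mask) if rule else None
        verdict = None
        if rule:
            if desc.area < rule.get("min_area", 0):
                verdict = ("min_area", desc.area)
            elif desc.circularity < rule.get("min_circularity", 0.0):
                verdict = ("min_circularity", desc.circularity)
        if verdict is None:
            kept.add(inst.class_id, inst.mask, support=inst.support,
                     confidence=inst.confidence)
        else:
            removed.append({"instance_id": inst.instance_id,
                            "class_name": name, "rule": verdict[0],
                            "value": float(verdict[1])})
    return kept, removed
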