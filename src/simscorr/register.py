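"""EM -> SIMS landmark registration.

The two modalities are related by a similarity transform (translation,
rotation, isotropic scale; no shear, no reflection).  The transform is fit
in closed form from anchor-point pairs, either supplied as a CSV or derived
automatically from nucleus-scale blobs visible in both modalities.

Point convention: ``(x, y) = (column, row)``, matching the image-transform
convention of scikit-image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy import ndimage as ndi
from skimage import measure
from skimage import transform as sktransform


class RegistrationError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityTransform:
    """p' = s * R(theta) * p + t, mapping EM (x, y) to SIMS (x, y)."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        s, th = self.scale, self.rotation
        tx, ty = self.translation
        return np.array([
            [s * np.cos(th), -s * np.sin(th), tx],
            [s * np.sin(th), s * np.cos(th), ty],
            [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2]

    def inverse(self) -> "SimilarityTransform":
        inv = np.linalg.inv(self.matrix)
        s = float(np.hypot(inv[0, 0], inv[1, 0]))
        th = float(np.arctan2(inv[1, 0], inv[0, 0]))
        return SimilarityTransform(s, th, (float(inv[0, 2]), float(inv[1, 2])))

    def to_skimage(self) -> sktransform.SimilarityTransform:
        return sktransform.SimilarityTransform(matrix=self.matrix)

    def to_json(self) -> str:
        return json.dumps({
            "scale": self.scale, "theta_deg": float(np.degrees(self.rotation)),
            "tx": self.translation[0], "ty": self.translation[1],
            "direction": "em_to_sims"})

    @classmethod
    def from_json(cls, text: str) -> "SimilarityTransform":
        d = json.loads(text)
        return cls(d["scale"], float(np.radians(d["theta_deg"])),
                   (d["tx"], d["ty"]))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(1.0, 0.0, (0.0, 0.0))


@dataclass(frozen=True)
class AnchorSet:
    """Paired EM/SIMS landmark coordinates, (x, y) pixels."""

    em: np.ndarray
    sims: np.ndarray

    def __post_init__(self):
        em = np.atleast_2d(np.asarray(self.em, dtype=float))
        sims = np.atleast_2d(np.asarray(self.sims, dtype=float))
        object.__setattr__(self, "em", em)
        object.__setattr__(self, "sims", sims)
        if em.shape != sims.shape or em.shape[1] != 2:
            raise ValueError("em and sims must be matching (N, 2) arrays")
        if len(em) < 2:
            raise RegistrationError("at least 2 anchor pairs are required")
        if not (np.isfinite(em).all() and np.isfinite(sims).all()):
            raise ValueError("anchor coordinates must be finite")
        if len(np.unique(em.round(9), axis=0)) < len(em):
            raise ValueError("duplicate EM anchor points")

    def __len__(self) -> int:
        return len(self.em)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "em_x": self.em[:, 0], "em_y": self.em[:, 1],
            "sims_x": self.sims[:, 0], "sims_y": self.sims[:, 1],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "AnchorSet":
        df = pd.read_csv(path)
        return cls(df[["em_x", "em_y"]].to_numpy(),
                   df[["sims_x", "sims_y"]].to_numpy())


def fit_similarity(anchors: AnchorSet) -> tuple[SimilarityTransform, float]:
    """Closed-form least-squares similarity fit (Umeyama, det > 0).

    Returns the transform and the RMS residual |T(em) - sims| in SIMS px.
    """
    src, dst = anchors.em, anchors.sims
    n = len(src)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    src0, dst0 = src - mu_s, dst - mu_d
    var_s = float((src0 ** 2).sum() / n)
    if var_s <= 0:
        raise RegistrationError("all EM anchor points coincide")
    cov = dst0.T @ src0 / n
    u, d, vt = np.linalg.svd(cov)
    sgn = np.ones(2)
    if np.linalg.det(u @ vt) < 0:  # forbid reflection
        sgn[-1] = -1.0
    rot = u @ np.diag(sgn) @ vt
    scale = float((d * sgn).sum() / var_s)
    if scale <= 0:
        raise RegistrationError("degenerate anchor configuration "
                                "(non-positive scale)")
    trans = mu_d - scale * (rot @ mu_s)
    theta = float(np.arctan2(rot[1, 0], rot[0, 0]))
    tform = SimilarityTransform(scale, theta, (float(trans[0]), float(trans[1])))
    resid = tform.apply(src) - dst
    rms = float(np.sqrt((resid ** 2).sum(axis=1).mean()))
    return tform, rms


def warp_mask(mask: np.ndarray, tform: SimilarityTransform,
              sims_shape: tuple[int, int]) -> np.ndarray:
    """Warp a boolean EM-frame mask into the SIMS frame.

    Inverse mapping with nearest-neighbour interpolation so the mask stays
    binary.  An empty result triggers a warning (mask outside the frame).
    """
    tf = tform.to_skimage()
    out = sktransform.warp(mask.astype(float), inverse_map=tf.inverse,
                           output_shape=tuple(sims_shape), order=0,
                           mode="constant", cval=0.0, preserve_range=True)
    out = out > 0.5
    if mask.any() and not out.any():
        warnings.warn("warped mask is empty: instance falls outside the "
                      "SIMS frame", stacklevel=2)
    return out


def warp_image(image: np.ndarray, tform: SimilarityTransform,
               sims_shape: tuple[int, int], order: int = 1) -> np.ndarray:
    """Warp an intensity image EM -> SIMS (bilinear by default)."""
    tf = tform.to_skimage()
    return sktransform.warp(image.astype(float), inverse_map=tf.inverse,
                            output_shape=tuple(sims_shape), order=order,
                            mode="constant", cval=0.0, preserve_range=True)


# ---------------------------------------------------------------------------
# automatic anchor generation from nucleus-scale blobs
# ---------------------------------------------------------------------------

def _blob_centroids(image: np.ndarray, max_blobs: int, min_area: int,
                    rel_area: float = 0.35) -> np.ndarray:
    """Centroids (x, y) of the dominant blobs deviating from the background.

    Works on either modality: blobs are connected regions whose intensity
    deviates strongly from the image median (nucleoli are dark in EM and
    CN-bright in SIMS).  Only components comparable in size to the largest
    one are kept, which selects nucleus-scale structures.
    """
    x = np.asarray(image, dtype=float)
    med = float(np.median(x))
    dev = np.abs(x - med)
    mad = float(np.median(np.abs(x - med)))
    sigma = max(1.4826 * mad, 1e-6)
    thr = max(8.0 * sigma, 0.35 * float(dev.max()))
    blobs = ndi.binary_fill_holes(dev > thr)
    lab = measure.label(blobs)
    props = [p for p in measure.regionprops(lab) if p.area >= min_area]
    if not props:
        return np.empty((0, 2))
    props.sort(key=lambda p: p.area, reverse=True)
    amax = props[0].area
    props = [p for p in props if p.area >= rel_area * amax][:max_blobs]
    return np.array([(p.centroid[1], p.centroid[0]) for p in props])


def _distance_signature(points: np.ndarray) -> np.ndarray:
    """Per-point sorted distances to the other points, scale-normalized."""
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    scale = d.sum() / max(len(points) * (len(points) - 1), 1)
    sig = np.sort(d, axis=1)[:, 1:] / max(scale, 1e-12)
    return sig


def auto_anchor_nuclei(em_image: np.ndarray, sims_image: np.ndarray,
                       max_blobs: int = 6, min_area: int = 20) -> AnchorSet:
    """Pair nucleus-scale blob centroids across modalities.

    Blobs are matched by their scale-normalized inter-blob distance
    signatures (rotation and scale invariant), solved as an assignment
    problem.  Raises :class:`RegistrationError` when fewer than two pairs
    can be formed; manual anchors are then required.
    """
    em_pts = _blob_centroids(em_image, max_blobs, min_area)
    # SIMS frames are typically coarser; relax the area floor with frame size
    area_ratio = (sims_image.shape[0] * sims_image.shape[1]) / float(
        em_image.shape[0] * em_image.shape[1])
    sims_min_area = max(4, int(min_area * min(1.0, area_ratio)))
    sims_pts = _blob_centroids(sims_image, max_blobs, sims_min_area)
    if len(em_pts) < 2 or len(sims_pts) < 2:
        raise RegistrationError(
            f"found {len(em_pts)} EM / {len(sims_pts)} SIMS candidate blobs; "
            "need >= 2 in each modality - provide manual anchors")
    n = min(len(em_pts), len(sims_pts))
    em_pts, sims_pts = em_pts[:n], sims_pts[:n]
    if n == 2:
        # two blobs: match larger-to-larger (both lists are area-sorted)
        return AnchorSet(em_pts, sims_pts)
    sig_em = _distance_signature(em_pts)
    sig_sims = _distance_signature(sims_pts)
    cost = np.linalg.norm(sig_em[:, None, :] - sig_sims[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    return AnchorSet(em_pts[rows], sims_pts[cols])
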