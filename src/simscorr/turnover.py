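"""Per-organelle isotope enrichment, decay fitting and group statistics.

Enrichment is the summed 15N/14N count ratio over an ROI (sum-then-divide,
equivalent to the count-weighted mean of pixel ratios).  Across chase times
the enrichment of a labeled pulse decays to the natural-abundance baseline
as E(t) = E_nat + (E0 - E_nat) * 2**(-t / t_half), which makes the fitted
time constant the half-life directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.draw import disk as draw_disk

from .rois import ROISet

#: Natural 15N/14N abundance, the default decay baseline.
DEFAULT_BASELINE = 0.0037


class DecayFitError(RuntimeError):
    pass


@dataclass(frozen=True)
class EnrichmentMeasurement:
    roi_id: int
    class_id: int
    chase_time: float       # hours
    cn14_counts: float
    cn15_counts: float
    n_pixels: int

    def __post_init__(self):
        if self.cn14_counts <= 0:
            raise ValueError("cn14_counts must be positive for a valid ratio")
        if self.cn15_counts < 0:
            raise ValueError("cn15_counts must be nonnegative")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")

    @property
    def ratio(self) -> float:
        return self.cn15_counts / self.cn14_counts


def roi_enrichment(rois: ROISet, cn14: np.ndarray, cn15: np.ndarray,
                   chase_time: float = 0.0) -> list[EnrichmentMeasurement]:
    """Summed-count enrichment ratio for every ROI.

    The ratio is sum(cn15) / sum(cn14) over the mask - not the mean of
    per-pixel ratios.  ROIs with zero total cn14 are excluded with a
    warning.  The images must already be dead-time and drift corrected.
    """
    cn14 = np.ma.filled(np.asarray(cn14, dtype=float), 0.0) \
        if np.ma.isMaskedArray(cn14) else np.asarray(cn14, dtype=float)
    cn15 = np.ma.filled(np.asarray(cn15, dtype=float), 0.0) \
        if np.ma.isMaskedArray(cn15) else np.asarray(cn15, dtype=float)
    if cn14.shape != tuple(rois.image_shape) or cn15.shape != cn14.shape:
        raise ValueError("ion images must match the ROI frame shape")
    out: list[EnrichmentMeasurement] = []
    for inst in rois:
        s14 = float(cn14[inst.mask].sum())
        s15 = float(cn15[inst.mask].sum())
        if s14 <= 0:
            warnings.warn(f"ROI {inst.instance_id}: zero cn14 counts, "
                          "excluded", stacklevel=2)
            continue
        out.append(EnrichmentMeasurement(inst.instance_id, inst.class_id,
                                         float(chase_time), s14, s15,
                                         inst.area))
    return out


def multipoint_enrichment(points, cn14: np.ndarray, cn15: np.ndarray,
                          radius: float = 2.0, chase_time: float = 0.0
                          ) -> list[EnrichmentMeasurement]:
    """Enrichment from counts summed over a small disk at each click point.

    ``points`` is a sequence of (x, y, class_id); ``radius`` 0 means the
    single pixel under the point.
    """
    cn14 = np.asarray(cn14, dtype=float)
    cn15 = np.asarray(cn15, dtype=float)
    h, w = cn14.shape
    out: list[EnrichmentMeasurement] = []
    for i, (x, y, class_id) in enumerate(points):
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"point {i} at ({x}, {y}) is out of bounds")
        if radius <= 0:
            rr = np.array([r])
            cc = np.array([c])
        else:
            rr, cc = draw_disk((r, c), radius + 0.5, shape=(h, w))
        s14 = float(cn14[rr, cc].sum())
        s15 = float(cn15[rr, cc].sum())
        if s14 <= 0:
            warnings.warn(f"point {i}: zero cn14 counts, excluded",
                          stacklevel=2)
            continue
        out.append(EnrichmentMeasurement(i, int(class_id), float(chase_time),
                                         s14, s15, int(len(rr))))
    return out


def measurements_to_frame(measurements, class_names=None) -> pd.DataFrame:
    """Long-format table: roi_id, class, chase_time_h, cn14, cn15, ratio."""
    rows = []
    for m in measurements:
        rows.append({
            "roi_id": m.roi_id, "class_id": m.class_id,
            "class_name": (class_names[m.class_id] if class_names is not None
                           else str(m.class_id)),
            "chase_time_h": m.chase_time, "cn14": m.cn14_counts,
            "cn15": m.cn15_counts, "ratio": m.ratio,
            "n_pixels": m.n_pixels})
    return pd.DataFrame(rows, columns=["roi_id", "class_id", "class_name",
                                       "chase_time_h", "cn14", "cn15",
                                       "ratio", "n_pixels"])


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayFit:
    t_half: float           # hours
    t_half_sem: float
    e0: float
    e_nat: float
    baseline_fixed: bool
    rss: float
    n_points: int
    class_id: int | None = None

    def as_dict(self) -> dict:
        return {"class_id": self.class_id, "t_half_h": self.t_half,
                "t_half_sem_h": self.t_half_sem, "e0": self.e0,
                "e_nat": self.e_nat, "baseline_fixed": self.baseline_fixed,
                "rss": self.rss, "n_points": self.n_points}


def _initial_guess(t: np.ndarray, y: np.ndarray, baseline: float
                   ) -> tuple[float, float]:
    """Log-linear fit on baseline-subtracted per-time means."""
    times = np.unique(t)
    means = np.array([y[t == ti].mean() for ti in times]) - baseline
    pos = means > 0
    if pos.sum() < 2:
        raise DecayFitError(
            "no decay signal: enrichment does not rise above the baseline "
            f"(amplitude {means.max():.3g})")
    slope, intercept = np.polyfit(times[pos], np.log(means[pos]), 1)
    if slope >= 0:
        # no decay visible; start from the observation span
        t_half0 = max(times.max(), 1.0)
    else:
        t_half0 = np.log(2.0) / -slope
    e0_0 = baseline + np.exp(intercept)
    return e0_0, t_half0


def fit_decay(measurements, fix_baseline: bool = True,
              baseline: float = DEFAULT_BASELINE,
              class_id: int | None = None) -> DecayFit:
    """Nonlinear least-squares fit of the half-life decay model.

    ``measurements`` is either a list of :class:`EnrichmentMeasurement`
    (one class) or a pair of arrays ``(t_hours, ratios)``.  With
    ``fix_baseline`` the asymptote is held at ``baseline``; otherwise it is
    a third free parameter.  Requires at least 3 distinct chase times and a
    positive signal amplitude; the half-life SEM comes from the parameter
    covariance.
    """
    if isinstance(measurements, tuple) and len(measurements) == 2:
        t = np.asarray(measurements[0], dtype=float)
        y = np.asarray(measurements[1], dtype=float)
    else:
        meas = list(measurements)
        t = np.array([m.chase_time for m in meas], dtype=float)
        y = np.array([m.ratio for m in meas], dtype=float)
        if class_id is None and meas:
            ids = {m.class_id for m in meas}
            if len(ids) > 1:
                raise ValueError("measurements span several classes; fit "
                                 "them separately")
            class_id = ids.pop()
    if len(t) != len(y) or len(t) == 0:
        raise ValueError("need matching nonempty time/ratio arrays")
    if (y < 0).any():
        raise ValueError("ratios must be nonnegative")
    n_times = len(np.unique(t))
    min_times = 3 if fix_baseline else 4
    if n_times < min_times:
        raise DecayFitError(f"need >= {min_times} distinct chase times, "
                            f"got {n_times}")

    e0_0, t_half0 = _initial_guess(t, y, baseline)
    t_half0 = float(np.clip(t_half0, 1e-3, 1e5))

    try:
        if fix_baseline:
            def model(tt, e0, t_half):
                return baseline + (e0 - baseline) * 2.0 ** (-tt / t_half)
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=[e0_0, t_half0],
                bounds=([baseline, 1e-6], [1.0, 1e6]), maxfev=20000)
            e0, t_half = popt
            e_nat = baseline
        else:
            def model(tt, e0, t_half, e_nat):
                return e_nat + (e0 - e_nat) * 2.0 ** (-tt / t_half)
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=[e0_0, t_half0, baseline],
                bounds=([0.0, 1e-6, 0.0], [1.0, 1e6, 1.0]), maxfev=20000)
            e0, t_half, e_nat = popt
    except RuntimeError as exc:
        raise DecayFitError(
            f"decay fit did not converge: {exc}; n={len(t)}, "
            f"t_half0={t_half0:.3g}, e0_0={e0_0:.3g}") from exc

    resid = y - model(t, *popt)
    sem = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    return DecayFit(t_half=float(t_half), t_half_sem=sem, e0=float(e0),
                    e_nat=float(e_nat), baseline_fixed=fix_baseline,
                    rss=float((resid ** 2).sum()), n_points=len(t),
                    class_id=class_id)


def fit_decay_by_class(measurements, fix_baseline: bool = True,
                       baseline: float = DEFAULT_BASELINE
                       ) -> dict[int, DecayFit]:
    """Group measurements by class and fit each series independently."""
    by_class: dict[int, list] = {}
    for m in measurements:
        by_class.setdefault(m.class_id, []).append(m)
    fits = {}
    for cls, meas in sorted(by_class.items()):
        fits[cls] = fit_decay(meas, fix_baseline=fix_baseline,
                              baseline=baseline, class_id=cls)
    return fits


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    stars: str
    n_a: int
    n_b: int


def significance_stars(p: float) -> str:
    """Star coding: * p<0.05, ** p<0.01, *** p<0.001, else 'ns'."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(group_a, group_b, equal_var: bool = False
                   ) -> GroupComparison:
    """Two-sample independent t-test (Welch by default) with star coding."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    t_stat = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t_stat):  # both groups constant and equal
        t_stat, p = 0.0, 1.0
    return GroupComparison(t_stat, p, significance_stars(p), len(a), len(b))
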