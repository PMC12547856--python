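import numpy as np
import pytest

from simscorr.phantom import IonPhantomSpec, PhantomSpec, decay_ratio, \
    make_em_phantom, make_ion_stack
from simscorr.rois import CLASS_NAMES, ROISet
from simscorr.sims import accumulate
from simscorr.turnover import (
    DEFAULT_BASELINE,
    DecayFitError,
    EnrichmentMeasurement,
    compare_groups,
    fit_decay,
    fit_decay_by_class,
    multipoint_enrichment,
    roi_enrichment,
    significance_stars,
)
from tests.conftest import disk_mask

MITO_ID = CLASS_NAMES.index("mitochondria")


class TestRoiEnrichment:
    def _rois(self, mask):
        rois = ROISet(image_shape=mask.shape)
        rois.add(MITO_ID, mask)
        return rois

    def test_uniform_ratio(self):
        mask = disk_mask((40, 40), (20, 20), 4)
        cn14 = np.full((40, 40), 100.0)
        cn15 = np.full((40, 40), 1.0)
        meas = roi_enrichment(self._rois(mask), cn14, cn15)
        assert len(meas) == 1
        assert meas[0].ratio == pytest.approx(0.01)
        assert meas[0].n_pixels == mask.sum()

    def test_zero_cn15_ratio_zero(self):
        mask = disk_mask((40, 40), (20, 20), 4)
        meas = roi_enrichment(self._rois(mask), np.full((40, 40), 10.0),
                              np.zeros((40, 40)))
        assert meas[0].ratio == 0.0

    def test_zero_cn14_roi_excluded(self):
        mask = disk_mask((40, 40), (20, 20), 4)
        with pytest.warns(UserWarning, match="zero cn14"):
            meas = roi_enrichment(self._rois(mask), np.zeros((40, 40)),
                                  np.zeros((40, 40)))
        assert meas == []

    def test_shape_mismatch(self):
        rois = self._rois(disk_mask((40, 40), (20, 20), 4))
        with pytest.raises(ValueError):
            roi_enrichment(rois, np.ones((30, 30)), np.ones((30, 30)))

    def test_noiseless_generator_ratio_exact_at_half_life(self):
        truth = make_em_phantom(PhantomSpec(
            image_shape=(96, 96), counts={"mitochondria": 2}, seed=1))[1]
        spec = IonPhantomSpec(sims_shape=(96, 96), e0=0.05,
                              half_lives={"mitochondria": 21.5},
                              poisson=False, n_planes=2)
        cn14, cn15 = make_ion_stack(spec, truth, 21.5)
        img14 = accumulate(cn14, [(0, 0)] * 2)
        img15 = accumulate(cn15, [(0, 0)] * 2)
        meas = roi_enrichment(truth, img14, img15, chase_time=21.5)
        expected = DEFAULT_BASELINE + (0.05 - DEFAULT_BASELINE) / 2
        for m in meas:
            assert m.ratio == pytest.approx(expected, rel=1e-12)

    def test_ratio_invariant_to_common_scaling(self):
        mask = disk_mask((40, 40), (20, 20), 6)
        rng = np.random.default_rng(0)
        cn14 = rng.poisson(100, (40, 40)).astype(float) + 1
        cn15 = rng.poisson(5, (40, 40)).astype(float)
        r1 = roi_enrichment(self._rois(mask), cn14, cn15)[0].ratio
        r2 = roi_enrichment(self._rois(mask), cn14 * 7.5, cn15 * 7.5)[0].ratio
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_sum_then_divide_equals_weighted_mean_of_pixel_ratios(self):
        mask = disk_mask((40, 40), (20, 20), 6)
        rng = np.random.default_rng(1)
        cn14 = rng.uniform(1, 200, (40, 40))
        cn15 = rng.uniform(0, 10, (40, 40))
        m = roi_enrichment(self._rois(mask), cn14, cn15)[0]
        pixel_ratios = cn15[mask] / cn14[mask]
        weighted = np.average(pixel_ratios, weights=cn14[mask])
        assert m.ratio == pytest.approx(weighted, rel=1e-12)


class TestMultipointEnrichment:
    def test_point_in_uniform_region_matches_roi(self):
        cn14 = np.full((40, 40), 100.0)
        cn15 = np.full((40, 40), 2.0)
        meas = multipoint_enrichment([(20, 20, MITO_ID)], cn14, cn15,
                                     radius=2)
        assert meas[0].ratio == pytest.approx(0.02)

    def test_radius_zero_single_pixel(self):
        cn14 = np.ones((10, 10))
        cn15 = np.zeros((10, 10))
        cn15[4, 7] = 0.5
        meas = multipoint_enrichment([(7, 4, 0)], cn14, cn15, radius=0)
        assert meas[0].n_pixels == 1
        assert meas[0].ratio == pytest.approx(0.5)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            multipoint_enrichment([(100, 100, 0)], np.ones((10, 10)),
                                  np.ones((10, 10)))

    def test_gradient_heterogeneity_vs_mask_ratio(self):
        # point ratios vary across a gradient ROI; the mask ratio is unique
        cn14 = np.full((40, 40), 100.0)
        cn15 = np.tile(np.linspace(0.5, 5.0, 40), (40, 1)) * 1.0
        mask = disk_mask((40, 40), (20, 20), 10)
        rois = ROISet(image_shape=(40, 40))
        rois.add(MITO_ID, mask)
        mask_ratio = roi_enrichment(rois, cn14, cn15)[0].ratio
        pts = [(12, 20, MITO_ID), (20, 20, MITO_ID), (28, 20, MITO_ID)]
        ratios = [m.ratio for m in multipoint_enrichment(pts, cn14, cn15)]
        assert np.std(ratios) > 0.001
        assert min(ratios) < mask_ratio < max(ratios)


def _series(t_half, times=(0.0, 12.0, 24.0, 48.0, 96.0), e0=0.05,
            e_nat=DEFAULT_BASELINE):
    t = np.asarray(times, dtype=float)
    return t, np.array([decay_ratio(ti, t_half, e0, e_nat) for ti in t])


class TestFitDecay:
    @pytest.mark.parametrize("t_half", [16.4, 21.5, 76.2])
    def test_noiseless_exact_recovery(self, t_half):
        fit = fit_decay(_series(t_half))
        assert fit.t_half == pytest.approx(t_half, abs=1e-6)
        assert fit.e0 == pytest.approx(0.05, rel=1e-6)
        assert fit.baseline_fixed

    def test_noiseless_sweep_any_half_life(self):
        for t_half in np.linspace(5.0, 100.0, 12):
            fit = fit_decay(_series(t_half))
            assert fit.t_half == pytest.approx(t_half, rel=1e-6)

    def test_free_baseline_fit(self):
        t, y = _series(30.0, e_nat=0.002)
        fit = fit_decay((t, y), fix_baseline=False)
        assert fit.t_half == pytest.approx(30.0, rel=1e-4)
        assert fit.e_nat == pytest.approx(0.002, abs=1e-5)
        assert not fit.baseline_fixed

    def test_flat_at_baseline_rejected(self):
        t = np.array([0.0, 12.0, 24.0, 48.0])
        y = np.full(4, DEFAULT_BASELINE)
        with pytest.raises(DecayFitError, match="no decay signal"):
            fit_decay((t, y))

    def test_too_few_times_rejected(self):
        with pytest.raises(DecayFitError, match="distinct chase times"):
            fit_decay((np.array([0.0, 24.0]), np.array([0.05, 0.03])))

    def test_measurement_objects_accepted(self):
        t, y = _series(21.5)
        meas = [EnrichmentMeasurement(i, MITO_ID, ti, 1000.0, 1000.0 * yi,
                                      50)
                for i, (ti, yi) in enumerate(zip(t, y))]
        fit = fit_decay(meas)
        assert fit.class_id == MITO_ID
        assert fit.t_half == pytest.approx(21.5, rel=1e-6)

    def test_mixed_classes_rejected(self):
        meas = [EnrichmentMeasurement(0, 0, 0.0, 100.0, 5.0, 10),
                EnrichmentMeasurement(1, 1, 12.0, 100.0, 4.0, 10),
                EnrichmentMeasurement(2, 0, 24.0, 100.0, 3.0, 10)]
        with pytest.raises(ValueError, match="several classes"):
            fit_decay(meas)

    def test_fit_by_class(self):
        meas = []
        for cls, t_half in ((0, 16.4), (1, 21.5)):
            t, y = _series(t_half)
            meas += [EnrichmentMeasurement(i, cls, ti, 1000.0, 1000.0 * yi,
                                           50)
                     for i, (ti, yi) in enumerate(zip(t, y))]
        fits = fit_decay_by_class(meas)
        assert fits[0].t_half == pytest.approx(16.4, rel=1e-6)
        assert fits[1].t_half == pytest.approx(21.5, rel=1e-6)

    def test_sem_positive_under_noise(self):
        rng = np.random.default_rng(3)
        t = np.repeat([0.0, 12.0, 24.0, 48.0, 96.0], 8)
        y = decay_ratio(t, 21.5, 0.05) * rng.normal(1.0, 0.03, t.size)
        fit = fit_decay((t, np.abs(y)))
        assert fit.t_half == pytest.approx(21.5, rel=0.15)
        assert fit.t_half_sem > 0

    def test_poisson_parameter_recovery(self):
        # synthetic replicate experiment: >= 10 ROIs per time, high counts
        rng = np.random.default_rng(4)
        hits = 0
        trials = 10
        for trial in range(trials):
            t_all, y_all = [], []
            for ti in (0.0, 12.0, 24.0, 48.0, 96.0):
                for _ in range(10):
                    n14 = rng.poisson(20000)
                    n15 = rng.poisson(20000 * decay_ratio(ti, 21.5, 0.05))
                    t_all.append(ti)
                    y_all.append(n15 / n14)
            fit = fit_decay((np.array(t_all), np.array(y_all)))
            if abs(fit.t_half - 21.5) / 21.5 < 0.10:
                hits += 1
        assert hits >= 9


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.stars == "ns"

    def test_clearly_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1e-4, 4)
        b = 1.0 + rng.normal(0.0, 1e-4, 4)
        res = compare_groups(a, b)
        assert res.p_value < 0.001
        assert res.stars == "***"

    def test_star_thresholds(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"

    def test_requires_two_observations(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_welch_vs_equal_var_flag(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 3, 10)
        welch = compare_groups(a, b, equal_var=False)
        student = compare_groups(a, b, equal_var=True)
        assert welch.p_value != student.p_value
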