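"""Tests for region extraction, peak areas, T/C, 4PL calibration, CV and
recovery."""

import numpy as np
import pytest

from lfianet import quantify as q
from lfianet import synthdata as sd


class TestMaskToRegions:
    def test_all_zero_probabilities(self):
        assert q.mask_to_regions(np.zeros(512)) == []

    def test_one_run_per_zone(self):
        prob = np.zeros(512)
        prob[100:140] = 0.9
        prob[330:380] = 0.9
        regions = q.mask_to_regions(prob, cutoff=0.6)
        assert [(r.start, r.end, r.zone) for r in regions] == \
               [(100, 140, "C"), (330, 380, "T")]

    def test_largest_run_kept_per_zone(self):
        prob = np.zeros(512)
        prob[230:235] = 0.9   # length 5
        prob[300:340] = 0.9   # length 40 -> kept
        prob[400:403] = 0.9   # length 3
        regions = q.mask_to_regions(prob, cutoff=0.6)
        assert [(r.start, r.end) for r in regions] == [(300, 340)]

    def test_cutoff_is_inclusive_threshold(self):
        prob = np.zeros(512)
        prob[100:110] = 0.6
        assert len(q.mask_to_regions(prob, cutoff=0.6)) == 1
        assert len(q.mask_to_regions(prob, cutoff=0.61)) == 0


class TestIntegrateRegion:
    def test_flat_trace_zero_area(self):
        region = q.PeakRegion(100, 200, "C")
        assert q.integrate_region(np.full(512, 300.0), region) == 0.0

    def test_rectangle_pulse(self):
        x = np.zeros(512)
        x[100:120] = 50.0  # height 50 over 20 samples
        region = q.PeakRegion(90, 130, "C")
        assert q.integrate_region(x, region) == pytest.approx(50 * 20)

    def test_gaussian_area_matches_quadrature(self):
        spec = sd.PeakSpec(center=120, amplitude=4000, sigma=9, zone="C")
        x = sd.render_trace([spec], sd.BaselineSpec(), np.random.default_rng(0))
        region = q.PeakRegion(60, 180, "C")
        area = q.integrate_region(x, region)
        oracle = float(np.sum(x[60:180]))  # flat zero baseline
        assert area == pytest.approx(oracle)
        assert area == pytest.approx(4000 * 9 * np.sqrt(2 * np.pi), rel=1e-3)

    def test_missing_region_is_zero(self):
        assert q.integrate_region(np.zeros(512), None) == 0.0


class TestTOverC:
    def test_basic_ratios(self):
        assert q.t_over_c(100.0, 100.0) == 1.0
        assert q.t_over_c(50.0, 0.0) == 0.0
        assert q.t_over_c(4.0, 10.0) == pytest.approx(2.5)

    def test_zero_c_area_invalid(self):
        with pytest.raises(q.InvalidAssayError):
            q.t_over_c(0.0, 10.0)


CAL_CONCS = np.array([0.0, 15.0, 50.0, 200.0, 300.0, 500.0])


class TestFourPL:
    def make_curve(self):
        return q.FourPLCurve(a=0.02, b=1.3, c=150.0, d=3.5)

    def test_parameter_recovery_on_noiseless_calibrators(self):
        truth = self.make_curve()
        fitted = q.fit_4pl(CAL_CONCS, truth(CAL_CONCS))
        for name in "abcd":
            assert getattr(fitted, name) == pytest.approx(getattr(truth, name),
                                                          rel=1e-6)
        assert fitted.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_roundtrip_inverse(self):
        curve = self.make_curve()
        for x in np.linspace(0.5, 499.5, 100):
            y = float(curve(x))
            assert q.inverse_4pl(curve, y) == pytest.approx(x, abs=1e-9, rel=1e-9)

    def test_inflection_response_maps_to_c(self):
        curve = self.make_curve()
        y_mid = float(curve(curve.c))
        assert q.inverse_4pl(curve, y_mid) == pytest.approx(curve.c, rel=1e-12)

    def test_out_of_range_response_rejected(self):
        curve = self.make_curve()
        with pytest.raises(q.InvalidAssayError):
            q.inverse_4pl(curve, 3.6)
        with pytest.raises(q.InvalidAssayError):
            q.inverse_4pl(curve, 0.01)

    def test_inverse_monotone_for_increasing_curve(self):
        curve = self.make_curve()
        ys = np.linspace(0.1, 3.0, 50)
        xs = [q.inverse_4pl(curve, y) for y in ys]
        assert np.all(np.diff(xs) > 0)

    def test_noisy_fit_stays_within_noise(self):
        truth = self.make_curve()
        rng = np.random.default_rng(5)
        noise_sd = 0.02
        y = truth(CAL_CONCS) + rng.normal(0, noise_sd, size=len(CAL_CONCS))
        fitted = q.fit_4pl(CAL_CONCS, y)
        resid = np.abs(fitted(CAL_CONCS) - y)
        assert resid.max() < 3 * noise_sd

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            q.fit_4pl(np.array([0, 1, 1, 1.0]), np.array([1, 2, 2, 2.0]))


class TestPrecisionAndRecovery:
    def test_cv_of_identical_values_is_zero(self):
        assert q.percent_cv([3.0, 3.0, 3.0]) == 0.0

    def test_cv_matches_definition(self, rng):
        v = rng.uniform(10, 20, size=10)
        assert q.percent_cv(v) == pytest.approx(100 * v.std(ddof=1) / v.mean())

    def test_recovery_identity(self):
        assert q.percent_recovery(42.0, 42.0) == 100.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            q.percent_cv([5.0])
        with pytest.raises(ValueError):
            q.percent_recovery(10.0, 0.0)


class TestAreaHomogeneity:
    def test_scaling_peaks_scales_areas_but_not_ratio(self):
        specs = [
            sd.PeakSpec(center=120, amplitude=5000, sigma=10, zone="C"),
            sd.PeakSpec(center=350, amplitude=2500, sigma=10, zone="T"),
        ]
        x1 = sd.render_trace(specs, sd.BaselineSpec(), np.random.default_rng(0))
        k = 3.7
        scaled = [sd.PeakSpec(s.center, k * s.amplitude, s.sigma, s.tau, s.zone)
                  for s in specs]
        xk = sd.render_trace(scaled, sd.BaselineSpec(), np.random.default_rng(0))
        c_reg = q.PeakRegion(80, 160, "C")
        t_reg = q.PeakRegion(310, 390, "T")
        a1c, a1t = q.integrate_region(x1, c_reg), q.integrate_region(x1, t_reg)
        akc, akt = q.integrate_region(xk, c_reg), q.integrate_region(xk, t_reg)
        assert akc == pytest.approx(k * a1c, rel=1e-9)
        assert akt == pytest.approx(k * a1t, rel=1e-9)
        assert q.t_over_c(akc, akt) == pytest.approx(q.t_over_c(a1c, a1t), rel=1e-9)


class _FakeClassifier:
    """Stands in for a trained PeakClassifier; emits a fixed class."""

    def __init__(self, label):
        from lfianet.models import ClassifierConfig
        self.config = ClassifierConfig()
        self.label = label

    def predict_proba(self, x):
        out = np.full((len(x), 4), 0.01)
        out[:, self.label - 1] = 0.97
        return out


class _FakeSegmenter:
    """Stands in for a trained UNetSegmenter; emits a fixed probability mask."""

    def __init__(self, prob_mask):
        from lfianet.models import SegmenterConfig
        self.config = SegmenterConfig()
        self.prob = prob_mask

    def forward(self, x, training=False):
        return np.tile(self.prob, (len(x), 1))


class TestAnalyzeTrace:
    """Pipeline dispatch logic, with model behavior stubbed out."""

    def trace(self):
        specs = [
            sd.PeakSpec(center=120, amplitude=5000, sigma=10, zone="C"),
            sd.PeakSpec(center=350, amplitude=2500, sigma=10, zone="T"),
        ]
        return sd.render_trace(specs, sd.BaselineSpec(offset=100.0),
                               np.random.default_rng(3))

    def test_noise_class_invalid(self):
        res = q.analyze_trace(self.trace(), _FakeClassifier(1), _FakeSegmenter(np.zeros(512)))
        assert res.label == 1 and not res.valid

    def test_only_t_class_invalid(self):
        res = q.analyze_trace(self.trace(), _FakeClassifier(3), _FakeSegmenter(np.zeros(512)))
        assert res.label == 3 and not res.valid

    def test_only_c_class_is_valid_zero(self):
        curve = q.FourPLCurve(a=0.02, b=1.3, c=150.0, d=3.5)
        res = q.analyze_trace(self.trace(), _FakeClassifier(2),
                              _FakeSegmenter(np.zeros(512)), curve=curve)
        assert res.valid and res.t_over_c == 0.0 and res.concentration == 0.0

    def test_double_peak_full_quantification(self):
        prob = np.zeros(512)
        prob[90:150] = 0.95
        prob[320:380] = 0.95
        curve = q.FourPLCurve(a=0.02, b=1.3, c=150.0, d=3.5)
        x = self.trace()
        res = q.analyze_trace(x, _FakeClassifier(4), _FakeSegmenter(prob), curve=curve)
        assert res.valid and res.label == 4
        expected_ratio = (q.integrate_region(x, q.PeakRegion(320, 380, "T"))
                          / q.integrate_region(x, q.PeakRegion(90, 150, "C")))
        assert res.t_over_c == pytest.approx(expected_ratio)
        assert res.concentration == pytest.approx(
            q.inverse_4pl(curve, expected_ratio), rel=1e-9)

    def test_missing_region_reported_invalid(self):
        prob = np.zeros(512)
        prob[90:150] = 0.95  # C only
        res = q.analyze_trace(self.trace(), _FakeClassifier(4), _FakeSegmenter(prob))
        assert res.label == 4 and not res.valid
        assert "no T region" in res.reason
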