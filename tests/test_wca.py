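"""Morlet CWT, wavelet coherence, red-noise significance, phase summaries."""

import numpy as np
import pytest

from thalfc.prep import TimeCourse
from thalfc.synth import gen_ar1_series, gen_oscillatory_pair
from thalfc.wca import (WcaParams, circular_mean, cone_of_influence, fit_ar1,
                        fourier_factor, mc_significance, morlet_cwt,
                        phase_classify, segment_phase_summary,
                        smooth_time_scale, wtc)

PARAMS = WcaParams(mc_n=100, seed=0)


def _sine(n=800, dt=3.01, freq=0.05, phase=0.0):
    t = np.arange(n) * dt
    return TimeCourse(np.sin(2 * np.pi * freq * t + phase), dt)


class TestMorletCwt:
    def test_zero_series_zero_coefficients(self):
        tc = TimeCourse(np.zeros(64), 1.0)
        res = morlet_cwt(tc, PARAMS)
        assert np.allclose(res.coeffs, 0.0)

    def test_ridge_at_oscillation_period(self):
        tc = _sine()
        res = morlet_cwt(tc, PARAMS)
        power = (np.abs(res.coeffs) ** 2).mean(axis=1)
        ridge_period = res.fourier_periods[np.argmax(power)]
        assert abs(np.log2(ridge_period / 20.0)) <= PARAMS.dj + 1e-12

    def test_fourier_period_closed_form(self):
        tc = _sine(n=64)
        res = morlet_cwt(tc, PARAMS)
        expected = 4 * np.pi / (6 + np.sqrt(38))
        assert np.allclose(res.fourier_periods / res.scales, expected)
        assert fourier_factor(6.0) == pytest.approx(expected)

    def test_periods_increasing_and_bounded(self):
        tc = _sine()
        res = morlet_cwt(tc, PARAMS)
        assert np.all(np.diff(res.fourier_periods) > 0)
        assert res.fourier_periods[-1] <= 800 * 3.01 / 2

    def test_nan_rejected(self):
        x = np.zeros(32)
        x[3] = np.nan
        with pytest.raises(ValueError):
            morlet_cwt(TimeCourse(x, 1.0), PARAMS)


class TestConeOfInfluence:
    def test_zero_at_edges_and_symmetric(self):
        coi = cone_of_influence(101, 2.0)
        assert coi[0] == 0.0 and coi[-1] == 0.0
        assert np.allclose(coi, coi[::-1])

    def test_midpoint_e_folding_closed_form(self):
        n, dt = 400, 3.01
        coi = cone_of_influence(n, dt)
        expected = np.sqrt(2) * fourier_factor(6.0) * (n / 2) * dt
        assert abs(coi[n // 2] - expected) / expected < 0.01


class TestSmoothing:
    def test_constant_field_preserved(self):
        scales = 2.0 * 2.0 ** (np.arange(20) / 12)
        F = np.full((20, 100), 3.3)
        out = smooth_time_scale(F, scales, dt=1.0)
        assert np.allclose(out, 3.3, atol=1e-12)

    def test_linearity(self, rng):
        scales = 2.0 * 2.0 ** (np.arange(15) / 12)
        F = rng.normal(size=(15, 80))
        G = rng.normal(size=(15, 80))
        lhs = smooth_time_scale(2 * F - 0.5 * G, scales, 1.0)
        rhs = 2 * smooth_time_scale(F, scales, 1.0) \
            - 0.5 * smooth_time_scale(G, scales, 1.0)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_impulse_spread_proportional_to_scale(self):
        scales = np.array([4.0, 8.0, 16.0])
        F = np.zeros((3, 201))
        F[:, 100] = 1.0
        out = smooth_time_scale(F, scales, dt=1.0, dj=1.0)  # no scale mixing
        t = np.arange(201)
        for j, s in enumerate(scales):
            w = out[j] / out[j].sum()
            sd = np.sqrt(np.sum(w * (t - 100) ** 2))
            assert sd == pytest.approx(s, rel=0.05)


class TestWtc:
    def test_self_coherence(self):
        x = TimeCourse(gen_ar1_series(400, 0.4, 1.0, 3).samples, 3.01)
        res = wtc(x, x, PARAMS)
        assert res.coherence[res.in_coi].min() >= 0.999

    def test_coherence_bounded(self, rng):
        x = TimeCourse(rng.normal(size=300), 2.0)
        y = TimeCourse(rng.normal(size=300), 2.0)
        res = wtc(x, y, PARAMS)
        assert res.coherence.min() >= 0.0 and res.coherence.max() <= 1.0

    def test_quadrature_pair_phase(self):
        # y ahead of x by a quarter cycle -> positive pi/2 phase (x lags y)
        x, y = _sine(), _sine(phase=np.pi / 2)
        res = wtc(x, y, PARAMS)
        j = np.argmin(np.abs(res.fourier_periods - 20.0))
        cells = res.in_coi[j]
        mean_phase = circular_mean(res.phase[j, cells])
        assert abs(mean_phase - np.pi / 2) < np.pi / 16

    def test_antiphase_pair(self):
        x, y = _sine(), _sine(phase=np.pi)
        res = wtc(x, y, PARAMS)
        j = np.argmin(np.abs(res.fourier_periods - 20.0))
        phases = np.abs(res.phase[j, res.in_coi[j]])
        assert np.all(np.abs(phases - np.pi) < np.pi / 16)

    def test_symmetry_and_antisymmetry(self):
        a = TimeCourse(gen_ar1_series(300, 0.3, 1.0, 4).samples, 3.01)
        b = TimeCourse(gen_ar1_series(300, 0.3, 1.0, 5).samples, 3.01)
        rab = wtc(a, b, PARAMS)
        rba = wtc(b, a, PARAMS)
        assert np.allclose(rab.coherence, rba.coherence, atol=1e-10)
        assert np.allclose(rab.phase, -rba.phase, atol=1e-8)

    def test_amplitude_invariance(self):
        a = TimeCourse(gen_ar1_series(300, 0.3, 1.0, 6).samples, 3.01)
        b = TimeCourse(gen_ar1_series(300, 0.3, 1.0, 7).samples, 3.01)
        r1 = wtc(a, b, PARAMS)
        r2 = wtc(a.with_samples(4.2 * a.samples),
                 b.with_samples(0.3 * b.samples), PARAMS)
        assert np.allclose(r1.coherence, r2.coherence, atol=1e-8)

    def test_constant_input_rejected(self):
        c = TimeCourse(np.ones(100), 1.0)
        x = TimeCourse(np.arange(100.0), 1.0)
        with pytest.raises(ValueError, match="constant"):
            wtc(c, x, PARAMS)


class TestFitAr1:
    def test_recovers_phi_sampling_distribution(self):
        hits = 0
        for seed in range(100):
            x = gen_ar1_series(800, 0.5, 1.0, seed)
            fit = fit_ar1(x)
            hits += 0.4 < fit.phi < 0.6
        assert hits >= 95

    def test_white_noise_phi_near_zero(self):
        x = gen_ar1_series(1000, 0.0, 1.0, 12)
        assert abs(fit_ar1(x).phi) < 0.1

    def test_linear_trend_flagged(self):
        tc = TimeCourse(np.linspace(0, 1, 500), 1.0)
        with pytest.warns(UserWarning, match="near 1"):
            fit = fit_ar1(tc)
        assert fit.phi > 0.95

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            fit_ar1(TimeCourse(np.ones(50), 1.0))


class TestMcSignificance:
    def test_thresholds_bounded_and_deterministic(self):
        x = gen_ar1_series(200, 0.4, 1.0, 1)
        fit = fit_ar1(x)
        thr1 = mc_significance(fit, fit, PARAMS, n=200, dt=3.01)
        thr2 = mc_significance(fit, fit, PARAMS, n=200, dt=3.01)
        assert np.array_equal(thr1, thr2)
        assert np.all((thr1 > 0) & (thr1 < 1))


class TestPhaseClassify:
    @pytest.mark.parametrize("angle,expected", [
        (0.0, "in_phase"),
        (np.pi, "antiphase"),
        (-np.pi, "antiphase"),          # normalised to pi
        (-np.pi / 2, "x_leads"),
        (np.pi / 2, "x_lags"),
        (0.2, "in_phase"),
        (2.9, "antiphase"),
        (5.0, "x_leads"),               # wraps to ~-1.28
    ])
    def test_cardinal_directions(self, angle, expected):
        assert phase_classify(angle) == expected


class TestSegmentPhaseSummary:
    def test_planted_offsets_recovered_per_segment(self):
        # three coherent segments with distinct offsets, snr 2, concatenated
        n_seg, dt, f = 200, 3.01, 0.05
        offsets = [np.pi, -np.pi / 2, 0.0]
        xs, ys = [], []
        for i, off in enumerate(offsets):
            x, y = gen_oscillatory_pair(n_seg, dt, f, off, snr=2.0,
                                        phi=0.3, seed=100 + i)
            xs.append(x.samples)
            ys.append(y.samples)
        bounds = [(0, 200), (200, 400), (400, 600)]
        X = TimeCourse(np.concatenate(xs), dt, segment_bounds=bounds)
        Y = TimeCourse(np.concatenate(ys), dt, segment_bounds=bounds)
        params = WcaParams(mc_n=300, seed=1)
        res = wtc(X, Y, params, significance=True)
        summary = segment_phase_summary(res, bounds,
                                        ["antiphase", "lead", "inphase"])
        recs = summary.to_records()
        assert [r["dominant_class"] for r in recs] == \
            ["antiphase", "x_leads", "in_phase"]
        for rec, off in zip(recs, offsets):
            err = np.angle(np.exp(1j * (rec["circular_mean_phase"] - off)))
            assert abs(err) < np.pi / 8

    def test_incoherent_segment_classified_none(self):
        # second segment: x keeps oscillating, y decouples into noise
        n_seg, dt = 200, 3.01
        x1, y1 = gen_oscillatory_pair(n_seg, dt, 0.05, 0.0, snr=2.0, seed=7)
        x2, _ = gen_oscillatory_pair(n_seg, dt, 0.05, 0.0, snr=2.0, seed=8)
        y2 = gen_ar1_series(n_seg, 0.3, 1.0, 9).samples
        bounds = [(0, 200), (200, 400)]
        X = TimeCourse(np.concatenate([x1.samples, x2.samples]), dt,
                       segment_bounds=bounds)
        Y = TimeCourse(np.concatenate([y1.samples, y2]), dt, segment_bounds=bounds)
        params = WcaParams(mc_n=300, seed=2)
        res = wtc(X, Y, params, significance=True)
        summary = segment_phase_summary(res, bounds, ["coh", "inc"])
        recs = summary.to_records()
        assert recs[0]["dominant_class"] == "in_phase"
        assert recs[1]["dominant_class"] == "none"
        assert recs[1]["sig_fraction"] < 2 * params.alpha + 1e-9
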