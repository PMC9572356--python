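"""Estimators: generative round trips, noise robustness, error contracts."""

import numpy as np
import pytest

from tdnmr import (
    EchoSeries,
    NoiseSpec,
    Phantom,
    RecoveryCurve,
    compare_m2_channels,
    fit_fid_rigid_mobile,
    fit_t1_sr,
    gen_fid,
    gen_se_series,
    gen_sr_curve,
    se_back_extrapolate,
)
from tdnmr.datasets import REFERENCE_M2_MSE, REFERENCE_M2_SE, SAMPLE_LABELS


class TestT1:
    @pytest.mark.parametrize("t1", [35.0, 50.0, 65.0])
    def test_noiseless_generative_identity(self, t1):
        res = fit_t1_sr(gen_sr_curve(t1))
        assert res.t1 == pytest.approx(t1, rel=1e-6)
        assert res.ci95[0] <= res.t1 <= res.ci95[1]
        assert res.quality.converged

    def test_monte_carlo_accuracy_at_snr50(self):
        errs = []
        for seed in range(50):
            curve = gen_sr_curve(50.0, noise=NoiseSpec(50.0, seed))
            errs.append(abs(fit_t1_sr(curve).t1 - 50.0) / 50.0)
        assert np.median(errs) < 0.05

    def test_input_contracts(self):
        with pytest.raises(ValueError, match="SR"):
            fit_t1_sr(RecoveryCurve(delays=[1, 2, 3, 4, 5],
                                    amplitudes=[0.1] * 5, kind="GS"))
        with pytest.raises(ValueError, match="5 points"):
            fit_t1_sr(RecoveryCurve(delays=[1, 2, 3],
                                    amplitudes=[0.1, 0.2, 0.3], kind="SR"))


class TestFidRigidMobile:
    def test_noiseless_recovery(self):
        ph = Phantom(rigid_fraction=0.6, m2_true=1.176e9)
        fit = fit_fid_rigid_mobile(gen_fid(ph))
        assert fit.m2.m2 == pytest.approx(1.176e9, rel=1e-3)
        assert fit.crystallinity_index == pytest.approx(0.600, abs=0.002)
        assert fit.quality.converged and not fit.degenerate

    def test_gaussian_only_limit(self):
        ph = Phantom(rigid_fraction=1.0, m2_true=9e8, b_over_a=0.0)
        fit = fit_fid_rigid_mobile(gen_fid(ph))
        assert fit.m2.m2 == pytest.approx(9e8, rel=1e-6)
        assert fit.crystallinity_index == pytest.approx(1.0, abs=1e-6)

    def test_ordering_preserved_across_m2_span(self):
        fitted = []
        for m2 in (8.55e8, 9.21e8, 10.92e8, 11.76e8, 12.02e8):
            fit = fit_fid_rigid_mobile(gen_fid(Phantom(m2_true=m2)))
            fitted.append(fit.m2.m2)
        assert np.all(np.diff(fitted) > 0)

    def test_crystallinity_invariant_under_rescaling(self):
        ph = Phantom(rigid_fraction=0.4)
        fid = gen_fid(ph)
        scaled = gen_fid(ph)
        scaled.amplitudes = scaled.amplitudes * 37.5
        a = fit_fid_rigid_mobile(fid).crystallinity_index
        b = fit_fid_rigid_mobile(scaled).crystallinity_index
        assert a == pytest.approx(b, rel=1e-6)

    def test_low_noise_bias(self):
        ph = Phantom(rigid_fraction=0.6, m2_true=1.176e9)
        m2s = [
            fit_fid_rigid_mobile(gen_fid(ph, noise=NoiseSpec(100.0, s))).m2.m2
            for s in range(20)
        ]
        assert abs(np.mean(m2s) / 1.176e9 - 1) < 0.02

    def test_deterministic_given_seed(self):
        fid = gen_fid(Phantom(), noise=NoiseSpec(100.0, 3))
        a = fit_fid_rigid_mobile(fid, seed=1)
        b = fit_fid_rigid_mobile(fid, seed=1)
        assert a.m2.m2 == b.m2.m2

    def test_too_few_points_rejected(self):
        fid = gen_fid(Phantom(), n_points=32)
        fid.times, fid.amplitudes = fid.times[:16], fid.amplitudes[:16]
        with pytest.raises(ValueError):
            fit_fid_rigid_mobile(fid)


class TestSeBackExtrapolation:
    def test_noiseless_generative_identity(self):
        ph = Phantom(rigid_fraction=0.3, m2_true=9e8)
        res = se_back_extrapolate(gen_se_series(ph, np.geomspace(4, 100, 10)))
        assert res.m2 == pytest.approx(9e8, rel=1e-9)
        assert res.a0 == pytest.approx(1.0, rel=1e-9)

    def test_flat_series_gives_zero_m2(self):
        series = EchoSeries(taus=[5.0, 10.0, 15.0, 20.0], amplitudes=[0.8] * 4)
        res = se_back_extrapolate(series)
        assert res.m2 == 0.0
        assert res.a0 == pytest.approx(0.8)
        assert not res.flagged

    def test_grossly_rising_series_rejected(self):
        series = EchoSeries(taus=[5.0, 10.0, 15.0, 20.0],
                            amplitudes=[0.5, 1.0, 0.4, 0.3])
        with pytest.raises(ValueError, match="rise"):
            se_back_extrapolate(series)

    def test_slowly_rising_series_flagged_negative_m2(self):
        taus = np.array([5.0, 10.0, 15.0, 20.0, 25.0, 30.0])
        series = EchoSeries(taus=taus, amplitudes=1.0 + 0.004 * taus)
        res = se_back_extrapolate(series)
        assert res.flagged and res.m2 < 0

    def test_zero_delay_amplitude_bias_at_snr100(self):
        ph = Phantom(rigid_fraction=0.3, m2_true=9e8)
        a0s = [
            se_back_extrapolate(
                gen_se_series(ph, np.linspace(6, 20, 6), noise=NoiseSpec(100.0, s))
            ).a0
            for s in range(100)
        ]
        assert abs(np.mean(a0s) - 1.0) < 0.02

    def test_agrees_with_fid_channel(self):
        # SE back-extrapolation and the FID decomposition see the same M2
        for m2 in (9e8, 1.1e9, 1.2e9):
            ph = Phantom(rigid_fraction=0.35, m2_true=m2)
            se_m2 = se_back_extrapolate(gen_se_series(ph, np.geomspace(4, 100, 10))).m2
            fid_m2 = fit_fid_rigid_mobile(gen_fid(ph)).m2.m2
            assert se_m2 == pytest.approx(fid_m2, rel=0.05)


class TestCompareChannels:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert compare_m2_channels(x, x).r == pytest.approx(1.0)
        assert compare_m2_channels(x, x[::-1]).r < 0

    def test_reference_benchmark_correlation(self):
        se = [REFERENCE_M2_SE[s] for s in SAMPLE_LABELS]
        mse = [REFERENCE_M2_MSE[s] for s in SAMPLE_LABELS]
        res = compare_m2_channels(se, mse)
        assert res.r >= 0.9
        assert res.p_value < 0.05
        assert res.n == 10

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compare_m2_channels([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
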