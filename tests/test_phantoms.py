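"""Phantom generators and the 1D lamellar spin-diffusion simulator."""

import math

import numpy as np
import pytest

from tdnmr import (
    DiffusionGrid,
    FixtureConfig,
    NoiseSpec,
    Phantom,
    default_mixing_times,
    export_fixture_set,
    gen_fid,
    gen_se_series,
    gen_sr_curve,
    simulate_goldman_shen,
)


def fourier_long_component(ph: Phantom, t_ms: np.ndarray, n_terms: int = 4000):
    """Closed-form Fourier-series solution for the mobile-phase integral on
    the periodic lamellar cell; independent oracle for the FTCS scheme."""
    w, d, diff = ph.mobile_width_nm, ph.d_true, ph.dsd_true
    period = w + d
    t_s = np.asarray(t_ms, dtype=float) * 1e-3
    k = np.arange(1, n_terms + 1)
    sin2 = np.sin(np.pi * k * w / period) ** 2
    rates = diff * (2 * np.pi * k / period) ** 2
    series = (2 * period / (np.pi**2 * k**2)) * sin2
    mobile_mass = w**2 / period + series @ np.exp(-np.outer(rates, t_s))
    return mobile_mass / w


class TestGenFid:
    def test_mobile_only_is_pure_exponential(self):
        ph = Phantom(rigid_fraction=0.0, t2_mobile=400.0)
        fid = gen_fid(ph, dwell=2.0, n_points=64)
        np.testing.assert_allclose(
            fid.amplitudes, np.exp(-fid.times / 400.0), rtol=1e-12)

    def test_rigid_gaussian_identity(self):
        ph = Phantom(rigid_fraction=1.0, m2_true=9e8, b_over_a=0.0)
        fid = gen_fid(ph, n_points=64)
        ts = fid.times * 1e-6
        np.testing.assert_allclose(fid.amplitudes, np.exp(-4.5e8 * ts**2), rtol=1e-12)

    def test_seeding_contract(self):
        ph = Phantom()
        a = gen_fid(ph, noise=NoiseSpec(100.0, 42))
        b = gen_fid(ph, noise=NoiseSpec(100.0, 42))
        c = gen_fid(ph, noise=NoiseSpec(100.0, 43))
        np.testing.assert_array_equal(a.amplitudes, b.amplitudes)
        assert not np.array_equal(a.amplitudes, c.amplitudes)

    def test_rejects_bad_acquisition(self):
        with pytest.raises(ValueError):
            gen_fid(Phantom(), dead_time=-1.0)
        with pytest.raises(ValueError):
            gen_fid(Phantom(), n_points=8)


class TestGenSr:
    def test_analytic_points(self):
        curve = gen_sr_curve(50.0, delays=np.array([1e-9, 50.0, 5000.0]))
        assert curve.amplitudes[0] == pytest.approx(0.0, abs=1e-9)
        assert curve.amplitudes[1] == pytest.approx(1 - math.exp(-1), rel=1e-12)
        assert curve.amplitudes[2] == pytest.approx(1.0, rel=1e-12)

    def test_short_window_warns(self):
        with pytest.warns(UserWarning, match="3\\*T1"):
            gen_sr_curve(200.0, delays=np.linspace(1, 300, 10))

    def test_rejects_nonpositive_t1(self):
        with pytest.raises(ValueError):
            gen_sr_curve(0.0)


class TestGenSe:
    def test_zero_delay_limit_and_monotonicity(self):
        ph = Phantom(rigid_fraction=0.3, m2_true=9e8)
        series = gen_se_series(ph, tau_list=np.geomspace(0.01, 50, 12))
        assert series.amplitudes[0] == pytest.approx(1.0, rel=1e-4)
        assert np.all(np.diff(series.amplitudes) < 0)

    def test_rigid_attenuation_factor(self):
        # at tau = 10 us and M2 = 9e8 Hz^2 the rigid factor is exp(-0.18)
        ph = Phantom(rigid_fraction=0.5, m2_true=9e8)
        series = gen_se_series(ph, tau_list=np.array([5.0, 10.0, 15.0, 20.0]))
        rigid = series.amplitudes[1] - 0.5
        assert rigid == pytest.approx(0.5 * math.exp(-0.18), rel=1e-12)


class TestGoldmanShen:
    PH = Phantom(d_true=5.0)

    def test_initial_condition_and_conservation(self):
        t = default_mixing_times(self.PH, n=12)
        curve = simulate_goldman_shen(self.PH, t)
        assert curve.amplitudes[0] == pytest.approx(1.0, abs=1e-12)
        assert curve.meta["total_drift"] < 1e-6

    def test_equilibrium_limit(self):
        # t >> (d+W)^2 / D relaxes to the uniform distribution W/(d+W)
        ph = Phantom(d_true=5.0, mobile_width=15.0)
        t_eq = 20.0**2 / ph.dsd_true * 1e3 * 3
        curve = simulate_goldman_shen(ph, [t_eq])
        assert curve.amplitudes[-1] == pytest.approx(15.0 / 20.0, rel=1e-4)

    def test_early_time_sqrt_law(self):
        """1 - L grows like sqrt(t): log-log slope 0.5 +/- 0.05."""
        t_nom = math.pi * self.PH.mobile_width_nm**2 / (4 * self.PH.dsd_true) * 1e3
        t = np.geomspace(t_nom / 500, t_nom / 50, 10)
        curve = simulate_goldman_shen(self.PH, t)
        slope = np.polyfit(np.log(t), np.log(1 - curve.amplitudes), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_fourier_series_oracle(self):
        t = default_mixing_times(self.PH, n=10)[1:]
        curve = simulate_goldman_shen(self.PH, t)
        np.testing.assert_allclose(
            curve.amplitudes, fourier_long_component(self.PH, t), rtol=5e-3)

    def test_grid_convergence(self):
        t = default_mixing_times(self.PH, n=8)[1:]
        coarse = simulate_goldman_shen(
            self.PH, t, grid=DiffusionGrid.for_phantom(self.PH, n_cells=96))
        fine = simulate_goldman_shen(
            self.PH, t, grid=DiffusionGrid.for_phantom(self.PH, n_cells=192))
        assert np.max(np.abs(fine.amplitudes / coarse.amplitudes - 1)) < 5e-3

    def test_unstable_grid_rejected(self):
        with pytest.raises(ValueError, match="unstable"):
            DiffusionGrid(n_cells=64, dx=0.1, dt=1.0, dsd=1.5e3)

    def test_short_component_complements_long(self):
        t = default_mixing_times(self.PH, n=8)
        curve = simulate_goldman_shen(self.PH, t)
        total = curve.meta["long_component_clean"] + curve.meta["short_component"]
        np.testing.assert_allclose(total, 1.0, rtol=1e-9)

    def test_t1_decay_option(self):
        t = default_mixing_times(self.PH, n=6)[1:]
        plain = simulate_goldman_shen(self.PH, t)
        decayed = simulate_goldman_shen(self.PH, t, apply_t1=True)
        np.testing.assert_allclose(
            decayed.amplitudes,
            plain.amplitudes * np.exp(-t / self.PH.t1_true), rtol=1e-9)


class TestFixtureExport:
    def test_byte_identical_for_same_seed(self, tmp_path):
        roster = {"SCG40-30": Phantom(m2_true=11.76e8, seed=5)}
        dirs = []
        for name in ("a", "b"):
            out = tmp_path / name
            export_fixture_set(FixtureConfig(
                out_dir=out, seed=7, n_replicates=2, fid_snr=100.0,
                curve_snr=50.0, phantoms=roster))
            dirs.append(out)
        files = sorted(p.name for p in dirs[0].iterdir())
        assert files == sorted(p.name for p in dirs[1].iterdir())
        for name in files:
            assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()

    def test_manifest_lists_all_samples(self, candy_fixture_dir):
        out, manifest = candy_fixture_dir
        assert len(manifest["samples"]) == 10
        for entry in manifest["samples"].values():
            for rep_files in entry["replicates"].values():
                for fname in rep_files.values():
                    assert (out / fname).exists()
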