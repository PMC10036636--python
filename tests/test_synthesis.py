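"""MUAP assembly, EMG superposition, montages and features."""

import warnings

import numpy as np
import pytest
from scipy import stats

from myosim import anatomy as A
from myosim import recruitment as R
from myosim import synthesis as SY
from myosim.sources import SourceParams
from myosim.synthesis import EMGRecording


def _single_fibre_pool(xy, pool_seed=0, **phys):
    fib = A.straight_fibre(
        start=np.array([xy[0], xy[1], -0.07]),
        direction=np.array([0.0, 0.0, 1.0]),
        length=0.14,
        **phys,
    )
    return A.MusclePool(
        muscle_id=0,
        fibres=[fib],
        motor_units=[A.MotorUnit(id=0, fibre_indices=np.array([0]))],
    )


class TestMUAP:
    def test_single_fibre_muap_equals_fibre_response(self, phantom_op):
        from myosim.sources import fibre_emg

        cfg, op = phantom_op
        pool = _single_fibre_pool((0.012, 0.0))
        params = SourceParams()
        transfers = [op.potentials_at(pool.fibres[0].points)]
        muap = SY.compute_muap(0, pool, transfers, params)
        times = params.time_grid(muap.waveform.shape[1] / params.fs)
        direct = fibre_emg(transfers[0], pool.fibres[0], params, times)
        assert np.allclose(muap.waveform, direct)

    def test_muap_linear_in_fibre_count(self, phantom_op):
        cfg, op = phantom_op
        fib = A.straight_fibre(
            start=np.array([0.012, 0.0, -0.07]),
            direction=np.array([0.0, 0.0, 1.0]),
            length=0.14,
        )
        transfers = [op.potentials_at(fib.points)] * 2
        single = A.MusclePool(0, [fib], [A.MotorUnit(0, np.array([0]))])
        double = A.MusclePool(0, [fib, fib], [A.MotorUnit(0, np.array([0, 1]))])
        params = SourceParams()
        m1 = SY.compute_muap(0, single, [transfers[0]], params)
        m2 = SY.compute_muap(0, double, transfers, params)
        assert np.allclose(m2.waveform, 2 * m1.waveform)

    def test_superficial_mu_larger_than_deep_on_nearest_channel(self, phantom_op):
        """Volume-conductor attenuation: the same MU moved deeper loses
        peak-to-peak amplitude on the closest electrode."""
        cfg, op = phantom_op
        params = SourceParams()
        amps = []
        for rho in (0.018, 0.010):  # 2 mm vs 10 mm below the muscle surface
            pool = _single_fibre_pool((rho, 0.0))
            transfers = [op.potentials_at(pool.fibres[0].points)]
            muap = SY.compute_muap(0, pool, transfers, params)
            ptp = np.ptp(muap.waveform, axis=1).max()
            amps.append(ptp)
        assert amps[0] > amps[1]

    def test_empty_mu_rejected(self, phantom_op):
        pool = _single_fibre_pool((0.012, 0.0))
        pool.motor_units[0] = A.MotorUnit(0, np.array([], dtype=int))
        with pytest.raises(ValueError, match="no fibres"):
            SY.compute_muap(0, pool, [np.ones((16, 281))], SourceParams())


class TestSynthesis:
    def _muap(self, n_e=4, width=40, fs=2000.0):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(n_e, width)) * np.hanning(width)
        return SY.MUAPTemplate(mu_id=0, waveform=w, fs=fs)

    def test_empty_spike_trains_give_silence(self):
        rec = SY.synthesize_emg(
            R.SpikeTrainSet([np.array([])]), [self._muap()], 2000.0, 0.5
        )
        assert np.all(rec.signal == 0)
        assert rec.n_samples == 1000

    def test_single_discharge_places_template(self):
        m = self._muap()
        rec = SY.synthesize_emg(
            R.SpikeTrainSet([np.array([0.1])]), [m], 2000.0, 0.5
        )
        start = int(round(0.1 * 2000))
        assert np.allclose(rec.signal[:, start : start + 40], m.waveform)
        mask = np.ones(rec.n_samples, bool)
        mask[start : start + 40] = False
        assert np.all(rec.signal[:, mask] == 0)

    def test_superposition_of_two_trains(self):
        m = self._muap()
        t1 = R.SpikeTrainSet([np.array([0.1])])
        t2 = R.SpikeTrainSet([np.array([0.11])])
        both = R.SpikeTrainSet([np.array([0.1, 0.11])])
        a = SY.synthesize_emg(t1, [m], 2000.0, 0.5).signal
        b = SY.synthesize_emg(t2, [m], 2000.0, 0.5).signal
        c = SY.synthesize_emg(both, [m], 2000.0, 0.5).signal
        assert np.allclose(c, a + b)

    def test_late_discharge_truncated_with_warning(self):
        m = self._muap()
        with pytest.warns(UserWarning, match="truncated"):
            rec = SY.synthesize_emg(
                R.SpikeTrainSet([np.array([0.495])]), [m], 2000.0, 0.5
            )
        assert rec.n_samples == 1000

    def test_rms_increases_with_excitation_on_nearest_channel(self, phantom_sim):
        """Trapezoid drive to 100% MVC: windowed RMS on the channel
        nearest the muscle tracks the drive level (Spearman > 0.9)."""
        sim = phantom_sim
        drive = R.trapezoid_drive(peak=1.0, ramp_s=1.6, plateau_s=0.8)
        model = R.RecruitmentModel.default(sim._pool.n_motor_units, rng_seed=2)
        rec, spikes = sim.run(drive, model)
        sd = SY.apply_montage(rec, "single-differential")
        window_s = 0.2
        rms = SY.rms_per_channel(sd, window_s)
        ch = int(np.argmax(rms.max(axis=1)))  # nearest channel: largest RMS
        t_win = (np.arange(rms.shape[1]) + 0.5) * window_s
        level = drive.at(t_win)
        up = t_win < 1.6  # up-ramp windows: drive level strictly increasing
        rho = stats.spearmanr(level[up], rms[ch][up]).statistic
        assert rho > 0.9


class TestMontage:
    def test_sixteen_electrodes_yield_fifteen_differential_channels(self):
        rec = EMGRecording(np.random.default_rng(0).normal(size=(16, 100)), 2000.0)
        sd = SY.apply_montage(rec, "single-differential")
        assert sd.n_channels == 15

    def test_double_differential_yields_fourteen(self):
        rec = EMGRecording(np.zeros((16, 10)), 2000.0)
        assert SY.apply_montage(rec, "double-differential").n_channels == 14

    def test_common_offset_invisible_to_differential(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 200))
        rec = EMGRecording(x, 2000.0)
        rec_off = EMGRecording(x + 3.7, 2000.0)
        a = SY.apply_montage(rec, "single-differential").signal
        b = SY.apply_montage(rec_off, "single-differential").signal
        assert np.allclose(a, b)

    def test_bipolar_pairs(self):
        x = np.arange(12, dtype=float).reshape(6, 2)
        rec = EMGRecording(x, 2000.0)
        bp = SY.apply_montage(rec, "bipolar", pairs=[(0, 3), (5, 1)])
        assert bp.n_channels == 2
        assert np.allclose(bp.signal[0], x[0] - x[3])

    def test_missing_electrode_in_pairs_rejected(self):
        rec = EMGRecording(np.zeros((4, 10)), 2000.0)
        with pytest.raises(ValueError, match="missing electrode"):
            SY.apply_montage(rec, "bipolar", pairs=[(0, 7)])


class TestFeatures:
    def test_rms_of_constant_signal(self):
        rec = EMGRecording(np.full((2, 1000), -3.0), 1000.0)
        assert np.allclose(SY.rms_per_channel(rec, 0.1), 3.0)

    def test_rms_of_zero_signal(self):
        rec = EMGRecording(np.zeros((1, 100)), 1000.0)
        assert np.all(SY.rms_per_channel(rec, 0.01) == 0)

    def test_rms_of_unit_sine_over_whole_periods(self):
        fs = 1000.0
        t = np.arange(2000) / fs
        rec = EMGRecording(np.sin(2 * np.pi * 10 * t)[None, :], fs)
        rms = SY.rms_per_channel(rec, 0.5)  # 5 whole periods per window
        assert np.allclose(rms, 1 / np.sqrt(2), atol=1e-6)

    def test_long_window_falls_back_with_warning(self):
        rec = EMGRecording(np.ones((1, 100)), 1000.0)
        with pytest.warns(UserWarning, match="window"):
            rms = SY.rms_per_channel(rec, 1.0)
        assert rms.shape == (1, 1)

    def test_spectrum_peaks_at_tone_frequency(self):
        fs = 2000.0
        t = np.arange(4000) / fs
        rec = EMGRecording(np.sin(2 * np.pi * 120 * t)[None, :], fs)
        freqs, power = SY.power_spectrum(rec, 0)
        assert freqs[np.argmax(power)] == pytest.approx(120.0, abs=0.5)

    def test_spectrum_parseval_consistency(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(1, 1537))  # odd length exercises the Nyquist branch
        rec = EMGRecording(x, 2000.0)
        _, power = SY.power_spectrum(rec, 0)
        assert power.sum() == pytest.approx((x**2).sum() / x.shape[1], rel=1e-9)

    def test_white_noise_spectrum_is_flat_on_average(self):
        rng = np.random.default_rng(11)
        fs, n = 1000.0, 1024
        avg = np.zeros(n // 2 + 1)
        for _ in range(100):
            rec = EMGRecording(rng.normal(size=(1, n)), fs)
            _, p = SY.power_spectrum(rec, 0)
            avg += p
        avg /= 100
        interior = avg[1:-1]
        assert interior.std() / interior.mean() < 0.15

    def test_invalid_channel_rejected(self):
        rec = EMGRecording(np.zeros((2, 64)), 1000.0)
        with pytest.raises(ValueError, match="channel"):
            SY.power_spectrum(rec, 5)


class TestStagedReuse:
    def test_changing_anatomy_and_drive_triggers_no_new_solves(self, phantom_sim):
        """The staged-reuse contract: new MU distributions, fibre
        physiology or drives must not re-solve the forward problem."""
        from myosim import forward as F

        sim = phantom_sim
        before = F.solve_counter.count
        # new drive
        sim.run(R.trapezoid_drive(peak=0.6, ramp_s=0.3, plateau_s=0.2))
        # new recruitment model
        sim.run(
            R.trapezoid_drive(peak=0.4, ramp_s=0.3, plateau_s=0.2),
            R.RecruitmentModel.default(sim._pool.n_motor_units, isi_cov=0.05),
        )
        # new MU distribution over the same fibres (transfers reused)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pop = A.UnitCirclePopulation.generate(
                n_fibres=300, n_mu=8, size_min=5, size_max=80, rng_seed=21
            )
            geom = A.MuscleGeometry(
                section=A.AnnularSectorSection(0.0095, 0.0185, -0.6, 0.6),
                length=0.14,
                origin=(0.0, 0.0, -0.07),
            )
            pool2 = A.morph_to_muscle(pop, geom, rng_seed=22)
        sim2 = type(sim)(sim.forward_op, sim.source_params)
        sim2.set_pool(pool2)
        sim2.run(R.trapezoid_drive(peak=0.8, ramp_s=0.3, plateau_s=0.2))
        assert F.solve_counter.count == before

    def test_emg_superposition_of_drives(self, phantom_sim):
        """EMG is linear: two MU subsets simulated jointly equal the sum
        of their separate recordings (identical seeds)."""
        sim = phantom_sim
        muaps = sim.muaps()
        n_mu = len(muaps)
        model = R.RecruitmentModel.default(n_mu, isi_cov=0.1, rng_seed=5)
        drive = R.trapezoid_drive(peak=0.9, ramp_s=0.4, plateau_s=0.3)
        rec, spikes = sim.run(drive, model)
        half = n_mu // 2
        a = SY.synthesize_emg(
            R.SpikeTrainSet(spikes.trains[:half]), muaps[:half], rec.fs, rec.duration
        )
        b = SY.synthesize_emg(
            R.SpikeTrainSet(spikes.trains[half:]), muaps[half:], rec.fs, rec.duration
        )
        assert np.allclose(a.signal + b.signal, rec.signal, atol=1e-12)
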