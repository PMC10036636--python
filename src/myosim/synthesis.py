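"""MUAP assembly, surface-EMG synthesis, montages and signal features.

A motor-unit action potential (MUAP) template is the sum of the
single-fibre responses of the MU's fibres, computed once per MU from the
per-fibre transfer potentials.  The surface EMG is then the
shift-and-add superposition of each MU's template at its discharge
times (snapped to the nearest sample), summed over motor units and over
muscles.  This convolutional assembly is what makes re-simulation with
new drives cheap: templates and transfers are reused, and no forward
solve is ever repeated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import MusclePool
from .recruitment import SpikeTrainSet
from .sources import SourceParams, fibre_emg

__all__ = [
    "MUAPTemplate",
    "EMGRecording",
    "compute_muap",
    "compute_muaps",
    "synthesize_emg",
    "apply_montage",
    "rms_per_channel",
    "power_spectrum",
]


@dataclass
class MUAPTemplate:
    """Electrode waveform of one MU discharge.

    ``waveform`` is (n_e, n_t) in mV at ``fs``; ``onset_sample`` is the
    sample index aligned with the discharge instant (0: the discharge
    starts the template).
    """

    mu_id: int
    waveform: np.ndarray
    fs: float
    onset_sample: int = 0

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("MUAP waveform must be finite")


@dataclass
class EMGRecording:
    """Multichannel sampled EMG with montage metadata."""

    signal: np.ndarray  # (n_channels, n_samples), mV
    fs: float
    montage: str = "monopolar"
    channel_names: list | None = None

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.channel_names is not None and len(self.channel_names) != len(self.signal):
            raise ValueError("channel metadata inconsistent with channel count")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def save(self, path, spikes: SpikeTrainSet | None = None, muaps=None) -> None:
        """HDF5 container: signal, fs, montage, optional spike trains and
        MUAP templates (the simulation metadata)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=self.signal)
            f.attrs["fs"] = self.fs
            f.attrs["montage"] = self.montage
            if spikes is not None:
                grp = f.create_group("spike_trains")
                for i, tr in enumerate(spikes.trains):
                    grp.create_dataset(str(i), data=tr)
            if muaps is not None:
                grp = f.create_group("muaps")
                for m in muaps:
                    d = grp.create_dataset(str(m.mu_id), data=m.waveform)
                    d.attrs["onset_sample"] = m.onset_sample


def compute_muap(
    mu_index: int,
    pool: MusclePool,
    transfers: np.ndarray | list,
    params: SourceParams,
    duration: float | None = None,
) -> MUAPTemplate:
    """Sum the fibre responses of one MU into a template.

    ``transfers`` holds one (n_e, n_z) transfer matrix per fibre of the
    pool (from ``ForwardOperator.potentials_at`` on each fibre's
    samples).  Template length covers the slowest fibre's propagation
    plus the source tail unless ``duration`` is given.
    """
    mu = pool.motor_units[mu_index]
    idx = np.asarray(mu.fibre_indices, dtype=int)
    if idx.size == 0:
        raise ValueError(f"motor unit {mu_index} has no fibres")
    if duration is None:
        dur = max(
            (max(pool.fibres[i].L1, pool.fibres[i].L2) + 0.02) / pool.fibres[i].velocity
            for i in idx
        )
    else:
        dur = duration
    times = params.time_grid(dur)
    wave = None
    for i in idx:
        contrib = fibre_emg(transfers[i], pool.fibres[i], params, times)
        wave = contrib if wave is None else wave + contrib
    return MUAPTemplate(mu_id=mu.id, waveform=wave, fs=params.fs)


def compute_muaps(pool, transfers, params, duration=None) -> list:
    common = duration
    if common is None:
        # shared template length so synthesis can reuse one time grid
        common = max(
            (max(f.L1, f.L2) + 0.02) / f.velocity for f in pool.fibres
        )
    return [
        compute_muap(m, pool, transfers, params, duration=common)
        for m in range(pool.n_motor_units)
    ]


def synthesize_emg(
    spikes: SpikeTrainSet,
    muaps: list,
    fs: float,
    duration: float,
) -> EMGRecording:
    """Shift-and-add superposition of MUAP templates at discharge times.

    Discharges snap to the nearest sample; templates extending past the
    recording end are truncated (with a warning).  Multiple muscles are
    summed by calling this per muscle and adding recordings, or by
    concatenating their spike trains and templates.
    """
    if not muaps:
        raise ValueError("no MUAP templates given")
    n_e = muaps[0].waveform.shape[0]
    if any(m.waveform.shape[0] != n_e or m.fs != fs for m in muaps):
        raise ValueError("all MUAPs must share the electrode set and fs")
    if spikes.n_mu != len(muaps):
        raise ValueError("one spike train per MUAP template required")
    n = int(round(duration * fs))
    out = np.zeros((n_e, n))
    truncated = 0
    for train, m in zip(spikes.trains, muaps):
        w = m.waveform
        lw = w.shape[1]
        for t in train:
            start = int(round(t * fs)) - m.onset_sample
            if start >= n:
                truncated += 1
                continue
            stop = min(start + lw, n)
            if stop <= 0:
                continue
            lo = max(-start, 0)
            out[:, max(start, 0) : stop] += w[:, lo : lo + (stop - max(start, 0))]
            if start + lw > n:
                truncated += 1
    if truncated:
        import warnings

        warnings.warn(f"{truncated} discharges truncated at the recording end")
    return EMGRecording(out, fs)


def apply_montage(rec: EMGRecording, montage, pairs=None) -> EMGRecording:
    """Derive a channel montage from monopolar channels.

    ``montage``: "monopolar" (passthrough), "single-differential"
    (ch_k = e_{k+1} - e_k, n-1 channels), "double-differential"
    (n-2 channels), or "bipolar" with explicit ``pairs`` [(i, j), ...]
    giving ch = e_i - e_j.
    """
    x = rec.signal
    if montage == "monopolar":
        return EMGRecording(x.copy(), rec.fs, "monopolar")
    if montage == "single-differential":
        return EMGRecording(x[1:] - x[:-1], rec.fs, "single-differential")
    if montage == "double-differential":
        sd = x[1:] - x[:-1]
        return EMGRecording(sd[1:] - sd[:-1], rec.fs, "double-differential")
    if montage == "bipolar":
        if not pairs:
            raise ValueError("bipolar montage requires electrode pairs")
        for i, j in pairs:
            if not (0 <= i < rec.n_channels and 0 <= j < rec.n_channels):
                raise ValueError(f"montage references missing electrode ({i}, {j})")
        return EMGRecording(
            np.stack([x[i] - x[j] for i, j in pairs]), rec.fs, "bipolar"
        )
    raise ValueError(f"unknown montage {montage!r}")


def rms_per_channel(rec: EMGRecording, window_s: float) -> np.ndarray:
    """Windowed root-mean-square feature, (n_channels, n_windows)."""
    if window_s <= 0:
        raise ValueError("window length must be positive")
    w = int(round(window_s * rec.fs))
    if w > rec.n_samples:
        import warnings

        warnings.warn("window longer than the recording; using one full window")
        w = rec.n_samples
    n_win = rec.n_samples // w
    x = rec.signal[:, : n_win * w].reshape(rec.n_channels, n_win, w)
    return np.sqrt((x**2).mean(axis=2))


def power_spectrum(rec: EMGRecording, channel: int) -> tuple:
    """One-sided periodogram (boxcar window) of one channel.

    Returns (freqs, power) normalized so that ``sum(power)`` equals the
    signal energy divided by the sample count (Parseval-consistent):
    power_k = c_k |X_k|^2 / N^2 with c_k = 2 except at DC and Nyquist.
    """
    if not 0 <= channel < rec.n_channels:
        raise ValueError(f"channel {channel} out of range")
    x = rec.signal[channel]
    n = len(x)
    if n == 0:
        raise ValueError("empty recording")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    coef = np.full(len(power), 2.0)
    coef[0] = 1.0
    if n % 2 == 0:
        coef[-1] = 1.0
    power = power * coef
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs)
    return freqs, power
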