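"""Motor-unit recruitment and discharge-train generation.

Excitation drives (fraction of maximum voluntary contraction, MVC, over
time) are converted into per-MU spike trains in three steps:

1. size-principle thresholds: MU ``i`` of ``n`` is recruited when the
   drive exceeds ``thr_i = thr_min (thr_max/thr_min)^((i-1)/(n-1))`` —
   the exponentially spaced threshold ladder of the classical
   Fuglevand pool, with the last MU recruited exactly at ``thr_max``
   (default 0.75 MVC, so a 75% MVC drive activates the whole pool);

2. rate coding: linear with saturation, ``rate = rate_min +
   slope (e - thr)`` clipped to ``[rate_min, rate_max]`` (defaults 8 and
   35 Hz); the default slope reaches saturation 0.25 MVC above
   threshold;

3. discharge times: the instantaneous rate is integrated; each
   inter-spike interval is perturbed by a unit-mean truncated-normal
   multiplier with the configured coefficient of variation, floored at a
   3 ms refractory interval.  Each MU uses a deterministic substream of
   the master seed, so adding MUs never perturbs existing trains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExcitationDrive",
    "ramp_plateau_drive",
    "trapezoid_drive",
    "RecruitmentModel",
    "assign_thresholds",
    "firing_rate",
    "SpikeTrainSet",
    "generate_spike_trains",
]


@dataclass
class ExcitationDrive:
    """Excitation e(t) in [0, 1] (fraction of MVC) for one muscle."""

    muscle_id: int
    times: np.ndarray
    excitation: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=float)
        if self.times.shape != self.excitation.shape:
            raise ValueError("times and excitation must have equal shape")
        if not np.all(np.isfinite(self.excitation)):
            raise ValueError("excitation must be finite")
        self.excitation = np.clip(self.excitation, 0.0, 1.0)

    @property
    def duration(self) -> float:
        return float(self.times[-1])

    def at(self, t) -> np.ndarray:
        return np.interp(t, self.times, self.excitation)

    @classmethod
    def from_csv(cls, path, muscle_id: int = 0, column: str | None = None):
        import pandas as pd

        df = pd.read_csv(path)
        tcol = df.columns[0]
        ecol = column or df.columns[1]
        return cls(muscle_id, df[tcol].to_numpy(), df[ecol].to_numpy())


def trapezoid_drive(
    peak: float = 1.0,
    ramp_s: float = 0.5,
    plateau_s: float = 1.0,
    muscle_id: int = 0,
    rate: float = 1000.0,
    lead_s: float = 0.0,
) -> ExcitationDrive:
    """Ramp up - hold - ramp down drive (the standard contraction profile)."""
    total = lead_s + 2 * ramp_s + plateau_s
    t = np.arange(0.0, total + 1.0 / rate, 1.0 / rate)
    e = np.interp(
        t,
        [0.0, lead_s, lead_s + ramp_s, lead_s + ramp_s + plateau_s, total],
        [0.0, 0.0, peak, peak, 0.0],
    )
    return ExcitationDrive(muscle_id, t, e)


def ramp_plateau_drive(
    peak: float = 1.0, ramp_s: float = 1.0, plateau_s: float = 1.0, muscle_id: int = 0,
    rate: float = 1000.0,
) -> ExcitationDrive:
    t = np.arange(0.0, ramp_s + plateau_s + 1.0 / rate, 1.0 / rate)
    e = np.minimum(t / ramp_s, 1.0) * peak
    return ExcitationDrive(muscle_id, t, e)


def assign_thresholds(
    n_mu: int, max_threshold: float = 0.75, min_threshold: float = 0.005
) -> np.ndarray:
    """Exponentially spaced recruitment thresholds (fractions of MVC)."""
    if n_mu < 1:
        raise ValueError("n_mu must be >= 1")
    if not (0 < min_threshold < max_threshold <= 1):
        raise ValueError("thresholds must satisfy 0 < min < max <= 1")
    if n_mu == 1:
        return np.array([min_threshold])
    i = np.arange(n_mu)
    return min_threshold * (max_threshold / min_threshold) ** (i / (n_mu - 1))


@dataclass
class RecruitmentModel:
    """Thresholds plus rate-coding and variability parameters."""

    thresholds: np.ndarray
    rate_min: float = 8.0
    rate_max: float = 35.0
    slope: float | None = None  # Hz per unit excitation; default saturates
    # 0.25 MVC above threshold
    isi_cov: float = 0.15
    refractory_s: float = 0.003
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be non-decreasing (size principle)")
        if not (0 < self.rate_min <= self.rate_max):
            raise ValueError("rates must satisfy 0 < rate_min <= rate_max")
        if self.isi_cov < 0:
            raise ValueError("ISI coefficient of variation must be >= 0")
        if self.slope is None:
            self.slope = (self.rate_max - self.rate_min) / 0.25

    @property
    def n_mu(self) -> int:
        return len(self.thresholds)

    @classmethod
    def default(cls, n_mu: int, **kw) -> "RecruitmentModel":
        return cls(assign_thresholds(n_mu), **kw)


def firing_rate(e, model: RecruitmentModel, mu: int):
    """Instantaneous firing rate (Hz) of MU ``mu`` at excitation ``e``."""
    e = np.asarray(e, dtype=float)
    thr = model.thresholds[mu]
    rate = model.rate_min + model.slope * (e - thr)
    rate = np.minimum(rate, model.rate_max)
    out = np.where(e >= thr, rate, 0.0)
    return out if out.ndim else float(out)


@dataclass
class SpikeTrainSet:
    """Sorted discharge times (s) per MU."""

    trains: list  # list of float arrays

    def __post_init__(self) -> None:
        self.trains = [np.asarray(t, dtype=float) for t in self.trains]
        for i, t in enumerate(self.trains):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"discharge times of MU {i} must be strictly increasing")

    @property
    def n_mu(self) -> int:
        return len(self.trains)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"mu_id": i, "time_s": float(t)}
            for i, tr in enumerate(self.trains)
            for t in tr
        ]
        return pd.DataFrame(rows, columns=["mu_id", "time_s"])


def _mu_rng(master_seed: int, mu: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(mu,)))


def generate_spike_trains(
    drive: ExcitationDrive, model: RecruitmentModel, duration: float
) -> SpikeTrainSet:
    """Integrate the rate coding into discharge times with ISI jitter."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if drive.duration < duration - 1e-12:
        raise ValueError(
            f"drive ends at {drive.duration} s, shorter than duration {duration} s"
        )
    trains = []
    for mu in range(model.n_mu):
        rng = _mu_rng(model.rng_seed, mu)
        thr = model.thresholds[mu]
        t = 0.0
        times = []
        guard = 0
        while t < duration:
            e = float(drive.at(t))
            if e < thr:
                # advance to the next threshold crossing (drive grid scan)
                ahead = drive.times > t
                above = ahead & (drive.excitation >= thr)
                if not above.any():
                    break
                t = float(drive.times[above][0])
                continue
            rate = firing_rate(e, model, mu)
            isi = 1.0 / rate
            if model.isi_cov > 0:
                mult = rng.normal(1.0, model.isi_cov)
                # truncate at +-3 sigma to keep the multiplier positive
                mult = float(np.clip(mult, 1.0 - 3 * model.isi_cov, 1.0 + 3 * model.isi_cov))
                isi *= max(mult, 1e-3)
            isi = max(isi, model.refractory_s)
            t = t + isi
            if t <= duration:
                times.append(t)
            guard += 1
            if guard > 10_000_000:  # pragma: no cover
                raise RuntimeError("spike generation runaway")
        trains.append(np.asarray(times))
    return SpikeTrainSet(trains)
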