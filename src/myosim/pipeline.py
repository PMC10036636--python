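"""Staged simulation pipeline with explicit reuse of expensive stages.

The forward solution (adjoint lead field) depends only on the conductor
mesh, conductivities and electrodes; the per-fibre transfer potentials
depend additionally on fibre *geometry*; fibre responses depend on the
source physiology; MUAP templates on the MU grouping; and the raw EMG
on the drives.  Each stage caches its output and is invalidated only by
changes upstream, so swapping fibre physiology, MU distributions or
excitation drives never re-solves the forward problem — the property
that makes large simulated-EMG datasets affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import forward as _forward
from .anatomy import MusclePool
from .recruitment import ExcitationDrive, RecruitmentModel, generate_spike_trains
from .sources import SourceParams
from .synthesis import EMGRecording, compute_muaps, synthesize_emg

__all__ = ["Simulation"]


@dataclass
class Simulation:
    """One volume conductor + electrode layout, many simulations.

    Parameters are supplied through setters; ``run`` produces an
    EMGRecording.  Stage caches: transfers (per fibre geometry), MUAPs
    (per pool/physiology), spikes (per drive/recruitment model).
    """

    forward_op: _forward.ForwardOperator
    source_params: SourceParams = field(default_factory=SourceParams)
    noise_std: float = 0.0  # optional additive white measurement noise, mV
    noise_seed: int = 0

    _pool: MusclePool | None = None
    _transfers: list | None = None
    _muaps: list | None = None

    def set_pool(self, pool: MusclePool, reuse_transfers: bool = False) -> None:
        """Attach a muscle pool.  With ``reuse_transfers=True`` the cached
        per-fibre transfer matrices are kept (valid when only physiology
        or MU grouping changed, not fibre paths)."""
        if not reuse_transfers or self._transfers is None or self._pool is None:
            self._transfers = None
        self._pool = pool
        self._muaps = None

    def transfers(self) -> list:
        if self._pool is None:
            raise RuntimeError("no muscle pool attached")
        if self._transfers is None:
            self._transfers = [
                self.forward_op.potentials_at(f.points) for f in self._pool.fibres
            ]
        return self._transfers

    def muaps(self) -> list:
        if self._muaps is None:
            self._muaps = compute_muaps(
                self._pool, self.transfers(), self.source_params
            )
        return self._muaps

    def run(
        self,
        drive: ExcitationDrive,
        model: RecruitmentModel | None = None,
        duration: float | None = None,
    ) -> tuple:
        """Simulate one contraction; returns (recording, spikes)."""
        pool = self._pool
        if pool is None:
            raise RuntimeError("no muscle pool attached")
        model = model or RecruitmentModel.default(pool.n_motor_units)
        if model.n_mu != pool.n_motor_units:
            raise ValueError("recruitment model size differs from the pool")
        duration = duration or drive.duration
        spikes = generate_spike_trains(drive, model, duration)
        rec = synthesize_emg(spikes, self.muaps(), self.source_params.fs, duration)
        if self.noise_std > 0:
            rng = np.random.default_rng(self.noise_seed)
            rec = EMGRecording(
                rec.signal + rng.normal(0.0, self.noise_std, rec.signal.shape),
                rec.fs,
                rec.montage,
            )
        return rec, spikes
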