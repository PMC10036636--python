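"""Intracellular action potential, travelling current source, fibre EMG.

The transmembrane current source of an excited fibre is modelled as two
waves leaving the neuromuscular junction (NMJ) at ``z0`` and travelling
at velocity ``v`` towards the tendons.  With the spatial intracellular
action potential (IAP) ``V_m`` and ``psi(z) = d/dz V_m(-z)``, the current
source density along the fibre is

    I(z, t) = sigma_in * pi * r^2 * dF/dz,
    F(z, t) = psi(z - z0 - v t) * w_L1(z - z0 - L1/2)
            - psi(-z + z0 - v t) * w_L2(z - z0 + L2/2),

where ``w_L`` is a Tukey window of length ``L`` confining each wave to
its active (non-tendon) semi-fibre, and L1 (right) and L2 (left) are the
semi-lengths from the end-plate to the tendons.

The IAP follows the classical cubic-exponential spatial description
``V_m(z) = 96 z^3 exp(-z) - 90`` with z in millimetres and V_m in
millivolts; this mm/mV convention is confined to this module (note that
mV/mm equals V/m, so ``psi`` values are SI as-is).  The electrode signal
of one fibre is the midpoint-rule source integral projected through the
per-sample transfer potentials (the fibre's basis-point solutions):

    v_fibre(t) = sigma_in pi r^2 * sum_i v_point(r(z_i))
                 * (F(z_i + D_i, t) - F(z_i - D_i, t)),

with ``D_i`` half-distances to the neighbouring samples.  Output is mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "iap",
    "psi",
    "dpsi",
    "tukey",
    "dtukey",
    "SourceParams",
    "wave_profile",
    "csd",
    "fibre_emg",
]

_REST_MV = -90.0


def iap(z_mm):
    """Spatial intracellular action potential, mV as a function of mm.

    ``96 z^3 exp(-z) - 90`` for z >= 0; the membrane ahead of the
    excitation (z < 0) is at the -90 mV resting level.
    """
    z = np.asarray(z_mm, dtype=float)
    out = np.full_like(z, _REST_MV)
    pos = z >= 0
    zp = z[pos]
    out[pos] = 96.0 * zp**3 * np.exp(-zp) + _REST_MV
    return out if out.ndim else float(out)


def _dvm(u):
    """dV_m/dz at z = u (mV/mm), zero for u < 0."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u >= 0
    up = u[pos]
    out[pos] = 96.0 * np.exp(-up) * up**2 * (3.0 - up)
    return out


def psi(z_mm):
    """psi(z) = d/dz V_m(-z) in mV/mm (equivalently V/m); support z <= 0."""
    z = np.asarray(z_mm, dtype=float)
    out = -_dvm(-z)
    return out if out.ndim else float(out)


def dpsi(z_mm):
    """Analytic derivative of psi (mV/mm^2)."""
    z = np.asarray(z_mm, dtype=float)
    out = np.zeros_like(z)
    neg = z <= 0
    u = -z[neg]
    # d/dz[-V_m'(-z)] = V_m''(-z); V_m''(u) = 96 e^-u (u^3 - 6u^2 + 6u)
    out[neg] = 96.0 * np.exp(-u) * (u**3 - 6.0 * u**2 + 6.0 * u)
    return out if out.ndim else float(out)


def tukey(u, length, alpha):
    """Continuous Tukey (tapered-cosine) window centred at 0.

    Flat on |u| <= (1 - alpha) L/2, cosine taper to zero at |u| = L/2.
    """
    u = np.abs(np.asarray(u, dtype=float))
    half = length / 2.0
    flat = (1.0 - alpha) * half
    out = np.zeros_like(u)
    out[u <= flat] = 1.0
    if alpha > 0:
        taper = (u > flat) & (u < half)
        out[taper] = 0.5 * (1.0 + np.cos(np.pi * (u[taper] - flat) / (alpha * half)))
    return out if out.ndim else float(out)


def dtukey(u, length, alpha):
    """Derivative of :func:`tukey` with respect to u."""
    uu = np.asarray(u, dtype=float)
    a = np.abs(uu)
    half = length / 2.0
    flat = (1.0 - alpha) * half
    out = np.zeros_like(a)
    if alpha > 0:
        taper = (a > flat) & (a < half)
        out[taper] = (
            -0.5
            * np.pi
            / (alpha * half)
            * np.sin(np.pi * (a[taper] - flat) / (alpha * half))
            * np.sign(uu[taper])
        )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SourceParams:
    """Source-model parameters.

    alpha : Tukey taper fraction (dimensionless, default 0.2).
    fs : sampling frequency in Hz (default 2000, the standard simulated
        EMG rate).
    """

    alpha: float = 0.2
    fs: float = 2000.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("Tukey taper alpha must be in [0, 1]")
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")

    def time_grid(self, duration: float) -> np.ndarray:
        n = int(round(duration * self.fs))
        return np.arange(n) / self.fs


def wave_profile(z, t, fibre, params: SourceParams):
    """F(z, t): the windowed two-wave source profile, SI in/out (V/m).

    ``z`` metres (broadcastable with ``t`` seconds); ``fibre`` provides
    z0, L1, L2, v (see anatomy.FibreGeometry).
    """
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    z0, l1, l2, v = fibre.z0, fibre.L1, fibre.L2, fibre.velocity
    arg_r = z - z0 - v * t
    arg_l = -z + z0 - v * t
    right = psi(arg_r * 1e3) * tukey(z - z0 - l1 / 2.0, l1, params.alpha)
    left = psi(arg_l * 1e3) * tukey(z - z0 + l2 / 2.0, l2, params.alpha)
    return right - left


def csd(z, t, fibre, params: SourceParams | None = None):
    """Current source density I(z, t) along the fibre, A/m (SI).

    Analytic z-derivative of the windowed wave profile scaled by
    ``sigma_in * pi * r^2``.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("time must be non-negative")
    params = params or SourceParams()
    z = np.asarray(z, dtype=float)
    t = np.asarray(t, dtype=float)
    z0, l1, l2, v = fibre.z0, fibre.L1, fibre.L2, fibre.velocity
    arg_r = z - z0 - v * t
    arg_l = -z + z0 - v * t
    w_r = tukey(z - z0 - l1 / 2.0, l1, params.alpha)
    w_l = tukey(z - z0 + l2 / 2.0, l2, params.alpha)
    # d/dz[psi(1e3*(z-z0-vt))] = 1e3 * dpsi(...)  (per metre)
    d_right = 1e3 * dpsi(arg_r * 1e3) * w_r + psi(arg_r * 1e3) * dtukey(
        z - z0 - l1 / 2.0, l1, params.alpha
    )
    d_left = -1e3 * dpsi(arg_l * 1e3) * w_l + psi(arg_l * 1e3) * dtukey(
        z - z0 + l2 / 2.0, l2, params.alpha
    )
    scale = fibre.sigma_in * np.pi * fibre.radius**2
    return scale * (d_right - d_left)


def fibre_emg(
    v_point_samples: np.ndarray,
    fibre,
    params: SourceParams,
    times: np.ndarray,
) -> np.ndarray:
    """Single-fibre electrode signals in mV.

    ``v_point_samples`` is (n_e, n_z): transfer potentials (V per unit A)
    at the fibre's arc-length samples ``fibre.z`` (from the forward
    operator or an analytic transfer).  Returns (n_e, n_times).
    """
    v = np.asarray(v_point_samples, dtype=float)
    zs = np.asarray(fibre.z, dtype=float)
    if v.ndim != 2 or v.shape[1] != len(zs):
        raise ValueError(
            f"transfer matrix has {v.shape[1] if v.ndim == 2 else '?'} samples, "
            f"fibre geometry has {len(zs)}"
        )
    times = np.asarray(times, dtype=float)
    # midpoint-rule cell edges: half-distances to neighbours, one-sided ends
    edges = np.empty(len(zs) + 1)
    edges[1:-1] = 0.5 * (zs[1:] + zs[:-1])
    edges[0] = zs[0]
    edges[-1] = zs[-1]
    f_hi = wave_profile(edges[1:, None], times[None, :], fibre, params)
    f_lo = wave_profile(edges[:-1, None], times[None, :], fibre, params)
    scale = fibre.sigma_in * np.pi * fibre.radius**2
    return 1e3 * scale * (v @ (f_hi - f_lo))  # volts -> mV
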