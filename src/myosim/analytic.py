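"""Closed-form and semi-analytic volume-conductor references.

Two oracles validate the FEM forward solver:

* the free-space point-source potential ``phi = 1/(4 pi sigma d)`` (with
  its anisotropic coordinate-scaling generalisation), valid for sources
  deep inside a large homogeneous conductor;

* the layered-cylinder model: concentric infinite cylinders (bone,
  muscle, fat, skin), isotropic except the muscle layer which may have
  distinct radial/angular and axial conductivities.  The potential of a
  point current source in the muscle is expanded in angular harmonics
  ``cos(n dtheta)`` and an axial Fourier wavenumber ``k``; per (n, k)
  the radial profile is built from modified Bessel functions I_n, K_n
  (argument scaled by sqrt(sigma_axial/sigma_radial) in the anisotropic
  layer), matched across interfaces by continuity of potential and
  normal current, with zero normal current at the outer surface.  The
  inverse Fourier transform is evaluated by panel Gauss-Legendre
  quadrature.

The n = 0 mode of an infinite insulated cylinder carries a 1/k^2
small-wavenumber divergence: a DC point source drives current to axial
infinity, so the monopolar potential is defined only up to an (infinite)
reference constant.  The implementation splits off the analytic
``C / k^2`` part, integrates it in closed form (the physical term is
linear in |dz|), and drops the reference constant — the documented gauge.
Balanced fibre sources and differential montages are unaffected.

The validation harness reproduces the classical comparison: a fibre at
1-11 mm depth in the four-layer phantom, 16 point electrodes on the
skin directly above it, single-differential signals, and the NMSE
``sum (a-b)^2 / sum b^2`` between FEM and analytic solutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from . import mesh as _mesh
from . import forward as _forward
from .anatomy import FibreGeometry, straight_fibre
from .sources import SourceParams, fibre_emg

__all__ = [
    "potential_homogeneous",
    "potential_homogeneous_anisotropic",
    "LayeredCylinderSpec",
    "potential_layered_cylinder",
    "analytic_fibre_signal",
    "nmse",
    "run_cylinder_validation",
    "ValidationConfig",
]


def potential_homogeneous(r, r0, sigma_iso: float):
    """Free-space potential 1/(4 pi sigma d), volts per unit ampere."""
    if sigma_iso <= 0:
        raise ValueError("conductivity must be positive")
    r = np.asarray(r, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    d = np.linalg.norm(r - r0, axis=-1)
    if np.any(d == 0):
        raise ValueError("field point coincides with the source")
    return 1.0 / (4.0 * np.pi * sigma_iso * d)


def potential_homogeneous_anisotropic(r, r0, sigma_diag):
    """Point source in an unbounded medium with diagonal conductivity.

    phi = 1 / (4 pi sqrt(sy sz dx^2 + sx sz dy^2 + sx sy dz^2)).
    """
    sx, sy, sz = (float(s) for s in sigma_diag)
    if min(sx, sy, sz) <= 0:
        raise ValueError("conductivities must be positive")
    d = np.asarray(r, dtype=float) - np.asarray(r0, dtype=float)
    q = sy * sz * d[..., 0] ** 2 + sx * sz * d[..., 1] ** 2 + sx * sy * d[..., 2] ** 2
    if np.any(q == 0):
        raise ValueError("field point coincides with the source")
    return 1.0 / (4.0 * np.pi * np.sqrt(q))


# --- layered cylinder --------------------------------------------------------


@dataclass(frozen=True)
class LayeredCylinderSpec:
    """Geometry, conductivities and numerical controls.

    radii : outer radii of the layers, strictly increasing (m).
    conductivities : one entry per layer; a float (isotropic) or a
        ``(sigma_radial_angular, sigma_axial)`` pair.
    muscle_layer : index of the layer allowed to contain sources.
    n_harmonics : angular truncation order N (modes 0..N).
    k_max : axial wavenumber cutoff (rad/m).
    n_panels, n_gauss : panel Gauss-Legendre quadrature of the inverse
        transform.
    """

    radii: tuple
    conductivities: tuple
    muscle_layer: int = 1
    n_harmonics: int = 30
    k_max: float = 1500.0
    n_panels: int = 80
    n_gauss: int = 10

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        object.__setattr__(self, "radii", radii)
        if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("radii must be positive and strictly increasing")
        conds = []
        for c in self.conductivities:
            if np.isscalar(c):
                conds.append((float(c), float(c)))
            else:
                conds.append((float(c[0]), float(c[1])))
        if len(conds) != len(radii):
            raise ValueError("one conductivity per layer required")
        if any(min(c) <= 0 for c in conds):
            raise ValueError("conductivities must be positive")
        object.__setattr__(self, "conductivities", tuple(conds))
        if self.n_harmonics < 0:
            raise ValueError("n_harmonics must be >= 0")
        if not 0 <= self.muscle_layer < len(radii):
            raise ValueError("muscle_layer out of range")

    @property
    def muscle_annulus(self) -> tuple:
        lo = self.radii[self.muscle_layer - 1] if self.muscle_layer else 0.0
        return lo, self.radii[self.muscle_layer]

    def axial_conductance(self) -> float:
        """Per-length axial conductance sum(sigma_z * layer area), S*m."""
        g = 0.0
        r_in = 0.0
        for r_out, (_, sz) in zip(self.radii, self.conductivities):
            g += sz * np.pi * (r_out**2 - r_in**2)
            r_in = r_out
        return g


def _k_grid(spec: LayeredCylinderSpec):
    nodes, weights = np.polynomial.legendre.leggauss(spec.n_gauss)
    edges = np.linspace(0.0, spec.k_max, spec.n_panels + 1)
    mid = 0.5 * (edges[1:] + edges[:-1])
    half = 0.5 * np.diff(edges)
    ks = (mid[:, None] + half[:, None] * nodes[None, :]).ravel()
    ws = (half[:, None] * weights[None, :]).ravel()
    return ks, ws


_X_MAX = 650.0  # raw modified-Bessel overflow guard


def _bessel_vf(n: int, x: np.ndarray):
    """(I_n, I_n', K_n, K_n') at x (raw, guarded)."""
    if x.size and x.max() > _X_MAX:
        raise ValueError(
            "Bessel argument too large; reduce k_max or the cylinder radius"
        )
    i = special.iv(n, x)
    ip = special.ivp(n, x)
    k = special.kv(n, x)
    kp = special.kvp(n, x)
    return i, ip, k, kp


def _radial_green_surface(spec: LayeredCylinderSpec, n: int, ks: np.ndarray,
                          rho0: float, rho_f: float) -> np.ndarray:
    """g_n(k): radial Green's function from source radius rho0 (muscle
    layer) to field radius rho_f (>= rho0), vectorized over k."""
    radii = spec.radii
    conds = spec.conductivities
    m = spec.muscle_layer
    if rho0 < 1e-9 and n >= 1:
        return np.zeros_like(ks)  # axis source: only n = 0 survives
    rho0 = max(rho0, 1e-7)  # regularized limit for the n = 0 mode

    def kappa(layer):
        sp_, sz_ = conds[layer]
        return np.sqrt(sz_ / sp_)

    # inward (regular) solution: propagate (value, flux) outward to rho0
    g0 = kappa(0) * ks
    v_in = special.iv(n, g0 * radii[0]) if m > 0 else None
    if m == 0:
        x0 = g0 * rho0
        v_in = special.iv(n, x0)
        f_in = conds[0][0] * g0 * special.ivp(n, x0)
    else:
        f_in = conds[0][0] * g0 * special.ivp(n, g0 * radii[0])
        for layer in range(1, m + 1):
            sp_, _ = conds[layer]
            kap = kappa(layer) * ks
            x_lo = kap * radii[layer - 1]
            i, ip, kk, kp = _bessel_vf(n, x_lo)
            w = i * kp - ip * kk  # = -1/x_lo
            a = (v_in * kp - f_in * kk / (sp_ * kap)) / w
            b = (f_in * i / (sp_ * kap) - v_in * ip) / w
            x_hi = kap * (rho0 if layer == m else radii[layer])
            i2, ip2, k2, kp2 = _bessel_vf(n, x_hi)
            v_in = a * i2 + b * k2
            f_in = sp_ * kap * (a * ip2 + b * kp2)
            # normalize to avoid magnitude growth (scale cancels in g)
            scale = np.maximum(np.abs(v_in), np.abs(f_in))
            scale[scale == 0] = 1.0
            v_in /= scale
            f_in /= scale

    # outward solution: Neumann at the outer radius, propagate inward,
    # keeping per-layer coefficients so we can evaluate at rho_f
    n_layers = len(radii)
    coeffs = [None] * n_layers
    sp_, _ = conds[-1]
    kap = kappa(n_layers - 1) * ks
    x_out = kap * radii[-1]
    i, ip, kk, kp = _bessel_vf(n, x_out)
    w = i * kp - ip * kk
    # v = 1, f = 0 at the surface
    a = kp / w
    b = -ip / w
    coeffs[n_layers - 1] = (a, b)
    v_out_srf = np.ones_like(ks)
    for layer in range(n_layers - 1, m, -1):
        sp_, _ = conds[layer]
        kap = kappa(layer) * ks
        x_lo = kap * radii[layer - 1]
        i, ip, kk, kp = _bessel_vf(n, x_lo)
        a, b = coeffs[layer]
        v = a * i + b * kk
        f = sp_ * kap * (a * ip + b * kp)
        sp2, _ = conds[layer - 1]
        kap2 = kappa(layer - 1) * ks
        x2 = kap2 * radii[layer - 1]
        i2, ip2, k2, kp2 = _bessel_vf(n, x2)
        w2 = i2 * kp2 - ip2 * k2
        a2 = (v * kp2 - f * k2 / (sp2 * kap2)) / w2
        b2 = (f * i2 / (sp2 * kap2) - v * ip2) / w2
        coeffs[layer - 1] = (a2, b2)
    sp_m, _ = conds[m]
    kap_m = kappa(m) * ks
    a, b = coeffs[m]
    x0 = kap_m * rho0
    i, ip, kk, kp = _bessel_vf(n, x0)
    v_out0 = a * i + b * kk
    f_out0 = sp_m * kap_m * (a * ip + b * kp)
    # value of the outward solution at the field radius
    f_layer = int(np.searchsorted(np.asarray(radii), rho_f * (1 - 1e-12), side="left"))
    f_layer = min(max(f_layer, m), n_layers - 1)
    af, bf = coeffs[f_layer]
    xf = kappa(f_layer) * ks * rho_f
    i_f, _, k_f, _ = _bessel_vf(n, xf)
    v_out_f = af * i_f + bf * k_f

    denom = rho0 * (f_in * v_out0 - f_out0 * v_in)
    return v_in * v_out_f / denom


def _n0_coefficient(spec: LayeredCylinderSpec, rho0: float, rho_f: float) -> float:
    """C = lim_{k->0} k^2 g_0(k): the uniform axial-spreading mode."""
    k_small = np.array([1e-3, 2e-3])
    g = _radial_green_surface(spec, 0, k_small, rho0, rho_f)
    c = float((g * k_small**2)[0])
    return c


def _tail_cos_over_k2(k0: float, a: np.ndarray) -> np.ndarray:
    """int_{k0}^inf cos(k a)/k^2 dk for a >= 0 (elementwise)."""
    a = np.abs(a)
    si, _ = special.sici(k0 * a)
    return np.cos(k0 * a) / k0 - a * (np.pi / 2.0 - si)


def potential_layered_cylinder(
    spec: LayeredCylinderSpec,
    source_point,
    field_points,
    check_convergence: bool = True,
    harmonic_tol: float = 1e-4,
) -> np.ndarray:
    """Potentials (V per unit A) of a point source in the muscle layer.

    ``source_point`` and ``field_points`` are Cartesian (x, y, z); field
    points may lie in any layer at or outside the source radius
    (electrodes are normally on the outer surface).  The potential
    reference is the documented axial gauge (an additive constant is
    dropped); differences between field points are physical.
    """
    src = np.asarray(source_point, dtype=float)
    pts = np.atleast_2d(np.asarray(field_points, dtype=float))
    t = layered_transfer(
        spec,
        src[:2],
        np.array([src[2]]),
        pts,
        check_convergence=check_convergence,
        harmonic_tol=harmonic_tol,
    )
    return t[:, 0]


def layered_transfer(
    spec: LayeredCylinderSpec,
    source_xy,
    source_z: np.ndarray,
    electrode_points,
    check_convergence: bool = True,
    harmonic_tol: float = 1e-4,
) -> np.ndarray:
    """Transfer matrix (n_e, n_z): potential at each electrode per unit
    point source at radius/angle ``source_xy`` and axial positions
    ``source_z``.  Vectorized over electrodes, source samples and the
    wavenumber grid (all sources share one radius)."""
    x0, y0 = (float(v) for v in source_xy)
    rho0 = float(np.hypot(x0, y0))
    th0 = float(np.arctan2(y0, x0))
    lo, hi = spec.muscle_annulus
    if not (lo - 1e-12 <= rho0 <= hi + 1e-12):
        raise ValueError(
            f"source radius {rho0:.4f} m outside the muscle layer [{lo}, {hi}]"
        )
    electrodes = np.atleast_2d(np.asarray(electrode_points, dtype=float))
    source_z = np.asarray(source_z, dtype=float)
    rho_e = np.hypot(electrodes[:, 0], electrodes[:, 1])
    th_e = np.arctan2(electrodes[:, 1], electrodes[:, 0])
    dz = electrodes[:, 2][:, None] - source_z[None, :]  # (n_e, n_z)
    dth = th_e - th0
    ks, ws = _k_grid(spec)
    out = np.zeros(dz.shape)
    rounds = np.round(rho_e, 10)
    for rf in np.unique(rounds):
        sel = np.where(rounds == rf)[0]
        dzs = dz[sel].reshape(-1)
        cosmat = np.cos(ks[None, :] * dzs[:, None])  # (n_sel*n_z, n_k)
        c0 = _n0_coefficient(spec, rho0, float(rf))
        acc = np.zeros((len(sel), len(source_z)))
        last = 0.0
        for n in range(spec.n_harmonics + 1):
            g = _radial_green_surface(spec, n, ks, rho0, float(rf))
            if n == 0:
                g = g - c0 / ks**2
            radial = (cosmat @ (ws * g)).reshape(len(sel), -1)
            eps = 1.0 if n == 0 else 2.0
            term = eps * np.cos(n * dth[sel])[:, None] * radial
            if n == 0:
                adz = np.abs(dzs).reshape(len(sel), -1)
                term = term - np.pi / 2.0 * c0 * adz - c0 * _tail_cos_over_k2(
                    spec.k_max, dzs
                ).reshape(len(sel), -1)
            acc += term
            scale = np.max(np.abs(acc))
            last = np.max(np.abs(term)) / scale if scale > 0 else 0.0
        if check_convergence and last > harmonic_tol:
            raise ValueError(
                f"harmonic series not converged: last term contributes "
                f"{last:.2e} (> {harmonic_tol}); increase n_harmonics"
            )
        out[sel] = acc / (2.0 * np.pi**2)
    return out


def analytic_fibre_signal(
    spec: LayeredCylinderSpec,
    fibre: FibreGeometry,
    params: SourceParams,
    electrode_points,
    times: np.ndarray,
) -> np.ndarray:
    """Per-channel analytic signals (mV) for an axis-parallel fibre.

    Superposes the layered-cylinder point-source solutions along the
    discretized fibre, weighted exactly as the FEM pipeline weights its
    basis-point transfers, so the two solutions differ only in the
    volume-conductor model.
    """
    pts = np.asarray(fibre.points, dtype=float)
    if np.ptp(pts[:, 0]) > 1e-9 or np.ptp(pts[:, 1]) > 1e-9:
        raise ValueError("analytic model requires a fibre parallel to the axis")
    transfer = layered_transfer(
        spec, pts[0, :2], pts[:, 2], electrode_points, check_convergence=False
    )
    return fibre_emg(transfer, fibre, params, times)


def nmse(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized mean square error sum((a-b)^2) / sum(b^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    denom = float((b**2).sum())
    if denom == 0:
        raise ValueError("reference signal is identically zero")
    return float(((a - b) ** 2).sum() / denom)


# --- validation harness ------------------------------------------------------


@dataclass(frozen=True)
class ValidationConfig:
    """Four-layer phantom validation setup.

    Defaults reproduce the classical comparison: bone/muscle/fat/skin
    radii 0.7/2/2.3/2.4 cm, a straight axial fibre at the requested depth
    below the muscle surface, and 16 point electrodes (8 mm pitch) on the
    skin directly above the fibre in a single-differential montage.
    """

    radii: tuple = (0.007, 0.02, 0.023, 0.024)
    sigma_bone: float = 0.02
    sigma_muscle_radial: float = 0.08
    sigma_muscle_axial: float = 0.4
    sigma_fat: float = 0.04
    sigma_skin: float = 0.44
    n_electrodes: int = 16
    pitch: float = 0.008
    fibre_half_length: float = 0.07
    active_fraction: float = 0.96
    velocity: float = 4.0
    cylinder_length: float = 0.3
    fs: float = 2000.0
    duration: float = 0.026
    delta: float = 5e-4
    alpha: float = 0.2

    def layered_spec(self, **overrides) -> LayeredCylinderSpec:
        kw = dict(
            radii=self.radii,
            conductivities=(
                self.sigma_bone,
                (self.sigma_muscle_radial, self.sigma_muscle_axial),
                self.sigma_fat,
                self.sigma_skin,
            ),
            muscle_layer=1,
        )
        kw.update(overrides)
        return LayeredCylinderSpec(**kw)

    def electrode_positions(self) -> np.ndarray:
        r = self.radii[-1]
        z = (np.arange(self.n_electrodes) - (self.n_electrodes - 1) / 2.0) * self.pitch
        return np.column_stack([np.full_like(z, r), np.zeros_like(z), z])

    def fibre_at_depth(self, depth_m: float) -> FibreGeometry:
        rho = self.radii[1] - depth_m
        lo = self.radii[0]
        if not (lo < rho < self.radii[1]):
            raise ValueError(
                f"depth {depth_m * 1e3:.1f} mm places the fibre outside the "
                "muscle annulus"
            )
        length = 2.0 * self.fibre_half_length
        return straight_fibre(
            start=np.array([rho, 0.0, -self.fibre_half_length]),
            direction=np.array([0.0, 0.0, 1.0]),
            length=length,
            delta=self.delta,
            z0_frac=0.5,
            active_fraction=self.active_fraction,
            velocity=self.velocity,
        )

    def phantom_mesh(self, resolution: str = "default") -> "_mesh.VolumeMesh":
        """Graded phantom mesh: fine in the outer muscle/fat/skin shells
        and around the electrode array, coarser in the bone and towards
        the cylinder ends."""
        scale = {"coarse": 1.6, "default": 1.0, "fine": 0.72}[resolution]
        r1, r2, r3, r4 = self.radii
        edge = 0.0022 * scale
        radial = np.concatenate(
            [
                np.linspace(0.0, r1, max(2, int(np.ceil(r1 / (2.5 * edge)))) + 1)[1:],
                np.linspace(r1, r2, max(2, int(np.ceil((r2 - r1) / edge))) + 1)[1:],
                np.linspace(r2, r3, max(1, int(np.ceil((r3 - r2) / edge))) + 1)[1:],
                np.linspace(r3, r4, max(1, int(np.ceil((r4 - r3) / edge))) + 1)[1:],
            ]
        )
        half = self.cylinder_length / 2.0
        z_core = self.fibre_half_length + 2 * self.pitch
        fine = np.arange(0.0, z_core, 0.8 * edge)
        n_tail = max(2, int(np.ceil((half - fine[-1]) / (4 * edge))))
        tail = np.linspace(fine[-1], half, n_tail + 1)[1:]
        zpos = np.concatenate([fine, tail])
        zfull = np.unique(np.concatenate([half - zpos[::-1], half + zpos]))
        # ensure electrode z-planes are mesh planes
        el_z = self.electrode_positions()[:, 2] + half
        zfull = np.unique(np.round(np.concatenate([zfull, el_z]), 12))
        n_theta = int(np.ceil(2 * np.pi * r4 / edge))
        spec = _mesh.CylinderPhantomSpec(
            radii=self.radii,
            length=self.cylinder_length,
            edge_length=edge,
            radial_positions=tuple(radial),
            axial_positions=tuple(zfull),
            n_theta=n_theta,
        )
        return _mesh.build_cylinder_phantom(spec)

    def conductivity_model(self) -> "_mesh.ConductivityModel":
        return _mesh.ConductivityModel(
            {
                _mesh.BONE: _mesh.IsotropicConductivity(self.sigma_bone),
                _mesh.muscle_region(0): _mesh.AnisotropicConductivity(
                    sigma_l=self.sigma_muscle_axial,
                    sigma_t=self.sigma_muscle_radial,
                    direction=(0.0, 0.0, 1.0),
                ),
                _mesh.FAT: _mesh.IsotropicConductivity(self.sigma_fat),
                _mesh.SKIN: _mesh.IsotropicConductivity(self.sigma_skin),
            }
        )


def _differential(signals: np.ndarray) -> np.ndarray:
    return signals[1:] - signals[:-1]


def run_cylinder_validation(
    depths_mm,
    mesh_resolution: str = "default",
    config: ValidationConfig | None = None,
    solver_tol: float = 1e-8,
    return_signals: bool = False,
):
    """NMSE between FEM and analytic differential signals per fibre depth.

    Builds the four-layer phantom once, computes the adjoint lead field
    for the 16-electrode array, then for each depth simulates the fibre
    through both the FEM pipeline and the layered-cylinder model and
    reports the NMSE of the single-differential signals.

    Returns a pandas DataFrame (depth_mm, nmse); with
    ``return_signals=True`` also a dict of (fem, analytic) signal pairs.
    """
    import pandas as pd

    cfg = config or ValidationConfig()
    depths = np.atleast_1d(np.asarray(depths_mm, dtype=float))
    lo, hi = cfg.layered_spec().muscle_annulus
    for d in depths:
        if not (0 < d * 1e-3 < hi - lo):
            raise ValueError(f"depth {d} mm outside the muscle annulus")
    mesh = cfg.phantom_mesh(mesh_resolution)
    mesh = cfg.conductivity_model().assign(mesh)
    electrodes = cfg.electrode_positions()  # mesh and fibre share z = 0 centre
    op = _forward.compute_forward_operator(
        mesh,
        [_forward.PointElectrode(tuple(p)) for p in electrodes],
        tol=solver_tol,
    )
    params = SourceParams(alpha=cfg.alpha, fs=cfg.fs)
    times = params.time_grid(cfg.duration)
    spec = cfg.layered_spec()
    rows, signals = [], {}
    for d in depths:
        fibre = cfg.fibre_at_depth(d * 1e-3)
        transfer = op.potentials_at(fibre.points)
        fem = _differential(fibre_emg(transfer, fibre, params, times))
        ana = _differential(
            analytic_fibre_signal(spec, fibre, params, electrodes, times)
        )
        err = nmse(fem, ana)
        rows.append({"depth_mm": float(d), "nmse": err})
        if return_signals:
            signals[float(d)] = (fem, ana)
    df = pd.DataFrame(rows)
    return (df, signals) if return_signals else df
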