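"""Fibre and motor-unit anatomy.

Fibre positions are drawn uniformly inside a unit circle, motor-unit
(MU) centres and circular territories are generated on top, and each
fibre joins one of the MUs covering it with probability proportional to
that MU's fibre density (target size / territory area).  Generating MUs
after the fibres keeps the fibre population — and therefore any
precomputed per-fibre transfer solutions — untouched when the MU
distribution is re-drawn (the staged-reuse contract).

MU target sizes follow the exponential (geometric) progression used by
size-principle pools: size_i = s_min (s_max/s_min)^((i-1)/(n-1)), e.g.
11..1150 fibres over 200 MUs.  Territory areas span a configured range
of the muscle cross-section (default 10-50%), assigned small-to-large
with MU size.

The dimensionless unit-circle population is morphed into a 3-D muscle by
mapping the disc onto the muscle cross-section and extruding along the
centreline; fibres run parallel to the centreline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "sample_fibres",
    "MotorUnitDescriptor",
    "generate_mu_layout",
    "assign_fibres",
    "UnitCirclePopulation",
    "FibreGeometry",
    "MotorUnit",
    "MusclePool",
    "CircleSection",
    "AnnularSectorSection",
    "MuscleGeometry",
    "morph_to_muscle",
    "discretize_fibre",
    "straight_fibre",
    "FibrePhysiology",
]


# --- unit-circle population --------------------------------------------------


def sample_fibres(n: int, rng_seed: int = 0) -> np.ndarray:
    """``n`` points uniform on the unit disc, (n, 2), reproducible."""
    if n < 0:
        raise ValueError("number of fibres must be non-negative")
    rng = np.random.default_rng(rng_seed)
    r = np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@dataclass(frozen=True)
class MotorUnitDescriptor:
    centre: tuple  # 2-D, unit-circle coordinates
    territory_radius: float
    target_size: float


def generate_mu_layout(
    n_mu: int,
    size_min: float = 11.0,
    size_max: float = 1150.0,
    area_frac_range: tuple = (0.10, 0.50),
    rng_seed: int = 0,
    jitter: float = 0.0,
) -> list:
    """Generate MU descriptors inside the unit circle.

    Target sizes grow exponentially from ``size_min`` to ``size_max``
    (endpoints exact).  Territory area fractions interpolate linearly
    across the configured range in MU-size order (small MU, small
    territory), with optional multiplicative jitter.  Centres are drawn
    uniformly in the disc of radius ``1 - territory_radius`` so
    territories stay inside the unit disc.
    """
    if n_mu < 1:
        raise ValueError("n_mu must be >= 1")
    if not (0 < size_min <= size_max):
        raise ValueError("sizes must satisfy 0 < size_min <= size_max")
    lo, hi = area_frac_range
    if not (0 < lo <= hi <= 1):
        raise ValueError("territory area fractions must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    if n_mu == 1:
        if size_min != size_max:
            import warnings

            warnings.warn("n_mu=1: target size set to size_min")
        sizes = np.array([size_min])
        fracs = np.array([lo])
    else:
        i = np.arange(n_mu)
        sizes = size_min * (size_max / size_min) ** (i / (n_mu - 1))
        fracs = lo + (hi - lo) * i / (n_mu - 1)
    if jitter > 0:
        fracs = fracs * np.exp(rng.normal(0.0, jitter, size=n_mu))
        fracs = np.clip(fracs, lo, hi)
    radii = np.sqrt(fracs)  # unit-disc area fraction -> radius
    out = []
    for i in range(n_mu):
        r_t = min(radii[i], 1.0)
        r_c = (1.0 - r_t) * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        out.append(
            MotorUnitDescriptor(
                centre=(r_c * np.cos(th), r_c * np.sin(th)),
                territory_radius=r_t,
                target_size=float(sizes[i]),
            )
        )
    return out


def assign_fibres(
    fibres: np.ndarray, mu_layout: Sequence[MotorUnitDescriptor], rng_seed: int = 0
) -> np.ndarray:
    """Assign each fibre to one covering MU, density-weighted.

    Selection probability among MUs whose territory contains the fibre is
    proportional to MU density (target size / territory area).  Fibres
    covered by no territory fall back to the MU with the nearest
    territory boundary (count reported via the returned info).
    Returns an (n_fibres,) int array of MU indices.
    """
    fibres = np.asarray(fibres, dtype=float)
    n_f = len(fibres)
    n_mu = len(mu_layout)
    centres = np.array([m.centre for m in mu_layout])
    radii = np.array([m.territory_radius for m in mu_layout])
    density = np.array(
        [m.target_size / (np.pi * m.territory_radius**2) for m in mu_layout]
    )
    rng = np.random.default_rng(rng_seed)
    d = np.linalg.norm(fibres[:, None, :] - centres[None, :, :], axis=2)
    covered = d <= radii[None, :]
    weights = covered * density[None, :]
    tot = weights.sum(axis=1)
    assignment = np.empty(n_f, dtype=np.int64)
    has = tot > 0
    if has.any():
        w = weights[has] / tot[has, None]
        cdf = np.cumsum(w, axis=1)
        u = rng.uniform(size=int(has.sum()))
        assignment[has] = (u[:, None] > cdf).sum(axis=1)
    if (~has).any():
        # nearest territory boundary
        gap = d[~has] - radii[None, :]
        assignment[~has] = np.argmin(gap, axis=1)
    return assignment


@dataclass
class UnitCirclePopulation:
    """Dimensionless fibre/MU population inside the unit circle."""

    fibres: np.ndarray  # (n_f, 2)
    mu_layout: list
    assignment: np.ndarray  # (n_f,) MU index

    def __post_init__(self) -> None:
        r = np.linalg.norm(self.fibres, axis=1)
        if r.size and r.max() > 1.0 + 1e-12:
            raise ValueError("fibre positions must lie inside the unit disc")
        if len(self.assignment) != len(self.fibres):
            raise ValueError("assignment must cover every fibre exactly once")

    @classmethod
    def generate(
        cls,
        n_fibres: int,
        n_mu: int,
        size_min: float = 11.0,
        size_max: float = 1150.0,
        area_frac_range: tuple = (0.10, 0.50),
        rng_seed: int = 0,
    ) -> "UnitCirclePopulation":
        fibres = sample_fibres(n_fibres, rng_seed)
        layout = generate_mu_layout(
            n_mu, size_min, size_max, area_frac_range, rng_seed=rng_seed + 1
        )
        assignment = assign_fibres(fibres, layout, rng_seed=rng_seed + 2)
        return cls(fibres, layout, assignment)


# --- 3-D fibre geometry ------------------------------------------------------


@dataclass
class FibreGeometry:
    """Discretized 3-D fibre path with physiology.

    points : (n, 3) polyline samples r(z_i), metres.
    z : (n,) strictly increasing arc-length samples, metres.
    z0 : NMJ arc position; L1/L2 : active semi-lengths towards the right
    and left tendon; radius : fibre radius; velocity : propagation
    velocity (m/s); sigma_in : intracellular conductivity (S/m).
    """

    points: np.ndarray
    z: np.ndarray
    z0: float
    L1: float
    L2: float
    radius: float = 25e-6
    velocity: float = 4.0
    sigma_in: float = 1.01

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if len(self.points) != len(self.z):
            raise ValueError("points and z must have equal length")
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("arc-length samples must be strictly increasing")
        length = self.z[-1] - self.z[0]
        if not (self.z[0] - 1e-12 <= self.z0 <= self.z[-1] + 1e-12):
            raise ValueError("NMJ position z0 must lie on the fibre")
        if self.L1 + self.L2 > length + 1e-12:
            raise ValueError("active semi-lengths L1 + L2 exceed fibre length")

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])


@dataclass
class MotorUnit:
    id: int
    fibre_indices: np.ndarray


@dataclass
class MusclePool:
    """All fibres of one muscle grouped into motor units.

    MU fibre-index lists partition the fibre set; MUs are ordered by
    non-decreasing size (size-principle ordering).
    """

    muscle_id: int
    fibres: list  # list of FibreGeometry
    motor_units: list  # list of MotorUnit

    def __post_init__(self) -> None:
        counts = np.zeros(len(self.fibres), dtype=int)
        for mu in self.motor_units:
            counts[np.asarray(mu.fibre_indices, dtype=int)] += 1
        if len(self.fibres) and not np.all(counts == 1):
            raise ValueError("motor units must partition the fibre set")
        sizes = [len(mu.fibre_indices) for mu in self.motor_units]
        if any(b < a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("motor units must be ordered by non-decreasing size")

    @property
    def n_fibres(self) -> int:
        return len(self.fibres)

    @property
    def n_motor_units(self) -> int:
        return len(self.motor_units)


# --- morphing into muscle geometry ------------------------------------------


@dataclass(frozen=True)
class CircleSection:
    """Circular muscle cross-section of given radius, centred at
    ``centre`` in the section plane (identity-type morph)."""

    radius: float
    centre: tuple = (0.0, 0.0)

    def map_points(self, p: np.ndarray) -> np.ndarray:
        return np.asarray(self.centre) + self.radius * p


@dataclass(frozen=True)
class AnnularSectorSection:
    """Annular-sector cross-section (for cylinder-phantom muscles).

    The unit disc maps onto the sector (rho in [r_lo, r_hi], theta in
    [th_lo, th_hi]) by the boundary-conforming rectangular map
    x -> rho, y -> theta; injective for th_hi - th_lo <= 2 pi.
    """

    r_lo: float
    r_hi: float
    th_lo: float = -np.pi / 4
    th_hi: float = np.pi / 4

    def __post_init__(self) -> None:
        if not (0 <= self.r_lo < self.r_hi):
            raise ValueError("annular sector radii must satisfy 0 <= r_lo < r_hi")
        if not (self.th_lo < self.th_hi <= self.th_lo + 2 * np.pi):
            raise ValueError("sector angles invalid (self-intersecting section)")

    def map_points(self, p: np.ndarray) -> np.ndarray:
        rho = self.r_lo + (p[:, 0] + 1.0) / 2.0 * (self.r_hi - self.r_lo)
        th = self.th_lo + (p[:, 1] + 1.0) / 2.0 * (self.th_hi - self.th_lo)
        return np.column_stack([rho * np.cos(th), rho * np.sin(th)])


@dataclass(frozen=True)
class MuscleGeometry:
    """Straight-centreline muscle: cross-section extruded along ``axis``
    from ``origin`` over ``length`` metres."""

    section: object
    length: float
    origin: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 0.0, 1.0)

    def frame(self):
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        # any unit vector not parallel to a
        h = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        e1 = np.cross(a, h)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        return a, e1, e2


@dataclass(frozen=True)
class FibrePhysiology:
    """Distributions for per-fibre physiological parameters.

    Conduction velocity ~ Normal(mean, sd) m/s; NMJ position jittered
    uniformly within ``nmj_jitter`` (fraction of fibre length) around the
    midpoint; tendon fraction is the total non-active fraction of the
    fibre length (split evenly between the two ends before NMJ offset).
    """

    velocity_mean: float = 4.0
    velocity_sd: float = 0.3
    nmj_jitter: float = 0.02
    tendon_fraction: float = 0.05
    radius: float = 25e-6
    sigma_in: float = 1.01


def discretize_fibre(path: np.ndarray, delta: float) -> tuple:
    """Resample a 3-D polyline at arc-length spacing <= delta.

    Returns (points, z): arc-length parameterized samples with endpoints
    included.  A path shorter than delta yields its two endpoints with a
    warning.
    """
    if delta <= 0:
        raise ValueError("sample spacing delta must be positive")
    path = np.asarray(path, dtype=float)
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total < delta:
        import warnings

        warnings.warn("fibre path shorter than sample spacing; using endpoints only")
        return path[[0, -1]], np.array([0.0, total])
    n = int(np.ceil(total / delta))
    z = np.linspace(0.0, total, n + 1)
    pts = np.column_stack(
        [np.interp(z, arc, path[:, k]) for k in range(path.shape[1])]
    )
    return pts, z


def straight_fibre(
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    delta: float = 5e-4,
    z0_frac: float = 0.5,
    active_fraction: float = 0.95,
    **physiology,
) -> FibreGeometry:
    """Convenience constructor for a straight fibre."""
    start = np.asarray(start, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    pts, z = discretize_fibre(np.array([start, start + length * d]), delta)
    z0 = z0_frac * length
    active = active_fraction * length
    l1 = min(active / 2.0, length - z0)
    l2 = min(active / 2.0, z0)
    return FibreGeometry(pts, z, z0=z0, L1=l1, L2=l2, **physiology)


def morph_to_muscle(
    population: UnitCirclePopulation,
    geometry: MuscleGeometry,
    delta: float = 5e-4,
    physiology: FibrePhysiology | None = None,
    rng_seed: int = 0,
    muscle_id: int = 0,
) -> MusclePool:
    """Map the unit-circle population into a 3-D muscle.

    Each 2-D fibre position maps through the cross-section and extrudes
    parallel to the centreline over the muscle length.  Per-fibre
    physiology is drawn from ``physiology`` with a deterministic
    per-fibre substream of ``rng_seed``.
    """
    phys = physiology or FibrePhysiology()
    a, e1, e2 = geometry.frame()
    origin = np.asarray(geometry.origin, dtype=float)
    sec = geometry.section.map_points(population.fibres)
    if len(np.unique(np.round(sec, 12), axis=0)) != len(sec):
        raise ValueError("cross-section map is not injective on the fibre set")
    rng = np.random.default_rng(rng_seed)
    length = geometry.length
    n_f = len(sec)
    vels = np.clip(rng.normal(phys.velocity_mean, phys.velocity_sd, n_f), 0.5, None)
    nmj = length * (0.5 + rng.uniform(-phys.nmj_jitter, phys.nmj_jitter, n_f))
    fibres = []
    for i in range(n_f):
        start = origin + sec[i, 0] * e1 + sec[i, 1] * e2
        pts, z = discretize_fibre(np.array([start, start + length * a]), delta)
        z0 = nmj[i]
        half_active = 0.5 * (1.0 - phys.tendon_fraction) * length
        fibres.append(
            FibreGeometry(
                pts,
                z,
                z0=z0,
                L1=min(half_active, length - z0),
                L2=min(half_active, z0),
                radius=phys.radius,
                velocity=float(vels[i]),
                sigma_in=phys.sigma_in,
            )
        )
    counts = np.array(
        [np.sum(population.assignment == m) for m in range(len(population.mu_layout))]
    )
    if np.any(counts == 0):
        import warnings

        warnings.warn(
            f"{int((counts == 0).sum())} motor units received no fibres and "
            "were dropped"
        )
    order = [int(m) for m in np.argsort(counts, kind="stable") if counts[m] > 0]
    mus = [
        MotorUnit(id=int(new_id), fibre_indices=np.where(population.assignment == old)[0])
        for new_id, old in enumerate(order)
    ]
    return MusclePool(muscle_id=muscle_id, fibres=fibres, motor_units=mus)
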