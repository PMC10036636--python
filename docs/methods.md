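# Methods

This note records the models implemented in `myosim`, the defaults
chosen where the underlying physiology or numerics leave freedom, and
what the validation does and does not establish.

## Volume conductor and forward problem

The conductor is a tetrahedral mesh with one region label (bone,
muscle ids, fat, skin) and one symmetric conductivity tensor per
tetrahedron. Muscle is anisotropic,
`sigma = sigma_t I + (sigma_l − sigma_t) d d^T`, with `d` the local
fibre direction; other tissues are isotropic. Internally everything is
SI (metres, seconds, S/m, volts); user-facing configs may carry
`_mm`/`_cm` suffixes that are converted at the boundary. The one
deliberate exception is the intracellular action potential, whose
classical closed form is stated in millimetres and millivolts; that
convention is confined to `sources.py` (conveniently, mV/mm ≡ V/m).

Tissue conductivities are not prescribed by the validation literature,
so the defaults are conventional values: bone 0.02, fat 0.04, skin
0.44, muscle 0.4 longitudinal / 0.08 transverse S/m (anisotropy ratio
5). All are configurable; the FEM-vs-analytic comparison uses the same
values on both sides, so its error bounds are insensitive to this
choice.

The quasi-static potential solves `div(sigma grad phi) = −I` with zero
Neumann data; P1 Galerkin assembly is exact per element (gradients are
constant on tets) and symmetrized to machine precision. The stiffness
matrix has the constant vector in its null space; uniqueness comes
from a zero-mean (average-reference) gauge. Electrode rows of `S^T`
are mean-centred before solving so the singular system is consistent;
monopolar outputs are therefore average-referenced, which drops out of
every differential montage.

**Linear solver.** The adjoint systems `A K^T = S^T` are solved by a
sparse LU factorization of the gauge-pinned system (vertex 0 pinned,
solutions re-centred) shared across all electrode right-hand sides;
for a consistent right-hand side this is exact for the singular
system, and one factorization amortized over `n_e` electrodes is much
faster than iterating per electrode at the mesh sizes this package
targets (10^4–10^5 vertices). A Jacobi-preconditioned conjugate
gradient solver is available (`method="cg"`) for memory-constrained
meshes. Residuals are verified against a default tolerance of 1e-8
because downstream signals are differences of near-equal potentials.

**Point sources.** Any interior source is evaluated by barycentric
interpolation of the basis solutions at the containing tet's vertices
(`v_point = V_basis λ`). Point location uses a centroid KD-tree with
an expanding candidate search; barycentric tolerance is 1e-10 and
face/edge ties resolve to the lowest tet index for determinism.
Patch electrodes are lumped (area-weighted vertex averages), which is
first-order consistent with P1 elements; electrodes snap to the
boundary within 1 mm by default.

**Cylinder phantom mesher.** The multi-layer phantom is meshed by a
structured generator: concentric node rings (always including the
exact layer radii) are stitched by a deterministic angular merge — so
no triangle ever crosses a tissue boundary, which matters for the thin
fat and skin shells — and the disc triangulation is extruded along the
axis, splitting each prism into three tetrahedra with a
smallest-global-index diagonal rule that guarantees a conforming mesh.
Radial, angular and axial grading are exposed on the spec; the
validation mesh refines the muscle/fat/skin shells and the axial core
under the electrode array. The phantom is a finite cylinder (default
length 0.3 m, comfortably longer than fibre plus array; the validation
suite checks that a 50% longer phantom changes the error negligibly).
Mesh I/O supports Gmsh MSH 2.2 and legacy VTK ASCII with region labels
as cell data; negative tets are repaired by vertex swap at load time
and orphan vertices are kept with a warning.

## Fibre sources

The spatial intracellular action potential is
`V_m(z) = 96 z^3 e^(−z) − 90` (mV, z in mm, resting −90 mV for z < 0);
`psi(z) = d/dz V_m(−z)` and the window derivative are evaluated
analytically — no numerical differencing anywhere in the source chain.
Each fibre carries two waves leaving the neuromuscular junction (NMJ)
at velocity `v`, confined to the active semi-lengths `L1`, `L2` by
Tukey windows (taper fraction 0.2 by default; the window family is
fixed, the taper is not, so it is configurable). The electrode signal
uses the midpoint rule over fibre samples with half-interval cell
edges; the default spacing of 0.5 mm changes signals by well under 1%
against a 10× refined quadrature (verified in the suite).

Default per-fibre physiology (used where a study does not specify
values): conduction velocity Normal(4, 0.3) m/s, NMJ jittered ±2% of
fibre length around the midpoint, 5% of the fibre length in the tendon
zones, fibre radius 25 µm, intracellular conductivity 1.01 S/m. These
are standard modelling values and all flow through configuration.

## Motor-unit anatomy

Fibres are sampled uniformly in the unit disc *first*; MU layouts are
generated on top and fibres are assigned afterwards. This ordering
guarantees a uniform fibre density by construction and means a new MU
distribution never touches fibre positions — hence never invalidates
cached per-fibre forward transfers (the staged-reuse contract, asserted
by solver call-counting in the tests).

MU target sizes follow the exponential progression
`s_i = s_min (s_max/s_min)^((i−1)/(n−1))` (endpoints exact; defaults
11 to 1150 fibres over 200 MUs, summing to ≈5×10^4). Territory area
fractions interpolate linearly from 10% to 50% of the cross-section in
MU-size order — small MUs get small territories — with optional
jitter; MU density is target size divided by territory area; centres
are drawn uniformly in the disc of radius `1 − r_territory` so
territories need no clipping. A fibre joins one covering MU with
probability proportional to its density; uncovered fibres (possible,
since coverage is not guaranteed) fall back to the nearest territory.
MUs that end up with zero fibres — likely only in deliberately tiny
pools — are dropped with a warning. Realized sizes recover the target
ranking (rank correlation > 0.95 averaged over repeated layout draws);
a single draw ranks lower (~0.91) because overlapping territories
compete, which is a property of the probabilistic assignment, not an
error.

The unit circle is morphed into a muscle by mapping the disc through a
cross-section (scaled circle; annular sector for phantom muscles; the
rectangular disc→sector map is a documented stand-in for
boundary-conforming morphing of arbitrary sections) and extruding
parallel to a straight centreline. Curved centrelines are out of
scope; `FibreGeometry` accepts arbitrary polylines, so externally
generated curved fibres (e.g. from diffusion imaging) can be supplied
directly.

## Recruitment and rate coding

Thresholds are exponentially spaced from 0.5% to 75% MVC (the last MU
recruited exactly at 75%, so a 75% drive activates the whole pool).
Rate coding is linear with saturation: 8 Hz at threshold, 35 Hz
ceiling, slope chosen so a MU saturates 0.25 MVC above its threshold —
all configurable, since only the 8–35 Hz range and the 75% full-
recruitment level are anchored. Discharge times integrate the
instantaneous rate; each inter-spike interval is scaled by a unit-mean
truncated-normal multiplier (±3 SD) with configurable coefficient of
variation (default 0.15) and floored at a 3 ms refractory interval.
Each MU draws from a deterministic substream of the master seed
(`SeedSequence(master, spawn_key=(mu,))`), so extending the pool never
perturbs existing trains.

## EMG synthesis

MUAP templates are computed once per MU (sum of its fibres' responses)
and treated as time-invariant across discharges; discharges snap to
the nearest sample at the default 2 kHz sampling rate. Montages:
monopolar, single/double differential along the array, and arbitrary
bipolar pairs. Features: windowed RMS and a boxcar periodogram
normalized so the one-sided power sums to signal energy over N
(Parseval-consistent). Optional additive white Gaussian measurement
noise is off by default; realistic noise and artefact models are out
of scope.

## Layered-cylinder reference and validation

The semi-analytic model expands the potential of a point source inside
an infinite layered cylinder in angular harmonics `cos(n Δθ)` and an
axial wavenumber integral. Per `(n, k)` the radial profile combines
modified Bessel functions `I_n`, `K_n`; the muscle layer's anisotropy
enters by scaling the radial argument with `sqrt(sigma_z/sigma_rho)`.
Value and radial-current continuity are imposed at interfaces, zero
radial current at the outer surface, and the source enters through the
radial Green's function jump. Each radial solution is verified in the
test suite against an independent 1-D finite-element oracle for the
same mode equation.

Numerics worth knowing:

* the inverse transform uses panel Gauss–Legendre quadrature (default
  80 panels × 10 nodes to `k_max = 1500` rad/m — the integrand decays
  like `exp(−k·(depth-dependent gap))`, so the tail is negligible for
  validation geometries, and raw Bessel arguments stay far from
  overflow; a guard raises if a configuration would overflow);
* the `n = 0` mode diverges as `C/k²` for `k → 0` because a DC point
  source in an infinite insulated cylinder drives current to axial
  infinity. `C = 2π / Σ(sigma_z · layer area)` in closed form; the
  implementation subtracts `C/k²`, integrates it analytically (the
  physical remainder is `−C|Δz|·π/2` plus an infinite constant that is
  dropped — the documented gauge) and adds an exact `Si`-based tail
  correction beyond `k_max`. Balanced fibre sources and differential
  montages are unaffected by the dropped constant;
* harmonic truncation defaults to N = 30 with a convergence check that
  raises if the last harmonic still contributes more than 1e-4.

The validation experiment rebuilds the classical comparison: four
layers (radii 0.7/2/2.3/2.4 cm), a straight axial fibre at 1–11 mm
below the muscle surface, 16 point electrodes at 8 mm pitch on the
skin directly above the fibre (the pitch is a convention of
high-density arrays; it is configurable), single-differential signals,
NMSE = Σ(a−b)²/Σb². At the default graded mesh (~3.4×10^5 tets,
~6×10^4 vertices, ~25 s on one CPU) the NMSE is ≈1.9% at 1 mm and
≈0.07% at 11 mm depth — within the 3%/5% bounds expected of a correct
implementation — decreases monotonically under refinement, and is
insensitive to cylinder length. Because both pipelines share the same
source quadrature, the comparison isolates the volume-conductor
solution, which is the quantity under test.

## Window generator

Training windows default to 160 samples at 2048 Hz with 130 channels:
with 50% probability the target MUAP is placed at the window centre
(positive label), 0–4 distractor templates from other classes are
added at uniform random offsets (each keeping at least one sample in
the window), unit-variance Gaussian noise is added, and the binary
label refers to target activity within the central 80 samples (a
target shifted beyond half the label span labels negative). Datasets
are organised as independent sets — e.g. 64 sets of 5 MUAP classes —
each with its own label space, with the generating spec and seeds in a
manifest; identical seeds reproduce byte-identical datasets.

## What the tests show — and what they do not

The synthetic phantom exercises every pipeline stage against
closed-form, brute-force or cross-method oracles, and the test suite
uses deliberately scaled problem sizes (coarse phantom meshes, pools
of 10^3–10^4 fibres, 25-seed stochastic recoveries) so the whole run
stays in minutes. Passing them establishes internal correctness of
the forward solution, source model, recruitment statistics and
assembly — not realism of any particular anatomy: real limbs have
curved fibres, inhomogeneous tissue, electrode-skin impedance, noise
and movement, none of which the phantom represents. The cylinder
validation bounds the numerical error of the FEM pipeline in a
geometry where an independent semi-analytic solution exists; accuracy
on anatomical meshes depends on their resolution in the same way.

## Known limitations

* Straight-centreline morphing only; no surface-to-volume meshing of
  arbitrary anatomy (pre-built tetrahedral meshes are accepted).
* P1 elements; no higher-order or boundary-element solvers.
* No motor-neuron biophysics, common synaptic noise or MU coherence;
  rate coding is memoryless.
* MUAP templates are stationary (no fatigue-related velocity change).
* The sparse LU default is memory-bound around ~3×10^5 vertices; use
  the CG option beyond that.
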