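# Methods

## Physical model

Light transport is treated in the geometric-optics limit: photons are
individual rays with a position (µm) and a unit direction, marched through
a slab of dielectric bodies by a constant geometric step s (default
10⁻³ mm = 1 µm). Volumetric scattering and absorption inside and between
the cells are neglected — at body temperature the lipid interior of an
adipocyte is optically clean, so the only events are Fresnel reflection and
Snell refraction at cell boundaries. Wave effects (diffraction,
interference, polarization) are outside the model; the simulated fluence is
therefore a ray-density quantity, not a coherent field.

Photons are launched on the z = 0 face with direction (0, 0, 1), uniformly
over the face (or over a rectangular window or circular beam when a
restricted illumination is wanted). Each step advances the position by
s·**e**. At every step the medium membership of both endpoints is compared;
if it differs, the interface point is located exactly (analytic ray–sphere
intersection) or by bisection to s/100 (voxel masks), and the photon is
either specularly reflected or refracted:

- reflection: **e**′ = **e** − 2(**e**·**n**)**n**;
- refraction: **e**₂ = µ**e** + (√((1−µ²)/(µ²a²) + 1) − 1)µa**n**, with
  µ = n₁/n₂ and a = **e**·**n**, the normal re-oriented so a < 0;
- the choice is stochastic: reflect with probability R(α_i), the
  unpolarized Fresnel reflectance, else refract. Past the critical angle
  (the square root above turns imaginary) the photon always reflects —
  total internal reflection, which is possible only when leaving a cell
  (µ = m > 1, critical angle arcsin(1/m) ≈ 76.1° for m = 1.03.)

Each photon is a weightless, indivisible ray: no splitting, no roulette.
Terminal states are transmitted (z ≥ thickness), back-reflected (z < 0),
side exit (lateral faces, absorbing), or a step-budget cut-off
(max_steps, default 10 × thickness/s, which bounds TIR-trapped orbits);
the terminal counts partition the launched photons exactly.

### Numerical choices

- The Fresnel formula is 0/0 at normal incidence; below α_i = 10⁻⁶ rad the
  analytic limit ((n₁−n₂)/(n₁+n₂))² is used. The tangent term is evaluated
  in a cosine form that stays finite when α_i + α_t = π/2 (Brewster
  suppression). Grazing hits (|**e**·**n**| < 10⁻⁹) are degenerate and
  terminate the photon (counted with the side exits).
- After an interface interaction the photon is offset by s/100 along its
  new direction so the next membership query is unambiguous.
- If two interfaces fall inside one step (possible at near-contact sphere
  gaps), the nearest crossing is used and a warning counter incremented;
  at s = 1 µm this affects a fraction ~10⁻⁵ of steps.
- The final step of a photon is clipped at the slab face: path beyond the
  boundary is not deposited as fluence.
- Fluence estimator: each (sub-)step deposits its path length (µm) into
  the voxel containing its midpoint — the standard collision-free
  path-length estimator. Grids are float32 on disk (32-bit TIFF); per-ray
  normalization (path / rays / voxel volume) makes runs of different sizes
  comparable.
- Determinism: one RNG stream drives launches and Fresnel decisions,
  re-seeded per fixed 10⁴-ray chunk by a fixed derivation from the run
  seed, so a run is bit-identical regardless of progress reporting.

## Scene generation (what the synthetic tissue emulates, and what not)

"Quasi-ordered" packing is realized as a cubic lattice (pitch = slab
extent / lattice count per axis) with one sphere per site, centres jittered
by a uniform per-axis offset up to jitter_fraction·pitch/2 (default 0.3),
and diameters uniform in mean ± halfwidth (defaults 60 ± 10 µm, the typical
adipocyte size band). Jittered placements overlapping an already-placed
sphere are re-drawn (≤ 100 attempts, then the un-jittered site); generated
scenes are checked pairwise non-overlapping. The generator requires
pitch ≥ mean + halfwidth so that the zero-jitter lattice can never overlap;
with 60 ± 10 µm cells this makes the minimum pitch 70 µm, hence the
8-layer reference slab is 560 µm deep. This emulates the near-contact,
near-lattice arrangement seen in real adipose tissue; it does not emulate
polydisperse clustering, cell-shape irregularity (that is what the voxel
masks are for), nor any physiological packing statistics — so slab results
show that quasi-order plus optical softness suffice for multi-spot
focusing, not that the simulated statistics match a particular tissue
sample.

Only the relative index m enters the optics, so absolute indices are fixed
as n_out = 1.36 (interstitial-fluid-like) with n_in = m·n_out for tissue
scenes, and n_out = 1, n_in = 1.44 for a cell in air. Points exactly on a
surface count as interior (removes a measure-zero ambiguity). Irregular
cells are closed binary voxel masks; their outward normals are the
negative gradient of the Gaussian-smoothed occupancy, interpolated
tri-linearly. The smoothing width is 2 voxels: at 1 µm pitch this leaves
~1° median normal error on a rasterized sphere, comfortably below the
paraxial surface tilt that drives lensing, whereas 1-voxel smoothing
leaves several degrees of noise that visibly biases the traced focus.

## Analysis

Axial profiles average the per-ray fluence over a lateral disc per
z-slice (default 3-slice moving average). For locating a focus, the bare
argmax is unreliable: once the converging beam is narrower than the
measurement footprint the profile is a flat-topped plateau symmetric about
the focus, so the peak locator takes the fluence-weighted centroid of the
contiguous ≥ 90%-of-max region around the argmax. Focal spots are 3D local
maxima of the Gaussian-smoothed (σ = 1 voxel) volume, kept above a
prominence threshold (default 0.1 of the global max) with a greedy
minimum-separation filter (default 20 µm) and axis-aligned FWHMs; these
thresholds are artifact-defined knobs — the underlying observation has no
quantitative spot statistics to calibrate against — and are exposed as
configuration. Focusing gain compares the downstream axial profile with an
empty-scene reference traced under identical conditions.

The paraxial ball-lens focal distance f = m·d/(4(m−1)), measured from the
sphere centre (both principal planes of a ball lens sit at its centre; this
is not the back focal length), serves as the independent closed-form
oracle: traced single-cell foci recover it to < 1% for m = 1.44 and
m = 1.03 (the latter needs a slab extended well past f so the caustic
plateau is not clipped).

## Reference problem sizes

The reference runs use 10⁵ rays (slab and single-cell studies alike) on
grids of 2 µm (slab) or 1 µm (single-cell) pitch; at these sizes the
compiled kernels trace the full slab study in seconds and every reported
quantity is stable to well inside its stated tolerance (e.g. the Fresnel
reflectance check is a 3σ binomial band at n = 10⁵). The ray count is a
deliberate scale-down of the 10⁶-ray full-resolution condition, which the
same configuration reproduces by changing `n_rays`.

## Design choices where the design was open

- Fresnel accounting by stochastic branching (one weightless photon per
  ray), not deterministic ray splitting: keeps the "individual rays"
  ensemble semantics and a fixed memory footprint; splitting is a possible
  alternative, not implemented.
- Interface location is exact (or bisected to s/100), not accepted at the
  ±s marching quantization: s = 1 µm is 1.7% of a cell diameter and focal
  positions are sensitive to it.
- Lateral boundaries absorb; no periodic wrap. This matches a finite
  illuminated field; near-wall columns are therefore edge-affected and the
  translation-covariance guarantee holds for the interior only.
- The monotone-focusing check across m = 1.01 → 1.06 uses the depth of the
  brightest interior focus (which scales like the cascade focal length,
  ∝ 1/(m−1), and decreases robustly with m) rather than a spot count: at
  10⁵-ray resolution the count at a fixed relative prominence is not a
  stable readout, because the global maximum it is measured against itself
  grows with m.

## Known limitations

- Voxel-mask surfaces are rasterized: crossings land on the staircase
  boundary within ± half a voxel. At 1 µm pitch this biases the traced
  focal distance of a voxelized 60 µm sphere by ~10% (the analytic-sphere
  path has no such bias); finer pitch reduces it at memory cost.
- Spot counts at fixed relative prominence fluctuate with the scene seed
  (typically 3–7 spots on the central column of the reference slab at
  10⁵ rays; some jitter realizations give 1–2 when one cascade focus
  dominates the interior). The slab analysis excludes a one-lattice-cell
  margin next to the absorbing walls, whose edge-affected columns would
  otherwise set the prominence reference.
- No volumetric scattering/absorption, no wave optics, no polarization,
  no temperature dependence of the lipid phase.
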