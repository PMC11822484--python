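# Methods

`mstsim` couples a deterministic heat-conduction solve to a stochastic
single-particle transport model. This note records the model, its
assumptions, the defaults and why they were chosen, and what the synthetic
runs can and cannot say about real experiments.

## Thermal stage

**Model.** A continuous-wave near-infrared laser (1560 nm) heats the water
film of a sample chamber: two borosilicate coverslips (150 µm each)
sandwiching an 8 µm water layer. Water absorbs with coefficient
α = 967 m⁻¹, so the absorbed power is P_abs = P_in (1 − e^{−αL}) with
L the film thickness. Because the beam's axial extent (~140 µm FWHM) far
exceeds the film, the heat is deposited uniformly in a cylinder of diameter
equal to the lateral FWHM (27.6 µm) spanning the film; dividing P_abs by the
cylinder volume gives the volumetric source Q_V. The steady temperature
field obeys ∇·(k∇T) + Q = 0 with Q = Q_V inside the cylinder and zero
elsewhere, water conductivity k(T) = 0.61 + 0.0012 (T − 298 K) W m⁻¹ K⁻¹,
a constant glass conductivity, continuous temperature and flux at the
interfaces, and ambient Dirichlet values (24 °C) on the outer surfaces.

**Discretisation.** The geometry is rotationally symmetric, so the problem
is solved in (r, z) on a cell-centred finite-volume mesh: uniform radial
cells to 1.5 source radii (faces aligned with the source edge), geometric
stretching to the lateral boundary (default 300 µm), uniform axial cells in
the water (odd count, so one cell centre lies exactly on the mid-plane) and
geometrically stretched cells through the glass. Face conductances use the
series (harmonic) combination of the adjacent half-cell resistances, which
handles the water/glass interface without smearing. The mild k(T)
nonlinearity is resolved by Picard iteration (conductivities frozen at the
previous iterate; default tolerance 10⁻⁶ K on the maximum update, cap 100
iterations; the reference case converges in 3). Finite volumes make the
discrete energy balance exact: the net flux through the Dirichlet faces
reproduces the injected power to the linear-solver round-off (~10⁻¹⁰
relative), and the default mesh is converged to <1 % in ΔT_max against a
doubled mesh.

**Verification.** The solver was checked against an independent
semi-analytic oracle — the Hankel-transform solution of a uniform
cylindrical source in a constant-k layered slab of infinite lateral extent —
agreeing to better than 0.1 % in the mid-plane temperature at all radii, and
against the textbook point-source far field P_abs/(4πkr) in a homogeneous
thick-slab configuration (within 5 % for r ≥ 3 source radii).

**Free parameters.** The glass conductivity is not fixed by the study
conditions; the default is 1.14 W m⁻¹ K⁻¹ (borosilicate, temperature
independent), exposed in the config. ΔT_max is insensitive (<2 %) to
doubling the lateral domain radius, and moves roughly inversely with the
glass conductivity (1.0 → 1.81 K, 1.14 → 1.66 K at 20.5 mW), which bounds
the model-fidelity uncertainty of the thermal stage at roughly ±10 %.
The ambient is 297.15 K for the solver boundary; room temperature for the
particle-stage formulas is 297 K. Both are configurable.

**Mid-plane field.** The 2D field that drives the particles is the z = 0
radial profile revolved onto a Cartesian grid (default ±150 µm, 0.5 µm
spacing), with gradients computed on the nodes by second-order central
differences and then sampled — like the temperature — by first-order
(bilinear) interpolation. Externally measured temperature maps (e.g. from
fluorescence thermometry) can be imported from delimited text in K or °C
and are treated identically.

## Particle stage

**Model.** Particles are 500 nm polystyrene spheres (radius a = 250 nm) in
water, far below the Reynolds/relaxation scales where inertia matters, so
the dynamics are overdamped: γ dr/dt = F_B + F_tph with Stokes drag
γ = 6πµ(T)a and µ(T) = 2.761×10⁻⁶ exp(1713/T) Pa s. The thermophoretic
drift is v = −D_T(T)∇T, equivalently a force F_tph = −γ(T) D_T(T) ∇T; the
tabulated mobility D_T(T) is linearly interpolated in temperature and
clamped beyond the table. Discretised with time step Δt:

    r_{i+1} = r_i − D_T(T_i) ∇T_i Δt + Δr_B,

with each component of Δr_B drawn from N(0, 2 k_B T_room Δt / γ(T_room)).
The random-force temperature is fixed at room temperature (a local-T mode
exists but is off by default). Normal deviates come from an explicit
Box–Muller transform of a seeded PCG64 uniform stream; runs are
bit-reproducible, and the Brownian-only control run with the same seed
consumes the identical increment sequence. Particles do not interact, and
the dynamics are purely 2D on the mid-plane (justified by the thin film:
no axial stratification and negligible convection at low power).

**Defaults.** 1000 particles start uniformly in a 100 × 100 µm² square and
run for 1200 s, recorded every 1 s. Δt = 0.05 s keeps the RMS Brownian step
(~0.4 µm) and the largest drift step (~0.01 µm) well below the field length
scale (~14 µm); a warning is emitted if the drift per step would exceed one
field cell. Walls are reflecting. The default box half-width is 150 µm —
deliberately larger than the init square: the experimental chamber is a
millimetre-scale reservoir, and the hallmark of the reference data (radial
concentration recovering to ~1 away from the spot) only occurs when the
particles displaced from the hot region can dilute into surrounding fluid.
A closed box the size of the init square conserves the particles inside the
analysis region and inflates the concentration ratio by ~25 %; with the
150 µm box the residual renormalisation is a few per cent. The init-sized
box remains available in the config for closed-cell studies.

**Mobility table.** The study interpolates a published temperature-dependent
D_T(T) for bare polystyrene spheres but does not print the table. The
shipped default is anchored at D_T(297 K) = 1.08×10⁻¹² m² K⁻¹ s⁻¹ — the
value consistent with the reported S_T = D_T/D = 1.1 K⁻¹ and
D(297 K) = 9.85×10⁻¹³ m² s⁻¹ — with a positive slope of 2×10⁻¹⁴
m² K⁻¹ s⁻¹ per K over 290–320 K, typical of aqueous polystyrene colloids.
The table is a first-class config input (two-column text file or inline),
so any published model can be substituted. Negative-S_T (thermophilic)
tables are representable but not modelled further.

## Analysis stage

Radial concentration: occupancies of the thermophoretic and the seed-matched
Brownian-only run are accumulated over all recorded frames in the 600–1200 s
window into 100 equal bins spanning 0–100 µm, and the per-bin ratio
N_tph/N_ref is the relative concentration c/c0. The central value is the
innermost bin with nonzero reference counts; because that 1 µm bin holds
only a handful of serially correlated counts, its single-run value scatters
with SD ≈ 0.06 between seeds, and pooling the innermost bins (an explicit
option) or averaging over seeds is recommended for quantitative work — the
acceptance script averages twelve seeded runs. Empty reference bins yield
an undefined (NaN) ratio, never a silent zero.

Soret inversion: at equilibrium, small temperature rise and negligible
convection, c/c0 = exp(−S_T (T − T0)), so S_T = −ln(c/c0)/ΔT and
D_T = S_T D(T). With the random-force temperature pinned at T_room the
exact steady state is exp(−S_T ∫ D(T)/D(T_room) dT); for the ~1.7 K rises
here the correction is a few per cent and the simple law is used, matching
the study's own evaluation.

Force profile: |F_tph| = γ(T) D_T(T) |∇T| is evaluated at 3000 positions
sampled uniformly in a 50 × 50 µm² region and averaged in 100 radial bins
over 0–50 µm. The profile is a deterministic function of radius up to the
anisotropy of the Cartesian grid, so the sample count only controls bin
coverage.

MSD: ensemble- and time-averaged, used to calibrate the engine against the
2D Einstein relation (slope 4D); the calibration runs in an enlarged box so
wall reflections do not bias the slope.

## Known limitations

- Every depletion observable inherits the thermal stage's amplitude
  uncertainty *exponentially*: c/c0 ≈ exp(−S_T ΔT), so the ±10 % spread in
  ΔT_max from the unknown glass conductivity maps to roughly ∓20 % on the
  central concentration ratio (with the default k_glass = 1.14 the 20.5 mW
  pipeline settles at c/c0 ≈ 0.17–0.20 at the spot centre; a lower glass
  conductivity near 1.0 W m⁻¹ K⁻¹ raises ΔT_max to ~1.8 K and deepens the
  depletion to ~0.15). When matching a specific experiment, calibrate
  `thermal.k_glass` against a measured spot temperature first.
- The force-profile peak computed from this thermal model is ~0.6 fN at
  20.5 mW, below the ~0.8 fN reported for the reference configuration. The
  continuum mid-plane gradient maximum of the layered-conduction model is
  1.30×10⁵ K m⁻¹ (confirmed by the independent Hankel oracle and stable
  under mesh refinement, glass conductivity in 1.0–1.2 W m⁻¹ K⁻¹, and
  domain-size changes), whereas ~0.8 fN implies ~1.8×10⁵ K m⁻¹. The
  discrepancy is consistent with gradient-recovery noise in elementwise FEM
  exports (|∇T| of a noisy gradient is biased upward near the source rim)
  or with figure-reading imprecision, but it cannot be reproduced by any
  parameter this model exposes.
- Transient heating, natural convection (relevant at the higher powers,
  where the reference experiments themselves do not equilibrate), Gaussian
  axial beam profiles, optical forces, hydrodynamic and interparticle
  interactions are all out of scope.
- The synthetic runs emulate ideal dilute hard spheres over a static field.
  They contain none of the experimental nuisances (scattering-intensity
  calibration, camera noise, surfactant effects, z-averaging of the
  dark-field signal), so agreement of the pipeline with its own oracles
  validates the method, not the microscopic D_T model; the latter enters
  only through the user-supplied table.

## Problem sizes

Default runs used throughout the tests and the acceptance script: ~11 000
finite-volume cells for the thermal solve (3 Picard iterations), 1000
particles × 24 000 steps per Brownian-dynamics run, twelve seeded run pairs
for the central-depletion estimate, and 3000 sampled positions for the
force profile. A full pipeline run completes in well under a minute on one
core.
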