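# Methods

## Scope and model

`rfasim` simulates irrigated-tip RF catheter ablation as a one-way-coupled
quasi-static electrical / transient thermal problem, in the configuration
used by the two preclinical lesion-assessment preparations:

* **BH** — a myocardium slab (homogeneous, non-contracting) under a blood
  pool that fills the chamber out to the domain boundary; the dispersive
  return electrode is a 0 V condition on every outer limit (the model is
  limited-domain: 40 mm around the electrode).
* **TM** — a striated-muscle slab under a blood pool of finite height
  (default 20 mm) topped by air, modeled as a zero-current boundary; all
  other outer limits are 0 V.
* **INTERMEDIATE** — TM geometry with myocardium properties, so the
  comparison TM vs. INTERMEDIATE isolates the material effect and
  INTERMEDIATE vs. BH the geometric one.

The catheter is a 7.5 Fr (2.5 mm) electrode of 3.5 mm total length,
idealized as a 2.25 mm cylinder plus a 1.25 mm-radius hemispherical tip
(the standard irrigated-tip idealization; the tip shape is not otherwise
constrained), on a polyurethane shaft modeled for four electrode diameters.
Orientations 90°/45°/0° use insertion depths 0.5/0.498/0.193 mm; these
equalize the electrode–tissue contact area to within 0.5 % (checked by
surface quadrature in the test suite). The tissue surface stays flat; the
electrode is embedded by Boolean subtraction (no mechanical deformation).

### Electrical problem

∇·(σ(T)∇Φ) = 0 with the electrode surface as an equipotential. Because the
Pt-Ir electrode is ~10⁷ times more conductive than tissue, its interior is
removed from the conduction domain and represented by a Dirichlet surface;
this avoids an ill-conditioned matrix without changing the field. Blood
(σ = 0.748 S/m) is a conductor but not part of the thermal domain; its
conductivity is held constant since its temperature is never solved. The
shaft conducts with σ = 10⁻⁵ S/m (insulator; ~10⁻⁶ of the power). Tissue
conductivity rises 1.5 %/°C from its 37 °C reference and collapses
log-linearly by a factor 100 across 99–101 °C (the collapse shape is not
prescribed by measurements; log-linear is smooth, monotone and bounded).

Constant-power control exploits linearity: the unit-voltage solve is
rescaled by √(P_target/P_unit) each step, which is exact at frozen σ. The
electrical problem is re-solved every thermal step. Per-region powers are
integrals of σ|∇Φ|²; P_T is the tissue share at the first in-pulse solve,
E_T the tissue share of cumulated energy at pulse end.

### Thermal problem

The bioheat equation in enthalpy form, ∂h/∂t = ∇·(k∇T) + Q_RF, on
tissue + electrode + shaft (blood excluded; capillary perfusion and
metabolic heat neglected as second-order). The enthalpy h(T) is piecewise
linear: slope ρc below 99 °C, H_t/ΔT across the 99–100 °C vaporization band
(H_t = 2.161×10⁹ J/m³ × water mass fraction; ΔT = 1 °C), and ρc again above
(dehydrated properties taken equal to hydrated — the known impact on lesion
size is ≪ 0.1 mm). The sensible branch extends below 37 °C so the 25 °C
irrigated zone is representable.

Boundary conditions: Robin (Newton cooling) against 37 °C blood with
h = 3310 W/m²K on electrode/shaft–blood and 694 W/m²K on tissue–blood
interfaces (0.1 m/s local flow); 25 °C Dirichlet on the cylindrical
electrode zone (multi-hole irrigation), with the hemispherical tip left
free — its blood-exposed part gets the electrode–blood Robin condition and
its buried part is an internal conduction interface; 37 °C Dirichlet on the
outer tissue contour.

### Damage and lesion metrics

Ω(t) = ∫ A e^(−Ea/(R·T_K)) dτ with A = 7.39×10³⁹ s⁻¹,
Ea = 2.577×10⁵ J/mol, one parameter set for both tissues, accumulated per
node by the trapezoidal rule on the solver's time grid (second order,
matching the stepping granularity). Ω = 1 (63 % cell death) is the lesion
contour; the threshold is configurable for sensitivity work. Depth is
measured from the undisturbed surface plane z = 0 (not from the electrode
tip); maximum width is the largest horizontal diameter over all depths;
volume is the exact integral of the supra-threshold region of the P1
interpolant (polygon clipping revolved in axisymmetric mode; the exact
piecewise-cubic simplex volume-fraction formula, verified against Monte
Carlo, in 3D). Volumes are full-lesion values (revolved / doubled
half-domain), consistent with half-ellipsoid estimates from the printed
depths and widths.

## Numerics

* **Discretization.** P1 finite elements; structured graded tensor-product
  meshes (triangles with alternating diagonals in axisymmetric mode, Kuhn
  6-tet splits in 3D). Region assignment is by element centroid, so the
  curved tip is a staircase at the local mesh size; grid lines are placed
  on all planar material interfaces (cylinder radius, surface plane, band
  edges of the domain), which the near-field volume checks show is accurate
  to ~1 % at default density.
* **Mode choice.** 90° scenarios are genuinely axisymmetric apart from the
  far-field box, whose influence is screened by the 0 V condition at 40 mm;
  they run in (r, z) with all measures carrying 2πr. 0°/45° scenarios run
  on a half-domain (one symmetry plane) with extensive quantities doubled.
* **Time stepping.** Implicit (backward) Euler, dt = 50 ms in-pulse and
  100 ms post-pulse by default (both inside the 20–100 ms range validated
  by the convergence criteria below). The apparent heat capacity is the
  *enthalpy secant* between the old and current iterate, lumped per node;
  after the Picard loop the accepted update is converted to an enthalpy
  increment and inverted through the monotone nodal enthalpy function, so
  a node crossing the latent band in one step conserves energy exactly.
  Nonlinearity is handled by damped Picard (tolerance 0.1 °C max nodal
  update, adaptive under-relaxation with floor 0.1, cap 30 iterations,
  recursive dt-halving to the 20 ms floor as a fallback) — plain
  undamped Picard cycles across the band edge once vaporization starts.
  LU factorizations are cached and reused while the capacity vector is
  unchanged (the common case below 99 °C).
* **Energy audit.** Every step independently computes deposited energy,
  stored-enthalpy change, Robin losses (facet integrals) and Dirichlet
  losses (constraint reactions); the run-cumulative balance closes to
  round-off and is asserted at 1 % in the tests.
* **Convergence controls.** The convergence harness compares lesion depth
  and peak tissue temperature across refinements with the 0.5 mm / 1 °C
  criteria. Default axisymmetric density (0.12 mm minimum edge at the
  electrode, ~2,700 nodes) reproduces the tabulated 90° lesion metrics
  within those criteria while running a 90 s scenario in ~10 s; the 0.1 mm
  setting reaches the 118 µm paper-grade refinement when wanted. 3D runs
  default to 0.55 mm minimum edge (~20k nodes) and are used for
  ordering/ratio statements and the anisotropy comparison, not for numeric
  equality — at these densities the staircase tip and cell size dominate
  absolute errors, but paired comparisons on a shared mesh cancel most of
  the discretization bias.
* **Degenerate inputs.** Zero-duration pulses are legal (inert run, empty
  lesion); nodes exactly on a contour level are emitted as contour points;
  empty lesions are a valid result, not an error.

## Anisotropy

Muscle thermal conductivity is ~30 % higher along fibers than across them.
The anisotropic variant uses a transversely isotropic tensor
diag(0.633, 0.487, 0.487) W/m·K with the fiber axis x parallel to the
tissue surface; the mean of the directional values equals the isotropic
0.56 W/m·K. The axisymmetric mode cannot represent a surface-parallel fiber
direction and rejects the flag; the study runs paired isotropic/anisotropic
simulations on one shared 3D mesh. The tested setting (25 W/20 s, 40 s
horizon, 1.1 mm cells) resolves the paired deltas: depth moves < 0.1 mm and
the fiber-direction width grows 0.2–0.3 mm relative to isotropic.

## What the analytic fixtures do and do not show

The verification module builds closed-form benchmarks: a convectively
cooled slab (≥ 10-term series plus the lumped small-Biot limit) for the
transient stepper and Robin machinery; concentric-spheres conduction
(conductance 4πσ/(1/r₁ − 1/r₂), Q ∝ r⁻⁴, exact power normalization) for
the electrical solve and the axisymmetric measures; and constant/ramped
temperature programs against high-precision quadrature for the damage
integral. These validate each operator against exact solutions; they do not
validate the biological inputs themselves (σ(T) law, Arrhenius constants,
convection coefficients), whose uncertainty — particularly the tissue
conductivities taken from a database with known sub-MHz limitations — is
the dominant real-world error source. Passing tests therefore demonstrate a
correct solver for the stated constitutive model, not clinical accuracy.

## Known limitations

* No steam dynamics: above ~100 °C the model only collapses σ and absorbs
  latent heat; it says nothing about steam pops.
* No tissue mechanics: contact force enters only through the fixed
  insertion depths; no surface deformation.
* No blood flow field: convection is coefficient-based; no temperature is
  solved in blood, so blood-side heating feedback is absent.
* One Arrhenius parameter set for both tissues.
* Power-controlled ablation only (no temperature- or impedance-control
  modes).
* 3D runs use centroid-voxel geometry at coarse density; their absolute
  lesion metrics carry O(cell size) error and are only used comparatively.
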