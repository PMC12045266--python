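# Methods

## Physical model

The package simulates electroporation of a single 2D (plane-geometry) cell
in a conducting bath between plate electrodes. Three membrane systems are
represented: the plasma membrane, the nuclear envelope, and the
endoplasmic reticulum as a family of up to 36 disjoint closed loops. All
bulk compartments (bath, cytoplasm, nucleoplasm, ER matrix) are aqueous
conductors (σ = 0.55 S/m, ε_r = 67 by default).

**Field problem.** The potential obeys the quasi-static charge-conservation
equation ∇·(σ∇φ + ε₀ε_r ∂ₜ∇φ) = 0 with Dirichlet electrodes (left edge at
U(t) = E_app·L_x, right edge grounded) and insulating top/bottom edges.
The bulk displacement term is off by default: the bulk Maxwell–Wagner time
ε₀ε_r/σ ≈ 1 ns is far below the 10 µs pulse edges, so conduction dominates.
It is switched on for the 100 ns pulse variant, whose 10 ns edges are
comparable to that time scale.

**Membranes.** A membrane of thickness d (10 nm plasma/ER, 40 nm nuclear
envelope) is 10⁴ times thinner than the domain; meshing it as a layer is
intractable and unnecessary. Each membrane is a zero-thickness polyline of
mesh edges whose nodes carry two potential DOFs (outer/inner). The normal
current through the interface is J·n = C_m dV_m/dt + g V_m with
V_m = φ_outer − φ_inner, C_m = ε₀ε_r/d and g = σ_m/d. This
distributed-impedance (contact-impedance) condition is the standard
equivalent of a resistive-capacitive thin layer at thickness ≪ radius; the
equivalence is checked by the Schwan validation below rather than assumed.

**Pore dynamics.** Electroporation follows the asymptotic reduction of the
Smoluchowski pore-energy model: pore density N(t) per membrane node with
dN/dt = α e^s (1 − (N/N₀)e^{−qs}), s = (V_m/V_ep)², and conductivity
σ_m = σ_m0 + N π r_p² σ_p K(V_m) with fixed pore radius r_p. K is the
voltage-dependent pore conductance factor of the asymptotic model
(energy barrier w₀ = 2.65 kT, relative entrance length n = 0.15); its
closed form has removable singularities at v_m = 0 and n·v_m = ±w₀
(v_m = F·V_m/RT) which are evaluated by their analytic limits, and the
large-v_m branch is computed with e^{v_m} divided out so it cannot
overflow. K rises from e^{−w₀} ≈ 0.071 at rest to ≈ 0.56 at 1 V and → 1
asymptotically.

Default parameters (α = 10⁹ m⁻²s⁻¹, N₀ = 1.5·10⁹ m⁻², V_ep = 0.258 V,
q = 2.46, r_p = 0.76 nm, σ_p = 1.3 S/m, T = 295 K; σ_m0 = 1.1·10⁻⁷ S/m for
plasma/ER and 1.1·10⁻⁵ S/m for the nuclear envelope, ε_r = 5 for all
membranes) are the classical mammalian-cell set. σ_p is nominally the
harmonic mean 2σ_eσ_i/(σ_e+σ_i) of the bulk conductivities, which would
give 0.55 S/m; the tabulated 1.3 S/m differs, and both are supported
(`sigma_p_mode = use_table_value | use_eq2`, default the tabulated value,
which is the stated simulation input of the source parameter set).

## Numerics

**Meshing.** A graded point cloud (membrane polylines resampled at
h_membrane, offset rings growing geometrically to h_bulk, a hexagonal bulk
lattice, box-edge points) is Delaunay-triangulated; required interface
segments missing from the triangulation are recovered by deleting the free
points that block them; one Laplacian smoothing pass improves shape
quality (minimum angle ≥ 15° on the shipped configurations). Region ids
are assigned by point-in-polygon tests of triangle centroids against the
resampled membrane polygons. Defaults h_membrane = 0.15 µm,
h_bulk = 1.5 µm resolve the cosine V_m profile with ~190 nodes on the
plasma membrane of the reference cell.

**Time stepping.** Backward Euler with 0.25 µs steps on the pulse edges
and 1 µs on the plateau (1 ns / 2.5 ns for the 100 ns variant), 10 µs
post-pulse tail. The membrane charging time of the reference cell is
~50 ns, far below the step — V_m tracks the pulse quasi-statically, which
is the regime of interest; the charging transient itself is validated
separately at nanosecond steps.

**Coupling.** Per step, a fixed-point iteration alternates the linear FEM
solve (SuperLU on the reduced system) with the frozen-V_m pore update, to a
relative V_m tolerance of 10⁻⁶ (max 25 iterations). The N update uses the
exact exponential integrator of the linear-in-N ODE, written in expm1 form:
N' = N + (N_eq − N)(1 − e^{−b dt}). The naive form
N_eq + (N − N_eq)e^{−b dt} loses all precision when N_eq ≫ N and
b·dt ≪ 1 — exactly the suprathreshold regime, where N_eq ~ 10²⁶ m⁻² while
N ~ 10¹². The raw fixed point diverges during the electroporation burst
(the loop gain scales like α e^s dt and reaches 10²–10³), so the iterate is
under-relaxed with Aitken's Δ² factor, which adapts the relaxation to the
local gain; a step that still fails is retried as two half steps. Transient
iterates are kept finite by clipping s so e^{qs}·N₀ stays representable and
by capping g far beyond its short-circuit limit; converged states never
reach either guard.

**Validation anchors.** (i) A homogeneous box reproduces the linear
potential to 0.1%. (ii) A resting disc cell reproduces the 2D steady-state
induced potential 2·E·R·cos θ at the pole within 2% and with cosine-fit
R² ≥ 0.99. Note the plane-geometry coefficient is 2, not the spherical
3/2 often quoted; `schwan_reference` returns both, and validation uses the
2D value. About −0.4% of the residual pole error is physical (finite
100 × 70 µm bath vs the unbounded-medium formula), the rest is bulk P1
discretization; the default resolution sits at −1.3%, chosen as the best
accuracy/runtime point from a refinement study (finer meshes halve the
error but quadruple run time). (iii) The membrane charging time matches
the cylinder analytic value τ = R·C_m·(1/σ_i + 1/σ_e) within 20% at
nanosecond steps.

## Reference geometry and calibration

The real imaged cell behind the reference observables is not distributable, so
the reference configuration is a surrogate disc cell, radius 4.4 µm with a
2 µm nucleus, centred in the 100 × 70 µm bath. The radius is a
calibration, not a measurement: it is chosen so that the 2D steady pole
potential at 1.2 kV/cm, 2·E·R = 1.056 V, reproduces the reported ~1.05 V
plasma-membrane plateau, which simultaneously places the TMP-criterion
threshold at 1.2 kV/cm on the 0.1 kV/cm grid. With this calibration the
transient run at 1.2 kV/cm yields a 20 µs plateau of 1.043 V and a pulse-end
pore density of 1.1·10¹² m⁻² at the pole (reported: ~2·10¹² m⁻²; the gap is
the −1.3% discretization bias amplified by the e^{(V_m/V_ep)²} rate, and
stays within the order-of-magnitude gate used for this quantity).

The pore-density threshold of the calibrated disc comes out at 1.5 kV/cm,
below the 1.7 kV/cm reference value. This is a genuine model-level difference,
not a numerical artifact: the peak N at 1.5 kV/cm is 24% above the 10¹⁴ m⁻²
level, changes by <0.5% under dt halving, and the threshold is unchanged
under mesh refinement. The V_m-based calibration fixes E·R but not the
suppression feedback that limits pore growth (set by σ_p·K and the
geometry); with the adopted K expression and tabulated σ_p the surrogate
disc's pore dynamics cross the criterion one to two grid steps early.
Nuclear/ER thresholds of synthetic geometries are reported by the sweep but
are regression numbers only — they depend strongly on the irregular
real-cell geometry and are not comparable to the reference organelle values.

## Synthetic imaging stage

`render_stain_image` produces a two-channel raster (nucleus stain, ER
stain) from a known geometry: binary masks, Gaussian blur (default 1 px),
additive Gaussian noise (default σ = 0.05), intensities clipped to [0, 1],
ground truth embedded. Segmentation is per-channel intensity k-means
(k = 2, brightest cluster = foreground), morphological opening,
small-region removal; vectorization traces the 0.5 iso-contour of each
region, converts to µm (raster row 0 is the image top; geometry y is up)
and simplifies with a 0.05 µm Douglas–Peucker tolerance. On these
synthetic images the round trip recovers boundaries with IoU ≥ 0.9 at the
default corruption level. What this does *not* show: performance on real
microscopy (uneven illumination, out-of-focus light, touching organelles,
staining artifacts) — the renderer models none of these, so the round-trip
numbers are an internal consistency check of the vectorization pipeline,
not a segmentation benchmark.

## Design choices where the design was open

- Arc-length origin/orientation along a membrane: counterclockwise,
  starting at the rightmost node (ties to larger y). Any convention works;
  this one is reproducible and puts s = 0 at the downstream pole.
- Observation point per membrane: the interface node with maximal |V_m| at
  the first plateau sample — reproducible and captures the pole behaviour.
  For the ER, profiles are reported on the longest closed loop.
- Threshold scope: |V_m| or N anywhere on the membrane at any saved time
  (the most literal reading of "regions began to appear"; no area
  requirement).
- Scan windows default to brackets around the expected thresholds to keep
  runs desk-scale; a full scan from 0.1 kV/cm is a parameter change.
- No sub-grid (bisection) refinement of thresholds: the reference
  procedure is the 0.1 kV/cm grid, and matching it keeps values comparable.

## Limitations

- 2D plane geometry: induced potentials scale with the cylinder
  coefficient 2 (not 3/2); absolute thresholds are therefore comparable
  only between 2D models.
- Fixed pore radius; no pore-radius dynamics, no resealing beyond the
  N-equation's own relaxation, no Joule heating, no electrode
  electrochemistry.
- Single pulse only; no trains.
- The surrogate geometry reproduces plasma-membrane observables by
  calibration; organelle-level numbers are not transferable to the real
  imaged cell.
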