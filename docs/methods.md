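# Methods

Conventions used throughout: lengths in Å, pressures in bar, surface
tensions in mN/m, energies in kcal/mol, charges in elementary charge
units. A frame is a set of sites with coordinates, a species label, a
molecule index and a site name, in an orthorhombic periodic box. The
membrane normal is +z; minimum-image displacements are a − b wrapped
per-dimension to [−L/2, L/2).

## Surface tension and area strain

γ = 0.01 · L_z · (P_zz − (P_xx + P_yy)/2) converts a pressure-tensor
record (bar, Å) to mN/m; for a bilayer the full box-normal virial
difference is attributed to the two interfaces jointly, matching the
imposed-tension ensemble convention. Area per lipid is the lateral box
area divided by the per-leaflet lipid count.

## K_A estimation (`mechanics`)

The model is ⟨A⟩(γ) = A₀ · (1 + γ/K_A), i.e. γ = K_A · ε + c with
ε = (⟨A⟩ − ⟨A⟩₀)/⟨A⟩₀ and ⟨A⟩₀ the mean area of the γ = 0 series. The
fit requires at least three distinct tensions including γ = 0.

* **Error model.** Each area series is reduced to (mean, SEM) with an
  autocorrelation-corrected SEM: the normalized autocovariance is
  summed to its first non-positive lag to give τ, the statistical
  inefficiency is g = 1 + 2τ, and SEM = sd·√(g/N). For an AR(1) process
  this recovers g = (1+φ)/(1−φ).
* **Weighted fit.** Area SEMs are converted to strain-axis SEMs and
  then to γ-axis residual standard deviations using a preliminary OLS
  slope, refined once. The WLS fit (statsmodels) reports parameter
  covariance **unscaled** (`scale = 1`): the weights already carry
  absolute units from the measured SEMs, so multiplying by the
  2-degrees-of-freedom residual variance estimate would make the K_A
  standard error a noisy draw rather than a calibrated one. With the
  unscaled covariance the 3·SE band covers the planted truth at the
  expected normal rate (verified over 200 replicates in the acceptance
  suite).
* **Bootstrap option.** `fit(method="bootstrap")` resamples each area
  series in blocks of ≈5τ frames and refits; it agrees with the
  analytic SE on synthetic AR(1) data.
* `percent_reduction(k, k_ref) = 100·(k_ref − k)/k_ref` reproduces the
  headline mixture-vs-pure comparisons (192.7 vs 245.81 → 22%; 220.5 vs
  245.81 → 10%).

Why statsmodels-style Model/Results: the fitted model is the product.
`AreaCompressibilityModel(series)` holds data and options;
`.fit()` returns an immutable `AreaCompressibilityResults` with
estimates, covariance-derived errors, `conf_int()`, `summary()` and
`to_dict()` for machine-readable output.

## Tail order parameters (`tail_order`)

S_C(i) = ⟨(3cos²θ_i − 1)/2⟩ for carbons i = 2..n−1, with θ_i the angle
between the minimum-image C(i−1)→C(i+1) vector and z. The estimator is
invariant to rotations about z and to vector negation. Per-carbon
standard errors use the same autocorrelation-corrected SEM over the
frame series (reported when ≥10 frames). Closed forms used as oracles:
fixed tilt θ gives S_C = (3cos²θ − 1)/2 exactly; isotropic tilt gives 0;
a von Mises–Fisher tilt with concentration κ gives the quadrature value
of E[P₂(u)] under the density ∝ exp(κu).

## Packing and mixing (`packing`)

* **Spacing distributions**: normalized histograms of same-leaflet
  phosphorus–phosphorus minimum-image distances (lateral by default),
  binned to min(L_x, L_y)/2.
* **Voronoi areas**: each leaflet's phosphorus xy-positions are wrapped,
  tiled over the 3×3 neighbouring periodic images, tessellated with
  scipy's Voronoi, and the central copy's cells measured with shapely.
  The central cells tile the box exactly, so the areas sum to L_x·L_y
  (asserted to 1e-6 relative); coincident generators are jittered by
  1e-6 Å and retried once. Verified against a 512² pixel-ownership
  rasterization oracle (within 2%).
* **Mixed-contact fraction**: f_mix = 100·C_AB/(C_AA + C_AB), where for
  primary species A, C_AB counts mixed same-leaflet phosphate pairs
  within the 11 Å cutoff and C_AA counts each A–A pair twice (once from
  each A lipid, i.e. A-centric contact counting). With this counting an
  ideally mixed leaflet at secondary fraction q gives E[f_mix] ≈ 100·q,
  which is what makes 35% the reference value for a random 65:35
  mixture. Contact searches use a periodic cKDTree.
* **Neighbour composition**: species fractions among GL1-site
  neighbours within 15 Å, per central species.

## Energetics (`energetics`)

Pair energies between sites of *different* molecules within a 12 Å
cutoff:

* Lennard-Jones with Lorentz–Berthelot mixing (ε geometric, σ
  arithmetic) and CHARMM potential switching between 10 and 12 Å
  (energy and force continuous at the cutoff).
* Coulomb k·q₁q₂ with k = 332.0636 kcal·Å/(mol·e²), either
  **shifted** (1/r − 1/r_c) or **reaction-field**
  (1/r + k_rf·r² − c_rf, k_rf = (ε_rf − 1)/((2ε_rf + 1)·r_c³), default
  ε_rf = 15).

Energies accumulate into cells keyed by unordered
((species, group), (species, group)) pairs, with groups the lipid
subunits head/phosphate/glycol/tail plus ion. From the cells:
**total** = all lipid–lipid energy; **partial** = total minus like-group
cells (the head–tail, phosphate–glycol, … cross-subunit energy);
per-species-pair totals/partials; and ion–head / ion–phosphate sums.
The closure total = partial + like-group-sum is exact by construction
and asserted to 1e-9 in tests. The box must be ≥ 2·cutoff in each
dimension so the single-image KDTree search is exact.

## Synthetic generators (`synthetic`)

All generators are bit-reproducible per seed and deliberately geometric:
every downstream statistic depends only on positions, labels and
charges, so controlled geometry gives exact expected values. They are
validation instruments, not physical models — no excluded volume between
tails, no solvent, no dynamics.

* `gen_leaflet_frames`: two leaflets on a jittered square lattice
  (spacing 8.1 Å ≈ 66 Å²/lipid), species drawn once per leaflet
  (random/checkerboard/block placement) at the requested composition
  (default 65:35), each lipid a HEAD/P/GL1 backbone with two straight
  18-carbon tails (C–C z-projection 1.27 Å) tilted per a fixed, von
  Mises–Fisher, or isotropic law, tails pointing to the midplane.
* `gen_gamma_area_series`: per-tension area series with means on the
  exact K_A line and stationary AR(1) noise (default φ = 0.9,
  sd = 1 Å² — inefficiency g = 19, comparable to real MD area series).
* `gen_pressure_record`: P_zz = 1 bar, lateral components set so the
  record inverts to the requested γ, plus optional iid noise.
* `gen_charged_toy_system`: molecules with one site per subunit group on
  a jittered 3D lattice (no overlaps, so r⁻¹² terms stay physical) with
  random charges/LJ parameters and optional Na⁺/Cl⁻ — sized for
  brute-force O(N²) energy oracles.

Defaults (composition 0.65, tensions {−7, 0, 7, 15} mN/m, true
K_A = 245.81 mN/m, A₀ = 66.3 Å²) mirror the simulated systems the
analyses target; they are set a priori from those study conditions, not
tuned to test outcomes.

## Numerical choices

* FFT-based autocovariance; τ truncated at the first non-positive term
  (initial-positive-sequence style) to avoid noise-dominated tails.
* Strain SEMs of exactly zero (noiseless series) get a relative floor
  (1e-12 of the largest SEM) purely to keep WLS weights finite; if all
  SEMs are zero the fit falls back to OLS.
* Voronoi ghost tiling uses all 8 neighbouring images, which is exact
  for any generator density at which cells are smaller than the box.
* Derived RNG seeds are drawn in [0, 2³¹).

## Limitations

* Orthorhombic boxes only; the membrane normal must be z.
* Leaflet assignment is by phosphorus z relative to the mean phosphorus
  z — valid for planar bilayers, not vesicles or heavily undulating
  membranes.
* The energy decomposition excludes all intramolecular pairs; it is an
  intermolecular interaction-energy accountant, not a force field (no
  bonded terms, no PME).
* K_A standard errors assume the per-γ area series are mutually
  independent and approximately stationary after the discard fraction.
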