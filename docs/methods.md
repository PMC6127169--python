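# Methods

## Geometry and conventions

A spheroid is an azimuthally symmetric ellipsoid. The polar angle `θ` is
measured from the rotation (symmetry) axis. For a **prolate** spheroid the
semi-major axis lies along the rotation axis; for an **oblate** spheroid the
semi-major axes span the equatorial plane. The spheroid's state is a pair of
confocal shells: the outer surface (semi-major axis `r_o`) and the anoxic
boundary (`r_n`), sharing the focal length `f`. Confocality, `e_o r_o =
e_n r_n = f`, holds by construction for a genuine spheroid and is the basis
of the section QC tests.

Internally all lengths are metres; the imaging and CLI layers speak
micrometres. The consumption-to-diffusion ratio `a/D` is of order
10¹⁰ mmHg m⁻², so mixed units are the dominant bug risk this convention
eliminates.

Two eccentricity conventions exist for building a geometry from `(r_o, e)`:
the default takes `e` as the *anoxic-shell* eccentricity (`f = e·r_n`,
updated while the free boundary is solved); the alternative pins the focal
length from the outer shell (`f = e·r_o`). Both are available behind
`convention=` in `solve_anoxic_geometry` and the scan drivers.

## Oxygen field

Steady state reaction–diffusion with constant volumetric consumption in the
viable shell:

    D ∇²P = a,   P = 0 and ∂P/∂n = 0 on the anoxic shell,   P(outer) = p_o.

Defaults: `p_o = 100 mmHg`, `D = 2×10⁻⁹ m² s⁻¹`, `a = 20 mmHg s⁻¹` — a
typical 500 µm spheroid culture scenario; at those values the anoxic
semi-major axis of a sphere is ≈ 341 µm.

**Sphere.** The classical radial solution (exact).

**Prolate/oblate.** In spheroidal coordinates `(σ, τ)` with focal length
`f`, the particular solution `a r²/(6D)` has angular content only up to the
degree-2 Legendre polynomial in `τ`. Adding the degree-0 and degree-2
axisymmetric harmonics — `Q₀(σ)`, `P₂(σ)`, `Q₂(σ)` and constants (arccot-
based analogues for the oblate system) — gives a four-parameter family of
exact Poisson solutions. The four coefficients are fixed by demanding
`P = 0` **and** `∂P/∂σ = 0` on the **entire anoxic shell** (both conditions can be
met exactly, order by order in the degree-0/degree-2 components). One
condition remains for the overall scale: the outer surface cannot be held
at a uniform pressure by this family, so the boundary value `p_o` is pinned
at the **semi-minor vertex** of the outer shell (the equator of a prolate
spheroid, the pole of an oblate one) — the point of the outer surface
closest to the anoxic core, where the oxygen supply is tightest.

Consequences, all quantified by the test suite:

* the PDE and both anoxic-boundary conditions hold exactly (verified by an
  independent finite-difference oracle);
* the outer-surface pressure is uniform only in the spherical limit; its
  angular spread grows with eccentricity and is precisely what the
  sphericity-error metric measures (146% RMS of `p_o` at `e = 0.9`);
* iso-pressure level sets are accurately elliptical, exactly confocal on
  the anoxic shell, but their focal length drifts ≈ 18% above the shell
  value mid-rim; the confocality *QC test* is unaffected (it uses the
  fitted shells, not mid-rim contours);
* inside the anoxic core the closed form is meaningless and the field
  evaluator clamps to 0 (the physical definition of anoxia); the
  sphericity metrics evaluate the unclamped analytic continuation.

Numerics: `Q₀`, `Q₂` and derivatives switch to asymptotic series above
σ = 4 (the textbook forms cancel catastrophically near the sphere limit);
both branches agree to ~10⁻¹³ at the switch point. The free boundary `r_n`
is found by `brentq` on a bracket stopping 10⁻⁶·`r_o` short of the surface
(the boundary bracket vanishes quadratically there, and OCR is monotone in
`r_n`, so the bracket is safe); the round-trip `solve → estimate` recovers
the consumption rate to better than 10⁻⁸ relative.

## OCR estimators

Five estimators map `(r_o, r_n, f, p_o, D)` to a consumption rate:
`sphere`, `prolate`, `oblate`, `combined` (the average of the two pressure
forms, inverted — preferred when a single section cannot identify the
solid) and `spherical_approx` (the sphere formula applied to the
angle-averaged radii of the shells — what an experimenter gets by ignoring
eccentricity). The angle-averaged radius uses the parametric
centroid-to-surface distance of the generating ellipse,

    r̄ = (2r/π) · E(e²),     ⟨d²⟩ = r² (1 − e²/2),   σ_r² = ⟨d²⟩ − r̄²,

with `E` the complete elliptic integral of the second kind; the closed
forms are verified against adaptive quadrature of `d(t)` to 10⁻⁹.

Uncertainties follow the first-order variance formula with
Richardson-refined central differences (relative step 10⁻⁶; the two-step
combination cancels the leading error term), cross-checked against
hand-derived analytic partials of the sphere estimator. For
`spherical_approx` the radius uncertainties combine, in quadrature, the
angular spread `σ_r` (the irreducible ambiguity of summarising an ellipse
by one radius) and any measurement uncertainty of the fitted axes. The
explosive growth of this uncertainty with eccentricity — a factor ~300
between `e = 0.1` and `e = 0.9` — is the quantitative reason the sphere
path is restricted to `e ≤ 0.3` in the section pipeline.

`mean_of_shape_estimates` (the arithmetic mean of the prolate and oblate
OCR numbers) is provided separately from `combined`; the two are close but
not identical, and `combined` is the principled form.

## Sphericity error metrics

For a spheroid nested in its circumscribing sphere of radius `r_o`,

    RMSE = sqrt( mean_θ (p_o − P(r_o, θ))² ),   percent = 100·RMSE/p_o,

computed by adaptive quadrature (relative tolerance 10⁻⁸, mirror symmetry
exploited on [0, π/2]). The default averages uniformly over the polar
angle; `weighting="area"` applies the sphere's `sin θ` element instead —
the two differ by up to ~20% at extreme eccentricity and the choice is
exposed because the literature does not fix it. The scan drivers
(`table2`, `wrong_assumption_scan`, `anoxic_radius_scan`) first solve the
free boundary at the true consumption rate, so each row describes a
physically consistent spheroid.

## Section imaging

The synthetic generator emulates a dual-stained section: a bright viable
rim (proliferation marker) around a darker anoxic core (hypoxia marker) on
a dark background, default intensity levels (0.05, 0.35, 0.75) with
additive Gaussian noise, deterministic per seed. Sections are computed
analytically as quadric/plane intersections, so the ground truth under
shear (an in-plane stretch, the classic sectioning artefact) and oblique
off-centre cuts is exact. Geometry of the artefacts: a stretch leaves the
two section ellipses with *equal eccentricity* and hence unequal focal
lengths (confocality fails); an off-centre cut parallel to the symmetry
axis scales the two ellipses by different factors (confocality fails,
concentricity survives); an *oblique* off-centre cut additionally
separates the two centres — which is why the generator tilts the cutting
plane (default 45°) whenever an offset is requested.

Segmentation: Gaussian smoothing (σ = 2 px), three-class Otsu thresholding
(background/core/rim), connected-component selection (blank images and
multi-spheroid scenes raise dedicated errors). Sub-pixel boundaries are
taken as iso-intensity contours at the *midpoint of the class means* — for
a smoothed step edge that level crosses at the true edge location,
removing the systematic bias of the raw Otsu threshold. Ellipses are fit
by direct least squares; the RMS point-to-ellipse residual serves as a
heuristic per-axis measurement uncertainty.

Decision logic (thresholds flag-overridable): outer eccentricity ≤ 0.3 →
sphere path (OCR from the mean fitted radii); above 0.3, the section must
pass confocality (relative focal-length error ≤ 0.05; both-near-circular
pairs pass trivially since the ratio is ill-conditioned below e ≈ 0.05)
and concentricity (centre distance ≤ 3 px) to be analysed as an ellipsoid
(combined estimator as headline, all three reported); otherwise it is
discarded. A missing core is reported as fully oxygenated, not an error.
Known blind spot, inherent to single sections: an off-centre cut of a
*perfect sphere* yields concentric circles with a misleading radius ratio
and cannot be detected geometrically.

What the generator does not emulate: uneven illumination, stain
heterogeneity and bleed-through, partial rim staining, debris, multiple
touching spheroids, z-blur. Passing end-to-end tests therefore demonstrate
the correctness of the geometry/QC/estimation chain, not robustness to
real-microscopy nuisance factors.

## Verification strategy

* An independent finite-difference oracle (test tree only, sharing no code
  with the field implementation) checks the PDE residual with an
  axisymmetric cylindrical stencil, and compares Dirichlet solves on
  boundary-fitted grids against the analytic fields: the sphere field
  agrees to < 0.5% of `p_o` at 2 µm resolution with second-order
  convergence; the ellipsoidal comparison is *reported* (bounded by the
  outer-surface nonuniformity) rather than asserted to vanish.
* Every closed-form integral is checked against quadrature; every
  estimator against the free-boundary solver (round trip); coordinate
  transforms against their inverses (10⁻¹² relative on 10⁴ points).
* End-to-end: 20 seeded synthetic sections across eccentricities 0–0.8 and
  noise levels 0/0.05 recover the generator's OCR within 10%; all sheared
  (≥ 1.2) and off-centre (≥ 0.25·r_n) fixtures are discarded, all clean
  central fixtures retained.

Problem sizes in the default test run (2 µm/px images ≈ 600² px, 10⁴-point
property samples, 10⁻⁸ quadrature tolerances) keep the full suite under a
minute while leaving every tolerance at least an order of magnitude above
its measurement floor.

## Known limitations

* Constant-rate consumption only: no Michaelis–Menten oxygen dependence,
  no glucose/drug co-transport, no time dependence or growth.
* The outer-surface pressure of the ellipsoidal closed form is exact only
  at the semi-minor vertex; at high eccentricity the field near the poles
  of the outer shell is an extrapolation and can even turn negative on the
  circumscribing sphere — the sphericity metrics deliberately measure this.
* Triaxial ellipsoids (three distinct axes) are out of scope.
* The uncertainty model is first-order (variance formula); it is known to
  be optimistic where the estimator is strongly nonlinear, i.e. exactly
  the high-eccentricity sphere-assumption regime it is used to warn about.
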