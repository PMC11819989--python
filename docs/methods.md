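# Methods

## The material model

The periodontal ligament (PDL) — the thin connective-tissue layer joining a
tooth root to alveolar bone — is modelled as an incompressible, transversely
isotropic hyperelastic mixture of two phases: an isotropic ground-substance
matrix with volume fraction Vm, and collagen fiber bundles with volume
fraction Vf = 1 − Vm aligned with the loading axis (after cyclic preload the
bundles orient along the applied force, so the fiber direction N is fixed to
(1, 0, 0)). The strain energy density is

    W = Vm·c1·(e^{Q1} − 1) + Vf·c2·(e^{Q2} − 1)
    Q1 = c3·(I1 − 3)² + c4·(α − 1)⁴
    Q2 = c5·(I1 − 3)² + c6·(α − 1)⁴

where I1 = tr C is the first invariant of the right Cauchy–Green tensor and
α = √I4 = λ is the fiber elongation (I4 = N·C·N). The second and fifth
invariants are neglected: matrix–fiber interaction is assumed small. Both
phases see both invariants; Vf enters only as a weight, which is the model's
point — the measured collagen fraction of a region predicts how strongly that
region stiffens.

Under incompressible uniaxial tension, λ2 = λ3 = λ^(−1/2), J = det F = 1,
I1 = λ² + 2/λ, I4 = λ². Eliminating the Lagrange pressure with the
traction-free lateral condition σ22 = σ33 = 0 yields the closed-form axial
Cauchy stress

    σ11 = (λ² − 1/λ)·4(I1−3)·[Vm c1 e^{Q1} c3 + Vf c2 e^{Q2} c5]
          + 4λ(λ−1)³·[c4 Vm c1 e^{Q1} + c6 Vf c2 e^{Q2}]

which is algebraically identical to λ·dW/dλ along the uniaxial path.

### Units and sign conventions

c1 and c2 carry stress units (MPa); c3…c6 are exponent coefficients and must
be dimensionless for e^{Q} to make sense, so the package treats them as such
even though published coefficient tables sometimes label them with MPa. No
sign or convexity restriction is imposed on c1…c6: fitted sets for real
tissue include a negative matrix stress scale, and the model is used as an
interpolant over the tested stretch range. `energy_diagnostics` reports any
negative-energy stretches for a given parameter set instead of forbidding
them.

A printed variant of the energy with a fiber exponent (λ − 4)⁴ is
inconsistent with its own derivative chain (the stress carries (λ − 1)³
terms); the package uses (λ − 1)⁴ in both phases throughout.

## Verification strategy (the oracle triangle)

Three independent routes to σ11 are implemented and cross-checked:

1. the closed form above (`constitutive.cauchy_stress_uniaxial`);
2. the full continuum pipeline (`tensor_oracle`): energy partials
   ∂W/∂I1, ∂W/∂I4 → S = 2(∂W/∂I1)E + 2(∂W/∂I4)N⊗N − pC⁻¹ → σ = F·S·Fᵀ,
   with C⁻¹ formed analytically for the diagonal case so no inversion
   tolerance pollutes the check;
3. a central finite difference λ·(W(λ+h) − W(λ−h))/(2h), default step
   h = 1e−6, which balances O(h²) truncation against round-off for
   O(1 MPa) stresses.

Routes 1–2 agree to better than 1e−9 relative (both are exact algebra);
route 3 agrees to 1e−5 relative. The lateral components of route 2 vanish to
below 1e−9 MPa — the defining property of the pressure term. Tensor
consistency checks in the kinematics layer use 1e−12 (pure closed-form
arithmetic).

## Fitting

The six-coefficient model is redundant against a single monotone tensile
curve, so fitting uses a three-parameter scheme: (c1, c3, c5) are free and
the remaining coefficients follow affine ties

    c2 = 0.39571·c1 + 6.30991
    c4 = −5.38351·c3 − 8.07826
    c6 = −5.53492·c5 + 4.62974

taken as given defaults (they were obtained from repeated fits to tensile
data that are not publicly deposited; re-deriving them is out of scope). Vf
is a fixed input from histology, never fitted. The objective is the
unweighted sum of squared Cauchy-stress residuals in MPa, minimised with
`scipy.optimize.least_squares` (Levenberg–Marquardt, or trust-region
reflective when box bounds are supplied). The reported R² is
1 − SS_res/SS_tot on stress.

The exponential model has genuine local minima: from the neutral init
(1, 1, 1) alone, one regional preset's basin is unreachable. `multistart=n`
therefore adds deterministic extra starts at the signed octant corners of
magnitude 20 — chosen once to span the coefficient magnitudes seen in
ligament fits (|c| up to ~56) — and only beyond 9 starts falls back to
seeded Gaussian jitter. With `multistart=9` all six presets are recovered
from noise-free self-generated curves to ≤1e−3 relative. An unconstrained
six-parameter mode (`fit_curve_unconstrained`, CLI `--no-constraints`)
exists for comparison only.

### Identifiability under noise

With 30 points on λ ∈ [1, 1.2] and additive stress noise of sd 0.01 MPa,
the free triplet is only weakly identified: the Cramér–Rao bound
σ²(JᵀJ)⁻¹ evaluated at the presets gives 1-sigma relative errors of
roughly 0.01–17 depending on preset and coefficient. Users should treat
individual fitted coefficients from noisy single curves as an interpolating
set, not as physical constants; the predicted stress curve itself is far
better determined than the coefficients. The test suite asserts what is
attainable — that the fitted residual variance matches the injected noise —
and documents the coefficient-level spread.

## Fiber volume fraction

Vf of a stained section is the area fraction Px/PI of collagen pixels
inside a region of interest, an area fraction on 2-D sections with no
stereological correction. Regional values are arithmetic means over five
sections. The count-based entry point is strict (fiber area > ROI area is
an error); the mask-based one clips fiber pixels outside the ROI, since
hand-traced ROIs routinely overlap the segmentation boundary. Colour
segmentation of Masson-stained images is deliberately not reproduced — the
original measurements were interactive with no stated thresholds — but a
clearly-labelled hue-threshold convenience (`masson_collagen_mask`,
default hue band 0.5–0.75) is provided as a starting point.

Reference per-section fractions for the neck, middle and apex root regions
of a human incisor ship with the package
(`fiber_fraction.REGION_SECTION_FRACTIONS_PCT`); their means
(60.312%, 63.142%, 51.988%) are the Vf presets used everywhere else.

## Synthetic data

Raw tensile curves for the PDL exist only as published plots, so the test
surface runs on synthetic stand-ins:

* **Curves**: the closed-form model evaluated on a 30-point grid over
  λ ∈ [1.0, 1.20] plus additive homoscedastic Gaussian noise, default
  sd 0.01 MPa. The grid covers the experimentally described regimes (flat
  toe below λ ≈ 1.05, steep rise above 1.1) without asserting unpublished
  axis limits; the noise sd is small against the ~1.4 MPa peak stresses
  observed in the stiffest region yet large enough to make recovery
  non-trivial. The noise model is deliberately simple: real tensile records
  have autocorrelated, heteroscedastic errors, rate dependence and
  specimen-to-specimen variability that the generator does not emulate, so
  passing recovery tests demonstrate correctness of the estimation
  machinery, not expected accuracy on real tissue.
* **Masks**: binary fiber masks with an exactly prescribed pixel count
  (round(Vf·h·w)), placed by seeded shuffling — uniform-random spatial
  arrangement, no fiber-bundle texture.

All generators are bitwise reproducible given a seed.

## Degenerate inputs and numerical guards

* Stretch λ ≤ 0 and Green strain ε ≤ −0.5 are domain errors.
* |Q1| or |Q2| > 700 raises an explicit overflow error naming the stretch
  (double-precision e^{709} overflows silently otherwise); during fitting
  such trial points return large finite residuals so the solver backs away.
* Curves must be strictly increasing in λ with λ[0] ≥ 1; R² requires ≥ 2
  points and nonzero observed variance; fits require ≥ 4 points with λ > 1.
* Curve CSV round-trips are lossless: writes use 17 significant digits and
  reads use correctly-rounded float parsing.

## Problem sizes

The verification and recovery procedures use 200 random parameter draws for
the oracle triangle and six presets × 30-point curves (nine optimizer starts
each) for recovery; the full pipeline, including the acceptance script,
completes in a few seconds.

## Known limitations

* Rate dependence (visco-hyperelasticity), shear, compression and general
  3-D boundary-value problems are out of scope; loading-rate labels are
  metadata only.
* The affine coefficient ties are inputs, not re-derived.
* Fiber volume fraction is a 2-D area fraction; no 3-D reconstruction.
* Fitted coefficients from noisy single curves are weakly identified (see
  above).
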