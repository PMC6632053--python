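# Methods

## Scope and data flow

The package models the four quantitative readouts of a stapled-peptide
optimization campaign against MDM2: (i) fluorescence-anisotropy (FP)
binding, direct and competitive; (ii) cellular reporter / LDH
dose–response; (iii) far-UV CD helicity; (iv) library-level analytics
joining all of the above with lipophilicity descriptors. Peptide
sequences are parsed from a compact hyphen-delimited notation into
typed residues (staple anchors R8/S5 at i, i+7; D-, N-methyl and
non-natural tokens), and the residue count feeds the per-residue CD
normalization. A synthetic-data layer generates every input class from
known truth so each stage is validated by recovery rather than by
opaque fixtures.

## Binding equilibria

All concentrations are nM internally; unit conversion happens only at
I/O. The direct 1:1 model is the quadratic mass balance; anisotropy is
the linear map `r = r0 + (rb − r0)·f`. The competition model is the
exact trigonometric solution of the two-ligand/one-site cubic in free
protein (coefficients d, e, f and angle θ as in the README). Default
assay constants are the calibrated tracer Kd1 = 13.0 nM, tracer
Lst = 50 nM and protein Pt = 250 nM; `Pt > Lst` is an assay-validity
condition (exposed as `assay_valid`, enforced by the fitting routines)
rather than a constraint of the equilibrium itself, which is defined
for any non-negative inputs.

Numerical evaluation: the arccos argument is clamped to [−1, 1] when
within 1e−9 of the boundary (round-off) and is an error beyond that
(bad inputs, reported with the d/e/f intermediates). The trigonometric
root cancels catastrophically when the competitor occupies a negligible
protein fraction — the extreme being Kd2 → ∞, where the argument rounds
to −1 and the small root is lost entirely — so two safeguards evaluate
the same equilibrium exactly: (a) two Newton polish steps on the cubic
for the ordinary regime, and (b) a perturbative reduction to the
single-ligand quadratic when the competitor occupancy
`Lt/(Kd2 + Pt + Lt)` is below 1e−3 (the iteration contracts at the
occupancy, so four sweeps reach ~1e−12 relative; the Lt = 0 reduction
becomes analytically exact). An independent oracle —
`solve_equilibrium_numeric`, bracketed Brent root-finding on the
monotone free-protein mass balance, residual ≤ 1e−9·Pt — shares no code
with the closed form and certifies it to ≤ 1e−6 relative (measured
~1e−11 worst case) over 10⁴ draws with Kd ∈ [0.1, 1e6] nM and
concentrations ∈ [1, 1e5] nM.

Fitting uses pooled-replicate least squares (lmfit/Levenberg–Marquardt)
over (log10 Kd, r0, rb), with multi-start over three decades around a
half-range heuristic to avoid local minima on weak binders. Standard
errors on Kd come from the delta method on the log10 scale.
Non-convergence returns `converged=False`, never an exception. A
competition fit flags `baseline_below_free_tracer` when the titration
tail or fitted baseline falls below the supplied free-tracer
anisotropy — the assay's signature of an unintended ligand–tracer
interaction.

## Dose–response and censoring

The curve model is a four-parameter logistic on log10 dose — the field
standard for reporter assays; the underlying campaign does not state
its model, so this is a package choice. Bottom initializes at 0 and top
at the observed maximum. Normalization is affine against assay-defined
controls (saturating activator for the p53 reporter; lytic peptide for
LDH); negative normalized values are preserved with a warning, never
clipped. Censoring: a fitted EC50 above the 50 µM ceiling, a dynamic
range under 20 percentage points, or a failed fit all yield ">50"
(units µM), which propagates into a censored cell/target ratio. Ratios
are `1000·EC50[µM]/Kd[nM]` rounded half-up to an integer — the rounding
rule validated against the printed, internally consistent library rows;
the 11 rows whose printed ratios differ by 1–2 from the recomputation
(presumably rounded from unrounded instrument values) are surfaced by
the lint report, not forced. Replicate potencies aggregate by geometric
mean, helicities by arithmetic mean.

## CD helicity

`MRE(λ) = θ_mdeg(λ)/(10·C·l·n)` with molar concentration C, pathlength
l (cm) and n residues; n defaults to the cap-exclusive residue count
(amino-acid-like caps are counted only on request — the convention used
by the source tables is not stated, so both are available). Two
estimators replace proprietary neural-network deconvolution, which is
deliberately out of scope: the printed per-peptide helicities are
treated as input data downstream, never as reproduction targets,
because the deconvolution software and the per-sample re-measured
concentrations are unavailable. The two-state 222 nm formula uses
Luo–Baldwin-style constants θ_helix∞ = −39500 deg·cm²·dmol⁻¹, k = 2.57,
θ_coil = −3000 (all overridable). The basis estimator solves a
non-negative least-squares decomposition onto helix/coil (optionally
sheet) reference shapes with the sum-to-one constraint imposed by a
heavily weighted augmentation row (enforced to ~1e−4). The reference
shapes are synthetic literature-shaped Gaussian-band curves (helix:
+193, −208, −222 nm bands; coil: −198 nm with a shallow 222 nm tail),
anchored at 222 nm to the same constants so the two estimators agree on
idealized spectra; they are generated analytically on any wavelength
grid rather than shipped as a numeric table.

## Synthetic data: what it emulates and what it does not

Generators are bit-reproducible: one global seed, with each generator
deriving an independent substream from (seed, stream label) so
interleaved calls never shift earlier draws. Defaults encode the study
conditions: triplicate titrations with anisotropy noise SD 0.005,
12-point log-spaced grids, the 13.0/50/250 nM assay constants, a 50 µM
cellular ceiling, 1 mM peptide in a 0.2 cm cuvette for CD, and
50-peptide libraries. The library generator plants
`log10(ratio) = a + b·logD + ε` with defaults a = 2.75, b = −0.5,
σ = 0.5 and logD ~ N(2.5, 1) — chosen so ratios span ~1–1000 as in real
series and the expected R² = Var(b·logD)/(Var + σ²) equals 0.5, the
magnitude reported for such correlations; EC50/Kd pairs are back-solved
to be exactly consistent with each ratio. The generators draw i.i.d.
Gaussian noise and ignore plate drift, inner-filter effects, serum
shifts and correlated replicate error, so passing recovery tests
demonstrate estimator correctness under the stated noise model, not
robustness to real instrument artifacts.

## Recovery calibrations

Noise-free generation followed by the matching fit is an exact
round-trip for every truth tested (the fits recover planted values to
≤ 1e−6 relative). Noisy calibrations run 200 fixed seeds at
σ_r = 0.005: direct titrations of Kd = 13 nM recover within ±15%, and
weak-binder competition titrations (Kd2 = 3600 nM, competitor up to
50 µM) within ±20%, each for ≥ 95% of seeds. These studies fix r0 at
the free-tracer anisotropy — a quantity the assay measures directly and
independently (its baseline validity checks compare against it) — while
floating rb and Kd; the default API mode floats all three, which is
noticeably less precise on partial displacement curves whose baseline
is never reached (the 3600 nM curve only falls from 94% to 54% bound
within the dose range). EC50 recovery at 5-point-percent noise over 10
doses stays within ±25%. The coverage convention (≥ 95% of 200 seeds)
is the package's own.

## Design choices and limitations

- The correlation's default response is log10(ratio): ratios span
  roughly 2–800 and a raw-ratio fit would be dominated by the extreme
  linear-analog rows; raw mode is retained because the original axis
  transform is not stated.
- Printed lipophilicity R² values are not reproduction targets: the
  underlying HPLC-LogD/ALogP values are not published, so the
  correlation stage is validated by planted-law recovery instead. ALogP
  is always consumed, never computed.
- "ND" helicities and ">50" potencies are first-class missing/censored
  states everywhere; they are never coerced to numbers, and censored
  results carry no curve-shape claims.
- The packaged library table stores printed values verbatim, including
  the one row label whose position index disagrees with its substituted
  column (the D-Trp variant labeled position 6 but substituted at 7);
  the parser trusts the column and the row keeps its printed name.
- No kinetic (time-resolved) binding, SPR/ITC fitting, serum-shift or
  plate-effect modeling; 3D structure and conformational chemistry are
  out of scope — residues are opaque tokens with chirality and
  methylation flags.
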