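# Methods

## The model

`vegfmouse` implements a whole-body, two-compartment mechanistic model of
vascular endothelial growth factor (VEGF) distribution in a 25 g mouse. The
body is split into a **blood** compartment (1.75 mL, of which 0.855 mL is
plasma) and a **tissue** compartment approximated as skeletal muscle
(21.93 cm³, parameterised on the gastrocnemius). Myocytes secrete the two
dominant VEGF-A splice isoforms, VEGF164 and VEGF120, at a fixed 92:8
expression ratio into the interstitial fluid. From there VEGF

* binds VEGFR-1 and VEGFR-2 (both isoforms) and NRP-1 (VEGF164 only) on the
  abluminal endothelial surface and NRP-1 on myocytes;
* is sequestered (VEGF164 only) by glycosaminoglycan chains in the three
  interstitial sub-regions — extracellular matrix (ECM), endothelial
  basement membrane (EBM) and parenchymal basement membrane (PBM);
* crosses the capillary wall by macromolecular permeability (k_p, both
  directions) and drains to the blood through lymph (k_L, one direction);
* in blood, binds the same receptors on the luminal endothelial surface and
  is cleared from plasma at c_V.

Receptor biology follows the established coupling topology: NRP-1 couples
unligated (and VEGF120-ligated) VEGFR-1; VEGF120 can still bind the
VEGFR-1/NRP-1 couple, so a VEGF120/VEGFR-1/NRP-1 ternary complex exists even
though VEGF120 never binds NRP-1 directly. VEGF164 bridges VEGFR-2 and
NRP-1 through two routes (VEGF164·R2 + N1 and VEGF164·N1 + R2). All surface
receptors and complexes internalise at a single rate k_int = 2.8×10⁻⁴ s⁻¹
and are replenished by constant insertion tuned to hold the resting surface
densities stationary. An anti-VEGF decoy receptor ("trap", 115 kDa) binds
either free isoform in either compartment into an inert complex; trap and
complex are transported and cleared but bind nothing else and are not
internalised.

The state is 40 concentrations (24 tissue, 16 blood species) in pmol per cm³
of the owning compartment, coupled by 94 mass-action reactions — 28
reversible binding steps (56 uni-directional reactions), 24
internalisations, 7 insertions, 2 secretions, 5 plasma clearances — plus
permeability/lymph transport terms and the infusion source. The exact
per-species equation list of the original work is supplementary-only; the
network here is reconstructed from the documented interaction diagram and
the antecedent human-model conventions, and the 24/16-species and
94-reaction counts are enforced as construction guards. The reconstruction
reproduces the reported steady states, dynamics, flow shares, distribution
and occupancy figures to within about a percent (see the test suite), which
is the strongest available evidence that the topology is the intended one.

### Units and referencing conventions

Free interstitial species are physically dissolved in the *available* fluid
volume: the fraction K_AV = 0.1131 cm³/cm³ of tissue accessible to a 45 kDa
molecule after excluding cells, collagen and sterically inaccessible pore
space. All molar driving forces (mass-action kinetics, transmural
concentration differences, lymph convection) therefore use C/K_AV for
tissue species and C/f_p (f_p = plasma fraction of blood, 0.489) for blood
species. The published per-volume kinetic tables are reproduced by exactly
these conversions, which is how the convention was pinned down. Molar
readouts in pM are always fluid-referenced (interstitial fluid or plasma).

Permeability flux for species i is k_p·S_NB·(C_B/f_p − C_N/K_AV) with
S_NB = 3415 cm² the total capillary surface; lymph flow is k_L·C_N/K_AV.
An intravenous dose is a constant-rate source over the infusion window
(default 60 s) of dose·M/(MW·τ·U_B) pmol cm⁻³ blood s⁻¹; a 25 mg/kg dose in
a 25 g mouse is 5435 pmol of trap.

## Geometry derivation

All geometric quantities derive from base measurements: capillary density
650 mm⁻², capillary:fiber ratio 1.95, fiber cross-section 2500 µm²,
luminal capillary diameter 5.25 µm with 0.5 µm wall, interstitial fraction
0.1526 (from 14.4 µL per 100 mg wet weight at 1.06 g/cm³ — the unrounded
value is required to reproduce the published ECM volume fraction exactly).
Two correction-factor conventions coexist in the source material and both
are honoured because each reproduces its published output: the capillary
perimeter factor 1.23 is a shape factor on P²/(4πA), so
P = 2√(πA·1.23) = 21.78 µm; the fiber factor 1.21 multiplies the circular
perimeter linearly. The published fiber perimeter (214.10 µm) is 0.17%
below the linear-correction reconstruction (214.47 µm) for reasons the
source does not state; following the same policy used for the EBM/PBM
volume fractions (whose generating formula is likewise unavailable), the
printed value is the canonical default and the formula value is exposed as
the derived alternative. The geometry report marks every quantity as
`printed` or `derived`.

Pore-theory partitioning: interstitial collagen (2.5% of body mass at
1.41 g/cm³) is split between basement membranes and ECM by the measured
0.0083 BM-to-total collagen ratio; fluid (non-collagen) volumes times the
stated partition coefficients (0.35 for both basement membranes, 0.90 for
ECM) compose K_AV. Full-precision recomputation matches every printed
value to within one or two units of its last printed digit; the residual
last-digit noise is the original authors' intermediate rounding and is the
resolution limit of reproduction.

Unit conversions derived from the geometry (receptor dimers/cell →
pmol/cm³, M → pmol/cm³ per region, surface-coupling rates) reproduce the
published conversion footnotes to three significant figures. One subtlety:
the blood molar conversion (4.89×10⁸ (pmol/cm³)/M) requires the plasma
volume 0.855 mL (3.42 mL per 100 g), not its rounded table print of
0.85 mL; the package uses 0.855.

## Numerical treatment

The right-hand side is compiled to `dy/dt = S₂·r₂(y) + L·y + c₀ + q_A(t)e`,
with S₂ the bimolecular stoichiometry, L a constant matrix holding every
first-order process (unbinding, internalisation, clearance, degradation,
permeability, lymph) and c₀ the constant sources. The Jacobian is analytic,
which is what keeps multi-start fitting affordable. Integration uses
SciPy's BDF with the original solver tolerances (rtol 10⁻⁵, atol 10⁻²⁰) for
time courses; infusion windows are integrated piecewise so the source
discontinuity never crosses a solver step. Steady states are obtained by
long integration (10⁷ s at rtol 10⁻⁸) followed by a Newton polish and are
*verified*, not assumed: the declared steady state must satisfy
max_i |dy_i/dt|/max(|y_i|, 10⁻¹²) < 10⁻⁸ s⁻¹. Tightening tolerances
ten-fold moves reported steady states by less than 0.01%. Peak detection
refines the grid argmax with a local quadratic and warns when a peak sits
on the horizon boundary. Parameter sweeps re-equilibrate each grid point,
seeding from the previous point (verified path-independent).

## Parameter estimation

Five free parameters are estimated: the VEGF164 secretion rate q_V164
(0.01–0.20 molecules·cell⁻¹ s⁻¹), lymphatic drainage k_L (7×10⁻⁶–7×10⁻⁴
cm³/s), plasma clearances of free trap c_A and complex c_VA (both
1.6×10⁻⁵–1.6×10⁻³ min⁻¹) and the trap equilibrium dissociation constant
K_d (0.25–5 pM; the unbinding rate 4.23×10⁻⁵ s⁻¹ stays fixed and k_on
adjusts). The objective is the weighted sum of squared residuals over
plasma concentrations (nM) of unbound trap and complex across the four
dose levels (1, 2.5, 10, 25 mg/kg), with weights 1/C_observed. Each of 20
trials starts from a uniform random point inside the bounds and runs
SciPy's bound-constrained trust-region-reflective least squares
(`least_squares(method="trf")`, parameters scaled by bound widths); the
reported estimate is the minimum-WSSR trial, and all trials are retained
in the fit report.

The original dose-response measurements exist only as figure points, so the
package ships the published optimum (q_V164 = 0.0626 molecules/cell/s,
k_L = 7.00×10⁻⁶ cm³/s, c_A = 8.86×10⁻⁴ min⁻¹, c_VA = 2.79×10⁻⁴ min⁻¹,
K_d = 0.37 pM) as its canonical parameter set and validates the estimation
machinery by **synthetic-truth recovery**: curves are simulated at a known
parameter vector, multiplicative mean-preserving lognormal noise of chosen
CV is applied, and the fit must find its way back. The reference design
has 58 records (matching the original study's count) spread over 1 h–5
weeks, with fewer records at low doses and late times where real assays
lose the analyte; the true replicate structure is unpublished and this
allocation is the package's documented approximation.

### What recovery can and cannot show

`estimation.asymptotic_standard_errors` propagates the noise model through
the linearised normal equations (sandwich covariance). At the reference
design with 10% noise the sampling SDs are roughly: c_A ≈ 4%, q_V164 ≈ 9%,
K_d ≈ 12%, c_VA ≈ 17% of their true values — and k_L is essentially
unidentifiable from plasma curves (SD above 100%; fits typically return
its lower bound, consistent with the original optimisation landing on that
bound). Consequently a single noisy dataset recovers c_A, q_V164 and K_d
comfortably within ~15%, while the c_VA estimate lands within 15% only at
the ~0.9σ level — about six draws in ten. The zero-noise limit recovers
every identifiable parameter to better than 0.01% with WSSR below 10⁻¹⁰
(versus ~10³ at random feasible points), and all 20 trials of a multi-start
collapse onto a single optimum (per-parameter spread under 0.2%), so the
estimator is unbiased and the optimisation reliably global within the
bounds; the residual dispersion is information-theoretic, set by the
design, not by the optimiser.

## The synthetic-data generator

The generator emulates the *structure* of the original pharmacokinetic
experiment: intravenous bolus doses spanning 25-fold, plasma sampling of
both unbound trap and complex, multiplicative assay noise, reciprocal-
concentration weighting. It does not emulate inter-animal variability
(every record comes from the same underlying mouse), assay floors/ceilings,
sampling-time jitter, or any model misspecification — the data generator
and the fitted model share the same equations. Passing recovery tests
therefore demonstrates that the estimation pipeline is correctly wired and
that the design informs the parameters as analysed above; it cannot
demonstrate robustness to biological scatter or model error.

## Variants

* **Tissue VEGF degradation**: first-order loss of free interstitial VEGF
  at 1.16×10⁻² min⁻¹ (60 min half-life), off by default. With the
  degradation-refit optimum the steady states drop to 0.082 pM (blood) and
  4.61 pM (tissue), 12–16% below the degradation-free model.
* **Myonuclear-domain length**: lengthening the domain from 8.56 µm to
  20 µm reduces myocytes (hence myocyte NRP-1) per unit tissue; the
  per-domain secretion rate is scaled by the length ratio so volumetric
  secretion is preserved. Steady states rise to 0.11/6.70 pM.

## Degenerate inputs, tie-breaks, tolerances

Non-positive geometry (blood mass exceeding body mass, basement membranes
exceeding the interstitium) raises typed errors rather than propagating
NaNs. Simulated states are clipped at zero after integration (BDF
undershoot at atol level). Fit trials that crash the solver return a large
finite penalty and are recorded as failures; the multi-start requires at
least one surviving trial. Comparisons against published numbers use the
printed precision of each number (within one to two units of the last
printed digit for table values, three significant figures for conversion
factors), never tighter than what the publication itself resolves.

## Known limitations

* Single averaged muscle-like tissue; no organ-specific compartments, no
  tumor, no platelets, no soluble receptor isoforms, no VEGF189/188.
* Receptor signalling, heterodimers and spatial gradients are out of scope.
* The 94-reaction enumeration is a reconstruction; its validation is
  behavioural (the reproduced results), not textual.
* k_L is reported by the estimator but should not be interpreted: the data
  do not constrain it (see identifiability analysis).
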