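# Methods

This note documents the models behind `beechtrial`, the choices made where a
design was genuinely open, and what the synthetic-data generators do and do
not emulate.

## Trait derivation

**Idealized vessel diameter.** A vessel measured as an ellipse with major
radius *a* and minor radius *b* (μm) is collapsed to
D = ((32(ab)³)/(a²+b²))^¼, the diameter of the circular capillary with the
same laminar conductance. For a circle this is 2a exactly; at fixed size,
flattening reduces D. Inputs with a < b are swapped with a logged warning
rather than rejected, because particle-analysis exports do not guarantee
axis order.

**Population traits.** Vessel density is the count over sapwood area
(n mm⁻²). The lumen-to-sapwood ratio uses π(D/2)² per vessel by default; the
true ellipse area πab is available through `lumen_area="ellipse"`, since
which convention a given imaging workflow used is generally not recoverable
— the two differ only for eccentric vessels (< 2 % at the eccentricities
simulated here). D_h = ΣD⁵/ΣD⁴ weights vessels by their conductance share
and therefore never falls below the arithmetic mean.

**Conductivities.** Theoretical conductivities use the Hagen–Poiseuille sum
((π ΣD⁴)/128η)·ρ with water at 20 °C (η = 1.002×10⁻⁹ MPa s,
ρ = 998.2 kg m⁻³), normalized by sapwood area (KS_theo) or by supplied leaf
area (KL_theo, conventionally reported in 10⁻⁴ units). Radii are carried in
μm and areas in mm², converting to SI only inside this computation, so that
every reported trait stays in its field unit. When sapwood area is not
measured directly it is regressed from the full cross-section as
A_xylem = −3.715 + 0.770·A_cross (beech branch segments); inputs at or below
the positivity root (≈ 4.825 mm²) are outside the calibration and rejected.

**Allometry.** Bergel's beech form factor
f = 0.4039 + 0.0017335·H + 1.1267/H − 118.188/D³ + 4.2×10⁻⁶·D² converts the
breast-height cylinder to stem volume. The D² coefficient is stored as
4.2×10⁻⁶: a positive exponent in circulation would give f ≈ 10⁸ for any
tree, while 10⁻⁶ reproduces realistic beech form factors near 0.5. ABI
divides final aboveground biomass by the stand age (default 19.0 yr,
planting to final survey; sapling starting biomass treated as negligible —
both overridable). BAI uses the first and last inventories only, with
elapsed time as exact day counts / 365.25.

## Vulnerability curves

PLC as a function of xylem pressure P (MPa, negative = tension) is modelled
with the two-parameter logistic PLC = 100/(1 + exp(s/25·(P − P50))). Fitting
is plain nonlinear least squares on the PLC scale — points at exactly 0 or
100 are kept unweighted, and no logit transform is applied, because the
measured quantity is bounded but the residual scale of interest is PLC
percent. Initialization is multi-start: P50 starts at the pressure whose
observed PLC is nearest 50 and the slope at the negated central
finite-difference gradient (the model derivative at the inflexion is exactly
−s), backed by a coarse (P50, s) fallback grid; the slope is optimized on
the log scale to keep it positive. P12 and P88 come from the analytic
inverse P = P50 + (25/s)·ln((100 − t)/t), which the tests verify against
numeric root-finding to 10⁻⁹ MPa; by logistic symmetry |P50 − P12| equals
|P88 − P50| exactly.

QC is configuration with conservative defaults: ≥ 4 points, observed PLC
spanning below 30 and above 70, and a maximum reached PLC of ≥ 90 % —
the measurement protocol spins segments until at least 90 % loss, so curves
stopping short are flagged rather than trusted. Degenerate series (constant
PLC) yield a flagged non-converged fit, never an exception.

## Climate indices

FAI = 100·T_Jul–Aug/(P_May–Jul + P_Jul–Aug): July precipitation enters both
interval sums, i.e. is double-weighted, reflecting peak mid-summer
evaporative demand. T_Jul–Aug is taken as the arithmetic mean of the July
and August monthly means — an interval temperature is a mean, and a sum
would leave the index's conventional 2–9 scale; a `interval_mean=False`
switch uses July alone. EQ = T_Jul/MAP × 1000. The global aridity index is a
database product and is only ever echoed through, never computed.

## Variance partitioning

The random model Y_ijk = μ + P_i + b_j + ε_ijk treats provenance and block
as *crossed* random intercepts (every provenance is planted in every block).
The Gaussian (restricted) log-likelihood is evaluated exactly through the
Woodbury identity on V = σ²_intra·I + σ²_inter·Z_P Z_Pᵀ + σ²_block·Z_B Z_Bᵀ
— the capacitance matrix has one row per provenance plus one per block, so
each evaluation is linear in the number of trees. Tests pin this
implementation to a dense-covariance brute-force likelihood (≤ 30
observations, 10⁻⁸), to the closed-form i.i.d. restricted likelihood, to
method-of-moments ANOVA estimators on balanced designs with interior optima,
and to statsmodels' MixedLM as an independent cross-check.

Estimation maximizes over log-variances with Nelder–Mead separately on
every boundary face (each subset of {σ²_inter, σ²_block} pinned to zero; the
all-zero face has a closed form) and keeps the best face. Zero variance
components are common in real trait data, and the face enumeration makes
those boundary solutions exact instead of leaving them at the optimizer's
log-scale floor. Two numerical guards exist purely for degenerate inputs: the
residual variance is floored at 10⁻¹⁰ of the response variance (keeps V
invertible for noise-free data) and random-effect variances are capped at
10⁶ times it (removes a flat ridge at infinity when the response is exactly
collinear with the fixed effects); neither binds on any realistic data.

**Testing provenance differentiation.** LR = 2(ll_full − ll_reduced) under
REML, clipped at zero, against the model without the provenance component.
The null σ²_inter = 0 lies on the boundary of the parameter space, so the LR
null distribution is the 50:50 mixture ½χ²₀ + ½χ²₁ and the χ²₁ p-value is
multiplied by 0.5; at LR = 0 the corrected p is exactly 0.5, its maximum.
The reported Δ_i is defined unambiguously as LR − 2 (the AIC difference for
one extra variance parameter). A 500-replicate null simulation in the
acceptance suite confirms the corrected test rejects at ≈ 5 %.

**CVs and VC percentages.** CV_inter is the sample SD of provenance means
over the grand mean (×100). CV_intra has no single canonical definition;
the default averages the within-provenance sample SDs over provenances, and
a pooled-within-SD variant (df-weighted) is exposed via `intra="pooled"`.
VC percentages are each σ̂² over their sum (×100) and always total 100.

**Climate model.** Y_ijk = α + β·FAI_i + P_i + b_j + ε_ijk, fitted by ML
because fixed effects cannot be compared across REML likelihoods; the slope
is tested by χ²₁ LRT (no boundary correction — β = 0 is interior). The
right-skewed traits KLemp, KLtheo and the Huber value are natural-log
transformed before fitting (configurable set). Standard errors of α and β
come from (XᵀV̂⁻¹X)⁻¹.

**Missing data** are dropped per trait (complete-case within column), so
each trait's n can differ. Correlations use pairwise-complete deletion for
the same reason; tree-level correlations carry an `inflated_df` flag because
pooling across provenances mixes variance sources, and no multiple-testing
correction is applied by default (a Holm option exists).

## Synthetic trial

The generators reproduce the study conditions: ten provenances × three
blocks (default four trees per cell, balanced), traits drawn exactly from
the additive random-effects model, vessel diameters lognormal (strictly
positive and right-skewed like real xylem) targeting a mean idealized
diameter of 24 μm with eccentricities 0.7–1.0, vulnerability curves on the
measurement grid −1.0 to −5.0 MPa in 0.25 MPa steps with additive Gaussian
PLC noise (SD 3 %) truncated to [0, 100] — the simplest error model
consistent with bounded measurements — and sinusoidal monthly climate
rescaled to exact MAT/MAP targets spanning 3.4–15.3 °C and 575–1080 mm.
Default trait grand means and spreads sit on the scale of the trial's
published provenance means, with residual spread about twice the provenance
spread, so realized CV_inter falls in the observed 4–15 % range.

The balanced default design is a deliberate idealization (the field
sampling was not perfectly balanced): balance is what makes the exact
method-of-moments oracle available to the tests. Real allocation of trees to
blocks is exposed as a parameter instead of guessed. The generators do not
emulate spatial plot layout, competition, within-canopy micro-environments,
or non-Gaussian measurement error — so passing tests demonstrate the
correctness of the estimators under the stated model, not robustness to
every field artefact.

Problem sizes used in the verification experiments — 200 curves for P50
recovery, 500 replicates for the null LRT calibration, 10×3×10 trials for
parameter recovery — were chosen to make Monte-Carlo error comfortably
smaller than the tolerances being checked while keeping the whole suite
runnable in a couple of minutes on a laptop.

## Known limitations

- REML here covers exactly the two crossed random intercepts the trial
  design needs; deeper nesting or spatial correlation is out of scope.
- The vulnerability fit offers no open-vessel artefact correction and no
  alternative (Weibull/exponential) curve families.
- Boundary p-values use the ½χ²₀ + ½χ²₁ mixture, which is asymptotic; at
  very small sample sizes the corrected test is only approximately
  calibrated (the null simulation covers the default design).
- Reference tables in `beechtrial.data` are published summary statistics,
  not raw data; analyses needing tree-level field records must supply their
  own CSVs in the documented schemas.
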