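# Methods

## Model

The pharmacokinetics of tamoxifen (TAM) and its measured metabolites
N-desmethyltamoxifen (NDM), 4-hydroxytamoxifen (4OH) and endoxifen
(END) are represented as a lumped linear cascade: one apparent
compartment per analyte, a first-order absorption depot per orally
dosed compound (TAM and END), first-order formation edges
TAM→NDM, TAM→4OH, NDM→END, 4OH→END, and one lumped first-order
elimination edge per analyte that absorbs conjugation (SULT/UGT) and
all further clearance. This is a deliberate reduction of a full
organ-level PBPK description: it retains exactly the quantities the
study design interrogates — steady-state pre-dose troughs, their
population percentiles, and their response to dose and regimen — at
desk scale. Organ physiology, protein binding, saturable kinetics and
conjugate species are out of scope.

States are drug amounts (mg); concentrations are amount/volume in µg/L.
Doses enter the depot as impulses scaled by a lumped
bioavailability/exposure factor. Between doses the state evolves as
`x(t+Δt) = expm(M·Δt)·x(t)`, which is exact for a constant-coefficient
linear system; the production engine therefore carries no
time-discretization error, and for populations the matrix exponentials
are batched across subjects. Two independent numerical routes guard
this engine: a conventional LSODA integration of the same ODEs
(`simulate(..., method="ivp")`, rtol 1e-10) and the closed-form
periodic steady state `x = (I − E)⁻¹ E b` with `E = expm(M·τ)`; the
test suite requires agreement to well under 0.1 % at trough times.

### CYP2D6 dependence

Each edge carries a CYP2D6 share *f*; its effective rate for a subject
with phenotype activity *a* (EM 1.0, IM 0.5 on the gene-dose scale —
one of two functional alleles — PM 0.0) and subject multiplier η₂D₆ is
`k_base·(f·a·η₂D₆ + (1−f))`. NDM→END 4-hydroxylation is treated as
CYP2D6-dominated with a small non-CYP2D6 residual (template f = 0.95),
which keeps PM endoxifen formation positive, as observed; TAM→4OH is
partly CYP2D6 (f = 0.5); N-demethylations are CYP2D6-independent
(f = 0).

### Trough convention

A trough is sampled immediately before the next scheduled dose: 24 h
after the previous dose under once-daily dosing, 12 h after the
evening dose under twice-daily dosing. This standard convention makes
a b.i.d. trough at equal daily dose slightly *higher* than the q.d.
trough of a linear system — so the reported b.i.d. values that sit
below their 40 mg q.d. counterparts cannot be equality anchors under
any linear model, and the b.i.d. arms are checked relationally instead
(below the EM 25th percentile; within the EM 4OH band).

## Default parameters

Time constants shape only the transient approach to steady state, not
the calibrated troughs: effective elimination half-lives TAM 7 d, NDM
18 d, 4OH 2 d, END 2.5 d; absorption half-life 3 h. Apparent volumes
are TAM/NDM 1000 L, 4OH 300 L, END 150 L. Two structural constraints
drove the NDM and END choices. First, the NDM/TAM trough ratios of the
target table (2.1–2.3) must be reachable with a non-negative lumped TAM
elimination rate, which bounds the NDM turnover from above
(kₙ ≤ k_T/2.1); an NDM half-life of 18 d satisfies this for all three
phenotypes with margin. Second, the fraction of NDM turnover consumed
by endoxifen formation must stay small (here ≈ 9 % for EM): if that
fraction is large, raising CYP2D6 activity depletes the NDM pool and
the endoxifen trough saturates in η₂D₆, and no lognormal activity
spread can reproduce the wide reference endoxifen percentiles. The
smaller endoxifen volume (150 L vs 1000 L) achieves this while keeping
the unit endoxifen exposure realistic.

## Calibration

All rate constants are derived per phenotype so the typical subject
(η = 1) reproduces a 12-entry target table of median troughs at 20 mg
q.d., day 360 (steady state; successive daily troughs then differ by
≪ 0.5 %). The table itself is derived in code from a handful of
anchors: EM 4OH 3.8 µg/L; EM END from lognormal quantile algebra on the
EM endoxifen 5th/25th percentiles (7.5, 14.08 µg/L ⇒ log-SD 0.649,
median 21.81 µg/L); PM END/4OH as half the 40 mg q.d. medians (8.14,
4.5 µg/L) under dose linearity; unit endoxifen exposure
k_END = (EM − PM)/3 = 5.91 µg/L per mg/day, so 3 mg/day closes the PM
gap; IM END = EM − k_END (1 mg/day closes the IM gap); IM 4OH 2.5 µg/L
chosen so its doubled dose stays inside the EM band. TAM/NDM absolute
levels are assumed anchors (EM 120/250 µg/L; IM ratios 1.1/1.2; PM
ratios 1.4/1.5) consistent with the up-to-threefold excess of the
doubled PM dose over the EM reference; they carry no absolute
acceptance weight. The same table ships as package data
(`data/trough_targets.csv`) and a test asserts CSV ≡ derivation.

Calibration exploits linearity and is exact in one pass: scale TAM
exposure to the TAM target (everything downstream scales with it);
scale TAM→NDM and TAM→4OH to their targets while compensating in the
lumped TAM elimination so the total TAM outflow — hence the TAM
profile — is unchanged; solve NDM→END from the affine END response
(two simulations), compensating in NDM elimination. Residuals are at
machine precision, re-calibration is a no-op, and infeasible targets
fail loudly naming the offending edge. Finally the END depot exposure
is scaled so 1 mg/day oral endoxifen alone yields a typical trough of
exactly k_END; the endoxifen subsystem carries no CYP2D6 dependence,
so this unit exposure is identical in every phenotype and adds by
superposition.

## Virtual population

Two independent lognormal, median-1 random effects: η_abs on oral
exposure (log-SD σ_abs = 0.28, a realistic ≈ 29 % CV; also the width
that lets the EM reference band span the assumed PM TAM/NDM
elevations of 1.4/1.5×), and η₂D₆ on CYP2D6 activity, inert for PMs.
Since η_abs scales the dose input of a linear system, every trough is
exactly proportional to it; η₂D₆ acts sub-proportionally through the
residual fraction, so the naive closed form
σ₂D₆ = √(0.649² − σ_abs²) (exact only for a multiplicative model)
undershoots the observed spread. σ₂D₆ is therefore calibrated
deterministically: the EM endoxifen trough factors as
η_abs · h(η₂D₆), h is tabulated once (monotone PCHIP over log η), the
trough CDF is computed by 64-node Gauss–Hermite quadrature, and σ₂D₆
is chosen by least squares on the log 5th/25th percentiles against
7.5/14.08 µg/L (default result ≈ 0.76). No sampling is involved, so
the calibration is seed-independent. IMs use the same σ values as EMs
(the only printed dispersion constraints are for EMs); PM endoxifen
spread then reduces to σ_abs alone.

What the generator emulates: the marginal trough dispersion of
postmenopausal European patients per phenotype at steady state. What
it does not: covariates (age, weight, CYP3A activity), genotype
sub-structure within phenotype, adherence, and within-subject
variability — so passing population checks validate the dispersion
model, not covariate realism.

## Trial engine and conventions

The default design enumerates exactly 15 protocols / 15,000 subjects.
Arm populations draw from `trial_seed + arm_index` via
`numpy.random.default_rng`; all outputs are byte-identical across
reruns with the same seed (timings go to the log stream, never into
output files). Group B is evaluated at the pre-dose trough on day 240,
the end of the second (escalated) phase; with an NDM half-life of 18 d
the second phase (120 d) reaches ≈ 99 % of its steady state, which is
the small systematic shortfall visible in the escalation medians
(≈ −1 %). Groups A and C are evaluated on day 360. Percentiles use
linear interpolation between order statistics (`numpy.percentile`
default) — stated because 5th/95th estimates at N = 1,000 are
estimator-sensitive. Classification against the EM reference band is
by arm median within [EM p5, EM p95]. The dose-finding criterion
operationalizes "similar plasma levels" as the median endoxifen trough
within ±10 % of the EM reference median; under the calibrated model
this discriminates cleanly (IM: 0.5 mg → −14 %, 1 mg → 0 %; PM: 2 mg
→ −27 %, 3 mg → 0 %, 4 mg → +27 %). The search is deterministic on the
typical subject and stochastic on populations; both return 1 mg/day
(IM) and 3 mg/day (PM).

## Statistical tolerances in the test suite

Stochastic assertions run at fixed seeds with tolerances sized to the
sampling distribution of the statistic. The asymptotic SE of a sample
median of a lognormal with log-SD σ is ≈ 1.2533·σ/√n of its value —
2.6 % for the EM endoxifen arm at N = 1,000 — so seed-invariance of
arm medians is asserted within 4·√2·SE per analyte (computed from the
model-implied log-SD) rather than a fixed few-percent figure that the
model's own dispersion would violate routinely; population-median
convergence to the typical trough is checked at N = 8,000.

## Known limitations

* The reduced cascade is calibrated to troughs; absolute peak
  concentrations and absorption-phase shapes are nominal.
* TAM/NDM absolute levels rest on assumed anchors; only their ratios
  and the threefold bound are meaningful.
* Linearity is assumed throughout; any saturable metabolism or
  time-dependent inhibition would break strict dose proportionality.
* The UM (ultra-rapid) phenotype and allele-level genotypes are not
  modeled.
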