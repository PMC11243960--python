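# Methods

This note documents the models, formulas, defaults and design choices
behind `fluoromics`, in the spirit of a model-documentation page: what is
computed, under which assumptions, and what the synthetic-data tests do and
do not demonstrate about real instrument data.

## OJIP transients and the JIP-test

**Generative model.**  Real OJIP rises are polyphasic; the generator uses
the minimal model that produces distinguishable O-J, J-I and I-P phases, a
three-exponential rise

    F(t) = Fo + (Fm − Fo) · Σᵢ wᵢ (1 − exp(−t/τᵢ)),   Σ wᵢ = 1,

with default time constants τ = (0.4 ms, 10 ms, 120 ms), which place the J
and I inflections near their defining times (2 ms and 30 ms), and default
weights w = (0.5, 0.3, 0.2), giving Vj ≈ 0.55 and Vi ≈ 0.83 — typical of a
healthy dark-adapted leaf.  Defaults Fo = 500, Fm = 2500 give Fv/Fm = 0.8.
This is a phenomenological curve shape, not a mechanistic electron-transport
simulation; it exists so that every downstream statistic has an analytic
oracle.

**Donor-side damage.**  Damage to the oxygen-evolving complex shows up as a
raised K band (300 µs) and a lowered Fm.  Both are emulated:
`k_band_weight` adds extra weight to the fastest phase (weights are then
renormalised), and the convenience constructor `with_donor_side_damage`
additionally scales Fm (default × 0.9).  Because the injected phase
(τ = 0.4 ms) is only ~53% complete at 300 µs versus ~99% at 2 ms, a weight
of 0.15 shifts Wk by about +0.008 — a deliberately subtle effect; Wk is
strictly increasing in the injected weight, which the tests verify over a
10-point sweep.

**Acquisition.**  The default grid is 120 log-spaced points from 10 µs to
2 s, mimicking a fast-fluorometer export.  Noise is multiplicative Gaussian
(`F·(1+ε)`, ε ~ N(0, σ)); the defaults use σ = 0.01 where noise is wanted.
Instrument sampling grids are not standardised, so the reader of real
exports only enforces coverage of the 300 µs – 30 ms cardinal window, not
any particular spacing.

**Cardinal points and normalisations.**  O is the global minimum (not
necessarily the first sample), P the global maximum; K/J/I are read at
exactly 300 µs / 2 ms / 30 ms by interpolation *linear in log-time*, the
appropriate scheme for log-spaced sampling.  The normalisations are the
standard `Ft/Fo`, `Vt = (Ft−Fo)/(Fm−Fo)`, `Wt = (Ft−Fo)/(FJ−Fo)`;
difference curves re-interpolate the control onto the treatment grid
(linear in log-time) before subtracting, and ΔWk is ΔWt at 300 µs.  Which
group serves as control is always the caller's choice.

**Derived parameters** follow the classical JIP-test formulary (Strasser
and co-workers), with time in ms where dimensional:

    φP0 = Fv/Fm = (Fm−Fo)/Fm          Vj = Vt(2 ms)      Vi = Vt(30 ms)
    Wk = Wt(300 µs)                   Mo = 4·(FK−Fo)/(Fm−Fo)  [ms⁻¹]
    Sm = ∫(Fm−Ft)dt / (Fm−Fo)  over [t_O, t_Fm], trapezoid, in ms
    ψ0 = 1−Vj                         ΨE0 = φP0·(1−Vj)
    RC/ABS = φP0·Vj/Mo                PIabs = RC/ABS · φP0/(1−φP0) · ψ0/(1−ψ0)
    TR0/RC = Mo/Vj                    ET0/RC = Mo/Vj·(1−Vj)

Per-cross-section quantities use the standard proxy ABS/CS0 ≈ Fo, so
TR0/CS0 = φP0·Fo, ET0/CS0 = ΨE0·Fo, RC/CS0 = (RC/ABS)·Fo; this convention
is stated here because CS-scaled values depend on it.  ψ0 is mapped to the
captured-energy probability (1−Vj) and ΨE0 to the absorbed-energy yield
(φP0·(1−Vj)), matching the captured-vs-absorbed wording in common use.
Mo uses the 300 µs sample with the factor 4 (= 1/0.25 ms), the standard
initial-slope approximation.  Sm integrates to t_Fm (no convention exists
for transients whose maximum precedes the end of the record).  When Vj is
0 or 1, the parameters that divide by it (PIabs, RC/ABS, TR0/RC, ET0/RC)
are reported as NaN with the reason in a flags map rather than aborting
the whole parameter set.  Numerical properties verified by tests: the
dimensionless parameters are invariant under uniform rescaling of the
fluorescence; doubling the grid density changes every parameter by < 0.5%;
Sm agrees with a 200 000-point quadrature of the closed form to < 0.5%.

## PAM quenching and rapid light curves

Per-step formulas: ΦPSII = (Fm′−F)/Fm′; NPQ = (Fm−Fm′)/Fm′;
Fo′ = F0/(Fv/Fm + F0/Fm′) (Oxborough–Baker, since no far-red Fo′
measurement is assumed); qP = (Fm′−F)/(Fm′−Fo′); rETR = ΦPSII·PAR·f·a with
PSII fraction f = 0.5 and leaf absorption a = 0.84, both exposed as
arguments because instruments rarely report them.  Y(NO) defaults to the
simplified lake-model form F/Fm; the Kramer form
1/(1+NPQ+qL(Fm/F0−1)) is available as an option, and with the
Oxborough–Baker Fo′ it reduces *algebraically* to F/Fm — the test suite
asserts this equivalence, so the option is a documentation device rather
than a numerical alternative.  Steps with Fm′ > Fm (negative NPQ) or
Fm′ = Fo′ (undefined qP) are flagged, never silently dropped.

The light curve uses the saturating, exponential-free tanh model
`rETR = ETRmax·tanh(α·PAR/ETRmax)`.  Fitting is least squares
(`scipy.optimize.curve_fit`) with multi-start initialisation (α from the
first two light steps, ETRmax from the largest rETR, plus perturbed
restarts), positivity bounds, and an explicit error on non-convergence.
Ek = ETRmax/α is a definition, never a fitted quantity.  At least four
distinct PAR steps are required.

The light-curve generator draws rETR from the tanh model with
multiplicative noise and *back-computes* F and Fm′ so that (Fm′−F)/Fm′
reproduces the implied ΦPSII exactly.  The photochemical quenching target
is qP = (ΦPSII/(Fv/Fm))^0.6, strictly decreasing in PAR; via the
Oxborough–Baker identity this fixes Fm′, and the induced NPQ rises
monotonically and is capped at `npq_max` (default 2.5).  Defaults: dark
pair (500, 2500), PAR steps (0, 25, 50, 100, 200, 400, 700, 1100) — the
range instruments use for rapid light curves, including the 700 µmol
m⁻²s⁻¹ step at which treatment effects on qP are conventionally compared —
α = 0.3, ETRmax = 60 (Ek = 200).  Round-trip tests recover (α, ETRmax) to
1e-6 relative on noiseless data and keep the median α error below 10% at
5% noise.

## Omics generation and screening

**Generator.**  Abundances are log-normal: per-feature baseline
log2-abundance ~ N(8, 1.5), plus a planted B-vs-A group effect (the
planted log2 fold change), plus latent factors, plus N(0, σ) noise on the
log2 scale, exponentiated to the linear scale.  Defaults: groups A–D,
3 replicates each, σ = 0.1.  Because the noise distribution is identical
across groups, the ratio of linear group means converges to 2^(planted
log2FC) as σ→0.  TF–target structure is one standard-normal latent factor
per TF, added to the TF and to each target scaled by a signed loading; a
+1 loading makes the target an exact multiplicative copy (linear Pearson
r → 1), a −1 loading guarantees a negative correlation (exactly −1 on the
log scale; the linear-scale magnitude is below 1 because 2^x and 2^−x are
not affinely related).  Gene–metabolite coupling adds one shared factor of
configurable strength to a chosen block in each layer, which the Mantel
stage detects.  The generator emulates the statistical structure the
screening rules assume — independent log-normal noise, planted mean
shifts, low-rank latent structure.  It does not emulate count-noise models,
batch effects, missingness or correlated library-size artefacts of real
sequencing/MS data, so passing recovery tests demonstrate correctness of
the statistics, not robustness to those artefacts.

**Screening rules** (defaults, applied per comparison "XvsY" = control X,
experimental Y; FC is the ratio of linear-scale group means):

| layer      | significance                  | fold change           |
|------------|-------------------------------|-----------------------|
| metabolite | PLS-DA VIP > 1                | FC ≥ 1.5 up, ≤ 0.67 down |
| protein    | Welch p < 0.05 (log2 scale)   | FC ≥ 1.2 up, ≤ 0.83 down |
| transcript | BH Q < 0.05                   | FC > 1 up, < 1 down   |

The protein test is a two-sided Welch t on log2 abundances (robust to
unequal variances at n = 3; the concrete test behind published protein
screens is rarely stated, so the choice is documented here).  The
transcript rule takes Q-values as given when a published table supplies
them, and applies Benjamini–Hochberg to its own Welch p-values otherwise;
the literal FC > 1 up-rule (any positive change) is implemented as stated,
with the threshold configurable for stricter screens.  VIP scores come
from a two-class PLS regression (class-coded response, unit-variance
scaling, 1 component by default — an approximation to the OPLS-DA VIP of
vendor metabolomics workflows; with a single predictive component the two
coincide up to the orthogonal filtering).  VIP satisfies Σ VIP² = number
of retained features; constant features are dropped with a warning.
Zero control means make FC undefined; a configurable offset is available
and recorded in the output metadata.  Calibration verified by tests: the
protein rule's false-call rate under a 1000-feature global null (n = 3,
σ = 0.1) is ≤ 7% (measured ≈ 0.2%, because a call needs both p < 0.05 and
a ≥ 1.2-fold shift), and sensitivity at planted |log2FC| = 2 is ≥ 95%
(measured 100%).  Heat-map preparation standardises each feature to mean 0
and sample sd 1 (ddof = 1, the convention of common heat-map tools).

## Correlation integration

Pearson r uses the product-moment formula with the exact two-sided t-test
(t = r√(n−2)/√(1−r²), df = n−2).  TF networks keep, per TF, the k genes
(default 50) with largest |r|, ties broken lexicographically by gene id so
results are deterministic; edges carry the sign of r, and the
"strongly correlated" filter defaults to |r| > 0.9.  Selection is
invariant under affine transforms of the expression values (Pearson
invariance, property-tested).

The Mantel test computes Euclidean sample–sample distance matrices from
feature × sample profiles, correlates their upper triangles, and assesses
significance by permuting the sample labels of one matrix.  When the
permutation group is small (n! ≤ requested permutations + 1) it is
enumerated exhaustively and the exact p (#{as-or-more extreme}/n!,
identity included) is returned; otherwise p = (1+#extreme)/(1+draws) from
seeded random draws.  One-sided "greater" is the default (co-structure is
the alternative of interest); two-sided is available.  Distance metric and
alternative are configurable since no single convention dominates.  The
per-enzyme variant groups genes by their EC annotation and tests each
block against the metabolite matrix, mirroring how pathway heat maps pair
enzyme gene-groups with named metabolites.  Calibration: under
independence the 0.05-level rejection rate over 200 seeds is 5% ± 3%
(tested), and p is reproducible given the seed.

## Pipeline and reproducibility

The pipeline reads a conventional input directory (transients,
light curves, omics tables + design), runs the enabled stages, and writes
one tidy table per stage plus a thresholds log and a JSON metadata record
of the seed and configuration.  Group summaries report mean ± SE with
compact-letter displays from one-way ANOVA followed by Fisher's LSD at
α = 0.05 (the convention for replicated phenotyping parameters; letters
are assigned by the insertion method, largest mean first).  Missing inputs
for an enabled stage fail before any computation.  Configuration is YAML
with validated keys; permutations ≥ 99 and top-k ≥ 1 are enforced.  Given
the same inputs, configuration and seed, all result tables are
byte-identical (tested).

## Problem sizes and known limitations

The test suite and examples run on deliberately small problems — 120-point
transients, 8-step light curves, tens-to-a-thousand features, 200-seed
calibration loops, ≤ 999 Mantel permutations — chosen so the full suite
completes in well under a minute while still pinning every formula to an
independent oracle.  Known limitations: no mechanistic electron-transport
ODE model behind the OJIP shape; no QA-reoxidation or heterogeneity
analysis; no image processing for fluorescence imaging systems; no
peptide/read-level omics processing (tables enter at the feature level);
the published summary tables packaged for the worked examples carry only
group-level statistics, so their correlations are filter inputs, not
recomputation targets.  No quantitative noise or effect-size
characterisation of real instrument data was available to anchor the
generator defaults; they are documented stand-ins chosen once, as above.
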