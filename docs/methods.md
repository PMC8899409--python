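# Methods

## Record schema and curation rules

A standardized database is a flat table (CSV/spreadsheet compatible),
one response measurement per row, with four data types: `OR`
(receptor responses: spikes/s in the empty-neuron system, nA in the
*Xenopus* oocyte system), `SSR` (native single-sensillum recordings,
spikes/s), `EAG` (electroantennogram, dimensionless after reference
normalization), and `BEHAVIOR` (two-choice preference index in
[−1, 1]).  Curation applies, per row:

- **Odorant canonicalization.** Names are matched case- and
  whitespace-insensitively against a synonym table (synonym →
  canonical name, with compound id and molecular weight).  There is no
  fuzzy matching: an unknown name is a hard error, because a silently
  mis-mapped odorant corrupts every downstream join.  Molecular
  weights come from this identity table, never from structure.
- **Preference metrics.** Choice counts give
  PI = (n_test − n_control)/(n_test + n_control).  Percent attraction
  *a* maps to 2a/100 − 1 and percent repellency *r* to 1 − 2r/100 — the
  two-alternative linear reading, chosen because it agrees with the
  counts formula when *a* is the test-arm share.  Protective efficacy
  is imported with the repellency map; the original metric name stays
  in the conversion log so an alternative mapping can be substituted.
- **Concentrations** are converted to V/V or W/V fractions (g/mL):
  molarity via *m*·MW/1000, ppm read as mg/L = 10⁻⁶ g/mL, a surface
  density *d* g/cm² over *A* cm² referenced to an application volume
  *V* mL via *d·A/V*.  Dry amounts pass through flagged as dry and
  never compare equal to solution concentrations in any matching
  operation.  Converted numbers are rounded to 10 significant digits,
  which makes every conversion exactly invertible at typical reporting
  precision (this is what lets the raw-export round-trip test demand
  field-identity).
- **EAG normalization** divides each unnormalized response by the
  study's mean response to a reference odorant — 1-octen-3-ol when
  present, else an odorant flagged as the reference in the input —
  and records the reference used.  Already-normalized rows pass
  through unchanged (idempotence).
- **Background subtraction** removes the solvent response from raw
  firing rates; results may be negative (inhibition) and flagged rows
  are never subtracted twice.
- **Decade rounding** pools concentrations across studies at the
  nearest power of ten: 10^round(log₁₀ c), with half-cases
  (c = x·10^(k+0.5)) rounded toward the lower exponent and a 10⁻⁹
  guard on the floating-point log.

Rows violating any rule are rejected and logged with the error; the
standardization report lists every conversion applied.

## Gaussian tuning and the permutation null

Tuning of OR responses to a molecular property x is quantified by
least-squares fitting r(x) = a·exp(−(x−b)²/(2σ²)) to the pooled
(property value, response) scatter — one pair per OR-odor measurement
at a fixed concentration decade (default 10⁻², the modal concentration
in the literature; empty-neuron records only, since oocyte currents
live on a different scale).  Only properties taking at least ten
distinct numeric values over the measured odorants are analyzed; σ is
reported directly as the standard deviation of the fitted Gaussian
(not the √2-scaled width some toolboxes use).  Negative (inhibitory)
responses stay in the fit.

The solver is a damped Gauss–Newton (Levenberg–Marquardt) iteration
vectorized over a batch dimension, so the hundreds of shuffle fits of
a permutation test run as one array pipeline.  Initialization is
deterministic and scale-aware: a₀ = max response, b₀ = x at the
maximum, σ₀ = IQR(x)/2 (floored at a tenth of the x range).  The
parameterization is unconstrained with |σ| reported, which equals a
σ > 0 constraint because the model is even in σ.  Termination per
problem: relative step < 1.49·10⁻⁸, relative cost improvement
< 1.49·10⁻⁸ (scipy's least-squares defaults, so degenerate fits
terminate the way practitioners expect), no damped step improving the
cost, or a 200-iteration budget.  The budget matters on structureless
data, where the Gaussian family has a flat valley (amplitude drifting
up while the center leaves the data range); it makes the procedure
total while staying deterministic.  A fit *fails* only when parameters
come out non-finite or zero-width.  Agreement with scipy's
`curve_fit` on signal data is asserted in the test suite to < 10⁻⁴
relative σ.

The reliability test shuffles the mapping between property values and
responses N times (default 1000) and reports
p = #{σ_shuffle ≤ σ_actual}/N.  Observed and shuffled fits go through
the identical solver, so the p-value is exchangeable under the null
(verified: type-I error 0.047–0.062 at α = 0.05 over 1000 replicate
null datasets).  Shuffle fits that fail score σ = +∞ — they can never
undercut the observed width, the conservative choice.  Each property's
shuffle stream is seeded by hashing the property name with the global
seed, so properties can be analyzed in any order, or alone, with
identical results.  For tiny samples the test can enumerate all n!
permutations instead of sampling.

## Descriptor model

The descriptor matrix (odorant × descriptor) is filtered in a fixed
cascade: drop descriptors with any missing value; drop variance
< 0.005, computed on raw unstandardized values because the threshold
is scale-dependent by construction; then greedily scan the survivors
in input order and drop any descriptor whose |Pearson r| with an
already-retained one exceeds 0.95 (keep-first tie-break — the choice
of which of a correlated pair survives is otherwise arbitrary, and
keep-first makes the result reproducible from the input file).  The
cascade never adds columns and is idempotent.

Odorants are partitioned 70/15/15 into train/validation/test
(validation and test rounded to nearest, remainder to train: 112
odorants → 78/17/17).  Per OR, a feedforward network with three
50-unit hidden layers is trained on standardized inputs and a
standardized response.  Training runs staged L-BFGS (300 iterations
per stage, ≤ 6 stages, tanh activation, L2 penalty α = 1.0); after
each stage the validation MSE is measured, the best-validation weights
are kept, and training stops after two stages without improvement.
The held-out validation set drives stopping directly rather than an
internal re-split.  These schedule choices were made because
first-order minibatch training on ~80-odorant panels generalized
erratically, while strongly regularized quasi-Newton training is
stable and deterministic given the seed.

The control model permutes the entries of the OR × odorant response
matrix globally (a per-row variant is available behind a flag) and
reads the permuted rows back as predictions, conserving the response
multiset.  Evaluation is per-OR Pearson R and mean absolute error on
the test odorants (an OR whose test responses have zero variance is
flagged, not dropped), with two-sided paired sign-rank comparisons of
model vs control across ORs for both metrics.

## Comparative analyses

All matching keys use decade-rounded concentrations; "zero response"
means exactly 0 after standardization (oocyte non-responses are
recorded as 0 in the source literature), with no epsilon band.

- **Technique crosstab**: join empty-neuron and oocyte datasets on
  (receptor, odorant, decade), averaging replicates per side; count
  the asymmetric cells and, among oocyte-zero pairs, break down the
  empty-neuron responses by sign with mean ± SD of the inhibitory
  subgroup on both sides of the oocyte zero/non-zero split.
- **Assay pairing**: per (odorant, decade, species) present in both
  category groups, average within group and emit one pair; sign-rank
  on the differences.  Presets: mosquito {landing} vs {dual_port,
  y_tube}; fly {t_maze} vs {dual_port, y_maze}.
- **Preference vs oviposition**: match per (odorant, decade) within a
  species, averaging replicates; species with fewer than 5 matched
  items are skipped with an explicit signal.
- **Cross-species**: per shared odorant, pair PIs at equal decades,
  else the closest decades within one decade of each other; equally
  near candidates resolve to the lower decade.  Fewer than 10 common
  odorants → skip signal.
- **Concentration deltas**: (odorant, assay, species, decade) cells
  need ≥ 2 data points (averaged); adjacent-decade cell pairs emit
  Δ = PI(higher) − PI(lower), sign-rank tested against zero, with an
  optional filter on the sign of the lower-decade PI.
- **Activation count vs PI**: an OR is "activated" at ≥ 10 spikes/s
  (inclusive); counts per (odorant, decade) are Pearson-correlated
  with the averaged PI at the same key.

Sign-rank tests drop zero differences, use the exact distribution for
n ≤ 25 when |differences| are tie-free, and the normal approximation
with continuity correction otherwise (scipy's implementation; the test
suite checks it against full 2ⁿ enumeration for n ≤ 10).  No
meta-analytic weighting and no multiple-testing correction are
applied: comparisons average data points unweighted, matching how such
compilations are analyzed.

## Synthetic database generator

The generator emulates the statistical structure of a curated
literature compilation, not its marginal distributions.  Defaults (one
choice, documented here):

- 200 odorants; 30 ORs split over 2 species; 12 studies.  Properties
  are Gaussian: a molecular-weight-like tuning property (mean 130,
  SD 40, floored at 30 g/mol) plus three nuisance properties.
- Empty-neuron responses: a\*·exp(−(x−b\*)²/(2σ\*²)) + N(0, 10) with
  a\* = 100 spikes/s, b\* = 130, σ\* = 30 — amplitude and noise at the
  scale of strong ligands in SSR data, width covering roughly the
  central quarter of the property range.  20% of OR-odor pairs get a
  uniform(5, 30) inhibitory offset subtracted so the
  negative-response subgroup analyses have mass.
- Oocyte records: gain·max(0, r_en − θ) with θ = 20 spikes/s and unit
  gain — a hard detection threshold emulating the less sensitive
  second technique.
- Behavior: PI = base(odor) − β(decade − reference) + δ(assay) −
  γ·(activated-OR count) + N(0, 0.1), clipped to [−1, 1] last;
  base ~ U(−0.5, 0.5), β = 0.2 per 10-fold, reference decade −3,
  δ = −0.3 for landing assays (−0.2 for T-maze), γ = 0.01 per
  activated OR.  Decades run in contiguous 2–3-step windows inside
  10⁻⁴..10⁻¹, two studies per cell so the ≥ 2-point eligibility rule
  has support.  Oviposition indices are drawn per mode — independent
  of, or correlated ρ = 0.8 with, the host-seeking base — and carry no
  concentration slope: egg-laying preference is modeled
  dose-independent so the independent mode is a true null for the
  PI-oviposition correlation.
- Descriptors: the property columns, near-duplicates of the tuning
  property (to exercise the correlation filter), 20 pure-noise
  columns, one constant column and four columns with missing entries.
- 5% of property-table entries are blanked to exercise the
  missing-property drop; the identity table keeps all molecular
  weights so unit conversions never lose rows.

A raw-variant exporter rewrites the standardized table in randomized
"as published" conventions (synonyms with scrambled case, molarity/
ppm/mass-per-area concentrations, percent metrics and choice counts,
unnormalized EAG with per-study scale factors, firing rates with the
solvent background added back) such that standardization recovers the
original table field-identically.

What the generator does *not* emulate: real odorant chemistry and its
descriptor correlation structure, realistic species/receptor
proportions, heteroscedastic measurement error, publication bias, or
inter-study systematic offsets beyond the planted assay effect.
Passing recovery tests therefore demonstrates that the analysis code
measures what it claims on data of known structure — not that the
scientific conclusions transfer to any particular real compilation.

## Validation studies and problem sizes

The acceptance studies run at these sizes, chosen to give stable
statistics at desk scale: permutation calibration over 1000 replicate
null datasets (100 pairs, 200 shuffles, α = 0.05); tuning recovery
over 50 seeds (200 pairs, noise 0.1·a\*); power at 1000 shuffles with
σ\* = 0.2 × property range; model-vs-control at 30 ORs × 112 odorants;
slope recovery at β ∈ {0.2, 0} on a 200-odorant database.  Recovery
studies that target one planted parameter zero the other effects
(e.g. assay offsets and the activation-count loading are off during
slope recovery, the inhibitory fraction is off during width recovery);
the full-default configuration is exercised jointly by the analysis
drivers and the database-level tests.  Known limitation: with all
effects active, clipping of extreme PIs at ±1 attenuates the apparent
slope slightly (≈ −0.19 recovered for β = 0.2 at the defaults).
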