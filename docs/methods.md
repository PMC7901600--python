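# Methods

## The model

`fourfold` operationalizes a geometric account of measures on binary
contingency data as a pipeline of perspective operations:

1. **Filtering.** A population of elements is categorized on `d` binary
   dimensions into a 2^d grid of frequency counts (`grid.categorize`).
   Categories are assumed dichotomous, exhaustive, and mutually
   exclusive; records with missing or out-of-registry values are
   rejected rather than imputed. Collapsing a grid dimension aggregates
   counts and is lossy — two distinct grids can share a shadow, which
   the test suite demonstrates constructively.
2. **Framing.** Two dimensions are selected and arranged as a 2×2
   matrix. Swapping dimension order and category orders yields
   2³ = 8 spatial layouts of the same information
   (`tables.enumerate_layouts`); all metric computation is label-aware,
   so every measure is invariant across the eight layouts.
3. **Focusing.** Measures arise by normalizing and selecting parts of
   the matrix: dividing by N gives joint probabilities; dividing by row,
   column, or diagonal margins gives conditional probabilities under the
   corresponding *perspective*; ratios and compositions of these give
   the likelihood/odds/contingency measures. Each lossy step records
   what it dropped (N at normalization, the margin pair at
   conditionalization) so the inverse maps (`denormalize`,
   `reconstruct`) are exact when that information is resupplied.
4. **Presenting.** A reported measure is transparent when its derivation
   chain is explicated. `render.transparency_report` emits the recorded
   steps, the dropped information, and a cell-role icon; replaying the
   steps must reproduce the value, and the test suite enforces this.

### The correspondence cube

When a third dimension Z is *defined* as the correspondence
(match/mismatch) of X and Y, four of the eight grid cells are
structurally impossible and the remaining four carry exactly the counts
a, b, c, d (`grid.PartialCube`). Projections of this partial cube — the
three 2×2 matrices obtained by viewing along each axis and the six
two-level trees obtained by stacking each matrix — rearrange the four
counts without aggregation, so all of them are informationally
equivalent, and `reconstruct_cube` inverts any of them exactly (an
exhaustive property test covers all nine routes).

Counting *spatial arrangements* at each level uses a canonical-signature
rule: two arrangements are distinct when their dimension-to-axis
assignment or category orders differ, and mirror/rotation duplicates are
deduplicated. Enumerating under this rule gives 24 arrangements per
level: 3 matrix framings × 8 layouts; 6 branch-ordered trees × 4
category orders; and the 24 proper rotations of the cube (signed
permutation matrices with determinant +1, which identifies each mirror
image with a rotation). The matrix and tree enumerations are exact; the
cube-level rule is the package's own convention for "distinct
orientation" and is documented here because other conventions (e.g.
counting reflections separately) would give 48.

## Conventions and numerical choices

- **Canonical orientation.** Columns carry the condition/exposure
  dimension X, rows the test/outcome dimension Y, and the top-left cell
  is positive∩positive. All other layouts are derived views. This
  orientation is the one whose implicit diagonal means "correct", which
  is why it is treated as the reference frame.
- **Rounding.** Reconstruction of expected frequencies from a
  probability parameterization rounds half away from zero at each stage
  and then fills each column's remaining cell, so column margins stay
  exact (e.g. an expected 95.04 false positives becomes 95 inside an
  intact group of 990). An `exact_rational` mode keeps cells as
  `fractions.Fraction` for analytic work; the worked-problem solver uses
  it so that the pipeline answer equals closed-form Bayes to 1e-9 rather
  than only after integer rounding. `denormalize` rounds a, b, c and
  repairs the total through d.
- **Undefined values.** A zero margin never raises: derivations that
  need it return an `Undefined` marker carrying the reason ("PPV: zero
  denominator (a+b)"). A ratio with zero denominator but nonzero
  numerator is reported as signed infinity (an empty error cell makes
  the odds ratio infinite, not undefined); 0/0 is undefined. No
  continuity correction is applied anywhere — zero-cell behaviour is
  reported as such rather than smoothed. Markers propagate through
  composite metrics.
- **Tolerances.** Probability identities are checked to 1e-9 absolute;
  count identities are exact integer equalities. The χ² score is
  computed as N·ΔP_row·ΔP_col and asserted against the classical
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) at every evaluation (they are
  algebraically equal; the assertion guards the implementation).
- **Percent formatting** is a presentation concern: metric objects carry
  exact values, and `format_percent` rounds half away from zero with a
  per-problem decimal profile (one decimal for the screening-problem
  conditionals, integers for the policy-analysis rates), matching how
  such figures are conventionally printed.
- **Alias resolution.** Metric names resolve through a registry of
  canonical definitions with per-domain aliases. An alias claimed by
  several domains for different measures must be qualified with a domain
  tag; unknown names fail with near-miss suggestions.
- **relative_increase** is defined as ARR divided by the baseline
  (unexposed) risk, i.e. (AR_e − AR_u)/AR_u = RR − 1. On the Titanic
  table this is 2.44 on exact rates and the conventional "factor of 2.5"
  on the rounded 70%/20% rates; the package reports the exact value and
  leaves rounding to presentation.

## Worked-problem encodings

Problem fixtures are encoded declaratively (givens tagged as
probability/frequency/count, a question naming a target metric) and
solved through the table pipeline. The short-menu format stores a
`PartialTable` holding only the top row and N; questions about the
unknown bottom-row split raise an under-determination error naming the
missing quantities. Monty Hall is enumerated exactly: 3! = 6 base
arrangements, the chosen-door row structurally zero, and a host-bias
parameter (probability of opening the lower-numbered free door) kept as
an exact rational so extreme biases produce exact 0/1 posteriors.
Empirical human solution rates (4%/24%/36% per mammography format, the
80% modal wrong answer, 87% sticking) are carried as annotation metadata
only and are never recomputed.

The Titanic table is *reconstructed* from four published summary
figures (N = 2201, 67.7% dead, 338 surviving male adults, 161 dead
women/children) because the full micro-data is not part of the package.
Since 67.7% is itself rounded, derived cells carry a ±1 count
uncertainty; the reported rates (20%/70%), ARR (50%) and conflict odds
(2.1) are insensitive to it at their printed precision. Three-dimensional
grid demonstrations use synthetic record sets generated in the tests.

## The synthetic-record generator

`io.synthesize_records` emulates a population screened by a binary test:
condition status Bernoulli(prevalence), then a test outcome per group at
the given sensitivity/specificity. `expected` mode emits the
deterministic expected counts under the rounding rules above (so
generator → tally → table reproduces the probability-format
reconstruction exactly, a property the suite checks across random
parameters); `sample` mode draws the three stages as binomials from a
single `numpy` generator seeded once, so identical seeds give identical
records. The generator produces independent, identically distributed
individuals with exact dichotomies — it does not emulate correlated
risk factors, covariate drift, verification bias, or measurement error,
so passing parameter-recovery tests demonstrates correctness of the
tally-and-focus machinery, not robustness to real-world sampling
artifacts. Parameter recovery is verified at n = 10^5 within three
binomial standard errors; this size keeps the whole suite in seconds on
one CPU while leaving the standard errors small enough to be a real
check.

## Known limitations

- Only 2×2 structures are supported (plus the 3×3 case matrix of the
  three-door problem, which is collapsed to 2×2 for analysis); no
  general r×c tables.
- No inferential statistics: the χ² *score* is provided as an
  association measure, without p-values or confidence intervals.
- No ROC/threshold analysis — the construct has no tunable threshold.
- Dichotomization of continuous variables is out of scope; records must
  arrive binary-coded or with an explicit value map.
- Icons and viz-specs are text/JSON stand-ins for graphical output; no
  plotting is performed.
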