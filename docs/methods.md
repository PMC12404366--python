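# Methods

## Model and assumptions

fruitqual scores a set of alternatives (fruit samples) against a two-level
index system: first-level criteria groups, each containing second-level
measured indicators. The method is a subjective–objective combination
scheme: expert judgment fixes how much each criterion *should* matter
(AHP), the data fixes how much each indicator *can* discriminate (entropy
weighting), and the fused weights drive a TOPSIS closeness ranking.

The implicit assumptions are those of the component methods: expert
pairwise judgments are meaningful on Saaty's 1–9 ratio scale and close
enough to consistent (CR ≤ 0.1); indicator desirability is monotone
(benefit/cost) or single-plateau (interval); Euclidean distance on the
weighted, normalized matrix is an acceptable aggregate of per-indicator
performance; and the sample set itself defines the frame of reference
(ideal and anti-ideal points are per-column extrema of the observed data,
so scores are relative to the cohort, not absolute grades).

## AHP stage

Weights are the normalized principal right eigenvector of each reciprocal
judgment matrix, obtained by power iteration started from the uniform
vector and stopped when successive normalized iterates agree within 1e-12
in max norm (iteration cap 100 000; for positive matrices of size ≤ 10
convergence takes tens of iterations). λmax is estimated from the final
iterate as the mean component-wise Rayleigh ratio. The eigenvector method
is the default because, on the packaged pineapple matrices, it reproduces
all published 4-decimal weights, whereas row geometric means deviate in the
fourth decimal for the inconsistent 4×4 eating-quality matrix (0.6558 vs
0.6572 for off-flavour). Row-geometric-mean extraction is available as
`ahp_method="geometric_mean"`; the two coincide exactly for any consistent
matrix and for every 3×3 reciprocal matrix.

Consistency uses the classical random-index table (RI = 0.58, 0.90, 1.12
for k = 3, 4, 5 …); k ≤ 2 is defined as CR = 0. In strict mode (default) a
CR above 0.1 raises an error; lenient mode records the failure in the
report instead.

Judgment matrices are validated structurally (unit diagonal, reciprocity to
relative tolerance 1e-9, entries within [1/9, 9]) and can be supplied as
full grids or upper triangles; fraction literals such as `1/7` are parsed
exactly via rational arithmetic.

## Orientation and entropy stage

All indicators are first oriented onto a common benefit scale in [0, 1]:
min-max for benefit, reversed min-max for cost, and for interval indicators
a score of 1 inside the optimal range `[lo, hi]` falling off linearly with
the excess distance, normalized by the column's largest excess `M`. `M` is
data-driven rather than a fixed constant so the transform lands in [0, 1]
for any input. A constant column (including an interval column with every
sample in range) is defined as all ones.

Entropy is computed on this oriented matrix, so cost and interval
indicators need no special casing downstream. Zero proportions use the
`0·ln 0 = 0` convention rather than epsilon-shifting: it is parameter-free,
and the oriented matrix legitimately contains zeros (every non-constant
column attains 0 at its worst sample). A constant column has entropy
exactly 1 (special-cased to avoid float residue) and objective weight 0; if
*every* column is constant the objective weights are undefined and an error
is raised.

One consequence of computing proportions on the min-max-oriented matrix is
worth spelling out: the entropy weight of a column depends on the *shape*
of its oriented distribution, not on its raw variance (min-max erases
scale). A column whose oriented mass concentrates in a few samples — e.g. a
right-skewed benefit indicator where most samples sit near the column
minimum — gets low entropy and a large weight. Conversely, a cost indicator
that is zero (best) for most samples maps to oriented values near 1 almost
everywhere, which *spreads* proportion mass evenly and yields a small
weight. Published entropy tables computed on scale-retaining
normalizations (where a low-variability column like moisture can reach
H ≈ 0.9998) are therefore not exactly reproducible from raw data under
this pipeline; the identity β = (1 − H)/Σ(1 − H) from a given entropy
column holds regardless and is what the package cross-checks against the
published study.

## Fusion stage

The default fusion is the normalized geometric mean
`w_j = √(α_j β_j) / Σ √(α_k β_k)`: log-weights are (up to an additive
constant) the average of the subjective and objective log-weights, and the
method is invariant to positive rescaling of either input. The normalized
plain product `α_j β_j / Σ α_k β_k` is implemented as an alternative
(`fusion="product"`); it double-counts agreement between the two sources —
fusing a vector with itself squares it rather than returning it — and, on
the packaged pineapple study, fails to reproduce the published
comprehensive weights that the geometric mean matches to 4 decimals. The
report records which method produced it.

## TOPSIS stage

Vector (root-sum-of-squares) normalization is the default, making closeness
invariant to positive rescaling of any raw column; min-max normalization is
available for sensitivity checks (`normalization="minmax"`). Because
orientation has already made every column benefit-type, the ideal point is
the per-column maximum and the anti-ideal the minimum. "Before weighting"
scores use uniform weights over the same oriented, normalized matrix —
the minimal reading that makes before/after correlations well defined.
Per-group scores rerun TOPSIS on each group's columns with that group's
comprehensive weights renormalized to sum to one.

Degenerate conventions: if a sample is at zero distance from both poles
(all samples identical) its closeness is 0.5; tied scores share the smaller
rank; score tables are sorted with a deterministic secondary key (sample
id) so output is stable.

Correlations between weighted and unweighted score vectors are Pearson
(matching the scatter-plot framing of before/after comparisons), with
Spearman reported as a supplementary diagnostic; a constant score vector
makes the correlation undefined and it is reported as null, never as 0.

## Synthetic data generator

The generator draws independent per-indicator values from uniform or
normal distributions, optionally clipped to physical ranges, with a seeded
`numpy` Generator (same spec + seed ⇒ identical table). The default
pineapple spec uses uniform distributions over plausible agronomic ranges
(maximum-entropy choice given only a range): e.g. sugar–acid ratio over
4–30 so the interval orientation is exercised below, inside and above its
(8, 20) optimum; moisture 80–90 g/100 g; vitamin C 10–60 mg/100 g. The
mechanical-damage ratio is a normal(0.05, 0.15) clipped at zero, putting a
point mass at 0 (many undamaged batches) with a dispersed damaged tail, and
single fruit weight is normal(1100, 250) g clipped at 300 g.

What the generator emulates: column ranges and dispersions of a market
survey, the zero-inflated damage column, and an interval indicator
straddling its optimum. What it does not: between-indicator correlations of
real fruit (total sugar vs soluble solids, acid vs sugar–acid ratio),
measurement error structure, or regional/varietal clustering. Passing
tests on synthetic data therefore validate the *pipeline arithmetic and its
invariances*, not the agronomic conclusions one would draw from real
measurements. In particular, per the entropy-shape note above, the
zero-inflated damage column does not dominate the objective weights under
this pipeline; property tests that need a known dominant-dispersion column
construct one explicitly (a zero-clipped half-normal, whose oriented mass
concentrates in few samples and wins the weight comparison in every one of
200 seeded replicates).

The packaged `fixtures()` returns the real study hierarchy and judgment
matrices together with a synthetic 23 × 15 sample table: the study's raw
measurement supplement is not redistributed, and any table at
`data/pineapple_s2.csv` (sample id column plus the 15 indicator ids) will
be picked up by the corresponding cross-check test.

## Numerical choices and limitations

- Internal computation is full double precision; tables display at 4
  decimals.
- Weight vectors are renormalized to sum to one at each stage boundary;
  reports assert Σα = Σβ = Σw = 1 within 1e-9.
- The pipeline contains no randomness: re-fitting the same inputs gives a
  bit-identical report (provenance includes a hash of all inputs).
- Problem sizes are small by construction (tens of samples, ≤ ~20
  indicators); nothing is optimized for large n, and rank-reversal
  phenomena of TOPSIS under added/removed alternatives are out of scope.
- No missing-data handling: tables must be complete and finite.
- Group decision aggregation (multiple experts), fuzzy AHP, CRITIC
  weighting and VIKOR/PROMETHEE ranking alternatives are deliberately not
  implemented.
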