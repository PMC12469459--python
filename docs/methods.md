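# Methods

## Run-length decomposition (`repeat_core`)

A repeat region is decomposed by a greedy left-to-right scan: at each
position the longest tandem run of the length-`motif_len` word starting
there is taken; positions opening no qualifying run become interstitial
sequence. Motifs are reduced to their primitive root (`AGAG → AG`) and
grouped by canonical rotation (lexicographically smallest; `GAA`, `AAG`,
`AGA` → class `AAG`). The recorded phase is the left-rotation of the
canonical form that reproduces the observed motif. A solitary unit
qualifies as a run only when its rotation class occurs at least twice in
the region; this keeps one-off words (a lone `GAC` inside a GAG/GAA tract)
out of the run list while preserving the conventional `(GAA)1` bookends of
compound repeats. Coordinates are 0-based half-open; the parenthetical
unit-count notation is produced only at output.

The major motif is the rotation class with the greatest total unit count
(ties: longest single pure run, then lexicographic; ties are reported).
`longest_pure_run` is rotation-tolerant — the longest uninterrupted tandem
array of any rotation of the query motif — because slippage competence
depends on the array, not on reading phase. Greedy decomposition is
phase-anchored and can split a cross-phase array, so `longest_pure_run` is
computed directly, not from the run list.

### Cryptic simplicity

The score is observed tandem-run coverage (fraction of positions inside a
run of ≥ 2 units, motif lengths 1..6) divided by its mean over seeded
i.i.d.-uniform random sequences of the same length. The null is
deliberately composition-free: cryptic simple sequences (CSS) are simple
*because* of their biased base composition, so a composition-preserving
permutation null would subtract exactly the signal of interest. Under this
definition uniform-random sequences score ≈ 1.0, the two published 19-bp
CSS variants score 1.21–1.30, and pure trinucleotide repeats score ≈ 1.7
(the ratio saturates near 2 at these lengths because the random background
itself has ~50% coverage). The statistic is an operationalisation choice:
no numeric definition of cryptic simplicity accompanies the study design
this package follows.

## Flank anchoring (`orthology`)

Flanks are aligned query-globally (every flank base aligned; free end gaps
on the target only) with BLASTN-like scores +2/−3/−5/−2, on both strands,
via Biopython's `PairwiseAligner`. Query-global alignment rather than
Smith–Waterman local alignment is used because local alignment trims
flank-terminal mismatches, which shifts extraction boundaries and breaks
exact region recovery; with query-global alignment "100% query coverage"
is structural and the inter-flank boundary is exact. Identity is computed
over alignment columns including internal gaps; coverage is span-based
(BLAST `qcovs` semantics). An epsilon surcharge (1e-4) on internal gap
opening breaks exact score ties between a terminal mismatch and an
equivalent gap+match in favour of the substitution reading, keeping
boundaries stable.

A flank counts as *found* only above 30% of its maximum attainable score;
random placements of a ≥ 20 bp query score near zero under these scores,
so the floor separates "flank absent" from "flank present but divergent"
(the latter reported as `below_identity` / `below_coverage`). One optimal
placement per flank per strand is considered; of the two strand
candidates the higher summed score wins (ties: shorter region, plus
strand). Minus-strand regions are returned reverse-complemented into locus
orientation. Default thresholds: identity ≥ 0.80, coverage = 1.00, region
≤ 2000 bp. Measured exact-recovery on simulated targets: 99.5% at 5%
flank divergence, 95% at 10%.

## Life-cycle classification (`lifecycle`)

Death is defined on the *longest pure run* of the reference major motif
(≤ T units, default T = 1), not the total unit count, because slippage
operates on uninterrupted arrays. Mechanism labels are resolved against
the alive reference structure:

- residual units are counted as literal occurrences of the reference major
  motif *as written* (e.g. `GAA`, not any rotation): the compound
  structure of the reference fixes the reading phase, and off-phase
  rotation matches inside a degenerated region are not surviving units;
- `interruption_degeneration`: ≥ 2 units survive in total but no pure run
  exceeds T;
- `css_replacement`: ≤ 1 unit survives, region length within ±50% of the
  reference, simplicity score ≥ 1.2 (above the uniform-random mean of
  ≈ 1.0; the published CSS exemplars score 1.21–1.30, and the score
  ceiling at these lengths is ≈ 2, so higher cutoffs would sit at the
  ceiling);
- `complete_loss`: no unit survives and the region shortened by at least
  one motif length (also the fallback for in-place motif substitution);
- `solitary_residual`: exactly one unit survives;
- `motif_replacement` (flag, may co-occur): a novel motif class (lengths
  1–6) with a run of ≥ 5 units absent from the reference — the birth
  threshold sits inside the 4–8 unit range conventional for short motifs.

Conspecific fixation (identical dead regions across genomes of one
species) is annotated as corroborating evidence, not required for a call.

State mapping uses unit-cost Sankoff dynamic programming over the two
states — exact on any rooted tree including multifurcations, equivalent to
Fitch parsimony on binary trees. Reported are the minimum transition
count, per-node optimal state sets, and every edge on which some
most-parsimonious reconstruction places a transition (direction labelled
loss or gain); the edge set, rather than a single narrative, is the honest
summary when loss-then-regain and independent-loss reconstructions tie.

## Bayesian model comparison (`threshold_bayes`)

Threshold model: independent Beta(1, 1) priors on p_high (death
probability at r ≤ T) and p_low (r > T); the marginal likelihood is the
product of two Beta-Binomial terms, closed form. Posterior summaries are
Beta means with equal-tailed 95% quantile intervals (not HPD). T is fixed
(default 1) with no prior over T.

Continuous model: logistic regression on the centred/scaled repeat number
with Normal(0, 2.5²) priors on both coefficients. The marginal likelihood
is integrated by 2-D Gauss–Hermite quadrature centred on the posterior
mode with Cholesky curvature scaling (adaptive GH). The mode is found by
Newton iteration on the concave ridge-penalised log posterior. With the
default 41 nodes per axis the estimate is stable to well under 1e-4 on
node doubling and agrees with large prior-sample Monte Carlo within its
standard error. Degenerate inputs: an empty dataset has log marginal
likelihood 0 under both models; a single observation with a death yields
exactly 1/2 under the logistic model by sign symmetry of the intercept
prior (used as a correctness check).

Bayes factors are reported as BF, ln BF and 2 ln BF with Kass–Raftery
categories (≤ 2 weak, (2, 6] positive, (6, 10] strong, > 10 very strong;
sign-symmetric). Observation tables are assembled one row per
species × locus using the modal allele per species; the death indicator
comes from the mechanism classification, not from the r ≤ T rule itself,
to avoid circularity between the indicator and the threshold being tested.

## Forward simulator (`synthetic_data`)

Per branch, events are placed by Gillespie sampling with exponential
waiting times; the run structure is re-decomposed after every event
because slippage rates depend on current run lengths. Processes:

- slippage: rate per run = `slippage_rate_per_unit` × max(0, units −
  `min_slippage_units`); ±1 unit with probability `expansion_bias` of
  expansion (default 0.5, an unbiased walk);
- point mutations in the repeat region (default 1e-3 /site /branch
  length) and in the flanks (2e-4), so repeat-length changes dominate
  flank substitutions as in real amplicon data;
- large deletions (default 5e-3 /branch length): uniform start in the
  repeat region, spans of 2–6 units, overrunning into the right flank by
  at most 10 bp.

No numeric mutation rates accompany the study design this package
follows; the defaults above are order-of-magnitude choices for a
slippage-dominated trinucleotide locus and are exercised by property
tests, not treated as estimates. Slippage rates (~0.2 events per branch
for a 12-unit run) keep tip repeat numbers in the observed 3–25 range on
trees of depth a few units; the elevated-deletion condition in the
analyses uses 5.0 /branch length, which kills ≈ 60% of tips on a
unit-length branch versus 0% in the deletion-free control. CSS-like dead
regions emerge from interruption accumulation; there is no separate CSS
event type. Every event is recorded; replaying the log from the root is
asserted to reproduce every tip byte-for-byte in the test suite.

What the generator does not emulate: within-species coalescent structure,
selection on coding repeats, recombination-associated mutation biases, and
sequencing artifacts. Passing tests therefore demonstrate correctness of
the inference machinery under the assumed mutational model, not robustness
to those real-data complications.

The observation-table generator draws repeat numbers from a configurable
distribution (default uniform 0–12; a two-group spec fixes the fraction at
or below T) and death indicators from the two-regime Bernoulli model. The
analysis and acceptance runs use 124 observations split 56 at-or-below /
68 above threshold with p_high = 0.92 and p_low = 0.07 — the group sizes
implied by the widths of the reported credible intervals at those
posterior means.

## Statistics (`lineage_stats`)

One-way fixed-effects ANOVA (scipy) on allele major counts between
lineages; the default unit of analysis is the allele (each allele one
row), configurable to species-consensus values. Consensus repeat number is
the mode, ties toward the smaller value. Stepwise-mutation support is the
fraction of adjacent pairs in each species' sorted unique allele ladder
differing by exactly one unit (species with a single allele excluded); it
replaces coalescent maximum-likelihood mutation-model testing, which is
out of scope here. No multiple-comparison correction is applied to
pairwise ANOVAs.

## Problem sizes

The test and acceptance runs use: 1000 random strings (length ≤ 100) for
run-finding oracle equivalence; 100 random datasets for the closed-form
vs quadrature check (Gauss–Legendre, exact for the polynomial integrand);
brute-force parsimony enumeration on trees of ≤ 10 tips; 200 simulated
targets for flank recovery; 500 replicates of n = 100 for posterior
interval calibration (measured coverage 0.932, within 3 binomial SE of
nominal 0.95 — equal-tailed Beta intervals are known to undercover
slightly at extreme rates with ~50 observations per group); 60 replicates
each for the step-truth and logistic-truth Bayes-factor medians; and
16-tip clades for the deletion-death experiment.

## Known limitations

- The decomposition reports single-length motifs per pass; mixed motif
  lengths in one structure require separate passes (novel-run detection in
  the mechanism classifier scans lengths 1–6 internally).
- Approximate/degenerate repeat detection (alignment-scored, Tandem
  Repeats Finder style) is out of scope.
- The flank aligner considers one optimal placement per strand, not all
  co-optimal placement pairs; for amplicon-scale targets (≤ a few kb with
  one locus copy) this is the intended regime.
- The cryptic-simplicity score is noisy for regions under ~25 bp (sd
  ≈ 0.3 under the null at 19 bp); the CSS mechanism call is therefore
  conjunctive with residual-unit and length conditions.
- Ancestral mapping is parsimony only; probabilistic character mapping and
  divergence-time estimation are out of scope.
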