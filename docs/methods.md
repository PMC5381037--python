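# Methods

This note documents the model implemented by `ibsancestry`, the choices
made where the design was genuinely open, and what the validation
simulations do and do not demonstrate.

## Input model

Every individual is a set of pseudo-haploid scaffolds: at each site one
base drawn uniformly from the individual's two homologues. This sidesteps
genotype calling at low coverage at the cost of halving the information per
site; the windowed score aggregates enough sites that the loss is
acceptable. All non-ACGT characters are treated as missing (N) before any
computation. Coordinates are 0-based half-open throughout (BED convention).
Trailing partial windows are dropped rather than padded, because the
emission variance derivation assumes a fixed window size.

## Window score

The score `x` is the difference of log mean IBS tract lengths against the
two reference panels, normalized by window size (the `1/w` factors cancel
in the difference but keep each term interpretable as a per-window rate).
Natural logarithms are used consistently in the scorer and the emission
model; only their consistency matters.

N-handling inside tracts is *skip-don't-break*: a site where either
sequence is N neither extends nor terminates a tract. The alternative
(breaking the tract without counting a mismatch) would shrink tract lengths
in proportion to missingness rather than divergence, biasing scores in
exactly the low-coverage regime the tool targets. A zero-mismatch
comparison yields one tract covering all informative matching sites, which
caps the score smoothly and avoids division by zero. A reference individual
with no informative tract in a window is excluded from its panel's average
(logged); a window losing an entire panel, or whose hybrid N-fraction
exceeds the skip threshold (default 0.25), becomes a SKIP window.

## Transition model

Per window step, each homologue independently switches ancestry with
probability `R = 1 − (1 − g·r)^w` and lands in population A with
probability `p`. Aggregating per-site probabilities to per-window steps via
`1 − (1 − ·)^w` keeps the transition structure consistent under window-size
changes. The drift correction `z` treats post-admixture recombination
events as alleles arising at frequency `1/(2N)` — about `2N·r` new events
per generation per site — and sums their second moments under the neutral
Wright–Fisher recursion, giving the closed form

    z = r · ( g − (2N−1) · (1 − (1 − 1/(2N))^g) ),

computed with `log1p`/`expm1` (the naive power loses all precision for
N ≳ 10⁹). This replaces a diffusion-equation treatment of the same
quantity; the closed form is exact under the WF model and is validated
against a forward WF Monte Carlo oracle in the test suite. At the
validation-run parameters (N = 3000, g = 1000, r = 10⁻⁸) the shared-event
term `Z·q` dominates the double-recombination term `R²q²`, as the model's
construction intends.

Ancestry→skip and skip→skip transitions use `s`, the genome-wide fraction
of skipped windows (computed once per hybrid over all retained scaffolds;
per-scaffold recomputation was rejected as unstable on short scaffolds).
Skip states copy their parent's cross transitions so that passing through
missing data does not change the probability of an ancestry switch; the
return-to-parent probability is the row complement. Start probabilities are
Hardy–Weinberg `(p², 2pq, q²)` over the ancestry states; the end
probability from every state is `1/n_windows` with each scaffold's own
window count. Degenerate rows (e.g. a single-window scaffold, where the end
probability is 1) are resolved by scaling the off-diagonal mass into the
available probability; genuinely saturated ancestry-switch probabilities
(`g·r·w` too large) raise an error advising a smaller window. A scaffold
whose *first* window is skipped would have zero start mass under the
Hardy–Weinberg start vector; in that case each skip state inherits its
parent ancestry state's start probability.

## Emission model

Each ancestry state S has expected per-site mismatch rates against the two
panels: `d(AA, vsA) = π_A`, `d(AA, vsB) = π_AB`, `d(AB, vsA) =
(π_A + π_AB)/2`, etc. The *analytic* mode computes the mean and SD of `x`
under a generative model in which per-window mismatch counts decompose into
independent Poisson components: events on the hybrid's own sampled lineage
(shared by every comparison), fixed inter-population difference sites at
rate `δ = π_AB − (π_A + π_B)/2` (shared within the opposite panel), and
each reference's private events at rate `π_pop/2`. Moments of
`ln(mean tract length)` are evaluated by direct summation over the Poisson
grids with third-order corrections; the shared components produce the
between-reference covariance that inflates the variance of a panel-averaged
score well beyond the independent-reference approximation (about 3-fold at
5 references), and the hybrid-lineage component induces a positive
covariance between the two panels that partially cancels in the score
difference. Simple first-order formulas (`μ = ln d_B − ln d_A`,
`σ² = 1/(a·w·d_A) + 1/(b·w·d_B)`) are biased by ~0.08 on the mean and ~20%+
on the SD at realistic parameters and are not used.

The *monte_carlo* mode simulates ≥ 2000 windows per state with the
synthetic-data generator and the real scorer and fits the realized mean and
SD; it is the authoritative reference (self-consistent with the scorer by
construction) and the analytic mode is required by the tests to agree with
it within 0.05 (mean) and 10% (SD). The analytic mode is the default in
the pipeline because it is deterministic and fast.

Emission SDs scale approximately as `1/√w`; "doubling w halves the
variance" holds to leading order only, because the tract-count distribution
at small `w·π` is strongly skewed.

### Window-size choice

The minimum admissible window requires an expected ≥ 10 IBS tracts per
panel comparison (`a·w·min_S d(S,vsA) ≥ 10` and likewise for B), keeping
the normal approximation serviceable. The recommender scans a grid (1 kb
steps up to 100 kb by default) and returns the smallest window whose
maximum pairwise emission-distribution overlap — `∫ min(f_i, f_j)`,
integrated numerically to better than 10⁻⁴ — is ≤ 0.5. If no grid value
qualifies, the largest is returned with a prominent low-differentiation
(low F_ST) warning. If a user forces a window with overlap > 0.5, all three
SDs are halved repeatedly until the overlap falls below 0.5 (count logged);
this sacrifices realism for discriminative power.

## Decoding and reporting

Decoding is Viterbi ("most likely sequence of ancestry states") in log
space; posterior marginals were considered and rejected for the primary
output to keep tract boundaries crisp. Ties break toward the fixed order
AA < AB < BB < sAA < sAB < sBB. Windows decoded into skip states are
reported with the parent ancestry label and flagged as imputed. The global
admixture proportion is `(2·AA + AB) / (2·labeled bases)`. Output is
deterministic and byte-identical regardless of the worker-process count.

The f̂ estimator uses the standard four-taxon ABBA/BABA site patterns on
single pseudo-haploid bases (no allele frequencies): with sequences
(P1 = unadmixed B, P2 = hybrid, P3a/P3b = two A individuals, O = outgroup),
`f̂ = S(P1,P2,P3a,O) / S(P1,P3b,P3a,O)` where S counts ABBA − BABA over
sites with all five bases informative. Negative f̂ is reported as computed
but the model's `p` is floored at 0.001 so unexpected introgression remains
detectable. π values are pooled mismatch/compared counts over scaffolds and
pairs (length-weighted), never averages of per-scaffold rates.

## Synthetic data

Two backends generate hybrid genomes with known truth.

**Mosaic backend** (`simulate_mosaic` + `materialize_sequences`): each
haplotype is a memoryless A/B mosaic with per-base switch rate
`1 − (1−r)^g ≈ g·r` and stationary A-fraction
`p_eff = p·(1 − m)^g` under per-generation replacement migration `m` —
deliberately the stationary consequence of the HMM's own generative
assumptions, so it tests the scorer/decoder, not coalescent tract-length
realism. Sequences descend from a single ancestral sequence: the two
population sequences each diverge at rate `δ/2`, individual chromosomes add
private mutations at `π_pop/2`, and the outgroup diverges from the common
ancestor at `3·π_AB`. Placing the outgroup on the shared ancestor (rather
than deriving one population from the other) is what makes ABBA/BABA
polarization — and hence f̂ — meaningful on synthetic data. Defaults use
the bear-system diversities (π_A = 0.000615, π_B = 0.00233,
π_AB = 0.003564), 10 × 1 Mb chromosomes, admixture 1000 generations ago,
and 0.001/generation migration in the migration variant.

**Coalescent backend** (`coalescent.py`, msprime): a four-population
demography sized from per-site diversities (θ_brown = 0.0017 →
N₀ ≈ 23 278; θ_polar = 4×10⁻⁴; θ_outgroup = 0.0021), generation time
11.35 y, μ = 1.825728×10⁻⁸, r = 1 cM/Mb, HKY mutations with a 4:1
transition:transversion ratio. The island hybrid population is founded
50/50 from the two species 1057 generations ago; the migration variant adds
0.001/generation replacement by mainland individuals from then until the
present. Truth comes from the simulated genealogies: a hybrid haplotype
segment has introgressor (A) origin iff its TMRCA with *all* A-panel
haplotypes is more recent than its TMRCA with all B-panel haplotypes *and*
postdates the species split (strict inequalities — this separates true
introgression from incomplete lineage sorting); otherwise it is labeled B,
the non-introgressed background; exact TMRCA ties are left uncalled.
Applying the split-time guard to the B side as well was rejected: the TMRCA
of a lineage with an entire large-Ne panel almost always predates the
split, which would leave most genuinely-B windows unevaluable.

### Evaluation

Truth is discretized to windows by majority vote of truth bases within each
window (ties and vote-less windows are excluded); per-state precision
(fraction of calls correct) and recall (fraction of truth detected) plus
overall window accuracy are pooled by summing confusion counts. The full
validation loop (`reproduce_table1`) estimates *every* model parameter from
the simulated data itself — π from the panels, p via f̂ per hybrid
(first brown individual, first two polar individuals, the outgroup) — and
runs the pipeline at w = 10 kb, g = 1000, N = 3000 with 5 + 5 references.
The default problem size is 5 replicates × 10 × 1 Mb chromosomes × 5
hybrids per demographic model, which gives ~25 000 evaluated windows per
model and stable pooled metrics while completing in a few minutes.

### What passing tests show — and do not show

The mosaic backend matches the HMM's assumptions exactly, so its accuracy
(~99%) is an upper bound demonstrating correctness of the machinery, not
field performance. The coalescent backend adds incomplete lineage sorting,
heavy-tailed tract lengths, and realistic linkage, and is the honest
benchmark (~87–93% window accuracy depending on demography). Neither
backend simulates sequencing error, reference bias, mapping artifacts, or
coverage heterogeneity; N-rich low-coverage behavior is exercised only
through the skip machinery. Heterozygous ancestry is systematically
over-called relative to truth (the known bias direction of this model
class); homozygous calls are the reliable ones.

## Numerical choices and degenerate inputs

* Poisson grids in the analytic emission mode truncate at the mean plus 10
  SDs plus a fixed pad; overlap integration uses 16 001 trapezoid points
  over the joint ±8 SD support.
* `π_AB < (π_A + π_B)/2` (populations less diverged than their internal
  diversity) clamps the fixed-difference rate δ at 0 with a warning.
* Scaffolds missing from any reference are dropped with a warning, not
  errored; scaffolds shorter than one window are dropped; inputs below the
  minimum scaffold length (default 500 kb) are filtered.
* All simulation and pseudo-haploidization randomness flows through
  explicit seeds; identical seeds give identical bytes.

## Known limitations

* The X/Z-chromosome transition adjustment is reserved but unimplemented;
  the flag errors.
* Recombination is a flat rate; per-site recombination maps are out of
  scope, as is estimating g from data.
* f̂ here uses single pseudo-haploid bases, not allele frequencies, and is
  noisy on short (~10 Mb) genomes; block-jackknife standard errors are not
  provided.
* Emission normality degrades near the minimum window bound; the bound is
  a heuristic (≥ 10 expected tracts), not a guarantee.
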