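# Methods

This note documents the models and estimators implemented in `wgdtrace`,
the defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that affect results.

## Homolog screening (`wgdtrace.homology`)

Domain-hit filtering keeps a profile-HMM hit when its sequence E-value and
per-domain E-value are at or below their thresholds (defaults 1e-2 each)
and the hit covers at least `min_coverage` (default 50%) of the HMM,
computed as (hmm_to − hmm_from + 1)/hmm_length. All thresholds are
inclusive. Two per-domain E-value dialects of HMMER's `--domtblout` are
supported: the conditional c-Evalue (default) and the independent i-Evalue.
When one protein carries several partial hits to the same HMM, the default
coverage test uses the best single domain; `merge_domains=True` instead
measures the union of the E-value-passing HMM spans, since the right choice
depends on how fragmented the search output is.

Redundancy clustering is greedy and incremental in the CD-HIT style:
sequences are processed longest-first (ties by id), and each sequence joins
the best-matching existing representative whose local-alignment identity is
at least `identity_min` (default 0.95) with coverage of the shorter
sequence at least `short_coverage_min` (default 0.6), else founds a new
cluster. Identity is matches over local-alignment columns. Word-size
pre-filters used by clustering tools for speed are accelerators, not
semantics, and are not reproduced. The tie rule used everywhere in this
module — bitscore descending, then E-value ascending, then lexicographic
subject id — makes all outcomes order-independent.

Reverse-best-hit orthology accepts every forward hit at E ≤ 1e-3 whose
reverse search's best hit (rank 1 under the tie rule, E ≤ 1e-3) equals the
query. The forward hit is deliberately *not* required to rank first: a true
ortholog is often outscored in the forward direction by a recent in-paralog
or a longer multi-domain protein, while the reverse direction remains
unambiguous. This is the screening rule the two-stage E-value scheme
(permissive 1e-2 discovery, stricter 1e-3 confirmation) feeds into; both
thresholds are exposed.

## Synteny and WGD evidence (`wgdtrace.synteny`)

Anchoring treats an unduplicated outgroup proteome as a fixed reference:
each paralog-family member must hit the outgroup at E < 1e-10, the family
is partitioned by the members' top outgroup hits, and only subgroups of at
least two members survive, anchored to the shared hit. Splitting by anchor
separates tandem or ancient paralogs that were lumped into one family from
the genuine post-duplication pairs the analysis is after.

Block detection works on gene *ranks* (order along the chromosome), not
base-pair coordinates — the property of interest is preserved relative
order. Anchored pairs between two regions are chained into maximal runs
that are strictly increasing in both regions (direct) or increasing in one
and decreasing in the other (inverted). The sliding window enters as a
locality constraint: successive pairs of a run must be within
`window_size` (default 100) ranks of each other on *both* regions. Runs
are found by repeatedly extracting the longest chain (O(n²) dynamic
program) until fewer than `min_pairs` (default 3) pairs remain; ties are
broken by a canonical key built from unordered gene-id pairs, which makes
the decomposition exactly symmetric under swapping the two regions. The
defaults follow common practice for WGD paralogon detection and are
CLI-exposed. When the two regions are the same chromosome (duplicates in
cis), trivial self-pairs are excluded and a block's two spans must not
overlap.

A caution inherent to the method: a random arrangement of k anchored pairs
contains a monotone subsequence of about 2√k pairs, so `min_pairs` should
be read as a noise floor for *sparse* anchor sets, not a significance
threshold. The null-control test quantifies this on shuffled orders.
Both per-block and total-distinct pair counts are reported, since a
"shared pairs" figure can be counted either way.

## Pairwise dN/dS (`wgdtrace.rates`)

The NG86 implementation makes two conventions explicit, because published
variants differ:

- **Sites.** For each codon position, the synonymous fraction is computed
  over the non-stop single-nucleotide changes at that position,
  renormalized when a stop neighbor is excluded; a position whose three
  alternatives are all stops contributes no sites. For codons with no stop
  neighbors this gives S + N = 3 exactly.
- **Differences.** For codon pairs differing at 2–3 positions, all
  shortest mutational pathways are enumerated; pathways through stop
  codons are excluded and the survivors re-weighted equally. If every
  pathway crosses a stop (rare), all pathways are used with stop-involving
  steps counted nonsynonymous.

Codons containing gaps or ambiguity in either sequence are deleted
pairwise (not column-wide), matching the pairwise character of the
computation. The Jukes–Cantor correction is undefined at p ≥ 3/4; such
values are flagged `None`, excluded from the affected average only, and
tallied — never clamped.

Clade summaries report ω as mean(dN)/mean(dS) by default. A
mean-of-pairwise-ratios mode exists because published tables of averaged
pairwise dN/dS are not always consistent with either convention, and the
user should be able to match both. Domain-partition summaries map 1-based
inclusive residue ranges of a reference sequence through alignment gaps to
codon columns.

## Codon-model likelihoods (`wgdtrace.codonml`)

The GY94 generator assigns rate q_ij = π_j · κ^[transition] ·
ω^[nonsynonymous] to single-nucleotide codon changes and 0 otherwise, over
the 61 sense codons of the standard code (any NCBI translation table is
accepted). Codon frequencies default to F3x4 estimated from the data, the
common convention; uniform, F1x4 and F61 are available. κ is always a free
ML parameter. Matrices are scaled per branch class so one unit of branch
length equals one expected substitution per codon under the model's
site-class mixture.

Likelihoods use Felsenstein pruning over site patterns, with exp(Qt) from
the eigendecomposition of the π^{1/2}-symmetrized generator (the model is
reversible; equilibrium frequencies are floored at 1e-8 before the
similarity transform). Gap and ambiguous codons integrate over all
compatible sense codons. Transition-probability rows are clipped at 0 to
remove eigendecomposition round-off.

The model zoo and free parameters (branch lengths aside): M0 (κ, ω);
two-ratio branch model (κ, ω_bg, ω_fg); M1a (κ, p0, ω0∈(0,1), ω1=1 fixed);
M2a_rel (M1a + free shared ω2, 5 params); clade model C (ω2 differs per
clade partition; M2a_rel is its null, df = clades − 1); branch-site model A
(background M1a classes plus 2a/2b with foreground ω2 ≥ 1; M1a is the null
of branch-site test 1, df = 2). Clades and foreground branches are read
from codeml-style `#k` (single branch) and `$k` (whole clade) marks in the
Newick input, or from a sidecar TSV. Degrees of freedom default to the
free-parameter difference; an explicit override exists because published
tables occasionally state a df that disagrees with their printed p-value,
and both conventions should be computable.

Optimization is bounded quasi-Newton (L-BFGS-B) over log-transformed rates
and logit/stick-breaking-transformed proportions, run independently from
every value in the ω start grid; every start's result is kept in the fit
record so multi-start behavior is auditable. Default grids: a wide
purifying-through-positive grid for clade model C
(0.001…10) and for branch-site A (1.25…10), two starts for the simpler
families. Convergence: optimizer ftol 1e-12 on the transformed problem,
outer alternation stops at |ΔlnL| < 1e-6.

Branch lengths are estimated under M0 — per-edge Brent optimization on
up/down partial likelihoods alternated with the rate parameters — and held
fixed for the richer families (`fit_model_series` wires this), which keeps
the richer fits to a handful of parameters; a flag co-estimates lengths in
any family when needed. Consequently LRT degrees of freedom count model
parameters only, the branch lengths being shared between null and
alternative.

LRT statistics are clamped at 0; an alternative fitting *worse* than its
null beyond tolerance raises (it indicates optimization failure, which
should be visible, not hidden). Benjamini–Hochberg adjustment is the
standard step-up procedure (delegated to statsmodels).

## Type-I functional divergence (`wgdtrace.divergence`)

Per-column substitution counts are computed on each cluster's subtree by
Fitch parsimony (gaps are wildcards). Parsimony undercounts multiple hits,
which *inflates* the apparent rate correlation between clusters and biases
θ toward 0; the default estimator therefore applies the per-edge
saturation correction −E·log(1 − c/E) (E = subtree edge count, c capped at
0.9·E); raw counts remain available via `method="fitch"`.

The probability model: a site's rate is gamma distributed with shape α
(mean 1); with probability 1 − θ the two clusters share one rate draw
(counts follow a correlated bivariate negative binomial), with probability
θ they draw independently (product of negative-binomial marginals). The
per-cluster scales d_j are fixed at the mean counts; θ and a single shared
α are estimated jointly by ML from three θ starts (method-of-moments
shapes seed α). The θ = 0 null re-profiles α, so the LRT has one degree of
freedom for θ; because θ sits on the boundary under the null, the χ²(1)
reference is conservative. Per-site posteriors are the usual mixture
responsibilities; the bootstrap SE resamples columns (default 500
replicates).

θ̂ is mildly biased downward at moderate divergence (low-count columns
carry little correlation information), which the recovery test bounds: at
the study conditions used throughout (two 8-leaf clusters, tip branches
0.5, internal 0.25, gamma shape 0.5, 500 columns), θ = 0.4 is recovered
within ±0.15.

Site selection follows the stepwise cutoff procedure: columns are removed
one at a time in descending order of the initial fit's posteriors, θ is
refitted on the remainder, and removal stops once the LRT p-value exceeds
α (default 0.05). The cutoff is the highest posterior among the surviving
columns and the selected sites are exactly those scoring strictly above it
(a removed column tying the best survivor is, by that rule, not selected).
The tree is kept fixed across refits; counts are per-column independent,
so refitting reduces to dropping columns.

## Synthetic data (`wgdtrace.simulate`)

All generators are pure functions of (parameters, seed); one global seed
fans out to independent per-generator streams keyed by generator name, so
adding a generator never perturbs existing outputs, and every dataset
ships a JSON-serializable truth record.

- **Codon alignments** draw root codons from π and evolve them through
  exp(Qt) per branch and site class; stop codons cannot be emitted because
  the state space excludes them. The generator shares the GY94 machinery's
  matrix construction but samples states rather than summing over them, so
  fit-versus-truth tests exercise the likelihood path non-circularly at
  the level that matters (the estimator).
- **WGD gene orders** duplicate an ancestral order, drop each copy
  independently with probability 1 − retention, and apply random segment
  inversions (strand-flipping) and translocations to one copy. Every
  surviving ancestral gene defines an anchored two-member family.
- **Divergent clusters** evolve residues under a uniform 20-state
  exchange model with per-column gamma rates, shared or independent
  between clusters per the planted θ. This is adequate for rate-divergence
  recovery and makes no claim about realistic amino-acid exchangeabilities.
- **Hit tables** plant mutually-best forward/reverse pairs, add weaker
  noise hits whose reverse best points elsewhere, and can plant decoys
  that outrank the true ortholog in the forward direction only —
  the case that distinguishes reverse-best-hit from bidirectional-best
  logic.

What the generators do *not* emulate: indels and alignment error, codon
usage bias beyond π, among-site ω variation in the branch-model
simulations, lineage-specific composition drift, and assembly or
annotation artifacts in gene orders. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions and
robustness to planted rearrangement/noise — not robustness to real-data
violations such as alignment error or saturation beyond the corrections
described above.

## Problem sizes and determinism

The verification experiments (test suite and `scripts/acceptance.py`) use:
200 random 10-codon pairs against the NG86 enumeration oracle; 4-taxon
exhaustive 61² state sums on 5-codon alignments; ω recovery at 8 taxa ×
300 codons; LRT calibration on 6 taxa × 100 codons over 200 null
replicates (100 in the acceptance script, which records each quantity's n);
synteny recovery on 1,000 ancestral genes at retention 0.3 with 2
inversions; divergence recovery at 500 columns with 50 null replicates.
These sizes make the full suite run in a couple of minutes on one CPU
while leaving each check statistically meaningful. All randomness flows
through explicit seeds; the pipeline reproduces its tables byte-for-byte
for a fixed config and seed.

## Known limitations

- The codon-model engine covers the six families above; site-model series
  (M3, M7/M8), empirical codon models and Bayes empirical Bayes site
  identification are out of scope.
- NG86 here is the equal-pathway-weighting variant with Jukes–Cantor
  correction; transition/transversion-weighted or ML pairwise distances
  are not provided.
- The divergence estimator is a count-based approximation to full
  likelihood rate-shift inference; its θ̂ is conservative (biased low) and
  its posteriors should be ranked, not read as calibrated probabilities.
- Branch-length sharing between nested models trades a small amount of
  lnL in the alternative for speed; co-estimation is available when exact
  per-model optima matter.
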