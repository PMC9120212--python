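# Methods

This note documents the models and conventions behind each module, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the package's known limitations.

## Data model

All analyses operate on four containers joined by specimen id: a
fixed-length `Alignment` (IUPAC nucleotides; `-` and `?` are treated
identically as missing data), a `Partition` (disjoint blocks covering the
specimen set), a symmetric `DistanceMatrix` with zero diagonal (symmetry
enforced to 1e-12), and a rooted `PhyloTree` with non-negative branch
lengths.  Mismatched id sets across inputs are fatal by default and are
reported as a set difference; an intersect mode restricts analysis to the
common subset instead (the situation where a few specimens — e.g. females
lacking diagnostic characters — carry sequences but no morphospecies
label).

## Distances

`p_distance` is the proportion of differing comparable sites under pairwise
deletion (default) or complete deletion.  Ambiguity codes compatible with
the opposing base (R vs A) count as matches — a deliberately conservative
(lump-ward) choice.  `jc69_distance` applies
d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 is reported as a saturation error
naming the offending pair rather than silently clamped.  GTR/ML distances
are not computed; externally produced matrices are accepted via
`read_matrix` (labelled TSV or PHYLIP dialect, auto-detected by whether the
file's first token is numeric).

## Threshold clustering (BIN proxy)

Single-linkage components of the graph with edges d < t, with t = 0.022
substitutions/site by default — the BOLD seed threshold.  This is an open
proxy: the RESL refinement steps behind real BIN assignment are unpublished
in implementable detail and out of scope.  Block count is non-increasing in
t, and the partition equals the single-linkage dendrogram cut at height t.

## Statistical parsimony (TCS-style)

Haplotypes are collapsed under a missing-tolerant policy (sequences merge
when every site is equal or missing in one of them; merging is by
transitive closure, so the result is order-independent).  Networks are the
connected components of the haplotype graph with edges wherever the
substitution-step count is at most the *connection limit*; components — not
network topology — are what delimitation needs, so no network layout is
estimated.

The connection limit is the largest number of observed differences j that
still has ≥ 95% probability (configurable) of involving no superimposed
substitution.  The probability convention is parameter-free and
combinatorial: j substitutions thrown uniformly on L sites occupy j
distinct sites with probability

    P(j; L) = Π_{i=1}^{j−1} (1 − i/L),

giving a limit of 8 steps at L = 658.  **Known limitation:** the original
TCS program connects haplotypes up to roughly 2% divergence at this length
(≈ 13 steps); its estimator conditions on population-level quantities in a
way that is not reconstructible from the published description.  Our
stricter limit means the TCS proxy over-splits relative to TCS 1.21: on
clean simulated communities (θ = 0.005) it recovers the true partition in
only ~78% of replicates, with every failure a single within-species split;
at a 13-step limit the same suite recovers ~99%.  The convention is pinned
by an independent oracle test and should be revisited if a verifiable
account of the original estimator becomes available.

## Barcode-gap discovery (ABGD-style)

For each prior divergence on a geometric grid (defaults: 50 steps from
0.001 to 0.1), ranked pairwise distances are scanned for the first jump
d[i+1] − d[i] that (a) closes above the prior (a gap straddling the prior
counts — otherwise a clean cluster structure with no distance inside the
gap could never be found from priors inside it), and (b) exceeds
`gap_width_x` (default 1.0) times the local jump scale, defined as the mean
of the *nonzero* jumps among the preceding `n_bins` (default 20) ranks.
Zero jumps are excluded from the scale because tied distances — ubiquitous
when specimens share haplotypes — otherwise drag the local mean toward zero
and turn every ordinary jump into a false gap; windows containing only ties
carry no scale and cannot host a gap.  A relative margin of 1e-9 keeps
exactly-equal spacing from reading as a gap through float noise.

The partition at a prior is the set of components below the gap threshold;
with recursion on (default), the search is repeated inside each block of
≥ 4 specimens until nothing splits (a gap is meaningless on fewer than 3
within-block distances).  One partition is reported per prior; duplicates
are collapsed in summaries.  Fidelity is to the behavioural contract of
barcode-gap discovery, not bit-compatibility with the original server — the
published internals (model-corrected priors, slope heuristics) are
deliberately simplified.

## Ranked hierarchical partitioning (ASAP-style)

Candidates are the partitions formed at each distinct single-linkage merge
height (ties coalesced).  Two scores per candidate:

* **panmixia p-value** — a seeded Monte-Carlo permutation test (default
  R = 999) of the statistic mean(between-block) − mean(within-block), with
  p = (1 + #{permuted strictly greater}) / (R + 1).  Ties are *not* counted
  as exceedances: a permutation that merely re-creates the same grouping
  carries no evidence against it, and counting ties puts a floor of the
  grouping-preservation probability under every coarse partition,
  systematically ranking true coarse structure below spurious fine
  structure.  One-block and all-singleton partitions have p = 1 by
  definition (no between- or within-block pairs).
* **relative gap width** — w = (next merge height − height)/height, 0 at
  the top level.

Each metric is ranked (1 = smallest p, 1 = largest w, minimum rank for
ties); the ASAP score is the mean of the two ranks, lower is better; final
ties break toward fewer blocks, then lower threshold.  The published
method's coalescent-derived p-value is replaced by this permutation test
with the same contract (small under structure, large under panmixia).
Because the 1-block partition has p = 1 and w = 0 by definition, it can
never be ranked first; on genuinely structureless data the top-ranked
candidate is simply arbitrary — this scorer is built to find structure, not
to certify its absence.

## Poisson tree processes (PTP)

A delimitation is an antichain of tree nodes covering all tips; edges from
the root down to and including each species root form the speciation class,
edges strictly inside species subtrees the within class.  Each class is
exponential; with rates profiled at their ML values a class with n branches
summing to s contributes n·ln(n/s) − n to the log-likelihood.  The
single-rate variant shares one within class; the multi-rate variant gives
each species its own and compares delimitations by AIC (unpenalised
per-species rates always favour maximal splitting).

Branches shorter than `min_branch` (default 1e-3 substitutions/site, about
one substitution per kilobase) are floored before rate estimation.  A
single barcode locus cannot resolve shorter branches, and without the floor
the profile likelihood builds degenerate near-infinite-rate classes out of
effectively-zero branches and over-splits — the same pathology the mPTP
program counters with its minimum-branch-length option.  Exact zeros are
additionally floored at 1e-9 if the user disables `min_branch`.

Search is exact (full antichain enumeration, count c(leaf) = 1,
c(node) = 1 + Π c(children)) for trees of ≤ 12 tips.  Larger trees use a
two-stage heuristic: for *fixed* class rates the optimal antichain
decomposes over the tree and is found by dynamic programming, so the search
alternates the DP with rate re-estimation from several edge-length-quantile
seedings, then polishes with single split/merge exchange moves.  The result
never scores below the one-species or every-tip-a-species baselines, and it
matched exhaustive enumeration on all 100 seeded test trees.  Bayesian
support values (bPTP) and mPTP's MCMC supports are out of scope; trees must
be rooted (a root polytomy is rejected with advice to root on an outgroup,
and a named outgroup can be pruned before delimitation).

## Congruence statistics

`match_count` intersects the two block sets; `match_ratio` is
2·N_match/(N_mol + N_morph).  Specimens present in only one partition are
dropped with a logged warning (strict mode errors instead).  Reported
ratios are rounded half-even to 2 decimals with full precision kept in
JSON; a `truncate` helper exists because published tables mix the two
conventions (0.675 printed as 0.67 is truncation, not rounding), and the
tests accept either where a source is ambiguous.  `universal_match_count`
counts reference blocks recovered identically by *every* method.
`pairwise_similarity` assembles the symmetric match-ratio matrix over all
method pairs (optionally including the reference partition as a row).

## Ordination

Similarities map to distances by d = 1 − s (default) or √(1 − s) (metric
for match-ratio-like similarities; the transform used by any given
published figure is rarely stated, so both are provided).  PCoA
Gower-centres B = −½·J·D²·J and eigendecomposes; axes with eigenvalues
above 1e-10 of the spectral scale are retained and scaled by √λ, negative
eigenvalues (match-ratio distances need not be Euclidean) are reported and
dropped, with no Cailliez correction by default.  Axis signs are fixed
(first nonzero loading positive) so outputs are bitwise reproducible.

## Synthetic communities

The generator emulates the data regime the delimitation comparison assumes,
with every quantity controlled and logged:

* **Within species:** random Kingman coalescent shapes rescaled so the mean
  pairwise path distance equals θ exactly (default 0.005 — about 3.3
  differences over 658 bp, typical intraspecific COI diversity).  The
  conditional rescaling pins realised diversity at θ, removing
  coalescent-height variance between replicates.
* **Between species:** an ultrametric backbone with join depths uniform in
  [B/2, B], where B = gap_factor × (largest within-species pairwise path
  distance).  The minimum between-species divergence therefore exceeds
  gap_factor times the deepest within-species divergence; the default
  gap_factor of 10 gives a decisive barcode gap, and 5 is the edge of
  reliable recovery for the distance thresholds used here.
* **Sequences:** evolved along the genealogy by exact per-site JC69
  transition sampling (658 sites by default), so simulation and in-pipeline
  distance models coincide.
* **Discordance events**, applied after the clean baseline and logged:
  *recent pairs* — two labelled species drawn from one shared coalescent
  haplotype pool, labels interleaved along the pool's tree-traversal order
  so both species carry haplotypes of every deep lineage (incomplete
  lineage sorting; no clade of ≥ 2 tips is pure-label, so distance-based
  methods must lump); *geographic splits* — a species built as two
  haplogroups ~3θ apart; *introgression* — a recipient specimen's sequence
  replaced by a mutated copy (θ/2 divergence) of a donor haplotype.
* Parameter combinations whose between-species barrier would saturate JC69
  are rejected before simulation.  A fixed seed makes the whole bundle
  (FASTA, Newick, partition, event log) byte-identical across runs.

What the generator does **not** emulate: recombination, migration matrices,
rate heterogeneity across sites or lineages, pseudogenes, contamination,
and alignment error.  Passing the recovery suite therefore shows the
engines are correct under their own assumptions — clean gaps, clock-like
genealogies, JC-like evolution — not that they are robust to everything
real barcodes do.

`make_partition_pair` constructs reference/MOTU pairs realising requested
exact-match, k-way-split and m-way-lump counts (feasibility is checked
constructively and violated bounds are named); a counts-based variant
solves for an event mix hitting target block counts, which is how the
study-scale count table is turned into live partition objects for the
acceptance computation.

## Problem sizes used in the validation suite

Recovery and discordance properties run on 5-species × 4-specimen
communities (20 sequences of 658 bp) over 100 and 50 seeded replicates
respectively; the PTP search-oracle equivalence uses 100 seeded trees of
4–12 tips; partition-pair round-trips use 1000 random feasible requests.
These sizes keep the full suite near ten seconds while leaving every
statistic far from its decision boundary (except the documented TCS case
above).

## Known limitations

* The TCS connection-limit convention is stricter than the original
  program's (see above); the TCS proxy over-splits accordingly.
* ABGD and ASAP are behavioural re-implementations, not bit-compatible with
  the original servers.
* BIN assignment is proxied by fixed-threshold single linkage.
* mPTP here is ML + AIC, without MCMC support values; bPTP is not
  implemented (its Bayesian machinery has no acceptance surface in a
  deterministic pipeline).
* The permutation panmixia test cannot prefer the 1-block partition on
  structureless data (see the ASAP section).
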