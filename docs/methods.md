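# Methods

## Propagation model

Effects of a phytochemical are modelled as a random walk with restart
(RWR) on an undirected molecular interaction network. The network's
adjacency matrix A (symmetric, zero diagonal; self-loops dropped at
load time) is row-normalised by degree, W = D⁻¹A, so that Wᵀ is
column-stochastic and the iteration

    p(t+1) = (1 − r)·Wᵀ p(t) + r·p₀

conserves probability mass. Isolated nodes receive a self-transition of
1 for the same reason. The restart probability defaults to r = 0.7 and
iteration stops when the L1 difference between successive iterates
falls below 10⁻⁸ (the convergence criterion needs a norm; L1 is the
common RWR choice and pairs naturally with mass conservation). A run
that reaches `max_iter` (10 000) first is flagged `converged=False`
rather than silently accepted. Because the spectral radius of
(1 − r)Wᵀ is at most 1 − r, convergence at r = 0.7 takes ~16 iterations
regardless of network size.

The seed vector assigns weight 1.0 to direct targets and 0.3 to
indirect targets, then is normalised to sum to one. Normalisation keeps
the iteration a probability iteration while preserving the 1 : 0.3
relative weighting; it rescales all phenotype scores of a compound by
the same constant and therefore cannot change the rank-based empirical
p-values. A target listed as both direct and indirect is kept as direct
(the stronger association wins); targets absent from the network are
dropped with a logged count.

## Empirical null and PVP binarisation

Raw phenotype scores (sums of steady-state node scores over each
phenotype's gene set) grow with the number of targets and with gene-set
size, so significance is assessed against random target profiles that
preserve the observed in-network direct and indirect target counts.
Random targets are drawn uniformly from all network nodes without
replacement (direct and indirect disjoint); the draw stream is
documented and reproducible: with `rng = numpy.random.default_rng(seed)`
the j-th profile is `rng.choice(n_nodes, size=nd+ni, replace=False)`,
first `nd` entries direct. The empirical p-value is

    p = (n_exceed + 1) / (n_random + 1),

where `n_exceed` counts random profiles whose phenotype score is
*strictly* greater than the observed one — ties do not count, which is
the conservative direction (it can only enlarge p). With `n_random`
defaulting to 1000 the smallest attainable p is 1/1001; phenotypes with
p < α (default 0.01, strict inequality) form the binary phenotype
vector of the compound. One master seed per run is expanded into
per-compound streams via SHA-256 of `(master_seed, compound_id)`,
truncated below 2³¹, so results are bit-reproducible and independent of
compound processing order. All `n_random + 1` propagations are iterated
as columns of one matrix, which keeps the permutation null cheap.

## Chemical properties

Five descriptors (MW, AlogP, H-bond donors, H-bond acceptors, rotatable
bonds) come from a pluggable backend: an RDKit backend computes them
from SMILES (AlogP is the Crippen estimate; the donor count follows
RDKit's `Lipinski.NumHDonors` SMARTS convention, under which water has
0 donors and ethanol 1 — backend name and version are recorded in
provenance), and a precomputed-table backend serves external values
verbatim. Rule-of-five "satisfaction" is at most one violation among
{MW > 500, AlogP > 5, HBD > 5, HBA > 10}, Lipinski's own convention;
a record with a missing descriptor is *unknown*, not non-compliant.

HIA, Caco-2 and BBB flags are tri-state inputs (true/false/unknown);
the published substructure-fingerprint and QSAR predictors behind them
are out of scope here, so flags normally arrive precomputed. A naive
logistic surrogate on MW/AlogP exists solely so synthetic runs have
non-trivial flags; it is labelled as such and must not be read as a
validated absorption model. Unknown flags never enter co-satisfaction
counts in either direction.

## Phenotype hierarchy and Wu–Palmer similarity

Concept triples use RB ("b broader than a" ⇒ b is a's parent), RN (the
inverse) and RO (other-related). A configuration switch flips RB/RN
polarity for dumps using the opposite orientation. Hierarchical edges
are added in lexicographic order and any edge that would close a cycle
is dropped deterministically with a warning. All parentless concepts
attach to a virtual root at depth 0, so concept hierarchies with many
roots (the common case for real terminologies) become one rooted DAG;
depth of a multi-parent concept is the shortest ancestor chain. Note
the virtual root shifts every tree root to depth 1.

Wu–Palmer similarity uses the deepest common ancestor (ties broken
lexicographically, logged) and shortest path lengths along hierarchical
edges only. RO edges never contribute to depth, LCS or path length —
they are non-hierarchical and including them would shortcut the
subsumption structure the measure depends on — but they remain
available for neighbourhood queries. Two concepts whose only common
ancestor is the virtual root get similarity 0; sim(c, c) = 1 for any
non-root concept.

## Evidence matching

A plant supports a predicted phenotype when the *maximum* Wu–Palmer
similarity between the phenotype and any of the plant's use concepts is
strictly greater than the threshold (default 0.8): selection is by the
best-matching pair, not an average, because one genuinely matching
traditional use is what constitutes evidence. `n_e` counts supporting
plants (not plant–use pairs, so duplicate use listings cannot inflate
it), and evidence-filtered effects are ranked by descending `n_e` with
dense ranking and lexicographic tie-break.

## Literature validation

`n_c` counts abstracts with at least one sentence mentioning both terms
(sentence-level co-mention is the stricter, more meaningful signal);
`n_o` counts abstracts mentioning either term anywhere, and the Jaccard
index `n_c / n_o` (0 when `n_o = 0`) corrects for term frequency. The
Fisher test classifies abstracts by term inclusion at the abstract
level and is one-sided (enrichment): only over-representation is
evidence of a real association. It is computed exactly via the
hypergeometric tail, with no normal approximation at any table size.
BH q-values are computed per association list (one family per
comparison set). The Mann–Whitney U test is exact — the permutation
distribution of U obtained by dynamic programming over midranks, valid
under ties — whenever n·m ≤ 400, and otherwise uses the tie-corrected
normal approximation; the mode is size-based and logged.

Precision under unknown true negatives is estimated by sampling
negative pairs from the prediction universe at controlled
positive:negative ratios (1:1, 1:10, or the full complement), repeated
10 times by default with fresh draws and reported as mean ± sd; recall
is TP/|positives| and independent of the skew.

## Synthetic data generator

The generator emulates the input *structure* of a real study at desk
scale, with planted signal so recovery is decidable: a 300-node
degree-heterogeneous (Chung–Lu, weights ∝ rank⁻⁰·⁴) network at mean
degree ≈ 6; 20 compounds with 9 direct / 6 indirect targets; 40
phenotypes with 8 genes each, placed as leaves of a 3-ary concept tree
of depth 4 (121 concepts); 40 plants of 3 compounds each; 2000
abstracts. Each compound gets 3 true phenotypes; its direct targets are
drawn from those phenotypes' own gene sets (indirect targets from their
one-hop neighbours), so the propagation signal exists by construction.
Plants containing a compound list a matching use concept (the phenotype
itself, or sometimes its parent — similarity 8/9 at leaf depth) with
probability 0.8 per true phenotype, plus random noise concepts. In the
corpus, a true pair co-occurs in a sentence at 20× the background rate
of 5×10⁻⁴ per abstract (background and solo-mention rates chosen so a
background pair co-occurs about once in the corpus, as sparse literature
does, while true pairs accumulate ~20 co-mentions). Corpus terms reuse
pipeline IDs verbatim, deliberately skipping entity normalisation.

All sampling flows through a single `numpy.random.default_rng` stream
in a fixed order and files are written in sorted order, so a spec and
seed reproduce byte-identical outputs across platforms.

What the generator does *not* emulate: realistic scale (tens of
thousands of proteins, millions of abstracts), literature entity
ambiguity, correlated phenotype gene sets, plant composition bias, or
realistic PPI topology beyond degree heterogeneity. Passing the
recovery tests therefore shows the machinery is correct and the planted
signal is recoverable at these sizes — not that prediction accuracy on
real databases would match.

## Numerical and design choices

- Tolerances: RWR L1 tolerance 10⁻⁸; linear-solve agreement asserted at
  10⁻⁶; conservation asserted at 10⁻⁶.
- Degenerate inputs: empty networks, empty gene–phenotype maps, empty
  target profiles and out-of-range p-values raise; α = 0 yields empty
  PVPs and valid, empty downstream tables.
- Problem sizes in tests: the null-calibration check uses 200 null
  compounds at `n_random = 200` on the default generator settings, and
  the recovery check uses `n_random = 1000` over the 20 default
  compounds — sizes at which the binomial error of the checked
  fractions is small relative to the asserted margins.
- The summary confidence interval is a Student-t interval on the
  per-compound predicted-effect counts (the "±" needs a definition;
  t on compound counts is the plainest one).
- Exact Mann–Whitney p-values use the symmetry of the permutation
  distribution of U about n·m/2 (which negating the data establishes
  also under ties), so "two-sided" is P(|U − nm/2| ≥ |u_obs − nm/2|).

## Known limitations

- Combination (multi-compound) effects and dosage are not modelled.
- The propagation treats the network as unsigned and undirected;
  activating and inhibiting interactions are indistinguishable.
- Evidence matching requires use concepts already mapped to the
  hierarchy's namespace; free-text extraction is out of scope.
- The surrogate availability predictor is a placeholder heuristic.
- `n_e`-based ranking favours well-botanised compounds: a compound found
  in many plants accumulates support more easily.
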