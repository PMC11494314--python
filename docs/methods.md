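# Methods

This note records the statistical model behind `tcrinfo`, the estimators
and their conventions, what the synthetic generators do and do not emulate,
and the numerical and design choices a maintainer should know about.

## Estimators

**Coincidence probability.** For a discrete feature X the population
quantity is p_C[X] = Σ_x P(x)². From a sample of N distinct clones the
package uses the unbiased pair-counting estimator
p̂_C = Σ_x n_x(n_x−1) / (N(N−1)). Pairs are counted over distinct clones,
never reads: each clonotype row enters once regardless of `clone_count`
(counts are metadata; count-weighted estimation is deliberately not the
default because clonal expansion would otherwise masquerade as feature
convergence).

**Conditional estimates.** p̂_C[X|Y] = Σ_y ρ₂(y) p̂_C[X|y] with
ρ₂(y) = P(y)²/Σ P(y)². The epitope distribution P(π) defaults to uniform
over epitope groups; a `size` option weights by usable clone counts, and
explicit mappings are accepted. Groups contributing fewer than two usable
values are dropped with a warning — they admit no pair estimate.

**Information scores.** Relevancy is the plug-in log-ratio
log₂(p̂_C[X|Π]/p̂_C[X]). No bias correction is applied before taking the
logarithm: the ratio of two unbiased estimators is not itself unbiased, and
the log adds a further small-sample bias of order Var(p̂)/p². This is
documented rather than corrected; at the pair counts used in the test suite
the bias is far below the reported uncertainties. Conditional relevancy
groups the background by Y (empirical P(y)) and the specific side by
(epitope, Y) with joint weights P(π)·P̂(y|π). Interaction information is
the printed difference I₂([X,Y],Π) − I₂(X,Π) − I₂(Y,Π), evaluated with all
three terms restricted to records where both features are present, so the
comparison is like-for-like.

**Uncertainty.** Clone-level bootstrap (default 200 replicates, seeded),
resampling within each epitope group and the background independently;
intervals are percentile intervals of the bits.

**Degenerate inputs.** A zero coincidence count makes the corresponding
entropy or information undefined; the package propagates `None` with a
diagnostic instead of inventing a value. This mirrors the practical
requirement that at least one coincidence be observed for the feature in
each population before its information can be quantified.

**Distances.** Levenshtein distances are unit-cost edit distances computed
with edlib; the paired-chain metric is the sum of per-chain CDR3 distances,
and records missing a required chain are excluded. Distance classes bin
pairs at exactly Δ (a Kronecker-delta reading of the per-distance
coincidence probability); a cumulative (≤ Δ) option exists but is not the
default. Distance computations run over unique values weighted by count
products, so results are independent of record order.

## Classification bounds

Posterior odds after a feature match multiply prior odds by 2^bits; the
minimal prior for posterior odds T is T·2^(−bits)/(1+T·2^(−bits)). The
threshold is expressed in odds (T = 19 ↔ posterior probability 0.95); the
CLI accepts probabilities and converts. The distinction between the spike
fraction P(π) and the true fraction of sequences specific to π (background
sequences can themselves be specific) is documented as negligible in the
regime where P(π) exceeds the background frequency of specific sequences,
and is not modeled. The critical fuzzy-match distance is the largest Δ
whose near-coincidence information still reaches the target posterior at
the given prior; distance classes with undefined information are skipped.

## Synthetic generators

**Background.** Per chain: categorical V and J usage (geometric-like, a
few dominant genes with a long tail), a categorical CDR3 length
distribution, and i.i.d. amino acid draws from a fixed composition, with a
leading cysteine. α and β are generated independently (random pairing).
This is deliberately much simpler than V(D)J junctional machinery: no
insertion/deletion model, no positional composition gradients, no
thymic-selection imprint. It is sufficient here because every analysis is
a ratio against this same background, and no claim validated by the test
suite depends on recombination realism. Consequence: passing tests show
the estimators and the mixture-model predictions are correct, not that any
particular bit value transfers to real repertoires.

Because the background factorizes and is known exactly,
`background_pc_exact` computes p_C[X|B] for gene/length/CDR3 features and
their products in closed form (CDR3: Σ_L P(L)² c^(L−1) with c = Σ_a p_a²).
This matters: full-chain coincidence probabilities are ~10⁻¹⁵, so no
feasible background *sample* contains a chain-level coincidence — real-data
analyses rely on observed full-TCR coincidences in large generated
backgrounds, and the package instead lets any information function accept
a precomputed background coincidence probability.

**Epitope-specific repertoires.** A mixture of M binding modes. Each mode
anchors one V and J gene per chain and a CDR3 motif template; a clone picks
a mode (equal weights by default), inherits the anchors, and mutates each
non-anchor template position to a uniform random residue with probability
`cdr3_noise_rate` (default 0.1 — high enough that exact CDR3 coincidences
remain common, low enough that modes stay well separated). Modes are
disjoint by default (distinct anchor V genes), and an optional
`false_positive_fraction` admixes background draws, emulating sorting
impurity.

With M disjoint equal-weight modes of equal within-mode coincidence q:
p_C[chain|π] = q/M, so each doubling of M costs one bit of per-chain
relevancy while α–β interaction information rises by exactly one bit
(within a mode the chains are independent, across modes they are fully
linked). The mode-count sweep therefore predicts slopes of −1
(interaction vs single-chain relevancy) and +1 (paired-chain vs
single-chain relevancy). These identities require modes of matched
entropy, so the sweep fixes mode templates to the modal background CDR3
length per chain; with free template lengths the per-mode q varies and the
regression attributes that variation to the slope.

**Spike-in experiment.** Queries are drawn from the two-component mixture
(specific with probability equal to the spike fraction, background
otherwise) over a shared categorical outcome set; a query is classified
positive when it equals a fresh reference draw from the specific
distribution. With a uniform background the cross-match probability equals
the background coincidence probability exactly, so the odds-multiplication
law is exact and the empirical posterior (fraction of true spikes among
positives) should match it to binomial error — which is what the tests
check, including per-distance-class for fuzzy matches on a
distance-regular outcome set.

**Random streams.** One root seed; independent child streams are spawned
per epitope in sweeps, so adding epitopes does not perturb earlier draws.
All generators are pure functions of their configuration and seed.

## Reduced alphabets

Alphabets are total maps of the 20 amino acids onto k group symbols;
groups are labeled by their lexicographically first member so equal
partitions compare equal. Property-based alphabets use complete-linkage
hierarchical clustering on a single 1-D scale, which yields contiguous
value intervals; the shipped scales (polarity, solvation free energy,
normalized Van der Waals volume, side-chain radius of gyration, tripeptide
accessible surface area) are literature values stored as a data file with
sources in its header, not hard-coded constants.

The greedy search is agglomerative: starting from 20 singletons it
repeatedly merges the pair of groups that maximizes the relevancy of the
remapped CDR3 feature, breaking ties lexicographically, until k groups
remain; merges with undefined relevancy score −∞. Greedy direction and
tie-breaks are this package's choices; the search strategy is isolated so
alternatives can be plugged in.

**A non-property worth knowing.** Order-2 coincidence information obeys no
data-processing inequality: merging outcomes can *increase* exact I₂
(unlike Shannon mutual information, Rényi information of order ≠ 1 is not
monotone under coarse-graining). A regression test pins a counterexample.
Practically this means a reduced alphabet can legitimately score higher
than a finer one, on exact distributions and not only through sampling
noise; "retained information" in the scoreboard is a measurement, not a
bounded fraction. Relatedly, the identity alphabet is not asserted to
dominate coarser alphabets on sampled data.

## Conventions and open choices

- Gene calls are normalized to gene level by stripping the `*NN` allele
  suffix; no cross-nomenclature translation is attempted.
- CDR3s are used exactly as given (`junction_aa` including the conserved
  terminal residues); sequences with non-canonical letters are dropped and
  counted in the table provenance.
- Net charge counts K/R as +1 and D/E as −1; histidine contributes 0 by
  default (configurable; fractional weights are binned to one decimal so
  values stay hashable).
- A "chain" feature is the product (V, J, CDR3) of that chain, and the
  full receptor is the product of both chains — chosen over a
  reconstructed full amino acid sequence because gene-level anchoring is
  what the data formats carry reliably.
- Background α/β pairing in analysis tables is whatever the input file
  contains; the synthetic generator pairs once per draw (a single-draw
  convention; resampled pairings can be produced by regenerating with
  another seed).
- Problem sizes in the test suite and the acceptance script (2000 clones
  per simulated epitope, 5 mode counts, 10⁴ unbiasedness replicates,
  ~10⁵-query spike-ins) were chosen so that Monte-Carlo error is several
  times smaller than the effect each check targets.

## Known limitations

- The background generator's simplicity (see above) makes absolute bit
  values on synthetic data larger than on real repertoires; only
  relationships among scores are meaningful there.
- Only order-2 Rényi quantities are implemented; Shannon-entropy
  estimation and higher Rényi orders are out of scope.
- Bootstrap intervals are percentile intervals and inherit the log-ratio
  estimator's small-sample bias near zero coincidence counts.
- Substitution-matrix-weighted distances (TCRdist-style) and multiclass
  epitope classification are not implemented.
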