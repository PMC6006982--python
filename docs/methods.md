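# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `entroflow`, in the order the pipeline runs.

## Entropy kernel

All entropies are entropies of clustering compositions: N subjects split
into K clusters of sizes N₁..N_K have H = −Σ pₖ log pₖ, pₖ = Nₖ/N. The
conditional entropy of composition Y given X is the size-weighted mean of
the within-cluster entropies, H(Y|X) = Σₖ pₖ H(Y|X=k), and the symmetric
normalized association is E[Y⇔X] = ½(H(Y|X)/H(Y) + H(X|Y)/H(X)).

Conventions: 0·log 0 = 0; a ratio term with zero marginal entropy
contributes 0 (a constant composition is perfectly predicted by
anything). **Natural log is the default base everywhere**; the base is a
pure rescaling and cancels in the normalized ratios, so no ordering or
decision in the pipeline depends on it. `uniform_uncertainty(N)` exposes
the log-N uncertainty of the uniform composition (base 2 by default, the
information-theoretic convention for counting binary questions).

## Possibly-gapped histograms

Continuous and discrete features are discretized by approximating the
empirical distribution function (ECDF) piecewise-linearly — no density
model, no continuity assumption:

- **Gap rule.** A hole between consecutive sorted distinct values becomes
  a gap when it exceeds `gap_factor` (default 5) × the median positive
  spacing **and** `min_gap_frac` (default 0.05) × the occupied range. The
  first condition is scale-free; the second was added because heavy-tailed
  features otherwise fragment into many spurious tail gaps (tail spacings
  routinely exceed 5× the median even in clean unimodal samples), which
  starves the central mass of bins.
- **Bin placement.** Within each gap-free segment, the ECDF chord with the
  largest vertical deviation is split at its point of maximum deviation,
  greedily, until every piece deviates ≤ `tol` (default 0.05, i.e. 5% of
  probability mass) or the global budget `max_bins` is reached. Each
  linear piece is one bin. If the gap rule produces more segments than
  the budget allows, only the widest gaps are kept.
- **Codes.** Bin indices are rescaled onto the common range 0..C−1 with
  C = 10 (configurable); codes increase strictly with bin order, so the
  coding is order-preserving, and `max_bins` is capped at C. C = 10 makes
  manually coded categorical schemes (on 0–9) and histogram codes
  directly comparable.

This equi-depth-flavored coding deliberately uniformizes each marginal:
all structural information except order and gaps is removed per feature,
and cluster structure is recovered downstream from the *joint* behavior
of feature groups, not from single-feature spacing.

Binary/categorical features: with an explicit override map, the map is
applied verbatim. Otherwise each label receives the rounded mean code of
its anchor feature (the non-categorical feature with the lowest mutual
conditional entropy against the labels, auto-selected unless configured),
with rounding ties broken toward the smaller code. Two labels with nearly
equal anchor means may legitimately share a code. If a matrix contains no
non-categorical feature at all, labels are ordered by name and spread
evenly over the range (a documented fallback; such matrices carry no
anchor information).

Missing values are rejected, not imputed. Values falling in a gap at
encode time are an error by default; `lenient` snaps them to the nearest
bin.

## DCG: regulated-walk ultrametric clustering

Given a distance matrix, the similarity at temperature T is
sᵢⱼ = exp(−dᵢⱼ/T) (unit diagonal), row-normalized into a transition
matrix. A *regulated* random walk moves between distinct nodes (self-stays
neither explore nor count — with unit diagonal similarities, self-loops
would otherwise dominate at low temperature and destroy the visit-count
bookkeeping), removes a node once its cumulative visit count exceeds
`visit_threshold` (default 5), renormalizes transitions over survivors,
and continues *from the removed node's own transition row* so the walk
keeps its locality; if that row has underflowed to zero it restarts at a
uniform surviving node. Removals whose recurrence time (arrivals since
the previous removal) exceeds `spike_factor` (default 5) × the running
median are spikes — the walk has entered a fresh region — and nodes
removed between consecutive spikes share a cluster. The inner loop is
compiled with numba; one `rng_seed` drives independent sub-streams for
every temperature.

An ensemble (default 100 trajectories) yields the cluster-sharing matrix
En; the cluster count N(T) is the number of leading eigenvalues of En
before the largest relative gap (λᵢ₋₁−λᵢ)/λᵢ₋₁, restricted to
eigenvalues ≥ 1% of the top one. The composition at N(T) comes from
average-linkage hierarchical clustering on 1−En.

**Temperature grid.** 25 geometric steps from `t_lo_scale` (default 0.2)
× the 5th percentile up to the 95th percentile of the positive distances.
The cold end sits *below* the typical distance because similarity
contrast is exponential in d/T: walks only become confined to tight
regions — the regime where spikes delineate clusters — once T is a
fraction of the distances to be resolved. At the hot end N(T) → 1; at
temperatures far below the finest structure the walk reads noise, which
the plateau rule filters out.

**Tree synthesis.** Maximal constant runs of N(T) of length ≥ `min_run`
(default 2) are plateaus; each contributes one level at its middle
temperature. Plateaus with equal N are deduplicated (longest run wins), a
one-cluster root is always present, and nesting is enforced from the
finest level upward: every finer cluster is reassigned wholesale to the
coarse cluster holding its majority (ties toward the larger coarse
cluster, then the smaller label). Level temperatures are then forced
strictly decreasing with fineness, so the cophenetic matrix is exactly
ultrametric by construction. The default working level (`level_rule =
"longest_plateau"`) is the non-root level with the longest plateau — the
most stable scale in the data.

## Data Mechanics

Iteration 0 builds the row tree from plain Euclidean distances between
coded rows. Each round then rebuilds the column tree from distances on
columns extended with the current row-cluster means (one extra unweighted
coordinate per cluster), and the row tree symmetrically from
column-cluster-mean-augmented distances, selecting the working level by
`level_rule`. Iteration stops when both selected compositions repeat, or
after `max_iter` = 3 rounds — empirically the compositions stabilize in
one or two.

The diagnostic *energy* of a (row, column) partition pair is the
within-block total variation Σ_blocks Σ (x − block mean)²; the trace
starts at the single-block baseline (total sum of squares, an upper bound
for any partition) and records the energy after each round. Data
Mechanics only permutes and frames the matrix: the multiset of entries is
invariant.

## Information flows

For a response-side composition Y and a covariate-side composition X on
the same subjects, each covariate cluster k gets the directed entropy
H(Y|X=k) of the response labels among its members; zero means the cluster
is response-pure — an exclusive linkage. The overall link score is the
size-weighted sum (≤ H(Y) always).

**Confirmation.** The null resamples response labels without replacement
(equivalently, permutes them across subjects; the response margins are
preserved exactly) `n_sims` = 1000 times; the per-cluster p-value is the
smoothed one-sided fraction (r+1)/(n_sims+1) of simulated within-cluster
entropies at or below the observed one. With a small label alphabet and a
fixed cluster size the entropy statistic is discrete, so p-values carry
atoms and are conservative near their resolution limit 1/(n_sims+1); with
richer response alphabets they are uniform to KS precision.

**Error rates.** Majority rule: cluster error = 1 − majority share
(ties broken toward the globally more frequent response label, logged);
randomized rule: 1 − Σ q² over within-cluster label shares. The serial
error of a multi-link flow is the error of the combined prediction where
each link casts its cluster-majority vote with weight ∝
1/(overall entropy + ε), ε = 10⁻⁶ (the floor keeps exact-zero-entropy
links finite and dominant). Because the covariate-side tree construction
never uses the response labels, the observed within-cluster error equals
the expected leave-one-out error — no cross-validation loop is needed,
and none is run.

**Pipeline.** `build_information_flow` computes the entropy matrix per
side, DCG-groups the features (a side with one feature, or an all-zero
entropy matrix, is a single group), runs Data Mechanics per group
(single-feature groups use their codes directly as the composition),
pairs every response-group composition with every covariate-group
composition, and assembles per response group a serial flow ordered by
ascending overall entropy — most informative first. "Directed" means
conditioning order only; no causal claim is made or implied.

## Synthetic study conditions

The generators plant exactly the structures the method assumes, at the
scale of the small tabular studies it targets:

- `make_planted_dataset`: n = 100 subjects by default; subjects carry a
  latent fine cluster, the response clusters are a coarsening of it, and
  linked covariate groups map the latent through their own maps with a
  given `exclusivity` (probability of following the map; 0 = fully
  independent). Features are cluster centers spaced `separation` = 6
  noise-SDs apart plus Gaussian noise (`noise` = 0.5 SD); a configurable
  number of features are binarized by median thresholding to exercise the
  anchor-coding path. Gaussian within-cluster noise means occasional
  boundary subjects and occasional spurious within-cluster gaps — the
  generator does *not* emulate real data's outliers, missingness or
  heavy-tailed measurement error, so passing tests demonstrate correct
  mechanics and statistical calibration, not robustness to data
  pathologies beyond those noise models.
- `make_synergistic_codes`: feature groups sharing a uniform latent code
  on 0..9 plus rounded-Gaussian code noise (SD `noise` = 0.5), clipped to
  the range — the conditions under which planted-group recovery is
  measured (3 groups × 5 features, 200 subjects).
- `make_checkerboard_matrix`: block-constant codes spread over the range
  plus discrete uniform noise on ±1 by default (60 × 12, 2 × 3 blocks) —
  the Data Mechanics test surface.

All generators are bit-reproducible under a fixed seed, and ground truth
is returned in the same label spaces the scorers consume.

## Numerical choices and degenerate inputs

- Constant feature → one bin, code 0; constant column in an entropy
  matrix → zero-entropy convention plus a logged warning.
- All-equal distance matrix → single-level (root-only) tree, logged.
- Single item → trivial one-cluster walk; two items are walked normally.
- Eigenvalues of En are clipped at 0 before the gap rule; the 1% floor
  keeps numerically tiny eigenvalues from inflating N(T).
- Ties in the categorical anchor rounding go to the smaller code; ties in
  nesting repair go to the larger coarse cluster; ties in majority votes
  go to the globally more frequent label. All tie rules are deterministic.
- JSON/CSV floats are written with 12 significant digits; identical seed
  and inputs give byte-identical JSON artifacts.

## Problem sizes

Default test and acceptance runs use the generators' stated conditions
(15–40 items for tree fixtures, 60–200 subjects, ≤ 15 features), chosen
as representative of the small multi-study designs this method targets;
the implementation is comfortable to a few thousand items per tree, above
which the dense similarity matrices and walk ensembles become the
bottleneck by design (no approximate-neighbor shortcuts are taken).

## Known limitations

- Cluster recovery after re-normalization is intrinsically stochastic:
  equi-depth coding erases marginal spacing, so structure whose signal
  lives only in one feature's spacing (not in joint behavior) can blur at
  bin boundaries; a minority of seeds show partial recovery on planted
  fixtures.
- Permutation p-values are discrete for small clusters over small label
  alphabets; they are valid but conservative there.
- The spike heuristic needs a few nodes per cluster to form a recurrence
  contrast; clusters of size 1–2 are found via the sharing-matrix
  eigenstructure rather than individual trajectories.
- The serial-flow weighting assumes link errors are roughly independent;
  strongly redundant covariate groups receive double weight rather than
  being de-duplicated.
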