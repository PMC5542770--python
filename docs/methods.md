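# Methods

`pdakit` implements two statistical analyses of annotated protein multiple
sequence alignments (MSAs), motivated by the study of J-protein (Hsp70
cochaperone) families, where canonical class A and class B members form
interclass complexes and where each organism carries a variable number of
paralogs of each class.

## 1. Phylogenetic discriminant analysis (PDA)

### Model and procedure

Given an alignment of width `N_pos` and a per-sequence phylogenetic group
label, PDA asks which *triplets* of alignment columns best separate the
groups, and from them which individual positions are discriminating.

For each candidate triplet `(i, j, k)`:

1. **Reduced alignment.** Only the three columns are kept.  Residues are
   one-hot encoded over a 22-symbol alphabet (20 amino acids, `X`, gap);
   each sequence becomes a 66-dimensional indicator vector.  Non-standard
   residue codes (B, Z, U, O, J) fold into `X`; `X` is treated as its own
   symbol throughout.
2. **Projection.** The encoded sequences are mean-centred and projected on
   their principal components, keeping the smallest subspace whose
   cumulative explained variance reaches `variance_kept` (default 0.95;
   1.0 keeps everything and is then an exact isometry).  Component signs
   are fixed by making the largest-magnitude loading positive, so results
   are fully deterministic.  If the reduced alignment has zero variance
   (all rows identical) the projection is a single all-zero column.
3. **Clustering.** Agglomerative hierarchical clustering (Euclidean
   metric, average linkage by default; ward/complete/single selectable)
   with the dendrogram cut at a height equal to the *mean of all pairwise
   sequence distances* in the projected space.  Merges at exactly the
   cutoff are performed, which makes the two-point boundary case (cutoff =
   their distance) a single cluster.  The number of clusters is therefore
   never chosen by hand.
4. **Mixing score.** Each cluster `c` containing a fraction `w(c)` of the
   sequences is scored by the Shannon entropy of its group composition,
   `h(c) = -Σ_i P(i|c) ln P(i|c)`, and the triplet by the weighted average

   `H = Σ_c w(c) h(c)`.

   `H = 0` means every cluster is phylogenetically pure; `H = ln G` (G
   groups) is maximal mixing.  Natural logarithms are used; rankings,
   p-values and selections are invariant under the base.

Scanning is exhaustive over all `C(N_pos, 3)` triplets, or uniform without
replacement (`sample_triplets`, explicit seed) when the combinatorial
budget is too large.  The per-triplet pipeline in the scan loop is the
same code path as the public single-triplet operations.

### Selection of discriminating positions

* **Empirical p-value** of a score: the fraction of scanned triplets with
  equal or lower `H` (self-inclusive; minimum `1/T`).
* **Reference score**: either the `H` of a designated reference triplet
  (e.g. an experimentally motivated one), or — when no reference triplet
  exists — the score delimiting a low percentile of the empirical `H`
  distribution (default 5%, no interpolation: the `floor(p·T/100)`-th
  smallest score, at least the smallest).
* **Selected set.** In reference-triplet mode the selected triplets are
  those *strictly below* the reference (the reference itself is never
  selected).  In percentile mode ties at the cut value are *included*: a
  percentile defines an inclusive lower tail, and on data where many
  triplets tie at `H = 0` (e.g. a perfectly discriminating planted signal)
  a strict cut below the 5th-percentile value would select nothing at all.
  The `inclusive` flag on `position_selection_frequency` exposes both
  conventions.
* **Selection frequency.** For the `m` selected triplets, each position's
  frequency of appearance; frequencies sum to 3 whenever `m > 0`.  `m = 0`
  yields all zeros and a warning.
* **Null model.** Under a uniform prior every position appears with
  probability `p_null = 3/N_pos`; with `m` selected triplets the standard
  error is `σ_p = sqrt(p_null (1 - p_null) / m)`.  Positions with
  frequency above `p_null + kσ_p` are called discriminating; `k = 3` is a
  permissive and `k = 10` a conservative call.  Note the null treats
  triplets as independent, which they are not (triplets share positions),
  so `k = 10` is the call to trust.  With few columns the thresholds
  saturate: at `N_pos = 15`, `p_null = 0.2` and the 10σ threshold is
  unreachable by construction — use 3σ or wider alignments.
* **Robustness.** `regroup_and_rescan` re-runs the analysis under coarser
  or finer group partitions; on planted data the recovered positions are
  stable from 2-group to 4-group relabelings (tested).

### What the synthetic generator emulates

`make_grouped_msa` draws background columns i.i.d. from a residue profile
(uniform over the 20 amino acids by default, `gap_rate` 0) and gives each
group a signature residue at the three planted positions with probability
`purity`.  Signature residues are assigned deterministically (g-th group
in sorted order gets the g-th amino acid alphabetically) so fixtures are
stable across versions.  This reproduces the *statistical* structure PDA
assumes — group-conditional residue distributions — but none of the
phylogenetic realism of real families: no tree-structured correlation
between sequences, no rate variation across sites, no indels, no
position-specific conservation gradients.  Passing tests therefore show
that the machinery recovers planted signal and stays calibrated under an
exchangeable null; they do not show robustness to tree-induced
pseudo-replication, which on real data is partly absorbed by the group
labels themselves.

### Study conditions used in tests

The default test conditions are two groups of 100 sequences, 25 columns,
planted triplet at purity 1.0 (signal) or 0.0 with permuted labels (null),
exhaustive scan of 2300 triplets, 20 replicate seeds.  These sizes keep a
full replicate set inside a few minutes while leaving the selection
statistics (m ≈ 500 selected triplets under signal, ≈ 115 under the null)
large enough to be meaningful.

## 2. Ensemble DCA with random paralog matching

### The pairing problem

Inter-protein direct coupling analysis needs matched pairs: which family-A
paralog interacts with which family-B paralog in each organism.  For
eukaryotic J-proteins this is unknown — paralog counts vary per organism,
partners are not annotated, and the genes are not co-localized, so
operon-based pairing is unavailable.  The implemented strategy matches
each family-A sequence with a uniformly random family-B sequence *of the
same organism*, one-to-one (each B used at most once; when one family has
excess paralogs, a uniformly random subset of it is matched), concatenates
the matched pairs into a joint alignment, scores couplings, and repeats
the whole procedure `R` times (default 300).  An inter-protein position
pair is *recorded* in a realization when its normalized coupling score
reaches `score_threshold` (default 0.8) and *selected* overall when it is
recorded in at least `appearance_threshold` (default 5%) of realizations.
True couplings recur across matchings; spurious ones do not.

Sequence reweighting (each sequence weighted by the inverse of its number
of neighbors at ≥ 90% identity over the full joint width, gap-gap columns
counting as matches) is applied to every concatenated alignment, i.e. per
realization.  Coupling scores are memoized on the realized pair set within
one ensemble run; when every organism has a single paralog per class the
matching is forced and all realizations coincide, so appearance fractions
are exactly 0 or 1.

### Built-in coupling scorer

The default scorer is mean-field DCA over a 21-state alphabet (20 amino
acids plus a combined gap/unknown state):

1. weighted single and pair frequencies;
2. the connected-correlation (covariance) matrix, regularized by a
   pseudocount of relative weight λ = 0.5 applied **at the covariance
   level**: `C_reg = (1-λ) C_data + λ C_uniform`, where `C_uniform` is the
   (block-diagonal) covariance of the uniform residue profile.  A
   frequency-level uniform pseudocount mixture — the textbook variant —
   makes the marginals and the joint shrink at incompatible rates and
   thereby manufactures systematic cross-column covariance proportional to
   `λ(1-λ) f_i f_j` for low-entropy columns; with a near-binary column
   pair this artifact exceeded every genuine coupling in the test system.
   Covariance-level shrinkage keeps independent columns uncorrelated in
   expectation regardless of their entropies, while still guaranteeing an
   invertible matrix;
3. inversion restricted to the 20 non-gap states; coupling blocks shifted
   to the zero-sum gauge;
4. the score of a column pair is the **squared** Frobenius norm of its
   coupling block, with the average-product correction (APC) applied to
   the squared norms.  Under the null the expected squared norm is
   proportional to `(k_i - 1)(k_j - 1)` — the product of the two columns'
   effective state counts — so it factorizes over columns and the rank-one
   APC removes it exactly even for alignments mixing low- and
   high-diversity columns.  (APC on the unsquared norm mis-centers such
   pairs: a pair of near-binary columns, whose block has ~1 data degree of
   freedom, then occasionally tops the many-degrees-of-freedom background
   on noise alone.)

Normalization of the inter-protein scores within each realization is
affine min-max to [0, 1] (maximum maps to 1; invariant under positive
affine transforms of the scores).  Degenerate cases: a single pair
normalizes to 1.0, all-equal scores to 0, both with a warning.  Intra-
protein couplings participate in the inversion and the APC but are not
thresholded; only the A-block × B-block is reported, 1-based in file
output.

Any scorer with the signature `(integer alignment, weights) -> L×L score
matrix` can be plugged in, e.g. an external asymmetric pseudo-likelihood
implementation; the built-in mean-field scorer is the deterministic,
desk-scale default.

### What the paired generator emulates

`make_paired_family` designates the i-th A-paralog and i-th B-paralog of
each organism as true partners.  At each planted `(pos_A, pos_B)` both
columns are restricted to a fixed two-residue alphabet; a true partner
copies its A-side state with probability `coupling_strength`, otherwise
flips it, while non-partners draw independently.  Background columns are
uniform over the 20 amino acids.  This is the simplest possible
covariance structure — a single binary latent state per planted pair — and
deliberately stress-tests the scorer with maximally heterogeneous column
entropies.  It does not emulate phylogenetic relatedness between
organisms, multi-state epistatic couplings, or gap structure.

Test conditions: 60 organisms, one or two paralogs per class, 20 + 20
columns, one planted pair at coupling strength 0.9, R = 50 realizations,
20 replicate seeds, with a negative control in which family-B organism
labels are shuffled (destroying the true partnerships but nothing else).
R = 50 rather than the production default 300 keeps 20 replicates with
controls inside a few minutes; with single paralogs the ensemble is
degenerate anyway, and with two paralogs per class 50 matchings already
sample the pairing space densely at this size.

## 3. Pre-processing rules

* **Gap filter**: a row is removed only when its gap fraction strictly
  exceeds the threshold (default 0.20) — "more than 20% gaps"; ties are
  retained.  Idempotent; may return an empty alignment.
* **Zinc-finger motif**: `CxxCxGxG`, counted over all (possibly
  overlapping) 8-residue windows of the *complete, unaligned* sequence.
  The literal C/G positions must match exactly (`X` does not satisfy
  them); wildcard positions accept anything.  Class A keeps ids with at
  least 2 motifs (the canonical zinc-finger region carries four, but
  glycine variants are tolerated by requiring only two); class B keeps ids
  with none; the rest are unassigned.  Thresholds are parameters.

## 4. Numerical and degenerate-input conventions

* PCA sign fixed by largest-magnitude loading; zero-variance input yields
  a one-column zero projection (explained fraction reported as 1).
* Dendrogram cut: merge when height ≤ cutoff; cluster labels contiguous
  from 0 in order of first appearance.
* `0 · log 0 = 0` in all entropies; `H` clipped at 0 against rounding.
* Percentile reference without interpolation; `k = max(1, floor(p·T/100))`.
* Empty selected set: zero frequencies, warning, no null model (σ
  undefined at m = 0).
* All stochastic operations (triplet sampling, matchings, generators) take
  explicit integer seeds; realization r of an ensemble uses
  `base_seed + r`.  Identical seeds give bit-identical outputs.

## 5. Known limitations

* The uniform-prior null for position selection ignores the combinatorial
  dependence between triplets sharing positions; its σ is optimistic,
  which is why the conservative 10σ call is the default headline.
* The mean-field scorer is a desk-scale substitute for pseudo-likelihood
  couplings by design choice; absolute score values are not comparable
  across alignments (hence the per-realization min-max normalization).
* Min-max normalization always maps some pair to 1, so every realization
  records at least one pair; significance comes from recurrence across
  matchings, not from a single realization.
* The synthetic generators are exchangeable across positions and across
  organisms; conclusions about tree-structured confounding cannot be drawn
  from them.
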