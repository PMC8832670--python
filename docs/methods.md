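# Methods

## Fragments and mirror extension

A candidate site is represented by residues at signed offsets −25…+25 around
a lysine (window length 51). When the protein is shorter than 25 residues on
one side, the missing offset −i is filled with the residue at +i (and vice
versa) — reflection across the central K. If some distance is missing on
*both* sides (protein shorter than flank+1 residues in total), the distance
is folded back into the covered range (sawtooth, boundary repeated) and the
same residue is written to both offsets, sourced from the side with more
real residues. This keeps the invariant residues[−i] = residues[+i] for
every mirrored pair under any truncation. Construction fails only when the
protein has fewer than two residues besides the site — there is then nothing
to reflect. Sequences must use the 20 standard one-letter symbols; records
with other characters are rejected at load rather than imputed. Site rows
pointing at a non-K residue are skipped with a warning so that noisy site
tables and whole-proteome scans both work; an unknown protein ID is a hard
error.

## Table compression

For a 2×m class-by-status table the chi-square is computed in the
positive-row form χ² = N²/(f⁺f⁻)[Σⱼ(f⁺ⱼ)²/fⱼ − (f⁺)²/N], which equals the
Pearson statistic; zero-total columns contribute nothing. Compression
repeatedly merges the pair of columns whose merge leaves the largest
chi-square (all pairs in unordered mode for residue tables, neighbors only
in adjacent mode for ordered numeric statuses). The merge is accepted only
if the local 2×2 Pearson test on the merged pair (1 df, no continuity
correction) has p ≥ α; otherwise the merge is undone and compression stops.

Numerical choices: α defaults to 0.05 everywhere (the level is a
convention, exposed in the config); ties between equally good merges go to
the lexicographically first pair; zero-total columns are merged first with
local p defined as 1 so empty statuses never block compression; a 2×2 table
with a zero row or column marginal has p = 1 (no evidence of difference).
The standard procedure floors at r = 2; inside the classifier's per-leaf
recompression the floor is 1, the final 2→1 merge still being gated by the
local test — this is what makes a feature "uninformative in a leaf" a
testable event rather than a special case. No Yates correction is used
anywhere, keeping the merge tests and the table statistic in the same
family.

## Key positions and the difference table

Key positions are offsets whose *compressed* table chi-square strictly
exceeds the mean over all 50 offsets; the window spans the outermost key
offsets and includes the central K (so the K frequency remains a usable
compositional feature). The difference table is built from the
*uncompressed* 2×20 tables: Δχ²ᵢⱼ is the chi-square with one extra count in
the (positive, j) cell minus the chi-square with one extra count in the
(negative, j) cell, with all marginals re-derived from the cells — the
increment changes f⁺, fⱼ and N, since they are sums. Scores are
antisymmetric under swapping the class rows, positive for residues enriched
in true sites. Test-time fragments are encoded with the training-set table;
it is frozen in the model file at full precision.

Compositional features are proportions, not counts: residue frequencies
normalized by window length, adjacent-pair frequencies by window length − 1.
Pairs are unordered (f_AR ≡ f_RA; 210 pairs), which halves the dimension and
densifies the matrix. Proportions keep features comparable across window
sizes and match the standard amino-acid-composition convention.

## ChiMIC

The dependence measure is implemented at contract level: rank-based axis
partitioning grown greedily, where a new boundary is accepted only if the
local chi-square test between the two sub-bins it creates (against the other
axis's bins) is significant at α. The score is the maximum over visited
grids of I(X;Y) normalized by the smaller axis-marginal entropy,
I / min(H(X_bins), H(Y_bins)). The entropy denominator (rather than
log₂ min(n_x, n_y)) is deliberate: it makes chimic(x, x) = 1 for *any*
variable with at least two distinct values, including unbalanced binary
features, which the redundancy-sharing step of feature selection relies on
(an exact duplicate must be fully redundant). For continuous variables the
two denominators agree at the equal-frequency grids the search visits, so
the independence background and functional scores are unchanged.

Axes with ≤ 4 distinct values keep one bin per value (a binary class label
is never re-binned); continuous axes start from an equal-frequency median
split, and candidate cuts are restricted to the central 80% of mass. The
restriction tames the multiple-testing inflation of maximally selected
splits on independent data — without it the background score for independent
pairs drifts upward; with it the mean at n = 100 sits near 0.07. The measure
is symmetrized by running the search in both axis orders and keeping the
better score, so symmetry is exact. Inputs shorter than 4 observations are
rejected; two constant inputs score 0 by convention.

## Chi-MIC-share selection

share(E) = Σᵢ∈E ChiMIC(Xᵢ;Y) / Σⱼ∈E ChiMIC(Xᵢ;Xⱼ), the self term fixed at 1.
The first feature is the relevance maximizer; each later step introduces the
candidate maximizing share(E), stopping when the score no longer increases,
and additionally — under forced termination, the default — when the relative
gain is ≤ 1%. The forced list is therefore a prefix of the natural list.
Ties break toward the lower column index. Pairwise redundancies are computed
lazily and cached (O(|Ω|·|S|) measure calls instead of the full |Ω|²
matrix). Note that forward selection evaluates single additions only: sets
like {relevant, duplicate, noise} can score marginally above the singleton
through the shared-denominator arithmetic, but no single addition does, so
greedy correctly stops — the per-step argmax, not a global subset optimum,
is the algorithm's contract.

## ChiDT

Retained features are discretized on their sorted distinct training values
by adjacent-mode compression. The first introduced feature is the gain-ratio
maximizer among features with at least average information gain (the
average rule uses ≥ so the pool is never empty when all gains are equal).
Each later candidate is recompressed within every current leaf; it is a
candidate if it keeps ≥ 2 bins somewhere, and its gain and intrinsic value
are sample-weighted sums over the leaves it actually splits — for the first
feature this reduces to the plain gain/IV definitions. The chosen feature
splits every leaf where it keeps ≥ 2 bins and leaves the others untouched,
producing variable-length conjunction rules. Leaves are never empty (empty
bins are absorbed during compression), so every training sample matches
exactly one rule and the rule counts conserve the class totals.

The decision table weights each rule's negative count by θ = total
positives / total negatives, so the weighted negative row sums back to the
positive total. A test sample is routed down the tree (bin edges are
midpoints between adjacent distinct training values, with the boundary bins
open to ±∞, so unseen values always route) and hypothetically added to its
rule first as a positive, then as a negative; the larger resulting
table chi-square wins. Ties — including the exact algebraic ties that
floating-point evaluation of the two row-symmetric tables can miss — go to
the negative (majority-prior) class via a relative tolerance of 1e-9.
Because the decision depends only on the matched rule, per-rule decisions
are precomputed at fit time. Weighted counts are kept at full precision
internally and rounded to 2 decimals only for display and the model file,
where they are recomputed from the raw counts on load.

## Synthetic data generator

The generator emulates the *structure* of succinylation benchmark data: 51-
residue fragments centered on K, a configurable positive:negative imbalance
defaulting to 1:10, and class-dependent residue biases at chosen offsets.
The positive class draws planted offsets from the background mixed with a
point mass on a target residue, calibrated so the total-variation distance
between class distributions equals the requested effect size exactly; all
other offsets are class-independent. The default background is uniform over
the 20 residues; a skewed option exercises zero-count columns in
compression. Defaults are 500 positives / 5000 negatives, signal at offsets
−2 and +1 with effect 0.5 — strong, clean positional signal at realistic
imbalance. What passing tests on this generator show is that the pipeline
recovers planted positional signal and classifies well under imbalance; they
do not show performance on real succinylation data, whose motifs are weaker,
correlated across positions, and homology-structured. The generator makes no
attempt at motif biology or evolutionary correlation.

## Problem sizes

The test suite trains on 200/2000 fragments (and smaller unit fixtures); the
acceptance script uses the generator defaults (500/5000 training, 250/2500
held out) and a 2000/20000 scan for key-position recovery. These sizes give
stable recovery and evaluation numbers while keeping a full run in the tens
of seconds.

## Known limitations

- ChiMIC internals follow the documented contract (local-test-gated growth,
  normalized MI), not a specific dynamic program; any measure satisfying the
  contract can be substituted via the `measure` hook in `select_features`.
- The decision chi-square uses the full 2×R balanced table. Comparing only
  the matched column pair is a plausible variant; it is not implemented.
- The classifier emits hard labels; there is no score calibration or ROC.
- Homology reduction of training data is out of scope; the generator does
  not model it.
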