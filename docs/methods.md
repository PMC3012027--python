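# Methods

## Problem and model

Given a protein multiple sequence alignment, a set of N candidate subgroups,
and an N×M hyperpartition over symbols {+, -, o}, the sampler jointly infers

* an assignment of every sequence to one subgroup row (including a designated
  *Rejected* row that absorbs pseudogene products and other aberrant
  sequences), and
* for each of the M categories (columns), a *pattern*: a set of alignment
  positions, each with a small residue set, that is conserved in the
  category's foreground subgroups and divergent in its background subgroups.

Each subgroup is anchored by a small seed alignment whose sequences are fixed
to that subgroup throughout sampling; all other sequences are free.

### Column evidence

For a category with foreground row set F and background row set B, a
candidate position is a column c and a residue set R (1–4 canonical amino
acids; gaps and 'X' are never members and always count as non-matches).
With redundancy weights w_i, the weighted match/non-match masses are

    mF = Σ_{i∈F, x_ic∈R} w_i,   uF = Σ_{i∈F, x_ic∉R} w_i,

and likewise mB, uB. The per-position evidence in nats is the beta-binomial
Bayes factor

    LLR(c, R) = lbb(mF, uF; aF, bF)
              + lbb(mB, uB; Aq, A(1−q))
              − lbb(mF+mB, uF+uB; Aq, A(1−q)),

with lbb(m, u; a, b) = ln B(a+m, b+u) − ln B(a, b). The foreground prior
Beta(aF=9, bF=1) encodes the expectation that a genuine pattern residue is
strongly conserved; the null Beta(Aq, A(1−q)) with concentration A = 20 is
matched to the residue set's probability q under the pooled weighted
composition of the whole input alignment (computed once; no external
database). The LLR is positive exactly when modeling foreground and
background separately beats a single pooled model — i.e. when the column
discriminates.

Two restrictions keep the selected patterns faithful to the notion of a
*foreground-conserved* pattern rather than a merely *different* column:

* **Direction.** A residue set is eligible only if its weighted foreground
  frequency exceeds its background frequency. Without this, a column in
  which some background subgroup is strongly conserved (a different
  category's signal) scores positive evidence with an anti-conserved
  foreground.
* **Set-choice prior.** Residue sets are chosen as the nested family
  {top1}, {top1, top2}, … by foreground frequency, and the selection
  objective is LLR − ln C(20, k) for a size-k set — the uniform Occam
  factor over same-size sets. Without it, simply picking the top-k
  foreground residues earns a spurious evidence bonus growing with k.
  Reported nats are the raw LLR of the winning set.

### Joint posterior

Each column enters a category's pattern independently with prior probability
ρ = 0.02, so a retained position contributes LLR − ln C(20,k) + ln(ρ/(1−ρ))
to the joint objective; free sequences carry a uniform assignment prior over
rows. With a ~200-column domain, ρ = 0.02 puts the prior expected pattern
size at a few positions, the scale typical of subfamily-diagnostic motifs;
the evidence term easily overrides it where signal exists (the inclusion
hurdle is ln((1−ρ)/ρ) ≈ 3.9 nats plus the set prior).

## Sampling

The sampler alternates:

1. **Assignment sweep.** Every non-seed sequence is detached from the
   per-category count caches and scored against every row; the score of a
   row is the *exact* change in the joint log-posterior from placing the
   sequence there (the Gibbs conditional — "probability proportional to the
   degree to which the change improves the model"). In greedy mode the
   argmax row wins, ties keeping the current row; in sample mode the row is
   drawn ∝ exp(score/T) with T annealed geometrically (2.0 × 0.98^sweep)
   toward greedy, which mitigates the multimodality of the joint posterior.
2. **Pattern sweep.** For every category and column the best eligible
   nested residue set is derived from the current weighted counts; the
   incumbent set of a retained column competes with the re-derived one, so
   in greedy mode each per-column decision is an exact conditional
   maximization. A category whose pattern comes out empty is reported as
   rejected, not an error.

Because every greedy move maximizes a conditional of the same objective,
the greedy log-posterior is non-decreasing by construction; this is asserted
per sweep in the tests. Convergence is declared after 3 consecutive sweeps
with no reassignment and no pattern change (cap 500 sweeps); the
best-scoring state visited is returned. All randomness flows from a single
integer seed through one `numpy` generator, so trajectories are
bit-reproducible.

**Initialization.** Each free sequence starts in the row whose seed
alignment contains its highest-identity seed; a tie between rows — including
identity zero everywhere — starts it in Rejected. The initial patterns are
one greedy pattern sweep from that assignment.

**Membership probabilities** are the softmax over rows of the per-row exact
scores, computed with the sequence held out of the counts.

## Hyperpartition

A rooted, labeled tree maps to a hyperpartition with one row and one column
per node: row i is '+' in column j if node i lies in j's subtree, '-' if in
a sibling subtree, 'o' otherwise; internal-node rows are *miscellaneous*
subgroups (clade members claimed by no leaf). The appended Rejected row is
background in the root's column — the root category contrasts the whole
family against the random-sequence sink, which is what gives the model its
rejection mechanism — and omitted elsewhere. Validity rules: every
non-rejected row has a foreground cell; no two rows share a foreground
signature; M ≥ N excluding the rejected row; every category has both a
foreground and a background row; the rejected row has no foreground cell.

## Preprocessing

Fragments (fewer than 100 non-gap residues, or under 50% column coverage —
the coverage rule is this package's operational definition of "fragment"
and is configurable) and near-identical sequences (>98% identity over
jointly non-gap columns, greedy first-seen-kept in input order) are removed.
Survivors are down-weighted with Henikoff position-based weights (gap counts
as a symbol type, as in PSI-BLAST), rescaled to mean 1.

## Synthetic data

The generator plants, per category, a set of columns with residue sets at
which foreground subgroups match with probability pF = 0.9 and background
subgroups with pB = 0.1 (omitted subgroups at the participant-weighted
pooled rate); all other columns are drawn from a uniform background
composition. The non-conserved branch draws from the composition restricted
to non-set residues, so realized set frequencies are exactly pF/pB in
expectation. Decoys are pure-composition sequences; the first three members
of each subgroup form its seed alignment. The standard recovery fixture is
3 subgroups × 100 sequences + 30 decoys on 200 columns with 10 planted
columns per category under a one-vs-rest hyperpartition.

The generator deliberately omits indels, rate variation, and within-subgroup
phylogenetic correlation. Passing recovery tests therefore demonstrates
correct inference under the model's own data-generating assumptions — not
robustness to alignment error or deep paralogy on real families.

## Numerical choices and edge cases

* Weighted-count differences are clamped at zero when float cancellation
  produces values in (−1e-6, 0); a genuinely negative mass raises.
* q is clipped to [1e-9, 1−1e-9].
* Ties break deterministically everywhere: assignments keep the current
  row; residue sets prefer the alphabetically earlier residue and the
  smaller set; displayed columns prefer lower indices.
* An all-gap foreground column yields no candidate; a category with an
  empty foreground after initialization is an error (its contrast is
  undefined), while an empty *pattern* is a rejected category.
* The frequency digit is floor(10f) clamped to 9 so f = 1.0 still occupies
  one character; histogram bars are a per-category linear rescale of nats
  to 1–10 (rendered ' ', '1'–'9', '!') — a relative display, while the
  pattern-info TSV carries the quantitative nats.

## Known limitations

* The identity purge is O(n²) in the worst case; fine at desk scale, slow
  beyond ~10⁴ sequences.
* Consensus seeds are supported only as rows of the main alignment (seed
  ids must occur in it).
* The model contrasts the foreground against both the background partition
  and the pooled sequences through a single three-part Bayes factor; the
  choice is isolated in `column_llr` and can be swapped without touching
  the sampler.
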