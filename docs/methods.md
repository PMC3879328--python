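# Methods

## Model

The error process is described by a surface P_error(pos, R): the probability
that a base sequenced as r1 at 1-based cycle `pos` is called as r2, for each
of the 12 directed substitutions R = r1→r2. The two indices are deliberately
not factorised — P_error(pos, R) is *not* constrained to equal
P_error(pos)·P_error(R) — because the dominant Illumina error mechanisms
interact: crosstalk (G↔T, A↔C dye-spectrum overlap) is roughly uniform along
the read, phasing/dephasing grows toward the read end, and T-fluorophore
carry-over inflates late-cycle miscalls into T specifically. Along the read
each substitution is summarised by A·e^(b·pos) over positions 2–24, the
functional form expected from phasing accumulation; negative b is allowed
(observed on HiSeq chemistry, where some rates fall along the read). The
position-1 rate is kept as a raw estimate, outside the exponential: first
cycles are systematically elevated for reasons (longer handling time at run
start) unrelated to phasing.

Estimation assumes that in a sufficiently deep library, the most abundant
sequence of a connected distance-1 subgraph (the *parent*) is the error-free
source of its neighbours, and that subgraphs whose parent holds a large
fraction of the subgraph's reads are essentially error-only. Per-graph
estimates use the error odds: if a parent is read a_parent times and a
specific single-substitution child a_child times, the per-read miscall
probability estimate is P̂ = a_child/(a_child + a_parent) — the unique
definition consistent with the prediction
N_error = P/(1−P)·N_correct used at correction time. Subgraphs whose parent
has no child at a cell contribute an explicit zero estimate there with the
same weight; without these, the "weighted average" would be a mean over
positives and systematically overestimate small rates.

## Estimation pipeline and numerical choices

- **Selection**: subgraphs with ≥ `min_subgraph_nodes` (default 40) nodes and
  parental abundance ratio a_parent/a_total ≥ t/100, with
  t ∈ {90, 85, 80, 75, 70, 30} consumed in descending order. 40 nodes is the
  regime in which a deep parent has sampled most of its 3L neighbours; the
  threshold list's irregular gap (70 … 30) is kept as given. Cells missing at
  a high threshold are filled from the next lower one (provenance recorded);
  cells missing everywhere are left to the fitted curve.
- **CI pruning**: per cell, a per-graph estimate is discarded when it exceeds
  ppf(0.975; n = a_parent, p = pooled rate)/n, the upper limit of the
  two-sided 95% binomial quantile interval, computed exactly
  (`scipy.stats.binom.ppf`) because the rates sit deep in the small-p regime
  where the normal approximation fails. The average is recomputed **once**
  from the survivors, not iterated to convergence. Note the exact quantile
  can be 0 when n·p is very small, in which case positive estimates from
  small graphs are dropped; the pooled value is dominated by large graphs,
  so the effect on the recomputed average is marginal.
- **Smoothing**: one left-to-right pass per substitution; a value exceeding
  `smoothing_factor` (default 2.0) times the mean of its two nearest
  neighbouring positions is replaced by that mean, already-smoothed left
  neighbours feeding later comparisons, single-neighbour rule at the ends.
  This targets cells whose abundance excess comes from biological variants
  at positions with no true errors — such cells produce one *consistent*
  inflated value, which interval pruning (an outlier test across graphs)
  cannot catch. Position 1 is excluded both as target and neighbour: its
  elevation is a platform feature, and clamping it to ~2× the position-2
  rate would destroy exactly the quantity the model reports raw.
- **Fit**: linear least squares on log(rate) vs position over the strictly
  positive cells in [2, 24]. Deterministic, initialisation-free, and exact
  on noiseless exponentials; zero cells are excluded (no information about
  the scale of an exponential). A substitution with no positive cell
  degrades to the flat-zero profile; a single positive cell raises
  `InsufficientDataError` rather than inventing a slope.
- **Ties and determinism**: parent ties break to the lexicographically
  smallest sequence; output tables sort by descending abundance then
  sequence; subgraph-size bins are 1, 2–19, 20–39, ≥40 (the bins must
  partition, so boundary sizes go to the higher bin at 20 and 40). Empty
  tables, empty graphs and empty selections are valid everywhere and
  propagate as gaps rather than errors.

## Correction

Classification is an exact one-sided binomial test with null "the sequence
is a sequencing error": observed child abundance k against
X ~ B(n = a_ref + k, P_error(pos, R)), p-value P(X ≥ k), rejection at
`alpha` (default 0.05) declaring a biological variant. An exact test was
chosen over the Z-approximation because expected error counts are routinely
below 5, exactly where the approximation is worst. Each subgraph is walked
breadth-first from its parent; every node is tested against its most
abundant already-classified neighbour, so sequences two or more
substitutions from the parent are handled through the chain, and a rejected
null re-roots its own descendants. Error abundances are merged into the
reference sequence by default (total abundance is conserved and asserted;
`merge=False` discards instead), and every merge is logged. No multiplicity
correction is applied by default — each child is its own hypothesis — which
keeps the per-child false-"biological" rate at ≤ alpha. Homopolymer removal
(run of one base ≥ `min_tract`, default 15 on 20–24-mers; values < 5
rejected) happens strictly last.

## Simulator

`simulate_dataset` emulates a deeply sequenced small-RNA library: `n_parents`
(default 2000) random parent sequences of lengths 20–24 with pairwise
Hamming distance ≥ 3 within a length, abundances log-uniform on
[20, 2×10⁵] (heavy-tailed, like real expression ranges; ≈4×10⁷ reads at the
defaults), and per-copy, per-position categorical errors with the
generating model's probabilities (default: the Illumina GA-style profile
shipped in `illumina_ga_lane2_model`). Cell error counts are drawn
multinomially per position — marginally binomial, as an error process of
independent per-read miscalls implies — and assigned to uniformly drawn
copy indices, with at most one substitution per copy and position
(duplicate draws within a position are collapsed, deflating rates by
~p/2 ≲ 0.3%, far below estimation noise). A copy can accumulate errors at
several positions, so the deeper graph levels the corrector must handle
arise naturally. Output is deterministic given the seed.

The ≥3 parent spacing guarantees unambiguous truth labels (no error child
of one parent can collide with another parent or its children), which real
libraries do not guarantee. The simulator also omits true biological
variants inside subgraphs, quality scores, indels, adapter read-through and
lane/flowcell spatial effects. Two consequences for interpreting results:
recovered-parameter accuracy reflects sampling noise plus the pipeline's own
estimator biases only, and *sensitivity on simulated data is structurally
1.0* — the only truth-correct sequences are subgraph parents, which the
corrector never merges. Specificity is the informative number (~0.92 by
reads at the defaults; the residual misses are mostly singleton multi-error
reads tested against low-abundance intermediate references). Passing these
tests shows the estimator and corrector are self-consistent at realistic
depth, not that real libraries meet the parent-dominance assumption.

## Evaluation

Sensitivity = fraction of correct reads retained; specificity = fraction of
erroneous reads identified — both over read counts by default (per unique
sequence as an option). Reference-based truth for control libraries calls a
sequence correct iff some equal-length window of the reference (both
strands; circular extension, since small control genomes usually are
circular) matches it exactly; sequences beyond the mismatch cap (default 3)
form a ">3" class excluded from rate denominators unless requested,
mirroring how capped mappers truncate such tables.

## Problem sizes

Tests and `scripts/acceptance.py` use the defaults above (2000 parents,
≈4×10⁷ reads, ≈10⁵ unique sequences); the full simulate→fit→correct→score
cycle takes well under a minute on one CPU, and graph construction scales
linearly in unique sequences × length. Parameter-recovery checks apply the
factor-2 criterion only to cells with ≥ 50 expected error events;
undersampled cells are reported but not asserted on, since their relative
error is unbounded by design.

## Known limitations

Errors introduced before cluster formation (reverse transcription, library
amplification) lack an abundant parent and are invisible to the model. The
exponential form is only trusted to position 24; longer reads would need a
second rising component or splines. Sequence-context effects (e.g. GGC
motifs) and within-lane spatial variation are not modelled. The exact
adapter-trimming overlap/mismatch schedule of upstream small-RNA pipelines
varies; the schedule here is configurable (default: overlap ≥ 6, mismatches
≤ ⌊overlap/10⌋) rather than canonical.
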