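# Methods

## Problem setting

Given protein sequences labeled positive (e.g. CDK-inhibitor-like) or
negative, learn a scoring function whose thresholded value discriminates
the classes, and evaluate it by leave-one-out cross-validation (LOO CV)
with a threshold scan. The positive class of interest is small and
sequence-diverse, so alignment-free compositional and profile-based
encodings are used rather than similarity search.

## Encodings

All encoders index residues alphabetically (A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,
S,T,V,W,Y) and ordered pairs as `20*idx(a)+idx(b)`. Any consistent order
works; this one is frozen so that feature columns, sparse export indices
and saved models are stable.

- **AAC** (20-d): `count(a)/N`. Sums to 1.
- **SAAC** (60-d): the sequence is split into three contiguous parts of
  lengths `floor(N/3), floor(N/3), N-2*floor(N/3)` (remainder to the final
  part — a deterministic reading of "three equal parts" needed for
  reproducibility), and AAC is computed per part. Each 20-block sums to 1.
  Requires N ≥ 3.
- **DPC** (400-d): adjacent ordered pairs divided by `N-1`, the number of
  adjacent pair occurrences. The denominator keeps the vector on the
  simplex; the alternative reading (dividing by the 400 possible pair
  types) would only rescale by a constant. Requires N ≥ 2.
- **Gapped dipeptides** (400-d): pairs `(p, p+gap+1)` divided by
  `N-gap-1`; gap=1 is the canonical one-gap ("2-gram") encoding and gap=0
  reproduces DPC exactly.
- **PSSM-400** (400-d): from an N×20 integer log-odds profile, each score
  is normalized with the logistic g(x) = 1/(1+exp(−x)) (monotone, g(0)=0.5,
  range (0,1)), then for each query-residue type a and substitution column
  b the normalized scores over positions carrying a are **summed and
  divided by N**. The aggregation statistic is a design choice: the
  length-normalized sum keeps vectors from proteins of different lengths
  comparable and degrades gracefully for residue types with few positions
  (absent types contribute a zero block). Plain `sum` and
  `mean-per-residue` are available via the `aggregate` switch but are not
  default.

No feature scaling is applied beyond these definitions; all compositional
values are already fractions in [0,1].

### PSSM input

Profiles are consumed as PSI-BLAST ASCII files (`-out_ascii_pssm` layout).
Only the first block of 20 log-odds columns is used — the logistic
normalization over signed x is only meaningful for log-odds, not for the
percentage block. File columns (order A R N D C Q E G H I L K M F P S T W
Y V) are remapped to the alphabetical order on parse. Scores outside ±20
are treated as parse corruption. Profile rows whose query residue is not a
canonical amino acid are excluded before aggregation, so profiles computed
on unsanitized sequences still align. Producing profiles (typically 3
PSI-BLAST iterations at E-value 0.001 against a curated database) is out
of scope; a synthetic profile generator (`self_score` on the query residue
column, `off_score` elsewhere, seeded integer Gaussian noise, clamped to
the parser band) stands in for pipeline testing.

## Classifiers

**SVM.** C-support-vector classification with the RBF kernel
exp(−γ‖u−v‖²), via scikit-learn; the optimizer is not part of this
package's contribution. Decision-function values are used raw (no Platt
scaling), matching margin-score semantics; near the margin they span
roughly [−1, 1]. Defaults: C = 1; γ = 1/(d·Var(X)) ("scale"). The
variance-scaled default matters: compositional vectors sit on the simplex
with pairwise squared distances of order 10⁻³–10⁻², so a width like 1/d
leaves the kernel nearly constant and compresses all decision scores into
a band much narrower than the 0.1 threshold-scan step — the class
separation survives in the score ordering (AUC) but becomes invisible to
the fixed grid. γ='auto' (1/d) and explicit floats remain available, and a
configured C = 0 is mapped to the backend default C = 1 (C = 0 is
degenerate for C-SVC). Decision-score *scales* are backend-specific, so
thresholds quoted for one SVM implementation do not transfer bit-for-bit
to another; the scan output reports the full table so users can see the
dependence.

**ANN.** A fully-connected net with one hidden layer; per-layer
activations are 'linear' or 'logistic' (input activation applied to the
features, e.g. the classic 20–12–1 topology uses linear input and logistic
hidden/output). Training is online (per-pattern, dataset order, no
shuffling) vanilla backpropagation against targets 1/0, learning rate 0.1
by default, weights initialized uniformly in [−0.5, 0.5] from an explicit
seed. After every cycle the training SSE is recorded; the returned model
is the weight snapshot with **minimal SSE**, so the cycle budget
(`max_cycles`) is an upper bound, not the stopping rule. Non-finite SSE
aborts with the offending cycle named. Everything is deterministic given
(data, config, seed).

Class imbalance is not reweighted by default (a `class_weight="balanced"`
flag exists, off by default).

## Evaluation protocol

- **LOO CV**: encodings are computed once per sequence (they depend only
  on that sequence, so there is no across-fold leakage); n models are
  trained on n−1 samples; the held-out decision score is recorded per
  sequence. For the ANN, the fold index offsets the weight seed so the
  whole CV is one deterministic function of the base seed. A fold whose
  training split would be single-class is an error.
- **Threshold scan**: Th from −1.0 to 1.0 in steps of 0.1 (21 points),
  label rule `score >= Th`, one full metric report per threshold.
- **Metrics**: SN, SP, ACC as percentages; MCC in [−1,1]; PPV in [0,1].
  All values are kept at full precision internally; rounding is display
  only. A zero MCC denominator yields MCC=0 with a degeneracy flag; PPV
  with TP+FP=0 is flagged undefined rather than NaN.
- **Operating point**: maximal accuracy, ties broken toward minimal
  |SN−SP| (preferring balanced errors), remaining ties toward the lower
  threshold.
- **ROC/AUC**: computed on the held-out LOO scores (the defensible choice
  when a single score set must serve; training-set ROC would be
  optimistic). One step per distinct score value; AUC by the trapezoidal
  rule, equal to the Mann-Whitney U statistic divided by n₊·n₋.

Note the scanned operating point is selected on the same held-out scores
it is reported on; the full scan table is always emitted alongside the
selected row so this selection dependence is visible.

## Synthetic data generator

Emulates the statistical structure the classifiers consume: two classes
distinguishable by residue composition. Sequences are i.i.d. draws from a
class-specific residue distribution; lengths uniform in `length_range`.
The negative class uses a fixed background (average database residue
frequencies); the positive class multiplies the frequencies of the frozen
subset {E, K, P, R} by `(1 + effect·1.5)` and renormalizes. Defaults:
n_pos = 56, n_neg = 300 (the class sizes of the motivating study design),
lengths 50–300 (typical small-protein range), effect = 0.9, seed = 42.
With the 1.5 gain, effect = 1 means a 2.5-fold pre-normalization
enrichment — strong but not degenerate — and effect = 0 is an exact null
(identical class distributions, LOO AUC ≈ 0.5). Matched synthetic PSSM
profiles are seeded per-sequence from the spec seed.

What the generator does **not** emulate: real positional structure
(domains, repeats, disorder), length/class correlations, phylogenetic
relatedness between sequences, or realistic PSI-BLAST profile noise.
Passing recovery tests therefore demonstrates that the pipeline is
correct and sensitive to a compositional signal of known size — not that
any particular accuracy will be achieved on real protein classes.

## Problem sizes used in checks

Library self-checks run LOO CV at the full 56/300 design for the headline
recovery numbers and at 20–75-sequence fixtures for structural properties;
oracle-equivalence suites use 1,000 random sequences of length 10–60 and
100 synthetic profiles, sizes at which the naive pure-Python counting
oracles remain fast while exercising all code paths.

## Known limitations

- SVM decision-score scale (and therefore any fixed threshold grid) is
  backend-dependent; only the score ordering (AUC) is portable.
- LOO CV retrains n models; for the ANN at realistic cycle counts this is
  slow, and no warm-start is attempted.
- Only LOO is provided (no k-fold), and no confidence intervals or
  classifier-comparison tests are computed — the protocol reports point
  metrics.
- Handling of non-standard residues (B, Z, J, X, U, O) is a policy choice
  (drop-with-warning by default, strict reject available); there is no
  single field convention.
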