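# Methods

## The grammar

Secondary structures are modeled as dot-bracket words over `{ ( , ) , . }`
generated by an unambiguous context-free grammar with nonterminals
`S T C A P L F H G B M O N U Z` and 29 labeled productions. The
decomposition mirrors the standard loop taxonomy:

| symbols | role |
|---|---|
| `S → T`, `T → C \| A \| CA \| AT \| CAT` | exterior loop as an alternating run/helix sequence |
| `C → ZC \| Z` | unpaired strands in the exterior loop |
| `A → (^{m_s} L )^{m_s}` | helix start: `m_s` stacked pairs at once |
| `P → ( L )`, `L → P` | helix extension, one pair at a time |
| `L → F \| G \| M` | the loop closed by a helix |
| `F → Z^{m_h−1} H`, `H → ZH \| Z` | hairpin loop (≥ `m_h` unpaired bases) |
| `G → BA \| AB \| BAB`, `B → ZB \| Z` | bulge (one run) / interior loop (two runs) |
| `M → UAO`, `O → UAN`, `N → UAN \| U`, `U → ZU \| ε` | multiloop with ≥ 2 helices and possibly empty strands |
| `Z → ∘` | one unpaired base |

Two printed-form ambiguities had to be resolved when transcribing the rule
set: the helix rules appear without their bracket terminals in the journal
rendering (which would leave the grammar unable to emit brackets and
non-terminating through the `L → P → L` cycle). The only reading consistent
with the rule annotations ("initiate helix", "extend helix") and with the
grammar generating exactly the dot-bracket words is the one above:
`A → (^{m_s} L )^{m_s}` and `P → ( L )`. The hairpin rule keeps its leading
symbols as the *nonterminal* `Z` repeated `m_h − 1` times (as printed), so
all unpaired-base emission stays attached to `Z → ∘`; for `m_h = 1` — the
only setting exercised by the experiments here — the distinction is vacuous.

Unambiguity makes parsing trivial: the unique leftmost derivation of a
structure is computed in linear time by structural recursion (maximal
paired components vs. unpaired runs at each level), not by a chart parser.
Parsing also enforces the structural minima: every hairpin must enclose at
least `m_h` unpaired bases and every helix must contain at least `m_s`
stacked pairs, with violations reported at the offending position.

### Parameters

A `ParamSet` holds one probability simplex per premise (transition
probabilities), a 4-point simplex over unpaired bases, and a 16-point
simplex over ordered base pairs. The joint probability of a
(structure, sequence) pair is the product of the transition probabilities
along the unique derivation times the emissions of all terminals (pairs are
emitted by the helix rules — the `m_s` outermost pairs of `A` each emit
independently — and unpaired bases by `Z → ∘`).

In the **length-dependent** variant (LSCFG) a transition probability is
conditioned on the length of the terminal subword its application derives:
`Pr_tr(rule, len)`. Training bins rule counts by that length; a
(rule, length) combination never seen in training has probability 0 — this
is what concentrates the length-dependent ensemble — with an optional
`fallback_to_plain` switch (off by default) to substitute the
length-independent estimate. Length dependence is implemented for
transitions only; emissions use the plain 4- and 16-point simplexes in
both variants.

Training is pure relative-frequency counting over parsed derivations and is
deterministic and corpus-order-independent. Premises never used by a corpus
receive a uniform distribution over their alternatives so the simplex
invariants hold exactly.

## Inside/outside computation

`α_X(i,j)` and `β_X(i,j)` are filled by a span dynamic program over a
binarized form of the grammar: the five three-nonterminal rules route
through four probability-1 helper symbols (`h_AT`, `h_AB`, `h_AO`, `h_AN`),
giving the standard O(n³) time / O(n²) memory contract. The helpers receive
chart values but are excluded from parameters, disturbance and reports.
This chart formulation is an equivalent replacement for an Earley-style
parser: it computes the same quantities at the same asymptotic cost.

Coordinates are 1-based inclusive `(i, j)`; the empty span is encoded
`(i, i−1)` and is populated only for the ε-capable symbols `U` and `N`
(`N` derives ε through `N → U → ε`).

Probabilities are kept in **linear space**, because the disturbance model
is defined on raw chart entries. Joint probabilities underflow for
sequences beyond a few hundred nucleotides; the intended input scale
(tRNA ~76 nt, 5S rRNA ~120 nt) is far from that limit, and no scaling or
log-sum machinery is provided.

An exponential-time enumeration oracle (`enumerate_structures`, capped at
n = 14 by default) generates every structure satisfying the grammar's
constraints and scores it by its derivation product. It is the independent
reference all charts and the sampler are tested against: inside totals
agree with enumeration sums to relative 1e−12, and inside–outside pair
probabilities agree with enumeration-weighted pair frequencies to 1e−10.

## Sampling

A draw proceeds top-down with a predetermined order: exterior-loop
decisions (`T`), then each paired substructure recursively (`A` places its
pairs, `L` chooses the loop type, `G`/`M`/`O`/`N` place split points). At a
context `(X, i, j)` the options are all alternative rules of `X` with all
structurally possible split-point assignments; an option's weight is
`Pr_tr · Π(child chart values) · Π(emissions)`, and the draw uses the
weights normalized by their sum (`norm_α`). For three-nonterminal rules
both split points are enumerated *jointly* at decision time rather than
sequentially through the helper charts — helpers are computed before any
disturbance, and routing decisions through them would silently mix exact
and disturbed mass.

Outside factors are omitted: for any reachable context, `β_X(i,j)` is a
common positive factor of every option weight and cancels under
normalization. `build_choice_set(..., outside=...)` multiplies it back in;
a test confirms the normalized distributions are identical.

Symbols with forced derivations on a fixed span (`C H B U` runs, `F`, and
`A`/`P` once their span is fixed) are emitted deterministically; their
chart values still enter the split-point weights of enclosing decisions,
which is why they belong to the disturbable symbol set.

### The modified (dead-end-tolerant) strategy

With an exact chart every drawn option is feasible (a positive weight
requires positive child chart values, and the chart value of `L` — which
guards every pair placement and is never disturbed — certifies the
interior). With a disturbed chart the sampler can draw structurally
impossible options. The strategy never backtracks; at the smallest
enclosing decision it settles for what could be formed:

* a helix that cannot be placed leaves its fragment unpaired;
* a loop whose decision dead-ends becomes a hairpin (its enclosing pairs
  are already placed and their interior is certified);
* a multiloop that completes only one helix degrades to a
  bulge/interior-like loop.

Every fallback is recorded as `(span, intended, realized)`. Because pairs
are only ever emitted with a certified interior, the output is *always* a
valid structure — it even parses under the grammar — and with an exact
chart no fallback can occur (property-tested over large draw counts).

Equal option weights need no tie-break: the draw inverts the cumulative
distribution with a fixed option order, so sampling is bit-reproducible
given the generator state. Choice sets are cached per chart, so repeated
draws cost only the random decisions (O(n²) worst case per draw).

## Disturbances

Given an exact chart, `disturb` applies one independent error draw per
gated entry in a fixed order (symbols in the order
`T C A P F G B M O N U`, then i, then j) and clamps the result to [0, 1]:

* `mep(prob)` — uniform on `[−prob·α, +prob·α]` (bounded relative error);
* `fep(prob)` — `±prob·α` with probability ½ each (worst-case relative);
* `mev(prob)` — uniform on `[−prob, +prob]` (bounded absolute error);
* `fev(prob)` — `±prob` with probability ½ each (worst-case absolute).

Gating is by symbol subset (any subset of the eleven sampling symbols;
`S L H Z` and the helpers are never disturbed — `Z`/`H` have forced
derivations on fixed spans, and `S`/`L` decisions are expressed entirely
through the sampling symbols' values) and by a span-length window: `op='+'`
disturbs spans longer than `win`, `op='−'` spans of length at most `win`.
Empty-span entries of `U` and `N` participate with span length 0. The
ungated "all lengths" variant is `win=0, op='+'`; note the printed sentinel
forms (`win=n, op='+'` / `win=−1, op='−'`) would gate no entry at all under
the strict window inequalities, so the constructor implements the declared
meaning rather than the printed sentinels.

Relative errors vanish at exact zeros, so the disturbed chart has exactly
the exact chart's support and only the *magnitudes* of the sampling
probabilities shift — the same structures remain possible. Absolute errors
create and destroy support, which is what makes them destructive;
`count_relevant` tabulates the nonzero entries (exact-only /
disturbed-only / both) for inside values and for choice-set options.

Disturbances apply post hoc to the stored chart: skewing `α_F` does not
recompute `α_A` from it, matching the model of corrupting a precomputed
table rather than the recursion.

## Predictions and evaluation

* **MP** maximizes the exact model probability over the distinct sampled
  candidates (ties: lexicographically smaller string). It always uses the
  undisturbed parameters — a derivation's probability depends only on the
  grammar parameters — which is why MP is the principle most resistant to
  disturbance.
* **MF** maximizes multiplicity (ties: exact probability, then
  lexicographic).
* **γ-MEA** maximizes `Σ_unpaired q_i + 2γ Σ_paired p_ij` over all
  non-crossing structures by a Nussinov-style dynamic program with
  traceback, where `p`/`q` are the observed sample frequencies. The factor
  2 on the pair term only reparameterizes γ; γ = 1 is the neutral default.
* **γ-centroid** maximizes `Σ_paired ((γ+1)·p_ij − 1)` with the same DP;
  equivalently it selects the pairs with `p_ij > 1/(γ+1)`, which at γ = 1
  is exactly the >50% consensus (such pairs are mutually non-crossing
  automatically). DP ties prefer fewer pairs, then leaving the leftmost
  position unpaired, so tracebacks are deterministic.

MEA/centroid outputs are ensemble summaries, not derivations: they enforce
balance, non-crossing and hairpins of at least one base, but not the
grammar's `m_s`/`m_h` minima.

Accuracy is measured per record as sensitivity `TP/(TP+FN)` and PPV
`TP/(TP+FP)` on base-pair sets. When a denominator is zero the measure is
reported as 1 if the comparison set is empty too, else 0, with a flag
(`*_defined = False`). ROC curves evaluate γ-MEA or γ-centroid on the
25-point grid `{1.25^k : −12 ≤ k ≤ −1} ∪ {2^k : 0 ≤ k ≤ 12}`; per γ the
mean sensitivity and mean PPV across records give one point, points are
sorted by PPV, extended to PPV 0 and 1 by constant continuation, and
integrated trapezoidally (averaging per-record AUCs instead is available
behind a flag).

**Abstract shapes** follow the standard five-level hierarchy: level 1 has
one bracket pair per maximal helix and `_` for every maximal unpaired run;
level 2 keeps `_` only in helix-interrupting (bulge/interior) loops; level
3 drops all `_`; level 4 merges helices separated only by bulges (runs on
one side); level 5 merges every single-helix interruption, leaving the
pure helix nesting pattern. A pair-free structure is `_` at every level
≥ 1. Each level is a function of the level-1 helix tree, so agreement at a
level propagates to all coarser levels. Quality statistics over a dataset:
CSP_freq (prediction has the reference shape), CSO_freq (reference shape
occurs in the sample), CS_num (mean occurrences of the reference shape per
sample), DS_num (mean distinct shapes per sample), each at levels 0–5.

**Loop profiles** report, per position, the sample frequency of being
unpaired within each loop type (hairpin, bulge/interior, multiloop,
exterior); the four frequencies sum to the position's unpaired frequency.
Sampler annotations are used directly; plain structures are re-annotated
through their unique derivation (both routes agree exactly).

**Cross-validation** partitions a corpus into k seeded folds of sizes
differing by at most one, trains on k−1 folds, and samples/predicts/scores
each held-out record, optionally under a disturbance whose per-record seed
is derived from the disturbance-spec seed and the record index. All
randomness flows
from explicit seeds; identical configurations reproduce identical outputs
byte for byte.

## Synthetic data

The grammar is its own generator: a derivation is expanded from `S` using
the transition probabilities (length-independent ones — lengths are not
known before expansion), then bases are emitted per the model's
factorization (unpaired i.i.d. from the 4-simplex, pairs jointly from the
16-simplex). Expansion aborts and redraws if the word exceeds 10× the
window maximum, guarding against rare runaway expansions; corpora are
completed by rejection sampling on a length window with a configurable
attempt budget.

The default generator parameters are hand-set to yield RNA-like ensembles:
helices of ~3.5 stacked pairs on average (`L → P` at 0.72), hairpin loops
of ~4 bases, sparse multiloops (`L → M` at 0.05) with a mean of ~2.5
branches, Watson–Crick-dominated pairing (CG/GC 0.46, AU/UA 0.32, GU/UG
0.16 total) — and a subcritical branching process, so lengths are finite
with tRNA-scale windows comfortably reachable. What the generator does
**not** emulate: real covariation, sequence motifs, loop-length
distributions of specific families, or any thermodynamic signal. Passing
tests therefore certify the *machinery* (charts, sampling distributions,
metrics) on a model-consistent world; they say nothing about predictive
accuracy on biological RNA, which depends on the training corpus.

A note on the parameter-recovery experiment: rejection on a narrow length
window conditions the corpus on length, so maximum likelihood converges to
*length-conditioned* transition probabilities, not the generator's
(empirically a 0.03 shift on the multiloop-branching rules under a tight
window). The recovery experiment therefore uses an effectively
unconstrained window, making the corpus an unconditioned model draw; with
5000 records all transitions are recovered within ±0.006.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for a desk-scale run: oracle
comparisons at n ≤ 10–14 (exhaustive enumeration), distributional sampler
checks at n = 8 with 10⁵ draws (total-variation ≤ 0.01), and the
disturbance-ordering experiment on a 100-record corpus of 50–70-nt
records with 10-fold cross-validation and 200 draws per record. Simplex
invariants hold to 1e−12; choice-set normalization to 1e−9; chart dumps
and parameter files serialize at full double precision (17 significant
digits, beyond the 12 the formats promise).

Known limitations: linear-space probabilities (no inputs beyond a few
hundred nt), no pseudoknots, no alternative grammar designs, generative
training only (no discriminative/conditional estimation), and the
backtracking repair variant of the sampler is deliberately not implemented
— the fallback strategy is the simpler, always-terminating choice.
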