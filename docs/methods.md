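# Methods

`mandarin_rc` simulates word-by-word processing difficulty for Mandarin
relative-clause (RC) sentences with a simple recurrent network (SRN) trained
on next-word prediction, and scores the network against exact
grammar-derived expectations with the Grammatical Prediction Error (GPE)
metric. This note documents the generative model, the network, the metric,
the experiment design, the numerical choices, and the known limitations —
including where the simulation's behaviour does and does not track the
reading-time phenomena it is meant to illuminate.

## The sentence grammar

Sentences are generated by a probabilistic finite-state grammar over six
grammatical categories mapped onto 28 localist units: animate nouns
(`aniN1..7`, units 0–6), inanimate nouns (`inaN1..7`, units 7–13),
transitive verbs (`VT1..6`, units 14–19), intransitive verbs (`VI1..6`,
units 20–25), the relativizer `DE` (unit 26) and the end-of-sentence marker
`EOS` (unit 27). The unit ordering is a package convention chosen so that
corpora and checkpoints are bit-stable.

Productions and their probabilities (all corpus-derived transitional
statistics, fixed as `GrammarSpec` defaults):

* `S → subNP VP` (0.7) / `VP` (0.3) — 30 % of sentences are pro-drop;
* `VP → VI` (0.21) / `VT objNP` (0.79);
* `subNP → aniN` (0.5) / `inaN` (0.34) / subject RC (0.16);
* `objNP → aniN` (0.18) / `inaN` (0.73) / object RC (0.09);
* RC type given position — subject: intransitive SRC 0.11, transitive SRC
  0.58, ORC 0.31; object: 0.26 / 0.47 / 0.27;
* embedded-noun and head-noun animacy conditioned on RC type and position,
  e.g. a subject-position transitive SRC takes an animate embedded noun
  with probability 0.35, and an animate-embedded SRC takes an animate head
  with probability 0.47. An ORC with an inanimate embedded noun *never*
  takes an animate head (probability 0), in either position.

RCs are head-final: `[RC material] DE head-noun`. A transitive SRC is
`VT N DE head`, an ORC `N VT DE head`, an intransitive SRC `VI DE head`.
The grammar has no recursion — an RC can modify the matrix subject and the
matrix object of the same sentence (the productions are independent), but
no RC can contain another. Words are drawn uniformly within their category,
so all seven animate nouns (etc.) are distributionally identical; animacy
exists only as a difference in where the two noun categories occur.

`enumerate_templates` expands the cross product of subject options (bare
animate / bare inanimate / 9 subject-RC variants / pro-drop) and VP options
(intransitive / transitive with bare or RC-modified object), giving 144
category-level sentence patterns whose probabilities sum to 1. Everything
analytic rests on this enumeration:

* `prefix_mass(prefix)` — summed probability of all patterns starting with
  a category prefix;
* `next_category_distribution(prefix)` — the exact conditional distribution
  of the next category, `prefix_mass(prefix + [c]) / prefix_mass(prefix)`.
  This is the *target activation* oracle for GPE scoring. It is the full
  Bayesian mixture over all structural continuations, e.g. after a
  sentence-initial `VT` (total mass 0.302: pro-drop verb or
  subject-SRC-initial verb) the next category is `inaN` with probability
  0.717, `aniN` 0.232, `VT` 0.033, `VI` 0.018.

The generator (`sample_category_sequence`) walks the productions directly
and never consults the enumeration, so sampling and enumeration check each
other; the test suite compares them by chi-square at n = 100,000 and by
distinct-pattern equality at n = 1,000,000.

### Structurally licensed but probability-zero prefixes

The test design (below) crosses animacy fully, which includes ORCs with an
inanimate embedded noun and an animate head — a configuration the grammar
assigns probability zero. Sentences in these two cells cannot be given
exact conditional targets beyond the head. For them the scoring oracle
falls back to the *limiting* conditional obtained by giving the zero cells
an infinitesimal probability δ and letting δ → 0 (numerically δ = 1e-9,
which cancels exactly in the conditionals of interest; residual
probabilities below 1e-6 are truncated and the distribution renormalised).
The limit equals the intuitive structural expectation: after any complete
subject NP the target is the VP split {VT 0.79, VI 0.21}, whatever the
animacy of the head that closed it. The grammar module itself keeps the
strict contract — a zero-mass prefix raises `UngrammaticalPrefixError`
naming the first bad position — and only the experiment layer opts into
the fallback.

## The network

A classic Elman SRN, written from scratch in NumPy:

* 28 localist input units, 40 logistic hidden units, 40 context units (an
  exact copy of the previous step's hidden activations), 28 output units;
* weights and biases initialised i.i.d. uniform on [−1, +1];
* trained on next-word prediction: for each word except the final `EOS`
  the target is the one-hot vector of the following word;
* stochastic gradient descent with classical momentum
  (`v ← 0.9·v − 0.05·g`, `w ← w + v`), one update per word (batch size 1),
  one pass through a 10,000-sentence corpus;
* backpropagation is single-step: the context is treated as a frozen input
  (no backpropagation through time), the defining SRN training scheme;
* the context is reset to 0.5 per unit (= logistic(0)) at every sentence
  boundary, in training and prediction alike; sentences are independent
  and nothing is predicted across a boundary.

Output units are logistic. The default loss is the summed squared error
(output delta `(y−t)·y·(1−y)`), the standard error function of the
simulator generation this architecture comes from; per-unit cross-entropy
(delta `y−t`) and a softmax output with multinomial cross-entropy are
selectable via `SRNConfig`. The choice matters: cross-entropy drives the
one-epoch network to sharply winner-take-all outputs, and with it the
object-modifying RC-type contrast and the RC-type × position interaction
come out with signs opposite to the replication targets, while under
sum-squared error both are robust (see Limitations). With logistic outputs
the total output activation is not normalised; after one training pass it
settles near 1 (the suite checks the mean total is within [0.5, 1.5]),
which is what makes the miss component of GPE meaningful.

Gradient correctness is verified against central finite differences
(relative tolerance 1e-6) for all five parameter blocks in all three
output/loss modes, and the momentum rule against a two-step hand
computation. Training is bitwise reproducible from the seed.

## Grammatical Prediction Error

For one output vector and one target category distribution *t*:

* *hits* — summed activation over units of categories with `t_c > 0`;
* *false alarms* — summed activation over units of the other categories;
* *misses* — `Σ_c max(0, t_c − a_c)` over grammatical categories, where
  `a_c` is the summed activation of category *c*'s units (shortfall only,
  clipped at zero);
* `GPE = 1 − hits / (hits + false alarms + misses)`, clamped to [0, 1];
  a degenerate zero denominator scores 1.

Targets and misses live at category level; hits and false alarms sum raw
unit activations. Worked example: if the target for the transitive-verb
category is 0.302 (its exact sentence-initial mass) and the network's VT
units sum to 0.26, the miss contribution is 0.042. Overestimating one
grammatical category is penalised implicitly: when the total output is
roughly conserved, dislocated activation produces shortfalls elsewhere.

### Which word a score belongs to

The word-to-score alignment is genuinely underdetermined in the tradition
this metric comes from, so both conventions are implemented:

* `predict_next` (default): the score assigned to word *n* uses the output
  produced **when word n is the input**, evaluated against the exact
  distribution of the continuation given words 1…n. The final `EOS` has no
  continuation and is not scored. This is the only reading under which
  head-animacy effects can surface *at* the head (the head is in the
  conditioning prefix), and the experiment reproduces exactly those
  effects there.
* `predict_current`: the score assigned to word *n* uses the output
  produced after word n−1, evaluated against the distribution *of*
  position *n*. The sentence-initial word is then unscorable (there is no
  pre-sentence output), and the two conventions yield the same numbers
  shifted by one position.

## The experiment

Sixteen test conditions cross modifying position (matrix subject vs
object) × RC type (SRC vs ORC) × head animacy × RC-noun animacy;
intransitive SRCs are excluded. Ten token sentences per condition give 160
test items. Object-modifying items all begin with an animate subject noun
and a transitive verb and end at the RC head (`aniN VT [RC] DE head EOS`);
subject-modifying items open with the RC and continue after the head with
a matrix VP drawn from the grammar's VP distribution, restricted to
bare-noun objects to keep items minimal. Every item is checked to be novel
— its token sequence occurs in no training corpus — and items are
resampled until novel (bounded retries).

Ten networks with different random initialisations play the role of
participants. By default each trains on its own freshly generated
10,000-sentence corpus (a `shared_corpus` flag trains all ten on one); all
seeds derive from a single master seed. Every item is scored word by word;
the critical rows kept for analysis are labelled `W1 W2 DE head head+1`
for subject-modifying items and `W3 W4 DE head` for object-modifying items
(whose `head` row, the last scorable one under the default convention, has
the end-of-sentence marker as its target; under `predict_current` the
labels are `W2…head+1` and `W3…EOS` instead).

Inference is deliberately modest: no mixed-effects models are fitted.
Condition × position means are summarised with across-network standard
errors, and effects are assessed by paired tests on per-network condition
means — a one-sample t on the differences plus an exact sign test — with
Cohen's d on the paired differences as effect size. Only effect
*directions* are treated as replication criteria; coefficient magnitudes
from the original mixed-model analyses are not desk-reproducible.
Zero-variance contrasts are reported as degenerate rather than crashing.

At the study scale (10 networks × 10,000 sentences × 1 epoch, 160 items)
the whole pipeline runs in well under a minute on one CPU; the test suite
runs the full configuration once and reuses it across the directional
checks.

## What the generator does and does not emulate

The corpus generator *is* the study's environment: the condition mixture
(70 % overt subject, 21 % intransitive VPs, RC rates and animacy splits as
above) is the object of interest, not a free parameter, and the defaults
are not tuning knobs. What it deliberately does not contain: semantics
(animacy is purely distributional), optionally transitive verbs, other
uses of DE, null objects, multiply embedded RCs, and any frequency
differences between words of the same category. Passing tests therefore
show that the network tracks *sequential statistics* of an idealised
environment; they say nothing about lexical, discourse or world-knowledge
contributions to human reading times.

## Numerical and design choices

* All probability arithmetic in double precision; categorical splits must
  sum to 1 within 1e-9; printed-value checks use the source's printed
  rounding.
* Prefix-mass queries are cached per template set; the enumeration is 144
  patterns, so nothing here is performance-critical.
* `logistic(z)` clips `z` at ±500 to keep `exp` finite.
* Checkpoints are NumPy `.npz` archives holding parameters, velocities,
  context, seed and config, and round-trip exactly.
* Corpus files are plain text, one sentence per line of vocabulary words,
  with a header comment recording the grammar hash, size and seed.
* Seeds: every stochastic component takes an explicit seed; the experiment
  derives corpus, network and test-set seeds from the master seed via a
  single generator, keeping them below 2^31.

## Limitations

* **The loss function is consequential.** One training epoch leaves the
  network far from convergence, and the relative difficulty ordering of
  conditions depends on how sharp the outputs are. The package default
  (sum-squared error) reproduces the object-modifying SRC/ORC reversal,
  both head-animacy preferences and the RC-type × position interaction
  across networks; cross-entropy training reverses several of these. Any
  conclusion drawn from this class of simulation should be checked under
  both.
* **One directional effect sits one position late.** The subject-modifying
  SRC-harder-than-ORC effect, expected at the head, appears in this
  implementation at the word after the head (where it holds in 10 of 10
  networks, in every animacy cell) while the head row itself shows a
  small difference in the opposite direction — even though the same head
  row reproduces both head-animacy preferences. The head row's target
  ({VT 0.79, VI 0.21} after a subject head) is identical for SRC and ORC
  items, so everything there rides on how the two RC word orders distort
  the context; where that distortion surfaces is evidently sensitive to
  simulator details that are not pinned down.
* **End-of-sentence error is not near zero.** With per-sentence context
  resets the row predicting `EOS` after an object-modifying head averages
  ≈ 0.5, not ≈ 0: the sentence-final `[… DE head]` state is confusable
  with a subject-RC head (after which a verb follows), and one epoch of
  training does not separate them. Near-zero end-of-sentence error with no
  condition differences would instead be expected if `EOS` were itself a
  trained input in a continuous sentence stream — a regime this package
  deliberately does not use, because sentences are modelled as independent
  items (and because, when tried, continuous training destroyed the
  robust directional effects).
* The lme4-style item/participant random-effect structure of
  reading-time analyses is intentionally replaced by paired across-network
  tests; p-values here describe simulation stability, not human data.
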