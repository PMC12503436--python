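# Methods

This note documents the scoring model, the numerical conventions, the
synthetic study conditions, and the design decisions taken where the problem
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Annotation model

A document annotation is a text plus a list of typed surface mentions and a
list of directed typed triplets. Eleven entity types cover the drug
repositioning domain (drug, disease, target, side_effect, gene, biomarker,
symptom, complication, anatomy, test, treatment); nine canonical relation
types each carry a named inverse, giving 18 directed labels. Inverse surface
names (`is_treated_by`, `has_target`, ...) are this package's own: the
reference schema defines bidirectional labels but publishes only the
canonical direction, so triplets are always compared after canonicalization
(inverse label swapped to canonical with head/tail exchanged — an idempotent
operation).

Character offsets are 0-based half-open and **optional**: the quintuple
output dialect carries no offsets, so spans are recorded where known (the
generator always records them) and otherwise anchored by first-occurrence
substring search. Annotation principles are checked as lint violations
(`OVERLAP_TYPE_CONFLICT`, `NESTED_ENTITY`, `PUNCTUATION_EDGE`,
`BIDIRECTIONAL_PAIR`, `CROSS_SENTENCE_WITH_INTRA_ALTERNATIVE`,
`INCOMPATIBLE_RELATION`, `UNANCHORED_SURFACE`) rather than exceptions,
because imperfect model output must remain representable and scoreable.
Nesting fires on strict containment of anchored spans; the punctuation rule
is a lint on leading/trailing punctuation and framing conjunctions ("and",
"or") and never rewrites a surface; a cross-sentence triplet is flagged only
when an intrasentence triplet with the same canonical relation exists inside
one of the two sentences it spans. Sentence bounds travel with the document;
for external text a period/question/exclamation splitter is the fallback.

The endpoint-type compatibility table (which head/tail types a relation
admits) is shipped as editable YAML because the authoritative full table is
not published; the default is a reconstruction. It additionally admits
`(treatment, disease)` for `treat` so the treatment entity type can
participate in relations at all — without it the type would exist only as
isolated mentions.

## Dual reward

Per document, the reward of a raw model output against gold is

    R = w_acc · R_acc + w_fmt · R_fmt,           w_acc = w_fmt = 0.50
    R_acc = α·S_entity + β·S_triplet + γ·S_rare  α = β = 0.45, γ = 0.10
    R_fmt = δ·S_tag + ε·S_length                 δ = 0.70, ε = 0.30

The seven coefficients are the tuned configuration reported for the
reference pipeline and are fully configurable.

**S_entity.** Predictions are aligned to gold greedily and one-to-one:
exact (surface, type) matches first, then partial matches (same type, token
overlap after punctuation strip — "BRCA2" vs "BRCA2 mutations"), in gold
order then prediction order, deterministically. Exact matches earn 1,
partial matches earn `partial_credit` (default 0.5 — the reference scheme
says only that partial overlap is rewarded, without a value). The
denominator is `max(n_gold, n_pred)`: a pure-recall normalizer would leave
false positives unpenalized, whereas max-count makes spurious output
strictly costly while keeping the score in [0, 1].

**S_triplet.** Correct means canonical-quintuple equality (both surfaces,
both types, relation). Dependency errors — right relation between
overlapping entities but a wrong entity or type — and spurious triplets
earn 0.

**S_rare.** The exactly-recovered fraction of rare gold items. Rarity is
judged against a *fixed reference table* (the published corpus composition),
not the current batch, so rewards are deterministic across batches; the
default threshold 0.05 marks gene (3.88%), side_effect (2.59%) and
increases_expression_of (0.39%) as rare.

**Vacuous terms.** When gold and prediction both contain no triplets, or
gold contains no rare items, that term is dropped and the remaining weights
renormalized — otherwise documents without rare content could never reach
R_acc = 1. The triplet term is kept (at 0) whenever the prediction invents
triplets, so hallucinated relations stay costly.

**Format.** S_tag is 1 iff the tag report is clean: balanced counts, proper
nesting, no closing-before-opening, exactly one think block, at least one
step inside it. S_length is 1 iff the think-content length lies in
`length_bounds` (default [200, 8000] characters). Length is counted in
characters of the think-block interior excluding the tag tokens themselves —
a tokenizer-independent unit, since the reference scheme never fixes one.

Surface comparison is case-sensitive by default (original casing is part of
the output contract); a case-insensitive mode exists. Parsing for reward
uses lenient mode (malformed entries dropped with diagnostics — a reward
must exist for any sample; an unparseable payload zeroes R_acc but format is
still scored); evaluation uses strict mode by default.

## GRPO numerics

Advantages standardize rewards within a sampled group using the
**population** standard deviation (divide by G): the defining formula
carries no ddof, and the population form keeps |A| exact for G = 2
([1, 0] → [1, −1]). Degenerate groups (σ below `std_floor`, default 1e-8)
yield all-zero advantages rather than an error: a uniform-reward group
carries no preference signal. The surrogate is per-output
`min(ρA, clip(ρ, 1−ε, 1+ε)A)` averaged over the group, minus `kl_beta`
times the mean k3 estimator `r − log r − 1` (non-negative, zero iff r = 1).
`clip_epsilon` and `kl_beta` are mandatory in the config — the reference
pipeline does not report its values, so none are silently assumed; the
JSONL CLI (`drkex grpo-check`) makes the component usable as an external
trainer check. Ratios are sequence-level; token aggregation is the caller's
concern.

## Evaluation harness

Evaluation is stricter than the reward: only exact string matches count as
true positives; boundary overlaps are errors. Items are deduplicated per
document to unique (surface, type) pairs or canonical quintuples, because
the offsetless output format cannot distinguish repeated mentions. The
overall row is micro-averaged by default (pooled tp/fp/fn, standard BioNLP
practice); macro is available. F1 is the harmonic mean with the 0/0 → 0
convention; values are kept at full precision internally and rounded to two
decimals only at report rendering.

Error classification uses a fixed priority order per item — exact match >
incorrect type (same surface) > boundary error (same type, overlapping
surface) > spurious/missing — so that every gold and predicted entity lands
in exactly one category (a conservation law the tests check). For triplets,
a prediction matching a missed gold on relation and both surfaces but
differing in an endpoint type is an incorrect-entity-type error; remaining
missed golds whose endpoints anchor in different sentences are
cross-sentence errors (this rule requires sentence bounds). The confusion
matrix counts exact matches on the diagonal and surface-matched,
type-mismatched predictions off-diagonal; predictions without any gold
surface match are excluded from the matrix.

Splitting is deterministic given a seed, document-level, with
`|train| = round(fraction · N)` and input order preserved within partitions.

## Synthetic study conditions

The generator emulates a curated drug-repositioning abstract corpus: short
template-realized sentences filled from a packaged gazetteer (invented but
plausible names per type, plus a few canonical exemplars such as Metformin,
cetuximab, Docetaxel, BRCA2, p53). Defaults, chosen once: entity and
relation mixtures equal to the published reference composition; 10–16
mentions and 2–4 triplets per document (so relation-induced mentions,
roughly six per document, leave enough standalone mentions for mixture
correction); 10% of triplets cross-sentence; one or two entity-free filler
sentences. Standalone mention types are sampled by deficit correction
against the target mixture, so empirical shares converge on the target
(within two percentage points by a few hundred documents). Triplets respect
the compatibility table and every surface occurs verbatim at its recorded
span, so generated gold passes validation with zero violations by
construction. Generation is byte-deterministic given (config, seed).

Perturbation injects each error type independently per item at its
configured rate: omission (entity and dependent triplets removed), spurious
additions (non-gold phrases taken verbatim from the document), type swaps
(via a confusable-type table — biomarker↔gene↔target,
side_effect↔complication — reflecting the confusions observed between
semantically adjacent categories; other types swap to a random type),
boundary shifts (adjacent-token extension or last-token truncation),
triplet-endpoint retyping, and cross-sentence triplet drops. Every injection
is logged; the log is the exact oracle for the error classifier, and
endpoint retyping is restricted to entities participating in exactly one
triplet so one injection maps to exactly one recoverable error. Rendered
outputs wrap the serialized prediction in a think/step block padded to an
exact character count; requested tag corruption (drop/duplicate/transpose a
tag token) is verified to actually break integrity before being returned,
because one specific transposition — swapping an adjacent `</step><step>`
pair — merely nests the steps and stays well-formed.

**What passing these tests does and does not show.** Template sentences have
none of the lexical variety, ellipsis, coreference, or annotation ambiguity
of real abstracts; surfaces are unique within a document and always appear
verbatim. Passing therefore demonstrates the *mechanics* — scoring,
matching, classification, recovery, determinism — under controlled
conditions, not extraction difficulty on real literature. Real-corpus
headline figures require a trained model and are out of scope here; the
harmonic-mean and composition identities in the acceptance script check
arithmetic consistency with published rows, not model quality.

## Problem sizes and tolerances

Property suites run at deliberate desk scale: 1000 randomized reward pairs,
1000 random tag sequences against an independent recursive-descent oracle,
200 corpora against a set-intersection oracle (plus a scikit-learn
cross-check of micro P/R/F1), error-recovery grids at rates 0.1/0.3/0.5,
and a 1000-document corpus for the split check. Floating-point assertions
use 1e-9 absolute tolerance for standardization identities and 1e-12 for
exact-zero means; mixture convergence is asserted at ±2 percentage points.

## Known limitations

- The compatibility table and inverse-label names are reconstructions;
  both are overridable in YAML.
- Whether any relation admits multiple head types in the reference schema is
  unstated; the default admits sets only where the domain forces them
  (`is_located_in`, `increases_expression_of`, `treat`).
- Reasoning length is counted in characters, not model tokens.
- JSON repair is entry-level only: a payload whose braces are unbalanced
  beyond recognition yields a fatal diagnostic, not a best-effort parse.
- Mention-level duplicate surfaces (same string annotated twice in one
  document) are collapsed by evaluation and never produced by the generator.
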