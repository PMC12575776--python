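# Methods

This note documents the model behind `rarescan`, its tunable parameters, the
numerical and design choices that were genuinely open, what the synthetic
corpus generator does and does not emulate, and known limitations.

## Detection model

The detector is a pattern-matching pipeline, not a trained model. Its unit of
matching is the **bag of lemmas**: an expression is tokenized (maximal runs of
word characters; punctuation discarded, digits kept), lowercased,
lemmatized, accent-stripped, and reduced to a multiset of lemmas serialized as
a sorted, space-joined canonical key. Bags are multisets, not sets, so a
repeated word is distinguished ("síndrome síndrome X" ≠ "síndrome X"), and
function words are kept — dictionary variants such as "Variante de la PKU"
contain them, and dropping them would merge distinct diseases. Ambiguity is
preserved: when two ORPHA codes share a normalized expression, one matched bag
yields one detection per code. This mirrors the granularity overlap inherent
in hierarchical rare-disease nomenclatures, where the same clinical entity can
carry codes at different levels; resolving it is an annotation decision, not a
matching decision.

### Normalization and tagging

Accent removal is applied *after* lemmatization, because Spanish lemma
lexicons are accented; lemma lookup may therefore use accented forms, while
every stored lemma and norm is accent-free lowercase. The tagger/lemmatizer is
a pluggable contract (token sequence in, equal-length `(pos, lemma)` list out,
deterministic). The bundled implementation combines a hand-built lexicon
(function words, frequent clinical verbs, irregular forms and kinship nouns)
with suffix rules: feminine/plural adjective endings map to a
masculine-singular lemma (`-osa/-osas → -oso`, `-ica → -ico`, participles
`-ada/-ida → -ado/-ido`, `-ales → -al`), numbers tag as `Z`, and any other
unknown word falls back to common noun with a plural-stripped lemma (never
stripping invariant endings such as `-sis`, `-tis`, `-is`, `-us`, so
"craneosinostosis" survives intact). The fallback-to-noun choice is
deliberate: out-of-lexicon vocabulary in clinical notes is overwhelmingly
nominal (disease names, drugs, abbreviations), and the keyphrase pattern is
anchored on nouns. Because the *same* normalizer processes notes and
dictionary, a systematic lemmatization quirk cancels out in matching; the
matcher enforces this by fingerprinting the normalizer and refusing
mixed-provenance comparisons.

The coarse pattern alphabet is derived by tag prefix (noun tags start with
`N`, including proper nouns; adjectives `ADJ`/`JJ`; prepositions `PREP`/`IN`),
with one override: tokens in the negation list (default `no`, `sin`, `ni`)
are `NEG` regardless of POS, since negation here is defined by trigger words,
not by any tagset. Any third-party Spanish tagger can be plugged in by
re-declaring its prefixes.

Sentence boundaries are sentence-final punctuation (`.!?;`) followed by
whitespace, plus newlines. This deliberately splits abbreviations
("T. Fallot" becomes two sentences); the telegraphic style of primary-care
notes makes abbreviation-aware splitting unreliable either way, and the known
cost is documented under limitations. Character offsets are 0-based,
end-exclusive, and every token slices back exactly to its surface.

### Keyphrase extraction and TF-IDF

Candidates are maximal, leftmost-longest, non-overlapping matches of
`(NEG? JJ* NN+ JJ* IN)? JJ* NN+ JJ*` over the symbol sequence. Two points of
the pattern were genuinely open and are both configurable:

* **Noun group as `NN+`.** The noun group is one-or-more nouns; a disease is
  expressed through a noun or noun phrase, and an all-adjective match would
  be vacuous.
* **Repeating prepositional group** (`repeat_pp_group`, default on): chained
  prepositional phrases ("inmunodeficiencia por deficiencia de factor H")
  form a single span.

For every maximal match containing a preposition, all contiguous sub-spans
matching the core `JJ* NN+ JJ*` are also emitted, and the matcher additionally
slides sub-windows (of exactly the word counts present in the dictionary)
inside retained keyphrases (`match_mode=subwindow`, default; `exact` restricts
to whole-keyphrase bags). Both mechanisms exist so that a disease embedded in
a larger noun phrase — "signos de craneosinostosis" — can still match by bag
equality. `NEG` tokens captured inside a span are excluded from its bag: they
are pattern context, not disease vocabulary.

TF-IDF uses raw term frequency times smoothed inverse document frequency,
`tf · (ln(N/df) + 1)`, with each note one document; per note at most
`top_k = 50` distinct bags are retained, ranked by weight, ties broken by
first occurrence (earlier wins) and then by key, so selection is fully
deterministic and independent of note order in the corpus.

### Post-filters

A detection whose dictionary-side expression is a single word with fewer than
`min_word_letters = 4` alphabetic characters, or the single word "síndrome",
is discarded. The filter keys on the *stored expression*, not the note
surface: the ambiguity motivating it — case-folded acronyms colliding with
ordinary words ("OI" vs "oí") — is a property of the stored name. Multiword
variants containing an acronym ("PKU leve") survive.

### Negation and family context

A NegEx-style pass per sentence: trigger phrases are matched longest-first,
left-to-right over normalized tokens, each match consuming its tokens — which
is how pseudo-negations neutralize the negation phrases they contain ("no se
puede descartar" hides the inner "no"). An entity is negated when a PREN ends
within `scope_window = 5` tokens before it (or a POST begins within 5 tokens
after it) with no other negation-class trigger between; family context fires
forward-only from FAM_PREN with FAM_CONJ (or another family trigger) as
blocker. The 5-token, sentence-bounded window is the classic NegEx
convention; it is a config value recorded in the run manifest. Negation-class
and family-class triggers block only within their own class, so "Madre sin
evidencia de X" is simultaneously family and negated.

Occurrence statuses aggregate per (note, disease): all-affirmed → `affirmed`,
all-negated → `negated`, mixed → `possible`; likewise `individual` /
`family` / `individual_and_family`.

The bundled lexicon (~40 entries) contains the standard Spanish clinical
negators, pseudo-negations, scope conjunctions and kinship terms. Two
consequences worth knowing: "ni" is a PREN, which is what places
list-continuation negations ("... ni leucomalacia periventricular") in scope;
and "descartando" / "no confirmada" are triggers, so suspicion-then-ruled-out
phrasings label as negated. Fixtures whose outcome depends on such
beyond-the-obvious triggers are marked lexicon-sensitive in the fixture file,
with their expected output under the bundled lexicon stated there.

## Patient classification

All of a patient's notes count as one grouped document: qualifying mentions —
panel code, negation in {affirmed, possible}, family in {individual,
individual_and_family} — are pooled across notes. `possible` qualifies by
default (`qualify_possible`) because the disease is mentioned affirmatively
at least once; exclusively negated or exclusively family-history detections
classify as "None", matching how ruled-out and family-antecedent cases are
treated as negative. Exactly one disease per patient is emitted: the panel
disease with the most qualifying evidence occurrences, ties broken by
earliest mention (note date, note order, position), then lowest ORPHA code —
an artifact decision, since no tie rule is forced by the task.

Evaluation is standard one-vs-rest multiclass precision/recall/F with pooled
micro averages (equal to accuracy in the single-label setting, hence
micro-P = micro-R = micro-F) and unweighted macro averages that include
zero-score classes; a class with no predictions has precision 0 by
convention. The implementation delegates to scikit-learn with
`zero_division=0`; tests verify it against a hand-computed confusion-matrix
oracle.

## Obfuscation

Blocklist phrases are matched on token boundaries, case- and
accent-insensitively, longest-first, and replaced by asterisks of exactly the
matched surface length (including interior spaces of multiword phrases), so
output length always equals input length and already-masked text is a fixed
point. Compilation cross-checks the blocklist against the disease dictionary:
any term whose bag equals a dictionary key is moved to a protected set, and
occurrences of protected disease expressions in the text shield their span
from masking by any other phrase. Maximal digit runs of ≥ 3 digits
(configurable) are masked with equal-length asterisks — long enough to catch
phone numbers and dates while sparing short clinical values ("5 mg");
asterisks were chosen over another placeholder for consistency with the term
rule.

## Synthetic corpus generator

The generator emulates the *statistical structure* the detector assumes:
short telegraphic notes assembled from ~30 bundled sentence frames (diagnosis
statements, negated findings with the trigger inside the scope window,
kinship-attributed mentions, and clinical filler with medications and
measurements), with one injected mention per note at rate `p_mention` and
optional near-miss distractors (bare "síndrome", ≤ 3-letter acronyms,
one-transposition misspellings). Each patient is either assigned one panel
disease or is a "None" patient whose mentions are forced to negated or family
context. Defaults — 200 patients, 1–5 notes each, `p_mention = 0.7`,
`p_variant = 0.3`, `p_negated = 0.08`, `p_family = 0.03`, `p_both = 0.01`,
`p_distractor = 0.1`, `p_patient_none = 0.3` — reflect a pediatric
primary-care follow-up corpus in which negation appears in roughly 8% and
family attribution in roughly 4% of mentions. A single seeded stream drives
all choices; the same seed reproduces the corpus byte-for-byte.

What passing on synthetic data shows — and does not. Mentions are injected
inside noun-phrase frames with triggers placed within scope, so clean-corpus
precision/recall of 1.0 and perfect context recovery validate the *machinery*
(pattern, bags, windows, scope rules), not robustness to real clinical prose:
free-word-order sentences, misspellings, ad-hoc abbreviations, cross-sentence
scope and discourse-level reasoning are exactly the phenomena the generator
does not produce (misspellings and acronyms appear only as distractors, to
assert they are *not* matched). Scores on real notes will be lower,
particularly recall.

Problem sizes in the shipped checks were chosen to exercise the corpus-level
code paths while keeping the suite quick to iterate on: 200 mixed notes for
oracle equivalence, ~500 for recovery invariants, 1,000 for the end-to-end
smoke run, 300 patients (~900 notes) in the acceptance script.

## Known limitations

* **Exact matching only.** No fuzzy or edit-distance matching: misspellings
  ("Tratalogia de fallot") and out-of-dictionary abbreviations ("Sd Marfan",
  "T. Fallot") are misses by design.
* **Determiners break keyphrases.** The POS pattern has no determiner slot,
  so a variant like "Variante de la PKU" is found as a dictionary entry but
  cannot be extracted verbatim from running text; detection of such mentions
  relies on other variants of the same disease.
* **Acronym filter trades recall for precision.** Standalone short acronyms
  ("PKU", "FQ") are always discarded, even when genuine.
* **Sentence-bounded context.** Negation or family scope never crosses a
  sentence boundary, and abbreviation periods split sentences.
* **Trigger coverage is lexicon-bound.** Unlisted negation phrasings pass
  as affirmed; the lexicon is data (`data/triggers_es.tsv`) and is meant to
  be extended per deployment.
* The bundled dictionary is a demonstration fixture; production use should
  load a full nomenclature export in the same TSV/JSON schema.
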