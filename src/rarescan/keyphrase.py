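"""POS-pattern keyphrase extraction and TF-IDF selection.

Candidate keyphrases are token spans whose coarse-symbol sequence matches

    (NEG? JJ* NN+ JJ* IN)? JJ* NN+ JJ*

i.e. a (possibly adjective-modified) noun group, optionally preceded by
prepositional noun groups. Disease names are noun phrases, so every candidate
must contain at least one noun. Two deliberate extensions, both on by
default and recorded in the run manifest:

* the optional prepositional group may repeat, so chained prepositional
  phrases ("inmunodeficiencia por deficiencia de factor H") form one span;
* every maximal match containing a preposition additionally emits its
  contiguous sub-spans matching the core ``JJ* NN+ JJ*``, so a disease
  embedded in a larger phrase ("signos de craneosinostosis") can still be
  matched by bag equality.

Per note, candidates are ranked by TF-IDF (raw tf x smoothed idf,
``tf * (ln(N/df) + 1)``) and at most ``k`` distinct bags are retained
(default 50).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass

from .dictionary import BagKey
from .textnorm import Sentence

_SYMBOL_CHAR = {"NEG": "G", "JJ": "J", "NN": "N", "IN": "I", "OTHER": "O"}
_PATTERN_REPEAT = re.compile(r"(?:G?J*N+J*I)*J*N+J*")
_PATTERN_SINGLE = re.compile(r"(?:G?J*N+J*I)?J*N+J*")
_CORE = re.compile(r"J*N+J*")


@dataclass(frozen=True)
class Keyphrase:
    """One candidate span in one sentence of one note.

    ``span`` is (start, end), 0-based end-exclusive over the sentence's
    tokens. ``bag`` is the bag of spanned lemmas with NEG tokens excluded
    (they are pattern context, not disease vocabulary). ``score`` is filled
    in at selection time.
    """

    note_id: str
    sentence_index: int
    span: tuple[int, int]
    surface: str
    bag: BagKey
    score: float = 0.0

    @property
    def key(self) -> str:
        return self.bag.canonical_key


def symbol_string(sentence: Sentence) -> str:
    """Encode a sentence's pattern symbols as a one-char-per-token string."""
    return "".join(_SYMBOL_CHAR[t.sym] for t in sentence.tokens)


def extract_candidate_spans(symbols: str, repeat_pp_group: bool = True) -> list[tuple[int, int]]:
    """Return candidate spans over a symbol string.

    Maximal, non-overlapping, leftmost-longest matches of the full pattern;
    for each maximal match containing IN, also every contiguous sub-span
    matching the core. Spans are sorted, deduplicated, end-exclusive.
    """
    pattern = _PATTERN_REPEAT if repeat_pp_group else _PATTERN_SINGLE
    spans: set[tuple[int, int]] = set()
    for m in pattern.finditer(symbols):
        if not m.group(0):
            continue
        start, end = m.start(), m.end()
        spans.add((start, end))
        if "I" in m.group(0):
            seg = m.group(0)
            for i in range(len(seg)):
                for j in range(i + 1, len(seg) + 1):
                    if (start + i, start + j) not in spans and _CORE.fullmatch(seg[i:j]):
                        spans.add((start + i, start + j))
    return sorted(spans)


def _bag_for_span(sentence: Sentence, start: int, end: int) -> BagKey | None:
    lemmas = [t.lemma for t in sentence.tokens[start:end] if t.sym != "NEG"]
    if not lemmas:
        return None
    return BagKey.from_lemmas(lemmas)


def extract_candidates(
    sentence: Sentence,
    note_id: str,
    sentence_index: int,
    repeat_pp_group: bool = True,
) -> list[Keyphrase]:
    """Extract all candidate keyphrases of one sentence."""
    symbols = symbol_string(sentence)
    out: list[Keyphrase] = []
    for start, end in extract_candidate_spans(symbols, repeat_pp_group):
        bag = _bag_for_span(sentence, start, end)
        if bag is None:
            continue
        toks = sentence.tokens[start:end]
        surface = sentence.text[toks[0].start - sentence.start : toks[-1].end - sentence.start]
        out.append(Keyphrase(note_id, sentence_index, (start, end), surface, bag))
    return out


@dataclass
class TfidfModel:
    """Document frequencies over canonical keys; documents are notes."""

    df: dict[str, int]
    n_docs: int

    def idf(self, key: str) -> float:
        d = self.df.get(key, 0)
        if d == 0:
            return math.log(self.n_docs) + 1.0 if self.n_docs > 0 else 1.0
        return math.log(self.n_docs / d) + 1.0

    def weight(self, key: str, tf: int) -> float:
        return tf * self.idf(key)


def fit_tfidf(corpus: dict[str, list[Keyphrase]]) -> TfidfModel:
    """Fit document frequencies over a {note_id: candidates} corpus.

    ``df(key)`` counts the notes containing the key at least once.
    """
    if not corpus:
        raise ValueError("cannot fit a TF-IDF model on an empty corpus")
    df: Counter = Counter()
    for candidates in corpus.values():
        df.update({kp.key for kp in candidates})
    return TfidfModel(df=dict(df), n_docs=len(corpus))


def select_top(
    keyphrases: list[Keyphrase], model: TfidfModel, k: int = 50
) -> list[Keyphrase]:
    """Retain the spans of at most ``k`` distinct bags of one note.

    Keys are ranked by TF-IDF weight descending; ties are broken by first
    occurrence position (earlier wins), then by key for full determinism.
    All spans of a retained key are kept, with ``score`` filled in.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tf: Counter = Counter(kp.key for kp in keyphrases)
    first_pos: dict[str, tuple[int, int, int]] = {}
    for kp in keyphrases:
        pos = (kp.sentence_index, kp.span[0], kp.span[1])
        if kp.key not in first_pos or pos < first_pos[kp.key]:
            first_pos[kp.key] = pos
    ranked = sorted(
        tf, key=lambda key: (-model.weight(key, tf[key]), first_pos[key], key)
    )
    retained = set(ranked[:k])
    return [
        Keyphrase(
            kp.note_id, kp.sentence_index, kp.span, kp.surface, kp.bag,
            score=model.weight(kp.key, tf[kp.key]),
        )
        for kp in keyphrases
        if kp.key in retained
    ]
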