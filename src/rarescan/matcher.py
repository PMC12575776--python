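"""Bag-equality matching of retained keyphrases against the dictionary index.

Two match kinds:

* ``exact_bag`` — the keyphrase's own bag equals a dictionary key;
* ``subwindow_bag`` — a contiguous token window inside the keyphrase, with
  the same word count as some dictionary expression, has an equal bag.

Sub-window matching (default on, configurable) lets a disease embedded in a
larger extracted phrase still match. Windows slide over the keyphrase's
non-NEG tokens, mirroring the NEG exclusion in keyphrase bags.

Post-filters remove the acronym-style false positives a lowercase matcher
cannot distinguish: a match whose *dictionary-side* expression is a single
word of three or fewer letters ("OI", "USH", "PKU"), or the single word
"síndrome", is discarded. The filter is keyed on the stored expression, not
the note surface, because the ambiguity is a property of the stored name;
multiword variants containing an acronym survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dictionary import BagKey, DictionaryIndex
from .keyphrase import Keyphrase
from .textnorm import Normalizer, Sentence


@dataclass(frozen=True)
class Evidence:
    """One matched window supporting a detection."""

    sentence_index: int
    span: tuple[int, int]  # token span over the sentence, end-exclusive
    surface: str
    expression: str  # dictionary-side expression
    match_kind: str  # exact_bag | subwindow_bag


@dataclass
class CandidateDetection:
    """One detected disease in one note, with all supporting evidence."""

    note_id: str
    orpha_code: str
    evidence: list[Evidence] = field(default_factory=list)


class NormalizerMismatchError(RuntimeError):
    """Keyphrases and index were built under different normalizers."""


def _window_surface(sentence: Sentence, positions: list[int]) -> str:
    toks = [sentence.tokens[p] for p in positions]
    return sentence.text[toks[0].start - sentence.start : toks[-1].end - sentence.start]


def match_note(
    keyphrases: list[Keyphrase],
    index: DictionaryIndex,
    sentences: list[Sentence],
    normalizer: Normalizer,
    match_mode: str = "subwindow",
) -> list[CandidateDetection]:
    """Match one note's retained keyphrases against the index.

    Detections for the same (note, code) are merged, keeping all evidence;
    evidence duplicated by overlapping keyphrase spans is emitted once.
    """
    if index.normalizer_fingerprint and index.normalizer_fingerprint != normalizer.fingerprint:
        raise NormalizerMismatchError(
            "dictionary index and keyphrases were built with different normalizers"
        )
    if match_mode not in ("exact", "subwindow"):
        raise ValueError(f"unknown match mode {match_mode!r}")

    merged: dict[str, CandidateDetection] = {}
    seen: set[tuple[str, int, int, int, str]] = set()
    note_id = keyphrases[0].note_id if keyphrases else ""

    def emit(code: str, ev: Evidence) -> None:
        sig = (code, ev.sentence_index, ev.span[0], ev.span[1], ev.expression)
        if sig in seen:
            return
        seen.add(sig)
        det = merged.setdefault(code, CandidateDetection(note_id, code))
        det.evidence.append(ev)

    for kp in keyphrases:
        sentence = sentences[kp.sentence_index]
        for code, expression in index.lookup(kp.bag):
            emit(code, Evidence(kp.sentence_index, kp.span, kp.surface,
                                expression, "exact_bag"))
        if match_mode != "subwindow":
            continue
        positions = [
            p for p in range(kp.span[0], kp.span[1])
            if sentence.tokens[p].sym != "NEG"
        ]
        sizes = sorted(s for s in index.expression_sizes if s < len(positions))
        for size in sizes:
            for i in range(len(positions) - size + 1):
                window = positions[i : i + size]
                bag = BagKey.from_lemmas([sentence.tokens[p].lemma for p in window])
                for code, expression in index.lookup(bag):
                    emit(code, Evidence(
                        kp.sentence_index,
                        (window[0], window[-1] + 1),
                        _window_surface(sentence, window),
                        expression,
                        "subwindow_bag",
                    ))
    return [merged[c] for c in sorted(merged)]


def _expression_filtered(expression: str, normalizer: Normalizer, min_letters: int) -> bool:
    """True if a dictionary expression fails the single-word post-filters."""
    toks = normalizer.tokens(expression)
    if len(toks) != 1:
        return False
    norm = toks[0].norm
    if sum(ch.isalpha() for ch in norm) < min_letters:
        return True
    return norm == "sindrome"


def apply_postfilters(
    detections: list[CandidateDetection],
    normalizer: Normalizer,
    min_word_letters: int = 4,
) -> list[CandidateDetection]:
    """Drop evidence via filtered expressions; drop detections left empty.

    Idempotent, and the output is always a subset of the input.
    """
    out: list[CandidateDetection] = []
    for det in detections:
        kept = [
            ev for ev in det.evidence
            if not _expression_filtered(ev.expression, normalizer, min_word_letters)
        ]
        if kept:
            out.append(CandidateDetection(det.note_id, det.orpha_code, kept))
    return out
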