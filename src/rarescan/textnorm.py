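"""Sentence splitting, tokenization, normalization and POS tagging for Spanish clinical text.

Clinical notes are short, telegraphic Spanish. The pipeline downstream only
needs four things from this module: stable sentence boundaries, tokens with
character offsets back into the note, an accent-free lowercase form and lemma
per token, and a coarse pattern symbol (``NN``/``JJ``/``IN``/``NEG``/``OTHER``)
driving keyphrase extraction.

The tagger/lemmatizer is a pluggable contract (token sequence in, equal-length
``(pos, lemma)`` sequence out, deterministic). The bundled
:class:`LexiconTagger` combines a hand-built lexicon shipped with the package
and a small set of Spanish suffix rules; it requires no model download and is
the implementation all tests run on. Any third-party Spanish tagger can be
plugged in by wrapping it in a callable with the same contract and declaring
its noun/adjective/preposition tag prefixes.
"""

from __future__ import annotations

import hashlib
import re
import unicodedata
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Protocol, Sequence

#: Tokens treated as negation markers regardless of their POS tag.
NEG_TOKENS = frozenset({"no", "sin", "ni"})

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SENT_BOUNDARY = re.compile(r"(?<=[.!?;])\s+|\n+")
_DIGITS_RE = re.compile(r"\d+$")


def strip_accents(text: str) -> str:
    """Remove combining diacritics (``á``->``a``, ``ñ``->``n``, ``ü``->``u``)."""
    decomposed = unicodedata.normalize("NFD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return unicodedata.normalize("NFC", stripped)


def normalize_token(surface: str) -> str:
    """Lowercase, accent-free form of a token."""
    return strip_accents(surface.lower())


@dataclass(frozen=True)
class TaggedToken:
    """One token of a sentence with its normalized forms and pattern symbol.

    ``start``/``end`` are 0-based, end-exclusive character offsets into the
    note text, so ``text[start:end] == surface``.
    """

    surface: str
    norm: str
    lemma: str
    pos: str
    sym: str
    start: int
    end: int


@dataclass(frozen=True)
class Sentence:
    """An ordered run of tagged tokens with its raw text and note offset."""

    text: str
    start: int
    tokens: tuple[TaggedToken, ...]


class Tagger(Protocol):
    """Contract for pluggable POS taggers/lemmatizers."""

    fingerprint: str

    def __call__(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        """Return one ``(pos, lemma)`` per input token, deterministically."""
        ...


def split_sentences(text: str) -> list[tuple[int, str]]:
    """Split note text into sentences, returning ``(offset, raw)`` pairs.

    Boundaries are sentence-final punctuation followed by whitespace, and
    newlines. Whitespace-only segments are dropped; the returned segments,
    together with the separators, cover the input text.
    """
    if not text:
        return []
    out: list[tuple[int, str]] = []
    pos = 0
    for m in _SENT_BOUNDARY.finditer(text):
        seg = text[pos : m.start()]
        if seg.strip():
            out.append((pos, seg))
        pos = m.end()
    tail = text[pos:]
    if tail.strip():
        out.append((pos, tail))
    return out


def tokenize_and_normalize(sentence: str) -> list[tuple[str, str, int, int]]:
    """Tokenize a raw sentence into ``(surface, norm, start, end)`` tuples.

    Tokens are maximal runs of word characters; punctuation-only material is
    discarded (so ``"T. Fallot"`` yields ``t`` and ``fallot``). Digits are
    retained. Offsets are relative to the sentence string.
    """
    return [
        (m.group(0), normalize_token(m.group(0)), m.start(), m.end())
        for m in _TOKEN_RE.finditer(sentence)
    ]


# --- bundled tagger -------------------------------------------------------

# Feminine/plural adjective endings mapped to a masculine-singular lemma.
# Ordered longest-first so e.g. "osas" wins over "osa".
_ADJ_SUFFIXES: tuple[tuple[str, str], ...] = (
    ("osas", "oso"),
    ("osos", "oso"),
    ("osa", "oso"),
    ("icas", "ico"),
    ("icos", "ico"),
    ("ica", "ico"),
    ("ivas", "ivo"),
    ("ivos", "ivo"),
    ("iva", "ivo"),
    ("adas", "ado"),
    ("ados", "ado"),
    ("ada", "ado"),
    ("idas", "ido"),
    ("idos", "ido"),
    ("ida", "ido"),
    ("ales", "al"),
    ("ares", "ar"),
    ("bles", "ble"),
)

# Invariant noun endings: never strip a plural "s" from these.
_INVARIANT_ENDINGS = ("sis", "tis", "xis", "is", "us")
_VOWELS = "aeiou"


def _singularize(word: str) -> str:
    if len(word) <= 3 or word.endswith(_INVARIANT_ENDINGS):
        return word
    if word.endswith("es") and word[-3] not in _VOWELS:
        return word[:-2]
    if word.endswith("s") and word[-2] in _VOWELS:
        return word[:-1]
    return word


class LexiconTagger:
    """Deterministic lexicon + suffix-rule tagger for Spanish.

    Lookup is by lowercase surface, with an accent-stripped alias for every
    entry so already-normalized text resolves identically. Unknown words fall
    back to: all-digit -> ``Z`` (number); adjective suffix rules -> ``ADJ``
    with a masculine-singular lemma; otherwise common noun ``NC`` with a
    plural-stripped lemma. The noun fallback is the documented behaviour for
    out-of-lexicon vocabulary (disease names, drug names, abbreviations).
    """

    #: prefixes declaring how this tagset maps onto the coarse pattern symbols
    noun_prefixes = ("N",)
    adj_prefixes = ("ADJ", "JJ")
    prep_prefixes = ("PREP", "IN")

    def __init__(self, entries: dict[str, tuple[str, str]]):
        self._entries: dict[str, tuple[str, str]] = {}
        for surface, (pos, lemma) in entries.items():
            key = surface.lower()
            self._entries.setdefault(key, (pos, lemma))
            self._entries.setdefault(strip_accents(key), (pos, lemma))
        blob = "\n".join(f"{k}\t{v[0]}\t{v[1]}" for k, v in sorted(self._entries.items()))
        self.fingerprint = hashlib.sha256(blob.encode("utf-8")).hexdigest()

    @classmethod
    def from_tsv(cls, text: str) -> "LexiconTagger":
        entries: dict[str, tuple[str, str]] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"lexicon line {lineno}: expected 3 tab-separated fields")
            surface, pos, lemma = (p.strip() for p in parts)
            entries[surface] = (pos, lemma)
        return cls(entries)

    @classmethod
    def bundled(cls) -> "LexiconTagger":
        text = resources.files("rarescan").joinpath("data/lexicon_es.tsv").read_text("utf-8")
        return cls.from_tsv(text)

    def _tag_one(self, token: str) -> tuple[str, str]:
        low = token.lower()
        hit = self._entries.get(low) or self._entries.get(strip_accents(low))
        if hit is not None:
            return hit
        if _DIGITS_RE.match(low):
            return ("Z", low)
        for suffix, repl in _ADJ_SUFFIXES:
            if low.endswith(suffix) and len(low) > len(suffix) + 1:
                return ("ADJ", low[: -len(suffix)] + repl)
        return ("NC", _singularize(low))

    def __call__(self, tokens: Sequence[str]) -> list[tuple[str, str]]:
        return [self._tag_one(t) for t in tokens]


def coarse_symbol(pos: str, norm: str, neg_tokens: frozenset[str] = NEG_TOKENS,
                  noun_prefixes: Sequence[str] = LexiconTagger.noun_prefixes,
                  adj_prefixes: Sequence[str] = LexiconTagger.adj_prefixes,
                  prep_prefixes: Sequence[str] = LexiconTagger.prep_prefixes) -> str:
    """Map a POS tag and normalized form to a pattern symbol.

    The negation-token override precedes the POS mapping: negation in the
    keyphrase pattern is defined by trigger words, not by any tagset.
    """
    if norm in neg_tokens:
        return "NEG"
    if pos.startswith(tuple(noun_prefixes)):
        return "NN"
    if pos.startswith(tuple(adj_prefixes)):
        return "JJ"
    if pos.startswith(tuple(prep_prefixes)):
        return "IN"
    return "OTHER"


def tag_and_lemmatize(
    tokens: Sequence[tuple[str, str, int, int]],
    tagger: Callable[[Sequence[str]], list[tuple[str, str]]],
    neg_tokens: frozenset[str] = NEG_TOKENS,
    sent_start: int = 0,
) -> list[TaggedToken]:
    """Tag and lemmatize ``(surface, norm, start, end)`` tuples into TaggedTokens.

    The lemma returned by the tagger may be accented (Spanish lemma lexicons
    are); accent removal is applied here as the final normalization step.
    Offsets are shifted by ``sent_start`` to become note-absolute.
    """
    surfaces = [t[0] for t in tokens]
    tagged = tagger(surfaces)
    if len(tagged) != len(surfaces):
        raise ValueError(
            f"tagger returned {len(tagged)} tags for {len(surfaces)} tokens"
        )
    out: list[TaggedToken] = []
    for (surface, norm, start, end), (pos, lemma) in zip(tokens, tagged):
        lemma_norm = normalize_token(lemma)
        out.append(
            TaggedToken(
                surface=surface,
                norm=norm,
                lemma=lemma_norm,
                pos=pos,
                sym=coarse_symbol(pos, norm, neg_tokens),
                start=start + sent_start,
                end=end + sent_start,
            )
        )
    return out


class Normalizer:
    """Bundle of tokenizer + tagger applied identically to notes and dictionary.

    The matcher refuses to compare structures built under different
    normalizers, so the fingerprint ties together the tagger and the
    negation-token list.
    """

    def __init__(self, tagger: Tagger | None = None,
                 neg_tokens: frozenset[str] = NEG_TOKENS):
        self.tagger = tagger if tagger is not None else LexiconTagger.bundled()
        self.neg_tokens = frozenset(neg_tokens)
        blob = self.tagger.fingerprint + "|" + ",".join(sorted(self.neg_tokens))
        self.fingerprint = hashlib.sha256(blob.encode("utf-8")).hexdigest()

    def sentences(self, text: str) -> list[Sentence]:
        """Full normalization of note text into tagged sentences."""
        out = []
        for offset, raw in split_sentences(text):
            toks = tokenize_and_normalize(raw)
            if not toks:
                continue
            tagged = tag_and_lemmatize(toks, self.tagger, self.neg_tokens, offset)
            out.append(Sentence(text=raw, start=offset, tokens=tuple(tagged)))
        return out

    def tokens(self, expression: str) -> list[TaggedToken]:
        """Normalize a standalone expression (dictionary name, trigger phrase)."""
        toks = tokenize_and_normalize(expression)
        return tag_and_lemmatize(toks, self.tagger, self.neg_tokens)

    def lemmas(self, expression: str) -> list[str]:
        return [t.lemma for t in self.tokens(expression)]
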