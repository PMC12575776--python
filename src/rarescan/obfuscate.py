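"""Dictionary-based de-identification with disease-name protection.

Sensitive terms (names, places, centre names) are replaced by asterisk runs
of exactly the matched surface length, so text layout and readability are
preserved. Because a blocklist compiled from population databases can collide
with disease nomenclature, every blocklist phrase whose bag equals a disease
dictionary key is moved to a protected set and never masked; occurrences of
protected disease expressions in the text are likewise shielded from masking
by any other phrase. Maximal digit runs (default: length >= 3) are masked to
cover phone numbers, dates and record numbers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .dictionary import BagKey, DictionaryIndex
from .textnorm import normalize_token

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass
class Blocklist:
    """Compiled masking rules: token phrases to mask, phrases never to mask."""

    phrases: set[tuple[str, ...]] = field(default_factory=set)  # normalized token tuples
    protected: set[tuple[str, ...]] = field(default_factory=set)
    digit_run: int = 3  # mask maximal digit runs of at least this length
    n_excluded: int = 0  # terms moved to protected during compilation

    @property
    def max_len(self) -> int:
        return max((len(p) for p in self.phrases | self.protected), default=0)


def _phrase_tokens(phrase: str) -> tuple[str, ...]:
    return tuple(normalize_token(m.group(0)) for m in _TOKEN_RE.finditer(phrase))


def compile_blocklist(
    terms: list[str] | str | Path,
    protected_index: DictionaryIndex | None = None,
    digit_run: int = 3,
) -> Blocklist:
    """Compile blocklist terms, cross-checking against the disease dictionary.

    ``terms`` is a list of phrases or a path to a one-phrase-per-line file.
    Any term whose bag of normalized tokens equals a dictionary key is
    excluded from masking and counted. Duplicates are dropped.
    """
    if isinstance(terms, (str, Path)):
        lines = Path(terms).read_text("utf-8").splitlines()
        terms = [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    bl = Blocklist(digit_run=digit_run)
    if protected_index is not None:
        for key in protected_index.mapping:
            for _, expression in protected_index.mapping[key]:
                bl.protected.add(_phrase_tokens(expression))
    for term in terms:
        toks = _phrase_tokens(term)
        if not toks:
            continue
        if protected_index is not None:
            key = BagKey.from_lemmas(list(toks)).canonical_key
            in_dict = key in protected_index.mapping or toks in bl.protected
        else:
            in_dict = False
        if in_dict:
            if toks not in bl.protected:
                bl.protected.add(toks)
            bl.n_excluded += 1
        else:
            bl.phrases.add(toks)
    return bl


def _find_phrase_spans(
    tokens: list[tuple[str, int, int]],
    phrases: set[tuple[str, ...]],
    max_len: int,
) -> list[tuple[int, int]]:
    """Character spans of maximal (longest-first) phrase occurrences."""
    spans: list[tuple[int, int]] = []
    i = 0
    while i < len(tokens):
        hit = None
        for size in range(min(max_len, len(tokens) - i), 0, -1):
            gram = tuple(t[0] for t in tokens[i : i + size])
            if gram in phrases:
                hit = size
                break
        if hit is None:
            i += 1
        else:
            spans.append((tokens[i][1], tokens[i + hit - 1][2]))
            i += hit
    return spans


def obfuscate_text(text: str, blocklist: Blocklist) -> str:
    """Mask blocklisted phrases and digit runs with equal-length asterisks.

    Matching is token-boundary, case- and accent-insensitive. Protected
    disease expressions are located first and never overwritten. Output
    length always equals input length; the operation is idempotent
    ('*' is not a word character, so masked spans cannot re-match).
    """
    tokens = [
        (normalize_token(m.group(0)), m.start(), m.end())
        for m in _TOKEN_RE.finditer(text)
    ]
    max_len = blocklist.max_len
    protected_spans = _find_phrase_spans(tokens, blocklist.protected, max_len)

    def is_protected(start: int, end: int) -> bool:
        return any(start < pe and end > ps for ps, pe in protected_spans)

    out = list(text)
    for start, end in _find_phrase_spans(tokens, blocklist.phrases, max_len):
        if not is_protected(start, end):
            out[start:end] = "*" * (end - start)
    if blocklist.digit_run > 0:
        for m in re.finditer(r"\d+", text):
            if len(m.group(0)) >= blocklist.digit_run and not is_protected(m.start(), m.end()):
                out[m.start() : m.end()] = "*" * (m.end() - m.start())
    return "".join(out)
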