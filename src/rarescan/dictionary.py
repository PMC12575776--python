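"""Rare-disease nomenclature: loading, normalization, and the bag-of-words index.

A disease is identified by its ORPHA code and carries a preferred name plus
naming variants (synonyms, acronyms, word-order variations). Because Spanish
noun phrases permute freely ("condromalacia rotuliana familiar" ==
"condromalacia familiar rotuliana"), every expression is reduced to an
order-free multiset of normalized lemmas — a :class:`BagKey` — and matching
downstream is exact bag equality.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .textnorm import Normalizer

#: Separator used in canonical keys; cannot occur inside a lemma (tokens are
#: word-character runs only).
KEY_SEP = " "


class EmptyBagError(ValueError):
    """Raised when an expression normalizes to an empty bag (all punctuation)."""


@dataclass(frozen=True)
class BagKey:
    """Order-free canonical form of an expression: a multiset of lemmas."""

    lemmas: tuple[str, ...]  # sorted, with multiplicity

    @classmethod
    def from_lemmas(cls, lemmas: list[str] | tuple[str, ...]) -> "BagKey":
        return cls(tuple(sorted(lemmas)))

    @property
    def canonical_key(self) -> str:
        return KEY_SEP.join(self.lemmas)

    @property
    def size(self) -> int:
        return len(self.lemmas)

    def counter(self) -> Counter:
        return Counter(self.lemmas)


@dataclass(frozen=True)
class RareDiseaseEntry:
    """One ORPHA-coded disease with its preferred name and naming variants."""

    orpha_code: str
    preferred_name: str
    variants: tuple[str, ...] = ()

    def expressions(self) -> tuple[str, ...]:
        return (self.preferred_name, *self.variants)


def to_bag(expression: str, normalizer: Normalizer) -> BagKey:
    """Normalize an expression into its bag of lemmas.

    Raises :class:`EmptyBagError` if nothing but punctuation remains, so an
    unusable expression is never silently indexed. Idempotent: re-applying to
    the serialized canonical key yields an equal bag.
    """
    if not expression.strip():
        raise EmptyBagError("expression is empty after trimming")
    lemmas = normalizer.lemmas(expression)
    if not lemmas:
        raise EmptyBagError(f"expression {expression!r} normalizes to an empty bag")
    return BagKey.from_lemmas(lemmas)


def load_dictionary(path: str | Path, format: str | None = None) -> list[RareDiseaseEntry]:
    """Load a dictionary from TSV (``orpha_code<TAB>name<TAB>variants``) or JSON.

    TSV variants are pipe-separated; lines starting with ``#`` and the header
    row are skipped. JSON is an array of ``{orpha_code, name, variants[]}``.
    Duplicate ORPHA codes and empty names are hard errors.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        raw = json.loads(path.read_text("utf-8"))
        rows = [
            (str(obj["orpha_code"]), obj["name"], list(obj.get("variants", [])), i)
            for i, obj in enumerate(raw, start=1)
        ]
    elif fmt == "tsv":
        rows = []
        for lineno, line in enumerate(path.read_text("utf-8").splitlines(), start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].strip().lower() == "orpha_code":  # header
                continue
            code = parts[0].strip()
            name = parts[1].strip() if len(parts) > 1 else ""
            variants_field = parts[2].strip() if len(parts) > 2 else ""
            variants = [v.strip() for v in variants_field.split("|") if v.strip()]
            rows.append((code, name, variants, lineno))
    else:
        raise ValueError(f"unknown dictionary format {fmt!r}")

    entries: list[RareDiseaseEntry] = []
    seen: dict[str, int] = {}
    for code, name, variants, lineno in rows:
        if not name:
            raise ValueError(f"row {lineno}: empty disease name for ORPHA code {code!r}")
        if code in seen:
            raise ValueError(
                f"duplicate ORPHA code {code!r} at rows {seen[code]} and {lineno}"
            )
        seen[code] = lineno
        entries.append(RareDiseaseEntry(code, name, tuple(variants)))
    return entries


def save_dictionary_json(entries: list[RareDiseaseEntry], path: str | Path) -> None:
    """Write the JSON mirror of a dictionary."""
    data = [
        {"orpha_code": e.orpha_code, "name": e.preferred_name, "variants": list(e.variants)}
        for e in entries
    ]
    Path(path).write_text(json.dumps(data, ensure_ascii=False, indent=1), "utf-8")


@dataclass
class DictionaryIndex:
    """Bag-equality index over every name and variant of every entry.

    ``mapping`` goes from canonical key to the list of ``(orpha_code,
    expression)`` pairs sharing that bag; ambiguity (one bag, several codes)
    is preserved, never resolved. ``expression_sizes`` is the set of
    word counts present, used by the sub-window matcher.
    """

    mapping: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    bag_sizes: dict[str, int] = field(default_factory=dict)
    n_entries: int = 0
    n_expressions: int = 0
    n_empty_skipped: int = 0
    normalizer_fingerprint: str = ""

    @property
    def expression_sizes(self) -> set[int]:
        return set(self.bag_sizes.values())

    def lookup(self, bag: BagKey) -> list[tuple[str, str]]:
        return self.mapping.get(bag.canonical_key, [])

    def collisions(self) -> dict[str, list[tuple[str, str]]]:
        """Keys shared by more than one ORPHA code."""
        return {
            k: v for k, v in self.mapping.items() if len({code for code, _ in v}) > 1
        }


def build_index(entries: list[RareDiseaseEntry], normalizer: Normalizer) -> DictionaryIndex:
    """Index every (entry, name-or-variant) pair under exactly one bag key.

    Expressions that normalize to the empty bag are counted and skipped
    rather than indexed.
    """
    index = DictionaryIndex(normalizer_fingerprint=normalizer.fingerprint)
    index.n_entries = len(entries)
    for entry in entries:
        for expression in entry.expressions():
            try:
                bag = to_bag(expression, normalizer)
            except EmptyBagError:
                index.n_empty_skipped += 1
                continue
            key = bag.canonical_key
            index.mapping.setdefault(key, []).append((entry.orpha_code, expression))
            index.bag_sizes[key] = bag.size
            index.n_expressions += 1
    return index
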