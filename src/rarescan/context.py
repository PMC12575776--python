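"""Negation and family-member context detection over detected mentions.

A NegEx-style rule system: a lexicon of trigger phrases tagged

* ``PREN`` / ``POST`` — negation triggers before / after the entity,
* ``PSEU`` — pseudo-negation, records doubt and blocks real triggers,
* ``CONJ`` — scope-terminating conjunction,
* ``FAM_PREN`` / ``FAM_CONJ`` — the analogous pair for family mentions
  (family scope is forward-only: only triggers before the entity count).

Triggers are matched longest-first, left to right, over normalized token
n-grams, so a pseudo-negation consumes the tokens of any shorter negation it
contains. An entity occurrence is negated when a PREN ends within the scope
window W before it (or a POST begins within W after it) with no blocking
trigger in between; family works the same way with FAM_PREN/FAM_CONJ.
Occurrence statuses are aggregated per (note, disease) into three-way labels:
``affirmed``/``negated``/``possible`` and
``individual``/``family``/``individual_and_family``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .textnorm import Sentence, normalize_token

VALID_TAGS = ("PREN", "POST", "PSEU", "CONJ", "FAM_PREN", "FAM_CONJ")
_NEGATION_TAGS = {"PREN", "POST", "PSEU", "CONJ"}
_FAMILY_TAGS = {"FAM_PREN", "FAM_CONJ"}

#: Default scope window, in tokens, the classic NegEx convention.
DEFAULT_SCOPE_WINDOW = 5


@dataclass(frozen=True)
class Trigger:
    phrase: str
    tag: str
    tokens: tuple[str, ...]  # normalized token sequence


@dataclass
class TriggerLexicon:
    """Scoped trigger phrases plus the scope window W (in tokens)."""

    triggers: list[Trigger]
    scope_window: int = DEFAULT_SCOPE_WINDOW

    def __post_init__(self) -> None:
        seen = set()
        for t in self.triggers:
            if (t.phrase, t.tag) in seen:
                raise ValueError(f"duplicate trigger ({t.phrase!r}, {t.tag})")
            seen.add((t.phrase, t.tag))

    @property
    def max_len(self) -> int:
        return max((len(t.tokens) for t in self.triggers), default=0)

    def by_tokens(self) -> dict[tuple[str, ...], list[Trigger]]:
        out: dict[tuple[str, ...], list[Trigger]] = {}
        for t in self.triggers:
            out.setdefault(t.tokens, []).append(t)
        return out


def _parse_trigger_lines(lines: list[str], scope_window: int) -> TriggerLexicon:
    triggers: list[Trigger] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"trigger line {lineno}: expected phrase<TAB>TAG")
        phrase, tag = parts[0].strip(), parts[1].strip()
        if not phrase:
            raise ValueError(f"trigger line {lineno}: empty phrase")
        if tag not in VALID_TAGS:
            raise ValueError(f"trigger line {lineno}: unknown tag {tag!r}")
        tokens = tuple(normalize_token(w) for w in phrase.split())
        triggers.append(Trigger(phrase, tag, tokens))
    return TriggerLexicon(triggers, scope_window)


def load_triggers(path: str | Path, scope_window: int = DEFAULT_SCOPE_WINDOW) -> TriggerLexicon:
    """Load a ``phrase<TAB>TAG`` lexicon; '#' lines are comments."""
    return _parse_trigger_lines(Path(path).read_text("utf-8").splitlines(), scope_window)


def bundled_triggers(scope_window: int = DEFAULT_SCOPE_WINDOW) -> TriggerLexicon:
    """The lexicon shipped with the package (~40 common Spanish triggers)."""
    text = resources.files("rarescan").joinpath("data/triggers_es.tsv").read_text("utf-8")
    return _parse_trigger_lines(text.splitlines(), scope_window)


@dataclass(frozen=True)
class TriggerOccurrence:
    tag: str
    phrase: str
    span: tuple[int, int]  # token span, end-exclusive


@dataclass(frozen=True)
class OccurrenceStatus:
    """Context judgement for one evidence occurrence of one mention."""

    negation: str  # affirmed | negated
    family: str  # individual | family
    negation_trigger: str | None = None
    family_trigger: str | None = None


def scan_triggers(sentence: Sentence, lexicon: TriggerLexicon) -> list[TriggerOccurrence]:
    """Longest-match, left-to-right trigger scan over normalized tokens.

    A match consumes its tokens, so overlapping shorter triggers are
    suppressed — in particular a pseudo-negation hides the negation phrases
    it contains, which is how PSEU neutralization is realized.
    """
    norms = [t.norm for t in sentence.tokens]
    table = lexicon.by_tokens()
    out: list[TriggerOccurrence] = []
    i = 0
    while i < len(norms):
        matched = None
        for size in range(min(lexicon.max_len, len(norms) - i), 0, -1):
            gram = tuple(norms[i : i + size])
            if gram in table:
                matched = (size, table[gram])
                break
        if matched is None:
            i += 1
            continue
        size, triggers = matched
        for trig in triggers:  # one n-gram may carry several tags
            out.append(TriggerOccurrence(trig.tag, trig.phrase, (i, i + size)))
        i += size
    return out


def _scope_clear(
    occurrences: list[TriggerOccurrence],
    gap: tuple[int, int],
    blocking_tags: set[str],
    firing: TriggerOccurrence,
) -> bool:
    """No blocking trigger lies strictly between the firing trigger and entity."""
    lo, hi = gap
    for occ in occurrences:
        if occ is firing or occ.tag not in blocking_tags:
            continue
        if occ.span[1] > lo and occ.span[0] < hi:
            return False
    return True


def judge_occurrence(
    entity_span: tuple[int, int],
    occurrences: list[TriggerOccurrence],
    scope_window: int = DEFAULT_SCOPE_WINDOW,
    n_tokens: int | None = None,
) -> OccurrenceStatus:
    """Judge one entity occurrence against the triggers of its sentence.

    A PREN fires when it ends at most W tokens before the entity start, with
    no other negation-class trigger between; a POST symmetrically after the
    entity. FAM_PREN fires forward-only with FAM_CONJ (or another family
    trigger) as blocker. Triggers overlapping the entity span never fire.
    """
    ent_start, ent_end = entity_span
    if n_tokens is not None and (ent_start < 0 or ent_end > n_tokens):
        raise ValueError("entity span crosses the sentence boundary")

    negation, neg_trigger = "affirmed", None
    family, fam_trigger = "individual", None
    for occ in occurrences:
        if occ.span[1] > ent_start and occ.span[0] < ent_end:
            continue  # overlaps the entity itself
        if occ.tag == "PREN" and occ.span[1] <= ent_start:
            distance = ent_start - occ.span[1]
            if distance <= scope_window and _scope_clear(
                occurrences, (occ.span[1], ent_start), _NEGATION_TAGS, occ
            ):
                negation, neg_trigger = "negated", occ.phrase
        elif occ.tag == "POST" and occ.span[0] >= ent_end:
            distance = occ.span[0] - ent_end
            if distance <= scope_window and _scope_clear(
                occurrences, (ent_end, occ.span[0]), _NEGATION_TAGS, occ
            ):
                negation, neg_trigger = "negated", occ.phrase
        elif occ.tag == "FAM_PREN" and occ.span[1] <= ent_start:
            distance = ent_start - occ.span[1]
            if distance <= scope_window and _scope_clear(
                occurrences, (occ.span[1], ent_start), _FAMILY_TAGS, occ
            ):
                family, fam_trigger = "family", occ.phrase
    return OccurrenceStatus(negation, family, neg_trigger, fam_trigger)


@dataclass(frozen=True)
class NoteLabels:
    """Three-way aggregation of occurrence statuses for one (note, disease)."""

    negation_label: str  # affirmed | negated | possible
    family_label: str  # individual | family | individual_and_family


def aggregate_note(statuses: list[OccurrenceStatus]) -> NoteLabels:
    """Aggregate occurrence statuses; mixtures become the third label."""
    if not statuses:
        raise ValueError("cannot aggregate an empty occurrence set")
    neg = Counter(s.negation for s in statuses)
    fam = Counter(s.family for s in statuses)
    if neg["negated"] == 0:
        negation_label = "affirmed"
    elif neg["affirmed"] == 0:
        negation_label = "negated"
    else:
        negation_label = "possible"
    if fam["family"] == 0:
        family_label = "individual"
    elif fam["individual"] == 0:
        family_label = "family"
    else:
        family_label = "individual_and_family"
    return NoteLabels(negation_label, family_label)
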