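"""Seeded generator of synthetic Spanish clinical-note corpora with ground truth.

The generator emulates the statistical structure the detector assumes: short
telegraphic pediatric follow-up notes built from noun-phrase sentence frames,
with disease mentions injected at configurable rates under affirmed, negated,
family and combined contexts, plus near-miss distractors (bare "síndrome",
short acronyms, one-transposition misspellings). It does not attempt
realistic clinical language; its purpose is a corpus whose true annotation is
known exactly, so detection and context recovery can be scored.

Each patient is either assigned one panel disease (their affirmed mentions
all use it) or is a "None" patient whose mentions are forced to negated or
family context - mirroring how ruled-out and family-history cases produce
negative patients. A single seeded pseudo-random stream drives all choices.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from importlib import resources

from .dictionary import RareDiseaseEntry
from .pipeline import ClinicalNote, MentionAnnotation, NONE_LABEL


@dataclass
class SynthConfig:
    """Generator knobs; probabilities are per note unless stated otherwise.

    Defaults mirror a primary-care pediatric follow-up corpus: one to five
    notes per patient, most mentions affirmed, negation in roughly 8% and
    family context in roughly 4% of mentions.
    """

    n_patients: int = 200
    notes_per_patient: tuple[int, int] = (1, 5)
    panel: dict[str, str] = field(default_factory=dict)  # orpha_code -> display name
    p_mention: float = 0.7
    p_variant: float = 0.3
    p_negated: float = 0.08
    p_family: float = 0.03
    p_both: float = 0.01
    p_distractor: float = 0.1
    p_patient_none: float = 0.3
    n_filler_sentences: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_mention", "p_variant", "p_negated", "p_family", "p_both",
                     "p_distractor", "p_patient_none"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_negated + self.p_family + self.p_both > 1.0:
            raise ValueError("p_negated + p_family + p_both must be <= 1")


@dataclass(frozen=True)
class TrueMention:
    note_id: str
    orpha_code: str
    negation: str  # affirmed | negated
    family: str  # individual | family
    expression: str


@dataclass
class Truth:
    """Ground truth emitted alongside a synthetic corpus."""

    seed: int
    mentions: list[TrueMention] = field(default_factory=list)
    patient_labels: dict[str, str] = field(default_factory=dict)  # display name or "None"

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mentions": [asdict(m) for m in self.mentions],
            "patient_labels": dict(self.patient_labels),
        }


_KIN = ("Padre", "Madre", "Abuelo", "Abuela", "Hermano", "Hermana")


def load_templates() -> dict[str, list[str]]:
    """Bundled sentence frames grouped by kind."""
    text = resources.files("rarescan").joinpath("data/templates_es.tsv").read_text("utf-8")
    out: dict[str, list[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        kind, template = line.split("\t", 1)
        out.setdefault(kind, []).append(template)
    return out


def _acronym(name: str) -> str:
    return "".join(w[0].upper() for w in name.split() if w[0].isalpha())


def _transpose(name: str, rng: random.Random) -> str:
    """Swap one adjacent letter pair so the word no longer matches exactly."""
    chars = list(name)
    idx = [i for i in range(len(chars) - 1)
           if chars[i].isalpha() and chars[i + 1].isalpha()
           and chars[i].lower() != chars[i + 1].lower()]
    if not idx:
        return name + "x"
    i = rng.choice(idx)
    chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def _distractor(entries: dict[str, RareDiseaseEntry], codes: list[str],
                rng: random.Random) -> str:
    kind = rng.choice(("syndrome", "acronym", "misspelling"))
    if kind == "syndrome":
        return "síndrome"
    entry = entries[rng.choice(codes)]
    if kind == "acronym":
        short = [v for v in entry.variants if len(v) <= 3]
        return rng.choice(short) if short else _acronym(entry.preferred_name)[:3] or "XY"
    return _transpose(entry.preferred_name, rng)


def generate(
    config: SynthConfig,
    entries: list[RareDiseaseEntry] | None = None,
) -> tuple[list[ClinicalNote], Truth]:
    """Generate a synthetic corpus and its exact ground truth.

    ``entries`` (defaulting to the panel codes looked up in the bundled
    dictionary) supplies preferred names and variants for injection.
    """
    if entries is None:
        from .resources import bundled_dictionary

        entries = bundled_dictionary()
    by_code = {e.orpha_code: e for e in entries}
    if not config.panel:
        raise ValueError("synth config requires a non-empty disease panel")
    for code, name in config.panel.items():
        if code not in by_code:
            raise ValueError(f"panel code {code} missing from the dictionary")
        if not name:
            raise ValueError(f"panel disease {code} has an empty name")

    rng = random.Random(config.seed)
    templates = load_templates()
    codes = sorted(config.panel)
    notes: list[ClinicalNote] = []
    truth = Truth(seed=config.seed)

    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        none_patient = rng.random() < config.p_patient_none
        assigned = None if none_patient else rng.choice(codes)
        truth.patient_labels[patient_id] = (
            NONE_LABEL if assigned is None else config.panel[assigned]
        )
        n_notes = rng.randint(*config.notes_per_patient)
        for v in range(n_notes):
            note_id = f"{patient_id}-N{v:02d}"
            sentences: list[str] = []
            n_fill = rng.randint(*config.n_filler_sentences)
            sentences.extend(rng.choice(templates["filler"]) for _ in range(n_fill))

            if rng.random() < config.p_mention:
                r = rng.random()
                if r < config.p_negated:
                    mention_ctx = ("negated", "individual")
                elif r < config.p_negated + config.p_family:
                    mention_ctx = ("affirmed", "family")
                elif r < config.p_negated + config.p_family + config.p_both:
                    mention_ctx = ("negated", "family")
                else:
                    mention_ctx = ("affirmed", "individual")
                if assigned is None:
                    # a None patient never gets an affirmed-individual mention
                    if mention_ctx == ("affirmed", "individual"):
                        mention_ctx = rng.choice(
                            (("negated", "individual"), ("affirmed", "family"))
                        )
                    code = rng.choice(codes)
                else:
                    code = assigned
                entry = by_code[code]
                use_variant = entry.variants and rng.random() < config.p_variant
                expression = rng.choice(entry.variants) if use_variant else entry.preferred_name
                negation, family = mention_ctx
                if negation == "negated" and family == "family":
                    frame = rng.choice(templates["both"])
                elif negation == "negated":
                    frame = rng.choice(templates["negated_pre"] + templates["negated_post"])
                elif family == "family":
                    frame = rng.choice(templates["family"])
                else:
                    frame = rng.choice(templates["affirm"])
                sentence = frame.replace("{X}", expression).replace("{KIN}", rng.choice(_KIN))
                pos = rng.randint(0, len(sentences))
                sentences.insert(pos, sentence)
                truth.mentions.append(
                    TrueMention(note_id, code, negation, family, expression)
                )

            if rng.random() < config.p_distractor:
                frame = rng.choice(templates["affirm"])
                sentences.insert(
                    rng.randint(0, len(sentences)),
                    frame.replace("{X}", _distractor(by_code, codes, rng)),
                )

            notes.append(ClinicalNote(
                patient_id=patient_id,
                episode_id=f"{patient_id}-E00",
                note_id=note_id,
                date=f"2020-{1 + (v % 12):02d}-{1 + (p % 28):02d}",
                text=" ".join(sentences),
            ))
    return notes, truth


@dataclass
class RecoveryScore:
    """Detection P/R/F against truth plus context-label confusion."""

    precision: float
    recall: float
    f_measure: float
    n_true: int
    n_predicted: int
    n_matched: int
    negation_confusion: dict[str, dict[str, int]]
    family_confusion: dict[str, dict[str, int]]

    @property
    def negation_accuracy(self) -> float:
        return _diag_accuracy(self.negation_confusion)

    @property
    def family_accuracy(self) -> float:
        return _diag_accuracy(self.family_confusion)


def _diag_accuracy(confusion: dict[str, dict[str, int]]) -> float:
    total = sum(sum(row.values()) for row in confusion.values())
    if total == 0:
        return 1.0
    return sum(confusion.get(k, {}).get(k, 0) for k in confusion) / total


def score_against_truth(
    annotations: list[MentionAnnotation], truth: Truth
) -> RecoveryScore:
    """Score detections on (note, code) identity; contexts on matched pairs.

    Note-level negation labels collapse ``possible`` onto ``negated`` side
    counts only via the confusion matrix (rows are truth, columns observed).
    """
    true_pairs = {(m.note_id, m.orpha_code): m for m in truth.mentions}
    pred_pairs = {(a.note_id, a.orpha_code): a for a in annotations}
    matched = set(true_pairs) & set(pred_pairs)
    precision = len(matched) / len(pred_pairs) if pred_pairs else 1.0
    recall = len(matched) / len(true_pairs) if true_pairs else 1.0
    f = (2 * precision * recall / (precision + recall)) if precision + recall else 0.0

    neg_conf: dict[str, dict[str, int]] = {}
    fam_conf: dict[str, dict[str, int]] = {}
    for pair in matched:
        m, a = true_pairs[pair], pred_pairs[pair]
        neg_conf.setdefault(m.negation, {}).setdefault(a.negation_label, 0)
        neg_conf[m.negation][a.negation_label] += 1
        fam_conf.setdefault(m.family, {}).setdefault(a.family_label, 0)
        fam_conf[m.family][a.family_label] += 1
    return RecoveryScore(
        precision=precision,
        recall=recall,
        f_measure=f,
        n_true=len(true_pairs),
        n_predicted=len(pred_pairs),
        n_matched=len(matched),
        negation_confusion=neg_conf,
        family_confusion=fam_conf,
    )
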