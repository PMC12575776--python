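"""End-to-end orchestration: I/O, annotation, patient classification, evaluation.

``annotate_corpus`` runs normalization -> keyphrase extraction -> TF-IDF
selection -> dictionary matching -> post-filters -> negation/family context
per note, returning one :class:`MentionAnnotation` per (note, disease) plus a
corpus summary. ``classify_patients`` reduces note-level annotations to one
label per patient against a closed disease panel (plus ``"None"``), and
``evaluate`` computes per-class and micro/macro precision/recall/F-measure.
"""

from __future__ import annotations

import csv
import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path

from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import context as ctx
from . import keyphrase as kp
from . import matcher as mt
from .dictionary import RareDiseaseEntry, build_index
from .textnorm import Normalizer

NONE_LABEL = "None"


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text note of one visit within one episode."""

    patient_id: str
    episode_id: str
    note_id: str
    date: str  # ISO-8601
    text: str


@dataclass
class MentionAnnotation:
    """One detected disease in one note with aggregated context labels."""

    note_id: str
    orpha_code: str
    name: str
    negation_label: str
    family_label: str
    evidence: list[dict] = field(default_factory=list)


@dataclass
class PipelineConfig:
    """Tunable knobs of the detection pipeline, mirrored by the CLI/config file."""

    top_k: int = 50
    scope_window: int = ctx.DEFAULT_SCOPE_WINDOW
    match_mode: str = "subwindow"  # or "exact"
    min_word_letters: int = 4  # single-word expressions shorter than this are dropped
    repeat_pp_group: bool = True
    qualify_possible: bool = True  # "possible" negation still qualifies for classification

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


# --- notes I/O ------------------------------------------------------------

_NOTE_FIELDS = ("patient_id", "episode_id", "note_id", "date", "text")


def read_notes(path: str | Path) -> list[ClinicalNote]:
    """Read notes from JSONL (one object per line) or CSV with the same header."""
    path = Path(path)
    notes: list[ClinicalNote] = []
    if path.suffix.lower() == ".csv":
        with path.open(encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                notes.append(ClinicalNote(**{f: row[f] for f in _NOTE_FIELDS}))
    else:
        for line in path.read_text("utf-8").splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            notes.append(ClinicalNote(**{f: obj[f] for f in _NOTE_FIELDS}))
    return notes


def write_notes(notes: list[ClinicalNote], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(json.dumps(asdict(note), ensure_ascii=False) + "\n")


def write_annotations(annotations: list[MentionAnnotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(json.dumps(asdict(ann), ensure_ascii=False) + "\n")


# --- annotation -----------------------------------------------------------

@dataclass
class CorpusSummary:
    """Corpus-level counts: mention coverage, context labels, entity overlap."""

    n_notes: int = 0
    n_notes_with_mentions: int = 0
    n_patients_with_mentions: int = 0
    n_distinct_codes: int = 0
    negation_counts: dict = field(default_factory=lambda: {"affirmed": 0, "negated": 0, "possible": 0})
    family_counts: dict = field(default_factory=lambda: {"individual": 0, "family": 0, "individual_and_family": 0})
    entities_per_note: dict = field(default_factory=dict)  # distinct codes per note -> n notes


def annotate_corpus(
    notes: list[ClinicalNote],
    entries: list[RareDiseaseEntry],
    triggers: ctx.TriggerLexicon,
    config: PipelineConfig | None = None,
    normalizer: Normalizer | None = None,
) -> tuple[list[MentionAnnotation], CorpusSummary]:
    """Annotate every note of a corpus with rare-disease mentions.

    The TF-IDF model is fitted on the candidate keyphrases of the whole
    corpus (each note is one document) before per-note selection.
    """
    config = config or PipelineConfig()
    normalizer = normalizer or Normalizer()
    seen_ids: set[str] = set()
    for note in notes:
        if note.note_id in seen_ids:
            raise ValueError(f"duplicate note_id {note.note_id!r}")
        seen_ids.add(note.note_id)

    index = build_index(entries, normalizer)
    names = {e.orpha_code: e.preferred_name for e in entries}

    parsed: dict[str, list] = {}
    candidates: dict[str, list[kp.Keyphrase]] = {}
    for note in notes:
        sentences = normalizer.sentences(note.text)
        cands: list[kp.Keyphrase] = []
        for s_idx, sentence in enumerate(sentences):
            cands.extend(
                kp.extract_candidates(sentence, note.note_id, s_idx, config.repeat_pp_group)
            )
        parsed[note.note_id] = sentences
        candidates[note.note_id] = cands

    annotations: list[MentionAnnotation] = []
    summary = CorpusSummary(n_notes=len(notes))
    if notes:
        model = kp.fit_tfidf(candidates)
        patients_with = set()
        codes_seen = set()
        for note in notes:
            sentences = parsed[note.note_id]
            retained = kp.select_top(candidates[note.note_id], model, config.top_k)
            detections = mt.match_note(
                retained, index, sentences, normalizer, config.match_mode
            )
            detections = mt.apply_postfilters(detections, normalizer, config.min_word_letters)
            if not detections:
                continue
            trigger_occ = [
                ctx.scan_triggers(s, triggers) for s in sentences
            ]
            summary.n_notes_with_mentions += 1
            patients_with.add(note.patient_id)
            n_codes_here = 0
            for det in detections:
                statuses = [
                    ctx.judge_occurrence(
                        ev.span, trigger_occ[ev.sentence_index],
                        triggers.scope_window, len(sentences[ev.sentence_index].tokens),
                    )
                    for ev in det.evidence
                ]
                labels = ctx.aggregate_note(statuses)
                codes_seen.add(det.orpha_code)
                n_codes_here += 1
                summary.negation_counts[labels.negation_label] += 1
                summary.family_counts[labels.family_label] += 1
                annotations.append(MentionAnnotation(
                    note_id=note.note_id,
                    orpha_code=det.orpha_code,
                    name=names.get(det.orpha_code, det.orpha_code),
                    negation_label=labels.negation_label,
                    family_label=labels.family_label,
                    evidence=[
                        {
                            "sentence": ev.sentence_index,
                            "span": list(ev.span),
                            "surface": ev.surface,
                            "expression": ev.expression,
                            "match_kind": ev.match_kind,
                            "negation": st.negation,
                            "family": st.family,
                        }
                        for ev, st in zip(det.evidence, statuses)
                    ],
                ))
            summary.entities_per_note[n_codes_here] = (
                summary.entities_per_note.get(n_codes_here, 0) + 1
            )
        summary.n_patients_with_mentions = len(patients_with)
        summary.n_distinct_codes = len(codes_seen)
    return annotations, summary


# --- patient-level classification ----------------------------------------

def classify_patients(
    annotations: list[MentionAnnotation],
    panel: dict[str, str],
    notes: list[ClinicalNote],
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Assign exactly one label (panel disease name or ``"None"``) per patient.

    All of a patient's notes count as one grouped document: qualifying
    mentions (panel code, affirmed or - configurably - possible, involving
    the individual) are pooled over the notes. A patient with none is
    ``"None"``; otherwise the panel disease with the most qualifying
    occurrences wins, ties broken by earliest first mention, then lowest
    ORPHA code. Exclusively negated or exclusively family-context detections
    therefore classify as ``"None"``.
    """
    config = config or PipelineConfig()
    note_info = {n.note_id: n for n in notes}
    note_order = {n.note_id: i for i, n in enumerate(notes)}
    qualifying_negation = {"affirmed", "possible"} if config.qualify_possible else {"affirmed"}
    qualifying_family = {"individual", "individual_and_family"}

    by_patient: dict[str, dict[str, list]] = defaultdict(lambda: defaultdict(list))
    for ann in annotations:
        if ann.orpha_code not in panel:
            continue
        if ann.negation_label not in qualifying_negation:
            continue
        if ann.family_label not in qualifying_family:
            continue
        note = note_info.get(ann.note_id)
        if note is None:
            raise ValueError(f"annotation references unknown note {ann.note_id!r}")
        first = min(
            (ev["sentence"], ev["span"][0]) for ev in ann.evidence
        ) if ann.evidence else (0, 0)
        by_patient[note.patient_id][ann.orpha_code].append(
            (note.date, note_order[ann.note_id], first, len(ann.evidence))
        )

    predictions: dict[str, str] = {}
    for note in notes:
        predictions.setdefault(note.patient_id, NONE_LABEL)
    for patient_id, per_code in by_patient.items():
        def sort_key(code: str):
            mentions = per_code[code]
            n_occurrences = sum(m[3] for m in mentions)
            earliest = min((m[0], m[1], m[2]) for m in mentions)
            code_num = int(code) if code.isdigit() else code
            return (-n_occurrences, earliest, code_num)

        best = min(per_code, key=sort_key)
        predictions[patient_id] = panel[best]
    return predictions


# --- evaluation -----------------------------------------------------------

@dataclass
class EvaluationReport:
    """Per-class and averaged precision/recall/F plus confusion counts."""

    classes: list[str]
    per_class: dict[str, dict[str, float]]
    micro: dict[str, float]
    macro: dict[str, float]
    confusion: dict[str, dict[str, int]]
    n_items: int

    def to_dict(self) -> dict:
        return asdict(self)

    def summary_table(self) -> str:
        width = max(len(c) for c in self.classes + ["Macro-average"]) + 2
        lines = [f"{'Class':<{width}}{'Precision':>10}{'Recall':>10}{'F-measure':>10}"]
        for c in self.classes:
            m = self.per_class[c]
            lines.append(
                f"{c:<{width}}{m['precision']:>10.4f}{m['recall']:>10.4f}{m['f_measure']:>10.4f}"
            )
        for name, m in (("Micro-average", self.micro), ("Macro-average", self.macro)):
            lines.append(
                f"{name:<{width}}{m['precision']:>10.4f}{m['recall']:>10.4f}{m['f_measure']:>10.4f}"
            )
        return "\n".join(lines)


def evaluate(
    predictions: dict[str, str],
    gold: dict[str, str],
    classes: list[str],
) -> EvaluationReport:
    """Multiclass one-vs-rest P/R/F with pooled micro and unweighted macro.

    Macro averages include zero-score classes; a class with no predictions
    has precision 0 by convention. Every gold item must have a prediction.
    """
    missing = sorted(set(gold) - set(predictions))
    if missing:
        raise ValueError(f"missing predictions for items: {missing[:5]}")
    items = sorted(gold)
    y_true = [gold[i] for i in items]
    y_pred = [predictions[i] for i in items]

    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=None, zero_division=0
    )
    per_class = {
        c: {"precision": float(p), "recall": float(r), "f_measure": float(f)}
        for c, p, r, f in zip(classes, prec, rec, f1)
    }
    micro = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="micro", zero_division=0
    )
    macro = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    confusion = {
        gc: {pc: int(cm[i][j]) for j, pc in enumerate(classes) if cm[i][j]}
        for i, gc in enumerate(classes)
    }
    return EvaluationReport(
        classes=list(classes),
        per_class=per_class,
        micro={"precision": float(micro[0]), "recall": float(micro[1]), "f_measure": float(micro[2])},
        macro={"precision": float(macro[0]), "recall": float(macro[1]), "f_measure": float(macro[2])},
        confusion=confusion,
        n_items=len(items),
    )


# --- run manifest ---------------------------------------------------------

def run_manifest(
    config: PipelineConfig,
    normalizer: Normalizer,
    dictionary_text: str = "",
    triggers_text: str = "",
    seed: int | None = None,
) -> dict:
    """Reproducibility record: config, input fingerprints, versions."""
    from . import __version__

    record = {
        "version": __version__,
        "top_k": config.top_k,
        "scope_window": config.scope_window,
        "match_mode": config.match_mode,
        "min_word_letters": config.min_word_letters,
        "repeat_pp_group": config.repeat_pp_group,
        "qualify_possible": config.qualify_possible,
        "tfidf_variant": "raw_tf*(ln(N/df)+1)",
        "normalizer_fingerprint": normalizer.fingerprint,
        "dictionary_sha256": hashlib.sha256(dictionary_text.encode("utf-8")).hexdigest(),
        "triggers_sha256": hashlib.sha256(triggers_text.encode("utf-8")).hexdigest(),
        "seed": seed,
    }
    blob = json.dumps(record, sort_keys=True, ensure_ascii=False)
    record["fingerprint"] = hashlib.sha256(blob.encode("utf-8")).hexdigest()
    return record
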