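import itertools

import pytest

import rarescan as rs
from rarescan import context as ctx


def occurrences(normalizer, lexicon, text):
    (sentence,) = normalizer.sentences(text)
    return sentence, ctx.scan_triggers(sentence, lexicon)


def lex(*pairs, window=5):
    triggers = [
        ctx.Trigger(phrase, tag, tuple(phrase.lower().split())) for phrase, tag in pairs
    ]
    return ctx.TriggerLexicon(triggers, scope_window=window)


def test_load_triggers_tags_and_errors(tmp_path):
    p = tmp_path / "trig.tsv"
    p.write_text(
        "# comment\nsin evidencia\tPREN\npodría ser descartado\tPSEU\n"
        "secundario a\tCONJ\ndebe ser descartado\tPOST\npadre\tFAM_PREN\n",
        "utf-8",
    )
    lexicon = ctx.load_triggers(p)
    assert {t.tag for t in lexicon.triggers} == {"PREN", "PSEU", "CONJ", "POST", "FAM_PREN"}
    assert ("sin", "evidencia") in {t.tokens for t in lexicon.triggers}

    bad = tmp_path / "bad.tsv"
    bad.write_text("frase\tNOPE\n", "utf-8")
    with pytest.raises(ValueError, match="line 1"):
        ctx.load_triggers(bad)


def test_duplicate_trigger_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        lex(("no", "PREN"), ("no", "PREN"))


def test_bundled_lexicon_contains_quoted_triggers(triggers):
    pairs = {(t.phrase, t.tag) for t in triggers.triggers}
    assert ("sin evidencia", "PREN") in pairs
    assert ("debe ser descartado", "POST") in pairs
    assert ("podría ser descartado", "PSEU") in pairs
    assert ("secundario a", "CONJ") in pairs


def test_longest_match_suppresses_contained_triggers(normalizer):
    lexicon = lex(("no se puede descartar", "PSEU"), ("no", "PREN"))
    _, occ = occurrences(normalizer, lexicon, "no se puede descartar fractura")
    assert [(o.tag, o.span) for o in occ] == [("PSEU", (0, 4))]


def test_scan_finds_post_trigger(normalizer, triggers):
    _, occ = occurrences(normalizer, triggers, "la fractura debe ser descartado")
    assert ("POST", (2, 5)) in [(o.tag, o.span) for o in occ]


def test_scan_empty_without_triggers(normalizer, triggers):
    _, occ = occurrences(normalizer, triggers, "control de peso en consulta")
    assert occ == []


def test_pren_scope_boundary_at_window():
    W = 5
    lexicon = lex(("sin", "PREN"), window=W)
    trig = [ctx.TriggerOccurrence("PREN", "sin", (0, 1))]
    at_window = ctx.judge_occurrence((1 + W, 2 + W), trig, W)
    assert at_window.negation == "negated"
    past_window = ctx.judge_occurrence((2 + W, 3 + W), trig, W)
    assert past_window.negation == "affirmed"


def test_post_scope_boundary_at_window():
    W = 5
    trig = [ctx.TriggerOccurrence("POST", "descartado", (10, 11))]
    assert ctx.judge_occurrence((4, 10 - W), trig, W).negation == "negated"
    trig2 = [ctx.TriggerOccurrence("POST", "descartado", (11, 12))]
    assert ctx.judge_occurrence((4, 11 - W - 1), trig2, W).negation == "affirmed"


def test_conj_between_trigger_and_entity_blocks():
    trig = [
        ctx.TriggerOccurrence("PREN", "no", (0, 1)),
        ctx.TriggerOccurrence("CONJ", "secundario a", (2, 4)),
    ]
    assert ctx.judge_occurrence((5, 6), trig, 5).negation == "affirmed"
    # without the conjunction the same geometry negates
    assert ctx.judge_occurrence((5, 6), trig[:1], 5).negation == "negated"


def test_fam_conj_blocks_family_scope():
    trig = [
        ctx.TriggerOccurrence("FAM_PREN", "madre", (0, 1)),
        ctx.TriggerOccurrence("FAM_CONJ", "paciente", (2, 3)),
    ]
    assert ctx.judge_occurrence((4, 5), trig, 5).family == "individual"
    assert ctx.judge_occurrence((4, 5), trig[:1], 5).family == "family"


def test_family_scope_is_forward_only():
    trig = [ctx.TriggerOccurrence("FAM_PREN", "padre", (6, 7))]
    assert ctx.judge_occurrence((2, 4), trig, 5).family == "individual"


def test_pseudo_negation_neutralizes(normalizer, triggers):
    sentence, occ = occurrences(
        normalizer, triggers, "no se puede descartar displasia renal"
    )
    status = ctx.judge_occurrence((4, 6), occ, triggers.scope_window, len(sentence.tokens))
    assert status.negation == "affirmed"


def test_entity_crossing_sentence_boundary_is_hard_error():
    with pytest.raises(ValueError, match="sentence boundary"):
        ctx.judge_occurrence((3, 9), [], 5, n_tokens=6)


def test_no_trigger_means_affirmed_individual(normalizer, triggers):
    sentence, occ = occurrences(normalizer, triggers, "fenilcetonuria en seguimiento")
    status = ctx.judge_occurrence((0, 1), occ, triggers.scope_window, len(sentence.tokens))
    assert (status.negation, status.family) == ("affirmed", "individual")


def test_empty_lexicon_affirms_everything(normalizer):
    empty = ctx.TriggerLexicon([], scope_window=5)
    sentence, occ = occurrences(normalizer, empty, "no hay signos de craneosinostosis")
    assert occ == []
    status = ctx.judge_occurrence((4, 5), occ, 5, len(sentence.tokens))
    assert (status.negation, status.family) == ("affirmed", "individual")


@pytest.mark.parametrize(
    "statuses,negation,family",
    [
        ([("affirmed", "individual")], "affirmed", "individual"),
        ([("affirmed", "individual"), ("affirmed", "individual")], "affirmed", "individual"),
        ([("negated", "individual")] * 2, "negated", "individual"),
        ([("affirmed", "individual"), ("negated", "individual")], "possible", "individual"),
        ([("affirmed", "family")], "affirmed", "family"),
        ([("affirmed", "individual"), ("affirmed", "family")], "affirmed", "individual_and_family"),
        ([("negated", "family"), ("affirmed", "individual")], "possible", "individual_and_family"),
    ],
)
def test_aggregation(statuses, negation, family):
    occ = [ctx.OccurrenceStatus(n, f) for n, f in statuses]
    labels = ctx.aggregate_note(occ)
    assert (labels.negation_label, labels.family_label) == (negation, family)


def test_aggregation_permutation_invariant():
    occ = [
        ctx.OccurrenceStatus("affirmed", "individual"),
        ctx.OccurrenceStatus("negated", "family"),
        ctx.OccurrenceStatus("negated", "individual"),
    ]
    results = {
        (ctx.aggregate_note(list(p)).negation_label,
         ctx.aggregate_note(list(p)).family_label)
        for p in itertools.permutations(occ)
    }
    assert results == {("possible", "individual_and_family")}


def test_aggregation_empty_is_hard_error():
    with pytest.raises(ValueError):
        ctx.aggregate_note([])
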