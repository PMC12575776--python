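import pytest

import rarescan as rs
from rarescan import keyphrase as kp
from rarescan import matcher as mt
from oracles import sliding_window_codes


def run_match(normalizer, index, text, mode="subwindow", top_k=50):
    sentences = normalizer.sentences(text)
    cands = []
    for i, s in enumerate(sentences):
        cands.extend(kp.extract_candidates(s, "n", i))
    model = kp.fit_tfidf({"n": cands})
    retained = kp.select_top(cands, model, top_k)
    return mt.match_note(retained, index, sentences, normalizer, mode), retained, sentences


def test_exact_bag_match_via_variant(normalizer, index):
    detections, _, _ = run_match(normalizer, index, "enfermedad de Lobstein")
    assert [d.orpha_code for d in detections] == ["666"]
    assert detections[0].evidence[0].expression == "Enfermedad de Lobstein"
    assert any(ev.match_kind == "exact_bag" for ev in detections[0].evidence)


def test_subwindow_match_inside_larger_keyphrase(normalizer, index):
    detections, _, _ = run_match(normalizer, index, "signos de craneosinostosis")
    codes = {d.orpha_code for d in detections}
    assert "1516" in codes
    det = next(d for d in detections if d.orpha_code == "1516")
    assert {ev.match_kind for ev in det.evidence} <= {"exact_bag", "subwindow_bag"}
    assert any(ev.surface == "craneosinostosis" for ev in det.evidence)


def test_exact_mode_skips_embedded_mentions(normalizer, index):
    # "sem por tetralogia de fallot" only matches through a sub-window
    text = "estudiado hace 15 sem por tetralogia de fallot"
    sub, _, _ = run_match(normalizer, index, text, mode="subwindow")
    exact, _, _ = run_match(normalizer, index, text, mode="exact")
    assert "3303" in {d.orpha_code for d in sub}
    assert "3303" not in {d.orpha_code for d in exact}


def test_absent_bag_yields_no_detection(normalizer, index):
    detections, _, _ = run_match(normalizer, index, "exploracion abdominal normal")
    assert detections == []


def test_duplicate_detections_merge_evidence(normalizer, index):
    text = "Craneosinostosis confirmada. Control de craneosinostosis."
    detections, _, _ = run_match(normalizer, index, text)
    det = next(d for d in detections if d.orpha_code == "1516")
    assert len(det.evidence) == 2
    assert len({(ev.sentence_index, ev.span) for ev in det.evidence}) == 2


def test_normalizer_mismatch_is_hard_error(normalizer, entries):
    other = rs.Normalizer(neg_tokens=frozenset({"no"}))
    index = rs.build_index(entries, other)
    with pytest.raises(mt.NormalizerMismatchError):
        run_match_with_index(normalizer, index, "craneosinostosis")


def run_match_with_index(normalizer, index, text):
    sentences = normalizer.sentences(text)
    cands = [c for i, s in enumerate(sentences) for c in kp.extract_candidates(s, "n", i)]
    model = kp.fit_tfidf({"n": cands})
    return mt.match_note(kp.select_top(cands, model, 50), index, sentences, normalizer)


@pytest.mark.parametrize(
    "text,code,kept",
    [
        ("diagnostico de OI", "666", False),  # 2-letter acronym discarded
        ("diagnostico de USH", "886", False),  # 3-letter acronym discarded
        ("diagnostico de PKU", "716", False),
        ("fenilcetonuria confirmada", "716", True),  # 14-letter single word kept
        ("presenta PKU leve", "79253", True),  # multiword variant containing acronym
    ],
)
def test_postfilters_on_single_word_expressions(normalizer, index, text, code, kept):
    detections, _, _ = run_match(normalizer, index, text)
    filtered = mt.apply_postfilters(detections, normalizer)
    assert (code in {d.orpha_code for d in filtered}) is kept
    if not kept:  # the raw match did exist before filtering
        assert code in {d.orpha_code for d in detections}


def test_postfilter_discards_bare_syndrome_expression(normalizer):
    entries = [rs.RareDiseaseEntry("7", "Síndrome", ())]
    index = rs.build_index(entries, normalizer)
    detections = run_match_with_index(normalizer, index, "impresiona de síndrome")
    assert {d.orpha_code for d in detections} == {"7"}
    assert mt.apply_postfilters(detections, normalizer) == []


def test_postfilters_monotone_and_idempotent(normalizer, index):
    detections, _, _ = run_match(
        normalizer, index, "diagnostico de USH con fenilcetonuria"
    )
    once = mt.apply_postfilters(detections, normalizer)
    codes_once = {d.orpha_code for d in once}
    assert codes_once <= {d.orpha_code for d in detections}
    twice = mt.apply_postfilters(once, normalizer)
    assert [(d.orpha_code, d.evidence) for d in twice] == [
        (d.orpha_code, d.evidence) for d in once
    ]


def test_match_equals_brute_force_oracle_on_mixed_corpus(normalizer, entries, index, panel):
    """Matcher detections equal the sliding-window oracle restricted to keyphrases."""
    cfg = rs.SynthConfig(n_patients=70, panel=panel, p_distractor=0.3,
                         p_variant=0.5, seed=11)
    notes, _ = rs.generate(cfg, entries)
    notes = notes[:200]
    for note in notes:
        detections, retained, sentences = run_match(normalizer, index, note.text)
        spans = {}
        for c in retained:
            spans.setdefault(c.sentence_index, []).append(c.span)
        oracle = sliding_window_codes(note.text, entries, normalizer, spans)
        assert {d.orpha_code for d in detections} == oracle, note.text


def test_match_equals_unrestricted_oracle_on_noun_phrase_corpus(
    normalizer, entries, index, panel
):
    cfg = rs.SynthConfig(n_patients=40, panel=panel, p_mention=1.0, p_variant=0.0,
                         p_negated=0.0, p_family=0.0, p_both=0.0, p_distractor=0.0,
                         p_patient_none=0.0, seed=5)
    notes, _ = rs.generate(cfg, entries)
    for note in notes:
        detections, _, _ = run_match(normalizer, index, note.text)
        oracle = sliding_window_codes(note.text, entries, normalizer, None)
        assert {d.orpha_code for d in detections} == oracle, note.text
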