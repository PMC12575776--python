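"""Independent brute-force oracles the implementation is checked against."""

import re
from collections import Counter

_CORE = re.compile(r"J*N+J*")


def pattern_spans_oracle(symbols: str, repeat_pp_group: bool = True):
    """Candidate spans by exhaustive enumeration + fullmatch.

    Maximal leftmost-longest matches are found by scanning every start and
    taking the longest fullmatching extent; nested core sub-spans of
    IN-bearing matches are enumerated exhaustively.
    """
    pattern = re.compile(r"(?:G?J*N+J*I)*J*N+J*" if repeat_pp_group
                         else r"(?:G?J*N+J*I)?J*N+J*")
    spans = set()
    i = 0
    while i < len(symbols):
        best = None
        for j in range(len(symbols), i, -1):
            if pattern.fullmatch(symbols[i:j]):
                best = j
                break
        if best is None:
            i += 1
            continue
        spans.add((i, best))
        if "I" in symbols[i:best]:
            for a in range(i, best):
                for b in range(a + 1, best + 1):
                    if _CORE.fullmatch(symbols[a:b]):
                        spans.add((a, b))
        i = best
    return sorted(spans)


def sliding_window_codes(note_text, entries, normalizer, keyphrase_spans=None,
                         min_word_letters=0):
    """(code set) found by sliding every dictionary-expression length window.

    Windows slide over non-NEG tokens of each sentence and match by lemma-bag
    (Counter) equality. ``keyphrase_spans`` maps sentence index -> token spans;
    when given, only windows lying inside some span count. Setting
    ``min_word_letters`` replicates the single-word post-filters.
    """
    sentences = normalizer.sentences(note_text)
    expressions = []
    for entry in entries:
        for expr in entry.expressions():
            lemmas = normalizer.lemmas(expr)
            if not lemmas:
                continue
            if min_word_letters and len(lemmas) == 1:
                norm = normalizer.tokens(expr)[0].norm
                if sum(c.isalpha() for c in norm) < min_word_letters or norm == "sindrome":
                    continue
            expressions.append((entry.orpha_code, Counter(lemmas), len(lemmas)))
    codes = set()
    for s_idx, sentence in enumerate(sentences):
        positions = [i for i, t in enumerate(sentence.tokens) if t.sym != "NEG"]
        for code, bag, length in expressions:
            if code in codes:
                continue
            for i in range(len(positions) - length + 1):
                window = positions[i : i + length]
                if keyphrase_spans is not None:
                    spans = keyphrase_spans.get(s_idx, [])
                    if not any(window[0] >= a and window[-1] < b for a, b in spans):
                        continue
                if Counter(sentence.tokens[p].lemma for p in window) == bag:
                    codes.add(code)
                    break
    return codes


def prf_from_confusion(confusion, classes):
    """Hand-computed one-vs-rest P/R/F from a {gold: {pred: n}} table."""
    per_class = {}
    tp_all = fp_all = fn_all = 0
    for c in classes:
        tp = confusion.get(c, {}).get(c, 0)
        fp = sum(confusion.get(g, {}).get(c, 0) for g in classes if g != c)
        fn = sum(n for p, n in confusion.get(c, {}).items() if p != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = (precision, recall, f)
        tp_all += tp
        fp_all += fp
        fn_all += fn
    micro_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    micro_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    micro_f = 2 * micro_p * micro_r / (micro_p + micro_r) if micro_p + micro_r else 0.0
    n = len(classes)
    macro = tuple(sum(per_class[c][i] for c in classes) / n for i in range(3))
    return per_class, (micro_p, micro_r, micro_f), macro
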