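"""Independent brute-force oracles used to cross-check the implementation.

Deliberately simple, separately-written code paths: a replace-and-split
tokenizer with exhaustive scans for the negation-scope oracle, and
statsmodels' beta-method interval as the exact-CI oracle.
"""

from typing import List, Sequence

_PUNCT = ".,;:()!?\"/-"


def o_tokens(text: str) -> List[str]:
    for ch in _PUNCT:
        text = text.replace(ch, f" {ch} ")
    return text.lower().split()


def oracle_negated(text: str, term: str, lexicon) -> bool:
    """Exhaustive-scan negation decision for the unique occurrence of term."""
    toks = o_tokens(text)
    tt = o_tokens(term)
    positions = [
        i for i in range(len(toks)) if toks[i:i + len(tt)] == tt
    ]
    assert len(positions) == 1, f"term {term!r} not unique in {text!r}"
    s = positions[0]
    e = s + len(tt) - 1
    terminators = set(lexicon.scope_terminators)
    for cue in lexicon.negation_cues_pre:
        ct = o_tokens(cue)
        m = len(ct)
        for q in range(len(toks)):
            if q - m + 1 < 0 or toks[q - m + 1:q + 1] != ct:
                continue
            if q < s and s - q <= lexicon.window_tokens:
                if not any(t in terminators for t in toks[q + 1:s]):
                    return True
    for cue in lexicon.negation_cues_post:
        ct = o_tokens(cue)
        m = len(ct)
        for p in range(len(toks)):
            if toks[p:p + m] != ct:
                continue
            if p > e and p - e <= lexicon.window_tokens:
                if not any(t in terminators for t in toks[e + 1:p]):
                    return True
    return False


# filler phrases by token length 0..6, all free of cues, terms and terminators
FILLERS: Sequence[str] = (
    "",
    "sign",
    "sign of",
    "evidence of residual",
    "residual sign of any",
    "clinically significant sign of any",
    "clinically significant residual sign of any",
)

#: one-token filler that is itself a scope terminator (blocks negation)
TERMINATOR_FILLER = "however"


def negation_grammar(lexicon):
    """Enumerate cue x filler x term strings (and post-cue variants).

    Yields (text, term) pairs; each text contains exactly one lexicon
    term occurrence whose negation status the oracle can decide.
    """
    fillers = list(FILLERS) + [TERMINATOR_FILLER]
    for term in lexicon.complication_terms:
        for cue in lexicon.negation_cues_pre:
            for filler in fillers:
                gap = f" {filler} " if filler else " "
                yield f"the exam shows {cue}{gap}{term} at this time", term
        for cue in lexicon.negation_cues_post:
            for filler in fillers:
                gap = f" {filler} " if filler else " "
                yield f"status of {term}{gap}{cue} per exam", term
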