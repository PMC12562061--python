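"""Fine-grained phrase- and clause-complexity indices over dependency trees.

The catalogue covers 20 indices in two families, computed per transcript:

* phrase complexity — modifier and dependent counts per nominal unit
  (all nominals, nominal subjects, objects of prepositions, direct objects,
  copular predicate nominals), with "_NN" variants restricted to
  non-pronoun heads;
* clause complexity — counts of clause-building material (subordinators,
  complement clauses, conjunctions, direct objects, prepositions) per
  clause, plus the mean and spread of dependents per clause.

All indices are ratios numerator-count / denominator-count defined over
(relation, POS) predicates on the canonical UD label set; standard
deviations are population (divide-by-N) over the per-unit dependent
counts.  A zero denominator makes an index undefined (``None``), never
silently zero.  The type-token ratio (TTR) is distinct lowercased
non-punctuation forms over total non-punctuation tokens.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .treebank_io import Sentence, Token, Treebank, TreebankError, coarse_pos

__all__ = [
    "INDEX_NAMES",
    "ClauseKind",
    "ClauseAnchor",
    "IndexVector",
    "clause_anchors",
    "compute_index",
    "compute_all_indices",
    "type_token_ratio",
]

INDEX_NAMES: tuple[str, ...] = (
    # phrase complexity
    "av_pobj_deps_NN",
    "amod_all_nominal_deps_NN_struct",
    "amod_dobj_deps_struct",
    "av_ncomp_deps_NN",
    "nominal_deps_stdev",
    "pobj_NN_stdev",
    "poss_nsubj_deps_NN_struct",
    "prep_all_nominal_deps_struct",
    "prep_nsubj_deps_NN_struct",
    "rcmod_nsubj_deps_NN_struct",
    "vmod_all_nominal_deps_NN_struct",
    # clause complexity
    "cc_per_cl",
    "ccomp_per_cl",
    "cl_av_deps",
    "cl_ndeps_std_dev",
    "conj_per_cl",
    "dobj_per_cl",
    "mark_per_cl",
    "prep_per_cl",
    "xcomp_per_cl",
)

_NOMINAL_POS = {"NOUN", "PROPN"}
_CLAUSAL_RELATIONS = {
    "ccomp": "complement",
    "xcomp": "open_complement",
    "advcl": "adverbial",
    "acl:relcl": "relative",
    "acl": "adverbial",
}


class ClauseKind(str, Enum):
    ROOT = "root"
    COMPLEMENT = "complement"
    OPEN_COMPLEMENT = "open_complement"
    ADVERBIAL = "adverbial"
    RELATIVE = "relative"
    COORDINATED = "coordinated"


@dataclass(frozen=True)
class ClauseAnchor:
    """The governing token of one clause within a sentence."""

    position: int
    clause_kind: ClauseKind


@dataclass
class IndexVector:
    """One transcript's syntactic index profile.

    ``values[name]`` is ``None`` where the denominator was zero;
    ``support[name]`` records that denominator size.
    """

    values: dict[str, float | None] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)
    ttr: float = float("nan")

    def as_row(self) -> dict[str, float | None]:
        row: dict[str, float | None] = dict(self.values)
        row["ttr"] = self.ttr
        return row


def clause_anchors(sentence: Sentence) -> list[ClauseAnchor]:
    """Clause-governing tokens: the root plus every clausal-relation token.

    Clausal relations are complement clauses (ccomp), open complements
    (xcomp), adverbial/participial clauses (advcl, acl), relative clauses
    (acl:relcl) and verb-headed coordination (conj on a VERB/AUX token).
    A verbless fragment yields exactly one anchor of kind ``root``.
    """
    anchors: list[ClauseAnchor] = []
    for token in sentence.tokens:
        if token.governor == 0:
            anchors.append(ClauseAnchor(token.position, ClauseKind.ROOT))
        elif token.relation in _CLAUSAL_RELATIONS:
            anchors.append(
                ClauseAnchor(token.position,
                             ClauseKind(_CLAUSAL_RELATIONS[token.relation]))
            )
        elif token.relation == "conj" and coarse_pos(token.upos) in ("VERB", "AUX"):
            anchors.append(ClauseAnchor(token.position, ClauseKind.COORDINATED))
    return anchors


# ---------------------------------------------------------------------------
# unit extraction helpers
# ---------------------------------------------------------------------------


def _is_nominal(token: Token, exclude_pronouns: bool) -> bool:
    pos = coarse_pos(token.upos)
    if pos in _NOMINAL_POS:
        return True
    return pos == "PRON" and not exclude_pronouns


def _dependent_count(sentence: Sentence, position: int) -> int:
    """Non-punctuation dependents of the token at ``position``."""
    return sum(
        1 for t in sentence.tokens if t.governor == position and not t.is_punct
    )


def _pobj_heads(sentence: Sentence, exclude_pronouns: bool) -> list[Token]:
    """Nominals functioning as object of a preposition: they govern a case
    marker (UD attaches the adposition to the embedded noun)."""
    with_case = {
        t.governor
        for t in sentence.tokens
        if t.relation == "case" and coarse_pos(t.upos) == "ADP"
    }
    return [
        t for t in sentence.tokens
        if t.position in with_case and _is_nominal(t, exclude_pronouns)
    ]


def _ncomp_heads(sentence: Sentence, exclude_pronouns: bool) -> list[Token]:
    """Nominals serving as copular predicate complements (govern a cop)."""
    with_cop = {t.governor for t in sentence.tokens if t.relation == "cop"}
    return [
        t for t in sentence.tokens
        if t.position in with_cop and _is_nominal(t, exclude_pronouns)
    ]


def _nsubj_heads(sentence: Sentence, exclude_pronouns: bool) -> list[Token]:
    return [
        t for t in sentence.tokens
        if t.relation in ("nsubj", "nsubj:pass") and _is_nominal(t, exclude_pronouns)
    ]


def _dobj_heads(sentence: Sentence) -> list[Token]:
    return [t for t in sentence.tokens if t.relation == "obj"]


def _child_relation_count(sentence: Sentence, heads: list[Token],
                          relations: tuple[str, ...]) -> int:
    head_positions = {t.position for t in heads}
    return sum(
        1 for t in sentence.tokens
        if t.governor in head_positions and t.relation in relations
    )


def _prep_count_within(sentence: Sentence, heads: list[Token]) -> int:
    """Adpositions marking a prepositional modifier of any head in ``heads``:
    case tokens whose governor is an nmod/obl child of a head."""
    head_positions = {t.position for t in heads}
    pp_heads = {
        t.position for t in sentence.tokens
        if t.governor in head_positions and t.relation in ("nmod", "obl")
    }
    return sum(
        1 for t in sentence.tokens
        if t.governor in pp_heads and t.relation == "case"
    )


def _population_stdev(counts: list[int]) -> float:
    n = len(counts)
    mean = sum(counts) / n
    return math.sqrt(sum((c - mean) ** 2 for c in counts) / n)


# ---------------------------------------------------------------------------
# index computation
# ---------------------------------------------------------------------------


def _ratio(numerator: float, denominator: int) -> tuple[float | None, int]:
    if denominator == 0:
        return None, 0
    return numerator / denominator, denominator


def _compute(treebank: Treebank, name: str) -> tuple[float | None, int]:
    sentences = treebank.sentences

    if name in ("cc_per_cl", "ccomp_per_cl", "cl_av_deps", "cl_ndeps_std_dev",
                "conj_per_cl", "dobj_per_cl", "mark_per_cl", "prep_per_cl",
                "xcomp_per_cl"):
        anchors_per_sentence = [clause_anchors(s) for s in sentences]
        n_clauses = sum(len(a) for a in anchors_per_sentence)
        if n_clauses == 0:
            return None, 0
        if name == "cl_av_deps" or name == "cl_ndeps_std_dev":
            counts = [
                _dependent_count(s, a.position)
                for s, anchors in zip(sentences, anchors_per_sentence)
                for a in anchors
            ]
            if name == "cl_av_deps":
                return sum(counts) / n_clauses, n_clauses
            return _population_stdev(counts), n_clauses
        if name == "mark_per_cl":
            num = sum(1 for s in sentences for t in s.tokens if t.relation == "mark")
        elif name == "ccomp_per_cl":
            num = sum(1 for s in sentences for t in s.tokens if t.relation == "ccomp")
        elif name == "xcomp_per_cl":
            num = sum(1 for s in sentences for t in s.tokens if t.relation == "xcomp")
        elif name == "dobj_per_cl":
            num = sum(len(_dobj_heads(s)) for s in sentences)
        elif name == "prep_per_cl":
            num = sum(
                1 for s in sentences for t in s.tokens
                if t.relation == "case" and coarse_pos(t.upos) == "ADP"
            )
        elif name == "conj_per_cl":
            # all coordinating-conjunction words
            num = sum(1 for s in sentences for t in s.tokens if t.relation == "cc")
        elif name == "cc_per_cl":
            # clause-level coordinators: cc attached to a verbal head
            num = 0
            for s in sentences:
                verbal = {
                    t.position for t in s.tokens
                    if coarse_pos(t.upos) in ("VERB", "AUX")
                }
                num += sum(
                    1 for t in s.tokens
                    if t.relation == "cc" and t.governor in verbal
                )
        else:  # pragma: no cover
            raise AssertionError(name)
        return num / n_clauses, n_clauses

    if name == "nominal_deps_stdev":
        counts = [
            _dependent_count(s, t.position)
            for s in sentences for t in s.tokens if _is_nominal(t, False)
        ]
        if not counts:
            return None, 0
        return _population_stdev(counts), len(counts)

    if name == "pobj_NN_stdev":
        counts = [
            _dependent_count(s, t.position)
            for s in sentences for t in _pobj_heads(s, exclude_pronouns=True)
        ]
        if not counts:
            return None, 0
        return _population_stdev(counts), len(counts)

    if name == "av_pobj_deps_NN":
        heads = [(s, t) for s in sentences
                 for t in _pobj_heads(s, exclude_pronouns=True)]
        return _ratio(sum(_dependent_count(s, t.position) for s, t in heads),
                      len(heads))

    if name == "av_ncomp_deps_NN":
        heads = [(s, t) for s in sentences
                 for t in _ncomp_heads(s, exclude_pronouns=True)]
        return _ratio(sum(_dependent_count(s, t.position) for s, t in heads),
                      len(heads))

    if name == "amod_all_nominal_deps_NN_struct":
        num = den = 0
        for s in sentences:
            heads = [t for t in s.tokens if _is_nominal(t, True)]
            den += len(heads)
            num += _child_relation_count(s, heads, ("amod",))
        return _ratio(num, den)

    if name == "amod_dobj_deps_struct":
        num = den = 0
        for s in sentences:
            heads = _dobj_heads(s)
            den += len(heads)
            num += _child_relation_count(s, heads, ("amod",))
        return _ratio(num, den)

    if name == "poss_nsubj_deps_NN_struct":
        num = den = 0
        for s in sentences:
            heads = _nsubj_heads(s, exclude_pronouns=True)
            den += len(heads)
            num += _child_relation_count(s, heads, ("nmod:poss",))
        return _ratio(num, den)

    if name == "prep_all_nominal_deps_struct":
        num = den = 0
        for s in sentences:
            heads = [t for t in s.tokens if _is_nominal(t, False)]
            den += len(heads)
            num += _prep_count_within(s, heads)
        return _ratio(num, den)

    if name == "prep_nsubj_deps_NN_struct":
        num = den = 0
        for s in sentences:
            heads = _nsubj_heads(s, exclude_pronouns=True)
            den += len(heads)
            num += _prep_count_within(s, heads)
        return _ratio(num, den)

    if name == "rcmod_nsubj_deps_NN_struct":
        num = den = 0
        for s in sentences:
            heads = _nsubj_heads(s, exclude_pronouns=True)
            den += len(heads)
            num += _child_relation_count(s, heads, ("acl:relcl",))
        return _ratio(num, den)

    if name == "vmod_all_nominal_deps_NN_struct":
        num = den = 0
        for s in sentences:
            heads = [t for t in s.tokens if _is_nominal(t, True)]
            den += len(heads)
            num += _child_relation_count(s, heads, ("acl",))
        return _ratio(num, den)

    raise KeyError(f"unknown index {name!r}")


def compute_index(treebank: Treebank, name: str) -> float | None:
    """One named index for a transcript; ``None`` when the denominator is 0."""
    value, _ = _compute(treebank, name)
    return value


def compute_all_indices(treebank: Treebank) -> IndexVector:
    """The full 20-index catalogue plus TTR for one transcript."""
    vector = IndexVector()
    for name in INDEX_NAMES:
        value, support = _compute(treebank, name)
        vector.values[name] = value
        vector.support[name] = support
    vector.ttr = type_token_ratio(treebank)
    return vector


def type_token_ratio(treebank: Treebank) -> float:
    """Distinct lowercased non-punctuation forms / total non-punctuation tokens.

    Disfluent repetitions count as tokens, so heavily fragmented speech with
    short utterances inflates TTR relative to fluent connected discourse.
    """
    tokens = [
        t.surface_form.lower()
        for s in treebank.sentences for t in s.tokens if not t.is_punct
    ]
    if not tokens:
        raise TreebankError("TTR undefined: no non-punctuation tokens")
    return len(set(tokens)) / len(tokens)
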