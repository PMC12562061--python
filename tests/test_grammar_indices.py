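"""Fine-grained syntactic index catalogue and TTR."""

import numpy as np
import pytest

from synspeech.grammar_indices import (
    INDEX_NAMES,
    ClauseKind,
    clause_anchors,
    compute_all_indices,
    compute_index,
    type_token_ratio,
)
from synspeech.treebank_io import Treebank, TreebankError

from conftest import make_sentence

# hand UD parse of "And he's going to fall because the stool is tilted ."
_BECAUSE_SENTENCE = [
    ("And", "CCONJ", 4, "cc"),
    ("he", "PRON", 4, "nsubj"),
    ("'s", "AUX", 4, "aux"),
    ("going", "VERB", 0, "root"),
    ("to", "PART", 6, "mark"),
    ("fall", "VERB", 4, "xcomp"),
    ("because", "SCONJ", 11, "mark"),
    ("the", "DET", 9, "det"),
    ("stool", "NOUN", 11, "nsubj"),
    ("is", "AUX", 11, "aux"),
    ("tilted", "VERB", 6, "advcl"),
    (".", "PUNCT", 4, "punct"),
]


def simple_clause(noun="boy", verb="runs", uid="u1"):
    return make_sentence([
        ("the", "DET", 2, "det"),
        (noun, "NOUN", 3, "nsubj"),
        (verb, "VERB", 0, "root"),
    ], utterance_id=uid)


class TestClauseAnchors:
    def test_subordinated_sentence_has_clausal_anchors(self):
        anchors = clause_anchors(make_sentence(_BECAUSE_SENTENCE))
        kinds = {a.clause_kind for a in anchors}
        assert len(anchors) >= 2
        assert ClauseKind.ROOT in kinds
        assert ClauseKind.ADVERBIAL in kinds
        assert ClauseKind.OPEN_COMPLEMENT in kinds

    def test_simple_sentence_single_root_anchor(self):
        anchors = clause_anchors(simple_clause())
        assert len(anchors) == 1
        assert anchors[0].clause_kind == ClauseKind.ROOT

    def test_nominal_fragment_is_one_root_clause(self):
        frag = make_sentence([
            ("and", "CCONJ", 3, "cc"),
            ("the", "DET", 3, "det"),
            ("window", "NOUN", 0, "root"),
        ])
        anchors = clause_anchors(frag)
        assert [a.clause_kind for a in anchors] == [ClauseKind.ROOT]

    def test_verb_coordination_counts_as_clause(self):
        s = make_sentence([
            ("he", "PRON", 2, "nsubj"),
            ("ran", "VERB", 0, "root"),
            ("and", "CCONJ", 4, "cc"),
            ("fell", "VERB", 2, "conj"),
        ])
        assert len(clause_anchors(s)) == 2

    def test_noun_coordination_is_not_a_clause(self):
        s = make_sentence([
            ("cups", "NOUN", 0, "root"),
            ("and", "CCONJ", 3, "cc"),
            ("dishes", "NOUN", 1, "conj"),
        ])
        assert len(clause_anchors(s)) == 1


class TestComputeIndex:
    def test_amod_on_nominal(self):
        # "short skirt": one adjectival modifier on one non-pronoun nominal
        s = make_sentence([
            ("short", "ADJ", 2, "amod"),
            ("skirt", "NOUN", 0, "root"),
        ])
        assert compute_index(Treebank([s]), "amod_all_nominal_deps_NN_struct") == 1.0

    def test_no_subordinators_gives_zero(self):
        tb = Treebank([simple_clause(uid=f"u{i}") for i in range(3)])
        assert compute_index(tb, "mark_per_cl") == 0.0

    def test_constant_dependents_per_clause(self):
        # every clause root governs exactly 1 non-punct dependent (the subject)
        tb = Treebank([simple_clause(uid=f"u{i}") for i in range(4)])
        assert compute_index(tb, "cl_av_deps") == 1.0
        assert compute_index(tb, "cl_ndeps_std_dev") == 0.0

    def test_planted_mark_rate(self):
        # 10 clauses total, 3 subordinators -> mark_per_cl = 0.3
        subordinated = make_sentence(_BECAUSE_SENTENCE)  # 3 clauses, 2 marks
        extra_mark = make_sentence([
            ("because", "SCONJ", 4, "mark"),
            ("it", "PRON", 4, "nsubj"),
            ("he", "PRON", 4, "obj"),
            ("fell", "VERB", 0, "root"),
        ])  # 1 clause, 1 mark
        fillers = [simple_clause(uid=f"f{i}") for i in range(6)]  # 6 clauses
        tb = Treebank([subordinated, extra_mark] + fillers)
        total_clauses = sum(len(clause_anchors(s)) for s in tb.sentences)
        assert total_clauses == 10
        assert compute_index(tb, "mark_per_cl") == pytest.approx(0.3)

    def test_zero_denominator_is_none_not_zero(self):
        # no non-pronoun nominal subjects anywhere
        s = make_sentence([("he", "PRON", 2, "nsubj"), ("ran", "VERB", 0, "root")])
        assert compute_index(Treebank([s]), "rcmod_nsubj_deps_NN_struct") is None

    def test_pobj_and_prep_indices(self):
        # "the boy in the kitchen runs": kitchen is object of preposition
        s = make_sentence([
            ("the", "DET", 2, "det"),
            ("boy", "NOUN", 7, "nsubj"),
            ("in", "ADP", 6, "case"),
            ("the", "DET", 6, "det"),
            ("big", "ADJ", 6, "amod"),
            ("kitchen", "NOUN", 2, "nmod"),
            ("runs", "VERB", 0, "root"),
        ])
        tb = Treebank([s])
        # kitchen has dependents in, the, big -> 3
        assert compute_index(tb, "av_pobj_deps_NN") == 3.0
        assert compute_index(tb, "prep_per_cl") == 1.0
        # one prepositional modifier on subject "boy"
        assert compute_index(tb, "prep_nsubj_deps_NN_struct") == 1.0
        # nominals: boy, kitchen -> 1 case marker / 2 nominals
        assert compute_index(tb, "prep_all_nominal_deps_struct") == 0.5

    def test_unknown_index_rejected(self, sample_treebank):
        with pytest.raises(KeyError):
            compute_index(sample_treebank, "no_such_index")


class TestComputeAllIndices:
    def test_vector_covers_catalogue(self, sample_treebank):
        vector = compute_all_indices(sample_treebank)
        assert set(vector.values) == set(INDEX_NAMES)
        assert len(vector.values) == 20
        assert all(name in vector.support for name in INDEX_NAMES)

    def test_empty_modifier_corpus_zero_with_positive_support(self):
        tb = Treebank([simple_clause(uid=f"u{i}") for i in range(3)])
        vector = compute_all_indices(tb)
        assert vector.values["amod_all_nominal_deps_NN_struct"] == 0.0
        assert vector.support["amod_all_nominal_deps_NN_struct"] == 3

    def test_sentence_order_invariance(self):
        s1 = make_sentence(_BECAUSE_SENTENCE, utterance_id="a")
        s2 = simple_clause(uid="b")
        forward = compute_all_indices(Treebank([s1, s2]))
        backward = compute_all_indices(Treebank([s2, s1]))
        assert forward.values == backward.values

    def test_doubling_preserves_ratios_and_lowers_ttr(self):
        s1 = make_sentence(_BECAUSE_SENTENCE, utterance_id="a")
        s2 = simple_clause(uid="b")
        single = Treebank([s1, s2])
        double = Treebank([s1, s2, s1, s2])
        v1, v2 = compute_all_indices(single), compute_all_indices(double)
        for name in INDEX_NAMES:
            if v1.values[name] is None:
                assert v2.values[name] is None
            else:
                assert v2.values[name] == pytest.approx(v1.values[name])
        assert v2.ttr <= v1.ttr

    def test_numerators_match_brute_force_scan(self):
        """Count-based numerators equal a direct token scan on a fixture."""
        tb = Treebank([make_sentence(_BECAUSE_SENTENCE)])
        clauses = sum(len(clause_anchors(s)) for s in tb.sentences)
        marks = sum(1 for s in tb.sentences for t in s.tokens
                    if t.relation == "mark")
        ccs = sum(1 for s in tb.sentences for t in s.tokens if t.relation == "cc")
        assert compute_index(tb, "mark_per_cl") == pytest.approx(marks / clauses)
        assert compute_index(tb, "conj_per_cl") == pytest.approx(ccs / clauses)


class TestTypeTokenRatio:
    def test_all_distinct(self):
        rows = [(f"w{i}", "NOUN", max(0, i), "obj" if i else "root")
                for i in range(10)]
        assert type_token_ratio(Treebank([make_sentence(rows)])) == 1.0

    def test_repeated_token(self):
        s = make_sentence([
            ("the", "DET", 2, "det"), ("The", "NOUN", 0, "root"),
            ("THE", "NOUN", 2, "conj"),
        ])
        assert type_token_ratio(Treebank([s])) == pytest.approx(1 / 3)

    def test_planted_type_count(self):
        # 400 tokens drawn from exactly 50 types -> 0.125
        rng = np.random.default_rng(0)
        sentences = []
        for i in range(40):
            rows = []
            for j in range(10):
                form = f"t{rng.integers(50)}" if (i or j) else "t0"
                rows.append((form, "NOUN", j, "obj" if j else "root"))
            sentences.append(make_sentence(rows, utterance_id=f"u{i}"))
        tb = Treebank(sentences)
        forms = {t.surface_form for s in tb.sentences for t in s.tokens}
        assume_types = len(forms)
        assert type_token_ratio(tb) == pytest.approx(assume_types / 400)

    def test_punctuation_excluded(self, sample_treebank):
        # 10 distinct words + repeated "the" out of 10 non-punct tokens
        assert type_token_ratio(sample_treebank) == pytest.approx(9 / 10)

    def test_empty_is_error(self):
        punct_only = make_sentence([(".", "PUNCT", 0, "root")])
        with pytest.raises(TreebankError):
            type_token_ratio(Treebank([punct_only]))
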