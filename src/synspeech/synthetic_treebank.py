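"""Seeded synthetic dependency treebanks emulating picture-description speech.

Real clinical corpora of connected speech are access-restricted, so every
pipeline stage is exercised on generated data instead.  Transcripts are
assembled from dependency-tree templates (subject-verb-object cores with
optional auxiliaries, determiner/adjective/possessive pre-modifiers,
adpositional post-modifiers, subordinate and relative clauses, existential
*there* frames, phrase- or clause-level coordination, verbless fragments
and disfluent repetitions), with content words drawn Zipf-wise from an
indexed vocabulary over a fixed function-word inventory.

Two presets encode the contrast between an AD-like profile (shorter
utterances, fewer subordinate/relative clauses, more existential frames,
fragments, repetitions and noun-phrase elaboration — hence a lower text
MDD and a more function-word-centred network) and an HC-like profile
(more clausal embedding and coordination, hence a higher text MDD).
Every generated sentence is a valid single-rooted acyclic tree, and
regeneration with the same (profile, seed) is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treebank_io import Sentence, Token, Treebank

__all__ = [
    "SyntacticProfile",
    "GeneratedCorpus",
    "FUNCTION_WORDS",
    "ad_profile",
    "hc_profile",
    "generate_corpus",
    "generate_sentence",
]

# fixed closed-class inventory; these become the function-word vertices of
# the dependency network
_DETERMINERS = ("the", "a")
_PREPOSITIONS = ("in", "on", "of", "from", "with", "under")
_AUXILIARIES = ("is", "was")
_PRONOUNS = ("he", "she", "it", "i", "they")
_POSSESSIVES = ("his", "her", "my")
_COORDINATORS = ("and", "but")
_SUBORDINATORS = ("because", "when", "if")
_COMPLEMENTIZER = "that"
_EXPLETIVE = "there"
_INFINITIVAL = "to"

FUNCTION_WORDS: frozenset[str] = frozenset(
    _DETERMINERS + _PREPOSITIONS + _AUXILIARIES + _PRONOUNS + _POSSESSIVES
    + _COORDINATORS + _SUBORDINATORS + (_COMPLEMENTIZER, _EXPLETIVE, _INFINITIVAL)
)


@dataclass(frozen=True)
class SyntacticProfile:
    """Generation parameters for one group's syntactic style.

    Probabilities are per opportunity: ``p_subordination`` per sentence,
    ``p_relative_clause`` and ``pp_postmod_rate`` per full noun phrase,
    ``adjective_rate`` is the expected adjectival modifiers per nominal.
    """

    p_subordination: float = 0.25
    p_relative_clause: float = 0.10
    p_clausal_coordination: float = 0.20
    p_phrasal_coordination: float = 0.20
    p_existential: float = 0.20
    adjective_rate: float = 0.30
    pp_postmod_rate: float = 0.25
    fragment_rate: float = 0.10
    repetition_rate: float = 0.05
    sentence_length_mean: float = 10.0
    vocab_size: int = 300
    zipf_exponent: float = 1.1
    n_transcripts: int = 150
    sentences_per_transcript_mean: float = 10.0
    p_pronoun_subject: float = 0.25
    p_object: float = 0.6
    p_copular: float = 0.15
    p_reduced_relative: float = 0.3
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("p_subordination", "p_relative_clause",
                     "p_clausal_coordination", "p_phrasal_coordination",
                     "p_existential", "fragment_rate", "repetition_rate",
                     "p_pronoun_subject", "p_object", "p_copular",
                     "p_reduced_relative"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.vocab_size < 10:
            raise ValueError("vocab_size must be >= 10")


def ad_profile() -> SyntacticProfile:
    """AD-like preset: linear, phrase-centred, fragment-prone speech."""
    return SyntacticProfile(
        p_subordination=0.05,
        p_relative_clause=0.04,
        p_clausal_coordination=0.10,
        p_copular=0.22,
        p_phrasal_coordination=0.25,
        p_existential=0.45,
        adjective_rate=0.65,
        pp_postmod_rate=0.55,
        fragment_rate=0.20,
        repetition_rate=0.12,
        sentence_length_mean=11.5,
        zipf_exponent=1.25,
        label="AD",
    )


def hc_profile() -> SyntacticProfile:
    """HC-like preset: hierarchical, clause-centred connected speech."""
    return SyntacticProfile(
        p_subordination=0.45,
        p_relative_clause=0.18,
        p_clausal_coordination=0.35,
        p_copular=0.10,
        p_phrasal_coordination=0.12,
        p_existential=0.10,
        adjective_rate=0.35,
        pp_postmod_rate=0.25,
        fragment_rate=0.05,
        repetition_rate=0.02,
        sentence_length_mean=14.5,
        zipf_exponent=1.05,
        label="HC",
    )


@dataclass
class GeneratedCorpus:
    """A generated two-hundred-odd-sentence corpus with its ground truth.

    ``transcripts`` holds one treebank per synthetic speaker (the
    statistical unit); ``treebank`` is the pooled corpus.
    """

    treebank: Treebank
    transcripts: list[Treebank]
    truth: SyntacticProfile
    seed: int


class _Lexicon:
    """Bounded-Zipf content vocabulary split into noun/verb/adjective classes."""

    def __init__(self, profile: SyntacticProfile) -> None:
        v = profile.vocab_size
        self.sizes = {
            "noun": max(4, int(v * 0.60)),
            "verb": max(3, int(v * 0.25)),
            "adj": max(3, v - int(v * 0.60) - int(v * 0.25)),
        }
        self.probs = {}
        for cls, size in self.sizes.items():
            ranks = np.arange(1, size + 1, dtype=float)
            weights = ranks ** (-profile.zipf_exponent)
            self.probs[cls] = weights / weights.sum()

    def draw(self, cls: str, rng: np.random.Generator) -> str:
        rank = rng.choice(self.sizes[cls], p=self.probs[cls]) + 1
        prefix = {"noun": "n", "verb": "v", "adj": "adj"}[cls]
        return f"{prefix}{rank}"


class _SentenceBuilder:
    """Accumulates tokens in linear order; heads fixed up at the end."""

    def __init__(self) -> None:
        self.forms: list[str] = []
        self.upos: list[str] = []
        self.heads: list[int] = []  # 0-based index of head, -1 = root
        self.rels: list[str] = []

    def add(self, form: str, upos: str, head: int, rel: str) -> int:
        """Append a token; returns its 0-based index.  ``head`` may be -2
        (patched later by the caller) or -1 (root)."""
        self.forms.append(form)
        self.upos.append(upos)
        self.heads.append(head)
        self.rels.append(rel)
        return len(self.forms) - 1

    def to_sentence(self, utterance_id: str, speaker_id: str) -> Sentence:
        tokens = [
            Token(
                position=i + 1,
                surface_form=form,
                upos=upos,
                governor=0 if head == -1 else head + 1,
                relation=rel,
                is_punct=(upos == "PUNCT" or rel == "punct"),
            )
            for i, (form, upos, head, rel)
            in enumerate(zip(self.forms, self.upos, self.heads, self.rels))
        ]
        return Sentence(tokens, utterance_id=utterance_id, speaker_id=speaker_id)


def _gen_np(
    b: _SentenceBuilder,
    rng: np.random.Generator,
    profile: SyntacticProfile,
    lex: _Lexicon,
    head: int,
    rel: str,
    allow_expansion: bool = True,
    allow_pronoun: bool = True,
) -> int:
    """Generate a noun phrase attached to ``head`` via ``rel``; returns the
    index of the phrase's head noun."""
    if allow_pronoun and rng.random() < profile.p_pronoun_subject:
        return b.add(rng.choice(_PRONOUNS), "PRON", head, rel)
    if rng.random() < 0.15:
        poss = b.add(rng.choice(_POSSESSIVES), "PRON", -2, "nmod:poss")
    else:
        poss = None
        det = b.add(rng.choice(_DETERMINERS), "DET", -2, "det")
    n_adj = rng.poisson(profile.adjective_rate)
    adjs = [b.add(lex.draw("adj", rng), "ADJ", -2, "amod") for _ in range(n_adj)]
    noun = b.add(lex.draw("noun", rng), "NOUN", head, rel)
    for idx in ([poss] if poss is not None else [det]) + adjs:
        b.heads[idx] = noun
    if not allow_expansion:
        return noun
    if rng.random() < profile.pp_postmod_rate:
        prep = b.add(rng.choice(_PREPOSITIONS), "ADP", -2, "case")
        inner = _gen_np(b, rng, profile, lex, noun, "nmod",
                        allow_expansion=False, allow_pronoun=False)
        b.heads[prep] = inner
    if rng.random() < profile.p_relative_clause:
        if rng.random() < profile.p_reduced_relative:
            # reduced relative / participial modifier: "the water spilling ..."
            relverb = b.add(lex.draw("verb", rng), "VERB", noun, "acl")
        else:
            relpron = b.add(_COMPLEMENTIZER, "PRON", -2, "nsubj")
            relverb = b.add(lex.draw("verb", rng), "VERB", noun, "acl:relcl")
            b.heads[relpron] = relverb
        if rng.random() < profile.p_object:
            _gen_np(b, rng, profile, lex, relverb, "obj",
                    allow_expansion=False)
    if rng.random() < profile.p_phrasal_coordination:
        cc = b.add(rng.choice(_COORDINATORS), "CCONJ", -2, "cc")
        second = _gen_np(b, rng, profile, lex, noun, "conj",
                         allow_expansion=False, allow_pronoun=False)
        b.heads[cc] = second
    return noun


def _gen_clause(
    b: _SentenceBuilder,
    rng: np.random.Generator,
    profile: SyntacticProfile,
    lex: _Lexicon,
    head: int,
    rel: str,
    depth: int = 0,
) -> int:
    """Generate a finite clause; returns the index of its clause head."""
    if rel == "root" and rng.random() < profile.p_existential:
        # existential frame: "there is NP (PP)" — a flat predication that
        # takes no clausal expansions
        expl = b.add(_EXPLETIVE, "PRON", -2, "expl")
        verb = b.add(rng.choice(_AUXILIARIES), "VERB", head, rel)
        b.heads[expl] = verb
        _gen_np(b, rng, profile, lex, verb, "nsubj", allow_pronoun=False)
        if rng.random() < profile.pp_postmod_rate:
            prep = b.add(rng.choice(_PREPOSITIONS), "ADP", -2, "case")
            obl = _gen_np(b, rng, profile, lex, verb, "obl",
                          allow_expansion=False, allow_pronoun=False)
            b.heads[prep] = obl
        return verb
    if rng.random() < profile.p_copular:
        # copular predication: "the X is a Y" — predicate nominal heads the
        # clause, with cop and nsubj children
        subj = _gen_np(b, rng, profile, lex, -2, "nsubj",
                       allow_expansion=False)
        cop = b.add(rng.choice(_AUXILIARIES), "AUX", -2, "cop")
        verb = _gen_np(b, rng, profile, lex, head, rel, allow_pronoun=False)
        b.heads[subj] = verb
        b.heads[cop] = verb
    else:
        if rng.random() < profile.repetition_rate:
            # disfluent restart: abandoned copy of the subject NP, attached
            # to the true subject as a reparandum
            rep = _gen_np(b, rng, profile, lex, -2, "reparandum",
                          allow_expansion=False, allow_pronoun=False)
            subj = _gen_np(b, rng, profile, lex, -2, "nsubj")
            b.heads[rep] = subj
        else:
            subj = _gen_np(b, rng, profile, lex, -2, "nsubj")
        if rng.random() < 0.4:
            aux = b.add(rng.choice(_AUXILIARIES), "AUX", -2, "aux")
        else:
            aux = None
        verb = b.add(lex.draw("verb", rng), "VERB", head, rel)
        b.heads[subj] = verb
        if aux is not None:
            b.heads[aux] = verb
        if rng.random() < profile.p_object:
            _gen_np(b, rng, profile, lex, verb, "obj")
        # extra adpositional adjunct; rate tied to target sentence length
        p_obl = min(0.9, max(0.05, (profile.sentence_length_mean - 6.0) / 12.0))
        if rng.random() < p_obl:
            prep = b.add(rng.choice(_PREPOSITIONS), "ADP", -2, "case")
            obl = _gen_np(b, rng, profile, lex, verb, "obl",
                          allow_expansion=False, allow_pronoun=False)
            b.heads[prep] = obl

    if depth == 0:
        if rng.random() < profile.p_subordination:
            kind = rng.choice(["advcl", "ccomp", "xcomp"])
            if kind == "advcl":
                mark = b.add(rng.choice(_SUBORDINATORS), "SCONJ", -2, "mark")
                sub = _gen_clause(b, rng, profile, lex, verb, "advcl", depth + 1)
                b.heads[mark] = sub
            elif kind == "ccomp":
                mark = b.add(_COMPLEMENTIZER, "SCONJ", -2, "mark")
                sub = _gen_clause(b, rng, profile, lex, verb, "ccomp", depth + 1)
                b.heads[mark] = sub
            else:
                mark = b.add(_INFINITIVAL, "PART", -2, "mark")
                sub = b.add(lex.draw("verb", rng), "VERB", verb, "xcomp")
                b.heads[mark] = sub
                if rng.random() < profile.p_object:
                    _gen_np(b, rng, profile, lex, sub, "obj",
                            allow_expansion=False)
        if rng.random() < profile.p_clausal_coordination:
            cc = b.add(rng.choice(_COORDINATORS), "CCONJ", -2, "cc")
            second = _gen_clause(b, rng, profile, lex, verb, "conj", depth + 1)
            b.heads[cc] = second
    return verb


def generate_sentence(
    rng: np.random.Generator,
    profile: SyntacticProfile,
    lex: _Lexicon | None = None,
    utterance_id: str = "u1",
    speaker_id: str = "",
) -> Sentence:
    """One synthetic utterance: a fragment or a finite clause with a period."""
    lex = lex or _Lexicon(profile)
    b = _SentenceBuilder()
    if rng.random() < profile.fragment_rate:
        # verbless phrase-only unit, e.g. "and the window"
        if rng.random() < 0.5:
            cc = b.add(rng.choice(_COORDINATORS), "CCONJ", -2, "cc")
        else:
            cc = None
        noun = _gen_np(b, rng, profile, lex, -1, "root", allow_pronoun=False)
        if cc is not None:
            b.heads[cc] = noun
    else:
        root = _gen_clause(b, rng, profile, lex, -1, "root")
        punct = b.add(".", "PUNCT", root, "punct")
        del punct
    return b.to_sentence(utterance_id, speaker_id)


def generate_corpus(
    profile: SyntacticProfile, seed: int
) -> GeneratedCorpus:
    """Generate a full multi-transcript corpus deterministically from a seed."""
    rng = np.random.default_rng(seed)
    lex = _Lexicon(profile)
    transcripts: list[Treebank] = []
    all_sentences: list[Sentence] = []
    for t in range(profile.n_transcripts):
        speaker = f"{profile.label or 'spk'}-{t + 1:03d}"
        n_sent = max(1, int(rng.poisson(profile.sentences_per_transcript_mean)))
        sentences = [
            generate_sentence(rng, profile, lex,
                              utterance_id=f"{speaker}-u{i + 1}",
                              speaker_id=speaker)
            for i in range(n_sent)
        ]
        transcripts.append(
            Treebank(sentences, group_label=profile.label, source_path=speaker)
        )
        all_sentences.extend(sentences)
    pooled = Treebank(all_sentences, group_label=profile.label,
                      source_path=f"synthetic:{profile.label}:{seed}")
    return GeneratedCorpus(
        treebank=pooled, transcripts=transcripts, truth=profile, seed=seed
    )
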