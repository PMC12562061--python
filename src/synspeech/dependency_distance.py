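"""Mean dependency distance (MDD) at sentence and text level.

The dependency distance of a syntactic link is the absolute difference
between the linear positions of a dependent and its governor.  Sentence
MDD averages these distances; text MDD pools all links of a treebank and
divides by (total words - number of sentences), so it is *not* the mean
of per-sentence values.

Two published conventions disagree on whether punctuation links enter the
sum and on the denominator, so both are provided as named presets:

``published_example``
    punctuation links included, denominator = (non-punctuation words - 1)
    per sentence — reproduces the worked 2.33 derivation for the sample
    sentence "The young lad is going to fall from the stool."

``stated_rule``
    punctuation links excluded, denominator = (words - sentences) — the
    stated rule that distances of punctuation marks and root tags are
    excluded from the calculation.

A third denominator mode, ``links_count``, divides by the number of links
actually used (this reproduces printed per-example values such as 1.67 for
"The mother was drying her dishes.").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .treebank_io import Sentence, Treebank, TreebankError

logger = logging.getLogger("synspeech")

__all__ = [
    "DependencyLink",
    "MddConvention",
    "MddResult",
    "PUBLISHED_EXAMPLE",
    "STATED_RULE",
    "link_distances",
    "mdd_sentence",
    "mdd_text",
]

_DENOMINATOR_MODES = ("words_minus_one", "links_count", "tokens_minus_sentences")


@dataclass(frozen=True)
class DependencyLink:
    """One non-root syntactic connection and its linear distance."""

    dependent_pos: int
    governor_pos: int
    relation: str
    distance: int

    def __post_init__(self) -> None:
        assert self.distance == abs(self.governor_pos - self.dependent_pos)


@dataclass(frozen=True)
class MddConvention:
    """Which links enter the MDD sum and what divides it."""

    include_punct_links: bool = True
    denominator_mode: str = "words_minus_one"
    name: str = ""

    def __post_init__(self) -> None:
        if self.denominator_mode not in _DENOMINATOR_MODES:
            raise ValueError(
                f"denominator_mode must be one of {_DENOMINATOR_MODES}, "
                f"got {self.denominator_mode!r}"
            )

    @classmethod
    def preset(cls, name: str) -> "MddConvention":
        if name == "published_example":
            return PUBLISHED_EXAMPLE
        if name == "stated_rule":
            return STATED_RULE
        raise ValueError(f"unknown MDD convention preset {name!r}")


PUBLISHED_EXAMPLE = MddConvention(
    include_punct_links=True,
    denominator_mode="words_minus_one",
    name="published_example",
)
STATED_RULE = MddConvention(
    include_punct_links=False,
    denominator_mode="tokens_minus_sentences",
    name="stated_rule",
)


@dataclass
class MddResult:
    """Per-sentence and pooled text MDD under one convention."""

    per_sentence: list[float | None]
    text_value: float
    convention: MddConvention
    n_links_used: int
    n_sentences_used: int = 0
    n_sentences_undefined: int = 0
    numerator: float = 0.0
    denominator: float = 0.0


def link_distances(
    sentence: Sentence, convention: MddConvention = PUBLISHED_EXAMPLE
) -> list[DependencyLink]:
    """All usable dependency links of a sentence.

    Root tokens (governor 0) never emit a link; punctuation links are
    dropped when the convention excludes them.
    """
    links = []
    for token in sentence.tokens:
        if token.governor == 0:
            continue
        if token.is_punct and not convention.include_punct_links:
            continue
        links.append(
            DependencyLink(
                dependent_pos=token.position,
                governor_pos=token.governor,
                relation=token.relation,
                distance=abs(token.governor - token.position),
            )
        )
    return links


def _sentence_denominator(
    sentence: Sentence, links: list[DependencyLink], convention: MddConvention
) -> int:
    # Per sentence, words_minus_one and tokens_minus_sentences coincide:
    # both are (non-punctuation word count - 1).  They differ only in how
    # the text-level pooling is described.
    if convention.denominator_mode == "links_count":
        return len(links)
    return len(sentence.non_punct_tokens()) - 1


def mdd_sentence(
    sentence: Sentence, convention: MddConvention = PUBLISHED_EXAMPLE
) -> float:
    """Sentence MDD: sum of used link distances over the convention's divisor.

    Raises :class:`TreebankError` for sentences where MDD is undefined
    (single-token fragments, no usable links); text-level aggregation
    excludes such sentences instead of failing.
    """
    links = link_distances(sentence, convention)
    denominator = _sentence_denominator(sentence, links, convention)
    if not links or denominator < 1:
        raise TreebankError(
            f"MDD undefined for sentence {sentence.utterance_id!r}: "
            f"{len(links)} usable links, denominator {denominator}"
        )
    return sum(link.distance for link in links) / denominator


def mdd_text(
    treebank: Treebank, convention: MddConvention = PUBLISHED_EXAMPLE
) -> MddResult:
    """Pooled text MDD over every sentence with usable links.

    The text value is (sum of all used distances) / (pooled denominator),
    not the mean of per-sentence values.  Sentences where MDD is undefined
    are excluded from both numerator and denominator and counted in
    ``n_sentences_undefined``.
    """
    numerator = 0.0
    denominator = 0.0
    n_links = 0
    used = 0
    undefined = 0
    per_sentence: list[float | None] = []
    for sentence in treebank.sentences:
        links = link_distances(sentence, convention)
        sent_den = _sentence_denominator(sentence, links, convention)
        if not links or sent_den < 1:
            undefined += 1
            per_sentence.append(None)
            logger.debug("MDD undefined for %s; excluded", sentence.utterance_id)
            continue
        sent_num = sum(link.distance for link in links)
        per_sentence.append(sent_num / sent_den)
        numerator += sent_num
        denominator += sent_den
        n_links += len(links)
        used += 1
    if used == 0:
        raise TreebankError("empty analysis set: no sentence has usable links")
    return MddResult(
        per_sentence=per_sentence,
        text_value=numerator / denominator,
        convention=convention,
        n_links_used=n_links,
        n_sentences_used=used,
        n_sentences_undefined=undefined,
        numerator=numerator,
        denominator=denominator,
    )
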