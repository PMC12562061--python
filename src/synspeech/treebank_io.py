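"""Reading, cleaning, segmenting and validating transcripts and treebanks.

CoNLL-U is the interchange format: ten tab-separated columns per token,
blank lines between sentences, ``# key = value`` comment lines carrying
metadata.  Multiword-token ranges (``1-2``) and empty nodes (``1.1``) carry
no usable head/position for positional dependency analysis and are skipped
with a warning.  The Pajek ``.net`` format (``*Vertices n`` / ``*Arcs``) is
supported for network interchange.

Dependency labels are normalised to a canonical Universal Dependencies v2
inventory; a configurable mapping table translates Stanford-style labels
(``prep``, ``pobj``, ``rcmod``, ``vmod``, ``poss``, ``dobj``) so that
treebanks in either dialect load into the same index semantics.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger("synspeech")

__all__ = [
    "Token",
    "Sentence",
    "Treebank",
    "CleaningConfig",
    "TreebankError",
    "ParseError",
    "ValidationError",
    "STANFORD_TO_UD",
    "PTB_TO_UPOS",
    "coarse_pos",
    "canonical_relation",
    "read_conllu",
    "read_conllu_text",
    "read_conllu_dir",
    "write_conllu",
    "conllu_to_string",
    "clean_transcript",
    "segment_utterances",
    "read_pajek_net",
    "write_pajek_net",
]


class TreebankError(Exception):
    """Base class for treebank I/O and validation failures."""


class ParseError(TreebankError):
    """Malformed input line; message carries file and line number."""


class ValidationError(TreebankError):
    """Structurally invalid sentence (cycle, multiple roots, bad head)."""


# Stanford/CoreNLP dependency labels -> canonical UD v2.  ``prep`` heads an
# adposition in Stanford style; after mapping it is treated as a case marker,
# so index code that counts adpositions sees both dialects identically.
STANFORD_TO_UD: dict[str, str] = {
    "prep": "case",
    "pobj": "nmod",
    "dobj": "obj",
    "iobj": "iobj",
    "rcmod": "acl:relcl",
    "vmod": "acl",
    "partmod": "acl",
    "infmod": "acl",
    "poss": "nmod:poss",
    "possessive": "case",
    "nn": "compound",
    "num": "nummod",
    "tmod": "obl:tmod",
    "npadvmod": "obl:npmod",
    "attr": "xcomp",
    "abbrev": "appos",
    "purpcl": "advcl",
    "complm": "mark",
    "rel": "obj",
}

# Penn-Treebank fine POS tags -> UD UPOS, so that treebanks tagged either way
# expose the same coarse categories to the index layer.
PTB_TO_UPOS: dict[str, str] = {
    "NN": "NOUN", "NNS": "NOUN",
    "NNP": "PROPN", "NNPS": "PROPN",
    "PRP": "PRON", "PRP$": "PRON", "WP": "PRON", "WP$": "PRON", "EX": "PRON",
    "VB": "VERB", "VBD": "VERB", "VBG": "VERB", "VBN": "VERB",
    "VBP": "VERB", "VBZ": "VERB", "MD": "AUX",
    "JJ": "ADJ", "JJR": "ADJ", "JJS": "ADJ",
    "RB": "ADV", "RBR": "ADV", "RBS": "ADV", "WRB": "ADV",
    "IN": "ADP", "TO": "PART", "RP": "PART", "POS": "PART",
    "DT": "DET", "PDT": "DET", "WDT": "DET",
    "CC": "CCONJ", "CD": "NUM", "UH": "INTJ", "FW": "X", "LS": "X",
    "SYM": "SYM",
    ".": "PUNCT", ",": "PUNCT", ":": "PUNCT", "``": "PUNCT", "''": "PUNCT",
    "-LRB-": "PUNCT", "-RRB-": "PUNCT", "HYPH": "PUNCT",
}

_UPOS = {
    "ADJ", "ADP", "ADV", "AUX", "CCONJ", "DET", "INTJ", "NOUN", "NUM",
    "PART", "PRON", "PROPN", "PUNCT", "SCONJ", "SYM", "VERB", "X",
}


def coarse_pos(tag: str) -> str:
    """Map a POS tag (UPOS or Penn Treebank) to a UD UPOS category."""
    if tag in _UPOS:
        return tag
    return PTB_TO_UPOS.get(tag, "X")


def canonical_relation(label: str, mapping: dict[str, str] | None = None) -> str:
    """Normalise a dependency label to the canonical UD v2 inventory."""
    table = STANFORD_TO_UD if mapping is None else mapping
    return table.get(label, label)


@dataclass(frozen=True)
class Token:
    """One word token in a dependency tree.

    ``position`` is the 1-based linear index inside the sentence;
    ``governor`` is 0 for the root token, otherwise the 1-based position of
    the head.
    """

    position: int
    surface_form: str
    upos: str
    governor: int
    relation: str
    is_punct: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"token position must be >= 1, got {self.position}")
        if self.governor < 0:
            raise ValidationError(f"governor must be >= 0, got {self.governor}")
        if self.governor == self.position:
            raise ValidationError(
                f"token at position {self.position} governs itself"
            )


@dataclass
class Sentence:
    """An ordered, validated dependency tree over one utterance."""

    tokens: list[Token]
    utterance_id: str = ""
    speaker_id: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        if n == 0:
            raise ValidationError(f"sentence {self.utterance_id!r}: no tokens")
        positions = [t.position for t in self.tokens]
        if positions != list(range(1, n + 1)):
            raise ValidationError(
                f"sentence {self.utterance_id!r}: positions not contiguous 1..{n}"
            )
        roots = [t for t in self.tokens if t.governor == 0]
        if len(roots) != 1:
            raise ValidationError(
                f"sentence {self.utterance_id!r}: {len(roots)} roots (need exactly 1)"
            )
        for t in self.tokens:
            if t.governor > n:
                raise ValidationError(
                    f"sentence {self.utterance_id!r}: token {t.position} "
                    f"has governor {t.governor} outside 1..{n}"
                )
        # acyclicity: walking head links from any token must reach the root
        for t in self.tokens:
            seen = set()
            g = t.governor
            while g != 0:
                if g in seen:
                    raise ValidationError(
                        f"sentence {self.utterance_id!r}: cycle through position {g}"
                    )
                seen.add(g)
                g = self.tokens[g - 1].governor

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[Token]:
        return iter(self.tokens)

    @property
    def root(self) -> Token:
        return next(t for t in self.tokens if t.governor == 0)

    def non_punct_tokens(self) -> list[Token]:
        return [t for t in self.tokens if not t.is_punct]

    def children(self, position: int) -> list[Token]:
        """Dependents of the token at ``position`` (0 = root pseudo-node)."""
        return [t for t in self.tokens if t.governor == position]


@dataclass
class Treebank:
    """A collection of dependency-parsed utterances for one transcript/group."""

    sentences: list[Sentence]
    group_label: str = ""
    source_path: str = ""

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[Sentence]:
        return iter(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)


@dataclass
class CleaningConfig:
    """Transcript-cleaning rules: filler interjections and stray symbols."""

    interjections: set[str] = field(default_factory=lambda: {"mhh", "umm", "um"})
    strip_symbols: set[str] = field(default_factory=lambda: {"<", ">", "&", "+"})


# ---------------------------------------------------------------------------
# CoNLL-U
# ---------------------------------------------------------------------------

_MWT_ID = re.compile(r"^\d+-\d+$")
_EMPTY_ID = re.compile(r"^\d+\.\d+$")


def _parse_conllu_sentences(
    lines: Iterable[str],
    source: str,
    relation_mapping: dict[str, str] | None,
) -> list[Sentence]:
    sentences: list[Sentence] = []
    rows: list[tuple[int, str, str, int, str]] = []
    sent_id = ""
    speaker = ""

    def flush(line_no: int) -> None:
        nonlocal rows, sent_id, speaker
        if not rows:
            return
        tokens = [
            Token(
                position=pos,
                surface_form=form,
                upos=upos,
                governor=head,
                relation=rel,
                is_punct=(coarse_pos(upos) == "PUNCT" or rel == "punct"),
            )
            for pos, form, upos, head, rel in rows
        ]
        try:
            sentence = Sentence(tokens, utterance_id=sent_id or f"s{len(sentences) + 1}",
                                speaker_id=speaker)
        except ValidationError as exc:
            raise ValidationError(f"{source}: before line {line_no}: {exc}") from exc
        sentences.append(sentence)
        rows, sent_id, speaker = [], "", ""

    line_no = 0
    for line_no, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(line_no)
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key == "sent_id":
                    sent_id = value.strip()
                elif key == "speaker":
                    speaker = value.strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(
                f"{source}:{line_no}: expected 10 tab-separated columns, got {len(cols)}"
            )
        tok_id = cols[0]
        if _MWT_ID.match(tok_id) or _EMPTY_ID.match(tok_id):
            logger.warning("%s:%d: skipping non-basic token line id=%s",
                           source, line_no, tok_id)
            continue
        try:
            position = int(tok_id)
            head = int(cols[6])
        except ValueError as exc:
            raise ParseError(f"{source}:{line_no}: non-integer ID or HEAD field") from exc
        form = cols[1]
        upos = cols[3] if cols[3] != "_" else cols[4]
        relation = canonical_relation(cols[7], relation_mapping)
        rows.append((position, form, upos, head, relation))
    flush(line_no + 1)
    return sentences


def read_conllu_text(
    text: str,
    group_label: str = "",
    source: str = "<string>",
    relation_mapping: dict[str, str] | None = None,
) -> Treebank:
    """Parse CoNLL-U content from a string.  See :func:`read_conllu`."""
    sentences = _parse_conllu_sentences(text.splitlines(), source, relation_mapping)
    if not sentences:
        raise ParseError(f"{source}: no sentences")
    return Treebank(sentences, group_label=group_label, source_path=source)


def read_conllu(
    path: str | Path,
    group_label: str = "",
    relation_mapping: dict[str, str] | None = None,
) -> Treebank:
    """Read a CoNLL-U file into a validated :class:`Treebank`.

    Dependency labels are normalised through ``relation_mapping``
    (default: the Stanford-to-UD table).  Multiword-token and empty-node
    lines are skipped with a logged warning.

    Raises
    ------
    ParseError
        On malformed lines or an empty file, with file and line number.
    ValidationError
        On a cyclic or multi-rooted sentence, naming the sentence.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        sentences = _parse_conllu_sentences(fh, str(path), relation_mapping)
    if not sentences:
        raise ParseError(f"{path}: no sentences")
    return Treebank(sentences, group_label=group_label, source_path=str(path))


def read_conllu_dir(
    directory: str | Path,
    group_label: str = "",
    relation_mapping: dict[str, str] | None = None,
) -> list[Treebank]:
    """Read every ``*.conllu`` file in a directory, one treebank per file."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.conllu"))
    if not paths:
        raise ParseError(f"{directory}: no .conllu files")
    return [read_conllu(p, group_label=group_label, relation_mapping=relation_mapping)
            for p in paths]


def conllu_to_string(treebank: Treebank) -> str:
    """Serialise a treebank to CoNLL-U text (basic token lines only)."""
    chunks: list[str] = []
    for sentence in treebank.sentences:
        lines = []
        if sentence.utterance_id:
            lines.append(f"# sent_id = {sentence.utterance_id}")
        if sentence.speaker_id:
            lines.append(f"# speaker = {sentence.speaker_id}")
        for t in sentence.tokens:
            lines.append("\t".join([
                str(t.position), t.surface_form, "_", t.upos, "_", "_",
                str(t.governor), t.relation, "_", "_",
            ]))
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def write_conllu(treebank: Treebank, path: str | Path) -> None:
    Path(path).write_text(conllu_to_string(treebank), encoding="utf-8")


# ---------------------------------------------------------------------------
# Transcript cleaning and segmentation
# ---------------------------------------------------------------------------


def clean_transcript(raw: str, config: CleaningConfig | None = None) -> str:
    """Remove filler interjections and stray symbols from transcript text.

    Interjections are matched case-insensitively on word boundaries, so the
    filler "um" is removed but the substring inside "summer" is not.
    Internal whitespace is collapsed to single spaces (newlines preserved as
    utterance boundaries); the result may be empty.
    """
    config = config or CleaningConfig()
    text = raw
    for symbol in config.strip_symbols:
        text = text.replace(symbol, " ")
    if config.interjections:
        pattern = r"\b(?:" + "|".join(
            re.escape(w) for w in sorted(config.interjections)
        ) + r")\b"
        text = re.sub(pattern, " ", text, flags=re.IGNORECASE)
    lines = [re.sub(r"[ \t]+", " ", ln).strip() for ln in text.splitlines()]
    return "\n".join(ln for ln in lines if ln)


_TERMINAL = re.compile(r"(?<=[.?!])\s+")


def segment_utterances(raw: str) -> list[str]:
    """Split cleaned transcript text into independent speech units.

    Units are delimited by terminal punctuation (``.?!``) and by line
    breaks, which stand in for dialogue boundaries.  Fragments and
    phrase-only units without terminal punctuation are kept as units of
    their own; no non-whitespace content is dropped.
    """
    units: list[str] = []
    for line in raw.splitlines():
        line = line.strip()
        if not line:
            continue
        units.extend(p.strip() for p in _TERMINAL.split(line) if p.strip())
    return units


# ---------------------------------------------------------------------------
# Pajek .net
# ---------------------------------------------------------------------------


def write_pajek_net(network: "DependencyNetwork", path: str | Path) -> None:
    """Write a network in Pajek ``.net`` format (quoted labels, 1-based ids).

    Arc relation labels are stored after the weight; ``write -> read ->
    write`` is byte-identical.
    """
    lines = [f"*Vertices {len(network.vertices)}"]
    index = {}
    for i, label in enumerate(network.vertices, start=1):
        index[label] = i
        lines.append(f'{i} "{label}"')
    lines.append("*Arcs")
    for (gov, dep, rel), weight in sorted(
        network.arcs.items(), key=lambda kv: (-kv[1], kv[0])
    ):
        lines.append(f"{index[gov]} {index[dep]} {weight} {rel}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_pajek_net(path: str | Path) -> "DependencyNetwork":
    """Read a Pajek ``.net`` file written by :func:`write_pajek_net`.

    Raises :class:`ParseError` on unknown section markers or vertex
    references outside the declared 1-based range.
    """
    from .dependency_network import DependencyNetwork

    path = Path(path)
    vertices: list[str] = []
    arcs: dict[tuple[str, str, str], int] = {}
    section = None
    n_declared = 0
    for line_no, line in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                   start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("*"):
            marker = line.split()[0].lower()
            if marker == "*vertices":
                section = "vertices"
                n_declared = int(line.split()[1])
            elif marker in ("*arcs", "*edges"):
                section = "arcs"
            else:
                raise ParseError(f"{path}:{line_no}: unknown section marker {line!r}")
            continue
        if section == "vertices":
            m = re.match(r'^(\d+)\s+"(.*)"\s*$', line)
            if not m:
                raise ParseError(f"{path}:{line_no}: malformed vertex line {line!r}")
            vertices.append(m.group(2))
        elif section == "arcs":
            parts = line.split(None, 3)
            if len(parts) < 3:
                raise ParseError(f"{path}:{line_no}: malformed arc line {line!r}")
            src, dst, weight = int(parts[0]), int(parts[1]), int(parts[2])
            rel = parts[3] if len(parts) > 3 else ""
            for v in (src, dst):
                if not 1 <= v <= n_declared:
                    raise ParseError(
                        f"{path}:{line_no}: vertex id {v} outside 1..{n_declared}"
                    )
            arcs[(vertices[src - 1], vertices[dst - 1], rel)] = weight
        else:
            raise ParseError(f"{path}:{line_no}: content before any section marker")
    return DependencyNetwork(vertices=vertices, arcs=arcs)
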