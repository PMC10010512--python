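"""Transcript container and CoNLL-like TSV input/output.

Transcripts arrive pre-tokenized and POS-tagged (Penn Treebank style tags);
tagging is an input to this package, not one of its stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Token:
    surface: str
    pos: str
    sentence_index: int


@dataclass
class Transcript:
    participant_id: str
    tokens: list[Token] = field(default_factory=list)
    raw_text: str | None = None

    def __post_init__(self) -> None:
        last = None
        for t in self.tokens:
            if last is not None and t.sentence_index < last:
                raise ValueError("sentence_index must be nondecreasing")
            last = t.sentence_index

    @classmethod
    def from_tuples(
        cls, participant_id: str, tuples, raw_text: str | None = None
    ) -> "Transcript":
        return cls(participant_id, [Token(s, p, i) for s, p, i in tuples], raw_text)

    @property
    def surfaces(self) -> list[str]:
        return [t.surface for t in self.tokens]

    def sentences(self) -> dict[int, list[Token]]:
        out: dict[int, list[Token]] = {}
        for t in self.tokens:
            out.setdefault(t.sentence_index, []).append(t)
        return out

    def to_tsv(self, path) -> None:
        """Write as CoNLL-like TSV: token, POS tag, sentence index."""
        with open(path, "w") as fh:
            fh.write("token\tpos\tsentence_index\n")
            for t in self.tokens:
                fh.write(f"{t.surface}\t{t.pos}\t{t.sentence_index}\n")

    @classmethod
    def from_tsv(cls, path, participant_id: str | None = None) -> "Transcript":
        path = Path(path)
        pid = participant_id if participant_id is not None else path.stem
        tokens: list[Token] = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("token"):
                raise ValueError(f"{path}: expected 'token\\tpos\\tsentence_index' header")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                surface, pos, idx = line.split("\t")
                tokens.append(Token(surface, pos, int(idx)))
        return cls(pid, tokens)


def read_transcript_dir(path) -> list[Transcript]:
    """Read every ``*.tsv`` transcript in a directory, participant id = file stem."""
    return [Transcript.from_tsv(p) for p in sorted(Path(path).glob("*.tsv"))]
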