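"""Content-unit lexicon for picture-description scoring.

A content unit is a predefined object, action, or location depicted in the picture
stimulus (e.g. "dog", "sink" for the Cookie Theft scene). Each unit is related or
unrelated to the depicted scenario and is localized to the left side, the right
side, or both sides of the picture ("kitchen", "family"). The default lexicon
shipped with the package is an editable stand-in for a study-specific scoring
rubric: every analysis parameterizes over the lexicon, which is data, not algorithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

Relatedness = Literal["related", "unrelated"]
Location = Literal["left", "right", "both"]


@dataclass(frozen=True)
class ContentUnit:
    unit_id: str
    surface_forms: tuple[str, ...]
    relatedness: Relatedness
    location: Location

    def __post_init__(self) -> None:
        if not self.surface_forms:
            raise ValueError(f"unit {self.unit_id!r} has no surface forms")
        for form in self.surface_forms:
            if not form or form != form.lower():
                raise ValueError(
                    f"surface form {form!r} of unit {self.unit_id!r} must be a "
                    "non-empty lowercase string"
                )
        if self.relatedness not in ("related", "unrelated"):
            raise ValueError(f"bad relatedness {self.relatedness!r}")
        if self.location not in ("left", "right", "both"):
            raise ValueError(f"bad location {self.location!r}")


@dataclass
class ContentUnitLexicon:
    entries: list[ContentUnit] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.unit_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("unit_ids must be unique")
        seen: dict[str, str] = {}
        for e in self.entries:
            for form in e.surface_forms:
                if form in seen and seen[form] != e.unit_id:
                    raise ValueError(
                        f"surface form {form!r} maps to both {seen[form]!r} "
                        f"and {e.unit_id!r}"
                    )
                seen[form] = e.unit_id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def surface_map(self) -> dict[tuple[str, ...], ContentUnit]:
        """Map from tokenized surface form to its unit."""
        out: dict[tuple[str, ...], ContentUnit] = {}
        for e in self.entries:
            for form in e.surface_forms:
                out[tuple(form.split())] = e
        return out

    def to_json(self, path) -> None:
        payload = [
            {
                "unit_id": e.unit_id,
                "surface_forms": list(e.surface_forms),
                "relatedness": e.relatedness,
                "location": e.location,
            }
            for e in self.entries
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ContentUnitLexicon":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload) -> "ContentUnitLexicon":
        return cls(
            [
                ContentUnit(
                    d["unit_id"],
                    tuple(d["surface_forms"]),
                    d["relatedness"],
                    d["location"],
                )
                for d in payload
            ]
        )


def default_lexicon() -> ContentUnitLexicon:
    """Default Cookie Theft content-unit lexicon shipped with the package."""
    text = resources.files("pdmci.data").joinpath("cookie_theft_lexicon.json").read_text()
    return ContentUnitLexicon._from_payload(json.loads(text))
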