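"""Feature registry: the named acoustic and language features the pipeline handles.

The default registry mirrors the study design this package supports: 44 acoustic
features computed from recorded picture-description responses (including six vocal
tremor measures that may be missing for some participants) and 47 language features
computed from transcripts. Acoustic features enter the pipeline as externally
supplied or synthetic columns; language features can be recomputed from transcripts
by :mod:`pdmci.scoring`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal

Modality = Literal["acoustic", "language"]

#: The six vocal-tremor measures that PRAAT-style extraction can fail to produce.
TREMOR_FEATURES = ("ATrP", "FTrP", "ATrI", "FTrI", "ATrF", "FTrF")

# Content-unit count features derived from the picture-description lexicon.
CONTENT_UNIT_FEATURES = (
    "Count of DISTINCT RELATED content units",
    "Count of RELATED content units",
    "Count of ALL content units",
    "Count of ALL DISTINCT content units",
    "Count of content units on RIGHT side of picture",
    "Count of DISTINCT content units on RIGHT side of picture",
    "Count of content units on LEFT side of picture",
    "Count of DISTINCT content units on LEFT side of picture",
    "Both Sides Total Content Units",
    "Both Sides Total Content Units DISTINCT",
)

LEXICAL_FEATURES = (
    "Count of nouns",
    "Count of prepositions",
    "Count of indefinite articles",
    "Count of modals",
    "Count of all function words",
    "Pro-sentences",
    "Count of verbs",
    "Count of adjectives",
    "Count of adverbs",
    "Count of pronouns",
    "Count of determiners",
    "Count of conjunctions",
    "Count of definite articles",
    "Count of proper nouns",
    "Count of cardinal numbers",
    "Count of wh-words",
    "Count of gerunds",
    "Count of past tense verbs",
    "Count of negations",
    "Count of interjections",
    "Count of fillers",
)

LENGTH_FEATURES = (
    "Count of words",
    "Count of Syllables",
    "Count of sentences",
    "Count of complete sentences",
    "Count of phrases",
    "Syllables per word min",
    "Syllables per word max",
    "Mean syllables per word",
    "Mean words per sentence",
    "Max words in a sentence",
    "Min words in a sentence",
    "Count of unique words",
    "Type token ratio",
    "Mean word length",
    "Max word length",
    "Count of long words",
)

#: All 47 default language features, in registry order.
LANGUAGE_FEATURES = CONTENT_UNIT_FEATURES + LEXICAL_FEATURES + LENGTH_FEATURES

# Acoustic feature names. These are column labels only: the pipeline never computes
# them from audio; they arrive from an external extractor or the synthetic generator.
ACOUSTIC_FEATURES = (
    "Acoustics mean of F0",
    "Acoustics standard deviation of F0",
    "Acoustics median of F0",
    "Acoustics minimum of F0",
    "Acoustics maximum of F0",
    "Acoustics range of F0",
    "Jitter local",
    "Jitter rap",
    "Jitter ppq5",
    "Jitter ddp",
    "Shimmer local",
    "Shimmer apq3",
    "Shimmer apq5",
    "Shimmer apq11",
    "Shimmer dda",
    "Harmonics to noise ratio mean",
    "Harmonics to noise ratio sd",
    "Intensity mean",
    "Intensity sd",
    "Intensity minimum",
    "Intensity maximum",
    "Speech rate",
    "Articulation rate",
    "Count of pauses",
    "Total pause duration",
    "Mean pause duration",
    "Speech breaks",
    "Voiced fraction",
    "Phonation time",
    "Response duration",
    "Formant F1 mean",
    "Formant F1 sd",
    "Formant F2 mean",
    "Formant F2 sd",
    "Formant F3 mean",
    "Formant F3 sd",
    "Spectral tilt",
    "Cepstral peak prominence",
) + TREMOR_FEATURES

# Language features that are counts of response material; these load on the shared
# verbosity factor in the synthetic generator and shift downward in amnestic MCI.
COUNT_TYPE_FEATURES = CONTENT_UNIT_FEATURES + (
    "Count of nouns",
    "Count of prepositions",
    "Count of indefinite articles",
    "Count of all function words",
    "Count of verbs",
    "Count of words",
    "Count of Syllables",
    "Count of sentences",
    "Count of complete sentences",
    "Count of phrases",
    "Count of unique words",
)


@dataclass(frozen=True)
class Feature:
    name: str
    modality: Modality
    may_be_missing: bool = False


@dataclass
class FeatureRegistry:
    """Ordered collection of named features with modality and missingness metadata."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names in registry: {dupes}")

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    def by_modality(self, modality: Modality) -> list[str]:
        return [f.name for f in self.features if f.modality == modality]

    @property
    def language(self) -> list[str]:
        return self.by_modality("language")

    @property
    def acoustic(self) -> list[str]:
        return self.by_modality("acoustic")

    @property
    def may_be_missing(self) -> list[str]:
        return [f.name for f in self.features if f.may_be_missing]

    def modality_of(self, name: str) -> Modality:
        for f in self.features:
            if f.name == name:
                return f.modality
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def to_json(self, path) -> None:
        payload = [
            {"name": f.name, "modality": f.modality, "may_be_missing": f.may_be_missing}
            for f in self.features
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FeatureRegistry":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            [
                Feature(d["name"], d["modality"], bool(d.get("may_be_missing", False)))
                for d in payload
            ]
        )

    @classmethod
    def from_names(
        cls,
        acoustic: Iterable[str] = (),
        language: Iterable[str] = (),
        may_be_missing: Iterable[str] = (),
    ) -> "FeatureRegistry":
        missing = set(may_be_missing)
        feats = [Feature(n, "acoustic", n in missing) for n in acoustic]
        feats += [Feature(n, "language", n in missing) for n in language]
        return cls(feats)


def default_registry() -> FeatureRegistry:
    """The default 44-acoustic / 47-language registry.

    Exactly the six vocal-tremor measures are flagged as possibly missing.
    """
    return FeatureRegistry.from_names(
        acoustic=ACOUSTIC_FEATURES,
        language=LANGUAGE_FEATURES,
        may_be_missing=TREMOR_FEATURES,
    )
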