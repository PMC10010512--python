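"""Transcript-derived language features.

Three groups of features are computed from a pre-tagged transcript:

* content-unit counts — mentions of lexicon units under RELATED/ALL, DISTINCT and
  side-of-picture (LEFT/RIGHT/Both Sides) filters;
* lexical-category counts — words per part-of-speech or closed-class list
  (nouns, prepositions, modals, indefinite articles, function words,
  pro-sentences, ...);
* response-length measures — words, syllables, sentences, phrases and per-word
  syllable statistics.

Content-unit matching is case-insensitive, longest-match-first over multi-token
spans, left-to-right and non-overlapping, so "cookie jar" is counted once as the
jar unit rather than as both "cookie" and "jar".
"""

from __future__ import annotations

import re
from typing import Callable, Iterable

from .lexicon import ContentUnit, ContentUnitLexicon
from .registry import FeatureRegistry, LANGUAGE_FEATURES
from .transcripts import Token, Transcript

# ---------------------------------------------------------------------------
# closed-class default word lists (configurable via ``category_map``)

DEFAULT_FUNCTION_WORDS = frozenset(
    """the a an and or but nor of in on at to with for from by as is are was were be
    been being am he she it they them we us i you me him his her its their our your
    my this that these those there here not no so if then than when while because
    about into over under up down out off some any all both each every who whom
    whose what which where why how do does did done have has had will would can
    could shall should may might must""".split()
)

DEFAULT_PRO_SENTENCES = frozenset(
    "yes no okay ok yeah yep nope alright sure uh-huh mm-hmm".split()
)

DEFAULT_NEGATIONS = frozenset("not n't no never none nothing nobody neither nor".split())

DEFAULT_FILLERS = frozenset("um uh er ah erm hmm mm".split())

_WORD_RE = re.compile(r"[A-Za-z0-9]")

#: tags that mark a finite verb for the complete-sentence rule
FINITE_VERB_TAGS = frozenset({"VBD", "VBP", "VBZ", "MD"})
#: tags that open a new chunk for the phrase-counting rule
_CHUNK_OPENERS = frozenset({"IN", "CC", "WRB", "WDT", "WP", "TO"})


def _is_word(token: Token) -> bool:
    return bool(_WORD_RE.search(token.surface))


def count_syllables(word: str) -> int:
    """Vowel-group heuristic syllable count (≥1 for any word with letters)."""
    w = word.lower()
    groups = re.findall(r"[aeiouy]+", w)
    n = len(groups)
    # silent final 'e' ("theme", "cake") but keep consonant+"le" ("little")
    if n > 1 and w.endswith("e") and not w.endswith(("le", "ee", "ie", "ye", "oe", "ue")):
        n -= 1
    return max(n, 1) if re.search(r"[a-z]", w) else 0


# ---------------------------------------------------------------------------
# content units


def match_content_units(t: Transcript, lex: ContentUnitLexicon) -> list[ContentUnit]:
    """All content-unit mentions in order of occurrence.

    Case-insensitive; multi-token surface forms are matched longest-first,
    left-to-right without overlap.
    """
    surface_map = lex.surface_map
    if not surface_map:
        return []
    max_len = max(len(k) for k in surface_map)
    words = [tok.surface.lower() for tok in t.tokens]
    mentions: list[ContentUnit] = []
    i = 0
    while i < len(words):
        hit = None
        for span in range(min(max_len, len(words) - i), 0, -1):
            unit = surface_map.get(tuple(words[i : i + span]))
            if unit is not None:
                hit = (unit, span)
                break
        if hit is not None:
            mentions.append(hit[0])
            i += hit[1]
        else:
            i += 1
    return mentions


def count_content_units(
    t: Transcript,
    lex: ContentUnitLexicon,
    relatedness_filter: str = "any",
    location_filter: str = "any",
    distinct: bool = False,
) -> int:
    """Count content-unit mentions (or distinct units) passing both filters."""
    if relatedness_filter not in ("related", "any"):
        raise ValueError(f"bad relatedness_filter {relatedness_filter!r}")
    if location_filter not in ("left", "right", "both", "any"):
        raise ValueError(f"bad location_filter {location_filter!r}")
    mentions = [
        u
        for u in match_content_units(t, lex)
        if (relatedness_filter == "any" or u.relatedness == relatedness_filter)
        and (location_filter == "any" or u.location == location_filter)
    ]
    if distinct:
        return len({u.unit_id for u in mentions})
    return len(mentions)


# ---------------------------------------------------------------------------
# lexical categories


def _default_category_map() -> dict[str, Callable[[Token], bool]]:
    def tag_in(*tags: str) -> Callable[[Token], bool]:
        tagset = frozenset(tags)
        return lambda tok: tok.pos in tagset

    def tag_prefix(prefix: str) -> Callable[[Token], bool]:
        return lambda tok: tok.pos.startswith(prefix)

    def surface_in(words: frozenset[str]) -> Callable[[Token], bool]:
        return lambda tok: tok.surface.lower() in words

    return {
        "nouns": tag_prefix("NN"),
        "prepositions": tag_in("IN"),
        "modals": tag_in("MD"),
        "indefinite articles": surface_in(frozenset({"a", "an"})),
        "definite articles": surface_in(frozenset({"the"})),
        "function words": surface_in(DEFAULT_FUNCTION_WORDS),
        "pro-sentences": surface_in(DEFAULT_PRO_SENTENCES),
        "verbs": tag_prefix("VB"),
        "adjectives": tag_prefix("JJ"),
        "adverbs": tag_prefix("RB"),
        "pronouns": tag_in("PRP", "PRP$", "WP", "WP$"),
        "determiners": tag_in("DT", "WDT", "PDT"),
        "conjunctions": tag_in("CC"),
        "proper nouns": tag_in("NNP", "NNPS"),
        "cardinal numbers": tag_in("CD"),
        "wh-words": tag_in("WDT", "WP", "WP$", "WRB"),
        "gerunds": tag_in("VBG"),
        "past tense verbs": tag_in("VBD"),
        "negations": surface_in(DEFAULT_NEGATIONS),
        "interjections": tag_in("UH"),
        "fillers": surface_in(DEFAULT_FILLERS),
    }


def lexical_counts(
    t: Transcript, category_map: dict[str, Callable[[Token], bool]] | None = None
) -> dict[str, int]:
    """Count word tokens per lexical category (POS tags and closed-class lists)."""
    cmap = _default_category_map() if category_map is None else category_map
    counts = {name: 0 for name in cmap}
    for tok in t.tokens:
        if not _is_word(tok):
            continue
        for name, rule in cmap.items():
            if rule(tok):
                counts[name] += 1
    return counts


# ---------------------------------------------------------------------------
# length measures


def _count_phrases(sentence: list[Token]) -> int:
    """Lightweight chunk count: a new phrase opens at the sentence start and at
    each coordinator/preposition/wh-word/infinitival marker."""
    n = 0
    open_ = False
    for tok in sentence:
        if not _is_word(tok):
            open_ = False
            continue
        if not open_ or tok.pos in _CHUNK_OPENERS:
            n += 1
            open_ = True
    return n


def length_measures(
    t: Transcript, syllable_counter: Callable[[str], int] | None = None
) -> dict[str, float]:
    """Response-length measures; empty transcripts score all zeros."""
    syl = syllable_counter or count_syllables
    words = [tok.surface for tok in t.tokens if _is_word(tok)]
    sentences = t.sentences()
    syllables = [syl(w) for w in words]
    sent_words = {
        idx: sum(1 for tok in toks if _is_word(tok)) for idx, toks in sentences.items()
    }
    n_words = len(words)
    complete = 0
    phrases = 0
    for idx, toks in sentences.items():
        tags = {tok.pos for tok in toks}
        if tags & FINITE_VERB_TAGS and any(
            tok.pos.startswith("NN") or tok.pos in ("PRP",) for tok in toks
        ):
            complete += 1
        phrases += _count_phrases(toks)
    lengths = [len(w) for w in words]
    unique = {w.lower() for w in words}
    nonzero_sent = [c for c in sent_words.values() if c > 0]
    return {
        "words": n_words,
        "syllables": sum(syllables),
        "sentences": len(sentences),
        "complete sentences": complete,
        "phrases": phrases,
        "syllables per word min": min(syllables) if syllables else 0,
        "syllables per word max": max(syllables) if syllables else 0,
        "mean syllables per word": (sum(syllables) / n_words) if n_words else 0.0,
        "mean words per sentence": (n_words / len(nonzero_sent)) if nonzero_sent else 0.0,
        "max words in a sentence": max(nonzero_sent) if nonzero_sent else 0,
        "min words in a sentence": min(nonzero_sent) if nonzero_sent else 0,
        "unique words": len(unique),
        "type token ratio": (len(unique) / n_words) if n_words else 0.0,
        "mean word length": (sum(lengths) / n_words) if n_words else 0.0,
        "max word length": max(lengths) if lengths else 0,
        "long words": sum(1 for s in syllables if s >= 3),
    }


# ---------------------------------------------------------------------------
# assembly

_CU = "count_content_units"

#: recipe table: feature name -> (kind, args)
_RECIPES: dict[str, tuple] = {
    "Count of DISTINCT RELATED content units": (_CU, "related", "any", True),
    "Count of RELATED content units": (_CU, "related", "any", False),
    "Count of ALL content units": (_CU, "any", "any", False),
    "Count of ALL DISTINCT content units": (_CU, "any", "any", True),
    "Count of content units on RIGHT side of picture": (_CU, "any", "right", False),
    "Count of DISTINCT content units on RIGHT side of picture": (_CU, "any", "right", True),
    "Count of content units on LEFT side of picture": (_CU, "any", "left", False),
    "Count of DISTINCT content units on LEFT side of picture": (_CU, "any", "left", True),
    "Both Sides Total Content Units": (_CU, "any", "both", False),
    "Both Sides Total Content Units DISTINCT": (_CU, "any", "both", True),
    "Count of nouns": ("lexical", "nouns"),
    "Count of prepositions": ("lexical", "prepositions"),
    "Count of indefinite articles": ("lexical", "indefinite articles"),
    "Count of modals": ("lexical", "modals"),
    "Count of all function words": ("lexical", "function words"),
    "Pro-sentences": ("lexical", "pro-sentences"),
    "Count of verbs": ("lexical", "verbs"),
    "Count of adjectives": ("lexical", "adjectives"),
    "Count of adverbs": ("lexical", "adverbs"),
    "Count of pronouns": ("lexical", "pronouns"),
    "Count of determiners": ("lexical", "determiners"),
    "Count of conjunctions": ("lexical", "conjunctions"),
    "Count of definite articles": ("lexical", "definite articles"),
    "Count of proper nouns": ("lexical", "proper nouns"),
    "Count of cardinal numbers": ("lexical", "cardinal numbers"),
    "Count of wh-words": ("lexical", "wh-words"),
    "Count of gerunds": ("lexical", "gerunds"),
    "Count of past tense verbs": ("lexical", "past tense verbs"),
    "Count of negations": ("lexical", "negations"),
    "Count of interjections": ("lexical", "interjections"),
    "Count of fillers": ("lexical", "fillers"),
    "Count of words": ("length", "words"),
    "Count of Syllables": ("length", "syllables"),
    "Count of sentences": ("length", "sentences"),
    "Count of complete sentences": ("length", "complete sentences"),
    "Count of phrases": ("length", "phrases"),
    "Syllables per word min": ("length", "syllables per word min"),
    "Syllables per word max": ("length", "syllables per word max"),
    "Mean syllables per word": ("length", "mean syllables per word"),
    "Mean words per sentence": ("length", "mean words per sentence"),
    "Max words in a sentence": ("length", "max words in a sentence"),
    "Min words in a sentence": ("length", "min words in a sentence"),
    "Count of unique words": ("length", "unique words"),
    "Type token ratio": ("length", "type token ratio"),
    "Mean word length": ("length", "mean word length"),
    "Max word length": ("length", "max word length"),
    "Count of long words": ("length", "long words"),
}

assert set(_RECIPES) == set(LANGUAGE_FEATURES)


def extract_language_features(
    t: Transcript,
    lex: ContentUnitLexicon,
    registry: FeatureRegistry,
    category_map: dict[str, Callable[[Token], bool]] | None = None,
    syllable_counter: Callable[[str], int] | None = None,
) -> dict[str, float]:
    """Assemble every language feature the registry declares for one transcript."""
    wanted = registry.language
    unknown = [name for name in wanted if name not in _RECIPES]
    if unknown:
        raise KeyError(f"no recipe for language feature(s): {unknown}")
    lex_counts = lexical_counts(t, category_map)
    lengths = length_measures(t, syllable_counter)
    out: dict[str, float] = {}
    for name in wanted:
        recipe = _RECIPES[name]
        if recipe[0] == _CU:
            _, rel, loc, distinct = recipe
            out[name] = count_content_units(t, lex, rel, loc, distinct)
        elif recipe[0] == "lexical":
            out[name] = lex_counts[recipe[1]]
        else:
            out[name] = lengths[recipe[1]]
    return out


def score_transcripts(
    transcripts: Iterable[Transcript],
    lex: ContentUnitLexicon,
    registry: FeatureRegistry,
    **kwargs,
):
    """Score many transcripts into a participant × language-feature DataFrame."""
    import pandas as pd

    rows = {
        t.participant_id: extract_language_features(t, lex, registry, **kwargs)
        for t in transcripts
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "participant_id"
    return df[registry.language]
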