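"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from pdmci.cohort import SyntheticConfig, generate_cohort, participants_frame
from pdmci.lexicon import ContentUnit, ContentUnitLexicon, default_lexicon
from pdmci.prep import quantile_normalize
from pdmci.registry import default_registry
from pdmci.transcripts import Transcript


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def toy_lexicon():
    return ContentUnitLexicon([
        ContentUnit("dog", ("dog",), "related", "left"),
        ContentUnit("sink", ("sink",), "related", "right"),
        ContentUnit("kitchen", ("kitchen",), "related", "both"),
        ContentUnit("jar", ("jar", "cookie jar"), "related", "left"),
        ContentUnit("garden", ("garden",), "unrelated", "right"),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (62/18/15), shared across tests."""
    participants, table, log = generate_cohort(SyntheticConfig(seed=11))
    return participants, table, participants_frame(participants), log


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    participants, table, pdf, _ = default_cohort
    return participants, quantile_normalize(table), pdf


def make_transcript(text: str, pid: str = "p1") -> Transcript:
    """Build a transcript from space-separated tokens; naive tags, one sentence
    per '.' token."""
    tokens = []
    sent = 0
    for word in text.split():
        tag = "." if word == "." else "NN"
        tokens.append((word, tag, sent))
        if word == ".":
            sent += 1
    return Transcript.from_tuples(pid, tokens)


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_auroc(scores, labels) -> float:
    """Pair-counting AUROC: wins + half-ties over all case-control pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(controls))


def brute_force_content_counts(tokens_lower, lexicon):
    """Token-window scanner independent of the package implementation.

    Enumerates every candidate (position, span) match, then resolves them
    left-to-right, preferring longer spans, without overlap. Returns the
    ordered list of matched units.
    """
    smap = lexicon.surface_map
    candidates = {}
    for start in range(len(tokens_lower)):
        for key, unit in smap.items():
            span = len(key)
            if tuple(tokens_lower[start : start + span]) == key:
                prev = candidates.get(start)
                if prev is None or span > prev[0]:
                    candidates[start] = (span, unit)
    matched = []
    pos = 0
    while pos < len(tokens_lower):
        if pos in candidates:
            span, unit = candidates[pos]
            matched.append(unit)
            pos += span
        else:
            pos += 1
    return matched


def exhaustive_best_threshold(scores, labels, min_specificity):
    """Exhaustive search over every candidate threshold (midpoints and ±inf)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(scores)
    cands = [-np.inf, np.inf] + list((uniq[:-1] + uniq[1:]) / 2)
    best = None
    for th in cands:
        pred = scores > th
        tp = np.sum(pred & (labels == 1))
        fp = np.sum(pred & (labels == 0))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        spec = tn / (tn + fp) if tn + fp else 0.0
        if spec < min_specificity:
            continue
        sens = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * sens / (prec + sens) if prec + sens > 0 else 0.0
        key = (f1, spec, th)
        if best is None or key > best:
            best = key
    return best  # (f1, specificity, threshold)
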