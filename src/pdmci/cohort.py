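"""Synthetic cohort generator.

Generates participant tables, feature matrices and toy transcripts with the
statistical structure the downstream analysis assumes: a three-group cohort
(healthy controls, amnestic MCI, non-amnestic MCI), correlated count-type
language features through a shared verbosity factor, group-specific mean shifts
on a latent standard-normal scale, and missingness confined to the six vocal
tremor measures. Defaults mirror the study design this pipeline supports:
62 HC / 18 aMCI / 15 naMCI, ages 64-85, count features depressed in aMCI,
pitch variability (F0 SD) elevated in aMCI, and near-null naMCI effects.

Because every feature is quantile normalized downstream, the generator works on
a latent Gaussian scale and only optionally maps count-type features through a
monotone link to nonnegative rounded counts; the native scale is immaterial to
the analysis.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .lexicon import ContentUnitLexicon
from .registry import (
    COUNT_TYPE_FEATURES,
    FeatureRegistry,
    default_registry,
)
from .tables import FeatureTable
from .transcripts import Token, Transcript

GROUPS = ("HC", "aMCI", "naMCI")

#: group → (age mean, age sd, female fraction), following the cohort's
#: demographic structure (HC 35/62 female, aMCI 6/18, naMCI 6/15).
DEFAULT_AGE_GENDER = {
    "HC": {"age_mean": 70.3, "age_sd": 4.5, "female_fraction": 35 / 62},
    "aMCI": {"age_mean": 70.2, "age_sd": 7.4, "female_fraction": 6 / 18},
    "naMCI": {"age_mean": 71.5, "age_sd": 5.8, "female_fraction": 6 / 15},
}

#: default latent shift (in SD units) of count-type features in the aMCI group
DEFAULT_COUNT_SHIFT = -1.2
#: default latent shift of F0 variability in the aMCI group
DEFAULT_F0SD_SHIFT = 0.8


def default_effect_map() -> dict[str, dict[str, float]]:
    """aMCI-specific shifts: count features down, F0 variability up; naMCI null."""
    effects: dict[str, dict[str, float]] = {
        f: {"aMCI": DEFAULT_COUNT_SHIFT} for f in COUNT_TYPE_FEATURES
    }
    effects["Acoustics standard deviation of F0"] = {"aMCI": DEFAULT_F0SD_SHIFT}
    return effects


@dataclass(frozen=True)
class Participant:
    id: str
    diagnosis: str
    age: float
    gender: str  # "female" or "male"

    def __post_init__(self) -> None:
        if self.diagnosis not in GROUPS:
            raise ValueError(f"diagnosis must be one of {GROUPS}, got {self.diagnosis!r}")
        if self.gender not in ("female", "male"):
            raise ValueError(f"gender must be female/male, got {self.gender!r}")


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic cohort.

    ``effect_map`` maps feature → (group → latent shift in SD units).
    ``verbosity_loading`` is the loading of count-type language features on a
    shared verbosity factor, inducing the correlation among response-length
    counts that the contrast analysis presumes.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"HC": 62, "aMCI": 18, "naMCI": 15}
    )
    effect_map: dict[str, dict[str, float]] = field(default_factory=default_effect_map)
    missing_rate: float = 0.05
    age_gender_model: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_AGE_GENDER.items()}
    )
    age_range: tuple[float, float] = (64.0, 85.0)
    verbosity_loading: float = 0.6
    use_count_link: bool = True
    count_link_mean: float = 20.0
    count_link_sd: float = 8.0
    #: per-group Poisson rate of related content-unit mentions in toy transcripts
    transcript_related_rate: dict[str, float] = field(
        default_factory=lambda: {"HC": 8.0, "aMCI": 4.0, "naMCI": 7.0}
    )
    transcript_unrelated_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"negative count for group {g!r}: {n}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"missing_rate must be in [0,1], got {self.missing_rate}")
        for f, shifts in self.effect_map.items():
            for g, d in shifts.items():
                if not np.isfinite(d):
                    raise ValueError(f"non-finite shift for {f!r} in {g!r}")
                if g not in GROUPS:
                    raise ValueError(f"unknown group {g!r} in effect_map")
                if self.n_per_group.get(g, 0) == 0 and d != 0.0:
                    warnings.warn(
                        f"effect on {f!r} requested for empty group {g!r}", stacklevel=3
                    )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def generate_cohort(
    config: SyntheticConfig, registry: FeatureRegistry | None = None
) -> tuple[list[Participant], FeatureTable, dict]:
    """Generate a synthetic cohort: participants, a feature matrix, and a log.

    Latent feature values are standard normal per group plus ``effect_map``
    shifts; count-type language features share a verbosity factor; count-type
    features are optionally mapped through a monotone rounded link; missing
    entries are injected only into ``may_be_missing`` features.
    """
    registry = registry if registry is not None else default_registry()
    config.validate()
    if not registry.language or not registry.acoustic:
        raise ValueError("registry must define at least one feature per modality")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range

    participants: list[Participant] = []
    rows = []
    count_set = set(COUNT_TYPE_FEATURES)
    load = config.verbosity_loading
    resid = float(np.sqrt(1.0 - load * load))
    names = registry.names

    for group in GROUPS:
        n = config.n_per_group.get(group, 0)
        ag = config.age_gender_model[group]
        ages = _truncated_normal(rng, ag["age_mean"], ag["age_sd"], lo, hi, n)
        female = rng.random(n) < ag["female_fraction"]
        verbosity = rng.normal(size=n)
        eps = rng.normal(size=(n, len(names)))
        for i in range(n):
            pid = f"{group}-{i + 1:03d}"
            participants.append(
                Participant(pid, group, float(np.round(ages[i], 1)),
                            "female" if female[i] else "male")
            )
            row = {}
            for j, f in enumerate(names):
                shift = config.effect_map.get(f, {}).get(group, 0.0)
                if f in count_set:
                    z = load * verbosity[i] + resid * eps[i, j] + shift
                    if config.use_count_link:
                        row[f] = float(
                            max(0.0, np.round(config.count_link_mean
                                              + config.count_link_sd * z))
                        )
                    else:
                        row[f] = float(z)
                else:
                    row[f] = float(eps[i, j] + shift)
            rows.append(row)

    df = pd.DataFrame(rows, index=[p.id for p in participants])
    df.index.name = "participant_id"

    # missingness confined to the registry's may_be_missing features
    for f in registry.may_be_missing:
        mask = rng.random(len(df)) < config.missing_rate
        df.loc[mask, f] = np.nan

    table = FeatureTable(df, registry, normalized=False)
    log = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "n_participants": len(participants),
        "n_features": len(registry),
    }
    return participants, table, log


# ---------------------------------------------------------------------------
# toy transcripts

_FILLER_SENTENCES = [
    [("it", "PRP"), ("looks", "VBZ"), ("busy", "JJ"), (".", ".")],
    [("everything", "NN"), ("seems", "VBZ"), ("fine", "JJ"), (".", ".")],
    [("they", "PRP"), ("are", "VBP"), ("not", "RB"), ("paying", "VBG"),
     ("attention", "NN"), (".", ".")],
]

def _mention_sentence(form: str) -> list[tuple[str, str]]:
    toks: list[tuple[str, str]] = [("there", "EX"), ("is", "VBZ"), ("a", "DT")]
    parts = form.split()
    for k, w in enumerate(parts):
        toks.append((w, "NN" if k == len(parts) - 1 else "JJ"))
    toks.append((".", "."))
    return toks


def generate_transcripts(
    config: SyntheticConfig,
    lexicon: ContentUnitLexicon,
    participants: list[Participant] | None = None,
) -> tuple[list[Transcript], list[dict]]:
    """Generate toy transcripts with known ground-truth content-unit counts.

    Each participant's transcript mentions Poisson(rate) related units (rate per
    diagnosis group) and Poisson(unrelated rate) unrelated units, each in its own
    short template sentence, interleaved with filler sentences. The returned
    ground truth gives, per transcript, the true ALL/RELATED/DISTINCT and
    per-side counts implied by the sampled mentions.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon must be non-empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    if participants is None:
        participants = generate_cohort(config)[0]

    related = [u for u in lexicon if u.relatedness == "related"]
    unrelated = [u for u in lexicon if u.relatedness == "unrelated"]

    transcripts: list[Transcript] = []
    truths: list[dict] = []
    for p in participants:
        lam = config.transcript_related_rate.get(p.diagnosis, 0.0)
        n_rel = rng.poisson(lam) if lam > 0 and related else 0
        n_unrel = (
            rng.poisson(config.transcript_unrelated_rate)
            if config.transcript_unrelated_rate > 0 and unrelated
            else 0
        )
        mentions = []
        if n_rel:
            mentions += [related[k] for k in rng.integers(0, len(related), n_rel)]
        if n_unrel:
            mentions += [unrelated[k] for k in rng.integers(0, len(unrelated), n_unrel)]

        tokens: list[Token] = []
        sent = 0
        for u in mentions:
            form = u.surface_forms[0]
            for s, tag in _mention_sentence(form):
                tokens.append(Token(s, tag, sent))
            sent += 1
            if rng.random() < 0.3:
                filler = _FILLER_SENTENCES[rng.integers(0, len(_FILLER_SENTENCES))]
                for s, tag in filler:
                    tokens.append(Token(s, tag, sent))
                sent += 1
        if not mentions:
            filler = _FILLER_SENTENCES[rng.integers(0, len(_FILLER_SENTENCES))]
            for s, tag in filler:
                tokens.append(Token(s, tag, sent))

        truth = {
            "participant_id": p.id,
            "ALL": len(mentions),
            "RELATED": sum(1 for u in mentions if u.relatedness == "related"),
            "ALL DISTINCT": len({u.unit_id for u in mentions}),
            "DISTINCT RELATED": len(
                {u.unit_id for u in mentions if u.relatedness == "related"}
            ),
            "LEFT": sum(1 for u in mentions if u.location == "left"),
            "RIGHT": sum(1 for u in mentions if u.location == "right"),
            "Both Sides": sum(1 for u in mentions if u.location == "both"),
        }
        transcripts.append(Transcript(p.id, tokens))
        truths.append(truth)
    return transcripts, truths


# ---------------------------------------------------------------------------
# serialization


def write_cohort(outdir, participants: list[Participant], table: FeatureTable,
                 config: SyntheticConfig, log: dict) -> None:
    """Write participants CSV, features CSV, and the ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"participant_id": p.id, "diagnosis": p.diagnosis, "age": p.age,
          "gender": p.gender} for p in participants]
    ).set_index("participant_id").to_csv(outdir / "participants.csv")
    table.to_csv(outdir / "features.csv")
    truth = {"seed": config.seed, "effect_map": config.effect_map, "log": log}
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def participants_frame(participants: list[Participant]) -> pd.DataFrame:
    """Participants as a DataFrame indexed by id, gender coded female=0, male=1."""
    df = pd.DataFrame(
        [{"participant_id": p.id, "diagnosis": p.diagnosis, "age": p.age,
          "gender": 0 if p.gender == "female" else 1} for p in participants]
    ).set_index("participant_id")
    return df
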