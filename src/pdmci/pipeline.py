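"""End-to-end pipeline orchestration with reproducibility plumbing.

A single global seed expands deterministically into per-stage seeds; every
output file is declared in a manifest with a content hash, so a rerun with the
same configuration is bitwise identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .cohort import (
    SyntheticConfig,
    generate_cohort,
    generate_transcripts,
    participants_frame,
    write_cohort,
)
from .lexicon import ContentUnitLexicon, default_lexicon
from .prep import build_contrasts, quantile_normalize
from .registry import FeatureRegistry, default_registry
from .risk import RiskConfig, PDRiskModel, TASKS, report_tables
from .scoring import score_transcripts
from .screen import FeatureScreen
from .tables import FeatureTable

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "prep", "screen", "riskscore", "report")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed, deterministically."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of the full workflow.

    Defaults reproduce the analysis settings this pipeline implements:
    5 CV folds, 10 CV repeats, Benjamini–Yekutieli FDR, specificity floor 0.85.
    """

    seed: int = 0
    out_dir: str = "pdmci_out"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    registry_path: str | None = None
    lexicon_path: str | None = None
    folds: int = 5
    repeats: int = 10
    fdr_method: str = "by"
    min_specificity: float = 0.85
    risk: RiskConfig = field(default_factory=RiskConfig)
    tasks: tuple[str, ...] = TASKS
    #: compute per-contrast CV classifiers too (slower); association always runs
    contrast_classifiers: bool = False
    skip: tuple[str, ...] = ()

    def validate(self) -> None:
        bad = [s for s in self.skip if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) in skip: {bad}")
        if self.fdr_method != "by":
            raise ValueError("only the Benjamini–Yekutieli FDR is supported")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**raw.pop("synthetic", {}))
        risk = RiskConfig(**raw.pop("risk", {}))
        for key in ("skip", "tasks"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=syn, risk=risk, **raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = (FeatureRegistry.from_json(config.registry_path)
                if config.registry_path else default_registry())
    lexicon = (ContentUnitLexicon.from_json(config.lexicon_path)
               if config.lexicon_path else default_lexicon())
    syn = config.synthetic
    cfg_dict = asdict(config)
    cfg_dict.pop("out_dir", None)  # hash the analysis configuration, not the location
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "stages": {},
        "files": {},
    }

    def record(stage: str, started: float, **counts) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(time.time() - started, 3), **counts
        }

    def fail(stage: str, exc: Exception):
        logger.error("stage %r failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- simulate ---------------------------------------------------------
    t0 = time.time()
    syn.seed = stage_seed(config.seed, "simulate")
    try:
        participants, table, log = generate_cohort(syn, registry)
        write_cohort(out, participants, table, syn, log)
    except Exception as exc:
        fail("simulate", exc)
    part_df = participants_frame(participants)
    record("simulate", t0, n_participants=len(participants),
           n_features=len(registry))

    # --- extract ----------------------------------------------------------
    if "extract" not in config.skip:
        t0 = time.time()
        try:
            transcripts, truths = generate_transcripts(syn, lexicon, participants)
            scored = score_transcripts(transcripts, lexicon, registry)
            scored.to_csv(out / "transcript_features.csv")
            pd.DataFrame(truths).set_index("participant_id").to_csv(
                out / "transcript_ground_truth.csv")
        except Exception as exc:
            fail("extract", exc)
        record("extract", t0, n_transcripts=len(transcripts))

    # --- prep ---------------------------------------------------------------
    t0 = time.time()
    try:
        normalized = quantile_normalize(table)
        normalized.to_csv(out / "features_normalized.csv")
        contrasts = build_contrasts(normalized, registry)
        contrasts.to_csv(out / "contrasts.csv")
    except Exception as exc:
        fail("prep", exc)
    record("prep", t0, n_contrasts=contrasts.n_contrasts,
           n_language_pairs=sum(1 for a, b in contrasts.pairs
                                if registry.modality_of(a) == "language"),
           n_acoustic_pairs=sum(1 for a, b in contrasts.pairs
                                if registry.modality_of(a) == "acoustic"))

    feature_screen = contrast_screen = None
    if "screen" not in config.skip:
        t0 = time.time()
        sseed = stage_seed(config.seed, "screen")
        amci = part_df[part_df["diagnosis"].isin(["aMCI", "HC"])]
        y = (amci["diagnosis"] == "aMCI").to_numpy(dtype=float)
        try:
            feature_screen = FeatureScreen(
                normalized.data.loc[amci.index], y, amci["age"], amci["gender"],
                family="features",
            ).fit(compute_classifiers=True, seed=sseed, folds=config.folds,
                  repeats=config.repeats, min_specificity=config.min_specificity)
            contrast_screen = FeatureScreen(
                contrasts.data.loc[amci.index], y, amci["age"], amci["gender"],
                family="contrasts",
            ).fit(compute_classifiers=config.contrast_classifiers, seed=sseed,
                  folds=config.folds, repeats=config.repeats,
                  min_specificity=config.min_specificity)
        except Exception as exc:
            fail("screen", exc)
        record("screen", t0, n_features=len(feature_screen.frame),
               n_contrasts=len(contrast_screen.frame))

    risk_results = []
    if "riskscore" not in config.skip:
        t0 = time.time()
        rseed = stage_seed(config.seed, "riskscore")
        try:
            for task in config.tasks:
                res = PDRiskModel(normalized, part_df, task, config.risk).fit(rseed)
                risk_results.append(res)
        except Exception as exc:
            fail("riskscore", exc)
        record("riskscore", t0,
               aurocs={r.task: round(r.auroc, 4) for r in risk_results})

    if "report" not in config.skip:
        t0 = time.time()
        try:
            written = report_tables(feature_screen, contrast_screen, risk_results,
                                    out / "report", table=normalized,
                                    participants=part_df)
        except Exception as exc:
            fail("report", exc)
        record("report", t0, n_files=len(written))

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _hash_file(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
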