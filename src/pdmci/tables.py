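"""In-memory containers for feature matrices and pairwise contrasts."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .registry import FeatureRegistry


@dataclass
class FeatureTable:
    """Participants × features matrix with registry metadata.

    ``data`` is indexed by participant id with one column per registry feature.
    Missing values are permitted only in features the registry flags
    ``may_be_missing``. ``normalized`` records whether columns have been
    quantile normalized.
    """

    data: pd.DataFrame
    registry: FeatureRegistry
    normalized: bool = False

    def __post_init__(self) -> None:
        missing_cols = [c for c in self.registry.names if c not in self.data.columns]
        if missing_cols:
            raise ValueError(f"feature table lacks registry columns: {missing_cols[:5]}")
        self.data = self.data[self.registry.names]
        allowed = set(self.registry.may_be_missing)
        bad = [
            c
            for c in self.data.columns
            if c not in allowed and self.data[c].isna().any()
        ]
        if bad:
            raise ValueError(f"missing values outside may_be_missing features: {bad[:5]}")

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.registry, self.normalized)

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def to_csv(self, path, sidecar: dict | None = None) -> None:
        path = Path(path)
        self.data.to_csv(path)
        meta = {"normalized": self.normalized, "n_features": len(self.registry)}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path, registry: FeatureRegistry, normalized: bool = False):
        df = pd.read_csv(path, index_col=0)
        return cls(df, registry, normalized)


@dataclass
class ContrastTable:
    """All within-modality pairwise differences of normalized features.

    One column per unordered same-modality pair (A, B), with A preceding B in
    registry order; the value is normalized(A) − normalized(B).
    """

    data: pd.DataFrame
    pairs: list[tuple[str, str]] = field(default_factory=list)

    SEP = " | "

    @staticmethod
    def key(a: str, b: str) -> str:
        return f"{a}{ContrastTable.SEP}{b}"

    def __post_init__(self) -> None:
        expected = [self.key(a, b) for a, b in self.pairs]
        if list(self.data.columns) != expected:
            raise ValueError("contrast columns do not match declared pairs")

    @property
    def n_contrasts(self) -> int:
        return len(self.pairs)

    def to_csv(self, path) -> None:
        self.data.to_csv(path)
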