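"""Table reading/writing and pipeline configuration.

All tables are tab-separated UTF-8 text with a header row: a counts table
(rows = features, columns = sample ids), sample metadata (sample_id,
subject_id, dyad_id, role, wave, age_months), behavior scores
(subject_id, dyad_id, wave, NEG, REG, MD) and a covariate table indexed
by dyad id.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["read_counts", "read_metadata", "read_behavior", "read_covariates",
           "read_tables", "PipelineConfig"]

_META_COLS = ["sample_id", "subject_id", "dyad_id", "role", "wave"]


def read_counts(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.shape[0] == 0:
        raise ValueError("no features in counts table")
    bad = table.columns[table.isna().any() | (table < 0).any()]
    if len(bad):
        raise ValueError(f"negative or missing counts in samples: {list(bad[:10])}")
    table.index = table.index.astype(str)
    table.index.name = "feature"
    return table


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={c: str for c in _META_COLS})
    missing = set(_META_COLS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    return meta


def read_behavior(path) -> pd.DataFrame:
    beh = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "dyad_id": str, "wave": str})
    missing = {"subject_id", "wave"} - set(beh.columns)
    if missing:
        raise ValueError(f"behavior table missing columns: {sorted(missing)}")
    return beh


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_tables(paths: dict) -> dict:
    """Read and cross-validate the four pipeline inputs.

    ``paths`` maps counts/metadata/behavior/covariates to file paths.
    Every counts sample must appear in the metadata.
    """
    counts = read_counts(paths["counts"])
    metadata = read_metadata(paths["metadata"])
    orphans = set(counts.columns) - set(metadata["sample_id"])
    if orphans:
        raise ValueError(
            "samples in counts absent from metadata: " + ", ".join(sorted(orphans)[:10])
        )
    out = {"counts": counts, "metadata": metadata}
    if "behavior" in paths:
        out["behavior"] = read_behavior(paths["behavior"])
    if "covariates" in paths:
        out["covariates"] = read_covariates(paths["covariates"])
    return out


@dataclass
class PipelineConfig:
    """Validated configuration for the full analysis pipeline."""

    counts: str
    metadata: str
    behavior: str
    covariates: str
    out_dir: str
    metric: str = "chao1"
    temperament_variants: tuple[str, ...] = ("NEG", "REG")
    n_components: int = 4
    min_abundance: float = 0.01
    min_prevalence: float = 0.10
    q_threshold: float = 0.05
    riclpm: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in ("counts", "metadata", "behavior", "covariates"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.metric not in ("chao1", "shannon"):
            raise ValueError(f"unknown metric {self.metric!r}")
        for v in self.temperament_variants:
            if v not in ("NEG", "REG"):
                raise ValueError(f"unknown temperament variant {v!r}")
        for name in ("min_abundance", "min_prevalence", "q_threshold"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "temperament_variants" in raw:
            raw["temperament_variants"] = tuple(raw["temperament_variants"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs go is
        excluded: two runs differing only in out_dir are the same analysis)."""
        d = asdict(self)
        d.pop("out_dir")
        d["temperament_variants"] = list(self.temperament_variants)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]
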