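"""Dyad-by-wave-by-channel panel container.

A :class:`DyadPanel` holds the four analysis channels — infant microbiome
diversity (IM), maternal microbiome diversity (MM), infant temperament
(IT) and maternal depression (MD) — for every dyad at every wave, plus a
missingness mask and per-dyad covariates.  It is the input to the
random-intercept cross-lagged panel model and the output of the synthetic
cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DyadPanel", "DEFAULT_CHANNELS", "DEFAULT_WAVES"]

DEFAULT_CHANNELS = ("IM", "MM", "IT", "MD")
DEFAULT_WAVES = ("T1", "T2", "T3")


@dataclass
class DyadPanel:
    """Values array of shape (n_dyads, n_waves, n_channels) with mask.

    ``mask`` is True where a cell is missing.  ``truth`` optionally retains
    the pre-masking values for recovery scoring in simulations; it is never
    consulted by any fitting code.
    """

    values: np.ndarray
    mask: np.ndarray
    covariates: np.ndarray
    dyad_ids: list[str]
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    waves: tuple[str, ...] = DEFAULT_WAVES
    truth: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.covariates = np.asarray(self.covariates, dtype=float)
        n, w, c = self.values.shape
        if self.mask.shape != (n, w, c):
            raise ValueError("mask shape does not match values")
        if self.covariates.shape[0] != n:
            raise ValueError("covariates must have one row per dyad")
        if len(self.dyad_ids) != n:
            raise ValueError("dyad_ids length mismatch")
        if w != len(self.waves) or c != len(self.channels):
            raise ValueError("wave/channel labels do not match array shape")

    @property
    def n_dyads(self) -> int:
        return self.values.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    def observed(self) -> np.ndarray:
        """Values with missing cells set to NaN."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    # -- TSV round trip -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: one row per (dyad, wave) with channel and
        covariate columns; missing cells are empty."""
        n, w, _ = self.values.shape
        rows = []
        for i in range(n):
            for t in range(w):
                row = {"dyad_id": self.dyad_ids[i], "wave": self.waves[t]}
                for k, ch in enumerate(self.channels):
                    row[ch] = np.nan if self.mask[i, t, k] else self.values[i, t, k]
                for j in range(self.covariates.shape[1]):
                    row[f"cov{j + 1}"] = self.covariates[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        channels: tuple[str, ...] = DEFAULT_CHANNELS,
        waves: tuple[str, ...] = DEFAULT_WAVES,
    ) -> "DyadPanel":
        dyads = list(dict.fromkeys(frame["dyad_id"].astype(str)))
        cov_cols = [c for c in frame.columns if c.startswith("cov")]
        n, w, c = len(dyads), len(waves), len(channels)
        values = np.zeros((n, w, c))
        mask = np.ones((n, w, c), dtype=bool)
        covariates = np.zeros((n, len(cov_cols)))
        idx = {d: i for i, d in enumerate(dyads)}
        widx = {wv: t for t, wv in enumerate(waves)}
        for _, row in frame.iterrows():
            i, t = idx[str(row["dyad_id"])], widx[row["wave"]]
            for k, ch in enumerate(channels):
                v = row[ch]
                if pd.notna(v):
                    values[i, t, k] = float(v)
                    mask[i, t, k] = False
            covariates[i] = [float(row[cc]) for cc in cov_cols]
        return cls(values, mask, covariates, dyads, channels, waves)

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "DyadPanel":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        return cls.from_frame(frame, **kwargs)
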