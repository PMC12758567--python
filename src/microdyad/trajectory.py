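"""Group-level diversity trajectories for mothers vs infants.

Fits a random-intercept linear mixed model of per-sample alpha diversity on
time (waves T1/T2/T3, treatment coded), role (infant reference, mother
indicator), their interaction, and the four covariate principal components,
with a random intercept per subject (mother and infant are distinct
subjects even within a dyad).  A significant time-by-role interaction is
probed with nine Bonferroni-corrected pairwise contrasts on estimated
marginal means: the three wave pairs within each role and the
mother-vs-infant difference at each wave, covariates held at their sample
means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .lmm import RandomInterceptLMM

__all__ = ["TrajectoryLMM", "PairwiseComparison", "fit_trajectory", "posthoc_pairwise"]

_WAVES = ("T1", "T2", "T3")
_ROLES = ("infant", "mother")


@dataclass(frozen=True)
class PairwiseComparison:
    contrast: str
    estimate: float
    se: float
    z: float
    p_raw: float
    p_bonferroni: float


def _design_row(role: str, wave: str, pc_means: np.ndarray, pc_names) -> pd.Series:
    row = {"Intercept": 1.0}
    for w in _WAVES[1:]:
        row[f"wave[{w}]"] = float(wave == w)
    row["role[mother]"] = float(role == "mother")
    for w in _WAVES[1:]:
        row[f"role[mother]:wave[{w}]"] = float(role == "mother" and wave == w)
    for name, m in zip(pc_names, pc_means):
        row[name] = m
    return pd.Series(row)


class TrajectoryLMM(BaseEstimator):
    """Diversity-over-time mixed model with role interaction.

    ``fit`` expects a long-format frame with columns ``value`` (diversity),
    ``subject_id``, ``role`` in {infant, mother}, ``wave`` in {T1, T2, T3}
    and the covariate score columns named in ``pc_columns``.
    """

    def __init__(self, pc_columns: tuple[str, ...] = ("PC1", "PC2", "PC3", "PC4")):
        self.pc_columns = pc_columns

    def _build_design(self, data: pd.DataFrame) -> pd.DataFrame:
        bad_wave = set(data["wave"]) - set(_WAVES)
        bad_role = set(data["role"]) - set(_ROLES)
        if bad_wave or bad_role:
            raise ValueError(f"unknown wave/role labels: {bad_wave | bad_role}")
        X = pd.DataFrame(index=data.index)
        X["Intercept"] = 1.0
        for w in _WAVES[1:]:
            X[f"wave[{w}]"] = (data["wave"] == w).astype(float)
        X["role[mother]"] = (data["role"] == "mother").astype(float)
        for w in _WAVES[1:]:
            X[f"role[mother]:wave[{w}]"] = X["role[mother]"] * X[f"wave[{w}]"]
        for pc in self.pc_columns:
            if pc in data.columns:
                X[pc] = data[pc].astype(float)
        return X

    def fit(self, data: pd.DataFrame, y=None):
        data = data.reset_index(drop=True)
        if data["wave"].nunique() < 2 or data["role"].nunique() < 2:
            raise ValueError("need at least two waves and both roles")
        X = self._build_design(data)
        self.pc_used_ = [c for c in self.pc_columns if c in X.columns]
        self.pc_means_ = X[self.pc_used_].mean().to_numpy() if self.pc_used_ else np.array([])
        engine = RandomInterceptLMM().fit(X, data["value"], data["subject_id"])
        self.engine_ = engine
        self.params_ = engine.params_
        self.bse_ = engine.bse_
        self.tvalues_ = engine.tvalues_
        self.pvalues_ = engine.pvalues_
        self.cov_params_ = engine.cov_params_
        self.sigma2_ = engine.sigma2_
        self.tau2_ = engine.tau2_
        self.reml_loglik_ = engine.reml_loglik_
        self.n_obs_ = engine.n_obs_
        self.n_subjects_ = engine.n_groups_
        return self

    # -- estimated marginal means ------------------------------------------
    def marginal_mean_row(self, role: str, wave: str) -> pd.Series:
        """Design row for the (role, wave) cell with covariates at their means."""
        row = _design_row(role, wave, self.pc_means_, self.pc_used_)
        return row.reindex(self.params_.index).fillna(0.0)

    def marginal_mean(self, role: str, wave: str) -> float:
        return float(self.marginal_mean_row(role, wave) @ self.params_)

    def posthoc_pairwise(self) -> list[PairwiseComparison]:
        """Nine Bonferroni-adjusted contrasts probing the interaction."""
        inter_cols = [c for c in self.params_.index if c.startswith("role[mother]:")]
        if not inter_cols:
            raise ValueError("post-hoc contrasts require the time-by-role interaction")
        pairs: list[tuple[str, tuple[str, str], tuple[str, str]]] = []
        for role in _ROLES:
            for i in range(len(_WAVES)):
                for j in range(i + 1, len(_WAVES)):
                    pairs.append(
                        (f"{role} {_WAVES[i]} vs {role} {_WAVES[j]}",
                         (role, _WAVES[i]), (role, _WAVES[j]))
                    )
        for w in _WAVES:
            pairs.append((f"infant {w} vs mother {w}", ("infant", w), ("mother", w)))
        m = len(pairs)
        out = []
        cov = self.cov_params_.to_numpy()
        for label, (r1, w1), (r2, w2) in pairs:
            c = (self.marginal_mean_row(r1, w1) - self.marginal_mean_row(r2, w2)).to_numpy()
            est = float(c @ self.params_.to_numpy())
            se = float(np.sqrt(c @ cov @ c))
            z = est / se
            p = float(2.0 * stats.norm.sf(abs(z)))
            out.append(PairwiseComparison(label, est, se, z, p, min(1.0, m * p)))
        return out


def fit_trajectory(diversity: pd.DataFrame, pcs: pd.DataFrame | None = None) -> TrajectoryLMM:
    """Join per-sample diversity to subject-level PC scores and fit the model.

    ``diversity`` needs columns value/subject_id/role/wave (as produced by
    :func:`microdyad.diversity.diversity_table` joined to sample records);
    ``pcs`` is indexed by the id its rows describe — subject ids or dyad ids
    (dyad-level scores are shared by both members).
    """
    data = diversity.copy()
    if pcs is not None:
        key = "subject_id"
        if "dyad_id" in data.columns and not set(data["subject_id"]).issubset(set(pcs.index)):
            key = "dyad_id"
        data = data.join(pcs, on=key)
    return TrajectoryLMM().fit(data)


def posthoc_pairwise(fit: TrajectoryLMM) -> list[PairwiseComparison]:
    return fit.posthoc_pairwise()
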