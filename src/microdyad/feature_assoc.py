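"""Per-feature microbiome-behavior association pipeline.

Mirrors the standard multivariable microbiome association workflow:
total-sum scaling to relative abundances, a joint abundance/prevalence
filter (keep features reaching 1% relative abundance in at least 10% of
samples), a log transform with a per-feature half-minimum pseudocount,
then one random-intercept linear mixed model per surviving feature with
infant negative emotionality, infant regulation, maternal depression, age
in months at assessment and the four covariate PCs as fixed effects and a
per-subject random intercept.  Analyses run separately on infant and
mother sample tables.  Benjamini-Hochberg adjustment is applied jointly
over the feature x behavioral-predictor family within a role (age and PC
terms are adjustment covariates, not hypotheses) and features are called
significant at q < 0.05.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .lmm import RandomInterceptLMM

logger = logging.getLogger(__name__)

__all__ = [
    "tss_normalize",
    "filter_features",
    "log_transform",
    "bh_adjust",
    "FeatureAssociation",
    "fit_feature_models",
]

BEHAVIOR_PREDICTORS = ("NEG", "REG", "MD")


def tss_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total so columns sum to one."""
    sums = table.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(f"zero-sum samples: {list(zero[:10])}")
    return table.div(sums, axis=1)


def filter_features(
    rel_table: pd.DataFrame,
    min_abundance: float = 0.01,
    min_prevalence: float = 0.10,
) -> list[str]:
    """Features reaching ``min_abundance`` in >= ceil(min_prevalence * n) samples."""
    for name, v in (("min_abundance", min_abundance), ("min_prevalence", min_prevalence)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    n = rel_table.shape[1]
    needed = int(np.ceil(min_prevalence * n))
    hits = (rel_table >= min_abundance).sum(axis=1)
    if needed == 0:
        keep = rel_table.index[(rel_table > 0).any(axis=1)]
    else:
        keep = rel_table.index[hits >= needed]
    return list(keep)


def log_transform(rel_table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """log(x + delta_f) with delta_f = half the feature's minimum positive value."""
    sub = rel_table.loc[features]
    out = {}
    for f, row in sub.iterrows():
        pos = row[row > 0]
        if pos.empty:
            raise ValueError(f"feature {f!r} has no positive values; pseudocount undefined")
        delta = 0.5 * pos.min()
        out[f] = np.log(row + delta)
    return pd.DataFrame(out).T


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1.  NaN p-values are
    excluded from the family (they do not count toward m) and propagate as
    NaN q-values with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    nan_mask = np.isnan(p)
    if nan_mask.any():
        warnings.warn("NaN p-values propagated as NaN q-values", stacklevel=2)
    valid = p[~nan_mask]
    if valid.size:
        if np.any((valid < 0) | (valid > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        m = valid.size
        order = np.argsort(valid, kind="stable")
        ranked = valid[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qv = np.empty(m)
        qv[order] = np.minimum(ranked, 1.0)
        q[~nan_mask] = qv
    return q


def _merge_predictors(
    metadata: pd.DataFrame,
    behavior: pd.DataFrame,
    pcs: pd.DataFrame | None,
    role: str,
) -> pd.DataFrame:
    """Sample-level predictor frame for one role's analysis.

    Temperament scales attach to the dyad's infant, depression to the
    dyad's mother, regardless of which role's samples are analyzed.
    """
    meta = metadata[metadata["role"] == role].copy()
    inf = behavior.dropna(subset=["NEG"])[["dyad_id", "wave", "NEG", "REG"]]
    mom = behavior.dropna(subset=["MD"])[["dyad_id", "wave", "MD"]]
    meta = meta.merge(inf, on=["dyad_id", "wave"], how="left")
    meta = meta.merge(mom, on=["dyad_id", "wave"], how="left")
    if pcs is not None:
        meta = meta.join(pcs, on="dyad_id")
    return meta


def fit_feature_models(
    transformed: pd.DataFrame,
    predictors: pd.DataFrame,
    pc_columns: tuple[str, ...] = ("PC1", "PC2", "PC3", "PC4"),
) -> pd.DataFrame:
    """One random-intercept LMM per feature (rows of ``transformed``).

    ``predictors`` must hold one row per sample with columns sample_id,
    subject_id, NEG, REG, MD, age_months and the PC scores.  Returns the
    long coefficient table (feature x predictor) with Wald p-values; BH
    q-values are attached by the caller over the behavioral family.
    """
    if predictors.duplicated(subset=["subject_id", "wave"]).any():
        raise ValueError("duplicate subject-wave rows in predictor table")
    fixed = [c for c in (*BEHAVIOR_PREDICTORS, "age_months", *pc_columns)
             if c in predictors.columns]
    data = predictors.dropna(subset=fixed).reset_index(drop=True)
    usable = []
    for c in fixed:
        if data[c].nunique() <= 1:
            logger.warning("dropping constant predictor %r", c)
        else:
            usable.append(c)
    X = pd.DataFrame({"Intercept": np.ones(len(data))})
    for c in usable:
        X[c] = data[c].astype(float).to_numpy()
    groups = data["subject_id"].to_numpy()
    cols = data["sample_id"].tolist()
    rows = []
    for feat, yrow in transformed[cols].iterrows():
        fit = RandomInterceptLMM().fit(X, yrow.to_numpy(dtype=float), groups)
        for c in usable:
            rows.append(
                {"feature": feat, "predictor": c,
                 "coefficient": fit.params_[c], "se": fit.bse_[c],
                 "p": fit.pvalues_[c]}
            )
    return pd.DataFrame(rows)


class FeatureAssociation(BaseEstimator):
    """End-to-end association stage for one role's sample table.

    ``fit(counts, metadata=..., behavior=..., pcs=...)`` runs TSS
    normalization, filtering, log transform and the per-feature mixed
    models, then BH-adjusts the behavioral coefficients.  Results land in
    ``results_`` sorted by q, with ``significant_`` the q < 0.05 subset.
    """

    def __init__(
        self,
        role: str = "infant",
        min_abundance: float = 0.01,
        min_prevalence: float = 0.10,
        q_threshold: float = 0.05,
        adjusted_family: tuple[str, ...] = BEHAVIOR_PREDICTORS,
    ):
        self.role = role
        self.min_abundance = min_abundance
        self.min_prevalence = min_prevalence
        self.q_threshold = q_threshold
        self.adjusted_family = adjusted_family

    def fit(self, counts: pd.DataFrame, metadata=None, behavior=None, pcs=None):
        if metadata is None or behavior is None:
            raise ValueError("metadata and behavior tables are required")
        preds = _merge_predictors(metadata, behavior, pcs, self.role)
        counts_role = counts[preds["sample_id"].tolist()]
        rel = tss_normalize(counts_role)
        self.features_ = filter_features(rel, self.min_abundance, self.min_prevalence)
        if not self.features_:
            self.results_ = pd.DataFrame(
                columns=["feature", "predictor", "coefficient", "se", "p", "q", "significant"]
            )
            self.significant_ = self.results_
            return self
        transformed = log_transform(rel, self.features_)
        table = fit_feature_models(transformed, preds)
        in_family = table["predictor"].isin(self.adjusted_family)
        q = np.full(len(table), np.nan)
        q[in_family.to_numpy()] = bh_adjust(table.loc[in_family, "p"].to_numpy())
        table["q"] = q
        table["significant"] = table["q"] < self.q_threshold
        self.results_ = table.sort_values(
            "q", na_position="last", kind="stable"
        ).reset_index(drop=True)
        self.significant_ = self.results_[self.results_["significant"]]
        return self
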