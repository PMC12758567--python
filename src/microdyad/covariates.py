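"""Covariate dimension reduction.

Downstream models adjust for four principal-component scores (PC1-PC4)
computed from whatever sociodemographic/health covariate table is supplied,
so that many correlated covariates can be controlled without exhausting
degrees of freedom.  PCA is run on the correlation matrix (z-scored
columns) because covariate tables mix units; categoricals are one-hot
encoded and missing cells mean-imputed first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = ["PCScores", "CovariatePCA", "reduce_covariates"]


@dataclass
class PCScores:
    """Principal-component adjustment scores for a covariate table."""

    scores: pd.DataFrame  # subjects x components, columns PC1..PCn
    loadings: pd.DataFrame  # variables x components
    explained_variance_ratio: np.ndarray = field(default_factory=lambda: np.array([]))


class CovariatePCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA over a mixed-type covariate table.

    The transformer one-hot encodes categorical columns (dropping the first
    level), mean-imputes missing numeric cells, z-scores every column and
    eigendecomposes the resulting correlation matrix.  Constant columns are
    dropped with a warning.  Component signs follow a fixed convention —
    the variable with the largest absolute loading loads positive — so
    repeated fits of the same table give identical score columns.

    Parameters
    ----------
    n_components : int, default 4
        Number of score columns returned.
    impute : {"mean"}, default "mean"
        Missing-cell strategy before standardization.

    Attributes
    ----------
    loadings_ : DataFrame, variables x components.
    explained_variance_ratio_ : ndarray of length ``n_components``.
    columns_ : list of encoded column names actually used.
    mean_, scale_ : per-column standardization constants.
    """

    def __init__(self, n_components: int = 4, impute: str = "mean"):
        self.n_components = n_components
        self.impute = impute

    # -- internal -----------------------------------------------------------
    def _encode(self, table: pd.DataFrame) -> pd.DataFrame:
        numeric = table.select_dtypes(include=[np.number])
        categorical = table.select_dtypes(exclude=[np.number])
        parts = [numeric]
        if categorical.shape[1]:
            parts.append(pd.get_dummies(categorical, drop_first=True, dtype=float))
        return pd.concat(parts, axis=1).astype(float)

    def fit(self, X: pd.DataFrame, y=None):
        if self.impute != "mean":
            raise ValueError(f"unknown imputation strategy {self.impute!r}")
        table = X.copy()
        enc = self._encode(table)
        enc = enc.fillna(enc.mean())
        scale = enc.std(ddof=1)
        constant = scale.index[(scale == 0) | scale.isna()]
        if len(constant):
            logger.warning("dropping constant covariate columns: %s", list(constant))
            enc = enc.drop(columns=constant)
            scale = scale.drop(index=constant)
        if enc.shape[1] < self.n_components:
            raise ValueError(
                f"only {enc.shape[1]} usable covariate columns for "
                f"{self.n_components} components"
            )
        if enc.shape[0] < self.n_components + 1:
            raise ValueError("need at least n_components + 1 rows")
        self.columns_ = list(enc.columns)
        self.mean_ = enc.mean().to_numpy()
        self.scale_ = scale.to_numpy()
        Z = (enc.to_numpy() - self.mean_) / self.scale_
        corr = np.corrcoef(Z, rowvar=False)
        eigval, eigvec = np.linalg.eigh(corr)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        eigval = np.clip(eigval, 0.0, None)
        k = self.n_components
        vecs = eigvec[:, :k]
        # sign convention: variable with the largest |loading| loads positive
        for j in range(k):
            i_max = np.argmax(np.abs(vecs[:, j]))
            if vecs[i_max, j] < 0:
                vecs[:, j] = -vecs[:, j]
        self.eigenvalues_ = eigval
        self.components_ = vecs  # variables x k, unit-norm eigenvectors
        self.explained_variance_ratio_ = eigval[:k] / eigval.sum()
        # loadings scaled by sqrt(eigenvalue): correlations between variable and score
        self.loadings_ = pd.DataFrame(
            vecs * np.sqrt(eigval[:k]),
            index=self.columns_,
            columns=[f"PC{j + 1}" for j in range(k)],
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        enc = self._encode(X.copy())
        enc = enc.reindex(columns=self.columns_, fill_value=0.0)
        enc = enc.fillna(pd.Series(self.mean_, index=self.columns_))
        Z = (enc.to_numpy() - self.mean_) / self.scale_
        scores = Z @ self.components_
        return pd.DataFrame(
            scores, index=X.index, columns=[f"PC{j + 1}" for j in range(self.n_components)]
        )


def reduce_covariates(
    covariate_table: pd.DataFrame, n_components: int = 4
) -> PCScores:
    """Fit :class:`CovariatePCA` and return scores, loadings and variance ratios.

    ``covariate_table`` is indexed by subject (or dyad) id; any non-numeric
    columns are one-hot encoded.
    """
    est = CovariatePCA(n_components=n_components).fit(covariate_table)
    scores = est.transform(covariate_table)
    return PCScores(
        scores=scores,
        loadings=est.loadings_,
        explained_variance_ratio=est.explained_variance_ratio_,
    )
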