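"""Trait integration: the species x trait matrix, its Pearson
correlation structure with significance flags, and PCA.

The unit of analysis is the species mean (n = 6 rows for the study
panel): correlations between traits are computed across species, with
two-sided p-values from the t transform on n - 2 degrees of freedom and
the conventional flag tiers (** p < 0.01, * p < 0.05, marginal
p < 0.10, no multiple-testing correction).  PCA standardizes each trait
column (z-scores) before the singular value decomposition, since traits
live on incommensurate units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

__all__ = ["CorrelationResult", "correlation_matrix", "TraitPCA",
           "build_trait_matrix"]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame
    n: int

    def flag_of(self, a: str, b: str) -> str:
        return str(self.flags.loc[a, b])


def _flag(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "."
    return ""


def correlation_matrix(matrix: pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlations across species rows.

    Zero-variance columns yield undefined (NaN) entries rather than an
    error, and are reported as such.
    """
    df = matrix.select_dtypes(include=[np.number])
    n = len(df)
    if n < 3:
        raise ValueError("need >= 3 species rows")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols,
                     columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            x, y = df[a].to_numpy(float), df[b].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                rij, pij = np.nan, np.nan
            else:
                res = sps.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    flags = p.map(_flag)
    np.fill_diagonal(flags.values, "")
    return CorrelationResult(r, p, flags, n)


class TraitPCA(BaseEstimator, TransformerMixin):
    """PCA of a species x trait matrix (standardized by default).

    Attributes
    ----------
    loadings_ : pd.DataFrame
        Trait loadings, traits x components.
    scores_ : pd.DataFrame
        Species scores on each component.
    variance_explained_ : np.ndarray
        Percent of total variance per axis (sums to 100 over all axes).
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, X, y=None):
        df = X.select_dtypes(include=[np.number]) \
            if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        if len(df) < 3:
            raise ValueError("need >= 3 species rows")
        vals = df.to_numpy(dtype=float)
        if self.standardize:
            sd = vals.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [c for c, s in zip(df.columns, sd) if s == 0]
                raise ValueError(
                    f"constant column(s) under standardization: {bad}")
            vals = (vals - vals.mean(axis=0)) / sd
        else:
            vals = vals - vals.mean(axis=0)
        self._pca = PCA(svd_solver="full").fit(vals)
        comps = [f"PC{k + 1}" for k in range(self._pca.n_components_)]
        self.loadings_ = pd.DataFrame(self._pca.components_.T,
                                      index=df.columns, columns=comps)
        self.scores_ = pd.DataFrame(self._pca.transform(vals),
                                    index=df.index, columns=comps)
        self.variance_explained_ = 100.0 * self._pca.explained_variance_ratio_
        self.n_features_in_ = vals.shape[1]
        self._columns = list(df.columns)
        self._center = df.to_numpy(float).mean(axis=0)
        self._scale = df.to_numpy(float).std(axis=0, ddof=1) \
            if self.standardize else np.ones(vals.shape[1])
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        df = X[self._columns] if isinstance(X, pd.DataFrame) \
            else pd.DataFrame(np.asarray(X), columns=self._columns)
        vals = (df.to_numpy(float) - self._center) / self._scale
        return self._pca.transform(vals)


def build_trait_matrix(summaries: list[pd.DataFrame]) -> tuple[pd.DataFrame, list]:
    """Join per-module species summaries into one species x trait matrix.

    Each summary is long-form with columns ``species``, ``trait`` and
    ``value``.  Duplicate species-trait pairs are rejected; missing
    cells are listed (not filled).
    """
    long = pd.concat(summaries, ignore_index=True)
    required = {"species", "trait", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"summaries need columns {sorted(required)}")
    dup = long.duplicated(subset=["species", "trait"])
    if dup.any():
        pairs = long.loc[dup, ["species", "trait"]].to_records(index=False)
        raise ValueError(f"duplicate species-trait pairs: {list(pairs)}")
    wide = long.pivot(index="species", columns="trait", values="value")
    missing = [(sp, tr) for sp in wide.index for tr in wide.columns
               if pd.isna(wide.loc[sp, tr])]
    return wide, missing
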