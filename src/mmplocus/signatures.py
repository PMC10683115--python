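"""Locus-partitioned signature scores and the rank-sum group comparison.

The headline statistic is the 3'/5' expression ratio: the per-sample mean of
standardized log2 expression over the 3' gene cluster minus the same mean
over the 5' cluster.  On the log2 scale this difference is the log of a
geometric-mean expression ratio, which is division-safe even when individual
linear values are zero.  The MMP1/MMP8 score is the analogous single-gene
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .expression import (
    ExpressionMatrix,
    log_normalize,
    replace_nondetected,
    standardize_by_median,
)
from .genome import LocusModel, default_mmp_locus

__all__ = [
    "SignatureScores",
    "signature_scores",
    "group_compare",
    "SignatureScorer",
    "score_cohort",
]

SCORE_COLUMNS = ["score_5prime", "score_3prime", "ratio", "mmp1_mmp8"]


@dataclass
class SignatureScores:
    """Per-sample 5', 3', ratio and MMP1/MMP8 signature scores."""

    table: pd.DataFrame  # index sample_id, columns SCORE_COLUMNS

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"missing score columns: {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def ratio(self) -> pd.Series:
        return self.table["ratio"]


def _set_mean(values: pd.DataFrame, gene_ids: list[str], aggregator: str) -> pd.Series:
    sub = values.loc[gene_ids]
    if aggregator == "mean":
        return sub.mean(axis=0)
    if aggregator == "median":
        return sub.median(axis=0)
    raise ValueError(f"unknown aggregator {aggregator!r}")


def signature_scores(
    m: ExpressionMatrix,
    locus: LocusModel | None = None,
    include_neighbors: bool = False,
    aggregator: str = "mean",
) -> SignatureScores:
    """Compute the four signature scores from a standardized matrix.

    Parameters
    ----------
    m : ExpressionMatrix
        Must be in ``standardized`` state.
    locus : LocusModel, optional
        Defaults to the Chr11q22.2 MMP locus; ``include_neighbors`` controls
        whether TMEM123/BIRC3 join the 5' set (ignored when ``locus`` is
        supplied explicitly).
    aggregator : str
        Per-set summary, ``mean`` (default) or ``median``.
    """
    if m.state != "standardized":
        raise ValueError(f"signature_scores requires standardized state, got {m.state}")
    if locus is None:
        locus = default_mmp_locus(include_neighbors=include_neighbors)
    five = [g.gene_id for g in locus.genes_on("5prime")]
    three = [g.gene_id for g in locus.genes_on("3prime")]
    needed = five + three + ["MMP1", "MMP8"]
    missing = [g for g in dict.fromkeys(needed) if g not in m.values.index]
    if missing:
        raise KeyError(f"gene ids missing from expression matrix: {missing}")
    s5 = _set_mean(m.values, five, aggregator)
    s3 = _set_mean(m.values, three, aggregator)
    table = pd.DataFrame(
        {
            "score_5prime": s5,
            "score_3prime": s3,
            "ratio": s3 - s5,
            "mmp1_mmp8": m.values.loc["MMP1"] - m.values.loc["MMP8"],
        }
    )
    table = table.rename_axis(index="sample_id")
    return SignatureScores(table)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def group_compare(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test with midranks for ties.

    Returns ``(U, p)`` where U is the statistic for the first group.  For
    combined sample size <= 10 the null is enumerated exactly over all
    label assignments (ties handled by midranks); otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 + n2 <= 10:
        # Exact null: every way of assigning n1 of the pooled ranks to group 1.
        obs_dev = abs(u1 - mu)
        n_total = n1 + n2
        count = 0
        base = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n_total), n1):
            u = ranks[list(idx)].sum() - base
            if abs(u - mu) >= obs_dev - 1e-12:
                count += 1
        p = count / comb(n_total, n1)
        return float(u1), float(p)

    # Normal approximation with tie correction.
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return float(u1), float(min(p, 1.0))


class SignatureScorer(BaseEstimator, TransformerMixin):
    """Cohort-calibrated transformer from raw counts to signature scores.

    ``fit`` learns the per-gene minimal detected signal and the per-gene
    cohort median of log2(count + 1); ``transform`` applies non-detected
    replacement, log2 normalization and median standardization with the
    learned statistics, then returns the per-sample score table.

    Fitting and transforming the same cohort reproduces the standard
    cohort-level pipeline exactly.

    Parameters
    ----------
    include_neighbors : bool
        Add TMEM123/BIRC3 to the 5' signature set.
    aggregator : str
        ``mean`` or ``median`` per-set summary.
    locus : LocusModel, optional
        Overrides the default MMP locus.
    """

    def __init__(
        self,
        include_neighbors: bool = False,
        aggregator: str = "mean",
        locus: LocusModel | None = None,
    ) -> None:
        self.include_neighbors = include_neighbors
        self.aggregator = aggregator
        self.locus = locus

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(X)
        raise TypeError("X must be an ExpressionMatrix or a genes x samples DataFrame")

    def fit(self, X, y=None) -> "SignatureScorer":
        m = self._as_matrix(X)
        if m.state != "raw_counts":
            raise ValueError("SignatureScorer fits on raw counts")
        replaced = replace_nondetected(m)
        logged = log_normalize(
            ExpressionMatrix(replaced.values, replaced.detect_mask, "raw_counts")
        )
        # Floor = per-gene minimal detected raw signal.
        mask = m.detect_mask.to_numpy()
        vals = m.values.to_numpy()
        self.gene_floor_ = pd.Series(
            np.where(mask, vals, np.inf).min(axis=1), index=m.values.index
        )
        self.gene_median_log2_ = logged.values.median(axis=1)
        self.n_features_in_ = m.shape[0]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "gene_median_log2_"):
            raise RuntimeError("SignatureScorer is not fitted")
        m = self._as_matrix(X)
        if m.state != "raw_counts":
            raise ValueError("SignatureScorer transforms raw counts")
        vals = m.values.copy()
        floors = self.gene_floor_.reindex(vals.index)
        if floors.isna().any():
            missing = list(floors.index[floors.isna()])
            raise KeyError(f"genes unseen at fit time: {missing}")
        vals = vals.where(m.detect_mask, floors, axis=0)
        logged = np.log2(vals + 1.0)
        standardized = logged.sub(self.gene_median_log2_.reindex(vals.index), axis=0)
        em = ExpressionMatrix(standardized, None, state="standardized")
        scores = signature_scores(
            em,
            locus=self.locus,
            include_neighbors=self.include_neighbors,
            aggregator=self.aggregator,
        )
        return scores.table

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def score_cohort(
    m: ExpressionMatrix,
    include_neighbors: bool = False,
    aggregator: str = "mean",
    locus: LocusModel | None = None,
) -> SignatureScores:
    """One-call cohort pipeline: replace -> log2 -> standardize -> score."""
    standardized = standardize_by_median(log_normalize(replace_nondetected(m)))
    return signature_scores(
        standardized,
        locus=locus,
        include_neighbors=include_neighbors,
        aggregator=aggregator,
    )
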