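"""Spectral quality control via local outlier factor (LOF) scores.

Spectra are embedded into their leading principal components (neighbor
distances in the raw 2101-dimensional space are dominated by noise) and
scored with the standard LOF statistic; scores near 1 indicate inliers and
samples whose score exceeds a fixed, logged threshold are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.neighbors import LocalOutlierFactor

__all__ = ["SpectralLOF", "OutlierReport", "lof_scores", "flag_outliers"]


@dataclass
class OutlierReport:
    sample: str
    lof_score: float
    flagged: bool
    k: int
    n_pcs: int
    threshold: float


class SpectralLOF(BaseEstimator):
    """LOF outlier detection on a PCA embedding of spectra.

    Parameters
    ----------
    k : int
        Neighbor count for the LOF statistic.
    n_pcs : int
        Dimension of the principal-component embedding; capped at what the
        data support.
    threshold : float
        Scores above this are flagged.  LOF has no universal scale; 1.5 is
        conventional practice and is recorded in every report row.
    """

    def __init__(self, k: int = 20, n_pcs: int = 10, threshold: float = 1.5):
        self.k = k
        self.n_pcs = n_pcs
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k >= n:
            raise ValueError(f"k={self.k} must be smaller than n samples ({n})")
        n_pcs = min(self.n_pcs, n - 1, X.shape[1])
        emb = PCA(n_components=n_pcs, svd_solver="full").fit_transform(X)
        lof = LocalOutlierFactor(n_neighbors=self.k)
        lof.fit(emb)
        self.n_pcs_ = n_pcs
        self.scores_ = -lof.negative_outlier_factor_
        self.flags_ = self.scores_ > self.threshold
        return self

    def report(self, sample_ids) -> list[OutlierReport]:
        return [
            OutlierReport(
                sample=str(s),
                lof_score=float(sc),
                flagged=bool(fl),
                k=self.k,
                n_pcs=self.n_pcs_,
                threshold=self.threshold,
            )
            for s, sc, fl in zip(sample_ids, self.scores_, self.flags_)
        ]


def lof_scores(spectra: pd.DataFrame, k: int = 20, n_pcs: int = 10) -> pd.Series:
    """Per-sample LOF scores on the top-``n_pcs`` PC embedding of spectra."""
    est = SpectralLOF(k=k, n_pcs=n_pcs).fit(spectra.values)
    return pd.Series(est.scores_, index=spectra.index, name="lof_score")


def flag_outliers(scores: pd.Series, threshold: float = 1.5,
                  k: int = 20, n_pcs: int = 10) -> list[OutlierReport]:
    """Deterministic thresholding of LOF scores into an audit report."""
    if not np.all(np.isfinite(scores.values)):
        raise ValueError("LOF scores must be finite")
    return [
        OutlierReport(
            sample=str(s), lof_score=float(v), flagged=bool(v > threshold),
            k=k, n_pcs=n_pcs, threshold=threshold,
        )
        for s, v in scores.items()
    ]


def report_to_frame(reports: list[OutlierReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample for r in reports],
            "lof_score": [r.lof_score for r in reports],
            "flagged": [r.flagged for r in reports],
        }
    ).set_index("sample")
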