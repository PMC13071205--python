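"""Per-wavelength linear-model adjustment of spectra for environmental effects.

For every wavelength w the model

    Y_w ~ LN + REP + BA + LN:REP + LN:BA + DT + CT + DT:CT + MO

is fitted by ordinary least squares with treatment contrasts, where LN is
the measurement technique (number of leaves in the clip), REP the replicate
set, BA the spatial patch, DT/CT day and time of day, and MO the maternal
origin.  Residuals are the adjusted phenotypes carried into downstream
analyses; sequential (Type I) sums of squares in the declared term order
give a per-wavelength variance partition whose shares stack to 100%.

Patch effects can alternatively enter as continuous covariates estimated
from phytometer (tester-genotype) plants: per patch and broad wavelength
block, the mean phytometer deviation from the grand phytometer mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "DesignMatrix",
    "EnvironmentalAdjuster",
    "build_design",
    "estimate_patch_effects",
    "fit_adjust",
    "adjust_scalar",
    "TERM_ORDER",
    "WAVELENGTH_BLOCKS",
]

# sequential decomposition order: measurement technique, spatial, temporal, maternal
TERM_ORDER = ["LN", "REP", "BA", "LN:REP", "LN:BA", "DT", "CT", "DT:CT", "MO"]

FACTORS = ["LN", "REP", "BA", "DT", "CT", "MO"]

# broad blocks used for phytometer-derived patch covariates
WAVELENGTH_BLOCKS = {"VIS": (400, 700), "NIR": (701, 1300), "SWIR": (1301, 2500)}


@dataclass
class DesignMatrix:
    """Treatment-contrast design with a term index for sequential SS."""

    X: np.ndarray
    columns: list[str]
    term_of_col: list[str]
    samples: list[str]
    dropped: list[str] = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        seen = []
        for t in self.term_of_col:
            if t not in seen and t != "(Intercept)":
                seen.append(t)
        return seen


def _dummies(levels: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    """Treatment contrasts: indicator per non-reference level."""
    cats = pd.Categorical(levels)
    names = [f"{prefix}[{lv}]" for lv in cats.categories[1:]]
    cols = np.stack(
        [(cats.codes == i).astype(float) for i in range(1, len(cats.categories))],
        axis=1,
    ) if len(cats.categories) > 1 else np.empty((len(levels), 0))
    return cols, names


def build_design(
    metadata: pd.DataFrame,
    ba_mode: str = "factor",
    patch_effects: pd.DataFrame | None = None,
    rank_tol: float = 1e-8,
) -> DesignMatrix:
    """Expand the adjustment model into a full-rank design matrix.

    Aliased (linearly dependent) columns are dropped greedily, in term
    order, with a warning.  With ``ba_mode='phytometer'`` the BA factor is
    replaced by continuous per-block patch covariates from
    :func:`estimate_patch_effects`.
    """
    missing = [c for c in FACTORS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks factor columns: {missing}")
    if metadata[FACTORS].isna().any().any():
        bad = metadata[FACTORS].isna().any()
        raise ValueError(f"missing metadata cells in terms: {list(bad[bad].index)}")
    if ba_mode not in ("factor", "phytometer"):
        raise ValueError("ba_mode must be 'factor' or 'phytometer'")

    n = len(metadata)
    blocks: list[tuple[str, np.ndarray, list[str]]] = []

    def factor_block(term: str) -> tuple[np.ndarray, list[str]]:
        if ":" in term:
            a, b = term.split(":")
            combo = metadata[a].astype(str) + ":" + metadata[b].astype(str)
            return _dummies(combo, term)
        return _dummies(metadata[term], term)

    for term in TERM_ORDER:
        if ba_mode == "phytometer" and term in ("BA", "LN:BA"):
            if term == "BA":
                if patch_effects is None:
                    raise ValueError(
                        "ba_mode='phytometer' requires a patch_effects table"
                    )
                pe = patch_effects.reindex(metadata["BA"]).to_numpy(dtype=float)
                pe = np.nan_to_num(pe)
                names = [f"BA_cov[{c}]" for c in patch_effects.columns]
                blocks.append(("BA", pe, names))
            continue  # LN:BA has no factor analogue in covariate mode
        cols, names = factor_block(term)
        blocks.append((term, cols, names))

    # greedy full-rank assembly via an orthonormal basis
    Q = np.ones((n, 1)) / np.sqrt(n)
    X_cols = [np.ones(n)]
    col_names = ["(Intercept)"]
    term_of_col = ["(Intercept)"]
    dropped: list[str] = []
    for term, cols, names in blocks:
        for j, name in enumerate(names):
            v = cols[:, j]
            r = v - Q @ (Q.T @ v)
            nrm = np.linalg.norm(r)
            if nrm <= rank_tol * max(np.linalg.norm(v), 1.0):
                dropped.append(name)
                continue
            Q = np.hstack([Q, (r / nrm)[:, None]])
            X_cols.append(v)
            col_names.append(name)
            term_of_col.append(term)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} aliased design columns: {dropped[:5]}…"
                      if len(dropped) > 5 else
                      f"dropped aliased design columns: {dropped}")

    return DesignMatrix(
        X=np.stack(X_cols, axis=1),
        columns=col_names,
        term_of_col=term_of_col,
        samples=[str(s) for s in metadata.index],
        dropped=dropped,
    )


def estimate_patch_effects(
    phytometer_spectra: pd.DataFrame,
    metadata: pd.DataFrame,
    blocks: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Per-patch mean phytometer deviation from the grand phytometer mean.

    Returns a patches x wavelength-block table usable as continuous BA
    covariates.  Patches without any phytometer get 0 with a warning.
    """
    blocks = blocks or WAVELENGTH_BLOCKS
    meta = metadata.loc[phytometer_spectra.index]
    wl = np.asarray(phytometer_spectra.columns, dtype=float)
    all_patches = sorted(metadata["BA"].unique())
    out = pd.DataFrame(0.0, index=pd.Index(all_patches, name="BA"),
                       columns=list(blocks))
    empty = []
    for name, (lo, hi) in blocks.items():
        sel = (wl >= lo) & (wl <= hi)
        block_means = phytometer_spectra.values[:, sel].mean(axis=1)
        grand = block_means.mean()
        per_patch = pd.Series(block_means - grand, index=meta["BA"].values)
        agg = per_patch.groupby(level=0).mean()
        out[name] = agg.reindex(all_patches).fillna(0.0).values
        empty = [p for p in all_patches if p not in agg.index]
    if empty:
        warnings.warn(f"patches without phytometer, effect imputed as 0: {empty}")
    return out


def _sequential_fit(Y: np.ndarray, design: DesignMatrix):
    """Shared OLS core: residuals plus Type I SS per term, vectorized over
    response columns."""
    n = Y.shape[0]
    if design.X.shape[0] != n:
        raise ValueError("design rows do not match number of samples")
    # orthonormalize in term order (X was assembled full-rank)
    Q, _ = np.linalg.qr(design.X)
    proj = Q.T @ Y  # (k, p)
    fitted = Q @ proj
    resid = Y - fitted

    ybar = Y.mean(axis=0, keepdims=True)
    tss = ((Y - ybar) ** 2).sum(axis=0)
    terms = design.terms
    ss = {}
    tvec = np.asarray(design.term_of_col)
    for t in terms:
        sel = tvec == t
        ss[t] = (proj[sel, :] ** 2).sum(axis=0)
    rss = ((resid) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        part = {t: np.where(tss > 0, 100.0 * s / tss, 0.0) for t, s in ss.items()}
        part["Residual"] = np.where(tss > 0, 100.0 * rss / tss, 100.0)
    return resid, part


def fit_adjust(
    spectra: pd.DataFrame, design: DesignMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """OLS-adjust every wavelength; return residual spectra and the percent
    variance partition (wavelength x term, summing to 100)."""
    str_index = [str(s) for s in spectra.index]
    if str_index != design.samples:
        # allow any row order: align by sample id
        order = pd.Index(str_index).get_indexer(design.samples)
        if (order < 0).any():
            raise ValueError("spectra samples do not match design samples")
        spectra = spectra.iloc[order]
    resid, part = _sequential_fit(spectra.to_numpy(dtype=float), design)
    adjusted = pd.DataFrame(resid, index=spectra.index, columns=spectra.columns)
    partition = pd.DataFrame(part, index=spectra.columns)
    partition.index.name = "wavelength_nm"
    return adjusted, partition


def adjust_scalar(values: pd.Series, design: DesignMatrix) -> pd.Series:
    """Adjust a scalar per-sample phenotype with the same linear model."""
    frame = values.to_frame(name=values.name or "value")
    adjusted, _ = fit_adjust(frame, design)
    return adjusted.iloc[:, 0]


class EnvironmentalAdjuster(TransformerMixin, BaseEstimator):
    """sklearn-style transformer: fit builds the design and OLS projection,
    transform returns residual (adjusted) spectra.

    Parameters
    ----------
    ba_mode : 'factor' or 'phytometer'
        Whether spatial patch enters as a categorical factor or as
        continuous phytometer-derived covariates.
    """

    def __init__(self, ba_mode: str = "factor"):
        self.ba_mode = ba_mode

    def fit(self, X: pd.DataFrame, y=None, *, metadata: pd.DataFrame):
        patch_effects = None
        if self.ba_mode == "phytometer":
            phyto = metadata["phytometer"].astype(bool)
            patch_effects = estimate_patch_effects(X.loc[phyto.values], metadata)
        self.design_ = build_design(
            metadata.loc[X.index], ba_mode=self.ba_mode, patch_effects=patch_effects
        )
        _, self.variance_partition_ = fit_adjust(X, self.design_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        adjusted, _ = fit_adjust(X, self.design_)
        return adjusted

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
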