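"""Hierarchical spectral clustering with parallel analysis (HSC-PA).

The method recursively bipartitions the wavelength set of an adjusted
spectral matrix.  At each node, Horn-style parallel analysis decides whether
one principal component suffices to describe the segment: eigenvalues of
the band correlation matrix are compared rank by rank against a percentile
of eigenvalues from null datasets obtained by permuting each band
independently across samples.  If more than one component is supported, the
bands are split in two by the sign of the Fiedler vector of the symmetric
normalized Laplacian of a squared-correlation similarity graph, and the
recursion continues on both halves.  Terminal segments — where a single
component suffices — contribute their PC1 score as one phenotype, so a
2101-band spectrum collapses into a small set of interpretable,
data-driven segment phenotypes for GWAS.

Segments need not be contiguous in wavelength: bands co-driven by the same
underlying leaf feature are grouped across gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh, svdvals
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SegmentNode",
    "SegmentTree",
    "HSCPA",
    "parallel_analysis",
    "split_segment",
    "run_hscpa",
    "segment_phenotypes",
]


@dataclass
class SegmentNode:
    id: int
    band_ids: np.ndarray  # wavelengths (nm), sorted, not necessarily contiguous
    level: int
    n_retained: int = 0
    parent: int | None = None
    children: tuple[int, int] | None = None
    terminal: bool = False
    loading: np.ndarray | None = None  # unit-norm PC1 weights (terminals)
    center: np.ndarray | None = None  # training band means (terminals)
    score_mean: float = 0.0
    score_sd: float = 1.0

    def band_intervals(self) -> list[tuple[int, int]]:
        """Run-length encode the band set as inclusive nm intervals."""
        b = np.sort(self.band_ids)
        breaks = np.flatnonzero(np.diff(b) > 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(b) - 1]])
        return [(int(b[s]), int(b[e])) for s, e in zip(starts, ends)]


@dataclass
class SegmentTree:
    nodes: dict[int, SegmentNode]
    params: dict = field(default_factory=dict)

    @property
    def terminals(self) -> list[SegmentNode]:
        return [n for n in sorted(self.nodes.values(), key=lambda n: n.id) if n.terminal]

    @property
    def n_terminals(self) -> int:
        return len(self.terminals)

    def to_text(self) -> str:
        lines = ["id\tlevel\tparent\tn_retained\tterminal\tbands"]
        for n in sorted(self.nodes.values(), key=lambda n: n.id):
            bands = ";".join(f"{a}-{b}" for a, b in n.band_intervals())
            lines.append(
                f"{n.id}\t{n.level}\t{'' if n.parent is None else n.parent}\t"
                f"{n.n_retained}\t{int(n.terminal)}\t{bands}"
            )
        return "\n".join(lines) + "\n"


def _correlation_eigenvalues(Z: np.ndarray) -> np.ndarray:
    """Eigenvalues of the band correlation matrix from standardized data,
    via singular values of the (n x p) matrix — O(min(n,p)^2 max(n,p))."""
    n = Z.shape[0]
    s = svdvals(Z)
    ev = np.zeros(min(Z.shape))
    ev[: len(s)] = s**2 / (n - 1)
    return ev


def _standardize_columns(X: np.ndarray, drop_constant: bool = True):
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        if drop_constant:
            warnings.warn(f"dropping {np.sum(~keep)} constant band(s) before analysis")
        X = X[:, keep]
        sd = sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    return Z, keep


def parallel_analysis(
    segment_values: np.ndarray,
    n_null: int = 100,
    quantile: float = 95.0,
    seed: int | np.random.Generator = 0,
) -> int:
    """Number of principal components supported by parallel analysis.

    Observed correlation-matrix eigenvalues are compared, rank by rank,
    with the ``quantile`` percentile of eigenvalues from ``n_null`` null
    datasets in which each band is independently permuted across samples.
    Counting stops at the first rank whose observed eigenvalue does not
    exceed its null percentile; the floor is 1 so every segment yields a
    usable phenotype.
    """
    X = np.asarray(segment_values, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("parallel analysis requires at least 3 samples")
    if p < 2:
        raise ValueError("parallel analysis requires at least 2 bands")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Z, _ = _standardize_columns(X)
    if Z.shape[1] < 2:
        return 1
    obs = _correlation_eigenvalues(Z)

    k = len(obs)
    null_ev = np.empty((n_null, k))
    for r in range(n_null):
        perm = np.argsort(rng.random((n, Z.shape[1])), axis=0)
        Zp = Z[perm, np.arange(Z.shape[1])]
        null_ev[r] = _correlation_eigenvalues(Zp)
    thresh = np.percentile(null_ev, quantile, axis=0)

    n_retained = 0
    for i in range(k):
        if obs[i] > thresh[i]:
            n_retained += 1
        else:
            break
    return max(n_retained, 1)


def _similarity(X: np.ndarray, kind: str = "squared") -> np.ndarray:
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, 1.0)
    return C**2 if kind == "squared" else np.abs(C)


def split_segment(
    segment_values: np.ndarray,
    band_ids: np.ndarray,
    similarity: str = "squared",
) -> tuple[np.ndarray, np.ndarray]:
    """Bipartition bands by the Fiedler vector of the normalized Laplacian.

    Similarity between bands is the squared Pearson correlation across
    samples (anti-correlated bands belong together, since a PC loading sign
    is arbitrary).  Bands with Fiedler entry exactly zero join the smaller
    side; degenerate (all-equal) similarity falls back to a band-index
    median split with a warning.
    """
    band_ids = np.asarray(band_ids)
    p = len(band_ids)
    if p < 2:
        raise ValueError("cannot split a segment with fewer than 2 bands")
    S = _similarity(np.asarray(segment_values, dtype=float), similarity)

    if np.allclose(S, S.flat[0]):
        warnings.warn("degenerate similarity; splitting at band-index median")
        half = p // 2
        return band_ids[:half], band_ids[half:]

    d = S.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    L = np.eye(p) - inv_sqrt[:, None] * S * inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=[0, 1])
    fiedler = vecs[:, 1]

    pos = fiedler > 0
    neg = fiedler < 0
    zero = ~(pos | neg)
    if zero.any():
        # zeros join the side with fewer bands
        if pos.sum() <= neg.sum():
            pos |= zero
        else:
            neg |= zero
    if not pos.any() or not neg.any():
        warnings.warn("one-sided Fiedler vector; splitting at its median")
        med = np.median(fiedler)
        pos = fiedler > med
        if not pos.any() or pos.all():
            half = p // 2
            order = np.argsort(fiedler, kind="stable")
            pos = np.zeros(p, bool)
            pos[order[half:]] = True
        neg = ~pos
    left, right = band_ids[neg], band_ids[pos]
    # canonical order: the side containing the lowest band id first
    if right.min() < left.min():
        left, right = right, left
    return left, right


def run_hscpa(
    adjusted: pd.DataFrame,
    n_null: int = 100,
    quantile: float = 95.0,
    min_bands: int = 5,
    max_depth: int = 8,
    seed: int = 0,
    similarity: str = "squared",
) -> SegmentTree:
    """Build the full segment tree over the wavelength grid.

    Breadth-first recursion from the complete band set: each node runs
    parallel analysis; nodes supporting a single component (or hitting the
    ``min_bands`` / ``max_depth`` guard rails) become terminals, others are
    split and their halves enqueued.  Node ids follow breadth-first order
    (root = 1).
    """
    X = adjusted.to_numpy(dtype=float)
    wl = np.asarray(adjusted.columns)
    nodes: dict[int, SegmentNode] = {}
    next_id = 1
    queue: list[SegmentNode] = []

    root = SegmentNode(id=next_id, band_ids=wl.copy(), level=1)
    nodes[root.id] = root
    queue.append(root)
    next_id += 1

    col_of = {int(w): i for i, w in enumerate(wl)}
    while queue:
        node = queue.pop(0)
        cols = [col_of[int(w)] for w in node.band_ids]
        sub = X[:, cols]
        node_rng = np.random.default_rng([seed, node.id])
        if len(cols) < 2:
            node.n_retained = 1
            node.terminal = True
            continue
        node.n_retained = parallel_analysis(sub, n_null=n_null, quantile=quantile,
                                            seed=node_rng)
        if (
            node.n_retained == 1
            or len(node.band_ids) < min_bands
            or node.level >= max_depth
        ):
            node.terminal = True
            continue
        left, right = split_segment(sub, node.band_ids, similarity=similarity)
        kids = []
        for bands in (left, right):
            child = SegmentNode(
                id=next_id, band_ids=np.sort(bands), level=node.level + 1,
                parent=node.id,
            )
            nodes[child.id] = child
            queue.append(child)
            kids.append(child.id)
            next_id += 1
        node.children = (kids[0], kids[1])

    tree = SegmentTree(
        nodes=nodes,
        params={
            "n_null": n_null, "quantile": quantile, "min_bands": min_bands,
            "max_depth": max_depth, "seed": seed, "similarity": similarity,
        },
    )
    _fit_terminal_loadings(tree, adjusted)
    return tree


def _fit_terminal_loadings(tree: SegmentTree, adjusted: pd.DataFrame) -> None:
    X = adjusted.to_numpy(dtype=float)
    col_of = {int(w): i for i, w in enumerate(adjusted.columns)}
    for node in tree.terminals:
        cols = [col_of[int(w)] for w in np.sort(node.band_ids)]
        sub = X[:, cols]
        center = sub.mean(axis=0)
        Xc = sub - center
        if Xc.shape[1] == 1:
            loading = np.ones(1)
        else:
            _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
            loading = Vt[0]
        if loading.sum() < 0:
            loading = -loading
        scores = Xc @ loading
        sd = scores.std(ddof=0)
        node.loading = loading
        node.center = center
        node.score_mean = float(scores.mean())
        node.score_sd = float(sd) if sd > 0 else 1.0


def segment_phenotypes(tree: SegmentTree, adjusted: pd.DataFrame) -> pd.DataFrame:
    """Standardized PC1 scores of every terminal segment (samples x terminals).

    Loadings and centering come from the fitted tree, so applying this to
    the fitting data gives exactly mean-0, variance-1 phenotypes.
    """
    X = adjusted.to_numpy(dtype=float)
    col_of = {int(w): i for i, w in enumerate(adjusted.columns)}
    out = {}
    for node in tree.terminals:
        if node.loading is None:
            raise ValueError("tree terminals carry no loadings; run run_hscpa first")
        cols = [col_of[int(w)] for w in np.sort(node.band_ids)]
        scores = (X[:, cols] - node.center) @ node.loading
        out[f"segment_{node.id}"] = (scores - node.score_mean) / node.score_sd
    return pd.DataFrame(out, index=adjusted.index)


class HSCPA(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping the HSC-PA segmentation.

    ``fit`` grows the segment tree on an adjusted spectral matrix;
    ``transform`` maps spectra to standardized terminal-segment PC1 scores.
    With a fixed ``seed`` the tree is deterministic.
    """

    def __init__(self, n_null: int = 100, quantile: float = 95.0,
                 min_bands: int = 5, max_depth: int = 8, seed: int = 0,
                 similarity: str = "squared"):
        self.n_null = n_null
        self.quantile = quantile
        self.min_bands = min_bands
        self.max_depth = max_depth
        self.seed = seed
        self.similarity = similarity

    def fit(self, X: pd.DataFrame, y=None):
        self.tree_ = run_hscpa(
            X, n_null=self.n_null, quantile=self.quantile,
            min_bands=self.min_bands, max_depth=self.max_depth,
            seed=self.seed, similarity=self.similarity,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return segment_phenotypes(self.tree_, X)
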