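"""Multiple-testing machinery and candidate-gene windowing.

Significance across many correlated spectral phenotypes is controlled with
the PhenoSpD recipe: pairwise phenotypic correlations are estimated from
GWAS summary statistics by cross-trait LD score regression,

    Z1j * Z2j = a + b * LDscore_j + eps_j      (across SNPs j)

whose intercept ``a`` estimates the phenotypic correlation between the two
traits; the eigenvalues of the resulting correlation matrix give the
effective number of independent tests Meff, and 0.05/Meff is the
genome-wide significance threshold.  Benjamini-Hochberg FDR adjustment,
the top-k "dynamic threshold" comparison between methods, and +/- window
candidate-gene extraction from a GFF3 annotation complete the stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix

__all__ = [
    "ld_scores",
    "phenospd_correlation",
    "meff",
    "significance_threshold",
    "bh_fdr",
    "top_k_dynamic",
    "candidate_genes",
    "GeneRecord",
]


def ld_scores(genotypes: GenotypeMatrix, window_bp: int = 1_000_000) -> pd.Series:
    """Per-SNP LD score: sum of squared Pearson correlations with all SNPs
    within ``window_bp`` on the same chromosome, self included (= 1)."""
    G = genotypes.dosages.astype(float)
    n, m = G.shape
    sd = G.std(axis=0)
    Z = np.zeros_like(G)
    ok = sd > 0
    Z[:, ok] = (G[:, ok] - G[:, ok].mean(axis=0)) / sd[ok]
    scores = np.ones(m)
    for c in np.unique(genotypes.chrom):
        idx = np.flatnonzero(genotypes.chrom == c)
        pos = genotypes.pos[idx]
        lo = np.searchsorted(pos, pos - window_bp, side="left")
        hi = np.searchsorted(pos, pos + window_bp, side="right")
        for k, j in enumerate(idx):
            if not ok[j]:
                continue
            part = idx[lo[k] : hi[k]]
            part = part[ok[part]]
            r = Z[:, part].T @ Z[:, j] / n
            scores[j] = float(np.sum(r**2))
    return pd.Series(scores, index=genotypes.snp_ids, name="ldscore")


def _nearest_psd(C: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix
    (eigenvalue clipping, unit diagonal restored)."""
    vals, vecs = np.linalg.eigh((C + C.T) / 2.0)
    if vals.min() >= 0:
        return C
    vals = np.clip(vals, 0.0, None)
    P = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(P), 1e-12, None))
    P = P / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def phenospd_correlation(
    zscores: pd.DataFrame,
    ld: pd.Series,
) -> pd.DataFrame:
    """Phenotypic correlation matrix from cross-trait LD score regression.

    ``zscores`` is SNPs x traits of per-SNP association z statistics.  For
    each trait pair, the product Z1*Z2 is regressed on the LD score; the
    intercept is the correlation estimate.  The matrix is symmetrized,
    clamped to [-1, 1] and PSD-projected.  Constant LD scores degrade the
    regression to the mean of Z1*Z2 (with a warning).
    """
    if len(zscores) < 50:
        raise ValueError("PhenoSpD needs >= 50 SNPs of summary statistics")
    Zm = zscores.to_numpy(dtype=float)
    L = ld.reindex(zscores.index).to_numpy(dtype=float)
    finite = np.isfinite(Zm).all(axis=1) & np.isfinite(L)
    Zm, L = Zm[finite], L[finite]
    t = Zm.shape[1]
    C = np.eye(t)
    const_ld = np.ptp(L) <= 1e-12
    if const_ld:
        warnings.warn("constant LD scores; falling back to mean cross-product")
    Lc = L - L.mean()
    denom = float(Lc @ Lc)
    for i in range(t):
        for j in range(i + 1, t):
            prod = Zm[:, i] * Zm[:, j]
            if const_ld or denom == 0:
                a = prod.mean()
            else:
                b = float(Lc @ (prod - prod.mean())) / denom
                a = prod.mean() - b * L.mean()
            C[i, j] = C[j, i] = a
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    C = _nearest_psd(C)
    return pd.DataFrame(C, index=zscores.columns, columns=zscores.columns)


def direct_correlation(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Direct phenotype-correlation alternative to the summary-statistic
    route, for when phenotype values are at hand."""
    C = np.corrcoef(phenotypes.to_numpy(dtype=float), rowvar=False)
    C = np.clip(np.nan_to_num(C, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(_nearest_psd(C), index=phenotypes.columns,
                        columns=phenotypes.columns)


def meff(corr: pd.DataFrame | np.ndarray, method: str = "spd") -> float:
    """Effective number of independent tests from correlation eigenvalues.

    ``spd`` (default) is the participation ratio (sum(lambda))^2 /
    sum(lambda^2): M for an identity matrix, 1 for a rank-one all-ones
    matrix.  ``nyholt`` and ``liji`` are the classical alternatives.
    """
    C = np.asarray(corr, dtype=float)
    vals = np.linalg.eigvalsh((C + C.T) / 2.0)
    if vals.min() < -1e-8:
        warnings.warn("correlation matrix not PSD; projecting")
        C = _nearest_psd(C)
        vals = np.linalg.eigvalsh(C)
    vals = np.clip(vals, 0.0, None)
    M = len(vals)
    if method == "spd":
        return float(vals.sum() ** 2 / np.sum(vals**2))
    if method == "nyholt":
        return float(1.0 + (M - 1.0) * (1.0 - np.var(vals, ddof=1) / M))
    if method == "liji":
        return float(np.sum(np.where(vals >= 1, 1.0, 0.0) + (vals - np.floor(vals))))
    raise ValueError(f"unknown meff method {method!r}")


def significance_threshold(meff_value: float, alpha: float = 0.05) -> float:
    """Bonferroni-style threshold alpha / Meff."""
    if meff_value < 1:
        raise ValueError("Meff must be >= 1")
    return alpha / meff_value


def bh_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def top_k_dynamic(
    results: pd.DataFrame | list[pd.DataFrame],
    k: int = 50,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Rank unique SNPs by their minimum p across phenotypes (and models);
    the k-th ranked min-p becomes a dynamic exploratory threshold.

    Returns ``(ranking, threshold, passing)`` where ranking lists unique
    SNPs ascending by min p (ties at rank k broken by chromosome/position,
    all tied SNPs retained) and passing holds every (SNP, phenotype, model)
    association with p <= threshold.
    """
    if isinstance(results, list):
        results = pd.concat(results, ignore_index=True)
    res = results.dropna(subset=["p"])
    grouped = (
        res.sort_values(["p", "chrom", "pos"], kind="stable")
        .groupby("snp", sort=False)
        .first()
        .reset_index()
    )
    if len(grouped) < k:
        raise ValueError(f"k={k} exceeds the {len(grouped)} unique SNPs")
    ranking = grouped.sort_values(
        ["p", "chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    ranking = ranking.rename(columns={"p": "min_p"})
    threshold = float(ranking["min_p"].iloc[k - 1])
    passing = res[res["p"] <= threshold].copy()
    return ranking, threshold, passing


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    annotation: str
    snp: str
    distance: int


def _parse_snp_id(snp: str) -> tuple[str, int]:
    chrom, _, pos = snp.rpartition("_")
    return chrom, int(pos)


def candidate_genes(
    snps: list[str],
    gff_path,
    window_bp: int = 100_000,
    whitelist: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Genes within +/- ``window_bp`` of each significant SNP.

    A gene is reported when its [start, end] span intersects
    [pos - window, pos + window] (both inclusive); distance is 0 for a SNP
    inside the gene, else base pairs to the nearest edge.  The optional
    whitelist (e.g. leaf-expressed gene ids) filters the output.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    whitelist = set(whitelist) if whitelist is not None else None
    records: list[GeneRecord] = []
    genes = list(db.features_of_type("gene"))
    known_chroms = {g.seqid for g in genes}
    for snp in snps:
        chrom, pos = _parse_snp_id(snp)
        if chrom not in known_chroms:
            warnings.warn(f"SNP {snp}: unknown chromosome {chrom!r}, skipped")
            continue
        lo, hi = pos - window_bp, pos + window_bp
        for g in genes:
            if g.seqid != chrom or g.end < lo or g.start > hi:
                continue
            gene_id = g.id
            if whitelist is not None and gene_id not in whitelist:
                continue
            if g.start <= pos <= g.end:
                dist = 0
            else:
                dist = min(abs(pos - g.start), abs(pos - g.end))
            records.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    annotation=g.attributes.get("Note", [""])[0]
                    or g.attributes.get("product", [""])[0],
                    snp=snp,
                    distance=dist,
                )
            )
    return pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["gene_id", "chrom", "start", "end", "strand", "annotation",
                 "snp", "distance"],
    )
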