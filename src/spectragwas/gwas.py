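"""Genotype I/O, kinship, and native GLM / MLM association scans.

The GLM scan is per-SNP ordinary least squares of the phenotype on an
intercept, optional covariates and the additive dosage, with a two-sided
t test on the dosage coefficient.  The MLM scan adds a polygenic random
effect with covariance proportional to a kinship matrix K: variance
components are estimated by REML through the eigendecomposition of K on
the null (no-SNP) model and — under the default P3D shortcut — reused for
every SNP, each tested by generalized least squares with a Wald t test.
With K = I the MLM collapses exactly to the GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "read_genotypes",
    "kinship",
    "glm_scan",
    "mlm_scan",
    "AssociationScan",
    "lambda_gc",
]


def read_genotypes(vcf_path) -> GenotypeMatrix:
    """Read a VCF into an additive dosage matrix (alt-allele count 0/1/2).

    Missing genotypes are imputed with the per-SNP mean dosage;
    multi-allelic records are skipped (count logged).  SNP ids follow the
    ``chr{N}_{pos}`` convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    dosages, chroms, positions = [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types, dtype=float)  # 0/1/2, 3 = missing
        miss = gt == 3
        if miss.all():
            continue
        if miss.any():
            gt[miss] = gt[~miss].mean()
        dosages.append(gt)
        chroms.append(v.CHROM.removeprefix("chr"))
        positions.append(v.POS)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    chrom = np.array(chroms)
    try:
        chrom = chrom.astype(int)
    except ValueError:
        pass
    return GenotypeMatrix(
        dosages=np.stack(dosages, axis=1),
        samples=samples,
        chrom=chrom,
        pos=np.array(positions, dtype=np.int64),
    )


def kinship(genotypes: GenotypeMatrix, method: str = "vanraden",
            jitter: float = 1e-6) -> pd.DataFrame:
    """Genomic relationship matrix from dosages.

    ``vanraden``: centered dosage cross-product scaled by 2*sum(p(1-p)).
    ``zhang``: the same matrix rescaled so its mean diagonal is 1 — a
    documented approximation of the GAPIT-style normalization.
    A small diagonal jitter keeps K positive semidefinite numerically.
    """
    M = genotypes.dosages.astype(float)
    p = M.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("kinship requires at least 2 polymorphic SNPs")
    Z = M[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = Z @ Z.T / denom
    if method == "zhang":
        K = K / np.mean(np.diag(K))
    elif method != "vanraden":
        raise ValueError(f"unknown kinship method {method!r}")
    K = (K + K.T) / 2.0 + jitter * np.eye(K.shape[0])
    return pd.DataFrame(K, index=genotypes.samples, columns=genotypes.samples)


def _residual_scan(yw: np.ndarray, Xw: np.ndarray, Gw: np.ndarray,
                   poly: np.ndarray) -> dict[str, np.ndarray]:
    """Shared weighted-least-squares core: test each column of Gw added to
    the base design Xw.  All inputs are already whitened."""
    n, q = Xw.shape
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RG = Gw - Q @ (Q.T @ Gw)
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = RG.T @ ry
    df = n - q - 1
    yy = ry @ ry

    ok = poly & (gg > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(ok, gy / gg, np.nan)
        rss = yy - np.where(ok, beta**2 * gg, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.where(ok, sigma2 / gg, np.nan))
        tstat = beta / se
    pvals = np.full(Gw.shape[1], np.nan)
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    pvals[ok] = np.clip(pvals[ok], np.finfo(float).tiny, 1.0)
    return {"effect": beta, "se": se, "stat": tstat, "p": pvals}


def _results_frame(genotypes: GenotypeMatrix, res: dict, model: str,
                   phenotype: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp": genotypes.snp_ids,
            "chrom": genotypes.chrom,
            "pos": genotypes.pos,
            "effect": res["effect"],
            "se": res["se"],
            "stat": res["stat"],
            "p": res["p"],
            "model": model,
            "phenotype": phenotype,
        }
    )


def _covariate_design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.hstack([X, C])
    return X


def glm_scan(
    phenotype: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    covariates: np.ndarray | None = None,
    phenotype_name: str = "phenotype",
) -> pd.DataFrame:
    """Per-SNP OLS association scan (general linear model)."""
    y = np.asarray(phenotype, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    n = len(y)
    if n != genotypes.n_samples:
        raise ValueError("phenotype length does not match genotype samples")
    X = _covariate_design(n, covariates)
    if n <= X.shape[1] + 1:
        raise ValueError("too few samples for the requested covariates")
    G = genotypes.dosages.astype(float)
    poly = G.std(axis=0) > 0
    res = _residual_scan(y, X, G, poly)
    return _results_frame(genotypes, res, "GLM", phenotype_name)


def _reml_delta(y: np.ndarray, X: np.ndarray, s: np.ndarray, U: np.ndarray):
    """REML variance-component estimation after rotating by the
    eigenvectors of K.  Returns (delta, sigma_g2, sigma_e2) with
    Var(y) = sigma_g2 * K + sigma_e2 * I and delta = sigma_g2 / sigma_e2."""
    n, q = X.shape
    ys = U.T @ y
    Xs = U.T @ X

    def neg_reml(log_delta: float) -> float:
        delta = np.exp(log_delta)
        d = delta * s + 1.0
        w = 1.0 / d
        Xw = Xs * w[:, None]
        A = Xs.T @ Xw
        b = Xw.T @ ys
        beta = np.linalg.solve(A, b)
        r = ys - Xs @ beta
        rss = r @ (w * r)
        sigma_e2 = rss / (n - q)
        _, logdet_A = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - q) * np.log(2.0 * np.pi * sigma_e2)
            + np.sum(np.log(d))
            + logdet_A
            + (n - q)
        )
        return -ll

    grid = np.linspace(-8.0, 8.0, 33)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    opt = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    delta = float(np.exp(opt.x))
    d = delta * s + 1.0
    w = 1.0 / d
    Xw = Xs * w[:, None]
    beta = np.linalg.solve(Xs.T @ Xw, Xw.T @ ys)
    r = ys - Xs @ beta
    sigma_e2 = float(r @ (w * r) / (n - q))
    return delta, delta * sigma_e2, sigma_e2


def mlm_scan(
    phenotype: np.ndarray | pd.Series,
    genotypes: GenotypeMatrix,
    kinship_matrix: pd.DataFrame | np.ndarray,
    covariates: np.ndarray | None = None,
    p3d: bool = True,
    phenotype_name: str = "phenotype",
) -> pd.DataFrame:
    """Mixed-linear-model association scan with a polygenic kinship term.

    Null-model REML fixes the variance-component ratio; with ``p3d`` it is
    reused for every SNP (per-SNP re-estimation otherwise).  Each SNP is
    tested by GLS with a Wald t test on the dosage effect.  The fitted
    heritability ``sigma_g2 / (sigma_g2 + sigma_e2)`` is attached to the
    result frame as ``DataFrame.attrs['h2']``.
    """
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    K = np.asarray(kinship_matrix, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship matrix does not match sample count")
    X = _covariate_design(n, covariates)
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6:
        raise ValueError("kinship matrix is not positive semidefinite")
    s = np.clip(s, 0.0, None)

    delta, sg2, se2 = _reml_delta(y, X, s, U)
    G = genotypes.dosages.astype(float)
    poly = G.std(axis=0) > 0

    def whiten_and_scan(delta_val: float, cols: np.ndarray | None = None):
        d = delta_val * s + 1.0
        w = 1.0 / np.sqrt(d)
        yw = (U.T @ y) * w
        Xw = (U.T @ X) * w[:, None]
        Gsel = G if cols is None else G[:, cols]
        Gw = (U.T @ Gsel) * w[:, None]
        psel = poly if cols is None else poly[cols]
        return _residual_scan(yw, Xw, Gw, psel)

    if p3d:
        res = whiten_and_scan(delta)
    else:
        keys = ("effect", "se", "stat", "p")
        res = {k: np.full(G.shape[1], np.nan) for k in keys}
        for j in range(G.shape[1]):
            if not poly[j]:
                continue
            Xj = np.hstack([X, G[:, [j]]])
            dj, _, _ = _reml_delta(y, Xj, s, U)
            rj = whiten_and_scan(dj, cols=np.array([j]))
            for k in keys:
                res[k][j] = rj[k][0]

    out = _results_frame(genotypes, res, "MLM", phenotype_name)
    out.attrs["h2"] = sg2 / (sg2 + se2) if (sg2 + se2) > 0 else 0.0
    out.attrs["sigma_g2"] = sg2
    out.attrs["sigma_e2"] = se2
    return out


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor (reported, never corrected for)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


@dataclass
class AssociationScan:
    """sklearn-style front end over the scan functions.

    ``model`` selects 'glm' or 'mlm'; fit(genotypes, phenotype) stores the
    per-SNP results in ``results_``.
    """

    model: str = "glm"
    p3d: bool = True

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "p3d": self.p3d}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, genotypes: GenotypeMatrix, phenotype,
            kinship_matrix=None, covariates=None, phenotype_name="phenotype"):
        if self.model == "glm":
            self.results_ = glm_scan(phenotype, genotypes, covariates,
                                     phenotype_name=phenotype_name)
        elif self.model == "mlm":
            if kinship_matrix is None:
                kinship_matrix = kinship(genotypes)
            self.results_ = mlm_scan(phenotype, genotypes, kinship_matrix,
                                     covariates, p3d=self.p3d,
                                     phenotype_name=phenotype_name)
        else:
            raise ValueError("model must be 'glm' or 'mlm'")
        return self
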