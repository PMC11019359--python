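"""Summary-statistics-only trans-eQTL scanning.

When individual-level expression is unavailable (e.g. meta-analysed blood
cohorts), the module correlation matrix Sigma is approximated by the
correlation, across SNPs, of the Z scores of SNPs that are insignificantly
associated with every module gene ("null SNPs").  That approximation is
noisy when few null SNPs are available: modules whose null-SNP-to-gene
ratio is 50 or below are gated out of scanning, because low ratios inflate
the test statistics.  Reads mis-assigned between homologous genes are a
second false-positive source: genes cross-mappable to any gene within
100 kb of the tested SNP are dynamically excluded from the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .pco import (GeneCorrelationMatrix, calibrate_omnibus, eigendecompose,
                  omnibus_pvalues, _component_pvalue_matrix)
from .preprocess import GeneModule
from .scan import ScanConfig, ScanResult, ZPanel, _excluded_genes

logger = logging.getLogger(__name__)

__all__ = [
    "SigmaEstimate",
    "select_null_snps",
    "estimate_sigma",
    "crossmap_exclude",
    "sumstats_scan",
]


@dataclass
class SigmaEstimate:
    """Null-SNP-based correlation matrix estimate with the ratio gate."""

    sigma: GeneCorrelationMatrix
    n_null_snps: int
    ratio: float
    gated: bool          # True = ratio above threshold, usable for scanning
    min_ratio: float


def select_null_snps(zpanel: ZPanel, module: GeneModule,
                     abs_z_max: float | None = None) -> list:
    """SNPs insignificantly associated with every module gene.

    Default threshold: per-gene two-sided p > 0.05, i.e. |Z| < 1.96.
    """
    if abs_z_max is None:
        abs_z_max = float(-special.ndtri(0.025))  # 1.959964...
    Z = zpanel.gene_columns(list(module.gene_ids))
    ok = np.all(np.abs(Z) < abs_z_max, axis=1)
    return [s for s, keep in zip(zpanel.snp_ids, ok) if keep]


def psd_repair(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal."""
    R = 0.5 * (R + R.T)
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= floor:
        return R
    vals = np.maximum(vals, floor)
    M = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(M))
    return M / np.outer(d, d)


def estimate_sigma(zpanel: ZPanel, module: GeneModule, null_snps=None,
                   min_ratio: float = 50.0, abs_z_max: float | None = None) -> SigmaEstimate:
    """Gene correlation matrix from null-SNP Z-score rows.

    Pearson correlation across the null-SNP rows per gene pair, followed by
    PSD repair.  ``gated`` is False when the null-SNP-to-gene ratio is at or
    below ``min_ratio``; such modules are excluded from scanning.
    """
    if null_snps is None:
        null_snps = select_null_snps(zpanel, module, abs_z_max=abs_z_max)
    if len(null_snps) < 2:
        raise ValueError(
            f"module {module.module_id}: {len(null_snps)} null SNPs; "
            f"need at least 2 to estimate correlations"
        )
    rows = [zpanel.snp_ids.index(s) for s in null_snps]
    Z = zpanel.gene_columns(list(module.gene_ids))[rows]
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(Z, rowvar=False)
    R = np.where(np.isfinite(R), R, 0.0)
    np.fill_diagonal(R, 1.0)
    R = psd_repair(R)
    ratio = len(null_snps) / module.size
    return SigmaEstimate(
        sigma=GeneCorrelationMatrix(module.gene_ids, R),
        n_null_snps=len(null_snps),
        ratio=float(ratio),
        gated=bool(ratio > min_ratio),
        min_ratio=float(min_ratio),
    )


def crossmap_exclude(snp_id: str, module: GeneModule, annotation: dict,
                     crossmap, zpanel: ZPanel, window_bp: int = 100_000) -> GeneModule:
    """Module minus same-chromosome genes and genes cross-mappable to the
    SNP's cis neighbourhood.

    Cis genes are those whose span intersects the closed interval
    [pos - window, pos + window] on the SNP's chromosome (1-based inclusive
    coordinates); any module gene cross-mappable to a cis gene is removed.
    """
    excluded = _excluded_genes(snp_id, module, zpanel, annotation, crossmap,
                               window_bp=window_bp)
    surviving = tuple(g for g in module.gene_ids if g not in excluded)
    if not surviving:
        return None  # caller records the pair as skipped
    return GeneModule(module.module_id, surviving, module.provenance)


def sumstats_scan(zpanel: ZPanel, modules, annotation, crossmap=None,
                  sigma_estimates: dict | None = None, min_ratio: float = 50.0,
                  config: ScanConfig | None = None,
                  multiple_testing: str = "bonferroni",
                  null_pool: np.ndarray | None = None) -> ScanResult:
    """Summary-statistics trans-PCO over all SNP x gated-module pairs.

    Significance defaults to Bonferroni across the tests performed (the
    convention for meta-analysed summary panels); supply ``null_pool`` and
    set ``multiple_testing='empirical'`` for permutation-style FDR instead.
    """
    from .scan import empirical_fdr

    config = config or ScanConfig()
    if sigma_estimates is None:
        sigma_estimates = {}
        for m in modules:
            try:
                sigma_estimates[m.module_id] = estimate_sigma(zpanel, m,
                                                              min_ratio=min_ratio)
            except ValueError as err:
                logger.warning("%s", err)
    rec, skipped = [], []
    cache: dict = {}
    for module in modules:
        est = sigma_estimates.get(module.module_id)
        if est is None:
            skipped.extend((s, module.module_id, "no_sigma_estimate")
                           for s in zpanel.snp_ids)
            continue
        if not est.gated:
            logger.info("module %s gated out (ratio %.1f <= %.0f)",
                        module.module_id, est.ratio, est.min_ratio)
            skipped.extend((s, module.module_id, "low_snp_to_gene_ratio")
                           for s in zpanel.snp_ids)
            continue
        groups: dict = {}
        for s in zpanel.snp_ids:
            excluded = frozenset(_excluded_genes(s, module, zpanel, annotation,
                                                 crossmap))
            groups.setdefault(excluded, []).append(s)
        for excluded, snps in groups.items():
            surviving = [g for g in module.gene_ids if g not in excluded]
            if not surviving:
                skipped.extend((s, module.module_id, "no_genes_after_exclusion")
                               for s in snps)
                continue
            key = (module.module_id, excluded)
            if key not in cache:
                sub = est.sigma.subset(surviving)
                model = eigendecompose(sub, lambda_min=config.lambda_min)
                calib = calibrate_omnibus(model, draws=config.calibration_draws,
                                          seed=config.seed)
                cache[key] = (model, calib)
            model, calib = cache[key]
            rows = [zpanel.snp_ids.index(s) for s in snps]
            Z = zpanel.gene_columns(surviving)[rows]
            T = Z @ model.eigenvectors[:, model.retained]
            _, pvals = _component_pvalue_matrix(T, model)
            p_pco = omnibus_pvalues(pvals.min(axis=1), calib)
            for s, p in zip(snps, p_pco):
                rec.append((s, zpanel.snp_chrom[s], zpanel.snp_pos[s],
                            module.module_id, len(surviving), float(p)))
    records = pd.DataFrame(
        rec, columns=["snp", "chrom", "pos", "module", "n_genes_tested", "p_pco"])
    if len(records):
        if multiple_testing == "bonferroni":
            n_tests = len(records)
            records = records.assign(
                p_adj=np.minimum(records["p_pco"] * n_tests, 1.0))
            records = records.assign(significant=records["p_adj"] <= 0.05)
        elif multiple_testing == "empirical":
            if null_pool is None:
                raise ValueError("empirical multiple testing needs a null_pool")
            q, sig = empirical_fdr(records["p_pco"].to_numpy(), null_pool,
                                   config.n_permutations, level=config.fdr_level)
            records = records.assign(q=q, significant=sig)
        else:
            raise ValueError(f"unknown multiple_testing {multiple_testing!r}")
    return ScanResult(records=records,
                      skipped=pd.DataFrame(skipped, columns=["snp", "module", "reason"]),
                      config=config, null_pool=null_pool)
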