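"""Expression preprocessing, QC filters and gene-module construction.

The pipeline expects bulk RNA-seq expression that has been (1) quantified as
TPM, (2) quantile-normalised across samples and mapped to a standard normal
within each gene, and (3) residualised on known covariates (genotype PCs,
expression PCs, cell-type proportions).  Genes failing the biotype filter
(protein-coding / lincRNA) or the mappability filter (score < 1) are removed
before any module is built, because multi-mapping reads between homologous
genes create spurious co-expression and spurious trans association.

Modules come either from correlation-based hierarchical clustering of the
residual expression (average linkage on 1 - |r|, minimum module size 10) or
from user-supplied GMT gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DEFAULT_BIOTYPES = frozenset({"protein_coding", "lincRNA"})

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "GeneModule",
    "CovariateMatrix",
    "GenotypeQCReport",
    "tpm_normalize",
    "quantile_then_inverse_normal",
    "regress_out_covariates",
    "filter_genes",
    "genotype_qc",
    "hwe_pvalue",
    "detect_coexpression_modules",
    "load_gene_sets",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Samples x genes expression, tagged with its processing stage."""

    sample_ids: list
    gene_ids: list
    values: np.ndarray
    stage: str = "counts"  # counts | tpm | normalized | residual

    _STAGES = ("counts", "tpm", "normalized", "residual")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        n, g = len(self.sample_ids), len(self.gene_ids)
        if self.values.shape != (n, g):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{n} samples x {g} genes"
            )
        if len(set(self.sample_ids)) != n or len(set(self.gene_ids)) != g:
            raise ValueError("duplicate sample or gene identifiers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(self.sample_ids, list(gene_ids),
                                self.values[:, idx], self.stage)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's location, biotype and alignability score."""

    gene_id: str
    chromosome: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    biotype: str
    mappability: float = 1.0

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if not (0.0 <= self.mappability <= 1.0):
            raise ValueError(f"{self.gene_id}: mappability outside [0, 1]")


@dataclass
class GeneModule:
    """An ordered, duplicate-free set of genes analysed jointly."""

    module_id: str
    gene_ids: tuple
    provenance: str = "coexpression"  # or "gene_set"

    def __post_init__(self):
        self.gene_ids = tuple(self.gene_ids)
        if len(self.gene_ids) == 0:
            raise ValueError(f"module {self.module_id} is empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"module {self.module_id} has duplicate genes")

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass
class CovariateMatrix:
    """Samples x covariates design (no intercept column; it is implicit)."""

    sample_ids: list
    names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.names)):
            raise ValueError("covariate matrix shape mismatch")


@dataclass
class GenotypeQCReport:
    n_input: int
    n_kept: int
    n_dropped_callrate: int = 0
    n_dropped_maf: int = 0
    n_dropped_hwe: int = 0


# --------------------------------------------------------------------------
# expression operations


def tpm_normalize(counts: ExpressionMatrix, gene_lengths) -> ExpressionMatrix:
    """Transcripts-per-million: length-normalised rates scaled to 1e6 per sample."""
    if counts.stage != "counts":
        raise ValueError(f"expected stage 'counts', got {counts.stage!r}")
    lengths = np.asarray([gene_lengths[g] for g in counts.gene_ids], dtype=float)
    if np.any(lengths <= 0):
        bad = [g for g, l in zip(counts.gene_ids, lengths) if l <= 0]
        raise ValueError(f"non-positive gene length for {bad[:5]}")
    rate = counts.values / lengths[None, :]
    totals = rate.sum(axis=1)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            f"sample(s) with zero total expression rate: "
            f"{[counts.sample_ids[i] for i in zero[:5]]}"
        )
    tpm = 1e6 * rate / totals[:, None]
    return ExpressionMatrix(counts.sample_ids, counts.gene_ids, tpm, "tpm")


def quantile_then_inverse_normal(x: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalise across samples, then rank-based inverse normal per gene.

    Step 1 replaces each sample's values by the mean quantile profile at the
    sample's own ranks, making every sample's distribution identical.  Step 2
    maps each gene column to Phi^{-1}((rank - 0.5) / N) with average ranks on
    ties, so each gene is exactly standard-normal-distributed in rank terms.
    """
    if len(x.sample_ids) < 2:
        raise ValueError("quantile normalisation needs at least 2 samples")
    V = x.values
    order = np.argsort(V, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(V, order, axis=1)
    mean_profile = sorted_vals.mean(axis=0)
    qn = np.empty_like(V)
    # ties within a sample receive the average of the tied mean-profile values
    for i in range(V.shape[0]):
        row = V[i]
        r = rankdata(row, method="average") - 1.0  # 0-based fractional ranks
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        qn[i] = 0.5 * (mean_profile[lo] + mean_profile[hi])
    n = V.shape[0]
    keep, cols = [], []
    for j, g in enumerate(x.gene_ids):
        col = qn[:, j]
        if np.ptp(col) == 0.0:
            logger.warning("gene %s constant after quantile normalisation; dropped", g)
            continue
        r = rankdata(col, method="average")
        cols.append(special.ndtri((r - 0.5) / n))
        keep.append(g)
    return ExpressionMatrix(x.sample_ids, keep, np.column_stack(cols), "normalized")


def regress_out_covariates(x: ExpressionMatrix, cov: CovariateMatrix) -> ExpressionMatrix:
    """Per-gene least-squares residuals on covariates plus an implicit intercept."""
    if cov.sample_ids != x.sample_ids:
        raise ValueError("covariate sample order does not match expression")
    n = len(x.sample_ids)
    if n <= cov.values.shape[1] + 1:
        raise ValueError("more covariates than residual degrees of freedom")
    X = np.column_stack([np.ones(n), cov.values])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify collinear columns by testing each against the preceding ones
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                collinear.append(cov.names[j - 1])
        raise ValueError(f"rank-deficient covariates: collinear columns {collinear}")
    beta, *_ = np.linalg.lstsq(X, x.values, rcond=None)
    resid = x.values - X @ beta
    return ExpressionMatrix(x.sample_ids, list(x.gene_ids), resid, "residual")


# --------------------------------------------------------------------------
# gene / genotype QC


def filter_genes(annotations, allowed_biotypes=DEFAULT_BIOTYPES,
                 min_mappability: float = 1.0) -> set:
    """Gene ids passing the biotype and gene-level mappability filters."""
    known = set(allowed_biotypes) | {
        "protein_coding", "lincRNA", "pseudogene", "miRNA", "snoRNA", "snRNA",
        "rRNA", "misc_RNA", "antisense", "processed_transcript", "lncRNA",
    }
    kept = set()
    for a in annotations:
        if a.biotype not in known:
            logger.warning("gene %s: unknown biotype %r, excluded", a.gene_id, a.biotype)
            continue
        if a.biotype in allowed_biotypes and a.mappability >= min_mappability:
            kept.add(a.gene_id)
    return kept


def hwe_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg equilibrium p-value from hard-call genotype counts.

    Exact (Wigginton et al.) conditional test for up to 1,000 individuals,
    chi-square goodness of fit above that.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    if n <= 1000:
        return _hwe_exact(n, n_rare, n_het)
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    exp = np.array([p * p, 2 * p * (1 - p), (1 - p) ** 2]) * n
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = np.sum((obs - exp) ** 2 / np.maximum(exp, 1e-12))
    return float(chi2_dist.sf(stat, df=1))


def _hwe_exact(n: int, n_rare: int, n_het_obs: int) -> float:
    """Exact HWE: sum of heterozygote-count probabilities <= observed's."""
    het_min = n_rare % 2
    hets = np.arange(het_min, n_rare + 1, 2)
    # unnormalised log-probabilities of each heterozygote count
    lg = special.gammaln
    n_common = 2 * n - n_rare
    logp = np.empty(hets.size)
    for i, h in enumerate(hets):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        logp[i] = (h * np.log(2.0) + lg(n + 1)
                   - lg(hom_r + 1) - lg(h + 1) - lg(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs_idx = (n_het_obs - het_min) // 2
    return float(min(prob[prob <= prob[obs_idx] * (1 + 1e-12)].sum(), 1.0))


def genotype_qc(dosages: pd.DataFrame, max_missing: float = 0.01,
                min_maf: float = 0.05, hwe_alpha: float = 1e-6):
    """Drop SNPs failing call-rate, MAF or Hardy-Weinberg thresholds.

    ``dosages`` is samples x SNPs in [0, 2] with NaN for missing calls.
    Thresholds follow common trans-eQTL practice: call rate > 99%, minor
    allele frequency > 5%, HWE p >= 1e-6 (hard calls obtained by rounding).
    Returns (filtered dosage frame, GenotypeQCReport).
    """
    V = dosages.to_numpy(dtype=float)
    n_samples, n_snps = V.shape
    miss = np.isnan(V).mean(axis=0)
    drop_call = miss > max_missing

    with np.errstate(invalid="ignore"):
        af = np.nanmean(V, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    drop_maf = ~drop_call & ~(maf > min_maf)

    drop_hwe = np.zeros(n_snps, dtype=bool)
    hard = np.rint(V)
    for j in range(n_snps):
        if drop_call[j] or drop_maf[j]:
            continue
        col = hard[:, j]
        col = col[~np.isnan(col)]
        counts = [int((col == g).sum()) for g in (0, 1, 2)]
        if hwe_pvalue(*counts) < hwe_alpha:
            drop_hwe[j] = True

    keep = ~(drop_call | drop_maf | drop_hwe)
    report = GenotypeQCReport(
        n_input=n_snps,
        n_kept=int(keep.sum()),
        n_dropped_callrate=int(drop_call.sum()),
        n_dropped_maf=int(drop_maf.sum()),
        n_dropped_hwe=int(drop_hwe.sum()),
    )
    if report.n_kept == 0:
        raise ValueError(
            f"all {n_snps} SNPs failed QC (call rate: {report.n_dropped_callrate}, "
            f"MAF: {report.n_dropped_maf}, HWE: {report.n_dropped_hwe})"
        )
    return dosages.loc[:, keep], report


# --------------------------------------------------------------------------
# modules


def detect_coexpression_modules(x: ExpressionMatrix, min_module_size: int = 10,
                                cut_height: float = 0.5) -> list:
    """Correlation-based hierarchical clustering into co-expression modules.

    Average-linkage clustering on the distance 1 - |r|; the tree is cut at
    ``cut_height`` and clusters smaller than ``min_module_size`` go to an
    unclustered pool (not returned).  Modules are numbered by decreasing
    size, genes within a module keep input order.
    """
    n_genes = len(x.gene_ids)
    if n_genes < min_module_size:
        raise ValueError(
            f"{n_genes} genes is fewer than the minimum module size {min_module_size}"
        )
    R = np.corrcoef(x.values, rowvar=False)
    D = 1.0 - np.abs(R)
    np.fill_diagonal(D, 0.0)
    D = np.clip(0.5 * (D + D.T), 0.0, 2.0)
    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=cut_height, criterion="distance")
    modules = []
    for lab in np.unique(labels):
        members = [g for g, l in zip(x.gene_ids, labels) if l == lab]
        if len(members) >= min_module_size:
            modules.append(members)
    modules.sort(key=lambda m: (-len(m), m[0]))
    return [GeneModule(f"M{i + 1}", tuple(m), "coexpression")
            for i, m in enumerate(modules)]


def load_gene_sets(path, annotation: dict | None = None,
                   min_size: int = 1) -> list:
    """Read GMT gene sets (name TAB description TAB gene ids...).

    Genes absent from ``annotation`` (a gene_id -> GeneAnnotation mapping)
    are dropped with a logged count; sets left empty are skipped.
    """
    modules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (needs name, "
                    f"description and at least one gene)"
                )
            name, _desc, *genes = parts
            seen, ordered = set(), []
            for g in genes:
                if not g:
                    continue
                if g in seen:
                    logger.warning("%s: duplicate gene %s in set %s", path, g, name)
                    continue
                seen.add(g)
                ordered.append(g)
            if annotation is not None:
                n_before = len(ordered)
                ordered = [g for g in ordered if g in annotation]
                if len(ordered) < n_before:
                    logger.warning("set %s: dropped %d unannotated genes",
                                   name, n_before - len(ordered))
            if len(ordered) < min_size or not ordered:
                logger.warning("set %s dropped (no usable genes)", name)
                continue
            modules.append(GeneModule(name, tuple(ordered), "gene_set"))
    return modules
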