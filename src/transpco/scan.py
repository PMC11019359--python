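"""Genome-wide trans-eQTL scan at the individual level.

For every SNP x module pair the scan (1) drops module genes on the SNP's
chromosome (and any genes cross-mappable to genes near the SNP, when a
cross-mappability table is supplied), (2) re-derives the correlation model
and omnibus calibration for the surviving gene subset, (3) evaluates the
PCO omnibus p-value from the univariate Z scores, and (4) converts p-values
to empirical q-values against a permutation null built by permuting
genotype sample labels, which breaks genotype-expression links while
preserving the expression correlation the test conditions on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import t as t_dist

from .pco import (GeneCorrelationMatrix, calibrate_omnibus, eigendecompose,
                  omnibus_pvalues, _component_pvalue_matrix)
from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

Z_CAP = 37.0  # |Z| at which two-sided normal p underflows the 1e-300 clamp

__all__ = [
    "ZPanel",
    "ScanConfig",
    "ScanResult",
    "LocusClump",
    "univariate_zscores",
    "test_snp_module",
    "genome_scan",
    "permutation_null",
    "empirical_fdr",
    "ld_clump",
]


@dataclass
class ZPanel:
    """Univariate Z scores of many SNPs against many genes."""

    snp_ids: list
    snp_chrom: dict          # snp_id -> chromosome
    snp_pos: dict            # snp_id -> position (bp, 1-based)
    gene_ids: list
    z: np.ndarray            # SNPs x genes
    n_samples: int | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.snp_ids), len(self.gene_ids)):
            raise ValueError("Z matrix shape does not match snp/gene ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("Z panel contains non-finite values")

    def gene_columns(self, genes) -> np.ndarray:
        idx = {g: j for j, g in enumerate(self.gene_ids)}
        return self.z[:, [idx[g] for g in genes]]


@dataclass
class ScanConfig:
    fdr_level: float = 0.10
    n_permutations: int = 10
    lambda_min: float = 0.1
    calibration_draws: int = 100_000
    min_genes: int = 1
    seed: int = 0


@dataclass
class ScanResult:
    """Records of all SNP-module tests plus skip reasons and provenance."""

    records: pd.DataFrame    # snp, chrom, pos, module, n_genes_tested, p_pco[, q, significant]
    skipped: pd.DataFrame    # snp, module, reason
    config: ScanConfig
    null_pool: np.ndarray | None = None


@dataclass
class LocusClump:
    lead_snp: str
    members: tuple
    lead_p: float


# --------------------------------------------------------------------------


def univariate_zscores(genotypes: pd.DataFrame, expression: ExpressionMatrix,
                       snp_positions: pd.DataFrame) -> ZPanel:
    """Wald Z of simple linear regression for every SNP x gene pair.

    Z = r sqrt((n-2)/(1-r^2)) mapped through the t -> standard-normal
    quantile bridge, with r the Pearson correlation of dosage and residual
    expression.  Monomorphic SNPs are excluded with a warning.
    """
    if list(genotypes.index) != list(expression.sample_ids):
        raise ValueError("genotype and expression sample order differ")
    G = genotypes.to_numpy(dtype=float)
    n = G.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples")
    sd = G.std(axis=0)
    poly = sd > 0
    if not np.all(poly):
        logger.warning("excluding %d monomorphic SNPs", int((~poly).sum()))
    snp_ids = [s for s, ok in zip(genotypes.columns, poly) if ok]
    Gc = G[:, poly] - G[:, poly].mean(axis=0)
    Gc /= np.linalg.norm(Gc, axis=0)
    Y = expression.values - expression.values.mean(axis=0)
    Y = Y / np.maximum(np.linalg.norm(Y, axis=0), 1e-300)
    r = Gc.T @ Y
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    # two-sided t probability -> equal-tail normal quantile, sign preserved
    logp_half = t_dist.logsf(np.abs(t), df=n - 2)
    z = np.sign(t) * np.clip(-special.ndtri_exp(logp_half), -Z_CAP, Z_CAP)
    chrom = snp_positions["chrom"].to_dict()
    pos = snp_positions["pos"].to_dict()
    return ZPanel(snp_ids, {s: chrom[s] for s in snp_ids},
                  {s: int(pos[s]) for s in snp_ids},
                  list(expression.gene_ids), z, n_samples=n)


def _excluded_genes(snp_id, module, zpanel, annotation, crossmap, window_bp=100_000):
    """Module genes removed for one SNP: same chromosome, plus cross-mappable
    to any gene overlapping the SNP's +/- window."""
    chrom = zpanel.snp_chrom[snp_id]
    excluded = {g for g in module.gene_ids
                if g in annotation and annotation[g].chromosome == chrom}
    if crossmap:
        pos = zpanel.snp_pos[snp_id]
        lo, hi = pos - window_bp, pos + window_bp
        cis = {g for g, a in annotation.items()
               if a.chromosome == chrom and a.start <= hi and a.end >= lo}
        partners = {b for (a, b) in crossmap if a in cis}
        excluded |= set(module.gene_ids) & partners
    return excluded


class _SubsetCache:
    """Per-(module, excluded-set) correlation model and omnibus calibration."""

    def __init__(self, config: ScanConfig):
        self.config = config
        self._store = {}
        self.hits = 0
        self.misses = 0

    def get(self, module, sigma: GeneCorrelationMatrix, excluded: frozenset):
        key = (module.module_id, excluded)
        if key not in self._store:
            self.misses += 1
            genes = [g for g in module.gene_ids if g not in excluded]
            sub = sigma.subset(genes)
            model = eigendecompose(sub, lambda_min=self.config.lambda_min)
            calib = calibrate_omnibus(model, draws=self.config.calibration_draws,
                                      seed=self.config.seed)
            self._store[key] = (model, calib)
        else:
            self.hits += 1
        return self._store[key]


def test_snp_module(snp_id, module, zpanel: ZPanel, sigma: GeneCorrelationMatrix,
                    annotation, crossmap=None, config: ScanConfig | None = None,
                    cache: _SubsetCache | None = None):
    """PCO result for one SNP-module pair after exclusion rules, or a skip reason."""
    from .pco import ZVector, pco_pvalue

    config = config or ScanConfig()
    cache = cache or _SubsetCache(config)
    excluded = _excluded_genes(snp_id, module, zpanel, annotation, crossmap)
    surviving = [g for g in module.gene_ids if g not in excluded]
    if len(surviving) < max(config.min_genes, 1):
        return None, "no_genes_after_exclusion"
    model, calib = cache.get(module, sigma, frozenset(excluded))
    zrow = zpanel.gene_columns(surviving)[zpanel.snp_ids.index(snp_id)]
    result = pco_pvalue(ZVector(snp_id, tuple(surviving), zrow), model, calib)
    result.n_genes_tested = len(surviving)
    return result, None


def module_sigma(expression: ExpressionMatrix, module) -> GeneCorrelationMatrix:
    """Sample Pearson correlation of the module's residual expression."""
    sub = expression.subset_genes(list(module.gene_ids))
    R = np.corrcoef(sub.values, rowvar=False)
    if R.ndim == 0:
        R = np.array([[1.0]])
    return GeneCorrelationMatrix(tuple(module.gene_ids), R)


def _scan_pvalues(zpanel: ZPanel, modules, sigmas, annotation, crossmap,
                  config: ScanConfig, cache: _SubsetCache):
    """All SNP x module omnibus p-values, grouped by exclusion subset."""
    rec, skipped = [], []
    for module in modules:
        sigma = sigmas[module.module_id]
        groups: dict = {}
        for s in zpanel.snp_ids:
            excluded = frozenset(_excluded_genes(s, module, zpanel, annotation, crossmap))
            groups.setdefault(excluded, []).append(s)
        for excluded, snps in groups.items():
            surviving = [g for g in module.gene_ids if g not in excluded]
            if len(surviving) < max(config.min_genes, 1):
                skipped.extend((s, module.module_id, "no_genes_after_exclusion")
                               for s in snps)
                continue
            model, calib = cache.get(module, sigma, excluded)
            rows = [zpanel.snp_ids.index(s) for s in snps]
            Z = zpanel.gene_columns(surviving)[rows]
            T = Z @ model.eigenvectors[:, model.retained]
            _, pvals = _component_pvalue_matrix(T, model)
            p_pco = omnibus_pvalues(pvals.min(axis=1), calib)
            for s, p in zip(snps, p_pco):
                rec.append((s, zpanel.snp_chrom[s], zpanel.snp_pos[s],
                            module.module_id, len(surviving), float(p)))
    records = pd.DataFrame(
        rec, columns=["snp", "chrom", "pos", "module", "n_genes_tested", "p_pco"]
    )
    skipped = pd.DataFrame(skipped, columns=["snp", "module", "reason"])
    return records, skipped


def genome_scan(genotypes: pd.DataFrame, expression: ExpressionMatrix,
                modules, annotation, snp_positions: pd.DataFrame,
                crossmap=None, config: ScanConfig | None = None,
                with_permutations: bool = True) -> ScanResult:
    """Full scan: observed p-values, permutation null pool, empirical q-values."""
    if not modules:
        raise ValueError("empty module list")
    config = config or ScanConfig()
    cache = _SubsetCache(config)
    zpanel = univariate_zscores(genotypes, expression, snp_positions)
    sigmas = {m.module_id: module_sigma(expression, m) for m in modules}
    records, skipped = _scan_pvalues(zpanel, modules, sigmas, annotation,
                                     crossmap, config, cache)

    null_pool = None
    if with_permutations:
        null_pool = permutation_null(genotypes, expression, modules, annotation,
                                     snp_positions, crossmap=crossmap,
                                     config=config, cache=cache, sigmas=sigmas)
        q, sig = empirical_fdr(records["p_pco"].to_numpy(), null_pool,
                               config.n_permutations, level=config.fdr_level)
        records = records.assign(q=q, significant=sig)
        # no significant pair may involve genes on the SNP's own chromosome
        for _, row in records[records["significant"]].iterrows():
            mod = next(m for m in modules if m.module_id == row["module"])
            same = [g for g in mod.gene_ids if g in annotation
                    and annotation[g].chromosome == row["chrom"]]
            assert row["n_genes_tested"] <= mod.size - len(same)
    logger.info("scan: %d records, %d skipped, calibration cache %d hits / %d misses",
                len(records), len(skipped), cache.hits, cache.misses)
    return ScanResult(records=records, skipped=skipped, config=config,
                      null_pool=null_pool)


def permutation_null(genotypes: pd.DataFrame, expression: ExpressionMatrix,
                     modules, annotation, snp_positions, crossmap=None,
                     config: ScanConfig | None = None, cache=None,
                     sigmas=None) -> np.ndarray:
    """Pooled p-values from scans with permuted genotype sample labels.

    One shared permutation per pass across all SNPs; expression (and hence
    every module correlation matrix) is untouched, so the permuted scans
    sample the test's exact null.  Deterministic given ``config.seed``.
    """
    config = config or ScanConfig()
    if config.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cache = cache or _SubsetCache(config)
    if sigmas is None:
        sigmas = {m.module_id: module_sigma(expression, m) for m in modules}
    rng = np.random.default_rng(config.seed)
    n = len(genotypes.index)
    pool = []
    for _ in range(config.n_permutations):
        perm = rng.permutation(n)
        gperm = pd.DataFrame(genotypes.to_numpy()[perm], index=genotypes.index,
                             columns=genotypes.columns)
        zpanel = univariate_zscores(gperm, expression, snp_positions)
        records, _ = _scan_pvalues(zpanel, modules, sigmas, annotation,
                                   crossmap, config, cache)
        pool.append(records["p_pco"].to_numpy())
    return np.concatenate(pool)


def empirical_fdr(observed: np.ndarray, null_pool: np.ndarray, n_perm: int,
                  level: float = 0.10):
    """Permutation plug-in q-values with monotonisation.

    q(t) = [#null <= t / n_perm] / max(1, #observed <= t), then running
    minimum from the largest observed p downward so q is non-decreasing in p.
    """
    observed = np.asarray(observed, dtype=float)
    null_pool = np.sort(np.asarray(null_pool, dtype=float))
    if null_pool.size == 0:
        raise ValueError("empty permutation null pool")
    order = np.argsort(observed, kind="stable")
    p_sorted = observed[order]
    n_null_le = np.searchsorted(null_pool, p_sorted, side="right")
    n_obs_le = np.arange(1, p_sorted.size + 1)
    raw_q = (n_null_le / n_perm) / np.maximum(1, n_obs_le)
    q_sorted = np.minimum.accumulate(raw_q[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q <= level


def ld_clump(snp_pvalues: pd.DataFrame, dosages: pd.DataFrame,
             r2_threshold: float = 0.2) -> list:
    """Greedy LD clumping of significant SNPs into independent loci.

    ``snp_pvalues`` needs columns snp, chrom, pos, p.  Repeatedly takes the
    best-p SNP (ties by genomic order) as a lead and absorbs every remaining
    SNP with dosage R^2 >= threshold to it.
    """
    df = snp_pvalues.drop_duplicates(subset="snp").copy()
    df = df.sort_values(["p", "chrom", "pos"], kind="stable")
    remaining = list(df["snp"])
    pmap = dict(zip(df["snp"], df["p"]))
    G = dosages[remaining].to_numpy(dtype=float) if remaining else None
    col = {s: i for i, s in enumerate(remaining)}
    clumps = []
    todo = list(remaining)
    while todo:
        lead = todo[0]
        members = [lead]
        gl = G[:, col[lead]]
        glc = gl - gl.mean()
        rest = []
        for s in todo[1:]:
            gs = G[:, col[s]]
            gsc = gs - gs.mean()
            denom = np.linalg.norm(glc) * np.linalg.norm(gsc)
            r2 = 0.0 if denom == 0 else (glc @ gsc / denom) ** 2
            (members if r2 >= r2_threshold else rest).append(s)
        clumps.append(LocusClump(lead_snp=lead, members=tuple(members),
                                 lead_p=float(pmap[lead])))
        todo = rest
    return clumps
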