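"""Synthetic cohorts with the statistical structure the trans-eQTL test assumes.

Provides block-equicorrelated gene modules (a stand-in for empirical module
correlation matrices), Hardy-Weinberg genotypes with optional AR(1) dosage
correlation for LD-dependent tests, multivariate-normal expression with
planted per-SNP trans effects, and deterministic gene annotations plus
cross-mappability tables.  Everything is regenerable bit-identically from a
seed, and planted truths are recorded so scan output can be scored without
re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pco import GeneCorrelationMatrix
from .preprocess import CovariateMatrix, ExpressionMatrix, GeneAnnotation

__all__ = [
    "CohortFixture",
    "make_block_sigma",
    "make_decay_sigma",
    "generate_cohort",
    "make_annotation_and_crossmap",
]


@dataclass
class CohortFixture:
    """A complete simulated cohort plus its generating truth."""

    genotypes: pd.DataFrame          # samples x SNPs dosages
    snp_positions: pd.DataFrame      # snp_id, chrom, pos
    expression: ExpressionMatrix     # stage 'residual'
    annotation: dict                 # gene_id -> GeneAnnotation
    covariates: CovariateMatrix | None
    sigma: GeneCorrelationMatrix
    planted_effects: dict = field(default_factory=dict)  # snp -> {gene: beta}
    seed: int | None = None


def make_block_sigma(block_sizes, rho_within, rho_between: float = 0.0,
                     gene_ids=None) -> GeneCorrelationMatrix:
    """Block-diagonal equicorrelation gene correlation matrix.

    Each block of size b has off-diagonal ``rho_within`` (eigenvalues
    1 + (b-1)rho and 1 - rho); distinct blocks share ``rho_between``.
    """
    block_sizes = [int(b) for b in block_sizes]
    K = sum(block_sizes)
    if not all(b >= 1 for b in block_sizes):
        raise ValueError("block sizes must be >= 1")
    rho_w = float(rho_within)
    rho_b = float(rho_between)
    if not (-1.0 < rho_b <= rho_w < 1.0):
        raise ValueError("need -1 < rho_between <= rho_within < 1")
    S = np.full((K, K), rho_b)
    i = 0
    for b in block_sizes:
        S[i:i + b, i:i + b] = rho_w
        i += b
    np.fill_diagonal(S, 1.0)
    if np.linalg.eigvalsh(S).min() < -1e-10:
        raise ValueError("requested correlations give a non-PSD matrix")
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(K)]
    return GeneCorrelationMatrix(tuple(gene_ids), S)


def make_decay_sigma(n_genes: int, top: float = 40.0, rate: float = 0.93,
                     seed: int = 7, gene_ids=None) -> GeneCorrelationMatrix:
    """Correlation matrix with a geometrically decaying eigenvalue spectrum.

    Empirical gene-module correlation matrices have a few dominant
    co-expression factors and a continuously decaying tail, part of which
    falls under the PC retention filter.  This generator reproduces that
    shape: eigenvalues proportional to ``top * rate**k`` (rescaled to trace
    K) in a random orthonormal basis, then renormalised to unit diagonal.
    Unlike block equicorrelation, all eigenvalues are distinct, so the PC
    basis is identifiable — the regime the test operates in on real data.
    """
    from scipy.stats import ortho_group

    K = int(n_genes)
    lam = top * rate ** np.arange(K)
    lam = lam * K / lam.sum()
    Q = ortho_group.rvs(K, random_state=seed)
    S = (Q * lam) @ Q.T
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(K)]
    return GeneCorrelationMatrix(tuple(gene_ids), S)


def make_annotation_and_crossmap(gene_ids, chromosomes, crossmap_pairs=(),
                                 mappability=None, gene_length: int = 10_000,
                                 spacing: int = 1_000_000):
    """Deterministic annotation and symmetric cross-mappability table.

    ``chromosomes`` maps gene id -> chromosome name, or is a list of
    chromosome names cycled across genes.  Genes on a chromosome are laid
    out in input order at ``spacing`` intervals.  ``mappability`` maps gene
    id -> score (default 1.0 everywhere).
    """
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("overlapping (duplicate) gene ids")
    if isinstance(chromosomes, dict):
        chrom_of = dict(chromosomes)
    else:
        chroms = list(chromosomes)
        chrom_of = {g: chroms[i % len(chroms)] for i, g in enumerate(gene_ids)}
    mapp = mappability or {}
    next_start: dict = {}
    annotation = {}
    for g in gene_ids:
        c = chrom_of[g]
        start = next_start.get(c, 1)
        annotation[g] = GeneAnnotation(
            gene_id=g, chromosome=c, start=start, end=start + gene_length - 1,
            biotype="protein_coding", mappability=float(mapp.get(g, 1.0)),
        )
        next_start[c] = start + spacing
    crossmap = set()
    for a, b in crossmap_pairs:
        if a == b:
            continue
        crossmap.add((a, b))
        crossmap.add((b, a))  # symmetric closure
    return annotation, crossmap


def generate_cohort(n_samples: int, sigma: GeneCorrelationMatrix,
                    snp_count: int, planted_effects: dict | None = None,
                    maf_range=(0.05, 0.5), seed: int = 0,
                    n_chromosomes: int = 2, ld_rho: float = 0.0,
                    annotation: dict | None = None) -> CohortFixture:
    """Simulate genotypes and expression with optional planted trans effects.

    Expression is ``G @ B + E`` with rows of E drawn from N(0, Sigma), so a
    SNP with effect beta on a gene explains beta^2 * 2 maf (1 - maf) variance
    by construction.  Genotypes are Binomial(2, maf) (Hardy-Weinberg, no LD);
    ``ld_rho`` > 0 instead builds AR(1)-correlated dosages within each
    chromosome to support LD-clumping tests.  SNPs alternate across
    ``n_chromosomes`` chromosomes in blocks; genes use ``annotation`` if
    given, else all genes are placed on chromosome "chrG" (so every SNP
    chromosome is trans to every gene).
    """
    rng = np.random.default_rng(seed)
    K = sigma.n_genes
    genes = list(sigma.gene_ids)
    planted_effects = dict(planted_effects or {})

    snp_ids = [f"rs{i + 1}" for i in range(snp_count)]
    mafs = rng.uniform(maf_range[0], maf_range[1], size=snp_count)
    snps_per_chrom = int(np.ceil(snp_count / n_chromosomes))
    chroms = [f"chr{1 + i // snps_per_chrom}" for i in range(snp_count)]
    positions = [100_000 + 50_000 * (i % snps_per_chrom) for i in range(snp_count)]

    if ld_rho > 0.0:
        # latent AR(1) Gaussians thresholded into HW genotype classes
        G = np.empty((n_samples, snp_count))
        for c in sorted(set(chroms)):
            idx = [j for j, cc in enumerate(chroms) if cc == c]
            z = rng.standard_normal((n_samples, len(idx)))
            for k in range(1, len(idx)):
                z[:, k] = ld_rho * z[:, k - 1] + np.sqrt(1 - ld_rho ** 2) * z[:, k]
            from scipy.special import ndtr
            u = ndtr(z)
            for k, j in enumerate(idx):
                p, q = mafs[j], 1.0 - mafs[j]
                G[:, j] = np.where(u[:, k] < q * q, 0.0,
                                   np.where(u[:, k] < q * q + 2 * p * q, 1.0, 2.0))
    else:
        G = rng.binomial(2, mafs[None, :], size=(n_samples, snp_count)).astype(float)

    L = np.linalg.cholesky(sigma.values + 1e-12 * np.eye(K))
    E = rng.standard_normal((n_samples, K)) @ L.T

    B = np.zeros((snp_count, K))
    gene_index = {g: j for j, g in enumerate(genes)}
    for snp, effects in planted_effects.items():
        i = snp_ids.index(snp)
        for g, beta in effects.items():
            B[i, gene_index[g]] = beta
    Y = G @ B + E

    if annotation is None:
        annotation, _ = make_annotation_and_crossmap(genes, ["chrG"])

    return CohortFixture(
        genotypes=pd.DataFrame(G, index=[f"s{i + 1}" for i in range(n_samples)],
                               columns=snp_ids),
        snp_positions=pd.DataFrame(
            {"snp_id": snp_ids, "chrom": chroms, "pos": positions}
        ).set_index("snp_id"),
        expression=ExpressionMatrix([f"s{i + 1}" for i in range(n_samples)],
                                    genes, Y, "residual"),
        annotation=annotation,
        covariates=None,
        sigma=sigma,
        planted_effects=planted_effects,
        seed=seed,
    )
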