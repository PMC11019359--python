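"""Power and type-I-error study for the omnibus test and its comparators.

Z scores for a module of K genes are simulated directly on the summary-
statistic scale: under the null Z ~ N(0, Sigma); under the alternative a
proportion gamma of genes receives a point-normal effect beta_k ~ N(0,
sigma_b2) and Z ~ N(sqrt(n) beta, Sigma), sqrt(n) being the score-statistic
scaling of a per-SNP effect at sample size n.  sigma_b2 is the per-SNP
trans genetic variance (0.001 is a realistic per-SNP trans heritability).

Three methods are compared:

* trans-PCO: the six-test PC omnibus;
* PC1:       association of the first expression PC only;
* MinP:      best univariate gene p-value, Bonferroni-corrected by K.

Significance in power studies uses the same empirical-FDR machinery as the
genome scan, against a matched pool of simulated null panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special
from scipy.stats import beta as beta_dist

from .pco import (CorrelationModel, GeneCorrelationMatrix, OmnibusCalibration,
                  calibrate_omnibus, eigendecompose, omnibus_pvalues,
                  _component_pvalue_matrix)
from .scan import ZPanel, empirical_fdr

METHODS = ("transPCO", "PC1", "MinP")

__all__ = [
    "METHODS",
    "SimulationConfig",
    "PowerTable",
    "simulate_null_z",
    "simulate_alt_z",
    "method_pvalues",
    "run_power_study",
    "run_type1_study",
]


@dataclass
class SimulationConfig:
    """Study conditions for one power/type-I scenario."""

    n: int = 500                 # cohort sample size
    gamma: float = 0.3           # causal gene proportion
    sigma_b2: float = 0.001      # per-SNP trans genetic variance
    n_snps: int = 10_000         # SNPs per replicate
    n_reps: int = 1_000          # replicates
    n_null_panels: int = 10      # matched null panels per replicate (FDR pool)
    fdr_level: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0 or self.sigma_b2 < 0 or self.n_snps < 1 or self.n_reps < 1:
            raise ValueError("invalid simulation configuration")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")

    def desk_scale(self) -> "SimulationConfig":
        """Reduced preset: 2,000 SNPs x 100 replicates."""
        return replace(self, n_snps=2_000, n_reps=100)


@dataclass
class PowerTable:
    """Mean power per method with normal-approximation 95% CIs."""

    table: pd.DataFrame          # method, power, ci_lo, ci_hi, mc_se
    config: SimulationConfig

    def power(self, method: str) -> float:
        return float(self.table.set_index("method").loc[method, "power"])

    def mc_se(self, method: str) -> float:
        return float(self.table.set_index("method").loc[method, "mc_se"])


def _zpanel_from_matrix(Z: np.ndarray, gene_ids, prefix="sim") -> ZPanel:
    snps = [f"{prefix}{i + 1}" for i in range(Z.shape[0])]
    return ZPanel(snps, {s: "chrSIM" for s in snps},
                  {s: i + 1 for i, s in enumerate(snps)}, list(gene_ids), Z)


def simulate_null_z(sigma: GeneCorrelationMatrix, n_snps: int, seed=0) -> ZPanel:
    """i.i.d. draws Z ~ N(0, Sigma), one row per SNP."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma.values + 1e-12 * np.eye(sigma.n_genes))
    Z = rng.standard_normal((n_snps, sigma.n_genes)) @ L.T
    return _zpanel_from_matrix(Z, sigma.gene_ids)


def simulate_alt_z(sigma: GeneCorrelationMatrix, config: SimulationConfig,
                   seed=None):
    """Alternative panel Z ~ N(sqrt(n) beta, Sigma) plus the causal mask.

    Per SNP, round(gamma K) genes (minimum 1 when gamma > 0) at uniformly
    random positions receive beta_k ~ N(0, sigma_b2).  With gamma = 0 the
    draw stream reduces exactly to :func:`simulate_null_z`.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    K = sigma.n_genes
    L = np.linalg.cholesky(sigma.values + 1e-12 * np.eye(K))
    Z = rng.standard_normal((config.n_snps, K)) @ L.T
    mask = np.zeros((config.n_snps, K), dtype=bool)
    if config.gamma > 0.0:
        n_causal = int(round(config.gamma * K))
        if n_causal < 1:
            import logging
            logging.getLogger(__name__).warning(
                "gamma * K < 1; using exactly one causal gene per SNP")
            n_causal = 1
        for i in range(config.n_snps):
            pos = rng.choice(K, size=n_causal, replace=False)
            beta = rng.normal(0.0, np.sqrt(config.sigma_b2), size=n_causal)
            Z[i, pos] += np.sqrt(config.n) * beta
            mask[i, pos] = True
    return _zpanel_from_matrix(Z, sigma.gene_ids), mask


def method_pvalues(Z: np.ndarray, model: CorrelationModel,
                   calib: OmnibusCalibration) -> dict:
    """p-values of the three methods for each row of a Z matrix."""
    T = Z @ model.eigenvectors[:, model.retained]
    _, comp = _component_pvalue_matrix(T, model)
    p_pco = omnibus_pvalues(comp.min(axis=1), calib)

    t1 = Z @ model.eigenvectors[:, 0]
    p_pc1 = 2.0 * special.ndtr(-np.abs(t1) / np.sqrt(model.eigenvalues[0]))

    K = Z.shape[1]
    p_gene = 2.0 * special.ndtr(-np.abs(Z))
    p_minp = np.minimum(1.0, K * p_gene.min(axis=1))
    return {"transPCO": p_pco, "PC1": np.maximum(p_pc1, 1e-300), "MinP": p_minp}


def _prepare_model(sigma, lambda_min=0.1, calibration_draws=200_000, seed=0):
    model = eigendecompose(sigma, lambda_min=lambda_min)
    calib = calibrate_omnibus(model, draws=calibration_draws, seed=seed)
    return model, calib


def run_power_study(sigma: GeneCorrelationMatrix, config: SimulationConfig,
                    methods=METHODS, model=None, calib=None) -> PowerTable:
    """Average power per method across replicates at empirical FDR control.

    Each replicate simulates one alternative panel and ``n_null_panels``
    matched null panels; per method, q-values against the pooled replicate
    null decide significance at ``config.fdr_level``.  Power is the mean
    proportion of significant SNPs; the MC standard error is across
    replicates.  Bit-reproducible given ``config.seed``.
    """
    if model is None or calib is None:
        model, calib = _prepare_model(sigma, seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    rep_seeds = ss.spawn(config.n_reps)
    hits = {m: np.empty(config.n_reps) for m in methods}
    for r in range(config.n_reps):
        child = np.random.default_rng(rep_seeds[r])
        alt_panel, _ = simulate_alt_z(sigma, config, seed=child)
        p_alt = method_pvalues(alt_panel.z, model, calib)
        null_Z = simulate_null_z(
            sigma, config.n_snps * config.n_null_panels, seed=child).z
        p_null = method_pvalues(null_Z, model, calib)
        for m in methods:
            _, sig = empirical_fdr(p_alt[m], p_null[m],
                                   n_perm=config.n_null_panels,
                                   level=config.fdr_level)
            hits[m][r] = sig.mean()
    rows = []
    for m in methods:
        mean = hits[m].mean()
        se = hits[m].std(ddof=1) / np.sqrt(config.n_reps) if config.n_reps > 1 else 0.0
        rows.append((m, mean, max(mean - 1.96 * se, 0.0),
                     min(mean + 1.96 * se, 1.0), se))
    return PowerTable(pd.DataFrame(rows, columns=["method", "power", "ci_lo",
                                                  "ci_hi", "mc_se"]),
                      config)


def run_type1_study(sigma: GeneCorrelationMatrix, config: SimulationConfig,
                    alphas=(0.05, 0.01), model=None, calib=None) -> pd.DataFrame:
    """Empirical rejection rate at nominal alpha per method over null panels.

    Returns a frame with exact (Clopper-Pearson) 99% binomial intervals.
    """
    if model is None or calib is None:
        model, calib = _prepare_model(sigma, seed=config.seed)
    Z = simulate_null_z(sigma, config.n_snps, seed=config.seed).z
    pvals = method_pvalues(Z, model, calib)
    n = config.n_snps
    rows = []
    for m, p in pvals.items():
        for a in alphas:
            k = int((p <= a).sum())
            lo = beta_dist.ppf(0.005, k, n - k + 1) if k > 0 else 0.0
            hi = beta_dist.ppf(0.995, k + 1, n - k) if k < n else 1.0
            rows.append((m, a, k / n, lo, hi))
    return pd.DataFrame(rows, columns=["method", "alpha", "rate",
                                       "ci99_lo", "ci99_hi"])
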