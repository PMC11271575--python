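"""Synthetic multi-ancestry GWAS data at desk scale.

Emulates the structure of a multi-population PRS study: block-diagonal
AR(1) LD that differs between populations, partially overlapping SNP
sets, sparse causal effects correlated across populations (correlation
rho_effect), fixed common-SNP heritability, and GWAS sampling noise at
a stated sample size. Summary statistics can be drawn directly from
their sampling distribution r_hat ~ N(R beta, R/n) (fast, default) or
computed from a simulated individual-level cohort (used to cross-check
the direct sampler).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypePanel, SumStats
from .ld_reference import LDBlock, LDBlockSet

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study design of the synthetic data.

    Defaults mirror a two-population design with a large auxiliary
    European-ancestry GWAS (n=100,000) and a smaller target GWAS
    (n=15,000), common-SNP heritability 0.4, cross-population effect
    correlation 0.8, polygenicity 0.01, and tuning/validation cohorts of
    10,000 each -- the study conditions this package is calibrated to,
    at a desk-scale SNP content of 2000.
    """

    populations: tuple = ("EUR", "AFR")
    p_snps: int = 2000
    block_size: int = 100
    rho_ld: tuple = (0.9, 0.7)
    freq_range: tuple = ((0.05, 0.5), (0.05, 0.5))
    shared_frac: float = 0.8
    p_causal: float = 0.01
    h2: float = 0.4
    rho_effect: float = 0.8
    alpha: float = 0.0  # selection exponent on 2f(1-f); 0 = strong selection
    n_gwas: tuple = (100_000, 15_000)
    n_tune: int = 10_000
    n_valid: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        M = len(self.populations)
        if len(self.rho_ld) != M or len(self.n_gwas) != M or len(self.freq_range) != M:
            raise ValueError("per-population settings must match population count")
        if not 0 < self.p_causal <= 1:
            raise ValueError("p_causal must be in (0, 1]")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if abs(self.rho_effect) > 1:
            raise ValueError("|rho_effect| must be <= 1")
        if self.n_tune <= 0 or self.n_valid <= 0 or any(n <= 0 for n in self.n_gwas):
            raise ValueError("all sample sizes must be positive")
        if any(abs(r) >= 1 for r in self.rho_ld):
            raise ValueError("AR(1) LD parameter must satisfy |rho| < 1")


def _rng(config_seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config_seed, tag]))


@dataclass
class TruthSet:
    """True causal architecture underlying one simulated study."""

    snp_table: pd.DataFrame          # snp_id, chrom, pos, a1, a2
    membership: pd.DataFrame         # snp x population bool
    freqs: pd.DataFrame              # snp x population a1 frequency
    effects: pd.DataFrame            # snp x population standardized effects
    causal_ids: np.ndarray
    h2_target: float
    realized_h2: dict = field(default_factory=dict)

    def beta(self, pop: str) -> pd.Series:
        member = self.membership[pop]
        return self.effects.loc[member, pop]


def _snp_structure(config: SimConfig):
    """SNP table, per-population membership and frequencies."""
    rng = _rng(config.seed, 0)
    p = config.p_snps
    ids = np.array([f"rs{i + 1}" for i in range(p)], dtype=object)
    snp_table = pd.DataFrame({"snp_id": ids, "chrom": "1",
                              "pos": np.arange(1, p + 1), "a1": "A", "a2": "G"})
    n_shared = int(round(config.shared_frac * p))
    shared = np.zeros(p, dtype=bool)
    shared[rng.choice(p, size=n_shared, replace=False)] = True
    member = pd.DataFrame(False, index=ids, columns=list(config.populations))
    member.loc[shared] = True
    specific = np.flatnonzero(~shared)
    for j, k in enumerate(specific):  # remainder split round-robin
        member.iloc[k, j % len(config.populations)] = True
    freqs = pd.DataFrame(0.0, index=ids, columns=list(config.populations))
    for i, pop in enumerate(config.populations):
        lo, hi = config.freq_range[i]
        freqs[pop] = rng.uniform(lo, hi, size=p)
    return snp_table, member, freqs


def block_intervals(config: SimConfig) -> pd.DataFrame:
    """BED-style intervals (0-based half-open) partitioning the SNP lattice."""
    starts = np.arange(0, config.p_snps, config.block_size)
    ends = np.minimum(starts + config.block_size, config.p_snps)
    return pd.DataFrame({"chrom": "1", "start": starts, "end": ends})


def gen_ld_blocks(config: SimConfig):
    """Per-population AR(1) LD: R_jk = rho_ld^|pos_j - pos_k| within a block.

    Population-specific SNP sets give each population a principal
    submatrix of the full AR(1) matrix (hence PSD). Returns
    (ld_by_pop, snp_table, membership, freqs).
    """
    snp_table, member, freqs = _snp_structure(config)
    intervals = block_intervals(config)
    ld_by_pop = {}
    for i, pop in enumerate(config.populations):
        rho = config.rho_ld[i]
        blocks = []
        for bi in range(len(intervals)):
            lo, hi = intervals.loc[bi, "start"], intervals.loc[bi, "end"]
            in_block = (snp_table["pos"] > lo) & (snp_table["pos"] <= hi)
            sub = snp_table.loc[in_block & member[pop].to_numpy()]
            pos = sub["pos"].to_numpy()
            R = rho ** np.abs(pos[:, None] - pos[None, :]) if len(pos) else np.zeros((0, 0))
            blocks.append(LDBlock(str(bi), sub["snp_id"].to_numpy(), R))
        ld_by_pop[pop] = LDBlockSet(pop, blocks)
    return ld_by_pop, snp_table, member, freqs


def simulate_effects(config: SimConfig, ld_by_pop: dict | None = None) -> TruthSet:
    """Draw the true causal architecture.

    Causal SNPs are a Bernoulli(p_causal) subset; for each causal SNP
    the effects in the populations carrying it are jointly normal with
    pairwise correlation rho_effect and per-population variance
    proportional to [2f(1-f)]^alpha on the standardized scale. Each
    population's effect vector is then rescaled so that its total genic
    variance beta' R beta equals h2.
    """
    if ld_by_pop is None:
        ld_by_pop, snp_table, member, freqs = gen_ld_blocks(config)
    else:
        snp_table, member, freqs = _snp_structure(config)
    rng = _rng(config.seed, 1)
    pops = list(config.populations)
    p = config.p_snps
    causal = rng.random(p) < config.p_causal
    if not causal.any():
        warnings.warn("p_causal * p < 1; forcing one causal SNP")
        causal[rng.integers(p)] = True
    ids = snp_table["snp_id"].to_numpy()
    effects = pd.DataFrame(0.0, index=ids, columns=pops)
    corr = np.full((len(pops), len(pops)), config.rho_effect)
    np.fill_diagonal(corr, 1.0)
    for k in np.flatnonzero(causal):
        snp = ids[k]
        carrier = [pop for pop in pops if member.loc[snp, pop]]
        if not carrier:
            continue
        sub = corr[np.ix_([pops.index(c) for c in carrier],
                          [pops.index(c) for c in carrier])]
        z = rng.multivariate_normal(np.zeros(len(carrier)), sub, method="svd")
        for j, pop in enumerate(carrier):
            f = freqs.loc[snp, pop]
            sd = (2 * f * (1 - f)) ** (config.alpha / 2.0)
            effects.loc[snp, pop] = z[j] * sd
    truth = TruthSet(snp_table, member, freqs, effects,
                     ids[causal], config.h2)
    # rescale each population to hit the target heritability exactly
    for pop in pops:
        v = _genic_variance(truth.effects[pop], ld_by_pop[pop])
        if v > 0:
            truth.effects[pop] *= np.sqrt(config.h2 / v)
            truth.realized_h2[pop] = config.h2
        else:
            truth.realized_h2[pop] = 0.0
    return truth


def _genic_variance(effects: pd.Series, ld: LDBlockSet) -> float:
    v = 0.0
    for block in ld.blocks:
        b = effects.reindex(block.snp_ids).fillna(0.0).to_numpy()
        if np.any(b):
            v += float(b @ block.R @ b)
    return v


def _block_sqrt(R: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() < -1e-8:
        warnings.warn("LD block not PSD within tolerance; adding 1e-8 ridge")
        vals = vals + 1e-8
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals) @ vecs.T


def simulate_sumstats(truth: TruthSet, ld: LDBlockSet, n_gwas: int,
                      seed: int, mode: str = "direct") -> SumStats:
    """GWAS summary statistics for one population.

    direct: per block, r_hat ~ N(R beta, R / n) via a symmetric square
    root of R. cohort: simulate an individual-level GWAS of size n and
    compute marginal correlations (slow; used for cross-validation of
    the sampler).
    """
    pop = ld.population
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    if mode == "cohort":
        panel, pheno = simulate_cohort(truth, ld, n_gwas, seed=seed)
        y = pheno["phenotype"].to_numpy()
        y = (y - y.mean()) / y.std()
        r = panel.dosages.T @ y / len(y)
        order = panel.snp_ids
    elif mode == "direct":
        parts, order_parts = [], []
        for block in ld.blocks:
            if len(block.snp_ids) == 0:
                continue
            beta = truth.effects[pop].reindex(block.snp_ids).fillna(0.0).to_numpy()
            mean = block.R @ beta
            A = _block_sqrt(block.R)
            noise = A @ rng.standard_normal(len(beta)) / np.sqrt(n_gwas)
            parts.append(mean + noise)
            order_parts.append(block.snp_ids)
        r = np.concatenate(parts)
        order = np.concatenate(order_parts)
    else:
        raise ValueError(f"unknown mode: {mode}")
    meta = truth.snp_table.set_index("snp_id").loc[order]
    df = pd.DataFrame({
        "snp_id": order, "chrom": meta["chrom"].to_numpy(),
        "pos": meta["pos"].to_numpy(), "a1": meta["a1"].to_numpy(),
        "a2": meta["a2"].to_numpy(), "r": np.clip(r, -1.0, 1.0),
        "n": n_gwas, "freq": truth.freqs.loc[order, pop].to_numpy(),
    })
    return SumStats(pop, df)


def simulate_cohort(truth: TruthSet, ld: LDBlockSet, n: int, seed: int,
                    covariate_count: int = 0, mode: str = "standardized",
                    binary: bool = False, prevalence: float | None = None):
    """Individual-level cohort with genotypes, phenotype and covariates.

    standardized mode draws genotype columns from N(0, R) per block;
    dosage mode discretizes two latent haplotypes to 0/1/2 by a
    binomial-probit construction at the population's allele
    frequencies. The phenotype is X beta + covariate effects + normal
    noise with variance 1 - h2; binary traits threshold the liability at
    the given prevalence.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if binary:
        if prevalence is None or not 0 < prevalence < 1:
            raise ValueError("binary mode requires prevalence in (0, 1)")
    pop = ld.population
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    X_parts, id_parts = [], []
    for block in ld.blocks:
        pb = len(block.snp_ids)
        if pb == 0:
            continue
        A = _block_sqrt(block.R)
        if mode == "standardized":
            X_parts.append(rng.standard_normal((n, pb)) @ A.T)
        elif mode == "dosage":
            f = truth.freqs.loc[block.snp_ids, pop].to_numpy()
            thresh = stats.norm.ppf(f)
            hap1 = (rng.standard_normal((n, pb)) @ A.T < thresh).astype(float)
            hap2 = (rng.standard_normal((n, pb)) @ A.T < thresh).astype(float)
            X_parts.append(hap1 + hap2)
        else:
            raise ValueError(f"unknown mode: {mode}")
        id_parts.append(block.snp_ids)
    X = np.column_stack(X_parts)
    snp_ids = np.concatenate(id_parts)
    sample_ids = np.array([f"{pop}_s{i}" for i in range(n)], dtype=object)
    snps = truth.snp_table.set_index("snp_id").loc[snp_ids].reset_index()
    panel = GenotypePanel(sample_ids, snps[["snp_id", "chrom", "pos", "a1", "a2"]],
                          X, standardized=(mode == "standardized"))
    beta = truth.effects[pop].reindex(snp_ids).fillna(0.0).to_numpy()
    Xs = panel.standardize().dosages if mode == "dosage" else X
    g = Xs @ beta
    h2 = truth.realized_h2.get(pop, truth.h2_target)
    liability = g + rng.standard_normal(n) * np.sqrt(max(1 - h2, 0.0))
    cov_cols = {}
    if covariate_count:
        gamma = 0.1  # fixed covariate effect on the liability scale
        for j in range(covariate_count):
            cov = rng.standard_normal(n)
            liability = liability + gamma * cov
            cov_cols[f"cov{j + 1}"] = cov
    if binary:
        cut = np.quantile(liability, 1 - prevalence)
        y = (liability > cut).astype(float)
    else:
        y = liability
    pheno = pd.DataFrame({"sample_id": sample_ids, "phenotype": y, **cov_cols})
    return panel, pheno
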