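"""Per-population, per-block LD correlation matrices and the
cross-population shared-SNP index.

The genome is divided into approximately independent LD blocks (BED
intervals, 0-based half-open); LD is the Pearson correlation of
mean-imputed dosages within each block, and blocks are treated as
independent, so the global LD matrix is block-diagonal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import GenotypePanel, SumStats

logger = logging.getLogger(__name__)


@dataclass
class LDBlock:
    block_id: str
    snp_ids: np.ndarray
    R: np.ndarray

    def validate(self, tol_sym: float = 1e-10, tol_eig: float = 1e-8) -> None:
        R = self.R
        if R.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError(f"block {self.block_id}: R shape mismatch")
        if len(R) == 0:
            return
        if np.abs(R - R.T).max() > tol_sym:
            raise ValueError(f"block {self.block_id}: R not symmetric")
        if np.abs(np.diag(R) - 1).max() > tol_sym:
            raise ValueError(f"block {self.block_id}: R diagonal not 1")
        if np.linalg.eigvalsh(R).min() < -tol_eig:
            raise ValueError(f"block {self.block_id}: R not PSD")


@dataclass
class LDBlockSet:
    population: str
    blocks: list[LDBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        all_ids = self.snp_ids
        if len(np.unique(all_ids)) != len(all_ids):
            raise ValueError("SNP ids must be disjoint across LD blocks")

    @property
    def snp_ids(self) -> np.ndarray:
        if not self.blocks:
            return np.array([], dtype=object)
        return np.concatenate([b.snp_ids for b in self.blocks])

    def validate(self) -> None:
        for b in self.blocks:
            b.validate()


@dataclass
class SharedSnpIndex:
    """Which SNPs each pair of populations has in common.

    ``pair_sets[(i1, i2)]`` (i1 < i2, by population label order as given)
    is the set of SNP ids modeled in both populations; a SNP present in
    exactly one population has an empty partner set and is penalized by
    the lasso only.
    """

    populations: list[str]
    pair_sets: dict[tuple[str, str], set] = field(default_factory=dict)

    def shared(self, pop_a: str, pop_b: str) -> set:
        key = tuple(sorted((pop_a, pop_b), key=self.populations.index))
        return self.pair_sets.get(key, set())

    def partners(self, pop: str, snp_id: str) -> set:
        out = set()
        for other in self.populations:
            if other != pop and snp_id in self.shared(pop, other):
                out.add(other)
        return out

    def is_population_specific(self, pop: str, snp_id: str) -> bool:
        return len(self.partners(pop, snp_id)) == 0


def load_block_intervals(path_or_df) -> pd.DataFrame:
    """BED intervals (chrom, start, end), 0-based half-open."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def _assign_blocks(snps: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Block index per SNP; SNPs outside every block go to the nearest
    block on their chromosome (logged)."""
    assign = np.full(len(snps), -1, dtype=int)
    pos0 = snps["pos"].to_numpy() - 1  # 1-based position -> 0-based coordinate
    chroms = snps["chrom"].astype(str).to_numpy()
    n_outside = 0
    for idx in range(len(snps)):
        cand = intervals.index[(intervals["chrom"] == chroms[idx])]
        if len(cand) == 0:
            continue
        starts = intervals.loc[cand, "start"].to_numpy()
        ends = intervals.loc[cand, "end"].to_numpy()
        inside = (starts <= pos0[idx]) & (pos0[idx] < ends)
        if inside.any():
            assign[idx] = cand[np.argmax(inside)]
        else:
            dist = np.minimum(np.abs(pos0[idx] - starts),
                              np.abs(pos0[idx] - (ends - 1)))
            assign[idx] = cand[np.argmin(dist)]
            n_outside += 1
    if n_outside:
        logger.info("%d SNPs fell outside every LD block; assigned to nearest", n_outside)
    return assign


def compute_block_ld(panel: GenotypePanel, block_intervals,
                     maf_min: float = 0.01) -> LDBlockSet:
    """Sample correlation matrix of dosages within each LD block.

    SNPs with reference MAF <= ``maf_min`` are excluded ("common" SNPs
    only); the panel must hold raw (unstandardized) dosages so that
    allele frequencies can be computed.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 reference samples to estimate LD")
    if panel.standardized:
        raise ValueError("compute_block_ld needs raw dosages (for MAF)")
    intervals = load_block_intervals(block_intervals)
    freq = panel.dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    common = maf > maf_min
    assign = _assign_blocks(panel.snps, intervals)
    blocks: list[LDBlock] = []
    for bi in range(len(intervals)):
        keep = common & (assign == bi)
        ids = panel.snps.loc[keep, "snp_id"].to_numpy()
        if len(ids) == 0:
            logger.warning("LD block %d is empty after MAF filtering", bi)
            blocks.append(LDBlock(str(bi), ids, np.zeros((0, 0))))
            continue
        X = panel.dosages[:, keep].astype(float)
        X = X - X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd < 1e-12] = 1.0
        X /= sd
        R = (X.T @ X) / panel.n_samples
        R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(R, 1.0)
        blocks.append(LDBlock(str(bi), ids, R))
    return LDBlockSet(panel.snps.attrs.get("population", "ref"), blocks)


def build_shared_index(sumstats_by_pop: list[SumStats]) -> SharedSnpIndex:
    """Pairwise shared-SNP sets across populations.

    Population membership of a SNP is data-driven: a SNP belongs to a
    population if it survived that population's harmonization and MAF
    filtering (i.e. appears in its summary statistics).
    """
    if len(sumstats_by_pop) < 1:
        raise ValueError("need at least one population")
    pops = [ss.population for ss in sumstats_by_pop]
    id_sets = {ss.population: set(ss.snp_ids) for ss in sumstats_by_pop}
    pair_sets = {}
    for p1, p2 in combinations(pops, 2):
        pair_sets[(p1, p2)] = id_sets[p1] & id_sets[p2]
    return SharedSnpIndex(pops, pair_sets)


def save_ld(ld: LDBlockSet, prefix: str) -> None:
    """Serialize to a binary matrix container (.npz) + JSON index."""
    arrays = {f"R_{i}": b.R for i, b in enumerate(ld.blocks)}
    np.savez_compressed(prefix + ".npz", **arrays)
    with open(prefix + ".npz", "rb") as fh:
        checksum = hashlib.sha256(fh.read()).hexdigest()
    index = {
        "population": ld.population,
        "checksum": checksum,
        "blocks": [{"block_id": b.block_id, "snp_ids": [str(s) for s in b.snp_ids]}
                   for b in ld.blocks],
    }
    with open(prefix + ".json", "w") as fh:
        json.dump(index, fh)


def load_ld(prefix: str) -> LDBlockSet:
    with open(prefix + ".json") as fh:
        index = json.load(fh)
    data = np.load(prefix + ".npz")
    blocks = [LDBlock(meta["block_id"], np.array(meta["snp_ids"], dtype=object),
                      data[f"R_{i}"])
              for i, meta in enumerate(index["blocks"])]
    return LDBlockSet(index["population"], blocks)
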