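"""Reading, writing and harmonizing the standard file formats of the pipeline.

GWAS summary statistics arrive as tab-delimited tables of standardized
marginal effects r ~ corr(SNP, trait); genotypes as PLINK 1 bed/bim/fam;
SNP weights as tab-delimited tables. All SNPs are harmonized to the
allele orientation of an LD reference panel before any modeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _plink

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "r", "n", "freq"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved without frequency checks."""
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


@dataclass
class SumStats:
    """Per-population GWAS summary statistics on the standardized scale.

    ``df`` holds one row per SNP with columns snp_id, chrom, pos, a1
    (effect allele), a2, r (standardized marginal effect in [-1, 1]),
    n (GWAS sample size) and freq (a1 frequency).
    """

    population: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SUMSTATS_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
        self.df = self.df[SUMSTATS_COLUMNS].reset_index(drop=True)
        if self.df["snp_id"].duplicated().any():
            dups = self.df.loc[self.df["snp_id"].duplicated(), "snp_id"].tolist()[:5]
            raise ValueError(f"duplicated snp_id in {self.population}: {dups} ...")
        if (self.df["r"].abs() > 1).any():
            raise ValueError("standardized effects must satisfy |r| <= 1")
        if (self.df["n"] <= 0).any():
            raise ValueError("GWAS sample sizes must be positive")
        if (self.df["a1"] == self.df["a2"]).any():
            raise ValueError("effect and other allele must differ")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def r(self) -> np.ndarray:
        return self.df["r"].to_numpy(dtype=float)


@dataclass
class HarmonizationReport:
    kept: int = 0
    flipped: int = 0
    dropped_not_in_reference: int = 0
    dropped_ambiguous: int = 0
    dropped_allele_mismatch: int = 0

    @property
    def dropped(self) -> int:
        return (self.dropped_not_in_reference + self.dropped_ambiguous
                + self.dropped_allele_mismatch)


@dataclass
class GenotypePanel:
    """Individual-level dosages for a set of samples and SNPs.

    ``dosages`` is samples x SNPs, counting copies of a1 (or standardized
    values if ``standardized``). ``monomorphic`` flags zero-variance SNPs.
    """

    sample_ids: np.ndarray
    snps: pd.DataFrame  # snp_id, chrom, pos, a1, a2
    dosages: np.ndarray
    standardized: bool = False
    monomorphic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(np.unique(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage matrix shape does not match sample/SNP metadata")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(self.dosages.shape[1], dtype=bool)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp_id"].to_numpy()

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def standardize(self) -> "GenotypePanel":
        """Center each SNP column and scale by its population (1/n) sd.

        Monomorphic columns become all-zero and are flagged. Missing
        dosages must have been imputed beforehand (read_genotypes does).
        """
        if self.standardized:
            return self
        X = self.dosages.astype(float).copy()
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population convention (ddof=0)
        mono = sd < 1e-12
        sd_safe = np.where(mono, 1.0, sd)
        X = (X - mean) / sd_safe
        X[:, mono] = 0.0
        return GenotypePanel(self.sample_ids, self.snps.copy(), X,
                             standardized=True, monomorphic=mono)

    def subset(self, snp_ids) -> "GenotypePanel":
        keep = self.snps["snp_id"].isin(set(snp_ids)).to_numpy()
        return GenotypePanel(self.sample_ids, self.snps.loc[keep].reset_index(drop=True),
                             self.dosages[:, keep], self.standardized,
                             self.monomorphic[keep])

    def score(self, weights: pd.Series) -> np.ndarray:
        """Polygenic score X @ w, aligning ``weights`` (indexed by snp_id)
        to this panel's SNPs; weights for absent SNPs are dropped with a log."""
        idx = pd.Index(self.snp_ids)
        common = weights.index.intersection(idx)
        n_drop = len(weights) - len(common)
        if n_drop:
            logger.info("score: %d of %d weighted SNPs absent from panel",
                        n_drop, len(weights))
        if len(common) == 0:
            return np.zeros(self.n_samples)
        pos = idx.get_indexer(common)
        return self.dosages[:, pos] @ weights.loc[common].to_numpy(dtype=float)


DEFAULT_COLUMN_MAP = {
    "snp_id": "snp_id", "chrom": "chrom", "pos": "pos",
    "a1": "a1", "a2": "a2", "r": "r", "n": "n", "freq": "freq",
}


def read_sumstats(path: str, population: str, ld_reference_snps: pd.DataFrame,
                  column_map: dict | None = None,
                  keep_ambiguous: bool = False) -> tuple[SumStats, HarmonizationReport]:
    """Read GWAS summary statistics and harmonize alleles to a reference.

    ``ld_reference_snps`` must carry snp_id, a1, a2 in the canonical
    orientation. Records whose alleles are reversed relative to the
    reference are flipped (r negated, alleles swapped, freq -> 1-freq);
    records not in the reference, with mismatching alleles, or (by
    default) strand-ambiguous A/T, C/G pairs are dropped.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+")
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    df = pd.DataFrame({dst: raw[src] for dst, src in cmap.items()})
    df["snp_id"] = df["snp_id"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
    if df["snp_id"].duplicated().any():
        raise ValueError(f"{path}: duplicated snp_id")
    return harmonize_sumstats(df, population, ld_reference_snps, keep_ambiguous)


def harmonize_sumstats(df: pd.DataFrame, population: str,
                       ld_reference_snps: pd.DataFrame,
                       keep_ambiguous: bool = False) -> tuple[SumStats, HarmonizationReport]:
    report = HarmonizationReport()
    ref = ld_reference_snps.set_index("snp_id")
    in_ref = df["snp_id"].isin(ref.index).to_numpy()
    report.dropped_not_in_reference = int((~in_ref).sum())
    df = df.loc[in_ref].copy()
    if not keep_ambiguous:
        amb = np.array([_is_ambiguous(a1, a2) for a1, a2 in zip(df["a1"], df["a2"])])
        report.dropped_ambiguous = int(amb.sum())
        df = df.loc[~amb]
    ra1 = ref.loc[df["snp_id"], "a1"].to_numpy()
    ra2 = ref.loc[df["snp_id"], "a2"].to_numpy()
    same = (df["a1"].to_numpy() == ra1) & (df["a2"].to_numpy() == ra2)
    rev = (df["a1"].to_numpy() == ra2) & (df["a2"].to_numpy() == ra1)
    report.dropped_allele_mismatch = int((~same & ~rev).sum())
    matched = same | rev
    df = df.loc[matched]
    flip = rev[matched]
    report.flipped = int(flip.sum())
    report.kept = len(df)
    out = df.copy()
    out.loc[flip, "r"] = -out.loc[flip, "r"]
    out.loc[flip, "freq"] = 1.0 - out.loc[flip, "freq"]
    a1 = out["a1"].copy()
    out.loc[flip, "a1"] = out.loc[flip, "a2"]
    out.loc[flip, "a2"] = a1[flip]
    if (out["r"].abs() > 1).any():
        raise ValueError("standardized effect |r| > 1 after harmonization")
    return SumStats(population, out), report


def write_sumstats(ss: SumStats, path: str) -> None:
    ss.df.to_csv(path, sep="\t", index=False)


def read_genotypes(prefix: str, snp_subset=None,
                   standardize: bool = False) -> GenotypePanel:
    """Read a PLINK 1 fileset into a GenotypePanel.

    Missing genotypes are mean-imputed per SNP before any standardization.
    """
    fam, bim, dosages = _plink.read_bed(prefix)
    snps = bim.rename(columns={})[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    if snp_subset is not None:
        keep = snps["snp_id"].isin(set(map(str, snp_subset))).to_numpy()
        if not keep.any():
            raise ValueError(f"{prefix}: no requested SNPs present in .bim")
        snps = snps.loc[keep].reset_index(drop=True)
        dosages = dosages[:, keep]
    # per-SNP mean imputation
    col_mean = np.nanmean(np.where(np.isnan(dosages), np.nan, dosages), axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing column -> 0
    nan_mask = np.isnan(dosages)
    if nan_mask.any():
        dosages = np.where(nan_mask, col_mean[None, :], dosages)
    panel = GenotypePanel(fam["iid"].to_numpy(), snps, dosages, standardized=False)
    return panel.standardize() if standardize else panel


def write_genotypes(panel: GenotypePanel, prefix: str) -> None:
    if panel.standardized:
        raise ValueError("cannot write standardized dosages to PLINK bed")
    fam = pd.DataFrame({"fid": panel.sample_ids, "iid": panel.sample_ids,
                        "father": "0", "mother": "0", "sex": 0, "phenotype": -9})
    bim = panel.snps.copy()
    bim["cm"] = 0
    _plink.write_bed(prefix, fam, bim, np.asarray(panel.dosages, dtype=float))


def write_weights(weights: pd.DataFrame, path: str, sparse: bool = False) -> None:
    """Write a SNP weight table (snp_id, chrom, pos, a1, a2, weight columns).

    With ``sparse=True`` rows whose weight columns are all zero are
    omitted. Non-finite weights are refused.
    """
    if len(weights) == 0:
        raise ValueError("refusing to write an empty weight table")
    meta = ["snp_id", "chrom", "pos", "a1", "a2"]
    wcols = [c for c in weights.columns if c not in meta]
    vals = weights[wcols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("weight table contains non-finite weights")
    out = weights
    if sparse:
        out = weights.loc[(vals != 0).any(axis=1)]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                     float_precision="round_trip")
    return df
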