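"""Minimal PLINK 1 binary fileset (.bed/.bim/.fam) codec.

Only SNP-major bed files are supported (the only layout modern tools
write). Genotypes are returned as dosages of the .bim A1 allele
(0/1/2, NaN for missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit codes -> A1 dosage; 01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    return bim


def read_fam(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                       dtype={"fid": str, "iid": str})


def read_bed(prefix: str) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Read a bed/bim/fam triplet.

    Returns (fam, bim, dosages) with dosages of shape (n_samples, n_snps),
    counting copies of the A1 allele; missing genotypes are NaN.
    """
    fam = read_fam(prefix + ".fam")
    bim = read_bim(prefix + ".bim")
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _MAGIC:
        raise ValueError(f"{prefix}.bed: not a PLINK 1 bed file (bad magic bytes)")
    if raw[2] != _SNP_MAJOR:
        raise ValueError(f"{prefix}.bed: only SNP-major bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * p:
        raise ValueError(f"{prefix}.bed: size does not match {n} samples x {p} SNPs")
    mat = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, sample index increasing within each byte (LSB first)
    codes = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    for j in range(4):
        codes[:, j::4] = (mat >> (2 * j)) & 0x03
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()
    return fam, bim, dosages


def write_bed(prefix: str, fam: pd.DataFrame, bim: pd.DataFrame,
              dosages: np.ndarray) -> None:
    """Write a bed/bim/fam triplet from A1-allele dosages (NaN = missing)."""
    n, p = dosages.shape
    if len(fam) != n or len(bim) != p:
        raise ValueError("fam/bim dimensions do not match the dosage matrix")
    fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    # dosage -> 2-bit code (inverse of _CODE_TO_DOSAGE)
    codes = np.full((p, n), 0x01, dtype=np.uint8)  # missing
    d = dosages.T
    codes[d == 2.0] = 0x00
    codes[d == 1.0] = 0x02
    codes[d == 0.0] = 0x03
    bytes_per_snp = (n + 3) // 4
    padded = np.full((p, bytes_per_snp * 4), 0x00, dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for j in range(4):
        packed |= padded[:, j::4] << (2 * j)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)
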