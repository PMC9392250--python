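"""Genotype container with marker map and PLINK/TSV input-output.

Genotypes are allele counts of the counted (A1) allele, coded 0/1/2 with -1
for missing, stored individuals x SNPs as int8. The marker map carries
snp_id, chromosome (integer autosome code), 1-based bp position and allele
codes; positions are kept sorted within chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "MISSING"]

MISSING = np.int8(-1)

MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "a1", "a2"]


def _check_map(marker_map: pd.DataFrame) -> pd.DataFrame:
    m = marker_map.copy().reset_index(drop=True)
    for col in ("snp_id", "chrom", "pos_bp"):
        if col not in m.columns:
            raise ValueError(f"marker map missing column {col!r}")
    if "a1" not in m.columns:
        m["a1"] = "A"
    if "a2" not in m.columns:
        m["a2"] = "B"
    m["chrom"] = m["chrom"].astype(np.int64)
    m["pos_bp"] = m["pos_bp"].astype(np.int64)
    if (m["pos_bp"] < 1).any():
        raise ValueError("positions must be 1-based (>= 1)")
    return m[MAP_COLUMNS + [c for c in m.columns if c not in MAP_COLUMNS]]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with its marker map."""

    ids: np.ndarray
    marker_map: pd.DataFrame
    X: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.marker_map = _check_map(self.marker_map)
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.shape != (len(self.ids), len(self.marker_map)):
            raise ValueError(
                f"genotype matrix shape {self.X.shape} inconsistent with "
                f"{len(self.ids)} ids x {len(self.marker_map)} SNPs"
            )

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.marker_map)

    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (non-missing)."""
        X = self.X
        obs = X >= 0
        cnt = np.where(obs, X, 0).sum(axis=0)
        denom = 2.0 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(denom > 0, cnt / denom, np.nan)
        return p

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def individual_call_rate(self) -> np.ndarray:
        if self.n_snps == 0:
            raise ValueError("empty genotype matrix")
        return (self.X >= 0).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        return (self.X >= 0).mean(axis=0)

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_snps) if cols is None else np.asarray(cols)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            ids=self.ids[rows],
            marker_map=self.marker_map.iloc[cols].reset_index(drop=True),
            X=self.X[np.ix_(rows, cols)],
        )

    def centered(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Gene content centered by 2p, missing entries mean-imputed (-> 0).

        This is the Z matrix of the genomic relationship matrix: rows are
        individuals, column j is genotype minus twice the allele frequency.
        """
        p = self.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
        Z = self.X.astype(np.float64)
        Z[self.X < 0] = np.nan
        Z -= 2.0 * p
        np.nan_to_num(Z, copy=False, nan=0.0)
        return Z

    # ------------------------- PLINK binary ---------------------------
    # .bed magic 0x6c 0x1b, SNP-major 0x01; 2-bit codes per individual:
    # 00 hom A1 (count 2), 10 het (1), 11 hom A2 (0), 01 missing.
    _BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
    _BED_ENCODE = {2: 0, -1: 1, 1: 2, 0: 3}

    def to_plink(self, prefix: str) -> None:
        fam = pd.DataFrame(
            {
                "fid": self.ids,
                "iid": self.ids,
                "father": 0,
                "mother": 0,
                "sex": 0,
                "pheno": -9,
            }
        )
        fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
        bim = pd.DataFrame(
            {
                "chrom": self.marker_map["chrom"],
                "snp_id": self.marker_map["snp_id"],
                "cm": 0,
                "pos_bp": self.marker_map["pos_bp"],
                "a1": self.marker_map["a1"],
                "a2": self.marker_map["a2"],
            }
        )
        bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
        n = self.n_individuals
        nbytes = (n + 3) // 4
        with open(f"{prefix}.bed", "wb") as fh:
            fh.write(bytes([0x6C, 0x1B, 0x01]))
            codes = np.empty((self.n_snps, n), dtype=np.uint8)
            for g, c in self._BED_ENCODE.items():
                codes[ (self.X.T == g) ] = c
            buf = np.zeros((self.n_snps, nbytes * 4), dtype=np.uint8)
            buf[:, :n] = codes
            packed = (
                buf[:, 0::4]
                | (buf[:, 1::4] << 2)
                | (buf[:, 2::4] << 4)
                | (buf[:, 3::4] << 6)
            )
            fh.write(packed.astype(np.uint8).tobytes())

    @classmethod
    def from_plink(cls, prefix: str) -> "GenotypeMatrix":
        fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
        ids = fam.iloc[:, 1].astype(np.int64).to_numpy()
        bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None)
        marker_map = pd.DataFrame(
            {
                "snp_id": bim.iloc[:, 1].astype(str),
                "chrom": bim.iloc[:, 0],
                "pos_bp": bim.iloc[:, 3],
                "a1": bim.iloc[:, 4].astype(str),
                "a2": bim.iloc[:, 5].astype(str),
            }
        )
        n, m = len(ids), len(marker_map)
        nbytes = (n + 3) // 4
        with open(f"{prefix}.bed", "rb") as fh:
            magic = fh.read(3)
            if magic != bytes([0x6C, 0x1B, 0x01]):
                raise ValueError("not a SNP-major PLINK .bed file")
            raw = np.frombuffer(fh.read(), dtype=np.uint8)
        if raw.size != m * nbytes:
            raise ValueError(".bed size inconsistent with .bim/.fam")
        raw = raw.reshape(m, nbytes)
        two_bit = np.empty((m, nbytes * 4), dtype=np.uint8)
        two_bit[:, 0::4] = raw & 3
        two_bit[:, 1::4] = (raw >> 2) & 3
        two_bit[:, 2::4] = (raw >> 4) & 3
        two_bit[:, 3::4] = (raw >> 6) & 3
        X = cls._BED_DECODE[two_bit[:, :n]].T
        return cls(ids=ids, marker_map=marker_map, X=X)

    # --------------------------- plain TSV ----------------------------
    def to_tsv(self, matrix_path: str, map_path: str) -> None:
        pd.DataFrame(self.X, index=self.ids, columns=self.marker_map["snp_id"]).to_csv(
            matrix_path, sep="\t", index_label="animal"
        )
        self.marker_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path: str, map_path: str) -> "GenotypeMatrix":
        mat = pd.read_csv(matrix_path, sep="\t", index_col="animal")
        marker_map = pd.read_csv(map_path, sep="\t")
        return cls(
            ids=mat.index.to_numpy(np.int64),
            marker_map=marker_map,
            X=mat.to_numpy(np.int8),
        )
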