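"""Genotype containers and on-disk interchange formats.

The in-memory model is :class:`GenotypeMatrix` (individuals x SNPs, additive
coding 0/1/2 counting the A1 allele, -1 = missing).  On disk we speak the two
formats the GREML ecosystem standardised on: PLINK 1 binary genotype triplets
(``.bed/.bim/.fam``, SNP-major) and GCTA binary relationship matrices
(``.grm.bin/.grm.N.bin/.grm.id``).  Both codecs are bit-exact round-trippers.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "read_grm_bin",
    "write_grm_bin",
    "read_phenotype",
    "write_phenotype",
    "read_snp_list",
]

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit PLINK codes -> A1-allele dosage (-1 = missing)
_CODE_TO_CALL = np.array([2, -1, 1, 0], dtype=np.int8)
_CALL_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Raised when a PLINK/GCTA binary file violates its format contract."""


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a sample of individuals.

    Parameters
    ----------
    samples : pandas.DataFrame
        One row per individual with at least ``fid`` and ``iid`` columns.
    snps : pandas.DataFrame
        One row per SNP with ``snp``, ``chrom`` (1-22), ``pos``, ``a1``, ``a2``.
    calls : numpy.ndarray
        ``(n_samples, n_snps)`` int8 array counting A1 alleles; -1 = missing.
    annotations : dict
        Named boolean masks over SNPs (genic membership, eQTL sets, ...).
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray
    annotations: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        for name, mask in self.annotations.items():
            if len(mask) != self.n_snps:
                raise ValueError(f"annotation {name!r} length != n_snps")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        return list(zip(self.samples["fid"], self.samples["iid"]))

    @property
    def freq(self) -> np.ndarray:
        """Counted-allele (A1) frequency per SNP from non-missing calls."""
        x = np.ma.masked_equal(self.calls, -1)
        p = x.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p, dtype=float)

    @property
    def maf(self) -> np.ndarray:
        p = self.freq
        return np.minimum(p, 1.0 - p)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == -1

    def set_annotation_from_ids(self, name: str, snp_ids) -> np.ndarray:
        """Register a boolean annotation mask from a collection of SNP ids."""
        wanted = set(snp_ids)
        mask = self.snps["snp"].isin(wanted).to_numpy()
        self.annotations[name] = mask
        return mask

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/SNP index arrays."""
        sidx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        midx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            samples=self.samples.iloc[sidx].reset_index(drop=True),
            snps=self.snps.iloc[midx].reset_index(drop=True),
            calls=self.calls[np.ix_(sidx, midx)].copy(),
            annotations={k: np.asarray(v)[midx].copy() for k, v in self.annotations.items()},
            meta=dict(self.meta),
        )


def write_plink(G: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``G`` as PLINK 1 binary (``prefix.bed/.bim/.fam``), SNP-major."""
    prefix = Path(prefix)
    snps = G.snps
    chrom = np.asarray(snps["chrom"], dtype=int)
    if chrom.min() < 1 or chrom.max() > 22:
        raise PlinkFormatError("chromosomes must be autosomal (1-22)")
    if snps["a1"].isna().any() or snps["a2"].isna().any():
        raise PlinkFormatError("missing allele labels")

    n, m = G.n_samples, G.n_snps
    codes = np.empty_like(G.calls, dtype=np.uint8)
    for call, code in _CALL_TO_CODE.items():
        codes[G.calls == call] = code
    # pack 4 samples/byte, sample index increasing from the low-order bits
    n_bytes = (n + 3) // 4
    padded = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T
    shifted = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(shifted.astype(np.uint8).tobytes())

    bim = pd.DataFrame(
        {
            "chrom": chrom,
            "snp": snps["snp"],
            "cm": snps.get("cm", pd.Series(np.zeros(m))),
            "pos": snps["pos"],
            "a1": snps["a1"],
            "a2": snps["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    fam = pd.DataFrame(
        {
            "fid": G.samples["fid"],
            "iid": G.samples["iid"],
            "father": G.samples.get("father", pd.Series(["0"] * n)),
            "mother": G.samples.get("mother", pd.Series(["0"] * n)),
            "sex": G.samples.get("sex", pd.Series([0] * n)),
            "pheno": G.samples.get("pheno", pd.Series([-9] * n)),
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError("bad .bed magic bytes")
    if raw[2:3] != _SNP_MAJOR:
        raise PlinkFormatError("individual-major .bed files are not supported")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != n_bytes * m:
        raise PlinkFormatError(
            f"truncated .bed payload: expected {n_bytes * m} bytes, got {payload.size}"
        )
    payload = payload.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = payload & 3
    codes[:, 1::4] = (payload >> 2) & 3
    codes[:, 2::4] = (payload >> 4) & 3
    codes[:, 3::4] = (payload >> 6) & 3
    calls = _CODE_TO_CALL[codes[:, :n]].T

    samples = fam[["fid", "iid", "father", "mother", "sex", "pheno"]]
    snps = bim[["snp", "chrom", "pos", "a1", "a2", "cm"]]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_grm_bin(ids, A, pair_counts, prefix: str | Path) -> None:
    """Write a relationship matrix in GCTA binary form.

    ``A`` and ``pair_counts`` are full symmetric ``(n, n)`` arrays; the lower
    triangle (row-major, diagonal included) is stored as little-endian float32.
    """
    prefix = Path(prefix)
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or np.asarray(pair_counts).shape != (n, n):
        raise PlinkFormatError("GRM matrices must be square and congruent")
    tri = np.tril_indices(n)
    with open(str(prefix) + ".grm.bin", "wb") as fh:
        fh.write(A[tri].astype("<f4").tobytes())
    with open(str(prefix) + ".grm.N.bin", "wb") as fh:
        fh.write(np.asarray(pair_counts, dtype=float)[tri].astype("<f4").tobytes())
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm_bin(prefix: str | Path):
    """Read a GCTA binary GRM; returns ``(ids, A, pair_counts)`` full matrices."""
    prefix = str(prefix)
    ids_df = pd.read_csv(
        prefix + ".grm.id", sep=r"\s+", header=None, names=["fid", "iid"], dtype=str
    )
    ids = list(zip(ids_df["fid"], ids_df["iid"]))
    n = len(ids)
    n_tri = n * (n + 1) // 2
    vals = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    if vals.size != n_tri:
        raise PlinkFormatError(
            f"triangle length {vals.size} does not match {n} ids (need {n_tri})"
        )
    cnts = np.fromfile(prefix + ".grm.N.bin", dtype="<f4")
    if cnts.size != n_tri:
        raise PlinkFormatError("grm.N.bin length does not match id count")
    tri = np.tril_indices(n)
    A = np.zeros((n, n))
    A[tri] = vals
    A = A + np.tril(A, -1).T
    N = np.zeros((n, n))
    N[tri] = cnts
    N = N + np.tril(N, -1).T
    return ids, A, N


def write_phenotype(path: str | Path, samples: pd.DataFrame, values) -> None:
    """Write FID IID value(s), whitespace-delimited, no header (PLINK dialect)."""
    df = pd.DataFrame({"fid": samples["fid"], "iid": samples["iid"]})
    values = np.atleast_2d(np.asarray(values))
    if values.shape[0] == 1 and values.shape[1] == len(df):
        values = values.T
    for j in range(values.shape[1]):
        df[f"v{j}"] = values[:, j]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_snp_list(path: str | Path) -> list[str]:
    """One SNP id per line (genic/eQTL membership lists and similar)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read FID IID value(s); -9 and NA parse to NaN."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str, 1: str},
                     na_values=["NA", "-9"])
    cols = ["fid", "iid"] + [f"v{j}" for j in range(df.shape[1] - 2)]
    df.columns = cols
    return df
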