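"""Readers and writers for the standard interchange formats of the pipeline.

Covers PLINK 1.9 BED/BIM/FAM triplets (SNP-major hard calls), GCTA binary
GRM triplets (``.grm.bin`` / ``.grm.N.bin`` / ``.grm.id``), and
whitespace-delimited phenotype / covariate / info-score tables keyed by
FID + IID (or variant id).

In-memory conventions:

* dosages count copies of the BIM allele-1 (the "counted" allele),
  stored as ``int8`` with :data:`MISSING` (−1) for no-calls;
* phenotypes are 0 = control, 1 = case, −1 = missing (PLINK's 1/2/−9
  codes are translated at the disk boundary);
* sex is 1 = male, 2 = female, 0 = unknown (the FAM code, unchanged).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "PlinkFormatError",
    "TableFormatError",
    "VariantInfo",
    "SampleInfo",
    "GenotypeMatrix",
    "KinshipMatrix",
    "read_plink",
    "write_plink",
    "read_grm_gcta",
    "write_grm_gcta",
    "read_table",
]

#: Sentinel for a missing hard call in a dosage matrix.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit code -> dosage of allele-1 (00=hom A1, 01=missing, 10=het, 11=hom A2)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """A PLINK file violates the BED/BIM/FAM format contract."""


class TableFormatError(ValueError):
    """A phenotype/covariate/info-score table is malformed."""


@dataclass
class VariantInfo:
    """One variant's metadata; ``allele_a1`` is the counted allele."""

    chrom: str
    pos: int
    id: str
    allele_a1: str
    allele_a2: str
    freq_a1: float | None = None
    info_score: float = 1.0

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.allele_a1 == self.allele_a2:
            raise ValueError(f"variant {self.id}: alleles must differ")
        if self.freq_a1 is not None and not (0.0 <= self.freq_a1 <= 1.0):
            raise ValueError(f"variant {self.id}: freq_a1 outside [0, 1]")
        if not (0.0 <= self.info_score <= 1.0):
            raise ValueError(f"variant {self.id}: info_score outside [0, 1]")

    @property
    def key(self) -> tuple[str, int, frozenset[str]]:
        """Cross-cohort identity: (chrom, pos, unordered allele pair)."""
        return (self.chrom, self.pos, frozenset((self.allele_a1, self.allele_a2)))


@dataclass
class SampleInfo:
    """One sample: family/individual ids, sex code, 0/1 phenotype, optional age."""

    fid: str
    iid: str
    sex: int = 0
    phenotype: int = MISSING
    age: float | None = None

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)


@dataclass
class GenotypeMatrix:
    """Hard-call dosages (n_samples × m_variants) with sample/variant metadata."""

    dosages: np.ndarray
    samples: list[SampleInfo]
    variants: list[VariantInfo]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        # int8 entries in [-1, 2] are exactly {MISSING, 0, 1, 2}
        if self.dosages.size and not (
            (self.dosages >= MISSING) & (self.dosages <= 2)
        ).all():
            bad = np.unique(self.dosages[(self.dosages < MISSING) | (self.dosages > 2)])
            raise ValueError(f"invalid dosage values {bad.tolist()}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def m_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per variant over non-missing calls (NaN if none)."""
        d = self.dosages
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        totals = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, totals / (2.0 * n_obs), np.nan)

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        variant_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.m_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(si, vi)].copy(),
            samples=[self.samples[i] for i in si],
            variants=[self.variants[j] for j in vi],
        )


@dataclass
class KinshipMatrix:
    """Symmetric n×n relatedness estimates with per-pair variant counts."""

    values: np.ndarray
    sample_ids: list[tuple[str, str]]
    n_variants_used: np.ndarray
    method_tag: str = "gcta"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.n_variants_used = np.asarray(self.n_variants_used, dtype=np.float64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"kinship shape {self.values.shape} != ({n}, {n})")
        if self.n_variants_used.shape != (n, n):
            raise ValueError("n_variants_used shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric within 1e-10")
        if np.any(np.diag(self.values) <= 0):
            raise ValueError("kinship diagonal entries must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def subset(self, idx: Sequence[int] | np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(idx)
        return KinshipMatrix(
            values=self.values[np.ix_(idx, idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            n_variants_used=self.n_variants_used[np.ix_(idx, idx)].copy(),
            method_tag=self.method_tag,
        )


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"PLINK member not found: {path}")
    return path


def read_plink(prefix: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK 1.9 BED/BIM/FAM triplet (SNP-major) at *prefix*."""
    prefix = Path(prefix)
    fam_path = _require(prefix.with_suffix(prefix.suffix + ".fam"))
    bim_path = _require(prefix.with_suffix(prefix.suffix + ".bim"))
    bed_path = _require(prefix.with_suffix(prefix.suffix + ".bed"))

    samples: list[SampleInfo] = []
    for line in fam_path.read_text().splitlines():
        if not line.strip():
            continue
        fid, iid, _pid, _mid, sex, pheno = line.split()[:6]
        samples.append(
            SampleInfo(
                fid=fid,
                iid=iid,
                sex=int(sex) if sex in ("0", "1", "2") else 0,
                phenotype={"1": 0, "2": 1}.get(pheno, MISSING),
            )
        )

    variants: list[VariantInfo] = []
    for line in bim_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, vid, _cm, pos, a1, a2 = line.split()[:6]
        variants.append(VariantInfo(chrom=chrom, pos=int(pos), id=vid, allele_a1=a1, allele_a2=a2))

    n, m = len(samples), len(variants)
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (expected {_BED_MAGIC.hex()}; "
            "only SNP-major BED is supported)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: size {len(raw)} != expected {expected} "
            f"(3 + ceil({n}/4)*{m})"
        )

    if m == 0 or n == 0:
        dosages = np.empty((n, m), dtype=np.int8)
    else:
        payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
        # unpack 2-bit codes, low bits first within each byte
        codes = (payload[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
        codes = codes.reshape(m, bytes_per_variant * 4)[:, :n]
        dosages = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeMatrix(dosages=dosages, samples=samples, variants=variants)


def write_plink(g: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write *g* as a PLINK 1.9 BED/BIM/FAM triplet at *prefix*."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(prefix.with_suffix(prefix.suffix + ".fam"), "w") as fh:
        for s in g.samples:
            pheno = {0: "1", 1: "2"}.get(s.phenotype, "-9")
            fh.write(f"{s.fid} {s.iid} 0 0 {s.sex} {pheno}\n")

    with open(prefix.with_suffix(prefix.suffix + ".bim"), "w") as fh:
        for v in g.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele_a1}\t{v.allele_a2}\n")

    n, m = g.n_samples, g.m_variants
    bytes_per_variant = (n + 3) // 4
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        if n and m:
            code_lut = np.empty(256, dtype=np.uint8)  # index by dosage + 1
            for dose, code in _DOSAGE_TO_CODE.items():
                code_lut[dose + 1] = code
            codes = code_lut[(g.dosages.T.astype(np.int16) + 1)]  # m x n
            padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
            padded[:, :n] = codes
            packed = (
                padded.reshape(m, bytes_per_variant, 4)
                << np.array([0, 2, 4, 6], dtype=np.uint8)
            ).sum(axis=2, dtype=np.uint8)
            fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# GCTA binary GRM triplet
# ---------------------------------------------------------------------------

def write_grm_gcta(k: KinshipMatrix, prefix: str | os.PathLike) -> None:
    """Write *k* in GCTA's binary GRM format (lower triangle, float32)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = k.n_samples
    tril = np.tril_indices(n)
    k.values[tril].astype("<f4").tofile(str(prefix) + ".grm.bin")
    k.n_variants_used[tril].astype("<f4").tofile(str(prefix) + ".grm.N.bin")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for fid, iid in k.sample_ids:
            fh.write(f"{fid}\t{iid}\n")


def read_grm_gcta(prefix: str | os.PathLike, method_tag: str = "gcta") -> KinshipMatrix:
    """Read a GCTA binary GRM triplet written by :func:`write_grm_gcta` (or GCTA)."""
    prefix = str(prefix)
    id_path = _require(Path(prefix + ".grm.id"))
    bin_path = _require(Path(prefix + ".grm.bin"))
    n_path = _require(Path(prefix + ".grm.N.bin"))

    sample_ids = [
        (parts[0], parts[1])
        for parts in (ln.split() for ln in id_path.read_text().splitlines() if ln.strip())
    ]
    n = len(sample_ids)
    n_tri = n * (n + 1) // 2
    tri = np.fromfile(bin_path, dtype="<f4")
    tri_n = np.fromfile(n_path, dtype="<f4")
    if tri.size != n_tri or tri_n.size != n_tri:
        raise PlinkFormatError(
            f"{bin_path}: expected {n_tri} float32 values for n={n}, "
            f"got {tri.size} (.grm.bin) / {tri_n.size} (.grm.N.bin)"
        )
    values = np.zeros((n, n))
    counts = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    values[il, jl] = tri
    values[jl, il] = tri
    counts[il, jl] = tri_n
    counts[jl, il] = tri_n
    return KinshipMatrix(values=values, sample_ids=sample_ids,
                         n_variants_used=counts, method_tag=method_tag)


# ---------------------------------------------------------------------------
# Whitespace-delimited tables
# ---------------------------------------------------------------------------

_NA_VALUES = ("-9", "NA", "na", "NaN")


def read_table(path: str | os.PathLike, kind: str) -> pd.DataFrame:
    """Read a whitespace-delimited table.

    ``kind='phenotype'``: columns FID IID PHENO (0/1 or PLINK 1/2; −9/NA missing).
    ``kind='covariate'``: columns FID IID then numeric covariates (header optional
    but recommended; a header is detected when the third field is non-numeric).
    ``kind='info_score'``: columns variant-id score.
    """
    path = Path(path)
    if kind not in ("phenotype", "covariate", "info_score"):
        raise ValueError(f"unknown table kind {kind!r}")
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")

    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    fields = first.split()
    if not fields:
        raise TableFormatError(f"{path}: empty table")

    def _is_num(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return tok in _NA_VALUES

    if kind == "info_score":
        df = pd.read_csv(path, sep=r"\s+", header=0 if not _is_num(fields[1]) else None,
                         na_values=_NA_VALUES)
        df.columns = ["ID", "INFO"] + list(df.columns[2:])
        df = df[["ID", "INFO"]].copy()
        df["ID"] = df["ID"].astype(str)
        df["INFO"] = pd.to_numeric(df["INFO"], errors="raise")
        if df["ID"].duplicated().any():
            dup = df["ID"][df["ID"].duplicated()].iloc[0]
            raise TableFormatError(f"{path}: duplicate variant id {dup!r}")
        return df

    has_header = len(fields) >= 3 and not _is_num(fields[2])
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None,
                     na_values=_NA_VALUES, dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise TableFormatError(f"{path}: need FID IID plus at least one value column")
    cols = list(df.columns)
    if not has_header:
        value_names = (["PHENO"] if kind == "phenotype"
                       else [f"COV{i}" for i in range(1, df.shape[1] - 1)])
        df.columns = ["FID", "IID"] + value_names
    else:
        df.columns = ["FID", "IID"] + [str(c) for c in cols[2:]]
    df["FID"] = df["FID"].astype(str)
    df["IID"] = df["IID"].astype(str)

    keys = df["FID"] + "\x00" + df["IID"]
    if keys.duplicated().any():
        i = int(np.flatnonzero(keys.duplicated())[0])
        raise TableFormatError(
            f"{path}: duplicate sample key ({df['FID'].iloc[i]}, {df['IID'].iloc[i]})"
        )
    for col in df.columns[2:]:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            ) from exc

    if kind == "phenotype":
        ph = df.columns[2]
        vals = df[ph].dropna().unique()
        # PLINK 1/2 coding -> internal 0/1
        if set(vals) <= {1.0, 2.0} and len(vals) > 0 and 2.0 in set(vals):
            df[ph] = df[ph] - 1.0
        if not set(df[ph].dropna().unique()) <= {0.0, 1.0}:
            raise TableFormatError(f"{path}: phenotype values must be 0/1 or 1/2")
    return df
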