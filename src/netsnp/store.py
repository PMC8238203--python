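"""Sparse genotype storage.

Biallelic diploid genotypes are encoded as small integers -- 0 for
homozygous reference, 1 for heterozygous, 2 for homozygous alternate and
-1 when either allele call is missing.  Because the vast majority of
exome loci are rare (most minor allele frequencies fall below 0.01), the
zero code dominates and only non-zero codes are stored, giving roughly a
hundred-fold reduction over the source VCF while remaining lossless.

The in-memory container wraps a ``scipy.sparse`` matrix (samples x loci)
so that per-locus allele counting over arbitrary sample subsets is a
vectorised operation.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("netsnp")

GENOTYPE_CODES = (-1, 0, 1, 2)

METADATA_COLUMNS = ("sample_id", "cohort", "status", "age", "braak", "apoe")

APOE_GENOTYPES = ("e22", "e23", "e24", "e33", "e34", "e44")


class VcfFormatError(ValueError):
    """Raised for VCF records the sparse encoding cannot represent."""


def encode_genotype(gt_call: str) -> int:
    """Encode a diploid GT string into a genotype code.

    ``0/0`` -> 0, het -> 1, ``1/1`` -> 2, any missing allele -> -1.
    Phased (``|``) and unphased (``/``) separators are equivalent.
    Allele indices >= 2 (multi-allelic records) raise ``VcfFormatError``.
    """
    sep = "/" if "/" in gt_call else "|"
    parts = gt_call.split(sep)
    if len(parts) != 2:
        raise VcfFormatError(f"not a diploid GT call: {gt_call!r}")
    alleles = []
    for p in parts:
        p = p.strip()
        if p == ".":
            alleles.append(None)
        elif p in ("0", "1"):
            alleles.append(int(p))
        else:
            raise VcfFormatError(f"unsupported allele index in {gt_call!r}")
    if alleles[0] is None or alleles[1] is None:
        return -1
    return alleles[0] + alleles[1]


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one biallelic locus (1-based VCF position)."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str] = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1 (VCF convention)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple:
        return (self.chromosome, self.position, self.alt_allele)


@dataclass
class SampleRecord:
    """Phenotype row: cohort, case/control status, age, optional Braak/APOE."""

    sample_id: str
    cohort: str
    status: str  # "case" | "control"
    age: float
    braak: Optional[int] = None
    apoe: Optional[str] = None

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case|control, got {self.status!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.braak is not None and not (1 <= int(self.braak) <= 6):
            raise ValueError("Braak stage must lie in 1..6")
        if self.apoe is not None and self.apoe not in APOE_GENOTYPES:
            raise ValueError(f"unknown APOE genotype {self.apoe!r}")


class GenotypeStore:
    """Sparse matrix of genotype codes plus per-locus metadata.

    Codes are held in a CSC matrix of int8 with explicit -1 entries for
    missing calls; code 0 is implicit (not stored).
    """

    def __init__(self, sample_ids: Sequence[str], loci: Sequence[LocusMeta],
                 matrix: sparse.spmatrix):
        self.sample_ids = list(sample_ids)
        self.loci = list(loci)
        mat = sparse.csc_matrix(matrix, dtype=np.int8)
        mat.sum_duplicates()
        if mat.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError("matrix shape does not match sample/locus counts")
        bad = np.setdiff1d(np.unique(mat.data), [-1, 1, 2])
        if bad.size:
            raise ValueError(f"invalid genotype codes in store: {bad}")
        keys = [l.key for l in self.loci]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate loci by (chromosome, position, alt)")
        self._mat = mat
        self._index = {k: i for i, k in enumerate(keys)}

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_index(self, key: tuple) -> int:
        return self._index[key]

    def dense_codes(self, rows: Optional[Sequence[int]] = None,
                    cols: Optional[Sequence[int]] = None) -> np.ndarray:
        """Dense int8 matrix of codes (missing kept as -1)."""
        mat = self._mat
        if rows is not None:
            mat = mat.tocsr()[np.asarray(rows, dtype=int)]
        if cols is not None:
            mat = sparse.csc_matrix(mat)[:, np.asarray(cols, dtype=int)]
        return np.asarray(mat.todense(), dtype=np.int8)

    def feature_codes(self, rows: Sequence[int], cols: Sequence[int]) -> np.ndarray:
        """Codes for classifier features: missing (-1) mapped to 0."""
        codes = self.dense_codes(rows, cols).astype(np.float64)
        n_missing = int((codes == -1).sum())
        if n_missing:
            logger.debug("feature matrix: %d missing cells imputed to 0", n_missing)
        codes[codes == -1] = 0.0
        return codes

    def locus_code_counts(self, rows: Optional[Sequence[int]] = None):
        """Per-locus counts of (het, hom-alt, missing) over a sample subset."""
        mat = self._mat
        if rows is not None:
            rows = np.asarray(rows, dtype=int)
            mat = mat.tocsr()[rows].tocsc()
        m = mat.shape[1]
        col_of = np.repeat(np.arange(m), np.diff(mat.indptr))
        het = np.bincount(col_of[mat.data == 1], minlength=m)
        hom = np.bincount(col_of[mat.data == 2], minlength=m)
        mis = np.bincount(col_of[mat.data == -1], minlength=m)
        return het, hom, mis

    # ------------------------------------------------------------------
    def to_nss(self, path) -> None:
        """Serialize to the .nss container: gzip text, JSON header line
        followed by one ``locus sample code`` triplet per stored entry."""
        path = Path(path)
        header = {
            "format": "nss-1",
            "sample_ids": self.sample_ids,
            "loci": [
                [l.chromosome, l.position, l.ref_allele, l.alt_allele, l.gene]
                for l in self.loci
            ],
        }
        coo = self._mat.tocoo()
        order = np.lexsort((coo.row, coo.col))
        with open(path, "wb") as raw, gzip.GzipFile(
                filename="", mode="wb", fileobj=raw,
                compresslevel=6, mtime=0) as gz:
            with io.TextIOWrapper(gz, encoding="utf-8", newline="\n") as out:
                out.write(json.dumps(header, separators=(",", ":")) + "\n")
                for i in order:
                    out.write(f"{coo.col[i]}\t{coo.row[i]}\t{coo.data[i]}\n")

    @classmethod
    def from_nss(cls, path) -> "GenotypeStore":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            header = json.loads(fh.readline())
            if header.get("format") != "nss-1":
                raise ValueError("not an nss-1 container")
            loci = [LocusMeta(c, int(p), r, a, g)
                    for c, p, r, a, g in header["loci"]]
            cols, rows, data = [], [], []
            for line in fh:
                c, r, d = line.split()
                cols.append(int(c)); rows.append(int(r)); data.append(int(d))
        mat = sparse.coo_matrix(
            (data, (rows, cols)),
            shape=(len(header["sample_ids"]), len(loci)), dtype=np.int8)
        return cls(header["sample_ids"], loci, mat)

    def to_dense_tsv(self, path) -> None:
        """Dense TSV export (small stores only): rows = loci, columns = samples."""
        codes = self.dense_codes().T
        df = pd.DataFrame(codes, columns=self.sample_ids)
        df.insert(0, "chrom", [l.chromosome for l in self.loci])
        df.insert(1, "pos", [l.position for l in self.loci])
        df.insert(2, "ref", [l.ref_allele for l in self.loci])
        df.insert(3, "alt", [l.alt_allele for l in self.loci])
        df.insert(4, "gene", [l.gene for l in self.loci])
        df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------
# VCF ingestion


def read_metadata(path) -> list[SampleRecord]:
    """Read the sample-metadata TSV (sample_id, cohort, status, age, braak, apoe)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    missing = set(("sample_id", "cohort", "status", "age")) - set(df.columns)
    if missing:
        raise ValueError(f"metadata lacks required columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        braak = getattr(row, "braak", None)
        braak = None if braak is None or pd.isna(braak) else int(braak)
        apoe = getattr(row, "apoe", None)
        apoe = None if apoe is None or (isinstance(apoe, float) and pd.isna(apoe)) else str(apoe)
        records.append(SampleRecord(str(row.sample_id), str(row.cohort),
                                    str(row.status), float(row.age), braak, apoe))
    return records


def write_metadata(records: Iterable[SampleRecord], path) -> None:
    rows = [{"sample_id": r.sample_id, "cohort": r.cohort, "status": r.status,
             "age": r.age, "braak": r.braak, "apoe": r.apoe} for r in records]
    pd.DataFrame(rows, columns=list(METADATA_COLUMNS)).to_csv(path, sep="\t", index=False)


def compress_vcf(vcf_path, metadata: Sequence[SampleRecord]) -> GenotypeStore:
    """Read a VCF (GT subfield only) into a sparse :class:`GenotypeStore`.

    Sample order follows the metadata order.  Multi-allelic records are
    skipped with a warning (pre-split with an external normalizer is the
    supported path for them).  Raises if any metadata sample is absent
    from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=False)
    vcf_samples = {s: i for i, s in enumerate(vcf.samples)}
    wanted = [r.sample_id for r in metadata]
    absent = [s for s in wanted if s not in vcf_samples]
    if absent:
        raise ValueError(f"metadata samples missing from VCF: {absent[:10]}")
    take = np.array([vcf_samples[s] for s in wanted], dtype=int)

    loci: list[LocusMeta] = []
    rows, cols, data = [], [], []
    n_skipped = 0
    for rec_no, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_skipped += 1
            logger.warning("skipping multi-allelic record %s:%d", rec.CHROM, rec.POS)
            continue
        try:
            # genotypes: rows [allele0, allele1, phased]; -1 = missing
            g = np.asarray(rec.genotypes, dtype=np.int64)[take, :2]
        except Exception as exc:  # pragma: no cover - cyvcf2 internal failures
            raise VcfFormatError(f"malformed VCF record #{rec_no + 1}") from exc
        if (g >= 2).any():
            n_skipped += 1
            logger.warning("skipping record with allele index >=2 at %s:%d",
                           rec.CHROM, rec.POS)
            continue
        codes = np.where((g < 0).any(axis=1), -1, g.sum(axis=1)).astype(np.int8)
        j = len(loci)
        gene = rec.INFO.get("GENE") if rec.INFO.get("GENE") else None
        loci.append(LocusMeta(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], gene))
        nz = np.nonzero(codes)[0]
        rows.extend(nz.tolist())
        cols.extend([j] * len(nz))
        data.extend(codes[nz].tolist())
    if n_skipped:
        logger.warning("skipped %d non-biallelic records", n_skipped)
    mat = sparse.coo_matrix((data, (rows, cols)),
                            shape=(len(wanted), len(loci)), dtype=np.int8)
    return GenotypeStore(wanted, loci, mat)


# ----------------------------------------------------------------------
# Allele statistics


@dataclass
class MinorAlleleStats:
    """Per-locus minor-allele summary over a sample subset (allele counting:
    2 alleles per non-missing sample; missing excluded from the denominator)."""

    minor_count: np.ndarray      # count of the minor allele
    total_alleles: np.ndarray    # 2 * non-missing samples
    maf: np.ndarray              # NaN where undefined (all missing)
    mfa_is_alt: np.ndarray       # bool: True where alt is the minor allele
    defined: np.ndarray          # bool: MAF defined in the subset

    @property
    def alt_count(self) -> np.ndarray:
        return np.where(self.mfa_is_alt, self.minor_count,
                        self.total_alleles - self.minor_count)


def minor_allele_stats(store: GenotypeStore,
                       subset: Optional[Sequence[int]] = None) -> MinorAlleleStats:
    """Minor-allele identity, counts and MAF per locus over ``subset``."""
    if subset is not None and len(subset) == 0:
        raise ValueError("subset must be non-empty")
    n = store.n_samples if subset is None else len(subset)
    het, hom, mis = store.locus_code_counts(subset)
    total = 2 * (n - mis)
    alt = het + 2 * hom
    defined = total > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(defined, alt / np.maximum(total, 1), np.nan)
    mfa_is_alt = alt_freq <= 0.5
    maf = np.where(mfa_is_alt, alt_freq, 1.0 - alt_freq)
    minor = np.where(mfa_is_alt, alt, total - alt)
    if not defined.all():
        logger.debug("%d loci with all genotypes missing in subset",
                     int((~defined).sum()))
    return MinorAlleleStats(minor_count=minor.astype(np.int64),
                            total_alleles=total.astype(np.int64),
                            maf=maf, mfa_is_alt=mfa_is_alt, defined=defined)
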