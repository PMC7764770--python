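"""Genotype and sample-metadata ingestion.

The internal representation is a dense samples x loci matrix of alt-allele
dosages (0, 1, 2) with ``MISSING`` (= -1) for uncalled genotypes, plus a
per-sample metadata table carrying the population cluster label (e.g.
"Northern"/"Southern") and the fishing-site id. Dosage counts ALT alleles
exactly as oriented in the VCF; no major/minor re-polarisation is applied,
since downstream F_ST and likelihood computations are invariant to allele
relabelling as long as the orientation is consistent across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for an uncalled genotype.
MISSING: int = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleTable",
    "ValidationReport",
    "read_genotype_vcf",
    "read_sample_metadata",
    "validate_dataset",
    "write_genotype_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
]


class GenotypeInputError(ValueError):
    """Raised for malformed genotype or metadata inputs."""


@dataclass
class GenotypeMatrix:
    """Dense biallelic genotype matrix with alt-allele dosage coding.

    Parameters
    ----------
    sample_ids : list of str
        Row labels; must be unique.
    locus_ids : list of str
        Column labels; must be unique.
    calls : ndarray of int8, shape (n_samples, n_loci)
        Entries in {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise GenotypeInputError(
                f"calls shape {self.calls.shape} does not match "
                f"({len(self.sample_ids)}, {len(self.locus_ids)})"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise GenotypeInputError("duplicate sample ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise GenotypeInputError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise GenotypeInputError(
                f"invalid dosage values: {np.unique(self.calls[bad])}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index], list(self.locus_ids),
            self.calls[index, :].copy(),
        )

    def subset_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            list(self.sample_ids), [self.locus_ids[i] for i in index],
            self.calls[:, index].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sample_ids), list(self.locus_ids),
                              self.calls.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls))


@dataclass
class SampleTable:
    """Per-sample metadata: cluster label and fishing-site id.

    Backed by a DataFrame with at least columns ``sample_id``, ``cluster``,
    ``site_id``; extra columns are preserved as opaque payload. Empty labels
    are stored as NaN.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "cluster", "site_id"}
        missing_cols = required - set(self.df.columns)
        if missing_cols:
            raise GenotypeInputError(
                f"metadata missing required columns: {sorted(missing_cols)}"
            )
        self.df = self.df.reset_index(drop=True)
        self.df["sample_id"] = self.df["sample_id"].astype(str)
        dup = self.df["sample_id"][self.df["sample_id"].duplicated()]
        if len(dup):
            raise GenotypeInputError(
                f"duplicate sample ids in metadata: {sorted(set(dup))}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def labels_for(self, sample_ids: list[str], by: str = "cluster") -> np.ndarray:
        """Return the grouping label per sample, aligned to ``sample_ids``.

        ``by`` is ``"cluster"`` (population level) or ``"site"`` (site_id).
        Samples absent from the table, or with an empty label, get NaN.
        """
        col = {"cluster": "cluster", "site": "site_id"}.get(by)
        if col is None:
            raise ValueError(f"unknown grouping {by!r}; use 'cluster' or 'site'")
        lookup = self.df.set_index("sample_id")[col]
        return np.array([lookup.get(s, np.nan) for s in sample_ids], dtype=object)


@dataclass
class ValidationReport:
    """Pure, side-effect-free summary of a genotype + metadata pairing."""

    n_samples: int
    n_loci: int
    n_missing_calls: int
    samples_without_metadata: list[str] = field(default_factory=list)
    monomorphic_loci: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)


def _parse_gt_record(variant, n_samples: int, locus_id: str) -> np.ndarray:
    """Map cyvcf2 genotype tuples to dosages, enforcing diploidy."""
    out = np.empty(n_samples, dtype=np.int8)
    for i, gt in enumerate(variant.genotypes):
        alleles = gt[:-1]  # last entry is the phased flag
        if len(alleles) != 2:
            raise GenotypeInputError(
                f"non-diploid genotype (ploidy {len(alleles)}) for sample index "
                f"{i} at record {locus_id}"
            )
        a, b = alleles
        if a < 0 or b < 0:
            out[i] = MISSING
        else:
            out[i] = a + b
    return out


def read_genotype_vcf(path: str | Path,
                      min_samples_called: float = 0.0) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Diploid GT fields map to alt-allele dosage (0/0 -> 0, 0/1 or 1/0 -> 1,
    1/1 -> 2, ./. -> MISSING); phased separators are treated like unphased.
    Multi-allelic or non-SNP records are skipped with a logged count. Loci
    whose called fraction falls below ``min_samples_called`` are dropped.
    Column order follows record order in the file.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise GenotypeInputError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise GenotypeInputError(f"unreadable VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        locus_id = (variant.ID if variant.ID not in (None, ".")
                    else f"{variant.CHROM}:{variant.POS}")
        dosages = _parse_gt_record(variant, n, locus_id)
        called_frac = float(np.mean(dosages != MISSING)) if n else 0.0
        if called_frac < min_samples_called:
            continue
        locus_ids.append(locus_id)
        columns.append(dosages)
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    calls = (np.column_stack(columns) if columns
             else np.empty((n, 0), dtype=np.int8))
    return GenotypeMatrix(sample_ids, locus_ids, calls)


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read a delimited metadata table (TSV or CSV, sniffed from header)."""
    path = Path(path)
    if not path.exists():
        raise GenotypeInputError(f"metadata file not found: {path}")
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in df.columns:
        df[col] = df[col].str.strip()
    df = df.mask(df == "", np.nan)
    return SampleTable(df)


def validate_dataset(g: GenotypeMatrix, s: SampleTable) -> ValidationReport:
    """Report shape, missingness, metadata coverage and monomorphic loci.

    Never raises: validation reports, the caller decides.
    """
    known = set(s.sample_ids)
    orphans = [sid for sid in g.sample_ids if sid not in known]
    mono: list[str] = []
    for j, locus in enumerate(g.locus_ids):
        col = g.calls[:, j]
        called = col[col != MISSING]
        if called.size == 0 or (called.min() == called.max() and
                                called[0] in (0, 2)):
            mono.append(locus)
    messages = []
    if orphans:
        messages.append(f"{len(orphans)} genotyped samples lack metadata")
    if mono:
        messages.append(f"{len(mono)} loci are monomorphic (or all-missing)")
    return ValidationReport(
        n_samples=g.n_samples,
        n_loci=g.n_loci,
        n_missing_calls=int(g.missing_mask.sum()),
        samples_without_metadata=orphans,
        monomorphic_loci=mono,
        messages=messages,
    )


# ---------------------------------------------------------------------------
# Writers (fixtures and the simulate CLI)

_GT_FOR_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotype_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with one biallelic SNP record per locus.

    Loci are placed on a single synthetic contig at consecutive positions
    with A/G alleles; the record ID carries the locus id, so a round trip
    through :func:`read_genotype_vcf` reproduces the matrix exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr_sim>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for j, locus in enumerate(g.locus_ids):
            gts = "\t".join(_GT_FOR_DOSAGE[int(d)] for d in g.calls[:, j])
            fh.write(f"chr_sim\t{j + 1}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Serialise as samples x loci TSV with '.' for missing calls."""
    df = pd.DataFrame(
        np.where(g.calls == MISSING, ".", g.calls.astype(str)),
        index=pd.Index(g.sample_ids, name="sample_id"),
        columns=g.locus_ids,
    )
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    calls = df.replace(".", str(MISSING)).astype(np.int8).to_numpy()
    return GenotypeMatrix(list(df.index.astype(str)),
                          list(df.columns.astype(str)), calls)
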