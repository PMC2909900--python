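"""Reading and writing case-control genotype datasets.

Two input routes: a delimited genotype table (samples x SNPs, dosages 0/1/2
as copies of the designated allele, ``NA`` for missing, plus a binary
phenotype column), and a biallelic VCF with a two-column phenotype sidecar
(sample id, 0/1 or control/case).  For VCF input the "capital" allele is the
ALT allele; downstream statistics are invariant to this orientation choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING",
    "DatasetError",
    "GenotypeDataset",
    "read_genotype_table",
    "read_vcf",
    "write_genotype_table",
]

#: Sentinel for a missing genotype in the int8 dosage matrix.
MISSING: int = -1

_CASE_WORDS = {"1", "case", "cases", "affected", "yes", "true"}
_CTL_WORDS = {"0", "control", "controls", "unaffected", "no", "false"}


class DatasetError(ValueError):
    """A genotype dataset failed validation on load."""


@dataclass
class GenotypeDataset:
    """In-memory case-control genotype matrix.

    ``genotypes[i, j]`` is the dosage (copies of the designated allele,
    0/1/2) of sample ``i`` at SNP ``j``, or :data:`MISSING`.  ``phenotype``
    is 1 for cases and 0 for controls.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    phenotype: np.ndarray
    genotypes: np.ndarray
    load_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.phenotype.shape != (n,):
            raise DatasetError("phenotype length does not match samples")
        if self.genotypes.shape != (n, m):
            raise DatasetError("genotype matrix shape does not match ids")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise DatasetError("phenotype must be binary 0/1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise DatasetError("need at least one case and one control")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"invalid dosage {self.genotypes[i, j]} for sample "
                f"{self.sample_ids[i]!r} at SNP {self.snp_ids[j]!r}")
        all_missing = (self.genotypes == MISSING).all(axis=0)
        if all_missing.any():
            j = int(np.argmax(all_missing))
            raise DatasetError(f"SNP {self.snp_ids[j]!r} has no called genotypes")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError as exc:
            raise KeyError(f"unknown SNP {snp_id!r}") from exc

    def to_dataframe(self) -> pd.DataFrame:
        geno = self.genotypes.astype(object)
        geno[self.genotypes == MISSING] = pd.NA
        df = pd.DataFrame(geno, columns=self.snp_ids)
        df.insert(0, "phenotype", self.phenotype)
        df.insert(0, "sample", self.sample_ids)
        return df


def _parse_phenotype(values, where: str) -> np.ndarray:
    out = np.empty(len(values), dtype=np.int8)
    for i, v in enumerate(values):
        word = str(v).strip().lower()
        if word in _CASE_WORDS:
            out[i] = 1
        elif word in _CTL_WORDS:
            out[i] = 0
        else:
            raise DatasetError(f"unparseable phenotype {v!r} in {where}")
    return out


def read_genotype_table(path,
                        phenotype_col: str = "phenotype",
                        sample_col: str | None = None,
                        delimiter: str | None = None) -> GenotypeDataset:
    """Load a delimited genotype table.

    The table must have a header row, one phenotype column (case=1,
    control=0), and one column of 0/1/2 dosages per SNP; ``NA`` or empty
    cells are missing.  The sample-id column defaults to the first column
    when it is non-numeric, otherwise row numbers are used.
    """
    path = Path(path)
    sep = delimiter
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str,
                     na_values=["NA", "NaN", "nan", ""], keep_default_na=False)
    if phenotype_col not in df.columns:
        raise DatasetError(f"phenotype column {phenotype_col!r} not found in {path}")
    if sample_col is None and len(df.columns) and df.columns[0] != phenotype_col:
        first = df.columns[0]
        if not df[first].str.fullmatch(r"[012]|NA", na=True).all():
            sample_col = first
    if sample_col is not None:
        sample_ids = df[sample_col].astype(str).tolist()
        value_cols = [c for c in df.columns if c not in (sample_col, phenotype_col)]
    else:
        sample_ids = [str(i) for i in range(len(df))]
        value_cols = [c for c in df.columns if c != phenotype_col]
    phenotype = _parse_phenotype(df[phenotype_col].tolist(), str(path))

    geno = np.full((len(df), len(value_cols)), MISSING, dtype=np.int8)
    for j, col in enumerate(value_cols):
        series = df[col]
        called = series.notna()
        vals = series[called]
        ok = vals.str.fullmatch(r"[012]")
        if not ok.all():
            bad = vals[~ok].iloc[0]
            raise DatasetError(f"invalid dosage {bad!r} in SNP column {col!r}")
        geno[called.to_numpy(), j] = vals.astype(np.int8)

    ds = GenotypeDataset(sample_ids=sample_ids, snp_ids=list(value_cols),
                         phenotype=phenotype, genotypes=geno)
    miss = float((ds.genotypes == MISSING).mean()) if ds.n_snps else 0.0
    ds.load_report = {"path": str(path), "samples": ds.n_samples,
                      "snps": ds.n_snps, "cases": ds.n_cases,
                      "controls": ds.n_controls, "missing_fraction": miss}
    logger.info("loaded %d samples x %d SNPs from %s (%.1f%% missing)",
                ds.n_samples, ds.n_snps, path, 100 * miss)
    return ds


def read_phenotype_file(path) -> dict[str, int]:
    """Two-column (sample, phenotype) TSV/CSV sidecar for VCF input."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise DatasetError(f"phenotype file {path} needs two columns")
    # tolerate a header row
    first = str(df.iloc[0, 1]).strip().lower()
    if first not in _CASE_WORDS | _CTL_WORDS:
        df = df.iloc[1:]
    pheno = _parse_phenotype(df.iloc[:, 1].tolist(), str(path))
    return dict(zip(df.iloc[:, 0].astype(str), (int(v) for v in pheno)))


def read_vcf(path, phenotype_file) -> GenotypeDataset:
    """Load a biallelic VCF; dosage counts the ALT allele.

    Multiallelic sites are skipped (tallied in ``load_report``); uncalled
    genotypes become :data:`MISSING`.  Every VCF sample must appear in the
    phenotype sidecar.
    """
    from cyvcf2 import VCF

    pheno_map = read_phenotype_file(phenotype_file)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pheno_map]
    if missing_samples:
        raise DatasetError(
            f"samples in VCF but not in phenotype file: {missing_samples[:5]}")

    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        dosage = np.asarray(var.gt_types, dtype=np.int8)
        dosage[dosage == 3] = MISSING  # gts012: 3 = unknown
        snp_ids.append(var.ID if var.ID not in (None, ".", "")
                       else f"{var.CHROM}:{var.POS}")
        columns.append(dosage)
    if not snp_ids:
        raise DatasetError(f"no biallelic sites in {path}")
    geno = np.stack(columns, axis=1)
    phenotype = np.array([pheno_map[s] for s in samples], dtype=np.int8)
    ds = GenotypeDataset(sample_ids=samples, snp_ids=snp_ids,
                         phenotype=phenotype, genotypes=geno)
    ds.load_report = {"path": str(path), "samples": ds.n_samples,
                      "snps": ds.n_snps, "multiallelic_skipped": skipped,
                      "cases": ds.n_cases, "controls": ds.n_controls}
    if skipped:
        logger.warning("skipped %d multiallelic site(s) in %s", skipped, path)
    return ds


def write_genotype_table(dataset: GenotypeDataset, path,
                         delimiter: str = "\t") -> None:
    """Write a dataset in the delimited-table input format (NA for missing)."""
    df = dataset.to_dataframe()
    df.to_csv(path, sep=delimiter, index=False, na_rep="NA")
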