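"""Reading genotypes, phenotypes and pedigree structure; writing scan results.

Supported inputs
----------------
* VCF 4.x (GT field only) via cyvcf2; biallelic SNPs are converted to
  alt-allele dosage, half-calls and missing GTs become missing, and
  multi-allelic records are skipped with a reported count.
* A plain-text dosage matrix dialect: TSV with columns ``snp_id``,
  ``chrom``, ``pos`` followed by one column per subject holding
  0/1/2/NA.
* A long-format phenotype table (CSV or TSV) with one row per subject
  visit and columns subject_id, pedigree_id, visit, age, smoke,
  medicine, gender, SBP, DBP; extra columns pass through.

Pedigree structure is a flat grouping id (the pedigree_id column): the
permutation schemes need membership only, not relationships.

Missing-value codes throughout: ``NA``, ``.``, empty string.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_CODES = ["NA", ".", ""]


@dataclass(eq=False)
class GenotypeMatrix:
    """Hard-call genotypes for m SNPs over a fixed subject order.

    ``dosages`` is an (m, n_subjects) float array of alt-allele counts
    in {0, 1, 2} with NaN for missing; subject order is identical across
    all rows and given by ``samples``.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]

    def __post_init__(self):
        if self.dosages.shape != (len(self.snp_ids), len(self.samples)):
            raise ValueError("dosage matrix shape does not match SNP/sample counts")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a dosage matrix.

    Coordinates stay 1-based as in the file.  Multi-allelic or
    non-SNP records are skipped (count logged); a file with zero usable
    records is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        dose = np.full(len(samples), np.nan)
        for j, gt in enumerate(var.genotypes):
            a = gt[:-1]  # last element is the phased flag
            if len(a) == 2 and a[0] >= 0 and a[1] >= 0:
                dose[j] = float(a[0] + a[1])
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(dose)
    if n_skipped:
        logger.warning("skipped %d multi-allelic/non-SNP record(s)", n_skipped)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    return GenotypeMatrix(
        snp_ids=np.asarray(ids), chrom=np.asarray(chroms),
        pos=np.asarray(poss, dtype=int), ref=np.asarray(refs),
        alt=np.asarray(alts), dosages=np.vstack(rows), samples=samples,
    )


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    """Read the simple TSV dosage dialect (snp_id, chrom, pos, subjects...)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str},
                     na_values=MISSING_CODES, keep_default_na=False)
    meta = ["snp_id", "chrom", "pos"]
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"dosage matrix missing required column(s): {missing}")
    samples = [c for c in df.columns if c not in meta]
    if not samples or df.empty:
        raise ValueError(f"no usable dosage records in {path}")
    dosages = df[samples].to_numpy(dtype=float)
    m = df.shape[0]
    return GenotypeMatrix(
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=int),
        ref=np.full(m, "N", dtype=object), alt=np.full(m, "N", dtype=object),
        dosages=dosages, samples=samples,
    )


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read and validate the long-format phenotype/covariate table.

    Delimiter is comma for ``.csv`` paths, tab otherwise.  Validates
    that (subject_id, visit) pairs are unique and that each subject has
    a single pedigree id; unknown extra columns are preserved.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, na_values=MISSING_CODES,
                     keep_default_na=False,
                     dtype={"subject_id": str, "pedigree_id": str})
    from .covariates import REQUIRED_LONG_COLUMNS

    missing = [c for c in REQUIRED_LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing required column(s): {missing}")
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "visit"]].to_records(index=False)
        raise ValueError(f"duplicate (subject_id, visit) pairs: {list(offenders)[:5]}")
    ped_counts = df.groupby("subject_id")["pedigree_id"].nunique()
    conflicted = ped_counts[ped_counts > 1]
    if not conflicted.empty:
        raise ValueError(
            f"subject(s) with conflicting pedigree ids: {list(conflicted.index)[:5]}"
        )
    return df


# ---------------------------------------------------------------------------
# results TSV

def _fmt_score(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6g}"


def _fmt_p(x) -> str:
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.6e}"


def result_columns(schemes: Iterable[str]) -> list[str]:
    cols = ["snp_id", "chrom", "pos", "env", "outcome", "n_used",
            "I_T", "I_G", "I_E", "I_GxE"]
    cols += [f"p_{s}" for s in schemes]
    cols += ["p_lrm", "flag"]
    return cols


def write_results(results: Iterable, path_or_handle, schemes: Iterable[str]) -> int:
    """Stream scan results to a TSV file; returns the row count written.

    One header line, rows in input order, scores printed to 6
    significant digits, p-values in scientific notation, missing values
    as ``NA``; the file ends with a newline.  Partial output is flushed
    before any I/O error propagates.
    """
    schemes = list(schemes)
    own = isinstance(path_or_handle, (str, bytes)) or hasattr(path_or_handle, "__fspath__")
    fh: IO[str] = open(path_or_handle, "w", encoding="utf-8") if own else path_or_handle
    n = 0
    try:
        fh.write("\t".join(result_columns(schemes)) + "\n")
        for res in results:
            sc = res.scores
            fields = [
                str(res.snp_id), str(res.chrom), str(res.pos), str(res.env),
                str(res.outcome), str(res.n_used),
                _fmt_score(sc.i_t if sc else None),
                _fmt_score(sc.i_g if sc else None),
                _fmt_score(sc.i_e if sc else None),
                _fmt_score(sc.i_gxe if sc else None),
            ]
            fields += [_fmt_p(res.p_perm.get(s)) for s in schemes]
            fields += [_fmt_p(res.p_lrm), res.flag if res.flag else "."]
            fh.write("\t".join(fields) + "\n")
            n += 1
    except OSError:
        logger.warning("I/O failure while writing %s; partial output flushed", path_or_handle)
        fh.flush()
        raise
    finally:
        fh.flush()
        if own:
            fh.close()
    return n


def read_results(path: str) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                       dtype={"snp_id": str, "chrom": str, "env": str,
                              "outcome": str, "flag": str})
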