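"""Genotype and phenotype ingestion, variant/line filters, record assembly.

Supported genotype sources: PLINK .bed/.bim/.fam trios (variant-major bed),
VCF v4.x (diploid GT field, read through cyvcf2), and plain delimited dosage
tables (rows = lines, columns = variants, NA = missing). Matching writers
exist for each format so synthetic datasets can be round-tripped through the
same readers the real data would use.
"""

from __future__ import annotations

import logging
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, RecordFrame

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "filter_variants",
    "complete_case_lines",
    "assemble_records",
    "records_from_sex_temperature",
]

_PLINK_MAGIC = b"\x6c\x1b\x01"
# two-bit codes in a variant-major .bed, mapped to alternate-allele dosage
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11
_DOSAGE_TO_BED_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read a genotype matrix, coercing calls to dosages in {0, 1, 2, missing}.

    Parameters
    ----------
    path
        For ``plink-bed``, the path of any member of the trio (or the prefix);
        for the other formats, the file itself.
    format
        One of ``plink-bed``, ``vcf``, ``delimited-dosage``.
    """
    readers = {
        "plink-bed": _read_plink,
        "vcf": _read_vcf,
        "delimited-dosage": _read_delimited,
    }
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one of {sorted(readers)}")
    return readers[format](Path(path))


def _read_delimited(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise IOError(f"genotype file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return GenotypeMatrix(
        line_ids=df.index.astype(str).to_numpy(dtype=object),
        variant_ids=df.columns.astype(str).to_numpy(dtype=object),
        dosages=df.to_numpy(dtype=float),
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    if not path.exists():
        raise IOError(f"VCF not found: {path}")
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = np.array(vcf.samples, dtype=object)
    variant_ids, columns = [], []
    n_multiallelic = 0
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for var in vcf:
        if len(var.ALT) > 1:
            n_multiallelic += 1
            continue
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        variant_ids.append(vid)
        columns.append(gt_map[np.asarray(var.gt_types)])
    vcf.close()
    if n_multiallelic:
        logger.warning("dropped %d multi-allelic site(s) from %s", n_multiallelic, path)
    dosages = (
        np.column_stack(columns) if columns else np.empty((len(line_ids), 0))
    )
    return GenotypeMatrix(line_ids, np.array(variant_ids, dtype=object), dosages)


def _plink_prefix(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in {".bed", ".bim", ".fam"} else path


def _read_plink(path: Path) -> GenotypeMatrix:
    prefix = _plink_prefix(path)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise IOError(f"PLINK trio member not found: {f}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    line_ids = fam_df[1].to_numpy(dtype=object)  # IID column
    variant_ids = bim_df[1].to_numpy(dtype=object)
    n, p = len(line_ids), len(variant_ids)
    raw = bed.read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{bed} is not a variant-major PLINK .bed (bad magic)")
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * p
    if len(raw) != expected:
        raise ValueError(
            f"{bed}: size {len(raw)} inconsistent with {n} samples x {p} variants "
            f"(expected {expected})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_variant)
    # unpack 2-bit codes, sample-within-byte little-endian
    codes = np.stack(
        [(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(p, -1)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # (n, p)
    return GenotypeMatrix(line_ids, variant_ids, dosages)


# ---------------------------------------------------------------------------
# writers


def write_genotypes(g: GenotypeMatrix, path, format: str) -> None:
    """Write a genotype matrix in one of the supported formats.

    ``plink-bed`` writes the trio next to ``path`` (treated as prefix).
    Heterozygous and missing calls survive every format; round-tripping
    through :func:`read_genotypes` is bit-faithful.
    """
    path = Path(path)
    if format == "delimited-dosage":
        df = pd.DataFrame(g.dosages, index=g.line_ids, columns=g.variant_ids)
        df.index.name = "line_id"
        df.to_csv(path, na_rep="NA")
    elif format == "vcf":
        _write_vcf(g, path)
    elif format == "plink-bed":
        _write_plink(g, _plink_prefix(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    gt_strings = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in g.line_ids)
            + "\n"
        )
        for j, vid in enumerate(g.variant_ids):
            calls = [
                gt_strings.get(d, "./.") if not np.isnan(d) else "./."
                for d in g.dosages[:, j]
            ]
            fh.write(f"1\t{j + 1}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def _write_plink(g: GenotypeMatrix, prefix: Path) -> None:
    n, p = g.n_lines, g.n_variants
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for lid in g.line_ids:
            fh.write(f"{lid} {lid} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, vid in enumerate(g.variant_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\tA\tT\n")
    codes = np.full((p, n), 1, dtype=np.uint8)  # 01 = missing
    for dosage, code in _DOSAGE_TO_BED_CODE.items():
        codes[(g.dosages.T == dosage)] = code
    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((p, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# filters


def filter_variants(
    g: GenotypeMatrix, maf_min: float = 0.05, max_missing: float = 0.2
) -> GenotypeMatrix:
    """Keep variants with MAF >= ``maf_min`` and missing rate <= ``max_missing``.

    MAF is min(f, 1-f) of the alternate-allele frequency computed from
    non-missing calls. Boundary values survive both filters (variants are
    removed only when strictly below the MAF threshold or strictly above the
    missingness threshold). Allele frequencies are recomputed on the output.
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not (0.0 <= max_missing <= 1.0):
        raise ValueError(f"max_missing must be in [0, 1], got {max_missing}")
    maf_ok = g.maf >= maf_min
    miss_ok = g.missing_rate <= max_missing
    keep = maf_ok & miss_ok
    if not keep.any():
        raise ValueError(
            f"all {g.n_variants} variants removed "
            f"({int((~maf_ok).sum())} below MAF {maf_min}, "
            f"{int((~miss_ok).sum())} above missing rate {max_missing})"
        )
    logger.info(
        "variant filter retained %d/%d (MAF >= %g, missing <= %g)",
        int(keep.sum()), g.n_variants, maf_min, max_missing,
    )
    return g.subset_variants(keep)


def complete_case_lines(records: RecordFrame, required_envs) -> RecordFrame:
    """Drop every record of any line missing a phenotype in a required environment.

    A line is removed if, for at least one environment in ``required_envs``,
    it has no record or its phenotype is NaN. The surviving lines form a
    complete grid over ``required_envs``.
    """
    required = list(required_envs)
    observed = set(records.table["env_id"])
    unknown = [e for e in required if e not in observed]
    if unknown:
        raise KeyError(f"required environments never observed: {unknown}")
    tab = records.table
    ok = tab["phenotype"].notna() & tab["env_id"].isin(required)
    per_line = tab.loc[ok].groupby("line_id")["env_id"].nunique()
    complete = set(per_line.index[per_line == len(required)])
    n_dropped = records.n_lines - len(complete)
    if n_dropped:
        logger.info("complete-case filter dropped %d of %d lines", n_dropped, records.n_lines)
    if not complete:
        logger.warning("complete-case filter removed every line")
    out = tab[tab["line_id"].isin(complete)].copy()
    return RecordFrame(out, list(records.covariate_names))


# ---------------------------------------------------------------------------
# assembly


def assemble_records(phenotype_table: pd.DataFrame, env_table: pd.DataFrame) -> RecordFrame:
    """Join phenotypes with environment covariates into an aligned RecordFrame.

    ``phenotype_table`` needs columns ``line_id``, ``env_id``, ``phenotype``;
    ``env_table`` has one row per environment: ``env_id`` plus the covariate
    columns, in the order they should appear in the q x c covariate matrix.
    """
    for col in ("line_id", "env_id", "phenotype"):
        if col not in phenotype_table.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    if "env_id" not in env_table.columns:
        raise ValueError("environment table missing column 'env_id'")
    covariate_names = [c for c in env_table.columns if c != "env_id"]
    unmatched = set(phenotype_table["env_id"]) - set(env_table["env_id"])
    if unmatched:
        raise KeyError(f"env_id not present in environment table: {sorted(unmatched)}")
    merged = phenotype_table[["line_id", "env_id", "phenotype"]].merge(
        env_table, on="env_id", how="left"
    )
    return RecordFrame(merged, covariate_names)


def records_from_sex_temperature(pheno: pd.DataFrame) -> RecordFrame:
    """Build a RecordFrame from a (line_id, sex, temperature, value) table.

    Environments are the sex-by-temperature cells, labelled ``F_18``-style.
    Sex is coded 0 for female, 1 for male; temperature is kept in degrees C.
    """
    df = pd.DataFrame(
        {
            "line_id": pheno["line_id"].astype(str),
            "sex": pheno["sex"],
            "temperature": pd.to_numeric(pheno["temperature"]),
            "phenotype": pd.to_numeric(pheno["value"]),
        }
    )
    sex_code = df["sex"].map(
        lambda s: {"F": 0, "M": 1, "0": 0, "1": 1, 0: 0, 1: 1}[s]
    )
    df["sex_code"] = sex_code.astype(float)
    df["env_id"] = np.where(sex_code == 0, "F", "M") + "_" + df["temperature"].map(
        lambda t: f"{t:g}"
    )
    env_table = (
        df.groupby("env_id", as_index=False)[["sex_code", "temperature"]]
        .first()
        .rename(columns={"sex_code": "sex"})
    )
    pheno_table = df[["line_id", "env_id", "phenotype"]]
    return assemble_records(pheno_table, env_table)
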