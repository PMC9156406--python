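"""Readers and writers for every pipeline input and output format.

Genotypes round-trip through PLINK BED/BIM/FAM (hard calls; the BIM
allele1 column is the dosage-counted effect allele) or plain-text VCF
(ALT is the counted allele; dosages from the DS FORMAT field when
present, otherwise from GT).  Tabular inputs (expression + sample
metadata, eQTL catalog, GWAS summary, phenotypes, gene annotation) are
TSV with schema validation; rows violating per-row invariants are
returned in a sidecar reject table instead of aborting the run.
Coordinates are 1-based inclusive (GRCh37/VCF convention) throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from coexprs.types import ExpressionMatrix, GenotypeDosageMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 .bed

# 2-bit PLINK codes -> dosage of the BIM allele1 (NaN = missing)
_BED_CODE_TO_DOSAGE = {0b00: 2.0, 0b01: np.nan, 0b10: 1.0, 0b11: 0.0}
_DOSAGE_TO_BED_CODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM


def write_plink(genotypes: GenotypeDosageMatrix, prefix: str) -> None:
    """Write hard-call dosages as <prefix>.bed/.bim/.fam (SNP-major).

    Dosages must be in {0, 1, 2, NaN}.  BIM allele1 = effect allele,
    allele2 = other allele, so a read-back counts the same allele.
    """
    dos = genotypes.dosages.to_numpy(dtype=float)
    finite = dos[~np.isnan(dos)]
    if not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
        raise ValueError("PLINK BED stores hard calls; dosages must be 0/1/2 or missing")
    n_ind, n_snp = dos.shape

    fam = pd.DataFrame(
        {
            "fid": genotypes.dosages.index,
            "iid": genotypes.dosages.index,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    v = genotypes.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "variant_id": v.index,
            "cm": 0,
            "pos": v["pos"],
            "a1": v["effect_allele"],
            "a2": v["other_allele"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    n_bytes = (n_ind + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(n_snp):
            buf = bytearray(n_bytes)
            col = dos[:, j]
            for i in range(n_ind):
                code = 0b01 if np.isnan(col[i]) else _DOSAGE_TO_BED_CODE[col[i]]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


def read_plink(prefix: str) -> GenotypeDosageMatrix:
    """Read <prefix>.bed/.bim/.fam into an effect-allele dosage matrix."""
    for ext in (".bed", ".bim", ".fam"):
        if not os.path.exists(prefix + ext):
            raise FileNotFoundError(f"missing companion file {prefix + ext}")
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
    )
    n_ind, n_snp = len(fam), len(bim)
    n_bytes = (n_ind + 3) // 4
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(
                f"bad PLINK BED magic bytes {magic!r} at offset 0 (expect SNP-major v1)"
            )
        data = fh.read()
    expected = n_bytes * n_snp
    if len(data) != expected:
        raise ValueError(
            f"truncated .bed: {len(data)} payload bytes at offset 3, expected {expected}"
        )
    raw = np.frombuffer(data, dtype=np.uint8).reshape(n_snp, n_bytes)
    # unpack 2-bit codes, individuals along axis 1
    codes = np.stack(
        [(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
    ).reshape(n_snp, n_bytes * 4)[:, :n_ind]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T  # individuals x SNPs
    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"].astype(str).to_numpy(),
            "pos": bim["pos"].astype(int).to_numpy(),
            "effect_allele": bim["a1"].to_numpy(),
            "other_allele": bim["a2"].to_numpy(),
        },
        index=pd.Index(bim["variant_id"], name="variant_id"),
    )
    frame = pd.DataFrame(
        dosages,
        index=pd.Index(fam["iid"].astype(str), name="individual_id"),
        columns=variants.index,
    )
    return GenotypeDosageMatrix(dosages=frame, variants=variants)


# ---------------------------------------------------------------------------
# VCF


def write_vcf(genotypes: GenotypeDosageMatrix, path: str) -> None:
    """Write a plain-text VCF with GT and DS fields; ALT is the counted allele."""
    dos = genotypes.dosages
    v = genotypes.variants
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n'
        )
        for chrom in pd.unique(v["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, dos.index))
            + "\n"
        )
        mat = dos.to_numpy(dtype=float)
        for j, vid in enumerate(v.index):
            row = v.iloc[j]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(vid),
                str(row["other_allele"]),
                str(row["effect_allele"]),
                ".",
                "PASS",
                ".",
                "GT:DS",
            ]
            for d in mat[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    hard = float(round(d))
                    gt = gt_of.get(hard, "./.") if abs(d - hard) < 1e-9 else "./."
                    fields.append(f"{gt}:{d:g}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str) -> GenotypeDosageMatrix:
    """Read a VCF into ALT-allele dosages (DS field preferred, else GT)."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        return _read_vcf_text(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, meta, ids = [], [], []
    for var in vcf:
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            col = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(col)
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        meta.append(
            {
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "effect_allele": str(var.ALT[0]) if var.ALT else ".",
                "other_allele": str(var.REF),
            }
        )
    variants = pd.DataFrame(
        meta, index=pd.Index(ids, name="variant_id"),
        columns=["chrom", "pos", "effect_allele", "other_allele"],
    )
    if rows:
        dosages = np.column_stack(rows)
    else:
        dosages = np.empty((len(samples), 0))
    frame = pd.DataFrame(
        dosages, index=pd.Index(samples, name="individual_id"), columns=variants.index
    )
    return GenotypeDosageMatrix(dosages=frame, variants=variants)


def _read_vcf_text(path: str) -> GenotypeDosageMatrix:
    """Minimal text fallback for uncompressed VCF with GT[:DS] fields."""
    samples: list[str] = []
    rows, meta, ids = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            parts = line.split("\t")
            if line.startswith("#CHROM"):
                samples = parts[9:]
                continue
            fmt = parts[8].split(":")
            ds_i = fmt.index("DS") if "DS" in fmt else None
            gt_i = fmt.index("GT") if "GT" in fmt else None
            col = []
            for cell in parts[9:]:
                sub = cell.split(":")
                val = np.nan
                if ds_i is not None and ds_i < len(sub) and sub[ds_i] not in (".", ""):
                    val = float(sub[ds_i])
                elif gt_i is not None and gt_i < len(sub):
                    alleles = sub[gt_i].replace("|", "/").split("/")
                    if "." not in alleles:
                        val = float(sum(int(a) > 0 for a in alleles))
                col.append(val)
            rows.append(np.array(col))
            ids.append(parts[2] if parts[2] != "." else f"{parts[0]}_{parts[1]}")
            meta.append(
                {
                    "chrom": parts[0],
                    "pos": int(parts[1]),
                    "effect_allele": parts[4],
                    "other_allele": parts[3],
                }
            )
    variants = pd.DataFrame(
        meta, index=pd.Index(ids, name="variant_id"),
        columns=["chrom", "pos", "effect_allele", "other_allele"],
    )
    dosages = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    frame = pd.DataFrame(
        dosages, index=pd.Index(samples, name="individual_id"), columns=variants.index
    )
    return GenotypeDosageMatrix(dosages=frame, variants=variants)


def read_genotypes(path: str, fmt: str = "auto") -> GenotypeDosageMatrix:
    """Dispatch to the PLINK or VCF reader (``fmt``: plink-bed / vcf / auto)."""
    if fmt == "auto":
        fmt = "vcf" if path.endswith(".vcf") or path.endswith(".vcf.gz") else "plink-bed"
    if fmt == "plink-bed":
        prefix = path[:-4] if path.endswith(".bed") else path
        return read_plink(prefix)
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# TSV tables with schema validation


@dataclass
class TableSchema:
    name: str
    required: tuple[str, ...]
    row_check: object = None  # callable(row) -> reason str or None


def _check_eqtl_row(row) -> str | None:
    if row["effect_allele"] == row["other_allele"]:
        return "effect_allele equals other_allele"
    if not (len(str(row["effect_allele"])) == 1 and len(str(row["other_allele"])) == 1):
        return "multi-allelic / non-single-base alleles"
    if str(row["effect_allele"]) not in "ACGT" or str(row["other_allele"]) not in "ACGT":
        return "non-ACGT allele"
    if not (0 < row["pval_nominal"] <= 1):
        return "pval_nominal outside (0, 1]"
    return None


def _check_gwas_row(row) -> str | None:
    if row["effect_allele"] == row["other_allele"]:
        return "effect_allele equals other_allele"
    if not (0 < row["p"] <= 1):
        return "p outside (0, 1]"
    return None


def _check_annotation_row(row) -> str | None:
    if row["start"] > row["end"]:
        return "start > end"
    chrom = str(row["chrom"]).removeprefix("chr")
    if not chrom.isdigit() or not (1 <= int(chrom) <= 22):
        return "non-autosomal chromosome"
    return None


SCHEMAS = {
    "eqtl": TableSchema(
        "eqtl",
        (
            "gene_id",
            "variant_id",
            "chrom",
            "pos",
            "effect_allele",
            "other_allele",
            "slope",
            "pval_nominal",
        ),
        _check_eqtl_row,
    ),
    "gwas": TableSchema(
        "gwas", ("variant_id", "effect_allele", "other_allele", "beta", "p"), _check_gwas_row
    ),
    "annotation": TableSchema(
        "annotation", ("gene_id", "chrom", "start", "end"), _check_annotation_row
    ),
    "phenotype": TableSchema("phenotype", ("individual_id",)),
    "sample_meta": TableSchema("sample_meta", ("sample_id", "region", "stage")),
}


def read_table(path: str, schema: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a TSV against a named schema; returns (valid rows, rejected rows).

    Header matching is order-insensitive; a missing mandatory column
    raises a schema error naming it.  Rejected rows carry a ``reason``
    column (the sidecar report).
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    sch = SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(sch.required) - set(df.columns)
    if missing:
        raise ValueError(f"{sch.name} table missing mandatory columns: {sorted(missing)}")
    if sch.row_check is None or df.empty:
        return df, pd.DataFrame(columns=[*df.columns, "reason"])
    reasons = df.apply(sch.row_check, axis=1)
    bad = reasons.notna()
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    return df[~bad].reset_index(drop=True), rejected.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# expression matrix


def write_expression(expr: ExpressionMatrix, values_path: str, meta_path: str) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id")
    expr.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_expression(values_path: str, meta_path: str) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="gene_id")
    meta, rejected = read_table(meta_path, "sample_meta")
    if len(rejected):
        raise ValueError(f"{len(rejected)} invalid sample-metadata rows")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, samples=meta)
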