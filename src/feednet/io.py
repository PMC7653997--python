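"""File formats: PLINK BED/BIM/FAM, phenotype TSV, annotation BED/GFF3.

Coordinate conventions: BIM and GFF3 are 1-based; annotation BED is
0-based half-open and converted on read, so everything is 1-based closed
in memory. Strand is carried but ignored by SNP-in-gene tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DataFormatError, GenotypeMatrix, ValidationError

__all__ = [
    "read_plink",
    "write_plink",
    "read_phenotypes",
    "write_phenotypes",
    "read_annotation",
    "write_annotation_bed",
    "write_annotation_gff3",
]

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = 0x01

# 2-bit PLINK codes -> A1 dosage; 0b01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

PHENOTYPE_REQUIRED = [
    "animal_id",
    "initial_weight",
    "final_weight",
    "test_days",
    "FI",
    "year",
    "dam_age_class",
    "twinning",
    "final_age",
]


# ---------------------------------------------------------------- PLINK

def read_plink(prefix: str) -> GenotypeMatrix:
    """Read a PLINK ``prefix.bed/.bim/.fam`` triplet (SNP-major BED)."""
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        raw = fh.read()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise DataFormatError(
            f"{prefix}.bed: bad magic bytes at offset 0: {raw[:2]!r}"
        )
    if raw[2] != _SNP_MAJOR:
        raise DataFormatError(
            f"{prefix}.bed: unsupported mode byte {raw[2]:#04x} at offset 2 "
            "(only SNP-major 0x01 supported)"
        )
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise DataFormatError(
            f"{prefix}.bed: payload is {len(raw)} bytes, expected {expected} "
            f"for {n} individuals x {m} variants (mismatch from offset "
            f"{min(len(raw), expected)})"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T  # (n, m)
    variants = bim[["variant_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=list(fam["iid"]))


def write_plink(g: GenotypeMatrix, prefix: str) -> None:
    """Write a SNP-major PLINK triplet; fractional dosages are rounded."""
    n, m = g.n_individuals, g.n_variants
    fam = pd.DataFrame(
        {
            "fid": g.samples,
            "iid": g.samples,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "variant_id": g.variants["variant_id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["a1"],
            "a2": g.variants["a2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    dos = np.rint(g.dosages)
    codes = np.full(dos.shape, 0b01, dtype=np.uint8)  # missing
    codes[dos == 2] = 0b00
    codes[dos == 1] = 0b10
    codes[dos == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            # pad with homozygous-A2 (0b11) to fill the final byte
            [codes, np.full((pad, m), 0b11, dtype=np.uint8)], axis=0
        )
    codes = codes.T.reshape(m, -1, 4)  # (m, bytes, 4)
    packed = (
        codes[:, :, 0]
        | (codes[:, :, 1] << 2)
        | (codes[:, :, 2] << 4)
        | (codes[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


# ------------------------------------------------------------ phenotypes

def read_phenotypes(path: str, required=None) -> pd.DataFrame:
    """Read a tab-separated phenotype table; 'NA' marks missing values.

    Missing values in required fields are rejected.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"animal_id": str})
    required = PHENOTYPE_REQUIRED if required is None else required
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise DataFormatError(f"{path}: missing required columns {missing_cols}")
    bad = [c for c in required if df[c].isna().any()]
    if bad:
        raise ValidationError(f"{path}: NA values in required fields {bad}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ------------------------------------------------------------ annotation

def read_annotation(path: str) -> pd.DataFrame:
    """Read gene intervals from BED (``*.bed``) or GFF3, 1-based closed out.

    Returns a DataFrame with ``gene_id, chrom, start, end, strand``.
    """
    if path.endswith((".gff", ".gff3")):
        return _read_gff3(path)
    return _read_bed(path)


def _read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=range(4),
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
    )
    if (df["end"] <= df["start"]).any():
        raise DataFormatError(f"{path}: BED intervals must satisfy start < end")
    out = df.copy()
    out["start"] = df["start"] + 1  # 0-based half-open -> 1-based closed
    out["strand"] = "."
    return out[["gene_id", "chrom", "start", "end", "strand"]]


def _read_gff3(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise DataFormatError(f"{path}:{ln}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
                    break
            if gene_id is None:
                raise DataFormatError(f"{path}:{ln}: gene feature without ID=")
            rows.append((gene_id, chrom, int(start), int(end), strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    if df["gene_id"].duplicated().any():
        raise DataFormatError(f"{path}: duplicated gene IDs")
    return df


def write_annotation_bed(ann: pd.DataFrame, path: str) -> None:
    out = pd.DataFrame(
        {
            "chrom": ann["chrom"],
            "start": ann["start"] - 1,  # back to 0-based half-open
            "end": ann["end"],
            "gene_id": ann["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_annotation_gff3(ann: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in ann.itertuples(index=False):
            strand = row.strand if row.strand in "+-" else "."
            fh.write(
                f"{row.chrom}\tfeednet\tgene\t{row.start}\t{row.end}\t.\t"
                f"{strand}\t.\tID={row.gene_id}\n"
            )
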