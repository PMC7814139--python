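"""Readers and writers for PLINK BED/BIM/FAM, GMT gene sets and gene ranges.

The PLINK binary layout is the SNP-major variant-1 format: a three-byte
header ``6c 1b 01`` followed by one row of ceil(n/4) bytes per variant, each
byte packing four samples two bits each, first sample in the lowest-order
bits.  Two-bit codes: ``00`` homozygous A1, ``01`` missing, ``10``
heterozygous, ``11`` homozygous A2.

The FAM family-ID column carries the genotyping batch label, which is how
this pipeline tracks platform/batch strata.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    CASE,
    CONTROL,
    MISSING,
    PHENO_MISSING,
    GeneModel,
    GeneSetCollection,
    GenotypeDataset,
    genes_frame,
)

_MAGIC = bytes((0x6C, 0x1B, 0x01))

# genotype count (A1 copies) -> 2-bit code, and back
_COUNT_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)

_SEX_TO_FAM = {"male": "1", "female": "2", "unknown": "0"}
_FAM_TO_SEX = {"1": "male", "2": "female"}


class PlinkFormatError(ValueError):
    """Malformed PLINK binary header or payload."""


class PlinkIntegrityError(ValueError):
    """BED payload size inconsistent with BIM/FAM dimensions."""


def _byte_decode_table() -> np.ndarray:
    """(256, 4) table mapping a packed byte to four A1 counts, sample 0 in
    the low-order bit pair."""
    table = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for k in range(4):
            table[byte, k] = _CODE_TO_COUNT[(byte >> (2 * k)) & 0b11]
    return table


_DECODE = _byte_decode_table()


def decode_bed_bytes(payload: np.ndarray, n_samples: int) -> np.ndarray:
    """Decode one variant's packed bytes into ``n_samples`` A1 counts."""
    return _DECODE[payload].reshape(-1)[:n_samples]


def encode_bed_bytes(counts: np.ndarray) -> np.ndarray:
    """Pack A1 counts (one variant, all samples) into SNP-major bytes."""
    counts = np.asarray(counts, dtype=np.int8)
    n = counts.size
    padded = np.full(-(-n // 4) * 4, 0, dtype=np.int8)  # pad with hom A2? no:
    # pad with code 0b00? PLINK pads with zero bits (code 00 = hom A1); any
    # pad value works because readers truncate to n. Use hom A2 (0) to match
    # the common convention of zero-count padding being ignored.
    padded[:n] = counts
    codes = np.empty(padded.size, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        codes[padded == count] = code
    quads = codes.reshape(-1, 4)
    packed = (
        quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    )
    return packed.astype(np.uint8)


def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK binary fileset.

    Accepts either a single prefix (``read_plink("cohort")``) or explicit
    ``.bed``/``.bim``/``.fam`` paths.
    """
    if bim_path is None and fam_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = Path(prefix + ".bed")
        bim_path = Path(prefix + ".bim")
        fam_path = Path(prefix + ".fam")
    else:
        bed_path, bim_path, fam_path = (
            Path(prefix_or_bed),
            Path(bim_path),
            Path(fam_path),
        )

    variants = _read_bim(bim_path)
    samples = _read_fam(fam_path)
    n, m = len(samples), len(variants)

    raw = bed_path.read_bytes()
    if raw[:2] != _MAGIC[:2]:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if len(raw) < 3 or raw[2] != 0x01:
        raise PlinkFormatError(f"{bed_path}: not in SNP-major mode")
    bytes_per_variant = -(-n // 4)
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise PlinkIntegrityError(
            f"{bed_path}: payload {payload.size} bytes, expected "
            f"{bytes_per_variant * m} for {n} samples x {m} variants"
        )
    decoded = _DECODE[payload.reshape(m, bytes_per_variant)]
    genotypes = decoded.reshape(m, -1)[:, :n].T.copy()
    ds = GenotypeDataset(genotypes, variants, samples)
    ds.validate()
    return ds


def write_plink(dataset: GenotypeDataset, prefix) -> dict[str, Path]:
    """Write a dataset as BED/BIM/FAM; round-trips losslessly via read_plink."""
    dataset.validate()
    prefix = str(prefix)
    bed_path, bim_path, fam_path = (
        Path(prefix + ".bed"),
        Path(prefix + ".bim"),
        Path(prefix + ".fam"),
    )
    _write_bim(dataset.variants, bim_path)
    _write_fam(dataset.samples, fam_path)
    n, m = dataset.n_samples, dataset.n_variants
    with open(bed_path, "wb") as fh:
        fh.write(_MAGIC)
        for j in range(m):
            fh.write(encode_bed_bytes(dataset.genotypes[:, j]).tobytes())
    return {"bed": bed_path, "bim": bim_path, "fam": fam_path}


def _read_bim(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "rsid", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "rsid": str, "a1": str, "a2": str},
    ) if Path(path).stat().st_size else pd.DataFrame(
        columns=["chrom", "rsid", "cm", "bp", "a1", "a2"]
    )
    out = df[["chrom", "rsid", "bp", "a1", "a2"]].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["bp"] = out["bp"].astype(np.int64) if len(out) else out["bp"]
    return out


def _write_bim(variants: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        for row in variants.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.rsid}\t0\t{row.bp}\t{row.a1}\t{row.a2}\n")


def _read_fam(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    pheno = df["pheno"].map({"2": CASE, "1": CONTROL}).fillna(PHENO_MISSING)
    out = pd.DataFrame(
        {
            "sample_id": df["iid"],
            "phenotype": pheno.astype(np.int8),
            "batch": df["fid"],
            "sex": df["sex"].map(_FAM_TO_SEX).fillna("unknown"),
        }
    )
    return out


def _write_fam(samples: pd.DataFrame, path: Path) -> None:
    pheno_map = {CASE: "2", CONTROL: "1", PHENO_MISSING: "-9"}
    with open(path, "w") as fh:
        for row in samples.itertuples(index=False):
            fh.write(
                f"{row.batch}\t{row.sample_id}\t0\t0\t"
                f"{_SEX_TO_FAM.get(row.sex, '0')}\t{pheno_map[int(row.phenotype)]}\n"
            )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------
class GmtParseError(ValueError):
    pass


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Gene tokens must be Entrez integers; duplicates within a line are
    dropped with a warning.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            name, description = fields[0], fields[1]
            genes: list[int] = []
            for tok in fields[2:]:
                if not tok:
                    continue
                try:
                    genes.append(int(tok))
                except ValueError:
                    raise GmtParseError(
                        f"{path}:{lineno}: non-integer gene token {tok!r}"
                    ) from None
            if len(set(genes)) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate gene ids in set {name!r}; deduplicated"
                )
            collection.add(name, genes, description)
    return collection


def write_gmt(collection: GeneSetCollection, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.provenance.get(name, "") or "."
            genes = "\t".join(str(g) for g in collection[name])
            fh.write(f"{name}\t{desc}\t{genes}\n")
    return path


def filter_gene_sets(
    collection: GeneSetCollection, min_genes: int = 10
) -> tuple[GeneSetCollection, list[str]]:
    """Drop gene sets with fewer than ``min_genes`` members.

    Returns the surviving collection and the names of the removed sets.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    keep = [n for n in collection.names() if len(collection[n]) >= min_genes]
    removed = [n for n in collection.names() if len(collection[n]) < min_genes]
    return collection.subset(keep), removed


# ---------------------------------------------------------------------------
# Gene ranges (tab-separated: gene_id, chrom, start, end, symbol)
# ---------------------------------------------------------------------------
_CHROM_ORDER = {str(c): c for c in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "XY": 25, "MT": 26})


def _chrom_sort_key(chrom: str) -> int:
    return _CHROM_ORDER.get(str(chrom), 99)


def read_gene_ranges(path) -> list[GeneModel]:
    """Read a 5-column gene range table, returned sorted by (chrom, start)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "chrom", "start", "end", "symbol"],
        dtype={"chrom": str, "symbol": str},
    )
    models = []
    for row in df.itertuples(index=False):
        models.append(
            GeneModel(
                gene_id=int(row.gene_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                symbol="" if pd.isna(row.symbol) else str(row.symbol),
            )
        )
    models.sort(key=lambda g: (_chrom_sort_key(g.chrom), g.start, g.gene_id))
    return models


def write_gene_ranges(genes: Sequence[GeneModel], path) -> Path:
    path = Path(path)
    genes_frame(genes).to_csv(path, sep="\t", header=False, index=False)
    return path
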