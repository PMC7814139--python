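"""Core in-memory containers for case-control genotype data.

Genotypes are stored as an ``n_samples x n_variants`` int8 matrix counting
copies of the A1 (minor) allele, with :data:`MISSING` (-1) marking no-calls.
Variant and sample metadata live in pandas DataFrames so that they can be
sliced, joined and written out with ordinary pandas idioms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call. Kept distinct from 0 everywhere.
MISSING: int = -1

#: Phenotype codes in ``samples["phenotype"]``.
CONTROL, CASE, PHENO_MISSING = 0, 1, -1

VARIANT_COLUMNS = ("chrom", "rsid", "bp", "a1", "a2")
SAMPLE_COLUMNS = ("sample_id", "phenotype", "batch", "sex")

AUTOSOMES = tuple(str(c) for c in range(1, 23))


@dataclass(frozen=True)
class VariantRecord:
    """A single biallelic marker; ``a1`` is the minor allele by convention."""

    chrom: str
    rsid: str
    bp: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise ValueError(f"{self.rsid}: bp must be >= 1, got {self.bp}")
        if self.a1 == self.a2:
            raise ValueError(f"{self.rsid}: a1 and a2 must differ")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    phenotype: int = PHENO_MISSING  # CASE, CONTROL or PHENO_MISSING
    batch: str = "0"
    sex: str = "unknown"  # {male, female, unknown}

    def __post_init__(self) -> None:
        if self.phenotype not in (CASE, CONTROL, PHENO_MISSING):
            raise ValueError(f"invalid phenotype code {self.phenotype}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"invalid sex {self.sex!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene interval, 1-based inclusive on both ends."""

    gene_id: int
    chrom: str
    start: int
    end: int
    symbol: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class GeneSetCollection:
    """Named sets of Entrez gene IDs with a free-text provenance tag per set.

    Gene IDs within a set are stored deduplicated, preserving first-seen
    order so that round-trips through GMT files are stable.
    """

    def __init__(
        self,
        sets: Mapping[str, Sequence[int]] | None = None,
        provenance: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, list[int]] = {}
        self.provenance: dict[str, str] = {}
        for name, genes in (sets or {}).items():
            self.add(name, genes, (provenance or {}).get(name, ""))

    def add(self, name: str, genes: Iterable[int], provenance: str = "") -> None:
        seen: dict[int, None] = {}
        for g in genes:
            seen.setdefault(int(g), None)
        self.sets[name] = list(seen)
        self.provenance[name] = provenance

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> list[int]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        names = list(names)
        return GeneSetCollection(
            {n: self.sets[n] for n in names},
            {n: self.provenance[n] for n in names},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self.sets)} sets)"


@dataclass
class GenotypeDataset:
    """An ``n x m`` A1-allele-count matrix plus variant/sample metadata.

    Invariants (checked by :meth:`validate`):

    * ``genotypes.shape == (len(samples), len(variants))``
    * entries are in ``{0, 1, 2, MISSING}``
    * rsids and sample_ids are unique
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if not isinstance(self.variants, pd.DataFrame):
            self.variants = variants_frame(self.variants)
        if not isinstance(self.samples, pd.DataFrame):
            self.samples = samples_frame(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # ---- shape / accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy()

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def is_control(self) -> np.ndarray:
        return self.phenotype == CONTROL

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.genotypes != MISSING

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} genotype rows")
        if len(self.variants) != m:
            raise ValueError(f"{len(self.variants)} variant rows for {m} columns")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries outside {0,1,2,missing}")
        if self.variants["rsid"].duplicated().any():
            dups = self.variants.loc[self.variants["rsid"].duplicated(), "rsid"]
            raise ValueError(f"duplicate rsids: {list(dups[:5])}")
        if self.samples["sample_id"].duplicated().any():
            dups = self.samples.loc[self.samples["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample ids: {list(dups[:5])}")
        if m and (self.variants["bp"] < 1).any():
            raise ValueError("variant bp must be >= 1")

    # ---- frequencies -------------------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Per-variant A1 allele frequency over non-missing calls (NaN if none)."""
        g = self.genotypes
        called = g != MISSING
        counts = np.where(called, g, 0).sum(axis=0)
        denom = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def orient_minor(self) -> tuple["GenotypeDataset", np.ndarray]:
        """Flip variants whose A1 frequency exceeds 0.5 so A1 is the minor allele.

        Returns the reoriented dataset and a boolean mask of flipped variants.
        """
        freq = self.allele_frequencies()
        flip = np.nan_to_num(freq) > 0.5
        g = self.genotypes.copy()
        if flip.any():
            cols = g[:, flip]
            swapped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
            g[:, flip] = swapped
        variants = self.variants.copy()
        a1 = variants["a1"].to_numpy().copy()
        a2 = variants["a2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip], a1[flip].copy()
        variants["a1"], variants["a2"] = a1, a2
        return GenotypeDataset(g, variants, self.samples.copy()), flip

    # ---- subsetting --------------------------------------------------------
    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            self.genotypes[index],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            self.genotypes[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(sample_ids)
        keep = ~self.samples["sample_id"].isin(drop).to_numpy()
        return self.take_samples(keep)

    def drop_variants(self, rsids: Iterable[str]) -> "GenotypeDataset":
        drop = set(rsids)
        keep = ~self.variants["rsid"].isin(drop).to_numpy()
        return self.take_variants(keep)

    def variant_index(self, rsids: Iterable[str]) -> np.ndarray:
        """Column indices of the given rsids, in the given order."""
        lookup = pd.Series(
            np.arange(self.n_variants), index=self.variants["rsid"].to_numpy()
        )
        return lookup.loc[list(rsids)].to_numpy()

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.genotypes.copy(), self.variants.copy(), self.samples.copy()
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
        )

    def __repr__(self) -> str:
        n_case = int(self.is_case.sum())
        n_ctrl = int(self.is_control.sum())
        return (
            f"GenotypeDataset({self.n_samples} samples "
            f"[{n_case} cases / {n_ctrl} controls], {self.n_variants} variants)"
        )


def variants_frame(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [(v.chrom, v.rsid, v.bp, v.a1, v.a2) for v in records]
    df = pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
    df["chrom"] = df["chrom"].astype(str)
    df["bp"] = df["bp"].astype(np.int64)
    return df


def samples_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = [(s.sample_id, s.phenotype, s.batch, s.sex) for s in records]
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    df["phenotype"] = df["phenotype"].astype(np.int8)
    return df


def genes_frame(models: Iterable[GeneModel]) -> pd.DataFrame:
    rows = [(g.gene_id, g.chrom, g.start, g.end, g.symbol) for g in models]
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "symbol"])
    df["chrom"] = df["chrom"].astype(str)
    return df
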