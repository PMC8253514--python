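"""In-memory containers shared across the pipeline.

Coordinates are 1-based inclusive everywhere inside the package (VCF
convention); BED input/output is converted at the I/O boundary.  Missing
genotypes are encoded as -1 in dosage matrices and as NaN in statistic
panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: Required columns of a variant table, in canonical order.
VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


def make_variant_table(
    chrom,
    pos,
    ref=None,
    alt=None,
    snp_id=None,
    consequence=None,
) -> pd.DataFrame:
    """Assemble a canonical variant table (one row per biallelic SNP).

    ``pos`` is 1-based.  ``snp_id`` defaults to ``"<chrom>:<pos>"``.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "G", dtype=object)
    if snp_id is None:
        snp_id = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    df = pd.DataFrame(
        {"snp_id": snp_id, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    )
    if consequence is not None:
        df["consequence"] = consequence
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].head(3).tolist()
        raise ValueError(f"duplicate snp_id values, e.g. {dups}")
    return df


def _check_sorted(variants: pd.DataFrame) -> None:
    grp = variants.groupby("chrom", sort=False)["pos"]
    if not grp.apply(lambda s: s.is_monotonic_increasing).all():
        raise ValueError("variants must be sorted by position within chromosome")


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes: ``2N`` rows (two per sample, adjacent) x ``M`` SNPs.

    Alleles are 0 (ref) / 1 (alt); phased data carry no missing calls.
    """

    haplotypes: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D (2N x M)")
        if self.haplotypes.shape[0] != 2 * len(self.samples):
            raise ValueError("haplotype row count must equal 2 x samples")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype column count must match variant table")
        _check_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def to_genotypes(self, groups: dict[str, str] | None = None) -> "GenotypeMatrix":
        """Collapse phased haplotypes into diploid dosages {0,1,2}."""
        dos = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        return GenotypeMatrix(dos, self.variants.copy(), list(self.samples), groups or {})

    def take_sites(self, idx) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            self.haplotypes[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )

    def take_samples(self, which: list[str]) -> "HaplotypeMatrix":
        pos = [self.samples.index(s) for s in which]
        rows = np.ravel([(2 * i, 2 * i + 1) for i in pos])
        return HaplotypeMatrix(self.haplotypes[rows], self.variants.copy(), list(which))


@dataclass
class GenotypeMatrix:
    """Diploid dosages: ``N`` samples x ``M`` SNPs, values {0,1,2,-1 missing}."""

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (N x M)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage row count must equal sample count")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage column count must match variant table")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        _check_sorted(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def group_of(self, sample: str) -> str:
        return self.groups[sample]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups.get(s) == group]

    def take_sites(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
            dict(self.groups),
        )

    def take_samples(self, which: list[str]) -> "GenotypeMatrix":
        pos = [self.samples.index(s) for s in which]
        return GenotypeMatrix(
            self.dosages[pos],
            self.variants.copy(),
            list(which),
            {s: g for s, g in self.groups.items() if s in set(which)},
        )


@dataclass
class SelectionRegion:
    """A contiguous run of SNPs below the boundary q threshold containing at
    least one SNP below the strong threshold."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_snp: str
    peak_pos: int
    peak_q: float
    member_snps: list[str]
    group: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.member_snps)


@dataclass
class CnvRegion:
    """Group-level consolidated CNV region (1-based inclusive)."""

    group: str
    chrom: str
    start_bp: int
    end_bp: int
    supporting_samples: frozenset[str]
    cn_class: str  # "loss" (CN 0) or "gain" (CN >= 4)

    @property
    def n_support(self) -> int:
        return len(self.supporting_samples)
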