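"""Readers and writers for the formats the pipeline touches.

Internal coordinates are always 1-based inclusive (VCF convention).
BED (0-based half-open) is converted at this boundary and the dialect
is remembered for round-trip writing.  Every writer logs a
sha256-stamped line for provenance.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from sweepscan.containers import (
    GenotypeMatrix,
    HaplotypeMatrix,
    make_variant_table,
)

logger = logging.getLogger("sweepscan.io")

BED0_HALFOPEN = "bed0_halfopen"
TSV1_INCLUSIVE = "tsv1_inclusive"


def _log_written(path: Path) -> None:
    digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    logger.info("wrote %s sha256=%s", path, digest)


def read_vcf(path) -> tuple[GenotypeMatrix, HaplotypeMatrix | None, pd.DataFrame]:
    """Load a VCF into dosages (+ haplotypes when fully phased).

    Multi-allelic and non-SNP records are dropped (count logged).  The
    haplotype matrix is returned only when every genotype call is
    phased and non-missing; otherwise None.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_rows, hap_rows = [], []
    chroms, poss, refs, alts, ids = [], [], [], [], []
    n_dropped = 0
    all_phased = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        gts = rec.genotypes
        if gts is None:
            raise ValueError(f"record {rec.CHROM}:{rec.POS} lacks GT")
        dos = np.empty(len(samples), dtype=np.int8)
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) != 3:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} sample {samples[i]}: "
                    f"non-diploid genotype {g[:-1]}"
                )
            a0, a1, phased = g
            if a0 < 0 or a1 < 0:
                dos[i] = -1
                all_phased = False
                hap[2 * i : 2 * i + 2] = 0
            else:
                dos[i] = a0 + a1
                hap[2 * i], hap[2 * i + 1] = a0, a1
                if not phased:
                    all_phased = False
        dosage_rows.append(dos)
        hap_rows.append(hap)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic-SNP records", path, n_dropped)
    variants = make_variant_table(chroms, poss, refs, alts, ids)
    dosages = (
        np.array(dosage_rows, dtype=np.int8).T
        if dosage_rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    geno = GenotypeMatrix(dosages, variants, samples)
    hapmat = None
    if all_phased and hap_rows:
        hapmat = HaplotypeMatrix(
            np.array(hap_rows, dtype=np.int8).T, variants.copy(), samples
        )
    geno.variants.attrs["n_dropped_records"] = n_dropped
    return geno, hapmat, variants


def write_vcf(hap: HaplotypeMatrix, path) -> None:
    """Write phased haplotypes as VCF 4.2 ('|'-separated GT)."""
    path = Path(path)
    v = hap.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in v["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hap.samples)
            + "\n"
        )
        h = hap.haplotypes
        for j in range(hap.n_sites):
            gts = "\t".join(
                f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(hap.n_samples)
            )
            fh.write(
                f"{v.at[j, 'chrom']}\t{v.at[j, 'pos']}\t{v.at[j, 'snp_id']}\t"
                f"{v.at[j, 'ref']}\t{v.at[j, 'alt']}\t.\t.\t.\tGT\t{gts}\n"
            )
    _log_written(path)


def read_intervals(path, dialect: str) -> pd.DataFrame:
    """Read an interval table, normalizing to 1-based inclusive.

    ``bed0_halfopen``: BED semantics (start+1, end).  ``tsv1_inclusive``:
    coordinates taken as-is.  Extra columns are preserved.  The source
    dialect is kept in ``DataFrame.attrs['dialect']`` for round-trips.
    """
    if dialect not in (BED0_HALFOPEN, TSV1_INCLUSIVE):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError("interval table needs >= 3 columns")
    names = ["chrom", "start_bp", "end_bp"] + [
        f"col{i}" for i in range(3, df.shape[1])
    ]
    df.columns = names
    df["start_bp"] = df["start_bp"].astype(np.int64)
    df["end_bp"] = df["end_bp"].astype(np.int64)
    if dialect == BED0_HALFOPEN:
        df["start_bp"] = df["start_bp"] + 1
    bad = df.index[df["start_bp"] > df["end_bp"]]
    if len(bad):
        raise ValueError(f"interval start > end at line {int(bad[0]) + 1}")
    df.attrs["dialect"] = dialect
    return df


def write_intervals(df: pd.DataFrame, path, dialect: str | None = None) -> None:
    """Write intervals back out, converting from internal coordinates."""
    dialect = dialect or df.attrs.get("dialect", TSV1_INCLUSIVE)
    out = df.copy()
    if dialect == BED0_HALFOPEN:
        out["start_bp"] = out["start_bp"] - 1
    out.to_csv(path, sep="\t", header=False, index=False)
    _log_written(Path(path))


def read_group_map(path) -> dict[str, str]:
    """2-column TSV: sample, group."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_group_map(groups: dict[str, str], path) -> None:
    pd.DataFrame(sorted(groups.items()), columns=["sample", "group"]).to_csv(
        path, sep="\t", header=False, index=False
    )
    _log_written(Path(path))


GENE_COLUMNS = ["gene_id", "gene_name", "chrom", "start_bp", "end_bp"]


def read_gene_table(path) -> pd.DataFrame:
    """5-column TSV (gene_id, gene_name, chrom, start_bp, end_bp), 1-based
    inclusive, header optional."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]) == "gene_id"
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        names=GENE_COLUMNS,
        dtype={"gene_id": str, "gene_name": str, "chrom": str},
    )
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in gene table")
    if (df["start_bp"] > df["end_bp"]).any():
        raise ValueError("gene with start > end")
    return df


def read_consequences(path) -> pd.DataFrame:
    """2+ column TSV (snp_id, consequence[, aa_change]); header optional."""
    first = pd.read_csv(path, sep="\t", nrows=1, header=None)
    has_header = str(first.iloc[0, 0]) == "snp_id"
    names = ["snp_id", "consequence", "aa_change"][: first.shape[1]]
    return pd.read_csv(
        path, sep="\t", header=0 if has_header else None, names=names, dtype=str
    )


def read_cnv_calls(path) -> pd.DataFrame:
    """BED-like TSV of per-sample CNV calls:
    chrom, start, end (0-based half-open), sample, group, CN."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start_bp", "end_bp", "sample", "group", "cn"],
        dtype={"chrom": str, "sample": str, "group": str},
    )
    df["start_bp"] = df["start_bp"].astype(np.int64) + 1
    df["cn"] = df["cn"].astype(int)
    return df


def write_outputs(
    panel: pd.DataFrame,
    regions_frame: pd.DataFrame,
    genes_frame: pd.DataFrame | None,
    cnvr_frame: pd.DataFrame | None,
    outdir,
    group: str = "all",
) -> dict[str, Path]:
    """Write the tabular output bundle for one group.

    Emits the statistic panel, regions, ranked genes, CNVRs and a
    Manhattan-ready (chrom, pos, q) table, all as TSV with fixed column
    order and deterministic row order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if not regions_frame.empty:
        known = set(panel["snp_id"])
        bad = set(regions_frame["peak_snp"]) - known
        if bad:
            raise ValueError(f"region peak SNPs absent from panel: {sorted(bad)[:3]}")

    def _emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / f"{group}.{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        _log_written(path)
        written[name] = path

    _emit(panel, "stat_panel")
    _emit(regions_frame, "regions")
    if genes_frame is not None:
        _emit(genes_frame, "ranked_genes")
    if cnvr_frame is not None:
        _emit(cnvr_frame, "cnvr")
    manhattan = panel[["chrom", "pos", "q"]].copy() if "q" in panel.columns else None
    if manhattan is not None:
        _emit(manhattan, "manhattan")
    return written
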