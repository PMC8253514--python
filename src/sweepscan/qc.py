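"""Plink-style sample and SNP quality-control filters.

Filters run in the fixed order mind -> geno -> maf, each stage
recomputing its quantity on the survivors of the previous stage (a SNP
can survive only because a badly genotyped sample was removed first).
Thresholds follow plink semantics: missingness filters are strict ">"
(a sample/SNP exactly at the limit survives), the MAF filter is strict
"<" (a SNP exactly at the floor survives).  MAF uses called alleles
only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sweepscan.containers import GenotypeMatrix


@dataclass
class QcThresholds:
    """mind: max per-sample missing fraction; geno: max per-SNP missing
    fraction; maf: min minor-allele frequency."""

    mind: float = 0.1
    geno: float = 0.1
    maf: float = 0.0
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("mind", "geno", "maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


#: thresholds used for array-genotype haplotype scans (keep almost all
#: alleles, tolerate 10% missingness)
ARRAY_HAPLOTYPE_THRESHOLDS = QcThresholds(mind=0.1, geno=0.1, maf=1e-7)
#: stricter thresholds used before allele-frequency based scans
STRICT_THRESHOLDS = QcThresholds(mind=0.05, geno=0.01, maf=0.05)


def apply_qc(
    geno: GenotypeMatrix, thresholds: QcThresholds
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three filters in order; return survivors and a report.

    The report has one row per removed entity: stage ('mind', 'geno',
    'maf'), entity id, observed value, threshold.
    """
    t = thresholds
    report_rows = []

    miss = geno.missing_mask()
    sample_miss = miss.mean(axis=1) if geno.n_sites else np.zeros(geno.n_samples)
    drop_samples = sample_miss > t.mind
    for i in np.nonzero(drop_samples)[0]:
        report_rows.append(("mind", geno.samples[i], float(sample_miss[i]), t.mind))
    if drop_samples.all():
        raise ValueError("QC removed every sample (mind filter)")
    keep_samples = [s for s, d in zip(geno.samples, drop_samples) if not d]
    g = geno.take_samples(keep_samples)

    miss = g.missing_mask()
    snp_miss = miss.mean(axis=0)
    drop_geno = snp_miss > t.geno
    for j in np.nonzero(drop_geno)[0]:
        report_rows.append(("geno", g.variants.at[j, "snp_id"], float(snp_miss[j]), t.geno))
    g = g.take_sites(np.nonzero(~drop_geno)[0])

    called = ~g.missing_mask()
    n_alleles = 2.0 * called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(called, g.dosages, 0).sum(axis=0) / n_alleles
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(n_alleles > 0, maf, 0.0)
    drop_maf = maf < t.maf
    for j in np.nonzero(drop_maf)[0]:
        report_rows.append(("maf", g.variants.at[j, "snp_id"], float(maf[j]), t.maf))
    g = g.take_sites(np.nonzero(~drop_maf)[0])

    if g.n_sites == 0:
        raise ValueError("QC removed every SNP")
    report = pd.DataFrame(
        report_rows, columns=["stage", "entity", "value", "threshold"]
    )
    return g, report
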