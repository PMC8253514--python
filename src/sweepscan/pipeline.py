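"""End-to-end orchestration: QC -> statistics -> DCMS -> regions -> genes
-> CNVR masking, per focal group, from a single run manifest.

Every stage is a pure function of (inputs, manifest, seed); the output
bundle carries a provenance JSON with versions, seed and thresholds so
two runs of the same manifest are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

import sweepscan
from sweepscan import cnvr as cnvr_mod
from sweepscan import io_formats, regions as regions_mod
from sweepscan.containers import HaplotypeMatrix
from sweepscan.dcms import DcmsConfig, attach_dcms
from sweepscan.qc import ARRAY_HAPLOTYPE_THRESHOLDS, STRICT_THRESHOLDS, QcThresholds, apply_qc
from sweepscan.selstats import WindowSpec, compute_group_stats

logger = logging.getLogger("sweepscan.pipeline")


@dataclass
class RunManifest:
    """Everything one scan needs; serializable to/from JSON."""

    vcf: str
    groups: str  # 2-column TSV path
    outdir: str
    focal_groups: Optional[list[str]] = None  # default: every group
    gene_table: Optional[str] = None
    cnv_calls: Optional[str] = None
    consequences: Optional[str] = None  # TSV: snp_id, consequence label
    #: light filter for the phased window/haplotype track
    qc: QcThresholds = field(default_factory=lambda: ARRAY_HAPLOTYPE_THRESHOLDS)
    #: strict common-variant filter for the FST track
    fst_qc: QcThresholds = field(default_factory=lambda: STRICT_THRESHOLDS)
    window: WindowSpec = field(default_factory=WindowSpec)
    dcms: DcmsConfig = field(default_factory=DcmsConfig)
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            vcf=raw["vcf"],
            groups=raw["groups"],
            outdir=raw["outdir"],
            focal_groups=raw.get("focal_groups"),
            gene_table=raw.get("gene_table"),
            cnv_calls=raw.get("cnv_calls"),
            consequences=raw.get("consequences"),
            qc=(QcThresholds(**raw["qc"]) if "qc" in raw else ARRAY_HAPLOTYPE_THRESHOLDS),
            fst_qc=(
                QcThresholds(**raw["fst_qc"]) if "fst_qc" in raw else STRICT_THRESHOLDS
            ),
            window=WindowSpec(**raw.get("window", {})),
            dcms=DcmsConfig(**raw.get("dcms", {})),
            seed=raw.get("seed", 0),
        )


def _subset_haplotypes(hap: HaplotypeMatrix, geno_qc) -> HaplotypeMatrix:
    """Restrict phased haplotypes to QC-surviving samples and SNPs."""
    keep_ids = set(geno_qc.variants["snp_id"])
    idx = np.nonzero(hap.variants["snp_id"].isin(keep_ids).to_numpy())[0]
    sub = hap.take_sites(idx)
    return sub.take_samples(list(geno_qc.samples))


def run_scan(manifest: RunManifest) -> dict:
    """Execute the full scan; returns a summary dict of per-group results.

    Stage failures abort with the stage name in the raised error.
    Missing optional inputs degrade gracefully (gene ranking or CNVR
    masking skipped with a warning).
    """
    m = manifest
    outdir = Path(m.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"groups": {}, "seed": m.seed}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    stage("load")
    geno, hap, variants = io_formats.read_vcf(m.vcf)
    geno.groups = io_formats.read_group_map(m.groups)
    if hap is None:
        raise ValueError(
            "stage load: input VCF is not fully phased; haplotype statistics "
            "(H12, H2/H1) require phased, complete genotypes"
        )

    stage("qc")
    geno_qc, qc_report = apply_qc(geno, m.qc)
    qc_path = outdir / "qc_report.tsv"
    qc_report.to_csv(qc_path, sep="\t", index=False)
    hap_qc = _subset_haplotypes(hap, geno_qc)
    geno_strict, _ = apply_qc(geno, m.fst_qc)
    fst_sites = set(geno_strict.variants["snp_id"]) & set(geno_qc.variants["snp_id"])
    logger.info(
        "qc survivors: %d samples, %d SNPs light track / %d SNPs FST track "
        "(removed %d entries)",
        geno_qc.n_samples,
        geno_qc.n_sites,
        len(fst_sites),
        len(qc_report),
    )

    if m.consequences:
        cons = io_formats.read_consequences(m.consequences)
        variants = variants.merge(cons, on="snp_id", how="left")

    gene_table = None
    if m.gene_table:
        gene_table = io_formats.read_gene_table(m.gene_table)
    cnvrs = []
    if m.cnv_calls:
        stage("cnvr")
        calls = io_formats.read_cnv_calls(m.cnv_calls)
        cnvrs = cnvr_mod.consolidate_cnvr(cnvr_mod.filter_abnormal_cn(calls))

    focal_groups = m.focal_groups or sorted(set(geno_qc.groups.values()))
    for group in focal_groups:
        stage(f"stats[{group}]")
        panel = compute_group_stats(
            hap_qc, geno_qc.groups, group, m.window, fst_sites=fst_sites
        )

        stage(f"dcms[{group}]")
        cfg = DcmsConfig(
            covariance_sample_size=m.dcms.covariance_sample_size,
            mcd_alpha=m.dcms.mcd_alpha,
            q_boundary=m.dcms.q_boundary,
            q_strong=m.dcms.q_strong,
            seed=m.seed + m.dcms.seed,
            tails=dict(m.dcms.tails),
        )
        panel, corr = attach_dcms(panel, cfg)

        stage(f"regions[{group}]")
        scored = panel.dropna(subset=["q"]).reset_index(drop=True)
        regs = regions_mod.call_regions(
            scored, cfg.q_boundary, cfg.q_strong, group=group
        )
        retained, excluded = cnvr_mod.mask_selection_regions(regs, cnvrs)

        genes_frame = None
        if gene_table is not None:
            frames = []
            for i, reg in enumerate(retained):
                ranked = regions_mod.rank_genes(reg, gene_table)
                ranked.insert(0, "region_index", i)
                frames.append(ranked)
            genes_frame = (
                pd.concat(frames, ignore_index=True)
                if frames
                else pd.DataFrame(
                    columns=["region_index", "gene_id", "gene_name", "distance_bp", "rank"]
                )
            )
        else:
            logger.warning("no gene table given: gene-ranking stage skipped")

        candidates = None
        if "consequence" in variants.columns:
            candidates = regions_mod.flag_candidate_missense(retained, variants, panel)

        stage(f"write[{group}]")
        written = io_formats.write_outputs(
            panel,
            regions_mod.regions_to_frame(retained),
            genes_frame,
            cnvr_mod.cnvrs_to_frame(cnvrs) if cnvrs else None,
            outdir,
            group=group,
        )
        excl_frame = regions_mod.regions_to_frame([r for r, _ in excluded])
        excl_frame["offending_cnvr"] = [
            f"{c.chrom}:{c.start_bp}-{c.end_bp}" for _, c in excluded
        ]
        excl_path = outdir / f"{group}.excluded_regions.tsv"
        excl_frame.to_csv(excl_path, sep="\t", index=False)
        if candidates is not None:
            cand_path = outdir / f"{group}.missense_candidates.tsv"
            candidates.to_csv(cand_path, sep="\t", index=False)

        summary["groups"][group] = {
            "n_snps": int(len(panel)),
            "n_regions": len(retained),
            "n_excluded_regions": len(excluded),
            "min_q": float(np.nanmin(panel["q"].to_numpy())) if len(panel) else None,
            "outputs": {k: str(v) for k, v in written.items()},
        }

    provenance = {
        "package": "sweepscan",
        "version": sweepscan.__version__,
        "seed": m.seed,
        "qc": vars(m.qc),
        "window": vars(m.window),
        "dcms": {k: v for k, v in vars(m.dcms).items() if k != "tails"},
        "tails": m.dcms.tails,
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return summary
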