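"""Selection regions, candidate genes, and candidate missense variants.

A selection region is a maximal contiguous run (in SNP-index order
within a chromosome) of SNPs with q below a boundary threshold
(default 0.2) that contains at least one SNP below a strong threshold
(default 0.01).  Genes overlapping a region are ranked by distance to
the region's most significant SNP; missense SNPs among region members
are flagged for peak status, FST support (smoothed FST >= 0.3) and
haplotype support (H12 or H2/H1 empirical p < 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from sweepscan.containers import SelectionRegion

FST_SUPPORT_THRESHOLD = 0.3
HAPLOTYPE_SUPPORT_P = 0.01


def call_regions(
    panel: pd.DataFrame,
    q_boundary: float = 0.2,
    q_strong: float = 0.01,
    group: str = "",
    max_gap_bp: int | None = None,
) -> list[SelectionRegion]:
    """Parse per-SNP q-values into selection regions.

    ``panel`` needs snp_id, chrom, pos, q (and optionally dcms for
    peak tie-breaking).  A SNP with missing q, or q >= q_boundary,
    breaks a run; runs without a q < q_strong seed are discarded.  With
    ``max_gap_bp`` set, a bp gap larger than the limit also breaks a
    run (off by default: contiguity lives in SNP-index space).
    """
    if q_strong > q_boundary:
        raise ValueError("q_strong must be <= q_boundary")
    if panel["q"].isna().any():
        warnings.warn("SNPs with missing q treated as non-qualifying")
    regions: list[SelectionRegion] = []
    dcms = panel["dcms"] if "dcms" in panel.columns else None
    for chrom, sub in panel.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        q = sub["q"].to_numpy(dtype=float)
        pos = sub["pos"].to_numpy()
        ids = sub["snp_id"].to_numpy()
        ok = ~np.isnan(q) & (q < q_boundary)
        run_start = None
        bounds = []
        for i in range(len(sub) + 1):
            inside = i < len(sub) and ok[i]
            if inside and run_start is not None and max_gap_bp is not None:
                if pos[i] - pos[i - 1] > max_gap_bp:
                    bounds.append((run_start, i))
                    run_start = i
                    continue
            if inside and run_start is None:
                run_start = i
            elif not inside and run_start is not None:
                bounds.append((run_start, i))
                run_start = None
        for lo, hi in bounds:
            qs = q[lo:hi]
            if not (qs < q_strong).any():
                continue
            # peak: min q, tie -> larger DCMS, then smaller position
            best = np.nonzero(qs == qs.min())[0]
            if len(best) > 1 and dcms is not None:
                d = dcms.loc[sub.index[lo:hi]].to_numpy(dtype=float)[best]
                d = np.where(np.isnan(d), -np.inf, d)
                best = best[d == d.max()]
            peak = lo + int(best[0])
            regions.append(
                SelectionRegion(
                    chrom=str(chrom),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi - 1]),
                    peak_snp=str(ids[peak]),
                    peak_pos=int(pos[peak]),
                    peak_q=float(q[peak]),
                    member_snps=[str(s) for s in ids[lo:hi]],
                    group=group,
                )
            )
    return regions


def rank_genes(
    region: SelectionRegion, genes: pd.DataFrame, top_k: int = 10
) -> pd.DataFrame:
    """Rank genes overlapping the region by distance to its peak SNP.

    ``genes`` columns: gene_id, gene_name, chrom, start_bp, end_bp
    (1-based inclusive).  Distance is 0 when the peak lies inside the
    gene, else the distance to the nearer gene boundary; ties break by
    ascending gene start.  At most ``top_k`` genes are returned, ranks
    dense from 1.
    """
    g = genes[
        (genes["chrom"].astype(str) == region.chrom)
        & (genes["start_bp"] <= region.end_bp)
        & (genes["end_bp"] >= region.start_bp)
    ].copy()
    if g.empty:
        return pd.DataFrame(
            columns=["gene_id", "gene_name", "distance_bp", "rank"]
        )
    inside = (g["start_bp"] <= region.peak_pos) & (region.peak_pos <= g["end_bp"])
    dist = np.minimum(
        np.abs(region.peak_pos - g["start_bp"]), np.abs(region.peak_pos - g["end_bp"])
    )
    g["distance_bp"] = np.where(inside, 0, dist).astype(np.int64)
    g = g.sort_values(["distance_bp", "start_bp"], kind="stable").head(top_k)
    g["rank"] = np.arange(1, len(g) + 1)
    return g[["gene_id", "gene_name", "distance_bp", "rank"]].reset_index(drop=True)


def flag_candidate_missense(
    regions: list[SelectionRegion],
    variants: pd.DataFrame,
    panel: pd.DataFrame,
    fst_threshold: float = FST_SUPPORT_THRESHOLD,
    haplotype_p: float = HAPLOTYPE_SUPPORT_P,
) -> pd.DataFrame:
    """Flag missense SNPs inside selection regions.

    One output row per (region, missense member SNP) with flags:
    ``peak_missense`` (the SNP is the region's peak), ``fst_support``
    (smoothed FST >= 0.3) and ``haplotype_support`` (H12 or H2/H1
    empirical p < 0.01).  Requires a ``consequence`` column on the
    variant table and ``fst_smoothed``, ``p_h12``, ``p_h2h1`` on the
    panel.
    """
    if "consequence" not in variants.columns:
        raise ValueError(
            "variant table lacks a 'consequence' column; missense candidates "
            "need variant-consequence annotations as input"
        )
    missense_ids = set(
        variants.loc[
            variants["consequence"]
            .astype(str)
            .str.contains("missense", case=False, na=False),
            "snp_id",
        ]
    )
    by_snp = panel.set_index("snp_id")
    rows = []
    for ridx, region in enumerate(regions):
        for snp in region.member_snps:
            if snp not in missense_ids:
                continue
            rec = by_snp.loc[snp]
            fst = float(rec.get("fst_smoothed", np.nan))
            ph12 = float(rec.get("p_h12", np.nan))
            ph2h1 = float(rec.get("p_h2h1", np.nan))
            rows.append(
                {
                    "region_index": ridx,
                    "group": region.group,
                    "chrom": region.chrom,
                    "snp_id": snp,
                    "pos": int(rec["pos"]),
                    "q": float(rec.get("q", np.nan)),
                    "fst_smoothed": fst,
                    "peak_missense": snp == region.peak_snp,
                    "fst_support": bool(fst >= fst_threshold),
                    "haplotype_support": bool(
                        (ph12 < haplotype_p) or (ph2h1 < haplotype_p)
                    ),
                }
            )
    cols = [
        "region_index",
        "group",
        "chrom",
        "snp_id",
        "pos",
        "q",
        "fst_smoothed",
        "peak_missense",
        "fst_support",
        "haplotype_support",
    ]
    return pd.DataFrame(rows, columns=cols)


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    """Tabular view of regions (deterministic column order)."""
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "n_snps": r.n_snps,
                "peak_snp": r.peak_snp,
                "peak_pos": r.peak_pos,
                "peak_q": r.peak_q,
            }
            for r in regions
        ],
        columns=[
            "group",
            "chrom",
            "start_bp",
            "end_bp",
            "n_snps",
            "peak_snp",
            "peak_pos",
            "peak_q",
        ],
    )
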