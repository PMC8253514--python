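"""Copy-number-variable regions (CNVRs) and selection-region masking.

Per-sample CNV segment calls (integer copy number per interval) are
filtered to abnormal dosages (CN 0 losses, CN >= 4 gains; CN 1-3 is
treated as normal), consolidated per group and dosage class into CNVRs
by single-linkage over a >= 50% reciprocal-overlap graph with support
from at least three distinct samples, and used to mask selection
regions whose interval overlaps a same-group CNVR by >= 1 bp.

All intervals are 1-based inclusive (length = end - start + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from sweepscan.containers import CnvRegion, SelectionRegion


def filter_abnormal_cn(calls: pd.DataFrame) -> pd.DataFrame:
    """Keep abnormal-dosage calls and label their class.

    CN 1-3 is normal dosage and dropped; CN 0 is a loss, CN >= 4 a
    gain.  Adds a ``cn_class`` column.
    """
    cn = calls["cn"].astype(int)
    keep = calls[(cn == 0) | (cn >= 4)].copy()
    keep["cn_class"] = np.where(keep["cn"].astype(int) == 0, "loss", "gain")
    return keep.reset_index(drop=True)


def _reciprocal_links(starts: np.ndarray, ends: np.ndarray, reciprocal: float):
    """Pairs (i, j) whose overlap covers >= ``reciprocal`` of both calls."""
    lengths = ends - starts + 1
    order = np.argsort(starts, kind="stable")
    links_i, links_j = [], []
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            if starts[j] > ends[i]:
                break
            ov = min(ends[i], ends[j]) - max(starts[i], starts[j]) + 1
            if ov >= reciprocal * lengths[i] and ov >= reciprocal * lengths[j]:
                links_i.append(i)
                links_j.append(j)
    return links_i, links_j


def consolidate_cnvr(
    calls: pd.DataFrame, min_support: int = 3, reciprocal: float = 0.5
) -> list[CnvRegion]:
    """Consolidate filtered calls into group-level CNVRs.

    Within each (group, chromosome, dosage class): calls are linked
    when their overlap is at least ``reciprocal`` of each call's
    length; connected components carried by >= ``min_support`` distinct
    samples become CNVRs spanning the union of their calls.  Identical
    CNVRs are deduplicated and CNVRs that touch or overlap are merged
    (supporting-sample sets are united, never reduced).
    """
    if "cn_class" not in calls.columns:
        calls = filter_abnormal_cn(calls)
    regions: list[CnvRegion] = []
    for (group, chrom, cls), sub in calls.groupby(
        ["group", "chrom", "cn_class"], sort=True
    ):
        starts = sub["start_bp"].to_numpy(dtype=np.int64)
        ends = sub["end_bp"].to_numpy(dtype=np.int64)
        samples = sub["sample"].to_numpy()
        k = len(sub)
        li, lj = _reciprocal_links(starts, ends, reciprocal)
        adj = coo_matrix((np.ones(len(li)), (li, lj)), shape=(k, k))
        n_comp, labels = connected_components(adj, directed=False)
        for comp in range(n_comp):
            member = labels == comp
            support = frozenset(samples[member])
            if len(support) < min_support:
                continue
            regions.append(
                CnvRegion(
                    group=str(group),
                    chrom=str(chrom),
                    start_bp=int(starts[member].min()),
                    end_bp=int(ends[member].max()),
                    supporting_samples=support,
                    cn_class=str(cls),
                )
            )
    return _merge_touching(_dedupe(regions))


def _dedupe(regions: list[CnvRegion]) -> list[CnvRegion]:
    seen = {}
    for r in regions:
        key = (r.group, r.chrom, r.start_bp, r.end_bp, r.cn_class)
        if key in seen:
            prev = seen[key]
            seen[key] = CnvRegion(
                r.group,
                r.chrom,
                r.start_bp,
                r.end_bp,
                prev.supporting_samples | r.supporting_samples,
                r.cn_class,
            )
        else:
            seen[key] = r
    return list(seen.values())


def _merge_touching(regions: list[CnvRegion]) -> list[CnvRegion]:
    out: list[CnvRegion] = []
    keyfn = lambda r: (r.group, r.chrom, r.cn_class, r.start_bp, r.end_bp)
    regions = sorted(regions, key=keyfn)
    for r in regions:
        if (
            out
            and (out[-1].group, out[-1].chrom, out[-1].cn_class)
            == (r.group, r.chrom, r.cn_class)
            and r.start_bp <= out[-1].end_bp + 1
        ):
            prev = out.pop()
            out.append(
                CnvRegion(
                    prev.group,
                    prev.chrom,
                    prev.start_bp,
                    max(prev.end_bp, r.end_bp),
                    prev.supporting_samples | r.supporting_samples,
                    prev.cn_class,
                )
            )
        else:
            out.append(r)
    return out


def mask_selection_regions(
    regions: list[SelectionRegion], cnvrs: list[CnvRegion]
) -> tuple[list[SelectionRegion], list[tuple[SelectionRegion, CnvRegion]]]:
    """Split selection regions into (retained, excluded-with-offender).

    A selection region is excluded when it shares >= 1 bp with any
    CNVR of the same group (CNVRs with an empty group apply to all).
    Retained + excluded always partition the input.
    """
    retained: list[SelectionRegion] = []
    excluded: list[tuple[SelectionRegion, CnvRegion]] = []
    for reg in regions:
        hit = None
        for c in cnvrs:
            if c.group and reg.group and c.group != reg.group:
                continue
            if c.chrom != reg.chrom:
                continue
            if c.start_bp <= reg.end_bp and c.end_bp >= reg.start_bp:
                hit = c
                break
        if hit is None:
            retained.append(reg)
        else:
            excluded.append((reg, hit))
    return retained, excluded


def cnvrs_to_frame(cnvrs: list[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": c.group,
                "chrom": c.chrom,
                "start_bp": c.start_bp,
                "end_bp": c.end_bp,
                "cn_class": c.cn_class,
                "n_support": c.n_support,
                "supporting_samples": ",".join(sorted(c.supporting_samples)),
            }
            for c in cnvrs
        ],
        columns=[
            "group",
            "chrom",
            "start_bp",
            "end_bp",
            "cn_class",
            "n_support",
            "supporting_samples",
        ],
    )
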