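"""Reference experiments: the study conditions for power and calibration.

The sweep-detection study embeds one forward-simulated chromosome
(neutral or carrying a hard sweep at its midpoint) in a panel of four
coalescent-simulated neutral chromosomes under the same two-breed
demography, then runs the full QC -> statistics -> DCMS -> q-value ->
region pipeline on the focal (swept) breed's 50-diploid sample.  A
replicate detects the sweep when a called region with peak q < 0.01
overlaps the true sweep interval (sweep position +- the expected
footprint s / (r ln 2N)).

These functions are the single source of truth for the package's own
power/calibration numbers; the acceptance machinery calls them.
"""

from __future__ import annotations

import warnings

import numpy as np

from sweepscan.dcms import DcmsConfig, attach_dcms
from sweepscan.popsim import SimConfig, SweepSpec, default_groups, simulate_population
from sweepscan.qc import STRICT_THRESHOLDS, apply_qc
from sweepscan.regions import call_regions
from sweepscan.selstats import WindowSpec, compute_group_stats

#: study conditions for the sweep-detection experiment (see docs/methods.md)
SWEEP_STUDY = dict(
    n_demes=2,
    deme_size=400,
    sample_size=50,
    n_generations=150,
    mutation_rate=2.5e-7,
    recombination_rate=2.5e-7,
    seq_length_bp=1_000_000,
    migration_rate=0.001,
    split_generation=0,
    n_neutral_chromosomes=4,
)

SWEEP_POSITION_BP = 500_000
SELECTION_COEFFICIENT = 0.1


def sweep_footprint_bp(config: SimConfig, s: float) -> int:
    """Expected hard-sweep footprint half-width, s / (r ln 2N), capped at
    the chromosome length (a non-recombining chromosome sweeps whole)."""
    denom = config.recombination_rate * np.log(2 * config.deme_size)
    if denom <= 0:
        return int(config.seq_length_bp)
    return min(int(s / denom), int(config.seq_length_bp))


def run_scan_replicate(seed: int, sweep: bool = True) -> dict:
    """One full-pipeline replicate under the study conditions.

    Returns detection status, the panel's minimum q, the fraction of
    scored SNPs at q < 0.01, and sweep bookkeeping.
    """
    spec = (
        SweepSpec(
            position_bp=SWEEP_POSITION_BP,
            selection_coefficient=SELECTION_COEFFICIENT,
            require_frequency=0.9,
        )
        if sweep
        else None
    )
    cfg = SimConfig(seed=seed, sweep_spec=spec, **SWEEP_STUDY)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hap, meta = simulate_population(cfg)
        groups = default_groups(cfg)
        geno = hap.to_genotypes(groups)
        strict, _ = apply_qc(geno, STRICT_THRESHOLDS)
        panel = compute_group_stats(
            hap, groups, "deme0", WindowSpec(), fst_sites=set(strict.variants["snp_id"])
        )
        # covariance sample capped above the panel size: all SNPs enter
        panel, _ = attach_dcms(
            panel, DcmsConfig(covariance_sample_size=10**9, seed=seed + 1)
        )
        scored = panel.dropna(subset=["q"]).reset_index(drop=True)
        regions = call_regions(scored, group="deme0")

    out = {
        "n_snps": int(len(panel)),
        "n_scored": int(len(scored)),
        "min_q": float(scored["q"].min()) if len(scored) else np.nan,
        "frac_q_below_0.01": float((scored["q"] < 0.01).mean()) if len(scored) else np.nan,
        "n_regions": len(regions),
    }
    if sweep:
        half = sweep_footprint_bp(cfg, SELECTION_COEFFICIENT)
        lo, hi = SWEEP_POSITION_BP - half, SWEEP_POSITION_BP + half
        out["focal_frequency"] = meta["sweep"]["final_frequency"]["deme0"]
        out["detected"] = any(
            r.chrom == "1" and r.start_bp <= hi and r.end_bp >= lo and r.peak_q < 0.01
            for r in regions
        )
    return out


def sweep_power_study(n_replicates: int = 20, seed: int = 0) -> dict:
    """Detection power over seeded sweep replicates conditioned on
    near-fixation (focal frequency >= 0.9 at sampling)."""
    results = [
        run_scan_replicate(seed * 1000 + i, sweep=True) for i in range(n_replicates)
    ]
    eligible = [r for r in results if r["focal_frequency"] >= 0.9]
    hits = sum(r["detected"] for r in eligible)
    return {
        "n_replicates": n_replicates,
        "n_near_fixed": len(eligible),
        "n_detected": hits,
        "power": hits / len(eligible) if eligible else np.nan,
        "replicates": results,
    }


def neutral_calibration_study(n_replicates: int = 20, seed: int = 0) -> dict:
    """False-positive calibration: fraction of SNPs at q < 0.01 under
    fully neutral simulations."""
    results = [
        run_scan_replicate(seed * 1000 + i, sweep=False)
        for i in range(n_replicates)
    ]
    fracs = [r["frac_q_below_0.01"] for r in results]
    return {
        "n_replicates": n_replicates,
        "mean_frac_q_below_0.01": float(np.nanmean(fracs)),
        "max_frac_q_below_0.01": float(np.nanmax(fracs)),
        "replicates": results,
    }
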