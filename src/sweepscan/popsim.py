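"""Forward Wright-Fisher simulation of multi-deme diploid populations.

The simulator produces phased haplotypes for a set of demes ("breeds"
or "groups") derived from a common ancestral population, with
infinite-sites-style mutation on an integer bp grid, uniform crossover
recombination, rare symmetric migration between demes, and an optional
planted selective sweep (hard: single new copy; soft: standing
variation at a configurable start frequency).  Selection is divergent
by default — beneficial in one focal deme, deleterious elsewhere — the
standard model of local adaptation, which keeps the sweep private to
the focal deme.

The ancestral population is initialized at mutation-drift equilibrium
with a coalescent simulation (msprime); the forward Wright-Fisher
engine then runs the recent, interesting part of history — breed
formation, migration and selection — generation by generation.  A pure
forward burn-in of 4N generations would dominate the runtime while
converging to exactly the state the coalescent supplies directly.

Everything is driven by one integer seed; a fixed seed gives
byte-identical output.  Scales are deliberately desk-sized (hundreds
of diploids, hundreds of forward generations): the goal is a faithful
qualitative signal (haplotype homozygosity, diversity loss, negative
Tajima's D, allele-frequency differentiation around the sweep), not a
realistic demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sweepscan.containers import GenotypeMatrix, HaplotypeMatrix, make_variant_table

MAX_SWEEP_RESTARTS = 50


class SweepLostError(RuntimeError):
    """Raised when the beneficial allele is lost in every retry."""


@dataclass
class SweepSpec:
    """A planted selective sweep.

    ``selection_coefficient`` is the additive fitness increment per copy
    (diploid fitness ``1 + s * copies``) in the focal deme.  Outside the
    focal deme the allele has effect ``away_selection_coefficient`` per
    copy, by default ``-selection_coefficient``: divergent selection, the
    standard model of local adaptation, which keeps the sweep private to
    the focal deme under migration-selection balance.  Set it to 0 for a
    globally neutral (exportable) allele.  ``start_generation`` (forward
    time) defaults to the deme split, so conditional fixation — expected
    after roughly (2/s) ln(2N) generations — completes shortly before
    the population is sampled, while the footprint is fresh.
    """

    position_bp: int
    selection_coefficient: float
    mode: str = "hard"  # "hard" | "soft"
    start_frequency: float = 0.05  # soft mode only
    start_generation: Optional[int] = None
    away_selection_coefficient: Optional[float] = None
    focal_deme: int = 0
    #: restart (like a lost allele) unless the focal-deme frequency reaches
    #: this value at sampling; None disables the conditioning
    require_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise ValueError(f"sweep mode must be 'hard' or 'soft', got {self.mode!r}")
        if self.selection_coefficient < 0:
            raise ValueError("selection coefficient must be >= 0")
        if not 0 < self.start_frequency < 1:
            raise ValueError("soft-sweep start frequency must be in (0,1)")


@dataclass
class SimConfig:
    """Parameters of one simulated multi-deme population.

    The demographic model: an ancestral population of
    ``ancestral_size`` diploids at mutation-drift equilibrium
    (coalescent-initialized) splits at ``split_generation`` (forward
    time, default 0: the demes exist from the start of the forward
    phase) into ``n_demes`` breed-like demes of ``deme_size`` diploids
    exchanging rare migrants.  After ``n_generations`` forward
    generations, ``sample_size`` diploids per deme are output —
    sequencing studies genotype a sample of animals, not the breed.  A
    deme must be large enough that a planted sweep outruns drift
    (N s >> ln 2N; the defaults give N s = 20), yet the sample stays
    small.

    The recombination rate is set so a hard sweep's footprint, roughly
    s / (r ln 2N) wide, spans many 25-SNP windows (~60 kb at s = 0.1)
    instead of collapsing into a single window.  The forward phase
    defaults to 160 generations — livestock breeds are young (herd
    books span tens of generations), and an old split would bury
    selection signals under drift-generated differentiation plateaus —
    which leaves a sweep started at the split just enough time to fix
    (expected (2/s) ln 2N ~ 135 generations at the defaults).
    Defaults give ~4,500 segregating SNPs on a 1 Mb chromosome in a
    sample of 2 x 50 diploids, keeping one replicate to a few seconds.
    """

    n_demes: int = 2
    deme_size: int = 200
    n_generations: int = 160  # forward generations after the coalescent init
    mutation_rate: float = 5e-7  # per site per generation
    recombination_rate: float = 2.5e-7  # per adjacent bp pair per generation
    seq_length_bp: int = 1_000_000
    migration_rate: float = 0.001  # breed-like demes: rare crossbreeding
    split_generation: int = 0  # forward generation at which demes form
    ancestral_size: Optional[int] = None  # diploids pre-split; default demes total
    sample_size: Optional[int] = None  # diploids sampled per deme; default 50
    #: extra neutral chromosomes simulated under the same demography with
    #: the coalescent and appended as chromosomes "2", "3", ...  A planted
    #: sweep must be a small fraction of the genome-wide panel — as it is
    #: of a real multi-chromosome genome — or its own footprint saturates
    #: the genome-wide empirical ranks downstream.
    n_neutral_chromosomes: int = 0
    sweep_spec: Optional[SweepSpec] = None
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.deme_size < 2:
            raise ValueError("deme_size must be >= 2 diploids")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.seq_length_bp < 2:
            raise ValueError("seq_length_bp must be >= 2")
        for name in ("mutation_rate", "recombination_rate", "migration_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.ancestral_size is None:
            self.ancestral_size = self.n_demes * self.deme_size
        if self.ancestral_size < 2:
            raise ValueError("ancestral_size must be >= 2 diploids")
        if self.sample_size is None:
            self.sample_size = min(50, self.deme_size)
        if not 2 <= self.sample_size <= self.deme_size:
            raise ValueError("sample_size must be in [2, deme_size]")
        if not 0 <= self.split_generation <= self.n_generations:
            raise ValueError("split_generation must lie within the run")
        if self.sweep_spec is not None:
            sw = self.sweep_spec
            if not 0 <= sw.position_bp < self.seq_length_bp:
                raise ValueError("sweep position must lie in [0, seq_length_bp)")
            if sw.start_generation is None:
                sw.start_generation = self.split_generation
            if sw.away_selection_coefficient is None:
                sw.away_selection_coefficient = -sw.selection_coefficient
            if not 0 <= sw.start_generation < self.n_generations:
                raise ValueError("sweep start generation must lie within the run")
            if sw.start_generation < self.split_generation:
                raise ValueError("sweep must start at or after the deme split")
            if sw.focal_deme >= self.n_demes:
                raise ValueError("focal deme out of range")


class _State:
    """Mutable simulation state: haplotypes x unsorted segregating columns."""

    def __init__(self, n_hap: int):
        self.hap = np.zeros((n_hap, 0), dtype=np.int8)
        self.pos = np.zeros(0, dtype=np.int64)  # 1-based bp, unsorted
        self.sweep_col: int | None = None

    def copy(self) -> "_State":
        st = _State(self.hap.shape[0])
        st.hap = self.hap.copy()
        st.pos = self.pos.copy()
        st.sweep_col = self.sweep_col
        return st


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco


@_njit(cache=True)
def _gametes_kernel(hap, rows_a, rows_b, ncx, cx_flat, cx_off, pos, out):
    """Fill ``out`` with gametes: a crossover after bp t flips strands
    for sites with pos > t (parity of thresholds below each site);
    site positions may be in any order."""
    n_gam, m = out.shape
    for g in range(n_gam):
        a = rows_a[g]
        b = rows_b[g]
        k = ncx[g]
        if k == 0:
            out[g, :] = hap[a, :]
            continue
        o = cx_off[g]
        for j in range(m):
            c = 0
            p = pos[j]
            for t in range(k):
                if cx_flat[o + t] < p:
                    c += 1
            out[g, j] = hap[a, j] if (c & 1) == 0 else hap[b, j]


def _make_gametes(
    hap: np.ndarray,
    parent_diploids: np.ndarray,
    pos: np.ndarray,
    recomb_expect: float,
    seq_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parent_diploids`` (diploid row indices)."""
    n_gam = len(parent_diploids)
    m = hap.shape[1]
    out = np.empty((n_gam, m), dtype=np.int8)
    start = rng.integers(0, 2, size=n_gam)
    ncx = (
        rng.poisson(recomb_expect, size=n_gam)
        if recomb_expect > 0 and m > 1
        else np.zeros(n_gam, dtype=np.int64)
    )
    rows_a = 2 * parent_diploids + start
    rows_b = 2 * parent_diploids + 1 - start
    cx_off = np.zeros(n_gam, dtype=np.int64)
    np.cumsum(ncx[:-1], out=cx_off[1:])
    total = int(ncx.sum())
    cx_flat = (
        rng.integers(1, seq_len, size=total)
        if total
        else np.zeros(0, dtype=np.int64)
    )
    if _HAVE_NUMBA and m:
        _gametes_kernel(hap, rows_a, rows_b, ncx, cx_flat, cx_off, pos, out)
        return out
    plain = ncx == 0
    out[plain] = hap[rows_a[plain]]
    for i in np.nonzero(~plain)[0]:
        t = np.sort(cx_flat[cx_off[i] : cx_off[i] + ncx[i]])
        parity = np.searchsorted(t, pos, side="left") % 2
        out[i] = np.where(parity == 0, hap[rows_a[i]], hap[rows_b[i]])
    return out


def _add_mutations(
    state: _State, n_hap: int, mut_expect: float, seq_len: int, rng: np.random.Generator
) -> None:
    """Append Poisson-many singleton columns (unsorted tail; the final
    variant table is sorted once at output)."""
    n_new = rng.poisson(mut_expect) if mut_expect > 0 else 0
    if n_new == 0:
        return
    existing = set(state.pos.tolist())
    new_pos = []
    while len(new_pos) < n_new:
        p = int(rng.integers(1, seq_len + 1))
        if p not in existing:
            existing.add(p)
            new_pos.append(p)
    carriers = rng.integers(0, n_hap, size=n_new)
    block = np.zeros((n_hap, n_new), dtype=np.int8)
    block[carriers, np.arange(n_new)] = 1
    state.hap = np.concatenate([state.hap, block], axis=1)
    state.pos = np.concatenate([state.pos, np.asarray(new_pos, dtype=np.int64)])


def _prune(state: _State, n_hap: int) -> None:
    """Drop fixed/lost columns (positions stay sorted); the sweep column
    is always retained."""
    counts = state.hap.sum(axis=0, dtype=np.int64)
    keep = (counts > 0) & (counts < n_hap)
    if state.sweep_col is not None:
        keep[state.sweep_col] = True
    if keep.all():
        return
    idx = np.nonzero(keep)[0]
    state.hap = np.ascontiguousarray(state.hap[:, idx])
    state.pos = state.pos[idx]
    if state.sweep_col is not None:
        state.sweep_col = int(np.searchsorted(idx, state.sweep_col))


def _step(
    state: _State,
    parent_deme_of: np.ndarray,
    child_deme_of: np.ndarray,
    cfg: SimConfig,
    selection_on: bool,
    rng: np.random.Generator,
    do_prune: bool = True,
) -> None:
    """Advance one non-overlapping Wright-Fisher generation in place.

    Parent and child generations may differ in size and deme layout
    (the deme split is a founder expansion).  A child deme with no
    parents in its own deme draws founders from the whole parent
    population.
    """
    n_parent = len(parent_deme_of)
    n_dip = len(child_deme_of)
    n_hap = 2 * n_dip
    sw = cfg.sweep_spec
    fitness = np.ones(n_parent)
    if selection_on and sw is not None and state.sweep_col is not None:
        dosage = (
            state.hap[0::2, state.sweep_col] + state.hap[1::2, state.sweep_col]
        ).astype(float)
        focal = parent_deme_of == sw.focal_deme
        fitness[focal] += sw.selection_coefficient * dosage[focal]
        fitness[~focal] += sw.away_selection_coefficient * dosage[~focal]
        np.clip(fitness, 1e-9, None, out=fitness)

    n_demes_now = int(child_deme_of.max()) + 1
    parent_demes = np.unique(parent_deme_of)
    mothers = np.empty(n_dip, dtype=np.int64)
    fathers = np.empty(n_dip, dtype=np.int64)
    for d in range(n_demes_now):
        child_idx = np.nonzero(child_deme_of == d)[0]
        k = len(child_idx)
        if k == 0:
            continue
        # migrant offspring draw both parents from one random other deme
        src = np.full(k, d)
        others = [x for x in parent_demes if x != d]
        if others and cfg.migration_rate > 0 and d in parent_demes:
            mig = rng.random(k) < cfg.migration_rate
            src[mig] = rng.choice(others, size=mig.sum())
        for s_deme in np.unique(src):
            pool = np.nonzero(parent_deme_of == s_deme)[0]
            if len(pool) == 0:  # founding a new deme
                pool = np.arange(n_parent)
            w = fitness[pool]
            prob = w / w.sum()
            sel = src == s_deme
            mothers[child_idx[sel]] = rng.choice(pool, size=sel.sum(), p=prob)
            fathers[child_idx[sel]] = rng.choice(pool, size=sel.sum(), p=prob)

    recomb_expect = cfg.recombination_rate * (cfg.seq_length_bp - 1)
    gam_a = _make_gametes(state.hap, mothers, state.pos, recomb_expect, cfg.seq_length_bp, rng)
    gam_b = _make_gametes(state.hap, fathers, state.pos, recomb_expect, cfg.seq_length_bp, rng)
    new_hap = np.empty((n_hap, state.hap.shape[1]), dtype=np.int8)
    new_hap[0::2] = gam_a
    new_hap[1::2] = gam_b
    state.hap = new_hap

    _add_mutations(
        state, n_hap, n_hap * cfg.mutation_rate * cfg.seq_length_bp, cfg.seq_length_bp, rng
    )
    if do_prune:
        _prune(state, n_hap)


def _introduce_sweep(state: _State, deme_of: np.ndarray, cfg: SimConfig, rng) -> None:
    sw = cfg.sweep_spec
    n_hap = 2 * len(deme_of)
    col = np.zeros((n_hap, 1), dtype=np.int8)
    focal_dip = np.nonzero(deme_of == sw.focal_deme)[0]
    focal_hap = np.ravel([(2 * i, 2 * i + 1) for i in focal_dip])
    if sw.mode == "hard":
        carriers = rng.choice(focal_hap, size=1, replace=False)
    else:
        k = max(1, round(sw.start_frequency * len(focal_hap)))
        carriers = rng.choice(focal_hap, size=k, replace=False)
    col[carriers, 0] = 1
    # drop any neutral mutation already occupying the sweep site
    spos = sw.position_bp + 1
    occupied = np.nonzero(state.pos == spos)[0]
    if len(occupied):
        keep = np.setdiff1d(np.arange(len(state.pos)), occupied)
        state.hap = state.hap[:, keep]
        state.pos = state.pos[keep]
    state.hap = np.concatenate([state.hap, col], axis=1)
    state.pos = np.concatenate([state.pos, [spos]])
    state.sweep_col = state.hap.shape[1] - 1


def _sweep_freqs(state: _State, deme_of: np.ndarray) -> dict[str, float]:
    col = state.hap[:, state.sweep_col]
    out = {"global": float(col.mean())}
    for d in np.unique(deme_of):
        dip = np.nonzero(deme_of == d)[0]
        rows = np.ravel([(2 * i, 2 * i + 1) for i in dip])
        out[f"deme{d}"] = float(col[rows].mean())
    return out


def _coalescent_init(cfg: SimConfig, rng: np.random.Generator) -> _State:
    """Equilibrium neutral variation for the forward phase's generation 0.

    A coalescent simulation at the ancestral population size supplies
    the standing variation; the forward engine owns everything after.
    """
    n_init = len(_deme_layout(cfg, 0))
    state = _State(2 * n_init)
    if cfg.mutation_rate <= 0:
        return state
    import msprime

    seed_anc = int(rng.integers(1, 2**31 - 1))
    seed_mut = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_init,
        population_size=cfg.ancestral_size,
        sequence_length=cfg.seq_length_bp,
        recombination_rate=cfg.recombination_rate,
        random_seed=seed_anc,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=cfg.mutation_rate,
        random_seed=seed_mut,
        model=msprime.BinaryMutationModel(),
    )
    geno = ts.genotype_matrix().astype(np.int8)  # sites x 2N, alleles 0/1
    pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    counts = geno.sum(axis=1)
    seg = (counts > 0) & (counts < geno.shape[1])
    state.hap = np.ascontiguousarray(geno[seg].T)
    state.pos = pos[seg]
    return state


def _deme_layout(cfg: SimConfig, gen: int) -> np.ndarray:
    """Deme assignment of the diploids alive at generation ``gen``."""
    if gen < cfg.split_generation:
        return np.zeros(cfg.ancestral_size, dtype=np.int64)
    return np.repeat(np.arange(cfg.n_demes), cfg.deme_size)


def simulate_population(config: SimConfig) -> tuple[HaplotypeMatrix, dict]:
    """Run one forward simulation; return phased haplotypes and metadata.

    The output holds ``sample_size`` diploids per deme; only sites
    segregating in that sample are retained, sorted by position.  For a
    planted sweep the run restarts from the introduction point (same
    neutral background, fresh randomness) whenever the beneficial
    allele is lost, up to ``MAX_SWEEP_RESTARTS`` times; metadata
    records the restart count and the sweep allele's final frequency
    per deme.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    state = _coalescent_init(cfg, rng)
    sw = cfg.sweep_spec
    meta: dict = {"n_restarts": 0, "sweep": None}

    gen = 0
    while gen < cfg.n_generations:
        if sw is not None and gen == sw.start_generation:
            snapshot = state.copy()
            restarts = 0
            while True:
                _introduce_sweep(state, _deme_layout(cfg, gen), cfg, rng)
                ok, fixed_at = _run_sweep_phase(state, cfg, gen, rng)
                if ok:
                    break
                restarts += 1
                if restarts > MAX_SWEEP_RESTARTS:
                    raise SweepLostError(
                        f"beneficial allele lost in all {MAX_SWEEP_RESTARTS} restarts"
                    )
                state = snapshot.copy()
            meta["n_restarts"] = restarts
            meta["sweep"] = {
                "position_bp": sw.position_bp + 1,
                "mode": sw.mode,
                "selection_coefficient": sw.selection_coefficient,
                "final_frequency": _sweep_freqs(state, _deme_layout(cfg, cfg.n_generations)),
                "fixation_generation": fixed_at,
            }
            gen = cfg.n_generations
            break
        _step(
            state,
            _deme_layout(cfg, gen),
            _deme_layout(cfg, gen + 1),
            cfg,
            selection_on=False,
            rng=rng,
            do_prune=(gen % 8 == 7) or gen + 1 >= cfg.n_generations,
        )
        gen += 1

    hap = _finalize(state, cfg)
    if cfg.n_neutral_chromosomes > 0:
        hap = _append_neutral_chromosomes(hap, cfg, rng)
    meta["config"] = cfg
    meta["n_segregating"] = hap.n_sites
    return hap, meta


def _append_neutral_chromosomes(
    hap: HaplotypeMatrix, cfg: SimConfig, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Coalescent-simulated neutral chromosomes under the same demography
    (ancestral split into migrating demes), appended after the forward
    chromosome.  Neutral loci need no forward machinery."""
    import msprime

    split_ago = cfg.n_generations - cfg.split_generation
    blocks = [hap.haplotypes]
    frames = [hap.variants]
    for k in range(cfg.n_neutral_chromosomes):
        dem = msprime.Demography()
        dem.add_population(name="anc", initial_size=cfg.ancestral_size)
        names = []
        for d in range(cfg.n_demes):
            name = f"deme{d}"
            dem.add_population(name=name, initial_size=cfg.deme_size)
            names.append(name)
        if split_ago > 0:
            dem.add_population_split(time=split_ago, derived=names, ancestral="anc")
        if cfg.n_demes > 1 and cfg.migration_rate > 0:
            dem.set_symmetric_migration_rate(names, cfg.migration_rate)
        ts = msprime.sim_ancestry(
            samples={name: cfg.sample_size for name in names},
            demography=dem,
            sequence_length=cfg.seq_length_bp,
            recombination_rate=cfg.recombination_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
        )
        ts = msprime.sim_mutations(
            ts,
            rate=cfg.mutation_rate,
            random_seed=int(rng.integers(1, 2**31 - 1)),
            model=msprime.BinaryMutationModel(),
        )
        geno = ts.genotype_matrix().astype(np.int8)
        pos = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
        counts = geno.sum(axis=1)
        seg = (counts > 0) & (counts < geno.shape[1])
        blocks.append(np.ascontiguousarray(geno[seg].T))
        chrom = str(k + 2)
        frames.append(
            make_variant_table(np.full(int(seg.sum()), chrom, dtype=object), pos[seg])
        )
    variants = pd.concat(frames, ignore_index=True)
    return HaplotypeMatrix(np.concatenate(blocks, axis=1), variants, list(hap.samples))


def _run_sweep_phase(
    state: _State, cfg: SimConfig, start_gen: int, rng
) -> tuple[bool, Optional[int]]:
    """Generations from sweep introduction to the end.

    Returns (survived, fixation_generation); fixation is the first
    forward generation at which the focal deme is fixed for the allele
    (None if never).
    """
    sw = cfg.sweep_spec
    fixed_at: Optional[int] = None
    for gen in range(start_gen, cfg.n_generations):
        _step(
            state,
            _deme_layout(cfg, gen),
            _deme_layout(cfg, gen + 1),
            cfg,
            selection_on=True,
            rng=rng,
            do_prune=(gen % 8 == 7) or gen + 1 >= cfg.n_generations,
        )
        col = state.hap[:, state.sweep_col]
        if col.sum() == 0:
            return False, None
        if fixed_at is None:
            layout = _deme_layout(cfg, gen + 1)
            dip = np.nonzero(layout == sw.focal_deme)[0]
            rows = np.ravel([(2 * i, 2 * i + 1) for i in dip])
            if col[rows].all():
                fixed_at = gen + 1
    if sw.require_frequency is not None:
        layout = _deme_layout(cfg, cfg.n_generations)
        dip = np.nonzero(layout == sw.focal_deme)[0]
        rows = np.ravel([(2 * i, 2 * i + 1) for i in dip])
        col = state.hap[:, state.sweep_col]
        if col[rows].mean() < sw.require_frequency:
            return False, None
    return True, fixed_at


def _finalize(state: _State, cfg: SimConfig) -> HaplotypeMatrix:
    """Sample diploids per deme, keep sites segregating in the sample."""
    final_layout = _deme_layout(cfg, cfg.n_generations)
    keep_dip = []
    for d in range(int(final_layout.max()) + 1):
        dip = np.nonzero(final_layout == d)[0][: cfg.sample_size]
        keep_dip.extend(dip.tolist())
    rows = np.ravel([(2 * i, 2 * i + 1) for i in keep_dip])
    hap_rows = state.hap[rows]
    counts = hap_rows.sum(axis=0)
    seg = (counts > 0) & (counts < hap_rows.shape[0])
    hap_rows = hap_rows[:, seg]
    pos = state.pos[seg]
    order = np.argsort(pos, kind="stable")
    hap_rows = hap_rows[:, order]
    pos = pos[order]
    n_demes_out = int(final_layout.max()) + 1
    samples = [
        f"d{d}_s{i}" for d in range(n_demes_out) for i in range(cfg.sample_size)
    ]
    variants = make_variant_table(np.full(len(pos), cfg.chrom, dtype=object), pos)
    return HaplotypeMatrix(hap_rows, variants, samples)


def default_groups(config: SimConfig) -> dict[str, str]:
    """Sample -> group map labelling each deme ``"deme<k>"``."""
    return {
        f"d{d}_s{i}": f"deme{d}"
        for d in range(config.n_demes)
        for i in range(config.sample_size)
    }


def ascertain_array_snps(
    hap: HaplotypeMatrix, target_count: int, maf_floor: float, seed: int
) -> HaplotypeMatrix:
    """Thin sites to ``target_count`` with MAF >= ``maf_floor``, emulating a
    medium-density genotyping array's common-variant ascertainment."""
    freq = hap.haplotypes.mean(axis=0)
    maf = np.minimum(freq, 1 - freq)
    eligible = np.nonzero(maf >= maf_floor)[0]
    if target_count > len(eligible):
        raise ValueError(
            f"requested {target_count} sites but only {len(eligible)} have "
            f"MAF >= {maf_floor}"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(eligible, size=target_count, replace=False))
    return hap.take_sites(chosen)


def inject_missingness(
    geno: GenotypeMatrix,
    snp_rates: float | np.ndarray,
    sample_rates: float | np.ndarray,
    seed: int,
) -> GenotypeMatrix:
    """Mask genotypes as missing with independent Bernoulli draws.

    A call is masked with probability ``1 - (1 - snp_rate)(1 - sample_rate)``,
    so each requested rate is the realized marginal rate when the other
    vector is zero.
    """
    snp_rates = np.broadcast_to(np.asarray(snp_rates, dtype=float), (geno.n_sites,))
    sample_rates = np.broadcast_to(
        np.asarray(sample_rates, dtype=float), (geno.n_samples,)
    )
    for arr, name in ((snp_rates, "snp_rates"), (sample_rates, "sample_rates")):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} must be in [0,1]")
    p = 1.0 - np.outer(1.0 - sample_rates, 1.0 - snp_rates)
    rng = np.random.default_rng(seed)
    mask = rng.random(p.shape) < p
    dos = geno.dosages.copy()
    dos[mask] = -1
    return GenotypeMatrix(dos, geno.variants.copy(), list(geno.samples), dict(geno.groups))


CNV_CALL_COLUMNS = ["chrom", "start_bp", "end_bp", "sample", "group", "cn"]


def simulate_cnv_fixture(
    groups: dict[str, str],
    spec: list[tuple[tuple[str, int, int], int, list[str]]],
    seq_length_bp: int | None = None,
) -> pd.DataFrame:
    """Deterministic per-sample CNV call table (1-based inclusive intervals).

    ``spec`` entries are ``((chrom, start_bp, end_bp), copy_number,
    carrier_samples)``; rows are emitted verbatim, one per carrier, with
    no consolidation.
    """
    rows = []
    for (chrom, start, end), cn, carriers in spec:
        if not 0 <= cn <= 8:
            raise ValueError(f"copy number {cn} outside supported range 0..8")
        if start > end:
            raise ValueError(f"interval start {start} > end {end}")
        if seq_length_bp is not None and end > seq_length_bp:
            raise ValueError(f"interval end {end} beyond chromosome length")
        for sample in carriers:
            if sample not in groups:
                raise ValueError(f"carrier sample {sample!r} has no group assignment")
            rows.append((chrom, start, end, sample, groups[sample], cn))
    return pd.DataFrame(rows, columns=CNV_CALL_COLUMNS)
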