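"""Forward Wright-Fisher simulation of a two-population diploid cohort.

The simulator produces phased haplotypes for a focal and a control
population descended from a common ancestor, with a population split,
per-epoch bottlenecks, optional symmetric-or-not migration, and an
injectable hard selective sweep.  It runs at desk scale: population sizes
and times are reduced and the per-bp mutation/recombination rates raised
so that the products ``mu * N`` and ``r * N`` (hence per-bp diversity and
population-scaled recombination) match the values one wants to emulate.

Reproduction is the classical discrete-generation Wright-Fisher scheme:
every offspring chromosome picks a diploid parent (weighted by fitness
when a sweep is active in that population), receives one of the parent's
two chromosomes, and with probability ``r * (L - 1)`` undergoes a single
crossover at a uniform breakpoint.  Mutation is infinite-sites on an
integer grid: each generation ``Poisson(n_hap * mu * L)`` new derived
alleles arise at previously monomorphic positions.  Allele 0 is always
the founding (ancestral) state, so VCF REF = ancestral and ALT = derived.

Besides the cohort itself, the module writes the standard files consumed
downstream (VCF 4.2 with phased GT, per-sample DP and site MQ; a
sample-to-population map; a constant-rate genetic map; a truth ledger)
and generates toy gene annotations plus a term-to-gene map so positional
annotation and enrichment are testable without external databases.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "SweepSpec",
    "SimulationConfig",
    "TruthRecord",
    "PhasedCohort",
    "GeneModel",
    "simulate_cohort",
    "write_cohort",
    "to_variant_table",
    "make_reference",
    "make_annotation_and_terms",
    "write_gff3",
    "write_term_map",
    "demographic_preset",
]

FOCAL = "focal"
CONTROL = "control"

# Probability that a simulated substitution is a transition; calibrated to
# the mammalian genome-wide ts/tv ratio of ~2.6 so the diagnostic statistic
# behaves realistically on synthetic cohorts.
_TS_PROB = 2.64 / 3.64
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SweepSpec:
    """A hard sweep injected into one population.

    position is a 0-based bp offset in [0, sequence_length); the derived
    allele is placed at 1-based coordinate position + 1.  The allele is
    introduced ``onset_generation`` generations before sampling on
    ``initial_copies`` chromosomes of the target population (default 1: a
    single origin, i.e. a hard sweep) and thereafter confers
    multiplicative fitness (1 + s) per copy.  With ``reinject_on_loss``
    a stochastically lost allele recurs by mutation on a fresh background
    in the next generation, conditioning the run on establishment; the
    successful sweep still has a single origin.  Note that under
    population-size rescaling s scales like 1/N, so desk-scale hard
    sweeps use s of order 0.1-1.
    """

    position: int
    s: float
    onset_generation: int
    population: int = 0
    initial_copies: int = 1
    reinject_on_loss: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a two-population cohort.

    Defaults are a desk-scale rendering of a divergent pair of deer
    populations: per-bp diversity ~5e-4 in the focal population, a split
    a modest fraction of 2N generations ago, and a recent bottleneck in
    the control population (which also lengthens its LD).  ``epochs``
    lists post-split size changes per population as (start_generation,
    diploid_size) pairs, start counted in generations before present and
    strictly decreasing; mutation/recombination rates are per bp per
    generation; ``generation_time`` (years) only labels outputs.
    """

    seed: int = 0
    sequence_length: int = 500_000
    mutation_rate: float = 1.25e-6
    recombination_rate: float = 2.0e-6
    generation_time: float = 6.3
    ancestral_size: int = 120
    pop_sizes: tuple[int, int] = (100, 40)
    epochs: tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]] = ((), ())
    split_generation: int = 30
    migration_rates: tuple[float, float] = (0.0, 0.0)
    sample_sizes: tuple[int, int] = (13, 4)
    burn_in: Optional[int] = None
    sweep: Optional[SweepSpec] = None
    chrom: str = "chr1"
    map_cm_per_mb: float = 2.53
    depth_mean: float = 8.0
    site_mq: float = 37.0

    def __post_init__(self) -> None:
        if self.sequence_length <= 0:
            raise ConfigError("sequence_length must be positive")
        sizes = [self.ancestral_size, *self.pop_sizes, *self.sample_sizes]
        for (_, n) in self.epochs[0] + self.epochs[1]:
            sizes.append(n)
        if any(n < 2 for n in sizes):
            raise ConfigError("all population and sample sizes must be >= 2")
        if not all(0.0 <= m < 1.0 for m in self.migration_rates):
            raise ConfigError("migration rates must lie in [0, 1)")
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigError("rates must be non-negative")
        if self.split_generation < 0:
            raise ConfigError("split_generation must be >= 0")
        for pop_epochs in self.epochs:
            starts = [g for g, _ in pop_epochs]
            if any(g <= 0 or g >= max(self.split_generation, 1) for g in starts):
                raise ConfigError(
                    "epoch start generations must lie strictly between 0 and "
                    "split_generation"
                )
            if sorted(starts, reverse=True) != starts or len(set(starts)) != len(starts):
                raise ConfigError("epoch starts must be strictly decreasing")
        for i in (0, 1):
            if self.sample_sizes[i] > self._base_size(i):
                raise ConfigError("sample size exceeds population size")
        if self.sweep is not None:
            sw = self.sweep
            if not 0 <= sw.position < self.sequence_length:
                raise ConfigError("sweep position outside [0, sequence_length)")
            if sw.population not in (0, 1):
                raise ConfigError("sweep population must be 0 or 1")
            if sw.s < 0:
                raise ConfigError("selection coefficient must be >= 0")
            if sw.initial_copies < 1:
                raise ConfigError("initial_copies must be >= 1")
            horizon = self.split_generation if self.split_generation > 0 else self._burn()
            if not 0 < sw.onset_generation < horizon:
                raise ConfigError(
                    "sweep onset must fall after the split (or within the "
                    "burn-in for a panmictic run)"
                )

    def _burn(self) -> int:
        return self.burn_in if self.burn_in is not None else 10 * self.ancestral_size

    def _base_size(self, pop: int) -> int:
        return self.pop_sizes[pop] if self.split_generation > 0 else self.ancestral_size

    def size_at(self, pop: int, g_before_present: int) -> int:
        """Diploid size of ``pop`` at ``g_before_present`` (< split)."""
        n = self.pop_sizes[pop]
        for g0, n0 in self.epochs[pop]:  # stored with decreasing g0
            if g_before_present <= g0:
                n = n0
        return n


@dataclass
class TruthRecord:
    """Ground truth for one simulated cohort, reproducible from config+seed."""

    seed: int
    sequence_length: int
    split_generation: int
    n_sites: int
    sweep_interval: Optional[tuple[int, int]]
    sweep_lost: bool
    sweep_fixed_globally: bool
    sweep_frequency: Optional[float]
    pop_sizes: tuple[int, int]
    epochs: tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]
    generation_time: float

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)!r}")
        return "\n".join(lines) + "\n"


@dataclass
class PhasedCohort:
    """Phased biallelic haplotypes for two labelled populations.

    ``haplotypes`` is (n_haplotypes, n_sites) with 0 = ancestral and
    1 = derived; haplotypes 2i and 2i+1 belong to diploid sample i.
    Positions are 1-based bp, strictly increasing; ``cm`` is the genetic
    position of each site.
    """

    chrom: str
    sequence_length: int
    positions: np.ndarray
    haplotypes: np.ndarray
    samples: list[str]
    populations: list[str]
    cm: np.ndarray

    def __post_init__(self) -> None:
        if self.haplotypes.shape != (2 * len(self.samples), len(self.positions)):
            raise InputError("haplotype matrix dimensions inconsistent")
        if len(self.populations) != len(self.samples):
            raise InputError("one population label per sample required")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise InputError("positions must be strictly increasing")
        if len(self.cm) != len(self.positions):
            raise InputError("one genetic position per site required")
        if len(self.cm) and np.any(np.diff(self.cm) < 0):
            raise InputError("cM must be non-decreasing with bp")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def haplotypes_for(self, population: str) -> np.ndarray:
        rows = [
            r
            for i, p in enumerate(self.populations)
            for r in (2 * i, 2 * i + 1)
            if p == population
        ]
        if not rows:
            raise InputError(f"unknown population label: {population!r}")
        return self.haplotypes[rows]


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------


class _State:
    """Mutable simulation state: per-population haplotype matrices sharing
    one sorted column set of segregating positions."""

    def __init__(self, n_diploid: int, L: int):
        self.mats: list[np.ndarray] = [np.zeros((2 * n_diploid, 0), dtype=np.uint8)]
        self.positions = np.empty(0, dtype=np.int64)
        self.L = L

    @property
    def n_hap(self) -> int:
        return sum(m.shape[0] for m in self.mats)

    def col_of(self, bp: int) -> Optional[int]:
        j = int(np.searchsorted(self.positions, bp))
        if j < len(self.positions) and self.positions[j] == bp:
            return j
        return None


def _reproduce(
    rng: np.random.Generator,
    state: _State,
    sizes_next: Sequence[int],
    migration: tuple[float, float],
    sel_weights: list[Optional[np.ndarray]],
    recomb_rate: float,
) -> None:
    """Advance one generation, replacing state.mats in place."""
    mats = state.mats
    positions = state.positions
    L = state.L
    hall = mats[0] if len(mats) == 1 else np.concatenate(mats, axis=0)
    offsets = np.zeros(len(mats), dtype=np.int64)
    if len(mats) == 2:
        offsets[1] = mats[0].shape[0]
    p_xo = min(1.0, recomb_rate * max(L - 1, 0))
    two_pop = len(mats) == 2

    new_mats = []
    for dest, n_dip in enumerate(sizes_next):
        n_off = 2 * n_dip
        if two_pop:
            src = np.full(n_off, dest, dtype=np.int64)
            m = migration[dest]
            if m > 0:
                src[rng.random(n_off) < m] = 1 - dest
        else:
            src = np.zeros(n_off, dtype=np.int64)
        parent = np.empty(n_off, dtype=np.int64)
        for sp in (0, 1) if two_pop else (0,):
            rows = np.nonzero(src == sp)[0]
            if rows.size == 0:
                continue
            n_par = mats[sp].shape[0] // 2
            w = sel_weights[sp]
            if w is not None:
                parent[rows] = rng.choice(n_par, size=rows.size, p=w / w.sum())
            else:
                parent[rows] = rng.integers(0, n_par, size=rows.size)
        start = rng.integers(0, 2, size=n_off)
        row_a = offsets[src] + 2 * parent + start
        row_b = offsets[src] + 2 * parent + (1 - start)
        child = hall[row_a].copy()
        if positions.size and p_xo > 0:
            do_x = rng.random(n_off) < p_xo
            xpos = rng.integers(1, L, size=n_off)
            if do_x.any():
                donors = hall[row_b[do_x]]
                mask = positions[None, :] > xpos[do_x][:, None]
                block = child[do_x]
                block[mask] = donors[mask]
                child[do_x] = block
        new_mats.append(child)
    state.mats = new_mats


def _mutate(rng: np.random.Generator, state: _State, mu: float) -> None:
    n_hap = state.n_hap
    lam = n_hap * mu * state.L
    n_new = rng.poisson(lam) if lam > 0 else 0
    if n_new == 0:
        return
    cand = np.unique(rng.integers(1, state.L + 1, size=n_new))
    cand = cand[~np.isin(cand, state.positions)]
    if cand.size == 0:
        return
    rows = rng.integers(0, n_hap, size=cand.size)
    row_off = 0
    extended = []
    for m in state.mats:
        z = np.zeros((m.shape[0], cand.size), dtype=np.uint8)
        local = (rows >= row_off) & (rows < row_off + m.shape[0])
        z[rows[local] - row_off, np.nonzero(local)[0]] = 1
        extended.append(np.concatenate([m, z], axis=1))
        row_off += m.shape[0]
    pos = np.concatenate([state.positions, cand])
    order = np.argsort(pos, kind="stable")
    state.positions = pos[order]
    state.mats = [m[:, order] for m in extended]


def _prune(state: _State, sweep_bp: Optional[int]) -> Optional[str]:
    """Drop monomorphic columns; report the fate of the swept site if it
    just left the segregating set ('lost' or 'fixed')."""
    if state.positions.size == 0:
        return None
    tot = sum(m.sum(axis=0, dtype=np.int64) for m in state.mats)
    keep = (tot > 0) & (tot < state.n_hap)
    fate = None
    if sweep_bp is not None:
        j = state.col_of(sweep_bp)
        if j is not None and not keep[j]:
            fate = "lost" if tot[j] == 0 else "fixed"
    state.positions = state.positions[keep]
    state.mats = [m[:, keep] for m in state.mats]
    return fate


def _inject_sweep(
    rng: np.random.Generator, state: _State, sweep: SweepSpec, sweep_bp: int
) -> None:
    target = sweep.population if len(state.mats) == 2 else 0
    j = state.col_of(sweep_bp)
    if j is None:
        pos = np.concatenate([state.positions, [sweep_bp]])
        order = np.argsort(pos, kind="stable")
        state.positions = pos[order]
        state.mats = [
            np.concatenate([m, np.zeros((m.shape[0], 1), dtype=np.uint8)], axis=1)[
                :, order
            ]
            for m in state.mats
        ]
        j = state.col_of(sweep_bp)
    mat = state.mats[target]
    k = min(sweep.initial_copies, mat.shape[0])
    rows = rng.choice(mat.shape[0], size=k, replace=False)
    mat[rows, j] = 1


def simulate_cohort(config: SimulationConfig) -> tuple[PhasedCohort, TruthRecord]:
    """Run the forward simulation and sample the configured cohort.

    Returns segregating biallelic sites only (among the sampled
    chromosomes), coded 0 = ancestral / 1 = derived.  Identical config and
    seed give identical results.
    """
    rng = np.random.default_rng(config.seed)
    L = config.sequence_length
    burn = config._burn()
    split = config.split_generation
    total = burn + split
    state = _State(config.ancestral_size, L)

    sweep = config.sweep
    sweep_bp = sweep.position + 1 if sweep is not None else None
    sweep_injected = False
    sweep_lost = False
    sweep_fixed = False

    for g in range(total, 0, -1):
        # inject the beneficial allele into the generation living at g
        if sweep is not None and not sweep_injected and g == sweep.onset_generation:
            _inject_sweep(rng, state, sweep, sweep_bp)
            sweep_injected = True

        g_next = g - 1
        if split > 0 and g_next <= split - 1:
            sizes_next = [config.size_at(0, g_next), config.size_at(1, g_next)]
        else:
            sizes_next = [config.ancestral_size]

        sel = [None] * max(len(state.mats), 1)
        if (
            sweep is not None
            and sweep_injected
            and not sweep_lost
            and state.col_of(sweep_bp) is not None
        ):
            target = sweep.population if len(state.mats) == 2 else 0
            j = state.col_of(sweep_bp)
            mat = state.mats[target]
            cnt = mat[0::2, j].astype(np.float64) + mat[1::2, j]
            sel[target] = (1.0 + sweep.s) ** cnt

        _reproduce(
            rng, state, sizes_next, config.migration_rates, sel,
            config.recombination_rate,
        )
        _mutate(rng, state, config.mutation_rate)
        fate = _prune(state, sweep_bp if sweep_injected else None)
        if fate == "lost":
            if sweep.reinject_on_loss and g_next > 0:
                # recurrent mutation at the site: a fresh single origin
                _inject_sweep(rng, state, sweep, sweep_bp)
            else:
                sweep_lost = True
        elif fate == "fixed":
            sweep_fixed = True

    # sample diploids
    sample_rows = []
    samples = []
    pops = []
    labels = (FOCAL, CONTROL)
    if len(state.mats) == 2:
        row_off = [0, state.mats[0].shape[0]]
        hall = np.concatenate(state.mats, axis=0)
        for p in (0, 1):
            n_dip = state.mats[p].shape[0] // 2
            chosen = np.sort(rng.choice(n_dip, size=config.sample_sizes[p], replace=False))
            for c in chosen:
                sample_rows.extend([row_off[p] + 2 * c, row_off[p] + 2 * c + 1])
            samples += [f"{labels[p]}_{i + 1:02d}" for i in range(config.sample_sizes[p])]
            pops += [labels[p]] * config.sample_sizes[p]
    else:  # panmictic: both samples drawn from the single pool
        hall = state.mats[0]
        n_dip = hall.shape[0] // 2
        n_tot = sum(config.sample_sizes)
        chosen = rng.choice(n_dip, size=n_tot, replace=False)
        for c in chosen:
            sample_rows.extend([2 * c, 2 * c + 1])
        for p in (0, 1):
            samples += [f"{labels[p]}_{i + 1:02d}" for i in range(config.sample_sizes[p])]
            pops += [labels[p]] * config.sample_sizes[p]

    haps = hall[sample_rows] if state.positions.size else hall[sample_rows, :0]
    sweep_freq = None
    if sweep is not None:
        # derived-allele frequency among the sampled focal (target)
        # chromosomes, measured before monomorphic columns are dropped
        target = labels[sweep.population]
        target_rows = [
            r for r, p in enumerate(np.repeat(pops, 2)) if p == target
        ]
        j = int(np.searchsorted(state.positions, sweep_bp))
        if j < len(state.positions) and state.positions[j] == sweep_bp:
            sweep_freq = float(haps[target_rows, j].mean())
        else:
            sweep_freq = 1.0 if sweep_fixed else 0.0
    if haps.shape[1]:
        tot = haps.sum(axis=0, dtype=np.int64)
        seg = (tot > 0) & (tot < haps.shape[0])
        haps = haps[:, seg]
        positions = state.positions[seg]
    else:
        positions = state.positions

    cm = positions.astype(np.float64) * (config.map_cm_per_mb / 1e6)
    cohort = PhasedCohort(
        chrom=config.chrom,
        sequence_length=L,
        positions=positions.copy(),
        haplotypes=np.ascontiguousarray(haps),
        samples=samples,
        populations=pops,
        cm=cm,
    )

    interval = None
    if sweep is not None:
        # ground-truth swept interval: the expected hitchhiking footprint
        # s / (r ln 2Ns) centred on the selected site (the whole sequence
        # when recombination is absent)
        n_target = (
            config.size_at(sweep.population, sweep.onset_generation)
            if split > 0
            else config.ancestral_size
        )
        if config.recombination_rate > 0 and 2 * n_target * sweep.s > 1:
            footprint = sweep.s / (
                config.recombination_rate * np.log(2 * n_target * sweep.s)
            )
        else:
            footprint = L
        half = int(min(footprint, L) // 2)
        interval = (
            max(0, sweep.position - half),
            min(L, sweep.position + half + 1),
        )

    truth = TruthRecord(
        seed=config.seed,
        sequence_length=L,
        split_generation=split,
        n_sites=cohort.n_sites,
        sweep_interval=interval,
        sweep_lost=sweep_lost,
        sweep_fixed_globally=sweep_fixed,
        sweep_frequency=sweep_freq,
        pop_sizes=config.pop_sizes,
        epochs=config.epochs,
        generation_time=config.generation_time,
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def make_reference(sequence_length: int, seed: int) -> str:
    """Random nucleotide reference sequence for toy annotation runs."""
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=sequence_length)])


def _ref_alt_alleles(
    rng: np.random.Generator, positions: np.ndarray, reference: Optional[str]
) -> tuple[list[str], list[str]]:
    if reference is None:
        refs = np.array(list("ACGT"))[rng.integers(0, 4, size=len(positions))].tolist()
    else:
        refs = [reference[p - 1] for p in positions]
    alts = []
    for r in refs:
        if rng.random() < _TS_PROB:
            alts.append(_TRANSITION[r])
        else:
            alts.append(_TRANSVERSIONS[r][rng.integers(0, 2)])
    return refs, alts


def write_cohort(
    cohort: PhasedCohort,
    truth: TruthRecord,
    output_dir: str | Path,
    *,
    reference: Optional[str] = None,
    depth_mean: float = 8.0,
    site_mq: float = 37.0,
    mq_low_fraction: float = 0.0,
    mq_low_value: float = 15.0,
) -> dict[str, Path]:
    """Write VCF, popmap, genetic map and truth ledger; returns the paths.

    DP is Poisson around ``depth_mean`` per sample per site and MQ a
    constant, with ``mq_low_fraction`` of sites optionally corrupted below
    it so quality filters are exercisable.  All randomness derives from
    the truth seed, so a cohort always writes byte-identical files.
    """
    if cohort.n_sites == 0:
        raise InputError("cannot write an empty cohort")
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise InputError(f"cannot create output directory {out}: {exc}") from exc

    rng = np.random.default_rng(np.uint32(truth.seed) + np.uint32(1_000_003))
    refs, alts = _ref_alt_alleles(rng, cohort.positions, reference)
    dp = rng.poisson(depth_mean, size=(cohort.n_sites, cohort.n_samples))
    mq = np.full(cohort.n_sites, float(site_mq))
    if mq_low_fraction > 0:
        n_bad = int(round(mq_low_fraction * cohort.n_sites))
        bad = rng.choice(cohort.n_sites, size=n_bad, replace=False)
        mq[bad] = mq_low_value

    vcf_path = out / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-simulator\n")
        fh.write(
            f"##contig=<ID={cohort.chrom},length={cohort.sequence_length}>\n"
        )
        fh.write(
            '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        H = cohort.haplotypes
        for i in range(cohort.n_sites):
            gts = [
                f"{H[2 * s, i]}|{H[2 * s + 1, i]}:{dp[i, s]}"
                for s in range(cohort.n_samples)
            ]
            fh.write(
                f"{cohort.chrom}\t{cohort.positions[i]}\t.\t{refs[i]}\t{alts[i]}\t"
                f".\tPASS\tMQ={mq[i]:.2f}\tGT:DP\t" + "\t".join(gts) + "\n"
            )

    popmap_path = out / "popmap.tsv"
    with open(popmap_path, "w") as fh:
        for s, p in zip(cohort.samples, cohort.populations):
            fh.write(f"{s}\t{p}\n")

    map_path = out / "genetic_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("chrom\tbp\tcm\n")
        rate = (
            (cohort.cm[-1] - cohort.cm[0]) / (cohort.positions[-1] - cohort.positions[0])
            if cohort.n_sites > 1 and cohort.positions[-1] != cohort.positions[0]
            else 2.53e-6
        )
        fh.write(f"{cohort.chrom}\t1\t{0.0:.8f}\n")
        fh.write(
            f"{cohort.chrom}\t{cohort.sequence_length}\t"
            f"{rate * (cohort.sequence_length - 1):.8f}\n"
        )

    truth_path = out / "truth.txt"
    truth_path.write_text(truth.to_text())

    return {
        "vcf": vcf_path,
        "popmap": popmap_path,
        "genetic_map": map_path,
        "truth": truth_path,
    }


def to_variant_table(
    cohort: PhasedCohort,
    *,
    reference: Optional[str] = None,
    depth: float = 8.0,
    mq: float = 37.0,
    seed: int = 0,
):
    """In-memory VariantTable view of a cohort (constant DP/MQ metadata)."""
    from .variants import VariantTable

    rng = np.random.default_rng(np.uint32(seed) + np.uint32(7))
    refs, alts = _ref_alt_alleles(rng, cohort.positions, reference)
    n_s, n_i = cohort.n_sites, cohort.n_samples
    gt = np.empty((n_s, n_i, 2), dtype=np.int8)
    gt[:, :, 0] = cohort.haplotypes[0::2].T
    gt[:, :, 1] = cohort.haplotypes[1::2].T
    return VariantTable(
        chrom=np.array([cohort.chrom] * n_s, dtype=object),
        pos=cohort.positions.astype(np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        mq=np.full(n_s, float(mq)),
        gt=gt,
        dp=np.full((n_s, n_i), int(round(depth)), dtype=np.int32),
        phased=np.ones((n_s, n_i), dtype=bool),
        samples=list(cohort.samples),
        populations=np.array(cohort.populations, dtype=object),
    )


# ---------------------------------------------------------------------------
# Toy annotation and term maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: 1-based inclusive span with CDS segments.

    The gene span equals the CDS span (no UTRs in toy annotations); each
    CDS segment length is a multiple of 3 so codons never straddle a
    segment awkwardly in tests.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InputError("strand must be '+' or '-'")
        for s, e in self.cds:
            if e < s:
                raise InputError("CDS end before start")


def make_annotation_and_terms(
    sequence_length: int,
    n_genes: int,
    n_terms: int,
    planted_term: Optional[tuple[str, Sequence[str]]] = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[GeneModel], dict[str, list[str]]]:
    """Generate non-overlapping toy gene models and a term-to-gene map.

    Every gene carries 1-3 CDS segments (each a multiple of 3 bp long) and
    is assigned to 1-3 terms so the map covers all genes.  If
    ``planted_term`` is given, that term's membership is exactly the
    supplied gene subset, enabling enrichment-recovery tests.
    """
    if n_genes < 0 or n_terms < 0:
        raise ConfigError("n_genes and n_terms must be >= 0")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    if n_genes > 0:
        margin = 1200  # leave room for up/downstream flanks and intergenic gaps
        slot = (sequence_length - margin) // n_genes
        max_span = slot - margin
        if max_span < 150:
            raise ConfigError(
                f"cannot place {n_genes} non-overlapping genes in "
                f"{sequence_length} bp"
            )
        for i in range(n_genes):
            slot_start = margin // 2 + i * slot
            # multi-kb gene bodies: mammalian-like spans dominated by introns
            n_cds = int(rng.integers(3, 8))
            cds_lens = 3 * rng.integers(40, 120, size=n_cds)
            intron_lens = rng.integers(2000, 8000, size=max(n_cds - 1, 0))
            span = int(cds_lens.sum() + intron_lens.sum())
            while span > max_span and n_cds > 1:
                n_cds -= 1
                cds_lens = cds_lens[:n_cds]
                intron_lens = intron_lens[: n_cds - 1]
                span = int(cds_lens.sum() + intron_lens.sum())
            if span > max_span:
                cds_lens = np.array([3 * max(20, (max_span // 3))])
                span = int(cds_lens.sum())
            offset = int(rng.integers(0, max(slot - span - margin, 1)))
            start = slot_start + offset
            segs = []
            pos = start
            for k in range(n_cds):
                segs.append((pos, pos + int(cds_lens[k]) - 1))
                pos += int(cds_lens[k])
                if k < n_cds - 1:
                    pos += int(intron_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{i + 1:03d}",
                    chrom=chrom,
                    start=segs[0][0],
                    end=segs[-1][1],
                    strand=strand,
                    cds=tuple(segs),
                )
            )

    term_ids = [f"TERM{i + 1:04d}" for i in range(n_terms)]
    term_map: dict[str, list[str]] = {t: [] for t in term_ids}
    if term_ids and genes:
        for g in genes:
            k = int(rng.integers(1, min(3, len(term_ids)) + 1))
            for t in rng.choice(len(term_ids), size=k, replace=False):
                term_map[term_ids[t]].append(g.gene_id)
        # terms must not be empty: top up from random genes
        for t in term_ids:
            if not term_map[t]:
                term_map[t].append(genes[int(rng.integers(0, len(genes)))].gene_id)
    if planted_term is not None:
        term, members = planted_term
        known = {g.gene_id for g in genes}
        bad = [m for m in members if m not in known]
        if bad:
            raise ConfigError(f"planted term members not among generated genes: {bad}")
        term_map[term] = list(members)
    return genes, {t: sorted(set(gs)) for t, gs in term_map.items()}


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsweepscan\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsweepscan\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for k, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tsweepscan\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds{k + 1};Parent={mrna}\n"
                )
    return path


def write_term_map(term_map: dict[str, Sequence[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for term in sorted(term_map):
            for gene in term_map[term]:
                fh.write(f"{term}\t{gene}\n")
    return path


def demographic_preset(
    seed: int = 0,
    sequence_length: int = 500_000,
    sweep: bool = False,
    s: float = 2.0,
    sweep_onset: int = 12,
) -> SimulationConfig:
    """The package's default two-population scenario, optionally with a
    strong hard sweep planted mid-sequence in the focal population."""
    sw = None
    if sweep:
        sw = SweepSpec(
            position=sequence_length // 2,
            s=s,
            onset_generation=sweep_onset,
            population=0,
        )
    return SimulationConfig(seed=seed, sequence_length=sequence_length, sweep=sw)
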