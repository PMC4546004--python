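"""Synthetic two-fragment mtDNA data with known ground truth.

Generates everything the analysis chain consumes: coalescent sequence data
under one- and two-population (isolation, zero migration) histories with the
slow-coding / fast-control-region rate contrast, demographic growth or
decline, stepping-stone spatial samples with coordinates, and geometric
age-class tables. Defaults mirror the fox study's conditions: 119 + 27
samples, a 363 bp coding fragment at 2.8 %/Mgen plus a 422 bp control
region at 17.75 %/Mgen, a split of ~288,000 generations and effective
female sizes of order 2e5.

Mutations are placed under infinite sites by default, so Hamming distances
equal true mutation counts and network/rho oracles are exact; a finite-sites
mode (recurrent hits) is available for realism tests. Every dataset carries
a :class:`SimTruth` sidecar with the realised TMRCAs, split time, per-branch
mutation counts and (for age data) the true survival rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._coalescent import (
    Genealogy,
    MutationDrop,
    Trajectory,
    drop_mutations,
    sample_genealogy,
)
from .dating import AgeClassTable, Fragment
from .errors import ConfigError
from .io import SequenceRecord, write_fasta, write_population_map

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimResult",
    "DEFAULT_FRAGMENTS",
    "simulate_isolation",
    "simulate_demography",
    "simulate_spatial",
    "simulate_ages",
]

DEFAULT_FRAGMENTS = (
    Fragment("cytb", 363, 2.8),
    Fragment("dloop", 422, 17.75),
)

BASES = np.array(list("ACGT"))
KM_PER_DEGREE_LAT = 111.32


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator. ``seed`` is mandatory.

    Times are generations; rates are percent per million generations per
    site; ``effective_size`` is the effective number of females.
    """

    seed: int
    n_samples: tuple[int, ...] = (119, 27)
    populations: tuple[str, ...] | None = None
    fragments: tuple[Fragment, ...] = DEFAULT_FRAGMENTS
    effective_size: float = 2e5
    split_time: float | None = 287_584.0
    ancestral_size: float | None = None
    growth_rate: float = 0.0
    epochs: tuple[tuple[float, float], ...] = ()
    n_locations: int = 5
    samples_per_location: int = 8
    lattice_spacing_km: float = 200.0
    migration_rate: float = 1e-5
    infinite_sites: bool = True

    def __post_init__(self):
        if self.effective_size <= 0:
            raise ConfigError("effective_size must be positive")
        if any(n <= 0 for n in self.n_samples):
            raise ConfigError("sample sizes must be positive")

    @property
    def per_fragment_rates(self) -> tuple[float, ...]:
        """Per-generation whole-fragment mutation rates."""
        return tuple(f.rate * f.length * 1e-8 for f in self.fragments)

    def trajectory(self) -> Trajectory:
        if self.epochs:
            return Trajectory("piecewise", epochs=self.epochs)
        if self.growth_rate != 0.0:
            return Trajectory(
                "exponential", n0=self.effective_size, rate=self.growth_rate
            )
        return Trajectory("constant", n0=self.effective_size)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded alongside a generated dataset."""

    tmrca: float
    tmrca_per_population: dict[str, float]
    split_time: float | None
    mutations_per_fragment: tuple[int, ...]
    branch_mutations: np.ndarray | None = None
    survival: float | None = None

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("quantity,value\n")
            fh.write(f"tmrca_generations,{self.tmrca}\n")
            for pop, t in self.tmrca_per_population.items():
                fh.write(f"tmrca_{pop},{t}\n")
            if self.split_time is not None:
                fh.write(f"split_time_generations,{self.split_time}\n")
            for i, m in enumerate(self.mutations_per_fragment):
                fh.write(f"mutations_fragment_{i},{m}\n")
            if self.survival is not None:
                fh.write(f"survival,{self.survival}\n")


@dataclass
class SimResult:
    """Generated records (one per sample per fragment) plus the truth."""

    records: list[SequenceRecord]
    truth: SimTruth
    config: SimConfig
    genealogy: Genealogy = field(repr=False, default=None)

    def population_map(self) -> dict[str, dict[str, object]]:
        out: dict[str, dict[str, object]] = {}
        for r in self.records:
            if r.sample_id not in out:
                entry: dict[str, object] = {"population": r.population}
                if r.latitude is not None:
                    entry["latitude"] = r.latitude
                    entry["longitude"] = r.longitude
                out[r.sample_id] = entry
        return out

    def write(self, outdir: str | Path, prefix: str = "sim") -> dict[str, Path]:
        """Emit FASTA + population map + truth sidecar; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{prefix}.fasta"
        popmap = outdir / f"{prefix}.popmap.tsv"
        truth = outdir / f"{prefix}.truth.csv"
        write_fasta(self.records, fasta)
        write_population_map(self.records, popmap)
        self.truth.to_csv(truth)
        return {"fasta": fasta, "popmap": popmap, "truth": truth}


def _ancestral_sequences(
    fragments: Sequence[Fragment], rng: np.random.Generator
) -> list[np.ndarray]:
    return [rng.choice(BASES, size=f.length) for f in fragments]


def _leaf_records(
    genealogy: Genealogy,
    drop: MutationDrop,
    config: SimConfig,
    rng: np.random.Generator,
    coordinates: dict[str, tuple[float, float]] | None = None,
) -> list[SequenceRecord]:
    """Materialise leaf sequences from mutation sets."""
    ancestors = _ancestral_sequences(config.fragments, rng)
    # one derived base per mutated site, fixed across leaves
    derived: dict[tuple[int, int], str] = {}
    for sites in drop.leaf_sites:
        for site in sites:
            if site not in derived:
                f, pos = site
                current = ancestors[f][pos]
                others = [b for b in "ACGT" if b != current]
                derived[site] = others[int(rng.integers(3))]
    records = []
    width = len(str(genealogy.n_leaves))
    for leaf in range(genealogy.n_leaves):
        pop = genealogy.leaf_population[leaf]
        sample_id = f"s{leaf:0{width}d}"
        lat, lon = (coordinates or {}).get(pop, (None, None))
        for f, frag in enumerate(config.fragments):
            seq = ancestors[f].copy()
            for site in drop.leaf_sites[leaf]:
                if site[0] == f:
                    seq[site[1]] = derived[site]
            records.append(
                SequenceRecord(
                    sample_id=sample_id,
                    fragment_id=frag.name,
                    bases="".join(seq),
                    population=pop,
                    latitude=lat,
                    longitude=lon,
                )
            )
    return records


def _truth_from(
    genealogy: Genealogy, drop: MutationDrop, split_time: float | None
) -> SimTruth:
    per_pop = {}
    pops = sorted(set(genealogy.leaf_population))
    for pop in pops:
        leaves = [
            i for i, p in enumerate(genealogy.leaf_population) if p == pop
        ]
        per_pop[pop] = genealogy.tmrca_of(leaves)
    return SimTruth(
        tmrca=genealogy.tmrca,
        tmrca_per_population=per_pop,
        split_time=split_time,
        mutations_per_fragment=tuple(
            int(x) for x in drop.branch_counts.sum(axis=1)
        ),
        branch_mutations=drop.branch_counts,
    )


def simulate_isolation(config: SimConfig) -> SimResult:
    """Two populations splitting without subsequent migration.

    Within each population a standard coalescent runs at the configured
    size until ``split_time`` generations ago, when the surviving lineages
    merge into the ancestral population.
    """
    if len(config.n_samples) != 2:
        raise ConfigError("isolation model needs exactly two populations")
    if config.split_time is None or config.split_time <= 0:
        raise ConfigError("isolation model needs split_time > 0")
    rng = np.random.default_rng(config.seed)
    pops = config.populations or ("west", "east")
    anc = Trajectory(
        "constant", n0=config.ancestral_size or config.effective_size
    )
    gen = sample_genealogy(
        config.n_samples,
        populations=pops,
        trajectory=config.trajectory(),
        split_time=config.split_time,
        ancestral_trajectory=anc,
        rng=rng,
    )
    drop = drop_mutations(
        gen,
        config.per_fragment_rates,
        [f.length for f in config.fragments],
        rng,
        infinite_sites=config.infinite_sites,
    )
    records = _leaf_records(gen, drop, config, rng)
    return SimResult(records, _truth_from(gen, drop, config.split_time), config, gen)


def simulate_demography(config: SimConfig) -> SimResult:
    """One population with a growth, decline or piecewise size history."""
    if len(config.n_samples) != 1:
        raise ConfigError("demographic model takes a single population")
    rng = np.random.default_rng(config.seed)
    pops = config.populations or ("pop1",)
    gen = sample_genealogy(
        config.n_samples,
        populations=pops,
        trajectory=config.trajectory(),
        rng=rng,
    )
    drop = drop_mutations(
        gen,
        config.per_fragment_rates,
        [f.length for f in config.fragments],
        rng,
        infinite_sites=config.infinite_sites,
    )
    records = _leaf_records(gen, drop, config, rng)
    return SimResult(records, _truth_from(gen, drop, None), config, gen)


def _stepping_stone_genealogy(
    config: SimConfig, rng: np.random.Generator
) -> Genealogy:
    """Structured coalescent on a line of demes with neighbour migration."""
    D = config.n_locations
    k = config.samples_per_location
    n_total = D * k
    deme_of: dict[int, int] = {}
    leaf_population = []
    for d in range(D):
        for _ in range(k):
            leaf = len(leaf_population)
            deme_of[leaf] = d
            leaf_population.append(f"loc{d + 1}")
    parent = [-1] * n_total
    times = [0.0] * n_total
    active = {i: deme_of[i] for i in range(n_total)}
    t = 0.0
    N = config.effective_size
    m = config.migration_rate
    while len(active) > 1:
        per_deme: dict[int, list[int]] = {}
        for lin, d in active.items():
            per_deme.setdefault(d, []).append(lin)
        coal_rates = {
            d: len(lins) * (len(lins) - 1) / (2.0 * N)
            for d, lins in per_deme.items()
        }
        mig_rate_per_lin = {
            lin: m * (2 if 0 < d < D - 1 else 1) for lin, d in active.items()
        }
        total = sum(coal_rates.values()) + sum(mig_rate_per_lin.values())
        t += rng.exponential(1.0 / total)
        u = rng.random() * total
        acc = 0.0
        event = None
        for d, r in coal_rates.items():
            acc += r
            if u < acc:
                event = ("coal", d)
                break
        if event is None:
            for lin, r in mig_rate_per_lin.items():
                acc += r
                if u < acc:
                    event = ("mig", lin)
                    break
        if event is None:  # numerical edge
            continue
        if event[0] == "coal":
            lins = per_deme[event[1]]
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
            node = len(parent)
            parent.append(-1)
            times.append(t)
            parent[a] = node
            parent[b] = node
            d = active.pop(a)
            active.pop(b)
            active[node] = d
        else:
            lin = event[1]
            d = active[lin]
            if d == 0:
                active[lin] = 1
            elif d == D - 1:
                active[lin] = D - 2
            else:
                active[lin] = d + (1 if rng.random() < 0.5 else -1)
    return Genealogy(
        parent=np.asarray(parent),
        time=np.asarray(times),
        leaf_population=leaf_population,
    )


def simulate_spatial(config: SimConfig) -> SimResult:
    """Stepping-stone demes on a line, with coordinates for Mantel tests.

    Demes sit ``lattice_spacing_km`` apart along a meridian; lineages
    migrate only between neighbouring demes, so expected genetic distance
    rises with lattice separation (isolation by distance).
    """
    if config.n_locations < 3:
        raise ConfigError("spatial mode needs >= 3 locations")
    if config.migration_rate <= 0:
        raise ConfigError("spatial mode needs migration_rate > 0")
    rng = np.random.default_rng(config.seed)
    gen = _stepping_stone_genealogy(config, rng)
    drop = drop_mutations(
        gen,
        config.per_fragment_rates,
        [f.length for f in config.fragments],
        rng,
        infinite_sites=config.infinite_sites,
    )
    coords = {
        f"loc{d + 1}": (
            d * config.lattice_spacing_km / KM_PER_DEGREE_LAT,
            0.0,
        )
        for d in range(config.n_locations)
    }
    records = _leaf_records(gen, drop, config, rng, coordinates=coords)
    return SimResult(records, _truth_from(gen, drop, None), config, gen)


def simulate_ages(
    n: int = 435, survival: float = 0.42, seed: int | None = None
) -> tuple[AgeClassTable, SimTruth]:
    """Draw adult age classes from a geometric survival distribution.

    Class x (x = 1, 2, ...) has probability s^(x-1) (1-s); the closed-form
    mean adult age is 1/(1-s).
    """
    if not 0.0 < survival < 1.0:
        raise ConfigError("survival must be in (0, 1)")
    if seed is None:
        raise ConfigError("a seed is required")
    rng = np.random.default_rng(seed)
    draws = rng.geometric(1.0 - survival, size=n)
    counts = np.bincount(draws)[1:]
    table = AgeClassTable(
        age_class=tuple(range(1, len(counts) + 1)),
        count=tuple(int(c) for c in counts),
    )
    truth = SimTruth(
        tmrca=math.nan,
        tmrca_per_population={},
        split_time=None,
        mutations_per_fragment=(),
        survival=survival,
    )
    return table, truth
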