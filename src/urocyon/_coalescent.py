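"""Kingman-coalescent primitives shared by the simulator and Fu's-Fs null.

Genealogies are simulated backward in time in units of generations for a
haploid (matrilineal) locus: with k lineages in a population of effective
female size N(t), the coalescence hazard is k(k-1)/(2 N(t)). Population-size
histories may be constant, exponential toward the present, or
piecewise-constant. Mutations fall on branches as a Poisson process; under
the default infinite-sites placement every mutation hits a fresh site, so
Hamming distances equal true mutation counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError


@dataclass(frozen=True)
class Trajectory:
    """Population size looking backward from the present.

    kind="constant": size n0 at all times.
    kind="exponential": N(t) = n0 * exp(-rate * t); rate > 0 means the
        population grew toward the present.
    kind="piecewise": epochs = ((t0, size0), (t1, size1), ...) with t0 = 0,
        times in generations ago, sizes constant within each epoch.
    """

    kind: str = "constant"
    n0: float = 1.0
    rate: float = 0.0
    epochs: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.kind not in ("constant", "exponential", "piecewise"):
            raise ConfigError(f"unknown trajectory kind {self.kind!r}")
        if self.kind == "piecewise":
            if not self.epochs or self.epochs[0][0] != 0:
                raise ConfigError("piecewise trajectory must start at time 0")
            if any(s <= 0 for _, s in self.epochs):
                raise ConfigError("population sizes must be positive")
        elif self.n0 <= 0:
            raise ConfigError("population size must be positive")

    def size_at(self, t: float) -> float:
        if self.kind == "constant":
            return self.n0
        if self.kind == "exponential":
            return self.n0 * math.exp(-self.rate * t)
        size = self.epochs[0][1]
        for start, s in self.epochs:
            if t >= start:
                size = s
        return size

    def waiting_time(self, k: int, t0: float, rng: np.random.Generator) -> float:
        """Generations until the next coalescence among k lineages, from t0.

        Returns inf when the cumulative hazard never reaches the drawn
        exponential deviate (possible under backward-decaying sizes).
        """
        if k < 2:
            return math.inf
        pairs = k * (k - 1) / 2.0
        e = rng.exponential()
        if self.kind == "constant":
            return e * self.n0 / pairs
        if self.kind == "exponential":
            g = self.rate
            if g == 0.0:
                return e * self.n0 / pairs
            # integral of exp(g t)/n0 from t0 to t0+dt equals e/pairs
            arg = math.exp(g * t0) + g * self.n0 * e / pairs
            if arg <= 0:
                return math.inf
            return math.log(arg) / g - t0
        # piecewise-constant: walk epochs spending hazard budget e
        remaining = e
        t = t0
        bounds = [start for start, _ in self.epochs] + [math.inf]
        for i, (start, size) in enumerate(self.epochs):
            end = bounds[i + 1]
            if t >= end:
                continue
            seg = max(start, t)
            hazard_rate = pairs / size
            if end == math.inf:
                return (seg - t0) + remaining / hazard_rate
            budget = hazard_rate * (end - seg)
            if remaining <= budget:
                return seg + remaining / hazard_rate - t0
            remaining -= budget
            t = end
        raise AssertionError("unreachable")


@dataclass
class Genealogy:
    """A coalescent tree: leaves 0..n-1, internal nodes appended after.

    ``parent[i]`` is -1 for the root; ``time[i]`` is the node's age in
    generations; ``leaf_population[i]`` labels each leaf.
    """

    parent: np.ndarray
    time: np.ndarray
    leaf_population: list[str]
    split_time: float | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_population)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def tmrca_of(self, leaves: Sequence[int]) -> float:
        """Age of the most recent common ancestor of the given leaves."""
        ancestors = None
        for leaf in leaves:
            chain = set()
            node = leaf
            while node >= 0:
                chain.add(node)
                node = int(self.parent[node])
            ancestors = chain if ancestors is None else ancestors & chain
        assert ancestors
        return float(min(self.time[list(ancestors)]))

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node."""
        lengths = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        lengths[has_parent] = (
            self.time[self.parent[has_parent]] - self.time[has_parent]
        )
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self) -> list[list[int]]:
        """For each node, the sampled leaves in its subtree."""
        n_nodes = len(self.parent)
        below: list[list[int]] = [[] for _ in range(n_nodes)]
        for leaf in range(self.n_leaves):
            node = leaf
            while node >= 0:
                below[node].append(leaf)
                node = int(self.parent[node])
        return below


def _coalesce_within(
    active: list[int],
    t: float,
    stop: float,
    trajectory: Trajectory,
    parent: list[int],
    times: list[float],
    rng: np.random.Generator,
) -> tuple[list[int], float]:
    """Coalesce `active` lineages until one remains or `stop` is reached."""
    while len(active) > 1:
        dt = trajectory.waiting_time(len(active), t, rng)
        if t + dt >= stop:
            return active, stop
        t += dt
        i, j = rng.choice(len(active), size=2, replace=False)
        node = len(parent)
        parent.append(-1)
        times.append(t)
        parent[active[i]] = node
        parent[active[j]] = node
        active = [x for k, x in enumerate(active) if k not in (i, j)] + [node]
    return active, t


def sample_genealogy(
    sample_sizes: Sequence[int],
    populations: Sequence[str] | None = None,
    trajectory: Trajectory | None = None,
    split_time: float | None = None,
    ancestral_trajectory: Trajectory | None = None,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate a genealogy for one population, or two isolated ones.

    With two sample sizes, each population coalesces independently under
    ``trajectory`` until ``split_time`` generations ago, when the remaining
    lineages merge into a single ancestral population (zero migration — the
    isolation-only history).
    """
    rng = rng if rng is not None else np.random.default_rng()
    trajectory = trajectory or Trajectory()
    if len(sample_sizes) not in (1, 2):
        raise ConfigError("sample_sizes must have one or two entries")
    if len(sample_sizes) == 2 and split_time is None:
        raise ConfigError("two populations require a split_time")
    if populations is None:
        populations = [f"pop{i + 1}" for i in range(len(sample_sizes))]
    leaf_population = [
        pop for pop, n in zip(populations, sample_sizes) for _ in range(n)
    ]
    n_total = sum(sample_sizes)
    parent = [-1] * n_total
    times = [0.0] * n_total

    if len(sample_sizes) == 1:
        active = list(range(n_total))
        active, _ = _coalesce_within(
            active, 0.0, math.inf, trajectory, parent, times, rng
        )
    else:
        groups = [
            list(range(sample_sizes[0])),
            list(range(sample_sizes[0], n_total)),
        ]
        merged: list[int] = []
        for g in groups:
            remaining, _ = _coalesce_within(
                g, 0.0, split_time, trajectory, parent, times, rng
            )
            merged.extend(remaining)
        anc = ancestral_trajectory or trajectory
        merged, _ = _coalesce_within(
            merged, split_time, math.inf, anc, parent, times, rng
        )
    return Genealogy(
        parent=np.asarray(parent),
        time=np.asarray(times),
        leaf_population=leaf_population,
        split_time=split_time,
    )


@dataclass
class MutationDrop:
    """Mutations placed on a genealogy over one or more fragments.

    ``leaf_sites[i]`` is the set of (fragment index, site) pairs at which
    leaf i carries the derived state; ``branch_counts[f][node]`` counts the
    mutations of fragment f on the branch above ``node``.
    """

    leaf_sites: list[set[tuple[int, int]]]
    branch_counts: np.ndarray
    finite_sites_fallback: bool = False


def _distinct_positions(frag_len: int, total: int, rng: np.random.Generator) -> np.ndarray:
    """`total` distinct site indices in [0, frag_len), cheap even for huge frag_len."""
    if frag_len <= 4 * total:
        return rng.permutation(frag_len)[:total]
    chosen: set[int] = set()
    while len(chosen) < total:
        draw = rng.integers(0, frag_len, size=total - len(chosen))
        chosen.update(int(x) for x in draw)
    return np.fromiter(chosen, dtype=np.int64, count=total)


def drop_mutations(
    genealogy: Genealogy,
    per_sequence_rates: Sequence[float],
    fragment_lengths: Sequence[int],
    rng: np.random.Generator,
    infinite_sites: bool = True,
) -> MutationDrop:
    """Scatter Poisson mutations on branches, one or more fragments.

    ``per_sequence_rates[f]`` is the expected number of mutations per
    generation over the whole fragment f. Under infinite sites every
    mutation occupies a previously untouched site of its fragment; when a
    fragment runs out of fresh sites the placement falls back to finite
    sites (recurrent hits allowed) with a warning.
    """
    lengths = genealogy.branch_lengths()
    n_nodes = len(lengths)
    n_frag = len(per_sequence_rates)
    branch_counts = np.zeros((n_frag, n_nodes), dtype=int)
    below = genealogy.leaves_below()
    leaf_sites: list[set[tuple[int, int]]] = [
        set() for _ in range(genealogy.n_leaves)
    ]
    fallback = False
    for f, (rate, frag_len) in enumerate(zip(per_sequence_rates, fragment_lengths)):
        counts = rng.poisson(rate * lengths)
        branch_counts[f] = counts
        total = int(counts.sum())
        if infinite_sites and total <= frag_len:
            positions = _distinct_positions(frag_len, total, rng)
        else:
            if infinite_sites:
                warnings.warn(
                    f"fragment {f}: {total} mutations exceed {frag_len} sites; "
                    "falling back to finite-sites placement",
                    stacklevel=2,
                )
            fallback = True
            positions = rng.integers(0, frag_len, size=total)
        idx = 0
        for node in range(n_nodes):
            for _ in range(counts[node]):
                site = (f, int(positions[idx]))
                for leaf in below[node]:
                    # a recurrent hit at the same site toggles the state back
                    if site in leaf_sites[leaf]:
                        leaf_sites[leaf].discard(site)
                    else:
                        leaf_sites[leaf].add(site)
                idx += 1
    return MutationDrop(
        leaf_sites=leaf_sites,
        branch_counts=branch_counts,
        finite_sites_fallback=fallback,
    )
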