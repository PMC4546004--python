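"""Spatial population structure: AMOVA, SAMOVA and isolation by distance.

Molecular variance is decomposed from the matrix of pairwise site
differences (the counts serve as squared distances, the convention of the
standard AMOVA). Phi_ST measures differentiation among populations,
Phi_CT among groups of populations and Phi_SC among populations within
groups. The SAMOVA-style search anneals over assignments of sampling
locations to K groups to maximise Phi_CT, and the Mantel test correlates
genetic with geographic distance under label permutation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import pairwise_difference
from .errors import ConfigError, DataError

__all__ = [
    "DistanceMatrix",
    "AmovaResult",
    "PartitionResult",
    "molecular_distances",
    "amova",
    "pairwise_phi_st",
    "samova_search",
    "exhaustive_samova",
    "mantel",
    "great_circle_distances",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix.

    kind: "molecular" (pairwise site differences), "geographic"
    (great-circle km) or "phi" (pairwise Phi_ST).
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "molecular"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DataError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise DataError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise DataError("matrix diagonal is not zero")

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.kind
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, index_label="label"
        )

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "molecular") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col="label")
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


def molecular_distances(
    sequences: Sequence[str], labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise site-difference counts (pairwise deletion of ambiguity)."""
    n = len(sequences)
    labels = list(labels) if labels is not None else [f"s{i}" for i in range(n)]
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pairwise_difference(sequences[i], sequences[j], proportion=False)
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m, "molecular")


# ---------------------------------------------------------------------------
# AMOVA


@dataclass(frozen=True)
class AmovaResult:
    """Variance components and Phi statistics of a (possibly grouped) AMOVA."""

    sigma_among_groups: float
    sigma_among_pops: float
    sigma_within: float
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float
    df: tuple[int, int, int]
    p_phi_ct: float | None = None
    p_phi_st: float | None = None
    n_permutations: int = 0
    seed: int | None = None

    @property
    def total_variance(self) -> float:
        return self.sigma_among_groups + self.sigma_among_pops + self.sigma_within


class _AmovaData:
    """Precomputed pairwise-difference sums for fast repeated decompositions."""

    def __init__(self, populations: Mapping[str, Sequence[str]]):
        small = [p for p, seqs in populations.items() if len(seqs) < 2]
        if small:
            warnings.warn(f"populations of size < 2 excluded: {small}")
        self.pops = [p for p in populations if p not in small]
        if len(self.pops) < 2:
            raise DataError("need at least 2 populations of size >= 2")
        seqs: list[str] = []
        bounds = [0]
        for p in self.pops:
            seqs.extend(populations[p])
            bounds.append(len(seqs))
        d = molecular_distances(seqs).values
        self.n_p = np.diff(bounds).astype(float)
        self.N = float(bounds[-1])
        P = len(self.pops)
        # T[p, q]: full cross sum for p != q; within-pop unordered-pair sum on diagonal
        self.T = np.zeros((P, P))
        for a in range(P):
            sa = slice(bounds[a], bounds[a + 1])
            self.T[a, a] = d[sa, sa].sum() / 2.0
            for b in range(a + 1, P):
                sb = slice(bounds[b], bounds[b + 1])
                self.T[a, b] = self.T[b, a] = d[sa, sb].sum()
        self.ss_total = d.sum() / 2.0 / self.N
        self.ss_within = float((np.diag(self.T) / self.n_p).sum())
        self._d = d
        self._bounds = bounds

    def decompose(self, groups: np.ndarray) -> AmovaResult:
        """Three-level decomposition for a group assignment of populations."""
        P = len(self.pops)
        G = int(groups.max()) + 1
        N, n_p = self.N, self.n_p
        ss_group_total = 0.0
        sum_npsq_over_Ng = 0.0
        sum_Ngsq = 0.0
        for g in range(G):
            members = np.flatnonzero(groups == g)
            if members.size == 0:
                raise DataError("empty group")
            Ng = n_p[members].sum()
            block = self.T[np.ix_(members, members)]
            # diagonal holds within sums, off-diagonal cross sums counted once
            ss_group_total += (np.triu(block).sum()) / Ng
            sum_npsq_over_Ng += (n_p[members] ** 2).sum() / Ng
            sum_Ngsq += Ng**2
        ssd_wp = self.ss_within
        ssd_ap = ss_group_total - ssd_wp
        ssd_ag = self.ss_total - ss_group_total
        df_ag, df_ap, df_wp = G - 1, P - G, int(N) - P
        sigma_c = ssd_wp / df_wp if df_wp > 0 else 0.0
        if df_ap > 0:
            n1 = (N - sum_npsq_over_Ng) / df_ap
            ms_ap = ssd_ap / df_ap
            sigma_b = (ms_ap - sigma_c) / n1 if n1 > 0 else 0.0
        else:
            sigma_b = 0.0
        if df_ag > 0:
            n2 = (sum_npsq_over_Ng - (n_p**2).sum() / N) / df_ag
            n3 = (N - sum_Ngsq / N) / df_ag
            ms_ag = ssd_ag / df_ag
            sigma_a = (ms_ag - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        else:
            sigma_a = 0.0
        total = sigma_a + sigma_b + sigma_c
        return AmovaResult(
            sigma_among_groups=sigma_a,
            sigma_among_pops=sigma_b,
            sigma_within=sigma_c,
            phi_ct=sigma_a / total if total > 0 else 0.0,
            phi_sc=sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else 0.0,
            phi_st=(sigma_a + sigma_b) / total if total > 0 else 0.0,
            df=(df_ag, df_ap, df_wp),
        )

    def phi_ct(self, groups: np.ndarray) -> float:
        return float(self.decompose(groups).phi_ct)

    def two_level(self, ss_within: float | None = None) -> AmovaResult:
        """Among/within-population decomposition (no grouping level)."""
        P = len(self.pops)
        N, n_p = self.N, self.n_p
        ssd_wp = self.ss_within if ss_within is None else ss_within
        ssd_ap = self.ss_total - ssd_wp
        df_ap, df_wp = P - 1, int(N) - P
        sigma_b = ssd_wp / df_wp if df_wp > 0 else 0.0
        n0 = (N - (n_p**2).sum() / N) / df_ap
        ms_ap = ssd_ap / df_ap
        sigma_a = (ms_ap - sigma_b) / n0
        total = sigma_a + sigma_b
        return AmovaResult(
            sigma_among_groups=0.0,
            sigma_among_pops=sigma_a,
            sigma_within=sigma_b,
            phi_ct=None,
            phi_sc=None,
            phi_st=sigma_a / total if total > 0 else 0.0,
            df=(0, df_ap, df_wp),
        )


def amova(
    populations: Mapping[str, Sequence[str]],
    groups: Mapping[str, str] | None = None,
    n_permutations: int = 0,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA from populations of aligned sequences.

    Without ``groups`` a two-level decomposition (among/within populations)
    yields Phi_ST, with a permutation p from reassigning individuals to
    populations. With ``groups`` (population -> group label) the three-level
    decomposition yields Phi_CT/Phi_SC/Phi_ST, with the Phi_CT permutation p
    from reassigning whole populations to groups.
    """
    data = _AmovaData(populations)
    rng = np.random.default_rng(seed) if n_permutations else None
    if groups is None:
        res = data.two_level()
        p_st = None
        if n_permutations:
            obs = res.phi_st
            hits = 0
            d, bounds = data._d, data._bounds
            order = np.arange(int(data.N))
            for _ in range(n_permutations):
                rng.shuffle(order)
                ss_w = 0.0
                for a in range(len(data.pops)):
                    idx = order[bounds[a] : bounds[a + 1]]
                    ss_w += d[np.ix_(idx, idx)].sum() / 2.0 / len(idx)
                if data.two_level(ss_w).phi_st >= obs:
                    hits += 1
            p_st = hits / n_permutations
        return AmovaResult(
            **{
                **res.__dict__,
                "p_phi_st": p_st,
                "n_permutations": n_permutations,
                "seed": seed,
            }
        )
    group_labels = sorted(set(groups.values()))
    gidx = {g: i for i, g in enumerate(group_labels)}
    try:
        assignment = np.array([gidx[groups[p]] for p in data.pops])
    except KeyError as exc:
        raise ConfigError(f"population {exc} missing from groups") from exc
    res = data.decompose(assignment)
    p_ct = None
    if n_permutations:
        obs = res.phi_ct
        hits = 0
        perm = assignment.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            try:
                if data.phi_ct(perm) >= obs:
                    hits += 1
            except DataError:  # a permutation emptied a group label
                hits += 1
        p_ct = hits / n_permutations
    return AmovaResult(
        **{
            **res.__dict__,
            "p_phi_ct": p_ct,
            "n_permutations": n_permutations,
            "seed": seed,
        }
    )


def pairwise_phi_st(
    populations: Mapping[str, Sequence[str]],
    truncate_negative: bool = False,
) -> DistanceMatrix:
    """Pairwise Phi_ST matrix over all populations of size >= 2.

    Negative estimates are retained by default; ``truncate_negative=True``
    clamps them to zero (useful as Mantel input).
    """
    pops = [p for p, seqs in populations.items() if len(seqs) >= 2]
    dropped = sorted(set(populations) - set(pops))
    if dropped:
        warnings.warn(f"populations of size 1 excluded: {dropped}")
    if len(pops) < 2:
        raise DataError("need >= 2 populations with >= 2 sequences")
    n = len(pops)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        res = amova({pops[i]: populations[pops[i]], pops[j]: populations[pops[j]]})
        v = res.phi_st
        if truncate_negative:
            v = max(v, 0.0)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(pops, m, "phi")


# ---------------------------------------------------------------------------
# SAMOVA


@dataclass(frozen=True)
class PartitionResult:
    """Best K-group assignment of sampling locations and its Phi_CT."""

    k: int
    assignment: dict[str, int]
    phi_ct: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    trace: tuple[float, ...] = ()

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for loc, g in self.assignment.items():
            out.setdefault(g, []).append(loc)
        return {g: sorted(v) for g, v in out.items()}


def _random_partition(P: int, K: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random surjective assignment of P locations to K groups."""
    while True:
        a = rng.integers(0, K, size=P)
        if len(np.unique(a)) == K:
            return a


def samova_search(
    populations: Mapping[str, Sequence[str]],
    k: int,
    n_restarts: int = 10,
    n_steps: int = 2000,
    n_permutations: int = 99,
    seed: int | None = None,
) -> PartitionResult:
    """Simulated-annealing search for the K-grouping maximising Phi_CT.

    Neighbour move: reassign one location to another group (moves emptying a
    group are rejected). Geometric cooling from an initial temperature set
    by the objective spread over 100 random partitions; best state over
    ``n_restarts`` independent chains. The permutation p-value reassigns
    whole locations among the best partition's groups.
    """
    data = _AmovaData(populations)
    P = len(data.pops)
    if not 2 <= k < P:
        raise ConfigError(f"K={k} must satisfy 2 <= K < {P} locations")
    rng = np.random.default_rng(seed)

    spread = [data.phi_ct(_random_partition(P, k, rng)) for _ in range(100)]
    t0 = max(float(np.std(spread)), 1e-4)
    t_end = t0 * 1e-3
    cooling = (t_end / t0) ** (1.0 / max(n_steps - 1, 1))

    best_a: np.ndarray | None = None
    best_phi = -np.inf
    trace: list[float] = []
    for _ in range(n_restarts):
        a = _random_partition(P, k, rng)
        phi = data.phi_ct(a)
        if phi > best_phi:
            best_phi, best_a = phi, a.copy()
        t = t0
        for _ in range(n_steps):
            loc = int(rng.integers(P))
            counts = np.bincount(a, minlength=k)
            if counts[a[loc]] == 1:
                t *= cooling
                continue
            new_g = int(rng.integers(k))
            if new_g == a[loc]:
                t *= cooling
                continue
            old = a[loc]
            a[loc] = new_g
            new_phi = data.phi_ct(a)
            delta = new_phi - phi
            if delta >= 0 or rng.random() < math.exp(delta / t):
                phi = new_phi
                if phi > best_phi:
                    best_phi, best_a = phi, a.copy()
            else:
                a[loc] = old
            t *= cooling
        trace.append(phi)

    p_value = None
    if n_permutations:
        hits = 0
        perm = best_a.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            try:
                if data.phi_ct(perm) >= best_phi:
                    hits += 1
            except DataError:
                hits += 1
        p_value = hits / n_permutations
    assignment = {p: int(g) for p, g in zip(data.pops, best_a)}
    return PartitionResult(
        k=k,
        assignment=assignment,
        phi_ct=float(best_phi),
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        trace=tuple(trace),
    )


def _partitions_into_k(items: Sequence, k: int):
    """All set partitions of `items` into exactly k non-empty blocks."""
    if k == 1:
        yield [list(items)]
        return
    if len(items) == k:
        yield [[x] for x in items]
        return
    first, rest = items[0], items[1:]
    for part in _partitions_into_k(rest, k - 1):
        yield [[first]] + part
    for part in _partitions_into_k(rest, k):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]


def exhaustive_samova(
    populations: Mapping[str, Sequence[str]], k: int
) -> PartitionResult:
    """Exact maximum-Phi_CT partition by enumerating all K-groupings."""
    data = _AmovaData(populations)
    P = len(data.pops)
    if not 2 <= k < P:
        raise ConfigError(f"K={k} must satisfy 2 <= K < {P} locations")
    best_phi, best_assign = -np.inf, None
    for blocks in _partitions_into_k(list(range(P)), k):
        a = np.zeros(P, dtype=int)
        for g, block in enumerate(blocks):
            a[block] = g
        phi = data.phi_ct(a)
        if phi > best_phi:
            best_phi, best_assign = phi, a.copy()
    assignment = {p: int(g) for p, g in zip(data.pops, best_assign)}
    return PartitionResult(
        k=k,
        assignment=assignment,
        phi_ct=float(best_phi),
        p_value=None,
        n_permutations=0,
        seed=None,
    )


# ---------------------------------------------------------------------------
# Mantel test and geography


def mantel(
    matrix_a: DistanceMatrix,
    matrix_b: DistanceMatrix,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided Mantel test of positive association between two matrices.

    r is the Pearson correlation of the off-diagonal elements; p is the
    fraction of label permutations of the second matrix with r at least as
    large as observed.
    """
    if matrix_a.labels != matrix_b.labels:
        raise DataError("matrices must share labels (same order)")
    n = len(matrix_a.labels)
    if n < 3:
        raise DataError("Mantel test needs >= 3 labels")
    iu = np.triu_indices(n, 1)
    x = matrix_a.values[iu]
    y = matrix_b.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("Mantel r undefined for a constant matrix")

    def corr(yy: np.ndarray) -> float:
        return float(np.corrcoef(x, yy)[0, 1])

    r = corr(y)
    rng = np.random.default_rng(seed)
    hits = 0
    b = matrix_b.values
    for _ in range(n_permutations):
        order = rng.permutation(n)
        if corr(b[np.ix_(order, order)][iu]) >= r:
            hits += 1
    p = hits / n_permutations if n_permutations else float("nan")
    return r, p


def great_circle_distances(
    coordinates: Mapping[str, tuple[float | None, float | None]],
) -> DistanceMatrix:
    """Haversine great-circle distances (km) between labelled coordinates.

    Locations with missing coordinates are dropped with a warning.
    """
    labels = []
    pts = []
    dropped = []
    for label, (lat, lon) in coordinates.items():
        if lat is None or lon is None:
            dropped.append(label)
            continue
        if not (-90 <= lat <= 90 and -180 <= lon <= 360):
            raise DataError(f"{label}: invalid coordinates ({lat}, {lon})")
        labels.append(label)
        pts.append((math.radians(lat), math.radians(lon)))
    if dropped:
        warnings.warn(f"locations without coordinates dropped: {sorted(dropped)}")
    n = len(labels)
    m = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        la1, lo1 = pts[i]
        la2, lo2 = pts[j]
        h = (
            math.sin((la2 - la1) / 2) ** 2
            + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))
        m[i, j] = m[j, i] = d
    return DistanceMatrix(labels, m, "geographic")
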