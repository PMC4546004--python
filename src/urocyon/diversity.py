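"""Diversity and divergence statistics, and Fu's Fs neutrality test.

Haplotype (gene) diversity uses Nei's unbiased estimator
h = n/(n-1) * (1 - sum p_i^2) with Nei's sampling variance; nucleotide
diversity pi is the frequency-weighted mean pairwise proportion of differing
sites (pairwise deletion of ambiguous positions), with the Nei & Tajima
total variance. Net divergence between two groups is
d_A = d_XY - (pi_X + pi_Y)/2, which strips ancestral polymorphism from a
split estimate. Fu's Fs is computed from the Ewens sampling formula with
theta estimated by the mean number of pairwise differences, and its p-value
comes from constant-size coalescent simulations at the observed theta.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._coalescent import Trajectory, drop_mutations, sample_genealogy
from .errors import ConfigError, DataError, UndefinedResultError

__all__ = [
    "DiversityResult",
    "DivergenceResult",
    "FsResult",
    "haplotype_diversity",
    "nucleotide_diversity",
    "net_divergence",
    "fu_fs",
    "ewens_k_tail_probability",
    "fs_from_counts",
    "pairwise_difference",
]


@dataclass(frozen=True)
class DiversityResult:
    """Haplotype and/or nucleotide diversity with sampling SDs."""

    n: int
    k: int | None = None
    h: float | None = None
    h_sd: float | None = None
    pi: float | None = None
    pi_sd: float | None = None


@dataclass(frozen=True)
class DivergenceResult:
    """Between-group divergence d_XY and net divergence d_A, per site."""

    d_xy: float
    pi_x: float
    pi_y: float
    model: str = "p-distance"

    @property
    def d_a(self) -> float:
        return self.d_xy - (self.pi_x + self.pi_y) / 2.0


@dataclass(frozen=True)
class FsResult:
    """Fu's Fs with its coalescent-null p-value.

    ``p_value`` is the plain quantile: the fraction of simulated Fs values
    <= the observed one. Significance is conventionally called at p < 0.02
    (Fu 1997); the 0.05 comparison is also exposed.
    """

    fs_observed: float
    theta_pi: float
    k_obs: int
    n: int
    p_value: float | None = None
    n_sims: int = 0
    seed: int | None = None

    @property
    def significant_at_002(self) -> bool | None:
        return None if self.p_value is None else self.p_value < 0.02

    @property
    def significant_at_005(self) -> bool | None:
        return None if self.p_value is None else self.p_value < 0.05


# ---------------------------------------------------------------------------
# haplotype diversity


def haplotype_diversity(counts: Sequence[int]) -> DiversityResult:
    """Nei's unbiased gene diversity and its SD from haplotype counts.

    h = n/(n-1) (1 - sum p_i^2);
    V(h) = 2/(n(n-1)) { 2(n-2) [sum p_i^3 - (sum p_i^2)^2]
                        + sum p_i^2 - (sum p_i^2)^2 }.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=float)
    if (np.asarray(counts) < 0).any():
        raise DataError("negative haplotype counts")
    n = c.sum()
    if n < 2:
        raise UndefinedResultError("haplotype diversity needs n >= 2")
    p = c / n
    s2 = float((p**2).sum())
    s3 = float((p**3).sum())
    h = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return DiversityResult(n=int(n), k=len(c), h=h, h_sd=math.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# pairwise distances and nucleotide diversity

_AMBIGUOUS = {"N", "-"}


def pairwise_difference(a: str, b: str, proportion: bool = True) -> float:
    """Differences between two aligned sequences with pairwise deletion.

    Sites where either sequence has N or a gap are skipped. Returns the
    proportion of differing comparable sites (or the raw count).
    """
    if len(a) != len(b):
        raise DataError("sequences of unequal length")
    comparable = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in _AMBIGUOUS or y in _AMBIGUOUS:
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise DataError("no comparable sites between sequence pair")
    return diffs / comparable if proportion else float(diffs)


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance for one aligned pair."""
    comparable = ts = tv = 0
    for x, y in zip(a, b):
        if x in _AMBIGUOUS or y in _AMBIGUOUS:
            continue
        comparable += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if comparable == 0:
        raise DataError("no comparable sites between sequence pair")
    P, Q = ts / comparable, tv / comparable
    inner1 = 1.0 - 2.0 * P - Q
    inner2 = 1.0 - 2.0 * Q
    if inner1 <= 0 or inner2 <= 0:
        raise DataError("K2P distance undefined (saturated pair)")
    return -0.5 * math.log(inner1) - 0.25 * math.log(inner2)


def _expand(sequences: Sequence[str], multiplicities: Sequence[int] | None) -> list[str]:
    if multiplicities is None:
        return list(sequences)
    if len(multiplicities) != len(sequences):
        raise DataError("multiplicities do not match sequences")
    return [s for s, m in zip(sequences, multiplicities) for _ in range(int(m))]


def _mean_pairwise(seqs: list[str], distance) -> float:
    """Mean of `distance` over all unordered pairs of individuals."""
    n = len(seqs)
    if n < 2:
        raise UndefinedResultError("need >= 2 sequences")
    total = 0.0
    n_pairs = 0
    dropped = 0
    for a, b in itertools.combinations(seqs, 2):
        try:
            total += distance(a, b)
            n_pairs += 1
        except DataError:
            dropped += 1
    if n_pairs == 0:
        raise DataError("no comparable sequence pairs")
    if dropped:
        import warnings

        warnings.warn(f"{dropped} sequence pair(s) dropped (no comparable sites)")
    return total / n_pairs


def nucleotide_diversity(
    sequences: Sequence[str],
    multiplicities: Sequence[int] | None = None,
    model: str = "p-distance",
) -> DiversityResult:
    """Nucleotide diversity pi per site, with the Nei & Tajima variance.

    V(pi) = (n+1)/(3(n-1)L) pi + 2(n^2+n+3)/(9n(n-1)) pi^2, where L is the
    sequence length; this is the total (stochastic + sampling) variance as
    reported by the standard desktop tools.
    """
    seqs = _expand(sequences, multiplicities)
    distance = pairwise_difference if model == "p-distance" else k2p_distance
    pi = _mean_pairwise(seqs, distance)
    n = len(seqs)
    L = len(seqs[0])
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    ) * pi**2
    return DiversityResult(
        n=n, k=len(set(seqs)), pi=pi, pi_sd=math.sqrt(max(var, 0.0))
    )


def net_divergence(
    group_x: Sequence[str],
    group_y: Sequence[str],
    multiplicities_x: Sequence[int] | None = None,
    multiplicities_y: Sequence[int] | None = None,
    model: str = "p-distance",
) -> DivergenceResult:
    """Between-group divergence d_XY and net divergence d_A.

    d_XY is the mean pairwise distance over all cross-group pairs; d_A
    subtracts the average within-group nucleotide diversity.
    """
    xs = _expand(group_x, multiplicities_x)
    ys = _expand(group_y, multiplicities_y)
    if not xs or not ys:
        raise DataError("both groups must be non-empty")
    distance = pairwise_difference if model == "p-distance" else k2p_distance
    total = 0.0
    for a in xs:
        for b in ys:
            total += distance(a, b)
    d_xy = total / (len(xs) * len(ys))
    # within-group diversity over the C(n,2) sample pairs (the desktop-tool
    # convention): random halves of one panmictic pool then give E[d_A] = 0
    pi_x = _mean_pairwise(xs, distance) if len(xs) > 1 else 0.0
    pi_y = _mean_pairwise(ys, distance) if len(ys) > 1 else 0.0
    name = "p-distance" if model == "p-distance" else "K2P"
    return DivergenceResult(d_xy=d_xy, pi_x=pi_x, pi_y=pi_y, model=name)


# ---------------------------------------------------------------------------
# Fu's Fs


def _log_stirling_first(n: int) -> np.ndarray:
    """log |S(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    prev = np.full(n + 1, -np.inf)
    prev[0] = 0.0  # S(0,0) = 1
    for m in range(1, n + 1):
        cur = np.full(n + 1, -np.inf)
        # S(m,k) = S(m-1,k-1) + (m-1) S(m-1,k)
        cur[1 : m + 1] = np.logaddexp(
            prev[0:m], math.log(m - 1) + prev[1 : m + 1] if m > 1 else -np.inf
        )
        prev = cur
    return prev


def ewens_k_tail_probability(k_obs: int, theta: float, n: int) -> float:
    """S' = P(K >= k_obs) for the allele count K under the Ewens formula.

    P(K = k) = |S(n,k)| theta^k / (theta)_n, with (theta)_n the rising
    factorial; computed in log space via the Stirling-number recursion.
    """
    if n < 1 or k_obs < 1:
        raise DataError("need n >= 1 and k_obs >= 1")
    if k_obs > n:
        return 0.0
    if k_obs == 1:
        return 1.0
    if theta <= 0:
        return 0.0
    log_s = _log_stirling_first(n)
    log_theta = math.log(theta)
    log_rising = sum(math.log(theta + i) for i in range(n))
    ks = np.arange(0, n + 1)
    log_p = log_s + ks * log_theta - log_rising
    # tail sum over k >= k_obs, guarded against rounding just above 1
    tail = float(np.exp(log_p[k_obs:]).sum())
    return min(tail, 1.0)


def fs_from_counts(k_obs: int, theta: float, n: int) -> float:
    """Fu's Fs = ln(S'/(1-S')); +/-inf sentinels at the boundaries."""
    s_prime = ewens_k_tail_probability(k_obs, theta, n)
    if s_prime >= 1.0:
        return math.inf
    if s_prime <= 0.0:
        return -math.inf
    return math.log(s_prime / (1.0 - s_prime))


def _fs_of_replicate(leaf_sites: list[set]) -> float:
    """Fs of one simulated infinite-sites sample."""
    n = len(leaf_sites)
    total = 0
    for a, b in itertools.combinations(leaf_sites, 2):
        total += len(a ^ b)
    theta_hat = total / (n * (n - 1) / 2)
    k = len({frozenset(s) for s in leaf_sites})
    return fs_from_counts(k, theta_hat, n)


def fu_fs(
    sequences: Sequence[str],
    multiplicities: Sequence[int] | None = None,
    n_sims: int = 1000,
    seed: int | None = None,
) -> FsResult:
    """Fu's Fs for an aligned sample, with a coalescent-null p-value.

    theta is estimated by the mean pairwise difference count (theta_pi).
    The null distribution comes from ``n_sims`` constant-size Kingman
    coalescent genealogies with infinite-sites mutations at the observed
    theta; the p-value is the fraction of simulated Fs <= the observed Fs
    (small Fs = an excess of alleles, the expansion signal).
    """
    seqs = _expand(sequences, multiplicities)
    n = len(seqs)
    if n < 2:
        raise UndefinedResultError("Fu's Fs needs n >= 2")
    theta_pi = _mean_pairwise(seqs, lambda a, b: pairwise_difference(a, b, False))
    k_obs = len(set(seqs))
    fs = fs_from_counts(k_obs, theta_pi, n)
    p_value = None
    if n_sims > 0:
        if seed is None:
            raise ConfigError("a seed is required for the coalescent null")
        rng = np.random.default_rng(seed)
        at_or_below = 0
        for _ in range(n_sims):
            gen = sample_genealogy([n], trajectory=Trajectory("constant", 1.0), rng=rng)
            drop = drop_mutations(gen, [theta_pi / 2.0], [10**9], rng)
            if _fs_of_replicate(drop.leaf_sites) <= fs:
                at_or_below += 1
        p_value = at_or_below / n_sims
    return FsResult(
        fs_observed=fs,
        theta_pi=theta_pi,
        k_obs=k_obs,
        n=n,
        p_value=p_value,
        n_sims=n_sims,
        seed=seed,
    )
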