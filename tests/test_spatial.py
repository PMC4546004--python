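"""AMOVA/Phi statistics, SAMOVA search, Mantel test, geography."""

import itertools
import math

import numpy as np
import pytest

from urocyon import spatial
from urocyon.errors import ConfigError, DataError


def _seq(rng, length=40):
    return "".join(rng.choice(list("ACGT"), size=length))


def _mutate(seq, rng, k):
    s = list(seq)
    for pos in rng.choice(len(s), size=k, replace=False):
        s[pos] = rng.choice([b for b in "ACGT" if b != s[pos]])
    return "".join(s)


def _amova_oracle(populations, groups):
    """Independent sums-of-squares AMOVA written as explicit nested loops."""
    pops = list(populations)
    seqs = []
    pop_of = []
    for p in pops:
        for s in populations[p]:
            seqs.append(s)
            pop_of.append(p)
    N = len(seqs)

    def d(a, b):
        return sum(x != y for x, y in zip(seqs[a], seqs[b]))

    def ss(idx):
        return sum(d(i, j) for i, j in itertools.combinations(idx, 2)) / len(idx)

    all_idx = list(range(N))
    ss_total = ss(all_idx)
    ss_wp = sum(ss([i for i in all_idx if pop_of[i] == p]) for p in pops)
    group_of = {p: groups[p] for p in pops}
    gs = sorted(set(group_of.values()))
    ss_groups = sum(
        ss([i for i in all_idx if group_of[pop_of[i]] in (g,)]) for g in gs
    )
    ssd_ag = ss_total - ss_groups
    ssd_ap = ss_groups - ss_wp
    ssd_wp = ss_wp
    P, G = len(pops), len(gs)
    n_p = {p: len(populations[p]) for p in pops}
    Ng = {g: sum(n_p[p] for p in pops if group_of[p] == g) for g in gs}
    sigma_c = ssd_wp / (N - P)
    n1 = (N - sum(sum(n_p[p] ** 2 for p in pops if group_of[p] == g) / Ng[g] for g in gs)) / (P - G) if P > G else 0
    n2 = (
        sum(sum(n_p[p] ** 2 for p in pops if group_of[p] == g) / Ng[g] for g in gs)
        - sum(n_p[p] ** 2 for p in pops) / N
    ) / (G - 1)
    n3 = (N - sum(Ng[g] ** 2 for g in gs) / N) / (G - 1)
    sigma_b = (ssd_ap / (P - G) - sigma_c) / n1 if P > G else 0.0
    sigma_a = (ssd_ag / (G - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c


class TestPhiSt:
    def test_fixed_populations_give_phi_one(self):
        a = ["A" * 20] * 5
        b = ["T" * 10 + "A" * 10] * 5
        res = spatial.amova({"A": a, "B": b})
        assert res.phi_st == pytest.approx(1.0)

    def test_panmictic_split_centres_on_zero(self):
        rng = np.random.default_rng(40)
        base = _seq(rng)
        pool = [_mutate(base, rng, int(rng.integers(1, 6))) for _ in range(12)]
        values = []
        for _ in range(100):
            order = rng.permutation(12)
            res = spatial.amova(
                {
                    "A": [pool[i] for i in order[:6]],
                    "B": [pool[i] for i in order[6:]],
                }
            )
            values.append(res.phi_st)
        mean = np.mean(values)
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert abs(mean) <= max(2 * se, 0.02)

    def test_three_level_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(41)
        base = _seq(rng)
        pops = {
            f"p{i}": [_mutate(base, rng, int(rng.integers(0, 8))) for _ in range(int(rng.integers(3, 7)))]
            for i in range(5)
        }
        groups = {"p0": "g1", "p1": "g1", "p2": "g2", "p3": "g2", "p4": "g2"}
        res = spatial.amova(pops, groups=groups)
        a, b, c = _amova_oracle(pops, groups)
        assert res.sigma_among_groups == pytest.approx(a)
        assert res.sigma_among_pops == pytest.approx(b)
        assert res.sigma_within == pytest.approx(c)
        assert res.phi_ct == pytest.approx(a / (a + b + c))

    def test_pairwise_matrix_symmetric_with_truncation_option(self):
        rng = np.random.default_rng(42)
        base = _seq(rng)
        pops = {
            f"p{i}": [_mutate(base, rng, 2) for _ in range(4)] for i in range(3)
        }
        m = spatial.pairwise_phi_st(pops)
        assert np.allclose(m.values, m.values.T)
        t = spatial.pairwise_phi_st(pops, truncate_negative=True)
        assert (t.values >= 0).all()

    def test_single_sequence_population_excluded_with_warning(self):
        pops = {"A": ["AAAA"] * 3, "B": ["TTTT"] * 3, "C": ["GGGG"]}
        with pytest.warns(UserWarning, match="size 1"):
            m = spatial.pairwise_phi_st(pops)
        assert m.labels == ["A", "B"]

    def test_permutation_p_deterministic_for_seed(self):
        rng = np.random.default_rng(43)
        base = _seq(rng)
        pops = {"A": [_mutate(base, rng, 2) for _ in range(5)],
                "B": [_mutate(base, rng, 2) for _ in range(5)]}
        r1 = spatial.amova(pops, n_permutations=200, seed=7)
        r2 = spatial.amova(pops, n_permutations=200, seed=7)
        assert r1.p_phi_st == r2.p_phi_st


class TestSamova:
    @pytest.fixture
    def seven_locations_one_outlier(self):
        rng = np.random.default_rng(44)
        base = _seq(rng, 60)
        pops = {
            f"L{i}": [_mutate(base, rng, int(rng.integers(0, 3))) for _ in range(4)]
            for i in range(6)
        }
        # one location fixed for a haplotype 8+ mutations from all others
        far = _mutate(base, rng, 12)
        pops["L6"] = [far] * 4
        return pops

    def test_private_divergent_location_isolated_at_k2(
        self, seven_locations_one_outlier
    ):
        ex = spatial.exhaustive_samova(seven_locations_one_outlier, 2)
        groups = ex.groups()
        singleton = [v for v in groups.values() if len(v) == 1]
        assert singleton == [["L6"]]
        sa = spatial.samova_search(
            seven_locations_one_outlier, 2, n_restarts=3, n_steps=500,
            n_permutations=0, seed=1,
        )
        assert sa.phi_ct == pytest.approx(ex.phi_ct)

    def test_identical_locations_grouped_at_k_minus_one(self):
        rng = np.random.default_rng(45)
        base = _seq(rng, 50)
        pops = {f"L{i}": [_mutate(base, rng, 3 + 2 * i) for _ in range(3)] for i in range(4)}
        twin = pops["L1"]
        pops["L4"] = list(twin)
        k = len(pops) - 1
        ex = spatial.exhaustive_samova(pops, k)
        paired = [sorted(v) for v in ex.groups().values() if len(v) == 2]
        assert ["L1", "L4"] in paired

    def test_annealing_reaches_exhaustive_optimum(self):
        rng = np.random.default_rng(46)
        base = _seq(rng, 50)
        hits = 0
        pops = {
            f"L{i}": [_mutate(base, rng, int(rng.integers(0, 6))) for _ in range(3)]
            for i in range(6)
        }
        for k in (2, 3):
            ex = spatial.exhaustive_samova(pops, k)
            for seed in range(10):
                sa = spatial.samova_search(
                    pops, k, n_restarts=3, n_steps=400, n_permutations=0, seed=seed
                )
                hits += sa.phi_ct >= ex.phi_ct - 1e-9
        assert hits >= 19  # 95% of 20 runs

    def test_k_bounds_enforced(self):
        pops = {"A": ["AAAA"] * 2, "B": ["TTTT"] * 2}
        with pytest.raises(ConfigError):
            spatial.samova_search(pops, 2, seed=0)

    def test_phi_ct_nondecreasing_in_k_for_exhaustive_optima(self):
        rng = np.random.default_rng(47)
        base = _seq(rng, 50)
        pops = {
            f"L{i}": [_mutate(base, rng, int(rng.integers(0, 5))) for _ in range(3)]
            for i in range(6)
        }
        best = [spatial.exhaustive_samova(pops, k).phi_ct for k in (2, 3, 4)]
        assert all(b >= a - 1e-9 for a, b in zip(best, best[1:]))


class TestMantel:
    def _matrix(self, rng, n=6):
        m = rng.random((n, n)) * 10
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return spatial.DistanceMatrix([f"l{i}" for i in range(n)], m)

    def test_scaled_matrix_gives_r_one(self):
        rng = np.random.default_rng(48)
        a = self._matrix(rng)
        b = spatial.DistanceMatrix(a.labels, 2 * a.values)
        r, p = spatial.mantel(a, b, n_permutations=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_null_p_values_roughly_uniform(self):
        """p over independent random matrices is ~uniform (KS at 1%)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(49)
        ps = []
        for trial in range(120):
            a = self._matrix(rng)
            b = self._matrix(rng)
            _, p = spatial.mantel(a, b, n_permutations=200, seed=trial)
            ps.append(p)
        stat = kstest(ps, "uniform")
        assert stat.pvalue > 0.01

    def test_constant_matrix_raises(self):
        a = spatial.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        rng = np.random.default_rng(50)
        with pytest.raises(DataError):
            spatial.mantel(a, self._matrix(rng, 3), n_permutations=10, seed=0)

    def test_agrees_with_skbio_mantel(self):
        """Independent cross-check of r against scikit-bio."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(51)
        a = self._matrix(rng)
        b = self._matrix(rng)
        r, _ = spatial.mantel(a, b, n_permutations=0, seed=0)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(a.values, a.labels), SkbioDM(b.values, b.labels),
            permutations=0,
        )
        assert r == pytest.approx(float(r_ref))

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(52)
        a, b = self._matrix(rng), self._matrix(rng)
        assert spatial.mantel(a, b, 500, seed=3) == spatial.mantel(a, b, 500, seed=3)


class TestGreatCircle:
    def test_identical_points_zero(self):
        m = spatial.great_circle_distances({"a": (10.0, 20.0), "b": (10.0, 20.0)})
        assert m.values[0, 1] == pytest.approx(0.0)

    def test_equatorial_quadrant(self):
        m = spatial.great_circle_distances({"a": (0.0, 0.0), "b": (0.0, 90.0)})
        assert m.values[0, 1] == pytest.approx(10_007.5, rel=1e-3)

    def test_triangle_inequality_on_random_points(self):
        rng = np.random.default_rng(53)
        coords = {
            f"p{i}": (float(rng.uniform(-80, 80)), float(rng.uniform(-179, 179)))
            for i in range(8)
        }
        m = spatial.great_circle_distances(coords)
        assert np.allclose(m.values, m.values.T)
        n = len(m.labels)
        for i, j, k in itertools.permutations(range(n), 3):
            assert m.values[i, j] <= m.values[i, k] + m.values[k, j] + 1e-6

    def test_missing_coordinates_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="without coordinates"):
            m = spatial.great_circle_distances(
                {"a": (0.0, 0.0), "b": (None, None), "c": (1.0, 1.0)}
            )
        assert m.labels == ["a", "c"]
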