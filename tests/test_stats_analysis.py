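"""Rank tests, multiplicity control and the region-wise comparison scheme.

Brute-force oracles (mid-rank computation from first principles, labeling
enumeration, literal step-up/step-down definitions) are implemented here,
independently of the library code they check.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

import retdefocus as rd

# ---------------------------------------------------------------------------
# Independent brute-force oracles


def midranks(values):
    """Mid-ranks by explicit pairwise counting (no library rank call)."""
    values = np.asarray(values, float)
    ranks = np.empty(values.size)
    for i, v in enumerate(values):
        less = np.sum(values < v)
        equal = np.sum(values == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_kruskal_h(groups):
    """Tie-corrected H from the definition."""
    pooled = np.concatenate(groups)
    ranks = midranks(pooled)
    N = pooled.size
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (N + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / correction if correction > 0 else 0.0


def brute_u_statistic(a, b):
    """U of `a` by pairwise counting with half-credit for ties."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sum(a[:, None] > b[None, :]) + 0.5 * np.sum(a[:, None] == b[None, :]))


def brute_exact_mwu_p(a, b):
    """Two-sided exact p by enumerating all labelings (tie-free data)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = brute_u_statistic(a, b)
    n = len(pooled)
    mu = n_a * (n - n_a) / 2.0
    count = total = 0
    for idx in combinations(range(n), n_a):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        u = brute_u_statistic(pooled[mask], pooled[~mask])
        total += 1
        count += abs(u - mu) >= abs(observed - mu) - 1e-12
    return count / total


def brute_bh(pvals, q):
    """Literal step-up definition: largest i with p_(i) <= (i/m) q."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    i_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * q:
            i_star = i
    reject = np.zeros(m, bool)
    reject[order[:i_star]] = True
    crit = i_star / m * q if i_star else 0.0
    return reject, crit


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_hand_computed_three_group_example(self):
        """Mean ranks 2, 5, 8 of {1,2,3},{4,5,6},{7,8,9} give H = 7.2."""
        kw = rd.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert kw.H == pytest.approx(7.2, abs=1e-12)
        assert kw.df == 2
        np.testing.assert_allclose(kw.group_mean_ranks, [2.0, 5.0, 8.0])

    def test_identical_groups_have_zero_h_and_p_one(self):
        kw = rd.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert kw.H == 0.0
        assert kw.p == 1.0

    def test_group_order_permutation_invariance(self, rng):
        groups = [rng.normal(size=7), rng.normal(size=5), rng.normal(size=9)]
        h1 = rd.kruskal_wallis(groups).H
        h2 = rd.kruskal_wallis([groups[2], groups[0], groups[1]]).H
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rd.kruskal_wallis([[1.0], []])
        with pytest.raises(ValueError, match="2 groups"):
            rd.kruskal_wallis([[1.0, 2.0]])

    def test_agrees_with_brute_force_on_random_small_instances(self):
        """500 random small instances (ties included): |H - oracle| < 1e-10."""
        rng = np.random.default_rng(77)
        for _ in range(500):
            k = int(rng.integers(2, 5))
            groups = [
                rng.integers(0, 8, size=int(rng.integers(2, 13))).astype(float)
                for _ in range(k)
            ]
            kw = rd.kruskal_wallis(groups)
            assert abs(kw.H - brute_kruskal_h(groups)) < 1e-10


# ---------------------------------------------------------------------------
# Mann-Whitney U


class TestMannWhitneyU:
    def test_small_exact_example(self):
        """{1,2} vs {3,4}: U = 0, two-sided p = 2/6."""
        u, p = rd.mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_give_central_u_and_p_one(self):
        u, p = rd.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(9 / 2)
        assert p == pytest.approx(1.0)

    def test_swap_duality(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9)
        u_ab, p_ab = rd.mann_whitney_u(a, b)
        u_ba, p_ba = rd.mann_whitney_u(b, a)
        assert u_ab + u_ba == pytest.approx(len(a) * len(b))
        assert p_ab == pytest.approx(p_ba, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rd.mann_whitney_u([], [1.0])

    def test_statistic_agrees_with_pairwise_counting(self):
        rng = np.random.default_rng(78)
        for _ in range(500):
            a = rng.integers(0, 10, size=int(rng.integers(1, 13))).astype(float)
            b = rng.integers(0, 10, size=int(rng.integers(1, 13))).astype(float)
            u, _ = rd.mann_whitney_u(a, b)
            assert abs(u - brute_u_statistic(a, b)) < 1e-10

    def test_exact_p_agrees_with_enumeration_oracle(self):
        """Tie-free small samples: p equals full labeling enumeration."""
        rng = np.random.default_rng(79)
        checked = 0
        while checked < 25:
            n_a, n_b = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            pooled = rng.permutation(rng.normal(size=n_a + n_b))
            a, b = pooled[:n_a], pooled[n_a:]
            u, p = rd.mann_whitney_u(a, b)
            assert p == pytest.approx(brute_exact_mwu_p(a, b), abs=1e-10)
            checked += 1

    def test_asymptotic_p_matches_tie_corrected_normal_formula(self):
        rng = np.random.default_rng(80)
        for _ in range(50):
            a = rng.integers(0, 6, size=20).astype(float)
            b = rng.integers(0, 6, size=25).astype(float)
            u, p = rd.mann_whitney_u(a, b)
            n1, n2 = len(a), len(b)
            n = n1 + n2
            pooled = np.concatenate([a, b])
            _, t = np.unique(pooled, return_counts=True)
            mu = n1 * n2 / 2.0
            sigma2 = n1 * n2 / 12.0 * ((n + 1) - np.sum(t**3 - t) / (n * (n - 1)))
            z = (u - mu) / np.sqrt(sigma2)
            assert p == pytest.approx(2 * sps.norm.sf(abs(z)), abs=1e-10)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


class TestBenjaminiHochberg:
    def test_all_small_pvalues_rejected_with_full_critical_value(self):
        reject, crit = rd.benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()
        assert crit == pytest.approx(0.05)

    def test_all_ones_rejects_nothing(self):
        reject, crit = rd.benjamini_hochberg([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()
        assert crit == 0.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            rd.benjamini_hochberg([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(81)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            q = float(rng.uniform(0.01, 0.2))
            reject, crit = rd.benjamini_hochberg(p, q)
            oracle_reject, oracle_crit = brute_bh(p, q)
            np.testing.assert_array_equal(reject, oracle_reject)
            assert crit == pytest.approx(oracle_crit, abs=1e-12)

    def test_matches_statsmodels_reject_flags(self, rng):
        p = rng.uniform(size=40)
        reject, _ = rd.benjamini_hochberg(p, q=0.05)
        sm_reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(reject, sm_reject)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.integers(0, 2**31 - 1))
    def test_input_order_invariance(self, pvals, seed):
        perm = np.random.default_rng(seed).permutation(len(pvals))
        reject, crit = rd.benjamini_hochberg(pvals, 0.05)
        reject_p, crit_p = rd.benjamini_hochberg(np.asarray(pvals)[perm], 0.05)
        np.testing.assert_array_equal(reject[perm], reject_p)
        assert crit == crit_p


# ---------------------------------------------------------------------------
# Post-hoc pairwise contrasts


class TestPosthocPairwise:
    def test_well_separated_groups_all_significant(self):
        groups = [np.arange(10), np.arange(100, 110), np.arange(200, 210)]
        pw = rd.posthoc_pairwise(rd.kruskal_wallis(groups))
        assert pw.table["significant"].all()
        assert pw.critical_p > 0

    def test_identical_pair_not_significant(self):
        groups = [np.arange(10), np.arange(10), np.arange(200, 210)]
        pw = rd.posthoc_pairwise(rd.kruskal_wallis(groups), labels=["a", "a2", "b"])
        row = pw.table[(pw.table.group_a == "a") & (pw.table.group_b == "a2")]
        assert not row["significant"].item()

    def test_holm_flags_equal_brute_force_holm_on_dunn_pvalues(self, rng):
        groups = [rng.normal(loc, size=30) for loc in (0.0, 0.4, 0.8, 0.2)]
        kw = rd.kruskal_wallis(groups)
        pw = rd.posthoc_pairwise(kw, method="holm")
        raw = pw.table["raw_p"].to_numpy()
        # literal step-down: sort raw p, compare to alpha/(m - i)
        m = raw.size
        order = np.argsort(raw)
        reject = np.zeros(m, bool)
        for rank, idx in enumerate(order):
            if raw[idx] <= 0.05 / (m - rank):
                reject[idx] = True
            else:
                break
        np.testing.assert_array_equal(pw.table["significant"].to_numpy(), reject)

    def test_alpha_out_of_range_rejected(self):
        kw = rd.kruskal_wallis([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            rd.posthoc_pairwise(kw, alpha=1.5)

    def test_constant_shift_monotonicity_of_z(self, rng):
        """Adding a constant to one group never decreases its |z| against
        a fixed reference group."""
        base = [rng.normal(size=40), rng.normal(size=40), rng.normal(size=40)]
        zs = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            shifted = [base[0], base[1] + shift, base[2]]
            kw = rd.kruskal_wallis(shifted)
            pw = rd.posthoc_pairwise(kw, labels=["ref", "shifted", "other"])
            row = pw.table[(pw.table.group_a == "ref") & (pw.table.group_b == "shifted")]
            zs.append(abs(row["z"].item()))
        assert zs == sorted(zs)


# ---------------------------------------------------------------------------
# Region-wise analysis


def _tiny_region_table(rng, optic_shift=0.0, n=60):
    """Region table for 1 scene x 1 profile x 3 optics over all 16 regions."""
    rows = []
    for ring in rd.Ring:
        for quad in rd.Quadrant:
            base = rng.normal(size=n)
            for optic, shift in (("NAKED", 0.0), ("NEAR_CENTRE", optic_shift),
                                 ("DISTANCE_CENTRE", 0.0)):
                values = base + shift if optic == "NEAR_CENTRE" else base
                rows.append(pd.DataFrame({
                    "scene": "OFFICE", "optic": optic, "profile": "NPS",
                    "ring": ring.value, "quadrant": quad.value, "value": values,
                }))
    return pd.concat(rows, ignore_index=True)


class TestRegionConditionAnalysis:
    def test_constant_shift_is_significant_in_every_region(self, masks, rng):
        """Two conditions differing by +2.25 D in every pixel differ in all
        regions; here with region-sized groups drawn once per region."""
        table = _tiny_region_table(rng, optic_shift=2.25, n=400)
        result = rd.region_condition_analysis(table, "optic")
        shifted = result.pairwise[
            (result.pairwise.group_a == "NEAR_CENTRE")
            | (result.pairwise.group_b == "NEAR_CENTRE")
        ]
        assert shifted["significant"].all()
        assert len(result.kw) == 16

    def test_identical_conditions_nowhere_significant(self, rng):
        table = _tiny_region_table(rng, optic_shift=0.0, n=60)
        result = rd.region_condition_analysis(table, "optic")
        assert not result.pairwise["significant"].any()
        assert len(result.nonsignificant) == len(result.pairwise)

    def test_bookkeeping_row_counts(self, rng):
        table = _tiny_region_table(rng, optic_shift=1.0, n=30)
        result = rd.region_condition_analysis(table, "optic")
        assert len(result.pairwise) == 16 * 3  # 16 regions x C(3,2) contrasts
        assert set(result.kw.columns) >= {"ring", "quadrant", "H", "df", "p"}

    def test_unknown_factor_rejected(self, rng):
        with pytest.raises(ValueError, match="factor"):
            rd.region_condition_analysis(_tiny_region_table(rng), "lens")
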