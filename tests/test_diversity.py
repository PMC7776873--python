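"""Shannon diversity, group ratios, Jaccard overlap, exact Spearman."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import archhist as ah
from archhist.diversity import DiversityError, min_positive_entropy

from conftest import identity_alignment, make_seq


class TestShannonIndex:
    @pytest.mark.parametrize("counts,expected", [
        ({"R": 4}, 0.0),
        ({"A": 2, "V": 2}, math.log(2)),
        ({"A": 2, "R": 1, "K": 1}, 1.5 * math.log(2) + 0.0),  # see below
    ])
    def test_known_columns(self, counts, expected):
        # {A:2,R:1,K:1}: H = 0.5 ln2 + 2*(0.25 ln4) = 1.0397
        assert ah.shannon_index(counts) == pytest.approx(expected, abs=1e-12)

    def test_mixed_column_value(self):
        assert ah.shannon_index({"A": 2, "R": 1, "K": 1}) == pytest.approx(
            1.0397, abs=1e-4
        )

    def test_zero_total_rejected(self):
        with pytest.raises(DiversityError):
            ah.shannon_index({"A": 0})

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1,
                    max_size=20))
    def test_maximal_iff_equifrequent(self, counts):
        residues = "ACDEFGHIKLMNPQRSTVWY"[: len(counts)]
        h = ah.shannon_index(dict(zip(residues, counts)))
        k = len(counts)
        assert h <= math.log(k) + 1e-12
        if len(set(counts)) == 1:
            assert h == pytest.approx(math.log(k), abs=1e-12)


def _two_group_alignment(col_a, col_b):
    """One informative column; group a = rows 0..len(col_a)-1, b = rest."""
    rows = {"REF": "A"}
    labels = {}
    for i, ch in enumerate(col_a):
        rows[f"a{i}"] = ch
        labels[f"a{i}"] = "A"
    for i, ch in enumerate(col_b):
        rows[f"b{i}"] = ch
        labels[f"b{i}"] = "B"
    aligned, posmap = identity_alignment(rows, "REF")
    return aligned, posmap, ah.GroupLabeling(labels)


class TestDiversityRatioProfile:
    def test_conserved_denominator_is_undefined_not_infinite(self):
        aligned, posmap, lab = _two_group_alignment("ARKE", "RRRR")
        prof = ah.diversity_ratio_profile(aligned, posmap, lab, "A", "B")
        row = prof.table.iloc[0]
        assert not row.ratio_defined and not row.both_zero
        assert np.isnan(row.ratio)

    def test_both_groups_conserved_sets_zero_zero_subflag(self):
        aligned, posmap, lab = _two_group_alignment("RRRR", "RRRR")
        row = ah.diversity_ratio_profile(
            aligned, posmap, lab, "A", "B"
        ).table.iloc[0]
        assert not row.ratio_defined and row.both_zero

    def test_identical_composition_gives_ratio_one(self):
        aligned, posmap, lab = _two_group_alignment("AAVV", "AAVV")
        row = ah.diversity_ratio_profile(
            aligned, posmap, lab, "A", "B"
        ).table.iloc[0]
        assert row.ratio == pytest.approx(1.0)

    def test_ln2_over_ln4_is_half(self):
        aligned, posmap, lab = _two_group_alignment("AAVV", "AVLI")
        row = ah.diversity_ratio_profile(
            aligned, posmap, lab, "A", "B"
        ).table.iloc[0]
        assert row.ratio == pytest.approx(math.log(2) / math.log(4))

    def test_unknown_group_rejected(self):
        aligned, posmap, lab = _two_group_alignment("AAVV", "AVLI")
        with pytest.raises(DiversityError):
            ah.diversity_ratio_profile(aligned, posmap, lab, "A", "nope")

    def test_gaps_and_x_excluded_from_counts(self):
        aligned, posmap, lab = _two_group_alignment("AV-X", "AVAV")
        row = ah.diversity_ratio_profile(
            aligned, posmap, lab, "A", "B"
        ).table.iloc[0]
        assert row.n_a == 2  # gap and X dropped

    def test_reciprocal_ratios_multiply_to_one(self):
        aligned, posmap, lab = _two_group_alignment("AAVV", "AVLI")
        fwd = ah.diversity_ratio_profile(aligned, posmap, lab, "A", "B")
        rev = ah.diversity_ratio_profile(aligned, posmap, lab, "B", "A")
        prod = fwd.table.iloc[0].ratio * rev.table.iloc[0].ratio
        assert prod == pytest.approx(1.0)


class TestJaccard:
    @pytest.mark.parametrize("col_a,col_b,expected", [
        ("RRRR", "RRRR", 1.0),
        ("RRRR", "KKKK", 0.0),
        ("ARKA", "RKEQ", 0.4),  # {A,R,K} vs {R,K,E,Q}: 2 shared / 5 union
    ])
    def test_known_overlaps(self, col_a, col_b, expected):
        aligned, posmap, lab = _two_group_alignment(col_a, col_b)
        series = ah.jaccard_profile(aligned, posmap, lab, "A", "B")
        assert series.loc[1] == pytest.approx(expected)

    def test_symmetric_and_bounded(self, small_sim):
        _, sim = small_sim
        fwd = ah.jaccard_profile(sim.aligned, sim.posmap, sim.labeling,
                                 "multi", "single")
        rev = ah.jaccard_profile(sim.aligned, sim.posmap, sim.labeling,
                                 "single", "multi")
        assert np.allclose(fwd.values, rev.values)
        assert ((fwd.values >= 0) & (fwd.values <= 1)).all()


class TestBaseInvariance:
    @given(st.lists(st.integers(min_value=0, max_value=30), min_size=2,
                    max_size=8).filter(lambda c: sum(x > 0 for x in c) >= 2))
    def test_ratio_same_in_nats_and_bits(self, counts_a):
        residues = "ACDEFGHI"[: len(counts_a)]
        counts_b = list(reversed(counts_a))
        ca = {r: c for r, c in zip(residues, counts_a) if c > 0}
        cb = {r: c for r, c in zip(residues, counts_b) if c > 0}
        h2 = lambda c: stats.entropy(list(c.values()), base=2)
        if h2(cb) == 0:
            return
        ratio_nats = ah.shannon_index(ca) / ah.shannon_index(cb)
        ratio_bits = h2(ca) / h2(cb)
        assert ratio_nats == pytest.approx(ratio_bits, rel=1e-9)


class TestRankedPositions:
    def test_undefined_with_diversity_ranks_above_defined(self):
        # position 1: A diverse, B conserved (undefined ratio, high H_a);
        # position 2: both mildly diverse
        rows = {"REF": "AA"}
        labels = {}
        for i, (c1, c2) in enumerate([("A", "A"), ("R", "A"), ("K", "V"),
                                      ("E", "V")]):
            rows[f"a{i}"] = c1 + c2
            labels[f"a{i}"] = "A"
        for i, (c1, c2) in enumerate([("R", "A"), ("R", "A"), ("R", "V"),
                                      ("R", "V")]):
            rows[f"b{i}"] = c1 + c2
            labels[f"b{i}"] = "B"
        aligned, posmap = identity_alignment(rows, "REF")
        prof = ah.diversity_ratio_profile(
            aligned, posmap, ah.GroupLabeling(labels), "A", "B"
        )
        assert prof.ranked_positions() == [1, 2]

    def test_min_positive_entropy_matches_single_deviant(self):
        assert min_positive_entropy(4) == pytest.approx(
            ah.shannon_index({"A": 3, "V": 1})
        )


def _spearman_oracle_p(x, y):
    """Two-sided permutation p-value via scipy rho over all n! shuffles."""
    rho_obs = stats.spearmanr(x, y).statistic
    n = len(y)
    hits = total = 0
    for perm in itertools.permutations(y):
        rho = stats.spearmanr(x, perm).statistic
        hits += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return hits / total


class TestSpearmanExact:
    def test_perfect_monotone_increasing(self):
        r = ah.spearman_exact([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)
        assert r.p_value == pytest.approx(2 / 120)
        assert r.mode == "exact"

    def test_perfect_monotone_decreasing(self):
        r = ah.spearman_exact([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert r.rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        r = ah.spearman_exact([1, 2, 3], [7, 7, 7])
        assert r.mode == "undefined" and math.isnan(r.rho)

    def test_ties_use_average_ranks(self):
        x = [1, 2, 2, 3]
        y = [4, 5, 6, 7]
        r = ah.spearman_exact(x, y)
        assert r.rho == pytest.approx(stats.spearmanr(x, y).statistic)

    @pytest.mark.parametrize("n", [3, 4, 5, 6])
    def test_matches_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(3):
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = ah.spearman_exact(x, y)
            assert r.mode == "exact"
            assert r.rho == pytest.approx(stats.spearmanr(x, y).statistic)
            assert r.p_value == pytest.approx(_spearman_oracle_p(x, y))

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = ah.spearman_exact(x, y)
        ref = stats.spearmanr(x, y)
        assert r.mode == "t-approx"
        assert r.rho == pytest.approx(ref.statistic)
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-6)
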