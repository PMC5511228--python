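"""SDR beta-diversity partitioning: identities, symmetry, oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insularis.errors import UndefinedPairError
from insularis.sdr import (
    cross_temporal_sdr,
    cross_temporal_table,
    pairwise_sdr,
    sdr_from_counts,
    simplex_table,
    turnover_counts,
)

from conftest import make_matrix


class TestPairwise:
    def test_identical_islands(self):
        m = make_matrix([[1, 1], [1, 1], [0, 0]])
        t = pairwise_sdr(m, "i0", "i1")
        assert t.as_tuple() == (1.0, 0.0, 0.0)

    def test_disjoint_islands(self):
        # 3 vs 5 species, none shared: S_t = 8
        cells = np.zeros((8, 2), dtype=int)
        cells[:3, 0] = 1
        cells[3:, 1] = 1
        t = pairwise_sdr(make_matrix(cells), "i0", "i1")
        assert t.similarity == 0.0
        assert t.richness_difference == pytest.approx(2 / 8)
        assert t.replacement == pytest.approx(6 / 8)

    def test_hand_worked_triple(self):
        # S_i=5, S_j=3, S_ij=2 -> S_t=6 and thirds everywhere
        t = sdr_from_counts(5, 3, 2)
        assert t.as_tuple() == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.integers(0, 2, size=(12, 4)))
        for a, b in itertools.combinations(m.island_ids, 2):
            assert pairwise_sdr(m, a, b).as_tuple() == pairwise_sdr(m, b, a).as_tuple()

    def test_empty_pair_undefined(self):
        m = make_matrix([[1, 0, 0], [1, 0, 0]])
        with pytest.raises(UndefinedPairError):
            pairwise_sdr(m, "i1", "i2")

    @given(st.integers(0, 60), st.integers(0, 60), st.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_components_sum_to_one_and_are_nonnegative(self, s_i, s_j, data):
        s_ij = data.draw(st.integers(0, min(s_i, s_j)))
        if s_i + s_j - s_ij == 0:
            return
        t = sdr_from_counts(s_i, s_j, s_ij)
        assert min(t.as_tuple()) >= 0
        assert sum(t.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_replacement_numerator_doubles_exactly(self):
        # S_t * R is an even integer for any valid counts
        for s_i, s_j, s_ij in [(9, 4, 1), (7, 7, 3), (5, 2, 2)]:
            t = sdr_from_counts(s_i, s_j, s_ij)
            s_t = s_i + s_j - s_ij
            assert (t.replacement * s_t) % 2 == pytest.approx(0, abs=1e-9)


class TestSimplexTable:
    def test_two_identical_islands_summary(self):
        m = make_matrix([[1, 1], [1, 1]])
        pairs, summary = simplex_table(m)
        assert summary.n_pairs == 1
        assert summary.mean_similarity_pct == pytest.approx(100.0)
        assert summary.mean_richness_difference_pct == pytest.approx(0.0)
        assert summary.mean_replacement_pct == pytest.approx(0.0)

    def test_means_equal_brute_force_per_pair_means(self):
        rng = np.random.default_rng(11)
        cells = rng.integers(0, 2, size=(6, 4))
        cells[0] = 1  # keep every island nonempty
        m = make_matrix(cells)
        pairs, summary = simplex_table(m)
        # independent recomputation from raw sets
        vals = []
        for a, b in itertools.combinations(range(4), 2):
            sa = set(np.flatnonzero(cells[:, a]))
            sb = set(np.flatnonzero(cells[:, b]))
            st_ = len(sa | sb)
            vals.append((len(sa & sb) / st_,
                         abs(len(sa) - len(sb)) / st_,
                         2 * min(len(sa - sb), len(sb - sa)) / st_))
        vals = np.array(vals)
        assert summary.mean_similarity_pct == pytest.approx(100 * vals[:, 0].mean())
        assert summary.mean_richness_difference_pct == pytest.approx(100 * vals[:, 1].mean())
        assert summary.mean_replacement_pct == pytest.approx(100 * vals[:, 2].mean())
        assert (summary.mean_similarity_pct + summary.mean_richness_difference_pct
                + summary.mean_replacement_pct) == pytest.approx(100.0, abs=1e-9)

    def test_undefined_pairs_excluded_not_zeroed(self):
        m = make_matrix([[1, 0, 0]])
        pairs, summary = simplex_table(m)
        assert summary.n_pairs == 2  # (i0,i1) and (i0,i2); (i1,i2) undefined
        assert summary.n_undefined == 1


class TestCrossTemporal:
    def test_identical_floras(self):
        m1 = make_matrix([[1, 0], [1, 1]], period="P1")
        m2 = make_matrix([[1, 0], [1, 1]], period="P2")
        t = cross_temporal_sdr(m1, m2, "i0")
        assert t.as_tuple() == (1.0, 0.0, 0.0)

    def test_hand_worked_period_sets(self):
        # {a,b,c} then {a,d}: S_t=4, S=1/4, D=1/4, R=1/2
        m1 = make_matrix([[1], [1], [1], [0]], species=list("abcd"), period="P1")
        m2 = make_matrix([[1], [0], [0], [1]], species=list("abcd"), period="P2")
        t = cross_temporal_sdr(m1, m2, "i0")
        assert t.as_tuple() == pytest.approx((0.25, 0.25, 0.5))

    def test_jaccard_consistent_with_turnover_counts(self):
        rng = np.random.default_rng(5)
        sp = [f"s{i}" for i in range(15)]
        m1 = make_matrix(rng.integers(0, 2, (15, 3)), species=sp, period="P1")
        m2 = make_matrix(rng.integers(0, 2, (15, 3)), species=sp, period="P2")
        for isl in m1.island_ids:
            stable, gained, lost = turnover_counts(m1, m2, isl)
            if stable + gained + lost == 0:
                continue
            t = cross_temporal_sdr(m1, m2, isl)
            assert t.similarity == pytest.approx(stable / (stable + gained + lost))

    def test_cross_temporal_table_joins_area(self):
        m1 = make_matrix([[1, 1], [0, 1]], period="P1")
        m2 = make_matrix([[1, 0], [1, 1]], period="P2")
        areas = pd.Series({"i0": 5.0, "i1": 50.0})
        table = cross_temporal_table(m1, m2, areas=areas)
        assert list(table["area_km2"]) == [5.0, 50.0]
        assert np.allclose(
            table[["similarity", "richness_difference", "replacement"]].sum(axis=1), 1.0)


class TestTurnover:
    def test_simple_gain_loss(self):
        m1 = make_matrix([[1], [1], [0]], species=list("abc"), period="P1")
        m2 = make_matrix([[0], [1], [1]], species=list("abc"), period="P2")
        assert turnover_counts(m1, m2, "i0") == (1, 1, 1)

    def test_identical_sets(self):
        m = make_matrix([[1], [1], [1]])
        assert turnover_counts(m, m, "i0") == (3, 0, 0)

    def test_archipelago_level_union(self):
        m1 = make_matrix([[1, 0], [0, 1], [0, 0]], species=list("abc"), period="P1")
        m2 = make_matrix([[0, 0], [1, 0], [0, 1]], species=list("abc"), period="P2")
        # union sets: {a,b} then {b,c}
        assert turnover_counts(m1, m2, island=None) == (1, 1, 1)
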