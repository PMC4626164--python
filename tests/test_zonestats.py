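"""Channel zones, hypergeometric over-representation, Jaccard index."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from periqeeg import (
    ZoneAssignment,
    fraction_in_zone,
    hypergeometric_pmf,
    jaccard_index,
    log_probability,
    overrepresentation_pvalue,
    read_zone_table,
    write_zone_table,
    zone_series,
)
from periqeeg.saliency import SaliencyMask


def _assignment(n, rbt, soz):
    return ZoneAssignment.from_sets(n, rbt, soz)


class TestZoneAssignment:
    def test_derived_zones(self):
        z = _assignment(10, {0, 1, 2}, {2, 3})
        assert z.sizes() == {"RBT": 3, "SOZ": 2, "OVL": 1, "NON": 6}
        assert (z.membership("OVL") <= z.membership("RBT")).all()
        assert (z.membership("OVL") <= z.membership("SOZ")).all()
        union = z.membership("RBT") | z.membership("SOZ")
        assert union.sum() + z.size("NON") == z.n

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _assignment(4, {5}, set())

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ZoneAssignment(("a", "a"), np.array([1, 0]), np.array([0, 1]))

    def test_reorder_and_subset(self):
        z = ZoneAssignment(("a", "b", "c"), np.array([1, 0, 1]), np.array([0, 0, 1]))
        r = z.reorder(("c", "a", "b"))
        assert list(r.in_rbt) == [True, True, False]
        s = r.subset(np.array([True, False, True]))
        assert s.labels == ("c", "b")
        with pytest.raises(ValueError, match="no entry"):
            z.reorder(("a", "zzz"))

    def test_tsv_roundtrip(self, tmp_path):
        z = _assignment(6, {0, 2}, {2, 3})
        path = tmp_path / "zones.tsv"
        write_zone_table(z, path)
        back = read_zone_table(path)
        assert np.array_equal(back.in_rbt, z.in_rbt)
        assert np.array_equal(back.in_soz, z.in_soz)

    def test_non_binary_flags_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("channel_label\tin_rbt\tin_soz\nA\t2\t0\n")
        with pytest.raises(ValueError, match="0/1"):
            read_zone_table(path)


class TestFraction:
    def test_half(self):
        assert fraction_in_zone(4, 2) == 0.5

    def test_undefined_without_salient_channels(self):
        assert math.isnan(fraction_in_zone(0, 0))

    def test_all_inside(self):
        assert fraction_in_zone(5, 5) == 1.0

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fraction_in_zone(2, 3)


class TestHypergeometric:
    def test_pmf_example(self):
        # 4 salient of 10 channels, zone of 5: P(exactly 2 inside) = 10*10/210
        assert hypergeometric_pmf(10, 5, 4, 2) == pytest.approx(100 / 210, abs=1e-12)

    def test_pmf_sums_to_one(self):
        for n in (5, 12, 30):
            for n_z in range(n + 1):
                for n_x in range(n + 1):
                    total = sum(
                        hypergeometric_pmf(n, n_z, n_x, v) for v in range(n_x + 1)
                    )
                    assert total == pytest.approx(1.0, abs=1e-12)

    def test_outside_support_is_zero(self):
        assert hypergeometric_pmf(10, 5, 4, 5) == 0.0
        assert hypergeometric_pmf(10, 8, 7, 2) == 0.0  # below nu_min = 5

    def test_tail_example(self):
        assert overrepresentation_pvalue(10, 5, 4, 4) == pytest.approx(5 / 210, abs=1e-12)

    def test_tail_at_nu_min_is_one(self):
        assert overrepresentation_pvalue(10, 5, 4, 0) == 1.0
        assert overrepresentation_pvalue(10, 8, 7, 5) == 1.0  # nu_min = 5

    def test_tail_monotone_in_m(self):
        p = [overrepresentation_pvalue(20, 8, 6, m) for m in range(7)]
        assert all(a >= b for a, b in zip(p, p[1:]))

    def test_impossible_intersection_rejected(self):
        with pytest.raises(ValueError):
            overrepresentation_pvalue(10, 5, 4, 5)

    def test_enumeration_spot_check(self):
        """Exact enumeration of 4-subsets of 10 elements (full grid in acceptance suite)."""
        n, n_z, n_x = 10, 5, 4
        zone = set(range(n_z))
        hits = {m: 0 for m in range(n_x + 1)}
        total = 0
        for subset in combinations(range(n), n_x):
            hits[len(zone & set(subset))] += 1
            total += 1
        for m in range(n_x + 1):
            tail = sum(hits[v] for v in range(m, n_x + 1)) / total
            assert overrepresentation_pvalue(n, n_z, n_x, m) == pytest.approx(tail, abs=1e-12)


class TestLogProbability:
    def test_significance_threshold(self):
        assert log_probability(0.05) == pytest.approx(1.30103, abs=1e-5)

    def test_p_one_is_zero(self):
        assert log_probability(1.0) == 0.0

    def test_nine_decades(self):
        assert log_probability(1e-9) == pytest.approx(9.0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            log_probability(0.0)
        with pytest.raises(ValueError):
            log_probability(1.5)


class TestJaccard:
    def test_worked_example(self):
        """13 resected, 11 onset-zone, 9 shared of 64 channels: union 15, J = 0.6."""
        rbt = set(range(13))
        soz = set(range(4, 15))
        z = _assignment(64, rbt, soz)
        assert z.size("OVL") == 9
        assert (z.membership("RBT") | z.membership("SOZ")).sum() == 15
        assert jaccard_index(z) == pytest.approx(0.6)

    def test_disjoint_sets(self):
        assert jaccard_index(_assignment(10, {0, 1}, {5, 6})) == 0.0

    def test_identical_sets(self):
        assert jaccard_index(_assignment(10, {0, 1, 2}, {0, 1, 2})) == 1.0

    def test_empty_union_undefined(self):
        assert math.isnan(jaccard_index(_assignment(10, set(), set())))


def _mask(mask_matrix, fs=1.0):
    mask_matrix = np.asarray(mask_matrix, dtype=bool)
    return SaliencyMask(
        mask=mask_matrix, times_s=np.arange(mask_matrix.shape[1], dtype=float)
    )


class TestZoneSeries:
    def test_all_salient_inside_zone(self):
        n, n_z = 60, 5
        z = _assignment(n, set(range(n_z)), set())
        m = np.zeros((n, 1), dtype=bool)
        m[:n_z, 0] = True
        df = zone_series(_mask(m), z)
        row = df[(df.zone == "RBT") & (df.step == 0)].iloc[0]
        assert row.F == 1.0
        assert row.L == pytest.approx(np.log10(math.comb(60, 5)), abs=1e-9)

    def test_empty_step_is_missing(self):
        z = _assignment(12, {0, 1}, {1, 2})
        df = zone_series(_mask(np.zeros((12, 3))), z)
        assert df.F.isna().all()
        assert df.L.isna().all()
        assert (df.P == 1.0).all()

    def test_partition_counts_sum_to_n_x(self, rng):
        z = _assignment(20, set(range(6)), set(range(4, 10)))
        m = rng.random((20, 40)) < 0.2
        df = zone_series(_mask(m), z)
        piv = df.pivot(index="step", columns="zone", values="n_intersect")
        n_x = df[df.zone == "RBT"].set_index("step")["n_X"]
        # RBT\OVL + OVL + SOZ\OVL + NON partitions the salient set
        disjoint = (piv["RBT"] - piv["OVL"]) + piv["OVL"] + (piv["SOZ"] - piv["OVL"]) + piv["NON"]
        assert (disjoint == n_x).all()

    def test_channel_mismatch_rejected(self):
        z = _assignment(5, {0}, {1})
        with pytest.raises(ValueError, match="channels"):
            zone_series(_mask(np.zeros((6, 2))), z)

    def test_l_finite_whenever_salient_exists(self, rng):
        z = _assignment(16, set(range(4)), set(range(2, 6)))
        m = rng.random((16, 100)) < 0.15
        df = zone_series(_mask(m), z)
        defined = df[df.n_X > 0]
        assert np.isfinite(defined.L).all()
        assert (defined.P > 0).all() and (defined.P <= 1).all()


def test_long_format_output_schema():
    z = _assignment(8, {0, 1}, {1, 2})
    df = zone_series(_mask(np.zeros((8, 2))), z)
    assert list(df.columns) == [
        "zone", "step", "time_s", "n", "n_Z", "n_X", "n_intersect", "F", "P", "L",
    ]
    assert sorted(df.zone.unique()) == ["NON", "OVL", "RBT", "SOZ"]
    assert isinstance(df, pd.DataFrame)
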