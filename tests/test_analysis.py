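import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strandflow.analysis import (
    ORDER_BINS,
    assign_orders,
    classify_cells,
    distance_to_order_map,
    division_frequency,
    fraction_by_order,
    invasive_index,
    order_band_edges,
    order_bin,
    predict_order,
    profile_by_order,
    relative_percentage,
    approach_speed,
    slope_classification,
    speed_summary,
)
from strandflow.synthesizer import sample_strands


def _flags(n, **cols):
    base = {"EdU": "-", "Ki67": "-", "H3S10p": "-", "CB1": "-"}
    df = pd.DataFrame([dict(base) for _ in range(n)])
    for k, v in cols.items():
        df[k] = v
    return df


class TestAssignOrders:
    def test_simple_sort(self):
        assert list(assign_orders([40, 5, 20])) == [3, 1, 2]

    def test_ties_keep_input_sequence(self):
        assert list(assign_orders([10.0, 10.0, 5.0])) == [2, 3, 1]

    def test_empty(self):
        assert assign_orders([]).size == 0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_orders([-1.0, 3.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1000), min_size=1, max_size=30))
    def test_is_a_permutation_ranking(self, dists):
        orders = assign_orders(dists)
        assert sorted(orders) == list(range(1, len(dists) + 1))
        assert np.all(np.array(dists)[np.argsort(orders)]
                      == np.sort(dists))

    def test_bins(self):
        assert [order_bin(r) for r in (1, 4, 5, 8, 9)] == \
            ["1", "4", "5-8", "5-8", None]


class TestFractionByOrder:
    def test_leader_s_fraction(self):
        # ten order-1 cells across ten strands, three EdU+
        df = _flags(10, EdU=["+"] * 3 + ["-"] * 7)
        df["strand_id"] = range(10)
        df["x_um"] = 10.0
        tab = fraction_by_order(df, "S")
        assert tab.loc[tab.order == "1", "fraction"].item() == \
            pytest.approx(0.30)
        assert tab.loc[tab.order == "1", "total"].item() == 10

    def test_ninth_cell_excluded(self):
        df = _flags(9, EdU="+")
        df["strand_id"] = 0
        df["x_um"] = np.arange(9) * 10.0
        tab = fraction_by_order(df, "S")
        assert tab["total"].sum() == 8

    def test_undetermined_excluded_everywhere(self):
        df = _flags(4, EdU=["+", "undetermined", "-", "undetermined"])
        df["strand_id"] = range(4)
        df["x_um"] = 5.0
        tab = fraction_by_order(df, "S")
        row = tab[tab.order == "1"]
        assert row["total"].item() == 2 and row["positive"].item() == 1

    def test_all_undetermined_flagged(self):
        df = _flags(3, EdU="undetermined")
        df["strand_id"] = range(3)
        df["x_um"] = 5.0
        tab = fraction_by_order(df, "S")
        assert tab["undefined"].all()
        assert tab["fraction"].isna().all()

    def test_derived_g2_classes(self):
        df = _flags(4, CB1=["+", "+", "+", "-"],
                    H3S10p=["-", "-", "+", "-"],
                    EdU=["+", "-", "-", "+"])
        df["strand_id"] = range(4)
        df["x_um"] = 5.0
        assert list(classify_cells(df, "G2")) == [1, 1, 0, 0]
        assert list(classify_cells(df, "early G2")) == [1, 0, 0, 0]
        assert list(classify_cells(df, "late G2")) == [0, 1, 0, 0]


class TestRelativePercentage:
    def test_ratio_arithmetic(self):
        df = _flags(20, Ki67="+", EdU=["+"] * 5 + ["-"] * 15)
        df["strand_id"] = range(20)
        df["x_um"] = 5.0
        rel = relative_percentage(df, "S", "proliferating")
        assert rel.loc[rel.order == "1", "ratio"].item() == pytest.approx(0.25)

    def test_identity(self):
        df = _flags(12, Ki67="+")
        df["strand_id"] = range(12)
        df["x_um"] = 5.0
        rel = relative_percentage(df, "proliferating", "proliferating")
        assert (rel["ratio"].dropna() == 1.0).all()

    def test_zero_reference_flagged(self):
        df = _flags(3, EdU="+")
        df["strand_id"] = range(3)
        df["x_um"] = 5.0
        rel = relative_percentage(df, "S", "proliferating")
        assert rel.loc[rel.order == "1", "undefined"].item()
        assert np.isnan(rel.loc[rel.order == "1", "ratio"].item())


class TestDistanceOrderBridge:
    def test_nearest_mean_and_tie_rule(self):
        omap = pd.DataFrame({"order": [1, 2], "mean_um": [10.0, 30.0],
                             "se_um": [1.0, 1.0], "n": [5, 5]})
        assert predict_order(12.0, omap) == 1
        assert predict_order(20.0, omap) == 1     # midpoint goes tipward
        assert predict_order(20.1, omap) == 2
        assert predict_order(500.0, omap) == 2    # clamp to last order

    def test_map_from_snapshots(self):
        rows = []
        for sid in range(40):
            for k in range(9):
                rows.append({"strand_id": sid, "x_um": 15.0 * k + 7.5})
        omap = distance_to_order_map(pd.DataFrame(rows))
        assert len(omap) == 8
        assert np.allclose(omap["mean_um"], 7.5 + 15.0 * np.arange(8))
        edges = order_band_edges(omap)
        assert np.allclose(edges, [0, 15, 30, 45, 60, 120])

    def test_non_monotone_means_warn(self):
        df = pd.DataFrame({"strand_id": [0, 0, 1],
                           "x_um": [10.0, 100.0, 200.0]})
        with pytest.warns(UserWarning, match="not monotone"):
            distance_to_order_map(df)

    def test_profile_by_order(self):
        x = np.linspace(0.0, 100.0, 101)
        edges = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])
        prof = profile_by_order(x.copy(), x, edges)
        assert np.allclose(prof, [9.5, 29.5, 49.5, 69.5, 89.5])


class TestDivisionFrequency:
    def test_arithmetic(self):
        ev = pd.DataFrame({"x_um": [10.0, 20.0, 30.0]})
        out = division_frequency(ev, [0.0, 50.0], total_duration=1200.0)
        assert out["frequency_per_um_min"].item() == pytest.approx(5.0e-5)

    def test_zero_events(self):
        ev = pd.DataFrame({"x_um": []})
        out = division_frequency(ev, [0.0, 50.0, 100.0], 100.0)
        assert (out["frequency_per_um_min"] == 0).all()

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        ev = pd.DataFrame({"x_um": rng.uniform(0, 100, 257)})
        out = division_frequency(ev, np.linspace(0, 100, 11), 60.0)
        assert out["count"].sum() == 257
        # integrating frequency over bins x duration returns the count
        integral = (out["frequency_per_um_min"]
                    * (out["x_hi"] - out["x_lo"]) * 60.0).sum()
        assert integral == pytest.approx(257)

    def test_bad_bins_rejected(self):
        ev = pd.DataFrame({"x_um": [10.0]})
        with pytest.raises(ValueError):
            division_frequency(ev, [0.0, 0.0, 50.0], 10.0)
        with pytest.raises(ValueError):
            division_frequency(ev, [20.0, 50.0], 10.0)

    def test_tip_exclusion(self):
        ev = pd.DataFrame({"x_um": [5.0, 15.0, 25.0]})
        out = division_frequency(ev, [0.0, 10.0, 20.0, 30.0], 10.0,
                                 normalize=True, tip_exclusion=10.0)
        assert out["excluded"].tolist() == [True, False, False]
        included = out.loc[~out["excluded"], "frequency_per_um_min"]
        assert out.loc[1, "normalized"] == pytest.approx(
            out.loc[1, "frequency_per_um_min"] / included.mean())


class TestApproachSpeed:
    def test_interval_speed(self):
        tr = pd.DataFrame({"id": [1, 1], "time_min": [0.0, 20.0],
                           "x_um": [50.0, 45.0]})
        out = approach_speed(tr)
        assert out["speed_um_min"].item() == pytest.approx(0.25)

    def test_stationary_and_single_point(self):
        tr = pd.DataFrame({"id": [1, 1, 2], "time_min": [0.0, 10.0, 0.0],
                           "x_um": [30.0, 30.0, 12.0]})
        out = approach_speed(tr)
        assert len(out) == 1                     # track 2 skipped
        assert out["speed_um_min"].item() == 0.0

    def test_summary_by_distance(self):
        rng = np.random.default_rng(1)
        n = 500
        tr = pd.DataFrame({
            "id": np.repeat(np.arange(n), 2),
            "time_min": np.tile([0.0, 20.0], n),
            "x_um": np.repeat(rng.uniform(0, 100, n), 2)
            + np.tile([0.0, -1.0], n),
            "phase": np.repeat(
                rng.choice(["G2", "G1"], n), 2),
        })
        sp = approach_speed(tr)
        out = speed_summary(sp, by="x_um", bins=[0, 50, 100],
                            per_phase=True)
        assert np.allclose(out["speed_mean"], 0.05)
        assert set(out["phase"]) == {"G1", "G2"}


class TestInvasiveIndex:
    @pytest.mark.parametrize("a0, at, expected",
                             [(1.0, 2.0, 1.0), (3.0, 3.0, 0.0),
                              (2.0, 1.0, -0.5)])
    def test_values(self, a0, at, expected):
        assert invasive_index(a0, at) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            invasive_index(0.0, 1.0)


class TestSlopeClassification:
    def test_front(self):
        lab, slope, _ = slope_classification([0.3, 0.2, 0.15, 0.12, 0.1])
        assert lab == "front-concentrated" and slope < 0

    def test_flat(self):
        lab, slope, _ = slope_classification([0.2] * 5)
        assert lab == "flat" and slope == 0

    def test_rear(self):
        lab, slope, _ = slope_classification([0.1, 0.15, 0.2, 0.25, 0.3])
        assert lab == "rear-concentrated" and slope > 0

    def test_se_flat_band_with_counts(self):
        # noisy but trendless: the count-weighted fit calls it flat
        y = [0.30, 0.31, 0.29, 0.31, 0.30]
        lab, _, se = slope_classification(y, weights=[100] * 5)
        assert lab == "flat" and se > 0

    def test_requires_three_bins(self):
        with pytest.raises(ValueError):
            slope_classification([0.1, np.nan, np.nan, 0.2, np.nan])


def test_end_to_end_order_recovery(stationary_full, spheroid,
                                   spheroid_grid):
    """Snapshots sampled from the continuum steady state, pushed through
    the order pipeline, reproduce the continuum per-order S fractions
    within Monte-Carlo error, and S is rear-concentrated."""
    solver, fld, age = stationary_full
    snap = sample_strands(fld, age, spheroid_grid, spheroid,
                          n_strands=500, seed=11)
    omap = distance_to_order_map(snap)
    edges = order_band_edges(omap)
    x = spheroid_grid.x_nodes

    # true-phase recovery
    snap_true = snap.copy()
    snap_true["S_true"] = np.where(snap["phase"] == "S", "+", "-")
    tab_true = fraction_by_order(snap_true, "S_true")
    expected = profile_by_order(fld.phase("S"), x, edges)
    for k in range(5):
        se = np.sqrt(expected[k] * (1 - expected[k]) / tab_true["total"][k])
        assert abs(tab_true["fraction"][k] - expected[k]) < 3 * se

    # the EdU readout of "S" additionally captures G2 cells younger than
    # the incubation window
    tab = fraction_by_order(snap, "S")
    early, _ = solver.early_late_split(age, spheroid.tau0)
    expected_edu = expected + profile_by_order(early, x, edges)
    for k in range(5):
        se = np.sqrt(expected_edu[k] * (1 - expected_edu[k])
                     / tab["total"][k])
        assert abs(tab["fraction"][k] - expected_edu[k]) < 3 * se

    lab, _, _ = slope_classification(tab["fraction"].to_numpy(),
                                     weights=tab["total"].to_numpy())
    assert lab == "rear-concentrated"


def test_g2_to_s_ratio_front_enriched(stationary_full, spheroid,
                                      spheroid_grid):
    """Under tip-ward G2 drift the G2/S ratio is larger at the leader
    than in the pooled follower bin."""
    _, fld, age = stationary_full
    snap = sample_strands(fld, age, spheroid_grid, spheroid,
                          n_strands=500, seed=12)
    rel = relative_percentage(snap, "G2", "S")
    assert rel["ratio"].iloc[0] > rel["ratio"].iloc[4]
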