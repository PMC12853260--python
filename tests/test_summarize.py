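"""Region-level increase/decrease summaries, relative changes, hemisphere
means, degree centralities and seed-channel views, checked against
hand-computed values on toy channel-level changes."""

import numpy as np
import pandas as pd
import pytest

from nirsgc import summarize
from nirsgc.datasets import ChannelMap
from nirsgc.gc import GCTensor
from nirsgc.summarize import (
    STANDARD_WINDOWS,
    WHOLE_WINDOW,
    DeltaGC,
    channel_increase_matrix,
    degree_centrality,
    delta_gc,
    hemisphere_means,
    region_change_integrated,
    region_change_timeresolved,
    region_summary_table,
    relative_change,
    seed_channel_view,
    window_indices,
)


def make_delta(diff, times=None, hand=None):
    diff = np.asarray(diff, dtype=float)
    n = diff.shape[0]
    for i in range(n):
        diff[i, i, :] = np.nan
    if times is None:
        times = np.arange(diff.shape[2], dtype=float)
    return DeltaGC(diff=diff, times=np.asarray(times, dtype=float), hand=hand)


@pytest.fixture
def toy_map():
    return ChannelMap.from_assignments(
        rois={"A": [0], "B": [1, 2]},
        hemispheres={"A": "ip", "B": "ip"},
        n_channels=3,
    )


def toy_tensor(values, times):
    gc = np.asarray(values, dtype=float)
    for i in range(gc.shape[0]):
        gc[i, i, :] = np.nan
    return GCTensor(gc=gc, times=np.asarray(times, dtype=float))


class TestDeltaGC:
    def test_identical_tensors_zero(self):
        vals = np.random.default_rng(0).random((3, 3, 4))
        a = toy_tensor(vals.copy(), np.arange(4))
        d = delta_gc(a, toy_tensor(vals.copy(), np.arange(4)))
        assert np.nanmax(np.abs(d.diff)) == 0

    def test_single_pair_offset(self):
        vals = np.zeros((3, 3, 4))
        post = vals.copy()
        post[0, 1, :] += 0.1
        d = delta_gc(toy_tensor(vals, np.arange(4)), toy_tensor(post, np.arange(4)))
        assert np.allclose(d.diff[0, 1], 0.1)
        off = ~np.eye(3, dtype=bool)
        other = d.diff[off]
        assert np.nansum(np.abs(other)) == pytest.approx(0.4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a = toy_tensor(rng.random((3, 3, 4)), np.arange(4))
        b = toy_tensor(rng.random((3, 3, 4)), np.arange(4))
        d_ab = delta_gc(a, b)
        d_ba = delta_gc(b, a)
        np.testing.assert_allclose(d_ab.diff, -d_ba.diff)

    def test_axis_mismatch_rejected(self):
        a = toy_tensor(np.zeros((3, 3, 4)), np.arange(4))
        b = toy_tensor(np.zeros((3, 3, 5)), np.arange(5))
        with pytest.raises(ValueError):
            delta_gc(a, b)


class TestTimeResolved:
    def test_mixed_signs(self, toy_map):
        # pairs A->B are (0,1) and (0,2): diffs {+0.3, -0.1}
        diff = np.zeros((3, 3, 1))
        diff[0, 1, 0] = 0.3
        diff[0, 2, 0] = -0.1
        inc, dec = region_change_timeresolved(make_delta(diff), toy_map, "A", "B", t=0)
        assert (inc, dec) == (0.3, -0.1)

    def test_all_negative_clips_increase_to_zero(self, toy_map):
        diff = np.zeros((3, 3, 1))
        diff[0, 1, 0] = -0.2
        diff[0, 2, 0] = -0.05
        inc, dec = region_change_timeresolved(make_delta(diff), toy_map, "A", "B", t=0)
        assert (inc, dec) == (0.0, -0.2)

    def test_single_channel_rois(self):
        cmap = ChannelMap.from_assignments(
            rois={"A": [0], "B": [1]}, hemispheres={"A": "ip", "B": "ip"}, n_channels=2
        )
        diff = np.zeros((2, 2, 1))
        diff[0, 1, 0] = 0.07
        inc, dec = region_change_timeresolved(make_delta(diff), cmap, "A", "B", t=0)
        assert (inc, dec) == (0.07, 0.0)

    def test_same_roi_rejected(self, toy_map):
        with pytest.raises(ValueError):
            region_change_timeresolved(make_delta(np.zeros((3, 3, 1))), toy_map, "A", "A")

    def test_empty_roi_rejected(self, toy_map):
        with pytest.raises(KeyError):
            toy_map.hemisphere_of("C")
        with pytest.raises(ValueError):
            region_change_timeresolved(make_delta(np.zeros((3, 3, 1))), toy_map, "A", "C")


class TestIntegrated:
    def test_positive_and_negative_sums(self, toy_map):
        # pair (0,1) diffs over time [+0.2, -0.1, +0.3]; pair (0,2) all zero
        diff = np.zeros((3, 3, 3))
        diff[0, 1] = [0.2, -0.1, 0.3]
        d = make_delta(diff, times=[0.0, 1.0, 2.0])
        inc, dec = region_change_integrated(d, toy_map, "A", "B", (0.0, 3.0))
        assert inc == pytest.approx(0.5)
        assert dec == pytest.approx(-0.1)

    def test_all_zero(self, toy_map):
        d = make_delta(np.zeros((3, 3, 3)))
        assert region_change_integrated(d, toy_map, "A", "B", (0.0, 3.0)) == (0.0, 0.0)

    def test_standard_windows_half_overlap(self):
        times = (np.arange(93) - 15) * 0.13  # [-1.95, 10.0] s
        idx = [set(window_indices(times, w)) for w in STANDARD_WINDOWS]
        for (lo, _), a, b in zip([w for w in STANDARD_WINDOWS[1:]], idx[:-1], idx[1:]):
            # consecutive 4 s windows share exactly the 2 s half-window [lo, lo+2)
            assert a & b == set(window_indices(times, (lo, lo + 2.0)))
        whole = set(window_indices(times, WHOLE_WINDOW))
        assert set().union(*idx) == whole

    def test_window_outside_axis_rejected(self, toy_map):
        d = make_delta(np.zeros((3, 3, 3)), times=[0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            region_change_integrated(d, toy_map, "A", "B", (50.0, 60.0))

    def test_whole_window_equals_union_of_standard_windows(self, toy_map):
        rng = np.random.default_rng(2)
        times = (np.arange(93) - 15) * 0.13
        d = make_delta(rng.standard_normal((3, 3, 93)) * 0.1, times=times)
        whole = region_change_integrated(d, toy_map, "A", "B", WHOLE_WINDOW)
        union_idx = sorted(
            set().union(*(set(window_indices(d.times, w)) for w in STANDARD_WINDOWS))
        )
        diffs = d.diff[0, [1, 2]][:, union_idx]
        pos = np.nansum(np.maximum(diffs, 0), axis=1).max()
        neg = np.nansum(np.minimum(diffs, 0), axis=1).min()
        assert whole == (pytest.approx(pos), pytest.approx(neg))

    def test_monotone_in_roi_size(self):
        # enlarging a ROI can only keep dGC+ equal/larger and dGC- equal/smaller
        rng = np.random.default_rng(3)
        diff = rng.standard_normal((4, 4, 5)) * 0.2
        d = make_delta(diff)
        small = ChannelMap.from_assignments(
            rois={"A": [0], "B": [2]}, hemispheres={"A": "ip", "B": "ip"}, n_channels=4
        )
        big = ChannelMap.from_assignments(
            rois={"A": [0, 1], "B": [2, 3]}, hemispheres={"A": "ip", "B": "ip"},
            n_channels=4,
        )
        win = (0.0, 5.0)
        inc_s, dec_s = region_change_integrated(d, small, "A", "B", win)
        inc_b, dec_b = region_change_integrated(d, big, "A", "B", win)
        assert inc_b >= inc_s and dec_b <= dec_s


class TestRelativeChange:
    def _summary(self, inc, dec):
        return pd.DataFrame(
            {
                "source_roi": ["A"],
                "target_roi": ["B"],
                "window": ["[-2,10)"],
                "increase": [inc],
                "decrease": [dec],
            }
        )

    def test_increase_difference(self):
        out = relative_change(self._summary(0.4, 0.0), self._summary(0.1, 0.0))
        assert out["rel_increase"].iloc[0] == pytest.approx(0.3)

    def test_decrease_sign_convention(self):
        # |aff -0.2| - |unaff -0.5| = -0.3: more pronounced for unaffected
        out = relative_change(self._summary(0.0, -0.2), self._summary(0.0, -0.5))
        assert out["rel_decrease"].iloc[0] == pytest.approx(-0.3)

    def test_identical_summaries_zero(self):
        out = relative_change(self._summary(0.2, -0.1), self._summary(0.2, -0.1))
        assert out["rel_increase"].iloc[0] == 0.0
        assert out["rel_decrease"].iloc[0] == 0.0

    def test_mismatched_pairs_rejected(self):
        other = self._summary(0.1, 0.0)
        other["target_roi"] = ["C"]
        with pytest.raises(ValueError):
            relative_change(self._summary(0.1, 0.0), other)


class TestHemisphereMeans:
    @pytest.fixture
    def hemi_map(self):
        return ChannelMap.from_assignments(
            rois={"ip-M1": [0], "ip-PMv": [1], "co-M1": [2], "SMA": [3]},
            hemispheres={"ip-M1": "ip", "ip-PMv": "ip", "co-M1": "co", "SMA": "medial"},
            n_channels=4,
        )

    def _summary(self, rows):
        return pd.DataFrame(
            rows, columns=["source_roi", "target_roi", "increase", "decrease"]
        )

    def test_uniform_significant_entries(self, hemi_map):
        rows = [
            ["ip-M1", "ip-PMv", 0.5, -0.1],
            ["ip-PMv", "ip-M1", 0.5, -0.1],
        ]
        out = hemisphere_means(self._summary(rows), hemi_map).set_index("group")
        assert out.loc["ip-ip", "mean_increase"] == pytest.approx(0.5)
        assert out.loc["ip-ip", "mean_decrease"] == pytest.approx(-0.1)

    def test_no_significant_entries_all_zero(self, hemi_map):
        rows = [["ip-M1", "ip-PMv", 0.5, -0.1]]
        sig = pd.DataFrame(
            {
                "source_roi": ["ip-M1"],
                "target_roi": ["ip-PMv"],
                "sig_increase": [False],
                "sig_decrease": [False],
            }
        )
        out = hemisphere_means(self._summary(rows), hemi_map, significant=sig)
        assert (out["mean_increase"] == 0).all()
        assert (out["mean_decrease"] == 0).all()

    def test_nonsignificant_counts_as_zero_in_mean(self, hemi_map):
        rows = [
            ["ip-M1", "ip-PMv", 0.4, 0.0],
            ["ip-PMv", "ip-M1", 0.2, 0.0],
        ]
        sig = pd.DataFrame(
            {
                "source_roi": ["ip-M1", "ip-PMv"],
                "target_roi": ["ip-PMv", "ip-M1"],
                "sig_increase": [True, False],
                "sig_decrease": [True, True],
            }
        )
        out = hemisphere_means(self._summary(rows), hemi_map, significant=sig)
        assert out.set_index("group").loc["ip-ip", "mean_increase"] == pytest.approx(0.2)

    def test_medial_roi_counts_in_both_hemispheres(self, hemi_map):
        rows = [
            ["SMA", "ip-M1", 0.3, 0.0],
            ["SMA", "co-M1", 0.7, 0.0],
        ]
        out = hemisphere_means(self._summary(rows), hemi_map).set_index("group")
        assert out.loc["ip-ip", "mean_increase"] == pytest.approx(0.3)
        assert out.loc["co-co", "mean_increase"] == pytest.approx(0.7)
        assert out.loc["ip-co", "n_pairs"] == 0

    def test_cross_hemisphere_pairs_pool_directions(self, hemi_map):
        rows = [
            ["ip-M1", "co-M1", 0.2, 0.0],
            ["co-M1", "ip-M1", 0.4, 0.0],
        ]
        out = hemisphere_means(self._summary(rows), hemi_map).set_index("group")
        assert out.loc["ip-co", "mean_increase"] == pytest.approx(0.3)


class TestDegreeCentrality:
    def test_single_edge(self):
        mat = np.zeros((3, 3))
        mat[0, 1] = 2.0
        out = degree_centrality(mat).set_index("node")
        assert out.loc[0, "out_degree"] == 2.0
        assert out.loc[1, "in_degree"] == 2.0
        assert out.loc[2, "total"] == 0.0

    def test_symmetric_pair(self):
        mat = np.zeros((2, 2))
        mat[0, 1] = mat[1, 0] = 1.5
        out = degree_centrality(mat)
        assert (out["total"] == 3.0).all()

    def test_three_node_sums_by_hand(self):
        # edges a->b:1, b->c:2, a->c:3 -> out(a)=4, in(c)=5
        edges = pd.DataFrame(
            {"source": [0, 1, 0], "target": [1, 2, 2], "weight": [1.0, 2.0, 3.0]}
        )
        out = degree_centrality(edges).set_index("node")
        assert out.loc[0, "out_degree"] == 4.0
        assert out.loc[2, "in_degree"] == 5.0

    def test_negative_weight_rejected(self):
        mat = np.zeros((2, 2))
        mat[0, 1] = -1.0
        with pytest.raises(ValueError):
            degree_centrality(mat)


class TestSeedChannelView:
    @pytest.fixture
    def seed_map(self):
        return ChannelMap.from_assignments(
            rois={"PMv": [0, 1], "M1": [2]},
            hemispheres={"PMv": "ip", "M1": "ip"},
            n_channels=3,
            seeds=[0, 1],
        )

    def test_degenerate_single_seed_matches_region_result(self):
        cmap = ChannelMap.from_assignments(
            rois={"PMv": [0], "M1": [1, 2]},
            hemispheres={"PMv": "ip", "M1": "ip"},
            n_channels=3,
            seeds=[0],
        )
        rng = np.random.default_rng(4)
        d = make_delta(rng.standard_normal((3, 3, 6)) * 0.1, times=np.arange(6.0))
        win = (0.0, 6.0)
        view = seed_channel_view(d, cmap, [0], win).set_index(["source", "target"])
        inc, _ = region_change_integrated(d, cmap, "PMv", "M1", win)
        assert view.loc[("PMv:ch0", "M1"), "increase"] == pytest.approx(inc)

    def test_per_seed_inflows_not_pooled(self, seed_map):
        diff = np.zeros((3, 3, 2))
        diff[2, 0] = [0.4, 0.0]   # M1 -> seed 0
        diff[2, 1] = [0.0, 0.1]   # M1 -> seed 1
        d = make_delta(diff, times=[0.0, 1.0])
        view = seed_channel_view(d, seed_map, [0, 1], (0.0, 2.0))
        idx = view.set_index(["source", "target"])["increase"]
        assert idx[("M1", "PMv:ch0")] == pytest.approx(0.4)
        assert idx[("M1", "PMv:ch1")] == pytest.approx(0.1)

    def test_all_negative_diffs_give_zero_increases(self, seed_map):
        d = make_delta(-0.2 * np.ones((3, 3, 2)), times=[0.0, 1.0])
        view = seed_channel_view(d, seed_map, [0, 1], (0.0, 2.0))
        assert (view["increase"] == 0).all()

    def test_seeds_across_rois_rejected(self):
        cmap = ChannelMap.from_assignments(
            rois={"PMv": [0], "M1": [1]},
            hemispheres={"PMv": "ip", "M1": "ip"},
            n_channels=2,
        )
        d = make_delta(np.zeros((2, 2, 1)))
        with pytest.raises(ValueError):
            seed_channel_view(d, cmap, [0, 1], (0.0, 1.0))


class TestChannelIncreaseMatrix:
    def test_unassigned_channels_excluded(self):
        cmap = ChannelMap.from_assignments(
            rois={"A": [0], "B": [1]}, hemispheres={"A": "ip", "B": "ip"}, n_channels=3
        )
        diff = np.full((3, 3, 2), 0.2)
        d = make_delta(diff, times=[0.0, 1.0])
        mat = channel_increase_matrix(d, cmap, (0.0, 2.0))
        assert mat[0, 1] == pytest.approx(0.4)
        assert mat[0, 2] == 0.0 and mat[2, 1] == 0.0
        assert np.all(np.diag(mat) == 0)


def test_region_summary_table_covers_all_pairs_and_windows(toy_map):
    rng = np.random.default_rng(5)
    times = (np.arange(93) - 15) * 0.13
    d = make_delta(rng.standard_normal((3, 3, 93)) * 0.1, times=times, hand="affected")
    table = region_summary_table(d, toy_map)
    assert len(table) == 2 * 6  # 2 ordered ROI pairs x (whole + 5 windows)
    assert (table["increase"] >= 0).all()
    assert (table["decrease"] <= 0).all()


def test_edges_to_dot_renders_weights():
    edges = pd.DataFrame(
        {"source": ["A"], "target": ["B"], "increase": [0.25]}
    )
    dot = summarize.edges_to_dot(edges)
    assert '"A" -> "B"' in dot and "0.25" in dot
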