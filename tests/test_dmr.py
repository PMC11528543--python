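"""DMW testing, BH adjustment and DMR merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import nomepipe as nm

from conftest import make_sites


def bh_oracle(pvals):
    """Independent step-up BH: sort, scale by m/rank, enforce monotonicity."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestBH:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),  # hand step-up
            ([0.04], [0.04]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            # hand-computed length-5 case
            ([0.01, 0.04, 0.03, 0.005, 0.5], [0.025, 0.05, 0.05, 0.025, 0.5]),
        ],
    )
    def test_matches_hand_computation(self, pvals, expected):
        np.testing.assert_allclose(nm.bh_fdr(pvals), expected)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    def test_matches_oracle_and_bounds(self, pvals):
        q = nm.bh_fdr(pvals)
        np.testing.assert_allclose(q, bh_oracle(pvals), atol=1e-12)
        assert np.all(q >= np.asarray(pvals) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone over ranks

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nm.bh_fdr([0.5, 1.5])


class TestWindowTest:
    def test_identical_groups_non_significant(self):
        delta, p = nm.test_window([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert delta == 0.0 and p == 1.0

    def test_hand_computed_t_statistic(self):
        # means 0.9 vs 0.5, each sample variance 4e-4, pooled SE
        # sqrt(4e-4 * 2/3): t = 0.4/0.0163299 = 24.4949, df = 4
        g1, g2 = [0.9, 0.92, 0.88], [0.5, 0.52, 0.48]
        delta, p = nm.test_window(g1, g2)
        t_hand = 0.4 / np.sqrt(4e-4 * (2 / 3))
        assert t_hand == pytest.approx(24.4949, abs=1e-4)
        assert delta == pytest.approx(0.4)
        assert p == pytest.approx(2 * stats.t.sf(t_hand, df=4), rel=1e-10)

    def test_group_swap_negates_delta_keeps_p(self):
        g1, g2 = [0.9, 0.8, 0.85], [0.5, 0.55, 0.6]
        d12, p12 = nm.test_window(g1, g2)
        d21, p21 = nm.test_window(g2, g1)
        assert d12 == pytest.approx(-d21)
        assert p12 == pytest.approx(p21)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            nm.test_window([0.5], [0.4, 0.6])

    def test_vectorised_path_matches_scalar(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame({"chrom": "c", "start": range(0, 3000, 300)})
        values["end"] = values["start"] + 300
        for s in ["a1", "a2", "a3", "b1", "b2", "b3"]:
            values[s] = rng.uniform(0, 1, size=10)
        tested = nm.test_windows(values, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        for i, row in tested.iterrows():
            d, p = nm.test_window(
                values.loc[i, ["a1", "a2", "a3"]], values.loc[i, ["b1", "b2", "b3"]]
            )
            assert row["delta"] == pytest.approx(d)
            assert row["p"] == pytest.approx(p, rel=1e-9)


class TestWindowValues:
    def test_window_level_and_missingness(self):
        sites = make_sites(
            [("c", p, "+", "WCG", m, 10) for p, m in [(10, 1), (50, 2), (100, 3)]]
            + [("c", 400, "+", "WCG", 5, 10), ("c", 500, "+", "WCG", 5, 10)]
        )
        windows = nm.tile_300bp({"c": 900})
        vals = nm.window_values({"s": sites}, windows)
        assert vals["s"].iloc[0] == pytest.approx(0.2)  # {0.1, 0.2, 0.3}
        assert np.isnan(vals["s"].iloc[1])  # 2 sites only
        assert np.isnan(vals["s"].iloc[2])  # no sites

    def test_tiling_example(self):
        tiles = nm.tile_300bp({"c": 1000})
        assert tiles[["start", "end"]].values.tolist() == [
            [0, 300], [300, 600], [600, 900], [900, 1000]
        ]


class TestDMWGates:
    def _tested(self, delta, p, q):
        return pd.DataFrame(
            {
                "chrom": ["c"], "start": [0], "end": [300],
                "mean_g1": [0.5 + delta / 2], "mean_g2": [0.5 - delta / 2],
                "delta": [delta], "p": [p], "q": [q],
            }
        )

    def test_effect_size_gate_is_strict(self):
        assert len(nm.call_dmws(self._tested(0.19, 1e-6, 1e-5))) == 0
        assert len(nm.call_dmws(self._tested(0.20, 1e-6, 1e-5))) == 0  # not > 0.20
        assert len(nm.call_dmws(self._tested(0.25, 0.04, 0.06))) == 0  # FDR gate
        dmw = nm.call_dmws(self._tested(0.25, 0.01, 0.03))
        assert len(dmw) == 1 and dmw["direction"].item() == "hyper"

    def test_hypo_direction(self):
        dmw = nm.call_dmws(self._tested(-0.25, 0.01, 0.03))
        assert dmw["direction"].item() == "hypo"


def _dmw(chrom, start, end, direction, delta=0.25):
    return {
        "chrom": chrom, "start": start, "end": end,
        "direction": direction, "delta": delta if direction == "hyper" else -delta,
    }


class TestMergeDMRs:
    def test_gap_of_exactly_300_merges(self):
        dmws = pd.DataFrame([_dmw("c", 0, 300, "hyper"), _dmw("c", 600, 900, "hyper")])
        dmrs = nm.merge_dmrs(dmws)
        assert len(dmrs) == 1
        assert (dmrs["start"].item(), dmrs["end"].item()) == (0, 900)
        assert dmrs["n_windows"].item() == 2

    def test_gap_above_300_stays_separate(self):
        dmws = pd.DataFrame([_dmw("c", 0, 300, "hyper"), _dmw("c", 601, 901, "hyper")])
        assert len(nm.merge_dmrs(dmws)) == 2

    def test_opposite_directions_never_merge(self):
        dmws = pd.DataFrame([_dmw("c", 0, 300, "hyper"), _dmw("c", 300, 600, "hypo")])
        dmrs = nm.merge_dmrs(dmws)
        assert len(dmrs) == 2
        assert set(dmrs["direction"]) == {"hyper", "hypo"}

    def test_merge_is_idempotent(self):
        dmws = pd.DataFrame(
            [
                _dmw("c", 0, 300, "hyper"),
                _dmw("c", 300, 600, "hyper"),
                _dmw("c", 1200, 1500, "hypo"),
            ]
        )
        once = nm.merge_dmrs(dmws)
        again = nm.merge_dmrs(
            once.rename(columns={})[["chrom", "start", "end", "direction", "delta"]]
        )
        pd.testing.assert_frame_equal(
            once[["chrom", "start", "end", "direction"]],
            again[["chrom", "start", "end", "direction"]],
        )

    def test_output_disjoint_per_direction(self, small_sim):
        tested, dmrs = nm.call_dmrs(
            small_sim["calls"]["g1"], small_sim["calls"]["g2"], small_sim["chrom_sizes"]
        )
        for direction, grp in dmrs.groupby("direction"):
            grp = grp.sort_values("start")
            assert (grp["start"].values[1:] >= grp["end"].values[:-1]).all()


class TestRecovery:
    def test_planted_dmrs_recovered_with_direction(self, small_sim):
        tested, dmrs = nm.call_dmrs(
            small_sim["calls"]["g1"], small_sim["calls"]["g2"], small_sim["chrom_sizes"]
        )
        truth = small_sim["truth"].dmrs
        sens, prec = nm.match_intervals(dmrs, truth)
        assert sens >= 0.8
        assert prec >= 0.8
        # direction agreement on matched plants
        for t in truth.itertuples(index=False):
            hits = dmrs[(dmrs["start"] < t.end) & (dmrs["end"] > t.start)]
            if len(hits):
                assert set(hits["direction"]) == {t.direction}
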