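"""Integer molecule allocation along the projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from papdiff import (
    DegenerateProfileError,
    DimensionlessProfile,
    InvalidParameterError,
    allocate,
    near_alpha,
    near_beta,
    profile,
    round_half_up,
    table3,
    tau_to_time,
    visible_profile,
)
from papdiff.allocation import TABLE3_CONDITIONS, TABLE3_REFERENCE


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.5, 1), (1.5, 2), (2.4, 2), (40.65, 41), (224.52, 225), (-0.5, -1), (0.0, 0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert round_half_up(value) == expected

    def test_vectorized(self):
        out = round_half_up(np.array([0.49, 0.5, 2.5]))
        assert out.tolist() == [0, 1, 3]


class TestAllocate:
    def test_gradient_arrival_snapshot(self):
        # 333 us with 100 PLC at 5000/s: ~167 molecules, 41 at the source
        # face and 2 at the store face
        t = tau_to_time(0.1)
        mp = allocate(profile(0.1, 11), 100 * 5000 * t, time_s=t)
        assert mp.total == 167
        assert near_alpha(mp) == 41
        assert near_beta(mp) == 2
        assert np.all(np.diff(mp.counts) <= 0)  # counts inherit monotonicity

    def test_near_steady_state_snapshot(self):
        mp = allocate(profile(1.5, 11), 2500.0)
        assert near_beta(mp) == 225

    def test_one_millisecond_snapshot(self):
        mp = allocate(profile(0.3, 11), 500.0)
        assert near_beta(mp) == 29

    def test_zero_total_gives_all_zero(self):
        mp = allocate(profile(0.3, 11), 0.0)
        assert mp.total == 0
        assert np.all(mp.counts == 0)
        assert not mp.is_degenerate

    def test_zero_weight_profile_cannot_distribute(self):
        flat = DimensionlessProfile(0.0, np.linspace(0, 1, 5), np.zeros(5))
        with pytest.raises(DegenerateProfileError):
            allocate(flat, 10.0)
        assert allocate(flat, 0.0).total == 0

    def test_negative_total_rejected(self):
        with pytest.raises(InvalidParameterError):
            allocate(profile(0.3, 11), -1.0)

    def test_conservation_under_rounding(self):
        for tau, n_total in [(0.1, 167), (0.3, 500), (1.5, 2500), (0.005, 8.35)]:
            mp = allocate(profile(tau, 11), n_total)
            assert abs(int(mp.counts.sum()) - mp.total) <= mp.n_points / 2

    def test_largest_remainder_is_exactly_conservative(self):
        for tau, n_total in [(0.1, 167), (0.3, 500.4), (1.5, 2500), (0.8, 1333.33)]:
            mp = allocate(profile(tau, 11), n_total, method="largest_remainder")
            assert int(mp.counts.sum()) == mp.total == round_half_up(n_total)

    def test_scale_equivariance_within_rounding(self):
        prof = profile(0.3, 11)
        small = allocate(prof, 400.0).counts
        big = allocate(prof, 800.0).counts
        assert np.all(np.abs(big - 2 * small) <= 1)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        tau=st.sampled_from([0.005, 0.1, 0.3, 0.8, 1.5]),
        n_total=st.floats(min_value=0.0, max_value=3000.0),
    )
    def test_counts_nonnegative_and_bounded(self, tau, n_total):
        mp = allocate(profile(tau, 11), n_total)
        assert np.all(mp.counts >= 0)
        assert mp.counts.sum() <= round_half_up(n_total) + mp.n_points / 2


class TestVisibility:
    def test_earliest_snapshot_shows_only_two_positions(self):
        # 16.7 us, 100 PLC at 5000/s: 6 molecules at the source, 2 having
        # diffused ~100 nm; everything further is sub-molecular
        t = tau_to_time(0.005)
        mp = allocate(profile(0.005, 11), 100 * 5000 * t, time_s=t)
        vis = visible_profile(mp)
        assert vis.positions_nm.tolist() == [0.0, 100.0]
        assert vis.counts.tolist() == [6, 2]
        assert not vis.is_degenerate

    def test_low_copy_regime_is_flagged_degenerate(self):
        # 1 PLC at 1000/s for 5 ms synthesizes 5 molecules; no position
        # expects even one whole molecule -> continuum profile meaningless
        mp = allocate(profile(1.5, 11), 5.0)
        assert mp.is_degenerate
        vis = visible_profile(mp)
        assert vis.n_points == 0
        assert vis.is_degenerate

    def test_all_zero_profile_is_empty_but_not_degenerate(self):
        vis = visible_profile(allocate(profile(0.3, 11), 0.0))
        assert vis.n_points == 0
        assert not vis.is_degenerate


class TestTable3:
    def test_consistent_reference_rows(self):
        """End-to-end pipeline matches the frozen per-condition reference."""
        df = table3()
        got = list(zip(df["total_ip3"], df["near_beta"]))
        assert got == [tuple(p) for p in TABLE3_REFERENCE]

    def test_single_row(self):
        df = table3([(10, 1000.0, 1.5)])
        assert len(df) == 1
        assert df["total_ip3"].iloc[0] == 50
        assert df["near_beta"].iloc[0] == 4

    def test_physical_time_entry(self):
        df = table3([(100, 5000.0, 1e-3)], times_are_tau=False)
        assert df["tau"].iloc[0] == pytest.approx(0.3)
        assert df["near_beta"].iloc[0] == 29

    def test_empty_scenario_list(self):
        df = table3([])
        assert df.empty
        assert list(df.columns[:4]) == ["n_plc", "kcat_per_s", "time_s", "tau"]

    def test_degenerate_rows_are_flagged(self):
        df = table3([(1, 1000.0, 1.5)])
        assert bool(df["degenerate"].iloc[0])
        assert not table3([(100, 5000.0, 1.5)])["degenerate"].iloc[0]
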