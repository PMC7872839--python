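"""Unit and property tests for the DFI computation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfikit.core import (
    CHANNELS,
    DEFAULT_WEIGHTS,
    BlendShapeFrame,
    EmptySessionError,
    MeasurementSession,
    RegionId,
    RegionWeights,
    SideId,
    assess_region,
    compute_dfi,
    extract_region_maxima,
    stennert_equivalent,
)

from conftest import make_frame, oracle_dfi, session_from_maxima

F, E, M = RegionId.FOREHEAD, RegionId.EYES, RegionId.MOUTH
L, R = SideId.LEFT, SideId.RIGHT


# --------------------------------------------------------------------------
# Domain-type validation


class TestDomainTypes:
    def test_region_iteration_order(self):
        assert list(RegionId) == [F, E, M]
        assert list(SideId) == [L, R]

    def test_frame_rejects_nan_and_out_of_range(self):
        with pytest.raises(ValueError, match="NaN"):
            make_frame(0.0, {(M, L): float("nan")})
        with pytest.raises(ValueError, match=r"outside \[0, 1\]"):
            make_frame(0.0, {(M, L): 1.2})

    def test_valid_frame_requires_all_channels(self):
        with pytest.raises(ValueError, match="missing channels"):
            BlendShapeFrame(timestamp=0.0, coeff={(M, L): 0.5}, valid=True)
        # invalid frames may be sparse (face not tracked)
        BlendShapeFrame(timestamp=0.0, coeff={}, valid=False)

    def test_session_rejects_non_monotone_timestamps(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            MeasurementSession(frames=(make_frame(1.0), make_frame(1.0)))

    def test_session_rejects_timestamps_past_duration(self):
        with pytest.raises(ValueError, match="exceeds duration_setting"):
            MeasurementSession(frames=(make_frame(6.0),), duration_setting=5)

    @pytest.mark.parametrize("bad", [4, 16])
    def test_duration_setting_bounds(self, bad):
        with pytest.raises(ValueError, match="duration_setting"):
            MeasurementSession(frames=(), duration_setting=bad)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            RegionWeights.from_sequence([0.1, 0.4, 0.4])
        w = RegionWeights.from_sequence([0.2, 0.4, 0.4])
        assert w[E] == 0.4

    def test_default_weights(self):
        assert [DEFAULT_WEIGHTS[r] for r in RegionId] == [0.10, 0.40, 0.50]


# --------------------------------------------------------------------------
# Maxima extraction


class TestExtractMaxima:
    def test_all_zero_session(self):
        session = MeasurementSession(
            frames=(make_frame(0.0), make_frame(0.5), make_frame(1.0))
        )
        maxima = extract_region_maxima(session)
        assert all(v == 0.0 for v in maxima.values())

    def test_single_channel_ramp(self):
        frames = tuple(
            make_frame(t, {(M, L): v})
            for t, v in [(0.0, 0.0), (1.0, 0.9), (2.0, 0.0)]
        )
        maxima = extract_region_maxima(MeasurementSession(frames=frames))
        assert maxima[(M, L)] == 0.9
        assert all(v == 0.0 for ch, v in maxima.items() if ch != (M, L))

    def test_invalid_frames_excluded_from_maxima(self):
        # the true peak (0.9) occurs only while tracking was lost
        frames = (
            make_frame(0.0, {(M, L): 0.4}),
            make_frame(1.0, {(M, L): 0.9}, valid=False),
            make_frame(2.0, {(M, L): 0.2}),
        )
        maxima = extract_region_maxima(MeasurementSession(frames=frames))
        assert maxima[(M, L)] == 0.4

    def test_no_valid_frames_raises(self):
        session = MeasurementSession(frames=(make_frame(0.0, valid=False),))
        with pytest.raises(EmptySessionError):
            extract_region_maxima(session)


# --------------------------------------------------------------------------
# Region assessment


class TestAssessRegion:
    def test_worked_asymmetry(self):
        a = assess_region(M, 0.6, 0.3)
        assert a.healthy_side is L
        assert a.weak_side is R
        assert a.delta_abs == pytest.approx(0.3)
        assert a.delta_rel == pytest.approx(50.0)
        assert a.rel_weak == pytest.approx(50.0)
        assert a.correction_factor == pytest.approx(1 / 0.6)
        assert a.active

    def test_exact_tie_gives_no_deduction(self):
        a = assess_region(E, 0.8, 0.8)
        assert a.healthy_side is None
        assert a.delta_rel == 0.0
        assert a.active

    def test_zero_movement_is_inactive(self):
        a = assess_region(F, 0.0, 0.0)
        assert not a.active
        assert a.delta_rel == 0.0
        assert a.correction_factor is None
        assert a.healthy_side is None

    def test_threshold_boundary(self):
        assert not assess_region(F, 0.04, 0.04).active
        assert assess_region(F, 0.05, 0.0).active

    @given(
        left=st.floats(0, 1),
        right=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_rel_weak_plus_delta_rel_is_100_when_active(self, left, right):
        a = assess_region(M, left, right)
        if a.active:
            assert a.rel_weak + a.delta_rel == pytest.approx(100.0)
        assert 0.0 <= a.delta_rel <= 100.0


# --------------------------------------------------------------------------
# Full DFI


class TestComputeDfi:
    def test_mirrored_session_is_fully_symmetric(self, mirrored_session):
        result = compute_dfi(mirrored_session)
        assert result.dfi[L] == 100.0
        assert result.dfi[R] == 100.0

    def test_complete_unilateral_palsy(self):
        session = session_from_maxima({F: (0.9, 0.0), E: (0.9, 0.0), M: (0.9, 0.0)})
        result = compute_dfi(session)
        assert result.dfi[R] == 0.0
        assert result.dfi[L] == 100.0

    def test_single_region_asymmetry_worked_example(self):
        session = session_from_maxima({F: (0.8, 0.8), E: (0.9, 0.9), M: (0.6, 0.3)})
        result = compute_dfi(session)
        assert result.regions[M].delta_rel == pytest.approx(50.0)
        assert result.dfi[R] == pytest.approx(75.0)
        assert result.dfi[L] == 100.0

    def test_per_region_side_attribution(self):
        # forehead weaker on the right... no: (0.4, 0.8) -> LEFT weak;
        # eyes (0.9, 0.45) -> RIGHT weak; mouth symmetric
        session = session_from_maxima({F: (0.4, 0.8), E: (0.9, 0.45), M: (0.6, 0.6)})
        result = compute_dfi(session)
        assert result.dfi[L] == pytest.approx(95.0)  # 100 - 0.10 * 50
        assert result.dfi[R] == pytest.approx(80.0)  # 100 - 0.40 * 50

    def test_custom_weights(self):
        session = session_from_maxima({F: (0.8, 0.8), E: (0.9, 0.9), M: (0.6, 0.3)})
        weights = RegionWeights.from_sequence([0.2, 0.4, 0.4])
        result = compute_dfi(session, weights=weights)
        assert result.dfi[R] == pytest.approx(80.0)

    def test_short_tracking_warning(self):
        session = MeasurementSession(
            frames=(make_frame(0.0), make_frame(0.5))
        )
        result = compute_dfi(session)
        assert any("1 s" in w for w in result.warnings)

    def test_skipped_gesture_flagged_not_penalized(self):
        session = session_from_maxima({F: (0.0, 0.0), E: (0.9, 0.9), M: (0.7, 0.7)})
        result = compute_dfi(session)
        assert result.dfi[L] == 100.0 and result.dfi[R] == 100.0
        assert any("forehead" in w for w in result.warnings)


class TestStennertEquivalent:
    @pytest.mark.parametrize(
        "maxima,expected",
        [
            ({F: (0.8, 0.8), E: (0.9, 0.9), M: (0.7, 0.7)}, 0.0),
            ({F: (0.9, 0.0), E: (0.9, 0.0), M: (0.9, 0.0)}, 10.0),
            ({F: (0.8, 0.8), E: (0.9, 0.9), M: (0.6, 0.3)}, 2.5),
        ],
    )
    def test_linear_map(self, maxima, expected):
        result = compute_dfi(session_from_maxima(maxima))
        assert stennert_equivalent(result) == pytest.approx(expected)


# --------------------------------------------------------------------------
# Properties

maxima_strategy = st.fixed_dictionaries(
    {
        r: st.tuples(
            st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
        )
        for r in RegionId
    }
)


class TestProperties:
    @given(maxima=maxima_strategy)
    @settings(max_examples=150, deadline=None)
    def test_range_and_unblamed_side_scores_100(self, maxima):
        """DFI stays in [0, 100]; a side weak in no region scores 100.

        Side attribution is per region, so both sides can carry
        deductions when different regions are weak on different sides.
        """
        result = compute_dfi(session_from_maxima(maxima))
        values = list(result.dfi.values())
        assert all(-1e-9 <= v <= 100.0 + 1e-9 for v in values)
        for side in SideId:
            if all(a.weak_side is not side for a in result.regions.values()):
                assert result.dfi[side] == 100.0

    @given(maxima=maxima_strategy)
    @settings(max_examples=150, deadline=None)
    def test_weight_conservation(self, maxima):
        result = compute_dfi(session_from_maxima(maxima))
        total_deduction = sum(100.0 - v for v in result.dfi.values())
        assert total_deduction <= 100.0 + 1e-9

    @given(
        maxima=maxima_strategy,
        scale=st.sampled_from([0.9, 0.5, 0.2]),
    )
    @settings(max_examples=150, deadline=None)
    def test_scale_invariance(self, maxima, scale):
        """The correction factor makes DFI amplitude-invariant."""
        base = compute_dfi(session_from_maxima(maxima))
        scaled_maxima = {
            r: (l * scale, rt * scale) for r, (l, rt) in maxima.items()
        }
        # only meaningful when activity status is unchanged by scaling
        for r in RegionId:
            if max(maxima[r]) >= 0.05 and max(scaled_maxima[r]) < 0.05:
                return
        scaled = compute_dfi(session_from_maxima(scaled_maxima))
        for side in SideId:
            assert scaled.dfi[side] == pytest.approx(
                base.dfi[side], abs=1e-9
            )

    @given(
        healthy=st.floats(0.2, 1.0),
        weak_hi=st.floats(0.0, 1.0),
        weak_lo=st.floats(0.0, 1.0),
        region=st.sampled_from(list(RegionId)),
    )
    @settings(max_examples=150, deadline=None)
    def test_monotonicity_in_weak_side(self, healthy, weak_hi, weak_lo, region):
        """Weakening the weak side further never raises its DFI."""
        hi, lo = max(weak_hi, weak_lo), min(weak_hi, weak_lo)
        hi, lo = min(hi, healthy), min(lo, healthy)

        def score(weak_value):
            maxima = {r: (0.8, 0.8) for r in RegionId}
            maxima[region] = (healthy, weak_value)
            return compute_dfi(session_from_maxima(maxima)).dfi[R]

        assert score(lo) <= score(hi) + 1e-9

    @given(maxima=maxima_strategy, seed=st.integers(0, 2**16))
    @settings(max_examples=100, deadline=None)
    def test_oracle_equivalence(self, maxima, seed):
        """Production scorer matches an exact-rational brute-force oracle."""
        session = session_from_maxima(maxima)
        result = compute_dfi(session)
        expected = oracle_dfi(session, DEFAULT_WEIGHTS)
        for side in SideId:
            assert result.dfi[side] == pytest.approx(expected[side], abs=1e-9)

    @given(maxima=maxima_strategy, seed=st.integers(0, 2**16))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance(self, maxima, seed):
        """Reassigning coefficient rows across timestamps changes nothing."""
        session = session_from_maxima(maxima)
        rng = random.Random(seed)
        coeffs = [dict(f.coeff) for f in session.frames]
        rng.shuffle(coeffs)
        shuffled = MeasurementSession(
            frames=tuple(
                BlendShapeFrame(timestamp=f.timestamp, coeff=c, valid=True)
                for f, c in zip(session.frames, coeffs)
            ),
            duration_setting=session.duration_setting,
        )
        assert compute_dfi(shuffled).dfi == compute_dfi(session).dfi
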