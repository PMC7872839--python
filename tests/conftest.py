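"""Shared fixtures and an independent brute-force scoring oracle."""

from __future__ import annotations

from fractions import Fraction

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from dfikit.core import (
    CHANNELS,
    BlendShapeFrame,
    MeasurementSession,
    RegionId,
    SideId,
)


def make_frame(t: float, values=None, valid: bool = True, **overrides):
    """Frame with all six channels, defaulting to 0.0."""
    coeff = {ch: 0.0 for ch in CHANNELS}
    if values:
        coeff.update(values)
    return BlendShapeFrame(timestamp=t, coeff=coeff, valid=valid, **overrides)


def session_from_maxima(maxima, duration_setting: int = 10, label: str = ""):
    """Build a small session whose per-channel maxima equal ``maxima``.

    ``maxima`` maps RegionId -> (max_left, max_right).  Each region's peak
    is placed in its own frame (other channels at zero there), bracketed
    by all-zero frames, so the channel maxima are exactly the given values.
    """
    frames = [make_frame(0.0)]
    t = 1.0
    for region in RegionId:
        left, right = maxima[region]
        frames.append(
            make_frame(
                t,
                {(region, SideId.LEFT): left, (region, SideId.RIGHT): right},
            )
        )
        frames.append(make_frame(t + 1.0))
        t += 2.0
    return MeasurementSession(
        frames=tuple(frames),
        duration_setting=duration_setting,
        label=label,
    )


def oracle_dfi(session, weights, activity_threshold=0.05):
    """Brute-force reference scorer, independent of the library path.

    Re-derives per-channel maxima by scanning every frame and applies the
    asymmetry formula in exact rational arithmetic (inputs converted via
    Fraction(float), which is lossless), so any disagreement beyond float
    rounding with the production implementation is a real defect.
    """
    maxima = {}
    for ch in CHANNELS:
        best = None
        for frame in session.frames:
            if not frame.valid:
                continue
            v = Fraction(frame.coeff[ch])
            if best is None or v > best:
                best = v
        assert best is not None, "oracle needs at least one valid frame"
        maxima[ch] = best

    deduction = {SideId.LEFT: Fraction(0), SideId.RIGHT: Fraction(0)}
    for region in RegionId:
        left = maxima[(region, SideId.LEFT)]
        right = maxima[(region, SideId.RIGHT)]
        stronger = max(left, right)
        if stronger < Fraction(activity_threshold) or left == right:
            continue
        delta_rel = (abs(left - right) / stronger) * 100
        weak = SideId.RIGHT if left > right else SideId.LEFT
        deduction[weak] += Fraction(weights[region]) * delta_rel
    return {s: float(100 - deduction[s]) for s in SideId}


@pytest.fixture
def mirrored_session():
    """All three gestures performed identically on both sides."""
    return session_from_maxima(
        {
            RegionId.FOREHEAD: (0.8, 0.8),
            RegionId.EYES: (0.9, 0.9),
            RegionId.MOUTH: (0.7, 0.7),
        }
    )
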