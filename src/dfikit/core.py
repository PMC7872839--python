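"""Core domain types and the Digital Facial Index (DFI) computation.

The DFI grades unilateral facial movement asymmetry from depth-camera
blend-shape coefficient streams.  Three voluntary gestures (brow raise,
eye closure, mouth-corner lift) are captured bilaterally; for each facial
region the per-side movement maxima are compared, the stronger ("healthy")
side is rescaled to 100% and the weaker side proportionally, and the
weighted relative differences (forehead 10%, eyes 40%, mouth 50%) are
deducted from a perfect score of 100.  A perfectly symmetric face scores
100 on both sides; a complete unilateral palsy scores 0 on the affected
side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RegionId",
    "SideId",
    "Channel",
    "CHANNELS",
    "BlendShapeFrame",
    "MeasurementSession",
    "RegionWeights",
    "DEFAULT_WEIGHTS",
    "DEFAULT_ACTIVITY_THRESHOLD",
    "RegionAsymmetry",
    "DFIResult",
    "ScoringError",
    "EmptySessionError",
    "extract_region_maxima",
    "assess_region",
    "compute_dfi",
    "stennert_equivalent",
]


class RegionId(Enum):
    """Facial region; iteration order is forehead, eyes, mouth."""

    FOREHEAD = "forehead"
    EYES = "eyes"
    MOUTH = "mouth"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SideId(Enum):
    """Anatomical side of the subject (not of the camera image)."""

    LEFT = "left"
    RIGHT = "right"

    @property
    def other(self) -> "SideId":
        return SideId.RIGHT if self is SideId.LEFT else SideId.LEFT

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


Channel = tuple[RegionId, SideId]

#: The six movement channels, in canonical order.
CHANNELS: tuple[Channel, ...] = tuple(
    (region, side) for region in RegionId for side in SideId
)

#: Default motility weighting: functional/cosmetic importance of each region.
DEFAULT_ACTIVITY_THRESHOLD = 0.05

MIN_DURATION_SETTING = 5
MAX_DURATION_SETTING = 15

#: Valid tracking shorter than this (seconds) triggers a quality warning.
SHORT_TRACKING_WARNING_S = 1.0


class ScoringError(Exception):
    """A session cannot be scored."""


class EmptySessionError(ScoringError):
    """No valid (face-tracked) frames available for scoring."""


def _check_coeff(value: float, channel: Channel) -> float:
    v = float(value)
    if math.isnan(v):
        raise ValueError(f"NaN coefficient for channel {channel}")
    if not 0.0 <= v <= 1.0:
        raise ValueError(
            f"coefficient {v!r} for channel {channel} outside [0, 1]"
        )
    return v


@dataclass(frozen=True)
class BlendShapeFrame:
    """One time-stamped sample of the six movement coefficients.

    ``valid`` flags whether the face was tracked in this frame; invalid
    frames carry no usable coefficients and are excluded from maxima.
    """

    timestamp: float
    coeff: Mapping[Channel, float]
    valid: bool = True

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp {self.timestamp!r}")
        coeff = dict(self.coeff)
        if self.valid:
            missing = [c for c in CHANNELS if c not in coeff]
            if missing:
                raise ValueError(f"valid frame missing channels: {missing}")
        for ch, v in coeff.items():
            coeff[ch] = _check_coeff(v, ch)
        object.__setattr__(self, "coeff", coeff)

    def value(self, region: RegionId, side: SideId) -> float:
        return self.coeff[(region, side)]


@dataclass(frozen=True)
class MeasurementSession:
    """An ordered blend-shape frame sequence plus capture metadata.

    ``duration_setting`` is the user-selected measurement window (5-15 s);
    ``nominal_rate`` is metadata only — timestamps are authoritative and no
    resampling is performed.
    """

    frames: tuple[BlendShapeFrame, ...]
    duration_setting: int = 10
    nominal_rate: float = 60.0
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "frames", tuple(self.frames))
        if not (
            MIN_DURATION_SETTING <= self.duration_setting <= MAX_DURATION_SETTING
        ):
            raise ValueError(
                f"duration_setting {self.duration_setting} outside "
                f"[{MIN_DURATION_SETTING}, {MAX_DURATION_SETTING}] s"
            )
        ts = [f.timestamp for f in self.frames]
        for a, b in zip(ts, ts[1:]):
            if not a < b:
                raise ValueError(
                    f"timestamps not strictly increasing ({a!r} -> {b!r})"
                )
        if ts and ts[-1] > self.duration_setting:
            raise ValueError(
                f"frame timestamp {ts[-1]!r} exceeds duration_setting "
                f"{self.duration_setting}"
            )

    @property
    def valid_frames(self) -> tuple[BlendShapeFrame, ...]:
        return tuple(f for f in self.frames if f.valid)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class RegionWeights:
    """Region weighting of the index; the three weights must sum to 1."""

    weight: Mapping[RegionId, float]

    def __post_init__(self) -> None:
        w = {r: float(self.weight[r]) for r in RegionId}
        for r, v in w.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"weight for {r} outside [0, 1]: {v!r}")
        if abs(sum(w.values()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(w.values())!r}")
        object.__setattr__(self, "weight", w)

    def __getitem__(self, region: RegionId) -> float:
        return self.weight[region]

    @classmethod
    def from_sequence(cls, values: Sequence[float]) -> "RegionWeights":
        """Build from (forehead, eyes, mouth) in canonical region order."""
        if len(values) != len(RegionId):
            raise ValueError("expected exactly three weights")
        return cls(dict(zip(RegionId, values)))


DEFAULT_WEIGHTS = RegionWeights(
    {RegionId.FOREHEAD: 0.10, RegionId.EYES: 0.40, RegionId.MOUTH: 0.50}
)


@dataclass(frozen=True)
class RegionAsymmetry:
    """Bilateral comparison of one region's movement maxima.

    ``healthy_side`` is the side with the strictly greater maximum, or
    ``None`` for a tie (symmetric evidence) or an inactive region.
    ``delta_rel`` is the relative motility difference in percent: the
    stronger side is rescaled to 100% by the correction factor
    ``f_C = 1 / stronger-side maximum`` and the weaker side proportionally,
    so ``rel_weak + delta_rel = 100`` for any active region.
    """

    region: RegionId
    max_left: float
    max_right: float
    healthy_side: SideId | None
    delta_abs: float
    rel_weak: float
    delta_rel: float
    correction_factor: float | None
    active: bool

    @property
    def weak_side(self) -> SideId | None:
        return None if self.healthy_side is None else self.healthy_side.other


@dataclass(frozen=True)
class DFIResult:
    """Both per-side DFI percentages plus the per-region breakdown."""

    dfi: Mapping[SideId, float]
    regions: Mapping[RegionId, RegionAsymmetry]
    weights: RegionWeights
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, side: SideId) -> float:
        return self.dfi[side]

    @property
    def weak_side_dfi(self) -> float:
        return min(self.dfi.values())


def extract_region_maxima(
    session: MeasurementSession,
) -> dict[Channel, float]:
    """Per-channel maximum coefficient over the session's valid frames.

    Untracked (invalid) frames contribute nothing; they are excluded
    rather than interpolated, since a maximum over the surviving frames
    is unaffected by gaps that miss the movement peaks.
    """
    valid = session.valid_frames
    if not valid:
        raise EmptySessionError(
            "session has no valid (face-tracked) frames; nothing to score"
        )
    return {
        ch: max(f.coeff[ch] for f in valid) for ch in CHANNELS
    }


def assess_region(
    region: RegionId,
    max_left: float,
    max_right: float,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> RegionAsymmetry:
    """Compare one region's per-side maxima and derive its asymmetry.

    When both maxima fall below ``activity_threshold`` the gesture was not
    performed; the region is inactive and contributes zero asymmetry
    (a skipped gesture must not read as palsy), and the correction factor
    is undefined.
    """
    if not (0.0 <= max_left <= 1.0 and 0.0 <= max_right <= 1.0):
        raise ValueError("region maxima must lie in [0, 1]")
    if activity_threshold < 0:
        raise ValueError("activity_threshold must be non-negative")

    delta_abs = abs(max_left - max_right)
    stronger = max(max_left, max_right)

    if stronger < activity_threshold:
        return RegionAsymmetry(
            region=region,
            max_left=max_left,
            max_right=max_right,
            healthy_side=None,
            delta_abs=delta_abs,
            rel_weak=100.0,
            delta_rel=0.0,
            correction_factor=None,
            active=False,
        )

    if max_left > max_right:
        healthy: SideId | None = SideId.LEFT
    elif max_right > max_left:
        healthy = SideId.RIGHT
    else:
        healthy = None  # exact tie: symmetric evidence, no deduction

    delta_rel = delta_abs / stronger * 100.0
    return RegionAsymmetry(
        region=region,
        max_left=max_left,
        max_right=max_right,
        healthy_side=healthy,
        delta_abs=delta_abs,
        rel_weak=100.0 - delta_rel,
        delta_rel=delta_rel,
        correction_factor=1.0 / stronger,
        active=True,
    )


def compute_dfi(
    session: MeasurementSession,
    weights: RegionWeights = DEFAULT_WEIGHTS,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> DFIResult:
    """Score a session: per-side DFI percentages with full breakdown.

    Each region's relative difference is charged to that region's weaker
    side (side attribution is per region, not global), scaled by the
    region weight, and deducted from 100.  A side that is the weaker one
    in no region scores exactly 100; in a strictly unilateral palsy this
    is the healthy side, but mixed findings can deduct from both sides.
    """
    maxima = extract_region_maxima(session)
    regions = {
        r: assess_region(
            r,
            maxima[(r, SideId.LEFT)],
            maxima[(r, SideId.RIGHT)],
            activity_threshold,
        )
        for r in RegionId
    }

    dfi = {}
    for side in SideId:
        deduction = sum(
            weights[r] * asym.delta_rel
            for r, asym in regions.items()
            if asym.weak_side is side
        )
        dfi[side] = 100.0 - deduction

    warnings = []
    valid_ts = [f.timestamp for f in session.valid_frames]
    if valid_ts[-1] - valid_ts[0] < SHORT_TRACKING_WARNING_S:
        warnings.append(
            "less than 1 s of valid face tracking; result may be unreliable"
        )
    inactive = [r.value for r, a in regions.items() if not a.active]
    if inactive:
        warnings.append(
            "inactive region(s) (gesture below activity threshold): "
            + ", ".join(inactive)
        )

    return DFIResult(
        dfi=dfi, regions=regions, weights=weights, warnings=tuple(warnings)
    )


def stennert_equivalent(result: DFIResult) -> float:
    """Map a DFI result onto a Stennert-motility-like 0-10 magnitude.

    Returns ``10 * (1 - weak-side DFI / 100)``: 0 for a symmetric face,
    10 for complete unilateral palsy.  The DFI convention is reciprocal
    to the clinician-graded Stennert index (where 10 is complete palsy);
    this is an unvalidated linear convenience mapping, not a clinically
    calibrated conversion.
    """
    return 10.0 * (1.0 - result.weak_side_dfi / 100.0)


def frames_from_arrays(
    timestamps: Iterable[float],
    coeffs: Mapping[Channel, Sequence[float]],
    valid: Iterable[bool] | None = None,
) -> tuple[BlendShapeFrame, ...]:
    """Convenience constructor: column arrays -> frame tuple."""
    ts = list(timestamps)
    flags = list(valid) if valid is not None else [True] * len(ts)
    return tuple(
        BlendShapeFrame(
            timestamp=t,
            coeff={ch: coeffs[ch][i] for ch in CHANNELS},
            valid=flags[i],
        )
        for i, t in enumerate(ts)
    )
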