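"""Synthetic blend-shape motion: a depth-camera stand-in with ground truth.

Emulates the DFI measurement protocol — three sequential voluntary
gestures (brow raise, eye closure, mouth-corner lift) inside a 5-15 s
window sampled at ~60 frames/s — with configurable unilateral weakness,
contralateral coupling, additive sensor noise, tracking dropouts and
viewing-angle attenuation.  Each gesture is a raised-cosine pulse, so the
noise-free per-channel maxima, and hence the expected DFI, are analytic.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNELS,
    DEFAULT_ACTIVITY_THRESHOLD,
    DEFAULT_WEIGHTS,
    BlendShapeFrame,
    Channel,
    MeasurementSession,
    RegionId,
    RegionWeights,
    SideId,
    assess_region,
    compute_dfi,
)

__all__ = [
    "GestureEpoch",
    "SimulationScenario",
    "GroundTruth",
    "ScenarioError",
    "default_epochs",
    "lateral_attenuation",
    "simulate_session",
    "drop_frames_keeping_peaks",
    "run_robustness_suite",
    "load_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
]


class ScenarioError(ValueError):
    """A simulation scenario is internally inconsistent."""


@dataclass(frozen=True)
class GestureEpoch:
    """One gesture's time window: the pulse rises from 0 at ``start`` to
    its peak at ``start + length/2`` and returns to 0 at ``start + length``."""

    region: RegionId
    start: float
    length: float


def default_epochs(duration: float) -> tuple[GestureEpoch, ...]:
    """Three equal thirds of the window: brow, then eyes, then mouth."""
    third = duration / 3.0
    order = (RegionId.FOREHEAD, RegionId.EYES, RegionId.MOUTH)
    return tuple(
        GestureEpoch(region=r, start=i * third, length=third)
        for i, r in enumerate(order)
    )


def lateral_attenuation(
    side: SideId, mouth_factor: float, eyes_factor: float = 1.0
) -> dict[SideId, dict[RegionId, float]]:
    """Static per-side attenuation profile for an oblique camera angle.

    Off-axis viewing degrades the tracked mouth-corner excursion far more
    than brow or eye channels, so the default profile attenuates only the
    mouth on the far side.  This is a qualitative emulation; no optical
    model is attempted.
    """
    profile = {r: 1.0 for r in RegionId}
    profile[RegionId.MOUTH] = mouth_factor
    profile[RegionId.EYES] = eyes_factor
    return {
        side: profile,
        side.other: {r: 1.0 for r in RegionId},
    }


def _full_attenuation() -> dict[SideId, dict[RegionId, float]]:
    return {s: {r: 1.0 for r in RegionId} for s in SideId}


#: Healthy gesture amplitudes: full voluntary effort rarely drives ARKit-style
#: coefficients to 1.0; eye closure saturates most, brow and mouth less so.
DEFAULT_AMPLITUDE = {
    RegionId.FOREHEAD: 0.8,
    RegionId.EYES: 0.9,
    RegionId.MOUTH: 0.7,
}


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth generative parameters for one simulated measurement.

    ``weakness`` multiplies the affected side's amplitude per region
    (1 = healthy, 0 = complete palsy).  ``contralateral_coupling`` is the
    residual fraction of movement the paralyzed side still shows when the
    healthy side moves maximally.  ``dropout`` marks a fraction of frames
    as untracked, either scattered at random or as one contiguous gap.
    """

    duration: float = 10.0
    rate: float = 60.0
    epochs: tuple[GestureEpoch, ...] = field(default_factory=tuple)
    amplitude: Mapping[RegionId, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDE)
    )
    weakness: Mapping[RegionId, float] = field(
        default_factory=lambda: {r: 1.0 for r in RegionId}
    )
    affected_side: SideId = SideId.LEFT
    contralateral_coupling: float = 0.05
    noise_sd: float = 0.0
    dropout: float = 0.0
    dropout_contiguous: bool = False
    angle_attenuation: Mapping[SideId, Mapping[RegionId, float]] = field(
        default_factory=_full_attenuation
    )
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not 5.0 <= self.duration <= 15.0:
            raise ScenarioError(
                f"duration {self.duration!r} outside the 5-15 s window"
            )
        if self.rate <= 0:
            raise ScenarioError("rate must be positive")
        epochs = tuple(self.epochs) or default_epochs(self.duration)
        object.__setattr__(self, "epochs", epochs)
        covered = {e.region for e in epochs}
        if covered != set(RegionId):
            raise ScenarioError(
                f"gesture schedule must cover all regions exactly once, "
                f"got {sorted(r.value for r in covered)}"
            )
        if len(epochs) != len(RegionId):
            raise ScenarioError("exactly one gesture epoch per region")
        for e in epochs:
            if e.length <= 0:
                raise ScenarioError(f"epoch for {e.region} has length <= 0")
            if e.start < 0 or e.start + e.length > self.duration + 1e-9:
                raise ScenarioError(
                    f"epoch for {e.region} exceeds the measurement window"
                )
        ordered = sorted(epochs, key=lambda e: e.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.start + a.length > b.start + 1e-9:
                raise ScenarioError(
                    f"epochs for {a.region} and {b.region} overlap"
                )
        for name, mapping, lo, hi in (
            ("amplitude", self.amplitude, 0.0, 1.0),
            ("weakness", self.weakness, 0.0, 1.0),
        ):
            vals = {r: float(mapping[r]) for r in RegionId}
            for r, v in vals.items():
                if not lo <= v <= hi:
                    raise ScenarioError(
                        f"{name}[{r.value}] = {v!r} outside [{lo}, {hi}]"
                    )
            object.__setattr__(self, name, vals)
        if any(self.amplitude[r] == 0.0 for r in RegionId):
            raise ScenarioError("healthy amplitude must be positive")
        if not 0.0 <= self.contralateral_coupling <= 1.0:
            raise ScenarioError("contralateral_coupling outside [0, 1]")
        if self.noise_sd < 0:
            raise ScenarioError("noise_sd must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ScenarioError("dropout fraction outside [0, 1)")
        att = {
            s: {r: float(self.angle_attenuation[s][r]) for r in RegionId}
            for s in SideId
        }
        for s in SideId:
            for r in RegionId:
                if not 0.0 <= att[s][r] <= 1.0:
                    raise ScenarioError("attenuation factors must be in [0, 1]")
        object.__setattr__(self, "angle_attenuation", att)

    def side_factor(self, region: RegionId, side: SideId) -> float:
        """Net multiplicative factor for one channel's noise-free peak."""
        if side is self.affected_side:
            w = self.weakness[region]
            base = w + self.contralateral_coupling * (1.0 - w)
        else:
            base = 1.0
        return base * self.angle_attenuation[side][region]


@dataclass(frozen=True)
class GroundTruth:
    """Analytic (noise-free) expectations implied by a scenario."""

    maxima: Mapping[Channel, float]
    dfi: Mapping[SideId, float]
    delta_rel: Mapping[RegionId, float]


def analytic_ground_truth(
    scenario: SimulationScenario,
    weights: RegionWeights = DEFAULT_WEIGHTS,
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> GroundTruth:
    """Expected maxima and DFI from the noise-free generative model."""
    maxima = {
        (r, s): scenario.amplitude[r] * scenario.side_factor(r, s)
        for r in RegionId
        for s in SideId
    }
    regions = {
        r: assess_region(
            r,
            maxima[(r, SideId.LEFT)],
            maxima[(r, SideId.RIGHT)],
            activity_threshold,
        )
        for r in RegionId
    }
    dfi = {
        side: 100.0
        - sum(
            weights[r] * a.delta_rel
            for r, a in regions.items()
            if a.weak_side is side
        )
        for side in SideId
    }
    return GroundTruth(
        maxima=maxima,
        dfi=dfi,
        delta_rel={r: a.delta_rel for r, a in regions.items()},
    )


def _pulse(t: np.ndarray, epoch: GestureEpoch) -> np.ndarray:
    """Raised-cosine pulse: 0 outside the epoch, 1 at its midpoint."""
    phase = (t - epoch.start) / epoch.length
    inside = (phase >= 0.0) & (phase <= 1.0)
    out = np.zeros_like(t)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase[inside]))
    return out


def simulate_session(
    scenario: SimulationScenario,
) -> tuple[MeasurementSession, GroundTruth]:
    """Generate one measurement session plus its analytic ground truth.

    Sampling instants are ``k / rate`` for ``k = 0 .. floor(duration*rate)``;
    with the default schedule every pulse midpoint coincides with a sampling
    instant, so the noise-free sampled maxima equal the analytic peaks.
    Gaussian noise is added per coefficient and clamped into [0, 1]
    (truncation by clamping).  Dropout marks frames invalid; at least the
    single best-tracked frame always survives so the session stays scoreable.
    """
    rng = np.random.default_rng(scenario.seed)
    n = int(math.floor(scenario.duration * scenario.rate)) + 1
    t = np.arange(n) / scenario.rate
    # keep the last sample inside the window (guards float edge cases)
    t = t[t <= scenario.duration]
    n = t.size

    cols: dict[Channel, np.ndarray] = {}
    for epoch in scenario.epochs:
        pulse = _pulse(t, epoch)
        for side in SideId:
            peak = scenario.amplitude[epoch.region] * scenario.side_factor(
                epoch.region, side
            )
            signal = peak * pulse
            if scenario.noise_sd > 0:
                signal = signal + rng.normal(0.0, scenario.noise_sd, size=n)
            cols[(epoch.region, side)] = np.clip(signal, 0.0, 1.0)

    valid = np.ones(n, dtype=bool)
    if scenario.dropout > 0:
        n_drop = int(round(scenario.dropout * n))
        n_drop = min(n_drop, n - 1)  # always keep at least one frame
        if scenario.dropout_contiguous:
            start = int(rng.integers(0, n - n_drop + 1))
            valid[start : start + n_drop] = False
        else:
            idx = rng.choice(n, size=n_drop, replace=False)
            valid[idx] = False
        if not valid.any():  # pragma: no cover - guarded by n_drop < n
            valid[0] = True

    frames = tuple(
        BlendShapeFrame(
            timestamp=float(t[i]),
            coeff={ch: float(cols[ch][i]) for ch in CHANNELS},
            valid=bool(valid[i]),
        )
        for i in range(n)
    )
    session = MeasurementSession(
        frames=frames,
        duration_setting=int(math.ceil(scenario.duration)),
        nominal_rate=scenario.rate,
        label=scenario.label,
    )
    return session, analytic_ground_truth(scenario)


def drop_frames_keeping_peaks(
    session: MeasurementSession, fraction: float, seed: int = 0
) -> MeasurementSession:
    """Delete a fraction of frames while protecting every channel's argmax.

    Models intermittent tracking loss (a shaky hand, the face briefly
    leaving the field of view) that happens to miss the movement peaks:
    the per-channel maxima, and therefore the DFI, are provably unchanged.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    valid_idx = [i for i, f in enumerate(session.frames) if f.valid]
    if not valid_idx:
        raise ValueError("session has no valid frames")
    protected = set()
    for ch in CHANNELS:
        protected.add(
            max(valid_idx, key=lambda i: session.frames[i].coeff[ch])
        )
    candidates = [i for i in range(len(session.frames)) if i not in protected]
    n_drop = min(int(round(fraction * len(session.frames))), len(candidates))
    dropped = set(rng.choice(candidates, size=n_drop, replace=False).tolist())
    kept = [f for i, f in enumerate(session.frames) if i not in dropped]
    return dataclasses.replace(session, frames=tuple(kept))


def run_robustness_suite(
    base: SimulationScenario,
    perturbations: Sequence[tuple[str, Mapping[str, Any]]],
    replicates: int,
    seed: int = 0,
    weights: RegionWeights = DEFAULT_WEIGHTS,
) -> pd.DataFrame:
    """Score replicated simulations under named scenario edits.

    Mirrors the structure of a repeated-measurement robustness experiment:
    for each perturbation (a dict of scenario field overrides applied to
    ``base``), ``replicates`` sessions are simulated with distinct
    sub-seeds and scored; the table reports mean and sample SD of both DFI
    sides, plus the analytic expectation for reference.
    """
    if replicates < 2:
        raise ValueError("replicates must be >= 2")
    rows = []
    ss = np.random.SeedSequence(seed)
    for name, edits in [("base", {}), *perturbations]:
        scenario = dataclasses.replace(base, **dict(edits))
        child_seeds = ss.spawn(1)[0].generate_state(replicates) % (2**31)
        left, right = [], []
        truth = None
        for rep_seed in child_seeds:
            rep = dataclasses.replace(scenario, seed=int(rep_seed))
            session, truth = simulate_session(rep)
            result = compute_dfi(session, weights=weights)
            left.append(result.dfi[SideId.LEFT])
            right.append(result.dfi[SideId.RIGHT])
        left_a, right_a = np.asarray(left), np.asarray(right)
        rows.append(
            {
                "perturbation": name,
                "n": replicates,
                "mean_left": left_a.mean(),
                "sd_left": left_a.std(ddof=1),
                "mean_right": right_a.mean(),
                "sd_right": right_a.std(ddof=1),
                "expected_left": truth.dfi[SideId.LEFT],
                "expected_right": truth.dfi[SideId.RIGHT],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Scenario (de)serialization: structured-text config consumed by the CLI.


def scenario_to_dict(scenario: SimulationScenario) -> dict[str, Any]:
    return {
        "duration": scenario.duration,
        "rate": scenario.rate,
        "epochs": [
            {"region": e.region.value, "start": e.start, "length": e.length}
            for e in scenario.epochs
        ],
        "amplitude": {r.value: scenario.amplitude[r] for r in RegionId},
        "weakness": {r.value: scenario.weakness[r] for r in RegionId},
        "affected_side": scenario.affected_side.value,
        "contralateral_coupling": scenario.contralateral_coupling,
        "noise_sd": scenario.noise_sd,
        "dropout": scenario.dropout,
        "dropout_contiguous": scenario.dropout_contiguous,
        "angle_attenuation": {
            s.value: {r.value: scenario.angle_attenuation[s][r] for r in RegionId}
            for s in SideId
        },
        "seed": scenario.seed,
        "label": scenario.label,
    }


def scenario_from_dict(data: Mapping[str, Any]) -> SimulationScenario:
    kwargs: dict[str, Any] = dict(data)
    if "epochs" in kwargs and kwargs["epochs"]:
        kwargs["epochs"] = tuple(
            GestureEpoch(
                region=RegionId(e["region"]),
                start=float(e["start"]),
                length=float(e["length"]),
            )
            for e in kwargs["epochs"]
        )
    else:
        kwargs.pop("epochs", None)
    for key in ("amplitude", "weakness"):
        if key in kwargs:
            kwargs[key] = {RegionId(k): float(v) for k, v in kwargs[key].items()}
    if "affected_side" in kwargs:
        kwargs["affected_side"] = SideId(kwargs["affected_side"])
    if "angle_attenuation" in kwargs:
        kwargs["angle_attenuation"] = {
            SideId(s): {RegionId(r): float(v) for r, v in prof.items()}
            for s, prof in kwargs["angle_attenuation"].items()
        }
    try:
        return SimulationScenario(**kwargs)
    except TypeError as exc:
        raise ScenarioError(f"bad scenario key: {exc}") from exc


def load_scenario(path) -> SimulationScenario:
    """Load a scenario from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ScenarioError(f"{path}: scenario file must be a mapping")
    return scenario_from_dict(data)
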