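"""Raw-export reading/writing, the session history store, and repeat stats.

The raw-export dialect is a tab-separated UTF-8 text file: optional
``#``-prefixed metadata preamble (duration setting, nominal rate, label),
a header row naming the timestamp, the six movement channels and the
tracking-validity flag, then one row per frame with all reals printed at
fixed 6-decimal precision.  Writing then reading a session reproduces it
exactly at that precision, and the layout imports cleanly into any
spreadsheet.

Streams exported with ARKit-style coefficient names (``browOuterUpLeft``,
``eyeBlinkRight``, ``mouthSmileLeft``, ...) are accepted via a built-in
header alias table.  Note the anatomical-side convention: columns are the
subject's left/right, so any selfie mirroring must be resolved upstream.
"""

from __future__ import annotations

import dataclasses
import io
import json
import logging
import math
import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import (
    CHANNELS,
    BlendShapeFrame,
    Channel,
    DFIResult,
    MeasurementSession,
    RegionId,
    SideId,
)

__all__ = [
    "CANONICAL_COLUMNS",
    "ARKIT_ALIASES",
    "SessionFormatError",
    "read_session",
    "write_session",
    "HistoryRecord",
    "SessionHistory",
    "GroupStats",
    "AnovaResult",
    "RepeatedMeasuresSummary",
    "summarize_repeats",
]

logger = logging.getLogger(__name__)

#: Clamp tolerance: values in [-0.05, 0) or (1, 1.05] clamp with a warning;
#: anything further out is rejected as corrupt.
CLAMP_TOLERANCE = 0.05

_CHANNEL_COLUMNS: dict[str, Channel] = {
    "brow_raise_left": (RegionId.FOREHEAD, SideId.LEFT),
    "brow_raise_right": (RegionId.FOREHEAD, SideId.RIGHT),
    "eye_closure_left": (RegionId.EYES, SideId.LEFT),
    "eye_closure_right": (RegionId.EYES, SideId.RIGHT),
    "mouth_corner_lift_left": (RegionId.MOUTH, SideId.LEFT),
    "mouth_corner_lift_right": (RegionId.MOUTH, SideId.RIGHT),
}

#: Header row of the dialect, in order.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "timestamp",
    *_CHANNEL_COLUMNS.keys(),
    "valid",
)

#: ARKit blend-shape names accepted as channel-column aliases on read.
ARKIT_ALIASES: dict[str, str] = {
    "browOuterUpLeft": "brow_raise_left",
    "browOuterUpRight": "brow_raise_right",
    "browInnerUpLeft": "brow_raise_left",
    "browInnerUpRight": "brow_raise_right",
    "eyeBlinkLeft": "eye_closure_left",
    "eyeBlinkRight": "eye_closure_right",
    "mouthSmileLeft": "mouth_corner_lift_left",
    "mouthSmileRight": "mouth_corner_lift_right",
}


class SessionFormatError(ValueError):
    """A raw session file violates the export dialect."""


def _clamp_coeff(value: float, column: str, line_no: int) -> float:
    if math.isnan(value):
        raise SessionFormatError(
            f"line {line_no}: NaN coefficient in column '{column}'"
        )
    if value < -CLAMP_TOLERANCE or value > 1.0 + CLAMP_TOLERANCE:
        raise SessionFormatError(
            f"line {line_no}: coefficient {value!r} in column '{column}' "
            f"outside clamp tolerance [-{CLAMP_TOLERANCE}, "
            f"{1 + CLAMP_TOLERANCE}]"
        )
    if value < 0.0 or value > 1.0:
        clamped = min(max(value, 0.0), 1.0)
        logger.warning(
            "line %d: clamped coefficient %r in column '%s' to %r",
            line_no,
            value,
            column,
            clamped,
        )
        return clamped
    return value


def _open_maybe(path_or_stream, mode: str):
    if isinstance(path_or_stream, (str, os.PathLike)):
        return open(path_or_stream, mode, encoding="utf-8", newline=""), True
    return path_or_stream, False


def read_session(path_or_stream) -> MeasurementSession:
    """Parse a raw-export file into a :class:`MeasurementSession`.

    Coefficients slightly outside [0, 1] (within the clamp tolerance) are
    clamped with a logged warning; values further out, malformed rows and
    non-monotone timestamps raise :class:`SessionFormatError` with the
    offending line number.
    """
    stream, should_close = _open_maybe(path_or_stream, "r")
    try:
        return _read_session_stream(stream)
    finally:
        if should_close:
            stream.close()


def _read_session_stream(stream: IO[str]) -> MeasurementSession:
    meta: dict[str, str] = {}
    header: list[str] | None = None
    frames: list[BlendShapeFrame] = []
    prev_ts: float | None = None

    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith("#"):
            if header is not None:
                raise SessionFormatError(
                    f"line {line_no}: metadata line after header"
                )
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if header is None:
            header = [ARKIT_ALIASES.get(h.strip(), h.strip()) for h in fields]
            missing = set(CANONICAL_COLUMNS) - set(header)
            if missing:
                raise SessionFormatError(
                    f"line {line_no}: header missing columns {sorted(missing)}"
                )
            continue
        if len(fields) != len(header):
            raise SessionFormatError(
                f"line {line_no}: expected {len(header)} fields, "
                f"got {len(fields)}"
            )
        row = dict(zip(header, fields))
        try:
            ts = float(row["timestamp"])
            valid = bool(int(row["valid"]))
            coeff = {
                _CHANNEL_COLUMNS[col]: _clamp_coeff(
                    float(row[col]), col, line_no
                )
                for col in _CHANNEL_COLUMNS
            }
        except SessionFormatError:
            raise
        except (KeyError, ValueError) as exc:
            raise SessionFormatError(
                f"line {line_no}: malformed row ({exc})"
            ) from exc
        if prev_ts is not None and not ts > prev_ts:
            raise SessionFormatError(
                f"line {line_no}: timestamp {ts!r} not strictly greater "
                f"than previous {prev_ts!r}"
            )
        prev_ts = ts
        frames.append(BlendShapeFrame(timestamp=ts, coeff=coeff, valid=valid))

    if header is None:
        raise SessionFormatError("no header row found")
    if not frames:
        raise SessionFormatError("no data rows after header (empty session)")

    return MeasurementSession(
        frames=tuple(frames),
        duration_setting=int(meta.get("duration_setting", 10)),
        nominal_rate=float(meta.get("nominal_rate", 60.0)),
        label=meta.get("label", ""),
    )


def write_session(session: MeasurementSession, path_or_stream) -> None:
    """Write a session in the raw-export dialect (deterministic bytes)."""
    stream, should_close = _open_maybe(path_or_stream, "w")
    try:
        stream.write(f"# duration_setting: {session.duration_setting}\n")
        stream.write(f"# nominal_rate: {session.nominal_rate:g}\n")
        if session.label:
            stream.write(f"# label: {session.label}\n")
        stream.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for frame in session.frames:
            cells = [f"{frame.timestamp:.6f}"]
            for col, ch in _CHANNEL_COLUMNS.items():
                cells.append(f"{frame.coeff.get(ch, 0.0):.6f}")
            cells.append("1" if frame.valid else "0")
            stream.write("\t".join(cells) + "\n")
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing session to {path_or_stream}: {exc}")
    finally:
        if should_close:
            stream.close()


def session_to_string(session: MeasurementSession) -> str:
    buf = io.StringIO()
    write_session(session, buf)
    return buf.getvalue()


# --------------------------------------------------------------------------
# History store: append-only JSON-lines file of scored measurements.


@dataclass(frozen=True)
class HistoryRecord:
    """One stored measurement: when it was taken, its label, its DFI."""

    recorded_at: str
    label: str
    dfi_left: float
    dfi_right: float
    delta_rel: Mapping[str, float]

    @classmethod
    def from_result(
        cls, result: DFIResult, recorded_at: str, label: str = ""
    ) -> "HistoryRecord":
        return cls(
            recorded_at=recorded_at,
            label=label,
            dfi_left=result.dfi[SideId.LEFT],
            dfi_right=result.dfi[SideId.RIGHT],
            delta_rel={
                r.value: asym.delta_rel for r, asym in result.regions.items()
            },
        )


class SessionHistory:
    """Append-only history of DFI measurements, one JSON record per line.

    JSON round-trips IEEE doubles exactly, so reloading reproduces every
    stored DFI value bit for bit.
    """

    def __init__(self, path) -> None:
        self.path = path

    def append(self, record: HistoryRecord) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(dataclasses.asdict(record)) + "\n")

    def load(self) -> list[HistoryRecord]:
        if not os.path.exists(self.path):
            return []
        records = []
        with open(self.path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(HistoryRecord(**json.loads(line)))
                except (json.JSONDecodeError, TypeError) as exc:
                    raise SessionFormatError(
                        f"{self.path}: bad history record at line "
                        f"{line_no}: {exc}"
                    ) from exc
        return records


# --------------------------------------------------------------------------
# Repeated-measures summary: group means/SDs and one-way ANOVA.


@dataclass(frozen=True)
class GroupStats:
    label: str
    n: int
    mean: float
    sd: float  # sample SD (n-1 denominator); 0.0 when n == 1


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    significant: bool  # at P <= .05
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass(frozen=True)
class RepeatedMeasuresSummary:
    groups: tuple[GroupStats, ...]
    anova: AnovaResult | None
    anova_omitted_reason: str | None = None


def summarize_repeats(
    groups: Mapping[str, Sequence[float]],
) -> RepeatedMeasuresSummary:
    """Per-group mean/SD plus a one-way ANOVA across groups.

    The ANOVA is the classic between/within sums-of-squares decomposition:
    ``F = MS_between / MS_within`` with ``df = (k-1, N-k)`` and the p-value
    from the F distribution's survival function.  Two degenerate cases are
    resolved explicitly: all groups constant with equal means gives F = 0
    (no evidence of a difference), while zero within-group variance with
    unequal means gives F = inf, p = 0, flagged as degenerate.
    """
    stats_out = []
    for label, values in groups.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        stats_out.append(
            GroupStats(label=label, n=int(arr.size), mean=float(arr.mean()), sd=sd)
        )

    if len(groups) < 2:
        return RepeatedMeasuresSummary(
            groups=tuple(stats_out),
            anova=None,
            anova_omitted_reason="ANOVA requires at least 2 groups",
        )

    arrays = [np.asarray(list(v), dtype=float) for v in groups.values()]
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    grand_mean = sum(a.sum() for a in arrays) / n_total
    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = k - 1
    df_within = n_total - k

    if df_within <= 0:
        return RepeatedMeasuresSummary(
            groups=tuple(stats_out),
            anova=None,
            anova_omitted_reason="no within-group degrees of freedom",
        )

    degenerate = False
    if ss_within == 0.0:
        if ss_between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, degenerate = math.inf, 0.0, True
    else:
        f_stat = (ss_between / df_between) / (ss_within / df_within)
        p = float(stats.f.sf(f_stat, df_between, df_within))

    return RepeatedMeasuresSummary(
        groups=tuple(stats_out),
        anova=AnovaResult(
            f=float(f_stat),
            df_between=df_between,
            df_within=df_within,
            p=p,
            significant=p <= 0.05,
            degenerate=degenerate,
        ),
    )
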