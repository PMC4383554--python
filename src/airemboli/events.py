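"""From detected Doppler signals to sized, phase-labelled bubbles.

The raw material is a time-sorted stream of high-intensity transient signals
per patient (time, side, MEBR).  This module applies the detection threshold
(signals must exceed background by at least 7 dB), identifies embolic
showers (rate above 5 emboli/s, where a common pre-shower background is
used), flags curtain intervals (showers too dense to resolve, excluded from
sizing), and converts each surviving event to a bubble diameter using the
patient's MCA diameter on that side and the haematocrit in effect at the
event time.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .acoustics import (
    AcousticContext,
    EmbolicEvent,
    InvalidInputError,
    SizedBubble,
    invert_mebr_batch,
    volume_of,
)

__all__ = [
    "PatientRecord",
    "SurgicalTimeline",
    "PatientSummary",
    "ShowerAnnotation",
    "filter_detections",
    "detect_showers",
    "mark_curtains",
    "haematocrit_at",
    "size_stream",
    "summarize_patient",
]

SHOWER_WINDOW_S = 1.0
SHOWER_RATE_THRESHOLD = 5.0   # emboli per second; a window must exceed this


@dataclass
class PatientRecord:
    """Per-patient context needed to size a stream and report a summary."""

    id: str
    mca_diameter_left: float    # mm
    mca_diameter_right: float   # mm
    procedure: str              # "CABG" | "MVR" | "AVR" | "combined"
    haematocrit_samples: list[tuple[float, float]]  # (time s, fraction), sorted
    bp_trace: list[tuple[float, float]] = field(default_factory=list)  # (time s, mmHg)
    signal_loss_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    monitoring_duration: float = 0.0   # s

    def __post_init__(self) -> None:
        for d in (self.mca_diameter_left, self.mca_diameter_right):
            if not 1.0 < d < 6.0:
                raise InvalidInputError(f"MCA diameter {d} mm outside (1, 6) mm")
        times = [t for t, _ in self.haematocrit_samples]
        if times != sorted(times):
            raise InvalidInputError("haematocrit samples must be sorted by time")
        for _, h in self.haematocrit_samples:
            if not 0.1 < h < 0.6:
                raise InvalidInputError(f"haematocrit {h} outside (0.1, 0.6)")

    def mca_diameter(self, side: str) -> float:
        return self.mca_diameter_left if side == "left" else self.mca_diameter_right


@dataclass
class SurgicalTimeline:
    """Ordered, contiguous, non-overlapping surgical stages."""

    stages: list[tuple[str, float, float]]   # (label, start s, end s)

    def __post_init__(self) -> None:
        for (la, sa, ea), (lb, sb, eb) in zip(self.stages, self.stages[1:]):
            if ea > sb:
                raise InvalidInputError(f"stages {la!r} and {lb!r} overlap")
        for label, s, e in self.stages:
            if e <= s:
                raise InvalidInputError(f"stage {label!r} has non-positive duration")

    def stage_at(self, t: float) -> str | None:
        for label, s, e in self.stages:
            if s <= t < e:
                return label
        return None


@dataclass
class PatientSummary:
    """Table-style per-patient roll-up of the analysis."""

    id: str
    n_emboli_left: int
    n_emboli_right: int
    total_volume: float                      # mL, both sides
    curtain_duration_left: float = 0.0       # s
    curtain_duration_right: float = 0.0
    signal_loss_left: float = 0.0            # min
    signal_loss_right: float = 0.0
    phase_medians: dict[str, float] = field(default_factory=dict)   # um per stage
    peak_affected_left: float | None = None  # % of terminal arterioles
    peak_affected_right: float | None = None
    procedure: str = ""

    def __post_init__(self) -> None:
        if self.n_emboli_left < 0 or self.n_emboli_right < 0:
            raise InvalidInputError("embolus counts must be >= 0")
        if self.total_volume < 0:
            raise InvalidInputError("total volume must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_emboli_left + self.n_emboli_right


@dataclass
class ShowerAnnotation:
    start: float
    end: float
    n_events: int
    background_time: float   # reference point just before shower onset


def _check_sorted(times) -> None:
    t = np.asarray(times, dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise InvalidInputError("events must be sorted by time")


def filter_detections(
    candidates: list[tuple[float, str, float]], threshold_db: float = 7.0
) -> list[EmbolicEvent]:
    """Keep candidate signals at or above the detection threshold (>= 7 dB).

    The threshold is applied to the measured MEBR as recorded, before any
    haematocrit normalisation.  Order is preserved.
    """
    _check_sorted([t for t, _, _ in candidates])
    return [
        EmbolicEvent(time=t, side=side, mebr=m)
        for t, side, m in candidates
        if m >= threshold_db
    ]


def detect_showers(
    events: list[EmbolicEvent],
    window: float = SHOWER_WINDOW_S,
    rate_threshold: float = SHOWER_RATE_THRESHOLD,
) -> list[ShowerAnnotation]:
    """Mark runs of events whose rate in a sliding window exceeds the threshold.

    Every event inside a shower gets ``background_window_start`` set to the
    moment just before the shower began, mirroring the practice of measuring
    one background level ahead of a dense burst.  Overlapping triggering
    windows are merged, so bursts separated by quiet gaps form distinct
    showers.  Events are annotated in place per side.
    """
    _check_sorted([e.time for e in events])
    showers: list[ShowerAnnotation] = []
    min_count = int(math.floor(rate_threshold * window)) + 1   # strictly exceeds
    for side in ("left", "right"):
        side_events = [e for e in events if e.side == side]
        times = [e.time for e in side_events]
        n = len(times)
        in_shower = [False] * n
        j = 0
        for i in range(n):
            # smallest j with times[i] - times[j] <= window
            j = bisect.bisect_left(times, times[i] - window, lo=j)
            if i - j + 1 >= min_count:
                for k in range(j, i + 1):
                    in_shower[k] = True
        # group flagged events into runs, splitting at gaps wider than the window
        i = 0
        while i < n:
            if not in_shower[i]:
                i += 1
                continue
            j = i
            while j + 1 < n and in_shower[j + 1] and times[j + 1] - times[j] <= window:
                j += 1
            bg = times[i]
            for k in range(i, j + 1):
                side_events[k].background_window_start = bg
            showers.append(
                ShowerAnnotation(
                    start=times[i], end=times[j], n_events=j - i + 1, background_time=bg
                )
            )
            i = j + 1
    showers.sort(key=lambda s: s.start)
    return showers


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mark_curtains(
    events: list[EmbolicEvent],
    curtain_intervals: dict[str, list[tuple[float, float]]],
) -> dict[str, float]:
    """Flag events inside curtain intervals and return total duration per side.

    Curtain-flagged events are excluded from sizing and simulation; only the
    curtain duration is reportable, since individual emboli cannot be
    resolved inside a curtain.  Overlapping intervals are merged.
    """
    durations: dict[str, float] = {}
    merged_by_side = {
        side: _merge_intervals(ivs) for side, ivs in curtain_intervals.items()
    }
    for side in ("left", "right"):
        merged = merged_by_side.get(side, [])
        durations[side] = sum(e - s for s, e in merged)
        for ev in events:
            if ev.side != side:
                continue
            if any(s <= ev.time <= e for s, e in merged):
                ev.curtain_member = True
    return durations


def haematocrit_at(patient: PatientRecord, t: float) -> float:
    """Haematocrit in effect at time ``t``: last observation carried forward."""
    samples = patient.haematocrit_samples
    if not samples:
        raise InvalidInputError(f"patient {patient.id}: no haematocrit samples")
    value = samples[0][1]
    for ts, h in samples:
        if ts <= t:
            value = h
        else:
            break
    return value


def size_stream(
    events: list[EmbolicEvent],
    patient: PatientRecord,
    side: str,
    timeline: SurgicalTimeline | None = None,
) -> list[SizedBubble | None]:
    """Size every non-curtain event on one side; order preserved.

    Each event is inverted under an acoustic context carrying that side's MCA
    diameter and the haematocrit in effect at the event time.  Events that
    cannot be sized yield ``None`` (flag-and-continue) rather than aborting
    the stream.  Inversion is batched over runs of events sharing the same
    haematocrit, which the piecewise-constant interpolation makes common.
    """
    side_events = [e for e in events if e.side == side and not e.curtain_member]
    if timeline is not None:
        for e in side_events:
            e.phase = timeline.stage_at(e.time)
    results: list[SizedBubble | None] = [None] * len(side_events)
    groups: dict[float, list[int]] = {}
    for i, e in enumerate(side_events):
        groups.setdefault(haematocrit_at(patient, e.time), []).append(i)
    for h, idxs in groups.items():
        ctx = AcousticContext(
            vessel_diameter=patient.mca_diameter(side), haematocrit=h
        )
        mebrs = [side_events[i].mebr for i in idxs]
        try:
            sized = invert_mebr_batch(mebrs, ctx)
        except InvalidInputError:
            sized = [None] * len(idxs)
        for i, sb in zip(idxs, sized):
            results[i] = sb
    return results


def summarize_patient(
    patient: PatientRecord,
    sized_left: list[SizedBubble | None],
    sized_right: list[SizedBubble | None],
    events_left: list[EmbolicEvent] | None = None,
    events_right: list[EmbolicEvent] | None = None,
    curtain_durations: dict[str, float] | None = None,
    peak_affected: dict[str, float] | None = None,
) -> PatientSummary:
    """Assemble the per-patient summary row.

    Counts are per side; total volume sums both sides.  Per-stage medians use
    the phase labels already attached to the events.  Peak affected-arteriole
    percentages are attached when simulation results are supplied.
    """
    left = [b for b in sized_left if b is not None]
    right = [b for b in sized_right if b is not None]
    total_volume = float(sum(b.volume for b in left) + sum(b.volume for b in right))

    phase_medians: dict[str, float] = {}
    if events_left is not None and events_right is not None:
        by_phase: dict[str, list[float]] = {}
        for evs, sized in ((events_left, sized_left), (events_right, sized_right)):
            non_curtain = [e for e in evs if not e.curtain_member]
            for e, b in zip(non_curtain, sized):
                if b is not None and e.phase is not None:
                    by_phase.setdefault(e.phase, []).append(b.diameter)
        phase_medians = {ph: float(np.median(ds)) for ph, ds in by_phase.items()}

    loss = patient.signal_loss_intervals
    loss_min = {
        side: sum(e - s for s, e in loss.get(side, [])) / 60.0
        for side in ("left", "right")
    }
    curtains = curtain_durations or {}
    peaks = peak_affected or {}
    return PatientSummary(
        id=patient.id,
        n_emboli_left=len(left),
        n_emboli_right=len(right),
        total_volume=total_volume,
        curtain_duration_left=curtains.get("left", 0.0),
        curtain_duration_right=curtains.get("right", 0.0),
        signal_loss_left=loss_min["left"],
        signal_loss_right=loss_min["right"],
        phase_medians=phase_medians,
        peak_affected_left=peaks.get("left"),
        peak_affected_right=peaks.get("right"),
        procedure=patient.procedure,
    )
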