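"""Neighbour-exchange (T1) detection and characterisation.

Detection works on quartets of tracked cells: the pair sharing an
interface before the swap (the losing diagonal) and the orthogonal pair
that gains contact.  Interfaces are made *immortal* — the identity of a
shortening interface transfers to the lengthening one after a swap — so
each quartet has exactly one owning diagonal in every frame: four-way
frames are assigned to the pair that most recently shared an interface,
and transient back-and-forth swaps shorter than five frames (2.5 min at
30-s frames) are smoothed away, shortest bouts first, before events are
counted.  A surviving ownership change is a "T1 gain", timed at the
frame the gaining pair first makes contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import CONTACT_EPS, EmbryoTracks

__all__ = [
    "QuartetSeries",
    "QuartetEvent",
    "ResolutionPhase",
    "ConnectivityError",
    "fill_owner_series",
    "smooth_owner_series",
    "events_from_series",
    "canonicalize_connectivity",
    "detect_t1_events",
    "t1_orientation",
    "gain_axis_class",
    "count_productive_t1s",
    "corrected_lost_gained_angle",
    "shortening_to_centroid_angle",
    "immortal_length_series",
    "resolution_phase_duration",
    "MIN_BOUT_FRAMES",
]

MIN_BOUT_FRAMES = 5          #: bouts shorter than this are reversed
DEFAULT_OFFSET_MIN = 5.0     #: pre/post measurement offset for orientations


class ConnectivityError(ValueError):
    """Tracked connectivity is topologically impossible for a quartet."""


@dataclass
class QuartetSeries:
    """Connectivity of one quartet over all frames, with immortal ownership.

    ``raw[f]`` is 1 if diagonal 1 physically owns the interface at frame
    ``f``, 2 for diagonal 2, ``None`` for a four-way (or zero-length)
    configuration.  ``owner[f]`` is the canonical ownership after
    four-way assignment and bout smoothing.
    """

    cells: frozenset
    diag1: tuple[int, int]
    diag2: tuple[int, int]
    frames: list[int]
    raw: list[int | None]
    owner: list[int] = field(default_factory=list)

    def pair(self, which: int) -> tuple[int, int]:
        return self.diag1 if which == 1 else self.diag2


@dataclass(frozen=True)
class QuartetEvent:
    """One detected T1 gain."""

    cells: frozenset
    losing_pair: tuple[int, int]
    gaining_pair: tuple[int, int]
    gain_frame: int


@dataclass(frozen=True)
class ResolutionPhase:
    start_frame: int
    end_frame: int            #: inclusive
    duration_min: float
    threshold_um: float


# ----------------------------------------------------------------------
# ownership-series core (pure functions; the rule oracle tests target these)
# ----------------------------------------------------------------------
def fill_owner_series(raw: list[int | None]) -> list[int]:
    """Assign four-way frames to the most recent owner.

    Leading unknown frames take the first known owner (a quartet whose
    record starts four-way cannot look further back).
    """
    known = [o for o in raw if o is not None]
    if not known:
        raise ValueError("owner series has no known frames")
    out: list[int] = []
    current = known[0]
    for o in raw:
        if o is not None:
            current = o
        out.append(current)
    return out


def _runs(series: list[int]) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (start, end_exclusive, value)."""
    runs = []
    start = 0
    for i in range(1, len(series) + 1):
        if i == len(series) or series[i] != series[start]:
            runs.append((start, i, series[start]))
            start = i
    return runs


def smooth_owner_series(
    filled: list[int], min_frames: int = MIN_BOUT_FRAMES
) -> list[int]:
    """Reverse transient ownership bouts, shortest first.

    A bout is a maximal run of frames whose owner differs from the
    (identical) stable owner both before and after it; runs at the
    series boundaries are never bouts.  Bouts shorter than
    ``min_frames`` are reversed — earliest first among equals — and the
    search repeats until none remain, so the result is idempotent.
    """
    s = list(filled)
    while True:
        runs = _runs(s)
        bouts = [
            (end - start, start, end)
            for k, (start, end, _val) in enumerate(runs)
            if 0 < k < len(runs) - 1 and runs[k - 1][2] == runs[k + 1][2]
            and (end - start) < min_frames
        ]
        if not bouts:
            return s
        _, start, end = min(bouts)
        s[start:end] = [s[start - 1]] * (end - start)


def events_from_series(q: QuartetSeries) -> list[QuartetEvent]:
    """Ownership changes surviving smoothing, timed at first contact."""
    events = []
    for i in range(1, len(q.owner)):
        if q.owner[i] != q.owner[i - 1]:
            gaining = q.owner[i]
            events.append(
                QuartetEvent(
                    cells=q.cells,
                    losing_pair=q.pair(q.owner[i - 1]),
                    gaining_pair=q.pair(gaining),
                    gain_frame=q.frames[i],
                )
            )
    return events


# ----------------------------------------------------------------------
# quartet discovery on tracks
# ----------------------------------------------------------------------
def canonicalize_connectivity(tracks: EmbryoTracks) -> list[QuartetSeries]:
    """Find swap-candidate quartets and canonicalise their ownership.

    A quartet is registered whenever a tracked interface disappears or
    appears between frames: its diagonals are the pair involved and the
    two common neighbours that complete the four-cell cycle.  For every
    quartet, the per-frame physical ownership is read off the interface
    table, four-way frames are assigned to the most recent owner, and
    transient bouts are smoothed.
    """
    frames = [int(f) for f in tracks.frames()]
    adj = {f: tracks.adjacency(f) for f in frames}
    neigh: dict[int, dict[int, set[int]]] = {}
    for f in frames:
        n: dict[int, set[int]] = {}
        for pair in adj[f]:
            a, b = tuple(pair)
            n.setdefault(a, set()).add(b)
            n.setdefault(b, set()).add(a)
        neigh[f] = n

    quartets: dict[tuple, tuple] = {}
    for f0, f1 in zip(frames[:-1], frames[1:]):
        changed = (adj[f0] - adj[f1]) | (adj[f1] - adj[f0])
        for pair in changed:
            a, b = tuple(pair)
            # common neighbours on the frame where the pair is connected
            ref = f0 if pair in adj[f0] else f1
            common = sorted(
                (neigh[ref].get(a, set()) & neigh[ref].get(b, set()))
            )
            if len(common) != 2:
                continue
            u, v = common
            key = frozenset((a, b, u, v))
            quartets.setdefault(
                tuple(sorted(key)), (key, tuple(sorted((a, b))), (u, v))
            )

    out = []
    for key, d1, d2 in quartets.values():
        raw: list[int | None] = []
        for f in frames:
            own1 = frozenset(d1) in adj[f]
            own2 = frozenset(d2) in adj[f]
            if own1 and own2:
                raise ConnectivityError(
                    f"both diagonals of quartet {sorted(key)} connected at frame {f}"
                )
            raw.append(1 if own1 else 2 if own2 else None)
        if all(o is None for o in raw):
            continue
        q = QuartetSeries(cells=key, diag1=d1, diag2=d2, frames=frames, raw=raw)
        q.owner = smooth_owner_series(fill_owner_series(raw))
        out.append(q)
    return out


def detect_t1_events(quartets: list[QuartetSeries]) -> list[QuartetEvent]:
    """All T1 gains across canonicalised quartets, sorted by gain frame."""
    events = [e for q in quartets for e in events_from_series(q)]
    return sorted(events, key=lambda e: (e.gain_frame, sorted(e.cells)))


# ----------------------------------------------------------------------
# angular measures
# ----------------------------------------------------------------------
def _offset_frames(tracks: EmbryoTracks, offset_min: float) -> int:
    return int(round(offset_min / tracks.frame_interval_min))


def _line_angle_deg(vec: np.ndarray) -> float:
    """Angle of an undirected line in degrees, in [0, 180)."""
    return float(np.degrees(np.arctan2(vec[1], vec[0]))) % 180.0


def _signed_line_diff(a_deg: float, b_deg: float) -> float:
    """Signed difference between undirected lines, in (-90, 90]."""
    return (a_deg - b_deg + 90.0) % 180.0 - 90.0


def _interface_vec(tracks: EmbryoTracks, frame: int, pair) -> np.ndarray | None:
    ends = tracks.interface_endpoints(frame).get(frozenset(pair))
    if ends is None:
        return None
    vec = ends[1] - ends[0]
    if np.linalg.norm(vec) <= CONTACT_EPS:
        return None
    return vec


def _centroid_vec(tracks: EmbryoTracks, frame: int, pair) -> np.ndarray | None:
    cents = tracks.centroids(frame)
    a, b = tuple(pair)
    if a not in cents or b not in cents:
        return None
    return cents[b] - cents[a]


def t1_orientation(
    event: QuartetEvent, tracks: EmbryoTracks, offset_min: float = DEFAULT_OFFSET_MIN
) -> float | None:
    """Orientation of the shortening interface ``offset_min`` before the gain.

    Angle to the AP axis in [0, 90]; ``None`` when the interface does
    not exist that far back (the event is then excluded from the
    statistic rather than erroring).
    """
    f = event.gain_frame - _offset_frames(tracks, offset_min)
    vec = _interface_vec(tracks, f, event.losing_pair)
    if vec is None:
        return None
    return tracks.axes.angle_to_ap(vec)


def gain_axis_class(event: QuartetEvent, tracks: EmbryoTracks) -> str | None:
    """'AP' or 'DV' by the gaining pair's centroid line versus 45 degrees."""
    vec = _centroid_vec(tracks, event.gain_frame, event.gaining_pair)
    if vec is None:
        return None
    return "AP" if tracks.axes.angle_to_ap(vec) < 45.0 else "DV"


def count_productive_t1s(
    events: list[QuartetEvent], tracks: EmbryoTracks
) -> pd.DataFrame:
    """Cumulative net productive swaps per frame, normalised.

    Productive swaps are DV-oriented gains (gaining centroid line more
    than 45° from AP) minus AP-oriented gains; the cumulative net count
    is divided by the number of DV-oriented interfaces present at each
    frame.  Frames with no DV-oriented interface get NaN.
    """
    frames = [int(f) for f in tracks.frames()]
    gains = {f: 0 for f in frames}
    for e in events:
        cls = gain_axis_class(e, tracks)
        if cls == "DV":
            gains[e.gain_frame] += 1
        elif cls == "AP":
            gains[e.gain_frame] -= 1
    rows = []
    cum = 0
    for f in frames:
        cum += gains[f]
        ends = tracks.interface_endpoints(f)
        n_dv = 0
        for pair, pts in ends.items():
            vec = pts[1] - pts[0]
            if np.linalg.norm(vec) > CONTACT_EPS and tracks.axes.angle_to_ap(vec) >= 45.0:
                n_dv += 1
        rows.append(
            {
                "frame": f,
                "net_gains": cum,
                "n_dv_interfaces": n_dv,
                "productive_per_dv_interface": cum / n_dv if n_dv else np.nan,
            }
        )
    return pd.DataFrame(rows)


def corrected_lost_gained_angle(
    event: QuartetEvent, tracks: EmbryoTracks, offset_min: float = DEFAULT_OFFSET_MIN
) -> float | None:
    """Rotation-corrected angle between lost and gained interfaces.

    The interfaces are measured ``offset_min`` before and after the
    gain; rigid rotation of the local quartet is removed by subtracting
    the rotation of the gaining pair's centroid–centroid line over the
    same period.  An idealised hexagonal T1 scores 90°.  Events whose
    measurement frames fall outside the track are excluded (``None``).
    """
    off = _offset_frames(tracks, offset_min)
    f_pre, f_post = event.gain_frame - off, event.gain_frame + off
    v_lost = _interface_vec(tracks, f_pre, event.losing_pair)
    v_gain = _interface_vec(tracks, f_post, event.gaining_pair)
    c_pre = _centroid_vec(tracks, f_pre, event.gaining_pair)
    c_post = _centroid_vec(tracks, f_post, event.gaining_pair)
    if v_lost is None or v_gain is None or c_pre is None or c_post is None:
        return None
    rot = _signed_line_diff(_line_angle_deg(c_post), _line_angle_deg(c_pre))
    diff = _signed_line_diff(_line_angle_deg(v_gain) - rot, _line_angle_deg(v_lost))
    return abs(diff)


def shortening_to_centroid_angle(
    event: QuartetEvent,
    tracks: EmbryoTracks,
    lookback_min: float = 15.0,
) -> list[tuple[int, float]]:
    """Angle between the shortening interface and the gaining centroid line.

    Evaluated at every frame from ``lookback_min`` before the gain up to
    the last pre-gain frame; frames where either quantity is missing are
    omitted.  An idealised hexagonal T1 scores 0° throughout.
    """
    off = _offset_frames(tracks, lookback_min)
    out = []
    for f in range(event.gain_frame - off, event.gain_frame):
        v = _interface_vec(tracks, f, event.losing_pair)
        c = _centroid_vec(tracks, f, event.gaining_pair)
        if v is None or c is None:
            continue
        out.append((f, abs(_signed_line_diff(_line_angle_deg(v), _line_angle_deg(c)))))
    return out


# ----------------------------------------------------------------------
# resolution phase
# ----------------------------------------------------------------------
def immortal_length_series(q: QuartetSeries, tracks: EmbryoTracks) -> np.ndarray:
    """Length of the quartet's immortal interface per frame (0 at four-ways)."""
    out = np.zeros(len(q.frames))
    for i, f in enumerate(q.frames):
        ln = tracks.interface_length(f, frozenset(q.pair(q.owner[i])))
        out[i] = 0.0 if ln is None else ln
    return out


def resolution_phase_duration(
    lengths: np.ndarray,
    frame_interval_s: float = 30.0,
    threshold_um: float = 0.75,
    smoothing_window: int = 5,
    swap_index: int | None = None,
) -> ResolutionPhase | None:
    """Duration of the sub-threshold interval straddling a swap.

    The length series (μm) is smoothed with a Hanning window to remove
    tracking noise, then the contiguous run of frames below
    ``threshold_um`` containing the swap (or, failing that, the series
    minimum) is measured.  Runs touching either end of the series are
    discarded: resolutions already under way when tracking begins, or
    unfinished when it ends, cannot be timed.
    """
    x = np.asarray(lengths, dtype=float)
    if smoothing_window > 1:
        w = np.hanning(smoothing_window)
        w = w / w.sum()
        pad = smoothing_window // 2
        xp = np.pad(x, pad, mode="edge")
        x = np.convolve(xp, w, mode="valid")
    below = x < threshold_um
    if not np.any(below):
        return None
    idx = swap_index if swap_index is not None else int(np.argmin(x))
    if not below[min(idx, len(below) - 1)]:
        return None
    i = min(idx, len(below) - 1)
    start = i
    while start > 0 and below[start - 1]:
        start -= 1
    end = i
    while end < len(below) - 1 and below[end + 1]:
        end += 1
    if start == 0 or end == len(below) - 1:
        return None  # clipped by the track boundary
    n = end - start + 1
    return ResolutionPhase(
        start_frame=start,
        end_frame=end,
        duration_min=n * frame_interval_s / 60.0,
        threshold_um=threshold_um,
    )
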