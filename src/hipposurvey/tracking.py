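"""Frame-overlay abundance estimation for a diving school.

A school total cannot be read off a single photo because a large fraction
of animals is submerged at any instant.  The estimator overlays a time
series of geo-referenced frames spanning longer than the maximum dive
(3-5 min for hippos), keeps a cumulative point layer, and matches each
frame's surfaced animals to existing tracks: matched tracks move to the new
position, unmatched surfacings open new tracks, and tracks are never
deleted when an animal dives.  The accumulated track count after the last
frame is the flight total.

Matching is greedy mutual-nearest-neighbour with a hard distance gate,
processed in increasing-distance order with deterministic tie-breaks — a
reproducible stand-in for the manual point editing the protocol was
developed with.  Frames are registered into one ground coordinate system
beforehand; :func:`estimate_transform` provides the least-squares 2-D
similarity (tie-point) registration used for real imagery.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .simulate import FramePointSet

__all__ = [
    "SimilarityTransform",
    "TransformEstimationError",
    "Track",
    "AccumulatedLayer",
    "estimate_transform",
    "accumulate",
    "estimate_flight_total",
]


class TransformEstimationError(RuntimeError):
    """Tie-point configuration too degenerate for a similarity transform."""


@dataclass(frozen=True)
class SimilarityTransform:
    """2-D similarity: x -> scale * R(angle) @ x + translation."""

    scale: float
    angle: float  # radians
    translation: tuple
    rms: float  # residual RMS (m) over the tie points

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.angle), math.sin(self.angle)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, float).reshape(-1, 2)
        return pts @ self.matrix.T + np.asarray(self.translation)


def estimate_transform(src, dst) -> SimilarityTransform:
    """Least-squares similarity transform from tie-point pairs (Umeyama).

    ``src`` and ``dst`` are (n, 2) matched coordinate arrays (n >= 3,
    not collinear).  Returns the transform mapping src onto dst together
    with the RMS residual; callers typically reject registrations whose
    RMS exceeds their accuracy budget (~0.5 m for drone tie points).
    """
    src = np.asarray(src, float).reshape(-1, 2)
    dst = np.asarray(dst, float).reshape(-1, 2)
    if src.shape != dst.shape:
        raise ValueError("src and dst must have the same shape")
    n = len(src)
    if n < 3:
        raise ValueError("need at least 3 tie-point pairs")
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    xs, xd = src - mu_s, dst - mu_d
    var_s = np.sum(xs**2) / n
    cov = xd.T @ xs / n
    U, D, Vt = np.linalg.svd(cov)
    if var_s <= 0 or D[1] / max(D[0], 1e-300) < 1e-10:
        raise TransformEstimationError(
            "tie points are collinear or coincident; similarity transform "
            "is not identifiable"
        )
    S = np.eye(2)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[1, 1] = -1.0
    R = U @ S @ Vt
    scale = np.trace(np.diag(D) @ S) / var_s
    t = mu_d - scale * R @ mu_s
    angle = math.atan2(R[1, 0], R[0, 0])
    tr = SimilarityTransform(float(scale), float(angle),
                             (float(t[0]), float(t[1])), 0.0)
    resid = tr.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SimilarityTransform(tr.scale, tr.angle, tr.translation, rms)


@dataclass
class Track:
    """One accumulated animal point: opened when first seen, never removed."""

    track_id: int
    first_frame: int
    position: np.ndarray  # last matched position
    n_matched: int = 1  # frames in which this track was matched (incl. first)

    def __post_init__(self):
        self.position = np.asarray(self.position, float)


@dataclass
class AccumulatedLayer:
    """Cumulative point layer over a frame sequence."""

    tracks: list = field(default_factory=list)
    frame_log: list = field(default_factory=list)  # per-frame match stats

    @property
    def total_estimate(self) -> int:
        return len(self.tracks)


def _match_frame(layer: AccumulatedLayer, frame: FramePointSet,
                 gate_radius: float) -> tuple[int, int]:
    """Greedy gated matching of one frame's points against the layer.

    Candidate (track, point) pairs within the gate are processed in
    increasing distance, ties broken by lower track index then lower point
    index; each track and each point is used at most once (this is exactly
    mutual-nearest-neighbour matching under the greedy order).
    """
    pts = frame.points
    n_matched = 0
    if len(layer.tracks) and len(pts):
        positions = np.array([t.position for t in layer.tracks])
        d = cdist(positions, pts)
        ti, pi = np.nonzero(d <= gate_radius)
        order = np.lexsort((pi, ti, d[ti, pi]))
        used_t = np.zeros(len(layer.tracks), bool)
        used_p = np.zeros(len(pts), bool)
        for k in order:
            a, b = ti[k], pi[k]
            if used_t[a] or used_p[b]:
                continue
            used_t[a] = used_p[b] = True
            layer.tracks[a].position = pts[b].copy()
            layer.tracks[a].n_matched += 1
            n_matched += 1
    else:
        used_p = np.zeros(len(pts), bool)
    n_new = 0
    for b in np.nonzero(~used_p)[0]:
        layer.tracks.append(
            Track(track_id=len(layer.tracks), first_frame=frame.frame_index,
                  position=pts[b])
        )
        n_new += 1
    return n_matched, n_new


def accumulate(frames, gate_radius: float = 5.0) -> AccumulatedLayer:
    """Run the cumulative tracker over a time-ordered frame sequence.

    ``gate_radius`` (m) bounds how far an animal may appear from its last
    matched position; the default of 5 m covers a hippo body length plus
    registration error.  Returns the accumulated layer; its
    ``total_estimate`` is the flight total.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("accumulate needs at least one frame")
    if gate_radius < 0:
        raise ValueError("gate_radius must be >= 0")
    ts = [f.timestamp for f in frames]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("frame timestamps must be strictly increasing")
    layer = AccumulatedLayer()
    for frame in frames:
        matched, new = _match_frame(layer, frame, gate_radius)
        layer.frame_log.append(
            {
                "frame_index": frame.frame_index,
                "points": len(frame.points),
                "matched": matched,
                "new": new,
                "missing": layer.total_estimate - matched - new,
            }
        )
    return layer


def estimate_flight_total(frames, gate_radius: float = 5.0,
                          min_frames: int = 15,
                          guarantee_window_s: float = 1500.0,
                          max_dive_s: float = 300.0) -> int:
    """Flight total from a full frame stack, with protocol checks.

    Requires at least ``min_frames`` frames; warns when the spanned window
    is shorter than the configured guarantee window or the maximum dive
    duration, in which case animals may never surface on camera and the
    estimate is a lower bound.
    """
    frames = list(frames)
    if len(frames) < min_frames:
        raise ValueError(
            f"need >= {min_frames} frames for a flight total, "
            f"got {len(frames)}"
        )
    span = frames[-1].timestamp - frames[0].timestamp
    if span < max(guarantee_window_s, max_dive_s):
        warnings.warn(
            f"frame stack spans {span:.0f} s, less than the coverage "
            f"guarantee window; estimate may miss animals",
            stacklevel=2,
        )
    return accumulate(frames, gate_radius).total_estimate
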