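"""Detection-based buffer-and-recover multi-animal tracker.

Per frame: detections are filtered by confidence and minimum box side,
deduplicated by greedy non-maximum suppression, then associated to the
constant-velocity Kalman predictions of live tracks by minimum-cost
(Hungarian) assignment on center distance, gated at a maximum pixel radius.
Matched tracks are corrected with the measurement; unmatched tracks coast on
their prediction for up to ``buffer_frames`` before termination; unmatched
detections spawn new tracks with strictly increasing, never reused ids.
The tracker contains no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


@dataclass
class Detection:
    box: np.ndarray          # (4,) x_min, y_min, x_max, y_max
    confidence: float
    class_index: int = 0
    frame: int = 0

    def __post_init__(self):
        self.box = np.asarray(self.box, float).reshape(4)
        if self.box[0] > self.box[2] or self.box[1] > self.box[3]:
            raise ValueError("detection box must satisfy min <= max")

    @property
    def center(self) -> np.ndarray:
        return np.array([(self.box[0] + self.box[2]) / 2, (self.box[1] + self.box[3]) / 2])

    @property
    def min_side(self) -> float:
        return float(min(self.box[2] - self.box[0], self.box[3] - self.box[1]))


@dataclass
class TrackerConfig:
    confidence_threshold: float = 0.5
    nms_threshold: float = 0.45
    min_box_side: float = 20.0
    gate_px: float = 100.0
    buffer_frames: int = 30
    min_hits_to_coast: int = 2   # detections required before a lost track keeps emitting
    process_noise: float = 1e-2
    measurement_noise: float = 1.0

    def __post_init__(self):
        if not (0 <= self.confidence_threshold <= 1 and 0 <= self.nms_threshold <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if self.gate_px <= 0 or self.buffer_frames <= 0:
            raise ValueError("gate and buffer must be positive")


# ---------------------------------------------------------------------------
# detection filtering


def iou(box_a: np.ndarray, box_b: np.ndarray) -> float:
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


def nms(detections: list[Detection], overlap_threshold: float) -> list[Detection]:
    """Greedy descending-confidence suppression; ties broken by input order."""
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].confidence, i))
    kept: list[int] = []
    for i in order:
        if all(iou(detections[i].box, detections[j].box) <= overlap_threshold for j in kept):
            kept.append(i)
    return [detections[i] for i in sorted(kept)]


def filter_detections(detections: list[Detection], config: TrackerConfig) -> list[Detection]:
    """Drop low-confidence detections and boxes with a side below the minimum."""
    return [
        d for d in detections
        if d.confidence >= config.confidence_threshold and d.min_side >= config.min_box_side
    ]


# ---------------------------------------------------------------------------
# constant-velocity Kalman filter (state: cx, cy, vx, vy; dt = 1 frame)


_F = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float)
_Hm = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)


@dataclass
class KalmanState:
    x: np.ndarray                 # (4,) cx, cy, vx, vy
    P: np.ndarray                 # (4, 4) covariance
    process_noise: float = 1e-2
    measurement_noise: float = 1.0

    @classmethod
    def from_measurement(cls, center, process_noise=1e-2, measurement_noise=1.0) -> "KalmanState":
        # diffuse prior: two updates then pin position and velocity exactly
        # (least-squares line through the first two measurements)
        x = np.array([center[0], center[1], 0.0, 0.0])
        P = np.diag([1e12, 1e12, 1e12, 1e12])
        return cls(x, P, process_noise, measurement_noise)


def kalman_predict(state: KalmanState) -> KalmanState:
    Q = np.diag([0.0, 0.0, state.process_noise, state.process_noise])
    x = _F @ state.x
    P = _F @ state.P @ _F.T + Q
    P = (P + P.T) / 2
    return KalmanState(x, P, state.process_noise, state.measurement_noise)


def kalman_update(state: KalmanState, measurement) -> KalmanState:
    z = np.asarray(measurement, float).reshape(2)
    R = np.eye(2) * state.measurement_noise
    S = _Hm @ state.P @ _Hm.T + R
    K = state.P @ _Hm.T @ np.linalg.inv(S)
    x = state.x + K @ (z - _Hm @ state.x)
    P = (np.eye(4) - K @ _Hm) @ state.P
    P = (P + P.T) / 2
    return KalmanState(x, P, state.process_noise, state.measurement_noise)


# ---------------------------------------------------------------------------
# association


def associate(
    predicted_centers: np.ndarray,
    detection_centers: np.ndarray,
    gate_px: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost one-to-one assignment on Euclidean center distance;
    pairs beyond the gate are forbidden.  Returns (matches, unmatched tracks,
    unmatched detections)."""
    n_t, n_d = len(predicted_centers), len(detection_centers)
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))
    cost = np.linalg.norm(
        np.asarray(predicted_centers)[:, None, :] - np.asarray(detection_centers)[None, :, :],
        axis=2,
    )
    big = gate_px * 1e6
    gated = np.where(cost <= gate_px, cost, big)
    rows, cols = linear_sum_assignment(gated)
    matches, un_t, un_d = [], set(range(n_t)), set(range(n_d))
    for r, c in zip(rows, cols):
        if cost[r, c] <= gate_px:
            matches.append((int(r), int(c)))
            un_t.discard(int(r))
            un_d.discard(int(c))
    return matches, sorted(un_t), sorted(un_d)


# ---------------------------------------------------------------------------
# track lifecycle


@dataclass
class Track:
    track_id: int
    state: KalmanState
    box: np.ndarray
    status: str = "active"          # active | lost | terminated
    frames_since_detection: int = 0
    hits: int = 1                   # detections absorbed so far
    history: list = field(default_factory=list)  # (frame, cx, cy)

    @property
    def center(self) -> np.ndarray:
        return self.state.x[:2]


class Tracker:
    """Stateful buffer-and-recover tracker; fold :meth:`step` over frames."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self._next_id = 1
        self.rows: list[dict] = []

    def step(self, frame: int, detections: list[Detection]) -> list[Track]:
        cfg = self.config
        dets = filter_detections(detections, cfg)
        dets = nms(dets, cfg.nms_threshold)
        live = [t for t in self.tracks if t.status != "terminated"]
        for t in live:
            t.state = kalman_predict(t.state)
        matches, un_t, un_d = associate(
            np.array([t.center for t in live]).reshape(-1, 2),
            np.array([d.center for d in dets]).reshape(-1, 2),
            cfg.gate_px,
        )
        for r, c in matches:
            t, d = live[r], dets[c]
            t.state = kalman_update(t.state, d.center)
            t.box = d.box.copy()
            t.status = "active"
            t.frames_since_detection = 0
            t.hits += 1
        for r in un_t:
            t = live[r]
            t.frames_since_detection += 1
            if t.frames_since_detection > cfg.buffer_frames:
                t.status = "terminated"
            else:
                t.status = "lost"
                # coast: keep the predicted position, shift the box with it
                shift = t.state.x[:2] - (t.box[:2] + t.box[2:]) / 2
                t.box = t.box + np.concatenate([shift, shift])
        for c in un_d:
            d = dets[c]
            state = kalman_update(
                KalmanState.from_measurement(d.center, cfg.process_noise, cfg.measurement_noise),
                d.center,
            )
            self.tracks.append(Track(self._next_id, state, d.box.copy()))
            self._next_id += 1
        out = [
            t for t in self.tracks
            if t.status == "active"
            or (t.status == "lost" and t.hits >= cfg.min_hits_to_coast)
        ]
        for t in out:
            cx, cy = t.center
            t.history.append((frame, float(cx), float(cy)))
            self.rows.append(
                {
                    "frame": frame, "track_id": t.track_id,
                    "cx": float(cx), "cy": float(cy),
                    "x_min": float(t.box[0]), "y_min": float(t.box[1]),
                    "x_max": float(t.box[2]), "y_max": float(t.box[3]),
                }
            )
        return out


def track_sequence(
    detection_stream: dict[int, list[Detection]] | list[list[Detection]],
    config: TrackerConfig | None = None,
) -> pd.DataFrame:
    """Fold the tracker over a frame-indexed detection stream into a track table
    with columns frame, track_id, cx, cy, x_min, y_min, x_max, y_max."""
    tracker = Tracker(config)
    if isinstance(detection_stream, dict):
        frames = sorted(detection_stream)
        items = [(f, detection_stream[f]) for f in frames]
    else:
        items = list(enumerate(detection_stream))
    for frame, dets in items:
        tracker.step(frame, dets)
    columns = ["frame", "track_id", "cx", "cy", "x_min", "y_min", "x_max", "y_max"]
    return pd.DataFrame(tracker.rows, columns=columns)


# ---------------------------------------------------------------------------
# CSV I/O


def read_detection_csv(path: str | Path) -> dict[int, list[Detection]]:
    """Load ``frame,x_min,y_min,x_max,y_max,confidence,class`` into a stream."""
    df = pd.read_csv(path)
    stream: dict[int, list[Detection]] = {}
    for row in df.itertuples(index=False):
        d = Detection(
            np.array([row.x_min, row.y_min, row.x_max, row.y_max]),
            float(row.confidence),
            int(getattr(row, "class", 0) if hasattr(row, "class") else getattr(row, "_6", 0)),
            int(row.frame),
        )
        stream.setdefault(int(row.frame), []).append(d)
    return stream


def write_detection_csv(stream: dict[int, list[Detection]], path: str | Path) -> None:
    rows = [
        {
            "frame": f, "x_min": d.box[0], "y_min": d.box[1],
            "x_max": d.box[2], "y_max": d.box[3],
            "confidence": d.confidence, "class": d.class_index,
        }
        for f in sorted(stream) for d in stream[f]
    ]
    pd.DataFrame(rows, columns=["frame", "x_min", "y_min", "x_max", "y_max", "confidence", "class"]).to_csv(
        path, index=False
    )
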