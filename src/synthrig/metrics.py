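"""Detection, tracking, pose and segmentation evaluation statistics.

* Center-based average precision: a detection is correct when its center lies
  within 5% of the image width of an unmatched ground-truth center; precision
  and recall are computed at 13 descending confidence thresholds equally spaced
  on [0.2, 0.8] and summed as AP = sum_n (R_n - R_{n-1}) P_n with the seed
  point R_0 = 0, P_0 = 1 (no trapezoidal interpolation).  mAP is the
  arithmetic mean of per-case APs.
* MOTA = 1 - (FN + FP + IDS) / total ground-truth detections, with Hungarian
  per-frame correspondence gated at d_max (50 px at 4k; 2% of frame width
  otherwise).  An identity switch is counted when a ground-truth id's matched
  track id changes; the new identity is then considered correct.  During
  overlap events (two or more ground-truth tracks closer than d_max)
  correspondence changes are suppressed while FN/FP still count.
* Pose error: mean pixel distance over keypoints above a confidence threshold
  (default 0.6), expressed relative to body length as a percentage.
* ACR: average class-wise recall over pixels, 100 * (y - (FP + FN)) / y
  averaged over images then classes.

Seeded simulators for detections and tracks provide synthetic fixtures for
testing the metric implementations and the tracker end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .tracker import Detection


class UndefinedMetricError(ValueError):
    """Raised when a metric has no defined value (e.g. no retained keypoints)."""


# ---------------------------------------------------------------------------
# average precision (center criterion)


@dataclass
class APConfig:
    thresholds: np.ndarray = field(
        default_factory=lambda: np.linspace(0.8, 0.2, 13)
    )  # descending
    center_tolerance_fraction: float = 0.05  # of image width

    def __post_init__(self):
        t = np.asarray(self.thresholds, float)
        if np.any(np.diff(t) >= 0):
            raise ValueError("thresholds must be strictly descending")
        self.thresholds = t


@dataclass
class APResult:
    precision: np.ndarray
    recall: np.ndarray
    ap: float


def _match_centers(
    det_centers: np.ndarray, det_conf: np.ndarray, gt: np.ndarray, tol: float
) -> int:
    """Greedy matching: detections in descending confidence order each take the
    nearest unmatched ground truth within tolerance.  Returns the TP count."""
    order = np.argsort(-det_conf, kind="stable")
    taken = np.zeros(len(gt), dtype=bool)
    tp = 0
    for i in order:
        d = np.linalg.norm(gt - det_centers[i], axis=1)
        d[taken] = np.inf
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol:
            taken[j] = True
            tp += 1
    return tp


def average_precision(
    detections: list[tuple[np.ndarray, float]] | np.ndarray,
    gt_centers: np.ndarray,
    image_width: float,
    config: APConfig | None = None,
) -> APResult:
    """Center-criterion AP over descending confidence thresholds.

    ``detections`` is a sequence of (center_xy, confidence).  The recall at
    the (virtual) first threshold is 0 and its precision 1, seeding the
    weighted sum AP = sum (R_n - R_{n-1}) P_n.
    """
    config = config or APConfig()
    gt = np.atleast_2d(np.asarray(gt_centers, float))
    if len(gt) == 0:
        raise UndefinedMetricError("average precision undefined for empty ground truth")
    if len(detections):
        centers = np.array([np.asarray(c, float) for c, _ in detections])
        conf = np.array([float(s) for _, s in detections])
    else:
        centers = np.zeros((0, 2))
        conf = np.zeros(0)
    tol = config.center_tolerance_fraction * image_width
    precisions, recalls = [], []
    for tau in config.thresholds:
        keep = conf >= tau
        n_det = int(keep.sum())
        if n_det == 0:
            precisions.append(1.0)
            recalls.append(0.0)
            continue
        tp = _match_centers(centers[keep], conf[keep], gt, tol)
        precisions.append(tp / n_det)
        recalls.append(tp / len(gt))
    ap = 0.0
    prev_r = 0.0
    for p, r in zip(precisions, recalls):
        ap += (r - prev_r) * p
        prev_r = r
    return APResult(np.array(precisions), np.array(recalls), float(ap))


def mean_average_precision(aps: list[float]) -> float:
    """Arithmetic mean of the per-case APs."""
    if not len(aps):
        raise UndefinedMetricError("mAP of an empty AP list is undefined")
    return float(np.mean(aps))


# ---------------------------------------------------------------------------
# MOTA


@dataclass
class MOTAConfig:
    d_max: float | None = None       # px; None -> 50 at 4k, else 2% of frame width
    frame_width: float = 3840.0

    def resolved_d_max(self) -> float:
        if self.d_max is not None:
            return float(self.d_max)
        if self.frame_width == 3840.0:
            return 50.0
        return 0.02 * self.frame_width


@dataclass
class MOTAResult:
    fn: int
    fp: int
    ids: int
    gt_total: int
    mota: float
    switch_events: list  # (frame, gt_id, old_inferred_id, new_inferred_id)
    overlap_frames: list


def _frame_table(df: pd.DataFrame) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for f, g in df.groupby("frame"):
        out[int(f)] = (g["track_id"].to_numpy(), g[["cx", "cy"]].to_numpy(float))
    return out


def mota(
    gt_tracks: pd.DataFrame,
    inferred_tracks: pd.DataFrame,
    config: MOTAConfig | None = None,
) -> MOTAResult:
    """Multiple object tracking accuracy with overlap-aware identity bookkeeping.

    Both tables need columns frame, track_id, cx, cy.  Per frame the ground
    truth is matched to inferred tracks by Hungarian assignment on center
    distance gated at d_max; unmatched ground truth counts FN, unmatched
    inferred counts FP.  Correspondence changes count one identity switch per
    reassigned ground-truth id — except during overlap events, where identity
    is only evaluated on exit so that transient swaps between nearby targets
    are suppressed (FN/FP still count).
    """
    config = config or MOTAConfig()
    d_max = config.resolved_d_max()
    gt_frames = _frame_table(gt_tracks)
    inf_frames = _frame_table(inferred_tracks)
    extra = set(inf_frames) - set(gt_frames)
    if extra:
        raise ValueError(f"inferred tracks contain frames outside the ground truth: {sorted(extra)[:5]}")
    fn = fp = ids = 0
    gt_total = 0
    corr: dict = {}
    switches = []
    overlap_frames = []
    for frame in sorted(gt_frames):
        g_ids, g_pos = gt_frames[frame]
        gt_total += len(g_ids)
        i_ids, i_pos = inf_frames.get(frame, (np.array([], dtype=int), np.zeros((0, 2))))
        # overlap event: any ground-truth pair closer than d_max
        overlap = False
        if len(g_pos) > 1:
            dd = np.linalg.norm(g_pos[:, None, :] - g_pos[None, :, :], axis=2)
            np.fill_diagonal(dd, np.inf)
            overlap = bool((dd < d_max).any())
        if overlap:
            overlap_frames.append(frame)
        if len(g_ids) and len(i_ids):
            cost = np.linalg.norm(g_pos[:, None, :] - i_pos[None, :, :], axis=2)
            gated = np.where(cost <= d_max, cost, d_max * 1e6)
            rows, cols = linear_sum_assignment(gated)
            matched = [(r, c) for r, c in zip(rows, cols) if cost[r, c] <= d_max]
        else:
            matched = []
        fn += len(g_ids) - len(matched)
        fp += len(i_ids) - len(matched)
        if overlap:
            continue  # identities evaluated only before/after the event
        for r, c in matched:
            g, i = g_ids[r], i_ids[c]
            if g in corr and corr[g] != i:
                ids += 1
                switches.append((frame, g, corr[g], i))
            corr[g] = i
    if gt_total == 0:
        raise UndefinedMetricError("MOTA undefined without ground-truth detections")
    value = 1.0 - (fn + fp + ids) / gt_total
    return MOTAResult(fn, fp, ids, gt_total, float(value), switches, overlap_frames)


# ---------------------------------------------------------------------------
# pose error


@dataclass
class PoseErrorResult:
    mean_px_error: float
    body_length: float
    relative_error_pct: float
    n_retained: int
    retained_fraction: float


def pose_error(
    gt_keypoints: np.ndarray,
    inferred_keypoints: np.ndarray,
    confidences: np.ndarray,
    body_length: float,
    confidence_threshold: float = 0.6,
) -> PoseErrorResult:
    """Mean pixel error over keypoints above the confidence threshold, and the
    body-length-relative percentage error 100 * mean_error / l."""
    if body_length <= 0:
        raise ValueError("body length must be positive")
    gt = np.atleast_2d(np.asarray(gt_keypoints, float))
    inf_ = np.atleast_2d(np.asarray(inferred_keypoints, float))
    conf = np.asarray(confidences, float).reshape(-1)
    if gt.shape != inf_.shape or len(conf) != len(gt):
        raise ValueError("keypoint arrays and confidences must align")
    keep = conf >= confidence_threshold
    if not keep.any():
        raise UndefinedMetricError(
            "no inferred keypoints above the confidence threshold; pose error undefined"
        )
    d = np.linalg.norm(gt[keep] - inf_[keep], axis=1)
    mean_px = float(d.mean())
    return PoseErrorResult(
        mean_px_error=mean_px,
        body_length=float(body_length),
        relative_error_pct=100.0 * mean_px / body_length,
        n_retained=int(keep.sum()),
        retained_fraction=float(keep.mean()),
    )


# ---------------------------------------------------------------------------
# average class-wise recall


@dataclass
class ACRResult:
    per_class_stats: dict  # class -> list of (gt pixels, FP, FN) per image
    acr: float


def acr(
    gt_maps: np.ndarray | list[np.ndarray],
    predicted_maps: np.ndarray | list[np.ndarray],
    classes: list[int],
) -> ACRResult:
    """Average class-wise recall: per class and image (y - (FP + FN)) / y where
    y is the class's ground-truth pixel count, FP the pixels falsely attributed
    to it, FN its pixels attributed elsewhere; averaged over images, then over
    classes, times 100."""
    if isinstance(gt_maps, np.ndarray) and gt_maps.ndim == 2:
        gt_maps, predicted_maps = [gt_maps], [predicted_maps]
    if len(gt_maps) != len(predicted_maps):
        raise ValueError("ground truth and prediction image counts differ")
    if not classes:
        raise ValueError("class list must be non-empty")
    stats: dict = {c: [] for c in classes}
    for g, p in zip(gt_maps, predicted_maps):
        g, p = np.asarray(g), np.asarray(p)
        if g.shape != p.shape:
            raise ValueError("label map dimensions differ")
        for c in classes:
            y = int((g == c).sum())
            if y == 0:
                raise ValueError(f"class {c} absent from a ground-truth map")
            fp_c = int(((p == c) & (g != c)).sum())
            fn_c = int(((g == c) & (p != c)).sum())
            stats[c].append((y, fp_c, fn_c))
    per_class = [
        float(np.mean([(y - (fp_c + fn_c)) / y for y, fp_c, fn_c in stats[c]]))
        for c in classes
    ]
    return ACRResult(stats, 100.0 * float(np.mean(per_class)))


# ---------------------------------------------------------------------------
# fixture simulators


def simulate_tracks(
    n_targets: int,
    n_frames: int,
    rng: np.random.Generator,
    image_size: tuple[float, float] = (3840.0, 2160.0),
    speed_range: tuple[float, float] = (1.0, 4.0),
    min_separation: float = 300.0,
) -> pd.DataFrame:
    """Constant-velocity ground-truth targets on a jittered grid.

    All targets share one velocity vector, so pairwise separations never change
    and targets spaced beyond ``min_separation`` never cross.
    """
    W, H = image_size
    cols = int(np.ceil(np.sqrt(n_targets)))
    rows_n = int(np.ceil(n_targets / cols))
    speed = rng.uniform(*speed_range)
    ang = rng.uniform(0, 2 * np.pi)
    vel = speed * np.array([np.cos(ang), np.sin(ang)])
    travel = np.abs(vel) * n_frames
    margin = travel + min_separation / 2
    xs = np.linspace(margin[0], W - margin[0], cols)
    ys = np.linspace(margin[1], H - margin[1], rows_n)
    starts = []
    for y in ys:
        for x in xs:
            starts.append(np.array([x, y]) + rng.uniform(-min_separation / 4, min_separation / 4, 2))
    starts = starts[:n_targets]
    rows = []
    for t in range(n_frames):
        for tid, s in enumerate(starts, start=1):
            c = s + vel * t
            rows.append({"frame": t, "track_id": tid, "cx": float(c[0]), "cy": float(c[1])})
    return pd.DataFrame(rows, columns=["frame", "track_id", "cx", "cy"])


def simulate_crossing_pair(
    n_frames: int,
    image_size: tuple[float, float] = (3840.0, 2160.0),
    speed: float = 10.0,
) -> pd.DataFrame:
    """Two targets whose straight paths cross at the sequence midpoint."""
    W, H = image_size
    mid = np.array([W / 2, H / 2])
    t_cross = n_frames / 2
    rows = []
    for tid, direction in ((1, np.array([1.0, 0.3])), (2, np.array([1.0, -0.3]))):
        d = direction / np.linalg.norm(direction) * speed
        start = mid - d * t_cross
        for t in range(n_frames):
            c = start + d * t
            rows.append({"frame": t, "track_id": tid, "cx": float(c[0]), "cy": float(c[1])})
    return pd.DataFrame(rows, columns=["frame", "track_id", "cx", "cy"])


def simulate_detections(
    gt_tracks: pd.DataFrame,
    rng: np.random.Generator,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    jitter_sigma: float = 0.0,
    box_size: float = 60.0,
    image_size: tuple[float, float] = (3840.0, 2160.0),
    true_conf_range: tuple[float, float] = (0.6, 1.0),
    fp_conf_range: tuple[float, float] = (0.2, 0.6),
) -> dict[int, list[Detection]]:
    """A noisy detector standing in for a trained network: each ground-truth
    center is emitted with probability 1 - fn_rate and Gaussian jitter; clutter
    false positives arrive Poisson(fp_rate) per frame, uniform in the image."""
    W, H = image_size
    stream: dict[int, list[Detection]] = {}
    half = box_size / 2
    for frame, g in gt_tracks.groupby("frame"):
        frame = int(frame)
        dets = []
        for row in g.itertuples(index=False):
            if rng.random() < fn_rate:
                continue
            c = np.array([row.cx, row.cy]) + rng.normal(0, jitter_sigma, 2)
            dets.append(
                Detection(
                    np.array([c[0] - half, c[1] - half, c[0] + half, c[1] + half]),
                    float(rng.uniform(*true_conf_range)), 0, frame,
                )
            )
        for _ in range(int(rng.poisson(fp_rate))):
            c = np.array([rng.uniform(0, W), rng.uniform(0, H)])
            dets.append(
                Detection(
                    np.array([c[0] - half, c[1] - half, c[0] + half, c[1] + half]),
                    float(rng.uniform(*fp_conf_range)), 0, frame,
                )
            )
        stream[frame] = dets
    return stream


def tracks_to_gt_detections(gt_tracks: pd.DataFrame) -> dict[int, list[tuple[np.ndarray, float]]]:
    """Per-frame (center, confidence=1.0) pairs from a ground-truth track table."""
    out: dict[int, list] = {}
    for row in gt_tracks.itertuples(index=False):
        out.setdefault(int(row.frame), []).append((np.array([row.cx, row.cy]), 1.0))
    return out
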