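"""Per-sample ground truth and the human-readable annotation files.

Each rendered sample is accompanied by a JSON sample file holding the camera
(position, rotation, diagonal FOV, 4x4 view-projection, depth encoding range)
and one record per subject: the bounding box (the smallest rectangle enclosing
all projected 2D keypoints, clipped to the image), per-keypoint 2D pixel and
camera-relative 3D coordinates with a visibility flag derived from the ID and
depth passes, and the occupancy fraction (own ID-pixels over box area).  A
single batch JSON describes the whole dataset and its population.

Layout: ``<out>/<dataset>/{batch.json, passes/{render,id,depth,normal,normal_world}/NNNNNN.png,
samples/NNNNNN.json}``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .rendering import CameraModel, PassSet, project
from .scene_generation import Scene

VISIBILITY = ("visible", "occluded", "out_of_frame")
OUT_OF_FRAME_XY = [-1.0, -1.0]  # sentinel for points with no valid projection


class AnnotationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# records


@dataclass
class KeypointRecord:
    name: str
    xy: list          # [x, y] px
    xyz_cam: list     # camera-relative 3D, world units
    visibility: str


@dataclass
class SubjectRecord:
    instance_id: int
    class_name: str
    bbox: list        # [x_min, y_min, x_max, y_max] px, clipped
    occupancy: float
    keypoints: list   # of KeypointRecord
    bbox_empty: bool = False


@dataclass
class CameraRecord:
    position: list
    rotation: list
    fov_diagonal_deg: float
    view_projection: list  # 4x4 nested list
    depth_near: float
    depth_far: float


@dataclass
class SampleAnnotation:
    sample_id: int
    camera: CameraRecord
    subjects: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BatchAnnotation:
    dataset_name: str
    n_samples: int
    seed: int
    pass_width: int
    pass_height: int
    subjects: list  # of dicts {instance_id, id_color[3], class_name, scale}

    def validate(self) -> None:
        ids = [s["instance_id"] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate instance_id in batch subject table")
        for s in self.subjects:
            if tuple(s["id_color"]) == (0, 0, 0):
                raise AnnotationError(
                    f"instance {s['instance_id']}: id_color (0,0,0) is reserved for background"
                )


# ---------------------------------------------------------------------------
# ground-truth computation


def compute_bbox(
    keypoints_2d: np.ndarray, image_dims: tuple[int, int]
) -> tuple[list, bool]:
    """Smallest rectangle enclosing all projected keypoints, clipped to the image.

    Returns ([x_min, y_min, x_max, y_max], empty_flag); the flag is set when the
    raw rectangle lies fully outside the image.
    """
    pts = np.atleast_2d(np.asarray(keypoints_2d, float))
    if len(pts) == 0:
        raise AnnotationError("compute_bbox requires at least one keypoint")
    W, H = image_dims
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    if x1 < 0 or y1 < 0 or x0 > W or y0 > H:
        return [0.0, 0.0, 0.0, 0.0], True
    return [
        float(np.clip(x0, 0, W)), float(np.clip(y0, 0, H)),
        float(np.clip(x1, 0, W)), float(np.clip(y1, 0, H)),
    ], False


def keypoint_visibility(
    xy: np.ndarray,
    kp_depth: float,
    id_pass: np.ndarray,
    depth_pass: np.ndarray,
    id_color: tuple[int, int, int],
    depth_tol: float = 0.01,
) -> str:
    """visible iff a 3x3 neighborhood pixel carries the subject's ID color at a
    depth within ``depth_tol`` (relative) of the keypoint's own depth."""
    H, W = depth_pass.shape
    x, y = int(np.floor(xy[0])), int(np.floor(xy[1]))
    if x < 0 or y < 0 or x >= W or y >= H or kp_depth <= 0:
        return "out_of_frame"
    y0, y1 = max(0, y - 1), min(H, y + 2)
    x0, x1 = max(0, x - 1), min(W, x + 2)
    patch_id = id_pass[y0:y1, x0:x1]
    patch_depth = depth_pass[y0:y1, x0:x1]
    match = np.all(patch_id == np.asarray(id_color, dtype=patch_id.dtype), axis=2)
    close = np.abs(patch_depth - kp_depth) <= depth_tol * kp_depth
    return "visible" if np.any(match & close) else "occluded"


def occupancy(id_pass: np.ndarray, box: list, id_color: tuple[int, int, int]) -> float:
    """Fraction of the box's pixels carrying the subject's ID color."""
    x0, y0, x1, y1 = box
    H, W = id_pass.shape[:2]
    ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
    ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
    ix1, iy1 = max(ix1, ix0 + 1), max(iy1, iy0 + 1)
    ix0, iy0 = np.clip(ix0, 0, W - 1), np.clip(iy0, 0, H - 1)
    ix1, iy1 = np.clip(ix1, ix0 + 1, W), np.clip(iy1, iy0 + 1, H)
    area = (ix1 - ix0) * (iy1 - iy0)
    if area <= 0:
        raise AnnotationError("occupancy of an empty box is undefined")
    patch = id_pass[iy0:iy1, ix0:ix1]
    count = int(np.all(patch == np.asarray(id_color, dtype=patch.dtype), axis=2).sum())
    return count / area


def annotate_sample(
    scene: Scene,
    camera: CameraModel,
    passes: PassSet,
    sample_id: int,
    near: float = 0.05,
    far: float = 200.0,
) -> SampleAnnotation:
    """Full ground truth for one rendered scene."""
    W, H = camera.resolution
    V = camera.view_matrix()
    cam_rec = CameraRecord(
        position=[float(v) for v in camera.position],
        rotation=[float(v) for v in camera.rotation],
        fov_diagonal_deg=camera.fov_diagonal_deg(),
        view_projection=[[float(v) for v in row] for row in camera.view_projection(near, far)],
        depth_near=float(near),
        depth_far=float(far),
    )
    subjects = []
    for s in scene.subjects:
        names = list(s.keypoints_world.keys())
        world = np.array([s.keypoints_world[n] for n in names])
        xy, z, behind = project(camera, world)
        cam_pts = world @ V[:3, :3].T + V[:3, 3]
        kps, bbox_pts = [], []
        for i, n in enumerate(names):
            if behind[i]:
                kps.append(KeypointRecord(n, list(OUT_OF_FRAME_XY), [float(v) for v in cam_pts[i]], "out_of_frame"))
                continue
            vis = keypoint_visibility(xy[i], float(z[i]), passes.id, passes.depth, s.instance.id_color)
            kps.append(
                KeypointRecord(n, [float(xy[i, 0]), float(xy[i, 1])], [float(v) for v in cam_pts[i]], vis)
            )
            bbox_pts.append(xy[i])
        if bbox_pts:
            box, empty = compute_bbox(np.array(bbox_pts), (W, H))
        else:
            box, empty = [0.0, 0.0, 0.0, 0.0], True
        occ = 0.0 if empty else occupancy(passes.id, box, s.instance.id_color)
        subjects.append(
            SubjectRecord(
                instance_id=s.instance.instance_id,
                class_name=s.instance.model.class_name,
                bbox=box,
                occupancy=float(occ),
                keypoints=kps,
                bbox_empty=bool(empty),
            )
        )
    return SampleAnnotation(sample_id=sample_id, camera=cam_rec, subjects=subjects)


# ---------------------------------------------------------------------------
# JSON round trips


def write_sample(annotation: SampleAnnotation, path: str | Path) -> None:
    Path(path).write_text(json.dumps(annotation.to_dict(), indent=1))


def read_sample(path: str | Path) -> SampleAnnotation:
    data = json.loads(Path(path).read_text())
    for key in ("sample_id", "camera", "subjects"):
        if key not in data:
            raise AnnotationError(f"sample file missing '{key}'")
    cam = data["camera"]
    for key in ("position", "rotation", "fov_diagonal_deg", "view_projection", "depth_near", "depth_far"):
        if key not in cam:
            raise AnnotationError(f"sample camera missing '{key}'")
    vp = cam["view_projection"]
    if len(vp) != 4 or any(len(row) != 4 for row in vp):
        raise AnnotationError("view_projection must be a 4x4 matrix")
    subjects = []
    for s in data["subjects"]:
        for key in ("instance_id", "class_name", "bbox", "occupancy", "keypoints"):
            if key not in s:
                raise AnnotationError(f"subject record missing '{key}'")
        kps = []
        for k in s["keypoints"]:
            for key in ("name", "xy", "xyz_cam", "visibility"):
                if key not in k:
                    raise AnnotationError(f"keypoint record missing '{key}'")
            if k["visibility"] not in VISIBILITY:
                raise AnnotationError(f"unknown visibility '{k['visibility']}'")
            kps.append(KeypointRecord(k["name"], k["xy"], k["xyz_cam"], k["visibility"]))
        subjects.append(
            SubjectRecord(
                s["instance_id"], s["class_name"], s["bbox"], s["occupancy"], kps,
                s.get("bbox_empty", False),
            )
        )
    return SampleAnnotation(
        data["sample_id"],
        CameraRecord(
            cam["position"], cam["rotation"], cam["fov_diagonal_deg"],
            cam["view_projection"], cam["depth_near"], cam["depth_far"],
        ),
        subjects,
    )


def write_batch(batch: BatchAnnotation, path: str | Path) -> None:
    batch.validate()
    Path(path).write_text(json.dumps(asdict(batch), indent=1))


def read_batch(path: str | Path) -> BatchAnnotation:
    data = json.loads(Path(path).read_text())
    for key in ("dataset_name", "n_samples", "seed", "pass_width", "pass_height", "subjects"):
        if key not in data:
            raise AnnotationError(f"batch file missing '{key}'")
    batch = BatchAnnotation(
        data["dataset_name"], data["n_samples"], data["seed"],
        data["pass_width"], data["pass_height"], data["subjects"],
    )
    batch.validate()
    return batch


# ---------------------------------------------------------------------------
# image-pass files


PASS_DIRS = ("render", "id", "depth", "normal", "normal_world")


def write_passes(
    passes: PassSet,
    dataset_dir: str | Path,
    index: int,
    near: float,
    far: float,
    render_format: str = "png",
    jpg_quality: int | None = None,
) -> None:
    """Write the pass images; render as PNG or JPG, data passes always
    uncompressed PNG (depth as 16-bit with linear near/far mapping)."""
    root = Path(dataset_dir) / "passes"
    name = f"{index:06d}"
    for d in PASS_DIRS:
        (root / d).mkdir(parents=True, exist_ok=True)
    render8 = (np.clip(passes.render, 0, 1) * 255).round().astype(np.uint8)
    if render_format == "jpg":
        Image.fromarray(render8).save(root / "render" / f"{name}.jpg", quality=jpg_quality or 90)
    else:
        Image.fromarray(render8).save(root / "render" / f"{name}.png", compress_level=1)
    Image.fromarray(passes.id).save(root / "id" / f"{name}.png", compress_level=1)
    d = np.clip((passes.depth - near) / (far - near), 0, 1)
    d[~np.isfinite(passes.depth)] = 1.0
    Image.fromarray((d * 65535).round().astype(np.uint16)).save(
        root / "depth" / f"{name}.png", compress_level=1
    )
    for key, arr in (("normal", passes.normal_view), ("normal_world", passes.normal_world)):
        Image.fromarray((np.clip(arr, 0, 1) * 255).round().astype(np.uint8)).save(
            root / key / f"{name}.png", compress_level=1
        )


def read_id_pass(dataset_dir: str | Path, index: int) -> np.ndarray:
    return np.asarray(Image.open(Path(dataset_dir) / "passes" / "id" / f"{index:06d}.png"))


def read_depth_pass(dataset_dir: str | Path, index: int, near: float, far: float) -> np.ndarray:
    raw = np.asarray(Image.open(Path(dataset_dir) / "passes" / "depth" / f"{index:06d}.png"))
    return near + raw.astype(float) / 65535.0 * (far - near)


# ---------------------------------------------------------------------------
# dataset handle


class Dataset:
    """Read access to a generated dataset directory."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.batch = read_batch(self.root / "batch.json")

    @property
    def n_samples(self) -> int:
        return self.batch.n_samples

    def sample(self, index: int) -> SampleAnnotation:
        return read_sample(self.root / "samples" / f"{index:06d}.json")

    def samples(self):
        for i in range(self.n_samples):
            yield i, self.sample(i)

    def id_pass(self, index: int) -> np.ndarray:
        return read_id_pass(self.root, index)

    def render_path(self, index: int) -> Path:
        d = self.root / "passes" / "render"
        for ext in ("png", "jpg"):
            p = d / f"{index:06d}.{ext}"
            if p.exists():
                return p
        raise FileNotFoundError(f"no render pass for sample {index}")

    def id_color_of(self, instance_id: int) -> tuple[int, int, int]:
        for s in self.batch.subjects:
            if s["instance_id"] == instance_id:
                return tuple(s["id_color"])
        raise KeyError(instance_id)
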