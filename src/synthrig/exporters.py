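"""Dataset exporters: YOLO boxes, COCO (detection + keypoints + masks), flat
keypoint tables for pose-estimation trainers, semantic-segmentation label maps,
and a camera-aware 3D pose format.

All exporters are read-only over the source dataset.  Occluded keypoints and
fully occluded subjects can be excluded with config toggles; COCO keypoint
visibility uses v=2 visible, v=1 occluded, v=0 out of frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotation_io import Dataset


@dataclass
class ExportConfig:
    exclude_occluded_keypoints: bool = False
    exclude_occluded_subjects: bool = True
    split_fraction: float = 0.8
    split_seed: int = 0
    mask_encoding: str = "rle"   # per_pixel | polygon | rle


# ---------------------------------------------------------------------------
# splits


def split_dataset(n_samples: int, fraction: float, seed: int) -> tuple[list[int], list[int]]:
    """Deterministic shuffled train/validation split; disjoint and exhaustive."""
    if not (0 < fraction < 1):
        raise ValueError("split fraction must lie in the open interval (0, 1)")
    idx = np.random.default_rng(seed).permutation(n_samples)
    cut = int(round(fraction * n_samples))
    return sorted(int(i) for i in idx[:cut]), sorted(int(i) for i in idx[cut:])


# ---------------------------------------------------------------------------
# YOLO


def to_yolo(dataset: Dataset, out_dir: str | Path, config: ExportConfig | None = None) -> dict:
    """Darknet-dialect labels: per image one text file of
    ``class_index cx cy w h`` lines normalized to [0,1] at 6 decimals,
    plus classes.txt and an image list.  Returns counts (written / skipped)."""
    config = config or ExportConfig()
    out = Path(out_dir)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    W, H = dataset.batch.pass_width, dataset.batch.pass_height
    classes = sorted({s["class_name"] for s in dataset.batch.subjects})
    class_index = {c: i for i, c in enumerate(classes)}
    written = skipped = 0
    image_list = []
    for i, sample in dataset.samples():
        lines = []
        for s in sample.subjects:
            if s.bbox_empty or (config.exclude_occluded_subjects and s.occupancy == 0):
                skipped += 1
                continue
            x0, y0, x1, y1 = s.bbox
            cx, cy = (x0 + x1) / 2 / W, (y0 + y1) / 2 / H
            w, h = (x1 - x0) / W, (y1 - y0) / H
            lines.append(f"{class_index[s.class_name]} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
            written += 1
        (out / "labels" / f"{i:06d}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
        image_list.append(str(dataset.render_path(i)))
    (out / "classes.txt").write_text("\n".join(classes) + "\n")
    (out / "images.txt").write_text("\n".join(image_list) + "\n")
    return {"written": written, "skipped": skipped}


def parse_yolo_labels(path: str | Path, image_dims: tuple[int, int]) -> list[tuple[int, list]]:
    """Read one YOLO label file back into (class_index, [x0, y0, x1, y1]) pixels."""
    W, H = image_dims
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        c, cx, cy, w, h = line.split()
        cx, cy, w, h = float(cx) * W, float(cy) * H, float(w) * W, float(h) * H
        out.append((int(c), [cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2]))
    return out


# ---------------------------------------------------------------------------
# COCO-style run-length encoding (column-major, starting with the zero run)


def rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=np.uint8).flatten(order="F")
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=np.uint8)
    pos, val = 0, 0
    for c in rle["counts"]:
        flat[pos:pos + c] = val
        pos += c
        val ^= 1
    return flat.reshape((h, w), order="F")


def mask_to_polygons(mask: np.ndarray, tolerance: float = 1.0) -> list[list[float]]:
    """Trace mask contours (marching squares) into COCO polygon lists,
    simplified to <= ``tolerance`` px."""
    from shapely.geometry import Polygon
    from skimage import measure

    polys = []
    padded = np.pad(mask.astype(float), 1)
    for contour in measure.find_contours(padded, 0.5):
        pts = contour[:, ::-1] - 1.0  # (row, col) -> (x, y), un-pad
        if len(pts) < 3:
            continue
        poly = Polygon(pts)
        if tolerance > 0:
            poly = poly.simplify(tolerance, preserve_topology=True)
        if poly.is_empty or poly.area < 1:
            continue
        xy = np.asarray(poly.exterior.coords[:-1]).ravel()
        if len(xy) >= 6:
            polys.append([float(v) for v in xy])
    return polys


def subject_mask(id_pass: np.ndarray, id_color: tuple[int, int, int]) -> np.ndarray:
    return np.all(id_pass[:, :, :3] == np.asarray(id_color, dtype=id_pass.dtype), axis=2)


def to_coco(dataset: Dataset, out_path: str | Path, config: ExportConfig | None = None) -> dict:
    """Single COCO JSON with images, categories (with keypoint names), and
    per-subject annotations: bbox [x,y,w,h], flattened keypoint triplets,
    segmentation (RLE or polygons), area = ID-pixel count."""
    config = config or ExportConfig()
    if config.mask_encoding not in ("rle", "polygon", "per_pixel"):
        raise ValueError(f"unknown mask encoding '{config.mask_encoding}'")
    vis_map = {"visible": 2, "occluded": 1, "out_of_frame": 0}
    classes = sorted({s["class_name"] for s in dataset.batch.subjects})
    first = dataset.sample(0) if dataset.n_samples else None
    kp_names = [k.name for k in first.subjects[0].keypoints] if first and first.subjects else []
    coco = {
        "images": [],
        "annotations": [],
        "categories": [
            {"id": ci + 1, "name": c, "keypoints": kp_names, "skeleton": []}
            for ci, c in enumerate(classes)
        ],
    }
    cat_id = {c: ci + 1 for ci, c in enumerate(classes)}
    ann_id = 0
    W, H = dataset.batch.pass_width, dataset.batch.pass_height
    for i, sample in dataset.samples():
        coco["images"].append(
            {"id": i, "file_name": dataset.render_path(i).name, "width": W, "height": H}
        )
        id_pass = dataset.id_pass(i)
        for s in sample.subjects:
            if s.bbox_empty or (config.exclude_occluded_subjects and s.occupancy == 0):
                continue
            mask = subject_mask(id_pass, dataset.id_color_of(s.instance_id))
            area = int(mask.sum())
            if config.mask_encoding == "polygon":
                seg = mask_to_polygons(mask)
            else:  # rle / per_pixel both serialize as uncompressed RLE
                seg = rle_encode(mask)
            flat_kp, n_labeled = [], 0
            for k in s.keypoints:
                v = vis_map[k.visibility]
                if config.exclude_occluded_keypoints and k.visibility == "occluded":
                    v = 0
                if v == 0:
                    flat_kp += [0.0, 0.0, 0]
                else:
                    flat_kp += [k.xy[0], k.xy[1], v]
                    n_labeled += 1
            x0, y0, x1, y1 = s.bbox
            ann_id += 1
            coco["annotations"].append(
                {
                    "id": ann_id,
                    "image_id": i,
                    "category_id": cat_id[s.class_name],
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": area,
                    "iscrowd": 0,
                    "segmentation": seg,
                    "keypoints": flat_kp,
                    "num_keypoints": n_labeled,
                }
            )
    Path(out_path).write_text(json.dumps(coco))
    return coco


# ---------------------------------------------------------------------------
# keypoint tables (DeepLabCut / SLEAP-style wide CSV)


def to_keypoint_table(
    dataset: Dataset, out_dir: str | Path, config: ExportConfig | None = None
) -> pd.DataFrame:
    """Wide table: one row per (image, instance); per keypoint x / y /
    likelihood columns (likelihood 1.0 for visible ground truth); occluded
    points blank when exclusion is on.  A skeleton JSON lists keypoint order
    and armature connections."""
    config = config or ExportConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, index = [], []
    kp_names: list[str] = []
    for i, sample in dataset.samples():
        for s in sample.subjects:
            if not kp_names:
                kp_names = [k.name for k in s.keypoints]
            row = {}
            for k in s.keypoints:
                hidden = k.visibility == "out_of_frame" or (
                    config.exclude_occluded_keypoints and k.visibility == "occluded"
                )
                row[(k.name, "x")] = np.nan if hidden else k.xy[0]
                row[(k.name, "y")] = np.nan if hidden else k.xy[1]
                row[(k.name, "likelihood")] = np.nan if hidden else 1.0
            rows.append(row)
            index.append((f"{i:06d}", s.instance_id))
    columns = pd.MultiIndex.from_tuples(
        [(n, c) for n in kp_names for c in ("x", "y", "likelihood")],
        names=["keypoint", "coord"],
    )
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=["image", "instance"]))
    df = df.reindex(columns=columns)
    df.to_csv(out / "keypoints.csv")
    skeleton = {"keypoints": kp_names, "connections": _armature_connections(dataset)}
    (out / "skeleton.json").write_text(json.dumps(skeleton, indent=1))
    return df


def _armature_connections(dataset: Dataset) -> list[list[str]]:
    # connections are keypoint pairs whose bones are parent/child; without the
    # model at hand, fall back to a chain in keypoint order per class
    if dataset.n_samples == 0:
        return []
    sample = dataset.sample(0)
    if not sample.subjects:
        return []
    names = [k.name for k in sample.subjects[0].keypoints]
    return [[a, b] for a, b in zip(names[:-1], names[1:])]


def read_keypoint_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, header=[0, 1], index_col=[0, 1])


# ---------------------------------------------------------------------------
# segmentation label maps


def to_segmentation_maps(
    dataset: Dataset, out_dir: str | Path, per_class: bool = False
) -> list[Path]:
    """8-bit single-channel label maps: 0 background, 1 any subject (binary
    default), or class_name -> 1..K in per-class mode."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classes = sorted({s["class_name"] for s in dataset.batch.subjects})
    if per_class and len(classes) > 255:
        raise ValueError("more than 255 classes cannot be encoded in 8 bits")
    label_of = {c: i + 1 for i, c in enumerate(classes)}
    color_class = {
        tuple(s["id_color"]): label_of[s["class_name"]] for s in dataset.batch.subjects
    }
    paths = []
    for i in range(dataset.n_samples):
        id_pass = dataset.id_pass(i)
        label = np.zeros(id_pass.shape[:2], dtype=np.uint8)
        if per_class:
            for color, cls in color_class.items():
                label[subject_mask(id_pass, color)] = cls
        else:
            label[np.any(id_pass[:, :, :3] != 0, axis=2)] = 1
        p = out / f"{i:06d}.png"
        Image.fromarray(label).save(p)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# 3D pose


def to_pose3d(dataset: Dataset, out_path: str | Path) -> dict:
    """Camera-aware pose export: per sample the intrinsic matrix, camera pose,
    view-projection matrix, and per-subject camera-relative 3D keypoints.
    Lossless with respect to the sample files."""
    samples = []
    W, H = dataset.batch.pass_width, dataset.batch.pass_height
    from scipy.spatial.transform import Rotation

    for i, sample in dataset.samples():
        cam = sample.camera
        fov = np.radians(cam.fov_diagonal_deg)
        diag_px = float(np.hypot(W, H))
        f_px = diag_px / (2 * np.tan(fov / 2))  # informational; fx/fy below are exact
        vp = np.array(cam.view_projection)
        # split the projection back out of VP via the stored camera pose
        R = Rotation.from_euler("XYZ", cam.rotation, degrees=True).as_matrix()
        V = np.eye(4)
        V[:3, :3] = R.T
        V[:3, 3] = -R.T @ np.asarray(cam.position)
        P = vp @ np.linalg.inv(V)
        fx = P[0, 0] * W / 2
        fy = P[1, 1] * H / 2
        intrinsics = [[fx, 0.0, W / 2], [0.0, fy, H / 2], [0.0, 0.0, 1.0]]
        samples.append(
            {
                "sample_id": sample.sample_id,
                "intrinsics": [[float(v) for v in row] for row in intrinsics],
                "focal_px_diagonal": f_px,
                "camera_position": cam.position,
                "camera_rotation": cam.rotation,
                "view_projection": cam.view_projection,
                "subjects": [
                    {
                        "instance_id": s.instance_id,
                        "keypoints": [
                            {"name": k.name, "xyz_cam": k.xyz_cam, "xy": k.xy,
                             "visibility": k.visibility}
                            for k in s.keypoints
                        ],
                    }
                    for s in sample.subjects
                ],
            }
        )
    doc = {"dataset": dataset.batch.dataset_name, "image_size": [W, H], "samples": samples}
    Path(out_path).write_text(json.dumps(doc))
    return doc
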