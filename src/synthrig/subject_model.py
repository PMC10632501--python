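"""Articulated subject models: armature, rigid per-bone binding, and the digital population.

A subject is a triangle mesh bound rigidly to a tree of bones.  Arthropod
exoskeletons are effectively rigid per segment, so each mesh vertex belongs to
exactly one bone and moves with that bone's frame — no soft skinning.  A
*population* is a set of instances of one or more subject models, each with a
random uniform scale, random appearance modifiers (hue / brightness / contrast /
saturation) and a unique non-black ID color used by the renderer's ID pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from scipy.spatial.transform import Rotation

JOINT_GROUPS = ("mesh_interacting", "mesh_independent", "fixed")


class ModelValidationError(ValueError):
    """Raised when a subject model violates an armature or binding invariant."""


@dataclass
class Bone:
    name: str
    parent: Optional[str]
    rest_offset: np.ndarray  # (3,) offset from the parent joint, model units
    segment_vertices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        self.rest_offset = np.asarray(self.rest_offset, dtype=float).reshape(3)
        self.segment_vertices = np.asarray(self.segment_vertices, dtype=int)


@dataclass
class Joint:
    bone: str
    axis_limits: np.ndarray  # (3, 2) degrees, per-axis (min, max)
    group: str = "fixed"

    def __post_init__(self):
        self.axis_limits = np.asarray(self.axis_limits, dtype=float).reshape(3, 2)
        if not np.all(np.isfinite(self.axis_limits)):
            raise ModelValidationError(f"joint '{self.bone}': non-finite axis limits")
        if np.any(self.axis_limits[:, 0] > self.axis_limits[:, 1]):
            raise ModelValidationError(f"joint '{self.bone}': min > max in axis limits")
        if self.group not in JOINT_GROUPS:
            raise ModelValidationError(f"joint '{self.bone}': unknown group '{self.group}'")


@dataclass
class SubjectModel:
    """A validated articulated mesh: geometry, armature, keypoints, proxies."""

    class_name: str
    vertices: np.ndarray        # (N, 3) rest positions, model units
    faces: np.ndarray           # (M, 3) int triangle indices
    base_color: np.ndarray      # (N, 3) RGB in [0, 1]
    bones: list[Bone] = field(default_factory=list)
    joints: list[Joint] = field(default_factory=list)
    keypoints: list[tuple[str, str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        self.base_color = np.asarray(self.base_color, dtype=float).reshape(-1, 3)
        self.keypoints = [(n, b, np.asarray(o, dtype=float).reshape(3)) for n, b, o in self.keypoints]
        self._bone_index = {b.name: i for i, b in enumerate(self.bones)}
        self._joint_by_bone = {j.bone: j for j in self.joints}
        self.validate()

    # -- lookups ---------------------------------------------------------

    def bone(self, name: str) -> Bone:
        return self.bones[self._bone_index[name]]

    def joint_for(self, bone_name: str) -> Optional[Joint]:
        return self._joint_by_bone.get(bone_name)

    @property
    def root(self) -> Bone:
        return next(b for b in self.bones if b.parent is None)

    def children_of(self, bone_name: str) -> list[Bone]:
        return [b for b in self.bones if b.parent == bone_name]

    def topo_order(self) -> list[Bone]:
        out, stack = [], [self.root]
        while stack:
            b = stack.pop()
            out.append(b)
            stack.extend(self.children_of(b.name))
        return out

    def rest_heads(self) -> dict[str, np.ndarray]:
        """Rest-pose head (joint pivot) position of every bone, root at its offset."""
        heads: dict[str, np.ndarray] = {}
        for b in self.topo_order():
            base = heads[b.parent] if b.parent is not None else np.zeros(3)
            heads[b.name] = base + b.rest_offset
        return heads

    def leg_chains(self) -> list[list[str]]:
        """Contiguous mesh-interacting chains, each ending at a leaf ("foot") bone."""
        chains = []
        for b in self.bones:
            j = self.joint_for(b.name)
            if j is None or j.group != "mesh_interacting" or self.children_of(b.name):
                continue
            chain = [b.name]
            cur = b
            while cur.parent is not None:
                pj = self.joint_for(cur.parent)
                if pj is None or pj.group != "mesh_interacting":
                    break
                chain.append(cur.parent)
                cur = self.bone(cur.parent)
            chains.append(chain[::-1])
        return chains

    def extent(self) -> float:
        lo, hi = self.vertices.min(axis=0), self.vertices.max(axis=0)
        return float(np.max(hi - lo))

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if len(self.faces) < 1:
            raise ModelValidationError("mesh must contain at least one triangle")
        if len(self.base_color) != len(self.vertices):
            raise ModelValidationError("base_color must be per-vertex")
        if np.any(self.base_color < 0) or np.any(self.base_color > 1):
            raise ModelValidationError("base_color must lie in [0,1]")
        names = [b.name for b in self.bones]
        if len(set(names)) != len(names):
            raise ModelValidationError("duplicate bone names")
        roots = [b for b in self.bones if b.parent is None]
        if len(roots) != 1:
            raise ModelValidationError(f"bone graph must have exactly one root, found {len(roots)}")
        for b in self.bones:
            if b.parent is not None and b.parent not in self._bone_index:
                raise ModelValidationError(f"bone '{b.name}': unknown parent '{b.parent}'")
        # tree check: walk to root from every bone, detecting cycles
        for b in self.bones:
            seen, cur = {b.name}, b
            while cur.parent is not None:
                if cur.parent in seen:
                    raise ModelValidationError(f"bone cycle involving '{cur.parent}'")
                seen.add(cur.parent)
                cur = self.bone(cur.parent)
        # every vertex belongs to exactly one bone
        owner = np.full(len(self.vertices), -1, dtype=int)
        for i, b in enumerate(self.bones):
            idx = b.segment_vertices
            if np.any(owner[idx] >= 0):
                dup = int(idx[owner[idx] >= 0][0])
                raise ModelValidationError(f"vertex {dup} bound to more than one bone")
            owner[idx] = i
        if np.any(owner < 0):
            raise ModelValidationError(f"orphan vertex {int(np.where(owner < 0)[0][0])} bound to no bone")
        for j in self.joints:
            if j.bone not in self._bone_index:
                raise ModelValidationError(f"joint references unknown bone '{j.bone}'")
        kp_names = [n for n, _, _ in self.keypoints]
        if len(set(kp_names)) != len(kp_names):
            raise ModelValidationError("duplicate keypoint names")
        for n, bone_name, _ in self.keypoints:
            if bone_name not in self._bone_index:
                raise ModelValidationError(f"keypoint '{n}' references unknown bone '{bone_name}'")

    # -- collision proxies ----------------------------------------------

    def bone_spheres(self) -> list[tuple[str, np.ndarray, float]]:
        """Per-bone proxy spheres (name, center, radius) fit to segment vertices;
        elongated segments are covered by a chain of spheres (capsule-like)."""
        out = []
        for b in self.bones:
            if len(b.segment_vertices) == 0:
                continue
            for c, r in fit_bone_spheres(self.vertices[b.segment_vertices]):
                out.append((b.name, c, r))
        return out


def fit_bone_spheres(points: np.ndarray) -> list[tuple[np.ndarray, float]]:
    """Cover a rigid segment's vertices with spheres along its principal axis.

    A single bounding sphere grossly overestimates elongated segments (a leg or
    body axis), so the segment is sliced along its longest direction into slabs
    of roughly cross-sectional width, each bounded by its own sphere.
    """
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    centered = pts - c
    # principal direction via the dominant right-singular vector
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    lo, hi = proj.min(), proj.max()
    radial = np.linalg.norm(centered - np.outer(proj, axis), axis=1)
    r_c = max(float(radial.max()), 1e-6)
    length = hi - lo
    n = max(1, int(np.ceil(length / (2 * r_c))))
    if n == 1:
        return [(c, float(np.linalg.norm(centered, axis=1).max()))]
    w = length / n
    out = []
    for k in range(n):
        a, b_ = lo + k * w, lo + (k + 1) * w
        sel = (proj >= a - 1e-12) & (proj <= b_ + 1e-12)
        mid = c + axis * (a + b_) / 2
        if sel.any():
            r = float(np.linalg.norm(pts[sel] - mid, axis=1).max())
        else:
            r = np.hypot(w / 2, r_c)
        out.append((mid, r))
    return out


# ---------------------------------------------------------------------------
# population


@dataclass
class ColorVariation:
    """Sampling ranges for per-instance appearance modifiers."""

    hue_deg: float = 15.0                       # hue shift ~ U(-hue_deg, +hue_deg)
    brightness: float = 0.1                     # additive offset ~ U(-b, +b)
    contrast: tuple[float, float] = (0.8, 1.2)  # multiplier range
    saturation: tuple[float, float] = (0.8, 1.2)


@dataclass
class PopulationSpec:
    entries: list[tuple[SubjectModel, float]]
    population_size: int
    scale_variation: float = 0.0
    color_variation: ColorVariation = field(default_factory=ColorVariation)

    def __post_init__(self):
        if self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        if self.scale_variation < 0:
            raise ValueError("scale_variation must be >= 0")
        total = sum(f for _, f in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions must sum to 1, got {total}")


@dataclass
class SubjectInstance:
    instance_id: int
    model: SubjectModel
    scale: float
    color_mods: tuple[float, float, float, float]  # (hue shift deg, brightness, contrast, saturation)
    id_color: tuple[int, int, int]

    def modified_color(self) -> np.ndarray:
        return apply_color_mods(self.model.base_color, self.color_mods)


def id_color_for_index(k: int) -> tuple[int, int, int]:
    """Deterministic instance-index -> RGB bijection; k >= 1, never (0,0,0)."""
    if k < 1 or k > 2**24 - 1:
        raise ValueError("instance index must be in [1, 2^24 - 1]")
    return (k % 256, (k // 256) % 256, k // 65536)


def build_population(spec: PopulationSpec, rng: np.random.Generator) -> list[SubjectInstance]:
    """Sample a digital population: class counts by largest-remainder rounding,
    uniform scale on [1-v, 1+v] (clipped at 0.05), appearance mods from the
    configured ranges, and a unique ID color per instance."""
    n = spec.population_size
    active = [(m, f) for m, f in spec.entries if f > 0]
    if n < len(active):
        raise ValueError(f"population_size {n} smaller than number of classes {len(active)}")
    raw = np.array([f * n for _, f in active])
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    v, cv = spec.scale_variation, spec.color_variation
    instances = []
    k = 0
    for (model, _), c in zip(active, counts):
        for _ in range(c):
            k += 1
            scale = max(0.05, float(rng.uniform(1 - v, 1 + v))) if v > 0 else 1.0
            mods = (
                float(rng.uniform(-cv.hue_deg, cv.hue_deg)),
                float(rng.uniform(-cv.brightness, cv.brightness)),
                float(rng.uniform(*cv.contrast)),
                float(rng.uniform(*cv.saturation)),
            )
            instances.append(
                SubjectInstance(k, model, scale, mods, id_color_for_index(k))
            )
    return instances


def apply_color_mods(base_color: np.ndarray, mods: Sequence[float]) -> np.ndarray:
    """Hue rotation and saturation in HSV space; brightness additive; contrast
    as (x - 0.5) * c + 0.5.  Total on [0,1]^3 inputs; output clipped to [0,1]."""
    hue_shift, brightness, contrast, saturation = mods
    rgb = np.clip(np.asarray(base_color, dtype=float), 0.0, 1.0)
    scalar = rgb.ndim == 1
    hsv = rgb_to_hsv(rgb.reshape(-1, 3))
    hsv[:, 0] = (hsv[:, 0] + hue_shift / 360.0) % 1.0
    hsv[:, 1] = np.clip(hsv[:, 1] * saturation, 0.0, 1.0)
    out = hsv_to_rgb(hsv)
    out = out + brightness
    out = (out - 0.5) * contrast + 0.5
    out = np.clip(out, 0.0, 1.0)
    return out[0] if scalar else out.reshape(rgb.shape)


# ---------------------------------------------------------------------------
# forward kinematics


def _rot(angles_deg: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("XYZ", angles_deg, degrees=True).as_matrix()


def bone_frames(
    model: SubjectModel, pose: dict[str, np.ndarray]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Posed (head position, orientation matrix) per bone.

    Each bone's frame composes parent transform x joint rotation x rest offset;
    ``pose`` maps bone name -> (3,) XYZ Euler angles in degrees for every
    non-fixed joint.  Angles are checked against the joint's axis limits.
    """
    frames: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for b in model.topo_order():
        j = model.joint_for(b.name)
        angles = np.zeros(3)
        if j is not None and j.group != "fixed":
            if b.name not in pose:
                raise ValueError(f"pose missing angles for joint '{b.name}'")
            angles = np.asarray(pose[b.name], dtype=float).reshape(3)
            lo, hi = j.axis_limits[:, 0], j.axis_limits[:, 1]
            bad = np.where((angles < lo - 1e-9) | (angles > hi + 1e-9))[0]
            if bad.size:
                ax = "xyz"[bad[0]]
                raise ValueError(
                    f"joint '{b.name}' axis {ax}: angle {angles[bad[0]]:.3f} outside "
                    f"limits [{lo[bad[0]]}, {hi[bad[0]]}]"
                )
        if b.parent is None:
            head = b.rest_offset.copy()
            orient = _rot(angles)
        else:
            p_head, p_orient = frames[b.parent]
            head = p_head + p_orient @ b.rest_offset
            orient = p_orient @ _rot(angles)
        frames[b.name] = (head, orient)
    return frames


def pose_mesh(
    model: SubjectModel,
    pose: dict[str, np.ndarray],
    scale: float = 1.0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Rigid forward kinematics: vertices and keypoints move with their bone.

    Returns posed vertex positions (N, 3) and a keypoint-name -> position map,
    uniformly scaled about the root head.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    frames = bone_frames(model, pose)
    rest_heads = model.rest_heads()
    verts = np.empty_like(model.vertices)
    for b in model.bones:
        if len(b.segment_vertices) == 0:
            continue
        head, orient = frames[b.name]
        local = model.vertices[b.segment_vertices] - rest_heads[b.name]
        verts[b.segment_vertices] = head + local @ orient.T
    kps = {}
    for name, bone_name, offset in model.keypoints:
        head, orient = frames[bone_name]
        kps[name] = head + orient @ offset
    root_head = frames[model.root.name][0]
    verts = root_head + scale * (verts - root_head)
    kps = {k: root_head + scale * (v - root_head) for k, v in kps.items()}
    return verts, kps


# ---------------------------------------------------------------------------
# file I/O


def load_subject(mesh_file: str | Path, sidecar_file: str | Path) -> SubjectModel:
    """Load an OBJ triangle mesh plus a JSON armature sidecar into a validated model.

    The sidecar declares ``class_name``, ``bones[]``, ``joints[]``, ``keypoints[]``
    and ``vertex_bone[]`` (per-vertex owning-bone index) and may carry an optional
    per-vertex ``colors`` table; without one the mesh's own vertex colors or a
    neutral gray are used.
    """
    import trimesh

    mesh = trimesh.load(str(mesh_file), file_type="obj", process=False, maintain_order=True)
    if not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise ModelValidationError(f"mesh file {mesh_file} contains no triangles")
    with open(sidecar_file) as fh:
        side = json.load(fh)
    for key in ("class_name", "bones", "joints", "keypoints", "vertex_bone"):
        if key not in side:
            raise ModelValidationError(f"sidecar missing key '{key}'")
    bones = [Bone(b["name"], b.get("parent"), np.array(b["rest_offset"], dtype=float)) for b in side["bones"]]
    vertex_bone = np.asarray(side["vertex_bone"], dtype=int)
    if len(vertex_bone) != len(mesh.vertices):
        raise ModelValidationError(
            f"vertex_bone length {len(vertex_bone)} != vertex count {len(mesh.vertices)}"
        )
    for i, b in enumerate(bones):
        b.segment_vertices = np.where(vertex_bone == i)[0]
    joints = [
        Joint(j["bone"], np.array(j["limits"], dtype=float), j.get("group", "fixed"))
        for j in side["joints"]
    ]
    keypoints = [(k["name"], k["bone"], np.array(k["offset"], dtype=float)) for k in side["keypoints"]]
    if "colors" in side:
        color = np.asarray(side["colors"], dtype=float)
    elif mesh.visual is not None and getattr(mesh.visual, "vertex_colors", None) is not None and len(
        mesh.visual.vertex_colors
    ) == len(mesh.vertices):
        color = np.asarray(mesh.visual.vertex_colors[:, :3], dtype=float) / 255.0
    else:
        color = np.full((len(mesh.vertices), 3), 0.5)
    return SubjectModel(
        class_name=side["class_name"],
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=int),
        base_color=color,
        bones=bones,
        joints=joints,
        keypoints=keypoints,
    )


def save_subject(model: SubjectModel, mesh_file: str | Path, sidecar_file: str | Path) -> None:
    """Write the OBJ mesh and JSON sidecar for a model (inverse of load_subject)."""
    import trimesh

    tm = trimesh.Trimesh(vertices=model.vertices, faces=model.faces, process=False)
    Path(mesh_file).write_text(tm.export(file_type="obj"))
    vertex_bone = np.full(len(model.vertices), -1, dtype=int)
    for i, b in enumerate(model.bones):
        vertex_bone[b.segment_vertices] = i
    side = {
        "class_name": model.class_name,
        "bones": [
            {"name": b.name, "parent": b.parent, "rest_offset": b.rest_offset.tolist()}
            for b in model.bones
        ],
        "joints": [
            {"bone": j.bone, "limits": j.axis_limits.tolist(), "group": j.group}
            for j in model.joints
        ],
        "keypoints": [
            {"name": n, "bone": b, "offset": o.tolist()} for n, b, o in model.keypoints
        ],
        "vertex_bone": vertex_bone.tolist(),
        "colors": model.base_color.tolist(),
    }
    Path(sidecar_file).write_text(json.dumps(side))
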