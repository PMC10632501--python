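"""Built-in primitive meshes: a rigged "stick insect" test subject and untextured
scatter assets (boxes, cylinders, icospheres, pebbles).

These stand in for photogrammetry-derived animal models and asset libraries so
the whole pipeline runs self-contained.  The stick subject is a box-segment
hexapod: one body bone plus six two-segment legs (femur + tibia), 13 bones in
total, each leg a mesh-interacting inverse-kinematics chain ending in a foot.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .subject_model import Bone, Joint, SubjectModel


def _segment_box(a: np.ndarray, b: np.ndarray, thickness: float) -> tuple[np.ndarray, np.ndarray]:
    """Thin box around segment a->b: 8 vertices, 12 triangles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    d = b - a
    L = np.linalg.norm(d)
    z = d / L
    ref = np.array([0.0, 0.0, 1.0]) if abs(z[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    x = np.cross(ref, z)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    t = thickness / 2
    verts = []
    for s in (0.0, 1.0):
        p = a + s * d
        for sx in (-1, 1):
            for sy in (-1, 1):
                verts.append(p + sx * t * x + sy * t * y)
    verts = np.array(verts)
    # faces of the 8-corner box (corners: end s*4 + sx*2 + sy)
    f = [
        (0, 1, 3), (0, 3, 2),          # bottom cap
        (4, 7, 5), (4, 6, 7),          # top cap
        (0, 4, 5), (0, 5, 1),
        (1, 5, 7), (1, 7, 3),
        (3, 7, 6), (3, 6, 2),
        (2, 6, 4), (2, 4, 0),
    ]
    return verts, np.array(f, dtype=int)


def make_stick_subject(
    class_name: str = "stick",
    body_length: float = 2.0,
    leg_span: float = 0.5,
    leg_drop: float = 0.5,
    thickness: float = 0.12,
    color: tuple[float, float, float] = (0.45, 0.30, 0.15),
    with_antennae: bool = False,
) -> SubjectModel:
    """Six-legged box-segment subject: body + 6 x (femur, tibia) = 13 bones.

    The body axis runs along +X with the root at the body center; femora point
    sideways (+/-Y), tibiae drop toward the ground.  Keypoints: head, thorax,
    abdomen tips and the six foot tips.  Joint limits permit standing poses on
    uneven terrain; antennae (mesh-independent) are optional extras.
    """
    half = body_length / 2
    bones = [Bone("body", None, np.zeros(3))]
    joints = [Joint("body", np.zeros((3, 2)), "fixed")]
    keypoints = [
        ("head", "body", np.array([half, 0.0, 0.0])),
        ("thorax", "body", np.zeros(3)),
        ("abdomen", "body", np.array([-half, 0.0, 0.0])),
    ]
    verts_all, faces_all, owner = [], [], []

    def add_segment(a, b, bone_idx):
        v, f = _segment_box(a, b, thickness)
        faces_all.append(f + sum(len(x) for x in verts_all))
        verts_all.append(v)
        owner.extend([bone_idx] * len(v))

    add_segment(np.array([-half, 0, 0]), np.array([half, 0, 0]), 0)

    hip_xs = [0.6 * half, 0.0, -0.6 * half]
    for i, hx in enumerate(hip_xs):
        for side, sgn in (("L", 1.0), ("R", -1.0)):
            leg = f"{side}{i + 1}"
            hip = np.array([hx, sgn * thickness, 0.0])
            femur_vec = np.array([0.0, sgn * leg_span, 0.0])
            tibia_vec = np.array([0.0, sgn * 0.15, -leg_drop])
            fi = len(bones)
            bones.append(Bone(f"femur_{leg}", "body", hip))
            joints.append(
                Joint(f"femur_{leg}", np.array([[-80, 80], [-80, 80], [-80, 80]]), "mesh_interacting")
            )
            ti = len(bones)
            bones.append(Bone(f"tibia_{leg}", f"femur_{leg}", femur_vec))
            joints.append(
                Joint(f"tibia_{leg}", np.array([[-135, 135], [-135, 135], [-135, 135]]), "mesh_interacting")
            )
            keypoints.append((f"foot_{leg}", f"tibia_{leg}", tibia_vec))
            add_segment(hip, hip + femur_vec, fi)
            add_segment(hip + femur_vec, hip + femur_vec + tibia_vec, ti)

    if with_antennae:
        for side, sgn in (("L", 1.0), ("R", -1.0)):
            ai = len(bones)
            base = np.array([half, sgn * 0.05, 0.05])
            tip = np.array([0.4, sgn * 0.2, 0.2])
            bones.append(Bone(f"antenna_{side}", "body", base))
            joints.append(
                Joint(f"antenna_{side}", np.array([[-30, 30], [-30, 30], [-30, 30]]), "mesh_independent")
            )
            keypoints.append((f"antenna_tip_{side}", f"antenna_{side}", tip))
            add_segment(base, base + tip, ai)

    vertices = np.vstack(verts_all)
    faces = np.vstack(faces_all)
    for idx, b in enumerate(bones):
        b.segment_vertices = np.where(np.array(owner) == idx)[0]
    base_color = np.tile(np.asarray(color, float), (len(vertices), 1))
    # mild per-vertex shade variation so appearance mods are observable
    base_color *= (0.9 + 0.1 * (vertices[:, 2:3] - vertices[:, 2].min()) / max(1e-9, np.ptp(vertices[:, 2])))
    return SubjectModel(
        class_name=class_name,
        vertices=vertices,
        faces=faces,
        base_color=np.clip(base_color, 0, 1),
        bones=bones,
        joints=joints,
        keypoints=keypoints,
    )


# ---------------------------------------------------------------------------
# asset primitives (scatterer library)


def _normalize_largest_extent(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    ext = mesh.extents.max()
    mesh.apply_scale(1.0 / ext)
    mesh.apply_translation(-mesh.bounds.mean(axis=0))
    return mesh

def make_box_asset() -> trimesh.Trimesh:
    return _normalize_largest_extent(trimesh.creation.box(extents=(1.0, 0.7, 0.5)))

def make_cylinder_asset(sections: int = 12) -> trimesh.Trimesh:
    return _normalize_largest_extent(trimesh.creation.cylinder(radius=0.3, height=1.0, sections=sections))

def make_icosphere_asset(subdivisions: int = 1) -> trimesh.Trimesh:
    return _normalize_largest_extent(trimesh.creation.icosphere(subdivisions=subdivisions))

def make_pebble_asset(seed: int = 0, subdivisions: int = 1) -> trimesh.Trimesh:
    """Icosphere with deterministic radial noise — an irregular stone."""
    rng = np.random.default_rng(seed)
    m = trimesh.creation.icosphere(subdivisions=subdivisions)
    v = m.vertices.copy()
    radii = 1.0 + 0.25 * rng.uniform(-1, 1, size=len(v))
    v *= radii[:, None]
    v[:, 2] *= 0.6  # flattened, like a river pebble
    return _normalize_largest_extent(trimesh.Trimesh(vertices=v, faces=m.faces, process=False))


ASSET_MAKERS = {
    "box": make_box_asset,
    "cylinder": make_cylinder_asset,
    "icosphere": make_icosphere_asset,
    "pebble": make_pebble_asset,
}


def default_asset_library(names: list[str] | None = None) -> list[trimesh.Trimesh]:
    """The built-in untextured asset set, largest extent normalized to 1."""
    names = names or ["box", "cylinder", "icosphere", "pebble"]
    return [ASSET_MAKERS[n]() for n in names]
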