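"""Subject placement and posing.

Placement is rejection sampling: a random position above the terrain and a
random center rotation are proposed, rejected while the subject's collision
proxies (per-bone bounding spheres) intersect terrain, scattered assets, or
previously placed subjects, and the accepted proposal is translated along the
subject's down-vector (world -Z rotated by the center rotation) until first
proxy contact.

Posing is contact-driven: each leg's foot target comes from a downward ray
cast near the foot's rest location, and a cyclic-coordinate-descent (CCD)
inverse-kinematics solver with per-axis joint-limit clamping bends the leg
chain to the target.  Legs without a valid target (or randomly selected legs)
are posed toward a random in-reach point instead and flagged mid-air.
Mesh-independent joints (head, antennae, ...) get uniform random angles
within their permissible ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .scene_generation import PlacedAsset, PlacedSubject, Scene
from .subject_model import SubjectInstance, bone_frames, pose_mesh


class PlacementError(RuntimeError):
    def __init__(self, message: str, attempts_used: int):
        super().__init__(message)
        self.attempts_used = attempts_used


@dataclass
class Placement:
    position: np.ndarray       # world position of the subject's geometric center
    center_rotation: np.ndarray  # XYZ Euler degrees
    attempts_used: int


@dataclass
class PosingConfig:
    ik_iterations: int = 50
    ik_tolerance: float = 0.02          # world units
    midair_fraction: float = 0.15       # probability a leg is posed to a free point
    restricted_sweeps: int = 1          # CCD sweeps used for mid-air legs
    retry_cap: int = 100
    tilt_deg: float = 20.0              # pitch/roll range of the center rotation
    drop_height: float = 2.0            # start-height range above the surface, x subject extent
    foot_jitter: float = 0.15           # horizontal jitter of foot-target rays, x subject extent


# ---------------------------------------------------------------------------
# geometric queries


def _rotmat(angles_deg) -> np.ndarray:
    return Rotation.from_euler("XYZ", np.asarray(angles_deg, float), degrees=True).as_matrix()


def point_obb_distance(p: np.ndarray, center: np.ndarray, half: np.ndarray, yaw_deg: float) -> float:
    """Signed-exterior distance from a point to a yaw-oriented box (0 inside)."""
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    local = R.T @ (p - center)
    d = np.maximum(np.abs(local) - half, 0.0)
    return float(np.linalg.norm(d))


def ray_obb_intersect(
    origin: np.ndarray, direction: np.ndarray,
    center: np.ndarray, half: np.ndarray, yaw_deg: float,
) -> float | None:
    """Slab-test ray/box intersection; returns smallest t >= 0 or None."""
    c, s = np.cos(np.radians(yaw_deg)), np.sin(np.radians(yaw_deg))
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
    o = R.T @ (origin - center)
    d = R.T @ direction
    t0, t1 = -np.inf, np.inf
    for k in range(3):
        if abs(d[k]) < 1e-12:
            if abs(o[k]) > half[k]:
                return None
        else:
            ta = (-half[k] - o[k]) / d[k]
            tb = (half[k] - o[k]) / d[k]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
    if t0 > t1 or t1 < 0:
        return None
    return max(t0, 0.0)


def _subject_spheres(instance: SubjectInstance) -> list[tuple[np.ndarray, float]]:
    """Model-frame proxy spheres at instance scale, zero pose."""
    from .subject_model import fit_bone_spheres

    verts, _ = pose_mesh(instance.model, _zero_pose(instance.model), instance.scale)
    out = []
    for b in instance.model.bones:
        if len(b.segment_vertices) == 0:
            continue
        out.extend(fit_bone_spheres(verts[b.segment_vertices]))
    return out


def _zero_pose(model) -> dict[str, np.ndarray]:
    pose = {}
    for j in model.joints:
        if j.group != "fixed":
            lo, hi = j.axis_limits[:, 0], j.axis_limits[:, 1]
            pose[j.bone] = np.clip(np.zeros(3), lo, hi)
    return pose


class CollisionField:
    """Precomputed scene geometry for fast batched sphere-clearance queries."""

    def __init__(self, scene: Scene):
        self.terrain = scene.terrain
        self.obbs = []
        for a in scene.assets:
            c, h, yaw = a.obb()
            cy, sy = np.cos(np.radians(yaw)), np.sin(np.radians(yaw))
            R = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1.0]])
            self.obbs.append((c, h, R))
        sph = [s for subj in scene.subjects for s in subj.spheres_world()]
        self.sub_centers = np.array([c for c, _ in sph]).reshape(-1, 3)
        self.sub_radii = np.array([r for _, r in sph])

    def min_clearance(self, centers: np.ndarray, radii: np.ndarray) -> float:
        """Smallest signed clearance of the query spheres to terrain / assets / subjects."""
        gap = np.inf
        h = self.terrain.height_at(centers[:, 0], centers[:, 1])
        fin = np.isfinite(h)
        if fin.any():
            gap = min(gap, float(((centers[:, 2] - radii) - h)[fin].min()))
        for c, half, R in self.obbs:
            local = (centers - c) @ R
            d = np.linalg.norm(np.maximum(np.abs(local) - half, 0.0), axis=1)
            gap = min(gap, float((d - radii).min()))
        if len(self.sub_centers):
            d = np.linalg.norm(centers[:, None, :] - self.sub_centers[None, :, :], axis=2)
            gap = min(gap, float((d - radii[:, None] - self.sub_radii[None, :]).min()))
        return gap


# ---------------------------------------------------------------------------
# placement


def place_subject(
    scene: Scene,
    instance: SubjectInstance,
    rng: np.random.Generator,
    config: PosingConfig | None = None,
    rotation: np.ndarray | None = None,
) -> Placement:
    """Rejection placement plus down-vector trace to first proxy contact.

    Proposals intersecting existing geometry, or starting below the ground
    surface, are redrawn (each counts one attempt).  The accepted proposal is
    translated along its down-vector until a proxy sphere first touches
    terrain, an asset, or a previously placed subject; a trace that exits the
    world redraws the rotation and repeats.  Raises PlacementError when
    ``retry_cap`` attempts are exhausted.
    """
    config = config or PosingConfig()
    terrain = scene.terrain
    half = terrain.extent / 2
    ext = instance.model.extent() * instance.scale
    spheres0 = _subject_spheres(instance)
    centers0 = np.array([c for c, _ in spheres0]) - np.mean(
        pose_mesh(instance.model, _zero_pose(instance.model), instance.scale)[0], axis=0
    )
    radii0 = np.array([r for _, r in spheres0])
    z_floor = float(terrain.heightfield.min())
    field = CollisionField(scene)

    for attempt in range(1, config.retry_cap + 1):
        x, y = rng.uniform(-half * 0.9, half * 0.9, size=2)
        rot = rotation
        if rot is None:
            rot = np.array([
                rng.uniform(-config.tilt_deg, config.tilt_deg),
                rng.uniform(-config.tilt_deg, config.tilt_deg),
                rng.uniform(0.0, 360.0),
            ])
        R = _rotmat(rot)
        surface = terrain.height_at(x, y)
        z = float(rng.uniform(surface + 0.6 * ext, surface + (0.6 + config.drop_height) * ext))
        pos = np.array([x, y, z])

        rotated = centers0 @ R.T

        def clearance_at(p):
            return field.min_clearance(p + rotated, radii0)

        if clearance_at(pos) <= 0:
            continue  # intersecting or below-ground start: rejected proposal

        down = R @ np.array([0.0, 0.0, -1.0])
        t_max = (z - z_floor + ext) / max(1e-9, -down[2]) if down[2] < 0 else 4 * ext
        step = max(1e-3, float(radii0.min()) / 2)
        t, hit = 0.0, None
        while t < t_max:
            t_next = min(t + step, t_max)
            if clearance_at(pos + t_next * down) <= 0:
                hit = (t, t_next)
                break
            t = t_next
        if hit is None:
            continue  # exited the world: redraw (spec: new rotation, repeat)
        lo, hi = hit
        for _ in range(60):  # bisect to contact
            mid = (lo + hi) / 2
            if clearance_at(pos + mid * down) <= 0:
                hi = mid
            else:
                lo = mid
        return Placement(pos + lo * down, rot, attempt)
    raise PlacementError(
        f"no valid placement in {config.retry_cap} attempts", config.retry_cap
    )


# ---------------------------------------------------------------------------
# ray-cast foot targets


def ray_cast_foot_target(
    foot_position: np.ndarray,
    scene: Scene,
    rng: np.random.Generator,
    jitter: float = 0.0,
    start_height: float = 1.0,
) -> np.ndarray | None:
    """Downward ray from a jittered point above the foot's rest location;
    returns the first surface hit (terrain, asset, or subject proxy), or None
    if the ray exits the world."""
    p = np.asarray(foot_position, float).copy()
    if jitter > 0:
        p[:2] += rng.uniform(-jitter, jitter, size=2)
    origin = p + np.array([0.0, 0.0, start_height])
    down = np.array([0.0, 0.0, -1.0])
    hits = []
    h = scene.terrain.height_at(origin[0], origin[1])
    if np.isfinite(h) and h <= origin[2]:
        hits.append(origin[2] - h)
    for a in scene.assets:
        c, half, yaw = a.obb()
        t = ray_obb_intersect(origin, down, c, half, yaw)
        if t is not None:
            hits.append(t)
    for s in scene.subjects:
        for sc, sr in s.spheres_world():
            oc = origin - sc
            b = np.dot(oc, down)
            disc = b * b - (np.dot(oc, oc) - sr * sr)
            if disc >= 0:
                t = -b - np.sqrt(disc)
                if t >= 0:
                    hits.append(t)
    if not hits:
        return None
    return origin + min(hits) * down


# ---------------------------------------------------------------------------
# cyclic coordinate descent IK


@dataclass
class IKChain:
    """A root->tip leg chain: joint pivots linked by fixed offsets.

    ``offsets[i]`` is the vector from joint i to joint i+1 in joint i's rest
    frame (the last offset reaches the tip); ``limits[i]`` are the per-axis
    (min, max) Euler limits in degrees.
    """

    base_position: np.ndarray
    base_orient: np.ndarray
    offsets: list[np.ndarray]
    limits: list[np.ndarray]
    max_iterations: int = 50
    tolerance: float = 0.02
    bone_names: list[str] = field(default_factory=list)

    @property
    def n_joints(self) -> int:
        return len(self.offsets)

    def reach(self) -> float:
        return float(sum(np.linalg.norm(o) for o in self.offsets))

    def fk(self, angles: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Joint pivot positions and tip position for (n,3) Euler angles."""
        pos = [np.asarray(self.base_position, float)]
        orient = np.asarray(self.base_orient, float)
        for i in range(self.n_joints):
            orient = orient @ _rotmat(angles[i])
            pos.append(pos[-1] + orient @ self.offsets[i])
        return pos[:-1], pos[-1]


def _axis_world_dir(base_orient: np.ndarray, prefix_angles: np.ndarray, axis: int) -> np.ndarray:
    """World direction of a joint's Euler axis given the preceding rotations."""
    unit = np.zeros(3)
    unit[axis] = 1.0
    if axis == 0:
        R = np.eye(3)
    else:
        partial = prefix_angles.copy()
        partial[axis:] = 0.0
        R = _rotmat(partial)
    return base_orient @ R @ unit


def solve_ik(
    chain: IKChain,
    target: np.ndarray,
    initial_angles: np.ndarray | None = None,
    max_sweeps: int | None = None,
) -> tuple[np.ndarray, bool, float]:
    """CCD with per-axis joint-limit clamping.

    Sweeps tip->root; for each joint axis the closed-form angle that rotates
    the tip toward the target (projected on the plane normal to the axis) is
    applied, clamped to the limits, and kept only if it does not increase the
    tip-to-target distance.  Unreachable targets leave the chain maximally
    extended toward the target.  Returns (angles, reached, final distance).
    """
    target = np.asarray(target, float)
    n = chain.n_joints
    angles = np.zeros((n, 3)) if initial_angles is None else np.array(initial_angles, float)
    for i in range(n):
        angles[i] = np.clip(angles[i], chain.limits[i][:, 0], chain.limits[i][:, 1])
    sweeps = chain.max_iterations if max_sweeps is None else max_sweeps
    _, tip = chain.fk(angles)
    best = float(np.linalg.norm(tip - target))
    for _ in range(sweeps):
        if best <= chain.tolerance:
            break
        improved = False
        for i in range(n - 1, -1, -1):
            for axis in range(3):
                lo, hi = chain.limits[i][axis]
                if hi - lo <= 0:
                    continue
                pivots, tip = chain.fk(angles)
                # orientation feeding joint i
                orient = np.asarray(chain.base_orient, float)
                for k in range(i):
                    orient = orient @ _rotmat(angles[k])
                w = _axis_world_dir(orient, angles[i], axis)
                u = tip - pivots[i]
                t = target - pivots[i]
                u_p = u - np.dot(u, w) * w
                t_p = t - np.dot(t, w) * w
                if np.linalg.norm(u_p) < 1e-12 or np.linalg.norm(t_p) < 1e-12:
                    continue
                delta = np.degrees(np.arctan2(np.dot(w, np.cross(u_p, t_p)), np.dot(u_p, t_p)))
                new = np.clip(angles[i][axis] + delta, lo, hi)
                if abs(new - angles[i][axis]) < 1e-12:
                    continue
                old = angles[i][axis]
                angles[i][axis] = new
                _, tip2 = chain.fk(angles)
                d2 = float(np.linalg.norm(tip2 - target))
                if d2 <= best + 1e-12:
                    if d2 < best - 1e-12:
                        improved = True
                    best = min(best, d2)
                else:
                    angles[i][axis] = old
        if not improved:
            break
    return angles, best <= chain.tolerance, best


# ---------------------------------------------------------------------------
# whole-subject posing


def _world_transform(placement: Placement, instance: SubjectInstance):
    """Map model-frame posed coordinates to world: rotate about the zero-pose
    geometric center, then translate the center to the placement position."""
    model = instance.model
    verts0, _ = pose_mesh(model, _zero_pose(model), instance.scale)
    centroid = verts0.mean(axis=0)
    R = _rotmat(placement.center_rotation)

    def to_world(p: np.ndarray) -> np.ndarray:
        return placement.position + (np.asarray(p) - centroid) @ R.T

    return to_world, R, centroid


def build_leg_chain(
    instance: SubjectInstance,
    chain_bones: list[str],
    pose: dict[str, np.ndarray],
    placement: Placement,
    config: PosingConfig,
) -> IKChain:
    """World-space IK chain for one leg given the current partial pose."""
    model = instance.model
    s = instance.scale
    frames = bone_frames(model, pose)
    rest_heads = model.rest_heads()
    root_head = rest_heads[model.root.name]
    to_world, R, centroid = _world_transform(placement, instance)

    first = chain_bones[0]
    head = frames[first][0]
    head_scaled = root_head + s * (head - root_head)
    base_pos = to_world(head_scaled)
    parent = model.bone(first).parent
    parent_orient = frames[parent][1] if parent else np.eye(3)
    base_orient = R @ parent_orient

    offsets, limits = [], []
    for i, bname in enumerate(chain_bones):
        j = model.joint_for(bname)
        limits.append(j.axis_limits.copy())
        if i + 1 < len(chain_bones):
            offsets.append(model.bone(chain_bones[i + 1]).rest_offset * s)
        else:
            tip_offset = None
            for _, kb, off in model.keypoints:
                if kb == bname:
                    tip_offset = off * s
            if tip_offset is None:
                tip_offset = model.bone(bname).rest_offset * s  # fallback: repeat segment
            offsets.append(tip_offset)
    return IKChain(
        base_pos, base_orient, offsets, limits,
        max_iterations=config.ik_iterations, tolerance=config.ik_tolerance,
        bone_names=list(chain_bones),
    )


def pose_subject(
    instance: SubjectInstance,
    placement: Placement,
    scene: Scene,
    rng: np.random.Generator,
    config: PosingConfig | None = None,
) -> PlacedSubject:
    """Pose all legs by ray-cast targets + IK and randomize mesh-independent joints.

    Returns the fully posed subject in world coordinates with per-leg
    grounded/mid-air status.  All returned angles respect joint limits.
    """
    config = config or PosingConfig()
    model = instance.model
    pose = _zero_pose(model)
    to_world, _, _ = _world_transform(placement, instance)
    ext = model.extent() * instance.scale
    statuses: dict[str, str] = {}

    for chain_bones in model.leg_chains():
        chain = build_leg_chain(instance, chain_bones, pose, placement, config)
        # rest foot position for the ray origin
        _, rest_tip = chain.fk(np.zeros((chain.n_joints, 3)))
        midair = rng.random() < config.midair_fraction
        target = None
        if not midair:
            target = ray_cast_foot_target(
                rest_tip, scene, rng,
                jitter=config.foot_jitter * chain.reach(), start_height=0.5 * ext,
            )
        sweeps = chain.max_iterations
        if target is None:
            midair = True
            surface = scene.terrain.height_at(chain.base_position[0], chain.base_position[1])
            for _ in range(20):  # random point within reach, not below the local surface
                d = rng.normal(size=3)
                d /= np.linalg.norm(d)
                cand = chain.base_position + d * chain.reach() * rng.uniform(0.3, 1.0)
                if not np.isfinite(surface) or cand[2] >= surface:
                    target = cand
                    break
            if target is None:
                target = chain.base_position + np.array([0, 0, 0.5]) * chain.reach()
            sweeps = config.restricted_sweeps
        angles, reached, _ = solve_ik(chain, target, max_sweeps=sweeps)
        for bname, ang in zip(chain_bones, angles):
            pose[bname] = ang
        leg = chain_bones[-1]
        statuses[leg] = "mid_air" if midair or not reached else "grounded"

    for j in model.joints:
        if j.group == "mesh_independent":
            lo, hi = j.axis_limits[:, 0], j.axis_limits[:, 1]
            pose[j.bone] = rng.uniform(lo, hi)

    verts, kps = pose_mesh(model, pose, instance.scale)
    return PlacedSubject(
        instance=instance,
        position=placement.position.copy(),
        rotation_deg=np.asarray(placement.center_rotation, float).copy(),
        pose_angles={k: np.asarray(v).copy() for k, v in pose.items()},
        vertices_world=to_world(verts),
        keypoints_world={k: to_world(v) for k, v in kps.items()},
        leg_status=statuses,
    )
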