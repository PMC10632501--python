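"""Deterministic software rendering of scenes into co-registered image passes.

A pinhole camera (right-handed world, Z up; camera space +Z forward, +X right,
+Y down; pixel origin top-left, centers at integer + 0.5) and a z-buffered
triangle rasterizer produce, per scene: an RGB render (Lambertian shading with
a directional sun, colored spotlights, ambient term and exponential distance
fog), an instance-ID pass (unique per-subject RGB, background exactly black),
a camera-plane depth pass, and surface-normal passes in view and world space.
Post-processing (temperature/tint, saturation, contrast, vignette, grain)
touches only the render pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .scene_generation import LightRig, Scene


@dataclass
class CameraModel:
    position: np.ndarray          # (3,) world
    rotation: np.ndarray          # (3,) XYZ Euler degrees of the camera axes
    focal_length: float = 35.0    # mm
    sensor_width: float = 36.0    # mm
    sensor_height: float = 24.0   # mm
    resolution: tuple[int, int] = (256, 256)   # (W, H) px
    aperture: float = 8.0         # f-number (depth-of-field proxy)
    exposure: float = 0.0         # EV offset

    def __post_init__(self):
        self.position = np.asarray(self.position, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3)
        if min(self.focal_length, self.sensor_width, self.sensor_height) <= 0:
            raise ValueError("focal length and sensor dimensions must be positive")
        if min(self.resolution) <= 0:
            raise ValueError("resolution must be positive")

    # -- derived quantities ---------------------------------------------

    def axes(self) -> np.ndarray:
        """Columns: camera right, down, forward unit vectors in world space."""
        return Rotation.from_euler("XYZ", self.rotation, degrees=True).as_matrix()

    def intrinsics(self) -> tuple[float, float, float, float]:
        W, H = self.resolution
        fx = self.focal_length * W / self.sensor_width
        fy = self.focal_length * H / self.sensor_height
        return fx, fy, W / 2.0, H / 2.0

    def fov_diagonal_deg(self) -> float:
        diag = np.hypot(self.sensor_width, self.sensor_height)
        return float(np.degrees(2 * np.arctan(diag / (2 * self.focal_length))))

    def view_matrix(self) -> np.ndarray:
        R = self.axes().T  # world -> camera
        V = np.eye(4)
        V[:3, :3] = R
        V[:3, 3] = -R @ self.position
        return V

    def projection_matrix(self, near: float, far: float) -> np.ndarray:
        fx, fy, _, _ = self.intrinsics()
        W, H = self.resolution
        P = np.zeros((4, 4))
        P[0, 0] = 2 * fx / W
        P[1, 1] = 2 * fy / H
        P[2, 2] = (far + near) / (far - near)
        P[2, 3] = -2 * far * near / (far - near)
        P[3, 2] = 1.0
        return P

    def view_projection(self, near: float = 0.05, far: float = 200.0) -> np.ndarray:
        return self.projection_matrix(near, far) @ self.view_matrix()


def camera_from_lookat(
    position: np.ndarray, target: np.ndarray, **kwargs
) -> CameraModel:
    """Camera at ``position`` with boresight through ``target`` (zero roll)."""
    position = np.asarray(position, float)
    forward = np.asarray(target, float) - position
    forward = forward / np.linalg.norm(forward)
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(forward, up)) > 0.999:
        up = np.array([1.0, 0.0, 0.0])
    right = np.cross(forward, up)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    axes = np.column_stack([right, down, forward])
    rot = Rotation.from_matrix(axes).as_euler("XYZ", degrees=True)
    return CameraModel(position=position, rotation=rot, **kwargs)


def project(camera: CameraModel, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World points -> (pixel xy (N,2), camera depth (N,), behind-camera flag (N,))."""
    pts = np.atleast_2d(np.asarray(points, float))
    V = camera.view_matrix()
    cam = pts @ V[:3, :3].T + V[:3, 3]
    fx, fy, cx, cy = camera.intrinsics()
    z = cam[:, 2]
    behind = z <= 0
    zs = np.where(behind, np.nan, z)
    px = cx + fx * cam[:, 0] / zs
    py = cy + fy * cam[:, 1] / zs
    return np.column_stack([px, py]), z, behind


def project_camera_space(
    camera: CameraModel, cam_points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Camera-relative 3D points -> pixel coordinates (intrinsics only)."""
    pts = np.atleast_2d(np.asarray(cam_points, float))
    fx, fy, cx, cy = camera.intrinsics()
    z = pts[:, 2]
    return np.column_stack([cx + fx * pts[:, 0] / z, cy + fy * pts[:, 1] / z]), z


def pixels_from_view_projection(
    vp: np.ndarray, world_points: np.ndarray, resolution: tuple[int, int]
) -> np.ndarray:
    """Pixel coordinates via a stored 4x4 view-projection matrix."""
    pts = np.atleast_2d(np.asarray(world_points, float))
    homo = np.column_stack([pts, np.ones(len(pts))]) @ np.asarray(vp).T
    ndc = homo[:, :2] / homo[:, 3:4]
    W, H = resolution
    return np.column_stack([(ndc[:, 0] + 1) / 2 * W, (ndc[:, 1] + 1) / 2 * H])


# ---------------------------------------------------------------------------
# camera randomization


@dataclass
class CameraConfig:
    resolution: tuple[int, int] = (256, 256)
    focal_range: tuple[float, float] = (28.0, 60.0)
    sensor: tuple[float, float] = (36.0, 24.0)
    distance_range: tuple[float, float] = (4.0, 9.0)
    elevation_range: tuple[float, float] = (20.0, 75.0)  # degrees above horizon
    offset_bound: float = 8.0                            # max boresight offset, degrees
    exposure_range: tuple[float, float] = (-0.3, 0.3)
    aperture_range: tuple[float, float] = (5.6, 11.0)


def spawn_camera(scene: Scene, rng: np.random.Generator, config: CameraConfig | None = None) -> CameraModel:
    """Aim a randomized camera at a randomly selected subject.

    Position is drawn in a spherical shell around the subject; the boresight is
    aimed at the subject center and then perturbed by a rotation of at most
    ``offset_bound`` degrees so the subject's image position varies.
    """
    config = config or CameraConfig()
    if not scene.subjects:
        raise ValueError("scene has no subjects to aim at")
    subject = scene.subjects[int(rng.integers(len(scene.subjects)))]
    center = subject.vertices_world.mean(axis=0)
    pos = None
    for _ in range(40):
        az = rng.uniform(0, 2 * np.pi)
        el = np.radians(rng.uniform(*config.elevation_range))
        dist = rng.uniform(*config.distance_range)
        cand = center + dist * np.array(
            [np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)]
        )
        h = scene.terrain.height_at(cand[0], cand[1])
        if not np.isfinite(h) or cand[2] > h + 0.3:
            pos = cand
            break
    if pos is None:
        pos = center + np.array([0, 0, np.mean(config.distance_range)])
    cam = camera_from_lookat(
        pos, center,
        focal_length=float(rng.uniform(*config.focal_range)),
        sensor_width=config.sensor[0], sensor_height=config.sensor[1],
        resolution=tuple(config.resolution),
        aperture=float(rng.uniform(*config.aperture_range)),
        exposure=float(rng.uniform(*config.exposure_range)),
    )
    if config.offset_bound > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0, config.offset_bound))
        R_off = Rotation.from_rotvec(axis * angle).as_matrix()
        new_axes = R_off @ cam.axes()
        cam.rotation = Rotation.from_matrix(new_axes).as_euler("XYZ", degrees=True)
    return cam


# ---------------------------------------------------------------------------
# rasterization


@dataclass
class PassSet:
    """The co-registered per-scene images plus auxiliary shading buffers."""

    render: np.ndarray        # (H, W, 3) float [0,1]
    id: np.ndarray            # (H, W, 3) uint8, background (0,0,0)
    depth: np.ndarray         # (H, W) float, camera-plane distance; inf for sky
    normal_view: np.ndarray   # (H, W, 3) float, encoded (n+1)/2
    normal_world: np.ndarray
    albedo: np.ndarray = None
    world_pos: np.ndarray = None
    hit: np.ndarray = None    # (H, W) bool


@dataclass
class DrawItem:
    vertices: np.ndarray                 # (N, 3) world
    faces: np.ndarray                    # (M, 3)
    vertex_colors: np.ndarray = None     # (N, 3) or None
    face_colors: np.ndarray = None       # (M, 3) or None
    id_color: tuple[int, int, int] | None = None


def scene_draw_items(scene: Scene) -> list[DrawItem]:
    items = []
    verts, faces, mat = scene.terrain.mesh()
    ca = np.asarray(scene.ground_colors[0], float)
    cb = np.asarray(scene.ground_colors[1], float)
    ground_col = ca * (1 - mat[:, None]) + cb * mat[:, None]
    items.append(DrawItem(verts, faces, vertex_colors=ground_col))
    for a in scene.assets:
        items.append(DrawItem(a.world_vertices(), np.asarray(a.mesh.faces), face_colors=a.face_colors))
    for s in scene.subjects:
        items.append(
            DrawItem(
                s.vertices_world, s.instance.model.faces,
                vertex_colors=s.instance.modified_color(),
                id_color=s.instance.id_color,
            )
        )
    return items


def rasterize(scene: Scene, camera: CameraModel, near: float = 0.05) -> PassSet:
    """Z-buffered rasterization of terrain, assets, and subjects.

    Produces the ID, depth and normal passes plus unlit geometry buffers
    (albedo, world position, hit mask) consumed by :func:`shade`.  Depth and
    colors are interpolated perspective-correctly; faces are flat-shaded with
    their geometric normal flipped toward the camera.
    """
    W, H = camera.resolution
    depth = np.full((H, W), np.inf)
    idpass = np.zeros((H, W, 3), dtype=np.uint8)
    albedo = np.zeros((H, W, 3))
    n_world = np.zeros((H, W, 3))
    n_view = np.zeros((H, W, 3))
    wpos = np.zeros((H, W, 3))
    hit = np.zeros((H, W), dtype=bool)
    V = camera.view_matrix()
    Rv = V[:3, :3]

    for item in scene_draw_items(scene):
        verts = item.vertices
        cam = verts @ Rv.T + V[:3, 3]
        pix, z, behind = project(camera, verts)
        tri = item.faces
        # geometric face normals, flipped toward the camera
        e1 = verts[tri[:, 1]] - verts[tri[:, 0]]
        e2 = verts[tri[:, 2]] - verts[tri[:, 0]]
        fn = np.cross(e1, e2)
        norms = np.linalg.norm(fn, axis=1)
        ok = norms > 1e-12
        fn[ok] /= norms[ok, None]
        to_cam = camera.position - verts[tri[:, 0]]
        flip = np.einsum("ij,ij->i", fn, to_cam) < 0
        fn[flip] *= -1
        fn_view = fn @ Rv.T

        if item.face_colors is not None:
            fcol = item.face_colors
        else:
            fcol = None
            vcol = item.vertex_colors

        for f_idx in range(len(tri)):
            i0, i1, i2 = tri[f_idx]
            if behind[i0] or behind[i1] or behind[i2] or not ok[f_idx]:
                continue
            p0, p1, p2 = pix[i0], pix[i1], pix[i2]
            xmin = max(int(np.floor(min(p0[0], p1[0], p2[0]))), 0)
            xmax = min(int(np.ceil(max(p0[0], p1[0], p2[0]))), W - 1)
            ymin = max(int(np.floor(min(p0[1], p1[1], p2[1]))), 0)
            ymax = min(int(np.ceil(max(p0[1], p1[1], p2[1]))), H - 1)
            if xmin > xmax or ymin > ymax:
                continue
            area = (p1[0] - p0[0]) * (p2[1] - p0[1]) - (p1[1] - p0[1]) * (p2[0] - p0[0])
            if abs(area) < 1e-12:
                continue
            xs = np.arange(xmin, xmax + 1) + 0.5
            ys = np.arange(ymin, ymax + 1) + 0.5
            gx, gy = np.meshgrid(xs, ys)
            w0 = (p2[0] - p1[0]) * (gy - p1[1]) - (p2[1] - p1[1]) * (gx - p1[0])
            w1 = (p0[0] - p2[0]) * (gy - p2[1]) - (p0[1] - p2[1]) * (gx - p2[0])
            w2 = (p1[0] - p0[0]) * (gy - p0[1]) - (p1[1] - p0[1]) * (gx - p0[0])
            inside = (
                ((w0 >= 0) & (w1 >= 0) & (w2 >= 0))
                if area > 0
                else ((w0 <= 0) & (w1 <= 0) & (w2 <= 0))
            )
            if not inside.any():
                continue
            l0, l1, l2 = w0 / area, w1 / area, w2 / area
            inv_z = l0 / z[i0] + l1 / z[i1] + l2 / z[i2]
            zpix = 1.0 / inv_z
            rows = gy.astype(int)
            cols = gx.astype(int)
            closer = inside & (zpix < depth[rows, cols])
            if not closer.any():
                continue
            rr, cc = rows[closer], cols[closer]
            depth[rr, cc] = zpix[closer]
            hit[rr, cc] = True
            n_world[rr, cc] = fn[f_idx]
            n_view[rr, cc] = fn_view[f_idx]
            if fcol is not None:
                albedo[rr, cc] = fcol[f_idx]
            else:
                c = (
                    (l0[closer] / z[i0])[:, None] * vcol[i0]
                    + (l1[closer] / z[i1])[:, None] * vcol[i1]
                    + (l2[closer] / z[i2])[:, None] * vcol[i2]
                ) * zpix[closer][:, None]
                albedo[rr, cc] = np.clip(c, 0, 1)
            # perspective-correct world position for point lights
            p = (
                (l0[closer] / z[i0])[:, None] * verts[i0]
                + (l1[closer] / z[i1])[:, None] * verts[i1]
                + (l2[closer] / z[i2])[:, None] * verts[i2]
            ) * zpix[closer][:, None]
            wpos[rr, cc] = p
            if item.id_color is not None:
                idpass[rr, cc] = item.id_color
            else:
                idpass[rr, cc] = 0

    return PassSet(
        render=np.zeros((H, W, 3)),
        id=idpass,
        depth=depth,
        normal_view=(n_view + 1) / 2 * hit[:, :, None],
        normal_world=(n_world + 1) / 2 * hit[:, :, None],
        albedo=albedo,
        world_pos=wpos,
        hit=hit,
    )


def shade(
    scene: Scene,
    camera: CameraModel,
    passes: PassSet,
    lights: LightRig | None = None,
    dof_blur_scale: float = 0.0,
) -> np.ndarray:
    """Lambertian shading of the rasterized buffers into the render pass.

    render = albedo * (ambient + sun + spotlights), fogged toward the sky color
    by exp(-density * depth), exposure applied as a 2^EV gain, clipped to [0,1].
    """
    lights = lights or scene.lights
    if lights is None:
        lights = LightRig(np.array([0, 0, -1.0]), np.ones(3), 1.0, [], 0.5, 0.0)
    H, W = passes.depth.shape
    n = passes.normal_world * 2 - 1
    light = np.full((H, W, 3), lights.ambient)
    ndl = np.clip(-(n @ lights.sun_direction), 0, None)
    light += ndl[:, :, None] * lights.sun_color * lights.sun_intensity
    for sp in lights.spotlights:
        L = sp.position - passes.world_pos
        dist = np.linalg.norm(L, axis=2)
        lhat = L / np.maximum(dist[:, :, None], 1e-9)
        cos_to_axis = -(lhat @ sp.direction)
        half_cone = np.radians(sp.cone_angle_deg / 2)
        cone = np.clip(
            (cos_to_axis - np.cos(half_cone)) / max(1e-6, 1 - np.cos(half_cone)), 0, 1
        )
        diffuse = np.clip(np.einsum("ijk,ijk->ij", n, lhat), 0, None)
        falloff = 1.0 / (1.0 + 0.05 * dist**2)
        light += (cone * diffuse * falloff * sp.intensity)[:, :, None] * sp.color
    render = passes.albedo * light
    sky = np.asarray(lights.sky_color, float)
    render = np.where(passes.hit[:, :, None], render, sky)
    if lights.fog_density > 0:
        f = np.exp(-lights.fog_density * np.where(passes.hit, passes.depth, 0.0))
        render = sky + (render - sky) * np.where(passes.hit, f, 1.0)[:, :, None]
    render = render * 2.0 ** camera.exposure
    if dof_blur_scale > 0 and camera.aperture > 0:
        from scipy.ndimage import gaussian_filter
        sigma = dof_blur_scale / camera.aperture
        if sigma > 0.05:
            render = gaussian_filter(render, sigma=(sigma, sigma, 0))
    return np.clip(render, 0.0, 1.0)


# ---------------------------------------------------------------------------
# post-processing


@dataclass
class PostProcessSpec:
    temperature: float = 0.0     # warm(+)/cool(-) channel gain shift
    tint: float = 0.0            # green/magenta shift
    saturation: float = 1.0
    contrast: float = 1.0
    vignette_strength: float = 0.0
    grain_amplitude: float = 0.0
    grain_seed: int = 0

    def __post_init__(self):
        if self.saturation < 0 or self.contrast < 0:
            raise ValueError("multipliers must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.temperature == 0 and self.tint == 0 and self.saturation == 1
            and self.contrast == 1 and self.vignette_strength == 0
            and self.grain_amplitude == 0
        )


def post_process(render: np.ndarray, spec: PostProcessSpec) -> np.ndarray:
    """Apply the render-pass-only filter stack; identity spec returns the image bitwise."""
    if spec.is_identity:
        return render
    out = render.astype(float).copy()
    if spec.temperature != 0 or spec.tint != 0:
        gains = np.array([1 + spec.temperature, 1 + spec.tint, 1 - spec.temperature])
        out = out * gains
    if spec.saturation != 1:
        gray = out.mean(axis=2, keepdims=True)
        out = gray + (out - gray) * spec.saturation
    if spec.contrast != 1:
        out = (out - 0.5) * spec.contrast + 0.5
    if spec.vignette_strength != 0:
        H, W = out.shape[:2]
        yy, xx = np.mgrid[0:H, 0:W]
        r2 = ((xx + 0.5 - W / 2) ** 2 + (yy + 0.5 - H / 2) ** 2)
        r2max = (W / 2) ** 2 + (H / 2) ** 2
        out = out * (1 - spec.vignette_strength * (r2 / r2max))[:, :, None]
    if spec.grain_amplitude != 0:
        g = np.random.default_rng(spec.grain_seed).normal(0, spec.grain_amplitude, out.shape)
        out = out + g
    return np.clip(out, 0.0, 1.0)
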