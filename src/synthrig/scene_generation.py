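"""Procedural environment generation under a leveled randomization hierarchy.

One scene per iteration: a terrain heightfield displaced by the red channel of a
procedurally generated RGB control map, asset instances dropped onto the surface
by scatterers, and a randomized light rig.  Levels are re-randomized at
configurable periods, ordered from computationally most to least demanding
(terrain, assets, subjects, then materials/lighting/camera every iteration);
regenerating a lower level cascades upward because higher-level elements depend
on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

# hierarchy levels, most to least expensive
LEVEL_TERRAIN, LEVEL_ASSETS, LEVEL_SUBJECTS, LEVEL_CAMERA = 0, 1, 2, 3


@dataclass
class NoiseSpec:
    octaves: int = 4          # pattern complexity
    frequency: int = 4        # base lattice frequency (granularity)
    amplitude: float = 0.5    # displacement strength of the red channel, in [0, 0.5]


@dataclass
class RGBMap:
    """Square control map; red encodes displacement around the 0.5 mean level,
    green drives the ground material blend, blue is filled but unused."""

    values: np.ndarray  # (res, res, 3) in [0, 1]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1] or v.shape[2] != 3:
            raise ValueError("RGBMap must be square with 3 channels")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("RGBMap values must lie in [0, 1]")
        self.values = v

    @property
    def resolution(self) -> int:
        return self.values.shape[0]


def value_noise_lattice(frequency: int, rng: np.random.Generator) -> np.ndarray:
    """Random lattice values in [0,1] on a (frequency+1)^2 grid (shared edge nodes)."""
    return rng.random((frequency + 1, frequency + 1))


def sample_value_noise(lattice: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Smoothstep-interpolated value noise at normalized coordinates u, v in [0,1]."""
    freq = lattice.shape[0] - 1
    x = np.clip(u, 0, 1) * freq
    y = np.clip(v, 0, 1) * freq
    i = np.minimum(x.astype(int), freq - 1)
    j = np.minimum(y.astype(int), freq - 1)
    fx, fy = x - i, y - j
    sx = fx * fx * (3 - 2 * fx)
    sy = fy * fy * (3 - 2 * fy)
    v00 = lattice[i, j]
    v10 = lattice[i + 1, j]
    v01 = lattice[i, j + 1]
    v11 = lattice[i + 1, j + 1]
    return (v00 * (1 - sx) * (1 - sy) + v10 * sx * (1 - sy)
            + v01 * (1 - sx) * sy + v11 * sx * sy)


def _octave_noise(resolution: int, spec: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Multi-octave value noise normalized to zero mean-level, range [-1, 1]."""
    u, v = np.meshgrid(
        np.linspace(0, 1, resolution), np.linspace(0, 1, resolution), indexing="ij"
    )
    total = np.zeros((resolution, resolution))
    amp, norm = 1.0, 0.0
    for o in range(spec.octaves):
        lattice = value_noise_lattice(spec.frequency * 2**o, rng)
        total += amp * (2 * sample_value_noise(lattice, u, v) - 1)
        norm += amp
        amp *= 0.5
    return total / norm


def generate_rgb_map(resolution: int, noise_spec: NoiseSpec, rng: np.random.Generator) -> RGBMap:
    """Procedural control map: red = 0.5 + amplitude * noise (displacement),
    green = independent material noise, blue filled but unused by default."""
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if noise_spec.amplitude == 0:
        red = np.full((resolution, resolution), 0.5)
    else:
        red = 0.5 + noise_spec.amplitude * _octave_noise(resolution, noise_spec, rng)
    green = 0.5 + 0.5 * _octave_noise(resolution, noise_spec, rng)
    blue = 0.5 + 0.5 * _octave_noise(resolution, noise_spec, rng)
    values = np.clip(np.stack([red, green, blue], axis=-1), 0.0, 1.0)
    return RGBMap(values)


@dataclass
class Terrain:
    """Heightfield over a square [-extent/2, extent/2]^2 footprint."""

    heightfield: np.ndarray   # (res, res) world-unit heights, index [i=x, j=y]
    extent: float
    amplitude: float
    material_field: np.ndarray

    @property
    def resolution(self) -> int:
        return self.heightfield.shape[0]

    def height_at(self, x: np.ndarray | float, y: np.ndarray | float) -> np.ndarray | float:
        """Bilinear height lookup; positions outside the extent return -inf."""
        x, y = np.asarray(x, float), np.asarray(y, float)
        half = self.extent / 2
        res = self.resolution
        gx = (x + half) / self.extent * (res - 1)
        gy = (y + half) / self.extent * (res - 1)
        inside = (gx >= 0) & (gx <= res - 1) & (gy >= 0) & (gy <= res - 1)
        gx_c = np.clip(gx, 0, res - 1)
        gy_c = np.clip(gy, 0, res - 1)
        i = np.minimum(gx_c.astype(int), res - 2)
        j = np.minimum(gy_c.astype(int), res - 2)
        fx, fy = gx_c - i, gy_c - j
        h = (self.heightfield[i, j] * (1 - fx) * (1 - fy)
             + self.heightfield[i + 1, j] * fx * (1 - fy)
             + self.heightfield[i, j + 1] * (1 - fx) * fy
             + self.heightfield[i + 1, j + 1] * fx * fy)
        h = np.where(inside, h, -np.inf)
        return float(h) if h.ndim == 0 else h

    def mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Triangulated grid: vertices (res^2, 3), faces, per-vertex material weight."""
        res = self.resolution
        half = self.extent / 2
        xs = np.linspace(-half, half, res)
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([gx.ravel(), gy.ravel(), self.heightfield.ravel()])
        idx = np.arange(res * res).reshape(res, res)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[:-1, 1:].ravel()
        d = idx[1:, 1:].ravel()
        faces = np.concatenate([np.column_stack([a, b, d]), np.column_stack([a, d, c])])
        return verts, faces, self.material_field.ravel()


def build_terrain(rgb_map: RGBMap, extent: float, amplitude: float) -> Terrain:
    """height(i,j) = (red - 0.5) * 2 * amplitude; red 0.5 is mean ground level."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    height = (rgb_map.values[:, :, 0] - 0.5) * 2.0 * amplitude
    return Terrain(height, float(extent), float(amplitude), rgb_map.values[:, :, 1].copy())


# ---------------------------------------------------------------------------
# scatterers


@dataclass
class Scatterer:
    asset_set: list[trimesh.Trimesh]
    size_range: tuple[float, float] = (0.5, 2.0)
    count_range: tuple[int, int] = (5, 20)
    color_a: tuple[float, float, float] = (0.5, 0.45, 0.4)
    color_b: tuple[float, float, float] = (0.35, 0.3, 0.25)

    def __post_init__(self):
        if not (0 < self.size_range[0] <= self.size_range[1]):
            raise ValueError("size_range must satisfy 0 < min <= max")
        if not (0 < self.count_range[0] <= self.count_range[1]):
            raise ValueError("count_range must satisfy 0 < min <= max")


@dataclass
class PlacedAsset:
    """One scattered instance: normalized source mesh + rigid placement."""

    mesh: trimesh.Trimesh
    position: np.ndarray     # (3,) world, base resting on the terrain
    yaw_deg: float
    size: float
    face_colors: np.ndarray  # (n_faces, 3)

    def transform(self) -> np.ndarray:
        c, s = np.cos(np.radians(self.yaw_deg)), np.sin(np.radians(self.yaw_deg))
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        T = np.eye(4)
        T[:3, :3] = R * self.size
        T[:3, 3] = self.position
        return T

    def world_vertices(self) -> np.ndarray:
        T = self.transform()
        return self.mesh.vertices @ T[:3, :3].T + T[:3, 3]

    def obb(self) -> tuple[np.ndarray, np.ndarray, float]:
        """Oriented bounding box (center, half-extents, yaw) for collision/rays."""
        lo, hi = self.mesh.bounds
        local_center = (lo + hi) / 2
        half = (hi - lo) / 2 * self.size
        T = self.transform()
        center = local_center @ T[:3, :3].T + T[:3, 3]
        return center, half, self.yaw_deg


def _procedural_face_colors(n_faces: int, scatterer: Scatterer, rng: np.random.Generator) -> np.ndarray:
    """Two-color noise blend shared by all instances of one scatterer."""
    w = rng.random(n_faces)[:, None]
    a = np.asarray(scatterer.color_a, float)
    b = np.asarray(scatterer.color_b, float)
    return a * (1 - w) + b * w


def scatter_assets(
    scatterers: list[Scatterer], terrain: Terrain, rng: np.random.Generator
) -> list[PlacedAsset]:
    """Per scatterer: pick one asset, draw a count, drop instances onto the
    heightfield with random yaw and uniform size; instances share the
    scatterer's procedural material."""
    placed = []
    half = terrain.extent / 2
    for sc in scatterers:
        if not sc.asset_set:
            raise ValueError("scatterer has an empty asset_set")
        asset = sc.asset_set[int(rng.integers(len(sc.asset_set)))]
        count = int(rng.integers(sc.count_range[0], sc.count_range[1] + 1))
        colors = _procedural_face_colors(len(asset.faces), sc, rng)
        for _ in range(count):
            size = float(rng.uniform(*sc.size_range))
            x, y = rng.uniform(-half, half, size=2)
            yaw = float(rng.uniform(0, 360))
            ground = terrain.height_at(x, y)
            z = ground - asset.bounds[0][2] * size  # rest the proxy bottom on the surface
            placed.append(PlacedAsset(asset, np.array([x, y, z]), yaw, size, colors))
    return placed


# ---------------------------------------------------------------------------
# lights


@dataclass
class Spotlight:
    position: np.ndarray
    direction: np.ndarray
    cone_angle_deg: float
    color: np.ndarray
    intensity: float


@dataclass
class LightRig:
    sun_direction: np.ndarray            # unit vector, pointing from the light
    sun_color: np.ndarray
    sun_intensity: float
    spotlights: list[Spotlight] = field(default_factory=list)
    ambient: float = 0.3
    fog_density: float = 0.0
    sky_color: np.ndarray = field(default_factory=lambda: np.array([0.7, 0.8, 0.9]))

    def __post_init__(self):
        if self.sun_intensity < 0 or self.ambient < 0 or self.fog_density < 0:
            raise ValueError("light intensities and fog density must be >= 0")


@dataclass
class LightConfig:
    spot_count_range: tuple[int, int] = (0, 3)
    spot_intensity_range: tuple[float, float] = (0.2, 1.0)
    spot_cone_range: tuple[float, float] = (20.0, 60.0)
    sun_intensity_range: tuple[float, float] = (0.4, 1.0)
    ambient_range: tuple[float, float] = (0.15, 0.45)
    fog_range: tuple[float, float] = (0.0, 0.02)
    spot_height_range: tuple[float, float] = (3.0, 10.0)


def randomize_lights(config: LightConfig, extent: float, rng: np.random.Generator) -> LightRig:
    """Sample a directional sun, ambient level, fog density, and 0..n colored spotlights."""
    az = rng.uniform(0, 2 * np.pi)
    el = rng.uniform(np.radians(25), np.radians(80))
    sun_dir = -np.array([np.cos(az) * np.cos(el), np.sin(az) * np.cos(el), np.sin(el)])
    sun_color = 1.0 - 0.15 * rng.random(3)
    sun_int = float(rng.uniform(*config.sun_intensity_range))
    ambient = float(rng.uniform(*config.ambient_range))
    fog = float(rng.uniform(*config.fog_range))
    n_spots = int(rng.integers(config.spot_count_range[0], config.spot_count_range[1] + 1))
    spots = []
    for _ in range(n_spots):
        pos = np.array([
            rng.uniform(-extent / 2, extent / 2),
            rng.uniform(-extent / 2, extent / 2),
            rng.uniform(*config.spot_height_range),
        ])
        d = np.array([rng.uniform(-0.3, 0.3), rng.uniform(-0.3, 0.3), -1.0])
        d /= np.linalg.norm(d)
        spots.append(Spotlight(
            pos, d,
            float(rng.uniform(*config.spot_cone_range)),
            0.4 + 0.6 * rng.random(3),
            float(rng.uniform(*config.spot_intensity_range)),
        ))
    sky = np.clip(np.array([0.55, 0.65, 0.8]) + 0.2 * (rng.random(3) - 0.5), 0, 1)
    return LightRig(sun_dir, sun_color, sun_int, spots, ambient, fog, sky)


# ---------------------------------------------------------------------------
# update schedule


@dataclass
class ScheduleState:
    """Per-level re-randomization periods (iterations); camera level is every iteration."""

    periods: tuple[int, int, int, int] = (20, 5, 1, 1)
    iteration: int = 0

    def __post_init__(self):
        if any(p < 1 for p in self.periods):
            raise ValueError("schedule periods must be >= 1")
        if self.periods[LEVEL_CAMERA] != 1:
            raise ValueError("camera/lighting/materials level must update every iteration")


def levels_due(periods: tuple[int, int, int, int], iteration: int) -> set[int]:
    """Levels to regenerate at this iteration: own period hit, plus cascade —
    regenerating a lower (more fundamental) level forces all higher levels."""
    due = {k for k, p in enumerate(periods) if iteration % p == 0}
    if due:
        due |= set(range(min(due), len(periods)))
    return due


def last_regen_iteration(periods: tuple[int, int, int, int], level: int, iteration: int) -> int:
    """Most recent iteration <= ``iteration`` at which ``level`` was regenerated."""
    for it in range(iteration, -1, -1):
        if level in levels_due(periods, it):
            return it
    return 0


def advance_schedule(state: ScheduleState) -> set[int]:
    """Return the set of levels due at the current iteration and advance the counter."""
    due = levels_due(state.periods, state.iteration)
    state.iteration += 1
    return due


# ---------------------------------------------------------------------------
# scene container


@dataclass
class PlacedSubject:
    """A population member placed and posed in the scene (filled by placement_pose)."""

    instance: object                       # SubjectInstance
    position: np.ndarray
    rotation_deg: np.ndarray               # center rotation, XYZ Euler degrees
    pose_angles: dict
    vertices_world: np.ndarray             # posed, scaled, placed mesh vertices
    keypoints_world: dict[str, np.ndarray]
    leg_status: dict[str, str] = field(default_factory=dict)

    def spheres_world(self) -> list[tuple[np.ndarray, float]]:
        """Proxy spheres of the placed mesh (capsule-like chains per bone)."""
        from .subject_model import fit_bone_spheres

        out = []
        for b in self.instance.model.bones:
            if len(b.segment_vertices) == 0:
                continue
            out.extend(fit_bone_spheres(self.vertices_world[b.segment_vertices]))
        return out


@dataclass
class Scene:
    terrain: Terrain
    assets: list[PlacedAsset] = field(default_factory=list)
    subjects: list[PlacedSubject] = field(default_factory=list)
    lights: Optional[LightRig] = None
    ground_colors: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.55, 0.5, 0.42), (0.3, 0.26, 0.2),
    )
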