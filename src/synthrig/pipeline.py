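"""Generation-loop orchestration: configuration, seeding, and dataset writing.

A run is a pure function of (config, seeds): every randomized element draws
from its own generator seeded by (master seed, regeneration iteration, element
tag), so adding or removing one element never perturbs the streams of the
others, re-running a config reproduces the dataset bitwise, and a run with the
same environment seed but a different subject seed yields identical terrain,
assets and lighting populated with different subjects.

Config mirrors a four-tab layout: general (samples, resolution, output),
subjects (population + posing), environment (terrain / scatterers / lights),
debug (seeds, schedule periods); camera and post-processing ranges ride along
as their own blocks.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import scene_generation as sg
from .annotation_io import (
    BatchAnnotation, SampleAnnotation, annotate_sample, write_batch, write_passes, write_sample,
)
from .placement_pose import PosingConfig, place_subject, pose_subject
from .primitives import default_asset_library, make_stick_subject
from .rendering import CameraConfig, PassSet, PostProcessSpec, post_process, rasterize, shade, spawn_camera
from .scene_generation import (
    LightConfig, NoiseSpec, Scene, build_terrain, generate_rgb_map, last_regen_iteration, scatter_assets,
)
from .subject_model import ColorVariation, PopulationSpec, build_population, load_subject

# element tags for seed derivation
TAG_TERRAIN, TAG_ASSETS, TAG_SUBJECTS, TAG_CAMERA, TAG_GRAIN, TAG_POPULATION = 11, 22, 33, 44, 55, 66


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


@dataclass
class GeneralConfig:
    n_samples: int = 10
    resolution: tuple[int, int] = (256, 256)
    dataset_name: str = "synthetic"
    output_dir: str = "out"
    render_format: str = "png"          # png | jpg
    jpg_quality: int = 90
    jpg_quality_random: bool = False    # randomize compression per sample


@dataclass
class SubjectsConfig:
    classes: list[dict] = field(default_factory=lambda: [{"name": "stick", "fraction": 1.0}])
    population_size: int = 3
    scale_variation: float = 0.2
    color_variation: ColorVariation = field(default_factory=ColorVariation)
    posing: PosingConfig = field(default_factory=PosingConfig)


@dataclass
class EnvironmentConfig:
    terrain_resolution: int = 256
    terrain_extent: float = 20.0
    terrain_amplitude: float = 0.8
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    scatterers: list[dict] = field(
        default_factory=lambda: [
            {"assets": ["box", "pebble"], "size_range": (0.3, 1.0), "count_range": (3, 8)},
            {"assets": ["cylinder", "icosphere"], "size_range": (0.2, 0.6), "count_range": (2, 6)},
        ]
    )
    lights: LightConfig = field(default_factory=LightConfig)


@dataclass
class PostConfig:
    temperature_range: tuple[float, float] = (-0.05, 0.05)
    tint_range: tuple[float, float] = (-0.03, 0.03)
    saturation_range: tuple[float, float] = (0.9, 1.1)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    vignette_range: tuple[float, float] = (0.0, 0.25)
    grain_range: tuple[float, float] = (0.0, 0.015)


@dataclass
class DebugConfig:
    seed: int = 0
    subject_seed: int | None = None     # defaults to the master seed
    schedule_periods: tuple[int, int, int, int] = (20, 5, 1, 1)


@dataclass
class GeneratorConfig:
    general: GeneralConfig = field(default_factory=GeneralConfig)
    subjects: SubjectsConfig = field(default_factory=SubjectsConfig)
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    post: PostConfig = field(default_factory=PostConfig)
    debug: DebugConfig = field(default_factory=DebugConfig)


def _apply(obj, data: dict, errors: list[str], prefix: str):
    for k, v in data.items():
        if not hasattr(obj, k):
            errors.append(f"{prefix}: unknown key '{k}'")
            continue
        cur = getattr(obj, k)
        if isinstance(cur, tuple) and isinstance(v, (list, tuple)):
            v = tuple(v)
        setattr(obj, k, v)
    return obj


def validate_config(source: str | Path | dict) -> GeneratorConfig:
    """Parse + normalize a config mapping (or YAML file); raises ConfigError
    with the full error list on invalid input, echoing defaults otherwise."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text())
    else:
        data = dict(source)
    errors: list[str] = []
    cfg = GeneratorConfig()
    if "subjects" not in data:
        errors.append("missing required block 'subjects'")
    for block, target in (
        ("general", cfg.general), ("subjects", cfg.subjects),
        ("environment", cfg.environment), ("camera", cfg.camera),
        ("post", cfg.post), ("debug", cfg.debug),
    ):
        raw = data.get(block, {})
        if not isinstance(raw, dict):
            errors.append(f"block '{block}' must be a mapping")
            continue
        sub = dict(raw)
        if block == "subjects":
            if "color_variation" in sub:
                cfg.subjects.color_variation = _apply(
                    ColorVariation(), sub.pop("color_variation"), errors, "subjects.color_variation")
            if "posing" in sub:
                cfg.subjects.posing = _apply(PosingConfig(), sub.pop("posing"), errors, "subjects.posing")
        if block == "environment":
            if "noise" in sub:
                cfg.environment.noise = _apply(NoiseSpec(), sub.pop("noise"), errors, "environment.noise")
            if "lights" in sub:
                cfg.environment.lights = _apply(LightConfig(), sub.pop("lights"), errors, "environment.lights")
        _apply(target, sub, errors, block)
    if cfg.general.n_samples < 1:
        errors.append("general.n_samples must be >= 1")
    res = cfg.general.resolution
    if min(res) < 32:
        errors.append("general.resolution must be >= 32")
    if cfg.environment.terrain_amplitude < 0:
        errors.append("environment.terrain_amplitude must be >= 0")
    if cfg.subjects.population_size < 1:
        errors.append("subjects.population_size must be >= 1")
    frac = sum(c.get("fraction", 0) for c in cfg.subjects.classes)
    if abs(frac - 1.0) > 1e-9:
        errors.append(f"subjects.classes fractions must sum to 1, got {frac}")
    if errors:
        raise ConfigError(errors)
    cfg.camera.resolution = tuple(res)
    return cfg


# ---------------------------------------------------------------------------
# seeding


def element_rng(master_seed: int, iteration: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, iteration, tag]))


def element_seed(master_seed: int, iteration: int, tag: int) -> int:
    return int(np.random.SeedSequence([master_seed, iteration, tag]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# model + population assembly


def build_models(cfg: SubjectsConfig) -> list:
    models = []
    for entry in cfg.classes:
        if "mesh" in entry:
            models.append(load_subject(entry["mesh"], entry["sidecar"]))
        else:
            models.append(
                make_stick_subject(
                    class_name=entry.get("name", "stick"),
                    color=tuple(entry.get("color", (0.45, 0.30, 0.15))),
                    body_length=float(entry.get("body_length", 2.0)),
                    with_antennae=bool(entry.get("with_antennae", False)),
                )
            )
    return models


def build_run_population(config: GeneratorConfig):
    sc = config.subjects
    models = build_models(sc)
    spec = PopulationSpec(
        entries=[(m, c.get("fraction", 1.0)) for m, c in zip(models, sc.classes)],
        population_size=sc.population_size,
        scale_variation=sc.scale_variation,
        color_variation=sc.color_variation,
    )
    subject_seed = config.debug.subject_seed
    if subject_seed is None:
        subject_seed = config.debug.seed
    rng = element_rng(subject_seed, 0, TAG_POPULATION)
    return build_population(spec, rng)


# ---------------------------------------------------------------------------
# one iteration


def _asset_library(env: EnvironmentConfig):
    lib = {}
    for sc in env.scatterers:
        for name in sc["assets"]:
            if name not in lib:
                lib[name] = default_asset_library([name])[0]
    return lib


def build_iteration(
    config: GeneratorConfig, population, iteration: int, caches: dict | None = None
) -> tuple[Scene, object, PostProcessSpec]:
    """Deterministically assemble the scene + camera for one iteration,
    honoring the per-level schedule (cached states reused between updates)."""
    caches = caches if caches is not None else {}
    env = config.environment
    periods = tuple(config.debug.schedule_periods)
    seed = config.debug.seed
    subject_seed = config.debug.subject_seed if config.debug.subject_seed is not None else seed

    k_t = last_regen_iteration(periods, sg.LEVEL_TERRAIN, iteration)
    key = ("terrain", k_t)
    if key not in caches:
        rng = element_rng(seed, k_t, TAG_TERRAIN)
        rgb = generate_rgb_map(env.terrain_resolution, env.noise, rng)
        caches[key] = build_terrain(rgb, env.terrain_extent, env.terrain_amplitude)
    terrain = caches[key]

    k_a = last_regen_iteration(periods, sg.LEVEL_ASSETS, iteration)
    key = ("assets", k_a)
    if key not in caches:
        rng = element_rng(seed, k_a, TAG_ASSETS)
        lib = _asset_library(env)
        scatterers = [
            sg.Scatterer(
                asset_set=[lib[n] for n in s["assets"]],
                size_range=tuple(s.get("size_range", (0.5, 2.0))),
                count_range=tuple(s.get("count_range", (5, 20))),
            )
            for s in env.scatterers
        ]
        caches[key] = scatter_assets(scatterers, terrain, rng)
    assets = caches[key]

    k_s = last_regen_iteration(periods, sg.LEVEL_SUBJECTS, iteration)
    key = ("subjects", k_s)
    if key not in caches:
        rng = element_rng(subject_seed, k_s, TAG_SUBJECTS)
        scene = Scene(terrain=terrain, assets=assets)
        for inst in population:
            placement = place_subject(scene, inst, rng, config.subjects.posing)
            scene.subjects.append(pose_subject(inst, placement, scene, rng, config.subjects.posing))
        caches[key] = scene.subjects
    scene = Scene(terrain=terrain, assets=assets, subjects=caches[key])

    rng = element_rng(seed, iteration, TAG_CAMERA)
    scene.lights = sg.randomize_lights(env.lights, env.terrain_extent, rng)
    camera = spawn_camera(scene, rng, config.camera)
    p = config.post
    post_spec = PostProcessSpec(
        temperature=float(rng.uniform(*p.temperature_range)),
        tint=float(rng.uniform(*p.tint_range)),
        saturation=float(rng.uniform(*p.saturation_range)),
        contrast=float(rng.uniform(*p.contrast_range)),
        vignette_strength=float(rng.uniform(*p.vignette_range)),
        grain_amplitude=float(rng.uniform(*p.grain_range)),
        grain_seed=element_seed(seed, iteration, TAG_GRAIN),
    )
    return scene, camera, post_spec


def render_iteration(
    scene: Scene, camera, post_spec: PostProcessSpec, near: float = 0.05, far: float = 200.0
) -> PassSet:
    passes = rasterize(scene, camera, near=near)
    passes.render = post_process(shade(scene, camera, passes), post_spec)
    return passes


# ---------------------------------------------------------------------------
# full runs


def preview(config: GeneratorConfig, iteration: int) -> tuple[PassSet, SampleAnnotation]:
    """Render iteration ``iteration`` exactly as :func:`generate` would,
    without writing a dataset."""
    population = build_run_population(config)
    scene, camera, post_spec = build_iteration(config, population, iteration)
    passes = render_iteration(scene, camera, post_spec)
    return passes, annotate_sample(scene, camera, passes, iteration)


def generate(config: GeneratorConfig, out_dir: str | Path | None = None) -> Path:
    """Run the full loop: n_samples scheduled scene iterations, four image
    passes + sample annotation each, one batch file, one run manifest.
    Returns the dataset directory."""
    t_start = time.time()
    out = Path(out_dir if out_dir is not None else config.general.output_dir)
    dataset_dir = out / config.general.dataset_name
    (dataset_dir / "samples").mkdir(parents=True, exist_ok=True)
    population = build_run_population(config)
    W, H = config.general.resolution
    batch = BatchAnnotation(
        dataset_name=config.general.dataset_name,
        n_samples=config.general.n_samples,
        seed=config.debug.seed,
        pass_width=W,
        pass_height=H,
        subjects=[
            {
                "instance_id": inst.instance_id,
                "id_color": list(inst.id_color),
                "class_name": inst.model.class_name,
                "scale": inst.scale,
            }
            for inst in population
        ],
    )
    write_batch(batch, dataset_dir / "batch.json")
    caches: dict = {}
    timings = []
    manifest = {
        "config": _config_dict(config),
        "complete": False,
        "toolkit": "synthrig 0.1.0",
        "warnings": [],
    }
    try:
        for i in range(config.general.n_samples):
            t0 = time.time()
            scene, camera, post_spec = build_iteration(config, population, i, caches)
            passes = render_iteration(scene, camera, post_spec)
            jpg_q = config.general.jpg_quality
            if config.general.render_format == "jpg" and config.general.jpg_quality_random:
                jpg_q = int(element_rng(config.debug.seed, i, TAG_GRAIN + 1).integers(60, 98))
            write_passes(
                passes, dataset_dir, i, near=0.05, far=200.0,
                render_format=config.general.render_format, jpg_quality=jpg_q,
            )
            ann = annotate_sample(scene, camera, passes, i)
            write_sample(ann, dataset_dir / "samples" / f"{i:06d}.json")
            timings.append(round(time.time() - t0, 4))
    except Exception as exc:
        manifest["failed_at_sample"] = len(timings)
        manifest["error"] = str(exc)
        manifest["per_sample_seconds"] = timings
        (dataset_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["complete"] = True
    manifest["per_sample_seconds"] = timings
    manifest["total_seconds"] = round(time.time() - t_start, 3)
    (dataset_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return dataset_dir


def _config_dict(config: GeneratorConfig) -> dict:
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [clean(v) for v in x]
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        return x

    return clean(asdict(config))
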