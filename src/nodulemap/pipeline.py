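"""End-to-end orchestration: phantom -> scene -> vision -> scan -> features
-> classification -> fusion -> evaluation.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
a master seed; identical configs produce identical outputs.  The default
experiment mirrors the physical study design: seven replicate phantoms,
each with eight inclusions (two per diameter in {3, 6, 9, 12} mm, the small
ones buried deeper), scanned on a 2 mm grid with realistic load-cell and
ultrasound noise, classified per feature map and fused with AND/OR logic.

Seed fan-out: the master seed spawns per-phantom seeds; each phantom seed
drives inclusion placement, the camera pose, per-point noise substreams and
the FCM initialisations for that phantom.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import __version__
from .classify import (
    ClassificationMap,
    DegenerateClusteringError,
    FcmParams,
    classify_values,
    fuse_and,
    fuse_or,
    save_classification,
)
from .evaluate import (
    ConfusionSummary,
    format_summary,
    pool_summaries,
    save_category_grid,
    save_category_png,
    save_summary,
    summarize_methods,
)
from .features import FeatureMaps, build_feature_maps, save_feature_maps
from .phantom import Phantom, make_reference_phantom, save_phantom
from .scan_sim import (
    AcquisitionConfig,
    ScanDataset,
    render_scene_image,
    save_dataset,
    simulate_scan,
)
from .vision import build_indentation_grid, normalize_orientation, subtract_background

__all__ = [
    "RunConfig",
    "PhantomResult",
    "run_single_phantom",
    "run_experiment",
    "run_pipeline",
]

METHOD_NAMES = ("stiffness", "ultrasound", "or", "and")


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment.

    ``n_phantoms`` replicate phantoms are generated (seed-derived layouts)
    and scanned; ``deep_small`` buries the 3 and 6 mm inclusions deeper
    than mid-thickness, reproducing the nodules that palpation misses.
    """

    seed: int = 0
    n_phantoms: int = 7
    deep_small: bool = True
    randomize_positions: bool = True
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fcm: FcmParams = field(default_factory=FcmParams)
    vision_threshold: float = 0.1
    grid_margin_mm: float = 1.5
    mm_per_pixel: float = 0.5
    use_vision: bool = True
    max_pose_offset_mm: float = 5.0
    max_pose_rotation_deg: float = 25.0
    save_raw_signals: bool = False
    save_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "acquisition" in data and isinstance(data["acquisition"], dict):
            data["acquisition"] = AcquisitionConfig(**data["acquisition"])
        if "fcm" in data and isinstance(data["fcm"], dict):
            data["fcm"] = FcmParams(**data["fcm"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def without_noise(self) -> "RunConfig":
        return replace(self, acquisition=self.acquisition.without_noise())


@dataclass
class PhantomResult:
    """All artifacts of one phantom's scan and classification."""

    phantom: Phantom
    phantom_seed: int
    dataset: ScanDataset
    features: FeatureMaps
    maps: dict[str, ClassificationMap]
    summaries: dict[str, ConfusionSummary]
    categories: dict[str, np.ndarray]
    truth: np.ndarray
    warnings: list[str]


def _phantom_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(int(master_seed) & 0x7FFFFFFF).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def _all_healthy_map(points, method: str) -> ClassificationMap:
    n = len(points)
    return ClassificationMap(
        points=points,
        labels=np.zeros(n, dtype=bool),
        tumor_membership=np.zeros(n),
        method=method,
    )


def _classify_or_degenerate(
    values, points, method: str, params: FcmParams, messages: list[str]
) -> ClassificationMap:
    try:
        return classify_values(values, points, method, params)
    except DegenerateClusteringError as exc:
        msg = f"{method}: degenerate clustering ({exc}); labeling all points healthy"
        warnings.warn(msg, stacklevel=3)
        messages.append(msg)
        return _all_healthy_map(points, method)


def run_single_phantom(
    config: RunConfig, phantom_seed: int, phantom: Phantom | None = None
) -> PhantomResult:
    """Run the whole pipeline for one phantom replica.

    ``phantom`` overrides the seed-generated reference phantom (e.g. a
    homogeneous block, or a layout loaded from file).
    """
    if phantom is None:
        phantom = make_reference_phantom(
            seed=phantom_seed,
            randomize_positions=config.randomize_positions,
            deep_small=config.deep_small,
        )
    acq = replace(config.acquisition, seed=phantom_seed)

    if config.use_vision:
        pose_rng = np.random.default_rng(np.random.SeedSequence((phantom_seed, 7)))
        pose = (
            float(pose_rng.uniform(-config.max_pose_offset_mm, config.max_pose_offset_mm)),
            float(pose_rng.uniform(-config.max_pose_offset_mm, config.max_pose_offset_mm)),
            float(
                pose_rng.uniform(
                    -config.max_pose_rotation_deg, config.max_pose_rotation_deg
                )
            ),
        )
        scene = render_scene_image(
            phantom, pose=pose, mm_per_pixel=config.mm_per_pixel, seed=phantom_seed
        )
        mask = subtract_background(
            scene.sample,
            scene.background,
            scene.mm_per_pixel,
            threshold=config.vision_threshold,
        )
        mask = normalize_orientation(mask)
        grid = build_indentation_grid(
            mask, step_mm=acq.grid_step_mm, margin_mm=config.grid_margin_mm
        )
        points = grid.points
    else:
        step = acq.grid_step_mm
        margin = config.grid_margin_mm
        xs = np.arange(0.0, phantom.length_mm + 1e-9, step)
        ys = np.arange(0.0, phantom.width_mm + 1e-9, step)
        points = np.array(
            [
                (x, y)
                for y in ys
                for x in xs
                if margin <= x <= phantom.length_mm - margin
                and margin <= y <= phantom.width_mm - margin
            ]
        )

    dataset = simulate_scan(phantom, points, acq)
    features = build_feature_maps(dataset)

    messages: list[str] = []
    fcm_k = replace(config.fcm, seed=phantom_seed)
    fcm_cia = replace(config.fcm, seed=phantom_seed + 1)
    stiffness_map = _classify_or_degenerate(
        features.k_values, points, "stiffness", fcm_k, messages
    )
    us_map = _classify_or_degenerate(
        features.cia_values, points, "ultrasound", fcm_cia, messages
    )
    maps = {
        "stiffness": stiffness_map,
        "ultrasound": us_map,
        "or": fuse_or(stiffness_map, us_map),
        "and": fuse_and(stiffness_map, us_map),
    }
    summaries, categories, truth = summarize_methods(dataset, maps, phantom)
    return PhantomResult(
        phantom=phantom,
        phantom_seed=phantom_seed,
        dataset=dataset,
        features=features,
        maps=maps,
        summaries=summaries,
        categories=categories,
        truth=truth,
        warnings=messages,
    )


def run_experiment(config: RunConfig) -> tuple[list[PhantomResult], dict[str, ConfusionSummary]]:
    """Run all phantom replicas and pool the per-method confusion counts."""
    seeds = _phantom_seeds(config.seed, config.n_phantoms)
    results = [run_single_phantom(config, s) for s in seeds]
    pooled = {
        name: pool_summaries([r.summaries[name] for r in results])
        for name in METHOD_NAMES
    }
    return results, pooled


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the experiment and write every artifact under ``out_dir``.

    Writes, per phantom: the phantom truth, the feature maps, the four
    classification maps, the four category grids and a confusion summary;
    plus the pooled summary, a human-readable report and a run manifest.
    Raw force traces and A-scan waveforms are written only when
    ``config.save_raw_signals`` is set (they dominate the output size).
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    results, pooled = run_experiment(config)

    report_lines = [f"nodulemap {__version__} | seed {config.seed} | "
                    f"{config.n_phantoms} phantom(s)"]
    for i, res in enumerate(results):
        pdir = out / f"phantom_{i:02d}"
        pdir.mkdir(exist_ok=True)
        save_phantom(res.phantom, pdir / "phantom.yaml")
        save_feature_maps(res.features, pdir / "features.tsv")
        for name, cmap in res.maps.items():
            save_classification(cmap, pdir / f"labels_{name}.tsv")
            save_category_grid(
                res.dataset.grid, res.categories[name], pdir / f"categories_{name}.tsv"
            )
            if config.save_plots:
                save_category_png(
                    res.dataset.grid,
                    res.categories[name],
                    pdir / f"categories_{name}.png",
                    title=f"phantom {i} - {name}",
                )
        save_summary(res.summaries, pdir / "summary.tsv")
        if config.save_raw_signals:
            save_dataset(res.dataset, pdir / "scan")
        report_lines.append(f"phantom {i} (seed {res.phantom_seed}):")
        for name in METHOD_NAMES:
            report_lines.append("  " + format_summary(name, res.summaries[name]))
        for msg in res.warnings:
            report_lines.append(f"  warning: {msg}")

    save_summary(pooled, out / "pooled_summary.tsv")
    report_lines.append(f"pooled over {len(results)} phantom(s):")
    for name in METHOD_NAMES:
        report_lines.append("  " + format_summary(name, pooled[name]))
    report = "\n".join(report_lines) + "\n"
    (out / "report.txt").write_text(report)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {"results": results, "pooled": pooled, "report": report}
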