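"""End-to-end orchestration: simulate → mask → detect → profile → stats.

A study is described by one config mapping and one integer seed; running it
produces a single run directory

    run/
      stacks/       rendered OME-TIFF stacks (one per simulated nerve)
      truth/        ground-truth intersection profiles (CSV)
      masks/        conduit label masks (8-bit TIFF)
      cleaned/      autofluorescence-subtracted stacks
      spots/        per-plane spot tables (CSV)
      profiles/     lesion-aligned raw count profiles (CSV)
      normalized/   baseline-normalized profiles (CSV)
      stats/        group comparison table and figure
      manifest.json

and a :class:`RunManifest` recording the config snapshot, the seed and a
SHA-256 per output file, so that re-running with identical inputs can be
verified to reproduce identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .detect import ResliceGeometry, detect_profile, spots_to_table, count_profile
from .errors import AxonQuantError, ConfigError
from .io import RunConfig, read_stack, write_profile_csv, write_stack
from .masking import (
    classify_conduit,
    extract_features,
    subtract_conduit,
    train_classifier,
    write_mask,
)
from .profiles import align_to_lesion, normalize_profile
from .render import ground_truth_labels, make_grid_for_scene, render_stack
from .scene import SceneParams, generate_scene, true_profile
from .stats import run_group_study


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    versions: dict = field(default_factory=dict)
    created: str = ""

    def record(self, stage: str, paths) -> None:
        entry = self.stages.setdefault(stage, {})
        for p in paths:
            p = Path(p)
            entry[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sample_seed(base: int, group_index: int, sample_index: int) -> int:
    h = hashlib.sha256(f"{base}:{group_index}:{sample_index}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_config(config: dict) -> None:
    """Schema check collecting every violation before any compute."""
    problems = []
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    groups = config.get("groups")
    if not isinstance(groups, dict) or len(groups) != 2:
        problems.append("config.groups must map exactly two group names to parameter overrides")
    n = config.get("n_per_group", 2)
    if not isinstance(n, int) or n < 2:
        problems.append(f"config.n_per_group must be an integer ≥ 2, got {n!r}")
    try:
        SceneParams(**{**config.get("scene", {}), "seed": 0})
    except (AxonQuantError, TypeError) as exc:
        problems.append(f"config.scene: {exc}")
    if isinstance(groups, dict):
        for name, overrides in groups.items():
            try:
                SceneParams(**{**config.get("scene", {}), **(overrides or {}), "seed": 0})
            except (AxonQuantError, TypeError) as exc:
                problems.append(f"config.groups.{name}: {exc}")
    try:
        RunConfig.from_dict(config.get("analysis", {})).validate()
    except AxonQuantError as exc:
        problems.append(str(exc))
    render = config.get("render", {})
    rng_um = render.get("axial_range_um")
    if rng_um is not None and not (len(rng_um) == 2 and rng_um[0] < rng_um[1]):
        problems.append(f"config.render.axial_range_um must be ordered, got {rng_um}")
    if problems:
        raise ConfigError("invalid study config:\n  - " + "\n  - ".join(problems))


def run_all(config: dict, out_dir, seed: int | None = None) -> RunManifest:
    """Execute every stage of a two-group simulated study.

    Any stage failure propagates with the stage name prefixed. Deterministic:
    identical (config, seed) reproduce identical stage output hashes.
    """
    validate_config(config)
    out = Path(out_dir)
    seed = int(config.get("seed", 0) if seed is None else seed)
    analysis = RunConfig.from_dict(config.get("analysis", {}))
    render_cfg = config.get("render", {})
    spacing = tuple(render_cfg.get("spacing_um", (2.45, 1.24, 1.24)))
    axial_range = render_cfg.get("axial_range_um")
    if axial_range is not None:
        axial_range = tuple(float(v) for v in axial_range)

    for sub in ("stacks", "truth", "masks", "cleaned", "spots", "profiles", "normalized", "stats"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config,
        seed=seed,
        versions={"axonquant": __version__, "numpy": np.__version__},
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise AxonQuantError(f"stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    samples = []  # (group, sample_id, scene, grid)
    with stage("simulate"):
        window = analysis.window_um
        for gi, (group, overrides) in enumerate(sorted(config["groups"].items())):
            for si in range(config.get("n_per_group", 2)):
                params = SceneParams(
                    **{
                        **config.get("scene", {}),
                        **(overrides or {}),
                        "seed": _sample_seed(seed, gi, si),
                    }
                )
                scene = generate_scene(params)
                grid = make_grid_for_scene(scene, axial_range, spacing)
                stack = render_stack(scene, axial_range, spacing)
                sid = f"{group}_{si:02d}"
                write_stack(stack, out / "stacks" / f"{sid}.ome.tif")
                truth = true_profile(scene, np.arange(window[0], window[1] + 1))
                write_profile_csv(
                    truth.positions_um, truth.true_counts, out / "truth" / f"{sid}.csv", "count"
                )
                samples.append((group, sid, scene, grid))
        manifest.record("simulate", list((out / "stacks").iterdir()) + list((out / "truth").iterdir()))

    with stage("mask"):
        cp = analysis.classifier
        model = None
        for group, sid, scene, grid in samples:
            stack = read_stack(out / "stacks" / f"{sid}.ome.tif")
            feats = extract_features(stack, cp.scales_um)
            if model is None:  # train on the first sample's ground-truth geometry
                labels = ground_truth_labels(scene, grid)
                model = train_classifier(
                    feats, labels, seed=seed, scales_um=cp.scales_um,
                    samples_per_class=cp.samples_per_class, n_estimators=cp.n_estimators,
                )
            mask = classify_conduit(stack, model, cp.closing_radius_um, features=feats)
            write_mask(mask, out / "masks" / f"{sid}.tif")
            cleaned = subtract_conduit(stack, mask)
            write_stack(cleaned, out / "cleaned" / f"{sid}.ome.tif")
        manifest.record("mask", list((out / "masks").iterdir()) + list((out / "cleaned").iterdir()))

    with stage("detect"):
        window = analysis.window_um
        for group, sid, scene, grid in samples:
            cleaned = read_stack(out / "cleaned" / f"{sid}.ome.tif")
            p0, p1 = grid.axis_annotation()
            geom = ResliceGeometry.from_points(
                p0, p1, analysis.detector.plane_halfwidth_um, analysis.detector.plane_step_um
            )
            lesion_x = grid.lesion_stack_x_um(scene)
            axis_len = (grid.shape[2] - 1) * grid.spacing_um[2]
            lo = max(window[0], int(np.ceil(-lesion_x)))
            hi = min(window[1], int(np.floor(axis_len - lesion_x)))
            stack_positions = np.arange(lo, hi + 1, dtype=float) + lesion_x
            spotsets = detect_profile(cleaned, geom, stack_positions, analysis.detector)
            spots_to_table(spotsets).to_csv(out / "spots" / f"{sid}.csv", index=False)
            raw_pos, counts = count_profile(spotsets)
            profile = align_to_lesion(raw_pos, counts, lesion_x, window)
            write_profile_csv(
                profile.positions_um, profile.counts, out / "profiles" / f"{sid}.csv", "count"
            )
        manifest.record("detect", list((out / "spots").iterdir()) + list((out / "profiles").iterdir()))

    with stage("profile"):
        from .profiles import IntersectionProfile

        for group, sid, scene, grid in samples:
            from .io import read_profile_csv

            pos, counts, _ = read_profile_csv(out / "profiles" / f"{sid}.csv")
            norm = normalize_profile(IntersectionProfile(pos, counts), analysis.baseline_um)
            write_profile_csv(norm.positions_um, norm.values, out / "normalized" / f"{sid}.csv")
        manifest.record("profile", list((out / "normalized").iterdir()))

    with stage("stats"):
        groups = sorted(config["groups"])
        # split profile CSVs by group into per-group views
        per_group = {g: out / "profiles" for g in groups}
        comparison, exclusions = _grouped_study(out / "profiles", groups, analysis)
        comparison.table.to_csv(out / "stats" / "comparison.csv", index=False)
        comparison.anova.to_csv(out / "stats" / "anova.csv", index=False)
        if exclusions:
            (out / "stats" / "exclusions.txt").write_text(
                "\n".join(f"{g}\t{n}\t{why}" for g, n, why in exclusions)
            )
        manifest.record("stats", [out / "stats" / "comparison.csv", out / "stats" / "anova.csv"])

    manifest.save(out / "manifest.json")
    return manifest


def _grouped_study(profiles_dir: Path, groups, analysis: RunConfig):
    """Group the per-sample profile CSVs by file-name prefix and compare."""
    import shutil
    import tempfile

    from .errors import ParameterError

    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        dirs = {}
        for g in groups:
            d = tmp / g
            d.mkdir()
            for f in sorted(profiles_dir.glob(f"{g}_*.csv")):
                shutil.copy(f, d / f.name)
            dirs[g] = d
        return run_group_study(
            dirs,
            analysis.segments_um,
            baseline_um=analysis.baseline_um,
            alpha=analysis.alpha,
        )
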