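"""Pipeline driver: segment -> align -> merge -> frame -> footprints -> stats.

Runs the full workflow over a (synthetic or user-supplied) cohort: each
specimen is "scanned" repeatedly, every scan is segmented and meshed, repeat
reconstructions are rigidly aligned onto the first-scan reference and their
deviation quantified, the aligned surfaces are merged into one coherent
model per bone, the femoral anatomical frame is built, paint marks are
traced into footprints, and cohort variation tables are rendered.

A failure in one specimen or one attachment is collected in the run
manifest and does not abort the remaining work.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage

from . import __version__
from .anatomy import bone_metrics, build_isb_frame, measure_femur
from .errors import FootprintMorphError, ParameterError
from .footprints import assign_footprints
from .io import write_csv, write_json
from .segmentation import LabelMask, extract_surface, split_paint, threshold_segment
from .stats import render_tables
from .surfaces import deviation_analysis, merge_and_clean, rigid_align
from .synthetic import make_cohort, make_repeat_scans, voxelize_scene

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every implicitly fixed constant of the workflow as a named knob."""

    hu_min: float = 250.0
    hu_max: float = 3000.0
    paint_hu_min: float = 2000.0
    trace_epsilon: float = 0.5
    trace_max_angle_deg: float = 45.0
    smoothing_iters: int = 10
    smoothing_lambda: float = 0.5
    deviation_samples: int = 10000
    spacing: float = 1.0
    noise_sd: float = 20.0
    n_scans: int = 2
    n_specimens: int = 4
    area_cv: float = 0.33
    position_jitter_mm: float = 3.0
    size_cv: float = 0.05
    seed: int = 0
    side_convention: str = "right"
    out_dir: str = "footprintmorph_run"
    write_meshes: bool = False

    def __post_init__(self):
        for name in ("hu_min", "hu_max", "paint_hu_min"):
            value = getattr(self, name)
            if not -1024 <= value <= 4000:
                raise ParameterError(f"{name}={value} outside the physical HU range [-1024, 4000]")
        if self.trace_epsilon <= 0:
            raise ParameterError("trace_epsilon must be positive")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_hashes: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    errors: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def _split_bone_components(mesh: trimesh.Trimesh, scene) -> dict[str, trimesh.Trimesh]:
    """Assign connected surface components to scene bones by proximity."""
    parts = mesh.split(only_watertight=False)
    centers = {b.name: b.bounds.mean(axis=0) for b in scene.bones}
    out: dict[str, list] = {}
    for part in parts:
        c = part.bounds.mean(axis=0)
        name = min(centers, key=lambda k: np.linalg.norm(centers[k] - c))
        out.setdefault(name, []).append(part)
    return {
        name: (max(ps, key=lambda m: m.area)) for name, ps in out.items()
    }


def _paint_meshes(paint_mask: LabelMask, scene) -> dict[str, trimesh.Trimesh]:
    """Mesh each connected paint component and assign it to its patch."""
    labels, n = ndimage.label(paint_mask.values)
    if n == 0:
        return {}
    pieces: dict[str, list] = {}
    for lab in range(1, n + 1):
        sub = LabelMask(labels == lab, paint_mask.spacing, paint_mask.origin, label="paint")
        part = extract_surface(sub, keep="all")
        c = part.bounds.mean(axis=0)
        patch = min(
            scene.patches, key=lambda p: np.linalg.norm(p.truth_centroid - c)
        )
        pieces.setdefault(patch.name, []).append(part)
    return {
        name: (trimesh.util.concatenate(ps) if len(ps) > 1 else ps[0])
        for name, ps in pieces.items()
    }


def _process_specimen(scene, config: PipelineConfig, seed: int, manifest: RunManifest):
    """Segment, align, merge and trace one specimen.  Returns per-specimen
    record dictionaries (deviations, bone metrics, femoral metrics,
    attachment metrics)."""
    scans = make_repeat_scans(
        scene, n_scans=config.n_scans, seed=seed, ground_truth=None
    )
    bone_meshes_per_scan = []
    paint_per_scan = []
    patch_scan = {}  # attachment -> scan index that provides its paint
    for k, (scan_scene, _) in enumerate(scans):
        volume = voxelize_scene(
            scan_scene, spacing=config.spacing, noise_sd=config.noise_sd, seed=seed + 1000 + k
        )
        primary = threshold_segment(volume, config.hu_min, config.hu_max)
        bone_mask, paint_mask = split_paint(volume, primary, config.paint_hu_min)
        surface = extract_surface(bone_mask, keep="all")
        bone_meshes_per_scan.append(_split_bone_components(surface, scan_scene))
        paint_per_scan.append(_paint_meshes(paint_mask, scan_scene))
    # each attachment's paint is taken from the scan it was "marked" in
    # (round-robin over scans, emulating step-wise dissection)
    for i, patch in enumerate(scene.patches):
        patch_scan[patch.name] = i % len(scans)

    reference = bone_meshes_per_scan[0]
    ref_landmarks = scans[0][0].landmarks
    deviations = []
    aligned_paint: dict[str, trimesh.Trimesh] = {}
    transforms_per_scan = [dict() for _ in scans]
    for k in range(1, len(scans)):
        scan_scene = scans[k][0]
        for bone_name, moving in bone_meshes_per_scan[k].items():
            if bone_name not in reference:
                continue
            lm_names = [
                n for n in scan_scene.landmarks
                if n.startswith(f"{bone_name}:") and n in ref_landmarks
            ]
            init = None
            if len(lm_names) >= 3:
                init = (
                    np.array([scan_scene.landmarks[n] for n in lm_names]),
                    np.array([ref_landmarks[n] for n in lm_names]),
                )
            transform = rigid_align(moving, reference[bone_name], init_landmarks=init, seed=seed + k)
            transforms_per_scan[k][bone_name] = transform
            aligned = transform.apply_mesh(moving)
            dev = deviation_analysis(
                aligned, reference[bone_name], n_samples=config.deviation_samples, seed=seed + 7 * k
            )
            deviations.append(
                {
                    "specimen": scene.specimen,
                    "bone": bone_name,
                    "scan": f"scan_{k + 1}",
                    "mean_mm": dev.mean,
                    "std_mm": dev.std,
                }
            )
    # paint marks follow the transformation matrices of their bones
    for patch in scene.patches:
        k = patch_scan[patch.name]
        paint = paint_per_scan[k].get(patch.name)
        if paint is None:
            manifest.warnings.append(
                f"{scene.specimen}: no paint component recovered for {patch.name!r}"
            )
            continue
        if k > 0 and patch.host_bone in transforms_per_scan[k]:
            paint = transforms_per_scan[k][patch.host_bone].apply_mesh(paint)
        aligned_paint[patch.name] = paint

    # coherent model per bone: the cleaned and smoothed reference
    # reconstruction; the aligned repeat reconstructions contribute the
    # deviation quantification and carry their scan's paint marks into the
    # reference frame (closed repeat shells overlap the reference rather
    # than extending it, so stitching them would double the surface)
    coherent = {
        name: merge_and_clean(
            [mesh],
            smoothing_iters=config.smoothing_iters,
            smoothing_lambda=config.smoothing_lambda,
        )
        for name, mesh in reference.items()
    }

    # anatomical frame from the reference-scan femur landmarks
    frame = None
    femoral_row = None
    if "femur" in coherent:
        try:
            side = scene.side
            frame = build_isb_frame(
                ref_landmarks["femur:head_center"],
                ref_landmarks["femur:epicondyle_medial"],
                ref_landmarks["femur:epicondyle_lateral"],
                side=side,
            )
            morph = measure_femur(
                coherent["femur"],
                {
                    "head_center": ref_landmarks["femur:head_center"],
                    "epicondyle_medial": ref_landmarks["femur:epicondyle_medial"],
                    "epicondyle_lateral": ref_landmarks["femur:epicondyle_lateral"],
                },
                frame=frame,
            )
            femoral_row = {
                "specimen": scene.specimen,
                "MA": morph.MA,
                "TEA": morph.TEA,
                "FHD": morph.FHD,
                "SD": morph.SD,
            }
        except (FootprintMorphError, KeyError) as exc:
            manifest.errors.append(f"{scene.specimen}: femoral morphometrics failed: {exc}")

    bone_rows = []
    for name, mesh in coherent.items():
        try:
            metrics = bone_metrics(mesh, frame=frame)
            bone_rows.append(
                {
                    "specimen": scene.specimen,
                    "bone": name,
                    "volume_mm3": metrics.volume,
                    "sa_mm2": metrics.surface_area,
                    "cogx": metrics.center_of_gravity[0],
                    "cogy": metrics.center_of_gravity[1],
                    "cogz": metrics.center_of_gravity[2],
                }
            )
        except FootprintMorphError as exc:
            manifest.errors.append(f"{scene.specimen}: metrics for bone {name!r} failed: {exc}")

    attachment_rows = []
    paints_by_bone: dict[str, dict] = {}
    roles = {}
    for patch in scene.patches:
        if patch.name in aligned_paint:
            paints_by_bone.setdefault(patch.host_bone, {})[patch.name] = aligned_paint[patch.name]
            roles[patch.name] = "insertion" if patch.name.endswith("_I") else "origin"
    for bone_name, paints in paints_by_bone.items():
        if bone_name not in coherent:
            continue
        try:
            footprints = assign_footprints(
                coherent[bone_name],
                paints,
                epsilon=config.trace_epsilon,
                max_normal_angle_deg=config.trace_max_angle_deg,
                roles=roles,
            )
        except FootprintMorphError as exc:
            manifest.errors.append(f"{scene.specimen}: tracing on {bone_name!r} failed: {exc}")
            continue
        for name, fp in footprints.items():
            try:
                centroid = fp.centroid
                bp = fp.breakthrough_point
                if frame is not None:
                    centroid = frame.to_frame(centroid)
                    bp = frame.to_frame(bp)
                if fp.breakthrough_fallback:
                    manifest.warnings.append(
                        f"{scene.specimen}: breakthrough fallback for {name!r}"
                    )
                attachment_rows.append(
                    {
                        "attachment": name,
                        "role": fp.attachment_role,
                        "bone": bone_name,
                        "specimen": scene.specimen,
                        "area_mm2": fp.area,
                        "cx": centroid[0],
                        "cy": centroid[1],
                        "cz": centroid[2],
                        "bx": bp[0],
                        "by": bp[1],
                        "bz": bp[2],
                        "fallback": fp.breakthrough_fallback,
                    }
                )
            except FootprintMorphError as exc:
                manifest.errors.append(
                    f"{scene.specimen}: footprint metrics for {name!r} failed: {exc}"
                )
    return deviations, bone_rows, femoral_row, attachment_rows, coherent


def run_pipeline(
    config: PipelineConfig,
    scenes=None,
    base_scene_params: dict | None = None,
) -> RunManifest:
    """Execute the full workflow and write all reports under ``out_dir``.

    ``scenes`` may be a pre-built list of synthetic specimens; otherwise a
    cohort is generated from ``base_scene_params`` (default knee scene) with
    the configured variation and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    manifest.input_hashes["config"] = _config_hash(config)
    t0 = time.perf_counter()

    if scenes is None:
        scenes, truth = make_cohort(
            n_specimens=config.n_specimens,
            base_scene_params=base_scene_params,
            variation_params={
                "area_cv": config.area_cv,
                "position_jitter_mm": config.position_jitter_mm,
                "size_cv": config.size_cv,
            },
            seed=config.seed,
        )
        (out / "ground_truth.json").write_text(truth.to_json())
    manifest.timings["cohort_generation_s"] = round(time.perf_counter() - t0, 3)

    all_dev, all_bone, all_fem, all_att = [], [], [], []
    for i, scene in enumerate(scenes):
        t = time.perf_counter()
        try:
            dev, bones, fem, att, coherent = _process_specimen(
                scene, config, seed=config.seed + 17 * (i + 1), manifest=manifest
            )
            all_dev.extend(dev)
            all_bone.extend(bones)
            if fem is not None:
                all_fem.append(fem)
            all_att.extend(att)
            if config.write_meshes:
                from .io import write_mesh

                for name, mesh in coherent.items():
                    write_mesh(mesh, out / "meshes" / f"{scene.specimen}_{name}.stl")
        except Exception as exc:  # noqa: BLE001 - isolate specimen failures
            manifest.errors.append(f"{scene.specimen}: specimen failed: {exc}")
        manifest.timings[f"{scene.specimen}_s"] = round(time.perf_counter() - t, 3)

    deviations = pd.DataFrame(all_dev, columns=["specimen", "bone", "scan", "mean_mm", "std_mm"])
    bone_morph = pd.DataFrame(
        all_bone, columns=["specimen", "bone", "volume_mm3", "sa_mm2", "cogx", "cogy", "cogz"]
    )
    femoral = pd.DataFrame(all_fem, columns=["specimen", "MA", "TEA", "FHD", "SD"])
    attachments = pd.DataFrame(
        all_att,
        columns=[
            "attachment", "role", "bone", "specimen",
            "area_mm2", "cx", "cy", "cz", "bx", "by", "bz", "fallback",
        ],
    )
    write_csv(deviations, out / "deviations.csv")
    write_csv(bone_morph, out / "bone_morphology.csv")
    write_csv(femoral, out / "femoral_morphometrics.csv")
    write_csv(attachments, out / "attachments.csv")

    tables = render_tables(
        deviations=deviations if not deviations.empty else None,
        bone_morphology=bone_morph if not bone_morph.empty else None,
        femoral=femoral if not femoral.empty else None,
        attachments=attachments if not attachments.empty else None,
    )
    for name, df in tables.items():
        write_csv(df, out / f"summary_{name}.csv")

    breakthroughs = {
        f"{row.specimen}:{row.attachment}": [row.bx, row.by, row.bz]
        for row in attachments.itertuples()
    }
    write_json(breakthroughs, out / "breakthrough_points.json")

    manifest.timings["total_s"] = round(time.perf_counter() - t0, 3)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
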