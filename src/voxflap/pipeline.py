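"""End-to-end reference pipeline and its configuration.

Wires the stages together: HU-window segmentation (with the vessel window
derived from an aortic-style reference sample), scripted brush repairs,
voxel compositing (muscle base minus vessels minus umbilicus), containment
classification of vessels, the measured grid overlay anchored on the
umbilicus, support struts, isosurface extraction, and export of per-part
binary STLs plus the JSON print manifest and the perforator grid-coordinate
report. A single config dict (YAML on disk) holds every tunable; its hash is
embedded in the manifest for provenance.
"""

from __future__ import annotations

import copy
import csv
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml
from scipy import ndimage

from . import __version__ as _version
from .errors import ConfigurationError, EmptySurfaceError
from .grid_overlay import PlaneArraySpec, apply_grid_overlay, map_perforators_to_grid
from .meshing import (
    PrintManifest,
    StrutSpec,
    check_watertight,
    extract_isosurface,
    generate_strut,
    make_part,
    split_by_material,
    write_manifest,
    write_stl,
)
from .phantom import PhantomTruth
from .volumes import (
    BrushStroke,
    LabelMask,
    ScalarVolume,
    SegmentationParams,
    apply_brush,
    sample_reference_range,
    threshold_segment,
)
from .voxel_engine import (
    GridSpec,
    Layer,
    LayerStack,
    MultiChannelGrid,
    classify_by_containment,
    composite,
    from_mask,
    measure_volume,
)

logger = logging.getLogger("voxflap")

#: Default pipeline configuration. Segmentation windows are the standard
#: muscle (180-230 HU) and reference-sampled vessel windows; the working
#: voxel size (1 mm) matches the phantom's source resolution so exported
#: meshes inherit the image voxel resolution; the grid is 1 cm spaced with a
#: 1 mm falloff at full strength, anchored on the umbilicus.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "voxel_size_mm": 1.0,
    "padding_mm": 2.0,
    "input": {"type": "phantom"},
    "segmentation": {
        "muscle": {
            "hu_lo": 180.0,
            "hu_hi": 230.0,
            "smoothing_sigma_mm": 0.0,
            "min_component_voxels": 0,
        },
        "vessels": {
            "reference_roi": {
                "center_mm": [64.0, 30.0, 35.0],
                "radius_mm": 2.0,
                "half_width_hu": 100.0,
            },
            "smoothing_sigma_mm": 0.0,
            "min_component_voxels": 0,
        },
        "umbilicus": {
            "hu_lo": 50.0,
            "hu_hi": 90.0,
            "smoothing_sigma_mm": 0.0,
            "min_component_voxels": 0,
        },
    },
    "brushes": [],
    # Vessel lumina carve holes out of the HU-segmented muscle (the lumen HU
    # sits in the vessel window, not the muscle window), so the containment
    # test runs against a reconstructed solid muscle: enclosed holes are
    # filled slice-wise along the slab-normal axis (the direction perforators
    # travel); an optional morphological closing can be added on top.
    "classification": {"fill_axis": 2, "closing_radius_mm": 0.0},
    "grid": {
        "spacing_mm": 10.0,
        "falloff_mm": 1.0,
        "strength": 1.0,
        "anchor": "auto:umbilicus",
        "normals": [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
    },
    "struts": [
        {"from": [64.0, 20.0, 20.0], "to": [64.0, 20.0, 36.0], "radius_mm": 1.5},
        {"from": [64.0, 80.0, 20.0], "to": [64.0, 80.0, 36.0], "radius_mm": 1.5},
    ],
    "export": {
        "iso_level": 0.5,
        "material_threshold": 0.5,
        "smooth_sigma_vox": 0.0,
        "finish": "glossy",
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str) -> dict:
    """Load a YAML config, overlaying it on the defaults, then validate."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(default_config(), user)
    validate_config(cfg)
    return cfg


def _deep_merge(base: dict, over: dict) -> dict:
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_merge(base[k], v)
        else:
            base[k] = v
    return base


def validate_config(cfg: dict) -> None:
    """Validate a pipeline config; errors name the offending field."""

    def _req(cond: bool, fieldname: str, msg: str) -> None:
        if not cond:
            raise ConfigurationError(f"{fieldname}: {msg}")

    _req(float(cfg.get("voxel_size_mm", 0)) > 0, "voxel_size_mm", "must be > 0")
    _req(float(cfg.get("padding_mm", -1)) >= 0, "padding_mm", "must be >= 0")
    seg = cfg.get("segmentation", {})
    for name, sc in seg.items():
        prefix = f"segmentation.{name}"
        if "reference_roi" in sc:
            roi = sc["reference_roi"]
            _req(len(roi.get("center_mm", [])) == 3, f"{prefix}.reference_roi.center_mm",
                 "must be a 3-vector (mm)")
            _req(float(roi.get("radius_mm", 0)) > 0, f"{prefix}.reference_roi.radius_mm",
                 "must be > 0")
            _req(float(roi.get("half_width_hu", 0)) > 0, f"{prefix}.reference_roi.half_width_hu",
                 "must be > 0")
        else:
            _req("hu_lo" in sc and "hu_hi" in sc, prefix,
                 "needs hu_lo/hu_hi or a reference_roi")
            _req(float(sc["hu_lo"]) < float(sc["hu_hi"]), f"{prefix}.hu_lo",
                 f"hu_lo ({sc['hu_lo']}) must be < hu_hi ({sc['hu_hi']})")
        _req(float(sc.get("smoothing_sigma_mm", 0)) >= 0,
             f"{prefix}.smoothing_sigma_mm", "must be >= 0")
        _req(int(sc.get("min_component_voxels", 0)) >= 0,
             f"{prefix}.min_component_voxels", "must be >= 0")
    for i, br in enumerate(cfg.get("brushes", [])):
        _req(br.get("mode") in ("fill", "erase"), f"brushes[{i}].mode", "must be fill|erase")
        _req(br.get("structure") in seg, f"brushes[{i}].structure",
             "must name a segmented structure")
        _req(float(br.get("radius_mm", 0)) > 0, f"brushes[{i}].radius_mm", "must be > 0")
        _req(len(br.get("centers_mm", [])) >= 1, f"brushes[{i}].centers_mm",
             "needs at least one point")
    _req(float(cfg.get("classification", {}).get("closing_radius_mm", 0)) >= 0,
         "classification.closing_radius_mm", "must be >= 0")
    fill_axis = cfg.get("classification", {}).get("fill_axis", None)
    _req(fill_axis is None or fill_axis in (0, 1, 2),
         "classification.fill_axis", "must be 0, 1, 2 or null")
    g = cfg.get("grid", {})
    _req(float(g.get("falloff_mm", 0)) > 0, "grid.falloff_mm", "must be > 0")
    _req(float(g.get("spacing_mm", 0)) > 2 * float(g.get("falloff_mm", 0)),
         "grid.spacing_mm", "must exceed twice grid.falloff_mm")
    _req(0 < float(g.get("strength", 0)) <= 1, "grid.strength", "must be in (0, 1]")
    anchor = g.get("anchor")
    _req(anchor == "auto:umbilicus" or (isinstance(anchor, (list, tuple)) and len(anchor) == 3),
         "grid.anchor", "must be 'auto:umbilicus' or a 3-vector (mm)")
    for i, st in enumerate(cfg.get("struts", [])):
        _req(len(st.get("from", [])) == 3 and len(st.get("to", [])) == 3,
             f"struts[{i}]", "needs 'from' and 'to' 3-vectors (mm)")
        _req(float(st.get("radius_mm", 1.5)) > 0, f"struts[{i}].radius_mm", "must be > 0")
    exp = cfg.get("export", {})
    _req(0 < float(exp.get("iso_level", 0.5)) < 1, "export.iso_level", "must be in (0, 1)")
    _req(0 < float(exp.get("material_threshold", 0.5)) < 1,
         "export.material_threshold", "must be in (0, 1)")
    _req(float(exp.get("smooth_sigma_vox", 0)) >= 0, "export.smooth_sigma_vox", "must be >= 0")


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _ball_structure(radius_mm: float, spacing) -> np.ndarray:
    r = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.ogrid[tuple(slice(-n, n + 1) for n in r)]
    d2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return d2 <= radius_mm**2


def fill_lumina(mask: np.ndarray, axis: int = 2) -> np.ndarray:
    """Fill holes enclosed within each 2-D slice perpendicular to ``axis``.

    Reconstructs a solid muscle from a segmentation whose vessel lumina were
    excluded by the HU window: a perforator tunnel shows up as an enclosed
    disk in every slice it crosses and is filled exactly, while vessel
    segments outside the muscle touch the slice background and stay open.
    """
    out = np.moveaxis(mask.copy(), axis, 0)
    for i in range(out.shape[0]):
        out[i] = ndimage.binary_fill_holes(out[i])
    return np.moveaxis(out, 0, axis)


@dataclass
class PipelineResult:
    """Everything the reference pipeline produces in one run."""

    manifest: PrintManifest
    perforator_cells: list
    masks: dict[str, LabelMask]
    grids: dict[str, MultiChannelGrid]
    outputs: dict[str, str] = dc_field(default_factory=dict)
    log: list = dc_field(default_factory=list)


def segment_structures(
    volume: ScalarVolume, cfg: dict
) -> tuple[dict[str, LabelMask], dict[str, dict]]:
    """Segment every configured structure; returns masks and per-structure
    details (window used, reference-sample mean where applicable)."""
    masks: dict[str, LabelMask] = {}
    details: dict[str, dict] = {}
    for name, sc in cfg["segmentation"].items():
        info: dict = {}
        if "reference_roi" in sc:
            roi = sc["reference_roi"]
            mean, params = sample_reference_range(
                volume, roi["center_mm"], float(roi["radius_mm"]),
                half_width=float(roi["half_width_hu"]),
            )
            params = SegmentationParams(
                hu_lo=params.hu_lo,
                hu_hi=params.hu_hi,
                smoothing_sigma=float(sc.get("smoothing_sigma_mm", 0.0)),
                min_component_voxels=int(sc.get("min_component_voxels", 0)),
            )
            info["reference_mean_hu"] = mean
        else:
            params = SegmentationParams(
                hu_lo=float(sc["hu_lo"]),
                hu_hi=float(sc["hu_hi"]),
                smoothing_sigma=float(sc.get("smoothing_sigma_mm", 0.0)),
                min_component_voxels=int(sc.get("min_component_voxels", 0)),
            )
        info["window_hu"] = [params.hu_lo, params.hu_hi]
        masks[name] = threshold_segment(volume, params, name=name)
        details[name] = info
    for br in cfg.get("brushes", []):
        stroke = BrushStroke(
            mode=br["mode"],
            centers=tuple(tuple(map(float, c)) for c in br["centers_mm"]),
            radius=float(br["radius_mm"]),
        )
        masks[br["structure"]] = apply_brush(masks[br["structure"]], stroke)
    return masks, details


def run_reference_pipeline(
    volume: ScalarVolume,
    truth: PhantomTruth | None = None,
    config: dict | None = None,
    output_dir: str | None = None,
) -> PipelineResult:
    """Run segment -> composite -> classify -> grid -> struts -> mesh -> export.

    ``truth`` (when available, e.g. from the phantom) supplies the perforator
    exit points for the grid-coordinate report; otherwise points may be
    listed in ``config['perforator_points_mm']``.
    """
    cfg = config or default_config()
    validate_config(cfg)
    log: list[dict] = []

    def _stage(name: str, **info) -> None:
        entry = {"stage": name, **info}
        log.append(entry)
        logger.info("stage %s: %s", name, json.dumps(info, default=str))

    # --- segmentation -----------------------------------------------------
    masks, seg_info = segment_structures(volume, cfg)
    _stage("segment", structures={n: m.count() for n, m in masks.items()}, params=seg_info)

    # --- voxelization -----------------------------------------------------
    spec = GridSpec.from_volume(
        volume, voxel_size=float(cfg["voxel_size_mm"]), padding=float(cfg["padding_mm"])
    )
    muscle_g = from_mask(masks["muscle"], spec)
    vessel_g = from_mask(masks["vessels"], spec)
    umb_g = from_mask(masks["umbilicus"], spec)
    _stage(
        "voxelize",
        voxel_size_mm=spec.voxel_size,
        dims=spec.dims,
        volumes_mm3={
            "muscle": measure_volume(muscle_g),
            "vessels": measure_volume(vessel_g),
            "umbilicus": measure_volume(umb_g),
        },
    )

    # --- containment classification --------------------------------------
    ccfg = cfg["classification"]
    closing_r = float(ccfg.get("closing_radius_mm", 0.0))
    fill_axis = ccfg.get("fill_axis", 2)
    muscle_solid = masks["muscle"].data.astype(bool)
    if fill_axis is not None:
        muscle_solid = fill_lumina(muscle_solid, axis=int(fill_axis))
    if closing_r > 0:
        struct = _ball_structure(closing_r, masks["muscle"].spacing)
        muscle_solid = ndimage.binary_closing(muscle_solid, structure=struct)
    solid_mask = LabelMask(
        data=muscle_solid,
        spacing=masks["muscle"].spacing,
        origin=masks["muscle"].origin,
        name="muscle_solid",
    )
    intra, extra = classify_by_containment(vessel_g, from_mask(solid_mask, spec))
    _stage("classify", intra_voxels=intra.count(), extra_voxels=extra.count(),
           fill_axis=fill_axis, closing_radius_mm=closing_r)

    # --- compositing: muscle base - vessels - umbilicus -------------------
    stack = LayerStack(
        layers=[
            Layer(source=muscle_g, op="replace"),
            Layer(source=vessel_g, op="subtract"),
            Layer(source=umb_g, op="subtract"),
        ],
        materials=("grid",),
    )
    comp = composite(stack, spec)
    _stage("composite", remaining_muscle_mm3=measure_volume(comp))

    # --- measured grid overlay --------------------------------------------
    gcfg = cfg["grid"]
    if gcfg["anchor"] == "auto:umbilicus":
        anchor = tuple(masks["umbilicus"].centroid())
    else:
        anchor = tuple(float(v) for v in gcfg["anchor"])
    plane_spec = PlaneArraySpec(
        spacing=float(gcfg["spacing_mm"]),
        falloff=float(gcfg["falloff_mm"]),
        strength=float(gcfg["strength"]),
        anchor=anchor,
        normals=tuple(tuple(map(float, n)) for n in gcfg["normals"]),
    )
    shape_hash_before = comp.shape_hash()
    comp = apply_grid_overlay(comp, plane_spec, material="grid")
    assert comp.shape_hash() == shape_hash_before  # morphology invariance
    _stage("grid_overlay", anchor_mm=list(anchor),
           grid_material_mm3=measure_volume(comp, "material:grid"))

    # --- struts ------------------------------------------------------------
    struts_g = MultiChannelGrid(spec)
    for st in cfg.get("struts", []):
        sgrid = generate_strut(
            StrutSpec(endpoints=(tuple(st["from"]), tuple(st["to"])),
                      radius=float(st.get("radius_mm", 1.5))),
            spec,
        )
        struts_g.shape = np.maximum(struts_g.shape, sgrid.shape)
    _stage("struts", count=len(cfg.get("struts", [])),
           struts_mm3=measure_volume(struts_g))

    # --- meshing -----------------------------------------------------------
    exp = cfg["export"]
    smooth = float(exp["smooth_sigma_vox"])
    level = float(exp["iso_level"])
    grid_mesh, muscle_mesh = split_by_material(
        comp, "grid", threshold=float(exp["material_threshold"]), smooth_sigma=smooth
    )
    meshes = {"grid_bands": grid_mesh, "muscle_remainder": muscle_mesh}
    for name, mask in (("vessels_intra", intra), ("vessels_extra", extra)):
        grid_of = from_mask(mask, spec)
        try:
            meshes[name] = extract_isosurface(grid_of, "shape", level=level, smooth_sigma=smooth)
        except EmptySurfaceError:
            logger.warning("part %s is empty; skipping", name)
    try:
        meshes["umbilicus"] = extract_isosurface(umb_g, "shape", level=level, smooth_sigma=smooth)
    except EmptySurfaceError:
        logger.warning("umbilicus segmentation empty; part skipped")
    if struts_g.shape.any():
        meshes["struts"] = extract_isosurface(struts_g, "shape", level=level, smooth_sigma=smooth)
    mesh_stats = {}
    for name, mesh in meshes.items():
        rep = check_watertight(mesh)
        mesh_stats[name] = {
            "faces": int(len(mesh.faces)),
            "volume_mm3": rep.signed_volume,
            "watertight": rep.passed,
        }
    _stage("mesh", parts=mesh_stats)

    # --- report + export ---------------------------------------------------
    if truth is not None and len(truth.exit_points):
        points = np.asarray(truth.exit_points)
    else:
        points = np.asarray(cfg.get("perforator_points_mm", []), float).reshape(-1, 3)
    cells = map_perforators_to_grid(points, plane_spec)
    _stage("perforators", cells=[{"cell": c.cell, "offsets_cm": c.offsets_cm} for c in cells])

    order = ["muscle_remainder", "grid_bands", "vessels_intra", "vessels_extra",
             "umbilicus", "struts"]
    style_over = {"finish": exp.get("finish", "glossy")}
    parts = [make_part(n, meshes[n], style_over) for n in order if n in meshes]
    manifest = PrintManifest(
        parts=parts,
        provenance={
            "tool": "voxflap",
            "version": _version,
            "config_sha256": config_hash(cfg),
            "seed": int(cfg.get("seed", 0)),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "grid_anchor_mm": list(anchor),
        },
    )

    outputs: dict[str, str] = {}
    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        for p in manifest.parts:
            path = os.path.join(output_dir, p.stl_name)
            write_stl(p.mesh, path)
            outputs[p.name] = path
        mpath = os.path.join(output_dir, "manifest.json")
        write_manifest(manifest, mpath)
        outputs["manifest"] = mpath
        rpath = os.path.join(output_dir, "perforators.csv")
        with open(rpath, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["point_id", "x_mm", "y_mm", "z_mm", "cell_u", "cell_v",
                        "offset_u_cm", "offset_v_cm"])
            for i, c in enumerate(cells):
                w.writerow([i, *[f"{v:.3f}" for v in c.point], *c.cell, *c.offsets_cm])
        outputs["perforators"] = rpath
        lpath = os.path.join(output_dir, "log.json")
        with open(lpath, "w") as fh:
            json.dump(log, fh, indent=2, default=str)
        outputs["log"] = lpath

    return PipelineResult(
        manifest=manifest,
        perforator_cells=cells,
        masks={**masks, "vessels_intra": intra, "vessels_extra": extra},
        grids={"composited": comp, "muscle": muscle_g, "vessels": vessel_g,
               "umbilicus": umb_g, "struts": struts_g},
        outputs=outputs,
        log=log,
    )
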