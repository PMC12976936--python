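"""File I/O: STL surfaces, tagged quad-mesh JSON, YAML configuration.

STL (binary or ASCII) goes through trimesh on the triangulated shell.  The
quad shell itself, with its region tags, boundary loops and structured-ring
layout, is stored in a small self-describing JSON schema (no installed
library writes tagged quad meshes).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .anatomy import AnatomyConfig, Centerline, TubeStructure, VesselModel

MESH_SCHEMA = "tevgsim-quadmesh-1"


def write_stl(model: VesselModel, path, ascii: bool = False) -> None:
    """Write the triangulated shell surface as STL."""
    mesh = model.to_trimesh()
    path = Path(path)
    if ascii:
        data = mesh.export(file_type="stl_ascii")
        path.write_bytes(data.encode() if isinstance(data, str) else data)
    else:
        mesh.export(str(path), file_type="stl")


def write_mesh_json(model: VesselModel, path) -> None:
    """Tagged quad shell mesh with loops, structure and centerline."""
    doc = {
        "schema": MESH_SCHEMA,
        "nodes": model.nodes.tolist(),
        "quads": model.quads.tolist(),
        "region_tags": list(map(str, model.region_tags)),
        "boundary_loops": {k: v.tolist() for k, v in model.boundary_loops.items()},
        "thickness": model.thickness,
        "flags": list(model.flags),
        "structure": {
            k: {"rings": v.rings.tolist(), "arclength": v.arclength.tolist(),
                "parent": v.parent, "attach_arclength": v.attach_arclength}
            for k, v in model.structure.items()},
    }
    if model.centerline is not None:
        doc["centerline"] = {"points": model.centerline.points.tolist(),
                             "radii": model.centerline.radii.tolist(),
                             "arclength": model.centerline.arclength.tolist()}
    Path(path).write_text(json.dumps(doc))


def read_mesh_json(path) -> VesselModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema") != MESH_SCHEMA:
        raise ValueError(f"not a {MESH_SCHEMA} file")
    centerline = None
    if "centerline" in doc:
        c = doc["centerline"]
        centerline = Centerline(np.asarray(c["points"]), np.asarray(c["radii"]),
                                np.asarray(c["arclength"]))
    structure = {
        k: TubeStructure(np.asarray(v["rings"], dtype=int),
                         np.asarray(v["arclength"]),
                         v.get("parent"), v.get("attach_arclength"))
        for k, v in doc.get("structure", {}).items()}
    return VesselModel(
        nodes=np.asarray(doc["nodes"], dtype=float),
        quads=np.asarray(doc["quads"], dtype=int),
        region_tags=np.asarray(doc["region_tags"]),
        boundary_loops={k: np.asarray(v, dtype=int)
                        for k, v in doc["boundary_loops"].items()},
        thickness=doc.get("thickness", 1.5),
        centerline=centerline,
        structure=structure,
        flags=doc.get("flags", []),
    )


def load_anatomy_config(path) -> AnatomyConfig:
    """AnatomyConfig from a YAML mapping (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(AnatomyConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown anatomy config keys: {sorted(unknown)}")
    return AnatomyConfig(**data)


def load_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def dump_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
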