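"""File formats: meshes, template pairing, cohort metadata, run outputs.

Correspondence is positional — the i-th vertex of every mesh is the i-th
template vertex — so meshes are always read and written with vertex order
preserved (``trimesh`` with ``process=False``).  The template's bilateral
pairing is a two-column CSV of 0-based vertex indices and the midline a
one-column CSV; cohort metadata is a CSV with header ``id,age,group,path``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .core import Cohort, TemplateTopology, as_configuration, centroid_size

__all__ = [
    "load_mesh",
    "save_mesh",
    "load_template",
    "save_template",
    "read_cohort",
    "write_outputs",
    "write_curve_csv",
    "read_curve_csv",
    "write_vertex_map_csv",
]


def load_mesh(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PLY/OBJ mesh; returns ``(vertices, faces)`` in file order."""
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64)


def save_mesh(path, vertices, faces, vertex_scalars: dict | None = None) -> None:
    """Write a mesh; optional per-vertex scalar fields become PLY properties."""
    path = Path(path)
    mesh = trimesh.Trimesh(
        vertices=as_configuration(vertices),
        faces=np.asarray(faces, dtype=np.int64),
        process=False,
    )
    if vertex_scalars:
        for name, values in vertex_scalars.items():
            mesh.vertex_attributes[name] = np.asarray(values, dtype=np.float32)
    mesh.export(str(path))


def load_template(mesh_path, pairs_csv, midline_csv, reflection_axis: str = "x"):
    """Load a template mesh plus its symmetry pairing and midline lists.

    Returns ``(TemplateTopology, base_configuration)``.
    """
    vertices, faces = load_mesh(mesh_path)
    pairs = pd.read_csv(pairs_csv, header=None).to_numpy(dtype=np.int64)
    midline = pd.read_csv(midline_csv, header=None).to_numpy(dtype=np.int64).ravel()
    topo = TemplateTopology(
        n_vertices=vertices.shape[0],
        faces=faces,
        symmetry_pairs=pairs,
        midline_vertices=midline,
        reflection_axis=reflection_axis,
    )
    return topo, vertices


def save_template(out_dir, topo: TemplateTopology, base) -> dict:
    """Write template mesh + pairing/midline CSVs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mesh": out / "template.ply",
        "pairs": out / "symmetry_pairs.csv",
        "midline": out / "midline.csv",
    }
    save_mesh(paths["mesh"], base, topo.faces)
    pd.DataFrame(topo.symmetry_pairs).to_csv(paths["pairs"], header=False, index=False)
    pd.DataFrame(topo.midline_vertices).to_csv(paths["midline"], header=False, index=False)
    return {k: str(v) for k, v in paths.items()}


def read_cohort(meta_csv, topo: TemplateTopology, base_dir=None) -> Cohort:
    """Load a cohort from a metadata CSV (``id,age,group,path``) plus meshes.

    Physical sizes are recorded from the raw meshes before any scaling.
    Malformed rows (wrong vertex count, unparseable or non-positive age,
    duplicate id, more than two groups) raise errors naming the offender.
    """
    meta = pd.read_csv(meta_csv, dtype={"id": str, "group": str})
    required = ["id", "age", "group", "path"]
    if list(meta.columns[:4]) != required:
        raise ValueError(f"metadata header must start with {','.join(required)}")
    if meta["id"].duplicated().any():
        dup = meta.loc[meta["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate case id {dup!r} in {meta_csv}")
    ages = pd.to_numeric(meta["age"], errors="coerce")
    if ages.isna().any() or (ages <= 0).any():
        row = meta.loc[ages.isna() | (ages <= 0)].iloc[0]
        raise ValueError(f"unparseable or non-positive age for case {row['id']!r}")
    if meta["group"].nunique() != 2:
        raise ValueError(
            f"cohort must contain exactly two groups, found {sorted(meta['group'].unique())}"
        )
    base = Path(base_dir) if base_dir is not None else Path(meta_csv).parent
    coords, sizes = [], []
    for _, row in meta.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        verts, _ = load_mesh(p)
        if verts.shape[0] != topo.n_vertices:
            raise ValueError(
                f"mesh {p} has {verts.shape[0]} vertices, template has {topo.n_vertices}"
            )
        coords.append(verts)
        sizes.append(centroid_size(verts))
    return Cohort(
        coords=np.stack(coords),
        ages=ages.to_numpy(dtype=float),
        groups=meta["group"].to_numpy(),
        sizes=np.array(sizes),
        ids=meta["id"].tolist(),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(results: dict, out_dir) -> dict:
    """Write named artifacts and a manifest with checksums.

    ``results`` maps artifact names to DataFrames (→ CSV), dicts (→ JSON) or
    arrays (→ CSV).  The layout and byte content are deterministic for fixed
    inputs, so re-running with the same seed reproduces identical checksums.
    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.12g")
        elif isinstance(obj, dict):
            path = out / f"{name}.json"
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))
        elif isinstance(obj, np.ndarray):
            path = out / f"{name}.csv"
            pd.DataFrame(obj).to_csv(path, index=False, float_format="%.12g")
        else:
            raise TypeError(f"cannot serialize artifact {name!r} of type {type(obj)}")
        entries.append({"name": name, "path": path.name, "sha256": _sha256(path)})
    manifest = {"artifacts": entries}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_curve_csv(path, ages, values, ci_low=None, ci_high=None, p_values=None) -> None:
    """Write an age-indexed curve (optionally with CI bounds and p-values)."""
    data = {"age": np.asarray(ages, dtype=float), "value": np.asarray(values, dtype=float)}
    if ci_low is not None:
        data["ci_low"] = np.asarray(ci_low, dtype=float)
    if ci_high is not None:
        data["ci_high"] = np.asarray(ci_high, dtype=float)
    if p_values is not None:
        data["p_value"] = np.asarray(p_values, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def read_curve_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_vertex_map_csv(path, maps: dict) -> None:
    """Write named per-vertex scalar fields as columns of one CSV."""
    pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in maps.items()}).to_csv(
        path, index=False, float_format="%.12g"
    )
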