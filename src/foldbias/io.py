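"""File I/O: GIFTI surfaces/metrics/labels, NIfTI volumes, text fixtures.

Synthetic sheet metadata (periodic domain, grid layout) rides along in
the GIFTI meta dictionary so participants survive a round trip to disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import gifti

from .mesh import ScalarMap, TriangleMesh, as_values
from .synth import Parcellation, VoxelGrid

_META_PERIOD = "foldbias_periodic_domain"
_META_GRID = "foldbias_grid_shape"


def save_surface(mesh: TriangleMesh, path) -> None:
    """Write a mesh as a GIFTI .surf.gii (pointset + triangle arrays)."""
    meta = {}
    if mesh.periodic_domain is not None:
        meta[_META_PERIOD] = json.dumps(list(mesh.periodic_domain))
    if mesh.grid_shape is not None:
        meta[_META_GRID] = json.dumps(list(mesh.grid_shape))
    coords = gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32),
        intent="NIFTI_INTENT_POINTSET",
        meta=gifti.GiftiMetaData(**meta) if meta else None,
    )
    tris = gifti.GiftiDataArray(
        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    gifti.GiftiImage(darrays=[coords, tris]).to_filename(str(path))


def load_surface(path) -> TriangleMesh:
    img = nib.load(str(path))
    coords = None
    faces = None
    periodic = None
    grid = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
            meta = dict(da.meta or {})
            if _META_PERIOD in meta:
                periodic = np.asarray(json.loads(meta[_META_PERIOD]), dtype=float)
            if _META_GRID in meta:
                grid = tuple(json.loads(meta[_META_GRID]))
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if coords is None or faces is None:
        raise ValueError(f"{path} lacks pointset/triangle arrays")
    return TriangleMesh(coords, faces, periodic_domain=periodic, grid_shape=grid)


def save_scalar(scalar_map, path, name: str | None = None) -> None:
    """Write a per-vertex scalar map as GIFTI .shape.gii / .func.gii."""
    v = as_values(scalar_map)
    if name is None:
        name = scalar_map.name if isinstance(scalar_map, ScalarMap) else ""
    da = gifti.GiftiDataArray(
        v.astype(np.float32),
        intent="NIFTI_INTENT_SHAPE",
        meta=gifti.GiftiMetaData(Name=name) if name else None,
    )
    gifti.GiftiImage(darrays=[da]).to_filename(str(path))


def load_scalar(path) -> ScalarMap:
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"{path} holds no data arrays")
    da = img.darrays[0]
    name = dict(da.meta or {}).get("Name", "")
    return ScalarMap(np.asarray(da.data, dtype=float), name=name)


def load_series(path) -> np.ndarray:
    """Read a metric file with one darray per timepoint as (n, T)."""
    img = nib.load(str(path))
    cols = [np.asarray(da.data, dtype=float).ravel() for da in img.darrays]
    return np.column_stack(cols)


def save_series(values: np.ndarray, path) -> None:
    """Write an (n, T) series as a .func.gii with one darray per timepoint."""
    values = np.asarray(values, dtype=float)
    darrays = [
        gifti.GiftiDataArray(values[:, t].astype(np.float32),
                             intent="NIFTI_INTENT_TIME_SERIES")
        for t in range(values.shape[1])
    ]
    gifti.GiftiImage(darrays=darrays).to_filename(str(path))


def save_labels(parcellation: Parcellation, path) -> None:
    """Write a parcellation as a GIFTI .label.gii."""
    table = gifti.GiftiLabelTable()
    rng = np.random.default_rng(0)
    for k in range(parcellation.n_parcels):
        r, g, b = rng.uniform(0, 1, 3)
        lab = gifti.GiftiLabel(key=k, red=r, green=g, blue=b, alpha=1.0)
        lab.label = f"parcel_{k}"
        table.labels.append(lab)
    da = gifti.GiftiDataArray(
        parcellation.labels.astype(np.int32), intent="NIFTI_INTENT_LABEL"
    )
    img = gifti.GiftiImage(darrays=[da], labeltable=table)
    img.to_filename(str(path))


def load_labels(path) -> Parcellation:
    img = nib.load(str(path))
    labels = np.asarray(img.darrays[0].data, dtype=np.int64)
    return Parcellation(labels=labels, n_parcels=int(labels.max()) + 1)


def save_volume(grid: VoxelGrid, path) -> None:
    """Write a voxel grid (3D or 4D values) as NIfTI."""
    if grid.values is None:
        raise ValueError("grid carries no values")
    nib.Nifti1Image(grid.values.astype(np.float32), grid.affine).to_filename(str(path))


def load_volume(path) -> VoxelGrid:
    img = nib.load(str(path))
    vals = np.asarray(img.dataobj, dtype=float)
    return VoxelGrid(shape=vals.shape[:3], affine=np.asarray(img.affine), values=vals)


def save_cohort_manifest(cohort, params, path) -> None:
    """JSON manifest describing a cohort: ids, seeds, fold parameters."""
    import dataclasses

    manifest = {
        "master_seed": cohort.master_seed,
        "params": dataclasses.asdict(params),
        "participants": [{"id": p.id, "seed": p.seed} for p in cohort],
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_cohort_manifest(path):
    """Rebuild a cohort from its manifest (regenerates meshes from seeds)."""
    import dataclasses

    from .synth import Cohort, FoldParameters, make_folded_sheet

    manifest = json.loads(Path(path).read_text())
    params = FoldParameters(**manifest["params"])
    participants = [
        make_folded_sheet(dataclasses.replace(params, seed=entry["seed"]))
        for entry in manifest["participants"]
    ]
    return Cohort(participants=participants, master_seed=manifest["master_seed"])


def save_scalar_text(scalar_map, path, delimiter: str = "\t") -> None:
    """Plain two-column (vertex index, value) text dialect for fixtures."""
    v = as_values(scalar_map)
    with open(path, "w") as fh:
        fh.write(f"vertex{delimiter}value\n")
        for i, val in enumerate(v):
            fh.write(f"{i}{delimiter}{val:.17g}\n")


def load_scalar_text(path, delimiter: str = "\t") -> ScalarMap:
    idx = []
    vals = []
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("vertex"):
            raise ValueError("missing 'vertex<delim>value' header")
        for line in fh:
            if not line.strip():
                continue
            i, v = line.split(delimiter)
            idx.append(int(i))
            vals.append(float(v))
    out = np.empty(len(vals))
    out[np.asarray(idx)] = vals
    return ScalarMap(out, name=Path(path).stem)


def save_kernel_text(kernel, path, delimiter: str = "\t") -> None:
    """Sparse triplet text cache (row, col, weight) for smoothing kernels."""
    coo = kernel.weights.tocoo()
    with open(path, "w") as fh:
        fh.write(f"# fwhm={kernel.fwhm} truncation={kernel.truncation_fraction} "
                 f"radius={kernel.radius} n={kernel.n_vertices}\n")
        fh.write(f"row{delimiter}col{delimiter}weight\n")
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r}{delimiter}{c}{delimiter}{v:.17g}\n")
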