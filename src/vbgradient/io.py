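"""Readers/writers (NIfTI-1, GIFTI, TSV, JSON sidecars) and run configuration.

Every binary output gets a plain-text mirror so results are diffable
without neuroimaging tooling: vertex maps as (vertex_id, value) TSV,
histograms as (bin_left, bin_right, count) TSV, and a JSON sidecar that
records enough (config, seed, versions, NaN count) to reconstruct a run.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import InputError, SpatialMismatchError
from .searchlight import SurfaceMesh, VertexResultMap, VolumeData

logger = logging.getLogger("vbgradient")


@dataclass
class RunConfig:
    """Everything needed to reproduce one mapping run."""

    data_path: str
    surface_path: str
    out_path: str
    volume_mask_path: str | None = None
    cortex_mask_path: str | None = None
    metric: str = "vb"
    normalization: str = "unnorm"
    min_neighbors: int = 3
    jobs: int = 1
    seed: int | None = None
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        for name in ("data_path", "surface_path", "volume_mask_path",
                     "cortex_mask_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InputError(f"{name.replace('_', ' ')} does not exist: {p}")
        out_dir = Path(self.out_path).resolve().parent
        if not out_dir.is_dir():
            raise InputError(f"output directory does not exist: {out_dir}")


# --- volumes -----------------------------------------------------------------

def load_volume(data_path, mask_path=None) -> VolumeData:
    """4-D NIfTI plus an optional 3-D binary mask (all-true when omitted)."""
    try:
        img = nib.load(str(data_path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InputError(f"cannot read NIfTI volume {data_path}: {exc}") from exc
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise InputError(
            f"{data_path}: expected a 4-D time-series volume, got shape {data.shape}"
        )
    if mask_path is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        try:
            mimg = nib.load(str(mask_path))
        except Exception as exc:
            raise InputError(f"cannot read mask {mask_path}: {exc}") from exc
        mask = np.asanyarray(mimg.dataobj) > 0
        if mask.shape != data.shape[:3]:
            raise SpatialMismatchError(
                f"mask {mask_path} shape {mask.shape} does not match "
                f"volume grid {data.shape[:3]}"
            )
    return VolumeData(values=data, affine=img.affine, mask=mask)


def save_volume(vol: VolumeData, data_path, mask_path=None) -> None:
    nib.save(nib.Nifti1Image(vol.values.astype(np.float64), vol.affine),
             str(data_path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.mask.astype(np.uint8), vol.affine),
                 str(mask_path))


# --- surfaces ----------------------------------------------------------------

def load_surface(surf_path, cortex_mask_path=None) -> SurfaceMesh:
    """GIFTI surface (.surf.gii) plus an optional per-vertex cortical mask."""
    try:
        gii = nib.load(str(surf_path))
    except Exception as exc:
        raise InputError(f"cannot read GIFTI surface {surf_path}: {exc}") from exc
    coords = tris = None
    for da in gii.darrays:
        intent = nib.nifti1.intent_codes.label.get(da.intent, da.intent)
        if intent == "pointset":
            coords = np.asarray(da.data, dtype=float)
        elif intent == "triangle":
            tris = np.asarray(da.data, dtype=int)
    if coords is None or tris is None:
        raise InputError(f"{surf_path}: GIFTI lacks pointset/triangle arrays")
    if cortex_mask_path is None:
        mask = np.ones(coords.shape[0], dtype=bool)
    else:
        try:
            mgii = nib.load(str(cortex_mask_path))
        except Exception as exc:
            raise InputError(f"cannot read cortex mask {cortex_mask_path}: {exc}") from exc
        mask = np.asarray(mgii.darrays[0].data).ravel() > 0
        if mask.shape[0] != coords.shape[0]:
            raise SpatialMismatchError(
                f"cortex mask has {mask.shape[0]} vertices, surface has "
                f"{coords.shape[0]}"
            )
    return SurfaceMesh(coordinates=coords, triangles=tris, vertex_mask=mask)


def save_surface(mesh: SurfaceMesh, surf_path, cortex_mask_path=None) -> None:
    gii = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.coordinates.astype(np.float32),
                                 intent="pointset"),
        nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                 intent="triangle"),
    ])
    nib.save(gii, str(surf_path))
    if cortex_mask_path is not None:
        mgii = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertex_mask.astype(np.int32),
                                     intent="shape"),
        ])
        nib.save(mgii, str(cortex_mask_path))


# --- vertex maps -------------------------------------------------------------

def save_vertex_map(vmap: VertexResultMap, func_path) -> None:
    """Per-vertex scalars as GIFTI .func.gii, NaN kept for unevaluable vertices.

    GIFTI functional arrays are float32 by standard; the TSV mirror written
    alongside preserves the values at full double precision.
    """
    da = nib.gifti.GiftiDataArray(vmap.values.astype(np.float32),
                                  intent="none", datatype="NIFTI_TYPE_FLOAT32")
    nib.save(nib.gifti.GiftiImage(darrays=[da]), str(func_path))


def load_vertex_map(func_path, metric="vb", normalization="n/a") -> VertexResultMap:
    gii = nib.load(str(func_path))
    return VertexResultMap(values=np.asarray(gii.darrays[0].data, dtype=float),
                           metric=metric, normalization=normalization)


def save_vertex_map_tsv(vmap: VertexResultMap, tsv_path) -> None:
    pd.DataFrame({"vertex_id": np.arange(vmap.values.size),
                  "value": vmap.values}).to_csv(tsv_path, sep="\t", index=False,
                                                float_format="%.17g")


def load_vertex_map_tsv(tsv_path, metric="vb", normalization="n/a") -> VertexResultMap:
    df = pd.read_csv(tsv_path, sep="\t", float_precision="round_trip")
    return VertexResultMap(values=df["value"].to_numpy(dtype=float),
                           metric=metric, normalization=normalization)


def save_histogram_tsv(values: np.ndarray, tsv_path, bins: int = 64) -> None:
    """Counts over equal-width bins of the finite values (for map histograms)."""
    finite = np.asarray(values)[np.isfinite(values)]
    if finite.size == 0:
        edges = np.array([0.0, 1.0])
        counts = np.array([0])
    else:
        counts, edges = np.histogram(finite, bins=bins)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                  "count": counts}).to_csv(tsv_path, sep="\t", index=False)


def save_sidecar(config: RunConfig, vmap: VertexResultMap, sidecar_path) -> None:
    payload = {
        "config": asdict(config),
        "metric": vmap.metric,
        "normalization": vmap.normalization,
        "n_vertices": int(vmap.values.size),
        "n_evaluated": vmap.n_evaluated,
        "n_nan": vmap.n_nan,
        "versions": _versions(),
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=2))


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"vbgradient": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "nibabel": nib.__version__,
            "python": sys.version.split()[0]}


# --- assembled entry points ---------------------------------------------------

def load_inputs(config: RunConfig) -> tuple[VolumeData, SurfaceMesh]:
    """Load and cross-validate the volume and surface named by ``config``."""
    config.validate_paths()
    vol = load_volume(config.data_path, config.volume_mask_path)
    mesh = load_surface(config.surface_path, config.cortex_mask_path)
    logger.info("loaded volume %s grid=%s k=%d; surface %s V=%d (%d unmasked)",
                config.data_path, vol.grid_shape, vol.k, config.surface_path,
                mesh.n_vertices, int(mesh.vertex_mask.sum()))
    return vol, mesh


def write_outputs(vmap: VertexResultMap, config: RunConfig) -> dict:
    """func.gii + TSV mirror + histogram TSV + JSON sidecar; returns the paths."""
    out = Path(config.out_path)
    stem = out.name
    for suffix in (".func.gii", ".gii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    base = out.parent / stem
    paths = {
        "func_gii": str(out),
        "tsv": f"{base}.tsv",
        "histogram": f"{base}.hist.tsv",
        "sidecar": f"{base}.json",
    }
    save_vertex_map(vmap, paths["func_gii"])
    save_vertex_map_tsv(vmap, paths["tsv"])
    save_histogram_tsv(vmap.values, paths["histogram"])
    save_sidecar(config, vmap, paths["sidecar"])
    logger.info("wrote map %s (%d evaluated, %d NaN)", out, vmap.n_evaluated,
                vmap.n_nan)
    return paths
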