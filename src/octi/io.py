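"""Configuration, mesh/field export, and run manifests.

Meshes are written as legacy-VTK ASCII unstructured grids (a plain-text
format readable by ParaView and friends) with an integer ``tissue_label``
cell array and optional per-node potential / field arrays.  Tables go to
CSV with fixed column order and full precision.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import (ElectrodeSpec, EyeModelParams, LabeledMesh, MeshSpec,
                       NAME_OF)

PROFILE_COLUMNS = ["direction", "abscissa_deg", "mmea_norm"]
STATS_COLUMNS = ["theta2", "alphaX", "alphaY", "direction", "fwhm_deg",
                 "width80_deg", "peak_value", "peak_offset_deg",
                 "contour_closed", "nerve_overlap"]


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_PARAM_KEYS = set(EyeModelParams.__dataclass_fields__)
_MESH_KEYS = set(MeshSpec.__dataclass_fields__) | {"preset"}


def load_config(path) -> dict:
    """Read a YAML config with ``model:``, ``mesh:``, ``experiment:`` blocks.

    Units follow the type definitions throughout: mm for lengths, degrees
    for angles, micrometers only for the electrode disc dimensions.
    """
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    for block, allowed in (("model", _PARAM_KEYS), ("mesh", _MESH_KEYS)):
        for key in cfg.get(block, {}) or {}:
            if key not in allowed:
                raise ValueError(
                    f"unknown key {block}.{key!r} in config {path}")
    return cfg


def params_from_config(cfg: dict) -> EyeModelParams:
    return EyeModelParams(**(cfg.get("model") or {}))


def mesh_spec_from_config(cfg: dict) -> MeshSpec:
    block = dict(cfg.get("mesh") or {})
    preset = block.pop("preset", None)
    if preset:
        base = MeshSpec.preset(preset)
        if block:
            from dataclasses import replace
            base = replace(base, **{k: v for k, v in block.items()})
        return base
    return MeshSpec(**block) if block else MeshSpec()


# ---------------------------------------------------------------------------
# Legacy VTK
# ---------------------------------------------------------------------------

def write_vtk(mesh: LabeledMesh, path,
              point_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the labeled tet mesh as legacy-VTK ASCII (text deliverable)."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("octi labeled eye mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_cells} {mesh.n_cells * 5}\n")
        cells = np.column_stack(
            [np.full(mesh.n_cells, 4, dtype=np.int64), mesh.tets])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_cells}\n")
        np.savetxt(f, np.full(mesh.n_cells, 10, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_cells}\n")
        f.write("SCALARS tissue_label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.labels, fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")


def read_vtk(path):
    """Read back a mesh written by :func:`write_vtk`.

    Returns (nodes, tets, labels); used for round-trip checks and external
    post-processing.
    """
    with open(path) as f:
        lines = f.read().split("\n")
    i = 0

    def seek(prefix):
        nonlocal i
        while i < len(lines) and not lines[i].startswith(prefix):
            i += 1
        return lines[i]

    n_pts = int(seek("POINTS").split()[1])
    nodes = np.loadtxt(lines[i + 1:i + 1 + n_pts])
    i += n_pts
    n_cells = int(seek("CELLS").split()[1])
    cells = np.loadtxt(lines[i + 1:i + 1 + n_cells], dtype=np.int64)
    tets = cells[:, 1:5]
    i += n_cells
    seek("SCALARS tissue_label")
    i += 2
    labels = np.loadtxt(lines[i:i + n_cells], dtype=np.int32)
    return nodes, tets, labels


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def profiles_frame(profiles: Dict[str, "ProfileCurve"]) -> pd.DataFrame:
    rows = []
    for d, c in profiles.items():
        for t, v in zip(c.abscissa, c.values):
            rows.append((d, float(t), float(v)))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def stats_rows(theta2: float, case, directions=("horizontal", "vertical",
                                                "diagonal")) -> List[dict]:
    r = case.ratios
    out = []
    for d in directions:
        st = case.stats
        out.append({
            "theta2": theta2,
            "alphaX": r.alphaX if r else 0.5,
            "alphaY": r.alphaY if r else 0.5,
            "direction": d,
            "fwhm_deg": st.fwhm[d].width if d in st.fwhm else np.nan,
            "width80_deg": st.width80[d].width if d in st.width80 else np.nan,
            "peak_value": st.central_peak_value.get(d, np.nan),
            "peak_offset_deg": st.central_peak_offset.get(d, np.nan),
            "contour_closed": st.contour_closed,
            "nerve_overlap": st.nerve_overlap,
        })
    return out


def stats_frame(rows: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(list(rows), columns=STATS_COLUMNS)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record: config snapshot, mesh hash, timings, outputs."""

    config: dict
    version: str = __version__
    mesh_hash: str = ""
    stages: Dict[str, float] = field(default_factory=dict)
    outputs: Dict[str, str] = field(default_factory=dict)

    def add_output(self, path) -> None:
        p = Path(path)
        self.outputs[p.name] = _checksum(p)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                manifest.stages[name] = time.perf_counter() - self.t0

        return _Timer()

    def write(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, default=str)
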