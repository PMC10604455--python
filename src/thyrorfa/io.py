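"""Writers for simulation artifacts: CSV traces, VTU field snapshots,
structured summaries.

The VTU writer emits plain ASCII XML unstructured-grid files (cell type 10,
linear tetrahedra) readable by ParaView/VTK and meshio; region labels and
solution fields are stored as cell data, nodal fields as point data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh, REGIONS
from .treatment import SimulationResult

__all__ = ["write_vtu", "write_traces", "write_summary", "load_summary"]


def _data_array(name: str, data: np.ndarray, indent: str = "        ") -> str:
    data = np.asarray(data)
    if data.dtype.kind in "iu":
        typ, fmt = "Int64", "%d"
    else:
        typ, fmt = "Float64", "%.10g"
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    body = "\n".join(indent + " ".join(fmt % v for v in np.atleast_1d(row))
                     for row in data)
    return (f'{indent[:-2]}<DataArray type="{typ}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{body}\n{indent[:-2]}</DataArray>")


def write_vtu(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> Path:
    """Write the mesh (+fields) as an ASCII .vtu file."""
    path = Path(path)
    n_pts, n_cells = len(mesh.nodes), len(mesh.tets)
    cell_data = {"region": mesh.region, **(cell_data or {})}
    parts = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "  <UnstructuredGrid>",
        f'    <Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        "      <Points>",
        _data_array("Points", mesh.nodes),
        "      </Points>",
        "      <Cells>",
        _data_array("connectivity", mesh.tets.reshape(-1)),
        _data_array("offsets", 4 * np.arange(1, n_cells + 1)),
        _data_array("types", np.full(n_cells, 10, dtype=np.int64)),
        "      </Cells>",
    ]
    if point_data:
        parts.append("      <PointData>")
        parts += [_data_array(k, v) for k, v in point_data.items()]
        parts.append("      </PointData>")
    parts.append("      <CellData>")
    parts += [_data_array(k, v) for k, v in cell_data.items()]
    parts.append("      </CellData>")
    parts += ["    </Piece>", "  </UnstructuredGrid>", "</VTKFile>", ""]
    path.write_text("\n".join(parts))
    return path


def write_traces(outdir, result: SimulationResult) -> dict[str, Path]:
    """Write impedance/energy/VRR/safety traces as RFC-4180 CSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, cols in (
        ("impedance", {"time_s": result.times, "impedance_ohm": result.impedance}),
        ("energy", {"time_s": result.times, "energy_J": result.energy}),
        ("vrr", {"time_s": result.times, "VRR_percent": result.vrr}),
        ("safety", {"time_s": result.times,
                    "shell_max_T_C": result.shell_max_T}),
    ):
        p = outdir / f"{name}.csv"
        pd.DataFrame(cols).to_csv(p, index=False, lineterminator="\r\n")
        written[name] = p
    return written


def write_summary(path, result: SimulationResult,
                  extra: dict | None = None) -> Path:
    """Machine-readable run summary (JSON)."""
    path = Path(path)
    shell = result.shell_max_T[np.isfinite(result.shell_max_T)]
    summary = {
        "power_W": result.params.power,
        "duration_s": result.params.duration,
        "scenario": result.scenario,
        "final_VRR_percent": float(result.vrr[-1]) if len(result.vrr) else 0.0,
        "peak_T_C": result.peak_T,
        "shell_max_T_C": float(shell.max()) if len(shell) else None,
        "impedance_initial_ohm": _first_finite(result.impedance),
        "impedance_drop_percent": result.impedance_drop_pct,
        "energy_J": float(result.energy[-1]) if len(result.energy) else 0.0,
        "transverse_width_mm": result.transverse_width * 1e3,
        **(extra or {}),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, allow_nan=True) + "\n")
    return path


def load_summary(path) -> dict:
    return json.loads(Path(path).read_text())


def _first_finite(arr) -> float | None:
    arr = np.asarray(arr)
    fin = arr[np.isfinite(arr)]
    return float(fin[0]) if len(fin) else None
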