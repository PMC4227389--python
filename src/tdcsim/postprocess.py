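"""Derived quantities and exports: E and J fields, AP sensitivity,
conduction velocity, probe traces, legacy-VTK and CSV output.

Electric field and current density are constant per P1 element and are
exported as cell data (never averaged to nodes) so that conductivity-
interface discontinuities survive into the output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .cell_model import FHNParams
from .mesh import SimplicialMesh, Tissue

__all__ = [
    "ProbeTrace",
    "electric_field",
    "current_density",
    "ap_sensitivity",
    "conduction_velocity",
    "pad_brain_field",
    "export_vtk",
    "read_vtk",
    "export_probes_csv",
]

#: Sentinel used to pad brain-only nodal fields out to the full node set.
BRAIN_PAD_SENTINEL = np.nan


@dataclass
class ProbeTrace:
    """Time series of one quantity at one (node-snapped) spatial point."""

    name: str
    location: tuple
    quantity: str          # 'v' | 'phi' | 'sensitivity'
    times: np.ndarray      # s, strictly increasing
    values: np.ndarray
    snap_distance: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must be congruent")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("probe times must be strictly increasing")


def electric_field(mesh: SimplicialMesh, phi: np.ndarray) -> np.ndarray:
    """E = -grad(Phi), exact per element for the P1 interpolant; (m, d)."""
    phi = np.asarray(phi, dtype=float)
    from .assembly import _p1_gradients

    g = _p1_gradients(mesh)                  # (m, d, d+1)
    nodal = phi[mesh.elements]               # (m, d+1)
    return -np.einsum("mdk,mk->md", g, nodal)


def current_density(E: np.ndarray, sigma_e: np.ndarray) -> np.ndarray:
    """J = M_e E per element; ``sigma_e`` is (m, d, d) (or (m,) isotropic)."""
    E = np.asarray(E, dtype=float)
    sigma_e = np.asarray(sigma_e, dtype=float)
    if sigma_e.ndim == 1:
        return sigma_e[:, None] * E
    return np.einsum("mab,mb->ma", sigma_e, E)


def ap_sensitivity(v, params: FHNParams) -> np.ndarray:
    """Depolarization from rest toward threshold, as a percentage.

        sensitivity = (v_rest - v) / (v_rest - v_th) * 100

    0% at rest, 100% at threshold; linear in v in between (and beyond).
    """
    v = np.asarray(v, dtype=float)
    denom = params.v_rest - params.v_th
    if denom == 0.0:
        raise ValueError("v_rest equals v_th (a = 0): sensitivity undefined")
    return (params.v_rest - v) / denom * 100.0


def _first_upward_crossing(trace: ProbeTrace, v_th: float) -> float:
    """Time of the first upward v_th crossing, linearly interpolated."""
    v, t = trace.values, trace.times
    below = v < v_th
    idx = np.flatnonzero(below[:-1] & (v[1:] >= v_th))
    if idx.size == 0:
        if np.all(v >= v_th):
            raise ValueError(
                f"probe {trace.name!r} never starts below threshold "
                f"({v_th:.4g} V); no upward crossing"
            )
        raise ValueError(
            f"probe {trace.name!r} never crosses threshold {v_th:.4g} V"
        )
    i = int(idx[0])
    frac = (v_th - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def conduction_velocity(
    trace_a: ProbeTrace,
    trace_b: ProbeTrace,
    params: FHNParams | float,
    distance: float | None = None,
) -> float:
    """Wavefront speed from threshold-crossing times at two probes (m/s).

    ``params`` may be an :class:`FHNParams` (its threshold is used) or a
    threshold voltage directly.  ``distance`` defaults to the Euclidean
    separation of the two (snapped) probe locations.
    """
    v_th = params.v_th if isinstance(params, FHNParams) else float(params)
    if distance is None:
        a = np.asarray(trace_a.location, dtype=float)
        b = np.asarray(trace_b.location, dtype=float)
        distance = float(np.linalg.norm(a - b))
    ta = _first_upward_crossing(trace_a, v_th)
    tb = _first_upward_crossing(trace_b, v_th)
    dt = abs(tb - ta)
    if dt == 0.0:
        raise ValueError(
            f"probes {trace_a.name!r} and {trace_b.name!r} cross threshold "
            "simultaneously; velocity undefined"
        )
    return distance / dt


def pad_brain_field(
    mesh: SimplicialMesh, values: np.ndarray, fill: float = BRAIN_PAD_SENTINEL
) -> np.ndarray:
    """Expand a brain-node field to all nodes, padding with ``fill`` (NaN)."""
    out = np.full(mesh.n_nodes, fill, dtype=float)
    out[mesh.brain_nodes()] = values
    return out


# ---------------------------------------------------------------------------
# Legacy-VTK ASCII export
# ---------------------------------------------------------------------------

_VTK_CELLTYPE = {2: 5, 3: 10}  # triangle, tetrahedron


def export_vtk(mesh: SimplicialMesh, fields: dict[str, np.ndarray], path) -> None:
    """Write mesh + fields as legacy VTK ASCII (UNSTRUCTURED_GRID).

    Field arrays of length n_nodes become point data, of length n_elements
    cell data; brain-node-length arrays are padded with NaN outside the
    brain.  2-vectors per element are written as 3-vectors (z = 0).  Tissue
    tags are always included as cell data.
    """
    n, m, d = mesh.n_nodes, mesh.n_elements, mesh.dim
    n_brain = len(mesh.brain_nodes())
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {"tissue": mesh.tissue_tag.astype(float)}
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] == n:
            point_data[name] = arr
        elif arr.shape[0] == m:
            cell_data[name] = arr
        elif arr.shape[0] == n_brain and arr.ndim == 1:
            point_data[name] = pad_brain_field(mesh, arr)
        else:
            raise ValueError(
                f"field {name!r} has length {arr.shape[0]}; expected "
                f"{n} (nodes), {m} (elements) or {n_brain} (brain nodes)"
            )

    out = ["# vtk DataFile Version 3.0", "tdcsim export", "ASCII",
           "DATASET UNSTRUCTURED_GRID"]
    out.append(f"POINTS {n} double")
    for xy in mesh.nodes:
        x, y = float(xy[0]), float(xy[1])
        z = float(xy[2]) if d == 3 else 0.0
        out.append(f"{x!r} {y!r} {z!r}")
    out.append(f"CELLS {m} {m * (d + 2)}")
    for el in mesh.elements:
        out.append(f"{d + 1} " + " ".join(str(v) for v in el))
    out.append(f"CELL_TYPES {m}")
    out.extend([str(_VTK_CELLTYPE[d])] * m)

    def emit(block: dict[str, np.ndarray], count: int) -> None:
        for name, arr in block.items():
            if arr.ndim == 1:
                out.append(f"SCALARS {name} double 1")
                out.append("LOOKUP_TABLE default")
                out.extend(f"{float(v)!r}" for v in arr)
            else:
                out.append(f"VECTORS {name} double")
                for row in arr:
                    z = float(row[2]) if len(row) == 3 else 0.0
                    out.append(f"{float(row[0])!r} {float(row[1])!r} {z!r}")

    if point_data:
        out.append(f"POINT_DATA {n}")
        emit(point_data, n)
    if cell_data:
        out.append(f"CELL_DATA {m}")
        emit(cell_data, m)
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def read_vtk(path) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read back a file written by :func:`export_vtk` (round-trip helper).

    Returns (points, cells, fields); point and cell fields share one dict.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0
    points = cells = None
    fields: dict[str, np.ndarray] = {}
    while i < len(tokens):
        line = tokens[i].split()
        if not line:
            i += 1
            continue
        key = line[0]
        if key == "POINTS":
            cnt = int(line[1])
            points = np.array(
                [[float(v) for v in tokens[i + 1 + k].split()] for k in range(cnt)]
            )
            i += cnt + 1
        elif key == "CELLS":
            cnt = int(line[1])
            cells = np.array(
                [[int(v) for v in tokens[i + 1 + k].split()[1:]] for k in range(cnt)]
            )
            i += cnt + 1
        elif key == "SCALARS":
            name = line[1]
            cnt = _current_count
            vals = np.array([float(tokens[i + 2 + k]) for k in range(cnt)])
            fields[name] = vals
            i += cnt + 2
        elif key == "VECTORS":
            name = line[1]
            cnt = _current_count
            vals = np.array(
                [[float(v) for v in tokens[i + 1 + k].split()] for k in range(cnt)]
            )
            fields[name] = vals
            i += cnt + 1
        elif key in ("POINT_DATA", "CELL_DATA"):
            _current_count = int(line[1])
            i += 1
        else:
            i += 1
    return points, cells, fields


def export_probes_csv(traces, path) -> None:
    """Write probe traces as CSV with header ``time,name,quantity,value``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time", "name", "quantity", "value"])
        for tr in traces:
            for t, v in zip(tr.times, tr.values):
                w.writerow([repr(float(t)), tr.name, tr.quantity, repr(float(v))])
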