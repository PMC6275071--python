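"""Readers and writers: PDB structures/trajectories, multi-frame XYZ,
force-field parameter tables, and steering-force records.

PDB parsing and formatting are delegated to biotite; this module converts
between biotite's ``AtomArray`` containers and the package's
:class:`~unbindkit.core.Topology` / :class:`~unbindkit.core.Trajectory`
types, and adds CONECT handling plus the validation the analysis layer
requires (consistent MODEL blocks, no duplicate atoms within a residue).

The steering-record and parameter formats are plain CSV with a versioned
header comment; see :func:`write_steering_records` for the column layout.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .core import (
    ELEMENT_MASSES, SteeringWindow, Topology, Trajectory, infer_element,
)

__all__ = [
    "read_pdb", "write_pdb", "read_xyz", "write_xyz",
    "read_parameters", "write_parameters",
    "read_steering_records", "write_steering_records",
    "ParseError",
]

STEERING_FORMAT_VERSION = "unbindkit-steering-v1"
PARAMS_FORMAT_VERSION = "unbindkit-params-v1"


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _mass_for(element: str) -> float:
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise ValueError(f"no mass known for element {element!r}") from None


def _prescan_pdb(text: str) -> None:
    """Validate ATOM/HETATM coordinate fields so errors can name the line."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6] in ("ATOM  ", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated {line[:6].strip()} record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: unparseable coordinate field "
                        f"{line[lo:hi]!r}") from None


def _parse_conect(text: str, n_atoms: int, serial_to_index: dict[int, int]) -> np.ndarray:
    bonds = set()
    for line in text.splitlines():
        if line.startswith("CONECT"):
            fields = [line[i:i + 5] for i in range(6, min(len(line), 31), 5)]
            serials = [int(f) for f in fields if f.strip()]
            if not serials:
                continue
            a = serial_to_index.get(serials[0])
            for s in serials[1:]:
                b = serial_to_index.get(s)
                if a is None or b is None or a == b:
                    continue
                bonds.add((min(a, b), max(a, b)))
    if not bonds:
        return np.empty((0, 2), dtype=int)
    return np.array(sorted(bonds), dtype=int)


def read_pdb(path) -> tuple[Topology, Trajectory]:
    """Read a (possibly multi-MODEL) PDB file.

    Returns one trajectory frame per MODEL block (a single frame if the file
    has no MODEL records).  Elements are taken from the element column when
    present, otherwise inferred from atom names.  CONECT records become the
    topology bond list.

    Raises
    ------
    ParseError
        On malformed ATOM/HETATM records (the message names the line), on
        MODEL blocks with differing atom counts, or on duplicate atoms
        within one residue.
    """
    text = Path(path).read_text()
    _prescan_pdb(text)
    pdb = PDBFile.read(_stdio.StringIO(text))
    try:
        stack = pdb.get_structure(model=None)
    except Exception as exc:  # unequal MODEL blocks etc.
        raise ParseError(f"{path}: inconsistent MODEL blocks ({exc})") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])

    arr = stack[0]
    elements = []
    for el, name in zip(arr.element, arr.atom_name):
        el = str(el).strip()
        elements.append(el.capitalize() if el else infer_element(name))
    # duplicate atom within one residue
    seen: set[tuple] = set()
    for i in range(stack.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.res_name[i], arr.atom_name[i])
        if key in seen:
            raise ParseError(
                f"duplicate atom {key[3]!r} in residue {key[2]} {key[1]} "
                f"chain {key[0]}")
        seen.add(key)

    serials = (arr.get_annotation("atom_id")
               if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, stack.array_length() + 1))
    serial_to_index = {int(s): i for i, s in enumerate(serials)}
    bonds = _parse_conect(text, stack.array_length(), serial_to_index)

    topology = Topology(
        atom_names=list(arr.atom_name),
        elements=[e.upper() if len(e) == 1 else e.capitalize() for e in elements],
        res_ids=arr.res_id,
        res_names=list(arr.res_name),
        chain_ids=list(arr.chain_id),
        masses=[_mass_for(e) for e in elements],
        bonds=bonds,
    )
    coords = np.asarray(stack.coord, dtype=float)
    return topology, Trajectory(topology, coords)


def write_pdb(path, topology: Topology, coords: np.ndarray,
              times=None) -> None:
    """Write coordinates (one frame or a stack) as a multi-MODEL PDB with
    CONECT records for the topology bonds."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = coords
    stack.chain_id = topology.chain_ids.astype("U4")
    stack.res_id = topology.res_ids
    stack.res_name = topology.res_names.astype("U5")
    stack.atom_name = topology.atom_names.astype("U6")
    stack.element = np.array([e.upper() for e in topology.elements], dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(stack[0] if n_frames == 1 else stack)
    buf = _stdio.StringIO()
    pdb.write(buf)
    lines = [l for l in buf.getvalue().splitlines() if l.strip() and l != "END"]
    for a, b in topology.bonds:
        lines.append(f"CONECT{a + 1:5d}{b + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, topology: Topology, coords: np.ndarray) -> None:
    """Write frames in plain multi-frame XYZ (element x y z, Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for el, (x, y, z) in zip(topology.elements, frame):
                fh.write(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


def read_xyz(path) -> tuple[list[str], np.ndarray]:
    """Read a multi-frame XYZ file; returns (elements, coords array)."""
    lines = Path(path).read_text().splitlines()
    frames, elements = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError(f"line {i + 1}: expected atom count") from None
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ParseError(f"line {i + 1}: truncated frame")
        els, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(f"line {i + 3 + j}: malformed XYZ row")
            els.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise ParseError(f"line {i + 1}: frame elements differ from first frame")
        frames.append(xyz)
        i += 2 + n
    if elements is None:
        raise ParseError("empty XYZ file")
    return elements, np.asarray(frames, dtype=float)


# ---------------------------------------------------------------------------
# force-field parameter tables
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["res_name", "atom_name", "charge", "lj_radius", "lj_epsilon",
                  "gb_radius", "lcpo_p1", "lcpo_p2", "lcpo_p3", "lcpo_p4"]


def write_parameters(path, table: pd.DataFrame) -> None:
    """Write a parameter table keyed by (residue name, atom name)."""
    missing = set(_PARAM_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"parameter table missing columns {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(f"# {PARAMS_FORMAT_VERSION}\n")
        table[_PARAM_COLUMNS].to_csv(fh, index=False)


def read_parameters(path, topology: Topology) -> Topology:
    """Attach force-field parameters from a CSV table to a topology.

    The table is keyed by ``(res_name, atom_name)`` and must cover every
    atom of the topology; columns are charge (e), lj_radius (Rmin/2, Å),
    lj_epsilon (kcal/mol), gb_radius (Å) and the four LCPO coefficients.

    Raises
    ------
    ValueError
        Listing every (residue, atom) key of the topology that the table
        does not provide.
    """
    table = pd.read_csv(path, comment="#")
    missing_cols = set(_PARAM_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ParseError(f"parameter table missing columns {sorted(missing_cols)}")
    lookup = {(r.res_name, r.atom_name): r for r in table.itertuples()}
    n = topology.n_atoms
    charges = np.empty(n)
    lj_r = np.empty(n)
    lj_e = np.empty(n)
    gb_r = np.empty(n)
    lcpo = np.empty((n, 4))
    missing = []
    for i in range(n):
        key = (topology.res_names[i], topology.atom_names[i])
        row = lookup.get(key)
        if row is None:
            missing.append(key)
            continue
        charges[i] = row.charge
        lj_r[i] = row.lj_radius
        lj_e[i] = row.lj_epsilon
        gb_r[i] = row.gb_radius
        lcpo[i] = (row.lcpo_p1, row.lcpo_p2, row.lcpo_p3, row.lcpo_p4)
    if missing:
        raise ValueError(
            "parameter table does not cover topology atoms: "
            + ", ".join(f"{r}/{a}" for r, a in sorted(set(missing))))
    return topology.with_parameters(
        charges=charges, lj_radius=lj_r, lj_epsilon=lj_e,
        gb_radius=gb_r, lcpo_params=lcpo)


# ---------------------------------------------------------------------------
# steering records
# ---------------------------------------------------------------------------

def write_steering_records(path, windows: list[SteeringWindow]) -> None:
    """Write steering windows as versioned CSV.

    One row per (window, segment, sample, center) with columns::

        window, displacement, n_equil_discarded, segment, sample,
        center, cx, cy, cz, fx, fy, fz

    where (cx,cy,cz) is the fixed position of the steered center for the
    window (Å) and (fx,fy,fz) the sampled force on it (kcal/mol/Å).
    """
    rows = []
    for w in windows:
        for seg_id, seg in enumerate(w.force_samples):
            for s, sample in enumerate(seg):
                for c in range(w.n_centers):
                    cx, cy, cz = w.center_positions[c]
                    fx, fy, fz = sample[c]
                    rows.append((w.lambda_index, w.displacement,
                                 w.n_equil_discarded, seg_id, s, c,
                                 cx, cy, cz, fx, fy, fz))
    frame = pd.DataFrame(rows, columns=[
        "window", "displacement", "n_equil_discarded", "segment", "sample",
        "center", "cx", "cy", "cz", "fx", "fy", "fz"])
    with open(path, "w") as fh:
        fh.write(f"# {STEERING_FORMAT_VERSION}\n")
        frame.to_csv(fh, index=False)  # default repr round-trips doubles exactly


def read_steering_records(path) -> list[SteeringWindow]:
    """Read steering windows from the CSV format of
    :func:`write_steering_records`.

    Windows are returned sorted by displacement.  Every window must carry
    exactly four segments; displacements must be strictly monotone across
    windows.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = {"window", "displacement", "segment", "sample", "center",
                "cx", "cy", "cz", "fx", "fy", "fz"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"steering records missing columns {sorted(missing)}")
    windows = []
    for widx, group in frame.groupby("window", sort=True):
        disp = float(group["displacement"].iloc[0])
        n_equil = int(group["n_equil_discarded"].iloc[0]) \
            if "n_equil_discarded" in group else 0
        centers = (group[group["segment"] == group["segment"].min()]
                   .sort_values(["sample", "center"]))
        n_centers = int(group["center"].max()) + 1
        first = centers[centers["sample"] == centers["sample"].iloc[0]]
        center_positions = first.sort_values("center")[["cx", "cy", "cz"]].to_numpy()
        seg_ids = sorted(group["segment"].unique())
        if seg_ids != [0, 1, 2, 3]:
            raise ValueError(
                f"window {widx}: expected segments 0..3, found {seg_ids}")
        segments = []
        for seg_id in seg_ids:
            seg = group[group["segment"] == seg_id].sort_values(["sample", "center"])
            n_samples = seg["sample"].nunique()
            forces = seg[["fx", "fy", "fz"]].to_numpy().reshape(n_samples, n_centers, 3)
            segments.append(forces)
        windows.append(SteeringWindow(
            lambda_index=int(widx), displacement=disp,
            center_positions=center_positions, force_samples=segments,
            n_equil_discarded=n_equil))
    windows.sort(key=lambda w: w.displacement)
    disps = [w.displacement for w in windows]
    if np.any(np.diff(disps) <= 0):
        raise ValueError("window displacements are not strictly increasing")
    return windows
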