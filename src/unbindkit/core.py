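"""Core domain types: topologies, selections, trajectories, steering records.

A :class:`Topology` is a struct-of-arrays description of the atoms of a
molecular system (names, residues, chains, masses and force-field
parameters); a :class:`Trajectory` is an ordered stack of coordinate frames
over one topology.  :class:`SteeringWindow` holds the sampled constraint
forces of one displacement window of a multi-center steered run, and
:class:`PMFProfile` the reconstructed potential of mean force along the
steering path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Topology",
    "Selection",
    "Trajectory",
    "SteeringWindow",
    "PMFProfile",
    "DecompositionTable",
    "ELEMENT_MASSES",
    "infer_element",
]

#: Masses (amu) for the elements that occur in protein/nucleic-acid systems.
ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "MN": 54.938, "SE": 78.971,
}

_TWO_LETTER = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "SE"}


def infer_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name.

    Digits are stripped; a leading two-letter symbol is recognised only for
    the common ions/halogens so that ``CA`` (an alpha carbon) maps to carbon
    while ``CL`` maps to chlorine only when unambiguous (e.g. ``CL-``).
    """
    name = atom_name.strip().upper()
    stripped = "".join(c for c in name if c.isalpha())
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    # Names like 'CL-' / 'NA+' or bare two-letter ion names.
    if stripped in _TWO_LETTER and (len(name) <= 2 or not name[2:].isalnum()):
        return stripped.capitalize()
    return stripped[0]


def _as_object_array(values: Sequence[str]) -> np.ndarray:
    out = np.empty(len(values), dtype=object)
    out[:] = list(values)
    return out


@dataclass
class Topology:
    """Static atom metadata for a molecular system.

    All per-atom fields are parallel arrays of length ``n_atoms``.  Force
    field columns (``charges`` in e, ``lj_radius`` as Rmin/2 in Å,
    ``lj_epsilon`` in kcal/mol, ``gb_radius`` intrinsic Born radius in Å,
    ``lcpo_params`` four dimensionless coefficients) default to NaN and are
    filled by :func:`unbindkit.io.read_parameters`.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    masses: np.ndarray
    charges: np.ndarray = None  # type: ignore[assignment]
    lj_radius: np.ndarray = None  # type: ignore[assignment]
    lj_epsilon: np.ndarray = None  # type: ignore[assignment]
    gb_radius: np.ndarray = None  # type: ignore[assignment]
    lcpo_params: np.ndarray = None  # type: ignore[assignment]
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        self.atom_names = _as_object_array(self.atom_names)
        self.elements = _as_object_array(self.elements)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = _as_object_array(self.res_names)
        self.chain_ids = _as_object_array(self.chain_ids)
        self.masses = np.asarray(self.masses, dtype=float)
        for name in ("charges", "lj_radius", "lj_epsilon", "gb_radius"):
            val = getattr(self, name)
            if val is None:
                val = np.full(n, np.nan)
            setattr(self, name, np.asarray(val, dtype=float))
        if self.lcpo_params is None:
            self.lcpo_params = np.full((n, 4), np.nan)
        self.lcpo_params = np.asarray(self.lcpo_params, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        self._validate()

    def _validate(self) -> None:
        n = self.n_atoms
        for name in ("elements", "res_ids", "res_names", "chain_ids",
                     "masses", "charges", "lj_radius", "lj_epsilon",
                     "gb_radius"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} has wrong length")
        if self.lcpo_params.shape != (n, 4):
            raise ValueError("lcpo_params must have shape (n_atoms, 4)")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be > 0")
        finite_lj = self.lj_radius[np.isfinite(self.lj_radius)]
        if np.any(finite_lj < 0):
            raise ValueError("lj_radius must be >= 0")
        finite_gb = self.gb_radius[np.isfinite(self.gb_radius)]
        if np.any(finite_gb <= 0):
            raise ValueError("gb_radius must be > 0 for GB atoms")
        if self.bonds.size:
            if self.bonds.min() < 0 or self.bonds.max() >= n:
                raise ValueError("bond index out of range")
            if np.any(self.bonds[:, 0] == self.bonds[:, 1]):
                raise ValueError("bond list contains a self-loop")
        # Residue ids must be unique within a chain: no two residues of the
        # same chain may share an id while differing in name.
        key = pd.DataFrame({
            "chain": self.chain_ids, "resid": self.res_ids,
            "resname": self.res_names,
        })
        per_res = key.drop_duplicates()
        dup = per_res.duplicated(subset=["chain", "resid"])
        if dup.any():
            bad = per_res[dup].iloc[0]
            raise ValueError(
                f"residue id {bad['resid']} is not unique within chain "
                f"{bad['chain']!r}")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique ``(chain, residue id, residue name)`` keys in atom order."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, i, r in zip(self.chain_ids, self.res_ids, self.res_names):
            seen.setdefault((c, int(i), r), None)
        return list(seen)

    def residue_index(self) -> np.ndarray:
        """Per-atom integer index into :attr:`residue_keys`."""
        keys = {k: i for i, k in enumerate(self.residue_keys)}
        return np.array([
            keys[(c, int(i), r)]
            for c, i, r in zip(self.chain_ids, self.res_ids, self.res_names)
        ], dtype=int)

    def bonded_hydrogens(self, index: int) -> list[int]:
        """Indices of hydrogen atoms bonded to atom ``index``."""
        out = []
        for a, b in self.bonds:
            if a == index and self.elements[b] == "H":
                out.append(int(b))
            elif b == index and self.elements[a] == "H":
                out.append(int(a))
        return sorted(out)

    def with_parameters(self, **columns: np.ndarray) -> "Topology":
        """Return a copy with the given parameter columns replaced."""
        kwargs = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        kwargs.update(columns)
        return Topology(**kwargs)

    # -- selection entry points ---------------------------------------
    def select(self, *, name: str | Iterable[str] | None = None,
               element: str | Iterable[str] | None = None,
               chain: str | Iterable[str] | None = None,
               res_id: int | Iterable[int] | None = None,
               res_name: str | Iterable[str] | None = None,
               heavy: bool = False,
               predicate: Callable[[int], bool] | None = None) -> "Selection":
        """Select atoms by attribute match; criteria are AND-combined."""
        mask = np.ones(self.n_atoms, dtype=bool)

        def _match(values: np.ndarray, crit) -> np.ndarray:
            if isinstance(crit, (str, int)):
                crit = [crit]
            crit_set = set(crit)
            return np.array([v in crit_set for v in values])

        if name is not None:
            mask &= _match(self.atom_names, name)
        if element is not None:
            mask &= _match(self.elements, element)
        if chain is not None:
            mask &= _match(self.chain_ids, chain)
        if res_id is not None:
            mask &= _match(self.res_ids, res_id)
        if res_name is not None:
            mask &= _match(self.res_names, res_name)
        if heavy:
            mask &= self.elements != "H"
        if predicate is not None:
            mask &= np.array([bool(predicate(i)) for i in range(self.n_atoms)])
        return Selection(self, np.flatnonzero(mask))

    def select_all(self) -> "Selection":
        return Selection(self, np.arange(self.n_atoms))


class Selection:
    """A sorted, unique set of atom indices bound to a topology.

    Supports set algebra: ``a | b``, ``a & b``, ``a - b``.
    """

    def __init__(self, topology: Topology, indices: Iterable[int]):
        idx = np.unique(np.asarray(list(indices), dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= topology.n_atoms):
            raise IndexError("selection index out of topology bounds")
        self.topology = topology
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Selection)
                and self.topology is other.topology
                and np.array_equal(self.indices, other.indices))

    def _check(self, other: "Selection") -> None:
        if self.topology is not other.topology:
            raise ValueError("selections belong to different topologies")

    def __or__(self, other: "Selection") -> "Selection":
        self._check(other)
        return Selection(self.topology, np.union1d(self.indices, other.indices))

    def __and__(self, other: "Selection") -> "Selection":
        self._check(other)
        return Selection(self.topology, np.intersect1d(self.indices, other.indices))

    def __sub__(self, other: "Selection") -> "Selection":
        self._check(other)
        return Selection(self.topology, np.setdiff1d(self.indices, other.indices))

    def __repr__(self) -> str:
        return f"<Selection of {len(self)}/{self.topology.n_atoms} atoms>"


@dataclass
class Trajectory:
    """Ordered coordinate frames (Å) over a topology, with times in ps."""

    topology: Topology
    coords: np.ndarray          # (n_frames, n_atoms, 3)
    times: np.ndarray = None    # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != self.n_frames:
            raise ValueError("times length must equal number of frames")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def subset(self, frame_indices: Sequence[int]) -> "Trajectory":
        idx = np.asarray(frame_indices, dtype=int)
        return Trajectory(self.topology, self.coords[idx], self.times[idx])


@dataclass
class SteeringWindow:
    """Sampled constraint forces for one displacement window.

    ``center_positions`` are the fixed positions u(λ) of the n steered
    centers for this window; ``force_samples`` holds the forces the rest of
    the system exerts on those centers, split into exactly four contiguous
    segments collected after discarding ``n_equil_discarded`` equilibration
    samples.
    """

    lambda_index: int
    displacement: float
    center_positions: np.ndarray           # (n_centers, 3)
    force_samples: list[np.ndarray]        # 4 arrays, each (n_samples_k, n_centers, 3)
    n_equil_discarded: int = 0

    def __post_init__(self) -> None:
        self.center_positions = np.asarray(self.center_positions, dtype=float).reshape(-1, 3)
        if self.displacement < 0:
            raise ValueError("displacement must be >= 0")
        if len(self.force_samples) != 4:
            raise ValueError(
                f"window {self.lambda_index}: expected 4 force segments, got "
                f"{len(self.force_samples)}")
        segs = []
        for k, seg in enumerate(self.force_samples):
            seg = np.asarray(seg, dtype=float)
            if seg.ndim != 3 or seg.shape[1:] != (self.n_centers, 3):
                raise ValueError(
                    f"window {self.lambda_index} segment {k}: expected shape "
                    f"(n, {self.n_centers}, 3)")
            if seg.shape[0] < 1:
                raise ValueError(
                    f"window {self.lambda_index} segment {k} is empty")
            segs.append(seg)
        self.force_samples = segs

    @property
    def n_centers(self) -> int:
        return self.center_positions.shape[0]

    @property
    def all_samples(self) -> np.ndarray:
        """All force samples concatenated, shape (n_total, n_centers, 3)."""
        return np.concatenate(self.force_samples, axis=0)


@dataclass
class PMFProfile:
    """Potential of mean force W on a displacement grid, anchored W(0)=0."""

    displacements: np.ndarray
    pmf: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.displacements = np.asarray(self.displacements, dtype=float)
        self.pmf = np.asarray(self.pmf, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.displacements) == len(self.pmf) == len(self.sigma)):
            raise ValueError("grid, pmf and sigma must have equal length")
        if np.any(np.diff(self.displacements) <= 0):
            raise ValueError("displacement grid must be strictly increasing")
        if abs(self.pmf[0]) > 1e-9:
            raise ValueError("pmf must be anchored at 0 at the first grid point")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "displacement": self.displacements,
            "pmf": self.pmf,
            "sigma": self.sigma,
        })


class DecompositionTable:
    """Per-residue interaction free-energy terms, averaged over snapshots.

    Rows are keyed by ``(chain, residue id, residue name)``; columns are the
    Coulomb, Lennard-Jones, GB polar and SASA nonpolar terms plus their sum,
    all in kcal/mol.
    """

    COLUMNS = ("E_ele", "E_vdw", "G_pol", "G_nonpol", "G_total")

    def __init__(self, frame: pd.DataFrame, n_snapshots: int):
        required = {"chain", "res_id", "res_name", *self.COLUMNS}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"decomposition table missing columns {sorted(missing)}")
        resid = frame["E_ele"] + frame["E_vdw"] + frame["G_pol"] + frame["G_nonpol"]
        if not np.allclose(resid, frame["G_total"], atol=1e-9):
            raise ValueError("G_total must equal the sum of the four terms")
        self.frame = frame.reset_index(drop=True)
        self.n_snapshots = int(n_snapshots)

    def totals(self) -> dict[str, float]:
        """Column sums over all rows (both sides of the interface)."""
        return {c: float(self.frame[c].sum()) for c in self.COLUMNS}

    def key_rows(self, threshold: float = 5.0) -> pd.DataFrame:
        """Rows whose total interaction magnitude is at least ``threshold``
        kcal/mol — the conventional key-residue filter."""
        return self.frame[self.frame["G_total"].abs() >= threshold].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __repr__(self) -> str:
        return (f"<DecompositionTable of {len(self.frame)} residues, "
                f"{self.n_snapshots} snapshots>")
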