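"""Implicit-solvent interaction energies and their per-residue decomposition.

The interaction free energy between two groups A and B across an interface
is split into four terms,

    ΔG = ΔE_ele + ΔE_vdw + ΔG_pol + ΔG_nonpol,

evaluated on snapshots of the complex trajectory (single-trajectory
convention: the unbound reference states reuse the complex geometry):

* ΔE_ele — Coulomb sum over all cross pairs, no cutoff;
* ΔE_vdw — 12-6 Lennard-Jones with Lorentz–Berthelot combination
  (Rmin/2 radii add, epsilons combine geometrically);
* ΔG_pol — generalized Born polar solvation with pairwise-descreening
  effective radii (OBC-II rescaling by default) and the Still interaction
  function f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / 4 R_i R_j));
* ΔG_nonpol = γ·SASA + β with the surface area from the LCPO
  pairwise-overlap approximation (γ = 0.005 kcal/(mol Å^2), β = 0).

Two per-residue assignment modes are provided.  ``mode="half"`` splits
every pair term half/half between the two residues, so the rows of the
resulting table sum exactly to the directly computed interface total of
each term.  ``mode="full"`` reports residue-to-whole-partner energies
(each cross pair at full weight on the focal residue), the quantity
conventionally quoted for key-residue rankings; its rows double-count
pairs across the two sides and omit the intra-group Born-radii relaxation
part of ΔG_pol, so no conservation identity is claimed for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DecompositionTable, Selection, Topology, Trajectory
from .units import COULOMB_CONSTANT, DEFAULT_PROBE_RADIUS

__all__ = [
    "GBModel", "NonpolarModel",
    "pairwise_coulomb_lj", "born_radii", "gb_polar_energy",
    "lcpo_sasa", "nonpolar_energy", "decompose_interface",
]

#: Element-specific descreening scale factors for the pairwise Born-radius
#: integral (AMBER GBn/OBC convention); unlisted elements use 0.8.
DEFAULT_SCREENING = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85,
                     "S": 0.96, "P": 0.86}


@dataclass
class GBModel:
    """Generalized Born model parameters.

    The default flavor is OBC-II: the pairwise-descreening integral I is
    rescaled through R_i^-1 = rho_i^-1 - tanh(αΨ - βΨ^2 + γΨ^3)/ρ_i with
    Ψ = I·rho_i, rho_i the offset-corrected intrinsic radius.
    """

    interior_dielectric: float = 1.0
    exterior_dielectric: float = 78.5
    flavor: str = "OBC2"
    offset: float = 0.09                     # Å
    alpha: float = 1.0
    beta: float = 0.8
    gamma: float = 4.85
    coulomb_constant: float = COULOMB_CONSTANT
    screening: dict = field(default_factory=lambda: dict(DEFAULT_SCREENING))

    def __post_init__(self) -> None:
        if not self.exterior_dielectric > self.interior_dielectric >= 1.0:
            raise ValueError("require exterior > interior >= 1")

    @property
    def prefactor(self) -> float:
        """-(1/2)(1/ε_in - 1/ε_out) k_c, kcal Å/(mol e^2)."""
        return -0.5 * (1.0 / self.interior_dielectric
                       - 1.0 / self.exterior_dielectric) * self.coulomb_constant


@dataclass
class NonpolarModel:
    """Surface-area nonpolar solvation: G_nonpol = γ·SASA + β."""

    gamma: float = 0.005        # kcal/(mol Å^2)
    beta: float = 0.0           # kcal/mol
    probe_radius: float = DEFAULT_PROBE_RADIUS


# ---------------------------------------------------------------------------
# Coulomb + Lennard-Jones cross terms
# ---------------------------------------------------------------------------

def _cross_distances(coords: np.ndarray, idx_a: np.ndarray,
                     idx_b: np.ndarray) -> np.ndarray:
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def _require_params(topology: Topology, columns: list[str]) -> None:
    for col in columns:
        if np.any(~np.isfinite(getattr(topology, col))):
            raise ValueError(
                f"topology is missing {col} parameters; attach them with "
                "read_parameters first")


def pairwise_coulomb_lj(coords: np.ndarray, topology: Topology,
                        group_a: Selection, group_b: Selection,
                        mode: str = "half",
                        coulomb_constant: float = COULOMB_CONSTANT,
                        ) -> tuple[float, float, pd.DataFrame]:
    """Coulomb and Lennard-Jones energy between two disjoint groups.

    Sums q_i q_j k_c / r and eps_ij[(Rmin_ij/r)^12 - 2(Rmin_ij/r)^6] over
    all cross pairs with no cutoff.  Returns (E_ele, E_vdw, per-residue
    table); the per-residue assignment follows ``mode`` (see module notes).
    """
    idx_a, idx_b = group_a.indices, group_b.indices
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups A and B must be disjoint")
    _require_params(topology, ["charges", "lj_radius", "lj_epsilon"])
    coords = np.asarray(coords, dtype=float)
    r = _cross_distances(coords, idx_a, idx_b)
    if np.any(r < 1e-6):
        raise ValueError("overlapping atoms across the interface (r < 1e-6 Å)")
    q = topology.charges
    ele = coulomb_constant * np.outer(q[idx_a], q[idx_b]) / r
    rmin = topology.lj_radius[idx_a][:, None] + topology.lj_radius[idx_b][None, :]
    eps = np.sqrt(np.outer(topology.lj_epsilon[idx_a],
                           topology.lj_epsilon[idx_b]))
    sr6 = (rmin / r) ** 6
    vdw = eps * (sr6 * sr6 - 2.0 * sr6)
    per_atom_ele, per_atom_vdw = _assign_cross(topology, idx_a, idx_b,
                                               ele, mode), \
        _assign_cross(topology, idx_a, idx_b, vdw, mode)
    table = _per_residue_frame(topology,
                               {"E_ele": per_atom_ele, "E_vdw": per_atom_vdw})
    return float(ele.sum()), float(vdw.sum()), table


def _assign_cross(topology: Topology, idx_a, idx_b, pair_matrix,
                  mode: str) -> np.ndarray:
    per_atom = np.zeros(topology.n_atoms)
    row = pair_matrix.sum(axis=1)
    col = pair_matrix.sum(axis=0)
    if mode == "half":
        np.add.at(per_atom, idx_a, 0.5 * row)
        np.add.at(per_atom, idx_b, 0.5 * col)
    elif mode == "full":
        np.add.at(per_atom, idx_a, row)
        np.add.at(per_atom, idx_b, col)
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    return per_atom


def _per_residue_frame(topology: Topology,
                       per_atom_columns: dict[str, np.ndarray]) -> pd.DataFrame:
    ridx = topology.residue_index()
    keys = topology.residue_keys
    data = {"chain": [k[0] for k in keys],
            "res_id": [k[1] for k in keys],
            "res_name": [k[2] for k in keys]}
    for name, values in per_atom_columns.items():
        sums = np.zeros(len(keys))
        np.add.at(sums, ridx, values)
        data[name] = sums
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# generalized Born
# ---------------------------------------------------------------------------

def _descreen_integral(d: np.ndarray, rho_i: np.ndarray,
                       s_j: np.ndarray) -> np.ndarray:
    """Pairwise descreening integral H(d, rho_i, s_j).

    The (1/4π)∫ dV/|x|^4 integral over a sphere of radius s_j at distance
    d from atom i, excluding the region inside atom i's own radius rho_i.
    Derived by shell integration; validated against direct numerical
    quadrature in the test suite.
    """
    U = d + s_j
    L = np.maximum(np.abs(d - s_j), rho_i)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = (0.5 * (1.0 / L - 1.0 / U)
             - np.log(U / L) / (4.0 * d)
             - (d * d - s_j * s_j) * (1.0 / L ** 2 - 1.0 / U ** 2) / (8.0 * d))
        # atom i's exclusion sphere entirely inside atom j's scaled sphere:
        # shells below s_j - d are completely buried
        engulfed = rho_i < (s_j - d)
        h = h + np.where(engulfed, 1.0 / rho_i - 1.0 / L, 0.0)
    return np.where(rho_i >= U, 0.0, h)


def born_radii(coords: np.ndarray, topology: Topology, model: GBModel,
               indices: np.ndarray | None = None) -> np.ndarray:
    """Effective Born radii (Å) for the given atoms (default: all).

    An isolated atom's effective radius equals its offset-corrected
    intrinsic radius; neighbors descreen it through the pairwise integral,
    rescaled by the OBC tanh form of the model.
    """
    _require_params(topology, ["gb_radius"])
    idx = (np.arange(topology.n_atoms) if indices is None
           else np.asarray(indices, dtype=int))
    coords = np.asarray(coords, dtype=float)
    rho0 = topology.gb_radius[idx]
    rho = rho0 - model.offset
    if np.any(rho <= 0):
        bad = idx[np.argmin(rho)]
        raise ValueError(
            f"atom {bad} ({topology.atom_names[bad]}) has intrinsic radius "
            f"<= offset")
    scale = np.array([model.screening.get(topology.elements[i], 0.8)
                      for i in idx])
    s = scale * rho
    n = len(idx)
    if n == 1:
        integral = np.zeros(1)
    else:
        diff = coords[idx][:, None, :] - coords[idx][None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=2))
        np.fill_diagonal(d, np.inf)
        h = _descreen_integral(d, rho[:, None], s[None, :])
        integral = np.nansum(np.where(np.isfinite(d), h, 0.0), axis=1)
    psi = integral * rho
    inv_r = 1.0 / rho - np.tanh(model.alpha * psi - model.beta * psi ** 2
                                + model.gamma * psi ** 3) / rho0
    radii = 1.0 / inv_r
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        bad = idx[int(np.flatnonzero(~np.isfinite(radii) | (radii <= 0))[0])]
        raise ValueError(
            f"non-finite effective Born radius for atom {bad} "
            f"({topology.atom_names[bad]})")
    return radii


def _gb_pair_matrix(coords: np.ndarray, charges: np.ndarray,
                    radii: np.ndarray, prefactor: float) -> np.ndarray:
    """Full (self-inclusive) GB energy matrix; its total sum is the GB
    polar solvation energy of the atom set."""
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    rr = np.outer(radii, radii)
    f = np.sqrt(r2 + rr * np.exp(-r2 / (4.0 * rr)))
    return prefactor * np.outer(charges, charges) / f


def gb_polar_energy(coords: np.ndarray, topology: Topology, model: GBModel,
                    group_a: Selection, group_b: Selection,
                    mode: str = "half",
                    ) -> tuple[float, pd.DataFrame]:
    """Interaction part of the GB polar solvation energy between two groups.

    Computed in the single-trajectory convention as
    E_GB(A∪B) - E_GB(A) - E_GB(B) at the same geometry, with Born radii
    recomputed for each state.  Returns the total (kcal/mol) and a
    per-residue table; in ``mode="half"`` the rows sum exactly to the
    total, in ``mode="full"`` each row holds the residue's screened cross
    interaction with the whole partner group at complex radii.
    """
    idx_a, idx_b = group_a.indices, group_b.indices
    if np.intersect1d(idx_a, idx_b).size:
        raise ValueError("groups A and B must be disjoint")
    _require_params(topology, ["charges"])
    coords = np.asarray(coords, dtype=float)
    q = topology.charges
    idx_ab = np.concatenate([idx_a, idx_b])

    radii_ab = born_radii(coords, topology, model, idx_ab)
    radii_a = born_radii(coords, topology, model, idx_a)
    radii_b = born_radii(coords, topology, model, idx_b)

    m_ab = _gb_pair_matrix(coords[idx_ab], q[idx_ab], radii_ab, model.prefactor)
    m_a = _gb_pair_matrix(coords[idx_a], q[idx_a], radii_a, model.prefactor)
    m_b = _gb_pair_matrix(coords[idx_b], q[idx_b], radii_b, model.prefactor)

    total = float(m_ab.sum() - m_a.sum() - m_b.sum())
    per_atom = np.zeros(topology.n_atoms)
    if mode == "half":
        # row sums assign each unordered pair half/half; self terms to owner
        np.add.at(per_atom, idx_ab, m_ab.sum(axis=1))
        np.add.at(per_atom, idx_a, -m_a.sum(axis=1))
        np.add.at(per_atom, idx_b, -m_b.sum(axis=1))
    elif mode == "full":
        na = len(idx_a)
        cross = m_ab[:na, na:]          # counted twice in the full sum
        np.add.at(per_atom, idx_a, 2.0 * cross.sum(axis=1))
        np.add.at(per_atom, idx_b, 2.0 * cross.sum(axis=0))
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    table = _per_residue_frame(topology, {"G_pol": per_atom})
    return total, table


# ---------------------------------------------------------------------------
# LCPO solvent-accessible surface area
# ---------------------------------------------------------------------------

def _cap_area(big_r: np.ndarray, other_r: np.ndarray,
              d: np.ndarray) -> np.ndarray:
    """Area of sphere (radius big_r) buried inside a sphere of radius
    other_r at center distance d (both probe-expanded)."""
    area = 2.0 * np.pi * big_r * (big_r - d / 2.0
                                  - (big_r ** 2 - other_r ** 2) / (2.0 * d))
    # full engulfment / containment edge cases
    area = np.where(d <= other_r - big_r, 4.0 * np.pi * big_r ** 2, area)
    area = np.where(d <= big_r - other_r, 0.0, area)
    return np.clip(area, 0.0, 4.0 * np.pi * big_r ** 2)


def lcpo_sasa(coords: np.ndarray, topology: Topology,
              probe_radius: float = DEFAULT_PROBE_RADIUS,
              radii: np.ndarray | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å^2) by the LCPO linear
    combination of pairwise overlaps.

    For heavy atom i with probe-expanded radius R_i, neighbor set N_i
    (overlapping expanded spheres) and A_jk the area of sphere j buried by
    sphere k:

        A_i = P1·4πR_i^2 + P2·Σ_j A_ij + P3·Σ_{j≠k∈N_i, overlapping} A_jk
              + P4·Σ_j A_ij·Σ_{k∈N_i∩N_j} A_jk

    with the four per-atom LCPO coefficients from the topology.  Hydrogens
    carry zero area.  ``radii`` defaults to the topology's lj_radius
    column (Rmin/2, the usual vdW-radius stand-in).
    """
    coords = np.asarray(coords, dtype=float)
    heavy = np.flatnonzero(topology.elements != "H")
    if radii is None:
        _require_params(topology, ["lj_radius"])
        radii = topology.lj_radius
    radii = np.asarray(radii, dtype=float)
    p = topology.lcpo_params
    if np.any(~np.isfinite(p[heavy])):
        bad = heavy[~np.all(np.isfinite(p[heavy]), axis=1)]
        names = ", ".join(f"{topology.res_names[i]}/{topology.atom_names[i]}"
                          for i in bad[:5])
        raise ValueError(f"missing LCPO coefficients for atoms: {names}")

    big = radii[heavy] + probe_radius
    diff = coords[heavy][:, None, :] - coords[heavy][None, :, :]
    d = np.sqrt(np.sum(diff * diff, axis=2))
    overlap = (d < big[:, None] + big[None, :])
    np.fill_diagonal(overlap, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(overlap,
                       _cap_area(big[:, None], big[None, :],
                                 np.where(d > 0, d, np.inf)), 0.0)

    n = len(heavy)
    sasa_heavy = np.empty(n)
    for a in range(n):
        nbrs = np.flatnonzero(overlap[a])
        s1 = 4.0 * np.pi * big[a] ** 2
        term2 = cap[a, nbrs].sum()
        term3 = 0.0
        term4 = 0.0
        for j in nbrs:
            ks = nbrs[overlap[j, nbrs]]
            ajk = cap[j, ks].sum()
            term3 += ajk
            term4 += cap[a, j] * ajk
        p1, p2, p3, p4 = p[heavy[a]]
        sasa_heavy[a] = max(0.0, p1 * s1 + p2 * term2 + p3 * term3 + p4 * term4)
    out = np.zeros(topology.n_atoms)
    out[heavy] = sasa_heavy
    return out


def nonpolar_energy(coords: np.ndarray, topology: Topology,
                    model: NonpolarModel) -> float:
    """G_nonpol = γ·(total SASA) + β for a single state."""
    return model.gamma * float(lcpo_sasa(coords, topology,
                                         model.probe_radius).sum()) + model.beta


# ---------------------------------------------------------------------------
# full interface decomposition
# ---------------------------------------------------------------------------

def snapshot_indices(n_frames: int, n_snapshots: int) -> np.ndarray:
    """Evenly spaced snapshot indices, the "N evenly from the tail" policy."""
    if n_snapshots < 1:
        raise ValueError("snapshot policy must select at least one frame")
    n = min(n_snapshots, n_frames)
    return np.unique(np.round(np.linspace(0, n_frames - 1, n)).astype(int))


def decompose_interface(trajectory: Trajectory, group_a: Selection,
                        group_b: Selection,
                        gb_model: GBModel | None = None,
                        nonpolar_model: NonpolarModel | None = None,
                        n_snapshots: int = 150,
                        mode: str = "half") -> DecompositionTable:
    """Per-residue interaction free-energy table averaged over snapshots.

    The nonpolar term of residue r is γ times the buried-area change of
    r's atoms upon complexation at fixed geometry (complex SASA minus
    isolated-own-group SASA); β is a per-state constant that cancels in
    the interaction difference and is therefore not spread over residues.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both interface groups must be nonempty")
    gb_model = gb_model or GBModel()
    nonpolar_model = nonpolar_model or NonpolarModel()
    top = trajectory.topology
    idx_a, idx_b = group_a.indices, group_b.indices
    idx_ab = np.concatenate([idx_a, idx_b])
    frames = snapshot_indices(trajectory.n_frames, n_snapshots)

    acc: dict[str, np.ndarray] = {}
    for f in frames:
        coords = trajectory.coords[f]
        _, _, mm = pairwise_coulomb_lj(coords, top, group_a, group_b,
                                       mode=mode,
                                       coulomb_constant=gb_model.coulomb_constant)
        _, pol = gb_polar_energy(coords, top, gb_model, group_a, group_b,
                                 mode=mode)
        sasa_ab = lcpo_sasa(coords, top, nonpolar_model.probe_radius)
        sasa_iso = np.zeros(top.n_atoms)
        for idx in (idx_a, idx_b):
            sub_coords = coords[idx]
            sub_top = _subset_topology(top, idx)
            sasa_iso[idx] = lcpo_sasa(sub_coords, sub_top,
                                      nonpolar_model.probe_radius)
        per_atom_np = np.zeros(top.n_atoms)
        per_atom_np[idx_ab] = nonpolar_model.gamma * (
            sasa_ab[idx_ab] - sasa_iso[idx_ab])
        np_table = _per_residue_frame(top, {"G_nonpol": per_atom_np})
        for name, col in (("E_ele", mm["E_ele"]), ("E_vdw", mm["E_vdw"]),
                          ("G_pol", pol["G_pol"]),
                          ("G_nonpol", np_table["G_nonpol"])):
            acc[name] = acc.get(name, 0.0) + col.to_numpy()

    keys = top.residue_keys
    frame = pd.DataFrame({
        "chain": [k[0] for k in keys],
        "res_id": [k[1] for k in keys],
        "res_name": [k[2] for k in keys],
    })
    for name in ("E_ele", "E_vdw", "G_pol", "G_nonpol"):
        frame[name] = acc[name] / len(frames)
    frame["G_total"] = (frame["E_ele"] + frame["E_vdw"]
                        + frame["G_pol"] + frame["G_nonpol"])
    # keep only residues that belong to the interface groups
    ridx = top.residue_index()
    involved = sorted({int(r) for r in ridx[idx_ab]})
    frame = frame.iloc[involved].reset_index(drop=True)
    return DecompositionTable(frame, n_snapshots=len(frames))


def _subset_topology(topology: Topology, indices: np.ndarray) -> Topology:
    idx = np.asarray(indices, dtype=int)
    old_to_new = {int(o): n for n, o in enumerate(idx)}
    bonds = [(old_to_new[a], old_to_new[b]) for a, b in topology.bonds
             if a in old_to_new and b in old_to_new]
    return Topology(
        atom_names=topology.atom_names[idx],
        elements=topology.elements[idx],
        res_ids=topology.res_ids[idx],
        res_names=topology.res_names[idx],
        chain_ids=topology.chain_ids[idx],
        masses=topology.masses[idx],
        charges=topology.charges[idx],
        lj_radius=topology.lj_radius[idx],
        lj_epsilon=topology.lj_epsilon[idx],
        gb_radius=topology.gb_radius[idx],
        lcpo_params=topology.lcpo_params[idx],
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
    )
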