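"""Trajectory statistics: superposed RMSD, radius of gyration, positional
covariance PCA, average-linkage clustering with sieving, hydrogen-bond
occupancy, group mass-center distances, native binding contacts and
residue contact maps.

All statistics operate on :class:`~unbindkit.core.Trajectory` /
:class:`~unbindkit.core.Selection` and are invariant under global
rigid-body motion of the frames.  Distances are in Å, occupancies and
contact fractions in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import Selection, Trajectory

__all__ = [
    "HBondSpec", "ContactSpec", "ClusterResult", "PCAResult", "QbResult",
    "kabsch", "superpose_rmsd", "radius_of_gyration", "pca",
    "cluster_frames", "hbond_occupancy", "group_center_distance",
    "native_contacts", "contact_map", "pairwise_bestfit_rmsd",
]


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal least-squares superposition (unweighted).

    Returns (rotation matrix R, mobile centroid, reference centroid) such
    that ``(x - mobile_centroid) @ R.T + reference_centroid`` superposes
    mobile onto reference.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    rot = vt.T @ flip @ u.T
    return rot, cm, cr


def _apply_fit(coords: np.ndarray, rot: np.ndarray, cm: np.ndarray,
               cr: np.ndarray) -> np.ndarray:
    return (coords - cm) @ rot.T + cr


def pairwise_bestfit_rmsd(x: np.ndarray, y: np.ndarray | None = None
                          ) -> np.ndarray:
    """Best-fit RMSD between every frame pair (each pair superposed
    independently), vectorised over pairs via batched 3x3 SVD.

    ``x`` has shape (a, m, 3); returns an (a, a) matrix, or an (a, b)
    matrix if ``y`` (shape (b, m, 3)) is given.
    """
    x = np.asarray(x, dtype=float)
    symmetric = y is None
    y = x if symmetric else np.asarray(y, dtype=float)
    m = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    tx = np.sum(xc * xc, axis=(1, 2))
    ty = np.sum(yc * yc, axis=(1, 2))
    h = np.einsum("pmi,qmj->pqij", xc, yc)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pqij,pqjk->pqik", u, vt))
    ssum = s[..., 0] + s[..., 1] + det * s[..., 2]
    msd = (tx[:, None] + ty[None, :] - 2.0 * ssum) / m
    return np.sqrt(np.clip(msd, 0.0, None))


def superpose_rmsd(trajectory: Trajectory, fit_selection: Selection,
                   measure_selection: Selection | None = None,
                   reference: int | np.ndarray = 0) -> np.ndarray:
    """Per-frame RMSD (Å) after optimal superposition.

    Each frame is superposed onto the reference (a frame index or explicit
    coordinates) by an unweighted Kabsch fit on ``fit_selection``; the RMSD
    is then measured on ``measure_selection`` (default: the fit selection).
    """
    if len(fit_selection) < 3:
        raise ValueError("need at least 3 atoms in the fit selection")
    measure = measure_selection if measure_selection is not None else fit_selection
    if len(measure) == 0:
        raise ValueError("measure selection is empty")
    ref = (trajectory.coords[reference] if isinstance(reference, (int, np.integer))
           else np.asarray(reference, dtype=float))
    fi, mi = fit_selection.indices, measure.indices
    out = np.empty(trajectory.n_frames)
    for f in range(trajectory.n_frames):
        frame = trajectory.coords[f]
        rot, cm, cr = kabsch(frame[fi], ref[fi])
        fitted = _apply_fit(frame[mi], rot, cm, cr)
        out[f] = np.sqrt(np.mean(np.sum((fitted - ref[mi]) ** 2, axis=1)))
    return out


def radius_of_gyration(trajectory: Trajectory, selection: Selection,
                       mass_weighted: bool = True) -> np.ndarray:
    """Per-frame radius of gyration sqrt(Σ w_i |x_i - x̄|² / Σ w_i) in Å."""
    if len(selection) == 0:
        raise ValueError("selection is empty")
    idx = selection.indices
    w = (trajectory.topology.masses[idx] if mass_weighted
         else np.ones(len(idx)))
    coords = trajectory.coords[:, idx]
    center = np.average(coords, axis=1, weights=w)
    dev = coords - center[:, None, :]
    return np.sqrt(np.average(np.sum(dev * dev, axis=2), axis=1, weights=w))


# ---------------------------------------------------------------------------
# PCA of positional covariance
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray            # descending, Å^2
    eigenvectors: np.ndarray           # (3m, 3m), columns match eigenvalues
    variance_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    mean_structure: np.ndarray         # (m, 3)

    def leading_fraction(self, k: int) -> float:
        """Cumulative variance fraction of the first k components."""
        return float(self.cumulative_fraction[k - 1])


def pca(trajectory: Trajectory, selection: Selection,
        superpose: bool = True, n_fit_iterations: int = 2) -> PCAResult:
    """Eigen-decomposition of the positional covariance of selected atoms.

    Frames are first superposed onto their average structure (fit,
    re-average, fit — repeated ``n_fit_iterations`` times) to remove
    rigid-body motion; set ``superpose=False`` when the frames carry no
    rigid-body component (e.g. i.i.d. fluctuations about a fixed mean).
    Eigenvalues are sorted descending; their cumulative fractions give the
    "first k components account for X%" statistic.
    """
    if trajectory.n_frames < 2:
        raise ValueError("PCA requires at least 2 frames")
    if len(selection) == 0:
        raise ValueError("selection is empty")
    coords = trajectory.coords[:, selection.indices].copy()
    if superpose:
        for _ in range(n_fit_iterations):
            mean = coords.mean(axis=0)
            for f in range(len(coords)):
                rot, cm, cr = kabsch(coords[f], mean)
                coords[f] = _apply_fit(coords[f], rot, cm, cr)
    mean = coords.mean(axis=0)
    flat = (coords - mean).reshape(len(coords), -1)
    cov = flat.T @ flat / (len(coords) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(eigenvalues=evals, eigenvectors=evecs,
                     variance_fraction=frac,
                     cumulative_fraction=np.cumsum(frac),
                     mean_structure=mean)


# ---------------------------------------------------------------------------
# clustering with sieve
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray                 # per-frame cluster id, 0-based, by population
    representatives: list[int]         # medoid frame index per cluster
    populations: np.ndarray            # fraction of all frames per cluster
    sieved_frames: np.ndarray          # frame indices used for agglomeration

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def cluster_frames(trajectory: Trajectory, selection: Selection,
                   n_clusters: int | None = None,
                   distance_threshold: float | None = None,
                   sieve: int = 1) -> ClusterResult:
    """Hierarchical agglomerative clustering of frames (average linkage,
    pairwise best-fit RMSD metric) with sieving.

    Every ``sieve``-th frame enters the agglomeration; remaining frames
    are then assigned to the nearest cluster representative (medoid) under
    the same metric, ties going to the lower cluster index.  Clusters are
    relabelled by decreasing population.  Exactly one of ``n_clusters`` or
    ``distance_threshold`` must be given.
    """
    if sieve < 1:
        raise ValueError("sieve must be >= 1")
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("give exactly one of n_clusters or distance_threshold")
    sieved = np.arange(0, trajectory.n_frames, sieve)
    if n_clusters is not None and n_clusters > len(sieved):
        raise ValueError(
            f"n_clusters={n_clusters} exceeds the {len(sieved)} sieved frames")
    coords = trajectory.coords[:, selection.indices]
    dmat = pairwise_bestfit_rmsd(coords[sieved])
    if len(sieved) == 1:
        sieved_labels = np.zeros(1, dtype=int)
    else:
        z = linkage(squareform(dmat, checks=False), method="average")
        if n_clusters is not None:
            sieved_labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1
        else:
            sieved_labels = fcluster(z, t=distance_threshold,
                                     criterion="distance") - 1

    cluster_ids = np.unique(sieved_labels)
    reps = []
    for cid in cluster_ids:
        members = np.flatnonzero(sieved_labels == cid)
        sub = dmat[np.ix_(members, members)]
        reps.append(int(sieved[members[np.argmin(sub.sum(axis=1))]]))

    labels = np.full(trajectory.n_frames, -1, dtype=int)
    labels[sieved] = sieved_labels
    rest = np.setdiff1d(np.arange(trajectory.n_frames), sieved)
    if rest.size:
        d_rest = pairwise_bestfit_rmsd(coords[rest], coords[np.asarray(reps)])
        labels[rest] = cluster_ids[np.argmin(d_rest, axis=1)]

    counts = np.array([(labels == cid).sum() for cid in cluster_ids])
    order = np.argsort(-counts, kind="stable")
    remap = {int(cluster_ids[o]): rank for rank, o in enumerate(order)}
    labels = np.array([remap[int(l)] for l in labels])
    reps = [reps[o] for o in order]
    populations = counts[order] / trajectory.n_frames
    return ClusterResult(labels=labels, representatives=reps,
                         populations=populations, sieved_frames=sieved)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HBondSpec:
    """Geometric hydrogen-bond criterion: acceptor-donor distance strictly
    below the cutoff and acceptor···H-donor angle strictly above the angle
    cutoff (strict inequalities on both boundaries)."""

    distance_cutoff: float = 3.5       # Å, acceptor-donor
    angle_cutoff: float = 120.0        # degrees at the hydrogen
    donor_elements: tuple = ("N", "O")
    acceptor_elements: tuple = ("N", "O")

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_cutoff <= 180.0:
            raise ValueError("angle cutoff must be in (0, 180]")
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be > 0")


def hbond_occupancy(trajectory: Trajectory, donor_group: Selection,
                    acceptor_group: Selection,
                    spec: HBondSpec | None = None,
                    ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-(donor, hydrogen, acceptor) occupancy: the fraction of frames in
    which both geometric criteria hold.

    Donors are N/O atoms of the donor group with at least one bonded
    hydrogen (donor-group N/O atoms without one are skipped with a
    warning).  Returns an occupancy table and the boolean per-frame
    timelines, shape (n_triples, n_frames).
    """
    spec = spec or HBondSpec()
    top = trajectory.topology
    donors = []
    skipped = []
    for i in donor_group.indices:
        if top.elements[i] not in spec.donor_elements:
            continue
        hydrogens = top.bonded_hydrogens(int(i))
        if not hydrogens:
            skipped.append(int(i))
            continue
        donors.extend((int(i), h) for h in hydrogens)
    if skipped:
        warnings.warn(
            f"{len(skipped)} donor-group atoms have no bonded hydrogen and "
            f"were skipped: {skipped[:5]}", stacklevel=2)
    acceptors = [int(i) for i in acceptor_group.indices
                 if top.elements[i] in spec.acceptor_elements]

    rows, timelines = [], []
    coords = trajectory.coords
    for d, h in donors:
        for a in acceptors:
            if a == d:
                continue
            da = np.linalg.norm(coords[:, a] - coords[:, d], axis=1)
            v1 = coords[:, a] - coords[:, h]
            v2 = coords[:, d] - coords[:, h]
            cosang = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            formed = (da < spec.distance_cutoff) & (angle > spec.angle_cutoff)
            timelines.append(formed)
            rows.append({
                "donor": d, "hydrogen": h, "acceptor": a,
                "donor_name": f"{top.chain_ids[d]}/{top.res_names[d]}"
                              f"{top.res_ids[d]}/{top.atom_names[d]}",
                "acceptor_name": f"{top.chain_ids[a]}/{top.res_names[a]}"
                                 f"{top.res_ids[a]}/{top.atom_names[a]}",
                "occupancy": float(formed.mean()),
            })
    table = pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor",
                                        "donor_name", "acceptor_name",
                                        "occupancy"])
    tl = (np.asarray(timelines) if timelines
          else np.empty((0, trajectory.n_frames), dtype=bool))
    return table, tl


# ---------------------------------------------------------------------------
# group centers, native contacts, contact maps
# ---------------------------------------------------------------------------

def group_center_distance(trajectory: Trajectory, group_a: Selection,
                          group_b: Selection,
                          mass_weighted: bool = True) -> np.ndarray:
    """Per-frame distance (Å) between the (mass-weighted) centroids of two
    atom groups."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    masses = trajectory.topology.masses

    def center(idx):
        w = masses[idx] if mass_weighted else np.ones(len(idx))
        return np.average(trajectory.coords[:, idx], axis=1, weights=w)

    return np.linalg.norm(center(group_a.indices) - center(group_b.indices),
                          axis=1)


@dataclass
class ContactSpec:
    """Native binding contact criterion: two residues from different groups
    are in contact when any pair of their heavy atoms is closer than the
    cutoff (strict inequality)."""

    cutoff: float = 3.5
    reference: int | np.ndarray = 0     # frame index or explicit coordinates
    heavy_only: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class QbResult:
    qb: np.ndarray                             # per-frame fraction
    native_pairs: list[tuple[tuple, tuple]]    # (residue key A, residue key B)
    timelines: np.ndarray                      # (n_pairs, n_frames) bool

    def timeline_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(
            [(f"{a[0]}/{a[2]}{a[1]}", f"{b[0]}/{b[2]}{b[1]}")
             for a, b in self.native_pairs], names=["residue_a", "residue_b"])
        return pd.DataFrame(self.timelines, index=idx)


def _residue_atom_groups(trajectory: Trajectory, selection: Selection,
                         heavy_only: bool) -> list[tuple[tuple, np.ndarray]]:
    top = trajectory.topology
    ridx = top.residue_index()
    keys = top.residue_keys
    groups: dict[int, list[int]] = {}
    for i in selection.indices:
        if heavy_only and top.elements[i] == "H":
            continue
        groups.setdefault(int(ridx[i]), []).append(int(i))
    return [(keys[r], np.array(groups[r])) for r in sorted(groups)]


def _min_dist(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
    return float(np.sqrt(np.sum(diff * diff, axis=2)).min())


def native_contacts(trajectory: Trajectory, group_a: Selection,
                    group_b: Selection,
                    spec: ContactSpec | None = None) -> QbResult:
    """Fraction of native binding contacts retained per frame (Qb).

    The native pair list is built from the reference structure: every
    (residue of A, residue of B) pair with any heavy-atom distance below
    the cutoff.  A frame retains a contact when the same criterion still
    holds.  Raises if the reference has no native contacts (Qb undefined).
    """
    spec = spec or ContactSpec()
    ref = (trajectory.coords[spec.reference]
           if isinstance(spec.reference, (int, np.integer))
           else np.asarray(spec.reference, dtype=float))
    res_a = _residue_atom_groups(trajectory, group_a, spec.heavy_only)
    res_b = _residue_atom_groups(trajectory, group_b, spec.heavy_only)
    pairs = []
    for key_a, idx_a in res_a:
        for key_b, idx_b in res_b:
            if _min_dist(ref, idx_a, idx_b) < spec.cutoff:
                pairs.append(((key_a, idx_a), (key_b, idx_b)))
    if not pairs:
        raise ValueError("no native contacts in the reference structure; "
                         "Qb is undefined")
    timelines = np.empty((len(pairs), trajectory.n_frames), dtype=bool)
    for p, ((_, idx_a), (_, idx_b)) in enumerate(pairs):
        for f in range(trajectory.n_frames):
            timelines[p, f] = _min_dist(trajectory.coords[f], idx_a,
                                        idx_b) < spec.cutoff
    return QbResult(
        qb=timelines.mean(axis=0),
        native_pairs=[(a[0], b[0]) for a, b in pairs],
        timelines=timelines,
    )


def contact_map(trajectory: Trajectory, frame_indices: list[int],
                cutoff: float = 3.5, heavy_only: bool = True,
                ) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Residue-residue boolean contact maps for representative frames and
    their logical AND (the contacts present in every frame).

    Returns (per-frame maps of shape (k, R, R), intersection map, residue
    keys).
    """
    if not frame_indices:
        raise ValueError("need at least one frame")
    groups = _residue_atom_groups(trajectory, trajectory.topology.select_all(),
                                  heavy_only)
    keys = [k for k, _ in groups]
    n_res = len(groups)
    maps = np.zeros((len(frame_indices), n_res, n_res), dtype=bool)
    for m, f in enumerate(frame_indices):
        coords = trajectory.coords[f]
        for i in range(n_res):
            for j in range(i + 1, n_res):
                contact = _min_dist(coords, groups[i][1], groups[j][1]) < cutoff
                maps[m, i, j] = maps[m, j, i] = contact
    return maps, maps.all(axis=0), keys
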