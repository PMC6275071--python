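"""Synthetic inputs with known ground truth.

Every test bed the package's estimators are exercised on is generated here:

* constrained-center force records sampled by Langevin dynamics over
  analytically tractable potentials (for the mean-force / PMF machinery),
* toy two-chain bead "complexes" with planted native contacts broken on a
  known schedule (for the contact statistics),
* trajectories with planted hydrogen-bond geometry, planted conformer
  clusters, and exactly known Gaussian covariance (for occupancy,
  clustering and PCA).

All randomness flows from one explicit integer seed; per-window /
per-frame generators derive child seeds with a fixed counter scheme
(``numpy.random.default_rng([seed, counter])``), so regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .core import SteeringWindow, Topology, Trajectory
from .units import KB, KCAL_PER_MOL_IN_AMU_A2_PS2

__all__ = [
    "AnalyticPotential", "LangevinSpec",
    "harmonic_well", "double_well", "harmonic_chain",
    "generate_steering_records",
    "generate_toy_complex", "ToyComplex",
    "generate_gaussian_trajectory",
    "generate_conformer_trajectory",
    "generate_hbond_trajectory",
    "generate_random_complex",
    "generate_sphere_cluster",
]


# ---------------------------------------------------------------------------
# analytic potentials
# ---------------------------------------------------------------------------

@dataclass
class AnalyticPotential:
    """An energy function over the concatenated coordinates of ``n_steered``
    constrained centers followed by ``n_free`` Langevin particles.

    ``energy`` maps a flat coordinate vector of length
    ``3*(n_steered+n_free)`` (Å) to kcal/mol; ``gradient`` returns the
    matching flat gradient in kcal/mol/Å.
    """

    name: str
    energy: Callable[[np.ndarray], float]
    gradient: Callable[[np.ndarray], np.ndarray]
    n_steered: int
    n_free: int = 0
    params: dict = field(default_factory=dict)

    @property
    def n_coords(self) -> int:
        return 3 * (self.n_steered + self.n_free)

    def numerical_gradient(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        g = np.empty_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            g[i] = (self.energy(xp) - self.energy(xm)) / (2 * h)
        return g


def harmonic_well(k: float) -> AnalyticPotential:
    """One steered center in an isotropic harmonic well U = k|x|^2 / 2."""
    def energy(x):
        return 0.5 * k * float(np.dot(x, x))

    def gradient(x):
        return k * np.asarray(x, dtype=float)

    return AnalyticPotential("harmonic_well", energy, gradient,
                             n_steered=1, params={"k": k})


def flat_potential(n_steered: int = 1) -> AnalyticPotential:
    """U identically zero (every recorded force is zero)."""
    return AnalyticPotential(
        "flat", lambda x: 0.0, lambda x: np.zeros_like(np.asarray(x, float)),
        n_steered=n_steered)


def double_well(a: float, b: float) -> AnalyticPotential:
    """Quartic double well U(x) = b[(x/a)^2 - 1]^2 on the steered center's
    x coordinate; minima at x = ±a, barrier height b at x = 0."""
    def energy(x):
        s = (x[0] / a) ** 2 - 1.0
        return b * s * s

    def gradient(x):
        g = np.zeros_like(np.asarray(x, float))
        s = (x[0] / a) ** 2 - 1.0
        g[0] = 4.0 * b * s * x[0] / a ** 2
        return g

    return AnalyticPotential("double_well", energy, gradient,
                             n_steered=1, params={"a": a, "b": b})


def harmonic_chain(spring_constants: Sequence[float]) -> AnalyticPotential:
    """A steered center coupled through a chain of Langevin particles.

    With spring constants ``(k_1, ..., k_{m+1})`` the energy is

        U = k_1|x_s - x_1|^2/2 + k_2|x_1 - x_2|^2/2 + ... + k_{m+1}|x_m|^2/2

    for ``m = len(spring_constants) - 1`` free particles.  Integrating the
    free particles out leaves an exactly harmonic potential of mean force
    on the steered center with effective constant ``k_eff`` given by the
    springs in series: 1/k_eff = sum_i 1/k_i.  The mean constrained force
    at steered position c is therefore -k_eff * c.
    """
    ks = np.asarray(spring_constants, dtype=float)
    if np.any(ks <= 0):
        raise ValueError("spring constants must be positive")
    m = len(ks) - 1

    def _nodes(x):
        # node 0 = steered center, nodes 1..m = free particles, node m+1 = origin
        pts = np.concatenate([np.asarray(x, float).reshape(-1, 3),
                              np.zeros((1, 3))])
        return pts

    def energy(x):
        pts = _nodes(x)
        d = pts[:-1] - pts[1:]
        return float(0.5 * np.sum(ks * np.sum(d * d, axis=1)))

    def gradient(x):
        pts = _nodes(x)
        d = pts[:-1] - pts[1:]              # d[i] = pts[i] - pts[i+1]
        g = np.zeros_like(pts)
        for i in range(len(ks)):
            g[i] += ks[i] * d[i]
            g[i + 1] -= ks[i] * d[i]
        return g[:-1].ravel()

    pot = AnalyticPotential("harmonic_chain", energy, gradient,
                            n_steered=1, n_free=m,
                            params={"ks": ks})
    pot.k_eff = 1.0 / np.sum(1.0 / ks)  # type: ignore[attr-defined]
    return pot


# ---------------------------------------------------------------------------
# Langevin sampling of constrained-center forces
# ---------------------------------------------------------------------------

@dataclass
class LangevinSpec:
    """Parameters of the BAOAB Langevin integrator used per window.

    ``n_steps_per_segment`` integration steps are taken for each of the
    four force-collection segments; the constraint forces are recorded
    every ``sample_stride`` steps.
    """

    temperature: float = 300.0        # K
    friction: float = 5.0             # 1/ps
    timestep: float = 0.002           # ps
    seed: int = 0
    n_steps_per_segment: int = 2000
    masses: float = 12.0              # amu (scalar, applied to all free particles)
    sample_stride: int = 4


class DivergenceError(RuntimeError):
    """A Langevin trajectory produced a non-finite coordinate."""


def _baoab_run(grad_free, x0, spec: LangevinSpec, rng, n_steps,
               record_every=0, record=None, window_index=0):
    """BAOAB splitting: half kick, half drift, exact OU, half drift, half kick."""
    dt = spec.timestep
    m = spec.masses
    x = np.array(x0, dtype=float)
    kT = KB * spec.temperature * KCAL_PER_MOL_IN_AMU_A2_PS2   # amu Å^2/ps^2
    v = rng.normal(0.0, np.sqrt(kT / m), size=x.shape)
    c1 = np.exp(-spec.friction * dt)
    c2 = np.sqrt(kT / m * (1.0 - c1 * c1))
    f = -grad_free(x)
    scale = KCAL_PER_MOL_IN_AMU_A2_PS2 / m
    with np.errstate(over="ignore", invalid="ignore"):
        return _baoab_loop(grad_free, x, v, f, scale, c1, c2, dt, rng,
                           n_steps, record_every, record, window_index)


def _baoab_loop(grad_free, x, v, f, scale, c1, c2, dt, rng, n_steps,
                record_every, record, window_index):
    for step in range(n_steps):
        v += 0.5 * dt * f * scale
        x += 0.5 * dt * v
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        f = -grad_free(x)
        v += 0.5 * dt * f * scale
        if not np.all(np.isfinite(x)):
            raise DivergenceError(
                f"window {window_index}: non-finite coordinate at step {step}")
        if record_every and (step + 1) % record_every == 0:
            record(x)
    return x


def path_displacements(path: np.ndarray) -> np.ndarray:
    """Cumulative arc length (Å) along a steering path of center positions,
    measured in the concatenated 3n-dimensional space."""
    path = np.asarray(path, dtype=float)
    flat = path.reshape(len(path), -1)
    steps = np.linalg.norm(np.diff(flat, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


def generate_steering_records(potential: AnalyticPotential,
                              path: np.ndarray,
                              spec: LangevinSpec,
                              equilibration_fraction: float = 0.2,
                              ) -> list[SteeringWindow]:
    """Sample constraint forces window by window along a steering path.

    For each window the steered centers are clamped at ``path[j]``
    (shape ``(n_windows, n_steered, 3)``); the free coordinates are first
    relaxed to the local energy minimum, equilibrated by Langevin dynamics
    for the stated fraction of the run, and then propagated through four
    equal collection segments during which the force the potential exerts
    on the clamped centers is recorded every ``spec.sample_stride`` steps.

    With no free coordinates the constraint force is deterministic and is
    recorded directly, once per would-be sample.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim != 3 or path.shape[1] != potential.n_steered:
        raise ValueError("path must have shape (n_windows, n_steered, 3)")
    if not 0.0 <= equilibration_fraction < 1.0:
        raise ValueError("equilibration_fraction must be in [0, 1)")
    disps = path_displacements(path)
    if len(disps) > 1 and np.any(np.diff(disps) <= 0):
        raise ValueError("steering path windows must be strictly ordered")

    ns3 = 3 * potential.n_steered
    n_samples_per_seg = spec.n_steps_per_segment // spec.sample_stride
    if n_samples_per_seg < 1:
        raise ValueError("n_steps_per_segment must be >= sample_stride")

    windows = []
    for j, centers in enumerate(path):
        steered_flat = centers.ravel()
        if potential.n_free == 0:
            force = -potential.gradient(steered_flat)[:ns3].reshape(-1, 3)
            seg = np.repeat(force[None], n_samples_per_seg, axis=0)
            segments = [seg.copy() for _ in range(4)]
            n_equil_discarded = 0
        else:
            rng = np.random.default_rng([spec.seed, j])

            def grad_free(xf, _s=steered_flat):
                full = np.concatenate([_s, xf.ravel()])
                return potential.gradient(full)[ns3:].reshape(-1, 3)

            def energy_free(xf, _s=steered_flat):
                return potential.energy(np.concatenate([_s, xf]))

            x0 = minimize(energy_free, np.zeros(3 * potential.n_free),
                          jac=lambda xf: np.asarray(
                              grad_free(xf.reshape(-1, 3))).ravel(),
                          method="L-BFGS-B").x.reshape(-1, 3)
            total_collect = 4 * spec.n_steps_per_segment
            n_equil = int(round(equilibration_fraction /
                                (1.0 - equilibration_fraction) * total_collect))
            x0 = _baoab_run(grad_free, x0, spec, rng, n_equil, window_index=j)

            samples: list[np.ndarray] = []

            def record(xf, _s=steered_flat):
                full = np.concatenate([_s, xf.ravel()])
                samples.append(-potential.gradient(full)[:ns3].reshape(-1, 3))

            _baoab_run(grad_free, x0, spec, rng, total_collect,
                       record_every=spec.sample_stride, record=record,
                       window_index=j)
            arr = np.asarray(samples)[:4 * n_samples_per_seg]
            segments = list(arr.reshape(4, n_samples_per_seg,
                                        potential.n_steered, 3))
            n_equil_discarded = n_equil // spec.sample_stride
        windows.append(SteeringWindow(
            lambda_index=j, displacement=float(disps[j]),
            center_positions=centers, force_samples=segments,
            n_equil_discarded=n_equil_discarded))
    return windows


# ---------------------------------------------------------------------------
# toy bead complexes with planted native contacts
# ---------------------------------------------------------------------------

@dataclass
class ToyComplex:
    """A planted-contact bead complex and its ground truth."""

    topology: Topology
    trajectory: Trajectory
    native_pairs: list[tuple[int, int]]        # (receptor residue index, ligand residue index)
    broken_per_frame: np.ndarray               # number of broken native pairs per frame
    expected_qb: np.ndarray                    # fraction of native pairs intact per frame


def _bead_topology(n_receptor: int, n_ligand: int) -> Topology:
    names = ["C1"] * (n_receptor + n_ligand)
    return Topology(
        atom_names=names,
        elements=["C"] * len(names),
        res_ids=list(range(1, n_receptor + 1)) + list(range(1, n_ligand + 1)),
        res_names=["BDR"] * n_receptor + ["BDL"] * n_ligand,
        chain_ids=["A"] * n_receptor + ["B"] * n_ligand,
        masses=[12.011] * len(names),
    )


def generate_toy_complex(n_beads_receptor: int, n_beads_ligand: int,
                         n_native_contacts: int, seed: int,
                         n_frames: int = 30,
                         broken_per_frame: Sequence[int] | None = None,
                         contact_distance: float = 3.0,
                         broken_distance: float = 8.0,
                         jitter: float = 0.05) -> ToyComplex:
    """Build a two-chain bead system whose native contacts break on a known
    schedule.

    Receptor beads (chain A) sit on a line 6 Å apart; ligand bead *i*
    (chain B) sits ``contact_distance`` Å above receptor bead *i* for the
    first ``n_native_contacts`` beads (a planted contact, < 3.5 Å) and far
    from every receptor bead otherwise.  By default the first third of the
    trajectory keeps every contact, then one further contact breaks per
    frame (the bead jumps to ``broken_distance`` Å) until all are gone.
    Per-frame jitter is kept far below the contact cutoff so the planted
    schedule is the exact ground truth.
    """
    if min(n_beads_receptor, n_beads_ligand, n_native_contacts) < 1:
        raise ValueError("bead and contact counts must be >= 1")
    if n_native_contacts > min(n_beads_receptor, n_beads_ligand):
        raise ValueError("more native contacts requested than bead pairs")
    top = _bead_topology(n_beads_receptor, n_beads_ligand)
    base = np.zeros((top.n_atoms, 3))
    for i in range(n_beads_receptor):
        base[i] = (6.0 * i, 0.0, 0.0)
    for j in range(n_beads_ligand):
        if j < n_native_contacts:
            base[n_beads_receptor + j] = (6.0 * j, contact_distance, 0.0)
        else:
            base[n_beads_receptor + j] = (6.0 * j, broken_distance + 4.0, 0.0)

    if broken_per_frame is None:
        intact = n_frames // 3
        sched = []
        for f in range(n_frames):
            sched.append(int(np.clip(f - intact + 1, 0, n_native_contacts)))
        broken_per_frame = sched
    broken_per_frame = np.asarray(broken_per_frame, dtype=int)
    if len(broken_per_frame) != n_frames:
        raise ValueError("broken_per_frame must have one entry per frame")
    if broken_per_frame.max() > n_native_contacts or broken_per_frame.min() < 0:
        raise ValueError("broken_per_frame entries out of range")

    rng = np.random.default_rng([seed, 0])
    frames = np.empty((n_frames, top.n_atoms, 3))
    for f in range(n_frames):
        coords = base.copy()
        for p in range(broken_per_frame[f]):
            coords[n_beads_receptor + p, 1] = broken_distance
        coords += rng.normal(0.0, jitter, size=coords.shape)
        frames[f] = coords
    traj = Trajectory(top, frames)
    native_pairs = [(i, i) for i in range(n_native_contacts)]
    expected_qb = 1.0 - broken_per_frame / n_native_contacts
    return ToyComplex(top, traj, native_pairs, broken_per_frame, expected_qb)


# ---------------------------------------------------------------------------
# Gaussian / conformer / H-bond trajectories
# ---------------------------------------------------------------------------

def _line_topology(n_atoms: int, chain: str = "A", element: str = "C") -> Topology:
    return Topology(
        atom_names=["C1"] * n_atoms,
        elements=[element] * n_atoms,
        res_ids=list(range(1, n_atoms + 1)),
        res_names=["BDS"] * n_atoms,
        chain_ids=[chain] * n_atoms,
        masses=[12.011] * n_atoms,
    )


def generate_gaussian_trajectory(n_atoms: int, covariance: np.ndarray,
                                 n_frames: int, seed: int,
                                 mean: np.ndarray | None = None) -> Trajectory:
    """Frames drawn i.i.d. from N(mean, covariance) over the 3m coordinates.

    ``covariance`` must be a symmetric positive semi-definite
    ``(3m, 3m)`` matrix (Å^2).  The default mean structure spaces the atoms
    10 Å apart on a line.
    """
    cov = np.asarray(covariance, dtype=float)
    d = 3 * n_atoms
    if cov.shape != (d, d):
        raise ValueError(f"covariance must have shape ({d}, {d})")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals, evecs = np.linalg.eigh(cov)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("covariance must be positive semi-definite")
    evals = np.clip(evals, 0.0, None)
    if mean is None:
        mean = np.zeros((n_atoms, 3))
        mean[:, 0] = 10.0 * np.arange(n_atoms)
    mean = np.asarray(mean, dtype=float).reshape(n_atoms, 3)
    rng = np.random.default_rng([seed, 0])
    z = rng.standard_normal((n_frames, d))
    samples = z @ (evecs * np.sqrt(evals)).T
    frames = mean[None] + samples.reshape(n_frames, n_atoms, 3)
    return Trajectory(_line_topology(n_atoms), frames)


def generate_conformer_trajectory(n_atoms: int, n_conformers: int,
                                  n_frames: int, seed: int,
                                  separation: float = 8.0,
                                  noise: float = 0.1,
                                  ) -> tuple[Trajectory, np.ndarray]:
    """A trajectory hopping between well-separated planted conformers.

    Conformer centers are random structures rejected until every pair is
    at least ``separation`` Å apart in best-fit RMSD terms (guaranteed here
    by construction: centers differ by large internal distortions); each
    frame is one center plus isotropic noise far below the separation.
    Returns the trajectory and the planted per-frame labels.
    """
    rng = np.random.default_rng([seed, 0])
    base = np.zeros((n_atoms, 3))
    base[:, 0] = 5.0 * np.arange(n_atoms)
    centers = []
    for c in range(n_conformers):
        conf = base.copy()
        # displace alternating atoms perpendicular to the chain, with a
        # distinct amplitude per conformer, to create internal (fit-proof)
        # differences of order `separation`
        conf[::2, 1] += separation * (c + 1)
        conf[1::2, 2] -= separation * (c + 1)
        centers.append(conf)
    labels = np.arange(n_frames) % n_conformers
    rng.shuffle(labels)
    frames = np.array([centers[l] + rng.normal(0, noise, base.shape)
                       for l in labels])
    return Trajectory(_line_topology(n_atoms), frames), labels


def generate_hbond_trajectory(formed: Sequence[bool], seed: int = 0,
                              distance_on: float = 2.9,
                              distance_off: float = 4.5,
                              angle_on: float = 180.0) -> Trajectory:
    """A donor(N-H, chain A)/acceptor(O, chain B) system whose hydrogen
    bond exists in exactly the frames flagged ``formed``.

    Formed frames use acceptor-donor distance ``distance_on`` and a linear
    acceptor-H-donor arrangement at ``angle_on`` degrees; broken frames
    place the acceptor at ``distance_off``, beyond the 3.5 Å cutoff.
    """
    top = Topology(
        atom_names=["N", "H", "O"],
        elements=["N", "H", "O"],
        res_ids=[1, 1, 1],
        res_names=["DON", "DON", "ACC"],
        chain_ids=["A", "A", "B"],
        masses=[14.007, 1.008, 15.999],
        bonds=[(0, 1)],
    )
    frames = []
    theta = np.deg2rad(180.0 - angle_on)
    for on in formed:
        d = distance_on if on else distance_off
        donor = np.array([0.0, 0.0, 0.0])
        h = np.array([1.0, 0.0, 0.0])
        # place acceptor so that the angle A-H-D equals angle_on
        acc_dir = np.array([np.cos(theta), np.sin(theta), 0.0])
        # solve for |HA| so that |DA| = d
        # donor at origin, H at (1,0,0): A = H + t*acc_dir with |A| = d
        b = 2.0 * np.dot(h, acc_dir)
        c = np.dot(h, h) - d * d
        t = (-b + np.sqrt(b * b - 4 * c)) / 2.0
        acc = h + t * acc_dir
        frames.append(np.stack([donor, h, acc]))
    return Trajectory(top, np.asarray(frames))


# ---------------------------------------------------------------------------
# random parameterised complexes and sphere clusters (energy test beds)
# ---------------------------------------------------------------------------

def generate_random_complex(n_atoms_a: int, n_atoms_b: int, seed: int,
                            box: float = 12.0, min_separation: float = 3.0,
                            ) -> tuple[Topology, np.ndarray]:
    """A random two-chain system with full force-field parameters.

    Atoms get random charges (net-neutral-ish), AMBER-magnitude LJ and GB
    radii, and pairwise-exact LCPO coefficients (P1=1, P2=-1, P3=P4=0).
    Positions are rejected until all pairs are at least ``min_separation``
    Å apart; the two chains occupy adjacent boxes so the interface carries
    genuine contacts.  Intended for conservation and invariance tests of
    the decomposition machinery.
    """
    rng = np.random.default_rng([seed, 0])
    n = n_atoms_a + n_atoms_b
    coords = np.empty((n, 3))
    placed = 0
    offset = np.zeros(3)
    while placed < n:
        if placed == n_atoms_a:
            offset = np.array([box + 0.5, 0.0, 0.0])
        cand = rng.uniform(0, box, size=3) + offset
        if placed == 0 or np.linalg.norm(coords[:placed] - cand, axis=1).min() \
                >= min_separation:
            coords[placed] = cand
            placed += 1
    elements = rng.choice(["C", "N", "O"], size=n)
    masses = [{"C": 12.011, "N": 14.007, "O": 15.999}[e] for e in elements]
    charges = rng.uniform(-0.8, 0.8, size=n)
    top = Topology(
        atom_names=[f"X{i % 9 + 1}" for i in range(n)],
        elements=list(elements),
        res_ids=list(range(1, n_atoms_a + 1)) + list(range(1, n_atoms_b + 1)),
        res_names=["RSA"] * n_atoms_a + ["RSB"] * n_atoms_b,
        chain_ids=["A"] * n_atoms_a + ["B"] * n_atoms_b,
        masses=masses,
        charges=charges,
        lj_radius=rng.uniform(1.5, 1.9, size=n),
        lj_epsilon=rng.uniform(0.05, 0.2, size=n),
        gb_radius=rng.uniform(1.2, 1.8, size=n),
        lcpo_params=np.tile([1.0, -1.0, 0.0, 0.0], (n, 1)),
    )
    return top, coords


def generate_sphere_cluster(n_atoms: int, seed: int,
                            radius_range: tuple[float, float] = (1.4, 2.0),
                            probe: float = 1.4,
                            overlap_factor: float = 0.85,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Random chain-like sphere cluster with pairwise but no triple overlap.

    Atom *m* is placed so its probe-expanded sphere overlaps atom *m-1*'s
    (at ``overlap_factor`` of the sum of expanded radii) while staying
    disjoint from every other sphere, so the pairwise-overlap surface-area
    treatment is exact.  Returns (vdW radii, coordinates).
    """
    rng = np.random.default_rng([seed, 0])
    radii = rng.uniform(*radius_range, size=n_atoms)
    expanded = radii + probe
    coords = np.zeros((n_atoms, 3))
    for m in range(1, n_atoms):
        target = overlap_factor * (expanded[m] + expanded[m - 1])
        for _attempt in range(1000):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            cand = coords[m - 1] + target * direction
            others = np.arange(m - 1)
            if others.size == 0 or np.all(
                    np.linalg.norm(coords[others] - cand, axis=1)
                    > expanded[others] + expanded[m] + 0.2):
                coords[m] = cand
                break
        else:
            raise RuntimeError("could not place sphere without triple overlap")
    return radii, coords
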