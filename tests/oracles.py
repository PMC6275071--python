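"""Independent numerical oracles the implementation is checked against.

These deliberately use different algorithms from the package: direct
quadrature for the descreening integral, Shrake–Rupley surface-point
counting for SASA, brute-force pair scans for contacts, and an
independent rotational fit for RMSD.
"""

import numpy as np


def numeric_descreen_integral(d: float, rho: float, s: float,
                              n: int = 2000) -> float:
    """(1/4π) ∫ dV/|x|⁴ over a sphere of radius s centred at distance d,
    excluding |x| < rho, by shell quadrature."""
    lo = max(rho, abs(d - s))
    total = 0.0
    if lo < d + s:
        u = np.linspace(lo + 1e-12, d + s - 1e-12, n)
        cos0 = (u * u + d * d - s * s) / (2.0 * u * d)
        shell_fraction = (1.0 - cos0) / 2.0
        total += np.trapezoid(shell_fraction / (u * u), u)
    if rho < s - d:  # exclusion ball fully inside the sphere
        u = np.linspace(rho, s - d, n)
        total += np.trapezoid(1.0 / (u * u), u)
    return float(total)


def shrake_rupley_sasa(radii, coords, probe=1.4, n_points=10_000):
    """Per-atom SASA by counting accessible points of a deterministic
    Fibonacci sphere lattice."""
    radii = np.asarray(radii, float)
    coords = np.asarray(coords, float)
    i = np.arange(n_points)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    y = 1.0 - 2.0 * i / (n_points - 1)
    r = np.sqrt(np.clip(1.0 - y * y, 0.0, None))
    theta = golden * i
    unit = np.stack([np.cos(theta) * r, y, np.sin(theta) * r], axis=1)
    expanded = radii + probe
    areas = np.empty(len(coords))
    for a in range(len(coords)):
        surface = coords[a] + expanded[a] * unit
        accessible = np.ones(n_points, dtype=bool)
        for b in range(len(coords)):
            if b == a:
                continue
            accessible &= (np.linalg.norm(surface - coords[b], axis=1)
                           >= expanded[b])
        areas[a] = 4.0 * np.pi * expanded[a] ** 2 * accessible.mean()
    return areas


def brute_force_qb(coords, residues_a, residues_b, cutoff=3.5):
    """Fraction of native residue pairs in contact, by scanning every
    heavy-atom pair; ``residues_*`` are lists of atom-index arrays."""
    pairs = []
    for idx_a in residues_a:
        for idx_b in residues_b:
            diff = coords[idx_a][:, None, :] - coords[idx_b][None, :, :]
            pairs.append(np.sqrt((diff ** 2).sum(axis=2)).min() < cutoff)
    return np.array(pairs)


def bestfit_rmsd_scipy(a, b):
    """Best-fit RMSD via scipy's independent rotational alignment."""
    from scipy.spatial.transform import Rotation
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    return float(np.sqrt(np.mean(np.sum((rot.apply(a) - b) ** 2, axis=1))))
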