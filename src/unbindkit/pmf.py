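"""Potential of mean force by thermodynamic integration along a
multi-center steering path.

The PMF over the 3n coordinates of n steered centers is a state function,
so its change between the bound and displaced states equals the line
integral of the mean constraint force along any path u(λ) connecting them:

    W(u_b) - W(u_a) = -∫ <F> · du

where <F> is the ensemble-average force the rest of the system exerts on
the clamped centers.  Forces from all centers are concatenated into a
single 3n-vector before the dot product.  The integral is discretised by
the trapezoidal rule between consecutive sampling windows; per-window
uncertainty comes from the spread of the four collection-segment means and
is propagated assuming independent windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import PMFProfile, SteeringWindow

__all__ = [
    "WindowSchedule", "MeanForceSeries",
    "build_schedule", "parse_schedule_rules",
    "estimate_mean_forces", "integrate_pmf", "compare_runs",
]

#: The graded window spacings used for the unbinding runs: fine near the
#: bound state, coarser further out.
DEFAULT_SPACING_RULES = [(0.0, 5.0, 0.1), (5.0, 13.0, 0.2), (13.0, None, 0.4)]


@dataclass
class WindowSchedule:
    """A strictly increasing displacement grid built from spacing rules."""

    rules: list[tuple[float, float, float]]
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid[0] != 0.0:
            raise ValueError("schedule must start at displacement 0")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("schedule grid must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.grid)

    @property
    def total(self) -> float:
        return float(self.grid[-1])


def parse_schedule_rules(text: str) -> list[tuple[float, float | None, float]]:
    """Parse a rule string like ``"0:5:0.1,5:13:0.2,13:end:0.4"``."""
    rules = []
    for part in text.split(","):
        start, end, spacing = part.strip().split(":")
        rules.append((float(start),
                      None if end.strip().lower() == "end" else float(end),
                      float(spacing)))
    return rules


def build_schedule(total_displacement: float,
                   rules: list[tuple[float, float | None, float]] | None = None,
                   ) -> WindowSchedule:
    """Build the displacement grid covering [0, total] from spacing rules.

    Each rule is ``(start, end, spacing)``; ``end=None`` means "to the
    total displacement".  Rules must be contiguous from 0 with positive
    spacings.  When the total is not a whole number of spacings past the
    last breakpoint, a short terminal step is appended so the grid ends
    exactly at the total.
    """
    if total_displacement <= 0:
        raise ValueError("total displacement must be > 0")
    if rules is None:
        rules = DEFAULT_SPACING_RULES
    resolved = []
    for start, end, spacing in rules:
        if spacing <= 0:
            raise ValueError("spacings must be > 0")
        resolved.append((float(start),
                         total_displacement if end is None else float(end),
                         float(spacing)))
    if resolved[0][0] != 0.0:
        raise ValueError("first rule must start at 0")
    for (s0, e0, _), (s1, _, _) in zip(resolved, resolved[1:]):
        if not np.isclose(e0, s1):
            raise ValueError(
                f"rules must be contiguous: segment ending at {e0} followed "
                f"by segment starting at {s1}")

    grid = [0.0]
    for start, end, spacing in resolved:
        if start >= total_displacement:
            break
        end = min(end, total_displacement)
        n_full = int(np.floor((end - start) / spacing + 1e-9))
        pts = start + spacing * np.arange(1, n_full + 1)
        grid.extend(pts.tolist())
        if not np.isclose(grid[-1], end):
            grid.append(end)   # short terminal step to land exactly on `end`
    grid = np.array(grid)
    # collapse numerically duplicate joints
    keep = np.concatenate([[True], np.diff(grid) > 1e-9])
    return WindowSchedule(rules=resolved, grid=np.round(grid[keep], 10))


@dataclass
class MeanForceSeries:
    """Per-window mean constraint force and its segment-based uncertainty.

    ``mean`` has shape (n_windows, n_centers, 3) in kcal/mol/Å;
    ``stderr`` the matching standard error of the mean estimated from the
    standard deviation of the four segment means divided by sqrt(4);
    ``segment_means`` has shape (n_windows, 4, n_centers, 3).
    """

    displacements: np.ndarray
    mean: np.ndarray
    stderr: np.ndarray
    segment_means: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.displacements)


def estimate_mean_forces(windows: list[SteeringWindow]) -> MeanForceSeries:
    """Average the sampled constraint forces of each window.

    The per-window mean is the average over all samples of all four
    segments; the uncertainty is sd(segment means, ddof=1)/sqrt(4), which
    absorbs sample autocorrelation on scales shorter than a segment.
    """
    if not windows:
        raise ValueError("no steering windows given")
    disps, means, errs, seg_means = [], [], [], []
    for w in windows:
        if len(w.force_samples) != 4:
            raise ValueError(
                f"window {w.lambda_index} has {len(w.force_samples)} segments; "
                "4 are required")
        sm = np.stack([seg.mean(axis=0) for seg in w.force_samples])
        disps.append(w.displacement)
        means.append(w.all_samples.mean(axis=0))
        errs.append(sm.std(axis=0, ddof=1) / np.sqrt(4.0))
        seg_means.append(sm)
    return MeanForceSeries(
        displacements=np.asarray(disps),
        mean=np.stack(means),
        stderr=np.stack(errs),
        segment_means=np.stack(seg_means),
    )


def integrate_pmf(series: MeanForceSeries,
                  center_paths: np.ndarray,
                  schedule: WindowSchedule | None = None) -> PMFProfile:
    """Line-integrate minus the mean force along the recorded center path.

    ``center_paths`` holds the recorded steered-center positions per
    window, shape (n_windows, n_centers, 3); the path increments du are
    taken from these recorded positions (concatenated to 3n-vectors), not
    re-idealised.  W(0) = 0 by convention; pulling against an attractive
    well therefore yields an increasing profile.

    The trapezoidal weights make each window's mean force enter the
    cumulative integral with coefficient (Δu_before + Δu_after)/2, and the
    reported sigma is the corresponding quadrature sum of the per-window
    standard errors, treating windows as independent.
    """
    path = np.asarray(center_paths, dtype=float)
    n = series.n_windows
    if path.shape[0] != n:
        raise ValueError(
            f"mean-force series has {n} windows but path has {path.shape[0]}")
    if schedule is not None and schedule.n_windows != n:
        raise ValueError(
            f"schedule has {schedule.n_windows} windows but series has {n}")
    flat_path = path.reshape(n, -1)
    forces = series.mean.reshape(n, -1)
    errs = series.stderr.reshape(n, -1)
    du = np.diff(flat_path, axis=0)                       # (n-1, 3n)
    steps = -0.5 * np.einsum("ij,ij->i", forces[:-1] + forces[1:], du)
    pmf = np.concatenate([[0.0], np.cumsum(steps)])

    # coefficient of window i's force in PMF_j, accumulated in quadrature
    var = np.zeros(n)
    coeff = np.zeros_like(flat_path)                      # running coefficient per window
    for j in range(1, n):
        coeff[j - 1] += 0.5 * du[j - 1]
        coeff[j] += 0.5 * du[j - 1]
        var[j] = np.sum((coeff[:j + 1] ** 2) * (errs[:j + 1] ** 2))
    displacements = (schedule.grid if schedule is not None
                     else series.displacements)
    return PMFProfile(displacements=displacements, pmf=pmf,
                      sigma=np.sqrt(var))


def compare_runs(profiles: list[PMFProfile], tolerance: float = 1.0) -> dict:
    """Convergence report for repeated PMF reconstructions on one grid.

    Profiles are re-anchored at 0, then the maximum absolute pairwise
    deviation and per-point z-scores (deviation over pooled sigma) are
    reported; the run set is flagged convergent when the maximum absolute
    deviation is within ``tolerance`` kcal/mol.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    grid = profiles[0].displacements
    for p in profiles[1:]:
        if len(p.displacements) != len(grid) or not np.allclose(
                p.displacements, grid):
            raise ValueError("profiles are not on identical grids")
    pmfs = np.stack([p.pmf - p.pmf[0] for p in profiles])
    sigmas = np.stack([p.sigma for p in profiles])
    max_dev = 0.0
    max_z = 0.0
    z_scores = np.zeros(len(grid))
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            dev = np.abs(pmfs[i] - pmfs[j])
            pooled = np.sqrt(sigmas[i] ** 2 + sigmas[j] ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(dev == 0.0, 0.0, dev / pooled)
            max_dev = max(max_dev, float(dev.max()))
            max_z = max(max_z, float(np.nanmax(z)) if np.any(np.isfinite(z)) else 0.0)
            z_scores = np.maximum(z_scores, np.nan_to_num(z, posinf=np.inf))
    return {
        "max_abs_deviation": max_dev,
        "max_z": max_z,
        "z_scores": z_scores,
        "convergent": bool(max_dev <= tolerance),
        "tolerance": tolerance,
        "n_profiles": len(profiles),
    }
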