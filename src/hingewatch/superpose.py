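"""Rigid-body superposition and mobility statistics.

Least-squares (Kabsch) fitting removes global translation and rotation
before any deviation or fluctuation is measured: per-frame RMSD traces
relative to a reference conformation, per-atom RMSF profiles about the mean
structure, and threshold-based detection of contiguous high-mobility
residue regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, TrajectoryError
from .structio import AtomIndexSet, GeometrySeries, Trajectory, frames_in_window

__all__ = [
    "SuperpositionResult",
    "MobilityProfile",
    "kabsch",
    "apply_fit",
    "rmsd_series",
    "rmsf_profile",
    "detect_mobile_regions",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation and the post-fit RMSD (Å).

    The fitted coordinates of the mobile set are ``mobile @ rotation.T +
    translation``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Solves for the proper rotation (determinant +1; a reflection is never
    returned) and translation minimizing the (optionally weighted) RMSD.
    Requires at least 3 non-collinear points; collinear or coincident point
    sets leave the rotation underdetermined and raise :class:`GeometryError`.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError(f"point sets must share shape (N, 3); got {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise GeometryError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
    w_norm = w / w.sum()
    cm = w_norm @ mobile
    cr = w_norm @ reference
    x = mobile - cm
    y = reference - cr
    cov = (x * w_norm[:, None]).T @ y
    u, s, vt = np.linalg.svd(cov)
    # collinearity check: a well-posed fit needs rank >= 2 in the centered sets
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-9:
        raise GeometryError("degenerate (collinear or coincident) point set; rotation underdetermined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    fitted = x @ rotation.T
    rmsd = float(np.sqrt(np.sum(w_norm * np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def apply_fit(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Fit ``frame`` to ``reference`` on ``fit_indices`` and transform all atoms."""
    res = kabsch(frame[fit_indices], reference[fit_indices], weights)
    return res.transform(frame)


def rmsd_series(
    traj: Trajectory,
    fit_set: AtomIndexSet,
    measure_set: AtomIndexSet | None = None,
    reference: int | np.ndarray = 0,
) -> GeometrySeries:
    """Per-frame RMSD to a reference after fitting each frame on ``fit_set``.

    ``measure_set`` defaults to ``fit_set``; restricting it to one domain
    while fitting on another isolates inter-domain motion (per-domain RMSD
    traces).  ``reference`` is a frame index or an explicit (N, 3) array.
    """
    fit_set.validate(traj.structure)
    if measure_set is None:
        measure_set = fit_set
    measure_set.validate(traj.structure)
    ref = traj.frames[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise TrajectoryError(f"reference must be (N, 3) over all {traj.n_atoms} atoms")
    m_idx = measure_set.indices
    values = np.empty(traj.n_frames)
    for i, frame in enumerate(traj.frames):
        fitted = apply_fit(frame, ref, fit_set.indices)
        diff = fitted[m_idx] - ref[m_idx]
        values[i] = np.sqrt(np.mean(np.sum(diff**2, axis=1)))
    return GeometrySeries(traj.times.copy(), values, kind="rmsd", label=measure_set.label)


@dataclass
class MobilityProfile:
    """Per-atom RMSF (Å) over a time window, with optional detected regions."""

    per_atom_rmsf: np.ndarray
    residue_indices: np.ndarray
    chain_ids: np.ndarray
    window: tuple[float, float]
    regions: list = field(default_factory=list)

    def __post_init__(self):
        self.per_atom_rmsf = np.asarray(self.per_atom_rmsf, dtype=float)
        if np.any(self.per_atom_rmsf < 0):
            raise ValueError("RMSF values must be non-negative")


def aligned_window_frames(
    traj: Trajectory,
    atom_set: AtomIndexSet,
    window: tuple[float, float] | None = None,
    closed: bool = True,
    n_iter: int = 2,
) -> np.ndarray:
    """Window frames restricted to ``atom_set`` and rigid-fitted.

    With ``n_iter == 0`` every frame is fitted to the first frame of the
    window.  With ``n_iter >= 1`` the fit reference is refined iteratively to
    the evolving mean structure (fit → recompute mean → refit), the usual
    procedure for fluctuations measured about mean positions.
    """
    atom_set.validate(traj.structure)
    if window is None:
        mask = np.ones(traj.n_frames, dtype=bool)
        window = (float(traj.times[0]), float(traj.times[-1]))
    else:
        mask = frames_in_window(traj.times, window[0], window[1], closed=closed)
    sub = traj.frames[mask][:, atom_set.indices, :]
    if sub.shape[0] < 1:
        raise TrajectoryError("window contains no frames")
    ref = sub[0]
    aligned = np.stack([kabsch(f, ref).transform(f) for f in sub])
    for _ in range(n_iter):
        ref = aligned.mean(axis=0)
        aligned = np.stack([kabsch(f, ref).transform(f) for f in aligned])
    return aligned


def rmsf_profile(
    traj: Trajectory,
    atom_set: AtomIndexSet,
    window: tuple[float, float] | None = None,
    closed: bool = True,
    n_iter: int = 2,
) -> MobilityProfile:
    """Root-mean-square fluctuation of each selected atom about its mean position.

    ``RMSF_i = sqrt(<|x_i - <x_i>|^2>)`` over the window frames after
    iterative mean-structure alignment (``n_iter`` refinement passes; 0 means
    plain alignment to the window's first frame, which matches the alignment
    used for covariance analysis).
    """
    aligned = aligned_window_frames(traj, atom_set, window, closed=closed, n_iter=n_iter)
    if aligned.shape[0] < 2:
        raise TrajectoryError("RMSF needs at least 2 frames in the window")
    mean = aligned.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    if window is None:
        window = (float(traj.times[0]), float(traj.times[-1]))
    res_idx = traj.structure.annotation("residue_index").astype(int)[atom_set.indices]
    chains = traj.structure.annotation("chain_id")[atom_set.indices]
    return MobilityProfile(rmsf, res_idx, chains, window)


def detect_mobile_regions(
    profile: MobilityProfile,
    threshold: float | None = None,
    gap_merge: int = 2,
    label_prefix: str = "region",
) -> list[tuple[int, int, str]]:
    """Contiguous residue runs whose RMSF exceeds a threshold.

    The default threshold is mean + 1 SD of the profile (there is no
    universal criterion for "high mobility"; the rule is configurable).
    Runs on the same chain separated by fewer than ``gap_merge`` residues
    are merged.  Returns sorted ``(start_residue, end_residue, label)``
    tuples and stores them on the profile.
    """
    rmsf = profile.per_atom_rmsf
    if rmsf.size == 0:
        return []
    if threshold is None:
        threshold = float(rmsf.mean() + rmsf.std())
    regions: list[tuple[int, int, str]] = []
    for chain in np.unique(profile.chain_ids):
        sel = profile.chain_ids == chain
        resids = profile.residue_indices[sel]
        order = np.argsort(resids, kind="stable")
        resids = resids[order]
        above = rmsf[sel][order] > threshold
        hot = np.unique(resids[above])
        if hot.size == 0:
            continue
        runs = []
        start = prev = int(hot[0])
        for r in hot[1:]:
            r = int(r)
            if r - prev < max(gap_merge, 1) + 1:
                prev = r
            else:
                runs.append((start, prev))
                start = prev = r
        runs.append((start, prev))
        for lo, hi in runs:
            regions.append((lo, hi, chain))
    regions.sort()
    labeled = [
        (lo, hi, f"{label_prefix}-{i + 1} (chain {chain})")
        for i, (lo, hi, chain) in enumerate(regions)
    ]
    profile.regions = labeled
    return labeled
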