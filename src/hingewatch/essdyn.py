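"""Essential dynamics: PCA of the Cartesian covariance of a trajectory.

Frames (restricted to an analysis atom set, typically the Cα atoms) are
rigid-fitted to the first frame of the analysis window to remove overall
translation and rotation, the 3n x 3n covariance ``C_ij = <(x_i - <x_i>)
(x_j - <x_j>)>`` is accumulated over the window, and its eigendecomposition
``Λ = Rᵀ C R`` yields principal components in decreasing order of
eigenvalue.  Each eigenvector is a collective displacement direction; its
eigenvalue is the variance (Å²) of the motion along it.

Covariance normalisation is 1/F (population, the time average as written)
by default; ``ddof=1`` switches to the sample convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .errors import ModeError, TrajectoryError
from .nmd import write_nmd
from .structio import (
    AtomIndexSet,
    GeometrySeries,
    Structure,
    Trajectory,
    frames_in_window,
)
from .superpose import kabsch

__all__ = [
    "PCResult",
    "CovarianceResult",
    "covariance_matrix",
    "pca",
    "essential_dynamics",
    "variance_spectrum",
    "project",
    "extreme_conformations",
    "porcupine_field",
    "export_porcupine",
]


@dataclass
class CovarianceResult:
    """Aligned-frame covariance matrix with its mean and alignment reference."""

    matrix: np.ndarray
    mean_coords: np.ndarray
    reference_coords: np.ndarray | None  # None when frames were not aligned
    n_frames: int
    window: tuple[float, float]


@dataclass
class PCResult:
    """Eigen-decomposition of a trajectory covariance matrix.

    ``eigenvalues`` are descending and in Å²; ``eigenvectors`` columns are
    unit collective-motion directions on the analysis atom set.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean_coords: np.ndarray
    reference_coords: np.ndarray | None = None
    atom_indices: np.ndarray | None = None
    n_frames_used: int = 0
    window: tuple[float, float] | None = None

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def component(self, i: int) -> np.ndarray:
        """Component i (0-based) as an (n, 3) unit displacement field."""
        if not 0 <= i < self.n_components:
            raise ModeError(f"component {i} out of range [0, {self.n_components})")
        return self.eigenvectors[:, i].reshape(-1, 3)


def _window_frames(
    traj: Trajectory,
    atom_set: AtomIndexSet,
    window: tuple[float, float] | None,
    closed: bool,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    atom_set.validate(traj.structure)
    if window is None:
        mask = np.ones(traj.n_frames, dtype=bool)
        window = (float(traj.times[0]), float(traj.times[-1]))
    else:
        mask = frames_in_window(traj.times, window[0], window[1], closed=closed)
    frames = traj.frames[mask][:, atom_set.indices, :]
    return frames, traj.times[mask], window


def _align_to_reference(frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    return np.stack([kabsch(f, reference).transform(f) for f in frames])


def covariance_matrix(
    traj: Trajectory,
    atom_set: AtomIndexSet,
    window: tuple[float, float] | None = None,
    closed: bool = True,
    align: bool = True,
    ddof: int = 0,
) -> CovarianceResult:
    """Cartesian covariance of the selected atoms over a time window.

    With ``align=True`` (default) every frame is first rigid-fitted to the
    window's initial conformation so that overall translation/rotation does
    not contaminate the internal-motion covariance.
    """
    frames, _, window = _window_frames(traj, atom_set, window, closed)
    f = frames.shape[0]
    if f < 2:
        raise TrajectoryError("covariance needs at least 2 frames in the window")
    reference = frames[0].copy() if align else None
    if align:
        frames = _align_to_reference(frames, reference)
    flat = frames.reshape(f, -1)
    mean = flat.mean(axis=0)
    dev = flat - mean
    denom = f - ddof
    c = dev.T @ dev / denom
    return CovarianceResult(
        matrix=c,
        mean_coords=mean.reshape(-1, 3),
        reference_coords=reference,
        n_frames=f,
        window=window,
    )


def pca(cov: CovarianceResult | np.ndarray, mean_coords: np.ndarray | None = None) -> PCResult:
    """Eigendecompose a covariance matrix into principal components.

    Accepts either a :class:`CovarianceResult` or a raw symmetric matrix.
    Eigenvalues come out in decreasing order; small negative values (numerical
    noise on a PSD matrix) are clamped to zero, genuinely negative spectra
    are rejected.
    """
    if isinstance(cov, CovarianceResult):
        c = cov.matrix
        mean_coords = cov.mean_coords
        reference = cov.reference_coords
        n_frames = cov.n_frames
        window = cov.window
    else:
        c = np.asarray(cov, dtype=float)
        reference = None
        n_frames = 0
        window = None
        if mean_coords is None:
            mean_coords = np.zeros((c.shape[0] // 3, 3))
    scale = np.abs(c).max() or 1.0
    if np.abs(c - c.T).max() / scale > 1e-8:
        raise ModeError("covariance matrix is not symmetric")
    eigenvalues, eigenvectors = eigh((c + c.T) / 2.0)
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    eigenvectors = eigenvectors[:, order]
    if eigenvalues.size and eigenvalues[-1] < -1e-8 * max(scale, 1.0):
        raise ModeError(f"covariance has a significantly negative eigenvalue {eigenvalues[-1]:.3e}")
    eigenvalues = np.clip(eigenvalues, 0.0, None)
    # sign convention: largest-|.| component positive
    idx = np.argmax(np.abs(eigenvectors), axis=0)
    signs = np.sign(eigenvectors[idx, np.arange(eigenvectors.shape[1])])
    signs[signs == 0] = 1.0
    return PCResult(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors * signs,
        mean_coords=np.asarray(mean_coords, dtype=float),
        reference_coords=reference,
        n_frames_used=n_frames,
        window=window,
    )


def essential_dynamics(
    traj: Trajectory,
    atom_set: AtomIndexSet,
    window: tuple[float, float] | None = None,
    closed: bool = True,
    align: bool = True,
    ddof: int = 0,
) -> PCResult:
    """Covariance + PCA in one step; records the analysis atom indices."""
    cov = covariance_matrix(traj, atom_set, window=window, closed=closed, align=align, ddof=ddof)
    result = pca(cov)
    result.atom_indices = atom_set.indices.copy()
    return result


def variance_spectrum(pc: PCResult, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Leading eigenvalues and cumulative explained-variance percentages.

    ``cumulative[k-1] = 100 * Σ_{i<=k} λ_i / Σ_all λ_i``.
    """
    if n_components > pc.n_components:
        raise ModeError(f"requested {n_components} components of {pc.n_components}")
    total = pc.eigenvalues.sum()
    if total <= 0:
        raise ModeError("total variance is zero; no motion to decompose")
    leading = pc.eigenvalues[:n_components]
    cumulative = 100.0 * np.cumsum(leading) / total
    return leading, cumulative


def _aligned_deviations(traj: Trajectory, pc: PCResult, atom_set: AtomIndexSet | None) -> np.ndarray:
    if atom_set is None:
        if pc.atom_indices is None:
            raise ModeError("PCResult carries no atom indices; pass atom_set explicitly")
        atom_set = AtomIndexSet(pc.atom_indices)
    atom_set.validate(traj.structure)
    frames = traj.frames[:, atom_set.indices, :]
    if pc.reference_coords is not None:
        frames = _align_to_reference(frames, pc.reference_coords)
    return frames.reshape(frames.shape[0], -1) - pc.mean_coords.ravel()


def project(
    traj: Trajectory,
    pc: PCResult,
    component: int,
    atom_set: AtomIndexSet | None = None,
) -> GeometrySeries:
    """Per-frame scalar projection ``p(t) = (x(t) - mean) · d_component`` (Å).

    Frames are aligned to the PCA's reference conformation before
    projection, mirroring the covariance alignment.
    """
    if not 0 <= component < pc.n_components:
        raise ModeError(f"component {component} out of range [0, {pc.n_components})")
    dev = _aligned_deviations(traj, pc, atom_set)
    values = dev @ pc.eigenvectors[:, component]
    return GeometrySeries(traj.times.copy(), values, kind="projection", label=f"PC{component + 1}")


def extreme_conformations(
    traj: Trajectory,
    pc: PCResult,
    component: int,
    atom_set: AtomIndexSet | None = None,
) -> tuple[Structure, Structure, int, int]:
    """The actual trajectory frames attaining minimum and maximum projection.

    Returns ``(min_structure, max_structure, min_index, max_index)`` built
    from the full (all-atom) frames — real conformations, not synthetic
    extrapolations along the component.
    """
    series = project(traj, pc, component, atom_set)
    i_min = int(np.argmin(series.values))
    i_max = int(np.argmax(series.values))
    s_min = traj.structure.with_coords(traj.frames[i_min])
    s_max = traj.structure.with_coords(traj.frames[i_max])
    return s_min, s_max, i_min, i_max


def porcupine_field(pc: PCResult, component: int, scale: float = 1.0) -> np.ndarray:
    """Per-atom arrow field ``scale * sqrt(λ) * d_atom`` (Å), anchored at the mean.

    Arrow lengths are proportional to each atom's share of the component's
    root-variance, the standard porcupine representation.
    """
    if not 0 <= component < pc.n_components:
        raise ModeError(f"component {component} out of range [0, {pc.n_components})")
    return scale * np.sqrt(pc.eigenvalues[component]) * pc.component(component)


def export_porcupine(
    pc: PCResult,
    components: list[int],
    path,
    title: str = "principal components",
    structure: Structure | None = None,
) -> None:
    """Write selected components as an NMD porcupine file (mean-anchored)."""
    modes = [
        (c + 1, float(np.sqrt(pc.eigenvalues[c])), pc.component(c))
        for c in components
    ]
    write_nmd(path, title, pc.mean_coords, modes, structure=structure)
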