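"""Normal-mode analysis stage.

The second-derivative (Hessian) matrix of the potential is modelled by an
anisotropic elastic network: every atom pair within a cutoff distance is
joined by a harmonic spring of uniform force constant, giving the 3x3
superelements ``-k r̂ r̂ᵀ`` off the diagonal and minus their row sums on it.
The pipeline downstream of the Hessian is the standard one: mass weighting
``M^{-1/2} H M^{-1/2}``, full eigendecomposition ``Λ = Rᵀ H' R`` with
eigenvalues in ascending order, frequencies ``ν_i = sqrt(λ_i) / 2π``,
removal of the six zero-frequency rigid-body (trivial) modes, and two
generators that turn a mode into coordinates: a harmonic oscillation
trajectory for visualisation, and a thermally weighted conformational
ensemble (amplitudes drawn per mode with classical-equipartition variance
``k_B T / λ_i``).

Externally computed Hessians (e.g. from a force-field minimisation) can be
imported from a dense text matrix and fed through the same pipeline.

Units: the elastic-network force constant is kJ mol⁻¹ Å⁻² (default 1),
masses are amu, lengths Å.  Mass-weighted eigenvalues are then
kJ mol⁻¹ amu⁻¹ Å⁻², for which the wavenumber conversion is
``ν̃ [cm⁻¹] = sqrt(λ) * 1e13 / (2π c)`` with c in cm/s (CODATA constants;
the prefactor works out to ≈53.088 cm⁻¹ per sqrt(eigenvalue unit)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.constants as const
from scipy.linalg import eigh
from scipy.spatial import cKDTree

from .errors import ModeError, ParseError
from .structio import (
    AtomIndexSet,
    Structure,
    Trajectory,
    read_matrix,
    substructure,
    write_matrix,
)

__all__ = [
    "KB_KJ_PER_MOL_K",
    "WAVENUMBER_FACTOR",
    "HessianModel",
    "ModeSet",
    "build_enm_hessian",
    "mass_weight",
    "eigendecompose",
    "frequencies",
    "split_trivial",
    "rigid_body_basis",
    "harmonic_trajectory",
    "thermal_ensemble",
    "import_hessian",
    "export_hessian",
]

#: Boltzmann constant in kJ mol⁻¹ K⁻¹ (gas constant / 1000).
KB_KJ_PER_MOL_K = const.R / 1000.0

#: sqrt(kJ mol⁻¹ amu⁻¹ Å⁻²) expressed as an angular frequency is 1e13 rad/s
#: exactly in CODATA units (1 kJ/mol per amu·Å² = 1e26 s⁻²); dividing by
#: 2π c (c in cm/s) converts to wavenumbers.
WAVENUMBER_FACTOR = 1.0e13 / (2.0 * np.pi * const.c * 100.0)


@dataclass
class HessianModel:
    """A 3N x 3N symmetric Hessian bound to reference coordinates.

    ``origin`` records whether the matrix came from the built-in elastic
    network (``"enm"``) or was imported.  ``mass_weighted`` flags whether
    the ``M^{-1/2} H M^{-1/2}`` transform has been applied.
    """

    matrix: np.ndarray
    origin: str
    reference_coords: np.ndarray
    masses: np.ndarray
    cutoff: float | None = None
    force_constant: float | None = None
    mass_weighted: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = self.reference_coords.shape[0]
        if self.matrix.shape != (3 * n, 3 * n):
            raise ModeError(f"Hessian shape {self.matrix.shape} != (3N, 3N) with N={n}")
        _check_symmetric(self.matrix)

    @property
    def n_atoms(self) -> int:
        return self.reference_coords.shape[0]


def _check_symmetric(m: np.ndarray, rtol: float = 1e-8) -> None:
    scale = np.abs(m).max()
    if scale == 0:
        return
    asym = np.abs(m - m.T).max() / scale
    if asym > rtol:
        raise ModeError(f"matrix is not symmetric (relative asymmetry {asym:.2e})")


@dataclass
class ModeSet:
    """Eigenvalues (ascending), unit eigenvector columns and metadata.

    ``eigenvectors[:, i]`` is the i-th mode (0-based; the field convention
    of counting modes NM1, NM2, ... is 1-based, so NM7 is column 6).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    reference_coords: np.ndarray
    masses: np.ndarray
    mass_weighted: bool = True
    n_trivial: int = 6
    index_offset: int = 0  # first column's position in the full spectrum
    rigid_body_overlap: np.ndarray | None = None

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Native-unit frequencies ν_i = sqrt(max(λ_i, 0)) / 2π."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None)) / (2.0 * np.pi)

    def cartesian_mode(self, i: int, normalize: bool = True) -> np.ndarray:
        """Mode i as an (N, 3) Cartesian displacement field.

        Mass-weighted eigenvectors are de-weighted by ``M^{-1/2}`` so the
        returned field is a real-space direction; by default renormalized to
        unit Euclidean norm.
        """
        v = self.eigenvectors[:, i].copy()
        if self.mass_weighted:
            v = v / np.sqrt(np.repeat(self.masses, 3))
        if normalize:
            v = v / np.linalg.norm(v)
        return v.reshape(-1, 3)


def build_enm_hessian(
    structure: Structure,
    atom_set: AtomIndexSet | None = None,
    cutoff: float = 13.0,
    k: float = 1.0,
) -> HessianModel:
    """Anisotropic elastic-network Hessian on the selected atoms.

    Every pair within ``cutoff`` Å contributes the off-diagonal 3x3
    superelement ``-k r̂ r̂ᵀ`` (r̂ the unit inter-atom vector); diagonal
    blocks are the negated sums of each row's off-diagonal blocks, which
    makes uniform translations exact zero modes by construction.  Atoms with
    no neighbour within the cutoff produce spurious zero modes and are
    reported with a warning.
    """
    if cutoff <= 0 or k <= 0:
        raise ModeError("cutoff and force constant must be positive")
    if atom_set is None:
        coords = structure.coords
        masses = structure.masses
    else:
        atom_set.validate(structure)
        coords = structure.coords[atom_set.indices]
        masses = structure.masses[atom_set.indices]
    n = coords.shape[0]
    if n < 2:
        raise ModeError("elastic network needs at least 2 atoms")
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    h = np.zeros((3 * n, 3 * n))
    degree = np.zeros(n, dtype=int)
    for i, j in pairs:
        rij = coords[j] - coords[i]
        dist2 = rij @ rij
        if dist2 == 0.0:
            continue  # coincident atoms carry no direction
        block = -k * np.outer(rij, rij) / dist2
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[sl_i, sl_j] += block
        h[sl_j, sl_i] += block
        h[sl_i, sl_i] -= block
        h[sl_j, sl_j] -= block
        degree[i] += 1
        degree[j] += 1
    isolated = np.nonzero(degree == 0)[0]
    if isolated.size:
        warnings.warn(
            f"{isolated.size} atom(s) have no neighbour within {cutoff} Å "
            f"(indices {isolated.tolist()[:10]}...); expect spurious zero modes",
            stacklevel=2,
        )
    return HessianModel(
        matrix=h,
        origin="enm",
        reference_coords=coords,
        masses=masses,
        cutoff=cutoff,
        force_constant=k,
    )


def mass_weight(h: HessianModel, masses: np.ndarray | None = None) -> HessianModel:
    """Apply the ``M^{-1/2} H M^{-1/2}`` transform (element-wise ``/sqrt(m_i m_j)``)."""
    if h.mass_weighted:
        raise ModeError("Hessian is already mass-weighted")
    m = h.masses if masses is None else np.asarray(masses, dtype=float)
    if m.shape != (h.n_atoms,):
        raise ModeError(f"need {h.n_atoms} masses, got {m.shape}")
    if np.any(m <= 0):
        raise ModeError("masses must be positive")
    inv_sqrt = 1.0 / np.sqrt(np.repeat(m, 3))
    weighted = h.matrix * np.outer(inv_sqrt, inv_sqrt)
    return replace(h, matrix=weighted, masses=m, mass_weighted=True)


def _normalize_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|.| component is positive."""
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def eigendecompose(h: HessianModel) -> ModeSet:
    """Full symmetric eigendecomposition, eigenvalues ascending.

    Eigenvector signs are normalized (largest-magnitude component positive)
    since the solver's signs are arbitrary.
    """
    _check_symmetric(h.matrix)
    eigenvalues, eigenvectors = eigh((h.matrix + h.matrix.T) / 2.0)
    eigenvectors = _normalize_signs(eigenvectors)
    return ModeSet(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        reference_coords=h.reference_coords,
        masses=h.masses,
        mass_weighted=h.mass_weighted,
    )


def frequencies(ms: ModeSet, unit: str = "native") -> np.ndarray:
    """Per-mode frequencies.

    ``native``: ν_i = sqrt(λ_i)/(2π) in the eigenvalue's own units.
    ``cm-1``: wavenumbers, valid when force constants are kJ mol⁻¹ Å⁻² and
    masses amu (see module docstring for the conversion factor).

    Small negative eigenvalues (within -1e-6 of the spectrum's maximum) are
    clamped to zero; larger ones indicate an ill-formed Hessian and raise.
    """
    lam = ms.eigenvalues.copy()
    lam_max = np.abs(lam).max() if lam.size else 0.0
    if lam_max > 0 and lam.min() < -1e-6 * lam_max:
        raise ModeError(
            f"significantly negative eigenvalue {lam.min():.3e}; the Hessian "
            "does not describe a minimum"
        )
    lam = np.clip(lam, 0.0, None)
    nu = np.sqrt(lam) / (2.0 * np.pi)
    if unit == "native":
        return nu
    if unit == "cm-1":
        if not ms.mass_weighted:
            raise ModeError("wavenumber conversion requires a mass-weighted mode set")
        return np.sqrt(lam) * WAVENUMBER_FACTOR
    raise ModeError(f"unknown frequency unit {unit!r}")


def rigid_body_basis(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal 3N x 6 basis of rigid translations and rotations.

    Built from the reference coordinates (rotations about the centre); when
    ``masses`` is given, the basis is orthonormal in mass-weighted
    coordinates, matching mass-weighted eigenvectors.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    w = np.ones(n) if masses is None else np.asarray(masses, dtype=float)
    center = (w[:, None] * coords).sum(axis=0) / w.sum()
    rel = coords - center
    basis = np.zeros((3 * n, 6))
    for a in range(3):
        basis[a::3, a] = 1.0  # translations
    axes = np.eye(3)
    for a in range(3):
        rot = np.cross(np.broadcast_to(axes[a], (n, 3)), rel)
        basis[:, 3 + a] = rot.ravel()
    if masses is not None:
        basis *= np.sqrt(np.repeat(w, 3))[:, None]
    q, _ = np.linalg.qr(basis)
    return q


def split_trivial(ms: ModeSet, n_trivial: int = 6) -> tuple[ModeSet, ModeSet]:
    """Split off the lowest-frequency (trivial) modes.

    For a connected structure the six lowest modes are the rigid-body
    translations/rotations with eigenvalues numerically zero.  Rather than
    trusting the count silently, the removed modes' projection onto the
    exactly constructed rigid-body basis is reported on the trivial set as
    ``rigid_body_overlap`` (per-mode, 1.0 = pure rigid motion).
    """
    if ms.n_modes < n_trivial:
        raise ModeError(f"mode set has {ms.n_modes} modes; cannot remove {n_trivial}")
    basis = rigid_body_basis(ms.reference_coords, ms.masses if ms.mass_weighted else None)
    removed = ms.eigenvectors[:, :n_trivial]
    overlap = np.linalg.norm(basis.T @ removed, axis=0)
    trivial = ModeSet(
        eigenvalues=ms.eigenvalues[:n_trivial],
        eigenvectors=removed,
        reference_coords=ms.reference_coords,
        masses=ms.masses,
        mass_weighted=ms.mass_weighted,
        n_trivial=n_trivial,
        index_offset=0,
        rigid_body_overlap=overlap,
    )
    nontrivial = ModeSet(
        eigenvalues=ms.eigenvalues[n_trivial:],
        eigenvectors=ms.eigenvectors[:, n_trivial:],
        reference_coords=ms.reference_coords,
        masses=ms.masses,
        mass_weighted=ms.mass_weighted,
        n_trivial=n_trivial,
        index_offset=n_trivial,
    )
    return trivial, nontrivial


def harmonic_trajectory(
    structure: Structure,
    atom_set: AtomIndexSet | None,
    ms: ModeSet,
    mode_index: int,
    amplitude: float,
    n_frames: int = 41,
    frame_dt: float = 1.0,
) -> Trajectory:
    """One full period of harmonic oscillation along a mode.

    Frames are ``x_ref + amplitude * sin(2π j / n_frames) * d`` for
    j = 0..n_frames-1, with ``d`` the unit Cartesian displacement of the
    mode.  Zero amplitude gives a static trajectory.
    """
    if n_frames < 1:
        raise ModeError("n_frames must be >= 1")
    sub = structure if atom_set is None else substructure(structure, atom_set)
    if ms.reference_coords.shape[0] != sub.n_atoms:
        raise ModeError("mode set and atom selection disagree on atom count")
    d = ms.cartesian_mode(mode_index)
    phases = np.sin(2.0 * np.pi * np.arange(n_frames) / n_frames)
    frames = ms.reference_coords[None] + amplitude * phases[:, None, None] * d[None]
    times = frame_dt * np.arange(n_frames)
    return Trajectory(sub.with_coords(ms.reference_coords), times, frames)


def thermal_ensemble(
    structure: Structure,
    atom_set: AtomIndexSet | None,
    ms: ModeSet,
    temperature: float = 300.0,
    n_conf: int = 5000,
    seed: int | np.random.Generator = 0,
    mode_indices: np.ndarray | None = None,
) -> Trajectory:
    """Conformational ensemble sampled from a set of non-trivial modes.

    Each conformation is ``x_ref + M^{-1/2} Σ_i c_i q_i`` with amplitudes
    drawn independently per mode, ``c_i ~ N(0, k_B T / λ_i)`` (classical
    equipartition in mass-weighted coordinates).  Requires strictly positive
    eigenvalues: trivial modes have λ = 0 and diverge, so passing them is an
    error — split them off first.  Reproducible for a fixed seed.
    """
    if temperature < 0:
        raise ModeError("temperature must be >= 0")
    sub = structure if atom_set is None else substructure(structure, atom_set)
    if ms.reference_coords.shape[0] != sub.n_atoms:
        raise ModeError("mode set and atom selection disagree on atom count")
    if not ms.mass_weighted:
        raise ModeError("thermal ensemble requires a mass-weighted mode set")
    cols = np.arange(ms.n_modes) if mode_indices is None else np.asarray(mode_indices, dtype=int)
    lam = ms.eigenvalues[cols]
    lam_max = np.abs(ms.eigenvalues).max()
    if np.any(lam <= 1e-8 * lam_max):
        raise ModeError(
            "ensemble includes (near-)zero eigenvalue modes; trivial rigid-body "
            "modes must be removed first"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    std = np.sqrt(KB_KJ_PER_MOL_K * temperature / lam)
    c = rng.normal(0.0, 1.0, size=(n_conf, cols.size)) * std
    q = ms.eigenvectors[:, cols]  # (3n, k), mass-weighted
    disp_mw = c @ q.T  # (n_conf, 3n)
    disp = disp_mw / np.sqrt(np.repeat(ms.masses, 3))[None, :]
    frames = ms.reference_coords[None] + disp.reshape(n_conf, -1, 3)
    times = np.arange(n_conf, dtype=float)
    return Trajectory(sub.with_coords(ms.reference_coords), times, frames)


def import_hessian(
    path,
    structure: Structure,
    atom_set: AtomIndexSet | None = None,
    mass_weighted: bool = False,
    asymmetry_tol: float = 1e-6,
) -> HessianModel:
    """Load an externally computed dense Hessian and bind it to a structure.

    The matrix is symmetrized as ``(H + Hᵀ)/2``; asymmetry beyond
    ``asymmetry_tol`` (relative) is an error, smaller asymmetry warns.
    """
    m = read_matrix(path)
    if atom_set is None:
        coords = structure.coords
        masses = structure.masses
    else:
        atom_set.validate(structure)
        coords = structure.coords[atom_set.indices]
        masses = structure.masses[atom_set.indices]
    n = coords.shape[0]
    if m.shape != (3 * n, 3 * n):
        raise ParseError(f"Hessian is {m.shape}, expected ({3 * n}, {3 * n}) for N={n} atoms")
    scale = np.abs(m).max() or 1.0
    asym = np.abs(m - m.T).max() / scale
    if asym > asymmetry_tol:
        raise ParseError(f"imported Hessian asymmetry {asym:.2e} exceeds tolerance {asymmetry_tol:.0e}")
    if asym > 0:
        warnings.warn(f"imported Hessian symmetrized (relative asymmetry {asym:.2e})", stacklevel=2)
    return HessianModel(
        matrix=(m + m.T) / 2.0,
        origin="imported",
        reference_coords=coords,
        masses=masses,
        mass_weighted=mass_weighted,
    )


def export_hessian(h: HessianModel, path) -> None:
    """Write the Hessian as dense text, re-importable by :func:`import_hessian`."""
    write_matrix(h.matrix, path)
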