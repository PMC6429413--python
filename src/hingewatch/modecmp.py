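"""Cross-system mode comparison by eigenvector inner products.

Two systems that differ in bound ligands have Hessians (and hence modes) of
different dimension, so their mode vectors cannot be compared directly.
The comparison protocol regenerates each normal mode as a thermal
conformational ensemble, reduces every conformation to an atom set the
systems share (e.g. the Cα, C, O, N main-chain atoms), and recovers the
mode on that common set as the first principal component of the reduced
ensemble.  For a single-mode ensemble only the first eigenvalue is
significant; λ₂/λ₁ is reported as a purity diagnostic for leakage through
the reduction.  Recovered modes are compared as |inner product| in [0, 1]:
1 means identical collective motion, 0 orthogonal (the eigenvector sign is
arbitrary, hence the absolute value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ModeError
from .essdyn import essential_dynamics
from .nma import ModeSet, thermal_ensemble
from .structio import AtomIndexSet, Structure, select_atoms

__all__ = [
    "RecoveredMode",
    "ComparisonMatrix",
    "inner_product",
    "comparison_matrix",
    "mode_via_ensemble",
]


@dataclass
class RecoveredMode:
    """A mode recovered on a common atom set, with its purity diagnostic."""

    vector: np.ndarray  # (3m,) unit vector on the common atom set
    label: str
    purity: float  # λ₂/λ₁ of the reduced-ensemble PCA
    atom_indices: np.ndarray | None = None


def inner_product(a: np.ndarray, b: np.ndarray) -> float:
    """|a·b| of two (defensively renormalized) equal-dimension vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ModeError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ModeError("cannot compare a zero vector")
    return float(abs(a @ b) / (na * nb))


@dataclass
class ComparisonMatrix:
    """All-pairs |inner product| matrix between two labelled mode lists."""

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ModeError("inner products must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)


def _as_vector(m) -> np.ndarray:
    return m.vector if isinstance(m, RecoveredMode) else np.asarray(m, dtype=float).ravel()


def _label(m, i: int, prefix: str) -> str:
    if isinstance(m, RecoveredMode) and m.label:
        return m.label
    return f"{prefix}{i + 1}"


def comparison_matrix(
    modes_a: list,
    modes_b: list,
    row_prefix: str = "A:mode",
    col_prefix: str = "B:mode",
) -> ComparisonMatrix:
    """Pairwise |inner product| matrix (rows: A's modes, columns: B's).

    All vectors must live on the same common atom set.  Comparing a set
    with itself gives 1.0 on the diagonal.
    """
    vecs_a = [_as_vector(m) for m in modes_a]
    vecs_b = [_as_vector(m) for m in modes_b]
    values = np.array([[inner_product(va, vb) for vb in vecs_b] for va in vecs_a])
    return ComparisonMatrix(
        values=np.clip(values, 0.0, 1.0),
        row_labels=[_label(m, i, row_prefix) for i, m in enumerate(modes_a)],
        col_labels=[_label(m, i, col_prefix) for i, m in enumerate(modes_b)],
    )


def mode_via_ensemble(
    structure: Structure,
    ms: ModeSet,
    mode_index: int,
    common_selector: str = "name CA C O N",
    temperature: float = 300.0,
    n_conf: int = 5000,
    seed: int = 0,
    ensemble_atom_set: AtomIndexSet | None = None,
    label: str = "",
    purity_warn: float = 0.05,
) -> RecoveredMode:
    """Recover one non-trivial mode on a common atom set via the ensemble route.

    Steps: (1) sample ``n_conf`` conformations at ``temperature`` along the
    single mode ``mode_index`` (0-based into ``ms``, which must already have
    trivial modes removed); (2) restrict every conformation to the atoms
    matched by ``common_selector``; (3) PCA of the reduced ensemble; PC1 is
    the recovered mode.  Warns when λ₂/λ₁ exceeds ``purity_warn`` (mode
    leakage through the reduction).
    """
    traj = thermal_ensemble(
        structure,
        ensemble_atom_set,
        ms,
        temperature=temperature,
        n_conf=n_conf,
        seed=seed,
        mode_indices=np.array([mode_index]),
    )
    common = select_atoms(traj.structure, common_selector)
    pc = essential_dynamics(traj, common, align=True)
    lam = pc.eigenvalues
    purity = float(lam[1] / lam[0]) if lam.size > 1 and lam[0] > 0 else 0.0
    if purity > purity_warn:
        warnings.warn(
            f"mode recovery purity λ2/λ1 = {purity:.3g} > {purity_warn}: "
            "the reduction leaks variance into higher components",
            stacklevel=2,
        )
    return RecoveredMode(
        vector=pc.eigenvectors[:, 0].copy(),
        label=label or f"mode{mode_index + ms.index_offset + 1}",
        purity=purity,
        atom_indices=common.indices.copy(),
    )
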