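"""Active-site closure and near-attack-conformation (NAC) geometry scans.

For a phosphoryl-transfer active site formed between two protein domains,
three per-frame observables are tracked along a trajectory:

* a closure distance between one marker atom in each domain (e.g. the
  ATP-coordinating Mg²⁺ in the nucleotide-binding domain and the Nε2 of the
  triose-anchoring histidine in the kinase domain) — its shortening signals
  active-site closure;
* the distance from a nucleophile hydroxyl oxygen to the γ-phosphorus;
* the O···P–O angle at the phosphorus vertex between the nucleophile
  oxygen and the leaving (bridging) oxygen of the scissile P–O bond — 180°
  is a perfect in-line attack.

A frame is a near-attack conformation when the distance is strictly below
``d_cut`` (default 3.5 Å) and the angle strictly above ``a_cut`` (default
155°).  Passing frames within ~3.3 Å (the P+O van der Waals contact sum)
are additionally annotated as van der Waals contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, SelectionError, TrajectoryError
from .structio import GeometrySeries, Structure, Trajectory, select_atoms

__all__ = [
    "VDW_CONTACT_OP",
    "SiteDefinition",
    "NacRecord",
    "NacCensus",
    "define_site",
    "closure_series",
    "op_distance_series",
    "opo_angle_series",
    "nac_filter",
    "nac_scatter",
]

#: van der Waals contact distance for P (1.9 Å) + O (1.4 Å), Å.
VDW_CONTACT_OP = 3.3


@dataclass(frozen=True)
class SiteDefinition:
    """Atom indices defining one active site's geometry observables."""

    label: str
    closure_pair: tuple[int, int]
    nucleophile_oxygens: dict  # {"O1": index, "O3": index, ...}
    gamma_phosphorus: int
    leaving_oxygen: int

    def __post_init__(self):
        indices = [*self.closure_pair, *self.nucleophile_oxygens.values(),
                   self.gamma_phosphorus, self.leaving_oxygen]
        if len(set(indices)) != len(indices):
            raise SelectionError(f"site {self.label!r}: atom indices must be distinct")

    def validate(self, structure: Structure) -> None:
        n = structure.n_atoms
        for i in [*self.closure_pair, *self.nucleophile_oxygens.values(),
                  self.gamma_phosphorus, self.leaving_oxygen]:
            if not 0 <= i < n:
                raise SelectionError(f"site {self.label!r}: atom index {i} out of range")


def _single(structure: Structure, selector: str, what: str, label: str) -> int:
    sel = select_atoms(structure, selector)
    if len(sel) != 1:
        raise SelectionError(
            f"site {label!r}: selector for {what} ({selector!r}) matched {len(sel)} atoms, need exactly 1"
        )
    return int(sel.indices[0])


def define_site(
    structure: Structure,
    label: str,
    closure_a: str,
    closure_b: str,
    gamma_phosphorus: str,
    leaving_oxygen: str,
    nucleophile_oxygens: dict | None = None,
) -> SiteDefinition:
    """Build a :class:`SiteDefinition` from single-atom selection expressions.

    Example for an hTKFC-like system (Mg2 marker in the L domain, His221
    Nε2 in the K domain, ATP γ-phosphorus/bridging oxygen, DHA hydroxyls):

    >>> define_site(s, "L2-K1",
    ...             closure_a="chain B and resname MG and name MG",
    ...             closure_b="chain A and resid 221 and name NE2",
    ...             gamma_phosphorus="chain B and name PG",
    ...             leaving_oxygen="chain B and name O3B",
    ...             nucleophile_oxygens={"O1": "chain A and resname DHA and name O1",
    ...                                  "O3": "chain A and resname DHA and name O3"})
    """
    nucleophile_oxygens = nucleophile_oxygens or {}
    return SiteDefinition(
        label=label,
        closure_pair=(
            _single(structure, closure_a, "closure atom A", label),
            _single(structure, closure_b, "closure atom B", label),
        ),
        nucleophile_oxygens={
            name: _single(structure, sel, f"nucleophile oxygen {name}", label)
            for name, sel in nucleophile_oxygens.items()
        },
        gamma_phosphorus=_single(structure, gamma_phosphorus, "gamma phosphorus", label),
        leaving_oxygen=_single(structure, leaving_oxygen, "leaving oxygen", label),
    )


def _pair_distances(traj: Trajectory, i: int, j: int) -> np.ndarray:
    d = traj.frames[:, i, :] - traj.frames[:, j, :]
    return np.linalg.norm(d, axis=1)


def closure_series(traj: Trajectory, site: SiteDefinition) -> GeometrySeries:
    """Per-frame distance between the site's two closure marker atoms (Å)."""
    site.validate(traj.structure)
    a, b = site.closure_pair
    values = _pair_distances(traj, a, b)
    return GeometrySeries(traj.times.copy(), values, kind="distance", label=f"{site.label} closure")


def op_distance_series(traj: Trajectory, site: SiteDefinition, oxygen_label: str) -> GeometrySeries:
    """Per-frame nucleophile-O···P distance (Å) for one labelled oxygen.

    Chemically equivalent hydroxyl oxygens are tracked separately, one
    series per label.  A zero distance (coincident atoms) is nonphysical
    and raises.
    """
    site.validate(traj.structure)
    if oxygen_label not in site.nucleophile_oxygens:
        raise SelectionError(
            f"site {site.label!r} has no nucleophile oxygen {oxygen_label!r} "
            f"(known: {sorted(site.nucleophile_oxygens)})"
        )
    o = site.nucleophile_oxygens[oxygen_label]
    values = _pair_distances(traj, o, site.gamma_phosphorus)
    if np.any(values == 0.0):
        raise GeometryError(
            f"site {site.label!r}: oxygen {oxygen_label} coincides with the "
            "phosphorus in at least one frame (nonphysical)"
        )
    return GeometrySeries(traj.times.copy(), values, kind="distance", label=f"{site.label} {oxygen_label}...P")


def opo_angle_series(traj: Trajectory, site: SiteDefinition, oxygen_label: str) -> GeometrySeries:
    """Per-frame O···P–O angle (degrees) at the phosphorus vertex.

    The angle is between the vectors P→O_nucleophile and P→O_leaving;
    180° means the nucleophile attacks exactly opposite the leaving oxygen
    (perfect in-line geometry).
    """
    site.validate(traj.structure)
    if oxygen_label not in site.nucleophile_oxygens:
        raise SelectionError(f"site {site.label!r} has no nucleophile oxygen {oxygen_label!r}")
    o = site.nucleophile_oxygens[oxygen_label]
    p = site.gamma_phosphorus
    lo = site.leaving_oxygen
    v1 = traj.frames[:, o, :] - traj.frames[:, p, :]
    v2 = traj.frames[:, lo, :] - traj.frames[:, p, :]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise GeometryError(f"site {site.label!r}: zero-length P–O vector in at least one frame")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    values = np.degrees(np.arccos(cosang))
    return GeometrySeries(traj.times.copy(), values, kind="angle", label=f"{site.label} {oxygen_label}...P-O")


@dataclass(frozen=True)
class NacRecord:
    """One frame's attack geometry and its pass/fail status."""

    frame_time: float
    oxygen_label: str
    distance: float
    angle: float
    passes: bool
    vdw_contact: bool = False

    def __post_init__(self):
        if not self.distance > 0:
            raise GeometryError("NAC distance must be positive")
        if not 0.0 <= self.angle <= 180.0:
            raise GeometryError("NAC angle must be within [0, 180] degrees")


@dataclass
class NacCensus:
    """NAC filter output: per-frame records plus summary statistics."""

    records: list
    d_cut: float
    a_cut: float
    n_pass: int = field(init=False)
    time_fraction: float = field(init=False)
    min_distance: float = field(init=False)
    max_angle: float = field(init=False)

    def __post_init__(self):
        n = len(self.records)
        passing = [r for r in self.records if r.passes]
        self.n_pass = len(passing)
        self.time_fraction = self.n_pass / n if n else 0.0
        self.min_distance = min((r.distance for r in self.records), default=float("nan"))
        self.max_angle = max((r.angle for r in self.records), default=float("nan"))

    @property
    def passing(self) -> list:
        return [r for r in self.records if r.passes]


def nac_filter(
    distances: GeometrySeries,
    angles: GeometrySeries,
    d_cut: float = 3.5,
    a_cut: float = 155.0,
    oxygen_label: str = "",
) -> NacCensus:
    """Joint census of near-attack conformations.

    A frame passes when ``distance < d_cut`` AND ``angle > a_cut`` — both
    inequalities strict, so a frame exactly at a threshold fails.  The two
    series must share an identical frame-time grid.
    """
    if len(distances) != len(angles) or not np.array_equal(distances.times, angles.times):
        raise TrajectoryError("distance and angle series are not on the same frame-time grid")
    label = oxygen_label or distances.label
    records = [
        NacRecord(
            frame_time=float(t),
            oxygen_label=label,
            distance=float(d),
            angle=float(a),
            passes=bool((d < d_cut) and (a > a_cut)),
            vdw_contact=bool((d < d_cut) and (a > a_cut) and (d <= VDW_CONTACT_OP)),
        )
        for t, d, a in zip(distances.times, distances.values, angles.values)
    ]
    return NacCensus(records=records, d_cut=d_cut, a_cut=a_cut)


def nac_scatter(census: NacCensus | list) -> pd.DataFrame:
    """(time, distance, angle, passes, vdw_contact) table for scatter plots.

    The passing subset is separable by the boolean column; an empty passing
    subset is a valid (empty-selection) outcome, not an error.
    """
    records = census.records if isinstance(census, NacCensus) else list(census)
    return pd.DataFrame(
        {
            "time_ps": [r.frame_time for r in records],
            "oxygen": [r.oxygen_label for r in records],
            "distance_A": [r.distance for r in records],
            "angle_deg": [r.angle for r in records],
            "passes": [r.passes for r in records],
            "vdw_contact": [r.vdw_contact for r in records],
        }
    )
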