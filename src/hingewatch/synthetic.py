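"""Synthetic two-domain dimer structures and trajectories.

This module generates study-shaped inputs for every analysis stage without
any download: an elongated homodimer of two subunits, each split into a
kinase-like (K) and a nucleotide-binding (L) domain, arranged L2-K1-K2-L1
along the long axis, with one active site at each L/K interface.  Each site
carries the minimal marker geometry the closure and near-attack analyses
need: a divalent-metal marker (MG) and a triose-anchoring histidine Nε2 on
opposite domains ≈14 Å apart (closure pair), a γ-phosphorus with its
bridging (leaving) oxygen, and two chemically equivalent nucleophile
hydroxyl oxygens.

Trajectories superimpose a few planted collective displacement fields —
linearized hinge-bend, twist and wobble rotations of the terminal L
domains — with Gaussian amplitudes of chosen variance, plus isotropic
Gaussian jitter, so the output covariance converges to a known planted
spectrum and PCA can be validated against ground truth.  Because the
rotations are linearized into fixed displacement fields, the planted motion
is exactly rank-k; the price is that large amplitudes are not physical
rotations (a warning is raised outside the linear regime).

Near-attack episodes are planted by steering a nucleophile oxygen along the
in-line direction of its site during chosen time windows; outside episodes
the attack geometry stays far (>10 Å).  Everything is deterministic given
the spec's seed (bit-identical output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, TrajectoryError
from .nma import rigid_body_basis
from .nacscan import SiteDefinition
from .structio import Atom, AtomIndexSet, Structure, Trajectory, element_mass, select_atoms

__all__ = [
    "PlantedMode",
    "NacEpisode",
    "SyntheticSpec",
    "default_planted_variances",
    "make_toy_dimer",
    "make_hinge_trajectory",
    "plant_nac_episode",
    "site_definitions",
]

#: effective volume per residue used to size the pseudo-globular domains, Å³
_VOLUME_PER_RESIDUE = 125.0


@dataclass(frozen=True)
class PlantedMode:
    """One planted collective motion: a named rotation field and its variance (Å²)."""

    kind: str  # {"hinge", "twist", "wobble"}
    variance: float

    def __post_init__(self):
        if self.kind not in ("hinge", "twist", "wobble"):
            raise ConfigError(f"unknown planted mode kind {self.kind!r}")
        if not self.variance > 0:
            raise ConfigError("planted variance must be positive")


@dataclass(frozen=True)
class NacEpisode:
    """A time window in which one nucleophile oxygen approaches its phosphorus.

    ``n_pass`` (optional) plants an exact census: a centered contiguous
    block of exactly ``n_pass`` frames whose geometry strictly satisfies
    distance < 3.5 Å and angle > 155°, reaching ``min_distance`` and
    ``max_angle`` at the block centre.  Without ``n_pass`` the approach is a
    smooth squared-sine bump and the passing count is emergent.
    """

    start_ps: float
    end_ps: float
    oxygen: str = "O3"
    min_distance: float = 3.16
    max_angle: float = 178.45
    n_pass: int | None = None
    edge_distance: float = 3.49  # just-passing geometry at the block edges
    edge_angle: float = 155.5

    def __post_init__(self):
        if not self.end_ps > self.start_ps:
            raise ConfigError("episode end must be after start")
        if not 0 < self.min_distance:
            raise ConfigError("min_distance must be positive")
        if not 0.0 < self.max_angle <= 180.0:
            raise ConfigError("max_angle must be within (0, 180]")
        if self.n_pass is not None:
            if self.n_pass < 1:
                raise ConfigError("n_pass must be >= 1 when given")
            if self.min_distance > self.edge_distance or self.max_angle < self.edge_angle:
                raise ConfigError(
                    "an exact-census episode needs min_distance <= edge_distance "
                    "and max_angle >= edge_angle"
                )


def default_planted_variances(
    n_atoms: int,
    noise_sigma: float,
    target_fraction: float = 0.68,
    split: tuple[float, float, float] = (0.60, 0.25, 0.15),
) -> tuple[float, float, float]:
    """Planted variances making the top-3 PCs carry ``target_fraction`` of variance.

    With k orthonormal planted fields of total variance V on n atoms plus
    isotropic jitter of σ per coordinate, the covariance spectrum is
    ``v_i + σ²`` along the planted directions and σ² elsewhere, so the top-3
    cumulative fraction is ``(V + 3σ²) / (V + 3nσ²)``.  Solving for V:
    ``V = 3σ²(f·n − 1)/(1 − f)``.
    """
    if not 0 < target_fraction < 1:
        raise ConfigError("target_fraction must be in (0, 1)")
    v_total = 3.0 * noise_sigma**2 * (target_fraction * n_atoms - 1.0) / (1.0 - target_fraction)
    if v_total <= 0:
        raise ConfigError("target fraction unreachable at this noise level / size")
    return tuple(v_total * s for s in split)


def _modes_for(n_ca: int, noise_sigma: float) -> list[PlantedMode]:
    # condition: the first 3 principal components explain 68% of the variance
    v = default_planted_variances(n_ca, noise_sigma)
    return [
        PlantedMode("hinge", v[0]),
        PlantedMode("twist", v[1]),
        PlantedMode("wobble", v[2]),
    ]


def _default_episodes() -> list[NacEpisode]:
    # near-attack phenomenology of the kinase-substrate system: transient
    # O1 approaches that never reach in-line angles, and one O3 window with
    # 395 genuinely passing snapshots reaching 3.16 Å / 178.45 deg
    return [
        NacEpisode(91_000.0, 92_000.0, oxygen="O1", min_distance=3.2, max_angle=120.0),
        NacEpisode(111_000.0, 115_000.0, oxygen="O1", min_distance=3.2, max_angle=120.0),
        NacEpisode(130_000.0, 160_000.0, oxygen="O1", min_distance=3.2, max_angle=120.0),
        NacEpisode(105_000.0, 112_000.0, oxygen="O3", min_distance=3.16, max_angle=178.45, n_pass=395),
    ]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic dimer and its trajectories.

    Defaults reproduce the shape of the studied systems: 575 residues per
    subunit (1150 Cα in the dimer; 4600 main-chain atoms with
    ``backbone=True``), three planted collective motions whose variances put
    68% of the trajectory variance in the first three principal components
    at the default jitter of 0.1 Å per coordinate, 1-ps frame spacing and a
    120-ns trajectory.
    """

    n_res_per_subunit: int = 575
    n_subunits: int = 2
    # residues 1..k_domain_end form the K domain; None keeps the reference
    # proportion (340 of 575) at any chain length
    k_domain_end: int | None = None
    # triose-anchoring histidine (K domain); None keeps the reference
    # position (221 of 575)
    his_resid: int | None = None
    # Å between adjacent domain centres; None sets 0.75 (R_K + R_L) so that
    # neighbouring domains overlap enough for an elastic network to connect
    # them at any size (≈30 Å at the reference 575-residue chain length)
    domain_spacing: float | None = None
    backbone: bool = False  # CA-only by default; True adds N, C, O per residue
    # None: hinge/twist/wobble variances solving the 68% top-3 condition at
    # this system's Cα count and noise level
    planted_modes: list | None = None
    noise_sigma: float = 0.1  # Å per coordinate
    n_frames: int = 120_001
    frame_dt: float = 1.0  # ps
    nac_episodes: list = field(default_factory=_default_episodes)
    seed: int = 2019

    def __post_init__(self):
        if self.n_subunits != 2:
            raise ConfigError("the dimer generator supports exactly 2 subunits")
        if self.k_domain_end is None:
            self.k_domain_end = max(1, round(self.n_res_per_subunit * 340 / 575))
        if self.his_resid is None:
            self.his_resid = min(max(1, round(self.n_res_per_subunit * 221 / 575)),
                                 self.k_domain_end)
        if self.domain_spacing is None:
            r_k = _domain_radius(self.k_domain_end)
            r_l = _domain_radius(self.n_res_per_subunit - self.k_domain_end)
            self.domain_spacing = 0.75 * (r_k + r_l)
        if self.planted_modes is None:
            self.planted_modes = _modes_for(
                self.n_subunits * self.n_res_per_subunit, self.noise_sigma
            )
        if not 1 <= self.k_domain_end < self.n_res_per_subunit:
            raise ConfigError("k_domain_end must split the chain into two non-empty domains")
        if not 1 <= self.his_resid <= self.k_domain_end:
            raise ConfigError("the anchored histidine must lie in the K domain")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.n_frames < 1 or self.frame_dt <= 0:
            raise ConfigError("need n_frames >= 1 and frame_dt > 0")


def _domain_radius(n_res: int) -> float:
    return (3.0 * n_res * _VOLUME_PER_RESIDUE / (4.0 * np.pi)) ** (1.0 / 3.0)


def _sphere_points(rng: np.random.Generator, n: int, center: np.ndarray, radius: float) -> np.ndarray:
    # uniform in the ball: direction x radius * u^(1/3)
    vec = rng.normal(size=(n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    r = radius * rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)
    return center + vec * r[:, None]


def _domain_layout(spec: SyntheticSpec) -> dict:
    """Domain centres along x for the L2-K1-K2-L1 arrangement."""
    s = spec.domain_spacing
    return {
        ("B", "L"): np.array([-1.5 * s, 0.0, 0.0]),
        ("A", "K"): np.array([-0.5 * s, 0.0, 0.0]),
        ("B", "K"): np.array([+0.5 * s, 0.0, 0.0]),
        ("A", "L"): np.array([+1.5 * s, 0.0, 0.0]),
    }


_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.30]),
    "C": np.array([1.20, 0.60, -0.30]),
    "O": np.array([1.90, 1.40, -0.50]),
}

_MASS = {sym: element_mass(sym) for sym in ("C", "N", "O", "P", "MG")}


def _site_marker_coords(spec: SyntheticSpec, site: str) -> dict:
    """Marker positions for one active site (baseline, open conformation)."""
    s = spec.domain_spacing
    if site == "L2-K1":
        iface = np.array([-1.0 * s, 0.0, 0.0])
        u = np.array([-1.0, 0.0, 0.0])  # toward the L side
    elif site == "K2-L1":
        iface = np.array([+1.0 * s, 0.0, 0.0])
        u = np.array([+1.0, 0.0, 0.0])
    else:
        raise ConfigError(f"unknown site {site!r}")
    y = np.array([0.0, 1.0, 0.0])
    return {
        "MG": iface + 7.0 * u + 2.5 * y,
        "PG": iface + 5.5 * u,
        "O3B": iface + 5.5 * u + 1.6 * y,
        "NE2": iface - 7.0 * u,
        "O1": iface - 8.0 * u + 0.8 * y,
        "O3": iface - 8.0 * u - 0.8 * y,
    }


def make_toy_dimer(spec: SyntheticSpec | None = None) -> Structure:
    """Deterministic pseudo-globular dimer with per-site marker atoms.

    Each domain is a uniform-density cloud of Cα positions (plus fixed-offset
    N, C, O atoms when ``spec.backbone``); the K-domain histidine receives an
    extra Nε2 atom at its site interface, and each site gets MG / γ-P /
    bridging-O / two hydroxyl-O marker atoms with the closure pair ≈14 Å
    apart in the open state.  The same seed always yields identical
    coordinates.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    layout = _domain_layout(spec)
    n_k = spec.k_domain_end
    n_l = spec.n_res_per_subunit - n_k
    # draw in fixed chain order so output is seed-stable
    ca: dict = {}
    for chain in ("A", "B"):
        ca[(chain, "K")] = _sphere_points(rng, n_k, layout[(chain, "K")], _domain_radius(n_k))
        ca[(chain, "L")] = _sphere_points(rng, n_l, layout[(chain, "L")], _domain_radius(n_l))
    his_site = {"A": "L2-K1", "B": "K2-L1"}  # chain whose His/triose serves each site
    atoms: list[Atom] = []
    for chain in ("A", "B"):
        markers = _site_marker_coords(spec, his_site[chain])
        coords = np.vstack([ca[(chain, "K")], ca[(chain, "L")]])
        for res in range(1, spec.n_res_per_subunit + 1):
            pos = coords[res - 1]
            resname = "HIS" if res == spec.his_resid else "ALA"
            if spec.backbone:
                atoms.append(Atom("N", "N", res, resname, chain, pos + _BACKBONE_OFFSETS["N"], _MASS["N"]))
            atoms.append(Atom("CA", "C", res, resname, chain, pos, _MASS["C"]))
            if res == spec.his_resid:
                atoms.append(Atom("NE2", "N", res, "HIS", chain, markers["NE2"], _MASS["N"]))
            if spec.backbone:
                atoms.append(Atom("C", "C", res, resname, chain, pos + _BACKBONE_OFFSETS["C"], _MASS["C"]))
                atoms.append(Atom("O", "O", res, resname, chain, pos + _BACKBONE_OFFSETS["O"], _MASS["O"]))
    # hetero markers: DHA oxygens live with the His chain; MG/ATP with the L
    # domain of the *other* site served by this chain's L domain
    l_site = {"A": "K2-L1", "B": "L2-K1"}  # site whose nucleotide this chain's L domain binds
    for chain in ("A", "B"):
        dha = _site_marker_coords(spec, his_site[chain])
        atoms.append(Atom("O1", "O", 601, "DHA", chain, dha["O1"], _MASS["O"]))
        atoms.append(Atom("O3", "O", 601, "DHA", chain, dha["O3"], _MASS["O"]))
        atp = _site_marker_coords(spec, l_site[chain])
        atoms.append(Atom("MG", "MG", 602, "MG", chain, atp["MG"], _MASS["MG"]))
        atoms.append(Atom("PG", "P", 603, "ATP", chain, atp["PG"], _MASS["P"]))
        atoms.append(Atom("O3B", "O", 603, "ATP", chain, atp["O3B"], _MASS["O"]))
    return Structure(atoms)


def site_definitions(structure: Structure) -> list[SiteDefinition]:
    """The two active sites of a generated dimer, as nacscan site definitions."""

    def idx(selector: str) -> int:
        sel = select_atoms(structure, selector)
        if len(sel) != 1:
            raise ConfigError(f"marker selector {selector!r} matched {len(sel)} atoms")
        return int(sel.indices[0])

    sites = []
    for label, his_chain, atp_chain in (("L2-K1", "A", "B"), ("K2-L1", "B", "A")):
        sites.append(
            SiteDefinition(
                label=label,
                closure_pair=(
                    idx(f"chain {atp_chain} and resname MG and name MG"),
                    idx(f"chain {his_chain} and name NE2"),
                ),
                nucleophile_oxygens={
                    "O1": idx(f"chain {his_chain} and resname DHA and name O1"),
                    "O3": idx(f"chain {his_chain} and resname DHA and name O3"),
                },
                gamma_phosphorus=idx(f"chain {atp_chain} and name PG"),
                leaving_oxygen=idx(f"chain {atp_chain} and name O3B"),
            )
        )
    return sites


def _rotation_field(coords: np.ndarray, mask: np.ndarray, axis: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    field = np.zeros_like(coords)
    field[mask] = np.cross(np.broadcast_to(axis, (mask.sum(), 3)), coords[mask] - pivot)
    return field


def _planted_fields(structure: Structure, spec: SyntheticSpec, ca: AtomIndexSet) -> np.ndarray:
    """Orthonormal planted displacement fields on the Cα atoms, (k, n_ca, 3).

    Hinge, twist and wobble are linearized rigid rotations of the terminal L
    domains (mirrored between subunits) about axes at the L/K interface or
    domain centre.  The raw fields are projected out of the rigid-body
    subspace of the Cα reference (so rigid-fitting in downstream analyses
    leaves them intact) and Gram-Schmidt orthonormalized.
    """
    coords = structure.coords[ca.indices]
    resid = structure.annotation("residue_index").astype(int)[ca.indices]
    chain = structure.annotation("chain_id")[ca.indices]
    layout = _domain_layout(spec)
    s = spec.domain_spacing
    x, y, z = np.eye(3)
    raw = []
    for mode in spec.planted_modes:
        field = np.zeros_like(coords)
        for ch, sign in (("A", 1.0), ("B", -1.0)):
            mask = (chain == ch) & (resid > spec.k_domain_end)
            center = layout[(ch, "L")]
            iface = center - sign * 0.5 * s * x  # L/K interface of this subunit
            if mode.kind == "hinge":
                field += _rotation_field(coords, mask, sign * y, iface)
            elif mode.kind == "twist":
                field += _rotation_field(coords, mask, sign * z, iface)
            else:  # wobble
                field += _rotation_field(coords, mask, sign * x, center)
        raw.append(field.ravel())
    basis = rigid_body_basis(coords)
    ortho = []
    for v in raw:
        v = v - basis @ (basis.T @ v)
        for u in ortho:
            v = v - u * (u @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ConfigError("planted mode fields are linearly dependent")
        ortho.append(v / norm)
    return np.stack([v.reshape(-1, 3) for v in ortho])


def make_hinge_trajectory(
    structure: Structure,
    spec: SyntheticSpec | None = None,
    n_frames: int | None = None,
    frame_dt: float | None = None,
) -> Trajectory:
    """Trajectory with planted collective modes plus isotropic jitter.

    Frame t is ``x_ref + Σ_i a_i(t) d_i + noise`` with ``a_i ~ N(0, √v_i)``
    and orthonormal fields ``d_i`` supported on the Cα atoms; the jitter
    (σ = ``spec.noise_sigma`` per coordinate) covers all protein atoms but
    not the site marker/ligand atoms, whose geometry is controlled
    separately by :func:`plant_nac_episode`.  The output covariance over the
    Cα set converges to the planted spectrum ``{v_i + σ²} ∪ {σ²}``.
    """
    spec = spec or SyntheticSpec()
    n_frames = spec.n_frames if n_frames is None else n_frames
    frame_dt = spec.frame_dt if frame_dt is None else frame_dt
    rng = np.random.default_rng(spec.seed + 1)
    ca = select_atoms(structure, "name CA")
    fields = _planted_fields(structure, spec, ca)  # (k, n_ca, 3)
    variances = np.array([m.variance for m in spec.planted_modes])
    # linear-regime guard: 3-sigma planted displacement should stay well
    # below the domain spacing, else the linearized rotation is unphysical
    max_disp = 3.0 * np.sqrt(variances).max() * np.abs(fields).max()
    if max_disp > 0.5 * spec.domain_spacing:
        warnings.warn(
            f"planted amplitude (3-sigma ≈ {max_disp:.1f} Å) exceeds the linear "
            "regime of the rotation fields",
            stacklevel=2,
        )
    protein = select_atoms(structure, "resid 1:600")  # everything but hetero markers
    ref = structure.coords
    amplitudes = rng.normal(size=(n_frames, len(variances))) * np.sqrt(variances)
    frames = np.broadcast_to(ref, (n_frames, *ref.shape)).copy()
    planted = np.einsum("fk,knc->fnc", amplitudes, fields)
    frames[:, ca.indices, :] += planted
    if spec.noise_sigma > 0:
        frames[:, protein.indices, :] += rng.normal(
            scale=spec.noise_sigma, size=(n_frames, len(protein), 3)
        )
    times = frame_dt * np.arange(n_frames)
    return Trajectory(structure, times, frames)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(u @ trial) > 0.9:
        trial = np.array([0.0, 0.0, 1.0])
    v = trial - u * (u @ trial)
    return v / np.linalg.norm(v)


def _episode_profile(episode: NacEpisode, times: np.ndarray, d0: float, a0: float):
    """Per-frame (distance, angle, active) profile of one episode."""
    mask = (times >= episode.start_ps) & (times < episode.end_ps)
    n = int(mask.sum())
    if n == 0:
        raise TrajectoryError(
            f"episode [{episode.start_ps}, {episode.end_ps}) ps contains no trajectory frames"
        )
    d = np.full(n, d0)
    a = np.full(n, a0)
    active = np.zeros(n, dtype=bool)
    if episode.n_pass is not None:
        if episode.n_pass > n:
            raise TrajectoryError(f"episode holds {n} frames, cannot plant {episode.n_pass} passing ones")
        start = (n - episode.n_pass) // 2
        block = np.arange(episode.n_pass)
        peak = episode.n_pass // 2
        denom = max(peak, episode.n_pass - 1 - peak, 1)
        s = 1.0 - np.abs(block - peak) / denom
        d[start : start + episode.n_pass] = episode.edge_distance - (episode.edge_distance - episode.min_distance) * s
        a[start : start + episode.n_pass] = episode.edge_angle + (episode.max_angle - episode.edge_angle) * s
        active[start : start + episode.n_pass] = True
    else:
        u = np.linspace(0.0, 1.0, n)
        bump = np.sin(np.pi * u) ** 2
        d[:] = d0 + (episode.min_distance - d0) * bump
        a[:] = a0 + (episode.max_angle - a0) * bump
        active[:] = True
    return mask, d, a, active


def plant_nac_episode(
    traj: Trajectory,
    site: SiteDefinition,
    episodes: list[NacEpisode] | NacEpisode,
) -> Trajectory:
    """Return a trajectory whose site geometry follows the planted episodes.

    During each episode the chosen nucleophile oxygen is placed at the
    prescribed distance from the γ-phosphorus along a direction making the
    prescribed O···P–O angle with the leaving oxygen; outside episodes the
    baseline (far, open) geometry is untouched.  Episodes moving the same
    oxygen must not overlap in time.
    """
    if isinstance(episodes, NacEpisode):
        episodes = [episodes]
    site.validate(traj.structure)
    by_oxygen: dict = {}
    for ep in episodes:
        by_oxygen.setdefault(ep.oxygen, []).append(ep)
    for oxygen, eps in by_oxygen.items():
        if oxygen not in site.nucleophile_oxygens:
            raise TrajectoryError(f"site {site.label!r} has no nucleophile oxygen {oxygen!r}")
        eps_sorted = sorted(eps, key=lambda e: e.start_ps)
        for prev, nxt in zip(eps_sorted, eps_sorted[1:]):
            if nxt.start_ps < prev.end_ps:
                raise TrajectoryError(
                    f"episodes for oxygen {oxygen} overlap at {nxt.start_ps} ps"
                )
    frames = traj.frames.copy()
    p_idx = site.gamma_phosphorus
    lo_idx = site.leaving_oxygen
    for ep in episodes:
        o_idx = site.nucleophile_oxygens[ep.oxygen]
        ref_p = traj.frames[0, p_idx]
        ref_lo = traj.frames[0, lo_idx]
        ref_o = traj.frames[0, o_idx]
        u = ref_lo - ref_p
        u = u / np.linalg.norm(u)
        v = _perpendicular(u)
        d0 = float(np.linalg.norm(ref_o - ref_p))
        a0 = float(np.degrees(np.arccos(np.clip((ref_o - ref_p) @ u / d0, -1.0, 1.0))))
        mask, d, a, active = _episode_profile(ep, traj.times, d0, a0)
        theta = np.radians(a[active])
        pos = ref_p + d[active, None] * (np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v)
        idx_frames = np.nonzero(mask)[0][active]
        # markers are static in the baseline trajectory, so the per-frame P
        # position equals the reference one; place the oxygen directly
        frames[idx_frames, o_idx, :] = pos
    return Trajectory(traj.structure, traj.times.copy(), frames)
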