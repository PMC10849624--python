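"""Trajectory observables for condensate demixing.

Implements the four analyses used to characterise two-species condensates:

* axial density profiles for slab-coexistence runs (dense layer recentred
  at the box midpoint per frame),
* the demixing order parameter: the chain-concentration ratio C_B/C_A in a
  sphere at the droplet centre, block-averaged (1 = well mixed, -> 0 =
  strongly demixed client),
* intermolecular residue-residue contact-propensity maps, normalised to
  average contacts per frame per chain,
* per-residue RMSF with optional rigid-body superposition, aggregated
  across chains (condensed phase) or replica trajectories (dilute phase).

All distance computations are minimum-image in the periodic box.  Cluster
detection is single-linkage at the contact cutoff (connected components of
the bead contact graph), so "the droplet" and "a contact" share one length
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .cg_engine import SystemState, Trajectory

__all__ = [
    "ContactMap",
    "DemixScore",
    "DensityProfile",
    "EmptyProductionError",
    "RMSFProfile",
    "UndefinedRatioError",
    "center_concentration_ratio",
    "concentration_series",
    "contact_map",
    "density_profile",
    "rmsf",
]


class EmptyProductionError(ValueError):
    """No production frames remain after removing equilibration."""


class UndefinedRatioError(ValueError):
    """Species A is absent from the centre sphere in some block."""


@dataclass
class DensityProfile:
    """Axial density profile, time-averaged over production frames."""

    axis: int
    bin_centers: np.ndarray  # nm
    bin_width: float
    number_density: dict[str, np.ndarray]  # beads / nm^3 per species
    chain_concentration: dict[str, np.ndarray]  # chains / nm^3 per species
    n_frames: int

    def integral(self, species: str) -> float:
        """Profile integral over the box = mean bead count of the species."""
        slab_volume = self.bin_width * self._cross_section
        return float(np.sum(self.number_density[species]) * slab_volume)

    _cross_section: float = 1.0


@dataclass
class DemixScore:
    """Demixing order parameter C_B/C_A at the droplet centre."""

    ratio: float  # mean of per-block ratios
    block_ratios: np.ndarray
    sem: float  # SD over block means / sqrt(n_blocks)
    n_blocks: int
    species_a: str
    species_b: str
    center_radius: str | float
    definition: str = "largest single-linkage cluster; sphere about its centre of mass"


@dataclass
class ContactMap:
    """Average intermolecular contacts per frame, per chain of species A."""

    matrix: np.ndarray  # (n_res_A, n_res_B)
    species_a: str
    species_b: str
    cutoff: float
    n_chains_a: int
    n_frames: int


@dataclass
class RMSFProfile:
    """Per-residue RMSF (nm) aggregated over chains of a selection."""

    residues: np.ndarray  # 1-based residue indices of the interval
    mean: np.ndarray  # (L,) mean RMSF across chains
    sd: np.ndarray  # (L,) SD across chains (0 when a single chain)
    per_chain: np.ndarray  # (n_chains, L)
    phase: str = ""
    superposed: bool = True


# ---------------------------------------------------------------------------
# Periodic geometry helpers


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _periodic_com(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Centre of mass on the torus via the circular (angular) mean."""
    theta = 2.0 * np.pi * pos / box
    mean_sin = np.sin(theta).mean(axis=0)
    mean_cos = np.cos(theta).mean(axis=0)
    ang = np.arctan2(mean_sin, mean_cos)
    return np.mod(ang / (2.0 * np.pi) * box, box)


def _largest_cluster(pos: np.ndarray, box: np.ndarray, cutoff: float) -> np.ndarray:
    """Indices of the largest single-linkage cluster at the given cutoff."""
    n = pos.shape[0]
    tree = cKDTree(pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.array([0])
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    counts = np.bincount(labels)
    return np.where(labels == np.argmax(counts))[0]


def _default_cutoff(topology: SystemState) -> float:
    return 1.5 * float(topology.sigma.max())


def _production(traj: Trajectory, equilibration_frames: int):
    frames = traj.frames[equilibration_frames:]
    if not frames:
        raise EmptyProductionError(
            f"no production frames (total {traj.n_frames}, equilibration {equilibration_frames})"
        )
    return frames


# ---------------------------------------------------------------------------
# Density profile


def density_profile(
    traj: Trajectory,
    axis: int = 2,
    n_bins: int = 50,
    equilibration_frames: int = 0,
    recenter: bool = True,
    cluster_cutoff: float | None = None,
) -> DensityProfile:
    """Time-averaged per-species density along a box axis.

    With ``recenter`` the largest cluster's centre of mass is moved to the
    box midpoint in every frame before binning, so a drifting dense slab
    does not smear the profile.  Recentring is a rigid periodic shift and
    therefore conserves the profile integral exactly.
    """
    frames = _production(traj, equilibration_frames)
    top = traj.topology
    box = top.box
    cutoff = cluster_cutoff if cluster_cutoff is not None else _default_cutoff(top)
    L = float(box[axis])
    edges = np.linspace(0.0, L, n_bins + 1)
    cross = float(np.prod(np.delete(box, axis)))
    species_names = sorted(set(top.species.tolist()))
    counts = {s: np.zeros(n_bins) for s in species_names}
    for fr in frames:
        pos = np.mod(fr.positions, box)
        x = pos[:, axis]
        if recenter:
            idx = _largest_cluster(pos, box, cutoff)
            com = _periodic_com(pos[idx], box)[axis]
            x = np.mod(x - com + L / 2.0, L)
        for s in species_names:
            sel = top.species == s
            h, _ = np.histogram(x[sel], bins=edges)
            counts[s] += h
    bin_vol = (L / n_bins) * cross
    nf = len(frames)
    number_density = {s: counts[s] / (nf * bin_vol) for s in species_names}
    chain_len = {
        s: int(np.sum(top.species == s) // max(1, len(set(top.chain_index[top.species == s].tolist()))))
        for s in species_names
    }
    chain_conc = {s: number_density[s] / chain_len[s] for s in species_names}
    prof = DensityProfile(
        axis=axis,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        bin_width=L / n_bins,
        number_density=number_density,
        chain_concentration=chain_conc,
        n_frames=nf,
    )
    prof._cross_section = cross
    return prof


# ---------------------------------------------------------------------------
# Demixing order parameter


def _center_concentrations(frames, top, species_a, species_b, len_by_species,
                           cutoff, center_radius):
    box = top.box
    conc_a = np.empty(len(frames))
    conc_b = np.empty(len(frames))
    for t, fr in enumerate(frames):
        pos = np.mod(fr.positions, box)
        idx = _largest_cluster(pos, box, cutoff)
        com = _periodic_com(pos[idx], box)
        d_cluster = np.linalg.norm(_min_image(pos[idx] - com, box), axis=1)
        if center_radius is None:
            rg = float(np.sqrt(np.mean(d_cluster**2)))
            radius = 0.5 * rg
        else:
            radius = center_radius
        d_all = np.linalg.norm(_min_image(pos - com, box), axis=1)
        in_sphere = d_all <= radius
        vol = 4.0 / 3.0 * np.pi * radius**3
        conc_a[t] = np.sum(in_sphere & (top.species == species_a)) / len_by_species[species_a] / vol
        conc_b[t] = np.sum(in_sphere & (top.species == species_b)) / len_by_species[species_b] / vol
    return conc_a, conc_b


def concentration_series(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    center_radius: float | None = None,
    equilibration_frames: int = 0,
    cluster_cutoff: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame centre chain concentrations (times_ns, C_A, C_B).

    The frame-resolved counterpart of :func:`center_concentration_ratio`,
    useful for onset-time detection (e.g. when the instantaneous ratio first
    drops below a threshold).
    """
    frames = _production(traj, equilibration_frames)
    top = traj.topology
    cutoff = cluster_cutoff if cluster_cutoff is not None else _default_cutoff(top)
    len_by_species = {}
    for sp in (species_a, species_b):
        sel = top.species == sp
        if not sel.any():
            raise ValueError(f"species {sp!r} not present in trajectory")
        len_by_species[sp] = int(np.sum(sel)) // len(set(top.chain_index[sel].tolist()))
    conc_a, conc_b = _center_concentrations(
        frames, top, species_a, species_b, len_by_species, cutoff, center_radius
    )
    times = np.array([f.time_ns for f in frames])
    return times, conc_a, conc_b


def center_concentration_ratio(
    traj: Trajectory,
    species_a: str,
    species_b: str,
    center_radius: float | None = None,
    n_blocks: int = 5,
    equilibration_frames: int = 0,
    cluster_cutoff: float | None = None,
) -> DemixScore:
    """Chain-concentration ratio C_B/C_A at the droplet centre.

    Per frame the largest single-linkage cluster defines the droplet; chain
    concentrations (beads in the centre sphere / chain length / sphere
    volume) of each species are accumulated.  Frames are split into
    ``n_blocks`` contiguous blocks; each block's ratio is the ratio of
    block-mean concentrations, and the score is mean +/- SEM over blocks.
    ``center_radius`` defaults to half the cluster's radius of gyration,
    evaluated per frame.
    """
    frames = _production(traj, equilibration_frames)
    if len(frames) < n_blocks:
        raise EmptyProductionError(
            f"{len(frames)} production frames < n_blocks={n_blocks}"
        )
    top = traj.topology
    box = top.box
    cutoff = cluster_cutoff if cluster_cutoff is not None else _default_cutoff(top)
    for sp in (species_a, species_b):
        if not np.any(top.species == sp):
            raise ValueError(f"species {sp!r} not present in trajectory")
    len_by_species = {}
    for sp in (species_a, species_b):
        sel = top.species == sp
        n_chains_sp = len(set(top.chain_index[sel].tolist()))
        len_by_species[sp] = int(np.sum(sel)) // n_chains_sp

    conc_a, conc_b = _center_concentrations(
        frames, top, species_a, species_b, len_by_species, cutoff, center_radius
    )

    block_ratios = np.empty(n_blocks)
    for b, chunk in enumerate(np.array_split(np.arange(len(frames)), n_blocks)):
        ca = conc_a[chunk].mean()
        cb = conc_b[chunk].mean()
        if ca == 0.0:
            raise UndefinedRatioError(
                f"species {species_a!r} absent from the centre sphere in block {b}"
            )
        block_ratios[b] = cb / ca
    sem = float(np.std(block_ratios, ddof=1) / np.sqrt(n_blocks)) if n_blocks >= 2 else 0.0
    return DemixScore(
        ratio=float(block_ratios.mean()),
        block_ratios=block_ratios,
        sem=sem,
        n_blocks=n_blocks,
        species_a=species_a,
        species_b=species_b,
        center_radius="0.5*Rg" if center_radius is None else center_radius,
    )


# ---------------------------------------------------------------------------
# Contact maps


def contact_map(
    traj: Trajectory,
    cutoff: float,
    pair: tuple[str, str],
    equilibration_frames: int = 0,
) -> ContactMap:
    """Intermolecular residue-residue contact propensity <N_ij>.

    A contact is a bead pair on *different chains* closer (minimum image)
    than ``cutoff``.  Entry (i, j) counts ordered contacts with residue i on
    a chain of species A and residue j on a chain of species B, averaged
    over frames and normalised by the number of A chains.  For A == B the
    ordered convention makes the map symmetric by construction.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = _production(traj, equilibration_frames)
    top = traj.topology
    species_a, species_b = pair
    box = top.box
    sel_a = top.species == species_a
    sel_b = top.species == species_b
    if not sel_a.any() or not sel_b.any():
        raise ValueError(f"species pair {pair} not present")
    n_res_a = int(top.residue_index[sel_a].max())
    n_res_b = int(top.residue_index[sel_b].max())
    n_chains_a = len(set(top.chain_index[sel_a].tolist()))
    m = np.zeros((n_res_a, n_res_b))
    for fr in frames:
        pos = np.mod(fr.positions, box)
        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        p, q = pairs[:, 0], pairs[:, 1]
        inter = top.chain_index[p] != top.chain_index[q]
        p, q = p[inter], q[inter]
        for a, b in ((p, q), (q, p)):
            hit = sel_a[a] & sel_b[b]
            if hit.any():
                np.add.at(m, (top.residue_index[a[hit]] - 1, top.residue_index[b[hit]] - 1), 1.0)
    m /= len(frames) * n_chains_a
    return ContactMap(
        matrix=m,
        species_a=species_a,
        species_b=species_b,
        cutoff=cutoff,
        n_chains_a=n_chains_a,
        n_frames=len(frames),
    )


# ---------------------------------------------------------------------------
# RMSF


def _make_whole(pos: np.ndarray, beads: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Unwrap one chain so consecutive beads are minimum-image neighbours."""
    coords = pos[beads].copy()
    for k in range(1, len(coords)):
        delta = _min_image(coords[k] - coords[k - 1], box)
        coords[k] = coords[k - 1] + delta
    return coords


def rmsf(
    traj: Trajectory,
    chains: list[int] | str | None = None,
    interval: tuple[int, int] | None = None,
    superpose: bool = True,
    phase: str = "",
) -> RMSFProfile:
    """Per-residue root-mean-square fluctuation over a residue interval.

    ``chains`` selects chain ids (or all chains of a species when given a
    species label; all chains when None).  Each chain is made whole across
    the periodic boundary, optionally superposed (Kabsch) onto its
    first-frame interval coordinates, and RMSF_i = sqrt(mean_t |r_i(t) -
    <r_i>|^2) is computed about the time-mean structure.  Profiles are
    aggregated as mean +/- SD across the selected chains; for dilute-phase
    statistics run one chain per replica trajectory and aggregate outside.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    top = traj.topology
    box = top.box
    if chains is None:
        chain_ids = sorted(set(top.chain_index.tolist()))
    elif isinstance(chains, str):
        chain_ids = sorted(set(top.chain_index[top.species == chains].tolist()))
    else:
        chain_ids = list(chains)
    if not chain_ids:
        raise ValueError("empty chain selection")

    profiles = []
    for cid in chain_ids:
        beads = np.where(top.chain_index == cid)[0]
        res = top.residue_index[beads]
        order = np.argsort(res)
        beads = beads[order]
        res = res[order]
        if interval is not None:
            lo, hi = interval
            if lo < res.min() or hi > res.max():
                raise ValueError(f"interval {interval} outside chain residues")
            keep = (res >= lo) & (res <= hi)
            beads = beads[keep]
            res = res[keep]
        coords = np.array([_make_whole(np.mod(f.positions, box), beads, box) for f in traj.frames])
        if superpose:
            ref = coords[0] - coords[0].mean(axis=0)
            aligned = np.empty_like(coords)
            for t in range(coords.shape[0]):
                x = coords[t] - coords[t].mean(axis=0)
                rot, _ = Rotation.align_vectors(ref, x)
                aligned[t] = rot.apply(x)
            coords = aligned
        mean_pos = coords.mean(axis=0)
        fl = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
        profiles.append(fl)
    per_chain = np.array(profiles)
    residues = res
    return RMSFProfile(
        residues=residues,
        mean=per_chain.mean(axis=0),
        sd=per_chain.std(axis=0, ddof=1) if per_chain.shape[0] > 1 else np.zeros(per_chain.shape[1]),
        per_chain=per_chain,
        phase=phase,
        superposed=superpose,
    )
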