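"""Coarse-grained two-species condensate engine.

Multi-chain bead-spring systems in droplet or slab geometry, evolved with
underdamped Langevin dynamics (BAOAB splitting) under a hydropathy-scaled
Lennard-Jones (Ashbaugh-Hatch) pair potential plus Debye-Hueckel
electrostatics.  Two features target intra-condensate demixing physics:

* **Homotypic interaction scaling** — :class:`ScaleRule` multiplies the
  attractive strength ``lambda_ij`` for bead pairs where *both* beads belong
  to the same species and fall inside the rule's region (e.g. a hydrophobic
  patch).  Cross-species pairs are never scaled, so the factor isolates
  "homotypic interaction strength" as a single knob.
* **Redox crosslinking** — reactive (cysteine-like) beads may stochastically
  form and break harmonic disulfide-like crosslinks, emulating oxidising
  (high ``oxidation_prob``) vs reducing (high ``reduction_prob``) conditions.

Units: nm, ps, amu, kJ/mol (so 1 kJ/mol = 1 amu nm^2/ps^2); temperatures in
kelvin; trajectory frame times in ns.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .sequence_model import CGBeadParams, ProteinChainSpec, parameterize

__all__ = [
    "KB",
    "KE_COULOMB",
    "DivergenceError",
    "Frame",
    "ForceFieldConfig",
    "PackingError",
    "RedoxParams",
    "ScaleRule",
    "SystemState",
    "Trajectory",
    "apply_redox_step",
    "build_droplet_system",
    "build_slab_system",
    "pair_energy",
    "step_langevin",
]

KB = 0.00831446261815324  # Boltzmann constant, kJ/mol/K
KE_COULOMB = 138.935458  # Coulomb prefactor, kJ mol^-1 nm e^-2


class PackingError(RuntimeError):
    """Chain insertion failed within the retry budget."""


class DivergenceError(RuntimeError):
    """A coordinate became non-finite during integration."""


@dataclass(frozen=True)
class ScaleRule:
    """Multiply attraction for homotypic bead pairs of one species.

    ``region`` is a 1-based inclusive residue interval or ``"all"``; the
    factor applies where *both* beads of a pair match.
    """

    species: str
    factor: float
    region: tuple[int, int] | str = "all"

    def __post_init__(self) -> None:
        if not np.isfinite(self.factor) or self.factor < 0:
            raise ValueError("scale factor must be finite and >= 0")
        if self.region != "all":
            s, e = self.region
            if not (1 <= s <= e):
                raise ValueError(f"invalid region {self.region}")


@dataclass(frozen=True)
class RedoxParams:
    """Stochastic disulfide-crosslink model parameters.

    Probabilities are per attempt window (one window per trajectory frame
    stride); ``capture_radius`` is the maximum bead separation (nm) at which
    a crosslink can form.
    """

    oxidation_prob: float = 0.0
    reduction_prob: float = 0.0
    capture_radius: float = 0.6
    intermolecular_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.oxidation_prob <= 1.0 and 0.0 <= self.reduction_prob <= 1.0):
            raise ValueError("redox probabilities must lie in [0, 1]")
        if self.capture_radius <= 0:
            raise ValueError("capture_radius must be positive")

    @property
    def active(self) -> bool:
        return self.oxidation_prob > 0 or self.reduction_prob > 0


@dataclass(frozen=True)
class ForceFieldConfig:
    """Pair-potential, bonded, thermodynamic and integration parameters."""

    epsilon: float = 0.8368  # kJ/mol
    ah_cutoff: float = 2.0  # nm
    dh_cutoff: float = 3.5  # nm
    debye_length: float = 1.0  # nm
    dielectric: float = 80.0
    bond_k: float = 4184.0  # kJ/mol/nm^2
    bond_r0: float = 0.38  # nm
    temperature: float = 300.0  # K
    friction: float = 0.1  # 1/ps
    timestep: float = 0.01  # ps
    homotypic_scales: tuple[ScaleRule, ...] = ()
    redox: RedoxParams = field(default_factory=RedoxParams)

    def __post_init__(self) -> None:
        for name in ("epsilon", "ah_cutoff", "dh_cutoff", "debye_length",
                     "dielectric", "bond_k", "bond_r0", "temperature", "timestep"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        object.__setattr__(self, "homotypic_scales", tuple(self.homotypic_scales))

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def check_timestep(self, min_mass: float) -> None:
        """Bond-oscillation stability bound: dt must resolve the stiffest bond.

        The fastest mode is the harmonic bond with reduced mass m/2; we
        require dt <= 5% of its period.
        """
        period = 2.0 * np.pi * np.sqrt(0.5 * min_mass / self.bond_k)
        if self.timestep > 0.05 * period:
            raise ValueError(
                f"timestep {self.timestep} ps exceeds stability bound "
                f"{0.05 * period:.4g} ps for bond_k={self.bond_k}, m={min_mass}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SystemState:
    """Bead coordinates plus topology, per-bead CG parameters and crosslinks."""

    positions: np.ndarray  # (N,3) nm
    velocities: np.ndarray  # (N,3) nm/ps
    box: np.ndarray  # (3,) nm, orthorhombic periodic
    chain_index: np.ndarray  # (N,) int, 0-based chain id
    species: np.ndarray  # (N,) str labels
    residue_index: np.ndarray  # (N,) 1-based within chain
    sigma: np.ndarray  # (N,) nm
    lam: np.ndarray  # (N,)
    charge: np.ndarray  # (N,) e
    mass: np.ndarray  # (N,) amu
    reactive: np.ndarray  # (N,) bool
    bonds: np.ndarray  # (M,2) int static chain bonds
    crosslinks: set[tuple[int, int]] = field(default_factory=set)
    rng_seed: int = 0

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_index.max()) + 1 if self.n_beads else 0

    def chain_lengths(self) -> np.ndarray:
        return np.bincount(self.chain_index)

    def wrapped_positions(self) -> np.ndarray:
        return np.mod(self.positions, self.box)

    def all_bonds(self) -> np.ndarray:
        """Static bonds plus current dynamic crosslinks."""
        if not self.crosslinks:
            return self.bonds
        xl = np.array(sorted(self.crosslinks), dtype=np.int64)
        return np.vstack([self.bonds, xl])

    def copy(self) -> "SystemState":
        return SystemState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=self.box.copy(),
            chain_index=self.chain_index.copy(),
            species=self.species.copy(),
            residue_index=self.residue_index.copy(),
            sigma=self.sigma.copy(),
            lam=self.lam.copy(),
            charge=self.charge.copy(),
            mass=self.mass.copy(),
            reactive=self.reactive.copy(),
            bonds=self.bonds.copy(),
            crosslinks=set(self.crosslinks),
            rng_seed=self.rng_seed,
        )

    def validate(self) -> None:
        lengths = self.chain_lengths()
        if self.bonds.shape[0] != int(np.sum(lengths - 1)):
            raise ValueError("static bond count must be chain length - 1 per chain")
        partner_count = np.zeros(self.n_beads, dtype=int)
        for i, j in self.crosslinks:
            partner_count[i] += 1
            partner_count[j] += 1
        if (partner_count > 1).any():
            raise ValueError("a reactive bead participates in >1 crosslink")


@dataclass(frozen=True)
class Frame:
    """One trajectory snapshot (positions wrapped into the box)."""

    time_ns: float
    positions: np.ndarray
    crosslinks: frozenset[tuple[int, int]]
    potential_energy: float
    kinetic_energy: float
    temperature: float


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology, with provenance."""

    topology: SystemState
    frames: list[Frame]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        n = self.topology.n_beads
        for f in self.frames:
            if f.positions.shape[0] != n:
                raise ValueError("bead count must be constant across frames")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_ns for f in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_positions(
        cls,
        topology: SystemState,
        positions: Sequence[np.ndarray],
        times: Sequence[float] | None = None,
        provenance: dict | None = None,
    ) -> "Trajectory":
        """Build a trajectory from raw coordinate frames (e.g. imported data)."""
        if times is None:
            times = np.arange(len(positions), dtype=float)
        frames = [
            Frame(float(t), np.asarray(p, dtype=float), frozenset(), np.nan, np.nan, np.nan)
            for t, p in zip(times, positions)
        ]
        return cls(topology=topology, frames=frames, provenance=provenance or {})


# ---------------------------------------------------------------------------
# Pair potential


def _combine(i: CGBeadParams, j: CGBeadParams) -> tuple[float, float]:
    return 0.5 * (i.sigma + j.sigma), 0.5 * (i.lam + j.lam)


def pair_energy(
    r: float,
    i: CGBeadParams,
    j: CGBeadParams,
    cfg: ForceFieldConfig,
    scale: float = 1.0,
) -> float:
    """Nonbonded pair energy (kJ/mol) at separation ``r`` (nm).

    Ashbaugh-Hatch short-range term: below the Lennard-Jones minimum
    ``2^(1/6) sigma_ij`` the potential is ``phi_LJ + (1 - lambda_ij s) eps``
    (repulsive core preserved); beyond it the attraction is scaled by
    ``lambda_ij s``.  A Debye-Hueckel term handles charges.  Both terms are
    truncated and shifted to zero at their cutoffs.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    sig, lam = _combine(i, j)
    lam = lam * scale
    eps = cfg.epsilon
    e = 0.0
    if r < cfg.ah_cutoff:
        def philj(x: float) -> float:
            sr6 = (sig / x) ** 6
            return 4.0 * eps * (sr6 * sr6 - sr6)

        shift = lam * philj(cfg.ah_cutoff)
        if r <= _kernels.SIXTH_ROOT_2 * sig:
            e += philj(r) + (1.0 - lam) * eps - shift
        else:
            e += lam * philj(r) - shift
    qq = KE_COULOMB * i.charge * j.charge / cfg.dielectric
    if qq != 0.0 and r < cfg.dh_cutoff:
        e += qq * (
            np.exp(-r / cfg.debye_length) / r
            - np.exp(-cfg.dh_cutoff / cfg.debye_length) / cfg.dh_cutoff
        )
    return float(e)


def _pair_tables(state: SystemState, cfg: ForceFieldConfig):
    """Dense pair matrices with homotypic scaling folded into lambda."""
    n = state.n_beads
    sig_ij = 0.5 * (state.sigma[:, None] + state.sigma[None, :])
    lam_ij = 0.5 * (state.lam[:, None] + state.lam[None, :])
    scale = np.ones((n, n))
    for rule in cfg.homotypic_scales:
        mask = state.species == rule.species
        if rule.region != "all":
            s, e = rule.region
            mask = mask & (state.residue_index >= s) & (state.residue_index <= e)
        idx = np.where(mask)[0]
        scale[np.ix_(idx, idx)] *= rule.factor
    lam_ij = lam_ij * scale
    qq_ij = KE_COULOMB * np.outer(state.charge, state.charge) / cfg.dielectric
    excl = np.zeros((n, n), dtype=np.bool_)
    for b in state.bonds:
        excl[b[0], b[1]] = True
        excl[b[1], b[0]] = True
    return sig_ij, lam_ij, qq_ij, excl


def system_energy(state: SystemState, cfg: ForceFieldConfig) -> float:
    """Total potential energy of a state (bonds + crosslinks + nonbonded)."""
    sig_ij, lam_ij, qq_ij, excl = _pair_tables(state, cfg)
    forces = np.empty_like(state.positions)
    pe = _kernels.compute_forces(
        state.positions, state.box, sig_ij, lam_ij, qq_ij, excl,
        cfg.epsilon, cfg.ah_cutoff, cfg.dh_cutoff, cfg.debye_length,
        np.ascontiguousarray(state.all_bonds(), dtype=np.int64),
        cfg.bond_k, cfg.bond_r0, forces,
    )
    return float(pe)


# ---------------------------------------------------------------------------
# System builders


def _min_image_dist(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    delta = delta - box * np.round(delta / box)
    return np.linalg.norm(delta, axis=-1)


def _grow_chain(
    rng: np.random.Generator,
    length: int,
    bond_r0: float,
    region_ok,
    occupied: list[np.ndarray],
    box: np.ndarray,
    tol: float,
    max_restarts: int,
) -> np.ndarray | None:
    """Grow one self-avoiding random-walk chain inside a region.

    Overlap checks use minimum-image distances so chains near a periodic
    boundary cannot clash with images of earlier chains.
    """
    flat = np.vstack(occupied) if occupied else np.empty((0, 3))
    tree = cKDTree(np.mod(flat, box), boxsize=box) if len(flat) else None
    for _ in range(max_restarts):
        start = region_ok(rng)
        if start is None:
            continue
        if tree is not None and tree.query(np.mod(start, box), k=1)[0] < tol:
            continue
        coords = [start]
        ok = True
        for _bead in range(1, length):
            placed = False
            for _try in range(60):
                v = rng.standard_normal(3)
                v /= np.linalg.norm(v)
                cand = coords[-1] + bond_r0 * v
                if not region_ok(rng, cand):
                    continue
                if tree is not None and tree.query(np.mod(cand, box), k=1)[0] < tol:
                    continue
                own = np.array(coords[:-1])
                if len(own) and np.min(_min_image_dist(own - cand, box)) < tol:
                    continue
                coords.append(cand)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(coords)
    return None


def _finish_build(
    chains_coords: list[np.ndarray],
    chain_specs: list[tuple[str, list[CGBeadParams]]],
    box: np.ndarray,
    cfg: ForceFieldConfig,
    rng: np.random.Generator,
    seed: int,
) -> SystemState:
    positions = np.vstack(chains_coords)
    n = positions.shape[0]
    chain_index = np.concatenate(
        [np.full(len(c), k) for k, c in enumerate(chains_coords)]
    )
    species = np.concatenate(
        [np.full(len(c), chain_specs[k][0]) for k, c in enumerate(chains_coords)]
    )
    residue_index = np.concatenate(
        [np.arange(1, len(c) + 1) for c in chains_coords]
    )
    beads = [b for (_, bl) in chain_specs for b in bl]
    sigma = np.array([b.sigma for b in beads])
    lam = np.array([b.lam for b in beads])
    charge = np.array([b.charge for b in beads])
    mass = np.array([b.mass for b in beads])
    reactive = np.array([b.reactive for b in beads])
    bonds = []
    off = 0
    for c in chains_coords:
        for i in range(len(c) - 1):
            bonds.append((off + i, off + i + 1))
        off += len(c)
    kT = cfg.kT
    velocities = rng.standard_normal((n, 3)) * np.sqrt(kT / mass)[:, None]
    state = SystemState(
        positions=np.mod(positions, box),
        velocities=velocities,
        box=box.astype(float),
        chain_index=chain_index.astype(np.int64),
        species=species,
        residue_index=residue_index.astype(np.int64),
        sigma=sigma,
        lam=lam,
        charge=charge,
        mass=mass,
        reactive=reactive,
        bonds=np.array(bonds, dtype=np.int64),
        crosslinks=set(),
        rng_seed=seed,
    )
    state.validate()
    return state


def _expand_chains(
    species_a: ProteinChainSpec,
    n_a: int,
    species_b: ProteinChainSpec | None,
    n_b: int,
    table: dict[str, CGBeadParams],
) -> list[tuple[str, list[CGBeadParams]]]:
    if n_a < 0 or n_b < 0 or n_a + n_b == 0:
        raise ValueError("need at least one chain")
    chain_specs: list[tuple[str, list[CGBeadParams]]] = []
    beads_a = parameterize(species_a, table)
    chain_specs += [(species_a.name, beads_a)] * n_a
    if species_b is not None and n_b:
        beads_b = parameterize(species_b, table)
        chain_specs += [(species_b.name, beads_b)] * n_b
    return chain_specs


def build_droplet_system(
    species_a: ProteinChainSpec,
    n_a: int,
    species_b: ProteinChainSpec | None,
    n_b: int,
    box: Sequence[float],
    cfg: ForceFieldConfig,
    table: dict[str, CGBeadParams],
    seed: int,
    droplet_radius: float | None = None,
    tolerance: float | None = None,
    max_restarts: int = 200,
) -> SystemState:
    """Pack chains as self-avoiding random walks inside a central sphere.

    The droplet radius defaults to the radius holding all beads at ~15%
    volume packing.  Velocities are Maxwell-Boltzmann at ``cfg.temperature``.
    """
    box = np.asarray(box, dtype=float)
    chain_specs = _expand_chains(species_a, n_a, species_b, n_b, table)
    sigmas = np.array([b.sigma for (_, bl) in chain_specs for b in bl])
    n_beads = len(sigmas)
    if droplet_radius is None:
        droplet_radius = (n_beads * float(np.mean(sigmas)) ** 3 / (8 * 0.15)) ** (1 / 3)
    if droplet_radius > box.min() / 2:
        raise PackingError(
            f"droplet radius {droplet_radius:.3g} nm does not fit in box {box}"
        )
    tol = tolerance if tolerance is not None else 0.9 * float(np.min(sigmas))
    center = box / 2
    rng = np.random.default_rng(seed)

    def region_ok(rg, cand=None):
        if cand is None:
            v = rg.standard_normal(3)
            v /= np.linalg.norm(v)
            p = center + v * droplet_radius * rg.random() ** (1 / 3)
            return p
        return np.linalg.norm(cand - center) <= droplet_radius

    coords = []
    for k, (_, beads) in enumerate(chain_specs):
        c = _grow_chain(rng, len(beads), cfg.bond_r0, region_ok, coords, box, tol, max_restarts)
        if c is None:
            raise PackingError(f"failed to insert chain {k} after {max_restarts} restarts")
        coords.append(c)
    return _finish_build(coords, chain_specs, box, cfg, rng, seed)


def build_slab_system(
    species_a: ProteinChainSpec,
    n_a: int,
    species_b: ProteinChainSpec | None,
    n_b: int,
    box: Sequence[float],
    cfg: ForceFieldConfig,
    table: dict[str, CGBeadParams],
    seed: int,
    slab_halfwidth: float | None = None,
    tolerance: float | None = None,
    max_restarts: int = 200,
) -> SystemState:
    """Pack chains into a central z-slab of an elongated periodic box."""
    box = np.asarray(box, dtype=float)
    chain_specs = _expand_chains(species_a, n_a, species_b, n_b, table)
    sigmas = np.array([b.sigma for (_, bl) in chain_specs for b in bl])
    if slab_halfwidth is None:
        slab_halfwidth = box[0] / 2
    tol = tolerance if tolerance is not None else 0.9 * float(np.min(sigmas))
    zc = box[2] / 2
    rng = np.random.default_rng(seed)

    def region_ok(rg, cand=None):
        if cand is None:
            p = np.array([
                rg.random() * box[0],
                rg.random() * box[1],
                zc + (2 * rg.random() - 1) * slab_halfwidth,
            ])
            return p
        return abs(cand[2] - zc) <= slab_halfwidth

    coords = []
    for k, (_, beads) in enumerate(chain_specs):
        c = _grow_chain(rng, len(beads), cfg.bond_r0, region_ok, coords, box, tol, max_restarts)
        if c is None:
            raise PackingError(f"failed to insert chain {k} after {max_restarts} restarts")
        coords.append(c)
    return _finish_build(coords, chain_specs, box, cfg, rng, seed)


# ---------------------------------------------------------------------------
# Redox crosslinking


def apply_redox_step(
    state: SystemState,
    redox: RedoxParams,
    rng: np.random.Generator | int,
) -> SystemState:
    """One stochastic crosslink attempt window (in place; returns the state).

    Formation is evaluated on reactive pairs unbonded at entry that lie
    within ``capture_radius`` (minimum image); breakage on crosslinks present
    at entry.  Randomised pair ordering enforces at most one partner per
    bead.  A no-op when no reactive beads exist.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    reactive_idx = np.where(state.reactive)[0]
    if reactive_idx.size == 0:
        return state

    existing = sorted(state.crosslinks)
    busy = set()
    for i, j in existing:
        busy.add(i)
        busy.add(j)

    to_break = [
        (i, j) for (i, j) in existing if rng.random() < redox.reduction_prob
    ]

    new_links = []
    if redox.oxidation_prob > 0:
        free = [i for i in reactive_idx if i not in busy]
        if len(free) >= 2:
            pos = np.mod(state.positions[free], state.box)
            tree = cKDTree(pos, boxsize=state.box)
            pairs = sorted(tree.query_pairs(redox.capture_radius))
            cand = []
            for a, b in pairs:
                i, j = free[a], free[b]
                if redox.intermolecular_only and state.chain_index[i] == state.chain_index[j]:
                    continue
                cand.append((min(i, j), max(i, j)))
            order = rng.permutation(len(cand))
            taken = set()
            for k in order:
                i, j = cand[k]
                if i in taken or j in taken:
                    continue
                if rng.random() < redox.oxidation_prob:
                    new_links.append((i, j))
                    taken.add(i)
                    taken.add(j)

    for pair in to_break:
        state.crosslinks.discard(pair)
    for pair in new_links:
        state.crosslinks.add(pair)
    return state


# ---------------------------------------------------------------------------
# Integration


def step_langevin(
    state: SystemState,
    n_steps: int,
    cfg: ForceFieldConfig,
    seed: int,
    stride: int | None = None,
    start_time_ps: float = 0.0,
) -> Trajectory:
    """Evolve a system with BAOAB Langevin dynamics.

    Frames (positions wrapped into the box, energies, instantaneous
    temperature, crosslink set) are emitted every ``stride`` steps; the
    initial state is frame 0.  Redox crosslink attempts, when enabled, run
    once per stride window (the neighbour bookkeeping interval).  The state
    is advanced in place; identical seeds give bit-identical trajectories.
    """
    cfg.check_timestep(float(state.mass.min()))
    if stride is None:
        stride = max(1, n_steps // 100)
    rng = np.random.default_rng(seed)
    redox_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]).generate_state(1)[0])

    sig_ij, lam_ij, qq_ij, excl = _pair_tables(state, cfg)
    dt = cfg.timestep
    c1 = float(np.exp(-cfg.friction * dt)) if cfg.friction > 0 else 1.0
    kT = cfg.kT
    n = state.n_beads

    def make_frame(t_ps: float, pe: float, ke: float) -> Frame:
        temp = 2.0 * ke / (3.0 * n * KB) if n else 0.0
        return Frame(
            time_ns=t_ps / 1000.0,
            positions=state.wrapped_positions(),
            crosslinks=frozenset(state.crosslinks),
            potential_energy=float(pe),
            kinetic_energy=float(ke),
            temperature=float(temp),
        )

    try:
        pe0 = system_energy(state, cfg)
    except ZeroDivisionError as exc:
        raise DivergenceError("coincident beads in the initial state (step 0)") from exc
    ke0 = float(0.5 * np.sum(state.mass[:, None] * state.velocities**2))
    frames = [make_frame(start_time_ps, pe0, ke0)]

    done = 0
    bonds = np.ascontiguousarray(state.all_bonds(), dtype=np.int64)
    while done < n_steps:
        m = min(stride, n_steps - done)
        noise = rng.standard_normal((m, n, 3))
        try:
            pe, ke = _kernels.baoab_chunk(
                state.positions, state.velocities, state.mass, state.box,
                sig_ij, lam_ij, qq_ij, excl,
                cfg.epsilon, cfg.ah_cutoff, cfg.dh_cutoff, cfg.debye_length,
                bonds, cfg.bond_k, cfg.bond_r0, dt, c1, kT, noise,
            )
        except ZeroDivisionError as exc:
            raise DivergenceError(
                f"coincident beads between steps {done} and {done + m}"
            ) from exc
        done += m
        if not np.isfinite(state.positions).all():
            raise DivergenceError(f"non-finite coordinate at step {done}")
        if cfg.redox.active:
            before = set(state.crosslinks)
            apply_redox_step(state, cfg.redox, redox_rng)
            if state.crosslinks != before:
                bonds = np.ascontiguousarray(state.all_bonds(), dtype=np.int64)
                pe = system_energy(state, cfg)
        frames.append(make_frame(start_time_ps + done * dt, pe, ke))

    return Trajectory(
        topology=state,
        frames=frames,
        provenance={"config_hash": cfg.config_hash(), "seed": seed, "n_steps": n_steps,
                    "stride": stride, "timestep_ps": dt},
    )
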