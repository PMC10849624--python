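"""Pair potential, system builders, Langevin integrator and redox model."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from conftest import make_state
from demixsim import _kernels
from demixsim.cg_engine import (
    DivergenceError,
    ForceFieldConfig,
    KB,
    PackingError,
    RedoxParams,
    ScaleRule,
    SystemState,
    apply_redox_step,
    build_droplet_system,
    build_slab_system,
    pair_energy,
    step_langevin,
    system_energy,
    _pair_tables,
)
from demixsim.sequence_model import CGBeadParams, ProteinChainSpec
from demixsim.synthetic_data import make_toy_chain_pair, toy_forcefield, SyntheticSequenceParams

RMIN = 2.0 ** (1.0 / 6.0)


def bead(lam=0.7, sigma=1.0, charge=0.0):
    return CGBeadParams(sigma=sigma, lam=lam, charge=charge, mass=1.0)


class TestPairPotential:
    def test_minimum_depth_is_minus_lambda_epsilon(self):
        """At r = 2^(1/6) sigma the well depth is -lambda*eps (up to the
        small cutoff shift, negligible for a 3-sigma cutoff)."""
        cfg = toy_forcefield()
        for lam in (0.3, 0.7, 1.0):
            b = bead(lam)
            e = pair_energy(RMIN, b, b, cfg)
            assert e == pytest.approx(-lam * cfg.epsilon, rel=0.01)
            # exact closed form including the truncation shift
            sr6 = (1.0 / cfg.ah_cutoff) ** 6
            shift = lam * 4.0 * cfg.epsilon * (sr6 * sr6 - sr6)
            assert e == pytest.approx(-lam * cfg.epsilon - shift, abs=1e-12)

    def test_zero_beyond_cutoff(self):
        cfg = toy_forcefield()
        b = bead(0.9, charge=1.0)
        for r in (cfg.ah_cutoff, cfg.ah_cutoff + 0.5, 10.0):
            assert pair_energy(r, b, b, cfg) == 0.0

    def test_pure_repulsion_when_lambda_zero(self):
        cfg = toy_forcefield()
        b = bead(0.0)
        for r in np.linspace(0.5, cfg.ah_cutoff + 1, 200):
            assert pair_energy(r, b, b, cfg) >= 0.0

    def test_continuity_at_branch_point_and_cutoffs(self):
        cfg = toy_forcefield()
        b = bead(0.85, charge=0.5)
        eps_r = 1e-9
        for r0 in (RMIN, cfg.ah_cutoff, cfg.dh_cutoff):
            lo = pair_energy(r0 - eps_r, b, b, cfg)
            hi = pair_energy(r0 + eps_r, b, b, cfg)
            assert abs(lo - hi) < 1e-6

    def test_homotypic_scale_deepens_attraction_only(self):
        cfg = toy_forcefield()
        b = bead(0.5)
        assert pair_energy(RMIN, b, b, cfg, scale=2.0) < pair_energy(RMIN, b, b, cfg)
        # repulsive core (r << sigma) unchanged in its divergence
        assert pair_energy(0.7, b, b, cfg, scale=2.0) > 0

    def test_debye_huckel_like_charges_repel_and_decay(self):
        cfg = toy_forcefield()
        b0, b1 = bead(0.0, charge=1.0), bead(0.0, charge=1.0)
        e1 = pair_energy(1.5, b0, b1, cfg) - pair_energy(1.5, bead(0.0), bead(0.0), cfg)
        e2 = pair_energy(2.5, b0, b1, cfg) - pair_energy(2.5, bead(0.0), bead(0.0), cfg)
        assert e1 > e2 > 0

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy(0.0, bead(), bead(), toy_forcefield())

    def test_kernel_energy_matches_scalar_reference(self):
        """Total nonbonded energy from the numba kernel equals the pairwise
        sum of the scalar pair_energy over all non-bonded pairs."""
        rng = np.random.default_rng(3)
        cfg = toy_forcefield()
        n = 24
        state = make_state(
            rng.uniform(5, 15, size=(n, 3)),
            chain_lengths=[6, 6, 6, 6],
            species=["a", "a", "b", "b"],
            lam=rng.uniform(0.2, 1.0, n),
            charge=rng.choice([-1.0, 0.0, 1.0], n),
            sigma=rng.uniform(0.8, 1.2, n),
        )
        total = system_energy(state, cfg)
        excl = {tuple(b) for b in state.bonds}
        expect = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl:
                    continue
                delta = state.positions[i] - state.positions[j]
                delta -= state.box * np.round(delta / state.box)
                r = float(np.linalg.norm(delta))
                bi = CGBeadParams(state.sigma[i], state.lam[i], state.charge[i], 1.0)
                bj = CGBeadParams(state.sigma[j], state.lam[j], state.charge[j], 1.0)
                expect += pair_energy(r, bi, bj, cfg)
        for i, j in excl:
            delta = state.positions[i] - state.positions[j]
            delta -= state.box * np.round(delta / state.box)
            r = float(np.linalg.norm(delta))
            expect += 0.5 * cfg.bond_k * (r - cfg.bond_r0) ** 2
        assert total == pytest.approx(expect, rel=1e-10)

    def test_forces_are_gradient_of_energy(self):
        rng = np.random.default_rng(5)
        cfg = toy_forcefield()
        state = make_state(
            rng.uniform(8, 12, size=(8, 3)),
            chain_lengths=[4, 4],
            species=["a", "b"],
            lam=rng.uniform(0.3, 0.9, 8),
        )
        sig, lam, qq, excl = _pair_tables(state, cfg)
        bonds = np.ascontiguousarray(state.bonds, dtype=np.int64)
        f = np.empty_like(state.positions)
        _kernels.compute_forces(
            state.positions, state.box, sig, lam, qq, excl, cfg.epsilon,
            cfg.ah_cutoff, cfg.dh_cutoff, cfg.debye_length, bonds,
            cfg.bond_k, cfg.bond_r0, f,
        )
        h = 1e-6
        for i in (0, 3, 7):
            for k in range(3):
                for sgn, store in ((1, "hi"), (-1, "lo")):
                    pos = state.positions.copy()
                    pos[i, k] += sgn * h
                    e = _kernels.compute_forces(
                        pos, state.box, sig, lam, qq, excl, cfg.epsilon,
                        cfg.ah_cutoff, cfg.dh_cutoff, cfg.debye_length, bonds,
                        cfg.bond_k, cfg.bond_r0, np.empty_like(pos),
                    )
                    if store == "hi":
                        ehi = e
                    else:
                        elo = e
                num = -(ehi - elo) / (2 * h)
                assert f[i, k] == pytest.approx(num, rel=1e-4, abs=1e-6)


@pytest.fixture(scope="module")
def toy_system():
    params = SyntheticSequenceParams(
        block_lambda=1.0, background_lambda=0.45, scaffold_lambda=0.6
    )
    client, scaffold, table = make_toy_chain_pair(params, 0)
    ff = toy_forcefield()
    return client, scaffold, table, ff


class TestBuilders:
    def test_droplet_counts_species_topology(self, toy_system):
        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 25, scaffold, 25, (40, 40, 40), ff, table, seed=1)
        assert state.n_chains == 50
        assert state.n_beads == 50 * 20
        assert np.sum(state.species == "client") == 25 * 20
        lengths = state.chain_lengths()
        assert state.bonds.shape[0] == int(np.sum(lengths - 1))

    def test_droplet_deterministic(self, toy_system):
        client, scaffold, table, ff = toy_system
        s1 = build_droplet_system(client, 5, scaffold, 5, (30, 30, 30), ff, table, seed=9)
        s2 = build_droplet_system(client, 5, scaffold, 5, (30, 30, 30), ff, table, seed=9)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)

    def test_droplet_packing_error_for_tiny_box(self, toy_system):
        client, scaffold, table, ff = toy_system
        with pytest.raises(PackingError):
            build_droplet_system(client, 25, scaffold, 25, (6, 6, 6), ff, table, seed=1)

    def test_droplet_respects_insertion_tolerance(self, toy_system):
        from scipy.spatial import cKDTree

        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 10, scaffold, 10, (30, 30, 30), ff, table, seed=4)
        pos = state.wrapped_positions()
        d = cKDTree(pos, boxsize=state.box).query(pos, k=2)[0][:, 1]
        assert d.min() >= 0.9 * state.sigma.min() - 1e-9

    def test_slab_beads_in_central_slab(self, toy_system):
        client, _, table, ff = toy_system
        box = (12.0, 12.0, 60.0)
        state = build_slab_system(client, 25, None, 0, box, ff, table, seed=2)
        z = state.positions[:, 2]
        assert np.all(np.abs(z - 30.0) <= 12.0 + 1e-9)
        assert state.n_chains == 25

    def test_zero_chains_rejected(self, toy_system):
        client, scaffold, table, ff = toy_system
        with pytest.raises(ValueError):
            build_slab_system(client, 0, scaffold, 0, (8, 8, 40), ff, table, seed=1)

    def test_velocities_maxwell_boltzmann(self, toy_system):
        """Build velocities standardised by sqrt(m/kT) pass a normality test."""
        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 10, scaffold, 10, (30, 30, 30), ff, table, seed=7)
        v = (state.velocities * np.sqrt(state.mass / ff.kT)[:, None]).ravel()
        assert stats.normaltest(v).pvalue > 1e-3
        assert np.var(v) == pytest.approx(1.0, rel=0.1)


class TestIntegrator:
    def test_same_seed_identical_trajectory(self, toy_system):
        client, scaffold, table, ff = toy_system
        state1 = build_droplet_system(client, 3, scaffold, 3, (25, 25, 25), ff, table, seed=8)
        state2 = state1.copy()
        t1 = step_langevin(state1, 500, ff, seed=42, stride=100)
        t2 = step_langevin(state2, 500, ff, seed=42, stride=100)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.positions, f2.positions)

    def test_topology_conserved(self, toy_system):
        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 3, scaffold, 3, (25, 25, 25), ff, table, seed=8)
        species0 = state.species.copy()
        bonds0 = state.bonds.copy()
        traj = step_langevin(state, 300, ff, seed=1, stride=100)
        assert np.array_equal(state.species, species0)
        assert np.array_equal(state.bonds, bonds0)
        assert all(f.positions.shape == (state.n_beads, 3) for f in traj.frames)
        assert np.all(np.diff(traj.times) > 0)

    def test_nve_energy_conservation(self, toy_system):
        """With friction 0 (noise off) BAOAB reduces to velocity Verlet; the
        total energy of a 2-chain system drifts < 1e-3 relative over 1e4
        steps at a small timestep."""
        client, scaffold, table, _ = toy_system
        ff = toy_forcefield(friction=1e-12, timestep=0.005)
        ff = dataclasses.replace(ff, friction=0.0)
        state = build_droplet_system(client, 1, scaffold, 1, (25, 25, 25), ff, table, seed=3)
        traj = step_langevin(state, 10_000, ff, seed=0, stride=500)
        etot = np.array([f.potential_energy + f.kinetic_energy for f in traj.frames])
        scale = max(abs(etot[0]), float(np.mean([f.kinetic_energy for f in traj.frames])))
        assert np.max(np.abs(etot - etot[0])) / scale < 1e-3

    def test_harmonic_dimer_bond_variance(self):
        """Bond-length variance of a thermalised dimer matches the Boltzmann
        value kT/k within 3 standard errors (block estimate)."""
        cfg = toy_forcefield(friction=1.0, timestep=0.01)
        chain = ProteinChainSpec(name="dimer", residues="GG")
        table = {"G": CGBeadParams(sigma=1.0, lam=0.0, charge=0.0, mass=1.0)}
        state = build_droplet_system(chain, 1, None, 0, (20, 20, 20), cfg, table,
                                     seed=2, droplet_radius=3.0)
        traj = step_langevin(state, 60_000, cfg, seed=5, stride=20)
        r = np.array([
            np.linalg.norm(f.positions[0] - f.positions[1] -
                           state.box * np.round((f.positions[0] - f.positions[1]) / state.box))
            for f in traj.frames[100:]
        ])
        blocks = np.array_split(r, 10)
        bvars = [np.var(b) for b in blocks]
        est = np.mean(bvars)
        se = np.std(bvars, ddof=1) / np.sqrt(len(bvars))
        expect = cfg.kT / cfg.bond_k
        assert abs(est - expect) <= 3 * se

    def test_thermostat_reaches_target_temperature(self, toy_system):
        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 5, scaffold, 5, (30, 30, 30), ff, table, seed=6)
        traj = step_langevin(state, 20_000, ff, seed=9, stride=500)
        temps = [f.temperature for f in traj.frames[-20:]]
        assert np.mean(temps) == pytest.approx(ff.temperature, rel=0.08)

    def test_energy_invariant_under_box_translation(self, toy_system):
        client, scaffold, table, ff = toy_system
        state = build_droplet_system(client, 3, scaffold, 3, (25, 25, 25), ff, table, seed=8)
        e0 = system_energy(state, ff)
        state.positions = state.positions + state.box * np.array([2.0, -1.0, 3.0])
        assert system_energy(state, ff) == pytest.approx(e0, rel=1e-12)
        state.positions = state.positions + np.array([0.37, 1.23, -4.2])
        e_shift = system_energy(state, ff)
        state.positions = np.mod(state.positions, state.box)
        assert system_energy(state, ff) == pytest.approx(e_shift, rel=1e-9)

    def test_unstable_timestep_rejected(self, toy_system):
        client, scaffold, table, _ = toy_system
        ff = toy_forcefield(timestep=0.5)
        state_ff = toy_forcefield()
        state = build_droplet_system(client, 1, scaffold, 1, (25, 25, 25), state_ff, table, seed=3)
        with pytest.raises(ValueError, match="stability"):
            step_langevin(state, 10, ff, seed=0)

    def test_divergence_reported_with_step(self):
        """Coincident nonbonded beads are singular; the error names the step
        range in which the integration failed."""
        pos = np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 11.0],
                        [10.0, 10.0, 10.0], [10.0, 10.0, 9.0]])
        state = make_state(pos, chain_lengths=[2, 2], species=["a", "b"], lam=1.0)
        cfg = toy_forcefield()
        with pytest.raises(DivergenceError, match="step"):
            step_langevin(state, 200, cfg, seed=0, stride=100)


class TestRedox:
    def two_reactive_chains(self, gap=0.5):
        pos = np.array([
            [10.0, 10.0, 10.0], [11.0, 10.0, 10.0],
            [10.0, 10.0 + gap, 10.0], [11.0, 10.0 + gap, 10.0],
        ])
        return make_state(pos, chain_lengths=[2, 2], species=["a", "a"],
                          reactive=[True, False, True, False])

    def test_zero_oxidation_prob_is_noop(self):
        state = self.two_reactive_chains()
        apply_redox_step(state, RedoxParams(oxidation_prob=0.0, capture_radius=1.0), 1)
        assert state.crosslinks == set()

    def test_forced_oxidation_forms_exactly_one_crosslink(self):
        state = self.two_reactive_chains()
        apply_redox_step(state, RedoxParams(oxidation_prob=1.0, capture_radius=1.0), 1)
        assert state.crosslinks == {(0, 2)}

    def test_full_reduction_clears_crosslinks(self):
        state = self.two_reactive_chains()
        state.crosslinks = {(0, 2)}
        apply_redox_step(
            state, RedoxParams(oxidation_prob=0.0, reduction_prob=1.0, capture_radius=1.0), 1
        )
        assert state.crosslinks == set()

    def test_at_most_one_partner_per_bead(self):
        # three mutually close reactive beads on three chains
        pos = np.array([
            [10.0, 10.0, 10.0], [11.0, 10.0, 10.0],
            [10.3, 10.0, 10.0], [11.3, 10.0, 10.0],
            [10.0, 10.3, 10.0], [11.0, 10.3, 10.0],
        ])
        state = make_state(pos, chain_lengths=[2, 2, 2], species=["a", "a", "a"],
                          reactive=[True, False, True, False, True, False])
        apply_redox_step(state, RedoxParams(oxidation_prob=1.0, capture_radius=1.0), 3)
        counts = np.zeros(6)
        for i, j in state.crosslinks:
            counts[i] += 1
            counts[j] += 1
        assert len(state.crosslinks) == 1
        assert counts.max() <= 1

    def test_intramolecular_pairs_skipped(self):
        pos = np.array([[10.0, 10.0, 10.0], [10.5, 10.0, 10.0]])
        state = make_state(pos, chain_lengths=[2], species=["a"],
                          reactive=[True, True])
        apply_redox_step(
            state,
            RedoxParams(oxidation_prob=1.0, capture_radius=1.0, intermolecular_only=True),
            1,
        )
        assert state.crosslinks == set()

    def test_capture_radius_respected(self):
        state = self.two_reactive_chains(gap=2.0)
        apply_redox_step(state, RedoxParams(oxidation_prob=1.0, capture_radius=1.0), 1)
        assert state.crosslinks == set()

    def test_no_reactive_beads_is_noop(self):
        state = self.two_reactive_chains()
        state.reactive[:] = False
        out = apply_redox_step(state, RedoxParams(oxidation_prob=1.0, capture_radius=1.0), 1)
        assert out.crosslinks == set()
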