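"""Shared fixtures: toy systems and cached small simulations.

Simulations are desk-scale (20-bead chains, 10+10 chains, tens of thousands
of Langevin steps in reduced units) and cached at session scope so the
demixing-scan and redox-sweep results are computed once and reused by both
the property tests and the acceptance tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from demixsim.cg_engine import (
    ForceFieldConfig,
    RedoxParams,
    ScaleRule,
    Trajectory,
    build_droplet_system,
    step_langevin,
)
from demixsim.condensate_metrics import center_concentration_ratio, concentration_series
from demixsim.synthetic_data import (
    SyntheticSequenceParams,
    make_toy_chain_pair,
    toy_forcefield,
)

#: Study conditions for the demixing scans: sticky client block (HP stand-in)
#: on a weakly sticky backbone, moderately sticky uniform scaffold.
TOY_PARAMS = SyntheticSequenceParams(
    block_lambda=1.0, background_lambda=0.45, scaffold_lambda=0.6
)

#: Identical-species control: both chains uniform.  0.65 keeps the droplet
#: compact, which the centre-ratio estimator needs for stable statistics;
#: the expected ratio is exactly 1 by label symmetry regardless of lambda.
MIXED_PARAMS = SyntheticSequenceParams(
    block_lambda=0.65, background_lambda=0.65, scaffold_lambda=0.65
)

BOX = (30.0, 30.0, 30.0)
SCAN_SEEDS = (11, 12, 13)
SCAN_STEPS = 30_000
MIXED_STEPS = 60_000
REDOX_STEPS = 40_000


def run_droplet(
    params: SyntheticSequenceParams,
    scale: float,
    seed: int,
    n_steps: int,
    redox: RedoxParams | None = None,
    stride: int | None = None,
    capture_radius: float = 1.3,
) -> Trajectory:
    """Build a 10+10 chain droplet and run Langevin production."""
    client, scaffold, table = make_toy_chain_pair(params, seed)
    scales = () if scale == 1.0 else (ScaleRule("client", scale, params.block),)
    overrides = {"homotypic_scales": scales}
    if redox is not None:
        overrides["redox"] = dataclasses.replace(redox, capture_radius=capture_radius)
    ff = dataclasses.replace(toy_forcefield(), **overrides)
    state = build_droplet_system(
        client, params.n_client_chains, scaffold, params.n_scaffold_chains,
        BOX, ff, table, seed,
    )
    return step_langevin(state, n_steps, ff, seed + 1000,
                         stride=stride or max(1, n_steps // 100))


def make_state(
    positions,
    chain_lengths,
    species,
    box=(30.0, 30.0, 30.0),
    sigma=1.0,
    lam=0.5,
    charge=0.0,
    mass=1.0,
    reactive=None,
):
    """Hand-build a SystemState for metric and redox tests.

    ``chain_lengths`` and ``species`` are per-chain; per-bead CG parameters
    are uniform scalars unless arrays are given.
    """
    from demixsim.cg_engine import SystemState

    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    assert sum(chain_lengths) == n
    chain_index = np.concatenate(
        [np.full(l, k, dtype=np.int64) for k, l in enumerate(chain_lengths)]
    )
    residue_index = np.concatenate(
        [np.arange(1, l + 1, dtype=np.int64) for l in chain_lengths]
    )
    species_arr = np.concatenate(
        [np.full(l, s) for s, l in zip(species, chain_lengths)]
    )
    bonds = []
    off = 0
    for l in chain_lengths:
        bonds += [(off + i, off + i + 1) for i in range(l - 1)]
        off += l
    full = lambda v: np.full(n, v, dtype=float) if np.isscalar(v) else np.asarray(v, dtype=float)
    return SystemState(
        positions=positions,
        velocities=np.zeros((n, 3)),
        box=np.asarray(box, dtype=float),
        chain_index=chain_index,
        species=species_arr,
        residue_index=residue_index,
        sigma=full(sigma),
        lam=full(lam),
        charge=full(charge),
        mass=full(mass),
        reactive=(np.zeros(n, dtype=bool) if reactive is None
                  else np.asarray(reactive, dtype=bool)),
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
    )


@pytest.fixture(scope="session")
def toy_params() -> SyntheticSequenceParams:
    return TOY_PARAMS


@pytest.fixture(scope="session")
def toy_ff() -> ForceFieldConfig:
    return toy_forcefield()


@pytest.fixture(scope="session")
def mixed_control_score():
    """Equimolar droplet of two identically parameterised species."""
    traj = run_droplet(MIXED_PARAMS, 1.0, seed=5, n_steps=MIXED_STEPS)
    eq = traj.n_frames // 3
    return center_concentration_ratio(
        traj, "client", "scaffold", n_blocks=5, equilibration_frames=eq
    )


@pytest.fixture(scope="session")
def homotypic_scale_scan():
    """Mean centre ratio vs homotypic scale, averaged over seeds.

    Returns {label: mean ratio} for the block-less client ("dhp": block
    lambda lowered to the backbone level) and scale factors 1, 1.5 and 2 on
    the sticky block.
    """
    results: dict[str, float] = {}
    dhp = dataclasses.replace(TOY_PARAMS, block_lambda=TOY_PARAMS.background_lambda)
    conditions = {"dhp": (dhp, 1.0), "s1": (TOY_PARAMS, 1.0),
                  "s1.5": (TOY_PARAMS, 1.5), "s2": (TOY_PARAMS, 2.0)}
    for label, (params, scale) in conditions.items():
        ratios = []
        for seed in SCAN_SEEDS:
            traj = run_droplet(params, scale, seed, SCAN_STEPS)
            eq = traj.n_frames // 3
            score = center_concentration_ratio(
                traj, "client", "scaffold", n_blocks=5, equilibration_frames=eq
            )
            ratios.append(score.ratio)
        results[label] = float(np.mean(ratios))
    return results


def demix_onset(traj, window: int = 15, threshold: float = 0.5,
                sustain: int = 15) -> float:
    """Demixing onset time (ns) from the smoothed centre-ratio series.

    Single-frame centre ratios carry heavy counting noise, so the ratio is
    smoothed with a ``window``-frame moving average and the onset is the
    start of the first run of ``sustain`` consecutive smoothed values below
    ``threshold``; inf when no sustained crossing occurs.
    """
    times, ca, cb = concentration_series(
        traj, "client", "scaffold", equilibration_frames=traj.n_frames // 5
    )
    k = np.ones(window) / window
    r = np.convolve(cb, k, "valid") / np.maximum(np.convolve(ca, k, "valid"), 1e-12)
    t = times[window - 1:]
    run = 0
    for i, below in enumerate(r < threshold):
        run = run + 1 if below else 0
        if run >= sustain:
            return float(t[i - sustain + 1])
    return np.inf


@pytest.fixture(scope="session")
def redox_sweep():
    """Oxidation-probability sweep at a marginal homotypic scale (s = 1.15).

    The base scale is chosen so the un-crosslinked control demixes slowly
    relative to the run length, which is what lets onset acceleration be
    resolved at all.  Returns {oxidation_prob: (mean steady-state crosslink
    count, mean onset time ns)} over seeds.
    """
    out: dict[float, tuple[float, float]] = {}
    for ox in (0.0, 0.1, 1.0):
        n_links, onsets = [], []
        for seed in (21, 22, 23):
            redox = RedoxParams(oxidation_prob=ox, reduction_prob=0.0)
            traj = run_droplet(TOY_PARAMS, 1.15, seed, REDOX_STEPS,
                               redox=redox, stride=200)
            tail = traj.frames[-traj.n_frames // 4:]
            n_links.append(np.mean([len(f.crosslinks) for f in tail]))
            onsets.append(demix_onset(traj))
        out[ox] = (float(np.mean(n_links)), float(np.mean(onsets)))
    return out
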