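"""Ground-truth generators for the demixing pipeline.

Two generators cover the pipeline's inputs:

* :func:`make_toy_chain_pair` builds a sticker-spacer-like *client* chain
  carrying a self-attractive block (a hydrophobic-patch stand-in) and two
  reactive cysteine-like beads, plus a uniform moderately sticky *scaffold*
  chain, together with a toy CG parameter table in reduced units (sigma = 1
  nm, mass = 1 amu, epsilon = 1 kJ/mol, kT = 1 kJ/mol).
* :func:`make_demixing_series` renders a two-channel condensate time-lapse
  in which the client channel redistributes into puncta that exclude the
  scaffold after a programmable onset, with Poisson photon noise and
  Gaussian camera noise.  The returned ground-truth record carries the
  noise-free frames, the true masks and the programmed kinetics, so every
  imaging readout can be computed without running the estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cg_engine import KB, ForceFieldConfig
from .demix_imaging import ImageSeries
from .sequence_model import CGBeadParams, DomainAnnotation, ProteinChainSpec

__all__ = [
    "DemixingGroundTruth",
    "SyntheticImageParams",
    "SyntheticSequenceParams",
    "make_demixing_series",
    "make_toy_chain_pair",
    "toy_forcefield",
]


# ---------------------------------------------------------------------------
# Toy chains


@dataclass(frozen=True)
class SyntheticSequenceParams:
    """Conditions for the toy client/scaffold chain pair.

    The client carries a sticky block (residues ``block``) at ``block_lambda``
    on a ``background_lambda`` backbone, with reactive cysteine stand-ins at
    ``reactive_positions``; the scaffold is uniform at ``scaffold_lambda``.
    Defaults give a 20-bead chain with a 6-bead block, the desk-scale
    analogue of a 414-residue chain with a 26-residue hydrophobic patch.
    """

    chain_length: int = 20
    block: tuple[int, int] = (12, 17)
    block_lambda: float = 1.0
    background_lambda: float = 0.45
    scaffold_lambda: float = 0.7
    reactive_positions: tuple[int, ...] = (8, 10)
    n_client_chains: int = 10
    n_scaffold_chains: int = 10
    sigma_nm: float = 1.0
    mass_amu: float = 1.0
    charge: float = 0.0

    def __post_init__(self) -> None:
        s, e = self.block
        if not (1 <= s <= e <= self.chain_length):
            raise ValueError(f"block {self.block} outside chain of length {self.chain_length}")
        for p in self.reactive_positions:
            if not (1 <= p <= self.chain_length):
                raise ValueError(f"reactive position {p} outside chain")
            if s <= p <= e:
                raise ValueError(f"reactive position {p} inside the sticky block")
        for lam in (self.block_lambda, self.background_lambda, self.scaffold_lambda):
            if lam < 0:
                raise ValueError("lambda levels must be >= 0")


def make_toy_chain_pair(
    params: SyntheticSequenceParams, seed: int = 0
) -> tuple[ProteinChainSpec, ProteinChainSpec, dict[str, CGBeadParams]]:
    """Build (client, scaffold) chain specs plus their CG table.

    Residue letters encode bead types: ``A`` background, ``F`` sticky block,
    ``C`` reactive cysteine stand-in, ``S`` scaffold.  Construction is
    deterministic; ``seed`` is recorded for provenance symmetry with the
    other generators.
    """
    s, e = params.block
    letters = ["A"] * params.chain_length
    for i in range(s - 1, e):
        letters[i] = "F"
    for p in params.reactive_positions:
        letters[p - 1] = "C"
    client = ProteinChainSpec(
        name="client",
        residues="".join(letters),
        domains=(DomainAnnotation("HP", s, e),),
        reactive_cysteines=frozenset(params.reactive_positions),
    )
    scaffold = ProteinChainSpec(
        name="scaffold",
        residues="S" * params.chain_length,
    )
    mk = lambda lam: CGBeadParams(
        sigma=params.sigma_nm, lam=lam, charge=params.charge, mass=params.mass_amu
    )
    table = {
        "A": mk(params.background_lambda),
        "F": mk(params.block_lambda),
        "C": mk(params.background_lambda),
        "S": mk(params.scaffold_lambda),
    }
    return client, scaffold, table


def toy_forcefield(**overrides) -> ForceFieldConfig:
    """Reduced-unit force field matched to the toy table.

    epsilon = 1 kJ/mol and T chosen so kT = 1 kJ/mol; bonds of length
    sigma; timestep at ~3% of the bond period.
    """
    defaults = dict(
        epsilon=1.0,
        ah_cutoff=3.0,
        dh_cutoff=3.0,
        debye_length=1.0,
        dielectric=80.0,
        bond_k=100.0,
        bond_r0=1.0,
        temperature=1.0 / KB,
        friction=0.1,
        timestep=0.015,
    )
    defaults.update(overrides)
    return ForceFieldConfig(**defaults)


# ---------------------------------------------------------------------------
# Synthetic demixing image series


@dataclass(frozen=True)
class SyntheticImageParams:
    """Conditions for the synthetic two-channel demixing time-lapse.

    The client redistributes into puncta between ``onset_h`` and
    ``onset_h + ramp_h`` (smooth ramp, exactly zero before onset), reaching
    ``enrichment`` times the mixed-phase client intensity; scaffold inside
    puncta decays complementarily by ``scaffold_exclusion``.  Frames default
    to one per hour over 10 h, echoing in vitro demixing timecourses.
    Photon noise is Poisson with ``photons_per_unit`` counts per intensity
    unit (0 disables); camera noise is Gaussian with ``gaussian_sd``.
    """

    shape: tuple[int, int] = (128, 128)
    n_condensates: int = 3
    condensate_radius_px: float = 14.0
    dome: float = 0.15  # relative centre-to-edge intensity fall-off
    speckle_amplitude: float = 0.25  # internal texture shared by both channels
    speckle_sigma_px: float = 3.0  # texture correlation length
    n_puncta: int = 3
    punctum_radius_px: float = 4.0
    enrichment: float = 3.0
    scaffold_exclusion: float = 1.0
    onset_h: float = 5.0
    ramp_h: float = 1.0
    n_frames: int = 11
    frame_interval_h: float = 1.0
    scaffold_amplitude: float = 100.0
    client_amplitude: float = 80.0
    background_level: float = 5.0
    photons_per_unit: float = 0.0
    gaussian_sd: float = 0.0
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        duration = (self.n_frames - 1) * self.frame_interval_h
        if not (0 < self.onset_h <= duration):
            raise ValueError("onset must fall within the series duration")
        if self.ramp_h <= 0:
            raise ValueError("ramp must be positive")
        if self.scaffold_exclusion < 0 or self.scaffold_exclusion > 1:
            raise ValueError("scaffold_exclusion must lie in [0, 1]")


@dataclass
class DemixingGroundTruth:
    """Everything needed to predict the imaging readouts without estimators."""

    clean_frames: np.ndarray  # (T, 2, H, W) noise-free images
    condensate_labels: np.ndarray  # (H, W) static geometry
    puncta_labels: np.ndarray  # (H, W)
    timestamps: np.ndarray  # h
    segregation: np.ndarray  # phi(t) in [0, 1]
    onset_h: float
    ramp_h: float
    enrichment: float
    expected_mixed_mean: np.ndarray  # background-subtracted client, per frame
    expected_demixed_mean: np.ndarray
    seed: int
    params: SyntheticImageParams = field(repr=False, default=None)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _place_disks(
    rng: np.random.Generator,
    n: int,
    radius: float,
    shape: tuple[int, int],
    margin: float,
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping disk centres."""
    centers: list[tuple[float, float]] = []
    H, W = shape
    for _ in range(4000):
        if len(centers) == n:
            break
        c = (margin + rng.random() * (H - 2 * margin),
             margin + rng.random() * (W - 2 * margin))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > (2 * radius + 2) ** 2 for o in centers):
            centers.append(c)
    if len(centers) < n:
        raise RuntimeError("could not place non-overlapping disks; reduce count or radius")
    return centers


def make_demixing_series(
    params: SyntheticImageParams, seed: int
) -> tuple[ImageSeries, DemixingGroundTruth]:
    """Render the two-channel series plus its ground-truth record.

    Condensates are smooth intensity domes modulated by a static speckle
    texture (condensate-internal heterogeneity); the texture is shared by
    both channels, so the noise-free pre-onset Pearson correlation is
    exactly 1 and the correlation survives realistic photon noise the way
    structured microscopy images do.  After onset the client mass
    redistributes into puncta
    under a smooth ramp with total client intensity per condensate conserved
    before noise; scaffold intensity inside puncta decays complementarily
    with scaffold mass likewise conserved.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    H, W = params.shape
    R = params.condensate_radius_px
    yy, xx = np.mgrid[0:H, 0:W]

    texture = np.ones((H, W))
    if params.speckle_amplitude > 0:
        g = gaussian_filter(rng.standard_normal((H, W)), params.speckle_sigma_px)
        texture = 1.0 + params.speckle_amplitude * g / g.std()
        texture = np.clip(texture, 0.1, None)

    centers = _place_disks(rng, params.n_condensates, R, params.shape, margin=R + 4)
    cond_labels = np.zeros((H, W), dtype=np.int32)
    punc_labels = np.zeros((H, W), dtype=np.int32)
    dome = np.zeros((H, W))
    punc_lbl = 0
    for k, c in enumerate(centers, start=1):
        d2 = (yy - c[0]) ** 2 + (xx - c[1]) ** 2
        inside = d2 <= R**2
        cond_labels[inside] = k
        dome[inside] = 1.0 - params.dome * d2[inside] / R**2
        # puncta on a ring at 0.45 R, equally spaced, random rotation:
        # guarantees separation from each other and the condensate rim
        theta0 = rng.random() * 2 * np.pi
        pcs = [
            (c[0] + 0.45 * R * np.sin(theta0 + 2 * np.pi * m / params.n_puncta),
             c[1] + 0.45 * R * np.cos(theta0 + 2 * np.pi * m / params.n_puncta))
            for m in range(params.n_puncta)
        ]
        for pc in pcs:
            punc_lbl += 1
            pd2 = (yy - pc[0]) ** 2 + (xx - pc[1]) ** 2
            punc_labels[(pd2 <= params.punctum_radius_px**2) & inside] = punc_lbl

    timestamps = np.arange(params.n_frames) * params.frame_interval_h
    phi = _smoothstep((timestamps - params.onset_h) / params.ramp_h)

    T = params.n_frames
    clean = np.zeros((T, 2, H, W))
    exp_mixed = np.full(T, np.nan)
    exp_demixed = np.full(T, np.nan)
    E = params.enrichment
    alpha = params.scaffold_exclusion
    P = (punc_labels > 0).astype(float)
    for t in range(T):
        sc = np.full((H, W), params.background_level, dtype=float)
        cl = np.full((H, W), params.background_level, dtype=float)
        for k in range(1, params.n_condensates + 1):
            sel = cond_labels == k
            d = dome * texture * sel
            psel = P * sel
            # client: mass-conserving redistribution into puncta
            weight_c = d * (1.0 + phi[t] * (E - 1.0) * psel)
            norm_c = d.sum() / weight_c.sum()
            cl[sel] += params.client_amplitude * norm_c * weight_c[sel]
            # scaffold: complementary exclusion from puncta, mass conserved
            weight_s = d * (1.0 - phi[t] * alpha * psel)
            norm_s = d.sum() / weight_s.sum()
            sc[sel] += params.scaffold_amplitude * norm_s * weight_s[sel]
        clean[t, 0] = sc
        clean[t, 1] = cl
        mixed_sel = (cond_labels > 0) & (punc_labels == 0)
        punc_sel = punc_labels > 0
        exp_mixed[t] = clean[t, 1][mixed_sel].mean() - params.background_level
        exp_demixed[t] = clean[t, 1][punc_sel].mean() - params.background_level

    noisy = clean.copy()
    if params.photons_per_unit > 0:
        noisy = rng.poisson(noisy * params.photons_per_unit) / params.photons_per_unit
    if params.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, params.gaussian_sd, size=noisy.shape)
    noisy = np.clip(noisy, 0.0, None)

    series = ImageSeries(
        frames=noisy,
        timestamps=timestamps,
        pixel_size_um=params.pixel_size_um,
        scaffold_channel=0,
        client_channel=1,
    )
    truth = DemixingGroundTruth(
        clean_frames=clean,
        condensate_labels=cond_labels,
        puncta_labels=punc_labels,
        timestamps=timestamps,
        segregation=phi,
        onset_h=params.onset_h,
        ramp_h=params.ramp_h,
        enrichment=E,
        expected_mixed_mean=exp_mixed,
        expected_demixed_mean=exp_demixed,
        seed=seed,
        params=params,
    )
    return series, truth
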