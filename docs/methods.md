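# Methods

## Coarse-grained model

One bead per residue. Bead parameters (σ in nm, stickiness λ, charge in e,
mass in amu) come from a per-residue table; the bundled default
(`demixsim/data/hps_params.tsv`) is an HPS-style hydropathy-scale set of the
kind standard for residue-level simulations of disordered-protein phase
separation. The table is data, not code: any table with the same columns can
be swapped in, which is also how the reduced-unit toy systems used in the
tests are parameterised.

Nonbonded interactions are the Ashbaugh–Hatch form: below the
Lennard-Jones minimum 2^{1/6}σᵢⱼ the potential is Φ_LJ + (1 − λᵢⱼ s)ε
(full repulsive core regardless of stickiness); beyond it the attractive
branch is scaled by λᵢⱼ s. Combining rules are arithmetic means for both σ
and λ. Charged beads additionally interact through a Debye–Hückel screened
Coulomb term (relative permittivity and screening length configurable).
Both terms are truncated and shifted to zero at their cutoffs, so the
potential is continuous everywhere; the well depth is −λε up to the
(small) shift. Bonds are harmonic springs; directly bonded pairs are
excluded from the nonbonded sum. Internally the unit system is
nm/ps/amu/kJ·mol⁻¹, which is self-consistent (1 kJ/mol = 1 amu·nm²·ps⁻²).

**Homotypic scaling.** A `ScaleRule` multiplies λᵢⱼ by a factor s where
*both* beads belong to the named species and fall inside the rule's residue
interval. Cross-species pairs are never scaled. This isolates "homotypic
interaction strength" as a single scanned knob: with arithmetic-mean
combining and s = 1 the mixing enthalpy of two species is ideal at the
mean-field level, and s > 1 introduces the net homotypic preference that
drives intra-condensate demixing. The scale acts only on the attractive
branch, never on the repulsive core.

**Redox crosslinks.** Reactive (cysteine-like) beads may form harmonic
crosslinks (same k and r₀ as chain bonds). Once per attempt window — one
window per frame stride — every unbonded reactive pair within the capture
radius forms a bond with probability `oxidation_prob`, and every existing
crosslink breaks with probability `reduction_prob`; formation is evaluated
against the set of bonds present at window entry, pairs are visited in
random order, and a bead can hold at most one crosslink. By default only
intermolecular pairs are eligible. This is deliberately a kinetic toy
model of oxidation chemistry: `oxidation_prob` high ↔ oxidising conditions,
`reduction_prob` high ↔ reducing conditions; no attempt is made to model
thiol/disulfide equilibria quantitatively. Crosslinked pairs keep their
nonbonded interaction (the bond simply adds to it).

**Integration.** Underdamped Langevin dynamics with the BAOAB splitting.
With friction = 0 the O-step is the identity and the scheme reduces to
velocity Verlet, which is how the energy-conservation test runs. A
timestep check at run start requires dt ≤ 5% of the stiffest bond period
(reduced mass m/2); the default toy settings (k = 100 ε/σ², m = 1,
dt = 0.015 τ) sit at ~3%. Forces are computed with minimum-image periodic
distances over all pairs (dense O(N²) kernel, adequate for the
few-hundred-bead systems this package targets); positions are wrapped only
at frame output, unwrapped coordinates are used internally. Trajectories
record wrapped positions, energies, instantaneous temperature and the
crosslink set per frame, plus a config hash and seed for provenance.

**System builders.** Chains are grown as self-avoiding random walks (bond
length r₀, minimum-image overlap tolerance 0.9·min σ) inside a central
sphere (droplet) or a central z-slab (slab coexistence geometry), with
bounded retries and a packing error on failure. Initial velocities are
Maxwell–Boltzmann at the configured temperature. The insertion tolerance
trades packing success against the size of the initial potential-energy
transient; 0.9σ keeps the worst initial contact near 7ε, which the
thermostat dissipates within a few hundred steps.

## Trajectory observables

**Demixing order parameter.** Per frame, beads are clustered by
single-linkage at the contact cutoff (default 1.5·max σ; connected
components of the contact graph), so droplet identification and contact
definition share one length scale. The droplet centre is the largest
cluster's centre of mass, computed with the circular-mean construction so
it is well defined under periodic boundaries. Chain concentrations
(bead count ÷ chain length ÷ sphere volume — correct for species of unequal
length) of both species are measured in a sphere of radius 0.5·R_g of the
cluster (the droplet centre is not otherwise sharply defined; half the
radius of gyration samples the core while keeping counts usable).
Production frames are split into n contiguous blocks (default 5); each
block's ratio is the ratio of block-mean concentrations, and the score is
the block mean ± SEM (SD over blocks / √n). Ratio 1 = well mixed; → 0 =
client-dominated core. With ~20 chains the centre sphere holds only a few
chain-equivalents, so block ratios carry substantial counting noise and
decorrelate slowly; the reported SEM reflects this honestly, and scans
average over seeds. A frame-resolved variant (`concentration_series`)
supports onset-time detection; because single-frame ratios are noisy,
onset detection smooths the series and requires a sustained crossing.

**Contact maps.** A contact is a bead pair on different chains within the
cutoff (minimum image). Entry (i, j) counts ordered contacts (residue i on
a species-A chain, residue j on a species-B chain), averaged per frame and
normalised by the number of A chains; for A = B the ordered convention
makes the map symmetric by construction. The brute-force O(N²) oracle in
the tests uses the same convention.

**RMSF.** Each selected chain is made whole across the periodic boundary,
optionally superposed (Kabsch) onto its first-frame interval coordinates,
and RMSF_i = √⟨|rᵢ(t) − ⟨rᵢ⟩|²⟩ is computed about the time-mean structure.
Profiles aggregate as mean ± SD across chains (condensed phase); for
dilute-phase statistics, run one chain per replica and aggregate outside.
For per-axis Gaussian jitter of SD g the expected RMSF is g√3, which the
tests verify.

**Density profiles.** Axial histograms averaged over frames, with the
largest cluster recentred to the box midpoint per frame (a rigid periodic
shift, so the profile integral is conserved exactly); per-species number
density and chain concentration are reported.

## Imaging quantification

Condensates are segmented on the scaffold channel: Gaussian smoothing
(σ = 2 px), Otsu threshold, minimum area 20 px, connected-component
labels. Client puncta use a lighter smoothing (σ = 1 px, since puncta are
small and heavy smoothing biases their intensity), an Otsu threshold
computed from client pixels inside condensates only, a 4 px minimum area,
and are clipped to condensate interiors. Pearson correlation is computed
within condensate masks only — the scientific question is *intra*-condensate
mixing, so background pixels must not inflate r. Frame-level r(t) is the
area-weighted mean over condensates; condensates with undefined correlation
(zero variance) are skipped and a frame with no valid condensate yields a
missing value rather than an error.

The demixing classification uses a threshold of 0.85 with a persistence of
2 consecutive frames (single-frame noise dips should not count as
demixing; the persistence rule is this package's choice). t_demix is the
first timestamp of the first sustained sub-threshold run; R_end is the
correlation at the final timepoint. Phase intensities subtract the
background (median client intensity outside all condensates) and report
mean client intensity in the mixed region (condensate minus puncta) and
demixed region (puncta), plus their ratio. Note the punctum detector will
happily report texture-driven "puncta" in a well-mixed condensate with
internal heterogeneity; the enrichment ratio near 1 in that regime is the
meaningful readout, not the punctum count.

## Synthetic data

**Toy chains.** The client is a 20-bead chain with a 6-bead sticky block
(residues 12–17, λ = 1.0) on a weakly sticky backbone (λ = 0.45) and two
reactive beads (positions 8 and 10) — the desk-scale analogue of a long
disordered protein with a short self-associating element and two exposed
cysteines. The scaffold is uniform at λ = 0.6, chosen so the scaffold
condenses on its own and the client's *mean* stickiness is slightly above
the scaffold's (0.615 vs 0.6): at s = 1 the droplet is near-mixed, and
raising s demixes the client into the core. Reduced test units: σ = 1 nm,
m = 1 amu, ε = 1 kJ/mol, T chosen so kT = ε.

**Image series.** Condensates are smooth intensity domes (15%
centre-to-edge fall-off) modulated by a static speckle texture (Gaussian-
filtered white noise, amplitude 0.25, correlation length 3 px) shared by
both channels — condensate-internal heterogeneity that lets Pearson
correlation survive realistic noise the way structured micrographs do,
while keeping the noise-free pre-onset correlation exactly 1 (the two
channels are affinely related). After the onset time the client
redistributes into fixed puncta under a smooth ramp that is exactly zero
before onset and exactly 1 after onset + ramp; punctum client intensity
reaches `enrichment` × the mixed-phase level, scaffold inside puncta decays
complementarily, and both channels conserve per-condensate mass before
noise. The ramp is a clipped smoothstep rather than an unbounded sigmoid so
that pre-onset frames are *exactly* mixed — this makes the ground truth
unambiguous for recovery tests. Noise is Poisson (configurable photons per
intensity unit) plus Gaussian read noise, then clipped at zero. Defaults:
3 condensates of radius 14 px in 128², 3 puncta each (radius 4 px on a ring
at 0.45 R), enrichment 3, onset 5 h, ramp 1 h, 11 frames at 1 h — echoing
the hour-scale granularity of in vitro demixing timecourses. The ground
truth record (clean frames, true masks, ramp, enrichment) suffices to
compute every imaging readout without the estimators.

What the generator does *not* emulate: optics (no PSF beyond Gaussian
blur), condensate motion/fusion, photobleaching, 3D sectioning, or
punctum nucleation kinetics (punctum sites are fixed from t = 0). Passing
recovery tests therefore demonstrates estimator correctness on clean
phenomenology, not robustness to all real-microscopy artefacts.

## Test-scale study conditions

CI-scale simulations use 10 + 10 chains × 20 beads in a 30 nm box and
3–6 × 10⁴ Langevin steps (the full 414-residue, µs-scale configuration is
supported but not exercised in the test suite). The homotypic scan runs
s ∈ {1, 1.5, 2} plus a block-less client (sticky block λ lowered to the
backbone level — the ΔHP analogue), three seeds each; the expected ordering
is block-less ≥ s=1 > s=1.5 > s=2 in the centre ratio. The redox sweep
runs oxidation probability {0, 0.1, 1} at a marginal homotypic scale
(s = 1.15) chosen so the un-crosslinked control demixes slowly relative to
the run length — a prerequisite for resolving onset acceleration; onset is
detected on a smoothed concentration-ratio series with a sustained-crossing
rule. The well-mixed acceptance control uses two identically parameterised
species (uniform λ = 0.65, which keeps the droplet compact enough for
stable centre statistics; the expected ratio is exactly 1 by label symmetry
regardless of λ) and longer production, since the centre-sphere estimator
is noisy at 20 chains.

## Known limitations

* The O(N²) force kernel is not meant for thousands of beads; a cell list
  would be the next step.
* The demixing order parameter is noisy for small droplets; treat single-
  seed values as qualitative and use seed averages for comparisons.
* The redox model has no chemistry (no pKa, no glutathione species); it
  reproduces directional trends only.
* Imaging segmentation assumes bright condensates on a dark background and
  roughly disk-like puncta; it has no illumination-correction step.
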