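# Methods

## Geometry

The cell model is a pair of concentric spheres — nucleus radius 5 µm,
cell radius 12.5 µm — at the centre of a planar 3×3 grid of touching
cells (pitch 25 µm) immersed in a cube of culture medium whose volume is
200 µL (side 5.85 mm). The grid arrangement is a modelling choice: the
9-cell layout's spacing and dimensionality are not otherwise
constrained, and at electron ranges far below a millimetre the medium
shape is irrelevant, so the simplest planar reading was adopted. Only
the central cell emits; the eight neighbours are tallied in aggregate as
cross-dose and never folded into the per-cell dose.

Gold enters by volume equivalence with the nanoparticle inventory
(N = 2.83×10⁸ spheres of 4 nm): either a central sphere of radius
(N)^{1/3}·d/2 ≈ 1.3 µm, or a shell around the nucleus of thickness
t = V/(4πr²) ≈ 30 nm (the exact cubic solution differs by <1% and is
available). In shell mode, six 10 nm water scoring shells tile 0–60 nm
outside the gold surface; they exist at identical radii in the
with-gold and without-gold variants so enhancement ratios compare like
with like.

## Source term

The bundled ¹⁷⁷Lu inventory uses a three-branch allowed-shape beta
spectrum (endpoints 497.8/385.4/176.5 keV, intensities 0.793/0.090/0.117)
with the relativistic point-charge Fermi correction for the Hf daughter,
tabulated per keV; its first moment is 134.2 keV, within 1% of the
standard 133.3 keV. Auger/Coster–Kronig emission is a six-line list;
IC electrons, X-rays and gammas are single average-energy lines
(110 keV × 0.12, 2.5 keV × 0.15, 172 keV × 0.166). The IC and gamma
averages are implementer-chosen to reproduce the standard per-decay
energy budget (≈13 keV IC, ≈29 keV photons); only the 2.5 keV X-ray
average is fixed by the study design. All of these are plain-text CSVs
regenerated by `scripts/make_fixtures.py`, and any alternative inventory
in the same format can be loaded. Energies below 100 eV are disallowed
in fixtures — transport would deposit them on the spot anyway.

## Transport

Electrons follow straight-line CSDA tracks: the collision stopping power
S(E) (relativistic Bethe above a validity cut — 1 keV for water, 20 keV
for gold — with anchored power-law extensions below, log–log
interpolated) is integrated segment-by-segment across region boundaries
using precomputed range/energy tables. Knock-on (delta-ray) electrons
above a 0.25 keV production threshold are sampled from the 1/T² Møller
spectrum with the proper linear density per material and transported
recursively; their energy is subtracted from the local segment deposit,
so energy balance is exact. There is no multiple-scattering deflection
and no energy straggling. This is a known bias — backscatter-sensitive
quantities and depth–dose shapes are not trustworthy — but
energy-deposition *fractions* in spheres micrometres across, which is
all the dosimetry consumes, are insensitive to track tortuosity at the
few-percent level. Electron cutoff: 0.1 keV, deposited locally.

Photons undergo photoelectric absorption and incoherent scattering
(Klein–Nishina, Kahn sampling); coherent scattering and bremsstrahlung
are omitted. Photoelectric absorption in gold resolves the deepest
accessible edge (M 2.21 keV, L 11.92 keV, K 80.7 keV): a photoelectron
of E−E_bind is emitted, a fluorescence photon with the tabulated yield
(0.03/0.35/0.96) may carry part of the binding energy, and the remainder
becomes an Auger burst split (0.92, 0.04, 0.04) — the dominant fraction
reflects that a gold M-vacancy relaxes mainly through a single M-N,N
Auger electron of ≈2.0 keV, the N-shell bindings being only tens of eV,
followed by a soft cascade that is effectively local. In water the
binding energy (0.54 keV) is deposited locally. Photon cutoff: 1 keV.

Attenuation coefficients are piecewise power laws anchored to standard
tabulated values (gold with explicit M/L/K edge discontinuities; checked
against reference values at 1, 10 and 100 keV to ~10%), plus the
analytic Klein–Nishina incoherent cross section. Given the declared
±50% comparison band for enhancement factors, this fidelity is adequate
and keeps the data bundle self-contained.

Forced interaction: a photon crossing the gold shell is split into a
collided branch (weight 1−e^{−µL}, interaction depth sampled from the
truncated exponential) and an uncollided branch (weight e^{−µL}); the
analog free-path sampling then treats the shell as transparent. The
scheme is unbiased (verified against analog runs) and is what makes
10 nm shell tallies from µm-distant sources feasible at desk scale.

Every run draws all randomness from one seeded `numpy` Generator; per
history, deposited + escaped energy is asserted equal to emitted energy
to 10⁻⁹ relative.

## Dosimetry

S-values divide the tallied energy per decay in a target (nucleus, any
shell, or the whole cell — tracked as a per-history aggregate so its
variance keeps cross-region covariance) by the target mass. The
cumulated activity uses the exact mean-life constant 1/ln 2 = 1.4427
rather than the rounded 1.44, so it agrees with the numerical integral
of A₀e^{−λt} to 10⁻⁹; to three significant figures the two coincide.

Activity in the medium irradiates the cell at the uniform-bath
charged-particle-equilibrium rate: absorbed energy per decay over the
bath mass, with electrons fully absorbed (ranges ≤ 2 mm versus a 2.9 mm
half-side) and photon energy weighted by 1−e^{−µ_en·ℓ̄} over the cube
mean chord ℓ̄ = 2a/3. An analog estimate of the medium→cell S-value is
statistically hopeless (geometric efficiency ≈ 4×10⁻⁸), and the
equilibrium value is the correct limit here; the approximation errs by
at most the photon share (≈3% of the per-decay energy).

Per-cell activity of an internalized compartment follows the
`volume_share` convention by default — fraction × A₀ × V_cell/V_medium,
the literal "200 µL of medium and a 25 µm cell diameter" reading — with
`per_seeded_cell` (fraction × A₀ / N seeded cells; 50,000 clonogenic,
20,000 MTT) as an alternative, because the underlying protocol text
supports both readings. The choice matters enormously: V_cell/V_medium
is 4×10⁻⁸ whereas 1/50,000 is 2×10⁻⁵, so the internalized-compartment
terms differ by ~500×. Under `volume_share` the targeted-scenario to
medium-only dose ratios are dominated by the medium terms (the efflux
scenarios sit at the analytic 0.3 + 0.7·Ã(14 d)/Ã(4 h) ≈ 31.5); under
`per_seeded_cell` the nucleus/cytoplasm terms dominate and the same
ratios reach several hundred. Both conventions are exposed and tested;
reported numbers state which one they used.

Scenario durations are the assay protocols: internalized compartments
decay for the assay length plus the 4 h incubation (clonogenic
14 d + 4 h, MTT 72 h + 4 h), medium terms for the 4 h incubation, and in
the efflux variants the internalized fraction decays inside for 4 h and
then in the medium for the assay remainder, taken literally at its
initial activity (the ~1.7% physical decay during incubation is below
every tolerance used).

## Dose enhancement

DEᵢ = Dᵢ(gold)/Dᵢ(water) per shell, from paired arms that share the
seed (common random numbers) so source-sampling variance cancels; the
standard error propagates both arms' tally errors. When the gold-arm
material is set to water the two arms are bitwise identical and DE ≡ 1,
which the suite asserts. The declared reproduction tolerance for the
reference DE values is ±50%: the simplified one-line relaxation cannot
match a full atomic-relaxation cascade in detail, and the qualitative
structure — X-rays far above the electron components near the shell,
monotone decay with distance — is the strict requirement.

## Assay statistics and synthetic data

PE and SF follow the standard clonogenic normalization (the commonly quoted SF
formula is ambiguous about the percent scale of PE; the implementation
uses colonies/(seeded·PE/100), the only reading under which the
untreated control is 100%). The optional exponential fit regresses
log SF on dose through the origin with inverse-variance weights equal to
the colony counts (var log N ≈ 1/N for Poisson) and a
dispersion-inflated t-interval; simulation shows ~95–97% CI coverage,
versus ~80% unweighted. The fit is an extension switch, off by default.

The uptake generator is F(1−e^{−k_in t})·e^{−k_out·max(0,t−t_peak)} with
replicate Gaussian noise truncated to [0, 100]%; t_peak defaults to the
95%-rise time, one interpretable parameter reproducing the observed
plateau-then-decline shape. Cell-line presets (U87/T98G/U373 with
plateaus 30/55/80%) mirror the qualitative ordering of the measured
lines. Colony counts are Poisson around seeded·PE/100·e^{−αD−βD²};
MTT absorbances are control·viability(D) plus truncated Gaussian noise.
The generators reproduce the statistical structure the estimators
assume — they do not emulate plate-position effects, counting bias in
dense wells, or receptor-mediated uptake kinetics, so passing tests
demonstrate estimator correctness, not biological realism.

## Problem sizes and determinism

The test suite runs at reduced history counts (hundreds to 1.5×10⁵
depending on the tally) chosen so every stochastic assertion sits at
≥3σ resolution; the acceptance script uses 6×10⁵ photon histories for
the X-ray enhancement profile, 10⁵ per electron component, and 2.5×10⁴
decays per Monte Carlo S-value source. Identical seeds give identical
outputs bit for bit, including across the paired enhancement arms.

## Known limitations

No multiple scattering, straggling, bremsstrahlung or coherent
scattering; single-line atomic relaxation per edge; attenuation data
accurate to ~10–30% between anchor points (within the declared DE band);
medium dose by equilibrium rather than transport; cross-dose between
neighbouring cells reported but not added to per-cell dose; absolute
per-cell doses inherit the per-cell activity convention ambiguity
described above.
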