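# Methods

This note documents the models, conventions and numerical choices the
package implements, what the synthetic fixtures do and do not emulate,
and the known limitations.

## System and units

Internal units are Å, ps, amu, kcal/mol and elementary charges; with
these, 1 kcal/mol = 418.4 amu·Å²/ps², which is the only conversion the
integrator needs.  Temperatures use k_B = 8.6173·10⁻⁵ eV/K
(1.98722·10⁻³ kcal/(mol·K)); the Coulomb constant is
332.0637 kcal·Å/(mol·e²); 1 kcal/mol = 0.0433641 eV.

An `AtomSystem` stores Cartesian positions, velocities, masses,
charges, species labels, an explicit bond list, a triclinic box (3×3
row-vector matrix with per-axis periodic flags) and group bookkeeping:
each atom is crystal ("HAP") or water ("WAT"), and every channel
hydroxyl carries an integer ion id shared by its O and H atoms.  All
atom indices are 0-based.

## Crystal construction

The hexagonal P6₃ hydroxyapatite cell (a = b = 9.417 Å, c = 6.875 Å,
γ = 120°) is built from a 44-site basis shipped as editable YAML.  The
basis was generated from classical apatite Wyckoff generators
(Kay–Young–Posner-type coordinates: Ca at 4f and 6h, P and two O at 6h,
O at 12i, hydroxyl O and H on the 6₃ axis) expanded under the six P6₃
symmetry operations; expanding the hydroxyl sites under P6₃
automatically yields the ordered (polar) arrangement with both O→H
vectors parallel to c.  The `disordered` option flips every second
hydroxyl, mimicking the P6₃/m statistical phase.  The basis is
configuration, not an endorsement of any particular refinement: tests
check counts, stoichiometry (Ca₁₀P₆O₂₆H₂ per cell,
charge neutrality) and hydroxyl geometry, never specific coordinates.

Supercells are explicit basis replications (no symmetry engine): an
n_x×n_y×n_z tiling has 44·n_x·n_y·n_z atoms and 2·n_x·n_y·n_z tagged
hydroxyls; the 4×4×2 cell used throughout has 1408 atoms and 64 ions.
Construction enforces a minimum non-bonded distance of 1.2 Å (the
covalent O–H at ≈0.96 Å is a bonded exception).

Solvation places rigid three-site waters (O–H 0.9572 Å, H–O–H 104.52°)
by rejection sampling inside a shell of configurable thickness around
the solute's bounding box, with a 2.4 Å minimum approach during
packing; `n_waters="auto"` fills the shell at 0.997 g/cm³.  Placement
is deterministic for a fixed seed.  `expand_box` lengthens each cell
vector by a margin without touching coordinates (vapour headspace).
The published water-cell (53.40×31.94×13.87 Å) and computational-cell
(~76.49×57.37×38.24 Å) dimensions for the solvated 4×4×2 system differ
by ~23–25 Å per axis rather than exactly 25; the builder implements the
margin arithmetic exactly and makes no attempt to force agreement —
both sizes are accepted as inputs.

## Interactions

Config-driven molecular mechanics: point-charge Coulomb, Lennard-Jones
in two selectable forms, and harmonic bonds/angles.

* 12-6: U = 4ε[(σ/r)¹² − (σ/r)⁶] (minimum −ε at 2^{1/6}σ).
* 9-6: U = ε[2(r₀/r)⁹ − 3(r₀/r)⁶] (class-II convention, minimum −ε at
  r₀).  Which pairs use which form is a config decision; the shipped
  default uses 9-6 for Ca–Ca as an exercised example.
* Bonds U = k(r−r₀)², angles U = k(θ−θ₀)².
* Unlisted cross pairs are Lorentz–Berthelot mixtures of the self
  entries; explicit entries override; mixing across different LJ forms
  is refused.
* Non-bonded pairs separated by one (1-2) or two (1-3) bonds are
  excluded.

Periodicity uses the minimum-image convention with a plain cutoff
(default 10 Å, required < half the smallest periodic box length) and an
energy shift so U(cutoff) = 0.  This is a deliberate deviation from
Ewald-based production electrostatics: the package targets desk-scale
qualitative fidelity, and every quantitative acceptance check is
either closed-form arithmetic or an internal-consistency property, so
nothing depends on long-range corrections.  For orthorhombic cells the
minimum image is the usual per-axis rounding; for triclinic (hexagonal)
cells the rounded fractional image is refined over the 27 neighbouring
lattice shifts, which is exact for any cell shape.

The shipped HAP parameter set (charges Ca +1.6, P +1.0, phosphate O
−0.85, hydroxyl O −1.2/H +0.4, summing to zero per formula unit, with
generic ionic LJ radii) is a placeholder configuration: the force field
actually fitted for HAP in the source study is not published, so the
defaults are chosen to be physically plausible and numerically
well-behaved, and no reported quantity depends on their values.

Energies and forces are evaluated by a vectorised engine that resolves
species tables, exclusion masks and bonded parameter lists once per
topology; analytic gradients are verified against central differences
to 10⁻⁶ relative in the test suite.

## Dynamics

Velocity Verlet with default dt = 0.5 fs (stiff O–H springs set the
scale; the source study does not state its timestep).  The collisional
thermostat follows the stochastic-collision picture: each atom
independently suffers a collision in a step with probability
rate·dt — the Bernoulli discretisation of the Poisson kick process —
receiving Δv = 2m₀/(m₀+m)(v₀−v) with v₀ drawn from the Maxwell
distribution at T_ref (each component Gaussian, variance k_B·T_ref/m₀).
Collision rate (default 10 ps⁻¹ per atom) and virtual mass m₀ (default:
the struck atom's own mass, making every collision a full velocity
exchange — the fastest-equilibrating choice) are tunable; they set the
coupling time only, not the stationary distribution, and no reported
quantity depends on them.

Rigid waters are maintained by iterative SHAKE position projection and
RATTLE velocity projection to 10⁻⁸ Å (velocities are re-projected after
thermostat kicks).  A stiff-spring flexible-water fallback is available
by simply giving the water species bond/angle parameters and removing
the constraints.

Protocols: `run_nvt` holds T_ref fixed; `run_linear_heating` ramps
T_ref = T₀ + rate·t (the study conditions are 700 K + 0.1 K/ps over
7 ns, reaching 1400 K).  Frames are recorded every 1 ps by default,
matching the analysis convention; each frame stores positions,
velocities, box, time, T_ref and the instantaneous kinetic temperature
T = Σmv²/(N_dof·k_B) with N_dof = 3N − n_constraints.  All randomness
flows through one seeded generator per run, so equal seeds give
bit-identical trajectories.  Integration aborts with a diagnostic if
coordinates go non-finite or beyond 10⁶ Å.

Verified properties: with the thermostat off, total energy drifts by
less than 10⁻⁴ relative over 10⁴ steps on the toy crystal and momentum
is conserved to round-off; with it on, the kinetic temperature is
driven to the setpoint and the stationary velocity distribution passes
a Kolmogorov–Smirnov test against the Maxwell form at α = 0.01.

## Detachment counting

The ledger algorithm: V is a zero vector with one slot per hydroxyl
ion.  At every frame the minimum distance from each ion to the
remaining crystal atoms is computed under minimum image; if it exceeds
the threshold (5 Å) the slot latches to 1 permanently, and ΣV(t) is the
cumulative number of ions that have ever detached — monotone
non-decreasing for any trajectory, which a property test enforces on
random trajectories.

Two readings were genuinely open and are both config flags, with these
defaults:

* "distance from the OH ion" = minimum over **both** its O and H atoms
  (the conservative reading);
* the host set = all crystal atoms except the queried ion, **including**
  other hydroxyls, **excluding** water (water is not part of the
  crystal).

## Melting and onset detection

The radius of gyration Rg = √(Σmᵢ|rᵢ−r_com|²/Σmᵢ) of the crystal
selection is tracked per frame; melting (slab-to-globule collapse) is
flagged when the boxcar-smoothed series drops a configurable fraction
(default 10%) below the initial plateau, reporting the collapse time.
The smoothing window (5 frames) keeps 1%-level noise from triggering a
10% criterion (false-positive rate <5% over 100 noise-only series in
the tests).

The onset temperature of active ion escape is not given a detection
rule by the source study; the package's rule is: the smallest setpoint
where the sliding-window slope of the mean detachment curve exceeds a
threshold, defaults 50 K window and 0.02 ions/K, both configurable and
always reported alongside the estimate.

Replicate averaging returns the pointwise mean and standard error over
equal-length series, as used for the 16-run campaign averages.

## Removal-energy profiles and the uncertainty chain

The scan rigidly translates the chosen hydroxyl(s) along +c and records
single-point total energies on a user grid starting at the bound
position.  No relaxation is performed — the scan is then deterministic
and matches the "energy at each distance z" reading; a relaxed scan can
be layered on top by minimising between points but is deliberately not
the default.  Grid points where the moved ion comes closer than 1.2 Å
to a host atom are flagged but still reported.

|ΔE| is the plateau height: the mean of the last 10% of the grid minus
the bound energy, with the tail required to be flat (range < 1% of
|ΔE|), otherwise the scan refuses and advises a longer grid.  The
conversion chain is |ΔE₁| = |ΔE|/n_cells, eV = kcal/mol × 0.0433641,
T = |ΔE₁|/k_B.

Uncertainty model: the quantum position blur of a thermal atom is
Δz = ħ/√(2mk_BT) (≈0.155 Å for hydrogen at 1000 K); the energy error
Δ(E₀₁) is the maximum |E(z+Δz)−E(z)| over a 2 Å near-surface window
(the window starts at the profile's steepest point, Δz defaults to
0.2 Å), and the relative error is δ = (Δ(E₀₁)/2)/|ΔE|, treating
±Δ(E₀₁)/2 as the spread.  The thermostat temperature dispersion obeys
2σ² = T_ref, i.e. σ = √(T_ref/2) — dimensionally informal but
implemented verbatim as stated; the 3σ band is computed from the
formula (3·σ(1150 K) ≈ 71.9 K), not copied from any published rounding.

## Synthetic fixtures

`make_toy_crystal` builds a rock-salt-like lattice of ±0.4 e point
charges with 12-6 cores and embeds O–H diatomics (net −0.4 e, harmonic
bond k = 500 kcal/mol/Å², 0.96 Å) on top-surface anion sites so the +z
escape path is open.  The magnitudes put diatomic removal energies at
order 10–100 kcal/mol (the 8-cell/2-ion default measures ≈26 kcal/mol),
the same order as hydroxyl removal from the real mineral.  What it does
*not* emulate: apatite stoichiometry or symmetry, the phosphate
vibrational spectrum, water vapour, or any fitted energetics — so
passing tests demonstrate algorithmic correctness and qualitative
thermal-activation behaviour, not quantitative HAP predictions.

`make_scripted_trajectory` produces trajectories whose detachment
events are known by construction: scripted ions are rigidly displaced
so their measured minimum host distance crosses the event target
exactly at the event frame (found by bisection, self-verified after
construction by re-measuring with the same machinery the ledger uses);
other atoms get i.i.d. 0.02 Å Gaussian jitter.  "Returns at frame k"
events let tests pin the *ever-detached* latching semantics.

`make_velocity_ensemble` draws Maxwell velocities at a stated
temperature; `make_melting_rg_series` produces plateau-then-sigmoid Rg
series with controlled depth, centre and noise.  Every generator is
deterministic under a fixed seed.

## Problem sizes used in the checks

The automated checks run on desk-scale systems chosen to finish in
minutes on one core: the 66-atom toy crystal for energy conservation
(10⁴ steps), thermostat statistics (8 ps), and the
temperature-dominance property (three setpoints × 8 seeds × 6 ps);
scripted 20–80-frame trajectories for the ledger oracle; and pure
arithmetic for the dispersion/uncertainty chain.  The full-scale study
conditions (solvated 4×4×2 supercell, ~5,900 atoms, 16 replicates of
10 ns, fixed-T grid 800–1175 K in 25 K steps) are expressible with the
same code paths and the `protocol` driver, but their headline outcomes
(onset near 1150 K, ~10 ions detached at 1150 K, melting at ≥1500 K)
additionally depend on the unpublished fitted force field and are
therefore out of scope for automated verification here.

## Known limitations

* No Ewald/PME: shifted-cutoff electrostatics only.
* No barostat: box sizes are inputs (the published water-cell size came
  from an NPT equilibration outside this package's scope).
* No dihedrals or polarisation; the HAP model here needs neither.
* The published atom count for the 16×4×2 supercell (5465) is
  inconsistent with 128 × 44 = 5632; the builder reproduces the
  arithmetic (5632), not the printed figure.
* PDB I/O keeps positions to 10⁻³ Å and infers masses from element
  symbols (unknown species fall back to unit mass); extended XYZ is the
  canonical lossless format.
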