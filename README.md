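# hapthermal

Molecular-dynamics toolkit for studying **thermal dehydroxylation of
hydroxyapatite** — the loss of channel OH⁻ ions from Ca₁₀(PO₄)₆(OH)₂ on
heating — together with the analysis and uncertainty arithmetic that
turns raw trajectories into detachment counts, onset temperatures and
removal energies.  It is aimed at computational materials/biomineral
researchers who want a small, fully scriptable, reproducible pipeline
rather than a production MD engine.

## What it does

* **Geometry** — builds the hexagonal P6₃ HAP unit cell (44 atoms,
  a = b = 9.417 Å, c = 6.875 Å, two channel hydroxyls per cell) from an
  editable YAML basis, replicates it into supercells (4×4×2 → 1408
  atoms, 64 tagged OH ions), packs a rigid three-site water shell around
  the crystal and adds vacuum headspace for vapour.
* **Dynamics** — velocity-Verlet integration with a *collisional
  thermostat*: atoms undergo random elastic collisions with virtual
  particles whose velocities follow the Maxwell distribution at the
  setpoint T_ref,

  m dv/dt = F + Σₖ f·δ(t − tₖ),  Δv = 2m₀/(m₀+m) · (v₀ − v),

  with fixed-setpoint and linear-heating (T_ref = T₀ + rate·t)
  protocols.  Interactions are config-driven Coulomb + 12-6/9-6
  Lennard-Jones with harmonic bonds/angles under the minimum-image
  convention; rigid waters are handled by SHAKE/RATTLE.
* **Analysis** — the detachment ledger: a per-ion binary vector V that
  latches to 1 the first time an OH ion's minimum distance to the
  remaining crystal atoms exceeds 5 Å; ΣV(t) is the number of ions that
  have *ever* detached (monotone by construction).  Plus
  radius-of-gyration melting detection, replicate averaging (mean ±
  SEM), and onset-temperature estimation from the mean detachment
  curve.
* **Energy statistics** — rigid removal scans E(z) of hydroxyls
  displaced along the c axis, the plateau removal energy |ΔE|, per-cell
  conversion |ΔE₁| = |ΔE|/n_cells (kcal/mol → eV), the equivalent
  temperature T = |ΔE₁|/k_B, the thermostat dispersion σ = √(T_ref/2),
  the thermal quantum position blur Δz = ħ/√(2mk_BT) and the resulting
  relative error δ of the removal energy.

## Worked example

Build a 2×2×1 supercell, inspect the dispersion arithmetic, and scan a
removal profile on the bundled toy ionic crystal:

```bash
$ hapthermal build --nx 2 --ny 2 --nz 1 --out hap.extxyz
wrote 176 atoms (8 OH ions) to hap.extxyz

$ hapthermal stats --tref 1150
{"T_ref_K": 1150.0, "sigma_K": 23.98, "two_sigma_K": 47.96,
 "thermal_energy_eV": 0.0991, "dz_hydrogen_A": 0.1448}

$ hapthermal fixtures --out-dir fx --seed 1
$ hapthermal scan-energy fx/toy_crystal.extxyz fx/toy_forcefield.yaml \
      --ions 0 --z-max 14 --z-step 0.2 --n-cells 8 --out prof.csv
|dE| = 26.1970 kcal/mol; per cell 3.2746 kcal/mol = 0.1420 eV; T = 1648 K; delta = 0.026
```

Reading the output: at a 1150 K setpoint the collisional thermostat's
temperature dispersion is σ ≈ 24 K (so a detachment temperature read
from a heating curve carries a ±2σ ≈ ±48 K band), the thermal energy
per particle is ≈ 0.1 eV, and a hydrogen atom's quantum position blur
is ≈ 0.14 Å.  The scan pulls one tagged O–H diatomic out of the toy
crystal: the total energy rises by ≈ 26 kcal/mol before flattening —
that plateau height is the removal energy, which the summary converts
to a per-cell energy and the equivalent temperature at which thermal
energy alone could pay for it.  δ is the relative uncertainty induced
by the near-surface energy gradient over the position blur.

MD protocols run the same way from the shell:

```bash
hapthermal run-heat hap32.extxyz ff.yaml traj.extxyz \
    --t0 700 --rate 0.1 --tmax 7000 --seed 3
hapthermal analyze detach traj.extxyz --out detach.csv
```

or programmatically via `hapthermal.run_nvt`, `run_linear_heating`,
`detachment_series`, `removal_profile`, … — see `docs/methods.md` for
the model details and numerical choices.

## Layout

```
src/hapthermal/
  geometry.py     unit cell, supercells, solvation, headspace
  forcefield.py   pair/bond/angle energies and analytic forces
  dynamics.py     velocity Verlet + collisional thermostat, protocols
  analysis.py     detachment ledger, Rg, averaging, onset, melting
  energystats.py  removal profiles and the unit/uncertainty chain
  synthetic.py    toy crystals, scripted trajectories, fixtures
  trajectory.py   trajectory container + extended-XYZ I/O
  io.py           PDB I/O, run configs, replicate protocol driver
  cli.py          `hapthermal` command-line interface
  data/           editable basis + force-field YAML defaults
```
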