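# Default interaction parameters for the hydroxyapatite model species.
#
# This is a generic, charge-balanced parameter set shipped as editable
# configuration: the Lennard-Jones well depths/radii are plausible ionic
# values and the charges match the shipped unit-cell basis (they sum to
# zero per Ca10(PO4)6(OH)2 formula unit).  It is NOT a fitted production
# force field; swap in your own file for quantitative work.
#
# Species: Ca, P, O (phosphate), O_H/H_O (channel hydroxyl), O_W/H_W
# (water).  Unlisted cross pairs are Lorentz-Berthelot mixed from the
# self entries below; explicit entries override mixing.  The Ca self
# entry uses the 9-6 form (class-II convention, minimum -epsilon at r0);
# all others are 12-6.

coulomb_k: 332.0637
cutoff: 10.0
shift: true

charges:
  Ca: 1.6
  P: 1.0
  O: -0.85
  O_H: -1.2
  H_O: 0.4
  O_W: -0.834
  H_W: 0.417

pairs:
  - {species: [Ca, Ca], form: lj9-6, epsilon: 0.24, sigma: 3.4}
  - {species: [P, P], form: lj12-6, epsilon: 0.20, sigma: 3.7}
  - {species: [O, O], form: lj12-6, epsilon: 0.16, sigma: 3.0}
  - {species: [O_H, O_H], form: lj12-6, epsilon: 0.16, sigma: 3.0}
  - {species: [H_O, H_O], form: lj12-6, epsilon: 0.01, sigma: 1.0}
  - {species: [O_W, O_W], form: lj12-6, epsilon: 0.1521, sigma: 3.1507}
  - {species: [H_W, H_W], form: lj12-6, epsilon: 0.01, sigma: 1.0}
  # explicit cross entries where mixing two different forms is undefined
  - {species: [Ca, P], form: lj12-6, epsilon: 0.22, sigma: 3.55}
  - {species: [Ca, O], form: lj12-6, epsilon: 0.20, sigma: 3.2}
  - {species: [Ca, O_H], form: lj12-6, epsilon: 0.20, sigma: 3.2}
  - {species: [Ca, H_O], form: lj12-6, epsilon: 0.05, sigma: 2.2}
  - {species: [Ca, O_W], form: lj12-6, epsilon: 0.19, sigma: 3.27}
  - {species: [Ca, H_W], form: lj12-6, epsilon: 0.05, sigma: 2.2}

bonds:
  - {species: [O_H, H_O], k: 553.0, r0: 0.96}
  - {species: [O_W, H_W], k: 553.0, r0: 0.9572}

angles:
  - {species: [H_W, O_W, H_W], k: 100.0, theta0: 104.52}
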