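comment: Hexagonal P6_3 hydroxyapatite Ca10(PO4)6(OH)2 basis, 44 sites; Kay-Young-Posner-type
  apatite coordinates expanded under P6_3 symmetry operations. O_H/H_O are the channel
  hydroxyl atoms; both O->H vectors point along -c (ordered phase). Charges are a
  generic charge-balanced partial-charge set.
a: 9.417
b: 9.417
c: 6.875
gamma: 120.0
basis:
- species: Ca
  frac:
  - 0.333333
  - 0.666667
  - 0.001
  charge: 1.6
- species: Ca
  frac:
  - 0.666667
  - 0.333333
  - 0.501
  charge: 1.6
- species: Ca
  frac:
  - 0.666667
  - 0.333333
  - 0.999
  charge: 1.6
- species: Ca
  frac:
  - 0.333333
  - 0.666667
  - 0.499
  charge: 1.6
- species: Ca
  frac:
  - 0.2466
  - 0.9931
  - 0.25
  charge: 1.6
- species: Ca
  frac:
  - 0.0069
  - 0.2535
  - 0.25
  charge: 1.6
- species: Ca
  frac:
  - 0.7465
  - 0.7534
  - 0.25
  charge: 1.6
- species: Ca
  frac:
  - 0.7534
  - 0.0069
  - 0.75
  charge: 1.6
- species: Ca
  frac:
  - 0.9931
  - 0.7465
  - 0.75
  charge: 1.6
- species: Ca
  frac:
  - 0.2535
  - 0.2466
  - 0.75
  charge: 1.6
- species: P
  frac:
  - 0.3982
  - 0.3682
  - 0.25
  charge: 1.0
- species: P
  frac:
  - 0.6318
  - 0.03
  - 0.25
  charge: 1.0
- species: P
  frac:
  - 0.97
  - 0.6018
  - 0.25
  charge: 1.0
- species: P
  frac:
  - 0.6018
  - 0.6318
  - 0.75
  charge: 1.0
- species: P
  frac:
  - 0.3682
  - 0.97
  - 0.75
  charge: 1.0
- species: P
  frac:
  - 0.03
  - 0.3982
  - 0.75
  charge: 1.0
- species: O
  frac:
  - 0.3282
  - 0.4846
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.5154
  - 0.8436
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.1564
  - 0.6718
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.6718
  - 0.5154
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.4846
  - 0.1564
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.8436
  - 0.3282
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.5875
  - 0.4652
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.5348
  - 0.1223
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.8777
  - 0.4125
  - 0.25
  charge: -0.85
- species: O
  frac:
  - 0.4125
  - 0.5348
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.4652
  - 0.8777
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.1223
  - 0.5875
  - 0.75
  charge: -0.85
- species: O
  frac:
  - 0.3433
  - 0.2579
  - 0.0705
  charge: -0.85
- species: O
  frac:
  - 0.7421
  - 0.0854
  - 0.0705
  charge: -0.85
- species: O
  frac:
  - 0.9146
  - 0.6567
  - 0.0705
  charge: -0.85
- species: O
  frac:
  - 0.6567
  - 0.7421
  - 0.5705
  charge: -0.85
- species: O
  frac:
  - 0.2579
  - 0.9146
  - 0.5705
  charge: -0.85
- species: O
  frac:
  - 0.0854
  - 0.3433
  - 0.5705
  charge: -0.85
- species: O
  frac:
  - 0.3433
  - 0.2579
  - 0.4295
  charge: -0.85
- species: O
  frac:
  - 0.7421
  - 0.0854
  - 0.4295
  charge: -0.85
- species: O
  frac:
  - 0.9146
  - 0.6567
  - 0.4295
  charge: -0.85
- species: O
  frac:
  - 0.6567
  - 0.7421
  - 0.9295
  charge: -0.85
- species: O
  frac:
  - 0.2579
  - 0.9146
  - 0.9295
  charge: -0.85
- species: O
  frac:
  - 0.0854
  - 0.3433
  - 0.9295
  charge: -0.85
- species: O_H
  frac:
  - 0.0
  - 0.0
  - 0.1978
  charge: -1.2
- species: O_H
  frac:
  - 0.0
  - 0.0
  - 0.6978
  charge: -1.2
- species: H_O
  frac:
  - 0.0
  - 0.0
  - 0.05816
  charge: 0.4
- species: H_O
  frac:
  - 0.0
  - 0.0
  - 0.55816
  charge: 0.4
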