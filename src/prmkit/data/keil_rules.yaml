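# Context-dependent trypsin cleavage probabilities, Keil-style.
#
# A candidate site is the bond after any K or R (position P1).  Its
# probability is looked up as follows, most specific context first:
#   1. an `exceptions` entry matching the full (P2, P1, P1') triple,
#   2. an `exceptions` entry matching (P1, P1'),
#   3. the `p1prime` table keyed on the residue after the bond,
#   4. `default`.
# P2 is the residue before P1; at the protein C-terminus (no P1')
# nothing can block the site, so it scores `default`.
version: 1
default: 1.0
p1prime:
  # proline after the basic residue blocks cleavage
  P: 0.0
exceptions:
  # tryptic proline block is lifted in these contexts
  - {p2: W, p1: K, p1prime: P, probability: 0.60}
  - {p2: M, p1: R, p1prime: P, probability: 0.60}
  # reduced cleavage efficiency next to acidic / cysteine / basic residues
  - {p1: K, p1prime: D, probability: 0.45}
  - {p1: R, p1prime: D, probability: 0.55}
  - {p1: K, p1prime: C, probability: 0.60}
  - {p1: R, p1prime: C, probability: 0.60}
  - {p1: K, p1prime: K, probability: 0.70}
  - {p1: K, p1prime: R, probability: 0.70}
  - {p1: R, p1prime: K, probability: 0.70}
  - {p1: R, p1prime: R, probability: 0.70}
  - {p2: D, p1: K, p1prime: D, probability: 0.30}
  - {p2: C, p1: K, p1prime: D, probability: 0.30}
  - {p2: C, p1: K, p1prime: Y, probability: 0.50}
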