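"""Recompute the reference skin-AMP panel's precursor m/z values.

Loads the bundled 18-peptide panel (13 skin antimicrobial proteins) and
prints each light/heavy precursor pair, recomputed from sequence,
charge, fixed carbamidomethyl-C and the SIL label masses.
"""

from prmkit.assay import load_bundled_panel
from prmkit.masses import precursor_mz

panel = load_bundled_panel()
print(f"{'gene':8s} {'peptide':20s} z  light m/z  heavy m/z")
for t in panel.targets:
    print(
        f"{t.protein_gene:8s} {t.sequence:20s} {t.charge}  "
        f"{precursor_mz(t.light):9.4f}  {precursor_mz(t.heavy):9.4f}"
        + ("   <- " + t.flags[0] if t.flags else "")
    )
# Each m/z is (M + z*proton)/z with monoisotopic masses; the two flagged
# peptides fall outside the 5-14 residue assay window but are pinned
# into the panel as explicitly requested targets.
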