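"""Design a PRM panel from protein sequences.

Builds a tiny synthetic proteome with two planted tryptic peptides,
digests it, screens peptide uniqueness against the full proteome and
assembles light/heavy targets with y-ion transitions.
"""

from prmkit.assay import PanelConfig, build_panel
from prmkit.masses import precursor_mz
from prmkit.simulate import generate_proteome

proteome = generate_proteome(
    5, planted_peptides=[(0, "GADVWFK"), (1, "ENAGEDPGLAR")], seed=42
)
panel, audit = build_panel(proteome, background=proteome, config=PanelConfig())

print(f"{len(panel.targets)} targets survived digestion + uniqueness screening:")
for t in panel.targets:
    print(
        f"  {t.accession}  {t.sequence:<14s} z={t.charge}  "
        f"light {precursor_mz(t.light):8.4f}  heavy {precursor_mz(t.heavy):8.4f}  "
        f"{len(t.transitions)} y-ion transitions"
    )
dropped = sum(1 for a in audit if not a["kept"] and a["peptide"])
print(f"{dropped} candidate peptides dropped (see audit trail for reasons).")
# The heavy (SIL) precursor sits +8.014/z Th above the light one for
# K-terminated peptides, +10.008/z for R-terminated ones.
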