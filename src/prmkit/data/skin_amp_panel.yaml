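# Bundled reference panel: 18 protein-specific tryptic peptides covering 13
# skin antimicrobial/immunomodulatory proteins, each monitored as a light
# (endogenous) / heavy (SIL-spiked) precursor pair.  Charges are stored per
# target; m/z values are always recomputed from sequence + modifications,
# never stored here.
version: 1
scan_range: [114.0, 1000.0]
collision_energy: 30.0
targets:
  - {gene: S100A8, protein_name: calcium-binding protein A8, accession: P05109, sequence: ALNSIIDVYHK, charge: 3}
  - {gene: S100A8, protein_name: calcium-binding protein A8, accession: P05109, sequence: GADVWFK, charge: 2}
  - {gene: S100A9, protein_name: calcium-binding protein A9, accession: P06702, sequence: DLYNFLK, charge: 2}
  - {gene: LL-37, protein_name: cathelicidin, accession: P49913, sequence: LLGDFFR, charge: 2}
  - {gene: DCD, protein_name: dermcidin, accession: P81605, sequence: ENAGEDPGLAR, charge: 2}
  - {gene: hBD1, protein_name: human beta-defensin 1, accession: P60022, sequence: IQGTCYR, charge: 2}
  - {gene: hBD2, protein_name: human beta-defensin 2, accession: O15263, sequence: GIGDPVTCLK, charge: 2}
  - {gene: hBD3, protein_name: human beta-defensin 3, accession: P81534, sequence: GIINTLQK, charge: 2}
  - {gene: hBD4, protein_name: human beta-defensin 4, accession: Q8WTQ1, sequence: ICGYGTAR, charge: 2}
  - {gene: LACRT, protein_name: lacritin, accession: Q9GZZ8, sequence: QELNPLK, charge: 2}
  - {gene: LACRT, protein_name: lacritin, accession: Q9GZZ8, sequence: SILLTEQALAK, charge: 2}
  - {gene: LCN2, protein_name: lipocalin-2, accession: P80188, sequence: VPLQQNFQDNQFQGK, charge: 2}
  - {gene: LCN2, protein_name: lipocalin-2, accession: P80188, sequence: SYNVTSVLFR, charge: 2}
  - {gene: LCN2, protein_name: lipocalin-2, accession: P80188, sequence: TFVPGCQPGEFTLGNIK, charge: 2}
  - {gene: LYZ, protein_name: lysozyme, accession: P61626, sequence: GISLANWMCLAK, charge: 2}
  - {gene: LYZ, protein_name: lysozyme, accession: P61626, sequence: WESGYNTR, charge: 2}
  - {gene: S100A7, protein_name: psoriasin, accession: P31151, sequence: SIIGMIDMFHK, charge: 2}
  - {gene: TSLP, protein_name: thymic stromal lymphopoietin, accession: Q969D9, sequence: CLEQVSQLQGLWR, charge: 2}
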