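# Methods

This note documents the models, parameter choices and numerical
conventions behind prmkit, and what the simulation-based tests do and do
not demonstrate about real data.

## Mass arithmetic

All masses are monoisotopic; the toolkit targets high-resolution
(Orbitrap-class) PRM readout where monoisotopic precursor selection is
the norm. Residue masses, the water mass (18.0105647 Da) and the proton
mass (1.00727647 Da) live in a versioned data file
(`data/residue_masses.json`). A peptide's neutral mass is the residue
sum plus water plus modification deltas; precursor m/z is
`(M + z·H⁺)/z`.

Fixed conventions:

- **Carbamidomethyl-C** (+57.021464 Da) is applied to every cysteine by
  default, matching the standard iodoacetamide alkylation step of
  bottom-up sample preparation.
- **SIL labels** sit on the C-terminal residue of the heavy peptide:
  ¹³C₆¹⁵N₂-Lys (+8.014199 Da) or ¹³C₆¹⁵N₄-Arg (+10.008269 Da). A
  non-tryptic C-terminus cannot carry a label and is rejected.
- Fragments are singly charged b/y ions only, enumerated for
  i = 1..n−1, with each modification delta travelling with the fragment
  containing the modified residue. Higher fragment charges, neutral
  losses and a/c/x/z series are out of scope. The default scan window is
  114–1000 Th (the targeted-MS2 acquisition range); a transition is only
  kept when both its light and heavy form fall inside the window, since
  the pair must be monitored in both channels.

Precursor charges are stored per target, not derived: printed assay
lists rarely carry them. The bundled panel uses z = 2 throughout except
ALNSIIDVYHK (z = 3), the only charge consistent with its reference m/z.
Published m/z values are rounded/truncated to 2–3 decimals, so
comparisons use a fixed 0.005 Th tolerance.

## Digestion model

Trypsin cleaves after K/R. Two site-scoring models:

- **strict** (default): probability 1.0 unless the next residue is
  proline, then 0.0. Deterministic and equal to the common
  "K/R-not-before-P" convention.
- **keil**: probabilities from a bundled context table
  (`data/keil_rules.yaml`, versioned) in the spirit of the Keil rules
  used by cleavage predictors — the proline block is lifted in WKP/MRP
  contexts, and acidic/basic/cysteine neighbours reduce efficiency.
  Lookup is most-specific-first: (P2,P1,P1') triple, then (P1,P1')
  pair, then the P1' table, then the default. The exact numeric values
  are a curated approximation; the table is data, not code, and can be
  replaced wholesale.

A C-terminal K/R counts as a (vacuously unblocked) site, so site lists
report it with probability 1.0/default. Digestion cuts at every site at
or above the probability threshold and emits products with up to
`max_missed` retained internal sites; with zero missed cleavages the
products partition the protein exactly. "Fully cleaved" candidates for
assay design mean: both boundaries score 1.0 **and** no internal site
reaches the threshold. Coordinates are 0-based half-open throughout. No
N-terminal Met stripping is performed.

## Uniqueness screening

Protein-specificity is decided by exact substring search against a
background proteome, the standard criterion for tryptic-length
peptides; this replaces an online homology search and removes any
dependence on database versions. Isoleucine and leucine are equated by
default because they are isobaric and indistinguishable by MS (this
only ever removes candidates, never adds them). Mismatch-tolerant
matching and isobaric substitutions beyond I/L are out of scope.

## Panel assembly

`build_panel` chains digest → filter → uniqueness → SIL pairing →
fragment generation and keeps a per-candidate audit trail. An explicit
override list can pin peptides (with their charges) into the panel;
pinned peptides that violate the length filter are **flagged, not
dropped** — two bundled targets (VPLQQNFQDNQFQGK, 15 aa;
TFVPGCQPGEFTLGNIK, 17 aa) are such cases, and the discrepancy is
surfaced in flags and reports rather than silently resolved. Modified
sequences use bracket notation (`C[+57.0]`, `K[+8.0]`, `R[+10.0]`),
unambiguous and ingestible by Skyline-style tools.

## Peak detection and quantification

Fragment XICs per (sample, peptide, channel) are resampled to a shared
grid if needed, summed and smoothed with a 5-point moving average. The
apex is the global maximum and must exceed a signal-to-noise threshold
(default 5) above baseline, where the baseline is the trace median and
noise its scaled MAD (1.4826·MAD). Boundaries walk from the apex to the
nearest valley or to where intensity falls below 1 % of apex height
above baseline. Each fragment is integrated by the trapezoid rule over
the boundaries after subtracting its own median background (negative
residuals clipped); the peak-group area is the fragment-area sum.

The **coelution criterion** gates detection: apex distance ≤ 0.1 min
(closed boundary — a delta exactly at tolerance passes) and boundary
overlap ≥ 50 % of the shorter peak. These thresholds are configuration,
not hard-code; no published values exist for them, and 0.1 min is a
typical apex tolerance for nano-LC peak widths of ~0.1–0.3 min.

For detected peptides the light channel is re-integrated over the
**heavy** peak's boundaries (the SIL spike is uniform across samples,
so its boundaries are the more reproducible window), and the ratio is
light area / heavy area. A zero heavy area is an error (missing spike),
not a ratio. Undetected peptides yield *absent* ratios — never zeros,
which would fabricate signal downstream. Technical replicates, when a
`replicate` column is present, are averaged at the ratio level, the
simplest estimator consistent with one-value-per-sample plotting.

## Group statistics

Shapiro–Wilk normality testing (delegated to `scipy.stats.shapiro`; its
coefficient machinery is standard and not this package's contribution)
routes to the nonparametric path whenever any group rejects at alpha or
is too small to test (n < 3). Kruskal–Wallis and Dunn are implemented
from the formulas (see README) with midranks and tie corrections; the
omnibus p comes from the chi-square distribution with k−1 df, Dunn's
two-sided p from the standard normal. The Dunn adjustment defaults to
Bonferroni over the tested pairs (none/Holm available). Degenerate
inputs: all-identical observations give H = 0, p = 1; a tie correction
that consumes all rank variance does the same.

Missing-data policy: groups where a peptide was never detected are
carried as empty, and pairs involving a group with fewer than
`min_detections` (default 3) observations are emitted as
skipped-and-flagged rather than tested — sparse detections cannot claim
significance. Peptides are treated independently; no across-peptide
multiple-testing correction is applied.

## Simulator

Chromatograms are Gaussian peaks (sigma default 4 s, optional
right-tail asymmetry) on a 0.02-min grid over a ±0.75-min window. The
heavy channel is spiked at a fixed apex height (10⁶ counts); the light
channel is the same peak scaled by the group's true ratio, with optional
per-sample lognormal biological spread (the *realized* ratio is what the
ground-truth manifest records). Both channels share an apex jittered
across samples (default sd 0.02 min) — they coelute by construction.
Fragment traces are scaled copies (weights 0.5/0.3/0.2) with independent
noise: multiplicative lognormal per point (mean-corrected, so noise adds
variance without biasing the level) plus a Poisson additive baseline.
This multiplicative-plus-baseline model is standard for XIC intensities
and keeps ratios positive. Signal-to-noise in the tests is apex height
over noise sd at apex, i.e. SNR 20 ↔ noise CV 5 %.

Synthetic proteomes draw background residues from an alphabet without
K/R/P so cut sites are fully controlled; planted tryptic peptides are
inserted after an R flank and are recovered exactly by a strict digest.

**The worked-example fixture** bundles the 18-peptide panel, the
published healthy/inflamed presence pattern, and two simulation
profiles: a 2×5-sample detection-validation design whose dropout map
mirrors the presence pattern, and a 3-region design (GP/SGR/AGR, n = 15
each) with SGR-elevated S100A8/LCN2/LACRT/LYZ peptides (5–10× — the
real effect sizes are not numerically published, so magnitudes were
chosen once to make power robust at n = 15) and a flat dermcidin
peptide. Regions where a peptide sits near the detection limit are
modeled as trace-level (ratio 0.06) with 60 % dropout rather than
strictly absent: real below-LOD analytes do produce occasional boundary
detections, and strict absence would leave the corresponding pairwise
tests with no data at all under the no-zero-imputation policy.

## What passing tests show — and what they don't

The simulator validates the *computational* chain: peak integration
against closed-form Gaussian areas, ratio recovery against planted
truth, detection monotonicity, statistical calibration (type-I error
4–6 % at alpha 0.05 under the null), and end-to-end reproduction of the
reference detection pattern and region contrasts at fixed seed. It does
**not** emulate interference from co-isolated analytes, retention-time
drift across runs, detector saturation, or chemical noise structure —
so passing tests say nothing about peak-picking robustness on real,
crowded chromatograms. Raw vendor formats and cross-run alignment are
out of scope; the quantification input is the long-format XIC TSV (an
mzML adapter would simply produce that table and is not shipped).

## Problem sizes

Test and acceptance runs use the study-scale designs directly (18
peptides × 45 samples × 2 channels × 3 fragments for the region
pipeline; 2000 replicates for the null-calibration check); the whole
suite runs in well under a minute on one CPU.
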