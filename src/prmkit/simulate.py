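"""Synthetic proteomes, chromatograms and multi-group sample sets.

The generator exists so that every stage — digestion, uniqueness,
quantification, group statistics — can be exercised against known ground
truth.  It emulates the structure of a stable-isotope-dilution PRM
experiment:

* the heavy (SIL) channel is spiked at a fixed level in every sample;
* the light channel is the heavy peak scaled by the true light-to-heavy
  ratio for that sample's group;
* both channels share an apex (they coelute by construction), jittered
  across samples;
* fragment traces are scaled copies of the peptide peak with independent
  noise: multiplicative lognormal intensity noise plus a Poisson-like
  additive baseline;
* peptides can drop out per (group, peptide) with a configured
  probability, leaving a baseline-only light trace.

Every run is fully determined by the config seed, and the emitted
ground-truth manifest records the realized ratio, apex and detectability
for each sample/peptide one-to-one with the traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import ProteinRecord

__all__ = [
    "SimulationConfig",
    "generate_proteome",
    "write_fasta",
    "simulate_xics",
    "make_study_fixture",
    "StudyFixture",
]

_ALPHABET = "ACDEFGHILMNQSTVWY"  # no K/R (reserved for cut sites), no P


@dataclass
class SimulationConfig:
    """Study design plus peak/noise parameters for one simulated run.

    ``true_ratios`` maps (group, peptide) to the light-to-heavy ratio;
    a missing entry means the peptide is not present in that group
    (equivalently dropout 1.0).  ``dropout`` overrides per (group,
    peptide) the probability that a sample yields no endogenous peak.
    """

    seed: int
    peptides: Sequence[str]
    groups: Sequence[str]
    samples_per_group: int = 15
    true_ratios: dict[tuple[str, str], float] = field(default_factory=dict)
    dropout: dict[tuple[str, str], float] = field(default_factory=dict)
    n_replicates: int = 1
    # chromatography: Gaussian peak, sigma in seconds, optional right-side
    # broadening (asymmetry > 0 widens the tail)
    peak_sigma_sec: float = 4.0
    asymmetry: float = 0.0
    rt_jitter_sd: float = 0.02  # minutes, across samples
    # intensities
    heavy_height: float = 1.0e6  # counts at apex, fixed SIL spike
    biological_cv: float = 0.0  # sample-to-sample spread of the light level
    noise_cv: float = 0.0  # multiplicative per-point lognormal noise
    baseline_level: float = 0.0  # mean of the Poisson-like additive baseline
    fragment_weights: Sequence[float] = (0.5, 0.3, 0.2)
    time_step_min: float = 0.02
    window_min: float = 0.75  # half-width of the emitted trace window

    def __post_init__(self) -> None:
        for key, r in self.true_ratios.items():
            if r <= 0:
                raise ValueError(f"true ratio must be > 0, got {r} for {key}")
        for key, p in self.dropout.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout must be in [0,1], got {p} for {key}")


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (80, 160),
    planted_peptides: Sequence[tuple[int, str]] = (),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random proteins with tryptic peptides planted at known positions.

    ``planted_peptides`` is a list of (protein_index, sequence) pairs;
    each planted peptide must end in K/R and is inserted flanked by an R
    on the left, so a strict digest recovers it exactly.  Background
    residues avoid K, R and P, keeping cut sites fully controlled.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    plants: dict[int, list[str]] = {}
    for idx, pep in planted_peptides:
        if pep[-1] not in "KR":
            raise ValueError(f"planted peptide {pep} must end in K or R")
        plants.setdefault(idx, []).append(pep)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        needed = sum(len(p) + 1 for p in plants.get(i, []))
        if needed > length:
            raise ValueError(
                f"planted peptides ({needed} residues incl. flanks) exceed "
                f"protein length {length} for protein {i}"
            )
        seq = "".join(rng.choice(list(_ALPHABET), size=length - needed))
        # sprinkle extra tryptic sites into the background
        chars = list(seq)
        for j in range(10, len(chars) - 1, 25):
            chars[j] = "K" if rng.random() < 0.5 else "R"
        seq = "".join(chars)
        for pep in plants.get(i, []):
            pos = int(rng.integers(5, max(6, len(seq) - 5)))
            seq = seq[:pos] + "R" + pep + seq[pos:]
        records.append(
            ProteinRecord(
                accession=f"SYN{i:04d}",
                description=f"SYN{i:04d} synthetic protein {i}",
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">sp|{rec.accession}|{rec.accession}_SYN {rec.description}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k : k + 60] + "\n")


def _peak_profile(
    t: np.ndarray, apex: float, sigma_min: float, asymmetry: float
) -> np.ndarray:
    sig_left = sigma_min
    sig_right = sigma_min * (1.0 + asymmetry)
    sig = np.where(t < apex, sig_left, sig_right)
    return np.exp(-0.5 * ((t - apex) / sig) ** 2)


def simulate_xics(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Emit (xic_table, ground_truth, sample->group manifest).

    The XIC table is long-format with columns sample_id, peptide,
    channel, fragment, time_min, intensity (plus replicate when
    ``n_replicates`` > 1).  The ground truth records, per sample/peptide,
    the *realized* ratio (after biological spread), the shared apex and a
    detectable flag; dropped-out peptides emit baseline-only light
    traces and ``detectable=False``.
    """
    rng = np.random.default_rng(config.seed)
    sigma_min = config.peak_sigma_sec / 60.0
    rows: list[tuple] = []
    truth_rows: list[dict] = []
    manifest: dict[str, str] = {}
    n_frag = len(config.fragment_weights)
    # deterministic per-peptide base retention times across a 10-50 min gradient
    base_rt = {
        pep: 10.0 + 40.0 * (k + 1) / (len(config.peptides) + 1)
        for k, pep in enumerate(config.peptides)
    }
    has_reps = config.n_replicates > 1
    for group in config.groups:
        for s in range(config.samples_per_group):
            sample_id = f"{group}_{s + 1:02d}"
            manifest[sample_id] = group
            for pep in config.peptides:
                ratio = config.true_ratios.get((group, pep))
                p_drop = config.dropout.get(
                    (group, pep), 0.0 if ratio is not None else 1.0
                )
                dropped = bool(rng.random() < p_drop) or ratio is None
                apex = base_rt[pep] + rng.normal(0.0, config.rt_jitter_sd)
                if config.biological_cv > 0 and not dropped:
                    realized = float(
                        ratio
                        * rng.lognormal(
                            -0.5 * np.log1p(config.biological_cv**2),
                            np.sqrt(np.log1p(config.biological_cv**2)),
                        )
                    )
                else:
                    realized = None if dropped else float(ratio)
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "peptide": pep,
                        "true_ratio": realized,
                        "true_apex": apex,
                        "detectable": not dropped,
                    }
                )
                t = np.arange(
                    base_rt[pep] - config.window_min,
                    base_rt[pep] + config.window_min + config.time_step_min / 2,
                    config.time_step_min,
                )
                profile = _peak_profile(t, apex, sigma_min, config.asymmetry)
                for rep in range(config.n_replicates):
                    for channel in ("light", "heavy"):
                        if channel == "heavy":
                            height = config.heavy_height
                        elif dropped:
                            height = 0.0
                        else:
                            height = realized * config.heavy_height
                        for f in range(n_frag):
                            y = height * config.fragment_weights[f] * profile
                            if config.noise_cv > 0:
                                sig = np.sqrt(np.log1p(config.noise_cv**2))
                                y = y * rng.lognormal(-0.5 * sig**2, sig, size=y.shape)
                            if config.baseline_level > 0:
                                y = y + rng.poisson(config.baseline_level, size=y.shape)
                            for tt, yy in zip(t, y):
                                if has_reps:
                                    rows.append(
                                        (sample_id, rep + 1, pep, channel, f"y{f + 3}", tt, yy)
                                    )
                                else:
                                    rows.append(
                                        (sample_id, pep, channel, f"y{f + 3}", tt, yy)
                                    )
    if has_reps:
        cols = ["sample_id", "replicate", "peptide", "channel", "fragment", "time_min", "intensity"]
    else:
        cols = ["sample_id", "peptide", "channel", "fragment", "time_min", "intensity"]
    xic = pd.DataFrame(rows, columns=cols)
    truth = pd.DataFrame(truth_rows)
    return xic, truth, manifest


# ---------------------------------------------------------------------------
# bundled worked-example fixture: the 18-peptide skin-AMP panel


@dataclass
class StudyFixture:
    """The bundled skin-AMP study conditions, ready to simulate.

    ``detection_config`` emulates the healthy/inflamed method-validation
    design (presence/absence of each peptide per condition);
    ``region_config`` emulates the three-region comparison (gland-poor
    GP, sebaceous-gland-rich SGR, apocrine-gland-rich AGR; n = 15 per
    region) with SGR-elevated S100A8/LCN2/LACRT/LYZ peptides and a flat
    dermcidin peptide.
    """

    panel: "object"
    presence_pattern: pd.DataFrame
    detection_config: SimulationConfig
    region_config: SimulationConfig


# Region profile, qualitative directions from the three-region comparison:
# SGR carries clearly elevated levels of the S100A8, LCN2 (VPLQ...), LACRT
# (SILL...) and LYZ (WESG...) peptides; the dermcidin peptide is flat.  In
# regions where a peptide sits near/below the detection limit it is modeled
# as trace-level with high dropout rather than strictly absent, so that the
# pairwise tests retain a handful of observations to rank (see methods note).
_TRACE = 0.06  # light-to-heavy ratio at the detection limit
_REGION_PROFILE: dict[str, dict[str, tuple[float | None, float]]] = {
    # peptide: {group: (ratio or None, dropout)}
    "ALNSIIDVYHK": {"GP": (_TRACE, 0.6), "SGR": (6.0, 0.0), "AGR": (1.0, 0.0)},
    "GADVWFK": {"GP": (0.2, 0.1), "SGR": (6.0, 0.0), "AGR": (1.0, 0.0)},
    "VPLQQNFQDNQFQGK": {"GP": (_TRACE, 0.6), "SGR": (6.0, 0.0), "AGR": (1.0, 0.0)},
    "SILLTEQALAK": {"GP": (0.2, 0.1), "SGR": (1.8, 0.0), "AGR": (_TRACE, 0.6)},
    "WESGYNTR": {"GP": (_TRACE, 0.6), "SGR": (1.5, 0.0), "AGR": (_TRACE, 0.6)},
    "ENAGEDPGLAR": {"GP": (1.0, 0.0), "SGR": (1.0, 0.0), "AGR": (1.0, 0.0)},
}


def make_study_fixture(seed: int = 20210419) -> StudyFixture:
    """Panel + presence pattern + simulation profiles for the worked example."""
    from importlib import resources

    from .assay import load_bundled_panel

    panel = load_bundled_panel()
    peptides = panel.peptides()
    import io

    pattern = pd.read_csv(
        io.StringIO(
            resources.files("prmkit.data").joinpath("presence_pattern.tsv").read_text()
        ),
        sep="\t",
    )
    # healthy/inflamed validation design: present peptides at ratio 1,
    # absent peptides fully dropped out
    det_ratios: dict[tuple[str, str], float] = {}
    for _, row in pattern.iterrows():
        for cond in ("healthy", "inflamed"):
            if row[cond] == "+":
                det_ratios[(cond, row["peptide"])] = 1.0
    detection_config = SimulationConfig(
        seed=seed,
        peptides=peptides,
        groups=("healthy", "inflamed"),
        samples_per_group=5,
        true_ratios=det_ratios,
        noise_cv=0.05,
        baseline_level=50.0,
        rt_jitter_sd=0.02,
    )
    region_ratios: dict[tuple[str, str], float] = {}
    region_dropout: dict[tuple[str, str], float] = {}
    for pep, prof in _REGION_PROFILE.items():
        for group, (ratio, p_drop) in prof.items():
            if ratio is not None:
                region_ratios[(group, pep)] = ratio
                region_dropout[(group, pep)] = p_drop
    region_config = SimulationConfig(
        seed=seed + 1,
        peptides=peptides,
        groups=("GP", "SGR", "AGR"),
        samples_per_group=15,
        true_ratios=region_ratios,
        dropout=region_dropout,
        biological_cv=0.35,
        noise_cv=0.05,
        baseline_level=50.0,
        rt_jitter_sd=0.02,
    )
    return StudyFixture(
        panel=panel,
        presence_pattern=pattern,
        detection_config=detection_config,
        region_config=region_config,
    )
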