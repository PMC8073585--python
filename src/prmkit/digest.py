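"""In-silico trypsin digestion with per-site cleavage-probability scoring.

Trypsin cuts C-terminal to K and R.  Two scoring models are provided:

* ``"strict"`` — probability 1.0 after every K/R not followed by proline,
  0.0 otherwise.  Fully deterministic, the default.
* ``"keil"`` — context-dependent probabilities from a bundled table
  (``data/keil_rules.yaml``) in the spirit of the Keil rules used by
  common cleavage predictors: the proline block may be lifted (WKP, MRP)
  and acidic/basic/cysteine neighbours reduce efficiency.

Peptides destined for a targeted assay are then filtered to fully
cleaved products ("100 % cleavage probability": both boundaries score
1.0 and no internal site reaches the cut threshold) of assay-friendly
length, 5-14 residues by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "ProteinRecord",
    "CleavageSite",
    "DigestPeptide",
    "read_fasta",
    "score_cleavage_sites",
    "digest",
    "filter_peptides",
]


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")

    @property
    def nonstandard_residues(self) -> set[str]:
        return set(self.sequence) - STANDARD_RESIDUES


def _accession_from_header(header_id: str) -> str:
    # UniProt-style "sp|P05109|S10A8_HUMAN" -> "P05109"
    parts = header_id.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return header_id


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA, parsing UniProt accessions when present."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                accession=_accession_from_header(rec.id),
                description=rec.description,
                sequence=str(rec.seq).upper(),
            )
        )
    return records


@dataclass(frozen=True)
class CleavageSite:
    """A candidate cut after ``position`` (0-based index of the K/R)."""

    position: int
    probability: float


@dataclass(frozen=True)
class DigestPeptide:
    sequence: str
    parent_accession: str
    start: int  # 0-based half-open coordinates in the parent
    end: int
    missed_cleavages: int
    min_boundary_probability: float


class _KeilTable:
    def __init__(self, raw: dict):
        self.default = float(raw.get("default", 1.0))
        self.p1prime = {k: float(v) for k, v in (raw.get("p1prime") or {}).items()}
        self.exceptions: list[dict] = raw.get("exceptions") or []

    @classmethod
    def bundled(cls) -> "_KeilTable":
        raw = yaml.safe_load(
            resources.files("prmkit.data").joinpath("keil_rules.yaml").read_text()
        )
        return cls(raw)

    def probability(self, p2: str | None, p1: str, p1prime: str | None) -> float:
        if p1prime is None:  # C-terminal K/R: nothing downstream to block
            return self.default
        # most specific context first: (P2,P1,P1') triples before (P1,P1') pairs
        for want_p2 in (True, False):
            for exc in self.exceptions:
                if ("p2" in exc) is not want_p2:
                    continue
                if exc["p1"] != p1 or exc["p1prime"] != p1prime:
                    continue
                if want_p2 and exc["p2"] != p2:
                    continue
                return float(exc["probability"])
        if p1prime in self.p1prime:
            return self.p1prime[p1prime]
        return self.default


def score_cleavage_sites(
    protein: ProteinRecord, rule_model: str = "strict"
) -> list[CleavageSite]:
    """Score every bond after a K/R, including a C-terminal K/R.

    A terminal site has no P1' residue: nothing can block it, so it
    scores 1.0 under "strict" and the table default under "keil"."""
    if rule_model not in ("strict", "keil"):
        raise ValueError(f"unknown rule_model {rule_model!r}")
    keil = _KeilTable.bundled() if rule_model == "keil" else None
    seq = protein.sequence
    sites = []
    for i in range(len(seq)):
        if seq[i] not in "KR":
            continue
        nxt = seq[i + 1] if i + 1 < len(seq) else None
        if keil is None:
            prob = 0.0 if nxt == "P" else 1.0
        else:
            prev = seq[i - 1] if i > 0 else None
            prob = keil.probability(prev, seq[i], nxt)
        sites.append(CleavageSite(position=i, probability=prob))
    return sites


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    rule_model: str = "strict",
    probability_threshold: float = 1.0,
) -> list[DigestPeptide]:
    """Cut at every site scoring >= threshold; emit up to ``max_missed``
    retained internal sites per product.

    With 0 missed cleavages the products partition the protein.  Each
    peptide records the lower of its two boundary-site probabilities
    (protein termini count as 1.0).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 0.0 <= probability_threshold <= 1.0:
        raise ValueError("probability_threshold must be in [0, 1]")
    seq = protein.sequence
    sites = score_cleavage_sites(protein, rule_model)
    prob_at = {s.position: s.probability for s in sites}
    cuts = [s.position for s in sites if s.probability >= probability_threshold]
    # segment boundaries as half-open [start, end)
    bounds = [0] + [c + 1 for c in cuts] + [len(seq)]
    if bounds[-2] == bounds[-1]:  # protein ends exactly on a cut
        bounds.pop()
    out = []
    nseg = len(bounds) - 1
    for i in range(nseg):
        for j in range(i, min(i + max_missed + 1, nseg)):
            start, end = bounds[i], bounds[j + 1]
            left_p = prob_at.get(start - 1, 1.0) if start > 0 else 1.0
            right_p = prob_at.get(end - 1, 1.0) if end < len(seq) else 1.0
            out.append(
                DigestPeptide(
                    sequence=seq[start:end],
                    parent_accession=protein.accession,
                    start=start,
                    end=end,
                    missed_cleavages=j - i,
                    min_boundary_probability=min(left_p, right_p),
                )
            )
    out.sort(key=lambda p: (p.start, p.end))
    return out


def filter_peptides(
    peptides: Iterable[DigestPeptide],
    min_len: int = 5,
    max_len: int = 14,
    probability_threshold: float = 1.0,
) -> list[DigestPeptide]:
    """Keep assay-suitable peptides: length in [min_len, max_len] and both
    boundaries at or above the probability threshold.  Order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [
        p
        for p in peptides
        if min_len <= len(p.sequence) <= max_len
        and p.min_boundary_probability >= probability_threshold
    ]
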