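"""Protein-specific (proteotypic) peptide screening.

A peptide is useful for targeted quantification only if it maps to exactly
one protein in the background proteome.  For tryptic-length peptides the
standard criterion is exact substring matching; by default isoleucine and
leucine are treated as equivalent, since they are isobaric and
indistinguishable by mass spectrometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .digest import DigestPeptide, ProteinRecord

__all__ = ["UniquenessVerdict", "screen_uniqueness", "verdicts_to_frame"]


@dataclass(frozen=True)
class UniquenessVerdict:
    peptide: str
    parent_accession: str
    is_unique: bool
    hit_accessions: tuple[str, ...]
    ile_leu_equivalent: bool


def _fold(seq: str, equate_ile_leu: bool) -> str:
    return seq.replace("I", "L") if equate_ile_leu else seq


def screen_uniqueness(
    peptides: Iterable[DigestPeptide],
    proteome: Sequence[ProteinRecord],
    equate_ile_leu: bool = True,
) -> list[UniquenessVerdict]:
    """Substring-search each peptide against every proteome sequence.

    A verdict is unique iff every hit falls on the peptide's declared
    parent accession.  A peptide absent from its own parent (when the
    parent is in the proteome) indicates inconsistent inputs and raises.
    """
    if not isinstance(proteome, (list, tuple)):
        proteome = list(proteome)
    folded = [(rec, _fold(rec.sequence, equate_ile_leu)) for rec in proteome]
    by_accession = {rec.accession for rec in proteome}
    out = []
    for pep in peptides:
        needle = _fold(pep.sequence, equate_ile_leu)
        hits = tuple(
            sorted({rec.accession for rec, seq in folded if needle in seq})
        )
        if pep.parent_accession in by_accession and pep.parent_accession not in hits:
            raise ValueError(
                f"peptide {pep.sequence} not found in its declared parent "
                f"{pep.parent_accession}: inconsistent inputs"
            )
        is_unique = hits == (pep.parent_accession,) or hits == ()
        out.append(
            UniquenessVerdict(
                peptide=pep.sequence,
                parent_accession=pep.parent_accession,
                is_unique=is_unique,
                hit_accessions=hits,
                ile_leu_equivalent=equate_ile_leu,
            )
        )
    return out


def verdicts_to_frame(verdicts: Sequence[UniquenessVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide": [v.peptide for v in verdicts],
            "parent_accession": [v.parent_accession for v in verdicts],
            "is_unique": [v.is_unique for v in verdicts],
            "hit_accessions": [";".join(v.hit_accessions) for v in verdicts],
            "ile_leu_equivalent": [v.ile_leu_equivalent for v in verdicts],
        }
    )


def write_verdicts_tsv(verdicts: Sequence[UniquenessVerdict], path: str | Path) -> None:
    verdicts_to_frame(verdicts).to_csv(path, sep="\t", index=False)
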