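"""Monoisotopic mass and m/z arithmetic for PRM peptide targets.

Everything downstream — precursor lists, transition lists, light/heavy
pairing — rests on the sums computed here.  Masses are monoisotopic
throughout (the assays are read out on a high-resolution Orbitrap
analyzer); average masses are deliberately not supported.

Two fixed-mass conventions matter:

* carbamidomethylation of cysteine (+57.021464 Da), the standard
  iodoacetamide alkylation applied as a fixed modification on every C;
* stable-isotope labels on the C-terminal tryptic residue of the heavy
  (SIL) peptide: Lys +8.014199 Da ([13C6][15N2]) or Arg +10.008269 Da
  ([13C6][15N4]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator

__all__ = [
    "AminoAcidMassTable",
    "Modification",
    "PeptideIon",
    "CARBAMIDOMETHYL",
    "SIL_LYS",
    "SIL_ARG",
    "DEFAULT_TABLE",
    "make_ion",
    "peptide_monoisotopic_mass",
    "precursor_mz",
    "sil_counterpart",
    "fragment_mz_series",
]


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Monoisotopic residue masses plus the water and proton constants."""

    residue_mass: dict[str, float]
    water_mass: float
    proton_mass: float

    @classmethod
    def from_bundled(cls) -> "AminoAcidMassTable":
        raw = json.loads(
            resources.files("prmkit.data").joinpath("residue_masses.json").read_text()
        )
        return cls(
            residue_mass=dict(raw["residue_mass"]),
            water_mass=float(raw["water_mass"]),
            proton_mass=float(raw["proton_mass"]),
        )


@dataclass(frozen=True)
class Modification:
    """A mass shift attached to a residue (or terminus)."""

    name: str
    target_rule: str  # one-letter residue code the mod may sit on
    delta_mass: float  # Da
    fixed: bool = False


CARBAMIDOMETHYL = Modification("carbamidomethyl", "C", 57.021464, fixed=True)
SIL_LYS = Modification("label:13C(6)15N(2)", "K", 8.014199)
SIL_ARG = Modification("label:13C(6)15N(4)", "R", 10.008269)

DEFAULT_TABLE = AminoAcidMassTable.from_bundled()


@dataclass(frozen=True)
class PeptideIon:
    """A charged peptide with site-specific modifications.

    ``modifications`` holds ``(position, Modification)`` pairs with
    0-based positions into ``sequence``.  Heavy ions carry exactly one
    SIL label on the C-terminal K or R.
    """

    sequence: str
    charge: int
    modifications: tuple[tuple[int, Modification], ...] = field(default_factory=tuple)
    is_heavy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        for pos, mod in self.modifications:
            if not (0 <= pos < len(self.sequence)):
                raise ValueError(f"modification position {pos} outside sequence")
            if self.sequence[pos] != mod.target_rule:
                raise ValueError(
                    f"modification {mod.name} targets {mod.target_rule} but "
                    f"position {pos} is {self.sequence[pos]}"
                )

    def modified_sequence(self) -> str:
        """Bracket notation, e.g. ``IQGTC[+57.0]YR`` or ``GADVWFK[+8.0]``."""
        deltas = {pos: mod.delta_mass for pos, mod in self.modifications}
        out = []
        for i, res in enumerate(self.sequence):
            out.append(res)
            if i in deltas:
                out.append(f"[{deltas[i]:+.1f}]")
        return "".join(out)


def make_ion(
    sequence: str,
    charge: int,
    heavy: bool = False,
    fixed_cam: bool = True,
) -> PeptideIon:
    """Build a :class:`PeptideIon` applying the standard fixed-mod policy.

    Carbamidomethyl is attached to every cysteine when ``fixed_cam`` is on;
    ``heavy`` additionally places the SIL label on the C-terminal K/R.
    """
    mods: list[tuple[int, Modification]] = []
    if fixed_cam:
        mods.extend((i, CARBAMIDOMETHYL) for i, r in enumerate(sequence) if r == "C")
    if heavy:
        term = sequence[-1]
        if term == "K":
            mods.append((len(sequence) - 1, SIL_LYS))
        elif term == "R":
            mods.append((len(sequence) - 1, SIL_ARG))
        else:
            raise ValueError(
                f"cannot SIL-label non-tryptic terminus {term!r} in {sequence}"
            )
    return PeptideIon(sequence, charge, tuple(mods), is_heavy=heavy)


def peptide_monoisotopic_mass(
    ion: PeptideIon, table: AminoAcidMassTable = DEFAULT_TABLE
) -> float:
    """Neutral monoisotopic mass: residue sum + water + modification deltas."""
    total = table.water_mass
    for i, res in enumerate(ion.sequence):
        try:
            total += table.residue_mass[res]
        except KeyError:
            raise ValueError(
                f"unknown residue {res!r} at position {i} in {ion.sequence}"
            ) from None
    total += sum(mod.delta_mass for _, mod in ion.modifications)
    return total


def precursor_mz(ion: PeptideIon, table: AminoAcidMassTable = DEFAULT_TABLE) -> float:
    """(M + z·H+) / z for the ion's stored charge."""
    if ion.charge < 1:
        raise ValueError(f"charge must be >= 1, got {ion.charge}")
    mass = peptide_monoisotopic_mass(ion, table)
    return (mass + ion.charge * table.proton_mass) / ion.charge


def sil_counterpart(ion: PeptideIon) -> PeptideIon:
    """The heavy (SIL) twin of a light ion.

    The label sits on the C-terminal residue, which a tryptic peptide ends
    with: K (+8.014199) or R (+10.008269).  Anything else is a non-tryptic
    terminus and is rejected.
    """
    if ion.is_heavy:
        raise ValueError("ion is already heavy")
    term = ion.sequence[-1]
    if term == "K":
        label = SIL_LYS
    elif term == "R":
        label = SIL_ARG
    else:
        raise ValueError(
            f"non-tryptic terminus {term!r}: SIL counterpart needs C-terminal K or R"
        )
    mods = ion.modifications + ((len(ion.sequence) - 1, label),)
    return replace(ion, modifications=mods, is_heavy=True)


def _iter_fragments(
    ion: PeptideIon, table: AminoAcidMassTable
) -> Iterator[tuple[str, float]]:
    n = len(ion.sequence)
    deltas = [0.0] * n
    for pos, mod in ion.modifications:
        deltas[pos] += mod.delta_mass
    # prefix[i] = summed residue+mod mass of the first i residues
    prefix = [0.0] * (n + 1)
    for i, res in enumerate(ion.sequence):
        if res not in table.residue_mass:
            raise ValueError(f"unknown residue {res!r} at position {i}")
        prefix[i + 1] = prefix[i] + table.residue_mass[res] + deltas[i]
    total = prefix[n]
    for i in range(1, n):
        # b_i: N-terminal fragment, y_i: C-terminal fragment, both 1+
        yield f"b{i}", prefix[i] + table.proton_mass
        yield f"y{i}", (total - prefix[n - i]) + table.water_mass + table.proton_mass


def fragment_mz_series(
    ion: PeptideIon,
    table: AminoAcidMassTable = DEFAULT_TABLE,
    scan_min: float = 114.0,
    scan_max: float = 1000.0,
) -> list[tuple[str, float]]:
    """Singly charged b/y fragment m/z inside the scan window.

    Fragments are enumerated for i = 1..n-1; a modification delta travels
    with whichever fragment contains the modified residue.  Entries outside
    ``[scan_min, scan_max]`` (the default 114-1000 Th targeted-MS2 window)
    are dropped.
    """
    if not scan_min < scan_max:
        raise ValueError(f"scan_min must be < scan_max, got {scan_min}, {scan_max}")
    out = [
        (label, mz)
        for label, mz in _iter_fragments(ion, table)
        if scan_min <= mz <= scan_max
    ]
    # stable order: b-series then y-series, each by index
    out.sort(key=lambda t: (t[0][0], int(t[0][1:])))
    return out
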