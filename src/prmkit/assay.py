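"""Assemble a PRM panel: light/heavy target pairs plus fragment transitions.

The panel builder chains digestion, length/probability filtering, a
uniqueness screen against a background proteome, SIL pairing and fragment
generation, and keeps a per-candidate audit trail of why each peptide was
kept or dropped.  Because printed target lists rarely carry charge states,
an explicit override list can pin peptides and charges; targets pinned by
override are flagged (not dropped) when they violate the length filter.

A bundled reference panel of 18 skin-AMP peptides covering 13 proteins is
available via :func:`load_bundled_panel`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import masses
from .digest import (
    DigestPeptide,
    ProteinRecord,
    digest,
    filter_peptides,
    read_fasta,
)
from .masses import PeptideIon, fragment_mz_series, make_ion, precursor_mz
from .uniqueness import screen_uniqueness

__all__ = [
    "PeptideTarget",
    "AssayPanel",
    "PanelConfig",
    "build_panel",
    "load_bundled_panel",
    "export_transition_list",
    "read_transition_list",
    "panel_to_yaml",
    "panel_from_yaml",
]

DEFAULT_SCAN_RANGE = (114.0, 1000.0)
DEFAULT_NCE = 30.0


@dataclass(frozen=True)
class PeptideTarget:
    """One monitored peptide: a light/heavy precursor pair with transitions."""

    protein_gene: str
    protein_name: str
    accession: str
    light: PeptideIon
    heavy: PeptideIon
    transitions: tuple[tuple[str, float], ...]
    flags: tuple[str, ...] = ()

    @property
    def sequence(self) -> str:
        return self.light.sequence

    @property
    def charge(self) -> int:
        return self.light.charge


@dataclass
class AssayPanel:
    targets: list[PeptideTarget]
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE
    collision_energy: float = DEFAULT_NCE

    def __post_init__(self) -> None:
        seen = set()
        for t in self.targets:
            for ion in (t.light, t.heavy):
                key = (ion.sequence, ion.charge, ion.is_heavy)
                if key in seen:
                    raise ValueError(f"duplicate target {key}")
                seen.add(key)

    def peptides(self) -> list[str]:
        return [t.sequence for t in self.targets]

    def target_for(self, peptide: str) -> PeptideTarget:
        for t in self.targets:
            if t.sequence == peptide:
                return t
        raise KeyError(peptide)


@dataclass
class PanelConfig:
    """Knobs for the design pipeline, with assay-standard defaults."""

    min_len: int = 5
    max_len: int = 14
    max_missed: int = 0
    rule_model: str = "strict"
    probability_threshold: float = 1.0
    equate_ile_leu: bool = True
    default_charge: int = 2
    scan_range: tuple[float, float] = DEFAULT_SCAN_RANGE
    collision_energy: float = DEFAULT_NCE
    # sequence -> charge; pins these peptides into the panel even if the
    # length filter would reject them (they are then flagged, not dropped)
    overrides: dict[str, int] = field(default_factory=dict)


def _make_target(
    protein: ProteinRecord,
    sequence: str,
    charge: int,
    gene: str,
    protein_name: str,
    scan_range: tuple[float, float],
    flags: tuple[str, ...] = (),
) -> PeptideTarget:
    light = make_ion(sequence, charge)
    heavy = masses.sil_counterpart(light)
    # default transitions: singly charged y-ions whose light AND heavy
    # forms both fall inside the scan window (the pair is monitored in
    # both channels, so a label-shifted fragment outside the window would
    # break the pairing)
    heavy_labels = {
        label
        for label, _ in fragment_mz_series(
            heavy, scan_min=scan_range[0], scan_max=scan_range[1]
        )
    }
    trans = tuple(
        (label, mz)
        for label, mz in fragment_mz_series(
            light, scan_min=scan_range[0], scan_max=scan_range[1]
        )
        if label.startswith("y") and label in heavy_labels
    )
    return PeptideTarget(
        protein_gene=gene,
        protein_name=protein_name,
        accession=protein.accession,
        light=light,
        heavy=heavy,
        transitions=trans,
        flags=flags,
    )


def build_panel(
    proteins: Sequence[ProteinRecord] | str | Path,
    background: Sequence[ProteinRecord] | str | Path | None = None,
    config: PanelConfig | None = None,
) -> tuple[AssayPanel, list[dict]]:
    """Digest -> filter -> uniqueness -> SIL pairing -> fragments.

    Returns the panel and an audit trail: one dict per candidate peptide
    with a ``kept`` flag and a ``reason``.  A protein with no surviving
    peptide contributes a warning entry rather than failing the build.
    """
    cfg = config or PanelConfig()
    if isinstance(proteins, (str, Path)):
        proteins = read_fasta(proteins)
    if isinstance(background, (str, Path)):
        background = read_fasta(background)
    background = list(background) if background else []

    audit: list[dict] = []
    targets: list[PeptideTarget] = []
    for protein in proteins:
        gene = protein.description.split()[-1] if protein.description else protein.accession
        peps = digest(
            protein,
            max_missed=cfg.max_missed,
            rule_model=cfg.rule_model,
            probability_threshold=cfg.probability_threshold,
        )
        survivors = filter_peptides(
            peps, cfg.min_len, cfg.max_len, cfg.probability_threshold
        )
        survivor_seqs = {p.sequence for p in survivors}
        # overrides may resurrect peptides outside the length window
        pinned: list[DigestPeptide] = [
            p
            for p in peps
            if p.sequence in cfg.overrides and p.sequence not in survivor_seqs
        ]
        candidates = survivors + pinned
        dropped = [p for p in peps if p.sequence not in {c.sequence for c in candidates}]
        for p in dropped:
            audit.append(
                {
                    "accession": protein.accession,
                    "peptide": p.sequence,
                    "kept": False,
                    "reason": "length/probability filter",
                }
            )
        if background:
            verdicts = {
                v.peptide: v
                for v in screen_uniqueness(candidates, background, cfg.equate_ile_leu)
            }
        else:
            verdicts = {}
        kept_any = False
        for p in candidates:
            v = verdicts.get(p.sequence)
            if v is not None and not v.is_unique:
                audit.append(
                    {
                        "accession": protein.accession,
                        "peptide": p.sequence,
                        "kept": False,
                        "reason": f"not unique (hits: {';'.join(v.hit_accessions)})",
                    }
                )
                continue
            if p.sequence[-1] not in "KR":
                audit.append(
                    {
                        "accession": protein.accession,
                        "peptide": p.sequence,
                        "kept": False,
                        "reason": "non-tryptic C-terminus (no SIL label site)",
                    }
                )
                continue
            flags = []
            if not (cfg.min_len <= len(p.sequence) <= cfg.max_len):
                flags.append(
                    f"length {len(p.sequence)} outside [{cfg.min_len}, {cfg.max_len}] "
                    "(pinned by override)"
                )
            charge = cfg.overrides.get(p.sequence, cfg.default_charge)
            if cfg.overrides and p.sequence not in cfg.overrides:
                audit.append(
                    {
                        "accession": protein.accession,
                        "peptide": p.sequence,
                        "kept": False,
                        "reason": "not in override list",
                    }
                )
                continue
            targets.append(
                _make_target(
                    protein,
                    p.sequence,
                    charge,
                    gene,
                    protein.description,
                    cfg.scan_range,
                    tuple(flags),
                )
            )
            kept_any = True
            audit.append(
                {
                    "accession": protein.accession,
                    "peptide": p.sequence,
                    "kept": True,
                    "reason": "; ".join(flags) if flags else "passed all filters",
                }
            )
        if not kept_any:
            audit.append(
                {
                    "accession": protein.accession,
                    "peptide": "",
                    "kept": False,
                    "reason": "WARNING: no surviving peptide for this protein",
                }
            )
    panel = AssayPanel(
        targets=targets,
        scan_range=cfg.scan_range,
        collision_energy=cfg.collision_energy,
    )
    return panel, audit


def load_bundled_panel() -> AssayPanel:
    """The bundled 18-peptide skin-AMP reference panel.

    Sequences, accessions and charges are stored; every m/z is recomputed
    from sequence and modifications at load time.
    """
    raw = yaml.safe_load(
        resources.files("prmkit.data").joinpath("skin_amp_panel.yaml").read_text()
    )
    scan_range = tuple(raw["scan_range"])
    targets = []
    for row in raw["targets"]:
        protein = ProteinRecord(
            accession=row["accession"],
            description=row["protein_name"],
            sequence=row["sequence"],  # placeholder parent; panel is pinned
        )
        flags = ()
        if not (5 <= len(row["sequence"]) <= 14):
            flags = (f"length {len(row['sequence'])} outside [5, 14]",)
        targets.append(
            _make_target(
                protein,
                row["sequence"],
                int(row["charge"]),
                row["gene"],
                row["protein_name"],
                scan_range,
                flags,
            )
        )
    return AssayPanel(
        targets=targets,
        scan_range=scan_range,
        collision_energy=float(raw["collision_energy"]),
    )


_TRANSITION_COLUMNS = [
    "protein",
    "modified_sequence",
    "precursor_mz",
    "precursor_charge",
    "fragment",
    "fragment_mz",
]
_SKYLINE_COLUMNS = [
    "Protein Name",
    "Modified Sequence",
    "Precursor Mz",
    "Precursor Charge",
    "Fragment Name",
    "Product Mz",
]


def export_transition_list(
    panel: AssayPanel, path: str | Path, dialect: str = "generic"
) -> None:
    """One CSV row per (target, channel, transition), deterministic order.

    Heavy-channel y-ion m/z are shifted by the label mass; b-ions are not
    (the label sits on the C-terminal residue).
    """
    if dialect not in ("skyline", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header = _SKYLINE_COLUMNS if dialect == "skyline" else _TRANSITION_COLUMNS
    rows = []
    for t in sorted(panel.targets, key=lambda t: (t.protein_gene, t.sequence)):
        for ion in (t.light, t.heavy):
            pre = precursor_mz(ion)
            frags = dict(
                fragment_mz_series(
                    ion, scan_min=panel.scan_range[0], scan_max=panel.scan_range[1]
                )
            )
            for label, _ in t.transitions:
                if label not in frags:
                    continue  # heavy shift can push a fragment out of range
                rows.append(
                    [
                        t.protein_gene,
                        ion.modified_sequence(),
                        f"{pre:.4f}",
                        ion.charge,
                        label,
                        f"{frags[label]:.4f}",
                    ]
                )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        writer.writerows(rows)


def read_transition_list(path: str | Path) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        rows = list(reader)
    # normalise either dialect to generic keys
    mapping = dict(zip(_SKYLINE_COLUMNS, _TRANSITION_COLUMNS))
    out = []
    for row in rows:
        norm = {mapping.get(k, k): v for k, v in row.items()}
        norm["precursor_mz"] = float(norm["precursor_mz"])
        norm["fragment_mz"] = float(norm["fragment_mz"])
        norm["precursor_charge"] = int(norm["precursor_charge"])
        out.append(norm)
    return out


def panel_to_yaml(panel: AssayPanel, path: str | Path) -> None:
    doc = {
        "version": 1,
        "scan_range": list(panel.scan_range),
        "collision_energy": panel.collision_energy,
        "targets": [
            {
                "gene": t.protein_gene,
                "protein_name": t.protein_name,
                "accession": t.accession,
                "sequence": t.sequence,
                "charge": t.charge,
                "flags": list(t.flags),
            }
            for t in panel.targets
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def panel_from_yaml(path: str | Path) -> AssayPanel:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    scan_range = tuple(raw["scan_range"])
    targets = []
    for row in raw["targets"]:
        protein = ProteinRecord(
            accession=row["accession"],
            description=row.get("protein_name", ""),
            sequence=row["sequence"],
        )
        targets.append(
            _make_target(
                protein,
                row["sequence"],
                int(row["charge"]),
                row["gene"],
                row.get("protein_name", ""),
                scan_range,
                tuple(row.get("flags", ())),
            )
        )
    return AssayPanel(
        targets=targets,
        scan_range=scan_range,
        collision_energy=float(raw.get("collision_energy", DEFAULT_NCE)),
    )


def write_audit_tsv(audit: Iterable[dict], path: str | Path) -> None:
    rows = list(audit)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["accession", "peptide", "kept", "reason"], delimiter="\t"
        )
        writer.writeheader()
        writer.writerows(rows)
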