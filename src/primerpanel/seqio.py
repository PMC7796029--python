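"""Data model and readers/writers for species-labeled sequences and primer tables.

Sequences live in :class:`SpeciesSequenceSet`, a mapping from species label to
records.  Species labels are parsed from FASTA headers using a configurable
convention (default ``id|species``); records without a separator are labeled
``"unknown"``.  Primer tables are tab-separated with columns ``Name``, ``Seq``,
``Length``, ``Tm`` and optionally ``Product``, ``Orientation``, ``Role`` and
``Target`` — the layout in which species-specific barcode panels are
conventionally published.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from ._iupac import GAP, validate

DEFAULT_HEADER_PATTERN = r"^(?P<id>[^|]+)\|(?P<species>.+)$"
UNKNOWN_SPECIES = "unknown"


class SequenceFormatError(ValueError):
    """Raised when an input sequence or table violates the format contract."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A single nucleotide record with a species label.

    Residues are uppercase IUPAC codes, 5'->3'; the gap character ``-`` is
    permitted only when ``aligned`` is set.
    """

    id: str
    species_label: str
    residues: str
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        pos = validate(self.residues, allow_gap=self.aligned)
        if pos is not None:
            raise SequenceFormatError(
                f"sequence {self.id!r}: invalid character "
                f"{self.residues[pos]!r} at position {pos + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> str:
        return self.residues.replace(GAP, "")


@dataclass
class SpeciesSequenceSet:
    """Mapping ``species label -> list of records`` with unique ids."""

    by_species: dict[str, list[NucleotideSequence]] = field(default_factory=dict)
    aligned: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for species, records in self.by_species.items():
            if not records:
                raise SequenceFormatError(f"species {species!r} has no sequences")
            for rec in records:
                if rec.id in seen:
                    raise SequenceFormatError(f"duplicate sequence id {rec.id!r}")
                seen.add(rec.id)
        if self.aligned:
            lengths = {len(r) for r in self}
            if len(lengths) > 1:
                raise SequenceFormatError(
                    f"aligned set has unequal lengths {sorted(lengths)}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.by_species)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        for records in self.by_species.values():
            yield from records

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_species.values())

    def __getitem__(self, species: str) -> list[NucleotideSequence]:
        return self.by_species[species]

    def get_by_id(self, seq_id: str) -> NucleotideSequence:
        for rec in self:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def alignment_length(self) -> int:
        if not self.aligned:
            raise SequenceFormatError("set is not aligned")
        return len(next(iter(self)))


@dataclass(frozen=True)
class Primer:
    """An oligo as synthesized, 5'->3' (reverse primers are the
    reverse-complement of the template top strand)."""

    name: str
    sequence: str
    orientation: str = "forward"  # forward | reverse
    role: str = "species_specific"  # universal | species_specific
    target_species: str | None = None
    reported_tm_C: float | None = None
    reported_length_bp: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 6:
            raise SequenceFormatError(
                f"primer {self.name!r}: length {len(self.sequence)} < 6"
            )
        pos = validate(self.sequence)
        if pos is not None:
            raise SequenceFormatError(
                f"primer {self.name!r}: invalid character at position {pos + 1}"
            )
        if self.orientation not in ("forward", "reverse"):
            raise SequenceFormatError(f"bad orientation {self.orientation!r}")
        if self.role not in ("universal", "species_specific"):
            raise SequenceFormatError(f"bad role {self.role!r}")
        if (
            self.reported_length_bp is not None
            and self.reported_length_bp != len(self.sequence)
        ):
            raise SequenceFormatError(
                f"primer {self.name!r}: reported length {self.reported_length_bp} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    expected_product_bp: int | None = None

    def __post_init__(self) -> None:
        if self.forward.orientation != "forward":
            raise SequenceFormatError(
                f"{self.forward.name!r} is not a forward primer"
            )
        if self.reverse.orientation != "reverse":
            raise SequenceFormatError(
                f"{self.reverse.name!r} is not a reverse primer"
            )


def read_fasta(
    path: str | Path,
    aligned: bool = False,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
) -> SpeciesSequenceSet:
    """Read a FASTA file into a species-keyed set.

    The species label is taken from the ``species`` group of
    ``header_pattern`` matched against the record description; records that
    do not match are labeled ``"unknown"``.
    """
    pattern = re.compile(header_pattern)
    by_species: dict[str, list[NucleotideSequence]] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        m = pattern.match(rec.description)
        if m:
            seq_id = m.group("id").strip()
            species = m.group("species").strip()
        else:
            seq_id = rec.id
            species = UNKNOWN_SPECIES
        by_species.setdefault(species, []).append(
            NucleotideSequence(seq_id, species, str(rec.seq), aligned=aligned)
        )
    if n == 0:
        raise SequenceFormatError(f"no FASTA records in {path}")
    return SpeciesSequenceSet(by_species, aligned=aligned)


def write_fasta(seq_set: SpeciesSequenceSet, path: str | Path) -> None:
    """Write a set back to FASTA using the ``id|species`` header convention."""
    with open(path, "w") as fh:
        for rec in seq_set:
            fh.write(f">{rec.id}|{rec.species_label}\n{rec.residues}\n")


_REQUIRED_COLS = ("Name", "Seq", "Length", "Tm")


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Map published header variants (e.g. "Seq. (5' -> 3')", "Tm (°C)")
    onto canonical names."""
    mapping = {}
    for col in df.columns:
        base = str(col).strip()
        for canon in ("Name", "Seq", "Length", "Tm", "Product",
                      "Orientation", "Role", "Target"):
            if base.lower().startswith(canon.lower()):
                mapping[col] = canon
                break
    return df.rename(columns=mapping)


def read_primer_table(path: str | Path) -> list[Primer]:
    """Read a tab-separated primer table.

    The printed ``Length`` column is cross-checked against the character
    count of ``Seq``; a mismatch rejects the row (with both numbers), which
    catches the most common transcription error in published primer tables.
    """
    df = _normalize_columns(pd.read_csv(path, sep="\t", dtype=str))
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SequenceFormatError(f"primer table missing columns {missing}")
    primers = []
    for _, row in df.iterrows():
        seq = str(row["Seq"]).strip().upper()
        length = int(row["Length"])
        if length != len(seq):
            raise SequenceFormatError(
                f"primer {row['Name']!r}: Length column says {length} but "
                f"sequence has {len(seq)} characters"
            )
        target = row.get("Target")
        if isinstance(target, str):
            target = target.strip() or None
            if target in ("-", "nan"):
                target = None
        else:
            target = None
        primers.append(
            Primer(
                name=str(row["Name"]).strip(),
                sequence=seq,
                orientation=str(row.get("Orientation", "forward")).strip(),
                role=str(row.get("Role", "species_specific")).strip(),
                target_species=target,
                reported_tm_C=float(row["Tm"]) if pd.notna(row["Tm"]) else None,
                reported_length_bp=length,
            )
        )
    return primers


def write_primer_table(primers: list[Primer], path: str | Path) -> None:
    rows = []
    for p in primers:
        rows.append(
            {
                "Name": p.name,
                "Seq": p.sequence,
                "Length": len(p),
                "Tm": p.reported_tm_C,
                "Orientation": p.orientation,
                "Role": p.role,
                "Target": p.target_species or "-",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_packaged_primers(marker: str) -> list[Primer]:
    """Load the packaged reference panel tables (``16s`` or ``coi``).

    These are the published 16S rRNA / COI panels for the three lethal Thai
    Chironex box jellyfish species, kept as package data so that table
    validation and thermodynamic checks run without any downloads.
    """
    marker = marker.lower()
    if marker not in ("16s", "coi"):
        raise ValueError(f"unknown marker {marker!r}")
    ref = resources.files("primerpanel.data") / f"primers_{marker}.tsv"
    with resources.as_file(ref) as p:
        return read_primer_table(p)


def write_panel_report(panel) -> str:
    """Render a panel in the conventional published layout.

    One row per primer, grouped by target species, with the shared universal
    primer repeated at the head of each species group; columns are exactly
    ``Name, Seq (5'->3'), Length, Tm, Product``.  Tm is rounded to one
    decimal.  Accepts a :class:`~primerpanel.design.PanelDesign` or a bare
    list of :class:`PrimerPair`.
    """
    header = "Name\tSeq (5'->3')\tLength\tTm\tProduct"
    lines = [header]

    def fmt(primer: Primer, product: int | None, tm: float | None) -> str:
        tm_s = f"{tm:.1f}" if tm is not None else ""
        prod_s = str(product) if product is not None else ""
        return f"{primer.name}\t{primer.sequence}\t{len(primer)}\t{tm_s}\t{prod_s}"

    pairs: list[PrimerPair]
    if hasattr(panel, "pairs"):
        pairs = list(panel.pairs.values()) if isinstance(panel.pairs, dict) else list(panel.pairs)
        if getattr(panel, "universal_pair", None) is not None:
            pairs = [panel.universal_pair] + pairs
    else:
        pairs = list(panel)

    for pair in pairs:
        for primer in (pair.forward, pair.reverse):
            tm = primer.reported_tm_C
            lines.append(fmt(primer, pair.expected_product_bp, tm))
    return "\n".join(lines) + "\n"
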