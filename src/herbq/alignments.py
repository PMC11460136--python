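"""Aligned barcode I/O and taxon grouping.

A :class:`BarcodeAlignment` holds a pre-aligned, gapped multi-FASTA for one
barcode locus (ITS, matK, ...) together with a species label per record.
Multiple accessions of the same species are expected and retained.  A
:class:`TaxonGrouping` declares which species form the target group (the
genuine drug) and which are adulterants, plus optional *joint taxa*: named
unions of adulterant species that may share a single diagnostic site.

Coordinates are 1-based alignment columns throughout.  Ambiguity codes and
gaps are preserved at read time; how they are treated is a screening-time
policy (see :mod:`herbq.screen`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import AlignmentError, ConfigError, InputError

#: Uppercase IUPAC nucleotide one-letter codes plus the gap character.
IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")

#: The four unambiguous bases.
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned sequence: identifier, species label, gapped sequence."""

    seq_id: str
    species: str
    seq: str


@dataclass
class BarcodeAlignment:
    """An aligned set of barcode sequences for a single locus.

    Invariants (checked on construction): all sequences share one length,
    sequence ids are unique, species labels are nonempty, and characters are
    uppercase IUPAC codes or gaps.
    """

    locus: str
    records: list[AlignmentRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"alignment {self.locus!r} has no records")
        length = len(self.records[0].seq)
        seen: set[str] = set()
        for rec in self.records:
            if len(rec.seq) != length:
                raise AlignmentError(
                    f"record {rec.seq_id!r} has length {len(rec.seq)}, "
                    f"expected {length} (ragged alignment)"
                )
            if rec.seq_id in seen:
                raise AlignmentError(f"duplicate sequence id {rec.seq_id!r}")
            seen.add(rec.seq_id)
            if not rec.species:
                raise AlignmentError(f"record {rec.seq_id!r} has an empty species label")
            bad = set(rec.seq) - IUPAC_CHARS
            if bad:
                raise InputError(
                    f"record {rec.seq_id!r} contains non-nucleotide "
                    f"character(s) {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].seq)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(r.species for r in self.records)

    def records_of(self, species: Iterable[str]) -> list[AlignmentRecord]:
        wanted = set(species)
        return [r for r in self.records if r.species in wanted]

    def column(self, pos: int) -> dict[str, str]:
        """Residues of every record at 1-based column ``pos``, keyed by seq_id.

        Gaps and ambiguity codes are preserved.
        """
        if not 1 <= pos <= self.length:
            raise InputError(
                f"column {pos} out of range 1..{self.length} for locus {self.locus!r}"
            )
        return {r.seq_id: r.seq[pos - 1] for r in self.records}

    def species_residues(self, pos: int) -> dict[str, frozenset[str]]:
        """Set of residues observed per species at 1-based column ``pos``."""
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.species, set()).add(r.seq[pos - 1])
        return {sp: frozenset(chars) for sp, chars in out.items()}


def column(alignment: BarcodeAlignment, pos: int) -> dict[str, str]:
    """Functional alias for :meth:`BarcodeAlignment.column`."""
    return alignment.column(pos)


def read_alignment(
    path: str | Path,
    locus: str,
    *,
    label_delimiter: str = "|",
    label_field: int = 1,
) -> BarcodeAlignment:
    """Read an aligned FASTA file into a :class:`BarcodeAlignment`.

    The species label is parsed from the FASTA description: the description is
    split on ``label_delimiter`` and field ``label_field`` (0-based) is taken.
    With the defaults, headers look like ``>acc123|F. cirrhosa``.

    Raises
    ------
    InputError
        Empty file, fewer than two records, non-IUPAC characters, or a header
        from which no species label can be parsed.
    AlignmentError
        Records of unequal length.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split(label_delimiter)
        if len(parts) <= label_field:
            raise InputError(
                f"header {rec.description!r} has no field {label_field} "
                f"when split on {label_delimiter!r}"
            )
        species = parts[label_field].strip()
        # the id is the first header field (Biopython's .id stops at whitespace)
        seq_id = parts[0].strip() if label_field != 0 else rec.id
        records.append(AlignmentRecord(seq_id, species, str(rec.seq).upper()))
    if not records:
        raise InputError(f"{path} contains no FASTA records")
    if len(records) < 2:
        raise InputError(f"{path} contains fewer than 2 records; nothing to align")
    return BarcodeAlignment(locus=locus, records=records)


def write_alignment(
    alignment: BarcodeAlignment,
    path: str | Path,
    *,
    label_delimiter: str = "|",
    width: int = 60,
) -> None:
    """Write canonical FASTA (60-column wrapping); round-trips with read_alignment."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in alignment.records:
            fh.write(f">{rec.seq_id}{label_delimiter}{rec.species}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


@dataclass(frozen=True)
class TaxonGrouping:
    """Partition of the species universe into target group and adulterants.

    ``joint_taxa`` maps a name (e.g. ``"FPB"``) to a subset of adulterant
    species that are screened jointly because no site separates them
    individually.  ``target_label`` names the target group in panels and
    reports (e.g. ``"FCB"``).
    """

    target_group: frozenset[str]
    adulterants: frozenset[str]
    joint_taxa: Mapping[str, frozenset[str]] = field(default_factory=dict)
    target_label: str = "target_group"

    def __post_init__(self) -> None:
        if not self.target_group or not self.adulterants:
            raise ConfigError("target group and adulterant set must both be nonempty")
        overlap = self.target_group & self.adulterants
        if overlap:
            raise ConfigError(
                f"species listed in both roles: {sorted(overlap)}"
            )
        for name, members in self.joint_taxa.items():
            if not members <= self.adulterants:
                raise ConfigError(
                    f"joint taxon {name!r} includes non-adulterant species "
                    f"{sorted(set(members) - self.adulterants)}"
                )

    @property
    def universe(self) -> frozenset[str]:
        return self.target_group | self.adulterants

    def resolve(self, taxon: str) -> frozenset[str]:
        """Expand a taxon name (species or joint taxon) to its species set."""
        if taxon in self.joint_taxa:
            return frozenset(self.joint_taxa[taxon])
        if taxon in self.universe:
            return frozenset({taxon})
        raise ConfigError(f"unknown taxon {taxon!r}")


def load_grouping(path: str | Path) -> TaxonGrouping:
    """Load a :class:`TaxonGrouping` from JSON or two-column TSV.

    JSON schema::

        {"target_group": [...], "adulterants": [...],
         "joint_taxa": {"FPB": [...]}, "target_label": "FCB"}

    TSV: one ``species<TAB>role`` line per species, role in
    ``{"target", "adulterant"}`` (joint taxa require the JSON form).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        data = json.loads(text)
        joint = {
            name: frozenset(members)
            for name, members in data.get("joint_taxa", {}).items()
        }
        return TaxonGrouping(
            target_group=frozenset(data.get("target_group", [])),
            adulterants=frozenset(data.get("adulterants", [])),
            joint_taxa=joint,
            target_label=data.get("target_label", "target_group"),
        )
    target, adulterant = set(), set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigError(f"{path}:{lineno}: expected 'species<TAB>role'")
        species, role = parts[0].strip(), parts[1].strip().lower()
        if role == "target":
            target.add(species)
        elif role == "adulterant":
            adulterant.add(species)
        else:
            raise ConfigError(f"{path}:{lineno}: unknown role {role!r}")
    return TaxonGrouping(frozenset(target), frozenset(adulterant))
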