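"""Input/output and validation for the shared data model.

The pipeline works on pre-aligned FASTA files (one per locus), a
specimen-to-species partition table (two-column TSV), and an optional
map of alignment coordinates to named gene regions (e.g. ITS1 / 5.8S /
ITS2).  All human-facing coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Determinate nucleotide states.
NUCLEOTIDES = frozenset("ACGT")
#: IUPAC ambiguity codes (incl. N); treated as missing data downstream.
AMBIGUITY = frozenset("RYSWKMBDHVN")
#: Gap symbol.
GAP = "-"
#: Full accepted residue alphabet.
ALPHABET = NUCLEOTIDES | AMBIGUITY | {GAP}


class AlignmentError(ValueError):
    """Raised when an input violates the alignment data-model invariants."""


@dataclass
class MultipleAlignment:
    """An equal-length gapped nucleotide alignment keyed by specimen id.

    Parameters
    ----------
    locus_name:
        Name of the locus the alignment spans (e.g. ``"ITS"`` or ``"COI"``).
    ids:
        Specimen identifiers, in input order.
    seqs:
        Residue strings, parallel to `ids`.  Uppercased on validation.
    """

    locus_name: str
    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must be parallel")
        if not self.ids:
            raise AlignmentError("empty alignment")
        seen: set[str] = set()
        for sid in self.ids:
            if not sid:
                raise AlignmentError("empty specimen id")
            if sid in seen:
                raise AlignmentError(f"duplicate specimen id {sid!r}")
            seen.add(sid)
        self.seqs = [s.upper() for s in self.seqs]
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError(f"empty sequence for {self.ids[0]!r}")
        for sid, s in zip(self.ids, self.seqs):
            if len(s) != length:
                raise AlignmentError(
                    f"unaligned input: record {sid!r} has length {len(s)}, "
                    f"expected {length}"
                )
            for pos, ch in enumerate(s, start=1):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal residue {ch!r} in record {sid!r} at position {pos}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        """Number of rows (specimens)."""
        return len(self.ids)

    def row(self, specimen_id: str) -> str:
        return self.seqs[self.ids.index(specimen_id)]

    def column(self, pos: int) -> str:
        """Residues of the 1-based column `pos`, in row order."""
        return "".join(s[pos - 1] for s in self.seqs)

    def subset(self, ids: list[str]) -> "MultipleAlignment":
        """Row-subset preserving the requested order."""
        idx = {sid: i for i, sid in enumerate(self.ids)}
        return MultipleAlignment(
            self.locus_name, list(ids), [self.seqs[idx[i]] for i in ids]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MultipleAlignment):
            return NotImplemented
        return (
            self.locus_name == other.locus_name
            and self.ids == other.ids
            and self.seqs == other.seqs
        )


@dataclass
class SpeciesPartition:
    """Specimen-to-species assignment defining the diagnosis groups."""

    assignment: dict[str, str]
    species_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species_order:
            order: list[str] = []
            for sp in self.assignment.values():
                if sp not in order:
                    order.append(sp)
            self.species_order = order
        for sp in self.species_order:
            if not sp:
                raise AlignmentError("blank species label")
            if not self.members(sp):
                raise AlignmentError(f"species {sp!r} has no specimens")

    def members(self, species: str) -> list[str]:
        return [sid for sid, sp in self.assignment.items() if sp == species]

    def species_of(self, specimen_id: str) -> str:
        return self.assignment[specimen_id]

    def check_covers(self, aln: MultipleAlignment) -> None:
        missing = [sid for sid in aln.ids if sid not in self.assignment]
        if missing:
            raise AlignmentError(
                f"specimens without species assignment: {', '.join(missing)}"
            )


@dataclass
class RegionMap:
    """Named, non-overlapping regions in 1-based inclusive alignment coordinates."""

    regions: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.regions = sorted(self.regions, key=lambda r: r[1])
        prev_end = 0
        for name, start, end in self.regions:
            if start < 1 or end < start:
                raise AlignmentError(f"bad region {name!r}: [{start}, {end}]")
            if start <= prev_end:
                raise AlignmentError(f"region {name!r} overlaps its predecessor")
            prev_end = end

    def region_of(self, pos: int) -> str:
        """Region name containing 1-based `pos`, or ``"unassigned"``."""
        for name, start, end in self.regions:
            if start <= pos <= end:
                return name
        return "unassigned"


def read_fasta(path, locus_name: str) -> MultipleAlignment:
    """Read an aligned FASTA file into a validated :class:`MultipleAlignment`.

    Record order is preserved and residues are uppercased.  Unequal record
    lengths, illegal residues and duplicate ids raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return MultipleAlignment(
        locus_name, [r.id for r in records], [str(r.seq) for r in records]
    )


def write_fasta(aln: MultipleAlignment, path) -> None:
    """Write an alignment as FASTA; ``read_fasta`` round-trips it exactly."""
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(aln.ids, aln.seqs)
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta-2line")


def read_partition(path) -> SpeciesPartition:
    """Read a two-column TSV ``specimen_id<TAB>species``.

    A header line is tolerated (detected as ``specimen`` / ``species``-like
    first row).  Species order is first-appearance order.  A specimen listed
    twice with different species raises a conflict error.
    """
    assignment: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            sid, sp = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sid.lower() in {"specimen", "specimen_id", "id"}:
                continue
            if not sp:
                raise AlignmentError(f"{path}:{lineno}: blank species for {sid!r}")
            if sid in assignment and assignment[sid] != sp:
                raise AlignmentError(
                    f"conflict: specimen {sid!r} assigned to both "
                    f"{assignment[sid]!r} and {sp!r}"
                )
            assignment[sid] = sp
    if not assignment:
        raise AlignmentError(f"empty partition table {path}")
    return SpeciesPartition(assignment)


def write_partition(part: SpeciesPartition, path) -> None:
    with open(path, "w") as handle:
        for sp in part.species_order:
            for sid in part.members(sp):
                handle.write(f"{sid}\t{sp}\n")


def read_regions(path) -> RegionMap:
    """Read a region map TSV ``region<TAB>start<TAB>end`` (1-based inclusive)."""
    regions: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            name = parts[0].strip()
            if lineno == 1 and name.lower() == "region":
                continue
            regions.append((name, int(parts[1]), int(parts[2])))
    return RegionMap(regions)


def write_regions(rmap: RegionMap, path) -> None:
    with open(path, "w") as handle:
        for name, start, end in rmap.regions:
            handle.write(f"{name}\t{start}\t{end}\n")


def fasta_string(aln: MultipleAlignment) -> str:
    """Alignment serialized as a FASTA string (two-line records)."""
    buf = io.StringIO()
    for sid, s in zip(aln.ids, aln.seqs):
        buf.write(f">{sid}\n{s}\n")
    return buf.getvalue()
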