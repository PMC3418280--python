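"""Character-based species diagnosis (Davis-Nixon characteristic attributes).

A *pure diagnostic character* for a species is an alignment position whose
state is fixed in every member of the species and absent from every
non-member.  When no single position suffices, a species may still be
diagnosable by a *composite diagnostic combination*: a minimal set of
positions, each fixed within the species, whose joint states occur in every
member but in no single individual outside the species.

Fixation is strict (every member shares the state); ambiguity codes are
missing data and conservatively block both fixation (an ambiguous member
cannot be confirmed to carry the state) and exclusivity (an ambiguous
non-member might carry it).  Under the default ``exclude-column`` gap
policy, columns containing any gap are removed from the search, since they
carry alignment rather than substitution signal; ``fifth-state`` treats the
gap as an ordinary character state for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal

from .seqio import GAP, NUCLEOTIDES, MultipleAlignment, RegionMap, SpeciesPartition

GapPolicy = Literal["exclude-column", "fifth-state"]


@dataclass(frozen=True)
class DiagnosticCharacter:
    """A pure diagnostic nucleotide: 1-based position and fixed state."""

    locus: str
    position: int
    state: str
    species: str
    region: str = "unassigned"


@dataclass(frozen=True)
class CompositeDiagnostic:
    """A minimal composite combination of (locus, position, state) members."""

    species: str
    members: tuple[tuple[str, int, str], ...]
    minimal: bool = True

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class SpeciesDiagnosis:
    species: str
    pure: list[DiagnosticCharacter] = field(default_factory=list)
    composite: list[CompositeDiagnostic] = field(default_factory=list)
    n_specimens: int = 0

    @property
    def verdict(self) -> str:
        if self.pure:
            return "pure"
        if self.composite:
            return "composite-only"
        return "undiagnosable"


@dataclass
class DiagnosisReport:
    """Per-species diagnosis merged across loci (the figure-style report)."""

    by_species: dict[str, SpeciesDiagnosis]

    def verdict(self, species: str) -> str:
        return self.by_species[species].verdict


def _determinate(gap_policy: GapPolicy) -> frozenset[str]:
    return NUCLEOTIDES | {GAP} if gap_policy == "fifth-state" else NUCLEOTIDES


def _candidate_columns(aln: MultipleAlignment, gap_policy: GapPolicy) -> list[int]:
    """1-based columns eligible for diagnosis under the gap policy."""
    cols = []
    for pos in range(1, aln.length + 1):
        col = aln.column(pos)
        if gap_policy == "exclude-column" and GAP in col:
            continue
        cols.append(pos)
    return cols


def _fixed_state(
    residues: list[str], determinate: frozenset[str]
) -> str | None:
    """The common determinate state of `residues`, or None if not fixed."""
    states = set(residues)
    if len(states) == 1 and residues[0] in determinate:
        return residues[0]
    return None


def find_pure_diagnostics(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    gap_policy: GapPolicy = "exclude-column",
) -> list[DiagnosticCharacter]:
    """All pure diagnostic characters of the alignment, per species.

    Returns exactly the (position, state, species) triples where the state
    is fixed and determinate within the species and every non-member carries
    a different determinate state at that position.
    """
    part.check_covers(aln)
    if len(part.species_order) < 2:
        raise ValueError("diagnosis requires >= 2 species")
    determinate = _determinate(gap_policy)
    member_rows = {
        sp: [aln.ids.index(sid) for sid in part.members(sp) if sid in set(aln.ids)]
        for sp in part.species_order
    }
    out: list[DiagnosticCharacter] = []
    for sp in part.species_order:
        rows = member_rows[sp]
        if not rows:
            continue
        others = [i for i in range(aln.n) if i not in set(rows)]
        found_any_column = False
        for pos in _candidate_columns(aln, gap_policy):
            col = aln.column(pos)
            if all(col[i] in determinate for i in rows):
                found_any_column = True
            state = _fixed_state([col[i] for i in rows], determinate)
            if state is None:
                continue
            # exclusivity: every non-member determinate and different
            if all(col[i] in determinate and col[i] != state for i in others):
                out.append(DiagnosticCharacter(aln.locus_name, pos, state, sp))
        if not found_any_column:
            warnings.warn(
                f"species {sp!r} has no fully determinate column in "
                f"{aln.locus_name}; diagnosis may be incomplete"
            )
    out.sort(key=lambda d: (part.species_order.index(d.species), d.position))
    return out


def find_composite_diagnostics(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    max_size: int = 6,
    gap_policy: GapPolicy = "exclude-column",
) -> list[CompositeDiagnostic]:
    """Minimal-cardinality composite combinations per species.

    The search is restricted, per species, to columns that are fixed and
    determinate within the species but not pure-diagnostic for it, and among
    those to columns that at least one non-member fails to match (a column
    matched by every non-member can never appear in a minimal set).  Subsets
    are enumerated by increasing cardinality; the first cardinality yielding
    a satisfying set is reported and the search stops for that species, which
    guarantees minimality (any working proper subset would have been found
    at a smaller cardinality, and single-column subsets are pure diagnostics,
    which are excluded).  Ordering is deterministic: (cardinality, positions).
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    part.check_covers(aln)
    determinate = _determinate(gap_policy)
    pure = find_pure_diagnostics(aln, part, gap_policy)
    pure_positions = {
        sp: {d.position for d in pure if d.species == sp}
        for sp in part.species_order
    }
    out: list[CompositeDiagnostic] = []
    id_set = set(aln.ids)
    for sp in part.species_order:
        rows = [aln.ids.index(sid) for sid in part.members(sp) if sid in id_set]
        if not rows:
            continue
        if pure_positions[sp]:
            # already diagnosable by single characters; composites are built
            # only from non-pure columns, so a combination may still exist,
            # but the verdict never depends on it.  Search anyway: the report
            # lists both lines of evidence.
            pass
        others = [i for i in range(aln.n) if i not in set(rows)]
        if not others:
            continue
        # candidate columns: fixed in species, not pure, informative vs >=1 other
        candidates: list[tuple[int, str]] = []
        for pos in _candidate_columns(aln, gap_policy):
            if pos in pure_positions[sp]:
                continue
            col = aln.column(pos)
            state = _fixed_state([col[i] for i in rows], determinate)
            if state is None:
                continue
            # a non-member "matches" if its residue equals the state, or is
            # missing (conservatively treated as a possible match)
            mismatching = [
                i for i in others if col[i] in determinate and col[i] != state
            ]
            if mismatching:
                candidates.append((pos, state))
        if not candidates:
            continue
        cols = {pos: aln.column(pos) for pos, _ in candidates}

        def matches(i: int, pos: int, state: str) -> bool:
            ch = cols[pos][i]
            return ch == state or ch not in determinate

        found: list[CompositeDiagnostic] = []
        for k in range(2, min(max_size, len(candidates)) + 1):
            for combo in combinations(candidates, k):
                if not any(
                    all(matches(i, pos, st) for pos, st in combo) for i in others
                ):
                    found.append(
                        CompositeDiagnostic(
                            sp,
                            tuple((aln.locus_name, pos, st) for pos, st in combo),
                        )
                    )
            if found:
                break
        out.extend(found)
    return out


def diagnose_locus(
    aln: MultipleAlignment,
    part: SpeciesPartition,
    max_size: int = 6,
    gap_policy: GapPolicy = "exclude-column",
) -> tuple[list[DiagnosticCharacter], list[CompositeDiagnostic]]:
    return (
        find_pure_diagnostics(aln, part, gap_policy),
        find_composite_diagnostics(aln, part, max_size, gap_policy),
    )


def diagnosis_report(
    per_locus: dict[str, tuple[list[DiagnosticCharacter], list[CompositeDiagnostic]]],
    part: SpeciesPartition,
    regions: dict[str, RegionMap] | None = None,
) -> DiagnosisReport:
    """Merge per-locus results into a per-species report with region labels."""
    regions = regions or {}
    by_species = {
        sp: SpeciesDiagnosis(sp, n_specimens=len(part.members(sp)))
        for sp in part.species_order
    }
    for locus, (pure, composites) in per_locus.items():
        rmap = regions.get(locus)
        for d in pure:
            region = rmap.region_of(d.position) if rmap else "unassigned"
            by_species[d.species].pure.append(
                DiagnosticCharacter(d.locus, d.position, d.state, d.species, region)
            )
        for c in composites:
            by_species[c.species].composite.append(c)
    return DiagnosisReport(by_species)


def report_tsv(report: DiagnosisReport) -> str:
    """TSV rendering: locus, species, kind, set id, position, state, region."""
    lines = ["locus\tspecies\tkind\tset_id\tposition\tstate\tregion"]
    for sp, diag in report.by_species.items():
        for d in diag.pure:
            lines.append(f"{d.locus}\t{sp}\tpure\t-\t{d.position}\t{d.state}\t{d.region}")
        for si, c in enumerate(diag.composite, start=1):
            for locus, pos, st in c.members:
                lines.append(
                    f"{locus}\t{sp}\tcomposite\t{si}\t{pos}\t{st}\tunassigned"
                )
    return "\n".join(lines) + "\n"


def report_text(report: DiagnosisReport) -> str:
    """Human-readable summary of the diagnosis."""
    lines: list[str] = []
    provisional = False
    for sp, diag in report.by_species.items():
        lines.append(f"{sp} (n = {diag.n_specimens}): verdict {diag.verdict}")
        for d in diag.pure:
            lines.append(
                f"  pure: {d.locus} position {d.position} = {d.state} [{d.region}]"
            )
        for c in diag.composite:
            members = ", ".join(f"{l}:{p}={s}" for l, p, s in c.members)
            lines.append(f"  composite (size {c.size}): {members}")
        if diag.n_specimens == 1:
            provisional = True
    if provisional:
        lines.append(
            "note: species represented by a single specimen are provisionally "
            "diagnostic (fixation within the species is trivially satisfied)"
        )
    return "\n".join(lines) + "\n"
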