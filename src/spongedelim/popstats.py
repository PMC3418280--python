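"""Alignment summary statistics.

Haplotype collapsing, Nei's unbiased haplotype diversity h, nucleotide
diversity pi, and classification of alignment columns into invariant,
singleton-variable and parsimony-informative sites.

Barcode data sets for low-divergence taxa often carry their intraspecific
variation exclusively in indels; the defaults here (gap-bearing columns
excluded from site counts, indels excluded from pi) are chosen so that such
data yield pi = 0 and zero intraspecific substitutions, while the indel
haplotypes remain visible to the indel-aware haplotype collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .seqio import GAP, NUCLEOTIDES, MultipleAlignment

GapPolicy = Literal["exclude-column", "fifth-state"]


@dataclass
class HaplotypeTable:
    """Distinct haplotypes of an alignment with counts and members."""

    haplotypes: list[tuple[str, int, list[str]]]
    mode: str

    @property
    def counts(self) -> list[int]:
        return [c for _, c, _ in self.haplotypes]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)


@dataclass
class SiteClassification:
    """Per-column classes and aggregate counts; classes sum to the length."""

    classes: list[str]

    def count(self, cls: str) -> int:
        return self.classes.count(cls)

    @property
    def variable(self) -> int:
        """Segregating-site count (singletons plus parsimony-informative)."""
        return self.count("variable-singleton") + self.count("parsimony-informative")

    @property
    def parsimony_informative(self) -> int:
        return self.count("parsimony-informative")

    @property
    def invariant(self) -> int:
        return self.count("invariant")


def collapse_haplotypes(
    aln: MultipleAlignment,
    mode: Literal["indel-aware", "substitutions-only"] = "indel-aware",
) -> HaplotypeTable:
    """Group identical rows into haplotypes.

    ``indel-aware`` compares full residue strings including gaps;
    ``substitutions-only`` first drops every column in which any row has a
    gap, so rows differing only by indels collapse together.
    """
    if mode == "substitutions-only":
        keep = [
            i
            for i in range(aln.length)
            if all(s[i] != GAP for s in aln.seqs)
        ]
        keys = ["".join(s[i] for i in keep) for s in aln.seqs]
    elif mode == "indel-aware":
        keys = list(aln.seqs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    groups: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    haplotypes = [
        (aln.seqs[members[0]], len(members), [aln.ids[i] for i in members])
        for members in groups.values()
    ]
    return HaplotypeTable(haplotypes, mode)


def haplotype_diversity(counts: Iterable[int]) -> float:
    """Nei's unbiased haplotype diversity h = n/(n-1) * (1 - sum p_i^2).

    h is 0 for a monomorphic sample and 1 for a sample of singletons.
    Undefined for fewer than two sequences.
    """
    counts = list(counts)
    if any(c <= 0 for c in counts):
        raise ValueError("haplotype counts must be positive")
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    ss = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1.0 - ss)


def nucleotide_diversity(
    aln: MultipleAlignment,
    deletion: Literal["pairwise", "complete"] = "pairwise",
    indels: Literal["exclude", "fifth-state"] = "exclude",
) -> float:
    """Average per-site pairwise difference (pi) among the rows.

    With ``indels="exclude"`` a site where either sequence of a pair carries
    a gap is skipped, so indel-only variation yields pi = 0.  With
    ``indels="fifth-state"`` the gap acts as a fifth character state.
    Ambiguity codes are always missing.  ``deletion="complete"`` drops every
    column containing a gap or missing residue in any row before comparing.
    """
    if aln.n < 2:
        raise ValueError("nucleotide diversity requires >= 2 rows")
    determinate = NUCLEOTIDES | ({GAP} if indels == "fifth-state" else set())
    seqs = aln.seqs
    if deletion == "complete":
        keep = [
            i
            for i in range(aln.length)
            if all(s[i] in determinate for s in seqs)
        ]
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    total = 0.0
    npairs = 0
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            diffs = comparable = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in determinate and b in determinate:
                    comparable += 1
                    if a != b:
                        diffs += 1
            if comparable == 0:
                raise ValueError(
                    f"zero comparable sites between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            total += diffs / comparable
            npairs += 1
    return total / npairs


def classify_sites(
    aln: MultipleAlignment, gap_policy: GapPolicy = "exclude-column"
) -> SiteClassification:
    """Classify every column of the alignment.

    A column is *variable* (segregating) if at least two determinate states
    are observed, and *parsimony-informative* if at least two states are each
    carried by at least two sequences.  Ambiguity codes are missing and never
    contribute a state.  Under ``exclude-column`` a column containing any gap
    is classed ``gap-excluded`` and contributes to no count; under
    ``fifth-state`` the gap is an ordinary state.
    """
    classes: list[str] = []
    for pos in range(1, aln.length + 1):
        col = aln.column(pos)
        if gap_policy == "exclude-column" and GAP in col:
            classes.append("gap-excluded")
            continue
        determinate = NUCLEOTIDES | ({GAP} if gap_policy == "fifth-state" else set())
        states: dict[str, int] = {}
        for ch in col:
            if ch in determinate:
                states[ch] = states.get(ch, 0) + 1
        if sum(states.values()) < 2:
            classes.append("missing-excluded")
        elif len(states) < 2:
            classes.append("invariant")
        elif sum(1 for c in states.values() if c >= 2) >= 2:
            classes.append("parsimony-informative")
        else:
            classes.append("variable-singleton")
    return SiteClassification(classes)


def locus_summary(
    aln: MultipleAlignment, gap_policy: GapPolicy = "exclude-column"
) -> dict:
    """One-row summary used by the ``stats`` CLI table."""
    haps = collapse_haplotypes(aln, "indel-aware")
    sites = classify_sites(aln, gap_policy)
    h = haplotype_diversity(haps.counts) if aln.n >= 2 else float("nan")
    pi = nucleotide_diversity(aln) if aln.n >= 2 else float("nan")
    return {
        "locus": aln.locus_name,
        "n_sequences": aln.n,
        "length": aln.length,
        "variable_sites": sites.variable,
        "parsimony_informative": sites.parsimony_informative,
        "haplotypes": haps.n_haplotypes,
        "haplotype_diversity": h,
        "nucleotide_diversity": pi,
    }
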