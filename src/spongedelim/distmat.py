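"""Pairwise divergence matrices.

Uncorrected p-distance with pairwise or complete deletion of sites carrying
gaps or ambiguity codes, optional Jukes-Cantor (JC69) and Kimura two-parameter
(K2P) corrections, and lower-triangular percent tables for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

import numpy as np

from .seqio import GAP, NUCLEOTIDES, MultipleAlignment

Model = Literal["p", "jc69", "k2p"]
Deletion = Literal["pairwise", "complete"]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric divergence matrix on taxon labels (proportions in [0, 1])."""

    labels: list[str]
    values: np.ndarray
    model: str = "p"
    deletion: str = "pairwise"
    comparable_sites: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise DistanceError("matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DistanceError("nonzero diagonal")
        if np.any(self.values < 0):
            raise DistanceError("negative distance")

    @property
    def n(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, labels: list[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        comp = (
            self.comparable_sites[np.ix_(idx, idx)]
            if self.comparable_sites is not None
            else None
        )
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.model, self.deletion, comp
        )


def p_distance(
    x: str, y: str, deletion: Deletion = "pairwise"
) -> tuple[float, int]:
    """Uncorrected p-distance between two aligned residue strings.

    Returns ``(proportion of differing sites, number of comparable sites)``.
    A site is comparable when both residues are determinate nucleotides; gaps
    and ambiguity codes at either sequence are skipped under pairwise
    deletion.  ``complete-context`` mode assumes the caller already masked
    the alignment and applies the same per-site rule.
    """
    if len(x) != len(y):
        raise DistanceError("sequences of unequal length")
    diffs = comparable = 0
    for a, b in zip(x.upper(), y.upper()):
        if a in NUCLEOTIDES and b in NUCLEOTIDES:
            comparable += 1
            if a != b:
                diffs += 1
    if comparable == 0:
        raise DistanceError("zero comparable sites")
    return diffs / comparable, comparable


def jc69(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - (4/3) p)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise DistanceError(f"JC69 undefined for p = {p}")
    return -0.75 * math.log(arg)


def _k2p(x: str, y: str) -> float:
    """Kimura two-parameter distance from transition/transversion proportions."""
    ts = tv = comparable = 0
    for a, b in zip(x, y):
        if a in NUCLEOTIDES and b in NUCLEOTIDES:
            comparable += 1
            if a != b:
                if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
                    ts += 1
                else:
                    tv += 1
    if comparable == 0:
        raise DistanceError("zero comparable sites")
    P, Q = ts / comparable, tv / comparable
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        raise DistanceError(f"K2P undefined for P = {P}, Q = {Q}")
    return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)


def mask_complete(aln: MultipleAlignment) -> MultipleAlignment:
    """Drop every column containing a gap or ambiguity code in any row."""
    keep = [
        i
        for i in range(aln.length)
        if all(s[i] in NUCLEOTIDES for s in aln.seqs)
    ]
    if not keep:
        raise DistanceError("complete deletion removed every column")
    return MultipleAlignment(
        aln.locus_name, list(aln.ids), ["".join(s[i] for i in keep) for s in aln.seqs]
    )


def distance_matrix(
    aln: MultipleAlignment,
    model: Model = "p",
    deletion: Deletion = "pairwise",
) -> DistanceMatrix:
    """All-pairs divergence matrix for the rows of an alignment."""
    if aln.n < 2:
        raise DistanceError("need >= 2 rows")
    work = mask_complete(aln) if deletion == "complete" else aln
    n = work.n
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                p, c = p_distance(work.seqs[i], work.seqs[j])
                if model == "p":
                    d = p
                elif model == "jc69":
                    d = jc69(p)
                elif model == "k2p":
                    d = _k2p(work.seqs[i], work.seqs[j])
                else:
                    raise DistanceError(f"unknown model {model!r}")
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({work.ids[i]!r}, {work.ids[j]!r}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = d
            comp[i, j] = comp[j, i] = c
    return DistanceMatrix(list(work.ids), values, model, deletion, comp)


def _round_half_up(value: float, digits: int) -> str:
    q = Decimal(10) ** -digits
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_distance_table(
    m: DistanceMatrix,
    scale: Literal["proportion", "percent"] = "percent",
    digits: int = 3,
) -> str:
    """Lower-triangular TSV table (half-away-from-zero rounding)."""
    factor = 100.0 if scale == "percent" else 1.0
    lines = ["\t" + "\t".join(m.labels[:-1])]
    for i in range(1, m.n):
        cells = [m.labels[i]]
        for j in range(i):
            cells.append(_round_half_up(m.values[i, j] * factor, digits))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def format_phylip(m: DistanceMatrix, digits: int = 6) -> str:
    """Square PHYLIP-style distance matrix for interoperability."""
    lines = [f"{m.n}"]
    for i, label in enumerate(m.labels):
        row = " ".join(f"{m.values[i, j]:.{digits}f}" for j in range(m.n))
        lines.append(f"{label.replace(' ', '_'):<12s} {row}")
    return "\n".join(lines) + "\n"


def read_phylip(text: str) -> DistanceMatrix:
    """Parse a square PHYLIP distance matrix (as written by `format_phylip`)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([float(v) for v in parts[1 : n + 1]])
    return DistanceMatrix(labels, np.array(rows))
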