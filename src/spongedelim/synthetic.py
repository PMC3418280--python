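"""Synthetic multi-species barcode alignments with planted, known truth.

The generator emulates the structure of low-divergence sponge barcode data:
a handful of species, each represented by one or a few near-identical
haplotypes; interspecific divergence of a few substitutions per locus
(~0.1-2%); intraspecific variation carried only by indels; planted pure
diagnostic sites; and planted composite-only diagnostic combinations.

Substitutions are placed without replacement among free positions, so
pairwise substitution counts are exact integers and expected p-distances
are exact ratios k/L rather than expectations.  Indels are insertions
carried by a subset of one species' specimens, realized as gap columns in
the emitted pre-aligned FASTA (no aligner in the loop).  One global seed
governs all randomness; per-locus streams are derived by stable hashing of
(seed, locus name), so truth files replay bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .seqio import (
    MultipleAlignment,
    RegionMap,
    SpeciesPartition,
    write_fasta,
    write_partition,
    write_regions,
)

BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """Raised for infeasible simulation specs, before any file is written."""


@dataclass
class LocusSpec:
    """Per-locus planted structure.

    ``pair_substitutions`` maps unordered species pairs to the number of
    substitutions separating their haplotypes (from private substitutions,
    planted pure diagnostics included).  The map is star-decomposed into
    per-species private counts; an inconsistent or non-integral map is an
    error.  ``planted_pure`` positions/states (state ``None`` = pick a state
    differing from the background) become pure diagnostics and draw from the
    same private budget.  Each member of a ``planted_composite`` set is
    shared with another species so it is never a pure diagnostic.
    """

    name: str
    length: int
    pair_substitutions: dict[tuple[str, str], int] = field(default_factory=dict)
    planted_pure: dict[str, list[tuple[int, str | None]]] = field(
        default_factory=dict
    )
    planted_composites: dict[str, list[list[tuple[int, str | None]]]] = field(
        default_factory=dict
    )
    indel_events: list[tuple[str, int]] = field(default_factory=list)
    regions: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SimSpec:
    seed: int
    species: list[tuple[str, int]]
    loci: list[LocusSpec]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "species": [[s, n] for s, n in self.species],
            "loci": [
                {
                    "name": l.name,
                    "length": l.length,
                    "pair_substitutions": [
                        [a, b, k] for (a, b), k in sorted(l.pair_substitutions.items())
                    ],
                    "planted_pure": {
                        sp: [[p, st] for p, st in v]
                        for sp, v in l.planted_pure.items()
                    },
                    "planted_composites": {
                        sp: [[[p, st] for p, st in cset] for cset in v]
                        for sp, v in l.planted_composites.items()
                    },
                    "indel_events": [[s, ln] for s, ln in l.indel_events],
                    "regions": [[n, a, b] for n, a, b in l.regions],
                }
                for l in self.loci
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimSpec":
        d = json.loads(text)
        loci = [
            LocusSpec(
                name=l["name"],
                length=l["length"],
                pair_substitutions={
                    tuple(sorted((a, b))): k
                    for a, b, k in l.get("pair_substitutions", [])
                },
                planted_pure={
                    sp: [(p, st) for p, st in v]
                    for sp, v in l.get("planted_pure", {}).items()
                },
                planted_composites={
                    sp: [[(p, st) for p, st in cset] for cset in v]
                    for sp, v in l.get("planted_composites", {}).items()
                },
                indel_events=[(s, ln) for s, ln in l.get("indel_events", [])],
                regions=[(n, a, b) for n, a, b in l.get("regions", [])],
            )
            for l in d["loci"]
        ]
        return cls(d["seed"], [(s, n) for s, n in d["species"]], loci)


@dataclass
class SimTruth:
    """Realized data plus the exact expected outputs of every pipeline stage."""

    alignments: dict[str, MultipleAlignment]
    partition: SpeciesPartition
    regions: dict[str, RegionMap]
    #: species -> list of (locus, 1-based position, state) pure diagnostics
    expected_pure: dict[str, list[tuple[str, int, str]]]
    #: species -> minimal composite cardinality (only composite-only species)
    expected_composite_cardinality: dict[str, int]
    #: (locus, species_a, species_b) -> substitution count between haplotypes
    pair_counts: dict[tuple[str, str, str], int]
    #: species -> specimen ids (the planted tree bipartitions)
    species_members: dict[str, list[str]]

    def to_json(self) -> str:
        payload = {
            "expected_pure": {
                sp: [[l, p, s] for l, p, s in v]
                for sp, v in sorted(self.expected_pure.items())
            },
            "expected_composite_cardinality": dict(
                sorted(self.expected_composite_cardinality.items())
            ),
            "pair_counts": [
                [l, a, b, k] for (l, a, b), k in sorted(self.pair_counts.items())
            ],
            "species_members": dict(sorted(self.species_members.items())),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _locus_rng(seed: int, locus_name: str) -> np.random.Generator:
    return np.random.default_rng(
        [seed % (2**31), zlib.crc32(locus_name.encode())]
    )


def _star_decompose(
    species: list[str], pairs: dict[tuple[str, str], int]
) -> dict[str, int]:
    """Solve k_ab = x_a + x_b for per-species private counts x."""
    if not pairs:
        return {sp: 0 for sp in species}
    norm = {tuple(sorted(k)): v for k, v in pairs.items()}

    def k(a: str, b: str) -> int:
        key = tuple(sorted((a, b)))
        if key not in norm:
            raise SimulationError(f"missing pair count for {key}")
        return norm[key]

    if len(species) == 2:
        a, b = species
        total = k(a, b)
        return {a: total - total // 2, b: total // 2}
    x: dict[str, int] = {}
    for sp in species:
        o1, o2 = [s for s in species if s != sp][:2]
        num = k(sp, o1) + k(sp, o2) - k(o1, o2)
        if num < 0 or num % 2:
            raise SimulationError(
                f"pair substitution counts are not star-decomposable at {sp!r}"
            )
        x[sp] = num // 2
    for (p, q), v in norm.items():
        if x[p] + x[q] != v:
            raise SimulationError(
                f"inconsistent pair substitution counts for ({p}, {q})"
            )
    return x


def simulate(spec: SimSpec, out_dir: str | Path | None = None) -> SimTruth:
    """Generate alignments and truth for `spec`; optionally write files.

    Writes, when `out_dir` is given: one FASTA per locus, ``partition.tsv``,
    ``regions_<locus>.tsv`` per locus with regions, ``spec.json`` and
    ``truth.json``.  Deterministic under (spec, seed).
    """
    species_labels = [s for s, _ in spec.species]
    if len(set(species_labels)) != len(species_labels):
        raise SimulationError("duplicate species labels")
    specimen_ids = {
        sp: [f"{sp}_{i + 1:02d}" for i in range(n)] for sp, n in spec.species
    }
    assignment = {
        sid: sp for sp, ids in specimen_ids.items() for sid in ids
    }
    partition = SpeciesPartition(assignment, species_labels)

    alignments: dict[str, MultipleAlignment] = {}
    regions: dict[str, RegionMap] = {}
    expected_pure: dict[str, list[tuple[str, int, str]]] = {
        sp: [] for sp in species_labels
    }
    pair_counts: dict[tuple[str, str, str], int] = {}
    composite_truth: dict[str, int] = {}

    for locus in spec.loci:
        rng = _locus_rng(spec.seed, locus.name)
        L = locus.length
        root = rng.choice(BASES, size=L)
        used: set[int] = set()  # 1-based positions carrying planted structure
        subs: dict[str, dict[int, str]] = {sp: {} for sp in species_labels}

        def take_state(pos: int, state: str | None) -> str:
            if not 1 <= pos <= L:
                raise SimulationError(
                    f"{locus.name}: planted position {pos} outside [1, {L}]"
                )
            if pos in used:
                raise SimulationError(
                    f"{locus.name}: planted position {pos} used twice"
                )
            bg = root[pos - 1]
            if state is None:
                choices = [b for b in "ACGT" if b != bg]
                state = choices[int(rng.integers(0, 3))]
            if state == bg:
                raise SimulationError(
                    f"{locus.name}: planted state at {pos} equals background"
                )
            used.add(pos)
            return state

        # planted pure diagnostics (private substitutions)
        for sp, sites in locus.planted_pure.items():
            for pos, st in sites:
                subs[sp][pos] = take_state(pos, st)

        # planted composite-only combinations: each member state is shared
        # with one other species, and members of a set are shared with at
        # least two distinct partners so no single non-member matches all
        for sp, csets in locus.planted_composites.items():
            others = [s for s in species_labels if s != sp]
            if len(others) < 2:
                raise SimulationError(
                    "composite-only planting needs >= 3 species (a single "
                    "other species would match every member)"
                )
            for cset in csets:
                if len(cset) < 2:
                    raise SimulationError("composite sets need >= 2 members")
                partners = list(rng.permutation(others))
                for mi, (pos, st) in enumerate(cset):
                    state = take_state(pos, st)
                    subs[sp][pos] = state
                    subs[partners[mi % len(partners)]][pos] = state

        # remaining private substitutions from the pair-count budget
        x = _star_decompose(species_labels, locus.pair_substitutions)
        free = [p for p in range(1, L + 1) if p not in used]
        for sp in species_labels:
            planted_private = len(locus.planted_pure.get(sp, []))
            extra = x.get(sp, 0) - planted_private
            if extra < 0:
                raise SimulationError(
                    f"{locus.name}: species {sp!r} has more planted pure "
                    "diagnostics than its pair-count budget allows"
                )
            if extra > len(free):
                raise SimulationError(f"{locus.name}: locus too short")
            picks = rng.choice(len(free), size=extra, replace=False)
            for k in sorted(int(i) for i in picks):
                pos = free[k]
                subs[sp][pos] = take_state(pos, None)
            free = [p for p in free if p not in used]

        # indel insertions: gap columns for everyone except a carrier subset
        gap_cols: set[int] = set()
        insertions: list[tuple[str, list[str], int, np.ndarray]] = []
        n_of = dict(spec.species)
        for sp, ln in locus.indel_events:
            runs = [
                start
                for start in range(1, L - ln + 2)
                if all(p not in used and p not in gap_cols
                       for p in range(start, start + ln))
            ]
            if not runs:
                raise SimulationError(
                    f"{locus.name}: no room for a {ln}-column indel"
                )
            start = runs[int(rng.integers(0, len(runs)))]
            cols = range(start, start + ln)
            gap_cols.update(cols)
            n_sp = n_of[sp]
            k_carriers = int(rng.integers(1, n_sp)) if n_sp > 1 else 1
            carrier_idx = sorted(
                int(i) for i in rng.choice(n_sp, size=k_carriers, replace=False)
            )
            carriers = [specimen_ids[sp][i] for i in carrier_idx]
            bases = rng.choice(BASES, size=ln)
            insertions.append((sp, carriers, start, bases))

        # species haplotypes and specimen rows
        haplotypes: dict[str, list[str]] = {}
        for sp in species_labels:
            hap = list(root)
            for pos, st in subs[sp].items():
                hap[pos - 1] = st
            for p in gap_cols:
                hap[p - 1] = "-"
            haplotypes[sp] = hap
        ids: list[str] = []
        seqs: list[str] = []
        for sp in species_labels:
            for sid in specimen_ids[sp]:
                row = list(haplotypes[sp])
                for isp, carriers, start, bases in insertions:
                    if sid in carriers:
                        row[start - 1 : start - 1 + len(bases)] = list(bases)
                ids.append(sid)
                seqs.append("".join(row))
        aln = MultipleAlignment(locus.name, ids, seqs)
        alignments[locus.name] = aln
        if locus.regions:
            regions[locus.name] = RegionMap(list(locus.regions))

        # --- truth, recomputed from the realized haplotypes -----------------
        hap_strings = {sp: "".join(h) for sp, h in haplotypes.items()}
        solid = [p for p in range(1, L + 1) if p not in gap_cols]
        for sp in species_labels:
            for pos in solid:
                st = hap_strings[sp][pos - 1]
                if all(
                    hap_strings[o][pos - 1] != st
                    for o in species_labels
                    if o != sp
                ):
                    expected_pure[sp].append((locus.name, pos, st))
        for a, b in combinations(sorted(species_labels), 2):
            count = sum(
                1
                for p in solid
                if hap_strings[a][p - 1] != hap_strings[b][p - 1]
            )
            pair_counts[(locus.name, a, b)] = count
        for sp in locus.planted_composites:
            card = _min_composite_cardinality(
                hap_strings, species_labels, sp, solid
            )
            if card is not None:
                composite_truth[sp] = min(
                    composite_truth.get(sp, card), card
                )

    truth = SimTruth(
        alignments=alignments,
        partition=partition,
        regions=regions,
        expected_pure={sp: sorted(v) for sp, v in expected_pure.items()},
        expected_composite_cardinality=composite_truth,
        pair_counts=pair_counts,
        species_members=specimen_ids,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, aln in alignments.items():
            write_fasta(aln, out / f"{name}.fasta")
        write_partition(partition, out / "partition.tsv")
        for name, rmap in regions.items():
            write_regions(rmap, out / f"regions_{name}.tsv")
        (out / "spec.json").write_text(spec.to_json())
        (out / "truth.json").write_text(truth.to_json())
    return truth


def _min_composite_cardinality(
    haps: dict[str, str], species: list[str], sp: str, solid: list[int]
) -> int | None:
    """Brute-force minimal composite cardinality on species haplotypes.

    Generator-side oracle, independent of the diagnostics module: works on
    the per-species haplotypes (fixation is automatic) and enumerates
    candidate-column subsets by increasing size.
    """
    others = [o for o in species if o != sp]
    pure = {
        p
        for p in solid
        if all(haps[o][p - 1] != haps[sp][p - 1] for o in others)
    }
    candidates = [
        p
        for p in solid
        if p not in pure
        and any(haps[o][p - 1] != haps[sp][p - 1] for o in others)
    ]
    for k in range(2, len(candidates) + 1):
        for combo in combinations(candidates, k):
            if not any(
                all(haps[o][p - 1] == haps[sp][p - 1] for p in combo)
                for o in others
            ):
                return k
    return None


def aplysina_like_spec(seed: int = 20120813) -> SimSpec:
    """A packaged spec mirroring the shape of the Eastern Pacific data.

    Three species with 6/4/5 specimens; an ITS-like 705 bp locus whose
    interspecific substitution counts are {2, 5, 5} over the 695 columns
    that remain comparable after a 10 bp intraspecific insertion in one
    species (so pairwise p-distances are exactly 2/695 = 0.288% and
    5/695 = 0.719%), with four pure diagnostics planted for one species and
    one each for the other two; and a COI-like 523 bp locus that is
    invariant except for a single substitution diagnostic for one species.
    """
    its = LocusSpec(
        name="ITS",
        length=705,
        pair_substitutions={
            ("A_clathrata", "A_revillagigedi"): 2,
            ("A_clathrata", "A_gerardogreeni"): 5,
            ("A_gerardogreeni", "A_revillagigedi"): 5,
        },
        planted_pure={
            "A_gerardogreeni": [(134, None), (298, None), (456, None), (642, None)],
            "A_revillagigedi": [(512, None)],
            "A_clathrata": [(87, None)],
        },
        indel_events=[("A_clathrata", 10)],
        regions=[("ITS1", 1, 230), ("5.8S", 231, 390), ("ITS2", 391, 705)],
    )
    coi = LocusSpec(
        name="COI",
        length=523,
        pair_substitutions={
            ("A_gerardogreeni", "A_revillagigedi"): 1,
            ("A_clathrata", "A_revillagigedi"): 1,
            ("A_clathrata", "A_gerardogreeni"): 0,
        },
        planted_pure={"A_revillagigedi": [(217, None)]},
        regions=[("COI", 1, 523)],
    )
    return SimSpec(
        seed=seed,
        species=[
            ("A_gerardogreeni", 6),
            ("A_revillagigedi", 4),
            ("A_clathrata", 5),
        ],
        loci=[its, coi],
    )
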