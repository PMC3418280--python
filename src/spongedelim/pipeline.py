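"""End-to-end delimitation workflow.

Wires the stages together — alignment statistics, divergence matrices,
character-based diagnosis, NJ tree with bootstrap, monophyly tests — and
emits a combined per-species-pair evidence report plus a hashed manifest so
a rerun with the same config and seed reproduces the bundle bit-for-bit.

The integrative report is structure only: each species-pair hypothesis is
listed with its independent lines of evidence (distance divergence, pure
diagnostics, composite diagnostics, monophyly) flagged supported / not
supported.  No numeric score combines them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

from . import diagnostics, distmat, phylo, popstats, seqio

log = logging.getLogger("spongedelim")


@dataclass
class RunConfig:
    """Fully serializable configuration for one pipeline run."""

    alignments: dict[str, str]  # locus name -> FASTA path
    partition: str
    out_dir: str
    regions: dict[str, str] = field(default_factory=dict)  # locus -> TSV path
    model: str = "p"
    deletion: str = "pairwise"
    gap_policy: str = "exclude-column"
    max_composite_size: int = 6
    bootstrap_reps: int = 0
    seed: int = 0
    tree_locus: str | None = None  # default: first locus

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns a summary dict (per-pair evidence flags and stage counts).
    On stage failure partial outputs are retained and the error is re-raised
    with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    written: list[Path] = [out / "config.json"]

    stage = "load"
    try:
        alns = {
            locus: seqio.read_fasta(path, locus)
            for locus, path in config.alignments.items()
        }
        part = seqio.read_partition(config.partition)
        for aln in alns.values():
            part.check_covers(aln)
        regions = {
            locus: seqio.read_regions(path)
            for locus, path in config.regions.items()
        }

        stage = "stats"
        stats_rows = []
        for locus, aln in alns.items():
            row = popstats.locus_summary(aln, config.gap_policy)
            stats_rows.append(row)
            log.info(
                "stats %s: n=%d length=%d variable=%d PI=%d haplotypes=%d",
                locus, row["n_sequences"], row["length"],
                row["variable_sites"], row["parsimony_informative"],
                row["haplotypes"],
            )
        stats_path = out / "stats.tsv"
        keys = list(stats_rows[0])
        with open(stats_path, "w") as fh:
            fh.write("\t".join(keys) + "\n")
            for row in stats_rows:
                fh.write("\t".join(_fmt(row[k]) for k in keys) + "\n")
        written.append(stats_path)

        stage = "distances"
        dms = {}
        for locus, aln in alns.items():
            dm = distmat.distance_matrix(aln, config.model, config.deletion)
            dms[locus] = dm
            p = out / f"distances_{locus}.tsv"
            p.write_text(distmat.format_distance_table(dm))
            written.append(p)
            p = out / f"distances_{locus}.phylip"
            p.write_text(distmat.format_phylip(dm))
            written.append(p)

        stage = "diagnose"
        if len(part.species_order) >= 2:
            per_locus = {
                locus: diagnostics.diagnose_locus(
                    aln, part, config.max_composite_size, config.gap_policy
                )
                for locus, aln in alns.items()
            }
        else:  # single-species input: nothing to diagnose against
            per_locus = {locus: ([], []) for locus in alns}
        report = diagnostics.diagnosis_report(per_locus, part, regions)
        p = out / "diagnostics.tsv"
        p.write_text(diagnostics.report_tsv(report))
        written.append(p)
        p = out / "diagnostics.txt"
        p.write_text(diagnostics.report_text(report))
        written.append(p)
        for sp, diag in report.by_species.items():
            log.info(
                "diagnose %s: %d pure, %d composite, verdict %s",
                sp, len(diag.pure), len(diag.composite), diag.verdict,
            )

        stage = "tree"
        tree_locus = config.tree_locus or next(iter(alns))
        tree_aln = alns[tree_locus]
        tree = None
        monophyly: dict[str, bool] = {}
        if tree_aln.n >= 3 and len(part.species_order) >= 2:
            if config.bootstrap_reps > 0 and tree_aln.n >= 4:
                bs = phylo.bootstrap_support(
                    tree_aln, config.bootstrap_reps, config.seed,
                    config.model, config.deletion,
                )
                tree = bs.tree
            else:
                tree = phylo.nj(dms[tree_locus])
            p = out / f"nj_{tree_locus}.nwk"
            p.write_text(phylo.write_newick(tree))
            written.append(p)
            for sp in part.species_order:
                members = [
                    sid for sid in part.members(sp) if sid in set(tree_aln.ids)
                ]
                monophyly[sp] = (
                    phylo.is_monophyletic(tree, members) if members else False
                )

        stage = "report"
        summary = _evidence_summary(
            part, dms, report, monophyly, tree_locus, config
        )
        p = out / "report.md"
        p.write_text(_render_report(summary))
        written.append(p)

        manifest = {
            str(p.relative_to(out)): _sha256(p) for p in sorted(written)
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
        return summary
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def _evidence_summary(part, dms, report, monophyly, tree_locus, config) -> dict:
    species = part.species_order
    pairs = {}
    for a, b in combinations(species, 2):
        lines = {}
        # distance: every interspecific distance exceeds every intraspecific one
        supported = False
        for locus, dm in dms.items():
            inter, intra = [], []
            in_a = set(part.members(a)) & set(dm.labels)
            in_b = set(part.members(b)) & set(dm.labels)
            for x in in_a:
                for y in in_b:
                    inter.append(dm.get(x, y))
            for grp in (in_a, in_b):
                for x, y in combinations(sorted(grp), 2):
                    intra.append(dm.get(x, y))
            if inter and min(inter) > (max(intra) if intra else 0.0):
                supported = True
        lines["distance_divergence"] = supported
        pure_a = len(report.by_species[a].pure)
        pure_b = len(report.by_species[b].pure)
        lines["pure_diagnostics"] = pure_a > 0 or pure_b > 0
        lines["composite_diagnostics"] = (
            len(report.by_species[a].composite) > 0
            or len(report.by_species[b].composite) > 0
        )
        lines["monophyly"] = bool(
            monophyly.get(a, False) and monophyly.get(b, False)
        )
        pairs[f"{a} vs {b}"] = {
            "evidence": lines,
            "n_supported": sum(lines.values()),
        }
    return {
        "species": list(species),
        "n_species": len(species),
        "tree_locus": tree_locus,
        "pairs": pairs,
        "monophyly": monophyly,
        "verdicts": {sp: report.verdict(sp) for sp in species},
    }


def _render_report(summary: dict) -> str:
    lines = ["# Species delimitation report", ""]
    if summary["n_species"] < 2:
        lines.append("No interspecific comparison possible: single species input.")
        return "\n".join(lines) + "\n"
    lines.append(f"Species analysed: {', '.join(summary['species'])}")
    lines.append("")
    for pair, info in summary["pairs"].items():
        lines.append(f"## {pair}")
        for name, ok in info["evidence"].items():
            flag = "supported" if ok else "not supported"
            lines.append(f"- {name.replace('_', ' ')}: {flag}")
        lines.append(
            f"- independent lines of evidence supporting distinction: "
            f"{info['n_supported']}"
        )
        lines.append("")
    lines.append("## Per-species diagnosability")
    for sp, verdict in summary["verdicts"].items():
        lines.append(f"- {sp}: {verdict}")
    return "\n".join(lines) + "\n"
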