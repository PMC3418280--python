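#!/usr/bin/env python
"""Per-locus diversity and site statistics of the synthetic study data.

Expected findings: the COI locus carries exactly one segregating site; the
ITS locus shows indel-only intraspecific variation in one species (two
indel-aware haplotypes, nucleotide diversity 0).
"""

from pathlib import Path

from spongedelim.popstats import (
    collapse_haplotypes,
    haplotype_diversity,
    locus_summary,
    nucleotide_diversity,
)
from spongedelim.seqio import read_fasta, read_partition

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    part = read_partition(ROOT / "sim" / "partition.tsv")
    rows = []
    for locus in ("ITS", "COI"):
        aln = read_fasta(ROOT / "sim" / f"{locus}.fasta", locus)
        rows.append(locus_summary(aln))
        print(f"{locus}: {rows[-1]['variable_sites']} variable, "
              f"{rows[-1]['parsimony_informative']} parsimony-informative")
        for sp in part.species_order:
            sub = aln.subset(part.members(sp))
            if sub.n < 2:
                continue
            haps = collapse_haplotypes(sub, "indel-aware")
            h = haplotype_diversity(haps.counts)
            pi = nucleotide_diversity(sub, indels="exclude")
            print(f"  {sp}: {haps.n_haplotypes} haplotype(s), "
                  f"h = {h:.2f}, pi = {pi:.4f}")
    out = ROOT / "stats.tsv"
    keys = list(rows[0])
    with open(out, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[k]) for k in keys) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
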