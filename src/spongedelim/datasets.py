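"""Bundled reference data.

A published pairwise ITS1-5.8S-ITS2 divergence matrix (% uncorrected
p-distance) among Eastern Pacific and Caribbean *Aplysina* species, used to
check that distance-tree reconstruction recovers the Eastern Pacific clade
{A. gerardogreeni, A. revillagigedi, A. clathrata, A. fistularis (CAL)}.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .distmat import DistanceMatrix

EASTERN_PACIFIC_CLADE = frozenset(
    {
        "A. gerardogreeni",
        "A. revillagigedi",
        "A. clathrata",
        "A. fistularis (CAL)",
    }
)


def load_aplysina_its_divergence(scale: str = "proportion") -> DistanceMatrix:
    """The reference *Aplysina* ITS divergence matrix (10 taxa).

    ``scale="percent"`` returns the values as printed (percent); the default
    converts to proportions for tree building.
    """
    path = resources.files("spongedelim").joinpath(
        "data", "aplysina_its_divergence_percent.tsv"
    )
    lines = path.read_text().strip().splitlines()
    labels = lines[0].split("\t")[1:]
    rows = []
    for line in lines[1:]:
        parts = line.split("\t")
        rows.append([float(v) for v in parts[1:]])
    values = np.array(rows)
    if scale == "proportion":
        values = values / 100.0
    return DistanceMatrix(labels, values, model="p", deletion="unknown")
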