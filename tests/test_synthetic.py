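import json

import numpy as np
import pytest

from spongedelim.diagnostics import (
    diagnosis_report,
    find_composite_diagnostics,
    find_pure_diagnostics,
)
from spongedelim.distmat import distance_matrix, p_distance
from spongedelim.phylo import is_monophyletic, nj
from spongedelim.popstats import classify_sites, collapse_haplotypes, nucleotide_diversity
from spongedelim.synthetic import (
    LocusSpec,
    SimSpec,
    SimulationError,
    aplysina_like_spec,
    simulate,
)


def small_spec(seed=1, **locus_kwargs):
    defaults = dict(
        name="loc",
        length=60,
        pair_substitutions={
            ("sp0", "sp1"): 2,
            ("sp0", "sp2"): 3,
            ("sp1", "sp2"): 3,
        },
    )
    defaults.update(locus_kwargs)
    return SimSpec(
        seed=seed,
        species=[("sp0", 2), ("sp1", 2), ("sp2", 2)],
        loci=[LocusSpec(**defaults)],
    )


class TestDeterminism:
    def test_same_spec_and_seed_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        spec = aplysina_like_spec(seed=5)
        simulate(spec, d1)
        simulate(spec, d2)
        for name in ("ITS.fasta", "COI.fasta", "partition.tsv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        t1 = simulate(aplysina_like_spec(seed=1))
        t2 = simulate(aplysina_like_spec(seed=2))
        assert t1.alignments["ITS"].seqs != t2.alignments["ITS"].seqs

    def test_spec_json_round_trip(self):
        spec = aplysina_like_spec()
        again = SimSpec.from_json(spec.to_json())
        assert again.to_json() == spec.to_json()


class TestInfeasibleSpecs:
    def test_planted_position_out_of_range(self, tmp_path):
        spec = small_spec(planted_pure={"sp0": [(99, None)]})
        with pytest.raises(SimulationError, match="outside"):
            simulate(spec, tmp_path / "x")
        assert not (tmp_path / "x").exists()  # no file written on error

    def test_non_decomposable_pair_counts(self):
        spec = small_spec(
            pair_substitutions={
                ("sp0", "sp1"): 1,
                ("sp0", "sp2"): 0,
                ("sp1", "sp2"): 0,
            }
        )
        with pytest.raises(SimulationError, match="decomposable"):
            simulate(spec)

    def test_composite_requires_three_species(self):
        spec = SimSpec(
            seed=1,
            species=[("a", 2), ("b", 2)],
            loci=[
                LocusSpec(
                    name="l",
                    length=40,
                    planted_composites={"a": [[(5, None), (10, None)]]},
                )
            ],
        )
        with pytest.raises(SimulationError, match="3 species"):
            simulate(spec)

    def test_budget_smaller_than_planted(self):
        spec = small_spec(
            planted_pure={"sp0": [(5, None), (10, None), (15, None)]}
        )
        # sp0 private budget is (2+3-3)/2 = 1 < 3 planted
        with pytest.raises(SimulationError, match="budget"):
            simulate(spec)


class TestMimicSpec:
    def test_coi_single_segregating_site(self, mimic_truth):
        assert classify_sites(mimic_truth.alignments["COI"]).variable == 1

    def test_its_pairwise_counts(self, mimic_truth):
        pc = mimic_truth.pair_counts
        assert pc[("ITS", "A_clathrata", "A_revillagigedi")] == 2
        assert pc[("ITS", "A_clathrata", "A_gerardogreeni")] == 5
        assert pc[("ITS", "A_gerardogreeni", "A_revillagigedi")] == 5

    def test_indel_only_intraspecific_variation(self, mimic_truth):
        its = mimic_truth.alignments["ITS"]
        cl = its.subset(mimic_truth.species_members["A_clathrata"])
        assert collapse_haplotypes(cl, "indel-aware").n_haplotypes == 2
        assert collapse_haplotypes(cl, "substitutions-only").n_haplotypes == 1
        assert nucleotide_diversity(cl, indels="exclude") == 0.0

    def test_coi_diagnostic_species_verdict_pure(self, mimic_truth):
        coi = mimic_truth.alignments["COI"]
        part = mimic_truth.partition
        report = diagnosis_report(
            {
                "COI": (
                    find_pure_diagnostics(coi, part),
                    find_composite_diagnostics(coi, part),
                )
            },
            part,
        )
        assert report.verdict("A_revillagigedi") == "pure"

    def test_truth_json_schema(self, tmp_path, mimic_truth):
        out = tmp_path / "sim"
        simulate(aplysina_like_spec(), out)
        truth = json.loads((out / "truth.json").read_text())
        assert set(truth) == {
            "expected_pure",
            "expected_composite_cardinality",
            "pair_counts",
            "species_members",
        }
        assert len(truth["expected_pure"]["A_gerardogreeni"]) == 4


class TestPlantedRecovery:
    """Full-pipeline parameter recovery on 20 random simulation specs."""

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_recovery(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n_species = int(rng.integers(3, 6))
        labels = [f"sp{k}" for k in range(n_species)]
        sizes = [int(rng.integers(1, 4)) for _ in labels]
        # private substitution counts >= 1 so every species separates
        x = {sp: int(rng.integers(1, 4)) for sp in labels}
        composite_sp = None
        if seed % 2 == 0:
            composite_sp = labels[int(rng.integers(0, n_species))]
            x[composite_sp] = 0
        pairs = {
            (a, b): x[a] + x[b]
            for i, a in enumerate(labels)
            for b in labels[i + 1:]
        }
        planted_comp = {}
        if composite_sp:
            planted_comp[composite_sp] = [[(5, None), (12, None)]]
        spec = SimSpec(
            seed=seed,
            species=list(zip(labels, sizes)),
            loci=[
                LocusSpec(
                    name="loc",
                    length=90,
                    pair_substitutions=pairs,
                    planted_composites=planted_comp,
                )
            ],
        )
        truth = simulate(spec)
        a = truth.alignments["loc"]
        part = truth.partition

        found_pure = {
            (d.species, d.position, d.state)
            for d in find_pure_diagnostics(a, part)
        }
        expected = {
            (sp, pos, st)
            for sp, lst in truth.expected_pure.items()
            for _, pos, st in lst
        }
        assert found_pure == expected  # all planted found, zero spurious

        if composite_sp:
            assert not truth.expected_pure[composite_sp]
            comps = [
                c
                for c in find_composite_diagnostics(a, part, max_size=4)
                if c.species == composite_sp
            ]
            assert comps
            card = truth.expected_composite_cardinality[composite_sp]
            assert {c.size for c in comps} == {card}

        # NJ on the specimen p-distance matrix recovers every species with
        # more than one specimen (interspecific counts all >= 1, intra = 0)
        if a.n >= 3:
            tree = nj(distance_matrix(a))
            for sp in labels:
                assert is_monophyletic(tree, truth.species_members[sp])

    def test_realized_pair_counts_match_pdistance(self):
        truth = simulate(small_spec(seed=3))
        a = truth.alignments["loc"]
        for (locus, s1, s2), k in truth.pair_counts.items():
            x = truth.species_members[s1][0]
            y = truth.species_members[s2][0]
            p, c = p_distance(a.row(x), a.row(y))
            assert p == pytest.approx(k / c)
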