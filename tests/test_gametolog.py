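"""Reciprocal-best-hit pairing, band classification, family clustering, and
region segmentation."""

import itertools

import numpy as np
import pytest

from parscope.gametolog import (
    GeneModel,
    IdentityBand,
    cluster_gene_family,
    family_copy_numbers,
    pair_gametologs,
    segment_regions,
)
from parscope.seqio import GenomicInterval
from parscope.simulate import mutate_sequence

from conftest import random_seq


def gene(gid, seq, start=0, chrom="X"):
    return GeneModel(gid, GenomicInterval(chrom, start, start + len(seq)), seq)


def diverged(rng, seq, divergence, seed):
    out, _ = mutate_sequence(seq, divergence, 0.0, seed)
    return out


class TestPairing:
    def test_single_pair_in_band_is_gametolog(self, rng):
        a = random_seq(rng, 1_000)
        pairs = pair_gametologs(
            [gene("xa", a)], [gene("ya", diverged(rng, a, 0.15, 1), chrom="Y")]
        )
        assert len(pairs) == 1
        assert pairs[0].classification == "gametolog"
        assert 0.80 <= pairs[0].identity <= 0.90

    def test_high_identity_pair_is_par_grade_not_gametolog(self, rng):
        # identity ~0.99 sits above the 60-96% gametolog band
        a = random_seq(rng, 1_000)
        pairs = pair_gametologs(
            [gene("xa", a)], [gene("ya", diverged(rng, a, 0.01, 2), chrom="Y")]
        )
        assert pairs[0].classification == "PAR-grade"

    def test_unrelated_best_hit_is_below_band(self, rng):
        pairs = pair_gametologs(
            [gene("xa", random_seq(rng, 1_000))],
            [gene("ya", random_seq(rng, 1_000), chrom="Y")],
        )
        assert pairs[0].classification == "below-band"
        assert pairs[0].identity < 0.60

    def test_rbh_symmetry(self, rng):
        xs, ys = [], []
        for i in range(4):
            a = random_seq(rng, 800)
            xs.append(gene(f"x{i}", a))
            ys.append(gene(f"y{i}", diverged(rng, a, 0.1 + 0.05 * i, i), chrom="Y"))
        fwd = pair_gametologs(xs, ys)
        rev = pair_gametologs(ys, xs)
        assert {(p.x_gene, p.y_gene, round(p.identity, 12)) for p in fwd} == {
            (p.y_gene, p.x_gene, round(p.identity, 12)) for p in rev
        }

    def test_duplicate_ids_rejected(self, rng):
        g = gene("same", random_seq(rng, 100))
        with pytest.raises(ValueError, match="duplicate"):
            pair_gametologs([g], [g])

    def test_clean_simulation_recovered_exactly(self, small_sim):
        pairs = pair_gametologs(small_sim.x_genes, small_sim.y_genes)
        pred = {(p.x_gene, p.y_gene) for p in pairs if p.classification == "gametolog"}
        true = {(x, y) for x, y, _ in small_sim.truth.gametolog_pairs}
        assert pred == true  # precision = recall = 1.0
        par_pred = {(p.x_gene, p.y_gene) for p in pairs if p.classification == "PAR-grade"}
        assert par_pred == {(x, y) for x, y, _ in small_sim.truth.par_pairs}


class TestFamilyClustering:
    def _family(self, rng, n, seed0=0):
        base = random_seq(rng, 1_000)
        return [
            gene(f"fam{i}", diverged(rng, base, 0.08, seed0 + i), start=2000 * i, chrom="Y")
            for i in range(n)
        ]

    def test_four_copy_family_recovered(self, rng):
        genes = self._family(rng, 4)
        fams = cluster_gene_family(genes, 0.70)
        assert len(set(fams.values())) == 1
        assert family_copy_numbers(fams) == {"fam0": 4}

    def test_family_plus_singleton(self, rng):
        genes = self._family(rng, 3) + [gene("lone", random_seq(rng, 1_000), chrom="Y")]
        fams = cluster_gene_family(genes, 0.70)
        counts = family_copy_numbers(fams)
        assert sorted(counts.values()) == [1, 3]
        assert fams["lone"] == "lone"

    def test_single_gene_is_its_own_family(self, rng):
        g = gene("solo", random_seq(rng, 500))
        assert cluster_gene_family([g]) == {"solo": "solo"}

    def test_matches_exhaustive_union_find_oracle(self, rng):
        from parscope.gametolog import _identity_matrix

        for trial in range(5):
            genes = []
            base = random_seq(rng, 400)
            for i in range(6):
                if i % 2 == 0:
                    genes.append(gene(f"g{i}", diverged(rng, base, 0.1, i), chrom="Y"))
                else:
                    genes.append(gene(f"g{i}", random_seq(rng, 400), chrom="Y"))
            genes_sorted = sorted(genes, key=lambda g: g.id)
            ident, _ = _identity_matrix(genes_sorted, genes_sorted)
            # brute-force transitive closure at the threshold
            n = len(genes_sorted)
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    i = parent[i]
                return i

            for i, j in itertools.combinations(range(n), 2):
                sym = (ident[i, j] + ident[j, i]) / 2
                if sym >= 0.70:
                    parent[find(i)] = find(j)
            oracle = {}
            for i in range(n):
                oracle.setdefault(find(i), set()).add(genes_sorted[i].id)
            got = {}
            for gid, fam in cluster_gene_family(genes, 0.70).items():
                got.setdefault(fam, set()).add(gid)
            assert set(map(frozenset, oracle.values())) == set(
                map(frozenset, got.values())
            )

    def test_order_invariance_and_count_conservation(self, rng):
        genes = self._family(rng, 4) + [gene("lone", random_seq(rng, 1_000), chrom="Y")]
        fwd = cluster_gene_family(genes, 0.70)
        rev = cluster_gene_family(genes[::-1], 0.70)
        assert fwd == rev
        assert sum(family_copy_numbers(fwd).values()) == len(genes)

    def test_simulated_families_recover_printed_copy_numbers(self, small_sim):
        fam_genes = [
            g for g in small_sim.y_genes if g.id in small_sim.truth.family_assignments
        ]
        counts = family_copy_numbers(cluster_gene_family(fam_genes, 0.70))
        assert sorted(counts.values()) == sorted(
            small_sim.truth.family_copy_numbers.values()
        )


class TestSegmentation:
    def _gene_at(self, gid, pos, chrom="Y"):
        return GeneModel(gid, GenomicInterval(chrom, pos, pos + 1_000), "")

    def test_xdeg_amp_xdeg_structure(self):
        par = GenomicInterval("Y", 0, 10_000)
        genes, labels = [], {}
        pos = 12_000
        for i in range(3):
            g = self._gene_at(f"g{i}", pos); pos += 2_000
            genes.append(g); labels[g.id] = "gametolog"
        for i in range(4):
            g = self._gene_at(f"m{i}", pos); pos += 2_000
            genes.append(g); labels[g.id] = "multi-copy"
        for i in range(2):
            g = self._gene_at(f"h{i}", pos); pos += 2_000
            genes.append(g); labels[g.id] = "gametolog"
        regions = segment_regions(genes, labels, par)
        assert [r.name for r in regions] == ["PAR", "X-d1", "ampliconic", "X-d2a"]
        assert [r.klass for r in regions] == [
            "PAR", "X-degenerate", "ampliconic", "X-degenerate",
        ]
        # region intervals span gene extents
        assert regions[1].interval.start == 12_000
        assert regions[1].interval.end == 12_000 + 2 * 2_000 + 1_000

    def test_empty_gene_list_gives_only_par(self):
        par = GenomicInterval("Y", 0, 5_000)
        assert [r.name for r in segment_regions([], {}, par)] == ["PAR"]

    def test_all_multicopy_single_ampliconic_region(self):
        par = GenomicInterval("Y", 0, 5_000)
        genes = [self._gene_at(f"m{i}", 6_000 + 1_500 * i) for i in range(5)]
        labels = {g.id: "multi-copy" for g in genes}
        regions = segment_regions(genes, labels, par)
        assert [r.name for r in regions] == ["PAR", "ampliconic"]

    def test_distant_same_label_runs_split_by_max_join(self):
        par = GenomicInterval("Y", 0, 5_000)
        genes = [self._gene_at("a", 6_000), self._gene_at("b", 400_000)]
        labels = {"a": "gametolog", "b": "gametolog"}
        regions = segment_regions(genes, labels, par, max_join=200_000)
        assert [r.name for r in regions] == ["PAR", "X-d1", "X-d2a"]

    def test_gametolog_inside_par_warns_and_reassigns(self):
        par = GenomicInterval("Y", 0, 5_000)
        genes = [self._gene_at("inpar", 1_000)]
        with pytest.warns(UserWarning, match="reassigned"):
            regions = segment_regions(genes, {"inpar": "gametolog"}, par)
        assert [r.name for r in regions] == ["PAR"]


def test_band_validation():
    with pytest.raises(ValueError):
        IdentityBand(lower=0.9, upper=0.8)
    band = IdentityBand()
    assert band.classify(0.96) == "gametolog"  # endpoints inclusive
    assert band.classify(0.60) == "gametolog"
    assert band.classify(0.9601) == "PAR-grade"
    assert band.classify(0.5999) == "below-band"
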