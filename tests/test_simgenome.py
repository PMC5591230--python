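"""Unit tests for the synthetic genome, truth set and diploid template."""

import numpy as np
import pytest
from scipy import stats

from asmbench import simgenome
from asmbench.errors import CapacityError, ConsistencyError, InputError


class TestGenerateReference:
    def test_length_and_alphabet(self):
        g = simgenome.generate_reference(1000, gc=0.5, seed=1)
        assert g.length == len(g.sequence) == 1000
        assert set(g.sequence) <= set("ACGT")

    def test_degenerate_gc(self):
        g = simgenome.generate_reference(1000, gc=1.0, seed=1)
        assert set(g.sequence) <= set("GC")
        g0 = simgenome.generate_reference(1000, gc=0.0, seed=1)
        assert set(g0.sequence) <= set("AT")

    def test_seed_determinism(self):
        a = simgenome.generate_reference(2000, gc=0.4, seed=9)
        b = simgenome.generate_reference(2000, gc=0.4, seed=9)
        assert a.sequence == b.sequence

    def test_rejects_tiny_genome(self):
        with pytest.raises(InputError):
            simgenome.generate_reference(10)


class TestGeneModel:
    def test_empty_model_is_all_intergenic(self, toy_genome):
        model = simgenome.generate_gene_model(toy_genome, n_genes=0)
        region = model.region_array(toy_genome.length)
        assert (region == simgenome.REGION_INTERGENIC).all()

    def test_exons_within_span_and_cds_in_exons(self, toy_gene_model):
        for g in toy_gene_model.genes:
            assert g.start < g.end
            for es, ee in g.exons:
                assert g.start <= es < ee <= g.end
            cs, ce = g.cds
            assert cs < ce
            # CDS endpoints fall inside exon bases
            exonic = set()
            for es, ee in g.exons:
                exonic.update(range(es, ee))
            assert cs in exonic and ce - 1 in exonic

    def test_genes_do_not_overlap(self, toy_gene_model):
        spans = sorted(g.span for g in toy_gene_model.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_region_partition_matches_position_scan(self, toy_genome, toy_gene_model):
        """Vectorised classification agrees with the per-position rule."""
        region = toy_gene_model.region_array(toy_genome.length)
        names = [simgenome.REGION_NAMES[int(c)] for c in region]
        # brute-force scan of every position via the scalar classifier
        for pos in range(0, toy_genome.length, 97):
            assert toy_gene_model.classify(pos) == names[pos]
        counts = {n: names.count(n) for n in set(names)}
        assert sum(counts.values()) == toy_genome.length

    def test_capacity_error(self, toy_genome):
        with pytest.raises(CapacityError):
            simgenome.generate_gene_model(toy_genome, n_genes=100)


class TestTruthVariants:
    def test_counts_and_types(self, toy_genome):
        vs = simgenome.sample_truth_variants(
            toy_genome, None, n_snv=20, n_indel=0, seed=5
        )
        assert len(vs) == 20
        assert all(v.vtype == "SNV" for v in vs)
        assert all(len(v.ref) == 1 and len(v.alt) == 1 and v.ref != v.alt for v in vs)

    def test_all_het_when_fraction_one(self, toy_genome):
        vs = simgenome.sample_truth_variants(
            toy_genome, None, n_snv=30, het_fraction=1.0, seed=5
        )
        assert all(v.genotype == "HET" for v in vs)

    def test_spacing_and_sorted(self, toy_truth):
        pos = [v.pos for v in toy_truth]
        assert pos == sorted(pos)
        assert min(np.diff(pos)) >= 150

    def test_ref_matches_reference(self, toy_genome, toy_truth):
        for v in toy_truth:
            assert toy_genome.sequence[v.pos - 1 : v.pos - 1 + len(v.ref)] == v.ref

    def test_het_share_within_binomial_bound(self):
        """At n=2000 the observed HET share stays inside the central
        99.9% binomial interval around the requested fraction."""
        g = simgenome.generate_reference(400_000, seed=21)
        vs = simgenome.sample_truth_variants(
            g, None, n_snv=2000, het_fraction=0.6, min_spacing=150, seed=7
        )
        n_het = sum(v.genotype == "HET" for v in vs)
        lo = stats.binom.ppf(0.0005, 2000, 0.6)
        hi = stats.binom.ppf(0.9995, 2000, 0.6)
        assert lo <= n_het <= hi

    def test_capacity_error_when_too_dense(self, toy_genome):
        with pytest.raises(CapacityError):
            simgenome.sample_truth_variants(
                toy_genome, None, n_snv=500, min_spacing=150, seed=1
            )


class TestDiploidTemplate:
    def test_zero_variants_identity(self, toy_genome):
        t = simgenome.build_diploid_template(toy_genome, [])
        assert t.hap1 == t.hap2 == toy_genome.sequence

    def test_hom_snv_on_both_haplotypes(self, toy_genome):
        p = 5000
        ref = toy_genome.sequence[p - 1]
        alt = "A" if ref != "A" else "C"
        v = simgenome.TruthVariant(toy_genome.name, p, ref, alt, "SNV", "HOM")
        t = simgenome.build_diploid_template(toy_genome, [v])
        for hap in t.haplotypes:
            assert hap[p - 1] == alt
            assert hap[: p - 1] == toy_genome.sequence[: p - 1]

    def test_het_deletion_coordinate_maps_round_trip(self):
        g = simgenome.generate_reference(1000, seed=3)
        g = simgenome.ReferenceGenome(g.name, g.sequence[:500])
        p = 200
        ref = g.sequence[p - 1 : p + 3]  # anchor + 3 deleted bases
        v = simgenome.TruthVariant(g.name, p, ref, ref[0], "DEL", "HET")
        t = simgenome.build_diploid_template(g, [v], seed=6)
        lens = sorted(len(h) for h in t.haplotypes)
        assert lens == [497, 500]
        for h in range(2):
            hap2ref, ref2hap = t.hap2ref[h], t.ref2hap[h]
            for i, rp in enumerate(hap2ref.tolist()):
                if rp >= 0:
                    assert ref2hap[rp] == i  # hap -> ref -> hap identity
            mapped = hap2ref[hap2ref >= 0]
            assert (np.diff(mapped) > 0).all()  # strictly increasing

    def test_het_carriers_recorded(self, toy_truth, toy_template):
        for v in toy_truth:
            c = toy_template.carriers[v.pos]
            assert sum(c) == (2 if v.genotype == "HOM" else 1)

    def test_ref_mismatch_raises(self, toy_genome):
        p = 100
        ref = toy_genome.sequence[p - 1]
        wrong = "A" if ref != "A" else "C"
        v = simgenome.TruthVariant(toy_genome.name, p, wrong, "G", "SNV", "HOM")
        with pytest.raises(ConsistencyError):
            simgenome.build_diploid_template(toy_genome, [v])

    def test_variant_alleles_land_on_carrier_haplotypes(
        self, toy_genome, toy_truth, toy_template
    ):
        """At every truth SNV the carrier haplotype shows the alternate
        base and the non-carrier the reference base (via the maps)."""
        for v in toy_truth:
            if v.vtype != "SNV":
                continue
            carriers = toy_template.carriers[v.pos]
            for h in range(2):
                hp = toy_template.ref2hap[h][v.pos - 1]
                base = toy_template.haplotypes[h][hp]
                assert base == (v.alt if carriers[h] else v.ref)


class TestConfidenceRegions:
    def test_full_fraction_single_interval(self, toy_genome):
        r = simgenome.make_confidence_bed(toy_genome, high_fraction=1.0)
        assert r.high == [(0, toy_genome.length)]

    def test_disjoint_sorted_within_bounds(self, toy_genome):
        r = simgenome.make_confidence_bed(toy_genome, 0.7, n_blocks=8, seed=3)
        prev_end = 0
        for s, e in r.high:
            assert prev_end <= s < e <= toy_genome.length
            prev_end = e

    def test_covered_fraction(self, toy_genome):
        r = simgenome.make_confidence_bed(toy_genome, 0.8, n_blocks=8, seed=3)
        covered = sum(e - s for s, e in r.high)
        assert 7000 <= covered <= 9000  # 0.8 of 10 kb, block granularity slack


class TestRoundTrips:
    def test_truth_vcf_round_trip(self, toy_truth, tmp_path):
        path = tmp_path / "truth.vcf"
        simgenome.write_truth_vcf(toy_truth, path)
        back = simgenome.read_truth_vcf(path)
        assert back == sorted(toy_truth, key=lambda v: v.pos)

    def test_fasta_round_trip(self, toy_genome, tmp_path):
        path = tmp_path / "ref.fa"
        simgenome.write_fasta(toy_genome, path)
        seqs = simgenome.read_fasta(path)
        assert seqs == {toy_genome.name: toy_genome.sequence}

    def test_gene_bed12_round_trip(self, toy_gene_model, toy_genome, tmp_path):
        path = tmp_path / "genes.bed"
        simgenome.write_gene_bed12(toy_gene_model, toy_genome.name, path)
        back = simgenome.read_gene_bed12(path)
        assert back == toy_gene_model
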