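"""Shared-seed discovery, guide design, sgRNA notation, cut sites."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tdprogram.errors import DataError
from tdprogram import seedguide, synthetic
from tdprogram.seedguide import SeedCluster, SeedMatch, SeedParameters, revcomp


def _as_pairs(clusters):
    return {(c.seed_seq, c.carriers) for c in clusters}


def _random_genes(rng, n_genes, length):
    return {
        f"g{i}": "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_genes)
    }


class TestFindSharedSeeds:
    def test_empty_gene_set_rejected(self):
        with pytest.raises(DataError):
            seedguide.find_shared_seeds({})

    def test_no_common_seed_yields_empty_list(self, rng):
        genes = {"a": "".join(rng.choice(list("ACGT"), 60)),
                 "b": "".join(rng.choice(list("ACGT"), 60))}
        assert seedguide.find_shared_seeds(genes) == []

    def test_planted_seed_recovered_with_all_carriers(self):
        planted = synthetic.gen_genes_with_seed(3, 200, 15, 3, rng_seed=1)
        clusters = seedguide.find_shared_seeds(planted.genes)
        top = clusters[0]
        assert top.carriers == planted.carriers
        assert top.seed_seq.endswith(planted.truth_seed) or planted.truth_seed in top.seed_seq
        for match in top.matches:
            start, end = planted.planted[match.gene_id]
            assert match.start <= start and match.end >= end

    def test_pam_required_at_every_counted_occurrence(self):
        seed = "ACGTACGTACGTA"  # 13-mer
        # gene a: seed + AGG (valid PAM); gene b: seed + ATT (no PAM).
        # T-homopolymer pads contribute no PAM on either strand.
        pad = "TTTTTTTTTT"
        genes = {"a": pad + seed + "AGG" + pad, "b": pad + seed + "ATT" + pad}
        assert seedguide.find_shared_seeds(genes) == []
        genes["b"] = pad + seed + "TGG" + pad
        clusters = seedguide.find_shared_seeds(genes)
        assert clusters and clusters[0].carriers == frozenset("ab")

    def test_agrees_with_bruteforce_oracle(self, seed_oracle, rng):
        for _ in range(10):
            genes = _random_genes(rng, 5, 300)
            got = _as_pairs(seedguide.find_shared_seeds(genes))
            assert got == seed_oracle(genes)

    def test_agrees_with_oracle_on_planted_sets(self, seed_oracle):
        for i in range(5):
            planted = synthetic.gen_genes_with_seed(8, 300, 13, 4, rng_seed=100 + i)
            got = _as_pairs(seedguide.find_shared_seeds(planted.genes))
            assert got == seed_oracle(planted.genes)

    def test_strand_symmetry(self):
        planted = synthetic.gen_genes_with_seed(6, 250, 14, 3, rng_seed=9)
        fwd = seedguide.find_shared_seeds(planted.genes)
        rc_genes = {g: revcomp(s) for g, s in planted.genes.items()}
        rev = seedguide.find_shared_seeds(rc_genes)
        assert _as_pairs(fwd) == _as_pairs(rev)
        fwd_matches = {
            (c.seed_seq, m.gene_id, m.start, m.end, m.strand)
            for c in fwd for m in c.matches
        }
        rev_matches = set()
        for c in rev:
            for m in c.matches:
                n = len(rc_genes[m.gene_id])
                rev_matches.add(
                    (c.seed_seq, m.gene_id, n - m.end, n - m.start,
                     "-" if m.strand == "+" else "+")
                )
        assert fwd_matches == rev_matches

    def test_sorted_by_carrier_count_then_length(self):
        planted = synthetic.gen_genes_with_seed(10, 400, 15, 5, rng_seed=3)
        clusters = seedguide.find_shared_seeds(planted.genes)
        keys = [(-len(c.carriers), -len(c.seed_seq)) for c in clusters]
        assert keys == sorted(keys)

    def test_n_bases_never_match(self):
        seed = "ACGTACGTACGTA"
        pad = "TTTTTTTTTT"
        genes = {
            "a": pad + seed + "AGG" + pad,
            "b": pad + seed.replace("T", "N", 1) + "AGG" + pad,
        }
        assert seedguide.find_shared_seeds(genes) == []


class TestExpectedRandomHits:
    @pytest.mark.parametrize(
        "seed_len, genome_len, expected",
        [
            (13, 3.2e9, 6.4e9 / 4**13),
            (16, 3.2e9, 6.4e9 / 4**16),
            (15, 3.0e4, 6.0e4 / 4**15),
        ],
    )
    def test_uniform_background(self, seed_len, genome_len, expected):
        assert seedguide.expected_random_hits(seed_len, genome_len, 0.5) == pytest.approx(
            expected, rel=1e-9
        )

    def test_seed_composition_changes_expectation(self):
        gc_rich = seedguide.expected_random_hits(10, 1e6, gc=0.6, seed="G" * 10)
        at_rich = seedguide.expected_random_hits(10, 1e6, gc=0.6, seed="A" * 10)
        assert gc_rich > at_rich

    @given(k=st.integers(8, 24))
    def test_monotone_decreasing_in_seed_len(self, k):
        assert seedguide.expected_random_hits(
            k + 1, 3.2e9
        ) < seedguide.expected_random_hits(k, 3.2e9)

    @given(g=st.floats(1e3, 1e9))
    def test_linear_in_genome_length(self, g):
        one = seedguide.expected_random_hits(13, g)
        two = seedguide.expected_random_hits(13, 2 * g)
        assert two == pytest.approx(2 * one)

    def test_invalid_gc_rejected(self):
        with pytest.raises(DataError):
            seedguide.expected_random_hits(13, 1e6, gc=1.0)


class TestParseModifiedSgrna:
    def test_published_guide_yields_twenty_nt_spacer(self):
        parsed = seedguide.parse_modified_sgrna(seedguide.PUBLISHED_TDI_RNA)
        assert len(parsed.spacer) == 20
        assert parsed.spacer == "ACUGUGAGUGUGGAGACCUU"
        assert parsed.scaffold_found
        assert parsed.scaffold.startswith(seedguide.SCAFFOLD_PREFIX)
        assert parsed.plain_rna == parsed.spacer + parsed.scaffold

    def test_ribo_prefix_without_scaffold_is_flagged(self):
        parsed = seedguide.parse_modified_sgrna("rArC")
        assert parsed.plain_rna == "AC"
        assert parsed.scaffold == ""
        assert not parsed.scaffold_found

    def test_methyl_and_thioate_notation(self):
        assert seedguide.parse_modified_sgrna("mA*mA*").plain_rna == "AA"

    def test_unrecognized_character_named_in_error(self):
        with pytest.raises(DataError, match="'X'"):
            seedguide.parse_modified_sgrna("mA*XG")

    def test_dangling_prefix_rejected(self):
        with pytest.raises(DataError):
            seedguide.parse_modified_sgrna("ACGm")


class TestDesignGuide:
    def _cluster(self, seed, genes):
        clusters = seedguide.find_shared_seeds(
            genes, SeedParameters(min_seed_len=min(13, len(seed)))
        )
        assert clusters
        return clusters[0]

    def test_seed_of_spacer_length_needs_no_padding(self):
        seed = "ACTGTGAGTGTGGAGACCTT"
        pad = "CATCATCATCAT"
        genes = {"a": pad + seed + "AGG" + pad, "b": pad + seed + "CGG" + pad}
        design = seedguide.design_guide(self._cluster(seed, genes), genes=genes)
        assert design.spacer == seedguide.dna_to_rna(seed)
        assert design.n_padded == 0 and not design.warning
        assert design.full_sgrna == design.spacer + seedguide.CANONICAL_SCAFFOLD

    def test_short_seed_padded_from_representative_carrier(self):
        planted = synthetic.gen_genes_with_seed(5, 300, 15, 3, rng_seed=21)
        clusters = seedguide.find_shared_seeds(planted.genes)
        design = seedguide.design_guide(clusters[0], genes=planted.genes)
        assert len(design.spacer) == 20
        assert design.n_padded == 20 - len(clusters[0].seed_seq)
        assert design.spacer.endswith(seedguide.dna_to_rna(clusters[0].seed_seq))
        rep = clusters[0].matches[0]
        seq = planted.genes[rep.gene_id]
        if rep.strand == "+":
            context = seq[rep.start - design.n_padded : rep.end]
        else:
            context = revcomp(seq[rep.start : rep.end + design.n_padded])
        assert design.spacer == seedguide.dna_to_rna(context)

    def test_no_flank_available_emits_seed_only_with_warning(self):
        seed = "ACGTACGTACGTAGT"
        genes = {"a": seed + "AGG" + "CT" * 10, "b": seed + "TGG" + "CT" * 10}
        design = seedguide.design_guide(self._cluster(seed, genes), genes=genes)
        assert design.warning
        assert design.spacer == seedguide.dna_to_rna(seed)

    def test_empty_cluster_rejected(self):
        cluster = SeedCluster("ACGT", frozenset(), [], 1.0)
        with pytest.raises(DataError):
            seedguide.design_guide(cluster)


class TestCutSites:
    def test_forward_strand_cut_three_bp_from_pam(self):
        match = SeedMatch("geneA", 100, 120, "+", "A" * 20, 120)
        cluster = SeedCluster("A" * 20, frozenset(["geneA"]), [match], 1.0)
        (cut,) = seedguide.cut_sites(cluster)
        assert (cut.start, cut.end, cut.strand) == (117, 118, "+")

    def test_reverse_strand_cut_reflected_on_forward_coordinates(self):
        # same protospacer on the - strand of a 300 bp gene: seed at forward
        # [180, 200), PAM at forward [177, 180)
        match = SeedMatch("geneA", 180, 200, "-", "A" * 20, 177)
        cluster = SeedCluster("A" * 20, frozenset(["geneA"]), [match], 1.0)
        (cut,) = seedguide.cut_sites(cluster)
        assert (cut.start, cut.end, cut.strand) == (182, 183, "-")

    def test_cut_site_lies_inside_planted_seed(self):
        planted = synthetic.gen_genes_with_seed(4, 200, 15, 4, rng_seed=5)
        clusters = seedguide.find_shared_seeds(planted.genes)
        for cut in seedguide.cut_sites(clusters[0]):
            start, end = planted.planted[cut.gene_id]
            assert start <= cut.start < end

    def test_empty_cluster_gives_empty_output(self):
        cluster = SeedCluster("ACGT", frozenset(), [], 1.0)
        assert seedguide.cut_sites(cluster) == []


class TestSeedParameters:
    def test_minimum_seed_length_floor(self):
        with pytest.raises(DataError):
            SeedParameters(min_seed_len=7)

    def test_pam_must_be_three_iupac_letters(self):
        with pytest.raises(DataError):
            SeedParameters(pam="NGGG")
        with pytest.raises(DataError):
            SeedParameters(pam="NQG")
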