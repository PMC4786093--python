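import pytest

from codonfit import (
    CodingSequence,
    DesignSpec,
    SimulationConfig,
    design_allele,
    diff_alleles,
    split_regions,
)
from codonfit.sequences import CODON_TO_AA
from codonfit.simulate import make_biased_gene_set


def _gene_with_leu_at(positions, length=50):
    codons = ["ATG"] + ["GCT"] * (length - 1)
    for p in positions:
        codons[p - 1] = "CTG"
    return CodingSequence("parent", "".join(codons))


class TestDesignAllele:
    def test_protected_prefix(self):
        parent = _gene_with_leu_at([10, 45])
        allele = design_allele(parent, DesignSpec({"Leu": "UUA"}, protected_prefix=40))
        assert allele.N == 1
        assert allele.substitutions[0].index == 45
        assert allele.substitutions[0].original == "CUG"
        assert allele.substitutions[0].new == "UUA"

    def test_identity_when_target_equals_existing(self):
        parent = _gene_with_leu_at([45])
        allele = design_allele(parent, DesignSpec({"Leu": "CUG"}, protected_prefix=40))
        assert allele.N == 0
        assert allele.seq.seq == parent.seq

    def test_non_synonymous_target_rejected(self):
        with pytest.raises(ValueError, match="does not encode"):
            DesignSpec({"Leu": "CCG"})

    def test_source_filter_restricts_replacement(self):
        codons = ["ATG"] + ["CGT"] * 5 + ["CGC"] * 5 + ["TAA"]
        parent = CodingSequence("p", "".join(codons))
        spec = DesignSpec({"Arg": "CGG"}, source_filter={"Arg": "CGU"}, protected_prefix=0)
        allele = design_allele(parent, spec)
        assert allele.N == 5
        assert all(s.original == "CGU" for s in allele.substitutions)

    def test_brute_force_count_and_protein_identity(self):
        cfg = SimulationConfig(seed=11, n_genes=1, gene_length=400)
        [parent] = make_biased_gene_set(cfg)
        spec = DesignSpec({"Leu": "CUA"}, protected_prefix=40)
        allele = design_allele(parent, spec)
        expected = sum(
            1
            for i, c in enumerate(parent.codons)
            if i >= 40 and CODON_TO_AA.get(c) == "L" and c != "CTA"
        )
        assert allele.N == expected
        assert allele.seq.translate() == parent.translate()

    def test_idempotent(self):
        cfg = SimulationConfig(seed=12, n_genes=1, gene_length=200)
        [parent] = make_biased_gene_set(cfg)
        spec = DesignSpec({"Pro": "CCA"}, protected_prefix=40)
        once = design_allele(parent, spec)
        twice = design_allele(once.seq, spec)
        assert twice.N == 0
        assert twice.seq.seq == once.seq.seq

    def test_combination_equals_union_of_singles(self):
        """A two-amino-acid design collects exactly the substitutions of the
        two single-amino-acid designs."""
        cfg = SimulationConfig(seed=13, n_genes=1, gene_length=400)
        [parent] = make_biased_gene_set(cfg)
        leu = design_allele(parent, DesignSpec({"Leu": "UUA"}))
        pro = design_allele(parent, DesignSpec({"Pro": "CCA"}))
        both = design_allele(parent, DesignSpec({"Leu": "UUA", "Pro": "CCA"}))
        assert set(both.substitutions) == set(leu.substitutions) | set(pro.substitutions)
        assert both.N == leu.N + pro.N

    def test_region_outside_gene_rejected(self):
        parent = _gene_with_leu_at([45])
        with pytest.raises(ValueError, match="outside"):
            design_allele(parent, DesignSpec({"Leu": "UUA"}, region=(1, 500)))


class TestSplitRegions:
    def test_halves_partition_full_design(self):
        cfg = SimulationConfig(seed=14, n_genes=1, gene_length=400)
        [parent] = make_biased_gene_set(cfg)
        spec = DesignSpec({"Leu": "UUA"})
        full = design_allele(parent, spec)
        first, second = split_regions(parent, spec)
        n1 = design_allele(parent, first).N
        n2 = design_allele(parent, second).N
        assert n1 + n2 == full.N

    def test_boundary_between_targets_reproduces_13_12_split(self):
        """With 25 targeted codons and the boundary placed after the 13th,
        the halves carry 13 and 12 substitutions."""
        positions = list(range(41, 41 + 25))
        parent = _gene_with_leu_at(positions, length=80)
        spec = DesignSpec({"Leu": "UUA"})
        boundary = positions[12]  # 13th targeted codon
        first, second = split_regions(parent, spec, boundary=boundary)
        assert design_allele(parent, first).N == 13
        assert design_allele(parent, second).N == 12

    def test_zero_targets_gives_empty_halves(self):
        parent = CodingSequence("p", "ATG" + "GCT" * 99)
        first, second = split_regions(parent, DesignSpec({"Leu": "UUA"}))
        assert design_allele(parent, first).N == 0
        assert design_allele(parent, second).N == 0

    def test_partition_holds_for_every_boundary(self):
        cfg = SimulationConfig(seed=15, n_genes=1, gene_length=120)
        [parent] = make_biased_gene_set(cfg)
        spec = DesignSpec({"Ala": "GCG"})
        full_n = design_allele(parent, spec).N
        for boundary in range(41, parent.n_codons - 1):
            first, second = split_regions(parent, spec, boundary=boundary)
            assert (
                design_allele(parent, first).N + design_allele(parent, second).N
                == full_n
            )


class TestDiff:
    def test_identical_sequences_empty_diff(self):
        a = CodingSequence("a", "ATGGCTTAA")
        assert diff_alleles(a, a) == []

    def test_single_change_recorded_with_index(self):
        a = CodingSequence("a", "ATGGCTGCTTAA")
        b = CodingSequence("b", "ATGGCTGCATAA")
        [sub] = diff_alleles(b, a)
        assert (sub.index, sub.original, sub.new) == (3, "GCU", "GCA")

    def test_round_trip_with_design(self):
        cfg = SimulationConfig(seed=16, n_genes=1, gene_length=300)
        [parent] = make_biased_gene_set(cfg)
        allele = design_allele(parent, DesignSpec({"Val": "GUC"}))
        assert tuple(diff_alleles(allele.seq, parent)) == allele.substitutions

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            diff_alleles(CodingSequence("a", "ATGTAA"), CodingSequence("b", "ATGGCTTAA"))


def test_protein_identity_and_partition_on_many_seeded_genes():
    """Designer preserves the protein and halves partition N on 100 seeded genes."""
    genes = make_biased_gene_set(SimulationConfig(seed=99, n_genes=100, gene_length=120))
    spec = DesignSpec({"Leu": "UUA", "Pro": "CCA"})
    for parent in genes:
        full = design_allele(parent, spec)
        assert full.seq.translate() == parent.translate()
        first, second = split_regions(parent, spec)
        assert design_allele(parent, first).N + design_allele(parent, second).N == full.N
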