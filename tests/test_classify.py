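import itertools
import math

import numpy as np
import pytest

from iscutrace.classify import (
    ClassifyError,
    IscUClassification,
    MotifSpec,
    compute_logo,
    check_criteria,
    dedupe_per_species,
    detect_cys_columns,
    residue_census,
)
from iscutrace.profiles import SeedAlignment, align_to_profile, calibrate_evalues
from iscutrace.screen import CalibratedHit, Gene, Genome, scan_proteome
from iscutrace import seeds as seedlib

from conftest import random_protein

LOG2_20 = math.log2(20)


def scaffold_genome(protein, taxon="T01", neighbor_label="iscS", neighbor_distance=2,
                    n_genes=15, scaffold_slot=7):
    """A genome with the candidate scaffold planted at a fixed slot."""
    rng = np.random.default_rng(99)
    genes = []
    for i in range(n_genes):
        label = "hypothetical"
        if neighbor_label and i == scaffold_slot + neighbor_distance:
            label = neighbor_label
        seq = protein if i == scaffold_slot else random_protein(rng, 100)
        genes.append(Gene(f"{taxon}_g{i:03d}", i, "+", seq, label))
    return Genome(taxon, taxon, {"domain": "Bacteria", "phylum": "phylum_A"}, genes)


def hit_for(genome, profile, slot=7):
    gene = genome.genes[slot]
    aln = align_to_profile(gene.protein, profile, query_id=gene.locus_id)
    return CalibratedHit(genome.taxon_id, gene.locus_id, "U-family", aln.score_bits, 1e-30, aln)


@pytest.fixture(scope="module")
def cys_refs(iscu_seed):
    return detect_cys_columns(iscu_seed)


class TestDetectCysColumns:
    def test_finds_the_three_invariant_columns(self, iscu_seed):
        assert detect_cys_columns(iscu_seed) == set(seedlib.ISCU_CYS_REFS)

    def test_includes_reference_106(self, iscu_seed):
        assert 106 in detect_cys_columns(iscu_seed)

    def test_half_conserved_fourth_column_excluded(self):
        # three invariant Cys columns plus one at 50% Cys
        rows = [
            ("ref", "ACACAC"),
            ("r1", "ACACAC"),
            ("r2", "ACWCAC"),
            ("r3", "ACWCAC"),
        ]
        seed = SeedAlignment(rows=rows, reference_row="ref")
        assert detect_cys_columns(seed, min_conservation=0.95) == {2, 4, 6}

    def test_fewer_than_three_qualifying_is_an_error(self):
        rows = [("ref", "ACDEFG"), ("r1", "ACDEFG")]
        with pytest.raises(ClassifyError, match="need 3"):
            detect_cys_columns(SeedAlignment(rows=rows, reference_row="ref"))


class TestCheckCriteria:
    def test_canonical_scaffold_accepted(self, iscu_profile, cys_refs):
        genome = scaffold_genome(iscu_profile.consensus)
        c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
        assert (c.c_cys, c.c_motif, c.c_nodomain, c.c_neighbor) == (True,) * 4
        assert c.accepted
        assert c.residue_108 == "I"

    def test_nifu_like_fusion_fails_only_the_domain_criterion(self, iscu_profile, cys_refs):
        rng = np.random.default_rng(5)
        fusion = iscu_profile.consensus + random_protein(rng, 200)
        genome = scaffold_genome(fusion)
        c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
        assert not c.c_nodomain
        assert c.c_cys and c.c_motif and c.c_neighbor
        assert not c.accepted

    def test_sufu_like_motifless_fails_only_the_motif_criterion(self, iscu_profile, cys_refs):
        seq = list(iscu_profile.consensus)
        for k, col in enumerate(iscu_profile.match_columns):
            if iscu_profile.ref_number_of_column.get(col) in range(99, 104):
                seq[k] = "G"
        genome = scaffold_genome("".join(seq))
        c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
        assert not c.c_motif
        assert c.c_cys and c.c_nodomain and c.c_neighbor
        assert not c.accepted

    def test_missing_cysteine_fails_cys_criterion(self, iscu_profile, cys_refs):
        seq = list(iscu_profile.consensus)
        col = iscu_profile.column_for_ref(106)
        seq[iscu_profile.match_columns.index(col)] = "A"
        genome = scaffold_genome("".join(seq))
        c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
        assert not c.c_cys
        assert not c.accepted

    @pytest.mark.parametrize("distance,expected", [(1, True), (5, True), (6, False)])
    def test_neighbor_window_boundary(self, iscu_profile, cys_refs, distance, expected):
        genome = scaffold_genome(iscu_profile.consensus, neighbor_distance=distance)
        c = check_criteria(
            hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs, window=5
        )
        assert c.c_neighbor is expected

    def test_candidate_does_not_count_itself_as_neighbor(self, iscu_profile, cys_refs):
        genome = scaffold_genome(iscu_profile.consensus, neighbor_label=None)
        genome.genes[7].annotation_label = "iscU"  # the candidate itself
        c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
        assert not c.c_neighbor

    def test_conjunction_over_all_flag_combinations(self):
        for flags in itertools.product([False, True], repeat=4):
            c = IscUClassification("T", "g", *flags, residue_108="I")
            assert c.accepted == all(flags)

    def test_residue_108_matches_manual_indexing(self, iscu_profile, cys_refs):
        # gapless scaffolds: the residue at reference 108 is literally the
        # 108th character of the query
        rng = np.random.default_rng(17)
        freqs = np.stack(
            [iscu_profile.columns[c].frequencies for c in iscu_profile.match_columns]
        )
        cum = np.cumsum(freqs, axis=1)
        from iscutrace.profiles import AMINO_ACIDS

        for _ in range(20):
            seq = list(iscu_profile.consensus)
            for k in range(len(seq)):
                if rng.random() < 0.05:
                    seq[k] = AMINO_ACIDS[int(np.searchsorted(cum[k], rng.random()))]
            q = "".join(seq)
            genome = scaffold_genome(q)
            c = check_criteria(hit_for(genome, iscu_profile), genome, iscu_profile, cys_refs)
            if c.residue_108 is not None and len(c.ref_residues) == iscu_profile.n_match:
                assert c.residue_108 == q[107]


class TestMotifSpec:
    @pytest.mark.parametrize(
        "observed,expected",
        [
            ("LPPVK", True),
            ("IPPVK", True),   # one substitution away from a proline: allowed
            ("LPPVR", True),
            ("IPPVR", False),  # two substitutions
            ("LAPVK", False),  # proline replaced: fixed position
            ("LPAVK", False),
            ("LPPV", False),   # wrong length
        ],
    )
    def test_mismatch_budget(self, observed, expected):
        assert MotifSpec().matches(observed) is expected


class TestResidueCensus:
    def _cls(self, taxon, aa, score=1.0, accepted=True, locus="g1"):
        f = accepted
        return IscUClassification(taxon, locus, f, f, f, f, residue_108=aa, score_bits=score)

    def _genomes(self, taxa, phylum="phylum_A"):
        return [
            Genome(t, t, {"domain": "Bacteria", "phylum": phylum}, []) for t in taxa
        ]

    def test_bookkeeping_and_ilv_fraction(self):
        cls = (
            [self._cls(f"A{i}", "I") for i in range(5)]
            + [self._cls(f"B{i}", "L") for i in range(3)]
            + [self._cls(f"C{i}", "M") for i in range(2)]
        )
        census = residue_census(cls, self._genomes([c.taxon_id for c in cls]))
        assert census.counts["phylum_A"] == {"I": 5, "L": 3, "M": 2}
        assert census.ilv_fraction("phylum_A") == pytest.approx(0.8)
        assert census.totals["phylum_A"] == 10

    def test_empty_input_gives_empty_census(self):
        census = residue_census([], [])
        assert census.counts == {}
        assert census.to_frame().empty

    def test_rejected_classifications_not_counted(self):
        cls = [self._cls("T1", "I"), self._cls("T2", "I", accepted=False)]
        census = residue_census(cls, self._genomes(["T1", "T2"]))
        assert census.totals["phylum_A"] == 1

    def test_per_species_deduplication_keeps_best_score(self):
        cls = [
            self._cls("T1", "I", score=5.0, locus="g1"),
            self._cls("T1", "M", score=9.0, locus="g2"),
        ]
        best = dedupe_per_species(cls)
        assert len(best) == 1 and best[0].residue_108 == "M"
        census = residue_census(cls, self._genomes(["T1"]))
        assert census.counts["phylum_A"] == {"M": 1}

    def test_totals_conserved(self):
        rng = np.random.default_rng(0)
        aas = [["I", "L", "V", "M", "N"][i] for i in rng.integers(5, size=30)]
        cls = [self._cls(f"T{i:02d}", aa) for i, aa in enumerate(aas)]
        census = residue_census(cls, self._genomes([c.taxon_id for c in cls]))
        assert sum(census.overall().values()) == 30


class TestSequenceLogo:
    def _member(self, taxon, residues):
        return IscUClassification(
            taxon, "g1", True, True, True, True,
            residue_108=residues.get(108), ref_residues=residues,
        )

    def test_invariant_column_reaches_maximum_information(self):
        members = [self._member(f"T{i}", {99: "P"}) for i in range(8)]
        logo = compute_logo(members, region=(99, 99))
        assert logo.information_bits[0] == pytest.approx(LOG2_20, abs=1e-9)

    def test_uniform_column_has_zero_information(self):
        from iscutrace.profiles import AMINO_ACIDS

        members = [self._member(f"T{i}", {99: aa}) for i, aa in enumerate(AMINO_ACIDS)]
        logo = compute_logo(members, region=(99, 99))
        assert logo.information_bits[0] == pytest.approx(0.0, abs=1e-9)

    def test_even_two_residue_split(self):
        members = [self._member(f"T{i}", {99: "V" if i % 2 else "I"}) for i in range(10)]
        logo = compute_logo(members, region=(99, 99))
        assert logo.information_bits[0] == pytest.approx(LOG2_20 - 1.0, abs=1e-9)

    def test_empty_column_reported_as_none(self):
        members = [self._member("T0", {99: "P"})]
        logo = compute_logo(members, region=(99, 100))
        assert logo.information_bits[1] is None

    def test_invariant_under_member_order_and_ids(self):
        rng = np.random.default_rng(3)
        residues = [{99: "L", 100: "P"} if i % 3 else {99: "I", 100: "P"} for i in range(9)]
        a = compute_logo([self._member(f"T{i}", r) for i, r in enumerate(residues)], (99, 100))
        perm = list(rng.permutation(9))
        b = compute_logo(
            [self._member(f"Z{k}", residues[i]) for k, i in enumerate(perm)], (99, 100)
        )
        np.testing.assert_allclose(a.frequencies, b.frequencies)
        assert a.information_bits == b.information_bits

    def test_no_accepted_members_is_an_error(self):
        with pytest.raises(ClassifyError):
            compute_logo([], region=(99, 108))
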