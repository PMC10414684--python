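import math
import random

import pytest

from helminthamp import sequelog_grouping as sg
from helminthamp.types import PrecursorProtein

from _oracles import UnionFind, sw_affine_brute

AA = "ACDEFGHIKLMNPQRSTVWY"


def blosum(a, b):
    return int(sg._BLOSUM62[sg._AA_INDEX[a], sg._AA_INDEX[b]])


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self):
        seq = "GFGRWLKKTWSKV"
        assert sg.smith_waterman(seq, seq) == sum(blosum(c, c) for c in seq) == 77

    def test_disjoint_alphabets_score_zero(self):
        assert sg.smith_waterman("KKKK", "DDDD") == 0

    def test_symmetry(self):
        rng = random.Random(3)
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 40)))
            assert sg.smith_waterman(a, b) == sg.smith_waterman(b, a)

    def test_matches_brute_force_dp(self):
        """200 random pairs against an independent three-matrix affine DP."""
        rng = random.Random(7)
        for _ in range(200):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 60)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 60)))
            assert sg.smith_waterman(a, b) == sw_affine_brute(a, b, blosum)

    def test_matches_external_aligner(self):
        """Cross-check against biotite's C aligner (open = 12, extend = 1
        reproduces the 11 + L gap-cost convention)."""
        seq_mod = pytest.importorskip("biotite.sequence")
        align = pytest.importorskip("biotite.sequence.align")
        matrix = align.SubstitutionMatrix.std_protein_matrix()
        rng = random.Random(9)
        for _ in range(30):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(10, 50)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(10, 50)))
            ext = align.align_optimal(
                seq_mod.ProteinSequence(a), seq_mod.ProteinSequence(b),
                matrix, gap_penalty=(-12, -1), local=True,
            )[0].score
            assert sg.smith_waterman(a, b) == ext

    def test_nonstandard_residue_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            sg.smith_waterman("AKXL", "AKL")


class TestBitScore:
    def test_formula_values(self):
        assert sg.bit_score(0) == pytest.approx(-math.log(0.041) / math.log(2), abs=1e-6)
        assert sg.bit_score(0) == pytest.approx(4.608, abs=1e-3)
        assert sg.bit_score(100) == pytest.approx(43.13, abs=0.01)

    def test_hundred_bits_needs_raw_248(self):
        assert sg.min_raw_for_bits(100.0) == 248
        assert sg.bit_score(248) >= 100.0 > sg.bit_score(247)

    def test_strictly_increasing(self):
        scores = [sg.bit_score(r) for r in range(0, 300, 10)]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_short_peptides_cannot_group_at_default_threshold(self):
        """Below ~45 residues even a perfect self-match stays under 100 bits
        (maximal BLOSUM62 diagonal 11 would need 23 tryptophans; realistic
        peptides need far more length), so mature-peptide grouping at the
        default threshold is impossible for short AMPs."""
        seq = "GFGRWLKKTWSKV" * 2  # 26 residues, realistic composition
        self_raw = sg.smith_waterman(seq, seq)
        assert sg.bit_score(self_raw) < 100.0


class TestExclusionFilter:
    CECROPIN_P1 = "SWLSKTAKKLENSAKKRISEGIAIAIQGGPR"

    def lib(self):
        return [PrecursorProtein("cecropin_p1", "library", self.CECROPIN_P1)]

    def test_identical_to_library_removed(self):
        item = sg.GroupingItem("p1", "g1", self.CECROPIN_P1)
        kept, removed = sg.exclusion_filter([item], self.lib())
        assert kept == []
        assert removed[0]["best_hit"] == "cecropin_p1"

    def test_empty_library_is_identity(self):
        item = sg.GroupingItem("p1", "g1", self.CECROPIN_P1)
        kept, removed = sg.exclusion_filter([item], [])
        assert kept == [item] and removed == []

    def test_unrelated_peptide_survives(self):
        item = sg.GroupingItem("p1", "g1", "DDDDDGGGGGDDDDDGGGGG")
        kept, _ = sg.exclusion_filter([item], self.lib())
        assert kept == [item]

    def test_planted_known_amp_copies_all_removed(self, default_bundle):
        seqs = {p.protein_id: p.sequence for p in default_bundle.proteins}
        items = []
        for row in default_bundle.families:
            if row["role"] == "known_amp":
                mature = seqs[row["protein_id"]][row["mature_start"] - 1 : row["mature_end"]]
                items.append(sg.GroupingItem(row["protein_id"], row["genome_id"], mature))
        assert len(items) == 12
        kept, removed = sg.exclusion_filter(items, default_bundle.known_amps)
        assert kept == [] and len(removed) == 12


class TestBuildGroups:
    def test_two_identical_sixty_mers_one_group(self):
        seq = "GFGKWVKKKWGSVRKGASKLVKGVKKVFPKKGIPIIRYERRF" + "KLAGKIGSKWSKAGQSLV"
        assert len(seq) == 60
        items = [sg.GroupingItem("a", "g1", seq), sg.GroupingItem("b", "g2", seq)]
        groups = sg.build_groups(items)
        assert len(groups) == 1
        assert groups[0].members == ("a", "b")

    def test_singletons_never_emitted(self):
        items = [sg.GroupingItem("a", "g1", "KLWKKWAKKWLK" * 5),
                 sg.GroupingItem("b", "g2", "DGESDNQSTPGH" * 5)]
        assert sg.build_groups(items) == []

    def test_single_genome_components_discarded(self):
        seq = "GFGKWVKKKWGSVRKGASKLVKGVKKVFPKKGIPIIRYERRF" + "KLAGKIGSKWSKAGQSLV"
        items = [sg.GroupingItem("a", "g1", seq), sg.GroupingItem("b", "g1", seq)]
        assert sg.build_groups(items) == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sg.build_groups([])

    def _family_items(self, bundle):
        seqs = {p.protein_id: p.sequence for p in bundle.proteins}
        return [
            sg.GroupingItem(r["protein_id"], r["genome_id"], seqs[r["protein_id"]])
            for r in bundle.families
            if r["role"] == "amp"
        ]

    def test_planted_families_recovered_and_match_union_find(self, default_bundle):
        items = self._family_items(default_bundle)
        groups = sg.build_groups(items)

        # oracle: union-find over the thresholded edge matrix
        bits = sg.pairwise_bits(items)
        uf = UnionFind(len(items))
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                if bits[i, j] >= 100.0:
                    uf.union(i, j)
        oracle = {
            frozenset(items[i].peptide_id for i in comp)
            for comp in uf.components()
            if len(comp) >= 2 and len({items[i].genome_id for i in comp}) >= 2
        }
        assert {frozenset(g.members) for g in groups} == oracle

        # every planted family comes back as exactly one pure component
        fam_of = {it.peptide_id: it.peptide_id.split("_")[0] for it in items}
        recovered = 0
        for g in groups:
            fams = {fam_of[m] for m in g.members}
            if len(fams) == 1 and len(g.members) == 4:
                recovered += 1
        assert recovered >= 0.9 * default_bundle.spec.n_families

    def test_grouping_invariant_to_input_order(self, default_bundle):
        items = self._family_items(default_bundle)
        shuffled = list(items)
        random.Random(5).shuffle(shuffled)
        a = [(g.group_id, g.members) for g in sg.build_groups(items)]
        b = [(g.group_id, g.members) for g in sg.build_groups(shuffled)]
        assert a == b


class TestConsensusAndRepresentative:
    def make_group(self, members):
        return sg.SequelogGroup(1, tuple(sorted(members)), frozenset({"g1", "g2"}))

    def test_identical_sequences(self):
        seqs = {"a": "KLWKKWAKKWLKG", "b": "KLWKKWAKKWLKG", "c": "KLWKKWAKKWLKG"}
        cons, rep = sg.consensus_and_representative(self.make_group(seqs), seqs)
        assert cons == "KLWKKWAKKWLKG"
        assert rep == "a"  # tie-break: smallest id

    def test_column_mode(self):
        seqs = {"a": "AAKK", "b": "AAKR", "c": "AAKK"}
        cons, _ = sg.consensus_and_representative(self.make_group(seqs), seqs)
        assert cons == "AAKK"

    def test_pair_group_requires_two(self):
        with pytest.raises(ValueError):
            sg.consensus_and_representative(
                sg.SequelogGroup(1, ("a",), frozenset({"g1"})), {"a": "AAKK"})

    def test_representative_close_to_planted_ancestor(self, default_bundle):
        """For ≥90 % of planted families the chosen representative is within
        one substitution of the mutated family's ancestor mature peptide."""
        seqs = {p.protein_id: p.sequence for p in default_bundle.proteins}
        by_family: dict[str, dict[str, str]] = {}
        for r in default_bundle.families:
            if r["role"] != "amp":
                continue
            mature = seqs[r["protein_id"]][r["mature_start"] - 1 : r["mature_end"]]
            by_family.setdefault(r["family_id"], {})[r["protein_id"]] = mature
        good = 0
        for fam, members in by_family.items():
            group = sg.SequelogGroup(1, tuple(sorted(members)), frozenset({"g"}))
            _, rep = sg.consensus_and_representative(group, members)
            ancestor = default_bundle.ancestors[fam]
            dist = sum(a != b for a, b in zip(members[rep], ancestor))
            dist += abs(len(members[rep]) - len(ancestor))
            if dist <= 1:
                good += 1
        assert good / len(by_family) >= 0.9
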