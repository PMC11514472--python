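from collections import Counter

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

import hic_curator as hc
from hic_curator.assembly_model import parse_provenance
from hic_curator.errors import BoundsError, FormatError, ParameterError

CANONICAL = """>ctg:0-100 1 100
>ctg:100-300 2 200
>ctg:300-600 3 300
1 -2 3
"""


def flat(doc):
    return [s for row in doc.layout for s in row]


class TestSerialisation:
    def test_parse_signed_layout(self):
        doc = hc.read_assembly(CANONICAL)
        assert [f.length for f in doc.fragments] == [100, 200, 300]
        assert doc.layout == [[1, -2, 3]]

    def test_write_read_is_identity_on_canonical_text(self):
        assert hc.write_assembly(hc.read_assembly(CANONICAL)) == CANONICAL

    def test_read_write_is_identity_on_documents(self, toy_doc):
        assert hc.read_assembly(hc.write_assembly(toy_doc)) == toy_doc

    @pytest.mark.parametrize(
        "text",
        [
            ">a 1 100\n>b 1 50\n1\n",  # duplicate id
            ">a 1 100\n1 4\n",  # unknown id in layout
            ">a 1 100\n>b 2 50\n1\n",  # id missing from layout
            ">a 1 100\nx y\n",  # non-integer layout token
        ],
    )
    def test_malformed_documents_rejected(self, text):
        with pytest.raises(FormatError):
            hc.read_assembly(text)

    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=1, max_size=8),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip_fuzz(self, lengths, rnd):
        pos = 0
        frags = []
        for i, ln in enumerate(lengths):
            frags.append(hc.Fragment(f"c:{pos}-{pos + ln}", i + 1, ln))
            pos += ln
        ids = [(i + 1) * rnd.choice([1, -1]) for i in range(len(lengths))]
        rnd.shuffle(ids)
        doc = hc.AssemblyDoc(frags, [ids])
        assert hc.read_assembly(hc.write_assembly(doc)) == doc


class TestLocate:
    def test_prefix_sum_oracle(self, toy_doc):
        assert hc.locate(toy_doc, 150) == (0, 1, 2, 50)
        assert hc.locate(toy_doc, 599) == (0, 2, 3, 299)

    def test_origin(self, toy_doc):
        assert hc.locate(toy_doc, 0) == (0, 0, 1, 0)

    def test_out_of_range(self, toy_doc):
        with pytest.raises(BoundsError):
            hc.locate(toy_doc, 600)


class TestSplit:
    def test_split_inside_forward_fragment(self, toy_doc):
        out = hc.split_at(toy_doc, 150)  # 50 bp into fragment 2
        assert [f.length for f in out.fragments] == [100, 50, 150, 300]
        assert flat(out) == [1, 2, 3, 4]
        assert out.total_length == toy_doc.total_length
        # provenance follows the native axis
        assert out.fragments[1].name == "ctg:100-150"
        assert out.fragments[2].name == "ctg:150-300"

    def test_split_on_boundary_is_noop(self, toy_doc):
        assert hc.split_at(toy_doc, 100) == toy_doc
        assert hc.split_at(toy_doc, 0) == toy_doc

    def test_split_inside_reverse_fragment_reflects_cut(self):
        frags = [hc.Fragment("c:0-100", 1, 100), hc.Fragment("c:100-300", 2, 200)]
        doc = hc.AssemblyDoc(frags, [[1, -2]])
        out = hc.split_at(doc, 150)  # 50 bp into the reversed fragment
        # native cut at 200-50=150 from the fragment start -> pieces 150/50,
        # laid out reversed so assembly order is the 50 bp piece first
        assert [f.length for f in out.fragments] == [100, 150, 50]
        assert out.layout == [[1, -3, -2]]
        assert out.fragments[1].name == "c:100-250"
        assert out.fragments[2].name == "c:250-300"


class TestMove:
    def test_list_surgery_example(self, toy_doc):
        out = hc.move_block(toy_doc, (300, 600), 0)  # fragment 3 to front
        assert flat(out) == [3, 1, 2]

    def test_move_to_own_position_is_identity(self, toy_doc):
        assert hc.move_block(toy_doc, (100, 300), 100) == toy_doc
        assert hc.move_block(toy_doc, (100, 300), 300) == toy_doc

    def test_move_and_move_back(self, toy_doc):
        once = hc.move_block(toy_doc, (300, 600), 0)
        back = hc.move_block(once, (0, 300), 600)
        assert back == toy_doc

    def test_insertion_inside_block_rejected(self, toy_doc):
        with pytest.raises(ParameterError):
            hc.move_block(toy_doc, (100, 600), 200)

    def test_unaligned_block_rejected(self, toy_doc):
        with pytest.raises(ParameterError):
            hc.move_block(toy_doc, (100, 250), 0)


class TestInvert:
    def test_reverse_and_negate(self, toy_doc):
        out = hc.invert_block(toy_doc, (100, 600))  # fragments 2 3
        assert flat(out) == [1, -3, -2]

    def test_involution(self, toy_doc):
        assert hc.invert_block(hc.invert_block(toy_doc, (100, 600)), (100, 600)) == toy_doc

    def test_single_fragment_flip(self, toy_doc):
        assert flat(hc.invert_block(toy_doc, (100, 300))) == [1, -2, 3]

    def test_empty_block_is_noop(self, toy_doc):
        assert hc.invert_block(toy_doc, (100, 100)) == toy_doc


class TestRelegate:
    def test_block_moves_to_new_trailing_scaffold(self, toy_doc):
        out = hc.relegate_debris(toy_doc, (100, 300))
        assert out.layout == [[1, 3], [2]]
        assert out.has_leftover

    def test_already_trailing_block_unchanged(self, toy_doc):
        out = hc.relegate_debris(toy_doc, (300, 600))
        assert out.layout == toy_doc.layout

    def test_successive_relegations_share_one_scaffold(self, toy_doc):
        out = hc.relegate_debris(toy_doc, (100, 300))
        out = hc.relegate_debris(out, (0, 100))
        assert out.layout == [[3], [2, 1]]

    def test_length_conserved(self, toy_doc):
        assert hc.relegate_debris(toy_doc, (100, 300)).total_length == 600


class TestBuildFasta:
    CONTIG = "ACGTTGCA" * 10  # 80 bp

    def test_single_forward_fragment_is_identity(self):
        doc = hc.AssemblyDoc([hc.Fragment("c:0-80", 1, 80)], [[1]])
        out = hc.build_fasta(doc, {"c": self.CONTIG}, gap_len=0)
        assert out == {"scaffold_1": self.CONTIG}

    def test_reverse_fragment_against_biopython(self):
        doc = hc.AssemblyDoc([hc.Fragment("c:10-50", 1, 40)], [[-1]])
        out = hc.build_fasta(doc, {"c": self.CONTIG}, gap_len=0)
        assert out["scaffold_1"] == str(Seq(self.CONTIG[10:50]).reverse_complement())

    def test_gap_of_exactly_gap_len_ns(self):
        doc = hc.AssemblyDoc(
            [hc.Fragment("c:0-30", 1, 30), hc.Fragment("c:30-80", 2, 50)], [[1, 2]]
        )
        seq = hc.build_fasta(doc, {"c": self.CONTIG}, gap_len=500)["scaffold_1"]
        assert seq == self.CONTIG[:30] + "N" * 500 + self.CONTIG[30:]

    def test_unresolvable_fragment_name(self):
        doc = hc.AssemblyDoc([hc.Fragment("mystery", 1, 10)], [[1]])
        with pytest.raises(Exception):
            hc.build_fasta(doc, {"c": self.CONTIG})


class TestEditInvariants:
    @given(st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_random_edit_sequences_permute_native_bases(self, rnd):
        """Any split/move/invert/relegate sequence is a signed permutation of
        the native bases: undoing order and orientation rebuilds the contig."""
        contig = "".join(rnd.choice("ACGT") for _ in range(600))
        doc = hc.AssemblyDoc([hc.Fragment("c:0-600", 1, 600)], [[1]])
        total = doc.total_length
        for _ in range(6):
            op = rnd.choice(["split", "move", "invert", "relegate"])
            bounds = doc.boundaries()
            if op == "split":
                doc = hc.split_at(doc, rnd.randrange(0, total))
            elif len(bounds) >= 3:
                inner = sorted(rnd.sample(bounds, 2))
                if inner[0] == inner[1]:
                    continue
                if op == "invert":
                    try:
                        doc = hc.invert_block(doc, tuple(inner))
                    except ParameterError:
                        continue
                elif op == "move":
                    target = rnd.choice([b for b in bounds if not inner[0] < b < inner[1]])
                    try:
                        doc = hc.move_block(doc, tuple(inner), target)
                    except ParameterError:
                        continue
                else:
                    try:
                        doc = hc.relegate_debris(doc, tuple(inner))
                    except ParameterError:
                        continue
            assert doc.total_length == total
        # undo the permutation: forward signs, fragments in provenance order
        ordered = sorted(doc.fragments, key=lambda f: parse_provenance(f.name)[1])
        undone = hc.AssemblyDoc(list(doc.fragments), [[f.id for f in ordered]])
        rebuilt = hc.build_fasta(undone, {"c": contig}, gap_len=0)["scaffold_1"]
        assert rebuilt == contig
        # provenance intervals tile the contig exactly once
        ivs = sorted(parse_provenance(f.name)[1:] for f in doc.fragments)
        assert ivs[0][0] == 0 and ivs[-1][1] == 600
        assert all(a[1] == b[0] for a, b in zip(ivs, ivs[1:]))
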