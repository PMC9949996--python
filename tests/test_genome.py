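"""Genome, ORF geometry, frameshift classification and site contexts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ovrfsim.genome import (
    Annotation,
    Genome,
    GenomeError,
    NoOverlapError,
    Orf,
    classify_frameshift,
    partition_regions,
    site_contexts,
)
from ovrfsim.rate_model import DistributionSpec

from oracles import frameshift_shift

SPEC = DistributionSpec(family="constant", value=0.5)


def orf(name, start, end, strand="+", segments=None):
    return Orf(name, segments or ((start, end),), strand, omega_spec=SPEC)


class TestGenomeValidation:
    def test_minimum_length(self):
        assert Genome("A" * 9).length == 9
        with pytest.raises(GenomeError, match="minimum"):
            Genome("ACGTACGT")  # 8 nt

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(GenomeError, match="non-ACGT"):
            Genome("ACGTNACGTA")

    def test_lowercase_normalized(self):
        assert Genome("acgtacgta").sequence == "ACGTACGTA"


class TestOrfValidation:
    def test_length_multiple_of_three(self):
        g = Genome("A" * 30)
        with pytest.raises(GenomeError, match="multiple of 3"):
            orf("x", 0, 10).validate(g)

    def test_bounds(self):
        g = Genome("A" * 30)
        with pytest.raises(GenomeError, match="bounds"):
            orf("x", 24, 33).validate(g)

    def test_wrap_requires_circular(self):
        g_lin = Genome("A" * 30, is_circular=False)
        g_circ = Genome("A" * 30, is_circular=True)
        wrapped = orf("x", 0, 0, segments=((24, 30), (0, 6)))
        with pytest.raises(GenomeError, match="circular"):
            wrapped.validate(g_lin)
        wrapped.validate(g_circ)

    def test_wrap_must_meet_at_origin(self):
        g = Genome("A" * 30, is_circular=True)
        with pytest.raises(GenomeError, match="origin"):
            orf("x", 0, 0, segments=((20, 26), (0, 6))).validate(g)


class TestClassifyFrameshift:
    def test_identical_frames(self):
        g = Genome("A" * 310)
        label = classify_frameshift(orf("a", 0, 300), orf("b", 0, 300), g)
        assert label.value == "+0"

    def test_plus_one_offset(self):
        g = Genome("A" * 310)
        label = classify_frameshift(orf("a", 0, 300), orf("b", 100, 301), g)
        assert label.value == "+1"

    def test_opposite_strand_digit_matches_enumeration(self):
        g = Genome("A" * 320)
        a = orf("a", 0, 300)
        b = orf("b", 12, 312, strand="-")
        label = classify_frameshift(a, b, g)
        assert label.sign == "-"
        assert label.shift == frameshift_shift(
            a.segments, "+", b.segments, "-")

    def test_no_overlap_error(self):
        g = Genome("A" * 100)
        with pytest.raises(NoOverlapError):
            classify_frameshift(orf("a", 0, 30), orf("b", 60, 90), g)

    @pytest.mark.parametrize("seed", range(20))
    def test_randomized_pairs_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 300
        g = Genome("A" * L)
        sa = int(rng.integers(0, 50))
        a = orf("a", sa, sa + 3 * int(rng.integers(20, 60)))
        sb = int(rng.integers(0, a.segments[0][1] - 9))
        strand = "+" if rng.random() < 0.5 else "-"
        b = orf("b", sb, sb + 3 * int(rng.integers(10, 40)), strand=strand)
        if b.segments[0][1] > L or not (
                set(range(*a.segments[0])) & set(range(*b.segments[0]))):
            pytest.skip("generated pair does not overlap")
        label = classify_frameshift(a, b, g)
        assert label.sign == ("+" if strand == "+" else "-")
        assert label.shift == frameshift_shift(
            a.segments, "+", b.segments, strand)

    def test_sign_is_symmetric(self):
        g = Genome("A" * 320)
        a, b = orf("a", 0, 300), orf("b", 12, 312, strand="-")
        assert classify_frameshift(a, b, g).sign == \
            classify_frameshift(b, a, g).sign


class TestPartitionRegions:
    def test_fig2_layout_gives_five_regions(self, fig2_setup):
        genome, orfs = fig2_setup
        regions = partition_regions(genome, orfs)
        assert len(regions) == 5
        memberships = {frozenset(r.orf_membership) for r in regions}
        assert memberships == {
            frozenset(), frozenset("a"), frozenset("b"),
            frozenset(["b", "c"]), frozenset("c"),
        }

    def test_zero_orfs_single_region(self):
        g = Genome("ACGT" * 5)
        regions = partition_regions(g, [])
        assert len(regions) == 1
        assert regions[0].orf_membership == frozenset()
        assert regions[0].sites == frozenset(range(20))

    def test_identical_intervals_two_regions(self):
        g = Genome("ACGT" * 10)
        regions = partition_regions(
            g, [orf("a", 6, 24), orf("b", 6, 24)])
        assert len(regions) == 2
        coding = next(r for r in regions if r.orf_membership)
        assert coding.orf_membership == frozenset(["a", "b"])
        assert coding.sites == frozenset(range(6, 24))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_regions_always_partition_the_genome(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(30, 120))
        g = Genome("A" * L)
        orfs = []
        for i in range(int(rng.integers(0, 4))):
            ncod = int(rng.integers(3, 10))
            start = int(rng.integers(0, max(1, L - 3 * ncod)))
            if start + 3 * ncod <= L:
                orfs.append(orf(f"o{i}", start, start + 3 * ncod,
                                strand="+" if rng.random() < 0.5 else "-"))
        regions = partition_regions(g, orfs)
        covered = [p for r in regions for p in r.sites]
        assert sorted(covered) == list(range(L))  # disjoint + complete
        for r in regions:
            for p in r.sites:
                membership = {o.name for o in orfs
                              if any(s <= p < e for s, e in o.segments)}
                assert membership == set(r.orf_membership)


class TestSiteContexts:
    def test_terminal_codons_protected(self):
        g = Genome("ATGAAATAGCCC")
        ctxs = site_contexts(g, [orf("x", 0, 9)])
        protected = [c.position for c in ctxs if c.protected]
        assert protected == [0, 1, 2, 6, 7, 8]
        assert all(not ctxs[p].frame_memberships for p in (9, 10, 11))

    def test_wrap_codon_spans_origin_and_is_protected(self):
        g = Genome("ACGTACGTACGT", is_circular=True)  # L = 12
        o = orf("w", 0, 0, segments=((8, 12), (0, 5)))  # 9 nt, wraps
        ctxs = site_contexts(g, [o])
        # reading order 8..11, 0..4; codon 1 = positions (11, 0, 1)
        ann = Annotation(g, [o])
        assert ann.codon_positions("w", 1) == [11, 0, 1]
        for p in (8, 9, 10, 2, 3, 4):  # first and last codons
            assert ctxs[p].protected
        for p in (11, 0, 1):  # interior codon across the origin
            assert not ctxs[p].protected

    def test_dual_membership_independent_codon_offsets(self):
        g = Genome("A" * 60)
        ctxs = site_contexts(g, [orf("a", 0, 30), orf("b", 10, 40)])
        ctx = ctxs[20]
        entries = dict(
            (name, (ci, off)) for name, ci, off in ctx.frame_memberships)
        assert entries["a"] == (6, 2)   # reading index 20
        assert entries["b"] == (3, 1)   # reading index 10


class TestCodonAt:
    def test_forward_codon(self):
        g = Genome("ATGAAATAG")
        ann = Annotation(g, [orf("x", 0, 9)])
        assert ann.codon_at(g.sequence, 4, "x") == ("AAA", 1)

    def test_reverse_complement_codon(self):
        g = Genome("CTATTTCAT")  # revcomp is ATGAAATAG
        ann = Annotation(g, [orf("x", 0, 9, strand="-")])
        codon, off = ann.codon_at(g.sequence, 4, "x")
        assert codon == "AAA" and off == 1

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_codon_concatenation_recovers_coding_sequence(self, strand):
        g = Genome("ACGTAACCGGTTACGTAACCGGTTACGTAA", is_circular=True)
        o = orf("w", 0, 0, strand=strand, segments=((21, 30), (0, 6)))
        ann = Annotation(g, [o])
        codons = []
        for ci in range(o.length // 3):
            p = ann.codon_positions("w", ci)[0]
            codon, off = ann.codon_at(g.sequence, p, "w")
            assert off == 0
            codons.append(codon)
        assert "".join(codons) == o.coding_sequence(g.sequence)


def test_circular_partition_invariant_under_rotation():
    """Linearizing a circular genome at an ORF-free cut point rotates the
    region partition without changing it."""
    base = "ACGTAACCGG" * 6  # L = 60
    g = Genome(base, is_circular=True)
    orfs = [orf("a", 5, 20), orf("b", 14, 35)]
    regions = partition_regions(g, orfs)
    member = {p: r.orf_membership for r in regions for p in r.sites}
    cut = 45  # outside both ORFs
    rot = Genome(base[cut:] + base[:cut], is_circular=False)
    shifted = [orf(o.name, (o.segments[0][0] - cut) % 60,
                   (o.segments[0][1] - cut - 1) % 60 + 1) for o in orfs]
    member_rot = {p: r.orf_membership
                  for r in partition_regions(rot, shifted) for p in r.sites}
    for p in range(60):
        assert member[p] == member_rot[(p - cut) % 60]
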