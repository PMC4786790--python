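"""Index design, demultiplexing, trimming, filtering, merging, dereplication."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplitree.pcr import Primer, PrimerPair
from amplitree.readproc import (
    ReadPair,
    Rejection,
    SampleInfo,
    SampleSheet,
    TrimmedPair,
    demultiplex,
    dereplicate,
    design_index_set,
    hamming,
    identify_and_trim,
    length_filters,
    merge_pair,
    process_pairs,
)
from amplitree.seq import revcomp


class TestDesignIndexSet:
    def test_96_six_nt_indices_distance_two(self):
        idx = design_index_set(96, length=6, min_dist=2, seed=0)
        assert len(idx) == 96 == len(set(idx))
        assert all(len(i) == 6 for i in idx)
        assert min(hamming(a, b) for a, b in itertools.combinations(idx, 2)) >= 2

    def test_infeasible_request_errors_with_bound(self):
        with pytest.raises(ValueError, match="bound"):
            design_index_set(2, length=1, min_dist=2, seed=0)

    def test_deterministic_per_seed(self):
        assert design_index_set(20, seed=7) == design_index_set(20, seed=7)
        assert design_index_set(20, seed=7) != design_index_set(20, seed=8)


def _pair(idx="ACACAC", r1="ACGT" * 10, r2="TGCA" * 10, rid="r0"):
    return ReadPair(rid, r1, [30] * len(r1), r2, [30] * len(r2), idx)


@pytest.fixture
def sheet():
    return SampleSheet(
        entries={
            "ACACAC": SampleInfo("s1", "site1", "upper", "before"),
            "GTGTGT": SampleInfo("s2", "site2", "lower", "after"),
        }
    )


class TestDemultiplex:
    def test_exact_match_assigned(self, sheet):
        out = demultiplex([_pair("ACACAC")], sheet)
        assert len(out["s1"]) == 1 and not out["unassigned"]

    def test_one_mismatch_unassigned_under_exact_policy(self, sheet):
        out = demultiplex([_pair("ACACAA")], sheet)
        assert len(out["unassigned"]) == 1

    def test_counts_conserved_on_random_input(self, sheet):
        rng = np.random.default_rng(3)
        pairs = [
            _pair("".join(rng.choice(list("ACGT"), size=6)), rid=f"r{i}")
            for i in range(200)
        ]
        out = demultiplex(pairs, sheet)
        assert sum(len(v) for v in out.values()) == 200

    def test_sheet_rejects_close_indices(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            SampleSheet(entries={"ACACAC": SampleInfo("a"), "ACACAT": SampleInfo("b")})


F = Primer("F", "ACCGGTTACCGGAATT")
R = Primer("R", "CAGGTCATGACCTTGCAG")
PANEL = [
    PrimerPair(assay="long", forward=F, reverse=R, min_product=50, max_product=500, min_read_len=50),
    PrimerPair(
        assay="short",
        forward=Primer("F2", "GGGAAATTTCCCGGGAAA"),
        reverse=Primer("R2", "CCCTTTAAAGGGCCCTTT"),
        min_product=30,
        max_product=500,
        min_read_len=17,
    ),
]


def _reads_from_fragment(fragment, read_length=120, rid="r0", idx="ACACAC"):
    def fill(t):
        while len(t) < read_length:
            t += "AGATCGGAAGAGCACACGTC"
        return t[:read_length]

    r1 = fill(fragment)
    r2 = fill(revcomp(fragment))
    return ReadPair(rid, r1, [35] * read_length, r2, [35] * read_length, idx)


class TestIdentifyAndTrim:
    def test_constructed_pair_trimmed_exactly(self):
        rng = np.random.default_rng(1)
        insert = "".join(rng.choice(list("ACGT"), size=70))
        pair = _reads_from_fragment(F.seq + insert + revcomp(R.seq))
        t = identify_and_trim(pair, PANEL)
        assert isinstance(t, TrimmedPair)
        assert t.assay == "long"
        assert t.r1_insert == insert
        assert t.r2_insert == revcomp(insert)
        assert (t.fwd_mismatches, t.rev_mismatches) == (0, 0)

    def test_short_amplicon_read_through_trimmed(self):
        rng = np.random.default_rng(2)
        insert = "".join(rng.choice(list("ACGT"), size=48))
        pp = PANEL[1]
        pair = _reads_from_fragment(pp.forward.seq + insert + revcomp(pp.reverse.seq))
        t = identify_and_trim(pair, PANEL)
        assert isinstance(t, TrimmedPair)
        assert len(t.r1_insert) == 48
        assert t.r1_insert == insert

    def test_offset_primer_found_within_window(self):
        rng = np.random.default_rng(3)
        insert = "".join(rng.choice(list("ACGT"), size=70))
        frag = F.seq + insert + revcomp(R.seq)
        pair = ReadPair(
            "r0",
            "GTC" + frag,  # forward primer at offset 3
            [35] * (len(frag) + 3),
            "AT" + revcomp(frag),
            [35] * (len(frag) + 2),
            "ACACAC",
        )
        t = identify_and_trim(pair, PANEL)
        assert isinstance(t, TrimmedPair) and t.r1_insert == insert

    def test_no_primer_rejected(self):
        pair = _pair()
        out = identify_and_trim(pair, PANEL)
        assert isinstance(out, Rejection) and out.reason == "no_primer"

    def test_ambiguous_tie_rejected(self):
        # both assays' primers present: r1 starts with assay-1 forward,
        # r2 starts with assay-2 reverse and vice versa is impossible, so
        # construct equal total mismatches via identical primers
        panel = [
            PrimerPair(assay="x", forward=F, reverse=R, min_product=50, max_product=500),
            PrimerPair(assay="y", forward=F, reverse=R, min_product=50, max_product=500),
        ]
        rng = np.random.default_rng(4)
        insert = "".join(rng.choice(list("ACGT"), size=70))
        pair = _reads_from_fragment(F.seq + insert + revcomp(R.seq))
        out = identify_and_trim(pair, panel)
        assert isinstance(out, Rejection) and out.reason == "ambiguous"


def _trimmed(l1, l2, assay="long", q1=None, q2=None, s1=None, s2=None):
    rng = np.random.default_rng(0)
    a = s1 if s1 is not None else "".join(rng.choice(list("ACGT"), size=l1))
    b = s2 if s2 is not None else "".join(rng.choice(list("ACGT"), size=l2))
    return TrimmedPair(
        id="t0",
        sample_id="s1",
        assay=assay,
        r1_insert=a,
        r1_qual=q1 or [35] * len(a),
        r2_insert=b,
        r2_qual=q2 or [35] * len(b),
        fwd_mismatches=0,
        rev_mismatches=0,
    )


class TestLengthFilters:
    def test_49_rejected_50_kept_under_default_minimum(self):
        assert isinstance(length_filters(_trimmed(49, 49), PANEL), Rejection)
        assert isinstance(length_filters(_trimmed(50, 50), PANEL), TrimmedPair)

    def test_short_assay_override_retains_short_inserts(self):
        t = _trimmed(30, 30, assay="short")
        assert isinstance(length_filters(t, PANEL), TrimmedPair)

    def test_length_difference_six_rejected_five_kept(self):
        out = length_filters(_trimmed(100, 106), PANEL)
        assert isinstance(out, Rejection) and out.reason == "length_diff"
        assert isinstance(length_filters(_trimmed(100, 105), PANEL), TrimmedPair)


class TestMergePair:
    def test_lossless_reconstruction_of_fragment(self):
        rng = np.random.default_rng(5)
        frag = "".join(rng.choice(list("ACGT"), size=180))
        t = _trimmed(0, 0, s1=frag, s2=revcomp(frag))
        assert merge_pair(t) == frag

    def test_partial_overlap_reconstruction(self):
        rng = np.random.default_rng(6)
        frag = "".join(rng.choice(list("ACGT"), size=300))
        t = _trimmed(0, 0, s1=frag[:200], s2=revcomp(frag[100:]))
        assert merge_pair(t) == frag

    def test_disagreement_resolved_by_higher_phred(self):
        rng = np.random.default_rng(20)
        frag = "".join(rng.choice(list("ACGT"), size=80))
        r1 = frag[:60]
        r2rc = frag[20:]
        # conflicting base in r1 inside the overlap, r2 carries the truth
        r1 = r1[:40] + ("T" if frag[40] != "T" else "A") + r1[41:]
        t = _trimmed(0, 0, s1=r1, s2=revcomp(r2rc), q1=[20] * 60, q2=[40] * 60)
        assert merge_pair(t) == frag

    def test_tie_quality_prefers_r1(self):
        rng = np.random.default_rng(21)
        frag = "".join(rng.choice(list("ACGT"), size=80))
        mutated = frag[:40] + ("T" if frag[40] != "T" else "A") + frag[41:60]
        t = _trimmed(0, 0, s1=mutated, s2=revcomp(frag[20:]), q1=[30] * 60, q2=[30] * 60)
        out = merge_pair(t)
        assert out[40] == mutated[40]

    def test_unrelated_inserts_rejected(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = "".join(rng.choice(list("ACGT"), size=100))
        out = merge_pair(_trimmed(0, 0, s1=a, s2=b))
        assert isinstance(out, Rejection) and out.reason == "no_overlap"

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_round_trip_over_random_fragments(self, seed):
        """Error-free pairs simulated from random 60–400 bp fragments with
        250 bp reads merge back to the exact fragment."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 401))
        frag = "".join(rng.choice(list("ACGT"), size=n))
        t = _trimmed(0, 0, s1=frag[:250], s2=revcomp(frag)[:250])
        assert merge_pair(t) == frag


class TestDereplicate:
    def test_counts_per_unique_sequence(self):
        items = [("a", "s1", "ACGT")] * 5 + [("a", "s1", "GGGG")] * 2
        out = dereplicate(items)
        assert {(m.seq, m.total_reads) for m in out} == {("ACGT", 5), ("GGGG", 2)}

    def test_same_sequence_two_samples_one_record(self):
        out = dereplicate([("a", "s1", "ACGT"), ("a", "s2", "ACGT")])
        assert len(out) == 1 and out[0].counts == {"s1": 1, "s2": 1}

    def test_distinct_assays_not_collapsed(self):
        out = dereplicate([("a", "s1", "ACGT"), ("b", "s1", "ACGT")])
        assert len(out) == 2

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["a", "b"]),
                st.sampled_from(["s1", "s2", "s3"]),
                st.sampled_from(["AAAA", "CCCC", "GGGG"]),
            ),
            max_size=40,
        )
    )
    def test_conservation_and_order_invariance(self, items):
        out = dereplicate(items)
        assert sum(m.total_reads for m in out) == len(items)
        shuffled = dereplicate(items[::-1])
        assert [(m.assay, m.seq, m.counts) for m in out] == [
            (m.assay, m.seq, m.counts) for m in shuffled
        ]


def test_pipeline_read_conservation(sheet):
    """assigned + every rejection reason + merged equals the input count."""
    rng = np.random.default_rng(9)
    pairs = []
    for i in range(60):
        insert = "".join(rng.choice(list("ACGT"), size=70))
        idx = ["ACACAC", "GTGTGT", "NNNNNN"][i % 3]
        pairs.append(_reads_from_fragment(F.seq + insert + revcomp(R.seq), rid=f"r{i}", idx=idx))
    pairs.append(_pair(rid="junk"))  # no primer
    res = process_pairs(pairs, sheet, PANEL)
    t = res.tallies
    rejected = sum(v for k, v in t.items() if ":" in k)
    assert t["input_pairs"] == len(pairs)
    assert rejected + t["merged_reads"] == t["input_pairs"]
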