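"""Adapter clipping, the filtering cascade and collapsed-library invariants."""

import collections

import pytest
from hypothesis import given, settings, strategies as st

from srnatlas import seqio
from srnatlas.seqio import (
    CollapsedLibrary,
    RawRead,
    abundance_filter,
    clip_adapter,
    collapse,
    length_filter,
    length_histogram,
)

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestClipAdapter:
    def test_full_adapter_after_insert_is_removed(self):
        insert = "ACGTACGTACGTACGTACGTAC"
        read, found = clip_adapter(RawRead("r", insert + ADAPTER), ADAPTER)
        assert found and read.sequence == insert

    def test_read_without_adapter_is_unchanged(self):
        read, found = clip_adapter(RawRead("r", "AAAATTTTCCCCGGGGAAAA"), ADAPTER)
        assert not found and read.sequence == "AAAATTTTCCCCGGGGAAAA"

    def test_short_gc_insert_yields_short_read_for_length_filter(self):
        # 7-nt GC-rich inserts form a second spectrum peak that the >15 nt
        # filter must remove downstream
        insert = "GCGGCCG"
        machine = (insert + ADAPTER + "ACACACAC")[:36]
        read, found = clip_adapter(RawRead("r", machine), ADAPTER)
        assert found and read.sequence == insert
        assert len(read) <= 15

    def test_truncated_adapter_at_three_prime_end(self):
        insert = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30 nt; only 6 adapter bases fit
        machine = (insert + ADAPTER)[:36]
        read, found = clip_adapter(RawRead("r", machine), ADAPTER, min_overlap=6)
        assert found and read.sequence == insert

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            clip_adapter(RawRead("r", "ACGT"), "")

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            RawRead("r", "")

    @given(insert=st.text(alphabet="AT", min_size=16, max_size=30))
    @settings(derandomize=True, max_examples=50)
    def test_idempotent_when_adapter_absent_from_insert(self, insert):
        # the adapter is GC-seeded so AT-only inserts can never contain it
        once, found = clip_adapter(RawRead("r", insert + ADAPTER), ADAPTER)
        assert found
        twice, found_again = clip_adapter(once, ADAPTER)
        assert twice.sequence == once.sequence and not found_again


class TestLengthFilter:
    def test_boundary_is_strict(self):
        lib = collapse(["A" * 15] * 5 + ["C" * 16] * 5)
        kept = length_filter(lib, 15)
        assert kept.entries == {"C" * 16: 5}

    def test_empty_input(self):
        assert length_filter(collapse([]), 15).entries == {}

    def test_min_len_zero_is_identity(self):
        lib = collapse(["ACGT", "AC"])
        assert length_filter(lib, 0).entries == lib.entries


class TestCollapse:
    def test_multiplicities(self):
        lib = collapse(["AAAC", "AAAC", "GGGT"])
        assert lib.entries == {"AAAC": 2, "GGGT": 1}

    def test_empty(self):
        assert collapse([]).entries == {} and collapse([]).total_raw == 0

    def test_single_sequence_many_copies(self):
        lib = collapse(["ACGTACGT"] * 10)
        assert lib.entries == {"ACGTACGT": 10}

    @given(st.lists(dna, max_size=60))
    @settings(derandomize=True, max_examples=60)
    def test_collapse_expand_is_multiset_identity(self, reads):
        lib = collapse(reads)
        assert collections.Counter(lib.expand()) == collections.Counter(reads)

    @given(st.lists(dna, max_size=40))
    @settings(derandomize=True, max_examples=40)
    def test_order_independent(self, reads):
        assert collapse(reads).entries == collapse(list(reversed(reads))).entries


class TestAbundanceFilter:
    def test_boundary_keeps_at_least_min_count(self):
        lib = CollapsedLibrary({"AAAA": 2, "CCCC": 3, "GGGG": 100}, 105)
        out, summary = abundance_filter(lib, 3)
        assert out.entries == {"CCCC": 3, "GGGG": 100}
        assert summary["retained_read_fraction"] == pytest.approx(103 / 105)

    def test_min_count_one_is_identity(self):
        lib = CollapsedLibrary({"AAAA": 1, "CCCC": 5}, 6)
        out, _ = abundance_filter(lib, 1)
        assert out.entries == lib.entries

    def test_retained_fraction_matches_spectrum_sum(self):
        # known count spectrum: brute-force expectation over the spectrum
        spectrum = {1: 50, 2: 20, 3: 10, 5: 4, 100: 1}  # count -> n tags

        def tag(i):  # deterministic unique DNA tags
            s = ""
            for _ in range(10):
                s += "ACGT"[i % 4]
                i //= 4
            return s
        entries = {}
        i = 0
        for count, n in spectrum.items():
            for _ in range(n):
                entries[tag(i) + tag(i + 7)] = count
                i += 1
        total = sum(entries.values())
        lib = CollapsedLibrary(entries, total)
        out, summary = abundance_filter(lib, 3)
        expected_reads = sum(c * n for c, n in spectrum.items() if c >= 3)
        assert summary["retained_unique"] == sum(n for c, n in spectrum.items() if c >= 3)
        assert summary["retained_read_fraction"] == pytest.approx(expected_reads / total)

    @given(st.dictionaries(dna, st.integers(1, 50), max_size=30))
    @settings(derandomize=True, max_examples=40)
    def test_retained_fraction_nonincreasing_in_min_count(self, entries):
        if not entries:
            return
        lib = CollapsedLibrary(dict(entries), sum(entries.values()))
        fracs = [abundance_filter(lib, k)[1]["retained_read_fraction"] for k in (1, 2, 3, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(fracs, fracs[1:]))


class TestLengthHistogram:
    def test_read_weighted_counts_and_mean(self):
        lib = CollapsedLibrary({"A" * 22: 3, "C" * 28: 1}, 4)
        hist, mean = length_histogram(lib)
        assert hist == {22: 3, 28: 1}
        assert mean == pytest.approx(23.5)

    def test_single_sequence(self):
        hist, mean = length_histogram(CollapsedLibrary({"ACGTACGT": 1}, 1))
        assert hist == {8: 1} and mean == 8.0

    def test_bimodal_spectrum_from_planted_mixture(self):
        lib = collapse(["A" * 22] * 90 + ["C" * 29] * 10)
        hist, mean = length_histogram(lib)
        assert max(hist, key=hist.get) == 22
        assert hist[29] == 10
        assert mean == pytest.approx(0.9 * 22 + 0.1 * 29)


class TestFileRoundtrips:
    def test_fastq_roundtrip(self, tmp_path):
        reads = [RawRead("a", "ACGT", "IIII"), RawRead("b", "GGGTTT", "IIIIII")]
        seqio.write_fastq(reads, tmp_path / "x.fastq")
        back = list(seqio.read_fastq(tmp_path / "x.fastq"))
        assert [(r.id, r.sequence, r.quality) for r in back] == [
            (r.id, r.sequence, r.quality) for r in reads
        ]

    def test_library_tsv_roundtrip(self, tmp_path):
        lib = collapse(["ACGTACGTACGTACGT"] * 4 + ["TTTTCCCCAAAAGGGG"] * 2)
        seqio.write_library_tsv(lib, tmp_path / "lib.tsv")
        back = seqio.read_library_tsv(tmp_path / "lib.tsv")
        assert back.entries == lib.entries

    def test_library_fasta_headers_carry_counts(self, tmp_path):
        lib = collapse(["ACGTACGTACGTACGT"] * 4 + ["TTTTCCCCAAAAGGGG"] * 2)
        seqio.write_library_fasta(lib, tmp_path / "lib.fasta")
        headers = [l[1:].strip() for l in open(tmp_path / "lib.fasta") if l.startswith(">")]
        assert headers == ["tag1_x4", "tag2_x2"]
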