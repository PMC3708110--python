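"""Interval calling, candidate filtering, star evidence, orthologs, families."""

import dataclasses

from srnatlas.align import Placement
from srnatlas.discover import (
    DiscoveryParams,
    ExpressedInterval,
    assign_families,
    call_intervals,
    detect_star_support,
    filter_candidates,
    find_orthologs,
)
from srnatlas.evaluation import novel_discovery_metrics
from srnatlas.fold import fold_hairpin


def _pl(start, end, strand="+", chrom="chr1", tag="", mm=0):
    return Placement(chrom, start, end, strand, mm, tag or "A" * (end - start), "genome")


class TestCallIntervals:
    def test_overlapping_same_strand_merge(self):
        pls = {"a": [_pl(100, 122, tag="a" * 22)], "b": [_pl(112, 134, tag="b" * 22)]}
        ivs = call_intervals(pls, {"a": 5, "b": 3})
        assert len(ivs) == 1
        assert (ivs[0].start, ivs[0].end, ivs[0].read_support) == (100, 134, 8)

    def test_opposite_strands_stay_separate(self):
        pls = {"a": [_pl(100, 122, "+")], "b": [_pl(100, 122, "-")]}
        ivs = call_intervals(pls, {"a": 5, "b": 3})
        assert len(ivs) == 2 and {iv.strand for iv in ivs} == {"+", "-"}

    def test_gap_beyond_merge_gap_splits(self):
        pls = {"a": [_pl(100, 122)], "b": [_pl(140, 162)]}
        assert len(call_intervals(pls, {"a": 1, "b": 1}, merge_gap=10)) == 2
        assert len(call_intervals(pls, {"a": 1, "b": 1}, merge_gap=20)) == 1

    def test_dominant_tag_is_highest_count(self):
        low, high = "A" * 22, "C" * 22
        pls = {low: [_pl(100, 122, tag=low)], high: [_pl(105, 127, tag=high)]}
        iv = call_intervals(pls, {low: 2, high: 9})[0]
        assert iv.dominant_tag == high and iv.dominant_start == 105


def _iv(support=150, length=22):
    return ExpressedInterval("chr1", 1000, 1000 + length, "+", support, "A" * length, 1000)


def _good_fold():
    m = "TAGCTTATCAGACTGATGTTGA"
    from srnatlas.seqio import revcomp

    return fold_hairpin("GG" + m + "TTCAAGTTAACG" + revcomp(m) + "CA"), (2, 24)


class TestFilterCandidates:
    def test_all_criteria_met_passes(self):
        fold, span = _good_fold()
        ok, trace = filter_candidates(_iv(), fold, span)
        assert ok and all(trace.values())

    def test_low_support_fails_only_read_support(self):
        fold, span = _good_fold()
        ok, trace = filter_candidates(_iv(support=50), fold, span)
        assert not ok and not trace["read_support"]
        assert all(v for k, v in trace.items() if k != "read_support")

    def test_sno_like_length_fails_length(self):
        fold, span = _good_fold()
        ok, trace = filter_candidates(_iv(length=28), fold, span)
        assert not ok and not trace["length"]

    def test_weak_fold_fails_structure(self):
        weak = fold_hairpin("A" * 60)
        ok, trace = filter_candidates(_iv(), weak, (10, 32))
        assert not ok and not trace["mfe"] and not trace["arm_pairing"]

    def test_monotone_in_thresholds(self):
        # weakening any threshold never turns a pass into a fail
        fold, span = _good_fold()
        base = DiscoveryParams()
        ok, _ = filter_candidates(_iv(support=120), fold, span, base)
        assert ok
        for weaker in (
            dataclasses.replace(base, min_reads=10),
            dataclasses.replace(base, min_len=18, max_len=30),
            dataclasses.replace(base, mfe_threshold=-5.0),
            dataclasses.replace(base, pairing_fraction=0.2),
        ):
            still_ok, _ = filter_candidates(_iv(support=120), fold, span, weaker)
            assert still_ok


class TestStarSupport:
    def test_star_positioned_reads_counted(self):
        fold, (ms, me) = _good_fold()
        s5 = fold.partner[me - 3]
        assert detect_star_support(fold, (ms, me), [(s5, 7), (s5 + 1, 2)]) == 9

    def test_mature_only_reads_give_zero(self):
        fold, span = _good_fold()
        assert detect_star_support(fold, span, [(span[0], 100)]) == 0

    def test_loop_reads_do_not_count(self):
        fold, (ms, me) = _good_fold()
        assert detect_star_support(fold, (ms, me), [(me + 2, 50)]) == 0


class TestOrthologs:
    foreign = {"hsa-mir-f": "TAGCTTATCAGACTGATGTTGA"}
    native = {"bta-mir-n": "ACCCTGTAGATCCGAATTTGTG"}

    def test_foreign_only_tag_is_called(self):
        calls = find_orthologs({self.foreign["hsa-mir-f"]: 40}, self.foreign, self.native)
        assert calls == {"hsa-mir-f": [(self.foreign["hsa-mir-f"], 40)]}

    def test_native_matching_tag_excluded(self):
        calls = find_orthologs({self.native["bta-mir-n"]: 40}, self.foreign, self.native)
        assert calls == {}

    def test_seed_mismatch_blocks_call(self):
        t = self.foreign["hsa-mir-f"]
        seed_mut = t[:3] + ("A" if t[3] != "A" else "C") + t[4:]
        assert find_orthologs({seed_mut: 10}, self.foreign, self.native) == {}

    def test_two_tail_mismatches_allowed(self):
        t = self.foreign["hsa-mir-f"]
        mut = t[:-2] + ("AA" if t[-2:] != "AA" else "CC")
        calls = find_orthologs({mut: 10}, self.foreign, self.native, max_mismatch=2)
        assert "hsa-mir-f" in calls


class TestFamilies:
    def test_same_seed_same_family(self):
        fams = assign_families({"a": "TAGCTTATCAGACTGATGTTGA", "b": "AAGCTTATCCCCCTGATGTTGA"})
        assert fams["a"] == fams["b"]

    def test_one_seed_substitution_splits(self):
        fams = assign_families({"a": "TAGCTTATCAGACTGATGTTGA", "b": "TAGCTTTTCAGACTGATGTTGA"})
        assert fams["a"] != fams["b"]

    def test_planted_family_recovered(self, study):
        man = study.manifest
        members = [m["name"] for m in man.mirnas if m["mature"][1:8] == man.mirnas[20]["mature"][1:8]]
        members += [n["name"] for n in man.novels if n["mature"][1:8] == man.mirnas[20]["mature"][1:8]]
        assert len(members) == 4  # three known + one novel planted with a shared seed
        seqs = {m["name"]: m["mature"] for m in man.mirnas}
        seqs |= {n["name"]: n["mature"] for n in man.novels}
        fams = assign_families(seqs)
        labels = {fams[m] for m in members}
        assert len(labels) == 1


class TestEndToEndDiscovery:
    def test_planted_hairpins_found_and_decoys_rejected(self, study):
        metrics = novel_discovery_metrics(study.manifest, study.result)
        assert metrics["n_recovered"] == metrics["n_planted"] == 3
        assert metrics["n_decoy_passes"] == 0
        assert metrics["n_other_passes"] == 0

    def test_star_supported_tier_for_planted_star_hairpins(self, study):
        passed = [c for c in study.result.candidates if c.passed]
        tiers = sorted(c.tier for c in passed)
        assert tiers.count("star_supported") == 2  # two planted with star reads
        assert tiers.count("structure_only") == 1

    def test_foreign_mature_recovered_as_ortholog(self, study):
        assert set(study.result.orthologs) == {"hsa-syn-mir-901"}
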