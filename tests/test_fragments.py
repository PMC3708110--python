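"""snoRNA/tRNA-derived fragment profiling: arms, dominance, clusters."""

import pytest

from srnatlas.align import Placement
from srnatlas.fragments import (
    FragmentRecord,
    cluster_report,
    dominant_fragment,
    profile_host_fragments,
    trna_family_totals,
)
from srnatlas.refcat import NcRNAAnnotation, ReferenceCatalog, load_references


def _catalog(host_len=70):
    genome = {"chr2": "ACGT" * 200}
    anns = [
        NcRNAAnnotation("sno-1", "snoRNA", "chr2", 100, 100 + host_len, "+"),
        NcRNAAnnotation("trna-a", "tRNA", "chr2", 300, 372, "+"),
        NcRNAAnnotation("trna-b", "tRNA", "chr2", 400, 472, "+"),
    ]
    cat = ReferenceCatalog(genome, {}, {}, anns, {"trna-a": "Gly-GCC", "trna-b": "Gly-GCC"})
    return cat


def _pl(host, start, end, tag=None, mm=0):
    return Placement(host, start, end, "+", mm, tag or "A" * (end - start), "reference")


class TestArms:
    def test_five_prime_start_in_first_quarter(self):
        recs = profile_host_fragments({"x": [_pl("sno-1", 0, 28, "x")]}, {"x": 5}, _catalog())
        assert recs[0].arm == "five_prime" and recs[0].length == 28

    def test_three_prime_end_in_last_quarter(self):
        recs = profile_host_fragments({"x": [_pl("sno-1", 42, 70)]}, {"x": 5}, _catalog())
        assert recs[0].arm == "three_prime"

    def test_middle_is_internal(self):
        recs = profile_host_fragments({"x": [_pl("sno-1", 25, 47)]}, {"x": 5}, _catalog())
        assert recs[0].arm == "internal"

    def test_full_length_flagged_degenerate(self):
        recs = profile_host_fragments({"x": [_pl("sno-1", 0, 70)]}, {"x": 2}, _catalog())
        assert recs[0].arm == "internal" and recs[0].full_length

    def test_arm_invariant_under_symmetric_padding(self):
        # same fragment relative position, host annotation padded both sides
        short = profile_host_fragments({"x": [_pl("sno-1", 0, 28)]}, {"x": 1}, _catalog(70))
        padded_cat = _catalog(70)
        # padding the host by 10 nt each side shifts the fragment by 10
        recs = profile_host_fragments({"x": [_pl("sno-1", 10, 38)]}, {"x": 1}, _catalog(90))
        assert short[0].arm == recs[0].arm == "five_prime"


class TestDominance:
    def test_highest_count_wins(self):
        recs = [
            FragmentRecord("h", "snoRNA", "A" * 28, 40, 68, "three_prime", 101948),
            FragmentRecord("h", "snoRNA", "C" * 26, 0, 26, "five_prime", 230),
        ]
        assert dominant_fragment(recs, "h").count == 101948

    def test_tie_broken_by_length_then_sequence(self):
        recs = [
            FragmentRecord("h", "snoRNA", "AAA", 0, 3, "five_prime", 5),
            FragmentRecord("h", "snoRNA", "CCCC", 0, 4, "five_prime", 5),
            FragmentRecord("h", "snoRNA", "GGGG", 10, 14, "internal", 5),
        ]
        dom = dominant_fragment(recs, "h")
        assert dom.fragment == "CCCC"  # longest; lexicographic among equals

    def test_single_fragment_is_its_own_dominant(self):
        recs = [FragmentRecord("h", "snoRNA", "AAAA", 0, 4, "five_prime", 1)]
        assert dominant_fragment(recs, "h") is recs[0]

    def test_unknown_host_raises(self):
        with pytest.raises(KeyError):
            dominant_fragment([], "nope")


class TestClusterReport:
    def test_zero_read_member_has_row(self):
        recs = [FragmentRecord("m1", "snoRNA", "AAAA", 0, 4, "five_prime", 9)]
        frame = cluster_report(recs, ["m1", "m2"])
        assert list(frame["host"]) == ["m1", "m2"]
        assert frame.loc[1, "total_reads"] == 0 and frame.loc[1, "dominant_fragment"] == ""

    def test_planted_cluster_fully_covered(self, study):
        members = [s["name"] for s in study.manifest.snorna_cluster]
        frame = cluster_report(study.result.fragment_records, members)
        assert (frame["total_reads"] > 0).all()
        # the first member carries the dominant product on its 3' arm
        assert "three_prime" in frame.loc[0, "arms"]

    def test_dominant_sno_product_matches_planted(self, study):
        man = study.manifest
        s0 = man.snorna_cluster[0]
        fr = max(s0["fragments"], key=lambda f: f["weight"])
        planted = s0["sequence"][fr["start"] : fr["end"]]
        dom = dominant_fragment(study.result.fragment_records, s0["name"])
        assert dom.fragment == planted and dom.arm == "three_prime"


class TestTRNAFamilies:
    def test_multi_copy_tag_counted_once_per_family(self):
        cat = _catalog()
        frag = "A" * 30
        pls = {"t": [_pl("trna-a", 0, 30, frag), _pl("trna-b", 0, 30, frag)]}
        recs = profile_host_fragments(pls, {"t": 36604}, cat)
        frame = trna_family_totals(recs, cat)
        row = frame[frame["family"] == "Gly-GCC"].iloc[0]
        assert row["total_reads"] == 36604  # not doubled
        assert row["n_genes"] == 2
        assert "five_prime" in row["arms"]

    def test_planted_nine_gene_family_recovered(self, study):
        catalog = load_references(
            study.paths["matures"], study.paths["gff"], study.paths["genome"], study.paths["trna_bed"]
        )
        frame = trna_family_totals(study.result.fragment_records, catalog)
        row = frame[frame["family"] == "Gly-GCC"].iloc[0]
        assert row["n_genes"] == 9
        assert row["arms"] == "five_prime"


class TestConservation:
    def test_fragment_counts_bounded_by_host_reads(self):
        cat = _catalog()
        pls = {
            "x": [_pl("sno-1", 0, 28)],
            "y": [_pl("sno-1", 40, 68)],
        }
        recs = profile_host_fragments(pls, {"x": 10, "y": 7}, cat)
        assert sum(r.count for r in recs if r.host_id == "sno-1") == 17
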