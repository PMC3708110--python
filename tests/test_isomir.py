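"""isomiR offsets and classes, star-arm ratios, positional variants."""

import pytest

from srnatlas.align import map_tags
from srnatlas.fold import fold_hairpin
from srnatlas.isomir import (
    ArmProfile,
    IsomiRRecord,
    arm_ratio,
    assign_isomirs,
    expected_star_start,
    infer_star_interval,
    variant_profile,
)
from srnatlas.refcat import Hairpin, MatureMiRNA, ReferenceCatalog
from srnatlas.seqio import revcomp


@pytest.fixture(scope="module")
def mir_catalog():
    """One hairpin with a 22-nt mature on the 5' arm."""
    mature = "TAGCTTATCAGACTGATGTTGA"
    prec = "GG" + mature + "TTCAAGTTAACG" + revcomp(mature) + "CA"
    hp = Hairpin("mir-t", prec, "chr1", 0, len(prec), "+",
                 {"5p": ("mir-t", 2, 2 + len(mature))})
    mat = MatureMiRNA("mir-t", mature, ["mir-t"], ["mir-t"], "5p")
    cat = ReferenceCatalog({"chr1": prec}, {"mir-t": mat}, {"mir-t": hp}, [])
    return cat, mature, prec


def _assign(cat, prec, tags_counts, window=5):
    placements = map_tags(list(tags_counts), {"mir-t": prec}, 1)
    return assign_isomirs(placements, tags_counts, cat, window)


class TestOffsets:
    def test_exact_mature_is_mature_mature(self, mir_catalog):
        cat, mature, prec = mir_catalog
        prof = _assign(cat, prec, {mature: 10})["mir-t"]
        r = prof.isomirs[0]
        assert (r.offset5, r.offset3, r.class5, r.class3, r.arm) == (0, 0, "mature", "mature", "mature")

    def test_one_shorter_at_three_prime_is_sub(self, mir_catalog):
        cat, mature, prec = mir_catalog
        prof = _assign(cat, prec, {mature[:-1]: 5})["mir-t"]
        r = prof.isomirs[0]
        assert (r.offset5, r.offset3, r.class3) == (0, -1, "sub")

    def test_shifted_five_prime_start(self, mir_catalog):
        cat, mature, prec = mir_catalog
        shorter = prec[3 : 2 + len(mature)]  # starts one base into the mature
        longer = prec[1 : 2 + len(mature)]  # starts one base upstream
        profs = _assign(cat, prec, {shorter: 3, longer: 2})
        recs = {r.tag: r for r in profs["mir-t"].isomirs}
        assert recs[shorter].offset5 == -1 and recs[shorter].class5 == "sub"
        assert recs[longer].offset5 == 1 and recs[longer].class5 == "super"

    def test_antisymmetry_sub_super_swap(self):
        for off in (-3, -1, 1, 3):
            a = IsomiRRecord("m", "A" * 20, off, 0, "mature", 1)
            b = IsomiRRecord("m", "A" * 20, -off, 0, "mature", 1)
            assert {a.class5, b.class5} == {"sub", "super"}

    def test_tag_outside_window_is_unassigned(self, mir_catalog):
        cat, mature, prec = mir_catalog
        loop_tag = prec[26:46]  # 5' end 24 nt past the mature boundary
        profs = _assign(cat, prec, {loop_tag: 4})
        assert all(loop_tag not in {r.tag for r in p.isomirs} for p in profs.values())

    def test_counts_conserved_per_mature(self, mir_catalog):
        cat, mature, prec = mir_catalog
        counts = {mature: 10, mature[:-1]: 7, prec[1 : 2 + len(mature)]: 3}
        prof = _assign(cat, prec, counts)["mir-t"]
        assert sum(r.count for r in prof.isomirs) == 20


class TestStarArm:
    def test_star_read_attributed_to_star_arm(self, mir_catalog):
        cat, mature, prec = mir_catalog
        fold = fold_hairpin(prec)
        star_iv = infer_star_interval(cat.hairpins["mir-t"], 2, 24, fold)
        assert star_iv is not None
        star_tag = prec[star_iv[0] : star_iv[1]]
        prof = _assign(cat, prec, {mature: 100, star_tag: 4})["mir-t"]
        assert prof.mature_count == 100 and prof.star_count == 4

    def test_expected_star_geometry_on_perfect_stem(self, mir_catalog):
        cat, mature, prec = mir_catalog
        fold = fold_hairpin(prec)
        s5 = expected_star_start(fold, 2, 24)
        # duplex partner of mature_end-3 on a fully paired stem
        assert s5 == fold.partner[24 - 3]


class TestArmRatio:
    def test_extremely_specific_processing(self):
        prof = ArmProfile("mir-21-like", [
            IsomiRRecord("mir-21-like", "A" * 22, 0, 0, "mature", 2318344),
            IsomiRRecord("mir-21-like", "C" * 22, 0, 0, "star", 27),
        ])
        assert arm_ratio(prof) == pytest.approx(27 / (2318344 + 27))
        assert arm_ratio(prof) == pytest.approx(1.165e-5, rel=1e-3)

    def test_less_extreme_star(self):
        prof = ArmProfile("mir-126-like", [
            IsomiRRecord("m", "A" * 22, 0, 0, "mature", 1014272),
            IsomiRRecord("m", "C" * 22, 0, 0, "star", 83798),
        ])
        assert arm_ratio(prof) == pytest.approx(0.0763, abs=2e-4)

    def test_star_only(self):
        prof = ArmProfile("m", [IsomiRRecord("m", "A" * 22, 0, 0, "star", 5)])
        assert arm_ratio(prof) == 1.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            arm_ratio(ArmProfile("m", []))


class TestVariantProfile:
    def test_three_percent_a_to_g(self):
        ref = "TTTTTATTTTTTTTTTTTTTTT"  # single A at position 5
        reads = [
            IsomiRRecord("m", ref, 0, 0, "mature", 97),
            IsomiRRecord("m", ref[:5] + "G" + ref[6:], 0, 0, "mature", 3),
        ]
        frame, a_to_g = variant_profile(reads, ref)
        assert a_to_g == {5: pytest.approx(0.03)}

    def test_identical_reads_have_zero_variants(self):
        ref = "ACGTACGTACGTACGTACGTAC"
        frame, a_to_g = variant_profile([IsomiRRecord("m", ref, 0, 0, "mature", 50)], ref)
        assert all(v == 0.0 for v in a_to_g.values())
        for pos, base in enumerate(ref):
            assert frame.loc[pos, base] == 50

    def test_offset_tags_align_to_mature_coordinates(self):
        ref = "AACCGGTTAACCGGTTAACCGG"
        shifted = ref[1:]  # offset5 = -1
        frame, _ = variant_profile([IsomiRRecord("m", shifted, -1, 0, "mature", 4)], ref)
        assert frame.loc[0, ["A", "C", "G", "T"]].sum() == 0  # position 0 uncovered
        assert frame.loc[1, ref[1]] == 4
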