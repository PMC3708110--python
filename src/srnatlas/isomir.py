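"""isomiR enumeration, star-arm accounting and positional variant profiling.

An isomiR is a tag whose 5'/3' ends deviate from the canonical miRBase
mature by small offsets.  Offsets are signed with negative meaning the tag
is *shorter* at that end: a tag one base short at the 3' end has
``offset3 = -1`` (class "sub"); one base longer is ``+1`` ("super"); zero
is "mature".  A tag is attributed to the arm (mature or star) whose
annotated 5' boundary lies within ``offset_window`` of the tag's 5' end,
nearest boundary winning ties.  Star arms missing from the catalog (most
non-model-organism entries) are inferred from the precursor's MFE fold
using standard duplex geometry (2-nt 3' overhangs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import Placement
from .fold import HairpinFold, fold_hairpin
from .refcat import Hairpin, ReferenceCatalog

__all__ = [
    "IsomiRRecord",
    "ArmProfile",
    "assign_isomirs",
    "arm_ratio",
    "variant_profile",
    "infer_star_interval",
    "expected_star_start",
]


def _offset_class(offset: int) -> str:
    if offset == 0:
        return "mature"
    return "sub" if offset < 0 else "super"


@dataclass(frozen=True)
class IsomiRRecord:
    mature_name: str
    tag: str
    offset5: int  # negative = shorter at the 5' end
    offset3: int  # negative = shorter at the 3' end
    arm: str  # "mature" | "star"
    count: int
    mismatches: int = 0
    nontemplated_3p: bool = False

    @property
    def class5(self) -> str:
        return _offset_class(self.offset5)

    @property
    def class3(self) -> str:
        return _offset_class(self.offset3)


@dataclass
class ArmProfile:
    """All reads attributed to one mature miRNA, split by arm."""

    mature_name: str
    isomirs: list[IsomiRRecord] = field(default_factory=list)

    @property
    def mature_count(self) -> int:
        return sum(r.count for r in self.isomirs if r.arm == "mature")

    @property
    def star_count(self) -> int:
        return sum(r.count for r in self.isomirs if r.arm == "star")


def arm_ratio(profile: ArmProfile) -> float:
    """Star fraction: star / (mature + star)."""
    total = profile.mature_count + profile.star_count
    if total == 0:
        raise ValueError(f"{profile.mature_name}: no reads on either arm")
    return profile.star_count / total


# ---------------------------------------------------------------------------
# star-arm inference from the precursor fold


def expected_star_start(fold: HairpinFold, mature_start: int, mature_end: int) -> int | None:
    """5' start of the star under 2-nt 3'-overhang duplex geometry.

    The star's 5' end pairs with the base two inside the mature's 3' end,
    i.e. position ``mature_end - 3``; nearby paired bases are consulted
    when that base itself is unpaired in the MFE structure.
    """
    part = fold.partner
    for probe in (mature_end - 3, mature_end - 4, mature_end - 2, mature_end - 5, mature_end - 1):
        if probe in part:
            j = part[probe]
            if j < mature_start or j >= mature_end:
                # antiparallel pairing: partner index drops as probe advances
                return j - (mature_end - 3 - probe)
    return None


def infer_star_interval(
    hairpin: Hairpin, mature_start: int, mature_end: int, fold: HairpinFold | None = None
) -> tuple[int, int] | None:
    """Infer the star interval on the arm opposite [mature_start, mature_end)."""
    fold = fold or fold_hairpin(hairpin.sequence)
    s5 = expected_star_start(fold, mature_start, mature_end)
    if s5 is None:
        return None
    length = mature_end - mature_start
    start = max(0, s5)
    end = min(start + length, len(hairpin.sequence))
    if end - start < 8 or (start < mature_end and end > mature_start):
        return None
    return start, end


# ---------------------------------------------------------------------------
# isomiR assignment


def assign_isomirs(
    placements_by_tag: Mapping[str, list[Placement]],
    counts: Mapping[str, int],
    catalog: ReferenceCatalog,
    offset_window: int = 5,
    folds: dict[str, HairpinFold] | None = None,
) -> dict[str, ArmProfile]:
    """Attribute hairpin-placed tags to mature/star arms as isomiR records.

    ``placements_by_tag`` must hold placements on precursor sequences.  A
    tag whose 5' end lies within ``offset_window`` of an arm's annotated
    (or inferred) 5' boundary is assigned to that arm of that mature, the
    nearest boundary winning; a tag outside every window is left out (loop
    or flank fragments).  Offsets for star-arm records are computed against
    the star interval.
    """
    folds = folds if folds is not None else {}
    # arm anchor table per hairpin: (mature_name, arm_label, start, end)
    anchors: dict[str, list[tuple[str, str, int, int]]] = {}
    for hid, hp in catalog.hairpins.items():
        rows: list[tuple[str, str, int, int]] = []
        named_arms = list(hp.mature_intervals.items())
        for arm, (name, s, e) in named_arms:
            rows.append((name, "mature", s, e))
        if len(named_arms) == 1:
            # opposite arm unannotated: infer the star from the fold
            (_, (name, s, e)) = named_arms[0][0], named_arms[0][1]
            if hid not in folds:
                folds[hid] = fold_hairpin(hp.sequence)
            star = infer_star_interval(hp, s, e, folds[hid])
            if star is not None:
                rows.append((name, "star", star[0], star[1]))
        elif len(named_arms) == 2:
            # both arms annotated: the heavier-named convention does not
            # apply here; treat each annotated arm as its own mature
            pass
        anchors[hid] = rows

    profiles: dict[str, ArmProfile] = {}
    for tag, pls in placements_by_tag.items():
        if not pls:
            continue
        # candidate arms across all best-stratum hairpin placements
        best: tuple[int, int, str, str] | None = None  # (|d5|, mm, name, ...) for tie-break
        chosen = None
        for p in pls:
            for name, arm, s, e in anchors.get(p.target_id, []):
                d5 = p.start - s
                if abs(d5) > offset_window:
                    continue
                key = (abs(d5), p.mismatches, name, arm)
                if best is None or key < best:
                    best = key
                    chosen = (name, arm, p, s, e)
        if chosen is None:
            continue
        name, arm, p, s, e = chosen
        offset5 = s - p.start
        offset3 = p.end - e
        hp_seq = catalog.hairpins[p.target_id].sequence
        # non-templated 3' addition: a super-3' tag whose added base(s)
        # mismatch the precursor template
        nta = False
        if offset3 > 0 and p.mismatches > 0:
            tail = tag[-offset3:]
            templ = hp_seq[p.end - offset3 : p.end]
            nta = tail != templ
        rec = IsomiRRecord(name, tag, offset5, offset3, arm, counts.get(tag, 0), p.mismatches, nta)
        profiles.setdefault(name, ArmProfile(name)).isomirs.append(rec)
    for prof in profiles.values():
        prof.isomirs.sort(key=lambda r: (-r.count, r.tag))
    return profiles


def variant_profile(
    records: Iterable[IsomiRRecord], reference_mature: str
) -> tuple[pd.DataFrame, dict[int, float]]:
    """Read-weighted per-position base counts over the mature interval.

    Only mature-arm records are tallied, each tag aligned to the mature by
    its 5' offset.  Returns the count matrix (positions x A/C/G/T) and, for
    every reference-A position, the G fraction (candidate A-to-I editing).
    """
    ref = reference_mature.upper().replace("U", "T")
    bases = "ACGT"
    mat = np.zeros((len(ref), 4), dtype=np.int64)
    for r in records:
        if r.arm != "mature":
            continue
        for k, c in enumerate(r.tag):
            pos = k - r.offset5  # tag position k sits at mature coordinate
            if 0 <= pos < len(ref) and c in bases:
                mat[pos, bases.index(c)] += r.count
    frame = pd.DataFrame(mat, columns=list(bases))
    frame.insert(0, "ref", list(ref))
    a_to_g: dict[int, float] = {}
    for pos, refbase in enumerate(ref):
        if refbase != "A":
            continue
        tot = mat[pos].sum()
        a_to_g[pos] = float(mat[pos, bases.index("G")] / tot) if tot else 0.0
    return frame, a_to_g


def isomir_table(profiles: Mapping[str, ArmProfile], denominator: int | None = None) -> pd.DataFrame:
    """Flat isomiR report (one row per mature/tag), optionally with RPM."""
    rows = []
    for name in sorted(profiles):
        for r in profiles[name].isomirs:
            row = {
                "mature": name,
                "tag": r.tag,
                "offset5": r.offset5,
                "offset3": r.offset3,
                "class5": r.class5,
                "class3": r.class3,
                "arm": r.arm,
                "count": r.count,
                "mismatches": r.mismatches,
                "nontemplated_3p": r.nontemplated_3p,
            }
            if denominator:
                row["rpm"] = round(r.count / denominator * 1e6, 1)
            rows.append(row)
    return pd.DataFrame(rows)
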