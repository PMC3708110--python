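"""Small RNAs processed from longer host ncRNAs: sno-miRNAs and tRNA fragments.

snoRNAs and tRNAs shed stable ~20-30 nt fragments; here each fragment is
recorded against its host with an arm call by a quartile rule (5' arm if
the fragment starts in the first quarter of the host, 3' arm if it ends in
the last quarter, internal otherwise).  Tags matching several identical
gene copies (multi-copy tRNAs) contribute their full count once to a
family aggregate keyed by anticodon (e.g. Gly-GCC) rather than once per
locus.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .align import Placement
from .refcat import ReferenceCatalog

__all__ = ["FragmentRecord", "profile_host_fragments", "dominant_fragment", "cluster_report", "trna_family_totals"]


@dataclass(frozen=True)
class FragmentRecord:
    host_id: str
    host_class: str
    fragment: str
    host_start: int
    host_end: int
    arm: str  # five_prime | three_prime | internal
    count: int
    full_length: bool = False

    @property
    def length(self) -> int:
        return self.host_end - self.host_start


def _arm_call(start: int, end: int, host_len: int) -> tuple[str, bool]:
    if end - start >= host_len:
        return "internal", True  # degenerate full-length fragment
    if start < 0.25 * host_len:
        return "five_prime", False
    if end > 0.75 * host_len:
        return "three_prime", False
    return "internal", False


def profile_host_fragments(
    placements_by_tag: Mapping[str, list[Placement]],
    counts: Mapping[str, int],
    catalog: ReferenceCatalog,
    host_classes: tuple[str, ...] = ("snoRNA", "tRNA"),
) -> list[FragmentRecord]:
    """One record per (host, distinct fragment) from host-sequence placements.

    ``placements_by_tag`` holds best-stratum placements of tags on host
    sequences (keyed by host id).  A tag placed on several hosts yields a
    record per host with its full count (family-level aggregation for
    multi-copy genes is done by :func:`trna_family_totals`).
    """
    host_class = {a.id: a.ncrna_class for a in catalog.annotations}
    host_len = {
        a.id: a.end - a.start for a in catalog.annotations if a.ncrna_class in host_classes
    }
    records = []
    for tag, pls in placements_by_tag.items():
        for p in pls:
            cls_ = host_class.get(p.target_id)
            if cls_ not in host_classes:
                continue
            arm, full = _arm_call(p.start, p.end, host_len[p.target_id])
            records.append(
                FragmentRecord(
                    p.target_id, cls_, tag, p.start, p.end, arm, counts.get(tag, 0), full
                )
            )
    return sorted(records, key=lambda r: (r.host_id, -r.count, r.fragment))


def dominant_fragment(records: list[FragmentRecord], host_id: str) -> FragmentRecord:
    """Highest-count fragment of a host; ties -> longer, then lexicographic."""
    cands = [r for r in records if r.host_id == host_id]
    if not cands:
        raise KeyError(f"no fragments recorded for host {host_id!r}")
    return max(cands, key=lambda r: (r.count, r.length, [-ord(c) for c in r.fragment]))


def cluster_report(
    records: list[FragmentRecord], cluster_members: list[str]
) -> pd.DataFrame:
    """Per-member summary for an ordered snoRNA cluster.

    Members with no reads still get a row (all zeros) so the cluster's
    coverage pattern is visible at a glance.
    """
    rows = []
    for member in cluster_members:
        mine = [r for r in records if r.host_id == member]
        total = sum(r.count for r in mine)
        arms = sorted({r.arm for r in mine})
        dom = dominant_fragment(records, member).fragment if mine else ""
        rows.append(
            {
                "host": member,
                "total_reads": total,
                "n_fragments": len(mine),
                "dominant_fragment": dom,
                "arms": ",".join(arms),
            }
        )
    return pd.DataFrame(rows, columns=["host", "total_reads", "n_fragments", "dominant_fragment", "arms"])


def trna_family_totals(
    records: list[FragmentRecord], catalog: ReferenceCatalog
) -> pd.DataFrame:
    """Aggregate tRNA fragments to anticodon families, counting each tag once.

    A fragment matching N gene copies of one family contributes its count a
    single time to that family (not N times); distinct gene copies hit are
    reported alongside.
    """
    fam = catalog.trna_families
    seen: dict[tuple[str, str], int] = {}
    genes: dict[str, set[str]] = {}
    arms: dict[str, set[str]] = {}
    for r in records:
        if r.host_class != "tRNA":
            continue
        family = fam.get(r.host_id, r.host_id)
        seen[(family, r.fragment)] = max(seen.get((family, r.fragment), 0), r.count)
        genes.setdefault(family, set()).add(r.host_id)
        arms.setdefault(family, set()).add(r.arm)
    rows = []
    for family in sorted(genes):
        total = sum(c for (f, _), c in seen.items() if f == family)
        rows.append(
            {
                "family": family,
                "total_reads": total,
                "n_genes": len(genes[family]),
                "arms": ",".join(sorted(arms[family])),
            }
        )
    return pd.DataFrame(rows, columns=["family", "total_reads", "n_genes", "arms"])


def fragments_table(records: list[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "host": r.host_id,
                "class": r.host_class,
                "fragment": r.fragment,
                "start": r.host_start,
                "end": r.host_end,
                "arm": r.arm,
                "length": r.length,
                "count": r.count,
                "full_length": r.full_length,
            }
            for r in records
        ]
    )
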