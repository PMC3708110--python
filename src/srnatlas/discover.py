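"""Novel miRNA discovery: expressed intervals, hairpin filters, orthologs, families.

Two evidence routes mirror standard practice for calling new miRNA genes
from expression data alone:

* ``star_supported`` — reads on *both* arms of a folded precursor, placed
  with the 2-nt 3'-overhang geometry a Dicer duplex leaves behind; the
  strongest evidence class.
* ``structure_only`` — a single well-expressed ~22-nt product sitting
  tightly on one arm of a stable single hairpin (read support > 100,
  dominant length 21-23 nt, MFE at or below -25 kcal/mol, exactly one
  terminal loop, mature pairing fraction >= 0.75 on one arm only).

Orthologs of foreign (e.g. human) miRBase matures are detected separately
by near-exact sequence match, and candidates sharing an identical seed
(positions 2-8) are grouped into families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .align import Placement
from .fold import HairpinFold, fold_hairpin
from .refcat import ReferenceCatalog, seed_of

__all__ = [
    "DiscoveryParams",
    "ExpressedInterval",
    "NovelCandidate",
    "call_intervals",
    "extract_hairpin_frame",
    "filter_candidates",
    "detect_star_support",
    "evaluate_candidates",
    "find_orthologs",
    "assign_families",
    "fold_hairpin",
]


@dataclass(frozen=True)
class DiscoveryParams:
    """Thresholds for the structure-based candidate filter."""

    min_reads: int = 100  # strict: read support must exceed this
    min_len: int = 21
    max_len: int = 23
    mfe_threshold: float = -25.0  # kcal/mol; candidate MFE must be <= this
    pairing_fraction: float = 0.75
    flank: int = 60
    merge_gap: int = 10
    star_tolerance: int = 2


@dataclass
class ExpressedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    read_support: int
    dominant_tag: str
    dominant_start: int  # genome coordinate of the dominant tag's placement

    @property
    def dominant_length(self) -> int:
        return len(self.dominant_tag)


@dataclass
class NovelCandidate:
    interval: ExpressedInterval
    fold: HairpinFold | None
    frame_start: int  # genome start of the folded frame
    passed: bool
    trace: dict[str, bool]
    tier: str = "structure_only"  # "star_supported" when star reads exist
    star_reads: int = 0
    family: str | None = None

    @property
    def mature_sequence(self) -> str:
        return self.interval.dominant_tag


def call_intervals(
    placements_by_tag: Mapping[str, list[Placement]],
    counts: Mapping[str, int],
    merge_gap: int = 10,
) -> list[ExpressedInterval]:
    """Strand-specific single-linkage merge of genome placements.

    Placements on the same chromosome and strand closer than ``merge_gap``
    are merged into one expressed interval; read support is count-weighted
    and the dominant tag is the highest-count tag (ties by sequence).
    """
    items: list[tuple[str, str, int, int, str, int]] = []
    for tag, pls in placements_by_tag.items():
        for p in pls:
            items.append((p.target_id, p.strand, p.start, p.end, tag, counts.get(tag, 0)))
    items.sort()
    intervals: list[ExpressedInterval] = []
    cur: list | None = None
    members: list[tuple[str, int, int]] = []

    def flush():
        if cur is None:
            return
        support = sum(c for _, c, _ in members)
        dom_tag, _, dom_start = max(members, key=lambda m: (m[1], m[0]))
        intervals.append(
            ExpressedInterval(cur[0], cur[2], cur[3], cur[1], support, dom_tag, dom_start)
        )

    for chrom, strand, start, end, tag, count in items:
        if cur is not None and (chrom, strand) == (cur[0], cur[1]) and start <= cur[3] + merge_gap:
            cur[3] = max(cur[3], end)
            members.append((tag, count, start))
        else:
            flush()
            cur = [chrom, strand, start, end]
            members = [(tag, count, start)]
    flush()
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.strand))


def extract_hairpin_frame(
    interval: ExpressedInterval,
    catalog: ReferenceCatalog,
    params: DiscoveryParams = DiscoveryParams(),
    folder=fold_hairpin,
) -> tuple[HairpinFold | None, int, tuple[int, int]]:
    """Fold candidate frames around an interval, keep the best-scoring one.

    Frames extend the interval by 0..flank nt on each side (20-nt grid),
    lengths clipped to [40, 120].  The best frame prefers a single hairpin
    loop, then higher dominant-tag pairing fraction, then lower MFE.
    Returns (fold, genome start of frame, mature interval within frame);
    the fold is in transcript orientation (reverse-complemented for '-').
    """
    chrom_len = len(catalog.genome[interval.chrom])
    best = None
    step = max(params.flank // 3, 1)
    exts = list(range(0, params.flank + 1, step))
    for left in exts:
        for right in exts:
            gs = max(0, interval.start - left)
            ge = min(chrom_len, interval.end + right)
            if not 40 <= ge - gs <= 120:
                continue
            seq = catalog.extract(interval.chrom, gs, ge, interval.strand)
            fold_ = folder(seq)
            if interval.strand == "+":
                ms = interval.dominant_start - gs
            else:
                ms = ge - (interval.dominant_start + interval.dominant_length)
            me = ms + interval.dominant_length
            if ms < 0 or me > len(seq):
                continue
            pf = fold_.pairing_fraction(ms, me)
            key = (fold_.n_hairpin_loops == 1, pf, -fold_.mfe)
            if best is None or key > best[0]:
                best = (key, fold_, gs, (ms, me))
    if best is None:
        return None, interval.start, (0, 0)
    return best[1], best[2], best[3]


def filter_candidates(
    interval: ExpressedInterval,
    fold_: HairpinFold | None,
    mature_span: tuple[int, int],
    params: DiscoveryParams = DiscoveryParams(),
) -> tuple[bool, dict[str, bool]]:
    """Apply the candidate criteria; returns pass/fail with per-criterion trace."""
    ms, me = mature_span
    trace = {
        "read_support": interval.read_support > params.min_reads,
        "length": params.min_len <= interval.dominant_length <= params.max_len,
        "mfe": fold_ is not None and fold_.mfe <= params.mfe_threshold,
        "single_hairpin": fold_ is not None and fold_.n_hairpin_loops == 1,
        "arm_pairing": fold_ is not None
        and me > ms
        and fold_.pairing_fraction(ms, me) >= params.pairing_fraction
        and fold_.one_arm(ms, me),
    }
    return all(trace.values()), trace


def detect_star_support(
    fold_: HairpinFold,
    mature_span: tuple[int, int],
    tag_positions: Iterable[tuple[int, int]],
    tolerance: int = 2,
) -> int:
    """Count reads whose 5' end sits where a Dicer star product would.

    ``tag_positions`` are (5' start within the folded frame, count) pairs.
    The expected star 5' end is the pairing partner of the base two inside
    the mature 3' end (2-nt 3' overhang), matched within ``tolerance``.
    """
    from .isomir import expected_star_start

    ms, me = mature_span
    s5 = expected_star_start(fold_, ms, me)
    if s5 is None:
        return 0
    star = 0
    for pos, count in tag_positions:
        if abs(pos - s5) <= tolerance and not ms <= pos < me:
            star += count
    return star


def evaluate_candidates(
    placements_by_tag: Mapping[str, list[Placement]],
    counts: Mapping[str, int],
    catalog: ReferenceCatalog,
    params: DiscoveryParams = DiscoveryParams(),
    folder=fold_hairpin,
) -> list[NovelCandidate]:
    """Full discovery pass over unannotated genome placements."""
    intervals = call_intervals(placements_by_tag, counts, params.merge_gap)
    candidates = []
    for iv in intervals:
        fold_, frame_start, mature_span = extract_hairpin_frame(iv, catalog, params, folder)
        ok, trace = filter_candidates(iv, fold_, mature_span, params)
        cand = NovelCandidate(iv, fold_, frame_start, ok, trace)
        if ok and fold_ is not None:
            positions = []
            frame_len = len(fold_.sequence)
            for tag, pls in placements_by_tag.items():
                for p in pls:
                    if p.target_id != iv.chrom or p.strand != iv.strand:
                        continue
                    if iv.strand == "+":
                        pos = p.start - frame_start
                    else:
                        pos = (frame_start + frame_len) - p.end
                    if 0 <= pos < frame_len:
                        positions.append((pos, counts.get(tag, 0)))
            cand.star_reads = detect_star_support(
                fold_, mature_span, positions, params.star_tolerance
            )
            cand.tier = "star_supported" if cand.star_reads > 0 else "structure_only"
        candidates.append(cand)
    return candidates


def find_orthologs(
    tags: Mapping[str, int],
    foreign_matures: Mapping[str, str],
    native_matures: Mapping[str, str],
    max_mismatch: int = 2,
) -> dict[str, list[tuple[str, int]]]:
    """Tags matching a foreign mature but no native one -> ortholog calls.

    A match allows up to ``max_mismatch`` substitutions over the shorter
    of tag/mature length anchored at the 5' end, with the seed region
    (positions 2-8) required to be exact.  Returns
    ``{foreign name: [(tag, count), ...]}``.
    """
    native = {s.upper().replace("U", "T") for s in native_matures.values()}
    calls: dict[str, list[tuple[str, int]]] = {}
    for tag, count in tags.items():
        t = tag.upper().replace("U", "T")
        if any(t in ns or ns in t for ns in native):
            continue
        for name, fseq in sorted(foreign_matures.items()):
            f = fseq.upper().replace("U", "T")
            L = min(len(t), len(f))
            if L < 16:
                continue
            mm = sum(a != b for a, b in zip(t[:L], f[:L]))
            if mm <= max_mismatch and t[1:8] == f[1:8]:
                calls.setdefault(name, []).append((tag, count))
                break
    return calls


def assign_families(sequences: Mapping[str, str]) -> dict[str, str]:
    """Group sequences sharing an identical seed (positions 2-8).

    Returns ``{name: family label}``; a family is named after its
    lexicographically earliest member.
    """
    by_seed: dict[str, list[str]] = {}
    for name, seq in sequences.items():
        by_seed.setdefault(seed_of(seq.upper().replace("U", "T")), []).append(name)
    out = {}
    for seed, names in by_seed.items():
        label = sorted(names)[0]
        for n in names:
            out[n] = label
    return out


def candidate_report(candidates: list[NovelCandidate]) -> str:
    """Per-candidate text blocks: locus, sequence, dot-bracket, MFE, evidence."""
    blocks = []
    for c in candidates:
        head = (
            f"{c.interval.chrom}:{c.interval.start}-{c.interval.end}({c.interval.strand}) "
            f"support={c.interval.read_support} len={c.interval.dominant_length} "
            f"tier={c.tier if c.passed else 'rejected'} star_reads={c.star_reads}"
        )
        lines = [head, f"mature  {c.mature_sequence}"]
        if c.fold is not None:
            lines += [f"frame   {c.fold.sequence}", f"fold    {c.fold.dot_bracket}", f"mfe     {c.fold.mfe:.1f} kcal/mol"]
        lines.append("criteria " + " ".join(f"{k}={'ok' if v else 'FAIL'}" for k, v in c.trace.items()))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"
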