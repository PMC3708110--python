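"""Substitution-only short-tag mapping with bounded mismatches.

Tags are mapped to reference sequences (mature miRNAs, precursors, genome
chromosomes) allowing up to ``max_mismatch`` substitutions (no indels:
isomiR analysis is offset/substitution based).  All placements in the best
stratum — the minimum observed mismatch count for that tag — are reported,
because a small RNA can legitimately arise from several loci.  Candidate
positions come from a pigeonhole seed: a tag with at most ``m`` mismatches
must match at least one of ``m+1`` non-overlapping segments exactly, so an
exact k-mer index over the references is sufficient for full sensitivity.
A brute-force sliding-window oracle (numpy Hamming scan) certifies the
seeded search in tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .seqio import CollapsedLibrary, revcomp

__all__ = ["Placement", "map_tags", "map_tag", "brute_force_oracle", "placements_to_bed", "placements_to_sam"]


@dataclass(frozen=True, order=True)
class Placement:
    """One placement of a tag on a reference interval."""

    target_id: str
    start: int  # 0-based on the forward reference
    end: int  # exclusive; end - start == len(tag)
    strand: str
    mismatches: int
    tag: str = ""
    target_kind: str = "reference"


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class _SegmentIndex:
    """Exact-match index of all reference substrings of one length."""

    def __init__(self, targets: Mapping[str, str], k: int):
        self.k = k
        self.table: dict[str, list[tuple[str, int]]] = {}
        for name, seq in targets.items():
            for i in range(len(seq) - k + 1):
                self.table.setdefault(seq[i : i + k], []).append((name, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.table.get(kmer, [])


class ReferenceIndex:
    """Seeded mismatch search over a set of named reference sequences."""

    def __init__(self, targets: Mapping[str, str], target_kind: str = "reference"):
        self.targets = {k: v.upper().replace("U", "T") for k, v in targets.items()}
        self.target_kind = target_kind
        self._arrays = {k: _encode(v) for k, v in self.targets.items()}
        self._segment_indexes: dict[int, _SegmentIndex] = {}

    def _index_for(self, k: int) -> _SegmentIndex:
        if k not in self._segment_indexes:
            self._segment_indexes[k] = _SegmentIndex(self.targets, k)
        return self._segment_indexes[k]

    def _candidates(self, tag: str, max_mismatch: int) -> set[tuple[str, int]]:
        nseg = max_mismatch + 1
        k = len(tag) // nseg
        if k < 1:
            return set()
        idx = self._index_for(k)
        cands: set[tuple[str, int]] = set()
        for i in range(nseg):
            off = i * k
            for name, pos in idx.hits(tag[off : off + k]):
                start = pos - off
                if 0 <= start <= len(self.targets[name]) - len(tag):
                    cands.add((name, start))
        return cands

    def search(self, tag: str, max_mismatch: int, strand: str = "+") -> list[Placement]:
        """All placements of ``tag`` with <= max_mismatch substitutions."""
        tag = tag.upper().replace("U", "T")
        if "N" in tag:
            return []  # N never seeds: ambiguous bases fail alignment
        arr = _encode(tag)
        out = []
        for name, start in self._candidates(tag, max_mismatch):
            mm = int(np.count_nonzero(self._arrays[name][start : start + len(tag)] != arr))
            if mm <= max_mismatch:
                out.append(
                    Placement(name, start, start + len(tag), strand, mm, tag, self.target_kind)
                )
        return out


def map_tag(
    tag: str,
    index: ReferenceIndex,
    max_mismatch: int = 1,
    both_strands: bool = False,
) -> list[Placement]:
    """Best-stratum placements of one tag (sorted deterministically)."""
    hits = index.search(tag, max_mismatch, "+")
    if both_strands:
        rc = revcomp(tag)
        hits += [
            Placement(p.target_id, p.start, p.end, "-", p.mismatches, tag, p.target_kind)
            for p in index.search(rc, max_mismatch, "-")
        ]
    if not hits:
        return []
    best = min(p.mismatches for p in hits)
    return sorted(p for p in hits if p.mismatches == best)


def map_tags(
    lib: CollapsedLibrary | Iterable[str],
    targets: Mapping[str, str] | ReferenceIndex,
    max_mismatch: int = 1,
    both_strands: bool = False,
    target_kind: str = "reference",
) -> dict[str, list[Placement]]:
    """Map every tag; unmapped tags get an empty placement list."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be in {0, 1, 2}")
    index = (
        targets
        if isinstance(targets, ReferenceIndex)
        else ReferenceIndex(targets, target_kind)
    )
    tags = lib.entries.keys() if isinstance(lib, CollapsedLibrary) else lib
    return {tag: map_tag(tag, index, max_mismatch, both_strands) for tag in tags}


# ---------------------------------------------------------------------------
# oracle


def brute_force_oracle(
    tag: str,
    reference: str,
    max_mismatch: int = 0,
    target_id: str = "ref",
    both_strands: bool = False,
) -> list[Placement]:
    """Exhaustive sliding-window Hamming scan (test oracle, refs <= 100 kb)."""
    if len(reference) > 100_000:
        raise ValueError("oracle restricted to references <= 100 kb")
    out: list[Placement] = []
    for strand in ["+", "-"] if both_strands else ["+"]:
        probe = tag if strand == "+" else revcomp(tag)
        probe = probe.upper().replace("U", "T")
        ref = reference.upper().replace("U", "T")
        L = len(probe)
        if L > len(ref) or "N" in probe:
            continue
        ref_arr = _encode(ref)
        probe_arr = _encode(probe)
        windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
        mm = (windows != probe_arr).sum(axis=1)
        for start in np.nonzero(mm <= max_mismatch)[0]:
            out.append(
                Placement(target_id, int(start), int(start) + L, strand, int(mm[start]), tag)
            )
    if not out:
        return []
    best = min(p.mismatches for p in out)
    return sorted(p for p in out if p.mismatches == best)


# ---------------------------------------------------------------------------
# export


def placements_to_bed(placements: Iterable[Placement], path) -> None:
    """BED6 + mismatch column; score column carries the mismatch count too."""
    rows = sorted(placements, key=lambda p: (p.target_id, p.start, p.strand, p.tag))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.target_id}\t{p.start}\t{p.end}\t{p.tag}\t{p.mismatches}\t{p.strand}\t{p.mismatches}\n"
            )


def placements_to_sam(
    placements: Iterable[Placement], targets: Mapping[str, str], path
) -> None:
    """Minimal unpaired SAM: @SQ from the catalog, NM tag for mismatches."""
    rows = sorted(placements, key=lambda p: (p.target_id, p.start, p.strand, p.tag))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(targets):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(targets[name])}\n")
        for i, p in enumerate(rows):
            flag = 16 if p.strand == "-" else 0
            seq = revcomp(p.tag) if p.strand == "-" else p.tag
            fh.write(
                f"tag{i}\t{flag}\t{p.target_id}\t{p.start + 1}\t255\t{len(p.tag)}M\t*\t0\t0\t"
                f"{seq}\t*\tNM:i:{p.mismatches}\n"
            )
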