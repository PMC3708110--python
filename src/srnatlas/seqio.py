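"""Sequence I/O, adapter clipping and the read-filtering cascade.

A deep-sequenced small RNA library arrives as raw reads of fixed machine
length: each read is ``insert + 3' adapter`` truncated to the read length.
Processing proceeds insert-first: clip the adapter, drop inserts too short
to be small regulatory RNAs, collapse the remaining reads into unique
sequences ("tags") with multiplicities, and finally drop tags seen fewer
times than a count threshold (singleton tags are dominated by sequencing
error).  All downstream analysis operates on the collapsed library.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio import SeqIO

__all__ = [
    "RawRead",
    "CollapsedLibrary",
    "clip_adapter",
    "clip_adapters",
    "length_filter",
    "length_filter_reads",
    "collapse",
    "abundance_filter",
    "length_histogram",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_library_fasta",
    "write_library_tsv",
    "read_library_tsv",
]

_DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned as DNA)."""
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawRead:
    """One sequencing read: identifier, uppercase sequence, optional phred."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CollapsedLibrary:
    """Unique tag sequences with occurrence counts.

    ``entries`` maps tag sequence -> positive multiplicity; ``total_raw`` is
    the number of reads that entered collapsing; ``provenance`` records the
    ordered list of filters applied (name, parameters) so a report can
    reproduce the cascade narrative.
    """

    entries: dict[str, int]
    total_raw: int
    provenance: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("all tag counts must be >= 1")
        if self.total_reads > self.total_raw:
            raise ValueError("sum of counts exceeds total_raw")

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def expand(self) -> Iterator[str]:
        """Inverse of collapse: yield each tag ``count`` times."""
        for seq, n in self.entries.items():
            for _ in range(n):
                yield seq


# ---------------------------------------------------------------------------
# adapter clipping


def clip_adapter(read: RawRead, adapter: str, min_overlap: int = 6) -> tuple[RawRead, bool]:
    """Remove the 3' adapter from a read by exact prefix matching.

    Searches for the leftmost occurrence of the full adapter anywhere in the
    read, or of an adapter prefix of length >= ``min_overlap`` ending exactly
    at the read's 3' end (the adapter running off the read).  Returns the
    insert (prefix preceding the match) and a found-flag; an unfound adapter
    leaves the read unchanged with flag ``False``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = read.sequence
    cut = seq.find(adapter)
    if cut < 0:
        # adapter truncated by the read end: try successively shorter prefixes
        for k in range(min(len(adapter), len(seq)) - 1, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut < 0:
        return read, False
    clipped = seq[:cut]
    if not clipped:
        # adapter dimer: empty insert; keep a sentinel single record removed
        # later by the length filter rather than erroring mid-stream
        return replace(read, sequence="N", quality="!" if read.quality else None), True
    qual = read.quality[:cut] if read.quality else None
    return replace(read, sequence=clipped, quality=qual), True


def clip_adapters(
    reads: Iterable[RawRead], adapter: str, min_overlap: int = 6
) -> Iterator[RawRead]:
    """Clip every read, keeping unclipped reads unchanged."""
    for r in reads:
        clipped, _ = clip_adapter(r, adapter, min_overlap)
        yield clipped


# ---------------------------------------------------------------------------
# filtering cascade


def length_filter_reads(reads: Iterable[RawRead], min_len: int = 15) -> Iterator[RawRead]:
    """Keep reads strictly longer than ``min_len`` nucleotides."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return (r for r in reads if len(r) > min_len)


def length_filter(lib: CollapsedLibrary, min_len: int = 15) -> CollapsedLibrary:
    """Keep tags strictly longer than ``min_len`` nucleotides."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    entries = {s: c for s, c in lib.entries.items() if len(s) > min_len}
    return CollapsedLibrary(
        entries,
        lib.total_raw,
        lib.provenance + [("length_filter", {"min_len": min_len})],
    )


def collapse(reads: Iterable[RawRead | str]) -> CollapsedLibrary:
    """Collapse a read multiset into unique sequences with exact counts."""
    counts: collections.Counter[str] = collections.Counter()
    for r in reads:
        counts[r if isinstance(r, str) else r.sequence] += 1
    total = sum(counts.values())
    return CollapsedLibrary(dict(counts), total, [("collapse", {})])


def abundance_filter(
    lib: CollapsedLibrary, min_count: int = 3
) -> tuple[CollapsedLibrary, dict]:
    """Drop tags seen fewer than ``min_count`` times.

    Returns the filtered library and a summary with the number of unique
    tags retained and the fraction of reads they account for.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    entries = {s: c for s, c in lib.entries.items() if c >= min_count}
    total_before = lib.total_reads
    retained_reads = sum(entries.values())
    summary = {
        "retained_unique": len(entries),
        "retained_reads": retained_reads,
        "retained_read_fraction": (retained_reads / total_before) if total_before else 0.0,
    }
    out = CollapsedLibrary(
        entries,
        lib.total_raw,
        lib.provenance + [("abundance_filter", {"min_count": min_count})],
    )
    return out, summary


def length_histogram(lib: CollapsedLibrary) -> tuple[dict[int, int], float]:
    """Read-weighted length spectrum and mean read length."""
    hist: collections.Counter[int] = collections.Counter()
    for seq, c in lib.entries.items():
        hist[len(seq)] += c
    total = sum(hist.values())
    mean = sum(l * c for l, c in hist.items()) / total if total else 0.0
    return dict(sorted(hist.items())), mean


# ---------------------------------------------------------------------------
# file formats


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream a sanger (phred+33) FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered ``{id: sequence}`` mapping (uppercase)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_library_fasta(lib: CollapsedLibrary, path: str | Path) -> None:
    """Serialize tags as FASTA with ``tag<k>_x<count>`` headers (count-sorted)."""
    ordered = sorted(lib.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    write_fasta({f"tag{i + 1}_x{c}": s for i, (s, c) in enumerate(ordered)}, path)


def write_library_tsv(lib: CollapsedLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\n")
        for s, c in sorted(lib.entries.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{s}\t{c}\n")


def read_library_tsv(path: str | Path) -> CollapsedLibrary:
    entries: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError(f"{path}: not a collapsed-library TSV")
        for line in fh:
            seq, c = line.split()
            entries[seq] = int(c)
    total = sum(entries.values())
    return CollapsedLibrary(entries, total, [("loaded", {"path": str(path)})])
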