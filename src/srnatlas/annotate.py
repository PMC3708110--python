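"""Assign tags to ncRNA classes and summarize library composition.

Each unique tag is assigned to exactly one ncRNA class (a partition: the
tag's whole count flows to one class) by overlapping its best-stratum
genome placements with the annotation catalog.  When a tag overlaps
annotations of several classes, an ordered precedence list decides
(miRNA first by default); ties within a class break by lowest mismatch
count then lexicographic annotation id.  Tags placed only on unannotated
genome become the input to novel-miRNA discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .align import Placement
from .refcat import ReferenceCatalog

DEFAULT_PRECEDENCE = (
    "miRNA",
    "snoRNA",
    "tRNA",
    "snRNA",
    "rRNA",
    "mt_rRNA",
    "mt_tRNA",
    "miscRNA",
)

__all__ = ["DEFAULT_PRECEDENCE", "TagAnnotation", "ClassSummary", "classify_tag", "classify_tags", "summarize_classes"]


@dataclass(frozen=True)
class TagAnnotation:
    tag: str
    ncrna_class: str | None  # None = genome-only (unannotated)
    feature_id: str | None
    placement: Placement | None


@dataclass
class ClassSummary:
    """Per-class distinct features, read totals and read fractions."""

    distinct: dict[str, int] = field(default_factory=dict)
    reads: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.reads.values())

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total_reads
        return {c: n / tot for c, n in self.reads.items()} if tot else {}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": c,
                "distinct_features": self.distinct.get(c, 0),
                "reads": self.reads.get(c, 0),
                "read_fraction": self.fractions.get(c, 0.0),
            }
            for c in sorted(self.reads, key=lambda c: -self.reads[c])
        ]
        return pd.DataFrame(rows, columns=["class", "distinct_features", "reads", "read_fraction"])


def classify_tag(
    tag: str,
    placements: Iterable[Placement],
    catalog: ReferenceCatalog,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> TagAnnotation:
    """Pick one (class, feature) for a tag from its genome placements."""
    rank = {c: i for i, c in enumerate(precedence)}
    best: tuple[int, int, str] | None = None  # (class rank, mismatches, feature id)
    chosen: tuple[str, str, Placement] | None = None
    hit_genome = False
    for p in placements:
        hit_genome = True
        for ann in catalog.overlapping(p.target_id, p.start, p.end, strand=p.strand):
            key = (rank.get(ann.ncrna_class, len(precedence)), p.mismatches, ann.id)
            if best is None or key < best:
                best = key
                chosen = (ann.ncrna_class, ann.id, p)
    if chosen is not None:
        return TagAnnotation(tag, chosen[0], chosen[1], chosen[2])
    if hit_genome:
        return TagAnnotation(tag, None, None, None)
    return TagAnnotation(tag, None, None, None)


def classify_tags(
    placements_by_tag: Mapping[str, list[Placement]],
    catalog: ReferenceCatalog,
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE,
) -> dict[str, TagAnnotation]:
    return {
        tag: classify_tag(tag, pls, catalog, precedence)
        for tag, pls in placements_by_tag.items()
        if pls  # unplaced tags carry no annotation at all
    }


def summarize_classes(
    annotations: Mapping[str, TagAnnotation], counts: Mapping[str, int]
) -> ClassSummary:
    """Read-weighted and distinct-feature tallies over classified tags."""
    reads: dict[str, int] = {}
    features: dict[str, set[str]] = {}
    for tag, ann in annotations.items():
        if ann.ncrna_class is None:
            continue
        reads[ann.ncrna_class] = reads.get(ann.ncrna_class, 0) + counts.get(tag, 0)
        features.setdefault(ann.ncrna_class, set()).add(ann.feature_id)
    return ClassSummary({c: len(s) for c, s in features.items()}, reads)


def plot_class_pies(summary: ClassSummary, path) -> None:
    """Optional composition pies (distinct features / read abundance)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    order = sorted(summary.reads, key=lambda c: -summary.reads[c])
    axes[0].pie([summary.distinct.get(c, 0) for c in order], labels=order)
    axes[0].set_title("distinct ncRNAs")
    axes[1].pie([summary.reads[c] for c in order], labels=order)
    axes[1].set_title("reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
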