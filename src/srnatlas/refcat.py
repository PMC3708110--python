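"""Reference catalog: genome, mature/precursor miRNAs, ncRNA annotations, tRNA genes.

The catalog is the pipeline's reference universe.  Mature miRNAs that share
an identical sequence but are encoded by several precursors are merged into
a single entry whose name joins the precursor-qualified names with ``//``
(so a read is counted once, not once per locus).  Coordinates are 0-based
half-open internally; GFF3 input/output is 1-based inclusive and BED is
0-based half-open.  Minus-strand loci are reverse-complemented on
extraction so that feature sequences always read 5'->3'.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from intervaltree import IntervalTree

from .seqio import read_fasta, revcomp, write_fasta

log = logging.getLogger(__name__)

NCRNA_CLASSES = (
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
    "mt_rRNA",
    "mt_tRNA",
    "miscRNA",
)

__all__ = [
    "NCRNA_CLASSES",
    "MatureMiRNA",
    "Hairpin",
    "NcRNAAnnotation",
    "ReferenceCatalog",
    "load_references",
    "seed_of",
]


@dataclass(frozen=True)
class NcRNAAnnotation:
    id: str
    ncrna_class: str
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(f"{self.id}: unknown ncRNA class {self.ncrna_class!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")


@dataclass
class Hairpin:
    """A miRNA precursor: its locus, 5'->3' sequence and per-arm mature intervals."""

    id: str
    sequence: str
    chrom: str
    start: int
    end: int
    strand: str
    # arm ("5p"/"3p") -> (mature name, start, end) within the precursor
    mature_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)


@dataclass
class MatureMiRNA:
    """A mature miRNA, possibly merged across identical-sequence precursors."""

    name: str
    sequence: str  # T-normalized DNA
    merged_names: list[str]
    host_precursors: list[str]
    arm: str = "unknown"

    @property
    def seed(self) -> str:
        return seed_of(self)


def seed_of(m: "MatureMiRNA | str") -> str:
    """Seed = mature positions 2-8 (1-based), the 7-mer driving targeting."""
    seq = m if isinstance(m, str) else m.sequence
    if len(seq) < 8:
        raise ValueError("sequence too short for a seed (need >= 8 nt)")
    return seq[1:8]


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


class ReferenceCatalog:
    """Indexed references: genome, merged matures, hairpins, annotations, tRNAs."""

    def __init__(
        self,
        genome: dict[str, str],
        matures: dict[str, MatureMiRNA],
        hairpins: dict[str, Hairpin],
        annotations: list[NcRNAAnnotation],
        trna_families: dict[str, str] | None = None,
        foreign_matures: dict[str, str] | None = None,
    ) -> None:
        self.genome = {k: _norm(v) for k, v in genome.items()}
        self.matures = matures
        self.hairpins = hairpins
        self.annotations = annotations
        self.trna_families = trna_families or {}
        self.foreign_matures = {k: _norm(v) for k, v in (foreign_matures or {}).items()}
        self._trees: dict[str, IntervalTree] = {}
        for ann in annotations:
            self._trees.setdefault(ann.chrom, IntervalTree())[ann.start : ann.end] = ann

    # -- queries ---------------------------------------------------------

    def overlapping(self, chrom: str, start: int, end: int, strand: str | None = None):
        """Annotations overlapping [start, end) on ``chrom`` (optionally same strand)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        if strand is not None:
            hits = [a for a in hits if a.strand == strand]
        return sorted(hits, key=lambda a: a.id)

    def extract(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.genome[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def mature_by_sequence(self, seq: str) -> MatureMiRNA | None:
        return self._seq2mature.get(_norm(seq))

    @property
    def _seq2mature(self) -> dict[str, MatureMiRNA]:
        if not hasattr(self, "_seq2mature_cache"):
            self._seq2mature_cache = {m.sequence: m for m in self.matures.values()}
        return self._seq2mature_cache

    # -- persistence -----------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Cache the catalog as a directory of deterministic text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(dict(sorted(self.genome.items())), outdir / "genome.fasta")
        with open(outdir / "matures.tsv", "w") as fh:
            fh.write("name\tsequence\tmerged_names\thost_precursors\tarm\n")
            for name in sorted(self.matures):
                m = self.matures[name]
                fh.write(
                    f"{m.name}\t{m.sequence}\t{','.join(m.merged_names)}\t"
                    f"{','.join(m.host_precursors)}\t{m.arm}\n"
                )
        with open(outdir / "hairpins.tsv", "w") as fh:
            fh.write("id\tsequence\tchrom\tstart\tend\tstrand\tmature_intervals\n")
            for hid in sorted(self.hairpins):
                h = self.hairpins[hid]
                ivs = ";".join(
                    f"{arm}:{nm}:{s}:{e}"
                    for arm, (nm, s, e) in sorted(h.mature_intervals.items())
                )
                fh.write(
                    f"{h.id}\t{h.sequence}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{ivs}\n"
                )
        with open(outdir / "annotations.tsv", "w") as fh:
            fh.write("id\tclass\tchrom\tstart\tend\tstrand\n")
            for a in sorted(self.annotations, key=lambda a: (a.chrom, a.start, a.id)):
                fh.write(
                    f"{a.id}\t{a.ncrna_class}\t{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\n"
                )
        with open(outdir / "trna_families.tsv", "w") as fh:
            fh.write("id\tfamily\n")
            for tid in sorted(self.trna_families):
                fh.write(f"{tid}\t{self.trna_families[tid]}\n")
        write_fasta(dict(sorted(self.foreign_matures.items())), outdir / "foreign_matures.fasta")

    @classmethod
    def load(cls, indir: str | Path) -> "ReferenceCatalog":
        indir = Path(indir)
        genome = read_fasta(indir / "genome.fasta")
        matures: dict[str, MatureMiRNA] = {}
        with open(indir / "matures.tsv") as fh:
            next(fh)
            for line in fh:
                name, seq, merged, hosts, arm = line.rstrip("\n").split("\t")
                matures[name] = MatureMiRNA(
                    name, seq, merged.split(","), hosts.split(",") if hosts else [], arm
                )
        hairpins: dict[str, Hairpin] = {}
        with open(indir / "hairpins.tsv") as fh:
            next(fh)
            for line in fh:
                hid, seq, chrom, s, e, strand, ivs = line.rstrip("\n").split("\t")
                intervals = {}
                if ivs:
                    for part in ivs.split(";"):
                        arm, nm, a, b = part.split(":")
                        intervals[arm] = (nm, int(a), int(b))
                hairpins[hid] = Hairpin(hid, seq, chrom, int(s), int(e), strand, intervals)
        annotations = []
        with open(indir / "annotations.tsv") as fh:
            next(fh)
            for line in fh:
                aid, cls_, chrom, s, e, strand = line.rstrip("\n").split("\t")
                annotations.append(NcRNAAnnotation(aid, cls_, chrom, int(s), int(e), strand))
        trna_families = {}
        fam_path = indir / "trna_families.tsv"
        if fam_path.exists():
            with open(fam_path) as fh:
                next(fh)
                for line in fh:
                    tid, fam = line.rstrip("\n").split("\t")
                    trna_families[tid] = fam
        foreign = {}
        fpath = indir / "foreign_matures.fasta"
        if fpath.exists():
            foreign = read_fasta(fpath)
        return cls(genome, matures, hairpins, annotations, trna_families, foreign)


# ---------------------------------------------------------------------------
# loading from standard formats


def _trna_family(name: str) -> str:
    """Family key (amino acid + anticodon) from a GtRNAdb-style gene name.

    ``tRNA-Gly-GCC-1-1`` -> ``Gly-GCC``; anything unparsable keys to itself.
    """
    parts = name.split("-")
    if len(parts) >= 3 and parts[0].lower().startswith("trna"):
        return f"{parts[1]}-{parts[2]}"
    return name


def load_references(
    mirna_fasta: str | Path,
    annotation_gff: str | Path | None,
    genome_fasta: str | Path,
    trna_bed: str | Path | None = None,
    foreign_mature_fasta: str | Path | None = None,
) -> ReferenceCatalog:
    """Build a :class:`ReferenceCatalog` from standard reference files.

    ``mirna_fasta`` holds mature miRNA sequences (miRBase-style: U allowed),
    one record per precursor-qualified name; precursor loci come from the
    miRNA-class GFF3 annotations, whose extracted genomic sequence must
    contain the mature.  Identical mature sequences are merged under a
    ``//``-joined name (precursor names in lexicographic order).
    """
    genome = {k: _norm(v) for k, v in read_fasta(genome_fasta).items()}

    annotations: list[NcRNAAnnotation] = []
    has_features = annotation_gff is not None and any(
        line.strip() and not line.startswith("#") for line in open(annotation_gff)
    )
    if has_features:
        db = gffutils.create_db(
            str(annotation_gff),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.all_features():
            cls_ = feat.featuretype
            if cls_ not in NCRNA_CLASSES:
                cls_ = feat.attributes.get("biotype", [cls_])[0]
            if cls_ not in NCRNA_CLASSES:
                warnings.warn(f"{feat.id}: unknown ncRNA class, bucketed as miscRNA")
                cls_ = "miscRNA"
            fid = feat.attributes.get("ID", [feat.id])[0]
            if feat.seqid not in genome:
                raise ValueError(f"annotation {fid}: unknown chromosome {feat.seqid}")
            start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive
            if not (0 <= start < end <= len(genome[feat.seqid])):
                raise ValueError(f"annotation {fid}: coordinates outside {feat.seqid}")
            annotations.append(
                NcRNAAnnotation(fid, cls_, feat.seqid, start, end, feat.strand or "+")
            )

    trna_families: dict[str, str] = {}
    if trna_bed is not None:
        with open(trna_bed) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else f"tRNA-{chrom}-{start}"
                strand = f[5] if len(f) > 5 else "+"
                if chrom not in genome or not (0 <= start < end <= len(genome[chrom])):
                    raise ValueError(f"tRNA gene {name}: coordinates outside {chrom}")
                annotations.append(NcRNAAnnotation(name, "tRNA", chrom, start, end, strand))
                trna_families[name] = _trna_family(name)

    # hairpins: extract each miRNA-class annotation's sequence
    hairpins: dict[str, Hairpin] = {}
    for a in annotations:
        if a.ncrna_class != "miRNA":
            continue
        seq = genome[a.chrom][a.start : a.end]
        if a.strand == "-":
            seq = revcomp(seq)
        hairpins[a.id] = Hairpin(a.id, seq, a.chrom, a.start, a.end, a.strand)

    # matures: associate with hosting hairpins by substring search, then merge
    raw_matures = {k: _norm(v) for k, v in read_fasta(mirna_fasta).items()}
    by_seq: dict[str, list[str]] = {}
    for name, seq in raw_matures.items():
        by_seq.setdefault(seq, []).append(name)

    matures: dict[str, MatureMiRNA] = {}
    for seq, names in by_seq.items():
        names = sorted(names)
        merged_name = "//".join(names)
        hosts = []
        arm = "unknown"
        for hid, hp in sorted(hairpins.items()):
            off = hp.sequence.find(seq)
            if off < 0:
                continue
            hosts.append(hid)
            mid = off + len(seq) / 2
            arm = "5p" if mid < len(hp.sequence) / 2 else "3p"
            hp.mature_intervals[arm] = (merged_name, off, off + len(seq))
        matures[merged_name] = MatureMiRNA(merged_name, seq, names, hosts, arm)

    foreign = read_fasta(foreign_mature_fasta) if foreign_mature_fasta else None
    cat = ReferenceCatalog(genome, matures, hairpins, annotations, trna_families, foreign)
    _check_mature_offsets(cat)
    return cat


def _check_mature_offsets(cat: ReferenceCatalog) -> None:
    """Assert every recorded mature interval matches the precursor sequence."""
    for hp in cat.hairpins.values():
        for arm, (name, s, e) in hp.mature_intervals.items():
            m = cat.matures.get(name)
            if m is not None and hp.sequence[s:e] != m.sequence:
                raise ValueError(f"{hp.id}/{arm}: mature {name} not at recorded offset")
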