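"""End-to-end orchestration: clip -> filter -> collapse -> map -> report.

``run_all`` executes the full analysis in a fixed order with a single
config object, writing per-stage reports (TSV/JSON/BED/FASTA) plus a
machine-readable summary into a run directory.  Reruns of the same inputs
and config produce byte-identical outputs; the plain-text log mirrors the
read cascade (raw -> >15 nt -> unique -> >=3-read unique -> fraction
retained).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import align, annotate, discover, fragments, isomir, quantify, seqio
from .refcat import load_references
from .synthetic import ADAPTER

log = logging.getLogger("srnatlas")

SCHEMA_VERSION = 1

__all__ = ["RunConfig", "RunResult", "run_all"]


@dataclass
class RunConfig:
    """All inputs and thresholds of a run; YAML round-trippable."""

    fastq: str
    mirna_fasta: str
    genome_fasta: str
    annotation_gff: str | None = None
    trna_bed: str | None = None
    foreign_mature_fasta: str | None = None
    outdir: str = "run"
    adapter: str = ADAPTER
    min_overlap: int = 6
    min_len: int = 15
    min_count: int = 3
    max_mismatch_reference: int = 1
    max_mismatch_genome: int = 0
    offset_window: int = 5
    merge_gap: int = 10
    novel_min_reads: int = 100
    novel_len: tuple[int, int] = (21, 23)
    mfe_threshold: float = -25.0
    pairing_fraction: float = 0.75
    flank: int = 60
    ortholog_max_mismatch: int = 2
    denominator_mode: str = "mirna_mapped"
    seed: int = 0

    def __post_init__(self) -> None:
        self.novel_len = tuple(self.novel_len)
        if not (1 <= self.min_count and 0 <= self.min_len):
            raise ValueError("thresholds out of range")
        if self.max_mismatch_reference not in (0, 1, 2) or self.max_mismatch_genome not in (0, 1, 2):
            raise ValueError("mismatch budgets must be in {0,1,2}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["novel_len"] = list(self.novel_len)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class RunResult:
    cascade: dict
    class_summary: annotate.ClassSummary
    expression: list
    profiles: dict
    fragment_records: list
    candidates: list
    orthologs: dict
    families: dict
    summary: dict = field(default_factory=dict)


def _stage(name: str):
    log.info("stage: %s", name)


def run_all(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- read processing cascade ---------------------------------------
    _stage("clip")
    reads = list(seqio.read_fastq(config.fastq))
    n_raw = len(reads)
    clipped = list(seqio.clip_adapters(reads, config.adapter, config.min_overlap))
    _stage("length_filter")
    kept = list(seqio.length_filter_reads(clipped, config.min_len))
    _stage("collapse")
    lib_all = seqio.collapse(kept)
    lib_all.total_raw = n_raw
    _stage("abundance_filter")
    lib, abundance_summary = seqio.abundance_filter(lib_all, config.min_count)
    cascade = {
        "raw_reads": n_raw,
        "reads_gt_min_len": len(kept),
        "unique_sequences": lib_all.n_unique,
        "unique_min_count": lib.n_unique,
        "retained_read_fraction": abundance_summary["retained_read_fraction"],
    }
    log.info(
        "cascade: %d raw -> %d >%d nt -> %d unique -> %d with >=%d reads (%.1f%% of reads)",
        n_raw, len(kept), config.min_len, lib_all.n_unique, lib.n_unique,
        config.min_count, 100 * abundance_summary["retained_read_fraction"],
    )
    seqio.write_library_tsv(lib, outdir / "collapsed.tsv")
    seqio.write_library_fasta(lib, outdir / "collapsed.fasta")

    # ---- references ----------------------------------------------------
    _stage("load_references")
    catalog = load_references(
        config.mirna_fasta,
        config.annotation_gff,
        config.genome_fasta,
        config.trna_bed,
        config.foreign_mature_fasta,
    )
    counts = lib.entries

    # ---- precursor mapping, isomiRs, expression ------------------------
    _stage("map_hairpins")
    hp_index = align.ReferenceIndex(
        {h.id: h.sequence for h in catalog.hairpins.values()}, "hairpin"
    )
    hp_placements = align.map_tags(lib, hp_index, config.max_mismatch_reference)
    _stage("isomirs")
    profiles = isomir.assign_isomirs(hp_placements, counts, catalog, config.offset_window)
    mature_counts = {name: p.mature_count for name, p in profiles.items() if p.mature_count}
    _stage("quantify")
    expression = quantify.rpm_table(mature_counts, config.denominator_mode,
                                    all_mapped_total=None if config.denominator_mode == "mirna_mapped" else 0)
    quantify.expression_frame(expression).to_csv(outdir / "expression.tsv", sep="\t", index=False)
    denom = sum(mature_counts.values())
    isomir.isomir_table(profiles, denom).to_csv(outdir / "isomirs.tsv", sep="\t", index=False)

    # ---- genome mapping + classification -------------------------------
    _stage("map_genome")
    genome_index = align.ReferenceIndex(catalog.genome, "genome")
    genome_placements = align.map_tags(lib, genome_index, config.max_mismatch_genome, both_strands=True)
    _stage("annotate")
    tag_annotations = annotate.classify_tags(genome_placements, catalog)
    class_summary = annotate.summarize_classes(tag_annotations, counts)
    class_summary.to_frame().to_csv(outdir / "class_summary.tsv", sep="\t", index=False)

    # ---- host fragments (snoRNA / tRNA) --------------------------------
    _stage("fragments")
    host_seqs = {
        a.id: catalog.extract(a.chrom, a.start, a.end, a.strand)
        for a in catalog.annotations
        if a.ncrna_class in ("snoRNA", "tRNA")
    }
    host_tags = [
        t for t, a in tag_annotations.items() if a.ncrna_class in ("snoRNA", "tRNA")
    ]
    host_placements = align.map_tags(host_tags, host_seqs, config.max_mismatch_reference)
    frag_records = fragments.profile_host_fragments(host_placements, counts, catalog)
    fragments.fragments_table(frag_records).to_csv(outdir / "fragments.tsv", sep="\t", index=False)
    fragments.trna_family_totals(frag_records, catalog).to_csv(
        outdir / "trna_families.tsv", sep="\t", index=False
    )

    # ---- orthologs then novel discovery on unannotated tags ------------
    _stage("orthologs")
    unannotated = {
        t: counts[t]
        for t, a in tag_annotations.items()
        if a.ncrna_class is None and genome_placements.get(t)
    }
    orthologs = discover.find_orthologs(
        unannotated,
        catalog.foreign_matures,
        {m.name: m.sequence for m in catalog.matures.values()},
        config.ortholog_max_mismatch,
    )
    ortho_tags = {tag for calls in orthologs.values() for tag, _ in calls}
    _stage("discover")
    params = discover.DiscoveryParams(
        min_reads=config.novel_min_reads,
        min_len=config.novel_len[0],
        max_len=config.novel_len[1],
        mfe_threshold=config.mfe_threshold,
        pairing_fraction=config.pairing_fraction,
        flank=config.flank,
        merge_gap=config.merge_gap,
    )
    novel_input = {
        t: genome_placements[t] for t in unannotated if t not in ortho_tags
    }
    candidates = discover.evaluate_candidates(novel_input, counts, catalog, params)
    passed = [c for c in candidates if c.passed]
    cand_sequences = {f"candidate-{i + 1}": c.mature_sequence for i, c in enumerate(passed)}
    families = discover.assign_families(
        {**{m.name: m.sequence for m in catalog.matures.values()}, **cand_sequences}
    )
    for i, c in enumerate(passed):
        c.family = families.get(f"candidate-{i + 1}")
    with open(outdir / "novel_candidates.txt", "w") as fh:
        fh.write(discover.candidate_report(candidates))
    with open(outdir / "novel_candidates.bed", "w") as fh:
        for c in passed:
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.tier}\t{iv.read_support}\t{iv.strand}\n"
            )

    # ---- summary --------------------------------------------------------
    summary = {
        "schema_version": SCHEMA_VERSION,
        "cascade": cascade,
        "class_reads": dict(sorted(class_summary.reads.items())),
        "class_distinct": dict(sorted(class_summary.distinct.items())),
        "n_mirnas_detected": len(mature_counts),
        "top_mirnas": [
            {"name": r.name, "total_reads": r.total_reads, "rpm": r.rpm}
            for r in expression[:10]
        ],
        "n_candidates": len(candidates),
        "n_candidates_passed": len(passed),
        "candidate_tiers": sorted(c.tier for c in passed),
        "orthologs": {k: sum(c for _, c in v) for k, v in sorted(orthologs.items())},
        "n_fragment_records": len(frag_records),
    }
    blob = json.dumps(summary, sort_keys=True).encode()
    summary["digest"] = hashlib.sha256(blob).hexdigest()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)

    return RunResult(
        cascade, class_summary, expression, profiles, frag_records, candidates,
        orthologs, families, summary,
    )
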