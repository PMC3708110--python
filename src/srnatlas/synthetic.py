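"""Synthetic small RNA library with a ground-truth manifest.

Generates a toy genome, reference catalog and simulated sequencing reads
whose statistical structure emulates a deep-sequenced endothelial small
RNA library: a dominant ~22-nt miRNA peak with one miRNA carrying about a
third of miRNA-mapped reads (weights are taken from the published
expression table shipped with the package), a minor 28-30 nt peak from a
snoRNA cluster and a multi-copy tRNA family, per-miRNA isomiR offset
distributions, tiny star-arm fractions, a rare positional A-to-G variant,
planted novel hairpins, shuffled-sequence decoys and one "foreign-only"
mature for ortholog detection.  Roughly half the raw reads are short
GC-rich inserts removed by the length filter, mirroring real libraries.

Everything is driven by a single integer seed; building the same manifest
twice yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from .fold import fold_hairpin
from .seqio import RawRead, revcomp

__all__ = [
    "ADAPTER",
    "Manifest",
    "RealizedTruth",
    "default_manifest",
    "build_genome",
    "simulate_reads",
    "dinucleotide_shuffle",
]

ADAPTER = "TCGTATGCCGTCTTCTGCTTG"  # 21-nt 3' sequencing adapter
_FILLER = "ACACGACGCTCTTCCGATCTACACGACGCTCTTCCGATCT"  # constant post-adapter carryover
READ_LENGTH = 36
LOOP_LEN = 12


def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle preserving the dinucleotide composition (random Eulerian walk)."""
    for _ in range(100):
        edges: dict[str, list[str]] = {}
        for a, b in zip(seq, seq[1:]):
            edges.setdefault(a, []).append(b)
        for v in edges.values():
            rng.shuffle(v)
        out = [seq[0]]
        ok = True
        for _ in range(len(seq) - 1):
            nxt = edges.get(out[-1])
            if not nxt:
                ok = False
                break
            out.append(nxt.pop())
        if ok and "".join(out) != seq:
            return "".join(out)
    return seq[::-1]  # degenerate composition; fall back to reversal


# ---------------------------------------------------------------------------
# manifest


@dataclass
class Manifest:
    """Planted features and study-scale weights; JSON-serializable."""

    seed: int
    adapter: str = ADAPTER
    read_length: int = READ_LENGTH
    error_rate: float = 5e-4  # per-base substitution probability
    # raw-read composition: the remainder is the annotated block
    raw_weights: dict = field(default_factory=lambda: {"short_junk": 0.47, "junk_random": 0.015})
    # read-weight of each ncRNA class within the annotated block
    class_weights: dict = field(
        default_factory=lambda: {
            "miRNA": 0.873,
            "snoRNA": 0.078,
            "tRNA": 0.028,
            "rRNA": 0.012,
            "snRNA": 0.005,
            "miscRNA": 0.004,
        }
    )
    mirnas: list = field(default_factory=list)
    snorna_cluster: list = field(default_factory=list)
    trna: dict = field(default_factory=dict)
    other_hosts: list = field(default_factory=list)
    novels: list = field(default_factory=list)
    decoys: list = field(default_factory=list)
    foreign: list = field(default_factory=list)
    short_junk_seqs: list = field(default_factory=list)
    junk_random_seqs: list = field(default_factory=list)

    @property
    def raw_annotated(self) -> float:
        extra = sum(x["raw_weight"] for x in self.novels + self.decoys + self.foreign)
        return 1.0 - self.raw_weights["short_junk"] - self.raw_weights["junk_random"] - extra

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _make_precursor(rng: np.random.Generator, mature: str, arm: str) -> dict:
    """Embed a mature in a fully base-paired stem-loop with duplex-geometry star.

    The stem is the mature against its exact reverse complement; the star
    carries the canonical 2-nt 3' overhang.  Folding is verified (MFE at or
    below -25 kcal/mol, single terminal loop, tight one-arm pairing).
    """
    loop = _rand_seq(rng, LOOP_LEN)
    lead, tail = _rand_seq(rng, 2), _rand_seq(rng, 2)
    # imperfect stem: real precursors carry internal mismatches, and they
    # keep the mature from being its own antisense match on the star arm
    opp = list(revcomp(mature))
    for pos in rng.choice(np.arange(4, len(opp) - 4), size=2, replace=False):
        opp[pos] = str(rng.choice([b for b in "ACGT" if b != opp[pos]]))
    opp_arm = "".join(opp)
    if arm == "5p":
        prec = lead + mature + loop + opp_arm + tail
        ms = 2
        star = opp_arm[2:] + tail
    else:
        prec = lead + opp_arm + loop + mature + tail
        ms = 2 + len(mature) + LOOP_LEN
        star = prec[4 : 4 + len(mature)]
    return {
        "precursor": prec,
        "mature_start": ms,
        "mature_end": ms + len(mature),
        "star": star,
        "arm": arm,
        "loop": loop,
    }


def _planted_hairpin(rng: np.random.Generator, length: int = 22, arm: str = "5p",
                     seed7: str | None = None, edit_pos: int | None = None) -> dict:
    """Rejection-sample a mature whose precursor passes the structure filter."""
    for _ in range(60):
        mature = _rand_seq(rng, length)
        if seed7 is not None:
            mature = mature[0] + seed7 + mature[8:]
        if edit_pos is not None:
            mature = mature[:edit_pos] + "A" + mature[edit_pos + 1 :]
        hp = _make_precursor(rng, mature, arm)
        f = fold_hairpin(hp["precursor"])
        if (
            f.mfe <= -25.0
            and f.n_hairpin_loops == 1
            and f.pairing_fraction(hp["mature_start"], hp["mature_end"]) >= 0.75
            and f.one_arm(hp["mature_start"], hp["mature_end"])
        ):
            hp["mature"] = mature
            return hp
    raise RuntimeError("could not construct a valid planted hairpin")


DEFAULT_ISOMIR_DIST = {"0,0": 0.5, "0,-1": 0.25, "0,1": 0.15, "0,-2": 0.1}


def default_manifest(seed: int = 0, n_mirnas: int = 25) -> Manifest:
    """Manifest emulating the study-scale library structure (see module doc)."""
    from .quantify import load_published_expression

    rng = np.random.default_rng(seed)
    man = Manifest(seed=seed)

    # --- miRNAs: abundance skew from the published table -----------------
    pub = load_published_expression()
    top = pub["rpm"].to_numpy()[: n_mirnas - 1] / 1e6
    weights = list(top) + [1.0 - float(top.sum())]
    family_seed = _rand_seq(rng, 7)  # shared by a planted 4-member family
    used: set[str] = set()
    for i, w in enumerate(weights):
        arm = "3p" if i % 4 == 3 else "5p"
        seed7 = family_seed if i in (20, 21, 22) else None
        edit_pos = 5 if i == 10 else None
        while True:
            hp = _planted_hairpin(rng, 22, arm, seed7, edit_pos)
            if hp["mature"] not in used:
                break
        used.add(hp["mature"])
        if i == 0:
            iso = {"0,-1": 0.6, "0,0": 0.25, "0,1": 0.1, "0,-2": 0.05}
            sf = 27 / (2318344 + 27)
        elif i == 2:
            iso = {"-1,0": 0.5, "0,0": 0.3, "0,-1": 0.2}
            sf = 83798 / (1014272 + 83798)
        elif i == 10:
            iso = {"0,0": 1.0}
            sf = 0.01
        else:
            iso = dict(DEFAULT_ISOMIR_DIST)
            sf = 0.01
        n_loci = 2 if i == 1 else 1
        names = (
            [f"syn-mir-{i + 1}"]
            if n_loci == 1
            else [f"syn-mir-{i + 1}-1", f"syn-mir-{i + 1}-2"]
        )
        man.mirnas.append(
            {
                "name": "//".join(sorted(names)),
                "precursor_names": names,
                "strand": "-" if i == 5 else "+",
                "weight": float(w),
                "isomir_dist": iso,
                "star_fraction": float(sf),
                "editing": {"pos": 5, "frac": 0.03} if i == 10 else None,
                **hp,
            }
        )

    # --- snoRNA cluster (host lengths 70-90; one dominant 3'-arm product) -
    lengths = [88, 70, 75, 80, 72]
    frag_plans = [
        [(-28, None, 0.60), (0, 26, 0.08)],
        [(0, 26, 0.04), (-27, None, 0.04)],
        [(0, 26, 0.04), (-27, None, 0.04)],
        [(0, 26, 0.04), (-27, None, 0.04)],
        [(0, 26, 0.04), (-27, None, 0.04)],
    ]
    for k, (L, plan) in enumerate(zip(lengths, frag_plans)):
        seq = _rand_seq(rng, L)
        frags = []
        for s, e, w in plan:
            if s < 0:
                s, e = L + s, L
            frags.append({"start": int(s), "end": int(e), "weight": float(w)})
        man.snorna_cluster.append(
            {
                "name": f"SYNORD{70 + k}",
                "sequence": seq,
                "strand": "-" if k == 3 else "+",
                "fragments": frags,
            }
        )

    # --- multi-copy tRNA family with a 5' fragment ------------------------
    trna_seq = _rand_seq(rng, 72)
    man.trna = {
        "family": "Gly-GCC",
        "n_genes": 9,
        "sequence": trna_seq,
        "fragment": {"start": 0, "end": 30, "weight": 1.0},
    }

    # --- other host classes ----------------------------------------------
    for name, cls_, L, (fs, fe) in (
        ("syn-rRNA-1", "rRNA", 120, (10, 32)),
        ("syn-snRNA-1", "snRNA", 100, (0, 24)),
        ("syn-miscRNA-1", "miscRNA", 90, (30, 52)),
    ):
        man.other_hosts.append(
            {
                "name": name,
                "class": cls_,
                "sequence": _rand_seq(rng, L),
                "fragment": {"start": fs, "end": fe, "weight": 1.0},
            }
        )

    # --- novel hairpins, decoys, foreign-only mature ----------------------
    for k in range(3):
        seed7 = family_seed if k == 0 else None
        hp = _planted_hairpin(rng, 22, "5p", seed7)
        man.novels.append(
            {
                "name": f"syn-novel-{k + 1}",
                "strand": "-" if k == 2 else "+",
                "raw_weight": 0.0015,
                "star_fraction": 0.1 if k < 2 else 0.0,
                "isomir_dist": {"0,0": 0.8, "0,-1": 0.2},
                **hp,
            }
        )
    for k in range(5):
        src = man.mirnas[k]["mature"]
        man.decoys.append(
            {
                "name": f"syn-decoy-{k + 1}",
                "sequence": dinucleotide_shuffle(src, rng),
                "strand": "-" if k == 2 else "+",
                "raw_weight": 0.001,
            }
        )
    fhp = _planted_hairpin(rng, 22, "5p")
    man.foreign.append(
        {"name": "hsa-syn-mir-901", "raw_weight": 0.001, "isomir_dist": {"0,0": 1.0}, **fhp}
    )

    # --- junk -------------------------------------------------------------
    man.short_junk_seqs = sorted({_rand_seq(rng, 7, "GGCCGCA") for _ in range(8)})
    man.junk_random_seqs = [_rand_seq(rng, 20) for _ in range(30)]
    return man


# ---------------------------------------------------------------------------
# genome construction


def build_genome(manifest: Manifest, outdir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, GFF3/BED annotations, mature FASTAs and manifest.

    Planted loci are recorded back into the manifest (chrom/start/end per
    feature) before it is serialized.  Deterministic given the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(manifest.seed + 1)
    genome: dict[str, str] = {}
    gff_rows: list[tuple] = []  # (chrom, class, start0, end0, strand, id)
    bed_rows: list[tuple] = []

    def build_chrom(name: str, features: list[tuple[str, str, str, str]], spacer: int) -> None:
        # features: (feature id, class or "" for unannotated, seq 5'->3', strand)
        parts = [_rand_seq(rng, spacer)]
        pos = spacer
        for fid, cls_, seq, strand in features:
            emb = revcomp(seq) if strand == "-" else seq
            parts.append(emb)
            start, end = pos, pos + len(seq)
            if cls_:
                if cls_ == "tRNA":
                    bed_rows.append((name, start, end, fid, 0, strand))
                else:
                    gff_rows.append((name, cls_, start, end, strand, fid))
            _record_locus(manifest, fid, name, start, end)
            pos = end
            parts.append(_rand_seq(rng, spacer))
            pos += spacer
        genome[name] = "".join(parts)

    feats1 = []
    for m in manifest.mirnas:
        for pname in m["precursor_names"]:
            feats1.append((pname, "miRNA", m["precursor"], m["strand"]))
    build_chrom("chr1", feats1, 60)

    feats2 = [
        (s["name"], "snoRNA", s["sequence"], s["strand"]) for s in manifest.snorna_cluster
    ]
    for g in range(manifest.trna["n_genes"]):
        feats2.append((f"tRNA-Gly-GCC-1-{g + 1}", "tRNA", manifest.trna["sequence"], "+"))
    for h in manifest.other_hosts:
        feats2.append((h["name"], h["class"], h["sequence"], "+"))
    build_chrom("chr2", feats2, 120)

    feats3 = [(n["name"], "", n["precursor"], n["strand"]) for n in manifest.novels]
    feats3 += [(d["name"], "", d["sequence"], d["strand"]) for d in manifest.decoys]
    feats3 += [(f["name"], "", f["precursor"], "+") for f in manifest.foreign]
    build_chrom("chr3", feats3, 250)

    paths = {
        "genome": outdir / "genome.fasta",
        "gff": outdir / "annotations.gff3",
        "trna_bed": outdir / "trna.bed",
        "matures": outdir / "matures.fasta",
        "foreign": outdir / "foreign_matures.fasta",
        "manifest": outdir / "manifest.json",
    }
    seqio.write_fasta(genome, paths["genome"])
    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, cls_, start, end, strand, fid in gff_rows:
            fh.write(
                f"{chrom}\tsynthetic\t{cls_}\t{start + 1}\t{end}\t.\t{strand}\t.\tID={fid};Name={fid}\n"
            )
    with open(paths["trna_bed"], "w") as fh:
        for chrom, start, end, fid, score, strand in bed_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{fid}\t{score}\t{strand}\n")
    matures = {}
    for m in manifest.mirnas:
        for pname in m["precursor_names"]:
            matures[pname] = m["mature"]
    seqio.write_fasta(matures, paths["matures"])
    seqio.write_fasta({f["name"]: f["mature"] for f in manifest.foreign}, paths["foreign"])
    manifest.to_json(paths["manifest"])
    return paths


def _record_locus(manifest: Manifest, fid: str, chrom: str, start: int, end: int) -> None:
    for group in (manifest.mirnas, manifest.novels, manifest.decoys, manifest.foreign,
                  manifest.snorna_cluster, manifest.other_hosts):
        for item in group:
            names = item.get("precursor_names", [item.get("name")])
            if fid in names or fid == item.get("name"):
                item.setdefault("loci", {})[fid] = [chrom, start, end]
    if fid.startswith("tRNA-"):
        manifest.trna.setdefault("loci", {})[fid] = [chrom, start, end]


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class RealizedTruth:
    """Exact post-simulation ground truth for one generated library."""

    templates: list  # dicts: feature, kind, insert, count (error-free reads)
    n_error_reads: int
    n_reads: int
    expected_cascade: dict = field(default_factory=dict)

    def counts_by(self, kind: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.templates:
            if t["kind"] == kind:
                out[t["feature"]] = out.get(t["feature"], 0) + t["count"]
        return out

    def offset_counts(self, feature: str) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for t in self.templates:
            if t["feature"] == feature and t["kind"] == "mirna":
                key = tuple(int(x) for x in t["subtype"].split(","))
                out[key] = out.get(key, 0) + t["count"]
        return out


def _isomir_insert(item: dict, o5: int, o3: int) -> str:
    s, e = item["mature_start"] - o5, item["mature_end"] + o3
    return item["precursor"][s:e]


def _templates(manifest: Manifest) -> list[dict]:
    """Expand the manifest into (insert, probability) templates."""
    T: list[dict] = []
    ann = manifest.raw_annotated
    cw = manifest.class_weights

    def add(feature: str, kind: str, subtype: str, insert: str, p: float) -> None:
        if p > 0:
            T.append({"feature": feature, "kind": kind, "subtype": subtype, "insert": insert, "p": p})

    for s in manifest.short_junk_seqs:
        add("short_junk", "junk", "", s, manifest.raw_weights["short_junk"] / len(manifest.short_junk_seqs))
    for s in manifest.junk_random_seqs:
        add("junk_random", "junk", "", s, manifest.raw_weights["junk_random"] / len(manifest.junk_random_seqs))

    for m in manifest.mirnas:
        base = ann * cw["miRNA"] * m["weight"]
        sf = m["star_fraction"]
        edit = m.get("editing")
        for key, p in m["isomir_dist"].items():
            o5, o3 = (int(x) for x in key.split(","))
            insert = _isomir_insert(m, o5, o3)
            pm = base * (1 - sf) * p
            pos = edit["pos"] + o5 if edit else -1  # edited base's index in the tag
            if edit and 0 <= pos < len(insert):
                ed_insert = insert[:pos] + "G" + insert[pos + 1 :]
                add(m["name"], "mirna", key, insert, pm * (1 - edit["frac"]))
                add(m["name"], "mirna_edited", key, ed_insert, pm * edit["frac"])
            else:
                add(m["name"], "mirna", key, insert, pm)
        add(m["name"], "star", "", m["star"], base * sf)

    for s in manifest.snorna_cluster:
        for fr in s["fragments"]:
            add(
                s["name"], "sno_fragment", f"{fr['start']},{fr['end']}",
                s["sequence"][fr["start"] : fr["end"]],
                ann * cw.get("snoRNA", 0.0) * fr["weight"],
            )
    fr = manifest.trna["fragment"]
    add(
        "tRNA-" + manifest.trna["family"], "trf", f"{fr['start']},{fr['end']}",
        manifest.trna["sequence"][fr["start"] : fr["end"]],
        ann * cw.get("tRNA", 0.0) * fr["weight"],
    )
    for h in manifest.other_hosts:
        fr = h["fragment"]
        add(
            h["name"], "host_fragment", f"{fr['start']},{fr['end']}",
            h["sequence"][fr["start"] : fr["end"]],
            ann * cw.get(h["class"], 0.0) * fr["weight"],
        )

    for n in manifest.novels:
        sf = n["star_fraction"]
        for key, p in n["isomir_dist"].items():
            o5, o3 = (int(x) for x in key.split(","))
            add(n["name"], "novel", key, _isomir_insert(n, o5, o3), n["raw_weight"] * (1 - sf) * p)
        if sf > 0:
            add(n["name"], "novel_star", "", n["star"], n["raw_weight"] * sf)
    for d in manifest.decoys:
        add(d["name"], "decoy", "", d["sequence"], d["raw_weight"])
    for f in manifest.foreign:
        add(f["name"], "foreign", "", f["mature"], f["raw_weight"])
    return T


def simulate_reads(
    manifest: Manifest,
    n_reads: int,
    seed: int | None = None,
    out_fastq: str | Path | None = None,
) -> tuple[list[RawRead], RealizedTruth]:
    """Draw a library of ``n_reads`` machine reads plus exact ground truth.

    Each read is ``insert + adapter (+ constant carryover)`` truncated to
    the machine read length, with per-base substitution errors at the
    manifest rate.  The realized truth records error-free counts per
    template and the cascade statistics the processing pipeline should
    reproduce exactly.
    """
    rng = np.random.default_rng(manifest.seed if seed is None else seed)
    T = _templates(manifest)
    probs = np.array([t["p"] for t in T])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_reads, probs)

    per_read_err = 1.0 - (1.0 - manifest.error_rate) ** manifest.read_length
    machine: list[str] = []
    truth_templates = []
    n_error = 0
    bases = np.array(list("ACGT"))
    for t, c in zip(T, counts):
        full = (t["insert"] + manifest.adapter + _FILLER)[: manifest.read_length]
        n_err = rng.binomial(c, per_read_err) if c else 0
        clean = int(c - n_err)
        machine.extend([full] * clean)
        for _ in range(n_err):
            pos = int(rng.integers(len(full)))
            alt = [b for b in "ACGT" if b != full[pos]]
            machine.append(full[:pos] + str(rng.choice(alt)) + full[pos + 1 :])
        n_error += n_err
        truth_templates.append({**{k: t[k] for k in ("feature", "kind", "subtype", "insert")}, "count": clean})

    order = rng.permutation(len(machine))
    reads = [RawRead(f"read{i}", machine[j]) for i, j in enumerate(order)]

    truth = RealizedTruth(truth_templates, int(n_error), n_reads)
    truth.expected_cascade = _expected_cascade(manifest, reads)
    if out_fastq is not None:
        seqio.write_fastq(reads, out_fastq)
    return reads, truth


def _expected_cascade(manifest: Manifest, reads: list[RawRead]) -> dict:
    """Cascade statistics (raw -> >15 nt -> unique -> >=3 reads) for a library."""
    clipped = list(seqio.clip_adapters(reads, manifest.adapter))
    kept = list(seqio.length_filter_reads(clipped, 15))
    lib = seqio.collapse(kept)
    filt, summary = seqio.abundance_filter(lib, 3)
    return {
        "raw_reads": len(reads),
        "reads_gt15": len(kept),
        "unique_gt15": lib.n_unique,
        "unique_min3": filt.n_unique,
        "retained_read_fraction": summary["retained_read_fraction"],
    }
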