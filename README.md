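# srnatlas

Small non-coding RNA deep-sequencing analysis: from raw Illumina-style
reads to quantified microRNAs and isomiRs, ncRNA class composition,
snoRNA-derived small RNAs (sno-miRNAs), 5' tRNA fragments, and novel
miRNA hairpin candidates.

## Who this is for

Deep sequencing of a small RNA library (gel-selected ~18-30 nt RNAs with
a ligated 3' adapter) is the standard way to profile the microRNA
repertoire of a cell type without prior sequence knowledge — for example
primary microvascular endothelial cells, where a handful of miRNAs
(miR-21, let-7f, miR-126) dominate the library.  `srnatlas` implements
the complete downstream analysis as a tested, deterministic Python
library with a thin CLI, plus a synthetic-library generator with a
ground-truth manifest so every stage can be verified end to end without
any external download.

## The analysis

1. **Read cascade** — clip the 3' adapter (exact match, configurable
   minimum overlap), keep inserts **> 15 nt**, collapse reads into unique
   tags with multiplicities, and drop tags seen **< 3** times (singleton
   tags are dominated by sequencing error; nearly all *reads* survive the
   filter even though most unique *sequences* do not).
2. **Mapping** — tags are placed on mature/precursor miRNA references and
   on the genome with at most 0-2 substitutions (no indels).  All
   placements in the best stratum (minimum mismatch count) are reported.
   A pigeonhole-seeded exact k-mer index guarantees full sensitivity; an
   exhaustive sliding-window oracle certifies it in the tests.
3. **Annotation** — each tag is assigned to one ncRNA class
   (miRNA > snoRNA > tRNA > snRNA > rRNA > miscRNA precedence) and the
   library composition is summarized by distinct features and by reads.
4. **isomiRs** — per mature miRNA, tags are classified by signed 5'/3'
   offsets (`sub` shorter / `mature` / `super` longer), attributed to the
   mature or star arm (star intervals are inferred from the precursor
   fold with 2-nt 3'-overhang duplex geometry when unannotated), and
   profiled per position for variants such as A-to-G transitions.
5. **Fragments** — snoRNA/tRNA-derived small RNAs are recorded per host
   with a quartile arm rule; multi-copy tRNA genes aggregate to anticodon
   families (a tag matching nine Gly-GCC genes is counted once).
6. **Novel miRNA discovery** — expressed intervals not overlapping any
   annotation are folded (built-in stacking-energy MFE folder) and pass if
   read support > 100, dominant length 21-23 nt, MFE <= -25 kcal/mol, a
   single hairpin loop, and tight one-arm pairing of the mature
   (fraction >= 0.75).  Candidates with reads at the expected star
   position are tiered `star_supported`, otherwise `structure_only`.
   Orthologs of foreign (e.g. human) matures are called separately by
   near-exact match with an exact seed (positions 2-8), and candidates
   sharing a seed are grouped into families.
7. **Quantification** — reads per million mapped
   (`RPM = count / miRNA-mapped total * 1e6`), library fractions, and
   qPCR relative expression `2^-dCt` with `dCt = Ct(miRNA) - Ct(5S rRNA)`.

## Worked example

```python
from pathlib import Path
from srnatlas import default_manifest, build_genome, simulate_reads, RunConfig, run_all

work = Path("scratch/demo"); work.mkdir(parents=True, exist_ok=True)
man = default_manifest(seed=1)                 # study-scale planted truth
paths = build_genome(man, work)                # genome.fasta, annotations.gff3, ...
simulate_reads(man, 200_000, out_fastq=work / "reads.fastq")

result = run_all(RunConfig(
    fastq=str(work / "reads.fastq"),
    mirna_fasta=str(paths["matures"]),
    genome_fasta=str(paths["genome"]),
    annotation_gff=str(paths["gff"]),
    trna_bed=str(paths["trna_bed"]),
    foreign_mature_fasta=str(paths["foreign"]),
    outdir=str(work / "run"),
))
print(result.cascade)
print({k: round(v, 3) for k, v in result.class_summary.fractions.items()})
print([(r.name, r.total_reads, r.rpm) for r in result.expression[:3]])
```

prints (seed 1):

```
{'raw_reads': 200000, 'reads_gt_min_len': 107341, 'unique_sequences': 1985,
 'unique_min_count': 456, 'retained_read_fraction': 0.98269...}
{'miRNA': 0.874, 'snoRNA': 0.078, 'rRNA': 0.012, 'tRNA': 0.027, 'snRNA': 0.005, 'miscRNA': 0.004}
[('syn-mir-1', 29440, 344110.2), ('syn-mir-2-1//syn-mir-2-2', 13413, 156778.2),
 ('syn-mir-3', 11923, 139362.3)]
```

Half the raw reads are short GC-rich inserts removed by the length
filter; of the surviving unique tags fewer than a quarter are seen three
or more times, yet those carry ~98% of the reads.  miRNAs account for ~87% of
annotated reads, the heaviest planted miRNA alone for ~34% — the
skew the generator plants from the published endothelial expression
table — and the pipeline also reports the planted snoRNA-cluster
fragments, the nine-gene Gly-GCC 5' tRNA fragment family, three novel
hairpin candidates (two star-supported) and one foreign-mature ortholog.

The same stages are available from the shell:

```bash
srnatlas simulate --seed 1 --n-reads 200000 --outdir scratch/demo
srnatlas run --config run.yaml
srnatlas clip reads.fastq --out clipped.fastq
srnatlas collapse clipped.fastq --out library.tsv
srnatlas filter library.tsv --min-count 3 --min-len 15 --out filtered.tsv
```

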