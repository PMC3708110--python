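# Methods

This note documents the models, parameter choices and numerical details
behind `srnatlas`, and what the synthetic-library tests do and do not
demonstrate about real data.

## Read processing

A machine read is modeled as `insert + 3' adapter (+ downstream
carryover)` truncated to the read length.  Adapter clipping is **exact**:
the leftmost occurrence of the full adapter, or of an adapter prefix of
at least `min_overlap` bases (default 6) ending at the read's 3' end, is
removed.  No mismatch tolerance and no quality-based trimming are
applied; with a per-base error rate around 0.05% the handful of reads
whose error falls in the adapter remain unclipped and are discarded
downstream as unmappable, which is the correct fate for them.  Adapter
dimers (empty inserts) are replaced by a single-`N` sentinel and removed
by the length filter rather than raised as errors mid-stream.

Boundary semantics are deliberately strict and asymmetric, matching the
way such cascades are usually reported: the length filter keeps inserts
**strictly longer** than `min_len` (default 15 nt), while the abundance
filter keeps tags with **at least** `min_count` reads (default 3, i.e.
"remove tags seen < 3 times"; the stricter "> 10 reads" variant used for
compact supplementary listings corresponds to `min_count=11`).  The
abundance filter's rationale is statistical, not biological: tags seen
once or twice are dominated by sequencing error, so removing them
collapses the unique-sequence list severalfold while retaining ~97-98%
of reads.

## Mapping model

Tags are placed on references (mature/precursor sequences, host ncRNAs,
genome) allowing 0-2 **substitutions only**.  Indels are not modeled:
isomiR analysis is an offset/substitution problem, and an indel-tolerant
aligner would conflate a 3'-shortened isomiR with a gapped alignment of
the full-length form.  For each tag all placements in the best stratum
(the minimum observed mismatch count) are reported, because a small RNA
can be legitimately encoded by several loci (multi-copy tRNAs, duplicated
miRNA precursors); choosing one would silently mis-assign counts.

Candidate positions come from a pigeonhole seed: a tag aligned with at
most `m` mismatches must contain at least one of `m+1` non-overlapping
segments exactly, so exact lookup of those segments in a k-mer index of
the references is lossless.  Correctness is certified by equivalence to a
brute-force sliding-window Hamming scan (numpy) over a thousand random
tag/reference pairs per test run — the guarantee rests on the oracle, not
on the seeding heuristic.  Tags containing `N` never seed and are
reported unplaced.  Default budgets: 1 mismatch against curated
references, 0 against the genome (used for novel-locus pileups, where
conservatism matters more than sensitivity).

## Annotation

Each tag is assigned to exactly one ncRNA class by overlapping its
best-stratum genome placements (strand-aware) with the annotation
catalog; a configurable precedence list (miRNA > snoRNA > tRNA > snRNA >
rRNA > mt_rRNA > mt_tRNA > miscRNA) resolves multi-class overlaps, with
ties broken by mismatch count then annotation id.  Assignment is a
partition — the tag's whole count flows to one class — so class read
fractions sum to one over annotated reads.  GFF3 input is 1-based
inclusive and converted internally to 0-based half-open; BED stays
0-based half-open; minus-strand features are reverse-complemented on
extraction so feature sequences always read 5'→3'.

## isomiRs and arms

Offsets are signed with negative meaning *shorter* at that end
(`offset3 = -1` for a tag one base short at the 3' end, class `sub`;
positive = `super`; 0 = `mature`).  A tag is attributed to an arm if its
5' end lies within `offset_window` (default 5 nt) of that arm's 5'
boundary, nearest boundary winning ties; tags outside every window (loop
fragments) are left unassigned.  Because most non-model-organism catalogs
lack star entries, an unannotated star arm is inferred from the
precursor's MFE fold using Dicer duplex geometry: the star's 5' end is
the pairing partner of the base two inside the mature's 3' end (2-nt 3'
overhang), with adjacent paired bases consulted when that base is
unpaired.  Non-templated 3' additions (a `super` 3' end that mismatches
the precursor template) are flagged on the record rather than split into
a separate class.  Positional variant profiles are read-weighted base
counts over mature coordinates; positions whose reference base is A
additionally report the G fraction, the signature of A-to-I editing.

## RNA folding

The built-in folder computes a minimum-"energy" secondary structure
under a deliberately simplified model: legal pairs AU/GC/GU, minimum
hairpin loop 3, energy = sum of nearest-neighbor stacking terms (a 36
-entry table of rough Turner-like values between -0.3 and -3.4 kcal/mol,
see `STACK_TABLE` in `srnatlas/fold.py`) plus a **helix nucleation
penalty of +3.5 kcal/mol per maximal helix**.  Loop-length terms,
dangles and coaxial stacking are omitted.  The model is a stem detector
for pre-miRNA-sized hairpins, not a general thermodynamic folder; its
absolute energies are calibrated only to the extent that a canonical
~22-bp miRNA stem scores around -30 to -45 kcal/mol, comfortably below
the -25 kcal/mol candidate threshold, while random sequence rarely does.
The dynamic program (two-matrix, O(n³), numba-accelerated with a pure
-python fallback) is exactly solvable and verified against independent
exhaustive enumeration of all legal pair sets on sequences up to 25 nt;
an adapter class can substitute an external `RNAfold` executable for
thermodynamic parity without touching any candidate logic.  The candidate
filter reads the stability threshold "free energy below 25 kcal/mol" as
ΔG ≤ -25 kcal/mol (magnitude), the only physically sensible sign.

## Novel miRNA discovery

Unannotated tags (after removing tags explained as orthologs of foreign
matures, which are handled by a separate near-exact match requiring an
exact seed) are merged into strand-specific expressed intervals
(single-linkage, gap ≤ 10 nt).  Around each interval a grid of frames
(0-60 nt extensions in 20-nt steps per side, frame length clipped to
40-120 nt) is folded and the best frame kept, preferring a single
hairpin loop, then higher mature pairing fraction, then lower MFE.  The
flank size and the grid step are the package's own choices — large
enough to capture a star arm on either side of a 22-nt product, small
enough that discovery over thousands of intervals stays cheap.  A
candidate passes if **all** of: read support > 100; dominant tag length
21-23 nt; MFE ≤ -25 kcal/mol; exactly one hairpin loop; mature pairing
fraction ≥ 0.75 with all partners on a single opposite arm.  The pairing
-fraction threshold (0.75) encodes "tight binding of the mature to one
side of a single hairpin" numerically.  Reads whose 5' end falls within
±2 nt of the geometric star position upgrade the candidate to
`star_supported` — the stronger evidence tier, since a recovered
mature/star duplex is the processing signature of a genuine precursor.

## Quantification

RPM uses the total of miRNA-mapped reads as denominator by default (so
per-miRNA RPM sums to one million); an `all_mapped` mode is available.
Reported RPM is rounded to one decimal and percentages to whole numbers.
For a published table printed as (count, RPM) rows, the implied
denominator can be recovered as the intersection of the per-row intervals
`count·1e6/(rpm±0.05)`; the shipped endothelial table yields a single
integer consistent with every row, which the desk checks exploit.  qPCR
relative expression is `2^-ΔCt` with ΔCt = Ct(target) − Ct(reference
5S rRNA); no primer-efficiency modeling.

## Synthetic library generator

The generator is the package's study-conditions oracle.  Defaults:

* **Raw composition** — 47% short GC-rich inserts (7 nt), 1.5% random
  unmappable 20-mers, ~1% unannotated features (novel hairpins, decoys,
  a foreign-only mature), remainder annotated ncRNA reads.  This mirrors
  real libraries in which roughly half the raw reads fail the >15 nt
  filter.
* **Class weights** (within annotated reads) — miRNA 0.873,
  snoRNA 0.078, tRNA 0.028, rRNA 0.012, snRNA 0.005, miscRNA 0.004.
* **miRNA abundance skew** — within-miRNA weights are the top-24 RPM
  fractions of the shipped published endothelial expression table plus
  one remainder entry, so the heaviest planted miRNA carries ~33.9% of
  miRNA-mapped reads and the tail follows the empirical skew.  One miRNA
  is encoded by two identical precursors to exercise `//`-merged naming.
* **isomiR distributions** — default {(0,0): 0.5, (0,-1): 0.25,
  (0,+1): 0.15, (0,-2): 0.1}; the top miRNA plants a dominant 3'-1 form
  (0.6), the third a dominant 5' variant, matching the qualitative
  observation that the most abundant isomiR often differs from the
  catalog entry.
* **Star fractions** — 27/2,318,371 for the top miRNA (extremely
  specific processing), 0.0763 for the miR-126-like third, 0.01
  elsewhere; star sequences carry the 2-nt 3'-overhang geometry.
* **Editing** — one mid-abundance miRNA carries a planted A→G at mature
  position 5 in 3% of its reads.
* **Hosts** — a 5-member snoRNA cluster (70-88 nt members, one dominant
  28-nt 3'-arm product at 60% of snoRNA reads, both arms populated on
  every member), a 9-copy identical tRNA-Gly-GCC family with a 30-nt 5'
  fragment, plus one rRNA/snRNA/miscRNA host each.
* **Structure truth** — planted precursors are `lead + mature + loop(12)
  + imperfect-revcomp(mature) + tail` with two stem mismatches
  (rejection-sampled until MFE ≤ -25, one loop, pairing ≥ 0.75).  The
  mismatches both add realism and prevent a mature from matching its own
  star arm antisense.  Decoys are dinucleotide-shuffled matures (random
  Eulerian walk) embedded without hairpin context at >100 reads, so they
  pass the expression filters and must be rejected on structure alone.
* **Errors** — uniform per-base substitutions at 5·10⁻⁴; read length 36;
  a fixed documented 21-mer adapter.

A single integer seed drives one RNG stream; building the same manifest
twice yields byte-identical files.  `simulate_reads` returns an exact
realized truth (error-free counts per planted template and the cascade
statistics the pipeline must reproduce), so cascade checks are exact
while distributional checks use binomial bounds.

**What the generator does not emulate:** ligation bias (real libraries
over/under-represent sequences by adapter ligation efficiency), quality
-score structure, indels, cross-mapping between paralogous miRNA
families, and genome-scale multi-mapping.  Passing tests therefore show
the *pipeline logic* is correct under the study's statistical structure,
not that the thresholds are optimal for any particular real library.

## Problem sizes

The shipped verification runs use a ~12-kb three-chromosome toy genome,
25 planted miRNAs, 200,000-read libraries for parameter-recovery and
discovery checks (20 seeds), 30,000-read libraries for the 10-seed
cascade-determinism check, 1,000 random tag/reference pairs for aligner
oracle equivalence and 200 sequences (≤25 nt) for folder oracle
equivalence — sizes chosen so the whole suite verifies every stage in a
few minutes on one core while keeping binomial error bands a few times
smaller than the effects being checked.

## Known limitations

* The folding energies are heuristic; absolute MFE values are not
  comparable to thermodynamic folders (use the `RNAfold` adapter where
  physical energies matter).
* Exact adapter matching slightly undercounts in high-error data.
* Sequencing-error variants of very abundant tags can individually
  exceed the 3-read filter; they map back to the parent miRNA within the
  mismatch budget and are counted as (rare, mismatched) isomiRs, which
  inflates high-abundance features by ~1% relative to low-abundance
  ones — visible in the recovery tests' tolerance bands.
* Single-library design: no replicates, no differential expression.
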