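# Methods

`homasm` assembles the transcriptome of an allopolyploid while keeping
homoeologs — the near-identical gene copies contributed by the parental
genomes (A, B and D in hexaploid bread wheat) — in separate contigs, and
evaluates how well that separation worked.  Everything runs at desk scale
on synthetic data with known ground truth; this note records the models,
the parameters that matter, and the design decisions taken where the
problem was genuinely open.

## The separation problem

Homoeologs in wheat are on average ~97.2% identical (sd ~1.8%), i.e. one
divergent site every ~36 bases between a pair of copies, or ~71 bases per
copy relative to their common ancestor.  A de-Bruijn-graph assembler whose
k-mer is shorter than the typical spacing between divergent sites cannot
see the difference between copies at graph-construction time and tends to
collapse them into chimeric contigs.  An overlap-layout-consensus (OLC)
assembler that scores whole read overlaps can reject an overlap carrying
~3% divergence, provided reads are long enough that a typical overlap
contains several divergent sites.  `homasm` implements this OLC route and
a two-stage pipeline around it.

## Local alignment (`homasm.align`)

All %ID quantities come from one in-package aligner: exact seeding
(word size 11), grouping of seed diagonals into bands (pad 50 diagonals),
and banded Smith-Waterman extension with affine gaps (match +1,
mismatch −2, gap open −3, gap extend −2; a gap run of length L costs
`open + L·extend`), both strands searched.  %ID is identities divided by
all alignment columns including gaps.  Database E-value cut-offs are
replaced by explicit `(min_aligned_length, min_pct_id, min_score)`
thresholds because E-values depend on database size and are not
reproducible outside a specific search engine.  On instances up to 1 kb
the banded search returns exactly the exhaustive dynamic-programming
optimum; the test suite verifies this against an independent
implementation on hundreds of random mutated-pair instances.
All-vs-all comparisons keep one best hit per unordered pair and demand a
number of shared seed words proportional to the minimum alignment length
before running the DP, which removes the quadratic cost of chance 11-mer
hits between unrelated sequences.

## Synthetic data (`homasm.synth`)

The generator emulates the statistical structure of a normalized
polyploid cDNA sequencing experiment:

* **Families.** Each family draws a target pairwise identity from
  Normal(97.2, 1.8) — rejected below 85, censored at 100 (strict
  rejection at the top would bias the mean down by ~0.23 because a
  noticeable mass of the distribution lies above 100; identical copies
  are biologically real).  Each of 1–3 genome copies independently
  receives half the implied divergence from a shared ancestral
  transcript, placed uniformly at random; 10% of events are 1-base
  indels, the rest substitutions.  Transcript lengths are log-normal
  (median 1300 bases, σ=0.35, clipped to [500, 8000]).
* **Reads.** Long reads are single-ended, length Normal(363.2, 60)
  clipped to [50, transcript length], with 1-base indel errors inside
  homopolymer runs (rate 0.01 per eligible position, i.e. ~0.25% per
  base; constant per-read PHRED reflecting the effective rate, ~Q26).
  Short reads are inward-facing 108-base pairs with inserts uniform in
  [250, 300] and substitution errors rising from 0.05% at the 5' end to
  0.4% at the 3' end; per-base qualities encode exactly the injected
  error probabilities.  Fragment placement mimics a three-population
  cDNA library (5'-terminal, 3'-terminal, internal at 15/15/70%), so
  transcript ends stay covered.
* **Normalization.** Per-copy expression is log-normal (σ=1) with
  coverage capped at 3× the median — the downstream effect of
  duplex-specific-nuclease normalization is reduced coverage skew, which
  is all the assembler ever sees.
* **Truth.** Every read carries its source family, genome copy, 0-based
  half-open coordinates and strand; error-free reads align back to their
  truth interval at 100%.  All sampling is deterministic given the
  config seed, down to byte-identical FASTA/FASTQ/TSV output.

The generator does not model rRNA contamination, splice isoforms,
library chimeras, or platform-specific quality pathologies beyond the
above; passing tests therefore demonstrate algorithmic behaviour under
idealised polyploid structure, not robustness to every artifact of real
libraries.

## Read QC (`homasm.readqc`)

Per read, in fixed order: adapter removal (longest read suffix matching
an adapter prefix with ≤2 mismatches, minimum 8 bases), truncation at
the start of the first run of more than 3 consecutive ambiguous bases or
more than 3 consecutive bases below Q20 (scanning 5'→3'; truncation
drops the 3' remainder, matching degrading-chemistry semantics), then
discard if median quality < 20, then discard if fewer than 50 bases
remain.  The rule order is fixed so each later rule sees the final
retained bases; a read of 49 good bases followed by a long bad tail is
therefore discarded by the *length* rule, not the median rule.  When one
mate of a pair is discarded the survivor is demoted to a single read.
QC is idempotent.

## Clustering (`homasm.cluster`)

Rough contigs sharing at least one exact canonical 32-mer (lexicographic
minimum of the word and its reverse complement — strand of a rough
contig is arbitrary) are merged transitively with union-find; reads join
every cluster they share a canonical 32-mer with, so a read may belong
to several clusters or none.  The partition equals the connected
components of the shared-k-mer graph (verified against an independent
graph library) and is invariant to input order.

## Assembly (`homasm.asm`)

Overlap candidates are seeded by shared 14-mers (query positions are
sampled at stride 7 above 100 reads; overlapping reads share dozens of
seed words, so sensitivity is unaffected at desk scale) and scored by
banded affine DP around the seed diagonals.  An overlap is accepted when
it spans ≥40 columns with *relative score* — DP score divided by the
maximum attainable score `match · columns` — at least 0.97 in strict
mode or 0.90 in permissive mode.  At match +1 / mismatch −2, each
substitution costs 3 points, so a 97%-identical homoeolog overlap scores
~0.91: above the permissive and far below the strict threshold, which is
the entire separation mechanism.

Greedy layout merges best overlaps first.  Because short perfect
overlaps inside conserved windows between homoeologs would still pass
any per-overlap threshold, every merge of two multi-read layouts is
validated: up to 8 implied read overlaps across the junction (largest
first, several partners per sampled read) are re-aligned and the merge
is rejected when their pooled divergence exceeds 1.5% (5% in permissive
mode).  Pooling gives the test statistical power that no single implied
overlap has — same-copy implied overlaps carry only sequencing error
(~0.5%), cross-copy ones ~3%.  This validation, and the conflict-driven
re-assembly below, are this package's own reconstruction of the
multi-pass strategy of quality-aware OLC assemblers, in which each pass
learns about possible mis-assemblies from the previous one.  Mate-pair insert bounds
(1–500) are advisory: violating merges are deferred behind all compliant
ones, then retried.

Consensus is called in two refinement rounds: a naive offset-stacked
draft, then per-read banded glocal realignment to the draft and a
gap-aware quality-weighted pileup, then realignment to the refined
consensus.  Read tips up to the first run of 4 consecutive matches are
clipped before voting, because an indel near a read end cannot be placed
as a gap and would otherwise smear into spurious terminal mismatches.
Per column the winning allele maximises `Σ(1−10^(−q/10))`; its error
probability is the quality-sum likelihood ratio against the strongest
competing allele, `10^((Q_lose−Q_win)/10)`, clipped to
`[10^(−6), 0.5]` (quality cap 60).  A genuinely ambiguous column —
balanced support for two alleles, the signature of collapsed homoeologs —
scores ~0.5 and poisons the contig mean; a lone dissenting read against
deep coverage scores the floor.  Terminal columns are trimmed back to
the first run of 20 confident columns.  Columns where a minority allele
has ≥2 supporting reads at ≥Q30 are conflict columns; reads are
bipartitioned by their alleles across the conflict columns (seeded at
the strongest column, remaining reads assigned by agreement) and each
part re-assembled, up to 3 passes.  Contigs pass the final filter iff
length > 250 and mean per-base error < 10⁻⁴.

## Two-stage pipeline (`homasm.pipeline`)

Stage 1 assembles all QC-surviving reads permissively; the deliberately
homoeolog-blind rough contigs exist only to group reads (this keeps all
copies of a gene in one cluster) and are discarded after 32-mer
clustering and read assignment.  Stage 2 re-assembles each cluster
strictly and filters; contigs wholly contained in a contig of another
cluster with which they share a multi-assigned read are dropped (the
de-duplication rule for reads assigned to several clusters is not
specified anywhere authoritative; exact containment on either strand is
our conservative choice).  Contigs are named `C{cluster}_{index}`.
Cluster assemblies are independent, so output is byte-identical under
any processing order — the package's substitute for a cluster-parallel
compute deployment.  Clusters above 20,000 reads are subsampled with a
seeded generator and a logged warning.

## Evaluation (`homasm.evalhom`)

Contigs are allocated to reference homoeologs by iteratively accepting
the globally highest %ID cell of the contig×homoeolog identity matrix
and deleting its row and column (ties lexicographic).  Chimerism is
assessed by splitting each reference homoeolog into three equal pieces
(remainder to the last) and re-allocating the contig per piece; pieces
without a qualifying hit are ignored — a contig covering one third of a
gene must not be auto-flagged — and disagreement between informative
pieces flags the contig.  The benchmark reports the fraction of
homoeologs identified (allocation %ID > 98), the fraction of assigned
contigs flagged chimeric, and the fraction whose alignment exceeds half
the homoeolog length.  The all-vs-all identity histogram (0.5% bins, one
best hit per pair, alignments ≥400 columns) estimates the homoeolog peak
after subtracting a background level taken as the median bin count over
85–92%; the background estimator is a design choice of this package and
is surfaced as a parameter.  The excess divided by three (each
expressed triplet contributes three pairwise hits) is a lower bound on
triplet count.  SNP-rate conversions expose both conventions in use:
per-sequence frequency `(100−ID)/2` with spacing `100/freq`, and
pairwise mismatch spacing `100/(100−ID)`.  Coverage profiling reports,
per %ID cut-off (90/98/99 by default), mean positional coverage of
references on a 100-bin relative axis, the fraction of references
matched at all, and the fraction whose best alignment spans >80% of
their length.

## Problem sizes and determinism

The test suite runs everything end-to-end at sizes a single CPU handles
in minutes: identity-peak recovery on 300 triplet families; the
strict-vs-permissive separation contrast on 50 families (median 900-base
transcripts, 30× coverage of 300-base reads); the resolution-limit check
on 12 families at 99.9% identity with 100-base reads (divergent-site
spacing far beyond the read length, where any overlap-based assembler
must merge the copies — with one divergent site per ~1000 bases most
overlaps are identical between copies); and a four-family two-stage
pipeline with mixed platforms.  Every stochastic component is driven by
explicit seeds; fixed seed and configuration give byte-identical
outputs.

## Known limitations

* The aligner's band is anchored on exact seeds; alignments of
  sequences diverged far beyond ~20% (no seeds) return nothing, which is
  outside the method's operating range.
* Conflict detection requires two minority reads at ≥Q30; assemblies of
  low-quality long reads only rely on overlap rejection and merge
  validation, not the multi-pass split.
* The consensus handles 1-base insertions per junction (the dominant
  error and divergence mode simulated); longer insertions are only
  represented through their flanking columns.
* Chimera detection needs families with ≥2 reference homoeologs and is
  blind to chimeras between members of different families.
* Runtime is O(candidate pairs × band area); the package is built for
  desk-scale experiments (10⁴–10⁵ reads), not production assembly.
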