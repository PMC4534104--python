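# Methods

`alomypipe` re-creates, at desk scale and on simulated data, the analysis
chain used to build and exploit a de novo transcriptome resource for a
herbicide-resistance study in the grass weed *Alopecurus myosuroides*
(black-grass): pooled single-end RNA-seq of resistant (R) and sensitive (S)
plants over a seven-point herbicide time-course, de novo assembly with
iterative redundancy reduction, RPKM-based expression screening, fold-change
differential-regulation analysis, GO enrichment with the elim algorithm, and
selection of constitutively over-expressed non-target-site-resistance (NTSR)
candidate contigs. This note records the models, the parameters that matter,
and the choices made where the design was genuinely open.

## The simulated study design (`simdata`)

The simulator is first-class code, not a fixture. It emulates:

- **Design.** Two phenotype pools (R, S) × seven time-points (UT, 6, 12, 24,
  36, 48, 73 HAT), one pooled library each: 14 libraries of single-end
  100-base reads with constant Phred quality. Library sizes are configurable
  and equal by default (the study reports similar depths across libraries).
- **Diploid unigenes.** Each transcript has two haplotypes differing by
  substitutions at `het_rate` (default 0.005/site), and no indels — the
  mapping contract downstream is ungapped, so substitution-only variation is
  the consistent choice. Transcript lengths are uniform on 600–1400 nt
  (mean ≈ 1 kb, the average length of grass coding sequences); base
  abundances are lognormal (σ = 0.25).
- **Pooling.** Each (transcript, library) weight is multiplied by the mean of
  `pool_size` = 6 lognormal(σ = 0.25) individual-plant factors, mimicking the
  equimolar pooling of six RNA samples per library and the plant-to-plant
  variation the study observed. Averaging across the pool is what keeps
  no-replicate fold-change screening workable, exactly as in the study.
- **Reads.** Origins are drawn proportional to weight × planted fold factor;
  the haplotype is uniform; start positions are uniform along the transcript
  (no positional bias model); substitution errors at `error_rate` = 0.003 per
  base. Reads are emitted sense-strand (the assembly and mapping stages treat
  data as stranded). Transcripts shorter than the read length are skipped
  with a warning.
- **Planted truth.** Effect classes plant: a common herbicide response
  (up and down in both pools, 4-fold), an abundant strongly down-regulated
  class (8× base abundance, shut down to 0.1× on treatment — the
  photosynthesis-type response), phenotype-specific responses, constitutive
  NTSR candidates (R/S ≥ 4 at *every* time-point including UT, labelled with
  an NTSR gene family), a UT decoy (R-specific induction at treated
  time-points only — must be rejected by the candidate screen), an
  expression-pattern-only class without an NTSR family label (must land in
  the near-miss bucket), and a low-expression class that the RPKM filter must
  remove. Class masses are balanced so that the total transcript output of
  treated and untreated libraries is equal in expectation (|log2| < 0.004);
  without this, proportional read sampling imposes a global apparent
  fold-change on every unregulated transcript. The simulator therefore does
  **not** emulate global mRNA-content shifts between conditions; a passing
  recovery test says nothing about how the fold/RPKM criteria behave on data
  with strong composition changes (a known limitation of RPKM-based
  screening on real data).
- **Determinism.** All randomness derives from the single config seed through
  named sub-streams (one per library, one for transcripts, one for
  annotations), so identical configs give byte-identical outputs.

A synthetic GO fragment (15 biological-process terms, is_a edges only) and a
transcriptional-marker panel are also generated, with enrichment planted into
the common-response classes, so the enrichment and marker-concordance stages
can be scored against truth.

## Draft assembly (`assembly`)

The external base assembler is replaced by a minimal de Bruijn stage (its
internals are ours, and deliberately simple): k-mers occurring once are
pruned as errors, contigs are maximal non-branching paths, and simple bubbles
(same flanking (k−1)-mers, equal arm length) are collapsed onto the
higher-coverage arm when the arms diverge by ≤ `max_divergence` = 0.01.
Unitig tips are extended through *unambiguous* singleton k-mers: terminal
k-mers of a transcript are covered by a single read start and would otherwise
always be lost, whereas error branches compete with a kept continuation and
never qualify.

The k schedule ascends (default 41–85 step 4); each iteration re-injects the
previous contigs as pseudo-reads tiled into 2k-long fragments counted with
weight 2, so regions assembled at small k survive the singleton pruning of
large-k graphs. Two consequences matter and are intended:

- at k = 41 a single-SNP bubble arm diverges by ~1.2 % > 1 %, so haplotypes
  are *not* merged early (the stringent setting) — allelic redundancy is
  carried forward, as in the study;
- at k = 85 unitigs that break at remaining branch points share their 84-nt
  branch node, longer than the 75-nt HSP floor, so the reduction stage can
  stitch and absorb them.

## Redundancy reduction (`assembly`)

Per schedule iteration — default (99 %, 20 nt, 100 nt), (97, 20, 100),
(95, 20, 75), (92, 20, 75), from most to least stringent:

1. **Containment clustering** absorbs contig B into a longer contig A when an
   ungapped placement of B (or its reverse complement) on A covers at least
   len(B) − overhang nucleotides at ≥ the identity threshold (identity =
   matches / aligned columns). Hosts are considered longest-first, ties by
   id; members travel with their host, so every input id appears exactly once
   in the output member closures. The output is closed at the stringency
   used.
2. **Overlap merging** greedily joins contigs with a terminal ungapped
   overlap ≥ the HSP length at ≥ the identity threshold, longest overlap
   first; at mismatching columns the consensus takes the longer input's base
   (ties: lexicographically smaller base).

Each iteration loops to a fixed point. Because later iterations are strictly
more permissive, the full procedure is idempotent on its own output. The
92 % iteration is where remaining allelic contig pairs (≤ 8 % divergence,
actually ~0.5 % here) collapse. Candidate pairs are generated from shared
15-mers (contigs shorter than 30 nt fall back to exhaustive offsets); a
containment at the 92 % floor whose every 15-mer window is disrupted could be
missed, which at the sub-1 % divergence of allelic contigs does not occur.

## Peptides and filters (`annotate`)

Coding-potential prediction is a six-frame maximal ATG→stop ORF finder
(floor 30 aa, the smallest peptide the upstream study retained); a trained
coding-potential model is out of scope at desk scale. The assembly-waste
rule keeps contigs ≥ 400 nt with RPKM ≥ 1.8 in ≥ 1 modality, and peptides
strictly longer than 134 aa (the table convention "> 134" is adopted over the
prose "shorter than 134 … discarded"; the two differ only at exactly 134).

## Mapping and RPKM (`quant`)

The mapping contract: ungapped, ≤ 5 mismatches, ≥ 50 % of the read aligned,
score = matched bases ≥ 24; only placements achieving the read's global
maximum score are kept, and a read counts once towards *every* best-score
contig (so redundant contigs receive comparable counts and fold-change
analysis is not biased by redundancy). With 100-nt reads the score floor is
non-binding; it matters for shorter reads and is kept configurable.

`map_read` enumerates every offset of every contig and is the reference
implementation (tested against an independent plain-python oracle).
`BulkMapper` is the production path: 2-bit-packed 16-mer seeds at six
disjoint read positions guarantee (pigeonhole, ≤ 5 mismatches) that every
fully embedded placement is found; placements hanging more than ~5 nt off a
contig end are not searched, which is immaterial for reads drawn from within
transcripts. RPKM = C·10⁹/(N·L) with N the *total* library size (mapped plus
unmapped). The expressed threshold 1.8 is the RPKM of two-fold coverage at
the study's mean per-library depth (2·10⁹/(100 · 159,089,080/14) = 1.76 →
1.8 at one decimal) and is contig-length independent.

**Modality QC.** The fraction of contigs with ≥ 1 mapped read is computed
per library; a library that is a significant low outlier under a two-sided
Grubbs test (α = 0.05, critical value from the t quantile:
G = (n−1)/√n · √(t²/(n−2+t²)), t = t₁₋α/(2n),n−2) is flagged and its whole
time-point excluded downstream — the same rule that removed the 48HAT
time-point in the study. Only a single outlier is tested; the anomaly
modelled is one bad library, not several.

## Differential regulation (`diffexp`)

With one pooled library per modality there are no replicates, so regulation
is called directly from the operative fold/RPKM criteria: A vs B is *up* iff
A/B ≥ 2 and max(A, B) ≥ 1.8, *down* symmetrically, else stable (ε = 0.1 RPKM
replaces zero denominators, keeping the call antisymmetric). Response sets
compare each treated modality with the phenotype's UT; a contig is common-up
when up in both pools in ≥ 1 retained treated modality each (not necessarily
the same one — the broader reading of the Venn partition); "all treated"
sets intersect over every retained time-point. The per-time-point regulated
counts are themselves Grubbs-tested, mirroring the admission test that kept
the separately-sampled 73HAT time-point.

Expression profiles over the time-course are labelled from r_t =
log2((RPKM_t+ε)/(UT+ε)) with a threshold of 1 (the 2-fold convention):
UP_ALL, DOWN_ALL, STABLE, UP_THEN_DOWN(t*), DOWN_THEN_UP(t*), PEAK(t*),
else COMPLEX. Marker concordance calls each reference marker's homolog at a
queried time-point in both pools and buckets markers into agree_both /
agree_one / disagree / no_homolog.

## GO enrichment (`goenrich`)

One-sided hypergeometric over-representation per term after true-path
propagation (is_a edges only; part_of is not traversed). The elim pass
processes terms most-specific-first (decreasing longest-path depth, ties by
id); a term significant at the elim cutoff (0.01, set equal to the reporting
threshold — the original cutoff is unstated) has its current genes removed
from all ancestors before they are tested. The population is the set of
annotated expressed contigs; study sets are intersected with it. No
multiple-testing correction is applied, matching the raw p < 10⁻² reporting.

## Candidate screen (`candidates`)

Best-hit homologs: per query the smallest E-value row wins (ties: higher bit
score, then lexicographic subject id); best E ≥ 10⁻⁵ is dropped. The NTSR
screen selects contigs with R/S RPKM ratio ≥ 2 at every retained time-point
*including UT* (ε = 0.1 for zero denominators) that carry an NTSR-family
label from the controlled vocabulary {cytochrome_P450, glycosyltransferase,
glutathione_S_transferase, ABC_transporter, peroxidase, esterase,
disease_resistance, transcription_factor}; expression-only passers are
reported separately. Flagged time-points are excluded from the screen (the
open question of whether the original screen used the dubious time-point is
resolved by excluding it). Candidates carry a `requires_independent_
validation` flag; the downstream qPCR validation statistics are out of scope.

## Statistics (`stats`)

N50 (descending cumulative-sum definition), gene density (integer genes/Mb),
genome coverage (one-decimal percent), core-gene completeness (best aligned
fraction strictly > 0.70 of a 248-protein core set), Pfam-family rank
correlation (Pearson on average-rank vectors over the union of families,
absent = 0 — equivalent to Spearman), and presence-pattern family sharing.
Rounding conventions are fixed to the printed precision of the comparative
figures they reproduce.

## Pipeline and problem sizes (`orchestrator`)

`run_pipeline` executes simulate → assemble → ORFs → quantify → QC → filters
→ response sets → enrichment → candidate screen → recovery scoring, with
per-stage wall times and checksums in a JSON report. The packaged demo
configuration uses 600 transcripts at 105,000 reads per library — the mean
per-contig depth of the full design (159,089,080/14 reads over 65,558
contigs ≈ 175 reads per 1-kb contig per library) at a size where the full
pipeline completes in a few minutes — with a 50 % detection dropout planted
in the resistant 48HAT library so the QC exclusion path is exercised, and a
draft k schedule thinned to (41, 63, 85). Assembly uses a 450,000-read
subsample pooled across libraries (~19× per-haplotype coverage for a
transcript of average abundance — roughly 7× for the down-regulated classes,
which receive the least read mass);
quantification maps every read of every library.

**Truth-recovery scoring.** Contigs are matched to truth transcripts by
shared 31-mers (≥ 50 % of the contig's k-mers in the best transcript); each
transcript is represented by its longest matched contig, because short
fragments carry few reads and make noisy calls. Per planted class,
sensitivity is the recovered fraction of its transcripts; per output set,
precision counts transcripts of any class that genuinely belongs in that set
(UT decoys are genuinely R-only-up; the abundant shutdown class is genuinely
common-down), with unmatched contigs in the set counted as false.

## Known limitations

- No indels anywhere (reads, haplotypes, alignments); no splice isoforms,
  paired ends, positional bias or quality decay.
- The bulk mapper does not search deep end-overlap placements (the exact
  mapper does).
- The composition balance noted above: RPKM fold screening on data with a
  global mRNA shift will behave worse than the recovery metrics suggest.
- The Grubbs QC tests a single outlier; two simultaneously bad libraries
  would mask each other.
- The synthetic GO DAG is tiny and is_a-only; elim behaviour on the full
  ontology (depth ties, cross-namespace terms) is exercised only in unit
  tests.
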