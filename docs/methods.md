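# Methods

`ribotx` re-implements, as a tested pipeline, the computational core of a
bacterial transcriptome/translatome study design: differential RNA-seq
(dRNA-seq) TSS mapping on a single high-G+C chromosome, promoter
architecture around the mapped TSSs, and ribosome-profiling-based
translation-efficiency (TE) analysis across four growth phases
(mid-exponential **M**, transition **T**, late exponential **L**,
stationary **S**). This note records the models, the parameter choices and
their rationale, the numerical conventions, and what the synthetic-data
experiments do and do not demonstrate.

## TSS calling from TEX+/TEX- 5'-end profiles

dRNA-seq sequences two libraries: one treated with a 5'-phosphate-dependent
exonuclease (TEX+), which degrades processed 5'-monophosphate RNAs and so
enriches primary transcript 5' ends, and an untreated control (TEX-). The
caller works on per-strand sparse maps of 5'-end read counts:

1. **Clustering.** Nonzero TEX+ positions are chained into clusters while
   the gap to the previous position is at most `cluster_gap` (100 bp).
   Gap-chaining is the transitive closure of the pairwise within-100-bp
   relation on sorted positions, which keeps a run of consecutive positions
   in one cluster regardless of its total span.
2. **Count filter.** Clusters with fewer than `min_reads` (3) total reads
   are removed; the same filter is applied again after sub-clustering.
3. **Sub-clustering by positional sd.** Within a cluster, sub-clusters grow
   greedily left to right: the next position joins the current sub-cluster
   while the *sample* standard deviation (n−1 divisor) of the extended
   member set stays strictly below `sd_threshold` (10). The n−1 divisor is
   forced by the worked values sd(100,114)=9.9, sd(100,114,128)=14 and
   sd(100..128)=8.5; the population divisor reproduces none of them.
   A single position has sd 0 by convention.
4. **Peak selection.** The maximal peak of each surviving sub-cluster is the
   candidate TSS. Height ties go to the 5'-most position on the TSS strand
   (lowest coordinate on +, highest on −) — the conservative choice of the
   earliest initiation site.
5. **Close-candidate pruning.** Within one original cluster, candidate
   groups whose positions again have sd below the threshold (same greedy
   growth) are collapsed to their highest peak.
6. **Control validation.** A candidate survives only if the TEX- library
   has at least one read within ±`control_window` (5) bp: a genuine primary
   5' end persists (attenuated) in the untreated library, whereas TEX+
   artefacts do not. Note this rule is a *presence* test in the control,
   not a TEX+/TEX− enrichment-ratio test; it is implemented exactly as
   stated. An enrichment-ratio mode was deliberately not added.

The pipeline is deterministic, strand-symmetric (greedy growth runs in
ascending genome order on both strands), and purely subtractive: raising
`min_reads` or `sd_threshold` never increases the number of called TSSs.
No further heuristic removal is applied beyond these stated filters — the
original workflow's manual curation is replaced by nothing, for
reproducibility, so very highly expressed loci may retain processed-end
artefacts that a curator would remove.

## TSS classification and 5'-UTR analysis

Each called TSS gets exactly one label with priority P > S > I > A > N.
Same-strand TSSs within the strand-oriented window from 500 bp upstream to
150 bp downstream of a gene's annotated start codon are primary (P, the
highest peak per gene; ties broken towards the start codon, then 5'-most)
or secondary (S). A TSS eligible for several genes is assigned to the gene
with the nearest start codon — the choice that minimises spurious long
UTRs. Remaining TSSs inside an ORF are internal (I) on the same strand or
antisense (A) on the opposite strand (ORF span only, no flanks); everything
else is intergenic (N). A and N TSSs are the novel-transcript (sRNA)
candidates; a candidate whose transcript's RPF RPKM reaches the
expressed-gene cutoff is flagged as ribosome-occupied.

The 5'-UTR of a P/S TSS is the strand-oriented distance to the start
codon's first base. A TSS downstream of the start codon (allowed by the
+150 window) would have a negative UTR; it is recorded as undefined and
excluded from UTR statistics. UTRs shorter than 9 nt mark leaderless
mRNAs (strict `< 9`, from the stated definition, although the histogram
bin label "0–9" could suggest otherwise); UTRs longer than 150 nt mark
long leaders.

## Promoter architecture

The −10 box is scanned as the IUPAC consensus TANNNT in the 20 nt
immediately upstream of the TSS (offsets −20..−1); the −35 box as NTGACC
in offsets −40..−25 ("between 40 and 25 bp upstream" read inclusively,
which matches the stated 16-bp window). When a window contains several
matches the TSS-proximal one is primary, matching canonical promoter
geometry. Logo windows add 8/7 nt flanks around the −10 hexamer (21-mer)
and 4/6 nt around the −35 hexamer (16-mer). The spacer counts nucleotides
strictly between the −35 hexamer 3' end and the −10 hexamer 5' end — the
strictly-between reading gives the canonical 15–20 nt range for
housekeeping-sigma promoters. G+C content excludes N from the denominator.
De novo motif discovery is out of scope: the two consensus boxes are taken
as given and scanned deterministically, so no motif-significance filter
exists. TIR profiles report, per gene group, the G+C of the 20-nt region
upstream of the start codon and per-offset purine fractions, with the
−12..−8 mean tracking the Shine-Dalgarno region.

## Normalization, differential flags and TE

Counts are normalized with the median-of-ratios size-factor estimator:
per-gene geometric-mean reference across samples, per-sample median of
count/reference over genes positive in all samples (verified in tests
against the DESeq2 reference implementation). Note the estimator fixes the
*relative* scale only: rescaling one sample rescales every normalized
column by a common constant through the geometric-mean reference.

The expressed-gene cutoff is the median normalized mRNA level of the
secondary-metabolic reference set at mid-exponential phase (where those
genes are assumed minimal); a gene is expressed when strictly above the
cutoff in at least one phase. The first and last 20 genes in chromosome
order are excluded from all expression analyses (terminal duplications).

A gene is differential when |fold-change| ≥ 2 **and** p < 0.05 in at
least two phase contrasts. The p-value comes from a two-sample
negative-binomial test with a normal approximation on the log scale: for
normalized values x1, x2 (one per condition), Var(log K) ≈ 1/μ + α under
NB(μ, α), giving

    z = (log(x2+½) − log(x1+½)) / sqrt(1/(x1+½) + 1/(x2+½) + 2α),

with a half-count continuity constant. The dispersion α is a pooled
method-of-moments estimate (median over gene×group moment estimates
(v−m)/m², clipped at 0) when replicate columns exist; with merged
one-column-per-phase matrices α is not identifiable — a cross-phase moment
estimate would absorb genuine biological fold-changes — so a fixed
default α = 0.05 is used, deliberately above the generator's α, making the
test conservative. At realistic depth the fold-change gate, not the
p-value, is binding.

TE = (RPF + 1)/(mRNA + 1) on normalized values; the pseudocount of 1
guards zero denominators and is applied at TE computation only, not in
differential testing. TE log2 fold-changes are differences of log2 TE.

## Buffering, pattern groups, stoichiometry

Translational buffering appears as a negative association between per-gene
Δlog2 mRNA and Δlog2 TE across phase contrasts; it is quantified by
Pearson r and the least-squares slope of ΔlogTE on ΔlogmRNA (overall and
per gene category). Because measured ΔlogTE = ΔlogRPF − ΔlogmRNA shares
the mRNA measurement noise with the regressor, the estimated slope carries
a small negative bias of −σ²_noise/(σ²_signal+σ²_noise) at a true slope of
0 (about −0.03 under the default conditions, vanishing at slope −1);
recovery tests budget for this inside their ±0.1 band.

Expression heat-map clustering uses manhattan distance with complete
linkage (scipy); the 16 expression-pattern groups per modality use
correlation distance (1 − Pearson r of log2(x+1) phase profiles), complete
linkage, tree cut at exactly k = 16 — the cut at k reproduces the 16×16 =
256 combinatorial grid. Genes with constant profiles (undefined
correlation) are set aside in a reserved flat group 0 before clustering.
Monotone trends are labelled I/D/flat by the least-squares slope of
log2(value+1) on phase index with threshold 1/(n_phases−1) (a fitted
end-to-end change of one log2 unit), combining into the II/ID/DI/DD groups.
The gene universe for grouping is the expressed set after terminal-gene
exclusion when run through the CLI pipeline.

Subunit stoichiometry: within an operon, each member's length-normalized
RPF is divided by the first member's, per phase, and per-phase ratios are
combined by geometric mean. Each phase gives an independent, log-unbiased
estimate of the same ratio; averaging in log space weights phases equally,
whereas a ratio of phase-sums is dominated by the deepest phase (phase
fold-changes are shared within an operon) and roughly doubles the
estimator's sd. Expected ratios come from the annotated copy numbers; the
first member must have nonzero RPF in every phase.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions and are fixed once:

| parameter | default | rationale |
|---|---|---|
| genome G+C | 0.72 | the target organism's genomic G+C |
| genome length / genes / TSSs | 100 kb / 60 / 50 | desk-scale chromosome; one gene per ~1.7 kb slot as in gene-dense bacterial genomes |
| leaderless fraction | 0.21 | the fraction reported for this genus |
| leadered UTR | lognormal, median 44 nt, σ=0.9 | reported median; σ set so ~10–15% of leaders exceed 150 nt |
| +1 purine probability | 0.88 | reported purine preference at the TSS |
| −10/−35 boxes | TANNNT at −12..−7; NTGACC at spacer 15–20 | canonical box placement; reported dominant spacer range |
| start codons | ATG 0.60 / GTG 0.35 / TTG 0.05 | reported usage pattern for high-G+C actinobacteria |
| TEX+ peak height | NB(mean 50), floored at 3 | sharp primary 5' ends; the floor guarantees every planted TSS passes the caller's count filter |
| TEX− retention | 0.4 within ±2 bp | primary ends persist attenuated in the control |
| processing sites | 0.5 /kb/strand, TEX− only | processed 5' ends are TEX-sensitive |
| background | 2 reads/kb/strand/library | uniform single-read noise |
| NB dispersion α | 0.01 | replicate-merged deep coverage is near-Poisson with mild overdispersion (replicate R² ≥ 0.96 territory) |
| baseline log2 mean / sd | 9 / 1.5 | mean counts ~500, two orders of magnitude spread |
| phase log2FC sd | 1.5 | many genes change > 4-fold into stationary phase |
| buffering slope | −0.5 | mid-range damping of RPF changes |
| RPF extra noise sd | 0.2 log2 | residual translational regulation |
| TE offset sd | 1.0 log2 | per-gene baseline TE spread; the top quintile gets an AGGAGG Shine-Dalgarno at −12..−7 of the start codon (leadered genes only) |
| secondary-metabolic genes | 15%, baseline −3 log2 at M, +1 log2/phase trend | low at mid-exponential, induced later — the premise of the expressed-gene cutoff |
| operons | 2-gene 1:4 and 8-gene 1:10:2:1:3:1:3:1, +2.5 log2 baseline | ribosomal-protein-like and ATP-synthase-like copy numbers; such operons are among the most expressed genes |

Operon members are consecutive, co-stranded, and share baseline, TE
offset, fold-changes and RPF noise, so stoichiometric proportionality (RPF)
versus uniformity (mRNA) is the operon's planted property and only NB
sampling perturbs it. mRNA count means are 2^(baseline+fc)·length/1 kb;
RPF means add the TE offset, the buffered fold-change
fc·(1+slope)+noise, and the stoichiometry factor. Planted TSSs are kept at
least 25 bp apart per strand so that, with noise zeroed, the caller's
sub-clustering and pruning recover the planted set exactly. All stages
draw from `numpy` Generators seeded as (seed, stage-index), so outputs
are byte-identical given the config.

**What the generator does not emulate:** condition-specific TSS usage
(one pooled TEX+/TEX− pair, not 44 conditions), peak shape (single-base 5'
ends only), transcript-isoform structure and operon-internal TSSs, mapping
artefacts and coverage bias, replicate structure (merged columns, as in
the target design), RNA secondary structure (TIR free energy is out of
scope), and genome-scale gene counts. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under the
stated generative model — not performance on real libraries, where manual
curation, mapping noise and biological confounders matter.

## Problem sizes and numerical conventions

Simulation studies use 60-gene/100-kb datasets for pipeline-level checks,
400 genes for classification-fraction recovery, and 1000-gene/1-Mb datasets
for buffering-slope recovery and differential calibration (200 planted
4-fold genes among 1000). Stoichiometry recovery averages recovered ratios
over five replicate datasets, since a single dataset's worst-of-seven
subunit error sits near 2.4 sd of the NB noise floor (√(2α) per phase).
All coordinates are 1-based inclusive internally; bedGraph/BED convert at
the io boundary. Sub-cluster and prune thresholds are strict (`sd < 10`).
Degenerate inputs fail loudly: empty FASTA, end < start features,
negative bedGraph values, non-integer or duplicate-gene count tables,
all-N sequences, single-sample size factors, sub-3-gene regressions.
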