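# Methods

This note records the models, conventions and numerical choices behind
`panfam`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know about.

## Coordinates and formats

All genomic coordinates are 1-based inclusive throughout the data model
— the native convention of GFF3 and VCF, the two primary input formats;
any 0-based input would be converted at the reader boundary. Multi-
transcript genes are collapsed to the transcript with the longest
summed CDS (ties broken by transcript id), giving one protein per gene;
the family is counted in genes, not isoforms. The HMMER `domtblout`
reader stores the per-domain *independent* E-value, not the
full-sequence E-value, because the family filter is a domain filter.
Diploid VCF genotypes from inbred lines are collapsed to haploid calls;
heterozygous or partially missing genotypes become missing — a
conservative choice for inbreds, where residual heterozygosity is rare
and unreliable.

## Family scan

A gene joins the family when ≥ 1 domain hit passes E ≤ `e_max`
(default 1e−5, inclusive). Multiple passing hits per gene are kept, as
tandem double-domain architectures are real in dirigent-like families.
The promoter is defined as the 2000 bp 5′ of the **CDS start** in
transcript orientation (not the transcript start), truncated and
flagged at contig edges. Genes whose CDS translates with an internal
stop are excluded with a logged warning rather than silently
translated. Chromosome names failing the (configurable) regex
`^chr([0-9]+)$` after lowercasing mark the gene as scaffold-placed.

Physicochemical properties: molecular weight and the Kyte–Doolittle
GRAVY and Guruprasad instability indices are computed with Biopython's
`ProteinAnalysis` (average residue masses; reported in kDa); tests
re-derive them by direct loops over the published residue/dipeptide
tables. The isoelectric point is the unique zero of the
Henderson–Hasselbalch net-charge curve over the EMBOSS pKa set
(N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5,
Y 10.1), solved by bisection on [0, 14] to |charge| < 1e−4. The charge
curve is strictly decreasing in pH, so the bracket is always valid.
pI values are tool-dependent (pKa sets differ across programs); they
are descriptive annotations, not comparable across software.

## Orthogroup refinement

"Similarity" is interpreted as percent identity over a global
(Needleman–Wunsch) alignment — BLOSUM62, gap open 10, gap extend 0.5 —
with identity = identical columns / alignment length, gaps counted in
the denominator. This is the conservative, symmetric reading of a 90 %
similarity threshold; the threshold is exposed as a flag. Subdivision
takes the single-linkage components of the "identity ≥ threshold" graph
— the unique parameter-free graph rule consistent with "genes below the
threshold get subgrouped" — enforces the ≥ 2-member rule, and moves
size-1 components to the singleton list. The operation is idempotent
and anti-monotone in the threshold (raising it only refines the
partition); both properties are tested, along with equivalence to a
brute-force union-find oracle.

An externally supplied orthogroup table (Orthogroups.tsv dialect) takes
precedence and is refined in place; the de novo path (single-linkage
over all proteins) is a fallback and is **not** equivalent to Markov
clustering on BLAST graphs. Alignment traceback ties are resolved
deterministically by taking the aligner's first optimal alignment.

## Pan matrix, occupancy, saturation

Presence is genome-level: an orthogroup is present in a genome iff it
has ≥ 1 member gene from it (copy number does not matter; singletons
are excluded). Occupancy classes for an n = 26 panel are core (k = 26),
softcore (24–25), shell (6–23) and variable (≤ 5); for other n the
cut-offs generalize as soft_min = ⌈0.92 n⌉ and var_max = ⌊0.20 n⌋,
chosen to reproduce the absolute cut-offs exactly at n = 26.

The saturation curve samples, for each s, `reps` subsets of s genomes
uniformly **without** replacement within a replicate (a subset of
distinct lines) and with replacement across replicates; the default is
1000 replicates with a mandatory seed recorded in the output. The
closed form of the expectation — per orthogroup
1 − C(n−k, s)/C(n, s) — is reported next to the bootstrap and is the
exact mean of the bootstrap estimator, which the tests verify both at 3
Monte-Carlo standard errors (1000 reps) and by convergence at 10⁴ reps.
`find_min_s` reports the smallest s whose analytic expectation reaches
a target discovery fraction (default 0.9); the value is a property of
the occupancy distribution at hand, not a constant of the method.

## Ka/Ks (NG86)

Codon alignments are built by back-threading CDS through the global
protein alignment (residue → codon, gap → `---`), after trimming
terminal stop codons; a translation mismatch is an error naming the
offending residue. The estimator is the canonical Nei–Gojobori
counting method, chosen because it is closed-form, assumption-light
(no transition/transversion bias — matching the generator's mutation
model) and verifiable against an exhaustive oracle:

- **sites**: per codon position, the fraction of the three alternative
  nucleotides producing a synonymous change, with changes to stop
  codons excluded from the denominator; summed over positions and
  averaged between the two sequences, so S + N = 3 × (compared codons)
  exactly;
- **differences**: for codon pairs differing at d positions, Sd and Nd
  are averaged with equal weight over the d! substitution orders;
  orders passing through a stop codon are excluded, and if that
  excludes all orders, all are kept (fallback);
- **correction**: pS = Sd/S, pN = Nd/N; Ks = −¾ ln(1 − 4/3 pS), same
  for Ka; the ratio is Ka/Ks.

Gapped, ambiguous or stop codon columns are dropped pairwise
(complete-pair deletion). Undefined ratios (Ks = 0, or pS/pN ≥ 3/4
where the log diverges) are reported as a status column, never as
numeric infinity, so per-orthogroup medians stay well defined.
Per-orthogroup summaries cover all cross-genome within-orthogroup
pairs; orthogroups are flagged when any pair has Ka/Ks > 1. The
counting rules match an independent exhaustive pathway-enumeration
oracle exactly on all 61 × 61 sense-codon pairs, and agree with
Biopython's independent NG86 implementation to within ~10 % (the
remaining gap is its different stop-exclusion conventions).

## Cis-regulatory elements

PlantCARE is a web service and is not reproduced; instead a packaged,
editable TSV of ~30 canonical plant elements (each with one IUPAC
pattern and one category) defines the scan. Matching is exact IUPAC
matching of all — possibly overlapping — occurrences on the given
strand plus its reverse complement; an `N` in the sequence matches
nothing. Overlap counting keeps the statistic deterministic and
oracle-checkable (a naive sliding-window oracle and strand symmetry are
both tested). The per-orthogroup profile is the fraction of member
genes with ≥ 1 hit in a category. Absolute counts depend on the motif
table and are not comparable with PlantCARE output.

## Tandem duplicates and GWAS windows

The tandem rule is a documented stand-in for collinearity-based tools:
two family genes are a tandem pair iff they share orthogroup and
chromosome and at most `max_intervening` (default 5) annotated genes —
counted over the FULL annotation — lie between them; clusters are the
transitive closure. GWAS candidate selection keeps signals with
resample model inclusion probability ≥ 0.05 and reports genes whose
interval extended by ±100 kb (inclusive at both ends, the plain reading
of "within 100 kb") contains the signal; distance is 0 inside the gene,
else bp to the nearest edge. Coordinate lift-over between assembly
versions is out of scope; inputs must share one coordinate system.

## Haplotypes and cluster skew

A haplotype is the concatenated allele string over the variant sites in
the gene body (flank 0 bp by default, exposed); lines with any missing
call in the region are excluded and counted separately. Haplotypes with
fewer than `min_count` = 2 carriers collapse into a "rare" class;
the rest are named Hap1, Hap2, … by descending count with lexicographic
tie-breaks. The skew score — max over haplotypes of the chi-square of
that haplotype's cluster counts against the cluster marginals, divided
by the number of counted lines — with its seeded label-permutation
p-value (default 999 permutations, so min p = 0.001) is a package
convention for quantifying a qualitative pattern, and the output says
so.

## Expression

FPKM uses the within-matrix column sum as library size (mapped-read
totals are upstream of the package boundary; this is a documented
deviation and is exact when the matrix holds all genes). Tissue
profiles are per-tissue means with per-gene z-scores of log₂(FPKM + 1)
across tissues; constant rows get null z-scores. Stress response is
log₂((treated + 1)/(control + 1)) on mean FPKM per organ, with
"induced" meaning log₂FC ≥ 1 (two-fold) — both the pseudo-count and the
threshold are labelled conventions.

## Synthetic data: what it emulates and what it does not

The generator plants a known truth behind every downstream statistic.
Defaults mirror the target study's scale: 26 genomes, 68 orthogroups
arranged to give ≈ 47 family genes per genome (22 core with three
multi-copy tandem arrays, 8 softcore at p = 0.94, 23 shell at
p = 0.3–0.75, 15 rare at p = 0.06, one on a scaffold), ~17 % of
orthogroups carrying the co-domain, 7 breeding clusters over 150 lines,
and a salt/mannitol two-organ count design with 3 replicates.

Coding sequences evolve from a per-orthogroup ancestral sequence along
a star phylogeny by an accept/reject codon process: each attempted
uniform single-nucleotide change is accepted with probability 1 if
synonymous, min(1, ω) if nonsynonymous; stop-creating changes are
rejected and redrawn. With attempts uniform over sites and alternative
nucleotides and no transition/transversion bias, the realized dN/dS
equals the planted ω under NG86's own mutation-opportunity model for
ω ≤ 1 — deliberately, so the estimator is tested under its own
assumptions. The default divergence (0.02 substitution attempts per
codon site per branch) keeps within-orthogroup protein identity near
95 %, clearly above the 90 % subdivision rule, while between-orthogroup
identity is that of unrelated random proteins; the dN/dS-recovery
experiments use 300-codon genes and 45 attempts per branch, placing
synonymous divergence well inside the Jukes–Cantor-correctable range.

Promoters are uniform-random with planted motifs at Poisson-rate,
non-overlapping positions; the planted motifs are the longer (≥ 8 bp)
table entries, whose background match probability in 2 kb is ≤ ~0.5 %,
so planted category proportions are recoverable within binomial error.
The population simulator assigns cluster c the "owned" haplotype
c mod H, mixing it with a uniform component by a skew weight — at
skew = 1 and H = K = 7 the haplotype-by-cluster table is exactly
one-hot. Count matrices add 400 effect-free background genes so that
planted effects do not perturb library sizes, mimicking a family
embedded in a transcriptome; negative-binomial noise uses dispersion
0.05.

Not emulated: real chromosome structure, transposable elements,
recombination, annotation errors, alignment ambiguity between
paralogs, linkage disequilibrium within gene regions, GC bias, or
mapping artifacts in counts. Passing on synthetic data therefore
demonstrates correctness of the statistics under their stated models,
not robustness to the full messiness of real assemblies.

## Determinism and problem sizes

Every stochastic step takes a mandatory seed (numpy `default_rng`), and
seeds plus parameters are echoed in the provenance header of every
output file; rerunning a pipeline with the same manifest and seed is
byte-identical, which the tests verify by checksums. The test suite and
the acceptance script run on reduced problem sizes chosen to exercise
every code path at comfortable statistical power: a 5-genome /
10-orthogroup pipeline study, 20-gene × 300-codon dN/dS families,
a 40 × 26 saturation matrix at 1000 bootstrap replicates, 150-line
populations with 999 permutations, and 100 random 30-gene instances
for the subdivision oracle.

## Known limitations

- The de novo clustering path is single-linkage on global identity; on
  families with domain shuffling it will chain through mosaics where
  graph-based orthology tools would not.
- NG86 has no transition/transversion or codon-frequency correction;
  planted-ω recovery holds because the generator matches its model.
  Real data with strong mutational bias will bias Ka/Ks.
- The motif table is a convention; category proportions change with the
  table and should be compared only within one table version.
- The tandem rank-distance rule approximates, but is not, a
  collinearity analysis; its counts are not comparable with MCScanX.
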