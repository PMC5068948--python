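# Methods

## The screening model

`divscreen` treats each transcript position with a biallelic variant as a
locus with species-level alt-allele frequencies estimated directly from
allele depths, F̂ = alt/(ref+alt). Both species are oriented against the
same shared reference transcriptome, so the per-SNP differentiation index
D = |F_A − F_B| is comparable across sites, and the per-unigene index D̄ is
the plain arithmetic mean of D over the unigene's callable SNPs. The screen
has no population-genetic model behind it: D is a descriptive index, and
the D̄ ≥ 0.94 threshold is a design constant chosen to isolate transcripts
with near-fixed interspecific differences. Gene flow between the species is
what makes such loci interesting — under ongoing exchange, most shared
polymorphism should show small D, so a unigene where every SNP is near
fixation stands out.

Working at the unigene level (the longest isoform per assembly component)
avoids counting the same SNP once per isoform. Ties in length are broken by
the lexicographically smallest transcript id, so the reduction is
deterministic. Variants on discarded isoforms never enter D̄.

## SNP filtering and sharing classes

A site is a SNP in species *s* when MAF_s ≥ 0.05, site quality ≥ 30 (one
Phred value per site, as in a VCF QUAL column) and depth_s ≥ 100 — all
inclusive. Sharing classes: *shared* passes in both species, *specific to
s* passes in *s* while the other species is adequately covered
(depth/quality pass) but below the MAF floor, and sites that cannot be
evaluated in one species are *uncallable*, never specific. Two points were
genuinely open and are resolved as explicit, flag-switchable choices:

* **Coverage requirement for specificity** (`require_coverage_for_specificity`,
  default on): calling a SNP "absent" in a species that was never covered
  there would conflate missingness with monomorphism.
* **Fixed-site callability** (`fixed_sites_callable`, default on): an
  oppositely fixed difference (F = 1 vs 0) has within-species MAF = 0 and
  would fail the per-species MAF rule in both species, yet it is exactly
  the signal the screen exists to find. Such sites are admitted to the D
  computation when both species pass depth/quality, and are tallied as
  their own class so the partition of input sites remains exact.

## Nei identity and distance

Per-locus identity is the normalised dot product of the two allele
frequency vectors; the summary reports the mean identity, −ln of that mean
(distance of the mean) and the mean of per-locus −ln I (mean of distances;
loci with I = 0 are excluded from this mean and counted). Both conventions
are reported because the two differ in general (Jensen's inequality puts
the distance of the mean below the mean of distances) and published
identity/distance pairs are not always consistent with a single convention.
The Shapiro–Wilk test on the D̄ distribution is descriptive only; no
decision logic depends on it (`scipy.stats.shapiro`).

## ORFs, codon usage

The ORF scan reports maximal stop-to-stop segments in all six frames,
preferring the first ATG in a segment and flagging start- or stop-less
segments as incomplete; the default retention threshold is ≥ 100 encoded
residues (inclusive; the strict reading "> 100" is a flag). The longest ORF
per transcript is primary.

Codon-usage bias is summarised by Wright's effective number of codons
Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, with F the codon homozygosity per
amino-acid family. The default homozygosity estimator is the plug-in
F = Σp̂², which attains the analytic endpoints exactly (uniform synonymous
usage → 61, one codon per amino acid → 20) and keeps Nc inside [20, 61] on
every input; the small-sample corrected estimator
F = (nΣp̂² − 1)/(n − 1) is available via `corrected=True` (clamped to the
analytic range). The three-fold class (Ile) borrows the mean of the two-
and four-fold classes when it has no usable family, the standard fallback.
Usage tables are compared by the mean squared difference of within-family
codon fractions.

## Orthology and Ka/Ks

Orthologs between the ingroup and the outgroup are called by reciprocal
best hit over global Needleman–Wunsch alignments (BLOSUM62, gap open −11 /
extend −1, via `Bio.Align.PairwiseAligner`). An absolute score floor
replaces a database e-value, which is not meaningful without database-size
context; ties for best score yield no pair (conservative). The first
optimal alignment in the aligner's deterministic enumeration order fixes
gap placement among co-optimal alignments.

Ka/Ks uses the Nei–Gojobori (1986) approximate method: per-codon fractional
site counting averaged over the two sequences (changes to stop codons
excluded from the per-position denominator, so S + N = 3 × compared codons
exactly); per-codon-pair synonymous/nonsynonymous differences averaged with
equal weight over minimal mutational pathways, with pathways crossing stop
codons excluded and weights renormalised (if every pathway is blocked, all
are used — a degenerate case that cannot arise between sense codons with
≤ 2 differences); Jukes–Cantor correction d = −(3/4)ln(1 − (4/3)p), with
p ≥ 3/4 flagged as saturated. Ks = 0 with Ka > 0 is reported as an
undefined-large ratio and flagged `ks_zero`. Columns with gaps, N, or a
stop codon are skipped and counted. The statistic is exactly symmetric in
its two arguments.

The three-way codon alignment for a triple is built by aligning ingroup-A
to ingroup-B and ingroup-A to the outgroup at the protein level, merging
the two alignments on the shared A sequence, and back-translating every row
to its source codons. The candidate branch rule is: ratio(A,B) ≥ 0.5 and
both outgroup ratios < 0.5 (both cutoffs configurable); the 0.5 ingroup
cutoff deliberately sits below the strict positive-selection bound of 1
because genes under partial positive selection retain conserved domains
that drag the gene-wide ratio down, especially between recently diverged
species. Genes whose ratios carry degenerate flags stay off the "clean"
candidate list but keep their call and rationale.

NG86 is an approximate counting method: it ignores transition/transversion
bias and codon-frequency bias, so on strongly biased real data its ratios
can deviate from maximum-likelihood estimates. The tests therefore validate
it against its own exhaustive-pathway definition and against simulations
from the matching generative process, not against model-averaged values.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* the screen consumes, at sizes
chosen to keep a full run in seconds:

* **Unigenes/isoforms** — components with 1–3 isoforms sharing an exonic
  core and differing by 3'/5' extensions of up to a quarter of the core, so
  the longest-isoform reduction is meaningful and deterministic.
* **SNP classes** — shared SNPs draw both true frequencies uniformly on
  (0.05, 0.95); species-specific SNPs draw one frequency there and fix the
  other at 0; fixed differences use (1, 0) or (0, 1). Observed counts are
  Binomial(depth, F) with depth drawn per site per species from a negative
  binomial (default mean 200, dispersion 10 — overdispersed RNA-seq-like
  coverage that exercises the depth filter). Site qualities are
  Normal(60, 10) truncated at 0. Fixed differences live on a dedicated
  unigene pool disjoint from the polymorphic pool (`n_fixed_unigenes`,
  default the 164-of-2612 proportion of the motivating study), which is
  what makes "the screen recovers exactly the planted set" a well-defined
  property: with shared frequencies confined to (0.05, 0.95), true D on
  polymorphic unigenes is at most 0.90, giving a ≥ 5σ margin below the 0.94
  threshold at depth 10⁴.
* **Ortholog triples** — each gene's ancestor is a uniform random sense
  CDS; tips evolve by a mutation–acceptance process: the number of accepted
  substitutions is Poisson(t × codons), proposals are uniform
  single-nucleotide changes, synonymous proposals are accepted with
  probability 1 and nonsynonymous with min(1, ω) (for ω > 1 the synonymous
  acceptance is down-weighted to 1/ω instead); stop-creating proposals are
  rejected. Each ingroup tip receives t_in/2 from the ancestor
  (default t_in = 0.05 substitutions per codon) and the outgroup
  t_out − t_in/2 under a purifying background ω = 0.1 (default
  t_out = 0.5), so both ingroup–outgroup paths have length t_out and the
  branch rule has a signal to detect. This is deliberately a simplified
  codon model — no transition/transversion bias, uniform codon
  frequencies, no indels — sufficient to make NG86 recovery testable, and
  documented as such.

What the generator does **not** emulate: sequencing error (fixed
differences are exactly fixed, so observed D = 1 at any depth), expression
levels and library replicates, within-species population structure (one
population per species), indels, misassembly, and paralogy beyond simple
decoys. Passing recovery tests therefore demonstrate that the pipeline's
logic is correct under its stated model, not that the thresholds are
optimal for any particular real dataset.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; VCF converts at the boundary
  (pysam on both read and write). The plain TSV variant table round-trips
  all fields exactly.
* Report writers order rows by D̄ descending then unigene id, so identical
  inputs give byte-identical outputs.
* All generators take a single integer seed; every simulation function is
  reproducible given it.
* Problem sizes used by the shipped verification run: 10⁴ sampled codon
  pairs for the pathway oracle; 200 genes × 300 codons per ω for estimator
  recovery; 100 + 100 triples for the branch-rule accuracy; 2,612 unigenes
  / 7,033 SNPs at depth 10⁴ for the fixed-difference recovery — sizes at
  which each check is stable from seed to seed while the whole suite runs
  in seconds.

## Known limitations

* NG86 with Jukes–Cantor saturates near p = 3/4; deeply diverged pairs get
  flagged, not corrected (no LWL85/YN00/ML fallback).
* The RBH stage aligns all-vs-all and is quadratic in the number of
  proteins; it is meant for the divergent subset (hundreds), not whole
  transcriptomes.
* SNP effect classification (NC/S/NS) uses the primary predicted ORF of
  the reference transcript; on transcripts whose true frame is not the
  longest ORF the call may be wrong, and codons containing N are reported
  undetermined rather than guessed.
* Allele frequencies come from pooled read depths, not genotype
  likelihoods; no correction for unequal individual contributions to a
  pool is attempted.
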