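# Methods

## The model of RB-pathway genetics

Tumors deregulate CDK4/6-RB signalling through a small set of largely
alternative lesions: amplification of *CCND1* or *CDK4* (more kinase
activity), deletion/mutation of *CDKN2A* (less inhibition), or loss of
*RB1* itself (the substrate removed, making upstream deregulation
redundant). The genetics module formalizes this as pairwise 2×2 tests:
for genes A and B, samples are cross-classified altered/unaltered,
OR = ad/bc, and the two-sided Fisher exact p is computed by the small-p
rule (sum of all hypergeometric outcomes no more probable than the
observed table). OR < 1 is called mutual exclusivity, OR > 1
co-occurrence. "Altered" means amplification, deep deletion, or
non-silent mutation; heterozygous (single-copy) loss is deliberately kept
out of this definition and tracked as its own axis, because single-copy
13q loss behaves differently — it is widespread, reduces expression of
many genes in cis, and tends to co-occur with, rather than exclude,
upstream CDK4/6 events. A flag folds het loss into "altered" for
sensitivity analysis. Zero-margin tables leave the OR undefined: the
entry is reported NA with the Fisher p still attached (no continuity
correction by default; Haldane–Anscombe +0.5 behind a flag). No
multiple-testing correction is applied to the filters — the pipeline
follows raw p < 0.05 throughout — but Benjamini–Hochberg columns are
emitted alongside every p column for transparency.

## Chromosome-arm dosage analysis

Dosage classes come directly from the discrete GISTIC codes (0 diploid,
−1 het loss, −2 deep deletion); no re-segmentation is attempted. Arm
profiles are per-gene loss frequencies with the full cohort as
denominator (not only tumors with a 13q event), ordered by the 1-based
start coordinate. Expression-by-dosage uses the pooled-variance Student
t-test — chosen because plain "Student's t" is the stated convention for
this analysis style; Welch is available behind a flag — and the survival
comparison is diploid vs het-loss only (deep deletions excluded, since
the question is specifically what *single-copy* loss does). The endpoint
(disease-free vs overall survival) is always an explicit argument.

## Signature derivation

The CDK4/6-RB integrated signature is built in three steps from a
parental / RB1-null isogenic pair treated with vehicle or a CDK4/6
inhibitor (duplicate libraries per arm):

1. **Repression filter.** Counts are CPM-normalized (count / library ×
   10⁶); fold changes and t-tests operate on log2(CPM + 1). The
   pseudocount of 1 is our choice — the fold-change scale is not
   otherwise pinned down — and is recorded in the signature provenance.
   Genes with log2FC ≤ −1 and p < 0.05 in the parental line are
   drug-repressed. The test is a plain two-sample Student t on the
   replicates; with duplicate libraries an empirical-Bayes moderated test
   would have more power, but the plain test is the stated convention and
   keeps the kernel oracle-checkable. The consequence — that duplicate
   libraries need low replicate noise for this test to have power — is a
   real limitation of the design, reflected in the generator defaults
   below.
2. **RB-dependency filter.** A gene repressed in the identically treated
   RB1-null line cannot require RB for its repression; parental hits that
   also pass the repression filter in the knockout are removed. Genes
   absent from the knockout data are retained with a warning.
3. **Correlation prune.** For each surviving gene, the maximum Pearson
   correlation to any other surviving gene is computed across a large
   clinical cohort; genes whose maximum is strictly below the mean of the
   maxima are pruned (genes exactly at the mean survive). Signed r is
   used, not |r|: the signature is a co-repressed module expected to
   correlate positively; an absolute-value mode exists behind a flag.

Scoring z-scores each signature gene across a cohort and averages per
sample, so scores are invariant to affine rescaling of any single gene
and to duplicating samples. Stratification ranks samples with a stable
sort and takes the lowest floor(0.25·n) and highest floor(0.25·n); ties
straddling a boundary move to the middle stratum, making strata
deterministic; fully tied scores are an error.

## Dosage differential expression

Per cohort and contrast (diploid vs het, diploid vs deep), every gene is
t-tested with |log2FC| ≥ 1 and p < 0.05 as significance; a cohort lacking
two samples in either class is ineligible. Recurrence keeps genes
significant in the same direction in more than 33% (het) / 66% (deep) of
eligible cohorts, where eligibility requires >10% het-loss / >5%
deep-deletion frequency; all comparisons are strict. The prose elsewhere
sometimes quotes 36% for the het threshold; 33% is the default here with
any value reachable through `min_fraction`. The hypergeometric-overlap
universe is the set of genes measured in all analyzed cohorts — the
natural choice when the universe is not otherwise specified — and is
recorded with the results.

## Bootstrap cutoffs and pre-ranked GSEA

Gene-wise Pearson correlation against the signature score yields a CC
vector per cohort. The cutoffs resample that vector with replacement
10,000 times (resample size = gene count) and take the 2.5th/97.5th
percentiles of the pooled resampled values; this pooled-percentile
reading produces gene-level cutoffs of the kind the selection step needs
(selection = beyond a cutoff AND p < 0.05). The alternative reading —
percentiles of per-resample means, i.e. a bootstrap CI of the mean CC —
is implemented behind `per_resample_means` for comparison; it yields a
much narrower interval around the mean. The seeded resampling contract
(one `default_rng(seed)`, a single `(n_boot, n_genes)` index draw) is
documented so an independent resampler reproduces the cutoffs exactly.

Selected genes are weighted W = CC·(−log10 p) (p floored at 1e-300 and
flagged), ranked descending with lexicographic tie-breaks, and scored by
the classic weighted Kolmogorov–Smirnov running sum: hits advance by
|W|/Σ|W| over hits, misses retreat by 1/(N−Nh), ES is the extremum.
Because phenotypes cannot be permuted in pre-ranked mode, the null
redraws each set's positions uniformly (gene-label permutation, set size
preserved, 1000 permutations by default); NES = ES / mean(|perm ES| of
matching sign), p is the same-sign exceedance fraction floored at
1/(n_perm+1). Correlation profiles across cohorts are clustered with
Ward-linkage hierarchical clustering cut at k = 5 by default (a k-means
mode is provided; the two conventions circulate for this analysis and
neither is privileged), with missing per-cohort values imputed as 0 under
a recorded mask.

## The synthetic study

The generator emulates the data model the pipeline consumes, with planted
truth for recovery tests. Per tumor a latent pathway mode is drawn —
rb1_loss, cdkn2a_del, ccnd1_amp, cdk4_amp, or none — which plants
exclusivity between RB1 loss and the CDK4/6 modes; the two amplification
modes add the partner oncogene with probability `co_amp_prob` (0.3),
planting co-occurrence. RB1-loss tumors receive a contiguous 13q deletion
covering the RB1 index: focal (endpoints uniform conditioned on covering
RB1) with probability `focal_weight` (0.5) else arm-level, deep with
probability 0.3, and shallow losses acquire a truncating RB1 mutation
with probability 0.7 (mutation + LOH biallelic inactivation). Expression
is Normal on the log2 scale (sd 1) with cis genes shifted −0.5 (het) /
−3.0 (deep) inside emitted segments, amplified oncogenes shifted +1, a
CDKN2A elevation of +1 when RB1 is lost (the feedback that makes the two
genes' expression anti-correlate), and 50 program genes sharing a latent
activity raised by β = 1 on RB1 loss. Survival is exponential with
hazard 0.01/month × exp(0.8·standardized activity), censored uniformly on
[0, 120] months (≈60% censoring). Defaults: 4 cohorts × 200 tumors, a
60-gene arm, sporadic background events at rate 0.02 per pathway gene.

The isogenic generator emits gamma-Poisson (negative binomial) counts
with baseline abundances lognormal(log 1000, 0.5) and dispersion 0.005,
duplicate libraries per arm; program and decoy genes are repressed
(log2 fold −2) only in drug-treated parental cells, RB-independent genes
in both genotypes. The abundance/dispersion defaults are set so a 2-df
t-test on duplicates detects the planted fold reliably — cell-line
replicates are tight, but this is the optimistic end of real data, and it
is what "plain t-test on duplicates" requires to work at all. The
clinical generator gives the program genes one latent factor with shared
variance 0.6 (pairwise correlation 0.6 in expectation) across 2000
samples, with "decoy" genes — repressed in the cell line yet independent
noise in tumors — to exercise the correlation prune.

What the synthetic study does not emulate: mutational signatures,
allele-specific copy number, purity/ploidy, between-gene expression
covariance beyond the single program factor, subtype structure, or
informative censoring. Passing recovery tests therefore demonstrates that
the pipeline's logic recovers planted effects of realistic size under
clean conditions — not that real cohorts would yield these effect sizes
or p-values.

## Numerical and calibration notes

* Problem sizes in the test suite and acceptance script (4×200 tumors,
  180-gene isogenic panel, 2000 clinical samples, 100–200 null seeds)
  were chosen as the smallest study at which every planted effect is
  comfortably detectable and null calibration is estimable to ±1–2%.
* The null-calibration study uses background-only cohorts with sporadic
  event rate 0.30 so that Fisher exact tests operate away from the
  heavily discrete regime (at low counts the exact test is conservative
  by construction and its rejection rate falls well under the nominal
  5%).
* With the planted program gain β = 1 equal to the DE fold threshold, the
  het-contrast up-calls are threshold-crossing events with ~50% per-gene
  sensitivity per cohort — the recurrence filter is what makes the
  recovered up-set clean. The deep contrast rests on far fewer samples
  (deep classes ≈ 6–12% of a cohort) and is correspondingly noisier.
* The het contrast's recurrent *down*-set is empty at the defaults: a
  −0.5 log2 cis shift cannot pass the |log2FC| ≥ 1 filter. The >90%
  cis-fraction statement is therefore exercised on the deep-deletion
  down-set, where it holds at 100%.
* k-means uses 25 restarts with the best within-cluster sum of squares
  kept and labels canonicalized by lexicographic centroid order, so a
  fixed seed yields identical labels across library versions.
* Degenerate inputs are first-class: zero-variance t-tests return
  flagged p∈{0,1}; constant genes are excluded from correlation and
  scoring with a notice; zero-event survival groups flag the log-rank as
  unreliable; identical clustering rows set a degeneracy flag.

## Known limitations

The plain t-test on duplicate libraries is the weakest link of the
derivation chain and is sensitive to replicate noise (a moderated test
would be the modern choice). Gene identifiers are matched as exact
strings (Hugo-style symbols); no alias resolution is attempted. Cox
models, exact log-rank, GISTIC peak calling, and network/enrichment-map
rendering are out of scope.
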