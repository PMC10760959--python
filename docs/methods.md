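# Methods

This note documents the models implemented in `peptigen`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic data does and does not emulate.

## K-mer machinery

K-mers are stored **canonically** — the lexicographic minimum of a
k-mer and its reverse complement — so counting and subtraction are
strand-robust; sequencing reads and assembled contigs have no defined
strand. Windows containing an ambiguous base (N) are dropped rather
than patched. Subtraction removes a sample k-mer when its count in the
reference table is at least 2 (`min_reference_count = 2`): a singleton
observation in the reference is treated as noise, in keeping with the
tolerance-reference role of the mTEC database. No occurrence threshold
is applied on the sample side by default.

Assembly is **unique-extension unitig assembly** on the
(k−1)-overlap graph: a seed k-mer is extended left and right while the
current node has exactly one successor and that successor exactly one
predecessor. Branches, already-consumed k-mers and reverse-complement
palindromes terminate the walk; there is no heuristic branch
resolution, so repeats ≥ k−1 split contigs deterministically. Every
k-mer of the input lands in exactly one contig (asserted by test), and
output is sorted by (length desc, sequence asc) with each contig in
canonical orientation, making assembly byte-reproducible.

Defaults: k = 33 for the cancer-specific database, k = 24 for the
smRNA database.

## Translation and database packing

Standard genetic code (table 1); any codon outside the standard sense
table — stops, codons with ambiguous bases, the contextual
selenocysteine codon — translates as stop. Translations are split at
**every** stop codon and all fragments ≥ 8 aa are kept
(`split_all`; a `prefix_only` switch keeps only the pre-stop prefix).
Keeping all fragments maximizes the candidate space, which is the
desired behavior for a search database. ERE reads are translated in
all **6** frames because read strand is unknown; contigs (smRNA and
cancer-specific) in **3** frames because canonical orientation already
collapses the strands.

Polypeptides are packed into entries of at most 10,000 aa joined by
the two-residue linker `JJ`, in (length desc, sequence asc) order with
sequential first-fit. Because J is not a residue of any candidate
peptide, no 8–11-mer window of an entry can span a linker; splitting
entries on `JJ` exactly recovers the packed polypeptides (tested).

## Identification filtering

The decoy-based FDR estimate at score threshold t is
(# decoys ≥ t) / (# targets ≥ t). The operating threshold is the
*minimum* t with estimate ≤ the requested FDR (default 1%); targets
scoring exactly t are retained and decoys at t are counted — the
conservative tie convention. On synthetic lists where false targets
share the decoy score distribution, the realized false-discovery
proportion averages ≈ 1% at the 1% setting (measured over 500 lists by
the acceptance script).

Binding filters keep peptides of 8–11 aa whose minimum predicted
eluted-ligand rank over the sample's typed HLA alleles is < 2%. The
shipped predictor is a mock: ranks derive from a SHA-256 hash of
(peptide, allele), uniform on [0, 100), identical across platforms,
with an override table for planting binders; a real predictor can be
plugged in through the same one-method interface.

L/I disambiguation: leucine and isoleucine are isobaric, so a
candidate whose L↔I variant is a retained non-candidate peptide is
discarded unless the candidate's RNA expression exceeds the variant's,
or the variant maps only to excluded region classes (hypervariable /
discordant), where its flag is unreliable.

## Expression in rphm

rphm = reads containing the full MAP-coding sequence (either strand)
per 10^8 total reads. Containment of the complete coding sequence is
the desk-scale counting unit; partial overlaps do not count. A tissue
is flagged as expressing an antigen when **strictly more than 10%** of
its samples exceed **8.55 rphm** (a fraction of exactly 0.10 is not
flagged); tissue summaries also carry mean rphm and mean
log10(rphm + 1) — log10 chosen as the heatmap-friendly convention.

## Classification rules

Ordered, short-circuiting, each step recorded in the call's trace:

1. **Origin.** Exact genomic placements of the coding sequence (both
   strands). Any exonic placement with ≥ 1 supporting read ⇒ exonic;
   otherwise the placement with most supporting reads wins. Reads are
   attributed to a placement when they fall inside its flanking
   context, which distinguishes repeated placements. Hypervariable
   placements (MHC/Ig/TCR-like loci) and sequences with no supported
   placement are excluded ⇒ rejected.
2. **Cohort prevalence.** Fraction of cohort samples with
   rphm > 2 must be ≥ 5%.
3. **mTSA.** Any coding-sequence variant absent from the germline
   polymorphism table.
4. **aeTSA.** Every normal tissue except testis non-expressing per the
   rule above; mTECs, blood and marrow count as normal tissues. The
   testis is exempt (immune-privileged, basis of the cancer-testis
   pattern).
5. **TAA.** Tumor-group mean rphm ≥ `taa_fold` (default 3) × the
   maximum mean among normal **nonhematopoietic** tissues
   (blood/marrow/mTEC excluded from the comparator; testis included).
   The fold-change quantification is this package's own choice: the
   qualitative criterion "overexpressed in tumor versus normal
   nonhematopoietic tissues" needs a numeric rule, and a 3× group-mean
   ratio is a conventional, configurable default. The trace records
   the comparator value and the fold achieved.

Because profiling is restricted to the exact MAP-coding sequence,
cancer-specific isoforms of otherwise expressed genes classify as
aeTSA automatically — no isoform-level special case is needed.

## Presentation and survival

Presented(antigen, sample) ⇔ rphm > 2 **and** rphm > the antigen's
nonnull median (median over samples with rphm > 0; an antigen with
all-zero expression is never expressed) **and** the patient has an
allele with predicted rank < 2%. Presented ⊆ expressed holds cell by
cell. Patient ids must be unique (one biopsy per patient).

The two-group log-rank test uses the hypergeometric variance with the
simultaneous-event convention for ties and a 1-df chi-square
reference; zero variance (e.g. identical groups) returns statistic 0,
p = 1. The implementation is cross-checked against lifelines in the
test suite. The median split assigns "high" strictly above the median
and "low" at or below, so degenerate all-equal counts produce an empty
high group (with a warning) rather than an arbitrary split.

## Synthetic data: what it emulates, what it does not

**Genome** (default 50 kb): non-overlapping exon / intron / ERE /
hypervariable tracks with intergenic gaps; exons carry a planted ORF
(ATG + sense codons + stop). Planted transcripts are exact genome
substrings; per-region fractions are flagged *tumor-only*.

**Reads** (default 100 nt): error-free exact substrings of expressed
transcripts, Poisson counts around the configured depth, uniform start
positions. Error-free reads keep subtraction ground truth exact; a
substitution-error rate is available and defaults to 0. Tumor-only
transcripts in an mTEC sample are rejected as an invalid
configuration. The relative sequencing depth of mTECs versus tumors is
not specified anywhere authoritative; equal depth is the default and
it is configurable. The default tissue panel: 2 tumors (expressing
everything, one shared exonic transcript boosted 10×), 3 mTECs,
2 testis (plus one tumor-only ERE transcript, emulating a
cancer-testis pattern), 5 normal tissues × 3 samples, blood and
marrow × 2 — a desk-scale surrogate for GTEx/mTEC/marrow panels.

**Identifications**: true peptides are 8–11-aa substrings of database
entries (never spanning a JJ linker) with Normal(3, 1) scores; decoys
are reversed peptides with Normal(0, 1) scores; optional false targets
share the decoy score distribution and carry a ground-truth false
label, enabling realized-FDR measurement.

**Cohort** (default 200 patients): genotypes are 6 alleles drawn from
a 24-allele pool. Presentation is **allele-specific**: each antigen is
assigned one presenting allele (rank drawn below 2%; all other alleles
well above), so a random patient can present a given antigen with
probability 6/24 = 0.25. This mirrors the biology — a given MAP
typically binds one HLA allotype — and it is what makes presented
counts genuinely HLA-driven rather than expression-driven. Antigen
expression is zero with probability 0.3, otherwise lognormal
(ln-scale mean 3, sd 1; median ≈ 20 rphm). Survival is exponential
with hazard (1/1500 d⁻¹) × hazard_ratio^I, where I indicates a
presented count above the cohort median; administrative censoring at
3,000 days (≈ 14% censored under the null). The exponential model is
the simplest with a plantable hazard ratio, and the log-rank design is
distribution-free.

Not modeled: MS spectra, retention times, TMT channels; paired-end
reads; splicing beyond whole-transcript presence/absence; pseudoalign-
ment/TPM estimation (TPMs are supplied); live predictor or database
lookups. Passing tests therefore demonstrate the correctness of the
decision logic and its operating characteristics under these
idealized conditions, not robustness to alignment artifacts,
sequencing error or search-engine score miscalibration.

## Operating characteristics (recomputed by `scripts/acceptance.py`)

* Type-I error of the presented-count log-rank chain at α = 0.05 under
  hazard_ratio = 1: within [0.03, 0.07] over 1,000 replicate cohorts.
* Power at hazard_ratio = 0.4, n = 200: > 0.8 over 200 replicates.
* HLA-restriction contrast: the presented split beats the
  expression-only control in ≥ 80% of replicates. Permuting HLA
  genotypes across patients collapses the association; a small
  residual above the nominal level (≈ 0.1 at these settings) is
  expected, because the "> 2 rphm and > nonnull median" rule leaves an
  expression component in presented counts that permutation cannot
  remove. Analytically, the correlation between original and permuted
  presented counts is (1−e)·P / (1−eP) per antigen, with e the
  per-sample probability of qualifying expression (≈ 0.35 at the
  defaults) and P the probability of carrying the presenting allele
  (0.25), giving ≈ 0.17 — enough for slightly-above-α rejection under
  a strong planted effect, and no more.

## Problem sizes

Defaults are desk-scale by design: 50-kb genome, ~18 transcripts,
hundreds of reads per sample, 250-record identification lists,
200-patient cohorts, and replicate counts of 200–1,000 for the
simulation studies. These sizes make every ground-truth assertion
exact and keep a full run in seconds while exercising every rule the
full-scale analysis would use; all of them are config fields.
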