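# Methods

This note records the models, parameter choices and numerical decisions
behind `pxmir`, and what the synthetic validation does and does not show.

## Synthetic study generator

The generator (`pxmir.simulate`) emulates a four-library small-RNA
time-course (control, 2 h, 4 h, 6 h) at desk scale. Defaults: 30,000
reads per library on a 100 kb single-contig genome carrying 30 known and
6 novel miRNA precursors, structural-RNA loci (rRNA, tRNA, snRNA,
snoRNA), repeat/exon/intron intervals, and 8 unstructured decoy loci.
The real experiment it mirrors sequenced ~12–15 M reads per library; we
scale depth and genome size down by roughly three orders of magnitude so
a complete run takes under a minute while preserving every statistical
feature the pipeline consumes (count ratios, length modes, filter
fractions). Counts are multinomial given per-class probabilities — the
simplest model consistent with single-library-per-condition sequencing;
no overdispersion by default.

Key choices:

* **Expression distribution.** Known-miRNA abundances are log-uniform
  between 2 and 1500 expected reads (at 30 k depth), so the catalog spans
  both abundant miRNAs and ones straddling the count-10 and TPM-1
  filters. Differentially expressed miRNAs get a fixed base proportion
  (0.006, i.e. ~180 expected control reads) so the power analysis runs at
  a defined operating point.
* **Fold-changes in proportion space.** A planted linear fold-change
  multiplies the miRNA's read proportion in the treatment library and the
  unannotated-background class absorbs the difference, so the planted
  log2FC is exactly what TPM-based estimation should recover (no
  renormalization bias).
* **Read anatomy.** Each read is (optional 5' contaminant) + insert + 3'
  adapter + filler with Phred+33 qualities. Planted failure classes are
  emitted at exact counts per library: low-quality (30 % of bases below
  Q20), 5' contaminant (12 nt of the 5' adapter prepended), missing 3'
  adapter (verified to contain no adapter match), and short insert
  (10–17 nt). All planted inserts are rejection-sampled to contain no
  internal 3'-adapter match (≥6 nt, ≤1 mismatch) and no 8-nt 5'-adapter
  prefix, so a correct cleaner reproduces the ledger *exactly*, read for
  read — any discrepancy is a bug, not noise.
* **Length profile.** miRNA-derived inserts are 21–22 nt (15 % are
  3'-trimmed isomiRs); other small-RNA and background inserts follow a
  distribution peaked at 28 nt, giving the bimodal 22/28 histogram
  characteristic of miRNA plus piRNA-sized populations.
* **Decoy loci.** Novel-miRNA discovery needs abundant unannotated tags
  that must be *rejected*. Decoys are A/C-only low-complexity regions: no
  Watson–Crick or wobble pair can form, so their excisions fold to 0
  kcal/mol and fail the MFE criterion deterministically. (Random-sequence
  decoys would be a weaker test: like real genomic background, random
  100-mers fold below −19 kcal/mol under any energy model, and rejection
  would then rest only on the stochastic randomization test.)
* **Planted target sites.** Strong sites are the reverse complement of
  miRNA positions 2–22 followed by an A (8mer seed plus full 3'
  complementarity). Weak decoy sites are seed-only, with the 14 nt facing
  the miRNA 3' half rejection-sampled to be non-pairing, so they cannot
  drift over the alignment/duplex thresholds by chance. Decoy UTRs are
  free of even the 6-mer seed core. qPCR tables encode
  `Ct_target = 25 − log2(relative expression) + N(0, 0.1)` against a
  constant reference, so 2^−ΔΔCT recovers the planted fold-change.

What passing on this generator does **not** show: robustness to
sequencing error inside reads, adapter variants, overdispersed counts,
multi-mapping ambiguity on repetitive genomes, or isomiR 5' heterogeneity
— none of which the generator produces.

## Read cleaning and annotation

Filter order is fixed: low quality → 5' contaminant → missing 3'
adapter/insert → length, with the first failing filter claiming the
read. "Low quality" is operationalized as more than 20 % of bases below
Q20 (the source protocol leaves it undefined); the 3' adapter is located
by the first position whose ≥6 nt adapter-prefix match has ≤1 mismatch,
scanning 5'→3'; a 5' contaminant is an exact 8 nt prefix of the 5'
adapter. Inserts outside 18–30 nt are removed by the length filter.

Mapping is exact and full-length on both strands via an 18-mer prefix
index (tags are ≥18 nt). Exact matching replaces a seed-and-extend
aligner deliberately: it keeps an enumerable brute-force oracle, and the
generator plants no mismatches. Annotation overlap is ≥1 nt against the
GFF3 features, with class priority rRNA > tRNA > snRNA > snoRNA > scRNA >
known miRNA > repeat > exon > intron and `unannotated` as fallback;
multi-mapping tags are classified across all their hits but counted once.

## Folding energy model

`pxmir.fold` is a Nussinov-style dynamic program over nested structures
scored with a deliberately small energy model, *not* a Turner-parameter
implementation: one stacking energy per pair type (G:C −3.0, A:U −2.0,
G:U −1.0 kcal/mol) for a pair sitting directly on another pair, a
constant +3.0 hairpin-closure penalty, a constant +2.0 penalty for a pair
enclosing non-stacked structure, and a minimum hairpin loop of 3 nt.
Energies are integers in tenths of kcal/mol internally so ties are exact;
ties prefer more pairs, then 5'-most pairing in the traceback. The
pipeline only consumes an MFE threshold and a dot-bracket string, and the
acceptance checks compare against exhaustive structure enumeration under
the same model, not against published energies. Under this model a
perfect 22-bp precursor stem folds to ≈ −50 kcal/mol and random 100-mers
to ≈ −35, so the −19 kcal/mol criterion separates paired from pair-poor
sequences, with the randomization test carrying the discrimination
against merely-random stability (as it does for the real tools).

The duplex scanner shares the stack table, adds +2.0 kcal/mol per
unpaired nucleotide between paired neighbors (at most 3 per side), and
takes the minimal-energy window per locus (window = miRNA length + 8,
step = half-window).

## Randomization test

`randfold_test` compares the observed MFE to dinucleotide-preserving
shuffles (Altschul–Erickson Euler-path construction: fixed last-edges
forming an arborescence into the final vertex, remaining edges permuted).
p = (1 + #{shuffles ≤ observed}) / (1 + n), bounded below by 1/(n+1); 199
shuffles give a floor of 0.005. In the pipeline the test runs only for
candidates that already pass the score and MFE criteria (skipped
candidates report p = 1.0, "no evidence"); the accepted set is provably
identical, since acceptance is a conjunction.

## Novel-candidate score

The discovery score is `log2(tag count) + 1` if ≥60 % of the tag's
positions are paired in the chosen excision (a star arm exists), else
`− 1`. It is recorded as `simplified_score`: it is a documented
simplification standing where a read-signature Bayesian model would be in
a full rediscovery tool, and nothing downstream interprets it beyond the
`> 1` acceptance cut. Tags with fewer than 10 total reads are not
examined, and tags stacking on an already-examined locus are collapsed
into it.

## Exact test

`p(y|x)` is computed in log space via `lgamma`, safe to counts ~10⁷; the
lower tail is a vectorized log-sum. `C + D = 1 + p(y|x)` holds to 1e−9 by
construction (both tails include the observed point). The two-sided
p-value doubles the smaller tail (capped at 1) — the conventional choice
where the source only defines the two tails. `N1`, `N2` are the
per-library clean-read totals; the alternative reading (per-miRNA
normalized expression) would make the ratio circular. Note that the
doubled-tail p-value is *not* exactly symmetric under swapping the two
libraries at small counts (e.g. x=0, y=1 at equal depths gives 1.0 one
way and 0.5 the other); this is a property of inclusive discrete tails,
not an implementation artifact, and the tests pin the identities that do
hold exactly.

## Target predictors

All three predictors are documented simplifications configured with
explicit defaults: seed scan calls ≥7mer site types; the alignment scores
+5 Watson–Crick, +1 G:U, −4 mismatch, −8/−2 affine gaps, seed columns
(miRNA positions 2–8) doubled, threshold 80, greedy non-overlapping
extraction; the duplex threshold is −20 kcal/mol. A perfect 22-nt site
scores 145, so the 80 threshold admits roughly 16-nt-equivalent
complementarity; on 400-nt random UTRs occasional alignment or duplex
calls do occur, and specificity comes from requiring all three predictors
to overlap (≥1 nt, same miRNA, same transcript, transitive clustering
into "spots"). Consensus is site-level; gene-level aggregation is the
set of transcripts carrying a consensus site.

## Enrichment and qPCR

Enrichment is the upper-tail hypergeometric probability per term with
k ≥ 1 target hits, all background genes as the universe, Bonferroni
correction by default (matching the DE stage; BH selectable),
significance at corrected p ≤ 0.05. ΔΔCt is computed per replicate
(rather than from group means) so the SEM of RQ is defined; Tukey HSD
uses the studentized range via statsmodels, and compact letters use
insert-and-absorb, lowercase at α = 0.05 and uppercase at α = 0.01.
Letters compare time points within each miRNA.

## Determinism and scale

One seed drives everything: the generator derives independent substreams
per stage from `SeedSequence([seed, k])`, so changing one stage's
internals never perturbs another's randomness, and two runs with the same
config produce byte-identical inputs, intermediates and reports. The
default problem sizes (30 k reads × 4 libraries, 100 kb genome, 60 UTRs)
were chosen so a full pipeline run completes in well under a minute on
one CPU; all thresholds are configurable through `PipelineConfig`.

## Known limitations

* Exact-match mapping cannot model mismatch tolerance; mapping
  percentages on real data would differ.
* The energy model's absolute kcal/mol values are calibrated only in the
  sense that planted stems clear the −19 threshold and pair-free
  sequences do not; they are not comparable to ViennaRNA/Turner values.
* The simplified candidate score is not a probabilistic read-signature
  model; it cannot rank marginal candidates the way a full rediscovery
  tool would.
* Single library per condition: the exact test models sampling noise
  only, not biological replication — as in the study design it mirrors.
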