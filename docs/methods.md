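# Methods

This note documents the statistical models, the synthetic-data
generator, numerical conventions, and the design decisions taken where
more than one reasonable construction existed.

## Adjacency co-regulation

### Definitions

Genes are ranked per chromosome by `(start, end, gene_id)`; coordinates
are 1-based inclusive (GFF3 convention; BED input is converted on
ingest, `start = bed_start + 1`). "Immediately adjacent" means
consecutive ranks in the full gene catalogue — no intervening annotated
gene of any kind. This is the strictest reading of adjacency and is
fully deterministic; looser readings (e.g. within-k-genes windows) are
deliberately out of scope.

Given a signed DE set (default selection `|log2FC| ≥ 0.8`, i.e. 1.74-fold,
and `p ≤ 0.05`, both boundaries inclusive):

* a **co-regulated set** is a *maximal* run of ≥ 2 consecutive-rank
  genes, all in the DE set with the same sign. Maximal runs are counted
  once whatever their length — a run of three is one set, not two
  pairs — and the run-length distribution is recoverable from the
  per-set member lists;
* a **discordant pair** is any consecutive-rank DE pair with opposite
  signs. A gene may simultaneously terminate a concordant run and
  participate in a discordant pair (signs +,+,− yield one set and one
  discordant pair); forbidding this would under-report discordance;
* **duplicate exclusion**: an adjacency link whose two genes share a
  `family_id` is removed before runs are assembled (and counted), since
  co-regulation of tandem duplicates is parsimoniously explained by
  duplicated regulatory elements rather than chromatin state. Family
  assignment is a user input (or the generator's truth labels); no
  paralog inference is built in.

The genomic span of a set is `max(end) − min(start) + 1` over its
members (1-based inclusive). The opposite-strand fraction is computed
over all *within-set consecutive pairs*; it is reported as NaN — never
0 — when there are no pairs.

### Enrichment tests

Three complementary nulls are computed, because no single construction
is canonical:

1. **Control-cohort χ².** The control cohort contains the genes with the
   smallest `|log2FC|` (DE genes excluded, exact-zero folds excluded),
   taken alternately from the positive- and negative-fold pools in order
   of increasing `|log2FC|` (ties broken by gene id), so that up/down
   counts differ by at most one. The mean log2FC of the cohort must lie
   within ±0.05 of zero (configurable); violation is an error rather
   than a silent warning. Control genes are scored for adjacency exactly
   like DE genes (sign = sign of their small fold change). The test is a
   Pearson χ² on the 2×2 table {cohort: DE, control} × {gene is a member
   of a same-sign adjacent run: yes, no}, df = 1, **no** continuity
   correction, upper-tail p. A zero table margin makes the test
   undefined and is reported as NaN.

2. **Binomial sign model.** If deregulation directions were independent
   across adjacent genes, a DE–DE adjacent pair would be sign-concordant
   with probability `P_conc = p² + q²` and discordant with
   `P_disc = 2pq`, where `p` is the up fraction among DE genes. Observed
   discordant pairs then estimate the chance rate of adjacency itself,
   so `E[concordant] = n_discordant · P_conc / P_disc` and the
   enrichment ratio is `(n_up_sets + n_down_sets) / E[concordant]`. The
   significance is the exact binomial upper tail of the observed
   concordant count among `concordant + discordant` trials with success
   probability `P_conc`. With zero discordant pairs the expectation is
   undefined: the ratio is reported as `inf` (NaN if there are also no
   sets), and the binomial p is still computed.

3. **Label permutation.** Deregulation labels (preserving the observed
   up and down counts) are reassigned uniformly at random over catalogue
   positions; the concordant-set count is recomputed each time, and
   `empirical_p = (1 + #{null ≥ observed})/(n_perm + 1)`. At least 99
   permutations are required. Runs never cross chromosome boundaries
   (enforced with sentinel positions). This null makes no distributional
   assumption and validates the two analytic tests; it is also the only
   one immune to questions about how the control cohort should be built.

All randomness flows through `numpy.random.default_rng(seed)` from a
single integer seed; identical seeds give bit-identical outputs.

## Cross-study concordance

A reference list maps genes to expected signs (+1, −1, or unsigned).
*Overall* concordance counts reference genes significantly changed in
the query in either direction (default filter: `p ≤ 0.05` with any
nonzero fold; the fold threshold is configurable); *strict* concordance
additionally requires the observed sign to equal the expectation, so
strict ≤ overall always. Reference genes never measured in the query
remain in the denominator by default — this matches how such
percentages are conventionally reported (e.g. 34 of 113 = 30%) — with
an option to drop unmeasured genes. Percentages are stored unrounded;
display values round half away from zero to integer percent.

## Genetics statistics

* **Segregation χ²**: `expected_i = total · ratio_i / Σratio`,
  `χ² = Σ(obs − exp)²/exp`, df = classes − 1, upper-tail p, no Yates
  correction (the correction would change the classic 1:3 worked
  examples from 0.32/0.77 to different values; uncorrected χ² is the
  convention for segregation tables). Invariant under rescaling the
  ratio.
* **Group summary**: mean and SEM = sample SD (n−1 denominator)/√n;
  n ≥ 2 required.
* **Fold effect**: numerator/denominator rounded half away from zero to
  a stated number of decimals — the convention of printed fold tables.
  Note that folds recomputed from *rounded* printed group values can
  differ from a table's printed fold by one unit in the last digit,
  because published tables are computed from unrounded raw data; the
  bundled checks therefore accept one-ULP agreement when the inputs are
  themselves printed values.
* **t-tests**: pooled-variance Student test by default, Welch optional,
  paired variant when samples align; all two-sided, df reported.

## Splice-consequence prediction

The gene model stores exon and intron sequences explicitly, the CDS
start offset within the mature mRNA (which must be an ATG), and the
annotated protein length (validated against the translated CDS on
construction). The donor-site check is reduced to the invariant GT
dinucleotide at intron positions 1–2 — no position-weight-matrix
scoring, since the question addressed is a point mutation at position 1.
Intron retention concatenates the intron in place; translation
(standard nuclear code, UGA/UAA/UAG stops, via Biopython) proceeds from
the ATG to the first stop. Residues whose codons end at or before the
exon–intron junction count as retained; later residues (including a
codon spanning the junction) count as novel; the stop position is the
1-based intron coordinate of the stop codon's first base. A cryptic
downstream donor can be modelled by retaining a frame-preserving prefix
of the intron (off by default; 21 nt adds seven residues).

The bundled TOP6B-like reconstruction is synthetic: the true genomic
sequence is not distributed, so a sequence is engineered with the
published geometry (2212-nt mature mRNA, 670-aa protein, 300-nt intron 7
after codon 198, a Met; mutant intron starting AT and encoding IIIYSYQV
then UGA at nt 25). The engineered expectations are fixed by
construction — reverse translation chooses the codons — not by running
the predictor, so the fixture is a genuine oracle. Note the junction
phase must be 0 and the *mutant* intron must start with the A of the
G→A substitution for the novel peptide to begin with Ile; the wild-type
GT donor would encode Val.

## Synthetic-data generator

What it emulates: ordered, strand-labelled, non-overlapping genes along
chromosomes (log-normal lengths, median ≈ 1.8 kb, and log-normal
intergenic gaps, mean ≈ 2 kb — compact plant-like spacing); a DE table
of null genes (`log2FC ~ N(0, 0.25)`, `p ~ U(0,1)`) with injected
blocks of 2–3 immediately adjacent genes sharing one sign
(`|log2FC| = 2.0 ± 0.15`, p drawn as `10⁻⁴ · Beta(1, 9)` so
thresholding behaves smoothly); optional adjacent duplicate pairs with
shared family id and correlated folds; binomial progeny counts; and the
splice fixtures above. Blocks are placed with a one-gene buffer so each
injected block is a maximal run, making truth labels directly
comparable to detected sets. Defaults (5 chromosomes × 1000 genes, 10
blocks of 2 at effect 2.0) run the full pipeline in under a second.

What it does **not** emulate: microarray intensities, dye effects or
normalization artefacts, expression correlation beyond the injected
blocks, gene-density or strand biases, overlapping or nested genes.
Consequently, passing tests demonstrate the correctness and calibration
of the statistics under the stated generative model — not robustness to
annotation errors or platform-specific noise in real data.

### Calibration and recovery checks

* With zero injected blocks the permutation p-value is calibrated: its
  rejection rate at α is inside a 3σ binomial band over 200 replicate
  simulations (mildly conservative because the set-count statistic is
  discrete). The calibration run uses a permissive selection
  (`null σ = 1.5`, `p ≤ 0.5`) so enough null genes are selected for the
  statistic to have spread; with the strict defaults almost no null
  gene passes and every p-value is 1, which is conservative but
  uninformative.
* Power is non-decreasing in the number of injected blocks (checked at
  0/5/15 blocks, fixed seeds).
* With 10 injected blocks of effect 2.0 in a 5 × 1000-gene genome, the
  default selection recovers ≥ 95% of injected members, the detected
  set count reaches 10, and the control-cohort χ² gives p < 0.01, in at
  least 19 of 20 seeded runs.

Problem sizes used in the test-suite simulations (2 × 400 genes for
calibration, 5 × 1000 for recovery, 99–199 permutations) keep a full
`pytest` run under ten seconds while leaving the binomial bands tight
enough to detect calibration errors of a few percentage points.

## Numerical conventions and degenerate inputs

* Undefined fractions/statistics are NaN, never 0 (empty strand
  fraction, χ² with a zero margin, binomial expectation with zero
  discordant pairs); unbounded ratios are `inf`. JSON reports map NaN to
  `null` and `inf` to the string `"inf"`.
* Ties in control-set selection and catalogue ordering are broken by
  gene id, making every output deterministic.
* Empty annotation files are valid (empty catalogue); an empty DE set
  produces a zeroed report with NaN test fields.
* Display rounding is half away from zero everywhere a printed value is
  mimicked; stored values are never rounded.

## Known limitations

* Adjacency is defined on gene ranks only; physical distance enters only
  through the span statistic. A distance-weighted null is out of scope.
* The control-cohort χ² treats genes as independent observations; the
  permutation test is provided precisely because that assumption is
  questionable for clustered data.
* Duplicate exclusion depends entirely on the supplied family map.
* The splice module reasons about one gene at a time and does not score
  splicing efficiency or genome-wide variant effects.
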