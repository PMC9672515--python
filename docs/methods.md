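# Methods

`cernapipe` implements a staged competing-endogenous-RNA (ceRNA) discovery
analysis for bulk miRNA / mRNA / circRNA expression profiles collected over
ordered developmental stages (the motivating design: tail adipose tissue at
6, 18 and 30 months, three animals per stage). The pipeline consumes count
matrices and sequences — read QC, alignment and back-splice detection are
upstream and out of scope — and produces per-comparison differential
expression calls, trend-profile enrichments, miRNA target predictions,
gene-set enrichments and direction-constrained mRNA–miRNA–circRNA triad
networks. A synthetic-data generator with planted ground truth makes every
stage testable without any external download.

## Normalization

* **CPM** (miRNA, mRNA): `value = count / sample_total × 10⁶`. By default the
  sample total is the matrix column sum (columns then sum to 10⁶ exactly).
  When the matrix covers only a subset of the library — always the case for
  the simulated data, whose features are a sample from a larger
  transcriptome — the per-sample *total mapped reads* are used as the
  denominator instead. This matters: with tens to hundreds of simulated
  features, column-sum CPM suffers a closure artifact in which a few
  strongly changing features inflate late-stage totals and compress every
  other feature's CPM ratio; per-mapped-reads CPM is immune and is how CPM
  is computed from full libraries in practice.
* **SRPBM** (circRNA): back-splice junction reads per billion mapped reads,
  `value = junction_reads / total_mapped × 10⁹`, with the library's total
  mapped reads supplied per sample.

## Differential expression

For one (later, earlier) stage pair, each feature gets:

* `log2FC = log2((mean_later + 0.5) / (mean_earlier + 0.5))` on the
  normalized scale (pseudocount 0.5 keeps zeros finite; the statistic is
  antisymmetric under swapping the orientation);
* a two-sided Welch (unequal-variance) t-test **on
  log2(normalized value + 0.5)**. The log transform is essential at n = 3:
  count variance grows as μ + φμ², and Welch's degrees of freedom collapse
  toward 2 under the resulting variance imbalance, costing most of the
  test's power on the natural scale (measured sensitivity ~0.64 vs ~0.91
  on the log scale at a planted 4-fold change, mean 500, φ = 0.1) while the
  log scale also keeps the null false-positive rate at ~0.04. Degenerate
  convention: two zero-variance groups give p = 1 when equal, p = 0
  otherwise.

Significance rules (all inequalities strict, no multiple-testing
correction by default, mirroring the original analysis; Benjamini–Hochberg
is available behind a switch):

| layer   | rule                        |
|---------|-----------------------------|
| miRNA   | p < 0.05                    |
| mRNA    | p < 0.05 and \|log2FC\| > 1 |
| circRNA | p < 0.05 and \|log2FC\| > 1 |

Direction is `up` when the later stage is higher. The high-expression
filter keeps features with across-sample mean normalized value strictly
above 1000. The default comparisons are 30M vs 6M, 30M vs 18M, 18M vs 6M.

## Trend profiles

All `(2c+1)^(S−1)` step profiles over S stages are enumerated (c = 2
default: 25 profiles for 3 stages — small enough that no greedy
model-profile preselection is needed). A feature's stage-mean vector is
assigned to the non-flat profile with maximal Pearson correlation to the
profile's cumulative value vector; constant vectors go to the flat profile.
Correlations are rounded to 12 decimals before the argmax so that profiles
whose value vectors are scalar multiples (analytically tied) deterministically
resolve to the lowest profile id. Enrichment permutes each feature's stage
labels independently per round; `expected_count` is the mean permuted count
and `p = (1 + #{rounds ≥ observed}) / (n_perm + 1)` (add-one: never 0).
`n_perm` defaults to 1000 (≥ 100 enforced).

## Target prediction

Canonical seed sites are found by scanning the target for the reverse
complement of miRNA nucleotides 2–7 and classifying each occurrence once at
its highest class: 8mer (m8 match 5′-adjacent on the target plus A opposite
position 1), 7mer-m8, 7mer-A1, 6mer. Watson–Crick pairing only for class
calls.

The 0–100 site score is a **surrogate**: the commercial score the printed
threshold refers to is unpublished, so the scale here preserves the decision
structure — base score by class (8mer 75, 7mer-m8 60, 7mer-A1 55, 6mer 40)
plus 15 × A/U fraction of the 30 flanking nucleotides plus 2 × the longest
consecutive Watson–Crick run between miRNA positions 13–17 and the opposite
target region (capped at 10), total capped at 100.

Duplex free energy is a nearest-neighbor stack sum on the seed-anchored,
gap-free duplex over miRNA positions 1–17: +4.09 kcal/mol initiation,
Turner-2004 Watson–Crick RNA/RNA stack constants (the 10 published unique
values expanded by strand symmetry to all 16 top-strand dinucleotides),
a flat −1.2 kcal/mol for any stack involving a G:U wobble (G:U counts as a
pair in energetics, never in class calls), and +1.0 per unpaired nucleotide
interior to the paired span. This is deliberately not a Smith–Waterman
hybridization alignment; it is desk-scale, deterministic and monotone
(extending a helix by an adjacent pair always lowers ΔG — an isolated
distal pair can cost loop penalty, as in real energetics).

A (miRNA, target) pair is a targeting relationship when the gene-level
score (max over sites) exceeds 50 **and** the gene-level energy (min over
sites) is below −20 kcal/mol, both strict. circRNA targets are scanned on
the linear spliced sequence; junction-spanning sites are not modeled
(known limitation).

## Gene-set enrichment

Over-representation by the exact hypergeometric upper tail
(`scipy.stats.hypergeom.sf`), one test per GMT set intersecting the
universe; the universe is the set of features actually present in the
expression matrix, not a genome. Significant at raw p < 0.05 (BH optional).

## Triad assembly

For one comparison, triad (g, m, c) is emitted iff all three are
significant, m targets g and m targets c (passing pairs), and m's direction
opposes both partners' — which forces g/c concordance, so exactly two modes
exist: down-up-down and up-down-up (ordered mRNA–miRNA–circRNA). Features
with direction "none" never enter triads; output is exhaustive,
duplicate-free and lexicographically ordered. Hub statistics count per-miRNA
mRNA targets, circRNA targets and triad memberships (sorted by total target
degree, ties by id).

## qPCR arithmetic

`2^−ΔΔCt` with `ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,cal −
Ct_ref,cal)`; replicate Ct values are averaged arithmetically before
differencing. Amplification-efficiency correction is out of scope.

## Synthetic data

The generator emulates the study's statistical structure rather than its
sequences:

* counts are negative binomial in mean–dispersion form
  (variance = μ + φμ², one shared φ, default 0.1) with feature-wise
  log-normal baselines (defaults: log-mean 5.3 ≈ 200 counts, log-sd 1.2)
  and per-sample library-size factors drawn log-uniformly (2–5 × 10⁷ mapped
  reads; 1–3 × 10⁶ for the shallower small-RNA libraries, so that highly
  expressed miRNAs genuinely exceed CPM 1000);
* planted DE features change monotonically: each stage step multiplies the
  mean by `2^(±lfc_magnitude)` (default 1.5). Differential miRNAs are
  planted mostly down (default 65%), differential circRNAs mostly up
  (default 60%), emulating the reported age contrast;
* sequences are uniform over {A,C,G,U}; planted target sites overwrite a
  random non-overlapping window with the reverse complement of miRNA
  positions 2–17 plus the class-defining A1/guard bases. The 3′
  complementarity is intentional: seed-only duplexes rarely clear the −20
  kcal/mol gate, so seed-only planting would make the planted truth
  unrecoverable under the stated thresholds. Site classes default to all
  8mer (configurable mix). If a target has no room, it is deterministically
  extended and planting retried;
* each differential miRNA is wired to (default) two anti-directional
  differential mRNAs, two anti-directional differential circRNAs and one
  non-differential decoy mRNA; the implied triads are enumerated
  exhaustively from the planted edges and directions and emitted as truth;
* circRNAs are represented as linear spliced sequences with the back-splice
  junction at position 0; annotations assign host genes among the mRNAs;
  gene sets are random mRNA subsets plus one set collecting the planted
  target genes (a positive control for the enrichment stage).

What the generator does **not** emulate: biological covariance between
features, GC/length biases, isoforms, junction-spanning sites, batch
effects, and realistic sequence composition. Passing recovery tests
therefore demonstrates the pipeline's correctness and statistical behavior
under the stated model, not its accuracy on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale, the
package's own choice of study condition: null calibration on 2000 features;
planted-DE recovery on 10 datasets of 400 features (|log2FC| = 2, mean 500,
φ = 0.1); end-to-end triad recovery on 5 datasets of 25/100/50
miRNA/mRNA/circRNA features with per-step lfc 2.5 ("strong DE": per-member
power ≈ 0.98, so the three-member, two-edge conjunction still clears 80%
recall); trend contrast with 80% down-planted miRNAs and 80% up-planted
circRNAs. Permutation counts are 100–999 depending on context. All
randomness flows from one master seed through `numpy.random.SeedSequence`
fan-out; identical configuration and seed reproduce every output file byte
for byte (no timestamps are written into results).

## Known limitations

* The Welch test at n = 3 is approximate on NB data even on the log scale;
  the documented null false-positive contract is [0.03, 0.07] at p < 0.05,
  not exact 0.05.
* The target score is a surrogate scale; only its threshold semantics
  (score > 50 with energy < −20) are meaningful, not absolute values.
* Direction opposition is the only ceRNA evidence used — no
  expression-correlation test across samples, matching the source design.
* Per-gene (not per-site) thresholding: gene-level score is the best site,
  energy the strongest duplex.
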