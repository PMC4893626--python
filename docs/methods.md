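# Methods

This note records the statistical model behind `hebkit`, the conventions the
classifiers use where more than one convention exists, and what the synthetic
data generator does and does not emulate.

## Setting

An interspecific hybrid carries two homoeologous gene copies, one from each
parental genome — here labelled R (maternal) and C (paternal), after the
cyprinid cross the toolkit was built around (*Carassius auratus* red var. ♀ ×
*Cyprinus carpio* ♂, with an F1 diploid hybrid and an F18 allotetraploid).
Two complementary questions are asked of RNA-seq read counts:

* **Expression level dominance (ELD)** — does a gene's *total* expression in
  the hybrid resemble one parent, the mid-parent average, or neither?
* **Homoeologue expression bias (HEB)** — *within* the hybrid, do the R and C
  copies contribute equally, as read off homoeologue-diagnostic SNPs?

Comparing the diploid hybrid (genome merger only) with the allotetraploid
(merger followed by genome doubling) against the in-silico mid-parent value
(MPV) attributes expression changes to one process or the other.

## Differential expression

Counts are normalised as RPKM, `1e9 * count / (library_size * length_bp)`,
with the library size the library's total mapped reads.  Genes must have at
least one read in every biological replicate of every group under analysis;
this prefilter is the only use made of replicate structure.  For each
contrast, replicate counts are pooled (summed) per group and each gene is
tested with a two-sided Fisher's exact test on
`[[count_A, count_B], [lib_A - count_A, lib_B - count_B]]`.  Two-sidedness
follows the point-probability rule (sum the probabilities of all tables whose
point probability is at most the observed one, with a `1e-7` relative
tolerance), the convention of standard exact-test implementations; the
implementation enumerates the hypergeometric support directly and is verified
in the test suite both against `scipy.stats.fisher_exact` and against exact
big-integer enumeration of every table with margins ≤ 30.

P-values are adjusted by Benjamini–Hochberg across genes (delegated to
`statsmodels`).  A gene is called `up`/`down` only when **both** q ≤ 0.05 and
|log2FC| > 1 ("fold change > 2"); otherwise `ns`.  log2FC is computed from
pooled RPKM with a pseudocount of 0.5 added to pooled counts — for the fold
change only, never for the test — so silenced genes keep a finite fold.

Pooling replicates makes the Fisher test anti-conservative for overdispersed
counts: with negative-binomial noise nearly every well-expressed gene reaches
a small q at a 1.1-fold difference.  The fold-change requirement is what
restores type-I control in practice; the null-simulation suite verifies that
the *joint* call rate stays at or below the nominal level.

## ELD categories

Three calls — hybrid vs R (`call_hr`), hybrid vs C (`call_hc`), R vs C
(`call_rc`, direction R relative to C) — index a decision table with twelve
Roman-numeral categories:

| category | call_hr | call_hc | call_rc | reading |
|---|---|---|---|---|
| I | down | down | up | transgressive down, R > C |
| II | down | down | ns | transgressive down, R = C |
| III | down | down | down | transgressive down, R < C |
| IV | up | up | down | transgressive up, R < C |
| V | up | up | ns | transgressive up, R = C |
| VI | up | up | up | transgressive up, R > C |
| VII | up | ns | down | paternal ELD at the higher C level |
| VIII | down | ns | up | paternal ELD at the lower C level |
| IX | ns | down | down | maternal ELD at the lower R level |
| X | ns | up | up | maternal ELD at the higher R level |
| XI | up | down | down | mid-parent, R < C |
| XII | down | up | up | mid-parent, R > C |

All-`ns` triples are `conserved`; the remaining 14 triples (e.g. parents
differ but the hybrid matches both) are `ambiguous` rather than forced into a
category.  The numeral assignment for VII–XII is fixed by which categories
appear in the hybrid-vs-parent up/down sets (vs C up = {IV, V, VI, X, XII},
vs C down = {I, II, III, IX, XI}, vs R up = {IV, V, VI, VII, XI}, vs R down =
{I, II, III, VIII, XII}); the ordering *within* {I, II, III} and {IV, V, VI}
is not constrained by those sets and follows the conventional scheme above —
it is a documented convention, not a derivable fact.  An enumeration test
pins the full 27-triple partition, and a duality test checks that swapping
the parents' roles permutes categories as I↔III, IV↔VI, VII↔X, VIII↔IX,
XI↔XII with II, V fixed.

## Homoeologue analysis

**Orthologue pairing** is reciprocal-best-hit on BLASTN tabular output:
best hit = lowest e-value, ties broken by longer alignment then smaller
subject id (so orthologue sets are reproducible); pairs are kept at
e ≤ 1e-20 and alignment length ≥ 300 bp.

**Diagnostic SNPs** are mismatch columns of the pairwise transcript
alignment, validated against parental pileups: in each parent with coverage
≥ 5, the expected allele must reach frequency ≥ 0.9.  The thresholds are
package defaults (exposed as parameters); they encode "fixed difference,
not polymorphism" at modest parental depth.

**Read binning**: a read votes R at every overlapped diagnostic site where
it carries the R allele and C for the C allele; the majority vote assigns
the read, with ties, zero informative sites, or an indel/clip over any
overlapped site going to `ambiguous`.  Reads never move between pairs, so
R + C + ambiguous equals the reads mapped to the pair.  On error-free reads
every non-ambiguous assignment is correct by construction, which the
fidelity suite confirms at 100%.

**Silencing / novel expression** use a threshold of 10 reads-homoeologue
per million mapped reads of the library (an alternative normalisation
against informative reads only is a function argument).  R-silencing: the R
homoeologue is silent in the hybrid while parent R expressed the gene;
novel expression: either homoeologue expressed in the hybrid while both
parents are silent.  The two flags are mutually exclusive by construction.

**HEB states.**  The parental state comes from the R-vs-C DE call
(R>C / R=C / R<C).  The progeny state tests the hybrid's R bin against its C
bin with a two-sided Fisher's exact test against a 1:1 expectation, at
P < 0.05 per pair with no FDR (the per-pair convention of the transition
table this reproduces).  1:1 is the natural null because the diploid hybrid
carries one copy of each genome and the allotetraploid two of each; the
shared Fisher margin is the library's total assigned reads.  Transition
classes are a total function on the 3×3 (parental, progeny) grid: equal
states → parental condition (including R=C → R=C), bias collapsing to R=C →
no bias in progeny, new or reversed bias → novel bias (3/2/4 cells,
enumeration-tested).  *Overall* bias requires the significant test;
*potential* bias is the sign of the R/C ratio alone, with ratio exactly 1
counted as potential C bias (the rule is strictly "> 1"; the tie is
documented here and tested).  Zero reads in both bins yields R=C with a
`no_data` flag.

## MPV trajectories

The MPV is the average of the two parents' replicate-mean normalised
expressions.  Because the Fisher machinery needs integer counts, the MPV
pseudo-library is the halved sum of the pooled parental counts, rounded,
with the pooled parental library sizes averaged the same way — this reuses
the exact-test machinery rather than inventing a separate statistic.
"Equality" between MPV, F1 and F18 is a direct DE test between the
respective libraries (not identity of category labels); the choice is
switchable in principle but is the default because the partition's =/≠
notation reads most naturally as pairwise tests.  Classes: all three calls
`ns` → no change; MPV = F1 with F1 ≠ F18 → change due to genome doubling;
MPV ≠ F1 with F1 = F18 → change due to genome merger; everything else →
other.  The HEB-state version substitutes the parental R-C divergence for
the MPV and compares states for equality.  Both partitions are
enumeration-tested (27 call triples → 1/6/6/14; 27 state triples → 3/6/6/12).

## qPCR

Relative expression is 2^−ΔΔCt with a user-named reference assay (β-actin
by default) and calibrator sample, assuming amplification efficiency 2.0.
A target not detected in any technical replicate is reported as
below-detection, never as a number; a homoeologue assay that never
amplifies while its partner does is reported as that homoeologue silenced.
Homoeologue bias offers two ratio conventions.  The default
`expression-ratio` mode converts cycles to expression,
ratio = 2^(meanCT_C − meanCT_R), because lower CT means more transcript; a
ratio above 1 is then R bias, tested by a two-sided t-test on replicate
ΔCt at P < 0.05.  The alternative `raw-ct-ratio` mode reproduces the
printed convention of reporting the plain meanCT_R / meanCT_C quotient
with ">1 ⇒ R bias"; that convention runs against CT semantics, so it is
shipped but not the default, and the discrepancy is deliberately surfaced
rather than silently resolved.

## Synthetic data generator

The generator emulates the four-group design (R, C, F1, F18; three
biological replicates each) with every ground truth recorded per gene.

* **Sequences**: gene lengths uniform on 500–2000 bp; the C orthologue
  differs from R at Bernoulli(0.01) substitution sites (diagnostic SNPs,
  uniform positions).  Defaults give ~10 SNPs per kilobase, a plausible
  scale for fixed differences between genera.
* **Expression**: each gene has a lognormal baseline weight (σ = 1) and a
  programmed ELD category drawn from a configurable mixture (70% conserved
  by default).  The category fixes (R, C, hybrid) multipliers as powers of
  the effect size f = 4.  Transgressive and mid-parent categories place the
  parents f² apart so that *every* relation a category declares significant
  is a true ≥ f-fold difference — with parents only f apart, a mid-parent
  hybrid would sit 2-fold from each parent, exactly at the fold-change
  boundary, and the category would contradict its own definition.
* **Counts**: negative binomial per replicate (dispersion 0.05, shared
  across groups — the field-standard noise model for RNA-seq counts; the
  study this emulates states none).  The reported library size is the
  column sum; expected library size is the design depth (1e6).
* **Homoeologue split**: the hybrid's R component is a *binomial split* of
  the replicate's total count at the gene's programmed mixing proportion ρ
  (f/(1+f), 1/2, or 1/(1+f) by progeny state; 0/1 under silencing).  The
  two homoeologues therefore share each replicate's biological noise, which
  reflects their shared cellular/trans environment and keeps the within-
  hybrid R:C ratio binomially distributed — the regime in which a 1:1
  Fisher test is calibrated.  Two independent NB draws would make the
  homoeologue ratio overdispersed and no count-based exact test could be
  both calibrated and powerful.
* **Hybrid scale**: the allotetraploid is simulated on the same per-library
  scale as the diploid hybrid — sequencing depth, not genome dose, sets
  library size — and identically distributed to F1 by default, so the
  "doubling" trajectory class has a known null rate.
* **Reads**: fixed length 100, uniform start, drawn from the homoeologue of
  origin and aligned to the R transcript (exact coordinates, substitutions
  only); the true origin is encoded in the read name.  No sequencing
  errors by default, keeping binning truth exact.
* **qPCR**: CT = 35 − log2(reads-per-million equivalent) + N(0, 0.15),
  triplicate technical replicates, `ND` sentinel for silenced assays.
* **Flags**: silencing (1%, split between R and C) and novel expression
  (0.5%) are drawn among genes programmed conserved/unbiased so flags never
  contradict a programmed effect.  The rates are set high enough that a
  2,000-gene simulation contains a testable handful of events; observed
  rates in real hybrid liver data are several-fold lower.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: sequencing errors and mapping bias (binning
fidelity is 100% by construction, a ceiling, not a field estimate), splice
isoforms, GC/length bias, polymorphism within parental lines, pair-specific
orthologue alignment artefacts, and per-hybrid differences in silencing
(one flag set applies to both hybrids).  Library-composition bias *is*
present — relative normalisation makes strongly transgressive genes shift
every other gene's apparent fold change — and is visible at small gene
counts; at the 2,000-gene validation scale its effect on calls is small.

## Validation problem sizes

The shipped validation suite uses: 2,000 genes × 12 libraries at depth 1e6
for null calibration and ELD/HEB recovery (the design's default
conditions); a 300-gene bundle for pipeline-level unit tests (with baseline
spread σ = 0.6, see composition note above); 200 genes at depth 5e4 pushed
through FASTQ/SAM for read-level binning fidelity; 60 genes with zero CT
noise for the qPCR identities.  Recovery under the default conditions is
~100% for ELD categories and ~96% for HEB progeny states (the shortfall is
the expected ~5% type-I rate of the per-pair P < 0.05 test on truly
unbiased pairs).

## Known limitations

* The pooled-Fisher design inherits the anti-conservativeness described
  above; it reproduces a two-library exact-test analysis, it is not a
  replicate-aware NB GLM and should not be used as one.
* Percentages are printed with half-up rounding at table precision; the
  audit layer recomputes them from counts and fails a run on mismatch.
* The reference count tables this package reproduces use 3,540
  SNP-diagnosable genes in the HEB transition table and 3,541 in the HEB
  trajectory partition; the one-gene discrepancy is preserved as printed,
  not reconciled.
* MPV pseudo-counts round half-integers; for very low counts this can
  perturb the exact test by one unit.
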