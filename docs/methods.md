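# Methods

## The problem

A small fraction of individuals carry *epivariations* (epimutations): rare,
locus-level DNA methylation states that deviate markedly from the
population. Some are primary events — stochastic errors in establishing or
maintaining an epigenetic state — while others are secondary to a cis
sequence mutation (for example a rare SNV disrupting a CTCF binding site
near the locus). On Infinium-style methylation arrays an epivariation
appears as a cluster of probes in one sample whose β values (fraction
methylated, in [0, 1]) lie far outside the distribution observed across
thousands of reference individuals. Because these events are usually
allelic — one allele switches state while the other does not — the bulk β
shift is roughly half the full range, ~0.3–0.5.

`epivar` implements the full analysis around that observation: outlier DMR
calling, quality control, inheritance classification in pedigrees,
enrichment statistics, linkage to candidate regulatory variants, functional
correlates in expression, and a seeded synthetic-data generator that
provides planted ground truth for every stage.

## The caller

**Reference mode.** Per-probe control summaries (mean, population SD, 0.1th
and 99.9th percentile, min, max; linear-interpolation quantiles, index
h = (n−1)q + 1) are computed once from the control cohort. For each test
sample, every 1-kb window anchored at a probe position is evaluated:

* *hypermethylation*: ≥ 3 probes with β strictly above the 99.9th control
  percentile **and** ≥ 0.15 above the control mean (criterion i), plus ≥ 1
  probe with β ≥ 0.10 above the control maximum (criterion ii; it may be
  one of the criterion-i probes);
* *hypomethylation* mirrors this against the 0.1th percentile, mean − 0.15,
  and minimum − 0.10.

Margins (≥ 0.15, ≥ 0.10) are inclusive; exceedance of the percentile is
strict. Because the criteria depend only on the probes a window contains,
anchoring windows at probe positions enumerates all distinct windows; this
makes the caller exactly checkable against a brute-force enumeration
oracle, which the test suite does on hundreds of random matrices.
Same-direction qualifying windows sharing a criterion-i probe merge into
one call (one biological event, one call); the call span is the probe span.
The extreme-probe requirement exists because single probes routinely yield
outlier values for technical reasons (underlying sequence variants, poor
hybridization); demanding several independent outliers plus one value
outside the entire control range suppresses those artifacts.

**Leave-one-out mode.** For cohorts with no external control set (e.g.
multi-tissue panels), each sample is compared against the rest: a probe
qualifies when its β is ≥ 0.15 beyond the max (or min) of all other
samples, ≥ 3 qualifying probes per window, no extreme-probe criterion.

**Imprinted loci** get a more lenient screen, since loss/gain of imprinting
moves a locus mean by only ~0.25–0.5 of the β scale: per locus, the
sample's mean β across the locus probes is compared with the distribution
of per-control locus means; a call fires at |difference| > 3 control SDs or
sample mean > 0.8 or < 0.2. The absolute rules are applied literally, which
can flag loci whose normal mean is already extreme — callers filtering for
biology should rely on the 3-SD rule at such loci.

## Quality control

* **Sex inference**: 2-means clustering on (mean chrY detection p, mean
  chrX β); the cluster with lower chrY detection p is male. Clustering
  avoids hard thresholds that would depend on cohort composition. Mismatch
  against reported sex flags the sample.
* **Homozygous deletions**: probes over a deleted region have no target DNA
  and report erratic β with failed detection p. Any window of ≤ 3 kb
  holding ≥ 3 probes with detection p > 0.01 in one sample is flagged
  (windows anchored at failing probes, merged when sharing failing probes),
  and DMR calls overlapping a same-sample flag are removed.
* **PCA screen**: samples beyond 4 robust SDs (MAD × 1.4826) from the
  median on any of the two leading components of mean-centered M values
  (logit2 β, clipped at 0.001) are flagged. The robust scale keeps one
  extreme sample from masking itself.
* **Post-hoc exclusion**: samples with > 10 curated calls are excluded
  (strictly greater; the boundary count is retained) — excess calls mark
  array-quality problems rather than many real events.
* **Curation flags** replace manual review: `noncontiguous` (a
  near-control probe strictly between two supporting probes — the signature
  of a random grouping of individually artifactual probes),
  `batch_suspect` (the carrier's processing batch is shifted ≥
  mean_delta/2 in the call's direction at ≥ half the call's probes), and
  `deletion_overlap`. Flagged calls are excluded from summary counts but
  always written to output.

## Inheritance and statistics

Carrier status of a family member at an event is decided by a deterministic
rule: mean β across the event's supporting probes deviating from the
control mean in the event's direction by ≥ 0.15 (mirroring the caller's
mean-deviation criterion). De novo classification requires both parents
present with data and both non-carrier; one carrier parent gives
inherited_maternal/paternal; missing parents without a carrier give
unknown.

Transmission counting: for every distinct segregating event (calls
clustered across samples by shared probes and direction) with a carrier
parent, each child of that parent with data is one informative meiosis,
transmitted when the child is a carrier. Under Mendelian inheritance half
of informative meioses transmit. The deficit test reports two statistics:
an exact two-sided binomial test at rate 0.5 (the headline number) and a
Fisher variant comparing the observed split against the integer-rounded
Mendelian expectation [[t, n−t], [round(n/2), n−round(n/2)]], provided for
comparability with contingency-style presentations of the same deficit.
Note the two differ substantially (the Fisher variant is conservative
because both margins are treated as random); both are printed.

All 2×2 association tests are two-sided Fisher exact tests (p = sum of
hypergeometric probabilities of tables with the observed margins whose
point probability does not exceed the observed one); a zero margin gives
p = 1 by convention. The implementation delegates to SciPy and is
property-tested against a full hypergeometric-enumeration oracle on all
margins ≤ 60. The expression direction test is a two-sided Wilcoxon
rank-sum (exact for group sizes ≤ 25, normal approximation with continuity
correction above), checked against full enumeration for n, m ≤ 7.

## Variant and functional linkage

Rare variants (population AF strictly below the cutoff; 0.1% for
population-scale screens with ±5 kb flanks, 1% for targeted sequencing with
±75 kb flanks) are paired with DMRs by position, annotated with containing
TF motif intervals (containment by the variant's anchor position — the
leftmost changed base for left-aligned indels), and checked for
co-segregation (variant carriers ⟺ DMR carriers among tested samples with
genotypes). The motif-disruption enrichment test counts sample–locus pairs:
each assayed sample at each DMR locus is one Bernoulli observation (≥ 1
rare motif-disrupting variant in the flank or not), carriers vs
non-carriers at the same loci.

Genes link to DMRs through promoter overlap (TSS ± 2 kb, strand-symmetric).
Expression outliers are ranked within the cohort (rank 1 = lowest; z from
full-cohort mean/SD). Allelic imbalance pools ref/alt read counts across
heterozygous transcribed SNVs with depth ≥ 7 per gene–sample *before*
taking the minor-allele fraction (per-site ratios are never averaged);
pooled minor fraction < 0.10 is flagged monoallelic (the threshold is a
configurable package choice).

**Cross-tissue concordance.** For each DMR called in tissue A, the
carrier's population rank of mean β at the event's probes is computed in
both tissues, oriented so 1.0 is most extreme in the call's direction. The
reported Spearman rho is computed over the continuous oriented deviations
(carrier mean β minus cohort median, direction-signed) rather than the
rank percentiles: a genuine outlier is almost always the single most
extreme sample in the tissue where it was called, so percentiles saturate
at 1.0 and their ranks carry no ordering information, whereas the
deviations preserve the magnitude ordering across events. Percentiles are
still reported per event.

## The synthetic-data generator

The generator emulates the structure the analysis assumes — and nothing
more:

* **Genome**: one synthetic autosome (`chrS`) with inter-probe gaps drawn
  geometrically (mean 500 bp), plus optional small chrX/chrY probe panels
  for sex-inference tests. Coordinates 1-based.
* **Baselines**: per-probe means are bimodal — Beta(2,18) (unmethylated),
  Beta(18,2) (methylated), Beta(10,10) (intermediate), mixed 0.45/0.45/0.10.
  Archetypes follow a Markov chain along the chromosome (stay probability
  0.9) so loci are coherent, as CpG islands and methylated domains are; the
  stationary mix equals the configured mix.
* **Noise**: per-sample values are Beta-distributed around the baseline
  with SD 0.02 (typical replicate precision at non-extreme probes;
  variance capped for validity near the boundaries).
* **Epivariations** are allelic: carrier β shifts by ±delta across a run of
  4 probes within 1 kb, clipped to [0.02, 0.98]. Per-event delta is drawn
  uniformly in 0.35 ± 0.10 (0.25–0.45), the bulk excursion range a
  one-allele switch produces; event loci are restricted to runs where the
  full shift is expressible without saturating the clip (baselines
  straddling both extremes cannot host a clean bulk shift), and the
  direction is chosen accordingly. Events never overlap.
* **Deletions**: detection p at ≥ 3 clustered probes drawn uniform
  (0.02, 0.5) and β replaced by uniform noise — the hybridization-failure
  signature. The null detection-p baseline of 0.001 keeps the false flag
  rate at the p > 0.01 threshold effectively zero.
* **Families**: mother, father, 2–4 children; parental events transmit to
  each child independently with probability τ (default 0.5, the Mendelian
  null; the transmission-deficit analyses simulate lower τ explicitly);
  children acquire private de novo events at a configurable per-child rate
  (default 0.1). Defaults for the cohort layer are 200 controls, 20 cases,
  2000 probes, 20 planted epivariations, 5 deletions.
* **Functional layer**: each event gets a synthetic gene with TSS inside
  the span. Carrier expression is placed at ±effect cohort SDs (down for
  hyper, up for hypo; effect ~ Normal(1.5, 0.3)) with a 0.3 residual —
  promoter methylation switches act nearly deterministically on their gene,
  which is what the placement encodes. Hyper-promoter carriers get
  near-monoallelic ASE counts (minor allele ~ Binomial(depth, 0.02));
  everyone else is balanced at 0.5. With probability `motif_coupling` the
  carrier harbors a private rare variant inside a CTCF motif placed in the
  event span; decoy motifs and common background variants are scattered
  elsewhere.

All randomness flows from a single integer seed through NumPy's PCG64;
identical configurations produce bit-identical outputs.

### What the generator does not emulate

Real 450k probe-to-genome annotation, type-I/II probe chemistry differences,
SNPs under probes, cell-composition effects, age drift, and mosaicism are
not modeled. Passing recovery tests therefore demonstrates the pipeline's
correctness on data satisfying its stated assumptions (clustered allelic
shifts well above noise), not robustness to every artifact of real arrays —
those artifacts are exactly what the curation flags and QC screens target,
and each is planted and tested in its idealized form only.

## Problem sizes and numerical choices

Test and acceptance runs use scaled cohorts chosen to make the measured
properties stable: 200 controls / 20 cases / 2000 probes for recovery, 40
families for inheritance, 200 random matrices (≤ 200 probes × ≤ 50
controls) for oracle equivalence, 100–250 replicates for calibration and
power checks. Quantile normalization builds its reference by averaging
per-sample empirical quantile functions on a common grid, which makes it
exactly idempotent on complete matrices and well-defined with missing
cells (rank-interpolated reference; missing stays missing). SD uses the
population denominator n throughout. Ties in ranks take average ranks.
Degenerate inputs (single-sample normalization, probes with < 2 controls,
loci without usable probes, zero-margin tables, constant expression) warn
or skip rather than fail, as documented per function.

## Known limitations

* The caller is a per-sample outlier detector; it does not model covariates
  or smooth regional signal, and recurrent events present in > 0.1% of the
  reference cohort become invisible (they enter the control percentiles).
* Carrier status in pedigrees uses a fixed 0.15 mean-deviation rule;
  mosaic parents below that deviation are classified non-carrier, which
  inflates apparent de novo rates exactly as visual inspection would.
* The Fisher variant of the transmission test treats the rounded Mendelian
  expectation as an observed margin; the binomial test is the statistically
  preferred statistic and the two can differ by an order of magnitude.
* Cross-tissue rho depends on event-magnitude spread; with identical
  planted deltas the deviation ordering is noise-driven and rho loses
  meaning even when concordance is perfect.
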