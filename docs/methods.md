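# Methods

## Problem and model

A multiplex pedigree segregating a phenotype under an apparently dominant
but incompletely penetrant mode of inheritance is exome-sequenced. The
working assumptions, which every downstream rule encodes, are:

1. a single causal allele entered the family through its founding couple
   (so no marry-in carries it);
2. every affected blood member carries it (no phenocopies among the
   affected);
3. carriers may be unaffected (incomplete penetrance), and specific
   unaffected members can be *obligate* carriers — forced to carry by
   their position between affected relatives.

The pipeline consumes a called, annotated VCF (annotation is an input
contract, not computed here) and a 6-column PED file.

## Role classification

Founders paired with another founder form the founding couple(s) and seed
the blood lineage; descent closes it. A founder outside the lineage with a
child by a lineage member is a **marry-in**. An unaffected blood member
with at least one affected child whose other parent is a marry-in is
inferred to be an **obligate carrier** — under assumptions (1)–(2) the
affected child's allele cannot have come from the marry-in side. The
inference is automatic but can be extended by an explicit
`obligate_carriers` config list, because in a real study that designation
is often made by argument rather than algorithm. Members of unknown
affection status join no filter role set: they are neither required
carriers nor excluders, which is the conservative choice in both
directions.

## Filter cascade

*QC stage* — pass iff MQ ≥ 30, MQ0 ≤ 4, DP ≥ 5, QUAL ≥ 50, FS ≤ 10. The
thresholds are phrased as strict removal rules ("< 30 removes"), so each
boundary value passes. The MQ0 clause is implemented as remove-if-MQ0 > 4
(the standard hard-filter direction); a `mq0_literal` flag flips it for
anyone who wants the inverted reading. Records missing a QC field are
rejected with reason `missing_qc_field` unless `missing_field_passes` is
set. The first failing criterion, in the fixed order above, is the
recorded rejection reason, making reports deterministic.

*Functional stage* — rejects synonymous variants, variants whose maximum
recorded database frequency exceeds 0.05 (absent frequency counts as 0: an
unobserved variant is potentially family-specific), variants with no
carrier at all, and variants whose carrier samples have mean depth < 6 or
mean variant-allele fraction < 0.30. "Mutation ratio" is read as the
variant-allele fraction alt_reads/depth. Aggregation over carriers is the
mean by default; a per-sample-minimum mode exists because the choice is
genuinely open.

*Segregation stage* — two sequential predicates whose intermediate counts
are reported separately: (i) every affected member and obligate carrier is
a called carrier; (ii) no marry-in is a called carrier. A missing call
fails predicate (i) (an uncalled required carrier cannot be confirmed to
share) but never satisfies predicate (ii) (only a confirmed carrier
excludes). Both directions are conservative for their predicate;
`missing_as_compatible` relaxes (i).

Stages are per-record predicates, hence idempotent, and QC/functional
commute; both facts are property-tested.

## Prioritization law

`overall = ann × popu × seg_dom`, a product — the combination rule is
forced by the arithmetic of the published candidate table this package
regresses against (`pedprio/data/reference_scores.tsv`).

- `seg_dom = π_a^a · π_u^u` with a = affected non-carriers, u = unaffected
  blood carriers excluding obligate carriers, π_a = 0.1, π_u = 0.8.
  The defaults are calibrated to the factorization patterns visible in the
  published scores (e.g. 5.12E−06 = 0.8³ × 10⁻⁵); both are config knobs
  since the upstream tool's internals are cited, not printed. Exempting
  obligate carriers from π_u is the central modeling commitment: without
  it a perfectly co-segregating variant carried by the obligate-carrier
  father could never score 1.
- `popu`: 1.0 if absent from dbSNP; 0.6 if present without a recorded
  frequency; 0.2 if max frequency < 0.001; 0.02 otherwise (including
  above the 5% filter cut — tiering is independent of filtering). The
  0.001/0.05 boundaries are inferred from the published value patterns
  and configurable.
- `ann`: 1.0 damaging/LoF, 0.8 nonsynonymous, 0.01 synonymous or
  noncoding; unknown classes score lowest with a warning.
- `null-sharing = (1/2)^m`, m = blood-member carriers among non-founders.
  Every published value in that column is an exact power of 1/2, which is
  what identifies it as a sharing statistic over informative
  transmissions; founders are excluded because their genotype is not a
  transmission.

Ranking is by descending overall score with ties broken by higher
population score, then (chrom, pos) — rank order is invariant under any
positive monotone transform of the overall scores.

Known precision caveat: one published row prints an overall score one unit
in the last place away from the product of its printed components
(consistent with the components themselves being rounded); the regression
test therefore allows half an ulp of the printed overall *plus* the
propagated half-ulp of each printed component.

## Expression statistics

- Pooled (equal-variance) two-sample t is the default because it
  reproduces all three published mouse t-statistics (−3.216, 4.946,
  −2.055) from their printed (mean, SD, n) summaries to three decimals,
  while Welch does not; Welch is a flag. Signs follow
  first-argument-minus-second, with the published group orders
  documented in the tests.
- The human before/after-treatment comparison is treated as two-sample,
  not paired, matching the stated analysis; its printed t values (3.652,
  2.131) are not exactly recoverable from 2-decimal summaries
  (recomputation gives ≈3.64, ≈2.15) and are checked as ±0.05 bands only.
- `pooled_t_from_raw` is *defined* as `pooled_t_from_summary` of the exact
  sample moments, so their equivalence is structural; the independent
  cross-check in the tests is `scipy.stats.ttest_ind`.
- K-S normality uses estimated mean/SD with the uncorrected asymptotic
  p-value (common statistical-package behaviour; conservative when
  parameters are estimated); the Lilliefors correction is opt-in via
  statsmodels.
- 2^−ΔΔCt with ΔΔCt = ΔCt_sample − ΔCt_calibrator, ΔCt = Ct_target −
  Ct_reference; invariant under a common shift of both target Cts.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed to the
published regime and are not tuning knobs:

- pedigree template: 22 members in three generations, 9 affected (5 male /
  4 female), five marry-ins, an unaffected father of two affected sons
  married to a marry-in (the obligate carrier). The full parent-child
  structure of the real family is not published; the packaged template is
  one consistent realization, illustrative rather than authoritative.
- causal allele planted heterozygous in a lineal founder and gene-dropped;
  penetrance 0.9 for carriers (a "high but not fully penetrant" dominant
  model), phenocopy rate 0 for non-carriers.
- background variants drawn at founder Hardy–Weinberg frequencies,
  Uniform(0.01, 0.5) by default (or a fixed frequency), with dbSNP ids and
  recorded frequencies; region classes drawn from a realistic
  exome-annotation mix, consequence synonymous/nonsynonymous for exonic
  and noncoding otherwise.
- reads: depth ~ Poisson(70), matching the published per-sample averages
  of roughly 46–80×; alt reads ~ Binomial(depth, 0.5) for hets and
  Binomial(depth, 1 − e_seq), e_seq = 0.005, for hom-alt (e_seq for
  hom-ref), small enough that het/hom allele-fraction distributions are
  well separated at 70×.
- optional per-call genotype-flip rate ε and missing-call rate, each
  injection recorded in the truth record so downstream expectations can be
  recomputed by brute force.
- allele frequencies are stored to 6 significant digits, matching the VCF
  reader's float normalization (cyvcf2 returns 32-bit floats), which is
  what makes read∘write∘read an *exact* identity.

What the generator does **not** emulate: linkage disequilibrium between
background variants, read-level artifacts (strand bias, mapping error —
QC INFO fields are emitted as clean constants), population demography, or
multi-family data. Tests passing on this generator therefore demonstrate
correctness of the *rules* under the stated model, not robustness to real
sequencing pathologies.

The expression generator draws independent Normal(mean, sd) groups; an
exact-moment mode affinely rescales each group so its sample mean/SD equal
the specification, which reconstructs raw data exactly compatible with
published summaries.

## Problem sizes and numerical choices

Simulation-based checks use 200 replicate datasets of 20 background
variants for cascade-vs-brute-force equality, 100 noiseless replicates for
planted-variant ranking recovery, 10,000 replicates for the t-test's
type-I error, and 200 seeds × n = 1000 for K-S calibration — sizes chosen
so each check's sampling error is far below its acceptance band while the
suite stays interactive. All randomness flows through
`numpy.random.default_rng(seed)`; analysis paths are seed-free and fully
deterministic, and a rerun with identical inputs and config is
byte-identical.

## Known limitations

- Dominant model only; recessive/compound-het/X-linked modes are out of
  scope.
- Single-family analysis; no kinship estimation or relatedness checks.
- The published intermediate variant counts (hundreds of thousands of
  called variants down to 26 candidates) depend on the study's raw
  sequencing data, which is not available; they are context, not test
  anchors.
- Annotation is consumed, never computed; the INFO-key schema in
  `pedprio.variants` is this package's own contract.
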