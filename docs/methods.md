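# Methods

This note documents the models, conventions and numerical choices behind
`karyometry`, the assumptions they rest on, and what the synthetic-data
generators do and do not emulate.

## Measurement model and data layout

The unit of observation is one metaphase spread of one specimen: 2n
chromosomes, each with a long-arm length *L*, short-arm length *S* and total
length *TL*, all in μm. Within a metaphase, chromosomes are ranked by
descending *TL* and consecutive ranks form homologue pairs (ranks 1-2 =
pair 1, and so on). In a uniform all-metacentric karyotype there is no
banding or morphology cue to pair homologues by, so size-rank pairing is the
only defensible rule; the data model would accept an explicit pairing if one
were available.

Two repair/validation conventions matter in practice:

- **Arm order.** Arms on a slide are unlabeled; a digitizing step can record
  them in either order. Rows with *L* < *S* are therefore swapped by default
  (logged), because the arm ratio *r* = *L*/*S* presumes *L* ≥ *S*. A strict
  mode rejects such rows instead.
- **Total length.** When a *TL* column is present it is treated as an
  independent measurement and checked against *L* + *S* within a tolerance
  (default 0.05 μm); when absent, *TL* := *L* + *S*.

Tables are plain CSV/TSV with a header, decimal points, and μm units —
deliberately boring so fixtures are bit-exact and round trips are lossless.

## Karyomorphometric statistics

- Arm ratio *r* = *L*/*S* ≥ 1.
- Morphology classes on *r*, lower-inclusive boundaries:
  M [1.0, 1.7), SM [1.7, 3.0), ST [3.0, 7.0), A [7.0, ∞). These are the
  classical Levan-style limits; the classification scheme is a parameter, so
  alternative conventions can be swapped in.
- Relative length RL = *TL* × 100 / Σ*TL*. The denominator is the diploid
  metaphase sum by default; the haploid (pair-averaged) representation is
  used in idiograms, where the ten pair RLs sum to 100.
- Asymmetry index AI = Σ long arms / Σ total length × 100, bounded in
  [50, 100]; AI = 50 exactly when every chromosome has equal arms.
- Karyotype length KL = Σ*TL* per metaphase, or Σ mean *TL* for a population
  summary, so a summary's KL is the sum of its printed per-chromosome means
  by construction.
- Karyotype formula: per-chromosome class labels counted in the fixed order
  M, SM, ST, A and rendered as e.g. `2K = 20M`; the arm number 2AN counts
  two arms for M and SM, one for ST and A (configurable). This convention
  gives 2AN = 40 for twenty metacentrics and matches common usage in ant
  cytogenetics; other communities count differently, hence the parameter.
- Population summaries average across metaphases (one per specimen by
  default; a colony-level grouping first averages within colonies). SD uses
  the sample (n−1) denominator throughout. A summary chromosome's morphology
  is classified from its mean arm ratio, not from a majority vote of
  per-specimen classes, because summaries report one class per ranked pair.
  With a single replicate the SD is reported as 0 and flagged rather than
  omitted.
- Measurement stability is screened with the coefficient of variation of
  per-specimen KL (SD/mean): individual CVs further than one SD from the
  mean CV are flagged. With only two specimens no flag is mathematically
  possible (|x − mean| = SD/√2), which the tests verify.

## Population comparison: analysis of deviance and pooling

Lengths in μm are continuous and roughly Gaussian at these scales, so the
comparison model is a one-way GLM with Gaussian family and identity link —
equivalently a one-way ANOVA. The deviance is the residual sum of squares;
the factor's explained deviance is the between-population sum of squares and
is tested with F = (ΔD/df_factor)/(D_resid/df_residual). The model is fitted
with statsmodels; the test suite checks it against hand-computed sums of
squares to 1e-10 relative.

Per-chromosome comparisons use both homologues of each metaphase as
observations (5 populations × 10 metaphases × 2 homologues gives the
(4, 95) df structure; karyotype length uses one KL per metaphase, giving
(4, 45)). Raw p-values are reported by default — ten parallel tests invite a
multiplicity correction, and a Holm adjustment is available by flag, but the
default mirrors standard reporting practice in this literature.

**Level pooling.** When the population effect is significant, populations
are grouped. A candidate grouping is a set partition of the populations; it
is *acceptable* when the F test of its deviance increase over the full
(all-populations-separate) model — numerator df equal to the number of
levels collapsed — is non-significant at α (non-significant meaning
p ≥ α, the complement of the usual rejection rule). The result is the
coarsest acceptable partition, ties broken by smaller residual deviance and
then by a canonical ordering, which makes the procedure deterministic and
checkable against exhaustive search. Up to 10 levels the lattice is searched
exhaustively (Bell(10) = 115,975 partitions, evaluated from per-level
sufficient statistics n, Σy, Σy²); beyond that a greedy agglomeration merges
the closest-mean pair of blocks whose merge stays acceptable. A greedy-only
definition was considered and rejected: greedy merge order cannot guarantee
agreement with the partition-lattice optimum, and the exact search is cheap
at realistic level counts. Degenerate inputs (zero variance everywhere)
return a single block with a flag; α → 0 pools everything, α → 1 keeps all
levels separate whenever any between-group variation exists.

Blocks are lettered in descending order of block mean ("a" = largest), the
usual compact-letter-display convention.

## Flow-cytometric genome size

The estimator is the standard internal-standard ratio: fluorescence is
proportional to DNA content, so
1C_sample = (peak_sample/peak_standard) × 1C_standard, with the
*D. melanogaster* standard at 1C = 0.18 pg and 1 pg = 978 Mbp. The relation
is invariant under any positive rescaling of the channel axis (gain
changes), and identical whether 2C peaks or doubled 1C estimates are used,
since the ploidy factor cancels.

Peak detection finds strict local maxima (scipy, small prominence floor to
ignore counting noise), keeps those whose events within ±30 channels amount
to ≥ 5% of all events, and summarizes each by the event-weighted mean and SD
in that window; overlapping windows are claimed tallest-first. The standard
peak is identified by proximity to a configured expected channel, or — when
none is given — as the lower-fluorescence peak, which is correct whenever
the sample genome exceeds the standard's (true for 0.30-0.35 pg samples
against 0.18 pg).

QC applies the CV ≤ 5% rule to both the sample and the standard peak
(conservative; applying it to one peak only would be laxer) and requires
≥ 10,000 recorded nuclei. Population estimates are means ± SD over at least
three QC-passing replicates.

## Synthetic data

The generators emulate the two raw inputs at the study's own scale:

- **Measurement tables.** Each population is parameterized by 20 homologue
  means ± SD (packaged verbatim from the published per-population table;
  five populations, n = 10 metaphases each). Per metaphase, each
  chromosome's TL ~ Normal(mean, SD), truncated at 0.1 μm (negligible at
  these parameter values); the arm ratio is uniform on [1.0, 1.3], keeping
  every simulated chromosome metacentric; arms follow from
  L = TL·r/(1+r), S = TL/(1+r); chromosomes are re-ranked by TL, as an
  observer would rank them. Homologue lengths are drawn independently — no
  within-pair or within-metaphase correlation, because no covariance
  information is published; an optional within-pair correlation flag exists
  for sensitivity checks. Consequence: simulated per-metaphase KL dispersion
  is √(Σ per-chromosome variances), which ignores any real within-metaphase
  correlation (e.g. condensation differences between spreads would correlate
  all lengths and inflate KL variance). Passing tests therefore demonstrate
  the pipeline's correctness under independence, not the field-data variance
  structure.
- **Histograms.** Events split between two Gaussian peaks — the standard at
  a nominal channel (default 200) and the sample at the channel implied by
  the fluorescence ratio — with a common CV (default 2%, comfortably inside
  the 5% QC limit), optional uniform background, binned onto a 1,024-channel
  grid so recovery tests include realistic binning error. Debris continua,
  doublets and S/G2 populations are not modeled.

All generators are pure functions of (parameters, seed).

## Problem sizes and tolerances

Defaults mirror the study design: 5 populations × 10 metaphases × 2n = 20
chromosomes, and 10,000-event histograms in 3 replicates. Stochastic
guarantees are stated over seed batteries: 2,000 null simulations for the
type-I error of the F test (checked within two binomial standard errors of
α = 0.05), 200 seeded study replications for power and pooling behaviour
(populations ≥ 10 μm apart in KL are never pooled together), and 200 seeded
histograms for genome-size recovery (within 0.005 pg of truth in ≥ 95% of
seeds). Exact quantities — unit conversions, formula rendering, fixture
sums — are asserted to printed precision; the two populations whose printed
per-chromosome means sum 0.01 μm away from their printed KL are asserted
with exactly that rounding tolerance.

## Known limitations

- Size-rank homologue pairing misassigns homologues when pair means are
  closer than measurement noise; this biases per-rank SDs slightly downward
  for adjacent pairs but leaves KL untouched (KL is a sum over all
  chromosomes).
- Ranking by observed TL inflates the top rank's mean (order-statistic
  bias), visible in parameter-recovery tests as a small positive offset at
  rank 1; it is well inside 3 standard errors at n = 10.
- The Gaussian GLM treats metaphases as independent; colony structure is
  ignored (a mixed model with colony as a random effect is out of scope).
- Peak detection assumes well-separated, roughly symmetric peaks; it is not
  a cell-cycle deconvolution.
- The CV screen and the 5%/10,000 QC thresholds are conventions, exposed as
  parameters rather than hard-coded truths.
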