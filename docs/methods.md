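# Methods

## The measurement model

A pairwise competition between a focal strain and a fluorescently marked
reference, serially diluted 1,000-fold each day (ten generations per day)
and read by flow cytometry every ten generations over thirty, yields a
ln(ratio) series that is linear in generation number with slope equal to
the selection coefficient of the focal strain. `estimate_s` fits that slope
by ordinary least squares over the available time points; a two-point
estimator `ln(R_T/R_0)/T` is available as an option for degraded series.
The OLS slope was adopted as the default because it is the standard
estimator for serial-transfer competitions and uses all observations.

Group processing mirrors how such assays are analysed in practice:

1. **Outlier filter.** Replicates whose selection coefficient deviates from
   the group median by more than 0.008 per generation are removed, in a
   single pass with the median computed on the raw group. Such jumps
   indicate a secondary genetic change in that culture rather than the
   fitness of the construct. The filter is applied to raw (pre-
   normalisation) per-group values, following the natural ordering of the
   protocol. Filtering the kept set again removes nothing (idempotence).
2. **Dye normalisation.** Every estimate is expressed relative to the mean
   control (wild-type) coefficient of its own dye batch, so that additive
   marker effects cancel across the dye swap. Because the same constant is
   subtracted within a batch, the test-minus-control group difference is
   unaffected by the marker effect, and the control group's residual
   variance still estimates the replicate noise, which keeps the
   downstream interval honest.
3. **Group comparison.** The selective disadvantage of an allele is
   mean(control) − mean(test), reported as a positive cost, with a
   two-tailed t-test and a 95 % CI from the t distribution of the mean
   difference. Welch's unequal-variance form is the default (the pooled
   form is available); with 24 near-normal replicates per group the two are
   practically identical, and Welch is the safer default when a filter has
   trimmed one group.

## Per-codon decomposition

Multiplicative fitness across substitutions, `ω = Π(1 − s_i)`, with the
equal-contribution assumption `ω = (1 − s)^N`, gives the per-codon cost
`s = 1 − (1 − s_total)^(1/N)`. The closed form is exact, is the inverse of
`combine_fitness` to 1e-12 over the relevant range (s ≤ 0.01, N ≤ 100),
reduces to `s_total/N` in the small-s limit, and is strictly decreasing
in N for fixed total.

The s-versus-N regression includes the wild-type point (0, 0) by default:
the wild-type allele is the shared reference of each allele series and its
cost is zero by construction. This choice reproduces the published fits
for the three leucine series and is overridable. The additivity test
compares the sum of the half-gene allele costs against the full allele
using replicate-level samples, with a Welch–Satterthwaite approximation
for the degrees of freedom of the three-group contrast.

## Codon-usage statistics

Counting excludes the first 40 codons of each gene (N-terminal codon bias
reflects selection on initiation, not elongation). RSCU is
`count / (family_total / family_size)`; families never observed are
reported as missing rather than zero so that the family-sum invariant
(ΣRSCU = family size) holds exactly wherever defined. Relative
adaptiveness divides by the RSCU of the family's reference codon — by
default its maximum-RSCU codon, configurable per family — so the preferred
codon has wa = 1. log(wa) uses base 10; the magnitudes published for
rare-versus-optimal codon ratios in enterobacterial highly expressed gene
sets are consistent with base-10 logarithms, and only the linearity of the
scale matters for the correlation analyses. The reference gene set
(elongation factors plus ribosomal proteins, in the original analysis) is
user-supplied FASTA; it is a recipe, not bundled data.

## Translation kinetics

`Δt_trans = 1/n_syn − 1/n_wt`, with `n` the summed concentration (µM) of
all tRNA species recognising the codon. Wobble recognition sets are data,
not code: the bundled table (`data/trna_abundance_synthetic.tsv`) is a
synthetic stand-in with E. coli-like isoacceptor structure and standard
wobble rules, usable for testing and demonstration; users with measured
abundances substitute their own TSV (columns `trna_id`,
`concentration_uM`, `codons`). Units are µM⁻¹ and are not converted to
seconds — downstream use is correlation, where only relative scale
matters. Δt is antisymmetric and additive along codon chains by
construction.

## Anti-SD hexamer scan

The scanner slides a 6-nt window at every offset (all three frames,
including windows spanning the protected prefix) and counts windows with
duplex energy strictly below each threshold, −4 and −6 kcal/mol by
default. Energies are a frozen lookup covering all 4096 RNA hexamers,
generated once with an RNA–RNA duplex minimum-free-energy calculation
(ViennaRNA RNAduplex 2.7.2) against the anti-SD sequence 5'-CACCUCCUUA-3'
(the 3' tail of 16S rRNA); `scripts/make_hexamer_table.py` regenerates it.
Freezing the table keeps the scan deterministic and independent of any
folding engine at run time. Both the anti-SD sequence and the energy table
are overridable. mRNA folding ΔΔG values are consumed from a table
(signed values accepted, since published "absolute" changes occasionally
carry sign); folding prediction itself is out of scope.

## qPCR quantification

Relative abundance uses the comparative-Ct method with amplification
efficiency fixed at 2.0 (configurable; no standard curve is modelled):
ΔCt against the mean of the reference genes, expressed as
`E^(−ΔΔCt)` against a calibrator sample. Technical dilutions (1, 1:10,
1:100) are averaged after correcting each Ct by log_E(dilution).
Half-lives come from the rifampicin run-out: OLS of log2(relative
quantity) on time, half-life = −1/slope, with a long-lived RNA (tmRNA) as
the decay reference; a non-negative slope is reported as "not estimable"
rather than as a number. Both quantities are invariant to uniform Ct
shifts (instrument offset).

## Synthetic data generator

The generator emulates the study conditions, and its defaults are those
conditions: twelve replicate cultures per dye batch with the dye swap on
(24 effective replicates per group), observations at generations
0/10/20/30, Gaussian ln-ratio noise with σ = 0.025 per observation
(0.0025 × 10 per ten-generation interval, ≈ 0.1 % per generation on fitted
slopes — comfortably inside the 0.8 % filter window, so ~99 % of clean
control slopes survive filtering), outlier replicates at probability 0.02
carrying a persistent ±0.015-per-generation slope jump (a secondary
genetic change, not measurement noise), and an additive per-dye marker
effect of 0.001 per generation that the normalisation stage must cancel.
Noise is applied to ln-ratio observations, matching how ratio data are
reported; an optional count-level mode draws focal-cell counts binomially
from 50,000 flow-cytometer events for robustness checks. Reference-set
genes are drawn codon-wise from per-family probabilities (default: the
preferred codon takes 0.75 of the mass), started with ATG, terminated with
TAA and free of internal stops by construction. qPCR series use
efficiency-2 amplification, stable reference genes and Gaussian Ct noise
(σ = 0.1).

What the generator does **not** emulate: density dependence or transfer
bottleneck drift in competitions, inter-gene codon correlation or amino
acid composition of real proteomes, position-dependent (accuracy-type)
fitness effects of synonymous codons, primer efficiency differences
between qPCR targets. Passing recovery tests therefore demonstrates the
statistical chain is correct and calibrated under the stated noise model,
not that these real-data complications are handled.

## Numerical and design choices

- Codon indexing is 1-based; the protected prefix is codons 1–40
  inclusive; stop codons are never counted in families nor edited.
- The first-half/second-half boundary is an explicit codon index
  (default: midpoint of the editable range), because the published 13/12
  split depends on the actual positions of targeted codons; halves always
  partition the editable range, so N_first + N_second = N_full for any
  boundary.
- Sequences are normalised to DNA internally; user-facing codons are RNA.
- Degenerate inputs fail loudly: zero decoding pools, unmapped codons or
  hexamers, reference codons with zero RSCU, constant samples in the
  normality check, non-positive ratios, and non-decaying qPCR series are
  all explicit errors or flagged results, never silent numbers.
- Simulation problem sizes in the test suite (10–100 genes of 100–400
  codons, 300–1,000 simulation seeds) were chosen as the smallest sizes at
  which the targeted statistical properties (coverage, calibration,
  convergence) are sharp.

## Known limitations

- The bundled tRNA table is a stand-in: Δt values computed from it have
  realistic structure (non-optimal codons decode slower) but are not the
  measured abundances, so correlations against it are demonstrations.
- The hexamer energy model is a nearest-neighbour duplex MFE against a
  fixed anti-SD tail; it ignores context (flanking structure, spacing to
  the ribosome).
- The per-codon decomposition assumes equal, independent contributions;
  the s-versus-N regressions and additivity tests are the tools provided
  to check that assumption on data.
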