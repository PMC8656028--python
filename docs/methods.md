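# Methods

This note documents the models implemented by `tdprogram`, the assumptions
behind them, and the design choices made where the underlying study left the
procedure open.

## Scientific setting

Human brain microvascular pericytes can transdifferentiate (TD) directly
into neurons. The study this package supports characterized that conversion
through four quantitative readouts, each of which has a bespoke
computational stage here:

1. the higher-order supercoiling state of individual loci, measured by
   electrophoretic fractionation into four zones followed by qPCR;
2. the per-cell propensity of conversion, inferred from population-level
   TD-chase counts through a Poisson model;
3. a single "multi-target" sgRNA designed against a seed region shared by
   hundreds of genes, used to program DNA cleavage genome-wide;
4. the temporal pattern of transcript loss and gain across the TD time
   course, analyzed as a missing-transcript intersection map.

## Zone-topology quantification (`tdprogram.qpcr`)

DNA crosslinked in situ is fractionated by electrophoretic mobility into
zones I (hyper-negatively supercoiled, low mobility) through IV (positively
supercoiled, high mobility), and a locus of interest (LoI) is quantified in
each zone by qPCR. The normalized occupancy of zone *i* is

    LoI_Zi = 2^{ΔCt(Z_i − Z_1)} / Σ_j 2^{ΔCt(Z_j − Z_1)}

**Sign convention.** Read literally, the exponent Ct_i − Ct_1 gives *more*
weight to zones with *higher* Ct — i.e. less template — which inverts
standard qPCR semantics. Whether the intended ΔCt is Ct_i − Ct_1 or
Ct_1 − Ct_i cannot be resolved from the formula alone, so the package
refuses to choose silently: `convention="printed"` computes the literal
form, `convention="abundance"` the physically standard form, and every
interface carries the flag. Both conventions produce distributions that
sum to 1 and are invariant under adding a constant to all four Ct values.

**Aggregation and sentinels.** Replicates are aggregated by arithmetic mean
of Ct before normalization (the common convention; the assay description
does not state one). A Ct at or above the 40-cycle sentinel (the 38-cycle
runs rounded up) means "not detected" and contributes weight 0; a locus
undetected in all four zones is an error, not a distribution.

**Topology shift.** Zone distributions are compared by the signed
center-of-mass shift Σ i·b_i − Σ i·a_i over zone indices 1–4. Positive
values mean movement toward the sc+ pole (zone IV), negative toward sc−
(zone I). This is a deliberate one-number summary of statements like
"expansion of zone IV"; it is antisymmetric and zero for identical
distributions. No periodicity estimator is provided for the ~2-min
oscillation of topology: the underlying claim is qualitative, and a
spectral estimate from four or five timepoints would be overreach.

**Pfaffl ratio.** Relative expression is efficiency-corrected:
`Eff_tar^ΔCt_tar(control−test) / Eff_ref^ΔCt_ref(control−test)`. The
TD-tendency score divides the geometric mean of the pro-neural ratios
(ATOH1, MASH1) by the pro-myogenic ratio (MYOD1); the geometric mean is
used because the source describes "the ratio of ATOH-1 and MASH-1 to
MYOD1" without a combiner, and the geometric mean is the scale-symmetric
choice for ratios.

## Poisson TD propensity (`tdprogram.poisson`)

Conversion events per cell per induction cycle are modelled as Poisson with
mean `m`, assuming TD is binary and cells are independent. Then
P(resist) = e^−m and P_TD = 1 − e^−m. The study's estimate is m = 0.5
per 20-min cycle, giving P_TD ≈ 39.3%; the `paper_style_percent` renderer
reproduces the published arithmetic exactly by rounding e^−0.5 to 0.6
first, hence 40%.

**Rate estimation.** From a chase with `converted` of `total` cells after
`c` cycles, the rate is m̂ = −ln(1 − converted/total)/c. The 95% CI is a
Wilson binomial interval for the converted fraction transformed through the
same map; Wilson is used because it behaves well near 0 and 1, where the
Wald interval collapses. A saturated chase (all cells converted) is flagged
as an infinite rate with a finite lower bound rather than an error.

**A deliberate inconsistency.** Under independent identical cycles,
two cycles at m = 0.5 convert 1 − e^−1 = 63.2% of the population, yet the
chase experiments report > 90% enrichment after two cycles. These numbers
cannot both follow from the model; the package implements the model as
stated and reports its own two-cycle prediction
(`predicted_enrichment_2_cycles`) alongside the estimate so the gap is
visible. A plausible reconciliation — a higher effective m under repeated
induction — is not assumed.

## Multi-target seed discovery (`tdprogram.seedguide`)

Cas9 cleavage requires an NGG PAM immediately 3′ of the protospacer and
tolerates mismatches outside a PAM-proximal seed of roughly 8–13 nt. A
spacer whose PAM-proximal seed matches a region shared across many genes
therefore cuts many loci with one guide.

**Search.** `find_shared_seeds` reports every maximal seed of length ≥ 13
(configurable, floor 8) that occurs exactly — no mismatch budget, either
strand — in at least `min_carriers` distinct genes with a valid PAM
immediately 3′ of every counted occurrence. Occurrences lacking a PAM are
not counted as carriers. Because every counted occurrence ends at a PAM,
candidates are enumerated as 5′-growing suffixes anchored at PAM sites,
which makes the search linear-ish in sequence length rather than quadratic
in substring count; the test suite proves equivalence against an exhaustive
substring oracle on random instances. Seeds whose every occurrence extends
to a longer seed with the identical carrier set are suppressed as
redundant. Output order is deterministic: carrier count desc, seed length
desc, expected random hits asc, sequence.

`N` bases never match anything — neither a seed position nor the `N` of
the PAM pattern — since an unknown base cannot license cleavage.

**Non-randomness score.** `expected_random_hits` gives the expected number
of exact occurrences of a seed in an i.i.d. background of stated length and
GC content, counting both strands: 2·L·Π p(base), which reduces to
2L/4^k at GC 0.5. For a 13-mer against a 3.2 Gb genome this is ≈ 95;
for a 16-mer ≈ 1.5 — the quantitative form of "conserved homologous
regions longer than 13 bp are unlikely to be randomly seeded".

**Guide assembly.** The spacer is the 20 nt (configurable) ending at the
PAM-proximal end of the seed, written as RNA, plus the canonical
S. pyogenes tracr scaffold. When the shared seed is shorter than the
spacer, the 5′ remainder is padded from a deterministic representative
carrier (first match in (gene, start, strand) order) and the number of
padded, non-shared positions is reported; those positions differ across
carriers by construction, which is exactly why the seed — not the full
spacer — defines specificity. Padding is skipped (with a warning flag)
only when no flank exists to pad from. `parse_modified_sgrna` strips
vendor chemistry notation (m/r prefixes, `*` linkages) and splits
spacer from scaffold at the canonical scaffold prefix; the published
TDi-RNA reagent string round-trips through parse → design exactly.

**Cut sites.** Blunt cleavage is placed 3 bp 5′ of the PAM, emitted as
0-based half-open single-base intervals in BED6. Coordinates are always
reported on the gene's forward strand, with reverse-strand arithmetic
verified by a strand-symmetry property (reverse-complementing every input
yields identical clusters with strands flipped and coordinates reflected).

**Scope.** The search runs on whatever FASTA it is given; the study's
genome-wide cluster of 469 genes depended on a specific genome build and an
unstated uniqueness protocol, and is not reproducible at package scale.
No off-target scoring or chromatin weighting is attempted.

## Missing-transcript analysis (`tdprogram.missingness`)

Abundance tables are binarized by a strict threshold (default 0: any
nonzero abundance counts as present — "undetectable" is not quantified in
the source, so the most permissive rule is the default and the threshold
is exposed). Transcripts are grouped by their exact missingness pattern
over timepoints; with n patterned timepoints there are 2^n − 2 non-trivial
patterns (30 for the five post-induction timepoints, matching the
published intersection map under the interpretation that the five
post-induction samples are patterned and the pre-induction control is the
baseline). When a baseline column is declared, patterns span only the
post-baseline timepoints.

Cluster labels use endpoint rules — lost (cluster-I): present at baseline,
absent at the final timepoint; retained (cluster-II): present throughout;
de novo (cluster-III): absent at baseline, present at the end; everything
else is transient ("other"). Endpoint rules are the minimal faithful
formalization of the published cluster descriptions; they deliberately do
not attempt to classify transient dips or pulses.

## Synthetic data (`tdprogram.synthetic`)

Every generator returns its ground truth, enabling exact round-trip tests
at zero noise and statistical recovery tests otherwise.

* **Gene sets.** Random sequences are uniform over {A,C,G,T} (GC = 0.5
  unless a `gc` parameter is given — no background model is stated by the
  source, so uniform is the neutral choice). The planted seed, followed by
  a random NGG PAM, is inserted at a random position of each carrier;
  rejection sampling (cap 100 tries) guarantees carriers hold exactly one
  occurrence and non-carriers none, on either strand. Cap exhaustion is an
  error signalling pathological parameters, not a silent degradation.
* **Ct tables.** Zone fractions are inverted through the configured
  convention (Ct_i = base ± log2(f_i/f_ref)); zero fractions map to the
  Ct-40 sentinel. Replicate noise is Gaussian on Ct — an assumption, as the
  source gives no noise model; Gaussian-on-Ct is the standard qPCR error
  model and multiplicative on abundance.
* **TD-chase cohorts.** Each unconverted cell converts per cycle with
  probability 1 − e^(−m·multiplier) (the Poisson zero-class complement,
  matching the model rather than a plain Bernoulli(m)); defaults are the
  study's conditions, m = 0.5 per cycle and cohorts of 10^4 cells.
* **Presence matrices.** Lost transcripts switch off at a random
  post-baseline timepoint and stay off; de-novo transcripts mirror that;
  retained transcripts are always present. Monotone on/off switching means
  the planted truth is exactly recoverable from endpoints.

What the generators do **not** emulate: amplification-efficiency drift or
inter-locus competition in qPCR, sequence composition bias or repeat
structure of real genomes, cell division and death during a chase, and
drop-out noise in transcript detection. Passing round trips therefore
demonstrate correctness of the formulas and algorithms, not robustness to
every artifact of real data.

## Problem sizes and determinism

Default analysis sizes are desk-scale, chosen so that every statistical
check is well-powered while the whole suite stays interactive: seed-search
equivalence runs on 100 random instances of 3–7 genes × 120–320 bp plus 50
planted sets of 8 × 300 bp; rate recovery uses 50 cohorts of 10^4 cells.
All randomness flows through explicit integer seeds (NumPy
`default_rng`); identical seeds give byte-identical outputs, and the
pipeline manifest records the seed plus a SHA-256 digest of every file.

## Known limitations

* The zone-formula sign ambiguity is surfaced, not resolved; analyses of
  real gels must choose a convention and state it.
* The Poisson model ignores cell division, death, and any induction-history
  dependence of m; the >90% two-cycle enrichment is inconsistent with
  independent cycles at m = 0.5 and is left unreconciled.
* Seed matching is exact; a mismatch budget (relevant to real off-target
  behaviour) is an extension point, off by default.
* Cluster labels depend only on endpoint timepoints; transient dynamics are
  grouped as "other" rather than subclassified.
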