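# Methods

`osteostage` stages a 28-day osteogenic differentiation time course of
mesenchymal stromal cells (MSCs) from three complementary data layers:
extracellular metabolite rates, intracellular ¹³C isotopologue
distributions, and RNA-seq differential expression. This note documents
the models, the defaults and why, the numerical choices, and what the
synthetic-data generators do and do not emulate.

## Metabolite phases

**Model.** Spent-medium concentrations of glucose, lactate, glutamine,
glutamate and ammonia are observed per donor per day, each sample drawn a
known dwell time (24 or 36 h) after a media change. Concentration change
relative to fresh medium reflects cellular uptake (negative rate) or
secretion (positive rate), in mmol/L/h.

**Smoothing.** `smooth_timecourse` drops days with more than 50% missing
values, substitutes remaining missing/below-detection values with the
metabolite's observed minimum, removes donor and batch offsets by
centering each group to the grand mean, and fits a cubic smoothing spline
over day with the penalty chosen by generalized cross-validation (GCV).
A donor/batch-centered GCV spline replaces a mixed-effects additive model
here: the downstream consumer needs only per-day fitted values, and the
spline reproduces constants and linear trends exactly while the GCV
penalty adapts to the signal-to-noise ratio. With fewer than five days
(GCV needs that many points) or exactly constant data, fitted values fall
back to the per-day means.

**Rates.** Two estimators are provided. `compute_rates` is the
adjacent-day difference of fitted values divided by the dwell hours of
the later day, for cumulative or externally smoothed series.
`rates_from_spent_medium` uses the spent-medium structure directly:
`(concentration − fresh baseline) / dwell`, averaged across donors; it is
the estimator used in the recovery studies because each sample is an
independent rate snapshot after a media change.

**Change points.** `EnergyDivisive` estimates multivariate change points
hierarchically. For segments A (m points) and B (n points) the energy
divergence with moment index α ∈ (0, 2) is

    Ê(A,B) = 2/(mn) Σᵢⱼ‖xᵢ−yⱼ‖^α − C(m,2)⁻¹ Σ‖xᵢ−xⱼ‖^α − C(n,2)⁻¹ Σ‖yᵢ−yⱼ‖^α

with within-segment terms 0 for singletons, and the test statistic is
Q = mn/(m+n)·Ê. Within each current segment the split maximizing Q
(subject to `min_segment` points per side, ties to the earliest day) is
assessed by a within-segment permutation test with the add-one estimator
p = (1 + #{Q_perm ≥ Q_obs})/(B + 1), which cannot return zero; splits
with p ≤ `sig_level` are accepted and both halves recursed into.
Defaults: α = 1, `sig_level` 0.05, 199 permutations, `min_segment` 3
(a 27-day series cannot support large minimum segments), seeded
permutation RNG. Metabolite rate series are standardized to unit
variance beforehand so that high-concentration metabolites (glucose)
do not dominate the Euclidean geometry; `RatePanel.standardized` records
this. The split search is O(T²) per permutation via 2-D prefix sums of
the distance-power matrix.

**Phase summaries.** Per phase and metabolite, the mean and SEM of daily
rates (SEM 0 and flagged for single-day phases), plus three named flux
ratios of phase-mean rates: glucose/lactate, glutamine/glutamate,
glutamine/ammonia. Ratios use unstandardized rates; a zero denominator
yields NaN with a flag. `expected_perfect_ratio` returns the
stoichiometric reference under the signed convention: −0.5 for
glucose/lactate (1 glucose → 2 lactate), −1 for glutamine/glutamate and
glutamine/ammonia (one-to-one). ALP activity (the differentiation
verification assay) is OD / (18.8 µmol⁻¹ × time[min]) × 1000 nmol/µmol.

## Isotope tracing

For a metabolite with n carbons, the measured mass-shift vector is the
true isotopologue distribution convolved with natural ¹³C labeling of
the untraced positions: `M[i,j] = C(n−j, i−j) p^{i−j} (1−p)^{n−i}`,
p = 0.0107. Columns of M are binomial probability distributions; p = 0
gives the identity. Correction solves `raw ≈ M·x` by non-negative least
squares (robust to noise-induced negative components, unlike direct
inversion) and renormalizes. Mean label enrichment is `Σ i·xᵢ / n`;
per-isotopologue fractions expose, e.g., M+6 vs M+11 of UDP-glucose as
glycolysis vs pentose-phosphate-pathway proxies. The same machinery
covers ¹⁵N tracing with n the nitrogen count and p = 0.00364. An
optional tracer-purity parameter (default 1.0, i.e. off) adds a binomial
thinning of the labeled positions. Intensities are normalized per µg of
BCA-assayed protein to account for cell number. Day-to-day statistical
comparisons of enrichment are routine t-tests/ANOVA and are left to
standard libraries.

## Response-gene filtering

A gene from the late-vs-early DE contrast is retained iff it is
(a) significant (p < 0.05 and BH-adjusted p < 0.1), (b) expressed —
the **maximum** of the two condition mean TPMs ≥ 2, so a gene induced
from silence passes, (c) strongly changed (|log2FC| ≥ 1),
(d) reproducible (SEM/|mean| ≤ ½ in **each** condition, the conservative
reading), and (e) donor-consistent: significant with the contrast's sign
in ≥ 2 of 3 donors (the complement of "only one donor"). The filter is
monotone in all thresholds and order-invariant. Classes: TF (DoRothEA-
like list), metabolic (reconstruction gene list), other — TF wins when a
gene is on both lists.

## Regulon inference

Per-gene z-scores across conditions (sample SD; zero-variance genes
excluded) are clustered separately for up- and downregulated response
genes by Ward-linkage agglomerative clustering on Euclidean distances
(the linkage is unspecified in the underlying procedure; Ward behaves
well for compact expression clusters). k runs from 3 to min(114, n−1);
each partition is scored by silhouette (↑), Calinski–Harabasz (↑) and
Davies–Bouldin (↓), and the k with the best mean rank across the three
indices wins, ties to the smallest k — a deliberate operationalization
of "consistently optimal".

Each cluster × regulator pair (regulators with at least one prior target
in the population) is tested for enrichment of the regulator's prior
targets with the hypergeometric upper tail; the population is the
respective direction's response-gene set, since the clusters partition
it. BH correction at α = 0.1 is applied across all cluster × regulator
tests within one direction. Significant (cluster ∩ prior-target) sets
sharing a regulator are unioned; the regulator itself is removed from
its own target set. A candidate becomes a regulon only if the Pearson
correlation between the regulator's expression profile and its targets'
mean profile exceeds 0.8 (computed on per-sample time × donor profiles;
negative correlates — repressors — are excluded by default and can be
kept with a flag). Regulon activity is the per-condition mean target
z-score; names follow `<regulator>.<n_targets>`.

**Switch classification** of the donor-averaged activity profile:
`up`/`down` if the last time point exceeds/undershoots the first by
δ = 0.5 z-units; otherwise `transient` if an interior maximum exceeds
both endpoints by δ; otherwise `flat` (a fourth label is needed because
a constant profile fits none of the other three).

**TF–TF network.** Directed edge A → B iff B is a target of A's retained
regulon and B is on the TF list; nodes carry regulon size and switch
direction; exported as SIF and GraphML (Cytoscape-compatible).

## Synthetic data

The generators produce every pipeline input with known ground truth,
seeded and byte-reproducible.

**Metabolites.** Concentration = DMEM/F12-like fresh-medium baseline
(glucose 17.5, glutamine 2.5, lactate 0, glutamate 0.05, ammonia
0.05 mmol/L — config-exposed since real media vary) + (phase rate +
donor intercept + batch offset) × dwell + Gaussian noise, truncated at 0
(mirroring detection-limit substitution). Defaults emulate the study
design: 4 donors, days 1–28 with day 14 dropped (forcing irregular
gaps), alternating 24/36 h dwells, phase boundaries at days 5 and 16,
and per-phase rates giving shifts of at least 1.5 residual SDs on the
donor-averaged rate scale (donor SD 0.003, batch SD 0.002 mmol/L/h,
residual 0.04 mmol/L). Setting all SDs to zero makes every downstream
estimator exact.

**Isotopologues.** Raw vector = correction matrix × true distribution,
scaled by total intensity and protein amount, with mean-corrected
log-normal multiplicative noise of CV `noise_cv` (default 0.02).
Defaults trace lactate (n=3), glutamate (n=5), glucose (n=6) and
UDP-glucose (n=11) at days 3/6/9/16/28 with trajectories qualitatively
matching the biology: lactate M+3 rising then falling, UDP-glucose M+6
rising while M+11 falls. Generation and correction are exact inverses
at zero noise.

**Expression.** 4 time points (days 3/6/16/28) × 3 donors. Planted
regulators follow monotone logistic switches (up or down) with switch
days staggered evenly across the sampled window per direction; targets
track their regulator with per-target scaling U(0.8, 1.2) plus log-scale
noise (default SD 0.2); background genes are stationary noise. The
default planted amplitude is 3 log2-units, in line with the strong
response genes such studies report (top regulator and metabolic genes
with 15–54-fold changes). Staggered timing is what makes regulons
separable as expression clusters — regulons sharing one temporal profile
are statistically indistinguishable and no clustering-based method can
split them. An optional per-regulon target switch delay models
transcriptional cascade latency, letting a TF target of one regulon
drive its own later-switching regulon (the TF–TF cascade scenario).
The prior database lists each planted regulator with its true targets
plus decoy targets, and decoy regulators (stationary expression) with
random target sets drawn half from response-like genes — emulating prior
entries whose regulator is not itself responsive; these exercise the
correlation gate. DE tables use two-sample t-tests on log2 expression
across donors as stand-ins for a count-model fit; only the table schema
is consumed downstream. Per-donor significance calls use a normal test
of the per-donor log2FC against the median within-condition SD.

**What the generators do not emulate:** count-level sampling noise and
dispersion structure of RNA-seq, donor-specific regulatory rewiring,
chromatographic/peak-integration artifacts, metabolite cross-talk
between pathways, and media evaporation effects. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
statistical model, not performance on real donor data.

## Problem sizes and reproducibility

The bundled studies use 5 metabolites × 27 days × 4 donors with 199
permutations (20 signal + 20 null seeds) for change-point recovery, and
a ~1030-gene matrix (10 planted regulons, 20 decoys) for regulon
recovery — sizes chosen to characterize operating behavior with
comfortable margins on a laptop-class machine. All randomness flows
through explicitly seeded `numpy` generators; the CLI writes a manifest
with package version, parameters, seeds and input checksums, and reruns
are byte-identical.

## Known limitations

- The permutation test is performed per segment during recursion;
  family-wise error across multiple accepted splits is not jointly
  controlled (inherent to the divisive strategy).
- GCV smoothing can round sharp concentration steps over 1–2 days at a
  phase boundary; the spent-medium rate estimator avoids this.
- NNLS correction is biased at distribution boundaries (components near
  0) for very noisy data; per-component error scales with noise CV.
- Regulon inference cannot distinguish regulators with statistically
  identical target profiles, and with only 4 time points the space of
  distinguishable temporal shapes is small.
- The TF–TF network contains influence edges only (no sign/strength
  beyond the regulon direction attribute).
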