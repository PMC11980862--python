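# Methods

This note documents the models, default parameters and numerical choices
behind `diatomring`, in the spirit of a statistical-software methods
appendix. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design model

A ring trial is a list of experiments, each a (participants × sample types ×
replicates) grid. The encoded study comprises two proficiency tests (E1:
DNA extraction, E2: PCR amplification; 17 labs, one replicate), two
method-comparison experiments (E3, E4; 9 labs, three replicates), and the
reference laboratory's own triplicates modelled as an ordinary participant
`RL` in a pseudo-experiment `REF`. Each unit covers four calibrated items:
river biofilm R, lake biofilm L, 12-strain mock M, water blank W. Expansion
gives 364 units; sequencing-inclusion rules (blanks unsequenced except three
that amplified unexpectedly, one failed amplicon) leave 275 sequenced
reactions and 51/50/81/81/9 retained community samples per experiment —
these counts are exact consequences of the design, verified in the
acceptance tests.

The nine method-comparison labs are not identified in the source design
beyond their number; the package uses the fixed subset
B, D, E, F, I, K, N, O, P (chosen to include the labs referenced in the
documented anomaly and re-sequencing events: E, O, P). Every unit is keyed
`experiment/participant/type/replicate`; table columns carry these keys, so
sample metadata never needs a sidecar.

## Synthetic data generator

The generator works at the taxon-count level — it emulates the statistical
structure of assigned ASV tables, not reads. Per sample:

1. **True composition.** The unit's community profile; anomalies (swap,
   α-mixture, contamination) replace or blend it first.
2. **Systematic lab bias.** Log-scale per-taxon vector b (lab-constant):
   expected composition ∝ p·exp(b). Default b ~ N(0, 0.08²) iid per taxon.
3. **Replicate noise.** iid N(0, 0.04²) log-scale per taxon per replicate.
4. **Dropout.** Taxa whose biased relative abundance falls below 5×10⁻⁴
   drop out with probability 0.5, then renormalise.
5. **Counts.** Multinomial at the configured depth (default 20,000 reads,
   the order of a shared MiSeq amplicon run); blanks are all-zero.

Reference communities: geometric rank-abundance series (ratio 0.8) over 60
river and 60 lake taxa sharing 30% of the smaller community, assigned to
taxa in seeded random order; the mock is 12 dedicated taxa; the blank is
empty. The geometric series yields the abundant/rare split that the
detection-threshold analysis needs (a long tail under 1%). A lognormal
rank-abundance model is available as an alternative.

The lab-effect magnitudes were fixed once, jointly, so that the simulated
regime matches a *successful* ring trial and the design constraints of the
downstream diagnostics: index-score SDs of a few hundredths to tenths of a
unit, diversity-metric CVs in the low percent range, between-lab community
dissimilarity (Bray-Curtis a few hundredths) dominating within-lab replicate
noise (hence participant-dominated PERMANOVA R²), and anomaly-probe
dissimilarities below the 0.05 swap/mixture detection cutoffs at depth 10⁵.
They are calibration knobs describing a plausible lab ensemble, not
estimates of any real laboratory.

Seeding: one master seed; each sample unit gets an independent substream
from `SeedSequence([master, blake2b(unit key)])`, so generated tables are
identical regardless of manifest ordering.

For injected-bias experiments the canonical perturbation is
`sensitivity_aligned_bias(traits, effect_size)`: b = effect·(s − mean s),
which over-amplifies pollution-sensitive taxa and therefore shifts the
trait-weighted index — the kind of directional error z-scores exist to
catch. The documented effect size is 0.5 log-units per sensitivity unit;
under the default noise model this drives the biased lab's |z| past 3
(median ≈ 3.4 with 17 labs) while leaving unbiased labs in control.

What the generator does **not** model: sequencing error, chimeras, index
hopping, taxonomic misassignment, compositional correlations between taxa,
overdispersion beyond multinomial, or between-run batch effects. Passing
tests therefore demonstrate the correctness and sensitivity of the
*statistics* under a clean compositional error model, not robustness of any
wet-lab protocol.

## Filtering rules

The low-abundance rule zeroes a cell when its count is below 10 reads *and*
below 0.01% of its sample's pre-filter total (conjunctive reading, per
cell); rows left all-zero are dropped. The disjunctive reading (`rule="or"`)
and a per-row variant (`per="row"`) are config switches, since the
prose of such rules is often ambiguous; fractions always use pre-filter
totals (the filter is applied once, not iteratively). Empty samples are
skipped and retained. Non-target and `<phylum>_unclassified` rows are
discarded before any analysis.

## Indices

IPS-type: raw = Σ aⱼsⱼvⱼ / Σ aⱼvⱼ on the 1–5 sensitivity scale, mapped by
4.75·raw − 3.75 onto 1–20 and clamped (clamps are flagged). IBD-type: class
loadings Fᵢ = Σₓ aₓP(x,i)vₓ / Σₓ aₓvₓ over seven classes with scores
c = 1…7; B = ΣFᵢcᵢ/ΣFᵢ mapped affinely from [1,7] onto [1,20]. Abundances
are renormalised over trait-covered taxa rather than penalising missing
traits; coverage is reported and scores with coverage < 0.7 (configurable)
are flagged invalid — index interpretation conventionally requires a
minimum contributing fraction, for which no universal number exists.
Status classes use half-open intervals with default boundaries 5/9/13/17
(boundary values take the higher class, so 17.0 is already "high").

The bundled trait generator produces purely synthetic sensitivity/indicator
values and class profiles (profile centre tracking sensitivity); real trait
databases are consumed through the TSV importer and are not redistributed.

## Proficiency statistics

μ/σ are the plain mean and (n−1) SD over all participants including the
scored one; ISO-style robust median/MAD scoring is available behind a flag
but off by default. σ = 0 yields z = 0 with a degeneracy flag and a passing
verdict (no dispersion to standardise against). The Youden "close to the
45° line" criterion is operationalised as |v| ≤ 2 on the rotated axis,
mirroring the 2-SD warning convention; the action box is |z| ≤ 3. A 95%
probability circle of radius √χ²₂(0.95) on standardised axes is provided for
plotting; an elliptical fit is deliberately not attempted.

Detection threshold: each taxon's representative abundance is the maximum
over detecting participants (worst-case guarantee; the mean variant is also
computed), and the threshold is the largest representative abundance among
taxa missed by at least one participant. Every taxon strictly above the
threshold was, by construction, seen by all — verified against brute-force
enumeration in the tests.

Mixture fitting: α is the closed-form projection of (q − B) onto (A − B),
clipped to [0,1]; the residual is Bray-Curtis between the query and the
fitted mixture. Identical references are rejected. Verdicts: swap when a
single reference other than the expected one matches within 0.05; mixture
when the best pair fits within 0.05 with α ∈ [0.2, 0.8]. Composition-match
ties break lexicographically by reference name (deterministic).

## Permutation tests

PERMANOVA uses Anderson's partition of squared Bray-Curtis distances
(pseudo-F, R² = SS_between/SS_total); MRPP uses the group-size-weighted mean
within-group distance with A = 1 − δ/E[δ]. Both use the
(1 + exceedances)/(1 + n_perm) Monte-Carlo estimator — never zero, bounded
below by 1/(1+n_perm) — and switch automatically to exhaustive enumeration
of distinct label arrangements when these number ≤ 10,000 (the identity
arrangement is then counted, keeping p ≥ 1/M). Singleton groups contribute
no within-group distance and are excluded from δ with a report.
Kruskal-Wallis delegates to the tie-corrected χ² implementation in scipy;
all-identical values return (H=0, p=1). nMDS minimises Kruskal stress-1 by
SMACOF with monotone regression (scikit-learn), best of 4 seeded starts;
coordinates are centred, rotated to principal axes and sign-fixed so a
given seed yields identical output.

## Problem sizes

The default test and acceptance runs use 60+60-taxon communities, depth
5,000–20,000 (100,000 for the anomaly-recovery probes, where the criterion
concerns the concentration limit), 50 seeds for the stochastic recovery
rates, and 99–999 permutations in the pipeline reports; exhaustive
enumeration covers the oracle comparisons at n ≤ 7. These sizes give stable
rates (flag-rate Monte-Carlo SE < 0.05) while the whole suite runs in tens
of seconds.

## Known limitations

- One-factor PERMANOVA only (no nesting/strata), matching the analyses it
  reproduces; pairwise contrasts beyond Bonferroni correction are out of
  scope.
- Bray-Curtis violates the triangle inequality; the nMDS and permutation
  machinery do not require metricity, but distance-based conclusions
  inherit this property.
- The generator's iid per-taxon bias cannot represent phylogenetically
  structured extraction bias; recovery rates on real data may differ.
- Hill numbers are computed on raw (post-filter) relative abundances; no
  rarefaction or coverage standardisation is offered.
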