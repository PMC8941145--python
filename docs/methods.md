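# Methods

This note records the models, parameter choices and numerical decisions
behind `sisca`, in the order data flows through the package.

## Isotope model

Predicted isotopologue patterns are *aggregated* (nominal-mass) isotope
distributions.  For a peptide of elemental composition
{C:n_C, H:n_H, N:n_N, O:n_O, S:n_S}, each element contributes the n-fold
self-convolution of its single-atom isotope distribution, indexed by
neutron count; element distributions are combined by discrete convolution.
Carbon is the labeling channel: each carbon atom is ¹³C with probability
equal to the RIA, so the carbon contribution is Binomial(n_C, RIA).  All
other elements stay at natural abundance (values in
`src/sisca/data/isotopes.tsv`, CIAAW/IUPAC representative abundances;
¹³C natural abundance 0.0107).  The model is exact up to unit-mass
aggregation — fine structure (the few-mDa splits between, e.g., ¹³C and
¹⁵N isotopologues) is not resolved, matching how Orbitrap peptide spectra
are read at the isotopologue level.  Peak positions are
base m/z + k·1.003355/z.

Self-convolutions use binary exponentiation, and the RIA-independent
non-carbon envelope is computed once per peptide and reused across the
whole reference grid.  Patterns are truncated at the shortest prefix
holding ≥ 99.9 % of the probability mass (`coverage=0.999`), then
renormalized; this bounds pattern length while discarding < 0.1 % of
abundance.  Correctness is checked in the test suite against an exhaustive
enumeration over every per-atom isotope assignment (feasible for ≤ 15
atoms), with agreement required to 1e-10 per isotopologue.

Residue compositions (`src/sisca/data/residues.tsv`) cover the 20 standard
amino acids; selenocysteine and pyrrolysine are unsupported.  Two fixed
modifications are modeled: carbamidomethylation of cysteine (+C₂H₃NO) and
oxidation of methionine (+O).  Masses are cross-checked against pyteomics
in the tests.

## Pattern extraction

Peptide identifications from unlabeled (¹²C) runs anchor the search in
labeled runs, which are assumed co-chromatographed.  Candidate positions
are m/z + k·1.003355/z for k = 0…n_C (the largest possible shift).  A
candidate peak matches when its mass deviation is strictly below 10 ppm
and its retention-time deviation strictly below 3 min (both configurable).
Among in-tolerance peaks the smallest |ppm| wins, ties going to the higher
intensity — manual extraction protocols state no rule, so the least-biased
deterministic one was chosen.  Positions with no matching peak are recorded
as zero rather than aborting: partially labeled populations legitimately
produce near-empty valleys between the unlabeled and labeled envelopes.

Quality gates: a peak at the M−1 position above 5 % of the pattern's
maximum intensity rejects the pattern (a lighter interfering species is
present); the 5 % default replaces a visual-inspection criterion that was
never quantified.  A neighbor peptide whose expected positions fall within
the ppm tolerance of the pattern's own positions, with retention-time
windows overlapping, rejects it as cross-contaminated.  MAG/time-point
groups supported by fewer than 2 replicates are dropped before
aggregation.  An optional cosine-similarity replicate-agreement filter
exists but is disabled by default (threshold 0), since no quantitative
criterion is canonical.

Peptide-to-organism attribution keeps a peptide only if all its proteins
lie in one MAG, or all its MAGs share one genus (then labeled
`genus:<name>`); peptides spanning genera are discarded.

## R² profiles, ordination, lifestyles

R² uses the standard definition 1 − SS_res/SS_tot with SS_tot taken about
the measured vector's mean, both vectors aligned on the union of
isotopologue indices (missing → 0) and normalized to sum 1.  Negative
values are retained — only the ordering across the grid and averages over
peptides matter, and clipping would bias means.  A perfectly uniform
measured vector makes SS_tot vanish; the implementation then returns 1 for
a numerically uniform prediction and −∞ otherwise (real patterns are never
uniform).

Profiles are aggregated by element-wise arithmetic mean over all peptides
and replicates of a MAG/time-point group.  Ordination is PCA of
mean-centered, *unscaled* feature vectors (all features already share the
R² scale).  The default layout concatenates each MAG's per-time-point
profiles into one 63-dimensional vector (21 grid points × 3 time points),
one point per organism; a per-MAG-time layout is available because the
aggregation is genuinely per time point and either reading is defensible.
Scores follow a deterministic sign convention (the largest-magnitude
loading of each component is positive).

Cluster membership is analyst-supplied; a Ward-linkage helper exists but
never chooses the number of clusters.  Cluster validation constructs 2-D
confidence ellipses of the cluster *mean* in PC1/PC2 — sample covariance
divided by n, scaled by the χ²(2) quantile at the requested confidence
(default 95 %) — and flags any pair whose ellipses intersect or contain
one another (tested by dense boundary sampling plus center containment,
720 points per boundary).  Singleton clusters get no ellipse and are
flagged rather than rejected.

Lifestyle classification runs on the trajectory of point-estimate RIAs
(grid argmax per time point, ties to the lower value and flagged).  Default
thresholds: high = 0.90, low-start = 0.75, unlabeled = 0.10, stability
range = 0.10.  Rules fire in order: high-and-stable → strict autotroph;
final ≥ 0.90 with first ≤ 0.75 → switching mixotroph; monotone rise ending
in (0.10, 0.90) → cross-feeding incorporator; all ≤ 0.10 → heterotroph on
unlabeled carbon; anything else falls back to cross-feeding incorporator
with an explicit rule tag.  The high gate is inclusive in the mixotroph
rule so a true RIA of 0.91 snapped to the 0.90 grid point keeps its label.
These thresholds are distilled from the expected RIA regimes of each
lifestyle, not printed rules, and live in configuration.

## Growth quantification

The measured series decomposes by anchoring on the monoisotopic peak: the
labeled envelope contributes essentially nothing at isotopologue 0, so
I_unlabeled = m₀ / p₀(natural), the scaled natural envelope is subtracted
(negative residuals floored at zero, floored mass flagged when above 1e-9
of the total), and the remainder is I_labeled.  On noise-free mixtures
this is exact for disjoint envelopes and accurate to ~1 % of total for
overlapping envelopes at RIA 0.20.

Doublings: the formula is implemented exactly as printed in the source
method, n = log₂[(I₁₂C + I₁₃C)/I₁₃C].  As printed it *decreases to zero as
labeling approaches completeness*, which conflicts with fast growers being
reported below a 2-day detection limit; the conventional variant
n = log₂[(I₁₂C + I₁₃C)/I₁₂C] (unlabeled intensity in the denominator,
under which complete labeling means many doublings) is provided as
`eq1_convention="unlabeled-denominator"`, and every output records the
convention used.  Whether the printed denominator is intentional cannot be
resolved from the text, so neither is asserted as intended.  t_d = Δt/n;
values below the 2-day default detection limit format as "<2 days";
n below 1e-6 is treated as no quantifiable doubling signal.  Per-MAG
generation times are the mean ± SD over ≥ 4 determinations; fewer report
as non-quantifiable ("na").

Community carbon replacement: each peptide contributes a ¹³C carbon
fraction (I_l·RIA + I_u·0.0107)/(I_l + I_u), and the community value is
their unweighted mean by default (each peptide one vote); intensity
weighting is available since the appropriate weighting is not canonical.

## Raman C-D pipeline

Fixed stage order: despike → calibrate → baseline → normalize; the
pipeline builder rejects any other order.  Calibration is a pass-through
hook because wavenumber/intensity calibration needs physical standard
spectra; synthetic data are generated on a calibrated axis.

Despiking replaces points deviating from a 7-point running median by more
than 8 robust SDs (1.4826·MAD).  Baseline removal is asymmetric least
squares: minimize Σwᵢ(yᵢ−zᵢ)² + λΣ(Δ²z)² with weights p above / 1−p below
the baseline; defaults λ = 1e7, p = 0.01, 10 iterations.  λ was set so
that corrected areas of physiologically broad bands (σ ≈ 45–55 cm⁻¹)
are preserved within 5 %; softer penalties let the baseline bulge into
broad bands and clip a third of their area.  The asymmetric weights are
computed against a Savitzky-Golay-smoothed copy (window 21, cubic) of the
spectrum — otherwise the baseline tracks the lower envelope of the *noise*,
leaving a positive offset that inflates integrated areas; the correction
itself is applied to the raw intensities.  The C-D ratio integrates
trapezoidally over 2040–2300 (C-D) and 2800–3100 cm⁻¹ (C-H), flooring
negatives at zero; it is invariant to overall intensity scale.  The
labeled/unlabeled classifier is PCA (5 components) followed by LDA, with
Ledoit-Wolf shrinkage applied (and flagged) if the within-class covariance
is singular.

## The simulator

`sisca.simulate` emulates the inputs of a ¹³C protein-SIP experiment with
known truth.  Defaults encode the study conditions the package targets:
three sampling points T1/T2/T3 at 21, 43 and 70 days; two replicate
microcosms; four trophic archetypes with RIA trajectories
(0.95, 0.95, 0.95), (0.65, 0.91, 0.91), (0.18, 0.53, 0.76) and
(0.06, 0.06, 0.06) — fixtures shaped after the canonical lifestyle
narratives, not measured data; 20 peptides per MAG of length 7–30 from an
in-silico tryptic digest (cleave after K/R, not before P, ≤ 2 missed
cleavages) of random uniform-composition proteins; charges 2–3; retention
times uniform in 10–120 min and identical across samples
(co-chromatography).  The default labeled fraction is 1.0 per time point —
over 21–70 days at the generation times these archetypes imply, the
pre-label protein pool is negligible; partial labeling is configured per
MAG either directly or by inverting the doublings formula (f = 2⁻ⁿ).
Spectral noise is per-peak multiplicative lognormal at CV 5 % (unit mean)
with ±3 ppm uniform m/z jitter and an optional absolute intensity floor;
total peptide intensity is lognormal around 1e6.  Raman cells get Gaussian
C-D (2170 ± 45 cm⁻¹) and C-H (2930 ± 55 cm⁻¹) bands whose areas realize
the requested C-D ratio, a smooth polynomial background, Gaussian noise at
1 % of the band amplitude, and optional cosmic spikes.

What the simulator does *not* emulate — and hence what passing tests do
not show about real data: ionization-efficiency differences, co-elution
chemistry and chimeric spectra, chromatographic drift between runs,
realistic proteome composition and abundance distributions, isotope
fractionation, and detector saturation.  Recovery rates measured here are
upper bounds for instrument data.

Outputs are byte-identical under a fixed seed.

## Problem sizes used in validation

The recovery checks run at deliberately compact scales: 500 peptides per
archetype for RIA recovery at 5 % CV; 4 archetypes × 5 MAGs × 20 peptides
× 2 replicates × 3 time points (2400 patterns) for cluster separation;
5 MAGs × 20 peptides for community carbon recovery; 100 cells for Raman
ratio recovery and 30 + 30 for classification.  These sizes give stable
statistics (binomial SE < 1 % on recovery rates) while keeping the full
suite fast.

## Known limitations

- RIA argmax on strongly *mixed* patterns (labeled fraction well below
  ~0.4) can lock onto the unlabeled component; the per-peptide labeled
  fraction from the decomposition should be consulted alongside.
- The overlap-rejection gate is conservative: with dense peak lists it
  discards ~10 % of otherwise valid patterns (random m/z collisions), the
  price of the contamination guarantee.
- Confidence-ellipse overlap is decided on PC1/PC2 only, as is standard
  for ordination plots; separation in higher components is ignored.
- mzML ingestion is not built in; peak lists arrive as TSV (any converter
  can produce them), keeping the I/O surface plain-text.
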