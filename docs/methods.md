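# Methods

This note documents the models and procedures implemented in
`kinodelta`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Measurement model and normalization

Each TMT plex quantifies up to 10 deletion-strain samples plus one
wild-type bridge channel. Reporter intensities are modelled as

    intensity = baseline · 2^effect · loading_factor · noise

where `effect` is the biological log2 change relative to wild type,
`loading_factor` is a per-channel sample-amount factor and `noise` is
multiplicative log-normal measurement error.

The normalization chain inverts this model step by step:

* **Isotopic impurity correction** solves the linear mixing system
  `observed = M · true` per molecule, where column *j* of `M` gives the
  fraction of reagent *j*'s signal appearing in each channel. Negative
  solutions (possible at low signal) are clamped to zero and counted.
  Rows with missing channels pass through uncorrected — with
  plex-structured missingness this case does not arise, and partial
  rows cannot be solved without imputation.
* **Peptide filtering** keeps peptides with summed signal-to-noise
  ≥ 200 across channels and isolation specificity ≥ 0.5, both
  inclusive. **Roll-up** sums unique peptides per protein; peptides
  shared between proteins are discarded entirely.
* **Loading equalization** rescales channels so summed protein signal
  is equal within the plex. Sums use only molecules observed in every
  channel of the plex, so missingness cannot bias the factors. The same
  factors are applied to the plex's phosphosite table, because site
  intensities inherit the protein loading of their sample.
* **Bridge ratios** are log2(sample) − log2(bridge) per molecule. Zero
  intensities become missing before the log transform (a zero reporter
  intensity is a detection failure, not a measured absence).
* **Trimmed-mean centering** subtracts each sample column's 5%-trimmed
  mean, absorbing the bridge channel's own measurement error. Centering
  is per sample column, not per plex globally: each channel has its own
  bridge-error realization and residual loading error, and per-column
  centering removes both. The 5% trim matches the trimmed-SD
  convention used for calling (below).
* **Joining** concatenates plexes by molecule identification; a
  molecule missing from a plex is missing in that plex's columns.
* **Protein normalization of phosphosites** subtracts the cognate
  protein's log2 ratio per (strain, replicate). Entries without a
  protein ratio keep the raw value with a provenance flag
  (`protein_normalized=False`); ~96% of site measurements are
  normalizable under the default missingness. The operation is exactly
  invertible: adding the protein matrix back restores the input.
* **Coverage filtering** keeps molecules quantified (either replicate)
  in at least ⌈50% · n_strains⌉ strains.

## Regulation calling

Replicates are merged by arithmetic mean. Per molecule, variability
across the strain panel is summarized by a **trimmed SD**: the merged
values are sorted, ⌊0.05·n⌋ values are removed from each tail, and the
SD (n−1 denominator) of the remainder is taken. Molecules with fewer
than three strain values are excluded.

A (strain, molecule) change is called when

* both replicates are present, each replicate's |ratio| ≥ 3·SD, and the
  replicates agree in sign (opposite-sign excursions are treated as
  irreproducibility, not regulation); or a single replicate is present
  with |ratio| ≥ 6·SD; and
* the merged |ratio| clears the level's fold-change floor: log2 0.38
  for proteins (minimum 1.3-fold) and 0.5 for phosphosites (minimum
  1.4-fold). The floor applies to the merged value; the SD test is
  per replicate.

The deleted gene's own product — and, at site level, phosphosites on
the deleted protein — is excluded from its strain's effector calls: the
deletion is the perturbation, not a response. Calling on a
protein-normalized site matrix additionally ignores pass-through
(unnormalized) entries, since an uncorrected value confounds
stoichiometry with abundance and cannot support a stoichiometry call;
the pass-through values remain available for correlation analyses.

**Attribution** compares the call sets from the raw and the
protein-normalized site matrices: `protein_driven` events are called
only on the raw matrix, `phospho_driven` on both, `newly_captured` only
after normalization. The **impact factor** of a strain is 100 × calls /
quantified molecules at that level.

## Correlation networks

Both network stages operate on merged, deletion-masked matrices
(the deleted gene's entries, and its phosphosites, are blanked in the
cognate strain to prevent deletion-driven pseudo-correlations).

*Strain pairs*: molecules measured in both strains and responsive
(|log2| ≥ floor) in **at least one** of the two qualify; requiring
responsiveness in both strains would bias toward shared responders and
routinely drop pairs below the 25-molecule minimum. Pearson r with a
two-sided p from the t transform (n−2 df) is computed for pairs with
≥ 25 qualifying molecules; BH adjustment runs over all evaluated pairs
within a level. Edges keep |r| ≥ 0.6; all other pairs enter the full
symmetric matrix as 0 (unit diagonal). The matrix row order for heatmap
export comes from average-linkage clustering of 1 − r.

*Molecule pairs*: pairwise-complete Pearson correlation over strains,
computed with dense matrix products (O(m²·s) in BLAS). Pairs need
shared measurements in ≥ ⌈50%·n_strains⌉ strains; edges require
|r| ≥ 0.7 **and** Bonferroni-adjusted p ≤ 0.001, where the Bonferroni
factor is the number of pairs actually evaluated (pairs failing the
overlap gate were never tested and do not inflate the correction).
Node pairs are reported in lexicographic order, making recomputation
bit-identical.

The **permutation test** shuffles every molecule's strain order
independently (missing entries travel with their values), preserving
each profile's marginal distribution while destroying cross-molecule
structure, then re-runs the identical edge scan (including the
Bonferroni factor). The false-positive rate is 100 × mean permuted
edge count / observed edge count; with zero observed edges the rate is
reported as undefined rather than zero.

**Edge attribution** is multi-label: an edge counts toward every
annotation class whose terms (or interaction pairs) cover both
endpoints, with phosphosites collapsed to host proteins; the union
("any") and unexplained fractions, and the same-protein fraction for
site networks, are reported alongside.

## Enrichment

All three modes use the upper hypergeometric tail P(X ≥ k) with BH
control at adjusted p ≤ 0.01. Term universes are intersected with the
stated background before computing term sizes, so annotation-only genes
cannot inflate the universe. The BH family is all tests within one
database (all strains or nodes × all terms × directions).

* *Regulator enrichment*: per molecule, do its regulating strains
  over-represent a pathway's regulators among all active regulators?
  The same-direction consistency filter (on the molecule's calls in
  pathway strains) is applied after testing and can be disabled; it
  replaces what would otherwise be manual curation of discordant
  patterns.
* *Effector enrichment*: per strain × direction, with multiple
  phosphosites per protein counted once and all perturbed proteins as
  background.
* *Neighbor enrichment*: per covariance-network node, the positively
  correlated neighbors against all positively connected proteins minus
  the node surveyed.

## Synthetic data generator

The generator emulates the panel design: `n_strains` (default 110)
strains, each deleting one distinct gene, assigned to
`n_assignment_groups` (14) groups of ≤ 10 sample channels; each group
is measured `replicate_count` (2) times with a wild-type bridge in
every plex — 28 plexes at the defaults.

Planted structure, all drawn from `effect_grid` magnitudes
(default {0.6, 1.0}) with random sign:

* each of `n_regulators` (10) regulator strains gets
  `targets_per_regulator` (30) protein targets and
  `phospho_targets_per_regulator` (30) phosphosite targets, of which
  `protein_driven_fraction` (0.6) move only through their host protein;
* `n_modules` (3) co-regulated modules of `module_size` (20) proteins,
  each moved jointly by several non-paired regulators — the substrate
  of covariance-network recovery;
* `n_shared_pairs` (1) regulator pairs share `shared_fraction` (0.8) of
  their protein and phospho targets with identical effects, emulating
  pathway co-membership (kinases in one cascade regulating a common
  target set);
* the deleted gene's own product is suppressed by `deletion_log2`
  (−5): a strong decrease without exact zeros that would break the log
  transform.

Effect families are planted on disjoint molecule sets — abundance
targets preferentially on proteins without phosphosites, phospho
targets on single-site hosts — so every downstream metric has an
unambiguous ground truth. Baselines are log-uniform over three orders
of magnitude (10⁴–10⁷). Per-channel loading factors are log-normal with
CV `loading_cv` (0.1). Measurement noise is multiplicative log-normal
with log2-scale SD `noise_sd` (0.1) on sample channels; the bridge is
modelled as a noise-free reference, so `noise_sd` directly
parameterizes the SD of a single replicate's log2 ratio and the
replicate difference has SD `noise_sd`·√2. Missingness removes a
molecule from all channels of a plex with probability
`missing_rate_plex`; the default 0.04 reproduces the ~96% fraction of
phosphosite measurements with an available cognate protein ratio. One
integer seed drives all randomness through independent child streams,
making every artifact byte-reproducible.

### What the generator does not emulate

No spectrum-level physics (co-isolation interference, ratio
compression), no peptide sequences, no abundance-dependent missingness
or noise, no batch effects beyond per-channel loading, and planted
effects are constant across replicates. Passing recovery tests
therefore demonstrates the correctness of the analysis logic under the
stated noise model, not performance on real spectra. Distribution
choices (baseline, loading, noise) are stand-ins; real reporter data
are not characterized by them. In particular the permutation
false-positive estimate on synthetic data (~1–2%) runs higher than
values typical of real panels, because the planted effect spikes are
denser and heavier-tailed relative to the noise floor than real
perturbation responses.

## Numerical choices and degenerate inputs

* Pearson r is clipped to [−1, 1]; pairs with zero variance report
  r = 0, p = 1 (and covariance pairs with undefined correlation are
  skipped). p-values use the t transform with n−2 df.
* The trimmed SD uses ⌊trim·n⌋ per tail with ties broken by sort
  order, giving deterministic results.
* BH adjustment is the standard step-up with monotonicity enforcement
  (via statsmodels); adjusted values do not depend on tie order.
* Bridge-channel zeros and missing bridge values blank the molecule's
  ratios for that plex, with counts logged.
* TSV matrices encode missing values as empty cells — never `NA` or 0,
  which would be ambiguous against true zeros. Phosphosite identifiers
  serialize as `PROT_pS123` / `PROT_pS123_pT130` with 1-based
  positions.

## Problem sizes used in the test suite

The acceptance checks simulate the full panel (110 strains ×
duplicates, 2,000 proteins, 3,000 phosphosites) for recovery and
network tests; the permutation-calibration check uses a 60 × 10
structure-free matrix with 300 permutations, and the acceptance
script's covariance false-positive estimate uses 100 permutations.
These sizes were chosen to give stable Monte-Carlo estimates at
interactive runtimes; all thresholds are the method defaults, never
adjusted per run.

## Known limitations

* Single-replicate calls at 6·trimmed-SD admit a small number of
  borderline noise calls at phosphosite level (trimmed SDs
  underestimate the heavier-tailed single-entry noise), visible as
  ~85–90% per-level precision in recovery runs; both-replicate calls
  are essentially exact.
* Phosphorylation stoichiometry itself is not estimated; normalized
  ratios are changes in stoichiometry, not absolute occupancies.
* The covariance scan holds several m × m float64 matrices in memory
  (~8·m² bytes each); panels beyond ~20,000 molecules would need a
  blocked implementation.
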