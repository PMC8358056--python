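# Methods

## Scope and model

`droughtkit` implements the computational chain of a cultivar
drought-resistance screen and its follow-on transcriptomic analysis:
conversion of raw assay measurements into six physiological stress
indices, fuzzy membership-function comprehensive evaluation and ranking of
cultivars, differential-expression time-course logic, expression-pattern
clustering, and Livak 2^−ΔΔCt qPCR quantification. Sequencing-scale steps
(read QC, de novo assembly, annotation, the DESeq2 model itself, GO/KEGG
enrichment) are out of scope: the package consumes — or simulates — the
tables those tools emit.

## Physiological indices

Each index is a deterministic formula over blank-corrected measurements.
Blank correction is the caller's responsibility because blanks differ per
protocol (solvent blank for pigments, TBA blank for MDA, reagent blank for
Coomassie). Units are carried on every tidy output row.

Two protocols publish no closed-form formula, so the package adopts the
field-standard definitions and exposes every scaling constant as an
explicit field of the assay record:

- **SOD**: one activity unit is the amount of enzyme causing 50 %
  inhibition of NBT photoreduction; activity (U g⁻¹ FW) =
  (inhibition/0.5) · (V_total/V_aliquot) / FW. The aliquot and extract
  volumes default to the modified protocol values (0.05 mL aliquot, 5 mL
  extract, 0.2 g tissue) but are plain parameters.
- **Proline** scaling mirrors the soluble-protein formula
  (curve µg · V_T / (V_S · W)), the conventional form for
  standard-curve-based osmolyte assays.

**MDA units.** The MDA formula is stated in µmol g⁻¹ FW, yet
stress-physiology results are routinely reported in nmol g⁻¹ (the two
differ by the ×1000 factor already present in the formula's denominator).
`compute_mda` returns µmol g⁻¹ by default and offers `as_nmol=True`;
neither convention is asserted as uniquely correct.

**Negative pigment concentrations**, which arise from noisy absorbances,
are clamped to zero with a `clamped` flag rather than raising: the
evaluation must stay robust on simulated noise, and the flag preserves the
information. Time-course summaries (`summarize_timecourse`) offer four
scalar reductions (final value, final/control fold change, mean
stress/control, peak fold change) because raw screens do not dictate which
scalar feeds the comprehensive evaluation; the mode is an explicit
argument, never a hidden default of the evaluation itself.

## Membership-function evaluation

Membership of observation x in index column [x_min, x_max] is
U = (x − x_min)/(x_max − x_min) for indices where larger is favorable
(Chl, SOD, SP, Pro) and 1 − U for damage indicators (REC, MDA). Default
directions follow this standard assignment and are overridable. Design
choices:

- **Ranking vs display.** Ranking always uses unrounded means; half-up
  rounding to two decimals is display only. Rounded composite scores
  collide easily (two cultivars can both print 0.66), so exact ties are
  broken by input order *and reported* in the result rather than silently
  resolved.
- **Degenerate columns** (max = min) raise an error naming the column:
  ranking on a constant index is meaningless and imputing 0.5 would hide a
  data problem.
- A precomputed membership matrix can be scored directly
  (`MembershipTable(..., source="supplied")`), which is how the packaged
  ten-cultivar reference table is reproduced exactly; supplied tables are
  not required to attain 0 and 1 in every column, since their provenance
  may include rounding.

Round-half-up uses the shortest decimal representation of the float, so a
stored 0.675 rounds to 0.68 rather than following the binary neighbour
down.

## DEG time-course logic

Calls use strict inequalities — adjusted p < 0.05 **and** |log₂FC| > 1 —
so boundary rows are excluded; up ⟺ log₂FC > 1, down ⟺ log₂FC < −1.
Missing adjusted p (DESeq2's independent-filtering NA) is treated as
non-significant. Venn analysis decomposes the four per-timepoint DEG sets
of one tissue into the 15 disjoint membership-pattern regions; k-way
intersections are sums of the disjoint regions they contain, which makes
the conservation property (regions sum to the union) testable directly.
Temporal classes are defined as *unions*: short-acting ⟺ differential at
6 h **or** 12 h, long-acting ⟺ at 24 h **or** 48 h — the per-timepoint DEG
sets are separate contrasts, and a gene may hold both flags. Classes are
per tissue; leaf and rhizome respond on different schedules and are never
pooled.

## Expression clustering

FPKM = count·10⁹/(length_bp · library_fragments). Clustering operates on
log₂(FPKM + 1) profiles (pseudocount 1, base 2 — conventional and
invertible). k-means uses k-means++ initialisation, 25 restarts, tolerance
1e-6, 300 iterations, fixed seed (scikit-learn backend), keeping the
lowest-WCSS partition; the reported objective is recomputed from the
returned labels and centroids rather than trusted from the fitter. k
defaults to 9 — the number of expression patterns distinguished in the
two-tissue × five-timepoint drought design. Per-gene z-scoring before
clustering is ON by default (pattern heatmaps compare temporal shapes, not
magnitudes) and OFF for profile reporting; both are flags because replicate
handling and row scaling are legitimately analysis choices.

## qPCR quantification

ΔCt = Ct(target) − Ct(reference) with replicates averaged on the Ct scale
(the standard Livak procedure; averaging after exponentiation biases the
estimate), ΔΔCt = ΔCt(sample) − mean ΔCt(calibrator), fold = 2^−ΔΔCt with
amplification efficiency fixed at 2. Calibrator self-normalisation is
exact on the log scale: the mean calibrator ΔΔCt is 0 by construction, so
the *geometric* mean calibrator fold change is exactly 1 (and a
single-sample calibrator has fold exactly 1). Group significance uses the
pooled-variance (classic Student) two-sample t-test on replicate fold
changes, two-sided, with stars at 0.05/0.01; testing on ΔCt instead is a
caller choice via `replicate_fold_changes`.

## Synthetic-data generator

One root seed feeds per-generator independent substreams
(`numpy.random.SeedSequence` spawn keys), so identical (seed, config)
pairs give byte-identical tables and adding a generator cannot perturb an
existing one. What each generator emulates, and what it does not:

- **Physiology** (`simulate_physiology`): per-cultivar index time courses
  with the qualitative drought trends — pigments rise then fall, REC
  increases monotonically, SOD dips then recovers, MDA accumulates
  (modelled as a monotone rise, the closest admissible shape to the
  rise–fall–rise some cultivars show), proline falls/surges/declines,
  soluble protein rises/falls/plateaus. Observations are Gaussian noise on
  the index scale added to the cultivar's noiseless trend, truncated to
  physical ranges, then **inverted** through the index formulas into raw
  measurements. The pigment inversion is under-determined, so it fixes
  A₄₇₀ = 0 and splits total concentration 3:2 between Chl a and b; the
  MDA inversion fixes D₄₅₀ = 0 and D₆₀₀ = 0.05. Baselines and amplitudes
  sit in realistic ranges for the units (e.g. MDA 15–33 nmol g⁻¹, SOD
  300–600 U g⁻¹). Real assays have heteroscedastic, instrument-specific
  noise and correlated replicates; passing round-trip tests therefore
  demonstrates formula correctness, not assay realism.
- **Index matrix** (`simulate_index_matrix`): latent per-index scores in
  [0, 1], the planted cultivar at the favorable extreme of every index,
  others strictly interior, rescaled to realistic index ranges (the
  evaluation is affine-invariant, so the ranges are cosmetic). At zero
  noise the planted cultivar attains membership 1.0 everywhere by
  construction.
- **DE tables** (`simulate_deg_table`): planted up/down genes draw
  |log₂FC| uniformly in (1.25, 1 + effect size) with adjusted p in
  (0, 0.05) open; nulls are strictly inside at least one threshold, a
  fifth of them with large fold changes but non-significant p to exercise
  the threshold conjunction. Open intervals keep the strict-inequality
  caller unambiguous, so planted-signal recovery is exact, not
  statistical. Default per-contrast fractions reproduce the leaf-mostly-up
  / rhizome-mostly-down, 12 h-peaked pattern of the motivating study
  (counts scaled by a nominal 25,000 tested genes). No count-level
  negative-binomial machinery is simulated.
- **Expression** (`simulate_expression`): gene profile = archetype +
  i.i.d. Gaussian noise. The nine default archetypes (log₂(FPKM+1) scale,
  two tissues × five timepoints, minimum pairwise spacing far above 1)
  encode tissue-specific temporal patterns: two leaf-specific
  (high–dip–recover; off-then-on) and seven rhizome-specific shapes.
  Real clusters have unequal sizes, correlated noise and ambiguous
  boundary genes; recovery tests certify the clustering plumbing, not
  biological separability.
- **Ct tables** (`simulate_ct`): treated target Ct shifted by
  −log₂(fold change) from a base of 25 cycles, reference gene constant at
  20 cycles, Gaussian replicate noise on the target Ct.

## Problem sizes

Defaults are sized for a desk-scale workflow: 10 cultivars × 6 timepoints
× 3 replicates for physiology, 2,000 genes for DE simulation, 450 genes
for cluster-recovery checks (50 per archetype), 10 random restarts ×
seeds for stochastic checks. The full test suite runs in well under a
minute on one CPU.

## Known limitations

- The exact per-cultivar scalar that feeds a published membership table
  (final-day value, fold change, or a time-course summary) is generally
  not recoverable from the table itself; the package therefore accepts
  precomputed membership matrices for exact reproduction and leaves the
  summary mode explicit.
- SOD and proline scaling constants depend on protocol volumes; defaults
  match the modified protocol but must be set per lab.
- The qPCR module assumes a single reference gene and fixed efficiency 2;
  multi-reference normalisation and efficiency calibration are out of
  scope.
- k-means local optimality is Lloyd-type (each point assigned to its
  nearest centroid); single-point relabelling with centroid recomputation
  (Hartigan moves) can in principle improve rare solutions on hard
  instances.
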