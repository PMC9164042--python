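# Methods

## The procedure

The pipeline consumes per-run peptide and protein report tables (TSV,
UTF-8, header row, ";"-joined multi-accession cells — the dialect of
delimiter-separated PeptideShaker exports) organized by a declared study
design (dataset → sample → replicate).  Run keys are codified as
`dataset_sample_replicate` strings ("1_1_1").  The built-in design
describes the six chorionic-villus datasets: dataset 1 with 3 samples × 2
replicates, datasets 2, 3, 5, 6 with 1 sample × 3 replicates, dataset 4
with 1 sample × 2 replicates (20 runs).

### QC exclusion

A run is excluded when its spectrum count (`n_spectra`, carried as report
metadata) falls below `min_spectra`.  The threshold is a required
configuration value rather than a constant because it is data-derived —
it reflects the spread of counts actually acquired in a given study.
Whether the count refers to spectra acquired or spectra matched is up to
the producer of the reports; both interpretations flow through the same
field.  After exclusion, the *effective* design spanned by the surviving
runs replaces the declared one (replicate indices renumbered); a dataset
whose samples end up with unequal replicate counts is rejected with a
request for an explicit design.

### Filter ladder

Stages are applied per dataset in a fixed order, each intersected with its
predecessor, so the sets form a chain `P_total ⊇ P_placenta ⊇ I_successful
⊇ I_proteins ⊇ I_reliably ⊇ Q_reliably` (asserted at construction):

* **P_placenta** removes accessions whose contaminant identification
  frequency is ≥ 0.67 (boundary inclusive), removes P01834 and P02768
  unconditionally, and keeps only placenta-annotated accessions.  The three
  restrictions commute, so their order is immaterial.  Accessions missing
  from the annotation table count as not annotated (conservative) and are
  tallied.
* **I_successful** requires ≥ 2 *distinct peptide sequences*, each with
  score ≥ 99 on the 0–100 confidence scale, within a single run.  The
  score threshold applies per peptide; counting distinct sequences (not
  spectra) is standard two-peptide-rule semantics.
* **I_proteins / I_reliably** generalize "2/3 or more" occupancy to
  ≥ ⌈2k/3⌉ of k items (k = 3 ⇒ 2; note for k = 2 this coincides with
  "all").  Default per-dataset rules for the built-in design: replicate
  occupancy ALL for the 2-replicate datasets (1, 4), 2/3 for the
  3-replicate ones; sample occupancy 2/3 for multi-sample dataset 1, ALL
  elsewhere.  Both stages are monotone in evidence: adding a peptide or a
  replicate observation never removes a protein.
* **Q_reliably** keeps a protein when CV ≤ 0.16 **or** FC ≤ 1.25 over its
  positive NSAF values across the dataset's runs.  The disjunction is
  deliberate — a conjunction would be stricter, and readers expecting
  "and" should note this.  CV uses the sample standard deviation (n − 1
  denominator, the R `sd` convention).  Proteins with fewer than two
  positive NSAF observations are dropped and logged (CV/FC undefined).
  For the multi-sample dataset 1 all six runs are pooled rather than
  aggregated per sample first.

The summary statistic `summarize_counts` reports mean and sample SD of a
count column, each rounded half-away-from-zero to an integer.

### NSAF, centering, categories

NSAFᵢ = (SpCᵢ/Lᵢ) / Σⱼ(SpCⱼ/Lⱼ), normalized over the full protein report
of the run, so the values sum to 1 per run.  A zero spectral count means
"unquantified in this run": the protein receives NSAF 0 and never enters
CV/FC (FC = max/min is undefined at zero).

The quantity that is centered and categorized is the **per-protein mean
NSAF** across the dataset's runs — one number per protein, centered so the
dataset's values sum to 0.  Quartile assignment uses rank cutoffs: sorted
ascending (ties broken by accession), the lowest ⌊n/4⌋ proteins are LOW,
the highest ⌊n/4⌋ HIGH, the remainder MEDIUM.  Rank cutoffs (rather than
interpolated quantile values) make category counts deterministic and tie
behaviour explicit.  The reported thresholds are the boundary centered
values (max LOW, min HIGH), summarized as mean ± sample SD across datasets
to 3 decimals.  Categorization requires ≥ 4 quantified proteins.

### Set comparison

* Exclusive intersections partition the union of up to 30 named sets by
  exact membership combination; counts therefore sum to the union size.
* Protein-list "variability" is Jaccard distance 1 − |A∩B|/|A∪B| on
  accession sets — a natural metric for presence/absence lists.  The
  per-run list at a ladder stage is the run's reported accessions
  intersected with the dataset's stage set.
* Clustering delegates to `scipy.cluster.hierarchy.linkage`; complete
  linkage is the default (single and average are available).  scipy's
  deterministic implementation fixes tie behaviour.
* Entanglement between two trees over the same labels:
  Σ|rank_left − rank_right|^L normalized by the maximum of that sum (the
  exact reversal), with L = 1.5 by default.  By default **no** untangling
  is performed — the score compares the declared reference order against
  the clustering exactly as built.  Because agglomerative merge order
  orients branches arbitrarily, an optional step-wise untangle rotates
  each merge node toward the reference (children ordered by mean reference
  rank) before scoring; use it when the question is topological agreement
  rather than drawn leaf order.  The rotation heuristic is greedy and not
  guaranteed optimal.
* The Wilcoxon rank-sum test reports the Mann–Whitney U of the first group
  (computed from pooled midranks) with an exact two-sided p-value,
  2·min(P(U ≤ w), P(U ≥ w)) capped at 1, taken from the full permutation
  distribution.  The distribution is evaluated by a dynamic program over
  doubled (integer) midranks — algebraically identical to enumerating all
  C(n₁+n₂, n₁) assignments, but O(n²·Σranks).  Groups larger than 12 fall
  back to the normal approximation with a logged notice.  For the protocol
  comparison, each group pools the within-dataset pairwise distances of its
  datasets (two 3-replicate datasets ⇒ C(3,2)·2 = 6 values per group); at
  sizes 6 and 6 the exact two-sided 5% critical value is U = 5.

## The synthetic generator

`simulate_study(design, params)` draws, per protein: a log-normal length
(median ≈ 400 aa, log-sd 0.45); an abundance class LOW/MEDIUM/HIGH
(weights 0.25/0.50/0.25) with a 4-fold step between classes; contaminant
status (10%) with identification frequencies drawn from two beta clusters
on either side of the 0.67 boundary (75% above); placental annotation
(85%); spurious status (10% of non-contaminants); stability (70%).
Per run, spectral counts are negative-binomial with mean
`counts_per_residue × length × class fold × dataset effect × replicate
factor` and size parameter `spectral_dispersion` (300 ⇒ mild
overdispersion).  The replicate factor is log-normal with sigma
`cv_target_stable` (0.08) or `cv_target_unstable` (0.80) — the knob the
CV/FC filter keys on.  Dataset structure comes from a per-(protein,
dataset) abundance effect (log-sd 0.5) and from 30% of proteins being
detectable only in a random half of the datasets; both are shared by a
dataset's runs, so they shape between-dataset overlap and clustering
without touching within-dataset reproducibility.  Truly present proteins
carry 2 + Poisson(1.5) distinct peptides per run with scores ≈ N(99.6,
0.35) clipped to [0, 100]; spurious ones carry 1 + Poisson(0.5) peptides
at ≈ N(85, 5), so they fail the two-peptide score filter.  Peptide
sequences are arbitrary 7–30 aa strings — only counts and scores feed the
pipeline, so no biological digestion is simulated.

`SimulationParams.well_separated()` (counts ×4.8 deeper, stable sigma
0.03, dispersion 500) is the documented setting for ground-truth recovery
checks: it makes the stable/unstable distinction nearly noiseless so that
recovery failures indicate implementation defects rather than sampling
noise.

What the generator does **not** emulate: shared peptides between proteins
(each synthetic peptide maps to one accession), score calibration against
a decoy model, retention-time or m/z structure, correlated contaminant
abundance, or realistic dynamic range (three discrete classes instead of a
continuum).  Passing tests therefore demonstrate the correctness of the
filtering and statistics on reports with this structure, not the
biological validity of any particular threshold on real data.

A known compositional effect is worth noting: because NSAF values are
normalized per run, strong swings of *unstable* proteins move the
normalizing denominator and impose a common-mode shift on every other
protein in that run.  In 2-replicate datasets this occasionally pushes
genuinely stable proteins past both CV and FC limits.  This is a property
of NSAF itself, not of the implementation; it is mildest when abundant
proteins are mostly stable.

## Numerical and design choices

* Scores, lengths and counts are validated on construction (scores in
  [0, 100], lengths ≥ 1, counts ≥ 0); duplicate accessions within a run
  and peptides referencing unreported accessions are rejected.
* `build_study` requires the run-key set to equal the design exactly;
  partial studies go through the effective-design path described under QC.
* Rounding: summary counts round half-away-from-zero (not banker's);
  thresholds report 3 decimals.
* The exact rank-sum DP uses doubled midranks to stay in integer arithmetic
  under ties; identical groups yield p = 1 by construction.
* Determinism: one integer seed drives the generator; identical (design,
  params) give byte-identical fixtures.  The pipeline writes outputs to a
  temporary directory and commits on success only, records a configuration
  hash (never a timestamp), and is byte-idempotent across reruns.
* Problem sizes in the test suite (studies of 30–600 proteins, 20 runs;
  100 randomized oracle studies; 20-seed sweeps) were chosen as the
  smallest scales at which the stochastic properties are comfortably
  stable.

## Limitations

* Protein inference/grouping, FDR estimation and search-engine specifics
  are out of scope: reports are taken as already grouped and scored.
* The contaminant frequency cutoff, score threshold, CV/FC limits and
  quartile rule are configurable but default to the values above; nothing
  in the package estimates them from data.
* The entanglement score depends on leaf order, which for an agglomerative
  tree is orientation-arbitrary unless untangling is applied; comparisons
  between studies should fix one convention.
* Excel report parsing is deliberately unsupported — export to TSV
  upstream.
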