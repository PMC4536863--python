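# Methods

## Scoring model

The package treats an MSAP/TMD experiment as a paired-digest classifier of
CCGG sites. Both HpaII and MspI cut the unmethylated site; MspI (but not
HpaII) also cuts when the internal cytosine carries CG methylation, and
HpaII (but not MspI) cuts when the external cytosine is hemimethylated in
CHG context. The four lane combinations therefore map bijectively onto
{unmethylated, CG, CHG, uninformative}. The (0,0) pattern is genuinely
ambiguous: a fully methylated site and an absent fragment produce the same
signal, so the assay can only bound methylation from below.

**Level denominator.** A sample's methylation level is
`(n_CG + n_CHG) / n_scored`. By default `n_scored` excludes (0,0) sites,
since they cannot be attributed to the assay's target process; the
alternative convention (count (0,0) as scored-but-monomorphic) is exposed
as `include_uninformative_in_denominator` for sensitivity analysis.
Excluding them can only raise the level, so the default is the more
generous estimate of per-site methylation among *interpretable* sites;
both conventions are exact on simulated truth when compared with the same
denominator.

**Site filters.** A site whose presence varies across samples while no
sample ever shows H ≠ M is excluded: in genome-wide MSAP it is
indistinguishable from ordinary AFLP sequence polymorphism
(`GENETIC_AFLP`); in a TE-anchored TMD display the natural reading is a
transposition presence/absence polymorphism (`TRANSPOSITION_NO_METH`).
The predicate is deliberately conservative — one methylation-polymorphic
sample anywhere retains the site. Sample QC excludes samples whose
missing-call fraction exceeds `max_missing` (default 0.2; the threshold is
a package choice, exposed in the config).

**Markers.** Each retained site contributes its H-lane and M-lane presence
as two separate binary markers (band-as-allele convention). Markers that
are constant across samples are kept; they cancel from Jaccard and only
rescale Bray-Curtis counts when shared.

## Resemblance

On binary data, Bray-Curtis similarity reduces to the Sørensen coincidence
`2a/(2a+b+c)` and Jaccard to `a/(a+b+c)` with a = shared presences and
b, c the one-sided presences; joint absences never contribute, so both
measures are invariant to all-absent markers and Bray-Curtis ≥ Jaccard for
every pair. Similarities are stored on [0,1] and converted to percentages
only at report time. Missing marker values are handled by
pairwise-complete deletion (a marker enters a pair's counts only if
observed in both samples). A pair of all-zero profiles has undefined
similarity; it is reported as 0 by default (configurable to raise).
Dissimilarity for clustering and ordination is `1 − S`.

## Clustering and SIMPROF

Clustering is agglomerative with group-average (UPGMA) linkage — the
conventional default for resemblance-based community analysis — computed
by scipy; a brute-force O(n³) recomputation serves as the test oracle.
Merge heights live on the dissimilarity scale. Newick export uses the
ultrametric convention node-depth = height/2, so the path length between
two leaves equals their cophenetic dissimilarity.

SIMPROF asks whether a group of samples contains multivariate structure.
The observed profile is the ascending vector of all within-group pairwise
similarities. The mean profile is the element-wise mean over
`n_perm_mean` datasets in which every marker is independently permuted
across the samples; the statistic is `π = Σ_k |observed_k − mean_k|`. A
second, independent batch of `n_perm_test` permuted profiles provides the
null distribution of π, and `p = (1 + #{π_perm ≥ π_obs})/(1 + n_perm_test)`
(add-one convention: p is never 0). π = 0 exactly when the observed
profile coincides with the mean profile. Function defaults are 999/999
permutations at α = 0.05.

Annotation runs top-down from the root with the standard stopping rule:
a node that fails to reject is declared homogeneous and none of its
descendants are tested (they inherit the verdict); nodes with < 3 samples
have ≤ 1 ordered similarity and are untestable. Each node draws its
permutations from the seed stream `[seed, node]`, so results are
reproducible and independent of traversal order. The observed profile is
sorted, hence exactly invariant to sample relabeling; the permutation
estimate of the mean profile (and so p) is invariant in distribution.

## ANOSIM and nMDS

ANOSIM ranks all n(n−1)/2 dissimilarities with mid-ranks for ties and
computes `R = (r̄_between − r̄_within)/(M/2)`, `M = n(n−1)/2`; R ∈ [−1,1]
with expectation 0 under label exchangeability. When the number of
distinct relabelings of the label multiset is within the permutation
budget (default 9999) the p-value is exact by full enumeration (the
observed labeling counts); otherwise it is Monte-Carlo with the add-one
convention. Pairwise tests re-rank each two-group submatrix; pairs with a
singleton group are skipped with a warning; pairwise p-values are reported
uncorrected with a Bonferroni column alongside.

nMDS minimizes stress by SMACOF with isotonic disparities (scikit-learn),
taking the best of `n_restarts` random initializations; restart r uses
seed stream `[seed, r]`, so the best stress is non-increasing in the
number of restarts on a fixed seed. The reported quantity is Kruskal
stress-1, recomputed from the final configuration via
pool-adjacent-violators regression of configuration distances on the
dissimilarities; the configuration is centered, and defined only up to
rotation/reflection. An input whose dissimilarities are all equal is
degenerate and triggers a warning.

The pipeline clusters on Bray-Curtis and runs ANOSIM/nMDS on Jaccard by
default — the sequence resemblance-based packages conventionally use for
this assay — and both measures can be overridden independently.

## The simulator

The generator emulates a five-population, common-garden MSAP survey; it is
the test bed for every stage, not a model of any particular genome.

* **States.** Each population × site has a distribution over
  {unmethylated, CG, CHG, fully-methylated} drawn from a Dirichlet centred
  on a shared base with concentration `1/divergence`; `divergence = 0`
  collapses all populations onto the base (an exchangeable null), larger
  values plant stronger structure. Samples draw states independently;
  lanes are emitted by the truth table above (fully-methylated → (0,0)).
* **Genetic sites.** A configurable fraction of sites carry a binary
  presence allele at population frequencies obtained by Beta resampling of
  a shared Uniform(0.2, 0.8) base frequency (Balding-Nichols style, same
  divergence knob), copied to both lanes.
* **Noise.** Every lane call flips independently with probability
  `band_error`.
* **Transmission.** A second generation keeps each methylation state with
  probability `inheritance_fidelity`, redraws otherwise from the
  population distribution, and inherits genetic alleles unchanged
  (selfing).

Defaults are the study-scale regime: 5 populations × 10 accessions × 447
sites; base state probabilities (0.315, 0.2223, 0.3627, 0.10), i.e. a
scoreable-methylated fraction of 0.65 with CHG:CG odds 62:38 and 10%
fully-methylated mass; 10% genetic sites; `band_error = 0.02`;
`divergence = 0.15` (clearly separated populations without being
degenerate); `inheritance_fidelity = 0.9`. All randomness descends from
one seed through named substreams (probabilities / states / genetic /
errors), so fixed seeds give byte-identical output.

What the simulator does **not** emulate: fragment sizes and co-migration
(band ids are assumed pre-binned and comparable across samples), PCR
selective-primer chemistry, TE copy-number evolution, linkage between
sites, and spatially structured missingness. Passing tests therefore
demonstrate correctness of the scoring and inference machinery under the
stated generative model, not robustness to every artifact of real gels.

## Numerical and design notes

* Band matrices store calls as int8 with −1 for missing; missingness is
  preserved exactly through I/O (`NA` in the TSV dialect) and never
  coerced to absence.
* Permutation p-values use ≥ comparisons with a 1e−12 slack so exhaustive
  enumeration always counts the observed labeling.
* Resemblance matrices are symmetrized (`(S + Sᵀ)/2`) and clipped to
  [0,1] to remove floating-point asymmetry before clustering.
* Tests and the bundled analysis scripts run the permutation machinery at
  reduced sizes (49–199 permutations, 1000-replicate calibrations at 12
  samples × 40 markers) — sizes chosen to give stable Monte-Carlo checks
  at interactive speed; the library defaults (999/999, 9999) are what an
  analysis of real data should use.
* Known limitations: the assay cannot separate full CCGG methylation from
  fragment absence (levels are lower bounds); SIMPROF's mean profile is
  estimated once per node rather than leave-one-out; pairwise-complete
  deletion can make a resemblance matrix non-Euclidean under heavy
  missingness (harmless for rank-based ANOSIM and nMDS, visible as
  negative eigenvalues in metric embeddings).
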