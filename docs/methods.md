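# Methods

## Scope and model

`funconn` implements a group comparison of resting-state functional
connectomes as binary graphs. The pipeline starts from ROI-level time
series (it deliberately does not touch voxel data or image formats): for
each subject it computes the N × N Pearson correlation matrix of the
regional signals, binarizes it by proportional thresholding across a grid
of edge densities, computes small-world metrics and nodal centrality on
each binary graph, and then tests each metric between groups density by
density. The three cohorts it is organized around are healthy controls
(HC) and Parkinson's disease patients without and with impulse control
disorders (PD_nICD, PD_ICD).

### Proportional thresholding

At density d the graph keeps exactly k = round(d · N(N−1)/2) edges — the
k largest positive correlations. Rounding is half-away-from-zero so the
edge count is deterministic and, e.g., d = 0.5 on N = 4 gives exactly 3
edges. Matching edge counts across subjects before comparing metrics is
the standard way to stop group differences in mean correlation from
masquerading as topology differences. Negative correlations never become
edges by default (`use_absolute=True` ranks by |r| instead); ties at the
cutoff break by lexicographic node-pair order, so the graph is a pure
function of the matrix. Graphs across a grid are nested by construction.
The default grid is 10–50% in 1% steps (41 densities).

### Small-world metrics

On each binary graph:

* **Cp** — mean local clustering coefficient. Nodes with degree < 2 have
  undefined local clustering; they contribute 0 and stay in the mean.
  This choice deflates Cp at very sparse densities and is stated here
  because the alternative (dropping those nodes) inflates it.
* **Lp** — characteristic path length, the mean BFS distance over all
  *reachable* ordered pairs. Disconnected graphs (possible at low
  density) do not produce infinities; instead the unreachable fraction
  of pairs is reported alongside (`frac_unreachable_pairs`). A
  largest-component convention was considered and rejected because it
  silently changes N across subjects.
* **σ** — Humphries–Gurney small-worldness
  σ = (Cp/⟨Cp_rand⟩) / (Lp/⟨Lp_rand⟩) = γ/λ, with the null averages
  taken over `n_nulls` (default 100) degree-preserving rewirings of the
  observed graph (Maslov–Sneppen double edge swaps, 10 swap attempts
  per edge; illegal proposals are skipped). σ > 1 is the small-world
  regime. On a complete graph no swap is legal, so γ = λ = σ = 1
  exactly.
* **Nodal centrality** — degree/(N−1) by default; normalized
  shortest-path betweenness as an option. The default is degree because
  it is the most common "nodal centrality" in binarized connectomics and
  is exactly testable; it is a package default, not a claim about what
  any particular study computed.

The rewiring and BFS inner loops are numba kernels (`_kernels.py`); all
their randomness is pre-drawn from numpy Generators, so every result is
bit-reproducible given a seed. Seeds are layered with
`numpy.random.SeedSequence`: fit seed → per-subject stream (mixed with a
CRC32 of the subject id) → per-density stream, so any single
subject/density cell can be recomputed in isolation.

### Group statistics

Metric curves are compared density by density with a two-tailed
pooled-variance t test (default) or a label-permutation test (10,000
permutations, seeded; p = (1 + #{|perm| ≥ |obs|})/(n_perm + 1)). Nodal
centralities are compared per node, either at a single density or after
averaging each subject's centrality over the density grid ("auc", the
default summary). Significance is uncorrected p < 0.05, two-tailed, by
design: with ~17 subjects per group, correction for 41 densities × 100
nodes leaves no power, which is the regime this class of study operates
in; Benjamini–Hochberg FDR is available behind the `fdr=True` flag. The
reported direction always refers to the first-named group.

The summary-statistics family (`anova_from_summary`, `ttest_from_summary`,
`chisq_contingency`) reconstructs one-way fixed-effects ANOVA and
pooled-variance t tests from printed (mean, SD, n) triples — these are
sufficient statistics, so the results equal raw-data computations to
floating precision — and Pearson chi-square without continuity
correction. The packaged demographics table for the PPMI-derived
PD-ICD/PD-nICD/HC cohort reproduces the published p-values at their
printed 2-dp precision for age, sex, disease duration, UPDRS-III, MoCA,
education and depression. The Hoehn–Yahr row is the known exception: the
printed 0.73 recomputes to 0.75 under every pooled test, which suggests
a nonparametric test was used for that row; it is documented rather than
matched.

## Synthetic cohorts

Because the original imaging data are access-restricted, the package
ships a generator whose outputs stand in for them end to end.

Each subject receives a planted graph on N = 100 nodes (the 100-parcel,
7-network cortical parcellation scale; labels follow the
`7Networks_<hemi>_<network>_<k>` convention). The default topology is
Watts–Strogatz with ring-lattice degree k = 10 and a group-specific
rewiring probability — the planted effect. Lower rewiring means higher
clustering *and* longer paths, so a single knob reproduces the reported
direction pattern. Defaults:

| group   | rewire_prob | planted position                      |
|---------|------------:|---------------------------------------|
| PD_ICD  | 0.05        | highest Cp, longest Lp                 |
| HC      | 0.15        | intermediate                           |
| PD_nICD | 0.30        | lowest Cp, shortest Lp                 |

with group sizes 16/18/18 and T = 210 volumes at TR = 2.4 s (the study's
acquisition length). Disconnected draws are redrawn up to 100 times and
then fail loudly — silently densifying would bias Cp.

The graph induces a correlation-form covariance
S = normalize(δI + c·A + g·(J−I)) with coupling c = 0.4 and a uniform
background g = 0.1 (`global_corr`) shared by every pair, the analogue of
the global BOLD component that makes empirical resting-state correlation
distributions predominantly positive. The background is load-bearing:
with g = 0, non-edge pairs have population correlation exactly zero,
half their sample correlations are negative by symmetry, and the 50%
density point of the default grid becomes infeasible under positive-only
thresholding. The diagonal load δ is adaptive —
δ = max(1, |λ_min(cA + g(J−I))|/0.95) — so the matrix is positive
definite by construction with a 5% eigenvalue margin (non-edges keep
exactly g/δ, edges (c+g)/δ); eigenvalue flooring at 10⁻³ remains as a
last-resort repair and a hard error reports the smallest eigenvalue if
even that fails.

Time series are a stationary multivariate Gaussian AR(1):
x_t = φ·x_{t−1} + ε_t with φ = 0.3 (a typical BOLD autocorrelation at a
2.4 s TR), ε_t ~ N(0, noise_sd²·S), initialized from the stationary
distribution (no burn-in). The stationary correlation equals that of S,
so `coupling` and `global_corr` translate directly into expected sample
correlations. With these defaults a true edge carries a sample
correlation of ≈ 0.2–0.3 versus ≈ 0.05 for background pairs at T = 210 —
a strong but not unrealistic contrast for averaged ROI signals.

What the generator does **not** emulate: hemodynamic response shape,
physiological and motion artifacts, scanner drift, spatial
autocorrelation between neighboring parcels, negative functional
coupling, and between-subject variability beyond the topology draw.
Passing tests therefore show that the pipeline recovers planted
topological group structure from temporally autocorrelated, noisy
multivariate signals at the study's T and n — not that it would detect
effects of this size in real BOLD data.

## Validation design and problem sizes

* **Oracle equivalence.** Cp, Lp, degree and betweenness are checked
  against deliberately naive brute-force implementations (triple-loop
  triangle counts, Floyd–Warshall, explicit enumeration of every
  shortest path) on every labeled graph with ≤ 5 nodes and 200 random
  6–7-node graphs.
* **Small-world regime.** A full-size default cohort (52 subjects, 41
  densities, 100 nulls per graph ≈ 213k null graphs) must give σ > 1 at
  every subject × density. This is also what `scripts/acceptance.py`
  recomputes.
* **Parameter recovery.** 100 replicate two-group cohorts (18 vs 18,
  rewiring 0.30 vs 0.05) are generated and pushed through the pipeline;
  the recovered direction of the group difference in density-averaged
  mean Cp and mean Lp must match the planted ground truth in ≥ 95% of
  replicates. Recovery runs on a 9-density grid (10–50% step 5%), the
  package's evaluation grid for replicate studies; the direction
  summary is insensitive to the grid step.
* **Test calibration.** Under exchangeable Gaussian null data the
  per-density and per-node tests must reject at 3–7% at nominal 5%
  (2000 simulated null datasets each). Calibration is a property of the
  testing machinery, so the null data are drawn directly at the
  metric level rather than through the imaging simulator.

## Known limitations

* Binary undirected graphs only; weighted variants, efficiency,
  modularity and rich-club metrics are out of scope.
* The positive-only thresholding policy makes densities approaching the
  positive-correlation fraction infeasible; the error message reports
  available vs requested edges.
* σ is computed per density; area-under-curve summaries of σ are not
  provided (nodal centrality does offer an "auc" summary).
* The permutation test permutes subject labels and therefore assumes
  exchangeability under the null; covariate adjustment is out of scope.
* At very sparse densities the degree-<2 clustering convention and
  reachable-pairs Lp make Cp and Lp less comparable across graphs with
  different fragmentation; `frac_unreachable_pairs` should be inspected
  before interpreting those densities.
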