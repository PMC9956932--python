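# Methods

## Model and assumptions

The method treats differential expression as an outlier-detection problem
in aggregate space rather than a hypothesis test. Its assumptions are
geometric, not distributional:

* after log transformation, equally expressed genes form a dense, oblong
  cloud along the equivalence line of the (mean₁, mean₂) plane;
* DE genes are a small minority, far enough off that line to be density
  outliers;
* within-strain replicate variability is informative on its own: genes
  with matching strain means can still differ in within-strain spread,
  visible off the diagonal of the (std₁, std₂) plane.

Batching is the essential trick. DBSCAN on the full gene set sees one
enormous dense region and calls few points noise; on a batch of a few
hundred genes, local density contrast is sharper and the pooled noise set
across batches is much larger. Batch composition therefore affects the
result, which is why batch order is part of the configuration
(`input` default, `shuffle` with a recorded seed and a
total-expression sort are provided for sensitivity analysis).

## Pinned-down choices the procedure leaves open

The published procedure leaves several details unstated; this
implementation fixes them explicitly so runs are reproducible:

* **DBSCAN variant** — neighbourhoods are closed balls (d ≤ r) and include
  the point itself, so N_min = 1 makes every point core; clusters are
  connected components of core points under mutual r-reachability; a
  border point joins the cluster of the lowest-index reachable core
  point; cluster ids 1..K follow the lowest member index. The clustering
  contains no randomness. Complexity is the plain O(n²) scan — batches
  are ≤ ~1022 points, so indexed variants buy nothing.
* **Log base** — 2 (transcriptomics convention), configurable. Every
  radius and threshold (r, T_std) lives on the chosen log scale, so the
  base is recorded in the output header.
* **Standard deviation** — sample std, denominator n − 1; recorded in the
  output header. Each strain therefore needs ≥ 2 samples.
* **Zero handling** — genes containing any zero are removed outright, no
  pseudocount (an optional pseudocount flag exists, default off). No
  library-size normalisation or variance stabilisation is applied
  anywhere.
* **Std stage** — default is the scalar rule |std₁ − std₂| > T_std, which
  is the only reading under which a single threshold varied in 0.05 steps
  is coherent; a std-space DBSCAN mode is also implemented and selectable.
  The stage runs per batch on that batch's compact-cluster genes, and
  only on genes the mean stage did not already flag, so no gene is called
  twice. In DBSCAN mode the Mahalanobis covariance is re-estimated from
  the std-space points.
* **Mahalanobis covariance** — estimated per batch from the 2-D points
  being clustered (sample covariance, n − 1), which adapts to the oblong
  cloud; `global` (covariance from all genes) and `identity` modes exist
  for sensitivity analysis. A ridge regulariser defaults to
  1e-8 · trace(C)/2 so a nearly collinear batch never aborts a run;
  ridge = 0 raises an explicit singularity error instead.
* **Minkowski p < 1** — computed by the same formula although it is not a
  metric (the triangle inequality fails); DBSCAN needs only a symmetric
  dissimilarity, and fractional p is one of the better-separating choices
  in practice. Nothing in the pipeline assumes the triangle inequality.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| r | log₂ expression | 0.2 | DBSCAN neighbourhood radius; doubling it collapses the noise set |
| N_min | count (self incl.) | 5 | neighbours needed for a core point; raising it grows the noise set |
| N_b | genes | 511 | batch size; several hundred balances outlier surfacing vs cluster stability |
| T_std | log₂ expression | 0.3 | std-gap cut; larger values select fewer genes |
| distance | — | Mahalanobis (per batch) | governs cluster shape; oblong measures suit the diagonal cloud |

r and N_min are hand-tuned per dataset by the method's own procedure:
raise them until the equivalence cloud is one compact cluster and only
genuinely off-line points are noise. Noise counts are provably monotone
here (non-increasing in r, non-decreasing in N_min, std calls
non-increasing in T_std), which the test suite asserts on random data.

## The synthetic generator

`SyntheticSpec` emulates the statistical shape of a two-inbred-strain bulk
RNA-seq comparison: 2000 genes by default, 10 + 11 samples, gene baselines
log₂-normal(5, 1.5), negative-binomial counts with dispersion 0.1 (a
typical biological-replicate value for bulk RNA-seq), 2.5 % of genes with
a ±2 log₂-fold mean shift in one strain, 1.5 % with equal means but 4×
dispersion in a randomly chosen strain, and 2 % forced to contain a zero
so the filter is exercised. Everything is drawn from one seeded
`numpy` generator, so outputs are bit-identical for a fixed seed, and a
truth table records each gene's class.

The generator reproduces the geometry the method exploits — diagonal
cloud, off-line mean outliers, off-diagonal std points — but deliberately
not the full texture of real data: no library-size differences between
samples, no gene–gene correlation, no length/GC effects, and a single
common dispersion rather than a mean–dispersion trend. Passing the
recovery tests therefore shows the pipeline implements the method
correctly and can separate planted effects of realistic size; it does not
certify sensitivity/specificity figures for any real dataset.

For this simulated geometry the cloud is broader than real mouse data, so
the tuned preset `synthetic_preset()` uses Mahalanobis, r = 0.6,
N_min = 10, T_std = 0.55 (N_b = 511). At the generator defaults this
recovers every surviving planted mean-shift gene with a null
false-positive rate around 3 %, and the std stage roughly triples the
recovery of planted variance genes. Variance effects are intrinsically
harder: with ~10 replicates the sampling error of a sample std is large,
so only about a third to a half of 4× dispersion genes clear a T_std that
keeps null std calls rare.

## Numerical notes

* Distance matrices are computed densely by broadcasting, symmetrised as
  (D + Dᵀ)/2 and given an exact zero diagonal; Mahalanobis squared
  distances are clipped at 0 before the square root.
* Minkowski p = 64 agrees with the Chebyshev distance to 1e-6 only when
  one coordinate difference dominates each pair (the excess factor is
  (1 + t⁶⁴)^(1/64) with t the min/max coordinate-diff ratio, up to
  2^(1/64) ≈ 1.011 for t = 1). The tests assert the 1e-6 agreement on
  dominant-direction clouds and the exact two-sided envelope
  D_cheb ≤ D_64 ≤ D_cheb·2^(1/64) in general.
* Batch splitting is exact ceil-division: 9196 genes at N_b = 511 give 17
  full batches and a last batch of 509. (Published batch layouts for this
  gene count are internally inconsistent by one gene; the exact split is
  used here and the last-batch size is not asserted against any external
  figure.)
* Degenerate inputs fail loudly and early: matrices with duplicate ids,
  designs without exactly two strains or with singleton strains, log of
  non-positive values, batches of fewer than two genes, covariance from
  fewer than three points, and an empty post-filter gene set all raise
  typed errors.

## Known limitations

* No automatic (r, N_min) selection; the method is hand-tuned by design,
  and results are sensitive to r in particular.
* Batch composition changes calls; with `input` order the pipeline is
  fully deterministic, but a different gene order is a different
  experiment. Use the shuffle mode with several seeds to gauge this.
* The std stage inherits the mean stage's compact clusters: a gene both
  mean- and variance-shifted is reported once, as a mean-stage call.
* Calls carry no effect sizes or significance measures; downstream
  comparison to statistical methods is by set overlap
  (`compare_sets`), with those methods' gene lists supplied as files.
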