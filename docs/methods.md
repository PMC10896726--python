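# Methods

Mathematical definitions of every analysis stage in `senmetflux`. Notation:
a data matrix \(X\) has features (metabolite peaks or genes) in rows and
samples in columns; samples carry a *batch* (senescence inducer), a
*timepoint* in days, a *replicate* index, and a *role* (`sample` or pooled
`qc`). A *sample identity* is the triple (timepoint, replicate, role); the
same identity recurs once per batch.

## 1. Synthetic study generator (`senmetflux.synthetic`)

The generator plants structure that the downstream stages are designed to
recover, and returns the complete ground truth.

**Temporal modules.** Each molecular layer gets \(M\) modules (default 5).
A module \(m\) in batch \(b\) has a base trajectory
\(f_{m,b}(t)\) drawn from a library of monotone and non-monotone shapes
(linear, logistic, transient pulse, biphasic), scaled by a random amplitude
(default magnitude 1.5, random sign) and anchored in a per-module day-0
band so module starting levels are stable across batches but diverse across
modules. A member feature \(i\) follows its module with a private
distortion and i.i.d. Gaussian noise (s.d. 0.2):

\[ z_{i,b}(t, r) = a_i\, f_{m(i),b}(t) + \varepsilon_{i,b,t,r}. \]

Module trajectories are rejection-sampled and greedily refined so that
distinct modules stay decorrelated (concatenated-profile \(|r|\) below a
separation threshold, default 0.3 for metabolite–metabolite pairs) while
each hub metabolite and its partner genes share a trajectory tightly enough
that the planted edges survive the downstream \(|\rho|>0.5\)-in-all-batches
selection with high probability.

**Hubs.** Two designated hub metabolites each share their trajectory with
30 partner genes, forming the bipartite stars the network stage should
rank on top.

**Intensities and batch effects.** Standardised levels are mapped to raw
intensities via a lognormal model,
\(x = 2^{\,\mu_i + \sigma_i z}\) with per-feature location
\(\mu_i \sim \mathcal N(\mu_0, s_\mu^2)\) (default \(s_\mu = 2\)). Batch
effects are purely multiplicative per (feature, batch) factors
\(g_{i,b} = 2^{\delta_{i,b}}\), \(\delta_{i,b}\sim\mathcal N(0,\sigma_g^2)\),
applied by `inject_batch_effects` on the raw scale and recorded in the
ground truth. Each batch also carries pooled-QC injections (the per-feature
mean of the batch's biological samples plus small technical noise, times the
same batch factor).

## 2. Differential calling (`senmetflux.differential`)

**Preprocessing.** Raw intensities are \(\log_2(x+1)\)-transformed. Genes
in the bottom 40 % of mean expression are removed before testing
(`low_expression_filter`). Replicates are collapsed by the median per
(batch, timepoint) for profile-level analyses (`collapse_replicates_median`).

**Per-batch ANOVA.** Within each batch, every feature is tested by one-way
ANOVA across timepoint groups (replicates as group members;
`scipy.stats.f_oneway` semantics). Groups with fewer than two finite values
and QC samples are excluded. Benjamini–Hochberg q-values are computed per
batch and modality:

\[ q_{(i)} = \min_{j \ge i} \; \frac{m\, p_{(j)}}{j}. \]

**Selection.** A feature is called differential in a batch when
\(q < 0.05\); genes must additionally pass a \(|\log_2\) fold change\(|
\ge \log_2 1.5\) gate between the extreme timepoints (computed on the log
scale).

**Metabolite-ratio (SAMS-style) fold changes.** For a ratio pair
(numerator \(A\), denominator \(B\)) in one batch the statistic is the
end-vs-start fold change on replicate means,

\[ \mathrm{FC} = \frac{\bar A_{\mathrm{end}} / \bar B_{\mathrm{end}}}
                     {\bar A_{\mathrm{start}} / \bar B_{\mathrm{start}}}, \]

with a two-sided one-sample t-test of the per-replicate end/start ratios
against 1. Computed on raw-scale levels; a `reference_timepoint` can
replace the course start when the earliest day is not proliferative.

## 3. Batch correction (`senmetflux.batch_correction`)

### Reference scaling (Eq. 1)

For peak \(i\), batch \(b\), sample \(s\):

\[ x^{\mathrm{corr}}_{i,s} \;=\; x_{i,s} \cdot \frac{R_i}{C_{i,b}}, \]

where \(R_i\) is the grand average of peak \(i\) over all samples and
\(C_{i,b}\) the average over the batch's *reference* samples. Three
reference schemes are provided: pooled **QC** injections, **baseline**
(day-0 samples), and **batch mean** (all samples of the batch).

If batch effects are purely multiplicative,
\(x_{i,s} = g_{i,b(s)}\, x^{\mathrm{true}}_{i,s}\), then
\(C_{i,b} = g_{i,b}\, C^{\mathrm{true}}_{i,b}\) and the factor \(g_{i,b}\)
cancels exactly: all batches are mapped onto the common reference
\(R_i / C^{\mathrm{true}}_{i,b}\)-scaled level, up to a per-feature global
constant (because \(R_i\) is itself computed from the corrupted data).
Any cross-batch metric that compares a peak with itself (r.s.d.,
repeatability) is therefore restored exactly; this is the worked-example
oracle \(\{1,3\},\{3,9\} \mapsto \{2,6\},\{2,6\}\).
Peaks with a zero or all-missing reference average in some batch are set to
missing for that batch and reported by a warning.

### Quantile normalisation

Every sample column is mapped onto the mean order-statistic distribution
(ties receive the average of their assigned quantiles). This equalises
marginals but cannot undo per-(peak, batch) factors, which the benchmark
is designed to expose.

### Empirical-Bayes location/scale adjustment

On the log scale, feature \(i\) in batch \(b\) is modelled as
\(x = \alpha_i + \gamma_{i,b} + \delta_{i,b}\,\varepsilon\) with additive
batch shifts \(\gamma_{i,b}\sim\mathcal N(\bar\gamma_b, \tau_b^2)\) and
multiplicative scale factors \(\delta_{i,b}^2\sim\) inverse-gamma. Batch
priors are estimated by moment matching, posteriors by the standard
iterative parametric EB update, and the adjusted value is

\[ x^{\mathrm{corr}} = \frac{x - \hat\alpha_i - \gamma^*_{i,b}}{\delta^*_{i,b}}
   + \hat\alpha_i. \]

With one batch the map is the identity up to numerical tolerance. Because
of shrinkage the adjustment removes batch mean separation almost, not
exactly, completely.

### Benchmark metrics

* **r.s.d.** — for each (peak, sample identity), the relative standard
  deviation across batches, \(\mathrm{sd}_{n-1}/\mathrm{mean}\); summarised
  by the median. Lower is better. Oracle: values \(\{1,2,3\}\) give
  \(1/2\).
* **Repeatability** — per peak,
  \(\sigma^2_{\mathrm{between}} / (\sigma^2_{\mathrm{between}} +
  \sigma^2_{\mathrm{within}})\), where between is the variance of
  per-identity means and within the mean of per-identity variances across
  batches. Higher is better (1 = batches agree perfectly within each
  identity). Oracles: \(\{\{1,1\},\{3,3\}\}\to 1\),
  \(\{\{0,2\},\{1,3\}\}\to 0.2\).
* **Bhattacharyya distance** — batches are embedded in PCA space of the
  sample profiles; each batch contributes a Gaussian \((\mu_b, \Sigma_b)\),
  and for each pair

  \[ D_B = \tfrac18 (\mu_1-\mu_2)^\top \bar\Sigma^{-1} (\mu_1-\mu_2)
         + \tfrac12 \ln \frac{\det\bar\Sigma}
                           {\sqrt{\det\Sigma_1 \det\Sigma_2}},
     \qquad \bar\Sigma = \tfrac{\Sigma_1+\Sigma_2}2 . \]

  Identical distributions give 0; two 1-D unit-variance Gaussians with
  \(\Delta\mu = 2\) give \(1/2\). An `as_printed` variant drops the square
  root in the determinant term (subtracting
  \(\tfrac14\ln\det\Sigma_1\det\Sigma_2\)), matching a formula variant
  found in the applied literature; the default is the standard form.
  A small ridge stabilises near-singular covariances.

`benchmark_methods` scores uncorrected data, the three reference schemes,
quantile normalisation and the EB adjustment on all three metrics (EB is
scored after mapping back to a common scale), records per-method failures
instead of aborting, and ranks methods per metric.

## 4. Module detection (`senmetflux.coexpression`)

Performed on replicate-median-collapsed, batch-corrected log profiles,
concatenated across batches (default \(4 \times 6 = 24\) columns).

1. **Soft threshold.** Candidate powers \(\beta \in \{1,\dots,20\}\) are
   scored by the signed scale-free fit: connectivities
   \(k_i = \sum_{j\ne i} |r_{ij}|^\beta\) are binned (10 log-spaced bins)
   and \(\log p(k)\) regressed on \(\log k\); the score is \(R^2\) signed
   negative when the slope is positive (an increasing degree distribution is
   not scale-free no matter the fit). The lowest power with score ≥ 0.8 is
   chosen; if none qualifies, a sample-count fallback is used
   (< 20 samples → 9, < 30 → 8, < 40 → 7, else 6) with a warning — the
   expected path for short concatenated time courses.
2. **Topological overlap.** Unsigned adjacency \(a_{ij} = |r_{ij}|^\beta\);

   \[ \mathrm{TOM}_{ij} = \frac{\sum_u a_{iu} a_{uj} + a_{ij}}
        {\min(k_i, k_j) + 1 - a_{ij}}, \qquad d_{ij} = 1 - \mathrm{TOM}_{ij}. \]

3. **Clustering.** Average-linkage hierarchical clustering of \(d\); the
   tree is cut at a height fraction of the maximum linkage height mapped
   from the `deep_split` setting (0→0.95, 1→0.90, 2→0.85, 3→0.80, 4→0.75;
   default 3 — higher deep split, lower cut, more and smaller modules).
   Clusters below `min_size` (default 3) are left unassigned (label 0).
4. **Eigenprofiles and merging.** A module's eigenprofile is the first
   principal component of its member profiles, sign-oriented to correlate
   positively with the mean member profile. Modules whose eigenprofiles
   correlate above 0.60 are merged iteratively and the eigenprofiles
   recomputed.

**Trajectory PCA.** The collapsed profiles are decomposed by PCA of the
(batch, timepoint) sample scores, giving per-batch trajectories through
component space and the explained-variance spectrum.

## 5. Network integration (`senmetflux.integration`)

For each batch, Spearman's \(\rho\) is computed between every differential
gene and every differential metabolite over the batch's collapsed time
profile. A gene–metabolite pair is kept when \(|\rho| > 0.5\) in **all**
batches (signs may differ between batches; the criterion is on magnitude).
Surviving pairs form an undirected bipartite graph; nodes are ranked by
exact betweenness centrality (Brandes' algorithm via `networkx`,
unnormalised, with a normalised column alongside), ties broken by degree
and then node id. Hub metabolites are the top-ranked metabolite nodes.

## 6. Enrichment (`senmetflux.enrichment`)

**Over-representation (ORA).** For a query of size \(n\) drawn from a
universe of size \(N\), against a set annotated to \(K\) universe members
with overlap \(k\): upper-tail hypergeometric
\(p = P(X \ge k)\), \(X \sim \mathrm{Hypergeom}(N, K, n)\)
(oracle: \(N{=}10, K{=}5, n{=}4, k{=}4 \Rightarrow p = 5/210\)), with BH
q-values across the collection.

**Pre-ranked GSEA.** Genes are ranked by a score (default: maximal absolute
log fold change across batches, sign kept). The enrichment score is the
maximum-deviation running sum with hit increments
\(|s_g|^w / \sum_{g'\in S} |s_{g'}|^w\) (weight \(w=1\)) and uniform miss
decrements. The null is built by gene-label permutation (random member
sets of the same size, ≥ 100 permutations);
\(\mathrm{NES} = ES / \mathrm{mean}(|ES_{\mathrm{null}}|\) of matching
sign\()\) and

\[ p = \frac{\#\{\text{same-sign null } |ES^*| \ge |ES|\} + 1}
           {\#\{\text{same-sign null}\} + 1}, \]

the standard same-sign normalisation, which is uniform under a random
ranking.

## 7. Pipeline (`senmetflux.pipeline`)

`run_pipeline(RunConfig)` executes: simulate (or ingest TSVs) → inject
planted batch effects (simulation mode) → batch-mean correction →
log transform → gene low-expression filter → per-batch differential →
correction benchmark (on raw corrupted data) → metabolite modules +
trajectory PCA (on corrected collapsed profiles) → differential-restricted
gene–metabolite network → optional enrichment (when a GMT is supplied).
All outputs are TSV plus a plain-text report; `manifest.json` records a
content hash of every output, so identical configs and seeds produce
byte-identical runs.
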