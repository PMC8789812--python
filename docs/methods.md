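# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Synthetic cohorts

The generator draws a miRNA × sample count matrix from

    K_ij ~ NB( mean = s_j · q_i · 2^{β_{i,g(j)}} ,  dispersion α_i )

* `q_i` — baseline expression, log-normal (`basemean_logmu = 3`,
  `basemean_logsd = 1.6` by default). The defaults give a heavy-tailed
  expression distribution with many low-count miRNAs and a few very abundant
  ones, the qualitative shape of serum small-RNA libraries; no published
  count-distribution parameters exist for the emulated study, so these are
  realistic free choices, fixed once.
* `s_j` — depth factors, log-normal with `depth_logsd = 0.35` (about 2-fold
  spread between shallow and deep libraries), rescaled to geometric mean 1 so
  they are identifiable.
* `α_i` — NB dispersion, constant 0.15 by default or gamma-distributed.
* `β` — planted log2 group effects, specified per group as (fraction,
  |log2FC|) with signs split evenly; effects multiply group means, which is
  exactly the quantity the Wald GLM estimates.
* Default cohort composition mirrors a two-site discovery design: 61 + 77 +
  27 samples (patients / controls / centenarians), controls split 58/19
  between sites.

**Co-expression blocks** are planted through a Gaussian copula: block
members share a per-sample latent factor with correlation
`ρ_latent = 2 sin(π ρ_b / 6)` (the inverse of the bivariate-normal Spearman
formula, so `ρ_b` is a *Spearman* target), and the latent normals are pushed
through the per-entry NB quantile function. This plants rank correlation —
the dependence MI detects — without changing any NB marginal.

**What the generator does not emulate:** age/sex covariate effects on
counts, batch/plate effects, adapter or alignment artifacts, spike-in
calibration curves, and the specific expression profile of any real cohort.
A green recovery test therefore establishes that the pipeline detects the
structure it claims to detect under its own model assumptions — not that it
would reproduce any particular study's numbers.

UMI read records are the exact inverse of UMI collapse: each count unit
becomes one distinct (sequence, UMI) pair replicated `1 + Poisson(rate)`
times; UMIs encode a global counter in base-36, so collisions are impossible
and the round trip is an identity at any duplication rate.

## Preprocessing

* Expressed filter: UMI count > 0 in at least one sample (idempotent).
* Size factors: median-of-ratios. Rows containing any zero are excluded from
  the geometric-mean reference (standard convention); a pseudo-reference
  over positive entries is available (`pseudo_reference=True`) for sparse
  matrices and is used automatically by `build_network` on small cohorts.
  Note the exact scaling identity is *relative*: scaling one column by c
  multiplies its factor by c relative to the others, while all normalized
  values shift by a common constant (the reference itself moves).
* Spike-in rows (id prefix `spikein-`) are ordinary rows excluded from
  size-factor estimation.
* PCA QC runs on `log2(normalized + 1)` over the most variable rows. This
  replaces a variance-stabilizing transform and is diagnostic only — it
  feeds no downstream inference.

## Differential expression

Per miRNA, a two-group NB GLM (log link, log size-factor offset) is fitted
by vectorized IRLS at fixed dispersion; `log2FC = β̂/ln 2`, Wald
`z = β̂/se`, two-sided normal p. Dispersion is the method-of-moments
estimate `α̂ = max((pooled within-group variance − mean)/mean², 10⁻⁸)` on
normalized counts, pooled within groups so planted effects do not inflate
it, re-estimated per contrast after site restriction.

Deliberate simplifications relative to full DESeq2-style machinery: no
dispersion shrinkage toward a trend, no independent filtering, no outlier
refitting, no log2FC shrinkage. The tests assert what this buys: type-I
error within [0.03, 0.07] at nominal 0.05, near-uniform null p (KS < 0.05 at
5000 null miRNAs, n = 30/group), |bias| < 0.1 on planted |log2FC| = 1, and
empirical FDR ≤ 1.5× nominal on mixed simulations. Rows with a runaway
coefficient (|β̂| > 20 in natural log, i.e. a group with all-zero counts)
are flagged non-converged and report missing p. BH adjustment excludes
missing p from the denominator. DEM calling is strict: `padj < 0.05`.

Normalization is pooled across all samples by default, with a per-contrast
option (`pooled_normalization=False`); the emulated workflow does not state
which was used.

## Candidate selection

Exclusive intersections partition the DEM union (asserted). Intersection
significance is a declared convention — the null draws independent uniform
random sets of the observed sizes from the expressed-miRNA universe and
counts how often the exclusive intersection reaches the observed size
(add-one Monte-Carlo p). For two sets this tail coincides with the
hypergeometric, which the tests cross-check. Selection rule (i) takes all
DEMs in the `top_k` most significant multi-contrast intersections; rule (ii)
takes the `n_unique` smallest-padj DEMs exclusive to each contrast, ties
broken by |log2FC| then id. Both rules apply an average-expression floor
(default 5 normalized counts — a qPCR detectability bound), computed as the
mean baseMean over the contrasts where the miRNA is a DEM. Literature-driven
candidates enter via an explicit `manual` list, never inferred.

## Network inference

MI is computed on `log2(normalized + 1)` profiles after a normal-scores
(empirical copula) transform, in nats.

* **Dithering.** Ranks are tied heavily at zero for low-count miRNAs;
  averaged tied ranks form atoms that a kernel density estimator reads as
  spurious dependence (inflating permutation thresholds and destroying block
  recovery on some datasets). Ties are therefore broken uniformly at random
  with the stage seed. This is standard for copula estimators on discrete
  data and is the single most consequential numerical choice in the module.
* **Kernel estimator.** Leave-one-out Gaussian KDE at the sample points;
  the joint density uses bandwidth matrix `h²Σ̂` with `h = n^{−1/6}`
  (Silverman's d = 2 scale) and `Σ̂` the sample covariance of the scores,
  keeping the kernel matched to the density's orientation at high
  dependence; marginals use the same scalar `h`. Leave-one-out removes the
  self-term bias, so independent profiles estimate ≈ 0. Against the
  bivariate-Gaussian closed form `−½ ln(1−ρ²)` the estimator is accurate to
  ~0.03 nats at n = 2000 across ρ ∈ {0, 0.3, 0.6, 0.9}. A plain product
  kernel without covariance adaptation underestimates by up to ~0.09 nats at
  ρ = 0.9, which motivated the choice.
* **Gaussian-copula estimator.** `−½ ln(1−ρ²)` with ρ the normal-scores
  correlation; exact for monotone dependence and much faster — appropriate
  for large node sets.
* **Threshold.** The independence threshold is the (1−α) quantile (α = 0.05)
  of MI values on row-wise permuted data (10 rounds × up to 500 sampled null
  pairs); a fixed-eps mode exists for exact reproducibility. Pointwise
  calibration: on fully independent data ≈ α of pairs survive.
* **DPI.** Strict inequalities, simultaneous removal after marking all
  triangles on the original MI values; ties keep both edges; scan order is
  irrelevant by construction (asserted against a brute-force all-triangles
  oracle). τ = 0.15 throughout.

Constant profiles get MI 0 with a warning. MI symmetry and non-negativity
are asserted on every matrix.

## Communities

Louvain optimization is delegated to networkx (`louvain_communities`) with
the MI weights, resolution γ = 1 and a seed-fixed visiting order; because
the greedy optimizer occasionally stalls in a merged local optimum, 8
seed-derived restarts are run and the highest-modularity partition kept
(deterministic given the seed). Modularity is computed independently as
`Q = Σ_c [w_c/W − γ(s_c/2W)²]` and cross-checked against networkx; an
edgeless graph has Q = 0 by convention. Degree quartile labels use
linear-interpolation quantiles within the node's own community, with strict
`>` against Q3 for "above the upper quartile" and strict `<` against the
median for "below median". DEM–community integration reports the
maximum-overlap community per DEM set (ties: smaller community, then lower
id) plus a hypergeometric enrichment p as supplementary output (universe =
network nodes). Degrees are computed on the post-DPI network — the pruned
matrix is "the" adjacency matrix of the analysis.

## qPCR (comparative Ct)

Technical replicates are averaged (flagged when their range exceeds 0.5
cycles). Controls are summarized by the arithmetic mean of their Ct — the
geometric mean of expression, the vendor convention. ΔΔCt contrasts group
means of per-sample ΔCt; `RQ = 2^{−ΔΔCt}` assumes amplification efficiency
2 exactly (no efficiency correction). Group tests are Student's t on ΔCt
(Welch behind `equal_var=False`), BH-corrected across targets within a
comparison; the significance flag requires both `RQ > 2 or RQ < 0.5` and
`padj < 0.05` — a magnitude gate that deliberately rejects statistically
clear but modest fold-changes. The exogenous spike-in is a per-sample QC
gate (|Ct − mean| > 2 SD), never a normalizer. Normalizer ranking orders
candidates by cross-sample Ct SD, then by distance from the preferred assay
range midpoint (default 25 cycles).

## Enrichment

All over-representation is one-sided hypergeometric with BH correction. The
universe is always the supplied table (distinct miRNAs for target
enrichment, the supplied gene universe for gene sets); web tools' internal
universes are not reproducible and are out of scope. Evidence labels are
normalized case-insensitively onto {strong, weak, non-functional}. Reported
target-enrichment hits additionally require ≥ 2 supporting interactions and
default to strong evidence only. The miRNA-augmented-pathway product is a
plain (pathway, gene, repressing miRNA) table — the informational content of
an augmented-pathway diagram without the drawing.

## Pipeline

Stage order: preprocessing → differential expression → selection → network
(per configured phenotype) → communities → integration; validation is a
separate entry point over a Ct table. Every artifact TSV carries a header
comment with tool version, seed and parameter hash; `manifest.json` records
stage order, checksums (content only, so re-runs are comparable) and
accumulated warnings. Failures abort with the stage name; input validation
happens before any output is written.

## Limitations

* The DE module is a calibrated approximation, not a reimplementation, of
  shrinkage-based count GLM packages; on real, small-n, trend-dispersed data
  those will differ.
* Kernel MI costs O(p²n²); for thousands of nodes use the Gaussian-copula
  estimator.
* Community counts and degree values depend on estimator, threshold and
  cohort; no attempt is made to reproduce any specific study's network
  statistics, which are not recoverable without the original data and tool
  internals.
* Covariate adjustment (age, sex), batch correction and consensus/bootstrap
  networks are out of scope.
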