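# Methods

## Scientific setting

The package analyzes rhizosphere bacterial communities sampled from
*Arabidopsis thaliana* hosts that differ in genetic background
(Columbia vs Landsberg erecta) and ploidy (diploid 2x vs
whole-genome-duplicated 4x), plus unplanted soil controls, and a
follow-up inoculation experiment in which plants of each genotype grow
in substrate inoculated with microbiomes conditioned by each genotype.
Inputs are an ASV count table (samples × taxa integer reads), a
taxonomy table, sample metadata, and a phenotype table.  All analyses
start at the count table; read QC, ASV inference, and taxonomy
assignment are upstream of this package.

## Dirichlet-multinomial differential abundance

### Model

For replicate $j$ in sampling group $g$ with depth $N_j$:

$$x_j \mid p_j \sim \mathrm{Multinomial}(N_j, p_j), \qquad
  p_j \mid \pi_g, \theta_g \sim \mathrm{Dirichlet}(\theta_g \pi_g).$$

$\pi_g$ is the expected relative-abundance vector of group $g$ (the
inferential target) and $\theta_g > 0$ the intensity: replicate
compositions scatter around $\pi_g$ with variance
$\pi_i(1-\pi_i)/(\theta_g+1)$ per taxon, so small $\theta$ means
strong replicate-to-replicate overdispersion and $\theta \to \infty$
recovers the plain multinomial.  The replicate-level $p_j$ is
integrated out analytically, leaving the Dirichlet-multinomial
compound likelihood with parameter vector $\theta_g \pi_g$.  The
marginal posterior of $(\pi_g, \theta_g)$ is identical to the
latent-$p$ formulation, but the collapsed sampler mixes far better
when the number of taxa runs into the hundreds.

Model features that matter in practice: proportions are estimated from
all replicates in a group (no rarefaction, unequal depths enter the
likelihood as-is); the composition is modeled as a whole rather than
taxon-by-taxon; and uncertainty propagates into every downstream
summary, so no separate multiple-testing correction is applied.

### Priors

- $\pi_g \sim \mathrm{Dirichlet}(c\,\mathbf{1})$ with $c = 1$ (flat on
  the simplex).  Configurable (`prior_concentration`).
- $\theta_g \sim \mathrm{half\text{-}Cauchy}(0, s)$ with $s = 1000$
  (`theta_prior_scale`) — the standard weakly-informative heavy-tailed
  choice for a scale-like parameter.  A Cauchy prior placed on
  $\log\theta$ instead was found to let $\theta$ wander into an
  essentially unbounded flat-likelihood tail when replication is low;
  the half-Cauchy's $\theta^{-2}$ tail keeps the posterior proper and
  well-behaved while remaining diffuse over the plausible range
  ($\theta \approx 10$–$10^4$).

Each group carries its own $\theta_g$.  The groups are then a-priori
independent, which makes the two-group models exactly separable; the
original analysis fit separate models per contrast and does not state
whether intensity was shared, so this is our interpretation, chosen
because it permits the $O(\text{replicates})$ coordinate updates
described next.

### Sampler

Adaptive random-walk Metropolis-within-Gibbs on the unconstrained
vector $y_g = \log(\theta_g \pi_g) = \log \alpha_g$ (with the matching
change-of-variable Jacobian; $\theta_g = \sum_i \alpha_{gi}$).  Each
sweep performs $K$ single-coordinate updates — the likelihood delta
for one coordinate costs $O(\text{replicates})$ because only one
$\alpha_i$ and the total $\theta$ change — plus one global scale move
that translates the whole $y_g$ vector (updating $\theta_g$ with
$\pi_g$ fixed), which decorrelates the overall scale.  Proposal
standard deviations adapt toward 44% acceptance (the 1-D optimum) by
Robbins-Monro during burn-in only, so retained draws form a valid
Markov chain.  The kernel is JIT-compiled with numba when available
and runs identically (slower) in pure Python otherwise; all random
inputs are pre-generated from named, seeded substreams, so runs are
bit-reproducible for a given seed and settings.

Defaults mirror the original analysis: 4 chains × (1,500 burn-in +
1,000 retained) = 4,000 posterior draws of the focal parameters.
Initialization is at empirical group proportions (jittered per chain,
$\theta_0 = 100$), and convergence is monitored with the classic
Gelman-Rubin potential scale reduction on the unconstrained scale
($\hat R = \sqrt{((n-1)/n \cdot W + B/n)/W}$, whole chains).

### Decision rule and fold changes

For each taxon $i$ and contrast $(g_1, g_2)$ the posterior of
$\Delta_i = \pi_{i,g_1} - \pi_{i,g_2}$ is formed from chain-pooled
draws; taxon $i$ is flagged when at least 95% of that mass lies
strictly on one side of zero (boundary counts as flagged; ties at
exactly zero count for neither side).  Log10 fold changes are
posterior summaries of $\log_{10}(\pi_{i,g_1}/\pi_{i,g_2})$.  The
three standard contrasts are fitted as separate two-group models with
pooled membership: 2x vs 4x, Col vs Ler, and Col-4x vs the other
three groups; soil controls are always excluded.

A property of this rule worth knowing (quantified by the calibration
simulations in the test suite and acceptance script): flagging at 95%
one-sided mass is a *two*-sided criterion at roughly
$|\text{mean}| > 1.645\,\text{SD}$, so under a true null its
false-flag rate is near 10% per contrast, pulled a little lower
(measured ≈ 8–9% at the emulated design) by prior shrinkage on rare
taxa.  Users wanting a ≈5% null rate should require the 95%
equal-tailed interval to exclude zero instead (97.5% one-sided mass),
which `compare_groups(level=0.975)` provides.

## Community statistics

- **Bray-Curtis** on raw counts ($\sum_i |u_i - v_i| / \sum_i (u_i +
  v_i)$, the adonis convention) and **Jaccard** on presence/absence as
  a true set dissimilarity, both via scipy's pdist.
- **PERMANOVA** (one factor): McArdle-Anderson decomposition of
  squared dissimilarities, $F = (SS_b/(k-1))/(SS_w/(n-k))$; the
  p-value permutes labels — exactly, over all distinct assignments,
  when their number is ≤ 10,000 (p = fraction with $F \ge F_{obs}$,
  identity included), else Monte Carlo with
  $p = (1 + \#\{F^\ast \ge F\})/(1 + n_{perm})$, default
  $n_{perm} = 999$.  Contrasts mirror the study table: plant vs soil
  (controls included), genotype, ploidy, and the post hoc Col-4x vs
  all others, each on both metrics; distance matrices are always
  computed after subsetting to the samples in the contrast.
- **PCoA**: eigendecomposition of the Gower-centered matrix; negative
  eigenvalues are reported, never silently corrected; coordinates use
  positive eigenvalues only.
- **Shannon** $H = -\sum p_i \ln p_i$ (natural log, zero-count taxa
  ignored) and **Welch's t** with Welch-Satterthwaite df for diversity
  contrasts.

## Phenotype analysis

Fixed-effect main-effects ANOVA (inoculum + genotype + block,
sequential SS in that order; sequential = marginal on balanced data —
tested).  No interactions by default, since the analysis names exactly
three explanatory variables; the genotype × inoculum interaction is
available behind a flag.  Display values are residuals after
regressing out genotype and block, averaged by inoculum.  Tukey HSD
compares inoculum level means using the full-model residual mean
square and df (Tukey-Kramer form for unequal sizes) with
studentized-range adjusted p-values and a greedy compact letter
display.  Planned contrasts (Col-2x vs Col-4x and Ler-2x vs Ler-4x
inocula) are single-df t tests on the full-model residual variance,
unadjusted because they are planned, not post hoc.  Missing responses
are dropped listwise per response.

## Synthetic data

The generator is the exact generative dual of the fitted likelihood:
baseline composition from a symmetric Dirichlet (concentration 0.5 by
default, giving the few-dominant/many-rare rank-abundance skew of real
16S data), group compositions derived by multiplying planted effect
taxa by a fold change and renormalizing (so every planted effect has a
closed-form true log10 fold change), replicate compositions
Dirichlet($\theta_{true}\pi_g$) with $\theta_{true} = 500$ by default,
counts multinomial at depths uniform on 36,033–143,254 (the observed
range; the study reports only the range, so uniform is the
assumption-minimal choice).  Default design: 4 groups × 8 replicates +
7 soil controls; soil gets the baseline perturbed by per-taxon
log-normal fold changes (SD 0.75).  The default taxon count is the
study-scale 2,689 but every analysis here runs desk-scale
(K = 50–300).  $\theta_{true}$ is a free parameter of the emulation —
the original study reports no overdispersion estimate.

What the generator does *not* emulate: taxon-taxon correlation beyond
the compositional constraint, depth-abundance artifacts, contamination,
sample dropout, or any sequence-level process.  Passing recovery tests
therefore demonstrates internal consistency of model + inference under
the model's own assumptions, not robustness to real-data violations of
them.

Phenotypes are additive: grand mean + genotype + inoculum + block +
Gaussian noise, 4 × 4 factorial with 24 plants per cell (≈ the
biomass-harvest scale) over 4 blocks.

## Numerical choices and degenerate inputs

- Compositions are kept strictly interior by the log-$\alpha$
  parameterization; no pseudocounts are added to data.
- The Dirichlet-multinomial log-pmf includes the multinomial
  coefficient (so the pmf sums to 1; verified by enumeration).
- Probability ties at the flagging boundary count as flagged (≥); draws
  exactly at zero difference count toward neither side.
- Zero within-chain variance yields $\hat R$ = NaN with a warning;
  acceptance rates outside [0.05, 0.95] after burn-in warn.
- A constant ANOVA response reports zero sums of squares and NaN F
  with a warning; rank-deficient designs raise.
- The ">100 reads" abundance filter is strictly greater-than; the 0.05
  display filter applies per sample to ASVs *before* rank aggregation,
  so displayed rank totals may sum below 1.
- TSV orientation is declared by flag, never guessed.

## Problem sizes

Test-suite and acceptance-script simulations use K = 50 taxa for
recovery/calibration/power (20 datasets each), K = 120 for the
end-to-end experiment, K = 300 for the worked analysis under
`analysis/`, and 1,000 reduced-size null datasets (12 samples, 20
taxa, 999 permutations) for PERMANOVA calibration — sizes chosen to
keep a full run in minutes on one core while leaving every statistical
conclusion stable across seeds.

## Known limitations

- Single intensity per group (no taxon-specific overdispersion), no
  covariates, no phylogenetic structure, no zero-inflation.
- One-factor PERMANOVA only; all the study-style contrasts are
  two-group, so multi-factor adonis is out of scope.
- The random-walk sampler is adequate at desk scale (effective sample
  sizes ≈ 200 per chain per parameter at defaults); for K in the
  thousands a gradient-based sampler behind the same interface would
  be preferable.
- The 95% one-sided-mass decision rule's null behavior is ~8–10%
  flagged, as discussed above; this is a property of the rule, not of
  the implementation.
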