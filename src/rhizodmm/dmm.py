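"""Hierarchical Bayesian Dirichlet-multinomial differential abundance.

Model
-----
Counts for replicate j in sampling group g are multinomial with
replicate-level proportions p_j, and p_j ~ Dirichlet(theta_g * pi_g):
pi_g is the expected composition of group g and theta_g > 0 the
intensity (small theta = strong replicate-to-replicate overdispersion).
The latent p_j is integrated out analytically, giving the
Dirichlet-multinomial compound likelihood

    P(x_j | pi, theta) = C(x_j) * G(theta)/G(N_j + theta)
                         * prod_i G(x_ji + theta pi_i)/G(theta pi_i)

with G the gamma function and C the multinomial coefficient.  The
marginal posterior of (pi, theta) is identical to the latent-p
formulation but mixes far better when the number of taxa is large.

Priors: symmetric Dirichlet(concentration c, default 1) on each pi_g;
half-Cauchy on theta_g (weakly informative heavy-tailed scale prior,
default scale 1,000).

Inference is adaptive random-walk Metropolis-within-Gibbs on the
unconstrained vector y_g = log(theta_g * pi_g): single-coordinate
updates (cheap: the likelihood delta is O(replicates)) plus one global
scale move per sweep that translates the whole y_g vector (i.e. updates
theta_g with pi_g held fixed).  Proposal scales adapt toward 44%
acceptance during burn-in only, so retained draws form a valid Markov
chain.  Default run length mirrors common practice for this model
class: 4 chains x (1,500 burn-in + 1,000 retained) = 4,000 posterior
draws.

Decision rule: taxon i differs between groups when at least 95% of the
posterior mass of pi_i,g1 - pi_i,g2 lies strictly on one side of zero.
No rarefaction and no multiple-comparison correction are applied;
analyses run on proportions estimated from all replicates per group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import substream
from .tables import CountTable, SampleMetadata

try:  # optional JIT; the pure-Python kernel is identical but slower
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (len(args) == 1 and callable(args[0])) else args[0]


DEFAULT_THETA_PRIOR_SCALE = 1000.0


@dataclass
class DMMSettings:
    """MCMC configuration for the Dirichlet-multinomial model."""

    chains: int = 4
    burn_in: int = 1500
    draws: int = 1000
    seed: int = 0
    credible_level: float = 0.95
    prior_concentration: float = 1.0
    theta_prior_scale: float = DEFAULT_THETA_PRIOR_SCALE
    init_coord_step: float = 0.5
    init_scale_step: float = 0.3
    theta_init: float = 100.0

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible level must be in (0, 1)")


@dataclass
class DMMPosterior:
    """Retained posterior draws for one fitted model.

    ``pi`` has shape (chains, draws, groups, taxa) with every draw a
    composition; ``theta`` has shape (chains, draws, groups) and is
    strictly positive.  Replicate-level compositions are marginalized
    analytically and therefore have no stored draws.
    """

    pi: np.ndarray
    theta: np.ndarray
    group_names: list
    taxon_ids: list
    acceptance: dict
    settings: DMMSettings

    @property
    def n_draws(self) -> int:
        """Total retained draws (chains x draws per chain)."""
        return self.pi.shape[0] * self.pi.shape[1]

    def _gidx(self, group: str) -> int:
        try:
            return self.group_names.index(group)
        except ValueError:
            raise KeyError(f"group {group!r} not in posterior {self.group_names}") from None

    def pooled_pi(self, group: str) -> np.ndarray:
        """Draws of pi for one group, pooled across chains: (chains*draws, K)."""
        g = self._gidx(group)
        return self.pi[:, :, g, :].reshape(-1, self.pi.shape[-1])

    def pooled_theta(self, group: str) -> np.ndarray:
        g = self._gidx(group)
        return self.theta[:, :, g].reshape(-1)

    def posterior_mean_pi(self, group: str) -> pd.Series:
        return pd.Series(self.pooled_pi(group).mean(axis=0), index=self.taxon_ids)


@dataclass
class DifferentialAbundanceResult:
    """Per-taxon posterior comparison of two groups.

    ``table`` columns: posterior mean of pi in each group, mean and
    equal-tailed interval of the difference, Pr(pi_g1 > pi_g2), the
    credible flag, direction, and posterior log10 fold-change summary.
    """

    table: pd.DataFrame
    g1: str
    g2: str
    level: float
    posterior: DMMPosterior = field(default=None, repr=False)

    @property
    def flagged(self) -> pd.Series:
        return self.table["flagged"]

    @property
    def n_flagged(self) -> int:
        return int(self.table["flagged"].sum())

    def flagged_taxa(self) -> list:
        return list(self.table.index[self.table["flagged"]])


# ---------------------------------------------------------------------------
# likelihood and posterior density


def dm_log_likelihood(counts, pi, theta, include_coefficient: bool = True):
    """Dirichlet-multinomial log-pmf of count vector(s) given (pi, theta).

    ``counts`` may be one count vector (returns a scalar) or a
    replicates x taxa matrix (returns one value per row).  ``pi`` must
    be strictly positive and sum to 1; the multinomial coefficient is
    included by default so the pmf sums to 1 over count vectors of a
    fixed depth.
    """
    x = np.atleast_2d(np.asarray(counts, dtype=float))
    pi = np.asarray(pi, dtype=float)
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if np.any(pi <= 0):
        raise ValueError("pi must be strictly positive (interior of the simplex)")
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("pi must sum to 1")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    alpha = theta * pi
    n = x.sum(axis=1)
    ll = gammaln(theta) - gammaln(n + theta)
    ll += (gammaln(x + alpha) - gammaln(alpha)).sum(axis=1)
    if include_coefficient:
        ll += gammaln(n + 1) - gammaln(x + 1).sum(axis=1)
    out = ll if np.ndim(counts) == 2 else float(ll[0])
    return out


def _half_cauchy_logpdf(theta: float, scale: float) -> float:
    z = theta / scale
    if z > 1e150:  # avoid overflow in z*z; tail is -2 log z
        return math.log(2.0 / (math.pi * scale)) - 2.0 * math.log(z)
    return math.log(2.0 / (math.pi * scale)) - math.log1p(z * z)


def _log_prior(pi, theta, concentration, scale):
    pi = np.asarray(pi, dtype=float)
    K = pi.size
    lp = gammaln(K * concentration) - K * gammaln(concentration)
    lp += (concentration - 1.0) * np.log(pi).sum()
    lp += _half_cauchy_logpdf(theta, scale)
    return lp


def log_posterior(pi_by_group, theta_by_group, counts_by_group,
                  settings: DMMSettings = None) -> float:
    """Unnormalized log posterior density over (pi_g, theta_g) per group.

    Groups are conditionally independent, so the result is the sum over
    groups of the Dirichlet-multinomial likelihood of that group's
    replicates plus the log priors.  This is the density the sampler
    targets (it works on log(theta*pi) internally with the matching
    change-of-variable Jacobian).  Raises if any component is
    non-finite.
    """
    settings = settings or DMMSettings()
    total = 0.0
    for g, pi in pi_by_group.items():
        theta = float(theta_by_group[g])
        X = np.atleast_2d(np.asarray(counts_by_group[g], dtype=float))
        if X.shape[0]:
            ll = float(np.sum(dm_log_likelihood(X, pi, theta)))
        else:
            ll = 0.0
        lp = _log_prior(pi, theta, settings.prior_concentration,
                        settings.theta_prior_scale)
        for name, value in (("likelihood", ll), ("prior", lp)):
            if not math.isfinite(value):
                raise ValueError(f"non-finite {name} term for group {g!r}")
        total += ll + lp
    return total


# ---------------------------------------------------------------------------
# sampler kernel


@njit(cache=True)
def _half_cauchy_kernel(theta, scale):
    z = theta / scale
    if z > 1e150:
        return math.log(2.0 / (math.pi * scale)) - 2.0 * math.log(z)
    return math.log(2.0 / (math.pi * scale)) - math.log1p(z * z)


@njit(cache=True)
def _chain_kernel(X, N, y, step, sstep, total, burn, normals, uniforms,
                  conc, scale, pi_out, theta_out):
    """One MCMC chain on y = log(theta*pi) for a single group.

    Per sweep: K single-coordinate Metropolis updates (likelihood delta
    in O(replicates)) then one global scale move.  ``step`` (per
    coordinate) and ``sstep`` (scale move, length-1 array) adapt toward
    0.44 acceptance during burn-in and are frozen afterwards.  Returns
    (accepted, proposed) counts over the retained phase.
    """
    n, K = X.shape
    alpha = np.exp(y)
    A = alpha.sum()
    acc_post = 0
    prop_post = 0
    for t in range(total):
        gain = (t + 1.0) ** -0.6
        adapting = t < burn
        for i in range(K):
            a = alpha[i]
            dy = step[i] * normals[t, i]
            ynew = y[i] + dy
            anew = math.exp(ynew)
            Anew = A - a + anew
            L = math.log(A)
            Lnew = math.log(Anew)
            d = n * (math.lgamma(Anew) - math.lgamma(A))
            d -= n * (math.lgamma(anew) - math.lgamma(a))
            for j in range(n):
                d += math.lgamma(X[j, i] + anew) - math.lgamma(X[j, i] + a)
                d -= math.lgamma(N[j] + Anew) - math.lgamma(N[j] + A)
            d += _half_cauchy_kernel(Anew, scale) - _half_cauchy_kernel(A, scale)
            d += -(K - 1.0) * (Lnew - L) + (conc - 1.0) * (dy - K * (Lnew - L)) + dy
            accept = math.log(uniforms[t, i]) < d
            if accept:
                y[i] = ynew
                alpha[i] = anew
                A = Anew
            if adapting:
                if accept:
                    step[i] *= math.exp(gain * 0.56)
                else:
                    step[i] *= math.exp(-gain * 0.44)
            else:
                prop_post += 1
                if accept:
                    acc_post += 1
        # global scale move: theta changes, pi fixed
        eps = sstep[0] * normals[t, K]
        ratio = math.exp(eps)
        Anew = A * ratio
        d = n * (math.lgamma(Anew) - math.lgamma(A))
        for j in range(n):
            d -= math.lgamma(N[j] + Anew) - math.lgamma(N[j] + A)
        for i in range(K):
            ai = alpha[i]
            ainew = ai * ratio
            d -= n * (math.lgamma(ainew) - math.lgamma(ai))
            for j in range(n):
                d += math.lgamma(X[j, i] + ainew) - math.lgamma(X[j, i] + ai)
        d += _half_cauchy_kernel(Anew, scale) - _half_cauchy_kernel(A, scale) + eps
        accept = math.log(uniforms[t, K]) < d
        if accept:
            for i in range(K):
                y[i] += eps
                alpha[i] *= ratio
            A = Anew
        if adapting:
            if accept:
                sstep[0] *= math.exp(gain * 0.56)
            else:
                sstep[0] *= math.exp(-gain * 0.44)
        else:
            prop_post += 1
            if accept:
                acc_post += 1
        if t >= burn:
            k = t - burn
            for i in range(K):
                pi_out[k, i] = alpha[i] / A
            theta_out[k] = A
    return acc_post, prop_post


def _fit_one_group(X: np.ndarray, settings: DMMSettings, rng: np.random.Generator):
    """Run all chains for one group; returns (pi_draws, theta_draws, accept)."""
    n, K = X.shape
    N = X.sum(axis=1)
    total = settings.burn_in + settings.draws
    # empirical-proportion initialization, jittered per chain
    pbar = ((X + 0.5).sum(axis=0)) / ((X + 0.5).sum())
    base_y = np.log(settings.theta_init * pbar)
    pi_draws = np.empty((settings.chains, settings.draws, K))
    theta_draws = np.empty((settings.chains, settings.draws))
    rates = []
    for c in range(settings.chains):
        y = base_y + rng.normal(0.0, 0.5, K)
        pi0 = np.exp(y)
        theta0 = pi0.sum()
        lp0 = log_posterior({"g": pi0 / theta0}, {"g": theta0}, {"g": X}, settings)
        if not math.isfinite(lp0):  # pragma: no cover - guarded in log_posterior
            raise ValueError("non-finite posterior density at initialization")
        normals = rng.standard_normal((total, K + 1))
        uniforms = rng.random((total, K + 1))
        step = np.full(K, settings.init_coord_step)
        sstep = np.array([settings.init_scale_step])
        acc, prop = _chain_kernel(
            np.ascontiguousarray(X, dtype=np.float64), N.astype(np.float64), y,
            step, sstep, total, settings.burn_in, normals, uniforms,
            settings.prior_concentration, settings.theta_prior_scale,
            pi_draws[c], theta_draws[c],
        )
        rates.append(acc / max(prop, 1))
    rate = float(np.mean(rates))
    if not 0.05 <= rate <= 0.95:
        warnings.warn(f"post-burn-in acceptance rate {rate:.3f} outside [0.05, 0.95]")
    return pi_draws, theta_draws, rate


def fit_dmm(ct: CountTable, groups, settings: DMMSettings = None) -> DMMPosterior:
    """Fit the Dirichlet-multinomial model to a count table.

    Parameters
    ----------
    ct : CountTable
    groups : mapping or pandas.Series
        sample id -> group label; samples absent from the mapping are
        excluded from the fit.
    settings : DMMSettings

    Returns
    -------
    DMMPosterior with chains x draws retained draws of (pi_g, theta_g)
    per group.  Deterministic given the settings seed.
    """
    settings = settings or DMMSettings()
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    samples = [s for s in ct.sample_ids if s in groups.index and pd.notna(groups.loc[s])]
    if not samples:
        raise ValueError("no samples covered by the group mapping")
    labels = groups.loc[samples]
    group_names = list(dict.fromkeys(labels))
    counts = ct.data.loc[samples]
    K = counts.shape[1]
    pi = np.empty((settings.chains, settings.draws, len(group_names), K))
    theta = np.empty((settings.chains, settings.draws, len(group_names)))
    acceptance = {}
    for g_idx, g in enumerate(group_names):
        X = counts.loc[labels[labels == g].index].to_numpy(dtype=np.float64)
        if X.shape[0] < 1:  # pragma: no cover
            raise ValueError(f"group {g!r} has no replicates")
        rng = substream(settings.seed, f"dmm:{g}")
        pi_g, theta_g, rate = _fit_one_group(X, settings, rng)
        pi[:, :, g_idx, :] = pi_g
        theta[:, :, g_idx] = theta_g
        acceptance[g] = rate
    return DMMPosterior(pi, theta, group_names, ct.taxon_ids, acceptance, settings)


# ---------------------------------------------------------------------------
# diagnostics and comparisons


def gelman_rubin(post: DMMPosterior) -> pd.Series:
    """Potential scale reduction factor per scalar parameter.

    Computed on the unconstrained scale (log(theta*pi) per taxon and
    log theta per group) with the classic formula
    R-hat = sqrt(((n-1)/n * W + B/n) / W) over whole chains.  Zero
    within-chain variance yields NaN with a warning.
    """
    chains, n, G, K = post.pi.shape
    if chains < 2 or n < 2:
        raise ValueError("need >= 2 chains and >= 2 draws per chain")
    names, series = [], []
    log_alpha = np.log(post.pi * post.theta[..., None])
    for g_idx, g in enumerate(post.group_names):
        for i, taxon in enumerate(post.taxon_ids):
            names.append(f"log_alpha[{g}][{taxon}]")
            series.append(log_alpha[:, :, g_idx, i])
        names.append(f"log_theta[{g}]")
        series.append(np.log(post.theta[:, :, g_idx]))
    values = []
    degenerate = False
    for draws in series:
        W = draws.var(axis=1, ddof=1).mean()
        if W == 0.0 or np.ptp(draws) == 0.0:
            degenerate = True
            values.append(np.nan)
            continue
        B = n * draws.mean(axis=1).var(ddof=1)
        V = (n - 1) / n * W + B / n
        values.append(math.sqrt(V / W))
    if degenerate:
        warnings.warn("zero within-chain variance for some parameters; R-hat is NaN")
    return pd.Series(values, index=names, name="rhat")


def log10_fold_changes(post: DMMPosterior, g1: str, g2: str,
                       level: float = 0.95) -> pd.DataFrame:
    """Posterior summaries of log10(pi_i,g1 / pi_i,g2) per taxon.

    The ``fold`` column expresses the posterior mean on the x-fold
    scale (e.g. an 8-fold enrichment is log10 FC 0.903).
    """
    draws = np.log10(post.pooled_pi(g1) / post.pooled_pi(g2))
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    mean = draws.mean(axis=0)
    return pd.DataFrame(
        {"log10_fc_mean": mean, "log10_fc_lo": lo, "log10_fc_hi": hi,
         "fold": 10.0 ** mean},
        index=pd.Index(post.taxon_ids, name="taxon"),
    )


def compare_groups(post: DMMPosterior, g1: str, g2: str,
                   level: float = None) -> DifferentialAbundanceResult:
    """Posterior-difference comparison of two groups with the credible rule.

    Pools draws across chains; taxon i is flagged when
    Pr(pi_i,g1 > pi_i,g2) >= level or <= 1 - level (boundary counts as
    flagged).  Reports the equal-tailed (1 - level) interval of the
    difference and the posterior log10 fold change.
    """
    level = post.settings.credible_level if level is None else level
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    d1 = post.pooled_pi(g1)
    d2 = post.pooled_pi(g2)
    diff = d1 - d2
    prob = (diff > 0).mean(axis=0)
    prob_neg = (diff < 0).mean(axis=0)  # differs from 1-prob only on ties
    flagged = (prob >= level) | (prob_neg >= level)
    lo, hi = np.quantile(diff, [(1 - level) / 2, 1 - (1 - level) / 2], axis=0)
    mean_diff = diff.mean(axis=0)
    direction = np.where(flagged, np.where(mean_diff > 0, g1, g2), "")
    table = pd.DataFrame(
        {
            f"mean_{g1}": d1.mean(axis=0),
            f"mean_{g2}": d2.mean(axis=0),
            "diff_mean": mean_diff,
            "diff_lo": lo,
            "diff_hi": hi,
            "prob_g1_greater": prob,
            "flagged": flagged,
            "direction": direction,
        },
        index=pd.Index(post.taxon_ids, name="taxon"),
    )
    table = table.join(log10_fold_changes(post, g1, g2, level))
    return DifferentialAbundanceResult(table, g1, g2, level, post)


#: the three standard two-group contrasts: rule mapping (genotype, ploidy)
#: to a pooled side, plus the fixed (g1, g2) orientation of the report
STANDARD_CONTRASTS = {
    "ploidy_2x_vs_4x": (lambda geno, ploidy: ploidy, ("2x", "4x")),
    "genotype_Col_vs_Ler": (lambda geno, ploidy: geno, ("Col", "Ler")),
    "Col4x_vs_others": (
        lambda geno, ploidy: "Col-4x" if (geno, ploidy) == ("Col", "4x") else "others",
        ("Col-4x", "others"),
    ),
}


def standard_comparisons(ct: CountTable, metadata: SampleMetadata,
                         settings: DMMSettings = None) -> dict:
    """Fit the three standard contrasts as separate two-group models.

    diploid vs tetraploid (pooled), Columbia vs Landsberg (pooled), and
    Col-4x vs the other three groups pooled.  Soil controls are always
    excluded.  Returns ``{contrast_name: DifferentialAbundanceResult}``.
    """
    settings = settings or DMMSettings()
    planted = metadata.planted()
    missing = set(("Col-2x", "Col-4x", "Ler-2x", "Ler-4x")) - set(planted.groups.unique())
    if missing:
        raise ValueError(f"metadata lacks groups {sorted(missing)}")
    ct_planted = ct.subset_samples([s for s in ct.sample_ids if s in planted.data.index])
    results = {}
    for name, (rule, sides) in STANDARD_CONTRASTS.items():
        mapping = {
            s: rule(planted.data.loc[s, "genotype"], planted.data.loc[s, "ploidy"])
            for s in ct_planted.sample_ids
        }
        post = fit_dmm(ct_planted, mapping, settings)
        results[name] = compare_groups(post, sides[0], sides[1])
    return results
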