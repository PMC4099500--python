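"""Bayesian allele-frequency estimation under partial selfing, and the
classic dominant-marker diversity statistics (PPL, Hj, DW rarity).

With a dominant marker only band presence/absence is observed. Writing q
for the frequency of the band-absence (null) allele and F for the
inbreeding coefficient, the probability of the null phenotype is

    P0(q) = q^2 + F q (1 - q)

so the band-absent count in a population of n individuals is
k ~ Binomial(n, P0(q)). The per-locus, per-population estimate q_hat is the
posterior mean of q under a Beta(a, b) prior, computed by deterministic
Gauss-Legendre quadrature on [0, 1] (exact to machine precision at these
problem sizes, avoiding the classical analytic approximations). The
"fitted" prior estimates (a, b) by Beta method-of-moments from the
across-loci distribution of moment-inverted null fractions.

Under predominant selfing at equilibrium the inbreeding coefficient follows
from the selfing rate s as F = s / (2 - s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import Dataset

_N_QUAD = 512
_QUAD_X, _QUAD_W = np.polynomial.legendre.leggauss(_N_QUAD)
_QUAD_X = 0.5 * (_QUAD_X + 1.0)       # map to (0, 1)
_QUAD_W = 0.5 * _QUAD_W


def selfing_to_inbreeding(s: float) -> float:
    """Equilibrium inbreeding coefficient F = s/(2-s) for selfing rate s."""
    if not (0.0 <= s <= 1.0):
        raise ValueError(f"selfing rate must be in [0, 1], got {s}")
    return s / (2.0 - s)


def null_phenotype_prob(q, F):
    """P0(q) = q^2 + F q (1-q): probability of showing no band."""
    q = np.asarray(q, dtype=float)
    return q * q + F * q * (1.0 - q)


# ---------------------------------------------------------------------------
# Posterior moments of q
# ---------------------------------------------------------------------------

def _posterior_moments(n, k, F, a, b):
    """Posterior E[q], E[q^2], E[P0(q)] for arrays n, k (broadcast together).

    Likelihood k ~ Bin(n, P0(q)), prior Beta(a, b); Gauss-Legendre quadrature
    with log-sum-exp stabilisation.
    """
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    n, k = np.broadcast_arrays(n, k)
    shape = n.shape
    n = n.ravel()[:, None]
    k = k.ravel()[:, None]
    q = _QUAD_X[None, :]
    P0 = null_phenotype_prob(q, F)
    with np.errstate(divide="ignore", invalid="ignore"):
        loglik = (k * np.log(P0) + (n - k) * np.log1p(-P0)
                  + (a - 1.0) * np.log(q) + (b - 1.0) * np.log1p(-q))
    loglik = np.where(np.isnan(loglik), -np.inf, loglik)
    m = loglik.max(axis=1, keepdims=True)
    w = np.exp(loglik - m) * _QUAD_W[None, :]
    Z = w.sum(axis=1)
    Eq = (w * q).sum(axis=1) / Z
    Eq2 = (w * q * q).sum(axis=1) / Z
    EP0 = (w * P0).sum(axis=1) / Z
    return Eq.reshape(shape), Eq2.reshape(shape), EP0.reshape(shape)


def posterior_q_lookup(n: int, F: float, a: float, b: float):
    """(q_hat, q_var, f_hat) indexed by k = 0..n for a fixed sample size.

    The workhorse for permutation tests, bootstraps and simulations: with n
    fixed, the estimator is a function of k only.
    """
    ks = np.arange(n + 1)
    Eq, Eq2, EP0 = _posterior_moments(np.full(n + 1, n), ks, F, a, b)
    return Eq, np.clip(Eq2 - Eq ** 2, 0.0, None), 1.0 - EP0


def _invert_p0(x, F):
    """Moment inversion of P0: solve q^2 + Fq(1-q) = x for q in [0,1]."""
    x = np.clip(np.asarray(x, dtype=float), 0.0, 1.0)
    if F >= 1.0 - 1e-12:
        return x
    aa = 1.0 - F
    disc = F * F + 4.0 * aa * x
    return np.clip((-F + np.sqrt(disc)) / (2.0 * aa), 0.0, 1.0)


def fit_beta_prior(ds: Dataset, F: float, floor: float = 0.25) -> tuple[float, float]:
    """Beta(a, b) prior by method of moments on moment-inverted null fractions.

    The observed per-population null-phenotype fractions k/n are mapped
    through the inverse of P0 to the q scale; (a, b) solve the Beta moment
    equations on those values, floored at ``floor`` to avoid degenerate
    priors.
    """
    counts = ds.band_counts()
    sizes = ds.population_sizes().loc[counts.index]
    nullfrac = 1.0 - counts.to_numpy() / sizes.to_numpy()[:, None]
    qs = _invert_p0(nullfrac, F).ravel()
    m, v = float(np.mean(qs)), float(np.var(qs))
    v = min(max(v, 1e-6), m * (1 - m) - 1e-6) if 0 < m < 1 else 1e-6
    common = m * (1 - m) / v - 1.0
    a = max(m * common, floor)
    b = max((1 - m) * common, floor)
    return a, b


@dataclass
class AlleleFreqTable:
    """Per population x locus posterior summaries of the null-allele frequency.

    ``q_hat``/``q_var``: posterior mean and variance of q; ``f_hat``:
    band frequency 1 - E[P0(q)]; ``n``: per-population sample sizes;
    ``k_absent``: band-absent counts. ``F`` and the Beta prior (a, b) are the
    estimation settings.
    """

    q_hat: pd.DataFrame
    q_var: pd.DataFrame
    f_hat: pd.DataFrame
    n: pd.Series
    k_absent: pd.DataFrame
    F: float
    prior: tuple[float, float]

    @property
    def populations(self) -> list[str]:
        return list(self.q_hat.index)

    @property
    def loci(self) -> list[str]:
        return list(self.q_hat.columns)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (population, locus, n, k_absent, q_hat, f_hat)."""
        recs = []
        for pop in self.populations:
            for loc in self.loci:
                recs.append({"population": pop, "locus": loc,
                             "n": int(self.n[pop]),
                             "k_absent": int(self.k_absent.loc[pop, loc]),
                             "q_hat": self.q_hat.loc[pop, loc],
                             "f_hat": self.f_hat.loc[pop, loc]})
        return pd.DataFrame(recs)


def estimate_allele_freqs(ds: Dataset, F: float,
                          prior: str | tuple[float, float] = "fitted") -> AlleleFreqTable:
    """Posterior allele-frequency table for every population x locus.

    ``prior`` is "uniform" (Beta(1,1)), "fitted" (method of moments across
    loci) or an explicit (a, b) tuple.
    """
    if not (0.0 <= F <= 1.0):
        raise ValueError("F must be in [0, 1]")
    ds = ds.drop_replicates()
    counts = ds.band_counts()
    sizes = ds.population_sizes().loc[counts.index]
    if (sizes == 0).any():
        raise ValueError("population with n=0")
    if prior == "uniform":
        a, b = 1.0, 1.0
    elif prior == "fitted":
        a, b = fit_beta_prior(ds, F)
    else:
        a, b = prior
    k_absent = sizes.to_numpy()[:, None] - counts.to_numpy()
    # one quadrature lookup per distinct population size
    q_hat = np.empty_like(counts.to_numpy(), dtype=float)
    q_var = np.empty_like(q_hat)
    f_hat = np.empty_like(q_hat)
    for n in np.unique(sizes.to_numpy()):
        rows = np.flatnonzero(sizes.to_numpy() == n)
        Eq, Vq, fh = posterior_q_lookup(int(n), F, a, b)
        q_hat[rows] = Eq[k_absent[rows]]
        q_var[rows] = Vq[k_absent[rows]]
        f_hat[rows] = fh[k_absent[rows]]
    idx, cols = counts.index, counts.columns
    return AlleleFreqTable(
        q_hat=pd.DataFrame(q_hat, index=idx, columns=cols),
        q_var=pd.DataFrame(q_var, index=idx, columns=cols),
        f_hat=pd.DataFrame(f_hat, index=idx, columns=cols),
        n=sizes, k_absent=pd.DataFrame(k_absent, index=idx, columns=cols),
        F=F, prior=(a, b))


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

def _standardized_draws(members, max_n, n_draws, rng):
    """Subsample draws standardizing sample size; a single full draw if n <= max_n."""
    if len(members) <= max_n:
        return [list(members)]
    return [list(rng.choice(members, size=max_n, replace=False))
            for _ in range(n_draws)]


def nei_gene_diversity(ds: Dataset, F: float,
                       prior: str | tuple[float, float] = "fitted",
                       max_n: int = 8, n_draws: int = 20,
                       seed: int | None = 0) -> pd.Series:
    """Nei's gene diversity Hj per population on standardized sample sizes.

    Hj = mean over loci of 2 q_hat (1 - q_hat); populations larger than
    ``max_n`` are subsampled to ``max_n`` individuals, averaged over
    ``n_draws`` random draws (bit-reproducible under ``seed``).
    """
    ds = ds.drop_replicates()
    rng = np.random.default_rng(seed)
    if prior == "fitted":
        prior = fit_beta_prior(ds, F)
    X = ds.band_matrix.presence
    out = {}
    lookups: dict[int, np.ndarray] = {}
    for pop, info in ds.populations.items():
        members = [m for m in info.members if m in X.index]
        vals = []
        for draw in _standardized_draws(members, max_n, n_draws, rng):
            n = len(draw)
            if n not in lookups:
                a, b = (1.0, 1.0) if prior == "uniform" else prior
                lookups[n] = posterior_q_lookup(n, F, a, b)[0]
            k = n - X.loc[draw].to_numpy().sum(axis=0)
            q = lookups[n][k]
            vals.append(np.mean(2.0 * q * (1.0 - q)))
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name="Hj").sort_index()


def ppl(ds: Dataset, level: float = 0.05, max_n: int = 8, n_draws: int = 20,
        seed: int | None = 0) -> pd.Series:
    """Percentage of polymorphic loci per population at the given level.

    A locus is polymorphic when its band frequency in the (standardized)
    subsample lies strictly inside (level, 1 - level).
    """
    ds = ds.drop_replicates()
    rng = np.random.default_rng(seed)
    X = ds.band_matrix.presence
    out = {}
    for pop, info in ds.populations.items():
        vals = []
        for draw in _standardized_draws(info.members, max_n, n_draws, rng):
            f = X.loc[draw].to_numpy().mean(axis=0)
            vals.append(100.0 * np.mean((f > level) & (f < 1.0 - level)))
        out[pop] = float(np.mean(vals))
    return pd.Series(out, name="PPL").sort_index()


def dw_rarity(ds: Dataset) -> pd.Series:
    """Frequency-down-weighted marker value (rarity index) per population.

    DW = sum over loci of (band count in population / band count in the
    whole dataset), divided by the population's sample size. Loci absent
    from the entire dataset are excluded. Populations holding globally rare
    bands score high.
    """
    ds = ds.drop_replicates()
    counts = ds.band_counts()
    total = counts.sum(axis=0)
    keep = total > 0
    ratio = counts.loc[:, keep].div(total[keep], axis=1)
    dw = ratio.sum(axis=1) / ds.population_sizes().loc[counts.index]
    return dw.rename("DW").sort_index()


def diversity_table(ds: Dataset, F: float, max_n: int = 8, n_draws: int = 20,
                    seed: int | None = 0) -> pd.DataFrame:
    """Per-population summary: n, PPL (%), Hj, DW."""
    return pd.DataFrame({
        "n": ds.population_sizes(),
        "PPL": ppl(ds, max_n=max_n, n_draws=n_draws, seed=seed),
        "Hj": nei_gene_diversity(ds, F, max_n=max_n, n_draws=n_draws, seed=seed),
        "DW": dw_rarity(ds),
    })
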