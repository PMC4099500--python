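"""Fst-outlier detection for dominant loci with consensus/replication rules.

Two detectors look for loci whose differentiation between habitat classes
exceeds the neutral expectation conditional on heterozygosity:

* an *envelope* detector: an island-model null (deme band-allele
  frequencies Beta-distributed around a resampled ancestral frequency,
  dominant phenotypes sampled with inbreeding) is simulated at the
  comparison's sample sizes and calibrated to the trimmed "neutral mean"
  Fst; each observed locus gets an upper-tail probability within its
  heterozygosity bin, controlled by Benjamini-Hochberg FDR;

* a *Bayesian* detector: a hierarchical logistic decomposition of
  per-locus, per-group differentiation, logit F_lg = alpha_l + beta_g,
  with a spike-and-slab prior on the locus effect alpha_l (prior inclusion
  odds 1:10) sampled by Metropolis-within-Gibbs; a locus is flagged at
  posterior inclusion probability >= 0.91 ("strong evidence").

A locus is a *significant outlier* when both detectors flag it in at
least one pooled between-habitat comparison, or the Bayesian detector
flags it in at least one between-habitat population pair — unless it is
also flagged in a same-habitat (control) comparison. A *replicated
outlier* is additionally supported by two between-habitat pairwise
comparisons sharing no population (parallel divergence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, logit
from statsmodels.stats.multitest import multipletests

from .freqs import null_phenotype_prob, posterior_q_lookup, _invert_p0
from .io_core import Dataset

STRONG_EVIDENCE = 0.91


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonSpec:
    name: str
    kind: str                      # "pooled" | "pairwise"
    scale: str
    group_a: list[str]
    group_b: list[str]
    habitat_a: str
    habitat_b: str
    control: bool                  # True when both groups share a habitat

    @property
    def populations(self) -> set[str]:
        return set(self.group_a) | set(self.group_b)

    @property
    def between_habitat(self) -> bool:
        return not self.control


def build_comparisons(ds: Dataset, scales: dict[str, list[str]] | None = None,
                      pairwise_scale: str = "landscape") -> list[ComparisonSpec]:
    """Pooled between-habitat specs per scale + all pairwise specs at one scale.

    ``scales`` maps a scale label to the populations it covers (default: a
    single "continental" scale over all populations). Pooled specs contrast
    the dune against the fen populations of the scale and are skipped with
    a warning when a scale holds a single habitat. Pairwise specs cover all
    population pairs of ``pairwise_scale`` (falling back to the first
    scale), tagged control when the two populations share a habitat.
    """
    hab = ds.habitat_of_population()
    if scales is None:
        scales = {"continental": list(ds.populations)}
    specs: list[ComparisonSpec] = []
    for label, pops in scales.items():
        dune = [p for p in pops if hab[p] == "dune"]
        fen = [p for p in pops if hab[p] == "fen"]
        if not dune or not fen:
            warnings.warn(f"scale {label!r} has a single habitat; pooled "
                          "comparison skipped", stacklevel=2)
            continue
        specs.append(ComparisonSpec(
            name=f"pooled:{label}", kind="pooled", scale=label,
            group_a=dune, group_b=fen, habitat_a="dune", habitat_b="fen",
            control=False))
    pw_pops = scales.get(pairwise_scale) or next(iter(scales.values()))
    for i, a in enumerate(pw_pops):
        for b in pw_pops[i + 1:]:
            specs.append(ComparisonSpec(
                name=f"pair:{a}|{b}", kind="pairwise", scale=pairwise_scale,
                group_a=[a], group_b=[b], habitat_a=hab[a], habitat_b=hab[b],
                control=hab[a] == hab[b]))
    return specs


def _group_counts(ds: Dataset, spec: ComparisonSpec):
    """((n_a, k_absent_a), (n_b, k_absent_b)) pooled over each group's pops."""
    counts = ds.band_counts()
    sizes = ds.population_sizes()
    out = []
    for group in (spec.group_a, spec.group_b):
        n = int(sizes.loc[group].sum())
        k = n - counts.loc[group].sum(axis=0).to_numpy()
        out.append((n, k.astype(int)))
    return out


# ---------------------------------------------------------------------------
# Two-group Fst on estimated frequencies
# ---------------------------------------------------------------------------

def _two_group_fst(nA, kA, nB, kB, F):
    """Per-locus noise-corrected Fst and He between two pooled groups.

    q_hat per group by uniform-prior posterior lookup; Fst numerator is the
    two-sample variance of q_hat minus the mean posterior variance;
    denominator the total term q_bar (1 - q_bar).
    """
    qA, vA, _ = (arr[kA] for arr in posterior_q_lookup(nA, F, 1.0, 1.0))
    qB, vB, _ = (arr[kB] for arr in posterior_q_lookup(nB, F, 1.0, 1.0))
    qbar = 0.5 * (qA + qB)
    num = 0.25 * (qA - qB) ** 2 - 0.25 * (vA + vB)   # plug-in (ddof=0) scale
    den = qbar * (1.0 - qbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 1e-12, num / den, np.nan)
    he = 2.0 * den
    return fst, he


# ---------------------------------------------------------------------------
# Envelope (island-model simulation) detector
# ---------------------------------------------------------------------------

@dataclass
class EnvelopeNull:
    sim_fst: np.ndarray
    sim_he: np.ndarray
    bin_edges: np.ndarray          # He bin edges (monotone)
    bin_of_sim: np.ndarray
    target_fst: float              # trimmed neutral-mean Fst aimed for
    achieved_fst: float
    n_sim: int
    F_is: float
    sizes: tuple[int, int]

    def quantile(self, he, q: float):
        """He-conditional Fst quantile(s) of the null, per observed locus."""
        b = np.clip(np.searchsorted(self.bin_edges, he, side="right") - 1,
                    0, len(self.bin_edges) - 2)
        out = np.empty(np.shape(he))
        for bi in np.unique(b):
            vals = self.sim_fst[self.bin_of_sim == bi]
            out[b == bi] = np.quantile(vals, q)
        return out

    def tail_prob(self, fst, he):
        """Upper-tail probability of each observed (fst, he) under the null."""
        fst = np.asarray(fst, dtype=float)
        he = np.asarray(he, dtype=float)
        b = np.clip(np.searchsorted(self.bin_edges, he, side="right") - 1,
                    0, len(self.bin_edges) - 2)
        p = np.ones_like(fst)
        for bi in np.unique(b):
            vals = np.sort(self.sim_fst[self.bin_of_sim == bi])
            sel = b == bi
            ge = len(vals) - np.searchsorted(vals, fst[sel], side="left")
            p[sel] = (1.0 + ge) / (len(vals) + 1.0)
        p[np.isnan(fst)] = 1.0
        return p


def _simulate_null(anc_pool, target_fst, nA, nB, F_is, n_sim, rng):
    """Simulate n_sim neutral dominant loci at the comparison's sample sizes."""
    p_anc = rng.choice(anc_pool, size=n_sim, replace=True)
    theta = 1.0 / target_fst - 1.0
    a = np.clip(p_anc * theta, 1e-3, None)
    b = np.clip((1.0 - p_anc) * theta, 1e-3, None)
    kk = []
    for n in (nA, nB):
        q = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)   # null-allele frequency
        kk.append(rng.binomial(n, null_phenotype_prob(q, F_is)))
    return _two_group_fst(nA, kk[0], nB, kk[1], F_is)


def _mean_fst(fst, he, mask=None):
    w = he / 2.0          # ratio-of-sums weighting by the denominator term
    ok = np.isfinite(fst) & (w > 1e-12)
    if mask is not None:
        ok &= mask
    return float(np.clip(np.sum(fst[ok] * w[ok]) / np.sum(w[ok]), 1e-3, 0.9))


def envelope_null(ds: Dataset, comparison: ComparisonSpec, F_is: float,
                  n_sim: int = 50000, seed: int | None = 0,
                  n_bins: int = 12, min_bin: int = 2000,
                  trim_quantile: float = 0.99,
                  n_calibrate: int = 3) -> EnvelopeNull:
    """He-conditional null envelope of Fst calibrated to the neutral mean.

    The target mean Fst is re-estimated after trimming provisional outliers
    (loci above the ``trim_quantile`` He-conditional null quantile), and
    the Beta island-model scale is iteratively adjusted until the mean of
    the *estimated* Fst over simulated loci matches the target.
    """
    (nA, kA), (nB, kB) = _group_counts(ds, comparison)
    obs_fst, obs_he = _two_group_fst(nA, kA, nB, kB, F_is)
    pooled_q = _invert_p0((kA + kB) / (nA + nB), F_is)
    anc_pool = np.clip(1.0 - pooled_q, 0.02, 0.98)   # band-allele frequencies
    rng = np.random.default_rng(seed)
    target = _mean_fst(obs_fst, obs_he)
    sim_fst = sim_he = None
    drive = target
    for _ in range(max(n_calibrate, 1)):
        # inner loop: match achieved estimated mean Fst to the current target
        for _ in range(3):
            sim_fst, sim_he = _simulate_null(anc_pool, drive, nA, nB, F_is,
                                             n_sim, rng)
            achieved = _mean_fst(sim_fst, sim_he)
            drive = float(np.clip(drive * target / achieved, 1e-3, 0.9))
        env = _build_envelope(sim_fst, sim_he, target, achieved, n_sim, F_is,
                              (nA, nB), n_bins, min_bin)
        keep = obs_fst <= env.quantile(obs_he, trim_quantile)
        new_target = _mean_fst(obs_fst, obs_he, mask=keep)
        if abs(new_target - target) < 0.002:
            target = new_target
            break
        drive *= new_target / target
        target = new_target
    return _build_envelope(sim_fst, sim_he, target, _mean_fst(sim_fst, sim_he),
                           n_sim, F_is, (nA, nB), n_bins, min_bin)


def _build_envelope(sim_fst, sim_he, target, achieved, n_sim, F_is, sizes,
                    n_bins, min_bin):
    ok = np.isfinite(sim_fst)
    sim_fst, sim_he = sim_fst[ok], sim_he[ok]
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(sim_he, qs))
    edges[0], edges[-1] = -np.inf, np.inf
    bin_of = np.clip(np.searchsorted(edges, sim_he, side="right") - 1,
                     0, len(edges) - 2)
    # merge sparse bins leftward
    counts = np.bincount(bin_of, minlength=len(edges) - 1)
    while len(edges) > 2 and counts.min() < min_bin:
        i = int(np.argmin(counts))
        edges = np.delete(edges, max(i, 1))
        bin_of = np.clip(np.searchsorted(edges, sim_he, side="right") - 1,
                         0, len(edges) - 2)
        counts = np.bincount(bin_of, minlength=len(edges) - 1)
    return EnvelopeNull(sim_fst=sim_fst, sim_he=sim_he, bin_edges=edges,
                        bin_of_sim=bin_of, target_fst=target,
                        achieved_fst=achieved, n_sim=n_sim, F_is=F_is,
                        sizes=sizes)


@dataclass
class OutlierCallSet:
    """Per (comparison, locus, detector) statistics and decisions."""

    calls: pd.DataFrame   # comparison, locus, detector, statistic, he, p, decision

    def concat(self, other: "OutlierCallSet") -> "OutlierCallSet":
        return OutlierCallSet(pd.concat([self.calls, other.calls],
                                        ignore_index=True))


def envelope_detect(ds: Dataset, comparison: ComparisonSpec,
                    envelope: EnvelopeNull, fdr: float = 0.05) -> OutlierCallSet:
    """Upper-tail (directional-selection) outliers against the envelope null.

    Per-locus tail probabilities within heterozygosity bins, BH-FDR within
    the comparison. Loci monomorphic in both groups are never outliers.
    """
    (nA, kA), (nB, kB) = _group_counts(ds, comparison)
    fst, he = _two_group_fst(nA, kA, nB, kB, envelope.F_is)
    p = envelope.tail_prob(fst, he)
    monomorphic = ((kA == 0) & (kB == 0)) | ((kA == nA) & (kB == nB))
    p[monomorphic] = 1.0
    reject = multipletests(p, alpha=fdr, method="fdr_bh")[0]
    loci = ds.band_matrix.locus_ids
    return OutlierCallSet(pd.DataFrame({
        "comparison": comparison.name, "locus": loci, "detector": "envelope",
        "statistic": fst, "he": he, "p": p,
        "decision": reject & ~monomorphic}))


# ---------------------------------------------------------------------------
# Bayesian spike-and-slab detector
# ---------------------------------------------------------------------------

@dataclass
class McmcSettings:
    n_iter: int = 4000
    burn_in: int = 2000
    thin: int = 5
    prior_odds: float = 10.0       # prior odds *against* inclusion (1:10)
    slab_sd: float = 1.8
    beta_prior_mean: float = -2.0
    beta_prior_sd: float = 1.8
    rhat_limit: float = 1.1


class _SpikeSlabSampler:
    """Metropolis-within-Gibbs sampler, vectorised over (comparison, locus).

    State arrays are shaped (C, L) for locus-level parameters, (C, G) for
    group effects and (C, L, G) for the latent group null-allele
    frequencies. All C comparisons run the same iterations independently,
    so a stack of comparisons costs roughly the wall time of one. The
    current Beta-density kernel, its normaliser and the binomial
    log-likelihood are cached and updated on acceptance; the normaliser
    cancels in the latent-frequency moves, which keeps the expensive
    ``betaln`` evaluations to a handful per sweep.
    """

    def __init__(self, n, k, F_is, settings: McmcSettings, seed,
                 likelihood_on: bool = True):
        # n: (C, G); k: (C, L, G)
        self.n = np.asarray(n, dtype=float)
        self.k = np.asarray(k, dtype=float)
        self.C, self.L, self.G = self.k.shape
        self.F_is = F_is
        self.s = settings
        self.rng = np.random.default_rng(seed)
        self.likelihood_on = likelihood_on
        pooled = self.k.sum(axis=2) / self.n.sum(axis=1)[:, None]
        self.p = np.clip(_invert_p0(pooled, F_is), 0.02, 0.98)   # ancestral q
        self.beta = np.full((self.C, self.G), settings.beta_prior_mean)
        self.a = self.rng.normal(0.0, settings.slab_sd, size=(self.C, self.L))
        self.delta = np.zeros((self.C, self.L), dtype=bool)
        with np.errstate(divide="ignore"):
            self.q = np.clip(_invert_p0(self.k / self.n[:, None, :], F_is),
                             0.02, 0.98)
        # data-informed pseudoprior for the excluded-state slab coefficient
        # (Carlin-Chib linking density): centred on the moment estimate of
        # the locus effect so inclusion jumps propose relevant values
        qbar = self.q.mean(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst0 = self.q.var(axis=2, ddof=1) / np.clip(qbar * (1 - qbar), 1e-6, None)
        fst0 = np.clip(np.where(np.isfinite(fst0), fst0, 1e-3), 1e-3, 0.995)
        base = logit(np.clip(np.median(fst0, axis=1, keepdims=True), 1e-3, 0.9))
        self._pseudo_mean = np.clip(logit(fst0) - base, -4.0, 8.0)
        self._pseudo_sd = 1.0
        self._refresh_caches()

    # -- likelihood pieces -------------------------------------------------
    def _binom_loglik(self, q):
        if not self.likelihood_on:
            return np.zeros_like(q)   # prior-only sanity mode
        P0 = np.clip(null_phenotype_prob(q, self.F_is), 1e-12, 1 - 1e-12)
        return self.k * np.log(P0) + (self.n[:, None, :] - self.k) * np.log1p(-P0)

    def _ab(self, alpha, p):
        """Beta(a, b) parameters from logit Fst = alpha + beta."""
        theta = np.clip(np.exp(-(alpha[:, :, None] + self.beta[:, None, :])),
                        1e-6, 1e7)
        a = np.clip(p[:, :, None] * theta, 1e-6, None)
        b = np.clip((1.0 - p[:, :, None]) * theta, 1e-6, None)
        return a, b

    def _kernel(self, q, a, b):
        return (a - 1.0) * np.log(q) + (b - 1.0) * np.log1p(-q)

    @property
    def alpha(self):
        return np.where(self.delta, self.a, 0.0)

    def _refresh_caches(self):
        self._cab = self._ab(self.alpha, self.p)          # current (a, b)
        a, b = self._cab
        self._kern = self._kernel(self.q, a, b)           # (C, L, G)
        self._norm = -betaln(a, b)
        self._bin = self._binom_loglik(self.q)

    # -- updates -----------------------------------------------------------
    def _update_q(self):
        # Beta normaliser and (a, b) unchanged: kernel + binomial ratio only
        a, b = self._cab
        z = logit(np.clip(self.q, 1e-9, 1 - 1e-9))
        qprop = expit(z + self.rng.normal(0, 0.5, size=z.shape))
        kern_p = self._kernel(qprop, a, b)
        bin_p = self._binom_loglik(qprop)
        ratio = (kern_p - self._kern) + (bin_p - self._bin) \
            + (np.log(qprop) + np.log1p(-qprop)) \
            - (np.log(self.q) + np.log1p(-self.q))       # logit-RW Jacobian
        accept = np.log(self.rng.random(z.shape)) < ratio
        self.q = np.where(accept, qprop, self.q)
        self._kern = np.where(accept, kern_p, self._kern)
        self._bin = np.where(accept, bin_p, self._bin)

    def _update_p(self):
        z = logit(self.p)
        pprop = expit(z + self.rng.normal(0, 0.4, size=z.shape))
        ap, bp = self._ab(self.alpha, pprop)
        kern_p = self._kernel(self.q, ap, bp)
        norm_p = -betaln(ap, bp)
        ratio = (kern_p + norm_p - self._kern - self._norm).sum(axis=2) \
            + np.log(pprop) + np.log1p(-pprop) - np.log(self.p) - np.log1p(-self.p)
        accept = np.log(self.rng.random(z.shape)) < ratio
        self.p = np.where(accept, pprop, self.p)
        m = accept[:, :, None]
        self._cab = (np.where(m, ap, self._cab[0]), np.where(m, bp, self._cab[1]))
        self._kern = np.where(m, kern_p, self._kern)
        self._norm = np.where(m, norm_p, self._norm)

    def _update_a(self):
        # slab coefficient: random walk where included, prior refresh where not
        aprop = self.a + self.rng.normal(0, 0.5, size=self.a.shape)
        ap, bp = self._ab(np.where(self.delta, aprop, 0.0), self.p)
        kern_p = self._kernel(self.q, ap, bp)
        norm_p = -betaln(ap, bp)
        ratio = (kern_p + norm_p - self._kern - self._norm).sum(axis=2) \
            - 0.5 * (aprop ** 2 - self.a ** 2) / self.s.slab_sd ** 2
        accept = (np.log(self.rng.random(self.a.shape)) < ratio) & self.delta
        self.a = np.where(accept, aprop, self.a)
        m = accept[:, :, None]
        self._cab = (np.where(m, ap, self._cab[0]), np.where(m, bp, self._cab[1]))
        self._kern = np.where(m, kern_p, self._kern)
        self._norm = np.where(m, norm_p, self._norm)
        fresh = self.rng.normal(self._pseudo_mean, self._pseudo_sd,
                                size=self.a.shape)
        self.a = np.where(self.delta, self.a, fresh)

    def _update_delta(self):
        # Gibbs on the inclusion indicator: evaluate the flipped state only
        other_alpha = np.where(self.delta, 0.0, self.a)
        ao, bo = self._ab(other_alpha, self.p)
        kern_o = self._kernel(self.q, ao, bo)
        norm_o = -betaln(ao, bo)
        ll_cur = (self._kern + self._norm).sum(axis=2)
        ll_other = (kern_o + norm_o).sum(axis=2)
        ll_in = np.where(self.delta, ll_cur, ll_other)
        ll_out = np.where(self.delta, ll_other, ll_cur)
        # Carlin-Chib correction: slab prior density over pseudoprior density
        log_prior_ratio = (-0.5 * (self.a / self.s.slab_sd) ** 2
                           - np.log(self.s.slab_sd)
                           + 0.5 * ((self.a - self._pseudo_mean)
                                    / self._pseudo_sd) ** 2
                           + np.log(self._pseudo_sd))
        log_odds = ll_in - ll_out + log_prior_ratio - np.log(self.s.prior_odds)
        u = self.rng.random(self.delta.shape)
        new_delta = np.log(u / (1 - u)) < log_odds
        changed = (new_delta != self.delta)[:, :, None]
        self.delta = new_delta
        self._cab = (np.where(changed, ao, self._cab[0]),
                     np.where(changed, bo, self._cab[1]))
        self._kern = np.where(changed, kern_o, self._kern)
        self._norm = np.where(changed, norm_o, self._norm)

    def _update_beta(self):
        alpha = self.alpha
        for g in range(self.G):
            bprop_g = self.beta[:, g] + self.rng.normal(0, 0.2, size=self.C)
            theta = np.clip(np.exp(-(alpha + bprop_g[:, None])), 1e-6, 1e7)
            ap = np.clip(self.p * theta, 1e-6, None)
            bp = np.clip((1.0 - self.p) * theta, 1e-6, None)
            kern_p = self._kernel(self.q[:, :, g], ap, bp)
            norm_p = -betaln(ap, bp)
            ratio = (kern_p + norm_p
                     - self._kern[:, :, g] - self._norm[:, :, g]).sum(axis=1) \
                - 0.5 * ((bprop_g - self.s.beta_prior_mean) ** 2
                         - (self.beta[:, g] - self.s.beta_prior_mean) ** 2) \
                / self.s.beta_prior_sd ** 2
            accept = np.log(self.rng.random(self.C)) < ratio
            self.beta[:, g] = np.where(accept, bprop_g, self.beta[:, g])
            m = accept[:, None]
            self._cab[0][:, :, g] = np.where(m, ap, self._cab[0][:, :, g])
            self._cab[1][:, :, g] = np.where(m, bp, self._cab[1][:, :, g])
            self._kern[:, :, g] = np.where(m, kern_p, self._kern[:, :, g])
            self._norm[:, :, g] = np.where(m, norm_p, self._norm[:, :, g])

    def run(self):
        s = self.s
        incl_sum = np.zeros((self.C, self.L))
        n_keep = 0
        alpha_samples = []
        for it in range(s.n_iter):
            self._update_q()
            self._update_p()
            self._update_a()
            self._update_delta()
            self._update_beta()
            if it >= s.burn_in and (it - s.burn_in) % s.thin == 0:
                incl_sum += self.delta
                alpha_samples.append(self.alpha.copy())
                n_keep += 1
        posterior = incl_sum / n_keep
        rhat = _split_rhat(np.array(alpha_samples))   # (C, L)
        return posterior, rhat


def spike_slab_scan(n, k, F_is, mcmc: McmcSettings | None = None,
                    seed: int | None = 0, likelihood_on: bool = True):
    """Low-level entry point: posterior inclusion probabilities and split R-hat.

    ``n``: (C, G) group sample sizes; ``k``: (C, L, G) band-absent counts.
    Stacking independent comparisons (possibly from different datasets)
    along the first axis runs them in a single sampler at near-constant
    wall time.
    """
    sampler = _SpikeSlabSampler(n, k, F_is, mcmc or McmcSettings(), seed,
                                likelihood_on=likelihood_on)
    return sampler.run()


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction on retained draws (S, C, L)."""
    S = chains.shape[0] // 2
    if S < 2:
        return np.ones(chains.shape[1:])
    halves = np.stack([chains[:S], chains[S:2 * S]])     # (2, S, C, L)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B = S * means.var(axis=0, ddof=1)
    var_plus = (S - 1) / S * W + B / S
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)
    return np.where(np.isfinite(rhat), rhat, 1.0)


def bayes_detect_many(ds: Dataset, comparisons: list[ComparisonSpec],
                      mcmc: McmcSettings | None = None,
                      seed: int | None = 0, F_is: float = 0.8349,
                      threshold: float = STRONG_EVIDENCE) -> OutlierCallSet:
    """Run the Bayesian detector on a stack of comparisons in one sampler."""
    if not comparisons:
        return OutlierCallSet(pd.DataFrame(
            columns=["comparison", "locus", "detector", "statistic", "he",
                     "p", "decision", "unreliable"]))
    mcmc = mcmc or McmcSettings()
    n = np.zeros((len(comparisons), 2), dtype=int)
    k = np.zeros((len(comparisons), ds.n_loci, 2), dtype=int)
    for c, spec in enumerate(comparisons):
        (nA, kA), (nB, kB) = _group_counts(ds, spec)
        n[c] = (nA, nB)
        k[c, :, 0], k[c, :, 1] = kA, kB
    sampler = _SpikeSlabSampler(n, k, F_is, mcmc, seed)
    posterior, rhat = sampler.run()
    loci = ds.band_matrix.locus_ids
    frames = []
    for c, spec in enumerate(comparisons):
        fst, he = _two_group_fst(n[c, 0], k[c, :, 0], n[c, 1], k[c, :, 1], F_is)
        unreliable = (posterior[c] >= threshold) & (rhat[c] > mcmc.rhat_limit)
        frames.append(pd.DataFrame({
            "comparison": spec.name, "locus": loci, "detector": "bayes",
            "statistic": posterior[c], "he": he, "p": 1.0 - posterior[c],
            "decision": posterior[c] >= threshold,
            "unreliable": unreliable}))
    return OutlierCallSet(pd.concat(frames, ignore_index=True))


def bayes_detect(ds: Dataset, comparison: ComparisonSpec,
                 mcmc: McmcSettings | None = None, seed: int | None = 0,
                 F_is: float = 0.8349,
                 threshold: float = STRONG_EVIDENCE) -> OutlierCallSet:
    """Bayesian outlier detection for a single comparison (>= 2 groups)."""
    return bayes_detect_many(ds, [comparison], mcmc=mcmc, seed=seed,
                             F_is=F_is, threshold=threshold)


# ---------------------------------------------------------------------------
# Consensus and replication rules
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    significant: dict[str, list[str]]        # locus -> supporting comparisons
    rejected_by_control: dict[str, list[str]]  # locus -> disqualifying comparisons
    replicated: dict[str, list[tuple[str, str]]] = field(default_factory=dict)


def consensus_outliers(calls: OutlierCallSet,
                       comparisons: list[ComparisonSpec]) -> ConsensusResult:
    """Apply the multi-scale consensus decision rule to a call set.

    Candidate loci: flagged by *both* detectors in the same pooled
    between-habitat comparison, or by the Bayesian detector in a
    between-habitat population pair. A candidate is rejected when it is
    also flagged in any same-habitat (control) comparison.
    """
    by_name = {c.name: c for c in comparisons}
    df = calls.calls
    flagged = df[df["decision"].astype(bool)]
    support: dict[str, set] = {}
    for (comp, locus), grp in flagged.groupby(["comparison", "locus"]):
        spec = by_name.get(comp)
        if spec is None or spec.control:
            continue
        detectors = set(grp["detector"])
        ok = (spec.kind == "pooled" and {"envelope", "bayes"} <= detectors) or \
             (spec.kind == "pairwise" and "bayes" in detectors)
        if ok:
            support.setdefault(locus, set()).add(comp)
    control_hits: dict[str, set] = {}
    for (comp, locus), _ in flagged.groupby(["comparison", "locus"]):
        spec = by_name.get(comp)
        if spec is not None and spec.control:
            control_hits.setdefault(locus, set()).add(comp)
    significant, rejected = {}, {}
    for locus, comps in support.items():
        if locus in control_hits:
            rejected[locus] = sorted(control_hits[locus])
        else:
            significant[locus] = sorted(comps)
    return ConsensusResult(significant=significant, rejected_by_control=rejected)


def replicated_outliers(cr: ConsensusResult,
                        comparisons: list[ComparisonSpec]) -> dict[str, list[tuple[str, str]]]:
    """Significant loci supported by two population-disjoint between-habitat pairs."""
    by_name = {c.name: c for c in comparisons}
    replicated: dict[str, list[tuple[str, str]]] = {}
    for locus, comps in cr.significant.items():
        pairs = [by_name[c] for c in comps
                 if c in by_name and by_name[c].kind == "pairwise"
                 and by_name[c].between_habitat]
        found = []
        for i, a in enumerate(pairs):
            for b in pairs[i + 1:]:
                if not (a.populations & b.populations):
                    found.append((a.name, b.name))
        if found:
            replicated[locus] = found
    cr.replicated = replicated
    return replicated
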