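"""Marker-quality pipeline for dominant band matrices.

Covers the standard AFLP hygiene steps: replicate-based genotyping error
rate (Bonin-style), clone (genet) detection by sub-error-rate mismatch,
fragment size vs frequency homoplasy screen, pairwise
linkage-disequilibrium scan with FDR control, band-frequency filtering,
and reduction of redundant (potentially linked) loci to single
representatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .io_core import Dataset


# ---------------------------------------------------------------------------
# Replicate error rate
# ---------------------------------------------------------------------------

@dataclass
class ErrorReport:
    per_locus_error: pd.Series     # locus -> fraction of discordant replicate pairs
    per_pair_error: pd.Series      # pair label -> fraction of discordant loci
    mean_error: float              # mean over loci (headline figure)
    mean_error_per_pair: float     # alternative averaging, reported alongside
    n_replicate_pairs: int
    replicate_ids: list[str]       # rows to exclude downstream


def replicate_error_rate(ds: Dataset) -> ErrorReport:
    """Genotyping error rate from declared replicate pairs.

    Per locus: the fraction of replicate pairs with discordant presence
    calls; the mean over loci is the headline rate. The per-pair-over-loci
    averaging is reported alongside (the two coincide when no data are
    missing, as here, but both conventions circulate).
    """
    pairs = ds.samples.replicate_pairs()
    if not pairs:
        raise ValueError("no replicate pairs declared (replicate_of column empty); "
                         "supply an error rate via configuration instead")
    X = ds.band_matrix.presence
    diffs = np.stack([(X.loc[o].to_numpy() != X.loc[r].to_numpy()) for o, r in pairs])
    per_locus = pd.Series(diffs.mean(axis=0), index=X.columns, name="error")
    per_pair = pd.Series(diffs.mean(axis=1),
                         index=[f"{o}|{r}" for o, r in pairs], name="error")
    return ErrorReport(
        per_locus_error=per_locus,
        per_pair_error=per_pair,
        mean_error=float(per_locus.mean()),
        mean_error_per_pair=float(per_pair.mean()),
        n_replicate_pairs=len(pairs),
        replicate_ids=[r for _, r in pairs])


# ---------------------------------------------------------------------------
# Clone detection
# ---------------------------------------------------------------------------

@dataclass
class GenetAssignment:
    genet_of: pd.Series            # individual -> genet label
    threshold_mismatches: int
    multi_ramet_genets: dict[str, list[str]]


def detect_clones(ds: Dataset, error_rate: float) -> GenetAssignment:
    """Group individuals into genets by sub-error-rate band mismatch.

    Two individuals belong to the same genet when connected (single
    linkage) under "<= round(error_rate * L) mismatches". The mismatch
    budget absorbs genotyping error when recognising ramets of one genet.
    """
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")
    ds = ds.drop_replicates()
    X = ds.band_matrix.values()
    L = X.shape[1]
    thr = int(np.rint(error_rate * L))
    # pairwise Hamming counts via matrix products
    Xf = X.astype(np.float64)
    same11 = Xf @ Xf.T
    same00 = (1 - Xf) @ (1 - Xf).T
    mismatches = L - same11 - same00
    adj = csr_matrix(mismatches <= thr)
    n_comp, labels = connected_components(adj, directed=False)
    ids = ds.band_matrix.individual_ids
    genet_of = pd.Series([f"G{l:04d}" for l in labels], index=ids, name="genet")
    multi = {g: list(members.index)
             for g, members in genet_of.groupby(genet_of) if len(members) > 1}
    return GenetAssignment(genet_of=genet_of, threshold_mismatches=thr,
                           multi_ramet_genets=multi)


# ---------------------------------------------------------------------------
# Homoplasy size-frequency screen
# ---------------------------------------------------------------------------

@dataclass
class SizeFrequencyResult:
    primer_combo: str
    r: float | None
    p: float | None
    decision: str                  # "ok", "negative_correlation", "na"
    cutoff_bp: int | None          # smallest scanned cutoff restoring p > alpha
    n_loci: int


def size_frequency_screen(ds: Dataset, primer_combo: str, alpha: float = 0.05,
                          cutoff_step: int = 50) -> SizeFrequencyResult:
    """Pearson correlation between fragment size and band frequency.

    A significant negative correlation flags potential size homoplasy (small
    comigrating fragments). When flagged, minimum-size cutoffs are scanned
    upward in ``cutoff_step`` bp steps until the correlation on the retained
    loci is no longer significantly negative.
    """
    meta = ds.band_matrix.locus_meta
    if meta is None:
        raise ValueError("size_frequency_screen requires locus metadata")
    loci = meta.index[meta["primer_combo"] == primer_combo]
    if len(loci) < 3:
        raise ValueError(f"primer combination {primer_combo!r} has <3 loci")
    X = ds.drop_replicates().band_matrix.presence[loci]
    freq = X.to_numpy().mean(axis=0)
    size = meta.loc[loci, "size_bp"].to_numpy(dtype=float)
    if np.ptp(freq) == 0 or np.ptp(size) == 0:
        return SizeFrequencyResult(primer_combo, None, None, "na", None, len(loci))
    r, p = stats.pearsonr(size, freq)
    if not (p < alpha and r < 0):
        return SizeFrequencyResult(primer_combo, float(r), float(p), "ok", None, len(loci))
    cutoff = None
    for c in range(cutoff_step, int(size.max()), cutoff_step):
        keep = size >= c
        if keep.sum() < 3 or np.ptp(freq[keep]) == 0:
            break
        rc, pc = stats.pearsonr(size[keep], freq[keep])
        if not (pc < alpha and rc < 0):
            cutoff = c
            break
    return SizeFrequencyResult(primer_combo, float(r), float(p),
                               "negative_correlation", cutoff, len(loci))


# ---------------------------------------------------------------------------
# Linkage-disequilibrium scan
# ---------------------------------------------------------------------------

@dataclass
class LdScanResult:
    pairs: pd.DataFrame            # locus_a, locus_b, lrt, p, q, flagged
    fraction_significant: dict[float, float]
    n_pairs: int


def _logistic_lrt_binary(X: np.ndarray):
    """LRT p-values of logistic regressions y ~ x over all column pairs.

    With a single binary predictor the logistic-regression likelihood-ratio
    statistic has the closed form 2N * MI(x, y) (the G statistic of the
    2x2 table), so no iterative fitting is needed. Returns (lrt, p,
    separated) matrices over pairs; ``separated`` marks perfectly separated
    pairs (a conditional probability of exactly 0 or 1).
    """
    N, L = X.shape
    Xf = X.astype(np.float64)
    n11 = Xf.T @ Xf
    colsum = Xf.sum(axis=0)
    n10 = colsum[:, None] - n11
    n01 = colsum[None, :] - n11
    n00 = N - n11 - n10 - n01
    lrt = np.zeros((L, L))
    for tbl, rowm, colm in (
            (n11, colsum[:, None], colsum[None, :]),
            (n10, colsum[:, None], N - colsum[None, :]),
            (n01, N - colsum[:, None], colsum[None, :]),
            (n00, N - colsum[:, None], N - colsum[None, :])):
        expected = rowm * colm / N
        with np.errstate(divide="ignore", invalid="ignore"):
            term = tbl * np.log(tbl / expected)
        lrt += np.where(tbl > 0, term, 0.0)
    lrt = 2.0 * lrt
    p = stats.chi2.sf(lrt, df=1)
    with np.errstate(invalid="ignore"):
        cond = np.stack([n11, n10, n01, n00])
    separated = (cond == 0).any(axis=0) & ~np.isclose(lrt, 0.0)
    return lrt, p, separated


def ld_scan(ds: Dataset, fdr: float = 0.05,
            cutoffs=(0.05, 0.01, 0.001, 0.0001)) -> LdScanResult:
    """Pairwise linkage-disequilibrium scan over all unordered locus pairs.

    Each pair is tested with the likelihood-ratio test of the slope in a
    logistic regression of one locus' presence on the other's; q-values by
    Benjamini-Hochberg; the fraction of pairs significant at each raw-p
    cutoff is reported.
    """
    ds = ds.drop_replicates()
    X = ds.band_matrix.values()
    if X.shape[1] < 2:
        raise ValueError("ld_scan needs at least 2 loci")
    lrt, p, separated = _logistic_lrt_binary(X)
    loci = ds.band_matrix.locus_ids
    iu, ju = np.triu_indices(len(loci), k=1)
    pv = p[iu, ju]
    qv = multipletests(pv, alpha=fdr, method="fdr_bh")[1]
    pairs = pd.DataFrame({
        "locus_a": np.asarray(loci, dtype=object)[iu],
        "locus_b": np.asarray(loci, dtype=object)[ju],
        "lrt": lrt[iu, ju], "p": pv, "q": qv,
        "flagged": separated[iu, ju]})
    frac = {c: float(np.mean(pv < c)) for c in cutoffs}
    return LdScanResult(pairs=pairs, fraction_significant=frac, n_pairs=len(pv))


# ---------------------------------------------------------------------------
# Frequency filter
# ---------------------------------------------------------------------------

def frequency_filter(ds: Dataset, min_f: float = 0.05, max_f: float = 0.95):
    """Drop loci with overall band frequency outside [min_f, max_f] (closed).

    Returns (filtered Dataset, kept locus list, dropped locus list).
    Idempotent. Raises if nothing survives.
    """
    X = ds.drop_replicates().band_matrix.presence
    f = X.to_numpy().mean(axis=0)
    keep_mask = (f >= min_f) & (f <= max_f)
    kept = list(np.asarray(X.columns, dtype=object)[keep_mask])
    dropped = list(np.asarray(X.columns, dtype=object)[~keep_mask])
    if not kept:
        raise ValueError("frequency filter removed every locus")
    return ds.subset_loci(kept), kept, dropped


# ---------------------------------------------------------------------------
# Redundant-locus reduction
# ---------------------------------------------------------------------------

@dataclass
class RedundancyReport:
    clusters: list[list[str]]      # clusters of size >= 2, representative first
    kept: list[str]
    dropped: list[str]


def redundant_locus_clusters(ds: Dataset, identity_threshold: float = 1.0):
    """Cluster loci with (near-)identical presence vectors; keep one each.

    Loci whose column concordance (fraction of equal calls across
    individuals) reaches ``identity_threshold`` are single-linkage
    clustered; the representative is the earliest locus by column order.
    Returns (reduced Dataset, RedundancyReport).
    """
    dsr = ds.drop_replicates()
    X = dsr.band_matrix.values().astype(np.float64)
    N, L = X.shape
    conc = (X.T @ X + (1 - X).T @ (1 - X)) / N
    adj = csr_matrix(conc >= identity_threshold)
    _, labels = connected_components(adj, directed=False)
    loci = np.asarray(ds.band_matrix.locus_ids, dtype=object)
    clusters, kept, dropped = [], [], []
    for lab in pd.unique(labels):
        members = list(loci[labels == lab])
        kept.append(members[0])
        if len(members) > 1:
            clusters.append(members)
            dropped.extend(members[1:])
    kept = [l for l in loci if l in set(kept)]  # preserve column order
    return ds.subset_loci(kept), RedundancyReport(clusters=clusters, kept=kept,
                                                  dropped=dropped)
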