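"""Population differentiation and clustering for dominant markers.

Fst is computed on Bayesian allele-frequency estimates: the per-locus
among-population variance of q_hat, corrected for estimation noise by
subtracting the mean posterior variance of q_hat, over the total
heterozygosity term q_bar (1 - q_bar); loci are combined as a ratio of
sums. Phi_PT is the AMOVA analogue computed directly on squared Euclidean
distances between binary phenotypes, with permutation significance. Nei's
standard distance, PCoA, bootstrap NJ consensus trees and the Mantel
isolation-by-distance test round out the standard toolbox.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import mantel as _skbio_mantel
from skbio.stats.ordination import pcoa as _skbio_pcoa
from skbio.tree import nj as _skbio_nj

from .freqs import AlleleFreqTable, posterior_q_lookup
from .io_core import Dataset
from .geo import pairwise_haversine_km


# ---------------------------------------------------------------------------
# Fst on estimated allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    fst: float
    sd_over_loci: float
    p_value: float | None
    n_permutations: int
    F_is: float
    per_locus: pd.Series


def _fst_from_moments(q_hat: np.ndarray, q_var: np.ndarray):
    """(per-locus numerator, denominator) of the noise-corrected Fst ratio.

    The numerator is the plug-in (ddof=0 scale) among-population variance of
    q_hat with the mean posterior variance of q_hat subtracted as the
    estimation-noise term; the denominator is the total term q_bar(1-q_bar),
    so complete fixation for alternative bands approaches 1.
    """
    r = q_hat.shape[0]
    s2_obs = q_hat.var(axis=0, ddof=1)
    sampling = q_var.mean(axis=0)
    qbar = q_hat.mean(axis=0)
    num = (s2_obs - sampling) * (r - 1) / r
    den = qbar * (1.0 - qbar)
    return num, den


def fst_global(aft: AlleleFreqTable, ds: Dataset | None = None,
               n_perm: int = 100, seed: int | None = 0) -> FstResult:
    """Global Fst over loci with a permutation test.

    The p-value permutes individuals among populations (sizes preserved),
    re-estimating frequencies each time; it requires ``ds``. Monomorphic
    datasets (zero denominator at every locus) are an error.
    """
    if len(aft.populations) < 2:
        raise ValueError("fst_global needs >= 2 populations")
    q = aft.q_hat.to_numpy()
    v = aft.q_var.to_numpy()
    num, den = _fst_from_moments(q, v)
    usable = den > 1e-12
    if not usable.any():
        raise ValueError("Fst undefined: dataset monomorphic at every locus")
    fst = float(max(num[usable].sum() / den[usable].sum(), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        per_locus = np.where(usable, num / den, np.nan)
    per_locus = pd.Series(per_locus, index=aft.loci, name="fst")
    p_value = None
    if ds is not None and n_perm > 0:
        rng = np.random.default_rng(seed)
        dsr = ds.drop_replicates()
        X = dsr.band_matrix.values()
        pops = dsr.population_of().to_numpy()
        sizes = pd.Series(pops).value_counts().sort_index()
        a, b = aft.prior
        lut = {int(n): posterior_q_lookup(int(n), aft.F, a, b) for n in sizes.unique()}
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(pops))
            qp, vp = _permuted_moments(X[perm], pops, sizes, lut)
            nump, denp = _fst_from_moments(qp, vp)
            up = denp > 1e-12
            fp = nump[up].sum() / denp[up].sum() if up.any() else 0.0
            if fp >= fst:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return FstResult(fst=fst, sd_over_loci=float(per_locus.std()),
                     p_value=p_value, n_permutations=n_perm, F_is=aft.F,
                     per_locus=per_locus)


def _permuted_moments(X, pops, sizes, lut):
    qs, vs = [], []
    start = 0
    order = sizes.index.to_numpy()
    # contiguous blocks after permutation keep population sizes fixed
    for pop in order:
        n = int(sizes[pop])
        k = n - X[start:start + n].sum(axis=0)
        Eq, Vq, _ = lut[n]
        qs.append(Eq[k])
        vs.append(Vq[k])
        start += n
    return np.stack(qs), np.stack(vs)


# ---------------------------------------------------------------------------
# AMOVA / Phi_PT
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    var_among: float       # sigma^2_AP
    var_within: float      # sigma^2_WP
    phi_pt: float
    p_value: float | None
    n_permutations: int


def _amova_from_sq(d2: np.ndarray, groups: np.ndarray) -> AmovaResult:
    """AMOVA components from a squared-distance matrix and group labels."""
    N = len(groups)
    labels, counts = np.unique(groups, return_counts=True)
    r = len(labels)
    ss_total = d2.sum() / (2.0 * N)
    ss_within = 0.0
    for g, n_g in zip(labels, counts):
        idx = np.flatnonzero(groups == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * n_g)
    ss_among = ss_total - ss_within
    df_among, df_within = r - 1, N - r
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among
    n0 = (N - (counts ** 2).sum() / N) / df_among
    var_within = ms_within
    var_among = max((ms_among - ms_within) / n0, 0.0) if n0 > 0 else 0.0
    tot = var_among + var_within
    phi = var_among / tot if tot > 0 else 0.0
    return AmovaResult(ss_among=ss_among, ss_within=ss_within,
                       df_among=df_among, df_within=df_within,
                       var_among=var_among, var_within=var_within,
                       phi_pt=phi, p_value=None, n_permutations=0)


def phipt_amova(ds: Dataset, grouping: str | pd.Series = "population_id",
                n_perm: int = 999, seed: int | None = 0) -> AmovaResult:
    """Phi_PT by AMOVA on squared Euclidean distances between phenotypes.

    ``grouping`` is a sample-table column name ("population_id",
    "habitat") or an individual -> group Series. Permutation p shuffles
    group labels among individuals.
    """
    dsr = ds.drop_replicates()
    X = dsr.band_matrix.values().astype(np.float64)
    if isinstance(grouping, str):
        groups = dsr.samples.table.loc[dsr.band_matrix.individual_ids, grouping].to_numpy()
    else:
        groups = grouping.loc[dsr.band_matrix.individual_ids].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("phipt_amova needs >= 2 groups")
    if (pd.Series(groups).value_counts() == 1).any():
        warnings.warn("group of size 1 present; within-group variance relies "
                      "on the remaining groups", stacklevel=2)
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2) \
        if X.shape[0] <= 600 else _sq_euclidean(X)
    res = _amova_from_sq(sq, groups)
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            res_p = _amova_from_sq(sq, rng.permutation(groups))
            if res_p.phi_pt >= res.phi_pt:
                hits += 1
        res.p_value = (hits + 1) / (n_perm + 1)
        res.n_permutations = n_perm
    return res


def _sq_euclidean(X):
    G = X @ X.T
    d = np.diag(G)
    return np.maximum(d[:, None] + d[None, :] - 2 * G, 0.0)


def pairwise_phipt(ds: Dataset, n_perm: int = 999, seed: int | None = 0) -> pd.DataFrame:
    """Symmetric matrix of pairwise Phi_PT between populations."""
    pops = ds.population_ids
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    rng = np.random.default_rng(seed)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            sub = ds.subset_populations([a, b])
            res = phipt_amova(sub, "population_id", n_perm=n_perm,
                              seed=int(rng.integers(2 ** 31)))
            out.loc[a, b] = out.loc[b, a] = res.phi_pt
    return out


# ---------------------------------------------------------------------------
# Nei distance, PCoA
# ---------------------------------------------------------------------------

def nei_distance_matrix(aft: AlleleFreqTable) -> pd.DataFrame:
    """Nei's standard genetic distance between populations.

    D = -ln( J_xy / sqrt(J_x J_y) ), with J the expected two-allele
    homozygosity averaged over loci: J_x = mean(q^2 + (1-q)^2),
    J_xy = mean(q_x q_y + (1-q_x)(1-q_y)). Non-positive J_xy yields NA
    with a warning.
    """
    Q = aft.q_hat.to_numpy()
    P = 1.0 - Q
    Jxy = (Q @ Q.T + P @ P.T) / Q.shape[1]
    Jx = np.diag(Jxy)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = -np.log(Jxy / np.sqrt(Jx[:, None] * Jx[None, :]))
    if (Jxy <= 0).any():
        warnings.warn("non-positive Nei identity; NA entries produced", stacklevel=2)
        D[Jxy <= 0] = np.nan
    np.fill_diagonal(D, 0.0)
    D = np.maximum(D, 0.0) if not np.isnan(D).any() else D
    return pd.DataFrame(D, index=aft.populations, columns=aft.populations)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dm: pd.DataFrame) -> PcoaResult:
    """Classical metric scaling of a symmetric distance matrix."""
    if dm.isna().to_numpy().any():
        raise ValueError("distance matrix contains NA entries; impute or drop "
                         "the affected populations first")
    sk = _skbio_pcoa(SkbioDM(dm.to_numpy(), ids=[str(i) for i in dm.index]),
                     number_of_dimensions=min(10, len(dm) - 1))
    coords = pd.DataFrame(sk.samples.to_numpy(), index=dm.index,
                          columns=[f"PCo{i+1}" for i in range(sk.samples.shape[1])])
    return PcoaResult(coordinates=coords,
                      eigenvalues=sk.eigvals.to_numpy(),
                      proportion_explained=sk.proportion_explained.to_numpy())


# ---------------------------------------------------------------------------
# Bootstrap NJ consensus
# ---------------------------------------------------------------------------

@dataclass
class NjConsensusResult:
    newick: str                    # midpoint-rooted full-data NJ with % support
    consensus_newick: str          # majority-rule consensus topology
    n_boot_used: int
    n_dropped: int


def _nj_newick(dm: pd.DataFrame) -> str:
    ids = [str(i) for i in dm.index]
    tree = _skbio_nj(SkbioDM(np.ascontiguousarray(dm.to_numpy(), dtype=float), ids=ids))
    return str(tree)


def nj_consensus(ds: Dataset, aft_builder, n_boot: int = 100,
                 seed: int | None = 0) -> NjConsensusResult:
    """Bootstrap (over loci) neighbour-joining consensus tree.

    ``aft_builder(dataset) -> AlleleFreqTable`` recomputes frequencies on
    each locus-resampled replicate. The reported tree is the full-data NJ
    tree, midpoint-rooted, with internal labels giving the percentage of
    bootstrap replicates containing each bipartition; the strict
    majority-rule consensus topology is returned alongside. Replicates with
    undefined Nei distances are dropped (counted).
    """
    if len(ds.populations) < 4:
        raise ValueError("nj_consensus needs >= 4 populations")
    rng = np.random.default_rng(seed)
    loci = ds.band_matrix.locus_ids
    taxa = dendropy.TaxonNamespace()
    boot_trees = dendropy.TreeList(taxon_namespace=taxa)
    dropped = 0
    for _ in range(n_boot):
        resampled = list(np.asarray(loci, dtype=object)[
            rng.integers(0, len(loci), size=len(loci))])
        # duplicated column labels are not allowed; rename on the fly
        sub = ds.band_matrix.presence[resampled]
        sub.columns = [f"b{i}" for i in range(len(resampled))]
        rep_ds = Dataset(
            type(ds.band_matrix)(sub, None), ds.samples, populations=ds.populations)
        aft = aft_builder(rep_ds)
        dmat = nei_distance_matrix(aft)
        if dmat.isna().to_numpy().any():
            dropped += 1
            continue
        boot_trees.append(dendropy.Tree.get(
            data=_nj_newick(dmat), schema="newick", taxon_namespace=taxa))
    if not boot_trees:
        raise ValueError("all bootstrap replicates dropped")
    full_aft = aft_builder(ds)
    full_dm = nei_distance_matrix(full_aft)
    full = dendropy.Tree.get(data=_nj_newick(full_dm), schema="newick",
                             taxon_namespace=taxa)
    # per-bipartition bootstrap support on the full tree, as % of replicates
    split_freqs = boot_trees.split_distribution(is_bipartitions_updated=False)
    full.encode_bipartitions()
    for edge in full.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or head.parent_node is None:
            continue
        freq = split_freqs.split_frequencies.get(edge.bipartition.split_bitmask, 0.0)
        head.label = f"{100.0 * freq:.0f}"
    full.reroot_at_midpoint(update_bipartitions=True)
    consensus = boot_trees.consensus(min_freq=0.5)
    return NjConsensusResult(
        newick=full.as_string(schema="newick").strip(),
        consensus_newick=consensus.as_string(schema="newick").strip(),
        n_boot_used=len(boot_trees), n_dropped=dropped)


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance
# ---------------------------------------------------------------------------

def mantel_ibd(genetic_dm: pd.DataFrame, geographic_dm: pd.DataFrame,
               n_perm: int = 999, seed: int | None = 0) -> tuple[float, float]:
    """One-sided Mantel test of isolation by distance.

    Pearson correlation of the off-diagonal entries; p-value by permuting
    rows/columns of one matrix (p >= 1/(n_perm+1), the observed statistic
    counts as part of the null set).
    """
    if list(genetic_dm.index) != list(geographic_dm.index):
        geographic_dm = geographic_dm.loc[genetic_dm.index, genetic_dm.index]
    for m in (genetic_dm, geographic_dm):
        off = m.to_numpy()[~np.eye(len(m), dtype=bool)]
        if np.ptp(off) == 0:
            raise ValueError("constant distance matrix: Mantel r undefined")
    ids = [str(i) for i in genetic_dm.index]
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        np.random.seed(int(rng.integers(2 ** 31)))  # skbio permutes via global RNG
        r, p, _ = _skbio_mantel(SkbioDM(genetic_dm.to_numpy(), ids=ids),
                                SkbioDM(geographic_dm.to_numpy(), ids=ids),
                                method="pearson", permutations=n_perm,
                                alternative="greater")
    return float(r), float(p)


def geographic_distance_matrix(ds: Dataset) -> pd.DataFrame:
    """Great-circle distances (km) between population centroids."""
    cent = ds.population_centroids()
    D = pairwise_haversine_km(cent["lon"].to_numpy(), cent["lat"].to_numpy())
    return pd.DataFrame(D, index=cent.index, columns=cent.index)
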