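import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

import dompop as dp
from dompop.freqs import AlleleFreqTable
from dompop.simulate import SimParams, simulate_metapopulation

from conftest import make_dataset

F91 = 0.91 / 1.09


def _aft_from_q(q_by_pop: dict[str, list[float]]):
    q = pd.DataFrame(q_by_pop).T
    q.columns = [f"L{k}" for k in range(q.shape[1])]
    return AlleleFreqTable(q_hat=q, q_var=q * 0.0, f_hat=1 - q,
                           n=pd.Series(10, index=q.index),
                           k_absent=(q * 0).astype(int), F=0.0, prior=(1.0, 1.0))


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def test_fst_identical_populations_near_zero():
    rng = np.random.default_rng(0)
    block = (rng.random((20, 100)) < 0.4).astype(int)
    ds = make_dataset(np.vstack([block, block]), ["A"] * 20 + ["B"] * 20)
    res = dp.fst_global(dp.estimate_allele_freqs(ds, F91), None, n_perm=0)
    assert res.fst == pytest.approx(0.0, abs=0.01)


def test_fst_fixed_alternative_bands_near_one():
    X = np.zeros((40, 50), dtype=int)
    X[:20, :25] = 1
    X[20:, 25:] = 1
    ds = make_dataset(X, ["A"] * 20 + ["B"] * 20)
    res = dp.fst_global(dp.estimate_allele_freqs(ds, F91), None, n_perm=0)
    assert res.fst > 0.85


def test_fst_monomorphic_is_error():
    ds = make_dataset(np.ones((10, 5), dtype=int), ["A"] * 5 + ["B"] * 5)
    aft = dp.estimate_allele_freqs(ds, F91, prior=(0.001, 0.001))
    aft.q_hat[:] = 1.0
    aft.q_var[:] = 0.0
    with pytest.raises(ValueError, match="monomorphic"):
        dp.fst_global(aft, None, n_perm=0)


def test_fst_permutation_p_floor(two_pop_dataset):
    aft = dp.estimate_allele_freqs(two_pop_dataset, F91)
    res = dp.fst_global(aft, two_pop_dataset, n_perm=19, seed=0)
    assert res.p_value >= 1 / 20
    assert res.n_permutations == 19


def test_fst_and_phipt_near_invariant_under_duplication():
    """Duplicating every individual changes results only through the
    sample-size-dependent corrections (posterior shrinkage, AMOVA df)."""
    params = SimParams(pop_sizes={f"P{i}": 15 for i in range(6)},
                       habitats={f"P{i}": "dune" for i in range(6)},
                       n_loci=200, fst=0.12, selfing=0.91, seed=9)
    ds, _ = simulate_metapopulation(params)
    X = ds.band_matrix.values()
    pops = ds.population_of().to_numpy()
    dup = make_dataset(np.repeat(X, 2, axis=0), list(np.repeat(pops, 2)))
    f1 = dp.fst_global(dp.estimate_allele_freqs(ds, F91, prior="uniform"),
                       None, n_perm=0).fst
    f2 = dp.fst_global(dp.estimate_allele_freqs(dup, F91, prior="uniform"),
                       None, n_perm=0).fst
    assert abs(f1 - f2) < 0.05
    p1 = dp.phipt_amova(ds, n_perm=0).phi_pt
    p2 = dp.phipt_amova(dup, n_perm=0).phi_pt
    assert abs(p1 - p2) < 0.05


# ---------------------------------------------------------------------------
# AMOVA / Phi_PT
# ---------------------------------------------------------------------------

def test_amova_hand_worked_toy():
    X = np.array([[1, 1, 0, 0], [1, 0, 0, 0], [1, 1, 1, 0],
                  [0, 0, 1, 1], [0, 1, 1, 1], [0, 0, 1, 0]])
    ds = make_dataset(X, ["A"] * 3 + ["B"] * 3,
                      habitats=["dune"] * 3 + ["fen"] * 3)
    res = dp.phipt_amova(ds, "population_id", n_perm=0)
    # frozen from an independent hand calculation on the squared distances
    assert res.ss_among == pytest.approx(3.0)
    assert res.ss_within == pytest.approx(8 / 3)
    assert res.df_among == 1 and res.df_within == 4
    assert res.phi_pt == pytest.approx(0.5384615384615385)


def test_amova_identical_groups():
    rng = np.random.default_rng(1)
    block = (rng.random((10, 40)) < 0.5).astype(int)
    ds = make_dataset(np.vstack([block, block]), ["A"] * 10 + ["B"] * 10)
    res = dp.phipt_amova(ds, n_perm=99, seed=0)
    assert res.phi_pt == pytest.approx(0.0, abs=1e-9)
    assert res.p_value > 0.2


def test_amova_null_p_roughly_uniform():
    rng = np.random.default_rng(2)
    ps = []
    for seed in range(10):
        X = (rng.random((24, 40)) < 0.5).astype(int)
        ds = make_dataset(X, ["A"] * 12 + ["B"] * 12)
        ps.append(dp.phipt_amova(ds, n_perm=99, seed=seed).p_value)
    ps = np.array(ps)
    assert ps.min() < 0.9 and ps.max() > 0.1   # not degenerate
    assert 0.1 < ps.mean() < 0.9


def test_pairwise_phipt_symmetric():
    rng = np.random.default_rng(3)
    X = (rng.random((30, 50)) < rng.random(50)).astype(int)
    ds = make_dataset(X, ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
    m = dp.pairwise_phipt(ds, n_perm=0)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 0)


# ---------------------------------------------------------------------------
# Nei distance & PCoA
# ---------------------------------------------------------------------------

def test_nei_distance_zero_for_identical_frequencies():
    aft = _aft_from_q({"X": [0.2, 0.6], "Y": [0.2, 0.6]})
    dm = dp.nei_distance_matrix(aft)
    assert dm.loc["X", "Y"] == pytest.approx(0.0, abs=1e-12)
    assert dm.loc["X", "X"] == 0.0


def test_nei_distance_hand_toy():
    aft = _aft_from_q({"X": [0.2, 0.6], "Y": [0.3, 0.5]})
    dm = dp.nei_distance_matrix(aft)
    assert dm.loc["X", "Y"] == pytest.approx(0.01631261365803845, abs=1e-10)


def test_pcoa_three_equidistant_points():
    D = pd.DataFrame(1.0 - np.eye(3), index=list("ABC"), columns=list("ABC"))
    res = dp.pcoa(D)
    pos = res.eigenvalues[res.eigenvalues > 1e-12]
    assert len(pos) == 2
    assert pos[0] == pytest.approx(pos[1])


def test_pcoa_recovers_planted_configuration():
    rng = np.random.default_rng(4)
    pts = rng.random((8, 2)) * 10
    ids = [f"p{i}" for i in range(8)]
    D = pd.DataFrame(squareform(pdist(pts)), index=ids, columns=ids)
    res = dp.pcoa(D)
    _, _, disparity = procrustes(pts, res.coordinates.to_numpy()[:, :2])
    assert disparity <= 1e-8
    # sum of positive eigenvalues equals the trace of the centred matrix
    assert res.eigenvalues.sum() == pytest.approx(
        np.sum(res.coordinates.to_numpy() ** 2), rel=1e-6)


def test_pcoa_rejects_na():
    D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=list("AB"),
                     columns=list("AB"))
    with pytest.raises(ValueError, match="NA"):
        dp.pcoa(D)


# ---------------------------------------------------------------------------
# NJ consensus
# ---------------------------------------------------------------------------

def _clustered_dataset(seed=0):
    """Six populations in two clearly diverged clades."""
    rng = np.random.default_rng(seed)
    f1 = rng.beta(2, 2, 120)
    f2 = np.clip(1 - f1 + rng.normal(0, 0.05, 120), 0.02, 0.98)
    rows, pops = [], []
    for j, base in enumerate([f1, f1, f1, f2, f2, f2]):
        f = np.clip(base + rng.normal(0, 0.04, 120), 0.01, 0.99)
        rows.append((rng.random((10, 120)) < f).astype(int))
        pops += [f"P{j}"] * 10
    return make_dataset(np.vstack(rows), pops)


def _builder(d):
    return dp.estimate_allele_freqs(d, F91, prior="uniform")


def test_nj_consensus_single_bootstrap_matches_replicate():
    ds = _clustered_dataset()
    res = dp.nj_consensus(ds, _builder, n_boot=1, seed=1)
    assert res.n_boot_used == 1
    tns = dendropy.TaxonNamespace()
    cons = dendropy.Tree.get(data=res.consensus_newick, schema="newick",
                             taxon_namespace=tns)
    assert {l.taxon.label for l in cons.leaf_node_iter()} == {f"P{j}" for j in range(6)}


def test_nj_consensus_strong_clades_high_support():
    ds = _clustered_dataset(seed=2)
    res = dp.nj_consensus(ds, _builder, n_boot=30, seed=0)
    tree = dendropy.Tree.get(data=res.newick, schema="newick")
    # find the bipartition separating P0-2 from P3-5 and read its support
    tree.encode_bipartitions()
    supports = []
    for node in tree.preorder_node_iter():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if leaves in ({"P0", "P1", "P2"}, {"P3", "P4", "P5"}) and node.label:
            supports.append(float(node.label))
    assert supports and max(supports) >= 95
    # all support labels are valid percentages
    for node in tree.preorder_node_iter():
        if node.label:
            assert 0 <= float(node.label) <= 100


def test_nj_recovers_additive_topology():
    from dompop.structure import _nj_newick
    D = pd.DataFrame(np.array([[0, 3, 9, 10], [3, 0, 10, 11],
                               [9, 10, 0, 5], [10, 11, 5, 0]], dtype=float),
                     index=list("ABCD"), columns=list("ABCD"))
    tree = dendropy.Tree.get(data=_nj_newick(D), schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    # additive distances are reproduced exactly -> topology AB|CD
    for a, b, d in [("A", "B", 3), ("C", "D", 5), ("A", "C", 9), ("B", "D", 11)]:
        assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(d)


def test_nj_consensus_needs_four_populations(two_pop_dataset):
    with pytest.raises(ValueError, match=">= 4"):
        dp.nj_consensus(two_pop_dataset, _builder, n_boot=2, seed=0)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _dm(ids, arr):
    return pd.DataFrame(arr, index=ids, columns=ids)


def test_mantel_identical_matrices():
    rng = np.random.default_rng(1)
    pts = rng.random((10, 2))
    ids = [f"p{i}" for i in range(10)]
    D = _dm(ids, squareform(pdist(pts)))
    r, p = dp.mantel_ibd(D, D, n_perm=999, seed=0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1000)


def test_mantel_linear_construction():
    rng = np.random.default_rng(2)
    pts = rng.random((12, 2))
    ids = [f"p{i}" for i in range(12)]
    G = squareform(pdist(pts))
    noise = rng.normal(0, 1e-3, G.shape)
    noise = (noise + noise.T) / 2
    H = 0.3 + 2.0 * G + noise
    np.fill_diagonal(H, 0)
    r, p = dp.mantel_ibd(_dm(ids, H), _dm(ids, G), n_perm=999, seed=0)
    assert r > 0.9 and p <= 0.001


def test_mantel_independent_null():
    rng = np.random.default_rng(3)
    ids = [f"p{i}" for i in range(10)]
    def rand_dm():
        a = rng.random((10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return _dm(ids, a)
    ps = [dp.mantel_ibd(rand_dm(), rand_dm(), n_perm=99, seed=s)[1]
          for s in range(8)]
    assert min(ps) > 0.001 or max(ps) > 0.3   # not systematically significant


def test_mantel_constant_matrix_error():
    ids = list("ABC")
    D = _dm(ids, 1.0 - np.eye(3))
    with pytest.raises(ValueError, match="constant"):
        dp.mantel_ibd(D, D, n_perm=99)
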