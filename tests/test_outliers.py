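import numpy as np
import pandas as pd
import pytest

import dompop as dp
from dompop.outliers import (ComparisonSpec, McmcSettings, OutlierCallSet,
                             _group_counts, spike_slab_scan)
from dompop.simulate import SimParams, simulate_metapopulation

from conftest import make_dataset

F91 = 0.91 / 1.09


def _habitat_ds(n_dune=2, n_fen=2, n_per=10, L=40, seed=0, **sim_kw):
    pops = {f"D{i}": n_per for i in range(n_dune)}
    pops.update({f"F{i}": n_per for i in range(n_fen)})
    habs = {p: ("dune" if p.startswith("D") else "fen") for p in pops}
    params = SimParams(pop_sizes=pops, habitats=habs, n_loci=L, fst=0.09,
                       selfing=0.91, seed=seed, **sim_kw)
    return simulate_metapopulation(params)


# ---------------------------------------------------------------------------
# Comparison construction
# ---------------------------------------------------------------------------

def test_build_comparisons_combinatorics():
    ds, _ = _habitat_ds(2, 2)
    comps = dp.build_comparisons(ds, scales={"landscape": list(ds.populations)})
    pooled = [c for c in comps if c.kind == "pooled"]
    pairs = [c for c in comps if c.kind == "pairwise"]
    assert len(pooled) == 1 and len(pairs) == 6
    assert sum(c.control for c in pairs) == 2
    assert sum(c.between_habitat for c in pairs) == 4
    # pooled group sizes match the declared memberships exactly
    (nA, _), (nB, _) = _group_counts(ds, pooled[0])
    assert nA == 20 and nB == 20


def test_build_comparisons_single_habitat_skips_pooled():
    rng = np.random.default_rng(0)
    X = (rng.random((12, 10)) < 0.5).astype(int)
    ds = make_dataset(X, ["A"] * 6 + ["B"] * 6, habitats=["dune"] * 12)
    with pytest.warns(UserWarning, match="single habitat"):
        comps = dp.build_comparisons(ds, scales={"landscape": ["A", "B"]})
    assert all(c.kind == "pairwise" for c in comps)


def test_multi_scale_pooled_specs():
    ds, _ = _habitat_ds(3, 3)
    scales = {"continental": list(ds.populations),
              "regional": ["D0", "F0", "D1", "F1"]}
    comps = dp.build_comparisons(ds, scales, pairwise_scale="regional")
    pooled = {c.scale for c in comps if c.kind == "pooled"}
    assert pooled == {"continental", "regional"}
    pairs = [c for c in comps if c.kind == "pairwise"]
    assert len(pairs) == 6   # 4 choose 2 within the regional scale


# ---------------------------------------------------------------------------
# Envelope null and detector
# ---------------------------------------------------------------------------

def test_envelope_self_consistent_calibration():
    ds, _ = _habitat_ds(3, 3, n_per=15, L=150, seed=1)
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    env = dp.envelope_null(ds, spec, F91, n_sim=20000, seed=0)
    assert abs(env.achieved_fst - env.target_fst) <= 0.01


def test_envelope_collapses_at_tiny_fst():
    ds, _ = _habitat_ds(2, 2, n_per=20, L=60, seed=2)
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    from dompop.outliers import _simulate_null
    rng = np.random.default_rng(0)
    fst_small, _ = _simulate_null(np.full(5000, 0.5), 0.002, 40, 40, F91, 5000, rng)
    fst_big, _ = _simulate_null(np.full(5000, 0.5), 0.2, 40, 40, F91, 5000, rng)
    # the null envelope collapses towards the sampling-noise floor as the
    # target differentiation goes to zero
    assert np.nanquantile(fst_small, 0.995) < 0.3 * np.nanquantile(fst_big, 0.995)
    assert np.nanmean(fst_small) < 0.01


def test_envelope_quantiles_monotone():
    ds, _ = _habitat_ds(3, 3, n_per=15, L=100, seed=3)
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    env = dp.envelope_null(ds, spec, F91, n_sim=15000, seed=1)
    he = np.linspace(0.05, 0.45, 9)
    q50 = env.quantile(he, 0.5)
    q99 = env.quantile(he, 0.99)
    assert np.all(q99 >= q50)


def test_envelope_detect_monomorphic_never_outlier():
    ds, _ = _habitat_ds(2, 2, n_per=15, L=50, seed=4)
    # force one locus monomorphic present everywhere
    ds.band_matrix.presence.iloc[:, 0] = 1
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    env = dp.envelope_null(ds, spec, F91, n_sim=10000, seed=0)
    calls = dp.envelope_detect(ds, spec, env)
    locus0 = calls.calls.iloc[0]
    assert not locus0["decision"] and locus0["p"] == 1.0


def test_envelope_detect_locus_order_invariant():
    ds, _ = _habitat_ds(3, 3, n_per=15, L=60, seed=5)
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    env = dp.envelope_null(ds, spec, F91, n_sim=10000, seed=0)
    calls = dp.envelope_detect(ds, spec, env).calls.set_index("locus")
    perm = list(np.random.default_rng(0).permutation(ds.band_matrix.locus_ids))
    ds2 = ds.subset_loci(perm)
    calls2 = dp.envelope_detect(ds2, spec, env).calls.set_index("locus")
    for loc in perm:
        assert calls.loc[loc, "decision"] == calls2.loc[loc, "decision"]
        assert calls.loc[loc, "p"] == calls2.loc[loc, "p"]


def test_envelope_detects_planted_strong_locus():
    ds, truth = _habitat_ds(6, 6, n_per=15, L=100, seed=7,
                            n_selected=1, delta=2.5)
    spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
            if c.kind == "pooled"][0]
    env = dp.envelope_null(ds, spec, F91, n_sim=40000, seed=0)
    calls = dp.envelope_detect(ds, spec, env)
    flagged = set(calls.calls.loc[calls.calls["decision"], "locus"])
    assert truth.selected_loci[0] in flagged


# ---------------------------------------------------------------------------
# Bayesian detector
# ---------------------------------------------------------------------------

def test_bayes_prior_only_recovers_prior_inclusion():
    rng = np.random.default_rng(0)
    n = np.full((2, 2), 20)
    k = rng.integers(0, 21, size=(2, 60, 2))
    post, _ = spike_slab_scan(n, k, F91, McmcSettings(n_iter=3000, burn_in=1000),
                              seed=1, likelihood_on=False)
    assert post.mean() == pytest.approx(1 / 11, abs=0.04)


def test_bayes_planted_strong_locus_power():
    # stack several seeded pooled comparisons into one sampler run
    ns, ks, planted = [], [], []
    for seed in range(8):
        ds, truth = _habitat_ds(6, 6, n_per=15, L=80, seed=20 + seed,
                                n_selected=1, delta=3.0)
        spec = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
                if c.kind == "pooled"][0]
        (nA, kA), (nB, kB) = _group_counts(ds, spec)
        ns.append((nA, nB))
        ks.append(np.column_stack([kA, kB]))
        planted.append(ds.band_matrix.locus_ids.index(truth.selected_loci[0]))
    post, rhat = spike_slab_scan(np.array(ns), np.array(ks), F91,
                                 McmcSettings(), seed=0)
    hits = sum(post[c, planted[c]] >= 0.91 for c in range(8))
    assert hits >= 6   # power >= ~80% for a strong planted effect
    assert np.isfinite(rhat).all()


def test_bayes_neutral_rarely_flags():
    ds, _ = _habitat_ds(3, 3, n_per=15, L=100, seed=30)
    comps = [c for c in dp.build_comparisons(ds, {"s": list(ds.populations)})
             if c.kind == "pooled"]
    calls = dp.bayes_detect_many(ds, comps, seed=1, F_is=F91)
    assert calls.calls["decision"].mean() <= 0.01


# ---------------------------------------------------------------------------
# Consensus and replication rules
# ---------------------------------------------------------------------------

def _specs():
    mk = lambda name, kind, ga, gb, ha, hb: ComparisonSpec(
        name=name, kind=kind, scale="s", group_a=ga, group_b=gb,
        habitat_a=ha, habitat_b=hb, control=(ha == hb))
    return [
        mk("pooled:s", "pooled", ["D1", "D2"], ["F1", "F2"], "dune", "fen"),
        mk("pair:D1|F1", "pairwise", ["D1"], ["F1"], "dune", "fen"),
        mk("pair:D2|F2", "pairwise", ["D2"], ["F2"], "dune", "fen"),
        mk("pair:D1|F2", "pairwise", ["D1"], ["F2"], "dune", "fen"),
        mk("pair:F1|F2", "pairwise", ["F1"], ["F2"], "fen", "fen"),
    ]


def _calls(rows):
    return OutlierCallSet(pd.DataFrame(
        rows, columns=["comparison", "locus", "detector", "statistic", "he",
                       "p", "decision"]))


def test_consensus_both_detectors_pooled_significant():
    calls = _calls([
        ("pooled:s", "L1", "envelope", 0.4, 0.3, 0.001, True),
        ("pooled:s", "L1", "bayes", 0.95, 0.3, 0.05, True),
    ])
    cr = dp.consensus_outliers(calls, _specs())
    assert cr.significant == {"L1": ["pooled:s"]}
    assert cr.rejected_by_control == {}


def test_consensus_envelope_only_not_significant():
    calls = _calls([("pooled:s", "L1", "envelope", 0.4, 0.3, 0.001, True)])
    cr = dp.consensus_outliers(calls, _specs())
    assert cr.significant == {}


def test_consensus_control_comparison_rejects():
    # flagged in a pooled comparison by both detectors, but also in a
    # fen-fen control pair: rejected
    calls = _calls([
        ("pooled:s", "L1", "envelope", 0.4, 0.3, 0.001, True),
        ("pooled:s", "L1", "bayes", 0.95, 0.3, 0.05, True),
        ("pair:F1|F2", "L1", "bayes", 0.93, 0.3, 0.07, True),
    ])
    cr = dp.consensus_outliers(calls, _specs())
    assert cr.significant == {}
    assert cr.rejected_by_control == {"L1": ["pair:F1|F2"]}


def test_consensus_pairwise_bayes_path():
    calls = _calls([("pair:D1|F1", "L7", "bayes", 0.95, 0.3, 0.05, True)])
    cr = dp.consensus_outliers(calls, _specs())
    assert cr.significant == {"L7": ["pair:D1|F1"]}


def test_consensus_is_pure_function():
    calls = _calls([("pair:D1|F1", "L7", "bayes", 0.95, 0.3, 0.05, True)])
    a = dp.consensus_outliers(calls, _specs())
    b = dp.consensus_outliers(calls, _specs())
    assert a.significant == b.significant
    assert a.rejected_by_control == b.rejected_by_control


def test_replicated_requires_population_disjoint_pairs():
    specs = _specs()
    disjoint = _calls([
        ("pair:D1|F1", "L7", "bayes", 0.95, 0.3, 0.05, True),
        ("pair:D2|F2", "L7", "bayes", 0.94, 0.3, 0.06, True),
    ])
    cr = dp.consensus_outliers(disjoint, specs)
    rep = dp.replicated_outliers(cr, specs)
    assert set(rep) == {"L7"}
    assert ("pair:D1|F1", "pair:D2|F2") in rep["L7"]

    shared = _calls([
        ("pair:D1|F1", "L7", "bayes", 0.95, 0.3, 0.05, True),
        ("pair:D1|F2", "L7", "bayes", 0.94, 0.3, 0.06, True),
    ])
    cr2 = dp.consensus_outliers(shared, specs)
    rep2 = dp.replicated_outliers(cr2, specs)
    assert rep2 == {}
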