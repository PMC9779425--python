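import math

import numpy as np
import pytest

from superbarcode import trees
from superbarcode.gmyc import GmycError, GmycModel
from superbarcode.simulate import sim_gene_tree, sim_species_tree
from superbarcode.compare import partition_compare


def _structured_tree(seed, n_species=8, depth_scale=1.0):
    """Gene tree with species depth scaled relative to coalescent depth."""
    sp = sim_species_tree(n_species, 1.0, seed, min_species_sep=1.5)
    if depth_scale != 1.0:
        for node in sp.preorder_node_iter():
            if node.edge.length is not None:
                node.edge.length *= depth_scale
    return sim_gene_tree(sp, 3, theta=0.001, subs_rate=0.003, seed=seed)


def straight_line_loglik(tree, T, lam_y, p_y, lam_c, p_c):
    """Independent reimplementation of the interval likelihood.

    Walks every inter-node interval of the ultrametric tree directly: below
    the threshold the rate is lam_c * sum_j C(m_j,2)**p_c over the clusters,
    above it lam_y * k**p_y; each event multiplies in the total rate of its
    regime, each interval the survival term.
    """
    ages = trees.node_ages(tree)
    internal = sorted((a for n, a in ages.items() if not n.is_leaf()))
    # cluster id per tip at threshold T
    cluster_roots = [n for n in tree.preorder_node_iter()
                     if ages[n] < T and (n.parent_node is None
                                         or ages[n.parent_node] >= T)]
    tip_cluster = {}
    for ci, r in enumerate(cluster_roots):
        for leaf in r.leaf_iter():
            tip_cluster[leaf.taxon.label] = ci

    def counts_at(t):
        """Per-cluster lineage counts and total lineages crossing height t."""
        per = [0] * len(cluster_roots)
        total = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            top = ages[node.parent_node]
            bot = ages[node]
            if bot <= t < top:
                total += 1
                if t < T:
                    leaf = next(node.leaf_iter())
                    per[tip_cluster[leaf.taxon.label]] += 1
        return per, total

    breakpoints = sorted(set(internal) | {0.0, T})
    ll = 0.0
    for lo, hi in zip(breakpoints, breakpoints[1:]):
        mid = (lo + hi) / 2.0
        per, total = counts_at(mid)
        if hi <= T:
            rate = lam_c * sum(
                (m * (m - 1) / 2.0) ** p_c for m in per if m >= 2)
        else:
            rate = lam_y * total ** p_y
        ll -= rate * (hi - lo)
        if hi in internal:
            ll += math.log(rate)
    return ll


def test_five_tip_likelihood_matches_straight_line_oracle():
    nwk = "(((a:0.1,b:0.1):0.9,(c:0.05,d:0.05):0.95):1.0,e:2.0);"
    tree = trees.tree_from_string(nwk)
    model = GmycModel(tree)
    T = 0.5
    lam_y, lam_c = 1.3, 7.0
    for p_y, p_c in [(1.0, 1.0), (0.7, 1.4)]:
        _, yule_struct, coal_struct = model._loglik_at(T)
        # evaluate at fixed parameters through the model's own pieces
        from superbarcode.gmyc import _coal_structure
        _, yule_ages, cl_ages, cl_n = model._split_at(T)
        ll = 0.0
        for j, a in enumerate(yule_ages):
            k = float(j + 2)
            lower = yule_ages[j + 1] if j + 1 < len(yule_ages) else T
            ll += math.log(lam_y * k ** p_y) - lam_y * k ** p_y * (a - lower)
        evs, ivs = _coal_structure(cl_ages, cl_n, T)
        for v in evs:
            ll += math.log(lam_c * float((v ** p_c).sum()))
        for v, dt in ivs:
            ll -= lam_c * float((v ** p_c).sum()) * dt
        oracle = straight_line_loglik(tree, T, lam_y, p_y, lam_c, p_c)
        assert abs(ll - oracle) < 1e-9


def test_two_tip_tree_rejected():
    with pytest.raises(GmycError, match="3 tips"):
        GmycModel(trees.tree_from_string("(a:1,b:1);"))


def test_non_ultrametric_rejected():
    with pytest.raises(GmycError, match="ultrametric"):
        GmycModel(trees.tree_from_string("((a:1,b:2):1,c:4);"))


def test_alternative_never_below_null():
    for seed in range(5):
        fit = GmycModel(_structured_tree(seed)).fit()
        assert fit.logL_alt >= fit.logL_null - 1e-9
        assert fit.LR >= 0.0
        assert 0.0 < fit.p_value <= 1.0


def test_recovers_species_partition_on_structured_tree():
    ok = 0
    for seed in range(20):
        gt = _structured_tree(seed)
        fit = GmycModel(gt).fit()
        truth = {l.taxon.label: l.taxon.label.rsplit("_s", 1)[0]
                 for l in gt.leaf_node_iter()}
        ok += abs(fit.n_entities - 8) <= 1 and fit.p_value < 0.05
    assert ok >= 16


def test_threshold_within_tree_depth():
    gt = _structured_tree(3)
    fit = GmycModel(gt).fit()
    assert 0.0 <= fit.threshold_time <= max(trees.tip_depths(gt).values()) + 1e-9


def _msc_tree(depth, seed, n_pops=8, k=3):
    """Multispecies-coalescent gene tree (msprime): real lineage sorting, so
    shallow species trees genuinely lose their cluster signal."""
    import msprime

    dem = msprime.Demography()
    for i in range(n_pops):
        dem.add_population(name=f"p{i}", initial_size=1.0)
    dem.add_population(name="anc", initial_size=1.0)
    dem.add_population_split(time=depth, derived=[f"p{i}" for i in range(n_pops)],
                             ancestral="anc")
    ts = msprime.sim_ancestry(samples={f"p{i}": k for i in range(n_pops)},
                              demography=dem, ploidy=1, random_seed=seed)
    return trees.tree_from_string(ts.first().as_newick())


def test_power_increases_with_species_depth():
    # deeper species separation -> higher detection rate of multi-species
    # structure (depths in coalescent units; below ~0.1 the species signal
    # is swamped by incomplete lineage sorting)
    rates = [sum(GmycModel(_msc_tree(d, s)).fit().p_value < 0.05
                 for s in range(1, 26))
             for d in (0.02, 0.1, 0.3, 1.0)]
    assert rates == sorted(rates)
    assert rates[-1] - rates[0] >= 10
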