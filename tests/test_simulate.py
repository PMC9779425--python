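import json
from itertools import combinations

import numpy as np
import pytest

from superbarcode import simulate, trees
from superbarcode.divstats import nucleotide_diversity, pairwise_p_distance
from superbarcode.barcode import k2p
from superbarcode.simulate import (
    SimulationError, SynthConfig, calypogeia_like, make_dataset,
    sim_alignment, sim_gene_tree, sim_species_tree, write_bundle,
)


def test_species_tree_structure():
    with pytest.raises(SimulationError):
        sim_species_tree(1, 1.0, 0)
    t = sim_species_tree(2, 1.0, 0)
    assert trees.n_tips(t) == 2 and trees.is_ultrametric(t)
    t10 = sim_species_tree(10, 1.0, 1)
    internal = sum(1 for n in t10.preorder_node_iter() if not n.is_leaf())
    assert internal == 9  # always n - 1 for a binary tree


def test_yule_depth_matches_closed_form():
    # E[root-to-tip depth] = sum_{k=2}^{n} 1/(b*k); check within 3 SE
    n, b, reps = 10, 1.0, 800
    depths = [max(trees.tip_depths(sim_species_tree(n, b, s)).values())
              for s in range(reps)]
    expect = sum(1.0 / (b * k) for k in range(2, n + 1))
    se = np.std(depths, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(depths) - expect) < 3 * se


def test_min_species_sep_floors_node_ages():
    t = sim_species_tree(6, 1.0, 3, min_species_sep=1.5)
    ages = [a for n, a in trees.node_ages(t).items() if not n.is_leaf()]
    assert min(ages) >= 1.5
    assert trees.is_ultrametric(t)


def test_gene_tree_counts_and_theta_zero():
    sp = sim_species_tree(4, 1.0, 0, min_species_sep=1.0)
    gt = sim_gene_tree(sp, 3, theta=0.0, subs_rate=0.01, seed=0)
    assert trees.n_tips(gt) == 12
    # theta=0: conspecific tips coalesce at depth 0 (zero-length branches)
    ages = trees.node_ages(gt)
    within = [a for n, a in ages.items()
              if not n.is_leaf()
              and len({l.taxon.label.rsplit("_s", 1)[0] for l in n.leaf_iter()}) == 1]
    assert all(a == 0.0 for a in within)
    assert len(within) == 4 * 2  # 3 specimens -> 2 coalescent nodes per species


def test_intraspecific_divergence_recovers_theta():
    # end-to-end: mean intraspecific p-distance ~ theta within 15%
    theta = 0.002
    vals = []
    for seed in range(60):
        cfg = SynthConfig(
            n_species=3, specimens_per_species=2, birth_rate=1.0, theta=theta,
            subs_rate=0.01, kappa=2.0, min_species_sep=1.0,
            region_template=[(4000, "CDS", 1.0)], indel_rate_noncoding=0.0,
            seed=seed)
        ds = make_dataset(cfg)
        m = ds.alignment.matrix
        ids = ds.alignment.ids
        for i, j in combinations(range(len(ids)), 2):
            if ds.true_partition[ids[i]] == ds.true_partition[ids[j]]:
                vals.append(pairwise_p_distance(m[i], m[j])[0])
    assert abs(np.mean(vals) - theta) / theta < 0.15


def test_null_model_and_transition_limit():
    t = sim_species_tree(3, 1.0, 0)
    cfg = SynthConfig(n_species=3, specimens_per_species=1, subs_rate=0.0,
                      region_template=[(500, "CDS", 1.0)],
                      indel_rate_noncoding=0.0, seed=1)
    ds = sim_alignment(t, cfg)
    assert len(set(ds.alignment.seqs)) == 1  # no rate -> identical sequences
    assert nucleotide_diversity(ds.alignment).pi == 0.0
    # kappa -> inf: essentially no transversions
    cfg2 = SynthConfig(n_species=3, specimens_per_species=1, subs_rate=0.05,
                       kappa=1e6, region_template=[(4000, "CDS", 1.0)],
                       indel_rate_noncoding=0.0, seed=2)
    ds2 = sim_alignment(t, cfg2)
    m = ds2.alignment.matrix
    diff = m[0] != m[1]
    tv = diff & ((m[0] & 1) != (m[1] & 1))
    assert tv.sum() == 0


def test_two_tip_k2p_recovers_rate_times_time():
    # mean K2P over replicates ~ 2 * r * t within 3 SE
    r, t_half = 0.01, 1.0
    import dendropy
    vals = []
    for seed in range(200):
        tree = dendropy.Tree.get(data="(a:1.0,b:1.0);", schema="newick")
        cfg = SynthConfig(n_species=2, specimens_per_species=1, subs_rate=r,
                          region_template=[(2000, "CDS", 1.0)],
                          indel_rate_noncoding=0.0, seed=seed)
        ds = sim_alignment(tree, cfg, {"a": "A", "b": "B"})
        vals.append(k2p(ds.alignment.matrix[0], ds.alignment.matrix[1]))
    se = np.std(vals, ddof=1) / np.sqrt(len(vals))
    assert abs(np.mean(vals) - 2 * r * t_half) < 3 * se


def test_pi_monotone_in_subs_rate():
    rates = [0.001, 0.003, 0.01, 0.03]
    means = []
    for r in rates:
        pis = []
        for seed in range(5):
            cfg = SynthConfig(n_species=4, specimens_per_species=2, subs_rate=r,
                              theta=r / 10, min_species_sep=0.5,
                              region_template=[(3000, "CDS", 1.0)],
                              indel_rate_noncoding=0.0, seed=seed)
            pis.append(nucleotide_diversity(make_dataset(cfg).alignment).pi)
        means.append(np.mean(pis))
    assert all(a < b for a, b in zip(means, means[1:]))


def test_indels_confined_to_noncoding(preset_ds):
    gap_cols = np.flatnonzero((preset_ds.alignment.matrix == 5).any(axis=0))
    noncoding = np.zeros(preset_ds.alignment.length, dtype=bool)
    for r in preset_ds.regions.by_category("spacer", "intron", "pseudogene"):
        noncoding[r.start:r.end] = True
    assert noncoding[gap_cols].all()
    assert len(gap_cols) > 0


def test_preset_mirrors_study_design(preset_ds):
    assert preset_ds.alignment.n_specimens == 26
    assert len(set(preset_ds.true_partition.values())) == 11
    sizes = sorted(np.unique(list(preset_ds.true_partition.values()),
                             return_counts=True)[1])
    assert sizes == [2] * 7 + [3] * 4


def test_bundle_determinism(tmp_path):
    cfg = calypogeia_like(seed=11, total_length=4000)
    d1, d2 = tmp_path / "one", tmp_path / "two"
    write_bundle(make_dataset(cfg), d1)
    write_bundle(make_dataset(cfg), d2)
    for name in ("alignment.fasta", "species.tsv", "regions.tsv", "tree.nwk",
                 "truth.json"):
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes()


def test_config_json_roundtrip():
    cfg = calypogeia_like(seed=3, hotspot=True)
    back = SynthConfig.from_json(cfg.to_json())
    assert back == cfg
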