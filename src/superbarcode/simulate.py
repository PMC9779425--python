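"""Synthetic organelle-like datasets with known truth.

The generator emulates the statistical structure of a genus-level organellar
super-barcoding study: a handful of species, two or three specimens each, a
long alignment in which noncoding regions (spacers, introns, pseudogenes)
evolve ~1.5-2x faster than coding ones, optional localized hotspot regions,
low intraspecific divergence (~1e-3 substitutions/site), interspecific
distances roughly an order of magnitude larger, and indels confined to
noncoding regions.

Three layers compose:

1. a Yule species tree (waiting time to the next speciation ~
   Exponential(birth_rate * k) with k current lineages), optionally pushed
   apart by a minimum species separation that lengthens every pendant
   species branch — this guarantees a floor on interspecific divergence
   without touching the topology;
2. a within-species Kingman coalescent grafted onto each species tip, with
   the coalescent timescale chosen so the expected pairwise intraspecific
   divergence equals ``theta`` after sequence simulation (incomplete lineage
   sorting across species is deliberately ignored: one organellar locus,
   strongly diverged species);
3. Kimura two-parameter site evolution along the gene tree (transition/
   transversion ratio ``kappa``, per-region rate multipliers), followed by
   indel block events in noncoding regions only, each gapping the whole
   descendant clade of the branch it arises on — so the generator emits a
   true alignment and no re-alignment step is needed.

All randomness flows from one root seed; each layer draws from a fixed
sub-stream (``default_rng([layer, seed])``) so datasets are byte-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .alignio import (
    Alignment, Region, RegionTable, write_alignment, write_regions, write_species_map,
    NONCODING_CATEGORIES,
)
from . import trees


class SimulationError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Parameters of one synthetic dataset.

    ``theta`` is the expected pairwise intraspecific divergence in
    substitutions/site; ``subs_rate`` is the baseline substitution rate per
    site per unit tree time; ``region_template`` lists
    ``(length, category, rate_multiplier)`` blocks laid end to end;
    ``hotspots`` adds ``(region_index, extra_multiplier)`` factors;
    ``min_species_sep`` lengthens every pendant species branch (time units),
    imposing a floor of ``2 * min_species_sep * subs_rate`` on
    interspecific divergence.
    """

    n_species: int = 11
    specimens_per_species: int | Sequence[int] = 2
    birth_rate: float = 1.0
    theta: float = 0.001
    subs_rate: float = 0.003
    kappa: float = 2.0
    region_template: list[tuple[int, str, float]] = field(default_factory=list)
    indel_rate_noncoding: float = 5e-4
    indel_len_geom_p: float = 0.3
    hotspots: list[tuple[int, float]] | None = None
    min_species_sep: float = 0.0
    coal_depth_cap: float | None = 3.0  # within-species TMRCA cap, units of Ne
    seed: int = 0

    def __post_init__(self):
        for name in ("birth_rate", "theta", "subs_rate", "indel_rate_noncoding",
                     "min_species_sep"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.kappa <= 0:
            raise SimulationError("kappa must be > 0")
        if self.region_template and sum(r[0] for r in self.region_template) < 1:
            raise SimulationError("region template has zero total length")

    @property
    def specimen_counts(self) -> list[int]:
        if isinstance(self.specimens_per_species, int):
            return [self.specimens_per_species] * self.n_species
        counts = list(self.specimens_per_species)
        if len(counts) != self.n_species:
            raise SimulationError("specimens_per_species list length != n_species")
        return counts

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SynthConfig":
        d = json.loads(text)
        d["region_template"] = [tuple(r) for r in d.get("region_template", [])]
        if d.get("hotspots"):
            d["hotspots"] = [tuple(h) for h in d["hotspots"]]
        return cls(**d)


@dataclass
class SynthDataset:
    alignment: Alignment
    regions: RegionTable
    true_partition: dict[str, str]
    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree
    config: SynthConfig


def _rng(layer: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([layer, seed])


def sim_species_tree(
    n_species: int, birth_rate: float, seed: int, min_species_sep: float = 0.0
) -> dendropy.Tree:
    """Pure-birth (Yule) ultrametric species tree with tips sp01..spNN."""
    if n_species < 2:
        raise SimulationError("need n_species >= 2")
    rng = _rng(1, seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active: list[tuple[dendropy.Node, float]] = [(a, 0.0), (b, 0.0)]
    t = 0.0
    while True:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        if k == n_species:
            break
        idx = int(rng.integers(k))
        node, born = active.pop(idx)
        node.edge.length = t - born
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active.extend([(c1, t), (c2, t)])
    for i, (node, born) in enumerate(active):
        node.edge.length = (t - born) + min_species_sep
        node.taxon = taxa.new_taxon(label=f"sp{i + 1:02d}")
    return tree


def _coalescent_subtree(
    labels: list[str], ne: float, rng: np.random.Generator,
    taxa: dendropy.TaxonNamespace, depth_cap: float | None = None,
) -> tuple[dendropy.Node, float]:
    """Kingman coalescent over `labels`; returns (root node, root age).

    ``depth_cap`` (in units of ``ne``) truncates event times: organellar
    genomes have small effective sizes and the emulated datasets show clean
    within-species clusters, so the deep exponential tail is cut off.  The
    cap barely moves the expected pairwise time (at the default 3*Ne, by
    about -5%).
    """
    lineages = []
    for lab in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label=lab)
        lineages.append((node, 0.0))
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / ne if ne > 0 else np.inf
        t += rng.exponential(1.0 / rate) if np.isfinite(rate) else 0.0
        if depth_cap is not None and ne > 0:
            t = min(t, depth_cap * ne)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nb, tb) = lineages.pop(j)
        (na, ta) = lineages.pop(i)
        parent = dendropy.Node()
        na.edge.length = t - ta
        nb.edge.length = t - tb
        parent.add_child(na)
        parent.add_child(nb)
        lineages.append((parent, t))
    return lineages[0][0], t


def sim_gene_tree(
    species_tree: dendropy.Tree,
    specimens_per_species: int | Sequence[int],
    theta: float,
    subs_rate: float,
    seed: int,
    coal_depth_cap: float | None = 3.0,
) -> dendropy.Tree:
    """Graft within-species coalescents onto each species tip.

    The coalescent timescale is ``theta / (2 * subs_rate)`` so that, after
    site simulation at ``subs_rate``, the expected pairwise intraspecific
    divergence is ``theta``.  A coalescent deeper than 90% of the pendant
    species branch is compressed onto it (relevant only when theta is of
    the order of the species separation).
    """
    if theta < 0:
        raise SimulationError("theta must be >= 0")
    rng = _rng(2, seed)
    ne = theta / (2.0 * subs_rate) if subs_rate > 0 else 0.0
    tree = species_tree.clone(depth=1)
    taxa = dendropy.TaxonNamespace()
    tree.taxon_namespace = taxa
    tips = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    counts = ([specimens_per_species] * len(tips)
              if isinstance(specimens_per_species, int) else list(specimens_per_species))
    if len(counts) != len(tips):
        raise SimulationError("specimens_per_species list length != n species tips")
    for tip, n_spec in zip(tips, counts):
        sp = tip.taxon.label
        labels = [f"{sp}_s{i + 1}" for i in range(n_spec)]
        if n_spec == 1:
            tip.taxon = taxa.new_taxon(label=labels[0])
            continue
        sub_root, t_mrca = _coalescent_subtree(labels, ne, rng, taxa, coal_depth_cap)
        pendant = tip.edge.length or 0.0
        if t_mrca > 0.9 * pendant and pendant > 0:
            scale = 0.9 * pendant / t_mrca
            for node in sub_root.preorder_iter():
                if node.edge.length is not None:
                    node.edge.length *= scale
            t_mrca *= scale
        parent = tip.parent_node
        parent.remove_child(tip)
        sub_root.edge.length = pendant - t_mrca
        parent.add_child(sub_root)
    tree.update_taxon_namespace()
    return tree


def _k2p_probs(mu: np.ndarray, kappa: float, t: float):
    """(p_same, p_ts, p_tv_each) for per-site total rates ``mu`` over time t."""
    alpha = kappa * mu / (kappa + 2.0)
    beta = mu / (kappa + 2.0)
    e4b = np.exp(-4.0 * beta * t)
    e2ab = np.exp(-2.0 * (alpha + beta) * t)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def _regions_from_template(template: list[tuple[int, str, float]]) -> RegionTable:
    counters: dict[str, int] = {}
    regs, pos = [], 0
    for length, cat, _mult in template:
        counters[cat] = counters.get(cat, 0) + 1
        regs.append(Region(f"{cat}_{counters[cat]}", pos, pos + int(length), cat))
        pos += int(length)
    return RegionTable(regs)


def sim_alignment(
    tree: dendropy.Tree, config: SynthConfig, species_of: dict[str, str] | None = None
) -> SynthDataset:
    """Evolve sequences along ``tree`` under K2P + region multipliers + indels."""
    template = config.region_template
    if not template:
        raise SimulationError("config.region_template is empty")
    regions = _regions_from_template(template)
    length = sum(int(r[0]) for r in template)
    rate = np.empty(length)
    for region, (rlen, cat, mult) in zip(regions, template):
        rate[region.start:region.end] = config.subs_rate * mult
    for idx, extra in (config.hotspots or []):
        r = regions[idx]
        rate[r.start:r.end] *= extra

    rng = _rng(3, config.seed)
    root_seq = rng.integers(0, 4, size=length, dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {}
    groups = {}  # distinct rate -> column indices, for vectorized evolution
    for v in np.unique(rate):
        groups[v] = np.flatnonzero(rate == v)

    stack = [(tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            child_seq = seq.copy()
            if t > 0:
                for v, cols in groups.items():
                    p_same, p_ts, p_tv = _k2p_probs(np.array([v]), config.kappa, t)
                    u = rng.random(cols.size)
                    b = child_seq[cols]
                    ts_mask = (u >= p_same) & (u < p_same + p_ts)
                    tv1_mask = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
                    tv2_mask = u >= p_same + p_ts + p_tv
                    b = np.where(ts_mask, b ^ 2, b)
                    b = np.where(tv1_mask, b ^ 1, b)
                    b = np.where(tv2_mask, b ^ 3, b)
                    child_seq[cols] = b
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                stack.append((child, child_seq))

    ids = sorted(seqs)
    mat = np.stack([seqs[i] for i in ids])
    row_of = {sid: k for k, sid in enumerate(ids)}

    # indel block events, noncoding regions only, shared by the descendant clade
    if config.indel_rate_noncoding > 0:
        noncoding = regions.by_category(*NONCODING_CATEGORIES)
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            t = node.edge.length or 0.0
            if t <= 0:
                continue
            clade = [row_of[leaf.taxon.label] for leaf in node.leaf_iter()]
            for r in noncoding:
                n_ev = rng.poisson(config.indel_rate_noncoding * r.length * t)
                for _ in range(n_ev):
                    start = int(rng.integers(r.start, r.end))
                    ln = int(rng.geometric(config.indel_len_geom_p))
                    end = min(start + ln, r.end)
                    mat[np.ix_(clade, np.arange(start, end))] = 5  # gap code

    if species_of is None:
        species_of = {sid: sid.rsplit("_s", 1)[0] for sid in ids}
    aln = Alignment.from_matrix(ids, mat, species_of)
    return SynthDataset(
        alignment=aln, regions=regions, true_partition=dict(species_of),
        gene_tree=tree, species_tree=tree, config=config,
    )


def make_dataset(config: SynthConfig) -> SynthDataset:
    """Species tree -> gene tree -> alignment, deterministically from one seed."""
    sp_tree = sim_species_tree(
        config.n_species, config.birth_rate, config.seed, config.min_species_sep
    )
    gene_tree = sim_gene_tree(
        sp_tree, config.specimen_counts, config.theta, config.subs_rate,
        config.seed, config.coal_depth_cap,
    )
    ds = sim_alignment(gene_tree, config)
    ds.species_tree = sp_tree
    return ds


def write_bundle(ds: SynthDataset, outdir: str | Path) -> dict[str, str]:
    """Write alignment.fasta / species.tsv / regions.tsv / tree.nwk / truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_alignment(ds.alignment, out / "alignment.fasta")
    write_species_map(ds.alignment.species_of, out / "species.tsv")
    write_regions(ds.regions, out / "regions.tsv")
    trees.write_tree(ds.gene_tree, out / "tree.nwk")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {"partition": ds.true_partition, "config": json.loads(ds.config.to_json())},
            fh, indent=2, sort_keys=True,
        )
    return {name: str(out / name) for name in
            ("alignment.fasta", "species.tsv", "regions.tsv", "tree.nwk", "truth.json")}


def _template_block(total_length: int) -> list[tuple[int, str, float]]:
    """Organelle-like template: ~70% coding-ish, ~30% faster noncoding."""
    unit = [
        (900, "CDS", 1.0), (350, "spacer", 1.5), (700, "CDS", 1.0),
        (300, "intron", 1.5), (800, "CDS", 1.0), (400, "spacer", 1.5),
    ]
    unit_len = sum(b[0] for b in unit)
    template: list[tuple[int, str, float]] = []
    # one rRNA block and one pseudogene near the middle, as in organelle maps
    reps = max(1, round((total_length - 1400) / unit_len))
    for i in range(reps):
        template.extend(unit)
        if i == reps // 2:
            template.append((500, "pseudogene", 1.5))
            template.append((900, "rRNA", 1.0))
    return template


def calypogeia_like(
    seed: int = 0, total_length: int = 20000, hotspot: bool = False,
    hotspot_multiplier: float = 10.0,
) -> SynthConfig:
    """Preset mirroring the study design: 11 species, 26 specimens.

    Four species carry three specimens and seven carry two; intraspecific
    divergence ~0.001 subst/site, interspecific divergence at least an order
    of magnitude larger (minimum species separation 1.7 time units at
    substitution rate 0.003), noncoding regions 1.5x faster than coding.
    ``hotspot=True`` multiplies the pseudogene region by a further factor
    (default 10), emulating a localized variation hotspot.
    """
    template = _template_block(total_length)
    hotspots = None
    if hotspot:
        idx = next(i for i, b in enumerate(template) if b[1] == "pseudogene")
        hotspots = [(idx, hotspot_multiplier)]
    return SynthConfig(
        n_species=11,
        specimens_per_species=[3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2],
        birth_rate=1.0,
        theta=0.001,
        subs_rate=0.003,
        kappa=2.0,
        region_template=template,
        indel_rate_noncoding=5e-4,
        indel_len_geom_p=0.3,
        hotspots=hotspots,
        min_species_sep=1.7,
        seed=seed,
    )
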