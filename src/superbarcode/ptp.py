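"""Poisson tree processes (PTP) species delimitation, ML and Bayesian.

The input is a rooted binary tree whose branch lengths are substitutions per
site (no ultrametrization).  A delimitation is a set of "species subtrees":
an antichain of nodes covering every tip.  Edges inside species subtrees are
within-species edges; the species subtrees' own stem edges and everything
above them are speciation edges.  Each class is modelled as iid Exponential
branch lengths with its own rate, so for a fixed delimitation the maximum
log-likelihood is the two-sample exponential profile

    logL = sum_class [ n log(n / S) - n ],   rate MLE = n / S,

with n the edge count and S the length sum of the class.  The ML search is
exhaustive for small trees (<= 12 tips) and greedy hill-climbing with
random restarts otherwise; the single-species and all-singleton
delimitations are always evaluated.  Ties in logL are broken toward fewer
species.

The Bayesian variant runs a Metropolis sampler over delimitations under a
uniform prior, with split/merge moves on species roots; per-species
posterior support is the fraction of post-burn-in samples containing
exactly that species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import trees

_RATE_CAP = 1e10


class PtpError(ValueError):
    pass


def exponential_loglik(n: int, total: float) -> tuple[float, float, bool]:
    """(logL, rate MLE, capped?) of n iid Exponential lengths summing to total."""
    if n == 0:
        return 0.0, float("nan"), False
    if total <= 0.0:
        return n * math.log(_RATE_CAP), _RATE_CAP, True
    rate = n / total
    if rate > _RATE_CAP:
        return n * math.log(_RATE_CAP) - _RATE_CAP * total, _RATE_CAP, True
    return n * math.log(rate) - n, rate, False


@dataclass
class PtpResults:
    """ML (and optionally Bayesian) PTP delimitation."""

    ml_partition: dict[str, int]
    species: list[frozenset]
    lambda_spec: float
    lambda_within: float
    logL: float
    flags: list[str] = field(default_factory=list)
    posterior_support: dict[frozenset, float] | None = None
    mcmc: dict | None = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def summary(self) -> str:
        lines = [
            "Poisson tree processes delimitation",
            f"  species               : {self.n_species}",
            f"  lambda speciation     : {self.lambda_spec:.6g}",
            f"  lambda within-species : {self.lambda_within:.6g}",
            f"  logL                  : {self.logL:.4f}",
        ]
        if self.mcmc is not None:
            lines.append(
                f"  MCMC: {self.mcmc['generations']} generations, thin "
                f"{self.mcmc['thinning']}, seed {self.mcmc['seed']}, acceptance "
                f"{self.mcmc['acceptance_rate']:.3f}"
            )
            for sp in self.species:
                sup = (self.posterior_support or {}).get(sp, 0.0)
                lines.append(f"    {{{','.join(sorted(sp))}}}: support {sup:.3f}")
        return "\n".join(lines)


class PtpModel:
    """PTP model over one rooted binary substitutions-scaled tree."""

    def __init__(self, tree: dendropy.Tree, exhaustive_max_tips: int = 12):
        if trees.n_tips(tree) < 3:
            raise PtpError("need >= 3 tips")
        if not trees.is_binary(tree) or len(tree.seed_node.child_nodes()) != 2:
            raise PtpError("need a rooted binary tree (midpoint_root() an unrooted one)")
        self.tree = tree
        self.exhaustive_max_tips = exhaustive_max_tips
        # flatten to arrays: node 0 is the seed; children/parent indices
        nodes = list(tree.preorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        n = len(nodes)
        self.parent = np.full(n, -1)
        self.children: list[tuple[int, ...]] = [()] * n
        self.edge_len = np.zeros(n)
        self.tip_labels: dict[int, str] = {}
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = self.index[id(nd.parent_node)]
                self.edge_len[i] = nd.edge.length or 0.0
            self.children[i] = tuple(self.index[id(c)] for c in nd.child_nodes())
            if nd.is_leaf():
                self.tip_labels[i] = nd.taxon.label
        # per node: edge count / length sum strictly below it, and tip sets
        self.sub_cnt = np.zeros(n, dtype=int)
        self.sub_sum = np.zeros(n)
        self.tipset: list[frozenset] = [frozenset()] * n
        for i in reversed(range(n)):
            if not self.children[i]:
                self.tipset[i] = frozenset([self.tip_labels[i]])
                continue
            cs = self.children[i]
            self.sub_cnt[i] = sum(self.sub_cnt[c] + 1 for c in cs)
            self.sub_sum[i] = sum(self.sub_sum[c] + self.edge_len[c] for c in cs)
            self.tipset[i] = frozenset().union(*(self.tipset[c] for c in cs))
        self.total_cnt = int(self.sub_cnt[0])
        self.total_sum = float(self.sub_sum[0])

    # -- likelihood ----------------------------------------------------
    def loglik(self, roots: frozenset) -> float:
        n_w = int(sum(self.sub_cnt[r] for r in roots))
        s_w = float(sum(self.sub_sum[r] for r in roots))
        ll_w, _, _ = exponential_loglik(n_w, s_w)
        ll_s, _, _ = exponential_loglik(self.total_cnt - n_w, self.total_sum - s_w)
        return ll_w + ll_s

    def _rates(self, roots: frozenset):
        n_w = int(sum(self.sub_cnt[r] for r in roots))
        s_w = float(sum(self.sub_sum[r] for r in roots))
        _, lam_w, cap_w = exponential_loglik(n_w, s_w)
        _, lam_s, cap_s = exponential_loglik(self.total_cnt - n_w, self.total_sum - s_w)
        flags = []
        if cap_w or cap_s:
            flags.append("rate_capped")
        return lam_s, lam_w, flags

    # -- delimitation space --------------------------------------------
    def enumerate_delimitations(self) -> list[frozenset]:
        """All admissible delimitations (antichains of nodes covering the tips)."""

        def rec(i: int) -> list[tuple[int, ...]]:
            out = [(i,)]
            if self.children[i]:
                l, r = self.children[i]
                out.extend(a + b for a in rec(l) for b in rec(r))
            return out

        return [frozenset(t) for t in rec(0)]

    def _moves(self, roots: frozenset) -> list[tuple[str, int]]:
        moves = [("split", r) for r in roots if self.children[r]]
        for r in roots:
            p = self.parent[r]
            if p >= 0 and all(c in roots for c in self.children[p]):
                if ("merge", p) not in moves:
                    moves.append(("merge", int(p)))
        # deduplicate merges (both children propose the same parent)
        seen, out = set(), []
        for mv in moves:
            if mv not in seen:
                seen.add(mv)
                out.append(mv)
        return out

    @staticmethod
    def _apply(roots: frozenset, move: tuple[str, int], children) -> frozenset:
        kind, node = move
        if kind == "split":
            return (roots - {node}) | set(children[node])
        return (roots - set(children[node])) | {node}

    def _to_partition(self, roots: frozenset) -> tuple[dict[str, int], list[frozenset]]:
        species = sorted((self.tipset[r] for r in roots), key=lambda s: sorted(s)[0])
        part = {tip: gi for gi, sp in enumerate(species) for tip in sp}
        return part, species

    # -- fitting -------------------------------------------------------
    def fit(self, n_restarts: int = 25, seed: int = 0) -> PtpResults:
        """ML delimitation: exhaustive for small trees, greedy otherwise."""
        n_tips = len(self.tip_labels)
        best: tuple[float, int, frozenset] | None = None

        def consider(roots: frozenset):
            nonlocal best
            ll = self.loglik(roots)
            if (best is None or ll > best[0] + 1e-12
                    or (ll > best[0] - 1e-12 and -len(roots) > best[1])):
                best = (ll, -len(roots), roots)

        if n_tips <= self.exhaustive_max_tips:
            for roots in self.enumerate_delimitations():
                consider(roots)
        else:
            rng = np.random.default_rng(seed)
            tips = frozenset(i for i in range(len(self.nodes)) if not self.children[i])
            consider(frozenset([0]))
            consider(tips)
            for _ in range(n_restarts):
                roots = self._random_state(rng)
                roots = self._hill_climb(roots)
                consider(roots)
        ll, _, roots = best
        part, species = self._to_partition(roots)
        lam_s, lam_w, flags = self._rates(roots)
        return PtpResults(ml_partition=part, species=species, lambda_spec=lam_s,
                          lambda_within=lam_w, logL=ll, flags=flags)

    def _random_state(self, rng: np.random.Generator) -> frozenset:
        """Random admissible delimitation via top-down random cuts."""
        roots, stack = [], [0]
        while stack:
            i = stack.pop()
            if not self.children[i] or rng.random() < 0.5:
                roots.append(i)
            else:
                stack.extend(self.children[i])
        return frozenset(roots)

    def _hill_climb(self, roots: frozenset) -> frozenset:
        cur, ll = roots, self.loglik(roots)
        while True:
            improved = False
            for mv in self._moves(cur):
                nxt = self._apply(cur, mv, self.children)
                ll_n = self.loglik(nxt)
                if ll_n > ll + 1e-12:
                    cur, ll, improved = nxt, ll_n, True
                    break
            if not improved:
                return cur

    def fit_mcmc(
        self,
        generations: int = 500_000,
        thinning: int = 100,
        seed: int = 123,
        burnin_frac: float = 0.10,
    ) -> PtpResults:
        """Metropolis sampling over delimitations, uniform prior.

        Deterministic for a fixed seed.  Support of a species is the
        fraction of retained samples that contain exactly that tip set as a
        species; the reported ML fields are from the best-likelihood state
        visited.  A split-half support correlation is included as a simple
        convergence diagnostic.
        """
        rng = np.random.default_rng(seed)
        cur = frozenset([0])
        ll = self.loglik(cur)
        best = (ll, cur)
        n_acc = 0
        samples: list[frozenset] = []
        for g in range(generations):
            moves = self._moves(cur)
            mv = moves[int(rng.integers(len(moves)))]
            nxt = self._apply(cur, mv, self.children)
            ll_n = self.loglik(nxt)
            hastings = len(moves) / len(self._moves(nxt))
            if math.log(rng.random() + 1e-300) < (ll_n - ll) + math.log(hastings):
                cur, ll = nxt, ll_n
                n_acc += 1
                if ll > best[0]:
                    best = (ll, cur)
            if (g + 1) % thinning == 0:
                samples.append(cur)
        n_burn = int(len(samples) * burnin_frac)
        kept = samples[n_burn:]
        counts: dict[frozenset, int] = {}
        halves: list[dict[frozenset, int]] = [{}, {}]
        for si, roots in enumerate(kept):
            for r in roots:
                sp = self.tipset[r]
                counts[sp] = counts.get(sp, 0) + 1
                halves[0 if si < len(kept) // 2 else 1][sp] = (
                    halves[0 if si < len(kept) // 2 else 1].get(sp, 0) + 1
                )
        support = {sp: c / len(kept) for sp, c in counts.items()}
        all_sp = sorted(counts, key=lambda s: sorted(s)[0])
        h0 = np.array([halves[0].get(sp, 0) for sp in all_sp], dtype=float)
        h1 = np.array([halves[1].get(sp, 0) for sp in all_sp], dtype=float)
        if len(all_sp) > 1 and h0.std() > 0 and h1.std() > 0:
            split_half = float(np.corrcoef(h0, h1)[0, 1])
        else:
            split_half = 1.0
        ll_best, roots_best = best
        part, species = self._to_partition(roots_best)
        lam_s, lam_w, flags = self._rates(roots_best)
        return PtpResults(
            ml_partition=part, species=species, lambda_spec=lam_s,
            lambda_within=lam_w, logL=ll_best, flags=flags,
            posterior_support={sp: support.get(sp, 0.0) for sp in species} | support,
            mcmc={"generations": generations, "thinning": thinning, "seed": seed,
                  "acceptance_rate": n_acc / max(generations, 1),
                  "split_half_correlation": split_half,
                  "n_samples": len(kept)},
        )


def ptp_ml(tree: dendropy.Tree, n_restarts: int = 25, seed: int = 0) -> PtpResults:
    return PtpModel(tree).fit(n_restarts=n_restarts, seed=seed)


def ptp_bayes(tree: dendropy.Tree, generations: int = 500_000, thinning: int = 100,
              seed: int = 123) -> PtpResults:
    return PtpModel(tree).fit_mcmc(generations=generations, thinning=thinning, seed=seed)
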