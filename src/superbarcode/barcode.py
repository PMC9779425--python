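"""Distance-based barcoding diagnostics.

Kimura 2-parameter (K2P) distances separate transitions (A<->G, C<->T;
proportion P) from transversions (proportion Q):

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

computed under pairwise deletion.  When the arguments of the logs are
non-positive (saturation) or no site is comparable, the entry is undefined
and flagged rather than raised.

On top of the distance matrix this module provides molecular diagnostic
characters (alignment columns fixed within a species and absent from all
others), the per-species barcoding gap (smallest distance to a
non-conspecific minus largest intraspecific distance) with a
label-permutation significance test, and the six sliding-window diagnostics
classically plotted for whole-organelle barcodes: mean K2P distance, zero
non-conspecific distances, zero matrix cells, clade congruence with the full
data set, diagnostic-position sums, and species monophyly in per-window
neighbor-joining trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .alignio import Alignment, encode_seq
from .divstats import sliding_windows
from . import trees

logger = logging.getLogger(__name__)

_VALID_MAX = 3


class BarcodeError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a validity mask.

    ``d`` holds NaN where the distance is undefined; ``defined`` is the
    boolean mask of computable entries (diagonal always True).
    """

    ids: list[str]
    d: np.ndarray
    defined: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_undefined_pairs(self) -> int:
        return int(np.sum(~self.defined[np.triu_indices(self.n, 1)]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


def _pq(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, valid sites) for two encoded sequences."""
    valid = (a <= _VALID_MAX) & (b <= _VALID_MAX)
    diff = (a != b) & valid
    ts = diff & ((a & 1) == (b & 1))  # same parity: A<->G or C<->T
    return int(ts.sum()), int(diff.sum() - ts.sum()), int(valid.sum())


def _k2p_from_pq(ts: int, tv: int, valid: int) -> float:
    if valid == 0:
        return float("nan")
    p, q = ts / valid, tv / valid
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * np.log(w1) - 0.25 * np.log(w2)


def k2p(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> float:
    """K2P distance for one pair; NaN marks an undefined (saturated) entry."""
    a = encode_seq(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode_seq(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise BarcodeError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    return _k2p_from_pq(*_pq(a, b))


def k2p_matrix(aln: Alignment, columns: tuple[int, int] | None = None) -> DistanceMatrix:
    """All-pairs K2P matrix; undefined entries are NaN-flagged, not raised."""
    m = aln.matrix
    if columns is not None:
        m = m[:, columns[0]:columns[1]]
    n = m.shape[0]
    d = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    for i, j in combinations(range(n), 2):
        val = _k2p_from_pq(*_pq(m[i], m[j]))
        d[i, j] = d[j, i] = val
        if np.isnan(val):
            defined[i, j] = defined[j, i] = False
    n_undef = int(np.sum(~defined)) // 2
    if n_undef:
        logger.info("k2p_matrix: %d undefined pairs", n_undef)
    return DistanceMatrix(ids=list(aln.ids), d=d, defined=defined)


def nuc_diag(aln: Alignment, columns: tuple[int, int] | None = None) -> dict[str, list[int]]:
    """Diagnostic columns per species (molecular diagnostic characters).

    A column is diagnostic for species S iff every member of S shares one
    state in {A,C,G,T} there and no non-member carries that state.  A gap or
    N inside S disqualifies the column; gaps/N among non-members neither
    match nor disqualify.
    """
    if len(set(aln.species_of.values())) < 2:
        raise BarcodeError("nuc_diag needs >= 2 species")
    m = aln.matrix
    lo = 0
    if columns is not None:
        lo = columns[0]
        m = m[:, columns[0]:columns[1]]
    members = aln.species_members()
    idx_of = {sid: i for i, sid in enumerate(aln.ids)}
    out: dict[str, list[int]] = {}
    for sp, sids in members.items():
        rows = np.array([idx_of[s] for s in sids])
        others = np.array([i for i in range(len(aln.ids)) if i not in set(rows)])
        x = m[rows[0]]
        fixed = (x <= _VALID_MAX) & (m[rows] == x).all(axis=0)
        absent = ~(m[others] == x).any(axis=0)
        out[sp] = [int(c) + lo for c in np.flatnonzero(fixed & absent)]
    return out


def mdc_counts(aln: Alignment) -> dict[str, int]:
    return {sp: len(cols) for sp, cols in nuc_diag(aln).items()}


def _species_gaps(d: np.ndarray, labels: np.ndarray, species: list[str]) -> dict[str, tuple[float, float, float]]:
    """(max_intra, min_inter, gap) per species; NaN-aware, singleton intra = 0."""
    out = {}
    iu = np.triu_indices(d.shape[0], 1)
    for sp in species:
        rows = labels == sp
        sub = d[np.ix_(rows, rows)]
        k = int(rows.sum())
        if k >= 2:
            intra = sub[np.triu_indices(k, 1)]
            max_intra = np.nanmax(intra) if np.isfinite(intra).any() else float("nan")
        else:
            max_intra = 0.0
        inter = d[np.ix_(rows, ~rows)]
        min_inter = np.nanmin(inter) if np.isfinite(inter).any() else float("nan")
        out[sp] = (float(max_intra), float(min_inter), float(min_inter - max_intra))
    return out


def barcoding_gap(
    dm: DistanceMatrix,
    species_of: Mapping[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    aln: Alignment | None = None,
) -> pd.DataFrame:
    """Per-species barcoding gap with a label-permutation p-value.

    The null permutes species labels over specimens with group sizes fixed;
    ``p = (1 + #{permuted gap >= observed}) / (1 + n_perm)``.  When ``aln``
    is given, diagnostic-character counts (MDC) are included.
    """
    labels = np.array([species_of[s] for s in dm.ids])
    species = list(dict.fromkeys(labels))
    if len(species) < 2:
        raise BarcodeError("need >= 2 species for a barcoding gap")
    obs = _species_gaps(dm.d, labels, species)
    rng = np.random.default_rng(seed)
    exceed = {sp: 0 for sp in species}
    for _ in range(n_perm):
        perm = _species_gaps(dm.d, rng.permutation(labels), species)
        for sp in species:
            if not np.isnan(perm[sp][2]) and perm[sp][2] >= obs[sp][2]:
                exceed[sp] += 1
    mdc = mdc_counts(aln) if aln is not None else {}
    sizes = {sp: int((labels == sp).sum()) for sp in species}
    rows = []
    for sp in species:
        mi, mn, gap = obs[sp]
        flags = []
        if sizes[sp] < 2:
            flags.append("singleton_intra_zero")
        if np.isnan(mi) or np.isnan(mn):
            flags.append("undefined_distances")
        rows.append(
            {"species": sp, "n": sizes[sp], "max_intra": mi, "min_inter": mn,
             "gap": gap, "p_value": (1 + exceed[sp]) / (1 + n_perm),
             "mdc_count": mdc.get(sp, np.nan), "flags": ";".join(flags)}
        )
    return pd.DataFrame(rows)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a fully-defined distance matrix."""
    if not dm.defined.all():
        raise trees.TreeError(
            "distance matrix has undefined entries; impute them or skip this window"
        )
    return trees.nj_tree(dm.ids, dm.d)


@dataclass
class WindowDiagnostics:
    """Six per-window barcode diagnostics plus the full-data baselines."""

    frame: pd.DataFrame
    baseline_prop_zero_cells: float
    full_tree: dendropy.Tree | None
    width: int
    step: int


def window_diagnostics(
    aln: Alignment, width: int = 500, step: int = 50,
    max_undefined_frac: float = 0.5,
) -> WindowDiagnostics:
    """The sliding-window barcode suite.

    Per window: (A) mean of defined K2P entries; (B) proportion of defined
    non-conspecific pairs at distance exactly 0; (C) proportion of defined
    off-diagonal cells at exactly 0 ("zero" means shared haplotype, no
    epsilon); (D) proportion of the full-data NJ tree's non-trivial
    bipartitions present in the window NJ tree; (E) total diagnostic columns
    summed over species; (F) proportion of species monophyletic in the
    window NJ tree (singletons count).  Windows whose NJ tree cannot be
    built (undefined distances) get NaN for D and F; windows with more than
    ``max_undefined_frac`` undefined cells are NaN throughout.
    """
    m = aln.matrix
    n = m.shape[0]
    wins = sliding_windows(aln.length, width, step)
    starts = np.array([w[0] for w in wins])
    ends = np.array([w[1] for w in wins])
    pairs = list(combinations(range(n), 2))
    labels = np.array([aln.species_of[s] for s in aln.ids])
    conspecific = np.array([labels[i] == labels[j] for i, j in pairs])

    # per-pair per-window K2P via cumulative transition/transversion counts
    dist = np.empty((len(wins), len(pairs)))
    for pi, (i, j) in enumerate(pairs):
        valid = (m[i] <= _VALID_MAX) & (m[j] <= _VALID_MAX)
        diff = (m[i] != m[j]) & valid
        ts = diff & ((m[i] & 1) == (m[j] & 1))
        cs_v = np.concatenate([[0], np.cumsum(valid)])
        cs_d = np.concatenate([[0], np.cumsum(diff)])
        cs_t = np.concatenate([[0], np.cumsum(ts)])
        nv = (cs_v[ends] - cs_v[starts]).astype(float)
        nd = cs_d[ends] - cs_d[starts]
        nt = cs_t[ends] - cs_t[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = nt / nv
            q = (nd - nt) / nv
            w1 = 1.0 - 2.0 * p - q
            w2 = 1.0 - 2.0 * q
            val = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        val[(nv == 0) | (w1 <= 0) | (w2 <= 0)] = np.nan
        dist[:, pi] = val

    full_dm = k2p_matrix(aln)
    iu = np.triu_indices(n, 1)
    full_defined = full_dm.defined[iu]
    baseline_zero = (
        float((full_dm.d[iu][full_defined] == 0.0).mean()) if full_defined.any() else float("nan")
    )
    full_tree = None
    full_bips: set[frozenset] = set()
    if full_dm.defined.all() and n >= 3:
        full_tree = nj_tree(full_dm)
        full_bips = trees.bipartitions(full_tree)
    members = aln.species_members()

    rows = []
    for w, (lo, hi) in enumerate(wins):
        dvec = dist[w]
        defined = ~np.isnan(dvec)
        row = {"start": lo, "end": hi, "mean_k2p": np.nan,
               "prop_zero_nonconspecific": np.nan, "prop_zero_cells": np.nan,
               "clade_congruence": np.nan, "diag_sum": np.nan,
               "prop_monophyletic": np.nan}
        if defined.mean() >= 1.0 - max_undefined_frac:
            row["mean_k2p"] = float(dvec[defined].mean()) if defined.any() else np.nan
            noncon = defined & ~conspecific
            if noncon.any():
                row["prop_zero_nonconspecific"] = float((dvec[noncon] == 0.0).mean())
            if defined.any():
                row["prop_zero_cells"] = float((dvec[defined] == 0.0).mean())
            row["diag_sum"] = float(
                sum(len(v) for v in nuc_diag(aln, (lo, hi)).values())
            )
            if defined.all() and n >= 3:
                dmat = np.zeros((n, n))
                for pi2, (i, j) in enumerate(pairs):
                    dmat[i, j] = dmat[j, i] = dvec[pi2]
                wtree = trees.nj_tree(list(aln.ids), dmat)
                if full_bips:
                    wbips = trees.bipartitions(wtree)
                    row["clade_congruence"] = len(full_bips & wbips) / len(full_bips)
                row["prop_monophyletic"] = float(
                    np.mean([trees.is_monophyletic(wtree, v) for v in members.values()])
                )
        rows.append(row)
    return WindowDiagnostics(
        frame=pd.DataFrame(rows), baseline_prop_zero_cells=baseline_zero,
        full_tree=full_tree, width=width, step=step,
    )
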