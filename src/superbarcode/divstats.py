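"""Nucleotide diversity (pi), SNP and indel statistics.

pi is the mean, over all unordered specimen pairs, of the per-site
proportion of differences.  Sites where either sequence of a pair carries a
gap or an N are excluded for that pair (pairwise deletion): whole-organelle
alignments have indel-rich spacers, and complete deletion would discard most
columns there.  Pairs left with zero comparable sites are excluded from the
mean and counted.

An indel event is a maximal run of consecutive columns sharing an identical
gap pattern (the exact set of gapped specimens), counted once per run — an
event count, not a gapped-column count.  Column counting is available via
``count_mode="columns"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .alignio import Alignment, AlignmentError, RegionTable, NONCODING_CATEGORIES

_VALID_MAX = 3  # codes 0..3 are A,C,G,T


class DiversityError(ValueError):
    pass


@dataclass
class DiversityStat:
    """pi with the pair bookkeeping plus segregating-site and indel counts."""

    pi: float
    n_pairs_used: int
    n_pairs_undefined: int
    snps: int
    indel_events: int


@dataclass
class WindowSeries:
    """Per-window values of one statistic; NaN marks undefined windows."""

    windows: list[tuple[int, int]]
    values: np.ndarray
    width: int
    step: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": [w[0] for w in self.windows],
             "end": [w[1] for w in self.windows],
             "value": self.values}
        )


from .alignio import encode_seq as _encode


def pairwise_p_distance(seq_a: str | np.ndarray, seq_b: str | np.ndarray) -> tuple[float, int]:
    """Proportion of differing sites under pairwise deletion.

    Returns ``(p, valid_sites)``; ``p`` is NaN when no site is comparable.
    """
    a = _encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = _encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise DiversityError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    valid = (a <= _VALID_MAX) & (b <= _VALID_MAX)
    nv = int(valid.sum())
    if nv == 0:
        return float("nan"), 0
    nd = int(((a != b) & valid).sum())
    return nd / nv, nv


def count_snps(m: np.ndarray) -> int:
    """Columns containing >= 2 distinct states from {A,C,G,T}; gaps/N ignored."""
    present = np.stack([(m == b).any(axis=0) for b in range(4)])
    return int((present.sum(axis=0) >= 2).sum())


def count_indel_events(m: np.ndarray, count_mode: str = "events") -> int:
    """Indel count over the columns of code-matrix ``m``.

    ``events``: maximal runs of identical nonzero gap patterns.
    ``columns``: number of columns containing at least one gap.
    """
    from .alignio import GAP_CODE

    gap = m == GAP_CODE
    nz = gap.any(axis=0)
    if count_mode == "columns":
        return int(nz.sum())
    if count_mode != "events":
        raise ValueError(f"unknown count_mode {count_mode!r}")
    if not nz.any():
        return 0
    _, pid = np.unique(gap.T, axis=0, return_inverse=True)
    pid = np.asarray(pid).ravel()
    new_run = np.empty(pid.shape, dtype=bool)
    new_run[0] = True
    new_run[1:] = pid[1:] != pid[:-1]
    return int((nz & new_run).sum())


def nucleotide_diversity(
    aln: Alignment,
    columns: tuple[int, int] | None = None,
    count_mode: str = "events",
) -> DiversityStat:
    """pi, SNP count and indel count over an alignment (or a column range)."""
    m = aln.matrix
    if columns is not None:
        a, b = columns
        if not (0 <= a <= b <= aln.length):
            raise DiversityError(f"columns [{a},{b}) out of range")
        m = m[:, a:b]
    valid = m <= _VALID_MAX
    total = 0.0
    used = undef = 0
    for i, j in combinations(range(m.shape[0]), 2):
        v = valid[i] & valid[j]
        nv = int(v.sum())
        if nv == 0:
            undef += 1
            continue
        total += ((m[i] != m[j]) & v).sum() / nv
        used += 1
    if used == 0:
        raise DiversityError("no comparable sites: every specimen pair is undefined")
    return DiversityStat(
        pi=total / used,
        n_pairs_used=used,
        n_pairs_undefined=undef,
        snps=count_snps(m),
        indel_events=count_indel_events(m, count_mode),
    )


def sliding_windows(length: int, width: int = 500, step: int = 50) -> list[tuple[int, int]]:
    """Half-open windows ``[k*step, k*step+width)`` fully inside the alignment.

    Trailing partial windows are dropped; an alignment shorter than one
    window yields the single window ``[0, length)``.
    """
    if width < 1 or step < 1:
        raise ValueError("width and step must be >= 1")
    if length < width:
        return [(0, length)]
    return [(k * step, k * step + width) for k in range((length - width) // step + 1)]


def windowed_pi(aln: Alignment, width: int = 500, step: int = 50) -> WindowSeries:
    """pi in sliding windows; undefined windows are NaN, never silently 0."""
    wins = sliding_windows(aln.length, width, step)
    m = aln.matrix
    valid = m <= _VALID_MAX
    starts = np.array([w[0] for w in wins])
    ends = np.array([w[1] for w in wins])
    ratio_sum = np.zeros(len(wins))
    pair_cnt = np.zeros(len(wins), dtype=int)
    for i, j in combinations(range(m.shape[0]), 2):
        v = valid[i] & valid[j]
        d = (m[i] != m[j]) & v
        cs_v = np.concatenate([[0], np.cumsum(v)])
        cs_d = np.concatenate([[0], np.cumsum(d)])
        nv = cs_v[ends] - cs_v[starts]
        nd = cs_d[ends] - cs_d[starts]
        ok = nv > 0
        ratio_sum[ok] += nd[ok] / nv[ok]
        pair_cnt += ok
    vals = np.full(len(wins), np.nan)
    ok = pair_cnt > 0
    vals[ok] = ratio_sum[ok] / pair_cnt[ok]
    return WindowSeries(windows=wins, values=vals, width=width, step=step)


def region_stats(
    aln: Alignment, regions: RegionTable, count_mode: str = "events"
) -> pd.DataFrame:
    """Per-region pi / SNP / indel table, ranked by pi (most variable first)."""
    regions.validate_for(aln)
    rows = []
    for r in regions:
        try:
            st = nucleotide_diversity(aln, (r.start, r.end), count_mode)
            pi, pairs, snps, indels = st.pi, st.n_pairs_used, st.snps, st.indel_events
        except DiversityError:
            pi, pairs = float("nan"), 0
            sub = aln.matrix[:, r.start:r.end]
            snps = count_snps(sub)
            indels = count_indel_events(sub, count_mode)
        rows.append(
            {"name": r.name, "category": r.category, "start": r.start, "end": r.end,
             "length": r.length, "pi": pi, "n_pairs_used": pairs,
             "snps": snps, "indel_events": indels}
        )
    df = pd.DataFrame(rows, columns=["name", "category", "start", "end", "length",
                                     "pi", "n_pairs_used", "snps", "indel_events"])
    return df.sort_values("pi", ascending=False, kind="mergesort").reset_index(drop=True)


def coding_noncoding_contrast(aln: Alignment, regions: RegionTable) -> dict[str, float]:
    """pi over concatenated CDS columns vs concatenated noncoding columns.

    Noncoding means spacer, intron or pseudogene (a nonfunctional gene copy
    accumulates mutations like a spacer); structural RNAs are excluded from
    both sides.
    """
    regions.validate_for(aln)

    def _cols(cats: Sequence[str]) -> np.ndarray:
        keep = np.zeros(aln.length, dtype=bool)
        for r in regions.by_category(*cats):
            keep[r.start:r.end] = True
        return keep

    out: dict[str, float] = {}
    for label, cats in (("coding", ("CDS",)), ("noncoding", NONCODING_CATEGORIES)):
        keep = _cols(cats)
        if not keep.any():
            out[label] = float("nan")
            continue
        sub = Alignment.from_matrix(aln.ids, aln.matrix[:, keep], aln.species_of)
        out[label] = nucleotide_diversity(sub).pi
    out["ratio"] = out["noncoding"] / out["coding"] if out.get("coding") else float("nan")
    return out
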