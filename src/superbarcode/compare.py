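"""Partition comparison utilities shared by the delimitation engines."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score


def partition_compare(a: Mapping[str, object], b: Mapping[str, object]) -> float:
    """Adjusted Rand Index between two partitions of the same specimens.

    1.0 iff the partitions are identical up to label names; ~0 for chance
    agreement.
    """
    if set(a) != set(b):
        raise ValueError("partitions cover different specimen sets")
    ids = sorted(a)
    la = pd.factorize(np.asarray([str(a[i]) for i in ids], dtype=object))[0]
    lb = pd.factorize(np.asarray([str(b[i]) for i in ids], dtype=object))[0]
    return float(adjusted_rand_score(la, lb))


def delimitation_report(
    results: Mapping[str, Mapping[str, object]],
    truth: Mapping[str, object] | None = None,
) -> dict:
    """Cross-method comparison table plus the disagreement surface.

    ``results`` maps method name -> partition (specimen -> group label).
    Returns a dict with a per-method summary frame, the pairwise-ARI matrix,
    and the list of specimens whose co-membership with some other specimen
    differs between at least two methods.
    """
    if not results:
        raise ValueError("empty results")
    methods = list(results)
    ids = sorted(next(iter(results.values())))
    for m in methods:
        if sorted(results[m]) != ids:
            raise ValueError(f"method {m!r} covers a different specimen set")
    rows = []
    for m in methods:
        part = results[m]
        rows.append({
            "method": m,
            "n_species": len(set(part.values())),
            "ari_vs_truth": partition_compare(part, truth) if truth is not None else np.nan,
        })
    summary = pd.DataFrame(rows)
    ari = pd.DataFrame(
        [[partition_compare(results[m1], results[m2]) for m2 in methods] for m1 in methods],
        index=methods, columns=methods,
    )
    # co-membership disagreement: specimens in a pair grouped by one method
    # but split by another
    disagree: set[str] = set()
    co = {}
    for m in methods:
        part = results[m]
        co[m] = {(s, t): part[s] == part[t] for i, s in enumerate(ids) for t in ids[i + 1:]}
    for i, s in enumerate(ids):
        for t in ids[i + 1:]:
            vals = {co[m][(s, t)] for m in methods}
            if len(vals) > 1:
                disagree.update((s, t))
    return {"summary": summary, "pairwise_ari": ari, "disagreements": sorted(disagree)}
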