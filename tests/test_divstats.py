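from itertools import combinations

import numpy as np
import pytest

from superbarcode import divstats
from superbarcode.alignio import Alignment, RegionTable
from superbarcode.divstats import (
    DiversityError, nucleotide_diversity, pairwise_p_distance, region_stats,
    sliding_windows, windowed_pi,
)

from conftest import random_alignment


def brute_force_pi(aln, lo=None, hi=None):
    """Independent double-loop oracle for pi under pairwise deletion."""
    seqs = [s[lo:hi] if lo is not None else s for s in aln.seqs]
    vals = []
    for a, b in combinations(seqs, 2):
        diffs = valid = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                valid += 1
                diffs += x != y
        if valid:
            vals.append(diffs / valid)
    return sum(vals) / len(vals)


def brute_force_snps(aln, lo=0, hi=None):
    hi = aln.length if hi is None else hi
    count = 0
    for c in range(lo, hi):
        states = {s[c] for s in aln.seqs} & set("ACGT")
        count += len(states) >= 2
    return count


@pytest.mark.parametrize("a,b,expected", [
    ("ACGT", "ACGT", (0.0, 4)),
    ("ACGT", "ACGA", (0.25, 4)),
    ("AC-T", "ACGT", (0.0, 3)),
])
def test_p_distance_examples(a, b, expected):
    assert pairwise_p_distance(a, b) == expected


def test_p_distance_undefined_and_mismatch():
    p, n = pairwise_p_distance("--", "AC")
    assert n == 0 and np.isnan(p)
    with pytest.raises(DiversityError, match="length mismatch"):
        pairwise_p_distance("ACG", "AC")


def test_pi_hand_enumeration(tiny_aln):
    st = nucleotide_diversity(tiny_aln)
    assert abs(st.pi - (0.25 + 0.5 + 0.25) / 3) < 1e-12
    assert st.n_pairs_used == 3


def test_pi_zero_for_identical_sequences():
    aln = Alignment(["a", "b", "c"], ["ACGT"] * 3, {x: x for x in "abc"})
    assert nucleotide_diversity(aln).pi == 0.0
    assert all(v == 0.0 for v in windowed_pi(aln, 2, 2).values)


def test_pi_matches_bruteforce_oracle(rng):
    for _ in range(10):
        aln = random_alignment(rng, n=10, length=200)
        assert abs(nucleotide_diversity(aln).pi - brute_force_pi(aln)) < 1e-12


def test_pi_invariant_under_reordering_and_column_permutation(rng):
    aln = random_alignment(rng, n=6, length=100)
    pi0 = nucleotide_diversity(aln).pi
    order = rng.permutation(len(aln.ids))
    shuffled = Alignment([aln.ids[i] for i in order], [aln.seqs[i] for i in order],
                         aln.species_of)
    assert abs(nucleotide_diversity(shuffled).pi - pi0) < 1e-12
    cols = rng.permutation(aln.length)
    permuted = Alignment.from_matrix(aln.ids, aln.matrix[:, cols], aln.species_of)
    assert abs(nucleotide_diversity(permuted).pi - pi0) < 1e-12


@pytest.mark.parametrize("length,width,step,n_windows,last", [
    (1000, 500, 50, 11, (500, 1000)),
    (500, 500, 50, 1, (0, 500)),
    (400, 500, 50, 1, (0, 400)),
])
def test_sliding_window_rule(length, width, step, n_windows, last):
    wins = sliding_windows(length, width, step)
    assert len(wins) == n_windows
    assert wins[-1] == last


def test_window_mean_equals_global_pi_on_gapfree_data(rng):
    # step == width tiles the alignment exactly
    aln = random_alignment(rng, n=6, length=400, gap_frac=0, n_frac=0)
    ws = windowed_pi(aln, width=50, step=50)
    assert abs(ws.values.mean() - nucleotide_diversity(aln).pi) < 1e-12


def test_concatenation_consistency_on_gapfree_data(rng):
    aln = random_alignment(rng, n=6, length=300, gap_frac=0, n_frac=0)
    regions = RegionTable([("r1", 0, 120, "CDS"), ("r2", 120, 300, "spacer")])
    df = region_stats(aln, regions)
    w = df.set_index("name")
    weighted = (w.loc["r1", "pi"] * 120 + w.loc["r2", "pi"] * 180) / 300
    assert abs(weighted - nucleotide_diversity(aln).pi) < 1e-9


def test_snp_and_indel_definitions():
    aln = Alignment(
        ["a", "b", "c"],
        ["AAAAAAAAAA", "AAAA----AA", "AAAAAAAAAT"],
        {x: x for x in "abc"},
    )
    st = nucleotide_diversity(aln)
    assert st.snps == 1          # last column A/A/T
    assert st.indel_events == 1  # one maximal run of one gap pattern
    # column counting mode
    assert nucleotide_diversity(aln, count_mode="columns").indel_events == 4
    gapless = Alignment(["a", "b"], ["ACGT", "ACGA"], {"a": "x", "b": "y"})
    assert nucleotide_diversity(gapless).indel_events == 0


def test_adjacent_distinct_gap_patterns_are_two_events():
    aln = Alignment(
        ["a", "b", "c"],
        ["A--AA", "AA--A", "AAAAA"],
        {x: x for x in "abc"},
    )
    # cols 1-2 gap in a only is split at col 2 where the pattern changes
    assert nucleotide_diversity(aln).indel_events == 3


def test_snp_count_matches_bruteforce(rng):
    for _ in range(5):
        aln = random_alignment(rng, n=8, length=150)
        assert nucleotide_diversity(aln).snps == brute_force_snps(aln)


def test_region_stats_ranked_by_pi(preset_ds):
    df = region_stats(preset_ds.alignment, preset_ds.regions)
    assert (df["pi"].values[:-1] >= df["pi"].values[1:]).all()
    assert set(df.columns) >= {"name", "category", "pi", "snps", "indel_events"}


def test_no_comparable_sites_error():
    aln = Alignment(["a", "b"], ["--", "AC"], {"a": "x", "b": "y"})
    with pytest.raises(DiversityError, match="no comparable sites"):
        nucleotide_diversity(aln)
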