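import math
from itertools import combinations

import numpy as np
import pytest

from superbarcode import barcode, trees
from superbarcode.alignio import Alignment
from superbarcode.barcode import (
    BarcodeError, barcoding_gap, k2p, k2p_matrix, nuc_diag, window_diagnostics,
)
from superbarcode.divstats import pairwise_p_distance

from conftest import random_alignment, similar_alignment


def brute_force_k2p(a, b):
    ts = tv = valid = 0
    pur = set("AG")
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            valid += 1
            if x != y:
                if (x in pur) == (y in pur):
                    ts += 1
                else:
                    tv += 1
    if valid == 0:
        return float("nan")
    p, q = ts / valid, tv / valid
    if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
        return float("nan")
    return -0.5 * math.log(1 - 2 * p - q) - 0.25 * math.log(1 - 2 * q)


def brute_force_nuc_diag(aln):
    members = aln.species_members()
    out = {}
    for sp, sids in members.items():
        inside = [aln.seqs[aln.ids.index(s)] for s in sids]
        outside = [aln.seqs[aln.ids.index(s)] for s in aln.ids if aln.species_of[s] != sp]
        cols = []
        for c in range(aln.length):
            states = {s[c] for s in inside}
            if len(states) == 1 and states <= set("ACGT"):
                x = states.pop()
                if all(o[c] != x for o in outside):
                    cols.append(c)
        out[sp] = cols
    return out


def test_k2p_closed_forms():
    assert k2p("ACGT", "ACGT") == 0.0
    assert abs(k2p("ACGT", "GCGT") - 0.346574) < 1e-6   # one A<->G transition
    assert abs(k2p("ACGT", "CCGT") - 0.317128) < 1e-6   # one A<->C transversion
    assert np.isnan(k2p("AG", "GA"))                    # saturated: P=1
    assert np.isnan(k2p("--", "AC"))                    # zero valid sites


def test_k2p_matrix_matches_bruteforce(rng):
    aln = similar_alignment(rng, n=6, length=200, divergence=0.15, gap_frac=0.05)
    dm = k2p_matrix(aln)
    assert np.allclose(dm.d, dm.d.T, equal_nan=True)
    assert np.all(np.diag(dm.d) == 0)
    for i, j in combinations(range(6), 2):
        expect = brute_force_k2p(aln.seqs[i], aln.seqs[j])
        if math.isnan(expect):
            assert not dm.defined[i, j]
        else:
            assert abs(dm.d[i, j] - expect) < 1e-12


def test_k2p_undefined_mask_symmetric():
    # a-b saturated (P=0.5); both are mildly diverged from c
    aln = Alignment(["a", "b", "c"], ["AGAA", "GAAA", "AAAA"], {x: x for x in "abc"})
    dm = k2p_matrix(aln)
    assert not dm.defined[0, 1] and not dm.defined[1, 0]
    assert dm.n_undefined_pairs == 1


def test_k2p_dominates_p_distance(rng):
    # the substitution correction can only stretch distances
    for _ in range(20):
        aln = random_alignment(rng, n=2, length=300, gap_frac=0.0, n_frac=0.0)
        d = k2p(aln.seqs[0], aln.seqs[1])
        p, _ = pairwise_p_distance(aln.seqs[0], aln.seqs[1])
        if not math.isnan(d):
            assert d >= p - 1e-12


def test_k2p_approaches_p_distance_at_low_divergence():
    # one substitution in 2000 sites
    a = "ACGT" * 500
    b = "G" + a[1:]
    d = k2p(a, b)
    p, _ = pairwise_p_distance(a, b)
    assert abs(d - p) < 0.001


def test_nuc_diag_policy_cases():
    aln = Alignment(
        ["a1", "a2", "b1", "b2"],
        ["TTA", "TTA", "CNC", "C-C"],
        {"a1": "S", "a2": "S", "b1": "O", "b2": "O"},
    )
    diag = nuc_diag(aln)
    # col 0: S fixed T, others C -> diagnostic for S (and O, complement)
    # col 1: S fixed T, others N/- -> still diagnostic for S; O disqualified (N in O)
    # col 2: S = A/A? col2 of S is A,A; O is C,C -> diagnostic both
    assert diag["S"] == [0, 1, 2]
    assert diag["O"] == [0, 2]


def test_nuc_diag_ambiguity_inside_species_disqualifies():
    aln = Alignment(
        ["a1", "a2", "b1"],
        ["T", "N", "C"],
        {"a1": "S", "a2": "S", "b1": "O"},
    )
    assert nuc_diag(aln)["S"] == []


def test_nuc_diag_matches_bruteforce(rng):
    aln = random_alignment(rng, n=9, length=120, n_species=3)
    assert nuc_diag(aln) == brute_force_nuc_diag(aln)


def test_nuc_diag_monotone_in_species_membership(rng):
    # adding a new specimen to S can only shrink (or keep) S's diagnostic set
    for _ in range(5):
        aln = random_alignment(rng, n=8, length=80, n_species=2, gap_frac=0, n_frac=0)
        base = set(nuc_diag(aln)["sp0"])
        new_seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=aln.length))
        grown_aln = Alignment(aln.ids + ["extra"], aln.seqs + [new_seq],
                              {**aln.species_of, "extra": "sp0"})
        assert set(nuc_diag(grown_aln)["sp0"]) <= base


def _two_species_matrix(k=5, intra=0.001, inter=0.1):
    ids = [f"a{i}" for i in range(k)] + [f"b{i}" for i in range(k)]
    d = np.full((2 * k, 2 * k), inter)
    d[:k, :k] = intra
    d[k:, k:] = intra
    np.fill_diagonal(d, 0.0)
    dm = barcode.DistanceMatrix(ids=ids, d=d, defined=np.ones((2 * k, 2 * k), bool))
    return dm, {i: i[0].upper() for i in ids}


def test_barcoding_gap_constructed_matrix():
    dm, species = _two_species_matrix()
    rep = barcoding_gap(dm, species, n_perm=1000, seed=1).set_index("species")
    for sp in "AB":
        assert abs(rep.loc[sp, "gap"] - 0.099) < 1e-12
        assert rep.loc[sp, "p_value"] <= 0.05


def test_barcoding_gap_needs_two_species():
    dm, _ = _two_species_matrix()
    with pytest.raises(BarcodeError, match="2 species"):
        barcoding_gap(dm, {i: "one" for i in dm.ids}, n_perm=10, seed=0)


def test_window_diagnostics_forced_values():
    # identical sequences: A=0, B=1, C=1, E=0 everywhere
    aln = Alignment(["a", "b", "c", "d"], ["ACGTACGT"] * 4,
                    {"a": "X", "b": "X", "c": "Y", "d": "Y"})
    wd = window_diagnostics(aln, width=4, step=4)
    assert (wd.frame["mean_k2p"] == 0).all()
    assert (wd.frame["prop_zero_nonconspecific"] == 1).all()
    assert (wd.frame["prop_zero_cells"] == 1).all()
    assert (wd.frame["diag_sum"] == 0).all()
    assert wd.baseline_prop_zero_cells == 1.0


def test_window_diagnostics_self_congruence(rng):
    aln = similar_alignment(rng, n=8, length=200, divergence=0.05)
    wd = window_diagnostics(aln, width=200, step=200)
    assert len(wd.frame) == 1
    assert wd.frame.loc[0, "clade_congruence"] == 1.0


def test_window_diagnostics_on_preset(preset_ds):
    wd = window_diagnostics(preset_ds.alignment, width=1000, step=1000)
    f = wd.frame
    ok = f["prop_monophyletic"].dropna()
    assert ((0 <= ok) & (ok <= 1)).all()
    assert f["diag_sum"].dropna().sum() > 0
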