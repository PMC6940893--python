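"""Sliding-window pi, per-feature pi, hotspots and windowed identity."""

import math
from itertools import combinations

import numpy as np
import pytest

from plastome.diversity import (
    MultipleAlignment,
    call_hotspots,
    identity_track,
    per_feature_pi,
    sliding_window_pi,
)
from plastome.genome import PlastomeError

from conftest import random_dna


def pi_oracle(rows, start, end):
    """Window pi recomputed pair-by-pair, site-by-site with plain loops."""
    vals = []
    for a, b in combinations(rows, 2):
        comp = diff = 0
        for i in range(start, end):
            x, y = a[i], b[i]
            if x in "ACGT" and y in "ACGT":
                comp += 1
                diff += x != y
        if comp:
            vals.append(diff / comp)
    return sum(vals) / len(vals) if vals else float("nan")


def test_alignment_validation():
    with pytest.raises(PlastomeError):
        MultipleAlignment(names=["a"], rows=["ACGT"])
    with pytest.raises(PlastomeError):
        MultipleAlignment(names=["a", "b"], rows=["ACGT", "ACG"])
    with pytest.raises(PlastomeError):
        MultipleAlignment(names=["a", "b"], rows=["ACGT", "ACGU"])


def test_identical_rows_give_zero_pi():
    aln = MultipleAlignment(names=["a", "b", "c"], rows=["ACGTACGT"] * 3)
    track = sliding_window_pi(aln, window=4, step=4)
    assert [w.value for w in track] == [0.0, 0.0]


def test_hand_computed_three_row_window():
    # one column with bases A/A/T among 4 columns: pairs differ 0,1,1 of 4
    aln = MultipleAlignment(names=list("abc"), rows=["AAAA", "AAAA", "ATAA"])
    track = sliding_window_pi(aln, window=4, step=4)
    assert len(track) == 1
    assert abs(track[0].value - (0 + 0.25 + 0.25) / 3) < 1e-15
    assert abs(track[0].value - (2 / 3) / 4) < 1e-15


def test_all_gap_window_is_missing():
    aln = MultipleAlignment(names=["a", "b"], rows=["ACGT", "----"])
    track = sliding_window_pi(aln, window=4, step=4)
    assert math.isnan(track[0].value) and track[0].n_sites_used == 0


def test_window_validation():
    aln = MultipleAlignment(names=["a", "b"], rows=["ACGT", "ACGT"])
    with pytest.raises(PlastomeError):
        sliding_window_pi(aln, window=0)
    with pytest.raises(PlastomeError):
        sliding_window_pi(aln, step=0)


@pytest.mark.parametrize("seed,n_rows", [(0, 2), (1, 3), (2, 4)])
def test_pi_matches_per_site_oracle(seed, n_rows):
    rng = np.random.default_rng(seed)
    L = 1000
    rows = []
    base = random_dna(rng, L)
    for _ in range(n_rows):
        row = list(base)
        for i in rng.integers(0, L, size=60):
            row[i] = "ACGT-N"[rng.integers(0, 6)]
        rows.append("".join(row))
    aln = MultipleAlignment(names=[f"r{i}" for i in range(n_rows)], rows=rows)
    for window, step in [(100, 100), (250, 100), (333, 333)]:
        for w in sliding_window_pi(aln, window=window, step=step):
            expected = pi_oracle(rows, w.window_start - 1, w.window_end)
            if math.isnan(expected):
                assert math.isnan(w.value)
            else:
                assert abs(w.value - expected) < 1e-12


def test_pi_invariant_under_row_reordering():
    rng = np.random.default_rng(5)
    rows = [random_dna(rng, 400) for _ in range(3)]
    a1 = MultipleAlignment(names=list("abc"), rows=rows)
    a2 = MultipleAlignment(names=list("cba"), rows=rows[::-1])
    t1 = sliding_window_pi(a1, 100, 100)
    t2 = sliding_window_pi(a2, 100, 100)
    assert [w.value for w in t1] == [w.value for w in t2]


def test_two_rows_pi_equals_one_minus_identity():
    rng = np.random.default_rng(6)
    base = random_dna(rng, 600)
    other = list(base)
    for i in rng.integers(0, 600, size=30):
        other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
    aln = MultipleAlignment(names=["r", "o"], rows=[base, "".join(other)])
    pi = sliding_window_pi(aln, 200, 200)
    ident = identity_track(aln, "r", "o", 200, 200)
    for w_pi, w_id in zip(pi, ident):
        assert abs(w_pi.value - (1 - w_id.value / 100)) < 1e-12


def test_per_feature_pi():
    aln = MultipleAlignment(names=["a", "b"], rows=["AAAAAAAAAA", "AAAAATAAAA"])
    table = per_feature_pi(
        aln,
        [
            ("invariant", "gene", [(1, 4)]),
            ("one_diff", "gene", [(1, 10)]),
            ("split", "intergenic", [(1, 3), (5, 7)]),
        ],
    )
    vals = dict(zip(table["feature"], table["pi"]))
    assert vals["invariant"] == 0.0
    assert abs(vals["one_diff"] - 0.1) < 1e-15
    assert abs(vals["split"] - 1 / 6) < 1e-15
    with pytest.raises(PlastomeError):
        per_feature_pi(aln, [("bad", "gene", [(5, 11)])])


def test_feature_classes_partition_reference_columns():
    # bookkeeping: gene + intergenic intervals tile the alignment exactly once
    intervals = [("g1", "gene", [(1, 4)]), ("i1", "intergenic", [(5, 8)]), ("g2", "gene", [(9, 10)])]
    covered = sorted(c for _, _, ivs in intervals for s, e in ivs for c in range(s, e + 1))
    assert covered == list(range(1, 11))


def test_hotspots():
    aln = MultipleAlignment(names=["a", "b"], rows=["A" * 100, "A" * 100])
    track = sliding_window_pi(aln, 10, 10)
    assert call_hotspots(track) == []
    with pytest.raises(PlastomeError):
        call_hotspots([])
    # threshold 0 with any polymorphism -> non-empty
    aln2 = MultipleAlignment(names=["a", "b"], rows=["A" * 100, "A" * 50 + "T" + "A" * 49])
    track2 = sliding_window_pi(aln2, 10, 10)
    assert call_hotspots(track2, threshold=0.0) != []
    assert call_hotspots(track2, threshold=0.1) == []  # strict inequality at 0.1


def test_hotspot_ordering_is_by_value_descending():
    rng = np.random.default_rng(7)
    base = random_dna(rng, 300)
    other = list(base)
    for i in range(0, 40):  # window 1 heavily diverged
        other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
    for i in range(100, 110):  # window 2 mildly diverged
        other[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[i]]
    aln = MultipleAlignment(names=["a", "b"], rows=[base, "".join(other)])
    hot = call_hotspots(sliding_window_pi(aln, 100, 100), threshold=0.02)
    assert [w.window_start for w in hot] == [1, 101]


def test_identity_examples():
    aln = MultipleAlignment(names=["r", "o"], rows=["ACGT" * 50, "ACGT" * 50])
    track = identity_track(aln, "r", "o", 100, 100)
    assert all(w.value == 100.0 for w in track)
    row = list("ACGT" * 25)
    row[10] = "C" if row[10] != "C" else "G"
    aln2 = MultipleAlignment(names=["r", "o"], rows=["ACGT" * 25, "".join(row)])
    track2 = identity_track(aln2, "r", "o", 100, 100)
    assert track2[0].value == 99.0
    aln3 = MultipleAlignment(names=["r", "o"], rows=["ACGT", "----"])
    assert math.isnan(identity_track(aln3, "r", "o", 4, 4)[0].value)


def test_planted_hotspot_windows_recovered_exactly():
    """Without the inversion, hotspot calls are exactly the planted windows."""
    import dataclasses

    from plastome.simulate import SimulationConfig, simulate_plastome_set

    cfg = dataclasses.replace(SimulationConfig(), inversion=False)
    sim = simulate_plastome_set(cfg, seed=21)
    track = sliding_window_pi(sim.alignment, cfg.window, cfg.window)
    hot = call_hotspots(track, threshold=0.02)
    got = sorted((w.window_start - 1) // cfg.window + 1 for w in hot)
    assert got == sim.truth.hotspot_windows
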