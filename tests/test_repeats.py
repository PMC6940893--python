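"""SSR and long-repeat detection against independent brute-force oracles."""

import numpy as np
import pytest

from plastome.genome import complement, revcomp
from plastome.repeats import (
    DEFAULT_MIN_COPIES,
    REPEAT_KINDS,
    find_long_repeats,
    find_ssrs,
    ssr_census,
)

from conftest import random_dna


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def ssr_oracle(seq: str, min_copies=DEFAULT_MIN_COPIES):
    """Enumerate maximal tandem runs start-by-start with plain string ops."""

    def primitive(m):
        return all(m != m[:d] * (len(m) // d) for d in range(1, len(m)) if len(m) % d == 0)

    out = set()
    n = len(seq)
    for u, thr in min_copies.items():
        for s in range(n - u):
            # chain-maximal on the left: the run would have started earlier
            if s >= 1 and s - 1 + u < n and seq[s - 1] == seq[s - 1 + u]:
                continue
            j = s + u
            while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                j += 1
            total = j - s
            if total < u + 1:
                continue  # no tandem chain at all
            copies = total // u
            motif = seq[s : s + u]
            if copies >= thr and primitive(motif) and "N" not in motif:
                out.add((motif, u, copies, s + 1, s + u * copies))
    return out


def repeat_oracle(seq: str, min_len=30, max_hamming=3, kinds=REPEAT_KINDS):
    """Full per-diagonal enumeration of maximal windows (numpy-assisted)."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n_mask = arr == ord("N")
    found = {k: set() for k in kinds}
    for kind in kinds:
        t = {
            "forward": seq,
            "complement": complement(seq),
            "reverse": seq[::-1],
            "palindromic": revcomp(seq),
        }[kind]
        t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
        t_nmask = t_arr == ord("N")
        for d in range(-(n - 1), n):
            lo = max(0, -d)
            length = min(n - lo, n - (lo + d))
            if length < min_len:
                continue
            a, b = arr[lo : lo + length], t_arr[lo + d : lo + d + length]
            mism = (a != b) | n_mask[lo : lo + length] | t_nmask[lo + d : lo + d + length]
            mpos = np.flatnonzero(mism)
            bounds = np.concatenate(([-1], mpos, [length]))
            k = len(mpos)
            for i in range(0, max(k - max_hamming, 0) + 1):
                j = i + max_hamming + 1
                w_lo = int(bounds[i]) + 1
                w_hi = int(bounds[j] if j <= k else length) - 1
                span = w_hi - w_lo + 1
                if span < min_len:
                    continue
                inner = min(j - 1, k) - i
                ss, st = lo + w_lo, lo + d + w_lo
                if kind in ("forward", "complement"):
                    a1, a2 = (ss, ss + span - 1), (st, st + span - 1)
                else:
                    a1 = (ss, ss + span - 1)
                    a2 = (n - st - span, n - st - 1)
                if a1 == a2:
                    continue
                if a1 > a2:
                    a1, a2 = a2, a1
                found[kind].add((a1, a2, inner))
    # containment filter, same convention as the finder's contract
    out = set()
    for kind in kinds:
        recs = found[kind]
        for a1, a2, mm in recs:
            contained = any(
                (b1, b2) != (a1, a2)
                and b1[0] <= a1[0] <= a1[1] <= b1[1]
                and b2[0] <= a2[0] <= a2[1] <= b2[1]
                for b1, b2, _ in recs
            )
            if not contained:
                out.add((kind, (a1[0] + 1, a1[1] + 1), (a2[0] + 1, a2[1] + 1), mm))
    return out


def records_as_set(records):
    return {(r.kind, r.arm1, r.arm2, r.mismatches) for r in records}


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("G" + "A" * 7 + "G", [("A", 1, 7, 2, 8)]),  # threshold boundary
        ("GC" + "A" * 6 + "GC", []),  # below mono threshold
        ("G" + "AC" * 4 + "G", [("AC", 2, 4, 2, 9)]),  # dinucleotide
        ("G" + "A" * 8 + "C", [("A", 1, 8, 2, 9)]),  # A8 is mono x8, never (AA)x4
        ("G" + "ATATAT" + "C", []),  # (AT)x3, below di threshold
        ("T" + "ATATATA" + "C", [("TA", 2, 4, 1, 8)]),  # leftmost phase wins
    ],
)
def test_find_ssrs_examples(seq, expected):
    got = [(r.motif, r.unit_len, r.copies, r.start, r.end) for r in find_ssrs(seq)]
    assert got == expected


def test_find_ssrs_rejects_non_dna():
    with pytest.raises(Exception):
        find_ssrs("ACGU" * 10)


def test_ssr_census_counts_per_unit_length():
    seq = "G" + "A" * 7 + "C" + "AT" * 4 + "G" + "ACG" * 4 + "T"
    census = ssr_census(find_ssrs(seq))
    assert census == {1: 1, 2: 1, 3: 1, 4: 0, 5: 0, 6: 0}


@pytest.mark.parametrize("seed", range(8))
def test_find_ssrs_matches_oracle_on_random_sequences(seed):
    rng = np.random.default_rng(seed)
    seq = random_dna(rng, 2000)
    # plant one SSR of each unit length to exercise every branch
    plants = ["A" * 8, "AT" * 5, "AGC" * 4, "ACGT" * 3, "AACGT" * 3, "AACGTC" * 3]
    pos = 100
    seq = list(seq)
    for run in plants:
        seq[pos : pos + len(run)] = list(run)
        pos += len(run) + 37
    seq = "".join(seq)
    got = {(r.motif, r.unit_len, r.copies, r.start, r.end) for r in find_ssrs(seq)}
    assert got == ssr_oracle(seq)


def test_find_ssrs_strand_symmetry():
    rng = np.random.default_rng(42)
    seq = random_dna(rng, 1500) + "AT" * 5 + "G" * 8 + random_dna(rng, 200)
    fwd = ssr_census(find_ssrs(seq))
    rev = ssr_census(find_ssrs(revcomp(seq)))
    assert fwd == rev


def test_find_ssrs_deterministic():
    rng = np.random.default_rng(3)
    seq = random_dna(rng, 3000)
    assert find_ssrs(seq) == find_ssrs(seq)


# ---------------------------------------------------------------------------
# long repeats
# ---------------------------------------------------------------------------


def test_planted_exact_duplicate_found_at_zero_hamming():
    rng = np.random.default_rng(10)
    seq = random_dna(rng, 5000)
    planted = seq[1000:1040]
    seq = seq[:3000] + planted + seq[3040:]
    records = [r for r in find_long_repeats(seq, max_hamming=0) if r.kind == "forward"]
    assert len(records) == 1
    assert records[0].mismatches == 0
    # maximal arms contain the planted 40-mers (chance flank matches extend)
    assert records[0].arm1[0] <= 1001 and records[0].arm1[1] >= 1040
    assert records[0].arm2[0] <= 3001 and records[0].arm2[1] >= 3040


def test_planted_palindrome_found():
    rng = np.random.default_rng(11)
    seq = random_dna(rng, 4000)
    seq = seq[:2500] + revcomp(seq[800:840]) + seq[2540:]
    records = [r for r in find_long_repeats(seq, max_hamming=0) if r.kind == "palindromic"]
    assert any(
        r.arm1[0] <= 801 and r.arm1[1] >= 840 and r.arm2[0] <= 2501 and r.arm2[1] >= 2540
        and r.mismatches == 0
        for r in records
    )


def test_copy_with_four_substitutions_not_reported():
    rng = np.random.default_rng(12)
    seq = random_dna(rng, 3000)
    copy = list(seq[500:530])
    for i in (3, 11, 19, 27):  # 4 substitutions > Hamming budget
        copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
    seq = seq[:2000] + "".join(copy) + seq[2030:]
    for r in find_long_repeats(seq, min_len=30, max_hamming=3):
        if r.kind != "forward":
            continue
        # no reported pair aligns the planted source with its mutated copy
        assert not (r.arm1[0] <= 501 <= r.arm1[1] and r.arm2[0] <= 2001 <= r.arm2[1])


def test_min_len_below_8_refused():
    with pytest.raises(Exception):
        find_long_repeats("ACGT" * 100, min_len=7)


@pytest.mark.parametrize("seed", range(4))
def test_find_long_repeats_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    seq = random_dna(rng, 700)
    # plant one pair of each kind so the oracle comparison is non-trivial
    arm = random_dna(rng, 34)
    seq = (
        seq[:50] + arm + seq[84:300] + arm  # forward
        + seq[334:420] + revcomp(arm)  # palindromic
        + seq[454:520] + complement(arm)  # complement
        + seq[554:600] + arm[::-1]  # reverse
        + seq[634:]
    )
    got = records_as_set(find_long_repeats(seq, min_len=30, max_hamming=3))
    assert got == repeat_oracle(seq, min_len=30, max_hamming=3)


def test_find_long_repeats_matches_oracle_at_2kb():
    rng = np.random.default_rng(200)
    seq = random_dna(rng, 2000)
    seq = seq[:900] + seq[100:135] + seq[935:]  # one planted forward pair
    got = records_as_set(find_long_repeats(seq, min_len=30, max_hamming=3))
    assert got == repeat_oracle(seq, min_len=30, max_hamming=3)


def test_n_bases_never_match():
    seq = "ACGTACGTACGTACGTACGTACGTACGTACGT" + "N" * 40 + "TTTT"
    # the poly-N block must not produce repeats on its own
    for r in find_long_repeats(seq, min_len=30, max_hamming=3):
        s1, e1 = r.arm1
        assert "N" not in seq[s1 - 1 : e1] or r.mismatches > 0
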