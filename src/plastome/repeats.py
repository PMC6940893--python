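"""Microsatellite (SSR) and approximate long-repeat detection.

SSR detection follows the MISA convention used in plastome surveys: a
maximal perfect tandem run of a primitive 1-6 bp unit is reported when its
copy number reaches the per-unit-length minimum (defaults 7, 4, 4, 3, 3, 3
for mono- through hexanucleotides).  Long repeats follow the REPuter
convention: maximal repeat pairs of four kinds (forward, reverse,
complement, palindromic) with arm length >= 30 bp and Hamming distance <= 3.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

from .genome import PlastomeError, complement, revcomp

DEFAULT_MIN_COPIES: dict[int, int] = {1: 7, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}

REPEAT_KINDS = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class SSRRecord:
    """A maximal perfect tandem run of a primitive motif (1-based inclusive)."""

    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    context: str = "intergenic"

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_len * self.copies:
            raise PlastomeError("SSR span inconsistent with unit_len x copies")


@dataclass(frozen=True)
class RepeatRecord:
    """A maximal repeat pair; arms are 1-based inclusive intervals of equal length."""

    kind: str
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    length: int
    mismatches: int


def _is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number repetition of a shorter unit."""
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest among all rotations of the motif and of its
    reverse complement; groups e.g. AG / GA / CT / TC into one class."""
    variants = []
    for m in (motif, revcomp(motif)):
        variants.extend(m[i:] + m[:i] for i in range(len(m)))
    return min(variants)


def find_ssrs(
    seq: str, min_copies: dict[int, int] | None = None
) -> list[SSRRecord]:
    """All maximal perfect tandem runs meeting their unit-length threshold.

    Each run is reported exactly once, at the primitive unit length of its
    motif, truncated to whole copies; records are sorted by start then unit
    length.  Runs containing N are never reported (N matches nothing).
    """
    if min_copies is None:
        min_copies = DEFAULT_MIN_COPIES
    bad = set(seq) - set("ACGTN")
    if bad:
        raise PlastomeError(f"non-DNA characters in sequence: {sorted(bad)}")
    if any(t < 1 for t in min_copies.values()):
        raise PlastomeError("SSR thresholds must be positive")
    n = len(seq)
    out: list[SSRRecord] = []
    for u, thr in sorted(min_copies.items()):
        j = u
        while j < n:
            if seq[j] == seq[j - u] and seq[j] != "N":
                run_start = j - u
                while j < n and seq[j] == seq[j - u] and seq[j] != "N":
                    j += 1
                total = j - run_start  # char length of the full tandem region
                copies = total // u
                motif = seq[run_start : run_start + u]
                if copies >= thr and _is_primitive(motif) and "N" not in motif:
                    out.append(
                        SSRRecord(
                            motif=motif,
                            unit_len=u,
                            copies=copies,
                            start=run_start + 1,
                            end=run_start + u * copies,
                        )
                    )
                # j now sits on the first non-matching position; the next
                # chain may start there or later
            else:
                j += 1
    out.sort(key=lambda r: (r.start, r.unit_len))
    return out


def ssr_census(records: list[SSRRecord]) -> dict[int, int]:
    """Number of SSR loci per unit length (1..6)."""
    census = collections.Counter(r.unit_len for r in records)
    return {u: census.get(u, 0) for u in range(1, 7)}


# ---------------------------------------------------------------------------
# Long repeats
# ---------------------------------------------------------------------------


def _maximal_pairs(
    s: str, t: str, min_len: int, max_hamming: int, skip_self_diagonal: bool
) -> set[tuple[int, int, int, int]]:
    """Maximal (start_s, start_t, length, mismatches) stretches of s vs t
    with at most ``max_hamming`` mismatches.

    Seed-and-extend by pigeonhole: any qualifying stretch of length
    ``min_len`` with <= h mismatches contains an exact seed of length
    ``min_len // (h + 1)``; every seed hit is extended to all maximal
    windows containing it.  N positions never match.
    """
    h = max_hamming
    q = min_len // (h + 1)
    ns, nt = len(s), len(t)
    index: dict[str, list[int]] = {}
    for p in range(nt - q + 1):
        w = t[p : p + q]
        if "N" not in w:
            index.setdefault(w, []).append(p)
    out: set[tuple[int, int, int, int]] = set()
    for i in range(ns - q + 1):
        w = s[i : i + q]
        if "N" in w:
            continue
        for p in index.get(w, ()):
            d = p - i
            if skip_self_diagonal and d == 0:
                continue
            # mismatch positions (s-coordinates) flanking the seed
            left_mms: list[int] = []
            si, ti = i - 1, p - 1
            while si >= 0 and ti >= 0 and len(left_mms) < h + 1:
                if s[si] != t[ti] or s[si] == "N" or t[ti] == "N":
                    left_mms.append(si)
                si -= 1
                ti -= 1
            right_mms: list[int] = []
            si, ti = i + q, p + q
            while si < ns and ti < nt and len(right_mms) < h + 1:
                if s[si] != t[ti] or s[si] == "N" or t[ti] == "N":
                    right_mms.append(si)
                si += 1
                ti += 1
            send = min(ns, nt - d)  # diagonal end (exclusive) in s-coords
            sstart = max(0, -d)
            for j in range(h + 1):
                k = h - j
                left_edge = left_mms[j] + 1 if j < len(left_mms) else sstart
                right_edge = right_mms[k] - 1 if k < len(right_mms) else send - 1
                span = right_edge - left_edge + 1
                if span < min_len:
                    continue
                mism = min(j, len(left_mms)) + min(k, len(right_mms))
                out.add((left_edge, left_edge + d, span, mism))
    return out


def find_long_repeats(
    seq: str,
    min_len: int = 30,
    max_hamming: int = 3,
    kinds: tuple[str, ...] = REPEAT_KINDS,
) -> list[RepeatRecord]:
    """Maximal repeat pairs of each requested kind.

    kinds: ``forward`` compares the sequence with itself, ``complement``
    with its complement, ``reverse`` with its reverse, and ``palindromic``
    with its reverse complement.  A pair is maximal when extending either
    end would exceed the Hamming budget or leave the sequence; pairs whose
    arms are both strictly contained within another reported pair of the
    same kind are dropped.  Self-trivial pairs (arm1 == arm2) are excluded;
    overlapping arms are allowed.
    """
    if min_len < 8:
        raise PlastomeError("min_len below 8 refused")
    n = len(seq)
    if n < min_len:
        return []
    unknown = set(kinds) - set(REPEAT_KINDS)
    if unknown:
        raise PlastomeError(f"unknown repeat kinds: {sorted(unknown)}")
    results: dict[str, set[tuple[tuple[int, int], tuple[int, int], int]]] = {
        k: set() for k in kinds
    }
    for kind in kinds:
        if kind == "forward":
            t_seq = seq
        elif kind == "complement":
            t_seq = complement(seq)
        elif kind == "reverse":
            t_seq = seq[::-1]
        else:
            t_seq = revcomp(seq)
        for ss, st, L, mm in _maximal_pairs(
            seq, t_seq, min_len, max_hamming, skip_self_diagonal=(kind == "forward")
        ):
            if kind in ("forward", "complement"):
                a1, a2 = (ss, ss + L - 1), (st, st + L - 1)
            else:
                # arm2 lives on the original sequence, reversed coordinates
                a2 = (n - st - L, n - st - 1)
                a1 = (ss, ss + L - 1)
            if a1 == a2:
                continue
            if a1 > a2:
                a1, a2 = a2, a1
            results[kind].add((a1, a2, mm))
    out: list[RepeatRecord] = []
    for kind in kinds:
        recs = sorted(results[kind])
        kept = []
        for a1, a2, mm in recs:
            contained = any(
                (b1, b2) != (a1, a2)
                and b1[0] <= a1[0]
                and a1[1] <= b1[1]
                and b2[0] <= a2[0]
                and a2[1] <= b2[1]
                for b1, b2, _ in recs
            )
            if not contained:
                kept.append((a1, a2, mm))
        for a1, a2, mm in kept:
            out.append(
                RepeatRecord(
                    kind=kind,
                    arm1=(a1[0] + 1, a1[1] + 1),
                    arm2=(a2[0] + 1, a2[1] + 1),
                    length=a1[1] - a1[0] + 1,
                    mismatches=mm,
                )
            )
    out.sort(key=lambda r: (REPEAT_KINDS.index(r.kind), r.arm1, r.arm2))
    return out
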