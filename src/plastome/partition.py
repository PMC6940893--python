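"""Quadripartite structure detection and region statistics.

Most angiosperm plastomes are tiled by four regions in circular order:
the large single-copy region (LSC), inverted repeat A (IRa), the small
single-copy region (SSC) and inverted repeat B (IRb), where IRa and IRb are
exact (or near-exact) reverse complements of each other.  Detection here
finds the longest exact reverse-complement repeat pair consistent with a
circular quadripartite tiling; the shorter of the two single-copy gaps is
labelled SSC.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .genome import AnnotatedPlastome, PlastomeError, revcomp


class NoIRDetectedError(PlastomeError):
    """No reverse-complement repeat pair of the required length exists."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """1-based inclusive intervals tiling the circular plastome.

    Intervals may wrap the origin (start > end).  Circular order is
    LSC -> IRa -> SSC -> IRb.
    """

    lsc: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    irb: tuple[int, int]
    genome_length: int

    def _ilen(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s + 1 if s <= e else self.genome_length - s + 1 + e

    @property
    def lsc_length(self) -> int:
        return self._ilen(self.lsc)

    @property
    def ssc_length(self) -> int:
        return self._ilen(self.ssc)

    @property
    def ir_length(self) -> int:
        return self._ilen(self.ira)

    def validate(self, plastome: AnnotatedPlastome) -> None:
        n = len(plastome.seq)
        if self.lsc_length + self.ssc_length + 2 * self.ir_length != n:
            raise PlastomeError("partition does not tile the genome")
        ira = plastome.region_seq(*self.ira)
        irb = plastome.region_seq(*self.irb)
        if ira != revcomp(irb):
            raise PlastomeError("IRa is not the reverse complement of IRb")
        if self.lsc_length < self.ssc_length:
            raise PlastomeError("LSC shorter than SSC")


def _maximal_rc_matches(seq: str, min_len: int, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact matches (i, j, L) between circular ``seq`` and its own
    reverse complement: seq[i:i+L] == revcomp(seq[j:j+L]), 0-based circular
    starts, L capped at len(seq)."""
    n = len(seq)
    rc = revcomp(seq)
    s2 = seq + seq
    r2 = rc + rc
    index: dict[str, list[int]] = {}
    for p in range(0, 2 * n - k + 1):
        index.setdefault(r2[p : p + k], []).append(p)
    seen_end: dict[int, int] = {}  # diagonal -> furthest i already covered
    out: set[tuple[int, int, int]] = set()
    for i in range(n):
        hits = index.get(s2[i : i + k])
        if not hits:
            continue
        for p in hits:
            d = p - i
            if seen_end.get(d, -1) >= i:
                continue
            # extend left
            li, lp = i, p
            while li > 0 and lp > 0 and s2[li - 1] == r2[lp - 1] and s2[li - 1] != "N":
                li -= 1
                lp -= 1
            # extend right
            ri, rp = i + k, p + k
            while ri < 2 * n and rp < 2 * n and s2[ri] == r2[rp] and s2[ri] != "N":
                ri += 1
                rp += 1
            seen_end[d] = ri - 1
            L = min(ri - li, n)
            if L < min_len:
                continue
            ii = li % n
            jj = (n - (lp % n) - L) % n
            a, b = sorted((ii, jj))
            out.add((a, b, L))
    return sorted(out)


def detect_quadripartite(
    plastome: AnnotatedPlastome, min_ir_len: int = 1000
) -> QuadripartitePartition:
    """Detect LSC/SSC/IRa/IRb from the longest exact reverse-complement pair.

    The search crosses the sequence origin (the genome is treated as
    circular by internal doubling).  Ties on IR length are broken by the
    candidate minimising the |LSC - SSC| asymmetry, then by lowest start
    coordinate.  Raises :class:`NoIRDetectedError` when no pair of length
    ``min_ir_len`` or more exists.
    """
    seq = plastome.seq
    n = len(seq)
    if min_ir_len < 8:
        raise PlastomeError("min_ir_len must be at least 8")
    k = min(min_ir_len, 24)

    def circ_iv(start0: int, length: int) -> tuple[int, int]:
        # 0-based circular start + length -> 1-based inclusive (may wrap)
        return (start0 % n + 1, (start0 + length - 1) % n + 1)

    candidates = []
    for a, b, L in _maximal_rc_matches(seq, min_ir_len, k):
        # arms must be disjoint on the circle and leave two non-empty gaps
        if (b - a) % n < L or (a - b) % n < L:
            continue
        g1 = (b - a) % n - L  # gap arm1 -> arm2 in circular order
        g2 = (a - b) % n - L  # gap arm2 -> arm1
        if g1 < 1 or g2 < 1:
            continue
        candidates.append((a, b, L, g1, g2))
    if not candidates:
        raise NoIRDetectedError(
            f"no reverse-complement repeat pair of length >= {min_ir_len} found"
        )
    best = max(candidates, key=lambda c: (c[2], -abs(c[3] - c[4]), -c[0]))
    a, b, L, g1, g2 = best
    arm1, arm2 = circ_iv(a, L), circ_iv(b, L)
    gap_a = circ_iv(a + L, g1)  # between arm1 and arm2
    gap_b = circ_iv(b + L, g2)  # between arm2 and arm1
    if g1 >= g2:
        lsc, ssc = gap_a, gap_b
        ira, irb = arm2, arm1
    else:
        lsc, ssc = gap_b, gap_a
        ira, irb = arm1, arm2
    part = QuadripartitePartition(lsc=lsc, ssc=ssc, ira=ira, irb=irb, genome_length=n)
    part.validate(plastome)
    return part


def _gc_percent(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    gc = seq.count("G") + seq.count("C")
    return float(
        Decimal(100.0 * gc / acgt).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def region_report(
    plastome: AnnotatedPlastome, partition: QuadripartitePartition
) -> pd.DataFrame:
    """Per-region length, fraction of genome, and %GC (plus an overall row).

    %GC = (G+C)/(A+C+G+T) x 100, rounded half-up to one decimal.  Fractions
    are of the total genome length; note that reporting each IR separately
    means the four region fractions sum to 1.
    """
    partition.validate(plastome)
    n = len(plastome.seq)
    rows = []
    for name, iv in [
        ("LSC", partition.lsc),
        ("IRa", partition.ira),
        ("SSC", partition.ssc),
        ("IRb", partition.irb),
    ]:
        sub = plastome.region_seq(*iv)
        rows.append(
            {
                "region": name,
                "start": iv[0],
                "end": iv[1],
                "length_bp": len(sub),
                "fraction_of_genome": len(sub) / n,
                "gc_percent": _gc_percent(sub),
            }
        )
    rows.append(
        {
            "region": "genome",
            "start": 1,
            "end": n,
            "length_bp": n,
            "fraction_of_genome": 1.0,
            "gc_percent": _gc_percent(plastome.seq),
        }
    )
    return pd.DataFrame(rows)


def ir_reduced_seq(
    plastome: AnnotatedPlastome, partition: QuadripartitePartition
) -> str:
    """Genome sequence with the IRb copy removed (LSC + IRa + SSC).

    Repeat and SSR censuses run on this reduced sequence to avoid counting
    every IR-internal repeat twice.
    """
    return (
        plastome.region_seq(*partition.lsc)
        + plastome.region_seq(*partition.ira)
        + plastome.region_seq(*partition.ssc)
    )
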