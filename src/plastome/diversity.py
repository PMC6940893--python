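"""Alignment-based polymorphism: sliding-window nucleotide diversity (pi),
per-feature pi, diversity hotspots and pairwise windowed identity.

Nucleotide diversity is the average proportion of differing sites between
two sequences drawn from the sample.  Per window it is computed with
pairwise deletion: for each unordered row pair only columns where both rows
carry A/C/G/T are compared, and the window value is the mean over pairs of
(differences / compared sites).  No multiple-hit correction is applied; the
value is the raw mean pairwise difference proportion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .genome import PlastomeError

_VALID = set("ACGTN-")


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows over the alphabet {A,C,G,T,N,-}."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise PlastomeError("alignment needs at least 2 rows")
        if len(self.names) != len(self.rows):
            raise PlastomeError("names/rows length mismatch")
        L = len(self.rows[0])
        for name, row in zip(self.names, self.rows):
            if len(row) != L:
                raise PlastomeError(f"row {name} has length {len(row)} != {L}")
            bad = set(row.upper()) - _VALID
            if bad:
                raise PlastomeError(f"row {name}: invalid characters {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def to_reference_coords(self, reference: str) -> np.ndarray:
        """1-based reference coordinate of every alignment column (0 where the
        reference row has a gap)."""
        row = self.row(reference)
        coords = np.zeros(self.length, dtype=int)
        pos = 0
        for i, c in enumerate(row):
            if c != "-":
                pos += 1
                coords[i] = pos
        return coords

    @classmethod
    def from_fasta(cls, path: str | Path) -> "MultipleAlignment":
        aln = AlignIO.read(str(path), "fasta")
        return cls(names=[r.id for r in aln], rows=[str(r.seq) for r in aln])


@dataclass(frozen=True)
class DiversityWindow:
    """One window of a diversity or identity track (alignment coordinates,
    1-based inclusive).  ``value`` is NaN when no sites were comparable."""

    window_start: int
    window_end: int
    value: float
    n_sites_used: int


def _encode_rows(aln: MultipleAlignment) -> np.ndarray:
    m = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8)
    return m.reshape(len(aln.rows), aln.length)


def _pair_arrays(enc: np.ndarray):
    """Per-pair (comparable, different) boolean matrices over columns."""
    base = (
        (enc == ord("A")) | (enc == ord("C")) | (enc == ord("G")) | (enc == ord("T"))
    )
    pairs = list(combinations(range(enc.shape[0]), 2))
    comp = np.array([base[i] & base[j] for i, j in pairs])
    diff = np.array([(enc[i] != enc[j]) for i, j in pairs]) & comp
    return comp, diff


def _pi_over_columns(comp: np.ndarray, diff: np.ndarray, cols: np.ndarray):
    """Mean over pairs of diff/compared restricted to ``cols``; NaN when no
    pair has a comparable site.  Returns (pi, n_sites_used)."""
    c = comp[:, cols].sum(axis=1)
    d = diff[:, cols].sum(axis=1)
    ok = c > 0
    n_used = int(comp[:, cols].any(axis=0).sum())
    if not ok.any():
        return float("nan"), n_used
    return float(np.mean(d[ok] / c[ok])), n_used


def sliding_window_pi(
    aln: MultipleAlignment, window: int = 500, step: int = 500
) -> list[DiversityWindow]:
    """Nucleotide diversity per sliding window of alignment columns."""
    if window < 1 or step < 1:
        raise PlastomeError("window and step must be >= 1")
    enc = _encode_rows(aln)
    comp, diff = _pair_arrays(enc)
    out = []
    for start in range(0, aln.length, step):
        end = min(start + window, aln.length)
        cols = np.arange(start, end)
        pi, n_used = _pi_over_columns(comp, diff, cols)
        out.append(DiversityWindow(start + 1, end, pi, n_used))
        if end == aln.length:
            break
    return out


def per_feature_pi(
    aln: MultipleAlignment,
    features: list[tuple[str, str, list[tuple[int, int]]]],
) -> pd.DataFrame:
    """Pi over the union of each feature's alignment columns.

    ``features`` are (name, class, intervals) with 1-based inclusive
    intervals in alignment coordinates; class is typically one of
    gene / intron / intergenic.
    """
    enc = _encode_rows(aln)
    comp, diff = _pair_arrays(enc)
    rows = []
    for name, cls, intervals in features:
        cols: list[int] = []
        for s, e in intervals:
            if s < 1 or e > aln.length or e < s:
                raise PlastomeError(f"feature {name}: interval ({s},{e}) outside alignment")
            cols.extend(range(s - 1, e))
        pi, n_used = _pi_over_columns(comp, diff, np.array(sorted(set(cols)), dtype=int))
        rows.append({"feature": name, "class": cls, "pi": pi, "n_sites_used": n_used})
    return pd.DataFrame(rows)


def call_hotspots(
    track: list[DiversityWindow], threshold: float = 0.02
) -> list[DiversityWindow]:
    """Windows with pi strictly above the threshold, sorted by value descending."""
    if not track:
        raise PlastomeError("empty track")
    hits = [w for w in track if not math.isnan(w.value) and w.value > threshold]
    hits.sort(key=lambda w: (-w.value, w.window_start))
    return hits


def identity_track(
    aln: MultipleAlignment,
    reference: str,
    other: str,
    window: int = 500,
    step: int = 500,
) -> list[DiversityWindow]:
    """Percent identity of ``other`` against ``reference`` per window.

    Columns where either row has a gap or N are not comparable; a window
    with no comparable column reports NaN.
    """
    if window < 1 or step < 1:
        raise PlastomeError("window and step must be >= 1")
    a = np.frombuffer(aln.row(reference).encode(), dtype=np.uint8)
    b = np.frombuffer(aln.row(other).encode(), dtype=np.uint8)
    base = lambda x: (x == ord("A")) | (x == ord("C")) | (x == ord("G")) | (x == ord("T"))
    comp = base(a) & base(b)
    match = comp & (a == b)
    out = []
    for start in range(0, aln.length, step):
        end = min(start + window, aln.length)
        c = int(comp[start:end].sum())
        m = int(match[start:end].sum())
        value = 100.0 * m / c if c else float("nan")
        out.append(DiversityWindow(start + 1, end, value, c))
        if end == aln.length:
            break
    return out


def track_to_frame(track: list[DiversityWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "window_start": w.window_start,
                "window_end": w.window_end,
                "value": w.value,
                "n_sites_used": w.n_sites_used,
            }
            for w in track
        ]
    )
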