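"""Inter-genome architecture comparison.

Compares plastomes at gene granularity: signed gene-order inversion
detection (the petN/psbM case), gene presence/absence matrices (by default
over the 11 ndh chlororespiratory genes), and reports of the genes flanking
or straddling the four single-copy/inverted-repeat junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import AnnotatedPlastome, NDH_GENES, PlastomeError, signed_gene_order
from .partition import QuadripartitePartition


@dataclass(frozen=True)
class StructuralDifference:
    kind: str  # inversion | presence_absence | translocation_or_other
    genes: tuple[str, ...]
    index_a: tuple[int, int]  # 0-based index range in order A (or (-1,-1))
    index_b: tuple[int, int]


def detect_inversions(
    order_a: list[tuple[str, int, str]], order_b: list[tuple[str, int, str]]
) -> list[StructuralDifference]:
    """Differences between two signed gene orders.

    Both orders are restricted to their shared (symbol, copy_index) keys;
    genes private to one genome are reported as ``presence_absence``.  Every
    maximal contiguous run where B disagrees with A is classified as an
    ``inversion`` when B's run equals A's run reversed with flipped strands,
    otherwise as ``translocation_or_other``.
    """
    if not order_a or not order_b:
        raise PlastomeError("empty gene order")
    keys_a = [(g, c) for g, c, _ in order_a]
    keys_b = [(g, c) for g, c, _ in order_b]
    shared = set(keys_a) & set(keys_b)
    out: list[StructuralDifference] = []
    for key in sorted(set(keys_a) ^ set(keys_b)):
        out.append(
            StructuralDifference(
                kind="presence_absence", genes=(key[0],), index_a=(-1, -1), index_b=(-1, -1)
            )
        )
    a = [(g, c, s) for g, c, s in order_a if (g, c) in shared]
    b = [(g, c, s) for g, c, s in order_b if (g, c) in shared]
    if len(a) != len(b):  # duplicate keys resolved differently; bail out coarsely
        raise PlastomeError("shared gene orders are not comparable (duplicate keys)")
    flip = {"+": "-", "-": "+"}
    i = 0
    n = len(a)
    while i < n:
        if a[i] == b[i]:
            i += 1
            continue
        j = i
        while j < n and a[j] != b[j]:
            j += 1
        run_a = a[i:j]
        run_b = b[i:j]
        reversed_flipped = [(g, c, flip[s]) for g, c, s in reversed(run_a)]
        kind = "inversion" if run_b == reversed_flipped else "translocation_or_other"
        out.append(
            StructuralDifference(
                kind=kind,
                genes=tuple(g for g, _, _ in run_a),
                index_a=(i, j - 1),
                index_b=(i, j - 1),
            )
        )
        i = j
    return out


def detect_inversions_between(
    pa: AnnotatedPlastome, pb: AnnotatedPlastome
) -> list[StructuralDifference]:
    return detect_inversions(signed_gene_order(pa), signed_gene_order(pb))


def presence_absence_matrix(
    plastomes: list[AnnotatedPlastome],
    gene_set: tuple[str, ...] = NDH_GENES,
) -> pd.DataFrame:
    """Binary genomes x genes matrix (1 iff a non-partial copy is annotated),
    plus a ``total`` column of per-genome sums.

    Symbols absent from every genome yield all-zero columns (a warning is
    carried in the DataFrame attrs rather than raised).
    """
    unknown = [
        g
        for g in gene_set
        if not any(f.name == g for p in plastomes for f in p.features)
    ]
    rows = []
    for p in plastomes:
        present = {f.name for f in p.features if not f.partial}
        rows.append([int(g in present) for g in gene_set])
    df = pd.DataFrame(rows, index=[p.id for p in plastomes], columns=list(gene_set))
    df["total"] = df.sum(axis=1)
    df.attrs["unknown_symbols"] = unknown
    return df


def ssc_boundary_report(
    plastome: AnnotatedPlastome, partition: QuadripartitePartition
) -> pd.DataFrame:
    """Genes nearest to (or straddling) each of the four region junctions.

    For every junction the nearest feature on each side is reported with its
    signed distance in bp (0 when the gene straddles the junction, in which
    case the overlap length on each side is given).  Distances are measured
    on the linearised coordinate system of the input record.
    """
    partition.validate(plastome)
    junctions = []
    for left, right, iv_left, iv_right in [
        ("LSC", "IRa", partition.lsc, partition.ira),
        ("IRa", "SSC", partition.ira, partition.ssc),
        ("SSC", "IRb", partition.ssc, partition.irb),
        ("IRb", "LSC", partition.irb, partition.lsc),
    ]:
        junctions.append((f"{left}/{right}", iv_left[1], iv_right[0]))
    feats = sorted(plastome.features, key=lambda f: f.start)
    rows = []
    for name, left_end, right_start in junctions:
        straddlers = [
            f
            for f in feats
            if f.start <= left_end and f.end >= right_start and right_start == left_end + 1
        ]
        if straddlers:
            for f in straddlers:
                rows.append(
                    {
                        "junction": name,
                        "gene": f.name,
                        "copy_index": f.copy_index,
                        "relation": "straddles",
                        "distance_bp": 0,
                        "overlap_left_bp": left_end - f.start + 1,
                        "overlap_right_bp": f.end - right_start + 1,
                    }
                )
            continue
        left_side = [f for f in feats if f.end <= left_end]
        right_side = [f for f in feats if f.start >= right_start]
        if left_side:
            f = max(left_side, key=lambda f: f.end)
            rows.append(
                {
                    "junction": name,
                    "gene": f.name,
                    "copy_index": f.copy_index,
                    "relation": "left",
                    "distance_bp": left_end - f.end,
                    "overlap_left_bp": 0,
                    "overlap_right_bp": 0,
                }
            )
        if right_side:
            f = min(right_side, key=lambda f: f.start)
            rows.append(
                {
                    "junction": name,
                    "gene": f.name,
                    "copy_index": f.copy_index,
                    "relation": "right",
                    "distance_bp": f.start - right_start,
                    "overlap_left_bp": 0,
                    "overlap_right_bp": 0,
                }
            )
    return pd.DataFrame(rows)


def apply_inversion(
    order: list[tuple[str, int, str]], index_range: tuple[int, int]
) -> list[tuple[str, int, str]]:
    """Reverse the block (inclusive index range) with flipped strands; used
    to round-trip detected inversions."""
    i, j = index_range
    flip = {"+": "-", "-": "+"}
    block = [(g, c, flip[s]) for g, c, s in reversed(order[i : j + 1])]
    return order[:i] + block + order[j + 1 :]
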