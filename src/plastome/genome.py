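"""Plastome sequences and annotations.

A chloroplast genome (plastome) is modelled as a circular DNA sequence plus
a flat list of gene features.  Each feature carries its gene symbol, a broad
category (protein-coding / tRNA / rRNA / pseudogene), a strand, and one or
more 1-based inclusive exon intervals.  Genes duplicated in the inverted
repeats appear as separate features sharing a symbol and distinguished by
``copy_index``; the trans-spliced rps12 gene is stored as separate features
per locus, flagged ``trans_spliced``.

Readers accept GenBank flat files and FASTA + GFF3 pairs; the writer emits
FASTA + GFF3 so that read -> write -> read round-trips exactly.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

PROTEIN_CODING = "protein_coding"
TRNA = "tRNA"
RRNA = "rRNA"
PSEUDOGENE = "pseudogene"

CATEGORIES = (PROTEIN_CODING, TRNA, RRNA, PSEUDOGENE)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: the 11 plastid NAD(P)H-dehydrogenase complex genes
NDH_GENES = tuple("ndh" + x for x in "ABCDEFGHIJK")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


class PlastomeError(ValueError):
    """Raised on malformed plastome input or contract violations."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene copy.

    ``parts`` are ordered 1-based inclusive exon intervals on the plus
    strand of the genome; for minus-strand genes the spliced transcript is
    the reverse complement of the concatenated parts.
    """

    name: str
    category: str
    strand: str
    parts: tuple[tuple[int, int], ...]
    copy_index: int = 1
    partial: bool = False
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise PlastomeError(f"unknown feature category {self.category!r}")
        if self.strand not in "+-":
            raise PlastomeError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.parts:
            raise PlastomeError(f"feature {self.name}: parts must be non-empty")
        ivs = sorted(self.parts)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise PlastomeError(f"feature {self.name}: overlapping parts")
        for s, e in self.parts:
            if s < 1 or e < s:
                raise PlastomeError(f"feature {self.name}: bad interval ({s},{e})")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.parts)

    @property
    def end(self) -> int:
        return max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)

    def spliced_seq(self, genome_seq: str) -> str:
        """Strand-oriented spliced sequence (5'->3' of the transcript)."""
        parts = sorted(self.parts)
        s = "".join(genome_seq[a - 1 : b] for a, b in parts)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class AnnotatedPlastome:
    """A circular plastome sequence with its gene features."""

    id: str
    seq: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise PlastomeError("empty sequence")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise PlastomeError(f"sequence contains non-DNA characters {sorted(bad)}")
        n = len(self.seq)
        for f in self.features:
            if f.end > n:
                raise PlastomeError(
                    f"feature {f.name} interval ends at {f.end} beyond sequence length {n}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def region_seq(self, start: int, end: int) -> str:
        """Subsequence for a 1-based inclusive interval; wraps the origin when start > end."""
        if start <= end:
            return self.seq[start - 1 : end]
        if not self.circular:
            raise PlastomeError("wrapping interval on a linear sequence")
        return self.seq[start - 1 :] + self.seq[:end]

    def features_by_symbol(self) -> dict[str, list[GeneFeature]]:
        by: dict[str, list[GeneFeature]] = collections.defaultdict(list)
        for f in self.features:
            by[f.name].append(f)
        return dict(by)


# ---------------------------------------------------------------------------
# GenBank / FASTA+GFF3 I/O
# ---------------------------------------------------------------------------

_GB_TYPE_MAP = {"CDS": PROTEIN_CODING, "tRNA": TRNA, "rRNA": RRNA}


def _parts_from_location(location) -> tuple[tuple[int, int], ...]:
    return tuple(
        sorted((int(p.start) + 1, int(p.end)) for p in location.parts)
    )


def _read_genbank(path: Path) -> AnnotatedPlastome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise PlastomeError(f"cannot parse GenBank file {path}: {exc}") from exc
    feats: list[GeneFeature] = []
    counters: collections.Counter[str] = collections.Counter()
    pseudo_symbols: set[str] = set()
    for sf in record.features:
        if sf.type == "gene" and ("pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers):
            sym = sf.qualifiers.get("gene", ["?"])[0]
            pseudo_symbols.add(sym)
            counters[sym] += 1
            feats.append(
                GeneFeature(
                    name=sym,
                    category=PSEUDOGENE,
                    strand="-" if sf.location.strand == -1 else "+",
                    parts=_parts_from_location(sf.location),
                    copy_index=counters[sym],
                    partial=True,
                )
            )
    for sf in record.features:
        cat = _GB_TYPE_MAP.get(sf.type)
        if cat is None:
            continue
        sym = sf.qualifiers.get("gene", sf.qualifiers.get("locus_tag", ["?"]))[0]
        if sym in pseudo_symbols:
            continue
        parts = _parts_from_location(sf.location)
        total = sum(e - s + 1 for s, e in parts)
        partial = cat == PROTEIN_CODING and total % 3 != 0
        counters[sym] += 1
        feats.append(
            GeneFeature(
                name=sym,
                category=cat,
                strand="-" if sf.location.strand == -1 else "+",
                parts=parts,
                copy_index=counters[sym],
                partial=partial,
                trans_spliced="trans_splicing" in sf.qualifiers,
            )
        )
    topo = record.annotations.get("topology", "circular")
    return AnnotatedPlastome(
        id=record.id, seq=str(record.seq), circular=topo != "linear", features=feats
    )


_GFF_TYPE_MAP = {"CDS": PROTEIN_CODING, "tRNA": TRNA, "rRNA": RRNA, "pseudogene": PSEUDOGENE}
_GFF_TYPE_INV = {v: k for k, v in _GFF_TYPE_MAP.items()}


def _read_fasta_gff3(fasta: Path, gff: Path | None) -> AnnotatedPlastome:
    try:
        record = next(SeqIO.parse(str(fasta), "fasta"))
    except (StopIteration, ValueError) as exc:
        raise PlastomeError(f"cannot parse FASTA file {fasta}: {exc}") from exc
    plastome = AnnotatedPlastome(id=record.id, seq=str(record.seq))
    if gff is None:
        return plastome
    import gffutils

    db = gffutils.create_db(str(gff), ":memory:", merge_strategy="create_unique")
    feats = []
    for gene in db.features_of_type("gene"):
        attrs = gene.attributes
        parts: list[tuple[int, int]] = []
        category = None
        for child in db.children(gene.id):
            if child.featuretype in _GFF_TYPE_MAP:
                category = _GFF_TYPE_MAP[child.featuretype]
                parts.append((child.start, child.end))
        if category is None:
            category = _GFF_TYPE_MAP.get(attrs.get("category", ["CDS"])[0], PROTEIN_CODING)
            parts = [(gene.start, gene.end)]
        feats.append(
            GeneFeature(
                name=attrs.get("gene", [gene.id])[0],
                category=category,
                strand=gene.strand if gene.strand in "+-" else "+",
                parts=tuple(sorted(parts)),
                copy_index=int(attrs.get("copy_index", ["1"])[0]),
                partial=attrs.get("partial", ["false"])[0] == "true",
                trans_spliced=attrs.get("trans_spliced", ["false"])[0] == "true",
            )
        )
    feats.sort(key=lambda f: (f.start, f.name, f.copy_index))
    plastome.features = feats
    plastome.__post_init__()  # re-validate feature bounds
    return plastome


def read_plastome(
    path: str | Path, format: str = "genbank", gff: str | Path | None = None
) -> AnnotatedPlastome:
    """Read a plastome from GenBank or FASTA (+ optional GFF3 annotation).

    Parameters
    ----------
    path
        GenBank flat file, or FASTA file when ``format="fasta+gff3"``.
    format
        ``"genbank"`` or ``"fasta+gff3"``.
    gff
        GFF3 annotation path for the FASTA route; if omitted and a sibling
        file with suffix ``.gff3`` exists it is used, else no features.
    """
    path = Path(path)
    if not path.exists():
        raise PlastomeError(f"no such file: {path}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+gff3":
        gffp = Path(gff) if gff is not None else path.with_suffix(".gff3")
        return _read_fasta_gff3(path, gffp if gffp.exists() else None)
    raise PlastomeError(f"unknown format {format!r}")


def write_plastome(plastome: AnnotatedPlastome, fasta: str | Path, gff: str | Path) -> None:
    """Write FASTA + GFF3 such that :func:`read_plastome` round-trips exactly."""
    fasta, gff = Path(fasta), Path(gff)
    with open(fasta, "w") as fh:
        fh.write(f">{plastome.id}\n")
        for i in range(0, len(plastome.seq), 70):
            fh.write(plastome.seq[i : i + 70] + "\n")
    feats = sorted(plastome.features, key=lambda f: (f.start, f.name, f.copy_index))
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.id} 1 {len(plastome.seq)}\n")
        for i, f in enumerate(feats, 1):
            gid = f"gene{i}"
            attrs = (
                f"ID={gid};gene={f.name};copy_index={f.copy_index};"
                f"partial={'true' if f.partial else 'false'};"
                f"trans_spliced={'true' if f.trans_spliced else 'false'}"
            )
            fh.write(
                f"{plastome.id}\tplastome\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )
            sub = _GFF_TYPE_INV[f.category]
            for j, (s, e) in enumerate(sorted(f.parts), 1):
                phase = "0" if f.category == PROTEIN_CODING else "."
                fh.write(
                    f"{plastome.id}\tplastome\t{sub}\t{s}\t{e}\t.\t{f.strand}\t{phase}\t"
                    f"ID={gid}.{j};Parent={gid}\n"
                )


# ---------------------------------------------------------------------------
# Gene census
# ---------------------------------------------------------------------------


def gene_census(plastome: AnnotatedPlastome) -> dict[str, int]:
    """Count annotated genes the way plastome papers tabulate them.

    ``total`` counts every feature copy; the per-category counts collapse IR
    duplicates by gene symbol.  ``intron_containing`` counts symbols with at
    least one multi-exon copy; ``ir_duplicated`` counts symbols present in
    more than one copy; ``partial`` counts symbols flagged partial or
    annotated as pseudogenes.
    """
    feats = plastome.features
    symbols = {f.name for f in feats}

    def uniq(pred) -> int:
        return len({f.name for f in feats if pred(f)})

    return {
        "total": len(feats),
        "unique_symbols": len(symbols),
        "unique_protein_coding": uniq(
            lambda f: f.category == PROTEIN_CODING and not f.partial
        ),
        "trna": uniq(lambda f: f.category == TRNA),
        "rrna": uniq(lambda f: f.category == RRNA),
        "intron_containing": uniq(lambda f: len(f.parts) > 1 and not f.trans_spliced),
        "ir_duplicated": sum(
            1 for sym, fs in plastome.features_by_symbol().items() if len(fs) > 1
        ),
        "partial": uniq(lambda f: f.partial or f.category == PSEUDOGENE),
    }


def signed_gene_order(plastome: AnnotatedPlastome) -> list[tuple[str, int, str]]:
    """(symbol, copy_index, strand) tuples ordered by ascending start coordinate."""
    feats = sorted(plastome.features, key=lambda f: (f.start, f.name, f.copy_index))
    return [(f.name, f.copy_index, f.strand) for f in feats]
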