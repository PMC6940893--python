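"""C-to-U RNA-editing site calling from per-replicate pileups.

Chloroplast transcripts undergo post-transcriptional C-to-U editing.  On
the genome plus strand an edited site appears as C positions with T reads
(plus-strand genes) or G positions with A reads (minus-strand genes).  A
site is called when the edited base is observed (editing level > 0) in at
least ``min_replicates`` biological replicates, each with coverage of at
least ``min_coverage`` uniquely mapped reads; the editing level per
replicate is edited/(edited + reference) x 100, so reads supporting neither
base (sequencing error) never enter the denominator.  Called sites inside a
CDS are annotated with the codon change under the plant-plastid (bacterial)
genetic code and a physicochemical classification of the amino-acid
transition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .genome import AnnotatedPlastome, GeneFeature, PlastomeError, PROTEIN_CODING

logger = logging.getLogger(__name__)

PILEUP_COLUMNS = ("replicate", "position", "A", "C", "G", "T")

#: hydrophilic -> hydrophobic transitions reported as physicochemical changes
PHYSICOCHEMICAL_CHANGED = {("S", "L"), ("S", "F"), ("R", "C")}
#: transitions reported as having no physicochemical consequence
PHYSICOCHEMICAL_UNCHANGED = {
    ("A", "V"),
    ("H", "Y"),
    ("L", "F"),
    ("P", "F"),
    ("P", "L"),
    ("P", "S"),
    ("R", "W"),
    ("T", "I"),
    ("T", "M"),
}

_AA = set("ACDEFGHIKLMNPQRSTVWY*")

PLASTID_CODON_TABLE = 11  # bacterial / plant-plastid genetic code


@dataclass(frozen=True)
class EditingFilterConfig:
    min_coverage: int = 10
    min_replicates: int = 2
    min_level: float = 0.0  # presence requires level strictly above this

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.min_replicates < 1 or self.min_level < 0:
            raise PlastomeError("editing filter parameters must be positive")


@dataclass
class EditingSite:
    gene: str
    position: int  # 1-based genome coordinate
    strand: str
    codon_from: str  # RNA triplet, e.g. "UCA"
    codon_to: str
    codon_position: int  # 1..3
    aa_from: str
    aa_to: str
    effect: str  # synonymous | nonsynonymous | stop_gained | unresolved
    physicochemical_change: bool
    levels: dict[str, float] = field(default_factory=dict)  # replicate -> 0..100
    coverages: dict[str, int] = field(default_factory=dict)
    notes: str = ""


def classify_physicochemical(aa_from: str, aa_to: str) -> tuple[bool, str]:
    """Physicochemical classification of an amino-acid transition.

    Follows the hydrophilic->hydrophobic enumeration used for plastid
    editing surveys verbatim (S->L, S->F, R->C change; A->V, H->Y, L->F,
    P->F, P->L, P->S, R->W, T->I, T->M do not); pairs outside the table
    are labelled ``unlisted`` and not flagged.  Transitions to or from a
    stop codon are flagged separately as ``stop_transition``.
    """
    for aa in (aa_from, aa_to):
        if aa not in _AA:
            raise PlastomeError(f"unknown residue {aa!r}")
    if aa_from == aa_to:
        return False, "identity"
    if "*" in (aa_from, aa_to):
        return False, "stop_transition"
    pair = (aa_from, aa_to)
    if pair in PHYSICOCHEMICAL_CHANGED:
        return True, "hydrophilic_to_hydrophobic"
    if pair in PHYSICOCHEMICAL_UNCHANGED:
        return False, "listed_no_change"
    return False, "unlisted"


def codon_effect(codon_from: str, codon_to: str) -> tuple[int, str, str, str]:
    """Effect of a C-to-U edit given the RNA codons before and after.

    Returns (codon_position 1-3, aa_from, aa_to, effect).  The codons must
    differ at exactly one position, by C -> U.
    """
    cf, ct = codon_from.upper().replace("T", "U"), codon_to.upper().replace("T", "U")
    if len(cf) != 3 or len(ct) != 3:
        raise PlastomeError("codons must be triplets")
    diffs = [i for i in range(3) if cf[i] != ct[i]]
    if len(diffs) != 1 or cf[diffs[0]] != "C" or ct[diffs[0]] != "U":
        raise PlastomeError(f"{codon_from}->{codon_to} is not a single C->U edit")
    pos = diffs[0] + 1
    aa_from = str(Seq(cf.replace("U", "T")).translate(table=PLASTID_CODON_TABLE))
    aa_to = str(Seq(ct.replace("U", "T")).translate(table=PLASTID_CODON_TABLE))
    if aa_to == "*":
        effect = "stop_gained"
    elif aa_from == aa_to:
        effect = "synonymous"
    else:
        effect = "nonsynonymous"
    return pos, aa_from, aa_to, effect


# ---------------------------------------------------------------------------
# CDS coordinate machinery
# ---------------------------------------------------------------------------


def _assemble_trans_spliced(
    plastome: AnnotatedPlastome, feature: GeneFeature
) -> list[GeneFeature] | None:
    """Ordered loci of a trans-spliced gene (same symbol and copy choice),
    or None when the transcript order is ambiguous."""
    loci = [
        f
        for f in plastome.features
        if f.name == feature.name and f.trans_spliced
    ]
    # collapse IR duplicates: keep the copy matching the query locus, else copy 1
    by_span: dict[tuple, list[GeneFeature]] = {}
    for f in loci:
        by_span.setdefault((f.length, len(f.parts)), []).append(f)
    chosen = []
    for group in by_span.values():
        same = [f for f in group if f.copy_index == feature.copy_index]
        chosen.append(same[0] if same else min(group, key=lambda f: f.copy_index))
    strands = {f.strand for f in chosen}
    if len(strands) != 1:
        return None
    ordered = sorted(chosen, key=lambda f: f.start)
    if strands == {"-"}:
        ordered = ordered[::-1]
    return ordered


def spliced_cds(
    plastome: AnnotatedPlastome, feature: GeneFeature
) -> tuple[str, list[int]] | None:
    """Spliced 5'->3' CDS sequence and, per transcript index, the 1-based
    genome position it came from.  Returns None for unresolvable
    trans-spliced assemblies."""
    loci = (
        _assemble_trans_spliced(plastome, feature)
        if feature.trans_spliced
        else [feature]
    )
    if loci is None:
        return None
    seq_parts: list[str] = []
    pos_parts: list[int] = []
    for f in loci:
        parts = sorted(f.parts)
        if f.strand == "-":
            parts = parts[::-1]
        for s, e in parts:
            block = plastome.seq[s - 1 : e]
            block_pos = list(range(s, e + 1))
            if f.strand == "-":
                from .genome import revcomp

                block = revcomp(block)
                block_pos = block_pos[::-1]
            seq_parts.append(block)
            pos_parts.extend(block_pos)
    return "".join(seq_parts), pos_parts


def annotate_codon_change(
    position: int, plastome: AnnotatedPlastome, feature: GeneFeature | None = None
) -> EditingSite:
    """Annotate the codon-level effect of a C-to-U edit at a genome position.

    The codon is taken from the spliced, strand-oriented CDS; the edited
    codon replaces the C at the transcript position with U and is translated
    under the plant-plastid genetic code.
    """
    if feature is None:
        feature = find_cds(plastome, position)
        if feature is None:
            raise PlastomeError(f"position {position} is not inside any CDS")
    assembled = spliced_cds(plastome, feature)
    if assembled is None:
        return EditingSite(
            gene=feature.name,
            position=position,
            strand=feature.strand,
            codon_from="",
            codon_to="",
            codon_position=0,
            aa_from="",
            aa_to="",
            effect="unresolved",
            physicochemical_change=False,
            notes="trans-spliced assembly unresolved",
        )
    cds, pos_map = assembled
    notes = []
    if len(cds) % 3 != 0:
        raise PlastomeError(f"partial CDS: {feature.name} length {len(cds)} not divisible by 3")
    t_idx = pos_map.index(position)
    if cds[t_idx] != "C":
        raise PlastomeError(
            f"reference base at {position} is {cds[t_idx]} on the {feature.name} strand, not C"
        )
    codon_idx = t_idx // 3
    offset = t_idx % 3
    codon_from_dna = cds[3 * codon_idx : 3 * codon_idx + 3]
    codon_to_dna = codon_from_dna[:offset] + "T" + codon_from_dna[offset + 1 :]
    pos_in_codon, aa_from, aa_to, effect = codon_effect(
        codon_from_dna.replace("T", "U"), codon_to_dna.replace("T", "U")
    )
    if codon_idx == 0:
        notes.append("edit within annotated start codon")
    changed, category = classify_physicochemical(aa_from, aa_to)
    if category == "stop_transition":
        notes.append("stop transition")
    return EditingSite(
        gene=feature.name,
        position=position,
        strand=feature.strand,
        codon_from=codon_from_dna.replace("T", "U"),
        codon_to=codon_to_dna.replace("T", "U"),
        codon_position=pos_in_codon,
        aa_from=aa_from,
        aa_to=aa_to,
        effect=effect,
        physicochemical_change=changed,
        notes="; ".join(notes),
    )


def find_cds(plastome: AnnotatedPlastome, position: int) -> GeneFeature | None:
    """The protein-coding, non-partial feature whose exons cover the position
    (first by start coordinate when several overlap)."""
    hits = [
        f
        for f in sorted(plastome.features, key=lambda f: (f.start, f.copy_index))
        if f.category == PROTEIN_CODING
        and not f.partial
        and any(s <= position <= e for s, e in f.parts)
    ]
    return hits[0] if hits else None


# ---------------------------------------------------------------------------
# Caller
# ---------------------------------------------------------------------------


def validate_pileups(pileups: pd.DataFrame) -> pd.DataFrame:
    missing = set(PILEUP_COLUMNS) - set(pileups.columns)
    if missing:
        raise PlastomeError(f"pileup table missing columns {sorted(missing)}")
    if (pileups[list("ACGT")] < 0).any().any():
        raise PlastomeError("negative base counts in pileup")
    return pileups


def call_editing_sites(
    pileups: pd.DataFrame,
    plastome: AnnotatedPlastome,
    cfg: EditingFilterConfig = EditingFilterConfig(),
) -> list[EditingSite]:
    """Call C-to-U editing sites from per-replicate pileups.

    ``pileups`` holds plus-strand base counts from uniquely mapped reads
    (columns replicate, position, A, C, G, T).  Levels are reported for all
    replicates, including zeros; sites outside any CDS, or whose reference
    base is not C on the gene strand, are skipped with a log entry.
    """
    validate_pileups(pileups)
    replicates = sorted(pileups["replicate"].astype(str).unique())
    if len(replicates) < cfg.min_replicates:
        raise PlastomeError(
            f"{len(replicates)} replicate(s) supplied; at least {cfg.min_replicates} required"
        )
    sites: list[EditingSite] = []
    for position, group in pileups.groupby("position", sort=True):
        position = int(position)
        if position < 1 or position > len(plastome.seq):
            raise PlastomeError(f"pileup position {position} outside genome")
        feature = find_cds(plastome, position)
        if feature is None:
            logger.debug("position %d not inside any CDS; skipped", position)
            continue
        ref_plus = plastome.seq[position - 1]
        if feature.strand == "+":
            if ref_plus != "C":
                logger.debug(
                    "position %d: reference %s not C on + gene %s; skipped",
                    position, ref_plus, feature.name,
                )
                continue
            ref_col, edited_col = "C", "T"
        else:
            if ref_plus != "G":
                logger.debug(
                    "position %d: reference %s not C on - gene %s; skipped",
                    position, ref_plus, feature.name,
                )
                continue
            ref_col, edited_col = "G", "A"
        levels: dict[str, float] = {r: 0.0 for r in replicates}
        coverages: dict[str, int] = {r: 0 for r in replicates}
        passing = 0
        for _, row in group.iterrows():
            rep = str(row["replicate"])
            cov = int(row["A"] + row["C"] + row["G"] + row["T"])
            edited = int(row[edited_col])
            ref = int(row[ref_col])
            level = 100.0 * edited / (edited + ref) if (edited + ref) > 0 else 0.0
            levels[rep] = level
            coverages[rep] = cov
            if level > cfg.min_level and cov >= cfg.min_coverage:
                passing += 1
        if passing < cfg.min_replicates:
            continue
        site = annotate_codon_change(position, plastome, feature)
        site.levels = levels
        site.coverages = coverages
        sites.append(site)
    return sites


def transition_spectrum(sites: list[EditingSite]) -> dict:
    """Multiset of amino-acid transitions and effect totals."""
    transitions: dict[tuple[str, str], int] = {}
    totals = {"synonymous": 0, "nonsynonymous": 0, "stop_gained": 0, "unresolved": 0}
    for s in sites:
        totals[s.effect] = totals.get(s.effect, 0) + 1
        if s.effect in ("nonsynonymous", "stop_gained"):
            key = (s.aa_from, s.aa_to)
            transitions[key] = transitions.get(key, 0) + 1
    return {"transitions": transitions, "totals": totals}


def sites_to_frame(sites: list[EditingSite]) -> pd.DataFrame:
    """Editing sites as a table shaped like published editing surveys."""
    rows = []
    for s in sites:
        row = {
            "gene": s.gene,
            "position": s.position,
            "strand": s.strand,
            "codon_from": s.codon_from,
            "codon_to": s.codon_to,
            "codon_position": s.codon_position,
            "aa_from": s.aa_from,
            "aa_to": s.aa_to,
            "effect": s.effect,
            "physicochemical_change": s.physicochemical_change,
            "notes": s.notes,
        }
        for rep in sorted(s.levels):
            row[f"level_{rep}"] = s.levels[rep]
        rows.append(row)
    return pd.DataFrame(rows)


def pileups_from_sam(
    path: str, replicate: str, min_mapq: int = 1, max_hits: int = 1
) -> pd.DataFrame:
    """Plus-strand base counts per covered position from a SAM/BAM file,
    keeping uniquely mapped reads only (NH tag <= max_hits when present,
    and mapping quality >= min_mapq)."""
    import pysam

    counts: dict[int, dict[str, int]] = {}
    with pysam.AlignmentFile(path) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > max_hits:
                continue
            seq = read.query_sequence
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base not in "ACGT":
                    continue
                col = counts.setdefault(rpos + 1, {"A": 0, "C": 0, "G": 0, "T": 0})
                col[base] += 1
    rows = [
        {"replicate": replicate, "position": pos, **bases}
        for pos, bases in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=list(PILEUP_COLUMNS))
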