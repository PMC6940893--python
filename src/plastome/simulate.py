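"""Seeded generator of synthetic plastome study sets with planted ground truth.

The generator emulates the structure of a three-morphotype intraspecific
plastome study at reduced scale: three haplotypes with circular
quadripartite genomes (genes duplicated in the IRs, an intron-bearing gene,
a trans-spliced two-locus gene), planted SSR and long-repeat motifs,
inter-haplotype SNP divergence with localised hotspots, a two-gene
inverted block in the third haplotype, per-replicate pileups with planted
C-to-U edits, and negative-binomial count matrices with 3/3/2 replicate
structure.

Background sequence is i.i.d. uniform over A/C/G/T and then repaired so
that it is free of accidental SSRs and long repeats above the reporting
thresholds; planted censuses are therefore exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import MultipleAlignment
from .editing import PILEUP_COLUMNS, spliced_cds
from .genome import (
    AnnotatedPlastome,
    GeneFeature,
    PlastomeError,
    PROTEIN_CODING,
    PSEUDOGENE,
    RRNA,
    TRNA,
    revcomp,
)
from .repeats import SSRRecord, find_long_repeats, find_ssrs

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneModel:
    name: str
    region: str  # lsc | ssc | ir
    strand: str
    exon_lens: tuple[int, ...]
    intron_lens: tuple[int, ...] = ()
    category: str = PROTEIN_CODING
    trans_spliced: bool = False
    partial: bool = False

    @property
    def span(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)


@dataclass(frozen=True)
class EditingPlanting:
    gene: str
    codon_index: int  # 0-based codon within the spliced CDS
    codon: str  # DNA codon on the gene strand, e.g. "TCA"
    edit_offset: int  # 0-2; must be a C in ``codon``
    levels: tuple[float, ...]  # percent, one per replicate
    coverage: int = 30

    def __post_init__(self) -> None:
        if self.codon[self.edit_offset] != "C":
            raise PlastomeError(
                f"editing planting in {self.gene}: codon {self.codon} has no C "
                f"at offset {self.edit_offset}"
            )
        if not all(0 <= l <= 100 for l in self.levels):
            raise PlastomeError("editing levels must be in [0, 100]")


def _default_genes() -> tuple[GeneModel, ...]:
    g = GeneModel
    return (
        # LSC, in layout order; petN/psbM lead so the invertible block is compact
        g("petN", "lsc", "+", (90,)),
        g("psbM", "lsc", "-", (105,)),
        g("psbA", "lsc", "+", (300,)),
        g("rps14", "lsc", "-", (303,)),
        g("rbcL", "lsc", "+", (501,)),
        g("petB", "lsc", "+", (60, 390), (90,)),
        g("psbB", "lsc", "+", (342,)),
        g("psaA", "lsc", "-", (402,)),
        g("matK", "lsc", "-", (510,)),
        g("atpF", "lsc", "+", (150, 240), (60,)),
        g("ndhC", "lsc", "-", (120,)),
        g("ndhK", "lsc", "-", (120,)),
        g("ndhJ", "lsc", "-", (120,)),
        g("trnH", "lsc", "+", (74,), category=TRNA),
        g("trnL", "lsc", "+", (80,), category=TRNA),
        g("rps12", "lsc", "+", (114,), trans_spliced=True),  # 5' locus
        # IR (one copy described; the generator mirrors it into IRb)
        g("rrn16", "ir", "+", (200,), category=RRNA),
        g("trnI", "ir", "+", (74,), category=TRNA),
        g("ndhB", "ir", "+", (120, 150), (60,)),
        g("rps12", "ir", "+", (120, 90), (50,), trans_spliced=True),  # 3' locus
        g("ycf15", "ir", "+", (100,), category=PSEUDOGENE, partial=True),
        # SSC
        g("ndhF", "ssc", "-", (180,)),
        g("ndhD", "ssc", "-", (150,)),
        g("ndhE", "ssc", "-", (120,)),
        g("ndhG", "ssc", "-", (120,)),
        g("ndhH", "ssc", "+", (150,)),
        g("ndhA", "ssc", "+", (90, 90), (60,)),
        g("ndhI", "ssc", "+", (120,)),
    )


def _default_editing() -> tuple[EditingPlanting, ...]:
    return (
        EditingPlanting("rps14", 5, "TCA", 1, (96.0, 100.0, 100.0)),
        EditingPlanting("petB", 10, "CCA", 1, (100.0, 100.0, 97.0)),
        EditingPlanting("rbcL", 20, "GCC", 2, (100.0, 100.0, 40.0)),
        EditingPlanting("psbB", 8, "TAC", 2, (100.0, 0.0, 100.0)),
        EditingPlanting("ndhD", 7, "CTA", 0, (100.0, 18.0, 100.0)),
    )


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data set.

    Defaults mirror the real study's design at reduced scale: three
    haplotypes, an inverted petN/psbM block in the third, 500-bp diversity
    windows with three planted hotspots, MISA/REPuter-style planted repeat
    censuses, C-to-U edits in single-copy genes observed across three
    pileup replicates, and an expression design of 3/3/2 replicates.
    """

    lsc_len: int = 7500
    ssc_len: int = 1400
    ir_len: int = 1300
    genes: tuple[GeneModel, ...] = field(default_factory=_default_genes)
    gene_zone_start: int = 2520  # 0-based LSC offset where gene layout begins
    gene_gap: int = 20
    haplotype_names: tuple[str, ...] = ("purple", "white", "yellow")
    background_sub_rate: float = 0.002
    hotspot_sub_rate: float = 0.05
    hotspot_intervals: tuple[tuple[int, int], ...] = (
        (501, 1000),
        (2001, 2500),
        (5501, 6000),
    )  # 1-based genome coordinates, inside the LSC
    window: int = 500
    inversion: bool = True
    inversion_genes: tuple[str, str] = ("petN", "psbM")
    inversion_haplotype: int = 2  # index into haplotype_names
    ssr_plantings: tuple[tuple[str, int], ...] = (
        ("A", 8),
        ("AT", 5),
        ("AGC", 4),
        ("ACGT", 3),
        ("AACGT", 3),
    )
    ssr_zone: tuple[int, int] = (1001, 1500)  # 1-based, inside the LSC
    repeat_plantings: tuple[tuple[str, int], ...] = (
        ("forward", 40),
        ("palindromic", 40),
    )
    repeat_zone: tuple[int, int] = (1501, 2000)
    min_ssr_copies: dict[int, int] = field(
        default_factory=lambda: {1: 7, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    repeat_min_len: int = 30
    repeat_max_hamming: int = 3
    # editing / pileups
    editing: tuple[EditingPlanting, ...] = field(default_factory=_default_editing)
    n_replicates: int = 3
    base_coverage: int = 30
    error_rate: float = 0.0
    binomial_editing_counts: bool = False
    pileup_genes: tuple[str, ...] | None = None  # None -> all non-partial CDS
    # expression
    groups: tuple[str, ...] = ("purple", "white", "yellow")
    group_replicates: tuple[int, ...] = (3, 3, 2)
    dispersion: float = 0.05
    group_effect_sd: float = 0.4
    mean_range: tuple[float, float] = (100.0, 400.0)  # baseline per-gene means
    library_size_range: tuple[float, float] = (0.7, 1.4)
    high_expression: dict[str, float] = field(
        default_factory=lambda: {"psbA": 5000.0, "rbcL": 5000.0, "psaA": 1500.0, "psbB": 1500.0}
    )

    def validate(self) -> None:
        for a, b in self.hotspot_intervals:
            if not (1 <= a <= b <= self.lsc_len):
                raise PlastomeError("hotspot interval outside the LSC")
        for rate in (self.background_sub_rate, self.hotspot_sub_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise PlastomeError("rates must be in [0, 1]")
        zones = [self.ssr_zone, self.repeat_zone]
        span = sum(g.span + self.gene_gap for g in self.genes if g.region == "lsc")
        if self.gene_zone_start + span > self.lsc_len - 10:
            raise PlastomeError("LSC gene layout does not fit")
        for z in zones:
            if z[1] > self.gene_zone_start:
                raise PlastomeError("planting zone overlaps the gene zone")


@dataclass
class PlantedEditingSite:
    gene: str
    position: int  # 1-based plus-strand genome coordinate
    strand: str
    codon_from: str  # RNA
    codon_to: str
    levels: tuple[float, ...]
    coverage: int


@dataclass
class GroundTruth:
    region_lengths: dict[str, int] = field(default_factory=dict)
    ssrs: list[SSRRecord] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    inversion_block: tuple[int, int] | None = None
    inversion_haplotype: str | None = None
    hotspot_windows: list[int] = field(default_factory=list)  # 1-based window index
    inversion_windows: list[int] = field(default_factory=list)
    substitutions: dict[str, list[int]] = field(default_factory=dict)
    editing_sites: list[PlantedEditingSite] = field(default_factory=list)
    expression_group_means: pd.DataFrame | None = None
    library_multipliers: pd.Series | None = None


@dataclass
class SimulationResult:
    plastomes: list[AnnotatedPlastome]
    alignment: MultipleAlignment
    truth: GroundTruth


# ---------------------------------------------------------------------------
# sequence building blocks
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        c = "".join(_BASES[rng.integers(0, 4, size=3)])
        if c not in _STOPS:
            return c


def _random_cds(rng: np.random.Generator, length: int, *, start: bool, stop: bool) -> str:
    if length % 3:
        raise PlastomeError("CDS length must be divisible by 3")
    k = length // 3
    codons = [_random_codon(rng) for _ in range(k)]
    if start:
        codons[0] = "ATG"
    if stop:
        codons[-1] = "TAA"
    return "".join(codons)


def _pre_mrna(model: GeneModel, cds: str) -> tuple[str, list[tuple[int, int]]]:
    """Pre-mRNA with introns and 0-based exon spans in pre-mRNA coordinates.

    Intron sequences are filled later; here they are placeholders replaced
    by the caller (we return the exon spans so the caller knows the gaps)."""
    spans = []
    pos = 0
    cpos = 0
    pieces = []
    for i, el in enumerate(model.exon_lens):
        pieces.append(cds[cpos : cpos + el])
        spans.append((pos, pos + el - 1))
        cpos += el
        pos += el
        if i < len(model.intron_lens):
            pieces.append("\0" * model.intron_lens[i])  # placeholder
            pos += model.intron_lens[i]
    return "".join(pieces), spans


def _place_gene(
    rng: np.random.Generator,
    model: GeneModel,
    cds: str,
) -> tuple[str, list[tuple[int, int]]]:
    """Genomic (plus-strand) sequence of the gene span and 0-based ascending
    exon intervals local to the span."""
    pre, spans = _pre_mrna(model, cds)
    pre = "".join(
        c if c != "\0" else str(_BASES[rng.integers(0, 4)]) for c in pre
    )
    T = len(pre)
    if model.strand == "+":
        return pre, spans
    genomic = revcomp(pre)
    g_spans = sorted((T - 1 - b, T - 1 - a) for a, b in spans)
    return genomic, g_spans


def _ssr_free_segment(rng: np.random.Generator, n: int, min_copies: dict[int, int]) -> str:
    while True:
        seg = "".join(_random_seq(rng, n))
        if not find_ssrs(seg, min_copies):
            return seg


# ---------------------------------------------------------------------------
# the plastome set
# ---------------------------------------------------------------------------


class _Builder:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.truth = GroundTruth()
        self.protected: set[int] = set()  # 0-based plus-strand positions
        self.features: list[GeneFeature] = []

    def build_reference(self) -> AnnotatedPlastome:
        cfg, rng = self.cfg, self.rng
        lsc = _random_seq(rng, cfg.lsc_len)
        ira = _random_seq(rng, cfg.ir_len)
        ssc = _random_seq(rng, cfg.ssc_len)
        self._lay_out_genes(lsc, ira, ssc)
        self._plant_ssrs(lsc)
        self._plant_repeats(lsc)
        self._fix_junctions(lsc, ira, ssc)
        self.lsc, self.ira, self.ssc = lsc, ira, ssc
        genome = self._compose()
        genome = self._repair(genome)
        plastome = AnnotatedPlastome(
            id=f"synthetic_{cfg.haplotype_names[0]}",
            seq=genome,
            features=sorted(self.features, key=lambda f: (f.start, f.name, f.copy_index)),
        )
        self.truth.region_lengths = {
            "genome": len(genome),
            "lsc": cfg.lsc_len,
            "ssc": cfg.ssc_len,
            "ir": cfg.ir_len,
        }
        return plastome

    # --- gene layout ---

    def _lay_out_genes(self, lsc, ira, ssc) -> None:
        cfg, rng = self.cfg, self.rng
        offsets = {"lsc": 0, "ir": cfg.lsc_len, "ssc": cfg.lsc_len + cfg.ir_len}
        cursors = {"lsc": cfg.gene_zone_start, "ir": 30, "ssc": 30}
        arrays = {"lsc": lsc, "ir": ira, "ssc": ssc}
        # the trans-spliced gene's CDS is generated once and split across loci
        ts_models = [g for g in cfg.genes if g.trans_spliced]
        ts_cds: dict[int, str] = {}
        if ts_models:
            total = sum(sum(g.exon_lens) for g in ts_models)
            full = _random_cds(rng, total, start=True, stop=True)
            pos = 0
            for g in ts_models:
                L = sum(g.exon_lens)
                ts_cds[id(g)] = full[pos : pos + L]
                pos += L
        for model in cfg.genes:
            if model.category == PROTEIN_CODING and not model.partial:
                if model.trans_spliced:
                    cds = ts_cds[id(model)]
                else:
                    cds = _random_cds(rng, sum(model.exon_lens), start=True, stop=True)
            else:
                cds = "".join(_random_seq(rng, sum(model.exon_lens)))
            cds = self._apply_planted_codons(model, cds)
            genomic, local_spans = _place_gene(rng, model, cds)
            region = model.region
            start_local = cursors[region]
            if start_local + len(genomic) > len(arrays[region]) - 10:
                raise PlastomeError(f"gene layout overflows the {region} region")
            arrays[region][start_local : start_local + len(genomic)] = list(genomic)
            cursors[region] += len(genomic) + cfg.gene_gap
            base = offsets[region] + start_local  # 0-based genome offset
            parts = tuple((base + a + 1, base + b + 1) for a, b in local_spans)
            self.features.append(
                GeneFeature(
                    name=model.name,
                    category=model.category,
                    strand=model.strand,
                    parts=parts,
                    copy_index=1,
                    partial=model.partial,
                    trans_spliced=model.trans_spliced,
                )
            )
            # protect start/stop codons and planted codons from later edits
            if model.category == PROTEIN_CODING and not model.partial:
                flat = [p for s, e in sorted(parts) for p in range(s - 1, e)]
                if model.strand == "-":
                    flat = flat[::-1]
                self.protected.update(flat[:3])
                self.protected.update(flat[-3:])
                for planting in self._plantings_for(model):
                    t0 = planting.codon_index * 3
                    self.protected.update(flat[t0 : t0 + 3])
            if region == "ir":
                self._mirror_ir_feature(parts, model)

    def _plantings_for(self, model: GeneModel) -> list[EditingPlanting]:
        if model.trans_spliced:
            return []  # keep planted edits in single-locus genes
        return [p for p in self.cfg.editing if p.gene == model.name]

    def _apply_planted_codons(self, model: GeneModel, cds: str) -> str:
        for p in self._plantings_for(model):
            if not (0 < p.codon_index < len(cds) // 3 - 1):
                raise PlastomeError(
                    f"editing planting in {p.gene}: codon index {p.codon_index} out of range"
                )
            i = p.codon_index * 3
            cds = cds[:i] + p.codon + cds[i + 3 :]
        return cds

    def _mirror_ir_feature(self, parts, model: GeneModel) -> None:
        cfg = self.cfg
        n = cfg.lsc_len + 2 * cfg.ir_len + cfg.ssc_len
        irb_start = cfg.lsc_len + cfg.ir_len + cfg.ssc_len  # 0-based
        ira_start = cfg.lsc_len
        mirrored = []
        for s, e in parts:
            ls, le = s - 1 - ira_start, e - 1 - ira_start  # IRa-local 0-based
            ms, me = cfg.ir_len - 1 - le, cfg.ir_len - 1 - ls
            mirrored.append((irb_start + ms + 1, irb_start + me + 1))
        flip = {"+": "-", "-": "+"}
        self.features.append(
            GeneFeature(
                name=model.name,
                category=model.category,
                strand=flip[model.strand],
                parts=tuple(sorted(mirrored)),
                copy_index=2,
                partial=model.partial,
                trans_spliced=model.trans_spliced,
            )
        )

    # --- plantings ---

    def _plant_ssrs(self, lsc) -> None:
        cfg, rng = self.cfg, self.rng
        cursor = cfg.ssr_zone[0] - 1  # 0-based
        for motif, copies in cfg.ssr_plantings:
            run = motif * copies
            # breaking flanks so the planted run is maximal and exact
            left = [b for b in "ACGT" if b != motif[-1]]
            right = [b for b in "ACGT" if b != motif[0]]
            lsc[cursor] = str(rng.choice(left))
            lsc[cursor + 1 : cursor + 1 + len(run)] = list(run)
            lsc[cursor + 1 + len(run)] = str(rng.choice(right))
            start = cursor + 2  # 1-based start of the run
            self.truth.ssrs.append(
                SSRRecord(
                    motif=motif,
                    unit_len=len(motif),
                    copies=copies,
                    start=start,
                    end=start + len(run) - 1,
                )
            )
            self.protected.update(range(cursor, cursor + len(run) + 2))
            cursor += len(run) + 2 + 10
            if cursor >= cfg.ssr_zone[1]:
                raise PlastomeError("SSR plantings do not fit their zone")

    def _plant_repeats(self, lsc) -> None:
        cfg, rng = self.cfg, self.rng
        zone_start = cfg.repeat_zone[0] - 1
        cursor = zone_start
        for kind, arm_len in cfg.repeat_plantings:
            arm = _ssr_free_segment(rng, arm_len, cfg.min_ssr_copies)
            if kind == "forward":
                copy = arm
            elif kind == "palindromic":
                copy = revcomp(arm)
            elif kind == "reverse":
                copy = arm[::-1]
            elif kind == "complement":
                from .genome import complement

                copy = complement(arm)
            else:
                raise PlastomeError(f"unknown planted repeat kind {kind}")
            a1 = cursor
            lsc[a1 : a1 + arm_len] = list(arm)
            a2 = cursor + arm_len + 20
            lsc[a2 : a2 + arm_len] = list(copy)
            self.truth.repeats.append(
                {
                    "kind": kind,
                    "arm1": (a1 + 1, a1 + arm_len),
                    "arm2": (a2 + 1, a2 + arm_len),
                    "length": arm_len,
                }
            )
            self.protected.update(range(a1, a1 + arm_len))
            self.protected.update(range(a2, a2 + arm_len))
            cursor = a2 + arm_len + 20
            if cursor >= cfg.repeat_zone[1]:
                raise PlastomeError("repeat plantings do not fit their zone")

    def _fix_junctions(self, lsc, ira, ssc) -> None:
        """Prevent accidental single-base extension of the IR pair across the
        region junctions, and protect the junction bases from substitutions."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = self.rng
        if lsc[-1] == comp[lsc[0]]:
            lsc[-1] = str(rng.choice([b for b in "ACGT" if b != comp[lsc[0]]]))
        if ssc[0] == comp[ssc[-1]]:
            ssc[0] = str(rng.choice([b for b in "ACGT" if b != comp[ssc[-1]]]))
        cfg = self.cfg
        for pos in (
            0,
            cfg.lsc_len - 1,
            cfg.lsc_len + cfg.ir_len,
            cfg.lsc_len + cfg.ir_len + cfg.ssc_len - 1,
        ):
            self.protected.add(pos)

    # --- composition and repair ---

    def _compose(self) -> str:
        return "".join(self.lsc) + "".join(self.ira) + "".join(self.ssc) + revcomp(
            "".join(self.ira)
        )

    def _pos_to_region(self, pos0: int) -> tuple[list[str], int, bool]:
        """Map a 0-based genome position to (region array, local index,
        needs_complement); IRb positions map onto IRa mirrored."""
        cfg = self.cfg
        if pos0 < cfg.lsc_len:
            return self.lsc, pos0, False
        if pos0 < cfg.lsc_len + cfg.ir_len:
            return self.ira, pos0 - cfg.lsc_len, False
        if pos0 < cfg.lsc_len + cfg.ir_len + cfg.ssc_len:
            return self.ssc, pos0 - cfg.lsc_len - cfg.ir_len, False
        local = pos0 - cfg.lsc_len - cfg.ir_len - cfg.ssc_len
        return self.ira, cfg.ir_len - 1 - local, True

    def _mutate(self, pos0: int, avoid: set[str]) -> None:
        arr, idx, needs_comp = self._pos_to_region(pos0)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if needs_comp:
            avoid = {comp[b] for b in avoid}
        choices = [b for b in "ACGT" if b not in avoid and b != arr[idx]]
        arr[idx] = str(self.rng.choice(choices))

    def _repair(self, genome: str) -> str:
        cfg = self.cfg
        planted_ssrs = {(r.start, r.end, r.motif) for r in self.truth.ssrs}
        for _ in range(60):
            dirty = False
            for rec in find_ssrs(genome, cfg.min_ssr_copies):
                if (rec.start, rec.end, rec.motif) in planted_ssrs:
                    continue
                span = [p for p in range(rec.start - 1, rec.end) if p not in self.protected]
                if not span:
                    raise PlastomeError("cannot repair SSR overlapping protected bases")
                mid = span[len(span) // 2]
                avoid = {genome[mid - 1]} if mid > 0 else set()
                if mid + 1 < len(genome):
                    avoid.add(genome[mid + 1])
                self._mutate(mid, avoid=avoid)
                dirty = True
            if not dirty:
                break
            genome = self._compose()
        else:
            raise PlastomeError("SSR repair did not converge")
        # long repeats on the IR-reduced sequence
        reduced_len = cfg.lsc_len + cfg.ir_len + cfg.ssc_len
        for _ in range(20):
            reduced = genome[:reduced_len]
            dirty = False
            for rec in find_long_repeats(
                reduced, cfg.repeat_min_len, cfg.repeat_max_hamming
            ):
                if self._accounted(rec):
                    continue
                arm = range(rec.arm2[0] - 1, rec.arm2[1])
                free = [p for p in arm if p not in self.protected]
                if not free:
                    free = [p for p in range(rec.arm1[0] - 1, rec.arm1[1]) if p not in self.protected]
                if not free:
                    raise PlastomeError("cannot repair accidental long repeat")
                step = max(len(free) // (cfg.repeat_max_hamming + 2), 1)
                for p in free[::step][: cfg.repeat_max_hamming + 2]:
                    self._mutate(p, avoid=set())
                dirty = True
            if not dirty:
                break
            genome = self._compose()
        else:
            raise PlastomeError("long-repeat repair did not converge")
        return genome

    def _accounted(self, rec) -> bool:
        """A found long repeat is accounted for when its arms contain a
        planted pair of the same kind (maximal extension widens the arms)."""
        for t in self.truth.repeats:
            if t["kind"] != rec.kind:
                continue
            (p1s, p1e), (p2s, p2e) = t["arm1"], t["arm2"]
            if (
                rec.arm1[0] <= p1s
                and p1e <= rec.arm1[1]
                and rec.arm2[0] <= p2s
                and p2e <= rec.arm2[1]
            ):
                return True
        return False


def _window_indices(interval: tuple[int, int], window: int) -> list[int]:
    first = (interval[0] - 1) // window + 1
    last = (interval[1] - 1) // window + 1
    return list(range(first, last + 1))


def simulate_plastome_set(
    cfg: SimulationConfig | None = None, seed: int = 0
) -> SimulationResult:
    """Generate the haplotype set, gap-free alignment, and ground truth.

    Haplotype 1 is the reference; the others carry i.i.d. substitutions at
    the background rate (elevated inside hotspot intervals), mirrored into
    IRb so the IRs stay exact reverse complements, and — when configured —
    the two-gene inverted block in the designated haplotype.  Identical
    seeds produce identical output bytes.
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    builder = _Builder(cfg, rng)
    reference = builder.build_reference()
    n = len(reference.seq)
    plastomes = [reference]
    truth = builder.truth
    truth.hotspot_windows = sorted(
        {w for iv in cfg.hotspot_intervals for w in _window_indices(iv, cfg.window)}
    )
    # substitution candidates: single-copy regions plus IRa (mirrored)
    sc_end = cfg.lsc_len + cfg.ir_len + cfg.ssc_len
    rates = np.full(sc_end, cfg.background_sub_rate)
    for a, b in cfg.hotspot_intervals:
        rates[a - 1 : b] = cfg.hotspot_sub_rate
    protected = builder.protected
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    planted_ssr_keys = {(r.start, r.end, r.motif) for r in truth.ssrs}

    def mirror_of(p: int) -> int | None:
        if cfg.lsc_len <= p < cfg.lsc_len + cfg.ir_len:
            return sc_end + (cfg.ir_len - 1 - (p - cfg.lsc_len))
        return None

    for h in range(1, len(cfg.haplotype_names)):
        draws = rng.random(sc_end) < rates
        positions = [int(p) for p in np.flatnonzero(draws) if p not in protected]
        seq = list(reference.seq)
        for p in positions:
            seq[p] = str(rng.choice([b for b in "ACGT" if b != seq[p]]))
            m = mirror_of(p)
            if m is not None:
                seq[m] = comp[seq[p]]
        # a substitution can complete an accidental SSR run; revert offenders
        # so planted censuses stay exact truth in every haplotype
        for _ in range(100):
            unwanted = [
                rec
                for rec in find_ssrs("".join(seq), cfg.min_ssr_copies)
                if (rec.start, rec.end, rec.motif) not in planted_ssr_keys
            ]
            if not unwanted:
                break
            # repair one record per scan: a single revert can fix several
            # records at once (e.g. the mirrored IRa/IRb pair)
            rec = unwanted[0]
            span = range(rec.start - 1, rec.end)
            hit = next((p for p in positions if p in span), None)
            if hit is None:  # run sits in IRb: find the mirrored source
                hit = next((p for p in positions if mirror_of(p) in span), None)
            if hit is None:
                raise PlastomeError("cannot attribute accidental SSR to a substitution")
            seq[hit] = reference.seq[hit]
            m = mirror_of(hit)
            if m is not None:
                seq[m] = reference.seq[m]
            positions.remove(hit)
        else:
            raise PlastomeError("haplotype SSR repair did not converge")
        features = list(reference.features)
        name = cfg.haplotype_names[h]
        truth.substitutions[name] = [int(p) + 1 for p in positions]
        if cfg.inversion and h == cfg.inversion_haplotype:
            seq, features, block = _apply_inversion(seq, features, cfg.inversion_genes)
            truth.inversion_block = block
            truth.inversion_haplotype = name
            truth.inversion_windows = _window_indices(block, cfg.window)
        plastomes.append(
            AnnotatedPlastome(
                id=f"synthetic_{name}",
                seq="".join(seq),
                features=sorted(features, key=lambda f: (f.start, f.name, f.copy_index)),
            )
        )
    alignment = MultipleAlignment(
        names=[p.id for p in plastomes], rows=[p.seq for p in plastomes]
    )
    return SimulationResult(plastomes=plastomes, alignment=alignment, truth=truth)


def _apply_inversion(seq: list[str], features: list[GeneFeature], genes: tuple[str, str]):
    involved = [f for f in features if f.name in genes]
    if len(involved) != len(genes):
        raise PlastomeError(f"inversion genes {genes} not found exactly once each")
    b1 = min(f.start for f in involved)
    b2 = max(f.end for f in involved)
    block = revcomp("".join(seq[b1 - 1 : b2]))
    seq = seq[: b1 - 1] + list(block) + seq[b2:]
    flip = {"+": "-", "-": "+"}
    out = []
    for f in features:
        if f not in involved:
            out.append(f)
            continue
        parts = tuple(
            sorted((b1 + b2 - e, b1 + b2 - s) for s, e in f.parts)
        )
        out.append(dataclasses.replace(f, parts=parts, strand=flip[f.strand]))
    return seq, out, (b1, b2)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------


def simulate_pileups(
    cfg: SimulationConfig | None = None,
    plastome: AnnotatedPlastome | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[PlantedEditingSite]]:
    """Per-replicate pileup table over all (selected) CDS positions, with the
    configured C-to-U edits planted.

    Planted sites carry the configured per-replicate coverage exactly; the
    planted edited-read count is the deterministic rounding of
    coverage x level / 100 by default (a binomial draw when
    ``cfg.binomial_editing_counts``), so planted levels are exact ground
    truth.  Elsewhere coverage is Poisson around ``base_coverage`` and, when
    ``error_rate`` > 0, each read miscalls to a uniform wrong base.
    """
    cfg = cfg or SimulationConfig()
    if plastome is None:
        plastome = simulate_plastome_set(cfg, seed=seed).plastomes[0]
    rng = np.random.default_rng(seed + 1_000_003)
    planted: dict[int, tuple[EditingPlanting, GeneFeature]] = {}
    truth_sites: list[PlantedEditingSite] = []
    cds_features = [
        f
        for f in sorted(plastome.features, key=lambda f: (f.start, f.copy_index))
        if f.category == PROTEIN_CODING and not f.partial
    ]
    for p in cfg.editing:
        feature = next(
            (f for f in cds_features if f.name == p.gene and f.copy_index == 1), None
        )
        if feature is None:
            raise PlastomeError(f"editing planting: no CDS named {p.gene}")
        if len(p.levels) != cfg.n_replicates:
            raise PlastomeError(
                f"editing planting in {p.gene}: {len(p.levels)} levels for "
                f"{cfg.n_replicates} replicates"
            )
        cds, pos_map = spliced_cds(plastome, feature)
        t = p.codon_index * 3 + p.edit_offset
        if cds[t] != "C":
            raise PlastomeError(f"planting at non-C reference in {p.gene}")
        position = pos_map[t]
        planted[position] = (p, feature)
        codon_from = cds[p.codon_index * 3 : p.codon_index * 3 + 3]
        codon_to = codon_from[: p.edit_offset] + "T" + codon_from[p.edit_offset + 1 :]
        truth_sites.append(
            PlantedEditingSite(
                gene=p.gene,
                position=position,
                strand=feature.strand,
                codon_from=codon_from.replace("T", "U"),
                codon_to=codon_to.replace("T", "U"),
                levels=p.levels,
                coverage=p.coverage,
            )
        )
    wanted = cfg.pileup_genes
    rows: list[tuple] = []
    for feature in cds_features:
        if wanted is not None and feature.name not in wanted:
            continue
        for s, e in sorted(feature.parts):
            for position in range(s, e + 1):
                ref = plastome.seq[position - 1]
                edited_base = "T" if feature.strand == "+" else "A"
                for r in range(cfg.n_replicates):
                    rep = f"rep{r + 1}"
                    if position in planted:
                        p, _ = planted[position]
                        cov = p.coverage
                        level = p.levels[r]
                        if cfg.binomial_editing_counts:
                            edited = int(rng.binomial(cov, level / 100.0))
                        else:
                            edited = int(round(cov * level / 100.0))
                        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
                        counts[edited_base] = edited
                        counts[ref] += cov - edited
                    else:
                        cov = int(rng.poisson(cfg.base_coverage))
                        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
                        if cfg.error_rate > 0 and cov > 0:
                            errs = int(rng.binomial(cov, cfg.error_rate))
                        else:
                            errs = 0
                        counts[ref] = cov - errs
                        if errs:
                            others = [b for b in "ACGT" if b != ref]
                            split = rng.multinomial(errs, [1 / 3] * 3)
                            for b, c in zip(others, split):
                                counts[b] += int(c)
                    rows.append(
                        (rep, position, counts["A"], counts["C"], counts["G"], counts["T"])
                    )
    pileups = pd.DataFrame(rows, columns=list(PILEUP_COLUMNS))
    pileups = pileups.drop_duplicates(subset=["replicate", "position"], keep="first")
    return pileups, truth_sites


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def expression_rows(plastome: AnnotatedPlastome) -> list[tuple[str, GeneFeature]]:
    """Row name per feature copy: duplicated genes get _1/_2 suffixes; the
    trans-spliced gene's parts become name, name_2, name_3."""
    by_symbol: dict[str, list[GeneFeature]] = {}
    for f in sorted(plastome.features, key=lambda f: (f.start, f.copy_index)):
        by_symbol.setdefault(f.name, []).append(f)
    rows = []
    for sym, fs in by_symbol.items():
        if len(fs) == 1:
            rows.append((sym, fs[0]))
        elif fs[0].trans_spliced:
            for i, f in enumerate(fs):
                rows.append((sym if i == 0 else f"{sym}_{i + 1}", f))
        else:
            for i, f in enumerate(fs):
                rows.append((f"{sym}_{i + 1}", f))
    rows.sort(key=lambda t: t[1].start)
    return rows


def simulate_counts(
    cfg: SimulationConfig | None = None,
    plastome: AnnotatedPlastome | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str], GroundTruth]:
    """Negative-binomial (Poisson at dispersion 0) count matrix with the
    configured group/replicate design and per-sample library multipliers."""
    cfg = cfg or SimulationConfig()
    if plastome is None:
        plastome = simulate_plastome_set(cfg, seed=seed).plastomes[0]
    rng = np.random.default_rng(seed + 7_000_003)
    rows = expression_rows(plastome)
    base_means = {}
    for name, feature in rows:
        if feature.name in cfg.high_expression:
            mu = cfg.high_expression[feature.name]
        elif feature.category == PROTEIN_CODING and not feature.partial:
            mu = float(rng.uniform(*cfg.mean_range))
        elif feature.category in (TRNA, RRNA):
            mu = float(rng.uniform(30, 80))
        else:
            mu = 5.0
        base_means[name] = mu
    group_means = {}
    for gi, group in enumerate(cfg.groups):
        if gi == 0 or cfg.group_effect_sd == 0:
            factors = np.ones(len(rows))
        else:
            factors = np.exp(rng.normal(0.0, cfg.group_effect_sd, size=len(rows)))
        group_means[group] = {
            name: base_means[name] * f for (name, _), f in zip(rows, factors)
        }
    samples = []
    groups_map = {}
    for group, nrep in zip(cfg.groups, cfg.group_replicates):
        for r in range(nrep):
            sample = f"{group}_{r + 1}"
            samples.append(sample)
            groups_map[sample] = group
    lo, hi = cfg.library_size_range
    multipliers = pd.Series(
        rng.uniform(lo, hi, size=len(samples)), index=samples, name="multiplier"
    )
    data = np.zeros((len(rows), len(samples)), dtype=int)
    for j, sample in enumerate(samples):
        group = groups_map[sample]
        for i, (name, _) in enumerate(rows):
            mu = group_means[group][name] * multipliers[sample]
            if cfg.dispersion > 0:
                nb_n = 1.0 / cfg.dispersion
                nb_p = nb_n / (nb_n + mu)
                data[i, j] = rng.negative_binomial(nb_n, nb_p)
            else:
                data[i, j] = rng.poisson(mu)
    counts = pd.DataFrame(data, index=[name for name, _ in rows], columns=samples)
    truth = GroundTruth(
        expression_group_means=pd.DataFrame(group_means),
        library_multipliers=multipliers,
    )
    return counts, groups_map, truth
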