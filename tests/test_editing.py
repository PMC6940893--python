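"""C-to-U editing caller, codon-effect annotation and classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from plastome.editing import (
    EditingFilterConfig,
    annotate_codon_change,
    call_editing_sites,
    classify_physicochemical,
    codon_effect,
    pileups_from_sam,
    transition_spectrum,
)
from plastome.genome import AnnotatedPlastome, GeneFeature, PlastomeError, revcomp
from plastome.simulate import SimulationConfig, simulate_pileups, simulate_plastome_set

from conftest import random_dna


# ---------------------------------------------------------------------------
# codon effects and physicochemical classes
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cf,ct,pos,aa_from,aa_to,effect",
    [
        ("CCA", "CUA", 2, "P", "L", "nonsynonymous"),
        ("GCC", "GCU", 3, "A", "A", "synonymous"),
        ("CAA", "UAA", 1, "Q", "*", "stop_gained"),
        ("UCA", "UUA", 2, "S", "L", "nonsynonymous"),
        ("CUA", "UUA", 1, "L", "L", "synonymous"),
        ("ACG", "AUG", 2, "T", "M", "nonsynonymous"),
    ],
)
def test_codon_effect(cf, ct, pos, aa_from, aa_to, effect):
    assert codon_effect(cf, ct) == (pos, aa_from, aa_to, effect)


@pytest.mark.parametrize("cf,ct", [("CCA", "CCA"), ("CCA", "GCA"), ("UUA", "UCA"), ("CCA", "CUU")])
def test_codon_effect_rejects_non_ctou(cf, ct):
    with pytest.raises(PlastomeError):
        codon_effect(cf, ct)


@pytest.mark.parametrize(
    "aa_from,aa_to,changed,category",
    [
        ("S", "L", True, "hydrophilic_to_hydrophobic"),
        ("S", "F", True, "hydrophilic_to_hydrophobic"),
        ("R", "C", True, "hydrophilic_to_hydrophobic"),
        ("A", "V", False, "listed_no_change"),
        ("R", "W", False, "listed_no_change"),  # enumerated as no-change
        ("T", "M", False, "listed_no_change"),
        ("P", "P", False, "identity"),
        ("Q", "*", False, "stop_transition"),
        ("G", "D", False, "unlisted"),
    ],
)
def test_classify_physicochemical(aa_from, aa_to, changed, category):
    assert classify_physicochemical(aa_from, aa_to) == (changed, category)


def test_classify_physicochemical_rejects_unknown_residue():
    with pytest.raises(PlastomeError):
        classify_physicochemical("B", "L")


# ---------------------------------------------------------------------------
# caller on hand-built pileups
# ---------------------------------------------------------------------------


def _mini_plastome():
    """60 bp genome: a plus-strand gene (4-33) and a minus-strand gene (37-54).

    Plus gene CDS: ATG CCA TTT GGG CAT CAA TGT AAA CCC TAA (30 nt);
    minus gene CDS: ATG TCA GGG CCC TAA (15 nt, genome carries revcomp).
    """
    plus_cds = "ATGCCATTTGGGCATCAATGTAAACCCTAA"
    minus_cds = "ATGTCAGGGCCCTAA"
    seq = "TTT" + plus_cds + "AGT" + revcomp(minus_cds) + "TTTGGG"
    feats = [
        GeneFeature("plusG", "protein_coding", "+", ((4, 33),)),
        GeneFeature("minusG", "protein_coding", "-", ((37, 51),)),
    ]
    return AnnotatedPlastome(id="mini", seq=seq, features=feats)


def _pileup(rows):
    return pd.DataFrame(rows, columns=["replicate", "position", "A", "C", "G", "T"])


def test_called_site_with_zero_level_replicate_retained():
    p = _mini_plastome()
    # position 8 = second C of the CCA codon (codon 2, position 2)
    rows = [
        ("r1", 8, 0, 1, 0, 24),  # level 96, cov 25
        ("r2", 8, 0, 0, 0, 30),  # level 100, cov 30
        ("r3", 8, 0, 20, 0, 0),  # level 0, cov 20
    ]
    sites = call_editing_sites(_pileup(rows), p)
    assert len(sites) == 1
    s = sites[0]
    assert s.gene == "plusG" and s.codon_from == "CCA" and s.codon_to == "CUA"
    assert s.codon_position == 2 and (s.aa_from, s.aa_to) == ("P", "L")
    assert s.levels == {"r1": 96.0, "r2": 100.0, "r3": 0.0}


def test_low_coverage_positive_replicate_fails_filter():
    p = _mini_plastome()
    rows = [
        ("r1", 8, 0, 1, 0, 8),  # coverage 9 < 10: does not count
        ("r2", 8, 0, 0, 0, 30),
        ("r3", 8, 0, 20, 0, 0),
    ]
    assert call_editing_sites(_pileup(rows), p) == []


def test_single_positive_replicate_fails_filter():
    p = _mini_plastome()
    rows = [
        ("r1", 8, 0, 0, 0, 30),
        ("r2", 8, 0, 25, 0, 0),
        ("r3", 8, 0, 20, 0, 0),
    ]
    assert call_editing_sites(_pileup(rows), p) == []


def test_minus_strand_gene_called_from_g_and_a_counts():
    p = _mini_plastome()
    # minus gene codon TCA: the C sits at genome position 48 as a G on plus
    pos = 47
    assert p.seq[pos - 1] == "G"
    rows = [
        ("r1", pos, 28, 0, 2, 0),  # A reads = edited, level 28/30
        ("r2", pos, 30, 0, 0, 0),
    ]
    sites = call_editing_sites(_pileup(rows), p)
    assert len(sites) == 1
    s = sites[0]
    assert s.gene == "minusG" and s.strand == "-"
    assert s.codon_from == "UCA" and s.codon_to == "UUA"
    assert (s.aa_from, s.aa_to) == ("S", "L") and s.physicochemical_change


def test_positions_outside_cds_or_non_c_are_skipped():
    p = _mini_plastome()
    rows = [
        ("r1", 1, 0, 0, 0, 30),  # intergenic
        ("r2", 1, 0, 0, 0, 30),
        ("r1", 7, 0, 0, 0, 30),  # inside CDS but ref is C on + at 7? -> C
        ("r2", 7, 0, 0, 0, 30),
        ("r1", 6, 30, 0, 0, 0),  # ref G (position 6): not C on + strand
        ("r2", 6, 30, 0, 0, 0),
    ]
    sites = call_editing_sites(_pileup(rows), p)
    assert [s.position for s in sites] == [7]


def test_level_denominator_excludes_error_reads():
    p = _mini_plastome()
    rows = [
        ("r1", 8, 5, 10, 5, 10),  # edited 10, ref 10 -> level 50 (A/G ignored)
        ("r2", 8, 0, 15, 0, 15),
    ]
    sites = call_editing_sites(_pileup(rows), p)
    assert sites[0].levels == {"r1": 50.0, "r2": 50.0}


def test_fewer_replicates_than_required_rejected():
    p = _mini_plastome()
    with pytest.raises(PlastomeError):
        call_editing_sites(_pileup([("r1", 8, 0, 0, 0, 30)]), p)


def test_editing_level_monotone_in_edited_reads():
    p = _mini_plastome()
    levels = []
    for t in range(0, 30, 5):
        rows = [("r1", 8, 0, 30 - t, 0, t), ("r2", 8, 0, 0, 0, 30)]
        sites = call_editing_sites(_pileup(rows), p)
        levels.append(sites[0].levels["r1"] if sites else 0.0)
    assert levels == sorted(levels)


def test_transition_spectrum_counts():
    p = _mini_plastome()
    rows = [
        ("r1", 8, 0, 0, 0, 30), ("r2", 8, 0, 0, 0, 30),      # P->L
        ("r1", 47, 30, 0, 0, 0), ("r2", 47, 30, 0, 0, 0),    # S->L (minus gene)
        ("r1", 30, 0, 0, 0, 30), ("r2", 30, 0, 0, 0, 30),    # CCC->CCU synonymous
    ]
    sites = call_editing_sites(_pileup(rows), p)
    spec = transition_spectrum(sites)
    assert spec["totals"]["nonsynonymous"] == 2
    assert spec["totals"]["synonymous"] == 1
    assert spec["transitions"] == {("P", "L"): 1, ("S", "L"): 1}
    assert transition_spectrum([]) == {
        "transitions": {},
        "totals": {"synonymous": 0, "nonsynonymous": 0, "stop_gained": 0, "unresolved": 0},
    }


# ---------------------------------------------------------------------------
# annotation on simulated genomes (introns, trans-splicing, strands)
# ---------------------------------------------------------------------------


def test_annotation_across_intron(reference):
    petB = next(f for f in reference.features if f.name == "petB")
    cds = petB.spliced_seq(reference.seq)
    # find a C in the second exon (transcript index >= first exon length)
    first_exon = petB.parts[0][1] - petB.parts[0][0] + 1
    idx = cds.index("C", first_exon + 3)
    from plastome.editing import spliced_cds

    _, pos_map = spliced_cds(reference, petB)
    site = annotate_codon_change(pos_map[idx], reference, petB)
    assert site.gene == "petB"
    assert site.codon_from[idx % 3] == "C" and site.codon_to[idx % 3] == "U"


def test_trans_spliced_gene_annotated_via_assembled_parts(reference):
    from plastome.editing import spliced_cds

    loci = [f for f in reference.features if f.name == "rps12" and f.copy_index == 1]
    locus5 = min(loci, key=lambda f: f.start)
    assembled = spliced_cds(reference, locus5)
    assert assembled is not None
    cds, pos_map = assembled
    assert len(cds) % 3 == 0 and cds.startswith("ATG") and cds.endswith("TAA")
    idx = cds.index("C", 3)
    site = annotate_codon_change(pos_map[idx], reference, locus5)
    assert site.gene == "rps12" and site.effect in ("synonymous", "nonsynonymous", "stop_gained")


def test_strand_consistency_under_reverse_complement():
    """Calling on the reverse-complemented genome with flipped annotations
    yields the same sites at mirrored positions."""
    p = _mini_plastome()
    n = len(p.seq)
    flip = {"+": "-", "-": "+"}
    rc_feats = [
        dataclasses.replace(
            f,
            strand=flip[f.strand],
            parts=tuple(sorted((n - e + 1, n - s + 1) for s, e in f.parts)),
        )
        for f in p.features
    ]
    rc = AnnotatedPlastome(id="rc", seq=revcomp(p.seq), features=rc_feats)
    rows = [("r1", 8, 0, 1, 0, 24), ("r2", 8, 0, 0, 0, 30)]
    rc_rows = [(rep, n - pos + 1, t, g, c, a) for rep, pos, a, c, g, t in rows]
    sites = call_editing_sites(_pileup(rows), p)
    rc_sites = call_editing_sites(_pileup(rc_rows), rc)
    assert len(sites) == len(rc_sites) == 1
    s, rs = sites[0], rc_sites[0]
    assert rs.position == n - s.position + 1
    assert (rs.codon_from, rs.codon_to, rs.aa_from, rs.aa_to) == (
        s.codon_from,
        s.codon_to,
        s.aa_from,
        s.aa_to,
    )


# ---------------------------------------------------------------------------
# planted-site recovery and recount oracle on simulated pileups
# ---------------------------------------------------------------------------


def level_recount_oracle(pileups, plastome):
    """Recompute per-position, per-replicate levels with plain loops."""
    levels = {}
    for _, row in pileups.iterrows():
        pos = int(row["position"])
        from plastome.editing import find_cds

        f = find_cds(plastome, pos)
        if f is None:
            continue
        ref, edited = ("C", "T") if f.strand == "+" else ("G", "A")
        denom = row[ref] + row[edited]
        lv = 100.0 * row[edited] / denom if denom else 0.0
        if plastome.seq[pos - 1] == ref:
            levels[(str(row["replicate"]), pos)] = lv
    return levels


def test_planted_sites_recovered_and_levels_match_oracle(sim_default):
    ref = sim_default.plastomes[0]
    pileups, planted = simulate_pileups(SimulationConfig(), ref, seed=11)
    sites = call_editing_sites(pileups, ref)
    assert {s.position for s in sites} == {t.position for t in planted}
    oracle = level_recount_oracle(pileups, ref)
    for s in sites:
        for rep, lv in s.levels.items():
            assert abs(lv - oracle[(rep, s.position)]) < 1e-9
    by_pos = {t.position: t for t in planted}
    for s in sites:
        t = by_pos[s.position]
        assert (s.codon_from, s.codon_to) == (t.codon_from, t.codon_to)
        for lv, want in zip((s.levels[f"rep{i+1}"] for i in range(3)), t.levels):
            assert abs(lv - want) <= 100.0 / (2 * t.coverage) + 1e-9


def test_planting_in_single_replicate_is_rejected():
    cfg = dataclasses.replace(
        SimulationConfig(),
        editing=(
            dataclasses.replace(SimulationConfig().editing[0], levels=(50.0, 0.0, 0.0)),
        ),
    )
    sim = simulate_plastome_set(cfg, seed=3)
    pileups, planted = simulate_pileups(cfg, sim.plastomes[0], seed=3)
    sites = call_editing_sites(pileups, sim.plastomes[0])
    assert sites == []


def test_pileups_from_sam_counts_unique_reads(tmp_path, reference):
    sam = tmp_path / "toy.sam"
    n = len(reference.seq)
    read1 = reference.seq[100:130]
    lines = [
        "@HD\tVN:1.6\tSO:unknown",
        f"@SQ\tSN:{reference.id}\tLN:{n}",
        f"u1\t0\t{reference.id}\t101\t60\t30M\t*\t0\t0\t{read1}\t{'I' * 30}\tNH:i:1",
        f"m1\t0\t{reference.id}\t201\t60\t30M\t*\t0\t0\t{reference.seq[200:230]}\t{'I' * 30}\tNH:i:3",
    ]
    sam.write_text("\n".join(lines) + "\n")
    df = pileups_from_sam(str(sam), replicate="r1")
    covered = set(df["position"])
    assert set(range(101, 131)) <= covered
    assert not covered & set(range(201, 231))  # multi-mapped read excluded
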