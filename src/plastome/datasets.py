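"""Published RNA-Seq-validated C-to-U editing sites for the three
Utricularia amethystina morphotypes (purple, white, yellow).

Each record carries the genome coordinate on that morphotype's plastome
(GenBank MN223721 / MN223722 / MN223720), the gene strand, the RNA codon
before and after editing, the printed codon position and amino-acid pair
("Synonym" marks synonymous sites), and per-biological-replicate editing
levels in percent.  The printed amino acids for the ndhB site (H -> Y) are
inconsistent with its own codons (CCA -> CUA encodes P -> L); consumers
should recompute effects from the codons and treat the printed letters as a
transcription error in the source table.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # morphotype, gene, position, strand, codon_from, codon_to, printed codon
    # position, printed aa_from, printed aa_to, physicochemical star, levels
    ("purple", "rps14", 36640, "-", "UCA", "UUA", 2, "S", "L", True, (96, 100, 100)),
    ("purple", "petB", 74797, "+", "CCA", "CUA", 2, "P", "L", False, (100, 100, 97)),
    ("white", "ndhB", 138239, "+", "CCA", "CUA", 2, "H", "Y", False, (92, 82, 0)),
    ("white", "ndhD", 113305, "-", "CUA", "UUA", 1, None, None, False, (100, 0, 100)),
    ("white", "rbcL", 55651, "+", "GCC", "GCU", 3, None, None, False, (100, 100, 0)),
    ("white", "rbcL", 55777, "+", "AUC", "AUU", 3, None, None, False, (100, 100, 0)),
    ("white", "rps14", 36572, "-", "UCA", "UUA", 2, "S", "L", True, (38, 14, 75)),
    ("white", "rps14", 36497, "-", "CCA", "CUA", 2, "P", "L", False, (100, 0, 72)),
    ("white", "rps14", 36553, "-", "AAC", "AAU", 3, None, None, False, (100, 100, 0)),
    ("white", "psbB", 72140, "+", "GGC", "GGU", 3, None, None, False, (100, 100, 0)),
    ("white", "psbB", 71372, "+", "UAC", "UAU", 3, None, None, False, (100, 0, 100)),
    ("white", "psaA", 39370, "-", "AUC", "AUU", 3, None, None, False, (100, 100, 100)),
    ("white", "petB", 74816, "+", "CCA", "CUA", 2, "P", "L", False, (100, 0, 97)),
    ("yellow", "rps14", 36439, "-", "CCA", "CUA", 2, "P", "L", False, (69, 71)),
    ("yellow", "ccsA", 111950, "+", "CUA", "UUA", 1, None, None, False, (18, 16)),
    ("yellow", "petB", 74948, "+", "CCA", "CUA", 2, "P", "L", False, (100, 100)),
]


def amethystina_editing_sites() -> pd.DataFrame:
    """The 16 RNA-Seq-validated editing sites as a DataFrame.

    ``printed_aa_from`` / ``printed_aa_to`` are None for synonymous rows
    (the source prints "Synonym" instead of an amino-acid pair).
    """
    return pd.DataFrame(
        _ROWS,
        columns=[
            "morphotype",
            "gene",
            "position",
            "strand",
            "codon_from",
            "codon_to",
            "printed_codon_position",
            "printed_aa_from",
            "printed_aa_to",
            "printed_physicochemical_star",
            "levels",
        ],
    )
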