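"""Generate the synthetic three-morphotype study set used by the analyses.

Writes three annotated quadripartite plastomes (FASTA + GFF3), their
gap-free alignment, per-replicate RNA-Seq pileups with planted C-to-U
edits, a 3/3/2-replicate count matrix, and the planted ground truth to
results/study_set/.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from plastome.genome import write_plastome
from plastome.simulate import (
    SimulationConfig,
    simulate_counts,
    simulate_pileups,
    simulate_plastome_set,
)

SEED = 17
OUT = Path(__file__).resolve().parent.parent / "results" / "study_set"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig()
    sim = simulate_plastome_set(cfg, seed=SEED)
    for p in sim.plastomes:
        write_plastome(p, OUT / f"{p.id}.fasta", OUT / f"{p.id}.gff3")
    with open(OUT / "alignment.fasta", "w") as fh:
        for name, row in zip(sim.alignment.names, sim.alignment.rows):
            fh.write(f">{name}\n{row}\n")
    pileups, planted = simulate_pileups(cfg, sim.plastomes[0], seed=SEED)
    pileups.to_csv(OUT / "pileups.tsv", sep="\t", index=False)
    counts, groups, _ = simulate_counts(cfg, sim.plastomes[0], seed=SEED)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    pd.DataFrame({"sample": list(groups), "group": list(groups.values())}).to_csv(
        OUT / "groups.tsv", sep="\t", index=False
    )
    truth = {
        "region_lengths": sim.truth.region_lengths,
        "ssrs": [dataclasses.asdict(r) for r in sim.truth.ssrs],
        "repeats": sim.truth.repeats,
        "inversion_block": sim.truth.inversion_block,
        "inversion_haplotype": sim.truth.inversion_haplotype,
        "hotspot_windows": sim.truth.hotspot_windows,
        "inversion_windows": sim.truth.inversion_windows,
        "editing_sites": [dataclasses.asdict(s) for s in planted],
    }
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"wrote study set (seed {SEED}) to {OUT}")
    print(f"  genomes: {[p.id for p in sim.plastomes]}")
    print(f"  genome length {len(sim.plastomes[0].seq):,} bp; "
          f"planted edits: {len(planted)}; counts: {counts.shape[0]} genes x {counts.shape[1]} samples")


if __name__ == "__main__":
    main()
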