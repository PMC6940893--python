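"""Chloroplast expression profiling.

RLE (median-of-ratios) normalization of the 3/3/2-replicate count matrix,
log2(norm + 1) transformation, and average-linkage clustering of sample
profiles on 1 - Pearson correlation (results/expression/).
"""

from pathlib import Path

import pandas as pd

from plastome.expression import expression_table

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "expression"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = pd.read_csv(ROOT / "study_set" / "counts.tsv", sep="\t", index_col=0)
    groups = dict(
        pd.read_csv(ROOT / "study_set" / "groups.tsv", sep="\t").values
    )
    result = expression_table(counts, groups)
    result["size_factors"].to_csv(OUT / "size_factors.tsv", sep="\t")
    result["normalized"].to_csv(OUT / "normalized_counts.tsv", sep="\t")
    result["heatmap"].to_csv(OUT / "log2_heatmap.tsv", sep="\t")
    (OUT / "dendrogram.nwk").write_text(result["newick"] + "\n")
    print("size factors:",
          {s: round(v, 3) for s, v in result["size_factors"].items()})
    leaves = result["leaf_order"]
    print("dendrogram leaf order:", leaves)
    blocks = [groups[s] for s in leaves]
    contiguous = [g for i, g in enumerate(blocks) if i == 0 or g != blocks[i - 1]]
    mono = len(contiguous) == len(set(blocks))
    print(f"replicates cluster by morphotype: {'yes' if mono else 'no'}")
    top = result["log2"].mean(axis=1).sort_values(ascending=False).head(4)
    print("highest expression (mean log2 norm+1):",
          {g: round(v, 2) for g, v in top.items()})


if __name__ == "__main__":
    main()
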