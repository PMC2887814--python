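#!/usr/bin/env python
"""Stage 4: expression-pattern structure of the selected genes.

* k-means (k = 4) over z-scored per-cell-type profiles, labelling each
  cluster pan / subgroup-only / other;
* the unsupervised sample correlation tree (1 - Pearson, average
  linkage) of the primary panel, exported as Newick;
* a relative tissue-percentage table built by pooling the reference
  cells into pseudo-tissue groups.

Writes results/patterns/.
"""

import warnings
from pathlib import Path

import pandas as pd

from ecrestrict.data_model import read_expression_tsv, read_sample_sheet
from ecrestrict.patterns import (correlation_cluster, kmeans_patterns,
                                 tissue_percentages)

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    matrix = read_expression_tsv(data / "primary_matrix.tsv")
    sheet = read_sample_sheet(data / "primary_samples.tsv")
    selected = pd.read_csv(ROOT / "restrict" / "restricted_genes.tsv",
                           sep="\t")
    genes = list(selected.loc[selected["selected"], "gene_id"])
    out = ROOT / "patterns"
    out.mkdir(parents=True, exist_ok=True)

    assignments = kmeans_patterns(matrix.subset_genes(genes), sheet,
                                  k=4, seed=SEED)
    assignments.to_csv(out / "pattern_assignments.tsv", sep="\t", index=False)
    counts = assignments["pattern_label"].value_counts()
    print("pattern split of selected genes:")
    for label, n in counts.items():
        print(f"  {label}: {n}")

    tree = correlation_cluster(matrix)
    (out / "sample_tree.nwk").write_text(tree.to_newick() + "\n")
    print(f"sample correlation tree written ({matrix.n_samples} leaves)")

    # pseudo-tissues: pool reference cells in groups of five
    ref_matrix = read_expression_tsv(data / "reference_matrix.tsv")
    frame = ref_matrix.to_frame().loc[genes]
    groups = {f"tissue_{i + 1}": frame.columns[i * 5:(i + 1) * 5]
              for i in range(frame.shape[1] // 5)}
    pseudo = pd.DataFrame({name: frame[cols].mean(axis=1)
                           for name, cols in groups.items()})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = tissue_percentages(pseudo)
    table.percent.to_csv(out / "tissue_percentages.tsv", sep="\t",
                         float_format="%.4g")
    dominant = table.percent.max(axis=1)
    print(f"tissue table: {len(table.percent)} genes x "
          f"{table.percent.shape[1]} pseudo-tissues; median dominant-tissue "
          f"share {dominant.median():.1f}%")


if __name__ == "__main__":
    main()
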