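#!/usr/bin/env python
"""Stage 5: the three enrichment analyses on the selected genes.

* Gene-set over-representation (Fisher + EASE + BH) against synthetic
  GMT sets, one of which is built to contain planted genes;
* the yes/no promoter-site gate on a synthetic hit-count table;
* miRNA seed-match enrichment on synthetic 3'UTRs in which one miRNA's
  seed sites were planted into the study UTRs.

Writes results/enrichment/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ecrestrict.data_model import GeneSet, GeneSetCollection, SequenceRecord
from ecrestrict.enrichment import (genes_with_sites, gmt_overrepresentation,
                                   mirna_enrichment, mirna_seed_match,
                                   seed_site, site_enrichment_gate)
from ecrestrict.synthetic_data import read_truth_tsv

SEED = 1
ROOT = Path(__file__).resolve().parent.parent / "results"


def random_utr(rng, length=300):
    return "".join(rng.choice(list("ACGT"), size=length))


def main() -> None:
    rng = np.random.default_rng(SEED)
    truth = read_truth_tsv(ROOT / "data" / "truth.tsv")
    selected = pd.read_csv(ROOT / "restrict" / "restricted_genes.tsv", sep="\t")
    study = list(selected.loc[selected["selected"], "gene_id"])
    background = list(truth.frame["gene_id"])
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)

    # --- gene sets: one planted (vascular-like), three random
    planted_members = tuple(study[: max(5, len(study) // 2)])
    sets = {"vasculature_like": GeneSet("vasculature_like",
                                        "contains planted genes",
                                        planted_members)}
    for i in range(3):
        members = tuple(rng.choice(background, size=40, replace=False))
        sets[f"random_{i}"] = GeneSet(f"random_{i}", "random control", members)
    table = gmt_overrepresentation(study, GeneSetCollection(sets), background)
    table.to_csv(out / "gene_set_enrichment.tsv", sep="\t", index=False,
                 float_format="%.4g")
    top = table.iloc[0]
    print(f"gene sets: top set {top['set_id']!r} overlap {top['overlap']}/"
          f"{top['set_size']}, p={top['p_value']:.3g}, "
          f"EASE p={top['ease_p']:.3g}, BH p={top['adjusted_p']:.3g}")

    # --- promoter-site gate on a synthetic hit table
    rows = []
    for name, yes_hits, no_hits in (("site_enriched", 28, 9),
                                    ("site_flat", 12, 11),
                                    ("site_weak", 15, 12)):
        result = site_enrichment_gate(yes_hits, 40, no_hits, 40, set_id=name)
        rows.append(vars(result))
    gate_table = pd.DataFrame(rows)
    gate_table.to_csv(out / "site_gate.tsv", sep="\t", index=False,
                      float_format="%.4g")
    n_pass = int(gate_table["passes_gate"].sum())
    print(f"promoter sites: {n_pass}/{len(gate_table)} families pass "
          "(p<0.01 and density ratio>1.2)")

    # --- miRNA seed matching: plant one miRNA's sites in study UTRs
    mirnas = [SequenceRecord(f"mir-{i}", random_utr(rng, 22))
              for i in range(1, 6)]
    planted_site = seed_site(mirnas[0])
    study_utrs, bg_utrs = [], []
    for g in background:
        seq = random_utr(rng)
        if g in study and rng.uniform() < 0.6:
            pos = int(rng.integers(0, len(seq) - 7))
            seq = seq[:pos] + planted_site + seq[pos + 7:]
        record = SequenceRecord(g, seq)
        bg_utrs.append(record)
        if g in study:
            study_utrs.append(record)
    study_matches = mirna_seed_match(study_utrs, mirnas)
    bg_matches = mirna_seed_match(bg_utrs, mirnas)
    mir_table = mirna_enrichment(genes_with_sites(study_matches),
                                 genes_with_sites(bg_matches),
                                 len(study_utrs), len(bg_utrs))
    mir_table.to_csv(out / "mirna_enrichment.tsv", sep="\t", index=False,
                     float_format="%.4g")
    top = mir_table.iloc[0]
    print(f"miRNA: top {top['mirna_id']} hits {top['study_hits']}/"
          f"{len(study_utrs)} study vs {top['background_hits']}/"
          f"{len(bg_utrs)} background, BH p={top['adjusted_p']:.3g}")


if __name__ == "__main__":
    main()
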