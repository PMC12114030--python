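#!/usr/bin/env python
"""Apply both knockout-discovery selection strategies to the cohort.

Strategy 1 keeps high-confidence pLoF variants (MAF < 2%) with at least
two complete knockouts in OMIM/Open-Targets genes; Strategy 2 keeps genes
with >= 10 distinct heterozygous carriers of rare (MAF <= 0.1%)
pathogenic-or-HC variants.  Writes the selections and candidate compound
heterozygotes under results/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from komet.selection import (
    candidate_compound_heterozygotes,
    carriers_from_dosage,
    read_gene_list,
    select_strategy1,
    select_strategy2,
)

BASE = Path(__file__).resolve().parents[1] / "results"


def main():
    d = BASE / "cohort"
    ann = pd.read_csv(d / "annotations.tsv", sep="\t")
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col="variant_id")
    carriers = carriers_from_dosage(geno)
    omim = read_gene_list(d / "omim_genes.txt")
    otg = read_gene_list(d / "open_targets_genes.txt")

    sel1 = select_strategy1(ann, carriers, omim, otg)
    sel2 = select_strategy2(ann, carriers, omim | otg)
    comp = candidate_compound_heterozygotes(ann, carriers)

    pd.DataFrame({"variant_id": sel1}).to_csv(BASE / "strategy1_variants.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": sel2}).to_csv(BASE / "strategy2_genes.tsv", sep="\t", index=False)
    print(f"strategy 1: {len(sel1)}/{len(ann)} variants selected: {sel1}")
    print(f"strategy 2: {len(sel2)} genes with >=10 pooled heterozygous carriers: {sel2}")
    print(f"candidate compound heterozygotes (not promoted to KO): "
          f"{ {g: len(s) for g, s in comp.items()} }")


if __name__ == "__main__":
    main()
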