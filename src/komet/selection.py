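"""Gene/variant selection strategies for human-knockout discovery.

Strategy 1 targets complete knockouts: high-confidence (LOFTEE HC) pLoF
variants with MAF < 2% carrying at least two homozygotes, in genes present
in the OMIM or Open Targets lists.  Strategy 2 targets genes with at least
10 distinct heterozygous carriers of rare (MAF <= 0.1%) pathogenic or HC
pLoF variants, restricted to a supplied disease-gene list.  MAF cutoffs
are strict "<" for Strategy 1 and "<=" for Strategy 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierSet",
    "carriers_from_dosage",
    "select_strategy1",
    "select_strategy2",
    "candidate_compound_heterozygotes",
]


@dataclass
class CarrierSet:
    variant_id: str
    homozygous_ids: set[str] = field(default_factory=set)
    heterozygous_ids: set[str] = field(default_factory=set)

    def __post_init__(self):
        overlap = self.homozygous_ids & self.heterozygous_ids
        if overlap:
            raise ValueError(
                f"{self.variant_id}: samples {sorted(overlap)} listed as both "
                "homozygous and heterozygous"
            )


def carriers_from_dosage(dosage: pd.DataFrame) -> dict[str, CarrierSet]:
    """Build carrier sets from a variants x samples dosage matrix (0/1/2)."""
    out = {}
    for vid, row in dosage.iterrows():
        out[vid] = CarrierSet(
            variant_id=vid,
            homozygous_ids=set(row.index[row == 2]),
            heterozygous_ids=set(row.index[row == 1]),
        )
    return out


def _require_carriers(annotations: pd.DataFrame, carrier_sets: dict[str, CarrierSet]):
    missing = [v for v in annotations["variant_id"] if v not in carrier_sets]
    if missing:
        raise KeyError(f"variants missing from carrier sets: {missing}")


def select_strategy1(
    annotations: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    omim_genes: set[str],
    open_targets_genes: set[str],
    maf_cutoff: float = 0.02,
    min_homozygotes: int = 2,
) -> list[str]:
    """Variants with LOFTEE HC, MAF < cutoff, >= 2 complete KOs, and gene in
    the union of the OMIM and Open Targets lists.  Order: gene, variant_id."""
    _require_carriers(annotations, carrier_sets)
    known = set(omim_genes) | set(open_targets_genes)
    keep = annotations[
        (annotations["loftee"] == "HC")
        & (annotations["maf"] < maf_cutoff)
        & annotations["gene"].isin(known)
        & annotations["variant_id"].map(
            lambda v: len(carrier_sets[v].homozygous_ids) >= min_homozygotes
        )
    ]
    keep = keep.sort_values(["gene", "variant_id"])
    return list(keep["variant_id"])


def select_strategy2(
    annotations: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    disease_genes: set[str],
    maf_cutoff: float = 0.001,
    min_carriers: int = 10,
) -> list[str]:
    """Genes from the disease list whose pooled distinct heterozygous
    carriers over rare (MAF <= cutoff) pathogenic-or-HC variants number at
    least ``min_carriers``.  Returns the sorted gene list."""
    _require_carriers(annotations, carrier_sets)
    if not disease_genes:
        logger.info("strategy 2: empty disease gene list, nothing to select")
        return []
    qualifying = annotations[
        (annotations["maf"] <= maf_cutoff)
        & (annotations["pathogenic"].astype(bool) | (annotations["loftee"] == "HC"))
        & annotations["gene"].isin(disease_genes)
    ]
    selected = []
    for gene, grp in qualifying.groupby("gene"):
        pooled: set[str] = set()
        for vid in grp["variant_id"]:
            pooled |= carrier_sets[vid].heterozygous_ids
        if len(pooled) >= min_carriers:
            selected.append(gene)
    return sorted(selected)


def candidate_compound_heterozygotes(
    annotations: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    maf_cutoff: float = 0.02,
) -> dict[str, set[str]]:
    """Samples heterozygous for >= 2 qualifying (HC, rare) variants of the
    same gene: *candidate* compound heterozygotes.  Phase is unknown, so
    they are reported for follow-up, never auto-promoted to knockouts."""
    _require_carriers(annotations, carrier_sets)
    qualifying = annotations[
        (annotations["loftee"] == "HC") & (annotations["maf"] < maf_cutoff)
    ]
    out: dict[str, set[str]] = {}
    for gene, grp in qualifying.groupby("gene"):
        counts: dict[str, int] = {}
        for vid in grp["variant_id"]:
            for s in carrier_sets[vid].heterozygous_ids:
                counts[s] = counts.get(s, 0) + 1
        hits = {s for s, c in counts.items() if c >= 2}
        if hits:
            out[gene] = hits
    return out


def read_gene_list(path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return genes
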