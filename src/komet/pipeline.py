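"""End-to-end orchestration: select -> preprocess -> associate -> (power)
-> ehr-scan, from a single YAML config, with a count ledger in the run log.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import association, disease, power, preprocess, selection
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "annotate_report"]


def annotate_report(
    records: list[association.AssociationRecord],
    drug_genes: set[str],
    omim_map: dict[str, str],
    strategy_map: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Left-join report annotations by gene symbol; unmatched genes blank."""
    frame = association.records_to_frame(records)
    frame["drug_target"] = frame["gene"].isin(drug_genes)
    frame["omim_disorder"] = frame["gene"].map(omim_map).fillna("")
    frame["strategy"] = frame["variant_id"].map(strategy_map or {}).fillna("").astype(str)
    return frame


def load_omim_map(path: Path) -> dict[str, str]:
    """Gene list or gene<TAB>disorder map; last entry wins on duplicates."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        gene = parts[0]
        if gene in out:
            logger.warning("duplicate gene %s in OMIM map; last entry wins", gene)
        out[gene] = parts[1] if len(parts) > 1 else ""
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write one TSV per stage plus a combined report.

    Any stage failure aborts with the stage name and cause; partial outputs
    for the run are removed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "load"
    try:
        for name in ("phenotypes", "genotypes", "annotations", "metabolites", "ehr", "controls"):
            p = getattr(config, name)
            if not p.exists():
                raise FileNotFoundError(f"input file not found: {p}")
        pheno = pd.read_csv(config.phenotypes, sep="\t", dtype={"sample_id": str})
        geno = pd.read_csv(config.genotypes, sep="\t", index_col="variant_id")
        annotations = pd.read_csv(config.annotations, sep="\t")
        abundance = pd.read_csv(config.metabolites, sep="\t", index_col="sample_id")
        ehr = pd.read_csv(config.ehr, sep="\t", dtype=str)
        if ehr.empty:
            ehr = pd.DataFrame(columns=["sample_id", "icd10_code"])
        controls = config.controls.read_text().split()
        carrier_sets = selection.carriers_from_dosage(geno)
        sample_ids = list(pheno["sample_id"])
        logger.info(
            "loaded %d samples, %d variants, %d metabolites, %d controls",
            len(sample_ids), len(carrier_sets), abundance.shape[1], len(controls),
        )

        stage = "select"
        omim = selection.read_gene_list(config.omim_genes)
        otg = selection.read_gene_list(config.open_targets_genes)
        drug = selection.read_gene_list(config.drug_genes)
        sel1 = selection.select_strategy1(annotations, carrier_sets, omim, otg)
        sel2 = selection.select_strategy2(annotations, carrier_sets, omim | otg)
        logger.info(
            "strategy 1 kept %d/%d variants; strategy 2 kept %d genes",
            len(sel1), len(carrier_sets), len(sel2),
        )
        written["selected"] = out / "selected_variants.tsv"
        pd.DataFrame({"variant_id": sel1}).to_csv(written["selected"], sep="\t", index=False)

        stage = "preprocess"
        resid = preprocess.preprocess_metabolites(
            abundance, pheno,
            max_missing=config.max_missing, alpha=config.alpha,
        )
        logger.info(
            "preprocess: %d -> %d metabolites after missingness filter and fits",
            abundance.shape[1], resid.residuals.shape[1],
        )
        written["residuals"] = out / "residuals.tsv"
        resid.residuals.to_csv(written["residuals"], sep="\t")

        stage = "associate"
        scan_sets = {v: carrier_sets[v] for v in sel1}
        m_eff = association.effective_tests(resid.residuals, config.variance_fraction)
        spec = association.significance_threshold(config.alpha, m_eff, max(len(scan_sets), 1))
        logger.info(
            "threshold alpha/%d/%d = %.3g", m_eff, len(scan_sets), spec.threshold
        )
        gene_of = dict(zip(annotations["variant_id"], annotations["gene"]))
        records = association.run_association_scan(
            resid.residuals, scan_sets, controls, spec, gene_of=gene_of
        )
        report = annotate_report(
            records, drug, load_omim_map(config.omim_genes),
            {v: 1 for v in sel1},
        )
        report = report.sort_values("metabolite_id", kind="mergesort")
        written["associations"] = out / "associations.tsv"
        report.to_csv(written["associations"], sep="\t", index=False)
        n_sig = int(report["significant"].sum())
        logger.info("association scan: %d records, %d significant", len(report), n_sig)
        miss = association.missingness_scan(resid.residuals, scan_sets, controls)
        written["missingness"] = out / "missingness.tsv"
        pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id, "metabolite_id": r.metabolite_id,
                    "n_ko_missing": r.n_ko_missing, "n_ko": r.n_ko,
                    "n_other_missing": r.n_other_missing, "n_other": r.n_other,
                    "p_value": r.p_value,
                }
                for r in miss
            ],
            columns=["variant_id", "metabolite_id", "n_ko_missing", "n_ko",
                     "n_other_missing", "n_other", "p_value"],
        ).to_csv(written["missingness"], sep="\t", index=False)

        if config.run_power:
            stage = "power"
            grid = power.simulate_power(
                power.PowerGridSpec(threshold=spec.threshold, seed=config.seed)
            )
            written["power"] = out / "power.tsv"
            power.power_report(grid, tsv_path=written["power"], png_path=out / "power.png")

        stage = "ehr-scan"
        cases = disease.recurrent_case_table(ehr, sample_ids)
        drecords, dthr = disease.disease_scan(
            cases, scan_sets, pheno, controls,
            alpha=config.alpha, age_bin_years=config.age_bin_years,
            min_cases=config.min_cases, min_ko=config.min_ko,
        )
        written["disease"] = out / "disease_associations.tsv"
        pd.DataFrame(
            [
                {
                    "variant_id": r.variant_id, "category": r.category,
                    "cmle_or": r.cmle_or, "p_value": r.p_value,
                    "n_cases": r.n_cases, "n_ko": r.n_ko,
                    "significant": r.significant,
                }
                for r in drecords
            ],
            columns=["variant_id", "category", "cmle_or", "p_value", "n_cases", "n_ko", "significant"],
        ).to_csv(written["disease"], sep="\t", index=False)
        logger.info(
            "disease scan: %d records at threshold %.3g", len(drecords), dthr
        )
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return written
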