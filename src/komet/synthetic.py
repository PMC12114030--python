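"""Synthetic biobank-style cohort generator.

Individual-level biobank data cannot be redistributed, so every downstream
stage is exercised on generated cohorts that reproduce the *structure* of
the real inputs: a phenotype table (age, sex, BMI, smoking, education,
sampling season, 10 genotype PCs), per-variant genotype calls, variant
annotations (LOFTEE confidence, MAF, pathogenicity), a raw metabolite
peak-area matrix with left-censoring below a limit of detection, and
recurrent ICD-10 diagnosis events with a configurable stratified odds
ratio between knockouts and controls.

Metabolite abundances are log-normal: the log value is a metabolite
baseline plus covariate effects plus an injected knockout shift (beta, in
units of the unit-variance noise) plus standard normal noise.  Values
below the per-metabolite ``lod_quantile`` are set missing, emulating
below-LOD censoring.  Every injected effect is recorded in a truth record
so recovery tests can verify the pipeline end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CohortConfig, EhrSpec, VariantSpec

__all__ = ["CohortBundle", "generate_cohort", "write_fixture", "read_fixture"]

_SMOKING = np.array(["never", "former", "current"])
_EDUCATION = np.array(["basic", "secondary", "higher"])
_SEASON = np.array(["winter", "spring", "summer", "autumn"])

# level whose indicator carries a configured categorical covariate effect
_EFFECT_LEVEL = {"smoking": "current", "education": "higher", "season": "summer"}


@dataclass
class CohortBundle:
    phenotypes: pd.DataFrame  # one row per sample
    genotypes: pd.DataFrame  # variants x samples, dosage 0/1/2
    annotations: pd.DataFrame  # one row per variant
    abundance: pd.DataFrame  # samples x metabolites, NaN = below LOD
    ehr: pd.DataFrame  # columns sample_id, icd10_code
    control_ids: list[str]
    truth: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.phenotypes["sample_id"])


def _covariate_design(pheno: pd.DataFrame) -> dict[str, np.ndarray]:
    """Standardized / indicator-coded covariate columns used for effects."""
    out = {}
    for col in ("age", "bmi"):
        x = pheno[col].to_numpy(dtype=float)
        out[col] = (x - x.mean()) / x.std()
    out["sex"] = (pheno["sex"] == "M").to_numpy(dtype=float)
    for col, level in _EFFECT_LEVEL.items():
        out[col] = (pheno[col] == level).to_numpy(dtype=float)
    for i in range(1, 11):
        out[f"pc{i}"] = pheno[f"pc{i}"].to_numpy(dtype=float)
    return out


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Generate a complete cohort bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{i:06d}" for i in range(1, n + 1)]

    pheno = pd.DataFrame(
        {
            "sample_id": samples,
            "age": rng.uniform(18.0, 90.0, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            **{f"pc{i}": rng.standard_normal(n).round(6) for i in range(1, 11)},
            "bmi": rng.normal(26.5, 4.5, n).clip(15.0, 55.0).round(2),
            "smoking": rng.choice(_SMOKING, n, p=[0.55, 0.25, 0.20]),
            "education": rng.choice(_EDUCATION, n, p=[0.20, 0.50, 0.30]),
            "season": rng.choice(_SEASON, n),
        }
    )

    # genotype dosages; carriers drawn without replacement per variant
    dosage = pd.DataFrame(
        0, index=[v.variant_id for v in config.variants], columns=samples, dtype=int
    )
    carriers: dict[str, dict[str, list[str]]] = {}
    for v in config.variants:
        picked = rng.choice(n, size=v.n_homozygous + v.n_heterozygous, replace=False)
        hom = [samples[i] for i in picked[: v.n_homozygous]]
        het = [samples[i] for i in picked[v.n_homozygous :]]
        dosage.loc[v.variant_id, hom] = 2
        dosage.loc[v.variant_id, het] = 1
        carriers[v.variant_id] = {"hom": sorted(hom), "het": sorted(het)}

    non_carriers = [s for s in samples if dosage[s].sum() == 0] if len(config.variants) else samples
    if len(non_carriers) < config.n_controls:
        raise ValueError(
            f"only {len(non_carriers)} carrier-free samples available for "
            f"{config.n_controls} controls"
        )
    control_ids = sorted(
        rng.choice(non_carriers, size=config.n_controls, replace=False).tolist()
    )

    annotations = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in config.variants],
            "gene": [v.gene for v in config.variants],
            "loftee": [v.loftee for v in config.variants],
            "maf": [v.maf for v in config.variants],
            "pathogenic": [v.pathogenic for v in config.variants],
            "in_omim": [v.in_omim for v in config.variants],
            "in_open_targets": [v.in_open_targets for v in config.variants],
        }
    )

    # metabolite matrix: log-normal with covariate effects + KO shifts
    design = _covariate_design(pheno)
    mets = [f"M{i:04d}" for i in range(1, config.n_metabolites + 1)]
    baseline = rng.uniform(10.0, 15.0, config.n_metabolites)
    log_x = baseline[None, :] + rng.standard_normal((n, config.n_metabolites))
    met_index = {m: j for j, m in enumerate(mets)}
    for met, pairs in config.covariate_effects.items():
        if met not in met_index:
            raise ValueError(f"covariate effect on unknown metabolite {met}")
        for cov, slope in pairs:
            log_x[:, met_index[met]] += slope * design[cov]
    truth_effects = []
    sample_pos = {s: i for i, s in enumerate(samples)}
    for v in config.variants:
        rows = [sample_pos[s] for s in carriers[v.variant_id]["hom"]]
        for met, beta in v.affected_metabolites:
            if met not in met_index:
                raise ValueError(f"{v.variant_id}: unknown metabolite {met}")
            log_x[rows, met_index[met]] += beta
            truth_effects.append(
                {"variant_id": v.variant_id, "gene": v.gene, "metabolite_id": met, "beta": beta}
            )

    abundance = pd.DataFrame(np.exp(log_x), index=samples, columns=mets)
    if config.lod_quantile > 0:
        lod = abundance.quantile(config.lod_quantile, axis=0)
        abundance = abundance.mask(abundance.lt(lod, axis=1))
    abundance.index.name = "sample_id"

    # covariate missingness is observational: applied after metabolites
    for cov, rate in config.covariate_missing_rates.items():
        if rate > 0:
            mask = rng.random(n) < rate
            pheno.loc[mask, cov] = np.nan

    ehr = _generate_ehr(rng, pheno, carriers, config.ehr_specs)

    truth = {
        "seed": config.seed,
        "metabolite_effects": truth_effects,
        "covariate_effects": {
            m: [[c, s] for c, s in pairs] for m, pairs in config.covariate_effects.items()
        },
        "lod_quantile": config.lod_quantile,
        "ehr_specs": [
            {
                "variant_id": e.variant_id,
                "icd10_category": e.icd10_category,
                "common_odds_ratio": e.common_odds_ratio,
                "baseline_rate": e.baseline_rate,
            }
            for e in config.ehr_specs
        ],
        "carriers": carriers,
        "control_ids": control_ids,
    }
    return CohortBundle(
        phenotypes=pheno,
        genotypes=dosage,
        annotations=annotations,
        abundance=abundance,
        ehr=ehr,
        control_ids=control_ids,
        truth=truth,
    )


def _generate_ehr(
    rng: np.random.Generator,
    pheno: pd.DataFrame,
    carriers: dict[str, dict[str, list[str]]],
    specs: list[EhrSpec],
) -> pd.DataFrame:
    """Recurrent-diagnosis events with stratum-constant baseline odds.

    Controls are cases at the baseline rate; knockouts' case odds are the
    baseline odds times the configured common odds ratio, identically in
    every sex x age stratum, so the conditional odds ratio equals the
    configured value.  Cases receive two events in the category (recurrence
    rule), and half-rate single events exercise the at-least-twice filter.
    """
    rows: list[tuple[str, str]] = []
    samples = pheno["sample_id"].to_numpy()
    n = len(samples)
    for spec in specs:
        ko = set(carriers.get(spec.variant_id, {}).get("hom", []))
        base_odds = spec.baseline_rate / (1.0 - spec.baseline_rate)
        ko_rate = spec.common_odds_ratio * base_odds / (1.0 + spec.common_odds_ratio * base_odds)
        p_case = np.where(np.isin(samples, list(ko)), ko_rate, spec.baseline_rate)
        is_case = rng.random(n) < p_case
        single = (~is_case) & (rng.random(n) < spec.baseline_rate / 2.0)
        for s in samples[is_case]:
            rows.append((s, f"{spec.icd10_category}.0"))
            rows.append((s, f"{spec.icd10_category}.8"))
        for s in samples[single]:
            rows.append((s, f"{spec.icd10_category}.9"))
    # unrelated background noise, never recurrent
    noise = rng.random(n) < 0.03
    for s in samples[noise]:
        rows.append((s, "Z76.0"))
    return pd.DataFrame(rows, columns=["sample_id", "icd10_code"])


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as the TSV/VCF fixture set the readers consume."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": d / "phenotypes.tsv",
        "genotypes": d / "genotypes.tsv",
        "vcf": d / "genotypes.vcf",
        "annotations": d / "annotations.tsv",
        "metabolites": d / "metabolites.tsv",
        "ehr": d / "ehr.tsv",
        "controls": d / "controls.txt",
        "omim_genes": d / "omim_genes.txt",
        "open_targets_genes": d / "open_targets_genes.txt",
        "drug_genes": d / "drug_genes.txt",
        "truth": d / "truth.json",
    }
    try:
        bundle.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
        geno = bundle.genotypes.copy()
        geno.insert(0, "variant_id", geno.index)
        geno.to_csv(paths["genotypes"], sep="\t", index=False)
        _write_vcf(bundle, paths["vcf"])
        bundle.annotations.to_csv(paths["annotations"], sep="\t", index=False)
        bundle.abundance.to_csv(paths["metabolites"], sep="\t")
        bundle.ehr.to_csv(paths["ehr"], sep="\t", index=False)
        paths["controls"].write_text("".join(s + "\n" for s in bundle.control_ids))
        ann = bundle.annotations
        for col, key in (
            ("in_omim", "omim_genes"),
            ("in_open_targets", "open_targets_genes"),
            ("in_open_targets", "drug_genes"),
        ):
            genes = sorted(set(ann.loc[ann[col].astype(bool), "gene"]))
            paths[key].write_text("".join(g + "\n" for g in genes))
        paths["truth"].write_text(json.dumps(bundle.truth, indent=1, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {d}: {exc}") from exc
    return paths


def _write_vcf(bundle: CohortBundle, path: Path) -> None:
    """Minimal VCF v4.2 with GT only; dosage 0/1/2 -> 0/0, 0/1, 1/1."""
    samples = bundle.sample_ids
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for pos, (vid, row) in enumerate(bundle.genotypes.iterrows(), start=1000):
            gts = "\t".join(gt_map[int(row[s])] for s in samples)
            fh.write(f"1\t{pos}\t{vid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf_dosage(path: str | Path) -> pd.DataFrame:
    """Read a (plain-text) VCF into a variants x samples dosage matrix."""
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        ids, rows = [], []
        for rec in vcf:
            ids.append(rec.id)
            dose = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                dose.append(-1 if gt is None or None in gt else int(sum(gt)))
            rows.append(dose)
    return pd.DataFrame(rows, index=ids, columns=samples, dtype=int)


def read_fixture(directory: str | Path) -> CohortBundle:
    """Read a fixture directory back into a bundle (round-trip inverse)."""
    d = Path(directory)
    pheno = pd.read_csv(d / "phenotypes.tsv", sep="\t", dtype={"sample_id": str})
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t", index_col="variant_id")
    annotations = pd.read_csv(d / "annotations.tsv", sep="\t")
    abundance = pd.read_csv(d / "metabolites.tsv", sep="\t", index_col="sample_id")
    ehr = pd.read_csv(d / "ehr.tsv", sep="\t", dtype=str)
    if ehr.empty:
        ehr = pd.DataFrame(columns=["sample_id", "icd10_code"])
    controls = (d / "controls.txt").read_text().split()
    truth = json.loads((d / "truth.json").read_text()) if (d / "truth.json").exists() else {}
    return CohortBundle(
        phenotypes=pheno,
        genotypes=geno,
        annotations=annotations,
        abundance=abundance,
        ehr=ehr,
        control_ids=controls,
        truth=truth,
    )
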