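"""Configuration types for the synthetic cohort generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["VariantSpec", "EhrSpec", "CohortConfig", "PipelineConfig"]


@dataclass
class VariantSpec:
    """One simulated loss-of-function variant.

    ``affected_metabolites`` lists (metabolite_id, beta) pairs: beta is the
    location shift, in residual standard deviations, added to the log
    abundance of homozygous (knockout) carriers; its sign is the direction
    of the effect.
    """

    variant_id: str
    gene: str
    n_homozygous: int = 0
    n_heterozygous: int = 0
    maf: float = 0.001
    loftee: str = "HC"  # HC | LC | none
    pathogenic: bool = False
    in_omim: bool = True
    in_open_targets: bool = False
    affected_metabolites: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")
        if self.n_homozygous < 0 or self.n_heterozygous < 0:
            raise ValueError(f"{self.variant_id}: carrier counts must be >= 0")
        if self.loftee not in ("HC", "LC", "none"):
            raise ValueError(f"{self.variant_id}: loftee must be HC, LC or none")
        for m, beta in self.affected_metabolites:
            if not np_isfinite(beta):
                raise ValueError(f"{self.variant_id}/{m}: beta must be finite")


def np_isfinite(x) -> bool:
    import math

    return math.isfinite(float(x))


@dataclass
class EhrSpec:
    """Injected variant-diagnosis association with a common odds ratio.

    Within every sex x age stratum, controls are cases for the ICD-10
    category at ``baseline_rate``; knockout carriers' case odds are the
    baseline odds multiplied by ``common_odds_ratio``, so the conditional
    (stratum-wise) odds ratio is the configured value by construction.
    """

    variant_id: str
    icd10_category: str
    common_odds_ratio: float = 1.0
    baseline_rate: float = 0.05

    def __post_init__(self):
        if self.common_odds_ratio <= 0:
            raise ValueError("common_odds_ratio must be > 0")
        if not 0.0 <= self.baseline_rate <= 1.0:
            raise ValueError("baseline_rate must be in [0, 1]")
        if len(self.icd10_category) != 3:
            raise ValueError("icd10_category must be a 3-character prefix")


@dataclass
class CohortConfig:
    n_samples: int = 1000
    n_controls: int = 258
    n_metabolites: int = 50
    variants: list[VariantSpec] = field(default_factory=list)
    # metabolite -> list of (covariate, slope on the log scale per SD or per
    # indicator); covariates: age, sex, bmi, smoking, season, education
    covariate_effects: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    lod_quantile: float = 0.0
    covariate_missing_rates: dict[str, float] = field(default_factory=dict)
    ehr_specs: list[EhrSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.n_controls > self.n_samples:
            raise ValueError("n_controls must not exceed n_samples")
        if not 0.0 <= self.lod_quantile < 1.0:
            raise ValueError("lod_quantile must be in [0, 1)")
        for cov, rate in self.covariate_missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {cov} outside [0, 1]")
        for v in self.variants:
            if v.n_homozygous + v.n_heterozygous > self.n_samples:
                raise ValueError(
                    f"{v.variant_id}: n_homozygous + n_heterozygous "
                    f"({v.n_homozygous + v.n_heterozygous}) exceeds n_samples "
                    f"({self.n_samples})"
                )
        self.variants = [
            v if isinstance(v, VariantSpec) else VariantSpec(**v) for v in self.variants
        ]
        self.ehr_specs = [
            e if isinstance(e, EhrSpec) else EhrSpec(**e) for e in self.ehr_specs
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "variants" in raw:
            raw["variants"] = [
                VariantSpec(
                    **{
                        **v,
                        "affected_metabolites": [
                            tuple(p) for p in v.get("affected_metabolites", [])
                        ],
                    }
                )
                for v in raw["variants"]
            ]
        if "ehr_specs" in raw:
            raw["ehr_specs"] = [EhrSpec(**e) for e in raw["ehr_specs"]]
        if "covariate_effects" in raw:
            raw["covariate_effects"] = {
                m: [tuple(p) for p in pairs]
                for m, pairs in raw["covariate_effects"].items()
            }
        return cls(**raw)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    phenotypes: Path
    genotypes: Path
    annotations: Path
    metabolites: Path
    ehr: Path
    controls: Path
    omim_genes: Path
    open_targets_genes: Path
    drug_genes: Path
    output_dir: Path
    alpha: float = 0.05
    max_missing: float = 0.95
    variance_fraction: float = 0.90
    age_bin_years: int = 10
    min_cases: int = 5
    min_ko: int = 2
    run_power: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in (
            "phenotypes",
            "genotypes",
            "annotations",
            "metabolites",
            "ehr",
            "controls",
            "omim_genes",
            "open_targets_genes",
            "drug_genes",
            "output_dir",
        ):
            setattr(self, name, Path(getattr(self, name)))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        cfg = cls(**raw)
        for name in (
            "phenotypes",
            "genotypes",
            "annotations",
            "metabolites",
            "ehr",
            "controls",
            "omim_genes",
            "open_targets_genes",
            "drug_genes",
            "output_dir",
        ):
            p = getattr(cfg, name)
            if not p.is_absolute():
                setattr(cfg, name, base / p)
        return cfg
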