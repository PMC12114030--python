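"""Knockout-versus-control metabolite association scan.

Each (variant, metabolite) pair is tested with the exact one-sided
Wilcoxon rank-sum test in the direction of the observed shift, after
dropping samples with that metabolite missing.  The study-wise threshold
is Bonferroni over an *effective* number of metabolite tests — the number
of principal components explaining a set fraction of the residual-matrix
variance — times the number of variants.  Per pair the scan also reports
the count of carriers beyond 3 control SDs and, where missingness is
present, a one-sided Fisher exact test of higher below-LOD missingness in
knockouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exact import exact_wilcoxon_one_sided, minimal_p
from .selection import CarrierSet

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "ThresholdSpec",
    "effective_tests",
    "significance_threshold",
    "count_3sd_outliers",
    "missingness_test",
    "MissingnessRecord",
    "missingness_scan",
    "run_association_scan",
    "records_to_frame",
]


@dataclass
class AssociationRecord:
    gene: str
    variant_id: str
    metabolite_id: str
    n_controls: int
    n_carriers: int
    n_outliers_3sd: int
    direction: str
    p_value: float
    significant: bool
    missingness_p: float | None = None


@dataclass(frozen=True)
class ThresholdSpec:
    alpha: float
    m_eff: int
    n_variants: int

    @property
    def threshold(self) -> float:
        return self.alpha / (self.m_eff * self.n_variants)


def significance_threshold(alpha: float, m_eff: int, n_variants: int) -> ThresholdSpec:
    """Bonferroni threshold alpha / (m_eff * n_variants), unrounded."""
    if alpha <= 0 or m_eff <= 0 or n_variants <= 0:
        raise ValueError("alpha, m_eff and n_variants must be positive")
    return ThresholdSpec(alpha=alpha, m_eff=m_eff, n_variants=n_variants)


def effective_tests(residuals: pd.DataFrame, variance_fraction: float = 0.90) -> int:
    """Smallest number of principal components explaining >= the given
    fraction of total variance of the residual matrix.

    Missing entries are zero-filled for this computation only — after
    z-scoring, zero is the column mean, so column means are preserved.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError(f"variance_fraction {variance_fraction} outside (0, 1]")
    X = residuals.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 metabolites")
    X = np.nan_to_num(X - np.nanmean(X, axis=0), nan=0.0)
    s = np.linalg.svd(X, compute_uv=False)
    ev = s**2
    total = ev.sum()
    if total == 0:
        return 0
    tol = ev.max() * max(X.shape) * np.finfo(float).eps
    rank = int((ev > tol).sum())
    cum = np.cumsum(ev) / total
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return min(k, rank)


def count_3sd_outliers(carrier_residuals, control_residuals) -> int:
    """Carriers whose residual lies outside control mean +/- 3 control SD."""
    x = np.asarray(carrier_residuals, dtype=float)
    y = np.asarray(control_residuals, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if y.size == 0:
        raise ValueError("control group is empty")
    mu, sd = y.mean(), y.std(ddof=1) if y.size > 1 else 0.0
    if sd == 0:
        logger.warning("control SD is zero; counting all carriers off the control value")
        return int((x != mu).sum())
    return int((np.abs(x - mu) > 3 * sd).sum())


def missingness_test(ko_detected_flags, other_detected_flags) -> float:
    """One-sided Fisher exact p for higher below-LOD missingness in KOs.

    Flags are True where the metabolite was detected.  The 2x2 table is
    (missing/detected) x (KO/other); the tail is the exact hypergeometric
    probability of at-least-observed KO missingness.
    """
    ko = np.asarray(ko_detected_flags, dtype=bool)
    other = np.asarray(other_detected_flags, dtype=bool)
    if ko.size == 0 or other.size == 0:
        raise ValueError("both groups must be nonempty")
    table = [
        [int((~ko).sum()), int(ko.sum())],
        [int((~other).sum()), int(other.sum())],
    ]
    if min(sum(table[0]), sum(table[1])) == 0 or min(
        table[0][0] + table[1][0], table[0][1] + table[1][1]
    ) == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])


@dataclass
class MissingnessRecord:
    variant_id: str
    metabolite_id: str
    n_ko_missing: int
    n_ko: int
    n_other_missing: int
    n_other: int
    p_value: float


def missingness_scan(
    residuals: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    control_ids: list[str],
) -> list[MissingnessRecord]:
    """Below-LOD missingness test per (variant, metabolite) pair with any
    missing value in either group.

    This channel covers pairs the rank test cannot touch — in particular a
    metabolite entirely missing in the knockouts, where absence itself is
    the signal (concentration under the detection limit).  Sorted by p.
    """
    controls = list(control_ids)
    records = []
    for vid, cs in sorted(carrier_sets.items()):
        ko = sorted(cs.homozygous_ids)
        if not ko:
            continue
        ko_block = residuals.loc[ko]
        ctrl_block = residuals.loc[controls]
        for met in residuals.columns:
            ko_det = ko_block[met].notna().to_numpy()
            other_det = ctrl_block[met].notna().to_numpy()
            if ko_det.all() and other_det.all():
                continue
            records.append(
                MissingnessRecord(
                    variant_id=vid,
                    metabolite_id=met,
                    n_ko_missing=int((~ko_det).sum()),
                    n_ko=len(ko),
                    n_other_missing=int((~other_det).sum()),
                    n_other=len(controls),
                    p_value=missingness_test(ko_det, other_det),
                )
            )
    records.sort(key=lambda r: (r.p_value, r.variant_id, r.metabolite_id))
    return records


def run_association_scan(
    residuals: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    control_ids: list[str],
    threshold_spec: ThresholdSpec,
    gene_of: dict[str, str] | None = None,
    min_attainable: bool = True,
) -> list[AssociationRecord]:
    """One record per (variant, metabolite) with both groups nonempty after
    missing-value exclusion, sorted by p ascending.

    ``min_attainable`` pre-screens pairs whose smallest attainable p (the
    fully separated configuration) already exceeds the threshold; those are
    still tested and reported, the flag only suppresses the `significant`
    mark — the printed p cannot clear the threshold either way, so the
    screen changes nothing and is kept purely as a sanity check.
    """
    controls = list(control_ids)
    unknown = set(controls) - set(residuals.index)
    if unknown:
        raise KeyError(f"unknown control sample IDs: {sorted(unknown)[:5]}")
    threshold = threshold_spec.threshold
    records: list[AssociationRecord] = []
    for vid, cs in sorted(carrier_sets.items()):
        ko = sorted(cs.homozygous_ids)
        unknown = set(ko) - set(residuals.index)
        if unknown:
            raise KeyError(f"{vid}: unknown carrier sample IDs: {sorted(unknown)[:5]}")
        if set(ko) & set(controls):
            raise ValueError(f"{vid}: carrier set overlaps control IDs")
        if not ko:
            logger.info("%s: no knockouts, skipped", vid)
            continue
        gene = (gene_of or {}).get(vid, "")
        ko_block = residuals.loc[ko]
        ctrl_block = residuals.loc[controls]
        for met in residuals.columns:
            x = ko_block[met].to_numpy(dtype=float)
            y = ctrl_block[met].to_numpy(dtype=float)
            xo, yo = x[~np.isnan(x)], y[~np.isnan(y)]
            miss_p = None
            if np.isnan(x).any() or np.isnan(y).any():
                miss_p = missingness_test(~np.isnan(x), ~np.isnan(y))
            if xo.size == 0 or yo.size == 0:
                logger.info("%s/%s: a group is empty after missing-value exclusion", vid, met)
                continue
            res = exact_wilcoxon_one_sided(xo, yo)
            records.append(
                AssociationRecord(
                    gene=gene,
                    variant_id=vid,
                    metabolite_id=met,
                    n_controls=int(yo.size),
                    n_carriers=int(xo.size),
                    n_outliers_3sd=count_3sd_outliers(xo, yo),
                    direction=res.direction,
                    p_value=res.p_value,
                    significant=res.p_value < threshold
                    and (not min_attainable or minimal_p(xo.size, yo.size) < threshold),
                    missingness_p=miss_p,
                )
            )
    records.sort(key=lambda r: (r.p_value, r.variant_id, r.metabolite_id))
    return records


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    cols = [
        "gene", "variant_id", "metabolite_id", "n_controls", "n_carriers",
        "n_outliers_3sd", "direction", "p_value", "significant", "missingness_p",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
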