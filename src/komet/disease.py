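"""Variant-diagnosis association from EHR events.

Case definition: a sample is a case for an ICD-10 three-character category
when at least two recorded diagnosis events fall in that category (codes
are uppercased, the dot stripped, and truncated to three characters before
counting — recurrence is evaluated at the category level).  Categories
with fewer than 5 cases and variants with fewer than 2 knockouts are
excluded.  Knockout-versus-control association is tested per (variant,
category) with a conditional exact test given the margins of the sex x
age-group strata: under the null the knockout-case total T is the
convolution of central hypergeometric distributions, and the two-sided p
sums the probabilities of outcomes no more probable than the observed T
(the probability-mass rule, which reduces to Fisher's two-sided exact test
for a single stratum).  The common odds ratio is estimated by conditional
maximum likelihood: the psi solving E_psi[T] = T_obs under the product of
noncentral hypergeometric likelihoods, with 0 or infinity returned on the
attainable boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp

from .selection import CarrierSet

logger = logging.getLogger(__name__)

__all__ = [
    "StratumTableSet",
    "DiseaseAssociationRecord",
    "recurrent_case_table",
    "apply_exclusions",
    "build_strata",
    "conditional_exact_test",
    "cmle_common_or",
    "disease_scan",
]


def normalize_icd10(code: str) -> str | None:
    """Three-character ICD-10 category, or None for malformed codes."""
    code = str(code).strip().upper().replace(".", "")
    return code[:3] if len(code) >= 3 else None


def recurrent_case_table(events: pd.DataFrame, samples: list[str]) -> pd.DataFrame:
    """Sample x category boolean case flags under the at-least-twice rule."""
    unknown = set(events["sample_id"]) - set(samples)
    if unknown:
        raise KeyError(f"EHR events for samples outside the cohort: {sorted(unknown)[:5]}")
    cats = events["icd10_code"].map(normalize_icd10)
    bad = cats.isna()
    if bad.any():
        logger.warning("skipping %d malformed ICD-10 codes", int(bad.sum()))
    ev = events.loc[~bad].assign(category=cats[~bad])
    counts = ev.groupby(["sample_id", "category"]).size().unstack(fill_value=0)
    table = counts.ge(2).reindex(index=samples, fill_value=False)
    return table.loc[:, table.any(axis=0)] if not table.empty else table


def apply_exclusions(
    case_table: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    min_cases: int = 5,
    min_ko: int = 2,
) -> tuple[list[str], list[str]]:
    """Surviving (categories, variants): >=min_cases cases, >=min_ko KOs."""
    n_cases = case_table.sum(axis=0)
    categories = sorted(n_cases.index[n_cases >= min_cases])
    variants = sorted(
        v for v, cs in carrier_sets.items() if len(cs.homozygous_ids) >= min_ko
    )
    logger.info(
        "exclusions: %d/%d categories and %d/%d variants survive",
        len(categories), case_table.shape[1], len(variants), len(carrier_sets),
    )
    return categories, variants


@dataclass
class StratumTableSet:
    variant_id: str
    category: str
    # each table [[ko_case, ko_noncase], [ctrl_case, ctrl_noncase]]
    strata: list[np.ndarray] = field(default_factory=list)
    stratum_keys: list[tuple] = field(default_factory=list)

    def informative(self) -> list[np.ndarray]:
        """Strata contributing to the conditional inference: both rows and
        both case margins nonzero-variance (no empty margin)."""
        keep = []
        for t in self.strata:
            r, s = t[0].sum(), t[1].sum()
            m = t[:, 0].sum()
            if r > 0 and s > 0 and 0 < m < r + s:
                keep.append(t)
        return keep


def build_strata(
    case_flags: pd.Series,
    carrier_set: CarrierSet,
    pheno: pd.DataFrame,
    control_ids: list[str],
    age_bin_years: int = 10,
    category: str = "",
) -> StratumTableSet:
    """One 2x2 table per (sex, age bin) with >=1 KO and >=1 control."""
    ph = pheno.set_index("sample_id")
    ko = sorted(carrier_set.homozygous_ids)
    groups = {s: "ko" for s in ko}
    groups.update({s: "ctrl" for s in control_ids})
    if set(ko) & set(control_ids):
        raise ValueError(f"{carrier_set.variant_id}: knockouts overlap controls")
    df = pd.DataFrame(
        {
            "group": pd.Series(groups),
            "case": case_flags.reindex(list(groups)).fillna(False).astype(bool),
            "sex": ph.loc[list(groups), "sex"],
            "age_bin": ((ph.loc[list(groups), "age"] - 18) // age_bin_years).astype(int),
        }
    )
    tables, keys = [], []
    for (sex, ab), grp in df.groupby(["sex", "age_bin"]):
        ko_rows = grp[grp["group"] == "ko"]
        ctrl_rows = grp[grp["group"] == "ctrl"]
        if ko_rows.empty or ctrl_rows.empty:
            continue
        t = np.array(
            [
                [int(ko_rows["case"].sum()), int((~ko_rows["case"]).sum())],
                [int(ctrl_rows["case"].sum()), int((~ctrl_rows["case"]).sum())],
            ]
        )
        tables.append(t)
        keys.append((sex, ab))
    if not tables:
        logger.warning("%s/%s: no stratum with both a KO and a control", carrier_set.variant_id, category)
    return StratumTableSet(
        variant_id=carrier_set.variant_id, category=category, strata=tables, stratum_keys=keys
    )


def _stratum_support(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Support a and log C(r,a) + C(s,m-a) weights for one stratum."""
    r = int(table[0].sum())
    s = int(table[1].sum())
    m = int(table[:, 0].sum())
    lo, hi = max(0, m - s), min(r, m)
    a = np.arange(lo, hi + 1)

    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return a, logc(r, a) + logc(s, m - a)


def _null_distribution(strata: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null (psi=1) distribution of T = sum of KO-case counts."""
    support = np.array([0])
    logpmf = np.array([0.0])
    for t in strata:
        a, lw = _stratum_support(t)
        lw = lw - logsumexp(lw)
        lo = support[0] + a[0]
        hi = support[-1] + a[-1]
        new = np.full(hi - lo + 1, -np.inf)
        for ai, lwi in zip(a, lw):
            seg = slice(support[0] + ai - lo, support[-1] + ai - lo + 1)
            new[seg] = np.logaddexp(new[seg], logpmf + lwi)
        support = np.arange(lo, hi + 1)
        logpmf = new
    return support, np.exp(logpmf)


def conditional_exact_test(strata: list[np.ndarray]) -> float:
    """Two-sided exact p given all strata margins (probability-mass rule)."""
    informative = [t for t in strata if _is_informative(t)]
    if not informative:
        logger.info("no informative stratum; p = 1")
        return 1.0
    t_obs = int(sum(t[0, 0] for t in informative))
    support, pmf = _null_distribution(informative)
    p_obs = pmf[t_obs - support[0]]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def _is_informative(t: np.ndarray) -> bool:
    r, s, m = t[0].sum(), t[1].sum(), t[:, 0].sum()
    return r > 0 and s > 0 and 0 < m < r + s


def _expected_t(log_psi: float, stratum_data) -> float:
    total = 0.0
    for a, lw in stratum_data:
        w = lw + a * log_psi
        w = w - logsumexp(w)
        total += float(np.exp(w) @ a)
    return total


def cmle_common_or(strata: list[np.ndarray], t_obs: int | None = None) -> tuple[float, bool]:
    """Conditional MLE of the common odds ratio psi.

    Solves E_psi[T] = T_obs by bracketed root search on log psi (E[T] is
    strictly increasing in psi, so the root is unique).  Returns
    (estimate, boundary_flag); the estimate is 0.0 or inf when T_obs sits
    on the attainable boundary.
    """
    informative = [t for t in strata if _is_informative(t)]
    if not informative:
        raise ValueError("no informative stratum: common OR is undefined")
    if t_obs is None:
        t_obs = int(sum(t[0, 0] for t in informative))
    data = [_stratum_support(t) for t in informative]
    t_min = int(sum(a[0] for a, _ in data))
    t_max = int(sum(a[-1] for a, _ in data))
    if t_obs <= t_min:
        return 0.0, True
    if t_obs >= t_max:
        return float("inf"), True

    def f(log_psi):
        return _expected_t(log_psi, data) - t_obs

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2
        if lo < -700:
            return 0.0, True
    while f(hi) < 0:
        hi *= 2
        if hi > 700:
            return float("inf"), True
    root = brentq(f, lo, hi, xtol=1e-8, rtol=1e-12)
    return float(np.exp(root)), False


@dataclass
class DiseaseAssociationRecord:
    variant_id: str
    category: str
    cmle_or: float
    p_value: float
    n_cases: int
    n_ko: int
    significant: bool
    boundary: bool = False


def disease_scan(
    case_table: pd.DataFrame,
    carrier_sets: dict[str, CarrierSet],
    pheno: pd.DataFrame,
    control_ids: list[str],
    alpha: float = 0.05,
    age_bin_years: int = 10,
    min_cases: int = 5,
    min_ko: int = 2,
) -> tuple[list[DiseaseAssociationRecord], float]:
    """Stratified exact scan over surviving (variant, category) pairs.

    The Bonferroni threshold is alpha / (surviving categories x surviving
    variants).  Returns (records sorted by p, threshold).
    """
    categories, variants = apply_exclusions(case_table, carrier_sets, min_cases, min_ko)
    if not categories or not variants:
        return [], float("nan")
    threshold = alpha / (len(categories) * len(variants))
    records = []
    for vid in variants:
        cs = carrier_sets[vid]
        for cat in categories:
            sts = build_strata(
                case_table[cat], cs, pheno, control_ids, age_bin_years, category=cat
            )
            informative = [t for t in sts.strata if _is_informative(t)]
            if not informative:
                continue
            p = conditional_exact_test(informative)
            psi, boundary = cmle_common_or(informative)
            records.append(
                DiseaseAssociationRecord(
                    variant_id=vid,
                    category=cat,
                    cmle_or=psi,
                    p_value=p,
                    n_cases=int(case_table[cat].sum()),
                    n_ko=len(cs.homozygous_ids),
                    significant=p < threshold,
                    boundary=boundary,
                )
            )
    records.sort(key=lambda r: (r.p_value, r.variant_id, r.category))
    return records, threshold
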