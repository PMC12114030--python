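"""Effective tests, thresholds, outlier counts, missingness test, scan."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from komet import CohortConfig, VariantSpec, generate_cohort, preprocess_metabolites
from komet.association import (
    count_3sd_outliers,
    effective_tests,
    missingness_test,
    run_association_scan,
    significance_threshold,
)
from komet.selection import CarrierSet, carriers_from_dosage


def test_effective_tests_dominant_component(rng):
    u = rng.standard_normal(50)
    v = rng.standard_normal(6)
    X = np.outer(u, v)
    X += 1e-6 * np.linalg.norm(X) * rng.standard_normal(X.shape) / np.sqrt(X.size)
    m = pd.DataFrame(X)
    assert effective_tests(m, 0.90) == 1


def test_effective_tests_matches_eigendecomposition(rng):
    X = rng.standard_normal((30, 8))
    m = pd.DataFrame(X)
    Xc = X - X.mean(axis=0)
    ev = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
    cum = np.cumsum(ev) / ev.sum()
    for vf in (0.5, 0.75, 0.9, 0.99):
        want = int(np.searchsorted(cum, vf - 1e-12) + 1)
        assert effective_tests(m, vf) == want


def test_effective_tests_rank_and_monotonicity(rng):
    X = rng.standard_normal((20, 5))
    X[:, 4] = X[:, 0] + X[:, 1]  # rank 4
    m = pd.DataFrame(X)
    assert effective_tests(m, 1.0) == 4
    ks = [effective_tests(m, vf) for vf in (0.99, 0.9, 0.7, 0.5, 0.3)]
    assert all(a >= b for a, b in zip(ks, ks[1:]))
    with pytest.raises(ValueError):
        effective_tests(m, 1.5)


def test_significance_threshold_printed_roundings():
    t1 = significance_threshold(0.05, 368, 152)
    assert t1.threshold == pytest.approx(8.9388e-7, rel=1e-4)
    assert f"{t1.threshold:.0e}" == "9e-07"
    t2 = significance_threshold(0.05, 588, 123)
    assert t2.threshold == pytest.approx(6.9133e-7, rel=1e-4)
    assert f"{t2.threshold:.0e}" == "7e-07"
    assert significance_threshold(0.05, 1, 1).threshold == pytest.approx(0.05)
    with pytest.raises(ValueError):
        significance_threshold(0.0, 10, 10)


def test_count_3sd_outliers(rng):
    controls = rng.standard_normal(300)
    assert count_3sd_outliers([5.0, 4.0, 3.5], controls) == 3
    assert count_3sd_outliers([float(controls.mean())], controls) == 0
    with pytest.raises(ValueError):
        count_3sd_outliers([1.0], [])
    # zero control SD: every carrier off the control value counts
    assert count_3sd_outliers([1.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1


def test_outlier_count_for_large_injected_effect(rng):
    """Normal tail arithmetic for a beta=5 shift with 6 knockouts: each KO
    exceeds 3 control SDs with probability Phi(2) ~ 0.977, so all six do in
    Phi(2)^6 ~ 87% of replicates and at least five in ~99.4%."""
    from scipy.stats import norm

    all6 = at_least5 = 0
    reps = 200
    for _ in range(reps):
        controls = rng.standard_normal(258)
        k = count_3sd_outliers(rng.standard_normal(6) + 5.0, controls)
        all6 += k == 6
        at_least5 += k >= 5
    p1 = norm.cdf(2.0) ** 6
    p5 = p1 + 6 * norm.cdf(2.0) ** 5 * norm.sf(2.0)
    assert abs(all6 / reps - p1) < 3 * np.sqrt(p1 * (1 - p1) / reps) + 0.02
    assert at_least5 / reps > p5 - 3 * np.sqrt(p5 * (1 - p5) / reps) - 0.01


def test_missingness_fisher_matches_printed_value():
    ko = np.zeros(10, dtype=bool)  # all 10 knockouts missing
    other = np.concatenate([np.zeros(61, bool), np.ones(910, bool)])
    p = missingness_test(ko, other)
    assert f"{p:.0e}" == "2e-12"


def test_missingness_degenerate_and_balanced_tables():
    assert missingness_test(np.ones(5, bool), np.ones(9, bool)) == 1.0
    p = missingness_test(
        np.array([True] * 5 + [False] * 5), np.array([True] * 5 + [False] * 5)
    )
    assert p >= 0.5


def test_missingness_matches_hypergeometric_summation(rng):
    """Brute-force tail over all tables with the observed margins."""
    for _ in range(30):
        ko = rng.random(int(rng.integers(2, 12))) < 0.5
        other = rng.random(int(rng.integers(2, 28))) < 0.7
        a = int((~ko).sum())  # KO missing
        m = a + int((~other).sum())  # total missing
        n1, n2 = ko.size, other.size
        total = comb(n1 + n2, m)
        tail = sum(
            comb(n1, x) * comb(n2, m - x)
            for x in range(a, min(n1, m) + 1)
            if 0 <= m - x <= n2
        )
        if m == 0 or m == n1 + n2:
            continue
        assert missingness_test(ko, other) == pytest.approx(tail / total, rel=1e-10)


def _residual_frame(rng, samples, n_met=6):
    return pd.DataFrame(
        rng.standard_normal((len(samples), n_met)),
        index=samples,
        columns=[f"M{i}" for i in range(n_met)],
    )


def test_scan_orders_flags_and_validates(rng):
    samples = [f"s{i}" for i in range(50)]
    resid = _residual_frame(rng, samples)
    resid.loc["s0", "M0"] = np.nan
    carriers = {"v1": CarrierSet("v1", {"s0", "s1", "s2"})}
    controls = samples[10:]
    spec = significance_threshold(0.05, 6, 1)
    recs = run_association_scan(resid, carriers, controls, spec)
    assert [r.p_value for r in recs] == sorted(r.p_value for r in recs)
    # a missingness record accompanies the pair with a missing value
    m0 = [r for r in recs if r.metabolite_id == "M0"][0]
    assert m0.missingness_p is not None and m0.n_carriers == 2
    with pytest.raises(KeyError, match="sX"):
        run_association_scan(
            resid, {"v": CarrierSet("v", {"sX"})}, controls, spec
        )
    with pytest.raises(ValueError, match="overlap"):
        run_association_scan(
            resid, {"v": CarrierSet("v", {controls[0]})}, controls, spec
        )


def test_scan_invariant_under_column_permutation(rng):
    samples = [f"s{i}" for i in range(40)]
    resid = _residual_frame(rng, samples)
    carriers = {"v1": CarrierSet("v1", {"s0", "s1"})}
    spec = significance_threshold(0.05, 6, 1)
    r1 = run_association_scan(resid, carriers, samples[10:], spec)
    r2 = run_association_scan(
        resid[list(resid.columns[::-1])], carriers, samples[10:], spec
    )
    assert [(r.metabolite_id, r.p_value) for r in r1] == [
        (r.metabolite_id, r.p_value) for r in r2
    ]


def test_null_scan_yields_no_hits_beyond_chance(rng):
    """beta=0 everywhere at a Bonferroni threshold: no significant records."""
    samples = [f"s{i}" for i in range(280)]
    resid = _residual_frame(rng, samples, n_met=40)
    carriers = {
        f"v{j}": CarrierSet(f"v{j}", set(samples[3 * j : 3 * j + 3])) for j in range(5)
    }
    controls = samples[20:]
    spec = significance_threshold(0.05, 40, 5)
    recs = run_association_scan(resid, carriers, controls, spec)
    assert sum(r.significant for r in recs) == 0


def test_missingness_scan_sees_fully_censored_knockouts(rng):
    """A metabolite entirely below LOD in the knockouts never reaches the
    rank test (empty group) but dominates the missingness scan — absence
    itself is the signal."""
    from komet.association import missingness_scan

    samples = [f"s{i}" for i in range(60)]
    resid = _residual_frame(rng, samples, n_met=4)
    ko = ["s0", "s1", "s2", "s3"]
    resid.loc[ko, "M0"] = np.nan  # all knockouts under the detection limit
    carriers = {"v1": CarrierSet("v1", set(ko))}
    controls = samples[10:]
    spec = significance_threshold(0.05, 4, 1)
    recs = run_association_scan(resid, carriers, controls, spec)
    assert not any(r.metabolite_id == "M0" for r in recs)
    miss = missingness_scan(resid, carriers, controls)
    top = miss[0]
    assert (top.metabolite_id, top.n_ko_missing) == ("M0", 4)
    # oracle: hypergeometric point probability of drawing all 4 missing
    want = 1 / comb(54, 4)
    assert top.p_value == pytest.approx(want, rel=1e-10)


def test_scan_recovers_injected_effect_end_to_end(small_cohort):
    b = small_cohort
    res = preprocess_metabolites(b.abundance, b.phenotypes)
    carriers = carriers_from_dosage(b.genotypes)
    m_eff = effective_tests(res.residuals)
    spec = significance_threshold(0.05, m_eff, len(carriers))
    recs = run_association_scan(res.residuals, carriers, b.control_ids, spec)
    sig = {(r.variant_id, r.metabolite_id) for r in recs if r.significant}
    truth = {
        (e["variant_id"], e["metabolite_id"]) for e in b.truth["metabolite_effects"]
    }
    assert sig == truth
    top = recs[0]
    assert top.direction == "+" and top.n_outliers_3sd == top.n_carriers == 6
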