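"""Mixed-model engine: transform oracle, recovery, LRT behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twinewas.datatypes import TwinCohort
from twinewas.lmm import (
    TwinLMM,
    design_matrix,
    inverse_normal_transform,
    lrt_pvalue,
)


def _twin_cohort(n_mz, n_dz, n_sgl=0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    fam = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n):
            fam += 1
            for k in (1, 2):
                rows.append((f"I{fam:04d}{k}", f"F{fam:04d}", zyg, rng.uniform(30, 80)))
    for _ in range(n_sgl):
        fam += 1
        rows.append((f"I{fam:04d}1", f"F{fam:04d}", "singleton", rng.uniform(30, 80)))
    df = pd.DataFrame(rows, columns=["individual_id", "family_id", "zygosity", "age"]).set_index("individual_id")
    df["sex"] = "F"
    df["chip_id"] = "chip0"
    df["chip_position"] = 1
    df["batch_id"] = "b1"
    return TwinCohort(df)


def _simulate_y(cohort, s2f, s2z, s2e, beta_age=0.0, seed=0):
    rng = np.random.default_rng(seed)
    s = cohort.samples
    fam_codes, fidx = np.unique(s["family_id"], return_inverse=True)
    y = np.sqrt(s2f) * rng.normal(size=len(fam_codes))[fidx]
    mz_fams = {f for f, g in s.groupby("family_id") if (g["zygosity"] == "MZ").all() and len(g) == 2}
    zpair = np.sqrt(s2z) * rng.normal(size=len(fam_codes))
    y = y + np.where(s["family_id"].isin(mz_fams).to_numpy(), zpair[fidx], 0.0)
    y = y + np.sqrt(s2e) * rng.normal(size=len(s))
    return y + beta_age * s["age"].to_numpy()


# ----- inverse normal transform ------------------------------------------


def test_blom_scores_for_three_values():
    out = inverse_normal_transform([1.0, 2.0, 3.0])
    expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert out[1] == 0.0 and out[0] == -out[2]  # symmetric around zero


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(-10_000, 10_000), min_size=4, max_size=40, unique=True))
def test_int_rank_invariance(values):
    """Any strictly monotone transform of the input leaves the output unchanged."""
    x = np.asarray(values, dtype=float) / 100.0
    a = inverse_normal_transform(x)
    b = inverse_normal_transform(np.exp(x / 120.0) + 3 * x)
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_int_moments_ties_and_missing():
    rng = np.random.default_rng(1)
    x = rng.normal(size=100)
    out = inverse_normal_transform(x)
    assert abs(out.mean()) < 0.02 and abs(out.std() - 1) < 0.05
    x2 = np.array([1.0, 1.0, 2.0, np.nan, 3.0])
    out2 = inverse_normal_transform(x2)
    assert np.isnan(out2[3]) and out2[0] == out2[1]
    assert np.isnan(inverse_normal_transform([2.0, 2.0, 2.0])).all()


# ----- fitting ------------------------------------------------------------


def test_variance_component_recovery():
    cohort = _twin_cohort(200, 200)
    y = _simulate_y(cohort, s2f=0.5, s2z=0.3, s2e=1.0, seed=3)
    ids = list(cohort.samples.index)
    eng = TwinLMM(cohort, ids)
    X = design_matrix(cohort, ids, chip=False, chip_order=False)
    res = eng.fit(y, X)
    assert abs(res.sigma2_f - 0.5) < 0.1
    assert abs(res.sigma2_z - 0.3) < 0.15
    assert abs(res.sigma2_e - 1.0) < 0.1
    assert res.converged


def test_zero_variance_limit_matches_ols():
    """With no true random-effect variance the fit collapses towards OLS.

    For an all-singleton cohort V is proportional to the identity for
    any family-variance ratio, so the match is exact; for a twin cohort
    the boundary MLE keeps the estimates near zero and the fixed
    effects close to OLS (not exactly: a finite sample can support a
    small positive within-pair covariance)."""
    cohort_s = _twin_cohort(0, 0, 60)
    ids = list(cohort_s.samples.index)
    rng = np.random.default_rng(5)
    X = design_matrix(cohort_s, ids, terms={"age": cohort_s.samples["age"]}, chip=False, chip_order=False)
    y = 2.0 + 0.01 * cohort_s.samples["age"].to_numpy() + rng.normal(size=len(ids))
    res = TwinLMM(cohort_s, ids).fit(y, X)
    ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
    np.testing.assert_allclose(res.beta, ols, atol=1e-6)

    cohort_t = _twin_cohort(30, 30, 10)
    ids = list(cohort_t.samples.index)
    X = design_matrix(cohort_t, ids, terms={"age": cohort_t.samples["age"]}, chip=False, chip_order=False)
    y = 2.0 + 0.01 * cohort_t.samples["age"].to_numpy() + rng.normal(size=len(ids))
    res = TwinLMM(cohort_t, ids).fit(y, X)
    ols = np.linalg.lstsq(X.to_numpy(), y, rcond=None)[0]
    np.testing.assert_allclose(res.beta, ols, atol=0.05)
    assert res.sigma2_f < 0.15 and res.sigma2_z < 0.2


def test_fixed_effect_coverage():
    """Planted slope lies within +-3 SE in ~95% of refits."""
    cohort = _twin_cohort(40, 50, 20)
    ids = list(cohort.samples.index)
    eng = TwinLMM(cohort, ids)
    X = design_matrix(cohort, ids, terms={"age": cohort.samples["age"]}, chip=False, chip_order=False)
    hits = 0
    n_sim = 60
    for s in range(n_sim):
        y = _simulate_y(cohort, 0.4, 0.3, 1.0, beta_age=0.02, seed=100 + s)
        res = eng.fit(y, X)
        b, se = res.coef("age")
        hits += abs(b - 0.02) <= 3 * se
    assert hits >= int(0.9 * n_sim)


def test_against_statsmodels_mixedlm():
    """Independent oracle: statsmodels MixedLM with a family intercept
    (no MZ component in truth) agrees on fixed effects and variance."""
    sm = pytest.importorskip("statsmodels.api")
    cohort = _twin_cohort(0, 80, 20, seed=2)
    ids = list(cohort.samples.index)
    y = _simulate_y(cohort, s2f=0.6, s2z=0.0, s2e=1.0, beta_age=0.02, seed=7)
    X = design_matrix(cohort, ids, terms={"age": cohort.samples["age"]}, chip=False, chip_order=False)
    ours = TwinLMM(cohort, ids).fit(y, X, reml=False)
    data = pd.DataFrame({"y": y, "age": cohort.samples["age"], "fam": cohort.samples["family_id"]})
    md = sm.MixedLM.from_formula("y ~ age", groups="fam", data=data)
    ref = md.fit(reml=False)
    b_ref = float(ref.params["age"])
    b_ours, se_ours = ours.coef("age")
    assert abs(b_ours - b_ref) < 1e-4
    assert abs(ours.sigma2_f - float(ref.cov_re.iloc[0, 0])) < 1e-2
    assert abs(ours.sigma2_e - float(ref.scale)) < 1e-2


def test_lrt_basics():
    assert lrt_pvalue(10.0, 10.0, 1) == 1.0
    assert abs(lrt_pvalue(10.0 + 3.84 / 2, 10.0, 1) - 0.0500) < 5e-4
    assert lrt_pvalue(9.0, 10.0, 1) == 1.0  # statistic floored at zero


def test_lrt_affine_invariance():
    cohort = _twin_cohort(20, 25, 5)
    ids = list(cohort.samples.index)
    eng = TwinLMM(cohort, ids)
    Xf = design_matrix(cohort, ids, terms={"age": cohort.samples["age"]}, chip=False, chip_order=False)
    Xn = Xf.drop(columns=["age"])
    y = _simulate_y(cohort, 0.3, 0.2, 1.0, beta_age=0.01, seed=11)
    r1 = eng.scan_lrt(y[:, None], Xf, Xn, term="age")
    r2 = eng.scan_lrt((7.3 * y - 2.0)[:, None], Xf, Xn, term="age")
    stat1 = 2 * (r1.ll_full[0] - r1.ll_null[0])
    stat2 = 2 * (r2.ll_full[0] - r2.ll_null[0])
    assert abs(stat1 - stat2) < 1e-4


def test_mz_only_aliasing_handled():
    """With MZ pairs only, family vs MZ-pair variance is unidentifiable;
    the family term is absorbed (fixed at zero) and the fit is finite."""
    cohort = _twin_cohort(40, 0)
    ids = list(cohort.samples.index)
    eng = TwinLMM(cohort, ids)
    assert not eng.f_identifiable
    y = _simulate_y(cohort, 0.0, 0.5, 1.0, seed=13)
    res = eng.fit(y, design_matrix(cohort, ids, chip=False, chip_order=False))
    assert np.isfinite(res.loglik)
    assert res.sigma2_f == 0.0
    assert res.sigma2_z > 0.1


def test_rank_deficient_design_drops_aliased_column():
    cohort = _twin_cohort(10, 10)
    ids = list(cohort.samples.index)
    X = design_matrix(cohort, ids, terms={"age": cohort.samples["age"]}, chip=False, chip_order=False)
    X["age_copy"] = X["age"]
    y = _simulate_y(cohort, 0.2, 0.1, 1.0, seed=17)
    with pytest.warns(UserWarning, match="aliased"):
        res = TwinLMM(cohort, ids).fit(y, X)
    assert "age_copy" not in res.names


def test_missing_responses_use_complete_cases():
    cohort = _twin_cohort(25, 25, 10)
    ids = list(cohort.samples.index)
    eng = TwinLMM(cohort, ids)
    X = design_matrix(cohort, ids, chip=False, chip_order=False)
    y = _simulate_y(cohort, 0.3, 0.2, 1.0, seed=19)
    y[3] = np.nan
    res = eng.fit(y, X)
    assert res.n_used == len(ids) - 1
    assert np.isfinite(res.loglik)


def test_too_few_complete_cases_fatal():
    cohort = _twin_cohort(2, 1)
    ids = list(cohort.samples.index)
    X = design_matrix(cohort, ids, terms={"age": cohort.samples["age"]}, chip=False, chip_order=False)
    y = np.full(len(ids), np.nan)
    y[:2] = [1.0, 2.0]
    with pytest.raises(ValueError, match="too few complete cases"):
        TwinLMM(cohort, ids).fit(y, X)
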