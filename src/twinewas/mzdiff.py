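"""Monozygotic within-pair difference analyses (MZ-DMRs).

Within-MZ-pair differences in methylation cancel genotype and shared
family environment, so phenotype-correlated methylation differences
point at environmentally mediated effects.  For each probe, the
methylation within-pair difference is regressed on the phenotype
within-pair difference by ordinary least squares and the overall
regression F-statistic provides the p-value; the age-corrected variant
adds the pair's (shared) age as a covariate and compares against the
null containing phenotype-difference-free terms.  FDR uses permutation
of the phenotype-difference vector across pairs.  A Monte-Carlo power
estimator for the within-pair correlation design accompanies the scan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, PhenotypeTable, TwinCohort
from .fdr import permutation_fdr

__all__ = ["pair_differences", "mz_dmr_scan", "mz_power_estimate", "MIN_COMPLETE_PAIRS"]

#: minimum number of complete pairs for a trait to be analysed
MIN_COMPLETE_PAIRS = 12


def pair_differences(
    m: MethylationMatrix,
    phenos: PhenotypeTable | None,
    cohort: TwinCohort,
    traits: tuple | None = None,
    min_pairs: int = MIN_COMPLETE_PAIRS,
) -> dict:
    """Signed within-MZ-pair differences for methylation and traits.

    Only MZ pairs whose two members were assayed in the same batch are
    used.  Twin ordering is fixed once per pair (lower individual id
    minus higher) and shared across all probes and traits, so flipping
    the order flips every sign coherently.  Traits observed in fewer
    than ``min_pairs`` complete pairs are excluded (and listed in
    ``excluded_traits``).
    """
    samples = cohort.samples
    pairs = [
        (a, b)
        for a, b in cohort.twin_pairs("MZ")
        if samples.loc[a, "batch_id"] == samples.loc[b, "batch_id"]
    ]
    pairs = [
        (a, b) for a, b in pairs if a in set(m.sample_ids) and b in set(m.sample_ids)
    ]
    if not pairs:
        raise ValueError("no eligible MZ pairs (same batch, both assayed)")
    pair_ids = [f"{a}|{b}" for a, b in pairs]
    d_meth = (
        m.betas[[a for a, _ in pairs]].to_numpy(dtype=float)
        - m.betas[[b for _, b in pairs]].to_numpy(dtype=float)
    )
    d_meth = pd.DataFrame(d_meth, index=m.probe_ids, columns=pair_ids)
    age = pd.Series([samples.loc[a, "age"] for a, _ in pairs], index=pair_ids, dtype=float)
    d_pheno = pd.DataFrame(index=pair_ids)
    excluded = []
    if phenos is not None:
        want = traits if traits is not None else list(phenos.values.columns)
        for t in want:
            v = phenos.values[t]
            d = np.array(
                [
                    v.get(a, np.nan) - v.get(b, np.nan)
                    for a, b in pairs
                ],
                dtype=float,
            )
            if np.isfinite(d).sum() >= min_pairs:
                d_pheno[t] = d
            else:
                excluded.append(t)
    return {
        "pairs": pairs,
        "d_meth": d_meth,
        "d_pheno": d_pheno,
        "age": age,
        "excluded_traits": excluded,
    }


def _ols_f_scan(Y: np.ndarray, X1: np.ndarray, X0: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised nested-OLS F-test: Y (n x P) on X1 vs X0 (X0 nested)."""
    n = Y.shape[0]

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        r = Y - X @ beta
        return np.einsum("ij,ij->j", r, r), np.linalg.matrix_rank(X), beta

    rss1, p1, beta1 = rss(X1)
    rss0, p0, _ = rss(X0)
    df1, df2 = p1 - p0, n - p1
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degenerate F-test degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    pvals = stats.f.sf(F, df1, df2)
    pvals = np.where(rss1 <= 0, np.finfo(float).tiny, pvals)  # perfect fit underflow flag
    return np.maximum(pvals, np.finfo(float).tiny), beta1


def mz_dmr_scan(
    diffs: dict,
    trait: str,
    adjust_age: bool = False,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
    intercept: bool = True,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """MZ-DMR scan: d_meth ~ d_pheno (+ age), overall-regression F p-value.

    Pairs missing the trait difference are dropped probe-wide (complete
    cases).  The permutation FDR shuffles the pairing of the phenotype
    differences against the methylation differences.  Returns (DmrResult
    table, FDR threshold, FDR curve).
    """
    if trait not in diffs["d_pheno"].columns:
        raise ValueError(f"trait {trait!r} not available (fewer than {MIN_COMPLETE_PAIRS} complete pairs?)")
    dp = diffs["d_pheno"][trait].to_numpy(dtype=float)
    ok = np.isfinite(dp)
    if ok.sum() < 3:
        raise ValueError("too few complete pairs")
    dp = dp[ok]
    if np.std(dp) == 0:
        raise ValueError(f"zero variance in {trait!r} within-pair differences")
    Y = diffs["d_meth"].to_numpy(dtype=float)[:, ok].T  # pairs x probes
    age = diffs["age"].to_numpy(dtype=float)[ok]
    n = len(dp)
    base = [np.ones(n)] if intercept else []
    if adjust_age:
        base.append(age)
    X0 = np.column_stack(base) if base else np.empty((n, 0))
    X1 = np.column_stack(base + [dp])
    pvals, beta1 = _ols_f_scan(Y, X1, X0)
    res = pd.DataFrame(
        {
            "probe_id": diffs["d_meth"].index,
            "trait": trait,
            "beta": beta1[-1],
            "p": pvals,
            "n_pairs": n,
            "age_adjusted": adjust_age,
        }
    )
    res["direction"] = np.where(res["beta"] >= 0, "hyper", "hypo")
    rng = np.random.default_rng(seed)
    perm_p = []
    for _ in range(n_perm):
        idx = rng.permutation(n)
        Xp = np.column_stack(base + [dp[idx]])
        pp, _ = _ols_f_scan(Y, Xp, X0)
        perm_p.append(pp)
    curve, threshold = permutation_fdr(res["p"].to_numpy(), perm_p, alpha=alpha)
    res["fdr_significant"] = (res["p"] <= threshold) if np.isfinite(threshold) else False
    return res, threshold, curve


def mz_power_estimate(
    r: float,
    n_pairs: int,
    alpha: float,
    n_sim: int = 2000,
    seed: int = 0,
) -> dict:
    """Monte-Carlo power of the within-pair correlation F-test.

    Draws bivariate-normal (methylation difference, phenotype
    difference) pairs at correlation ``r``, applies the same simple-
    regression overall F-test as the scan, and reports the fraction of
    simulations below ``alpha`` with a binomial 95% CI, alongside the
    analytic Fisher-z approximation.
    """
    if not (abs(r) < 1):
        raise ValueError("|r| must be < 1")
    if n_pairs < 3:
        raise ValueError("need at least 3 pairs")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    chol = np.linalg.cholesky(cov)
    hits = 0
    for _ in range(n_sim):
        z = rng.standard_normal((n_pairs, 2)) @ chol.T
        res = stats.linregress(z[:, 1], z[:, 0])
        if res.pvalue < alpha:
            hits += 1
    power = hits / n_sim
    ci = stats.binomtest(hits, n_sim).proportion_ci(0.95)
    # analytic comparison: Fisher z, two-sided
    zr = np.arctanh(r)
    se = 1.0 / np.sqrt(n_pairs - 3)
    zcrit = stats.norm.isf(alpha / 2.0)
    analytic = float(
        stats.norm.sf(zcrit - abs(zr) / se) + stats.norm.cdf(-zcrit - abs(zr) / se)
    )
    return {
        "power": float(power),
        "ci_low": float(ci.low),
        "ci_high": float(ci.high),
        "analytic_fisher_z": analytic,
        "n_sim": int(n_sim),
    }
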