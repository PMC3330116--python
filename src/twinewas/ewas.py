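"""Epigenome-wide association scans for age and age-related phenotypes.

a-DMRs: per probe, raw methylation betas are regressed on chronological
age with chip and chip-order fixed effects and family/zygosity random
effects; the age term is tested by likelihood ratio against the model
without it.  ap-DMRs substitute a phenotype for age and are run both
with and without age adjustment.  Scans can be repeated on
inverse-normal transformed betas; the reported rank concordance between
the raw and normalised runs guards against scale-driven artefacts.

Genome-wide significance uses a twin-structure-preserving permutation:
methylation profiles move between families in blocks (co-twins
together, within strata of family size and zygosity), so twin
correlation, co-methylation and each phenotype's missingness pattern
are all preserved under the null.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, PhenotypeTable, TwinCohort
from .fdr import family_permutation, permutation_fdr
from .lmm import TwinLMM, design_matrix, inverse_normal_transform

__all__ = [
    "scan_dmrs",
    "permutation_fdr_ewas",
    "wbc_association",
    "bonferroni_nominal_threshold",
]


def _trait_values(trait: str, cohort: TwinCohort, phenos: PhenotypeTable | None) -> pd.Series:
    if trait == "age":
        return cohort.samples["age"].astype(float)
    if phenos is None or trait not in phenos.values.columns:
        raise ValueError(f"unknown trait {trait!r}")
    return phenos.values[trait].astype(float)


def scan_dmrs(
    m: MethylationMatrix,
    cohort: TwinCohort,
    trait: str = "age",
    phenos: PhenotypeTable | None = None,
    adjust_age: bool = False,
    raw_scale: bool = True,
    sample_permutation: dict | None = None,
) -> pd.DataFrame:
    """Per-probe twin-LMM EWAS of ``trait`` ("age" or a phenotype name).

    Returns a DmrResult table: probe_id, trait, beta, se, p (LRT),
    direction (hyper/hypo by the sign of beta), n_used, convergence.
    ``raw_scale=False`` applies the inverse-normal transform per probe
    first.  ``sample_permutation`` maps each individual to the
    methylation-profile donor (the permutation null).
    """
    ids = [s for s in cohort.individual_ids if s in set(m.sample_ids)]
    tvals = _trait_values(trait, cohort, phenos).loc[ids]
    if tvals.nunique(dropna=True) <= 1:
        raise ValueError(f"trait {trait!r} is constant in the analysed samples")
    keep = [s for s in ids if np.isfinite(tvals.loc[s])]
    sub_cohort = cohort.subset(keep)
    eng = TwinLMM(sub_cohort, keep)
    terms: dict = {}
    if adjust_age and trait != "age":
        terms["age"] = cohort.samples["age"].astype(float)
    terms[trait] = tvals
    X_full = design_matrix(cohort, keep, terms=terms)
    X_null = X_full.drop(columns=[trait])
    donors = [sample_permutation.get(s, s) if sample_permutation else s for s in keep]
    Y = m.betas.loc[:, donors].to_numpy(dtype=float).T  # samples x probes
    if not raw_scale:
        Y = np.apply_along_axis(inverse_normal_transform, 0, Y)
    res = eng.scan_lrt(Y, X_full, X_null, term=trait)
    res.insert(0, "probe_id", list(m.probe_ids))
    res.insert(1, "trait", trait)
    res["direction"] = np.where(res["beta"] >= 0, "hyper", "hypo")
    res["age_adjusted"] = bool(adjust_age and trait != "age")
    return res


def permutation_fdr_ewas(
    observed: pd.DataFrame,
    m: MethylationMatrix,
    cohort: TwinCohort,
    trait: str = "age",
    phenos: PhenotypeTable | None = None,
    adjust_age: bool = False,
    raw_scale: bool = True,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Family-block permutation FDR for an EWAS scan.

    Each replicate reassigns methylation profiles among families within
    (size, zygosity) strata and rescans; FDR(t) is the mean permuted hit
    count over observed hits.  Returns (curve, threshold, observed table
    with ``fdr_significant``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perm_p = []
    for _ in range(n_perm):
        mapping = family_permutation(cohort, rng)
        res = scan_dmrs(
            m,
            cohort,
            trait,
            phenos,
            adjust_age=adjust_age,
            raw_scale=raw_scale,
            sample_permutation=mapping,
        )
        perm_p.append(res["p"].to_numpy())
    curve, threshold = permutation_fdr(observed["p"].to_numpy(), perm_p, alpha=alpha)
    out = observed.copy()
    out["fdr_significant"] = (out["p"] <= threshold) if np.isfinite(threshold) else False
    return curve, threshold, out


def bonferroni_nominal_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni nominal per-test threshold alpha/n.

    Returns (exact value, value rounded to one significant figure — the
    printed form).
    """
    if n_tests <= 0:
        raise ValueError("n_tests must be positive")
    exact = alpha / n_tests
    mag = 10.0 ** np.floor(np.log10(exact))
    printed = float(np.round(exact / mag) * mag)
    return float(exact), printed


def wbc_association(
    dmr_probes,
    m: MethylationMatrix,
    cohort: TwinCohort,
    wbc: pd.DataFrame,
    cell_types: tuple = ("neutrophils", "eosinophils", "monocytes", "lymphocytes"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Association of methylation with WBC sub-type counts at DMR probes.

    Per (probe, cell type): twin LMM of methylation on the cell count
    with chip/order covariates; the Bonferroni nominal threshold is
    alpha divided by the number of DMR probes tested.  Returns
    (association table, summary with the exact and one-significant-
    figure thresholds).
    """
    probes = [p for p in dmr_probes if p in set(m.probe_ids)]
    if len(probes) == 0:
        return (
            pd.DataFrame(columns=["probe_id", "cell_type", "beta", "se", "p", "significant"]),
            {"n_probes": 0, "threshold_exact": float("nan"), "threshold_printed": float("nan")},
        )
    exact, printed = bonferroni_nominal_threshold(len(probes), alpha)
    ids = [s for s in cohort.individual_ids if s in set(m.sample_ids) and s in wbc.index]
    recs = []
    for cell in cell_types:
        if cell not in wbc.columns:
            warnings.warn(f"cell type {cell!r} missing from WBC table; skipped")
            continue
        counts = wbc.loc[ids, cell].astype(float)
        keep = [s for s in ids if np.isfinite(counts.loc[s])]
        sub_cohort = cohort.subset(keep)
        eng = TwinLMM(sub_cohort, keep)
        X_full = design_matrix(cohort, keep, terms={cell: counts})
        X_null = X_full.drop(columns=[cell])
        Y = m.betas.loc[probes, keep].to_numpy(dtype=float).T
        res = eng.scan_lrt(Y, X_full, X_null, term=cell)
        for pid, row in zip(probes, res.itertuples()):
            recs.append((pid, cell, row.beta, row.se, row.p, row.p <= exact))
    table = pd.DataFrame(recs, columns=["probe_id", "cell_type", "beta", "se", "p", "significant"])
    summary = {
        "n_probes": len(probes),
        "threshold_exact": exact,
        "threshold_printed": printed,
        "n_significant": int(table["significant"].sum()),
    }
    return table, summary
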