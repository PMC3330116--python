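"""Cis-meQTL mapping with permutation-based FDR.

For every (probe, SNP) pair with the SNP inside the cis window
(default 100 kb either side of the CpG), methylation — inverse-normal
transformed per probe — is regressed on additive dosage with chip and
chip-order fixed effects and the twin random-effect structure; the
genotype term is tested by likelihood ratio.  FDR is estimated by
permuting methylation sample labels against the genotypes (one label
permutation per replicate, all probes moved together so co-methylation
is preserved) and collecting the best SNP per probe per replicate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, MethylationMatrix, TwinCohort
from .fdr import permutation_fdr
from .lmm import TwinLMM, design_matrix, inverse_normal_transform

__all__ = ["cis_pairs", "scan_meqtls", "permutation_fdr_meqtl", "best_snp_per_probe"]


def cis_pairs(
    annotation: pd.DataFrame,
    genos: GenotypeMatrix,
    window: int = 100_000,
) -> tuple[pd.DataFrame, dict]:
    """All (probe, SNP) pairs with |pos_snp - pos_cpg| <= window, same chromosome.

    Positions are 1-based points; the boundary is inclusive, so a SNP at
    exactly ``window`` bp is tested and one at ``window`` + 1 bp is not.
    Returns (pair table with signed distance snp - cpg, report counting
    probes without any cis SNP).
    """
    if window <= 0:
        raise ValueError("cis window must be positive")
    snp = genos.snp_map.reset_index().rename(columns={genos.snp_map.index.name or "index": "snp_id"})
    out = []
    for chrom, probes in annotation.groupby("chrom", sort=True):
        s = snp[snp["chrom"].astype(str) == str(chrom)].sort_values("pos")
        if s.empty:
            continue
        spos = s["pos"].to_numpy()
        for pid, row in probes.iterrows():
            lo = np.searchsorted(spos, row["pos"] - window, side="left")
            hi = np.searchsorted(spos, row["pos"] + window, side="right")
            for k in range(lo, hi):
                out.append((pid, s["snp_id"].iloc[k], int(spos[k] - row["pos"])))
    pairs = pd.DataFrame(out, columns=["probe_id", "snp_id", "distance"])
    tested = pairs["probe_id"].nunique()
    report = {
        "n_probes_in": int(len(annotation)),
        "n_probes_tested": int(tested),
        "n_probes_no_cis_snp": int(len(annotation) - tested),
        "n_pairs": int(len(pairs)),
        "window": int(window),
    }
    return pairs, report


def _aligned_samples(m: MethylationMatrix, genos: GenotypeMatrix, cohort: TwinCohort) -> list:
    shared = [s for s in cohort.individual_ids if s in set(m.sample_ids) and s in set(genos.sample_ids)]
    return shared


def scan_meqtls(
    pairs: pd.DataFrame,
    m: MethylationMatrix,
    genos: GenotypeMatrix,
    cohort: TwinCohort,
    normalize: bool = True,
    sample_permutation: dict | None = None,
) -> pd.DataFrame:
    """Twin-LMM association for every cis pair.

    Methylation is inverse-normal transformed per probe (the scan's
    precondition); the LRT compares chip+order+genotype against
    chip+order.  Monomorphic SNPs in the analysed subset are skipped and
    counted in the ``skipped`` attribute of the result.

    ``sample_permutation`` (methylation-donor mapping) implements the
    permutation null: each individual keeps genotype/covariates but
    receives another individual's methylation profile.
    """
    ids = _aligned_samples(m, genos, cohort)
    if len(ids) < 10:
        raise ValueError("too few samples shared by methylation and genotypes")
    meth_source = [sample_permutation.get(s, s) if sample_permutation else s for s in ids]
    sub_cohort = cohort.subset(ids)
    eng = TwinLMM(sub_cohort, ids)
    base = design_matrix(cohort, ids)
    Xn = base.to_numpy(dtype=float)
    probe_list = pairs["probe_id"].unique()
    B = m.betas.loc[probe_list, meth_source].to_numpy(dtype=float)
    if normalize:
        B = np.apply_along_axis(inverse_normal_transform, 1, B)
    probe_ix = {p: i for i, p in enumerate(probe_list)}
    usable = ~np.isnan(B).all(axis=1)

    # one batched null fit per probe (design shared by all probes)
    Y = B.T  # samples x probes
    comp_n = eng._components(Xn, Y)
    bn, cn, ll_null, _ = eng._optimise(comp_n)

    dos = genos.dosages.loc[:, ids]
    n, p_full = len(ids), Xn.shape[1] + 1
    recs = []
    skipped = 0
    for snp_id, grp in pairs.groupby("snp_id", sort=True):
        d = dos.loc[snp_id].to_numpy(dtype=float)
        if np.nanstd(d) == 0:
            skipped += len(grp)
            continue
        Xf = np.column_stack([Xn, d])
        pidx = [probe_ix[p] for p in grp["probe_id"]]
        ok = [i for i in pidx if usable[i]]
        if not ok:
            skipped += len(grp)
            continue
        comp_f = eng._components(Xf, Y[:, ok])
        bf, cf, ll_full, _ = eng._optimise(comp_f, init_bc=(bn[ok], cn[ok]))
        llf, beta, A, s2 = eng._ll_at(comp_f, bf, cf, want_fit=True)
        Ainv = np.linalg.pinv(A)
        se = np.sqrt(np.maximum(s2 * Ainv[:, -1, -1], 0.0))
        for j, i in enumerate(ok):
            stat = max(2.0 * (ll_full[j] - ll_null[i]), 0.0) * (n - p_full) / n
            recs.append(
                (
                    probe_list[i],
                    snp_id,
                    int(grp.loc[grp["probe_id"] == probe_list[i], "distance"].iloc[0]),
                    float(beta[j, -1]),
                    float(se[j]),
                    float(stats.chi2.sf(stat, 1)),
                )
            )
    res = pd.DataFrame(recs, columns=["probe_id", "snp_id", "distance", "beta", "se", "p"])
    res = best_snp_per_probe(res)
    res.attrs["skipped"] = skipped
    res.attrs["n_samples"] = len(ids)
    return res


def best_snp_per_probe(res: pd.DataFrame) -> pd.DataFrame:
    """Flag the top SNP per probe (smallest p, ties by |distance|, then id)."""
    res = res.copy()
    if res.empty:
        res["is_best_per_probe"] = pd.Series(dtype=bool)
        return res
    ranked = res.assign(absd=res["distance"].abs()).sort_values(
        ["probe_id", "p", "absd", "snp_id"]
    )
    best = ranked.groupby("probe_id", sort=False).head(1).index
    res["is_best_per_probe"] = res.index.isin(best)
    return res


def permutation_fdr_meqtl(
    observed: pd.DataFrame,
    pairs: pd.DataFrame,
    m: MethylationMatrix,
    genos: GenotypeMatrix,
    cohort: TwinCohort,
    n_perm: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float, pd.DataFrame]:
    """Permutation FDR for the cis scan on best-SNP-per-probe p-values.

    Each replicate shuffles the methylation sample labels against
    genotypes (whole columns move together, preserving co-methylation
    and ignoring twin structure — it is the genotype-methylation pairing
    that the null breaks), rescans, and keeps the most associated SNP
    per probe.  Returns (FDR curve, 5% threshold, observed table with
    the ``fdr_significant`` flag on best-per-probe rows).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = _aligned_samples(m, genos, cohort)
    rng = np.random.default_rng(seed)
    obs_best = observed.loc[observed["is_best_per_probe"], "p"].to_numpy()
    perm_best = []
    for _ in range(n_perm):
        perm_ids = list(rng.permutation(ids))
        mapping = dict(zip(ids, perm_ids))
        res = scan_meqtls(pairs, m, genos, cohort, sample_permutation=mapping)
        perm_best.append(res.loc[res["is_best_per_probe"], "p"].to_numpy())
    curve, threshold = permutation_fdr(obs_best, perm_best, alpha=alpha)
    out = observed.copy()
    out["fdr_significant"] = (out["p"] <= threshold) if np.isfinite(threshold) else False
    return curve, threshold, out
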