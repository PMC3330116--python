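"""Genotype-methylation-phenotype mediation overlap.

The mediation screen asks whether SNPs that drive methylation in cis
(cis-meQTLs) also associate with an age-related phenotype, while the
same CpG associates with the same phenotype (an ap-DMR signal) — the
pattern expected if methylation mediates a genotype-phenotype
association.  It is a set-overlap procedure, not a formal mediation
decomposition:

1. cis-meQTL (probe, SNP) pairs at the scan's FDR threshold;
2. of those SNPs, the ones with suggestive GWAS evidence (P <= 0.001)
   for one of the 12 quantitative phenotypes;
3. of those probes, the ones with suggestive ap-DMR evidence
   (P <= 0.01) for the *same* phenotype.

The expected overlap under "methylation mediates nothing" is obtained
by permuting the methylation data only (family-block permutation that
preserves twin structure and co-methylation), re-running the cis scan,
taking the top-k probes (k = the observed meQTL probe count, ranked by
best cis p-value, ties by probe id), and re-assessing the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, MethylationMatrix, PhenotypeTable, TwinCohort
from .fdr import family_permutation
from .lmm import TwinLMM, design_matrix
from .simulate import GWAS_TRAITS

__all__ = ["gwas_scan", "threeway_overlap", "permuted_overlap_null", "OverlapReport"]


@dataclass
class OverlapReport:
    """Stage counts of the three-way overlap."""

    n_meqtl_probes: int
    n_meqtl_snps: int
    n_snps_also_gwas: int
    n_probes_of_those: int
    n_probes_threeway: int
    n_snps_threeway: int
    per_trait: dict = field(default_factory=dict)

    @property
    def percent_threeway(self) -> float:
        """100 x three-way probes / meQTL probes."""
        if self.n_meqtl_probes == 0:
            return float("nan")
        return 100.0 * self.n_probes_threeway / self.n_meqtl_probes

    def validate(self) -> None:
        if not (self.n_probes_threeway <= self.n_probes_of_those <= self.n_meqtl_probes):
            raise ValueError("overlap stage counts must shrink monotonically")


def gwas_scan(
    phenos: PhenotypeTable,
    genos: GenotypeMatrix,
    cohort: TwinCohort,
    trait: str,
    suggestive_p: float = 0.001,
) -> pd.DataFrame:
    """Additive-model twin-LMM GWAS of one quantitative phenotype.

    The model mirrors the cis scan with phenotype substituted for
    methylation: trait ~ dosage + chip + order with family/zygosity
    random effects.  Only the 12 quantitative age-related phenotypes
    are eligible; monomorphic SNPs are skipped and counted.
    """
    if trait not in GWAS_TRAITS:
        raise ValueError(
            f"trait {trait!r} is not among the 12 GWAS phenotypes {GWAS_TRAITS}"
        )
    ids = [
        s
        for s in cohort.individual_ids
        if s in set(genos.sample_ids) and np.isfinite(phenos.values[trait].get(s, np.nan))
    ]
    if len(ids) < 10:
        raise ValueError("too few samples with phenotype and genotypes")
    sub_cohort = cohort.subset(ids)
    eng = TwinLMM(sub_cohort, ids)
    y = phenos.values[trait].loc[ids].to_numpy(dtype=float)
    base = design_matrix(cohort, ids)
    Xn = base.to_numpy(dtype=float)
    n = len(ids)
    comp_n = eng._components(Xn, y[:, None])
    bn, cn, ll_null, _ = eng._optimise(comp_n)
    dos = genos.dosages.loc[:, ids]
    p_full = Xn.shape[1] + 1
    recs, skipped = [], 0
    for snp_id in genos.snp_ids:
        d = dos.loc[snp_id].to_numpy(dtype=float)
        if np.nanstd(d) == 0:
            skipped += 1
            continue
        Xf = np.column_stack([Xn, d])
        comp_f = eng._components(Xf, y[:, None])
        bf, cf, llf, _ = eng._optimise(comp_f, init_bc=(bn, cn))
        llv, beta, A, s2 = eng._ll_at(comp_f, bf, cf, want_fit=True)
        se = float(np.sqrt(max(s2[0] * np.linalg.pinv(A[0])[-1, -1], 0.0)))
        stat = max(2.0 * (llf[0] - ll_null[0]), 0.0) * (n - p_full) / n
        recs.append((snp_id, float(beta[0, -1]), se, float(stats.chi2.sf(stat, 1))))
    res = pd.DataFrame(recs, columns=["snp_id", "beta", "se", "p"])
    res["trait"] = trait
    res["suggestive"] = res["p"] <= suggestive_p
    res.attrs["skipped"] = skipped
    res.attrs["n_samples"] = n
    return res


def threeway_overlap(
    meqtls: pd.DataFrame,
    gwas: dict,
    apdmrs: dict,
    p_gwas: float = 0.001,
    p_apdmr: float = 0.01,
) -> tuple[OverlapReport, pd.DataFrame]:
    """Three-way overlap across meQTL, GWAS and ap-DMR results.

    ``meqtls``: significant cis pairs (rows with probe_id, snp_id; e.g.
    the ``fdr_significant`` subset of the cis scan).  ``gwas`` maps
    trait -> per-SNP table (snp_id, p); ``apdmrs`` maps trait ->
    per-probe table (probe_id, p).  A probe is three-way if one of its
    cis-meQTL SNPs is GWAS-suggestive for a trait for which the probe is
    also ap-DMR-suggestive.
    """
    if set(gwas) != set(apdmrs):
        raise ValueError(
            f"trait mismatch between GWAS ({sorted(gwas)}) and ap-DMR ({sorted(apdmrs)}) tables"
        )
    probes = set(meqtls["probe_id"])
    snps = set(meqtls["snp_id"])
    sugg_snps: dict = {}
    sugg_probes: dict = {}
    for t in gwas:
        g = gwas[t]
        sugg_snps[t] = set(g.loc[g["p"] <= p_gwas, "snp_id"]) & snps
        a = apdmrs[t]
        sugg_probes[t] = set(a.loc[a["p"] <= p_apdmr, "probe_id"]) & probes
    snps_also_gwas = set().union(*sugg_snps.values()) if sugg_snps else set()
    probes_of_those = set(
        meqtls.loc[meqtls["snp_id"].isin(snps_also_gwas), "probe_id"]
    )
    rows = []
    threeway_probes: set = set()
    threeway_snps: set = set()
    per_trait = {}
    for t in gwas:
        sub = meqtls[meqtls["snp_id"].isin(sugg_snps[t]) & meqtls["probe_id"].isin(sugg_probes[t])]
        per_trait[t] = {
            "n_probes": int(sub["probe_id"].nunique()),
            "n_snps": int(sub["snp_id"].nunique()),
        }
        threeway_probes |= set(sub["probe_id"])
        threeway_snps |= set(sub["snp_id"])
        for _, r in sub.iterrows():
            rows.append((r["probe_id"], r["snp_id"], t))
    report = OverlapReport(
        n_meqtl_probes=int(len(probes)),
        n_meqtl_snps=int(len(snps)),
        n_snps_also_gwas=int(len(snps_also_gwas)),
        n_probes_of_those=int(len(probes_of_those)),
        n_probes_threeway=int(len(threeway_probes)),
        n_snps_threeway=int(len(threeway_snps)),
        per_trait=per_trait,
    )
    report.validate()
    detail = pd.DataFrame(rows, columns=["probe_id", "snp_id", "trait"])
    return report, detail


def permuted_overlap_null(
    pairs: pd.DataFrame,
    m: MethylationMatrix,
    genos: GenotypeMatrix,
    phenos: PhenotypeTable,
    cohort: TwinCohort,
    gwas: dict,
    n_top: int,
    n_perm: int = 2,
    seed: int = 0,
    p_gwas: float = 0.001,
    p_apdmr: float = 0.01,
    traits: tuple | None = None,
) -> dict:
    """Null three-way overlap from methylation-only permutations.

    Per replicate: family-preserving methylation permutation, cis scan
    rerun, the top ``n_top`` probes by best cis p-value taken as the
    permuted meQTL set, ap-DMR suggestive evidence recomputed on the
    permuted methylation, and the overlap re-assessed against the
    *unchanged* GWAS tables.  Returns mean probe count and percent.
    """
    from .ewas import scan_dmrs
    from .meqtl import scan_meqtls

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    traits = tuple(traits if traits is not None else gwas.keys())
    rng = np.random.default_rng(seed)
    null_counts, null_pcts = [], []
    for _ in range(n_perm):
        mapping = family_permutation(cohort, rng)
        res = scan_meqtls(pairs, m, genos, cohort, sample_permutation=mapping)
        best = res[res["is_best_per_probe"]].sort_values(["p", "probe_id"]).head(n_top)
        top_probes = set(best["probe_id"])
        pseudo_sig = res[res["probe_id"].isin(top_probes)]
        apdmrs = {
            t: scan_dmrs(m, cohort, t, phenos, sample_permutation=mapping)
            for t in traits
        }
        report, _ = threeway_overlap(
            pseudo_sig, {t: gwas[t] for t in traits}, apdmrs, p_gwas=p_gwas, p_apdmr=p_apdmr
        )
        null_counts.append(report.n_probes_threeway)
        null_pcts.append(
            100.0 * report.n_probes_threeway / n_top if n_top else float("nan")
        )
    return {
        "mean_null_probes": float(np.mean(null_counts)),
        "mean_null_percent": float(np.mean(null_pcts)),
        "replicates": null_counts,
        "n_top": int(n_top),
        "n_perm": int(n_perm),
    }
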