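#!/usr/bin/env python
"""Genotype-methylation-phenotype mediation overlap.

GWAS for the quantitative phenotypes, then the three-way overlap:
cis-meQTL SNPs that are GWAS-suggestive (P <= 0.001) for a trait whose
CpG is also ap-DMR-suggestive (P <= 0.01) for the same trait.  The
expected overlap under no mediation comes from two methylation-only
family-block permutations.
"""

import json
from pathlib import Path

from twinewas.ewas import scan_dmrs
from twinewas.io_qc import read_dataset
from twinewas.meqtl import cis_pairs, permutation_fdr_meqtl, scan_meqtls
from twinewas.overlap import gwas_scan, permuted_overlap_null, threeway_overlap
from twinewas.simulate import GWAS_TRAITS

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    d = ROOT / "data"
    paths = {k: d / f"{k}.tsv" for k in ("methylation", "annotation", "samples", "dosages", "snp_map", "phenotypes", "truth")}
    b = read_dataset(paths)

    pairs, _ = cis_pairs(b.methylation.annotation, b.genotypes)
    res = scan_meqtls(pairs, b.methylation, b.genotypes, b.cohort)
    _, thr, res = permutation_fdr_meqtl(res, pairs, b.methylation, b.genotypes, b.cohort, n_perm=10, seed=6)
    sig = res[res["fdr_significant"]]
    print(f"meQTL stage: {sig['probe_id'].nunique()} probes / {sig['snp_id'].nunique()} SNPs at FDR 5%")

    traits = [t for t in GWAS_TRAITS if t in b.phenotypes.values.columns]
    gwas = {t: gwas_scan(b.phenotypes, b.genotypes, b.cohort, t) for t in traits}
    apdmrs = {t: scan_dmrs(b.methylation, b.cohort, t, b.phenotypes) for t in traits}
    report, detail = threeway_overlap(sig, gwas, apdmrs)
    detail.to_csv(ROOT / "threeway_pairs.tsv", sep="\t", index=False)
    print(
        f"three-way overlap: {report.n_probes_threeway} probes "
        f"({report.percent_threeway:.2f}% of {report.n_meqtl_probes} meQTL probes), "
        f"{report.n_snps_threeway} SNPs"
    )

    null = permuted_overlap_null(
        pairs, b.methylation, b.genotypes, b.phenotypes, b.cohort, gwas,
        n_top=max(report.n_meqtl_probes, 1), n_perm=2, seed=6,
    )
    print(f"permuted null: mean {null['mean_null_probes']:.1f} probes ({null['mean_null_percent']:.2f}%)")
    with open(ROOT / "overlap_report.json", "w") as fh:
        json.dump(
            {
                "n_meqtl_probes": report.n_meqtl_probes,
                "n_meqtl_snps": report.n_meqtl_snps,
                "n_snps_also_gwas": report.n_snps_also_gwas,
                "n_probes_of_those": report.n_probes_of_those,
                "n_probes_threeway": report.n_probes_threeway,
                "n_snps_threeway": report.n_snps_threeway,
                "percent_threeway": report.percent_threeway,
                "per_trait": report.per_trait,
                "null": null,
            },
            fh,
            indent=2,
        )


if __name__ == "__main__":
    main()
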