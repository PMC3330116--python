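#!/usr/bin/env python
"""Cis-meQTL scan (100 kb window) with 10-permutation FDR.

Reports the number of probes with cis-meQTLs at FDR 5%, the p-value
threshold that level corresponds to, and the percent of tested probes
carrying a cis-meQTL.
"""

from pathlib import Path

from twinewas.io_qc import read_dataset
from twinewas.meqtl import cis_pairs, permutation_fdr_meqtl, scan_meqtls
from twinewas.util import percent

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    d = ROOT / "data"
    paths = {k: d / f"{k}.tsv" for k in ("methylation", "annotation", "samples", "dosages", "snp_map", "truth")}
    b = read_dataset(paths)

    pairs, report = cis_pairs(b.methylation.annotation, b.genotypes, window=100_000)
    print(f"{report['n_pairs']} cis pairs over {report['n_probes_tested']} probes "
          f"({report['n_probes_no_cis_snp']} probes without a cis SNP)")
    res = scan_meqtls(pairs, b.methylation, b.genotypes, b.cohort)
    curve, thr, res = permutation_fdr_meqtl(
        res, pairs, b.methylation, b.genotypes, b.cohort, n_perm=10, seed=1
    )
    res.to_csv(ROOT / "meqtl.tsv", sep="\t", index=False, na_rep="NA")
    curve.to_csv(ROOT / "meqtl_fdr_curve.tsv", sep="\t", index=False, na_rep="NA")

    sig_probes = res.loc[res["fdr_significant"], "probe_id"].nunique()
    sig_snps = res.loc[res["fdr_significant"], "snp_id"].nunique()
    tested = report["n_probes_tested"]
    print(f"FDR 5% threshold P = {thr:.2e}")
    print(f"{sig_probes} probes with cis-meQTLs ({percent(sig_probes, tested):.1f}% of {tested} tested), "
          f"{sig_snps} SNPs involved")
    if b.truth is not None:
        qtl = set(b.truth.index[b.truth["class"] == "meqtl"])
        declared = set(res.loc[res["fdr_significant"], "probe_id"])
        print(f"truth check: {len(declared & qtl)} true / {len(declared - qtl)} false declared")


if __name__ == "__main__":
    main()
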