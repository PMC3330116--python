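"""Readers/writers for all on-disk formats, probe QC, PCA covariate screen.

Conventions
-----------
* All tabular formats are TSV.  Methylation: first column ``probe_id``,
  header row of sample ids.  Missing values are the literal ``NA``.
* Genomic positions in TSV/VCF are 1-based; BED intervals are 0-based
  half-open; internal distance arithmetic uses 1-based point coordinates.
* Samples are columns in all matrices; alignment is by sample id.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import (
    DatasetBundle,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
    TwinCohort,
)

logger = logging.getLogger("twinewas")

NA = "NA"

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_methylation",
    "read_cohort",
    "read_genotypes",
    "read_genotypes_vcf",
    "read_phenotypes",
    "read_bed",
    "read_config",
    "probe_qc",
    "pca_covariate_screen",
]


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index_label=index_label)


def write_dataset(bundle: DatasetBundle, outdir) -> dict:
    """Write a bundle to ``outdir`` as the full TSV format set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    m = bundle.methylation
    _write_tsv(m.betas, outdir / "methylation.tsv", "probe_id")
    ann = m.annotation.copy()
    for col in ("cpg_island", "unique", "autosomal"):
        if col in ann.columns:
            ann[col] = ann[col].astype(int)
    _write_tsv(ann, outdir / "annotation.tsv", "probe_id")
    _write_tsv(bundle.cohort.samples, outdir / "samples.tsv", "individual_id")
    paths.update(
        methylation=outdir / "methylation.tsv",
        annotation=outdir / "annotation.tsv",
        samples=outdir / "samples.tsv",
    )
    if bundle.genotypes is not None:
        _write_tsv(bundle.genotypes.dosages, outdir / "dosages.tsv", "snp_id")
        _write_tsv(bundle.genotypes.snp_map, outdir / "snp_map.tsv", "snp_id")
        paths.update(dosages=outdir / "dosages.tsv", snp_map=outdir / "snp_map.tsv")
    if bundle.phenotypes is not None:
        _write_tsv(bundle.phenotypes.values, outdir / "phenotypes.tsv", "individual_id")
        paths["phenotypes"] = outdir / "phenotypes.tsv"
    if bundle.expression is not None:
        _write_tsv(bundle.expression, outdir / "expression.tsv", "gene")
        paths["expression"] = outdir / "expression.tsv"
    if bundle.wbc is not None:
        _write_tsv(bundle.wbc, outdir / "wbc.tsv", "individual_id")
        paths["wbc"] = outdir / "wbc.tsv"
    if bundle.truth is not None:
        _write_tsv(bundle.truth, outdir / "truth.tsv", "probe_id")
        paths["truth"] = outdir / "truth.tsv"
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(
            {
                "n_probes": int(m.n_probes),
                "n_samples": int(len(m.sample_ids)),
                "n_snps": int(len(bundle.genotypes.snp_ids)) if bundle.genotypes is not None else 0,
                **{k: v for k, v in bundle.log.items()},
            },
            fh,
            indent=2,
        )
    return paths


def read_methylation(meth_path, annotation_path) -> MethylationMatrix:
    betas = pd.read_csv(meth_path, sep="\t", index_col=0, na_values=[NA])
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, na_values=[NA])
    for col in ("chrom", "pos"):
        if col not in ann.columns:
            raise ValueError(f"annotation file missing mandatory column {col!r}")
    ann["chrom"] = ann["chrom"].astype(str)
    for col in ("cpg_island", "unique", "autosomal"):
        if col in ann.columns:
            ann[col] = ann[col].astype(bool)
    return MethylationMatrix(betas, ann)


def read_cohort(path) -> TwinCohort:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    missing = [c for c in TwinCohort.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing mandatory columns: {missing}")
    return TwinCohort(df)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path, sep="\t", index_col=0, na_values=[NA]))


def read_genotypes(dosage_path, snp_map_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=[NA])
    snp_map = pd.read_csv(snp_map_path, sep="\t", index_col=0, na_values=[NA])
    snp_map["chrom"] = snp_map["chrom"].astype(str)
    return GenotypeMatrix(dos, snp_map)


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read dosages from a VCF: DS format field if present, else GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        sid = var.ID or f"{var.CHROM}:{var.POS}"
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).ravel()[: len(samples)]
        else:
            gt = np.asarray(var.gt_types, dtype=float)
            # cyvcf2 gt_types: 0=hom_ref 1=het 2=unknown 3=hom_alt
            ds = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        ids.append(sid)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        rows.append(ds)
    dos = pd.DataFrame(np.array(rows), index=pd.Index(ids, name="snp_id"), columns=samples)
    snp_map = pd.DataFrame({"chrom": chroms, "pos": poss}, index=dos.index)
    return GenotypeMatrix(dos, snp_map)


def read_bed(path) -> pd.DataFrame:
    """BED intervals (0-based half-open) as columns chrom/start/end."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"], comment="#"
    )
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def read_dataset(paths: dict, config: dict | None = None) -> DatasetBundle:
    """Load and align the full bundle.

    ``paths`` maps the keys written by :func:`write_dataset` to files.
    Sample alignment: the master sample set is the intersection of the
    methylation matrix and the sample sheet (mismatches are dropped and
    counted in the bundle log); genotype/phenotype/expression/wbc tables
    are restricted to their available samples in master order, so a
    sample without genotypes stays in the EWAS but is excluded from the
    meQTL scan by the scan's own alignment.
    """
    m = read_methylation(paths["methylation"], paths["annotation"])
    cohort = read_cohort(paths["samples"])
    master = [s for s in cohort.individual_ids if s in set(m.sample_ids)]
    n_dropped = (len(cohort.individual_ids) - len(master)) + (len(m.sample_ids) - len(master))
    if n_dropped:
        logger.warning("dropped %d samples not shared by methylation and sample sheet", n_dropped)
        warnings.warn(f"dropped {n_dropped} samples not shared across core tables")
    m = m.subset_samples(master)
    cohort = cohort.subset(master)
    log = {"n_samples_dropped_core": int(n_dropped)}

    genos = phenos = expr = wbc = truth = None
    if "dosages" in paths:
        genos = read_genotypes(paths["dosages"], paths["snp_map"])
    elif "vcf" in paths:
        genos = read_genotypes_vcf(paths["vcf"])
    if genos is not None:
        shared = [s for s in master if s in set(genos.sample_ids)]
        if len(shared) < len(master):
            msg = f"{len(master) - len(shared)} samples lack genotypes; retained for EWAS, excluded from meQTL"
            logger.warning(msg)
            warnings.warn(msg)
            log["n_samples_without_genotypes"] = len(master) - len(shared)
        genos = genos.subset_samples(shared)
    if "phenotypes" in paths:
        phenos = read_phenotypes(paths["phenotypes"])
        phenos = PhenotypeTable(phenos.values.reindex(master))
    if "expression" in paths:
        expr = pd.read_csv(paths["expression"], sep="\t", index_col=0, na_values=[NA])
        expr = expr[[s for s in master if s in expr.columns]]
    if "wbc" in paths:
        wbc = pd.read_csv(paths["wbc"], sep="\t", index_col=0, na_values=[NA]).reindex(master)
    if "truth" in paths:
        truth = pd.read_csv(paths["truth"], sep="\t", index_col=0, na_values=[NA], keep_default_na=False)
    return DatasetBundle(
        methylation=m,
        cohort=cohort,
        genotypes=genos,
        phenotypes=phenos,
        expression=expr,
        truth=truth,
        wbc=wbc,
        log=log,
    )


def probe_qc(
    m: MethylationMatrix,
    require_unique: bool = True,
    drop_missing: bool = True,
    autosomal_only: bool = False,
) -> tuple[MethylationMatrix, dict]:
    """Filter probes; report counts dropped per reason and autosomal/X split.

    Idempotent: applying the same filters to the result changes nothing.
    """
    keep = pd.Series(True, index=m.probe_ids)
    report: dict = {"n_input": int(m.n_probes)}
    if require_unique and "unique" in m.annotation.columns:
        nonunique = ~m.annotation["unique"].astype(bool)
        report["dropped_nonunique"] = int((keep & nonunique).sum())
        keep &= ~nonunique
    if drop_missing:
        has_missing = m.betas.isna().any(axis=1)
        report["dropped_missing"] = int((keep & has_missing).sum())
        keep &= ~has_missing
    auto = m.annotation["autosomal"].astype(bool)
    if autosomal_only:
        report["dropped_non_autosomal"] = int((keep & ~auto).sum())
        keep &= auto
    if not keep.any():
        raise ValueError("probe QC removed every probe")
    out = m.subset_probes(m.probe_ids[keep])
    report["n_retained"] = int(out.n_probes)
    report["n_autosomal"] = int(out.annotation["autosomal"].sum())
    report["n_x"] = int((~out.annotation["autosomal"].astype(bool)).sum())
    return out, report


def _anova_p(scores: np.ndarray, covariate: pd.Series) -> float:
    """One-way linear-model F-test of PC scores on one covariate.

    Categorical covariates enter as groups (one-way ANOVA); numeric ones
    as a single linear term.  A constant covariate returns p = 1.0.
    """
    cov = covariate
    if cov.nunique(dropna=True) <= 1:
        return 1.0
    if cov.dtype.kind in "OUSb" or str(cov.dtype) == "category":
        groups = [scores[(cov == g).to_numpy()] for g in cov.dropna().unique()]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) < 2:
            return 1.0
        f, p = stats.f_oneway(*groups)
        return float(p) if np.isfinite(p) else 1.0
    ok = cov.notna().to_numpy()
    res = stats.linregress(cov.to_numpy(dtype=float)[ok], scores[ok])
    return float(res.pvalue) if np.isfinite(res.pvalue) else 1.0


def pca_covariate_screen(
    m: MethylationMatrix,
    cohort: TwinCohort,
    n_pcs: int = 5,
    covariates: tuple = ("age", "chip_id", "chip_position"),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list]:
    """Associate leading methylation PCs with candidate confounders.

    Betas are standardised to N(0,1) per probe before the decomposition.
    Returns (p-value table indexed PC1..PCn, covariates flagged because
    they associate with PC1 or PC2 at ``alpha``).
    """
    n_samples = len(m.sample_ids)
    if n_pcs > n_samples:
        raise ValueError(f"n_pcs={n_pcs} exceeds sample count {n_samples}")
    X = m.betas.to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    # sample-space PCs of the probe-standardised matrix
    _, _, Vt = np.linalg.svd(Xs - Xs.mean(axis=1, keepdims=True), full_matrices=False)
    scores = Vt[:n_pcs]  # (n_pcs, n_samples)
    sub = cohort.samples.loc[list(m.sample_ids)]
    pvals = pd.DataFrame(
        index=[f"PC{i + 1}" for i in range(n_pcs)], columns=list(covariates), dtype=float
    )
    for i in range(n_pcs):
        for cov in covariates:
            pvals.iloc[i, pvals.columns.get_loc(cov)] = _anova_p(scores[i], sub[cov])
    flagged = [
        c
        for c in covariates
        if (pvals.loc["PC1", c] < alpha) or (n_pcs > 1 and pvals.loc["PC2", c] < alpha)
    ]
    return pvals, flagged
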