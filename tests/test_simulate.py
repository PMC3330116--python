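"""Generator contracts: cohort structure, Mendelian sharing, effect recovery."""

import numpy as np
import pytest
from scipy import stats

from twinewas.concordance import icc_by_zygosity
from twinewas.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_dataset,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
)


def test_cohort_counts_and_structure():
    coh = simulate_cohort(SimulationConfig())
    s = coh.samples
    assert len(s) == 172
    fams = s.groupby("family_id").size()
    assert (fams == 2).sum() == 76 and (fams == 1).sum() == 20
    ages = s.groupby("family_id")["age"].nunique()
    assert (ages == 1).all()  # co-twins share age
    assert s["age"].between(32, 80).all()

    tiny = simulate_cohort(SimulationConfig(n_mz_pairs=1, n_dz_pairs=0, n_singletons=0))
    assert len(tiny.samples) == 2
    assert set(tiny.samples["zygosity"]) == {"MZ"}
    assert tiny.samples["family_id"].nunique() == 1


def test_zero_individuals_fatal():
    with pytest.raises(ValueError, match="at least one"):
        simulate_cohort(SimulationConfig(n_mz_pairs=0, n_dz_pairs=0, n_singletons=0))


def test_seed_determinism():
    cfg = SimulationConfig(n_probes=40, seed=9)
    b1, b2 = simulate_dataset(cfg), simulate_dataset(cfg)
    assert b1.cohort.samples.equals(b2.cohort.samples)
    assert b1.methylation.betas.equals(b2.methylation.betas)
    assert b1.genotypes.dosages.equals(b2.genotypes.dosages)
    assert b1.phenotypes.values.equals(b2.phenotypes.values)
    assert b1.expression.equals(b2.expression)


def test_mz_pairs_share_genotypes_exactly(bundle):
    dos = bundle.genotypes.dosages
    for a, b in bundle.cohort.twin_pairs("MZ"):
        np.testing.assert_array_equal(dos[a].to_numpy(), dos[b].to_numpy())


def test_dz_dosage_correlation_is_half():
    """Sibling sharing: DZ co-twin dosage correlation ~0.5."""
    cfg = SimulationConfig(
        n_mz_pairs=0, n_dz_pairs=3000, n_singletons=0, n_probes=60,
        snps_per_probe=2, seed=3,
    )
    coh = simulate_cohort(cfg)
    genos = simulate_genotypes(cfg, coh)
    pairs = coh.twin_pairs("DZ")
    d1 = genos.dosages[[a for a, _ in pairs]].to_numpy()
    d2 = genos.dosages[[b for _, b in pairs]].to_numpy()
    rs = [
        np.corrcoef(d1[i], d2[i])[0, 1]
        for i in range(d1.shape[0])
        if d1[i].std() > 0 and d2[i].std() > 0
    ]
    assert abs(np.mean(rs) - 0.5) < 0.02


def test_hwe_dosage_mean_at_half_maf():
    cfg = SimulationConfig(
        n_mz_pairs=0, n_dz_pairs=0, n_singletons=4000, n_probes=10,
        maf_range=(0.5, 0.5), seed=7,
    )
    coh = simulate_cohort(cfg)
    genos = simulate_genotypes(cfg, coh)
    assert abs(genos.dosages.to_numpy().mean() - 1.0) < 0.03


def test_bad_maf_fatal(bundle):
    import pandas as pd

    snp_map = pd.DataFrame(
        {"chrom": ["1"], "pos": [100], "maf": [0.7], "causal_for": [""]},
        index=pd.Index(["rsX"], name="snp_id"),
    )
    with pytest.raises(ValueError, match="MAF"):
        simulate_genotypes(SimulationConfig(), bundle.cohort, snp_map)


def test_null_model_mz_dz_indistinguishable():
    """With all genetic and shared-environment variance off, MZ and DZ
    ICC distributions are statistically indistinguishable."""
    cfg = SimulationConfig(
        n_probes=400, frac_heritable=0, frac_meqtl=0, frac_age=0,
        family_sd=0.0, chip_sd=0.0, comethylation_sd=0.0, n_batches=1, seed=19,
    )
    coh = simulate_cohort(cfg)
    m, _ = simulate_methylation(cfg, coh)
    icc = icc_by_zygosity(m, coh, per_batch=False)
    ks = stats.ks_2samp(icc["icc_mz"].dropna(), icc["icc_dz"].dropna())
    assert ks.pvalue > 0.01


def test_age_class_sign_mix_matches_hyper_fraction(age_rich_bundle):
    truth = age_rich_bundle.truth
    slopes = truth.loc[truth["class"] == "age", "age_slope"].astype(float)
    assert len(slopes) == 300
    assert abs((slopes > 0).mean() - 0.98) < 0.05


def test_invalid_configs_fatal():
    with pytest.raises(ValueError, match="fractions"):
        SimulationConfig(frac_heritable=0.8, frac_meqtl=0.3)
    with pytest.raises(ValueError, match="block size"):
        SimulationConfig(block_bp=0)
    with pytest.raises(ValueError, match="must be >= 0"):
        SimulationConfig(noise_sd=-1)


def test_phenotype_slope_recovery_and_missingness():
    """Refitting the SBP age slope at n=5000 recovers 0.663; telomere
    missingness leaves ~62.2% observed."""
    cfg = SimulationConfig(
        n_mz_pairs=0, n_dz_pairs=0, n_singletons=5000, n_probes=10, seed=11,
    )
    coh = simulate_cohort(cfg)
    ph = simulate_phenotypes(cfg, coh)
    sbp = ph.values["SBP"]
    age = coh.samples["age"]
    ok = sbp.notna()
    slope = stats.linregress(age[ok], sbp[ok]).slope
    assert abs(slope - 0.663) < 0.05
    assert abs(ph.values["Telomere"].notna().mean() - 0.622) < 0.025


def test_phenotype_zero_noise_zero_slope_constant():
    cfg = SimulationConfig(
        n_mz_pairs=2, n_dz_pairs=2, n_singletons=2, n_probes=10,
        trait_params={"SBP": (0.0, 1.0, 0.0, 120.0)},
        pheno_family_sd_frac=0.0,
    )
    coh = simulate_cohort(cfg)
    ph = simulate_phenotypes(cfg, coh)
    assert (ph.values["SBP"] == 120.0).all()


def test_expression_coupling_sign():
    cfg = SimulationConfig(n_probes=200, seed=13)
    b = simulate_dataset(cfg)
    rhos = []
    for gene, expr_row in b.expression.iterrows():
        meth = b.methylation.betas.loc[
            b.methylation.annotation["nearest_gene"] == gene
        ].mean(axis=0)
        rhos.append(stats.spearmanr(meth, expr_row[meth.index]).statistic)
    assert np.mean(rhos) < -0.2

    m0, _ = simulate_methylation(cfg, b.cohort, b.genotypes)
    cfg0 = cfg.replace(expression_coupling=0.0, expression_coupling_other=0.0)
    e0 = simulate_expression(cfg0, m0)
    rhos0 = []
    for gene, expr_row in e0.iterrows():
        meth = m0.betas.loc[m0.annotation["nearest_gene"] == gene].mean(axis=0)
        rhos0.append(stats.spearmanr(meth, expr_row[meth.index]).statistic)
    assert abs(np.mean(rhos0)) < 0.05


def test_truth_sidecar_labels_every_probe(bundle):
    truth = bundle.truth
    assert list(truth.index) == list(bundle.methylation.probe_ids)
    assert set(truth["class"]) <= {"heritable", "meqtl", "age", "null"}
    qtl = truth[truth["class"] == "meqtl"]
    assert (qtl["causal_snp"] != "").all()
    assert (qtl["meqtl_beta"] != 0).all()
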