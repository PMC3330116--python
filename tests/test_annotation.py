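"""Co-methylation decay, interval enrichment, expression coupling, replication."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinewas.annotation import (
    comethylation_profile,
    enrichment_bootstrap,
    interval_membership,
    methylation_expression_correlation,
    replication_check,
    replication_fractions,
)
from twinewas.datatypes import MethylationMatrix
from twinewas.ewas import scan_dmrs
from twinewas.simulate import SimulationConfig, simulate_dataset


def test_duplicated_probe_perfect_correlation():
    rng = np.random.default_rng(0)
    v = rng.uniform(0.2, 0.8, size=30)
    betas = pd.DataFrame([v, v], index=["cgA", "cgB"], columns=[f"s{i}" for i in range(30)])
    ann = pd.DataFrame(
        {"chrom": "1", "pos": [1000, 1100], "nearest_gene": "G", "tss_distance": 0,
         "cpg_island": True, "unique": True},
        index=["cgA", "cgB"],
    )
    prof = comethylation_profile(MethylationMatrix(betas, ann))
    assert prof.loc[0, "n_pairs"] == 1
    assert prof.loc[0, "mean_spearman"] == pytest.approx(1.0, abs=1e-9)


def test_independent_probes_near_zero_everywhere():
    rng = np.random.default_rng(1)
    n = 60
    betas = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(n, 40)),
        index=[f"cg{i}" for i in range(n)],
        columns=[f"s{i}" for i in range(40)],
    )
    ann = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(n) * 400 + 1, "nearest_gene": "G",
         "tss_distance": 0, "cpg_island": True, "unique": True},
        index=betas.index,
    )
    prof = comethylation_profile(MethylationMatrix(betas, ann))
    assert prof["mean_spearman"].abs().max() < 0.12


def test_comethylation_decays_with_distance(bundle):
    """Block co-methylation (2 kb scale) yields decreasing bin means."""
    prof = comethylation_profile(bundle.methylation)
    means = prof["mean_spearman"].to_numpy()
    assert means[0] > means[1] > means[2]
    assert means[0] > means[-1] + 0.05


def test_unrelated_vs_all_individuals_close(bundle):
    cohort = bundle.cohort
    one_per_family = cohort.samples.groupby("family_id").head(1).index
    prof_all = comethylation_profile(bundle.methylation)
    prof_unrel = comethylation_profile(bundle.methylation, sample_subset=list(one_per_family))
    ok = (prof_all["n_pairs"] > 5).to_numpy()
    diff = (prof_all["mean_spearman"] - prof_unrel["mean_spearman"]).abs().to_numpy()[ok]
    assert np.nanmax(diff) < 0.05


def test_interval_membership_half_open_boundaries():
    track = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200]})
    pos = pd.DataFrame({"chrom": "1", "pos": [100, 101, 200, 201]})
    got = interval_membership(pos, track)
    np.testing.assert_array_equal(got, [False, True, True, False])


def test_enrichment_identity_and_arithmetic(bundle):
    ann = bundle.methylation.annotation
    tracks = {"cpg_island": ann["cpg_island"]}
    bg = list(bundle.methylation.probe_ids)
    res = enrichment_bootstrap(bg, bg, tracks, ann, n_boot=100, seed=0)
    assert res["enrichment"].iloc[0] == pytest.approx(1.0)
    assert res["ci_low"].iloc[0] <= 1.0 <= res["ci_high"].iloc[0]

    # study arithmetic: 300 of 490 DMRs in islands vs 11,299 of 26,690
    flags = pd.Series(False, index=[f"p{i}" for i in range(26_690)])
    flags.iloc[:11_299] = True
    ann2 = pd.DataFrame({"chrom": "1", "pos": 1, "cpg_island": flags})
    dmr = list(flags.index[:300]) + list(flags.index[11_299 : 11_299 + 190])
    res2 = enrichment_bootstrap(dmr, list(flags.index), {"cpg_island": flags}, ann2, n_boot=10, seed=0)
    assert res2["enrichment"].iloc[0] == pytest.approx((300 / 490) / (11_299 / 26_690), abs=1e-12)
    assert res2["enrichment"].iloc[0] == pytest.approx(1.446, abs=5e-4)


def test_island_biased_class_ci_excludes_one(age_rich_bundle):
    b = age_rich_bundle
    ann = b.methylation.annotation
    dmr = list(b.truth.index[b.truth["class"] == "age"])
    res = enrichment_bootstrap(
        dmr, list(b.methylation.probe_ids), {"cpg_island": ann["cpg_island"]}, ann,
        n_boot=500, seed=1,
    )
    assert res["ci_low"].iloc[0] > 1.0


def test_empty_background_category_flagged(bundle):
    ann = bundle.methylation.annotation
    none = pd.Series(False, index=ann.index)
    res = enrichment_bootstrap(
        list(ann.index[:5]), list(ann.index), {"empty": none}, ann, n_boot=10
    )
    assert np.isnan(res["enrichment"].iloc[0])


def test_expression_exact_negative_and_independent(bundle):
    m = bundle.methylation
    genes = m.annotation["nearest_gene"]
    gene_meth = m.betas.groupby(genes).mean()
    expr = -gene_meth
    # window wide enough to keep every probe, so the internal gene means
    # match the ones the oracle expression was built from
    table, summary = methylation_expression_correlation(m, expr, tss_window=5000)
    np.testing.assert_allclose(table["rho"], -1.0, atol=1e-9)
    assert summary["wilcoxon_p"] < 1e-10
    rng = np.random.default_rng(2)
    expr2 = pd.DataFrame(
        rng.normal(size=gene_meth.shape), index=gene_meth.index, columns=gene_meth.columns
    )
    _, s2 = methylation_expression_correlation(m, expr2, tss_window=5000)
    assert abs(s2["mean_rho"]) < 0.05


def test_generator_expression_coupling_detected(bundle):
    table, summary = methylation_expression_correlation(bundle.methylation, bundle.expression)
    assert summary["mean_rho"] < -0.1
    assert summary["wilcoxon_p"] < 0.01


def test_replication_identity_and_fractions(bundle):
    res = scan_dmrs(bundle.methylation, bundle.cohort, "age")
    disc = res.nsmallest(30, "p")
    table, summary = replication_check(disc, bundle.methylation, bundle.cohort, mode="lmm")
    assert summary["pct_same_direction"] == 100.0

    f = replication_fractions(184, 184, 490)
    assert f["pct_same_direction"] == pytest.approx(37.55, abs=0.01)
    assert round(f["pct_same_direction"]) == 38


def test_replication_in_younger_mz_cohort():
    """a-DMRs discovered at study scale keep their direction in a second,
    younger all-MZ cohort drawn from the same truth (22 pairs, ages 20-61)."""
    cfg = SimulationConfig(n_probes=300, frac_age=0.3, frac_meqtl=0.0, seed=61)
    b = simulate_dataset(cfg)
    res = scan_dmrs(b.methylation, b.cohort, "age")
    truth_age = set(b.truth.index[b.truth["class"] == "age"])
    disc = res[res["probe_id"].isin(truth_age) & (res["p"] < 1e-4)]
    assert len(disc) >= 40

    # same seed => same probe-level truth; different cohort composition
    cfg2 = cfg.replace(n_mz_pairs=22, n_dz_pairs=0, n_singletons=0, age_range=(20.0, 61.0))
    b2 = simulate_dataset(cfg2)
    assert (b2.truth["age_slope"] == b.truth["age_slope"]).all()
    assert list(b2.methylation.probe_ids) == list(b.methylation.probe_ids)
    table, summary = replication_check(disc, b2.methylation, b2.cohort, mode="lmm")
    assert summary["pct_same_direction"] >= 75.0

    # unrelated-subset Spearman mode runs on one twin per pair
    one_per_pair = b2.cohort.samples.groupby("family_id").head(1).index
    m2 = b2.methylation.subset_samples(one_per_pair)
    table_u, summary_u = replication_check(disc, m2, b2.cohort, mode="unrelated_spearman")
    assert summary_u["pct_same_direction"] >= 60.0


def test_replication_sign_randomized_truth_near_half(bundle):
    rng = np.random.default_rng(9)
    res = scan_dmrs(bundle.methylation, bundle.cohort, "age")
    flipped = res.copy()
    flipped["beta"] = rng.choice([-1.0, 1.0], size=len(flipped)) * flipped["beta"].abs()
    table, summary = replication_check(flipped, bundle.methylation, bundle.cohort, mode="lmm")
    assert 35.0 <= summary["pct_same_direction"] <= 65.0


def test_missing_probe_stays_in_denominator(bundle):
    res = scan_dmrs(bundle.methylation, bundle.cohort, "age").nsmallest(10, "p")
    keep = [p for p in bundle.methylation.probe_ids if p not in set(res["probe_id"].iloc[:2])]
    m2 = bundle.methylation.subset_probes(keep)
    table, summary = replication_check(res, m2, bundle.cohort, mode="lmm")
    assert summary["n_discovery"] == 10
    assert summary["n_untested"] == 2
    assert not table.loc[~table["tested"], "same_direction"].any()
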