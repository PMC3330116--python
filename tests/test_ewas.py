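"""EWAS scans, twin-preserving permutation FDR, and blood-count checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from twinewas.concordance import pairwise_profile_correlations
from twinewas.datatypes import MethylationMatrix, TwinCohort
from twinewas.ewas import (
    bonferroni_nominal_threshold,
    permutation_fdr_ewas,
    scan_dmrs,
    wbc_association,
)
from twinewas.fdr import family_permutation
from twinewas.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="module")
def age_scan(bundle):
    return scan_dmrs(bundle.methylation, bundle.cohort, "age")


def test_planted_age_effects_detected(bundle, age_scan):
    """Age-class probes (slope ~1.2e-2 on the liability scale, i.e. a
    few 1e-3 per year in beta units) are recovered at FDR 5%."""
    curve, thr, res = permutation_fdr_ewas(
        age_scan, bundle.methylation, bundle.cohort, "age", n_perm=12, seed=2
    )
    truth = bundle.truth
    agecls = set(truth.index[truth["class"] == "age"])
    declared = set(res.loc[res["fdr_significant"], "probe_id"])
    assert len(declared & agecls) / len(agecls) >= 0.9
    # beta-scale magnitude comparable to the strongest age DMRs (1e-3..4e-3/yr)
    betas = res.set_index("probe_id").loc[sorted(agecls), "beta"].abs()
    assert 5e-4 < betas.median() < 6e-3


def test_direction_convention(age_scan):
    assert (age_scan.loc[age_scan["beta"] >= 0, "direction"] == "hyper").all()
    assert (age_scan.loc[age_scan["beta"] < 0, "direction"] == "hypo").all()


def test_shuffled_trait_gives_nominal_false_positives(bundle):
    rng = np.random.default_rng(4)
    shuffled = pd.Series(
        rng.permutation(bundle.cohort.samples["age"].to_numpy()),
        index=bundle.cohort.samples.index,
    )
    from twinewas.datatypes import PhenotypeTable

    phen = PhenotypeTable(shuffled.to_frame("SBP"))
    res = scan_dmrs(bundle.methylation, bundle.cohort, "SBP", phen)
    frac = (res["p"] < 0.05).mean()
    assert frac < 0.12  # ~5% nominal plus co-methylation clumping noise


def test_constant_trait_fatal(bundle):
    from twinewas.datatypes import PhenotypeTable

    phen = PhenotypeTable(
        pd.DataFrame({"SBP": 1.0}, index=bundle.cohort.samples.index)
    )
    with pytest.raises(ValueError, match="constant"):
        scan_dmrs(bundle.methylation, bundle.cohort, "SBP", phen)


def test_raw_and_normalized_scans_agree_on_top_ranks(bundle):
    raw = scan_dmrs(bundle.methylation, bundle.cohort, "age", raw_scale=True)
    norm = scan_dmrs(bundle.methylation, bundle.cohort, "age", raw_scale=False)
    k = 20
    top_raw = set(raw.nsmallest(k, "p")["probe_id"])
    top_norm = set(norm.nsmallest(k, "p")["probe_id"])
    assert len(top_raw & top_norm) >= int(0.7 * k)


def test_family_permutation_preserves_twin_correlation(bundle):
    """Permuted methylation keeps the within-pair correlation structure."""
    rng = np.random.default_rng(7)
    mapping = family_permutation(bundle.cohort, rng)
    assert sorted(mapping) == sorted(mapping.values())  # a true permutation
    donors = [mapping[s] for s in bundle.methylation.sample_ids]
    permuted = MethylationMatrix(
        pd.DataFrame(
            bundle.methylation.betas[donors].to_numpy(),
            index=bundle.methylation.probe_ids,
            columns=bundle.methylation.sample_ids,
        ),
        bundle.methylation.annotation,
    )
    _, s_orig = pairwise_profile_correlations(bundle.methylation, bundle.cohort, max_unrelated=50)
    _, s_perm = pairwise_profile_correlations(permuted, bundle.cohort, max_unrelated=50)
    for grp in ("MZ", "DZ"):
        a = s_orig.set_index("group").loc[grp, "mean"]
        b = s_perm.set_index("group").loc[grp, "mean"]
        assert abs(a - b) < 0.02


def test_family_permutation_degenerate_stratum_fatal():
    rows = []
    for fam, zyg in (("F1", "MZ"), ("F2", "MZ"), ("F3", "DZ"), ("F4", "DZ"), ("F5", "DZ")):
        for k in (1, 2):
            rows.append((f"{fam}_{k}", fam, zyg, 50.0, "F", "c0", k, "b1"))
    df = pd.DataFrame(
        rows,
        columns=["individual_id", "family_id", "zygosity", "age", "sex", "chip_id", "chip_position", "batch_id"],
    ).set_index("individual_id")
    with pytest.raises(ValueError, match="stratum"):
        family_permutation(TwinCohort(df), np.random.default_rng(0))


def test_pure_null_scan_declares_nothing():
    cfg = SimulationConfig(
        n_probes=200, frac_heritable=0.2, frac_meqtl=0, frac_age=0, seed=41
    )
    b = simulate_dataset(cfg)
    res = scan_dmrs(b.methylation, b.cohort, "age")
    _, thr, out = permutation_fdr_ewas(res, b.methylation, b.cohort, "age", n_perm=10, seed=1)
    assert out["fdr_significant"].sum() <= 2


def test_hyper_fraction_matches_generator(age_rich_bundle):
    """Declared synthetic a-DMRs are ~98% hyper-methylated (within 0.05)."""
    b = age_rich_bundle
    res = scan_dmrs(b.methylation, b.cohort, "age")
    _, thr, out = permutation_fdr_ewas(res, b.methylation, b.cohort, "age", n_perm=8, seed=3)
    sig = out[out["fdr_significant"]]
    assert len(sig) >= 100
    hyper = (sig["direction"] == "hyper").mean()
    assert abs(hyper - 0.98) <= 0.05


def test_bonferroni_threshold_printed_form():
    exact, printed = bonferroni_nominal_threshold(493)
    assert exact == pytest.approx(0.05 / 493)
    assert printed == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        bonferroni_nominal_threshold(0)


def test_wbc_association_flags_planted_lymphocyte_probes(bundle):
    probes = list(bundle.methylation.probe_ids[:8])  # includes planted 3, 4
    table, summary = wbc_association(probes, bundle.methylation, bundle.cohort, bundle.wbc)
    lymph = table[table["cell_type"] == "lymphocytes"].set_index("probe_id")
    planted = [bundle.methylation.probe_ids[i] for i in (3, 4)]
    assert lymph.loc[planted, "significant"].all()
    neut = table[table["cell_type"] == "neutrophils"].set_index("probe_id")
    unplanted = [p for p in probes if p not in planted]
    # unplanted probes are not systematically neutrophil-associated
    assert (~neut.loc[unplanted, "significant"]).mean() >= 0.75


def test_wbc_missing_cell_type_warns_and_empty_input_ok(bundle):
    wbc2 = bundle.wbc.drop(columns=["eosinophils"])
    with pytest.warns(UserWarning, match="eosinophils"):
        table, _ = wbc_association(
            list(bundle.methylation.probe_ids[:2]), bundle.methylation, bundle.cohort, wbc2
        )
    assert set(table["cell_type"]) == {"neutrophils", "monocytes", "lymphocytes"}
    empty, summary = wbc_association([], bundle.methylation, bundle.cohort, bundle.wbc)
    assert empty[0].empty if isinstance(empty, tuple) else empty.empty
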