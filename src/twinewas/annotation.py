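"""Functional characterisation of DMRs.

Co-methylation decay profiles, enrichment of probe sets in genomic
annotation tracks (CpG islands, histone peaks) with bootstrap
percentile confidence intervals, methylation-expression correlation at
DMR genes, and replication of discovery DMRs in a second cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, TwinCohort
from .lmm import TwinLMM, design_matrix, inverse_normal_transform

__all__ = [
    "comethylation_profile",
    "interval_membership",
    "enrichment_bootstrap",
    "methylation_expression_correlation",
    "replication_check",
    "replication_fractions",
]

DEFAULT_BINS = (0, 500, 1000, 2000, 5000, 10_000, 50_000)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks (for vectorised Spearman)."""
    return np.apply_along_axis(stats.rankdata, 1, X)


def comethylation_profile(
    m: MethylationMatrix,
    max_dist: int = 50_000,
    bins: tuple = DEFAULT_BINS,
    probe_subset=None,
    sample_subset=None,
) -> pd.DataFrame:
    """Mean Spearman correlation of probe pairs binned by bp distance.

    All same-chromosome probe pairs within ``max_dist`` are binned by
    half-open distance intervals [bins[k], bins[k+1]); the Spearman
    correlation of each pair is computed across individuals (optionally
    restricted to ``sample_subset``, e.g. unrelated individuals only;
    ``probe_subset`` restricts the *first* probe of each pair, e.g. to
    a-DMRs).  Empty bins are reported with count 0 and NaN mean rather
    than propagating NaN into other bins.
    """
    ann = m.annotation
    cols = list(sample_subset) if sample_subset is not None else list(m.sample_ids)
    if len(cols) < 3:
        raise ValueError("need at least 3 individuals")
    B = m.betas.loc[:, cols].to_numpy(dtype=float)
    R = _rank_rows(B)
    R = (R - R.mean(axis=1, keepdims=True)) / np.maximum(R.std(axis=1, keepdims=True), 1e-12)
    subset = set(probe_subset) if probe_subset is not None else None
    edges = np.asarray(bins, dtype=float)
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    pos_all = ann["pos"].to_numpy()
    idx_all = np.arange(len(ann))
    for chrom in ann["chrom"].unique():
        on = ann["chrom"].to_numpy() == chrom
        order = np.argsort(pos_all[on], kind="stable")
        idx = idx_all[on][order]
        pos = pos_all[on][order]
        for a in range(len(idx)):
            if subset is not None and m.probe_ids[idx[a]] not in subset:
                continue
            for b_ in range(a + 1, len(idx)):
                d = pos[b_] - pos[a]
                if d > max_dist or d >= edges[-1]:
                    break
                k = int(np.searchsorted(edges, d, side="right") - 1)
                if k < 0:
                    continue
                rho = float(np.mean(R[idx[a]] * R[idx[b_]]))
                sums[k] += rho
                counts[k] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_low": edges[:-1].astype(int),
            "bin_high": edges[1:].astype(int),
            "mean_spearman": means,
            "n_pairs": counts,
        }
    )


def interval_membership(positions: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Is each 1-based point inside any 0-based half-open BED interval?

    ``positions`` needs columns chrom/pos.  A 1-based point p falls in
    interval [start, end) iff start < p <= end in 1-based terms, i.e.
    start <= p - 1 < end.
    """
    out = np.zeros(len(positions), dtype=bool)
    for chrom, sub in track.groupby("chrom"):
        ivs = sub.sort_values("start")
        starts = ivs["start"].to_numpy()
        ends = ivs["end"].to_numpy()
        # merge overlapping intervals
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        m_starts = np.asarray(m_starts)
        m_ends = np.asarray(m_ends)
        on = (positions["chrom"].astype(str) == str(chrom)).to_numpy()
        p0 = positions.loc[on, "pos"].to_numpy() - 1  # 0-based point
        j = np.searchsorted(m_starts, p0, side="right") - 1
        ok = (j >= 0) & (p0 < m_ends[np.maximum(j, 0)])
        out[on] = ok
    return out


def enrichment_bootstrap(
    dmr_probes,
    background,
    tracks: dict,
    annotation: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Enrichment of a probe set in annotation tracks with bootstrap CIs.

    enrichment = (proportion of DMR probes in the category) /
    (proportion of background probes in the category); the 95% CI is
    the percentile interval over ``n_boot`` resamplings (with
    replacement) of the DMR set.  ``tracks`` maps category name to a
    BED DataFrame (chrom/start/end) *or* to a boolean Series indexed by
    probe id (e.g. the CpG-island annotation flag).
    """
    rng = np.random.default_rng(seed)
    dmr = [p for p in dmr_probes if p in annotation.index]
    bg = [p for p in background if p in annotation.index]
    rows = []
    for name, track in tracks.items():
        if isinstance(track, pd.DataFrame):
            member = pd.Series(
                interval_membership(annotation[["chrom", "pos"]], track),
                index=annotation.index,
            )
        else:
            member = track.astype(bool).reindex(annotation.index, fill_value=False)
        prop_bg = float(member.loc[bg].mean()) if bg else float("nan")
        in_dmr = member.loc[dmr].to_numpy(dtype=float)
        prop_dmr = float(in_dmr.mean()) if len(in_dmr) else float("nan")
        if not prop_bg or not np.isfinite(prop_bg):
            rows.append((name, prop_dmr, prop_bg, float("nan"), float("nan"), float("nan")))
            continue
        enr = prop_dmr / prop_bg
        boots = np.array(
            [
                in_dmr[rng.integers(0, len(in_dmr), size=len(in_dmr))].mean() / prop_bg
                for _ in range(n_boot)
            ]
        )
        rows.append(
            (
                name,
                prop_dmr,
                prop_bg,
                enr,
                float(np.percentile(boots, 2.5)),
                float(np.percentile(boots, 97.5)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["category", "prop_dmr", "prop_background", "enrichment", "ci_low", "ci_high"],
    )


def methylation_expression_correlation(
    m: MethylationMatrix,
    expr: pd.DataFrame,
    tss_window: int = 2000,
    probe_subset=None,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlation of methylation with expression.

    Probes are restricted to |tss_distance| <= window (and optionally
    to a probe subset, e.g. a-DMRs); per gene, methylation (and
    expression, if multiple probes map to it) is averaged, then the
    Spearman rho across shared individuals is computed.  The rho
    distribution is tested against zero by Wilcoxon signed rank.
    """
    ann = m.annotation
    keep = ann["tss_distance"].abs() <= tss_window
    if probe_subset is not None:
        keep &= ann.index.isin(set(probe_subset))
    shared = [s for s in m.sample_ids if s in expr.columns]
    if len(shared) < 5:
        raise ValueError("too few shared individuals between methylation and expression")
    sub = m.betas.loc[keep, shared]
    genes = ann.loc[keep, "nearest_gene"]
    gene_meth = sub.groupby(genes).mean()
    rows, skipped = [], 0
    for gene, mvals in gene_meth.iterrows():
        if gene not in expr.index:
            skipped += 1
            continue
        evals_ = expr.loc[gene, shared].astype(float)
        ok = np.isfinite(mvals.to_numpy()) & np.isfinite(evals_.to_numpy())
        if ok.sum() < 5 or mvals[ok].nunique() < 2:
            skipped += 1
            continue
        rho, p = stats.spearmanr(mvals[ok], evals_[ok])
        rows.append((gene, float(rho), float(p), int(ok.sum())))
    table = pd.DataFrame(rows, columns=["gene", "rho", "p", "n"])
    if len(table) >= 10 and (table["rho"] != 0).any():
        w = stats.wilcoxon(table["rho"])
        test_p = float(w.pvalue)
    else:
        test_p = float("nan")
    summary = {
        "n_genes": int(len(table)),
        "n_skipped": int(skipped),
        "mean_rho": float(table["rho"].mean()) if len(table) else float("nan"),
        "wilcoxon_p": test_p,
    }
    return table, summary


def replication_check(
    discovery: pd.DataFrame,
    m2: MethylationMatrix,
    cohort2: TwinCohort,
    mode: str = "lmm",
    nominal_alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Replicate discovery DMRs (vs age) in an independent cohort.

    ``mode="lmm"``: normalised betas regressed on age with chip, order
    and sex fixed effects and a family random intercept (the mixed-sex
    twin replication design).  ``mode="unrelated_spearman"``: Spearman
    correlation of raw betas with age (for unrelated subsets).

    Summary fractions use *all* discovery DMRs as denominator; probes
    absent from the replication panel stay in the denominator, flagged
    untested.
    """
    disc = discovery.set_index("probe_id")
    probes = [p for p in disc.index if p in set(m2.probe_ids)]
    ids = list(m2.sample_ids)
    rows = []
    if mode == "lmm":
        cohort_ids = [s for s in cohort2.individual_ids if s in set(ids)]
        eng = TwinLMM(cohort2.subset(cohort_ids), cohort_ids)
        X_full = design_matrix(
            cohort2, cohort_ids, terms={"age": cohort2.samples["age"].astype(float)}, sex=True
        )
        X_null = X_full.drop(columns=["age"])
        Y = m2.betas.loc[probes, cohort_ids].to_numpy(dtype=float).T
        Y = np.apply_along_axis(inverse_normal_transform, 0, Y)
        res = eng.scan_lrt(Y, X_full, X_null, term="age")
        for pid, row in zip(probes, res.itertuples()):
            rows.append((pid, float(row.beta), float(row.p)))
    elif mode == "unrelated_spearman":
        age = cohort2.samples.loc[[s for s in ids if s in cohort2.samples.index], "age"]
        for pid in probes:
            y = m2.betas.loc[pid, age.index].to_numpy(dtype=float)
            ok = np.isfinite(y)
            rho, p = stats.spearmanr(age.to_numpy(dtype=float)[ok], y[ok])
            rows.append((pid, float(rho), float(p)))
    else:
        raise ValueError(f"unknown replication mode {mode!r}")
    rep = pd.DataFrame(rows, columns=["probe_id", "effect", "p"]).set_index("probe_id")
    out = []
    for pid in disc.index:
        if pid in rep.index:
            eff, p = rep.loc[pid, "effect"], rep.loc[pid, "p"]
            same = bool(np.sign(eff) == np.sign(disc.loc[pid, "beta"]))
            out.append((pid, eff, p, same, same and p <= nominal_alpha, True))
        else:
            out.append((pid, np.nan, np.nan, False, False, False))
    table = pd.DataFrame(
        out,
        columns=["probe_id", "replication_effect", "replication_p", "same_direction", "replicated_nominal", "tested"],
    )
    summary = replication_fractions(
        int(table["same_direction"].sum()),
        int(table["replicated_nominal"].sum()),
        int(len(table)),
    )
    summary["n_untested"] = int((~table["tested"]).sum())
    return table, summary


def replication_fractions(n_same_direction: int, n_nominal: int, n_discovery: int) -> dict:
    """Replication percentages over the full discovery set denominator."""
    if n_discovery <= 0:
        raise ValueError("empty discovery set")
    return {
        "n_discovery": int(n_discovery),
        "n_same_direction": int(n_same_direction),
        "n_replicated_nominal": int(n_nominal),
        "pct_same_direction": 100.0 * n_same_direction / n_discovery,
        "pct_replicated_nominal": 100.0 * n_nominal / n_discovery,
    }
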