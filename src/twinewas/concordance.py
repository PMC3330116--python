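"""Twin similarity statistics: profile correlations, ICCs, heritability.

Heritability per probe follows the Falconer-style estimator
``h2 = 2 (ICC_MZ - ICC_DZ)`` with the one-way random-effects
ICC(1,1) = (MSB - MSW)/(MSB + MSW) from the pair-level ANOVA.  ICCs and
heritabilities are computed within each methylation batch separately,
and h2 is reported raw (it is not truncated to [0, 1]).
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MethylationMatrix, TwinCohort

__all__ = [
    "probe_icc",
    "icc_by_zygosity",
    "pairwise_profile_correlations",
    "heritability_summary",
]


def probe_icc(values, pairs) -> float:
    """One-way random-effects ICC(1,1) for one probe.

    ``values`` are the measurements, ``pairs`` the parallel pair labels
    (each label appearing exactly twice for a complete pair).  Pairs
    with a missing member are excluded; fewer than 2 complete pairs
    gives NaN (the undefined flag — such probes are excluded from
    summaries).
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(pairs)
    df = pd.DataFrame({"v": v, "pair": p}).dropna()
    counts = df.groupby("pair")["v"].count()
    keep = counts.index[counts == 2]
    df = df[df["pair"].isin(keep)]
    n = len(keep)
    if n < 2:
        return float("nan")
    wide = df.groupby("pair")["v"].apply(lambda s: s.to_numpy()).to_dict()
    y = np.array([wide[k] for k in keep])  # (n_pairs, 2)
    return float(_icc_from_pairs(y[:, 0][None, :], y[:, 1][None, :])[0])


def _icc_from_pairs(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Vectorised ICC(1,1): y1, y2 are (n_probes, n_pairs) co-twin values."""
    n = y1.shape[1]
    mean_pair = (y1 + y2) / 2.0
    grand = mean_pair.mean(axis=1, keepdims=True)
    ssb = 2.0 * ((mean_pair - grand) ** 2).sum(axis=1)
    msb = ssb / (n - 1)
    ssw = (((y1 - mean_pair) ** 2) + ((y2 - mean_pair) ** 2)).sum(axis=1)
    msw = ssw / n
    denom = msb + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.where(denom > 0, (msb - msw) / denom, np.nan)
    return icc


def icc_by_zygosity(
    m: MethylationMatrix,
    cohort: TwinCohort,
    per_batch: bool = True,
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Per-probe MZ and DZ ICCs plus h2 = 2(ICC_MZ - ICC_DZ).

    Only pairs whose two members sit in the same batch contribute, and
    with ``per_batch`` ICCs are computed within each batch separately
    (one output row-block per batch); probes are never pooled across
    batches in that mode.
    """
    samples = cohort.samples
    batches = sorted(samples["batch_id"].unique()) if per_batch else ["all"]
    if per_batch and len(batches) == 1:
        warnings.warn("single batch present; computing one summary")
    out = []
    for batch in batches:
        rows = {"batch_id": batch}
        counts = {}
        for zyg in ("MZ", "DZ"):
            # only pairs assayed together in one batch are comparable
            pairs = [
                (a, b)
                for a, b in cohort.twin_pairs(zyg)
                if samples.loc[a, "batch_id"] == samples.loc[b, "batch_id"]
                and (batch == "all" or samples.loc[a, "batch_id"] == batch)
            ]
            counts[zyg] = len(pairs)
            if len(pairs) < min_pairs:
                rows[f"icc_{zyg.lower()}"] = np.full(m.n_probes, np.nan)
                continue
            y1 = m.betas[[a for a, _ in pairs]].to_numpy(dtype=float)
            y2 = m.betas[[b for _, b in pairs]].to_numpy(dtype=float)
            ok = np.isfinite(y1) & np.isfinite(y2)
            if ok.all():
                rows[f"icc_{zyg.lower()}"] = _icc_from_pairs(y1, y2)
            else:
                vals = np.empty(m.n_probes)
                labels = np.repeat(np.arange(len(pairs)), 2)
                for i in range(m.n_probes):
                    inter = np.column_stack([y1[i], y2[i]]).ravel()
                    vals[i] = probe_icc(inter, labels)
                rows[f"icc_{zyg.lower()}"] = vals
        df = pd.DataFrame(
            {
                "probe_id": m.probe_ids,
                "batch_id": batch,
                "icc_mz": rows.get("icc_mz"),
                "icc_dz": rows.get("icc_dz"),
                "n_mz_pairs": counts.get("MZ", 0),
                "n_dz_pairs": counts.get("DZ", 0),
            }
        )
        df["heritability"] = 2.0 * (df["icc_mz"] - df["icc_dz"])
        out.append(df)
    return pd.concat(out, ignore_index=True)


def pairwise_profile_correlations(
    m: MethylationMatrix,
    cohort: TwinCohort,
    within_batch: bool = True,
    max_unrelated: int | None = 5000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-profile Pearson correlations by pair type (MZ/DZ/unrelated).

    Twin pairs require both members in the same batch when
    ``within_batch``; unrelated pairs enumerate all cross-family
    same-batch pairs (seeded subsample if over ``max_unrelated``).
    Returns (per-pair table, group summary).
    """
    if m.n_probes == 0:
        raise ValueError("no probes")
    samples = cohort.samples
    B = m.betas

    def corr(a, b):
        x, y = B[a].to_numpy(dtype=float), B[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        return float(np.corrcoef(x[ok], y[ok])[0, 1])

    recs = []
    for zyg in ("MZ", "DZ"):
        for a, b in cohort.twin_pairs(zyg):
            if within_batch and samples.loc[a, "batch_id"] != samples.loc[b, "batch_id"]:
                continue
            recs.append((zyg, a, b, corr(a, b)))
    unrel = [
        (a, b)
        for a, b in combinations(sorted(samples.index), 2)
        if samples.loc[a, "family_id"] != samples.loc[b, "family_id"]
        and (not within_batch or samples.loc[a, "batch_id"] == samples.loc[b, "batch_id"])
    ]
    if max_unrelated is not None and len(unrel) > max_unrelated:
        rng = np.random.default_rng(seed)
        unrel = [unrel[i] for i in rng.choice(len(unrel), size=max_unrelated, replace=False)]
    for a, b in unrel:
        recs.append(("unrelated", a, b, corr(a, b)))
    table = pd.DataFrame(recs, columns=["group", "id1", "id2", "r"])
    summary = table.groupby("group")["r"].agg(["count", "mean", "median"]).reset_index()
    return table, summary


def heritability_summary(
    icc_df: pd.DataFrame,
    per_batch: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Genome-wide heritability summary per batch.

    Mean h2 with a bootstrap percentile 95% CI over probes, plus a
    paired Wilcoxon signed-rank test of the per-probe ICC_MZ vs ICC_DZ
    distributions.
    """
    if icc_df.empty:
        raise ValueError("empty ICC table")
    rng = np.random.default_rng(seed)
    group_col = "batch_id" if per_batch else None
    groups = icc_df.groupby(group_col) if group_col else [("all", icc_df)]
    rows = []
    for batch, df in groups:
        h2 = df["heritability"].to_numpy(dtype=float)
        h2 = h2[np.isfinite(h2)]
        if len(h2) == 0:
            continue
        boots = np.array(
            [h2[rng.integers(0, len(h2), size=len(h2))].mean() for _ in range(n_boot)]
        )
        ok = df.dropna(subset=["icc_mz", "icc_dz"])
        if len(ok) >= 10 and (ok["icc_mz"] != ok["icc_dz"]).any():
            wstat = stats.wilcoxon(ok["icc_mz"], ok["icc_dz"])
            wp = float(wstat.pvalue)
        else:
            wp = float("nan")
        rows.append(
            {
                "batch_id": batch if not isinstance(batch, tuple) else batch[0],
                "n_probes": int(len(h2)),
                "mean_icc_mz": float(np.nanmean(df["icc_mz"])),
                "mean_icc_dz": float(np.nanmean(df["icc_dz"])),
                "mean_h2": float(h2.mean()),
                "ci_low": float(np.percentile(boots, 2.5)),
                "ci_high": float(np.percentile(boots, 97.5)),
                "wilcoxon_p_mz_vs_dz": wp,
            }
        )
    return pd.DataFrame(rows)
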