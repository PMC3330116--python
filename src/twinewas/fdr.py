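"""Permutation-based FDR estimation shared by all scans.

FDR at a p-value threshold t is the average number of permuted-data
hits at t divided by the number of observed hits at t.  The reported
curve is monotonised q-value style (running minimum from the largest
threshold down), which makes FDR(t) non-decreasing in t; the 5%
threshold is the largest observed p-value whose monotonised FDR is
at or below the target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["permutation_fdr", "family_permutation"]


def permutation_fdr(
    observed_p: np.ndarray,
    permuted_p: np.ndarray,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Estimate FDR(t) on the observed p-value grid.

    Parameters
    ----------
    observed_p : p-values from the real scan (NaN entries ignored).
    permuted_p : array of p-values pooled from permutation replicates,
        shape (n_perm, n_units) or flat; each replicate is assumed to
        contribute the same number of units as the observed scan.
    alpha : target FDR level.

    Returns
    -------
    (curve, threshold): curve has columns threshold/n_observed/
    mean_permuted/fdr_raw/fdr; threshold is the largest observed p with
    monotonised FDR <= alpha (NaN if none).
    """
    obs = np.asarray(observed_p, dtype=float)
    obs = obs[np.isfinite(obs)]
    if obs.size == 0:
        raise ValueError("no observed p-values")
    if isinstance(permuted_p, (list, tuple)):
        n_perm = len(permuted_p)
        perm_flat = np.concatenate([np.asarray(a, dtype=float).ravel() for a in permuted_p])
    else:
        perm = np.asarray(permuted_p, dtype=float)
        if perm.ndim == 1:
            perm = perm[None, :]
        n_perm = perm.shape[0]
        perm_flat = perm.ravel()
    perm_flat = np.sort(perm_flat[np.isfinite(perm_flat)])
    grid = np.unique(obs)
    obs_sorted = np.sort(obs)
    n_obs = np.searchsorted(obs_sorted, grid, side="right")
    n_perm_hits = np.searchsorted(perm_flat, grid, side="right") / n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(n_obs > 0, n_perm_hits / n_obs, np.nan)
    fdr = np.minimum.accumulate(np.minimum(raw, np.inf)[::-1])[::-1]
    fdr = np.minimum(fdr, 1.0)
    curve = pd.DataFrame(
        {
            "threshold": grid,
            "n_observed": n_obs,
            "mean_permuted": n_perm_hits,
            "fdr_raw": raw,
            "fdr": fdr,
        }
    )
    sig = curve.loc[curve["fdr"] <= alpha, "threshold"]
    threshold = float(sig.max()) if len(sig) else float("nan")
    return curve, threshold


def family_permutation(cohort, rng: np.random.Generator) -> dict:
    """Twin-structure-preserving permutation of methylation profiles.

    Families are stratified by (size, zygosity); within each stratum the
    methylation column *blocks* (both co-twins' profiles together, in
    within-family id order) are reassigned among families.  Traits,
    covariates and missingness patterns stay with the individuals, so
    only the methylation-to-individual pairing is broken while within-
    pair co-methylation and twin correlation are preserved.

    Returns a mapping {individual_id: individual_id whose methylation
    profile it receives}.  Raises if any stratum has < 3 families
    (degenerate permutation space).
    """
    samples = cohort.samples
    strata: dict[tuple, list[list[str]]] = {}
    for _, grp in samples.groupby("family_id", sort=True):
        key = (len(grp), grp["zygosity"].iloc[0])
        strata.setdefault(key, []).append(sorted(grp.index))
    mapping: dict = {}
    for key, fams in strata.items():
        if len(fams) < 3:
            raise ValueError(
                f"permutation stratum {key} has only {len(fams)} families; twin-preserving permutation is degenerate"
            )
        order = rng.permutation(len(fams))
        for src, dst in zip(fams, [fams[i] for i in order]):
            for a, b in zip(src, dst):
                mapping[a] = b
    return mapping
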