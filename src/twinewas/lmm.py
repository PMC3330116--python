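"""Linear mixed-model machinery for twin cohorts.

The model for a response vector y (one probe, or one trait) is

    y = X beta + u_family + u_mzpair + e

with a random intercept per family (variance ``sigma2_f``), an extra
random intercept shared only within MZ pairs (``sigma2_z``), and iid
residuals (``sigma2_e``).  Marginal covariance of a co-twin pair is
``sigma2_f + sigma2_z * 1[MZ]``, so MZ pairs are at least as correlated
as DZ pairs — the random-effect encoding of family structure and
zygosity.

Because families have at most two members the covariance matrix is
block diagonal with 2x2 blocks, and an orthonormal sum/difference
rotation of each pair diagonalises every block: pair sums have variance
``sigma2_e (1 + 2 d)`` and pair differences ``sigma2_e``, with ``d``
the within-pair covariance ratio ((sigma2_f + sigma2_z)/sigma2_e for
MZ, sigma2_f/sigma2_e for DZ).  Writing b = sigma2_f/sigma2_e and
c = sigma2_z/sigma2_e, the transformed rows fall into five groups (MZ
sums, DZ sums, differences, non-MZ singletons, MZ singletons) whose GLS
weights are scalar functions of (b, c).  The weighted normal equations
are therefore linear combinations of five precomputed cross-product
matrices, making one profile-likelihood evaluation O(p^2) regardless of
sample size and allowing the (b, c) optimisation to be vectorised
across thousands of probes at once (coarse log-grid followed by a
zooming 3x3 pattern search).

Maximum likelihood is used for likelihood-ratio tests; REML is
available for variance-component reporting.  Profiled beta and sigma2_e
are closed-form at each (b, c).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import TwinCohort

__all__ = [
    "inverse_normal_transform",
    "TwinLMM",
    "FitResult",
    "lrt_pvalue",
    "design_matrix",
]

# coarse variance-ratio grid (sigma2 / sigma2_e); 0 covers the boundary
_GRID = np.array([0.0, 0.02, 0.08, 0.25, 0.7, 1.8, 4.5, 12.0])
# zoom factors for the per-probe pattern-search refinement
_ZOOM = (2.5, 1.6, 1.3, 1.14, 1.07, 1.03)


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Ranks r (ties averaged) map to normal quantiles at (r - 3/8)/(n + 1/4).
    Missing values stay missing and do not consume ranks.  Returns all
    NaN (no exception) when fewer than 3 non-missing values exist or all
    values are identical; callers treat an all-NaN return as "probe
    skipped".
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    n = int(ok.sum())
    if n < 3 or np.nanmax(x) == np.nanmin(x):
        return out
    r = stats.rankdata(x[ok], method="average")
    out[ok] = stats.norm.ppf((r - 0.375) / (n + 0.25))
    return out


@dataclass
class FitResult:
    """One fitted twin LMM."""

    beta: np.ndarray
    se: np.ndarray
    names: list
    sigma2_f: float
    sigma2_z: float
    sigma2_e: float
    loglik: float
    n_used: int
    converged: bool
    reml: bool = False

    def coef(self, name) -> tuple[float, float]:
        i = list(self.names).index(name)
        return float(self.beta[i]), float(self.se[i])

    def wald_p(self, name) -> float:
        b, se = self.coef(name)
        if se <= 0:
            return np.nan
        return float(2 * stats.norm.sf(abs(b) / se))


def lrt_pvalue(ll_full: float, ll_null: float, df: int) -> float:
    """Upper-tail chi-square p for 2(ll_full - ll_null), floored at 0."""
    stat = max(2.0 * (ll_full - ll_null), 0.0)
    return float(stats.chi2.sf(stat, df))


def design_matrix(
    cohort: TwinCohort,
    sample_ids,
    terms: dict | None = None,
    chip: bool = True,
    chip_order: bool = True,
    sex: bool = False,
) -> pd.DataFrame:
    """Fixed-effect design: intercept, chip dummies, chip order, extras.

    ``terms`` maps column name -> per-individual Series/array of extra
    covariates (age, a phenotype, a genotype dosage...).  Chip is
    categorical (dummy-coded against the first chip); chip order is the
    ordinal position on the chip, entered linearly.
    """
    sub = cohort.samples.loc[list(sample_ids)]
    cols = {"intercept": np.ones(len(sub))}
    if chip:
        dummies = pd.get_dummies(sub["chip_id"], prefix="chip", drop_first=True, dtype=float)
        for c in dummies.columns:
            cols[c] = dummies[c].to_numpy()
    if chip_order:
        cols["chip_position"] = sub["chip_position"].to_numpy(dtype=float)
    if sex:
        sx = sub["sex"].astype(str)
        if sx.nunique() > 1:
            cols["sex_male"] = (sx == "M").to_numpy(dtype=float)
    if terms:
        for name, vals in terms.items():
            v = pd.Series(vals)
            cols[name] = v.loc[list(sample_ids)].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=sub.index)


def _drop_aliased(X: np.ndarray, names: list) -> tuple[np.ndarray, list, list]:
    """Greedily drop columns that are linear combinations of earlier ones."""
    keep, dropped = [], []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


class TwinLMM:
    """Twin LMM engine bound to one cohort and one sample order.

    Parameters
    ----------
    cohort : TwinCohort
    sample_ids : ordered sample ids defining the row order of responses
        and design matrices passed to :meth:`fit` / :meth:`scan_lrt`.
    """

    def __init__(self, cohort: TwinCohort, sample_ids):
        self.sample_ids = list(sample_ids)
        if len(self.sample_ids) == 0:
            raise ValueError("no samples")
        sub = cohort.samples.loc[self.sample_ids]
        if sub["family_id"].nunique() == 0:
            raise ValueError("no families")
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        i1, i2, is_mz = [], [], []
        singles, single_is_mz = [], []
        for _, grp in sub.groupby("family_id", sort=True):
            idx = [pos[s] for s in sorted(grp.index)]
            if len(idx) == 2 and grp["zygosity"].iloc[0] != "singleton":
                i1.append(idx[0])
                i2.append(idx[1])
                is_mz.append(grp["zygosity"].iloc[0] == "MZ")
            else:
                for s in sorted(grp.index):
                    singles.append(pos[s])
                    single_is_mz.append(sub.loc[s, "zygosity"] == "MZ")
        self.i1 = np.array(i1, dtype=int)
        self.i2 = np.array(i2, dtype=int)
        self.pair_is_mz = np.array(is_mz, dtype=bool)
        self.singles = np.array(singles, dtype=int)
        self.single_is_mz = np.array(single_is_mz, dtype=bool)
        self.n = len(self.sample_ids)
        self.n_mz = int(self.pair_is_mz.sum())
        self.n_dz = int((~self.pair_is_mz).sum())
        self.n_sgl_mz = int(self.single_is_mz.sum())
        self.n_sgl_dz = int((~self.single_is_mz).sum())
        # identifiability: sigma2_f needs DZ pairs or singletons, sigma2_z MZ pairs
        self.f_identifiable = (self.n_dz + len(self.singles)) > 0
        self.z_identifiable = (self.n_mz + self.n_sgl_mz) > 0 and self.n_mz > 0

    # ----- structure helpers ------------------------------------------

    def transform(self, M: np.ndarray) -> list[np.ndarray]:
        """Split rows (samples) into the five homoscedastic groups.

        Returns [MZ pair sums, DZ pair sums, pair differences, non-MZ
        singleton rows, MZ singleton rows], each scaled so its variance
        is ``sigma2_e * v_k(b, c)``.
        """
        M = np.asarray(M, dtype=float)
        one_d = M.ndim == 1
        if one_d:
            M = M[:, None]
        s = (M[self.i1] + M[self.i2]) / np.sqrt(2.0)
        d = (M[self.i1] - M[self.i2]) / np.sqrt(2.0)
        parts = [
            s[self.pair_is_mz],
            s[~self.pair_is_mz],
            d,
            M[self.singles][~self.single_is_mz],
            M[self.singles][self.single_is_mz],
        ]
        return [p[:, 0] for p in parts] if one_d else parts

    @staticmethod
    def _weights(b, c):
        """1/v_k for the five groups at ratio arrays (b, c)."""
        b = np.asarray(b, dtype=float)
        c = np.asarray(c, dtype=float)
        return np.stack(
            [
                1.0 / (1.0 + 2.0 * (b + c)),  # MZ sums
                1.0 / (1.0 + 2.0 * b),  # DZ sums
                np.ones_like(b),  # differences
                1.0 / (1.0 + b),  # non-MZ singletons
                1.0 / (1.0 + b + c),  # MZ singletons
            ]
        )

    def _logdet_v(self, b, c):
        return (
            self.n_mz * np.log1p(2.0 * (np.asarray(b) + np.asarray(c)))
            + self.n_dz * np.log1p(2.0 * np.asarray(b))
            + self.n_sgl_dz * np.log1p(np.asarray(b))
            + self.n_sgl_mz * np.log1p(np.asarray(b) + np.asarray(c))
        )

    def _components(self, X: np.ndarray, Y: np.ndarray):
        """Per-group cross products: A_k = Zk'Zk, B_k = Zk'Yk, yy_k."""
        Zs = self.transform(X)
        Ys = self.transform(Y)
        A = np.stack([z.T @ z for z in Zs])  # (5, p, p)
        B = np.stack([z.T @ y for z, y in zip(Zs, Ys)])  # (5, p, P)
        yy = np.stack([np.einsum("ij,ij->j", y, y) for y in Ys])  # (5, P)
        return A, B, yy

    def _ll_at(self, comp, b, c, reml=False, want_fit=False):
        """Profile log-likelihood at per-probe ratio vectors (b, c).

        comp is the output of :meth:`_components`; b, c are scalars or
        (P,) arrays.  Returns ll (P,), and with ``want_fit`` also
        (beta (P,p), cov-scale matrices (P,p,p), sigma2_e (P,)).
        """
        A_k, B_k, yy_k = comp
        P = B_k.shape[2]
        b = np.broadcast_to(np.asarray(b, dtype=float), (P,))
        c = np.broadcast_to(np.asarray(c, dtype=float), (P,))
        w = self._weights(b, c)  # (5, P)
        A = np.einsum("kp,kij->pij", w, A_k)  # (P, p, p)
        By = np.einsum("kp,kip->pi", w, B_k)  # (P, p)
        yy = np.einsum("kp,kp->p", w, yy_k)
        try:
            beta = np.linalg.solve(A, By[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(A[j], By[j], rcond=None)[0] for j in range(P)])
        rss = np.maximum(yy - np.einsum("pi,pi->p", By, beta), 1e-300)
        n, p = self.n, A_k.shape[1]
        logv = self._logdet_v(b, c)
        if reml:
            dof = n - p
            s2 = rss / dof
            _, logdetA = np.linalg.slogdet(A)
            ll = -0.5 * (dof * (np.log(2 * np.pi * s2) + 1.0) + logv + logdetA)
        else:
            s2 = rss / n
            ll = -0.5 * (n * (np.log(2 * np.pi * s2) + 1.0) + logv)
        if want_fit:
            return ll, beta, A, s2
        return ll

    # ----- variance-ratio optimisation --------------------------------

    def _optimise(self, comp, reml=False, extra_zoom=(), init_bc=None):
        """Coarse grid + zooming pattern search, vectorised across probes.

        ``init_bc`` = (b0, c0) arrays warm-starts the search (e.g. from
        the null model's ratios) and skips the coarse grid.  Returns
        (b, c, ll) arrays and a convergence flag array.
        """
        P = comp[1].shape[2]
        floor = 1e-4  # ratios below this are indistinguishable from 0
        if init_bc is not None:
            best_b = np.broadcast_to(np.asarray(init_bc[0], dtype=float), (P,)).copy()
            best_c = np.broadcast_to(np.asarray(init_bc[1], dtype=float), (P,)).copy()
            best_ll = self._ll_at(comp, best_b, best_c, reml=reml).copy()
            zoom = (3.0, 2.0) + tuple(_ZOOM)[1:]
        else:
            bs = _GRID if self.f_identifiable else np.array([0.0])
            cs = _GRID if self.z_identifiable else np.array([0.0])
            best_ll = np.full(P, -np.inf)
            best_b = np.zeros(P)
            best_c = np.zeros(P)
            for b in bs:
                for c in cs:
                    ll = self._ll_at(comp, b, c, reml=reml)
                    upd = ll > best_ll
                    best_ll[upd] = ll[upd]
                    best_b[upd] = b
                    best_c[upd] = c
            zoom = tuple(_ZOOM)
        prev_ll = best_ll.copy()
        for s in zoom + tuple(extra_zoom):
            cand_b = [best_b] if not self.f_identifiable else [
                best_b,
                np.maximum(best_b / s, floor) * (best_b > 0),
                np.maximum(best_b, floor) * s,
            ]
            cand_c = [best_c] if not self.z_identifiable else [
                best_c,
                np.maximum(best_c / s, floor) * (best_c > 0),
                np.maximum(best_c, floor) * s,
            ]
            for b in cand_b:
                for c in cand_c:
                    ll = self._ll_at(comp, b, c, reml=reml)
                    upd = ll > best_ll
                    best_ll[upd] = ll[upd]
                    best_b[upd] = np.broadcast_to(b, (P,))[upd]
                    best_c[upd] = np.broadcast_to(c, (P,))[upd]
        converged = (best_ll - prev_ll) < np.inf  # refined below by callers
        return best_b, best_c, best_ll, converged

    # ----- public fitting API -----------------------------------------

    def fit(self, y, X, reml: bool = False, tol: float = 1e-8, max_rounds: int = 200) -> FitResult:
        """Fit one response; X may be a DataFrame (column names kept).

        The zoom search continues until the log-likelihood improves by
        less than ``tol`` between rounds (or ``max_rounds`` shrinkage
        rounds), the deterministic analogue of an iteration cap.
        """
        names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
        Xv = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(y) & np.isfinite(Xv).all(axis=1)
        if not ok.all():
            sub = self._subset(ok)
            return sub.fit(y[ok], pd.DataFrame(Xv[ok], columns=names), reml=reml, tol=tol)
        Xv, names, dropped = _drop_aliased(Xv, names)
        if dropped:
            warnings.warn(f"dropping aliased design columns: {dropped}")
        if len(y) < Xv.shape[1] + 3:
            raise ValueError("too few complete cases for the requested design")
        comp = self._components(Xv, y[:, None])
        b, c, ll, _ = self._optimise(comp, reml=reml)
        # continue shrinking until ll gain < tol
        conv = False
        s = 1.02
        for _ in range(max_rounds):
            ll_prev = ll.copy()
            b, c, ll, _ = self._refine_once(comp, b, c, ll, s, reml)
            if ll[0] - ll_prev[0] < tol:
                conv = True
                break
            s = max(1.0 + (s - 1.0) * 0.7, 1.0005)
        ll_f, beta, A, s2 = self._ll_at(comp, b, c, reml=reml, want_fit=True)
        cov = s2[0] * np.linalg.pinv(A[0])
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        s2e = float(s2[0])
        return FitResult(
            beta=beta[0],
            se=se,
            names=names,
            sigma2_f=float(b[0] * s2e) if b[0] > 2e-4 else 0.0,
            sigma2_z=float(c[0] * s2e) if c[0] > 2e-4 else 0.0,
            sigma2_e=s2e,
            loglik=float(ll_f[0]),
            n_used=int(self.n),
            converged=conv,
            reml=reml,
        )

    def _refine_once(self, comp, b, c, ll, s, reml):
        floor = 1e-4
        best_b, best_c, best_ll = b.copy(), c.copy(), ll.copy()
        cand_b = [b] if not self.f_identifiable else [b, np.maximum(b / s, floor) * (b > 0), np.maximum(b, floor) * s]
        cand_c = [c] if not self.z_identifiable else [c, np.maximum(c / s, floor) * (c > 0), np.maximum(c, floor) * s]
        for bb in cand_b:
            for cc in cand_c:
                l2 = self._ll_at(comp, bb, cc, reml=reml)
                upd = l2 > best_ll
                best_ll[upd] = l2[upd]
                best_b[upd] = np.broadcast_to(bb, bb.shape)[upd]
                best_c[upd] = np.broadcast_to(cc, cc.shape)[upd]
        return best_b, best_c, best_ll, None

    def _subset(self, mask: np.ndarray) -> "TwinLMM":
        """Engine restricted to samples where mask is True; a surviving
        member of a broken pair is treated as a singleton of its zygosity."""
        sub = TwinLMM.__new__(TwinLMM)
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        pos = {s: i for i, s in enumerate(ids)}
        keep_old = {self.sample_ids.index(s) for s in ids}
        i1, i2, is_mz, singles, s_mz = [], [], [], [], []
        for a, bb, mz in zip(self.i1, self.i2, self.pair_is_mz):
            ina, inb = a in keep_old, bb in keep_old
            if ina and inb:
                i1.append(pos[self.sample_ids[a]])
                i2.append(pos[self.sample_ids[bb]])
                is_mz.append(mz)
            elif ina or inb:
                k = a if ina else bb
                singles.append(pos[self.sample_ids[k]])
                s_mz.append(mz)
        for k, mz in zip(self.singles, self.single_is_mz):
            if k in keep_old:
                singles.append(pos[self.sample_ids[k]])
                s_mz.append(mz)
        sub.sample_ids = ids
        sub.i1 = np.array(i1, dtype=int)
        sub.i2 = np.array(i2, dtype=int)
        sub.pair_is_mz = np.array(is_mz, dtype=bool)
        sub.singles = np.array(singles, dtype=int)
        sub.single_is_mz = np.array(s_mz, dtype=bool)
        sub.n = len(ids)
        sub.n_mz = int(sub.pair_is_mz.sum())
        sub.n_dz = int((~sub.pair_is_mz).sum())
        sub.n_sgl_mz = int(sub.single_is_mz.sum())
        sub.n_sgl_dz = int((~sub.single_is_mz).sum())
        sub.f_identifiable = (sub.n_dz + len(sub.singles)) > 0
        sub.z_identifiable = sub.n_mz > 0
        return sub

    def scan_lrt(self, Y: np.ndarray, X_full, X_null, term: str, bartlett: bool = True) -> pd.DataFrame:
        """LRT of ``term`` for many responses sharing one design.

        Y is (n_samples, n_probes); X_full must contain every column of
        X_null plus ``term``.  Rows with missing design values must be
        removed by the caller; probes with missing responses fall back
        to per-probe complete-case fits.  Returns a DataFrame with beta,
        se (Wald, at the ML variance components), p (LRT) and
        bookkeeping columns.

        With ``bartlett`` (default) the LRT statistic is scaled by
        (n - p)/n before the chi-square tail — a small-sample correction
        for the downward bias of ML residual variance that matters once
        the fixed-effect dimension (chip dummies) is non-trivial
        relative to the sample size.
        """
        names_f = list(X_full.columns)
        names_n = list(X_null.columns)
        extra = [cn for cn in names_f if cn not in names_n]
        if extra != [term] or any(cn not in names_f for cn in names_n):
            raise ValueError("null design must be nested in full design, differing by the term")
        Xf = X_full.to_numpy(dtype=float)
        Xn = X_null.to_numpy(dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, P = Y.shape
        term_ix = names_f.index(term)
        complete = np.isfinite(Y).all(axis=0)
        out = {
            "beta": np.full(P, np.nan),
            "se": np.full(P, np.nan),
            "ll_full": np.full(P, np.nan),
            "ll_null": np.full(P, np.nan),
            "sigma2_f": np.full(P, np.nan),
            "sigma2_z": np.full(P, np.nan),
            "sigma2_e": np.full(P, np.nan),
            "n_used": np.full(P, n, dtype=int),
            "converged": np.ones(P, dtype=bool),
        }
        if complete.any():
            idx = np.where(complete)[0]
            Yc = Y[:, idx]
            comp_f = self._components(Xf, Yc)
            comp_n = self._components(Xn, Yc)
            bf, cf, llf, _ = self._optimise(comp_f)
            bn, cn, lln, _ = self._optimise(comp_n)
            _, beta, A, s2 = self._ll_at(comp_f, bf, cf, want_fit=True)
            Ainv = np.linalg.pinv(A)
            se = np.sqrt(np.maximum(s2 * Ainv[:, term_ix, term_ix], 0.0))
            out["beta"][idx] = beta[:, term_ix]
            out["se"][idx] = se
            out["ll_full"][idx] = llf
            out["ll_null"][idx] = lln
            out["sigma2_f"][idx] = bf * s2
            out["sigma2_z"][idx] = cf * s2
            out["sigma2_e"][idx] = s2
        for j in np.where(~complete)[0]:
            yj = Y[:, j]
            ok = np.isfinite(yj)
            if ok.sum() < Xf.shape[1] + 3:
                out["converged"][j] = False
                continue
            subeng = self._subset(ok)
            rf = subeng.fit(yj[ok], pd.DataFrame(Xf[ok], columns=names_f))
            rn = subeng.fit(yj[ok], pd.DataFrame(Xn[ok], columns=names_n))
            bcoef, scoef = rf.coef(term)
            out["beta"][j], out["se"][j] = bcoef, scoef
            out["ll_full"][j], out["ll_null"][j] = rf.loglik, rn.loglik
            out["sigma2_f"][j], out["sigma2_z"][j], out["sigma2_e"][j] = (
                rf.sigma2_f,
                rf.sigma2_z,
                rf.sigma2_e,
            )
            out["n_used"][j] = rf.n_used
            out["converged"][j] = rf.converged and rn.converged
        stat = np.maximum(2.0 * (out["ll_full"] - out["ll_null"]), 0.0)
        if bartlett:
            stat = stat * (out["n_used"] - Xf.shape[1]) / out["n_used"]
        out["p"] = stats.chi2.sf(stat, df=1)
        return pd.DataFrame(out)
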