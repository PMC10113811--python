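"""Binomial GEE with AR1 working correlation for diel presence analysis.

The marginal model is a logistic regression of hourly acoustic presence on
light regime (four-level factor) and, optionally, regime-specific slopes for
the hourly ambient-noise level, estimated by generalized estimating equations
(Liang & Zeger).  Hours within a detection day form a cluster; the working
correlation is AR1, corr(e_t, e_s) = alpha^|t-s| on the hour index, with
alpha re-estimated from lag-1 Pearson residual products at each iteration.
Uncertainty comes from the robust (sandwich) covariance, so standard errors
are valid even when the AR1 working structure is misspecified.

Organised statsmodels-style: build a :class:`PresenceGEE` model from data
(usually via :meth:`PresenceGEE.from_dataframe` on a detection-day table),
call :meth:`~PresenceGEE.fit`, and read estimates, contrasts, compact letter
displays and serial-correlation diagnostics off the returned
:class:`PresenceGEEResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .solar import REGIMES

__all__ = [
    "PresenceGEE",
    "PresenceGEEResults",
    "fit_gee",
    "wald_contrast",
    "letter_display",
    "durbin_watson",
    "acf",
]


# ---------------------------------------------------------------------------
# diagnostics (module-level operations; results methods delegate here)

def durbin_watson(residuals: np.ndarray, groups: np.ndarray | None = None) -> float:
    """Durbin-Watson statistic, pooled across clusters.

    d = sum_clusters sum_{t>=2} (e_t - e_{t-1})^2 / sum e^2, in [0, 4];
    ~2 under serial independence.  Successive differences never straddle a
    cluster boundary.
    """
    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least two residuals")
    den = float(np.sum(e**2))
    if den == 0:
        raise ValueError("Durbin-Watson undefined for all-zero residuals")
    if groups is None:
        num = float(np.sum(np.diff(e) ** 2))
    else:
        groups = np.asarray(groups)
        d = np.diff(e)
        same = groups[1:] == groups[:-1]
        num = float(np.sum(d[same] ** 2))
    return num / den


def acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelation r_0..r_max_lag (r_0 = 1 exactly)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= max_lag:
        raise ValueError("series must be longer than max_lag")
    xc = x - x.mean()
    den = float(np.sum(xc**2))
    if den == 0:
        raise ValueError("ACF undefined for zero-variance input")
    return np.array([1.0] + [float(np.sum(xc[: n - k] * xc[k:])) / den for k in range(1, max_lag + 1)])


def letter_display(pairs: dict[tuple[str, str], bool], levels: list[str] | None = None) -> dict[str, str]:
    """Compact letter display from pairwise significance.

    ``pairs`` maps each unordered level pair to True when the pair differs
    significantly.  Letters are the maximal cliques of the non-significance
    graph, so two levels share a letter iff their contrast is non-significant.
    """
    if levels is None:
        levels = sorted({lv for pair in pairs for lv in pair})
    adj = {lv: set() for lv in levels}
    for (a, b), sig in pairs.items():
        if not sig and a != b:
            adj[a].add(b)
            adj[b].add(a)

    cliques: list[set[str]] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in sorted(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(levels), set())
    order = {lv: i for i, lv in enumerate(levels)}
    cliques.sort(key=lambda c: min(order[v] for v in c))
    letters = {lv: "" for lv in levels}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for lv in clique:
            letters[lv] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


# ---------------------------------------------------------------------------
# model

class PresenceGEE:
    """Marginal logistic model for clustered binary presence.

    Parameters
    ----------
    endog : (n,) binary response.
    exog : (n, p) design matrix (include the intercept column).
    groups : (n,) cluster identifiers; observations need not be sorted.
    time : (n,) integer within-cluster time index (hour); gaps widen the
        working correlation as alpha**gap.  Defaults to observation order.
    cov_struct : "ar1" or "independence".
    """

    def __init__(self, endog, exog, groups, time=None, cov_struct: str = "ar1", exog_names=None):
        endog = np.asarray(endog, dtype=float)
        exog = np.asarray(exog, dtype=float)
        groups = np.asarray(groups)
        if cov_struct not in ("ar1", "independence"):
            raise ValueError(f"unknown working correlation {cov_struct!r}")
        if set(np.unique(endog)) - {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        if exog.ndim != 2 or len(exog) != len(endog) or len(groups) != len(endog):
            raise ValueError("endog, exog and groups must align")
        time = np.arange(len(endog)) if time is None else np.asarray(time, dtype=int)
        order = np.lexsort((time, groups))
        self.endog = endog[order]
        self.exog = exog[order]
        self.groups = groups[order]
        self.time = time[order]
        self.cov_struct = cov_struct
        self.exog_names = list(exog_names) if exog_names is not None else [f"x{j}" for j in range(exog.shape[1])]
        # cluster slices on the sorted arrays
        _, starts = np.unique(self.groups, return_index=True)
        starts = np.sort(starts)
        self._slices = [slice(s, e) for s, e in zip(starts, list(starts[1:]) + [len(endog)])]
        if len(self._slices) < 2:
            raise ValueError("need at least two clusters")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        # metadata filled by from_dataframe for contrast construction
        self._regime_info: dict | None = None

    # -- construction from a detection-day table ---------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        response: str = "presence",
        regime_col: str = "regime",
        noise_col: str | None = None,
        reference: str = "night",
        cluster_cols: tuple[str, ...] | None = None,
        time_col: str = "hour_of_day",
        cov_struct: str = "ar1",
    ) -> "PresenceGEE":
        """Build the diel model from an hourly detection-day table.

        Design: intercept + regime dummies (``reference`` omitted) and, when
        ``noise_col`` is given, one mean-centred noise slope per regime (the
        "effect of noise in each light regime").  Clusters default to
        site-date (the detection day); the within-day hour is the AR1 index.
        """
        df = df.copy()
        levels = [r for r in REGIMES if r in set(df[regime_col])]
        if reference not in levels:
            reference = levels[0]
        if cluster_cols is None:
            df["_date"] = pd.to_datetime(df["utc_hour"], utc=True).dt.date.astype(str)
            cluster_cols = ("site", "_date") if "site" in df.columns else ("_date",)
        groups = df[list(cluster_cols)].astype(str).agg("|".join, axis=1).to_numpy()
        n = len(df)
        cols = [np.ones(n)]
        names = ["intercept"]
        for lv in levels:
            if lv == reference:
                continue
            cols.append((df[regime_col] == lv).to_numpy(dtype=float))
            names.append(f"regime[{lv}]")
        noise_mean = None
        if noise_col is not None:
            noise_mean = float(df[noise_col].mean())
            centred = df[noise_col].to_numpy(dtype=float) - noise_mean
            for lv in levels:
                cols.append(centred * (df[regime_col] == lv).to_numpy(dtype=float))
                names.append(f"noise:{lv}")
        model = cls(
            endog=df[response].to_numpy(),
            exog=np.column_stack(cols),
            groups=groups,
            time=df[time_col].to_numpy(dtype=int),
            cov_struct=cov_struct,
            exog_names=names,
        )
        model._regime_info = {"levels": levels, "reference": reference, "noise_mean": noise_mean}
        return model

    # -- fitting ------------------------------------------------------------

    def _corr_solve(self, alpha: float, dt: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        """Solve R x = rhs for the AR1 correlation on time offsets ``dt``."""
        if self.cov_struct == "independence" or alpha == 0.0:
            return rhs
        R = alpha ** np.abs(dt[:, None] - dt[None, :])
        return np.linalg.solve(R, rhs)

    def fit(self, maxiter: int = 100, tol: float = 1e-8, start_params=None) -> "PresenceGEEResults":
        """Iterate estimating equations to convergence (relative coefficient
        change below ``tol``); robust sandwich covariance at the solution."""
        y, X = self.endog, self.exog
        n, p = X.shape
        if y.min() == y.max():
            raise ValueError("separation: response is constant; the logistic fit diverges")
        beta = np.zeros(p) if start_params is None else np.asarray(start_params, dtype=float)
        alpha = 0.0
        converged = False
        n_iter = 0
        for n_iter in range(1, maxiter + 1):
            eta = X @ beta
            mu = expit(eta)
            var = mu * (1 - mu)
            r = (y - mu) / np.sqrt(np.maximum(var, 1e-12))
            phi = float(np.sum(r**2) / max(n - p, 1))
            if self.cov_struct == "ar1":
                num, n_pairs = 0.0, 0
                for sl in self._slices:
                    rs, ts = r[sl], self.time[sl]
                    lag1 = np.flatnonzero(np.diff(ts) == 1)
                    num += float(np.sum(rs[lag1] * rs[lag1 + 1]))
                    n_pairs += len(lag1)
                alpha = num / (max(n_pairs - p, 1) * phi) if n_pairs else 0.0
                alpha = float(np.clip(alpha, -0.99, 0.99))
            B = np.zeros((p, p))
            score = np.zeros(p)
            M = np.zeros((p, p))
            sqv = np.sqrt(np.maximum(var, 1e-12))
            for sl in self._slices:
                U = sqv[sl, None] * X[sl]  # sqrt(A) X
                rhs = np.column_stack([U, r[sl]])
                sol = self._corr_solve(alpha, self.time[sl], rhs)
                RU, Rr = sol[:, :p], sol[:, p]
                B += U.T @ RU
                si = U.T @ Rr
                score += si
                M += np.outer(si, si)
            try:
                step = np.linalg.solve(B, score)
            except np.linalg.LinAlgError as exc:
                raise ValueError("singular GEE weighted information; check design") from exc
            # step-halving against runaway coefficients
            while np.max(np.abs(beta + step)) > 50 and np.max(np.abs(step)) > 1e-3:
                step /= 2.0
            beta = beta + step
            if np.max(np.abs(beta)) > 40:
                raise ValueError("separation: coefficients diverging; data separate the response")
            if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
                converged = True
                break
        if not converged:
            warnings.warn("GEE did not converge; returning last iterate")
        Binv = np.linalg.inv(B)
        cov = Binv @ M @ Binv
        cov = (cov + cov.T) / 2.0
        eta = X @ beta
        mu = expit(eta)
        resid = (y - mu) / np.sqrt(np.maximum(mu * (1 - mu), 1e-12))
        return PresenceGEEResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_robust=pd.DataFrame(cov, index=self.exog_names, columns=self.exog_names),
            ar1_alpha=alpha if self.cov_struct == "ar1" else 0.0,
            scale=float(np.sum(resid**2) / max(n - p, 1)),
            converged=converged,
            n_iter=n_iter,
            fittedvalues=mu,
            resid_pearson=resid,
        )


@dataclass
class PresenceGEEResults:
    """Fitted GEE: coefficients, robust covariance, diagnostics, displays."""

    model: PresenceGEE
    params: pd.Series
    cov_robust: pd.DataFrame
    ar1_alpha: float
    scale: float
    converged: bool
    n_iter: int
    fittedvalues: np.ndarray
    resid_pearson: np.ndarray

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust.values)), index=self.params.index)

    @property
    def n_obs(self) -> int:
        return len(self.model.endog)

    @property
    def n_clusters(self) -> int:
        return len(self.model._slices)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    # -- contrasts and letters ----------------------------------------------

    def _design_row(self, regime: str) -> np.ndarray:
        """Design row for a regime at the mean (centred 0) noise level."""
        info = self.model._regime_info
        if info is None:
            raise ValueError("contrasts need a model built via from_dataframe")
        if regime not in info["levels"]:
            raise ValueError(f"regime {regime!r} not in model levels {info['levels']}")
        row = np.zeros(len(self.params))
        names = list(self.params.index)
        row[names.index("intercept")] = 1.0
        key = f"regime[{regime}]"
        if key in names:
            row[names.index(key)] = 1.0
        return row

    def wald_contrast(self, pair: tuple[str, str]) -> dict:
        """Logit-scale contrast regime_i - regime_j at mean noise, robust z test."""
        c = self._design_row(pair[0]) - self._design_row(pair[1])
        est = float(c @ self.params.values)
        se = float(np.sqrt(c @ self.cov_robust.values @ c))
        if se == 0:
            z, pval = 0.0, 1.0
        else:
            z = est / se
            pval = 2.0 * float(norm.sf(abs(z)))
        return {"pair": pair, "estimate": est, "se": se, "z": z, "p": pval}

    def contrasts(self) -> pd.DataFrame:
        """All pairwise regime contrasts (unadjusted two-sided normal p-values)."""
        levels = self.model._regime_info["levels"]
        rows = [
            self.wald_contrast((levels[i], levels[j]))
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
        return pd.DataFrame(rows)

    def letters(self, alpha: float = 0.05, holm: bool = False) -> dict[str, str]:
        """Compact letter display: regimes sharing a letter do not differ at
        ``alpha``.  Optional Holm step-down adjustment of the six p-values."""
        con = self.contrasts()
        pvals = con["p"].to_numpy()
        if holm:
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * pvals[idx])
                adj[idx] = min(running, 1.0)
            pvals = adj
        sig = {tuple(pair): bool(pv < alpha) for pair, pv in zip(con["pair"], pvals)}
        return letter_display(sig, levels=self.model._regime_info["levels"])

    # -- diagnostics ---------------------------------------------------------

    def durbin_watson(self) -> float:
        return durbin_watson(self.resid_pearson, groups=self.model.groups)

    def acf(self, max_lag: int = 24) -> np.ndarray:
        return acf(self.resid_pearson, max_lag)

    def summary(self, alpha: float = 0.05) -> str:
        z = self.params / self.bse
        pvals = 2 * norm.sf(np.abs(z))
        ci = self.conf_int(alpha)
        lines = [
            "Binomial GEE (logit link), working correlation: "
            + self.model.cov_struct,
            f"n_obs = {self.n_obs}, clusters = {self.n_clusters}, "
            f"converged = {self.converged} in {self.n_iter} iterations",
            f"AR1 alpha = {self.ar1_alpha:.4f}, scale = {self.scale:.4f}",
            "",
            f"{'term':<16}{'coef':>10}{'rob.se':>10}{'z':>8}{'P>|z|':>9}"
            f"{'[' + format(1 - alpha, '.0%'):>10}{'CI]':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{z[name]:>8.2f}{pvals[list(self.params.index).index(name)]:>9.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        try:
            lines.append("")
            lines.append(f"Durbin-Watson (pooled within clusters): {self.durbin_watson():.3f}")
        except ValueError:
            pass
        return "\n".join(lines)


def fit_gee(
    table: pd.DataFrame,
    noise_col: str | None = None,
    reference: str = "night",
    cov_struct: str = "ar1",
    **fit_kwargs,
) -> PresenceGEEResults:
    """One-call fit of the diel presence GEE on a detection-day table."""
    model = PresenceGEE.from_dataframe(
        table, noise_col=noise_col, reference=reference, cov_struct=cov_struct
    )
    return model.fit(**fit_kwargs)


def wald_contrast(fit: PresenceGEEResults, pair: tuple[str, str]) -> dict:
    """Module-level convenience mirroring :meth:`PresenceGEEResults.wald_contrast`."""
    return fit.wald_contrast(pair)
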