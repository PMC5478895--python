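"""Normalization and per-feature factorial linear modelling.

The model describes log2 abundance of each feature (transcript, protein or
metabolite) in a 2x2 factorial chemostat study::

    expr = b0 + b_Nlim * x_Nlim + b_DGA * x_DGA + b_DGAxNlim * x_DGA * x_Nlim + e

Counts are filtered on CPM support, scaled with trimmed-mean-of-M-values
(TMM) factors, log2-CPM transformed, and fitted feature-wise by (weighted)
least squares.  Residual variances are moderated with an empirical-Bayes
scaled inverse chi-square prior estimated by moment matching on log s^2,
yielding moderated t statistics with augmented degrees of freedom; P values
are Benjamini-Hochberg adjusted per coefficient across features.

The same class fits protein and metabolite matrices: construct with
:meth:`FactorialDE.from_counts` for raw counts or directly from an
already-log-scale matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import StudyDesign

__all__ = [
    "COEF_NAMES",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "voom_weights",
    "adjust_bh",
    "FactorialDE",
    "FactorialDEResults",
]

COEF_NAMES = ("Intercept", "Nlim", "DGA", "DGAxNlim")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def cpm(counts: pd.DataFrame, lib_sizes: np.ndarray | None = None) -> pd.DataFrame:
    """Counts per million, per library."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_numpy(float)
    return counts / lib_sizes * 1e6


def filter_low_counts(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    min_libraries: int = 3,
    lib_sizes: np.ndarray | None = None,
) -> pd.DataFrame:
    """Keep features with CPM strictly above ``min_cpm`` in at least
    ``min_libraries`` libraries."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_numpy(float)
    if np.any(lib_sizes <= 0):
        raise ValueError("library sizes must be positive")
    keep = (cpm(counts, lib_sizes) > min_cpm).sum(axis=1) >= min_libraries
    if not keep.any():
        warnings.warn("CPM filter removed every feature", stacklevel=2)
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors (Robinson & Oshlack).

    For each library against a reference library, per-gene log ratios
    M = log2 relative abundance ratio and average abundances A are computed
    over genes expressed in both; the most extreme ``trim_m`` fraction of M
    on each side and ``trim_a`` of A are discarded, and the factor is
    2**(weighted mean of the kept M) with inverse asymptotic binomial
    variance weights.  Factors are rescaled to geometric mean 1.

    The reference defaults to the library whose upper-quartile CPM is
    closest to the mean upper-quartile CPM.
    """
    y = counts.to_numpy(float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"library {bad!r} has no counts after filtering")
    if ref_sample is None:
        uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)

    log_factors = np.zeros(y.shape[1])
    yr, nr = y[:, ref_idx], lib[ref_idx]
    for j in range(y.shape[1]):
        if j == ref_idx:
            continue
        yk, nk = y[:, j], lib[j]
        ok = (yk > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(f"no shared expressed genes with reference for {counts.columns[j]!r}")
        pk, pr = yk[ok] / nk, yr[ok] / nr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (nk - yk[ok]) / (nk * yk[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        n = m.size
        # double trim by rank, as in the original formulation
        rm = stats.rankdata(m, method="ordinal")
        ra = stats.rankdata(a, method="ordinal")
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            keep = np.ones(n, bool)
        with np.errstate(divide="ignore"):
            log_factors[j] = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    factors = 2.0 ** (log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame,
    factors: pd.Series | None = None,
    lib_sizes: np.ndarray | None = None,
    prior_count: float = 0.5,
    offset: float = 1.0,
) -> pd.DataFrame:
    """log2((count + 0.5) / (lib_size * factor + 1) * 1e6)."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).to_numpy(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib_sizes * factors.loc[counts.columns].to_numpy(float)
    return np.log2((counts + prior_count) / (eff + offset) * 1e6)


def voom_weights(
    expr: pd.DataFrame,
    design_matrix: pd.DataFrame,
    lib_sizes: np.ndarray,
    frac: float = 0.5,
) -> pd.DataFrame:
    """Precision weights from a mean-variance trend fit.

    A feature-wise OLS fit yields residual standard deviations; the square
    root of SD is regressed (lowess) on the mean log2 count, the trend is
    evaluated at each observation's fitted log2 count, and the weight is the
    inverse fourth power of the trend value.
    """
    X = design_matrix.to_numpy(float)
    Y = expr.to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    dfr = X.shape[0] - X.shape[1]
    sd = np.sqrt((resid**2).sum(axis=1) / dfr)
    # mean log2 count per feature on the count scale used for the trend
    mean_log_count = Y.mean(axis=1) + np.log2(np.mean(lib_sizes) + 1.0) - np.log2(1e6)
    trend = lowess(np.sqrt(sd), mean_log_count, frac=frac, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    fitted_log_count = fitted + np.log2(np.mean(lib_sizes) + 1.0) - np.log2(1e6)
    interp = np.interp(fitted_log_count, tx, ty)
    w = np.clip(interp, 1e-6, None) ** -4
    return pd.DataFrame(w, index=expr.index, columns=expr.columns)


def adjust_bh(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma(x) = y
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float, np.ndarray]:
    """Moment-matched scaled inverse chi-square prior for residual variances.

    Returns ``(df_prior, s2_prior, s2_posterior)`` where the posterior is
    ``(d0*s0^2 + df*s^2) / (d0 + df)``; ``df_prior`` may be ``inf`` when the
    observed variances are less dispersed than chi-square sampling alone
    would produce.
    """
    s2 = np.asarray(s2, float)
    # numerically-zero variances (constant features) carry no information
    # about the prior and would wreck the log-scale moments
    ok = s2 > np.finfo(float).eps * max(1.0, float(s2.max(initial=0.0)))
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)), np.full_like(s2, np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    if np.isfinite(d0):
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        s2_post = np.full_like(s2, s02)
    return d0, s02, s2_post


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class FactorialDE:
    """Feature-wise 2x2 factorial linear model on a log2 abundance matrix.

    Parameters
    ----------
    expr :
        features x samples log2 abundance matrix (finite values).
    design :
        :class:`~factoromics.io.StudyDesign`; its model matrix has columns
        Intercept, Nlim, DGA, DGAxNlim.
    weights :
        Optional per-observation precision weights (same shape as ``expr``),
        e.g. from :func:`voom_weights`.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        design: StudyDesign,
        weights: pd.DataFrame | None = None,
    ) -> None:
        if list(expr.columns) != design.sample_ids:
            expr = expr.loc[:, design.sample_ids]
        if not np.isfinite(expr.to_numpy(float)).all():
            raise ValueError("expression matrix contains non-finite values")
        X = design.model_matrix().to_numpy(float)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                "rank-deficient design: the Nlim/DGA/DGAxNlim columns are collinear "
                "(a factor combination is unobserved)"
            )
        if X.shape[0] - X.shape[1] < 2:
            raise ValueError("need at least 2 residual degrees of freedom")
        self.expr = expr
        self.design = design
        self.weights = weights

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        design: StudyDesign,
        min_cpm: float = 1.0,
        min_libraries: int = 3,
        use_voom_weights: bool = False,
    ) -> "FactorialDE":
        """Filter on CPM support, TMM-normalize, log2-CPM transform."""
        counts = counts.loc[:, design.sample_ids]
        lib_sizes = counts.sum(axis=0).to_numpy(float)
        filtered = filter_low_counts(counts, min_cpm, min_libraries, lib_sizes)
        factors = tmm_factors(filtered)
        expr = log_cpm(filtered, factors, lib_sizes)
        weights = None
        if use_voom_weights:
            weights = voom_weights(expr, design.model_matrix(), lib_sizes)
        model = cls(expr, design, weights)
        model.norm_factors = factors
        model.lib_sizes = pd.Series(lib_sizes, index=counts.columns)
        return model

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, design: StudyDesign, **kwargs
    ) -> "FactorialDE":
        """Build from an already log-scale features x samples DataFrame."""
        return cls(frame, design, **kwargs)

    # -- estimation --------------------------------------------------------

    def fit(self, moderate: bool = True) -> "FactorialDEResults":
        X = self.design.model_matrix().to_numpy(float)
        Y = self.expr.to_numpy(float)
        n, p = X.shape
        g = Y.shape[0]
        df_resid = n - p

        if self.weights is None:
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = (XtX_inv @ X.T @ Y.T).T
            resid = Y - beta @ X.T
            s2 = (resid**2).sum(axis=1) / df_resid
            unscaled = np.tile(np.diag(XtX_inv), (g, 1))
        else:
            W = self.weights.loc[self.expr.index, self.expr.columns].to_numpy(float)
            beta = np.empty((g, p))
            s2 = np.empty(g)
            unscaled = np.empty((g, p))
            for i in range(g):
                w = W[i]
                Xw = X * w[:, None]
                XtWX_inv = np.linalg.inv(X.T @ Xw)
                b = XtWX_inv @ Xw.T @ Y[i]
                r = Y[i] - X @ b
                beta[i] = b
                s2[i] = np.sum(w * r**2) / df_resid
                unscaled[i] = np.diag(XtWX_inv)

        if moderate:
            df_prior, s2_prior, s2_post = squeeze_variances(s2, df_resid)
        else:
            df_prior, s2_prior, s2_post = 0.0, np.nan, s2.copy()
        df_total = df_resid + (df_prior if np.isfinite(df_prior) else np.inf)

        se = np.sqrt(s2_post[:, None] * unscaled)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
        if np.isfinite(df_total):
            pvals = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        else:
            pvals = 2.0 * stats.norm.sf(np.abs(tstat))
        adj = np.column_stack([adjust_bh(pvals[:, j]) for j in range(p)])

        idx = self.expr.index
        cols = list(COEF_NAMES)
        return FactorialDEResults(
            model=self,
            coefficients=pd.DataFrame(beta, index=idx, columns=cols),
            stderr=pd.DataFrame(se, index=idx, columns=cols),
            tvalues=pd.DataFrame(tstat, index=idx, columns=cols),
            pvalues=pd.DataFrame(pvals, index=idx, columns=cols),
            adj_pvalues=pd.DataFrame(adj, index=idx, columns=cols),
            s2_resid=pd.Series(s2, index=idx),
            s2_post=pd.Series(s2_post, index=idx),
            unscaled_cov_diag=pd.DataFrame(unscaled, index=idx, columns=cols),
            df_resid=df_resid,
            df_prior=df_prior,
            s2_prior=s2_prior,
        )


class FactorialDEResults:
    """Per-feature estimates, moderated statistics and adjusted P values."""

    def __init__(
        self,
        model: FactorialDE,
        coefficients: pd.DataFrame,
        stderr: pd.DataFrame,
        tvalues: pd.DataFrame,
        pvalues: pd.DataFrame,
        adj_pvalues: pd.DataFrame,
        s2_resid: pd.Series,
        s2_post: pd.Series,
        unscaled_cov_diag: pd.DataFrame,
        df_resid: float,
        df_prior: float,
        s2_prior: float,
    ) -> None:
        self.model = model
        self.coefficients = coefficients
        self.stderr = stderr
        self.tvalues = tvalues
        self.pvalues = pvalues
        self.adj_pvalues = adj_pvalues
        self.s2_resid = s2_resid
        self.s2_post = s2_post
        self.unscaled_cov_diag = unscaled_cov_diag
        self.df_resid = df_resid
        self.df_prior = df_prior
        self.s2_prior = s2_prior

    @property
    def df_total(self) -> float:
        return self.df_resid + self.df_prior

    @property
    def directional_adj_pvalues(self) -> pd.DataFrame:
        """Adjusted P signed by the coefficient's direction."""
        return np.sign(self.coefficients) * self.adj_pvalues

    def significant(self, coef: str | None = None, alpha: float = 0.05) -> pd.Index:
        """Features significant for one coefficient, or (default) for the
        minimum over the three non-intercept coefficients."""
        if coef is not None:
            return self.adj_pvalues.index[self.adj_pvalues[coef] < alpha]
        non_int = self.adj_pvalues[["Nlim", "DGA", "DGAxNlim"]]
        return non_int.index[non_int.min(axis=1) < alpha]

    def contrast(self, c: np.ndarray) -> pd.DataFrame:
        """Moderated t test of the linear combination ``c @ beta`` per feature.

        ``c`` is length 4 over (Intercept, Nlim, DGA, DGAxNlim).  Returns a
        DataFrame with estimate, se, t, P, adjusted P.  Because the 2x2
        design matrix is binary, the variance of ``c @ beta`` uses the exact
        unscaled covariance of the fit.
        """
        c = np.asarray(c, float)
        X = self.model.design.model_matrix().to_numpy(float)
        if self.model.weights is None:
            cov_unscaled = np.linalg.inv(X.T @ X)
            var_unscaled = float(c @ cov_unscaled @ c)
            var = self.s2_post.to_numpy() * var_unscaled
        else:
            W = self.model.weights.to_numpy(float)
            var = np.empty(len(self.s2_post))
            for i in range(len(var)):
                cov_u = np.linalg.inv(X.T @ (X * W[i][:, None]))
                var[i] = self.s2_post.iloc[i] * float(c @ cov_u @ c)
        est = self.coefficients.to_numpy() @ c
        se = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / np.where(se > 0, se, 1.0), 0.0)
        if np.isfinite(self.df_total):
            p = 2.0 * stats.t.sf(np.abs(t), self.df_total)
        else:
            p = 2.0 * stats.norm.sf(np.abs(t))
        return pd.DataFrame(
            {"estimate": est, "se": se, "t": t, "pvalue": p, "adj_pvalue": adjust_bh(p)},
            index=self.coefficients.index,
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat per-feature table: estimate/t/P/adjP/directional adjP per coefficient."""
        parts = []
        dirp = self.directional_adj_pvalues
        for coef in self.coefficients.columns:
            part = pd.DataFrame(
                {
                    f"{coef}_beta": self.coefficients[coef],
                    f"{coef}_t": self.tvalues[coef],
                    f"{coef}_p": self.pvalues[coef],
                    f"{coef}_adj_p": self.adj_pvalues[coef],
                    f"{coef}_dir_adj_p": dirp[coef],
                }
            )
            parts.append(part)
        return pd.concat(parts, axis=1)

    def summary(self, alpha: float = 0.05) -> str:
        lines = [
            "Factorial differential expression (2x2, interaction model)",
            f"  features: {len(self.coefficients)}    samples: {self.model.design.n_samples}",
            f"  residual df: {self.df_resid}    prior df: {self.df_prior:.3g}"
            f"    posterior df: {self.df_total:.3g}",
            f"  significant features (BH adj P < {alpha}) per factor:",
        ]
        for coef in ("Nlim", "DGA", "DGAxNlim"):
            n_sig = int((self.adj_pvalues[coef] < alpha).sum())
            n_up = int(((self.adj_pvalues[coef] < alpha) & (self.coefficients[coef] > 0)).sum())
            lines.append(f"    {coef:>9}: {n_sig:5d}  ({n_up} up, {n_sig - n_up} down)")
        return "\n".join(lines)
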