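"""Per-analyte linear regression with empirical-Bayes variance moderation.

This module is the shared computational engine behind both component tests of
the directional mediation screen: every analyte on a panel is fit against the
same design matrix by ordinary least squares, and the per-analyte residual
variances are then shrunk toward a panel-wide prior estimated by matching the
first two moments of the log sample variances to a scaled-F marginal. The
resulting moderated t-statistics gain degrees of freedom, which is where most
of the small-sample power of the method comes from.

The model for analyte g is

    y_g = X beta_g + eps_g,   eps_g ~ N(0, sigma_g^2 I)

with the hierarchical prior 1/sigma_g^2 ~ chi^2_{d0} / (d0 s0^2).  The
posterior variance is the precision-weighted blend

    s2_post_g = (d0 s0^2 + d_g s2_g) / (d0 + d_g)

and the moderated t for a coefficient uses s2_post on d_g + d0 degrees of
freedom.  d0 = +inf means complete shrinkage to the pooled variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "LinearFitSet",
    "VariancePrior",
    "ModeratedFitSet",
    "build_design",
    "fit_linear_models",
    "estimate_variance_prior",
    "moderate",
    "trigamma_inverse",
    "EmpiricalBayesLinearModel",
]

# moderated t switches to the normal reference above this total df
_NORMAL_DF = 1e6


@dataclass
class DesignMatrix:
    """Samples x terms design with labelled columns.

    The first column is the intercept unless it was explicitly suppressed at
    construction time.
    """

    values: np.ndarray
    term_names: list[str]
    sample_ids: list[str]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_terms(self) -> int:
        return self.values.shape[1]


@dataclass
class LinearFitSet:
    """Ordinary least-squares results for a panel of analytes."""

    coef: np.ndarray              # analytes x terms
    stdev_unscaled: np.ndarray    # terms (shared across analytes; SE = u * s)
    s2: np.ndarray                # per-analyte residual variance
    df_resid: np.ndarray          # per-analyte residual df
    analyte_ids: list[str]
    term_names: list[str]
    excluded: list[str] = field(default_factory=list)  # zero-variance analytes


@dataclass
class VariancePrior:
    """Scaled inverse-chi-square prior on residual variances.

    d0 = +inf means the log-variances show no dispersion beyond chi-square
    sampling noise, i.e. complete shrinkage to ``s0sq``; d0 = 0 disables
    moderation entirely.
    """

    d0: float
    s0sq: float


@dataclass
class ModeratedFitSet(LinearFitSet):
    """LinearFitSet augmented with the EB posterior variance and moderated t."""

    prior: VariancePrior = None
    s2_post: np.ndarray = None
    df_total: np.ndarray = None
    t: np.ndarray = None          # analytes x terms
    p: np.ndarray = None          # analytes x terms, two-sided


def _encode_column(col: pd.Series, name: str) -> np.ndarray:
    """Numeric passthrough; two-level categoricals become 0/1 (reference =
    first level in sorted order, i.e. the control arm for ctrl/trt labels)."""
    if pd.api.types.is_numeric_dtype(col):
        vals = col.to_numpy(dtype=float)
    else:
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) != 2:
            raise ValueError(
                f"term {name!r} is non-numeric with {len(levels)} levels; "
                "only two-level factors are supported"
            )
        vals = (col.astype(str) == levels[1]).to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"term {name!r} contains missing or non-finite values")
    return vals


def build_design(
    pheno: pd.DataFrame,
    terms: list[str],
    intercept: bool = True,
) -> DesignMatrix:
    """Build a design matrix from phenotype columns.

    Parameters
    ----------
    pheno : DataFrame indexed by sample id.
    terms : phenotype columns to include, in order, after the intercept.
        Binary exposures may be numeric 0/1 or two-level labels (coded 0/1
        with the alphabetically first level as reference).
    intercept : include a leading column of ones (default).

    Raises
    ------
    ValueError on missing columns, constant (zero-variance) terms, or a
    rank-deficient design (the collinear terms are named).
    """
    missing = [t for t in terms if t not in pheno.columns]
    if missing:
        raise ValueError(f"terms not found in phenotype table: {missing}")
    cols, names = [], []
    if intercept:
        cols.append(np.ones(len(pheno)))
        names.append("(Intercept)")
    for t in terms:
        v = _encode_column(pheno[t], t)
        if np.ptp(v) == 0:
            raise ValueError(f"term {t!r} is constant (zero variance)")
        cols.append(v)
        names.append(t)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending terms for the error message
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")
    return DesignMatrix(X, names, [str(s) for s in pheno.index])


def _as_matrix(Y) -> tuple[np.ndarray, list[str]]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), [str(i) for i in Y.index]
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    return Y, [f"A{i}" for i in range(Y.shape[0])]


def fit_linear_models(Y, X: DesignMatrix | np.ndarray) -> LinearFitSet:
    """Fit the same design to every analyte by QR-based least squares.

    Parameters
    ----------
    Y : analytes x samples matrix (DataFrame with analyte index, or ndarray).
    X : DesignMatrix (or plain samples x terms ndarray).

    Analytes with zero variance across samples are excluded (logged and
    recorded in ``excluded``).  More terms than samples is a hard error.
    """
    Ymat, ids = _as_matrix(Y)
    if isinstance(X, DesignMatrix):
        Xmat, term_names = X.values, X.term_names
    else:
        Xmat = np.asarray(X, dtype=float)
        term_names = [f"x{j}" for j in range(Xmat.shape[1])]
    n, k = Xmat.shape
    if Ymat.shape[1] != n:
        raise ValueError(
            f"analyte matrix has {Ymat.shape[1]} samples but design has {n} rows"
        )
    if k >= n:
        raise ValueError(f"design has {k} terms for only {n} samples")

    keep = Ymat.std(axis=1) > 0
    excluded = [ids[i] for i in np.flatnonzero(~keep)]
    if excluded:
        logger.warning(
            "excluding %d zero-variance analyte(s): %s", len(excluded), excluded[:5]
        )
        Ymat = Ymat[keep]
        ids = [ids[i] for i in np.flatnonzero(keep)]

    Q, R = np.linalg.qr(Xmat)
    coef = np.linalg.solve(R, Q.T @ Ymat.T).T          # analytes x terms
    fitted = (Q @ (Q.T @ Ymat.T)).T
    resid = Ymat - fitted
    df = n - k
    s2 = np.einsum("ij,ij->i", resid, resid) / df
    Rinv = np.linalg.inv(R)
    stdev_unscaled = np.sqrt(np.einsum("ij,ij->i", Rinv, Rinv))
    return LinearFitSet(
        coef=coef,
        stdev_unscaled=stdev_unscaled,
        s2=s2,
        df_resid=np.full(len(ids), float(df)),
        analyte_ids=ids,
        term_names=term_names,
        excluded=excluded,
    )


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Closed-form start from trigamma(x) ~ 1/x + 1/(2 x^2); monotonicity of the
    trigamma function makes the iteration globally well behaved here.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


def estimate_variance_prior(s2, df_resid) -> VariancePrior:
    """Moment-match the scaled-F marginal of the sample variances.

    Under the hierarchical model, s2_g ~ s0^2 F(d_g, d0), so log s2 has mean
    and variance expressible through digamma/trigamma functions of d_g/2 and
    d0/2.  The excess of the empirical variance of log s2 over the expected
    chi-square sampling variance identifies d0 (trigamma inversion); the mean
    identifies s0^2.  Zero excess dispersion gives d0 = +inf with s0^2 equal
    to the pooled mean variance; fewer than 2 usable analytes disables
    moderation (d0 = 0).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df_resid, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    if ok.sum() < 2:
        logger.warning(
            "variance prior needs >= 2 analytes with positive variance; "
            "got %d -- moderation disabled", int(ok.sum())
        )
        pooled = float(np.mean(s2[ok])) if ok.any() else 1.0
        return VariancePrior(d0=0.0, s0sq=pooled)
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, df / 2)))
    if evar <= 0:
        return VariancePrior(d0=np.inf, s0sq=float(np.mean(s2)))
    d0 = 2.0 * trigamma_inverse(evar)
    s0sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return VariancePrior(d0=float(d0), s0sq=s0sq)


def moderate(fits: LinearFitSet, prior: VariancePrior) -> ModeratedFitSet:
    """Blend per-analyte variances with the prior and form moderated t / p.

    d0 = 0 reproduces the ordinary t-test exactly; d0 = +inf uses the pooled
    prior variance with total df capped at the pooled residual df.  When the
    total df exceeds 1e6 the normal reference is used.
    """
    d = fits.df_resid
    d0, s0 = prior.d0, prior.s0sq
    if np.isinf(d0):
        s2_post = np.full_like(fits.s2, s0)
        df_total = np.full_like(d, float(np.sum(d)))
    elif d0 == 0:
        s2_post = fits.s2.copy()
        df_total = d.copy()
    else:
        s2_post = (d0 * s0 + d * fits.s2) / (d0 + d)
        df_total = np.minimum(d + d0, float(np.sum(d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fits.coef / (fits.stdev_unscaled[None, :] * np.sqrt(s2_post)[:, None])
    t = np.where(fits.coef == 0, 0.0, t)
    p = np.empty_like(t)
    normal = df_total > _NORMAL_DF
    if normal.any():
        p[normal] = 2 * stats.norm.sf(np.abs(t[normal]))
    if (~normal).any():
        p[~normal] = 2 * stats.t.sf(np.abs(t[~normal]), df_total[~normal, None])
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return ModeratedFitSet(
        coef=fits.coef,
        stdev_unscaled=fits.stdev_unscaled,
        s2=fits.s2,
        df_resid=fits.df_resid,
        analyte_ids=fits.analyte_ids,
        term_names=fits.term_names,
        excluded=fits.excluded,
        prior=prior,
        s2_post=s2_post,
        df_total=df_total,
        t=t,
        p=p,
    )


class EmpiricalBayesLinearModel(BaseEstimator):
    """Panel-wide linear model with empirical-Bayes moderated t-statistics.

    scikit-learn-style estimator face over :func:`fit_linear_models`,
    :func:`estimate_variance_prior` and :func:`moderate`.

    Parameters
    ----------
    moderated : bool, default True
        Estimate the variance prior across analytes and moderate; when False
        ordinary per-analyte t-tests are reported (d0 = 0).
    prior : VariancePrior or None
        Supply a prior explicitly instead of estimating it.

    Attributes (after fit)
    ----------------------
    coef_, t_, pvalues_ : analytes x terms arrays
    s2_, s2_post_, df_total_ : per-analyte vectors
    prior_ : VariancePrior
    fit_ : the full ModeratedFitSet
    """

    def __init__(self, moderated: bool = True, prior: VariancePrior | None = None):
        self.moderated = moderated
        self.prior = prior

    def fit(self, X, Y):
        """X: DesignMatrix or samples x terms array; Y: analytes x samples."""
        fits = fit_linear_models(Y, X)
        if self.prior is not None:
            prior = self.prior
        elif self.moderated:
            prior = estimate_variance_prior(fits.s2, fits.df_resid)
        else:
            prior = VariancePrior(d0=0.0, s0sq=float(np.mean(fits.s2)))
        mod = moderate(fits, prior)
        self.fit_ = mod
        self.prior_ = prior
        self.coef_ = mod.coef
        self.t_ = mod.t
        self.pvalues_ = mod.p
        self.s2_ = mod.s2
        self.s2_post_ = mod.s2_post
        self.df_total_ = mod.df_total
        self.analyte_ids_ = mod.analyte_ids
        self.term_names_ = mod.term_names
        return self
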