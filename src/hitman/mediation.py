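"""Directional high-throughput mediation tests and their comparators.

The causal chain tested per analyte is

    exposure  ->  analyte  ->  outcome        (given the exposure)

with a direction of the exposure's total effect on the outcome prespecified
from prior knowledge.  The two component tests are

  (I)  exposure -> analyte:  regression of the analyte on the exposure
  (II) analyte -> outcome | exposure: partial association of analyte and
       outcome given the exposure

and the joint-significance p-value is the maximum of the two two-sided
component p-values.  The directional screen then classifies each analyte:
its mediated direction is sign(beta_EM) * sign(beta_MY).  If that matches the
prespecified total-effect sign the analyte is a *consistent* candidate and
the joint p-value is halved; otherwise the p-value becomes one.  Both
component tests may share strength across the panel through empirical-Bayes
variance moderation (see :mod:`hitman.linmod`); component (II) is fit with
the analyte as response (analyte ~ outcome + exposure) so the moderation
machinery applies, which is exact for the unmoderated t by partial-
correlation symmetry.

A quasi-Bayesian potential-outcomes comparator (average causal mediation
effect for the linear, no-interaction model) and Benjamini-Hochberg FDR
adjustment round out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .linmod import (
    VariancePrior,
    build_design,
    estimate_variance_prior,
    fit_linear_models,
    moderate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "DirectionGateError",
    "total_effect",
    "check_direction",
    "em_scores",
    "my_scores",
    "hitman",
    "hitman_simple",
    "joint_significance",
    "potential_outcomes_mediation",
    "bh_adjust",
    "HitmanMediator",
    "JointSignificanceTest",
    "PotentialOutcomesMediation",
]

RESULT_COLUMNS = [
    "analyte_id", "em_beta", "em_p", "my_beta", "my_p",
    "consistent", "p_joint", "p_hitman", "q_hitman",
]


class DirectionGateError(RuntimeError):
    """Raised when the observed total effect contradicts the prespecified
    direction (gate_mode='error'): the directional test must not be run."""


@dataclass
class Direction:
    """Prespecified sign of the exposure's causal effect on the outcome.

    gate_mode controls what happens when the observed total effect disagrees:
    'error' aborts, 'warn' proceeds with a logged warning, 'ignore' proceeds
    silently (used by batch simulations where the true sign is known).
    """

    sign: int
    gate_mode: str = "error"

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("direction sign must be -1 or +1")
        if self.gate_mode not in ("error", "warn", "ignore"):
            raise ValueError("gate_mode must be one of error/warn/ignore")


# ---------------------------------------------------------------------------
# low-level numpy cores (shared with the Monte-Carlo machinery in evaluate)
# ---------------------------------------------------------------------------

def _ols_t(X: np.ndarray, y: np.ndarray, j: int) -> tuple[float, float]:
    """t-test for coefficient j of y ~ X; returns (beta_j, two-sided p)."""
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = resid @ resid / (n - k)
    xtx_inv = np.linalg.inv(X.T @ X)
    if s2 == 0:
        return float(beta[j]), (1.0 if beta[j] == 0 else np.finfo(float).tiny)
    se = np.sqrt(s2 * xtx_inv[j, j])
    t = beta[j] / se
    p = 2 * stats.t.sf(abs(t), n - k)
    return float(beta[j]), float(max(p, np.finfo(float).tiny))


def _panel_scores(
    M: np.ndarray,
    X: np.ndarray,
    j: int,
    moderated: bool,
    prior: VariancePrior | None = None,
):
    """Per-analyte (beta_j, p_j) for panel M (analytes x samples) on design X.

    Returns (beta, p, prior_used, excluded_mask) where excluded_mask marks
    zero-variance analytes (their beta/p are NaN).
    """
    G = M.shape[0]
    keep = M.std(axis=1) > 0
    beta = np.full(G, np.nan)
    p = np.full(G, np.nan)
    fits = fit_linear_models(M[keep], X)
    if prior is None:
        if moderated:
            prior = estimate_variance_prior(fits.s2, fits.df_resid)
        else:
            prior = VariancePrior(d0=0.0, s0sq=float(np.mean(fits.s2)))
    mod = moderate(fits, prior)
    beta[keep] = mod.coef[:, j]
    p[keep] = mod.p[:, j]
    return beta, p, prior, ~keep


def _combine_directional(em_beta, em_p, my_beta, my_p, sign: int, mode: str):
    """Apply the directional rule to joint-significance p-values.

    consistent  <=>  sign(em_beta) * sign(my_beta) == prespecified sign.
    mode='consistent': consistent analytes get p_joint/2, others 1.
    mode='inconsistent': analytes whose mediated direction *opposes* the
    prespecified sign get p_joint/2, others 1.  A zero component effect makes
    an analyte neither (conservative p = 1 in both modes).
    """
    prod = np.sign(em_beta) * np.sign(my_beta)
    consistent = prod == sign
    p_joint = np.maximum(em_p, my_p)
    if mode == "consistent":
        halve = consistent
    elif mode == "inconsistent":
        halve = prod == -sign
    else:
        raise ValueError("mode must be 'consistent' or 'inconsistent'")
    p_dir = np.where(halve, p_joint / 2, 1.0)
    p_dir = np.where(np.isnan(p_joint), np.nan, p_dir)
    return consistent, p_joint, p_dir


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries are excluded from the adjustment and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _pheno_arrays(pheno, exposure_col, outcome_col, covariate_cols):
    covariate_cols = list(covariate_cols or [])
    cols = [exposure_col, outcome_col] + covariate_cols
    missing = [c for c in cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table is missing column(s): {missing}")
    sub = pheno[cols].dropna()
    if len(sub) < len(pheno):
        logger.info("dropped %d sample(s) with missing phenotype values",
                    len(pheno) - len(sub))
    design = build_design(sub, [exposure_col] + covariate_cols)
    e = design.values[:, 1]
    y = sub[outcome_col].to_numpy(dtype=float)
    covs = design.values[:, 2:] if covariate_cols else None
    return sub, e, y, covs


def total_effect(
    pheno: pd.DataFrame,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    covariate_cols: list[str] | None = None,
) -> tuple[float, float, int]:
    """OLS total effect of the exposure on the outcome (+ covariates).

    Returns (beta, two-sided p, sign) where sign is 0 for an exactly zero
    estimate.  Binary exposures need >= 3 samples per arm; an empty arm is a
    hard error (raised by the constant-term check in the design).
    """
    sub, e, y, covs = _pheno_arrays(pheno, exposure_col, outcome_col, covariate_cols)
    uniq = np.unique(e)
    if len(uniq) == 2:
        counts = [(e == u).sum() for u in uniq]
        if min(counts) < 3:
            logger.warning("fewer than 3 samples in one exposure arm (%s)", counts)
    X = np.column_stack([np.ones_like(e), e] + ([covs] if covs is not None else []))
    beta, p = _ols_t(X, y, 1)
    # snap numerically-zero estimates so identical arms report sign 0
    if abs(beta) < 1e-10 * max(1.0, float(np.std(y))):
        beta = 0.0
    return beta, p, int(np.sign(beta))


def check_direction(observed_sign: int, direction: Direction) -> bool:
    """Gate the directional test on the observed total-effect sign.

    Returns True on pass.  On disagreement (or a zero observed sign) the
    behaviour follows direction.gate_mode: 'error' raises
    :class:`DirectionGateError`, 'warn' logs and proceeds, 'ignore' proceeds
    silently.
    """
    if observed_sign == direction.sign:
        return True
    msg = (
        f"observed total-effect sign ({observed_sign:+d}) does not match the "
        f"prespecified direction ({direction.sign:+d}); a directional "
        "mediation test is invalid in this situation"
    )
    if direction.gate_mode == "error":
        raise DirectionGateError(msg)
    if direction.gate_mode == "warn":
        logger.warning(msg)
    return False


def _align(M: pd.DataFrame, pheno: pd.DataFrame):
    """Strict sample-id intersection between analyte columns and pheno rows."""
    M = M.copy()
    pheno = pheno.copy()
    M.columns = M.columns.map(str)
    pheno.index = pheno.index.map(str)
    common = [s for s in M.columns if s in set(pheno.index)]
    if not common:
        raise ValueError("no overlapping sample ids between analyte matrix and "
                         "phenotype table")
    dropped = sorted(set(M.columns).symmetric_difference(pheno.index))
    if dropped:
        logger.info("dropping %d non-overlapping sample(s): %s",
                    len(dropped), dropped[:10])
    return M.loc[:, common], pheno.loc[common]


def em_scores(
    M: pd.DataFrame,
    pheno: pd.DataFrame,
    moderated: bool = True,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    covariate_cols: list[str] | None = None,
):
    """Component (I): per-analyte regression of analyte on exposure.

    Returns a DataFrame with columns beta, p indexed by analyte id.
    """
    M, pheno = _align(M, pheno)
    sub, e, _, covs = _pheno_arrays(pheno, exposure_col, outcome_col, covariate_cols)
    Mm = M.loc[:, sub.index].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(e), e] + ([covs] if covs is not None else []))
    beta, p, _, _ = _panel_scores(Mm, X, 1, moderated)
    return pd.DataFrame({"beta": beta, "p": p}, index=M.index)


def my_scores(
    M: pd.DataFrame,
    pheno: pd.DataFrame,
    moderated: bool = True,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    covariate_cols: list[str] | None = None,
):
    """Component (II): partial association of analyte and outcome given the
    exposure (+ covariates), fit as analyte ~ outcome + exposure so the
    empirical-Bayes machinery applies with the analyte as response.  The
    reported sign carries the sign of the partial association; the
    unmoderated t is identical in either regression orientation.
    """
    M, pheno = _align(M, pheno)
    sub, e, y, covs = _pheno_arrays(pheno, exposure_col, outcome_col, covariate_cols)
    Mm = M.loc[:, sub.index].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), y, e] + ([covs] if covs is not None else []))
    beta, p, _, _ = _panel_scores(Mm, X, 1, moderated)
    return pd.DataFrame({"beta": beta, "p": p}, index=M.index)


def hitman(
    M: pd.DataFrame,
    pheno: pd.DataFrame,
    direction: Direction | int,
    moderated: bool = True,
    mode: str = "consistent",
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    covariate_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Run the directional mediation screen over an analyte panel.

    See :class:`HitmanMediator` for the estimator interface.  Returns the
    mediation result table sorted by the directional p-value (analyte id as
    tiebreak) with columns
    analyte_id, em_beta, em_p, my_beta, my_p, consistent, p_joint, p_hitman,
    q_hitman.
    """
    est = HitmanMediator(
        direction=direction, moderated=moderated, mode=mode,
        exposure_col=exposure_col, outcome_col=outcome_col,
        covariate_cols=covariate_cols,
    ).fit(M.T, pheno)
    return est.results_


def hitman_simple(M, pheno, direction, **kwargs) -> pd.DataFrame:
    """The simplified screen without empirical-Bayes moderation (ordinary
    t-tests for both components); otherwise identical to :func:`hitman`."""
    return hitman(M, pheno, direction, moderated=False, **kwargs)


def joint_significance(
    M: pd.DataFrame,
    pheno: pd.DataFrame,
    exposure_col: str = "exposure",
    outcome_col: str = "outcome",
    covariate_cols: list[str] | None = None,
) -> pd.Series:
    """Plain (non-directional, unmoderated) joint-significance p-values:
    the maximum of the two two-sided component p-values per analyte."""
    em = em_scores(M, pheno, moderated=False, exposure_col=exposure_col,
                   outcome_col=outcome_col, covariate_cols=covariate_cols)
    my = my_scores(M, pheno, moderated=False, exposure_col=exposure_col,
                   outcome_col=outcome_col, covariate_cols=covariate_cols)
    return pd.Series(np.maximum(em["p"], my["p"]), index=em.index, name="p_joint")


def potential_outcomes_mediation(
    e, m, y, nsim: int = 1000, seed=None,
    conf_level: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Quasi-Bayesian potential-outcomes mediation test for one mediator.

    Linear, no-interaction case: fit m ~ e and y ~ m + e by OLS, draw the two
    relevant coefficients from their asymptotic normal sampling
    distributions, and form ACME draws a_draw * b_draw.  Returns the ACME
    point estimate (a_hat * b_hat), the percentile confidence interval, and
    the two-sided tail probability of zero among the draws.
    """
    if nsim < 1000:
        logger.warning("nsim=%d < 1000 gives unstable p-value resolution", nsim)
    rng = np.random.default_rng(seed)
    e = np.asarray(e, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(e) == 0:
        raise ValueError("exposure is constant; mediation model cannot be fit")
    ones = np.ones_like(e)

    def fit(X, resp, j):
        n, k = X.shape
        beta, *_ = np.linalg.lstsq(X, resp, rcond=None)
        resid = resp - X @ beta
        s2 = resid @ resid / (n - k)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[j, j])
        return beta[j], se

    a_hat, a_se = fit(np.column_stack([ones, e]), m, 1)
    b_hat, b_se = fit(np.column_stack([ones, m, e]), y, 1)
    draws = (a_hat + a_se * rng.standard_normal(nsim)) * (
        b_hat + b_se * rng.standard_normal(nsim))
    acme = float(a_hat * b_hat)
    lo, hi = np.quantile(draws, [(1 - conf_level) / 2, (1 + conf_level) / 2])
    p = 2 * min(np.mean(draws <= 0), np.mean(draws >= 0))
    return acme, (float(lo), float(hi)), float(min(max(p, 1.0 / nsim), 1.0))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class HitmanMediator(BaseEstimator):
    """Directional, optionally EB-moderated mediation screen.

    Parameters
    ----------
    direction : int (+1/-1) or Direction
        Prespecified sign of the exposure's causal effect on the outcome.
        Must come from prior knowledge, never from the data at hand.
    gate_mode : 'error' | 'warn' | 'ignore'
        Behaviour when the observed total effect disagrees with `direction`
        (ignored if a full Direction object is passed).
    moderated : bool, default True
        Use empirical-Bayes variance moderation across the panel in both
        component tests.
    mode : 'consistent' (default) | 'inconsistent'
        Which mediated direction is of interest.  'inconsistent' flips the
        rule: analytes opposing the prespecified direction are halved and
        consistent ones get p = 1.
    exposure_col, outcome_col, covariate_cols
        Column names in the phenotype table.  The exposure may be binary
        (coded 0/1, or any two labels) or a numeric score.

    Attributes (after fit)
    ----------------------
    results_ : DataFrame with columns analyte_id, em_beta, em_p, my_beta,
        my_p, consistent, p_joint, p_hitman, q_hitman, sorted by p_hitman.
    pvalues_, qvalues_ : Series indexed by analyte id (input order).
    total_effect_, total_effect_p_, observed_sign_ : total-effect summary.
    prior_em_, prior_my_ : VariancePrior used in each component test.
    excluded_analytes_ : zero-variance analytes dropped from the screen.

    Examples
    --------
    >>> est = HitmanMediator(direction=-1).fit(X, pheno)   # doctest: +SKIP
    >>> est.results_.head()                                # doctest: +SKIP
    """

    def __init__(self, direction=None, gate_mode="error", moderated=True,
                 mode="consistent", exposure_col="exposure",
                 outcome_col="outcome", covariate_cols=None):
        self.direction = direction
        self.gate_mode = gate_mode
        self.moderated = moderated
        self.mode = mode
        self.exposure_col = exposure_col
        self.outcome_col = outcome_col
        self.covariate_cols = covariate_cols

    def _direction(self) -> Direction:
        if isinstance(self.direction, Direction):
            return self.direction
        if self.direction in (-1, 1):
            return Direction(int(self.direction), self.gate_mode)
        raise ValueError(
            "a prespecified direction (+1 or -1, or a Direction) is required; "
            "a directional mediation test must not be run without one"
        )

    def fit(self, X, pheno: pd.DataFrame):
        """Fit the screen.

        X : samples x analytes DataFrame (or array); pheno : DataFrame
        indexed by sample id with exposure, outcome and covariate columns.
        """
        direction = self._direction()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             index=[str(i) for i in pheno.index])
        M = X.T  # analytes x samples
        M, pheno = _align(M, pheno)
        sub, e, y, covs = _pheno_arrays(
            pheno, self.exposure_col, self.outcome_col, self.covariate_cols)
        Mm = M.loc[:, sub.index].to_numpy(dtype=float)
        ids = [str(i) for i in M.index]

        beta_t, p_t, sign_t = total_effect(
            pheno, self.exposure_col, self.outcome_col, self.covariate_cols)
        check_direction(sign_t, direction)

        extra = [covs] if covs is not None else []
        X_em = np.column_stack([np.ones_like(e), e] + extra)
        X_my = np.column_stack([np.ones_like(e), y, e] + extra)
        em_beta, em_p, prior_em, excl = _panel_scores(Mm, X_em, 1, self.moderated)
        my_beta, my_p, prior_my, _ = _panel_scores(Mm, X_my, 1, self.moderated)

        zero = ((em_beta == 0) | (my_beta == 0)) & ~np.isnan(em_beta)
        if zero.any():
            logger.warning("%d analyte(s) with an exactly zero component "
                           "effect treated as not consistent", int(zero.sum()))
        consistent, p_joint, p_dir = _combine_directional(
            em_beta, em_p, my_beta, my_p, direction.sign, self.mode)
        q = bh_adjust(p_dir)

        res = pd.DataFrame({
            "analyte_id": ids,
            "em_beta": em_beta, "em_p": em_p,
            "my_beta": my_beta, "my_p": my_p,
            "consistent": consistent,
            "p_joint": p_joint, "p_hitman": p_dir, "q_hitman": q,
        })
        self.excluded_analytes_ = [ids[i] for i in np.flatnonzero(excl)]
        res = res[~np.isnan(res["p_hitman"])]
        res = res.sort_values(["p_hitman", "analyte_id"],
                              kind="mergesort").reset_index(drop=True)
        self.results_ = res
        self.pvalues_ = pd.Series(p_dir, index=ids, name="p_hitman")
        self.qvalues_ = pd.Series(q, index=ids, name="q_hitman")
        self.total_effect_ = beta_t
        self.total_effect_p_ = p_t
        self.observed_sign_ = sign_t
        self.prior_em_ = prior_em
        self.prior_my_ = prior_my
        self.n_samples_ = len(sub)
        return self

    def significant(self, q: float = 0.05) -> list[str]:
        """Analyte ids called at BH FDR <= q."""
        r = self.results_
        return list(r.loc[r["q_hitman"] <= q, "analyte_id"])


class JointSignificanceTest(BaseEstimator):
    """Plain joint-significance mediation screen (non-directional).

    Unmoderated by default, matching its common use as a comparator.
    Attributes after fit: pvalues_ (Series), qvalues_ (BH), results_.
    """

    def __init__(self, moderated: bool = False, exposure_col="exposure",
                 outcome_col="outcome", covariate_cols=None):
        self.moderated = moderated
        self.exposure_col = exposure_col
        self.outcome_col = outcome_col
        self.covariate_cols = covariate_cols

    def fit(self, X, pheno: pd.DataFrame):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float),
                             index=[str(i) for i in pheno.index])
        M = X.T
        em = em_scores(M, pheno, self.moderated, self.exposure_col,
                       self.outcome_col, self.covariate_cols)
        my = my_scores(M, pheno, self.moderated, self.exposure_col,
                       self.outcome_col, self.covariate_cols)
        p = np.maximum(em["p"].to_numpy(), my["p"].to_numpy())
        self.pvalues_ = pd.Series(p, index=em.index, name="p_joint")
        self.qvalues_ = pd.Series(bh_adjust(p), index=em.index, name="q_joint")
        self.results_ = pd.DataFrame({
            "analyte_id": [str(i) for i in em.index],
            "em_beta": em["beta"].to_numpy(), "em_p": em["p"].to_numpy(),
            "my_beta": my["beta"].to_numpy(), "my_p": my["p"].to_numpy(),
            "p_joint": p, "q_joint": self.qvalues_.to_numpy(),
        })
        return self


class PotentialOutcomesMediation(BaseEstimator):
    """Quasi-Bayesian potential-outcomes mediation for a single mediator.

    Parameters: nsim (coefficient draws, >= 1000 recommended), seed,
    conf_level.  After fit(e, m, y): acme_, ci_, pvalue_.
    """

    def __init__(self, nsim: int = 1000, seed=None, conf_level: float = 0.95):
        self.nsim = nsim
        self.seed = seed
        self.conf_level = conf_level

    def fit(self, e, m, y):
        self.acme_, self.ci_, self.pvalue_ = potential_outcomes_mediation(
            e, m, y, nsim=self.nsim, seed=self.seed, conf_level=self.conf_level)
        return self
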