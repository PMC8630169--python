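"""Monte-Carlo power, type-I-error and FDR studies over simulated panels.

Every requested method is evaluated on the *same* stream of simulated
datasets (common random numbers), so between-method comparisons are paired
and the 2x2 replicate-count comparison (Fisher exact) is well defined.

For a single true mediator, power is the fraction of replicates in which that
mediator passes the threshold rule; for multi-mediator panels it is the mean
per-replicate true-positive proportion.  Threshold rules are either a nominal
per-analyte p-value cutoff ("nominal", alpha) or panel-wide BH FDR
thresholding ("fdr", q).  Monte-Carlo binomial standard errors are always
reported so comparisons with external power figures are tolerance-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .linmod import VariancePrior, estimate_variance_prior, fit_linear_models, moderate
from .mediation import _combine_directional, bh_adjust, potential_outcomes_mediation
from .simulate import SimConfig, _draw, correlation_root

logger = logging.getLogger(__name__)

__all__ = [
    "PowerStudyResult",
    "MethodComparison",
    "run_power_study",
    "fisher_compare",
    "mcnemar_compare",
    "realized_fdr",
    "METHODS",
]

METHODS = ("hitman", "hitman_simple", "joint_significance", "potential_outcomes")


@dataclass
class PowerStudyResult:
    """Power estimate for one method under one simulation configuration."""

    method: str
    config: SimConfig
    B: int
    threshold_rule: tuple
    k_detected: float
    power: float
    mc_se: float
    detections: np.ndarray = field(repr=False, default=None)
    fdp: np.ndarray = field(repr=False, default=None)  # per-replicate FDP (fdr rule)

    @property
    def realized_fdr(self) -> float | None:
        return None if self.fdp is None else float(np.mean(self.fdp))


@dataclass
class MethodComparison:
    """Two-sided Fisher exact comparison of detection counts."""

    counts: np.ndarray            # 2x2: rows methods, cols (detected, not)
    odds_ratio: float
    ci95: tuple[float, float]
    p: float


def _component_stats(M: np.ndarray, X: np.ndarray):
    """OLS fit of panel M (analytes x samples) on design X; returns the fit
    plus a closure producing (beta_j, p_j) under a given variance prior."""
    return fit_linear_models(M, X)


def _beta_p(fits, prior: VariancePrior, j: int = 1):
    mod = moderate(fits, prior)
    return mod.coef[:, j], mod.p[:, j]


def _replicate_pvalues(E, M, Y, sign, methods, nsim_po, rng):
    """Per-analyte p-value vectors for each requested method on one dataset."""
    ones = np.ones_like(E)
    X_em = np.column_stack([ones, E])
    X_my = np.column_stack([ones, Y, E])
    fits_em = _component_stats(M, X_em)
    fits_my = _component_stats(M, X_my)
    no_prior = VariancePrior(0.0, 1.0)
    out = {}
    need_plain = {"joint_significance", "hitman_simple"} & set(methods)
    if need_plain:
        em_b0, em_p0 = _beta_p(fits_em, no_prior)
        my_b0, my_p0 = _beta_p(fits_my, no_prior)
        if "joint_significance" in methods:
            out["joint_significance"] = np.maximum(em_p0, my_p0)
        if "hitman_simple" in methods:
            _, _, p = _combine_directional(em_b0, em_p0, my_b0, my_p0,
                                           sign, "consistent")
            out["hitman_simple"] = p
    if "hitman" in methods:
        pr_em = estimate_variance_prior(fits_em.s2, fits_em.df_resid)
        pr_my = estimate_variance_prior(fits_my.s2, fits_my.df_resid)
        em_b, em_p = _beta_p(fits_em, pr_em)
        my_b, my_p = _beta_p(fits_my, pr_my)
        _, _, p = _combine_directional(em_b, em_p, my_b, my_p, sign, "consistent")
        out["hitman"] = p
    return out


def run_power_study(
    methods,
    config: SimConfig,
    B: int,
    threshold_rule=("nominal", 0.05),
    seed: int = 0,
    nsim_po: int = 1000,
) -> list[PowerStudyResult]:
    """Estimate power for each method over B common-random-number replicates.

    methods : subset of {hitman, hitman_simple, joint_significance,
        potential_outcomes}.  The potential-outcomes test is evaluated on
        each true mediator individually (with a cost warning for large
        panels).
    threshold_rule : ("nominal", alpha) or ("fdr", q).
    seed : master seed; replicate streams are spawned from it, so the same
        seed reproduces the study exactly for any method subset.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown method(s) {sorted(unknown)}; "
                         f"valid: {list(METHODS)}")
    kind, cut = threshold_rule
    if kind not in ("nominal", "fdr"):
        raise ValueError("threshold_rule must be ('nominal', alpha) or ('fdr', q)")
    a_is_mediator = None  # computed from the first replicate's labels
    if "potential_outcomes" in methods and (
            config.n_consistent + config.n_inconsistent) > 1:
        logger.warning("potential_outcomes with multiple mediators loops "
                       "per-analyte; this is slow")

    L = correlation_root(config)
    children = np.random.SeedSequence(seed).spawn(B)
    det = {m: np.zeros(B) for m in methods}
    fdp = {m: np.zeros(B) for m in methods} if kind == "fdr" else None

    for bidx, child in enumerate(children):
        rng = np.random.default_rng(child)
        E, M, Y, labels, sign = _draw(config, rng, L)
        if a_is_mediator is None:
            a_is_mediator = labels == "consistent-mediator"
            med_idx = np.flatnonzero(a_is_mediator)
            if len(med_idx) == 0:
                # null study: type-I error of any positive call on the panel
                med_idx = np.arange(config.G)
        pvals = _replicate_pvalues(E, M, Y, sign, methods, nsim_po, rng)
        for m in methods:
            if m == "potential_outcomes":
                p = np.full(config.G, np.nan)
                for g in med_idx:
                    _, _, p[g] = potential_outcomes_mediation(
                        E, M[g], Y, nsim=nsim_po, seed=rng)
            else:
                p = pvals[m]
            if kind == "nominal":
                calls = p < cut
            else:
                q = bh_adjust(p)
                calls = q <= cut
                n_calls = int(np.nansum(calls))
                n_false = int(np.nansum(calls & ~a_is_mediator))
                fdp[m][bidx] = n_false / n_calls if n_calls else 0.0
            # for null configurations (no analyte labelled as a true
            # mediator) this is the per-analyte rejection rate, i.e. the
            # empirical type-I error
            det[m][bidx] = float(np.nanmean(np.asarray(calls, dtype=float)[med_idx]))

    results = []
    for m in methods:
        power = float(np.mean(det[m]))
        results.append(PowerStudyResult(
            method=m, config=config, B=B, threshold_rule=threshold_rule,
            k_detected=float(np.sum(det[m])), power=power,
            mc_se=float(np.sqrt(power * (1 - power) / B)),
            detections=det[m],
            fdp=None if fdp is None else fdp[m],
        ))
    return results


def fisher_compare(kA: int, nA: int, kB: int, nB: int) -> MethodComparison:
    """Two-sided Fisher exact comparison of two detection proportions.

    p comes from the conditional hypergeometric test; the odds ratio is the
    sample OR kA (nB - kB) / (kB (nA - kA)) and its 95% CI uses the log-OR
    normal approximation.  A zero cell triggers the Haldane 0.5 continuity
    correction for the OR/CI (logged).
    """
    if min(kA, kB) < 0 or kA > nA or kB > nB:
        raise ValueError("need 0 <= k <= n for both methods")
    table = np.array([[kA, nA - kA], [kB, nB - kB]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table.copy()
    if (t == 0).any():
        logger.info("zero cell in 2x2 table; applying 0.5 continuity correction")
        t += 0.5
    odds_ratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    se = float(np.sqrt((1.0 / t).sum()))
    lo, hi = np.exp(np.log(odds_ratio) + np.array([-1, 1]) * 1.959963984540054 * se)
    return MethodComparison(counts=table.astype(int), odds_ratio=float(odds_ratio),
                            ci95=(float(lo), float(hi)), p=float(p))


def mcnemar_compare(detA: np.ndarray, detB: np.ndarray) -> MethodComparison:
    """Paired (McNemar) comparison of per-replicate detections.

    Uses the exact binomial McNemar test on the discordant pairs; the odds
    ratio is the discordant-pair ratio.  Provided as a variant of
    :func:`fisher_compare` for common-random-number studies.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    dA = np.asarray(detA, dtype=bool)
    dB = np.asarray(detB, dtype=bool)
    if dA.shape != dB.shape:
        raise ValueError("detection vectors must have equal length")
    table = np.array([
        [np.sum(dA & dB), np.sum(dA & ~dB)],
        [np.sum(~dA & dB), np.sum(~dA & ~dB)],
    ])
    res = mcnemar(table, exact=True)
    b, c = table[0, 1], table[1, 0]
    if min(b, c) == 0:
        b, c = b + 0.5, c + 0.5
    orr = b / c
    se = np.sqrt(1 / b + 1 / c)
    lo, hi = np.exp(np.log(orr) + np.array([-1, 1]) * 1.959963984540054 * se)
    return MethodComparison(counts=table, odds_ratio=float(orr),
                            ci95=(float(lo), float(hi)), p=float(res.pvalue))


def realized_fdr(results: pd.DataFrame, truth: pd.Series, q_star: float = 0.05,
                 mode: str = "consistent") -> float:
    """False discovery proportion of FDR-level calls against truth labels.

    results : mediation result table with analyte_id and q_hitman (or a
        q column named q_joint).
    truth : per-analyte labels from the simulator.
    A replicate with no calls contributes an FDP of 0 (the standard
    convention, so the average estimates the FDR).
    """
    qcol = "q_hitman" if "q_hitman" in results.columns else "q_joint"
    called = results.loc[results[qcol] <= q_star, "analyte_id"]
    if len(called) == 0:
        return 0.0
    target = ("consistent-mediator" if mode == "consistent"
              else "inconsistent-mediator")
    labels = truth.loc[called]
    return float(np.mean(labels != target))
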