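import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hitman.mediation import (
    Direction,
    DirectionGateError,
    HitmanMediator,
    JointSignificanceTest,
    PotentialOutcomesMediation,
    _combine_directional,
    bh_adjust,
    check_direction,
    em_scores,
    hitman,
    hitman_simple,
    joint_significance,
    my_scores,
    potential_outcomes_mediation,
    total_effect,
)


def _pheno(e, y, **extra):
    return pd.DataFrame({"exposure": e, "outcome": y, **extra},
                        index=[f"S{i}" for i in range(len(e))])


def _panel(M, ids=None):
    M = np.atleast_2d(np.asarray(M, dtype=float))
    ids = ids or [f"A{i}" for i in range(M.shape[0])]
    return pd.DataFrame(M, index=ids, columns=[f"S{i}" for i in range(M.shape[1])])


# -------------------------------------------------------------- total effect

def test_total_effect_sign_tracks_group_means():
    e = np.r_[np.zeros(5), np.ones(5)]
    beta, p, sign = total_effect(_pheno(e, np.r_[np.full(5, 2.0), np.ones(5)]
                                        + 0.01 * np.arange(10)))
    assert sign == -1 and beta < 0


def test_total_effect_identical_arms_is_null():
    e = np.r_[np.zeros(4), np.ones(4)]
    y = np.r_[1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
    beta, p, sign = total_effect(_pheno(e, y))
    assert beta == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert sign == 0


def test_total_effect_empty_arm_errors():
    with pytest.raises(ValueError):
        total_effect(_pheno(np.ones(6), np.arange(6.0)))


# ---------------------------------------------------------------- direction

def test_direction_gate_pass_and_abort():
    assert check_direction(-1, Direction(-1)) is True
    with pytest.raises(DirectionGateError):
        check_direction(+1, Direction(-1, "error"))
    with pytest.raises(DirectionGateError):
        check_direction(0, Direction(-1, "error"))


def test_direction_gate_warn_and_ignore_proceed(caplog):
    assert check_direction(0, Direction(-1, "warn")) is False
    assert any("does not match" in r.message for r in caplog.records)
    assert check_direction(+1, Direction(-1, "ignore")) is False


def test_direction_validation():
    with pytest.raises(ValueError):
        Direction(0)
    with pytest.raises(ValueError):
        Direction(1, gate_mode="maybe")


# ------------------------------------------------------------- em / my tests

def test_em_detects_exposure_tracking_analyte(rng):
    e = np.r_[np.zeros(10), np.ones(10)]
    M = _panel([e + 0.01 * rng.standard_normal(20),
                rng.standard_normal(20)])
    em = em_scores(M, _pheno(e, rng.standard_normal(20)), moderated=False)
    assert em.loc["A0", "p"] < 1e-3
    assert em.loc["A0", "beta"] == pytest.approx(1.0, abs=0.05)


def test_em_null_under_permuted_exposure(rng):
    """Permuting exposure labels severs the link: p approximately uniform."""
    e = rng.permutation(np.r_[np.zeros(15), np.ones(15)])
    M = _panel(rng.standard_normal((800, 30)))
    em = em_scores(M, _pheno(e, rng.standard_normal(30)), moderated=False)
    assert stats.kstest(em["p"], "uniform").pvalue > 0.01


def test_constant_analyte_flagged_and_excluded(rng, toy_panel):
    M, pheno = toy_panel
    M = M.copy()
    M.loc["FLAT"] = 3.0
    est = HitmanMediator(direction=-1, gate_mode="ignore").fit(M.T, pheno)
    assert est.excluded_analytes_ == ["FLAT"]
    assert "FLAT" not in set(est.results_["analyte_id"])


def test_my_partial_t_symmetric_between_orientations(rng):
    """Unmoderated t for (analyte ~ outcome + exposure, outcome coef) equals
    the t for (outcome ~ analyte + exposure, analyte coef): the partial
    correlation is orientation-free."""
    n = 25
    e = rng.standard_normal(n)
    y = 0.4 * e + rng.standard_normal(n)
    M = rng.standard_normal((12, n)) + 0.3 * y
    my = my_scores(_panel(M), _pheno(e, y), moderated=False)
    for g in range(12):
        X = np.column_stack([np.ones(n), M[g], e])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t_dual = beta[1] / se
        p_dual = 2 * stats.t.sf(abs(t_dual), n - 3)
        assert my["p"].iloc[g] == pytest.approx(p_dual, abs=1e-10)
        assert np.sign(my["beta"].iloc[g]) == np.sign(t_dual)


def test_my_detects_outcome_copy(rng):
    e = np.r_[np.zeros(10), np.ones(10)]
    y = rng.standard_normal(20)
    my = my_scores(_panel([y]), _pheno(e, y), moderated=False)
    assert my["p"].iloc[0] < 1e-6


# ------------------------------------------------------------ the main screen

def test_directional_rule_arithmetic():
    em_b, em_p = np.array([1.0]), np.array([0.02])
    my_b, my_p = np.array([1.0]), np.array([0.04])
    consistent, p_joint, p_dir = _combine_directional(em_b, em_p, my_b, my_p, 1,
                                                      "consistent")
    assert consistent[0]
    assert p_joint[0] == pytest.approx(0.04)
    assert p_dir[0] == pytest.approx(0.02)


def test_consistent_and_inconsistent_patterns(toy_panel):
    """Direction -1 (exposure lowers the outcome): an analyte lowered by the
    exposure whose decrease tracks the outcome decrease is consistent (p
    halved); one whose decrease tracks an outcome increase gets p = 1."""
    M, pheno = toy_panel
    res = hitman(M, pheno, Direction(-1)).set_index("analyte_id")
    assert res.loc["A_cons", "consistent"]
    assert res.loc["A_cons", "p_hitman"] == pytest.approx(
        res.loc["A_cons", "p_joint"] / 2)
    assert not res.loc["A_incons", "consistent"]
    assert res.loc["A_incons", "p_hitman"] == 1.0


def test_inconsistent_mode_flips_the_rule(toy_panel):
    M, pheno = toy_panel
    res = hitman(M, pheno, Direction(-1), mode="inconsistent").set_index("analyte_id")
    assert res.loc["A_cons", "p_hitman"] == 1.0
    assert res.loc["A_incons", "p_hitman"] == pytest.approx(
        res.loc["A_incons", "p_joint"] / 2)


@given(st.integers(-1000, 1000), st.integers(-1000, 1000),
       st.floats(1e-6, 1.0), st.floats(1e-6, 1.0),
       st.sampled_from([-1, 1]))
@settings(max_examples=200, deadline=None)
def test_mode_complementarity(eb, mb, ep, mp, sign):
    """With nonzero component effects exactly one of the two modes halves
    the joint p; the other returns 1."""
    em_b, my_b = np.array([float(eb or 1)]), np.array([float(mb or 1)])
    em_p, my_p = np.array([ep]), np.array([mp])
    _, pj, p_cons = _combine_directional(em_b, em_p, my_b, my_p, sign, "consistent")
    _, _, p_incons = _combine_directional(em_b, em_p, my_b, my_p, sign, "inconsistent")
    halved = sorted([p_cons[0], p_incons[0]])
    assert halved[0] == pytest.approx(pj[0] / 2)
    assert halved[1] == 1.0


def test_zero_component_effect_is_conservative():
    _, _, p = _combine_directional(np.array([0.0]), np.array([0.5]),
                                   np.array([1.0]), np.array([0.5]), 1,
                                   "consistent")
    assert p[0] == 1.0


def test_gate_blocks_contradicted_direction(toy_panel):
    M, pheno = toy_panel
    with pytest.raises(DirectionGateError):
        hitman(M, pheno, Direction(+1, "error"))


def test_joint_significance_equals_unmoderated_joint_p(toy_panel):
    M, pheno = toy_panel
    pj = joint_significance(M, pheno)
    res = hitman_simple(M, pheno, Direction(-1)).set_index("analyte_id")
    np.testing.assert_allclose(res.loc[pj.index, "p_joint"], pj, rtol=1e-12)


def test_dominance_of_directional_p(toy_panel):
    M, pheno = toy_panel
    pj = joint_significance(M, pheno)
    res = hitman_simple(M, pheno, Direction(-1)).set_index("analyte_id")
    for aid in pj.index:
        if res.loc[aid, "consistent"]:
            assert res.loc[aid, "p_hitman"] <= pj[aid]
        else:
            assert res.loc[aid, "p_hitman"] == 1.0


def test_single_analyte_panel_simple_equals_moderated(rng):
    """With one analyte there is no panel to learn a prior from (d0 = 0), so
    the moderated screen degenerates to the simple one exactly."""
    e = np.r_[np.zeros(8), np.ones(8)]
    y = -e + 0.5 * rng.standard_normal(16)
    M = _panel([-0.8 * e + 0.5 * rng.standard_normal(16)])
    pheno = _pheno(e, y)
    r_mod = hitman(M, pheno, Direction(-1, "ignore"), moderated=True)
    r_simple = hitman_simple(M, pheno, Direction(-1, "ignore"))
    np.testing.assert_allclose(r_mod["p_hitman"], r_simple["p_hitman"], rtol=1e-12)


def test_covariate_enters_all_models(rng, toy_panel):
    M, pheno = toy_panel
    pheno = pheno.copy()
    pheno["bmi_change"] = rng.standard_normal(len(pheno))
    res = hitman(M, pheno, Direction(-1), covariate_cols=["bmi_change"])
    assert len(res) == len(M)


def test_results_sorted_deterministically(toy_panel):
    M, pheno = toy_panel
    res = hitman(M, pheno, Direction(-1))
    key = list(zip(res["p_hitman"], res["analyte_id"]))
    assert key == sorted(key)


def test_estimator_params_clone_roundtrip():
    from sklearn.base import clone
    est = HitmanMediator(direction=-1, moderated=False, mode="inconsistent")
    est2 = clone(est)
    assert est2.get_params()["mode"] == "inconsistent"


# ---------------------------------------------------------------------- BH

def test_bh_hand_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert bh_adjust([0.3])[0] == pytest.approx(0.3)
    np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
    q = bh_adjust([0.01, np.nan, 0.5])
    assert np.isnan(q[1]) and not np.isnan(q[[0, 2]]).any()


def _bh_brute(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def test_bh_matches_brute_force_step_up(rng):
    for _ in range(1000):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_adjust(p), _bh_brute(p), rtol=1e-12)


# ------------------------------------------------------- potential outcomes

def test_potential_outcomes_strong_mediation(rng):
    n = 200
    e = rng.standard_normal(n)
    m = e + 0.1 * rng.standard_normal(n)
    y = m + 0.1 * rng.standard_normal(n)
    est = PotentialOutcomesMediation(nsim=2000, seed=1).fit(e, m, y)
    # se(acme) ~ 0.07 here, dominated by the m-e collinearity in the y model
    assert est.acme_ == pytest.approx(1.0, abs=0.2)
    assert est.pvalue_ < 0.01
    assert est.ci_[0] < est.acme_ < est.ci_[1]


def test_potential_outcomes_constant_exposure_errors():
    with pytest.raises(ValueError):
        potential_outcomes_mediation(np.ones(10), np.arange(10.0),
                                     np.arange(10.0), nsim=1000, seed=0)


def test_potential_outcomes_null_calibration():
    """With b = 0 the ACME p-value is approximately uniform over replicates."""
    rng = np.random.default_rng(5)
    ps = []
    for _ in range(300):
        n = 100
        e = rng.standard_normal(n)
        m = 0.5 * e + rng.standard_normal(n)
        y = 0.5 * e + rng.standard_normal(n)   # outcome ignores the mediator
        _, _, p = potential_outcomes_mediation(e, m, y, nsim=1000, seed=rng)
        ps.append(p)
    assert stats.kstest(ps, "uniform").pvalue > 0.001
    assert abs(np.mean(np.array(ps) < 0.05) - 0.05) < 0.05
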