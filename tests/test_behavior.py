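"""Signal-detection and diffusion analyses: d', log-duration curve fits,
AUC conversion, EZ diffusion, bootstrap, and the synthetic trial tables."""

import numpy as np
import pytest
from scipy.stats import norm

from gainscope.behavior import (DEFAULT_ALPHA_DISTRIBUTED, DEFAULT_KAPPA,
                                DPrimeCurveModel, EZParams,
                                PROTOCOL_DURATIONS_MS, auc_to_dprime,
                                bootstrap_ci, dprime, dprime_to_auc,
                                dprime_by_duration, ez_by_condition,
                                ez_diffusion, ez_forward, fit_dprime_curve,
                                log_curve, simulate_detection_trials,
                                simulate_ez_trials)


# -- d' ---------------------------------------------------------------------

def test_dprime_values_and_symmetry():
    assert dprime(50, 50, 50, 50) == pytest.approx(0.0)
    # H = 0.84, FA = 0.16 with exact rates
    assert dprime(84, 16, 16, 84) == pytest.approx(1.9891, abs=1e-3)
    assert dprime(16, 84, 84, 16) == pytest.approx(-dprime(84, 16, 16, 84))


def test_dprime_edge_correction_and_errors():
    d = dprime(10, 0, 0, 10)           # perfect performance stays finite
    assert np.isfinite(d) and d > 3
    with pytest.raises(ValueError):
        dprime(0, 0, 5, 5)
    with pytest.raises(ValueError):
        dprime(-1, 5, 5, 5)


# -- logarithmic curve fit ---------------------------------------------------

def test_curve_fit_noiseless_roundtrip():
    t = np.array(PROTOCOL_DURATIONS_MS)
    y = log_curve(t, 1.5, 1 / 163.6)
    res = fit_dprime_curve(t, y)
    assert res.alpha["all"] == pytest.approx(1.5, rel=0.01)
    assert res.kappa == pytest.approx(1 / 163.6, rel=0.01)
    # doubling d' doubles alpha, kappa unchanged
    res2 = fit_dprime_curve(t, 2 * y)
    assert res2.alpha["all"] == pytest.approx(3.0, rel=0.01)
    assert res2.kappa == pytest.approx(res.kappa, rel=0.01)
    # the curve passes through the origin: adding (0, 0) changes nothing
    res3 = fit_dprime_curve(np.r_[t, 0.0], np.r_[y, 0.0])
    assert res3.alpha["all"] == pytest.approx(res.alpha["all"], rel=1e-3)


def test_curve_fit_two_conditions_shared_kappa():
    t = np.array(PROTOCOL_DURATIONS_MS)
    y_d = log_curve(t, 1.5, 1 / 163.6)
    y_f = log_curve(t, 1.5 * 1.67, 1 / 163.6)
    model = DPrimeCurveModel(np.r_[t, t], np.r_[y_f, y_d],
                             ["focal"] * 6 + ["distributed"] * 6)
    res = model.fit()
    assert res.alpha_ratio == pytest.approx(1.67, rel=0.01)
    assert res.kappa_for("focal") == res.kappa_for("distributed")
    assert res.threshold_duration(1.0, "distributed") == pytest.approx(155.0,
                                                                       rel=0.02)
    assert "alpha" in res.summary()


def test_curve_fit_degenerate_all_zero():
    res = fit_dprime_curve([10, 20, 40], [0.0, 0.0, 0.0])
    assert res.alpha["all"] == 0.0
    assert not res.kappa_identifiable


# -- d' <-> AUC --------------------------------------------------------------

def test_auc_dprime_conversion():
    assert auc_to_dprime(0.5) == pytest.approx(0.0)
    d = auc_to_dprime(0.75)
    assert d == pytest.approx(0.9539, abs=1e-3)
    assert round(d) == 1
    for a in (0.1, 0.37, 0.5, 0.88):
        assert dprime_to_auc(auc_to_dprime(a)) == pytest.approx(a, abs=1e-10)
    with pytest.raises(ValueError):
        auc_to_dprime(1.0)
    with pytest.raises(ValueError):
        auc_to_dprime(0.0)


def test_auc_dprime_montecarlo_consistency(rng):
    """AUC computed from two equal-variance normal score distributions
    separated by d' maps back to that d'."""
    from gainscope.observer import auc

    d_true = 1.2
    present = rng.normal(d_true, 1.0, 100_000)
    absent = rng.normal(0.0, 1.0, 100_000)
    assert auc_to_dprime(auc(present, absent)) == pytest.approx(d_true,
                                                                abs=0.02)


# -- EZ diffusion ------------------------------------------------------------

@pytest.mark.parametrize("v,a,ter", [(0.25, 0.12, 0.3), (0.1, 0.08, 0.45),
                                     (0.4, 0.2, 0.2), (-0.15, 0.1, 0.3)])
def test_ez_roundtrip_exact(v, a, ter):
    pc, mrt, vrt = ez_forward(EZParams(v, a, ter))
    rec = ez_diffusion(pc, mrt, vrt)
    assert rec.drift == pytest.approx(v, abs=1e-8)
    assert rec.bound == pytest.approx(a, abs=1e-8)
    assert rec.non_decision == pytest.approx(ter, abs=1e-8)


def test_ez_drift_monotone_in_accuracy():
    drifts = [ez_diffusion(pc, 0.5, 0.04).drift
              for pc in np.linspace(0.55, 0.98, 10)]
    assert np.all(np.diff(drifts) > 0)


def test_ez_nondecision_is_mrt_minus_decision_time():
    params = ez_diffusion(0.85, 0.62, 0.05)
    _, mrt, _ = ez_forward(params)
    assert mrt == pytest.approx(0.62, abs=1e-10)
    # Ter accounts for exactly the predicted decision time
    y = -params.drift * params.bound / params.scaling**2
    mdt = (params.bound / (2 * params.drift)) * (1 - np.exp(y)) / (1 + np.exp(y))
    assert params.non_decision == pytest.approx(0.62 - mdt, abs=1e-12)


def test_ez_edge_correction():
    rec = ez_diffusion(1.0, 0.5, 0.04, n_trials=100)
    assert np.isfinite(rec.drift) and rec.drift > 0
    rec05 = ez_diffusion(0.5, 0.5, 0.04, n_trials=100)
    assert np.isfinite(rec05.drift)
    with pytest.raises(ValueError):
        ez_diffusion(0.8, 0.5, 0.0)


# -- bootstrap ---------------------------------------------------------------

def test_bootstrap_constant_and_determinism():
    lo, hi = bootstrap_ci(np.mean, np.full(20, 3.25), seed=1)
    assert lo == hi == 3.25
    a = bootstrap_ci(np.median, np.arange(30.0), seed=9)
    b = bootstrap_ci(np.median, np.arange(30.0), seed=9)
    assert a == b
    with pytest.raises(ValueError):
        bootstrap_ci(np.mean, [])


def test_bootstrap_coverage_on_normal_data():
    """95% percentile intervals for the mean cover the true value about 95%
    of the time (n = 200 per replicate, 200 meta-replicates)."""
    rng = np.random.default_rng(77)
    covered = 0
    for i in range(200):
        data = rng.standard_normal(200)
        lo, hi = bootstrap_ci(np.mean, data, n_boot=500, seed=i)
        covered += lo <= 0.0 <= hi
    assert 0.89 <= covered / 200 <= 0.99


# -- synthetic trial tables --------------------------------------------------

def test_trial_table_schema_and_determinism():
    t1 = simulate_detection_trials(n_trials_per_cell=50, seed=3)
    t2 = simulate_detection_trials(n_trials_per_cell=50, seed=3)
    assert t1.equals(t2)
    assert set(t1["duration_ms"]) == set(PROTOCOL_DURATIONS_MS)
    assert set(t1["condition"]) == {"focal", "distributed"}
    assert (t1["rt"] > 0).all()
    pts = dprime_by_duration(t1)
    assert len(pts) == 12
    # sensitivity increases with duration in both conditions
    for cond, sub in pts.groupby("condition"):
        s = sub.sort_values("duration_ms")["dprime"].to_numpy()
        assert s[-1] > s[0]


def test_alpha_ratio_recovery_from_trials():
    trials = simulate_detection_trials(n_trials_per_cell=800, seed=5)
    res = DPrimeCurveModel.from_trials(trials).fit()
    assert res.alpha["focal"] / res.alpha["distributed"] == pytest.approx(
        1.67, rel=0.15)


def test_ez_recovery_from_ez_matched_trials():
    ez = ez_by_condition(simulate_ez_trials(n_trials=4000, seed=2))
    ezi = ez.set_index("condition")
    assert ezi.loc["focal", "drift"] / ezi.loc["distributed", "drift"] == \
        pytest.approx(1.61, rel=0.1)
    assert ezi.loc["distributed", "non_decision"] == pytest.approx(0.38,
                                                                   abs=0.04)
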