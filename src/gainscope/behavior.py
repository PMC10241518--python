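"""Signal-detection and diffusion-model analysis of behavioral trial tables.

Covers the analysis chain for a cued detection experiment:

* sensitivity d' = Z(H) - Z(FA) per duration bin;
* a logarithmic sensitivity curve d'(t) = alpha * log(kappa * t + 1), with a
  per-condition alpha and (by default) a shared rate kappa, exposed through a
  statsmodels-style ``DPrimeCurveModel(...).fit() -> DPrimeCurveResults``;
* conversion between d' and ROC area, d' = sqrt(2) * Z(AUC);
* the closed-form EZ-diffusion transform from (percent correct, mean RT,
  RT variance) to (drift rate v, bound separation a, non-decision time Ter);
* percentile bootstrap confidence intervals (n = 1000, 95% by default).

A synthetic trial-table generator reproduces the study conditions — six
stimulus durations from 8.3 to 266.7 ms, focal/distributed cueing with a
focal d' advantage — so every estimator can be validated by parameter
recovery without any human data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: stimulus durations (ms): 1, 2, 4, 8, 16, 32 video frames at 120 Hz
PROTOCOL_DURATIONS_MS = (8.3, 16.7, 33.3, 66.7, 133.3, 266.7)

EZ_SCALING = 0.1   # conventional diffusion scaling parameter s


# ---------------------------------------------------------------------------
# d-prime and AUC
# ---------------------------------------------------------------------------

def _edge_corrected_rate(count: int, n: int) -> float:
    """Log-linear correction (count + 0.5) / (n + 1), applied only when the
    raw rate would be 0 or 1 (keeping Z finite)."""
    rate = count / n
    if rate in (0.0, 1.0):
        return (count + 0.5) / (n + 1)
    return rate


def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """Sensitivity d' = Z(H) - Z(FA) from response counts."""
    for v in (hits, misses, false_alarms, correct_rejections):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_sig = hits + misses
    n_noise = false_alarms + correct_rejections
    if n_sig == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    H = _edge_corrected_rate(hits, n_sig)
    FA = _edge_corrected_rate(false_alarms, n_noise)
    return float(norm.ppf(H) - norm.ppf(FA))


def auc_to_dprime(auc: float) -> float:
    """d' = sqrt(2) * Z(AUC) (equal-variance signal detection)."""
    if not 0.0 < auc < 1.0:
        raise ValueError("AUC must be strictly between 0 and 1")
    return float(np.sqrt(2.0) * norm.ppf(auc))


def dprime_to_auc(d: float) -> float:
    return float(norm.cdf(d / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# logarithmic d' curve: statsmodels-style model / results pair
# ---------------------------------------------------------------------------

def log_curve(t, alpha, kappa):
    """d'(t) = alpha * log(kappa t + 1); passes through the origin."""
    return alpha * np.log(kappa * np.asarray(t, float) + 1.0)


class DPrimeCurveModel:
    """Least-squares model for d' as a logarithmic function of duration.

    Parameters
    ----------
    durations, dprimes : array-like
        Per-bin stimulus durations (ms) and observed d' values.
    condition : array-like of str, optional
        Condition label per point (e.g. focal/distributed).  Each condition
        gets its own scale alpha; the rate kappa (1/ms) is shared across
        conditions unless ``share_kappa=False``.
    """

    def __init__(self, durations, dprimes, condition=None, share_kappa=True):
        self.durations = np.asarray(durations, float)
        self.dprimes = np.asarray(dprimes, float)
        if self.durations.shape != self.dprimes.shape:
            raise ValueError("durations and dprimes must align")
        if np.sum(np.isfinite(self.dprimes)) < 2:
            raise ValueError("need at least 2 finite d' points")
        if condition is None:
            condition = np.array(["all"] * len(self.durations))
        self.condition = np.asarray(condition)
        self.conditions = list(dict.fromkeys(self.condition.tolist()))
        self.share_kappa = bool(share_kappa)

    @classmethod
    def from_trials(cls, trials: pd.DataFrame, share_kappa: bool = True
                    ) -> "DPrimeCurveModel":
        pts = dprime_by_duration(trials)
        return cls(pts["duration_ms"], pts["dprime"], pts["condition"],
                   share_kappa=share_kappa)

    def _fit_once(self, kappa0: float):
        conds = self.conditions
        mask = np.isfinite(self.dprimes)
        t, y, cond = self.durations[mask], self.dprimes[mask], self.condition[mask]

        def resid(theta):
            alphas, log_k = theta[:-1], theta[-1]
            k = np.exp(log_k)
            r = np.empty_like(y)
            for ci, cname in enumerate(conds):
                sel = cond == cname
                r[sel] = y[sel] - log_curve(t[sel], alphas[ci], k)
            return r

        x0 = np.concatenate([np.full(len(conds), max(np.abs(y).max(), 0.1)),
                             [np.log(kappa0)]])
        return optimize.least_squares(resid, x0, method="lm", max_nfev=2000)

    def fit(self, kappa_grid: Sequence[float] = tuple(np.logspace(-3, -1, 7))
            ) -> "DPrimeCurveResults":
        """Nonlinear least squares with multi-start over kappa to avoid local
        minima; degenerate all-zero data yields alpha = 0 with kappa flagged
        unidentifiable."""
        if self.share_kappa:
            best = None
            for k0 in kappa_grid:
                sol = self._fit_once(k0)
                if best is None or sol.cost < best.cost:
                    best = sol
            alphas = dict(zip(self.conditions, best.x[:-1]))
            kappa = float(np.exp(best.x[-1]))
            resid = best.fun
            identifiable = bool(np.any(np.abs(self.dprimes) > 1e-12))
            if not identifiable:
                alphas = {c: 0.0 for c in self.conditions}
            return DPrimeCurveResults(self, alphas, kappa, resid,
                                      kappa_identifiable=identifiable)
        # independent per-condition fits
        alphas, kappas, resid = {}, {}, []
        for cname in self.conditions:
            sel = self.condition == cname
            sub = DPrimeCurveModel(self.durations[sel], self.dprimes[sel])
            res = sub.fit(kappa_grid)
            alphas[cname] = res.alpha["all"]
            kappas[cname] = res.kappa
            resid.append(res.resid)
        return DPrimeCurveResults(self, alphas, kappas, np.concatenate(resid))


@dataclass
class DPrimeCurveResults:
    """Fitted logarithmic sensitivity curve."""

    model: DPrimeCurveModel
    alpha: dict                   # per-condition scale
    kappa: object                 # shared float, or per-condition dict
    resid: np.ndarray
    kappa_identifiable: bool = True

    def kappa_for(self, condition) -> float:
        return self.kappa[condition] if isinstance(self.kappa, dict) else self.kappa

    def predict(self, t, condition=None) -> np.ndarray:
        condition = condition or self.model.conditions[0]
        return log_curve(t, self.alpha[condition], self.kappa_for(condition))

    def threshold_duration(self, level: float = 1.0, condition=None) -> float:
        """Duration (ms) at which the fitted curve reaches d' = level."""
        condition = condition or self.model.conditions[0]
        a = self.alpha[condition]
        k = self.kappa_for(condition)
        if a <= 0 or k <= 0:
            return float("inf")
        return float((np.exp(level / a) - 1.0) / k)

    @property
    def alpha_ratio(self) -> float:
        """Ratio of the two conditions' alphas (first / second in order of
        appearance); the focal-vs-distributed sensitivity scaling."""
        if len(self.model.conditions) != 2:
            raise ValueError("alpha_ratio is defined for exactly 2 conditions")
        c0, c1 = self.model.conditions
        return self.alpha[c0] / self.alpha[c1]

    def summary(self) -> str:
        lines = ["d'(t) = alpha * log(kappa t + 1)   [t in ms]",
                 "-" * 46]
        for c in self.model.conditions:
            lines.append(f"  alpha[{c}] = {self.alpha[c]:.4f}   "
                         f"kappa = {self.kappa_for(c):.6f} /ms   "
                         f"(1/kappa = {1 / self.kappa_for(c):.1f} ms)")
        lines.append(f"  residual SS = {float(np.sum(self.resid ** 2)):.4f}  "
                     f"n = {len(self.resid)}")
        if not self.kappa_identifiable:
            lines.append("  note: all-zero data; kappa not identifiable")
        return "\n".join(lines)


def fit_dprime_curve(durations, dprimes, condition=None, share_kappa=True
                     ) -> DPrimeCurveResults:
    """Functional wrapper around :class:`DPrimeCurveModel`."""
    return DPrimeCurveModel(durations, dprimes, condition, share_kappa).fit()


# ---------------------------------------------------------------------------
# EZ diffusion
# ---------------------------------------------------------------------------

@dataclass
class EZParams:
    """Closed-form diffusion parameters: drift rate v, bound separation a,
    non-decision time Ter (s), under scaling s."""

    drift: float
    bound: float
    non_decision: float
    scaling: float = EZ_SCALING


def ez_forward(params: EZParams) -> tuple:
    """Moment predictions (P_correct, mean RT, RT variance) of the EZ model."""
    v, a, s = params.drift, params.bound, params.scaling
    if a <= 0:
        raise ValueError("bound separation must be positive")
    y = -v * a / s**2
    pc = 1.0 / (1.0 + np.exp(y))
    if v == 0:
        mdt = a**2 / (4 * s**2)
        vrt = a**4 / (24 * s**4)  # v -> 0 limit of the general expression
    else:
        ey = np.exp(y)
        mdt = (a / (2 * v)) * (1 - ey) / (1 + ey)
        vrt = (a * s**2 / (2 * v**3)) * (2 * y * ey - ey**2 + 1) / (ey + 1) ** 2
    return float(pc), float(params.non_decision + mdt), float(vrt)


def ez_diffusion(p_correct: float, mean_rt: float, var_rt: float,
                 n_trials: Optional[int] = None, s: float = EZ_SCALING
                 ) -> EZParams:
    """Invert (P_correct, MRT, VRT) to (v, a, Ter) in closed form.

    P_correct exactly 0, 0.5 or 1 is edge-corrected first (it makes the
    logit degenerate): toward 0.5 by the log-linear rule when at the
    extremes, and away from 0.5 by half a trial's worth when exactly at
    chance.
    """
    if var_rt <= 0:
        raise ValueError("RT variance must be positive")
    n = n_trials if n_trials is not None else 1000
    pc = p_correct
    if pc <= 0.0 or pc >= 1.0:
        pc = (pc * n + 0.5) / (n + 1)
        logger.info("ez_diffusion: edge-corrected Pc=%.3f -> %.4f", p_correct, pc)
    if pc == 0.5:
        pc = 0.5 + 0.5 / (n + 1)
        logger.info("ez_diffusion: Pc at chance; nudged to %.4f", pc)
    L = np.log(pc / (1 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5)
    v = np.sign(pc - 0.5) * s * (x / var_rt) ** 0.25
    a = s**2 * L / v
    y = -v * a / s**2
    ey = np.exp(y)
    mdt = (a / (2 * v)) * (1 - ey) / (1 + ey)
    return EZParams(float(v), float(a), float(mean_rt - mdt), s)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic: Callable, data, n_boot: int = 1000,
                 level: float = 0.95, seed: Optional[int] = None) -> tuple:
    """Seeded percentile bootstrap interval for ``statistic(data)``."""
    data = np.asarray(data)
    if data.size == 0:
        raise ValueError("bootstrap needs non-empty data")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(data), size=(n_boot, len(data)))
    stats = np.array([statistic(data[i]) for i in idx])
    lo = float(np.percentile(stats, 100 * (1 - level) / 2))
    hi = float(np.percentile(stats, 100 * (1 + level) / 2))
    return (lo, hi)


# ---------------------------------------------------------------------------
# synthetic trial tables (the study conditions, simulated)
# ---------------------------------------------------------------------------

#: distributed-condition scale consistent with a d' = 1 threshold at 155 ms
#: under kappa = 1/163.6 per ms
DEFAULT_ALPHA_DISTRIBUTED = 1.0 / np.log(155.0 / 163.6 + 1.0)
DEFAULT_ALPHA_RATIO = 1.67            # focal / distributed sensitivity scaling
DEFAULT_KAPPA = 1.0 / 163.6           # 1/ms
#: per-condition diffusion parameters used for RT generation: the focal
#: condition has 1.61x the drift and 1.57x the bound of distributed, and a
#: shorter non-decision time (0.26 s vs 0.38 s)
DEFAULT_EZ = {
    "distributed": EZParams(drift=0.18, bound=0.11, non_decision=0.38),
    "focal": EZParams(drift=0.18 * 1.61, bound=0.11 * 1.57, non_decision=0.26),
}


def simulate_detection_trials(n_trials_per_cell: int = 400,
                              alpha_distributed: float = DEFAULT_ALPHA_DISTRIBUTED,
                              alpha_ratio: float = DEFAULT_ALPHA_RATIO,
                              kappa: float = DEFAULT_KAPPA,
                              durations=PROTOCOL_DURATIONS_MS,
                              ez_params: dict = None,
                              seed: int = 0) -> pd.DataFrame:
    """Simulate a focal/distributed detection trial table.

    Choices follow an unbiased equal-variance observer whose sensitivity is
    d'(t) = alpha_cond * log(kappa t + 1) (hit rate Phi(d'/2), false-alarm
    rate Phi(-d'/2)); reaction times are drawn per condition from a normal
    law whose mean and variance match the EZ-diffusion forward moments
    (negatives rejected), so the EZ transform is recoverable from the table.
    """
    ez_params = ez_params or DEFAULT_EZ
    rng = np.random.default_rng([seed, 41])
    alphas = {"distributed": alpha_distributed,
              "focal": alpha_distributed * alpha_ratio}
    rows = []
    for condition, alpha in alphas.items():
        _, mrt, vrt = ez_forward(ez_params[condition])
        sd = np.sqrt(vrt)
        for t in durations:
            d = log_curve(t, alpha, kappa)
            hit_rate = norm.cdf(d / 2)
            fa_rate = norm.cdf(-d / 2)
            present = rng.random(n_trials_per_cell) < 0.5
            p_resp = np.where(present, hit_rate, fa_rate)
            responded = rng.random(n_trials_per_cell) < p_resp
            rt = rng.normal(mrt, sd, size=n_trials_per_cell)
            while np.any(rt <= 0):
                bad = rt <= 0
                rt[bad] = rng.normal(mrt, sd, size=int(bad.sum()))
            for i in range(n_trials_per_cell):
                rows.append({
                    "observer": 0, "category": 0, "condition": condition,
                    "duration_ms": t, "target_present": bool(present[i]),
                    "response": bool(responded[i]),
                    "correct": bool(responded[i] == present[i]),
                    "rt": float(rt[i]),
                })
    return pd.DataFrame(rows)


def simulate_ez_trials(ez_params: dict = None, n_trials: int = 2000,
                       seed: int = 0) -> pd.DataFrame:
    """Trial table whose choices and RT moments both follow the EZ-diffusion
    forward model, so :func:`ez_diffusion` is validated by parameter
    recovery: accuracy ~ Bernoulli(Pc(v, a)) and RT ~ Normal(MRT, VRT)
    (negatives rejected)."""
    ez_params = ez_params or DEFAULT_EZ
    rng = np.random.default_rng([seed, 43])
    rows = []
    for condition, params in ez_params.items():
        pc, mrt, vrt = ez_forward(params)
        sd = np.sqrt(vrt)
        correct = rng.random(n_trials) < pc
        rt = rng.normal(mrt, sd, size=n_trials)
        while np.any(rt <= 0):
            bad = rt <= 0
            rt[bad] = rng.normal(mrt, sd, size=int(bad.sum()))
        for i in range(n_trials):
            rows.append({"observer": 0, "condition": condition,
                         "correct": bool(correct[i]), "rt": float(rt[i])})
    return pd.DataFrame(rows)


def dprime_by_duration(trials: pd.DataFrame) -> pd.DataFrame:
    """Bin a trial table by (condition, duration) and compute d' per cell."""
    out = []
    for (cond, dur), cell in trials.groupby(["condition", "duration_ms"]):
        sig = cell[cell["target_present"]]
        noise = cell[~cell["target_present"]]
        out.append({
            "condition": cond, "duration_ms": dur,
            "dprime": dprime(int(sig["response"].sum()),
                             int((~sig["response"]).sum()),
                             int(noise["response"].sum()),
                             int((~noise["response"]).sum())),
            "n": len(cell),
        })
    return pd.DataFrame(out)


def ez_by_condition(trials: pd.DataFrame) -> pd.DataFrame:
    """EZ-diffusion parameters per condition from a trial table."""
    out = []
    for cond, cell in trials.groupby("condition"):
        pc = cell["correct"].mean()
        params = ez_diffusion(pc, cell["rt"].mean(), cell["rt"].var(ddof=1),
                              n_trials=len(cell))
        out.append({"condition": cond, "p_correct": pc,
                    "drift": params.drift, "bound": params.bound,
                    "non_decision": params.non_decision})
    return pd.DataFrame(out)
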