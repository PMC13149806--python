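"""MAP estimation of accumulator parameters from choices and RTs.

Free parameters per participant: drift efficiency (one scalar per attribute
stream), response threshold, non-decision time, and — for the start-time
model — per-attribute onset latencies.  Diffusion noise is fixed at
``sigma^2 = 0.5`` per option-stream per ms to pin the evidence scale.

The likelihood of a (choice, RT) pair is the Wiener first-passage density at
the chosen boundary evaluated at the decision time ``RT - NDT`` (ms), with
drift ``v = sum_a delta_a * dmu_a`` and difference-process variance
``2 n sigma^2``.  The start-time model has piecewise-constant drift and uses
the grid solver from :mod:`driftspread.fpt` instead of the analytic density.

Priors are Gaussian on transformed parameters: log for the positives
(drift, threshold; prior mean at 1) and logit for the unit-interval
parameters (NDT, start times; prior mean at 0.4), with unit prior SD on the
transformed scale by default.  The posterior mode is found by multi-start
quasi-Newton optimisation; a curvature-based (Laplace) covariance at the
mode provides approximate uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .config import FitConfig
from .fpt import stddm_fpt, wiener_fpt_density
from .simulate import DEFAULT_NOISE_VAR, ModelParams

log = logging.getLogger(__name__)

#: parameter layout per model kind: (name, transform) in optimisation order
_LAYOUT = {
    "ddm": (("drift", "log"), ("threshold", "log"), ("ndt", "logit")),
    "maddm": (
        ("drift_p", "log"), ("drift_n", "log"),
        ("threshold", "log"), ("ndt", "logit"),
    ),
    "stddm": (
        ("drift_p", "log"), ("drift_n", "log"),
        ("threshold", "log"), ("ndt", "logit"),
        ("start_p", "logit"), ("start_n", "logit"),
    ),
}


@dataclass
class PriorSpec:
    """Gaussian priors on transformed parameters.

    ``means`` holds natural-scale prior centres (1 for drift and threshold,
    0.4 for NDT and start times); ``scale`` is the common SD on the
    transformed (log / logit) scale.
    """

    means: dict | None = None
    scale: float = 1.0

    def centre(self, name: str) -> float:
        defaults = {"drift": 1.0, "drift_p": 1.0, "drift_n": 1.0,
                    "threshold": 1.0, "ndt": 0.4, "start_p": 0.4, "start_n": 0.4}
        if self.means and name in self.means:
            return self.means[name]
        return defaults[name]


@dataclass
class FitResult:
    participant_id: object
    kind: str
    params: ModelParams
    estimates: dict
    cov_transformed: np.ndarray
    log_joint: float
    log_joint_at_prior: float
    converged: bool
    n_trials: int


def _to_natural(x, layout):
    out = {}
    for val, (name, tr) in zip(x, layout):
        out[name] = float(np.exp(val)) if tr == "log" else float(expit(val))
    return out


def _to_transformed(values, layout):
    x = np.empty(len(layout))
    for k, (name, tr) in enumerate(layout):
        v = values[name]
        x[k] = np.log(v) if tr == "log" else logit(np.clip(v, 1e-6, 1 - 1e-6))
    return x


def _params_from_estimates(kind: str, est: dict) -> ModelParams:
    if kind == "ddm":
        return ModelParams(kind="ddm", drift=[est["drift"]],
                           threshold=est["threshold"], ndt=est["ndt"])
    drift = [est["drift_p"], est["drift_n"]]
    if kind == "maddm":
        return ModelParams(kind="maddm", drift=drift,
                           threshold=est["threshold"], ndt=est["ndt"])
    return ModelParams(kind="stddm", drift=drift, threshold=est["threshold"],
                       ndt=est["ndt"],
                       start_times=[est["start_p"], est["start_n"]])


def trial_loglik(params: ModelParams, dmu, choice, rt, floor=np.log(1e-12)):
    """Log density of one (choice, RT) pair under ``params``.

    ``dmu`` is the value difference (DDM) or per-attribute differences.
    ``rt`` in seconds.  RT at or below NDT yields the floor penalty rather
    than -inf so the MAP objective stays finite.
    """
    dmu = np.atleast_1d(np.asarray(dmu, dtype=float))
    ll = loglik_vector(params, dmu[None, :], np.atleast_1d(choice),
                       np.atleast_1d(float(rt)), floor=floor)
    return float(ll[0])


def loglik_vector(params: ModelParams, dmu_mat, choice, rt, floor=np.log(1e-12),
                  truncation=None):
    """Vectorised per-trial log-likelihoods for constant-drift models.

    ``truncation=(rt_min, rt_max)`` conditions each trial's density on the
    RT falling inside the observation window (the likelihood appropriate for
    data that passed the RT exclusions).  For the start-time model this
    falls back to per-trial grid solves; see :func:`stddm_trial_loglik`.
    """
    choice = np.asarray(choice)
    rt = np.asarray(rt, dtype=float)
    t_dec = (rt - params.ndt) * 1000.0
    ok = t_dec > 0
    out = np.full(rt.shape, floor, dtype=float)
    if params.kind == "stddm":
        for i in np.nonzero(ok)[0]:
            out[i] = stddm_trial_loglik(
                params, dmu_mat[i], int(choice[i]), float(rt[i]), floor=floor
            )
        return out
    n = params.n_attributes
    v = (np.atleast_2d(dmu_mat) * params.drift).sum(axis=1)
    sigma_d2 = 2.0 * n * params.noise_var
    up, lo = wiener_fpt_density(t_dec[ok], 0.0, params.threshold, sigma_d2)
    # drift enters only through an exponential tilt of the zero-drift series:
    # f_lower(t|v) = f_lower(t|0) * exp(-vn*a/2 - vn^2 t/2), and the upper
    # density is the same with vn -> -vn (start is symmetric).  Work in log
    # space so large drifts cannot overflow.
    s = np.sqrt(sigma_d2)
    a = 2.0 * params.threshold / s
    vn = v[ok] / s
    with np.errstate(divide="ignore"):
        log_base = np.where(choice[ok] == 1, np.log(up), np.log(lo))
    sign = np.where(choice[ok] == 1, 1.0, -1.0)
    ldens = log_base + sign * vn * a * 0.5 - vn**2 * t_dec[ok] / 2.0
    if truncation is not None:
        t_lo = max((truncation[0] - params.ndt) * 1000.0, 1.0)
        t_hi = max((truncation[1] - params.ndt) * 1000.0, t_lo + 1.0)
        # window mass: up(t|v)+lo(t|v) = f0(t) * 2 cosh(vn a/2) * exp(-vn^2 t/2)
        tg = np.linspace(t_lo, t_hi, 400)
        f0 = wiener_fpt_density(tg, 0.0, params.threshold, sigma_d2)[0]
        I = np.trapezoid(f0[None, :] * np.exp(-np.outer(vn**2, tg) / 2.0), tg, axis=1)
        x = vn * a * 0.5
        log_z = np.logaddexp(x, -x) + np.log(np.maximum(I, 1e-300))
        ldens = ldens - log_z
    out[ok] = np.maximum(ldens, floor)
    return out


def stddm_trial_loglik(params: ModelParams, dmu_attr, choice, rt,
                       floor=np.log(1e-12), dt_ms=1.0, dx=0.5):
    """Grid-solver likelihood for one start-time-model trial."""
    t_dec = (rt - params.ndt) * 1000.0
    if t_dec <= 0:
        return floor
    rates = params.drift * np.asarray(dmu_attr, dtype=float)
    onset = params.start_times * 1000.0
    res = stddm_fpt(rates, onset, params.threshold,
                    noise_var=params.noise_var,
                    t_max_ms=t_dec + dt_ms, dt_ms=dt_ms, dx=dx)
    k = min(int(np.floor(t_dec / dt_ms)), len(res.t_grid) - 1)
    dens = res.upper_density[k] if choice == 1 else res.lower_density[k]
    return float(max(np.log(max(dens, 0.0)) if dens > 0 else floor, floor))


def _neg_log_joint(x, kind, layout, dmu_mat, choice, rt, prior: PriorSpec,
                   prior_centre_x, floor, truncation=None):
    est = _to_natural(x, layout)
    try:
        params = _params_from_estimates(kind, est)
    except ValueError:
        return 1e12
    ll = loglik_vector(params, dmu_mat, choice, rt, floor=floor,
                       truncation=truncation).sum()
    lp = -0.5 * np.sum(((x - prior_centre_x) / prior.scale) ** 2)
    return -(ll + lp)


def _moment_start(dmu_mat, choice, rt, layout, noise_var):
    """Crude method-of-moments initialisation for the optimiser."""
    n = dmu_mat.shape[1]
    sigma_d2 = 2.0 * n * noise_var
    ndt0 = 0.35
    t_bar = max(np.mean(rt) - ndt0, 0.05) * 1000.0
    theta0 = float(np.sqrt(max(t_bar * sigma_d2 / 2.0, 25.0)))
    dv = dmu_mat.sum(axis=1)
    # logistic slope of choice on summed difference ~ 2*theta*delta/sigma_d2
    sd_dv = np.std(dv) or 1.0
    r = np.corrcoef(dv, choice)[0, 1] if np.std(choice) > 0 else 0.3
    slope = np.clip(4.0 * r / sd_dv, 0.5, 200.0)
    delta0 = float(np.clip(slope * sigma_d2 / (2.0 * theta0), 1e-3, 0.5))
    vals = {}
    for name, _ in layout:
        if name.startswith("drift"):
            vals[name] = delta0
        elif name == "threshold":
            vals[name] = theta0
        elif name == "ndt":
            vals[name] = ndt0
        else:
            vals[name] = 0.2
    return _to_transformed(vals, layout)


def fit_participant(
    kind: str,
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    participant_id=None,
    rng: np.random.Generator | None = None,
    min_trials: int = 20,
    truncation: tuple | str | None = "auto",
) -> FitResult:
    """MAP fit of one participant's choices and RTs under one model kind.

    ``trials`` needs columns ``choice``, ``rt`` and ``dv`` (DDM) or
    ``dp``/``dn`` (multi-attribute kinds).  ``truncation="auto"`` conditions
    the likelihood on the standard 0.5-10 s RT observation window (use
    ``None`` for untruncated data).
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    rng = rng or np.random.default_rng(0)
    if kind not in _LAYOUT:
        raise ValueError(f"unknown model kind {kind!r}")
    if len(trials) < min_trials:
        raise ValueError(f"need >= {min_trials} trials, got {len(trials)}")
    layout = _LAYOUT[kind]
    if kind == "ddm":
        dmu_mat = trials[["dv"]].to_numpy(dtype=float)
    else:
        dmu_mat = trials[["dp", "dn"]].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy()
    rt = trials["rt"].to_numpy(dtype=float)
    floor = config.loglik_floor

    if truncation == "auto":
        from .derive import RT_MAX_S, RT_MIN_S

        truncation = (RT_MIN_S, RT_MAX_S)
    if kind == "stddm":
        truncation = None  # grid likelihood; window correction not applied
    centre_x = _to_transformed({n: priors.centre(n) for n, _ in layout}, layout)
    args = (kind, layout, dmu_mat, choice, rt, priors, centre_x, floor, truncation)

    starts = [centre_x, _moment_start(dmu_mat, choice, rt, layout, DEFAULT_NOISE_VAR)]
    while len(starts) < config.n_starts + 1:
        starts.append(starts[1] + rng.normal(0, 0.5, size=len(layout)))

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            _neg_log_joint, x0, args=args, method="L-BFGS-B",
            options={"maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"participant {participant_id}: all fit starts failed")

    est = _to_natural(best.x, layout)
    params = _params_from_estimates(kind, est)
    cov = _laplace_cov(best.x, args)
    lj_mode = -best.fun
    lj_prior = -_neg_log_joint(centre_x, *args)
    return FitResult(
        participant_id=participant_id, kind=kind, params=params,
        estimates=est, cov_transformed=cov,
        log_joint=lj_mode, log_joint_at_prior=lj_prior,
        converged=converged, n_trials=len(trials),
    )


def _laplace_cov(x, args, h=1e-4):
    """Covariance from a central-difference Hessian of the negative log joint."""
    k = len(x)
    H = np.zeros((k, k))
    f = lambda z: _neg_log_joint(z, *args)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((k, k), np.nan)


def fit_cohort(kind: str, trials: pd.DataFrame, priors: PriorSpec | None = None,
               config: FitConfig | None = None, seed: int = 0,
               truncation: tuple | str | None = "auto") -> dict:
    """Fit every participant in a trial table; returns {participant_id: FitResult}."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(8,)))
    out = {}
    for pid, grp in trials.groupby("participant_id", sort=True):
        try:
            out[pid] = fit_participant(
                kind, grp, priors=priors, config=config,
                participant_id=pid, rng=rng, truncation=truncation,
            )
        except (RuntimeError, ValueError) as exc:
            log.warning("participant %s: fit failed (%s)", pid, exc)
    return out
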