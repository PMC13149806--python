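"""Trial-level simulators for the DDM family.

Three nested accumulator models of binary value-based choice:

* **DDM** — net evidence for option 1 over option 2 accumulates at rate
  ``delta * (mu1 - mu2)`` plus white noise until it reaches ``+threshold``
  (choose option 1) or ``-threshold`` (choose option 2).
* **maDDM** — one evidence stream per attribute, each with its own drift
  scalar ``delta_a`` applied to the attribute-level value difference; the
  streams sum into the net accumulator that is compared with the threshold.
* **stDDM** — the maDDM with per-attribute onset latencies: an attribute
  contributes nothing before its start time.

Time is discretised at 1 ms. Momentary noise on each option's accumulator
(per attribute stream) is an independent draw from ``N(0, sigma^2)`` with
``sigma^2 = 0.5`` per step, so the *difference* process for one attribute has
per-step variance ``2 sigma^2`` and the net process ``2 n sigma^2`` for
``n`` attributes.  Because only evidence differences enter the stopping rule
and the readout, the simulator integrates the difference process of each
attribute stream directly (one Gaussian draw per attribute per step), which
is distributionally identical to simulating the two options separately.

Response time is the crossing step converted to seconds plus the
non-decision time: ``RT = T / 1000 + NDT``.  Trials that have not crossed by
10,000 steps (10 s) are flagged as non-terminated; downstream filtering
removes them together with over-long RTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_STEPS = 10_000
STEP_MS = 1  # accumulation step, milliseconds
DEFAULT_NOISE_VAR = 0.5  # per-option, per-attribute, per-step variance

_KINDS = ("ddm", "maddm", "stddm")


@dataclass
class ModelParams:
    """Per-participant accumulator parameters.

    ``drift`` is a scalar (DDM) or one value per attribute (maDDM/stDDM), in
    evidence units per ms per value unit.  ``threshold`` is the absorbing
    bound on net evidence.  ``ndt`` (non-decision time) and ``start_times``
    are in seconds, both constrained to [0, 1].
    """

    kind: str
    drift: np.ndarray
    threshold: float
    ndt: float
    start_times: np.ndarray | None = None
    noise_var: float = DEFAULT_NOISE_VAR

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.drift = np.atleast_1d(np.asarray(self.drift, dtype=float))
        if not np.all(np.isfinite(self.drift)) or np.any(self.drift <= 0):
            raise ValueError("drift components must be finite and > 0")
        if self.kind == "ddm" and self.drift.size != 1:
            raise ValueError("ddm takes a single drift scalar")
        if not (np.isfinite(self.threshold) and self.threshold > 0):
            raise ValueError("threshold must be finite and > 0")
        if not (0.0 <= self.ndt <= 1.0):
            raise ValueError("ndt must lie in [0, 1] seconds")
        if self.start_times is None:
            self.start_times = np.zeros_like(self.drift)
        else:
            self.start_times = np.atleast_1d(np.asarray(self.start_times, dtype=float))
        if self.start_times.shape != self.drift.shape:
            raise ValueError("start_times must match drift shape")
        if np.any(self.start_times < 0) or np.any(self.start_times > 1):
            raise ValueError("start_times must lie in [0, 1] seconds")
        if self.kind != "stddm" and np.any(self.start_times != 0):
            raise ValueError("non-zero start_times only valid for stddm")
        if not (np.isfinite(self.noise_var) and self.noise_var >= 0):
            raise ValueError("noise_var must be finite and >= 0")  # 0 = noise-free limit

    @property
    def n_attributes(self) -> int:
        return self.drift.size


@dataclass
class TrialOutcome:
    """Result of one simulated choice trial.

    ``choice`` is 1 when option 1 was selected (net evidence hit the upper
    bound), 0 otherwise.  ``evidence`` is the final net evidence ``E``;
    ``decision_steps`` the crossing step ``T`` (ms, excludes NDT);
    ``evidence_attr`` / ``accum_steps_attr`` hold the per-attribute final
    difference evidence and effective accumulation durations used by the
    spreading-of-alternatives readout.
    """

    choice: int
    rt: float
    evidence: float
    decision_steps: int
    terminated: bool
    evidence_attr: np.ndarray = field(default_factory=lambda: np.zeros(0))
    accum_steps_attr: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))


def closed_form_choice_prob(v, threshold, sigma_d2):
    """P(upper bound first) for a Wiener process started midway between ±threshold.

    ``v`` is drift per step, ``sigma_d2`` the per-step variance of the
    *difference* process.  The absorbing-boundary solution is
    ``1 / (1 + exp(-2 * threshold * v / sigma_d2))``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.asarray(threshold) <= 0) or np.any(np.asarray(sigma_d2) <= 0):
        raise ValueError("threshold and sigma_d2 must be > 0")
    from scipy.special import expit

    return expit(2.0 * threshold * v / sigma_d2)


def closed_form_mean_dt(v, threshold, sigma_d2):
    """Expected decision time (steps) for the symmetric-start Wiener process.

    ``(threshold/v) * tanh(threshold*v/sigma_d2)`` for ``v != 0``, with the
    zero-drift limit ``threshold**2 / sigma_d2``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.asarray(threshold) <= 0) or np.any(np.asarray(sigma_d2) <= 0):
        raise ValueError("threshold and sigma_d2 must be > 0")
    out = np.empty_like(v, dtype=float)
    nz = v != 0
    with np.errstate(divide="ignore", invalid="ignore"):
        out[nz] = (threshold / v[nz]) * np.tanh(threshold * v[nz] / sigma_d2)
    out[~nz] = threshold**2 / sigma_d2
    return out if out.ndim else float(out)


def simulate_batch(
    drift_rates: np.ndarray,
    threshold: float | np.ndarray,
    rng: np.random.Generator,
    onset_steps: np.ndarray | None = None,
    noise_var: float = DEFAULT_NOISE_VAR,
    max_steps: int = MAX_STEPS,
    pre_onset: str = "silence",
    _block: int = 256,
) -> dict:
    """Vectorised first-passage simulation of attribute-stream accumulators.

    Parameters
    ----------
    drift_rates : (n_trials, n_attr) array
        Per-trial, per-attribute drift of the difference process
        (``delta_a * dmu_a``), evidence units per step.
    threshold : scalar or (n_trials,) array
        Absorbing bound on net evidence (sum over attributes).
    onset_steps : (n_trials, n_attr) int array, optional
        Step index before which an attribute contributes nothing.
    pre_onset : {"silence", "noise"}
        Before onset, either the whole increment is zeroed (default) or only
        the drift is zeroed while noise still accumulates.

    Returns a dict of arrays: ``choice``, ``decision_steps``, ``evidence``,
    ``evidence_attr``, ``accum_steps_attr``, ``terminated``.
    """
    drift_rates = np.atleast_2d(np.asarray(drift_rates, dtype=float))
    n_trials, n_attr = drift_rates.shape
    if not np.all(np.isfinite(drift_rates)):
        raise ValueError("drift_rates must be finite")
    if pre_onset not in ("silence", "noise"):
        raise ValueError("pre_onset must be 'silence' or 'noise'")
    theta = np.broadcast_to(np.asarray(threshold, dtype=float), (n_trials,)).copy()
    if np.any(~np.isfinite(theta)) or np.any(theta <= 0):
        raise ValueError("threshold must be finite and > 0")
    if onset_steps is None:
        onset = np.zeros((n_trials, n_attr), dtype=np.int64)
    else:
        onset = np.broadcast_to(
            np.asarray(onset_steps, dtype=np.int64), (n_trials, n_attr)
        ).copy()

    step_sd = np.sqrt(2.0 * noise_var)  # difference-process noise per stream

    choice = np.zeros(n_trials, dtype=np.int8)
    T = np.full(n_trials, max_steps, dtype=np.int64)
    E = np.zeros(n_trials)
    E_attr = np.zeros((n_trials, n_attr))
    terminated = np.zeros(n_trials, dtype=bool)

    active = np.arange(n_trials)
    state = np.zeros((n_trials, n_attr))  # per-attribute accumulated difference
    has_onset = bool(np.any(onset > 0))
    budget = 4_000_000  # elements per block chunk, caps peak memory
    t0 = 0
    while active.size and t0 < max_steps:
        na = active.size
        block = int(np.clip(budget // max(na * n_attr, 1), 64, 16384))
        block = min(block, max_steps - t0)
        if n_attr == 1 and not has_onset:
            inc = rng.standard_normal((na, block)) * step_sd
            inc += drift_rates[active]  # (na, 1) broadcasts over steps
            inc[:, 0] += state[active, 0]
            cum = np.cumsum(inc, axis=1)
            net = cum
            cum_attr = cum[:, :, None]
        else:
            eps = rng.standard_normal((na, block, n_attr)) * step_sd
            if has_onset:
                # steps t0+1 .. t0+block (1-based); attribute live once t > onset
                steps = np.arange(t0 + 1, t0 + block + 1)
                live = steps[None, :, None] > onset[active][:, None, :]
                if pre_onset == "silence":
                    inc = (eps + drift_rates[active][:, None, :]) * live
                else:
                    inc = eps + drift_rates[active][:, None, :] * live
            else:
                inc = eps + drift_rates[active][:, None, :]
            inc[:, 0, :] += state[active]
            cum_attr = np.cumsum(inc, axis=1)
            net = cum_attr.sum(axis=2)
            cum = None
        hit = np.abs(net) >= theta[active][:, None]
        any_hit = hit.any(axis=1)
        if any_hit.any():
            idx = np.argmax(hit, axis=1)  # first crossing within block
            done = active[any_hit]
            j = idx[any_hit]
            T[done] = t0 + j + 1
            E[done] = net[any_hit, j]
            E_attr[done] = cum_attr[any_hit, j, :]
            choice[done] = (E[done] > 0).astype(np.int8)
            terminated[done] = True
        still = ~any_hit
        state[active[still]] = cum_attr[still, -1, :]
        active = active[still]
        t0 += block

    # non-terminated trials keep the cap-step state for bookkeeping
    if active.size:
        E[active] = state[active].sum(axis=1)
        E_attr[active] = state[active]
        choice[active] = (E[active] > 0).astype(np.int8)

    accum = np.maximum(T[:, None] - onset, 0)
    return {
        "choice": choice,
        "decision_steps": T,
        "evidence": E,
        "evidence_attr": E_attr,
        "accum_steps_attr": accum,
        "terminated": terminated,
    }


def _single(params: ModelParams, drift_rates, onset_steps, seed, pre_onset) -> TrialOutcome:
    rng = np.random.default_rng(seed)
    out = simulate_batch(
        np.asarray(drift_rates, dtype=float)[None, :],
        params.threshold,
        rng,
        onset_steps=None if onset_steps is None else np.asarray(onset_steps)[None, :],
        noise_var=params.noise_var,
        pre_onset=pre_onset,
    )
    term = bool(out["terminated"][0])
    T = int(out["decision_steps"][0])
    return TrialOutcome(
        choice=int(out["choice"][0]),
        rt=(T / 1000.0 + params.ndt) if term else float("nan"),
        evidence=float(out["evidence"][0]),
        decision_steps=T,
        terminated=term,
        evidence_attr=out["evidence_attr"][0],
        accum_steps_attr=out["accum_steps_attr"][0],
    )


def simulate_ddm_trial(params: ModelParams, mu1: float, mu2: float, seed) -> TrialOutcome:
    """One classic-DDM trial with option values ``mu1``, ``mu2``."""
    if params.kind != "ddm":
        raise ValueError("params.kind must be 'ddm'")
    if not (np.isfinite(mu1) and np.isfinite(mu2)):
        raise ValueError("option values must be finite")
    return _single(params, [params.drift[0] * (mu1 - mu2)], None, seed, "silence")


def simulate_maddm_trial(params: ModelParams, mu1_attr, mu2_attr, seed) -> TrialOutcome:
    """One multi-attribute trial; ``mu1_attr``/``mu2_attr`` are per-attribute values."""
    if params.kind != "maddm":
        raise ValueError("params.kind must be 'maddm'")
    d = np.asarray(mu1_attr, dtype=float) - np.asarray(mu2_attr, dtype=float)
    if d.shape != params.drift.shape:
        raise ValueError("attribute count mismatch")
    if not np.all(np.isfinite(d)):
        raise ValueError("attribute values must be finite")
    return _single(params, params.drift * d, None, seed, "silence")


def simulate_stddm_trial(
    params: ModelParams, mu1_attr, mu2_attr, seed, pre_onset: str = "silence"
) -> TrialOutcome:
    """One start-time-DDM trial: attribute ``a`` joins at ``start_times[a]`` seconds."""
    if params.kind != "stddm":
        raise ValueError("params.kind must be 'stddm'")
    d = np.asarray(mu1_attr, dtype=float) - np.asarray(mu2_attr, dtype=float)
    if d.shape != params.drift.shape:
        raise ValueError("attribute count mismatch")
    if not np.all(np.isfinite(d)):
        raise ValueError("attribute values must be finite")
    onset = np.round(params.start_times * 1000.0).astype(np.int64)
    return _single(params, params.drift * d, onset, seed, pre_onset)


def simulate_cohort_trials(
    trials: pd.DataFrame,
    params_by_participant: dict,
    kind: str,
    seed: int,
    pre_onset: str = "silence",
) -> pd.DataFrame:
    """Simulate every trial of a derived-trial table under one model kind.

    ``trials`` must carry ``participant_id``, ``trial_id`` and the value
    differences ``dv`` (DDM) or ``dp``/``dn`` (maDDM/stDDM).  Drift per trial
    is the participant's drift scalar(s) applied to those differences.
    Returns the table with simulation columns appended (choice, rt, evidence,
    decision_steps, per-attribute evidence and accumulation steps,
    terminated).
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out_frames = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        p = params_by_participant[pid]
        if p.kind != kind:
            raise ValueError(f"participant {pid}: params are {p.kind!r}, wanted {kind!r}")
        if kind == "ddm":
            rates = p.drift[0] * grp["dv"].to_numpy()[:, None]
            onset = None
        else:
            d = grp[["dp", "dn"]].to_numpy()
            rates = p.drift[None, :] * d
            onset = (
                np.round(p.start_times * 1000.0).astype(np.int64)[None, :]
                if kind == "stddm"
                else None
            )
        res = simulate_batch(
            rates, p.threshold, rng, onset_steps=onset,
            noise_var=p.noise_var, pre_onset=pre_onset,
        )
        g = grp.copy()
        g["model"] = kind
        g["choice"] = res["choice"]
        g["decision_steps"] = res["decision_steps"]
        g["evidence"] = res["evidence"]
        g["terminated"] = res["terminated"]
        g["rt"] = np.where(
            res["terminated"], res["decision_steps"] / 1000.0 + p.ndt, np.nan
        )
        for a in range(res["evidence_attr"].shape[1]):
            g[f"evidence_attr_{a + 1}"] = res["evidence_attr"][:, a]
            g[f"accum_steps_attr_{a + 1}"] = res["accum_steps_attr"][:, a]
        out_frames.append(g)
    return pd.concat(out_frames, ignore_index=True)
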