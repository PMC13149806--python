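"""Spreading of alternatives (SoA) from the accumulator's final state.

After a choice, the accumulator's terminal state provides an "inferred"
value difference

    dV_T = E / (drift * T)

the final net evidence divided by drift efficiency and deliberation time.
The spread is the gap between this inferred difference and the anticipated
difference from pre-choice ratings, signed in chosen-minus-rejected
convention:

    SoA = C * (dV_T - dV),   C = +1 if option 1 chosen, -1 otherwise.

Two readouts are provided for the multi-attribute models, where "drift" is
a vector:

* ``"net"`` (default) — the literal formula with drift taken as the total
  drift mass ``sum_a delta_a``, so ``dV_T = E / (sum_a delta_a * T)``.
  Net evidence weights attributes by their drift shares
  ``delta_a / sum delta``, while the anticipated dV weights them by the
  rating weights; on high-disparity trials this mismatch makes the
  inferred value tilt systematically toward the attributes that dominate
  deliberation — the mechanism by which attribute information generates
  disparity-dependent spread.
* ``"per_attribute"`` — infer each attribute's value difference separately,
  ``dmu_hat_a = E_a / (delta_a * T_a)`` (``T_a`` the attribute's effective
  accumulation steps, shortened by its onset latency under the start-time
  model), and recombine with the participant's rating weights,
  ``dV_T = sum_a w_a * dmu_hat_a``.  This readout is exactly unbiased for
  the rating-scale value difference — it preserves the noise-free identity
  ``dV_T = dV`` — and for the same reason produces no systematic
  disparity effect.  An attribute that never entered accumulation
  (``T_a = 0``) contributes its anticipated difference unchanged: evidence
  never accrued for it, so it cannot spread.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ModelParams


def infer_dvt(
    evidence,
    decision_steps,
    params: ModelParams,
    readout: str = "net",
    weights=None,
    evidence_attr=None,
    accum_steps_attr=None,
    anticipated_attr=None,
):
    """Inferred value difference dV_T from a terminated trial.

    For the DDM both readouts coincide with ``E / (drift * T)``.  See the
    module docstring for the multi-attribute readouts.  ``weights`` (the
    participant's attribute weights) and the per-attribute state are needed
    only for ``readout="per_attribute"``.
    """
    T = np.asarray(decision_steps, dtype=float)
    if np.any(T < 1):
        raise ValueError("dV_T undefined for T < 1")
    if params.kind == "ddm":
        return np.asarray(evidence, dtype=float) / (params.drift[0] * T)
    if readout == "net":
        return np.asarray(evidence, dtype=float) / (params.drift.sum() * T)
    if readout != "per_attribute":
        raise ValueError("readout must be 'net' or 'per_attribute'")
    if weights is None or evidence_attr is None or accum_steps_attr is None:
        raise ValueError("per-attribute readout needs weights and per-attribute state")
    w = np.asarray(weights, dtype=float)
    if w.shape[-1] != params.n_attributes:
        raise ValueError("weights must have one entry per attribute")
    e_a = np.atleast_2d(np.asarray(evidence_attr, dtype=float))
    t_a = np.atleast_2d(np.asarray(accum_steps_attr, dtype=float))
    dmu_hat = np.empty_like(e_a)
    active = t_a > 0
    dmu_hat[active] = e_a[active] / (
        np.broadcast_to(params.drift, e_a.shape)[active] * t_a[active]
    )
    if (~active).any():
        if anticipated_attr is None:
            raise ValueError("an attribute never accumulated; anticipated_attr required")
        ant = np.broadcast_to(np.atleast_2d(anticipated_attr), e_a.shape)
        dmu_hat[~active] = ant[~active]
    out = (np.atleast_2d(w) * dmu_hat).sum(axis=-1)
    return out if np.ndim(evidence) else float(out[0])


def compute_soa(dv_t, dv, choice):
    """Chosen-minus-rejected spread: ``C * (dV_T - dV)`` with C = ±1."""
    c = np.where(np.asarray(choice) == 1, 1.0, -1.0)
    return c * (np.asarray(dv_t, dtype=float) - np.asarray(dv, dtype=float))


def compute_consistency(choice, dv):
    """1 when the chosen option had the higher pre-choice value, 0 otherwise.

    Ties (dv == 0) return NaN and are excluded from consistency summaries.
    """
    choice = np.asarray(choice)
    dv = np.asarray(dv, dtype=float)
    out = np.where((choice == 1) == (dv > 0), 1.0, 0.0)
    return np.where(dv == 0, np.nan, out)


def add_soa_columns(
    trials: pd.DataFrame, params_by_participant: dict, readout: str = "net"
) -> pd.DataFrame:
    """Append ``dv_inferred``, ``soa`` and ``consistent`` to a simulated table.

    ``trials`` must be the output of the simulator joined with the derived
    columns (dv, dp, dn, w_P, w_N); only terminated trials get a readout.
    """
    out = trials.copy()
    out["dv_inferred"] = np.nan
    for pid, grp in out.groupby("participant_id", sort=True):
        p = params_by_participant[pid]
        g = grp.loc[grp["terminated"].astype(bool)]
        if g.empty:
            continue
        if p.kind == "ddm" or readout == "net":
            dvt = infer_dvt(
                g["evidence"].to_numpy(), g["decision_steps"].to_numpy(), p,
                readout=readout,
            )
        else:
            dvt = infer_dvt(
                g["evidence"].to_numpy(),
                g["decision_steps"].to_numpy(),
                p,
                readout=readout,
                weights=g[["w_P", "w_N"]].to_numpy(),
                evidence_attr=g[["evidence_attr_1", "evidence_attr_2"]].to_numpy(),
                accum_steps_attr=g[["accum_steps_attr_1", "accum_steps_attr_2"]].to_numpy(),
                anticipated_attr=g[["dp", "dn"]].to_numpy(),
            )
        out.loc[g.index, "dv_inferred"] = dvt
    out["soa"] = compute_soa(out["dv_inferred"], out["dv"], out["choice"])
    out["consistent"] = compute_consistency(out["choice"], out["dv"])
    return out
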