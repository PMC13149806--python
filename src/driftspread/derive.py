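"""Per-trial derived quantities and exclusion rules.

For each choice trial between options i and j we compute the rating
differences ``dv = V_i - V_j`` (and ``dp``, ``dn`` for the attributes) and
the attribute disparity ``D``: the distance between the two options along
the iso-value direction of attribute space.  With per-participant attribute
weights ``(w_P, w_N)`` estimated by regressing overall value on the
attributes, the iso-value vector is ``[-w_P, w_N]`` and

    D = | ( [P_i N_i] - [P_j N_j] ) . [-w_P, w_N] | / ||[-w_P, w_N]||

D is zero when the options differ only in overall value (no attribute
conflict) and large when each option dominates on a different attribute at
similar overall value.  Exclusion rules: trials with RT below 0.5 s or above
10 s are dropped (boundary values retained), and participants whose choices
track their ratings too weakly — logistic slope of choice on dv below 1 —
are screened out.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger(__name__)

RT_MIN_S = 0.5
RT_MAX_S = 10.0
SCREEN_SLOPE_MIN = 1.0


def fit_attribute_weights(ratings: pd.DataFrame) -> pd.DataFrame:
    """Per-participant OLS of overall value on the two attributes.

    Returns one row per participant: ``w_P``, ``w_N``, ``intercept``,
    ``fit_r2`` and a ``flagged`` column set when the design is rank-deficient
    (e.g. P == N for all options) or an estimated weight is negative.
    """
    rows = []
    for pid, grp in ratings.groupby("participant_id", sort=True):
        if len(grp) < 3:
            raise ValueError(f"participant {pid}: need >= 3 rated options")
        X = sm.add_constant(grp[["P", "N"]].to_numpy())
        if np.linalg.matrix_rank(X) < 3:
            rows.append((pid, np.nan, np.nan, np.nan, np.nan, True))
            log.warning("participant %s: rank-deficient attribute design", pid)
            continue
        res = sm.OLS(grp["V"].to_numpy(), X).fit()
        w_p, w_n = res.params[1], res.params[2]
        flagged = bool(w_p < 0 or w_n < 0)
        if flagged:
            log.warning("participant %s: negative attribute weight (w_P=%.3g, w_N=%.3g)",
                        pid, w_p, w_n)
        rows.append((pid, w_p, w_n, res.params[0], res.rsquared, flagged))
    return pd.DataFrame(
        rows, columns=["participant_id", "w_P", "w_N", "intercept", "fit_r2", "flagged"]
    )


def compute_disparity(p_i, n_i, p_j, n_j, w_p, w_n):
    """Attribute disparity between two options (vectorised).

    Projection of the option difference onto the unit iso-value vector
    ``[-w_P, w_N] / ||.||``, in absolute value.  Symmetric in (i, j) and
    invariant to rescaling both weights by the same positive constant.
    """
    w_p = np.asarray(w_p, dtype=float)
    w_n = np.asarray(w_n, dtype=float)
    norm = np.hypot(w_p, w_n)
    if np.any(norm == 0):
        raise ValueError("disparity undefined for zero weight vector")
    num = (np.asarray(p_i) - np.asarray(p_j)) * (-w_p) + (
        np.asarray(n_i) - np.asarray(n_j)
    ) * w_n
    return np.abs(num) / norm


def compute_trial_differences(
    ratings: pd.DataFrame, pairings: pd.DataFrame, weights: pd.DataFrame
) -> pd.DataFrame:
    """Build the per-trial table of dv, dp, dn, |dv| and disparity.

    ``dv`` follows the option-1-minus-option-2 convention (option_i minus
    option_j), so swapping a pair flips dv's sign but leaves D unchanged.
    """
    idx = ratings.set_index(["participant_id", "option_id"])
    for col, opt in (("_i", "option_i"), ("_j", "option_j")):
        key = pd.MultiIndex.from_frame(pairings[["participant_id", opt]])
        missing = ~key.isin(idx.index)
        if missing.any():
            bad = pairings.loc[missing, ["participant_id", "trial_id"]].iloc[0]
            raise ValueError(
                f"missing rating for trial {bad['trial_id']} of participant "
                f"{bad['participant_id']}"
            )
    out = pairings.merge(
        ratings.rename(columns={"option_id": "option_i", "V": "V_i", "P": "P_i", "N": "N_i"}),
        on=["participant_id", "option_i"],
    ).merge(
        ratings.rename(columns={"option_id": "option_j", "V": "V_j", "P": "P_j", "N": "N_j"}),
        on=["participant_id", "option_j"],
    ).merge(weights[["participant_id", "w_P", "w_N"]], on="participant_id")
    out["dv"] = out["V_i"] - out["V_j"]
    out["dp"] = out["P_i"] - out["P_j"]
    out["dn"] = out["N_i"] - out["N_j"]
    out["abs_dv"] = out["dv"].abs()
    out["disparity"] = compute_disparity(
        out["P_i"], out["N_i"], out["P_j"], out["N_j"], out["w_P"], out["w_N"]
    )
    cols = [
        "participant_id", "trial_id", "option_i", "option_j",
        "dv", "dp", "dn", "abs_dv", "disparity", "w_P", "w_N",
    ]
    return out[cols].sort_values(["participant_id", "trial_id"]).reset_index(drop=True)


def filter_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop trials with RT < 0.5 s or > 10 s (and non-terminated simulations).

    Boundary RTs of exactly 0.5 and 10 s are retained.  Returns the filtered
    table (a pure row subset) and an exclusion log.
    """
    rt = trials["rt"]
    if (rt.dropna() < 0).any():
        raise ValueError("negative RT encountered: data-integrity error")
    not_term = (
        ~trials["terminated"].astype(bool)
        if "terminated" in trials
        else rt.isna()
    )
    too_fast = rt < RT_MIN_S
    too_slow = rt > RT_MAX_S
    keep = ~(too_fast | too_slow | not_term | rt.isna())
    logrec = {
        "n_total": int(len(trials)),
        "n_kept": int(keep.sum()),
        "n_too_fast": int(too_fast.sum()),
        "n_too_slow": int(too_slow.sum()),
        "n_not_terminated": int((not_term & ~too_slow).sum()),
        "excluded_fraction": float(1.0 - keep.mean()) if len(trials) else 0.0,
    }
    return trials.loc[keep].copy(), logrec


def _logistic_slope(choice: np.ndarray, dv: np.ndarray) -> float:
    """Slope of a univariate logistic regression of choice on dv.

    Complete separation is treated as slope = +inf (a perfectly consistent
    responder).
    """
    if choice.min() == choice.max():
        return np.inf if len(choice) else np.nan
    # separation check: all positive-dv chosen and negative-dv rejected
    if ((dv > 0) == (choice == 1)).all() and not np.any(dv == 0):
        return np.inf
    X = sm.add_constant(dv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(choice, X).fit(disp=0, maxiter=200)
        except Exception:
            return np.inf
    slope = float(res.params[1])
    if not np.isfinite(slope) or slope > 50:
        return np.inf
    return slope


def screen_participants(trials: pd.DataFrame, min_trials: int = 10) -> pd.DataFrame:
    """Flag participants whose choices track ratings too weakly.

    Per participant, a logistic regression of choice (option 1 = 1) on dv;
    participants with slope < 1 are dropped.  Complete separation keeps the
    participant with a warning (slope recorded as inf).
    """
    rows = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        if len(grp) < min_trials:
            rows.append((pid, np.nan, False, "too_few_trials"))
            continue
        slope = _logistic_slope(grp["choice"].to_numpy(), grp["dv"].to_numpy())
        if np.isinf(slope):
            log.warning("participant %s: complete separation in screening; kept", pid)
            rows.append((pid, slope, True, "separation"))
        else:
            rows.append((pid, slope, slope >= SCREEN_SLOPE_MIN, "ok"))
    return pd.DataFrame(rows, columns=["participant_id", "slope", "keep", "note"])
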