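"""Synthetic rating-and-choice cohorts.

The experimental design this emulates: participants rate a set of snack-food
options for overall value (V) and for two attributes — pleasure (P) and
nutrition (N) — then choose within pairs formed from the same options, each
option appearing in exactly one pair.

The generator draws per-participant attribute weights ``w_P, w_N > 0`` and
produces ratings on [0, 1] with ``V = clip(w_P * P + w_N * N + eta, 0, 1)``;
P and N share a configurable cross-option correlation (Gaussian copula with
uniform marginals).  True accumulator parameters for every model variant are
drawn from truncated-normal hyperpriors inside the bounds the fitting module
enforces, so parameter-recovery studies are well-posed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .config import CohortConfig, Hyperprior
from .simulate import ModelParams

log = logging.getLogger(__name__)


def _draw_truncnorm(h: Hyperprior, size, rng: np.random.Generator) -> np.ndarray:
    if h.sd == 0:
        return np.full(size, float(np.clip(h.mean, h.low, h.high)))
    a = (h.low - h.mean) / h.sd
    b = (h.high - h.mean) / h.sd
    return stats.truncnorm.rvs(a, b, loc=h.mean, scale=h.sd, size=size, random_state=rng)


def make_pairings(option_ids, seed) -> pd.DataFrame:
    """Uniformly random perfect matching of the options into choice trials.

    Every option appears in exactly one pair.  Deterministic given ``seed``
    (an int or a Generator).
    """
    option_ids = list(option_ids)
    if len(option_ids) % 2 != 0:
        raise ValueError("cannot pair an odd number of options")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(option_ids))
    rows = []
    for t in range(len(option_ids) // 2):
        i, j = perm[2 * t], perm[2 * t + 1]
        rows.append((t, option_ids[i], option_ids[j]))
    return pd.DataFrame(rows, columns=["trial_id", "option_i", "option_j"])


def generate_cohort(config: CohortConfig):
    """Generate ratings, pairings and true model parameters for a cohort.

    Returns ``(ratings, pairings, true_params)`` where ``ratings`` has one
    row per (participant, option) with columns V, P, N; ``pairings`` one row
    per choice trial; and ``true_params`` maps participant_id to a dict of
    :class:`~driftspread.simulate.ModelParams`, one per model kind.
    """
    if config.rating_noise_sd < 0:
        raise ValueError("rating_noise_sd must be >= 0")
    n_p, n_o = config.n_participants, config.n_options
    rng_attr = substream(config.seed, "attributes")
    rng_w = substream(config.seed, "weights")
    rng_eta = substream(config.seed, "rating_noise")
    rng_pair = substream(config.seed, "pairing")
    rng_par = substream(config.seed, "true_params")

    w_p = _draw_truncnorm(config.attr_weight_p, n_p, rng_w)
    w_n = _draw_truncnorm(config.attr_weight_n, n_p, rng_w)

    # P, N via Gaussian copula -> uniform marginals with target correlation
    rho = 2.0 * np.sin(np.pi * config.attr_correlation / 6.0)  # uniform->normal corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng_attr.multivariate_normal(np.zeros(2), cov, size=(n_p, n_o))
    pn = stats.norm.cdf(z)  # (n_p, n_o, 2) in [0, 1]

    eta = rng_eta.normal(0.0, config.rating_noise_sd, size=(n_p, n_o))
    v_raw = w_p[:, None] * pn[:, :, 0] + w_n[:, None] * pn[:, :, 1] + eta
    v = np.clip(v_raw, 0.0, 1.0)
    clipped = float(np.mean(v_raw != v))
    if clipped > 0.1:
        log.warning("%.1f%% of V ratings clipped to [0, 1]; weight recovery may bias",
                    100 * clipped)

    ratings = pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(n_p), n_o),
            "option_id": np.tile(np.arange(n_o), n_p),
            "V": v.ravel(),
            "P": pn[:, :, 0].ravel(),
            "N": pn[:, :, 1].ravel(),
        }
    )

    pair_frames = []
    for pid in range(n_p):
        pf = make_pairings(np.arange(n_o), rng_pair)
        pf.insert(0, "participant_id", pid)
        pair_frames.append(pf)
    pairings = pd.concat(pair_frames, ignore_index=True)

    hp = config.param_hyperpriors
    draws = {
        name: _draw_truncnorm(hp[name], n_p, rng_par)
        for name in ("drift", "drift_p", "drift_n", "threshold", "threshold_ma",
                     "ndt", "start_p", "start_n")
    }
    true_params = {}
    for pid in range(n_p):
        true_params[pid] = {
            "ddm": ModelParams(
                kind="ddm", drift=[draws["drift"][pid]],
                threshold=draws["threshold"][pid], ndt=draws["ndt"][pid],
            ),
            "maddm": ModelParams(
                kind="maddm",
                drift=[draws["drift_p"][pid], draws["drift_n"][pid]],
                threshold=draws["threshold_ma"][pid], ndt=draws["ndt"][pid],
            ),
            "stddm": ModelParams(
                kind="stddm",
                drift=[draws["drift_p"][pid], draws["drift_n"][pid]],
                threshold=draws["threshold_ma"][pid], ndt=draws["ndt"][pid],
                start_times=[draws["start_p"][pid], draws["start_n"][pid]],
            ),
        }
    meta = {
        "true_weights": pd.DataFrame(
            {"participant_id": np.arange(n_p), "w_P": w_p, "w_N": w_n}
        ),
        "clipped_fraction": clipped,
    }
    return ratings, pairings, true_params, meta


def params_to_json(true_params: dict) -> dict:
    """JSON-serialisable view of a true-parameter mapping."""
    out = {}
    for pid, by_kind in true_params.items():
        out[str(pid)] = {
            kind: {
                "drift": list(map(float, p.drift)),
                "threshold": float(p.threshold),
                "ndt": float(p.ndt),
                "start_times": list(map(float, p.start_times)),
                "noise_var": float(p.noise_var),
            }
            for kind, p in by_kind.items()
        }
    return out


def params_from_json(data: dict) -> dict:
    out = {}
    for pid, by_kind in data.items():
        out[int(pid)] = {
            kind: ModelParams(
                kind=kind,
                drift=d["drift"],
                threshold=d["threshold"],
                ndt=d["ndt"],
                start_times=d["start_times"],
                noise_var=d.get("noise_var", 0.5),
            )
            for kind, d in by_kind.items()
        }
    return out


def write_cohort(out_dir, ratings, pairings, true_params) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ratings.to_csv(out / "ratings.csv", index=False, float_format="%.10g")
    pairings.to_csv(out / "pairings.csv", index=False)
    (out / "true_params.json").write_text(
        json.dumps(params_to_json(true_params), indent=1, sort_keys=True)
    )
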