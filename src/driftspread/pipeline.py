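"""End-to-end orchestration: cohort -> trials -> spread -> analyses -> report.

Every stage is seeded from the single top-level seed through named
substreams, so a rerun with the same config produces byte-identical report
tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import analyze, cohort, derive, soa
from .config import PipelineConfig
from .fit import fit_cohort
from .simulate import simulate_cohort_trials

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def build_trial_table(config: PipelineConfig):
    """Generate the cohort and the derived per-trial table (no simulation yet)."""
    cfg = config.cohort.model_copy(update={"seed": config.seed})
    ratings, pairings, true_params, meta = cohort.generate_cohort(cfg)
    weights = derive.fit_attribute_weights(ratings)
    trials = derive.compute_trial_differences(ratings, pairings, weights)
    return ratings, pairings, true_params, weights, trials, meta


def simulate_and_analyze(config: PipelineConfig, out_dir: str | Path | None = None):
    """Run the full study under each configured model kind.

    Returns a report dict; when ``out_dir`` is given, writes trials CSVs,
    regression JSON, split and quantile-bin CSVs, and a manifest.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ratings, pairings, true_params, weights, trials, meta = build_trial_table(config)
    cohort.write_cohort(out, ratings, pairings, true_params)
    weights.to_csv(out / "attribute_weights.csv", index=False, float_format=_FLOAT_FMT)

    report = {"seed": config.seed, "models": {}, "exclusions": {}}
    split_frames, qbin_frames = [], []
    for kind in config.models:
        params = {pid: by_kind[kind] for pid, by_kind in true_params.items()}
        if config.use_fitted_params:
            sim0 = simulate_cohort_trials(trials, params, kind, config.seed)
            filt0, _ = derive.filter_trials(sim0)
            fits = fit_cohort(kind, filt0, seed=config.seed)
            params = {pid: fr.params for pid, fr in fits.items()}
            trials_k = trials[trials["participant_id"].isin(params)].copy()
        else:
            trials_k = trials
        stream = {"ddm": 5, "maddm": 6, "stddm": 7}[kind]
        sim = simulate_cohort_trials(trials_k, params, kind, config.seed * 10 + stream)
        filtered, excl = derive.filter_trials(sim)
        screened = derive.screen_participants(filtered)
        keep_ids = set(screened.loc[screened["keep"], "participant_id"])
        excl["n_participants_dropped"] = int(
            (~screened["keep"]).sum()
        )
        analysed = filtered[filtered["participant_id"].isin(keep_ids)].copy()
        analysed = soa.add_soa_columns(analysed, params)
        analysed.to_csv(out / f"trials_{kind}.csv", index=False, float_format=_FLOAT_FMT)

        regs = {
            "soa": analyze.run_soa_regression(analysed),
            "rt": analyze.run_rt_regression(analysed),
            "consistency": analyze.run_consistency_regression(analysed),
        }
        splits = pd.concat(
            [
                analyze.median_split_summary(analysed, "soa"),
                analyze.median_split_summary(analysed, "consistent"),
                analyze.median_split_summary(analysed, "rt", stat="median"),
            ],
            ignore_index=True,
        )
        splits.insert(0, "model", kind)
        split_frames.append(splits)
        for bin_var, split_var, outc in (
            ("abs_dv", "rt", "consistent"),
            ("rt", "abs_dv", "consistent"),
            ("abs_dv", "rt", "soa"),
            ("rt", "abs_dv", "soa"),
        ):
            q = analyze.quantile_bin_table(analysed, bin_var, split_var, outc)
            q.insert(0, "model", kind)
            q.insert(1, "bin_var", bin_var)
            qbin_frames.append(q)

        report["models"][kind] = {k: r.to_dict() for k, r in regs.items()}
        report["exclusions"][kind] = excl

    split_all = pd.concat(split_frames, ignore_index=True)
    split_all.to_csv(out / "median_splits.csv", index=False, float_format=_FLOAT_FMT)
    qbin_all = pd.concat(qbin_frames, ignore_index=True)
    qbin_all.to_csv(out / "quantile_bins.csv", index=False, float_format=_FLOAT_FMT)
    (out / "regressions.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "models": list(config.models),
        "n_participants": config.cohort.n_participants,
        "n_options": config.cohort.n_options,
        "clipped_rating_fraction": meta["clipped_fraction"],
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None):
    """Alias for :func:`simulate_and_analyze` (the full study)."""
    return simulate_and_analyze(config, out_dir)
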