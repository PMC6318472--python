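"""End-to-end orchestration: simulate -> metrics -> Tobit -> SCR GLM -> group stats.

One :class:`~chokelab.config.RunConfig` (a single JSON document) drives the
whole analysis.  Every stage is a pure function of the config and the
master seed — per-participant random streams are namespaced, so deleting
intermediates and re-running reproduces the report byte-identically
(timestamps are deliberately excluded from the payload).

Stages
------
1. simulate: cohort traits, trial schedules, Bernoulli outcomes, gamble
   choices, and 100 Hz skin-conductance traces.
2. metrics: success tables, choking scores, loss-aversion estimates
   (participants with boundary/sentinel estimates are excluded from
   loss-aversion analyses, mirroring standard practice).
3. tobit: random-intercept censored regression of the choking score on
   condition and mean-corrected loss aversion, Wald table and partial
   effects.
4. scr: per participant — band-pass filter, downsample, convolutional GLM
   with parametric modulators; plus the follow-up cell-indicator GLM.
5. group: one-sample t-tests per regressor, paired cell contrasts, and
   the difference-score regression coupling SCR hyperarousal to choking.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig
from .errors import ChokelabError, InferenceError
from .group import correlate_diffs, group_ttest, paired_cell_contrast
from .metrics import choking_scores, estimate_loss_aversion, success_table
from .scr import (bandpass_filter, build_design_matrix, canonical_scrf,
                  downsample, fit_scr_glm, indicator_recoding)
from .synthetic import (generate_cohort, generate_gamble_choices,
                        generate_scr_trace, participant_scr_gain)
from .tobit import (fit_tobit, make_design, partial_effect_reappraisal,
                    expected_choking, wald_inference)

__all__ = ["RunReport", "run_pipeline"]

log = logging.getLogger("chokelab.pipeline")

#: cell contrasts of the follow-up indicator analysis, as (name, cell_a, cell_b)
CONTRASTS = [
    ("failed_high_baseline_vs_success_high_baseline",
     "cell_baseline_failure_high:scrf", "cell_baseline_success_high:scrf"),
    ("failed_high_baseline_vs_failed_high_reappraisal",
     "cell_baseline_failure_high:scrf", "cell_reappraisal_failure_high:scrf"),
    ("failed_low_baseline_vs_failed_low_reappraisal",
     "cell_baseline_failure_low:scrf", "cell_reappraisal_failure_low:scrf"),
]


@dataclass
class RunReport:
    """Consolidated, JSON-serialisable pipeline report."""

    seed: int
    config_hash: str
    n_participants: int
    n_lambda_excluded: int
    mean_choking: dict
    tobit: dict
    scr_group: pd.DataFrame
    contrasts: pd.DataFrame
    diff_regression: dict
    outputs: dict = field(default_factory=dict)

    def payload(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_participants": self.n_participants,
            "n_lambda_excluded": self.n_lambda_excluded,
            "mean_choking": self.mean_choking,
            "tobit": self.tobit,
            "scr_group": self.scr_group.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "diff_regression": self.diff_regression,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.payload(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_hash(config: RunConfig) -> str:
    payload = config.to_dict()
    payload.pop("out_dir", None)  # a location, not a scientific input
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class _Stage:
    """Names the failing stage when a pipeline step raises."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, ChokelabError):
            raise ChokelabError(f"stage '{self.name}' failed: {exc}") from exc
        if isinstance(exc, ChokelabError):
            exc.args = (f"stage '{self.name}' failed: {exc}",)
        log.info("stage %s: done", self.name)
        return False


def run_pipeline(config: RunConfig | None = None,
                 write_outputs: bool = True) -> RunReport:
    """Execute all stages on a synthetic cohort; see module docstring.

    With ``write_outputs`` every tabular intermediate and the report are
    written under ``config.out_dir`` in the documented dialects (traces
    are regenerable from config + seed and are only written by the CLI's
    ``simulate`` verb, to keep run directories light).
    """
    if config is None:
        config = RunConfig()
    config.validate()
    seed = config.seed
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: simulate ------------------------------------------------
    with _Stage("simulate"):
        participants, trials = generate_cohort(config.cohort, seed)
        choices = pd.concat(
            [generate_gamble_choices(p, choice_noise=config.analysis.choice_noise,
                                     seed=seed)
             for p in participants], ignore_index=True)

    # -- stage 2: metrics -------------------------------------------------
    with _Stage("metrics"):
        perf = success_table(trials)
        scores = choking_scores(perf)
        lam_rows = []
        for p in participants:
            est = estimate_loss_aversion(
                choices[choices["participant_id"] == p.id],
                bounds=config.analysis.lambda_bounds)
            lam_rows.append({"participant_id": p.id, "lambda_hat": est.lam,
                             "noise": est.noise, "excluded": est.excluded,
                             "flags": ",".join(sorted(est.flags))})
        lam_table = pd.DataFrame(lam_rows)
        kept = lam_table[~lam_table["excluded"]]
        lambdas = kept.set_index("participant_id")["lambda_hat"]

    # -- stage 3: tobit ---------------------------------------------------
    with _Stage("tobit"):
        design = make_design(
            scores, lambdas,
            include_interaction=config.analysis.include_interaction)
        fit = fit_tobit(design,
                        random_intercept=config.analysis.random_intercept,
                        n_quad=config.analysis.n_quad, seed=seed)
        wald = wald_inference(fit)
        pe = partial_effect_reappraisal(fit)
        e_base = expected_choking(
            _xrow(fit, condition=0.0), fit)
        e_reap = expected_choking(
            _xrow(fit, condition=1.0), fit)
        tobit_summary = {
            "coefficients": {
                name: {"estimate": float(wald.loc[name, "estimate"]),
                       "se": float(wald.loc[name, "se"]),
                       "z": float(wald.loc[name, "z"]),
                       "p": float(wald.loc[name, "p"])}
                for name in wald.index
            },
            "sigma": fit.sigma,
            "tau": fit.tau,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_obs": fit.n_obs,
            "n_participants": fit.n_groups,
            "expected_choking_baseline_pp": e_base,
            "expected_choking_reappraisal_pp": e_reap,
            "partial_effect_reappraisal_pp": pe,
        }

    # -- stage 4: scr -----------------------------------------------------
    with _Stage("scr"):
        scr_cfg = config.scr
        basis = canonical_scrf(scr_cfg.analysis_rate)
        rec_basis = canonical_scrf(scr_cfg.sampling_rate)
        main_betas, cell_betas = [], []
        for p in participants:
            schedule = trials[trials["participant_id"] == p.id].reset_index(drop=True)
            gain = participant_scr_gain(scr_cfg.amplitude, seed, p.id)
            # hyperarousal scales with the participant's relative choke depth,
            # coupling sympathetic arousal to behavioural choking
            depth_ref = config.cohort.choke_depth_mean or 1.0
            rec = generate_scr_trace(
                schedule, scr_cfg.amplitude, noise_sd=scr_cfg.noise_sd,
                drift=scr_cfg.drift, seed=seed,
                sampling_rate=scr_cfg.sampling_rate, basis=rec_basis, gain=gain,
                arousal_scale=p.choke_depth / depth_ref)
            filt = bandpass_filter(rec, scr_cfg.filter_low, scr_cfg.filter_high,
                                   scr_cfg.filter_order)
            down = downsample(filt, scr_cfg.analysis_rate)
            dm = build_design_matrix(
                schedule, basis, scr_cfg.analysis_rate,
                center_modulators=config.analysis.center_modulators)
            main_betas.append(fit_scr_glm(down, dm).betas.rename(p.id))
            ind = indicator_recoding(
                schedule, basis, scr_cfg.analysis_rate,
                high_set=config.analysis.high_set, include_nuisance=True)
            cell_betas.append(fit_scr_glm(down, ind).betas.rename(p.id))
        main_df = pd.DataFrame(main_betas)
        cell_df = pd.DataFrame(cell_betas)

    # -- stage 5: group ---------------------------------------------------
    with _Stage("group"):
        rows = []
        for col in main_df.columns:
            if col == "const" or not col.endswith(":scrf"):
                continue
            vals = main_df[col].dropna()
            try:
                r = group_ttest(vals, name=col)
            except InferenceError:
                continue
            rows.append({"regressor": col, "n": r.n, "mean": r.mean, "t": r.t,
                         "df": r.df, "p": r.p, "ci_lo": r.ci95[0],
                         "ci_hi": r.ci95[1]})
        scr_group = pd.DataFrame(rows)

        crows = []
        for name, a, b in CONTRASTS:
            if a not in cell_df.columns or b not in cell_df.columns:
                continue
            pair = cell_df[[a, b]].dropna()
            r = paired_cell_contrast(pair[a], pair[b], name=name)
            crows.append({"contrast": name, "n": r.n, "mean_diff": r.mean,
                          "t": r.t, "df": r.df, "p": r.p})
        contrasts = pd.DataFrame(crows)

        # SCR hyperarousal difference vs behavioural choking difference
        wide = scores.pivot(index="participant_id", columns="condition",
                            values="choking_pp")
        choking_diff = (wide["baseline"] - wide["reappraisal"]).dropna()
        a, b = ("cell_baseline_failure_high:scrf",
                "cell_reappraisal_failure_high:scrf")
        diff_regression: dict = {}
        if a in cell_df.columns and b in cell_df.columns:
            scr_diff = (cell_df[a] - cell_df[b]).dropna()
            common = choking_diff.index.intersection(scr_diff.index)
            if len(common) >= 3:
                reg = correlate_diffs(choking_diff.loc[common],
                                      scr_diff.loc[common])
                diff_regression = {
                    "slope": reg.slope, "intercept": reg.intercept,
                    "r": reg.r, "t": reg.t, "df": reg.df, "p": reg.p,
                    "n": reg.n}

    mean_choking = (scores.groupby("condition")["choking_pp"].mean()
                    .round(6).to_dict())
    report = RunReport(
        seed=seed,
        config_hash=_config_hash(config),
        n_participants=len(participants),
        n_lambda_excluded=int(lam_table["excluded"].sum()),
        mean_choking=mean_choking,
        tobit=tobit_summary,
        scr_group=scr_group,
        contrasts=contrasts,
        diff_regression=diff_regression,
    )

    if write_outputs:
        with _Stage("write"):
            config.to_json(out / "config.json")
            cio.write_trials(trials, out / "trials.tsv")
            cio.write_choices(choices, out / "choices.tsv")
            perf.to_csv(out / "performance.tsv", sep="\t", index=False)
            scores.to_csv(out / "choking.tsv", sep="\t", index=False)
            lam_table.to_csv(out / "loss_aversion.tsv", sep="\t", index=False)
            with open(out / "tobit.json", "w") as fh:
                json.dump(tobit_summary, fh, indent=2, sort_keys=True)
                fh.write("\n")
            (out / "tobit.txt").write_text(_tobit_text(tobit_summary))
            scr_group.to_csv(out / "scr_group.tsv", sep="\t", index=False)
            contrasts.to_csv(out / "scr_contrasts.tsv", sep="\t", index=False)
            report.to_json(out / "report.json")
            report.outputs = {p.name: str(p) for p in sorted(out.iterdir())}
    return report


def _xrow(fit, condition: float, lambda_c: float = 0.0) -> np.ndarray:
    row = []
    for name in fit.beta.index:
        row.append({"const": 1.0, "condition": condition,
                    "lambda_c": lambda_c,
                    "condition_x_lambda_c": condition * lambda_c}[name])
    return np.array(row)


def _tobit_text(summary: dict) -> str:
    lines = ["Tobit regression of choking (percentage points)",
             f"n = {summary['n_obs']} rows, "
             f"{summary['n_participants']} participants",
             "",
             f"{'term':<22}{'estimate':>10}{'se':>10}{'z':>8}{'p':>10}"]
    for name, c in summary["coefficients"].items():
        lines.append(f"{name:<22}{c['estimate']:>10.3f}{c['se']:>10.3f}"
                     f"{c['z']:>8.2f}{c['p']:>10.4f}")
    lines += ["",
              f"sigma = {summary['sigma']:.3f}   tau = {summary['tau']:.3f}   "
              f"loglik = {summary['loglik']:.3f}",
              f"E[choking | baseline]    = {summary['expected_choking_baseline_pp']:.2f} pp",
              f"E[choking | reappraisal] = {summary['expected_choking_reappraisal_pp']:.2f} pp",
              f"partial effect of reappraisal = "
              f"{summary['partial_effect_reappraisal_pp']:.2f} pp",
              ""]
    return "\n".join(lines)
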