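"""Behavioral performance tables, the choking statistic and loss aversion.

The choking metric for one participant in one condition is the gap, in
percentage points, between the participant's success proportion at the
incentive level where their performance peaked and their success
proportion at the maximum ($100) incentive.  It is zero exactly when
performance peaks at $100 and positive otherwise, so it is left-censored
at zero by construction — the reason the downstream regression is a
Tobit rather than OLS.

Loss aversion (lambda) is estimated from mixed-gamble accept/reject
choices by maximum likelihood under the same logistic choice model the
generator uses: accept with probability
``logistic(0.5 * (gain - lambda * loss) / noise)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_expit

from .config import INCENTIVE_LEVELS
from .errors import DomainError

__all__ = [
    "success_table",
    "complete_participants",
    "choking_score",
    "choking_scores",
    "LossAversionEstimate",
    "estimate_loss_aversion",
]

MAX_INCENTIVE = max(INCENTIVE_LEVELS)
N_CELLS = 2 * len(INCENTIVE_LEVELS)


def success_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant success proportions by condition x incentive.

    Returns a tidy table with columns participant_id, condition,
    incentive, n_trials, n_success, proportion, complete.  ``complete``
    is True for participants with at least one trial in every one of the
    10 (condition x incentive) cells; incomplete participants are
    excluded downstream (with a warning) rather than imputed.  Empty
    input yields an empty table.
    """
    cols = ["participant_id", "condition", "incentive",
            "n_trials", "n_success", "proportion", "complete"]
    if len(trials) == 0:
        return pd.DataFrame(columns=cols)
    grouped = (
        trials.assign(success=lambda d: (d["outcome"] == "success").astype(int))
        .groupby(["participant_id", "condition", "incentive"], sort=True)
        .agg(n_trials=("success", "size"), n_success=("success", "sum"))
        .reset_index()
    )
    grouped["proportion"] = grouped["n_success"] / grouped["n_trials"]
    n_cells = grouped.groupby("participant_id")["incentive"].size()
    complete = n_cells[n_cells == N_CELLS].index
    grouped["complete"] = grouped["participant_id"].isin(complete)
    return grouped[cols]


def complete_participants(perf: pd.DataFrame) -> list[str]:
    """Participants with all 10 cells populated."""
    if len(perf) == 0:
        return []
    return sorted(perf.loc[perf["complete"], "participant_id"].unique())


def choking_score(row: Mapping[int, float]) -> float:
    """Choking statistic for one condition's per-incentive proportions.

    ``100 * (max over incentive levels of proportion - proportion at the
    maximum incentive)`` in percentage points; >= 0 by construction and 0
    exactly when the $100 cell attains the row maximum.
    """
    missing = [lev for lev in INCENTIVE_LEVELS if lev not in row]
    if missing:
        raise DomainError(f"missing incentive level(s): {missing}")
    props = np.array([float(row[lev]) for lev in INCENTIVE_LEVELS])
    if np.any(props < 0) or np.any(props > 1):
        raise DomainError("proportions must lie in [0, 1]")
    return float(100.0 * (props.max() - float(row[MAX_INCENTIVE])))


def choking_scores(perf: pd.DataFrame) -> pd.DataFrame:
    """Choking score per (participant x condition) from a success table.

    Incomplete participants are skipped with a warning and do not appear
    in the output (listwise exclusion).
    """
    rows = []
    if len(perf) == 0:
        return pd.DataFrame(columns=["participant_id", "condition", "choking_pp"])
    incomplete = sorted(set(perf["participant_id"]) -
                        set(complete_participants(perf)))
    if incomplete:
        warnings.warn(
            f"excluding participants with incomplete cells: {incomplete}",
            stacklevel=2)
    keep = perf[perf["complete"]]
    for (pid, cond), grp in keep.groupby(["participant_id", "condition"],
                                         sort=True):
        row = dict(zip(grp["incentive"].astype(int), grp["proportion"]))
        rows.append({"participant_id": pid, "condition": cond,
                     "choking_pp": choking_score(row)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loss aversion


@dataclass
class LossAversionEstimate:
    """Maximum-likelihood loss aversion with diagnostic flags.

    flags may contain 'non_identifiable' (no variation in choices),
    'boundary' (estimate at a search bound) and 'exclusion' (estimate at
    a bound or sentinel value, marking the participant for removal from
    analyses involving loss aversion).
    """

    lam: float
    noise: float
    loglik: float
    converged: bool
    flags: set[str] = field(default_factory=set)

    @property
    def excluded(self) -> bool:
        return "exclusion" in self.flags


def _choice_negll(params: np.ndarray, gains: np.ndarray, losses: np.ndarray,
                  accepted: np.ndarray) -> float:
    log_lam, log_noise = params
    pv = 0.5 * (gains - np.exp(log_lam) * losses) / np.exp(log_noise)
    # log P(accept) = log_expit(pv); log P(reject) = log_expit(-pv)
    ll = np.where(accepted, log_expit(pv), log_expit(-pv))
    return -float(ll.sum())


def estimate_loss_aversion(
    choices: pd.DataFrame,
    bounds: tuple[float, float] = (0.05, 10.0),
) -> LossAversionEstimate:
    """Fit (lambda, choice noise) to mixed-gamble choices by ML.

    The optimisation runs on log scale within ``bounds`` for lambda.
    All-accept or all-reject choice sets are non-identifiable: the
    estimate is pinned at the corresponding bound and flagged, never
    raised as an exception.  Estimates at a bound (which subsumes the
    sentinel values 0 and 10 under the default bounds) carry an
    'exclusion' flag mirroring removal of degenerate estimates from
    loss-aversion analyses.
    """
    lo, hi = bounds
    if not 0 < lo < hi:
        raise DomainError("bounds must satisfy 0 < lo < hi")
    gains = choices["gain"].to_numpy(dtype=float)
    losses = choices["loss"].to_numpy(dtype=float)
    accepted = choices["accepted"].to_numpy(dtype=bool)
    if len(gains) == 0:
        raise DomainError("no choices provided")
    if np.any(gains <= 0) or np.any(losses <= 0):
        raise DomainError("mixed gambles require gain > 0 and loss > 0")

    if accepted.all() or (~accepted).all():
        lam = lo if accepted.all() else hi
        return LossAversionEstimate(
            lam=lam, noise=np.nan, loglik=0.0, converged=False,
            flags={"non_identifiable", "boundary", "exclusion"})

    best = None
    for lam0 in (0.5, 1.0, 2.0, 4.0):
        res = optimize.minimize(
            _choice_negll,
            x0=np.array([np.log(lam0), np.log(2.0)]),
            args=(gains, losses, accepted),
            method="L-BFGS-B",
            bounds=[(np.log(lo), np.log(hi)), (np.log(1e-2), np.log(1e3))],
        )
        if best is None or res.fun < best.fun:
            best = res
    lam = float(np.exp(best.x[0]))
    noise = float(np.exp(best.x[1]))
    flags: set[str] = set()
    if lam <= lo * (1 + 1e-3) or lam >= hi * (1 - 1e-3):
        flags |= {"boundary", "exclusion"}
    # sentinel values marking degenerate estimates even with wider bounds
    if lam <= 0.05 or lam >= 10.0:
        flags.add("exclusion")
    return LossAversionEstimate(lam=lam, noise=noise, loglik=-float(best.fun),
                                converged=bool(best.success), flags=flags)
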