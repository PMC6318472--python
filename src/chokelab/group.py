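"""Group-level inference on per-participant parameter estimates.

Mirrors the between-subject stage of a two-level psychophysiology
analysis: each participant contributes one amplitude estimate per
regressor, and group effects are one-sample two-tailed t-tests of those
estimates against zero; cell contrasts are paired t-tests on
within-participant differences; brain/physiology-behaviour coupling is a
simple regression of one difference score on another.  All p-values are
reported raw (no multiplicity correction).  Degenerate inputs (n too
small, zero variance) raise :class:`InferenceError` rather than emitting
NaN statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InferenceError

__all__ = [
    "GroupTestResult",
    "DiffRegression",
    "group_ttest",
    "paired_cell_contrast",
    "correlate_diffs",
]


@dataclass
class GroupTestResult:
    """One-sample (or paired-difference) t-test summary."""

    regressor_name: str
    n: int
    mean: float
    t: float
    df: int
    p: float
    ci95: tuple[float, float]


def group_ttest(estimates, name: str = "") -> GroupTestResult:
    """Two-tailed one-sample t-test of per-participant estimates against 0."""
    x = np.asarray(estimates, dtype=float)
    if len(x) < 2:
        raise InferenceError(f"group test needs n >= 2, got n = {len(x)}")
    if not np.all(np.isfinite(x)):
        raise InferenceError("non-finite estimates in group test")
    sd = x.std(ddof=1)
    n = len(x)
    mean = float(x.mean())
    if sd <= 1e-12 * max(1.0, abs(mean)):
        raise InferenceError("zero variance across participants")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = float(2 * stats.t.sf(abs(t), df))
    half = float(stats.t.ppf(0.975, df) * se)
    return GroupTestResult(regressor_name=name, n=n, mean=mean, t=float(t),
                           df=df, p=p, ci95=(mean - half, mean + half))


def paired_cell_contrast(cell_a, cell_b, name: str = "") -> GroupTestResult:
    """Paired t-test of two per-participant cell estimates (a minus b).

    Participants missing either cell must be excluded by the caller
    (pairwise deletion); inputs must be aligned per participant.
    """
    a = np.asarray(cell_a, dtype=float)
    b = np.asarray(cell_b, dtype=float)
    if a.shape != b.shape:
        raise InferenceError("cell vectors are not aligned")
    if len(a) < 2:
        raise InferenceError("paired contrast needs >= 2 complete pairs")
    return group_ttest(a - b, name=name)


@dataclass
class DiffRegression:
    """Simple regression of one difference score on another."""

    slope: float
    intercept: float
    r: float
    t: float
    df: int
    p: float
    n: int


def correlate_diffs(x_diff, y_diff) -> DiffRegression:
    """Regress per-participant difference scores y on x.

    Returns the slope with its t-test (df = n - 2) and the Pearson
    correlation; symmetric in x and y as far as r and the t statistic of
    the association are concerned.
    """
    x = np.asarray(x_diff, dtype=float)
    y = np.asarray(y_diff, dtype=float)
    if x.shape != y.shape:
        raise InferenceError("difference-score vectors are not aligned")
    n = len(x)
    if n < 3:
        raise InferenceError(f"difference regression needs n >= 3, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InferenceError("non-finite difference scores")
    if x.std() == 0:
        raise InferenceError("constant predictor in difference regression")
    if y.std() == 0:
        raise InferenceError("constant response in difference regression")
    res = stats.linregress(x, y)
    r = float(res.rvalue)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    return DiffRegression(slope=float(res.slope), intercept=float(res.intercept),
                          r=r, t=float(t), df=df, p=float(res.pvalue), n=n)
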