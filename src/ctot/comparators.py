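"""Conventional comparison methods for censored qPCR data.

These are the approaches the CTOT methodology is benchmarked against:

* **MC (maximum cycle)** — replace every censored target Ct by the
  cutoff, then a two-sample t-test on the delta-Ct values.
* **CO (complete observations)** — discard censored samples, then a
  t-test on the remainder; when a group drops below two samples the
  analysis is not possible (the CNA outcome), reported explicitly.
* **equal-variance t** — the commercial-tool pipeline: target Ct values
  at or above the tool's maximum cutoff (default 40) are capped there,
  followed by a pooled-variance two-sample two-tailed t-test.

Delta-Ct is ``target Ct - normalizer Ct`` throughout.  The t-tests are
scipy's; only the censoring bookkeeping is this package's.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .dataio import AnalysisFrame
from .errors import AnalysisNotPossible, DataValidationError

__all__ = ["ComparatorResult", "mc_method", "co_method", "equal_variance_t"]


@dataclass(frozen=True)
class ComparatorResult:
    method: str               # "MC" | "CO" | "t-equal-var"
    p_value: float
    statistic: float
    df: float
    n1_used: int
    n2_used: int
    n_imputed: int            # 0 for CO
    n_dropped: int            # 0 for MC
    variant: str              # "welch" | "pooled"
    group_levels: Optional[tuple] = None


def _split_delta(frame: AnalysisFrame, ct: np.ndarray):
    delta = ct - frame.normalizer_ct
    g = frame.group
    return delta[g == 0], delta[g == 1]


def _ttest(a: np.ndarray, b: np.ndarray, variant: str):
    if len(a) < 2 or len(b) < 2:
        raise AnalysisNotPossible(
            f"analysis not possible: a group has fewer than 2 observations "
            f"(n1={len(a)}, n2={len(b)})"
        )
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue), float(res.df)


def _require_two_group(frame: AnalysisFrame):
    if frame.mode != "two-group":
        raise DataValidationError("comparator methods require a two-group frame")


def mc_method(frame: AnalysisFrame, variant: str = "welch") -> ComparatorResult:
    """Maximum-cycle imputation followed by a two-sided t-test.

    Censored target Ct values (at or above the cutoff) are set equal to
    the cutoff before delta-Ct is formed; nothing is dropped.  The
    default t-variant is Welch; ``variant="pooled"`` gives the
    equal-variance form.
    """
    _require_two_group(frame)
    censored = frame.ct >= frame.cutoff
    ct = np.where(censored, frame.cutoff, frame.ct)
    a, b = _split_delta(frame, ct)
    stat, p, df = _ttest(a, b, variant)
    return ComparatorResult(
        method="MC", p_value=p, statistic=stat, df=df,
        n1_used=len(a), n2_used=len(b),
        n_imputed=int(censored.sum()), n_dropped=0,
        variant=variant, group_levels=frame.group_levels,
    )


def co_method(frame: AnalysisFrame, variant: str = "welch") -> ComparatorResult:
    """Complete-observation analysis: censored samples are excluded.

    Raises :class:`~ctot.errors.AnalysisNotPossible` when exclusion
    leaves a group with fewer than two samples — the CNA outcome,
    reported explicitly rather than silently skipped.
    """
    _require_two_group(frame)
    keep = frame.ct < frame.cutoff
    delta = (frame.ct - frame.normalizer_ct)[keep]
    g = frame.group[keep]
    a, b = delta[g == 0], delta[g == 1]
    stat, p, df = _ttest(a, b, variant)
    return ComparatorResult(
        method="CO", p_value=p, statistic=stat, df=df,
        n1_used=len(a), n2_used=len(b),
        n_imputed=0, n_dropped=int((~keep).sum()),
        variant=variant, group_levels=frame.group_levels,
    )


def equal_variance_t(frame: AnalysisFrame, commercial_cap: float = 40.0) -> ComparatorResult:
    """Commercial-tool pipeline: cap at the tool maximum, pooled t-test.

    Target Ct values at or above ``commercial_cap`` (default 40) are
    replaced by the cap — e.g. a recorded Ct of 50 is analyzed as 40 —
    then a two-sample, unpaired, two-tailed t-test assuming equal
    variances is applied to the delta-Ct values.
    """
    _require_two_group(frame)
    capped = frame.ct >= commercial_cap
    ct = np.where(capped, commercial_cap, frame.ct)
    a, b = _split_delta(frame, ct)
    stat, p, df = _ttest(a, b, "pooled")
    return ComparatorResult(
        method="t-equal-var", p_value=p, statistic=stat, df=df,
        n1_used=len(a), n2_used=len(b),
        n_imputed=int(capped.sum()), n_dropped=0,
        variant="pooled", group_levels=frame.group_levels,
    )
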