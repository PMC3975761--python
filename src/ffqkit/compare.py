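"""Statistical comparison of two processing runs.

Per-variable summary statistics (mean, sample SD, median, min, max),
quintile cut-points computed from a designated *reference* run, and the
quintile-shift tabulation: how many participants land in a different
quintile when the same cohort is processed under a second configuration,
and how many move by more than one quintile. Because cut-points come from
the reference run only, the comparison is deliberately asymmetric.

Quintile boundary rule: value <= cutpoint_k puts the value in quintile <= k
(ties go to the lower quintile). The percentile definition is a named,
swappable policy; the default is inclusive linear interpolation between
closest ranks, matching common statistical software.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStats",
    "ShiftReport",
    "summarize",
    "quintile_cutpoints",
    "assign_quintiles",
    "quintile_shift",
    "compare_runs",
    "PERCENTILE_POLICIES",
]

#: Named percentile policies (numpy interpolation methods).
PERCENTILE_POLICIES: dict[str, str] = {
    "inclusive_linear": "linear",
    "exclusive": "weibull",
    "nearest_rank": "inverted_cdf",
}


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    minimum: float
    maximum: float


@dataclass(frozen=True)
class ShiftReport:
    variable: str
    cutpoints: tuple[float, float, float, float]
    n: int
    n_changed: int
    pct_changed: float
    n_changed_gt1: int
    pct_changed_gt1: float


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample (n-1) SD, median, min, max of a non-empty vector."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty vector")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=sd,
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def quintile_cutpoints(
    reference: Sequence[float], policy: str = "inclusive_linear"
) -> tuple[float, float, float, float]:
    """20th/40th/60th/80th percentiles of the reference run's values."""
    arr = np.asarray(reference, dtype=float)
    if arr.size < 5:
        raise ValueError(f"need at least 5 reference values, got {arr.size}")
    method = PERCENTILE_POLICIES[policy]
    cps = np.percentile(arr, [20, 40, 60, 80], method=method)
    return tuple(float(c) for c in cps)  # type: ignore[return-value]


def assign_quintiles(
    values: Sequence[float], cutpoints: Sequence[float]
) -> np.ndarray:
    """Quintile (1-5) per value: value <= cutpoint_k => quintile <= k."""
    arr = np.asarray(values, dtype=float)
    cps = np.asarray(cutpoints, dtype=float)
    return 1 + (arr[:, None] > cps[None, :]).sum(axis=1)


def quintile_shift(
    reference_values: Sequence[float],
    new_values: Sequence[float],
    ids: Sequence[str],
    variable: str = "",
    policy: str = "inclusive_linear",
) -> ShiftReport:
    """Bin both runs with reference-derived cut-points and count movers."""
    ref = np.asarray(reference_values, dtype=float)
    new = np.asarray(new_values, dtype=float)
    if not (len(ref) == len(new) == len(ids)):
        raise ValueError(
            f"misaligned inputs: {len(ref)} reference, {len(new)} new, {len(ids)} ids"
        )
    cps = quintile_cutpoints(ref, policy)
    q_ref = assign_quintiles(ref, cps)
    q_new = assign_quintiles(new, cps)
    moved = np.abs(q_new - q_ref)
    n = len(ref)
    n_changed = int((moved > 0).sum())
    n_gt1 = int((moved > 1).sum())
    return ShiftReport(
        variable=variable,
        cutpoints=cps,
        n=n,
        n_changed=n_changed,
        pct_changed=100.0 * n_changed / n,
        n_changed_gt1=n_gt1,
        pct_changed_gt1=100.0 * n_gt1 / n,
    )


def compare_runs(
    reference: pd.DataFrame,
    new: pd.DataFrame,
    by: str | None = None,
    policy: str = "inclusive_linear",
) -> pd.DataFrame:
    """Per-variable comparison table of two wide (format-1 style) runs.

    Both frames need an ``id`` column and identical variable columns; rows
    are aligned by id (inner join order = reference order). With ``by`` set
    to a column of the reference frame (e.g. participant sex), every
    statistic — including the quintile cut-points — is computed per stratum.
    Returns one row per (stratum,) variable mirroring a summary table:
    median/mean/SD/min/max for each run plus shift counts and percentages.
    """
    strata = [None] if by is None else list(dict.fromkeys(reference[by]))
    variables = [c for c in reference.columns if c not in ("id", by)]
    new_indexed = new.set_index("id")
    rows = []
    for stratum in strata:
        ref_s = reference if stratum is None else reference[reference[by] == stratum]
        ids = [i for i in ref_s["id"] if i in new_indexed.index]
        ref_s = ref_s.set_index("id").loc[ids]
        new_s = new_indexed.loc[ids]
        for var in variables:
            ref_vals = ref_s[var].astype(float).to_numpy()
            new_vals = new_s[var].astype(float).to_numpy()
            s_ref = summarize(ref_vals)
            s_new = summarize(new_vals)
            shift = quintile_shift(ref_vals, new_vals, ids, var, policy)
            rows.append(
                {
                    "stratum": stratum if stratum is not None else "all",
                    "variable": var,
                    "n": s_ref.n,
                    "ref_median": s_ref.median,
                    "ref_mean": s_ref.mean,
                    "ref_sd": s_ref.sd,
                    "ref_min": s_ref.minimum,
                    "ref_max": s_ref.maximum,
                    "new_median": s_new.median,
                    "new_mean": s_new.mean,
                    "new_sd": s_new.sd,
                    "new_min": s_new.minimum,
                    "new_max": s_new.maximum,
                    "n_changed": shift.n_changed,
                    "pct_changed": shift.pct_changed,
                    "n_changed_gt1": shift.n_changed_gt1,
                    "pct_changed_gt1": shift.pct_changed_gt1,
                }
            )
    return pd.DataFrame(rows)
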